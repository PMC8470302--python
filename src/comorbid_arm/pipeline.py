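"""End-to-end orchestration: cohort -> transactions -> tables -> rules -> graphs.

A run takes one input source (a records CSV, an exact-marginal spec, or
a stochastic generator config), analyses the pooled cohort plus each
requested principal-diagnosis subgroup, and writes a fixed-layout
report bundle::

    <out>/
      manifest.json                  config echo + versions + seed
      run.log
      records.csv                    the analysed cohort
      prevalence_<flag>.csv          per-subgroup prevalence + chi-square
      <SG>_transactions.csv
      <SG>_frequency.csv             blocks above the support threshold
      <SG>_rules.csv                 report table, 3-dp fixed formatting
      <SG>_rules_raw.csv             same rules, full float precision
      <SG>_graph.graphml             top-rule network

Identical config plus deterministic input reproduces the bundle
byte-identically (the manifest carries everything needed to rerun).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .icd import MoodSubgroup
from .mining import AprioriMiner, MiningConfig, rules_to_frame
from .network import build_rule_graph, export_graph
from .prevalence import (
    DegenerateTableError,
    block_relative_frequency,
    format_p,
    prevalence_chi_square,
    prevalence_table,
)
from .records import DischargeRecord, read_records, write_records
from .synthetic import (
    ExactCohortSpec,
    PlantedAssociation,
    StochasticCohortConfig,
    generate_exact_cohort,
    generate_random_cohort,
)
from .transactions import build_transactions, write_transactions

__all__ = ["PipelineConfig", "ReportBundle", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_SUBGROUPS = (
    MoodSubgroup.ALL,
    MoodSubgroup.MANIC,
    MoodSubgroup.BIPOLAR,
    MoodSubgroup.DEPRESSIVE,
    MoodSubgroup.RECURRENT_DEPRESSIVE,
    MoodSubgroup.PERSISTENT,
    MoodSubgroup.OTHER,
    MoodSubgroup.UNSPECIFIED,
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    output_dir: Path
    records_csv: Path | None = None
    exact_spec: ExactCohortSpec | None = None
    stochastic: StochasticCohortConfig | None = None
    subgroups: Sequence[MoodSubgroup] = ALL_SUBGROUPS
    mining: MiningConfig = field(default_factory=MiningConfig)
    frequency_threshold: float = 0.05
    max_graph_rules: int = 20
    top_k_report: int = 5
    unknown_codes: str = "skip"
    same_block_policy: str = "keep"
    log_level: str = "INFO"

    def validate(self) -> None:
        sources = [self.records_csv, self.exact_spec, self.stochastic]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one input source required: records_csv, exact_spec or stochastic"
            )
        if self.records_csv is not None and not Path(self.records_csv).exists():
            raise FileNotFoundError(self.records_csv)

    @property
    def seed(self) -> int | None:
        return self.stochastic.seed if self.stochastic is not None else None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base_dir: Path | None = None) -> "PipelineConfig":
        base = Path(base_dir) if base_dir else Path.cwd()

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        source = raw.get("input", {})
        exact = stochastic = records_csv = None
        if "records_csv" in source:
            records_csv = resolve(source["records_csv"])
        elif "exact" in source:
            e = source["exact"]
            exact = ExactCohortSpec(
                n=int(e["n"]),
                subgroup=MoodSubgroup(e.get("subgroup", "ALL")),
                block_counts={k: int(v) for k, v in e.get("block_counts", {}).items()},
                joint_counts={
                    tuple(j["items"]): int(j["count"]) for j in e.get("joint_counts", [])
                },
            )
        elif "stochastic" in source:
            s = dict(source["stochastic"])
            planted = tuple(
                PlantedAssociation(p["block_a"], p["block_b"], float(p["p_pair"]))
                for p in s.pop("planted_associations", [])
            )
            kwargs = {"seed": int(s.pop("seed"))}
            if planted:
                kwargs["planted_associations"] = planted
            if "n_per_subgroup" in s:
                kwargs["n_per_subgroup"] = {
                    MoodSubgroup(k): int(v) for k, v in s.pop("n_per_subgroup").items()
                }
            for key in ("demographics", "base_block_prevalence", "max_additional"):
                if key in s:
                    kwargs[key] = s.pop(key)
            stochastic = StochasticCohortConfig(**kwargs)
        mining = MiningConfig(**raw.get("mining", {}))
        return cls(
            output_dir=resolve(raw["output_dir"]),
            records_csv=records_csv,
            exact_spec=exact,
            stochastic=stochastic,
            subgroups=tuple(MoodSubgroup(s) for s in raw.get("subgroups", [])) or ALL_SUBGROUPS,
            mining=mining,
            frequency_threshold=float(raw.get("frequency_threshold", 0.05)),
            max_graph_rules=int(raw.get("max_graph_rules", 20)),
            top_k_report=int(raw.get("top_k_report", 5)),
            unknown_codes=raw.get("unknown_codes", "skip"),
            same_block_policy=raw.get("same_block_policy", "keep"),
            log_level=raw.get("log_level", "INFO"),
        )


@dataclass
class ReportBundle:
    output_dir: Path
    manifest: dict
    files: dict[str, Path]


def _config_echo(config: PipelineConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, MoodSubgroup):
            return obj.value
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, Mapping):
            return {str(encode(k)): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, set, frozenset)):
            return [encode(v) for v in obj]
        return obj

    return {
        "output_dir": str(config.output_dir),
        "records_csv": str(config.records_csv) if config.records_csv else None,
        "exact_spec": encode(config.exact_spec) if config.exact_spec else None,
        "stochastic": encode(config.stochastic) if config.stochastic else None,
        "subgroups": [s.value for s in config.subgroups],
        "mining": encode(config.mining),
        "frequency_threshold": config.frequency_threshold,
        "max_graph_rules": config.max_graph_rules,
        "top_k_report": config.top_k_report,
        "unknown_codes": config.unknown_codes,
        "same_block_policy": config.same_block_policy,
        "seed": config.seed,
    }


def _load_cohort(config: PipelineConfig) -> list[DischargeRecord]:
    if config.records_csv is not None:
        return read_records(config.records_csv)
    if config.exact_spec is not None:
        return generate_exact_cohort(config.exact_spec)
    return generate_random_cohort(config.stochastic)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage for each requested subgroup."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("comorbid_arm")
    root.addHandler(handler)
    root.setLevel(config.log_level)

    files: dict[str, Path] = {}
    stage = "load-cohort"
    try:
        records = _load_cohort(config)
        logger.info("stage %s: %d records", stage, len(records))
        write_records(records, out / "records.csv")
        files["records"] = out / "records.csv"

        stage = "prevalence"
        if records:
            for flag in ("psychiatric", "physical", "any"):
                table = prevalence_table(
                    records, "subgroup", flag, unknown=config.unknown_codes
                )
                try:
                    chi = prevalence_chi_square(
                        records, "subgroup", flag,
                        unknown=config.unknown_codes, allow_degenerate=True,
                    )
                    table.attrs["chi_square"] = chi.statistic
                    foot = (
                        f"# chi2={chi.statistic:.3f} df={chi.df} "
                        f"p={format_p(chi.p_value)} valid={chi.valid}\n"
                    )
                except (DegenerateTableError, ValueError):
                    foot = "# chi2=N/A\n"
                path = out / f"prevalence_{flag}.csv"
                with path.open("w", encoding="utf-8") as fh:
                    table.to_csv(fh, index=False, float_format="%.2f")
                    fh.write(foot)
                files[f"prevalence_{flag}"] = path
            logger.info("stage %s: 3 tables", stage)
        else:
            logger.warning("empty cohort: skipping prevalence tables")

        pooled_n = 0
        for sg in config.subgroups:
            stage = f"subgroup-{sg.value}"
            tset = build_transactions(
                records,
                sg,
                unknown=config.unknown_codes,
                same_block_policy=config.same_block_policy,
            )
            if sg is not MoodSubgroup.ALL:
                pooled_n += tset.n
            write_transactions(tset, out / f"{sg.value}_transactions.csv")
            files[f"{sg.value}_transactions"] = out / f"{sg.value}_transactions.csv"

            freq_path = out / f"{sg.value}_frequency.csv"
            with freq_path.open("w", encoding="utf-8") as fh:
                fh.write("block_id,support\n")
                if tset.n:
                    for block, support in block_relative_frequency(
                        tset, config.frequency_threshold
                    ):
                        fh.write(f"{block},{support:.3f}\n")
            files[f"{sg.value}_frequency"] = freq_path

            miner = AprioriMiner(
                min_support=config.mining.min_support,
                min_confidence=config.mining.min_confidence,
                min_lift=config.mining.min_lift,
                strict_lift=config.mining.strict_lift,
                max_antecedent_size=config.mining.max_antecedent_size,
            )
            if tset.n:
                miner.fit(tset)
                rules = miner.rules_
            else:
                logger.warning("subgroup %s: empty cohort, no rules mined", sg.value)
                rules = []
            logger.info(
                "stage %s: n=%d, %d rules pass filters", stage, tset.n, len(rules)
            )

            report = rules_to_frame(rules[: config.top_k_report])
            report.insert(0, "subgroup", sg.value)
            report_cols = ["subgroup", "rule", "N", "support", "confidence", "lift", "IS"]
            report[report_cols].to_csv(
                out / f"{sg.value}_rules.csv", index=False, float_format="%.3f"
            )
            rules_to_frame(rules).to_csv(out / f"{sg.value}_rules_raw.csv", index=False)
            files[f"{sg.value}_rules"] = out / f"{sg.value}_rules.csv"
            files[f"{sg.value}_rules_raw"] = out / f"{sg.value}_rules_raw.csv"

            graph = build_rule_graph(rules, max_rules=config.max_graph_rules)
            files[f"{sg.value}_graph"] = export_graph(
                graph, out / f"{sg.value}_graph.graphml", "graphml"
            )

        if MoodSubgroup.ALL in config.subgroups and set(config.subgroups) >= set(
            ALL_SUBGROUPS
        ):
            n_all = build_transactions(records, MoodSubgroup.ALL, unknown=config.unknown_codes).n
            if pooled_n != n_all:
                raise PipelineStageError(
                    f"stage conservation: subgroup n sum {pooled_n} != pooled n {n_all}"
                )

        stage = "manifest"
        manifest = {
            "package": "comorbid-arm",
            "version": __version__,
            "python": sys.version.split()[0],
            "config": _config_echo(config),
            "n_records": len(records),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        files["manifest"] = out / "manifest.json"
        return ReportBundle(output_dir=out, manifest=manifest, files=files)
    except PipelineStageError:
        raise
    except Exception as exc:
        for path in files.values():  # remove partial outputs
            Path(path).unlink(missing_ok=True)
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
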