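"""End-to-end orchestration: I/O, configuration, and the full analysis run.

A run either reads an assessment CSV or generates a synthetic cohort,
then sequences the analysis: reference norms -> severity bands (manual
and reference) -> dual classification of the index cohort -> clustered
binomial/ordinal comparison -> power arithmetic -> Markdown report.
Every artifact is stamped with a hash of the resolved configuration so
outputs are traceable to their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._utils import markdown_table
from .cohort_synth import (
    AssessmentRecord,
    SynthConfig,
    generate_cohorts,
    records_to_frame,
)
from .cohort_comparison import MlmFit, build_long, fit_binomial_mlm, fit_ordinal_mlm
from .design_power import PowerDesign, accrual_ratio, simulate_power
from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    SchemaError,
    TermRefError,
)
from .reference_norms import (
    COMPOSITES,
    bands_table,
    derive_bands,
    estimate_norms,
    manual_bands,
    norms_table,
)
from .severity_classification import (
    ClassificationTable,
    classify_cohort,
    summary_table,
)

logger = logging.getLogger("termref")

REQUIRED_COLUMNS = ("child_id", "center_id", "cohort", *COMPOSITES)


# ---------------------------------------------------------------------------
# assessment CSV I/O


def read_assessments(path: str | Path) -> list[AssessmentRecord]:
    """Read typed assessment records from a CSV file.

    Blank score cells become missing; rows with untypable scores or an
    unknown cohort label are rejected — malformed score rows are dropped
    and logged with their line numbers, an invalid cohort value raises a
    :class:`SchemaError` (it indicates the wrong file, not a bad row).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"child_id": str, "center_id": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols}")
    bad_cohort = set(frame["cohort"].dropna()) - {"reference", "index"}
    if bad_cohort:
        raise SchemaError(
            f"{path}: cohort values outside {{reference, index}}: {sorted(bad_cohort)}"
        )
    covariate_cols = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
    records: list[AssessmentRecord] = []
    rejected: list[int] = []
    for i, row in frame.iterrows():
        line_no = i + 2  # header is line 1
        try:
            scores = {}
            for comp in COMPOSITES:
                v = row[comp]
                if pd.isna(v):
                    scores[comp] = None
                else:
                    scores[comp] = int(float(v))
                    if float(v) != scores[comp]:
                        raise ValueError(f"non-integer {comp} score {v!r}")
            records.append(
                AssessmentRecord(
                    child_id=str(row["child_id"]),
                    center_id=str(row["center_id"]),
                    cohort=str(row["cohort"]),
                    **scores,
                    covariates={
                        k: row[k] for k in covariate_cols if not pd.isna(row[k])
                    },
                )
            )
        except (ValueError, TermRefError) as exc:
            rejected.append(line_no)
            logger.warning("read_assessments: line %d rejected (%s)", line_no, exc)
    if rejected:
        logger.warning(
            "read_assessments: %d of %d rows rejected (lines %s)",
            len(rejected),
            len(frame),
            rejected,
        )
    return records


def write_assessments(records: Sequence[AssessmentRecord], path: str | Path) -> None:
    """Write records as UTF-8 comma-separated CSV with header."""
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_path: Optional[str] = None
    synth: Optional[SynthConfig] = SynthConfig()
    band_sources: tuple[str, ...] = ("manual", "reference")
    covariates: tuple[str, ...] = ()
    n_nodes: int = 21
    child_intercept: bool = False
    power: PowerDesign = PowerDesign()
    out_dir: str = "termref_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_path is None and self.synth is None:
            raise ConfigurationError("need either an input CSV or a synth config")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input file not found: {self.input_path}")
        bad = set(self.band_sources) - {"manual", "reference"}
        if bad:
            raise ConfigurationError(f"unknown band sources: {sorted(bad)}")

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        raw.update(overrides)
        if "synth" in raw and isinstance(raw["synth"], dict):
            for key in (
                "composite_means_ref",
                "composite_sds_ref",
                "composite_means_index",
                "composite_sds_index",
                "missing_rates",
                "index_sizes",
            ):
                if key in raw["synth"] and raw["synth"][key] is not None:
                    raw["synth"][key] = tuple(raw["synth"][key])
            raw["synth"] = SynthConfig(**raw["synth"])
        if "power" in raw and isinstance(raw["power"], dict):
            raw["power"] = PowerDesign(**raw["power"])
        for key in ("band_sources", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunResult:
    """Everything one pipeline run produced."""

    config: RunConfig
    records: list[AssessmentRecord]
    norms: "pd.DataFrame"
    bands: dict[str, dict]
    classifications: dict[str, ClassificationTable]
    fits: dict[str, MlmFit]
    power: dict
    report: str
    out_dir: Path


def _stage(name: str):
    """Decorator tagging stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except TermRefError as exc:
                raise type(exc)(f"[{name}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Deterministic given (config, seed): the same configuration writes
    byte-identical tables. Artifacts: assessments CSV (when synthesised),
    norms CSV, bands CSV, per-child classification CSV, comparison CSV,
    power JSON, and report.md; all stamped with the config hash.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config.config_hash()

    # --- data
    if config.input_path is not None:
        records = _stage("read_assessments")(read_assessments)(config.input_path)
    else:
        synth = dataclasses.replace(config.synth, seed=config.seed)
        records = _stage("cohort_synth")(generate_cohorts)(synth)
        write_assessments(records, out / "assessments.csv")
    records = [r for r in records if r.has_any_score()]
    if not records:
        raise InsufficientDataError("[read_assessments] no analyzable records")

    ref = [r for r in records if r.cohort == "reference"]
    index = [r for r in records if r.cohort == "index"]

    # --- reference norms and bands
    @_stage("reference_norms")
    def _norms():
        out_norms = []
        for comp in COMPOSITES:
            scores = [getattr(r, comp) for r in ref]
            out_norms.append(estimate_norms(scores, comp))
        return out_norms

    norms = _norms()
    bands = {
        "manual": {c: manual_bands(c) for c in COMPOSITES},
        "reference": {nm.composite: derive_bands(nm) for nm in norms},
    }
    bands = {src: bands[src] for src in config.band_sources}

    # --- classification of the index cohort
    @_stage("severity_classification")
    def _classify():
        frame = records_to_frame(index)
        return {
            src: classify_cohort(frame, bands[src], src) for src in config.band_sources
        }

    classifications = _classify()

    # --- clustered comparison (needs both sources)
    fits: dict[str, MlmFit] = {}
    if {"manual", "reference"} <= set(config.band_sources):

        @_stage("cohort_comparison")
        def _compare():
            res = {}
            long_bin = build_long(
                classifications["manual"], classifications["reference"], "binary"
            )
            res["overall_binary"] = fit_binomial_mlm(
                long_bin,
                covariates=config.covariates,
                n_nodes=config.n_nodes,
                child_intercept=config.child_intercept,
            )
            long_ord = build_long(
                classifications["manual"], classifications["reference"], "ordinal"
            )
            res["overall_ordinal"] = fit_ordinal_mlm(
                long_ord, covariates=config.covariates, n_nodes=config.n_nodes
            )
            return res

        fits = _compare()

    # --- power
    power_design = dataclasses.replace(config.power, seed=config.seed)
    power = _stage("design_power")(simulate_power)(power_design)
    power_payload = {
        "design": _as_jsonable(power_design),
        "estimate": _as_jsonable(power),
        "config_hash": stamp,
    }

    # --- write artifacts
    norms_frame = norms_table(norms)
    norms_frame["config_hash"] = stamp
    norms_frame.to_csv(out / "norms.csv", index=False)

    all_bands = [b for src in bands.values() for b in src.values()]
    bands_frame = bands_table(all_bands)
    bands_frame["config_hash"] = stamp
    bands_frame.to_csv(out / "bands.csv", index=False)

    cls_frames = []
    for src, table in classifications.items():
        f = table.frame.copy()
        for col in (*COMPOSITES, "overall"):
            f[col] = f[col].map(lambda v: None if v is None else v.label)
        cls_frames.append(f)
    cls_all = pd.concat(cls_frames, ignore_index=True)
    cls_all["config_hash"] = stamp
    cls_all.to_csv(out / "classification.csv", index=False)

    summaries = pd.concat(
        [summary_table(t) for t in classifications.values()], ignore_index=True
    )
    summaries["config_hash"] = stamp
    summaries.to_csv(out / "comparison.csv", index=False)

    (out / "power.json").write_text(json.dumps(power_payload, indent=2))

    report = _render_report(
        config, stamp, records, norms_frame, bands_frame, summaries, fits, power
    )
    (out / "report.md").write_text(report)
    logger.info("pipeline complete: artifacts in %s (config %s)", out, stamp)

    return RunResult(
        config=config,
        records=records,
        norms=norms_frame,
        bands=bands,
        classifications=classifications,
        fits=fits,
        power=power_payload,
        report=report,
        out_dir=out,
    )


def _render_report(
    config, stamp, records, norms_frame, bands_frame, summaries, fits, power
) -> str:
    n_ref = sum(r.cohort == "reference" for r in records)
    n_index = sum(r.cohort == "index" for r in records)
    lines = [
        "# Term-reference recalibration report",
        "",
        f"Config hash: `{stamp}`; seed: {config.seed}",
        "",
        f"Children analyzed: {n_index} index, {n_ref} reference "
        f"(accrual {accrual_ratio(n_index, n_ref) if n_ref else 'n/a'})",
        "",
        "## Reference-sample norms",
        "",
        markdown_table(
            ["composite", "n", "mean", "sd", "sd 95% CI"],
            [
                (
                    r["composite"],
                    r["n"],
                    r["mean"],
                    r["sd"],
                    f"{r['sd_ci_low']}-{r['sd_ci_high']}",
                )
                for _, r in norms_frame.iterrows()
            ],
        ),
        "",
        "## Severity bands",
        "",
        markdown_table(
            ["composite", "source", "moderate cut", "severe cut"],
            [
                (r["composite"], r["source"], r["moderate_cut"], r["severe_cut"])
                for _, r in bands_frame.iterrows()
            ],
        ),
        "",
        "## Classification of the index cohort",
        "",
        markdown_table(
            ["analysis", "source", "level", "n", "%", "denominator"],
            [
                (
                    r["analysis"],
                    r["source"],
                    r["level"],
                    r["n"],
                    r["percent"],
                    r["denominator"],
                )
                for _, r in summaries.iterrows()
            ],
        ),
        "",
    ]
    if fits:
        lines += [
            "## Clustered band-source comparison (overall impairment)",
            "",
            markdown_table(
                ["model", "OR (reference vs manual)", "95% CI", "p", "ICC"],
                [
                    (
                        fit.model,
                        f"{fit.odds_ratio:.2f}",
                        f"({fit.or_ci_low:.2f}, {fit.or_ci_high:.2f})",
                        f"{fit.p_value:.2g}",
                        f"{fit.icc:.3f}",
                    )
                    for fit in fits.values()
                ],
            ),
            "",
        ]
    lines += [
        "## Design power",
        "",
        f"Simulated power {power.power:.3f} "
        f"(95% MC CI {power.mc_ci_low:.3f}-{power.mc_ci_high:.3f}, "
        f"{power.n_sims} replicates, seed {power.seed})",
        "",
    ]
    return "\n".join(lines)
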