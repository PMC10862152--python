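"""End-to-end analysis pipeline.

QC/exclusion → cohort ingest (simulated, tabular, or measured from
label images) → group summaries → sex-stratified isometry tests (full
cohort and the over-5s sensitivity analysis) → penalized-spline trend
surfaces → a structured run report. Every artifact records the seed and
a config fingerprint; a fixed seed and config give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import IsometryResult, format_p, run_stratified
from .cohort import read_cohort_csv, validate_cohort, volume_col, write_cohort_csv
from .morphometry import measure_participant, read_label_volume, summarize_groups
from .muscles import MUSCLES, SEXES
from .synthetic import (
    asynchronous_spec,
    calibrate_from_summary,
    simulate_cohort,
    synchronous_spec,
)
from .trends import absolute_volume_trends, relative_volume_trends

log = logging.getLogger("leggrowth")

INPUT_MODES = ("simulate", "cohort-table", "label-volumes")


class PipelineConfigError(ValueError):
    """Invalid or inconsistent analysis configuration."""


@dataclass
class AnalysisConfig:
    """Settings for one analysis run.

    Exactly one input mode is active: ``simulate`` draws a synthetic
    cohort (``generator`` chooses the band-wise calibrated model or an
    allometric model, ``synchronous``/``asynchronous``),
    ``cohort-table`` reads a participant CSV, and ``label-volumes``
    measures a directory of label images plus a demographics CSV.
    """

    input_mode: str = "simulate"
    outdir: str = "leggrowth_out"
    seed: int = 0
    alpha: float = 0.05
    min_age_sensitivity: float = 5.0
    #: bootstrap draws for the isometry-test calibration; the p-value
    #: floor is 1/(n_boot+1), so the default resolves below 0.001
    n_boot: int = 4999
    spline_basis_size: int = 10
    flatness_tol: float = 0.05
    fit_trends: bool = True
    # simulate mode
    generator: str = "bandwise"          # bandwise | synchronous | asynchronous
    n_per_group: dict[str, tuple[int, ...]] | None = None
    # cohort-table mode
    cohort_path: str | None = None
    # label-volumes mode
    volumes_dir: str | None = None
    demographics_path: str | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise PipelineConfigError(f"input_mode must be one of {INPUT_MODES}")
        if self.input_mode == "cohort-table" and not self.cohort_path:
            raise PipelineConfigError("cohort-table mode needs cohort_path")
        if self.input_mode == "label-volumes" and not (
            self.volumes_dir and self.demographics_path
        ):
            raise PipelineConfigError(
                "label-volumes mode needs volumes_dir and demographics_path"
            )
        if not 0 < self.alpha < 1:
            raise PipelineConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "n_per_group" in raw and raw["n_per_group"] is not None:
            raw["n_per_group"] = {k: tuple(v) for k, v in raw["n_per_group"].items()}
        return cls(**raw)

    def fingerprint(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config_fingerprint: str
    seed: int
    version: str
    n_recruited: int
    n_excluded: int
    n_analysed: int
    exclusion_reasons: dict[str, int]
    counts_by_stratum: dict[str, int]
    isometry: dict[str, dict]
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark motion-artefact rows as excluded.

    Returns the updated table and an exclusion log (participant,
    reason). Rows already excluded keep their status; recruited =
    analysed + excluded always holds afterwards.
    """
    out = cohort.copy()
    flagged = out["motion_artefact"].astype(bool)
    out.loc[flagged, "included"] = False
    entries = [
        {"participant": p, "reason": "motion_artefact"}
        for p in out.loc[flagged, "participant"]
    ]
    log.info("exclusions: %d of %d rows flagged for motion artefact", flagged.sum(), len(out))
    return out, pd.DataFrame(entries, columns=["participant", "reason"])


def _ingest(config: AnalysisConfig) -> pd.DataFrame:
    if config.input_mode == "simulate":
        if config.generator == "bandwise":
            spec = calibrate_from_summary()
        elif config.generator == "synchronous":
            spec = synchronous_spec()
        elif config.generator == "asynchronous":
            spec = asynchronous_spec()
        else:
            raise PipelineConfigError(f"unknown generator {config.generator!r}")
        return simulate_cohort(spec, config.n_per_group, seed=config.seed)
    if config.input_mode == "cohort-table":
        return read_cohort_csv(config.cohort_path)
    return cohort_from_label_volumes(config.volumes_dir, config.demographics_path)


def cohort_from_label_volumes(volumes_dir: str | Path, demographics_path: str | Path) -> pd.DataFrame:
    """Build a cohort table by measuring label images.

    ``volumes_dir`` holds one ``<participant>.nii`` (+ ``.json``
    sidecar) per participant; the demographics CSV supplies
    ``participant, sex, age`` and optional ``motion_artefact``. Muscle
    labels must use the canonical 10 codes; bone labels TIB and FIB
    give tibia and fibula lengths.
    """
    demo = pd.read_csv(demographics_path, dtype={"participant": "string", "sex": "string"})
    rows = []
    for _, d in demo.iterrows():
        lv = read_label_volume(Path(volumes_dir) / f"{d['participant']}.nii")
        meas = measure_participant(lv)
        row = {
            "participant": d["participant"],
            "sex": d["sex"],
            "age": float(d["age"]),
            "body_mass": float(d.get("body_mass", np.nan)),
            "height": float(d.get("height", np.nan)),
            "tibia_length": meas.get("tib_length", np.nan),
            "fibula_length": meas.get("fib_length", np.nan),
            "motion_artefact": bool(d.get("motion_artefact", False)),
            "included": True,
        }
        for m in MUSCLES:
            row[volume_col(m)] = meas.get(volume_col(m), np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["participant"] = df["participant"].astype("string")
    df["sex"] = df["sex"].astype("string")
    return validate_cohort(df)


def _isometry_payload(res: IsometryResult | None) -> dict:
    if res is None:
        return {"skipped": True, "reason": "stratum too small for joint test"}
    return {
        "skipped": False,
        "n": res.n,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "p_chi2": res.p_chi2,
        "calibration": res.calibration,
        "p_printed": format_p(res.p_value),
        "eigen_multiplicity_flag": res.eigen_multiplicity_flag,
    }


def run_all(config: AnalysisConfig) -> RunReport:
    """Execute the full analysis and write all artifacts to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    outputs: dict[str, str] = {}

    cohort = _ingest(config)
    cohort, excl_log = apply_exclusions(cohort)
    n_recruited = len(cohort)
    n_analysed = int(cohort["included"].sum())

    def _save(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        outputs[name] = str(path)

    if n_recruited:
        write_cohort_csv(cohort, outdir / "cohort.csv")
        outputs["cohort.csv"] = str(outdir / "cohort.csv")
    else:
        _save("cohort.csv", cohort)
    _save("exclusions.csv", excl_log)
    summary = summarize_groups(cohort)
    _save("group_summary.csv", summary)

    counts = {
        f"{sex}": int(((cohort["sex"] == sex) & cohort["included"]).sum()) for sex in SEXES
    }

    isometry: dict[str, dict] = {}
    for tag, min_age in (("full", None), ("sensitivity", config.min_age_sensitivity)):
        try:
            results = run_stratified(
                cohort, min_age=min_age, seed=config.seed, n_boot=config.n_boot
            )
        except ValueError as err:
            warnings_log.append(f"isometry ({tag}): {err}")
            results = {sex: None for sex in SEXES}
        for sex, res in results.items():
            isometry[f"{sex}_{tag}"] = _isometry_payload(res)
            if res is None:
                warnings_log.append(f"isometry ({tag}, {sex}): stratum skipped (too small)")
            else:
                _save(f"pairwise_slopes_{sex}_{tag}.csv", res.pairwise)

    if config.fit_trends and n_analysed >= 5:
        rel = relative_volume_trends(cohort, config.spline_basis_size, config.flatness_tol)
        absr = absolute_volume_trends(cohort, config.spline_basis_size, config.flatness_tol)
        _save("trends_relative.csv", rel.tidy())
        _save("trends_absolute.csv", absr.tidy())
        _save("constancy_flags.csv", rel.constancy_flags())
        for key, msg in {**rel.errors, **absr.errors}.items():
            warnings_log.append(f"trend fit {key}: {msg}")
    elif config.fit_trends:
        warnings_log.append("trends skipped: fewer than 5 analysed rows")

    report = RunReport(
        config_fingerprint=config.fingerprint(),
        seed=config.seed,
        version=__version__,
        n_recruited=n_recruited,
        n_excluded=n_recruited - n_analysed,
        n_analysed=n_analysed,
        exclusion_reasons=excl_log["reason"].value_counts().to_dict() if len(excl_log) else {},
        counts_by_stratum=counts,
        isometry=isometry,
        warnings=warnings_log,
        outputs=outputs,
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
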