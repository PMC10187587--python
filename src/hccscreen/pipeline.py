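"""End-to-end pipeline: simulate -> exposure -> survival models -> bias
corrections -> report tables.

All stages run off a single :class:`RunConfig` with one seed; every written
table carries the configuration hash so grid outputs remain traceable to
their assumptions. Outputs are plain CSV (figure-style outputs are emitted
as their underlying data).
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

from hccscreen.cohort import CohortBundle, generate_cohort
from hccscreen.config import CohortConfig
from hccscreen.exposure import DEFAULT_WINDOW, SCREEN_WINDOW, build_exposure_table
from hccscreen.grid import (
    DEFAULT_HORIZONS_MONTHS,
    DEFAULT_SOJOURN_MEANS,
    default_scenarios,
    run_sensitivity_grid,
)
from hccscreen.lengthbias import LengthBiasScenario
from hccscreen.leadtime import SojournModel, apply_lead_time_correction
from hccscreen.survival import (
    apply_exclusions,
    cumulative_incidence,
    fit_cox,
    fit_subdistribution,
    km_estimate,
    logrank_test,
)

logger = logging.getLogger(__name__)

PATIENT_SCHEMA = ["patient_id", "time_months", "event", "cause",
                  "tumor_size_cm", "multifocal", "vascular_invasion", "metastasis"]
IMAGING_SCHEMA = ["patient_id", "month_offset", "procedure_code"]

#: adjustment covariates for the multivariable models (all present in the
#: synthetic patient table)
DEFAULT_COVARIATES = ["female", "age_c", "comorbidity", "etiology", "diabetes",
                      "cirrhosis", "ascites", "encephalopathy", "early_stage"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    patients_path: str | None = None  # read mode when both paths are set
    imaging_path: str | None = None
    exposure_window: tuple[int, int] = DEFAULT_WINDOW
    screen_window: tuple[int, int] = SCREEN_WINDOW
    sojourn_means: tuple[float, ...] = DEFAULT_SOJOURN_MEANS
    scenarios: list[LengthBiasScenario] = field(default_factory=default_scenarios)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    horizons_months: tuple[float, ...] = DEFAULT_HORIZONS_MONTHS
    include_zero_month: bool = False
    run_competing_risks: bool = True
    group_p_values: bool = False
    out_dir: str = "hccscreen_out"

    @property
    def read_mode(self) -> bool:
        return self.patients_path is not None and self.imaging_path is not None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "scenarios" in d:
            d["scenarios"] = [LengthBiasScenario(**s) for s in d["scenarios"]]
        for key in ("exposure_window", "screen_window", "sojourn_means",
                    "horizons_months"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        # hash the analytic configuration; where outputs land is not part of it
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run (all also persisted as CSV)."""

    descriptive: pd.DataFrame
    ptc_histogram: pd.DataFrame
    km_curves: pd.DataFrame
    model_results: pd.DataFrame
    competing_risks: pd.DataFrame | None
    sensitivity_grid: pd.DataFrame
    manifest: dict


class SchemaError(ValueError):
    pass


def _validate_schema(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    null_rows = df[required].isna().any(axis=1)
    if null_rows.any():
        row = int(np.nonzero(null_rows.to_numpy())[0][0])
        raise SchemaError(f"{name}: null value in required column at row {row}")


def summarize_cohort(
    patients: pd.DataFrame,
    exposure: pd.DataFrame,
    p_values: bool = False,
) -> pd.DataFrame:
    """Descriptive table: per-imaging-group counts and percentages for
    categorical characteristics and mean +/- SD for continuous ones.

    Percentages are within group (each characteristic's levels sum to 100 up
    to rounding). Optional group-comparison p-values use Pearson chi-square
    (categorical) and one-way ANOVA (continuous).
    """
    from scipy import stats

    df = patients.merge(
        exposure[["patient_id", "group", "etiology", "early_stage",
                  "screen_detected"]],
        on="patient_id",
    )
    groups = [g for g in ("ctmri", "ultrasound", "none") if g in set(df["group"])]
    categorical = ["female", "comorbidity", "etiology", "diabetes", "cirrhosis",
                   "ascites", "encephalopathy", "early_stage", "screen_detected"]
    continuous = ["age"]
    rows = []
    for char in categorical:
        levels = sorted(df[char].unique(), key=str)
        pval = np.nan
        if p_values:
            tab = pd.crosstab(df[char], df["group"])
            if tab.shape[0] > 1 and tab.shape[1] > 1:
                pval = float(stats.chi2_contingency(tab)[1])
        for lev in levels:
            row = {"characteristic": char, "level": str(lev), "statistic": "n (%)",
                   "p_value": pval}
            for g in groups + ["total"]:
                sub = df if g == "total" else df[df["group"] == g]
                n = int((sub[char] == lev).sum())
                pct = 100.0 * n / len(sub) if len(sub) else np.nan
                row[f"{g}"] = f"{n} ({pct:.1f})"
            rows.append(row)
    for char in continuous:
        pval = np.nan
        if p_values:
            samples = [df.loc[df["group"] == g, char] for g in groups]
            if len(samples) > 1:
                pval = float(stats.f_oneway(*samples)[1])
        row = {"characteristic": char, "level": "", "statistic": "mean (SD)",
               "p_value": pval}
        for g in groups + ["total"]:
            sub = df if g == "total" else df[df["group"] == g]
            row[f"{g}"] = f"{sub[char].mean():.1f} ({sub[char].std():.1f})"
        rows.append(row)
    return pd.DataFrame(rows)


def ptc_histogram(exposure: pd.DataFrame) -> pd.DataFrame:
    """Decile-binned PTC distribution per modality, with a dedicated zero
    bin and the fraction of patients above 50% coverage."""
    edges = np.arange(0.0, 1.01, 0.1)
    labels = ["0"] + [f"({10*i}-{10*(i+1)}]" for i in range(10)]
    rows = []
    for col, modality in (("ptc_us", "ultrasound"), ("ptc_ctmri", "ctmri"),
                          ("ptc_any", "any")):
        v = exposure[col].to_numpy(float)
        counts = [int((v == 0).sum())]
        for lo, hi in zip(edges[:-1], edges[1:]):
            counts.append(int(((v > lo + 1e-12) & (v <= hi + 1e-12)).sum()))
        frac_gt50 = float((v > 0.5).mean())
        for lab, c in zip(labels, counts):
            rows.append({"modality": modality, "bin": lab, "count": c,
                         "frac_gt_50pct": frac_gt50})
    return pd.DataFrame(rows)


def _km_curves_table(analysis: pd.DataFrame, screen, sojourn: SojournModel,
                     time_col="time_months") -> pd.DataFrame:
    """KM curves per imaging group, unadjusted and lead-time adjusted."""
    corrected = apply_lead_time_correction(analysis, screen, sojourn,
                                           time_col=time_col)
    frames = []
    for adj, col in (("unadjusted", time_col), ("lead", "corrected_time_months")):
        for g, sub in corrected.groupby("group"):
            km = km_estimate(sub[col].to_numpy(float), sub["event"].to_numpy(int))
            tab = km.table[["time", "survival", "ci_low", "ci_high"]].copy()
            tab.insert(0, "stratum", g)
            tab.insert(0, "adjustment", adj)
            tab["median"] = km.median
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write all report CSVs to
    ``config.out_dir``. Deterministic given the configuration (seed
    included)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log = {"config_hash": chash, "stages": []}

    if config.read_mode:
        patients = pd.read_csv(config.patients_path)
        imaging = pd.read_csv(config.imaging_path,
                              dtype={"procedure_code": str})
        _validate_schema(patients, PATIENT_SCHEMA, str(config.patients_path))
        _validate_schema(imaging, IMAGING_SCHEMA, str(config.imaging_path))
        truth = None
    else:
        bundle: CohortBundle = generate_cohort(config.cohort)
        patients, imaging, truth = bundle
        patients.to_csv(out / "patients.csv", index=False)
        imaging.to_csv(out / "imaging.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    log["stages"].append({"stage": "input", "n_patients": len(patients),
                          "n_claims": len(imaging)})

    exposure = build_exposure_table(patients, imaging,
                                    window=config.exposure_window,
                                    screen_window=config.screen_window)
    exposure.to_csv(out / "exposure.csv", index=False)
    log["stages"].append({
        "stage": "exposure",
        "groups": exposure["group"].value_counts().to_dict(),
        "n_screen_detected": int(exposure["screen_detected"].sum()),
    })

    merged = patients.merge(exposure, on="patient_id")
    analysis, n_excluded = apply_exclusions(
        merged, include_zero_month=config.include_zero_month)
    log["stages"].append({"stage": "exclusions", "n_excluded_zero_month": n_excluded,
                          "n_analysis": len(analysis)})

    descriptive = summarize_cohort(patients, exposure,
                                   p_values=config.group_p_values)
    hist = ptc_histogram(exposure)

    base_mean = 1.0 / config.cohort.sojourn_rate_per_month
    sojourn = SojournModel.from_mean(base_mean)
    screen = analysis["screen_detected"].to_numpy(bool)
    km_curves = _km_curves_table(analysis, screen, sojourn)
    chi2, df_, p = logrank_test(analysis["time_months"], analysis["event"],
                                analysis["group"])
    log["stages"].append({"stage": "km", "logrank_chi2": chi2, "df": df_,
                          "p": p})

    m1 = fit_cox(analysis, specification="group_model",
                 covariates=config.covariates)
    m2 = fit_cox(analysis, specification="ptc_model",
                 covariates=config.covariates)
    model_frames = [m1.to_frame(), m2.to_frame()]

    competing = None
    if config.run_competing_risks:
        cif = cumulative_incidence(analysis["time_months"], analysis["cause"])
        cif_frames = []
        for cause, tab in cif.items():
            t2 = tab.copy()
            t2.insert(0, "cause", cause)
            cif_frames.append(t2)
        competing = pd.concat(cif_frames, ignore_index=True)
        for cause in ("hcc_death", "other_death"):
            if (analysis["cause"] == cause).sum() == 0:
                continue
            fg = fit_subdistribution(analysis, cause_of_interest=cause,
                                     covariates=config.covariates,
                                     specification="group_model")
            model_frames.append(fg.to_frame())

    models = pd.concat(model_frames, ignore_index=True)

    sens_grid = run_sensitivity_grid(
        analysis, screen,
        sojourn_means=config.sojourn_means,
        scenarios=config.scenarios,
        horizons_months=config.horizons_months,
    )

    from hccscreen import __version__ as pkg_version

    manifest = {
        "config_hash": chash,
        "seed": config.cohort.seed,
        "package_version": pkg_version,
        "config": config.to_dict(),
        "log": log,
    }

    outputs = {
        "descriptive_table.csv": descriptive,
        "ptc_histogram.csv": hist,
        "km_curves.csv": km_curves,
        "model_results.csv": models,
        "sensitivity_grid.csv": sens_grid,
    }
    if competing is not None:
        outputs["cumulative_incidence.csv"] = competing
    for name, tab in outputs.items():
        tab = tab.copy()
        tab["config_hash"] = chash
        tab.to_csv(out / name, index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return ReportBundle(
        descriptive=descriptive,
        ptc_histogram=hist,
        km_curves=km_curves,
        model_results=models,
        competing_risks=competing,
        sensitivity_grid=sens_grid,
        manifest=manifest,
    )
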