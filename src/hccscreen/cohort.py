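"""Synthetic Medicare-claims-like HCC cohort generator with known natural history.

Every patient carries a latent tumor natural history: a preclinical onset
time, an exponential sojourn (the window in which the tumor is asymptomatic
but screen-detectable), and a slow/fast growth class. Imaging exams arrive as
two monthly streams (semiannual surveillance with imperfect adherence, plus a
Poisson stream of other abdominal imaging); an exam falling inside the
preclinical window detects the tumor with a modality-specific sensitivity.
Screen detection truncates the sojourn early, producing a genuinely
exponential lead time; otherwise the tumor surfaces clinically at the end of
its sojourn.

Post-diagnosis survival is built on the natural-history clock: the latent
HCC-death time runs from clinical surfacing, so that — when the true
screening effect is zero — screen detection inflates observed survival by
exactly the lead time and nothing else. This makes lead-time-bias artifacts,
and their correction, verifiable against ground truth.

Times are continuous internally; the claims layer (imaging months, diagnosis
month, follow-up) is reported at whole-month granularity as in Medicare data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from hccscreen.config import CohortConfig, ConfigError

US_CODES = ("76700", "76705")
CT_CODES = ("74160", "74170", "74177")
MRI_CODES = ("74182", "74183")

_COMORBIDITY_LEVELS = ("low", "moderate", "high")
_ETIOLOGY_CATS = ("HCV", "NAFLD", "ALD", "HBV", "Others")
_ETIOLOGY_PROBS = (0.336, 0.356, 0.176, 0.048, 0.084)


class GrowthClass(str, Enum):
    slow = "slow"
    fast = "fast"


class DetectionMode(str, Enum):
    screen = "screen"
    clinical = "clinical"


class Exam(NamedTuple):
    """A single imaging exam on the calendar-month grid (pre-diagnosis)."""

    month: int
    modality: str  # "ultrasound" or "ctmri"


@dataclass
class NaturalHistory:
    """Latent tumor history: onset, sojourn and growth class.

    ``onset_time`` and ``surfacing_time`` are continuous calendar times in
    months; ``surfacing_month`` is the (integer) calendar month in which the
    tumor would present clinically.
    """

    onset_time: float
    sojourn_months: float
    growth_class: GrowthClass

    @property
    def surfacing_time(self) -> float:
        return self.onset_time + self.sojourn_months

    @property
    def surfacing_month(self) -> int:
        return int(math.ceil(self.surfacing_time))


class CohortBundle(NamedTuple):
    """The three tables written by the generator."""

    patients: pd.DataFrame
    imaging: pd.DataFrame
    truth: pd.DataFrame


def _sensitivity(config: CohortConfig, modality: str) -> float:
    return (
        config.exam_sensitivity_us
        if modality == "ultrasound"
        else config.exam_sensitivity_ctmri
    )


def simulate_detection(
    history: NaturalHistory,
    exams: Sequence[Exam],
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[DetectionMode, float]:
    """Run the detection mechanism for one patient.

    Each exam whose month falls in the preclinical window
    ``[onset_time, surfacing_time)`` independently detects the tumor with its
    modality's sensitivity; the first success fixes screen detection at that
    exam's month. Otherwise the tumor surfaces clinically.

    Returns ``(mode, diagnosis_time)`` where ``diagnosis_time`` is the exam
    month (screen) or the continuous surfacing time (clinical).
    """
    months = [e.month for e in exams]
    if any(b < a for a, b in zip(months, months[1:])):
        raise ValueError("exams must be sorted by month")
    for exam in exams:
        if history.onset_time <= exam.month < history.surfacing_time:
            if rng.random() < _sensitivity(config, exam.modality):
                return DetectionMode.screen, float(exam.month)
    return DetectionMode.clinical, history.surfacing_time


def simulate_survival(
    *,
    lead_time_months: float,
    screen_detected: bool,
    slow: bool,
    early_stage: bool,
    covariates: dict[str, float],
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[float, str]:
    """Draw one patient's observed follow-up (continuous months) and cause.

    The latent HCC-death clock starts at clinical surfacing: observed time
    from diagnosis is ``lead_time + Exp(h_hcc)``. The other-cause clock and
    administrative censoring run from diagnosis. Returns ``(time, cause)``
    with cause in {"hcc_death", "other_death", "censored"}.
    """
    log_hr = math.log(config.slow_theta) * slow
    log_hr += config.true_screening_log_hr * screen_detected
    for name, beta in config.log_hazard_effects.items():
        if name == "early_stage":
            log_hr += beta * early_stage
        else:
            log_hr += beta * covariates[name]
    h_hcc = config.baseline_hcc_hazard_per_month * math.exp(log_hr)
    t_hcc = lead_time_months + rng.exponential(1.0 / h_hcc)
    h_other = config.other_cause_hazard_per_month
    t_other = rng.exponential(1.0 / h_other) if h_other > 0 else math.inf
    t = min(t_hcc, t_other, float(config.admin_censor_months))
    if t == t_hcc and t < config.admin_censor_months:
        cause = "hcc_death"
    elif t == t_other and t < config.admin_censor_months:
        cause = "other_death"
    else:
        cause = "censored"
    return t, cause


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographic and clinical covariates with elderly-Medicare-like marginals."""
    female = rng.random(n) < 0.33
    age = np.clip(rng.normal(76.8, 6.2, n), 66.0, 99.0).round(1)
    comorbidity = rng.choice(_COMORBIDITY_LEVELS, size=n, p=(0.754, 0.142, 0.104))
    etiology = rng.choice(_ETIOLOGY_CATS, size=n, p=_ETIOLOGY_PROBS)
    diabetes = rng.random(n) < 0.64
    obesity = rng.random(n) < 0.30
    bariatric = rng.random(n) < 0.02
    dyslipidemia = rng.random(n) < 0.50
    hypertension = rng.random(n) < 0.70
    # NAFLD is under-coded in claims: code ~60% directly, let the rest be
    # recoverable through the metabolic surrogate rule.
    is_nafld = etiology == "NAFLD"
    nafld_coded = is_nafld & (rng.random(n) < 0.6)
    obesity = obesity | (is_nafld & ~nafld_coded)
    return pd.DataFrame(
        {
            "female": female.astype(int),
            "age": age,
            "age_c": age - 77.0,
            "comorbidity": comorbidity,
            "hcv": (etiology == "HCV").astype(int),
            "hbv": (etiology == "HBV").astype(int),
            "ald": (etiology == "ALD").astype(int),
            "other_liver": (etiology == "Others").astype(int),
            "nafld_coded": nafld_coded.astype(int),
            "obesity": obesity.astype(int),
            "diabetes": diabetes.astype(int),
            "bariatric": bariatric.astype(int),
            "dyslipidemia": dyslipidemia.astype(int),
            "hypertension": hypertension.astype(int),
            "cirrhosis": (rng.random(n) < 0.75).astype(int),
            "ascites": (rng.random(n) < 0.43).astype(int),
            "encephalopathy": (rng.random(n) < 0.17).astype(int),
        }
    )


def _draw_tumor_fields(
    early: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Tumor size/extent fields consistent with the latent early-stage flag."""
    n = early.size
    size = np.round(rng.uniform(1.0, 5.0, n), 1)
    multifocal = np.zeros(n, dtype=bool)
    vascular = np.zeros(n, dtype=bool)
    metastasis = np.zeros(n, dtype=bool)
    late = ~early
    n_late = int(late.sum())
    if n_late:
        big = rng.random(n_late) < 0.5
        size_late = np.where(
            big,
            np.round(rng.uniform(5.1, 12.0, n_late), 1),
            np.round(rng.uniform(1.0, 5.0, n_late), 1),
        )
        mf = rng.random(n_late) < 0.7
        vi = rng.random(n_late) < 0.4
        mt = rng.random(n_late) < 0.3
        # a small tumor must violate at least one other early-stage criterion
        none_set = ~big & ~mf & ~vi & ~mt
        mf = mf | none_set
        size[late] = size_late
        multifocal[late] = mf
        vascular[late] = vi
        metastasis[late] = mt
    return pd.DataFrame(
        {
            "tumor_size_cm": size,
            "multifocal": multifocal.astype(int),
            "vascular_invasion": vascular.astype(int),
            "metastasis": metastasis.astype(int),
        }
    )


def _exam_months(
    config: CohortConfig, surfacing: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized exam streams.

    Returns ``(months, is_us, patient_index)`` flattened over all exams that
    occur strictly before each patient's clinical surfacing time.
    """
    n = surfacing.size
    horizon = int(math.ceil(surfacing.max()))
    # semiannual surveillance slots
    enrolled = rng.random(n) < config.surveillance_enrollment
    phase = rng.integers(0, 6, size=n)
    n_slots = horizon // 6 + 2
    slot_months = phase[:, None] + 6 * np.arange(n_slots)[None, :]
    attend = rng.random((n, n_slots)) < config.surveillance_adherence
    surv_mask = enrolled[:, None] & attend & (slot_months < surfacing[:, None])
    # other (diagnostic/incidental) imaging: at most one claim per month
    p_month = 1.0 - math.exp(-config.diagnostic_imaging_rate)
    diag_months = np.arange(horizon + 1)[None, :]
    diag_mask = (rng.random((n, horizon + 1)) < p_month) & (
        diag_months < surfacing[:, None]
    )
    pi_s, slot = np.nonzero(surv_mask)
    m_s = slot_months[pi_s, slot]
    pi_d, m_d = np.nonzero(diag_mask)
    months = np.concatenate([m_s, m_d])
    pidx = np.concatenate([pi_s, pi_d])
    is_us = rng.random(months.size) < config.modality_mix["ultrasound"]
    order = np.lexsort((months, pidx))
    return months[order], is_us[order], pidx[order]


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full synthetic cohort.

    Returns a :class:`CohortBundle` of three tables: ``patients`` (covariates,
    diagnosis fields, follow-up), ``imaging`` (one row per prediagnostic
    claim: patient_id, month_offset, procedure_code), and ``truth`` (latent
    natural history including detection mode and true lead time).
    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    known = {"female", "age_c", "age", "ascites", "encephalopathy", "diabetes",
             "cirrhosis", "early_stage"}
    for key in config.log_hazard_effects:
        if key not in known:
            raise ConfigError(f"log_hazard_effects key '{key}' is not a covariate")

    n = config.n_patients
    rng = np.random.default_rng(config.seed)
    lb = config.lookback_months

    covs = _draw_covariates(n, rng)

    slow = rng.random(n) < config.slow_fraction
    base_mean = 1.0 / config.sojourn_rate_per_month
    mean_sojourn = np.where(
        slow, base_mean * config.slow_sojourn_multiplier, base_mean
    )
    sojourn = rng.exponential(mean_sojourn)
    onset = rng.uniform(lb + 6.0, lb + 30.0, n)
    surfacing = onset + sojourn

    months, is_us, pidx = _exam_months(config, surfacing, rng)

    # detection: first successful exam inside [onset, surfacing)
    sens = np.where(is_us, config.exam_sensitivity_us, config.exam_sensitivity_ctmri)
    in_window = months >= onset[pidx]  # exams already < surfacing by construction
    hit = in_window & (rng.random(months.size) < sens)
    diag_time = surfacing.copy()
    screen = np.zeros(n, dtype=bool)
    if hit.any():
        hit_p = pidx[hit]
        hit_m = months[hit].astype(float)
        # exams are sorted by month within patient; keep the first hit
        first = np.unique(hit_p, return_index=True)[1]
        diag_time[hit_p[first]] = hit_m[first]
        screen[hit_p[first]] = True
    diag_month = np.floor(diag_time).astype(int)
    lead = np.where(screen, surfacing - diag_time, 0.0)

    # imaging claims table: months strictly before the diagnosis month and
    # within the lookback window (same-month imaging is excluded, as in the
    # claims-extraction rule downstream)
    offsets = months - diag_month[pidx]
    keep = (offsets <= -1) & (offsets >= -lb)
    ev_p, ev_off, ev_us = pidx[keep], offsets[keep], is_us[keep]
    codes = np.empty(ev_p.size, dtype=object)
    us_mask = ev_us
    codes[us_mask] = rng.choice(US_CODES, size=int(us_mask.sum()))
    n_ct = int((~us_mask).sum())
    is_ct = rng.random(n_ct) < 0.7
    ct_codes = np.where(
        is_ct, rng.choice(CT_CODES, size=n_ct), rng.choice(MRI_CODES, size=n_ct)
    )
    codes[~us_mask] = ct_codes

    # stage at diagnosis: screen detection shifts toward early stage
    p_early = np.where(screen, config.stage_shift_prob_screen, config.stage_prob_clinical)
    early = rng.random(n) < p_early
    tumor = _draw_tumor_fields(early, rng)

    # survival from diagnosis
    log_hr = np.log(config.slow_theta) * slow + config.true_screening_log_hr * screen
    for name, beta in config.log_hazard_effects.items():
        x = early.astype(float) if name == "early_stage" else covs[name].to_numpy(float)
        log_hr = log_hr + beta * x
    h_hcc = config.baseline_hcc_hazard_per_month * np.exp(log_hr)
    t_hcc = lead + rng.exponential(1.0 / h_hcc)
    if config.other_cause_hazard_per_month > 0:
        t_other = rng.exponential(1.0 / config.other_cause_hazard_per_month, n)
    else:
        t_other = np.full(n, np.inf)
    censor = float(config.admin_censor_months)
    t = np.minimum(np.minimum(t_hcc, t_other), censor)
    cause = np.where(
        (t == t_hcc) & (t < censor),
        "hcc_death",
        np.where((t == t_other) & (t < censor), "other_death", "censored"),
    )
    time_months = np.floor(t).astype(int)
    event = (cause != "censored").astype(int)

    width = max(6, len(str(n)))
    pid = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    patients = pd.DataFrame({"patient_id": pid})
    patients = pd.concat([patients, covs, tumor], axis=1)
    patients["diagnosis_month"] = diag_month
    patients["time_months"] = time_months
    patients["event"] = event
    patients["cause"] = cause

    imaging = pd.DataFrame(
        {
            "patient_id": pid[ev_p],
            "month_offset": ev_off.astype(int),
            "procedure_code": codes.astype(str),
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "onset_time": onset.round(6),
            "sojourn_months": sojourn.round(6),
            "growth_class": np.where(slow, "slow", "fast"),
            "surfacing_month": np.ceil(surfacing).astype(int),
            "detection_mode": np.where(screen, "screen", "clinical"),
            "diagnosis_month": diag_month,
            "lead_time_months": lead.round(6),
            "early_stage": early.astype(int),
            "time_exact": t.round(6),
        }
    )
    return CohortBundle(patients=patients, imaging=imaging, truth=truth)
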