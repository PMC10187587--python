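"""Configuration objects for the synthetic cohort generator.

The defaults emulate an elderly Medicare HCC cohort: roughly two thirds of
patients have some abdominal imaging in the 3 years before diagnosis, imaging
coverage is sparse (low proportion of time covered), the preclinical sojourn
is exponential with a 6-month mean, one fifth of tumors are slow-growing, and
post-diagnosis survival has a median around a year with competing other-cause
mortality and 5-year administrative censoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping


class ConfigError(ValueError):
    """Raised when a configuration field violates its declared constraints."""


def _default_log_hazard_effects() -> dict[str, float]:
    # log hazard-ratio effects applied to the HCC-death hazard; keys refer to
    # columns of the generated patient table ("age_c" is age centered at 77,
    # per year).
    return {
        "female": -0.10,
        "age_c": 0.02,
        "ascites": 0.55,
        "encephalopathy": 0.35,
        "early_stage": -0.60,
    }


def _default_modality_mix() -> dict[str, float]:
    return {"ultrasound": 0.6, "ctmri": 0.4}


@dataclass
class CohortConfig:
    """Parameters of the synthetic natural-history / claims generator.

    Attributes
    ----------
    n_patients:
        Cohort size.
    lookback_months:
        Length of the prediagnostic claims window (months).
    sojourn_rate_per_month:
        Rate lambda of the exponential preclinical sojourn; mean sojourn is
        1/lambda months (default 6 months).
    slow_fraction:
        Proportion (1 - q) of tumors in the slow-growing class.
    slow_theta:
        Relative risk theta of HCC death for slow vs aggressive tumors
        (multiplies the HCC-death hazard).
    slow_sojourn_multiplier:
        Factor by which the slow class's mean sojourn exceeds the base mean;
        values > 1 produce length-biased screen detection.
    surveillance_enrollment:
        Probability a patient is in a semiannual surveillance program at all.
    surveillance_adherence:
        Per-6-month-period probability that an enrolled patient actually
        attends the scheduled exam.
    diagnostic_imaging_rate:
        Poisson rate (per month) of non-surveillance abdominal imaging.
    modality_mix:
        Proportions of exams that are ultrasound vs CT/MRI; must sum to 1.
    exam_sensitivity_us / exam_sensitivity_ctmri:
        Per-exam probability of detecting a tumor in its preclinical phase.
    stage_shift_prob_screen / stage_prob_clinical:
        Probability of early-stage disease at diagnosis by detection mode.
    baseline_hcc_hazard_per_month / other_cause_hazard_per_month:
        Constant cause-specific hazards after clinical surfacing / diagnosis.
    log_hazard_effects:
        Covariate name -> log hazard ratio on the HCC-death hazard.
    true_screening_log_hr:
        Extra log hazard ratio applied to screen-detected patients; 0 encodes
        no true benefit beyond stage and lead-time mechanics.
    admin_censor_months:
        Administrative censoring time measured from diagnosis.
    seed:
        Seed of the generator's random stream.
    """

    n_patients: int = 5000
    lookback_months: int = 36
    sojourn_rate_per_month: float = 1.0 / 6.0
    slow_fraction: float = 0.2
    slow_theta: float = 0.9
    slow_sojourn_multiplier: float = 2.0
    surveillance_enrollment: float = 0.33
    surveillance_adherence: float = 0.55
    diagnostic_imaging_rate: float = 0.014
    modality_mix: Mapping[str, float] = field(default_factory=_default_modality_mix)
    exam_sensitivity_us: float = 0.5
    exam_sensitivity_ctmri: float = 0.85
    stage_shift_prob_screen: float = 0.45
    stage_prob_clinical: float = 0.15
    baseline_hcc_hazard_per_month: float = 0.028
    other_cause_hazard_per_month: float = 0.012
    log_hazard_effects: Mapping[str, float] = field(
        default_factory=_default_log_hazard_effects
    )
    true_screening_log_hr: float = 0.0
    admin_censor_months: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n_patients, int) and self.n_patients > 0):
            raise ConfigError("n_patients must be a positive integer")
        if not (isinstance(self.lookback_months, int) and self.lookback_months > 0):
            raise ConfigError("lookback_months must be a positive integer")
        for name in ("sojourn_rate_per_month", "slow_sojourn_multiplier",
                     "baseline_hcc_hazard_per_month"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.other_cause_hazard_per_month < 0:
            raise ConfigError("other_cause_hazard_per_month must be >= 0")
        if self.diagnostic_imaging_rate < 0:
            raise ConfigError("diagnostic_imaging_rate must be >= 0")
        for name in ("slow_fraction", "surveillance_enrollment",
                     "surveillance_adherence", "exam_sensitivity_us",
                     "exam_sensitivity_ctmri", "stage_shift_prob_screen",
                     "stage_prob_clinical"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.slow_theta <= 1.0:
            raise ConfigError("slow_theta must lie in (0, 1]")
        mix = dict(self.modality_mix)
        if set(mix) != {"ultrasound", "ctmri"}:
            raise ConfigError("modality_mix must have keys 'ultrasound' and 'ctmri'")
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError("modality_mix proportions must be >= 0 and sum to 1")
        if not (isinstance(self.admin_censor_months, int) and self.admin_censor_months > 0):
            raise ConfigError("admin_censor_months must be a positive integer")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    def replace(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["modality_mix"] = dict(self.modality_mix)
        d["log_hazard_effects"] = dict(self.log_hazard_effects)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(**dict(d))
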