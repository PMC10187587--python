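"""Claims-derived imaging exposure constructs.

Converts raw prediagnostic imaging claims (patient id, month offset relative
to the diagnosis month, CPT procedure code) into the exposure variables used
in the survival models: modality classification, imaging-group assignment
(CT/MRI > ultrasound > none), proportion of time covered (PTC), the
screen-detected flag, the liver-disease etiology hierarchy, and the
early-stage tumor classification.

Month convention: the diagnosis month is 0 and prediagnostic months are
negative (-1 is the month before diagnosis). Imaging in the diagnosis month
itself is excluded.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: CPT code -> modality. Abdominal ultrasound (76700, 76705), contrast CT
#: (74160, 74170, 74177) and MRI (74182, 74183).
CPT_MODALITY_MAP: dict[str, str] = {
    "76700": "ultrasound",
    "76705": "ultrasound",
    "74160": "ct",
    "74170": "ct",
    "74177": "ct",
    "74182": "mri",
    "74183": "mri",
}

DEFAULT_WINDOW: tuple[int, int] = (-36, -1)
SCREEN_WINDOW: tuple[int, int] = (-6, -1)
COVERAGE_MONTHS = 7


class Modality(str, Enum):
    ultrasound = "ultrasound"
    ct = "ct"
    mri = "mri"


class UnknownCodeError(ValueError):
    pass


def classify_modality(procedure_code: str, *, on_unknown: str = "raise") -> Modality | None:
    """Map a CPT procedure code to its imaging modality.

    ``on_unknown`` is either ``"raise"`` (default) or ``"skip"``, in which
    case unknown codes are logged and ``None`` is returned.
    """
    if not isinstance(procedure_code, str) or not procedure_code:
        raise UnknownCodeError("procedure code must be a nonempty string")
    modality = CPT_MODALITY_MAP.get(procedure_code)
    if modality is None:
        if on_unknown == "skip":
            logger.warning("skipping unrecognized procedure code %r", procedure_code)
            return None
        raise UnknownCodeError(f"unrecognized procedure code {procedure_code!r}")
    return Modality(modality)


def _check_window(window: Sequence[int]) -> tuple[int, int]:
    lo, hi = int(window[0]), int(window[1])
    if not (lo <= hi <= -1):
        raise ValueError(f"window must satisfy lo <= hi <= -1, got ({lo}, {hi})")
    return lo, hi


def _modalities(events: pd.DataFrame, on_unknown: str = "raise") -> pd.Series:
    mods = events["procedure_code"].map(
        lambda c: (m := classify_modality(c, on_unknown=on_unknown)) and m.value
    )
    return mods


def assign_group(
    events: pd.DataFrame, window: Sequence[int] = DEFAULT_WINDOW
) -> str:
    """Assign one patient's imaging group over a prediagnostic window.

    At least one CT or MRI in the window -> ``"ctmri"``; otherwise at least
    one ultrasound -> ``"ultrasound"``; otherwise ``"none"``. The window is
    configurable (e.g. ``(-7, -1)`` for the short-window sensitivity
    analysis).
    """
    lo, hi = _check_window(window)
    if len(events) == 0:
        return "none"
    off = events["month_offset"].to_numpy(int)
    mods = _modalities(events)
    in_win = (off >= lo) & (off <= hi)
    if ((mods.isin(["ct", "mri"])) & in_win).any():
        return "ctmri"
    if ((mods == "ultrasound") & in_win).any():
        return "ultrasound"
    return "none"


def compute_ptc(
    events: pd.DataFrame,
    window: Sequence[int] = DEFAULT_WINDOW,
    coverage_months: int = COVERAGE_MONTHS,
    modalities: Iterable[str] | None = None,
) -> float:
    """Proportion of the window covered by imaging for one patient.

    Each exam at month ``m`` covers ``{m, ..., m + coverage_months - 1}``
    truncated at month -1 (coverage cannot extend into or past the diagnosis
    month). PTC is the size of the union of covered months intersected with
    the window, divided by the window length. ``modalities`` restricts the
    qualifying exams (e.g. ``{"ultrasound"}`` or ``{"ct", "mri"}``).
    """
    lo, hi = _check_window(window)
    length = hi - lo + 1
    if len(events) == 0:
        return 0.0
    off = events["month_offset"].to_numpy(int)
    mods = _modalities(events).to_numpy()
    if modalities is not None:
        allowed = set(modalities)
        sel = np.array([m in allowed for m in mods])
        off = off[sel]
    off = off[(off >= lo) & (off <= hi)]
    if (events["month_offset"].to_numpy(int) > -1).any():
        raise ValueError("month_offset must be <= -1 (diagnosis-month imaging excluded)")
    covered: set[int] = set()
    for m in off:
        covered.update(range(m, min(m + coverage_months, 0)))
    covered &= set(range(lo, hi + 1))
    return len(covered) / length


def flag_screen_detected(
    events: pd.DataFrame, window: Sequence[int] = SCREEN_WINDOW
) -> bool:
    """True iff the patient had any imaging exam within the screening window
    (default: the 6 months before the diagnosis month)."""
    lo, hi = _check_window(window)
    if len(events) == 0:
        return False
    off = events["month_offset"].to_numpy(int)
    return bool(((off >= lo) & (off <= hi)).any())


def assign_etiology(flags: dict | pd.Series) -> str:
    """Liver-disease etiology by hierarchy HCV > HBV > ALD > Others > NAFLD.

    NAFLD is assigned when directly coded, or through the surrogate rule
    (obesity, diabetes, bariatric surgery history, or dyslipidemia together
    with hypertension) in the absence of any other liver-disease flag.
    Returns one of "HCV", "HBV", "ALD", "Others", "NAFLD", "None".
    """
    g = lambda k: bool(flags.get(k, False))
    if g("hcv"):
        return "HCV"
    if g("hbv"):
        return "HBV"
    if g("ald"):
        return "ALD"
    if g("other_liver"):
        return "Others"
    surrogate = g("obesity") or g("diabetes") or g("bariatric") or (
        g("dyslipidemia") and g("hypertension")
    )
    if g("nafld_coded") or surrogate:
        return "NAFLD"
    return "None"


def classify_early_stage(
    size_cm: float, multifocal: bool, vascular_invasion: bool, metastasis: bool
) -> bool:
    """Early-stage HCC: a single tumor <= 5 cm without vascular invasion or
    extrahepatic metastasis."""
    if not size_cm > 0:
        raise ValueError(f"tumor size must be positive, got {size_cm}")
    return (not multifocal) and size_cm <= 5.0 and (not vascular_invasion) and (
        not metastasis
    )


def build_exposure_table(
    patients: pd.DataFrame,
    imaging: pd.DataFrame,
    window: Sequence[int] = DEFAULT_WINDOW,
    screen_window: Sequence[int] = SCREEN_WINDOW,
    coverage_months: int = COVERAGE_MONTHS,
) -> pd.DataFrame:
    """Per-patient exposure summary for a whole cohort.

    Returns one row per patient of ``patients`` with columns: group, ptc_us,
    ptc_ctmri, ptc_any, screen_detected, etiology, early_stage. Patients with
    no claims fall in group "none" with all PTCs zero.
    """
    _check_window(window)
    if (imaging["month_offset"] > -1).any():
        raise ValueError("imaging contains month_offset > -1; diagnosis-month "
                         "claims must be excluded upstream")
    grouped = dict(tuple(imaging.groupby("patient_id", sort=False)))
    empty = imaging.iloc[0:0]
    rows = []
    for _, pat in patients.iterrows():
        ev = grouped.get(pat["patient_id"], empty)
        rows.append(
            {
                "patient_id": pat["patient_id"],
                "group": assign_group(ev, window),
                "ptc_us": compute_ptc(ev, window, coverage_months, {"ultrasound"}),
                "ptc_ctmri": compute_ptc(ev, window, coverage_months, {"ct", "mri"}),
                "ptc_any": compute_ptc(ev, window, coverage_months),
                "screen_detected": flag_screen_detected(ev, screen_window),
                "etiology": assign_etiology(pat),
                "early_stage": int(
                    classify_early_stage(
                        float(pat["tumor_size_cm"]),
                        bool(pat["multifocal"]),
                        bool(pat["vascular_invasion"]),
                        bool(pat["metastasis"]),
                    )
                ),
            }
        )
    out = pd.DataFrame(rows)
    out["screen_detected"] = out["screen_detected"].astype(int)
    return out
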