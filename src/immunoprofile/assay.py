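"""Closed-form assay readout computations and positivity-cutoff rules.

Covers the serology readouts around the marker panel: pseudovirus
neutralization percent and 4PL ID50/ID80 titers, MSD ACE2 percent blocking,
ADCP scores, seronegative-panel positivity cutoffs, and AU -> BAU (WHO
binding antibody unit) conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitratedResponse",
    "CutoffRule",
    "percent_neutralization",
    "fit_4pl_titer",
    "percent_blocking",
    "adcp_score",
    "derive_cutoff",
    "au_to_bau",
    "AU_TO_BAU_FACTORS",
    "NEGATIVE_TITER",
    "FAILED_TITER",
]

#: WHO International Standard conversion factors, MSD AU/mL -> BAU/mL.
AU_TO_BAU_FACTORS = {"nucleocapsid": 0.00236, "rbd": 0.0272, "spike": 0.00901}

#: Titer assigned to negative calls (MPI < 10%), for graphing purposes.
NEGATIVE_TITER = 5.0
#: Titer assigned to positive calls whose 4PL estimation failed.
FAILED_TITER = 10.0


@dataclass
class TitratedResponse:
    """A neutralization titration: reciprocal dilutions and percent inhibition."""

    dilutions: np.ndarray
    percent_inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.dilutions = np.asarray(self.dilutions, dtype=float)
        self.percent_inhibition = np.asarray(self.percent_inhibition, dtype=float)
        if self.dilutions.shape != self.percent_inhibition.shape:
            raise ValueError("dilutions and percent_inhibition must align")
        if np.any(self.dilutions <= 0):
            raise ValueError("reciprocal dilutions must be positive")

    @property
    def mpi(self) -> float:
        """Maximum percent inhibition over the titration."""
        return float(np.max(self.percent_inhibition))


@dataclass
class CutoffRule:
    """Positivity-cutoff convention derived from a seronegative panel."""

    kind: Literal["percentile95_and_floor", "mean_plus_3sd", "percentile95_and_3median"]
    floor: float = 100.0
    truncate_negatives: bool = False


def percent_neutralization(rlu_sample, rlu_uninfected, rlu_infected):
    """[1 - (RLU_sample - RLU_uninfected)/(RLU_infected - RLU_uninfected)] x 100."""
    denom = np.asarray(rlu_infected, dtype=float) - np.asarray(rlu_uninfected, dtype=float)
    if np.any(denom == 0):
        raise ZeroDivisionError("infected and uninfected RLU must differ")
    out = (1.0 - (np.asarray(rlu_sample, dtype=float) - rlu_uninfected) / denom) * 100.0
    return out if out.ndim else float(out)


def percent_blocking(ecl_sample, ecl_calibrator1, ecl_blank):
    """(1 - (ECL_sample - ECL_cal1)/(ECL_blank - ECL_cal1)) x 100."""
    denom = np.asarray(ecl_blank, dtype=float) - np.asarray(ecl_calibrator1, dtype=float)
    if np.any(denom == 0):
        raise ZeroDivisionError("blank and calibrator-1 ECL must differ")
    out = (1.0 - (np.asarray(ecl_sample, dtype=float) - ecl_calibrator1) / denom) * 100.0
    return out if out.ndim else float(out)


def adcp_score(mfi_sample, freq_pos_sample, mfi_control, freq_pos_control) -> float:
    """(MFI x frequency positive) normalized by the PBS-control product."""
    denom = mfi_control * freq_pos_control
    if denom == 0:
        raise ZeroDivisionError("control MFI x frequency product must be nonzero")
    return (mfi_sample * freq_pos_sample) / denom


def _four_pl(logd, lower, upper, log_infl, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (logd - log_infl)))


def fit_4pl_titer(curve: TitratedResponse, level: int = 50) -> float:
    """ID50/ID80 titer from a titration curve.

    Negative calls (MPI < 10%) get titer 5; positive calls are fitted with a
    four-parameter logistic on log reciprocal dilution (least squares,
    asymptotes bounded in [-10, 110]) and inverted at ``level``. Estimation
    failure — non-convergence, an upper asymptote below ``level``, or an
    inverted titer outside the tested dilution range — gives titer 10.
    """
    if level not in (50, 80):
        raise ValueError("level must be 50 or 80")
    if curve.dilutions.size < 4:
        raise ValueError("at least 4 dilution points required")
    if curve.mpi < 10.0:
        return NEGATIVE_TITER

    logd = np.log10(curve.dilutions)
    y = curve.percent_inhibition
    p0 = np.array([0.0, max(curve.mpi, 50.0), np.median(logd), -1.5])
    lo = np.array([-10.0, -10.0, logd.min() - 3, -20.0])
    hi = np.array([110.0, 110.0, logd.max() + 3, 20.0])
    p0 = np.clip(p0, lo, hi)
    try:
        fit = least_squares(
            lambda p: _four_pl(logd, *p) - y, p0, bounds=(lo, hi), method="trf"
        )
    except Exception:
        return FAILED_TITER
    if not fit.success:
        return FAILED_TITER
    lower, upper, log_infl, slope = fit.x
    lv = float(level)
    # invert: level = lower + (upper-lower)/(1+exp(-slope (t - infl)))
    if not (min(lower, upper) < lv < max(lower, upper)) or slope == 0:
        return FAILED_TITER
    frac = (upper - lower) / (lv - lower) - 1.0
    if frac <= 0:
        return FAILED_TITER
    # Inversion handles either slope sign; titration curves decrease in
    # reciprocal dilution (more dilute serum neutralizes less).
    log_titer = log_infl - np.log(frac) / slope
    titer = 10.0 ** log_titer
    if not (curve.dilutions.min() <= titer <= curve.dilutions.max()):
        return FAILED_TITER
    return float(titer)


def derive_cutoff(negatives: Sequence[float], rule: CutoffRule) -> float:
    """Positivity threshold from seronegative readouts under a stated rule.

    Percentiles use linear interpolation between order statistics.
    """
    x = np.asarray(negatives, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("at least 2 seronegative observations required")
    if rule.truncate_negatives:
        x = np.maximum(x, 0.0)
    if rule.kind == "percentile95_and_floor":
        return float(max(np.percentile(x, 95), rule.floor))
    if rule.kind == "mean_plus_3sd":
        return float(np.mean(x) + 3.0 * np.std(x, ddof=1))
    if rule.kind == "percentile95_and_3median":
        return float(max(np.percentile(x, 95), 3.0 * np.median(x)))
    raise ValueError(f"unknown cutoff rule: {rule.kind}")


def au_to_bau(au_per_ml: float, analyte: str) -> float:
    """Convert MSD AU/mL to WHO BAU/mL by the analyte's conversion factor."""
    if au_per_ml < 0:
        raise ValueError("AU/mL must be nonnegative")
    try:
        return au_per_ml * AU_TO_BAU_FACTORS[analyte.lower()]
    except KeyError:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of "
                         f"{sorted(AU_TO_BAU_FACTORS)}") from None
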