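"""Bioanalytical method-validation statistics.

Implements the standard statistics of an LC-MS/MS plasma-assay validation:
weighted (1/x^2) linear calibration with back-calculation, replicate
precision (RSD%) and accuracy (% of nominal) at the QC levels, extraction
recovery and matrix effect from peak-area comparisons, signal-to-noise LLOQ
screening, and the regulatory acceptance windows (LLOQ: accuracy 80-120% and
RSD <= 20%; other levels: accuracy 85-115% and RSD <= 15%; windows treated as
closed intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import statsmodels.api as sm

from .errors import (
    InvalidNoiseError,
    InvalidReferenceError,
    RankDeficientError,
    UndefinedPrecisionError,
)

Weighting = Literal["1/x2", "1/x", "none"]
QCLevel = Literal["LLOQ", "LQC", "MQC", "HQC"]


@dataclass(frozen=True)
class CalibrationSeries:
    """Calibrator responses for one analyte.

    ``nominal_concs`` in ng/mL; ``response_ratios`` are analyte/IS peak-area
    ratios aligned to them.  At least two distinct positive levels are
    required to identify the line; a full validation design uses >= 6 levels
    (see :attr:`design_ok`).
    """

    analyte_id: str
    nominal_concs: np.ndarray
    response_ratios: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.nominal_concs, dtype=float)
        y = np.asarray(self.response_ratios, dtype=float)
        object.__setattr__(self, "nominal_concs", x)
        object.__setattr__(self, "response_ratios", y)
        if len(x) != len(y):
            raise ValueError("nominal_concs and response_ratios must align")
        if np.any(x <= 0):
            raise ValueError("nominal concentrations must be positive")
        if np.any(y <= 0):
            raise ValueError("response ratios must be positive")
        if len(np.unique(x)) < 2:
            raise RankDeficientError(
                f"calibration for {self.analyte_id}: a single distinct level "
                "cannot identify slope and intercept"
            )

    @property
    def design_ok(self) -> bool:
        """True when the series has >= 6 distinct levels (guidance design)."""
        return len(np.unique(self.nominal_concs)) >= 6


@dataclass(frozen=True)
class CalibrationFit:
    """Weighted linear calibration y = slope*x + intercept.

    ``r`` is the weighted Pearson correlation under the same weights used for
    the fit.  ``valid`` is False for non-positive slopes (a flat or inverted
    response curve cannot quantify).
    """

    analyte_id: str
    slope: float
    intercept: float
    r: float
    weighting: Weighting

    @property
    def valid(self) -> bool:
        return self.slope > 0


class BackCalcResult(NamedTuple):
    conc: float
    negative: bool


@dataclass(frozen=True)
class QCBatch:
    """Replicate measurements of one QC level under one condition."""

    analyte_id: str
    level: QCLevel
    nominal: float
    measured: np.ndarray
    condition: str = "intra-day"

    def __post_init__(self) -> None:
        m = np.asarray(self.measured, dtype=float)
        object.__setattr__(self, "measured", m)
        if self.nominal <= 0:
            raise ValueError("nominal concentration must be positive")
        if len(m) < 3:
            raise ValueError("a QC batch needs at least 3 replicates")


def _weights_for(x: np.ndarray, weighting: Weighting) -> np.ndarray:
    if weighting == "1/x2":
        return 1.0 / x**2
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "none":
        return np.ones_like(x)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_calibration(
    series: CalibrationSeries, weighting: Weighting = "1/x2"
) -> CalibrationFit:
    """Weighted least-squares line through the calibrators.

    Minimises sum_i w_i (y_i - a - b x_i)^2 with w_i = 1/x_i^2 by default,
    the conventional weighting for heteroscedastic LC-MS/MS response where
    the error scales with concentration.
    """
    x = series.nominal_concs
    y = series.response_ratios
    w = _weights_for(x, weighting)
    if np.ptp(y) == 0.0:
        # flat response: the exact solution is a horizontal line
        return CalibrationFit(
            analyte_id=series.analyte_id,
            slope=0.0,
            intercept=float(y[0]),
            r=0.0,
            weighting=weighting,
        )
    model = sm.WLS(y, sm.add_constant(x), weights=w)
    res = model.fit()
    intercept, slope = res.params

    # weighted Pearson correlation
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    cov = np.average((x - xm) * (y - ym), weights=w)
    vx = np.average((x - xm) ** 2, weights=w)
    vy = np.average((y - ym) ** 2, weights=w)
    r = float(cov / np.sqrt(vx * vy)) if vx > 0 and vy > 0 else 0.0

    return CalibrationFit(
        analyte_id=series.analyte_id,
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        weighting=weighting,
    )


def back_calculate(fit: CalibrationFit, response_ratio: float) -> BackCalcResult:
    """Invert the calibration line: conc = (response - intercept) / slope.

    A negative result is reported with its flag set, never clamped.
    """
    if fit.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot back-calculate")
    conc = (response_ratio - fit.intercept) / fit.slope
    return BackCalcResult(conc=float(conc), negative=conc < 0)


def qc_statistics(batch: QCBatch) -> tuple[float, float]:
    """Precision (RSD %) and accuracy (% of nominal) of a QC batch.

    RSD uses the sample standard deviation (ddof=1).
    """
    m = batch.measured
    mean = float(m.mean())
    if mean <= 0:
        raise UndefinedPrecisionError(
            f"{batch.analyte_id} {batch.level}: non-positive mean {mean}"
        )
    rsd = 100.0 * float(m.std(ddof=1)) / mean
    accuracy = 100.0 * mean / batch.nominal
    return rsd, accuracy


def recovery_and_matrix(
    extracted: float, post_spiked: float, neat: float
) -> tuple[float, float]:
    """Extraction recovery and matrix effect from mean peak areas.

    recovery% = 100 * extracted / post-spiked (spiked-before vs spiked-after
    extraction); matrix effect% = 100 * post-spiked / neat-solvent.
    """
    if post_spiked <= 0 or neat <= 0:
        raise InvalidReferenceError(
            f"reference means must be positive (post_spiked={post_spiked}, neat={neat})"
        )
    if extracted <= 0:
        raise InvalidReferenceError(f"extracted mean must be positive ({extracted})")
    return 100.0 * extracted / post_spiked, 100.0 * post_spiked / neat


@dataclass(frozen=True)
class AcceptanceReport:
    """Verdict of the regulatory precision/accuracy windows for one batch."""

    level: str
    accuracy_pct: float
    precision_rsd: float
    accuracy_window: tuple[float, float]
    rsd_limit: float
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def acceptance_check(
    accuracy_pct: float, precision_rsd: float, level: QCLevel
) -> AcceptanceReport:
    """Apply the acceptance windows: LLOQ 80-120% / <=20%; others 85-115% / <=15%.

    Bounds are closed: a batch exactly on a limit passes.
    """
    if level == "LLOQ":
        lo, hi, rsd_max = 80.0, 120.0, 20.0
    else:
        lo, hi, rsd_max = 85.0, 115.0, 15.0
    reasons: list[str] = []
    if accuracy_pct < lo:
        reasons.append(f"accuracy below {lo:g}%")
    if accuracy_pct > hi:
        reasons.append(f"accuracy above {hi:g}%")
    if precision_rsd > rsd_max:
        reasons.append(f"RSD above {rsd_max:g}%")
    return AcceptanceReport(
        level=level,
        accuracy_pct=accuracy_pct,
        precision_rsd=precision_rsd,
        accuracy_window=(lo, hi),
        rsd_limit=rsd_max,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def lloq_check(signal: float, noise: float) -> bool:
    """LLOQ screen: pass iff signal-to-noise ratio is strictly greater than 10."""
    if noise <= 0:
        raise InvalidNoiseError(f"noise must be positive, got {noise}")
    return signal / noise > 10.0
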