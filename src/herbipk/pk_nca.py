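"""Non-compartmental analysis (NCA) of single-analyte concentration-time profiles.

The module estimates the standard exposure and disposition parameters of an
extravascular (oral) profile without assuming a compartmental model:

* ``Cmax``/``Tmax`` — maximum observed quantifiable concentration and its time
  (ties broken to the earliest time);
* ``AUC0-t``/``AUMC0-t`` — trapezoidal areas under C(t) and t*C(t) up to the
  last quantifiable time, by the linear or linear-up/log-down rule;
* ``lambda_z`` — terminal elimination rate from log-linear regression over the
  trailing window that maximises adjusted R^2;
* extrapolated quantities ``AUC0-inf``, ``AUMC0-inf``, ``MRT``, ``t1/2``,
  ``Vz/F`` and ``CLz/F``.

Below-LLOQ (BLQ) handling follows common bioanalytical convention: pre-Tmax
BLQ observations are set to zero and kept, interior BLQ observations are
dropped, and trailing BLQ observations are excluded from both integration and
terminal-slope fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    InsufficientDataError,
    NoQuantifiableDataError,
    TerminalPhaseError,
)

logger = logging.getLogger(__name__)

#: Nominal sampling grid of the rat study being emulated: 5, 15 and 30 min
#: and 1, 2, 4, 8, 12 and 24 h post-dose, in hours.
STUDY_SCHEDULE_H: tuple[float, ...] = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

AUC_METHODS = ("linear", "linear-up/log-down")

# mg/kg divided by ng*h/mL: 1 mg = 1e6 ng and 1 L = 1e3 mL, net factor 1e3
# to express clearance in L/h/kg.
_DOSE_AUC_TO_L_PER_H_PER_KG = 1.0e3


@dataclass(frozen=True)
class ConcProfile:
    """One subject x analyte concentration-time series.

    Parameters
    ----------
    subject_id, analyte_id
        Identifiers; free-form strings.
    times
        Sampling times in hours, strictly increasing, non-negative.
    concs
        Concentrations in ng/mL aligned to ``times``; non-negative.
    blq_flags
        Per-point indicator that the observation is below the LLOQ.
    dose
        Administered dose per body weight (extract-equivalent), mg/kg.
    lloq
        Lower limit of quantification, ng/mL (> 0).
    """

    subject_id: str
    analyte_id: str
    times: np.ndarray
    concs: np.ndarray
    blq_flags: np.ndarray
    dose: float
    lloq: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        concs = np.asarray(self.concs, dtype=float)
        blq = np.asarray(self.blq_flags, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concs", concs)
        object.__setattr__(self, "blq_flags", blq)
        if not (len(times) == len(concs) == len(blq)):
            raise ValueError("times, concs and blq_flags must have equal length")
        if len(times) < 3:
            raise ValueError("a profile needs at least 3 sampling points")
        if np.any(times < 0):
            raise ValueError("sampling times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(concs < 0):
            raise ValueError("concentrations must be non-negative")
        if not self.lloq > 0:
            raise ValueError("lloq must be positive")
        if np.any(concs[~blq] < self.lloq):
            raise ValueError("quantifiable (non-BLQ) concentrations must be >= lloq")

    @property
    def n_quantifiable(self) -> int:
        return int(np.count_nonzero(~self.blq_flags))


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result.

    ``lambda_z`` is the (positive) elimination rate constant in 1/h;
    ``intercept`` is on the natural-log concentration scale; ``adj_r2`` is the
    adjusted coefficient of determination of the selected window, clipped to
    [0, 1]; ``t_first``/``t_last`` bound the window in hours.
    """

    lambda_z: float
    intercept: float
    n_points: int
    adj_r2: float
    t_first: float
    t_last: float

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.lambda_z


@dataclass(frozen=True)
class NCAResult:
    """Full NCA parameter vector for one profile.

    Extrapolation-dependent fields (``auc_0_inf``, ``aumc_0_inf``,
    ``mrt_0_inf``, ``t_half``, ``vz_f``, ``clz_f``, ``pct_extrapolated``) are
    ``None`` when the terminal phase could not be estimated.
    """

    subject_id: str
    analyte_id: str
    cmax: float
    tmax: float
    auc_0_t: float
    aumc_0_t: float
    mrt_0_t: float
    t_half: Optional[float]
    auc_0_inf: Optional[float]
    aumc_0_inf: Optional[float]
    mrt_0_inf: Optional[float]
    vz_f: Optional[float]
    clz_f: Optional[float]
    pct_extrapolated: Optional[float]
    lambda_fit: Optional[LambdaZFit] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "analyte_id": self.analyte_id,
            "cmax": self.cmax,
            "tmax": self.tmax,
            "t_half": self.t_half,
            "auc_0_t": self.auc_0_t,
            "auc_0_inf": self.auc_0_inf,
            "aumc_0_t": self.aumc_0_t,
            "aumc_0_inf": self.aumc_0_inf,
            "mrt_0_t": self.mrt_0_t,
            "mrt_0_inf": self.mrt_0_inf,
            "vz_f": self.vz_f,
            "clz_f": self.clz_f,
            "pct_extrapolated": self.pct_extrapolated,
            "lambda_z": self.lambda_fit.lambda_z if self.lambda_fit else None,
            "lambda_z_n_points": self.lambda_fit.n_points if self.lambda_fit else None,
            "lambda_z_adj_r2": self.lambda_fit.adj_r2 if self.lambda_fit else None,
        }
        return d


# ---------------------------------------------------------------------------
# BLQ policy
# ---------------------------------------------------------------------------

def usable_points(profile: ConcProfile) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ policy and return (times, concs) usable for integration.

    Pre-Tmax BLQ points are kept with concentration zero; interior BLQ points
    (after Tmax but before the last quantifiable time) are dropped; trailing
    BLQ points are dropped.
    """
    q = ~profile.blq_flags
    if not np.any(q):
        raise NoQuantifiableDataError(
            f"profile {profile.subject_id}/{profile.analyte_id}: all points BLQ"
        )
    q_idx = np.flatnonzero(q)
    cmax_pos = q_idx[int(np.argmax(profile.concs[q_idx]))]
    keep_t: list[float] = []
    keep_c: list[float] = []
    for i, (t, c, is_blq) in enumerate(
        zip(profile.times, profile.concs, profile.blq_flags)
    ):
        if not is_blq:
            keep_t.append(t)
            keep_c.append(c)
        elif i < cmax_pos:
            keep_t.append(t)
            keep_c.append(0.0)
        # interior or trailing BLQ: dropped
    return np.asarray(keep_t), np.asarray(keep_c)


# ---------------------------------------------------------------------------
# Cmax / Tmax
# ---------------------------------------------------------------------------

def find_cmax_tmax(profile: ConcProfile) -> tuple[float, float]:
    """Maximum quantifiable concentration and the earliest time attaining it."""
    q = ~profile.blq_flags
    if not np.any(q):
        raise NoQuantifiableDataError(
            f"profile {profile.subject_id}/{profile.analyte_id}: all points BLQ"
        )
    concs = profile.concs[q]
    times = profile.times[q]
    imax = int(np.argmax(concs))  # argmax returns the first maximum: earliest time
    return float(concs[imax]), float(times[imax])


# ---------------------------------------------------------------------------
# Trapezoidal areas
# ---------------------------------------------------------------------------

def _segment_areas(
    t1: float, t2: float, c1: float, c2: float, log_down: bool
) -> tuple[float, float]:
    """AUC and AUMC of one segment.

    The log rule applies only on a strict decline between positive
    concentrations; otherwise the linear rule is used.
    """
    dt = t2 - t1
    if log_down and c1 > c2 > 0.0:
        ratio = math.log(c1 / c2)
        k = dt / ratio  # = 1/lambda over the segment
        auc = (c1 - c2) * k
        aumc = (t1 * c1 - t2 * c2) * k + (c1 - c2) * k * k
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def auc_0_t(
    profile: ConcProfile, method: str = "linear"
) -> tuple[float, float]:
    """AUC0-t and AUMC0-t over the usable points of a profile.

    Parameters
    ----------
    profile
        Concentration-time profile.
    method
        ``"linear"`` (default) or ``"linear-up/log-down"``.

    Returns
    -------
    (auc, aumc)
        In ng*h/mL and ng*h^2/mL.
    """
    if method not in AUC_METHODS:
        raise ValueError(f"unknown AUC method {method!r}; choose from {AUC_METHODS}")
    times, concs = usable_points(profile)
    if len(times) < 2:
        raise InsufficientDataError(
            f"profile {profile.subject_id}/{profile.analyte_id}: "
            f"need >= 2 usable points, got {len(times)}"
        )
    log_down = method == "linear-up/log-down"
    auc = 0.0
    aumc = 0.0
    for i in range(len(times) - 1):
        a, m = _segment_areas(times[i], times[i + 1], concs[i], concs[i + 1], log_down)
        auc += a
        aumc += m
    return auc, aumc


# ---------------------------------------------------------------------------
# Terminal slope
# ---------------------------------------------------------------------------

def _ols_loglinear(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and adjusted R^2 of log-concentration on time."""
    n = len(t)
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    sse = float(np.sum((logc - fitted) ** 2))
    sst = float(np.sum((logc - logc.mean()) ** 2))
    if sst <= 0.0:
        r2 = 1.0 if sse <= 1e-300 else 0.0
    else:
        r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), adj


def fit_lambda_z(profile: ConcProfile, min_points: int = 3) -> LambdaZFit:
    """Estimate the terminal elimination rate by best-adjusted-R^2 regression.

    Candidate windows are the trailing runs of ``k`` quantifiable points
    strictly after Tmax, for ``k`` from ``min_points`` up to all post-Tmax
    points; the window maximising adjusted R^2 (ties to the longer window)
    wins, subject to a strictly negative slope.  When the strictly-post-Tmax
    tail is shorter than ``min_points`` the Tmax point itself joins the pool,
    which covers profiles that decline monotonically from the first sample.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    q = ~profile.blq_flags
    if not np.any(q):
        raise NoQuantifiableDataError(
            f"profile {profile.subject_id}/{profile.analyte_id}: all points BLQ"
        )
    times = profile.times[q]
    concs = profile.concs[q]
    imax = int(np.argmax(concs))
    tail_t = times[imax + 1:]
    tail_c = concs[imax + 1:]
    if len(tail_t) < min_points:
        # monotone-decline fallback: admit the peak itself
        tail_t = times[imax:]
        tail_c = concs[imax:]
    pos = tail_c > 0
    tail_t, tail_c = tail_t[pos], tail_c[pos]
    if len(tail_t) < min_points:
        raise InsufficientDataError(
            f"profile {profile.subject_id}/{profile.analyte_id}: "
            f"{len(tail_t)} usable terminal points < min_points={min_points}"
        )
    logc = np.log(tail_c)
    best: Optional[tuple[float, int, float, float]] = None  # adj, k, slope, icpt
    for k in range(min_points, len(tail_t) + 1):
        t_win = tail_t[-k:]
        c_win = logc[-k:]
        slope, intercept, adj = _ols_loglinear(t_win, c_win)
        if slope >= 0.0:
            continue
        if best is None or adj > best[0] + 1e-12 or (
            abs(adj - best[0]) <= 1e-12 and k > best[1]
        ):
            best = (adj, k, slope, intercept)
    if best is None:
        raise TerminalPhaseError(
            f"profile {profile.subject_id}/{profile.analyte_id}: "
            "no trailing window with a declining terminal phase"
        )
    adj, k, slope, intercept = best
    return LambdaZFit(
        lambda_z=-slope,
        intercept=intercept,
        n_points=k,
        adj_r2=float(min(max(adj, 0.0), 1.0)),
        t_first=float(tail_t[-k]),
        t_last=float(tail_t[-1]),
    )


# ---------------------------------------------------------------------------
# Full NCA
# ---------------------------------------------------------------------------

def run_nca(
    profile: ConcProfile,
    method: str = "linear",
    min_points: int = 3,
) -> NCAResult:
    """Compute the full NCA parameter vector for one profile.

    Extrapolated parameters use the last quantifiable concentration ``Clast``
    and the fitted terminal rate: ``AUC0-inf = AUC0-t + Clast/lambda_z``,
    ``AUMC0-inf = AUMC0-t + Clast*tlast/lambda_z + Clast/lambda_z^2``.
    ``CLz/F = dose / AUC0-inf`` and ``Vz/F = CLz/F / lambda_z`` are reported in
    L/h/kg and L/kg for dose in mg/kg and concentrations in ng/mL.  When the
    terminal phase is not estimable those fields are ``None``.
    """
    cmax, tmax = find_cmax_tmax(profile)
    auc_t, aumc_t = auc_0_t(profile, method=method)
    mrt_t = aumc_t / auc_t if auc_t > 0 else float("nan")

    try:
        lam = fit_lambda_z(profile, min_points=min_points)
    except (TerminalPhaseError, InsufficientDataError) as exc:
        logger.warning("terminal phase not estimable: %s", exc)
        return NCAResult(
            subject_id=profile.subject_id,
            analyte_id=profile.analyte_id,
            cmax=cmax,
            tmax=tmax,
            auc_0_t=auc_t,
            aumc_0_t=aumc_t,
            mrt_0_t=mrt_t,
            t_half=None,
            auc_0_inf=None,
            aumc_0_inf=None,
            mrt_0_inf=None,
            vz_f=None,
            clz_f=None,
            pct_extrapolated=None,
            lambda_fit=None,
        )

    times_u, concs_u = usable_points(profile)
    clast = float(concs_u[-1])
    tlast = float(times_u[-1])
    lz = lam.lambda_z
    auc_inf = auc_t + clast / lz
    aumc_inf = aumc_t + clast * tlast / lz + clast / lz**2
    mrt_inf = aumc_inf / auc_inf
    pct_extrap = 100.0 * (1.0 - auc_t / auc_inf)

    if profile.dose > 0:
        clz_f = profile.dose / auc_inf * _DOSE_AUC_TO_L_PER_H_PER_KG
        vz_f = clz_f / lz
    else:
        logger.warning(
            "profile %s/%s: non-positive dose; CLz/F and Vz/F not computed",
            profile.subject_id,
            profile.analyte_id,
        )
        clz_f = None
        vz_f = None

    return NCAResult(
        subject_id=profile.subject_id,
        analyte_id=profile.analyte_id,
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        aumc_0_t=aumc_t,
        mrt_0_t=mrt_t,
        t_half=lam.t_half,
        auc_0_inf=auc_inf,
        aumc_0_inf=aumc_inf,
        mrt_0_inf=mrt_inf,
        vz_f=vz_f,
        clz_f=clz_f,
        pct_extrapolated=pct_extrap,
        lambda_fit=lam,
    )
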