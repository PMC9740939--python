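"""AUC-weighted integration of multi-analyte pharmacokinetic profiles.

A multi-component herbal medicine exposes the body to several analytes at
once; no single analyte's profile represents the preparation.  The integrated
approach assigns each analyte j a weighting coefficient proportional to its
systemic exposure,

    w_j = AUC_j / sum_k AUC_k,

and forms the integrated concentration at each sampling time as the convex
combination

    c_T(t) = sum_j w_j * c_j(t).

Standard NCA on c_T(t) then yields one holistic parameter set for the
preparation.  Because the trapezoidal rule is linear in concentrations, the
integrated AUC0-t equals the weighted sum of component AUC0-t values exactly
whenever all components share the same integration support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GridAlignmentError, InvalidAUCError, WeightCoverageError
from .pk_nca import ConcProfile, NCAResult, run_nca

logger = logging.getLogger(__name__)

WeightBasis = Literal["auc_0_inf", "auc_0_t"]
WeightScope = Literal["pooled-mean", "per-subject"]

#: Parameter rows of the summary table, in report order.
SUMMARY_PARAMS: tuple[str, ...] = (
    "t_half",
    "cmax",
    "tmax",
    "auc_0_t",
    "auc_0_inf",
    "mrt_0_t",
    "mrt_0_inf",
    "vz_f",
    "clz_f",
)

PARAM_LABELS: Mapping[str, str] = {
    "t_half": "T1/2z (h)",
    "cmax": "Cmax (ng/mL)",
    "tmax": "Tmax (h)",
    "auc_0_t": "AUC0-t (ng h/mL)",
    "auc_0_inf": "AUC0-inf (ng h/mL)",
    "mrt_0_t": "MRT0-t (h)",
    "mrt_0_inf": "MRT0-inf (h)",
    "vz_f": "Vz/F (L/kg)",
    "clz_f": "CLz/F (L/h/kg)",
}


@dataclass(frozen=True)
class WeightVector:
    """AUC-proportional weighting coefficients for a set of analytes."""

    analyte_ids: tuple[str, ...]
    weights: np.ndarray
    basis: str
    scope: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "analyte_ids", tuple(self.analyte_ids))
        if len(self.analyte_ids) != len(w):
            raise ValueError("analyte_ids and weights must align")
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.analyte_ids, map(float, self.weights)))


@dataclass(frozen=True)
class IntegratedProfile:
    """Weighted integrated concentration-time curve for one subject."""

    subject_id: str
    times: np.ndarray
    concs: np.ndarray
    weights_used: WeightVector

    def to_conc_profile(self, dose: float, lloqs: Mapping[str, float]) -> ConcProfile:
        """View the integrated curve as a ConcProfile suitable for NCA.

        The effective LLOQ is the smallest weighted component LLOQ: any
        non-zero integrated concentration has at least one quantifiable
        component, hence is at least ``min_j w_j * lloq_j``.
        """
        w = self.weights_used.as_dict()
        eff_lloq = min(w[a] * lloqs[a] for a in self.weights_used.analyte_ids)
        blq = self.concs < eff_lloq
        return ConcProfile(
            subject_id=self.subject_id,
            analyte_id="__integrated__",
            times=self.times,
            concs=self.concs,
            blq_flags=blq,
            dose=dose,
            lloq=eff_lloq,
        )


def compute_weights(
    aucs: Mapping[str, Optional[float]],
    basis: WeightBasis = "auc_0_inf",
    scope: WeightScope = "pooled-mean",
) -> WeightVector:
    """AUC-proportional weights: w_j = AUC_j / sum_k AUC_k.

    Raises
    ------
    InvalidAUCError
        If any analyte's AUC is missing or non-positive (the message names
        the offending analyte).
    """
    if not aucs:
        raise InvalidAUCError("no analytes supplied")
    ids = tuple(aucs.keys())
    values = []
    for a in ids:
        v = aucs[a]
        if v is None or not np.isfinite(v) or v <= 0:
            raise InvalidAUCError(f"AUC for analyte {a!r} is missing or non-positive: {v!r}")
        values.append(float(v))
    arr = np.asarray(values)
    return WeightVector(
        analyte_ids=ids, weights=arr / arr.sum(), basis=basis, scope=scope
    )


def integrate_profiles(
    profiles: Sequence[ConcProfile], weights: WeightVector
) -> IntegratedProfile:
    """Pointwise weighted sum of one subject's analyte profiles.

    All profiles must share the same subject and the same nominal time grid;
    BLQ component concentrations enter the sum as zero.
    """
    if not profiles:
        raise WeightCoverageError("no profiles supplied")
    supplied = {p.analyte_id for p in profiles}
    expected = set(weights.analyte_ids)
    if supplied != expected:
        raise WeightCoverageError(
            f"weights cover {sorted(expected)} but profiles supply {sorted(supplied)}"
        )
    subjects = {p.subject_id for p in profiles}
    if len(subjects) != 1:
        raise GridAlignmentError(f"profiles span multiple subjects: {sorted(subjects)}")
    ref = profiles[0].times
    for p in profiles[1:]:
        if len(p.times) != len(ref) or not np.allclose(p.times, ref, rtol=0, atol=0):
            offending = sorted(set(np.round(p.times, 6)) ^ set(np.round(ref, 6)))
            raise GridAlignmentError(
                f"time grid of {p.analyte_id} differs from {profiles[0].analyte_id}: "
                f"offending times {offending}"
            )
    w = weights.as_dict()
    total = np.zeros_like(ref, dtype=float)
    for p in profiles:
        concs = np.where(p.blq_flags, 0.0, p.concs)
        total += w[p.analyte_id] * concs
    return IntegratedProfile(
        subject_id=profiles[0].subject_id,
        times=ref.copy(),
        concs=total,
        weights_used=weights,
    )


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class IntegratedStudyResult:
    """Per-analyte NCA, weight vector(s) and integrated-profile NCA."""

    per_analyte: pd.DataFrame          # one row per subject x analyte
    weights: WeightVector | dict[str, WeightVector]
    integrated: pd.DataFrame           # one row per subject
    summary: pd.DataFrame              # mean +/- SD, analytes + "Integrated Data"
    integrated_results: list[NCAResult]


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd


def _format_summary(frames: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Rows = parameters (report labels), columns = analyte / Integrated Data."""
    out: dict[str, list[str]] = {}
    for col, df in frames.items():
        cells = []
        for param in SUMMARY_PARAMS:
            mean, sd = _mean_sd(df[param].tolist())
            if np.isnan(mean):
                cells.append("NE")
            elif np.isnan(sd):
                cells.append(f"{mean:.4g}")
            else:
                cells.append(f"{mean:.4g} ± {sd:.4g}")
        out[col] = cells
    return pd.DataFrame(out, index=[PARAM_LABELS[p] for p in SUMMARY_PARAMS])


def integrated_study(
    profiles: Sequence[ConcProfile],
    method: str = "linear",
    min_points: int = 3,
    basis: WeightBasis = "auc_0_inf",
    scope: WeightScope = "pooled-mean",
) -> IntegratedStudyResult:
    """Run the full integrated-PK analysis over a study.

    Steps: per-subject, per-analyte NCA; AUC-proportional weights (pooled
    across subjects by default, or per subject); weighted integrated profile
    per subject; NCA on each integrated profile; mean +/- SD summary table
    with one column per analyte plus ``"Integrated Data"``.

    Subjects missing any analyte (or missing the AUC basis for any analyte)
    are excluded from the integrated stage with a logged warning.
    """
    analytes = sorted({p.analyte_id for p in profiles})
    by_subject: dict[str, dict[str, ConcProfile]] = {}
    for p in profiles:
        by_subject.setdefault(p.subject_id, {})[p.analyte_id] = p

    nca_rows: list[dict] = []
    nca_by_subject: dict[str, dict[str, NCAResult]] = {}
    for sid, d in by_subject.items():
        for a, p in d.items():
            res = run_nca(p, method=method, min_points=min_points)
            nca_rows.append(res.to_dict())
            nca_by_subject.setdefault(sid, {})[a] = res
    per_analyte = pd.DataFrame(nca_rows).sort_values(
        ["analyte_id", "subject_id"]
    ).reset_index(drop=True)

    # subjects eligible for integration: every analyte present with a usable basis
    def basis_value(res: NCAResult) -> Optional[float]:
        return getattr(res, basis)

    eligible: list[str] = []
    for sid in sorted(by_subject):
        d = nca_by_subject[sid]
        if set(d) != set(analytes):
            logger.warning("subject %s missing analytes %s; excluded from integration",
                           sid, sorted(set(analytes) - set(d)))
            continue
        if any(basis_value(d[a]) is None for a in analytes):
            logger.warning("subject %s lacks %s for some analyte; excluded", sid, basis)
            continue
        eligible.append(sid)
    if not eligible:
        raise InvalidAUCError(f"no subject has a complete {basis} vector")

    weights_obj: WeightVector | dict[str, WeightVector]
    if scope == "pooled-mean":
        mean_aucs = {
            a: float(np.mean([basis_value(nca_by_subject[s][a]) for s in eligible]))
            for a in analytes
        }
        pooled = compute_weights(mean_aucs, basis=basis, scope=scope)
        weights_by_subject = {sid: pooled for sid in eligible}
        weights_obj = pooled
    elif scope == "per-subject":
        weights_by_subject = {
            sid: compute_weights(
                {a: basis_value(nca_by_subject[sid][a]) for a in analytes},
                basis=basis,
                scope=scope,
            )
            for sid in eligible
        }
        weights_obj = weights_by_subject
    else:
        raise ValueError(f"unknown weight scope {scope!r}")

    integrated_rows: list[dict] = []
    integrated_results: list[NCAResult] = []
    for sid in eligible:
        d = by_subject[sid]
        prof_list = [d[a] for a in analytes]
        ip = integrate_profiles(prof_list, weights_by_subject[sid])
        lloqs = {a: d[a].lloq for a in analytes}
        dose = prof_list[0].dose
        res = run_nca(
            ip.to_conc_profile(dose=dose, lloqs=lloqs),
            method=method,
            min_points=min_points,
        )
        integrated_rows.append(res.to_dict())
        integrated_results.append(res)
    integrated = pd.DataFrame(integrated_rows).reset_index(drop=True)

    frames = {
        a: per_analyte[per_analyte["analyte_id"] == a].reset_index(drop=True)
        for a in analytes
    }
    frames["Integrated Data"] = integrated
    summary = _format_summary(frames)

    return IntegratedStudyResult(
        per_analyte=per_analyte,
        weights=weights_obj,
        integrated=integrated,
        summary=summary,
        integrated_results=integrated_results,
    )
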