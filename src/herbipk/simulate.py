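"""Synthetic study generators with known ground truth.

Three generators mirror the shapes of the real inputs the pipeline consumes:

* :func:`simulate_pk_study` — a rat plasma study of five analytes in six
  subjects on the 5 min-24 h schedule, with one-compartment first-order oral
  kinetics ``C(t) = scale * ka/(ka-ke) * (exp(-ke t) - exp(-ka t))``,
  lognormal inter-individual variability on (ka, ke, scale), a
  proportional-plus-additive assay error, and LLOQ censoring;
* :func:`simulate_validation_batch` — replicate QC measurements with a known
  bias and CV;
* :func:`simulate_network_study` — compound/disease target sets with a fixed
  intersection, an Erdos-Renyi PPI layer spanning the intersection, one
  planted enriched pathway and uniform decoys.

All generators are pure functions of (configuration, seed): the same seed
reproduces the same tables bit for bit.

The default analyte presets are scaled so that the noise-free exposure
(AUC0-inf = scale/ke) and terminal half-life (ln 2/ke) of each analyte land
at the magnitudes reported for the five absorbed constituents of the herbal
extract being emulated (TSG-, EG-, PG-, AE- and EM-like), which keeps the
AUC-proportional weights of the integration stage non-degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .network import InteractionNetwork, TargetSet
from .pk_nca import STUDY_SCHEDULE_H, ConcProfile
from .validation import QCBatch


@dataclass(frozen=True)
class AnalyteKinetics:
    """One-compartment oral parameters for one analyte.

    ``ka``/``ke`` in 1/h; ``scale`` in ng/mL is the coefficient F*D/V, so the
    noise-free AUC0-inf is ``scale/ke``; ``lloq`` in ng/mL.
    """

    ka: float
    ke: float
    scale: float
    lloq: float

    def conc(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.scale * self.ka / (self.ka - self.ke) * (
            np.exp(-self.ke * t) - np.exp(-self.ka * t)
        )

    @property
    def auc_inf(self) -> float:
        return self.scale / self.ke

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.ke


#: Default analytes: ke from the reported terminal half-lives, scale from the
#: reported mean AUC0-inf values, ka set for a 0.25-0.5 h Tmax, LLOQ from the
#: assay's calibration table.
DEFAULT_ANALYTES: Mapping[str, AnalyteKinetics] = {
    "TSG": AnalyteKinetics(ka=16.0, ke=math.log(2) / 2.22, scale=758.2 * math.log(2) / 2.22, lloq=0.500),
    "EG": AnalyteKinetics(ka=8.0, ke=math.log(2) / 6.47, scale=345.8 * math.log(2) / 6.47, lloq=0.125),
    "PG": AnalyteKinetics(ka=16.0, ke=math.log(2) / 12.3, scale=205.0 * math.log(2) / 12.3, lloq=0.500),
    "AE": AnalyteKinetics(ka=16.0, ke=math.log(2) / 6.42, scale=70.28 * math.log(2) / 6.42, lloq=0.500),
    "EM": AnalyteKinetics(ka=20.0, ke=math.log(2) / 11.1, scale=1041.0 * math.log(2) / 11.1, lloq=0.500),
}

#: Oral extract dose, mg/kg (18 g/kg of extract-equivalent).
DEFAULT_DOSE_MG_PER_KG = 18000.0


@dataclass(frozen=True)
class SimStudyConfig:
    """Generative parameters for a synthetic plasma PK study."""

    analytes: Mapping[str, AnalyteKinetics] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTES)
    )
    n_subjects: int = 6
    sampling_times: tuple[float, ...] = STUDY_SCHEDULE_H
    iiv_cv: float = 0.20          # lognormal CV on ka, ke and scale
    error_prop: float = 0.10      # proportional assay CV
    error_add: float = 0.10       # additive assay SD, ng/mL
    dose: float = DEFAULT_DOSE_MG_PER_KG
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ConfigurationError("analytes: at least one analyte required")
        for name, k in self.analytes.items():
            if k.ka <= 0 or k.ke <= 0:
                raise ConfigurationError(f"analytes[{name}]: rates must be positive")
            if k.ka == k.ke:
                raise ConfigurationError(f"analytes[{name}]: ka must differ from ke")
            if k.scale <= 0:
                raise ConfigurationError(f"analytes[{name}]: scale must be positive")
            if k.lloq <= 0:
                raise ConfigurationError(f"analytes[{name}]: lloq must be positive")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects: must be >= 1")
        times = np.asarray(self.sampling_times, dtype=float)
        if len(times) < 3 or np.any(np.diff(times) <= 0) or np.any(times < 0):
            raise ConfigurationError(
                "sampling_times: need >= 3 strictly increasing non-negative times"
            )
        for fname in ("iiv_cv", "error_prop", "error_add"):
            if getattr(self, fname) < 0:
                raise ConfigurationError(f"{fname}: must be >= 0")
        if self.dose <= 0:
            raise ConfigurationError("dose: must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-median lognormal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_pk_study(config: SimStudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one study; return (long concentration table, ground-truth table).

    The concentration table has columns ``subject_id, analyte, time_h,
    conc_ng_ml, blq`` (blq as 0/1); the truth table records each subject x
    analyte's individual ka, ke, scale, true AUC0-inf (= scale/ke) and true
    terminal half-life.  Measured values below the analyte LLOQ are flagged
    BLQ (negative draws are floored at zero and flagged).
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sampling_times, dtype=float)
    conc_rows: list[dict] = []
    truth_rows: list[dict] = []
    for s in range(1, config.n_subjects + 1):
        sid = f"R{s:02d}"
        for analyte, kin in config.analytes.items():
            fka, fke, fsc = _lognormal_factor(rng, config.iiv_cv, 3)
            ka_i = kin.ka * fka
            ke_i = kin.ke * fke
            if abs(ka_i - ke_i) < 1e-9 * ka_i:   # flip-flop degeneracy guard
                ke_i *= 1.0 + 1e-6
            scale_i = kin.scale * fsc
            indiv = AnalyteKinetics(ka=ka_i, ke=ke_i, scale=scale_i, lloq=kin.lloq)
            c_true = indiv.conc(times)
            eps_p = rng.normal(0.0, 1.0, size=len(times))
            eps_a = rng.normal(0.0, 1.0, size=len(times))
            c_obs = c_true * (1.0 + config.error_prop * eps_p) + config.error_add * eps_a
            c_obs = np.maximum(c_obs, 0.0)
            blq = c_obs < kin.lloq
            for t, c, b in zip(times, c_obs, blq):
                conc_rows.append(
                    {
                        "subject_id": sid,
                        "analyte": analyte,
                        "time_h": float(t),
                        "conc_ng_ml": float(c),
                        "blq": int(b),
                    }
                )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "analyte": analyte,
                    "ka": ka_i,
                    "ke": ke_i,
                    "scale": scale_i,
                    "auc_0_inf_true": indiv.auc_inf,
                    "t_half_true": indiv.t_half,
                    "seed": config.seed,
                }
            )
    conc = pd.DataFrame(conc_rows)
    truth = pd.DataFrame(truth_rows)
    return conc, truth


def profiles_from_table(
    conc: pd.DataFrame,
    doses: Mapping[str, float] | float,
    lloqs: Mapping[str, float],
) -> list[ConcProfile]:
    """Group a long-format table into ConcProfile objects (sorted by time)."""
    if isinstance(doses, (int, float)):
        doses = {a: float(doses) for a in conc["analyte"].unique()}
    out: list[ConcProfile] = []
    for (sid, analyte), grp in conc.groupby(["subject_id", "analyte"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            ConcProfile(
                subject_id=str(sid),
                analyte_id=str(analyte),
                times=grp["time_h"].to_numpy(dtype=float),
                concs=grp["conc_ng_ml"].to_numpy(dtype=float),
                blq_flags=grp["blq"].to_numpy(dtype=bool),
                dose=doses[str(analyte)],
                lloq=lloqs[str(analyte)],
            )
        )
    return out


def simulate_validation_batch(
    nominal_levels: Mapping[str, float],
    true_bias_pct: float = 100.0,
    true_cv_pct: float = 5.0,
    n_replicates: int = 6,
    seed: int = 0,
    analyte_id: str = "A1",
    condition: str = "intra-day",
) -> list[QCBatch]:
    """Replicate QC batches with measured ~ nominal * bias * (1 + cv * Z).

    ``nominal_levels`` maps level labels (e.g. ``LQC``) to nominal
    concentrations in ng/mL.
    """
    if n_replicates < 3:
        raise ConfigurationError("n_replicates: must be >= 3")
    if true_cv_pct < 0:
        raise ConfigurationError("true_cv_pct: must be >= 0")
    rng = np.random.default_rng(seed)
    batches: list[QCBatch] = []
    for level, nominal in nominal_levels.items():
        z = rng.normal(0.0, 1.0, size=n_replicates)
        measured = nominal * (true_bias_pct / 100.0) * (1.0 + true_cv_pct / 100.0 * z)
        batches.append(
            QCBatch(
                analyte_id=analyte_id,
                level=level,  # type: ignore[arg-type]
                nominal=float(nominal),
                measured=measured,
                condition=condition,
            )
        )
    return batches


@dataclass(frozen=True)
class NetworkStudy:
    """Synthetic network-pharmacology inputs plus their ground truth."""

    compound_targets: TargetSet
    disease_targets: TargetSet
    network: InteractionNetwork
    genesets: dict[str, frozenset[str]]
    planted_pathway: str
    intersection: frozenset[str]
    seed: int


def simulate_network_study(
    n_universe: int = 200,
    n_compound: int = 40,
    n_disease: int = 60,
    overlap: int = 15,
    planted_pathway_size: int = 12,
    planted_overlap: int = 10,
    n_decoy_pathways: int = 20,
    edge_density: float = 0.05,
    seed: int = 0,
) -> NetworkStudy:
    """Plant a known intersection and one enriched pathway in a random universe.

    The compound and disease sets share exactly ``overlap`` members; the
    planted pathway contains ``planted_overlap`` intersection members (its
    remaining members are drawn outside the intersection); decoy pathways are
    uniform draws of the same size.  Edges are Erdos-Renyi at
    ``edge_density`` plus a guaranteed path spanning the intersection so the
    subnetwork of interest is connected.
    """
    if overlap > min(n_compound, n_disease):
        raise ConfigurationError("overlap: exceeds min(n_compound, n_disease)")
    if planted_overlap > min(planted_pathway_size, overlap):
        raise ConfigurationError(
            "planted_overlap: exceeds min(planted_pathway_size, overlap)"
        )
    if n_compound + n_disease - overlap > n_universe:
        raise ConfigurationError("n_universe: too small for the requested sets")
    if not (0.0 <= edge_density <= 1.0):
        raise ConfigurationError("edge_density: must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = [f"G{i:04d}" for i in range(1, n_universe + 1)]
    perm = rng.permutation(n_universe)
    inter = [universe[i] for i in perm[:overlap]]
    comp_only = [universe[i] for i in perm[overlap : n_compound]]
    dis_only = [
        universe[i] for i in perm[n_compound : n_compound + n_disease - overlap]
    ]
    compound = TargetSet(label="compound", targets=frozenset(inter + comp_only))
    disease = TargetSet(label="disease", targets=frozenset(inter + dis_only))

    # planted pathway: planted_overlap intersection members + outside filler
    inter_sorted = sorted(inter)
    planted_members: set[str] = set()
    if planted_overlap > 0:
        planted_members = set(
            map(str, rng.choice(inter_sorted, size=planted_overlap, replace=False))
        )
    outside = sorted(set(universe) - set(inter))
    filler = planted_pathway_size - planted_overlap
    if filler > 0:
        planted_members |= set(
            map(str, rng.choice(outside, size=filler, replace=False))
        )
    genesets: dict[str, frozenset[str]] = {"PW_PLANTED": frozenset(planted_members)}
    for d in range(1, n_decoy_pathways + 1):
        members = rng.choice(universe, size=planted_pathway_size, replace=False)
        genesets[f"PW_DECOY{d:03d}"] = frozenset(map(str, members))

    # PPI layer: ER(edge_density) + a path spanning the intersection
    edges: set[tuple[str, str]] = set()
    iu, ju = np.triu_indices(n_universe, k=1)
    hit = rng.random(len(iu)) < edge_density
    for i, j in zip(iu[hit], ju[hit]):
        edges.add((universe[i], universe[j]))
    for a, b in zip(inter_sorted, inter_sorted[1:]):
        edges.add(tuple(sorted((a, b))))  # type: ignore[arg-type]
    network = InteractionNetwork.from_edges(sorted(edges), extra_nodes=universe)

    return NetworkStudy(
        compound_targets=compound,
        disease_targets=disease,
        network=network,
        genesets=genesets,
        planted_pathway="PW_PLANTED",
        intersection=frozenset(inter),
        seed=seed,
    )
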