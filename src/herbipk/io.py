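"""File readers/writers, pipeline configuration and the end-to-end runner.

Formats: concentration tables and reports are UTF-8 comma-separated CSV with
a mandatory header and '.' decimals; gene sets use the Broad GMT convention
(name, description, members, tab-separated); PPI edge lists are TSV
``node_a<TAB>node_b[<TAB>score]``; subnetworks export as SIF with interaction
type ``pp``.  Every file the pipeline writes starts with a comment line
recording the configuration hash and seed, and loaders skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (
    DuplicateRecordError,
    HerbipkError,
    ParseError,
    SchemaError,
)
from .integration import WeightVector, integrated_study
from .network import (
    InteractionNetwork,
    TargetSet,
    enrich_pathways,
    enrichment_table,
    intersect_targets,
    select_key_targets,
    topology_metrics,
)
from .pk_nca import ConcProfile
from .validation import (
    CalibrationSeries,
    QCBatch,
    acceptance_check,
    fit_calibration,
    qc_statistics,
)

logger = logging.getLogger(__name__)

CONC_COLUMNS = ("subject_id", "analyte", "time_h", "conc_ng_ml", "blq")


# ---------------------------------------------------------------------------
# Concentration tables
# ---------------------------------------------------------------------------

def load_concentration_table(
    path: str | Path,
    doses: Mapping[str, float] | float,
    lloqs: Mapping[str, float],
) -> list[ConcProfile]:
    """Read a long-format concentration CSV into ConcProfile objects.

    Schema: ``subject_id,analyte,time_h,conc_ng_ml,blq``.  Rows are grouped
    by subject x analyte and sorted by time; duplicate (subject, analyte,
    time) rows are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in CONC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    for col in ("time_h", "conc_ng_ml", "blq"):
        for line_offset, raw in enumerate(df[col], start=2):
            try:
                float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path.name} line {line_offset}: cannot parse {col}={raw!r}"
                ) from None
        df[col] = df[col].astype(float)
    dup = df.duplicated(subset=["subject_id", "analyte", "time_h"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["subject_id", "analyte", "time_h"]].drop_duplicates()
        raise DuplicateRecordError(
            f"{path.name}: duplicate (subject, analyte, time) rows: "
            f"{offenders.to_dict('records')}"
        )
    if isinstance(doses, (int, float)):
        doses = {a: float(doses) for a in df["analyte"].unique()}
    profiles: list[ConcProfile] = []
    for (sid, analyte), grp in df.groupby(["subject_id", "analyte"], sort=True):
        grp = grp.sort_values("time_h")
        profiles.append(
            ConcProfile(
                subject_id=str(sid),
                analyte_id=str(analyte),
                times=grp["time_h"].to_numpy(dtype=float),
                concs=grp["conc_ng_ml"].to_numpy(dtype=float),
                blq_flags=grp["blq"].to_numpy(dtype=float).astype(bool),
                dose=doses[str(analyte)],
                lloq=lloqs[str(analyte)],
            )
        )
    return profiles


def _stamp(path: Path, text: str, config_hash: str = "", seed: Optional[int] = None) -> None:
    header = f"# herbipk v{__version__} config_hash={config_hash} seed={seed}\n"
    path.write_text(header + text, encoding="utf-8")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str = "",
    seed: Optional[int] = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as stamped CSV (config hash + seed comment line)."""
    buf = _io.StringIO()
    df.to_csv(buf, index=index)
    _stamp(Path(path), buf.getvalue(), config_hash, seed)


def write_conc_table(
    conc: pd.DataFrame, path: str | Path, config_hash: str = "", seed: Optional[int] = None
) -> None:
    write_table(conc[list(CONC_COLUMNS)], path, config_hash, seed)


# ---------------------------------------------------------------------------
# Target lists / edges / GMT / SIF
# ---------------------------------------------------------------------------

def read_targets(path: str | Path, label: Optional[str] = None) -> TargetSet:
    """One identifier per line (or first TSV column); '#' lines skipped."""
    path = Path(path)
    ids = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.append(line.split("\t")[0])
    return TargetSet(label=label or path.stem, targets=frozenset(ids))


def write_targets(ts: TargetSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ts.targets)) + "\n", encoding="utf-8")


def read_edges(path: str | Path) -> list[tuple]:
    """TSV edge list ``a<TAB>b[<TAB>score]`` (STRING-export compatible)."""
    path = Path(path)
    edges: list[tuple] = []
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path.name} line {ln}: need at least two columns")
        if len(parts) >= 3 and parts[2] != "":
            try:
                score = float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {ln}: cannot parse score {parts[2]!r}"
                ) from None
            edges.append((parts[0], parts[1], score))
        else:
            edges.append((parts[0], parts[1]))
    return edges


def write_edges(edges: Iterable[tuple], path: str | Path) -> None:
    lines = []
    for e in edges:
        if len(e) > 2 and e[2] is not None:
            lines.append(f"{e[0]}\t{e[1]}\t{e[2]}")
        else:
            lines.append(f"{e[0]}\t{e[1]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Broad-convention GMT: name, description, members (tab-separated)."""
    genesets: dict[str, frozenset[str]] = {}
    for ln, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{Path(path).name} line {ln}: need name, description, members")
        genesets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return genesets


def write_gmt(genesets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "herbipk"] + sorted(members))
        for name, members in sorted(genesets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_sif(network: InteractionNetwork, path: str | Path) -> None:
    """Cytoscape-loadable SIF with interaction type ``pp``."""
    lines = []
    seen = set()
    for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
        if (a, b) in seen:
            continue
        seen.add((a, b))
        lines.append(f"{a}\tpp\t{b}")
    for node in sorted(network.graph.nodes):
        if network.graph.degree(node) == 0:
            lines.append(node)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; round-trips through YAML/JSON."""

    conc_path: str
    dose_mg_per_kg: float
    lloqs: dict[str, float]
    out_dir: str
    method: str = "linear"
    min_points: int = 3
    basis: str = "auc_0_inf"
    scope: str = "pooled-mean"
    cal_path: Optional[str] = None
    qc_path: Optional[str] = None
    compound_targets_path: Optional[str] = None
    disease_targets_path: Optional[str] = None
    ppi_path: Optional[str] = None
    gmt_path: Optional[str] = None
    score_cutoff: Optional[float] = None
    ease: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _validation_stage(config: PipelineConfig, out: Path, h: str) -> int:
    rows = []
    if config.cal_path:
        cal = pd.read_csv(config.cal_path, comment="#")
        for analyte, grp in cal.groupby("analyte"):
            series = CalibrationSeries(
                analyte_id=str(analyte),
                nominal_concs=grp["nominal_ng_ml"].to_numpy(dtype=float),
                response_ratios=grp["response_ratio"].to_numpy(dtype=float),
            )
            fit = fit_calibration(series)
            rows.append(
                {
                    "analyte": analyte,
                    "kind": "calibration",
                    "level": "",
                    "condition": "",
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r": fit.r,
                    "rsd_pct": np.nan,
                    "accuracy_pct": np.nan,
                    "passed": fit.valid,
                }
            )
    if config.qc_path:
        qc = pd.read_csv(config.qc_path, comment="#")
        for (analyte, level, condition), grp in qc.groupby(
            ["analyte", "level", "condition"]
        ):
            batch = QCBatch(
                analyte_id=str(analyte),
                level=str(level),  # type: ignore[arg-type]
                nominal=float(grp["nominal_ng_ml"].iloc[0]),
                measured=grp["measured_ng_ml"].to_numpy(dtype=float),
                condition=str(condition),
            )
            rsd, acc = qc_statistics(batch)
            rep = acceptance_check(acc, rsd, batch.level)
            rows.append(
                {
                    "analyte": analyte,
                    "kind": "qc",
                    "level": level,
                    "condition": condition,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "r": np.nan,
                    "rsd_pct": rsd,
                    "accuracy_pct": acc,
                    "passed": rep.passed,
                }
            )
    report = pd.DataFrame(rows)
    write_table(report, out / "validation_report.csv", h, None)
    return len(report)


def _network_stage(config: PipelineConfig, out: Path, h: str) -> dict:
    compound = read_targets(config.compound_targets_path, "compound")
    disease = read_targets(config.disease_targets_path, "disease")
    common = intersect_targets(compound, disease)
    edges = read_edges(config.ppi_path)
    net = InteractionNetwork.from_edges(edges, score_cutoff=config.score_cutoff)
    sub = net.subnetwork(common.targets & net.nodes)
    metrics = topology_metrics(sub)
    key = select_key_targets(metrics)
    write_table(metrics.reset_index(), out / "node_metrics.csv", h, config.seed)
    write_sif(sub, out / "subnetwork.sif")
    pd.DataFrame({"target": key}).pipe(
        write_table, out / "key_targets.csv", h, config.seed
    )
    counts = {
        "n_compound": len(compound),
        "n_disease": len(disease),
        "n_intersection": len(common),
        "n_key_targets": len(key),
    }
    if config.gmt_path:
        genesets = read_gmt(config.gmt_path)
        universe = net.nodes
        query = common.targets & universe
        results = enrich_pathways(
            TargetSet(label=common.label, targets=query),
            genesets,
            universe,
            ease=config.ease,
        )
        write_table(enrichment_table(results), out / "enrichment.csv", h, config.seed)
        counts["n_pathways_tested"] = len(results)
    return counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run validate (optional) → NCA → weights → integrated NCA → network.

    Writes the summary tables plus ``manifest.json`` recording the config
    hash, seed, package version and per-stage row counts; any stage failure
    halts with a stage-labelled error while earlier outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    manifest: dict = {
        "config_hash": h,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        raise HerbipkError(f"stage {stage!r} failed: {exc}") from exc

    # validation (optional)
    if config.cal_path or config.qc_path:
        try:
            n = _validation_stage(config, out, h)
            manifest["stages"]["validation"] = {"status": "ok", "rows": n}
        except Exception as exc:
            fail("validation", exc)
    else:
        manifest["stages"]["validation"] = {"status": "skipped"}

    # PK stages
    try:
        profiles = load_concentration_table(
            config.conc_path, config.dose_mg_per_kg, config.lloqs
        )
        result = integrated_study(
            profiles,
            method=config.method,
            min_points=config.min_points,
            basis=config.basis,  # type: ignore[arg-type]
            scope=config.scope,  # type: ignore[arg-type]
        )
        write_table(result.per_analyte, out / "nca_per_subject.csv", h, config.seed)
        write_table(result.integrated, out / "integrated_per_subject.csv", h, config.seed)
        write_table(
            result.summary.rename_axis("parameter").reset_index(),
            out / "nca_summary.csv",
            h,
            config.seed,
        )
        weights = result.weights
        if isinstance(weights, WeightVector):
            wdf = pd.DataFrame(
                {"analyte": weights.analyte_ids, "weight": weights.weights}
            )
        else:
            wdf = pd.DataFrame(
                [
                    {"subject_id": sid, "analyte": a, "weight": w}
                    for sid, wv in weights.items()
                    for a, w in wv.as_dict().items()
                ]
            )
        write_table(wdf, out / "weights.csv", h, config.seed)
        manifest["stages"]["pk"] = {
            "status": "ok",
            "rows": int(len(result.per_analyte)),
            "subjects_integrated": int(len(result.integrated)),
        }
    except Exception as exc:
        fail("pk", exc)

    # network (optional)
    net_inputs = (
        config.compound_targets_path,
        config.disease_targets_path,
        config.ppi_path,
    )
    if all(net_inputs):
        try:
            counts = _network_stage(config, out, h)
            manifest["stages"]["network"] = {"status": "ok", **counts}
        except Exception as exc:
            fail("network", exc)
    else:
        manifest["stages"]["network"] = {"status": "skipped"}

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
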