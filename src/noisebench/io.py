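"""On-disk formats, run configuration and the end-to-end pipeline.

Count matrices travel as a Matrix Market bundle (``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv`` + ``cells.csv`` metadata) or as a dense
CSV with a ``<stem>.cells.csv`` sidecar; smFISH cell tables as flat CSV.
Round trips are lossless for integer matrices.  ``run_pipeline`` chains
the stages of the two analysis arms (UMI-matrix and cell-table) plus the
method-scoring comparison, and emits a manifest with content hashes so a
rerun with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy import sparse

from . import burst as burst_mod
from . import extrinsic as ext_mod
from . import metrics as met_mod
from . import scoring as score_mod
from .simulate import GroundTruth, SimConfig, simulate_smfish, simulate_umi_matrix
from .metrics import CountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_cell_table",
    "write_cell_table",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("noisebench")

CELL_TABLE_REQUIRED = ["cell_id", "condition", "replicate", "area"]


# ---------------------------------------------------------------------------
# Count matrices


def write_count_matrix(m: CountMatrix, path) -> Path:
    """Write an MTX bundle into directory ``path`` (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(m.counts)
    field = "integer" if np.issubdtype(m.counts.dtype, np.integer) else "real"
    sio.mmwrite(path / "matrix.mtx", mat, field=field)
    (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    meta = m.cell_meta[["condition", "replicate"]].copy()
    meta.insert(0, "cell_id", m.cell_ids)
    meta.to_csv(path / "cells.csv", index=False)
    return path


def _read_mtx_bundle(path: Path) -> CountMatrix:
    mtx = path / "matrix.mtx"
    try:
        counts = np.asarray(sio.mmread(mtx).todense())
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    gene_ids = [l.split("\t")[0] for l in (path / "genes.tsv").read_text().splitlines() if l]
    cell_ids = [l.split("\t")[0] for l in (path / "barcodes.tsv").read_text().splitlines() if l]
    meta = pd.read_csv(path / "cells.csv").set_index("cell_id")
    if counts.size == 0:
        raise ValueError(f"empty count matrix in {mtx}")
    if np.allclose(counts, np.rint(counts)):
        counts = np.rint(counts).astype(np.int64)
    return CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                       cell_meta=meta[["condition", "replicate"]])


def write_count_matrix_csv(m: CountMatrix, path) -> Path:
    """Dense-CSV fallback: genes as rows, cells as columns, plus sidecar."""
    path = Path(path)
    df = pd.DataFrame(m.counts, index=pd.Index(m.gene_ids, name="gene_id"),
                      columns=m.cell_ids)
    df.to_csv(path)
    meta = m.cell_meta[["condition", "replicate"]].copy()
    meta.insert(0, "cell_id", m.cell_ids)
    meta.to_csv(path.with_suffix(".cells.csv"), index=False)
    return path


def read_count_matrix(path) -> CountMatrix:
    """Read an MTX bundle directory or a dense CSV (with cells sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix input not found: {path}")
    if path.is_dir():
        return _read_mtx_bundle(path)
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"empty count matrix in {path}")
    sidecar = path.with_suffix(".cells.csv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar).set_index("cell_id")
    else:
        raise FileNotFoundError(
            f"dense CSV {path} needs a {sidecar.name} metadata sidecar"
        )
    counts = df.to_numpy()
    if np.allclose(counts, np.rint(counts)):
        counts = np.rint(counts).astype(np.int64)
    return CountMatrix(
        counts=counts,
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        cell_meta=meta[["condition", "replicate"]],
    )


# ---------------------------------------------------------------------------
# Cell tables and ground truth


def write_cell_table(t: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t.to_csv(path, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cell table not found: {path}")
    t = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_REQUIRED if c not in t.columns]
    if missing:
        raise ValueError(f"cell table {path} missing required columns: {missing}")
    if not any(c.startswith("count_") for c in t.columns):
        raise ValueError(f"cell table {path} has no count_<gene> columns")
    dupes = t["cell_id"][t["cell_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate cell_id values in {path}: {dupes[:5]}")
    if (t["area"] <= 0).any():
        raise ValueError(f"non-positive cell areas in {path}")
    return t


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    payload = {
        "genes": truth.genes.to_dict(orient="records"),
        "cells": truth.cells.to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(genes=pd.DataFrame(d["genes"]), cells=pd.DataFrame(d["cells"]))


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclasses.dataclass
class RunConfig:
    """Everything a full run needs; serializable to/from YAML or JSON."""

    sim: SimConfig
    out_dir: str = "noisebench_run"
    seed: int = 0
    # UMI arm
    qc_min_genes: int = 0
    qc_min_umi: int = 0
    qc_max_mito_frac: float | None = None
    coverage_min_mean: float = 0.1
    coverage_min_detect_frac: float = 0.05
    normalize_scale: float = 1e4
    # cell-table arm
    filter_alpha: float = 0.01
    filter_n_perm: int = 10_000
    filter_init_trim: tuple[float, float] = (5, 95)
    filter_iter_trim: tuple[float, float] = (2, 98)
    filter_r_max: float = 0.45
    filter_min_cells: int = 50
    filter_max_iter: int = 25
    burst_min_cells: int = 25
    # scoring: extra method tables (name -> fold-change TSV path)
    method_tables: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["filter_init_trim"] = list(self.filter_init_trim)
        d["filter_iter_trim"] = list(self.filter_iter_trim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["sim"] = SimConfig.from_dict(d["sim"])
        for k in ("filter_init_trim", "filter_iter_trim"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Simulate-and-analyze end to end; return the run manifest.

    Stage order: simulate both arms -> [UMI arm] QC -> coverage filter ->
    depth normalization -> per-replicate noise -> replicate average ->
    fold changes -> [cell-table arm] extrinsic filter per gene ->
    per-replicate noise -> replicate average -> fold changes (the
    reference) -> burst fits and fold changes -> reciprocity regression
    -> scoring of the UMI arm (plus any ingested method tables) against
    the reference.  All outputs land in ``config.out_dir``; the manifest
    records the config hash and a sha256 per output file.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only: where outputs land and how
    # verbosely we log must not change the run's identity
    hashable = {k: v for k, v in config.to_dict().items()
                if k not in ("out_dir", "log_level")}
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(hashable, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "warnings": [],
        "outputs": {},
    }
    files: dict[str, Path] = {}

    sim = dataclasses.replace(config.sim, seed=config.seed)

    # --- cell-table (smFISH-like) arm: the reference
    fish_t, fish_c, truth = simulate_smfish(sim)
    files["cells_treated"] = write_cell_table(fish_t, out / "cells_treated.csv")
    files["cells_control"] = write_cell_table(fish_c, out / "cells_control.csv")
    files["ground_truth"] = write_ground_truth(truth, out / "ground_truth.json")

    pooled = pd.concat([fish_c, fish_t], ignore_index=True)
    gene_ids = [c[len("count_"):] for c in pooled.columns if c.startswith("count_")]
    filter_results = {}
    filtered = {}
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(99,)))
    for gid in gene_ids:
        res = ext_mod.iterative_extrinsic_filter(
            pooled, gid,
            alpha=config.filter_alpha, n_perm=config.filter_n_perm,
            init_trim=config.filter_init_trim, iter_trim=config.filter_iter_trim,
            r_max=config.filter_r_max, min_cells=config.filter_min_cells,
            max_iter=config.filter_max_iter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        filter_results[gid] = res
        manifest["warnings"] += [f"{gid}: {w}" for w in res.warnings]
        filtered[gid] = pooled[pooled["cell_id"].isin(res.retained_ids)]
    (out / "filter_results.json").write_text(json.dumps(
        {g: r.to_dict() for g, r in filter_results.items()}))
    files["filter_results"] = out / "filter_results.json"

    def fish_summaries(condition: str) -> list[pd.DataFrame]:
        per_rep: dict[int, list[pd.DataFrame]] = {}
        for gid in gene_ids:
            sub = filtered[gid]
            sub = sub[sub["condition"] == condition]
            for rep, grp in sub.groupby("replicate"):
                s = met_mod.noise_summary(
                    grp[f"count_{gid}"].to_numpy()[np.newaxis, :], gene_ids=[gid]
                )
                per_rep.setdefault(rep, []).append(s)
        return [pd.concat(v, ignore_index=True) for _, v in sorted(per_rep.items())]

    fish_sum_t = met_mod.replicate_average(fish_summaries("treated"))
    fish_sum_c = met_mod.replicate_average(fish_summaries("control"))
    fish_fc = met_mod.fold_change_table(fish_sum_t, fish_sum_c)
    files["smfish_fold_changes"] = _write_tsv(fish_fc, out / "smfish_fold_changes.tsv")

    fish_cells = {gid: tab for gid, tab in filtered.items()}
    fits_t = []
    fits_c = []
    for gid in gene_ids:
        tab = fish_cells[gid]
        fits_t += burst_mod.fit_cell_table(
            tab[tab["condition"] == "treated"], genes=[gid],
            min_cells=config.burst_min_cells)
        fits_c += burst_mod.fit_cell_table(
            tab[tab["condition"] == "control"], genes=[gid],
            min_cells=config.burst_min_cells)
    burst_fc = burst_mod.burst_fold_changes(fits_t, fits_c)
    files["burst_fold_changes"] = _write_tsv(
        burst_fc.per_gene, out / "burst_fold_changes.tsv")
    reps = burst_fc.per_replicate
    reps = reps[reps["replicate"] != "pooled"]
    if len(reps) >= 3 and reps["log2_d_f"].nunique() > 1:
        regression = burst_mod.reciprocity_regression(
            reps["log2_d_f"], reps["log2_d_b"])
    else:
        regression = None
        manifest["warnings"].append("too few burst fits for reciprocity regression")
    (out / "reciprocity.json").write_text(json.dumps(regression))
    files["reciprocity"] = out / "reciprocity.json"

    # --- UMI (scRNA-seq-like) arm
    umi_t, umi_c, _ = simulate_umi_matrix(sim)

    def umi_fold_changes(mt: CountMatrix, mc: CountMatrix) -> pd.DataFrame:
        summaries = []
        for m in (mt, mc):
            # min_umi floor of 1: zero-total cells are unnormalizable
            m, _ = met_mod.qc_filter_cells(
                m, min_genes=config.qc_min_genes,
                min_umi=max(1, config.qc_min_umi),
                max_mito_frac=config.qc_max_mito_frac)
            m = met_mod.gene_coverage_filter(
                m, config.coverage_min_mean, config.coverage_min_detect_frac)
            m = met_mod.raw_normalize(m, scale=config.normalize_scale)
            reps = []
            for rep_id in sorted(m.cell_meta["replicate"].unique()):
                sub = m.subset_cells(
                    (m.cell_meta["replicate"] == rep_id).to_numpy())
                reps.append(met_mod.noise_summary(sub))
            summaries.append(met_mod.replicate_average(reps))
        return met_mod.fold_change_table(*summaries)

    umi_fc = umi_fold_changes(umi_t, umi_c)
    files["umi_fold_changes"] = _write_tsv(umi_fc, out / "umi_fold_changes.tsv")

    # --- scoring
    tables = {"umi_raw": umi_fc}
    for name, p in config.method_tables.items():
        tables[name] = pd.read_csv(p, sep="\t")
    scores = score_mod.rank_methods(tables, fish_fc)
    files["scores"] = _write_tsv(scores, out / "scores.tsv")
    under = score_mod.underestimation_report(tables, fish_fc)
    files["underestimation"] = _write_tsv(under, out / "underestimation.tsv")

    for name, p in files.items():
        manifest["outputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
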