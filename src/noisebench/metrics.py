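"""Count-matrix QC, depth normalization, and per-gene noise summaries.

The quantities of interest for each gene are its mean mRNA level mu, the
squared coefficient of variation CV2 = sigma^2 / mu^2, and the Fano
factor FF = sigma^2 / mu across cells.  Fano = 1 marks Poissonian
expression; FF > 1 indicates bursty (super-Poissonian) transcription.
Treated/control ratios of these metrics ("fold changes", d_*) are the
common currency of all downstream stages.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "QCReport",
    "qc_filter_cells",
    "gene_coverage_filter",
    "raw_normalize",
    "noise_summary",
    "cell_table_noise_summary",
    "fold_change_table",
    "replicate_average",
    "negative_control_split",
    "compare_populations",
    "amplified_fraction",
]

SUMMARY_COLUMNS = ["gene_id", "n_cells", "mean", "var", "cv2", "fano", "undefined"]
FOLD_COLUMNS = ["gene_id", "d_mean", "d_cv2", "d_fano"]


@dataclass
class CountMatrix:
    """Genes x cells count matrix with per-cell metadata.

    ``counts`` is integer for raw data; normalized matrices are
    real-valued (``normalized`` records the scale applied).  ``cell_meta``
    is indexed by cell id and always carries ``condition``, ``replicate``,
    plus derived ``total_count``, ``n_genes`` and ``mito_frac`` columns.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    normalized: float | None = None
    mito_gene_prefix: str = "mt-"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} count rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} count columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        meta = self.cell_meta.copy()
        missing = set(self.cell_ids) - set(meta.index.astype(str))
        if missing:
            raise ValueError(f"cell_meta missing rows for cells: {sorted(missing)[:5]}")
        meta = meta.loc[self.cell_ids]
        meta["total_count"] = self.counts.sum(axis=0)
        meta["n_genes"] = (self.counts > 0).sum(axis=0)
        mito = np.array(
            [g.lower().startswith(self.mito_gene_prefix.lower()) for g in self.gene_ids]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(
                meta["total_count"].to_numpy() > 0,
                self.counts[mito].sum(axis=0) / meta["total_count"].to_numpy(),
                0.0,
            )
        meta["mito_frac"] = frac
        self.cell_meta = meta

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx][["condition", "replicate"]],
            normalized=self.normalized,
            mito_gene_prefix=self.mito_gene_prefix,
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cell_meta=self.cell_meta[["condition", "replicate"]],
            normalized=self.normalized,
            mito_gene_prefix=self.mito_gene_prefix,
        )


@dataclass
class QCReport:
    """Cells removed per criterion (a cell may fail several)."""

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)


def qc_filter_cells(
    m: CountMatrix,
    min_genes: int = 0,
    min_umi: int = 0,
    max_genes: int | None = None,
    max_umi: int | None = None,
    max_mito_frac: float | None = None,
    mito_gene_prefix: str | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells by detected genes, depth and mito content.

    Boundary semantics: minimum thresholds are inclusive (a cell with
    exactly ``min_genes`` detected genes is kept), maximum thresholds and
    the mitochondrial fraction are strict (a cell at exactly
    ``max_mito_frac`` is removed, matching the "<10%" convention).
    """
    if min_genes < 0 or min_umi < 0:
        raise ValueError("thresholds must be non-negative")
    if mito_gene_prefix is not None and mito_gene_prefix != m.mito_gene_prefix:
        m = CountMatrix(
            counts=m.counts,
            gene_ids=list(m.gene_ids),
            cell_ids=list(m.cell_ids),
            cell_meta=m.cell_meta[["condition", "replicate"]],
            normalized=m.normalized,
            mito_gene_prefix=mito_gene_prefix,
        )
    meta = m.cell_meta
    checks = {
        "min_genes": meta["n_genes"].to_numpy() >= min_genes,
        "min_umi": meta["total_count"].to_numpy() >= min_umi,
    }
    if max_genes is not None:
        checks["max_genes"] = meta["n_genes"].to_numpy() < max_genes
    if max_umi is not None:
        checks["max_umi"] = meta["total_count"].to_numpy() < max_umi
    if max_mito_frac is not None:
        checks["max_mito_frac"] = meta["mito_frac"].to_numpy() < max_mito_frac
    keep = np.logical_and.reduce(list(checks.values()))
    report = QCReport(
        n_input=m.n_cells,
        n_retained=int(keep.sum()),
        removed={k: int((~v).sum()) for k, v in checks.items()},
    )
    if report.n_retained == 0:
        raise ValueError(
            "QC removed all cells; removed per criterion: " f"{report.removed}"
        )
    return m.subset_cells(keep), report


def gene_coverage_filter(
    m: CountMatrix,
    min_mean_count: float = 0.1,
    min_detect_frac: float = 0.05,
) -> CountMatrix:
    """Keep genes with sufficient coverage in *every* condition.

    A gene passes in a condition when its mean count and its detection
    fraction (cells with count > 0) both reach the thresholds; the gene
    is retained only if it passes in all conditions present (intersection
    rule), so downstream fold changes are computable for every retained
    gene.
    """
    if not (0.0 <= min_detect_frac <= 1.0):
        raise ValueError("min_detect_frac must be in [0, 1]")
    conditions = m.cell_meta["condition"].to_numpy()
    keep = np.ones(m.n_genes, dtype=bool)
    for cond in pd.unique(conditions):
        sub = m.counts[:, conditions == cond]
        means = sub.mean(axis=1)
        detect = (sub > 0).mean(axis=1)
        keep &= (means >= min_mean_count) & (detect >= min_detect_frac)
    if not keep.any():
        warnings.warn("gene_coverage_filter removed all genes", stacklevel=2)
    return m.subset_genes(keep)


def raw_normalize(m: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """Depth normalization: each cell divided by its total, times ``scale``.

    After normalization every cell's values sum to ``scale`` exactly (up
    to float round-off), and within-cell gene proportions are preserved.
    """
    totals = m.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [m.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total count cannot be normalized: {names}")
    normed = m.counts / totals[np.newaxis, :] * scale
    return CountMatrix(
        counts=normed,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        cell_meta=m.cell_meta[["condition", "replicate"]],
        normalized=scale,
        mito_gene_prefix=m.mito_gene_prefix,
    )


def noise_summary(values, gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-gene noise summary: n, mean, variance (ddof=1), CV2 and Fano.

    ``values`` is a :class:`CountMatrix`, a genes x cells array, or a
    1-D vector for a single gene.  Genes with zero mean get ``cv2`` and
    ``fano`` as NaN and ``undefined=True`` — flagged, never dropped.
    """
    if isinstance(values, CountMatrix):
        gene_ids = list(values.gene_ids)
        arr = np.asarray(values.counts, dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(arr.shape[0])]
    if arr.shape[1] < 2:
        raise ValueError("noise summary requires at least 2 cells")
    n = arr.shape[1]
    mu = arr.mean(axis=1)
    var = arr.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
        fano = np.where(mu > 0, var / mu, np.nan)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_cells": n,
            "mean": mu,
            "var": var,
            "cv2": cv2,
            "fano": fano,
            "undefined": mu == 0,
        }
    )


def cell_table_noise_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Noise summary for an smFISH cell table (``count_<gene>`` columns)."""
    count_cols = [c for c in cells.columns if c.startswith("count_")]
    if not count_cols:
        raise ValueError("cell table has no count_<gene> columns")
    gene_ids = [c[len("count_"):] for c in count_cols]
    arr = cells[count_cols].to_numpy(dtype=float).T
    return noise_summary(arr, gene_ids=gene_ids)


def fold_change_table(
    treated: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Treated/control ratios of mean, CV2 and Fano, per gene.

    Genes missing from either summary, or whose control metrics are zero
    or undefined, are excluded; the exclusions with reasons are attached
    as ``result.attrs['excluded']``.
    """
    t = treated.set_index("gene_id")
    c = control.set_index("gene_id")
    common = t.index.intersection(c.index)
    if len(common) == 0:
        raise ValueError("no overlapping genes between treated and control")
    excluded: list[tuple[str, str]] = []
    rows = []
    for gid in common:
        tr, cr = t.loc[gid], c.loc[gid]
        if tr["undefined"] or cr["undefined"]:
            excluded.append((gid, "zero mean"))
            continue
        if cr["mean"] <= 0 or cr["cv2"] <= 0 or cr["fano"] <= 0:
            excluded.append((gid, "non-positive control metric"))
            continue
        rows.append(
            {
                "gene_id": gid,
                "d_mean": tr["mean"] / cr["mean"],
                "d_cv2": tr["cv2"] / cr["cv2"],
                "d_fano": tr["fano"] / cr["fano"],
            }
        )
    out = pd.DataFrame(rows, columns=FOLD_COLUMNS)
    out.attrs["excluded"] = excluded
    for gid in set(t.index) ^ set(c.index):
        excluded.append((gid, "missing in one condition"))
    return out


def replicate_average(summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-gene metrics over replicates.

    A gene must be present (and defined) in *all* replicates to be kept;
    metrics are arithmetically averaged, ``n_cells`` summed.
    """
    if not summaries:
        raise ValueError("no summaries to average")
    if len(summaries) == 1:
        return summaries[0].copy()
    indexed = [s[~s["undefined"]].set_index("gene_id") for s in summaries]
    common = indexed[0].index
    for s in indexed[1:]:
        common = common.intersection(s.index)
    metrics = ["mean", "var", "cv2", "fano"]
    acc = sum(s.loc[common, metrics] for s in indexed) / len(indexed)
    out = acc.reset_index()
    n_cells = sum(s.loc[common, "n_cells"].to_numpy() for s in indexed) if len(common) else []
    out.insert(1, "n_cells", n_cells)
    out["undefined"] = False
    return out[SUMMARY_COLUMNS]


def negative_control_split(
    m: CountMatrix, seed: int = 0
) -> tuple[CountMatrix, CountMatrix, dict]:
    """Randomly split cells into two disjoint halves and compare their noise.

    The report carries rank-sum p-values comparing the per-gene CV2 and
    Fano vectors between halves — a negative control: on homogeneous data
    the halves should be statistically indistinguishable.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_cells)
    half = m.n_cells // 2
    a = m.subset_cells(np.sort(perm[:half]))
    b = m.subset_cells(np.sort(perm[half:]))
    sa, sb = noise_summary(a), noise_summary(b)
    report = {}
    for metric in ("cv2", "fano"):
        va = sa[metric].dropna().to_numpy()
        vb = sb[metric].dropna().to_numpy()
        stat, p = compare_populations(va, vb, test="rank_sum")
        report[f"{metric}_rank_sum_p"] = p
        report[f"{metric}_rank_sum_stat"] = stat
    report["n_a"], report["n_b"] = a.n_cells, b.n_cells
    return a, b, report


# ---------------------------------------------------------------------------
# Rank tests


def _signed_rank_exact(diffs: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank p by enumerating the 2^n sign assignments.

    Uses the permutation distribution of W+ conditional on the observed
    mid-ranks (valid with ties among |d|), computed by dynamic programming
    over doubled ranks so all weights are integers.
    """
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # distribution of 2*W+ over all sign patterns
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0**n
    w2 = int(round(2 * w_plus))
    p_ge = float(dist[w2:].sum())
    p_le = float(dist[: w2 + 1].sum())
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_plus, p


def compare_populations(
    a,
    b,
    test: str = "rank_sum",
    alternative: str = "two_sided",
    paired: bool = False,
) -> tuple[float, float]:
    """Non-parametric two-group comparison.

    ``rank_sum`` is the Wilcoxon rank-sum (Mann-Whitney U) test for
    independent samples; ``signed_rank`` the paired Wilcoxon signed-rank
    test (zeros dropped, Wilcoxon's original policy).  Small samples
    (n <= 25) get exact enumeration; larger ones the normal approximation
    with continuity correction.  Returns ``(statistic, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    if test == "signed_rank" or paired and test != "rank_sum":
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length, aligned samples")
        d = a - b
        nz = int(np.count_nonzero(d))
        if nz == 0:
            return 0.0, 1.0
        if nz <= 25:
            return _signed_rank_exact(d, alternative)
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=True, alternative=alt,
            method="approx",
        )
        return float(res.statistic), float(res.pvalue)
    if test != "rank_sum":
        raise ValueError(f"unknown test {test!r}")
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum requires non-empty samples")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size <= 25 and b.size <= 25 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative=alt, method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative=alt, method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def amplified_fraction(
    fc: pd.DataFrame, metric: str = "d_fano", threshold: float = 1.0
) -> float:
    """Fraction of genes whose fold change in ``metric`` exceeds ``threshold``."""
    if not metric.startswith("d_"):
        metric = f"d_{metric}"
    vals = fc[metric].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite fold changes")
    return float(np.mean(vals > threshold))
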