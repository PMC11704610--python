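"""Score normalization methods against an smFISH fold-change reference.

A method k supplies per-gene treated/control fold changes D_jk for the
mean, CV2 and Fano factor; the smFISH reference supplies E_j.  For each
metric the deviation is

    chi_ik = median_j ( (D_jk - E_j) / E_j )^2

and the combined score S_k = chi_mean + chi_cv2 + chi_fano.  The method
with minimal S tracks the direct single-molecule counts most closely.
The median makes chi robust: fewer than half the genes going wrong
cannot drag it outside the range of the clean genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "chi_metric",
    "combined_score",
    "rank_methods",
    "underestimation_report",
    "fold_change_correlations",
]

METRICS = ("d_mean", "d_cv2", "d_fano")


def _aligned(d: pd.Series, e: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    common = d.index.intersection(e.index)
    dv = d.loc[common].to_numpy(dtype=float)
    ev = e.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(dv) & np.isfinite(ev) & (ev != 0)
    return dv[ok], ev[ok]


def chi_metric(d, e) -> float:
    """Median squared relative deviation of method values from the reference.

    ``d`` and ``e`` are per-gene value mappings (Series indexed by gene
    id, or aligned arrays).  Genes with missing or zero reference are
    excluded pairwise.  Even-length medians average the central pair.
    """
    if not isinstance(d, pd.Series):
        d = pd.Series(np.asarray(d, dtype=float))
    if not isinstance(e, pd.Series):
        e = pd.Series(np.asarray(e, dtype=float))
    dv, ev = _aligned(d, e)
    if dv.size == 0:
        raise ValueError("no overlapping genes with a usable reference value")
    return float(np.median(((dv - ev) / ev) ** 2))


def combined_score(chi_mean: float, chi_cv2: float, chi_fano: float) -> float:
    """S = chi_mean + chi_cv2 + chi_fano (lower = closer to the reference)."""
    return chi_mean + chi_cv2 + chi_fano


def rank_methods(
    tables: dict[str, pd.DataFrame], reference: pd.DataFrame
) -> pd.DataFrame:
    """Score every method table against the reference; sort ascending by S.

    Tables are fold-change DataFrames with ``gene_id`` and the three
    ``d_*`` columns.  Ties in S are broken lexicographically by method
    name.  Returns one row per method with chi per metric, S, rank and
    the per-metric gene counts used.
    """
    ref = reference.set_index("gene_id")
    rows = []
    for name in sorted(tables):
        tab = tables[name].set_index("gene_id")
        chis = {}
        n_used = {}
        for metric in METRICS:
            dv, ev = _aligned(tab[metric], ref[metric])
            if dv.size == 0:
                raise ValueError(
                    f"method {name!r}: no overlapping genes for {metric}"
                )
            chis[metric] = float(np.median(((dv - ev) / ev) ** 2))
            n_used[metric] = int(dv.size)
        rows.append(
            {
                "method": name,
                "chi_mean": chis["d_mean"],
                "chi_cv2": chis["d_cv2"],
                "chi_fano": chis["d_fano"],
                "S": combined_score(chis["d_mean"], chis["d_cv2"], chis["d_fano"]),
                "n_genes_mean": n_used["d_mean"],
                "n_genes_cv2": n_used["d_cv2"],
                "n_genes_fano": n_used["d_fano"],
            }
        )
    out = pd.DataFrame(rows).sort_values(["S", "method"], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def underestimation_report(
    tables: dict[str, pd.DataFrame],
    reference: pd.DataFrame,
    metric: str = "d_fano",
) -> pd.DataFrame:
    """Quantify systematic shrinkage of fold changes toward 1.

    For each method: the fraction of genes whose fold change sits
    strictly closer to 1 than the reference on the log scale
    (|log2 D| < |log2 E|; exact ties count as neither), and the median
    of |log2 D| - |log2 E| (negative = the method compresses the effect
    the reference sees).
    """
    ref = reference.set_index("gene_id")[metric]
    rows = []
    for name in sorted(tables):
        dv, ev = _aligned(tables[name].set_index("gene_id")[metric], ref)
        ok = (dv > 0) & (ev > 0)
        dl, el = np.abs(np.log2(dv[ok])), np.abs(np.log2(ev[ok]))
        if dl.size == 0:
            raise ValueError(f"method {name!r}: no usable genes")
        rows.append(
            {
                "method": name,
                "metric": metric,
                "frac_underestimated": float(np.mean(dl < el)),
                "median_abs_log2_diff": float(np.median(dl - el)),
                "n_genes": int(dl.size),
            }
        )
    return pd.DataFrame(rows)


def fold_change_correlations(
    tables: dict[str, pd.DataFrame], metric: str = "d_fano"
) -> pd.DataFrame:
    """Pairwise Pearson correlations of log fold-change vectors.

    Convenience diagnostic for method agreement; computed on genes
    shared by each pair.
    """
    names = sorted(tables)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        sa = tables[a].set_index("gene_id")[metric]
        for b in names[i + 1:]:
            sb = tables[b].set_index("gene_id")[metric]
            common = sa.index.intersection(sb.index)
            va, vb = np.log(sa.loc[common]), np.log(sb.loc[common])
            r = float(np.corrcoef(va, vb)[0, 1]) if len(common) > 2 else np.nan
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
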