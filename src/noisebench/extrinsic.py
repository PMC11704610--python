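"""Extrinsic-noise filtering of smFISH cell tables by cell size.

Cell-to-cell differences in size (and hence total transcriptional
capacity) inflate apparent expression noise beyond the intrinsic
bursting component.  Two complementary remedies are implemented:

* the iterative percentile filter — trim area outliers from the pooled
  control+treated population (5th/95th percentile once, then 2nd/98th
  repeatedly) until (a) a permutation test can no longer distinguish the
  two conditions' area distributions and (b) count-vs-area correlation
  is weak in both conditions;
* the regression correction — remove the component of count variance
  explained by a linear fit on area, leaving a size-corrected noise
  summary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import noise_summary

__all__ = [
    "FilterResult",
    "permutation_test",
    "area_trim",
    "size_expression_correlation",
    "iterative_extrinsic_filter",
    "size_corrected_noise",
]

CONTROL = "control"
TREATED = "treated"


def permutation_test(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: str = "replacement",
) -> float:
    """Permutation p-value for a difference in group means.

    The statistic is ``|mean(A) - mean(B)|``.  Modes:

    ``replacement``
        group labels resampled with replacement from the pooled values
        (bootstrap-style), p = (1 + #{perm stat >= observed}) / (1 + n_perm);
    ``permutation``
        classical label shuffling without replacement, same estimator;
    ``exhaustive``
        every C(n, n_a) relabeling enumerated, p = #{stat >= observed} / total
        (the identity relabeling guarantees p >= 1/total).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("permutation test requires two non-empty groups")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    if mode == "exhaustive":
        count = total = 0
        # tolerance absorbs float noise so the observed split itself counts
        eps = 1e-12 * (1.0 + observed)
        for idx in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += stat >= observed - eps
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    if mode == "replacement":
        ia = rng.integers(0, n, size=(n_perm, na))
        ib = rng.integers(0, n, size=(n_perm, n - na))
        stat = np.abs(pooled[ia].mean(axis=1) - pooled[ib].mean(axis=1))
    elif mode == "permutation":
        stat = np.empty(n_perm)
        for i in range(n_perm):
            p = rng.permutation(pooled)
            stat[i] = abs(p[:na].mean() - p[na:].mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    eps = 1e-12 * (1.0 + observed)
    return (1 + int(np.sum(stat >= observed - eps))) / (1 + n_perm)


def area_trim(cells: pd.DataFrame, low_pct: float, high_pct: float) -> pd.DataFrame:
    """Drop cells outside the pooled area percentile band.

    Percentile bounds are computed on the combined (all-condition) area
    vector with linear interpolation; cells exactly at a bound are kept,
    so an all-equal area column is returned unchanged.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    areas = cells["area"].to_numpy(dtype=float)
    lo, hi = np.percentile(areas, [low_pct, high_pct])
    keep = (areas >= lo) & (areas <= hi)
    return cells.loc[keep].reset_index(drop=True)


def size_expression_correlation(cells: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Per-condition OLS of count on area: r, R^2 = r^2, slope, intercept, p."""
    col = gene if gene in cells.columns else f"count_{gene}"
    if col not in cells.columns:
        raise KeyError(f"gene {gene!r} not in cell table")
    rows = []
    for cond, grp in cells.groupby("condition", sort=True):
        x = grp["area"].to_numpy(dtype=float)
        y = grp[col].to_numpy(dtype=float)
        if x.size < 3 or np.all(x == x[0]):
            rows.append({"condition": cond, "n": x.size, "r": np.nan,
                         "r2": np.nan, "slope": np.nan, "intercept": np.nan,
                         "p": np.nan})
            continue
        res = stats.linregress(x, y)
        rows.append(
            {
                "condition": cond,
                "n": x.size,
                "r": res.rvalue,
                "r2": res.rvalue**2,
                "slope": res.slope,
                "intercept": res.intercept,
                "p": res.pvalue,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FilterResult:
    """Outcome of the iterative extrinsic filter for one gene."""

    retained_ids: list
    n_iterations: int
    final_p: float
    correlations: pd.DataFrame
    n_per_condition: dict
    converged: bool
    trace: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retained_ids": list(self.retained_ids),
            "n_iterations": self.n_iterations,
            "final_p": self.final_p,
            "correlations": self.correlations.to_dict(orient="records"),
            "n_per_condition": {k: int(v) for k, v in self.n_per_condition.items()},
            "converged": self.converged,
            "trace": self.trace,
            "warnings": self.warnings,
        }


def iterative_extrinsic_filter(
    cells: pd.DataFrame,
    gene: str,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    init_trim: tuple[float, float] = (5, 95),
    iter_trim: tuple[float, float] = (2, 98),
    r_max: float = 0.45,
    min_cells: int = 50,
    max_iter: int = 25,
    seed: int | None = None,
) -> FilterResult:
    """Iterative pooled-percentile filter of cell-size outliers.

    Applies the initial trim once, then repeats the tighter trim on the
    surviving pooled population until the control/treated area
    distributions are statistically indistinguishable (permutation
    p > alpha) *and* the count-vs-area correlation satisfies
    ``|r| < r_max`` in both conditions.  Each round removes at least the
    trim tails, so the retained set shrinks weakly and the loop always
    terminates within ``max_iter`` rounds.  Conditions falling below
    ``min_cells`` raise a warning flag (analyses expect > 50 cells per
    treatment); an exhausted condition is an error.
    """
    conds = set(cells["condition"].unique())
    if not {CONTROL, TREATED} <= conds:
        raise ValueError(f"need both conditions present, got {sorted(conds)}")
    rng = np.random.default_rng(seed)
    current = area_trim(cells, *init_trim)
    trace: list[dict] = []
    warnings_: list[str] = []
    converged = False
    final_p = np.nan
    corr = pd.DataFrame()
    n_iterations = 0
    for iteration in range(max_iter + 1):
        by_cond = {c: current[current["condition"] == c] for c in (CONTROL, TREATED)}
        n_per = {c: len(g) for c, g in by_cond.items()}
        empty = [c for c, k in n_per.items() if k == 0]
        if empty:
            raise ValueError(
                f"condition(s) {empty} exhausted at iteration {iteration}; "
                f"trace: {trace}"
            )
        p = permutation_test(
            by_cond[CONTROL]["area"],
            by_cond[TREATED]["area"],
            n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        corr = size_expression_correlation(current, gene)
        max_abs_r = float(np.nanmax(np.abs(corr["r"].to_numpy())))
        trace.append(
            {
                "iteration": iteration,
                "n_control": n_per[CONTROL],
                "n_treated": n_per[TREATED],
                "permutation_p": p,
                "max_abs_r": max_abs_r,
            }
        )
        final_p = p
        n_iterations = iteration
        if p > alpha and max_abs_r < r_max:
            converged = True
            break
        if iteration == max_iter:
            break
        current = area_trim(current, *iter_trim)
    counts_by_cond = {CONTROL: 0, TREATED: 0}
    counts_by_cond.update(current["condition"].value_counts().to_dict())
    for c, k in counts_by_cond.items():
        if k < min_cells:
            warnings_.append(
                f"condition {c!r} retains {k} cells (< {min_cells} per treatment)"
            )
    if not converged:
        warnings_.append(
            f"did not converge within {max_iter} iterations "
            f"(final p={final_p:.4g}, max |r|={trace[-1]['max_abs_r']:.3f})"
        )
    return FilterResult(
        retained_ids=list(current["cell_id"]),
        n_iterations=n_iterations,
        final_p=final_p,
        correlations=corr,
        n_per_condition={c: len(current[current["condition"] == c])
                         for c in (CONTROL, TREATED)},
        converged=converged,
        trace=trace,
        warnings=warnings_,
    )


def size_corrected_noise(cells: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Cell-size-corrected noise summary, per condition.

    Counts are regressed on area (OLS, per condition); the corrected
    variance is the variance of the residuals (ddof=1, so it never
    exceeds the raw variance), the corrected mean is the raw mean, and
    CV2/Fano are recomputed from the pair.  Counts independent of size
    are essentially unchanged; a perfect linear size dependence corrects
    to zero variance.
    """
    col = gene if gene in cells.columns else f"count_{gene}"
    if col not in cells.columns:
        raise KeyError(f"gene {gene!r} not in cell table")
    rows = []
    for cond, grp in cells.groupby("condition", sort=True):
        x = grp["area"].to_numpy(dtype=float)
        y = grp[col].to_numpy(dtype=float)
        if y.size < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 cells")
        if np.all(x == x[0]):
            resid = y - y.mean()
        else:
            res = stats.linregress(x, y)
            resid = y - (res.intercept + res.slope * x)
        mu = y.mean()
        var = resid.var(ddof=1)
        rows.append(
            {
                "condition": cond,
                "gene_id": col.removeprefix("count_"),
                "n_cells": y.size,
                "mean": mu,
                "var": var,
                "cv2": var / mu**2 if mu > 0 else np.nan,
                "fano": var / mu if mu > 0 else np.nan,
                "undefined": mu == 0,
            }
        )
    return pd.DataFrame(rows)
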