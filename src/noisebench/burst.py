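"""Negative-binomial maximum-likelihood inference of bursting parameters.

Under the two-state bursting model at steady state, mRNA copy numbers
follow a negative binomial (Gamma-Poisson) distribution whose size
parameter r equals the burst frequency f (bursts per mRNA lifetime) and
whose success probability p maps to the burst size b = (1 - p) / p.
The moment identities

    mean = b * f        Fano = 1 + b

make the fitted parameters directly interpretable.  Fits are per gene,
per condition and per replicate (with a pooled-replicate variant), and
treated/control ratios of b and f test for the reciprocal
(homeostatic) signature: noise changes with the mean held fixed require
log2(db) = -log2(df).

mRNA lifetime is normalized to 1 and assumed unchanged by treatment, so
burst frequencies (and their fold changes) are relative quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import compare_populations

__all__ = [
    "BurstFit",
    "BurstFoldChange",
    "fit_negative_binomial",
    "fit_cell_table",
    "burst_fold_changes",
    "reciprocity_regression",
    "homeostasis_report",
]


@dataclass
class BurstFit:
    """A fitted negative binomial and its bursting interpretation."""

    gene_id: str
    condition: str
    replicate: str
    nb_size: float       # r = burst frequency f
    nb_prob: float       # p in (0, 1]
    burst_size: float    # b = (1 - p) / p
    mean: float          # implied mean b * f
    fano: float          # implied Fano 1 + b
    loglik: float
    n_cells: int
    converged: bool
    boundary: bool       # Poisson-boundary fit (variance <= mean)

    @property
    def burst_frequency(self) -> float:
        return self.nb_size


def _nb_loglik(counts: np.ndarray, r: float, p: float) -> float:
    return float(stats.nbinom.logpmf(counts, r, p).sum())


def fit_negative_binomial(
    counts,
    gene_id: str = "",
    condition: str = "",
    replicate: str = "pooled",
    min_cells: int = 25,
) -> BurstFit:
    """Fit NB(r, p) by maximum likelihood; extract burst size and frequency.

    A single-parameter profile likelihood over log r is maximized, with
    p(r) = r / (r + mean) in closed form from the first-moment condition
    (the MLE constrains the fitted mean to the sample mean, so the
    implied mean b*f equals the sample mean exactly).  Initialization is
    by method of moments.  Samples with variance <= mean have no interior
    optimum and return a flagged Poisson-boundary fit (b = 0, f = mean).
    """
    x = np.asarray(counts)
    if x.size < min_cells:
        raise ValueError(f"need >= {min_cells} counts, got {x.size}")
    if not np.allclose(x, np.rint(x)) or np.any(x < 0):
        raise ValueError("counts must be non-negative integers")
    x = np.rint(x).astype(np.int64)
    mu = x.mean()
    if mu == 0:
        raise ValueError("all counts are zero; nothing to fit")
    var = x.var(ddof=1)
    n = x.size

    def boundary_fit() -> BurstFit:
        # Poisson limit: r -> inf, p -> 1, b -> 0
        ll = float(stats.poisson.logpmf(x, mu).sum())
        return BurstFit(
            gene_id=gene_id, condition=condition, replicate=replicate,
            nb_size=float(mu), nb_prob=1.0, burst_size=0.0,
            mean=float(mu), fano=1.0, loglik=ll, n_cells=n,
            converged=True, boundary=True,
        )

    if var <= mu:
        return boundary_fit()

    r0 = mu**2 / (var - mu)

    def neg_profile(log_r: float) -> float:
        r = math.exp(log_r)
        p = r / (r + mu)
        return -_nb_loglik(x, r, p)

    res = optimize.minimize_scalar(
        neg_profile,
        bounds=(math.log(r0) - 12.0, math.log(r0) + 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    r_hat = math.exp(res.x)
    # huge r means the data are effectively Poisson: prefer the stable boundary
    if r_hat > 1e6 * max(mu, 1.0):
        return boundary_fit()
    p_hat = r_hat / (r_hat + mu)
    b_hat = (1.0 - p_hat) / p_hat
    return BurstFit(
        gene_id=gene_id, condition=condition, replicate=replicate,
        nb_size=r_hat, nb_prob=p_hat, burst_size=b_hat,
        mean=b_hat * r_hat, fano=1.0 + b_hat,
        loglik=-float(res.fun), n_cells=n,
        converged=bool(res.success), boundary=False,
    )


def fit_cell_table(
    cells: pd.DataFrame,
    genes: list[str] | None = None,
    per_replicate: bool = True,
    pooled: bool = True,
    min_cells: int = 25,
) -> list[BurstFit]:
    """Fit every requested gene of an smFISH cell table.

    Emits per-replicate fits and/or a pooled-replicate fit for each
    gene x condition; genes/replicates with too few cells are skipped.
    """
    count_cols = [c for c in cells.columns if c.startswith("count_")]
    all_genes = [c[len("count_"):] for c in count_cols]
    genes = all_genes if genes is None else genes
    fits: list[BurstFit] = []
    for cond, grp in cells.groupby("condition", sort=True):
        for gid in genes:
            col = f"count_{gid}"
            blocks: list[tuple[str, np.ndarray]] = []
            if per_replicate:
                blocks += [
                    (str(rep), sub[col].to_numpy())
                    for rep, sub in grp.groupby("replicate", sort=True)
                ]
            if pooled:
                blocks.append(("pooled", grp[col].to_numpy()))
            for rep, x in blocks:
                if x.size < min_cells or x.sum() == 0:
                    continue
                fits.append(
                    fit_negative_binomial(
                        x, gene_id=gid, condition=str(cond), replicate=rep,
                        min_cells=min_cells,
                    )
                )
    return fits


@dataclass
class BurstFoldChange:
    """Treated/control burst-parameter ratios.

    ``per_replicate`` has one row per gene x replicate (including any
    "pooled" fits); ``per_gene`` aggregates replicate rows per gene with
    the mean and SEM of the log2 fold changes.
    """

    per_replicate: pd.DataFrame
    per_gene: pd.DataFrame


def burst_fold_changes(
    fits_treated: list[BurstFit], fits_control: list[BurstFit]
) -> BurstFoldChange:
    """Pair fits by gene x replicate and form db = b_t/b_c, df = f_t/f_c."""
    def index(fits):
        return {(f.gene_id, f.replicate): f for f in fits}

    t, c = index(fits_treated), index(fits_control)
    rows = []
    for key in sorted(set(t) & set(c)):
        ft, fc = t[key], c[key]
        if fc.burst_size <= 0 or fc.nb_size <= 0:
            continue  # boundary control fit: ratios undefined
        db = ft.burst_size / fc.burst_size
        df = ft.nb_size / fc.nb_size
        rows.append(
            {
                "gene_id": key[0],
                "replicate": key[1],
                "d_b": db,
                "d_f": df,
                "log2_d_b": np.log2(db) if db > 0 else -np.inf,
                "log2_d_f": np.log2(df),
                "d_mean": ft.mean / fc.mean,
            }
        )
    per_rep = pd.DataFrame(
        rows,
        columns=["gene_id", "replicate", "d_b", "d_f",
                 "log2_d_b", "log2_d_f", "d_mean"],
    )
    reps = per_rep[per_rep["replicate"] != "pooled"]
    agg_rows = []
    for gid, grp in reps.groupby("gene_id", sort=True):
        k = len(grp)
        lb, lf = grp["log2_d_b"].to_numpy(), grp["log2_d_f"].to_numpy()
        agg_rows.append(
            {
                "gene_id": gid,
                "n_replicates": k,
                "log2_d_b": lb.mean(),
                "log2_d_f": lf.mean(),
                "sem_log2_d_b": lb.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0,
                "sem_log2_d_f": lf.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0,
                "d_b": float(2 ** lb.mean()),
                "d_f": float(2 ** lf.mean()),
                "d_mean": float(grp["d_mean"].mean()),
            }
        )
    per_gene = pd.DataFrame(
        agg_rows,
        columns=["gene_id", "n_replicates", "log2_d_b", "log2_d_f",
                 "sem_log2_d_b", "sem_log2_d_f", "d_b", "d_f", "d_mean"],
    )
    return BurstFoldChange(per_replicate=per_rep, per_gene=per_gene)


def reciprocity_regression(log2_d_f, log2_d_b) -> dict:
    """OLS of log2(db) on log2(df) across genes/replicates.

    Homeostatic (mean-preserving) perturbations satisfy
    log2(db) = -log2(df), so the fitted slope is -1 with intercept 0.
    Returns slope, intercept and their standard errors.
    """
    x = np.asarray(log2_d_f, dtype=float)
    y = np.asarray(log2_d_b, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("degenerate design: all abscissae identical")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "se_slope": float(res.stderr),
        "se_intercept": float(res.intercept_stderr),
        "r": float(res.rvalue),
        "n": int(x.size),
    }


def homeostasis_report(
    burst_fc: BurstFoldChange,
    noise_fc: pd.DataFrame | None = None,
    mean_tol: float = 0.25,
    recip_tol: float = 0.25,
) -> dict:
    """Classify genes and test the homeostatic-amplification signature.

    Per-gene classes on (log2 d_mean, log2 d_b, log2 d_f):

    ``mean_shifted``
        b and f scaled by a similar factor (|log2 d_b - log2 d_f| <=
        ``recip_tol``) with the mean moved beyond ``mean_tol``;
    ``homeostatic``
        mean within tolerance and b, f moving in opposite directions
        (or one essentially unchanged);
    ``non_reciprocal_outlier``
        anything else, e.g. burst size and frequency both increased by
        unequal factors.

    One-sample signed-rank tests on log fold changes across genes (the
    paired treated-vs-control test): d_mean two-sided, d_cv2 / d_fano /
    d_b one-sided greater, d_f one-sided less.
    """
    g = burst_fc.per_gene
    classes = {}
    for _, row in g.iterrows():
        lm = math.log2(row["d_mean"]) if row["d_mean"] > 0 else math.inf
        lb, lf = row["log2_d_b"], row["log2_d_f"]
        if abs(lb - lf) <= recip_tol and abs(lm) > mean_tol:
            cls = "mean_shifted"
        elif abs(lm) <= mean_tol and lb * lf <= 0:
            cls = "homeostatic"
        else:
            cls = "non_reciprocal_outlier"
        classes[row["gene_id"]] = cls

    def one_sample_signed_rank(vals, alternative):
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return math.nan
        _, p = compare_populations(
            vals, np.zeros_like(vals), test="signed_rank",
            alternative=alternative, paired=True,
        )
        return p

    tests = {
        "d_b_greater_p": one_sample_signed_rank(g["log2_d_b"], "greater"),
        "d_f_less_p": one_sample_signed_rank(g["log2_d_f"], "less"),
        "d_mean_two_sided_p": one_sample_signed_rank(
            np.log2(g["d_mean"].to_numpy(dtype=float)), "two_sided"
        ),
    }
    if noise_fc is not None:
        for metric in ("d_cv2", "d_fano"):
            tests[f"{metric}_greater_p"] = one_sample_signed_rank(
                np.log2(noise_fc[metric].to_numpy(dtype=float)), "greater"
            )
        tests["noise_d_mean_two_sided_p"] = one_sample_signed_rank(
            np.log2(noise_fc["d_mean"].to_numpy(dtype=float)), "two_sided"
        )
    return {"classification": classes, "tests": tests}
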