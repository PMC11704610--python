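"""Synthetic bursty gene-expression data with known ground truth.

Generates smFISH-like per-cell spot-count tables and scRNA-seq-like UMI
count matrices from a two-state bursting (Gamma-Poisson / negative
binomial) model, with three layers a real experiment carries on top of
the intrinsic bursting noise:

* an extrinsic cell-size factor: each cell's transcription rate is
  multiplied by ``(A / Abar) ** eta`` where ``A`` is its area,
* a treated condition whose burst size is multiplied by ``c`` while the
  burst frequency is divided by ``c`` (homeostatic noise amplification:
  the mean ``b * f`` is unchanged, the Fano factor ``1 + b`` grows),
* per-cell binomial capture of molecules with probability ``beta``
  (UMI matrices only), the mechanism that compresses observed noise
  fold changes relative to direct counting.

Every dataset is returned together with a :class:`GroundTruth` holding
the per-gene parameters and per-cell nuisance variables; ground truth is
for tests only and is never consumed by the analysis stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logit, expit

__all__ = [
    "GeneSpec",
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_smfish",
    "simulate_umi_matrix",
    "simulate_method_tables",
]

CONTROL = "control"
TREATED = "treated"


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class GeneSpec:
    """One gene of the bursting model.

    Parameters
    ----------
    gene_id : str
        Unique identifier; ids starting with the mitochondrial prefix
        (e.g. ``mt-``) are treated as mitochondrial by downstream QC.
    burst_size : float
        Mean number of mRNAs produced per burst, ``b >= 0``.  Intrinsic
        Fano factor is ``1 + b``; ``b = 0`` is the Poisson limit.
    burst_frequency : float
        Bursts per mRNA lifetime, ``f > 0``.  Intrinsic mean is ``b * f``
        (``f`` itself in the Poisson limit).
    """

    gene_id: str
    burst_size: float
    burst_frequency: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.burst_size) or self.burst_size < 0:
            raise ConfigError(
                f"burst_size must be finite and >= 0, got {self.burst_size!r} "
                f"for gene {self.gene_id!r}"
            )
        if not np.isfinite(self.burst_frequency) or self.burst_frequency <= 0:
            raise ConfigError(
                f"burst_frequency must be finite and > 0, got "
                f"{self.burst_frequency!r} for gene {self.gene_id!r}"
            )

    @property
    def intrinsic_mean(self) -> float:
        if self.burst_size == 0:
            return self.burst_frequency
        return self.burst_size * self.burst_frequency

    @property
    def intrinsic_fano(self) -> float:
        return 1.0 + self.burst_size


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a paired treated/control simulation.

    ``amplification`` (c) realizes the homeostatic perturbation: the
    treated condition uses burst size ``c * b`` and frequency ``f / c``,
    so the intrinsic mean is unchanged exactly.  ``area_shift_treated``
    multiplies treated-cell areas, deliberately injecting an extrinsic
    difference for exercising the extrinsic filter.
    """

    genes: tuple[GeneSpec, ...]
    n_cells: int = 200
    n_replicates: int = 3
    extrinsic_coupling: float = 1.0
    area_log_mean: float = 5.0
    area_log_sd: float = 0.25
    capture_mean: float = 0.1
    capture_sd: float = 0.0
    amplification: float = 2.0
    area_shift_treated: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) == 0:
            raise ConfigError("genes must be non-empty")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ConfigError("genes contains duplicate gene_id values")
        if self.n_cells <= 0:
            raise ConfigError(f"n_cells must be positive, got {self.n_cells}")
        if self.n_replicates <= 0:
            raise ConfigError(
                f"n_replicates must be positive, got {self.n_replicates}"
            )
        for name in ("extrinsic_coupling", "area_log_sd", "area_shift_treated"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.isfinite(self.area_log_mean):
            raise ConfigError(f"area_log_mean must be finite, got {self.area_log_mean!r}")
        if not (0 < self.capture_mean <= 1):
            raise ConfigError(
                f"capture_mean must be in (0, 1], got {self.capture_mean!r}"
            )
        if not np.isfinite(self.capture_sd) or self.capture_sd < 0:
            raise ConfigError(f"capture_sd must be finite and >= 0, got {self.capture_sd!r}")
        if not np.isfinite(self.amplification) or self.amplification < 1:
            raise ConfigError(
                f"amplification must be finite and >= 1, got {self.amplification!r}"
            )

    def gene_params(self, condition: str) -> list[tuple[str, float, float]]:
        """Per-gene (id, b, f) effective in ``condition``."""
        c = self.amplification if condition == TREATED else 1.0
        return [
            (g.gene_id, c * g.burst_size, g.burst_frequency / c)
            for g in self.genes
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genes"] = [asdict(g) for g in self.genes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["genes"] = tuple(GeneSpec(**g) for g in d["genes"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True parameters behind a simulated dataset (test-only).

    ``genes`` has one row per gene x condition with the effective burst
    size/frequency and implied intrinsic mean and Fano; ``cells`` has one
    row per cell with its area and (for UMI data) capture probability.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame

    def gene_row(self, gene_id: str, condition: str) -> pd.Series:
        g = self.genes
        sel = g[(g["gene_id"] == gene_id) & (g["condition"] == condition)]
        if len(sel) != 1:
            raise KeyError(f"no ground truth for {gene_id!r} / {condition!r}")
        return sel.iloc[0]


def _truth_gene_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for condition in (CONTROL, TREATED):
        for gene_id, b, f in config.gene_params(condition):
            mean = f if b == 0 else b * f
            rows.append(
                {
                    "gene_id": gene_id,
                    "condition": condition,
                    "burst_size": b,
                    "burst_frequency": f,
                    "intrinsic_mean": mean,
                    "intrinsic_fano": 1.0 + b,
                }
            )
    return pd.DataFrame(rows)


def _draw_counts(
    rng: np.random.Generator,
    b: float,
    f: float,
    size_factor: np.ndarray,
) -> np.ndarray:
    """Gamma-Poisson draw: rate ~ Gamma(shape=f, scale=b), modulated by size.

    b = 0 falls back to the Poisson limit with rate f.
    """
    n = size_factor.shape[0]
    if b == 0:
        return rng.poisson(f * size_factor)
    lam = rng.gamma(shape=f, scale=b, size=n)
    return rng.poisson(lam * size_factor)


def _cell_block(
    rng: np.random.Generator,
    config: SimConfig,
    condition: str,
    replicate: int,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """One condition x replicate block: counts (genes x cells) plus areas."""
    n = config.n_cells
    areas = rng.lognormal(config.area_log_mean, config.area_log_sd, size=n)
    if condition == TREATED:
        areas = areas * config.area_shift_treated
    eta = config.extrinsic_coupling
    # relative size against the realized mean keeps the factor centered at 1
    size_factor = (areas / areas.mean()) ** eta if eta > 0 else np.ones(n)
    counts = np.empty((len(config.genes), n), dtype=np.int64)
    for i, (_, b, f) in enumerate(config.gene_params(condition)):
        counts[i] = _draw_counts(rng, b, f, size_factor)
    meta = pd.DataFrame(
        {
            "condition": condition,
            "replicate": replicate,
            "area": areas,
        }
    )
    return meta, counts, areas


def _substreams(config: SimConfig, salt: int) -> dict[tuple[str, int], np.random.Generator]:
    """Independent generator per condition x replicate, derived from the seed.

    Salting separates the smFISH and UMI layers so the two generators do
    not share streams even under the same config.
    """
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(salt,))
    keys = [
        (cond, rep)
        for cond in (CONTROL, TREATED)
        for rep in range(1, config.n_replicates + 1)
    ]
    children = ss.spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


def simulate_smfish(config: SimConfig):
    """Simulate paired smFISH-like cell tables.

    Returns ``(treated, control, truth)`` where each table is a DataFrame
    with columns ``cell_id, condition, replicate, area, count_<gene>...``
    holding exact per-cell molecule counts.  With ``extrinsic_coupling=0``
    each gene's marginal counts are NB with mean ``b*f`` and Fano ``1+b``.
    """
    rngs = _substreams(config, salt=0)
    gene_ids = [g.gene_id for g in config.genes]
    tables = {CONTROL: [], TREATED: []}
    cell_rows = []
    for (condition, replicate), rng in rngs.items():
        meta, counts, areas = _cell_block(rng, config, condition, replicate)
        block = meta.copy()
        prefix = "t" if condition == TREATED else "c"
        block.insert(
            0,
            "cell_id",
            [f"{prefix}{replicate}_{i:05d}" for i in range(config.n_cells)],
        )
        for i, gid in enumerate(gene_ids):
            block[f"count_{gid}"] = counts[i]
        tables[condition].append(block)
        cell_rows.append(block[["cell_id", "condition", "replicate", "area"]])
    treated = pd.concat(tables[TREATED], ignore_index=True)
    control = pd.concat(tables[CONTROL], ignore_index=True)
    cells = pd.concat(cell_rows, ignore_index=True)
    cells["capture"] = 1.0
    truth = GroundTruth(genes=_truth_gene_table(config), cells=cells)
    return treated, control, truth


def _draw_capture(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    """Per-cell capture probabilities.

    capture_sd = 0 gives the exact uniform-beta mode used by the analytic
    thinning identities; otherwise beta is logit-normal with the spread
    mapped from the probability scale by the delta method, clipped away
    from 0.
    """
    m = config.capture_mean
    if config.capture_sd == 0 or m == 1.0:
        return np.full(n, m)
    sd_logit = config.capture_sd / (m * (1.0 - m))
    beta = expit(rng.normal(logit(m), sd_logit, size=n))
    return np.clip(beta, 1e-12, 1.0)


def simulate_umi_matrix(config: SimConfig):
    """Simulate paired scRNA-seq-like UMI matrices.

    True per-cell counts are drawn exactly as in :func:`simulate_smfish`
    (including the extrinsic size factor), then each molecule is captured
    independently with the cell's probability ``beta``: the observed count
    is ``Binomial(true, beta)``.  For uniform beta this maps NB(b, f) to
    NB(beta*b, f) — burst frequency is invariant under thinning while the
    apparent burst size shrinks, so the observed Fano is ``1 + beta*b``.

    Returns ``(treated, control, truth)`` as :class:`~noisebench.metrics.CountMatrix`.
    """
    from .metrics import CountMatrix  # deferred; metrics imports nothing from here

    rngs = _substreams(config, salt=1)
    gene_ids = [g.gene_id for g in config.genes]
    per_condition: dict[str, list] = {CONTROL: [], TREATED: []}
    cell_rows = []
    for (condition, replicate), rng in rngs.items():
        meta, counts, areas = _cell_block(rng, config, condition, replicate)
        beta = _draw_capture(rng, config, config.n_cells)
        observed = rng.binomial(counts, beta[np.newaxis, :])
        prefix = "t" if condition == TREATED else "c"
        cell_ids = [f"{prefix}{replicate}_{i:05d}" for i in range(config.n_cells)]
        per_condition[condition].append((observed, cell_ids, meta))
        cell_rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids,
                    "condition": condition,
                    "replicate": replicate,
                    "area": areas,
                    "capture": beta,
                }
            )
        )

    def assemble(blocks) -> CountMatrix:
        counts = np.concatenate([b[0] for b in blocks], axis=1)
        cell_ids = [cid for b in blocks for cid in b[1]]
        meta = pd.concat(
            [b[2][["condition", "replicate"]] for b in blocks], ignore_index=True
        )
        meta.index = pd.Index(cell_ids, name="cell_id")
        return CountMatrix(counts=counts, gene_ids=list(gene_ids),
                           cell_ids=cell_ids, cell_meta=meta)

    treated = assemble(per_condition[TREATED])
    control = assemble(per_condition[CONTROL])
    truth = GroundTruth(
        genes=_truth_gene_table(config),
        cells=pd.concat(cell_rows, ignore_index=True),
    )
    return treated, control, truth


def simulate_method_tables(
    reference: pd.DataFrame,
    shrink: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    metrics: Sequence[str] = ("d_mean", "d_cv2", "d_fano"),
) -> pd.DataFrame:
    """Manufacture a normalization-method fold-change table from a reference.

    Log fold changes are shrunk toward 0 by factor ``shrink`` (``s=0``
    returns the reference, ``s=1`` collapses every fold change to 1) and
    perturbed with multiplicative lognormal noise of ``jitter_sd`` on the
    natural-log scale.  Used to test the scoring stage with methods of
    known, ordered quality.
    """
    if not (0.0 <= shrink <= 1.0):
        raise ValueError(f"shrink must be in [0, 1], got {shrink!r}")
    for m in metrics:
        if m not in reference.columns:
            raise ValueError(f"reference lacks column {m!r}")
        vals = reference[m].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"reference column {m!r} must be positive and finite")
    rng = np.random.default_rng(seed)
    out = reference.copy()
    for m in metrics:
        logv = np.log(out[m].to_numpy(dtype=float))
        logv = (1.0 - shrink) * logv
        if jitter_sd > 0:
            logv = logv + rng.normal(0.0, jitter_sd, size=logv.shape)
        out[m] = np.exp(logv)
    return out
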