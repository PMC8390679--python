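"""Regularized negative-binomial normalization and differential expression.

Counts are modelled with a depth-offset NB model: the expected count of gene
g in cell c is mu_gc = N_c * p_g, where N_c is the cell's total UMI and p_g
the gene's share of the grand total.  A per-gene dispersion theta_g is fit by
maximum likelihood and regularized by kernel-smoothing log10 theta over
log10 mean expression, after which Pearson residuals

    z_gc = (x_gc - mu_gc) / sqrt(mu_gc + mu_gc^2 / theta_g)

(clipped to +-sqrt(n_cells)) are the normalization substrate.  Differential
expression between two cell groups uses a two-tailed Welch's t test on the
residuals per gene, Benjamini-Hochberg FDR, and an empirical null band: the
99.9th percentile of per-gene absolute mean differences over random
partitions of the pooled cells into groups of the same sizes.  A gene is
called significant only if q < fdr AND its mean difference exceeds the band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .ingest_qc import UmiCountMatrix

__all__ = [
    "NbFit",
    "ResidualMatrix",
    "NullBand",
    "DeConfig",
    "log_normalize_scale",
    "fit_nb_model",
    "pearson_residuals",
    "welch_t",
    "permutation_null_band",
    "bh_fdr",
    "run_de",
]

_THETA_MIN = 1e-2
_THETA_MAX = 1e6


@dataclass
class NbFit:
    """Offset-NB model parameters for one count matrix."""

    gene_ids: np.ndarray
    p: np.ndarray  # per-gene expected fraction of a cell's counts
    theta_raw: np.ndarray  # per-gene ML dispersion (NaN for all-zero genes)
    theta: np.ndarray  # regularized dispersion
    clip: float  # residual clip bound, sqrt(n_cells)
    n_cells: int


@dataclass
class ResidualMatrix:
    """Clipped Pearson residuals, genes x cells (dense)."""

    z: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    clip: float

    @property
    def n_genes(self) -> int:
        return self.z.shape[0]

    @property
    def n_cells(self) -> int:
        return self.z.shape[1]


@dataclass(frozen=True)
class NullBand:
    band: float
    n_partitions: int
    percentile: float
    seed: int

    def __post_init__(self) -> None:
        if self.band < 0:
            raise ValueError("band must be nonnegative")


@dataclass(frozen=True)
class DeConfig:
    fdr: float = 0.01
    percentile: float = 99.9
    n_partitions: int = 100
    seed: int = 0


def log_normalize_scale(m: UmiCountMatrix, scale_total: int = 10_000) -> pd.DataFrame:
    """ln(1 + scale_total * x / N_c) then per-gene z-scaling (heatmap substrate).

    Zero-variance genes map to all-zero rows.  Cells with zero totals raise.
    """
    totals = m.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run QC first")
    x = m.to_dense().astype(float)
    y = np.log1p(scale_total * x / totals[None, :])
    mu = y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (y - mu) / sd, 0.0)
    return pd.DataFrame(z, index=pd.Index(m.gene_ids, name="gene"), columns=m.barcodes)


# ----------------------------------------------------------------------
# NB fit and residuals
# ----------------------------------------------------------------------

def _nb_negloglik_factory(x: np.ndarray, mu: np.ndarray):
    n = x.size
    # gammaln(x + theta) depends on theta and the multiset of counts only
    ux, counts = np.unique(x, return_counts=True)

    def negloglik(log10_theta: float) -> float:
        theta = 10.0 ** log10_theta
        ll = (
            float(counts @ gammaln(ux + theta))
            - n * gammaln(theta)
            + n * theta * np.log(theta)
            - float(np.sum((x + theta) * np.log(theta + mu)))
        )
        return -ll

    return negloglik


def fit_nb_model(m: UmiCountMatrix, bandwidth: float | None = None) -> NbFit:
    """Fit the depth-offset NB model with kernel-regularized dispersion.

    p_g comes from gene totals; theta_g-hat is the per-gene ML estimate with
    mu_gc = N_c * p_g fixed, bounded to [1e-2, 1e6] (the upper bound is the
    Poisson limit).  Regularized theta_g is a Nadaraya-Watson estimate of
    log10 theta-hat over log10 mean expression with a Gaussian kernel;
    bandwidth defaults to Silverman's rule.  All-zero genes are excluded
    (their residuals are defined as 0).
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    totals = m.cell_totals().astype(float)
    gene_totals = m.gene_totals().astype(float)
    grand = gene_totals.sum()
    p = gene_totals / grand

    theta_raw = np.full(m.n_genes, np.nan)
    csr = m.values.tocsr()
    lo, hi = np.log10(_THETA_MIN), np.log10(_THETA_MAX)
    for g in range(m.n_genes):
        if gene_totals[g] == 0:
            continue
        row = np.zeros(m.n_cells)
        start, end = csr.indptr[g], csr.indptr[g + 1]
        row[csr.indices[start:end]] = csr.data[start:end]
        mu = totals * p[g]
        res = minimize_scalar(
            _nb_negloglik_factory(row, mu),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-4},
        )
        theta_raw[g] = 10.0 ** res.x

    fitted = np.isfinite(theta_raw)
    log_mean = np.log10(gene_totals[fitted] / m.n_cells)
    log_theta = np.log10(theta_raw[fitted])
    # near-Poisson genes drive theta-hat to extremes; winsorize the tails so
    # the kernel mean tracks the bulk of the dispersion trend
    lo_w, hi_w = np.percentile(log_theta, [2.5, 97.5])
    log_theta = np.clip(log_theta, lo_w, hi_w)
    if bandwidth is None:
        n = log_mean.size
        sd = np.std(log_mean, ddof=1) if n > 1 else 1.0
        iqr = np.subtract(*np.percentile(log_mean, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = max(0.9 * spread * n ** (-0.2), 1e-3)

    theta = np.full(m.n_genes, np.nan)
    # Nadaraya-Watson in manageable blocks
    targets = np.flatnonzero(fitted)
    for block in np.array_split(targets, max(1, len(targets) // 512)):
        d = (np.log10(gene_totals[block] / m.n_cells)[:, None] - log_mean[None, :]) / bandwidth
        w = np.exp(-0.5 * d * d)
        theta[block] = 10.0 ** (w @ log_theta / w.sum(axis=1))
    theta = np.clip(theta, _THETA_MIN, _THETA_MAX)

    return NbFit(
        gene_ids=m.gene_ids.copy(),
        p=p,
        theta_raw=theta_raw,
        theta=theta,
        clip=float(np.sqrt(m.n_cells)),
        n_cells=m.n_cells,
    )


def pearson_residuals(m: UmiCountMatrix, fit: NbFit) -> ResidualMatrix:
    """Clipped NB Pearson residuals under the fitted offset model."""
    if not np.array_equal(fit.gene_ids, m.gene_ids) or fit.n_cells != m.n_cells:
        raise ValueError("fit was computed on a different matrix")
    totals = m.cell_totals().astype(float)
    x = m.to_dense().astype(float)
    mu = fit.p[:, None] * totals[None, :]
    theta = np.where(np.isfinite(fit.theta), fit.theta, np.inf)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        var = mu + mu * mu / theta
        z = np.where(var > 0, (x - mu) / np.sqrt(var), 0.0)
    z = np.clip(z, -fit.clip, fit.clip)
    return ResidualMatrix(z=z, gene_ids=m.gene_ids.copy(), barcodes=m.barcodes.copy(), clip=fit.clip)


# ----------------------------------------------------------------------
# Welch's t, null band, FDR
# ----------------------------------------------------------------------

_P_FLOOR = np.nextafter(0, 1)


def _welch_rows(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch's t over rows of two genes x cells blocks."""
    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA, vB = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = vA / nA + vB / nB
    diff = mA - mB
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / ((vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1)),
            nA + nB - 2,
        )
    p = 2.0 * t_dist.sf(np.abs(t), df)
    # degenerate: both groups constant
    zero_var = se2 == 0
    equal = zero_var & (diff == 0)
    unequal = zero_var & (diff != 0)
    p[equal] = 1.0
    p[unequal] = _P_FLOOR
    t[unequal] = np.sign(diff[unequal]) * np.inf
    return t, df, p


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's t statistic, Satterthwaite df, and two-tailed p for two samples."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, df, p = _welch_rows(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def permutation_null_band(
    residuals: ResidualMatrix,
    group_sizes: tuple[int, int],
    n_partitions: int = 100,
    percentile: float = 99.9,
    seed: int = 0,
) -> NullBand:
    """Empirical band for |group mean difference| under random cell partitions.

    Each partition splits the pooled cells (all columns of ``residuals``)
    into random disjoint subsets of sizes (nA, nB) without replacement; the
    band is the requested percentile of the pooled genes x partitions
    absolute mean differences.
    """
    nA, nB = group_sizes
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 cells")
    n = residuals.n_cells
    if nA + nB > n:
        raise ValueError("group sizes exceed the number of pooled cells")
    rng = np.random.default_rng(seed)
    diffs = np.empty((n_partitions, residuals.n_genes))
    z = residuals.z
    for i in range(n_partitions):
        perm = rng.permutation(n)
        a, b = perm[:nA], perm[nA : nA + nB]
        diffs[i] = np.abs(z[:, a].mean(axis=1) - z[:, b].mean(axis=1))
    band = float(np.percentile(diffs.ravel(), percentile))
    return NullBand(band=band, n_partitions=n_partitions, percentile=percentile, seed=seed)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p, float)
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    m: UmiCountMatrix,
    group_a,
    group_b,
    config: DeConfig = DeConfig(),
) -> pd.DataFrame:
    """Full DE pipeline between two disjoint barcode groups.

    Fits the NB model on the pooled A+B cells, computes residuals, per-gene
    Welch's t with BH FDR, and the permutation null band; a gene is flagged
    significant iff q < fdr AND |mean difference| > band.  The returned table
    is sorted by p and carries volcano-ready columns.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    pooled = group_a + group_b
    sub = m.subset_cells_by_barcode(pooled)
    fit = fit_nb_model(sub)
    res = pearson_residuals(sub, fit)
    nA, nB = len(group_a), len(group_b)
    A, B = res.z[:, :nA], res.z[:, nA:]
    t, df, p = _welch_rows(A, B)
    q = bh_fdr(p)
    band = permutation_null_band(
        res, (nA, nB), config.n_partitions, config.percentile, config.seed
    )
    diff = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(np.maximum(p, _P_FLOOR))
    table = pd.DataFrame(
        {
            "gene": sub.gene_ids,
            "mean_diff": diff,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "neg_log10_p": nlp,
            "band": band.band,
            "significant": (q < config.fdr) & (np.abs(diff) > band.band),
        }
    ).sort_values("p", kind="mergesort", ignore_index=True)
    return table
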