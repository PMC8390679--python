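"""Regulon activity: recovery-curve AUC, dip-test binarization, activity matrix.

A regulon (a transcription factor with its target gene set, TF included) is
scored per cell by the area under its recovery curve: genes are ranked by
decreasing count within the cell (ties broken by a seeded shuffle, since UMI
data is tie-dominated), hits(x) counts regulon genes at rank <= x, and

    A = sum_{x=1..k} hits(x) / sum_{x=1..k} min(x, |R|)

for a rank cutoff k (default: 5% of genes).  Per-regulon AUC distributions
are then binarized: Hartigan's dip test decides modality; unimodal
distributions threshold at mean + 2 sd, bimodal ones at the trough of the
kernel-smoothed density between the two main peaks.  Regulons active in
fewer than 1% of cells are dropped, and the remaining boolean matrix is
hierarchically clustered (Jaccard distance) on both axes for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde

from .ingest_qc import UmiCountMatrix

__all__ = [
    "AucMatrix",
    "BinarizationResult",
    "BinaryActivityMatrix",
    "prefilter_genes",
    "auc_score",
    "dip_statistic",
    "dip_test",
    "binarize_regulon",
    "binarize_matrix",
]


def prefilter_genes(
    m: UmiCountMatrix,
    min_umi_per_frac: int = 3,
    cell_frac: float = 0.01,
) -> list[str]:
    """Gene prefilter for regulon analysis input.

    With min_cells = ceil(cell_frac * n_cells) and
    min_counts = min_umi_per_frac * min_cells, keep genes with total counts
    >= min_counts AND expression (count > 0) in >= min_cells cells.  At 1300
    cells and the defaults this is the (39 counts, 13 cells) rule.
    """
    min_cells = math.ceil(cell_frac * m.n_cells)
    min_counts = min_umi_per_frac * min_cells
    totals = m.gene_totals()
    n_expr = m.cells_per_gene()
    keep = (totals >= min_counts) & (n_expr >= min_cells)
    return [g for g, k in zip(m.gene_ids, keep) if k]


def prefilter_thresholds(n_cells: int, min_umi_per_frac: int = 3, cell_frac: float = 0.01) -> tuple[int, int]:
    """(min_counts, min_cells) implied by the prefilter rule at a given size."""
    min_cells = math.ceil(cell_frac * n_cells)
    return min_umi_per_frac * min_cells, min_cells


# ----------------------------------------------------------------------
# recovery-curve AUC
# ----------------------------------------------------------------------


@dataclass
class AucMatrix:
    values: pd.DataFrame  # regulons x cells, in [0, 1] (NaN for unresolvable regulons)
    k: int
    seed: int

    @property
    def regulons(self) -> list[str]:
        return list(self.values.index)


def _max_recovery(k: int, n_hits: int) -> int:
    """sum_{x=1..k} min(x, n_hits)."""
    if k <= n_hits:
        return k * (k + 1) // 2
    return n_hits * (n_hits + 1) // 2 + (k - n_hits) * n_hits


def auc_score(
    m: UmiCountMatrix,
    regulons: dict,
    k: int | None = None,
    seed: int = 0,
) -> AucMatrix:
    """Recovery-curve AUC of each regulon in each cell.

    ``regulons`` maps TF name -> iterable of member genes.  Genes missing
    from the matrix are ignored; a regulon with no present genes yields a
    NaN row (flagged by a warning).  k defaults to ceil(5% of genes).
    """
    n_genes = m.n_genes
    if k is None:
        k = math.ceil(0.05 * n_genes)
    if k > n_genes:
        raise ValueError("rank cutoff k exceeds the number of genes")
    rng = np.random.default_rng(seed)
    X = m.to_dense().astype(np.int64)  # genes x cells
    # per-cell ranking by decreasing count; seeded uniform keys break ties
    tiebreak = rng.random(X.shape)
    order = np.lexsort((tiebreak, -X), axis=0)  # gene indices, best first
    ranks = np.empty_like(order)
    col = np.arange(X.shape[1])[None, :]
    ranks[order, col] = np.arange(1, n_genes + 1)[:, None]

    gene_set = set(m.gene_ids)
    lookup = {g: i for i, g in enumerate(m.gene_ids)}
    rows = {}
    for name, genes in regulons.items():
        present = [g for g in dict.fromkeys(genes) if g in gene_set]
        if not present:
            warnings.warn(f"regulon {name!r} has no genes in the matrix", stacklevel=2)
            rows[name] = np.full(X.shape[1], np.nan)
            continue
        idx = np.array([lookup[g] for g in present])
        rr = ranks[idx]  # members x cells
        raw = np.clip(k - rr + 1, 0, None).sum(axis=0)
        rows[name] = raw / _max_recovery(k, len(present))
    values = pd.DataFrame(rows, index=pd.Index(m.barcodes, name="barcode")).T
    return AucMatrix(values=values, k=k, seed=seed)


# ----------------------------------------------------------------------
# Hartigan dip
# ----------------------------------------------------------------------

def dip_statistic(values) -> float:
    """Hartigan-Hartigan dip: max distance of the ECDF from the closest
    unimodal CDF, computed with the iterative greatest-convex-minorant /
    least-concave-majorant algorithm on the sorted sample.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    X = np.concatenate([[0.0], x])  # 1-indexed

    # candidate change points for the GCM (mn) and LCM (mj) over the whole sample
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (X[j] - X[mnj]) * (mnj - mnmnj) < (X[mnj] - X[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for kk in range(n - 1, 0, -1):
        mj[kk] = kk + 1
        while True:
            mjk = mj[kk]
            mjmjk = mj[mjk]
            if mjk == n or (X[kk] - X[mjk]) * (mjk - mjmjk) < (X[mjk] - X[mjmjk]) * (kk - mjk):
                break
            mj[kk] = mjmjk

    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)
    low, high = 1, n
    dip = 1.0  # in count units; the minimal dip 1/(2n) after final scaling

    while True:
        # GCM change points from high down to low; LCM from low up to high
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i

        ix, iv = ig - 1, 2
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (X[lcmiv] - X[gcmi1]) * (gcmix - gcmi1) / (
                        X[gcmix] - X[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (X[gcmix] - X[lcmiv1]) * (lcmiv - lcmiv1) / (X[lcmiv] - X[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # max deviation of the ECDF above the GCM outside the modal interval
        dl = 0.0
        for j in range(ig, l_gcm):
            je, jb = gcm[j], gcm[j + 1]
            if je - jb > 1 and X[je] != X[jb]:
                C = (je - jb) / (X[je] - X[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (X[jj] - X[jb]) * C
                    if t > dl:
                        dl = t
        # ... and below the LCM
        du = 0.0
        for j in range(ih, l_lcm):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and X[je] != X[jb]:
                C = (je - jb) / (X[je] - X[jb])
                for jj in range(jb, je + 1):
                    t = (X[jj] - X[jb]) * C - (jj - jb - 1)
                    if t > du:
                        du = t
        dipnew = max(dl, du)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


@lru_cache(maxsize=32)
def _null_dips(n: int, n_boot: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.uniform(size=n)) for _ in range(n_boot))


def dip_test(values, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p value.

    p is the fraction of ``n_boot`` seeded uniform(0,1) samples of the same
    size whose dip is at least as large as the observed one (the uniform is
    the calibration distribution of the test).  Fewer than 4 finite values,
    or all-identical values, raise: the caller must route those to the
    degenerate binarization rule.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("dip test requires at least 4 finite values")
    if np.min(x) == np.max(x):
        raise ValueError("dip test undefined for constant values")
    D = dip_statistic(x)
    null = np.array(_null_dips(int(x.size), int(n_boot), int(seed)))
    p = float(np.mean(null >= D))
    return D, p


# ----------------------------------------------------------------------
# binarization
# ----------------------------------------------------------------------


@dataclass
class BinarizationResult:
    regulon: str
    dip: float
    dip_p: float
    modality: str  # "unimodal" | "bimodal" | "degenerate"
    threshold: float
    rule: str  # "mean+2sd" | "kde-trough"
    active_fraction: float


@dataclass
class BinaryActivityMatrix:
    values: pd.DataFrame  # retained regulons x cells, bool
    row_order: list
    col_order: list


def binarize_regulon(
    auc_values,
    dip_result: tuple[float, float],
    alpha: float = 0.05,
    grid_size: int = 512,
) -> tuple[float, str, np.ndarray]:
    """Threshold one regulon's AUC distribution; returns (tau, rule, active mask).

    dip p >= alpha (unimodal): tau = mean + 2 sd.  Otherwise (bimodal):
    Gaussian KDE with Silverman bandwidth on [min - 3h, max + 3h], the two
    highest local maxima are the peaks and tau is the density minimum
    strictly between them.  If fewer than two local maxima emerge on the
    grid the unimodal rule is used with a warning.  Activity is strict:
    AUC > tau.
    """
    x = np.asarray(auc_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("AUC values must be finite")
    _, dip_p = dip_result
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=0))
    if sd == 0:
        return mean, "mean+2sd", x > mean
    if dip_p >= alpha:
        tau = mean + 2.0 * sd
        return tau, "mean+2sd", x > tau

    kde = gaussian_kde(x, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    ) + 1
    if interior.size < 2:
        warnings.warn(
            "bimodal call but <2 density peaks on the grid; falling back to mean+2sd",
            stacklevel=2,
        )
        tau = mean + 2.0 * sd
        return tau, "mean+2sd", x > tau
    top2 = interior[np.argsort(dens[interior])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    trough = lo + 1 + int(np.argmin(dens[lo + 1 : hi]))
    tau = float(grid[trough])
    return tau, "kde-trough", x > tau


def binarize_matrix(
    auc: AucMatrix,
    alpha: float = 0.05,
    min_active_frac: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, BinaryActivityMatrix]:
    """Binarize every regulon, drop near-silent ones, cluster the rest.

    Returns the per-regulon binarization report and the boolean activity
    matrix restricted to regulons active in at least ``min_active_frac`` of
    cells, hierarchically clustered (Jaccard distance, average linkage) on
    both axes.
    """
    reports = []
    masks = {}
    for name, row in auc.values.iterrows():
        x = row.to_numpy(dtype=float)
        if np.all(np.isnan(x)):
            reports.append(
                BinarizationResult(name, np.nan, np.nan, "degenerate", np.nan, "none", 0.0)
            )
            continue
        try:
            D, p = dip_test(x, n_boot=n_boot, seed=seed)
            modality = "bimodal" if p < alpha else "unimodal"
        except ValueError:
            D, p, modality = np.nan, np.nan, "degenerate"
        tau, rule, active = binarize_regulon(x, (D, 1.0 if np.isnan(p) else p), alpha=alpha)
        frac = float(active.mean())
        reports.append(BinarizationResult(name, D, p, modality, tau, rule, frac))
        if frac >= min_active_frac:
            masks[name] = active
    report_df = pd.DataFrame([vars(r) for r in reports]).set_index("regulon")

    if not masks:
        warnings.warn("no regulon is active in enough cells", stacklevel=2)
        empty = pd.DataFrame(columns=auc.values.columns)
        return report_df, BinaryActivityMatrix(empty, [], list(auc.values.columns))

    bin_df = pd.DataFrame(masks, index=auc.values.columns).T  # regulons x cells
    row_order = list(bin_df.index)
    col_order = list(bin_df.columns)
    if bin_df.shape[0] > 2:
        dr = pdist(bin_df.values.astype(bool), metric="jaccard")
        row_order = [bin_df.index[i] for i in leaves_list(linkage(dr, method="average"))]
    if bin_df.shape[1] > 2 and bin_df.shape[0] >= 1:
        dc = pdist(bin_df.values.T.astype(bool), metric="jaccard")
        col_order = [bin_df.columns[i] for i in leaves_list(linkage(dc, method="average"))]
    bin_df = bin_df.loc[row_order, col_order]
    return report_df, BinaryActivityMatrix(bin_df, row_order, col_order)
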