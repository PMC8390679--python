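"""Synthetic peri-gastrulation embryo atlas generator with known ground truth.

Emulates droplet scRNA-seq of wild-type and ISL1-mutant primate embryos at a
single late time point: eight cell populations (epiblast and its derivatives
amnion AM-1/AM-2 and mesoderm meso-1/meso-2, plus endoderm, trophoblast and
extraembryonic mesenchyme), an ISL1 regulon whose targets (BMP4-like,
WNT6-like, ...) are expressed in amnion and multiplicatively silenced by a
factor delta in mutant amnion cells, trophoblast-exclusive choriogonadotropin
reporter genes whose presence elsewhere is purely ambient, lognormal library
sizes, negative-binomial counts, and a latent epiblast pseudotime driving a
naive-to-primed expression switch.  Mutant embryos additionally show the
compositional phenotype: mesoderm nearly absent, amnion over-represented.

Counts are drawn NB(mean = libsize * profile * effect, dispersion theta) and
ambient contamination is mixed at the *rate* level: each cell's expected
expression is (1 - rho) * endogenous + rho * ambient, where the ambient
profile is the expected aggregate over the whole sample.  This keeps totals
calibrated and makes rho identifiable by the exclusive-marker estimator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ingest_qc import UmiCountMatrix

__all__ = ["CELL_TYPES", "SimConfig", "SimTruth", "build_default_config", "simulate_dataset"]

CELL_TYPES = (
    "Epi",
    "AM-1",
    "AM-2",
    "meso-1",
    "meso-2",
    "Endo",
    "Trophoblast",
    "ExE-Mech",
)
EPI_DERIVED = ("Epi", "AM-1", "AM-2", "meso-1", "meso-2")
AMNION = ("AM-1", "AM-2")
MESODERM = ("meso-1", "meso-2")

_WT_PROPORTIONS = {
    "Epi": 0.35,
    "AM-1": 0.10,
    "AM-2": 0.10,
    "meso-1": 0.10,
    "meso-2": 0.10,
    "Endo": 0.10,
    "Trophoblast": 0.10,
    "ExE-Mech": 0.05,
}
# mutant: mesoderm collapses to 1% each; amnion expands to compensate
_MT_PROPORTIONS = {
    **_WT_PROPORTIONS,
    "meso-1": 0.01,
    "meso-2": 0.01,
    "AM-1": 0.19,
    "AM-2": 0.19,
}


def _default_proportions() -> dict:
    return {"wt": dict(_WT_PROPORTIONS), "mt": dict(_MT_PROPORTIONS)}


@dataclass
class SimConfig:
    """Parameters of the synthetic embryo atlas.

    delta is the multiplicative effect of the mutation on regulon targets in
    amnion cells (0 < delta <= 1; 1 means no effect), rho_true the ambient
    contamination fraction, theta the NB inverse-dispersion
    (variance mu + mu^2/theta).
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 1500
    cell_type_proportions: dict = field(default_factory=_default_proportions)
    marker_block_size: int = 25
    regulon_tf: str = "ISL1"
    regulon_n_targets: int = 50
    delta: float = 0.3
    rho_true: float = 0.10
    n_reporter_genes: int = 3
    n_mito_genes: int = 13
    mito_fraction: float = 0.04
    libsize_log_mean: float = math.log(5000.0)
    libsize_log_sd: float = 0.4
    theta: float = 10.0
    n_naive_genes: int = 20
    n_primed_genes: int = 20
    day: str = "D14"
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not (0 < self.delta <= 1):
            raise ValueError("delta must lie in (0, 1]")
        if not (0 <= self.rho_true < 1):
            raise ValueError("rho_true must lie in [0, 1)")
        for name in (
            "n_genes",
            "n_cells_per_condition",
            "marker_block_size",
            "regulon_n_targets",
            "n_reporter_genes",
            "n_mito_genes",
            "n_naive_genes",
            "n_primed_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        for cond, props in self.cell_type_proportions.items():
            if set(props) != set(CELL_TYPES):
                raise ValueError(f"condition {cond!r} must specify all cell types")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"proportions for condition {cond!r} sum to {total}, not 1"
                )
        n_special = (
            self.n_reporter_genes
            + self.n_mito_genes
            + len(CELL_TYPES) * self.marker_block_size
            + 1
            + self.regulon_n_targets
            + self.n_naive_genes
            + self.n_primed_genes
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_special} structured genes"
            )
        return self


def build_default_config(overrides: Mapping | None = None) -> SimConfig:
    """Default configuration with optional field overrides (validated)."""
    overrides = dict(overrides or {})
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return SimConfig(**overrides).validate()


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    cell_type: pd.Series
    condition: pd.Series
    pseudotime: pd.Series  # in [0, 1] for epiblast cells, NaN otherwise
    regulon: dict  # TF name -> list of member genes (TF included)
    effect: pd.Series  # per-gene multiplier applied in mutant amnion cells
    rho_true: float
    ambient_profile: dict  # condition -> simplex over genes
    expected_mean: dict  # (condition, cell type) -> per-unit-libsize profile
    marker_sets: dict  # cell type -> list of marker genes
    naive_genes: list
    primed_genes: list
    reporter_genes: list
    mito_genes: list
    gene_ids: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "cell_type": self.cell_type.to_dict(),
            "condition": self.condition.to_dict(),
            "pseudotime": {
                k: (None if pd.isna(v) else float(v))
                for k, v in self.pseudotime.items()
            },
            "regulon": self.regulon,
            "effect": {g: float(e) for g, e in self.effect.items() if e != 1.0},
            "rho_true": self.rho_true,
            "reporter_genes": self.reporter_genes,
            "mito_genes": self.mito_genes,
            "naive_genes": self.naive_genes,
            "primed_genes": self.primed_genes,
            "marker_sets": self.marker_sets,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


# ----------------------------------------------------------------------
# gene panel layout
# ----------------------------------------------------------------------

def _gene_panel(config: SimConfig) -> dict:
    """Assign names and roles to the gene axis."""
    names: list[str] = []
    panel: dict = {}
    panel["reporters"] = [f"CGB{i + 1}" for i in range(config.n_reporter_genes)]
    names += panel["reporters"]
    panel["mito"] = [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    names += panel["mito"]
    markers = {}
    for ct in CELL_TYPES:
        markers[ct] = [f"MK-{ct}-{i + 1:02d}" for i in range(config.marker_block_size)]
        names += markers[ct]
    panel["markers"] = markers
    targets = ["BMP4", "WNT6"] + [
        f"{config.regulon_tf}-TGT-{i + 1:02d}" for i in range(config.regulon_n_targets - 2)
    ]
    panel["tf"] = config.regulon_tf
    panel["targets"] = targets
    names += [config.regulon_tf] + targets
    panel["naive"] = [f"NAIVE-{i + 1:02d}" for i in range(config.n_naive_genes)]
    panel["primed"] = [f"PRIMED-{i + 1:02d}" for i in range(config.n_primed_genes)]
    names += panel["naive"] + panel["primed"]
    n_bg = config.n_genes - len(names)
    panel["background"] = [f"GENE-{i + 1:04d}" for i in range(n_bg)]
    names += panel["background"]
    panel["gene_ids"] = np.array(names, dtype=str)
    return panel


_MARKER_FOLD = 8.0
_TARGET_FOLD = 8.0
_TARGET_OFF = 0.15  # residual target expression outside amnion
_TF_OFF = 0.02
_PT_FOLD = 4.0  # naive/primed genes in epiblast
_PT_OFF = 0.1
# choriogonadotropin-like reporters dominate the trophoblast transcriptome the
# way hCG subunit transcripts dominate early syncytiotrophoblast; graded shares
_REPORTER_SHARES = (0.20, 0.15, 0.10)


def _type_profiles(config: SimConfig, panel: dict, rng: np.random.Generator) -> np.ndarray:
    """Expected per-unit-libsize expression profile for each cell type (wt)."""
    G = config.n_genes
    gene_ids = panel["gene_ids"]
    idx = {g: i for i, g in enumerate(gene_ids)}
    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    # the BMP4/WNT6-like ligands are among the most abundant regulon targets,
    # so their loss dominates the mutant-amnion differential signal
    hi = float(np.quantile(base, 0.99))
    base[idx["BMP4"]] = 2.0 * hi
    base[idx["WNT6"]] = 1.5 * hi

    W = np.tile(base, (len(CELL_TYPES), 1))
    rep_idx = [idx[g] for g in panel["reporters"]]
    W[:, rep_idx] = 0.0

    for t, ct in enumerate(CELL_TYPES):
        for g in panel["markers"][ct]:
            W[t, idx[g]] *= _MARKER_FOLD

    tgt_idx = [idx[g] for g in panel["targets"]]
    tf_idx = idx[panel["tf"]]
    am_rows = [CELL_TYPES.index(ct) for ct in AMNION]
    for t in range(len(CELL_TYPES)):
        fold = _TARGET_FOLD if t in am_rows else _TARGET_OFF
        W[t, tgt_idx] *= fold
        W[t, tf_idx] *= _TARGET_FOLD if t in am_rows else _TF_OFF

    pt_idx = [idx[g] for g in panel["naive"] + panel["primed"]]
    epi_row = CELL_TYPES.index("Epi")
    for t in range(len(CELL_TYPES)):
        W[t, pt_idx] *= _PT_FOLD if t == epi_row else _PT_OFF

    # mito genes occupy a fixed fraction of every profile
    mito_idx = [idx[g] for g in panel["mito"]]
    non_special = np.ones(G, bool)
    non_special[mito_idx] = False
    for t in range(len(CELL_TYPES)):
        s_other = W[t, non_special].sum()
        target_total = config.mito_fraction / (1 - config.mito_fraction) * s_other
        w_mito = W[t, mito_idx]
        W[t, mito_idx] = w_mito / w_mito.sum() * target_total

    # reporters: exclusive, abundant trophoblast transcripts
    troph_row = CELL_TYPES.index("Trophoblast")
    s_other = W[troph_row].sum()
    shares = np.array(
        [_REPORTER_SHARES[i % len(_REPORTER_SHARES)] for i in range(len(rep_idx))]
    )
    shares = shares / shares.sum() * min(0.45, shares.sum())
    W[troph_row, rep_idx] = shares * s_other / (1 - shares.sum())

    return W / W.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------

def simulate_dataset(config: SimConfig, seed: int | None = None) -> tuple[UmiCountMatrix, SimTruth]:
    """Draw a wild-type + mutant dataset; identical (config, seed) -> identical output."""
    config.validate()
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(int(seed))
    s_profile, s_assign, s_counts = root.spawn(3)
    rng_profile = np.random.default_rng(s_profile)
    rng_assign = np.random.default_rng(s_assign)
    rng_counts = np.random.default_rng(s_counts)

    panel = _gene_panel(config)
    gene_ids = panel["gene_ids"]
    idx = {g: i for i, g in enumerate(gene_ids)}
    profiles_wt = _type_profiles(config, panel, rng_profile)

    regulon_genes = [panel["tf"]] + panel["targets"]
    regulon_idx = np.array([idx[g] for g in regulon_genes])
    effect = pd.Series(1.0, index=gene_ids)
    effect.iloc[regulon_idx] = config.delta

    naive_idx = np.array([idx[g] for g in panel["naive"]])
    primed_idx = np.array([idx[g] for g in panel["primed"]])
    epi_row = CELL_TYPES.index("Epi")

    # expected per-type profiles, with the mutant amnion effect applied
    expected_mean: dict = {}
    profiles = {"wt": profiles_wt, "mt": profiles_wt.copy()}
    for t, ct in enumerate(CELL_TYPES):
        expected_mean[("wt", ct)] = profiles_wt[t].copy()
    mt = profiles["mt"]
    for ct in AMNION:
        t = CELL_TYPES.index(ct)
        mt[t, regulon_idx] *= config.delta
    for t, ct in enumerate(CELL_TYPES):
        expected_mean[("mt", ct)] = mt[t].copy()

    # ambient profile per condition: expected aggregate over populations
    ambient = {}
    for cond in ("wt", "mt"):
        props = np.array(
            [config.cell_type_proportions[cond][ct] for ct in CELL_TYPES]
        )
        agg = props @ profiles[cond]
        ambient[cond] = agg / agg.sum()

    n = config.n_cells_per_condition
    barcodes, cell_types, conditions, pseudotimes = [], [], [], []
    counts_blocks = []
    for cond in ("wt", "mt"):
        props = np.array([config.cell_type_proportions[cond][ct] for ct in CELL_TYPES])
        type_idx = rng_assign.choice(len(CELL_TYPES), size=n, p=props)
        t_latent = rng_assign.uniform(0.0, 1.0, size=n)  # used for epiblast only
        libsize = rng_counts.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n)

        rates = profiles[cond][type_idx] * libsize[:, None]  # cells x genes (endogenous)
        is_epi = type_idx == epi_row
        if is_epi.any():
            epi_profiles = profiles[cond][epi_row][None, :] * np.ones((is_epi.sum(), 1))
            tt = t_latent[is_epi]
            epi_profiles[:, naive_idx] *= (2.0 * (1.0 - tt))[:, None]
            epi_profiles[:, primed_idx] *= (2.0 * tt)[:, None]
            epi_profiles /= epi_profiles.sum(axis=1, keepdims=True)
            rates[is_epi] = epi_profiles * libsize[is_epi, None]

        rho = config.rho_true
        total_rate = (1.0 - rho) * rates + rho * libsize[:, None] * ambient[cond][None, :]

        p_nb = config.theta / (config.theta + total_rate)
        block = rng_counts.negative_binomial(config.theta, p_nb)
        counts_blocks.append(block)

        barcodes += [f"{cond}-{i + 1:05d}" for i in range(n)]
        cell_types += [CELL_TYPES[t] for t in type_idx]
        conditions += [cond] * n
        pseudotimes += [t_latent[i] if is_epi[i] else np.nan for i in range(n)]

    counts = np.vstack(counts_blocks).T  # genes x cells
    barcodes = np.array(barcodes, dtype=str)
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "day": config.day,
            "batch": "B1",
            "cell_type": cell_types,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    m = UmiCountMatrix(sp.csr_matrix(counts), gene_ids, barcodes, meta)

    truth = SimTruth(
        cell_type=pd.Series(cell_types, index=barcodes, name="cell_type"),
        condition=pd.Series(conditions, index=barcodes, name="condition"),
        pseudotime=pd.Series(pseudotimes, index=barcodes, name="pseudotime"),
        regulon={panel["tf"]: regulon_genes},
        effect=effect,
        rho_true=config.rho_true,
        ambient_profile=ambient,
        expected_mean=expected_mean,
        marker_sets={ct: list(panel["markers"][ct]) for ct in CELL_TYPES},
        naive_genes=list(panel["naive"]),
        primed_genes=list(panel["primed"]),
        reporter_genes=list(panel["reporters"]),
        mito_genes=list(panel["mito"]),
        gene_ids=gene_ids,
    )
    return m, truth
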