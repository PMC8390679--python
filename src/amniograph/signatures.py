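"""Per-cell gene-signature scoring (ratio-of-sums, "signature share" style).

A cell's score for a signature is the share of its total UMI carried by the
signature genes, times 100.  The score is additive over disjoint signatures
and invariant to scaling a cell's counts, and the all-genes signature scores
exactly 100 in every cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest_qc import UmiCountMatrix

__all__ = ["GeneSignature", "read_gmt", "write_gmt", "score_signature", "score_signatures"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


def read_gmt(path) -> list[GeneSignature]:
    """Read a GMT file: one tab-separated line per set (name, description, genes...).

    Duplicate genes within a line are dropped with a warning; lines with
    fewer than three fields raise ``ValueError``.
    """
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated",
                    stacklevel=2,
                )
            sigs.append(GeneSignature(name=name, genes=tuple(deduped), description=desc))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description or sig.name, *sig.genes]) + "\n")
    return path


def score_signature(m: UmiCountMatrix, sig: GeneSignature) -> pd.Series:
    """Score s_c = 100 * (signature counts in cell c) / N_c for every cell.

    Signature genes absent from the matrix contribute zero (logged).  If no
    signature gene is present at all the result is all-zero (with a warning).
    """
    totals = m.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run QC first")
    present = [g for g in sig.genes if g in set(m.gene_ids)]
    missing = len(sig.genes) - len(present)
    if missing:
        log.info("signature %s: %d/%d genes absent from matrix", sig.name, missing, len(sig.genes))
    if not present:
        warnings.warn(f"signature {sig.name!r} has no genes in the matrix", stacklevel=2)
        return pd.Series(0.0, index=pd.Index(m.barcodes, name="barcode"), name=sig.name)
    idx = m.gene_index(present)
    sig_counts = np.asarray(m.values[idx].sum(axis=0)).ravel().astype(float)
    return pd.Series(
        100.0 * sig_counts / totals,
        index=pd.Index(m.barcodes, name="barcode"),
        name=sig.name,
    )


def score_signatures(m: UmiCountMatrix, sigs: Sequence[GeneSignature]) -> pd.DataFrame:
    """Cells x signatures score table."""
    return pd.DataFrame({s.name: score_signature(m, s) for s in sigs})
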