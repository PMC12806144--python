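"""Genes x motifs count matrices (CREF) and their binary incidence variant (CREI).

The CREF matrix of a species holds, for every protein-coding gene, the number
of occurrences of each cis-regulatory motif within the proximal promoter
window around its transcription start site.  Rows are genes, columns are
motifs.  The incidence (CREI) variant records only presence/absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class MatrixError(ValueError):
    """Raised for inconsistent or invalid count matrices."""


@dataclass
class CrefMatrix:
    """Non-negative integer genes x motifs occurrence-count matrix.

    Parameters
    ----------
    counts
        ``(g, m)`` array of non-negative integers.
    gene_ids, motif_ids
        Unique row and column labels.
    species
        Free-text species tag carried through the pipeline.
    """

    counts: np.ndarray
    gene_ids: list[str]
    motif_ids: list[str]
    species: str = "unknown"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise MatrixError("counts must be a 2-D array")
        g, m = self.counts.shape
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.motif_ids = [str(x) for x in self.motif_ids]
        if len(self.gene_ids) != g or len(self.motif_ids) != m:
            raise MatrixError(
                f"label lengths ({len(self.gene_ids)}, {len(self.motif_ids)}) "
                f"do not match matrix shape {self.counts.shape}"
            )
        if len(set(self.gene_ids)) != g:
            raise MatrixError("gene ids are not unique")
        if len(set(self.motif_ids)) != m:
            raise MatrixError("motif ids are not unique")
        if self.counts.size and self.counts.min() < 0:
            raise MatrixError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_motifs(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.motif_ids)

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column gene id, header row of motif ids."""
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, species: str = "unknown") -> "CrefMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            counts=df.to_numpy(),
            gene_ids=[str(i) for i in df.index],
            motif_ids=[str(c) for c in df.columns],
            species=species,
        )


def build_crei(cref: CrefMatrix) -> CrefMatrix:
    """Binary incidence matrix: entry 1 iff the motif occurs at least once."""
    inc = (np.asarray(cref.counts) > 0).astype(np.int64)
    return CrefMatrix(inc, list(cref.gene_ids), list(cref.motif_ids), cref.species)


def motif_multiplicity_quantiles(
    cref: CrefMatrix,
    probs: Sequence[float] = (0.10, 0.50, 0.90),
) -> pd.DataFrame:
    """Per-motif quantiles of occurrence counts across genes, rounded to int.

    Uses the type-1 empirical quantile (inverted CDF) and half-up rounding,
    so that e.g. the 10%/50%/90% summaries of each motif's count distribution
    are themselves integers comparable across motifs.

    Returns a DataFrame indexed by motif id with one column per probability.
    """
    probs = list(probs)
    if any(not (0.0 < p < 1.0) for p in probs):
        raise MatrixError("quantile probabilities must lie in (0, 1)")
    if sorted(probs) != probs:
        raise MatrixError("quantile probabilities must be sorted ascending")
    q = np.quantile(np.asarray(cref.counts, dtype=float), probs, axis=0,
                    method="inverted_cdf")
    # round half-up to integers: counts summaries stay on the count scale
    q = np.floor(q + 0.5).astype(np.int64)
    return pd.DataFrame(
        q.T, index=list(cref.motif_ids), columns=[f"q{p:g}" for p in probs]
    )
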