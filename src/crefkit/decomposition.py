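"""Robust low-rank + sparse decomposition and polarized dual eigen-modules.

The observed count matrix is modelled as ``C_tilde = C + S`` where ``C`` is
low-rank (the shared regulatory structure) and ``S`` is sparse (outliers).
``C`` is recovered by solving

    min ||C||_* + lambda * ||S||_1   subject to   C_tilde = C + S

with the inexact augmented Lagrange multipliers (IALM) algorithm, i.e.
alternating singular-value thresholding on ``C`` and entrywise soft
thresholding on ``S``.  The SVD of ``C`` then yields ordered dual
eigen-modules (rho_k, u_k, v_k); level 0 is the baseline (dense offset)
and is excluded from cross-species comparisons downstream.

Polarization fixes the arbitrary SVD sign by a skewness rule and sorts each
eigenvector's loadings in descending order; the head of the order is the
positive pole, the tail the negative pole.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CrefMatrix


class DecompositionError(ValueError):
    pass


@dataclass
class ConvergenceRecord:
    iterations: int
    residual: float
    converged: bool
    tol: float
    lam: float


def _soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def rpca_ialm(
    ctilde: np.ndarray | CrefMatrix,
    lam: float | str = "auto",
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, ConvergenceRecord]:
    """Split a matrix into low-rank + sparse parts by nuclear-norm + L1 IALM.

    Parameters
    ----------
    ctilde
        The observed matrix (a :class:`CrefMatrix` or plain array).
    lam
        Sparsity penalty; ``"auto"`` uses ``1/sqrt(max(g, m))``.
    tol
        Convergence threshold on ``||C_tilde - C - S||_F / ||C_tilde||_F``.
    max_iter
        Iteration cap; non-convergence returns the best iterate with
        ``converged=False``.

    Returns ``(C, S, record)``.
    """
    D = np.asarray(
        ctilde.counts if isinstance(ctilde, CrefMatrix) else ctilde, dtype=float
    )
    if D.ndim != 2:
        raise DecompositionError("input must be a 2-D matrix")
    if not np.all(np.isfinite(D)):
        raise DecompositionError("input matrix contains non-finite entries")
    g, m = D.shape
    if lam == "auto":
        lam_val = 1.0 / np.sqrt(max(g, m))
    else:
        lam_val = float(lam)
        if lam_val <= 0:
            raise DecompositionError("lambda must be positive")

    norm_fro = np.linalg.norm(D, "fro")
    if norm_fro == 0:  # zero matrix decomposes trivially
        rec = ConvergenceRecord(0, 0.0, True, tol, lam_val)
        return np.zeros_like(D), np.zeros_like(D), rec

    norm_two = np.linalg.norm(D, 2)
    norm_inf = np.abs(D).max() / lam_val
    Y = D / max(norm_two, norm_inf)
    mu = 1.25 / norm_two
    mu_bar = mu * 1e7
    rho = 1.5

    S = np.zeros_like(D)
    C = np.zeros_like(D)
    err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # singular-value thresholding step for the low-rank part
        U, sv, Vt = np.linalg.svd(D - S + Y / mu, full_matrices=False)
        sv_thr = np.maximum(sv - 1.0 / mu, 0.0)
        rank = int(np.count_nonzero(sv_thr))
        C = (U[:, :rank] * sv_thr[:rank]) @ Vt[:rank]
        # entrywise soft thresholding for the sparse part
        S = _soft_threshold(D - C + Y / mu, lam_val / mu)
        Z = D - C - S
        Y = Y + mu * Z
        mu = min(mu * rho, mu_bar)
        err = np.linalg.norm(Z, "fro") / norm_fro
        if err <= tol:
            break
    converged = err <= tol
    rec = ConvergenceRecord(it, float(err), bool(converged), tol, lam_val)
    return C, S, rec


@dataclass
class EigenModule:
    """One dual eigen-module: a singular triplet with polarization orders."""

    level: int
    singular_value: float
    gene_vector: np.ndarray
    motif_vector: np.ndarray
    gene_ids: list[str]
    motif_ids: list[str]
    gene_order: np.ndarray | None = None
    motif_order: np.ndarray | None = None
    sign_fixed: bool = False
    degenerate: bool = False

    @property
    def is_baseline(self) -> bool:
        return self.level == 0


def _sign_for(v: np.ndarray, labels: list[str]) -> float:
    """Sign convention: positive skewness of loadings; ties by the sign of
    the largest-magnitude loading (label order breaks exact magnitude ties)."""
    skew = float(np.sum(v**3))
    if abs(skew) > 1e-12:
        return 1.0 if skew > 0 else -1.0
    mags = np.abs(v)
    best = np.lexsort((labels, -mags))[0]
    s = np.sign(v[best])
    return float(s) if s != 0 else 1.0


def _descending_order(v: np.ndarray, labels: list[str]) -> np.ndarray:
    """Indices sorting loadings in descending order, ties broken by label."""
    return np.lexsort((labels, -v))


def polarize(module: EigenModule) -> EigenModule:
    """Fix the sign of a module and sort both eigenvectors' loadings.

    The sign making the motif-eigenvector positively skewed is applied to
    the motif vector, and the gene vector is flipped along with it so the
    singular value stays non-negative.  Polarizing twice equals polarizing
    once.  An all-equal (degenerate) vector keeps its sign and is ordered by
    label, with the ``degenerate`` flag set.
    """
    v = module.motif_vector
    u = module.gene_vector
    degenerate = bool(np.allclose(v, v.flat[0])) if v.size else True
    if not degenerate:
        s = _sign_for(v, module.motif_ids)
        v = s * v
        u = s * u
    module.motif_vector = v
    module.gene_vector = u
    module.degenerate = degenerate
    module.sign_fixed = True
    module.motif_order = _descending_order(v, module.motif_ids)
    module.gene_order = _descending_order(u, module.gene_ids)
    return module


@dataclass
class DualDecomposition:
    """Low-rank + sparse split of a CREF matrix with its eigen-modules."""

    low_rank: np.ndarray
    sparse: np.ndarray
    modules: list[EigenModule]
    lam: float
    convergence: ConvergenceRecord
    gene_ids: list[str]
    motif_ids: list[str]
    species: str = "unknown"

    @property
    def singular_values(self) -> np.ndarray:
        return np.array([m.singular_value for m in self.modules])

    def module(self, level: int) -> EigenModule:
        for m in self.modules:
            if m.level == level:
                return m
        raise DecompositionError(f"no module at level {level}")

    @property
    def n_levels(self) -> int:
        """Highest retained level (level 0 is the baseline)."""
        return len(self.modules) - 1

    # ---- serialization -------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "decomp") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        levels = [m.level for m in self.modules]
        sv = pd.DataFrame(
            {"level": levels, "singular_value": self.singular_values}
        )
        gene = pd.DataFrame(
            np.column_stack([m.gene_vector for m in self.modules]),
            index=self.gene_ids,
            columns=[f"level_{k}" for k in levels],
        )
        motif = pd.DataFrame(
            np.column_stack([m.motif_vector for m in self.modules]),
            index=self.motif_ids,
            columns=[f"level_{k}" for k in levels],
        )
        paths = {
            "singular_values": outdir / f"{prefix}.singular_values.tsv",
            "gene_loadings": outdir / f"{prefix}.gene_loadings.tsv",
            "motif_loadings": outdir / f"{prefix}.motif_loadings.tsv",
            "convergence": outdir / f"{prefix}.convergence.json",
        }
        # %.17g round-trips IEEE doubles exactly, so polarization orders
        # (which may hinge on near-ties) survive serialization
        sv.to_csv(paths["singular_values"], sep="\t", index=False,
                  float_format="%.17g")
        gene.index.name = "gene_id"
        gene.to_csv(paths["gene_loadings"], sep="\t", float_format="%.17g")
        motif.index.name = "motif_id"
        motif.to_csv(paths["motif_loadings"], sep="\t", float_format="%.17g")
        paths["convergence"].write_text(
            json.dumps(
                {
                    "iterations": self.convergence.iterations,
                    "residual": self.convergence.residual,
                    "converged": self.convergence.converged,
                    "tol": self.convergence.tol,
                    "lambda": self.lam,
                    "species": self.species,
                },
                indent=2,
            )
        )
        return paths

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "decomp") -> "DualDecomposition":
        outdir = Path(outdir)
        sv = pd.read_csv(outdir / f"{prefix}.singular_values.tsv", sep="\t",
                         float_precision="round_trip")
        gene = pd.read_csv(outdir / f"{prefix}.gene_loadings.tsv", sep="\t",
                           index_col=0, float_precision="round_trip")
        motif = pd.read_csv(outdir / f"{prefix}.motif_loadings.tsv", sep="\t",
                            index_col=0, float_precision="round_trip")
        conv = json.loads((outdir / f"{prefix}.convergence.json").read_text())
        gene_ids = [str(i) for i in gene.index]
        motif_ids = [str(i) for i in motif.index]
        modules = []
        for _, row in sv.iterrows():
            k = int(row["level"])
            mod = EigenModule(
                level=k,
                singular_value=float(row["singular_value"]),
                gene_vector=gene[f"level_{k}"].to_numpy(),
                motif_vector=motif[f"level_{k}"].to_numpy(),
                gene_ids=gene_ids,
                motif_ids=motif_ids,
            )
            modules.append(polarize(mod))
        rec = ConvergenceRecord(
            conv["iterations"], conv["residual"], conv["converged"],
            conv["tol"], conv["lambda"],
        )
        return cls(
            low_rank=np.zeros((0, 0)),
            sparse=np.zeros((0, 0)),
            modules=modules,
            lam=conv["lambda"],
            convergence=rec,
            gene_ids=gene_ids,
            motif_ids=motif_ids,
            species=conv.get("species", "unknown"),
        )


def svd_modules(
    C: np.ndarray,
    n_levels: int,
    gene_ids: list[str] | None = None,
    motif_ids: list[str] | None = None,
) -> list[EigenModule]:
    """Truncated SVD of the low-rank part as polarized eigen-modules 0..n_levels."""
    C = np.asarray(C, dtype=float)
    g, m = C.shape
    if n_levels + 1 > min(g, m):
        raise DecompositionError(
            f"n_levels={n_levels} too large for a {g}x{m} matrix"
        )
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    motif_ids = motif_ids or [f"m{j}" for j in range(m)]
    U, sv, Vt = np.linalg.svd(C, full_matrices=False)
    modules = []
    for k in range(n_levels + 1):
        mod = EigenModule(
            level=k,
            singular_value=float(sv[k]),
            gene_vector=U[:, k].copy(),
            motif_vector=Vt[k].copy(),
            gene_ids=gene_ids,
            motif_ids=motif_ids,
        )
        modules.append(polarize(mod))
    return modules


def decompose(
    cref: CrefMatrix,
    n_levels: int = 10,
    lam: float | str = "auto",
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> DualDecomposition:
    """Full pipeline step: robust split followed by polarized SVD modules."""
    C, S, rec = rpca_ialm(cref, lam=lam, tol=tol, max_iter=max_iter)
    n_levels = min(n_levels, min(C.shape) - 1)
    modules = svd_modules(C, n_levels, list(cref.gene_ids), list(cref.motif_ids))
    return DualDecomposition(
        low_rank=C,
        sparse=S,
        modules=modules,
        lam=rec.lam,
        convergence=rec,
        gene_ids=list(cref.gene_ids),
        motif_ids=list(cref.motif_ids),
        species=cref.species,
    )
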