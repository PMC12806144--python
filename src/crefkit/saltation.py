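"""Module stability and cross-species comparison of eigen-modules.

Stability of a dual eigen-module is governed by the normalized spectral gap
(relative distance) to its neighbour:

    d_k = (rho_k - rho_{k+1}) / rho_k

First-order perturbation theory for the eigenvectors of ``C^T C`` shows the
sensitivity of the k-th module to a symmetric perturbation is inversely
proportional to the gap between its eigenvalue and its neighbours'; after
normalizing by the local scale this gives sensitivity ~ 1/d_k.  A
near-degenerate pair is therefore free to rotate within its 2-D eigenspace
under small changes of the matrix — the mechanism behind "saltational"
(qualitative) module change, as opposed to gradual quantitative change.

Cross-species comparison works on motif-eigenvectors, which share a common
dimension across species (gene spaces differ and are never compared
directly): per-level Pearson correlation after sign alignment, Deming
(errors-in-both-variables) regression of the loadings, and the rotation
angle of one species' vector within the other's 2-D eigen-plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DualDecomposition


class StabilityError(ValueError):
    pass


class ComparisonError(ValueError):
    pass


# --------------------------------------------------------------------------
# spectral gaps
# --------------------------------------------------------------------------

@dataclass
class StabilityProfile:
    """Relative distances between adjacent eigen-modules (baseline excluded)."""

    relative_distances: dict[int, float]  # level k -> d_k for pair (k, k+1)
    flags: dict[int, str] = field(default_factory=dict)

    def flag(self, d_small: float) -> dict[int, str]:
        self.flags = {
            k: ("unstable" if d < d_small else "stable")
            for k, d in self.relative_distances.items()
        }
        return self.flags


def relative_distances(
    singular_values: np.ndarray, first_level: int = 1
) -> StabilityProfile:
    """Per-pair relative distances d_k = (rho_k - rho_{k+1})/rho_k.

    ``singular_values`` holds the ordered values starting at ``first_level``
    (pass the spectrum without its level-0 baseline, the default indexing);
    one distance is reported per adjacent pair, keyed by the lower level.
    """
    rho = np.asarray(singular_values, dtype=float)
    if rho.ndim != 1 or rho.size < 2:
        raise StabilityError("need at least two singular values")
    if np.any(np.diff(rho) > 1e-9 * max(rho[0], 1.0)):
        raise StabilityError("singular values must be non-increasing")
    if np.any(rho[:-1] <= 0):
        raise StabilityError("zero singular value: relative distance undefined")
    dists = {
        first_level + i: float((rho[i] - rho[i + 1]) / rho[i])
        for i in range(rho.size - 1)
    }
    return StabilityProfile(relative_distances=dists)


# --------------------------------------------------------------------------
# first-order perturbation of motif-eigenvectors
# --------------------------------------------------------------------------

@dataclass
class Perturbation:
    """A symmetric perturbation of the motif Gram matrix C^T C."""

    E: np.ndarray

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.ndim != 2 or E.shape[0] != E.shape[1]:
            raise StabilityError("perturbation must be square")
        if not np.allclose(E, E.T, atol=1e-12 * max(1.0, np.abs(E).max())):
            raise StabilityError("perturbation must be symmetric")
        self.E = 0.5 * (E + E.T)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.E, 2))


def perturb_first_order(
    C: np.ndarray, E: np.ndarray | Perturbation, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """First-order perturbed motif-eigenvectors v_hat_k, v_hat_{k+1}.

    The eigenvectors of ``C^T C + E`` are expanded around those of ``C^T C``:

        v_hat_k = v_k + sum_{j != k} (v_j^T E v_k) / (lambda_k - lambda_j) v_j

    with eigenvalue denominators ``lambda = rho^2`` (the eigenvalues of the
    Gram matrix; using singular-value differences instead would misstate the
    local scale).  Results are normalized to unit length.  A degenerate pair
    (rho_k == rho_{k+1}) has no well-defined first-order direction and
    raises ``StabilityError``.
    """
    if not isinstance(E, Perturbation):
        E = Perturbation(E)
    C = np.asarray(C, dtype=float)
    _, sv, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T
    lam = sv**2
    if k + 1 >= sv.size:
        raise StabilityError(f"level pair ({k}, {k + 1}) out of range")
    if abs(lam[k] - lam[k + 1]) <= 1e-12 * max(lam[k], 1.0):
        raise StabilityError(f"degenerate pair ({k}, {k + 1}): rho_k == rho_k+1")

    def expand(idx: int) -> np.ndarray:
        v = V[:, idx]
        Ev = E.E @ v
        coeff = V.T @ Ev  # v_j^T E v_idx for all j
        denom = lam[idx] - lam
        denom[idx] = np.inf
        # directions with (numerically) identical eigenvalues are skipped
        denom[np.abs(denom) <= 1e-12 * max(lam[idx], 1.0)] = np.inf
        vhat = v + V @ (coeff / denom)
        return vhat / np.linalg.norm(vhat)

    return expand(k), expand(k + 1)


def sensitivity_curve(
    gaps: np.ndarray,
    k: int = 2,
    n_dim: int = 40,
    n_levels: int = 6,
    perturb_scale: float = 1e-3,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo check of the sensitivity ~ 1/d_k law.

    For each relative distance ``d`` in ``gaps`` a matrix with that gap at
    level pair ``(k, k+1)`` is constructed (random orthonormal factors, fixed
    across gaps), perturbed by ``n_reps`` random symmetric matrices of
    spectral norm ``perturb_scale`` (on the Gram-matrix scale), and the mean
    angle between the true and perturbed k-th motif-eigenvector is recorded.

    The 1/d law describes intra-pair mixing, so it is visible while the
    swept gap stays the smallest spectral scale: the constructed spectrum
    keeps all other levels well separated, and gaps larger than the
    neighbouring separations are rejected.

    Returns a DataFrame with columns ``d_k`` and ``mean_deviation_rad``.
    """
    rng = np.random.default_rng(seed)
    gaps = np.asarray(gaps, dtype=float)
    # fixed random orthonormal bases
    U = np.linalg.qr(rng.standard_normal((n_dim * 2, n_levels + 1)))[0]
    V = np.linalg.qr(rng.standard_normal((n_dim, n_levels + 1)))[0]
    rows = []
    for d in gaps:
        # widely separated levels; only the (k, k+1) gap is swept
        rho = 10.0 * 0.75 ** np.arange(n_levels + 1)
        rho[k + 1] = rho[k] * (1.0 - d)
        if np.any(np.diff(rho) >= 0):
            raise StabilityError(
                f"gap {d} is not the smallest spectral scale of the construction"
            )
        C = (U * rho) @ V.T
        G = C.T @ C
        _, vecs = np.linalg.eigh(G)
        v_true = vecs[:, ::-1][:, k]
        devs = []
        for _ in range(n_reps):
            A = rng.standard_normal((n_dim, n_dim))
            E = 0.5 * (A + A.T)
            E *= perturb_scale / np.linalg.norm(E, 2)
            _, pvecs = np.linalg.eigh(G + E)
            v_hat = pvecs[:, ::-1][:, k]
            cosang = min(abs(float(v_true @ v_hat)), 1.0)
            devs.append(np.arccos(cosang))
        rows.append({"d_k": float(d), "mean_deviation_rad": float(np.mean(devs))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cross-species comparison
# --------------------------------------------------------------------------

def compare_motif_eigenvectors(
    vA: np.ndarray,
    vB: np.ndarray,
    labels_a: list[str] | None = None,
    labels_b: list[str] | None = None,
) -> tuple[float, bool]:
    """Pearson correlation of two species' motif-eigenvectors, sign-aligned.

    SVD signs are arbitrary, so ``vB`` is flipped first whenever that makes
    the correlation positive; the flip is reported.  Motif label orders must
    agree when provided.
    """
    vA = np.asarray(vA, dtype=float)
    vB = np.asarray(vB, dtype=float)
    if vA.shape != vB.shape:
        raise ComparisonError(f"length mismatch: {vA.shape} vs {vB.shape}")
    if labels_a is not None and labels_b is not None and list(labels_a) != list(labels_b):
        raise ComparisonError("motif label orders differ between species")
    r = float(stats.pearsonr(vA, vB).statistic)
    if r < 0:
        return -r, True
    return r, False


def deming_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Deming regression with error-variance ratio 1 (both axes noisy).

    slope = [s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)] / (2 s_xy),
    intercept = mean(y) - slope * mean(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ComparisonError("need at least three paired observations")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2) / (x.size - 1)
    syy = np.sum((y - ym) ** 2) / (x.size - 1)
    sxy = np.sum((x - xm) * (y - ym)) / (x.size - 1)
    if abs(sxy) < 1e-300:
        raise ComparisonError("zero covariance: Deming slope undefined")
    slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = ym - slope * xm
    return float(slope), float(intercept)


def rotation_angle(
    v_k: np.ndarray, v_k1: np.ndarray, probe: np.ndarray
) -> tuple[float, float]:
    """Rotation of ``probe`` within the reference plane span(v_k, v_{k+1}).

    Returns ``(angle_deg, out_of_plane)`` where the angle uses absolute
    inner products (sign-free, hence in [0, 90] degrees) and
    ``out_of_plane = 1 - ||projection||^2`` reports leakage outside the
    reference plane separately.
    """
    v_k = np.asarray(v_k, dtype=float)
    v_k1 = np.asarray(v_k1, dtype=float)
    probe = np.asarray(probe, dtype=float)
    if abs(float(v_k @ v_k1)) > 1.0 - 1e-9:
        raise ComparisonError("degenerate (collinear) reference pair")
    p1 = float(probe @ v_k)
    p2 = float(probe @ v_k1)
    angle = float(np.degrees(np.arctan2(abs(p2), abs(p1))))
    out_of_plane = float(max(0.0, 1.0 - (p1**2 + p2**2)))
    return angle, out_of_plane


@dataclass
class ComparisonResult:
    """Per-level cross-species comparison table and classification."""

    table: pd.DataFrame  # level, r, sign_flipped, slope, intercept, angle_deg,
    #                      out_of_plane, d_k, label
    species_a: str
    species_b: str

    def level_row(self, level: int) -> pd.Series:
        row = self.table[self.table["level"] == level]
        if row.empty:
            raise ComparisonError(f"no comparison at level {level}")
        return row.iloc[0]


def classify_levels(
    stability: StabilityProfile,
    correlations: dict[int, float],
    r_conserved: float = 0.95,
    d_small: float = 0.05,
) -> dict[int, str]:
    """Label each level conserved / divergent / saltation.

    A level is "saltation" when its adjacent-pair gap in the focal species is
    small (d < d_small) *and* the cross-species correlation is low
    (r < r_conserved); "conserved" when r >= r_conserved; otherwise
    "divergent" (changed without the near-degeneracy that licenses a
    qualitative rotation).
    """
    if not (0 < r_conserved < 1 and 0 < d_small < 1):
        raise ComparisonError("thresholds must lie in (0, 1)")
    labels = {}
    for level, r in correlations.items():
        d = stability.relative_distances.get(level, np.inf)
        if r >= r_conserved:
            labels[level] = "conserved"
        elif d < d_small:
            labels[level] = "saltation"
        else:
            labels[level] = "divergent"
    return labels


def compare_decompositions(
    decomp_a: DualDecomposition,
    decomp_b: DualDecomposition,
    levels: list[int] | None = None,
    r_conserved: float = 0.95,
    d_small: float = 0.05,
) -> ComparisonResult:
    """Full per-level comparison of two species' decompositions.

    Motif-eigenvectors are compared at each requested level (baseline level 0
    excluded by default); the rotation angle is measured for species B's
    vector within species A's (k, k+1) plane, so the last retained level has
    no angle.  Stability gaps are those of species A (the focal species).
    """
    if list(decomp_a.motif_ids) != list(decomp_b.motif_ids):
        raise ComparisonError("decompositions have different motif universes")
    max_level = min(decomp_a.n_levels, decomp_b.n_levels)
    if levels is None:
        levels = list(range(1, max_level + 1))
    if any(lv < 1 or lv > max_level for lv in levels):
        raise ComparisonError("requested levels outside decomposition depth")
    sv = decomp_a.singular_values[1:]
    positive = int(np.argmax(sv <= 0)) if np.any(sv <= 0) else sv.size
    if positive < 2:
        raise ComparisonError("focal spectrum has fewer than two positive levels")
    stability = relative_distances(sv[:positive], first_level=1)
    rows = []
    for lv in levels:
        va = decomp_a.module(lv).motif_vector
        vb = decomp_b.module(lv).motif_vector
        r, flipped = compare_motif_eigenvectors(
            va, vb, decomp_a.motif_ids, decomp_b.motif_ids
        )
        vb_aligned = -vb if flipped else vb
        try:
            slope, intercept = deming_fit(va, vb_aligned)
        except ComparisonError:  # degenerate level: no covariance to fit
            slope, intercept = np.nan, np.nan
        if lv + 1 <= decomp_a.n_levels:
            angle, oop = rotation_angle(
                va, decomp_a.module(lv + 1).motif_vector, vb
            )
        else:
            angle, oop = np.nan, np.nan
        rows.append(
            {
                "level": lv,
                "r": r,
                "sign_flipped": flipped,
                "slope": slope,
                "intercept": intercept,
                "angle_deg": angle,
                "out_of_plane": oop,
                "d_k": stability.relative_distances.get(lv, np.nan),
            }
        )
    table = pd.DataFrame(rows)
    labels = classify_levels(
        stability,
        {int(r["level"]): float(r["r"]) for r in rows},
        r_conserved=r_conserved,
        d_small=d_small,
    )
    table["label"] = [labels[int(lv)] for lv in table["level"]]
    return ComparisonResult(
        table=table, species_a=decomp_a.species, species_b=decomp_b.species
    )
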