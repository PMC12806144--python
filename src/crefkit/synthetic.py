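"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without genome downloads or a
proprietary motif library: this module plants known ground truth into

* genes x motifs count matrices — a low-rank signal (dense positive baseline
  plus sparse two-pole factors, mirroring the level-0 baseline and the
  polarized modules of real CREF matrices) corrupted by sparse outliers and
  count noise;
* species pairs whose motif-eigenvectors differ only by a known rotation of
  one adjacent level pair with a controllable spectral gap — the saltation
  scenario;
* promoter sequences carrying exact planted motif occurrences on a
  rejection-sampled hit-free background, with matching FASTA/GFF3 records;
* gene sets enriched at an eigenvector pole with controllable strength;
* repeat consensus sequences carrying a planted subset of motifs.

All randomness flows from one explicit seed per call; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enrichment import GeneSetCollection
from .matrix import CrefMatrix
from .pwm import BASES, Pwm, PwmLibrary, reverse_complement, scan_sequence

WINDOW = 1501  # promoter fixture length: 1000 upstream + TSS + 500 downstream


class SyntheticError(ValueError):
    pass


class CapacityError(SyntheticError):
    """Planted sites cannot fit into the target sequence."""


# --------------------------------------------------------------------------
# planted low-rank models
# --------------------------------------------------------------------------

def _two_pole_factors(
    n: int, n_levels: int, block: int, perm: np.ndarray | None = None
) -> np.ndarray:
    """Orthonormal (n, n_levels+1) factor matrix.

    Column 0 is the dense positive baseline 1/sqrt(n); column k (k >= 1) is a
    zero-sum two-pole vector supported on its own block of ``block``
    coordinates: a strong sparse positive pole (block/3 entries at +2a) and a
    weaker spread negative pole (2*block/3 entries at -a), giving positive
    skewness by construction.  Disjoint supports and zero column sums make
    the columns exactly orthonormal.
    """
    if block % 3 != 0 or block <= 0:
        raise SyntheticError("factor block size must be a positive multiple of 3")
    if n_levels * block > n:
        raise SyntheticError(
            f"{n_levels} blocks of {block} do not fit into {n} coordinates"
        )
    idx = np.arange(n) if perm is None else np.asarray(perm)
    F = np.zeros((n, n_levels + 1))
    F[:, 0] = 1.0 / math.sqrt(n)
    h = block // 3
    a = 1.0 / math.sqrt(6 * h)
    for k in range(1, n_levels + 1):
        sl = idx[(k - 1) * block : k * block]
        F[sl[:h], k] = 2 * a
        F[sl[h:], k] = -a
    return F


@dataclass
class PlantedModel:
    """Ground truth for a planted low-rank count matrix.

    ``spectrum`` holds rho_0 > rho_1 > ... > rho_s; ``gene_factors`` and
    ``motif_factors`` are orthonormal column sets (level 0 = baseline).
    """

    n_genes: int
    n_motifs: int
    spectrum: np.ndarray
    gene_factors: np.ndarray
    motif_factors: np.ndarray
    corruption_fraction: float = 0.0
    noise_model: str = "none"  # none | poisson | rounded-gaussian
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.spectrum.ndim != 1 or np.any(np.diff(self.spectrum) >= 0):
            raise SyntheticError("spectrum must be strictly decreasing")
        if np.any(self.spectrum <= 0):
            raise SyntheticError("spectrum must be positive")
        s1 = self.spectrum.size
        for name, F, n in (
            ("gene", self.gene_factors, self.n_genes),
            ("motif", self.motif_factors, self.n_motifs),
        ):
            F = np.asarray(F, dtype=float)
            if F.shape != (n, s1):
                raise SyntheticError(f"{name} factors must be ({n}, {s1})")
            gram = F.T @ F
            if np.max(np.abs(gram - np.eye(s1))) > 1e-10:
                raise SyntheticError(f"{name} factor columns are not orthonormal")
        if not (0.0 <= self.corruption_fraction < 1.0):
            raise SyntheticError("corruption_fraction must lie in [0, 1)")
        if self.noise_model not in ("none", "poisson", "rounded-gaussian"):
            raise SyntheticError(f"unknown noise model {self.noise_model!r}")

    @property
    def n_levels(self) -> int:
        return self.spectrum.size - 1

    @property
    def low_rank(self) -> np.ndarray:
        """The planted low-rank matrix L = sum_k rho_k u_k v_k^T (entrywise >= 0)."""
        return (self.gene_factors * self.spectrum) @ self.motif_factors.T


def make_planted_model(
    n_genes: int = 2000,
    n_motifs: int = 400,
    n_levels: int = 6,
    depth: float = 50.0,
    strengths: np.ndarray | None = None,
    gene_block: int | None = None,
    motif_block: int | None = None,
    corruption_fraction: float = 0.0,
    noise_model: str = "none",
    noise_sigma: float = 1.0,
    seed: int = 0,
    gene_perm: np.ndarray | None = None,
) -> PlantedModel:
    """Construct a planted model with guaranteed entrywise-non-negative signal.

    ``depth`` is the baseline expected count per cell (the level-0 offset);
    ``strengths`` (each in (0, 1), strictly decreasing) set the pole singular
    values relative to the largest value compatible with non-negativity, so
    the minimum entry of the signal is ``depth * (1 - max(strengths))``.
    Block sizes default to an even partition of the coordinates over the
    non-baseline levels (rounded down to a multiple of 3).
    """
    if gene_block is None:
        gene_block = (n_genes // n_levels) // 3 * 3
    if motif_block is None:
        motif_block = (n_motifs // n_levels) // 3 * 3
    if strengths is None:
        # capped below 0.5 so the signal stays entrywise non-negative even
        # when a species pair rotates a strong pole onto a negative one
        strengths = np.linspace(0.45, 0.20, n_levels)
    strengths = np.asarray(strengths, dtype=float)
    if strengths.size != n_levels:
        raise SyntheticError("need one strength per non-baseline level")
    if np.any((strengths <= 0) | (strengths >= 1)):
        raise SyntheticError("strengths must lie in (0, 1)")
    rho0 = depth * math.sqrt(n_genes * n_motifs)
    scale = depth * math.sqrt(gene_block * motif_block)
    spectrum = np.concatenate([[rho0], strengths * scale])
    U = _two_pole_factors(n_genes, n_levels, gene_block, perm=gene_perm)
    V = _two_pole_factors(n_motifs, n_levels, motif_block)
    return PlantedModel(
        n_genes=n_genes,
        n_motifs=n_motifs,
        spectrum=spectrum,
        gene_factors=U,
        motif_factors=V,
        corruption_fraction=corruption_fraction,
        noise_model=noise_model,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass
class SimulatedCref:
    """A generated count matrix together with its ground truth."""

    cref: CrefMatrix
    low_rank: np.ndarray  # planted L
    sparse_true: np.ndarray  # planted outliers S
    raw: np.ndarray  # L + S before noise/rounding/clipping
    outlier_mask: np.ndarray  # boolean, exactly ceil(f * g * m) True entries
    model: PlantedModel

    def write_ground_truth(self, path: str | Path) -> None:
        payload = {
            "spectrum": self.model.spectrum.tolist(),
            "gene_factors": self.model.gene_factors.tolist(),
            "motif_factors": self.model.motif_factors.tolist(),
            "outlier_mask": np.argwhere(self.outlier_mask).tolist(),
            "corruption_fraction": self.model.corruption_fraction,
            "noise_model": self.model.noise_model,
            "seed": self.model.seed,
        }
        Path(path).write_text(json.dumps(payload))


def gen_cref(model: PlantedModel, species: str = "synthetic") -> SimulatedCref:
    """Generate a non-negative integer count matrix from a planted model.

    The observed matrix is ``round(max(0, base + S))`` where ``base`` is the
    planted low-rank signal L under the chosen count-noise model (Poisson
    draws with mean L, rounded Gaussian, or none) and ``S`` plants exactly
    ``ceil(corruption_fraction * g * m)`` large positive outliers (spurious
    count excesses) at seeded positions.
    """
    rng = np.random.default_rng(model.seed)
    g, m = model.n_genes, model.n_motifs
    L = model.low_rank
    if L.min() < -1e-9:
        raise SyntheticError("planted signal has negative entries")
    L = np.maximum(L, 0.0)

    n_out = math.ceil(model.corruption_fraction * g * m)
    mask = np.zeros(g * m, dtype=bool)
    S = np.zeros(g * m)
    if n_out:
        pos = rng.choice(g * m, size=n_out, replace=False)
        mask[pos] = True
        S[pos] = rng.uniform(0.5, 1.5, size=n_out) * max(L.max(), 1.0)
    mask = mask.reshape(g, m)
    S = S.reshape(g, m)

    if model.noise_model == "poisson":
        base = rng.poisson(L).astype(float)
    elif model.noise_model == "rounded-gaussian":
        base = L + rng.normal(0.0, model.noise_sigma, size=L.shape)
    else:
        base = L
    counts = np.floor(np.maximum(base + S, 0.0) + 0.5).astype(np.int64)
    gene_ids = [f"g{i:05d}" for i in range(g)]
    motif_ids = [f"m{j:04d}" for j in range(m)]
    return SimulatedCref(
        cref=CrefMatrix(counts, gene_ids, motif_ids, species=species),
        low_rank=L,
        sparse_true=S,
        raw=L + S,
        outlier_mask=mask,
        model=model,
    )


# --------------------------------------------------------------------------
# species pairs with a planted rotation (saltation scenario)
# --------------------------------------------------------------------------

@dataclass
class SaltationScenario:
    """A two-species design with one planted eigenvector-pair rotation.

    Species B shares species A's motif factors except at the adjacent level
    pair ``rotated_level_pair``, whose columns are rotated within their 2-D
    span by ``rotation_deg``; the spectrum of both species is adjusted so the
    pair's relative distance equals ``gap_fraction``; B's gene factors are
    freshly drawn (species have different gene spaces).
    """

    base: PlantedModel
    rotated_level_pair: tuple[int, int] = (4, 5)
    rotation_deg: float = 40.0
    gap_fraction: float = 0.02
    conserved_levels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        k, k1 = self.rotated_level_pair
        if k1 != k + 1:
            raise SyntheticError("rotated level pair must be adjacent")
        if not (1 <= k and k1 <= self.base.n_levels):
            raise SyntheticError(
                f"rotated pair {self.rotated_level_pair} outside levels "
                f"1..{self.base.n_levels}"
            )
        if not (0.0 <= self.rotation_deg <= 90.0):
            raise SyntheticError("rotation must lie in [0, 90] degrees")
        if self.gap_fraction <= 0:
            raise SyntheticError("gap fraction must be positive")
        if not self.conserved_levels:
            self.conserved_levels = [
                lv for lv in range(1, self.base.n_levels + 1) if lv not in (k, k1)
            ]


def _adjust_gap(spectrum: np.ndarray, k: int, gap: float) -> np.ndarray:
    """Set (rho_k - rho_{k+1})/rho_k = gap, keeping the spectrum decreasing."""
    out = spectrum.copy()
    out[k + 1] = out[k] * (1.0 - gap)
    if np.any(np.diff(out) >= 0):
        raise SyntheticError(
            f"gap {gap} at pair ({k}, {k + 1}) breaks strict spectrum ordering"
        )
    return out


def gen_species_pair(
    scenario: SaltationScenario,
) -> tuple[SimulatedCref, SimulatedCref]:
    """Generate the two species of a saltation scenario (shared motif labels)."""
    base = scenario.base
    k, _ = scenario.rotated_level_pair
    spectrum = _adjust_gap(base.spectrum, k, scenario.gap_fraction)

    model_a = PlantedModel(
        n_genes=base.n_genes,
        n_motifs=base.n_motifs,
        spectrum=spectrum,
        gene_factors=base.gene_factors,
        motif_factors=base.motif_factors,
        corruption_fraction=base.corruption_fraction,
        noise_model=base.noise_model,
        noise_sigma=base.noise_sigma,
        seed=base.seed,
    )

    theta = math.radians(scenario.rotation_deg)
    V_b = base.motif_factors.copy()
    vk = base.motif_factors[:, k]
    vk1 = base.motif_factors[:, k + 1]
    V_b[:, k] = math.cos(theta) * vk + math.sin(theta) * vk1
    V_b[:, k + 1] = -math.sin(theta) * vk + math.cos(theta) * vk1

    rng = np.random.default_rng(base.seed)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    perm = np.random.default_rng(sub_seed).permutation(base.n_genes)
    # fresh gene factors reuse the block geometry of the base model
    gene_block = int(np.count_nonzero(base.gene_factors[:, 1]))
    U_b = _two_pole_factors(base.n_genes, base.n_levels, gene_block, perm=perm)
    model_b = PlantedModel(
        n_genes=base.n_genes,
        n_motifs=base.n_motifs,
        spectrum=spectrum,
        gene_factors=U_b,
        motif_factors=V_b,
        corruption_fraction=base.corruption_fraction,
        noise_model=base.noise_model,
        noise_sigma=base.noise_sigma,
        seed=sub_seed,
    )
    return gen_cref(model_a, species="species_A"), gen_cref(model_b, species="species_B")


def saltation_scenario(
    seed: int = 0,
    rotation_deg: float = 40.0,
    level_pair: tuple[int, int] = (4, 5),
    gap_fraction: float = 0.02,
    n_genes: int = 2000,
    n_motifs: int = 400,
    n_levels: int = 6,
    depth: float = 51200.0,
    noise_model: str = "poisson",
    corruption_fraction: float = 0.0,
) -> SaltationScenario:
    """The standard two-species saltation study design.

    The baseline depth sets the count scale and hence the Poisson
    signal-to-noise ratio.  A near-degenerate pair (gap ~2%) is by design
    maximally sensitive to perturbation, so the default depth keeps the
    sampling-noise rotation of that pair an order of magnitude below the
    planted rotation; at low depth the planted geometry is unrecoverable in
    principle, not merely in practice.
    """
    base = make_planted_model(
        n_genes=n_genes,
        n_motifs=n_motifs,
        n_levels=n_levels,
        depth=depth,
        corruption_fraction=corruption_fraction,
        noise_model=noise_model,
        seed=seed,
    )
    return SaltationScenario(
        base=base,
        rotated_level_pair=level_pair,
        rotation_deg=rotation_deg,
        gap_fraction=gap_fraction,
    )


# --------------------------------------------------------------------------
# PWM libraries and sequence fixtures
# --------------------------------------------------------------------------

from .pwm import _BASE_INDEX as _BIDX


def _site_could_trigger(pwm: Pwm, site: str, profile: str,
                        skip_forward_exact: bool = False) -> bool:
    """Whether a window overlapping a planted ``site`` is prone to hit ``pwm``.

    Checks every shift on both strands, completing off-site positions with
    their *average* weight under a uniform background.  A shift whose
    expected completion reaches the thresholds (e.g. a long shifted overlap
    between two consensus sequences) would make a hit likely for a large
    fraction of background draws, so rejection sampling of the background
    could stall; shifts that need several lucky background bases are left to
    the rejection loop.  ``skip_forward_exact`` exempts the full forward
    alignment (the intended hit of a motif on its own consensus).
    """
    mss_min, css_min = pwm.threshold(profile)
    L = len(pwm)
    W, wmin = pwm._weighted, pwm._wmin
    wbar = W.mean(axis=1)
    core = pwm._core_mask
    if pwm._range_all <= 1e-12 or pwm._range_core <= 1e-12:
        return False
    for strand, s in (("+", site), ("-", reverse_complement(site))):
        n = len(s)
        for shift in range(-(L - 1), n):
            if skip_forward_exact and strand == "+" and shift == 0 and n == L:
                continue
            cur_all = 0.0
            cur_core = 0.0
            for i in range(L):
                pos = shift + i
                w = W[i, _BIDX[s[pos]]] if 0 <= pos < n else wbar[i]
                cur_all += w
                if core[i]:
                    cur_core += w
            mss = (cur_all - wmin.sum()) / pwm._range_all
            css = (cur_core - wmin[core].sum()) / pwm._range_core
            if mss >= mss_min and css >= css_min:
                return True
    return False


def random_pwm_library(
    n_motifs: int = 6,
    length: int = 15,
    sharpness: float = 0.94,
    seed: int = 0,
    profile: str = "minFN",
    max_tries: int = 500,
) -> PwmLibrary:
    """Random sharp PWMs (one dominant base per position, prob ``sharpness``).

    Motifs of this sharpness and length are specific enough that random
    background rarely produces hits at the default thresholds, which keeps
    the rejection sampling of hit-free fixtures fast.  Candidate consensus
    sequences are redrawn until the motifs are mutually distinguishable at
    the given profile under a worst-case background: no window overlapping a
    planted consensus of one motif can ever hit another motif (or the same
    motif at a nonzero shift or on the opposite strand), whatever the
    surrounding bases.  Libraries violating this could not host exact site
    planting.
    """
    rng = np.random.default_rng(seed)
    entries: list[Pwm] = []
    off = (1.0 - sharpness) / 3.0

    def distinguishable(candidate: Pwm) -> bool:
        cons = candidate.consensus
        if _site_could_trigger(candidate, cons, profile, skip_forward_exact=True):
            return False
        for other in entries:
            if _site_could_trigger(other, cons, profile):
                return False
            if _site_could_trigger(candidate, other.consensus, profile):
                return False
        return True

    for j in range(n_motifs):
        for _ in range(max_tries):
            consensus = rng.integers(0, 4, size=length)
            probs = np.full((length, 4), off)
            probs[np.arange(length), consensus] = sharpness
            pwm = Pwm(id=f"M{j:03d}", probabilities=probs)
            if distinguishable(pwm):
                entries.append(pwm)
                break
        else:
            raise SyntheticError(
                f"could not draw {n_motifs} mutually distinguishable motifs "
                f"of length {length} in {max_tries} tries each"
            )
    return PwmLibrary(entries)


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _place_sites(
    rng: np.random.Generator, total_len: int, site_lens: list[int]
) -> list[int]:
    """Non-overlapping start positions for sites of given lengths (random order
    preserved); raises CapacityError when the sites cannot fit."""
    used = sum(site_lens)
    free = total_len - used
    if free < 0:
        raise CapacityError(
            f"{used} bp of planted sites exceed the {total_len} bp window"
        )
    # distribute the free space as random gaps before each site and at the end
    k = len(site_lens)
    cuts = np.sort(rng.integers(0, free + 1, size=k))
    gaps = np.diff(np.concatenate([[0], cuts]))
    starts = []
    pos = 0
    for gap, slen in zip(gaps, site_lens):
        pos += int(gap)
        starts.append(pos)
        pos += slen
    return starts


@dataclass
class PromoterFixture:
    """A 1501-bp promoter sequence with exactly the planted motif content."""

    gene_id: str
    chrom: str
    sequence: str
    tss: int  # 0-based position within the contig
    strand: str
    expected_counts: dict[str, int]
    planted_sites: list[tuple[str, int, str]]  # (motif_id, start, strand)

    def gff3_lines(self) -> list[str]:
        """Gene + transcript features placing the TSS so the promoter window
        maps onto the whole contig (1-based inclusive GFF3 coordinates)."""
        start1 = self.tss + 1
        end1 = len(self.sequence)
        return [
            f"{self.chrom}\tcrefkit\tgene\t{start1}\t{end1}\t.\t{self.strand}\t.\t"
            f"ID={self.gene_id};gene_id={self.gene_id}",
            f"{self.chrom}\tcrefkit\tmRNA\t{start1}\t{end1}\t.\t{self.strand}\t.\t"
            f"ID={self.gene_id}.t1;Parent={self.gene_id};"
            f"transcript_id={self.gene_id}.t1",
        ]


def gen_promoter_fixture(
    counts_row: dict[str, int] | np.ndarray,
    pwm_lib: PwmLibrary,
    bg_gc: float = 0.4,
    seed: int = 0,
    profile: str = "minFN",
    gene_id: str = "gene_0",
    chrom: str = "chr_0",
    site_strands: dict[str, str] | None = None,
    max_tries: int = 500,
) -> PromoterFixture:
    """A promoter sequence containing exactly the requested motif counts.

    Consensus sequences of each motif are planted at non-overlapping seeded
    positions (forward or reverse strand); the i.i.d. background at the given
    GC content is re-drawn until a scan of the assembled sequence yields
    exactly the planted counts for every library motif, so the fixture is
    sound by construction.  ``site_strands`` can force the strand of all
    sites of a motif (e.g. ``{"M001": "-"}``).
    """
    if not (0.0 < bg_gc < 1.0):
        raise SyntheticError("background GC content must lie in (0, 1)")
    if isinstance(counts_row, dict):
        expected = {p.id: int(counts_row.get(p.id, 0)) for p in pwm_lib}
    else:
        counts_row = np.asarray(counts_row)
        if counts_row.size != len(pwm_lib):
            raise SyntheticError("counts row length does not match the PWM library")
        expected = {p.id: int(c) for p, c in zip(pwm_lib, counts_row)}
    if any(c < 0 for c in expected.values()):
        raise SyntheticError("planted counts must be non-negative")

    sites: list[tuple[str, str]] = []  # (motif_id, site sequence 5'->3' on + strand)
    site_strand: list[str] = []
    rng = np.random.default_rng(seed)
    for pwm in pwm_lib:
        for _ in range(expected[pwm.id]):
            strand = (site_strands or {}).get(pwm.id) or ("+-"[rng.integers(0, 2)])
            seq = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
            sites.append((pwm.id, seq))
            site_strand.append(strand)

    order = rng.permutation(len(sites)) if sites else np.array([], dtype=int)
    sites = [sites[i] for i in order]
    site_strand = [site_strand[i] for i in order]
    site_lens = [len(s) for _, s in sites]

    for _ in range(max_tries):
        starts = _place_sites(rng, WINDOW, site_lens)
        seq = list(_random_background(rng, WINDOW, bg_gc))
        placed = []
        for (mid, s), start in zip(sites, starts):
            seq[start : start + len(s)] = s
            placed.append((mid, start))
        sequence = "".join(seq)
        observed = {p.id: scan_sequence(p, sequence, profile) for p in pwm_lib}
        if observed == expected:
            planted = [
                (mid, start, st)
                for (mid, start), st in zip(placed, site_strand)
            ]
            planted.sort(key=lambda t: t[1])
            return PromoterFixture(
                gene_id=gene_id,
                chrom=chrom,
                sequence=sequence,
                tss=1000,
                strand="+",
                expected_counts=expected,
                planted_sites=planted,
            )
    raise SyntheticError(
        f"no hit-free background found in {max_tries} tries; the motif library "
        "may be too permissive for exact planting"
    )


@dataclass
class GenomeFixture:
    """A multi-gene synthetic genome: one 1501-bp contig per gene."""

    fixtures: list[PromoterFixture]
    expected: CrefMatrix

    def fasta_text(self) -> str:
        return "".join(f">{f.chrom}\n{f.sequence}\n" for f in self.fixtures)

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for f in self.fixtures:
            lines.extend(f.gff3_lines())
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / f"{prefix}.fa",
            "gff3": outdir / f"{prefix}.gff3",
            "expected": outdir / f"{prefix}.expected_cref.tsv",
        }
        paths["fasta"].write_text(self.fasta_text())
        paths["gff3"].write_text(self.gff3_text())
        self.expected.write_tsv(paths["expected"])
        return paths


def gen_genome_fixture(
    counts: np.ndarray,
    pwm_lib: PwmLibrary,
    bg_gc: float = 0.4,
    seed: int = 0,
    profile: str = "minFN",
    species: str = "synthetic",
) -> GenomeFixture:
    """Promoter fixtures for a whole (genes x motifs) count matrix.

    Gene ``i`` lives on its own contig with its TSS placed so the promoter
    window covers the full 1501-bp sequence.
    """
    counts = np.asarray(counts)
    rng = np.random.default_rng(seed)
    fixtures = []
    for i in range(counts.shape[0]):
        fixtures.append(
            gen_promoter_fixture(
                counts[i],
                pwm_lib,
                bg_gc=bg_gc,
                seed=int(rng.integers(0, 2**31 - 1)),
                profile=profile,
                gene_id=f"gene_{i}",
                chrom=f"chr_{i}",
            )
        )
    expected = CrefMatrix(
        counts.astype(np.int64),
        [f.gene_id for f in fixtures],
        pwm_lib.motif_ids,
        species=species,
    )
    return GenomeFixture(fixtures=fixtures, expected=expected)


# --------------------------------------------------------------------------
# gene sets
# --------------------------------------------------------------------------

def gen_gene_sets(
    loadings: np.ndarray,
    gene_ids: list[str],
    n_enriched: int = 5,
    n_null: int = 5,
    strength: float = 1.0,
    set_size: int = 20,
    seed: int = 0,
    pole_scale: int = 100,
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Gene sets enriched at the positive pole of a gene-eigenvector.

    Enriched sets draw members without replacement with probability
    proportional to a rank weight raised to a strength-controlled power:
    weight ``((g - r + 1)/g) ** (strength * g / pole_scale)`` for descending
    rank ``r``.  At strength 0 this is uniform (indistinguishable from the
    null sets); at strength 1 the draws concentrate in roughly the top
    ``pole_scale`` ranks.  Returns the collection and a per-set flag
    ("enriched" / "null").
    """
    loadings = np.asarray(loadings, dtype=float)
    g = loadings.size
    if set_size >= g:
        raise SyntheticError("set_size must be smaller than the gene universe")
    if not (0.0 <= strength <= 1.0):
        raise SyntheticError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = np.argsort(-loadings, kind="stable")
    ranks = np.empty(g, dtype=float)
    ranks[order] = np.arange(1, g + 1)
    beta = strength * g / pole_scale
    weights = ((g - ranks + 1.0) / g) ** beta
    probs = weights / weights.sum()
    sets: dict[str, list[str]] = {}
    flags: dict[str, str] = {}
    for i in range(n_enriched):
        idx = rng.choice(g, size=set_size, replace=False, p=probs)
        name = f"enriched_{i:02d}"
        sets[name] = [gene_ids[j] for j in idx]
        flags[name] = "enriched"
    for i in range(n_null):
        idx = rng.choice(g, size=set_size, replace=False)
        name = f"null_{i:02d}"
        sets[name] = [gene_ids[j] for j in idx]
        flags[name] = "null"
    return GeneSetCollection(sets=sets, source="synthetic"), flags


# --------------------------------------------------------------------------
# repeat consensus libraries
# --------------------------------------------------------------------------

@dataclass
class RepeatFixture:
    """Synthetic repeat consensus sequences with known planted motif content."""

    consensi: list[tuple[str, str]]  # (name, sequence)
    planted: set[str]

    def fasta_text(self) -> str:
        return "".join(f">{name}\n{seq}\n" for name, seq in self.consensi)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.fasta_text())


def gen_repeat_library(
    pwm_lib: PwmLibrary,
    planted_subset: set[str] | list[str],
    seed: int = 0,
    n_consensus: int = 3,
    consensus_length: int = 350,
    bg_gc: float = 0.45,
    profile: str = "minFN",
    max_tries: int = 500,
    name_prefix: str = "REP",
) -> RepeatFixture:
    """Repeat consensus sequences containing exactly the planted motifs.

    The planted motifs' consensus sites are distributed round-robin over the
    consensus sequences; backgrounds are rejection-sampled until a scan of
    every sequence finds the planted motifs and nothing else.
    """
    planted = sorted(set(planted_subset))
    known = set(pwm_lib.motif_ids)
    unknown = set(planted) - known
    if unknown:
        raise SyntheticError(f"planted motifs not in library: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    per_seq: list[list[str]] = [[] for _ in range(n_consensus)]
    for i, mid in enumerate(planted):
        per_seq[i % n_consensus].append(mid)

    for _ in range(max_tries):
        consensi = []
        for s in range(n_consensus):
            site_seqs = []
            for mid in per_seq[s]:
                strand = "+-"[rng.integers(0, 2)]
                cons = pwm_lib[mid].consensus
                site_seqs.append(cons if strand == "+" else reverse_complement(cons))
            starts = _place_sites(rng, consensus_length, [len(x) for x in site_seqs])
            seq = list(_random_background(rng, consensus_length, bg_gc))
            for site, start in zip(site_seqs, starts):
                seq[start : start + len(site)] = site
            consensi.append((f"{name_prefix}{s}", "".join(seq)))
        found = set()
        for pwm in pwm_lib:
            if any(scan_sequence(pwm, seq, profile) > 0 for _, seq in consensi):
                found.add(pwm.id)
        if found == set(planted):
            return RepeatFixture(consensi=consensi, planted=set(planted))
    raise SyntheticError(
        f"no clean repeat background found in {max_tries} tries"
    )
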