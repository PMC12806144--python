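"""Transposable-element motif content (MPA) and repeat-overlap utilities.

An MPA ("motif present on Alu", generalised to any repeat family) is a motif
whose PWM hits a repeat consensus sequence at the scanning threshold.
Counting MPAs among the top-N motifs at an eigenvector pole, per level and
species, quantifies how much of a regulatory module's motif content repeats
could have delivered; the ape-to-human relative change of those counts
highlights levels where repeat-borne motifs accumulated.  Jaccard similarity
compares the motif content of two repeat families, and an interval-overlap
utility flags pole genes whose promoter windows carry annotated repeat
insertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .decomposition import DualDecomposition
from .promoter import PromoterRegion
from .pwm import PwmLibrary, scan_sequence


class MpaError(ValueError):
    pass


def find_mpa(
    pwm_lib: PwmLibrary,
    repeat_fasta: str | Path | list[tuple[str, str]],
    profile: str = "minFN",
) -> set[str]:
    """Motifs with at least one hit (either strand) on any consensus sequence.

    ``repeat_fasta`` may be a FASTA path or a pre-parsed list of
    ``(name, sequence)`` pairs.  An empty library or empty file yields the
    empty set.
    """
    if isinstance(repeat_fasta, (str, Path)):
        seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(repeat_fasta), "fasta")]
    else:
        seqs = list(repeat_fasta)
    found: set[str] = set()
    for pwm in pwm_lib:
        for _, seq in seqs:
            if scan_sequence(pwm, seq, profile) > 0:
                found.add(pwm.id)
                break
    return found


def pole_motifs(
    decomposition: DualDecomposition, level: int, pole: str = "positive", n: int = 100
) -> set[str]:
    """Top-``n`` motif ids of the polarized motif order at the given pole."""
    module = decomposition.module(level)
    m = len(module.motif_ids)
    if n > m:
        raise MpaError(f"requested top {n} of only {m} motifs")
    order = module.motif_order
    if pole == "positive":
        idx = order[:n]
    elif pole == "negative":
        idx = order[::-1][:n]
    else:
        raise MpaError(f"pole must be positive/negative, got {pole!r}")
    return {module.motif_ids[i] for i in idx}


def mpa_relative_change(count_focal: int, count_ref: int) -> float:
    """Relative change of MPA counts from a reference species, in percent."""
    if count_ref <= 0:
        raise MpaError("reference MPA count is zero: relative change undefined")
    return 100.0 * (count_focal - count_ref) / count_ref


def jaccard(set_a: set, set_b: set) -> tuple[float, bool]:
    """Jaccard similarity |A&B|/|A|B|; two empty sets give 1 with a flag."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        return 1.0, True
    return len(set_a & set_b) / len(union), False


@dataclass
class MpaResult:
    """Per-level MPA pole counts and relative changes across species."""

    mpa_set: set[str]
    pole_size: int
    counts: pd.DataFrame  # columns: species, level, pole, mpa_count
    relative_changes: pd.DataFrame  # columns: level, pole, reference, change_pct

    def write_tsv(self, path: str | Path) -> None:
        merged = self.counts.merge(
            self.relative_changes, on=["level", "pole"], how="left"
        )
        merged.to_csv(path, sep="\t", index=False)


def mpa_analysis(
    decompositions: dict[str, DualDecomposition],
    pwm_lib: PwmLibrary,
    repeat_fasta: str | Path | list[tuple[str, str]],
    focal: str,
    levels: list[int] | None = None,
    pole_size: int = 100,
    poles: tuple[str, ...] = ("positive",),
    profile: str = "minFN",
) -> MpaResult:
    """Count repeat-borne motifs at each species' eigenvector poles.

    For every level and pole, the number of MPAs among the top-``pole_size``
    motifs is counted per species, and the relative change of the focal
    species against each other species (the reference) is reported where the
    reference count is positive.
    """
    if focal not in decompositions:
        raise MpaError(f"focal species {focal!r} not among decompositions")
    mpa = find_mpa(pwm_lib, repeat_fasta, profile)
    if levels is None:
        depth = min(d.n_levels for d in decompositions.values())
        levels = list(range(1, depth + 1))
    count_rows = []
    counts: dict[tuple[str, int, str], int] = {}
    for species, decomp in decompositions.items():
        for lv in levels:
            for pole in poles:
                c = len(pole_motifs(decomp, lv, pole, pole_size) & mpa)
                counts[(species, lv, pole)] = c
                count_rows.append(
                    {"species": species, "level": lv, "pole": pole, "mpa_count": c}
                )
    change_rows = []
    for ref in decompositions:
        if ref == focal:
            continue
        for lv in levels:
            for pole in poles:
                ref_count = counts[(ref, lv, pole)]
                if ref_count > 0:
                    change = mpa_relative_change(counts[(focal, lv, pole)], ref_count)
                else:
                    change = np.nan
                change_rows.append(
                    {
                        "level": lv,
                        "pole": pole,
                        "reference": ref,
                        "change_pct": change,
                    }
                )
    return MpaResult(
        mpa_set=mpa,
        pole_size=pole_size,
        counts=pd.DataFrame(count_rows),
        relative_changes=pd.DataFrame(change_rows),
    )


# --------------------------------------------------------------------------
# repeat insertions overlapping promoter windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatInterval:
    """A repeat annotation as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 0:
            raise MpaError(f"malformed interval {self.chrom}:{self.start}-{self.end}")


def read_bed(path: str | Path) -> list[RepeatInterval]:
    """Read BED (0-based half-open; name from column 4 when present)."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise MpaError(f"malformed BED line {i + 1}: {line[:80]!r}")
        name = fields[3] if len(fields) > 3 else f"repeat_{i}"
        try:
            out.append(RepeatInterval(fields[0], int(fields[1]), int(fields[2]), name))
        except ValueError as exc:
            raise MpaError(f"malformed BED line {i + 1}: {exc}") from exc
    return out


def read_repeatmasker_out(path: str | Path) -> list[RepeatInterval]:
    """Read a RepeatMasker ``.out`` table (1-based inclusive query coordinates)."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        s = line.strip()
        if not s or s.lower().startswith(("sw", "score", "there were no")):
            continue
        fields = s.split()
        if len(fields) < 10:
            raise MpaError(f"malformed RepeatMasker line {i + 1}: {line[:80]!r}")
        try:
            chrom, begin, end, name = fields[4], int(fields[5]), int(fields[6]), fields[9]
        except ValueError as exc:
            raise MpaError(f"malformed RepeatMasker line {i + 1}: {exc}") from exc
        out.append(RepeatInterval(chrom, begin - 1, end, name))
    return out


def read_repeat_intervals(path: str | Path) -> list[RepeatInterval]:
    """Read repeat intervals, sniffing BED vs RepeatMasker ``.out``."""
    path = Path(path)
    if path.suffix == ".out":
        return read_repeatmasker_out(path)
    return read_bed(path)


def flag_repeat_insertions(
    promoters: list[PromoterRegion],
    repeat_intervals: list[RepeatInterval],
) -> pd.DataFrame:
    """All (gene, repeat) pairs whose intervals overlap by >= 1 bp.

    Both inputs use 0-based half-open coordinates on the same assembly.
    Returns a table sorted by (gene, repeat, overlap start) with the overlap
    length in bp.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for rep in repeat_intervals:
        if rep.end == rep.start:
            continue  # zero-length insertions cannot overlap by >= 1 bp
        trees.setdefault(rep.chrom, IntervalTree()).addi(rep.start, rep.end, rep)
    rows = []
    for prom in promoters:
        tree = trees.get(prom.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(prom.start, prom.end):
            rep = iv.data
            overlap = min(prom.end, rep.end) - max(prom.start, rep.start)
            if overlap >= 1:
                rows.append(
                    {
                        "gene_id": prom.gene_id,
                        "repeat": rep.name,
                        "chrom": prom.chrom,
                        "overlap_start": max(prom.start, rep.start),
                        "overlap_bp": overlap,
                    }
                )
    table = pd.DataFrame(rows, columns=["gene_id", "repeat", "chrom",
                                        "overlap_start", "overlap_bp"])
    return table.sort_values(
        ["gene_id", "repeat", "overlap_start"], kind="mergesort"
    ).reset_index(drop=True)
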