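"""Position weight matrices and MATCH-style promoter scanning.

A motif is a position weight matrix (PWM) giving the probability of each base
at each position of the binding site.  Scanning uses the information-weighted
similarity scores popularised by the MATCH program:

* per-position information weight ``I(i) = sum_b f(i,b) * ln(4 f(i,b))``
* raw window score ``sum_i I(i) * f(i, b_i)`` for window bases ``b_i``
* matrix similarity score (MSS) rescales the raw score between the scores of
  the per-position least- and most-probable bases, so MSS lies in [0, 1]
  and the consensus sequence scores exactly 1
* core similarity score (CSS) is the same quantity restricted to the five
  consecutive positions of highest information content.

A window is reported as a hit when both MSS and CSS clear the thresholds of
the active profile ("minFN" favours sensitivity, "minFP" specificity).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Default uniform threshold profiles (mss_min, css_min).  The canonical
#: per-motif MATCH profiles are proprietary; these package defaults keep the
#: intended sensitivity ordering (minFN admits everything minFP does).
DEFAULT_PROFILES: dict[str, tuple[float, float]] = {
    "minFN": (0.70, 0.75),
    "minFP": (0.90, 0.95),
}

#: Pseudocount added to base probabilities before computing information
#: weights, so zero-probability bases do not produce ln(0).
PSEUDOCOUNT = 0.01

CORE_LENGTH = 5


class PwmError(ValueError):
    """Raised for malformed PWMs or threshold profiles."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """A single position weight matrix.

    ``probabilities`` is an ``(L, 4)`` row-stochastic matrix over A, C, G, T.
    ``thresholds`` maps profile names to ``(mss_min, css_min)`` pairs.
    """

    id: str
    probabilities: np.ndarray
    thresholds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise PwmError(f"{self.id}: probabilities must be (L, 4)")
        if p.shape[0] < 4:
            raise PwmError(f"{self.id}: motif length must be >= 4")
        if np.any(p < 0):
            raise PwmError(f"{self.id}: negative probabilities")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise PwmError(f"{self.id}: probability rows must sum to 1")
        self.probabilities = p
        self._prepare()

    def _prepare(self) -> None:
        # regularised frequencies used for all scoring
        f = (self.probabilities + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
        with np.errstate(divide="ignore", invalid="ignore"):
            info = np.sum(f * np.log(4.0 * f), axis=1)  # I(i) >= 0
        self._freq = f
        self._info = info
        self._weighted = info[:, None] * f  # I(i) * f(i, b)
        self._wmin = self._weighted.min(axis=1)
        self._wmax = self._weighted.max(axis=1)
        # core = contiguous block of CORE_LENGTH positions of max information
        L = len(info)
        if L >= CORE_LENGTH:
            windows = np.lib.stride_tricks.sliding_window_view(info, CORE_LENGTH)
            start = int(np.argmax(windows.sum(axis=1)))
        else:  # motif shorter than the core: the core clamps to the motif
            start = 0
        self.core_positions = tuple(range(start, min(start + CORE_LENGTH, L)))
        core = np.array(self.core_positions)
        self._core_mask = np.zeros(L, dtype=bool)
        self._core_mask[core] = True
        self._range_all = float(self._wmax.sum() - self._wmin.sum())
        self._range_core = float(self._wmax[core].sum() - self._wmin[core].sum())
        self.degenerate = self._range_all <= 1e-12

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    @property
    def consensus(self) -> str:
        """Most probable base at each position."""
        return "".join(BASES[i] for i in np.argmax(self.probabilities, axis=1))

    def threshold(self, profile: str) -> tuple[float, float]:
        try:
            return self.thresholds[profile]
        except KeyError:
            raise PwmError(f"{self.id}: no threshold profile named {profile!r}")


def score_pwm_window(pwm: Pwm, window: str) -> tuple[float, float]:
    """MATCH-style (mss, css) similarity scores of one window, each in [0, 1].

    Raises ``PwmError`` on a length mismatch.  Windows containing ambiguous
    bases are the caller's responsibility (the scanner skips them).  A fully
    uninformative PWM (all rows uniform) is degenerate: both scores are
    defined as 0 and ``pwm.degenerate`` is set.
    """
    if len(window) != len(pwm):
        raise PwmError(
            f"{pwm.id}: window length {len(window)} != motif length {len(pwm)}"
        )
    try:
        idx = np.fromiter((_BASE_INDEX[b] for b in window.upper()), dtype=np.int64)
    except KeyError as exc:
        raise PwmError(f"{pwm.id}: ambiguous base {exc} in window") from exc
    w = pwm._weighted[np.arange(len(pwm)), idx]
    if pwm.degenerate:
        return 0.0, 0.0
    mss = float((w.sum() - pwm._wmin.sum()) / pwm._range_all)
    core = pwm._core_mask
    if pwm._range_core <= 1e-12:
        css = 0.0
    else:
        css = float(
            (w[core].sum() - pwm._wmin[core].sum()) / pwm._range_core
        )
    return mss, css


def _encode(seq: str) -> np.ndarray:
    """Encode a sequence as A,C,G,T -> 0..3; anything else -> -1."""
    table = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


def _strand_hits(pwm: Pwm, codes: np.ndarray, mss_min: float, css_min: float) -> int:
    L = len(pwm)
    n = codes.size
    if n < L:
        return 0
    win = np.lib.stride_tricks.sliding_window_view(codes, L)  # (n-L+1, L)
    valid = np.all(win >= 0, axis=1)  # windows containing N are skipped
    if not valid.any():
        return 0
    win = win[valid]
    pos = np.arange(L)
    w = pwm._weighted[pos, win]  # (n_valid, L)
    mss = (w.sum(axis=1) - pwm._wmin.sum()) / pwm._range_all
    core = pwm._core_mask
    if pwm._range_core <= 1e-12:
        return 0
    css = (w[:, core].sum(axis=1) - pwm._wmin[core].sum()) / pwm._range_core
    return int(np.count_nonzero((mss >= mss_min) & (css >= css_min)))


def scan_sequence(pwm: Pwm, sequence: str, profile: str = "minFN") -> int:
    """Count hits of ``pwm`` on both strands of ``sequence``.

    Every window position is scored independently, so overlapping occurrences
    each count; a palindromic site contributes one hit per strand.  Windows
    containing ambiguous bases are skipped.  A sequence shorter than the
    motif yields 0.
    """
    mss_min, css_min = pwm.threshold(profile)
    if len(sequence) < len(pwm):
        return 0
    if pwm.degenerate:
        return 0
    fwd = _strand_hits(pwm, _encode(sequence), mss_min, css_min)
    rev = _strand_hits(pwm, _encode(reverse_complement(sequence)), mss_min, css_min)
    return fwd + rev


@dataclass
class PwmLibrary:
    """An ordered collection of PWMs with shared threshold profiles."""

    entries: list[Pwm]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.entries]
        if len(set(ids)) != len(ids):
            raise PwmError("duplicate motif ids in library")
        self._by_id = {p.id: p for p in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, motif_id: str) -> Pwm:
        return self._by_id[motif_id]

    @property
    def motif_ids(self) -> list[str]:
        return [p.id for p in self.entries]

    def set_profile(self, name: str, mss_min: float, css_min: float) -> None:
        for p in self.entries:
            p.thresholds[name] = (mss_min, css_min)


def _motif_to_pwm(m, fallback_id: str) -> Pwm:
    counts = np.array([list(m.counts[b]) for b in BASES], dtype=float).T  # (L, 4)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    probs = counts / totals
    mid = getattr(m, "matrix_id", None) or m.name
    if not mid and isinstance(m, dict):  # TRANSFAC motifs are dict-like
        mid = m.get("AC") or m.get("ID")
    return Pwm(id=str(mid or fallback_id), probabilities=probs)


def read_transfac(path: str | Path) -> PwmLibrary:
    """Read a TRANSFAC-format matrix file (P0 header, count rows)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "TRANSFAC")
    entries = [_motif_to_pwm(m, f"motif_{i}") for i, m in enumerate(records)]
    return PwmLibrary(entries)


def read_jaspar(path: str | Path) -> PwmLibrary:
    """Read JASPAR PFM text (``>id name`` headers, one row per base)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    entries = [_motif_to_pwm(m, f"motif_{i}") for i, m in enumerate(records)]
    return PwmLibrary(entries)


def read_pwm_library(path: str | Path, fmt: str | None = None) -> PwmLibrary:
    """Read a PWM library, sniffing TRANSFAC vs JASPAR when ``fmt`` is None."""
    path = Path(path)
    if fmt is None:
        head = path.read_text()[:2000]
        fmt = "jaspar" if head.lstrip().startswith(">") else "transfac"
    fmt = fmt.lower()
    if fmt == "transfac":
        return read_transfac(path)
    if fmt == "jaspar":
        return read_jaspar(path)
    raise PwmError(f"unknown PWM library format: {fmt!r}")


def write_transfac(lib: PwmLibrary, path: str | Path, scale: int = 100) -> None:
    """Write the library in TRANSFAC matrix format (scaled pseudo-counts)."""
    out = io.StringIO()
    out.write("VV  crefkit PWM library\n//\n")
    for p in lib:
        out.write(f"AC  {p.id}\nID  {p.id}\n")
        out.write("P0      A      C      G      T\n")
        for i, row in enumerate(p.probabilities, start=1):
            cnt = np.floor(row * scale + 0.5).astype(int)
            out.write(
                f"{i:02d}  {cnt[0]:5d}  {cnt[1]:5d}  {cnt[2]:5d}  {cnt[3]:5d}\n"
            )
        out.write("XX\n//\n")
    Path(path).write_text(out.getvalue())


def load_thresholds_tsv(lib: PwmLibrary, path: str | Path, profile: str) -> None:
    """Load per-motif thresholds (columns: motif_id, mss_min, css_min)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        mid = str(row["motif_id"])
        if mid in lib._by_id:
            lib[mid].thresholds[profile] = (
                float(row["mss_min"]),
                float(row["css_min"]),
            )
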