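"""Independent brute-force motif scanner used as a test oracle.

Reimplements the information-weighted similarity scoring with plain Python
loops, from the probability matrices alone, sharing no code with the package
scanner.  Simple on purpose; per-motif preprocessing is hoisted out of the
window loop so whole-fixture scans stay affordable.
"""

import math

PSEUDOCOUNT = 0.01
CORE_LENGTH = 5
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _regularize(probs):
    return [
        [(p + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT) for p in row] for row in probs
    ]


def _info(freqs):
    return [sum(f * math.log(4.0 * f) for f in row) for row in freqs]


def _core_start(info):
    if len(info) < CORE_LENGTH:
        return 0
    best, best_sum = 0, -1.0
    for s in range(len(info) - CORE_LENGTH + 1):
        total = sum(info[s : s + CORE_LENGTH])
        if total > best_sum:
            best, best_sum = s, total
    return best


class _Prepared:
    """Per-motif quantities derived once from the probability matrix."""

    def __init__(self, probs):
        freqs = _regularize(probs)
        info = _info(freqs)
        start = _core_start(info)
        self.length = len(probs)
        self.core = set(range(start, min(start + CORE_LENGTH, self.length)))
        self.weighted = [
            [info[i] * f for f in row] for i, row in enumerate(freqs)
        ]
        self.min_all = sum(min(w) for w in self.weighted)
        self.max_all = sum(max(w) for w in self.weighted)
        self.min_core = sum(min(self.weighted[i]) for i in self.core)
        self.max_core = sum(max(self.weighted[i]) for i in self.core)

    def scores(self, window):
        """(mss, css) of one window, or None on an ambiguous base."""
        cur_all = 0.0
        cur_core = 0.0
        for i in range(self.length):
            base = window[i].upper()
            if base not in BASE_INDEX:
                return None
            w = self.weighted[i][BASE_INDEX[base]]
            cur_all += w
            if i in self.core:
                cur_core += w
        range_all = self.max_all - self.min_all
        range_core = self.max_core - self.min_core
        if range_all <= 1e-12:
            return 0.0, 0.0
        mss = (cur_all - self.min_all) / range_all
        css = 0.0 if range_core <= 1e-12 else (cur_core - self.min_core) / range_core
        return mss, css


def oracle_scores(probs, window):
    """(mss, css) of one window, or None if the window has ambiguous bases."""
    return _Prepared(probs).scores(window)


def oracle_scan(probs, sequence, mss_min, css_min):
    """Hit count of one motif on both strands of a sequence."""
    prepared = _Prepared(probs)
    L = prepared.length
    total = 0
    for seq in (sequence, reverse_complement(sequence)):
        seq = seq.upper()
        for s in range(len(seq) - L + 1):
            scores = prepared.scores(seq[s : s + L])
            if scores is None:
                continue
            mss, css = scores
            if mss >= mss_min and css >= css_min:
                total += 1
    return total


def reverse_complement(seq):
    return "".join(COMPLEMENT.get(b.upper(), "N") for b in reversed(seq))


def oracle_cref(pwm_probs, thresholds, promoter_seqs):
    """Count matrix for promoter sequences: rows genes, columns motifs."""
    return [
        [
            oracle_scan(probs, seq, mss_min, css_min)
            for probs, (mss_min, css_min) in zip(pwm_probs, thresholds)
        ]
        for seq in promoter_seqs
    ]
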