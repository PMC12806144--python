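"""Rank-based gene-set enrichment along polarized gene-eigenvectors.

A gene set is enriched at a pole of a gene-eigenvector when its members'
loadings rank significantly toward that pole, assessed by the one-sided
Wilcoxon (Mann-Whitney) rank-sum test of member vs. non-member loadings.
Ranks are computed on the raw (sign-fixed) loadings with midranks for ties;
the pole chooses the alternative hypothesis direction.  Small problems use
exact enumeration of the rank-sum null; larger ones use the normal
approximation with tie and continuity corrections.

Raw p-values are reported by default (Benjamini-Hochberg adjustment is
available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DualDecomposition

logger = logging.getLogger(__name__)

EXACT_MAX_MEMBERS = 10
EXACT_MAX_UNIVERSE = 30


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. read from a GMT file)."""

    sets: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def resolve(self, universe: list[str]) -> tuple[dict[str, list[str]], int]:
        """Drop members absent from the universe; return (resolved, n_dropped)."""
        uni = set(universe)
        resolved = {}
        dropped = 0
        for name, members in self.sets.items():
            kept = [g for g in members if g in uni]
            dropped += len(members) - len(kept)
            resolved[name] = kept
        return resolved, dropped


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise EnrichmentError(f"malformed GMT line: {line[:80]!r}")
        name, desc, *genes = fields
        sets[name] = [g for g in genes if g]
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, source=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnrichmentResult:
    set_name: str
    level: int
    pole: str
    p_value: float
    n_in_universe: int
    rank_sum: float
    method: str


def _exact_ranksum_tail(
    ranks2: np.ndarray, k: int, observed2: int, alternative: str
) -> float:
    """Exact tail probability of the rank-sum under uniform subset draws.

    ``ranks2`` are doubled midranks (integers even with ties); the null is
    every k-subset of the universe equally likely.  Dynamic programming over
    the doubled-rank-sum distribution.
    """
    ranks2 = np.asarray(ranks2, dtype=np.int64)
    n = ranks2.size
    smax = int(np.sort(ranks2)[-k:].sum())
    dp = np.zeros((k + 1, smax + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(k, 0, -1):
            dp[j, r:] += dp[j - 1, : smax + 1 - r]
    total = comb(n, k)
    if alternative == "greater":
        tail = dp[k, observed2:].sum()
    else:
        tail = dp[k, : observed2 + 1].sum()
    return float(tail / total)


def wilcoxon_enrichment(
    loadings: np.ndarray,
    gene_ids: list[str],
    members: set[str] | list[str],
    pole: str = "positive",
    level: int = -1,
    set_name: str = "",
) -> EnrichmentResult:
    """One-sided rank-sum enrichment of a gene set toward an eigenvector pole.

    ``pole="positive"`` tests whether member loadings rank higher than
    non-members'; ``"negative"`` tests whether they rank lower.  The set is
    first resolved against the gene universe (unresolved ids dropped); a set
    covering the whole universe is degenerate and returns p = 1.
    """
    if pole not in ("positive", "negative"):
        raise EnrichmentError(f"pole must be positive/negative, got {pole!r}")
    loadings = np.asarray(loadings, dtype=float)
    universe = list(gene_ids)
    if loadings.size != len(universe):
        raise EnrichmentError("loadings and gene ids differ in length")
    member_set = set(members) & set(universe)
    if not member_set:
        raise EnrichmentError(f"set {set_name!r}: no members in the gene universe")
    mask = np.array([g in member_set for g in universe])
    k = int(mask.sum())
    n = loadings.size
    ranks = stats.rankdata(loadings)  # midranks, ascending
    rank_sum = float(ranks[mask].sum())
    alternative = "greater" if pole == "positive" else "less"
    if k == n:  # degenerate: the set is the whole universe
        return EnrichmentResult(set_name, level, pole, 1.0, k, rank_sum, "degenerate")
    if k <= EXACT_MAX_MEMBERS and n <= EXACT_MAX_UNIVERSE:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        obs2 = int(np.rint(2 * rank_sum))
        p = _exact_ranksum_tail(ranks2, k, obs2, alternative)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            loadings[mask],
            loadings[~mask],
            alternative=alternative,
            method="asymptotic",
            use_continuity=True,
        )
        p = float(res.pvalue)
        method = "normal"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return EnrichmentResult(set_name, level, pole, p, k, rank_sum, method)


def enrich_all(
    decomposition: DualDecomposition,
    collection: GeneSetCollection,
    levels: list[int],
    poles: tuple[str, ...] = ("positive",),
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Enrichment of every set at every (level, pole) combination.

    Returns one row per (set, level, pole) with raw p-values; a ``p_bh``
    column is added only when ``benjamini_hochberg`` is set.
    """
    for lv in levels:
        if lv < 0 or lv > decomposition.n_levels:
            raise EnrichmentError(f"level {lv} outside decomposition depth")
    resolved, dropped = collection.resolve(decomposition.gene_ids)
    if dropped:
        logger.warning("dropped %d unresolved gene-set members", dropped)
    rows = []
    for lv in levels:
        u = decomposition.module(lv).gene_vector
        for pole in poles:
            for name, members in resolved.items():
                if not members:
                    logger.warning("set %s empty after resolution; skipped", name)
                    continue
                res = wilcoxon_enrichment(
                    u, decomposition.gene_ids, members, pole, lv, name
                )
                rows.append(
                    {
                        "set": name,
                        "level": lv,
                        "pole": pole,
                        "n": res.n_in_universe,
                        "rank_sum": res.rank_sum,
                        "p": res.p_value,
                        "method": res.method,
                    }
                )
    table = pd.DataFrame(rows)
    if benjamini_hochberg and not table.empty:
        from statsmodels.stats.multitest import multipletests

        table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def top_pole_genes(
    decomposition: DualDecomposition, level: int, pole: str, n: int
) -> pd.DataFrame:
    """The ``n`` most extreme genes at a pole of the polarized gene order.

    Returns a DataFrame with 1-based ``rank`` and ``gene_id`` columns,
    most extreme first.
    """
    module = decomposition.module(level)
    g = len(module.gene_ids)
    if n > g:
        raise EnrichmentError(f"requested top {n} of only {g} genes")
    order = module.gene_order
    if pole == "positive":
        idx = order[:n]
    elif pole == "negative":
        idx = order[::-1][:n]
    else:
        raise EnrichmentError(f"pole must be positive/negative, got {pole!r}")
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "gene_id": [module.gene_ids[i] for i in idx],
        }
    )


def species_specific_top_genes(
    focal: DualDecomposition,
    others: list[DualDecomposition],
    level: int,
    n: int,
    pole: str = "positive",
    ortholog_map: dict[str, dict[str, str]] | None = None,
) -> list[str]:
    """Focal-species top-N pole genes absent from every other species' top-N.

    ``ortholog_map[species][focal_gene]`` maps focal ids into each other
    species' gene namespace; identity is assumed where no map is given.
    A focal gene with no ortholog in a species cannot rank there and counts
    as species-specific (logged).
    """
    focal_top = list(top_pole_genes(focal, level, pole, n)["gene_id"])
    other_tops = [
        set(top_pole_genes(d, level, pole, min(n, len(d.gene_ids)))["gene_id"])
        for d in others
    ]
    out = []
    for gene in focal_top:
        specific = True
        for d, top in zip(others, other_tops):
            mapped = gene
            if ortholog_map is not None:
                species_map = ortholog_map.get(d.species, {})
                if gene not in species_map:
                    logger.info(
                        "gene %s unmapped in %s: treated as species-specific",
                        gene, d.species,
                    )
                    continue
                mapped = species_map[gene]
            if mapped in top:
                specific = False
                break
        if specific:
            out.append(gene)
    return out
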