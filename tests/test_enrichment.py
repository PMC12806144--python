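import numpy as np
import pytest

from crefkit.decomposition import decompose
from crefkit.enrichment import (
    EnrichmentError,
    GeneSetCollection,
    enrich_all,
    read_gmt,
    species_specific_top_genes,
    top_pole_genes,
    wilcoxon_enrichment,
    write_gmt,
)
from crefkit.synthetic import gen_gene_sets


def universe(n):
    return [f"g{i}" for i in range(n)]


class TestWilcoxonEnrichment:
    def test_exact_p_for_top_three_of_ten(self):
        """A 3-member set occupying the top 3 of 10 ranks has exactly one
        favourable configuration out of C(10,3)."""
        loadings = np.arange(10.0)
        res = wilcoxon_enrichment(loadings, universe(10), {"g7", "g8", "g9"})
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 120)

    def test_whole_universe_is_degenerate(self):
        res = wilcoxon_enrichment(np.arange(5.0), universe(5), set(universe(5)))
        assert res.p_value == 1.0

    def test_negative_pole_mirrors_positive(self):
        loadings = np.arange(10.0)
        bottom = {"g0", "g1", "g2"}
        res = wilcoxon_enrichment(loadings, universe(10), bottom, pole="negative")
        assert res.p_value == pytest.approx(1 / 120)

    def test_unresolvable_set_rejected(self):
        with pytest.raises(EnrichmentError, match="no members"):
            wilcoxon_enrichment(np.arange(5.0), universe(5), {"nope"})

    def test_exact_handles_ties_via_midranks(self):
        loadings = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 2.0])
        res = wilcoxon_enrichment(loadings, universe(6), {"g4", "g5"})
        # enumerate by hand: doubled midranks (4,4,4,9,9,12); T_obs = 21;
        # of C(6,2)=15 subsets, only (g3,g5),(g4,g5) reach 21
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 15)

    def test_normal_approximation_close_to_exact(self):
        """On universes small enough to enumerate, the tie/continuity
        corrected normal approximation agrees with the exact tail."""
        rng = np.random.default_rng(0)
        from crefkit import enrichment as en

        for seed in range(10):
            loadings = np.round(rng.standard_normal(28), 1)
            members = {f"g{i}" for i in rng.choice(28, 8, replace=False)}
            exact = wilcoxon_enrichment(loadings, universe(28), members)
            assert exact.method == "exact"
            # force the large-sample path on the same data
            orig = en.EXACT_MAX_UNIVERSE
            en.EXACT_MAX_UNIVERSE = 0
            try:
                approx = wilcoxon_enrichment(loadings, universe(28), members)
            finally:
                en.EXACT_MAX_UNIVERSE = orig
            assert approx.method == "normal"
            assert approx.p_value == pytest.approx(exact.p_value, rel=0.10)

    def test_null_p_values_are_calibrated(self):
        rng = np.random.default_rng(1)
        g = 1000
        loadings = rng.standard_normal(g)
        ids = universe(g)
        pvals = []
        for _ in range(400):
            members = {ids[i] for i in rng.choice(g, 15, replace=False)}
            pvals.append(wilcoxon_enrichment(loadings, ids, members).p_value)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert abs(rate - 0.05) < 0.03


@pytest.fixture(scope="module")
def decomp(planted_sim):
    return decompose(planted_sim.cref, n_levels=4)


class TestEnrichAll:
    def test_planted_set_is_most_significant(self, decomp):
        loadings = decomp.module(2).gene_vector
        coll, flags = gen_gene_sets(
            loadings, decomp.gene_ids, n_enriched=1, n_null=6,
            strength=1.0, set_size=15, seed=2, pole_scale=40,
        )
        table = enrich_all(decomp, coll, levels=[2])
        best = table.loc[table["p"].idxmin(), "set"]
        assert flags[best] == "enriched"

    def test_deterministic(self, decomp):
        coll, _ = gen_gene_sets(
            decomp.module(1).gene_vector, decomp.gene_ids,
            n_enriched=2, n_null=2, set_size=10, seed=3,
        )
        a = enrich_all(decomp, coll, levels=[1, 2], poles=("positive", "negative"))
        b = enrich_all(decomp, coll, levels=[1, 2], poles=("positive", "negative"))
        assert a.equals(b)

    def test_p_monotone_in_rank_sum_at_fixed_size(self, decomp):
        rng = np.random.default_rng(4)
        coll = GeneSetCollection(
            sets={
                f"s{i}": [decomp.gene_ids[j] for j in rng.choice(300, 12, replace=False)]
                for i in range(12)
            }
        )
        table = enrich_all(decomp, coll, levels=[1])
        t = table.sort_values("rank_sum")
        assert (np.diff(t["p"].to_numpy()) <= 1e-12).all()

    def test_bh_column_only_on_request(self, decomp):
        coll = GeneSetCollection(sets={"s": decomp.gene_ids[:5]})
        raw = enrich_all(decomp, coll, levels=[1])
        adj = enrich_all(decomp, coll, levels=[1], benjamini_hochberg=True)
        assert "p_bh" not in raw.columns
        assert "p_bh" in adj.columns

    def test_level_outside_depth_rejected(self, decomp):
        coll = GeneSetCollection(sets={"s": decomp.gene_ids[:5]})
        with pytest.raises(EnrichmentError):
            enrich_all(decomp, coll, levels=[99])


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            sets={"a": ["g1", "g2"], "b": ["g3"]},
            descriptions={"a": "first", "b": "second"},
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\n")
        with pytest.raises(EnrichmentError, match="malformed"):
            read_gmt(path)


class TestTopPoleGenes:
    def test_full_order_and_single_gene(self, decomp):
        g = len(decomp.gene_ids)
        full = top_pole_genes(decomp, 1, "positive", g)
        assert len(full) == g
        top1 = top_pole_genes(decomp, 1, "positive", 1)
        assert list(top1["gene_id"]) == [full["gene_id"].iloc[0]]

    def test_positive_pole_holds_planted_pole_genes(self, planted_sim, decomp):
        u = planted_sim.model.gene_factors[:, 1]
        planted_pole = {planted_sim.cref.gene_ids[i] for i in np.where(u > 0)[0]}
        top = set(top_pole_genes(decomp, 1, "positive", len(planted_pole))["gene_id"])
        assert top == planted_pole

    def test_negative_pole_is_reversed_order(self, decomp):
        g = len(decomp.gene_ids)
        pos = list(top_pole_genes(decomp, 1, "positive", g)["gene_id"])
        neg = list(top_pole_genes(decomp, 1, "negative", g)["gene_id"])
        assert neg == pos[::-1]

    def test_oversized_request_rejected(self, decomp):
        with pytest.raises(EnrichmentError):
            top_pole_genes(decomp, 1, "positive", 10**6)


class TestSpeciesSpecificTopGenes:
    def test_identical_species_give_empty_list(self, planted_sim):
        d = decompose(planted_sim.cref, n_levels=2)
        assert species_specific_top_genes(d, [d], level=1, n=20) == []

    def test_zero_n_gives_empty_list(self, planted_sim):
        d = decompose(planted_sim.cref, n_levels=2)
        assert species_specific_top_genes(d, [d], level=1, n=0) == []

    def test_planted_focal_only_gene_found(self, planted_sim):
        d = decompose(planted_sim.cref, n_levels=2)
        top = top_pole_genes(d, 1, "positive", 10)
        focal_only = top["gene_id"].iloc[0]
        # the other species maps every gene except the focal top gene
        omap = {
            "other": {
                g: g for g in planted_sim.cref.gene_ids if g != focal_only
            }
        }
        other = decompose(planted_sim.cref, n_levels=2)
        other.species = "other"
        out = species_specific_top_genes(
            d, [other], level=1, n=10, ortholog_map=omap
        )
        assert out == [focal_only]
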