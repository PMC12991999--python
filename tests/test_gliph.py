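"""Motif clustering: k-mer machinery, enrichment null, global clusters."""

import itertools

import numpy as np
import pandas as pd
import pytest

import tcrgvhd as t
from tcrgvhd.gliph import GliphConfig, kmer_table, motif_pvalues


def make_pool(cdr3s, sample_id="S1"):
    return pd.DataFrame(
        {"sample_id": sample_id, "cdr3_aa": list(cdr3s), "v_gene": "TRBV1"}
    )


class TestInterior:
    def test_default_trim_drops_three_each_side(self):
        assert t.interior("CASSIRSSYEQYF") == "SIRSSYE"

    def test_zero_trim_is_identity(self):
        assert t.interior("CASSF", trim=(0, 0)) == "CASSF"

    def test_minimal_length_leaves_one_residue(self):
        assert t.interior("CASSYEQ") == "S"

    def test_too_short_rejected(self):
        with pytest.raises(t.ConfigError):
            t.interior("CASSYE")


class TestKmerTable:
    def test_enumerates_all_kmers(self):
        table = kmer_table(["CASSIRSSYEQYF"], 3)  # interior SIRSSYE
        assert set(table) == {"SIR", "IRS", "RSS", "SSY", "SYE"}
        assert all(count == 1 for count, _ in table.values())

    def test_presence_semantics_within_one_cdr3(self):
        table = kmer_table(["CASSSSSQYF"], 3)  # interior SSSS
        assert table["SSS"][0] == 1

    def test_shared_kmer_counts_supporters(self):
        table = kmer_table(["CASQGAYEQYF", "CTSQGASNQPF"], 3)
        count, supporters = table["QGA"]
        assert count == 2 and len(supporters) == 2


class TestSelection:
    def make_rep(self, counts):
        return t.Repertoire.from_counts(counts, sample_id="s1")

    def test_frequency_floor_is_strict(self):
        filler = {"CASSPDRGAYGYTF": 1_000_000 - 201}
        rep = self.make_rep(
            {"CASSIRSSYEQYF": 101, "CASSLGQAYEQYF": 100, **filler}
        )
        pool = t.select_input_clonotypes([rep], GliphConfig())
        kept = set(pool["cdr3_aa"])
        assert "CASSIRSSYEQYF" in kept  # 0.0101% > 0.01%
        assert "CASSLGQAYEQYF" not in kept  # exactly 0.01% excluded

    def test_length_cutoff_applied(self):
        rep = self.make_rep({"CASSYEQ": 500, "CASSYEQF": 500})
        pool = t.select_input_clonotypes([rep], GliphConfig())
        assert set(pool["cdr3_aa"]) == {"CASSYEQF"}  # length 7 dropped

    def test_empty_pool_is_an_error(self):
        rep = self.make_rep({"CASSYEQ": 10})
        with pytest.raises(t.ConfigError):
            t.select_input_clonotypes([rep], GliphConfig())


class TestLocalEnrichment:
    def test_motif_absent_from_reference_gets_minimal_p(self):
        cfg = GliphConfig(simulation_depth=200, kmer_lengths=(3,), seed=0)
        sample = make_pool(
            [f"CAS{side}WQH{tail}F" for side, tail in
             zip("SDEGR", ["YEQY", "SNQP", "TGEL", "NTEA", "YGYT"])]
        )
        ref = t.generate_reference(2_000, seed=1)
        groups = t.local_motif_enrichment(sample, ref, cfg)
        by_sig = {g.signature: g for g in groups}
        assert "WQH" in by_sig
        assert by_sig["WQH"].p_empirical == pytest.approx(1 / 201)
        assert by_sig["WQH"].enrichment_fold >= cfg.min_fold_enrichment

    def test_support_below_min_depth_never_tested(self):
        cfg = GliphConfig(simulation_depth=100, kmer_lengths=(4,), seed=0)
        sample = make_pool(["CASSWQHYEQYF", "CASRWQHYSNQPF"])  # support 2 < 3
        ref = t.generate_reference(500, seed=1)
        tab = motif_pvalues(sample, ref, cfg)
        assert "WQHY" not in set(tab["motif"])

    def test_retained_motifs_respect_min_depth(self, tiny_cohort):
        cfg = GliphConfig(simulation_depth=100, seed=0)
        cohort, _ = t.normalize_cohort(tiny_cohort, 10_000, seed=0)
        ref = t.generate_reference(6_000, seed=1)
        groups = t.build_gliph_groups(cohort, ref, cfg)
        for g in groups:
            if g.kind == "local":
                support = len({m[1] for m in g.members})
                assert support >= cfg.kmer_min_depth

    def test_reference_smaller_than_pool_rejected(self):
        cfg = GliphConfig(simulation_depth=50)
        sample = make_pool([f"CASS{a}{b}RSSYEQYF" for a, b in
                            itertools.product("ADE", repeat=2)])
        with pytest.raises(t.ConfigError):
            t.local_motif_enrichment(sample, ["CASSLGRAYEQYF"], cfg)


class TestGlobalGroups:
    def test_single_interior_substitution_groups(self):
        pool = make_pool(["CASSIRSSYEQYF", "CASSIRSTYEQYF"])
        groups = t.global_similarity_groups(pool, GliphConfig())
        assert len(groups) == 1
        assert {m[1] for m in groups[0].members} == set(pool["cdr3_aa"])

    def test_different_lengths_never_grouped(self):
        pool = make_pool(["CASSIRSSYEQYF", "CASSIRSSYEQYAF"])
        assert t.global_similarity_groups(pool, GliphConfig()) == []

    def test_matches_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        cdr3s = set()
        # deliberately collision-prone: short, tiny alphabet subset
        while len(cdr3s) < 300:
            L = int(rng.integers(9, 12))
            cdr3s.add("C" + "".join(rng.choice(letters[:6], L - 2)) + "F")
        pool = make_pool(sorted(cdr3s))
        cfg = GliphConfig()
        got = {
            frozenset(m[1] for m in g.members)
            for g in t.global_similarity_groups(pool, cfg)
        }

        # O(n^2) oracle: explicit pairwise interior Hamming <= 1 on equal lengths
        parent = {c: c for c in cdr3s}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in itertools.combinations(sorted(cdr3s), 2):
            if len(a) != len(b):
                continue
            ia, ib = a[3:-3], b[3:-3]
            if sum(x != y for x, y in zip(ia, ib)) <= 1:
                parent[find(a)] = find(b)
        comps = {}
        for c in cdr3s:
            comps.setdefault(find(c), set()).add(c)
        expected = {frozenset(v) for v in comps.values() if len(v) >= 2}
        assert got == expected


class TestDeterminismAndRecovery:
    def test_group_set_invariant_to_sample_order(self, tiny_cohort):
        cfg = GliphConfig(simulation_depth=100, seed=3)
        cohort, _ = t.normalize_cohort(tiny_cohort, 10_000, seed=3)
        ref = t.generate_reference(6_000, seed=4)
        a = t.build_gliph_groups(cohort, ref, cfg)
        b = t.build_gliph_groups(list(reversed(cohort)), ref, cfg)
        assert [(g.group_id, g.members) for g in a] == [
            (g.group_id, g.members) for g in b
        ]

    def test_spiked_panel_recovered_with_broad_sample_support(self):
        cfg = t.CohortConfig(
            n_per_group={"GVHD": 10},
            richness={"GVHD": 400},
            total_reads=30_000,
            motif_spike_fraction=0.05,
            planted_cdr3s=(),
            seed=21,
        )
        cohort, _ = t.normalize_cohort(t.generate_cohort(cfg), 25_000, seed=21)
        ref = t.generate_reference(10_000, seed=22)
        gcfg = GliphConfig(simulation_depth=200, seed=21)
        groups = t.build_gliph_groups(cohort, ref, gcfg)
        by_sig = {g.signature: g for g in groups if g.kind == "local"}
        for motif in cfg.motif_panel:
            assert motif in by_sig
            assert len(by_sig[motif].sample_ids) >= 9
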