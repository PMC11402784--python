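"""k-mer enrichment, the combined clustering distance, motif-group
recovery and the positional motif/PAS analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from utrdecay import motifs
from utrdecay.core import CrosslinkTrack
from utrdecay.motifs import MotifGroup
from utrdecay.simulate import KMER_FAMILIES, make_kmer_family_ranks


class TestSubstringJaccard:
    def test_substring_set_of_uga(self):
        assert motifs.substring_set("UGA") == {"U", "G", "A", "UG", "GA"}

    def test_hand_enumerated_distance_uga_ugg(self):
        # {U,G,A,UG,GA} vs {U,G,UG,GG}: 3 shared, 6 in union
        assert motifs.substring_jaccard_distance("UGA", "UGG") == pytest.approx(0.5)

    def test_identity_is_zero(self):
        for km in ("UGA", "AUUAU", "GGGGG"):
            assert motifs.substring_jaccard_distance(km, km) == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            motifs.substring_jaccard_distance("UGA", "UGAA")

    def test_empty_kmer_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motifs.substring_set("")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(3, 7), st.data())
    def test_metric_properties_on_random_pairs(self, k, data):
        bases = "ACGU"
        a = "".join(data.draw(st.sampled_from(bases)) for _ in range(k))
        b = "".join(data.draw(st.sampled_from(bases)) for _ in range(k))
        d_ab = motifs.substring_jaccard_distance(a, b)
        d_ba = motifs.substring_jaccard_distance(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
        if a == b:
            assert d_ab == 0.0


class TestCombineDistances:
    def test_pythagorean_combination(self):
        # scaled entries 0.6 / 0.8 combine to 1.0 (3-4-5 triangle)
        a = np.array([[0, 1, 0.6], [1, 0, 1], [0.6, 1, 0]])
        b = np.array([[0, 1, 0.8], [1, 0, 1], [0.8, 1, 0]])
        sa, sb = motifs._scale(a), motifs._scale(b)
        combined = motifs.combine_distances(a, b)
        assert np.allclose(combined, np.sqrt(sa ** 2 + sb ** 2))
        assert np.allclose(np.diag(combined), 0)
        assert np.allclose(combined, combined.T)

    def test_identical_kmer_pair_stays_zero(self):
        a = np.array([[0.0, 2.0], [2.0, 0.0]])
        combined = motifs.combine_distances(a, a)
        assert combined[0, 0] == 0.0 and combined[1, 1] == 0.0

    def test_all_zero_matrix_passes_through_other(self):
        a = np.zeros((3, 3))
        b = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        combined = motifs.combine_distances(a, b)
        assert np.allclose(combined, motifs._scale(b))

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            motifs.combine_distances(bad, np.zeros((2, 2)))


class TestClusterKmers:
    def test_duplicated_kmers_cluster_together(self):
        kmers = ["AUUAU", "AUUAU", "GGGAG", "GAUGA"]
        jac = motifs.jaccard_matrix(kmers)
        rank = motifs.rank_distance_matrix(np.array([1, 2, 50, 90]))
        combined = motifs.combine_distances(rank, jac)
        groups = motifs.cluster_kmers(combined, kmers, n_clusters=3)
        by_kmer = {k: g.name for g in groups for k in g.kmers}
        assert len(by_kmer) == 3  # duplicate collapses into one group

    def test_two_planted_families_recovered_by_two_cut(self):
        """UPGMA 2-cut matches the brute-force best 2-partition."""
        kmers = ["AUUAU", "UUAUU", "UAUUA", "GGGAG", "AGGGA", "GGGUG"]
        ranks = np.array([1.0, 2, 3, 40, 41, 42])
        combined = motifs.combine_distances(motifs.rank_distance_matrix(ranks),
                                            motifs.jaccard_matrix(kmers))
        groups = motifs.cluster_kmers(combined, kmers, n_clusters=2)
        parts = {frozenset(g.kmers) for g in groups}
        assert parts == {frozenset(kmers[:3]), frozenset(kmers[3:])}

        # oracle: minimize summed within-group combined distance over all
        # 2-partitions into non-empty sets
        best, best_cost = None, np.inf
        for mask in range(1, 2 ** 6 - 1):
            sets = [[i for i in range(6) if (mask >> i) & 1],
                    [i for i in range(6) if not (mask >> i) & 1]]
            cost = sum(combined[i, j] for grp in sets
                       for i, j in itertools.combinations(grp, 2))
            if cost < best_cost:
                best_cost, best = cost, {frozenset(kmers[i] for i in grp)
                                         for grp in sets}
        assert parts == best

    def test_n_clusters_equals_n_kmers_gives_singletons(self):
        kmers = ["AUUAU", "GGGAG", "GAUGA", "CCCCC"]
        combined = motifs.combine_distances(
            motifs.rank_distance_matrix(np.arange(4.0) * 10),
            motifs.jaccard_matrix(kmers))
        groups = motifs.cluster_kmers(combined, kmers, n_clusters=4)
        assert sorted(len(g.kmers) for g in groups) == [1, 1, 1, 1]

    def test_order_invariance_of_clustering(self):
        df = make_kmer_family_ranks(seed=0)
        kmers = list(df["kmer"])
        rng = np.random.default_rng(1)
        reference = None
        for _ in range(20):
            perm = rng.permutation(len(kmers))
            km = [kmers[i] for i in perm]
            ranks = df["rank"].to_numpy()[perm]
            combined = motifs.combine_distances(
                motifs.rank_distance_matrix(ranks), motifs.jaccard_matrix(km))
            groups = motifs.cluster_kmers(combined, km, n_clusters=3)
            parts = frozenset(frozenset(g.kmers) for g in groups)
            reference = reference or parts
            assert parts == reference

    def test_three_family_recovery_rate_over_seeds(self):
        hits = 0
        for seed in range(20):
            df = make_kmer_family_ranks(seed=seed)
            kmers = list(df["kmer"])
            combined = motifs.combine_distances(
                motifs.rank_distance_matrix(df["rank"].to_numpy()),
                motifs.jaccard_matrix(kmers))
            groups = motifs.cluster_kmers(combined, kmers, n_clusters=3)
            found = frozenset(frozenset(g.kmers) for g in groups)
            want = frozenset(frozenset(v) for v in KMER_FAMILIES.values())
            hits += found == want
        assert hits >= 18  # >= 90% of seeds

    def test_group_union_and_disjointness(self):
        df = make_kmer_family_ranks(seed=3)
        kmers = list(df["kmer"])
        combined = motifs.combine_distances(
            motifs.rank_distance_matrix(df["rank"].to_numpy()),
            motifs.jaccard_matrix(kmers))
        groups = motifs.cluster_kmers(combined, kmers, n_clusters=4)
        members = [k for g in groups for k in g.kmers]
        assert sorted(members) == sorted(kmers)


class TestEnrichment:
    def test_planted_kmer_ranks_first(self):
        # every cross-link sits on a planted AUUAA occurrence
        rng = np.random.default_rng(0)
        seqs, track = {}, CrosslinkTrack("toy")
        for i in range(30):
            seq = list(rng.choice(list("ACGT"), 200))
            vec = np.zeros(200, dtype=int)
            for start in (50, 120):
                seq[start : start + 5] = list("ATTAA")
                vec[start] = 3
            seqs[f"g{i}"] = "".join(seq)
            track.set_gene(f"g{i}", vec)
        stats = motifs.kmer_enrichment(track, seqs, n_shuffle=30, seed=1)
        assert stats.table.iloc[0]["kmer"] == "AUUAA"
        assert 0 in stats.relevant_positions["AUUAA"]

    def test_null_track_is_calibrated(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            seqs, track = {}, CrosslinkTrack("null")
            for i in range(40):
                seqs[f"g{i}"] = "".join(rng.choice(list("ACGT"), 300))
                vec = np.zeros(300, dtype=int)
                vec[rng.integers(0, 300, size=4)] = 1
                track.set_gene(f"g{i}", vec)
            stats = motifs.kmer_enrichment(track, seqs, n_shuffle=100, seed=seed)
            hits += stats.table["p"].min() >= 0.001
        assert hits >= 9

    def test_absent_kmer_scores_zero(self):
        seqs = {"g0": "ACGT" * 50}
        track = CrosslinkTrack("t")
        vec = np.zeros(200, dtype=int)
        vec[100] = 5
        track.set_gene("g0", vec)
        with pytest.warns(UserWarning, match="widening"):
            stats = motifs.kmer_enrichment(track, seqs, n_shuffle=20, seed=0)
        row = stats.table.set_index("kmer").loc["UUUUU"]
        assert row["score"] == 0.0 and row["p"] == 1.0


class TestCoverage:
    def test_single_crosslink_full_coverage_at_kmer_offsets(self):
        seq = "A" * 100
        seq = seq[:55] + "GTGTG" + seq[60:]
        track = CrosslinkTrack("t")
        vec = np.zeros(100, dtype=int)
        vec[50] = 1
        track.set_gene("g", vec)
        group = MotifGroup("other", ["GUGUG"])
        prof = motifs.motif_coverage_around_crosslinks(
            track, {"g": seq}, group, half_window=20, smooth_window=1)
        prof = prof.set_index("offset")
        for off in range(5, 10):
            assert prof.loc[off, "pct"] == 100.0
        assert prof.loc[4, "pct"] == 0.0 and prof.loc[10, "pct"] == 0.0

    def test_no_group_kmers_gives_zero_profile(self):
        track = CrosslinkTrack("t")
        vec = np.zeros(60, dtype=int)
        vec[30] = 2
        track.set_gene("g", vec)
        prof = motifs.motif_coverage_around_crosslinks(
            track, {"g": "A" * 60}, MotifGroup("other", ["GGGGG"]),
            half_window=10)
        assert (prof["pct"] == 0).all()

    def test_cdna_cap_equalizes_deep_sites(self):
        seq = "C" * 30 + "ATTAT" + "C" * 30
        group = MotifGroup("AUU", ["AUUAU"])
        profiles = []
        for count in (100, 20):
            track = CrosslinkTrack("t")
            vec = np.zeros(len(seq), dtype=int)
            vec[30] = count
            track.set_gene("g", vec)
            profiles.append(motifs.motif_coverage_around_crosslinks(
                track, {"g": seq}, group, half_window=10)["pct"].to_numpy())
        assert np.allclose(profiles[0], profiles[1])

    def test_empty_group_rejected(self):
        track = CrosslinkTrack("t")
        track.set_gene("g", np.array([0, 1, 0]))
        with pytest.raises(ValueError, match="empty"):
            motifs.motif_coverage_around_crosslinks(track, {"g": "ACG"},
                                                    MotifGroup("x", []))

    def test_region_coverage_hand_overlay(self):
        # AUUAU windows at offsets 0 and 3 cover nucleotides 0..7 = 8 of 10
        seqs = {"g": "ATTATTATTT"}
        group = MotifGroup("AUU", ["AUUAU"])
        cov = motifs.motif_region_coverage(seqs, group, [("g", 0, 10)], bin_nt=10)
        assert cov.shape == (1,)
        assert cov[0] == pytest.approx(80.0)
        # adding the shifted UUAUU member extends coverage to 9 of 10
        group2 = MotifGroup("AUU", ["AUUAU", "UUAUU"])
        cov2 = motifs.motif_region_coverage(seqs, group2, [("g", 0, 10)], bin_nt=10)
        assert cov2[0] == pytest.approx(90.0)

    def test_region_coverage_single_full_kmer(self):
        seqs = {"g": "GTGTG"}
        cov = motifs.motif_region_coverage(seqs, MotifGroup("x", ["GUGUG"]),
                                           [("g", 0, 5)], bin_nt=10)
        assert cov[0] == pytest.approx(100.0)

    def test_region_coverage_no_match_zero(self):
        seqs = {"g": "A" * 25}
        cov = motifs.motif_region_coverage(seqs, MotifGroup("x", ["GGGGG"]),
                                           [("g", 0, 25)], bin_nt=10)
        assert np.allclose(cov, 0.0)


class TestPasAnchoring:
    def test_rightmost_valid_pas_wins(self):
        seq = "C" * 10 + "AATAAA" + "C" * 30 + "AATAAA" + "C" * 25
        assert motifs.locate_terminal_pas(seq) == 46

    def test_pas_too_close_to_end_is_invalid(self):
        seq = "C" * 40 + "AATAAA" + "C" * 10
        assert motifs.locate_terminal_pas(seq) is None

    def test_no_match_returns_none(self):
        assert motifs.locate_terminal_pas("C" * 60) is None

    def test_trimer_valency_hand_count(self):
        seq = "ATTATTATTT" + "C" * 86 + "AATAAA" + "C" * 25
        counts, excluded = motifs.trimer_valency({"g": seq}, "AUU", window=100)
        assert counts["g"] == 3
        assert excluded == []

    def test_trimer_valency_absent_trimer(self):
        seq = "A" * 100 + "AATAAA" + "C" * 25
        counts, _ = motifs.trimer_valency({"g": seq}, "AUU")
        assert counts["g"] == 0

    def test_trimer_valency_reports_missing_pas(self):
        counts, excluded = motifs.trimer_valency({"g": "C" * 130}, "AUU")
        assert excluded == ["g"] and counts == {}

    def test_down_class_valency_exceeds_control(self, small_world):
        seqs = {r.gene_id: r.sequence for r in small_world["records"]}
        counts, _ = motifs.trimer_valency(seqs, "AUU")
        truth = small_world["truth"]
        down = [counts[g] for g in counts if truth.classes[g] == "down"]
        ctrl = [counts[g] for g in counts if truth.classes[g] == "control"]
        assert np.median(down) > np.median(ctrl)


class TestBindingSites:
    def _track(self, length, positions):
        track = CrosslinkTrack("m")
        vec = np.zeros(length, dtype=int)
        for p, c in positions:
            vec[p] = c
        track.set_gene("g", vec)
        return track

    def test_kmer_at_relevant_offset_emits_site(self):
        seq = "C" * 33 + "ATTAT" + "C" * 30
        track = self._track(len(seq), [(30, 4)])
        sites = motifs.assign_binding_sites(
            track, {"g": seq}, MotifGroup("AUU", ["AUUAU"]), {"AUUAU": [3]})
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (33, 38)
        assert sites[0].support == 4

    def test_kmer_outside_flank_ignored(self):
        seq = "C" * 30 + "ATTAT" + "C" * 30
        track = self._track(len(seq), [(4, 2)])  # offset +26 > 20
        sites = motifs.assign_binding_sites(
            track, {"g": seq}, MotifGroup("AUU", ["AUUAU"]), {"AUUAU": [26]})
        assert sites == []

    def test_shared_kmer_merges_sites_and_sums_counts(self):
        seq = "C" * 36 + "ATTAT" + "C" * 30
        track = self._track(len(seq), [(30, 2), (34, 3)])
        sites = motifs.assign_binding_sites(
            track, {"g": seq}, MotifGroup("AUU", ["AUUAU"]),
            {"AUUAU": [2, 6]})
        assert len(sites) == 1
        assert sites[0].support == 5


class TestPeaks:
    def test_book_ended_peaks_merge(self):
        merged = motifs.merge_peaks([("g", 10, 20), ("g", 20, 30)])
        assert merged == [("g", 10, 30)]

    def test_one_nt_overlap_classifies_as_overlapping(self):
        _, _, flags = motifs.merge_and_overlap_peaks([("g", 10, 20)],
                                                     [("g", 19, 25)])
        assert flags == [True]

    def test_book_ended_across_sets_not_overlapping(self):
        _, _, flags = motifs.merge_and_overlap_peaks([("g", 10, 20)],
                                                     [("g", 20, 30)])
        assert flags == [False]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="start > end"):
            motifs.merge_peaks([("g", 5, 3)])


class TestNucleotideComposition:
    def test_all_a_background_is_100_percent_a(self):
        seq = "A" * 120 + "AATAAA" + "A" * 25
        comp = motifs.nucleotide_composition_around_pas({"g": seq})
        outside_t = comp["offset"] != 2  # the PAS hexamer's own T
        assert np.allclose(comp.loc[outside_t, "A"], 100.0)
        assert np.allclose(comp["C"], 0.0)

    def test_two_sequences_split_50_50(self):
        s1 = "A" * 120 + "AATAAA" + "C" * 25
        s2 = "T" * 120 + "AATAAA" + "C" * 25
        comp = motifs.nucleotide_composition_around_pas({"g1": s1, "g2": s2})
        row = comp.set_index("offset").loc[-10]
        assert row["A"] == 50.0 and row["T"] == 50.0

    def test_columns_sum_to_100_pre_smoothing(self):
        rng = np.random.default_rng(0)
        seqs = {}
        for i in range(10):
            s = "".join(rng.choice(list("ACGT"), 130)).replace("AATAAA", "AATCAA")
            seqs[f"g{i}"] = s[:100] + "AATAAA" + s[106:]
        comp = motifs.nucleotide_composition_around_pas(seqs)
        totals = comp[["A", "C", "G", "T"]].sum(axis=1)
        assert np.allclose(totals, 100.0, atol=1e-9)

    def test_no_valid_sequences_rejected(self):
        with pytest.raises(ValueError, match="valid terminal PAS"):
            motifs.nucleotide_composition_around_pas({"g": "C" * 200})
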