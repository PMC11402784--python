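"""Coverage normalization, smoothing and every positional summary,
checked against naive per-position recomputation where it matters."""

import numpy as np
import pandas as pd
import pytest

from utrdecay import clip
from utrdecay.core import CrosslinkTrack, UtrRecord


def naive_triangular_smooth(values, window):
    """Explicit-loop triangular rolling mean with nearest-valid edge fill."""
    n = len(values)
    # symmetric triangular weights 1,3,5,...,5,3,1 (even window)
    kernel = [2 * min(j, window - 1 - j) + 1 for j in range(window)]
    total = float(sum(kernel))
    start = (window - 1) // 2
    core = [sum(k * values[i + j] for j, k in enumerate(kernel)) / total
            for i in range(n - window + 1)]
    out = []
    for pos in range(n):
        idx = min(max(pos - start, 0), len(core) - 1)
        out.append(core[idx])
    return np.array(out)


def naive_metaprofile_mean(track, records, expr, span, window):
    """Per-position brute-force recomputation: normalize, window, smooth,
    average — all with plain loops."""
    lib = track.library_size
    rows = []
    for rec in records:
        counts = track.get(rec.gene_id, rec.width)
        win = []
        for off in range(span[0], span[1]):
            pos = rec.pas_position + off
            if 0 <= pos < rec.width:
                win.append(counts[pos] * 1e6 / lib / expr[rec.gene_id])
            else:
                win.append(np.nan)
        valid = [i for i, v in enumerate(win) if not np.isnan(v)]
        seg = [win[i] for i in valid]
        if len(seg) >= window:
            sm = naive_triangular_smooth(seg, window)
            for i, v in zip(valid, sm):
                win[i] = v
        rows.append(win)
    mat = np.array(rows, dtype=float)
    return np.nanmean(mat, axis=0)


class TestGeneLevelTpm:
    def test_sum_within_gene_then_mean_over_replicates(self):
        rep = pd.DataFrame({"transcript_id": ["t1", "t2"],
                            "gene_id": ["g", "g"], "tpm": [3.0, 7.0]})
        out = clip.gene_level_tpm([rep, rep.copy()])
        assert out["g"] == 10.0

    def test_mean_over_distinct_replicates(self):
        reps = [pd.DataFrame({"transcript_id": ["t"], "gene_id": ["g"],
                              "tpm": [v]}) for v in (8.0, 12.0)]
        assert clip.gene_level_tpm(reps)["g"] == 10.0

    def test_transcript_without_gene_excluded_with_warning(self):
        rep = pd.DataFrame({"transcript_id": ["t1", "t2"],
                            "gene_id": ["g", None], "tpm": [3.0, 7.0]})
        with pytest.warns(UserWarning, match="without"):
            out = clip.gene_level_tpm([rep])
        assert list(out.index) == ["g"]


class TestNormalizeCoverage:
    def _one_gene(self, count, lib_pad, tpm, length=100):
        rec = UtrRecord("g", "A" * length)
        track = CrosslinkTrack("s")
        vec = np.zeros(length, dtype=int)
        vec[10] = count
        track.set_gene("g", vec)
        if lib_pad:
            track.set_gene("pad", np.array([lib_pad]))
        return rec, track, {"g": tpm}

    def test_cpm_per_tpm_arithmetic(self):
        rec, track, expr = self._one_gene(5, 499_995, 5.0)
        norm = clip.normalize_coverage(track, [rec], expr)
        assert norm["g"][10] == pytest.approx(2.0)  # 10 CPM / 5 TPM

    def test_doubling_library_halves_values(self):
        rec, t1, expr = self._one_gene(5, 499_995, 5.0)
        _, t2, _ = self._one_gene(5, 999_995, 5.0)
        n1 = clip.normalize_coverage(t1, [rec], expr)["g"]
        n2 = clip.normalize_coverage(t2, [rec], expr)["g"]
        assert np.allclose(n1, 2 * n2)

    def test_zero_tpm_region_dropped(self):
        rec, track, _ = self._one_gene(5, 100, 5.0)
        with pytest.warns(UserWarning, match="dropped"):
            norm = clip.normalize_coverage(track, [rec], {"g": 0.0})
        assert "g" not in norm

    def test_tpm_scaling_is_exactly_inverse(self):
        rec, track, _ = self._one_gene(7, 1000, 1.0)
        n1 = clip.normalize_coverage(track, [rec], {"g": 2.0})["g"]
        n3 = clip.normalize_coverage(track, [rec], {"g": 6.0})["g"]
        assert np.allclose(n1, 3.0 * n3)

    def test_cpm_conservation(self, small_world):
        track = small_world["tracks"]["naive"]
        cpm_total = sum((v * 1e6 / track.library_size).sum()
                        for v in track.counts.values())
        assert cpm_total == pytest.approx(1e6, abs=1e-6)


class TestSmoothing:
    def test_constant_input_unchanged(self):
        v = np.ones(50)
        assert np.allclose(clip.smooth_profile(v, 20), 1.0)

    def test_kernel_mass_conserved_for_interior_impulse(self):
        v = np.zeros(101)
        v[50] = 1.0
        sm = clip.smooth_profile(v, 21)
        assert sm.sum() == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(sm[50 - 10 : 50 + 11][::-1], sm[50 - 10 : 50 + 11])

    def test_window_one_is_identity(self):
        v = np.arange(10.0)
        assert np.allclose(clip.smooth_profile(v, 1), v)

    def test_oversized_window_warns_and_passes_through(self):
        v = np.arange(5.0)
        with pytest.warns(UserWarning, match="exceeds"):
            out = clip.smooth_profile(v, 10)
        assert np.allclose(out, v)


class TestMetaprofile:
    def test_single_region_mean_equals_profile_and_zero_ci(self, three_gene_fixture):
        records, track, expr = three_gene_fixture
        rec = records[:1]
        prof = clip.metaprofile(track, rec, clip.pas_anchors(rec), (-50, 10),
                                expr, n_boot=200, seed=0)
        assert prof.n_regions == 1
        assert np.allclose(prof.mean, prof.region_matrix[0], equal_nan=True)
        assert np.allclose(prof.ci_lo, prof.ci_hi, equal_nan=True)

    def test_two_disjoint_half_signals_average_elementwise(self):
        recs = [UtrRecord("g1", "C" * 100), UtrRecord("g2", "C" * 100)]
        track = CrosslinkTrack("s")
        v1, v2 = np.zeros(100, dtype=int), np.zeros(100, dtype=int)
        v1[:50], v2[50:] = 4, 4
        track.set_gene("g1", v1)
        track.set_gene("g2", v2)
        expr = {"g1": 1.0, "g2": 1.0}
        anchors = {"g1": 50, "g2": 50}
        prof = clip.metaprofile(track, recs, anchors, (-50, 50), expr,
                                smooth_window=1, n_boot=10, seed=0)
        per_region = prof.region_matrix
        assert np.allclose(prof.mean, np.nanmean(per_region, axis=0))
        assert np.allclose(prof.mean, prof.mean[0])  # flat at half the signal

    def test_matches_naive_per_position_oracle(self, three_gene_fixture):
        records, track, expr = three_gene_fixture
        span = (-80, 20)
        prof = clip.metaprofile(track, records, clip.pas_anchors(records),
                                span, expr, smooth_window=20, n_boot=10, seed=0)
        oracle = naive_metaprofile_mean(track, records, expr, span, window=20)
        assert np.allclose(prof.mean, oracle, atol=1e-9, equal_nan=True)

    def test_bootstrap_ci_reproducible_and_contains_mean(self, three_gene_fixture):
        records, track, expr = three_gene_fixture
        args = (track, records, clip.pas_anchors(records), (-50, 0), expr)
        p1 = clip.metaprofile(*args, n_boot=300, seed=5)
        p2 = clip.metaprofile(*args, n_boot=300, seed=5)
        assert np.allclose(p1.ci_lo, p2.ci_lo, equal_nan=True)
        ok = ~np.isnan(p1.mean)
        assert (p1.ci_lo[ok] <= p1.mean[ok] + 1e-12).all()
        assert (p1.ci_hi[ok] >= p1.mean[ok] - 1e-12).all()

    def test_no_surviving_regions_rejected(self, three_gene_fixture):
        records, track, expr = three_gene_fixture
        with pytest.raises(ValueError, match="survive"):
            clip.metaprofile(track, records, clip.pas_anchors(records),
                             (-50, 0), expr, min_length=10_000)


class TestTranscriptBins:
    def test_hundred_nt_region_gives_unit_bins(self):
        assert np.array_equal(clip.bin_boundaries(100, 100), np.arange(101))

    def test_remainder_spread_over_leading_bins(self):
        edges = clip.bin_boundaries(103, 100)
        widths = np.diff(edges)
        assert widths.sum() == 103
        assert (widths[:3] == 2).all() and (widths[3:] == 1).all()

    def test_uniform_signal_gives_flat_bins(self):
        rec = UtrRecord("g", "C" * 250)
        track = CrosslinkTrack("s")
        track.set_gene("g", np.full(250, 2, dtype=int))
        out = clip.transcript_binned_metaprofile(
            track, {"g": {"utr3": (0, 250)}}, [rec], {"g": 1.0})
        vals = out["utr3"]["mean"].to_numpy()
        assert np.allclose(vals, vals[0])

    def test_signal_in_last_decile_lands_in_top_bins(self):
        rec = UtrRecord("g", "C" * 200)
        track = CrosslinkTrack("s")
        vec = np.zeros(200, dtype=int)
        vec[180:] = 5
        track.set_gene("g", vec)
        out = clip.transcript_binned_metaprofile(
            track, {"g": {"utr3": (0, 200)}}, [rec], {"g": 1.0})
        vals = out["utr3"]["mean"].to_numpy()
        assert vals[:90].sum() == 0
        assert vals[90:].sum() > 0

    def test_matches_naive_binning_oracle(self, three_gene_fixture):
        records, track, expr = three_gene_fixture
        regions = {r.gene_id: {"utr3": (0, r.width)} for r in records}
        out = clip.transcript_binned_metaprofile(track, regions, records, expr)
        lib = track.library_size
        oracle_rows = []
        for rec in records:
            vals = track.get(rec.gene_id, rec.width) * 1e6 / lib / expr[rec.gene_id]
            edges = clip.bin_boundaries(rec.width, 100)
            row = np.array([vals[a:b].sum() / (b - a)
                            for a, b in zip(edges[:-1], edges[1:])])
            oracle_rows.append(row)
        oracle = np.vstack(oracle_rows).mean(axis=0)
        assert np.allclose(out["utr3"]["mean"].to_numpy(), oracle, atol=1e-9)

    def test_short_region_flagged(self):
        rec = UtrRecord("g", "C" * 40)
        track = CrosslinkTrack("s")
        track.set_gene("g", np.ones(40, dtype=int))
        with pytest.warns(UserWarning, match="repeated boundaries"):
            clip.transcript_binned_metaprofile(track,
                                               {"g": {"utr3": (0, 40)}},
                                               [rec], {"g": 1.0})


class TestHeatmap:
    def _single_row(self, counts, window=1, tpm=2.0):
        rec = UtrRecord("g", "C" * len(counts))
        track = CrosslinkTrack("s")
        track.set_gene("g", np.asarray(counts, dtype=int))
        return clip.per_utr_heatmap(track, [rec], {"g": tpm}, window=window)

    def test_min_max_scaling(self):
        out = self._single_row([2, 4, 6])
        assert np.allclose(out["matrix"][0], [0.0, 0.5, 1.0])

    def test_all_zero_row_stays_zero(self):
        out = self._single_row([0, 0, 0])
        assert np.allclose(out["matrix"][0], 0.0)

    def test_constant_nonzero_row_maps_to_zero(self):
        out = self._single_row([3, 3, 3])
        assert np.allclose(out["matrix"][0], 0.0)

    def test_abundance_column_normalization(self):
        out = self._single_row([2, 4, 6], tpm=2.0)
        # total CPM = 1e6; length 3; TPM 2 -> 1e6 / 6
        assert out["abundance"][0] == pytest.approx(1e6 / 6)


class TestBinnedLog2FC:
    def _tracks(self, a, b):
        rec = UtrRecord("g", "C" * len(a))
        ta, tb = CrosslinkTrack("a"), CrosslinkTrack("b")
        ta.set_gene("g", np.asarray(a, dtype=int))
        tb.set_gene("g", np.asarray(b, dtype=int))
        return rec, ta, tb

    def test_identical_tracks_give_zero(self):
        a = np.tile([1, 0, 2, 0], 25)
        rec, ta, tb = self._tracks(a, a)
        out = clip.binned_log2fc(ta, tb, [rec], bin_nt=20, span=100)
        assert np.allclose(out["log2fc"], 0.0)

    def test_empty_bins_in_both_give_zero(self):
        a = np.zeros(100, dtype=int)
        a[0] = 10
        rec, ta, tb = self._tracks(a, a)
        out = clip.binned_log2fc(ta, tb, [rec], bin_nt=20, span=100)
        assert np.allclose(out["log2fc"], 0.0)

    def test_percentage_arithmetic(self):
        # bin percentages 1 vs 3 -> log2(4/2) = 1
        a = np.zeros(100, dtype=int)
        b = np.zeros(100, dtype=int)
        a[10], a[30] = 1, 99
        b[10], b[30] = 3, 97
        rec, ta, tb = self._tracks(a, b)
        out = clip.binned_log2fc(ta, tb, [rec], bin_nt=20, span=100)
        assert out.loc[out["bin"] == 0, "log2fc"].iloc[0] == pytest.approx(1.0)

    def test_short_region_skipped(self):
        rec, ta, tb = self._tracks(np.ones(80, dtype=int), np.ones(80, dtype=int))
        out = clip.binned_log2fc(ta, tb, [rec], bin_nt=20, span=100)
        assert out.empty


class TestTerminalAbundance:
    def _record(self, gene, length, cls="control"):
        return UtrRecord(gene, "C" * length, regulation_class=cls)

    def test_engineered_fixture_keeps_exactly_two(self):
        # five UTRs: too short / low TPM / too few cDNAs / two survivors
        records = [self._record("short", 700),
                   self._record("lowtpm", 900),
                   self._record("sparse", 900),
                   self._record("ok1", 900, "down"),
                   self._record("ok2", 1000, "down")]
        track = CrosslinkTrack("s")
        for rec in records:
            vec = np.zeros(rec.width, dtype=int)
            if rec.gene_id == "sparse":
                vec[:300] = 0
                vec[0] = 4          # start window: only 4 cDNAs
                vec[-300:] = 1
            else:
                vec[:300] = 1
                vec[-300:] = 2
            track.set_gene(rec.gene_id, vec)
        expr = {"short": 5.0, "lowtpm": 0.5, "sparse": 5.0,
                "ok1": 5.0, "ok2": 8.0}
        table, tally = clip.terminal_abundance([track], records, expr)
        assert tally == {"length": 1, "expression": 1, "min_cdnas": 1, "kept": 2}
        assert sorted(table["gene_id"]) == ["ok1", "ok2"]

    def test_terminal_exceeds_start_when_signal_terminal(self):
        rec = self._record("g", 1000)
        track = CrosslinkTrack("s")
        vec = np.zeros(1000, dtype=int)
        vec[:300] = 1
        vec[-300:] = 3
        track.set_gene("g", vec)
        table, _ = clip.terminal_abundance([track], [rec], {"g": 2.0})
        row = table.iloc[0]
        assert row["terminal_window"] == pytest.approx(3 * row["start_window"])
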