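import numpy as np
import pandas as pd
import pytest

from larkszip.io import ProteinRecord, VariantRecord
from larkszip.screen import (ScreenConfig, SequenceWindow, apply_mutation,
                             compare_pathogenic_benign, extract_window,
                             map_variants_to_larks, mutation_heatmap,
                             residue_context_enrichment, run_screen,
                             scan_larks, score_zipper_pair, select_pair,
                             LarksCall, ZipperScorePair)


class TestWindows:
    def test_krt8_58_64_reads_sgmggit(self, krt8):
        assert extract_window(krt8, 58, 64).sequence == "SGMGGIT"

    def test_krt8_52_58_reads_ggyggas(self, krt8):
        assert extract_window(krt8, 52, 58).sequence == "GGYGGAS"

    def test_window_before_offset_rejected(self, krt8):
        with pytest.raises(IndexError, match="2..90"):
            extract_window(krt8, 1, 7)

    def test_g62c_gives_sgmgcit(self, krt8, fixtures):
        w = extract_window(krt8, 58, 64)
        g62c = next(v for v in fixtures.variants if v.label == "KRT8:G62C")
        assert apply_mutation(w, g62c).sequence == "SGMGCIT"

    def test_g55a_gives_ggyagas(self, krt8, fixtures):
        w = extract_window(krt8, 52, 58)
        g55a = next(v for v in fixtures.variants if v.label == "KRT8:G55A")
        assert apply_mutation(w, g55a).sequence == "GGYAGAS"

    def test_wild_type_mismatch_is_a_consistency_error(self, krt8):
        w = extract_window(krt8, 58, 64)
        bad = VariantRecord("KRT8", 62, "A", "C", "pathogenic", "x")
        with pytest.raises(ValueError, match="mismatch"):
            apply_mutation(w, bad)


class TestScan:
    def test_window_count_is_length_minus_k_plus_one(self, krt8_core, templates, config):
        calls = scan_larks(krt8_core, list(templates.values()), config)
        assert len(calls) == len(krt8_core) - config.k + 1

    def test_krt8_core_has_accepted_windows_in_52_59(self, krt8_core, templates, config):
        calls = scan_larks(krt8_core, list(templates.values()), config)
        accepted_starts = [c.window.start for c in calls if c.accepted]
        assert any(52 <= s <= 59 for s in accepted_starts)

    def test_acceptance_flag_matches_threshold(self, krt8_core, templates, config):
        for c in scan_larks(krt8_core, list(templates.values()), config):
            assert c.accepted == (c.e_larks <= config.tau_L)

    def test_windows_with_x_are_skipped(self, templates, config):
        p = ProteinRecord("PX", "GGGGGXGGGGGG")
        calls = scan_larks(p, list(templates.values()), config)
        covered = {s for c in calls for s in range(c.window.start, c.window.end + 1)}
        assert 6 not in covered
        assert len(calls) == 1  # only the X-free suffix window survives


class TestVariantMapping:
    def _call(self, pid, start, end, accepted=True):
        w = SequenceWindow(pid, start, end, "G" * (end - start + 1))
        return LarksCall(window=w, best_template="t", e_larks=-1.0, accepted=accepted)

    def test_containment_semantics(self):
        v = VariantRecord("P", 62, "G", "C", "pathogenic", "x")
        calls = [self._call("P", 57, 62), self._call("P", 62, 67),
                 self._call("P", 63, 68), self._call("P", 50, 70, accepted=False)]
        matched, unmatched = map_variants_to_larks([v], calls)
        assert len(matched) == 1
        (_, hits), = matched
        assert [(c.window.start, c.window.end) for c in hits] == [(57, 62), (62, 67)]

    def test_unmatched_variants_counted(self):
        v = VariantRecord("P", 10, "G", "C", "benign", "x")
        matched, unmatched = map_variants_to_larks([v], [self._call("P", 20, 25)])
        assert not matched and unmatched == [v]

    def test_matching_invariant_to_call_order(self):
        v = VariantRecord("P", 5, "G", "A", "other", "x")
        calls = [self._call("P", 1, 6), self._call("P", 3, 8), self._call("P", 5, 10)]
        m1, _ = map_variants_to_larks([v], calls)
        m2, _ = map_variants_to_larks([v], calls[::-1])
        k1 = [(c.window.start, c.window.end) for c in m1[0][1]]
        k2 = [(c.window.start, c.window.end) for c in m2[0][1]]
        assert k1 == k2


class TestZipperPairs:
    def test_self_pair_delta_zero_not_converted(self, config):
        p = ZipperScorePair(
            variant=VariantRecord("P", 3, "G", "A", "other", "x"),
            wt_window=SequenceWindow("P", 1, 6, "GGGGGG"),
            mut_window=SequenceWindow("P", 1, 6, "GGGGGG"),
            e_zip_wt=-5.0, e_zip_mut=-5.0)
        assert p.delta == 0.0
        assert not (p.e_zip_mut <= config.tau_Z and p.delta <= config.delta_max)

    def test_g62c_register_improves_the_zipper(self, krt8, zipper, config, fixtures):
        g62c = next(v for v in fixtures.variants if v.label == "KRT8:G62C")
        w = extract_window(krt8, 59, 64)  # GMGGIT register
        pair = score_zipper_pair(g62c, w, zipper, config)
        assert pair.mut_window.sequence == "GMGCIT"
        assert pair.delta < 0
        assert pair.converted

    def test_argument_order_antisymmetry(self, krt8, zipper, config, fixtures):
        g62c = next(v for v in fixtures.variants if v.label == "KRT8:G62C")
        w = extract_window(krt8, 59, 64)
        pair = score_zipper_pair(g62c, w, zipper, config)
        # swapping wt and mut exactly flips the sign of delta
        reverse = pair.e_zip_wt - pair.e_zip_mut
        assert reverse == -pair.delta

    def test_selection_prefers_viable_min_delta(self, config):
        v = VariantRecord("P", 3, "G", "A", "other", "x")
        w = SequenceWindow("P", 1, 6, "GGGGGG")
        mk = lambda e_wt, e_mut: ZipperScorePair(v, w, w, e_wt, e_mut)
        viable_small = mk(0.0, -50.0)            # delta -50, viable
        clashing_better_delta = mk(5000.0, 4000.0)  # delta -1000, not viable
        assert select_pair([viable_small, clashing_better_delta], config) is viable_small
        # with no viable register, fall back to the lowest mutant energy
        assert select_pair([clashing_better_delta, mk(9000.0, 8000.0)],
                           config) is clashing_better_delta


class TestDescriptive:
    def test_heatmap_counts(self):
        vs = [VariantRecord("P", 1, "G", "V", "other", "x"),
              VariantRecord("P", 2, "G", "V", "other", "x"),
              VariantRecord("P", 3, "P", "L", "other", "x")]
        m = mutation_heatmap(vs)
        assert m.counts.loc["G", "V"] == 2
        assert m.counts.loc["P", "L"] == 1
        assert m.total == 3
        assert np.all(np.diag(m.counts.values) == 0)

    def test_empty_heatmap_is_zero(self):
        assert mutation_heatmap([]).total == 0

    def test_enrichment_arithmetic(self):
        vs = [VariantRecord("P", i, "G", "V", "other", "x") for i in range(1, 4)]
        bg = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        table = residue_context_enrichment(vs, bg)
        g_wt = table[(table.residue == "G") & (table.side == "wt")].iloc[0]
        assert g_wt.enrichment == pytest.approx(1.0 / 0.05)

    def test_enrichment_invariant_under_duplication(self):
        vs = [VariantRecord("P", 1, "G", "S", "other", "x"),
              VariantRecord("P", 2, "Y", "H", "other", "x")]
        bg = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        t1 = residue_context_enrichment(vs, bg)
        t2 = residue_context_enrichment(vs * 3, bg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_background_flagged(self):
        vs = [VariantRecord("P", 1, "G", "S", "other", "x")]
        table = residue_context_enrichment(vs, {"G": 0.0})
        g = table[(table.residue == "G") & (table.side == "wt")].iloc[0]
        assert g.undefined and np.isnan(g.enrichment)

    def test_identical_groups_have_zero_differences(self, config):
        v = VariantRecord("P", 3, "G", "A", "pathogenic", "x")
        w = SequenceWindow("P", 1, 6, "GGGGGG")
        pairs = [ZipperScorePair(v, w, w, -10.0, -60.0) for _ in range(4)]
        out = compare_pathogenic_benign(pairs, list(pairs))
        assert out["pathogenic"] == out["benign"]
        assert len(out["scatter"]) == 8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_pathogenic_benign([], [])


class TestRunScreen:
    def test_krt8_variants_all_matched_and_scored(self, krt8_core, fixtures, config):
        krt8_variants = [v for v in fixtures.variants if v.protein_id == "KRT8"]
        report = run_screen([krt8_core], krt8_variants, config)
        assert set(report.table.variant) == {"KRT8:Y54H", "KRT8:G55A", "KRT8:G62C"}
        assert (report.table.delta < 0).all()
        assert report.table.converted.all()
        assert len(report.rejected) == 0

    def test_repeat_run_is_byte_identical(self, krt8_core, fixtures, config):
        krt8_variants = [v for v in fixtures.variants if v.protein_id == "KRT8"][:1]
        r1 = run_screen([krt8_core], krt8_variants, config)
        r2 = run_screen([krt8_core], krt8_variants, config)
        assert r1.to_json() == r2.to_json()

    def test_impossible_threshold_gives_empty_report(self, krt8_core, fixtures, config):
        from dataclasses import replace
        cfg = replace(config, tau_L=-np.inf)
        report = run_screen([krt8_core], fixtures.variants[:3], cfg)
        assert report.table.empty

    def test_wild_type_mismatches_are_quarantined(self, krt8_core, config):
        bad = VariantRecord("KRT8", 62, "A", "C", "pathogenic", "x")
        off_range = VariantRecord("KRT8", 500, "G", "C", "pathogenic", "x")
        report = run_screen([krt8_core], [bad, off_range], config)
        assert len(report.rejected) == 2
        assert report.table.empty
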