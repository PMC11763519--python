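import math

import numpy as np
import pytest

from orsite import (
    AlignmentSet,
    FamilySpec,
    ScreenConfig,
    Site,
    SitePanel,
    canonical_matrix,
    gen_family,
    mean_pairwise_distance,
    permutation_null,
    results_frame,
    screen_sites,
    site_pairwise_distances,
)

from ._bruteforce import brute_force_site


def small_family(seed, n_seq=5, length=5, gap_rate=0.15):
    aln, truth = gen_family(
        FamilySpec(
            n_background=n_seq - 2, n_foreground=2, length=length,
            planted_sites=(), gap_rate=gap_rate, seed=seed,
        )
    )
    return aln, truth


class TestSitePairwiseDistances:
    def test_identical_column_gives_zero_distances(self):
        d = site_pairwise_distances(["L", "L", "L"])
        assert list(d) == [0.0, 0.0, 0.0] and d.mean() == 0.0

    def test_mixed_column_enumerates_all_pairs(self):
        d = site_pairwise_distances(["L", "I", "L"])
        assert sorted(d) == [0.0, 5.0, 5.0]
        assert d.mean() == pytest.approx(10 / 3)

    def test_degenerate_inputs_give_empty(self):
        assert site_pairwise_distances(["L"]).size == 0
        assert site_pairwise_distances([]).size == 0
        assert math.isnan(mean_pairwise_distance(["L"]))

    def test_accepts_counter_multiset(self, toy_alignment):
        from orsite import extract_column

        prof = extract_column(toy_alignment, 2, ["REF", "A1", "A2"])
        d = site_pairwise_distances(prof.counts)
        assert d.size == 3


class TestScreenAgainstBruteForce:
    def test_means_and_pair_counts_match_literal_enumeration(self, rng):
        for _ in range(10):
            seed = int(rng.integers(2**31))
            aln, truth = small_family(seed)
            seqs = dict(zip(aln.ids, aln.sequences))
            panel = SitePanel([Site(p) for p in range(1, aln.width + 1)])
            fg = list(truth.foreground_ids)
            res = screen_sites(aln, panel, "REF", fg, None, ScreenConfig(seed=seed))
            for r in res:
                fg_mean, n_fg_pairs, _ = brute_force_site(seqs, r.column, fg)
                bg_mean, n_bg_pairs, _ = brute_force_site(seqs, r.column, aln.ids)
                assert r.n_fg_pairs == n_fg_pairs and r.n_bg_pairs == n_bg_pairs
                if fg_mean is None:
                    assert math.isnan(r.fg_mean)
                else:
                    assert r.fg_mean == pytest.approx(fg_mean)
                assert r.bg_mean == pytest.approx(bg_mean)


class TestScreenBehavior:
    def test_results_invariant_to_record_order_and_relabeling(self):
        aln, truth = small_family(99, n_seq=8, length=6)
        panel = SitePanel([Site(p) for p in (1, 3, 5)])
        fg = list(truth.foreground_ids)
        base = screen_sites(aln, panel, "REF", fg, None, ScreenConfig(seed=1))

        order = [0, 3, 1, 5, 2, 4, 6, 7]
        relabeled = {i: f"Z{k}" for k, i in enumerate(aln.ids)}
        relabeled["REF"] = "REF"
        aln2 = AlignmentSet(
            [relabeled[aln.ids[i]] for i in order], [aln.sequences[i] for i in order]
        )
        res2 = screen_sites(
            aln2, panel, "REF", [relabeled[i] for i in fg], None, ScreenConfig(seed=1)
        )
        for a, b in zip(base, res2):
            assert (a.fg_mean, a.bg_mean, a.n_fg_pairs, a.n_bg_pairs) == (
                b.fg_mean, b.bg_mean, b.n_fg_pairs, b.n_bg_pairs,
            )
            assert a.p_value == pytest.approx(b.p_value, nan_ok=True)
            assert a.conserved == b.conserved

    def test_scaling_all_distances_preserves_rank_test_and_flags(self):
        aln, truth = small_family(7, n_seq=10, length=6, gap_rate=0.0)
        panel = SitePanel([Site(p) for p in range(1, 7)])
        fg = list(truth.foreground_ids) + ["BG0001", "BG0002"]
        cfg = ScreenConfig(test="mann_whitney", seed=0)
        base = screen_sites(aln, panel, "REF", fg, None, cfg)
        scaled = screen_sites(aln, panel, "REF", fg, None, cfg, matrix=canonical_matrix() * 3.7)
        for a, b in zip(base, scaled):
            assert b.fg_mean == pytest.approx(3.7 * a.fg_mean, nan_ok=True)
            assert b.p_value == pytest.approx(a.p_value, nan_ok=True)
            assert b.conserved == a.conserved

    def test_all_gap_foreground_site_reported_not_dropped(self):
        aln = AlignmentSet(
            ["REF", "B1", "F1", "F2"],
            ["MLKTY", "MIKTY", "M-KTY", "M-KTY"],
        )
        res = screen_sites(
            aln, SitePanel([Site(2)]), "REF", ["F1", "F2"], None, ScreenConfig(seed=0)
        )
        assert len(res) == 1
        r = res[0]
        assert math.isnan(r.p_value) and not r.conserved
        assert "insufficient foreground" in r.note
        assert r.n_fg == 0

    def test_identical_foreground_and_background_not_flagged(self):
        aln, _ = small_family(3, n_seq=6, length=4, gap_rate=0.0)
        res = screen_sites(
            aln, SitePanel([Site(1), Site(2)]), "REF", list(aln.ids), list(aln.ids),
            ScreenConfig(seed=0),
        )
        for r in res:
            assert r.fg_mean == pytest.approx(r.bg_mean)
            assert not r.conserved

    def test_too_small_foreground_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="at least 2 foreground"):
            screen_sites(toy_alignment, SitePanel([Site(1)]), "REF", ["A1"])

    def test_monomorphic_alignment_gives_p_one(self):
        aln = AlignmentSet(["REF", "a", "b", "c"], ["MMM"] * 4)
        res = screen_sites(aln, SitePanel([Site(2)]), "REF", ["a", "b"])
        assert res[0].p_value == 1.0 and not res[0].conserved

    def test_bh_correction_never_enlarges_flag_set(self):
        aln, truth = gen_family(FamilySpec(n_background=40, n_foreground=5, length=30,
                                           planted_sites=(5, 20), radius=0.0, seed=11))
        panel = SitePanel([Site(p) for p in range(1, 31)])
        fg = list(truth.foreground_ids)
        raw = screen_sites(aln, panel, "REF", fg, None, ScreenConfig(seed=2))
        bh = screen_sites(aln, panel, "REF", fg, None,
                          ScreenConfig(seed=2, multiple_testing="bh"))
        raw_flags = {r.position for r in raw if r.conserved}
        bh_flags = {r.position for r in bh if r.conserved}
        assert bh_flags <= raw_flags
        for a, b in zip(raw, bh):
            if not math.isnan(b.q_value):
                assert b.q_value >= a.p_value - 1e-12

    def test_results_frame_has_one_row_per_site(self, toy_alignment):
        res = screen_sites(
            toy_alignment, SitePanel([Site(2), Site(4)]), "REF", ["A1", "A2"], None
        )
        df = results_frame(res)
        assert list(df["position"]) == [2, 4]
        assert {"fg_mean", "bg_mean", "p_value", "conserved"} <= set(df.columns)


class TestPermutationNull:
    def test_monomorphic_foreground_attains_minimal_p(self):
        # foreground all identical (mean 0), polymorphic background
        seqs = ["L", "L", "L"] + list("ACDEFGHIKMNPQRSTVWY")
        aln = AlignmentSet([f"s{i}" for i in range(len(seqs))], seqs)
        p, obs = permutation_null(aln, 1, ["s0", "s1", "s2"], None, n_perm=999, seed=5)
        assert obs == 0.0
        assert p <= 1 / (1 + 999) + 0.01

    def test_zero_permutations_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(toy_alignment, 1, ["A1", "A2"], n_perm=0)

    def test_reproducible_under_fixed_seed(self):
        aln, truth = small_family(17, n_seq=12, length=4, gap_rate=0.0)
        fg = list(truth.foreground_ids)
        p1, _ = permutation_null(aln, 2, fg, None, n_perm=500, seed=42)
        p2, _ = permutation_null(aln, 2, fg, None, n_perm=500, seed=42)
        assert p1 == p2

    def test_background_smaller_than_foreground_unavailable(self):
        aln = AlignmentSet(["a", "b", "c"], ["LLL", "III", "VVV"])
        p, _ = permutation_null(aln, 1, ["a", "b", "c"], ["a", "b"], n_perm=100, seed=0)
        assert math.isnan(p)

    def test_config_requires_enough_permutations(self):
        with pytest.raises(ValueError, match="100"):
            ScreenConfig(test="permutation", permutations=50)
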