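"""Rank-sum tests, Holm adjustment, rank-biserial effect sizes."""

import itertools
import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import enameliso as ei
from enameliso.core import EmptyProfileError, InvalidInputError


def brute_force_exact_p(x, y):
    """Two-sided exact rank-sum p by enumerating all C(n+m, n) labelings."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    observed = u_stat(x, y)
    mean_u = len(x) * len(y) / 2.0
    dev = abs(observed - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    def test_hand_enumerated_case(self):
        W, p = ei.rank_sum_test([1, 2], [3, 4])
        assert W == 0.0
        assert p == pytest.approx(1 / 3)

    def test_maximal_separation(self):
        W, _ = ei.rank_sum_test([4, 5, 6], [1, 2, 3])
        assert W == 9.0

    def test_half_tie_counting(self):
        W, _ = ei.rank_sum_test([1, 2, 2], [2, 3])
        assert W == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            ei.rank_sum_test([], [1.0])

    @pytest.mark.parametrize("n1, n2", [(2, 2), (3, 4), (5, 5), (6, 3), (6, 6)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            W, p = ei.rank_sum_test(x, y, mode="exact")
            assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_complement_identity_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n1, n2 = rng.integers(1, 9, 2)
            # mix continuous and tied data
            x = np.round(rng.normal(0, 1, n1), 1)
            y = np.round(rng.normal(0, 1, n2), 1)
            wxy, _ = ei.rank_sum_test(x, y)
            wyx, _ = ei.rank_sum_test(y, x)
            assert wxy + wyx == pytest.approx(n1 * n2)

    def test_auto_mode_falls_back_on_ties(self):
        # tied data cannot use the exact continuous null; must not crash
        _, p = ei.rank_sum_test([1, 2, 2], [2, 3], mode="auto")
        assert 0.0 <= p <= 1.0


class TestHolm:
    def test_hand_worked_stepdown(self):
        assert ei.holm_adjust([0.01, 0.03, 0.04]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert ei.holm_adjust([0.2]) == [0.2]

    def test_equal_pair_doubled(self):
        assert ei.holm_adjust([0.05, 0.05]) == pytest.approx([0.10, 0.10])

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            ours = ei.holm_adjust(p)
            _, oracle, _, _ = multipletests(p, method="holm")
            assert ours == pytest.approx(oracle.tolist(), abs=1e-12)

    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 20)
        adj = ei.holm_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ei.holm_adjust([0.1, 1.2])


class TestRankBiserial:
    def test_complete_separation_orientations(self):
        r, *_ = ei.rank_biserial([5, 6], [1, 2], n_boot=100, seed=0)
        assert r == 1.0
        r, *_ = ei.rank_biserial([1, 2], [5, 6], n_boot=100, seed=0)
        assert r == -1.0

    def test_balanced_pairs_give_zero(self):
        r, *_ = ei.rank_biserial([3, 4], [1, 5], n_boot=100, seed=0)
        assert r == 0.0

    def test_identity_with_u_statistic(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = rng.integers(2, 10, 2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.3, 1, n2)
            W, _ = ei.rank_sum_test(x, y)
            r, *_ = ei.rank_biserial(x, y, n_boot=100, seed=0)
            assert r == pytest.approx(2 * W / (n1 * n2) - 1, abs=1e-12)

    def test_bootstrap_ci_reproducible(self):
        x, y = [1.0, 2.5, 3.1], [2.0, 2.2, 4.0, 5.1]
        a = ei.rank_biserial(x, y, n_boot=500, seed=42)
        b = ei.rank_biserial(x, y, n_boot=500, seed=42)
        assert a == b

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning):
            ei.rank_biserial([1, 2], [3, 4], n_boot=50, seed=0)


class TestCollapse:
    def test_fossil_specimen_means(self, fossil_profiles):
        ds = ei.collapse_serial_to_individual(fossil_profiles, "d13C_diet_meq")
        assert sorted(round(v, 1) for v in ds.values) == [-15.2, -14.2, -13.7]
        assert ds.provenance == "serial_collapsed"

    def test_constant_profile_collapses_to_constant(self):
        samples = tuple(
            ei.SerialSample(f"G{i}", i, -2.0, -6.0) for i in range(1, 5)
        )
        p = ei.SpecimenProfile("C", "t", "pleistocene", samples)
        ds = ei.collapse_serial_to_individual([p], "d13C_enamel")
        assert ds.values == (-2.0,)

    def test_missing_leading_samples_excluded(self, juvenile):
        ds = ei.collapse_serial_to_individual([juvenile], "d13C_enamel")
        # mean over the 9 measured grooves only
        assert ds.values[0] == pytest.approx(-2.6233333, abs=1e-6)

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyProfileError):
            ei.collapse_serial_to_individual([], "d18O")


class TestCompareFocalVsAll:
    def _datasets(self, shifts, n=8, seed=0):
        rng = np.random.default_rng(seed)
        out = [
            ei.TaxonDataset("focal", "pleistocene", "d13C_diet_meq",
                            tuple(rng.normal(-14.0, 0.5, n)))
        ]
        for i, s in enumerate(shifts):
            out.append(
                ei.TaxonDataset(f"taxon{i}", "pleistocene", "d13C_diet_meq",
                                tuple(rng.normal(-14.0 + s, 0.5, n)))
            )
        return out

    def test_effect_size_order_follows_location_shifts(self):
        res = ei.compare_focal_vs_all(
            self._datasets([-4.0, -2.0, -0.5]), "focal", "d13C_diet_meq",
            n_boot=300, seed=1,
        )
        by_taxon = {r.other: abs(r.r) for r in res}
        assert by_taxon["taxon0"] >= by_taxon["taxon1"] >= by_taxon["taxon2"]

    def test_identical_datasets_uncertain(self):
        vals = tuple(np.linspace(-15, -13, 8))
        ds = [
            ei.TaxonDataset("focal", "pleistocene", "d13C_diet_meq", vals),
            ei.TaxonDataset("twin", "pleistocene", "d13C_diet_meq", vals),
        ]
        res = ei.compare_focal_vs_all(ds, "focal", "d13C_diet_meq",
                                      n_boot=300, seed=2)[0]
        assert res.r == 0.0
        assert res.interpretation == "uncertain"

    def test_holm_applied_within_family(self):
        res = ei.compare_focal_vs_all(
            self._datasets([-4.0, -2.0, -0.5]), "focal", "d13C_diet_meq",
            n_boot=200, seed=3,
        )
        raw = [r.p_raw for r in res]
        assert [r.p_holm for r in res] == pytest.approx(ei.holm_adjust(raw))
        assert all(r.p_holm >= r.p_raw for r in res)

    def test_missing_focal_rejected(self):
        with pytest.raises(InvalidInputError):
            ei.compare_focal_vs_all(self._datasets([1.0]), "nobody", "d13C_diet_meq")

    def test_strong_negative_shift_reads_focal_higher(self):
        # comparison taxon entirely more negative -> r = +1, focal_higher
        ds = [
            ei.TaxonDataset("focal", "pleistocene", "d13C_diet_meq",
                            (-14.0, -13.5, -13.9)),
            ei.TaxonDataset("c3_browser", "modern", "d13C_diet_meq",
                            (-27.0, -26.5, -27.5)),
        ]
        res = ei.compare_focal_vs_all(ds, "focal", "d13C_diet_meq",
                                      n_boot=300, seed=4)[0]
        assert res.r == 1.0
        assert res.interpretation == "focal_higher"
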