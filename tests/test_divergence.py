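"""Six divergence parameters and the signed-rank locus comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats

from its2barcode import (
    Direction,
    PairClass,
    Region,
    SimulationConfig,
    compare_loci,
    divergence_summary,
    excise_true_region,
    interspecific_summary,
    intraspecific_summary,
    simulate_corpus,
    wilcoxon_signed_rank,
)
from its2barcode.distance import DistanceModel, distance_matrix

from conftest import dm_from_pairs, make_corpus


def brute_wilcoxon_p(diffs) -> float:
    """Exact two-sided p by literal enumeration of all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    sums = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    p = 2 * min((sums <= w + 1e-12).mean(), (sums >= w - 1e-12).mean())
    return min(1.0, p)


def five_record_setup():
    """Species A with 3 samples, species B with 2, plus distances."""
    corpus = make_corpus([
        ("a1", "G", "A", "ACGT"), ("a2", "G", "A", "ACGT"),
        ("a3", "G", "A", "ACGT"), ("b1", "G", "B", "ACGT"),
        ("b2", "G", "B", "ACGT"),
    ])
    dm = dm_from_pairs(
        ["a1", "a2", "a3", "b1", "b2"],
        {("a1", "a2"): 0.01, ("a1", "a3"): 0.02, ("a2", "a3"): 0.03,
         ("b1", "b2"): 0.04,
         # interspecific distances (unused by the intra summary)
         ("a1", "b1"): 0.1, ("a1", "b2"): 0.1, ("a2", "b1"): 0.1,
         ("a2", "b2"): 0.1, ("a3", "b1"): 0.1, ("a3", "b2"): 0.1},
    )
    return corpus, dm


class TestIntraspecific:
    def test_hand_computed_example(self):
        corpus, dm = five_record_setup()
        avg, mx, pooled, n_sp, n_nan = intraspecific_summary(dm, corpus)
        assert avg.mean == pytest.approx(0.03)    # mean(0.02, 0.04)
        assert mx.mean == pytest.approx(0.035)    # mean(0.03, 0.04)
        assert pooled.mean == pytest.approx(0.025)
        assert n_sp == 2 and n_nan == 0

    def test_identical_conspecifics_give_zero(self):
        corpus = make_corpus([
            ("a1", "G", "A", "ACGT"), ("a2", "G", "A", "ACGT"),
        ])
        dm = dm_from_pairs(["a1", "a2"], {("a1", "a2"): 0.0})
        avg, mx, pooled, *_ = intraspecific_summary(dm, corpus)
        assert avg.mean == mx.mean == pooled.mean == 0.0

    def test_single_pair_species(self):
        corpus = make_corpus([
            ("a1", "G", "A", "ACGT"), ("a2", "G", "A", "ACGT"),
        ])
        dm = dm_from_pairs(["a1", "a2"], {("a1", "a2"): 0.017})
        avg, mx, pooled, *_ = intraspecific_summary(dm, corpus)
        assert avg.mean == mx.mean == pooled.mean == pytest.approx(0.017)

    def test_no_multisample_species_errors(self):
        corpus = make_corpus([
            ("a1", "G", "A", "ACGT"), ("b1", "G", "B", "ACGT"),
        ])
        dm = dm_from_pairs(["a1", "b1"], {("a1", "b1"): 0.1})
        with pytest.raises(ValueError, match="2 samples"):
            intraspecific_summary(dm, corpus)


class TestInterspecific:
    def test_hand_computed_example(self):
        corpus = make_corpus([
            ("a1", "G", "A", "ACGT"), ("b1", "G", "B", "ACGT"),
            ("c1", "G", "C", "ACGT"),
        ])
        dm = dm_from_pairs(
            ["a1", "b1", "c1"],
            {("a1", "b1"): 0.10, ("a1", "c1"): 0.12, ("b1", "c1"): 0.20},
        )
        avg, nearest, pooled, n_gen, n_nan = interspecific_summary(dm, corpus)
        assert avg.mean == pytest.approx(0.14)
        assert nearest.mean == pytest.approx((0.10 + 0.10 + 0.12) / 3)
        assert pooled.mean == pytest.approx(0.14)
        assert n_gen == 1

    def test_cross_genus_pairs_excluded(self):
        corpus = make_corpus([
            ("a1", "G", "A", "ACGT"), ("b1", "G", "B", "ACGT"),
            ("x1", "H", "X", "ACGT"), ("y1", "H", "Y", "ACGT"),
        ])
        dm = dm_from_pairs(
            ["a1", "b1", "x1", "y1"],
            {("a1", "b1"): 0.1, ("x1", "y1"): 0.2,
             # huge cross-genus distances that must not leak in
             ("a1", "x1"): 0.9, ("a1", "y1"): 0.9,
             ("b1", "x1"): 0.9, ("b1", "y1"): 0.9},
        )
        avg, nearest, pooled, n_gen, _ = interspecific_summary(dm, corpus)
        assert pooled.mean == pytest.approx(0.15)
        assert n_gen == 2

    def test_singleton_species_nearest_is_single_distance(self):
        corpus = make_corpus([
            ("a1", "G", "A", "ACGT"), ("b1", "G", "B", "ACGT"),
        ])
        dm = dm_from_pairs(["a1", "b1"], {("a1", "b1"): 0.07})
        _, nearest, _, _, _ = interspecific_summary(dm, corpus)
        assert nearest.mean == pytest.approx(0.07)

    def test_no_multispecies_genus_errors(self):
        corpus = make_corpus([
            ("a1", "G", "A", "ACGT"), ("x1", "H", "X", "ACGT"),
        ])
        dm = dm_from_pairs(["a1", "x1"], {("a1", "x1"): 0.3})
        with pytest.raises(ValueError, match="2 species"):
            interspecific_summary(dm, corpus)


class TestPooledIdentity:
    def test_pooled_mean_is_weighted_average_of_per_unit_means(self):
        rng = np.random.default_rng(23)
        rows = []
        k = 0
        for s in range(4):
            for _ in range(int(rng.integers(2, 5))):
                k += 1
                rows.append((f"r{k}", "G", f"sp{s}", "ACGT"))
        corpus = make_corpus(rows)
        labels = [r[0] for r in rows]
        pairs = {}
        for a, b in itertools.combinations(labels, 2):
            pairs[(a, b)] = float(rng.uniform(0.001, 0.2))
        dm = dm_from_pairs(labels, pairs)
        _, _, pooled, *_ = intraspecific_summary(dm, corpus)
        # recompute as weighted average of per-species means
        num = den = 0.0
        for g, s in corpus.species:
            rids = corpus.records_of_species(g, s)
            ds = [dm[a, b] for a, b in itertools.combinations(rids, 2)]
            if ds:
                num += np.mean(ds) * len(ds)
                den += len(ds)
        assert pooled.mean == pytest.approx(num / den)


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert (res.w_plus, res.w_minus) == (6.0, 0.0)
        assert res.direction is Direction.B_GT_A

    def test_mixed_signs_exact_p(self):
        # differences {+1, -2, +3}: ranks {1, 2, 3}, W+ = 4, W- = 2
        res = wilcoxon_signed_rank([0, 2, 0], [1, 0, 3])
        assert (res.w_plus, res.w_minus) == (4.0, 2.0)
        assert res.p_value == pytest.approx(brute_wilcoxon_p([1, -2, 3]))

    def test_all_zero_differences(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.n == 0
        assert res.p_value == 1.0
        assert res.direction is Direction.NONE

    def test_rank_sum_identity_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            n = int(rng.integers(1, 40))
            a = np.round(rng.normal(0, 1, n), 2)
            b = np.round(rng.normal(0.1, 1, n), 2)
            res = wilcoxon_signed_rank(a, b)
            assert res.w_plus + res.w_minus == pytest.approx(
                res.n * (res.n + 1) / 2
            )

    def test_exact_matches_enumeration_up_to_n10(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            d = np.round(rng.normal(0.2, 1, n), 1)
            res = wilcoxon_signed_rank(np.zeros(n), d)
            assert res.p_value == pytest.approx(brute_wilcoxon_p(d), abs=1e-12)

    def test_large_n_matches_scipy_approximation(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(30, 100))
            a = rng.normal(0, 1, n)
            b = a + rng.normal(0.1, 0.5, n)
            if trial % 3 == 0:  # force ties
                a, b = np.round(a, 1), np.round(b, 1)
            res = wilcoxon_signed_rank(a, b)
            d = (b - a)[(b - a) != 0]
            sp = stats.wilcoxon(
                d, correction=True, method="approx", alternative="two-sided"
            )
            assert res.p_value == pytest.approx(float(sp.pvalue), abs=1e-10)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestCompareLoci:
    def test_uniform_shift_gives_locus2_direction(self):
        corpus, dm1 = five_record_setup()
        dm2 = dm_from_pairs(
            dm1.labels,
            {(a, b): dm1[a, b] + 0.01
             for a, b in itertools.combinations(dm1.labels, 2)},
        )
        results = compare_loci(dm1, dm2, corpus)
        for res in results.values():
            assert res.direction is Direction.B_GT_A
            assert res.w_minus == 0.0

    def test_identical_loci_flat(self):
        corpus, dm1 = five_record_setup()
        results = compare_loci(dm1, dm1, corpus)
        for res in results.values():
            assert res.n == 0
            assert res.p_value == 1.0
            assert res.direction is Direction.NONE

    def test_disjoint_matrices_rejected(self):
        corpus, dm1 = five_record_setup()
        dm2 = dm_from_pairs(["z1", "z2"], {("z1", "z2"): 0.1})
        with pytest.raises(ValueError, match="share no record"):
            compare_loci(dm1, dm2, corpus)

    def test_conserved_block_dilutes_full_its(self):
        # the invariant 5.8S inside full ITS lowers its distances, so the
        # excised ITS2 should diverge faster for nearly all pairs
        cfg = SimulationConfig(
            n_genera=4, species_per_genus=(2, 3),
            samples_per_species=(2, 2),
            d_intra=0.01, d_inter=0.06,
            conserved_rate_5_8s=0.0, indel_rate=0.0, seed=31,
        )
        corpus, truth = simulate_corpus(cfg)
        full = excise_true_region(corpus, truth, Region.ITS_FULL)
        its2 = excise_true_region(corpus, truth, Region.ITS2)
        dm_full = distance_matrix(full, DistanceModel.K2P)
        dm_its2 = distance_matrix(its2, DistanceModel.K2P)
        results = compare_loci(dm_full, dm_its2, its2)
        inter = results[PairClass.INTERSPECIFIC]
        assert inter.direction is Direction.B_GT_A
        total = inter.n * (inter.n + 1) / 2
        assert inter.w_plus >= 0.95 * total


class TestBarcodeGap:
    @pytest.mark.parametrize("seed,d_intra,d_inter", [
        (41, 0.005, 0.05),
        (42, 0.01, 0.08),
        (43, 0.02, 0.12),
    ])
    def test_intra_below_inter(self, seed, d_intra, d_inter):
        cfg = SimulationConfig(
            n_genera=4, species_per_genus=(2, 3),
            samples_per_species=(2, 2),
            d_intra=d_intra, d_inter=d_inter,
            conserved_rate_5_8s=0.002, indel_rate=0.0, seed=seed,
        )
        corpus, truth = simulate_corpus(cfg)
        its2 = excise_true_region(corpus, truth, Region.ITS2)
        dm = distance_matrix(its2, DistanceModel.K2P)
        summary = divergence_summary(dm, its2)
        assert summary.avg_intra_avg.mean < summary.avg_interbyG_avg.mean
        assert summary.avg_intra_avg.mean <= summary.avg_intra_max.mean
        assert summary.avg_interbyG_min.mean <= summary.avg_interbyG_avg.mean
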