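"""Best hit / best match / best close match, against a naive oracle."""

import math

import numpy as np
import pytest

from its2barcode import (
    Category,
    Criterion,
    Rank,
    best_close_match_identify,
    best_hit_identify,
    best_match_identify,
    identify_corpus,
    per_genus_report,
)
from its2barcode.distance import (
    DistanceModel,
    align_global,
    align_local_score,
    distance_matrix,
    p_distance,
)
from its2barcode.identification import IdentificationOutcome

from conftest import dm_from_pairs, make_corpus, random_toy_corpus


# ---------------------------------------------------------------------------
# Naive oracle: per-query loops with the plain category rules, no shared
# matrix machinery and no tie tolerance (p-distance ties are exact ratios)
# ---------------------------------------------------------------------------

def oracle_categorize(query, tied_taxa, rank):
    labels = (
        {t for t in tied_taxa} if rank is Rank.SPECIES
        else {t[0] for t in tied_taxa}
    )
    own = query.taxon if rank is Rank.SPECIES else query.genus
    if len(labels) >= 2:
        return Category.AMBIGUOUS
    return Category.CORRECT if own in labels else Category.INCORRECT


def oracle_best_hit(query, corpus, rank):
    best, tied = -math.inf, []
    for ref in corpus:
        if ref.record_id == query.record_id:
            continue
        s = align_local_score(query.sequence, ref.sequence)
        if s > best:
            best, tied = s, [ref.taxon]
        elif s == best:
            tied.append(ref.taxon)
    return oracle_categorize(query, tied, rank)


def oracle_nearest(query, corpus):
    best, tied = math.inf, []
    for ref in corpus:
        if ref.record_id == query.record_id:
            continue
        d = p_distance(align_global(query.sequence, ref.sequence))
        if d < best:
            best, tied = d, [ref.taxon]
        elif d == best:
            tied.append(ref.taxon)
    return best, tied


def oracle_best_match(query, corpus, rank):
    _, tied = oracle_nearest(query, corpus)
    return oracle_categorize(query, tied, rank)


def oracle_best_close_match(query, corpus, rank, threshold=0.03):
    best, tied = oracle_nearest(query, corpus)
    if best > threshold:
        return Category.NO_MATCH
    return oracle_categorize(query, tied, rank)


# ---------------------------------------------------------------------------


class TestBestHit:
    def test_identical_conspecific_reference_correct(self):
        corpus = make_corpus([
            ("q", "Abies", "alba", "ACGTACGTACGTACGTACGT"),
            ("r1", "Abies", "alba", "ACGTACGTACGTACGTACGT"),
            ("r2", "Picea", "abies", "TTTTGGGGCCCCAAAATTTT"),
        ])
        for rank in Rank:
            out = best_hit_identify(corpus["q"], corpus, rank=rank)
            assert out.category is Category.CORRECT

    def test_tie_between_species_same_genus(self):
        # both references differ from the query by one substitution at
        # the same score, so they tie at the top
        corpus = make_corpus([
            ("q", "Abies", "alba", "ACGTACGTACGTACGTACGT"),
            ("r1", "Abies", "alba", "ACGTACGTACGTACGTACGA"),
            ("r2", "Abies", "cephalonica", "CCGTACGTACGTACGTACGT"),
        ])
        sp = best_hit_identify(corpus["q"], corpus, rank=Rank.SPECIES)
        gn = best_hit_identify(corpus["q"], corpus, rank=Rank.GENUS)
        assert sp.category is Category.AMBIGUOUS
        assert len(sp.matched_taxa) == 2
        assert gn.category is Category.CORRECT

    def test_congener_top_hit(self):
        corpus = make_corpus([
            ("q", "Abies", "alba", "ACGTACGTACGTACGTACGT"),
            ("r1", "Abies", "cephalonica", "ACGTACGTACGTACGTACGT"),
            ("r2", "Picea", "abies", "TTTTGGGGCCCCAAAATTTT"),
        ])
        sp = best_hit_identify(corpus["q"], corpus, rank=Rank.SPECIES)
        gn = best_hit_identify(corpus["q"], corpus, rank=Rank.GENUS)
        assert sp.category is Category.INCORRECT
        assert gn.category is Category.CORRECT

    def test_empty_reference_rejected(self):
        corpus = make_corpus([("q", "A", "a", "ACGT")])
        with pytest.raises(ValueError):
            best_hit_identify(corpus["q"], corpus)


class TestBestMatch:
    def test_near_conspecific_correct(self):
        corpus = make_corpus([
            ("q", "A", "a", "ACGT"), ("r1", "A", "a", "ACGT"),
            ("r2", "B", "b", "ACGT"),
        ])
        dm = dm_from_pairs(
            ["q", "r1", "r2"],
            {("q", "r1"): 0.004, ("q", "r2"): 0.2, ("r1", "r2"): 0.2},
        )
        out = best_match_identify(corpus["q"], corpus, dm)
        assert out.category is Category.CORRECT
        assert out.best_distance_or_score == pytest.approx(0.004)

    def test_tied_minimum_from_two_species_ambiguous(self):
        corpus = make_corpus([
            ("q", "A", "a", "ACGT"), ("r1", "A", "a", "ACGT"),
            ("r2", "B", "b", "ACGT"),
        ])
        dm = dm_from_pairs(
            ["q", "r1", "r2"],
            {("q", "r1"): 0.05, ("q", "r2"): 0.05, ("r1", "r2"): 0.2},
        )
        out = best_match_identify(corpus["q"], corpus, dm)
        assert out.category is Category.AMBIGUOUS

    def test_singleton_species_never_correct(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            corpus = random_toy_corpus(rng, n_max=10)
            dm = distance_matrix(corpus, DistanceModel.P_DIST, warn_nan=False)
            for rec in corpus:
                if len(corpus.records_of_species(*rec.taxon)) == 1:
                    out = best_match_identify(rec, corpus, dm)
                    assert out.category is not Category.CORRECT


class TestBestCloseMatch:
    def _setup(self, d):
        corpus = make_corpus([
            ("q", "A", "a", "ACGT"), ("r1", "A", "a", "ACGT"),
        ])
        dm = dm_from_pairs(["q", "r1"], {("q", "r1"): d})
        return corpus, dm

    def test_distant_nearest_is_no_match(self):
        corpus, dm = self._setup(0.05)
        out = best_close_match_identify(corpus["q"], corpus, dm, 0.03)
        assert out.category is Category.NO_MATCH
        assert out.matched_taxa == frozenset()

    def test_close_conspecific_correct(self):
        corpus, dm = self._setup(0.01)
        out = best_close_match_identify(corpus["q"], corpus, dm, 0.03)
        assert out.category is Category.CORRECT

    def test_boundary_inclusive(self):
        corpus, dm = self._setup(0.03)
        out = best_close_match_identify(corpus["q"], corpus, dm, 0.03)
        assert out.category is Category.CORRECT

    def test_threshold_to_one_converges_to_best_match(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            corpus = random_toy_corpus(rng, n_max=12)
            dm = distance_matrix(corpus, DistanceModel.P_DIST, warn_nan=False)
            for rec in corpus:
                bm = best_match_identify(rec, corpus, dm)
                bcm = best_close_match_identify(rec, corpus, dm, 0.999999)
                assert bcm.category is bm.category
                assert bcm.matched_taxa == bm.matched_taxa

    def test_no_match_monotone_in_threshold(self):
        rng = np.random.default_rng(10)
        corpus = random_toy_corpus(rng, n_max=14)
        dm = distance_matrix(corpus, DistanceModel.P_DIST, warn_nan=False)
        counts = []
        for thr in (0.005, 0.02, 0.05, 0.2):
            n_nm = sum(
                best_close_match_identify(rec, corpus, dm, thr).category
                is Category.NO_MATCH
                for rec in corpus
            )
            counts.append(n_nm)
        assert counts == sorted(counts, reverse=True)


class TestIdentifyCorpus:
    def test_percentages_partition(self):
        rng = np.random.default_rng(14)
        corpus = random_toy_corpus(rng, n_max=12)
        for criterion in Criterion:
            report, outcomes = identify_corpus(corpus, criterion)
            assert len(outcomes) == report.n_queries == len(corpus)
            total = (report.pct_correct + report.pct_ambiguous
                     + report.pct_incorrect + report.pct_no_match)
            assert total == pytest.approx(100.0)

    def test_all_singletons_best_match_zero_correct(self):
        rng = np.random.default_rng(15)
        rows = [
            (f"r{i}", f"G{i % 3}", f"sp{i}",
             "".join("ACGT"[b] for b in rng.integers(0, 4, 60)))
            for i in range(9)
        ]
        corpus = make_corpus(rows)
        report, _ = identify_corpus(corpus, Criterion.BEST_MATCH)
        assert report.pct_correct == 0.0

    def test_genus_rank_at_least_species_rank_for_best_hit(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            corpus = random_toy_corpus(rng, n_max=14)
            sp, _ = identify_corpus(corpus, Criterion.BEST_HIT, Rank.SPECIES)
            gn, _ = identify_corpus(corpus, Criterion.BEST_HIT, Rank.GENUS)
            assert gn.pct_correct >= sp.pct_correct

    def test_agreement_with_naive_oracle(self):
        rng = np.random.default_rng(18)
        oracle_fn = {
            Criterion.BEST_HIT: oracle_best_hit,
            Criterion.BEST_MATCH: oracle_best_match,
            Criterion.BEST_CLOSE_MATCH: oracle_best_close_match,
        }
        for _ in range(8):
            corpus = random_toy_corpus(rng, n_max=12)
            dm = distance_matrix(corpus, DistanceModel.P_DIST, warn_nan=False)
            for criterion in Criterion:
                for rank in Rank:
                    _, outcomes = identify_corpus(
                        corpus, criterion, rank, dm=dm
                    )
                    for out in outcomes:
                        expected = oracle_fn[criterion](
                            corpus[out.query_id], corpus, rank
                        )
                        assert out.category is expected, (
                            f"{criterion} {rank} {out.query_id}"
                        )


class TestPerGenusReport:
    @staticmethod
    def _outcomes(n_total, n_wrong, genus="Gunnera"):
        outs = []
        for i in range(n_total):
            cat = Category.INCORRECT if i < n_wrong else Category.CORRECT
            outs.append(IdentificationOutcome(
                f"{genus}_{i}", Criterion.BEST_HIT, Rank.SPECIES, cat,
                100.0, frozenset([(genus, "x")]),
            ))
        return outs

    @staticmethod
    def _corpus(n_samples, genus="Gunnera"):
        # one sample per species: n_samples == n_species
        return make_corpus([
            (f"{genus}_{i}", genus, f"sp{i}", "ACGT")
            for i in range(n_samples)
        ])

    def test_twenty_samples_one_wrong_is_five_percent(self):
        corpus = self._corpus(20)
        rows = per_genus_report(self._outcomes(20, 1), corpus, min_species=20)
        assert len(rows) == 1
        assert rows[0]["pct_unidentified"] == pytest.approx(5.00)
        assert rows[0]["n_samples"] == 20

    def test_small_genus_excluded(self):
        corpus = self._corpus(5)
        rows = per_genus_report(self._outcomes(5, 1), corpus, min_species=20)
        assert rows == []

    def test_all_correct_is_zero_percent(self):
        corpus = self._corpus(20)
        rows = per_genus_report(self._outcomes(20, 0), corpus, min_species=20)
        assert rows[0]["pct_unidentified"] == 0.0
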