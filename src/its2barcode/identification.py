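"""Leave-one-out species identification under three criteria.

* BEST_HIT — score the query against every other sequence by optimal
  local alignment (exhaustive Smith–Waterman, no heuristic seeding); the
  top-scoring reference's taxon is the call.
* BEST_MATCH — the minimum p-distance neighbour's taxon is the call,
  however distant.
* BEST_CLOSE_MATCH — best match gated by a distance threshold (default
  0.03, i.e. the 97% similarity rule, inclusive at the boundary);
  queries whose nearest neighbour lies beyond the threshold are NO_MATCH.

Categories: CORRECT if all tied best references collapse to the query's
taxon at the tested rank; INCORRECT if they collapse to a single wrong
taxon; AMBIGUOUS if the tied set spans >= 2 taxa at that rank.  Every
record is queried once against all the others (leave-one-out on
record_id only); singleton-species queries stay in the denominator
unless excluded explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .distance import (
    LOCAL_SCORING,
    DistanceMatrix,
    DistanceModel,
    Scoring,
    align_local_score,
    distance_matrix,
)
from .seq_model import Corpus, TaxonRecord

__all__ = [
    "Criterion",
    "Rank",
    "Category",
    "IdentificationOutcome",
    "IdentificationReport",
    "best_hit_identify",
    "local_score_matrix",
    "best_match_identify",
    "best_close_match_identify",
    "identify_corpus",
    "per_genus_report",
    "DEFAULT_THRESHOLD",
    "DISTANCE_TIE_RTOL",
]

DEFAULT_THRESHOLD = 0.03
#: relative tolerance declaring two real-valued distances tied
DISTANCE_TIE_RTOL = 1e-9


class Criterion(str, Enum):
    BEST_HIT = "BEST_HIT"
    BEST_MATCH = "BEST_MATCH"
    BEST_CLOSE_MATCH = "BEST_CLOSE_MATCH"


class Rank(str, Enum):
    SPECIES = "SPECIES"
    GENUS = "GENUS"


class Category(str, Enum):
    CORRECT = "CORRECT"
    AMBIGUOUS = "AMBIGUOUS"
    INCORRECT = "INCORRECT"
    NO_MATCH = "NO_MATCH"


@dataclass(frozen=True)
class IdentificationOutcome:
    query_id: str
    criterion: Criterion
    rank: Rank
    category: Category
    best_distance_or_score: float
    matched_taxa: frozenset[tuple[str, str]]

    TSV_HEADER = "query_id\tcriterion\trank\tcategory\tbest\tmatched_taxa"

    def to_tsv_row(self) -> str:
        taxa = ";".join(
            f"{g} {s}" for g, s in sorted(self.matched_taxa)
        ) or "."
        return (
            f"{self.query_id}\t{self.criterion.value}\t{self.rank.value}\t"
            f"{self.category.value}\t{self.best_distance_or_score:.6g}\t{taxa}"
        )


@dataclass(frozen=True)
class IdentificationReport:
    criterion: Criterion
    rank: Rank
    n_queries: int
    pct_correct: float
    pct_ambiguous: float
    pct_incorrect: float
    pct_no_match: float

    def __post_init__(self) -> None:
        total = (
            self.pct_correct + self.pct_ambiguous
            + self.pct_incorrect + self.pct_no_match
        )
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"percentages sum to {total}, not 100")

    TSV_HEADER = (
        "criterion\trank\tn_queries\tpct_correct\tpct_ambiguous\t"
        "pct_incorrect\tpct_no_match"
    )

    def to_tsv_row(self) -> str:
        return (
            f"{self.criterion.value}\t{self.rank.value}\t{self.n_queries}\t"
            f"{self.pct_correct:.2f}\t{self.pct_ambiguous:.2f}\t"
            f"{self.pct_incorrect:.2f}\t{self.pct_no_match:.2f}"
        )


def _categorize(
    query: TaxonRecord,
    matched_taxa: Iterable[tuple[str, str]],
    rank: Rank,
) -> Category:
    """Collapse the tied best taxa to ``rank`` and compare with the query."""
    if rank is Rank.SPECIES:
        tied = {t for t in matched_taxa}
        own = query.taxon
    else:
        tied = {t[0] for t in matched_taxa}
        own = query.genus
    if len(tied) >= 2:
        return Category.AMBIGUOUS
    return Category.CORRECT if own in tied else Category.INCORRECT


# ---------------------------------------------------------------------------
# Per-query criteria
# ---------------------------------------------------------------------------

def local_score_matrix(
    corpus: Corpus, scoring: Scoring = LOCAL_SCORING
) -> np.ndarray:
    """Symmetric matrix of optimal local-alignment scores over the corpus.

    The diagonal is -inf so that leave-one-out maxima ignore self-hits.
    """
    records = list(corpus)
    n = len(records)
    scores = np.full((n, n), -math.inf)
    for i in range(n):
        for j in range(i + 1, n):
            s = align_local_score(
                records[i].sequence, records[j].sequence, scoring
            )
            scores[i, j] = scores[j, i] = s
    return scores


def best_hit_identify(
    query: TaxonRecord,
    reference: Corpus,
    scoring: Scoring = LOCAL_SCORING,
    rank: Rank = Rank.SPECIES,
) -> IdentificationOutcome:
    """Exhaustive local-alignment best hit; integer-score exact ties."""
    refs = [r for r in reference if r.record_id != query.record_id]
    if not refs:
        raise ValueError("reference corpus is empty after leave-one-out")
    scores = [
        align_local_score(query.sequence, r.sequence, scoring) for r in refs
    ]
    top = max(scores)
    tied = [r.taxon for r, s in zip(refs, scores) if s == top]
    return IdentificationOutcome(
        query_id=query.record_id,
        criterion=Criterion.BEST_HIT,
        rank=rank,
        category=_categorize(query, tied, rank),
        best_distance_or_score=top,
        matched_taxa=frozenset(tied),
    )


def _nearest_set(
    query: TaxonRecord, reference: Corpus, dm: DistanceMatrix
) -> tuple[float, list[tuple[str, str]]]:
    best = math.inf
    tied: list[tuple[str, str]] = []
    for ref in reference:
        if ref.record_id == query.record_id:
            continue
        d = dm[query.record_id, ref.record_id]
        if math.isnan(d):
            continue
        if d < best and not math.isclose(
            d, best, rel_tol=DISTANCE_TIE_RTOL, abs_tol=DISTANCE_TIE_RTOL
        ):
            best = d
            tied = [ref.taxon]
        elif math.isclose(
            d, best, rel_tol=DISTANCE_TIE_RTOL, abs_tol=DISTANCE_TIE_RTOL
        ):
            tied.append(ref.taxon)
    if not tied:
        raise ValueError(
            f"no defined distance between {query.record_id!r} and any reference"
        )
    return best, tied


def best_match_identify(
    query: TaxonRecord,
    reference: Corpus,
    dm: DistanceMatrix,
    rank: Rank = Rank.SPECIES,
) -> IdentificationOutcome:
    """Nearest-neighbour call with no distance gate."""
    best, tied = _nearest_set(query, reference, dm)
    return IdentificationOutcome(
        query_id=query.record_id,
        criterion=Criterion.BEST_MATCH,
        rank=rank,
        category=_categorize(query, tied, rank),
        best_distance_or_score=best,
        matched_taxa=frozenset(tied),
    )


def best_close_match_identify(
    query: TaxonRecord,
    reference: Corpus,
    dm: DistanceMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    rank: Rank = Rank.SPECIES,
) -> IdentificationOutcome:
    """Nearest-neighbour call gated by the similarity threshold.

    A query whose minimum distance exceeds ``threshold`` (strictly; the
    boundary is inclusive) is NO_MATCH; otherwise the call is made from
    the minimum-distance set exactly as in best match.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    best, tied = _nearest_set(query, reference, dm)
    if best > threshold and not math.isclose(
        best, threshold, rel_tol=DISTANCE_TIE_RTOL, abs_tol=DISTANCE_TIE_RTOL
    ):
        return IdentificationOutcome(
            query_id=query.record_id,
            criterion=Criterion.BEST_CLOSE_MATCH,
            rank=rank,
            category=Category.NO_MATCH,
            best_distance_or_score=best,
            matched_taxa=frozenset(),
        )
    return IdentificationOutcome(
        query_id=query.record_id,
        criterion=Criterion.BEST_CLOSE_MATCH,
        rank=rank,
        category=_categorize(query, tied, rank),
        best_distance_or_score=best,
        matched_taxa=frozenset(tied),
    )


# ---------------------------------------------------------------------------
# Corpus-level runs
# ---------------------------------------------------------------------------

def identify_corpus(
    corpus: Corpus,
    criterion: Criterion,
    rank: Rank = Rank.SPECIES,
    *,
    dm: DistanceMatrix | None = None,
    scores: np.ndarray | None = None,
    scoring: Scoring = LOCAL_SCORING,
    threshold: float = DEFAULT_THRESHOLD,
    include_singletons: bool = True,
) -> tuple[IdentificationReport, list[IdentificationOutcome]]:
    """Query every record against all the others (leave-one-out).

    Distance-based criteria need a p-distance matrix; one is computed if
    not supplied.  For BEST_HIT a precomputed :func:`local_score_matrix`
    can be passed to reuse alignments across ranks.
    ``include_singletons=False`` drops queries whose species has no
    other sample (they can never be CORRECT at species rank under the
    nearest-neighbour criteria).
    """
    records = list(corpus)
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if criterion is Criterion.BEST_HIT:
        if scores is None:
            scores = local_score_matrix(corpus, scoring)
    elif dm is None:
        dm = distance_matrix(corpus, model=DistanceModel.P_DIST)

    outcomes: list[IdentificationOutcome] = []
    for qi, rec in enumerate(records):
        if not include_singletons:
            if len(corpus.records_of_species(*rec.taxon)) < 2:
                continue
        if criterion is Criterion.BEST_HIT:
            row = scores[qi]
            top = float(row.max())
            tied = [records[j].taxon for j in np.flatnonzero(row == top)]
            out = IdentificationOutcome(
                query_id=rec.record_id,
                criterion=criterion,
                rank=rank,
                category=_categorize(rec, tied, rank),
                best_distance_or_score=top,
                matched_taxa=frozenset(tied),
            )
        elif criterion is Criterion.BEST_MATCH:
            out = best_match_identify(rec, corpus, dm, rank)
        else:
            out = best_close_match_identify(rec, corpus, dm, threshold, rank)
        outcomes.append(out)

    n = len(outcomes)
    counts = {cat: 0 for cat in Category}
    for o in outcomes:
        counts[o.category] += 1
    report = IdentificationReport(
        criterion=criterion,
        rank=rank,
        n_queries=n,
        pct_correct=100.0 * counts[Category.CORRECT] / n,
        pct_ambiguous=100.0 * counts[Category.AMBIGUOUS] / n,
        pct_incorrect=100.0 * counts[Category.INCORRECT] / n,
        pct_no_match=100.0 * counts[Category.NO_MATCH] / n,
    )
    return report, outcomes


def per_genus_report(
    per_query: Sequence[IdentificationOutcome],
    corpus: Corpus,
    min_species: int = 20,
) -> list[dict]:
    """Per-genus unidentified rate at species rank.

    Qualifying genera contain at least ``min_species`` species in the
    corpus; a query counts as unidentified when its outcome is anything
    but CORRECT.  Rates are percentages rounded to 2 decimals.
    """
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    by_query = {o.query_id: o for o in per_query}
    rows = []
    for genus in corpus.genera:
        species_list = corpus.species_of_genus(genus)
        if len(species_list) < min_species:
            continue
        qids = [
            rid
            for sp in species_list
            for rid in corpus.records_of_species(genus, sp)
            if rid in by_query
        ]
        if not qids:
            continue
        n_bad = sum(
            by_query[rid].category is not Category.CORRECT for rid in qids
        )
        rows.append(
            {
                "genus": genus,
                "n_species": len(species_list),
                "n_samples": len(qids),
                "pct_unidentified": round(100.0 * n_bad / len(qids), 2),
            }
        )
    return rows


def write_outcomes_tsv(
    outcomes: Iterable[IdentificationOutcome], path: str | Path
) -> None:
    lines = [IdentificationOutcome.TSV_HEADER]
    lines += [o.to_tsv_row() for o in outcomes]
    Path(path).write_text("\n".join(lines) + "\n")


def write_reports_tsv(
    reports: Iterable[IdentificationReport], path: str | Path
) -> None:
    lines = [IdentificationReport.TSV_HEADER]
    lines += [r.to_tsv_row() for r in reports]
    Path(path).write_text("\n".join(lines) + "\n")
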