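"""Pairwise alignment and genetic distances.

Distances are computed per pair from an optimal global alignment
(Needleman–Wunsch with affine gaps, via Biopython's pairwise aligner).
Aligned columns containing a gap or any non-ACGT symbol in either
sequence are excluded ("pairwise deletion"); the remaining columns give
transition/transversion counts from which either the uncorrected
p-distance or the Kimura 2-parameter (K2P) distance is derived:

    P = transitions / n_compared,  Q = transversions / n_compared
    p  = P + Q
    d_K2P = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

K2P is undefined (NaN) when either logarithm's argument is <= 0
(saturation); NaN entries are counted and excluded downstream.

A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from .seq_model import Corpus

__all__ = [
    "Scoring",
    "GLOBAL_SCORING",
    "LOCAL_SCORING",
    "PairwiseAlignment",
    "DistanceModel",
    "DistanceMatrix",
    "align_global",
    "align_local_score",
    "p_distance",
    "k2p_distance",
    "k2p_from_counts",
    "pairwise_counts",
    "distance_matrices",
    "distance_matrix",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def to_aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


#: default scheme for global alignment feeding the distance computations
GLOBAL_SCORING = Scoring(match=1, mismatch=-1, gap_open=-5, gap_extend=-2)
#: default scheme for local-alignment best-hit search (nucleotide-search-like)
LOCAL_SCORING = Scoring(match=1, mismatch=-3, gap_open=-5, gap_extend=-2)


@dataclass(frozen=True)
class PairwiseAlignment:
    """One aligned pair with site-pattern counts over comparable columns."""

    aligned_a: str
    aligned_b: str
    score: float
    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("substitution counts exceed compared sites")


def _count_columns(aligned_a: str, aligned_b: str) -> tuple[int, int, int]:
    n_comp = n_ts = n_tv = 0
    for x, y in zip(aligned_a, aligned_b):
        if x not in _ACGT or y not in _ACGT:
            continue
        n_comp += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            n_ts += 1
        else:
            n_tv += 1
    return n_comp, n_ts, n_tv


def align_global(
    a: str, b: str, scoring: Scoring = GLOBAL_SCORING
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences with counted site patterns.

    Deterministic: of co-optimal alignments, the aligner's first
    enumeration order is taken.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = scoring.to_aligner("global")
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    n_comp, n_ts, n_tv = _count_columns(sa, sb)
    return PairwiseAlignment(
        aligned_a=sa, aligned_b=sb, score=float(aln.score),
        n_compared=n_comp, n_transitions=n_ts, n_transversions=n_tv,
    )


def align_local_score(
    a: str, b: str, scoring: Scoring = LOCAL_SCORING
) -> float:
    """Optimal local (Smith–Waterman) alignment score only."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return float(scoring.to_aligner("local").score(a, b))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def p_distance(aln: PairwiseAlignment) -> float:
    """Uncorrected proportion of differing comparable sites; NaN if none."""
    if aln.n_compared == 0:
        return math.nan
    return (aln.n_transitions + aln.n_transversions) / aln.n_compared


def k2p_from_counts(n_ts: int, n_tv: int, n_compared: int) -> float:
    """K2P distance from raw counts; NaN at saturation or zero overlap."""
    if n_compared == 0:
        return math.nan
    P = n_ts / n_compared
    Q = n_tv / n_compared
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.nan
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def k2p_distance(aln: PairwiseAlignment) -> float:
    return k2p_from_counts(
        aln.n_transitions, aln.n_transversions, aln.n_compared
    )


class DistanceModel(str, Enum):
    P_DIST = "P_DIST"
    K2P = "K2P"


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labelled records."""

    labels: list[str]
    values: np.ndarray
    model: DistanceModel

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        self.values = v
        self._pos = {lab: i for i, lab in enumerate(self.labels)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self._pos[pair[0]], self._pos[pair[1]]
        return float(self.values[i, j])

    @property
    def n_nan(self) -> int:
        """Count of undefined distances in the upper triangle."""
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def row(self, label: str) -> np.ndarray:
        return self.values[self._pos[label]]

    # -- serialization ------------------------------------------------------
    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(
                lab + "\t" + "\t".join(
                    "nan" if math.isnan(v) else f"{v:.8f}" for v in row
                )
            )
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())

    def to_phylip(self) -> str:
        """Square PHYLIP format (relaxed names, tab-separated)."""
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(
                lab + "\t" + "\t".join(
                    "nan" if math.isnan(v) else f"{v:.8f}" for v in row
                )
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, path: str | Path,
                 model: DistanceModel = DistanceModel.K2P) -> "DistanceMatrix":
        lines = Path(path).read_text().splitlines()
        labels = lines[0].split("\t")[1:]
        rows = [
            [float(x) for x in line.split("\t")[1:]] for line in lines[1:]
        ]
        return cls(labels=labels, values=np.array(rows), model=model)


def pairwise_counts(
    corpus: Corpus, scoring: Scoring = GLOBAL_SCORING
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Align all unordered pairs once; return site-pattern count matrices.

    Returns ``(labels, n_transitions, n_transversions, n_compared)``,
    each matrix symmetric with a zero diagonal.
    """
    records = list(corpus)
    if len(records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    n = len(records)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    aligner = scoring.to_aligner("global")
    for i, j in itertools.combinations(range(n), 2):
        aln = aligner.align(records[i].sequence, records[j].sequence)[0]
        a, b, c = _count_columns(str(aln[0]), str(aln[1]))
        comp[i, j] = comp[j, i] = a
        ts[i, j] = ts[j, i] = b
        tv[i, j] = tv[j, i] = c
    labels = [r.record_id for r in records]
    return labels, ts, tv, comp


def _matrix_from_counts(
    labels: list[str],
    ts: np.ndarray,
    tv: np.ndarray,
    comp: np.ndarray,
    model: DistanceModel,
) -> DistanceMatrix:
    with np.errstate(divide="ignore", invalid="ignore"):
        if model is DistanceModel.P_DIST:
            vals = np.where(comp > 0, (ts + tv) / np.maximum(comp, 1), np.nan)
        else:
            P = ts / np.maximum(comp, 1)
            Q = tv / np.maximum(comp, 1)
            arg1 = 1.0 - 2.0 * P - Q
            arg2 = 1.0 - 2.0 * Q
            ok = (comp > 0) & (arg1 > 0) & (arg2 > 0)
            vals = np.where(
                ok,
                -0.5 * np.log(np.where(ok, arg1, 1.0))
                - 0.25 * np.log(np.where(ok, arg2, 1.0)),
                np.nan,
            )
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels=labels, values=vals, model=model)


def distance_matrices(
    corpus: Corpus,
    models: Sequence[DistanceModel],
    scoring: Scoring = GLOBAL_SCORING,
) -> dict[DistanceModel, DistanceMatrix]:
    """Distance matrices under several models from a single alignment pass."""
    labels, ts, tv, comp = pairwise_counts(corpus, scoring)
    return {
        m: _matrix_from_counts(labels, ts, tv, comp, m) for m in models
    }


def distance_matrix(
    corpus: Corpus,
    model: DistanceModel = DistanceModel.K2P,
    scoring: Scoring = GLOBAL_SCORING,
    warn_nan: bool = True,
) -> DistanceMatrix:
    """All-pairs distances from global alignments (upper triangle mirrored)."""
    dm = distance_matrices(corpus, [model], scoring)[model]
    if dm.n_nan and warn_nan:
        warnings.warn(
            f"{dm.n_nan} pairwise distances undefined under {model.value}",
            stacklevel=2,
        )
    return dm
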