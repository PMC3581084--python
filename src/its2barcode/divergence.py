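"""Barcode-gap statistics and the paired locus comparison.

Six parameters summarize a labelled distance matrix.  Intraspecific,
over species with >= 2 samples:

* ``avg_intra_avg``   — mean over species of the species' mean
  conspecific distance (average intraspecific difference);
* ``avg_intra_max``   — mean over species of the species' maximum
  conspecific distance (average coalescent depth);
* ``avg_intra_between_intra_species`` — mean over all conspecific pairs
  pooled (theta analogue).

Interspecific, over congeneric heterospecific pairs only:

* ``avg_interbyG_avg`` — mean over genera of the genus' mean congeneric
  heterospecific distance (average theta prime);
* ``avg_interbyG_min`` — mean over species of each species' nearest
  heterospecific congener distance (smallest interspecific distance);
* ``avg_between_interbyGenus`` — mean over all congeneric heterospecific
  pairs pooled (average interspecific distance).

Each is reported as mean +/- SD over its averaging units.  Undefined
(NaN) distances are excluded everywhere and counted.

The two barcode loci are compared with a Wilcoxon signed-rank test over
paired per-pair distances (the same sequence pair measured on each
locus): exact two-sided p-value for n <= 25 via the rank-sum null
distribution, normal approximation with tie and continuity correction
beyond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .distance import DistanceMatrix
from .seq_model import Corpus

__all__ = [
    "MeanSD",
    "DivergenceSummary",
    "intraspecific_summary",
    "interspecific_summary",
    "divergence_summary",
    "Direction",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "PairClass",
    "paired_distances",
    "compare_loci",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class MeanSD:
    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.4f} ± {self.sd:.4f}"


def _mean_sd(values: Sequence[float]) -> MeanSD:
    """Mean and sample SD (ddof=1; SD is 0 for a single unit)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return MeanSD(math.nan, math.nan, 0)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return MeanSD(float(arr.mean()), sd, int(arr.size))


@dataclass(frozen=True)
class DivergenceSummary:
    """The six divergence parameters for one locus."""

    avg_intra_avg: MeanSD
    avg_intra_max: MeanSD
    avg_intra_between_intra_species: MeanSD
    avg_interbyG_avg: MeanSD
    avg_interbyG_min: MeanSD
    avg_between_interbyGenus: MeanSD
    n_species_used: int
    n_genera_used: int
    n_nan_excluded: int = 0

    ROW_ORDER = (
        "avg_intra_avg",
        "avg_intra_max",
        "avg_intra_between_intra_species",
        "avg_interbyG_avg",
        "avg_interbyG_min",
        "avg_between_interbyGenus",
    )

    def to_tsv(self) -> str:
        lines = ["parameter\tmean\tsd\tn_units"]
        for name in self.ROW_ORDER:
            m: MeanSD = getattr(self, name)
            lines.append(f"{name}\t{m.mean:.4f}\t{m.sd:.4f}\t{m.n}")
        lines.append(f"# n_species_used={self.n_species_used}")
        lines.append(f"# n_genera_used={self.n_genera_used}")
        lines.append(f"# n_nan_excluded={self.n_nan_excluded}")
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def _finite(values: Iterable[float]) -> tuple[list[float], int]:
    kept, dropped = [], 0
    for v in values:
        if math.isnan(v):
            dropped += 1
        else:
            kept.append(v)
    return kept, dropped


def intraspecific_summary(
    dm: DistanceMatrix, corpus: Corpus
) -> tuple[MeanSD, MeanSD, MeanSD, int, int]:
    """Per-species mean, per-species max, and pooled conspecific distances.

    Returns (avg_intra_avg, avg_intra_max, pooled, n_species_used,
    n_nan_excluded); species need >= 2 samples to contribute.
    """
    per_species_mean, per_species_max, pooled = [], [], []
    n_used = n_nan = 0
    for genus, species in corpus.species:
        rids = corpus.records_of_species(genus, species)
        if len(rids) < 2:
            continue
        dists = [dm[a, b] for a, b in combinations(rids, 2)]
        dists, dropped = _finite(dists)
        n_nan += dropped
        if not dists:
            continue
        n_used += 1
        per_species_mean.append(float(np.mean(dists)))
        per_species_max.append(float(np.max(dists)))
        pooled.extend(dists)
    if n_used == 0:
        raise ValueError(
            "no species with >= 2 samples and defined distances; "
            "intraspecific summary is undefined"
        )
    return (
        _mean_sd(per_species_mean),
        _mean_sd(per_species_max),
        _mean_sd(pooled),
        n_used,
        n_nan,
    )


def interspecific_summary(
    dm: DistanceMatrix, corpus: Corpus
) -> tuple[MeanSD, MeanSD, MeanSD, int, int]:
    """Congeneric heterospecific distance summaries.

    Returns (avg_interbyG_avg, avg_interbyG_min, pooled, n_genera_used,
    n_nan_excluded); genera need >= 2 species to contribute.  Cross-genus
    pairs are never considered.
    """
    per_genus_mean, per_species_nearest, pooled = [], [], []
    n_used = n_nan = 0
    for genus in corpus.genera:
        species_list = corpus.species_of_genus(genus)
        if len(species_list) < 2:
            continue
        genus_dists = []
        nearest: dict[str, float] = {}
        for sp_a, sp_b in combinations(species_list, 2):
            for a in corpus.records_of_species(genus, sp_a):
                for b in corpus.records_of_species(genus, sp_b):
                    d = dm[a, b]
                    if math.isnan(d):
                        n_nan += 1
                        continue
                    genus_dists.append(d)
                    for sp in (sp_a, sp_b):
                        nearest[sp] = min(nearest.get(sp, math.inf), d)
        if not genus_dists:
            continue
        n_used += 1
        per_genus_mean.append(float(np.mean(genus_dists)))
        per_species_nearest.extend(nearest.values())
        pooled.extend(genus_dists)
    if n_used == 0:
        raise ValueError(
            "no genus with >= 2 species and defined distances; "
            "interspecific summary is undefined"
        )
    return (
        _mean_sd(per_genus_mean),
        _mean_sd(per_species_nearest),
        _mean_sd(pooled),
        n_used,
        n_nan,
    )


def divergence_summary(dm: DistanceMatrix, corpus: Corpus) -> DivergenceSummary:
    """All six parameters for one locus run."""
    intra_avg, intra_max, intra_pool, n_sp, nan_i = intraspecific_summary(
        dm, corpus
    )
    inter_avg, inter_min, inter_pool, n_gen, nan_e = interspecific_summary(
        dm, corpus
    )
    return DivergenceSummary(
        avg_intra_avg=intra_avg,
        avg_intra_max=intra_max,
        avg_intra_between_intra_species=intra_pool,
        avg_interbyG_avg=inter_avg,
        avg_interbyG_min=inter_min,
        avg_between_interbyGenus=inter_pool,
        n_species_used=n_sp,
        n_genera_used=n_gen,
        n_nan_excluded=nan_i + nan_e,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

class Direction(str, Enum):
    A_GT_B = "A_GT_B"
    B_GT_A = "B_GT_A"
    NONE = "NONE"


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test of paired samples; differences are b - a.

    ``w_plus`` is the rank sum of pairs where b > a, so direction
    B_GT_A means the second sample tends larger.
    """

    w_plus: float
    w_minus: float
    n: int
    p_value: float
    direction: Direction

    def to_tsv(self) -> str:
        return (
            "w_plus\tw_minus\tn\tp_value\tdirection\n"
            f"{self.w_plus}\t{self.w_minus}\t{self.n}\t"
            f"{self.p_value:.6g}\t{self.direction.value}\n"
        )


def _exact_two_sided_p(ranks2: np.ndarray, w_plus2: float) -> float:
    """Exact p under the sign-flip null via rank-sum convolution.

    ``ranks2`` are midranks doubled to integers; the null distribution of
    the (doubled) positive rank sum is built by polynomial convolution —
    equivalent to enumerating all 2^n sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus2))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on differences b - a.

    Zero differences are dropped; |differences| are ranked with midranks
    for ties.  Exact p-value for n <= 25; otherwise a normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("paired samples must be equal-length 1-D, size >= 1")
    d = b - a
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 0, 1.0, Direction.NONE)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if n <= EXACT_N_MAX:
        p = _exact_two_sided_p(np.round(ranks * 2), w_plus * 2)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 from the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            p = 1.0
        else:
            delta = w_plus - mean
            cc = 0.5 * np.sign(delta)
            z = (delta - cc) / math.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    if w_plus > w_minus:
        direction = Direction.B_GT_A
    elif w_plus < w_minus:
        direction = Direction.A_GT_B
    else:
        direction = Direction.NONE
    return WilcoxonResult(w_plus, w_minus, n, p, direction)


# ---------------------------------------------------------------------------
# Locus comparison
# ---------------------------------------------------------------------------

class PairClass(str, Enum):
    INTRASPECIFIC = "INTRASPECIFIC"
    INTERSPECIFIC = "INTERSPECIFIC"


def _pairs_of_class(corpus: Corpus, kind: PairClass):
    if kind is PairClass.INTRASPECIFIC:
        for genus, species in corpus.species:
            rids = corpus.records_of_species(genus, species)
            yield from combinations(rids, 2)
    else:
        for genus in corpus.genera:
            species_list = corpus.species_of_genus(genus)
            for sp_a, sp_b in combinations(species_list, 2):
                for a in corpus.records_of_species(genus, sp_a):
                    for b in corpus.records_of_species(genus, sp_b):
                        yield (a, b)


def paired_distances(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    corpus: Corpus,
    kind: PairClass,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched per-pair distances under two loci (NaN pairs dropped)."""
    common = set(dm_a.labels) & set(dm_b.labels)
    if not common:
        raise ValueError("distance matrices share no record_ids")
    xs, ys = [], []
    for a, b in _pairs_of_class(corpus, kind):
        if a not in common or b not in common:
            continue
        da, db = dm_a[a, b], dm_b[a, b]
        if math.isnan(da) or math.isnan(db):
            continue
        xs.append(da)
        ys.append(db)
    return np.asarray(xs), np.asarray(ys)


def compare_loci(
    dm_locus1: DistanceMatrix,
    dm_locus2: DistanceMatrix,
    corpus: Corpus,
) -> dict[PairClass, WilcoxonResult]:
    """Wilcoxon signed-rank comparison of two loci per divergence class.

    Pairs at the level of individual sequence pairs: conspecific sample
    pairs for the intraspecific test, congeneric heterospecific pairs for
    the interspecific test.  Direction B_GT_A means locus 2 diverges
    faster.  Classes with no usable pairs are omitted from the result.
    """
    out: dict[PairClass, WilcoxonResult] = {}
    for kind in PairClass:
        xs, ys = paired_distances(dm_locus1, dm_locus2, corpus, kind)
        if xs.size == 0:
            continue
        out[kind] = wilcoxon_signed_rank(xs, ys)
    return out
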