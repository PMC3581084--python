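"""ITS2 excision by conserved-motif placement.

Full-length ITS records are annotated by locating two conserved motifs —
the 3' region of the 5.8S gene and the 5' flank of 28S — with a per-motif
profile model (position-specific log-odds emissions with affine
insert/delete penalties), decoded by Viterbi dynamic programming that is
global over the profile and local over the sequence ("glocal").  The ITS2
interval is everything between the end of the 5.8S placement and the
start of the 28S-flank placement.

Scores are log-odds in bits against a uniform background (0.25 per base);
a placement below the profile's score threshold counts as "motif not
found".  Both orientations are scored and the record is flipped when the
reverse complement wins for both motifs, since database submissions vary
in orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seq_model import Corpus, Region, TaxonRecord

__all__ = [
    "AnnotationStatus",
    "RegionAnnotation",
    "MotifProfile",
    "build_profile",
    "annotate",
    "annotate_corpus",
    "default_profiles",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class AnnotationStatus(str, Enum):
    OK = "OK"
    NO_5_8S = "NO_5_8S"
    NO_FLANK = "NO_FLANK"
    TRUNCATED = "TRUNCATED"


@dataclass(frozen=True)
class RegionAnnotation:
    """Region boundaries (0-based half-open) inferred for one record.

    ``its1`` starts at 0 and therefore includes any leading 18S tail; the
    5' boundary of ITS1 is not refined beyond the 5.8S placement.
    Intervals are ``None`` when the 5.8S motif was not found.
    """

    record_id: str
    its1: tuple[int, int] | None
    r5_8s: tuple[int, int] | None
    its2: tuple[int, int] | None
    score_5_8s: float
    score_flank: float
    status: AnnotationStatus
    flipped: bool = False

    TSV_HEADER = (
        "record_id\tits1_start\tits1_end\tr5_8s_start\tr5_8s_end\t"
        "its2_start\tits2_end\tscore_5_8s\tscore_flank\tstatus\tflipped"
    )

    def to_tsv_row(self) -> str:
        def iv(t):
            return f"{t[0]}\t{t[1]}" if t is not None else ".\t."

        return (
            f"{self.record_id}\t{iv(self.its1)}\t{iv(self.r5_8s)}\t"
            f"{iv(self.its2)}\t{self.score_5_8s:.2f}\t{self.score_flank:.2f}\t"
            f"{self.status.value}\t{int(self.flipped)}"
        )


@dataclass(frozen=True)
class MotifProfile:
    """Position-specific scoring profile for one conserved motif.

    ``log_odds`` is an (L, 4) array of log2(p/0.25) per match position and
    base (A, C, G, T order).  Insertions and deletions relative to the
    profile carry affine penalties in bits (negative values).
    """

    name: str
    log_odds: np.ndarray
    insert_open: float = -6.0
    insert_extend: float = -1.0
    delete_open: float = -6.0
    delete_extend: float = -1.0
    score_threshold: float = 10.0

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        if lo.ndim != 2 or lo.shape[1] != 4:
            raise ValueError("log_odds must be an (L, 4) array")
        if lo.shape[0] < 10:
            raise ValueError("profile length must be >= 10 positions")
        object.__setattr__(self, "log_odds", lo)

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[0])

    # -- serialization ------------------------------------------------------
    def to_tsv(self) -> str:
        lines = [
            f"# name={self.name}",
            f"# insert_open={self.insert_open}",
            f"# insert_extend={self.insert_extend}",
            f"# delete_open={self.delete_open}",
            f"# delete_extend={self.delete_extend}",
            f"# score_threshold={self.score_threshold}",
            "position\tlogodds_A\tlogodds_C\tlogodds_G\tlogodds_T",
        ]
        for pos, row in enumerate(self.log_odds):
            lines.append(
                f"{pos}\t" + "\t".join(f"{v:.6f}" for v in row)
            )
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifProfile":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("position"):
                rows.append([float(x) for x in line.split("\t")[1:5]])
        return cls(
            name=meta.get("name", "profile"),
            log_odds=np.array(rows),
            insert_open=float(meta.get("insert_open", -6.0)),
            insert_extend=float(meta.get("insert_extend", -1.0)),
            delete_open=float(meta.get("delete_open", -6.0)),
            delete_extend=float(meta.get("delete_extend", -1.0)),
            score_threshold=float(meta.get("score_threshold", 10.0)),
        )


def build_profile(
    aligned_references: Sequence[str],
    pseudocount: float = 0.5,
    name: str = "profile",
    **kwargs,
) -> MotifProfile:
    """Build a profile from an alignment of reference motif sequences.

    Columns with more than 50% gap characters are dropped from the
    match-state set.  Per kept column, the emission probability of base b
    is (count_b + pseudocount) / (n_observed + 4*pseudocount), converted
    to log2 odds against the uniform 0.25 background.
    """
    refs = [r.upper().replace("U", "T") for r in aligned_references]
    if len(refs) < 2:
        raise ValueError("need at least 2 reference sequences")
    L = len(refs[0])
    if any(len(r) != L for r in refs):
        raise ValueError("reference sequences must have equal aligned length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    rows = []
    for col in range(L):
        column = [r[col] for r in refs]
        n_gap = sum(c == "-" for c in column)
        if n_gap * 2 > len(column):
            continue
        counts = np.zeros(4)
        for c in column:
            if c in _BASE_INDEX:
                counts[_BASE_INDEX[c]] += 1
        total = counts.sum()
        probs = (counts + pseudocount) / (total + 4.0 * pseudocount)
        with np.errstate(divide="ignore"):
            rows.append(np.log2(probs / 0.25))
    return MotifProfile(name=name, log_odds=np.array(rows), **kwargs)


# ---------------------------------------------------------------------------
# Glocal Viterbi placement
# ---------------------------------------------------------------------------

_NEG = -1e30


def _encode(seq: str) -> np.ndarray:
    """Base indices 0..3; ambiguity codes map to 4 (background emission)."""
    out = np.full(len(seq), 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def find_motif(profile: MotifProfile, sequence: str) -> tuple[float, int, int]:
    """Best glocal placement of ``profile`` in ``sequence``.

    Returns ``(score_bits, start, end)`` with [start, end) the placed
    window, 0-based half-open.  The profile must be fully traversed
    (matches or deletions); the sequence is free outside the window.
    Deterministic: earliest end, then the latest compatible start among
    ties, is reported.
    """
    L = profile.length
    n = len(sequence)
    if n == 0:
        return (_NEG, 0, 0)
    enc = _encode(sequence)
    # emission table with a zero-score background row for ambiguity codes
    emit = np.vstack([profile.log_odds.T, np.zeros(L)])  # (5, L)

    io, ie = profile.insert_open, profile.insert_extend
    do, de = profile.delete_open, profile.delete_extend
    cols = np.arange(L + 1)

    def d_from_m(m_row: np.ndarray, s_row: np.ndarray):
        """Collapsed M->D...D chain via prefix max; returns (D, SD) rows."""
        b = m_row[:-1] - cols[:-1] * de  # k = 0..L-1
        acc = np.maximum.accumulate(b)
        # index of the (last) k achieving the running max
        marks = np.where(b >= acc, np.arange(L), 0)
        kbest = np.maximum.accumulate(marks)
        d = np.full(L + 1, _NEG)
        sd = np.zeros(L + 1, dtype=np.int64)
        d[1:] = acc + do + (cols[1:] - 1) * de
        sd[1:] = s_row[kbest]
        return d, sd

    # rows indexed by consumed profile positions j = 0..L
    M = np.full(L + 1, _NEG)
    M[0] = 0.0
    I = np.full(L + 1, _NEG)
    SM = np.zeros(L + 1, dtype=np.int64)
    SI = np.zeros(L + 1, dtype=np.int64)
    D, SD = d_from_m(M, SM)

    best_score, best_start, best_end = _NEG, 0, 0
    for i in range(1, n + 1):
        c = enc[i - 1]
        # M: align char i-1 to profile position j
        stacked = np.stack([M[:-1], I[:-1], D[:-1]])
        starts = np.stack([SM[:-1], SI[:-1], SD[:-1]])
        w = np.argmax(stacked, axis=0)
        newM = np.full(L + 1, _NEG)
        newSM = np.zeros(L + 1, dtype=np.int64)
        newM[1:] = emit[c] + np.take_along_axis(
            stacked, w[None, :], 0
        )[0]
        newSM[1:] = np.take_along_axis(starts, w[None, :], 0)[0]
        newM[0] = 0.0
        newSM[0] = i  # fresh start: window would begin at char i
        # correct fresh-start bookkeeping for j=1..L entered from column 0:
        # column 0 of the PREVIOUS row had start == i-1 by construction
        newI = np.full(L + 1, _NEG)
        from_open = M + io
        from_ext = I + ie
        takeo = from_open >= from_ext
        newI[1:] = np.where(takeo, from_open, from_ext)[1:]
        newSI = np.where(takeo, SM, SI)
        M, SM = newM, newSM
        I, SI = newI, newSI
        D, SD = d_from_m(M, SM)
        end_here = max(M[L], D[L])
        if end_here > best_score:
            best_score = float(end_here)
            best_end = i
            best_start = int(SM[L] if M[L] >= D[L] else SD[L])
    return best_score, best_start, best_end


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def annotate(
    record: TaxonRecord,
    profile_5_8s: MotifProfile,
    profile_flank: MotifProfile,
) -> RegionAnnotation:
    """Delimit ITS1 / 5.8S / ITS2 on one full-length ITS record."""
    seq = record.sequence
    fwd_58 = find_motif(profile_5_8s, seq)
    fwd_fl = find_motif(profile_flank, seq)
    rc = _revcomp(seq)
    rev_58 = find_motif(profile_5_8s, rc)
    rev_fl = find_motif(profile_flank, rc)

    flipped = rev_58[0] > fwd_58[0] and rev_fl[0] > fwd_fl[0]
    if flipped:
        seq, s58, sfl = rc, rev_58, rev_fl
    else:
        s58, sfl = fwd_58, fwd_fl
    score58, start58, end58 = s58
    scorefl, startfl, endfl = sfl
    n = len(seq)

    found58 = score58 >= profile_5_8s.score_threshold
    foundfl = scorefl >= profile_flank.score_threshold

    if not found58:
        return RegionAnnotation(
            record.record_id, None, None, None,
            score58, scorefl, AnnotationStatus.NO_5_8S, flipped,
        )

    status = AnnotationStatus.OK
    if foundfl and startfl < end58:
        # placements conflict: reject the lower-scoring motif
        if scorefl < score58:
            foundfl = False
            status = AnnotationStatus.NO_FLANK
        else:
            return RegionAnnotation(
                record.record_id, None, None, None,
                score58, scorefl, AnnotationStatus.NO_5_8S, flipped,
            )
    if not foundfl:
        if status is not AnnotationStatus.NO_FLANK:
            status = AnnotationStatus.TRUNCATED
        its2_end = n
    else:
        its2_end = startfl

    return RegionAnnotation(
        record_id=record.record_id,
        its1=(0, start58),
        r5_8s=(start58, end58),
        its2=(end58, its2_end),
        score_5_8s=score58,
        score_flank=scorefl,
        status=status,
        flipped=flipped,
    )


def annotate_corpus(
    corpus: Corpus,
    profile_5_8s: MotifProfile,
    profile_flank: MotifProfile,
) -> tuple[Corpus, list[RegionAnnotation]]:
    """Annotate every record and excise ITS2 where it was delimited.

    The returned corpus keeps only records with status OK or TRUNCATED,
    re-tagged ``region=ITS2``; the annotation table covers all inputs.
    """
    annotations = []
    kept = []
    for rec in corpus:
        ann = annotate(rec, profile_5_8s, profile_flank)
        annotations.append(ann)
        if ann.status in (AnnotationStatus.OK, AnnotationStatus.TRUNCATED):
            seq = rec.sequence
            if ann.flipped:
                seq = _revcomp(seq)
            lo, hi = ann.its2
            if hi > lo:
                kept.append(
                    TaxonRecord(rec.record_id, rec.genus, rec.species,
                                seq[lo:hi], Region.ITS2)
                )
    return Corpus(kept), annotations


def write_annotation_table(
    annotations: Iterable[RegionAnnotation], path: str | Path
) -> None:
    lines = [RegionAnnotation.TSV_HEADER]
    lines += [a.to_tsv_row() for a in annotations]
    Path(path).write_text("\n".join(lines) + "\n")


def default_profiles(
    pseudocount: float = 0.5,
    score_threshold: float = 10.0,
    n_references: int = 8,
    reference_noise: float = 0.01,
    seed: int = 20130117,
) -> tuple[MotifProfile, MotifProfile]:
    """Profiles for the synthetic 5.8S and 28S-flank reference motifs.

    Built from lightly perturbed copies of the fixed synthetic motifs, the
    way a real profile would be built from an alignment of annotated
    database sequences.  These are synthetic stand-ins: for biological
    work, build profiles from a real reference alignment instead.
    """
    from .synthetic import REF_5_8S, REF_FLANK_28S

    rng = np.random.default_rng(seed)

    def refs(motif: str) -> list[str]:
        out = []
        for _ in range(n_references):
            chars = list(motif)
            for pos in np.flatnonzero(rng.random(len(chars)) < reference_noise):
                chars[pos] = "ACGT"[rng.integers(0, 4)]
            out.append("".join(chars))
        return out

    p58 = build_profile(refs(REF_5_8S), pseudocount, name="5_8S",
                        score_threshold=score_threshold)
    pfl = build_profile(refs(REF_FLANK_28S), pseudocount, name="28S_flank",
                        score_threshold=score_threshold)
    return p58, pfl
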