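"""Synthetic barcode-corpus generator.

Emits corpora with the structure the downstream analyses assume: a
genus/species/sample hierarchy with unequal sampling, intraspecific
divergence well below interspecific divergence (a "barcode gap"), and a
composite ribosomal architecture

    [18S tail flank] ITS1 [5.8S] ITS2 [28S head flank]

in which the 5.8S gene and the flanks are nearly invariant while the two
spacers evolve freely.  Spacer/conserved divergence parameters are the
EXPECTED PAIRWISE divergence between two tips: each branch (species
ancestor from genus root, sample from species ancestor) mutates sites
independently with per-site probability d/2, so that two sister tips
differ at ~d of spacer sites for small d.

Everything is deterministic given the seed.  The conserved reference
motifs are fixed synthetic sequences (not real rRNA), so no download is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_model import Corpus, Region, TaxonRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "TruthEntry",
    "simulate_corpus",
    "excise_true_region",
    "REF_5_8S",
    "REF_FLANK_18S",
    "REF_FLANK_28S",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
#: transition partner of each base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])


def _fixed_motif(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


#: Fixed synthetic 160-nt stand-in for the conserved 5.8S gene.
REF_5_8S = _fixed_motif(160, 58)
#: Fixed synthetic 60-nt stand-in for the 3' end of 18S (leading flank).
REF_FLANK_18S = _fixed_motif(60, 18)
#: Fixed synthetic 60-nt stand-in for the 5' end of 28S (trailing flank).
REF_FLANK_28S = _fixed_motif(60, 28)


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and divergence regime of a simulated corpus.

    Length defaults centre the full ITS near 634 nt (ITS1 ~240 + 5.8S 160
    + ITS2 ~233) and ITS2 near 233 nt, the average lengths of the two
    regions in large plant surveys.  Divergence defaults sit in the regime
    of published ITS barcode-gap tables: mean intraspecific distance just
    above 0.01, mean congeneric interspecific distance near 0.07.
    """

    n_genera: int = 20
    species_per_genus: tuple[int, int] = (2, 8)
    samples_per_species: tuple[int, int] = (1, 4)
    len_its1: tuple[int, int] = (225, 255)
    len_5_8s: tuple[int, int] = (160, 160)
    len_its2: tuple[int, int] = (218, 248)
    len_flank: tuple[int, int] = (60, 60)
    d_intra: float = 0.015
    d_inter: float = 0.07
    conserved_rate_5_8s: float = 0.002
    indel_rate: float = 0.001
    ts_tv_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.d_intra < self.d_inter <= 0.75):
            raise ValueError("require 0 <= d_intra < d_inter <= 0.75")
        if self.conserved_rate_5_8s > self.d_intra:
            raise ValueError("conserved_rate_5_8s must not exceed d_intra")
        for name in ("species_per_genus", "samples_per_species",
                     "len_its1", "len_5_8s", "len_its2", "len_flank"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")


@dataclass(frozen=True)
class TruthEntry:
    """Ground-truth region boundaries (0-based half-open) and taxonomy."""

    record_id: str
    genus: str
    species: str
    its1_start: int
    its1_end: int      # == 5.8S start
    r5_8s_end: int     # == ITS2 start
    its2_end: int
    seq_length: int

    @property
    def its_full(self) -> tuple[int, int]:
        return (self.its1_start, self.its2_end)

    @property
    def its1(self) -> tuple[int, int]:
        return (self.its1_start, self.its1_end)

    @property
    def r5_8s(self) -> tuple[int, int]:
        return (self.its1_end, self.r5_8s_end)

    @property
    def its2(self) -> tuple[int, int]:
        return (self.r5_8s_end, self.its2_end)


@dataclass
class SyntheticTruth:
    """Per-record truth plus the ancestral sequences the corpus grew from."""

    entries: dict[str, TruthEntry]
    genus_roots: dict[str, str]
    species_ancestors: dict[tuple[str, str], str]

    def __getitem__(self, record_id: str) -> TruthEntry:
        return self.entries[record_id]

    def to_tsv(self) -> str:
        lines = ["record_id\tits1_start\tits1_end\tr5_8s_end\tits2_end"]
        for e in self.entries.values():
            lines.append(
                f"{e.record_id}\t{e.its1_start}\t{e.its1_end}\t"
                f"{e.r5_8s_end}\t{e.its2_end}"
            )
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


# ---------------------------------------------------------------------------
# Mutation machinery (arrays of base indices 0..3)
# ---------------------------------------------------------------------------

def _seq_to_idx(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)


def _idx_to_seq(idx: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in idx)


def _mutate(idx: np.ndarray, rate: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``.

    A substituted site becomes its transition partner with probability
    kappa/(kappa+2) and each of the two transversion partners with
    probability 1/(kappa+2).
    """
    out = idx.copy()
    if rate <= 0 or len(idx) == 0:
        return out
    hit = rng.random(len(idx)) < rate
    n = int(hit.sum())
    if n == 0:
        return out
    u = rng.random(n)
    p_ts = kappa / (kappa + 2.0)
    old = out[hit]
    new = np.where(
        u < p_ts,
        _TRANSITION[old],
        # transversion: pick one of the two partners of opposite ring type
        np.where(
            u < p_ts + (1.0 - p_ts) / 2.0,
            _tv_partner(old, 0),
            _tv_partner(old, 1),
        ),
    )
    out[hit] = new
    return out


def _tv_partner(old: np.ndarray, which: int) -> np.ndarray:
    """The two transversion partners of each base index.

    Purines {A=0, G=2} pair with pyrimidines {C=1, T=3} and vice versa.
    """
    purine = (old % 2) == 0
    first = np.where(purine, 1, 0)   # C for purines, A for pyrimidines
    second = np.where(purine, 3, 2)  # T for purines, G for pyrimidines
    return first if which == 0 else second


def _apply_indels(idx: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Single-base insertions/deletions, each site hit with prob ``rate``."""
    if rate <= 0 or len(idx) == 0:
        return idx
    hit = np.flatnonzero(rng.random(len(idx)) < rate)
    if len(hit) == 0:
        return idx
    out = idx
    # process right-to-left so earlier positions stay valid
    for pos in hit[::-1]:
        if rng.random() < 0.5 and len(out) > 1:
            out = np.delete(out, pos)
        else:
            out = np.insert(out, pos, rng.integers(0, 4))
    return out


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _draw_len(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def simulate_corpus(
    config: SimulationConfig,
) -> tuple[Corpus, SyntheticTruth]:
    """Grow a corpus from per-genus root sequences.

    Per genus: spacers are uniform-random, conserved segments are copied
    from the fixed reference motifs.  Species ancestors mutate spacer
    sites at d_inter/2 and conserved sites at conserved_rate_5_8s/2;
    samples mutate from their species ancestor at d_intra/2 (spacers) and
    conserved_rate_5_8s/2 (conserved).  Indels (single-base) are applied
    only in spacers, after substitutions.
    """
    rng = np.random.default_rng(config.seed)
    kappa = config.ts_tv_ratio
    half = 0.5  # branch rate = pairwise divergence / 2

    flank5 = _seq_to_idx(REF_FLANK_18S)
    flank3 = _seq_to_idx(REF_FLANK_28S)
    r58_ref = _seq_to_idx(REF_5_8S)

    records: list[TaxonRecord] = []
    entries: dict[str, TruthEntry] = {}
    genus_roots: dict[str, str] = {}
    species_ancestors: dict[tuple[str, str], str] = {}

    for gi in range(config.n_genera):
        genus = f"Genus{gi + 1:03d}"
        its1_len = _draw_len(rng, config.len_its1)
        its2_len = _draw_len(rng, config.len_its2)
        r58_len = _draw_len(rng, config.len_5_8s)
        flank_len = _draw_len(rng, config.len_flank)
        root = {
            "flank5": flank5[:flank_len].copy(),
            "its1": rng.integers(0, 4, size=its1_len),
            "r58": r58_ref[:r58_len].copy(),
            "its2": rng.integers(0, 4, size=its2_len),
            "flank3": flank3[:flank_len].copy(),
        }
        genus_roots[genus] = _idx_to_seq(
            np.concatenate(list(root.values()))
        )
        n_species = int(rng.integers(config.species_per_genus[0],
                                     config.species_per_genus[1] + 1))
        for si in range(n_species):
            species = f"species{si + 1:03d}"
            anc = {
                "flank5": _mutate(root["flank5"],
                                  config.conserved_rate_5_8s * half,
                                  kappa, rng),
                "its1": _mutate(root["its1"], config.d_inter * half,
                                kappa, rng),
                "r58": _mutate(root["r58"],
                               config.conserved_rate_5_8s * half,
                               kappa, rng),
                "its2": _mutate(root["its2"], config.d_inter * half,
                                kappa, rng),
                "flank3": _mutate(root["flank3"],
                                  config.conserved_rate_5_8s * half,
                                  kappa, rng),
            }
            species_ancestors[(genus, species)] = _idx_to_seq(
                np.concatenate(list(anc.values()))
            )
            n_samples = int(rng.integers(config.samples_per_species[0],
                                         config.samples_per_species[1] + 1))
            for ki in range(n_samples):
                rid = f"G{gi + 1:03d}S{si + 1:03d}R{ki + 1:02d}"
                segs = {
                    "flank5": _mutate(anc["flank5"],
                                      config.conserved_rate_5_8s * half,
                                      kappa, rng),
                    "its1": _mutate(anc["its1"], config.d_intra * half,
                                    kappa, rng),
                    "r58": _mutate(anc["r58"],
                                   config.conserved_rate_5_8s * half,
                                   kappa, rng),
                    "its2": _mutate(anc["its2"], config.d_intra * half,
                                    kappa, rng),
                    "flank3": _mutate(anc["flank3"],
                                      config.conserved_rate_5_8s * half,
                                      kappa, rng),
                }
                segs["its1"] = _apply_indels(segs["its1"],
                                             config.indel_rate, rng)
                segs["its2"] = _apply_indels(segs["its2"],
                                             config.indel_rate, rng)
                lens = {k: len(v) for k, v in segs.items()}
                seq = _idx_to_seq(np.concatenate(list(segs.values())))
                its1_start = lens["flank5"]
                its1_end = its1_start + lens["its1"]
                r58_end = its1_end + lens["r58"]
                its2_end = r58_end + lens["its2"]
                records.append(
                    TaxonRecord(rid, genus, species, seq, Region.ITS_FULL)
                )
                entries[rid] = TruthEntry(
                    record_id=rid, genus=genus, species=species,
                    its1_start=its1_start, its1_end=its1_end,
                    r5_8s_end=r58_end, its2_end=its2_end,
                    seq_length=len(seq),
                )

    truth = SyntheticTruth(entries, genus_roots, species_ancestors)
    return Corpus(records), truth


def excise_true_region(
    corpus: Corpus, truth: SyntheticTruth, region: Region
) -> Corpus:
    """Cut every record down to its true region using generator truth."""
    if region not in (Region.ITS_FULL, Region.ITS1, Region.R5_8S, Region.ITS2):
        raise ValueError(f"cannot excise region {region}")

    def cut(rec: TaxonRecord) -> str:
        try:
            e = truth[rec.record_id]
        except KeyError:
            raise ValueError(
                f"record {rec.record_id!r} absent from truth"
            ) from None
        if region is Region.ITS_FULL:
            lo, hi = e.its_full
        elif region is Region.ITS1:
            lo, hi = e.its1
        elif region is Region.R5_8S:
            lo, hi = e.r5_8s
        else:
            lo, hi = e.its2
        return rec.sequence[lo:hi]

    return corpus.map_sequences(cut, region=region)
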