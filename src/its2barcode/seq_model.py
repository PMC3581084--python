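"""Core sequence data model: records, corpora, I/O and curation.

A barcode corpus is a collection of nuclear ribosomal ITS (or ITS2)
sequences, each labelled with a genus and species.  Sequences travel as
FASTA; taxonomy travels in a sidecar TSV (``record_id  genus  species``)
because description-line formats in public databases are too inconsistent
to parse reliably.  Curation applies the pre-analysis filters: drop
sequences shorter than a minimum length (default 100 bp) and drop records
without a usable genus+species label.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Region",
    "TaxonRecord",
    "Corpus",
    "CurationReport",
    "read_corpus",
    "write_corpus",
    "curate",
    "corpus_summary",
    "CorpusSummary",
]

#: IUPAC nucleotide codes plus gap; 'U' is normalized to 'T' on ingest.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

_WS = re.compile(r"\s+")


class Region(str, Enum):
    """Which part of the ribosomal cistron a sequence represents."""

    ITS_FULL = "ITS_FULL"
    ITS1 = "ITS1"
    R5_8S = "R5_8S"
    ITS2 = "ITS2"
    UNKNOWN = "UNKNOWN"


def normalize_sequence(raw: str) -> str:
    """Uppercase, convert RNA 'U' to 'T', and validate the alphabet."""
    seq = raw.strip().upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)!r}")
    return seq


def normalize_name(name: str) -> str:
    """Collapse whitespace and strip a taxon name component."""
    return _WS.sub(" ", name.strip())


@dataclass(frozen=True)
class TaxonRecord:
    """One sequence with its taxonomic labels and region tag."""

    record_id: str
    genus: str
    species: str
    sequence: str
    region: Region = Region.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        object.__setattr__(self, "genus", normalize_name(self.genus))
        object.__setattr__(self, "species", normalize_name(self.species))

    @property
    def taxon(self) -> tuple[str, str]:
        """The (genus, species) pair used for identity throughout."""
        return (self.genus, self.species)

    def __len__(self) -> int:
        return len(self.sequence)


class Corpus:
    """Ordered collection of :class:`TaxonRecord` with taxonomy indices.

    Species identity is exact string match on the normalized
    (genus, species) pair; no synonym resolution is attempted.
    """

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: "OrderedDict[str, TaxonRecord]" = OrderedDict()
        for rec in records:
            if rec.record_id in self._records:
                raise ValueError(f"duplicate record_id: {rec.record_id!r}")
            self._records[rec.record_id] = rec
        # genus -> species -> [record_id]
        self._index: dict[str, dict[str, list[str]]] = {}
        for rec in self._records.values():
            self._index.setdefault(rec.genus, {}).setdefault(
                rec.species, []
            ).append(rec.record_id)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self._records.values())

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __getitem__(self, record_id: str) -> TaxonRecord:
        return self._records[record_id]

    # -- views --------------------------------------------------------------
    @property
    def record_ids(self) -> list[str]:
        return list(self._records)

    @property
    def genera(self) -> list[str]:
        return sorted(self._index)

    @property
    def species(self) -> list[tuple[str, str]]:
        return sorted(
            (g, s) for g, sp in self._index.items() for s in sp
        )

    def records_of_species(self, genus: str, species: str) -> list[str]:
        return list(self._index.get(genus, {}).get(species, []))

    def species_of_genus(self, genus: str) -> list[str]:
        return sorted(self._index.get(genus, {}))

    @property
    def n_species(self) -> int:
        return sum(len(sp) for sp in self._index.values())

    @property
    def n_genera(self) -> int:
        return len(self._index)

    def map_sequences(self, fn, region: Region | None = None) -> "Corpus":
        """New corpus with ``fn(record) -> sequence`` applied to every record."""
        out = []
        for rec in self:
            new_seq = fn(rec)
            out.append(
                replace(rec, sequence=new_seq, region=region or rec.region)
            )
        return Corpus(out)

    def subset(self, record_ids: Iterable[str]) -> "Corpus":
        """Sub-corpus restricted to ``record_ids``, ingest order preserved."""
        wanted = set(record_ids)
        return Corpus(rec for rec in self if rec.record_id in wanted)


@dataclass(frozen=True)
class CurationReport:
    """Bookkeeping for the pre-analysis filters; counts partition the input."""

    n_input: int
    n_removed_short: int
    n_removed_unlabelled: int
    n_kept: int
    min_length_bp: int

    def __post_init__(self) -> None:
        if self.n_input != (
            self.n_removed_short + self.n_removed_unlabelled + self.n_kept
        ):
            raise ValueError("curation counts do not partition the input")

    def to_tsv(self) -> str:
        head = "n_input\tn_removed_short\tn_removed_unlabelled\tn_kept\tmin_length_bp"
        row = (
            f"{self.n_input}\t{self.n_removed_short}\t"
            f"{self.n_removed_unlabelled}\t{self.n_kept}\t{self.min_length_bp}"
        )
        return head + "\n" + row + "\n"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_taxonomy(taxonomy_path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a ``record_id\\tgenus\\tspecies`` TSV into a mapping."""
    table: dict[str, tuple[str, str]] = {}
    with open(taxonomy_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["record_id", "genus", "species"]:
            raise ValueError(
                f"taxonomy header must be record_id/genus/species, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{taxonomy_path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            rid, genus, species = parts[0], parts[1], parts[2]
            if rid in table:
                raise ValueError(f"duplicate taxonomy entry for {rid!r}")
            table[rid] = (genus, species)
    return table


def read_corpus(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    region: Region = Region.UNKNOWN,
    *,
    parse_descriptions: bool = False,
) -> Corpus:
    """Load a FASTA + taxonomy-TSV pair into a :class:`Corpus`.

    Every FASTA record ID must appear in the taxonomy table.  With
    ``parse_descriptions=True`` a missing entry falls back to reading
    "Genus species" from the FASTA description line (off by default:
    description formats are unreliable).
    """
    taxonomy = read_taxonomy(taxonomy_path)
    records = []
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = seqrec.id
        if rid in taxonomy:
            genus, species = taxonomy[rid]
        elif parse_descriptions:
            words = seqrec.description.split()
            # drop the ID token if the description repeats it
            if words and words[0] == rid:
                words = words[1:]
            if len(words) < 2:
                raise ValueError(
                    f"record {rid!r} absent from taxonomy and description "
                    "does not contain 'Genus species'"
                )
            genus, species = words[0], words[1]
        else:
            raise ValueError(f"record {rid!r} missing from taxonomy table")
        records.append(
            TaxonRecord(rid, genus, species, str(seqrec.seq), region)
        )
    return Corpus(records)


def write_corpus(
    corpus: Corpus,
    fasta_path: str | Path,
    taxonomy_path: str | Path | None = None,
    *,
    line_width: int = 70,
) -> None:
    """Write FASTA (wrapped) and, optionally, the taxonomy sidecar TSV."""
    seqrecs = [
        SeqRecord(Seq(rec.sequence), id=rec.record_id, description="")
        for rec in corpus
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seqrecs)
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            fh.write("record_id\tgenus\tspecies\n")
            for rec in corpus:
                fh.write(f"{rec.record_id}\t{rec.genus}\t{rec.species}\n")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def curate(
    corpus: Corpus, min_length_bp: int = 100
) -> tuple[Corpus, CurationReport]:
    """Apply the pre-analysis filters.

    Removes, in order: sequences shorter than ``min_length_bp``
    (ungapped length), then records whose genus or species label is
    empty.  A record failing both tests is counted once, as short.
    """
    if min_length_bp < 1:
        raise ValueError("min_length_bp must be >= 1")
    kept, n_short, n_unlabelled = [], 0, 0
    for rec in corpus:
        if len(rec.sequence.replace("-", "")) < min_length_bp:
            n_short += 1
        elif not rec.genus or not rec.species:
            n_unlabelled += 1
        else:
            kept.append(rec)
    report = CurationReport(
        n_input=len(corpus),
        n_removed_short=n_short,
        n_removed_unlabelled=n_unlabelled,
        n_kept=len(kept),
        min_length_bp=min_length_bp,
    )
    return Corpus(kept), report


@dataclass(frozen=True)
class CorpusSummary:
    n_samples: int
    n_genera: int
    n_species: int
    mean_length: float

    def as_tuple(self) -> tuple[int, int, int, float]:
        return (self.n_samples, self.n_genera, self.n_species, self.mean_length)


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Sample/genus/species counts and mean sequence length (1 decimal)."""
    if len(corpus) == 0:
        raise ValueError("cannot summarize an empty corpus")
    lengths = [len(rec) for rec in corpus]
    return CorpusSummary(
        n_samples=len(corpus),
        n_genera=corpus.n_genera,
        n_species=corpus.n_species,
        mean_length=round(sum(lengths) / len(lengths), 1),
    )
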