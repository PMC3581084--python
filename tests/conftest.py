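"""Shared fixtures: tiny hand-built corpora and seeded synthetic ones."""

from __future__ import annotations

import numpy as np
import pytest

from its2barcode import (
    Corpus,
    Region,
    SimulationConfig,
    TaxonRecord,
    default_profiles,
    simulate_corpus,
)
from its2barcode.distance import DistanceMatrix, DistanceModel


def make_corpus(rows, region=Region.UNKNOWN) -> Corpus:
    """Corpus from (record_id, genus, species, sequence) tuples."""
    return Corpus(TaxonRecord(*row, region) for row in rows)


def dm_from_pairs(labels, pairs, model=DistanceModel.P_DIST) -> DistanceMatrix:
    """Distance matrix from a {(a, b): d} dict (symmetrized)."""
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    vals = np.zeros((n, n))
    for (a, b), d in pairs.items():
        vals[pos[a], pos[b]] = vals[pos[b], pos[a]] = d
    return DistanceMatrix(labels=list(labels), values=vals, model=model)


def random_toy_corpus(rng: np.random.Generator, n_max: int = 16) -> Corpus:
    """Small random corpus of short ungapped sequences for oracle tests.

    Sequences are mutated copies of per-species templates so that
    conspecific records are usually (not always) each other's nearest
    neighbours; some species are singletons.
    """
    n_genera = int(rng.integers(2, 4))
    records = []
    k = 0
    while True:
        for g in range(n_genera):
            base = rng.integers(0, 4, size=int(rng.integers(40, 70)))
            for s in range(int(rng.integers(1, 4))):
                tmpl = base.copy()
                hit = rng.random(len(tmpl)) < 0.08
                tmpl[hit] = rng.integers(0, 4, size=int(hit.sum()))
                for r in range(int(rng.integers(1, 3))):
                    seq = tmpl.copy()
                    hit = rng.random(len(seq)) < 0.02
                    seq[hit] = rng.integers(0, 4, size=int(hit.sum()))
                    k += 1
                    records.append(
                        TaxonRecord(
                            f"r{k:03d}", f"G{g}", f"sp{s}",
                            "".join("ACGT"[i] for i in seq),
                        )
                    )
                    if k >= n_max:
                        return Corpus(records)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded corpus with truth, shared across tests."""
    cfg = SimulationConfig(
        n_genera=5,
        species_per_genus=(2, 4),
        samples_per_species=(2, 3),
        seed=101,
    )
    return cfg, *simulate_corpus(cfg)
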