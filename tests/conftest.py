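"""Shared fixtures and the naive all-substrings alignment oracle.

The oracle deliberately avoids the package's index machinery: it scans
every reference window on both strands with a vectorised Hamming
comparison, so index/classifier results can be checked against it exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from sigmeta.classify import classify_sample, fragment_reads
from sigmeta.index import build_index, revcomp
from sigmeta.simulate import default_fixture
from sigmeta.taxonomy import TaxonNode, Taxonomy, curate_references

_VALID_CODES = frozenset(b"ACGT")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class OracleIndex:
    """Brute-force Hamming scan over all reference windows, both strands."""

    def __init__(self, curated, k: int = 50):
        self.k = k
        stacks: dict[int, list[np.ndarray]] = {}
        for ref in curated:
            for strand in (ref.seq, revcomp(ref.seq)):
                if len(strand) < k:
                    continue
                arr = np.lib.stride_tricks.sliding_window_view(_encode(strand), k)
                valid = np.isin(arr, list(_VALID_CODES)).all(axis=1)
                if valid.any():
                    stacks.setdefault(ref.taxid, []).append(arr[valid])
        self.windows = {t: np.vstack(v) for t, v in stacks.items()}

    def search(self, kmer: str, max_mm: int = 3) -> frozenset:
        q = _encode(kmer)
        if not _VALID_CODES.issuperset(q.tolist()):
            return frozenset()
        hits = set()
        for taxid, arr in self.windows.items():
            if ((arr != q).sum(axis=1) <= max_mm).any():
                hits.add(taxid)
        return frozenset(hits)


def oracle_classify(fragments, oracle: OracleIndex, max_mm: int = 3, genus_map=None):
    """Independent re-implementation of the per-taxon counting rules."""
    per_taxon: dict[int, list[int]] = {}
    for kmer, mult in fragments.items():
        hits = oracle.search(kmer, max_mm=max_mm)
        if genus_map is not None:
            hits = frozenset(genus_map[t] for t in hits)
        if not hits:
            continue
        sig = len(hits) == 1
        for t in hits:
            counts = per_taxon.setdefault(t, [0, 0, 0, 0])
            counts[0] += mult
            counts[1] += 1
            if sig:
                counts[2] += mult
                counts[3] += 1
    return per_taxon


@pytest.fixture
def tiny_taxonomy():
    """root → genus 10 → species 100, 101; species 100 → strain 1000."""
    return Taxonomy(
        [
            TaxonNode(1, "root", "no_rank", 1),
            TaxonNode(10, "Genus A", "genus", 1),
            TaxonNode(100, "Species one", "species", 10),
            TaxonNode(101, "Species two", "species", 10),
            TaxonNode(1000, "Species one strain", "strain", 100),
        ]
    )


@pytest.fixture(scope="session")
def default_world():
    """The package's stated default fixture, classified once per session.

    5 present species (fractions 0.40/0.30/0.15/0.10/0.05), 10,000 reads of
    150 bp at 1% substitution error, plus an absent relative sharing 0.9 of
    its genome with the least-abundant present species.
    """
    pangenome, truth, reads, read_truth = default_fixture(seed=11)
    curated = curate_references(pangenome.references, pangenome.taxonomy)
    index = build_index(curated)
    fragments, _ = fragment_reads(reads)
    summaries, metrics = classify_sample(fragments, index)
    return {
        "pangenome": pangenome,
        "truth": truth,
        "reads": reads,
        "read_truth": read_truth,
        "curated": curated,
        "index": index,
        "fragments": fragments,
        "summaries": summaries,
        "metrics": metrics,
    }
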