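"""Mismatch-tolerant k-mer index over labelled reference sequences.

The classifier needs, for a 50-mer query, the set of taxa whose reference
sequences contain a substring within Hamming distance ``max_mm`` of the
query on either strand.  A full-text index (FM-index or similar) is one way
to honour that contract; at the scale this package targets, hash postings
over canonical k-mers plus a pigeonhole seed table are exact, simple and
fast:

* every reference window of length k is stored under its canonical form
  (lexicographic minimum of the window and its reverse complement), so
  fragments from either strand match;
* for a query with up to ``max_mm`` mismatches, the window is split into
  ``max_mm + 1`` contiguous blocks; at least one block must match exactly
  (pigeonhole), so candidates are gathered from per-block exact seed maps
  and verified with a full Hamming comparison.

Windows containing ambiguity codes (N) are excluded from both the index and
queries, so the mismatch budget is never consumed by no-calls.

The same structure indexes KO gene libraries (labels are KO ids) and
species references (labels are taxids).
"""

from __future__ import annotations

import json
import logging
from typing import Hashable, Iterable

from .errors import DataError
from .taxonomy import ReferenceSequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _hamming_within(a: str, b: str, budget: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return False
    return True


class KmerIndex:
    """Canonical k-mer postings with pigeonhole mismatch search.

    Parameters
    ----------
    k:
        Fragment length in bases (default 50).
    """

    def __init__(self, k: int = 50):
        if k < 1:
            raise DataError(f"k must be >= 1, got {k}")
        self.k = int(k)
        self._postings: dict[str, frozenset] = {}
        self._building: dict[str, set] = {}
        self.label_lengths: dict[Hashable, int] = {}
        self._label_seqs: dict[Hashable, list[str]] = {}
        self._seed_maps: dict[int, list[dict[str, list[str]]]] = {}
        self._cache: dict[tuple[str, int], frozenset] = {}

    # -- construction ----------------------------------------------------
    def add_sequence(self, label: Hashable, seq: str) -> None:
        """Index every valid length-k window of ``seq`` under ``label``."""
        seq = seq.upper()
        k = self.k
        self.label_lengths[label] = self.label_lengths.get(label, 0) + len(seq)
        self._label_seqs.setdefault(label, []).append(seq)
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if not _VALID.issuperset(window):
                continue
            self._building.setdefault(canonical(window), set()).add(label)
        # invalidate derived structures
        self._postings = {}
        self._seed_maps.clear()
        self._cache.clear()

    def _finalize(self) -> None:
        if not self._postings and self._building:
            self._postings = {kmer: frozenset(v) for kmer, v in self._building.items()}

    @property
    def postings(self) -> dict:
        """Canonical k-mer → frozenset of labels (built on first access)."""
        self._finalize()
        return self._postings

    @property
    def labels(self) -> list:
        return sorted(self.label_lengths)

    def __len__(self) -> int:
        return len(self.postings)

    def total_length(self, label: Hashable) -> int:
        """Total indexed reference bases for ``label``."""
        return self.label_lengths[label]

    def sequences(self, label: Hashable) -> list[str]:
        """The raw reference sequences stored for ``label``."""
        return list(self._label_seqs.get(label, ()))

    # -- search ----------------------------------------------------------
    def _blocks(self, n_blocks: int) -> list[tuple[int, int]]:
        base, extra = divmod(self.k, n_blocks)
        bounds, start = [], 0
        for i in range(n_blocks):
            size = base + (1 if i < extra else 0)
            bounds.append((start, start + size))
            start += size
        return bounds

    def _seed_map(self, n_blocks: int) -> list[dict[str, list[str]]]:
        cached = self._seed_maps.get(n_blocks)
        if cached is not None:
            return cached
        self._finalize()
        bounds = self._blocks(n_blocks)
        maps: list[dict[str, list[str]]] = [{} for _ in bounds]
        for kmer in self.postings:
            for (s, e), m in zip(bounds, maps):
                m.setdefault(kmer[s:e], []).append(kmer)
        self._seed_maps[n_blocks] = maps
        return maps

    def search(self, kmer: str, max_mm: int = 3) -> frozenset:
        """Labels owning a reference window within ``max_mm`` mismatches.

        Strand-symmetric: ``search(f) == search(revcomp(f))``.  Queries
        containing characters outside A/C/G/T return the empty set.
        """
        if len(kmer) != self.k:
            raise DataError(f"query length {len(kmer)} != k={self.k}")
        if not _VALID.issuperset(kmer):
            return frozenset()
        self._finalize()
        canon = canonical(kmer)
        key = (canon, max_mm)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if max_mm == 0:
            result = self.postings.get(canon, frozenset())
        else:
            maps = self._seed_map(max_mm + 1)
            bounds = self._blocks(max_mm + 1)
            matched: set[str] = set()
            for q in (canon, revcomp(canon)):
                for (s, e), m in zip(bounds, maps):
                    for cand in m.get(q[s:e], ()):
                        if cand not in matched and _hamming_within(q, cand, max_mm):
                            matched.add(cand)
            labels: set = set()
            for cand in matched:
                labels |= self.postings[cand]
            result = frozenset(labels)
        self._cache[key] = result
        return result

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Write the index to a JSON file (internal format)."""
        self._finalize()
        payload = {
            "k": self.k,
            "postings": {kmer: sorted(map(str, v)) for kmer, v in self.postings.items()},
            "label_lengths": {str(lb): n for lb, n in self.label_lengths.items()},
            "label_seqs": {str(lb): seqs for lb, seqs in self._label_seqs.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "KmerIndex":
        with open(path) as fh:
            payload = json.load(fh)

        def _label(s: str):
            return int(s) if s.lstrip("-").isdigit() else s

        idx = cls(k=payload["k"])
        idx._postings = {
            kmer: frozenset(_label(v) for v in vals)
            for kmer, vals in payload["postings"].items()
        }
        idx._building = {kmer: set(v) for kmer, v in idx._postings.items()}
        idx.label_lengths = {_label(s): n for s, n in payload["label_lengths"].items()}
        idx._label_seqs = {_label(s): seqs for s, seqs in payload["label_seqs"].items()}
        return idx


def build_index(curated: Iterable[ReferenceSequence], k: int = 50) -> KmerIndex:
    """Build a reference index from curated sequences.

    Raises :class:`DataError` when no sequence is at least ``k`` bases long
    (the index would be empty).
    """
    idx = KmerIndex(k=k)
    any_long = False
    for ref in curated:
        idx.add_sequence(ref.taxid, ref.seq)
        if len(ref.seq) >= k:
            any_long = True
    if not idx.label_lengths:
        raise DataError("no curated sequences supplied")
    if not any_long:
        raise DataError(f"all sequences shorter than k={k}; index would be empty")
    return idx
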