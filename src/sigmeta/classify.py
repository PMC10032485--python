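"""Fragment-based taxonomic classification.

Reads are segmented into non-overlapping 50-mer fragments (pairing
information ignored; the trailing remainder shorter than k is dropped) and
each fragment is aligned against the reference index with up to three
mismatches tolerated.  A fragment whose hit set at the evaluated rank
contains exactly one taxon is a *signature* hit — the unit of unambiguous
evidence.  Counts come in a total/unique duality: "total" weights fragments
by their multiplicity in the sample, "unique" counts each distinct fragment
sequence once.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .errors import DataError
from .index import KmerIndex, _VALID
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    """A distinct fragment sequence and its occurrence count in the sample."""

    kmer: str
    multiplicity: int = 1


@dataclass
class SampleHitMetrics:
    """Sample-level query and hit accounting.

    A fragment with at least one hit contributes its multiplicity to
    ``total_hits`` (and 1 to ``unique_hits``); a fragment whose hit set has
    size exactly one contributes likewise to the signature counts.
    """

    total_queries: int = 0
    total_unique_queries: int = 0
    total_hits: int = 0
    unique_hits: int = 0
    total_signature_hits: int = 0
    unique_signature_hits: int = 0


@dataclass
class TaxonHitSummary:
    """Per-taxon hit counts at species or genus rank."""

    taxid: int
    rank: str
    total_hits: int = 0
    unique_hits: int = 0
    total_signature_hits: int = 0
    unique_signature_hits: int = 0


def fragment_reads(
    reads: Iterable[Union[str, tuple]], k: int = 50
) -> tuple[Counter, SampleHitMetrics]:
    """Segment reads into non-overlapping k-mers, merged by sequence.

    ``reads`` yields sequences (or ``(read_id, sequence)`` pairs; pairing is
    ignored).  Each read of length L yields ``L // k`` fragments at offsets
    0, k, 2k, ...; fragments containing characters outside A/C/G/T (including
    N no-calls) are skipped with a logged warning and do not count as
    queries.  Returns the fragment multiset (k-mer -> multiplicity) and a
    partially-populated :class:`SampleHitMetrics` (query counts only).
    """
    fragments: Counter = Counter()
    n_skipped = 0
    for read in reads:
        seq = (read[1] if isinstance(read, tuple) else read).upper()
        for i in range(0, len(seq) - k + 1, k):
            frag = seq[i : i + k]
            if not _VALID.issuperset(frag):
                n_skipped += 1
                continue
            fragments[frag] += 1
    if n_skipped:
        logger.warning("skipped %d fragments with non-ACGT characters", n_skipped)
    metrics = SampleHitMetrics(
        total_queries=sum(fragments.values()),
        total_unique_queries=len(fragments),
    )
    return fragments, metrics


def read_fastq(path) -> list[tuple[str, str]]:
    """Load a FASTQ file (gzip-transparent) as (read_id, sequence) pairs."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


def align_fragment(fragment: Union[Fragment, str], index: KmerIndex, max_mm: int = 3) -> frozenset:
    """Species taxids whose references lie within ``max_mm`` mismatches."""
    kmer = fragment.kmer if isinstance(fragment, Fragment) else fragment
    return index.search(kmer, max_mm=max_mm)


def classify_sample(
    fragments: Mapping[str, int],
    index: KmerIndex,
    rank: str = "species",
    taxonomy: Optional[Taxonomy] = None,
    max_mm: int = 3,
) -> tuple[list[TaxonHitSummary], SampleHitMetrics]:
    """Classify a fragment multiset and summarise hits per taxon.

    For genus rank, every species hit is mapped to its genus ancestor
    *before* uniqueness is evaluated, so two species of the same genus
    still yield a genus-level signature hit.  Species without a genus
    ancestor keep their own taxid (flagged once in the log).
    """
    if rank not in ("species", "genus"):
        raise DataError(f"rank must be species or genus, got {rank!r}")
    if rank == "genus" and taxonomy is None:
        raise DataError("genus-rank classification requires a taxonomy")

    genus_cache: dict[int, int] = {}

    def to_rank(taxid: int) -> int:
        if rank == "species":
            return taxid
        mapped = genus_cache.get(taxid)
        if mapped is None:
            g = taxonomy.genus_of(taxid)
            if g is None:
                logger.warning("taxid %d has no genus ancestor; kept as-is", taxid)
                g = taxid
            genus_cache[taxid] = mapped = g
        return mapped

    metrics = SampleHitMetrics(
        total_queries=sum(fragments.values()),
        total_unique_queries=len(fragments),
    )
    summaries: dict[int, TaxonHitSummary] = {}
    for kmer, mult in fragments.items():
        hits = index.search(kmer, max_mm=max_mm)
        if not hits:
            continue
        ranked = {to_rank(t) for t in hits}
        metrics.total_hits += mult
        metrics.unique_hits += 1
        is_signature = len(ranked) == 1
        if is_signature:
            metrics.total_signature_hits += mult
            metrics.unique_signature_hits += 1
        for taxid in ranked:
            s = summaries.get(taxid)
            if s is None:
                s = summaries[taxid] = TaxonHitSummary(taxid=taxid, rank=rank)
            s.total_hits += mult
            s.unique_hits += 1
            if is_signature:
                s.total_signature_hits += mult
                s.unique_signature_hits += 1
    return [summaries[t] for t in sorted(summaries)], metrics


def summaries_to_frame(
    summaries: Iterable[TaxonHitSummary],
    sample_id: str = "",
    taxonomy: Optional[Taxonomy] = None,
) -> pd.DataFrame:
    """Tabulate per-taxon hit summaries (one row per taxon)."""
    rows = [
        {
            "sample_id": sample_id,
            "taxid": s.taxid,
            "rank": s.rank,
            "name": taxonomy.name_of(s.taxid) if taxonomy else "",
            "total_hits": s.total_hits,
            "unique_hits": s.unique_hits,
            "total_signature_hits": s.total_signature_hits,
            "unique_signature_hits": s.unique_signature_hits,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "taxid",
            "rank",
            "name",
            "total_hits",
            "unique_hits",
            "total_signature_hits",
            "unique_signature_hits",
        ],
    )


def metrics_to_frame(metrics: SampleHitMetrics, sample_id: str = "") -> pd.DataFrame:
    """Single-row table of sample-level query/hit metrics."""
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "total_queries": metrics.total_queries,
                "total_unique_queries": metrics.total_unique_queries,
                "total_hits": metrics.total_hits,
                "unique_hits": metrics.unique_hits,
                "total_signature_hits": metrics.total_signature_hits,
                "unique_signature_hits": metrics.unique_signature_hits,
            }
        ]
    )
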