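"""Signature-space functional profiling against a KEGG Orthology library.

The same non-overlapping 50-mer fragments used for taxonomic classification
are mapped against a library of KO gene families (gene sequences pooled and
de-duplicated across contributing species).  Because a fragment can — and
often does — align to genes of several KOs, only fragments that
unambiguously support a single function are counted.  Counts are normalised
to RPKM (reads per kilobase of unique aggregate gene sequence per million
sample fragments).  Per-sample top-N KO sets are unioned, Bray-Curtis
dissimilarities computed over that set, and samples ordinated by principal
coordinates (classical scaling) — the appropriate embedding for a
non-Euclidean dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DataError
from .index import KmerIndex

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 500


@dataclass
class KOEntry:
    """One KO family: pooled unique gene sequences and their total length."""

    ko_id: str
    gene_seqs: set = field(default_factory=set)

    @property
    def aggregate_length(self) -> int:
        return sum(len(s) for s in self.gene_seqs)


@dataclass
class KOProfile:
    """Per-sample KO counts and RPKM values, with discard accounting."""

    sample_id: str
    table: pd.DataFrame  # columns: ko_id, count, rpkm
    total_fragments: int
    discarded_multi: int
    discarded_nohit: int


def build_ko_library(
    gene_records: Iterable[tuple],
) -> dict[str, KOEntry]:
    """Pool (ko_id, gene sequence) pairs into one entry per KO.

    ``gene_records`` yields ``(ko_id, seq)`` or ``(ko_id, seq, species)``
    tuples (the species tag, when present, is informational only).  Member
    sequences are de-duplicated by sequence text across species.
    """
    library: dict[str, KOEntry] = {}
    n = 0
    for rec in gene_records:
        ko_id, seq = str(rec[0]), str(rec[1]).upper()
        entry = library.get(ko_id)
        if entry is None:
            entry = library[ko_id] = KOEntry(ko_id=ko_id)
        entry.gene_seqs.add(seq)
        n += 1
    if not library:
        raise DataError("empty KO gene input")
    logger.info("KO library: %d KOs from %d gene records", len(library), n)
    return library


def load_ko_library(fasta_path, map_path) -> dict[str, KOEntry]:
    """Build a KO library from a gene FASTA and a gene→KO map TSV.

    The map is tab-delimited with header columns gene_id, ko_id (and
    optionally species_taxid).
    """
    from Bio import SeqIO

    table = pd.read_csv(map_path, sep="\t", dtype=str)
    gene_to_ko = dict(zip(table["gene_id"], table["ko_id"]))
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ko = gene_to_ko.get(rec.id)
        if ko is None:
            raise DataError(f"gene {rec.id!r} missing from KO map")
        records.append((ko, str(rec.seq)))
    return build_ko_library(records)


def build_ko_index(library: Mapping[str, KOEntry], k: int = 50) -> KmerIndex:
    """Index the library's unique gene sequences, labelled by KO id."""
    idx = KmerIndex(k=k)
    for ko_id in sorted(library):
        for seq in sorted(library[ko_id].gene_seqs):
            idx.add_sequence(ko_id, seq)
    return idx


def rpkm(count: float, aggregate_length_bases: int, total_fragments: int) -> float:
    """Reads per kilobase of unique reference sequence per million fragments."""
    if aggregate_length_bases < 1 or total_fragments < 1:
        raise DataError("rpkm denominators must be >= 1")
    return (count / (aggregate_length_bases / 1000.0)) / (total_fragments / 1e6)


def annotate_fragments(
    fragments: Mapping[str, int],
    library: Mapping[str, KOEntry],
    ko_index: Optional[KmerIndex] = None,
    max_mm: int = 3,
    sample_id: str = "",
) -> KOProfile:
    """Bin fragments into KO signature space.

    A fragment matching genes of exactly one KO (within ``max_mm``
    mismatches) adds its multiplicity to that KO's count; fragments hitting
    several KOs or nothing are discarded but accounted, so that
    ``assigned + discarded_multi + discarded_nohit == total_fragments``.
    """
    if not library:
        raise DataError("empty KO library")
    if ko_index is None:
        ko_index = build_ko_index(library)
    counts = {ko: 0 for ko in library}
    total = multi = nohit = 0
    for kmer, mult in fragments.items():
        total += mult
        hits = ko_index.search(kmer, max_mm=max_mm)
        if not hits:
            nohit += mult
        elif len(hits) == 1:
            counts[next(iter(hits))] += mult
        else:
            multi += mult
    rows = [
        {
            "ko_id": ko,
            "count": counts[ko],
            "rpkm": rpkm(counts[ko], library[ko].aggregate_length, total)
            if total >= 1
            else 0.0,
        }
        for ko in sorted(library)
    ]
    return KOProfile(
        sample_id=sample_id,
        table=pd.DataFrame(rows, columns=["ko_id", "count", "rpkm"]),
        total_fragments=total,
        discarded_multi=multi,
        discarded_nohit=nohit,
    )


def top_n_union(profiles: Sequence[KOProfile], n: int = DEFAULT_TOP_N) -> set:
    """Union of each sample's ``n`` highest-RPKM KOs.

    Deterministic tie-break: RPKM descending, then KO id ascending.  KOs
    with zero RPKM never enter a sample's top set.
    """
    union: set = set()
    for profile in profiles:
        table = profile.table[profile.table["rpkm"] > 0]
        if table.empty:
            raise DataError(f"sample {profile.sample_id!r} has no nonzero KO")
        top = table.sort_values(
            ["rpkm", "ko_id"], ascending=[False, True], kind="stable"
        ).head(n)
        union |= set(top["ko_id"])
    return union


def profiles_to_matrix(
    profiles: Sequence[KOProfile], ko_ids: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Samples × KOs RPKM matrix, optionally restricted to a KO set."""
    cols = sorted(ko_ids) if ko_ids is not None else None
    rows = {}
    for p in profiles:
        series = p.table.set_index("ko_id")["rpkm"]
        rows[p.sample_id] = series.reindex(cols, fill_value=0.0) if cols else series
    return pd.DataFrame(rows).T.fillna(0.0)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i); zero diagonal, symmetric,
    bounded in [0, 1].  Two all-zero rows make the dissimilarity undefined
    and raise an error.
    """
    values = np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise DataError("Bray-Curtis requires non-negative abundances")
    zero_rows = (values.sum(axis=1) == 0).sum()
    if zero_rows >= 2:
        raise DataError(
            f"{zero_rows} all-zero samples: pairwise Bray-Curtis undefined"
        )
    dm = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dm, index=matrix.index, columns=matrix.index)


def principal_coordinates(
    dissimilarity: pd.DataFrame, n_axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (PCoA) of a dissimilarity matrix.

    Double-centers the squared dissimilarities, eigendecomposes, and keeps
    the top ``n_axes`` positive eigenvalues (axes ordered by eigenvalue;
    negative eigenvalues — expected for non-Euclidean input — are dropped
    with a logged warning).  Returns sample coordinates and the fraction of
    positive-eigenvalue variance per axis.
    """
    dm = np.asarray(dissimilarity, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise DataError("dissimilarity matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise DataError("dissimilarity matrix must be symmetric")
    n = dm.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centering @ (dm**2) @ centering
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_negative = int((eigvals < -1e-10).sum())
    if n_negative:
        logger.warning(
            "dropping %d negative eigenvalues (non-Euclidean dissimilarity)",
            n_negative,
        )
    positive = np.clip(eigvals, 0.0, None)
    keep = min(n_axes, int((positive > 1e-12).sum()))
    coords = eigvecs[:, :keep] * np.sqrt(positive[:keep])
    total = positive.sum()
    explained = positive[:keep] / total if total > 0 else np.zeros(keep)
    frame = pd.DataFrame(
        coords,
        index=dissimilarity.index,
        columns=[f"PCo{i + 1}" for i in range(keep)],
    )
    return frame, explained
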