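"""Taxonomy handling and reference curation.

Signature-based read binning needs a reference set in which every sequence
is labelled at species rank: sub-species (strain and below) labels are
collapsed up to their parent species, and sequences that cannot be resolved
to species rank or better — or that carry an "environmental" flag — are
discarded.  This module loads a taxonomy from two TSV tables (nodes and
names), provides rank navigation (species/genus ancestors), and applies
those curation rules to reference sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .errors import TaxonomyError

logger = logging.getLogger(__name__)

#: canonical rank names recognised below species level
SUB_SPECIES_RANKS = frozenset(
    {
        "subspecies",
        "strain",
        "varietas",
        "forma",
        "isolate",
        "serotype",
        "serogroup",
        "biotype",
        "genotype",
        "pathogroup",
        "no_rank",
    }
)


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy tree."""

    taxid: int
    name: str
    rank: str
    parent: int


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference sequence with its (possibly sub-species) taxon label."""

    seq_id: str
    taxid: int
    seq: str
    environmental: bool = False


class Taxonomy:
    """Navigable taxonomy tree with lookup by taxid and by exact name.

    The parent chain of every node must terminate at a single root (a node
    whose parent is itself).  Construction validates acyclicity.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid} in taxonomy")
            self._nodes[node.taxid] = node
        self._by_name = {n.name: n.taxid for n in self._nodes.values() if n.name}
        self._root = self._validate()
        self._children: dict[int, list[int]] = {}
        for n in self._nodes.values():
            if n.taxid != n.parent:
                self._children.setdefault(n.parent, []).append(n.taxid)

    def _validate(self) -> int:
        roots = [n.taxid for n in self._nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one root (parent == taxid); found {roots}"
            )
        root = roots[0]
        for start in self._nodes:
            seen = set()
            tid = start
            while tid != root:
                if tid in seen:
                    raise TaxonomyError(f"cycle in parent chain at taxid {tid}")
                seen.add(tid)
                node = self._nodes.get(tid)
                if node is None:
                    raise TaxonomyError(f"parent taxid {tid} missing from taxonomy")
                tid = node.parent
        return root

    # -- basic lookups ---------------------------------------------------
    @property
    def root(self) -> int:
        return self._root

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"taxid {taxid} not in taxonomy") from None

    def name_of(self, taxid: int) -> str:
        return self.node(taxid).name

    def rank_of(self, taxid: int) -> str:
        return self.node(taxid).rank

    def by_name(self, name: str) -> int:
        try:
            return self._by_name[name]
        except KeyError:
            raise TaxonomyError(f"name {name!r} not in taxonomy") from None

    def children(self, taxid: int) -> list[int]:
        return list(self._children.get(taxid, ()))

    # -- rank navigation -------------------------------------------------
    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """Nearest ancestor (including the node itself) at ``rank``, or None."""
        tid = taxid
        while True:
            node = self.node(tid)
            if node.rank == rank:
                return tid
            if tid == self._root:
                return None
            tid = node.parent

    def species_of(self, taxid: int) -> Optional[int]:
        return self.ancestor_at_rank(taxid, "species")

    def genus_of(self, taxid: int) -> Optional[int]:
        return self.ancestor_at_rank(taxid, "genus")

    def species_under(self, taxid: int) -> list[int]:
        """All species-rank descendants of ``taxid`` (depth-first order)."""
        out = []
        stack = [taxid]
        while stack:
            tid = stack.pop()
            if self.rank_of(tid) == "species":
                out.append(tid)
            stack.extend(self._children.get(tid, ()))
        return sorted(out)


def load_taxonomy(nodes_path, names_path) -> Taxonomy:
    """Load a taxonomy from a nodes TSV and a names TSV.

    ``nodes_path``: tab-delimited with header columns taxid, parent_taxid,
    rank.  ``names_path``: taxid, name.  Duplicate taxids raise an error
    naming the offending row.
    """
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"taxid": int, "parent_taxid": int})
    names = pd.read_csv(names_path, sep="\t", dtype={"taxid": int})
    for col in ("taxid", "parent_taxid", "rank"):
        if col not in nodes.columns:
            raise TaxonomyError(f"nodes table missing column {col!r}")
    dup = nodes["taxid"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise TaxonomyError(
            f"duplicate taxid {nodes.at[row, 'taxid']} in nodes table (row {row + 2})"
        )
    name_map = dict(zip(names["taxid"], names["name"]))
    out = [
        TaxonNode(
            taxid=int(r.taxid),
            name=str(name_map.get(int(r.taxid), f"taxid:{int(r.taxid)}")),
            rank=str(r.rank),
            parent=int(r.parent_taxid),
        )
        for r in nodes.itertuples()
    ]
    return Taxonomy(out)


def curate_references(
    seqs: Iterable[ReferenceSequence], taxonomy: Taxonomy
) -> list[ReferenceSequence]:
    """Apply species-level curation to a reference set.

    * sequences flagged environmental are dropped;
    * sequences at sub-species rank are re-labelled with their species
      ancestor's taxid;
    * sequences whose taxid resolves only to genus rank or higher are
      dropped;
    * a taxid absent from the taxonomy is an error naming the sequence.

    The operation is idempotent: curated output passes through unchanged.
    """
    out: list[ReferenceSequence] = []
    n_env = n_norank = 0
    for ref in seqs:
        if ref.taxid not in taxonomy:
            raise TaxonomyError(
                f"sequence {ref.seq_id!r}: taxid {ref.taxid} not in taxonomy"
            )
        if ref.environmental:
            n_env += 1
            continue
        species = taxonomy.species_of(ref.taxid)
        if species is None:
            n_norank += 1
            continue
        out.append(ref if ref.taxid == species else replace(ref, taxid=species))
    if n_env or n_norank:
        logger.info(
            "curation dropped %d environmental and %d above-species sequences",
            n_env,
            n_norank,
        )
    return out


def load_reference_fasta(fasta_path, labels_path) -> list[ReferenceSequence]:
    """Read a reference FASTA plus its taxon-label TSV.

    The label table is tab-delimited with header columns seq_id, taxid and
    environmental (0/1).  Every FASTA record must be labelled.
    """
    from Bio import SeqIO

    labels = pd.read_csv(labels_path, sep="\t", dtype={"seq_id": str, "taxid": int})
    if "environmental" not in labels.columns:
        labels["environmental"] = 0
    table = {
        str(r.seq_id): (int(r.taxid), bool(r.environmental))
        for r in labels.itertuples()
    }
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in table:
            raise TaxonomyError(f"sequence {rec.id!r} missing from label table")
        taxid, env = table[rec.id]
        refs.append(
            ReferenceSequence(
                seq_id=rec.id, taxid=taxid, seq=str(rec.seq).upper(), environmental=env
            )
        )
    return refs
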