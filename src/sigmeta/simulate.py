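"""Synthetic inputs with known truth for every pipeline stage.

The generator emulates the structure the classifier assumes rather than any
particular organism: random genomes with planted, verbatim-copied shared
blocks (so the signature / shared status of every 50-mer is exactly
computable), reads drawn from a known taxon composition with independent
per-base substitution errors, KO gene sets with controlled cross-KO
overlap, BLAST-style hit tables with planted organisms and
boundary-straddling rows, and per-method classifier profiles with known
dropout.  Everything is deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import ClassifierProfile
from .errors import DataError
from .taxonomy import ReferenceSequence, TaxonNode, Taxonomy

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: default fixture scale: completes the full pipeline in well under a minute
DEFAULT_N_TAXA = 5
DEFAULT_GENOME_LENGTH = 20_000
DEFAULT_N_READS = 10_000
DEFAULT_READ_LENGTH = 150
DEFAULT_ERROR_RATE = 0.01

ROOT_TAXID = 1
_GENUS_BASE = 10
_SPECIES_BASE = 100
_STRAIN_TAXID = 1001


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


@dataclass
class PangenomeSpec:
    """Stated world for a synthetic multi-species reference pangenome.

    ``sharing[i, j]`` is the target fraction of taxon j's genome copied
    verbatim from taxon i (symmetric, unit diagonal).  Shared blocks for
    different pairs occupy disjoint genome regions, so realized pairwise
    shared 50-mer fractions match the targets up to k-1 edge positions.
    """

    n_taxa: int = DEFAULT_N_TAXA
    genome_length: int = DEFAULT_GENOME_LENGTH
    sharing: Optional[np.ndarray] = None  # defaults to identity (no sharing)
    seed: int = 0
    include_strain: bool = True
    include_environmental: bool = True
    strain_length: int = 500
    shared_genus_pair: bool = True  # species 1 and 2 share a genus

    def sharing_matrix(self) -> np.ndarray:
        if self.sharing is None:
            return np.eye(self.n_taxa)
        m = np.asarray(self.sharing, dtype=float)
        if m.shape != (self.n_taxa, self.n_taxa):
            raise DataError(f"sharing matrix must be {self.n_taxa}x{self.n_taxa}")
        if not np.allclose(m, m.T):
            raise DataError("sharing matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise DataError("sharing matrix diagonal must be 1")
        return m


@dataclass
class Pangenome:
    """Generated references with their taxonomy and truth bookkeeping."""

    spec: PangenomeSpec
    taxonomy: Taxonomy
    references: list  # raw ReferenceSequence (pre-curation; includes strain/env)
    genomes: dict  # species taxid -> main genome string (post-sharing)

    @property
    def species_taxids(self) -> list:
        return sorted(self.genomes)

    def write(self, outdir) -> dict:
        """Write reference FASTA, taxon-label TSV and taxonomy TSVs."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "references.fasta"),
            "labels": os.path.join(outdir, "labels.tsv"),
            "nodes": os.path.join(outdir, "nodes.tsv"),
            "names": os.path.join(outdir, "names.tsv"),
        }
        write_fasta(((r.seq_id, r.seq) for r in self.references), paths["fasta"])
        pd.DataFrame(
            [
                {"seq_id": r.seq_id, "taxid": r.taxid, "environmental": int(r.environmental)}
                for r in self.references
            ]
        ).to_csv(paths["labels"], sep="\t", index=False)
        nodes, names = [], []
        for tid in sorted(self.taxonomy._nodes):
            node = self.taxonomy.node(tid)
            nodes.append({"taxid": tid, "parent_taxid": node.parent, "rank": node.rank})
            names.append({"taxid": tid, "name": node.name})
        pd.DataFrame(nodes).to_csv(paths["nodes"], sep="\t", index=False)
        pd.DataFrame(names).to_csv(paths["names"], sep="\t", index=False)
        return paths


def generate_pangenome(spec: PangenomeSpec) -> Pangenome:
    """Generate random genomes realizing the pairwise sharing matrix.

    Includes one strain-level labelled sequence (under species 1) and one
    environmental-flagged sequence (labelled species 2 when present) so the
    curation rules are exercised.
    """
    if spec.n_taxa < 1:
        raise DataError("need at least one taxon")
    sharing = spec.sharing_matrix()
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_taxa, spec.genome_length
    genomes = {i: _random_seq(rng, length) for i in range(n)}

    # Per-genome cursors keep every planted block in a region where neither
    # partner has been (or will be) overwritten, so no unintended three-way
    # sharing arises and realized pairwise fractions stay exact.
    cursors = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = float(sharing[i, j])
            if s <= 0:
                continue
            block = int(round(s * length))
            start = max(cursors[i], cursors[j])
            if start + block > length:
                raise DataError("sharing matrix plants more blocks than genome length")
            g = genomes[j]
            genomes[j] = g[:start] + genomes[i][start : start + block] + g[start + block :]
            cursors[i] = cursors[j] = start + block

    species = [_SPECIES_BASE + i + 1 for i in range(n)]
    nodes = [TaxonNode(ROOT_TAXID, "root", "no_rank", ROOT_TAXID)]
    for i, sp in enumerate(species):
        if spec.shared_genus_pair and i == 1 and n >= 2:
            genus = _GENUS_BASE + 1  # species 1 and 2 under one genus
        else:
            genus = _GENUS_BASE + i + 1
        if all(node.taxid != genus for node in nodes):
            nodes.append(TaxonNode(genus, f"Genus{genus - _GENUS_BASE}", "genus", ROOT_TAXID))
        nodes.append(TaxonNode(sp, f"Species {i + 1}", "species", genus))
    refs = [
        ReferenceSequence(seq_id=f"chr_sp{i + 1}", taxid=sp, seq=genomes[i])
        for i, sp in enumerate(species)
    ]
    if spec.include_strain:
        nodes.append(TaxonNode(_STRAIN_TAXID, "Species 1 strain X", "strain", species[0]))
        refs.append(
            ReferenceSequence(
                seq_id="plasmid_sp1_strainX",
                taxid=_STRAIN_TAXID,
                seq=_random_seq(rng, spec.strain_length),
            )
        )
    if spec.include_environmental and n >= 2:
        refs.append(
            ReferenceSequence(
                seq_id="env_clone",
                taxid=species[1],
                seq=_random_seq(rng, spec.strain_length),
                environmental=True,
            )
        )
    taxonomy = Taxonomy(nodes)
    return Pangenome(
        spec=spec,
        taxonomy=taxonomy,
        references=refs,
        genomes={sp: genomes[i] for i, sp in enumerate(species)},
    )


@dataclass
class CompositionTruth:
    """Stated read composition: per-taxon fractions, depth, error model."""

    fractions: dict  # species taxid -> read fraction, summing to 1
    n_reads: int = DEFAULT_N_READS
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"read fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions.values()):
            raise DataError("read fractions must be non-negative")
        if not (0.0 <= self.error_rate <= 0.25):
            raise DataError(f"error rate {self.error_rate} outside [0, 0.25]")


def simulate_reads(
    truth: CompositionTruth, pangenome: Pangenome
) -> tuple[list, pd.DataFrame]:
    """Draw reads from known taxa with substitution errors.

    Positions are uniform over each source genome; strands are random (the
    classifier must be strand-agnostic); errors are independent per-base
    substitutions at the stated rate.  Returns ``(read_id, sequence)``
    pairs and a truth table recording each read's source taxon, position
    and strand.
    """
    if truth.read_length < 50:
        raise DataError("read_length must be >= 50 (no fragment fits otherwise)")
    rng = np.random.default_rng(truth.seed)
    taxids = sorted(truth.fractions)
    probs = np.array([truth.fractions[t] for t in taxids])
    sources = rng.choice(len(taxids), size=truth.n_reads, p=probs)
    reads, rows = [], []
    comp = str.maketrans("ACGT", "TGCA")
    for ridx, src in enumerate(sources):
        taxid = taxids[src]
        genome = pangenome.genomes[taxid]
        start = int(rng.integers(0, len(genome) - truth.read_length + 1))
        seq = genome[start : start + truth.read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = seq.translate(comp)[::-1]
        if truth.error_rate > 0:
            errors = np.nonzero(rng.random(truth.read_length) < truth.error_rate)[0]
            if errors.size:
                chars = list(seq)
                for pos in errors:
                    choices = [b for b in "ACGT" if b != chars[pos]]
                    chars[pos] = choices[int(rng.integers(0, 3))]
                seq = "".join(chars)
        read_id = f"read_{ridx:06d}"
        reads.append((read_id, seq))
        rows.append({"read_id": read_id, "taxid": taxid, "start": start, "strand": strand})
    return reads, pd.DataFrame(rows, columns=["read_id", "taxid", "start", "strand"])


def default_fixture(seed: int = 0):
    """The package's stated default world, end to end.

    Five species are present with fractions (0.40, 0.30, 0.15, 0.10, 0.05)
    at 10,000 reads of 150 bp and 1% substitution error; a sixth "ghost"
    species shares 90% of its genome with the least-abundant present
    species but contributes no reads — the classic absent near-relative a
    confident caller must discard.

    Returns ``(pangenome, truth, reads, read_truth)``.
    """
    n = 6
    sharing = np.eye(n)
    sharing[4, 5] = sharing[5, 4] = 0.9  # ghost (taxon 6) mirrors taxon 5
    pangenome = generate_pangenome(
        PangenomeSpec(n_taxa=n, sharing=sharing, seed=seed)
    )
    present = pangenome.species_taxids[:5]
    fractions = dict(zip(present, (0.40, 0.30, 0.15, 0.10, 0.05)))
    truth = CompositionTruth(fractions=fractions, seed=seed + 1)
    reads, read_truth = simulate_reads(truth, pangenome)
    return pangenome, truth, reads, read_truth


# ---------------------------------------------------------------------------
# KO gene sets


@dataclass
class KOGeneSet:
    """Synthetic KO gene library with known cross-KO overlap."""

    records: list  # (ko_id, seq, species) tuples
    gene_map: pd.DataFrame  # gene_id, ko_id, species_taxid
    genes: dict  # gene_id -> seq
    overlap_pairs: list  # [(ko_a, ko_b, planted_fraction)]

    def write(self, fasta_path, map_path) -> None:
        write_fasta(self.genes.items(), fasta_path)
        self.gene_map.to_csv(map_path, sep="\t", index=False)


def generate_ko_genes(
    n_kos: int = 10,
    species_assignments: Optional[Mapping[str, Sequence[int]]] = None,
    cross_ko_overlap: float = 0.0,
    gene_length: int = 1000,
    seed: int = 0,
) -> KOGeneSet:
    """Generate KO gene families with a controlled shared-50-mer fraction.

    Consecutive KO pairs (K1, K2), (K3, K4), ... have ``cross_ko_overlap``
    of their first gene copied verbatim between them, so fragments from the
    shared blocks hit two KOs and exercise the unambiguous-only discard
    path.  ``species_assignments`` maps KO id to contributing species
    taxids (default: two species alternating).
    """
    if not (0.0 <= cross_ko_overlap <= 1.0):
        raise DataError("cross_ko_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ko_ids = [f"K{i + 1:05d}" for i in range(n_kos)]
    if species_assignments is None:
        species_assignments = {
            ko: [_SPECIES_BASE + 1 + (i % 2)] for i, ko in enumerate(ko_ids)
        }
    genes: dict[str, str] = {}
    records, map_rows = [], []
    first_gene: dict[str, str] = {}
    for ko in ko_ids:
        for species in species_assignments.get(ko, [_SPECIES_BASE + 1]):
            gene_id = f"{ko}_sp{species}"
            seq = _random_seq(rng, gene_length)
            genes[gene_id] = seq
            first_gene.setdefault(ko, gene_id)
            map_rows.append({"gene_id": gene_id, "ko_id": ko, "species_taxid": species})
    overlap_pairs = []
    if cross_ko_overlap > 0:
        block = int(round(cross_ko_overlap * gene_length))
        for a, b in zip(ko_ids[::2], ko_ids[1::2]):
            ga, gb = first_gene[a], first_gene[b]
            donor = genes[ga]
            genes[gb] = donor[:block] + genes[gb][block:]
            overlap_pairs.append((a, b, cross_ko_overlap))
    for row in map_rows:
        records.append((row["ko_id"], genes[row["gene_id"]], row["species_taxid"]))
    return KOGeneSet(
        records=records,
        gene_map=pd.DataFrame(map_rows, columns=["gene_id", "ko_id", "species_taxid"]),
        genes=genes,
        overlap_pairs=overlap_pairs,
    )


# ---------------------------------------------------------------------------
# BLAST fixtures


@dataclass
class BlastFixture:
    """Synthetic assembly + hit table with exactly known contributions."""

    scaffolds: list  # (id, seq) incl. one sub-1kb scaffold dropped by the filter
    hits: pd.DataFrame  # BLAST tabular columns
    truth_contributions: pd.DataFrame  # organism, fraction (post-filter)
    truth_boundary: pd.DataFrame  # qseqid, expected pass/fail
    assembly_total_bases: int

    def write(self, fasta_path, hits_path) -> None:
        write_fasta(self.scaffolds, fasta_path)
        self.hits.to_csv(hits_path, sep="\t", index=False, header=False)


def _hit_row(qseqid, sseqid, pident, length, evalue, bitscore, qlen, staxids=""):
    return {
        "qseqid": qseqid,
        "sseqid": sseqid,
        "pident": pident,
        "length": length,
        "mismatch": 0,
        "gapopen": 0,
        "qstart": 1,
        "qend": min(length, qlen),
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": bitscore,
        "qlen": qlen,
        "staxids": staxids,
    }


def generate_blast_fixture(
    n_scaffolds: int = 8,
    planted_contributions: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    scaffold_length: int = 2000,
) -> BlastFixture:
    """Plant organisms into an assembly and emit the matching hit table.

    ``planted_contributions`` maps organism name to the fraction of
    *aligned-scaffold* slots it receives; each planted slot is a
    full-length, clearly-passing top hit.  On top of those, the fixture
    appends scaffolds carrying hits at every quality-filter boundary
    (identity 79.9/80.0, coverage 0.249/0.250, e-value 1e-6/1e-7), one
    bit-score tie resolved by e-value, one hit-less scaffold, and one
    999-base scaffold that the length filter must drop.  The truth tables
    state the post-filter contribution fractions and per-boundary pass
    verdicts, computed from the planting arithmetic alone.
    """
    if planted_contributions is None:
        planted_contributions = {"OrgA": 0.5, "OrgB": 0.25}
    if sum(planted_contributions.values()) > 1.0 + 1e-9:
        raise DataError("planted contributions exceed the assembly")
    rng = np.random.default_rng(seed)
    slots = {
        org: int(round(f * n_scaffolds)) for org, f in planted_contributions.items()
    }
    if sum(slots.values()) > n_scaffolds:
        raise DataError("planted fractions do not fit the scaffold count")

    scaffolds, hits, assigned_bases = [], [], {}
    idx = 0
    L = scaffold_length
    for org, n_slots in slots.items():
        for _ in range(n_slots):
            sid = f"scf_{idx:03d}"
            idx += 1
            scaffolds.append((sid, _random_seq(rng, L)))
            hits.append(_hit_row(sid, f"ref_{org}", 99.0, L, 1e-50, 2 * L, L, org))
            assigned_bases[org] = assigned_bases.get(org, 0) + L

    boundary_rows = []

    def boundary(tag, pident, cov, evalue, expected_pass):
        nonlocal idx
        sid = f"scf_b_{tag}"
        idx += 1
        scaffolds.append((sid, _random_seq(rng, L)))
        length = int(round(cov * L))
        hits.append(
            _hit_row(sid, "ref_Boundary", pident, length, evalue, 100.0, L, "Boundary")
        )
        boundary_rows.append({"qseqid": sid, "expected_pass": expected_pass})
        if expected_pass:
            assigned_bases["Boundary"] = assigned_bases.get("Boundary", 0) + length

    boundary("ident_fail", 79.9, 0.9, 1e-20, False)
    boundary("ident_pass", 80.0, 0.9, 1e-20, True)
    boundary("cov_fail", 95.0, 0.249, 1e-20, False)
    boundary("cov_pass", 95.0, 0.250, 1e-20, True)
    boundary("eval_fail", 95.0, 0.9, 1e-6, False)
    boundary("eval_pass", 95.0, 0.9, 1e-7, True)

    # bit-score tie: equal bitscore, the lower e-value subject must win
    tie_id = "scf_tie"
    scaffolds.append((tie_id, _random_seq(rng, L)))
    hits.append(_hit_row(tie_id, "ref_TieLoser", 98.0, L, 1e-40, 500.0, L, "TieLoser"))
    hits.append(_hit_row(tie_id, "ref_TieWinner", 98.0, L, 1e-50, 500.0, L, "TieWinner"))
    assigned_bases["TieWinner"] = assigned_bases.get("TieWinner", 0) + L

    # a scaffold with no hits at all, and a sub-1kb scaffold with a perfect
    # hit that the length filter must exclude from the assembly
    scaffolds.append(("scf_nohit", _random_seq(rng, L)))
    scaffolds.append(("scf_short", _random_seq(rng, 999)))
    hits.append(_hit_row("scf_short", "ref_Short", 100.0, 999, 1e-80, 1800.0, 999, "Short"))

    kept = [(sid, seq) for sid, seq in scaffolds if len(seq) >= 1000]
    total = sum(len(seq) for _, seq in kept)
    rows = [
        {"organism": org, "fraction": bases / total}
        for org, bases in sorted(assigned_bases.items())
    ]
    rows.append(
        {
            "organism": "unassigned",
            "fraction": (total - sum(assigned_bases.values())) / total,
        }
    )
    hits_df = pd.DataFrame(hits, columns=list(_hit_row("", "", 0, 0, 0, 0, 0)))
    return BlastFixture(
        scaffolds=scaffolds,
        hits=hits_df,
        truth_contributions=pd.DataFrame(rows, columns=["organism", "fraction"]),
        truth_boundary=pd.DataFrame(boundary_rows, columns=["qseqid", "expected_pass"]),
        assembly_total_bases=total,
    )


# ---------------------------------------------------------------------------
# Multi-method profiles


def generate_method_profiles(
    truth: Mapping[str, Sequence[str]],
    per_method: Mapping[str, tuple],
    seed: int = 0,
    rank: str = "species",
    spurious_pool: int = 50,
) -> list:
    """Simulate classifier profiles from one truth with per-method noise.

    ``truth`` maps sample id to the taxa truly present; ``per_method`` maps
    method name to ``(sensitivity, false_call_rate)``.  Each method
    independently detects each true taxon with probability ``sensitivity``
    and adds each of ``spurious_pool`` decoy taxa with probability
    ``false_call_rate``.
    """
    rng = np.random.default_rng(seed)
    decoys = [f"Decoyus sp{i + 1}" for i in range(spurious_pool)]
    profiles = []
    for method in sorted(per_method):
        sens, false_rate = per_method[method]
        for sample_id in sorted(truth):
            calls = {}
            for taxon in truth[sample_id]:
                if rng.random() < sens:
                    calls[taxon] = 1.0
            if false_rate > 0:
                for decoy in decoys:
                    if rng.random() < false_rate:
                        calls[decoy] = 1.0
            profiles.append(
                ClassifierProfile(
                    method=method, sample_id=sample_id, rank=rank, calls=calls
                )
            )
    return profiles


# ---------------------------------------------------------------------------
# Writers shared by the generators


def write_fasta(records, path, width: int = 80) -> None:
    """Write (id, seq) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads, path) -> None:
    """Write (id, seq) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
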