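"""Cross-classifier consensus: harmonise taxonomic calls and count agreement.

Different classifiers (true-alignment signature binning, k-mer
reclassification à la Kraken/Bracken, marker genes à la MetaPhlAn) see
different slices of a community.  This module ingests each tool's native
profile format, harmonises taxon names, and counts — per (taxon, sample)
call — how many methods agree, partitioning all calls into made-by-1,
made-by-2, ..., made-by-all bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

DIALECTS = ("signature_tsv", "kraken_report", "metaphlan_profile")

#: tiers counted as present for the signature classifier
CONFIDENT_TIERS = frozenset({"medium", "high", "very_high"})

_RANK_PREFIX = {"species": "s__", "genus": "g__"}
_KRAKEN_RANK = {"species": "S", "genus": "G"}


@dataclass
class ClassifierProfile:
    """One method's calls for one sample at one rank."""

    method: str
    sample_id: str
    rank: str
    calls: dict = field(default_factory=dict)  # taxon name -> abundance


def normalize_name(name: str, synonyms: Optional[Mapping[str, str]] = None) -> str:
    """Trim rank prefixes/underscores and apply the synonym table."""
    name = name.strip()
    for prefix in ("k__", "p__", "c__", "o__", "f__", "g__", "s__"):
        if name.startswith(prefix):
            name = name[len(prefix):]
    name = name.replace("_", " ").strip()
    if synonyms:
        name = synonyms.get(name, name)
    return name


def load_synonyms(path) -> dict[str, str]:
    """Read a two-column TSV (alias, canonical) of taxon synonym pairs."""
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))


def _load_signature_tsv(path, rank, synonyms) -> dict:
    table = pd.read_csv(path, sep="\t")
    calls = {}
    for _, row in table.iterrows():
        if str(row.get("rank", rank)) != rank:
            continue
        if str(row.get("tier", "low")) not in CONFIDENT_TIERS:
            continue
        name = normalize_name(str(row["name"]), synonyms)
        calls[name] = calls.get(name, 0.0) + float(row["n_unique_signature"])
    return calls


def _load_kraken_report(path, rank, synonyms) -> dict:
    want = _KRAKEN_RANK[rank]
    calls = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise DataError(f"{path}: malformed kraken report row at line {lineno}")
            try:
                clade_reads = float(parts[1])
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric read count at line {lineno}"
                ) from None
            if parts[3].strip() != want:
                continue
            name = normalize_name(parts[5], synonyms)
            if clade_reads > 0:
                calls[name] = calls.get(name, 0.0) + clade_reads
    return calls


def _load_metaphlan(path, rank, synonyms) -> dict:
    prefix = _RANK_PREFIX[rank]
    calls = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}: malformed metaphlan row at line {lineno}")
            clade = parts[0]
            last = clade.split("|")[-1]
            if not last.startswith(prefix):
                continue
            try:
                abundance = float(parts[1])
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric abundance at line {lineno}"
                ) from None
            if abundance > 0:
                name = normalize_name(last, synonyms)
                calls[name] = calls.get(name, 0.0) + abundance
    return calls


def load_profile(
    path,
    dialect: str,
    method: str,
    sample_id: str,
    rank: str = "species",
    synonyms: Optional[Mapping[str, str]] = None,
) -> ClassifierProfile:
    """Parse one classifier output file into a rank-filtered profile."""
    if rank not in ("species", "genus"):
        raise ConfigError(f"rank must be species or genus, got {rank!r}")
    loaders = {
        "signature_tsv": _load_signature_tsv,
        "kraken_report": _load_kraken_report,
        "metaphlan_profile": _load_metaphlan,
    }
    if dialect not in loaders:
        raise ConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    calls = loaders[dialect](path, rank, synonyms)
    return ClassifierProfile(method=method, sample_id=sample_id, rank=rank, calls=calls)


@dataclass
class AgreementResult:
    """Per-call method agreement and its overlap partition."""

    matrix: pd.DataFrame  # taxa × samples; cells = number of agreeing methods
    overlap: dict  # agreement level (1..M) -> number of calls
    n_methods: int

    @property
    def total_calls(self) -> int:
        return sum(self.overlap.values())


def agreement(profiles: Sequence[ClassifierProfile], rank: str) -> AgreementResult:
    """Count, per (taxon, sample) call, the number of methods that made it.

    A call is a (taxon, sample) pair present (abundance > 0) in at least one
    method.  The overlap partition bins calls by their agreement level and
    sums to the total number of calls.
    """
    profiles = [p for p in profiles if p.rank == rank]
    methods = sorted({p.method for p in profiles})
    if len(methods) < 2:
        raise DataError("agreement needs profiles from at least two methods")
    presence: dict[tuple[str, str], set] = {}
    for p in profiles:
        for taxon, value in p.calls.items():
            if value > 0:
                presence.setdefault((taxon, p.sample_id), set()).add(p.method)
    taxa = sorted({t for t, _ in presence})
    samples = sorted({s for _, s in presence})
    matrix = pd.DataFrame(0, index=taxa, columns=samples, dtype=int)
    overlap = {level: 0 for level in range(1, len(methods) + 1)}
    for (taxon, sample), made_by in presence.items():
        matrix.at[taxon, sample] = len(made_by)
        overlap[len(made_by)] += 1
    return AgreementResult(matrix=matrix, overlap=overlap, n_methods=len(methods))


def merged_abundance_table(profiles: Sequence[ClassifierProfile]) -> pd.DataFrame:
    """Merge one method's per-sample profiles into a taxa × samples table.

    Missing (taxon, sample) cells are 0; taxa whose calls are all zero are
    dropped; columns are ordered by sample id.
    """
    methods = {p.method for p in profiles}
    if len(methods) > 1:
        raise DataError(f"merged table expects one method, got {sorted(methods)}")
    samples = sorted({p.sample_id for p in profiles})
    taxa = sorted({t for p in profiles for t, v in p.calls.items() if v > 0})
    table = pd.DataFrame(0.0, index=taxa, columns=samples)
    for p in profiles:
        for taxon, value in p.calls.items():
            if value > 0:
                table.at[taxon, p.sample_id] += value
    return table
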