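"""Scaffold-level taxonomic attribution from BLAST tabular output.

Scaffolds of at least 1 kb are aligned against a nucleotide database
(alignment itself is out of scope; the tabular hits are the input).  Per
scaffold the top hit is selected by bit score (ties broken by lower
e-value, then input order) and retained only if it covers at least 25% of
the query with at least 80% identity and an e-value of 1e-7 or lower — all
boundaries inclusive.  The contribution of each organism to the assembly is
the sum of its scaffolds' top-hit alignment lengths (capped at scaffold
length) divided by the total bases of the ≥ 1 kb assembly; the remainder is
reported as unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

MIN_SCAFFOLD_LEN = 1000
MIN_COVERAGE = 0.25
MIN_IDENTITY = 80.0
MAX_EVALUE = 1e-7

#: standard 12 tabular columns plus qlen and staxids
BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
    "staxids",
)
_NUMERIC = {
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
    "qlen": int,
}


@dataclass(frozen=True)
class BlastHit:
    """One typed BLAST tabular row."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    qlen: int
    staxids: str = ""
    line: int = 0


def filter_scaffolds(scaffolds, min_len: int = MIN_SCAFFOLD_LEN) -> list:
    """Keep scaffolds of length ≥ ``min_len`` (inclusive).

    ``scaffolds`` is a FASTA path or an iterable of ``(id, seq)`` pairs /
    Biopython records.  Returns ``(id, seq)`` pairs.
    """
    if isinstance(scaffolds, (str, bytes)) or hasattr(scaffolds, "__fspath__"):
        from Bio import SeqIO

        records = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(scaffolds), "fasta"))
    else:
        records = (
            (rec.id, str(rec.seq)) if hasattr(rec, "seq") else (rec[0], rec[1])
            for rec in scaffolds
        )
    return [(sid, seq) for sid, seq in records if len(seq) >= min_len]


def parse_blast_tabular(path) -> pd.DataFrame:
    """Parse BLAST tabular output (12 standard columns + qlen + staxids).

    Lines starting with '#' are skipped; rows with the wrong column count or
    unparsable numerics raise an error naming the line.  A 12-column file
    (missing qlen) is a configuration error, since coverage cannot be
    computed without the query length.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 12:
                raise ConfigError(
                    f"{path}: 12-column BLAST format lacks qlen "
                    "(use -outfmt '6 std qlen staxids')"
                )
            if len(parts) < 13:
                raise DataError(f"{path}: truncated row at line {lineno}")
            row = {"qseqid": parts[0], "sseqid": parts[1], "line": lineno}
            try:
                for (col, caster), value in zip(_NUMERIC.items(), parts[2:13]):
                    row[col] = caster(value)
            except ValueError:
                raise DataError(
                    f"{path}: unparsable numeric field at line {lineno}"
                ) from None
            row["staxids"] = parts[13] if len(parts) > 13 else ""
            rows.append(row)
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", *list(_NUMERIC), "staxids", "line"])


def select_top_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Best hit per scaffold: maximum bit score, ties by lower e-value, then
    input order.  Deterministic under any shuffling of input rows."""
    if hits.empty:
        return hits
    if "line" not in hits.columns:
        hits = hits.reset_index(drop=True).assign(line=lambda d: d.index + 1)
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "line"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    return ordered.groupby("qseqid", sort=True).head(1).reset_index(drop=True)


def select_top_hit(hits: Sequence[BlastHit]) -> Optional[BlastHit]:
    """Top hit among hits of one scaffold (or None when there are none)."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, h.line))


def apply_quality_filters(
    hit,
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    max_e: float = MAX_EVALUE,
) -> bool:
    """Inclusive quality rules: coverage ≥ min_cov, identity ≥ min_ident,
    e-value ≤ max_e.  Coverage is alignment length over query length."""
    coverage = hit.length / hit.qlen
    return coverage >= min_cov and hit.pident >= min_ident and hit.evalue <= max_e


def quality_mask(
    hits: pd.DataFrame,
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    max_e: float = MAX_EVALUE,
) -> pd.Series:
    """Vectorised :func:`apply_quality_filters` over a hit table."""
    coverage = hits["length"] / hits["qlen"]
    return (coverage >= min_cov) & (hits["pident"] >= min_ident) & (hits["evalue"] <= max_e)


def _organism_key(row) -> str:
    staxids = str(row.staxids).strip()
    return staxids if staxids and staxids.lower() not in ("", "nan", "n/a") else str(row.sseqid)


def contribution_fractions(
    top_hits: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    assembly_total_bases: Optional[int] = None,
) -> pd.DataFrame:
    """Per-organism base fractions of the assembly.

    ``top_hits`` holds the quality-passing top hit per scaffold.  Alignment
    lengths are capped at the scaffold's length so fractions cannot exceed
    one; the organism key is the subject taxid when present, else the
    subject id.  The table ends with an ``unassigned`` row so that the
    fractions sum to 1.
    """
    if assembly_total_bases is None:
        assembly_total_bases = sum(scaffold_lengths.values())
    if assembly_total_bases <= 0:
        raise DataError("assembly has no bases")
    assigned: dict[str, int] = {}
    for row in top_hits.itertuples():
        cap = scaffold_lengths.get(row.qseqid)
        if cap is None:
            raise DataError(f"scaffold {row.qseqid!r} missing from assembly")
        bases = min(int(row.length), int(cap))
        key = _organism_key(row)
        assigned[key] = assigned.get(key, 0) + bases
    rows = [
        {"organism": org, "bases": n, "fraction": n / assembly_total_bases}
        for org, n in sorted(assigned.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    unassigned = assembly_total_bases - sum(assigned.values())
    rows.append(
        {
            "organism": "unassigned",
            "bases": unassigned,
            "fraction": unassigned / assembly_total_bases,
        }
    )
    return pd.DataFrame(rows, columns=["organism", "bases", "fraction"])


def annotation_summary(
    scaffold_ids: Iterable[str],
    hits: pd.DataFrame,
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    max_e: float = MAX_EVALUE,
) -> dict:
    """Per-sample scaffold annotation accounting.

    "annotated" scaffolds have at least one BLAST hit; "high-quality"
    scaffolds have a top hit passing the quality filters.  Because the
    published convention for the two percentage columns is ambiguous, both
    candidate denominators are emitted (share of all scaffolds and share of
    annotated scaffolds).
    """
    scaffold_ids = list(scaffold_ids)
    total = len(scaffold_ids)
    if total == 0:
        raise DataError("no scaffolds supplied")
    with_hits = set(hits["qseqid"]) & set(scaffold_ids) if not hits.empty else set()
    top = select_top_hits(hits[hits["qseqid"].isin(with_hits)]) if with_hits else hits
    if top is not None and not top.empty:
        passing = top[quality_mask(top, min_cov, min_ident, max_e)]
        high_quality = set(passing["qseqid"])
    else:
        high_quality = set()
    annotated = len(with_hits)
    hq = len(high_quality)
    return {
        "total_scaffolds": total,
        "annotated": annotated,
        "without_hits": total - annotated,
        "pct_without_hits": 100.0 * (total - annotated) / total,
        "high_quality": hq,
        "without_high_quality": annotated - hq,
        "pct_without_hq_of_total": 100.0 * (total - hq) / total,
        "pct_without_hq_of_annotated": (
            100.0 * (annotated - hq) / annotated if annotated else 0.0
        ),
    }
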