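"""Confidence scoring of candidate taxa via the signature-ratio proportion test.

For each candidate taxon T the observed signature ratio SR̂ (signature hits /
total hits in the sample) is compared against the ratio SR expected from the
taxon's own reference sequences, estimated by drawing error-free 50-mers
from the references and classifying them against the full index.  A
one-sample proportion z-test

    z = (SR̂ − SR) / sqrt(SR (1 − SR) / n)

(with the expected proportion in the variance and n the number of
estimation trials, 100,000 by default) yields a two-sided p-value; Cohen's h
(|2 arcsin √SR̂ − 2 arcsin √SR|) measures the effect size and
ratio = SR̂ / SR the direct discrepancy.  Candidates are tiered:

* very high — ≥ 300 unique signature hits, h < 0.4 and ratio < 2.5;
* high      — ≥ 300 unique signature hits, h < 0.5 and ratio < 2.5;
* medium    — ≥ 300 unique signature hits and ratio < 4;
* low       — anything else; low-tier calls are discarded from summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .classify import TaxonHitSummary
from .errors import DataError
from .index import KmerIndex, _VALID
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

TIERS = ("very_high", "high", "medium", "low")

#: default tier thresholds
MIN_UNIQUE_SIGNATURE = 300
H_VERY_HIGH = 0.4
H_HIGH = 0.5
RATIO_CONFIDENT = 2.5
RATIO_MEDIUM = 4.0
DEFAULT_N_TRIALS = 100_000


@dataclass
class ConfidenceRecord:
    """Proportion-test outcome and confidence tier for one candidate taxon."""

    taxid: int
    observed_sr: float
    expected_sr: float
    n_trials: int
    z: Optional[float]
    p_value: Optional[float]
    cohens_h: float
    ratio: Optional[float]
    n_unique_signature: int
    tier: str = "low"
    degenerate: bool = False


def estimate_expected_sr(
    taxid: int,
    index: KmerIndex,
    n: int = DEFAULT_N_TRIALS,
    seed: Optional[int] = 0,
    max_mm: int = 3,
    rank: str = "species",
    taxonomy: Optional[Taxonomy] = None,
) -> tuple[float, int]:
    """Expected signature ratio of a taxon, by sampling its own references.

    Draws ``n`` k-mers uniformly at random (with replacement, error-free)
    from the taxon's curated reference sequences, classifies each against
    the full index, and returns ``(#signature among hits / #hits, n)``.
    Windows containing N are excluded from the draw.
    """
    seqs = index.sequences(taxid)
    if not seqs:
        raise DataError(f"taxon {taxid} has no reference sequence in the index")
    k = index.k
    windows: list[tuple[int, int]] = []
    for si, seq in enumerate(seqs):
        for pos in range(len(seq) - k + 1):
            if _VALID.issuperset(seq[pos : pos + k]):
                windows.append((si, pos))
    if not windows:
        raise DataError(f"taxon {taxid} has no valid length-{k} window")

    genus_cache: dict[int, int] = {}

    def to_rank(t: int) -> int:
        if rank == "species":
            return t
        g = genus_cache.get(t)
        if g is None:
            g = taxonomy.genus_of(t) if taxonomy else None
            genus_cache[t] = g = t if g is None else g
        return g

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(windows), size=n)
    n_hit = n_sig = 0
    for w in picks:
        si, pos = windows[w]
        hits = index.search(seqs[si][pos : pos + k], max_mm=max_mm)
        if hits:
            n_hit += 1
            if len({to_rank(t) for t in hits}) == 1:
                n_sig += 1
    if n_hit == 0:
        raise DataError(f"no sampled fragment of taxon {taxid} hit the index")
    return n_sig / n_hit, n


def enumerate_expected_sr(
    taxid: int,
    index: KmerIndex,
    max_mm: int = 3,
    rank: str = "species",
    taxonomy: Optional[Taxonomy] = None,
) -> float:
    """Exhaustive signature fraction over every reference window of a taxon.

    The position-weighted limit that :func:`estimate_expected_sr` converges
    to as n grows.
    """
    seqs = index.sequences(taxid)
    if not seqs:
        raise DataError(f"taxon {taxid} has no reference sequence in the index")
    k = index.k
    n_hit = n_sig = 0
    for seq in seqs:
        for pos in range(len(seq) - k + 1):
            window = seq[pos : pos + k]
            if not _VALID.issuperset(window):
                continue
            hits = index.search(window, max_mm=max_mm)
            if rank == "genus" and taxonomy is not None:
                hits = {taxonomy.genus_of(t) or t for t in hits}
            if hits:
                n_hit += 1
                if len(hits) == 1:
                    n_sig += 1
    if n_hit == 0:
        raise DataError(f"taxon {taxid} has no valid window hitting the index")
    return n_sig / n_hit


def proportion_z(observed_sr: float, expected_sr: float, n: int) -> tuple[float, float]:
    """One-sample proportion test statistic and two-sided normal p-value."""
    if not (0.0 < expected_sr < 1.0):
        raise DataError(
            f"expected proportion {expected_sr} gives a degenerate variance"
        )
    if n < 1:
        raise DataError("n must be >= 1")
    z = (observed_sr - expected_sr) / math.sqrt(expected_sr * (1.0 - expected_sr) / n)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


def cohens_h(p1: float, p2: float) -> float:
    """Arcsine-difference effect size between two proportions (absolute)."""
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise DataError(f"proportion {p} outside [0, 1]")
    return abs(2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2)))


def assign_tier(
    n_unique_signature: int,
    h: Optional[float],
    ratio: Optional[float],
    min_sig: int = MIN_UNIQUE_SIGNATURE,
) -> str:
    """Confidence tier from unique-signature count, Cohen's h and ratio.

    Rules are evaluated in order very_high → high → medium; the first match
    wins, otherwise low.  An undefined ratio (expected proportion of zero)
    can never satisfy a ratio bound, so such records fall to low.
    """
    if n_unique_signature >= min_sig and ratio is not None:
        if ratio < RATIO_CONFIDENT and h is not None:
            if h < H_VERY_HIGH:
                return "very_high"
            if h < H_HIGH:
                return "high"
        if ratio < RATIO_MEDIUM:
            return "medium"
    return "low"


def score_taxa(
    summaries: Iterable[TaxonHitSummary],
    index: KmerIndex,
    n: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    max_mm: int = 3,
    rank: str = "species",
    taxonomy: Optional[Taxonomy] = None,
    z_n_override: Optional[int] = None,
) -> list[ConfidenceRecord]:
    """Score every candidate taxon with a hit summary.

    ``z_n_override`` substitutes a different trial count in the z statistic
    (e.g. the sample's observed total hits) in place of the expected-SR
    estimation count.
    """
    summaries = list(summaries)
    records = []
    children = np.random.SeedSequence(seed).spawn(max(len(summaries), 1))
    for summary, child in zip(summaries, children):
        if summary.total_hits == 0:
            continue
        observed = summary.total_signature_hits / summary.total_hits
        expected, n_trials = estimate_expected_sr(
            summary.taxid,
            index,
            n=n,
            seed=child,
            max_mm=max_mm,
            rank=rank,
            taxonomy=taxonomy,
        )
        degenerate = not (0.0 < expected < 1.0)
        if degenerate:
            z = p = None
        else:
            z, p = proportion_z(observed, expected, z_n_override or n_trials)
        ratio = observed / expected if expected > 0 else None
        h = cohens_h(observed, expected)
        rec = ConfidenceRecord(
            taxid=summary.taxid,
            observed_sr=observed,
            expected_sr=expected,
            n_trials=n_trials,
            z=z,
            p_value=p,
            cohens_h=h,
            ratio=ratio,
            n_unique_signature=summary.unique_signature_hits,
            degenerate=degenerate,
        )
        rec.tier = assign_tier(rec.n_unique_signature, rec.cohens_h, rec.ratio)
        records.append(rec)
    return records


def filter_candidates(
    records: Iterable[ConfidenceRecord],
) -> tuple[list[ConfidenceRecord], list[ConfidenceRecord]]:
    """Split records into (kept: tier ≥ medium, discarded: low), order-preserving."""
    kept, discarded = [], []
    for rec in records:
        (discarded if rec.tier == "low" else kept).append(rec)
    return kept, discarded


def records_to_frame(
    records: Iterable[ConfidenceRecord],
    rank: str = "species",
    taxonomy: Optional[Taxonomy] = None,
) -> pd.DataFrame:
    """Tabulate confidence records, one row per taxon."""
    rows = [
        {
            "taxid": r.taxid,
            "name": taxonomy.name_of(r.taxid) if taxonomy else "",
            "rank": rank,
            "observed_sr": r.observed_sr,
            "expected_sr": r.expected_sr,
            "z": r.z,
            "p_value": r.p_value,
            "cohens_h": r.cohens_h,
            "ratio": r.ratio,
            "n_unique_signature": r.n_unique_signature,
            "tier": r.tier,
            "degenerate": r.degenerate,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "taxid",
            "name",
            "rank",
            "observed_sr",
            "expected_sr",
            "z",
            "p_value",
            "cohens_h",
            "ratio",
            "n_unique_signature",
            "tier",
            "degenerate",
        ],
    )
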