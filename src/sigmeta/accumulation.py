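"""Species-accumulation curves by read subsampling.

To judge whether sequencing depth was sufficient, each sample's reads are
subsampled without replacement at 10% intervals from 10% to 90% of total
reads, ten replicates per fraction, and the number of species with at least
one species-level signature hit is counted in every subsample.  With 20
samples this schedules 20 × 10 × 9 = 1,800 classification runs.  A plateau
before 100% indicates that deeper sequencing would reveal few additional
(sufficiently common) species.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import classify_sample, fragment_reads
from .errors import DataError
from .index import KmerIndex

#: default subsampling fractions: 10% .. 90% in 10% steps
DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 10))
DEFAULT_N_REPS = 10


def schedule(
    sample_ids: Sequence[str],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_reps: int = DEFAULT_N_REPS,
) -> list[tuple[str, float, int]]:
    """Enumerate every (sample, fraction, replicate) classification run."""
    return [
        (str(sid), float(f), rep)
        for sid in sample_ids
        for rep in range(n_reps)
        for f in fractions
    ]


def _replicate_seed(master_seed: int, sample_id: str, replicate: int):
    """Deterministic per-replicate seed so any run is independently reproducible."""
    return np.random.SeedSequence(
        [
            int(master_seed),
            zlib.crc32(str(sample_id).encode()),
            int(replicate),
        ]
    )


def subsample_reads(reads: Sequence, fraction: float, seed) -> list:
    """Draw ``round(fraction * N)`` reads without replacement, deterministically."""
    if not (0.0 < fraction <= 1.0):
        raise DataError(f"fraction must be in (0, 1], got {fraction}")
    reads = list(reads)
    if fraction == 1.0:
        return reads
    n_draw = int(fraction * len(reads) + 0.5)
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(reads), size=n_draw, replace=False)
    return [reads[i] for i in sorted(picks)]


def species_richness(
    reads: Iterable,
    index: KmerIndex,
    max_mm: int = 3,
    k: Optional[int] = None,
) -> int:
    """Number of species with ≥ 1 species-level signature hit in the reads."""
    fragments, _ = fragment_reads(reads, k=k or index.k)
    summaries, _ = classify_sample(fragments, index, rank="species", max_mm=max_mm)
    return sum(1 for s in summaries if s.total_signature_hits > 0)


@dataclass
class AccumulationCurve:
    """Long-format accumulation table plus its per-fraction summary."""

    sample_id: str
    table: pd.DataFrame  # columns: sample_id, fraction, replicate, species_count

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of species_count per fraction."""
        g = self.table.groupby("fraction")["species_count"]
        out = g.agg(mean="mean", sd="std").reset_index()
        out.insert(0, "sample_id", self.sample_id)
        return out


def accumulation_curve(
    sample_id: str,
    reads: Sequence,
    index: KmerIndex,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    max_mm: int = 3,
) -> AccumulationCurve:
    """Species accumulation under read subsampling.

    Reads (not fragments) are the subsampling unit; each subsample is then
    fragmented and classified.  Within one replicate the fractions are
    nested: a single random permutation of the reads is drawn and fraction
    f takes its first round(f·N) entries, so species counts — and hence the
    mean curve — are non-decreasing in the fraction by construction, as a
    rarefaction curve should be.  The full-sample (fraction 1.0) point is
    appended once as replicate 0.
    """
    reads = list(reads)
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_replicate_seed(seed, sample_id, rep))
        order = rng.permutation(len(reads))
        for fraction in fractions:
            if not (0.0 < fraction <= 1.0):
                raise DataError(f"fraction must be in (0, 1], got {fraction}")
            n_draw = int(fraction * len(reads) + 0.5)
            subset = [reads[i] for i in sorted(order[:n_draw])]
            rows.append(
                {
                    "sample_id": sample_id,
                    "fraction": float(fraction),
                    "replicate": rep,
                    "species_count": species_richness(subset, index, max_mm=max_mm),
                }
            )
    rows.append(
        {
            "sample_id": sample_id,
            "fraction": 1.0,
            "replicate": 0,
            "species_count": species_richness(reads, index, max_mm=max_mm),
        }
    )
    return AccumulationCurve(sample_id=sample_id, table=pd.DataFrame(rows))
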