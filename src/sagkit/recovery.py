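"""Genome recovery and completeness modelling for pooled single-cell libraries.

A library's recoverable territory is its coverage mask (sites with depth at
or above a floor); co-assembly of several libraries is modelled as the union
of their masks.  Completeness is a marker-recovery proxy: the percentage of
core-gene-like marker intervals whose length is sufficiently covered — a
stand-in for running a core-eukaryotic-gene completeness estimator on an
actual assembly.  Assembly size is proxied by the covered base count, which
preserves the completeness-versus-size relationship without an assembler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import (
    AmplificationModel,
    GenomeModel,
    LibraryPileup,
    PhasedVariantSet,
    simulate_library,
)


@dataclass
class CoverageMask:
    """Boolean covered/uncovered vector over genome positions."""

    library_id: str
    covered: np.ndarray
    min_depth: int = 1

    def __post_init__(self) -> None:
        self.covered = np.asarray(self.covered, dtype=bool)

    @property
    def length(self) -> int:
        return int(self.covered.size)

    @property
    def covered_fraction(self) -> float:
        return float(self.covered.mean()) if self.covered.size else 0.0

    @property
    def covered_bases(self) -> int:
        return int(self.covered.sum())


def mask_from_pileup(pileup: LibraryPileup, min_depth: int = 1) -> CoverageMask:
    """Covered ⇔ total depth >= min_depth (inclusive)."""
    return CoverageMask(
        library_id=pileup.library_id,
        covered=pileup.total_depth >= min_depth,
        min_depth=min_depth,
    )


def union_mask(masks: list[CoverageMask]) -> CoverageMask:
    """Positionwise OR of masks: the co-assembly's recoverable territory."""
    if not masks:
        raise ValueError("need at least one mask")
    lengths = {m.length for m in masks}
    if len(lengths) != 1:
        raise ValueError(f"mask lengths differ: {sorted(lengths)}")
    out = np.zeros(masks[0].length, dtype=bool)
    for m in masks:
        out |= m.covered
    return CoverageMask(library_id="union", covered=out, min_depth=masks[0].min_depth)


@dataclass
class MarkerSet:
    """Non-overlapping marker intervals standing in for core genes.

    A marker counts as recovered when at least `recover_frac` of its length
    is covered (inclusive threshold).
    """

    intervals: list  # (start, end) 0-based half-open
    recover_frac: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.recover_frac <= 1:
            raise ValueError("recover_frac must lie in (0, 1]")
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("marker intervals must not overlap")
        for s, e in ivs:
            if not 0 <= s < e:
                raise ValueError(f"bad interval ({s}, {e})")
        self.intervals = ivs


def make_markers(
    genome_length: int, n_markers: int = 100, marker_len: int = 500
) -> MarkerSet:
    """Evenly spaced marker intervals across a genome."""
    if n_markers * marker_len > genome_length:
        raise ValueError("markers do not fit in the genome")
    stride = genome_length // n_markers
    return MarkerSet(intervals=[(i * stride, i * stride + marker_len) for i in range(n_markers)])


def marker_completeness(mask: CoverageMask, markers: MarkerSet) -> float:
    """Percentage of markers whose covered length reaches the recovery floor."""
    if not markers.intervals:
        raise ValueError("empty marker set")
    recovered = 0
    for s, e in markers.intervals:
        if e > mask.length:
            raise ValueError(f"marker ({s}, {e}) extends past the genome")
        cov = int(mask.covered[s:e].sum())
        if cov >= markers.recover_frac * (e - s):
            recovered += 1
    return 100.0 * recovered / len(markers.intervals)


@dataclass
class RecoveryReport:
    """Per-library and co-assembly (union) recovery of one experiment.

    `table` has one row per library plus a final "union" row with columns
    library_id, cells, covered_fraction, covered_bases, completeness_pct,
    incorporated_read_fraction.
    """

    table: pd.DataFrame
    masks: list = field(default_factory=list)
    union: CoverageMask | None = None

    @property
    def points(self) -> pd.DataFrame:
        """Completeness-vs-size scatter table (libraries only)."""
        lib = self.table[self.table["library_id"] != "union"]
        return lib[["library_id", "completeness_pct", "covered_bases"]].copy()


def recovery_experiment(
    genome: GenomeModel,
    variants: PhasedVariantSet,
    amp: AmplificationModel,
    library_design: list[int],
    seed: int = 0,
    markers: MarkerSet | None = None,
    min_depth: int = 1,
) -> RecoveryReport:
    """Simulate one multi-library recovery experiment.

    Each entry of `library_design` is the cell count of one library; all
    libraries are drawn from the same individual.  Per-library coverage
    masks, marker completeness and the union (co-assembly proxy) are
    reported, along with the fraction of each library's reads falling
    inside the union mask.
    """
    if not library_design:
        raise ValueError("library design is empty")
    if markers is None:
        markers = make_markers(genome.length, n_markers=min(100, genome.length // 500), marker_len=min(500, genome.length // 10))
    pileups = [
        simulate_library(genome, variants, cells=c, amp=amp, seed=seed * 1000 + i)
        for i, c in enumerate(library_design)
    ]
    masks = [mask_from_pileup(p, min_depth=min_depth) for p in pileups]
    union = union_mask(masks)
    rows = []
    for p, m in zip(pileups, masks):
        depth = p.total_depth
        total_reads = int(depth.sum())
        incorporated = (
            float(depth[union.covered].sum() / total_reads) if total_reads else 0.0
        )
        rows.append(
            {
                "library_id": p.library_id,
                "cells": p.cells,
                "covered_fraction": m.covered_fraction,
                "covered_bases": m.covered_bases,
                "completeness_pct": marker_completeness(m, markers),
                "incorporated_read_fraction": incorporated,
            }
        )
    rows.append(
        {
            "library_id": "union",
            "cells": int(sum(library_design)),
            "covered_fraction": union.covered_fraction,
            "covered_bases": union.covered_bases,
            "completeness_pct": marker_completeness(union, markers),
            "incorporated_read_fraction": 1.0,
        }
    )
    return RecoveryReport(table=pd.DataFrame(rows), masks=masks, union=union)


def completeness_size_correlation(points: pd.DataFrame) -> float:
    """Pearson correlation of completeness against the covered-base proxy."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = points["covered_bases"].to_numpy(float)
    y = points["completeness_pct"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance in correlation inputs")
    r, _p = stats.pearsonr(x, y)
    return float(r)
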