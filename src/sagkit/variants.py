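"""Variant calling and ploidy inference from single-cell library pileups.

The calling stage mirrors a pooled-frequency caller: a SNV is emitted at any
site with depth >= 5 where a non-reference base reaches 2 reads and 1% of
the depth.  Downstream, calls are split into a heterozygous band (allele
frequency strictly above 0.25 and below 0.95) and reference-discordant fixed
differences (>= 0.99), and ploidy is read off the allele-frequency spectrum:
an interior mode at 1/2 indicates diploidy, modes at 1/3 and 2/3 triploidy,
and a near-empty heterozygous band haploidy.  K-mer spectra corroborate the
calls, and heterozygous-SNP sharing across independent libraries separates
within-cell heterozygosity from cell-to-cell polymorphism.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .synthetic import BASES, GenomeModel, LibraryPileup

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class VariantCall:
    """One single-nucleotide variant call in one library."""

    position: int  # 0-based
    ref: str
    alt: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if not 0 < self.alt_count <= self.depth:
            raise ValueError("alt_count must lie in (0, depth]")

    @property
    def af(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt)


@dataclass
class VariantCallSet:
    """Ordered variant calls for one library (unique positions)."""

    library_id: str
    cells: int
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [c.position for c in self.calls]
        if len(positions) != len(set(positions)):
            raise ValueError("positions must be unique within a call set")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def afs_values(self) -> np.ndarray:
        return np.array([c.af for c in self.calls])

    def keys(self) -> set[tuple[int, str]]:
        return {c.key for c in self.calls}


def call_variants(
    pileup: LibraryPileup,
    reference: GenomeModel,
    min_coverage: int = 5,
    min_alt_frac: float = 0.01,
    min_alt_reads: int = 2,
) -> VariantCallSet:
    """Pooled-frequency SNV calling from a base-depth pileup.

    A call is emitted at each site with total depth >= `min_coverage` where
    some non-reference base has count >= `min_alt_reads` and fraction >=
    `min_alt_frac` of the depth; the best-supported such base is reported
    (ties broken alphabetically).  Only single-nucleotide substitutions are
    considered.
    """
    if pileup.length != reference.length:
        raise ValueError(
            f"pileup length {pileup.length} != reference length {reference.length}"
        )
    depths = pileup.depths
    total = depths.sum(axis=1)
    ref_idx = reference.base_indices()
    alt_counts = depths.copy()
    alt_counts[np.arange(len(ref_idx)), ref_idx] = -1  # mask the reference base
    # best non-reference base; argmax breaks ties toward the smaller index,
    # i.e. alphabetically
    best_idx = alt_counts.argmax(axis=1)
    best_count = alt_counts[np.arange(len(ref_idx)), best_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, best_count / np.maximum(total, 1), 0.0)
    callable_sites = (
        (total >= min_coverage)
        & (best_count >= min_alt_reads)
        & (frac >= min_alt_frac)
    )
    positions = np.flatnonzero(callable_sites)
    calls = [
        VariantCall(
            position=int(p),
            ref=BASES[ref_idx[p]],
            alt=BASES[best_idx[p]],
            depth=int(total[p]),
            alt_count=int(best_count[p]),
        )
        for p in positions
    ]
    return VariantCallSet(library_id=pileup.library_id, cells=pileup.cells, calls=calls)


def partition_calls(
    calls: VariantCallSet,
    het_lower: float = 0.25,
    het_upper: float = 0.95,
    fixed_min: float = 0.99,
) -> tuple[VariantCallSet, VariantCallSet, VariantCallSet]:
    """Split calls into heterozygous band, fixed differences, and the rest.

    Heterozygous: het_lower < af < het_upper (both strict — a call at
    exactly 25% is discarded).  Fixed: af >= fixed_min.  The three parts
    partition the input.
    """
    if not 0 < het_lower < het_upper <= fixed_min <= 1:
        raise ValueError(
            "thresholds must satisfy 0 < het_lower < het_upper <= fixed_min <= 1"
        )
    het, fixed, discarded = [], [], []
    for c in calls:
        if het_lower < c.af < het_upper:
            het.append(c)
        elif c.af >= fixed_min:
            fixed.append(c)
        else:
            discarded.append(c)
    mk = lambda cs: VariantCallSet(calls.library_id, calls.cells, cs)
    return mk(het), mk(fixed), mk(discarded)


@dataclass
class AlleleFrequencySpectrum:
    """Histogram of per-site alternate-allele fractions over (0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/edges length mismatch")

    @property
    def n_variants(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def afs(calls: VariantCallSet, bin_width: float = 0.02) -> AlleleFrequencySpectrum:
    """Bin allele frequencies of (heterozygous) calls into a spectrum."""
    nbins = round(1.0 / bin_width)
    if abs(nbins * bin_width - 1.0) > 1e-9 or nbins < 1:
        raise ValueError(f"bin_width {bin_width} must divide 1 evenly")
    edges = np.linspace(0.0, 1.0, nbins + 1)
    values = calls.afs_values()
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram's last bin is closed on the right, so af = 1.0 is included
    return AlleleFrequencySpectrum(bin_edges=edges, counts=counts)


@dataclass
class KmerSpectrum:
    """Multiplicity histogram of distinct k-mers."""

    k: int
    histogram: dict  # multiplicity -> number of distinct k-mers
    canonical: bool

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.histogram.items())


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def kmer_spectrum(
    sequences, k: int, canonical: bool = False
) -> KmerSpectrum:
    """Exact k-mer multiplicity histogram over a collection of sequences.

    K-mers containing non-ACGT characters are skipped.  In canonical mode a
    k-mer and its reverse complement are counted as one (the
    lexicographically smaller spelling).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = list(sequences)
    if all(len(s) < k for s in seqs):
        raise ValueError(f"k={k} exceeds every sequence length")
    acgt = set(BASES)
    counter: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not set(kmer) <= acgt:
                continue
            if canonical:
                kmer = min(kmer, _revcomp(kmer))
            counter[kmer] += 1
    hist = Counter(counter.values())
    return KmerSpectrum(k=k, histogram=dict(hist), canonical=canonical)


def detect_peaks(
    values,
    positions=None,
    smooth_window: int = 3,
    min_prominence_frac: float = 0.1,
    refine: bool = False,
    refine_halfwidth: int = 4,
) -> list[float]:
    """Peak positions of a histogram after moving-average smoothing.

    Local maxima of the smoothed series whose prominence reaches
    `min_prominence_frac` of the global smoothed maximum; positions are
    returned in increasing order.  `positions` defaults to indices.
    With `refine`, each peak position is replaced by the intensity-weighted
    centroid over ±`refine_halfwidth` bins — far more stable than the argmax
    bin for broad, noisy modes.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty histogram")
    if positions is None:
        positions = np.arange(v.size, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(v, kernel, mode="same")
    else:
        sm = v
    if sm.max() <= 0:
        return []
    padded = np.concatenate([[0.0], sm, [0.0]])  # make edge maxima visible
    idx, _ = find_peaks(padded, prominence=min_prominence_frac * sm.max())
    idx = [i - 1 for i in idx if 0 <= i - 1 < v.size]
    out = []
    for i in idx:
        if refine:
            lo = max(0, i - refine_halfwidth)
            hi = min(v.size, i + refine_halfwidth + 1)
            weights = sm[lo:hi]
            if weights.sum() > 0:
                out.append(float(np.average(positions[lo:hi], weights=weights)))
                continue
        out.append(float(positions[i]))
    return out


@dataclass(frozen=True)
class PloidyThresholds:
    """Tunables of the allele-frequency-spectrum ploidy classifier."""

    haploid_max_density: float = 50.0  # het SNPs per callable Mb
    peak_tol: float = 0.05  # tolerance around 1/2, 1/3, 2/3
    min_prominence_frac: float = 0.2
    smooth_window: int = 3
    kde_bandwidth: float = 0.05  # Gaussian bandwidth for mode estimation


def _afs_density_peaks(
    spectrum: AlleleFrequencySpectrum,
    bandwidth: float,
    min_prominence_frac: float,
) -> list[tuple[float, float]]:
    """(position, height) modes of a Gaussian-kernel density of the spectrum.

    Kernel smoothing of bin-centre masses approximates a KDE of the
    underlying allele fractions (binning error <= half a bin width) and
    locates broad modes far more stably than the argmax histogram bin.
    """
    if spectrum.n_variants == 0:
        return []
    grid = np.arange(0.0, 1.0 + 1e-9, 0.0025)
    centers = spectrum.bin_centers
    weights = spectrum.counts.astype(float)
    dens = np.zeros_like(grid)
    for c, w in zip(centers, weights):
        if w > 0:
            dens += w * np.exp(-0.5 * ((grid - c) / bandwidth) ** 2)
    if dens.max() <= 0:
        return []
    idx, _ = find_peaks(
        np.concatenate([[0.0], dens, [0.0]]), prominence=min_prominence_frac * dens.max()
    )
    idx = [i - 1 for i in idx if 0 <= i - 1 < grid.size]
    # order by position; dominance can be recovered from the density heights
    return [(float(grid[i]), float(dens[i])) for i in idx]


@dataclass
class PloidyCall:
    label: str  # haploid | diploid | triploid | unknown
    het_density: float
    peak_positions: list
    shared_het_count: int = 0
    evidence: str = ""


def classify_ploidy(
    afs_result: AlleleFrequencySpectrum,
    kspec: KmerSpectrum | None = None,
    het_density: float = 0.0,
    thresholds: PloidyThresholds = PloidyThresholds(),
) -> PloidyCall:
    """Classify ploidy from the heterozygous allele-frequency spectrum.

    haploid: heterozygous density below `haploid_max_density` and no
    interior AF peak.  diploid: the dominant interior peak lies within
    `peak_tol` of 1/2.  triploid: peaks within `peak_tol` of both 1/3 and
    2/3.  Conflicting diploid and triploid evidence, or anything else,
    yields unknown.  A k-mer spectrum, when provided, only annotates the
    evidence string (a heterozygous mode near half the homozygous mode
    supports diploidy); allele-frequency evidence decides.
    """
    t = thresholds
    peak_info = _afs_density_peaks(
        afs_result, bandwidth=t.kde_bandwidth, min_prominence_frac=t.min_prominence_frac
    )
    peak_info = [(p, h) for p, h in peak_info if 0.0 < p < 1.0]
    interior = [p for p, _h in peak_info]
    tol = t.peak_tol + 1e-9  # inclusive tolerance, robust to float rounding
    notes = [f"het_density={het_density:.1f}/Mb", f"peaks={[round(p, 3) for p in interior]}"]

    dominant = None
    if peak_info:
        dominant = max(peak_info, key=lambda ph: ph[1])[0]

    triploid_ev = any(abs(p - 1 / 3) <= tol for p in interior) and any(
        abs(p - 2 / 3) <= tol for p in interior
    )
    diploid_ev = dominant is not None and abs(dominant - 0.5) <= tol

    if kspec is not None and kspec.histogram:
        modes = detect_peaks(
            list(kspec.histogram.values()),
            positions=list(kspec.histogram.keys()),
            smooth_window=1,
            min_prominence_frac=t.min_prominence_frac,
        )
        notes.append(f"kmer_modes={[round(m, 1) for m in modes]}")
        if len(modes) >= 2 and abs(modes[0] * 2 - modes[-1]) <= 0.2 * modes[-1]:
            notes.append("kmer: het mode at half the homozygous mode (diploid-like)")

    if het_density < t.haploid_max_density and not interior:
        label = "haploid"
    elif triploid_ev and diploid_ev:
        label = "unknown"
        notes.append("conflicting diploid and triploid evidence")
    elif triploid_ev:
        label = "triploid"
    elif diploid_ev:
        label = "diploid"
    else:
        label = "unknown"
    return PloidyCall(
        label=label,
        het_density=het_density,
        peak_positions=interior,
        evidence="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# Sharing analyses across libraries


@dataclass
class SharingReport:
    """Heterozygous-SNP sharing across independent libraries.

    pairwise: (library_id, library_id) -> count of het calls matching on
    (position, alt).  multi_library_count: calls present in at least two
    libraries.  The classification compares the multi-library count per
    callable megabase against the non-haploid threshold.
    """

    pairwise: dict
    multi_library_count: int
    per_library: dict
    callable_mb: float | None = None
    non_haploid_per_mb: float = 250.0
    haploid_per_mb: float = 50.0

    @property
    def multi_per_mb(self) -> float | None:
        if self.callable_mb is None or self.callable_mb <= 0:
            return None
        return self.multi_library_count / self.callable_mb

    @property
    def classification(self) -> str:
        rate = self.multi_per_mb
        if rate is None:
            return "unknown"
        if rate > self.non_haploid_per_mb:
            return "non_haploid_by_sharing"
        if rate < self.haploid_per_mb:
            return "haploid_like"
        return "intermediate"


def shared_het_analysis(
    callsets: list[VariantCallSet],
    callable_mb: float | None = None,
    non_haploid_per_mb: float = 250.0,
    haploid_per_mb: float = 50.0,
) -> SharingReport:
    """Count heterozygous calls recurring across libraries.

    Recurrence of the same (position, alt) het call in independent
    single-cell libraries marks within-individual heterozygosity (every
    cell carries it) as opposed to cell-to-cell polymorphism.  Default
    density thresholds correspond to genome-wide bounds of 10,000 (non-
    haploid) and 2,000 (haploid) shared SNPs on a 40-Mb genome.
    """
    if len(callsets) < 2:
        raise ValueError("at least two call sets are required")
    keysets = {cs.library_id: cs.keys() for cs in callsets}
    pairwise = {
        (a, b): len(keysets[a] & keysets[b])
        for a, b in itertools.combinations(keysets, 2)
    }
    counts: Counter = Counter()
    for ks in keysets.values():
        counts.update(ks)
    multi = sum(1 for _k, n in counts.items() if n >= 2)
    per_library = {lid: len(ks) for lid, ks in keysets.items()}
    return SharingReport(
        pairwise=pairwise,
        multi_library_count=multi,
        per_library=per_library,
        callable_mb=callable_mb,
        non_haploid_per_mb=non_haploid_per_mb,
        haploid_per_mb=haploid_per_mb,
    )


def isolate_recovery(
    isolate_calls: VariantCallSet, library_calls: VariantCallSet
) -> float:
    """Fraction of isolate SNPs recovered by a single-cell library."""
    isolate = isolate_calls.keys()
    if not isolate:
        raise ValueError("isolate call set is empty")
    return len(isolate & library_calls.keys()) / len(isolate)


def fixed_difference_sharing(
    callsets: list[VariantCallSet],
    gene_intervals: dict,
    per_gene_coverage,
    coverage_min: float = 0.9,
    fixed_min: float = 0.99,
) -> dict:
    """Exclusive-intersection (UpSet) table of fixed differences by gene.

    Only genes with coverage strictly above `coverage_min` in *all*
    libraries are considered; within them, calls with af >= `fixed_min`
    are grouped by the exact set of libraries carrying them.  Returns
    {frozenset of library_ids: count}.
    """
    libs = [cs.library_id for cs in callsets]
    for lib in libs:
        if lib not in per_gene_coverage.index:
            raise ValueError(f"missing coverage row for library {lib!r}")
        for gene in gene_intervals:
            if gene not in per_gene_coverage.columns:
                raise ValueError(f"missing coverage column for gene {gene!r}")
    eligible = [
        gene
        for gene in gene_intervals
        if (per_gene_coverage.loc[libs, gene] > coverage_min).all()
    ]
    spans = [gene_intervals[g] for g in eligible]

    def in_eligible(pos: int) -> bool:
        return any(s <= pos < e for s, e in spans)

    membership: dict = {}
    for cs in callsets:
        for c in cs:
            if c.af >= fixed_min and in_eligible(c.position):
                membership.setdefault(c.key, set()).add(cs.library_id)
    table: Counter = Counter(frozenset(v) for v in membership.values())
    return dict(table)
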