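"""Synthetic data generators for single-amplified-genome (SAG) analyses.

Everything downstream of wet-lab sequencing is driven from here: reference
genomes, planted variants with ploidy-determined allele fractions, pooled
single-cell libraries with MDA-style amplification dropout, enzyme
presence/absence matrices, and orthology cluster tables.

The amplification model is a per-genome-copy two-state Markov chain along the
chromosome (covered/dropped tracts with geometric lengths), a lognormal gain
per covered tract, and Poisson read depth — a tractable emulation of the
long-tract coverage bias of multiple displacement amplification, with a
closed-form stationary coverage probability that serves as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparative import OrthoClusterSet, PresenceAbsenceMatrix

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
# for base i, the three other base indices (error targets)
_OTHER = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int64)


@dataclass(frozen=True)
class GenomeModel:
    """A reference chromosome: an ACGT string plus the seed that made it."""

    sequence: str
    seed: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_indices(self) -> np.ndarray:
        """Sequence as an int array (A=0, C=1, G=2, T=3)."""
        return np.array([_BASE_IDX[b] for b in self.sequence], dtype=np.int64)


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> GenomeModel:
    """Draw an i.i.d. random genome with the requested GC content.

    Parameters
    ----------
    length : genome size in base pairs (must be positive).
    gc : P(G) + P(C), split evenly between G and C (and A/T likewise).
    seed : RNG seed; regeneration with the same seed is bit-identical.
    """
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(list(BASES), size=length, p=probs)
    return GenomeModel(sequence="".join(seq), seed=seed)


@dataclass(frozen=True)
class PloidyConfig:
    """Ploidy and per-base polymorphism rates for one simulated individual.

    het_rate is the density of within-individual heterozygous sites;
    fixed_rate the density of homozygous differences from the reference.
    A haploid individual has no within-cell heterozygosity by definition.
    """

    ploidy: int
    het_rate: float = 0.0
    fixed_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2, 3):
            raise ValueError(f"ploidy must be 1, 2 or 3, got {self.ploidy}")
        if not 0.0 <= self.het_rate <= 0.05:
            raise ValueError(f"het_rate must lie in [0, 0.05], got {self.het_rate}")
        if self.fixed_rate < 0:
            raise ValueError("fixed_rate must be non-negative")
        if self.ploidy == 1 and self.het_rate > 0:
            raise ValueError("a haploid genome cannot carry heterozygous sites")


@dataclass
class PhasedVariantSet:
    """Planted variants with known alternate-copy counts (the latent truth).

    At a site with ``alt_copies`` of ``ploidy`` genome copies carrying the
    alternate base, the expected observed allele fraction is
    alt_copies / ploidy — 1/2 for diploid het sites, 1/3 or 2/3 for triploid.
    """

    ploidy: int
    positions: np.ndarray  # int64, strictly increasing, 0-based
    ref: np.ndarray  # unicode length-1
    alt: np.ndarray
    alt_copies: np.ndarray  # int64 in [1, ploidy]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.alt_copies = np.asarray(self.alt_copies, dtype=np.int64)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("variant positions must be strictly increasing")
        if self.alt_copies.size and (
            self.alt_copies.min() < 1 or self.alt_copies.max() > self.ploidy
        ):
            raise ValueError("alt_copies must lie in [1, ploidy]")

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def het_mask(self) -> np.ndarray:
        """Heterozygous ⇔ alt_copies < ploidy."""
        return self.alt_copies < self.ploidy

    @property
    def expected_af(self) -> np.ndarray:
        return self.alt_copies / self.ploidy


def plant_variants(
    genome: GenomeModel, config: PloidyConfig, seed: int = 0
) -> PhasedVariantSet:
    """Plant heterozygous and fixed variants onto a reference.

    Heterozygous site count is Binomial(length, het_rate).  For ploidy 3 the
    alternate-copy count at each het site is drawn uniformly from {1, 2}, so
    expected allele fractions concentrate at 1/3 and 2/3; for ploidy 2 it is
    always 1 (expected fraction 1/2).  Fixed-difference sites carry the
    alternate on every copy.
    """
    rng = np.random.default_rng(seed)
    L = genome.length
    u = rng.random(L)
    het_sites = u < config.het_rate
    fixed_sites = (u >= config.het_rate) & (u < config.het_rate + config.fixed_rate)
    positions = np.flatnonzero(het_sites | fixed_sites)
    is_het = het_sites[positions]

    ref = np.array(list(genome.sequence))[positions]
    ref_idx = np.array([_BASE_IDX[b] for b in ref], dtype=np.int64)
    alt_idx = _OTHER[ref_idx, rng.integers(0, 3, size=positions.size)]
    alt = np.array(list(BASES))[alt_idx]

    alt_copies = np.full(positions.size, config.ploidy, dtype=np.int64)
    if config.ploidy == 2:
        alt_copies[is_het] = 1
    elif config.ploidy == 3:
        alt_copies[is_het] = rng.integers(1, 3, size=int(is_het.sum()))
    return PhasedVariantSet(
        ploidy=config.ploidy, positions=positions, ref=ref, alt=alt, alt_copies=alt_copies
    )


@dataclass(frozen=True)
class AmplificationModel:
    """Whole-genome-amplification emulation parameters.

    covered_prob : stationary probability that one genome copy is amplified
        at a site (per-copy coverage breadth).
    mean_tract_bp : mean length of a covered tract; together with
        covered_prob it fixes the dropped-tract mean through stationarity.
        Setting mean_tract_bp = 1/(1 - covered_prob) makes per-site coverage
        i.i.d. (the independent-dropout special case).
    gain_sigma : log-scale spread of the per-tract amplification gain
        (lognormal with unit mean).
    error_rate : per-base miscall probability, uniform over the other bases.
    mean_depth : target mean read depth per amplified genome copy.
    """

    covered_prob: float = 0.7
    mean_tract_bp: float = 2000.0
    gain_sigma: float = 0.5
    error_rate: float = 0.005
    mean_depth: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.covered_prob <= 1.0:
            raise ValueError("covered_prob must lie in [0, 1]")
        if self.mean_tract_bp < 1:
            raise ValueError("mean_tract_bp must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")


@dataclass
class LibraryPileup:
    """Per-site base depths for one pooled library (columns A, C, G, T)."""

    library_id: str
    cells: int
    depths: np.ndarray  # (L, 4) int64

    @property
    def length(self) -> int:
        return int(self.depths.shape[0])

    @property
    def total_depth(self) -> np.ndarray:
        return self.depths.sum(axis=1)


def _alternating_runs(
    length: int, p_leave_cov: float, p_leave_drop: float, covered_prob: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Run lengths and states of the stationary two-state chain over `length` sites.

    Returns (run_lengths, run_states); run_states is boolean (True = covered).
    Geometric run lengths make this exactly the stationary Markov chain when
    the initial state is drawn from the stationary law (memorylessness).
    """
    state = bool(rng.random() < covered_prob)
    lengths: list[np.ndarray] = []
    states: list[np.ndarray] = []
    total = 0
    # mean run length of the alternating sequence, for batch sizing
    mean_run = 0.5 / p_leave_cov + 0.5 / p_leave_drop
    chunk = max(16, int(1.2 * length / mean_run) + 8)
    while total < length:
        n_first = (chunk + 1) // 2  # runs in the starting state
        p_first, p_second = (
            (p_leave_cov, p_leave_drop) if state else (p_leave_drop, p_leave_cov)
        )
        runs = np.empty(chunk, dtype=np.int64)
        runs[0::2] = rng.geometric(p_first, size=n_first)
        runs[1::2] = rng.geometric(p_second, size=chunk - n_first)
        st = np.empty(chunk, dtype=bool)
        st[0::2] = state
        st[1::2] = not state
        lengths.append(runs)
        states.append(st)
        total += int(runs.sum())
        state = not bool(st[-1])  # next chunk starts in the opposite state
    run_lengths = np.concatenate(lengths)
    run_states = np.concatenate(states)
    # truncate to exactly `length` sites
    ends = np.cumsum(run_lengths)
    last = int(np.searchsorted(ends, length))
    run_lengths = run_lengths[: last + 1].copy()
    run_states = run_states[: last + 1]
    run_lengths[-1] -= int(ends[last] - length)
    return run_lengths, run_states


def _copy_depth(
    length: int, amp: AmplificationModel, rng
) -> np.ndarray:
    """Read depth along one genome copy: tract dropout + lognormal gain + Poisson."""
    p = amp.covered_prob
    if p <= 0.0 or amp.mean_depth == 0:
        return np.zeros(length, dtype=np.int64)
    if p >= 1.0:
        gains = rng.lognormal(-0.5 * amp.gain_sigma**2, amp.gain_sigma)
        return rng.poisson(amp.mean_depth * gains, size=length)
    a = min(1.0, 1.0 / amp.mean_tract_bp)  # covered -> dropped
    b = min(1.0, a * p / (1.0 - p))  # dropped -> covered
    run_lengths, run_states = _alternating_runs(length, a, b, p, rng)
    lam = np.zeros(length)
    cov_lengths = run_lengths[run_states]
    if cov_lengths.size:
        gains = rng.lognormal(
            -0.5 * amp.gain_sigma**2, amp.gain_sigma, size=cov_lengths.size
        )
        mask = np.repeat(run_states, run_lengths)
        lam[mask] = amp.mean_depth * np.repeat(gains, cov_lengths)
    return rng.poisson(lam)


def simulate_library(
    genome: GenomeModel,
    variants: PhasedVariantSet,
    cells: int,
    amp: AmplificationModel,
    seed: int = 0,
    library_id: str | None = None,
) -> LibraryPileup:
    """Simulate the pooled pileup of `cells` cells of one individual.

    Each cell contributes `ploidy` genome copies; each copy is amplified
    independently under the tract-dropout model, sequenced at the copy's
    alleles with uniform miscalls at `error_rate`, and depths are summed.
    The first `alt_copies` copies of each cell carry the alternate allele.
    """
    if cells < 1:
        raise ValueError(f"cells must be >= 1, got {cells}")
    rng = np.random.default_rng(seed)
    L = genome.length
    ploidy = variants.ploidy
    ref_idx = np.array([_BASE_IDX[b] for b in genome.sequence], dtype=np.int64)
    alt_idx = np.array([_BASE_IDX[b] for b in variants.alt], dtype=np.int64)

    counts = np.zeros((L, 4), dtype=np.int64)
    rows = np.arange(L)
    for _cell in range(cells):
        for copy_i in range(ploidy):
            true_base = ref_idx.copy()
            carries = variants.alt_copies > copy_i
            true_base[variants.positions[carries]] = alt_idx[carries]
            depth = _copy_depth(L, amp, rng)
            if amp.error_rate > 0:
                errs = rng.binomial(depth, amp.error_rate)
                correct = depth - errs
                e1 = rng.binomial(errs, 1.0 / 3.0)
                e2 = rng.binomial(errs - e1, 0.5)
                e3 = errs - e1 - e2
                others = _OTHER[true_base]
                np.add.at(counts, (rows, true_base), correct)
                np.add.at(counts, (rows, others[:, 0]), e1)
                np.add.at(counts, (rows, others[:, 1]), e2)
                np.add.at(counts, (rows, others[:, 2]), e3)
            else:
                np.add.at(counts, (rows, true_base), depth)
    lid = library_id or f"lib_c{cells}_s{seed}"
    return LibraryPileup(library_id=lid, cells=cells, depths=counts)


def sample_reads(
    genome: GenomeModel, read_length: int, mean_depth: float, seed: int = 0
) -> list[str]:
    """Uniformly sampled error-free substrings at a target mean depth.

    A minimal read model for k-mer spectrum experiments (no qualities,
    no errors, forward strand only).
    """
    if read_length < 1 or read_length > genome.length:
        raise ValueError("read_length must lie in [1, genome length]")
    rng = np.random.default_rng(seed)
    n_reads = int(round(mean_depth * genome.length / read_length))
    starts = rng.integers(0, genome.length - read_length + 1, size=n_reads)
    return [genome.sequence[s : s + read_length] for s in starts]


# ---------------------------------------------------------------------------
# Presence/absence matrices


@dataclass(frozen=True)
class ECMatrixSpec:
    """Blueprint for a synthetic enzyme presence/absence matrix.

    deficiency_plan maps a core-enzyme name to the list of target species
    that lack it; everything not planned is present (core enzymes) or random
    below the core threshold (accessory enzymes).
    """

    n_free_living: int
    n_target: int
    n_core_enzymes: int
    n_noncore: int
    deficiency_plan: dict = field(default_factory=dict)
    seed: int = 0
    core_dropout: int = 0  # free-living species lacking each core enzyme
    core_frac: float = 0.75

    def free_living_names(self) -> list[str]:
        return [f"FL{i + 1:02d}" for i in range(self.n_free_living)]

    def target_names(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_target)]

    def core_names(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.n_core_enzymes)]

    def noncore_names(self) -> list[str]:
        return [f"N{i + 1:03d}" for i in range(self.n_noncore)]

    def __post_init__(self) -> None:
        for v in (self.n_free_living, self.n_target, self.n_core_enzymes, self.n_noncore):
            if v < 0:
                raise ValueError("all counts must be >= 0")
        targets = set(self.target_names())
        enzymes = set(self.core_names()) | set(self.noncore_names())
        for enz, absent in self.deficiency_plan.items():
            if enz not in enzymes:
                raise ValueError(f"deficiency_plan references undeclared enzyme {enz!r}")
            bad = set(absent) - targets
            if bad:
                raise ValueError(f"deficiency_plan references undeclared targets {sorted(bad)}")


def make_ec_matrix(spec: ECMatrixSpec) -> PresenceAbsenceMatrix:
    """Build a binary species × enzyme matrix that realises `spec` exactly."""
    rng = np.random.default_rng(spec.seed)
    fl = spec.free_living_names()
    tg = spec.target_names()
    species = fl + tg
    roles = pd.Series(
        ["free_living"] * len(fl) + ["target"] * len(tg), index=species, name="role"
    )
    import math

    core_thr = math.ceil(spec.core_frac * len(fl)) if fl else 0
    rows = {}
    for enz in spec.core_names():
        row = pd.Series(1, index=species, dtype=np.int64)
        if spec.core_dropout > 0 and fl:
            if len(fl) - spec.core_dropout < core_thr:
                raise ValueError("core_dropout would push a core enzyme below the core threshold")
            drop = rng.choice(fl, size=spec.core_dropout, replace=False)
            row[list(drop)] = 0
        for t in spec.deficiency_plan.get(enz, []):
            row[t] = 0
        rows[enz] = row
    for enz in spec.noncore_names():
        row = pd.Series(0, index=species, dtype=np.int64)
        if fl and core_thr > 0:
            n_present = int(rng.integers(0, core_thr))  # strictly below threshold
            if n_present:
                row[list(rng.choice(fl, size=n_present, replace=False))] = 1
        if tg:
            row[tg] = rng.integers(0, 2, size=len(tg))
        for t in spec.deficiency_plan.get(enz, []):
            row[t] = 0
        rows[enz] = row
    data = pd.DataFrame(rows).T.reindex(columns=species) if rows else pd.DataFrame(
        index=pd.Index([], dtype=object), columns=species, dtype=np.int64
    )
    return PresenceAbsenceMatrix(data=data.astype(np.int64), roles=roles)


_CORE_MET_TARGETS = ["Ra", "Bh", "Cp", "Dc", "Pc", "Ts", "Sp", "Mb"]
# enzyme -> target species carrying it (all 10 enzymes are core across the
# 24-species free-living panel)
_CORE_MET_PRESENCE = {
    "EC 2.7.7.4": ["Ra", "Mb"],  # ATP sulfurylase
    "EC 2.7.1.25": ["Ra", "Mb"],  # adenylyl-sulfate kinase
    "EC 1.8.4.8": ["Mb"],  # phosphoadenylyl-sulfate reductase
    "EC 1.8.1.2": ["Mb"],  # sulfite reductase (NADPH)
    "EC 2.8.1.6": ["Mb", "Bh"],  # biotin synthase
    "EC 6.3.4.15": ["Mb", "Ra", "Sp"],  # biotin--(acetyl-CoA-carboxylase) ligase
    "EC 2.5.1.3": ["Bh"],  # thiamine phosphate synthase
    "EC 2.7.1.50": ["Bh"],  # hydroxyethylthiazole kinase
    "EC 2.3.3.1": list(_CORE_MET_TARGETS),  # citrate synthase — in every genome
    "EC 2.3.3.8": ["Cp", "Bh"],  # ATP citrate synthase — chytrids only
}


def core_metabolism_fixture() -> PresenceAbsenceMatrix:
    """The packaged core-metabolism presence/absence matrix.

    Eight target genomes (Ra = R. allomycis, Bh = B. helicus,
    Cp = C. protostelioides, Dc = D. cristalligena, Pc = P. cylindrospora,
    Ts = T. sphaerospora, Sp = S. pseudoplumigaleata, Mb = M. bicuspidata)
    by ten sulfate/thiamine/biotin/citrate-pathway enzymes, plus a 24-species
    free-living panel in which all ten enzymes are universally present.
    """
    fl = [f"FL{i + 1:02d}" for i in range(24)]
    species = fl + _CORE_MET_TARGETS
    roles = pd.Series(
        ["free_living"] * 24 + ["target"] * 8, index=species, name="role"
    )
    data = pd.DataFrame(0, index=list(_CORE_MET_PRESENCE), columns=species, dtype=np.int64)
    data[fl] = 1
    for enz, present in _CORE_MET_PRESENCE.items():
        data.loc[enz, present] = 1
    return PresenceAbsenceMatrix(data=data, roles=roles)


# ---------------------------------------------------------------------------
# Orthology cluster tables


def single_copy_model(rng) -> int:
    return 1


def poisson_copy_model(lam: float):
    """Copy-count model: 1 + Poisson(lam) extra copies for present species."""

    def model(rng) -> int:
        return 1 + int(rng.poisson(lam))

    return model


def fixed_missing_model(m: int):
    """Exactly m species missing from every cluster."""

    def model(rng) -> int:
        return m

    return model


def uniform_missing_model(max_missing: int):
    def model(rng) -> int:
        return int(rng.integers(0, max_missing + 1))

    return model


def make_ortho_clusters(
    n_genomes: int,
    n_clusters: int,
    copy_model=None,
    missing_model=None,
    seed: int = 0,
) -> OrthoClusterSet:
    """Random orthology cluster tables with retained ground truth.

    copy_model(rng) -> per-present-species gene copy count (default 1);
    missing_model(rng) -> number of species absent from a cluster
    (default Uniform{0..min(3, n_genomes-1)}).  Truth columns `n_missing`
    and `max_copies` support oracle tests of the selection stage.
    """
    if n_genomes <= 0 or n_clusters <= 0:
        raise ValueError("n_genomes and n_clusters must be positive")
    rng = np.random.default_rng(seed)
    copy_model = copy_model or single_copy_model
    missing_model = missing_model or uniform_missing_model(min(3, n_genomes - 1))
    species = [f"G{i + 1:02d}" for i in range(n_genomes)]
    counts = np.zeros((n_clusters, n_genomes), dtype=np.int64)
    truth_missing = np.zeros(n_clusters, dtype=np.int64)
    truth_maxcopy = np.zeros(n_clusters, dtype=np.int64)
    for c in range(n_clusters):
        m = int(missing_model(rng))
        m = min(m, n_genomes)
        absent = rng.choice(n_genomes, size=m, replace=False) if m else np.array([], dtype=int)
        present = np.setdiff1d(np.arange(n_genomes), absent)
        for s in present:
            counts[c, s] = copy_model(rng)
        truth_missing[c] = m
        truth_maxcopy[c] = counts[c].max() if present.size else 0
    ids = [f"CL{c + 1:05d}" for c in range(n_clusters)]
    df = pd.DataFrame(counts, index=ids, columns=species)
    lengths = pd.Series(rng.integers(100, 1001, size=n_clusters), index=ids, name="length")
    truth = pd.DataFrame(
        {"n_missing": truth_missing, "max_copies": truth_maxcopy}, index=ids
    )
    return OrthoClusterSet(counts=df, lengths=lengths, truth=truth)
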