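"""Readers, writers, the scaffold-length filter, and run configuration.

File formats: FASTA for genomes and scaffolds (via Biopython); a minimal
VCF v4.2 dialect (CHROM/POS/ID/REF/ALT/QUAL/FILTER/INFO only, pooled-
frequency INFO fields DP/AO/AF, truth sets with AC/AN) with 1-based POS;
TSV for pileups, matrices, cluster tables and reports; BED for coverage
masks (0-based half-open covered runs); Newick for trees (via dendropy);
and a flat key=value text file for run configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .comparative import OrthoClusterSet, PresenceAbsenceMatrix
from .recovery import CoverageMask
from .synthetic import GenomeModel, LibraryPileup, PhasedVariantSet
from .variants import VariantCall, VariantCallSet

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: list[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_genome_fasta(genome: GenomeModel, path, name: str = "chr1") -> None:
    write_fasta([SeqRecord(Seq(genome.sequence), id=name, description="")], path)


def read_genome_fasta(path, seed: int = -1) -> GenomeModel:
    recs = read_fasta(path)
    if len(recs) != 1:
        raise ValueError("expected a single-sequence FASTA")
    return GenomeModel(sequence=str(recs[0].seq).upper(), seed=seed)


def filter_scaffolds(records: list[SeqRecord], min_len: int = 2000) -> list[SeqRecord]:
    """Drop scaffolds shorter than `min_len` (a 2,000-bp scaffold is kept).

    Short scaffolds from sparse single-cell assemblies are phylogenetically
    ambiguous; this reproduces the standard post-assembly length filter.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in records if len(r.seq) >= min_len]


# ---------------------------------------------------------------------------
# Pileup TSV


def write_pileup(pileup: LibraryPileup, path, contig: str = "chr1") -> None:
    df = pd.DataFrame(pileup.depths, columns=["depth_A", "depth_C", "depth_G", "depth_T"])
    df.insert(0, "pos0", np.arange(pileup.length))
    df.insert(0, "contig", contig)
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path, library_id: str = "lib", cells: int = 1) -> LibraryPileup:
    df = pd.read_csv(path, sep="\t")
    depths = df[["depth_A", "depth_C", "depth_G", "depth_T"]].to_numpy(np.int64)
    return LibraryPileup(library_id=library_id, cells=cells, depths=depths)


# ---------------------------------------------------------------------------
# Minimal VCF v4.2 subset

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n'
    '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observations">\n'
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">\n'
    '##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate copies in genotype">\n'
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total genome copies (ploidy)">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(callset: VariantCallSet, path, contig: str = "chr1") -> None:
    """Write calls as the minimal pooled-frequency VCF dialect (POS 1-based)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in callset:
            info = f"DP={c.depth};AO={c.alt_count};AF={c.af:.6g}"
            fh.write(f"{contig}\t{c.position + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_vcf(path, library_id: str = "lib", cells: int = 1) -> VariantCallSet:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            calls.append(
                VariantCall(
                    position=int(pos) - 1,
                    ref=ref,
                    alt=alt,
                    depth=int(fields["DP"]),
                    alt_count=int(fields["AO"]),
                )
            )
    return VariantCallSet(library_id=library_id, cells=cells, calls=calls)


def write_truth_vcf(variants: PhasedVariantSet, path, contig: str = "chr1") -> None:
    """Write a planted variant set with AC (alt copies) / AN (ploidy) INFO."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for pos, ref, alt, ac in zip(
            variants.positions, variants.ref, variants.alt, variants.alt_copies
        ):
            fh.write(
                f"{contig}\t{int(pos) + 1}\t.\t{ref}\t{alt}\t.\tPASS\tAC={int(ac)};AN={variants.ploidy}\n"
            )


def read_truth_vcf(path) -> PhasedVariantSet:
    positions, refs, alts, acs = [], [], [], []
    ploidy = 1
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            _c, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            positions.append(int(pos) - 1)
            refs.append(ref)
            alts.append(alt)
            acs.append(int(fields["AC"]))
            ploidy = int(fields["AN"])
    return PhasedVariantSet(
        ploidy=ploidy,
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        alt_copies=np.array(acs, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# BED masks


def write_mask_bed(mask: CoverageMask, path, contig: str = "chr1") -> None:
    """Covered runs as 0-based half-open BED intervals."""
    cov = mask.covered
    with open(path, "w") as fh:
        if cov.size:
            edges = np.flatnonzero(np.diff(cov.astype(np.int8)))
            starts = ([0] if cov[0] else []) + [int(e) + 1 for e in edges if not cov[e]]
            ends = [int(e) + 1 for e in edges if cov[e]] + ([int(cov.size)] if cov[-1] else [])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\n")


def read_mask_bed(path, length: int, library_id: str = "mask") -> CoverageMask:
    covered = np.zeros(length, dtype=bool)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _c, s, e = line.split("\t")[:3]
            covered[int(s) : int(e)] = True
    return CoverageMask(library_id=library_id, covered=covered)


# ---------------------------------------------------------------------------
# Matrices and cluster tables


def write_matrix_tsv(matrix: PresenceAbsenceMatrix, path) -> None:
    """Matrix TSV with a `#roles` comment line carrying species roles."""
    with open(path, "w") as fh:
        roles = ";".join(f"{sp}={matrix.roles[sp]}" for sp in matrix.data.columns)
        fh.write(f"#roles\t{roles}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="function")


def read_matrix_tsv(path) -> PresenceAbsenceMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#roles\t"):
            raise ValueError("missing #roles line")
        roles = pd.Series(
            dict(kv.split("=", 1) for kv in first.split("\t", 1)[1].strip().split(";"))
        )
        df = pd.read_csv(fh, sep="\t", index_col="function")
    return PresenceAbsenceMatrix(data=df.astype(np.int64), roles=roles)


def write_clusters_tsv(clusters: OrthoClusterSet, path) -> None:
    df = clusters.counts.copy()
    if clusters.lengths is not None:
        df["length"] = clusters.lengths
    df.to_csv(path, sep="\t", index_label="cluster_id")


def read_clusters_tsv(path) -> OrthoClusterSet:
    df = pd.read_csv(path, sep="\t", index_col="cluster_id")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length")
    return OrthoClusterSet(counts=df.astype(np.int64), lengths=lengths)


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_string, rooted: bool = True) -> dendropy.Tree:
    src = str(path_or_string)
    kwargs = {"schema": "newick"}
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, **kwargs)
    else:
        tree = dendropy.Tree.get(path=src, **kwargs)
    tree.is_rooted = rooted
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its conventional default.

    Serialises losslessly to a flat key=value text file.  Thresholds carry
    the analysis-stage defaults: pooled calling at min_coverage 5 / 1% / 2
    alt reads, the 25% heterozygous allele-frequency floor, the 90% gene
    coverage gate, the 2,000-bp scaffold floor, the 75% free-living core
    rule with >= 5 absent targets, orthogroup selection with up to 8 missing
    taxa and >= 3 present, and 70% marker-length recovery.
    """

    seed: int = 1
    # genome
    genome_length: int = 100_000
    gc: float = 0.5
    # ploidy / variants
    ploidy: int = 2
    het_rate: float = 0.005
    fixed_rate: float = 0.001
    # amplification
    covered_prob: float = 0.7
    mean_tract_bp: float = 2000.0
    gain_sigma: float = 0.5
    error_rate: float = 0.005
    mean_depth: float = 30.0
    # library design
    library_design: tuple = (1, 10)
    # variant calling
    min_coverage: int = 5
    min_alt_frac: float = 0.01
    min_alt_reads: int = 2
    # partition
    het_lower: float = 0.25
    het_upper: float = 0.95
    fixed_min: float = 0.99
    # AFS / classification
    bin_width: float = 0.02
    haploid_max_density: float = 50.0
    peak_tol: float = 0.05
    min_prominence_frac: float = 0.2
    smooth_window: int = 3
    # sharing
    non_haploid_per_mb: float = 250.0
    haploid_per_mb: float = 50.0
    coverage_min: float = 0.9
    # recovery
    mask_min_depth: int = 1
    recover_frac: float = 0.70
    # comparative
    core_frac: float = 0.75
    min_absent_targets: int = 5
    max_missing: int = 8
    min_taxa: int = 3
    min_r2: float = 0.3
    min_n: int = 3
    # scaffold filter
    min_scaffold_len: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.het_lower < self.het_upper <= self.fixed_min <= 1:
            raise ValueError("het/fixed thresholds out of order")
        if not 0 <= self.covered_prob <= 1:
            raise ValueError("covered_prob out of range")
        if self.ploidy not in (1, 2, 3):
            raise ValueError("ploidy must be 1, 2 or 3")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, val = (x.strip() for x in line.split("=", 1))
                raw[key] = val
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.type in ("int", int):
                kwargs[f.name] = int(val)
            elif f.type in ("float", float):
                kwargs[f.name] = float(val)
            elif f.type in ("tuple", tuple):
                kwargs[f.name] = tuple(int(x) for x in val.split(",") if x)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)
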