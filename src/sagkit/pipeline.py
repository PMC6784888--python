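"""End-to-end orchestration: simulate → call → classify → recover → screen.

`ploidy_replicate` is the canonical desk-scale experiment: one simulated
individual of known ploidy, a 1-cell and a 10-cell library, pooled-frequency
variant calling, allele-frequency-spectrum classification, and cross-library
sharing.  `run_demo` exercises every stage once and writes all reports.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative, io, recovery, synthetic, variants

logger = logging.getLogger("sagkit")


@dataclass
class ReplicateResult:
    """Everything measured on one simulated individual."""

    true_ploidy: int
    call: variants.PloidyCall
    het_sets: dict  # library_id -> het VariantCallSet
    callable_mb: dict  # library_id -> callable megabases
    sharing: variants.SharingReport | None
    afs: variants.AlleleFrequencySpectrum


def _amp_from_config(cfg: io.RunConfig) -> synthetic.AmplificationModel:
    return synthetic.AmplificationModel(
        covered_prob=cfg.covered_prob,
        mean_tract_bp=cfg.mean_tract_bp,
        gain_sigma=cfg.gain_sigma,
        error_rate=cfg.error_rate,
        mean_depth=cfg.mean_depth,
    )


def ploidy_replicate(
    seed: int,
    ploidy: int,
    length: int = 100_000,
    het_rate: float = 0.005,
    fixed_rate: float = 0.001,
    amp: synthetic.AmplificationModel | None = None,
    design: tuple = (1, 10),
    cfg: io.RunConfig | None = None,
) -> ReplicateResult:
    """Simulate one individual plus its libraries and classify its ploidy.

    Classification uses the most cell-rich library's heterozygous spectrum
    (deepest, hence sharpest allele-fraction modes); sharing across the
    libraries is reported alongside.
    """
    cfg = cfg or io.RunConfig()
    amp = amp or _amp_from_config(cfg)
    genome = synthetic.simulate_genome(length, gc=cfg.gc, seed=seed)
    pconf = synthetic.PloidyConfig(
        ploidy=ploidy,
        het_rate=het_rate if ploidy > 1 else 0.0,
        fixed_rate=fixed_rate,
    )
    planted = synthetic.plant_variants(genome, pconf, seed=seed + 1)

    het_sets, callable_mb, callsets = {}, {}, []
    best_lib, best_cells = None, -1
    for i, cells in enumerate(design):
        pileup = synthetic.simulate_library(
            genome, planted, cells=cells, amp=amp, seed=seed + 2 + i
        )
        calls = variants.call_variants(
            pileup,
            genome,
            min_coverage=cfg.min_coverage,
            min_alt_frac=cfg.min_alt_frac,
            min_alt_reads=cfg.min_alt_reads,
        )
        het, _fixed, _disc = variants.partition_calls(
            calls, cfg.het_lower, cfg.het_upper, cfg.fixed_min
        )
        het_sets[pileup.library_id] = het
        callable_mb[pileup.library_id] = float(
            (pileup.total_depth >= cfg.min_coverage).sum() / 1e6
        )
        callsets.append(het)
        if cells > best_cells:
            best_cells, best_lib = cells, pileup.library_id

    spectrum = variants.afs(het_sets[best_lib], bin_width=cfg.bin_width)
    mb = callable_mb[best_lib]
    density = len(het_sets[best_lib]) / mb if mb > 0 else 0.0
    call = variants.classify_ploidy(
        spectrum,
        het_density=density,
        thresholds=variants.PloidyThresholds(
            haploid_max_density=cfg.haploid_max_density,
            peak_tol=cfg.peak_tol,
            min_prominence_frac=cfg.min_prominence_frac,
            smooth_window=cfg.smooth_window,
        ),
    )
    sharing = None
    if len(callsets) >= 2:
        sharing = variants.shared_het_analysis(
            callsets,
            callable_mb=mb,
            non_haploid_per_mb=cfg.non_haploid_per_mb,
            haploid_per_mb=cfg.haploid_per_mb,
        )
        call.shared_het_count = sharing.multi_library_count
    return ReplicateResult(
        true_ploidy=ploidy,
        call=call,
        het_sets=het_sets,
        callable_mb=callable_mb,
        sharing=sharing,
        afs=spectrum,
    )


def _demo_tree_and_states():
    """A small rooted tree with binary characters for the ancestral stage."""
    newick = "((((T1,T2)n4,T3)n3,(F1,F2)n2)n1,F3)root;"
    tree = io.read_newick(newick, rooted=True)
    states = pd.DataFrame(
        {
            "enzA": {"T1": 0, "T2": 0, "T3": 0, "F1": 1, "F2": 1, "F3": 1},
            "enzB": {"T1": 1, "T2": 1, "T3": 1, "F1": 1, "F2": 1, "F3": 1},
        }
    )
    return tree, states


def run_demo(cfg: io.RunConfig, outdir) -> dict:
    """Run every pipeline stage once at desk scale and write all reports.

    Simulates one individual per ploidy (1, 2, 3), calls and classifies
    each, runs the recovery experiment, the packaged core-metabolism
    deficiency screen, orthogroup selection, ancestral reconstruction and a
    tree-congruence check.  Raises if any internal invariant fails, so a
    nonzero exit propagates to the command line.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"seed": cfg.seed}

    # ploidy stage
    labels = {}
    for ploidy in (1, 2, 3):
        rep = ploidy_replicate(
            seed=cfg.seed + 100 * ploidy,
            ploidy=ploidy,
            length=cfg.genome_length,
            het_rate=cfg.het_rate,
            fixed_rate=cfg.fixed_rate,
            design=tuple(cfg.library_design),
            cfg=cfg,
        )
        labels[ploidy] = rep.call.label
        pd.DataFrame(
            {"bin_center": rep.afs.bin_centers, "count": rep.afs.counts}
        ).to_csv(out / f"afs_ploidy{ploidy}.tsv", sep="\t", index=False)
        logger.info("ploidy %d classified as %s (%s)", ploidy, rep.call.label, rep.call.evidence)
    summary["ploidy_labels"] = labels

    # recovery stage
    genome = synthetic.simulate_genome(cfg.genome_length, gc=cfg.gc, seed=cfg.seed)
    planted = synthetic.plant_variants(
        genome, synthetic.PloidyConfig(1, 0.0, cfg.fixed_rate), seed=cfg.seed + 1
    )
    report = recovery.recovery_experiment(
        genome,
        planted,
        _amp_from_config(cfg),
        library_design=list(cfg.library_design),
        seed=cfg.seed,
        min_depth=cfg.mask_min_depth,
    )
    report.table.to_csv(out / "recovery.tsv", sep="\t", index=False)
    lib_rows = report.table[report.table["library_id"] != "union"]
    union_row = report.table[report.table["library_id"] == "union"].iloc[0]
    if not (union_row["completeness_pct"] >= lib_rows["completeness_pct"]).all():
        raise AssertionError("union completeness fell below an individual library")
    summary["union_completeness_pct"] = float(union_row["completeness_pct"])
    summary["max_library_completeness_pct"] = float(lib_rows["completeness_pct"].max())

    # comparative stage
    matrix = synthetic.core_metabolism_fixture()
    screen = comparative.deficiency_screen(
        matrix, core_frac=cfg.core_frac, min_absent_targets=cfg.min_absent_targets
    )
    screen.to_csv(out / "deficiency_screen.tsv", sep="\t")
    summary["deficient_enzymes"] = int(screen["deficient"].sum())

    clusters = synthetic.make_ortho_clusters(12, 200, seed=cfg.seed)
    selected = comparative.select_single_copy_clusters(
        clusters, max_missing=cfg.max_missing, min_taxa=cfg.min_taxa
    )
    missing, _ = comparative.supermatrix_stats(clusters, selected)
    missing.to_csv(out / "supermatrix_missing.tsv", sep="\t")
    summary["selected_clusters"] = len(selected)

    tree, states = _demo_tree_and_states()
    anc = comparative.fitch_ancestral(tree, states, ancestor="root")
    anc.branch_events.to_csv(out / "ancestral_events.tsv", sep="\t", index=False)
    summary["parsimony_changes"] = {k: int(v) for k, v in anc.change_counts.items()}

    ref = io.read_newick("((T1,T2),(T3,(F1,F2)),F3);", rooted=True)
    rf, congruent = comparative.rf_congruence(ref, ref, "T1")
    if rf != 0 or not congruent:
        raise AssertionError("self-congruence invariant failed")
    summary["self_rf"] = rf

    cfg.to_file(out / "config.txt")
    summary["elapsed_s"] = round(time.time() - t0, 2)
    logger.info("demo complete in %.1fs", summary["elapsed_s"])
    return summary


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
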