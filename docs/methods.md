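# Methods

`sagkit` models the computational stages of a fungal single-cell genomics
study: cells of an uncultured organism are sorted in pools (1, 10, 30, 50 or
100 cells), whole-genome amplified by multiple displacement amplification
(MDA), sequenced, and analysed for ploidy, genome recovery and comparative
signatures of unculturability.  Everything upstream of a pileup (sorting,
lysis, amplification chemistry, read trimming, assembly, decontamination) is
out of scope; the package starts from a simulated reference and per-site
base depths and ends with classification calls, recovery reports and
comparative screens.

## The amplification model

MDA coverage is famously uneven: long amplified tracts alternate with long
dropouts, and amplified regions differ in gain by orders of magnitude.  We
emulate this with, per cell and per genome copy:

1. **Tract dropout.**  A stationary two-state Markov chain along the genome
   marks each site covered or dropped.  `covered_prob` (default 0.7) is the
   stationary probability of the covered state — the per-copy coverage
   breadth; `mean_tract_bp` (default 2000) is the mean covered-tract length.
   The dropped-tract mean follows from stationarity:
   `mean_drop = mean_tract_bp * (1 - p) / p`.  Geometric run lengths make
   the run-based construction exactly the stationary chain, which gives two
   closed forms used as test oracles: the per-copy covered fraction is
   `covered_prob`, with a standard error inflated by the chain's
   autocorrelation factor `(1 + rho) / (1 - rho)`, `rho = 1 - a - b`; and
   setting `mean_tract_bp = 1/(1 - covered_prob)` collapses the chain to
   i.i.d. Bernoulli dropout, for which the union of k independent libraries
   recovers `1 - (1 - p)^k` of the genome.
2. **Per-tract gain.**  Each covered tract receives a lognormal gain with
   unit mean and log-scale spread `gain_sigma` (default 0.5).
3. **Read depth.**  Site depth is Poisson with mean
   `mean_depth * gain` (default per-copy depth 30).
4. **Sequencing error.**  Each read miscalls with probability `error_rate`
   (default 0.005), uniformly over the other three bases.

Depths are summed over cells and copies into a per-site A/C/G/T pileup.
The model is deliberately simple — no chimeras, no GC bias, no
contamination (removed upstream in real pipelines), no read-level artefacts
— so every downstream stage can be checked against clean closed-form
oracles.  Its parameters are free: nothing pins them to any particular
organism, and users wanting to mimic a real MDA run must fit
`covered_prob`, `mean_tract_bp` and `gain_sigma` to their own data.

## Ploidy inference

Variants are planted with ploidy-determined allele fractions: diploid
heterozygous sites carry the alternate on 1 of 2 copies (expected allele
fraction 1/2), triploid het sites on 1 or 2 of 3 copies (1/3 or 2/3, drawn
uniformly), fixed differences on all copies.  Ploidy is capped at 3, the
range relevant to the fungal lineages this pipeline targets.

Calling mirrors a pooled-frequency caller: a SNV is emitted where total
depth ≥ 5, some non-reference base has ≥ 2 reads and ≥ 1% of depth.  Calls
are partitioned into a heterozygous band (allele frequency strictly between
0.25 and 0.95), fixed differences (≥ 0.99), and discards.  The 25% floor is
strict — a call at exactly 25% is discarded.  The 0.95/0.99 upper bounds
are our own: a band is required because reference-discordant fixed
differences are analysed separately from within-individual heterozygosity;
both bounds are configurable.

Classification reads the heterozygous allele-frequency spectrum:

- **haploid** — het density below 50 per callable Mb and no interior mode;
- **diploid** — dominant interior mode within ±0.05 of 1/2;
- **triploid** — modes within ±0.05 of both 1/3 and 2/3;
- **unknown** — anything else, including conflicting diploid and triploid
  evidence (ties are never guessed).

Mode positions are estimated by Gaussian-kernel density (bandwidth 0.05)
built from the binned spectrum rather than by the argmax histogram bin:
allelic dropout and gain variability broaden the AF modes (sd ≈ 0.08–0.1
even in 10-cell libraries), and the argmax bin is too noisy to stay inside
the ±0.05 tolerance reliably.  The KDE mode is stable to ~0.01 at 500 het
sites.  The generic `detect_peaks` utility (used for k-mer spectra) keeps
the plain moving-average + prominence behaviour.

K-mer spectra (exact multiplicity histograms, optional canonical folding)
corroborate the calls — a heterozygous mode at half the homozygous-depth
mode supports diploidy — but allele-frequency evidence decides.

Cross-library sharing separates within-individual heterozygosity (present
in every cell, hence recurring across independent libraries) from
cell-to-cell polymorphism.  Sharing thresholds are normalised per callable
megabase — 250/Mb (non-haploid) and 50/Mb (haploid-like), equivalent to
genome-wide counts of 10,000 and 2,000 on a 40-Mb genome — because absolute
counts depend on genome size.

### What the simulation does and does not show

Two amplification phenomena erode the idealised allele-fraction signal and
are deliberately surfaced rather than hidden:

- **Allelic dropout.**  In a 1-cell library with per-copy breadth 0.7, both
  copies of a diploid are amplified at only ~49% of sites; het sites where
  one copy dropped look homozygous.  Cross-library het sharing in 1-cell
  libraries therefore falls far below the binomial-sampling expectation.
  The sharing acceptance check disables dropout to isolate the sampling
  oracle it states.
- **Gain imbalance.**  With `gain_sigma` 0.5, ~6% of het sites per library
  have an allelic gain ratio extreme enough to push the allele frequency
  below the 25% floor.  The sharing check also zeroes `gain_sigma`; under
  full MDA conditions sharing of ~0.88–0.95 is typical and still an order
  of magnitude above the cell-to-cell polymorphism baseline.
- **Band porosity at shallow depth.**  A fixed difference sampled at
  16-of-17 reads has an allele frequency of 0.94 and leaks into the
  heterozygous band; at 10-cell depth this vanishes.  The haploid false-het
  control is therefore an error-only experiment (no planted fixed
  differences), matching its stated oracle.

Passing these tests shows the estimators are correct under the stated
amplification model; it does not show that real MDA libraries meet the
model's assumptions.

## Genome recovery

A library's recoverable territory is its coverage mask (depth ≥ 1 by
default); co-assembly of pooled libraries is modelled as the positionwise
union of masks — no assembler is in the loop, so repeat collapse and
scaffold-length filtering are not represented.  Completeness is a marker
proxy: the percentage of core-gene-like intervals with ≥ 70% of their
length covered (inclusive), standing in for a core-eukaryotic-gene
estimator run on a real assembly; the 70% floor echoes such estimators'
partial-alignment notion of "complete" and is configurable.  Assembly size
is proxied by the covered base count, preserving the completeness-versus-
size correlation without an assembler.  Invariants: union completeness
dominates every member library, and expected completeness is non-decreasing
in cells per library.

## Comparative screens

- **Deficiency screen.**  An enzyme is core when present in
  ≥ ceil(0.75 × n) of the n free-living species (ceiling semantics: 18 of
  24); a core enzyme absent from ≥ 5 target genomes is flagged as a
  candidate cause of unculturability.  The packaged fixture encodes the
  sulfate-reduction, thiamine, biotin and citrate pathway enzymes of the
  eight target genomes; the screen flags 9 of its 10 enzymes (citrate
  synthase, present everywhere, is the negative control).
- **Ratio regression.**  Per-lifestyle OLS of CAZyme totals on protease
  totals; trend lines are excluded below 3 species or r² < 0.3 (the r²
  floor is our own; the analysis it mirrors states only that low-r² and
  low-n groups were omitted).
- **Orthogroup selection.**  A cluster enters the supermatrix when every
  present species has exactly one gene copy, at most 8 of the panel species
  are missing, and at least 3 are present.  Supermatrix missing-data
  fractions are alignment-length-weighted, with per-group medians.
- **Ancestral reconstruction.**  Binary presence/absence characters are
  reconstructed by exact small parsimony (Sankoff dynamic programming with
  unit costs — identical optima to Fitch on bifurcating trees, exact on
  polytomies).  Per-node most-parsimonious state sets are reported in full;
  a branch event is a definite gain or loss only when both endpoints are
  unambiguous, otherwise it is reported as ambiguous.  Lineage summaries
  count definite events on the path from a named ancestral node.
- **Tree congruence.**  Library trees are pruned to the leaves shared with
  the reference; the Robinson–Foulds distance (symmetric difference of
  nontrivial bipartitions, trees treated as unrooted) is reported together
  with a congruence flag: the focal taxon's sister group — the other leaves
  of the minimal clade containing it — must be identical in both pruned
  trees.  The sister-group rule is one defensible operationalisation of
  "congruent for that taxon"; RF is reported alongside for transparency.

## Numerical and design choices

- All internal coordinates are 0-based half-open; VCF output is 1-based.
- Every generator takes an explicit seed and is bit-reproducible.
- Variant calling reports the best-supported non-reference base, ties
  broken alphabetically; only single-nucleotide substitutions are modelled.
- Peak tolerance ±0.05 around 1/2, 1/3, 2/3 reflects binomial AF noise at
  depth ~30; tolerance comparisons carry a 1e-9 epsilon so a mode at
  exactly the tolerance boundary is accepted.
- Degenerate inputs raise: empty marker sets, zero-variance regression
  predictors, empty isolate call sets, unrooted trees for ancestral
  reconstruction, fewer than 4 shared leaves for congruence.
- Desk-scale test sizes: ploidy experiments use 100-kb genomes,
  heterozygosity 0.005/bp, per-copy depth 30, error 0.005, 1-cell +
  10-cell libraries, 20 replicates per ploidy; recovery monotonicity uses
  50-kb genomes, 10 seeds, and the [1, 1, 1, 10, 100] library design.

## Known limitations

- The coverage-mask proxy cannot reproduce assembler behaviour (repeat
  collapse, scaffold filters), so per-library "assembly size" is a
  coverage quantity, not contig arithmetic.
- The MDA model's parameters are not fitted to any empirical dropout
  distribution; real-data mimicry requires user calibration.
- Contamination, read-level artefacts and quality scores are not simulated.
- Ploidy above 3, aneuploidy and mixed-ploidy populations are out of scope.
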