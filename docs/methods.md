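# Methods

## Distance estimation

Input is a set of per-locus orthologous protein alignments; the pipeline
never aligns sequences itself (alignment quality is the caller's contract).
Loci are concatenated column-wise in a declared order into a supermatrix
with recorded half-open, 0-based partition ranges. Two policies handle loci
missing in some species: `drop_taxon` (default) keeps only species present
in every listed locus — the convention used when a subunit lacking
annotation in a genome would otherwise force that species out of the whole
analysis — and `gap_fill` pads absent loci with gap columns. Under pairwise
deletion the two give identical distances for species present everywhere,
which the test-suite asserts.

The p-distance between two rows is the proportion of differing residues
among *comparable* columns: both residues in the standard 20-letter
alphabet. Gaps (`-`) and unknowns (`X`) are excluded — an unknown residue
must not count as a mismatch. A pair with zero comparable columns is a
*missing* pair, propagated as an explicit NaN with a warning; it is never
reported as distance 0, and tree building refuses incomplete matrices.
The default model is the p-distance with pairwise deletion, consistent
with heatmaps drawn on a [0, 1] proportion scale capped at 0.6; because
distance software defaults are often ambiguous, the Poisson correction
`d = −ln(1−p)`, the gamma correction `d = a((1−p)^(−1/a) − 1)` and
complete deletion are all available as configuration so the choice can be
explored rather than guessed. Display clipping at 0.6 is used only for
heatmap rendering, never for statistics or trees.

## Divergence-time normalization

The divergence time `T` of a species pair is the age of their most recent
common ancestor in the input time tree — the one-way time, the quantity
divergence-time databases report — not the two-way path time; the constant
factor cancels in every clade comparison. The normalized distance is
`D_norm = D_raw / (T/100)` so that 100 MY = 1; `T = 100` is the fixed
point where raw and normalized coincide, and doubling all node ages halves
every `D_norm`.

Clade-pair distributions are summarised by mean, sample SD (n−1),
median and quartiles (violin annotation: solid median, dotted quartiles).
Groups are compared by classical one-way ANOVA; post hoc pairwise
comparisons use the studentized-range (Tukey HSD) distribution with the
Tukey–Kramer standard error `sqrt(MSW/2 (1/n_i + 1/n_j))`, exact for
balanced groups and the standard conservative extension for the unequal
pair counts interclade groups always have. Significance stars follow
* p<0.05, ** p<0.01, *** p<0.001. **Caveat:** pairwise distances sharing a
species are not independent, so these p-values are approximate descriptive
statistics, not exact tests; `jackknife_anova` drops one taxon at a time
and re-runs the ANOVA to show whether a conclusion hinges on any single
species. Which clade-pair groups enter the ANOVA is a config choice
(default: all between-clade groups present).

## Tree building

Trees are reconstructed by Saitou–Nei neighbor-joining rather than
maximum likelihood: the distance matrix is the pipeline's primary object,
NJ is consistent on additive matrices, and the downstream claim the tree
supports is qualitative (which clades cluster), for which NJ + bootstrap
is adequate. Q-criterion ties break on the smallest (i, j) index pair in
the current node ordering, making the topology deterministic given input
order. Negative NJ branch lengths are clamped to zero with the deficit
moved to the sister branch, preserving the joined pair's path length.

Bootstrap support resamples alignment columns with replacement (same total
length), recomputes the matrix and the NJ tree, and scores each internal
bipartition of the point-estimate tree by the percentage of replicates
containing it. Resampling is over the whole concatenated alignment by
default; locus-stratified resampling (within partitions) is a flag.
Replicate r draws from a stream derived from (seed, r), so any single
replicate can be regenerated. Replicates yielding an incomparable pair are
dropped and counted; more than 10% dropped aborts the run.

## The simulator

The synthetic-data generator is first-class, tested code: it is the ground
truth every downstream stage is validated against. Sequences evolve along
a time-calibrated tree under a 20-state CTMC. Branch expected distance is
`d = mu (t/100) r_branch s_locus g_site` with `mu` in substitutions per
site per 100 MY. The default model is equal-rates (the 20-state
Jukes-Cantor analogue), whose transition probability has the closed form
`P(same|d) = 1/20 + (19/20) exp(−(20/19) d)` and hence a closed-form
expected p-distance `p = (19/20)(1 − exp(−(20/19) d_path))` — chosen
precisely so acceptance checks compare simulation output against analytic
values rather than against the code under test. A general reversible model
(20×20 symmetric exchangeability matrix + equilibrium frequencies, scaled
to one expected substitution per site) is supported via the matrix
exponential; it has no closed-form oracle and is checked by Monte Carlo.
Site-rate heterogeneity uses the discrete-gamma approximation with
equal-probability categories and conditional-mean rates (default 4
categories); category rates average exactly 1. No indels are simulated:
the analysis consumes a fixed alignment, so the true alignment stays
exact and gaps enter only through per-locus taxon dropout.

### Study conditions

`make_paper_like_dataset` fixes the simulated analogue of the motivating
study: 15 taxa in five clades (4 primates, 4 rodents, 3 Laurasiatherians,
2 Afrotherians, 2 marsupials) on an ultrametric tree with the
eutherian–marsupial split at 160 MY and the marsupial crown at 82 MY;
10 loci named after the channel subunits, 2,330 total columns with
heterogeneous lengths and mild per-locus rate scalars; rodent stem and
crown branches at rate multiplier 2.0 and marsupial branches at 0.5;
baseline `mu = 0.12` substitutions/site/100 MY, putting raw interclade
p-distances in the 0.2–0.35 band a 0–0.6 heatmap scale implies for
fast-evolving reproductive proteins; and exactly one (locus, taxon)
dropout — the ninth subunit absent in one marsupial — mirroring a subunit
unannotated in a real genome. These defaults are the study conditions, not
tuning knobs.

What the generator does *not* emulate: indels and alignment error,
empirical amino-acid exchangeabilities and compositional bias, among-locus
tree discordance, and correlated rate variation. Passing tests therefore
demonstrate that the pipeline's statistics recover known lineage rates
from clean alignments of realistic size — not that any particular real
dataset is free of alignment or annotation artefacts.

## Motif scan

The IQ-motif scanner reports consensus-class matches only:
`IQ_full = [FILV]Qxxx[RK]Gxxx[RK]` (11 residues) and the relaxed
`IQ_like = [FILVM]Qxxx[RK]xxxx` (10 residues), scanned left to right,
strictest class first, non-overlapping. The relaxed class exists because
biologically confirmed calmodulin-binding sites frequently lack the strict
glycine/basic anchors. The numeric propensity scores produced by
web-based calmodulin-target predictors are intentionally not reproduced —
their algorithms are unpublished — so the scanner's output is the match
set with coordinates (0-based half-open), the [FILVM]-Q anchor position,
and a C-terminal flag (anchor within the final `window` residues,
default 21, the span a short terminal truncation construct removes).

## Numerical and design notes

- Symmetry of distance matrices is exact by construction (each unordered
  pair computed once); the zero diagonal likewise.
- Ultrametricity tolerance for time trees: relative 1e-6 of root age.
  Node ages may alternatively be supplied as internal node labels.
- Taxon names are matched across loci by exact string equality after
  trimming FASTA headers at the first whitespace; no fuzzy matching.
- All randomness (simulation, bootstrap) flows through one integer seed;
  per-locus and per-replicate streams are derived sub-streams, so outputs
  are bit-identical across runs and platforms.
- Problem sizes in the test-suite (50-replicate reversal check, 1,000-run
  ANOVA null calibration, B=500 bootstrap stability, 20,000-site
  calibration alignments) were chosen as the smallest sizes at which the
  Monte-Carlo tolerances quoted in the tests are comfortably resolvable.

## Known limitations

- No maximum-likelihood tree search or model selection; NJ is the only
  tree method. For publication-grade phylogenies use a dedicated ML tool
  on the same concatenated FASTA this pipeline writes.
- The ANOVA on pairwise distances inherits the non-independence caveat
  above; the jackknife is a sensitivity check, not a fix.
- Divergence times are taken as known constants; their uncertainty is not
  propagated into the normalized distances.
- The simulator's equal-rates default underestimates the rate
  heterogeneity of real proteins unless gamma site rates and per-locus
  scalars are enabled.
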