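# Methods

## The generative model of a sorting screen

`sortscreen.simulate` models a pooled knockout screen read out by iterative
fluorescence-activated sorting. The quantities with biological meaning are:

- **φ_g** — gate-survival probability: the chance that a cell whose copy of
  gene *g* is disrupted falls inside the sort gate. Wild-type (and
  neutral-knockout) cells fall in at the baseline rate **φ0**
  (`gate_fraction`, default 0.005 — a tight 0.5% gate). A *hit* gene has
  φ_g > φ0; the default planted effect φ_g = 0.3 corresponds to a knockout
  that strongly activates the reporter.
- **w_g** — relative growth fitness per round. *Essential* genes have
  w_g < 1 and are progressively diluted during the expansion phases; this is
  the mechanism by which growth-required genes cannot enrich in this screen
  design even when their knockout would drive the phenotype.
- **ε_i** — editing efficiency of guide *i*, drawn once per screen from
  Beta(8, 2) (mean 0.8) and shared across replicates: guide-intrinsic
  efficacy is the biologically shared component that makes two-replicate
  enrichment informative. A cell carrying guide *i* behaves as a knockout
  with probability ε_i and as wild type otherwise, so its gate survival is
  ε_i φ_g + (1 − ε_i) φ0.

One screen is simulated as:

1. **Seeding.** Library proportions are log-normally skewed
   (`library_skew_sd`, default 0.4 in natural log — the typical abundance
   spread of a pooled lentiviral prep) and `coverage × n_sgrnas` cells
   (default 300× coverage, matching the >300× the protocol targets) are
   drawn multinomially. MOI (default 0.4) is carried as metadata under the
   standard single-infection approximation at MOI ≤ 0.5; it does not enter
   the desk-scale arithmetic separately from coverage.
2. **Sorting rounds** (default 4). Each round is growth → sort → expansion.
   Growth multiplies abundances by w_g and renormalizes to the population
   size (relative fitness; the two-week expansion is collapsed into a single
   multiplier per round for identifiability at desk scale). The sort then
   processes `sorted_cells_per_round` cells (default 2×10⁵), drawn
   multinomially over current proportions, and each processed cell is
   *collected* with its gate-survival probability — a binomial thinning. The
   expected collected share of guide *i* is therefore proportional to
   n_i · [ε_i φ_g + (1 − ε_i) φ0], the closed form the tests check. The
   collected pool is expanded back to the population size.

   Modeling collection as per-cell gate acceptance (rather than fixing the
   number of collected cells) matters: a 0.5% gate over a bottlenecked
   throughput collects few cells per guide and the resulting near-critical
   branching drift is exactly what empties most of a library over four
   rounds. With the defaults, an all-neutral screen ends with ~94% of guides
   at zero sorted reads and ~2% of guides holding the majority of the pool —
   the qualitative structure such screens show — while planted hits, whose
   collection odds are ~60× the baseline, take the pool over
   deterministically.
3. **Sequencing.** `reads_per_sample` reads (default: one per seeded cell,
   i.e. coverage×library-size, keeping >300× read coverage) are drawn
   multinomially from the current pool. Each read is laid out like the real
   amplicon: a random 0–8-nt stagger, the 24-nt constant primer tail ending
   in `GAAACACCG`, the 20-nt spacer, then vector scaffold, truncated to
   71 nt, constant quality, optional iid per-base substitution errors. The
   exact multinomial tally is returned alongside the FASTQ and serves as the
   counting oracle.

Replicates share the ground truth (φ, w, ε) but draw everything stochastic
independently; replicate *r* is seeded with `seed + 1000·r`.

### What the simulator does not emulate

PCR duplicates and amplification bias, index hopping, paired-end reads,
multi-infection at high MOI, clone-lineage effects, gate drift between
sessions, and real guide-sequence-dependent efficacy. Passing tests
therefore demonstrate the pipeline's correctness and calibration under a
faithful abstraction of the sorting process, not performance on any
particular sequencing run.

## Exact-match counting

The protocol counts only reads that completely match a library spacer. The
primary path finds the constant anchor `GAAACACCG` within the window the
primer stagger allows and requires the following 20-mer to equal a spacer
exactly; reads whose anchor is destroyed fall back to scanning all 20-mers
and are assigned only when exactly one library spacer occurs (ambiguity is
never counted). Whether the original analysis was anchored or position-free
is not documented; both paths are provided and the anchored-first choice is
logged. There is no mismatch tolerance and, by default, no
reverse-complement search (the single-primer design reads spacers on one
strand); a flag enables it. Counting is streaming, with memory proportional
to the library.

## Candidate selection (subset filter)

Per replicate: `lfc = log2((sorted + 0.5)/(unsorted + 0.5))` on raw counts.
The pseudo-count 0.5 keeps the value finite at zero. Guides pass if, in
every replicate, the unsorted count is ≥ 30 **and** lfc is strictly > −5;
genes with ≥ 2 passing guides (non-targeting controls excluded) are
candidates. Choices worth stating:

- **Orientation** is sorted/unsorted, so enrichment is positive. After four
  rounds most of the library collapses to lfc ≈ log2(0.5/n) ≈ −9; the −5
  threshold then reads as "retained in the sorted pool", which is the only
  orientation under which the stated threshold selects enriched guides. It
  is configurable and recorded in output metadata.
- **No library-size normalization** at this stage (none is documented for
  it); normalization appears only in the rank-aggregation stage.
- The gene threshold default is 2 **inclusive** — the known-positive gene in
  the original screen survived with exactly two guides enriched in both
  replicates — and is configurable.
- The lfc boundary is strict (>), so a guide exactly at the threshold fails.

## Rank aggregation

Guides are scored by the mean over paired replicates of
log2((sorted + 0.5)/(unsorted + 0.5)) on total-count-normalized counts,
after removing guides with a raw unsorted count of zero in any replicate;
ranked descending (positive selection) with lexicographic id tie-breaks for
bitwise reproducibility. The gene statistic is α-RRA: with sorted
normalized ranks r(1) ≤ … ≤ r(k),
P_j = I_{r(j)}(j, k−j+1) — the Beta(j, k−j+1) lower tail, identical to the
binomial upper tail Σ_{m≥j} C(k,m) r^m (1−r)^{k−m} — and
ρ = min{P_j : r(j) ≤ α}, ρ = 1 if no rank is inside the top-α fraction
(α default 0.1).

This deliberately replaces the negative-binomial guide-level test of
model-based screen analyzers with the paired fold-change: after four rounds
of sorting the signal is presence/absence rather than a modest mean shift,
and the fold-change is the screen's own primary readout. Outputs carry a
metadata line noting the divergence.

**Permutation null.** For each distinct gene size k, ρ is recomputed
`n_perm` times (default 1000) on k normalized ranks sampled without
replacement from the pooled observed ranks, ignoring gene assignment; nulls
are cached per k and the pooled ranks are sorted first, so results are
independent of gene iteration order. p = (1 + #{null ρ ≤ observed})/(1 +
n_perm), with exact ties between observed and null broken uniformly at
random (seeded). The tie rule matters: ρ has a genuine atom at 1 (a gene
misses the top-α fraction entirely with probability (1−α)^k ≈ 0.53 at
k = 6), and resolving that tie block conservatively would stack half of all
null genes at p = 1; the randomized rank restores an exactly uniform null
PIT while reducing to the plain add-one formula whenever there is no tie.
Benjamini–Hochberg FDR is applied across genes.

## Flow gating

Events are two positive channels; the analysis lives entirely in
log10(GFP/RFP), where the internal-control RFP cancels. Unactivated cells
sit at 0 with ratio noise `noise_sd` (default 0.15 dex); activated cells are
shifted down by `flux_log_drop` (default 1.0 dex). The gate is the lower
`quantile` (default 1%) of a control sample's log-ratio — the original ROI
is defined only graphically, so a reproducible control-anchored definition
is used — and ties exactly at the threshold are not gated. The
background-corrected activated fraction is (observed − q)/(1 − q), exact
when the activated mode lies fully below the gate (flux_log_drop ≥ ~3×
noise_sd). FCS ingestion is optional (CSV is the native format; an FCS
reader activates only if `fcsparser` is installed).

## Numerical and degenerate-input choices

- ρ demands sorted input (a contract, not a silent sort) and ranks in
  (0, 1]; permutation p-values are bounded in [1/(n_perm+1), 1].
- All randomness flows from one integer seed through named generators;
  identical seeds give byte-identical FASTQ.
- Zero-read samples, empty libraries, empty gates, zero-total columns, and
  mismatched sgRNA sets raise explicit errors rather than propagating NaNs.
- Reads too short to hold stagger + anchor + spacer are a configuration
  error at simulation time and are counted unassigned at quantification
  time.

## Problem sizes

The test and acceptance runs use desk-scale screens — 1,000 genes × 6
guides (plus a 600-guide counting fixture at 50,000 reads and 50,000-event
flow samples) — chosen so the whole suite recomputes every calibration from
scratch in seconds while preserving the regime that matters: coverage ≈ 300
cells and reads per guide, a 0.5% gate, and a sort bottleneck small relative
to library diversity.

## Known limitations

The permutation null conditions on the pooled rank list, so extremely
concentrated screens (few distinct surviving guides) discretize the null;
the subset filter's null specificity comes from sorting drift washing out
the library, not from the filter itself — on data without that structure
(e.g. a single gentle sort) it will pass most guides by design; and the
gene-level candidate threshold treats all guides equally, with no weighting
by guide efficacy.
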