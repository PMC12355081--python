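# Methods

This note documents the models, procedures and design choices behind
`parpomics`, in the spirit of a statistical-methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study layout

The pipeline is organized around a fixed experimental design: two parent
breast-cancer cell lines (a BRCA1-mutant and a BRCA2-mutant background), three
Olaparib-resistant (OR) derivatives per parent, three treatments per line
(untreated, 1 mM H₂O₂, and 10 μM Olaparib pretreatment before H₂O₂), and four
biological replicates per condition. `SampleDesign` validates this layout
(unique line × treatment × replicate triples) and derives the two replicate
groupings the filters need: *conditions* (line × treatment, used for PTM
layers, where treatment drives the signal) and *lines* (treatments pooled,
used for the proteome, which is measured untreated).

## ADPr site quantification

ADP-ribosylation evidence arrives as PSM-level records with a localization
probability — the search engine's confidence that the modification sits on a
specific residue. Site tables are built in six steps: remove decoy
(reverse-database) and contaminant PSMs; remove PSMs carrying more than one
ADPr (their summed intensity cannot be attributed to a single site); key
features by (protein, 1-based position, residue); call a site *identified*
when its best localization probability anywhere exceeds 0.9; quantify per
sample as the sum of linear intensities of that site's PSMs with localization
above 0.75; drop non-identified sites. Both thresholds are read strictly
(`>`), so boundary values are excluded; they are configurable. Identification
is a per-feature global property while quantification gating is per-record —
a site identified confidently in one run may draw quantitative values from
slightly less confident PSMs in other runs, which is exactly the
two-threshold convention of the field. Summation (not maximum) across
qualifying PSMs follows the usual site-intensity convention; `aggregate="max"`
is available. No cross-sample normalization is applied to ADPr intensities by
default (label-free quantification of enriched ADPr peptides is typically run
without normalization because treatment changes the global signal itself).

The minimum-replicate filter keeps a feature when at least one group has at
least `min_reps` (default 3) quantified replicates. Output summaries include
the residue distribution of identified sites (fractions over observed
residues, summing to 1), summed signal per line × treatment, and UpSet-style
exclusive intersection counts of site sets across cell lines.

## Phosphosite processing

Phosphopeptide quantifications are collapsed to sites by summing linear
intensities of peptides passing the 0.75 localization-score cutoff per site
and sample. Peptide multiplicity classes (singly/doubly phosphorylated
species) are not modeled. Two cleaning steps follow on the log2 scale:

* **Censoring.** Values with log2 intensity strictly below 0 (linear
  intensity < 1) are quantification artifacts and become missing; 0 itself is
  retained.
* **Median-centering.** With sample medians m_j (present values only) and
  grand mean m̄ = mean_j(m_j), each sample receives the factor f_j = m̄ − m_j
  and values become x′_ij = x_ij + f_j. Every output sample median then equals
  m̄, within-sample differences are preserved exactly, and the operation is
  idempotent. The prose convention for this normalization is sign-ambiguous
  ("intensities subtracted from factors" would flip the matrix); the only
  reading that centers samples is the additive one implemented here, and the
  `NormalizationReport` records medians and factors so the choice is
  auditable.

## Proteome cleaning

Protein-group tables are filtered of reverse hits, contaminants and groups
only identified by modified peptides; LFQ intensity 0 (the "not quantified"
convention of label-free output) becomes missing; values are log2-transformed;
and proteins quantified in fewer than three replicates of every cell line are
removed. Grouping by cell line — not condition — is deliberate: proteome
samples are untreated, so a line's replicates across nominal treatment labels
are exchangeable.

## Differential statistics

The central statistic is the SAM-style moderated t:

d = (x̄_a − x̄_b) / (SE_pooled + s₀),  SE_pooled = s_p √(1/n_a + 1/n_b)

with the equal-variance pooled standard deviation s_p and a moderation
constant s₀ (default 0.1) that damps features whose sample variance is small
by chance (with s₀ = 0, d is exactly the pooled Student t). Features with
fewer than three present values in either group are untestable and reported
as such rather than raising.

Significance uses a randomization FDR with 250 permutations by default: group
labels are permuted jointly across all features per randomization (preserving
feature–feature correlation); for a threshold t,

FDR(t) = mean over permutations of #{|d*| ≥ t} / #{|d| ≥ t};

the per-feature q-value is the smallest FDR(t) over thresholds admitting the
feature, and the significant set is the largest set with estimated FDR at or
below the target (default 0.05). No π₀ correction is applied — the plain
ratio is the simplest defensible estimator and is conservative. When the
requested number of randomizations exceeds the number of distinct label
assignments (70 for balanced 4 vs 4), assignments are sampled with
replacement and a warning is emitted. All draws flow from a caller-supplied
seed.

A deliberate property of this estimator is worth documenting: strongly
differential features contribute their own permuted statistics to the null
pool (including occasional identity/mirror assignments), which inflates the
estimated FDR near the top of the ranking and makes the procedure
conservative. In a regime of modest per-feature power — e.g. a 4-sd shift at
4 vs 4 replicates, where the noncentral-t power at the FDR-implied threshold
is only ~0.7 — recovery is limited by power, not by the estimator; under the
defaults this pipeline validates against (1000 features, 5% differential at
2 log2 units with replicate noise sd 0.3, i.e. ~6.7 sd effects), power is
essentially 1 and the test suite verifies ≥ 90% recovery at realized
FDR ≤ 0.10 over ten seeds.

Missing values are imputed only when a volcano is explicitly run in imputed
mode (needed when a protein is entirely absent in one group, as with
BRCA1-reversion events). Imputation is the downshifted-normal convention:
per sample, missing entries are drawn from
Normal(mean_j − 1.8·sd_j, (0.3·sd_j)²), placing imputed values in the
low-intensity tail where missing-not-at-random dropout lives. Width 0.3 and
downshift 1.8 are the de facto standard defaults and are configurable.

Supporting tests: many-to-one Dunnett-adjusted comparisons (each OR line vs
its parent) via the equicorrelated multivariate-t distribution, evaluated by
scipy's seeded randomized quadrature — with one comparison the adjusted p
equals the pooled two-sided t-test p exactly, and the degenerate all-constant
case reports p = 1; Benjamini–Hochberg step-up adjustment (statsmodels);
two-sided Fisher-exact over-representation of a foreground set against a
background across named gene sets, BH-adjusted across sets.

## Integration

Quadrant classification joins each phosphosite's differential result with its
protein's: both significant and same fold-change sign → *same_direction*;
both significant, opposite signs → *opposite_directions*; otherwise
*phospho_only* / *protein_only* / *not_significant*. Significance is
inherited from each layer's own test; no joint test is recomputed. Sites
whose protein was not measured are flagged `protein_unmeasured`.

Peptide coverage maps use exact substring matching (no I/L equivalence,
because coverage figures plot identified peptides as reported), 1-based
inclusive intervals, all occurrences reported; domain overlap is closed-
interval intersection, so touching endpoints count. PCA operates on
feature-centered log2 values without scaling, complete-case by default, with
each component's sign fixed so its largest-magnitude loading is positive.
CC50 summaries report per-line replicate means and mean-based ratios to the
parent line, alongside per-replicate extreme ratios, since the aggregation
behind printed fold ranges is not standardized.

## Acquired variants

A variant (keyed by chromosome, position, ref, alt after uppercase allele
normalization; multi-allelic records are split by the reader) is *present* in
a replicate when a record exists with alternate-allele depth ≥ 2, and
*acquired* in a clone when present in ≥ 3 clone replicates and present in
zero parent replicates. "Absent in parent" is depth-gated by default — a
parent record with alt depth 1 still counts as absent; a strict mode
(no parent record at all) is provided because the prose convention does not
distinguish the two.

## Metabolite calibration

Calibration points are (nominal concentration x_i, analyte/internal-standard
area ratio y_i). The line is fitted by weighted least squares with
w_i = 1/x_i², the standard weighting for series spanning orders of magnitude
(it equalizes relative rather than absolute residuals); x is the nominal
concentration. Exponent 0 recovers OLS. Points whose back-calculated
concentration x̂_i = (y_i − b)/a errs by strictly more than 15% are excluded
and the curve refitted once (single-pass; an iterate-to-convergence flag
exists). Noise is the standard deviation of blank signals — the data model
carries no per-peak noise estimates, so a blank-based S/N estimator is the
natural choice — and the LoQ is the lowest retained calibration level with
signal/noise ≥ 10. Sample concentrations below LoQ are flagged, not dropped,
mirroring how below-LoQ analytes (NMN, NAMN, NA, NAAD) are reported rather
than discarded. Optional normalization divides concentrations by the
cell line's average protein amount. Zero blank variance leaves the LoQ
undefined: a warning, and nothing is flagged.

## Synthetic data

The generator produces every input with known ground truth. Intensities are
simulated on the log2 scale (log-normal linear intensities): per-feature
baselines ~ Normal(25, 2²), replicate noise sd 0.3 (≈ 20% CV, typical for
label-free MS), 5% of features differential between OR and parent lines with
signed effects of magnitude ~ Normal(2, 0.5²) log2 units, and ADPr treatment
effects of (0, +5, +1) log2 units for (untreated, H₂O₂, Olaparib+H₂O₂) —
strong oxidative induction that PARP inhibition suppresses. Detection is
missing-not-at-random: a feature is observed with probability
σ((x − 21)/1) in its true log2 intensity x, so low-abundance features drop
out first, which is the regime downshifted imputation targets. Localization
probabilities come from a two-component mixture — Beta(40, 1.5) for
well-localized features (85%) and Beta(8, 8) for ambiguous ones — so both
the 0.9 and 0.75 gates bite. Decoy/contaminant records (5%), multi-ADPr PSMs
(5%), phosphopeptide artifacts with sub-unit intensities (2%), parent-absent
"reversion-like" proteins (10), planted acquired/narrowly-failing/
parent-carrier variants, and noiseless-or-noisy calibration series with
blanks complete the picture. All draws derive from one seed through
deterministic per-layer sub-streams, so identical parameters give identical
tables.

What the generator does **not** emulate: peptide-level interference and
shared peptides, retention-time drift, batch effects, correlated feature
blocks (each feature's noise is independent), true biological pathway
structure, and read-level sequencing noise. Passing tests therefore
demonstrate correctness of the post-search computations under a clean
generative model, not robustness to every artifact of real acquisitions.

## Problem sizes and numerical choices

Simulation-backed checks use 1000 features at 4 vs 4 replicates with 250
randomizations, averaged over 10 seeds where a rate is asserted; brute-force
oracle comparisons use 200 random evidence tables (≤ 50 records) and 100
random variant-table sets; the Dunnett check compares against a 10⁶-draw
Monte-Carlo evaluation of the max-|T| probability within ±0.005. Ties in the
FDR threshold scan resolve toward the larger rejection set. Degenerate
inputs are contracts, not crashes: all-constant Dunnett groups give p = 1,
zero-variance features give d = Δmean/s₀, empty evidence gives an empty site
matrix, and samples with no present values raise named errors in
normalization and imputation. Matrix I/O writes floats with `%.6g`; the
evidence reader parses floats exactly (round-trip precision), so write→read
is value-identical and re-writing is byte-identical.

## Known limitations

* The randomization FDR is the plain-ratio estimator without π₀ or the
  asymmetric-curve variant; it is conservative when many features are
  strongly differential.
* Phosphosite multiplicity and razor-peptide protein inference are out of
  scope; site keys assume the upstream collapse resolved them.
* The VCF reader consumes only CHROM/POS/REF/ALT/AD and assumes one sample
  per call; annotation is passed through as free text.
* Dunnett probabilities use randomized quadrature with a reported seed rather
  than deterministic multivariate-t quadrature; repeated calls with the same
  seed agree exactly, different seeds agree to quadrature tolerance.
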