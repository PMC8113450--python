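# Methods

This note documents the statistical models, the tunable parameters and their
defaults, the numerical conventions, and the design choices made where the
methodology was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic study

The generator (`wobblelab.synthetic`) emulates a mouse study of Elongator
loss-of-function at embryonic day 14.5: a 3-vs-3 DIA proteome with six
spike-in peptides, a 6-vs-6 brain transcriptome with sex as a covariate,
streamline-count structural connectomes with six subjects per group, and
LC-MS tRNA-modification peak areas with five animals per genotype. Default
sizes are desk-scale — 500 proteins (~2,500 peptides), 2,000 genes, 40
connectome nodes — chosen so the full test suite runs in about a minute on
one core; `SimConfig.study_scale()` switches to 2,695 proteins / 12,600
peptides / 14,266 genes / 106 nodes. All randomness flows from one seed via
fixed per-stage derived streams; identical configs give byte-identical
output files.

**Coding sequences.** Each CDS is ATG + body + stop, with per-gene
amino-acid composition drawn from Dirichlet(2) over the 20 amino acids and
per-family synonymous-codon preferences from Dirichlet(0.6). The
concentration 0.6 deliberately produces strong between-gene codon bias, so
AA-/AG-ending codon fractions form a wide continuum — the covariate the
planted proteome effect needs. Stop codons are excluded from all truth
fractions, matching the RSCU definition over sense codons.

**Proteome.** A protein's true log2 fold-change (mutant vs control) is

    codon_effect_slope * (AA_fraction - mean) + length_effect_slope * (log2 length - mean)

with defaults −6.0 and −0.5. Centring the covariates makes the planted
effect two-sided: AA-rich / long proteins go down and AA-poor / short ones
go up, giving non-degenerate up *and* down sets (a one-sided baseline would
put every protein in one set). Biological noise (sd 0.2 log2 units) is drawn
per protein × sample and shared by that protein's peptides; technical noise
(sd 0.1) is per peptide × sample. Spike-ins carry technical noise only.
Intensities are simulated directly on the log2 scale.

**Transcriptome.** Counts are negative-binomial (dispersion 0.1) with
log-normal baselines (median ≈ 200 counts), per-sample library-size factors,
10% of genes given a ±1 log2FC group effect, and an optional sex effect.
The default sex layout is 5M:1F (mutant) vs 1M:5F (control) — imbalanced
but not confounded. This is deliberate: embryo cohorts are rarely
sex-matched, and an imbalanced layout is precisely the situation in which
modelling sex as a batch term matters. With an exactly balanced layout,
omitting a sex effect only inflates residual variance and the group test
becomes *conservative*; with the imbalanced default, omission biases the
group estimate and demonstrably inflates the false-positive rate, which the
acceptance suite verifies.

**Connectomes.** Edge weights are rounded log-normal streamline counts
(log-mean ~ N(3, 1) per edge, within-group log-sd 0.4) — nonnegative and
right-skewed like tract counts. In mutant subjects the 28 edges of an
8-node planted clique are shifted by +1.4 on the log scale, sized so the
expected edge-wise t (~6) comfortably clears the primary thresholds under
study while remaining a realistic "hyperconnectivity" effect.

**Modifications.** Mutant peak areas are the control level times a
per-modification reduction factor (default 0.4 for the U34-dependent ncm⁵U,
mcm⁵U, mcm⁵s²U; 1.0 for the independent m¹A, m⁷G, t⁶A) before multiplicative
log-normal noise (sd 0.15). Ψ areas are genotype-independent.

What the generator does **not** emulate: peptide missingness mechanisms
beyond optional MCAR, intensity-dependent mean–variance trends, shared
peptides between proteins, real codon-usage phylogenetic structure, spatial
autocorrelation of connectome edges, or chromatographic artefacts. Passing
tests demonstrate correctness of the statistical machinery under these
idealized conditions, not performance on real instrument data, and the
original study's headline counts (917/14,266 DE genes; 1,159 up / 828 down
proteins) depend on the deposited datasets and are not reproduced here.

## Proteome differential expression

- **Cyclic loess**: all sample pairs per cycle, 3 cycles, lowess span 0.7.
  The method is named in standard label-free workflows without parameters;
  these defaults pass both the constant-offset and the intensity-dependent
  trend-removal properties.
- **Technical variance**: σ²_tech is the pooled within-spike variance across
  all samples (group structure ignored — spikes carry no biology),
  denominator Σ(nᵢ−1). The correction is applied to residual variances
  *before* EB shrinkage: s²_corr = max(s² − σ²_tech, 10⁻⁸). Note the
  deliberate trade-off: the observed fold-change still carries technical
  sampling noise, so testing against the corrected variance discounts
  technical variability rather than modelling it; under the generator's
  model this is mildly anticonservative. The calibration checks therefore
  exercise the σ²_tech = 0 path, which isolates the moderated test itself.
- **Moderation**: per peptide, an OLS fit of the group indicator (plus any
  covariates), pooled by missingness pattern; hyperparameters (s₀², d₀) by
  the method of moments on log corrected variances (the classic
  inverse-chi-square/F fit, with the trigamma inverse solved by Newton
  iteration); moderated t = b/√(s²_post·v_b) on d₀ + d df. d₀ may be forced
  to 0 (classical t, verified to 1e−9) or ∞ (complete pooling; normal
  reference). Peptides with fewer than 2 finite observations per group are
  flagged untested; missing values are handled pairwise-complete.
- **Roll-up**: Simes p = min_k(n·p₍ₖ₎/k); trimmed-mean log2FC discards
  ⌊0.2·n⌋ peptides per tail (n ≤ 4 ⇒ plain mean — flooring is the only
  reading of "top and lower 20%" that never discards everything); BH q
  across proteins; calls use *strict* q < 0.1 and a strict fold-change sign
  (FC = 0 is logged and left "ns").

## Codon-usage bias

RSCU uses the standard genetic code with stop codons excluded; single-codon
families (ATG, TGG) score 1 when observed; unobserved families are omitted
rather than zero-filled (a 0 would be a strong bias claim, absence is no
data). The implementation is cross-checked in the tests against
`seqinr::uco`, the reference RSCU implementation. ΔRSCU is median(up) −
median(down) per codon — positive means higher usage among up-regulated
proteins, so the U34 signature (down set enriched in AA-ending codons)
appears as ΔRSCU < 0 for AAA/CAA/GAA. Mann–Whitney tests are exact for ≤ 8
per side (including a full enumeration path under ties) and tie-corrected
normal otherwise; codons observed in fewer than 3 genes per side are
skipped. The length-bias operation reports both a short-vs-long rank-sum
test (set dichotomized at the reference median, equals-median members
uninformative) and a sign test of the set against the reference median; a
one-sided split is degenerate and returns p = 1 with a flag.

## Transcript filtering, normalization and ranking

The CPM filter keeps genes with CPM ≥ 0.5 in ≥ 6 samples. The removal
phrasing ("less than this value in at least six samples") differs on
boundary genes when the two thresholds do not sum to the sample count; the
literal variant is available via `literal=True` and both are reproducible.
Filtering precedes normalization and uses raw library sizes. TMM follows
the reference algorithm exactly (upper-quartile reference selection, 30%/5%
two-sided trims on M/A, precision weights, geometric-mean-1 rescaling) and
is verified against `edgeR::calcNormFactors` to 1e−6. Note the factor
*direction*: a library monopolized by a few boosted genes receives a factor
below 1, the edgeR convention.

The DE engine models log2-CPM (prior count 0.5, TMM-effective library
sizes) linearly with group + sex and reuses the peptide moderation
machinery, rather than fitting a full negative-binomial GLM: the inferential
target here is the (p, sign) pair feeding the p/RTS metric, and the
moderated linear model is verified to hold its nominal type-I error on
NB-generated counts at realistic depths. Confounded designs (sex ≡ group)
are rejected with an explicit aliasing error. The ranking metric is raw
DE p divided by RTS, ascending, ties broken by gene id; genes without an
RTS entry are excluded and counted; RTS ≤ 0 is an input error; the
RTS ≥ 0.03 prioritization threshold of the original TRIAGE workflow is
carried as a flag column.

## Network-based statistic

Edge statistics are pooled-variance two-sample t (the NBS toolbox default;
Welch is not used), one-sided, run separately per direction — the increase
and decrease analyses are exact negatives of each other. Zero-variance
edges score 0 when the group means agree and ±∞ otherwise. Components are
connected components of the strictly-supra-threshold graph, scored by
extent (edge count). The permutation null is the maximum component extent
over group relabelings: full enumeration when the design admits at most
`n_perm` distinct relabelings (a 6-vs-6 design has C(12,6) − 1 = 923, so the
default 1,000-permutation request enumerates exactly), otherwise seeded
uniform sampling without replacement. FWER p = (1 + #{null ≥ extent}) /
(n_used + 1), bounded below by 1/(n_used+1). The threshold scan shares one
permutation schedule across thresholds (2.5–3.5, step 0.1 by default; the
step is a package choice, the endpoints follow the standard range) and
reports the threshold with the lowest corrected p, ties toward the lower
threshold. Near-symmetric matrices (round-trip artefacts ≤ 1e−6) are
symmetrized by averaging on ingest; both raw-count and seed-normalized
matrices are accepted since the statistic is invariant to per-dataset
scaling.

## tRNA-modification normalization

Levels are per-sample area ratios to Ψ (scale-invariant by construction);
relative levels divide by the control-genotype mean, making the control row
exactly 1. Genotype comparison uses one-way ANOVA plus Dunnett-style
many-to-one t statistics (pooled within-group variance) whose family-wise
adjustment is the permutation tail probability of the maximum |t| across
comparisons — assumption-light, seeded, and calibrated in the acceptance
suite — rather than multivariate-t quantiles. Normalization is per sample
before any averaging, the standard internal-standard practice.

## Numerical conventions and degenerate inputs

- Variance floor 10⁻⁸ (log2² units) after technical subtraction.
- Simes over an empty p-set, an empty up/down RSCU set, an empty genotype
  table and an all-excluded peptide matrix are explicit errors, not NaNs.
- n_genes = 0 is valid and produces empty outputs.
- Strict inequalities at every significance boundary (q < 0.1, statistic >
  t_primary, adjusted p < α).
- All TSV output uses a fixed float format; JSON is key-sorted — both so
  reruns are byte-identical.

## Problem sizes used in the checks

The acceptance suite runs at the generator's default desk scale: 5,000
features for the calibration nulls, 500 replicates for variance-recovery
Monte Carlo, 100 seeds for planted-effect recovery, 200 null datasets ×
923 enumerated relabelings for NBS FWER, and 500 null tables × 500
permutations for the Dunnett calibration. These sizes give binomial
standard errors comfortably inside the asserted bands while keeping the
whole suite around a minute of CPU.
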