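# Methods

This note records the models implemented in `pedimpute`, the parameter
choices that matter, what the simulator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## Study design being emulated

The package targets the design of extended-family imputation studies:
every participant is array-genotyped on a sparse scaffold (~hundreds of
markers over a few Mb), a subset is sequenced on a dense panel
(~thousands of variants containing the scaffold as a subset), and the
goal is to impute the dense genotypes of unsequenced or masked
individuals.  Default panel-membership fractions are 43.7% with both
data types, 51.6% array-only and 4.7% sequence-only; the default region
spans 2.5 Mb at 1 cM/Mb.  Pedigree sizes are drawn from an empirical
family-size distribution over sizes 3–15 (mode at 5, counts
6, 8, 24, 17, 15, 5, 8, 1, 3, 7, 2, 2, 2), and pedigrees are grown by
repeatedly adding children to existing couples or marrying in founder
spouses, which yields two- and three-generation families at realistic
rates.  Evaluation masks the dense data of sequenced individuals one at
a time (default 20 replicates) and pools replicates per variant.

## Simulator

**Founder haplotypes.** Founders and the external reference are mosaics
of K ancestral haplotypes: each haplotype follows a Markov ancestor
path with per-site switch probability `ancestry_switch_prob`, and each
variant's carriers are drawn as Binomial(H, f) and packed into the
site's preferred ancestral clades (the haplotypes copying a given
ancestor at that site).  Common variants fill whole clades and are
therefore strongly tagged by local ancestry; rare variants occupy a
small fraction of one clade and are only partially tagged, so
population imputability degrades continuously with frequency — the
qualitative behaviour reported for real panels, where IQS falls as MAF
falls even though concordance rises.  Target frequencies come from a
three-bin mixture (weights 0.61 / 0.22 / 0.17 over (0, 0.01],
(0.01, 0.05], (0.05, 0.4], log-uniform within bins), matching the
variant-count proportions such studies report.

Defaults K = 40 and switch 2×10⁻³ per site were calibrated once so that
the population engine's common-variant IQS on the default study lands
in the 0.8–0.9 range reported for production imputation on comparable
data, and were then frozen.  The external ("cosmopolitan") reference
uses the same ancestor pool with Balding–Nichols drifted frequencies
(Fst 0.05 by default), so it shares haplotype structure but not exact
frequencies; its rare-variant carriers are re-drawn independently,
making rare variation effectively population-private, as observed in
real panels.

**Gene dropping.** Each meiosis draws a Poisson number of crossovers
with mean equal to the map length in Morgans, places them uniformly on
the cM scale, and maps them to bp by inverse interpolation.  Child
haplotype 0 is paternal by convention; true phase and grandparental
origin are retained as ground truth.  Missingness is injected
missing-completely-at-random as the union of a variant-wise and an
individual-wise Bernoulli layer (defaults 2% each; no mechanism beyond
MCAR is modelled).

**What the simulator does not emulate:** coalescent genealogy (the
mosaic is a stand-in with tunable LD, not a population-genetic model),
genotyping error, batch or informative missingness, phasing error (true
phase stands in for pre-phased data), X-linked inheritance, and
inbreeding loops (rejected with an error).  Passing tests therefore
demonstrate correctness of the inference machinery under idealised
phasing and error-free genotypes, not performance on noisy real data.

## Quality control

Variants, then individuals, are removed when their missing fraction is
*strictly greater* than the threshold (defaults: 5% for scaffold
variants and individuals, 10% for sequence variants), the order chosen
to match how such studies report counts.  The two-pass order is
iterated to a fixed point so that filtering is idempotent.  LD pruning
is greedy within sliding windows (50 variants, step 5, the conventional
settings): the worst pair at or above r² = 0.2 loses its lower-MAF
member (ties: the later position) until the window is clean.  r² is the
squared Pearson correlation of genotype dosages over individuals
complete at both sites (composite LD, the `--indep-pairwise`
convention); monomorphic or under-observed pairs are flagged undefined.
Marker clusters are maximal intervals spanning every pair with
r² above threshold plus all intervening markers.

## Population engine

A haploid Li–Stephens copying model per target haplotype: hidden state
= the reference haplotype being copied (H states), switch probability
between adjacent sites `1 − exp(−ρ·ΔcM/H)` with the destination uniform
over all H haplotypes, symmetric allele miscopy ε.  Defaults ε = 0.001
and ρ = 10 (≈1 expected switch per 10 cM per 100 reference haplotypes).
Scaled forward–backward (per-site normalisation, no silent underflow)
yields per-site P(alt) per haplotype; the two haplotypes are imputed
independently and combined multiplicatively into genotype 3-vectors.
Target haplotypes come from the simulator's true phase (an external
pre-phased panel can be supplied instead); an unphased fallback mode
uses homozygous scaffold sites only.  With no observations the
posterior reduces to the error-smoothed panel frequency
f(1−ε) + (1−f)ε, which the tests verify in closed form; with ≤5
haplotypes and ≤6 sites the posteriors equal exhaustive hidden-path
summation to 1e−8.

## Family engine

A transmission-segment approximation to pedigree multipoint imputation,
chosen deliberately over the Lander–Green inheritance-vector
likelihood: per-meiosis two-state chains keep inference exact and fast
at any family size while capturing the mechanism — copying dense
genotypes through inferred identity-by-descent segments — at the cost
of ignoring joint constraints between meioses.

The working subset around a masked individual is their nuclear family
(parents, full siblings, spouses, children) plus grandparents and
grandchildren.  Scaffold variants with any impossible duo/trio
transmission in the subset are excluded before inference (missing
genotypes never trigger the flag).  For each meiosis, a two-state HMM
over the scaffold markers (Haldane switch probabilities from map
distance; emissions only where the parent is heterozygous with both
parent and child observed, using the other parent's genotype or the
subset allele frequency for the co-transmitted allele) yields posterior
weights for which parental haplotype each interval was inherited from;
uninformative meioses get flat 0.5 weights, and the segments tile the
region with breakpoints at marker midpoints.

Dense imputation combines, at every variant, the masked individual's
two transmitted-allele distributions.  Evidence is assembled exactly
over the nuclear core — a joint distribution over both parents'
ordered haplotype pairs, multiplied by every sibling's genotype
likelihood under their own segment weights — and approximately beyond
it: ancestors contribute through per-haplotype allele priors
(recursively propagated down meioses), and descendants through
per-branch independent likelihoods, with evidence below an observed
genotype screened off.  Sites with no informative relatives fall back
to Hardy–Weinberg at the subset allele frequency and are flagged
low-confidence.  Two parental-phase modes exist at dense sites:
`agnostic` (default; heterozygous parents contribute a 50/50 split,
resolvable by children's evidence) and `benchmark` (simulator truth
phase).  On nuclear families the posteriors equal exhaustive
enumeration over all parental haplotype configurations and
transmissions to 1e−8, which the tests assert.

## Two-stage combination

Stage-1 posteriors are thresholded to best-guess genotypes (argmax iff
strictly above 0.9; ties never qualify), filtered by MAF strictly above
the cutoff (0.01, 0.05, or none — "none" is first-class, since
filtering by frequency is the part of the design most worth relaxing),
and merged into the scaffold.  Open points resolved here, each exposed
as configuration: the MAF used for the cutoff is computed from the
local sequenced panel plus the accepted best-guess calls (the only
dense frequency source available at run time; reference-panel MAF is a
switch); the probability threshold is applied before the MAF filter;
at overlapping variants the observed scaffold call beats the imputed
one (observed calls carry no imputation uncertainty); and accepted
variants that would introduce a Mendelian inconsistency in the family
subset are dropped.

Merged variants act as *direct evidence* — the family stage treats them
as observed sites of the masked individual and never contradicts them —
but not as linkage markers: transmission segments are always inferred
from the GWAS scaffold alone.  This follows the empirical finding that
scaffold density barely changes family-based imputation, and it makes
the below-cutoff behaviour exact by construction: variants the filter
excludes have posteriors identical to a family-only run, turning the
reported "almost identical" observation into an invariant the tests
assert bitwise.

## Evaluation

IQS is Cohen's Kappa on the probability-weighted 3×3 table (cells are
sums of posterior 3-vectors grouped by true genotype); it equals
classical Kappa exactly when all posteriors are degenerate, can be
negative, and is undefined when either the true or the imputed
best-guess genotypes are monomorphic by allele frequency or when chance
agreement is total.  Dosage correlation is the Pearson correlation of
true dosage against posterior-expected dosage, undefined under the same
polymorphism rule or zero variance.  Masked replicates are pooled per
variant before scoring (a per-replicate correlation over one individual
would be undefined); per-bin summaries report the count of variants
with a defined score, the mean and the sample variance, over half-open
bins (low, high] — so MAF exactly 0.05 falls in (0.01, 0.05].  True MAF
for binning comes from the full simulated truth panel, not the masked
subset.  Only non-scaffold dense variants are scored (the imputation
targets).

## Numerical and reproducibility choices

All randomness flows from one master seed through per-stage
`SeedSequence` streams keyed by stage name, so adding a stage never
perturbs another stage's draws and every output is bit-reproducible.
Forward–backward passes normalise per site; degenerate joint
distributions (probability zero everywhere, possible only with
contradictory external data) fall back to the Hardy–Weinberg prior
rather than dividing by zero.  GEN files carry 4 decimal places and are
renormalised on read with a warning when a triplet's sum is off by more
than 0.01.  PED files carry no allele orientation, so lossless
round-trips require the variant template.  Default problem sizes (20
families, 2000 sequence variants, 200 scaffold variants, 20 masked
replicates) keep a full experiment under a minute on one CPU while
populating every MAF bin.

## Known limitations

The population engine is a transparent functional stand-in, not an
emulation of any production tool — no MCMC, no chunking, no internal
info score, no parameter mapping to such tools is claimed.  The family
engine's cross-meiosis independence understates information in dense
sibships; descendant evidence uses per-branch independence (loopy
around unsequenced spouses); half-siblings share no "nuclear" link.
How unsequenced intermediate relatives are weighted is a stated
approximation (ancestor priors plus descendant likelihoods), since no
canonical rule exists.  Monomorphic-imputation exclusion makes rare-bin
summaries a selected subset — the `#SNP_p` counts must be read together
with the means, as in the evaluation convention itself.
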