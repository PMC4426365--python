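# Methods

This note records the models behind `subdrift`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data do and
do not establish about real data.

## Drift model

Substrain divergence is modeled as a Poisson process of *fixed* homozygous
mutations. A dated genealogy (`SeparationSchedule`) gives each branch a
length in generations (calendar-year interval × `generations_per_year`,
default 4/yr); a branch with `g` generations accrues
`Poisson(lambda_fix · g)` mutations, each carried homozygously by exactly
the tips below the branch. There is no segregating heterozygous phase:
the analyses consume only homozygous fixed differences, so the transient
period between mutation and fixation is collapsed into the instantaneous
fixation event. Consequences of this simplification:

* pairwise distances are sums of independent Poisson counts along the
  tip-to-tip path, with expectation `lambda_fix × path generations`;
* recent mutations still segregating in a real colony are invisible, so
  the model underestimates very recent divergence — exactly the bias the
  homozygous-only filtering of real call sets has.

Defaults: `lambda_fix = 0.3` fixed mutations/lineage/generation over the
surveyed target, which at the default genealogy yields pairwise counts of
the same order as the published five-substrain exome table (tens of fixed
differences over 2–3 decades). Class fractions default to the observed
composition of that screen (`indel_fraction = 0.24`, i.e. 55/227;
`coding_fraction = 0.29`, i.e. 66/227 ≈ 0.29). Variant positions are drawn
uniformly without replacement from a 19-autosome + X chromosome-length
model (mm10-like sizes); recurrent mutation is disallowed, which is
realistic at these mutation counts.

The default genealogy encodes the colony history recoverable from the
substrains' documented provenance: a source colony in 1980; the Lt and
BomTac lineages separated in 1984; ShiJcl and MrkTac in 1986; ShiLtDvs
split from ShiLt in 1992; all sampled in 2014. Exact per-pair separation
dates are not published, so the schedule is a constructor argument
everywhere it is consumed.

## Distances, SDPs, rates

Distances are plain Hamming counts over class-filtered variants (SNP,
indel, coding, all); "coding" is membership of the consequence label in a
configurable set (missense, synonymous, stop gained/lost, frameshift,
inframe indel). Matrices are validated for symmetry, zero diagonal and
nonnegativity; min/max summaries break ties by lexicographic pair order.

The fixation-rate estimate divides each pair's coding count by
`2 × years since separation` — both lineages accumulate mutations — with a
`single_lineage` switch for the 1× convention, since a pairwise
count-per-year figure can be quoted either way and the published endpoints
alone cannot disambiguate the convention. Per-generation endpoints divide
by `generations_per_year`. Full precision is kept internally; reporting
rounds to 2 decimals, half away from zero.

## Phylogeny

Alignments are concatenated SNP columns (one column per variant, each
substrain contributing its homozygous base). Such alignments contain no
constant sites; the clock test is computed on them as-is, which is how a
fixed-difference panel is analyzed in practice. An ascertainment
correction is deliberately not applied (the test compares two models on
the same ascertained data, so the first-order effect cancels).

*Neighbor joining* is implemented directly because the package pins down
two behaviors left open by generic implementations: Q-criterion ties break
by lexicographic pair order, and a negative branch-length estimate is
clamped to zero with the deficit shifted to its sister edge so the joined
pair's distance is preserved. scikit-bio's `nj` serves as an independent
cross-check in the tests.

*Maximum likelihood* is exhaustive: all (2n−5)!! unrooted topologies
(15 for n = 5) with the 2n−3 branch lengths optimized per topology, or all
(2n−3)!! rooted topologies for the clock model with n−1 nested node
heights (root height plus one fraction in [0, 1] per internal node, so
ultrametricity holds by construction). Enumeration is refused above 8
taxa. The GTR model uses empirical base frequencies (pseudocount 1) and
six exchangeabilities with GT fixed at 1; transition matrices come from
the symmetric eigendecomposition of the detailed-balance rate matrix,
scaled to one expected substitution per unit branch length. Likelihoods
use Felsenstein pruning over compressed site patterns.

Optimization is L-BFGS-B with numerical gradients, branch lengths bounded
to [1e−9, 10], log-exchangeabilities to [−7, 7], ftol 1e−8, ≤500
iterations — deterministic given the input. Topologies are first ranked
with exchangeabilities at their initial values; the two best are then
refitted with exchangeabilities free. This two-stage scheme is an
efficiency choice; at these taxon counts the ranking stage essentially
always identifies the ML topology, and the runner-up refit guards the rare
near-tie.

*Clock LRT.* The unconstrained fit is the full enumeration above. The
clock fit searches the 2n−3 rootings of the free ML topology (an empirical
check against full rooted enumeration found no likelihood difference, at a
15× cost saving), first with the free fit's substitution model, then
refitting exchangeabilities on the best rooting so both hypotheses
maximize over the same model parameters. The statistic 2·ΔlnL is referred
to χ² with df = n − 2 = (2n−3) − (n−1), without a boundary-mixture
correction — the plain form of the test. Under clock-true simulation
(5 taxa × 2000 sites) the empirical size at α = 0.05 is ≈ 0.04–0.07 and
the p-values pass a KS uniformity check, so the plain χ² reference is
adequate at these sizes.

## Pooled-capture artifact estimation

The generative model: a read from substrain *s* at a SNP locus carries,
with probability *j*, the true allele of a uniformly chosen other library
in *s*'s capture pool (template switching during co-amplification);
otherwise, with probability *e*, a uniformly chosen base other than *s*'s
allele; otherwise *s*'s own allele. Jump targets are uniform over
pool-mates (equal pooling assumed); errors are uniform over the three
alternatives, with no quality-score model. Counts are exact multinomials,
so per-cell totals equal the configured depth.

The estimator mirrors the published analysis: loci are kept when every
substrain has ≥ `min_depth` (default 100) reads; per (locus, focal
substrain) cell, reads are bucketed focal / jump / error, where the jump
bucket is any base that is another same-pool substrain's major allele and
differs from the focal allele. A base that could be either a jump or an
error is assigned to the jump bucket; `jump_corrected = jump − error/3` is
reported as the deconvolved alternative. Cells where no pool-mate differs
have no jump bucket and are excluded from jump summaries (their error
frequency still counts). Under this convention the expected bucket masses
are `E[jump] = j + (1−j)e/3` (the in-pool allele also collects one third
of the errors) and `E[error] = (1−j)·2e/3` when one alternative base is an
in-pool allele; the recovery tests assert exactly these masses.
`error_freq` is computed as the complement of the two rounded
frequencies, which makes the per-cell identity
`focal + jump + error = 1` hold exactly in floating point.

Note the observed per-cell jump frequency estimates the *visible* jump
rate: in a 3-library pool where only one pool-mate differs, only half of
the switched templates change the base, so the cell-level frequency sits
below the underlying per-read switching probability. The defaults
(`depth 200`, `e = 0.05%`, `j = 1.6%`) reproduce the regime reported for
a deep pooled exome capture.

## CNV scan

Per-probe centering subtracts the across-substrain median, so a
copy-neutral cell sits near 0 and a substrain-specific loss is a negative
residual; a shift shared by the majority of substrains is absorbed by the
median and therefore invisible (a warning states this breakdown mode).
Deletions are maximal runs of ≥ `min_run` (default 3) consecutive probes
below `threshold` (default −0.5) per substrain; calls with identical probe
spans merge across substrains. Reported coordinates are the first/last
probe of the run (1-based inclusive internally, BED half-open on export):
probe arrays bracket breakpoints, they do not localize them. At the
defaults, a 13-probe δ = −2 deletion in σ = 0.1 noise is recovered with
its exact span essentially always, while a null cell crosses the
threshold with probability ≈ 2.9e−7, so 100-probe null tracks are almost
never called; at σ = 0.3 the exact-span rate drops to ≈ 0.9 because a
flanking null probe occasionally extends the run — a property of
run-threshold calling, not a defect.

## Pipeline determinism

Every stochastic stage takes an explicit seed; the CLI derives per-stage
seeds as `SeedSequence([seed, crc32(stage)])`. JSON is written with sorted
keys and TSV floats with fixed formats, so identical configuration and
seed reproduce byte-identical outputs; the acceptance script verifies this
by diffing two full pipeline runs.

## Problem sizes in the acceptance script

The script re-measures each guarantee at the size its statistical
tolerance was stated for: 400 clock-true replicates of 5 taxa × 2000 sites
for test calibration, 100 replicates × 5000 sites for topology recovery,
1000 drift replicates, 200 planted/null CNV tracks, depth 5000 × 22 loci
for artifact recovery, and 200 random additive matrices for NJ. These
sizes keep the full recomputation to a few minutes on one CPU.

## Limitations

* The drift simulator draws positions uniformly; real exomes cluster
  variants by capture design and mutational spectrum, and real indel
  lengths are not modeled beyond 1–3 bp.
* SNP-only alignments carry no information about rate heterogeneity;
  no Γ-rate model is provided, and trees with more than 8 taxa are out of
  scope by construction.
* The artifact estimator attributes all in-pool minor variants to template
  switching; index hopping and cross-contamination would be counted as
  jumps too.
* The CNV caller targets losses; gains are available behind a flag but
  use the mirrored threshold, not a calibrated one, and no segmentation
  model (HMM or otherwise) is attempted.
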