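# Methods

This note records the statistical models behind `ystrpop`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data calibrations do and do not demonstrate.

## Data model

A haplotype is a mapping from locus to one call: an integer repeat count,
a microvariant (integer + partial repeat in bp, e.g. 18.2), a null (no
amplification), or a multi-allelic duplication pattern (e.g. 19,20 at a
normally single-copy locus). The default panel is the 17-locus Yfiler
set; DYS385, a naturally duplicated marker typed as an unordered pair, is
stored as two pseudo-loci sorted ascending with microvariants ordered by
(repeats, partial), so 15.2 sits between 15 and 16. DYS389II is stored as
reported (no subtraction of the nested DYS389I fragment). On input,
`Null`, `null`, `-` and `0` all denote a null; `Null` is emitted. The
panel also carries each locus's allelic-ladder integer range; integers
outside it are treated as off-ladder variant alleles by the census (this
is what makes rare alleles such as DYS456·12 or Y-GATA-H4·14 countable as
"allelic variants" alongside partial-repeat microvariants).

## Forensic statistics

Gene diversity uses Nei's unbiased estimator GD = n/(n−1)(1 − Σ pᵢ²),
identically equal to the probability that two samples drawn without
replacement differ (property-tested exhaustively for n ≤ 8). Haplotype
identity for HD/UH/DC is the full serialized 17-locus profile, nulls and
duplication patterns included, computed before any filtering. Per-locus
GD at DYS385a/b treats the sorted pair as one compound category, and the
"average GD" is reported both with that compound locus (16 values) and
without it (15 values). Null alleles count as their own allele category
in per-locus GD; a config switch (`joint_dys385`) exposes the pseudo-locus
alternative. Display rounding: 4 decimals for diversities, 2 for
percentages.

## Rst by two-group AMOVA

The molecular distance between two haplotypes is d(i,j) = Σ_loci
(aᵢ − aⱼ)² on repeat counts (DYS385 contributes its two sorted pseudo-loci
separately). For groups of sizes n_a, n_b (N total):

- SS_total = (1/N)·Σ_{i<j} d(i,j), SS_within = Σ_groups (1/n_g)·Σ_{i<j∈g} d(i,j)
- σ²_within = SS_within/(N−2), n′ = N − (n_a²+n_b²)/N
- σ²_among = (SS_total − SS_within − σ²_within)/n′
- Rst = σ²_among/(σ²_among + σ²_within)

Negative estimates (sampling noise around zero differentiation) are
reported as computed, not clipped. A pool with zero total molecular
variance raises an error. The implementation is verified against a
brute-force oracle that evaluates the same components with explicit pair
loops, over exhaustively enumerated small datasets.

Significance: individuals are pooled and reassigned to groups of the
original sizes; p = #{Rst_perm ≥ Rst_obs}/M with ties counted as ≥ (the
conservative choice) and the simple-proportion estimator by default
(`p_estimator="plus_one"` switches to (k+1)/(M+1)). An exhaustive mode
enumerates every split for tiny pools. Bonferroni: with k populations the
default correction divides α by k(k−1)/2 (for 24 populations, 276 tests,
per-test threshold 0.05/276 ≈ 0.0002).

Before Rst, the YHRD-style filter removes haplotypes with a null,
microvariant or duplication at any included single-copy locus, exempting
DYS385a/b; configured loci (default DYS458) are dropped for everyone
first, so irregularities confined to them cost nothing. A null inside the
DYS385 pair still forces removal, because its repeat coordinate would be
undefined — this is the one removal rule added beyond the standard list,
and it is logged.

## Ordination

Classical (Torgerson) scaling: negative Rst entries are clipped to zero
(configurable), B = −½·J·D²·J is double-centered, and the top two
eigenpairs give coordinates, axes ordered by eigenvalue with the sign
fixed so each axis's largest-magnitude coordinate is positive. Goodness
of fit is the share of positive eigenvalue mass captured by two axes.
Stress-minimizing MDS was deliberately not implemented: distance matrices
of this size embed well metrically, and downstream claims are about
cluster topology, not exact coordinates.

## DA distance, neighbor joining, bootstrap

DA = 1 − (1/L)·Σ_loci Σ_alleles √(xᵢyᵢ), restricted to the shared loci of
the two frequency tables (with L = shared count) so that panels of
different sizes can be mixed; DYS385a/b is one compound locus by default,
consistent with the forensic module. NJ is the standard Saitou–Nei
agglomeration; Q-criterion ties break on the lexicographically smallest
pair of cluster labels (a cluster is labeled by its smallest leaf), making
the topology deterministic; negative branch-length estimates are clamped
to zero with the deficit moved to the sister branch. Bootstrap resamples
loci with replacement (the natural unit for frequency-based trees),
recomputes DA + NJ, and reports each original internal bipartition's
replicate percentage; all replicates derive from one seed. NJ is verified
to reproduce additive matrices exactly (path-length matrix equal to the
input within 1e-9) and the newick output is cross-checked against an
independent tree library in the test suite.

## Median-joining networks and the rho clock

Construction iterates two steps until closure: (1) the ε-relaxed minimum
spanning network over the current nodes under weighted single-step (L1)
distance — an edge (u,v) is kept iff d(u,v) ≤ (the distance level at which
u's and v's components merge) + ε, which at ε = 0 is the union of all
minimum spanning trees; (2) for each connected triplet (two of three pairs
linked — such a triplet always shares a central node, which is how the
scan is organized), the coordinate-wise median is admitted as a new node
when its star cost beats the triplet's own spanning cost, with ε relaxing
admission relative to the cheapest candidate of the pass. Haplotypes with
microvariants, duplications, or nulls at included loci are removed first
and logged (their step distance is undefined); duplicate haplotypes
collapse into one node carrying multiplicity and per-population counts.

Maximum-parsimony post-processing greedily removes median vectors whose
removal does not lengthen the minimum spanning structure over the
remaining nodes (degree-1 medians always go). This is a simplification of
exact Steiner pruning: it guarantees a connected result no longer than its
input with all observed nodes preserved, but not global Steiner
optimality.

rho is the multiplicity-weighted mean shortest-path length from a chosen
ancestral node to every observed haplotype copy; copies coinciding with
the ancestor contribute zero. The ancestral node is a user decision (the
biological question), with a helper suggesting the multiplicity-weighted
most central node; published analyses choose it by inspection, so point
estimates are inherently analyst-dependent. Conversion: t = ρ/(L·μ)
generations, ×25 years; the SE uses the star-genealogy approximation
se(ρ) = √(ρ/n) and scales identically, so estimates under the two bundled
rates (0.00267 pedigree, 0.00069 evolutionary, both per locus per
generation) always differ by exactly their ratio ≈ 3.870. The
approximation understates uncertainty for non-star genealogies.

## Haplogroup prediction

Likelihood of haplogroup h is Π over scored loci of f_h(allele), with
unseen alleles floored at 1e-4 so one off-table allele cannot zero a
lineage; loci with null or multi-allelic calls are skipped. Posteriors
follow from Bayes' rule over the table's priors; the fitness score is the
per-locus geometric-mean likelihood ratio against the best haplogroup's
modal profile, scaled to 100 — a transparent operationalization, not a
reimplementation of any published predictor's internal score. A call is
ambiguous when fitness < 25, posterior < 50%, or the posterior is tied
(ties also break alphabetically). Distribution tables count unambiguous
calls only. The corrected discrepancy rate between two predictors drops
disagreements whose labels share at least the macro-haplogroup letter plus
first digit (J2a1 vs J2a2 agree at J2); note this convention also treats
R1a vs R1b as sub-clade-level. No published haplogroup frequency table is
bundled — the built-in reference is a clearly labeled synthetic toy — so
real-data distributions require a user-supplied CSV.

## Synthetic data

The simulator implements a strict symmetric single-step mutation model:
per lineage and locus, Poisson(μ·t) mutations of ±1 repeat each (no
multi-step mutations, no allele-range boundaries beyond positivity, one
rate for all loci — config hooks exist but defaults stay uniform, matching
the step-counting assumptions of Rst, the networks and rho). The star
generator records each sample's true mutation count, so the generating
genealogy can be rebuilt exactly and the rho clock calibrated against
known truth: on a star of n = 200, L = 8, μ = 0.00267, t = 1000, E[ρ]
equals L·μ·t and the estimate recovers t within 3 SE. Note that the
observed net repeat displacement is smaller than the mutation count
(opposite steps cancel), which is precisely why deep ages estimated from
observed networks are biased downward — the calibration isolates the
estimator from that saturation by using true counts. The split generator
evolves one ancestor independently into each population's founder for
t_split generations and then radiates each founder as a star, producing
genuine among-population variance; at t_split = 0 pairwise Rst is centered
on zero, and the permutation test's type-I error at α = 0.05 stays inside
[0.03, 0.07] over 400 simulated panmictic pairs (199 permutations each,
n = 50 per group — sizes chosen to keep the whole calibration in tens of
seconds). Artifact injection converts integer calls to nulls, +0.2
microvariants, or duplication patterns at per-call rates with a full truth
log, which the census and filter tests cross-check entry by entry.

What the synthetic regime does **not** emulate: locus-specific mutation
rates, multi-step mutations, population growth or migration, haplogroup
structure, or linkage between male lineages and sampling design. Passing
calibrations therefore validate the estimators' arithmetic and their
behavior under their own model assumptions, not the accuracy of any
real-data inference.

## Published-survey inputs

`ystrpop.refdata` embeds the printed summary tables of the five-group
Northern Iraqi Yfiler survey: per-population counts of every irregular
allele, per-population (n, distinct, unique) haplotype counts, the
combined per-locus gene diversities, and the 24-population Rst/P matrix.
The raw 500 genotypes are deposited externally (YHRD YA004212–YA004216)
and are not redistributed, so quantities that require them — overall HD,
per-locus GD recomputed from genotypes, the Rst values themselves — are
not recomputed here; the reconstructions in `refdata` reproduce exactly
those statistics that are functions of the printed counts (UH, DC, census
frequencies and class totals, GD averages, Bonferroni significance
re-flagging), and say so in their docstrings.

## Numerical conventions and degenerate inputs

Frequencies are exact ratios of integer counts; GD requires n ≥ 2.
Distance matrices are validated symmetric with a zero diagonal and
symmetrized against floating-point drift. An all-zero matrix yields the
degenerate MDS embedding at the origin with a warning; identical frequency
tables yield a degenerate (all-zero DA) tree flagged as such. Permutation
ties count in favor of the null. MJ construction caps at 64 closure
passes (never reached in practice; a warning is emitted if it ever is).
Repeat counts in simulation are floored at 1. Seeds: every stochastic
routine takes one integer seed; the pipeline fans a global seed out to
stages via a fixed affine map, and all derived seeds stay below 2³¹.
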