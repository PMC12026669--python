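# Methods

This note documents the models behind `kinchain`, the parameter choices
that matter, and what the simulation-based tests do and do not establish
about real casework data.

## Kinship-chain model

A kinship chain is a path between two individuals in an outbred pedigree,
written as alternating sex labels and arrows. Supported path shapes are the
common pairwise relationships of degrees one to three — parent–offspring,
full siblings, grandparental, half-sibling, avuncular, great-grandparental,
first-cousin, half-avuncular and grand-avuncular — plus unrelated pairs.
Inbred or compound relationships (e.g. three-quarter siblings) and chains
between more than two focal individuals are out of scope; the parser
rejects path shapes outside this inventory rather than guessing.

Canonicalization resolves the two spellings of every chain (forward and
reversed) to the lexicographically smaller string under a token order in
which `→` sorts before `←`; the couple token is always written `FM`.
Unrelated chains are two unordered sex letters. Under these rules the sex
labelings of the path templates deduplicate to 7/22/58/3 chains by
category, 90 in total.

Lineage properties are not hand-tabulated but derived from the chain's
minimal pedigree:

* **Y sharing** — both endpoints male and their father-line closures
  intersect;
* **mtDNA sharing** — the mother-line closures intersect;
* **guaranteed X IBD** — decided by exhaustive per-locus gene dropping:
  symbolic founder alleles are dropped through the pedigree under *every*
  combination of maternal-meiosis choices (at most 2⁵ for these paths), and
  the flag is set only if the endpoints share an allele in all of them.
  Exactly six chains qualify: `F→F`, `F→M`, `F←M` (father–daughter),
  `F←FM→F`, `F→M→F` and `F←M→F`. Notably, a full-sibling aunt–niece chain
  (`F←FM→F→F`) does **not** qualify: the niece can inherit only
  grandmother-derived X material while the aunt carries the grandmother's
  other X, leaving no obligate sharing, even though its X-IBS0 is near zero
  on average.

## Synthetic marker panel

Real per-locus allele frequencies for the emulated multiplex are not
redistributable, and every downstream statistic depends on information
content rather than on specific allele labels. The generator therefore
draws a synthetic panel matching the published per-type diversity:

| parameter | default | rationale |
|---|---|---|
| locus counts | 52 A-STR / 132 SNP / 27 X-STR / 48 Y-STR / 1 mt | the emulated panel after QC exclusions |
| mean alleles per STR locus | 8.83 (A), 7.78 (X), 5.85 (Y) | published observed means; per-locus k ~ max(3, Poisson(target)) |
| STR frequency spectrum | symmetric Dirichlet, α = 0.7 | α calibrated once so the expected unrelated male–male Y-IBS, 48·E[(α+1)/(kα+1)], equals the published unrelated mean ≈ 17.3; implies A-STR heterozygosity ≈ 0.74, typical of forensic multiplexes |
| SNP minor-allele frequency | uniform on [0.1, 0.5] | identity-informative SNPs are ascertained for common variation |
| genetic map | uniform, 1 cM/Mb over GRCh37 chromosome lengths | a download-free stand-in for an interpolated sex-averaged map; recombination fractions remain realistic in scale |
| Y / mtDNA founder pools | 108 haplotypes each, per-locus/per-site independent draws | mirrors assigning founder haplotypes from a reference sample of 108; haplotypes are almost surely unique (mtDNA pool haplotype diversity ≥ 0.999) |

Haplotype diversity uses HD = N(1 − Σp²)/(N − 1) with **N the number of
sampled individuals** (not distinct haplotypes): only that reading
reproduces the reference value 0.9996539 for 108 individuals carrying 104
singleton and 2 doubleton haplotypes.

## Pedigree simulation

Founders draw alleles i.i.d. from the panel frequencies (Hardy–Weinberg
and linkage equilibrium by construction). Transmission:

* **Autosomes and maternal X** — a recombinant gamete: a random starting
  haplotype per chromosome, then a phase switch at each adjacent marker
  interval with probability r = ½·tanh(2d) (Kosambi) for interval length d;
  crossovers in different intervals are independent (no interference — the
  simplest Markov model consistent with using a map function).
* **Paternal X** — passed intact to daughters apart from per-locus STR
  mutation; sons receive no paternal X.
* **Y** — father to son with per-locus mutation at 0.002.
* **mtDNA** — mother to child, mutation- and heteroplasmy-free.

STR mutation is the symmetric single-step model (±1 repeat, rate 0.002 per
locus per meiosis); SNPs flip at 1e-8. Each chain's minimal pedigree is
instantiated per replicate with anonymous unrelated founders as off-path
spouses; all founders are unrelated (no inbreeding loops). A single seeded
`numpy` generator drives every draw, so a dataset is a pure function of
(panel, seed). Replicates of one chain are simulated as `(n_reps, n_loci)`
arrays, which keeps 90 chains × 1000 replicates around 10–20 s on one core
— the problem size used throughout the tests and the acceptance script
(2000 replicates for the degree-ordering property).

## IBS scoring conventions

Per locus, *ibs* is the multiset intersection of the two allele sets (so a
hemizygous male X contributes a single-allele multiset and caps *ibs* at 1
against anyone), *ibs0* = 1 iff *ibs* = 0. Y-IBS counts per-locus equality
of haploid alleles; it is **missing**, not zero, for any pair that is not
male–male, and the classifier treats missingness as a dedicated
"inapplicable" category rather than imputing. M-IBS is a whole-haplotype
identity indicator. Only the autosomal scores are normalized (across the
STR and SNP subsets); X scores are raw sums, matching the magnitudes the
reference distributions display (full sisters ≈ 45 of 54, same-patriline
Y ≈ 47.7 of 48). Scoring a male–male X locus 0/1 rather than 0/2 is a
convention choice; it only rescales one feature and is flagged for
sensitivity testing.

## Bayesian-network classifier

Scores are discretized into equal-frequency bins, B = max(2, ⌊n^(1/3)⌋)
for n training rows (the convention of the common discretization
packages); binary M-IBS and the sex pair pass through as categories, and
out-of-range test values clamp to the edge bins. The default network is the
class node pointing at every score plus the two empirically dependent pairs
A-IBS→A-IBS0 and X-IBS→X-IBS0; an optional mode hill-climbs additional
score→score edges by BIC. CPTs use add-one smoothing; the class prior is
uniform (simulated classes are balanced); argmax ties break
lexicographically.

**The observed sex pair is a classifier input.** In casework the sexes of
the two compared individuals are known, and tasks are posed against
sex-matched unrelated pairs, so every network includes the unordered sex
pair (MM/MF/FF) as an observed child of the class node. This is what makes
the reference accuracy structure reachable at all: with autosomal scores
only, the four parent–offspring chains are distributionally identical, and
the first-degree 7-class accuracy of ≈ 85% is exactly the 6/7 achieved when
sexes restrict the candidate set (four same-sex classes and mixed-sex full
siblings resolved; father–daughter vs mother–son a coin flip). Without the
sex node that task cannot exceed ≈ 2/7. Likewise the autosomal-only
second-degree accuracy lands at the 3/22 chance level because each sex-pair
stratum contains autosomally exchangeable classes.

Evaluation is stratified 5-fold cross-validation with the discretizer and
network refit per fold; reports include overall, per-class, top-2 accuracy
and the confusion matrix.

## Merging indistinguishable chains (mKCs)

Chains are merged on centroids in score space: scores are z-standardized
over all rows (missing Y imputed with the unrelated male–male mean first,
so all chains live in one 6-space), per-chain mean vectors are computed,
pairwise Euclidean distances are divided by the largest centroid distance
(normalized distance D ∈ [0, 1]), and chains closer than a threshold D
merge by single-linkage connected components — deterministic and monotone:
the mKC count is non-increasing in D, 90 singletons at D = 0.

Two properties of this definition are worth knowing. At the threshold that
yields ~23 merged classes (D ≈ 0.06–0.08 on simulated data) all seven
first-degree chains and the three unrelated chains remain singletons, and
classification accuracy on merged labels exceeds 95%. But the *absolute*
D scale is not comparable to the reference analysis: "normalized distance"
is not fully specified there, and under the definition used here D = 0.22
already merges down to single digits of mKCs. Alternative deterministic
definitions (complete/average linkage; rank-transformed or within-class-
whitened spaces) were examined and none reproduces the reference D scale
while preserving its qualitative singleton structure; the qualitative
behavior (rapid monotone decrease of the mKC count with D, accuracy rising
as resolution drops) is robust across all of them.

PCA summaries use the same standardized 6-score matrix; on default
simulated data the first three components explain ≈ 87% of the variance,
with first-degree chains well separated from everything else.

## What the synthetic study does and does not show

The generator emulates the *information content* of the real panel
(per-type allele diversity, Y/mtDNA pool diversity, map scale), not its
specific loci: allele frequencies are exchangeable draws, linkage reflects
a uniform map, and there is no genotyping error, dropout, null allele or
mtDNA heteroplasmy (a real full-sibling trio in the reference data was
initially split by a point-heteroplasmy). Passing tests therefore
establish correctness of the chain calculus, the transmission model, the
scores and the classifiers, and reproduce the reference accuracy structure
at simulation level; they do not certify accuracy on any particular real
population, and third-degree accuracies here run a few points above the
reference values — the discrete classifier used here sits essentially at
the Bayes optimum of the simulated score distributions, whereas the
reference implementation evidently lost a few points to its own
discretization/structure choices (its printed score moments imply a higher
attainable accuracy than its printed accuracy).

## Numerical and degenerate-input choices

Frequencies are validated to sum to 1 within 1e-6 (files carry ≥ 12
significant digits); Dirichlet draws are floored at 1e-6 to keep every
allele representable. Bin edges equal to the column maximum are dropped so
the top bin is never empty; constant score columns collapse to one category
with a warning. Chains with fewer than k members per class are rejected by
cross-validation rather than silently unstratified. The merge threshold is
validated to [0, 1]; D = 0 yields no edges even between identical centroids
(strict inequality). All randomness flows from a single integer seed;
identical configuration and seed reproduce byte-identical output tables.
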