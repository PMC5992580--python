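# Methods

## Scope and model

`famburden` prioritises germline candidate genes in small family
cohorts where association testing is impossible. Its statistical core
is intentionally minimal: every inference is an exact combinatorial
test on counts — hypergeometric over-representation, one-tailed Fisher
burden comparison, Bonferroni control — applied after a deterministic
filtering cascade. There is no fitted model; the scientific content is
in *what* is counted (rare, protein-affecting, affected-carried
variants; one occurrence per affected family; LoF only for burden) and
in the exactness and reproducibility of the tests.

Assumptions baked into the counting:

- Autosomal, diploid genotypes; alt-allele counts per sample, with
  half-missing calls contributing their observed allele only.
- One gene symbol per annotated alt allele (no transcript resolution);
  multi-allelic records are decomposed per alt allele before filtering.
- Rarity can be judged from a single reference allele frequency, with
  absence from the panel implying rarity.
- Within a family, shared variants descend from a common haplotype, so
  a variant is counted once per family regardless of how many affected
  members carry it.
- Incomplete penetrance: an unaffected carrier never disqualifies a
  variant; segregation asks only that every sequenced affected member
  carries it. A family with fewer than two sequenced members (or no
  sequenced affected member) is uninformative.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `max_control_af` | 0.05 | strict `<` threshold on the reference allele frequency; the conventional "uncommon" cut for dominant predisposition screens |
| `missense_rule` | `both` | SIFT deleterious AND PolyPhen damaging; `either` offered because the conjunction in prose descriptions of such filters is often ambiguous |
| `possibly_damaging_counts` | true | PolyPhen "possibly damaging" counts as damaging; configurable |
| `missing_prediction_fails` | true | missense lacking a SIFT/PolyPhen call fails that predictor (conservative) |
| `hypervariable_fraction` | 0.01 | fraction of genes dropped as hypervariable, ranked by rare protein-affecting variant count; ties at the cut are all dropped |
| `min_cluster_size` | 5 | a cluster is five or more physically interacting candidate genes |
| term size window | [10, 200] | GO terms eligible for assignment; smaller terms are unstable, larger ones uninformative |
| `alpha` | 0.05 | significance threshold on Bonferroni-adjusted over-representation p |
| `burden_mode` | `proportion_of_burden` | see below |

## Numerical choices

- Hypergeometric probabilities are exact rationals built from
  arbitrary-precision integer binomial coefficients; tail sums are
  computed in integer arithmetic and converted to float once. No
  normal approximation at any table size. If an exact tail underflows
  float conversion, a log-gamma evaluation of the leading term is
  returned, so a p-value is never reported as 0.
- Bonferroni multiplies by the number of tested terms by default; the
  family size `m` is configurable (e.g. to count only terms with
  nonzero overlap) because over-representation services differ on this
  and the choice is not recoverable from published output.
- Deterministic tie-breaking everywhere: clusters are ordered by size
  then first member; term assignment breaks ties by smaller adjusted
  p, then smaller term, then lexicographic id; gene lists are sorted.
  Two runs with the same inputs are byte-identical without any seed.
- Degenerate inputs fail loudly: empty contingency tables, empty
  candidate lists, a burden test with a zero total in either cohort,
  and clusters outside the annotation background are domain errors,
  not silent zeros.

## Open design points and the choices made

**Order of gene-level operations.** Collapsing-then-filtering can drop
hypervariable genes either before or after selecting LoF-containing
genes. Published accounts of this style of pipeline are internally
inconsistent about the base set for the "top 1%" (the arithmetic of
reported counts suggests the 1% was taken on the LoF-selected set, not
the full gene set). Default here: hypervariable exclusion AFTER LoF
selection (`exclusion_order="lof_first"`); the other order is available
as `exclude_first`. Neither is asserted as ground truth.

**Burden table construction.** How the 2×2 for the term burden test is
assembled from case and control counts is genuinely underdetermined:
denominators could be each cohort's total filtered LoF count or its
chromosome count, and control occurrences could be counted per allele
or per individual. Both defensible modes are implemented and reported
explicitly — `proportion_of_burden` (default: in-term vs out-of-term
counts, total filtered LoF burden as denominator; self-normalising
against coverage and calling differences between internally and
externally produced datasets) and `carrier` (count vs 2N − count). The
control side of `proportion_of_burden` uses aggregated allele counts,
the case side family-deduplicated occurrences; both totals are
restricted to the post-exclusion gene universe so hypervariable genes
distort neither cohort.

**Carrier meta-analysis units.** The cross-study enrichment test
defaults to allele-level denominators (2N chromosomes per cohort, one
counted allele per heterozygous carrier), matching aggregation of
allele counts across studies; with the packaged *PALB2* records this
gives p = 0.0386 vs the 503 reference Europeans. A per-individual
`carrier` unit is provided (p = 0.0384 on the same counts). The
packaged records table carries six nominally-LoF carriers (after the
flagged exclusion of an unpublished report that did not fit the search
criteria); the published bookkeeping counts five of 329, so the
published count ships alongside the records and drives the headline
test, with the discrepancy flagged in the report.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *structure* of a 22-family
gastric-cancer exome study: the per-family counts of sequenced
affected/unaffected members (28 + 11), a 503-individual control panel,
a ~1000-gene universe, annotation strings in Sequence Ontology terms
with SIFT/PolyPhen calls and a European reference allele frequency, a
sparse physical-interaction network, and GO-style gene sets.

Mechanics: each family has two unsequenced founders; rare variants
arise on founder haplotypes (per-haplotype per-gene rate 0.01 for LoF,
similar for damaging and benign missense) and are transmitted to each
child with probability ½, independently per variant. This yields
realistic within-family sharing, segregation failures, and
unaffected-only carriers. The planted effect adds *extra* novel LoF
variants (absent from the reference panel) in the 20 planted-term genes
at (multiplier − 1) × background rate, so multiplier 1 is an *exact*
null — planted genes are then statistically indistinguishable from
background, which is what the type-I calibration runs exploit.
Background variant AFs straddle the 0.05 threshold (60% rare, 20%
common, 20% absent) to exercise the rarity filter; ten designated
hypervariable genes carry ~15× variant rates in families and controls
alike, mimicking the mucin/HLA-type genes such pipelines must discard;
a handful of genuinely common shared variants exercise the AF filter's
multi-carrier path. Rates were chosen once to give exome-plausible
totals (≈950 filtered variants across 22 families, ≈340 LoF genes)
and are not tuned.

Not emulated: linkage disequilibrium and within-chromosome
co-transmission (variants segregate independently), sequencing error
and genotype-likelihood uncertainty (only random missingness at rate
0.002), population stratification between families and controls,
recurrent mutations shared across families, and GO graph structure
(terms are flat sets; no propagation). Passing the synthetic
calibration and recovery checks therefore demonstrates correctness of
the counting and testing machinery under the generator's idealised
inheritance model, not robustness to stratification, relatedness
mis-specification, or annotation error in real exomes.

## Problem sizes used by the acceptance script

The script calibrates the null on 1000 simulated cohorts and measures
recovery on 100, both at the default cohort size — large enough for a
±1.4% Monte-Carlo standard error on the type-I rate while keeping a
full run around one minute on a single core. The Fisher oracle sweep
covers every 2×2 table with all margins ≤ 12 (5550 tables), the
largest exhaustive family that is instant to enumerate exactly.

## Known limitations

- Gene identity is by symbol; aliasing between annotation sources is
  the caller's problem.
- The clusterer is plain connected components on the physical
  interaction subgraph; it does not reproduce proprietary weighted
  clustering of network services, only the grouping role the network
  plays in the analysis.
- GO annotations are taken as given (pre-propagated if desired).
- The burden test compares aggregated counts, not genotypes, on the
  control side; individual-level control data cannot be modelled.
- Fisher's exact test is conservative on discrete tables; observed
  type-I error in the null calibration runs (~0.02–0.03 at nominal
  0.05) reflects that, not an error.
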