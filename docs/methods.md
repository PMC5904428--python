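# Methods

This note documents the models, conventions and numerical choices behind
`barcodegeo`, and what the synthetic data can and cannot establish.

## Distances

The only genetic distance used is the uncorrected p-distance. For a pair
of equal-length rows, every position where either row carries a character
outside {A, C, G, T} (gap, N, any IUPAC ambiguity) is removed *for that
pair* (pairwise deletion), and p = mismatches / compared sites. The matrix
of all pairs is accumulated with mask matrix products, so survey-scale
inputs (≈100 × 657) are instantaneous. A pair sharing no unambiguous site
has no defined distance and raises rather than returning 0 or NaN.

Two different missing-data conventions deliberately coexist in the
package: distances use pairwise deletion, haplotype collapsing removes
ambiguous columns dataset-wide (below). Both conventions are standard in
the tools this pipeline mirrors, and they are *not* interchangeable —
tests cover each against brute-force oracles.

Per-specimen summaries report median, maximum and mean distance to the
other ingroup members; the median of an even count is the mean of the two
central values. The barcoding-gap report takes the maximum over
focal-taxon pairs and the minimum over focal-vs-other pairs, overall and
per other taxon; the gap is "present" iff min-inter > max-intra.
Percentages are rendered at one decimal only at presentation; internal
values keep full precision.

## Geography

Distances between specimens use the spherical law of cosines with
R = 6,367 km, the Earth radius at central European latitudes. The arccos
argument is clamped to [−1, 1] to keep identical and antipodal points
finite under rounding error. This exact dialect (rather than haversine or
an ellipsoid) was adopted because it reproduces the survey's printed
kilometre values at nearest-km rounding; haversine agrees within 0.1 km at
these scales and serves as the numerical oracle in tests. Isolation by
distance is summarised by ordinary least squares of p-distance on
kilometres over all pairs; pairs at 0 km have an undefined p-per-km ratio
and are reported as missing in the ratio column.

## Haplotypes and diversity

Collapsing removes every column containing any non-ACGT character in any
record (the "exclude sites with missing data" option of the haplotyping
tools this mirrors), then groups rows by exact identity over the retained
columns. Haplotype IDs are first-occurrence ordinals (H1, H2, ...).

Statistics on the full matrix, counting only A/C/G/T states per column:
segregating sites S (columns with ≥2 states), total mutations
η = Σ (states − 1) — so a triallelic column contributes 2 — haplotype
diversity Hd = n/(n−1)·(1 − Σ(Xᵢ/n)²), and nucleotide diversity π as the
plain mean over unordered pairs of the per-site difference fraction on the
complete-data columns (an n/(n−1) bias-corrected variant is available via
a flag; at survey scale the difference is below printed precision).

Synonymous/replacement classification is per polymorphic column: each
non-majority state's codon (embedded in the column-majority consensus,
reading frame 0 by default, invertebrate mitochondrial code) is translated
against the majority-state codon. Columns whose codon context is
incomplete or ambiguous are left unclassified, so the classified total can
fall short of η at multi-hit or edge sites; the counting rule is
deterministic and majority-anchored because the ancestral state is
unknowable from one alignment. The "non-synonymous only" second collapse
masks every column whose minor states are all synonymous to the majority
state and re-collapses, leaving only replacement variation to separate
haplotypes.

## Statistical-parsimony network

The connection limit J follows the statistical-parsimony idea: connect
haplotype pairs only while the probability is ≥ α (default 0.95) that the
observed differences reflect single substitutions with no hidden changes.
The probability model implemented here is a closed-form pair model:
substitutions per site are Poisson with mean λ on the path joining the
pair, under Jukes–Cantor symmetry. λ is estimated from the observed
difference fraction j/L by inverting the JC saturation curve,
λ = −¾ ln(1 − 4j/(3L)), and

P(parsimony) = [λe^{−λ} / (¾(1 − e^{−4λ/3}))]^j · [e^{−λ} / (¼ + ¾e^{−4λ/3})]^{L−j}.

J is the largest j with P ≥ α; for the 657-position barcode at α = 0.95
this gives J = 8, frozen as a regression value in the tests. This model is
somewhat more conservative than the coalescent-averaged limits of the
original TCS software (which typically allows a few more steps at this
length); a `fixed_limit` override exists for users who want to match a
specific published limit.

Construction is agglomerative, Kruskal-like: haplotype pairs in order of
increasing step count (ties by lexicographic ID pair), each connected
through a private chain of step−1 anonymous median nodes when either the
pair spans two components or the direct chain is strictly shorter than the
current graph distance. The second clause retains genuine
alternative-path loops (e.g. four haplotypes on a unit-step cycle) without
ever duplicating an existing minimum-length path — on tree-like inputs the
result is exactly a minimum spanning network, verified against a
brute-force oracle. Median nodes are anonymous placeholders (no sequence
reconstruction): only step counts matter for the topology, matching the
small open circles of typical TCS renderings. Construction is fully
deterministic.

## Richness estimation

Chao1 uses the small-sample multiplier A = (n−1)/n by default:
S₁ = S_obs + A·F1²/(2F2), or S₁ = S_obs + A·F1(F1−1)/2 when F2 = 0. The
default variance is the bias-corrected branch
var = F2·(A r²/2 + A² r³ + A² r⁴/4) with r = F1/F2 (the classic branch
without the A factors is selectable); the 95% CI applies the log-normal
transform to F0 = S₁ − S_obs with z = 1.96, keeping the lower bound above
S_obs. This combination reproduces, to the integer, the benchmark output
of the abundance-based estimator software the package was validated
against (e.g. S_obs 47, n 97, F1 38, F2 2 → 404 with CI 140–1,426). ACE
uses the standard rare-class cutoff of 10 and falls back to S_obs without
rare classes; an all-singleton rare class (coverage 0) raises.

Rarefaction is analytic: E[S(m)] = S_obs − Σᵢ C(n−Xᵢ, m)/C(n, m), computed
with log-gamma to avoid overflow, with the exact hypergeometric variance
(including pairwise joint-absence terms) for the confidence band.
Extrapolation uses the unseen-class model S(n+m*) = S_obs +
F0·(1 − (1 − q)^{m*}), q = F1/(nF0 + F1), which meets the interpolated
curve at m = n and tends to the Chao1 asymptote. The samples-needed
projection inverts this closed form; because the asymptote is approached
only asymptotically, the default stopping rule is "within 0.5 haplotypes
of the point estimate", with a target-fraction alternative (e.g. 95% of
the asymptote). Randomised accumulation curves (seed-controlled shuffles
of the reference sample) are provided for plotting envelopes only;
expectations always come from the analytic formulas.

## Synthetic data

The generator emulates exactly the features the pipeline measures: a pool
of haplotypes derived from a random stop-codon-free root by placing
substitutions along a random branching order (star-ish: each new lineage
picks a uniform random parent); a skewed abundance law (geometric by
default, Zipf and uniform available); substitutions biased 9:1 toward
synonymous changes (COI-like; rejection-sampled per placement); regional
coordinate centres with Gaussian dispersion; optional isolation by
distance (centres ordered along longitude by root distance of their
lineages); optional missing data as N characters. Defaults mirror the
survey's conditions: 97 specimens, 657 positions, a 400-haplotype pool
(the survey's own richness estimate) sampled far below saturation — the
geometric decay 0.04 makes the expected observed richness ≈48 at n = 97.
Every dataset carries a truth ledger (root, per-haplotype mutations with
labels, sampled pool indices) that exactly explains the polymorphic
columns when no missing data is injected.

`paper_shaped_fixture()` is the survey-shaped dataset: the real printed
coordinate/bioregion table joined to synthetic sequences carrying the
reconstructed abundance composition — dominants 17/15/10/4 and 38
singletons are printed marginals; the residual 13 specimens are completed
as 3+3+3+2+2, the minimal-style completion with two doubletons consistent
with the printed Chao1 arithmetic. The completion and the sequences are
reconstruction, not data: statistics fixed by the abundance vector and the
coordinates (haplotype counts, Hd, Chao1 and its CI, pair counts,
kilometre values) are faithful to the survey; sequence-borne statistics
(π, segregating-site and synonymous/replacement totals, the interspecific
minima) are realistic in magnitude but not the survey's values, and
nothing in the tests pretends otherwise. Passing tests on synthetic data
therefore demonstrate the correctness of the algorithms and the abundance
arithmetic, not agreement with the deposited sequences.

## Numerical and degenerate-input conventions

Ambiguity is defined as "anything outside A/C/G/T" everywhere. Pairs with
no shared unambiguous site, empty alignments, singleton ingroups,
zero-retained-column collapses, degenerate OLS (constant x) and
coverage-zero ACE all raise with specific messages rather than returning
sentinel values; report-only screens (stop codons) never raise. All
randomness flows through explicit `numpy` Generators seeded per dataset;
no global state is touched. Problem sizes in the tests are chosen so the
whole suite (including the 200-seed estimator-recovery and 50-replicate
IBD sign checks) runs in well under a minute on one CPU.

## Known limitations

- The parsimony-limit model is a pair approximation, not the original
  coalescent recursion; limits are conservative by a few steps at barcode
  lengths.
- Median nodes carry no reconstructed sequences, so networks with many
  long chains overstate topological freedom relative to sequence-aware
  TCS implementations; loops are retained, not resolved.
- The classified synonymous/replacement totals depend on the
  majority-anchored convention at multi-state sites; other tools may
  report slightly different splits for the same matrix.
- Incidence-based estimators (Chao2, ICE, jackknife) and
  recombination-aware statistics are out of scope.
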