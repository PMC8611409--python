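# Methods

## Data model

A screen yields a bipartite network: edges connect TF identifiers to promoter
identifiers (promoters are named by their downstream gene, so target sets and
DEG sets share a namespace). Edges are presence/absence; duplicate input rows
are collapsed with a logged count. Identifiers are uppercased on read (AGI
locus convention), and an identifier occurring in both roles is rejected as a
bipartiteness violation. Promoters screened without any interaction are kept
out of all counts and reported in a separate field, so `n_promoters` means
"promoters with ≥ 1 interaction". A promoter may belong to several pathways;
it then contributes its TFs to each pathway's TF set exactly once (set
semantics — all contingency tables count distinct TFs, never edges).

## Exact tests

All enrichment statistics condition on the margins of a 2×2 table and use the
hypergeometric distribution, computed in log space from a cached log-factorial
table (stable for universes of tens of thousands of genes):

- one-tailed (`greater`): `p = P(X ≥ a)`; when `a` sits at the support floor
  the value is exactly 1;
- two-sided: the minimum-likelihood rule — the sum of `P(X = x)` over support
  points with `pmf(x) ≤ pmf(a)·(1 + 1e-7)`. The relative tolerance absorbs
  floating-point ties and matches the convention of the common reference
  implementations, keeping adjusted p-values comparable across tools.

The reported odds ratio is the unconditional sample OR `(a·d)/(b·c)` — `+inf`
when `b·c = 0` with `a·d > 0`, undefined (NaN) when both products vanish —
rather than the conditional MLE: the downstream uses (the regional rank score)
only need a monotone, reproducible enrichment measure, and the sample OR
avoids iterative root finding. An optional Haldane +0.5 correction exists for
the OR only, never for p. No chi-square approximation is used anywhere.

Adjustments are implemented directly: BH is the step-up cumulative minimum of
`p(i)·m/i` over the sorted order, Holm the step-down cumulative maximum of
`p(i)·(m−i+1)`, both capped at 1 and returned in input order. The test suite
pins both against hand-worked examples and statsmodels, and verifies
rank-monotonicity and permutation equivariance.

Correctness of the exact tests is established by exhaustive enumeration: for
every 2×2 table with `N ≤ 60` (≈ 700k tables), both tails agree to 1e-12 with
an independent oracle built from exact integer binomial coefficients.

## Stage-specific conventions

**Pathway pairs.** For pathways A and B, `a=|A∩B|`, `b=|A\B|`, `c=|B\A|`,
`d = universe − |A∪B|`; this is the only construction that guarantees
non-negative cells. The universe defaults to the number of TFs *screened*
(2,039 in the motivating assay scale), not TFs detected, and is configurable.
One-tailed tests, BH-adjusted jointly across all C(P,2) pairs. The regional
score for a focal pathway is `p_adj / OR` per partner, ranked ascending; ties
break by larger shared count, then partner label; `OR = 0` ⇒ score `+inf`
(last), undefined OR ⇒ excluded with a warning. Note the direction of the
universe effect: enlarging `d` with `a,b,c` fixed makes the same overlap more
surprising, so the one-tailed p is non-increasing in `d`.

**Family × compartment.** Localization calls resolve per gene with
experimental evidence overriding consensus prediction; contradictory rows
within the winning tier are an error, not a silent pick. Within a pathway
subnetwork, for each (family F, step E, compartment C): `a` = distinct TFs of
F binding ≥ 1 gene of (E, C), `b` = the rest of F in the assayed collection,
`c`/`d` analogous for non-F TFs — so every table sums to the collection size.
The standard family-membership × binding-status construction is used (the
alternative margin assignments are degenerate or asymmetric); this is recorded
here as the package's convention. Two-sided tests, Holm-adjusted across all
triples with ≥ 1 annotated gene; `p_adj < 0.05` flags significance. A
descriptive per-family binding fraction (`a` over the family's
subnetwork-active members) accompanies each test.

**Conditional co-expression.** Pearson r is computed per edge per compendium;
a gene absent from a compendium or with a zero-variance profile yields a
missing flag (NaN), which never passes and is never imputed. The pass rule is
`|r| ≥ threshold` with threshold 0.8 — the boundary value passes (≥, not >).
Compendia are analyzed marginally; no pooling. Edges group by their exact
pass-set (Venn cells); the summary reports edges passing anywhere, exclusive
to one dataset, and in exactly two. Probe-to-gene collapsing and normalization
are upstream concerns: this module requires one row per gene.

**DEG validation.** The universe is the set of genes tested for differential
expression in that contrast — not the genome — because the enrichment
question is posed within the DE analysis. Predicted targets outside the
universe are dropped with a warning. Target and pathway enrichment are
one-tailed; the compartment variant is two-sided and restricted to the
pathway's genes, asking whether the DE response concentrates in one
compartment's isoforms. Degenerate cases behave sensibly: a DEG set equal to
the universe gives p = 1 with an undefined OR; a single-compartment pathway
gives p = 1.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the conditions
under which the pipeline's recovery properties are stated.

**Scale.** Quarter scale relative to a genome-scale screen: 500 TFs, 60
promoters in 12 pathways with a realistic size spread (TCA-cycle analogue 14
genes, glycolysis 16, down to single-gene pathways), plus two deliberate
multi-pathway genes so pathway sizes sum to more than the promoter count.
This keeps a full simulate-analyze cycle around 50 ms so that 100-replicate
recovery estimates run in seconds.

**Binding model.** Edge (t, g) is Bernoulli with probability
`clip(base · breadth_t · boosts, 0, 1)`; `base = 0.04` reproduces the edge
density of a dense Y1H screen, and `breadth_t` is log-normal (σ = 0.6,
mean-normalized to 1), giving generalist/specialist TF heterogeneity. That
heterogeneity alone makes *every* pathway pair share more TFs than an
independence null — the qualitative background of such screens — on top of
which structure is planted:

- *Pathway-pair sharing*: a random 10% of TFs ("co-regulators") have their
  per-gene binding probability into both pathways of a planted pair
  multiplied by a boost. The recovery property is stated for a planted pair
  in the measured-OR ≥ 5 regime with both TF sets ≥ 30; with boost 15 between
  the two 2-gene sulfur amino-acid pathways the measured OR has median ≈ 8–9,
  and the planted pair attains the smallest adjusted p in ≥ 90% of 100
  replicates. The *default* bundle instead plants moderate boosts between the
  glucosinolate pathway and methionine/cysteine biosynthesis, mirroring the
  precursor-supply relationship the regional rank is meant to surface.
- *Family bias*: TFs of one family (default LBD, sampled at 3× weight,
  ≈ 65 members) bind genes of one (step, compartment) group at 4× probability.
  The planted group is the three-gene mitochondrial PDH analogue (a
  multi-gene complex in real annotations); with a single gene the ×4 signal
  is too dilute for reliable top-ranking, with three it tops the Holm-adjusted
  list in ≥ 85% of 100 replicates.
- *Exclusive co-expression*: all profiles are i.i.d. standard normal; a
  planted target in its planted dataset is rewritten as
  `ρ·z_tf + sqrt(1−ρ²)·ε`, so the population correlation is exactly ρ there
  and 0 elsewhere. At ρ = 0.95 and n = 40 samples, sample r exceeds 0.8 with
  near-certainty (Fisher-z argument), while a null |r| ≥ 0.8 at n = 40 is a
  far-tail event — hence ≥ 90% correct exclusive classification and ≪ 5%
  null pass rate.
- *DEG overlap*: the overlap count between a 100-gene target set and a
  400-gene DEG set in a 5,000-gene universe is drawn from the Fisher
  noncentral hypergeometric distribution with odds 4, conditioned on the DEG
  total; the estimated OR recovers the planted value (median ≈ 4, within
  [3, 5.5]) with power ≈ 1 at α = 0.05.

**Determinism.** Each generator call derives its RNG stream from
(seed, generator-name) via a seed sequence, so identical seeds give
byte-identical output files and adding a generator never perturbs another.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* each stage assumes:
bipartite Bernoulli binding with TF-breadth heterogeneity, set-based pathway
membership, Gaussian expression with planted exclusive correlations, and
odds-ratio-structured DEG overlap. It does not emulate microarray probe
effects, normalization artifacts, correlated backgrounds between related
compendia (e.g. salt vs osmotic stress), promoter sequence, or Y1H
false-positive structure. Passing recovery tests therefore demonstrates that
the estimators detect the effects they target at realistic sizes and are
correctly calibrated under clean nulls — not that any particular biological
dataset will show those effects. Analyses of real screens additionally
depend on annotation versions (pathway membership, probe-to-gene maps,
localization databases), to which the co-expression Venn counts in
particular are sensitive.

## Numerical and degenerate-input choices

- Log-space pmf with a grown-on-demand log-factorial table; exact 1.0 for
  the whole-support tail.
- Two-sided tie tolerance `1 + 1e-7`, as above.
- Adjusted p-values are returned as plain floats, capped at 1.
- Empty edge files parse to empty networks (not errors); empty summaries are
  all-zero. A single annotated pathway yields an empty pair list with a
  warning. Missing correlations and undefined ORs are flags, not exceptions;
  errors are reserved for malformed input (missing columns, negative cells,
  bipartiteness violations, contradictory experimental localization).
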