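# Methods

## Model and procedure

The package tests for gene conversion between X and Y gametologs in
strata whose recombination stopped before the split of Laurasiatheria
(cattle) from Euarchontoglires (human, mouse). The data are a
seven-role coding alignment (bx, by, hx, hy, mx, my, out); the analysis
chain is:

1. **Column filtering.** Columns containing `-` or `N` in *any* role are
   excluded. `N` is treated like a gap: an ambiguity code cannot be
   polarized. All coordinates are 0-based internally; reports print
   1-based positions.
2. **Polarization.** A retained column enters the analysis only if the
   seven states contain exactly two nucleotides (three or more variants
   suggest hypermutability; one variant is uninformative). The outgroup
   variant is coded 0, the alternative 1, giving a six-bit pattern in the
   fixed order (bx, by, hx, hy, mx, my).
3. **Parsimony classification.** Each of the 64 patterns is assigned the
   minimal set of branch substitutions producing it on the preradiation
   tree `(out, (bx, (hx, mx)sx)xstem, (by, (hy, my)sy)ystem)`. In the
   binary coding, a substitution on a branch flips every leaf below it,
   so the implementation searches subsets of the ten ingroup branches by
   XOR of leaf masks; an independent test oracle enumerates all 2^11
   branch subsets (outgroup branch included) by explicit state
   propagation. A pattern and its complement are equivalent: the cheaper
   orientation wins, ties keep the polarized orientation (so `101010`
   reports the X stem, its complement the Y stem; `000000` is
   monomorphic while `111111` is the one-substitution outgroup-branch
   pattern). `min_substitutions` does not charge the outgroup-branch
   flip when the complement orientation is used.
4. **Lumping and the 18-pattern scheme.** With a single Laurasiatheria
   representative, a substitution on the bovine terminal branch and one
   on the stem uniting human and mouse are indistinguishable classes:
   they are pooled as *bsx*/*bsy*. The within-lineage class comprises
   the matched pairs {bx+by, sx+sy, hx+hy, mx+my} (6 patterns including
   complements), the among-lineage class the six terminal cross pairs
   (12 patterns). Two-substitution patterns that cross the lumped
   classes (e.g. bovine-X with stem-Y, `100101`) or pair a stem with a
   foreign terminal (e.g. `001110`) are *not* part of the scheme — the
   published table omits them, and some of them are mimicable by a
   single substitution plus conversion, so they carry no clean signal
   either way. They are classified `complex` and excluded, as is
   anything needing ≥ 3 substitutions.
5. **The co-double test.** Conditional on N = within + among, the
   no-conversion null puts the within count at Binomial(N, 1/3) (each
   substitution class appears twice among the within rows and four
   times among the among rows of the scheme). Default inference is the
   exact upper tail P(X ≥ within) — deterministic and exactly what the
   Monte-Carlo procedure estimates; the MC version (default 10^6 draws,
   seed 20170912, add-one correction so p is never 0) is retained for
   fidelity to the original procedure, and a two-sided chi-square
   goodness-of-fit against (N/3, 2N/3) without continuity correction is
   reported alongside (the correction is deliberately absent: the
   borderline published value p = .05004 for counts 33/42 is exact only
   without it).
6. **Topology prerequisite.** The test is meaningless on a
   non-preradiative gene tree. Verdict `preradiation` requires both (a)
   a neighbor-joining tree (p-distance or JC69 on gap-free columns;
   scikit-bio's Saitou–Nei implementation) containing the {bx, hx, mx}
   split, and (b) more stem-branch single patterns (`101010`-type) than
   species-synapomorphy patterns (`110000`-type, which a species-first
   topology would produce as singles). Disagreement gives `ambiguous`;
   both indicators against give `postradiation`; a gene with no signal
   at all is `ambiguous`. The pipeline withholds the conversion p-value
   unless the verdict is `preradiation` or `--force` is given.
   Maximum-composite-likelihood distances, branch lengths and bootstrap
   support are intentionally not reproduced — only the topology matters
   for the prerequisite.
7. **Homogeneity checks.** Classified within/among sites are split into
   transitions/transversions; codons are split into
   synonymous/nonsynonymous. Both 2×2 tables get a chi-square whose
   p-value comes from 10^5+ margin-fixed (multiple hypergeometric)
   simulated tables — the convention of R's
   `chisq.test(simulate.p.value=TRUE)`, against which the implementation
   was cross-validated to four decimals. A zero margin yields p = 1 with
   a warning.
8. **Codon windows.** For the codon analysis the outgroup is excluded
   (requiring two codon variants across all seven sequences leaves too
   few codons). Windows are consecutive triples of ingroup gap-free
   columns starting at `cds_frame_offset` (default 0: alignments of
   complete CDS from the start codon); codons overlapping an excluded
   column are dropped. A codon qualifies if the six ingroup sequences
   show exactly two codon variants; it inherits the lineage class(es)
   of the classified sites it contains, counted once per class (with a
   warning if both classes occur); stop-involving pairs count as
   nonsynonymous with a warning.
9. **Spacing check.** Gaps between successive occurrences of a
   conversion-supporting pattern (default `000011` pooled with its
   complement `111100`; a strict single-orientation mode and a
   raw-column mode exist) are compared to the geometric distribution via
   Q–Q quantiles at plotting positions (i − 0.5)/n, with
   p̂ = 1/mean(gap). Gaps are measured in analyzed-site ranks because the
   geometric null — every analyzed site an independent trial — is only
   coherent on that scale. The published analysis is graphical; the
   Kolmogorov–Smirnov-style discrepancy plus parametric bootstrap band
   (p refitted per replicate) is an extension of this package so the
   check can run unattended.

## Simulator

Each site evolves independently down the preradiation tree: root state
from the base frequencies (default uniform), then a per-branch Bernoulli
substitution jumping to one of the other three nucleotides uniformly —
a Jukes–Cantor-like per-branch model, adequate because the analysis
keeps only biallelic patterns. After the terminal branches each lineage
independently converts with its per-site probability, overwriting the
acceptor gametolog with the donor state (direction fixed or random per
event). Conversion is whole-site (tract length 1) by default, matching
the per-site test and the empirically negligible autocorrelation; a
geometric tract-length option (`tract_mean`, start rate scaled to keep
the marginal per-site probability) exists to build clustered
counter-example fixtures.

Default branch substitution probabilities (per site): out .15,
xstem .05, ystem .075, bx .02, by .03, hx .02, hy .03, mx .026, my .039,
sx .002, sy .003. These encode the study conditions: Y branches ~1.5× X
(higher Y mutation rate), mouse ~1.3× the other species (short rodent
generation time), the internal Euarchontoglires branch ~a tenth of a
terminal branch (~8 vs ~76 MY), and substantial gametolog stems
(variable differentiation time before the radiation). At these rates
the expected within fraction without conversion is ≈ .339 — the 1:2
ratio is exact under class-equal rates and degrades only at second
order under realistic inequality, which is what the null-robustness
check exercises.

What the simulator does *not* emulate: indels (the test uses gap-free
sites only), context-dependent or among-site rate variation, a
realistic mutation spectrum, and back-substitution dynamics beyond the
per-branch Bernoulli draw. Passing tests therefore show the method's
operating characteristics under the idealized per-site model, not
robustness to alignment error or rate heterogeneity along the sequence.

## Problem sizes used in the checks

The null-robustness check uses one 10^5-site alignment (within
fraction vs 1/3 at 3 MC SE) and 2000 conversion-free 5000-site
replicates for the type-I error at α = .05 (threshold .06); power
monotonicity uses 500 replicates at each conversion rate in
{0, .005, .01, .02} on 5000-site genes. Replicates with zero double
patterns count as non-rejections. These sizes put the Monte-Carlo error
well below the asserted margins.

## Design choices where the design was open

* **JSON (not YAML) simulator configs**; the schema mirrors `SimParams`
  field for field, and the CLI overrides sites/seed.
* **Role maps are an explicit input file**, never parsed from FASTA
  headers — public accession headers are heterogeneous across species.
* **N = within + among** as the binomial sample size (the count of
  double-substitution sites): this reading reproduces the published
  per-gene p-values.
* **Seeding**: every stochastic stage draws from a master seed through a
  spawned `SeedSequence`, in a fixed documented order.
* **NJ tie-breaking** follows scikit-bio's deterministic agglomeration;
  degenerate (star-like) matrices may resolve arbitrarily but
  reproducibly.

## Known limitations and surfaced inconsistencies

* The published per-pattern counts for USP9X/Y sum to an among-lineage
  total of 130, while the published summary table prints 113 (within,
  96, matches; the transition/transversion table's row sums support
  130). The package reproduces what the per-pattern counts imply and
  does not guess which table is right.
* The published rodent within-lineage counts quoted in the text (24 of
  30, 24 of 42, 61 of 96, 27 of 33) do not match the corresponding
  per-pattern column sums (23/30, 31/35, 60/96, 26/33); the package
  reproduces the column sums.
* The published simulated chi-square p-values carry visible Monte-Carlo
  noise (consistent with R's default 2000 replicates, SE ≈ .01); the
  converged margin-fixed values are .7153, .4121, 1, .4948 against
  printed .73, .39, 1, .52.
* The test's 1:2 null is exact only when the per-class substitution
  rates are balanced between lineages; strongly species-correlated rate
  differences push the null within fraction above 1/3 and would make
  the test anticonservative. At realistic inequality levels (defaults
  above) the effect is second-order and the type-I error stays
  controlled.
* Direction and tract length of conversion are not inferred — with
  these data the original mutation cannot be identified, so donor and
  acceptor are symmetric.
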