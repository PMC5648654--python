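# codouble

Detecting exchange of genetic information (gene conversion) between X- and
Y-chromosomal gametologs in **old evolutionary strata** — strata in which
X–Y recombination stopped before the Laurasiatheria/Euarchontoglires
radiation (~84 MYA), so that the gene tree is *preradiative*: the X copies
of cattle, human and mouse form one clade and the Y copies another.

After that much divergence, direct sequence comparison cannot tell a
conversion tract from ordinary substitution. `codouble` implements a
comparative site-pattern test (a variant of the "co-double" method) that
can, using only a seven-sequence coding alignment: the X and Y gametologs
of cattle (*Bos taurus*), human (*Homo sapiens*) and mouse
(*Mus musculus*), plus the platypus (*Ornithorhynchus anatinus*) homolog
as outgroup. It is aimed at researchers in sex-chromosome evolution and
molecular phylogenetics.

## The test

Each gap-free alignment column with exactly two nucleotide variants is
coded as a six-bit pattern in the order (bx, by, hx, hy, mx, my), the
outgroup variant mapped to 0. On the preradiation tree, parsimony sorts
the biallelic patterns into:

* **within-lineage doubles** (6 patterns, e.g. `00 11 00` = hx + hy) —
  explainable by X *and* Y substitutions in one lineage, **or** by a single
  substitution plus a gene conversion within that lineage;
* **among-lineage doubles** (12 patterns, e.g. `01 10 11` = bsx + hy) —
  requiring substitutions on X and Y branches of *different* lineages,
  which conversion cannot mimic (those chromosomes never shared a cell);
* singles, monomorphic and complex patterns, which carry no usable signal
  and are set aside (singles still feed the topology check).

Substitutions on the bovine terminal branch and on the stem uniting human
and mouse are pooled into the lumped classes *bsx*/*bsy*; a pattern and its
bitwise complement are equivalent (an extra outgroup-branch substitution
just swaps 0s and 1s).

Without conversion, a double substitution is twice as likely to land in
the among class as in the within class, so conditional on the total
N = within + among the within count is Binomial(N, 1/3). The test is the
one-sided exact binomial tail

P(X ≥ within), X ~ Bin(N, 1/3),

with a seeded Monte-Carlo version and a two-sided chi-square variant
alongside. Prerequisite: the gene must actually show a preradiation
topology, checked by neighbor joining plus single-substitution pattern
support; genes failing the check (the classic *ZFX/Y* situation) are
refused unless `--force`. Companion analyses probe the assumptions:
transition/transversion and synonymous/nonsynonymous homogeneity across
the two classes (margin-fixed simulated chi-square), and a geometric Q–Q
check that conversion-supporting patterns are not spatially clustered.

A simulator generates alignments on the same tree with per-branch
substitution probabilities and per-lineage conversion probabilities
(optionally in geometric tracts), for type-I error, power and oracle
testing.

## Worked example

Test the published DDX3X/Y counts (30 within, 35 among):

```bash
$ codouble test --within 30 --among 35
{
  "within": 30,
  "among": 35,
  "n_total": 65,
  "p_one_sided_exact": 0.02145051444877495,
  "p_one_sided_mc": 0.021293978706021295,
  "n_draws": 1000000,
  "seed": 20170912,
  "chi2_stat": 4.807692307692308,
  "p_chi2_two_sided": 0.028332962784810203
}
```

30 of 65 double patterns are within-lineage (46%, against the 33%
expected from double substitutions alone); the exact tail probability
0.0215 rejects the no-conversion null at the 5% level — evidence that
gene conversion kept touching this gametolog pair long after its stratum
stopped recombining.

The full pipeline on a simulated conversion-free gene:

```bash
$ codouble simulate --sites 5000 --seed 42 --out demo.fasta --roles demo_roles.tsv
$ codouble run --msa demo.fasta --roles demo_roles.tsv --gene demo --out report.json
```

`report.json` then contains (abridged):

```
"topology": {"preradiation_support": 424, "postradiation_support": 4,
             "nj_preradiative": true, "verdict": "preradiation"},
"test":     {"within": 4, "among": 5, "p_one_sided_exact": 0.3497, ...}
```

424 stem-branch single patterns against 4 species-synapomorphy patterns
confirm the preradiation topology, and with conversion switched off the
within fraction (4 of 9) gives an unremarkable p = 0.35.

Real alignments are consumed the same way: an aligned FASTA plus a
two-column role map TSV (`record_id<TAB>role`, roles
`bx by hx hy mx my out`).

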