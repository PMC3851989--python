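# coremod — mutated core modules from somatic mutations, CNVs and expression

`coremod` identifies *mutated core modules* in tumor cohorts: small gene sets
that are altered in many patients, mutually exclusively, and whose mutations
measurably perturb the transcriptome.  It is aimed at cancer-genomics
analysts who have per-sample somatic mutation calls, gene-level copy-number
significance calls and a normalised expression matrix, and who want de-novo
candidate driver pathways without using any protein-interaction network or
pathway database.

## Method

Somatic and CNV calls are OR-merged over common samples into a binary
mutation matrix **A** (samples × genes); genes altered in exactly the same
samples collapse into *metagenes*.  Two vertex- and edge-weighted networks
are built over the filtered gene set *G* (genes whose mutation status splits
the common samples into groups of ≥ 2):

* mutation network: vertex weight `h_i = m_i / m` (coverage) and edge weight
  `v_ij = #(exactly one of i,j altered) / #(at least one altered)`
  (mutual exclusivity);
* expression network: vertex weight `f_i = 1 − (1/d) Σ_r p_r`, where `p_r`
  is the two-sample t-test p-value of expression gene *r* between carriers
  and non-carriers of *i* (transcriptome-wide influence), and edge weight
  `u_ij = |Pearson(e_i, e_j)|` on mutation-ordered expression vectors.

They are combined into one integrative network with

```
w_ij = δ·u_ij + v_ij ,   c_i = δ·ξ·f_i + η·h_i ,
ξ = u/f ,  η = v/h ,  δ = k·v/u        (f, u, h, v = weight maxima; k = 1)
```

Coherent subnetworks maximise `x'Wx + λ c'x` subject to `Σ x_i^β = 1`,
`x ≥ 0` (λ = 1, β = 1), solved by the multiplicative update

```
x_i ← x_i · (2(Wx)_i + λc_i) / (2 x'Wx + λ c'x)
```

whose support (entries > 0.1) is the candidate module.  Candidates are
certified by two permutation tests: **p1** compares the module's summed
vertex+edge weight against random same-size vertex sets, and **p2** compares
its sample coverage against switching permutations of **A** (margin-
preserving 2×2 swaps; with per-gene alteration counts fixed, high coverage ⇔
exclusivity).  Non-exclusive modules are reduced by repeatedly dropping the
smaller-`x` member of the least-exclusive pair.  Certified modules are
removed from the network and extraction repeats.

## Worked example

```bash
python examples/03_extract_core_modules.py
```

prints, for a seeded synthetic cohort of 100 samples × 50 genes with one
planted strictly exclusive 3-gene module at 60% coverage:

```
mutated core module report
  units in network |G|: 29  (|G0|=41, collapsed units=41, |S|=100)
  certified modules: 1
  module 1: g000, g001, g002 | coverage 60/100 | p1 < 0.001 | p2 < 0.001

extraction rounds (candidates before testing):
      certified: g000, g001, g002
    rejected_p1: g007, g029, g046, g048

best Jaccard vs the planted module: 1.00 (1.0 = exact recovery)
```

The planted trio is recovered exactly: it covers 60 of 100 samples, none of
1000 random 3-gene sets is heavier (p1 < 0.001), and none of 1000
margin-preserving permutations reaches its coverage (p2 < 0.001).  The next
candidate fails the significance test, so extraction stops.

The same analysis from the shell:

```bash
coremod simulate --out data --seed 11
coremod run --somatic data/somatic.tsv --cnv data/cnv.tsv \
            --expression data/expression.tsv --out results --seed 11
coremod test-module --somatic data/somatic.tsv --cnv data/cnv.tsv \
            --expression data/expression.tsv --genes g000,g001,g002
```

`coremod networks` exports the weighted networks as TSV/GraphML.  Inputs are
tab-separated matrices (first column sample labels, first row gene labels);
binary for the two call sets, real-valued for expression.

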