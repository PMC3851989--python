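# Methods

## Model

The package treats driver-pathway discovery as weighted-subnetwork
extraction on a gene graph whose weights encode the four signatures expected
of a mutated core module: high coverage, mutual exclusivity of alterations,
strong transcriptome-wide influence of each member's mutation, and
correlated mutation-ordered expression.  No prior pathway or interaction
knowledge enters; every weight is computed from the cohort itself.

### Matrices

Somatic calls and gene-level CNV significance calls are OR-merged over their
common samples into the binary matrix A (a gene is "altered" in a sample if
either source says so).  Columns with identical alteration patterns are
indistinguishable to every downstream statistic and are collapsed into
metagenes (label = member labels joined with "/"); all-zero columns are
dropped.  Collapsing composes membership maps and is idempotent.  Collapsing
runs on the full mutation-sample set, before intersecting with expression
samples; the common samples S are the sorted intersection and define the
canonical sample order for all vectors.

The expression matrix B is consumed as-is and assumed already normalised;
only its statistical structure (mean shifts under mutation, correlated
profiles) is used.

### Network weights

For unit *i* with `n_i(1) ≥ 2` carriers and `n_i(2) ≥ 2` non-carriers in S:

* `h_i = m_i/m` — coverage over **all** samples of A (not only S), since
  alteration frequency is defined by the mutation data alone.  A
  configuration flag restricts to S for a strict-intersection variant.
* `v_ij` — #(exactly one altered)/#(at least one altered) over A's rows;
  pairs never altered get 0.
* `f_i = 1 − mean_r(p_r)` over all d expression genes, where `p_r` is the
  two-sided pooled-variance two-sample t-test p-value for gene *r* between
  carriers and non-carriers of *i* (Welch available as an option).  Genes
  with zero variance in both groups carry no evidence and contribute
  `p_r = 1`.  For a null unit `f_i ≈ 0.5` (uniform p-values average 0.5);
  only differences above that baseline are informative.
* `u_ij = |Pearson(e_i, e_j)|`, where `e_i` is unit *i*'s expression over S
  reordered carriers-first (canonical order within blocks) and the two
  reordered vectors are correlated positionally.  This takes the
  mutation-ordered construction literally; since reordering two vectors by
  *different* permutations changes their correlation, the plain
  sample-aligned correlation is available as `edge_mode="plain"`.  Constant
  vectors yield 0.  Metagenes use their collapsed column on the mutation
  side and the member-averaged expression profile (members lacking
  expression data are ignored and logged) on the expression side.

### Integration

With `f, u, h, v` the maxima of the four weight families, `ξ = u/f` and
`η = v/h` put vertex and edge weights on a common scale within each network,
and `δ = k·v/u` balances the two networks; `k` (default 1) up-weights the
mutation network relative to expression (`k = 2` reproduces the
mutation+expression-only variant that trusts expression less).  Then
`w_ij = δ·u_ij + v_ij` and `c_i = δ·ξ·f_i + η·h_i`.  A zero maximum in any
family is a degenerate input and raises an error.  `network_source`
switches between `full`, `mutation_only` (δ = 0) and `no_cnv` (somatic
calls only) modes.

## Optimisation

Modules maximise `x'Wx + λ·c'x` on the simplex `Σ x_i^β = 1, x ≥ 0`
(λ = 1, β = 1; β = 1 yields sparse supports, β = 2 is accepted but only
exercised by invariants).  The multiplicative update

    x_i ← [ x_i (2(Wx)_i + λc_i) / (2x'Wx + λc'x) ]^(1/β)

is a growth transform of a polynomial with non-negative coefficients, so for
β = 1 the iterate stays exactly on the simplex, zeros stay zero, and the
objective never decreases; both properties are asserted in the tests
(simplex to 1e−12, monotonicity to 1e−9).

Choices the procedure leaves open, fixed here and configurable:

* initialisation uniform `x = 1/n` (random restarts with recorded seed
  available; the best local optimum by objective is kept);
* convergence when `max_i |Δx_i| < 1e−10`, cap 10 000 iterations — the
  update is cheap and a tight tolerance stabilises the cutoff-based support;
  non-convergence returns a flagged result with a warning, not an error;
* support read-off at `x_i > 0.1`;
* on exactly symmetric instances the uniform start is a symmetric fixed
  point; an optional support-size bound triggers one seeded ε-perturbed
  re-solve;
* extraction loop: solve → extract → test → remove the candidate's vertices
  (certified or not) → repeat; stops when fewer than two vertices remain, no
  entry clears the cutoff, or — by default — the first candidate fails the
  weight-sum significance test.  Singleton candidates are discarded without
  testing (exclusivity needs at least a pair).  A pre-loop exclusion list
  supports removing dominant or artifact-prone genes (the use case being
  genes like TP53, mutated in most samples, or TTN, a known artifact
  magnet) before extraction.

## Statistical certification

**Weight-sum significance (p1).**  For a candidate with b units and weight
sum C (vertex weights plus unordered-pair edge weights), 1000 random b-sets
are drawn uniformly without replacement from the *original* integrative
network (not the current reduced one) and p1 is the fraction with sum
strictly exceeding C.  No pseudocount; a result of 0 is reported as
p < 0.001.

**Mutual exclusivity (p2).**  The observed statistic is the module's
coverage (samples with ≥ 1 altered member; the exactly-one variant is a
config option).  The null is the uniform distribution over binary matrices
with A's row and column sums, sampled by switching permutations: accepted
2×2 double-edge swaps, 10 per 1-entry of A per chain (the standard mixing
heuristic for bipartite swap chains), independent chains per permutation,
with a proposal cap so swap-free matrices terminate.  Chains permute the
full matrix; the statistic is evaluated on the module's columns (permuting
only those columns would be vacuous — swaps preserve row sums, hence
submatrix coverage).  With margins fixed, higher coverage is equivalent to
stronger exclusivity.  p2 counts permutations with statistic ≥ observed
(non-strict), so the test errs conservative.  On small matrices the
integer-valued statistic makes p2 noticeably conservative (type-I error
~0.02–0.03 at nominal 0.05 on 100-sample, 12-gene fixtures); the calibration
test therefore uses 600 × 20 matrices with per-gene rates 0.05–0.30, where
the null statistic is nearly continuous and the measured type-I error is
statistically consistent with the nominal level.  The test is never
anti-conservative.

**Reduction.**  A failing module with b > 2 units is shrunk one unit at a
time: take the pair with minimal `v_ij` (ties: lexicographic pair order) and
drop its member with the smaller solution entry x (ties: drop the
higher-coverage member, keeping the rarer, more specific unit; final ties go
against the later label).  Retest after each removal; stop at significance
or b = 2.  The trace of removals, with the implicated pair and entries, is
part of the module report.  Thresholds default to 0.05 for both tests.

All randomness derives from one seed; reports carry no timestamps, so a
fixed configuration reproduces byte-identical output.  The swap kernel is
numba-compiled for throughput; its semantics are plain double-edge swaps and
the margin-preservation tests exercise the compiled path directly.

## Synthetic benchmark

The generator emulates the joint structure the pipeline targets.  Defaults
are the benchmark conditions used across the tests: 100 samples, 50 genes,
one strictly exclusive 3-gene module covering 60% of samples (covered
samples partitioned randomly among members, each member guaranteed at least
one), passenger mutations i.i.d. Bernoulli(0.02) on non-planted columns
(planted margins stay exact), a 1.5-SD expression shift in 10 influenced
genes per driver, within-module expression correlation 0.5 via a shared
per-module latent factor, unit noise SD.  Alterations are split at random
between the somatic and CNV outputs so the OR-merge reconstructs them;
optional metagene pairs force identical columns.  Everything is
deterministic per seed, and the emitted ground truth records realised (not
target) patterns.

What the generator does **not** model: mutational signatures, CNV segment
geometry, sample purity, expression-normalisation artifacts, or
heavy-tailed expression noise.  Passing the recovery benchmark therefore
shows the pipeline recovers clean planted structure at realistic sizes, not
that it is robust to every property of real tumor cohorts.

### Known behaviour at benchmark scale

With 100 samples and a 2% passenger rate, any two rare passengers are almost
always perfectly exclusive (`v = 1`), so edge weights cannot separate
passengers from drivers — only coverage and influence can, and both are
weak for genes with 2–3 alterations.  Two consequences, both verified to be
properties of the model's true optimum rather than optimiser failures
(multi-restart solves and restricted-subnetwork solves find the same
optima): the optimal module occasionally includes one exclusive passenger
whose entry lands just above the 0.1 cutoff, and occasionally drops a
planted member whose mutation-ordered correlation edges happen to be weak.
Exact first-module recovery under the default benchmark is roughly 70–80%
of seeds, with the remainder recovering the module up to one extra or one
missing gene (Jaccard 3/4 or 2/3); `scripts/acceptance.py` reports the
measured rate.

## Limitations

* The optimisation is local; sequential extraction with vertex removal is a
  greedy decomposition and offers no global guarantee.
* p1 draws random vertex sets from the original network even in later
  rounds, so later p-values are conservative relative to the shrunken
  network.
* The mutation-ordered `u_ij` is kept for fidelity to the construction it
  implements, but it mixes signal with alignment noise; `edge_mode="plain"`
  is the statistically cleaner alternative when correlation per se is of
  interest.
* No multiple-testing correction is applied across modules, matching the
  certification procedure implemented.
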