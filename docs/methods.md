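# Methods

## Model and threat setting

The package targets the standard outsourcing triangle: a *data owner*
who holds per-SNP allele counts from a case-control cohort, an
untrusted *cloud* that evaluates the chi-square circuit on encrypted
values, and an *authorized user* who decrypts the released result.  The
cloud is assumed semi-honest: it follows the protocol but may inspect
everything it sees.  Accordingly the code enforces a structural
separation — the cloud-phase functions accept ciphertexts only and have
no decryption capability (this is asserted by a test that walks their
ASTs for decryption calls).

Encryption itself is **simulated**.  A `CipherVec` is a vector of
residues mod a prime p with SIMD slot semantics (aligned slot-wise add,
subtract, multiply; plaintext-scalar multiply/add; no rotations, which
the circuits never need).  The simulation layer meters every operation
and tracks multiplicative depth, so circuit costs can be asserted
analytically, but it provides no confidentiality and models no noise:
depth is the proxy for the modulus-chain budget a leveled scheme (BGV
et al.) would need; the scheme's own parameters (security level, key
sizes, key switching) are out of scope, as are wall-clock timings.

### Cost conventions

* `hm_count` — ciphertext×ciphertext multiplications, the expensive
  operation both protocols minimize.
* `pm_count` — plaintext-scalar multiplications, metered separately and
  free of depth.  The polynomial coefficients and 4n are publicly
  computable, so a real implementation can replace these products by
  repeated additions; the analytic HM budgets below count only
  ciphertext products, and the meter follows that convention.
* `ha_count` — ciphertext and plaintext-constant additions/subtractions.
* `max_depth` — the longest chain of sequential ciphertext
  multiplications (cumulative circuit depth).

## Exact statistic

For a biallelic SNP with observed allele counts O₁₁, O₁₂ (case) and
O₂₁, O₂₂ (control), the four-cell statistic Σ (O−E)²/E with
E_ij = (column total)·N_i/(N₁+N₂) is computed in exact rational
arithmetic and equals, when N₁ = N₂ = 2n,

    χ² = 4n(O₁₁−O₂₁)² / [s(4n−s)],   s = O₁₁+O₂₁.

The identity is verified exhaustively for n ≤ 10 and on random larger
tables; `chi2_general` is additionally cross-checked against the
uncorrected contingency test in scipy.  P-values use the 1-df
chi-square survival function.  Monomorphic SNPs (s ∈ {0, 4n}) have a
zero denominator and no defined statistic; the data owner filters them
before encryption — they are flagged in the results and excluded from
accuracy metrics, never silently dropped.

## Errorless division

Dividend m ∈ [0, m̄] and divisor w ∈ [1, w̄] are mapped to
F(m, w) = m·w^(p−2) mod p.  With p prime and > m̄·w̄ the map is
injective on irreducible fractions (both directions are tested
exhaustively up to m̄ = w̄ = 30), so a lookup table built over all
coprime pairs in range decodes the exact rational.  The table is built
in plaintext (it depends only on public bounds and p), verified
collision-free at build time, and serialized as a two-column TSV.

The encrypted evaluation is square-and-multiply over the bits of p−2:
⌊log₂(p−2)⌋ squarings plus one multiplication per set bit, i.e.
exactly ⌊log₂(p−2)⌋ + popcount(p−2) HMs (10 at p = 101).  One indexing
convention had to be fixed: writing p−2 = Σ_{i=0}^{h} 2^{v_i}, the
symbol h counts set bits *minus one* (h+1 set bits in total); under
this reading the analytic total 1 + h + ⌊log₂(p−2)⌋ is exact, and the
depth never exceeds it.

Zero dividends are admitted and decode through the 0/1 entry; zero
divisors are rejected at encryption time.

For chi-square use, the numerator 4n·A ≤ 16n³ and denominator B ≤ 4n²
would naively demand p > 64n⁵ and a table of ~10¹³ fractions at
n = 200.  The table is therefore restricted to *feasible* pairs — the
O(n²) fractions actually reachable from count pairs (O₁₁, O₂₁) — and
the default modulus is the smallest prime above 16n³·4n².  A smaller
user-supplied modulus is accepted exactly when the build-time
injectivity verification of the feasible table passes; an observed
collision raises a modulus-too-small error.

## Approximate division

Given a public scale M < p, the targets t_i = ⌊M/B_i⌋ over the node
set B_i = i(4n−i), i = 1..2n, define a unique interpolating polynomial
of degree 2n−1 over **Z**_p.  Nodes and targets are computed in exact
unbounded integers before reduction; interpolation denominators become
Fermat inverses (they exist because every difference is a nonzero
residue).  Coefficient expansion is O(k²): the full product Π(x−B_l)
is built once and each per-node factor recovered by synthetic
division, which matters at k = 400.  Off the node set the polynomial
is defined but meaningless — feasibility is the caller's contract, and
is enforced pre-encryption in the pipeline.

Encrypted evaluation splits the coefficients into C groups of d:

    f(x) = Σ_{c=0}^{C−1} x^{cd} · Σ_{i=0}^{d−1} h_{cd+i} x^i

with baby steps 1..x^d and giant steps (x^d)^0..(x^d)^{C−1} both from
a binary-tree product (x^i = x^{l1}·x^{l2} with l1 the largest power
of two below i), costing exactly d−1 and C−2 HMs and depth ⌈log₂ d⌉ /
⌈log₂(C−1)⌉.  The c = 0 outer term is added directly (its giant step
is the trivial 1), so one grouped division costs exactly d + 2C − 4
HMs.  The published line-by-line budget totals 2C + d − 3 — one more
than the lines sum to — so the tests assert the printed total as an
upper bound while the meter records the exact count.  The depth bound
⌊log₂(C−2)⌋ + ⌊log₂(d−1)⌋ + 3 is asserted for C ≥ 3, d ≥ 2; degenerate
plans (d ≤ 1 or C ≤ 2), where the log formulas lose meaning, fall back
to a single-group sum over the full power basis.

### Group-size selection

The HM count behaves like F(d) = d + 2(2n−1)/d − 3, minimized at
d = √(2(2n−1)).  `choose_group_params` compares the two integers
bracketing that square root under the *exact rational* F (ties to the
smaller d) and sets C = ⌊(2n−1)/d⌋ + 1; for n = 200 this yields
(d, C) = (28, 15).  A discretized objective (replacing 2(2n−1)/d by
its floor) would pick d = 29 here — the continuous form is the one
this package treats as definitional, because it reproduces the
reference parameterization.  A brute-force sweep over all group sizes
can beat the square-root rule by at most one HM (verified for
n ≤ 50); the rule is kept for its closed form.

### Accuracy contract

The released value is A·⌊M/B⌋, so the reconstructed statistic
4n·A·⌊M/B⌋/M underestimates χ² by the relative factor
1 − B⌊M/B⌋/M ≤ B/M ≤ 4n²/M.  Over the feasible region max A/B = 1
(the statistic's maximum is 4n), hence A·⌊M/B⌋ ≤ M < p and the release
never wraps; this is why M defaults to p−1 when only p is given.  When
neither is given the pipeline picks M = 4n²·10⁶ — a 10⁻⁶ relative
error budget — and p as the smallest prime above M.  The bound is
checked exhaustively at n = 10 and on the cohort-scale synthetic panel
(n = 200, M = 25.6×10⁹, bound 6.25×10⁻⁴ %).

## Parallelism and the pipeline

All circuits are slot-parallel: S SNPs are packed into ⌈S/L_s⌉
ciphertext batches (default L_s = 864, which holds a 311-SNP panel in
one batch), and results are invariant to the batch split (tested).
`run_pipeline` stages the three roles explicitly, logs the effective
(p, M, d, C, L_s) and the error bound, and emits a results TSV plus a
cost-report JSON.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
equal groups of n individuals, per-SNP minor-allele frequency q drawn
uniformly from [0.05, 0.5], genotypes Binomial(2, q) under
Hardy-Weinberg equilibrium, and a fraction of associated SNPs whose
case-group frequency is shifted by a fixed delta (clipped below 1).
Defaults — 311 SNPs, n = 200, 8% associated, delta = 0.15 — mirror the
shape and signal density of the challenge panel this workload
originates from (311 SNPs with ≈24 hits at the 0.05 cutoff).  A direct
count-level null generator (O₁₁, O₂₁ ~ Binomial(2n, q), shared q)
calibrates the type-I error of the exact test at scale.

What the generator does *not* model: linkage disequilibrium,
population structure, relatedness, genotyping error, missingness.
Passing tests therefore demonstrate correctness of the circuits and
the accuracy contract of the division protocols on realistic count
distributions — not robustness of the chi-square test itself to the
confounders real cohorts carry.

## Numerical and design choices

* All residues are canonicalized to [0, p−1]; subtraction wraps and is
  repaired where algebra guarantees it (e.g. (p−x)² ≡ x² with the true
  square < p for the numerator A).
* Exact rational arithmetic (`fractions.Fraction`) wherever a quantity
  is exact by construction: lookup decoding, the equal-group statistic,
  the rescaling 4n·val/M.  Floats appear only at the reporting surface.
* Primality and next-prime selection delegate to sympy (deterministic
  for the 64-bit moduli used here); interpolation, inverses, and the
  protocols themselves are implemented in this package.
* Precision/recall against the exact statistic can legitimately differ
  from 1 only when an exact p-value lies within the protocol's error of
  a cutoff; `evaluate_accuracy` reports such boundary SNPs explicitly
  rather than hiding them in the aggregate.
* Genotype coding: a genotype value counts copies of allele 'a', so
  O₁₂ is the genotype sum over cases.  Flipping the coding permutes
  table columns and leaves the statistic unchanged (tested).
* Missing genotypes are rejected, not imputed: the equal-totals
  identity N₁ = N₂ = 2n assumes complete data.

## Problem sizes

The test suite runs its exhaustive oracles at desk scale by choice:
errorless round trips to bounds of 30, divisor-set oracles to n = 20,
identity checks to n = 10 exhaustively, and the full encrypted cohort
pipeline at the published cohort-scale parameters (311 SNPs, n = 200,
400-node interpolation) — the whole suite completes in seconds.

## Known limitations

* The simulation proves nothing about confidentiality; serialized
  ciphertexts are labeled as simulation output and are plaintext.
* The approximate protocol is only exact on the precomputed divisor
  node set; it is not a general encrypted division.
* Errorless division at chi-square scale relies on the feasible-pair
  restriction; for workloads whose fraction set is not enumerable the
  protocol does not scale.
* Unequal group sizes are supported in plaintext analysis only; the
  encrypted pipelines require N₁ = N₂ = 2n.
* The transmission-disequilibrium extension for family-based designs
  is not implemented.
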