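# foresee-gwas

Fully outsourced secure chi-square association testing for case-control
GWAS, over a metered simulated homomorphic-encryption (HE) layer.

## The problem

In a genome-wide association study, each SNP is tested for an allele-
frequency difference between a case and a control group via a 2×2
contingency table and the chi-square statistic.  Outsourcing this to an
untrusted cloud under homomorphic encryption runs into one specific
wall: leveled HE schemes support addition and multiplication in a
residue ring **Z**_p, but not division — and the statistic is a ratio.
Releasing numerator and denominator separately leaks the underlying
allele counts, so the division itself must happen under encryption.

For equal groups of *n* individuals (allele totals N₁ = N₂ = 2n) the
four-cell statistic collapses to a single division:

    χ² = 4n · (O₁₁ − O₂₁)² / [ (O₁₁ + O₂₁) · (4n − (O₁₁ + O₂₁)) ]

with integer numerator A = (O₁₁ − O₂₁)² and denominator
B = s(4n − s), s = O₁₁ + O₂₁.  This package implements two protocols
that finish the division in the encrypted domain:

* **Errorless division.**  Release the single residue
  F(m, w) = m·w^(p−2) mod p (the Fermat-inverse product).  For a prime
  p > m̄·w̄ this map is injective on irreducible fractions, so an
  authorized user decodes the *exact* rational m/w from a precomputed
  lookup table — and learns only the reduced fraction, never (m, w).
* **Approximate division.**  Release A·⌊M/B⌋ for a public scale M < p.
  Since B only takes the 2n values B_i = i(4n − i), a degree-(2n−1)
  polynomial interpolated over **Z**_p (Lagrange nodes B_i, targets
  ⌊M/B_i⌋, denominators replaced by Fermat inverses) computes ⌊M/B⌋
  exactly on the feasible set.  Then χ² ≈ 4n·A·⌊M/B⌋/M with relative
  error at most 4n²/M (i.e. 400n²/M %).  Evaluation is grouped
  baby-step/giant-step with a binary-tree power basis: d + 2C − 4
  ciphertext multiplications at group size d ≈ √(2(2n−1)),
  C = ⌊(2n−1)/d⌋ + 1 groups — e.g. (d, C) = (28, 15) at n = 200.

Ciphertexts here are **simulated**: vectors of residues mod p with SIMD
slot semantics, a multiplicative-depth tracker, and counters for every
homomorphic operation.  The artifact validates circuits, exactness, and
cost budgets; it provides no confidentiality itself.

## Worked example

```bash
python examples/01_errorless_division.py
```

```
modulus p = 101; lookup table holds 64 irreducible fractions
  4/3: released residue u =  35 -> decoded 4/3 (exactly 1.333333)
  2/1: released residue u =   2 -> decoded 2 (exactly 2.000000)
  8/4: released residue u =   2 -> decoded 2 (exactly 2.000000)
circuit cost: 10 homomorphic multiplications, depth 7
```

With bounds m̄ = w̄ = 10 the modulus is 101 (least prime above 100).
The pair (4, 3) maps to 4·3⁹⁹ ≡ 35 (mod 101) and decodes back to the
exact fraction 4/3; (2, 1) and (8, 4) collide at residue 2 by design —
equivalent fractions are indistinguishable after release.  The
square-and-multiply circuit costs ⌊log₂ 99⌋ + popcount(99) = 10
ciphertext multiplications.

The other examples run the approximate division on its full node set
(`02`), both encrypted chi-square pipelines against the exact statistic
on hand-made SNPs (`03`), and a 311-SNP, n = 200 synthetic cohort under
the cohort-scale parameters p = 25600000039, M = 25600000000 (`04`),
reporting MSE ≈ 4×10⁻¹⁰, a maximum statistic error ≈ 1.5×10⁻⁴, and
precision = recall = 1 at p-value cutoffs 0.05/0.01/0.005.

A thin CLI wraps the same library calls:

```bash
foresee simulate --snps 311 --n 200 --seed 7 --out geno.tsv
foresee counts --genotypes geno.tsv --out counts.tsv
foresee chi2 --mode approx --in counts.tsv --out results.tsv --cost-report cost.json
foresee report --exact exact.tsv --protocol results.tsv
```

## Layout

| Path | Contents |
| --- | --- |
| `src/foresee/modmath.py` | prime selection, Fermat inverses, Lagrange interpolation over **Z**_p |
| `src/foresee/he_sim.py` | slot-batched simulated ciphertexts + cost metering |
| `src/foresee/errorless_div.py` | Fermat mapping, lookup-table build/decode |
| `src/foresee/approx_div.py` | division plans, binary-tree powers, grouped evaluation |
| `src/foresee/gwas_chi2.py` | allele counting, exact/encrypted chi-square, accuracy metrics |
| `src/foresee/synthdata.py` | seeded synthetic case-control cohorts |
| `src/foresee/io.py`, `cli.py` | TSV/VCF formats, config, pipeline phases, CLI |
| `docs/methods.md` | model, parameters, numerical choices, limitations |
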