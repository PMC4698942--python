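"""Case-control chi-square association testing, plaintext and encrypted.

Per SNP, allele counts form a 2x2 table (alleles A/a by case/control).
With equal group sizes n the classical statistic

    chi2 = sum (O_ij - E_ij)^2 / E_ij

collapses to the single-division form

    chi2 = 4n * (O11 - O21)^2 / [ (O11 + O21) * (4n - (O11 + O21)) ],

whose numerator A = (O11 - O21)^2 and denominator
B = (O11 + O21)(4n - (O11 + O21)) are integers computable from the two
encrypted counts with additions and multiplications.  The two encrypted
pipelines differ only in how they divide:

* approximate: release A * floor(M/B) via the interpolated integer
  division, so chi2 ~= 4n * A * floor(M/B) / M with relative error at
  most B/M <= 4n^2/M (the published bound, 400 n^2 / M per cent);
* errorless: release the Fermat mapping of the exact fraction
  4n*A / B and decode it against a feasible-pair lookup table.

The cloud-phase functions (``cloud_*``) accept ciphertexts only and
never see a decryption capability; the convenience wrappers around them
play the data-owner and authorized-user roles.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .approx_div import ApproxDivPlan, secure_integer_divide
from .errorless_div import FractionLookup, decode, secure_map
from .exceptions import InputError, ModulusTooSmallError, ParameterError
from .he_sim import CipherVec, HESession, he_add, he_mul, he_sub, pt_add, pt_mul
from .modmath import smallest_prime_above

__all__ = [
    "SNPCounts",
    "Chi2Result",
    "AccuracyReport",
    "allele_count_table",
    "chi2_general",
    "chi2_equal_groups",
    "chi2_pvalue",
    "feasible_pairs",
    "build_chi2_lookup",
    "default_errorless_modulus",
    "cloud_chi2_approx",
    "cloud_chi2_errorless",
    "secure_chi2_approx",
    "secure_chi2_errorless",
    "evaluate_accuracy",
    "approx_relative_error_bound",
]

DEFAULT_CUTOFFS = (0.05, 0.01, 0.005)


@dataclass(frozen=True)
class SNPCounts:
    """Observed 2x2 allele counts for one SNP.

    O11/O12: counts of alleles A and a in cases; O21/O22: the same in
    controls.  N1, N2 are the per-group allele totals (2n each when the
    groups both contain n individuals).
    """

    snp_id: str
    o11: int
    o12: int
    o21: int
    o22: int

    def __post_init__(self):
        for v in (self.o11, self.o12, self.o21, self.o22):
            if v < 0:
                raise InputError(f"negative allele count in SNP {self.snp_id}")

    @property
    def n1(self) -> int:
        return self.o11 + self.o12

    @property
    def n2(self) -> int:
        return self.o21 + self.o22

    @property
    def monomorphic(self) -> bool:
        """True when one allele is absent from both groups combined."""
        return self.o11 + self.o21 == 0 or self.o12 + self.o22 == 0


@dataclass(frozen=True)
class Chi2Result:
    """Exact and (optionally) protocol-computed statistic for one SNP."""

    snp_id: str
    chi2_exact: float | None
    chi2_protocol: float | None
    pvalue: float | None
    monomorphic: bool


@dataclass(frozen=True)
class AccuracyReport:
    """Protocol-vs-exact agreement metrics over a SNP panel."""

    mse: float
    max_abs_error: float
    # cutoff -> (n_significant_exact, precision, recall)
    by_cutoff: dict[float, tuple[int, float, float]]
    # indices of SNPs whose exact p-value sits within boundary_tol of a cutoff
    boundary: dict[float, tuple[int, ...]]


def allele_count_table(
    genotypes: np.ndarray | Sequence[Sequence[int]],
    groups: Sequence[str],
    snp_ids: Sequence[str] | None = None,
) -> list[SNPCounts]:
    """Count alleles per SNP from a genotype matrix.

    ``genotypes`` is SNPs x individuals with entries in {0, 1, 2}
    counting copies of allele 'a'; ``groups`` labels each individual
    column as ``"case"`` or ``"control"``.  Missing genotypes are
    rejected: the equal-totals identity N1 = N2 = 2n that the encrypted
    pipelines rely on assumes complete data.
    """
    G = np.asarray(genotypes)
    if G.ndim != 2:
        raise InputError("genotype matrix must be 2-dimensional (SNP x individual)")
    if G.shape[1] != len(groups):
        raise InputError(
            f"{G.shape[1]} genotype columns but {len(groups)} group labels"
        )
    if not np.isin(G, (0, 1, 2)).all():
        bad = np.unique(G[~np.isin(G, (0, 1, 2))])
        raise InputError(
            f"genotypes must be 0/1/2 copies of allele 'a'; found {bad.tolist()}"
        )
    labels = np.asarray([str(g).lower() for g in groups])
    case = labels == "case"
    control = labels == "control"
    if not (case | control).all():
        raise InputError("group labels must be 'case' or 'control'")
    if case.sum() == 0 or control.sum() == 0:
        raise InputError("both case and control groups must be nonempty")
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(G.shape[0])]

    o12 = G[:, case].sum(axis=1)          # copies of 'a' among cases
    o22 = G[:, control].sum(axis=1)
    o11 = 2 * int(case.sum()) - o12       # copies of 'A'
    o21 = 2 * int(control.sum()) - o22
    return [
        SNPCounts(str(sid), int(a), int(b), int(c), int(d))
        for sid, a, b, c, d in zip(snp_ids, o11, o12, o21, o22)
    ]


def chi2_general(t: SNPCounts) -> float:
    """The four-cell statistic for arbitrary group sizes (plaintext).

    E_ij = (column total j) * N_i / (N1 + N2); raises on monomorphic
    tables where an expected count vanishes.
    """
    n1, n2 = t.n1, t.n2
    total = n1 + n2
    if total == 0:
        raise InputError(f"SNP {t.snp_id}: empty table")
    obs = [[t.o11, t.o12], [t.o21, t.o22]]
    col = [t.o11 + t.o21, t.o12 + t.o22]
    row = [n1, n2]
    acc = Fraction(0)
    for i in range(2):
        for j in range(2):
            e = Fraction(col[j] * row[i], total)
            if e == 0:
                raise ParameterError(
                    f"SNP {t.snp_id} is monomorphic: expected count is zero"
                )
            acc += Fraction((obs[i][j] - e) ** 2, 1) / e
    return float(acc)


def chi2_equal_groups(o11: int, o21: int, n: int) -> Fraction:
    """Exact single-division statistic for equal groups of n patients.

    Returns the exact rational 4n(O11-O21)^2 / [s(4n-s)] with
    s = O11 + O21; identical to :func:`chi2_general` whenever
    N1 = N2 = 2n.
    """
    if not (0 <= o11 <= 2 * n and 0 <= o21 <= 2 * n):
        raise InputError(f"counts ({o11}, {o21}) outside [0, 2n] for n={n}")
    s = o11 + o21
    if s == 0 or s == 4 * n:
        raise ParameterError("monomorphic SNP: chi-square denominator is zero")
    return Fraction(4 * n * (o11 - o21) ** 2, s * (4 * n - s))


def chi2_pvalue(x: float) -> float:
    """Upper-tail probability of the 1-df chi-square distribution."""
    if x < 0:
        raise InputError(f"chi-square statistic must be >= 0, got {x}")
    return float(stats.chi2.sf(x, df=1))


def approx_relative_error_bound(n: int, M: int) -> float:
    """Worst-case relative error of the approximate statistic, as a fraction.

    1 - B*floor(M/B)/M <= B/M <= 4n^2/M (the largest feasible divisor
    is B = 4n^2).  Multiply by 100 for the percentage form 400n^2/M %.
    """
    return 4 * n * n / M


def feasible_pairs(n: int) -> Iterable[tuple[int, int]]:
    """All non-monomorphic (O11, O21) count pairs for group size n."""
    for o11 in range(2 * n + 1):
        for o21 in range(2 * n + 1):
            s = o11 + o21
            if 0 < s < 4 * n:
                yield o11, o21


def default_errorless_modulus(n: int) -> int:
    """Smallest prime guaranteeing injective decoding at statistic scale.

    The numerator 4n(O11-O21)^2 is at most 16n^3 and the denominator at
    most 4n^2, so any prime above their product keeps the Fermat mapping
    one-to-one on every feasible fraction.
    """
    return smallest_prime_above(16 * n**3 * 4 * n**2)


def build_chi2_lookup(n: int, p: int | None = None) -> FractionLookup:
    """Decode table for the errorless chi-square pipeline.

    Restricted to *feasible* numerator/denominator pairs — those
    reachable from actual count pairs (O11, O21) — rather than all
    fractions below the worst-case bounds, which keeps the table at
    O(n^2) entries.  Injectivity is verified entry by entry, so a
    user-supplied modulus smaller than :func:`default_errorless_modulus`
    is accepted exactly when it decodes unambiguously.
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if p is None:
        p = default_errorless_modulus(n)
    table: dict[int, Fraction] = {}
    for o11, o21 in feasible_pairs(n):
        s = o11 + o21
        num = 4 * n * (o11 - o21) ** 2
        den = s * (4 * n - s)
        u = num % p * pow(den, p - 2, p) % p
        frac = Fraction(num, den)
        prev = table.get(u)
        if prev is not None and prev != frac:
            raise ModulusTooSmallError(
                f"modulus {p} cannot distinguish chi-square values "
                f"{prev} and {frac} (both map to {u})"
            )
        table[u] = frac
    return FractionLookup(m_max=16 * n**3, w_max=4 * n**2, p=p, table=table)


# ---------------------------------------------------------------------------
# Cloud phase: ciphertexts in, ciphertexts out.  No decryption here.
# ---------------------------------------------------------------------------

def _numerator_denominator(
    o11_ct: CipherVec, o21_ct: CipherVec, n: int
) -> tuple[CipherVec, CipherVec]:
    """A-hat = (O11-O21)^2 and B-hat = s(4n-s) from encrypted counts.

    The subtraction wraps mod p, but squaring repairs it:
    (p-x)^2 = x^2 (mod p) and the true square is below p, so the slot
    holds the genuine integer A.  Costs 2 HMs and depth 1.
    """
    p = o11_ct.p
    diff = he_sub(o11_ct, o21_ct)
    a_hat = he_mul(diff, diff)
    s = he_add(o11_ct, o21_ct)
    s_compl = pt_add(pt_mul(s, p - 1), 4 * n)  # 4n - s mod p
    b_hat = he_mul(s, s_compl)
    return a_hat, b_hat


def cloud_chi2_approx(
    o11_ct: CipherVec, o21_ct: CipherVec, n: int, plan: ApproxDivPlan
) -> CipherVec:
    """Encrypted approximate statistic: releases A * floor(M/B) per slot."""
    a_hat, b_hat = _numerator_denominator(o11_ct, o21_ct, n)
    q_hat = secure_integer_divide(b_hat, plan)
    return he_mul(a_hat, q_hat)


def cloud_chi2_errorless(
    o11_ct: CipherVec, o21_ct: CipherVec, n: int
) -> CipherVec:
    """Encrypted errorless statistic: releases the Fermat mapping of
    the exact fraction 4n*A / B per slot."""
    a_hat, b_hat = _numerator_denominator(o11_ct, o21_ct, n)
    num = pt_mul(a_hat, 4 * n)
    return secure_map(num, b_hat)


# ---------------------------------------------------------------------------
# End-to-end wrappers (data owner encrypts, cloud computes, user decodes)
# ---------------------------------------------------------------------------

def _check_feasible(o11s: Sequence[int], o21s: Sequence[int], n: int) -> None:
    for o11, o21 in zip(o11s, o21s):
        if not (0 <= o11 <= 2 * n and 0 <= o21 <= 2 * n):
            raise InputError(f"counts ({o11}, {o21}) out of range for n={n}")
        if o11 + o21 in (0, 4 * n):
            raise ParameterError(
                f"monomorphic pair ({o11}, {o21}) must be filtered before "
                f"encryption: its divisor is outside the node set"
            )


def secure_chi2_approx(
    o11s: Sequence[int],
    o21s: Sequence[int],
    n: int,
    plan: ApproxDivPlan,
    session: HESession | None = None,
    snp_ids: Sequence[str] | None = None,
) -> list[Chi2Result]:
    """Run the approximate pipeline on feasible count pairs.

    Encrypts the two count vectors, runs :func:`cloud_chi2_approx`, and
    rescales the released integer: chi2 ~= 4n * A*floor(M/B) / M.
    """
    if len(o11s) != len(o21s):
        raise InputError("count vectors must have equal length")
    _check_feasible(o11s, o21s, n)
    if session is None:
        session = HESession(plan.p, n_slots=max(len(o11s), 1))
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(len(o11s))]
    released = session.decrypt(
        cloud_chi2_approx(session.encrypt(o11s), session.encrypt(o21s), n, plan)
    )
    out = []
    for sid, o11, o21, val in zip(snp_ids, o11s, o21s, released):
        exact = chi2_equal_groups(o11, o21, n)
        approx = float(Fraction(4 * n * val, plan.M))
        out.append(
            Chi2Result(
                snp_id=str(sid),
                chi2_exact=float(exact),
                chi2_protocol=approx,
                pvalue=chi2_pvalue(approx),
                monomorphic=False,
            )
        )
    return out


def secure_chi2_errorless(
    o11s: Sequence[int],
    o21s: Sequence[int],
    n: int,
    p: int | None = None,
    lookup: FractionLookup | None = None,
    session: HESession | None = None,
    snp_ids: Sequence[str] | None = None,
) -> list[Chi2Result]:
    """Run the errorless pipeline: the decoded statistic is exact."""
    if len(o11s) != len(o21s):
        raise InputError("count vectors must have equal length")
    _check_feasible(o11s, o21s, n)
    if lookup is None:
        lookup = build_chi2_lookup(n, p)
    if session is None:
        session = HESession(lookup.p, n_slots=max(len(o11s), 1))
    elif session.p != lookup.p:
        raise ParameterError("session modulus does not match the lookup table")
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(len(o11s))]
    released = session.decrypt(
        cloud_chi2_errorless(session.encrypt(o11s), session.encrypt(o21s), n)
    )
    out = []
    for sid, o11, o21, u in zip(snp_ids, o11s, o21s, released):
        value = decode(u, lookup)
        out.append(
            Chi2Result(
                snp_id=str(sid),
                chi2_exact=float(chi2_equal_groups(o11, o21, n)),
                chi2_protocol=float(value),
                pvalue=chi2_pvalue(float(value)),
                monomorphic=False,
            )
        )
    return out


def evaluate_accuracy(
    exact: Sequence[float],
    protocol: Sequence[float],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    boundary_tol: float = 0.0,
) -> AccuracyReport:
    """Score protocol statistics against the exact ones.

    Returns the MSE and maximum absolute error between the two
    statistic vectors and, at each p-value cutoff, the precision and
    recall of the protocol's significant set against the exact one.
    SNPs whose exact p-value lies within ``boundary_tol`` of a cutoff
    are reported in ``boundary``: at those SNPs a correctly bounded
    approximation error can still legitimately flip significance.
    """
    if len(exact) != len(protocol):
        raise InputError("exact and protocol result lists must align")
    ex = np.asarray(exact, dtype=float)
    pr = np.asarray(protocol, dtype=float)
    err = pr - ex
    mse = float(np.mean(err**2)) if len(ex) else 0.0
    max_err = float(np.max(np.abs(err))) if len(ex) else 0.0
    p_ex = stats.chi2.sf(ex, df=1)
    p_pr = stats.chi2.sf(pr, df=1)
    by_cutoff: dict[float, tuple[int, float, float]] = {}
    boundary: dict[float, tuple[int, ...]] = {}
    for cut in cutoffs:
        sig_ex = p_ex < cut
        sig_pr = p_pr < cut
        tp = int(np.sum(sig_ex & sig_pr))
        precision = tp / int(np.sum(sig_pr)) if sig_pr.any() else 1.0
        recall = tp / int(np.sum(sig_ex)) if sig_ex.any() else 1.0
        by_cutoff[cut] = (int(np.sum(sig_ex)), precision, recall)
        boundary[cut] = tuple(
            int(i) for i in np.nonzero(np.abs(p_ex - cut) <= boundary_tol)[0]
        )
    return AccuracyReport(
        mse=mse, max_abs_error=max_err, by_cutoff=by_cutoff, boundary=boundary
    )
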