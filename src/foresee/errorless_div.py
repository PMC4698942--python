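"""Secure errorless division via a Fermat one-to-one mapping.

The protocol releases, for an encrypted dividend m in [0, m_max] and
divisor w in [1, w_max], the single residue

    F(m, w) = m * w**(p-2)  (mod p),

i.e. m times the Fermat inverse of w.  When the prime modulus satisfies
p > m_max * w_max this map is injective on *irreducible fractions*: two
pairs share a residue exactly when they reduce to the same fraction
m*/w*.  An authorized user therefore recovers the exact rational result
from a precomputed lookup table of all irreducible fractions in range,
while the released residue reveals only the reduced fraction, never the
operand pair itself.

In the encrypted domain the exponentiation is a square-and-multiply
circuit (repeated squaring of w-hat, then one multiplication per set
bit of p-2), costing ``floor(log2(p-2)) + popcount(p-2)`` homomorphic
multiplications.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from pathlib import Path

from .exceptions import InputError, ModulusTooSmallError, ParameterError
from .he_sim import CipherVec, he_mul

__all__ = [
    "FractionLookup",
    "map_fraction_plain",
    "secure_map",
    "build_fraction_lookup",
    "decode",
    "write_lookup_tsv",
    "read_lookup_tsv",
    "errorless_hm_count",
]


@dataclass(frozen=True)
class FractionLookup:
    """Decode table from mapped residue u to the irreducible fraction.

    ``table[u] == Fraction(m, w)`` for every residue that an in-range
    (dividend, divisor) pair can produce.  Injectivity is verified at
    build time; a collision means the modulus is too small.
    """

    m_max: int
    w_max: int
    p: int
    table: dict[int, Fraction]

    def __contains__(self, u: int) -> bool:
        return u in self.table

    def __len__(self) -> int:
        return len(self.table)


def map_fraction_plain(m: int, w: int, p: int) -> int:
    """Plaintext reference of the mapping: ``m * w**(p-2) mod p``."""
    if w % p == 0:
        raise ParameterError("divisor must be nonzero mod p")
    return m % p * pow(w % p, p - 2, p) % p


def errorless_hm_count(p: int) -> int:
    """Analytic HM cost of the mapping circuit for modulus ``p``."""
    e = p - 2
    return (e.bit_length() - 1) + bin(e).count("1")


def secure_map(
    m_ct: CipherVec,
    w_ct: CipherVec,
    m_max: int | None = None,
    w_max: int | None = None,
) -> CipherVec:
    """Square-and-multiply evaluation of F(m, w) on ciphertexts.

    Builds the squaring chain s_0 = w-hat, s_i = s_{i-1}^2 up to
    i = floor(log2(p-2)), then multiplies m-hat by s_{v} for every set
    bit position v of p-2.  Exactly
    ``floor(log2(p-2)) + popcount(p-2)`` HMs; depth at most
    ``floor(log2(p-2)) + popcount(p-2)``.

    When the bounds are supplied, the injectivity precondition
    p > m_max * w_max is checked; without them the caller is trusted.
    """
    p = m_ct.p
    if w_ct.p != p:
        raise ParameterError("dividend and divisor ciphertexts use different moduli")
    if m_max is not None and w_max is not None and p <= m_max * w_max:
        raise ParameterError(
            f"modulus {p} <= m_max*w_max = {m_max * w_max}: mapping not injective"
        )
    e = p - 2
    if e < 1:
        raise ParameterError(f"modulus {p} too small for the mapping")
    n_squarings = e.bit_length() - 1  # floor(log2(p-2))
    chain = [w_ct]
    for _ in range(n_squarings):
        chain.append(he_mul(chain[-1], chain[-1]))
    result = m_ct
    for v in range(e.bit_length()):
        if (e >> v) & 1:
            result = he_mul(result, chain[v])
    return result


def build_fraction_lookup(m_max: int, w_max: int, p: int) -> FractionLookup:
    """Enumerate all irreducible fractions in range and index them.

    Stores ``u = m* * (w*)**(p-2) mod p -> m*/w*`` for every coprime
    pair with 0 <= m* <= m_max, 1 <= w* <= w_max (zero is represented
    as 0/1).  Fails with :class:`ModulusTooSmallError` if two distinct
    fractions collide, which the injectivity result rules out whenever
    p > m_max * w_max.
    """
    if m_max < 0 or w_max < 1:
        raise InputError(f"bounds out of range: m_max={m_max}, w_max={w_max}")
    if p <= m_max * w_max:
        raise ParameterError(
            f"modulus {p} must exceed m_max*w_max = {m_max * w_max}"
        )
    table: dict[int, Fraction] = {}
    for w in range(1, w_max + 1):
        inv_w = pow(w, p - 2, p)
        for m in range(0, m_max + 1):
            if gcd(m, w) != 1:
                continue
            u = m * inv_w % p
            frac = Fraction(m, w)
            prev = table.get(u)
            if prev is not None and prev != frac:
                raise ModulusTooSmallError(
                    f"distinct fractions {prev} and {frac} both map to {u} "
                    f"under p={p}"
                )
            table[u] = frac
    return FractionLookup(m_max=m_max, w_max=w_max, p=p, table=table)


def decode(u: int, lut: FractionLookup) -> Fraction:
    """Recover the exact rational result from a mapped residue."""
    try:
        return lut.table[u]
    except KeyError:
        raise InputError(
            f"residue {u} is not in the decode table: the ciphertext did not "
            f"arise from dividends <= {lut.m_max} and divisors <= {lut.w_max}"
        ) from None


def write_lookup_tsv(lut: FractionLookup, path: str | Path) -> None:
    """Serialize the table as sorted two-column TSV (u, ``m*/w*``)."""
    with open(path, "w") as fh:
        fh.write(f"# errorless-division lookup: m_max={lut.m_max} "
                 f"w_max={lut.w_max} p={lut.p}\n")
        fh.write("u\tfraction\n")
        for u in sorted(lut.table):
            f = lut.table[u]
            fh.write(f"{u}\t{f.numerator}/{f.denominator}\n")


def read_lookup_tsv(path: str | Path) -> FractionLookup:
    m_max = w_max = p = None
    table: dict[int, Fraction] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    key, _, val = tok.partition("=")
                    if key == "m_max":
                        m_max = int(val)
                    elif key == "w_max":
                        w_max = int(val)
                    elif key == "p":
                        p = int(val)
                continue
            if line.startswith("u\t"):
                continue
            u_str, frac_str = line.split("\t")
            num, _, den = frac_str.partition("/")
            table[int(u_str)] = Fraction(int(num), int(den or 1))
    if m_max is None or w_max is None or p is None:
        raise InputError(f"lookup file {path} is missing its parameter header")
    return FractionLookup(m_max=m_max, w_max=w_max, p=p, table=table)
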