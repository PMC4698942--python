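"""Exact modular arithmetic over a prime ciphertext modulus.

Everything downstream (the division protocols, the simulated-encryption
layer) works in the residue ring Z_p for a single prime p chosen large
enough for the values being encoded.  This module supplies prime
selection, modular exponentiation, Fermat inverses, and Lagrange
interpolation coefficients over Z_p, all on arbitrary-precision Python
integers so no modulus size silently overflows.
"""

from __future__ import annotations

from typing import Sequence

import sympy

from .exceptions import InputError, ParameterError

__all__ = [
    "smallest_prime_above",
    "mod_pow",
    "mod_inverse",
    "lagrange_coeffs_mod_p",
    "poly_eval_mod_p",
]


def smallest_prime_above(bound: int) -> int:
    """Return the least prime strictly greater than ``bound``.

    Used to pick the ciphertext modulus: the errorless protocol needs
    p > m_max * w_max for its mapping to be injective, and the
    approximate protocol needs p > M for the Fermat inverses to exist.

    Parameters
    ----------
    bound : int
        Positive integer lower bound (exclusive).

    Examples
    --------
    >>> smallest_prime_above(100)
    101
    >>> smallest_prime_above(10000)
    10007
    """
    if not isinstance(bound, (int,)) or isinstance(bound, bool):
        raise InputError(f"bound must be an integer, got {type(bound).__name__}")
    if bound < 1:
        raise InputError(f"bound must be positive, got {bound}")
    return int(sympy.nextprime(bound))


def _check_modulus(p: int) -> None:
    if p < 2:
        raise ParameterError(f"modulus must be >= 2, got {p}")


def mod_pow(base: int, exponent: int, p: int) -> int:
    """Compute ``base**exponent mod p`` by square-and-multiply.

    A thin, range-checked wrapper over Python's built-in three-argument
    ``pow``; kept as a named operation because the encrypted-domain
    protocols mirror exactly this exponentiation circuit.
    """
    _check_modulus(p)
    if not 0 <= base < p:
        raise ParameterError(f"base {base} outside canonical range [0, {p - 1}]")
    if exponent < 0:
        raise ParameterError("exponent must be nonnegative")
    return pow(base, exponent, p)


def mod_inverse(a: int, p: int) -> int:
    """Multiplicative inverse of ``a`` modulo the prime ``p``.

    Computed as ``a**(p-2) mod p`` (Fermat's little theorem), the same
    route the encrypted protocol uses, rather than the extended
    Euclidean algorithm, so plaintext and ciphertext paths agree
    operation-for-operation.
    """
    _check_modulus(p)
    a = a % p
    if a == 0:
        raise ParameterError(f"0 has no inverse modulo {p}")
    return pow(a, p - 2, p)


def poly_eval_mod_p(coeffs: Sequence[int], x: int, p: int) -> int:
    """Horner evaluation of ``sum(coeffs[i] * x**i) mod p``."""
    acc = 0
    for c in reversed(coeffs):
        acc = (acc * x + c) % p
    return acc


def lagrange_coeffs_mod_p(
    nodes: Sequence[int], targets: Sequence[int], p: int
) -> list[int]:
    """Coefficients of the interpolating polynomial over Z_p.

    Returns ``h`` of length ``k = len(nodes)`` with
    ``sum(h[i] * node**i) % p == target`` at every (node, target) pair,
    all coefficients canonicalized to [0, p-1].

    The expansion is O(k^2): the full product ``prod(x - B_l)`` is
    built once, each per-node factor ``prod_{l != i}(x - B_l)`` is
    recovered by synthetic division, and the barycentric-style weight
    ``1 / prod_{l != i}(B_i - B_l)`` is a Fermat inverse of that
    quotient evaluated at ``B_i``.  A direct per-node product would be
    O(k^3), which matters at the k = 2n = 400 used for cohort-scale
    division plans.

    Raises
    ------
    ParameterError
        If two nodes coincide modulo p (degenerate interpolation).
    """
    _check_modulus(p)
    if len(nodes) != len(targets):
        raise InputError(
            f"nodes and targets must have equal length "
            f"({len(nodes)} != {len(targets)})"
        )
    if not nodes:
        raise InputError("at least one node is required")
    k = len(nodes)
    nodes = [x % p for x in nodes]
    targets = [t % p for t in targets]
    if len(set(nodes)) != k:
        raise ParameterError("interpolation nodes must be pairwise distinct mod p")

    # full[j] = coefficient of x^j in prod(x - B_l); degree k
    full = [1]
    for b in nodes:
        nxt = [0] * (len(full) + 1)
        for j, c in enumerate(full):
            nxt[j + 1] = (nxt[j + 1] + c) % p
            nxt[j] = (nxt[j] - c * b) % p
        full = nxt

    coeffs = [0] * k
    for b_i, t_i in zip(nodes, targets):
        if t_i == 0:
            continue
        # synthetic division: full = (x - b_i) * q, q has degree k-1
        q = [0] * k
        q[k - 1] = full[k]
        for j in range(k - 2, -1, -1):
            q[j] = (full[j + 1] + q[j + 1] * b_i) % p
        u_i = poly_eval_mod_p(q, b_i, p)  # = prod_{l != i}(B_i - B_l)
        scale = t_i * mod_inverse(u_i, p) % p
        for j in range(k):
            coeffs[j] = (coeffs[j] + scale * q[j]) % p
    return coeffs
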