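"""Slot-batched simulated-encryption layer with cost metering.

A ``CipherVec`` is NOT encrypted: it is a vector of residues mod p plus
bookkeeping.  The point of the layer is that its arithmetic contract is
exactly what a leveled homomorphic scheme exposes — aligned slot-wise
addition and multiplication (SIMD over ``L_s`` slots), plaintext-scalar
operations, no inter-slot rotation — and that every operation is
metered, so circuits written against it are valid HE circuits and their
homomorphic-multiplication (HM) counts and multiplicative depth can be
asserted against analytic budgets.

Cost conventions
----------------
* ``hm_count``: ciphertext x ciphertext multiplications.  The expensive
  operation in a real scheme; the quantity the protocols minimize.
* ``ha_count``: ciphertext additions/subtractions and plaintext-constant
  additions (all cheap, no depth).
* ``pm_count``: plaintext-scalar multiplications.  Metered separately
  and contributing no depth: scalar coefficients are publicly
  computable, so a real implementation replaces them by repeated
  additions, and the published HM budgets exclude them.
* ``max_depth``: length of the longest chain of sequential ciphertext
  multiplications (the cumulative circuit depth, CCD), a proxy for the
  modulus-chain length a leveled scheme would need.  No noise is
  simulated.

Serialized ciphertexts are explicitly labeled as simulation output;
they provide no confidentiality whatsoever.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import sympy

from .exceptions import IncompatibleCipherError, InputError, ParameterError

__all__ = [
    "CostMeter",
    "CostReport",
    "CipherVec",
    "HESession",
    "encrypt_vector",
    "decrypt_vector",
    "he_add",
    "he_sub",
    "he_mul",
    "pt_mul",
    "pt_add",
    "const_like",
    "serialize_cipher",
    "deserialize_cipher",
]


@dataclass(frozen=True)
class CostReport:
    """Immutable snapshot of a session's operation counters."""

    hm_count: int
    ha_count: int
    pm_count: int
    max_depth: int

    def as_dict(self) -> dict:
        return {
            "hm_count": self.hm_count,
            "ha_count": self.ha_count,
            "pm_count": self.pm_count,
            "max_depth": self.max_depth,
        }


@dataclass
class CostMeter:
    """Mutable, session-scoped operation counters.

    Counters are monotone between explicit ``reset`` calls so that each
    protocol run can be costed against a clean baseline.
    """

    hm_count: int = 0
    ha_count: int = 0
    pm_count: int = 0
    max_depth: int = 0

    def observe_depth(self, depth: int) -> None:
        if depth > self.max_depth:
            self.max_depth = depth

    def reset(self) -> None:
        self.hm_count = 0
        self.ha_count = 0
        self.pm_count = 0
        self.max_depth = 0

    def report(self) -> CostReport:
        return CostReport(self.hm_count, self.ha_count, self.pm_count, self.max_depth)


@dataclass(frozen=True)
class CipherVec:
    """A simulated ciphertext: residue slots plus circuit metadata.

    ``slots`` are canonical residues in [0, p-1]; ``depth`` is the
    multiplicative depth of the deepest slot's circuit (0 for a fresh
    encryption).  Arithmetic must go through the module-level operation
    functions so that the shared meter stays truthful.
    """

    slots: tuple[int, ...]
    depth: int
    p: int
    meter: CostMeter = field(repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.slots)


def _require_compatible(a: CipherVec, b: CipherVec) -> None:
    if a.p != b.p:
        raise IncompatibleCipherError(f"modulus mismatch: {a.p} != {b.p}")
    if len(a.slots) != len(b.slots):
        raise IncompatibleCipherError(
            f"slot-count mismatch: {len(a.slots)} != {len(b.slots)}"
        )


def encrypt_vector(
    values: Iterable[int], p: int, n_slots: int, meter: CostMeter | None = None
) -> CipherVec:
    """Pack ``values`` into the slots of a fresh depth-0 ciphertext.

    Unused trailing slots are zero-padded; values are reduced to the
    canonical residue range.  Encryption is free on the meter (key
    generation and actual lattice encryption are out of scope).
    """
    vals = list(values)
    if len(vals) > n_slots:
        raise InputError(f"{len(vals)} values exceed the {n_slots}-slot capacity")
    if p < 2:
        raise ParameterError(f"modulus must be >= 2, got {p}")
    meter = meter if meter is not None else CostMeter()
    slots = tuple(int(v) % p for v in vals) + (0,) * (n_slots - len(vals))
    return CipherVec(slots=slots, depth=0, p=p, meter=meter)


def decrypt_vector(c: CipherVec) -> list[int]:
    """Return the slot residues in [0, p-1]."""
    return list(c.slots)


def he_add(a: CipherVec, b: CipherVec) -> CipherVec:
    """Slot-wise ciphertext addition; depth = max of operands."""
    _require_compatible(a, b)
    a.meter.ha_count += 1
    slots = tuple((x + y) % a.p for x, y in zip(a.slots, b.slots))
    depth = max(a.depth, b.depth)
    a.meter.observe_depth(depth)
    return CipherVec(slots=slots, depth=depth, p=a.p, meter=a.meter)


def he_sub(a: CipherVec, b: CipherVec) -> CipherVec:
    """Slot-wise ciphertext subtraction (negation is free in HE)."""
    _require_compatible(a, b)
    a.meter.ha_count += 1
    slots = tuple((x - y) % a.p for x, y in zip(a.slots, b.slots))
    depth = max(a.depth, b.depth)
    a.meter.observe_depth(depth)
    return CipherVec(slots=slots, depth=depth, p=a.p, meter=a.meter)


def he_mul(a: CipherVec, b: CipherVec) -> CipherVec:
    """Slot-wise ciphertext multiplication; depth = max + 1, one HM."""
    _require_compatible(a, b)
    a.meter.hm_count += 1
    slots = tuple((x * y) % a.p for x, y in zip(a.slots, b.slots))
    depth = max(a.depth, b.depth) + 1
    a.meter.observe_depth(depth)
    return CipherVec(slots=slots, depth=depth, p=a.p, meter=a.meter)


def pt_mul(a: CipherVec, k: int) -> CipherVec:
    """Multiply every slot by the public plaintext scalar ``k``.

    Contributes no multiplicative depth and is counted apart from HMs
    (``pm_count``): the scalar is public, so the operation is
    realizable as repeated additions.
    """
    k = int(k) % a.p
    a.meter.pm_count += 1
    slots = tuple((x * k) % a.p for x in a.slots)
    return CipherVec(slots=slots, depth=a.depth, p=a.p, meter=a.meter)


def pt_add(a: CipherVec, k: int) -> CipherVec:
    """Add the public plaintext scalar ``k`` to every slot (no depth)."""
    k = int(k) % a.p
    a.meter.ha_count += 1
    slots = tuple((x + k) % a.p for x in a.slots)
    return CipherVec(slots=slots, depth=a.depth, p=a.p, meter=a.meter)


def const_like(a: CipherVec, value: int) -> CipherVec:
    """A depth-0, meter-free constant vector compatible with ``a``.

    Models the 'transparent' encoding of a public constant (e.g. the
    1-vector that heads a power basis); creating it costs nothing.
    """
    return CipherVec(
        slots=(int(value) % a.p,) * len(a.slots), depth=0, p=a.p, meter=a.meter
    )


def serialize_cipher(c: CipherVec) -> str:
    """One JSON-lines record; clearly labeled as simulation output."""
    return json.dumps(
        {"simulation": True, "slots": list(c.slots), "depth": c.depth, "p": c.p}
    )


def deserialize_cipher(line: str, meter: CostMeter | None = None) -> CipherVec:
    rec = json.loads(line)
    if not rec.get("simulation"):
        raise InputError("record is not a labeled simulation ciphertext")
    return CipherVec(
        slots=tuple(int(v) for v in rec["slots"]),
        depth=int(rec["depth"]),
        p=int(rec["p"]),
        meter=meter if meter is not None else CostMeter(),
    )


class HESession:
    """Holds the modulus, slot count, and meter for one protocol run.

    The session object owns encryption and decryption.  Cloud-side
    circuit code should accept ``CipherVec`` arguments and use the
    module-level arithmetic functions only, never a session — that
    separation is what makes "the cloud never decrypts" checkable.
    """

    def __init__(self, p: int, n_slots: int = 1):
        if n_slots < 1:
            raise ParameterError(f"slot count must be >= 1, got {n_slots}")
        if p < 2 or not sympy.isprime(p):
            raise ParameterError(f"ciphertext modulus must be prime, got {p}")
        self.p = int(p)
        self.n_slots = int(n_slots)
        self.meter = CostMeter()

    def encrypt(self, values: Iterable[int]) -> CipherVec:
        return encrypt_vector(values, self.p, self.n_slots, self.meter)

    def decrypt(self, c: CipherVec) -> list[int]:
        if c.p != self.p:
            raise IncompatibleCipherError(
                f"ciphertext modulus {c.p} does not match session modulus {self.p}"
            )
        return decrypt_vector(c)

    def cost_report(self) -> CostReport:
        return self.meter.report()

    def reset_meter(self) -> None:
        self.meter.reset()
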