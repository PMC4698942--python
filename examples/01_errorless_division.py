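"""Errorless secure division: exact fractions from a single released residue.

Maps an encrypted (dividend, divisor) pair to one residue mod p via the
Fermat-inverse product m * w^(p-2), then decodes it with a lookup table
of all irreducible fractions in range.  The decoded result is the exact
rational m/w; the released residue reveals only the reduced fraction.
"""

from foresee import HESession, build_fraction_lookup, decode, secure_map
from foresee.modmath import smallest_prime_above

m_max = w_max = 10
p = smallest_prime_above(m_max * w_max)  # 101, the least safe modulus
lookup = build_fraction_lookup(m_max, w_max, p)
print(f"modulus p = {p}; lookup table holds {len(lookup)} irreducible fractions")

session = HESession(p, n_slots=3)
# three divisions at once, one per SIMD slot: 4/3, 2/1, and 8/4
m_ct = session.encrypt([4, 2, 8])
w_ct = session.encrypt([3, 1, 4])
released = session.decrypt(secure_map(m_ct, w_ct, m_max, w_max))

for (m, w), u in zip([(4, 3), (2, 1), (8, 4)], released):
    frac = decode(u, lookup)
    print(f"  {m}/{w}: released residue u = {u:3d} -> decoded {frac} "
          f"(exactly {float(frac):.6f})")

report = session.cost_report()
print(f"circuit cost: {report.hm_count} homomorphic multiplications, "
      f"depth {report.max_depth}")
print("note: 8/4 and 2/1 released the same residue — the protocol only ever")
print("reveals the reduced fraction, never the operand pair.")
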