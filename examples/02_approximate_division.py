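"""Approximate secure division: scaled integer quotients by interpolation.

For equal case-control groups of n individuals the chi-square divisor
only takes the 2n values B_i = i(4n - i), so one polynomial with
f(B_i) = floor(M/B_i) over Z_p divides exactly on that set.  Grouped
baby-step/giant-step evaluation keeps the homomorphic-multiplication
count near 2*sqrt(4n) instead of 2n.
"""

from foresee import HESession, build_plan, choose_group_params, secure_integer_divide
from foresee.modmath import smallest_prime_above

n = 10                      # individuals per group -> 20 feasible divisors
M = 10**6                   # public scale; relative error bound 4n^2/M
p = smallest_prime_above(M)

d, C = choose_group_params(n)
plan = build_plan(n, p, M)
print(f"n={n}: divisor nodes B_1..B_{2*n} = {plan.nodes[:4]}...{plan.nodes[-2:]}")
print(f"group size d={d}, groups C={C}; published HM budget 2C+d-3 = {2*C+d-3}")

session = HESession(p, n_slots=2 * n)
x_ct = session.encrypt(list(plan.nodes))     # all nodes at once, one per slot
quotients = session.decrypt(secure_integer_divide(x_ct, plan))

ok = all(q == M // b for q, b in zip(quotients, plan.nodes))
print(f"floor(M/B) recovered exactly on all {2*n} nodes: {ok}")
print(f"  e.g. B={plan.nodes[0]}: released {quotients[0]}, "
      f"plaintext floor({M}/{plan.nodes[0]}) = {M // plan.nodes[0]}")
report = session.cost_report()
print(f"metered cost: {report.hm_count} HMs (budget {2*C+d-3}), "
      f"depth {report.max_depth}")
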