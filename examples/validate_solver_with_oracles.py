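"""Check the two-step solver against brute-force oracles on a toy program.

The interval LP  max [2,3]·x  s.t.  x <= [4,5], x >= 0  has four endpoint
realizations with optima {8, 10, 12, 15}; the two-step solution must bracket
them.  The Monte-Carlo oracle samples coefficients uniformly inside their
intervals, so its empirical range always sits inside the endpoint range.
"""

from wetlandilp import (
    IntervalLinearProgram,
    endpoint_oracle,
    mc_oracle,
    solve_ilp,
)

ilp = IntervalLinearProgram(
    sense="maximize", c=[(2, 3)], A=[[(1, 1)]], b=[(4, 5)], row_senses=["le"]
)
solution = solve_ilp(ilp)
f = solution.f_opt
print(f"two-step solution: f = [{f.lower:.2f}, {f.upper:.2f}], "
      f"x = [{solution.x_opt[0].lower:.2f}, {solution.x_opt[0].upper:.2f}]")

ep = endpoint_oracle(ilp, solution)
print(f"endpoint oracle ({ep.n_realizations} crisp LPs): "
      f"[{ep.empirical_min:.2f}, {ep.empirical_max:.2f}] -> {ep.verdict}")

mc = mc_oracle(ilp, samples=1000, seed=1, solution=solution)
print(f"mc oracle (1000 samples):        "
      f"[{mc.empirical_min:.2f}, {mc.empirical_max:.2f}] -> {mc.verdict}")
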