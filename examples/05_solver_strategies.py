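"""The three BCD update strategies and strong-rule screening are exact.

All strategies minimize the same objective and return identical
coefficients; the correlation-table path is the compiled fast route, and
strong-rule screening (with KKT re-admission) never changes the solution.
"""

import time

import numpy as np

from fusedggm import (
    RegularizationPair,
    SimulationSpec,
    bcd_solve,
    build_node_problem,
    simulate_study,
    standardize,
)

spec = SimulationSpec("random", p=40, n1=120, n2=120,
                      rewire_fraction=0.1, seed=4)
_, pair = simulate_study(spec)
std = standardize(pair)
prob = build_node_problem(std, 0)
reg = RegularizationPair(0.3, 0.05)

results = {}
for strategy in ("naive", "resi_upd", "corr_mtx"):
    t0 = time.perf_counter()
    st = bcd_solve(prob, reg, strategy=strategy, tol=1e-10)
    results[strategy] = st
    print(f"{strategy:10s}: objective={st.objective:.10f} "
          f"sweeps={st.n_sweeps} ({time.perf_counter() - t0:.4f}s)")

ref = results["naive"]
for s in ("resi_upd", "corr_mtx"):
    d = max(np.max(np.abs(results[s].beta1 - ref.beta1)),
            np.max(np.abs(results[s].beta2 - ref.beta2)))
    print(f"max |coef difference| {s} vs naive: {d:.2e}")

screened = bcd_solve(prob, reg, tol=1e-10, screen=True)
d = np.max(np.abs(screened.beta1 - ref.beta1))
print(f"strong rule kept {screened.active_set.size}/{prob.n_predictors} "
      f"predictors; max deviation from unscreened solve: {d:.2e}")
print("Identical solutions confirm the accelerations are exact rewrites, "
      "not approximations.")
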