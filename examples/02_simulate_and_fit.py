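"""Simulate a gene cohort with known parameters and refit them.

Forward-simulates damage and repair on 200k genes, aggregates the surviving
lesions into an observed:expected surface, and recovers the generating
parameters by grid search plus simplex refinement (Pv pinned at 0.8 as in
the simulation study).
"""

from tcrdyn import GridSpec, SimulationConfig, TcrParams, fit_surface
from tcrdyn.simulate import simulate_cohort_data

true = TcrParams(pd=0.25, pr=0.25, pv=0.8, m=1.5)
data = simulate_cohort_data(true, SimulationConfig(n_genes=200_000), rng=42)
fit = fit_surface(data.surface(), GridSpec.coarse(), fixed={"pv": 0.8})

print(f"true:      Pd={true.pd:.3f}  Pr={true.pr:.3f}  m={true.m:.3f}")
p = fit.params
print(f"estimated: Pd={p.pd:.3f}  Pr={p.pr:.3f}  m={p.m:.3f}")
print(f"L1 distance at the optimum: {fit.distance:.3f} over 240 cells")
print(
    "\nEstimates track the truth up to the sampling noise of a 200k-gene\n"
    "cohort; Pr is the least identifiable parameter because restart only\n"
    "matters when a gene carries multiple lesions."
)
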