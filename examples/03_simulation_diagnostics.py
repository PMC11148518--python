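"""Recruitment simulation and RDS monitoring diagnostics.

Generates a synthetic hidden-population contact graph, runs the
agent-based recruitment process on it, builds the recruitment forest,
and computes waves, the RDS-II weighted prevalence of the monitored
trait, its convergence trace, and per-group homophily.
"""

from webrds import (
    PopulationModel,
    SimConfig,
    build_forest,
    convergence_trace,
    generate_population,
    homophily,
    rds2_estimate,
    run_recruitment,
)

model = PopulationModel(
    n=2000, degree_distribution=("poisson", 8.0), trait_prevalence=0.3,
    within_group_preference=0.5,
)
graph = generate_population(model, rng_seed=1)
true_p = sum(1 for i in graph.nodes if graph.nodes[i]["trait"]) / graph.number_of_nodes()
print(f"population: n={graph.number_of_nodes()}, trait prevalence {true_p:.3f}")

config = SimConfig(initial_seeds=8, added_seeds=4, duration_days=120, rng_seed=1)
result = run_recruitment(graph, config)

completers = [
    r for r in result.roster.participants.values() if r.interview_complete
]
print(f"recruitment: {len(result.roster)} portal entries, {len(completers)} completers")

forest = build_forest(result.roster)
print(f"max wave reached: {forest.max_wave()} (seeds are wave 0)")

indicator = [r.interview_responses["hiv_test_12m"] == 1 for r in completers]
degrees = [r.degree for r in completers]
est = rds2_estimate(indicator, degrees)
print(f"RDS-II weighted prevalence: {est:.3f} (population truth {true_p:.3f})")
# the inverse-degree weights undo the oversampling of well-connected peers

trace = convergence_trace(indicator, degrees, tolerance=0.05, window=50)
print(f"convergence declared at sample size: {trace.converged_at}")

groups = {pid: (r.region or "R0") for pid, r in result.roster.participants.items()
          if not r.duplicate_phone}
degs = {pid: (r.degree or 5) for pid, r in result.roster.participants.items()
        if not r.duplicate_phone}
h = homophily(forest, groups, degs)
print("homophily by region (1 = neutral mixing):",
      {k: (round(v, 2) if v is not None else None) for k, v in sorted(h.items())})
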