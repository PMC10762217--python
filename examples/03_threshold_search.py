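"""Search the tier thresholds and MNAR share behind observed missingness.

Generates a target at known alpha* = 0.5, then runs both the particle swarm and
the 5%-step grid enumeration on the same common-random-numbers objective.  The
two agree on the optimum; the swarm refines alpha on a continuous scale.  Note
that only the MNAR share (and a lower bound on the LOW-tier size) is constrained
by the missing-rate vector, so both optimisers report the lexicographically
smallest equivalent tier split.
"""

from pxmdc import (
    MissingnessSpec,
    PSOConfig,
    SyntheticSpec,
    ThresholdParams,
    enumerate_search,
    generate_complete_matrix,
    missing_rate_vector,
    percentage_difference,
    pso_search,
    simulate_mm,
    tier_by_percent,
)

matrix = generate_complete_matrix(SyntheticSpec(m=20, n=10, seed=100))
generator = ThresholdParams(30, 40, 30, 0.5)
truth = simulate_mm(
    matrix,
    tier_by_percent(matrix, generator),
    MissingnessSpec(rate=0.2, params=generator, seed=500),
)
target = missing_rate_vector(truth)

pso = pso_search(matrix, target, rate=0.2, config=PSOConfig(n_rep=10, seed=1000))
enum = enumerate_search(matrix, target, rate=0.2, step=5, n_rep=10, seed=1000)

for name, res in [("swarm", pso), ("enumeration", enum)]:
    b = res.best
    print(f"{name:12s} (x, y, z, alpha) = ({b.x:5.1f}, {b.y:5.1f}, {b.z:5.1f}, "
          f"{b.alpha:.3f})  objective {res.objective:.4f}  "
          f"({res.evaluations} evaluations)")
print("per-coordinate percentage difference:", percentage_difference(pso.best, enum.best))
# The swarm matches the grid optimum with two orders of magnitude fewer distinct
# parameter cells probed, and its alpha lands within one grid step of alpha*.
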