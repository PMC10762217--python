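"""Pan missing data left and extract the maximal complete subset.

The complete left-aligned block (X^Complete) is what the threshold search and
training-set simulation run on; the 80% rule widens it when heavy missingness
would leave too few columns.
"""

from pxmdc import (
    MissingnessSpec,
    SyntheticSpec,
    ThresholdParams,
    eighty_percent_filter,
    generate_complete_matrix,
    max_complete_subset,
    pan_left,
    simulate_mm,
    tier_by_mean_rule,
)

matrix = generate_complete_matrix(SyntheticSpec(m=100, n=30, seed=1))
masked = simulate_mm(
    matrix,
    tier_by_mean_rule(matrix),
    MissingnessSpec(rate=0.25, params=ThresholdParams(0, 0, 100, 0.5), seed=3),
)

from pxmdc.core_io import MatrixError

try:
    subset = max_complete_subset(pan_left(masked))
    print(f"without the 80% rule: {subset.shape[0]} metabolites x {subset.shape[1]} columns")
except MatrixError as err:
    # at 25% missingness the most censored metabolite can lose every sample
    print(f"without the 80% rule: {err}")

filtered = eighty_percent_filter(masked)
subset80 = max_complete_subset(pan_left(filtered))
print(f"with the 80% rule:    {subset80.shape[0]} metabolites x {subset80.shape[1]} columns")
# Dropping metabolites missing in >20% of samples sacrifices rows but yields a
# much wider complete block for downstream simulation.
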