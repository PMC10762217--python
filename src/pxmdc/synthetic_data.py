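"""Synthetic complete abundance matrices with a metabolomics-like dynamic range.

GC-MS metabolite abundances span several orders of magnitude between metabolites,
which is what makes mean-based concentration tiering (above the grand mean = HIGH,
below a tenth of it = LOW) meaningful.  The generator draws each metabolite's mean
abundance log-uniformly over a configurable decade range and each sample value
log-normally around that mean with a fixed coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AbundanceMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    ``log_mean_range`` is the (low, high) span of metabolite log10 mean abundances;
    a width of >= 2 decades guarantees a non-degenerate high/low tier split.
    ``within_metabolite_cv`` is the coefficient of variation of one metabolite's
    values across samples.
    """

    m: int = 100
    n: int = 30
    log_mean_range: tuple[float, float] = (0.0, 3.0)
    within_metabolite_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 4 or self.n < 4:
            raise ValueError("need at least 4 metabolites and 4 samples")
        lo, hi = self.log_mean_range
        if not lo < hi:
            raise ValueError("log_mean_range must satisfy low < high")
        if self.within_metabolite_cv <= 0:
            raise ValueError("within_metabolite_cv must be positive")


def generate_complete_matrix(spec: SyntheticSpec) -> AbundanceMatrix:
    """Draw a complete m x n abundance matrix per the spec; deterministic in seed.

    Metabolite means are 10**Uniform(log_mean_range); sample values are log-normal
    around each mean with CV = within_metabolite_cv, so every value is positive.
    """
    rng = np.random.default_rng(spec.seed)
    log_means = rng.uniform(*spec.log_mean_range, size=spec.m)
    means = 10.0 ** log_means
    # log-normal with exact target mean and CV: sigma^2 = ln(1 + cv^2)
    sigma2 = np.log1p(spec.within_metabolite_cv**2)
    sigma = np.sqrt(sigma2)
    mu = np.log(means) - sigma2 / 2.0
    values = rng.lognormal(mean=mu[:, None], sigma=sigma, size=(spec.m, spec.n))
    width = max(len(str(spec.m)), 3)
    metabolite_ids = [f"met_{i:0{width}d}" for i in range(spec.m)]
    sample_ids = [f"s{j:03d}" for j in range(spec.n)]
    return AbundanceMatrix(
        metabolite_ids=metabolite_ids, sample_ids=sample_ids, values=values
    )


def default_fixture(seed: int = 0) -> AbundanceMatrix:
    """The standard 100 x 30 test fixture (3 decades of spread, CV 0.25)."""
    return generate_complete_matrix(SyntheticSpec(seed=seed))
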