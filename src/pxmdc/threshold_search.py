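"""Search for the tier thresholds (x, y, z) and MNAR share alpha behind observed
missingness.

The objective compares per-metabolite missing-rate vectors: candidate params are
used to re-simulate missingness on the complete subset, and the mean Euclidean
distance to the observed matrix's missing-rate vector over ``n_rep`` replicates
is minimised.  Replicates use common random numbers (the same sub-seed stream for
every candidate), which removes simulation noise from comparisons between nearby
parameter vectors.  Two optimisers are provided: global-best particle-swarm
optimisation and exhaustive grid enumeration (the oracle the swarm is validated
against).

Because MNAR placement involves only LOW-tier metabolites and MCAR is uniform,
the objective depends on the parameters only through the LOW-tier metabolite
count and the MNAR cell count; the x/y split of the remaining metabolites is
exactly flat.  Both optimisers therefore break objective ties toward the
lexicographically smallest (x, y, z, alpha), which pins down a unique reported
optimum on flat manifolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AbundanceMatrix, MaskedMatrix, ThresholdParams
from .mm_simulator import (
    _draw_mm_cells,
    _lex_ranks,
    _rank_descending,
    _round_half_up,
    tier_counts_from_percent,
)


def replicate_seed(seed: int, rep: int) -> int:
    """Integer sub-seed for replicate ``rep`` of an objective evaluation.

    The stream depends on (master seed, replicate) only, never on the candidate
    params, so all candidates see identical draws (common random numbers).
    """
    return int(np.random.SeedSequence([int(seed), int(rep)]).generate_state(1)[0])


def missing_rate_vector(masked: MaskedMatrix) -> np.ndarray:
    """Per-metabolite missing fraction, ordered by metabolite id (lexicographic)."""
    rates = masked.mask.mean(axis=1)
    order = np.argsort(np.asarray(masked.metabolite_ids, dtype=object))
    return rates[order]


def vector_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two missing-rate vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


class ObjectiveEvaluator:
    """Precomputed state for repeated objective evaluations on one instance.

    Exploits that the objective is a function of (LOW-tier count, MNAR cell
    count) alone: evaluations are cached exactly on that key, which makes both
    enumeration and PSO cheap.
    """

    def __init__(
        self,
        complete: AbundanceMatrix,
        target: np.ndarray,
        rate: float,
        n_rep: int = 10,
        seed: int = 0,
    ):
        target = np.asarray(target, dtype=float)
        m, n = complete.shape
        if target.shape != (m,):
            raise ValueError(
                f"target vector length {target.shape} does not match {m} metabolites"
            )
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"rate must lie in [0, 1), got {rate}")
        self.complete = complete
        self.target = target
        self.rate = float(rate)
        self.n_rep = int(n_rep)
        self.seed = int(seed)
        self.m, self.n = m, n
        self.k = _round_half_up(rate * m * n)
        self._order = _rank_descending(complete)  # mean-desc metabolite ranking
        self._met_lex = _lex_ranks(complete.metabolite_ids)
        self._samp_lex = _lex_ranks(complete.sample_ids)
        self._id_order = np.argsort(np.asarray(complete.metabolite_ids, dtype=object))
        self._rep_seeds = [replicate_seed(seed, r) for r in range(self.n_rep)]
        self._cache: dict[tuple[int, int], float] = {}
        self.evaluations = 0

    def effective_key(self, params: ThresholdParams) -> tuple[int, int]:
        """(LOW-tier metabolite count, MNAR cell count) implied by params."""
        _, _, n_low = tier_counts_from_percent(params, self.m)
        capacity = n_low * self.n
        k_mnar = min(_round_half_up(params.alpha * self.k), self.k, capacity)
        return n_low, k_mnar

    def __call__(self, params: ThresholdParams) -> float:
        self.evaluations += 1
        if self.k == 0:
            return vector_distance(np.zeros(self.m), self.target)
        key = self.effective_key(params)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        n_low, k_mnar = key
        low_rows = np.zeros(self.m, dtype=bool)
        if n_low:
            low_rows[self._order[self.m - n_low :]] = True
        dists = np.empty(self.n_rep)
        for r, sub_seed in enumerate(self._rep_seeds):
            rng = np.random.default_rng(sub_seed)
            mnar, mcar = _draw_mm_cells(
                self.complete.values,
                low_rows,
                self._met_lex,
                self._samp_lex,
                self.k,
                k_mnar,
                rng,
            )
            counts = np.bincount(mnar // self.n, minlength=self.m) + np.bincount(
                mcar // self.n, minlength=self.m
            )
            sim_vec = counts[self._id_order] / self.n
            dists[r] = vector_distance(sim_vec, self.target)
        value = float(dists.mean())
        self._cache[key] = value
        return value


def objective(
    params: ThresholdParams,
    complete: AbundanceMatrix,
    target: np.ndarray,
    rate: float,
    n_rep: int = 10,
    seed: int = 0,
) -> float:
    """Mean Euclidean distance between simulated and target missing-rate vectors."""
    return ObjectiveEvaluator(complete, target, rate, n_rep=n_rep, seed=seed)(params)


@dataclass(frozen=True)
class SearchResult:
    best: ThresholdParams
    objective: float
    trace: list[float]
    evaluations: int
    seed: int

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be nonnegative")
        if any(b > a + 1e-12 for a, b in zip(self.trace, self.trace[1:])):
            raise ValueError("trace must be non-increasing")


@dataclass(frozen=True)
class PSOConfig:
    """Global-best PSO settings (standard constriction-coefficient values)."""

    swarm_size: int = 30
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    max_iter: int = 100
    patience: int = 20  # stop after this many iterations without improvement
    n_rep: int = 10
    seed: int = 0


def decode_position(pos: np.ndarray) -> ThresholdParams:
    """Map a free 3-vector (u1, u2, a) onto the (x, y, z, alpha) simplex.

    x = clip(u1, 0, 100); y = min(clip(u2, 0, 100), 100 - x); z = remainder;
    alpha = clip(a, 0, 1).  Coordinates stay interpretable and every grid point
    of the enumeration is reachable.
    """
    x = float(np.clip(pos[0], 0.0, 100.0))
    y = float(min(np.clip(pos[1], 0.0, 100.0), 100.0 - x))
    z = 100.0 - x - y
    alpha = float(np.clip(pos[2], 0.0, 1.0))
    return ThresholdParams(x=x, y=y, z=z, alpha=alpha)


def _lex_better(a: ThresholdParams, b: ThresholdParams) -> bool:
    return a.as_tuple() < b.as_tuple()


_LO = np.array([0.0, 0.0, 0.0])
_HI = np.array([100.0, 100.0, 1.0])
_VMAX = (_HI - _LO) / 2.0


def pso_search(
    complete: AbundanceMatrix,
    target: np.ndarray,
    rate: float,
    config: PSOConfig = PSOConfig(),
    _objective=None,
) -> SearchResult:
    """Global-best PSO over (x, y, z, alpha); deterministic under config.seed.

    ``_objective`` may override the default missing-rate-vector objective with
    any callable ``ThresholdParams -> float`` (used by tests with analytic
    functions).
    """
    f = _objective or ObjectiveEvaluator(
        complete, target, rate, n_rep=config.n_rep, seed=config.seed
    )
    rng = np.random.default_rng(config.seed)
    s = config.swarm_size
    pos = rng.uniform(_LO, _HI, size=(s, 3))
    vel = rng.uniform(-_VMAX, _VMAX, size=(s, 3))
    evaluations = 0

    def evaluate(p: np.ndarray) -> tuple[float, ThresholdParams]:
        nonlocal evaluations
        params = decode_position(p)
        evaluations += 1
        return f(params), params

    pbest_pos = pos.copy()
    pbest_val = np.empty(s)
    pbest_par: list[ThresholdParams] = [None] * s  # type: ignore[list-item]
    for i in range(s):
        pbest_val[i], pbest_par[i] = evaluate(pos[i])
    g = int(np.argmin(pbest_val))
    gbest_val, gbest_par, gbest_pos = pbest_val[g], pbest_par[g], pbest_pos[g].copy()
    for i in range(s):  # lexicographic tie-break among the initial swarm
        if pbest_val[i] == gbest_val and _lex_better(pbest_par[i], gbest_par):
            gbest_par, gbest_pos = pbest_par[i], pbest_pos[i].copy()

    trace = [float(gbest_val)]
    stagnant = 0
    for _ in range(config.max_iter):
        r1 = rng.uniform(size=(s, 3))
        r2 = rng.uniform(size=(s, 3))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest_pos - pos)
            + config.social * r2 * (gbest_pos[None, :] - pos)
        )
        vel = np.clip(vel, -_VMAX, _VMAX)
        pos = np.clip(pos + vel, _LO, _HI)
        improved = False
        for i in range(s):
            val, params = evaluate(pos[i])
            if val < pbest_val[i] or (
                val == pbest_val[i] and _lex_better(params, pbest_par[i])
            ):
                pbest_val[i], pbest_par[i] = val, params
                pbest_pos[i] = pos[i]
            if val < gbest_val:
                gbest_val, gbest_par, gbest_pos = val, params, pos[i].copy()
                improved = True
            elif val == gbest_val and _lex_better(params, gbest_par):
                gbest_par, gbest_pos = params, pos[i].copy()
        trace.append(float(gbest_val))
        stagnant = 0 if improved else stagnant + 1
        if stagnant >= config.patience:
            break
    return SearchResult(
        best=gbest_par,
        objective=float(gbest_val),
        trace=trace,
        evaluations=evaluations,
        seed=config.seed,
    )


def enumerate_search(
    complete: AbundanceMatrix,
    target: np.ndarray,
    rate: float,
    step: int = 1,
    n_rep: int = 10,
    seed: int = 0,
) -> SearchResult:
    """Exhaustive grid search: x, y, z multiples of ``step`` summing to 100,
    alpha from ``step``% to 100% in steps of ``step``%.

    Returns the exact grid minimum; ties go to the lexicographically smallest
    (x, y, z, alpha).  The grid is visited in lexicographic order with strict
    improvement, which realises that tie-break.
    """
    if step <= 0 or 100 % step != 0:
        raise ValueError(f"step must be a positive divisor of 100, got {step}")
    f = ObjectiveEvaluator(complete, target, rate, n_rep=n_rep, seed=seed)
    best_val = np.inf
    best_par: ThresholdParams | None = None
    trace: list[float] = []
    evaluations = 0
    alphas = [a / 100.0 for a in range(step, 101, step)]
    for x in range(0, 101, step):
        for y in range(0, 101 - x, step):
            z = 100 - x - y
            for alpha in alphas:
                params = ThresholdParams(x=float(x), y=float(y), z=float(z), alpha=alpha)
                val = f(params)
                evaluations += 1
                if val < best_val:
                    best_val, best_par = val, params
                trace.append(float(best_val))
    assert best_par is not None
    return SearchResult(
        best=best_par,
        objective=float(best_val),
        trace=trace,
        evaluations=evaluations,
        seed=seed,
    )


def percentage_difference(
    pso: ThresholdParams, enum: ThresholdParams
) -> dict[str, float]:
    """Per-coordinate |pso - enum| / pso, with alpha on the percent scale.

    The convention divides by the swarm's result; a coordinate where both are
    zero contributes 0, and a zero swarm coordinate against a nonzero
    enumeration coordinate yields inf.
    """
    out: dict[str, float] = {}
    pairs = {
        "x": (pso.x, enum.x),
        "y": (pso.y, enum.y),
        "z": (pso.z, enum.z),
        "alpha": (pso.alpha * 100.0, enum.alpha * 100.0),
    }
    for name, (p, e) in pairs.items():
        if p == 0.0:
            out[name] = 0.0 if e == 0.0 else float("inf")
        else:
            out[name] = abs(p - e) / p
    return out
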