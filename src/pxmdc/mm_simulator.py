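"""Mixed-missingness (MM) injection: concentration tiering + labeled MNAR/MCAR.

The MM model tiers metabolites into HIGH / MEDIUM / LOW concentration levels and
then removes cells by two mechanisms: MNAR as left-censoring — the globally
smallest values among LOW-tier cells fall below a shared detection limit — and
MCAR drawn uniformly from whatever remains observed.  ``alpha`` fixes the MNAR
share of all missing cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import (
    MCAR,
    MNAR,
    AbundanceMatrix,
    MaskedMatrix,
    MissingnessSpec,
    ThresholdParams,
)

logger = logging.getLogger(__name__)

HIGH = "HIGH"
MEDIUM = "MEDIUM"
LOW = "LOW"
TIERS = (HIGH, MEDIUM, LOW)


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


@dataclass(frozen=True)
class TierAssignment:
    """Per-metabolite concentration tier plus the rule that produced it."""

    metabolite_ids: list[str]
    tiers: np.ndarray  # array of HIGH/MEDIUM/LOW strings, aligned to metabolite_ids
    rule: str  # "percent-threshold" | "mean-based"

    def __post_init__(self) -> None:
        tiers = np.asarray(self.tiers, dtype=object)
        if tiers.shape != (len(self.metabolite_ids),):
            raise ValueError("one tier required per metabolite")
        bad = set(tiers) - set(TIERS)
        if bad:
            raise ValueError(f"unknown tiers: {sorted(bad)}")
        object.__setattr__(self, "tiers", tiers)

    def counts(self) -> dict[str, int]:
        return {t: int(np.sum(self.tiers == t)) for t in TIERS}

    @property
    def low_mask(self) -> np.ndarray:
        return self.tiers == LOW


def _rank_descending(matrix: AbundanceMatrix) -> np.ndarray:
    """Metabolite indices ordered by mean abundance desc, ties by id (lex asc)."""
    means = np.nanmean(matrix.values, axis=1)
    id_rank = np.argsort(np.argsort(np.asarray(matrix.metabolite_ids, dtype=object)))
    return np.lexsort((id_rank, -means))


def tier_counts_from_percent(params: ThresholdParams, m: int) -> tuple[int, int, int]:
    """(n_high, n_medium, n_low) from percent thresholds, round-half-up on counts."""
    n_high = min(_round_half_up(params.x / 100.0 * m), m)
    n_med = min(_round_half_up(params.y / 100.0 * m), m - n_high)
    return n_high, n_med, m - n_high - n_med


def tier_by_percent(matrix: AbundanceMatrix, params: ThresholdParams) -> TierAssignment:
    """Rank metabolites by mean abundance (desc) and cut at x% / y% / z%."""
    m = len(matrix.metabolite_ids)
    order = _rank_descending(matrix)
    n_high, n_med, _ = tier_counts_from_percent(params, m)
    tiers = np.empty(m, dtype=object)
    tiers[order[:n_high]] = HIGH
    tiers[order[n_high : n_high + n_med]] = MEDIUM
    tiers[order[n_high + n_med :]] = LOW
    return TierAssignment(
        metabolite_ids=list(matrix.metabolite_ids), tiers=tiers, rule="percent-threshold"
    )


def tier_by_mean_rule(matrix: AbundanceMatrix) -> TierAssignment:
    """Grand-mean rule: mean > g is HIGH, mean < g/10 is LOW, else MEDIUM.

    ``g`` is the mean over all cells.  Inequalities are strict, so a metabolite
    sitting exactly on a boundary is MEDIUM.
    """
    g = float(matrix.values.mean())
    means = matrix.values.mean(axis=1)
    tiers = np.where(means > g, HIGH, np.where(means < g / 10.0, LOW, MEDIUM))
    return TierAssignment(
        metabolite_ids=list(matrix.metabolite_ids),
        tiers=tiers.astype(object),
        rule="mean-based",
    )


def _lex_ranks(ids: list[str]) -> np.ndarray:
    return np.argsort(np.argsort(np.asarray(ids, dtype=object)))


def _draw_mm_cells(
    values: np.ndarray,
    low_rows: np.ndarray,
    met_lex: np.ndarray,
    samp_lex: np.ndarray,
    k: int,
    k_mnar: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick (mnar_flat, mcar_flat) cell indices; shared by simulator and objective.

    MNAR = the k_mnar smallest values among LOW-row cells (ties broken by
    metabolite id then sample id); MCAR = uniform without replacement from the
    remaining cells.  Flat indices are row-major.
    """
    m, n = values.shape
    if k_mnar > 0:
        li, lj = np.nonzero(np.broadcast_to(low_rows[:, None], (m, n)))
        order = np.lexsort((samp_lex[lj], met_lex[li], values[li, lj]))
        sel = order[:k_mnar]
        mnar_flat = li[sel] * n + lj[sel]
    else:
        mnar_flat = np.empty(0, dtype=np.intp)
    k_mcar = k - k_mnar
    if k_mcar > 0:
        remaining = np.ones(m * n, dtype=bool)
        remaining[mnar_flat] = False
        pool = np.nonzero(remaining)[0]
        mcar_flat = pool[rng.choice(pool.size, size=k_mcar, replace=False)]
    else:
        mcar_flat = np.empty(0, dtype=np.intp)
    return mnar_flat, mcar_flat


def simulate_mm(
    matrix: AbundanceMatrix, tiers: TierAssignment, spec: MissingnessSpec
) -> MaskedMatrix:
    """Inject labeled MM missingness into a complete matrix.

    Total masked cells k = round(r*m*n); of those, round(alpha*k) are MNAR
    (capped at the LOW-tier cell count, with the shortfall reassigned to MCAR and
    a warning logged) and the rest MCAR.  Deterministic under the spec's seed.
    """
    if list(tiers.metabolite_ids) != list(matrix.metabolite_ids):
        raise ValueError("tier assignment does not match matrix metabolites")
    m, n = matrix.shape
    k = _round_half_up(spec.rate * m * n)
    if k == 0:
        out = matrix.as_masked()
        return MaskedMatrix(
            metabolite_ids=out.metabolite_ids,
            sample_ids=out.sample_ids,
            values=out.values,
            mask=out.mask,
            labels={},
        )
    low_rows = tiers.low_mask
    capacity = int(low_rows.sum()) * n
    k_mnar_want = min(_round_half_up(spec.params.alpha * k), k)
    k_mnar = min(k_mnar_want, capacity)
    if k_mnar < k_mnar_want:
        logger.warning(
            "MNAR demand %d exceeds LOW-tier capacity %d; %d cells reassigned to MCAR",
            k_mnar_want,
            capacity,
            k_mnar_want - k_mnar,
        )
    rng = np.random.default_rng(spec.seed)
    mnar_flat, mcar_flat = _draw_mm_cells(
        matrix.values,
        low_rows,
        _lex_ranks(matrix.metabolite_ids),
        _lex_ranks(matrix.sample_ids),
        k,
        k_mnar,
        rng,
    )
    mask = np.zeros(m * n, dtype=bool)
    mask[mnar_flat] = True
    mask[mcar_flat] = True
    labels: dict[tuple[int, int], str] = {}
    for flat in mnar_flat:
        labels[(int(flat) // n, int(flat) % n)] = MNAR
    for flat in mcar_flat:
        labels[(int(flat) // n, int(flat) % n)] = MCAR
    return MaskedMatrix(
        metabolite_ids=list(matrix.metabolite_ids),
        sample_ids=list(matrix.sample_ids),
        values=matrix.values,
        mask=mask.reshape(m, n),
        labels=labels,
    )
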