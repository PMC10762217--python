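"""Per-missing-cell feature construction for the mechanism classifier.

Each missing cell becomes one row of nine features: the lengths of the
contiguous missing runs through the cell along its metabolite row and its sample
column, five summary statistics of the metabolite's observed values (max, min,
median, mean, missing rate), the metabolite identity (integer-coded), and the
metabolite's concentration tier.  Left-censored (MNAR) cells sit in low-tier,
high-missing-rate metabolites with long column runs, which is the signal the
classifier exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AbundanceMatrix, MaskedMatrix, MissingnessSpec, ThresholdParams
from .mm_simulator import TierAssignment, TIERS, simulate_mm, tier_by_percent
from .threshold_search import replicate_seed

logger = logging.getLogger(__name__)

#: Column order of the numeric/categorical feature block, fixed across the package.
FEATURE_COLUMNS = [
    "run_len_row",
    "run_len_col",
    "met_max",
    "met_min",
    "met_median",
    "met_mean",
    "met_missing_rate",
    "metabolite_code",
    "tier_code",
]

#: Reserved code for metabolites unseen at training time.
UNSEEN_CODE = -1

TIER_CODES = {t: i for i, t in enumerate(TIERS)}  # HIGH=0, MEDIUM=1, LOW=2


@dataclass(frozen=True)
class FeatureTable:
    """Feature rows (one per missing cell) plus the categorical encoders.

    ``frame`` columns: metabolite_id, sample_id, the FEATURE_COLUMNS block, and
    ``label`` (MNAR/MCAR or None).  ``metabolite_codes`` is the bijection from
    metabolite id to integer code that must be shared between training and
    prediction within one pipeline run.
    """

    frame: pd.DataFrame
    metabolite_codes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def design_matrix(self) -> pd.DataFrame:
        return self.frame[FEATURE_COLUMNS]


def _run_lengths(mask_line: np.ndarray) -> np.ndarray:
    """For each True position, the length of its maximal contiguous True run."""
    out = np.zeros(mask_line.size, dtype=int)
    start = None
    for idx in range(mask_line.size + 1):
        inside = idx < mask_line.size and mask_line[idx]
        if inside and start is None:
            start = idx
        elif not inside and start is not None:
            out[start:idx] = idx - start
            start = None
    return out


def extract_features(
    masked: MaskedMatrix,
    tiers: TierAssignment,
    metabolite_codes: dict[str, int] | None = None,
) -> FeatureTable:
    """One feature row per missing cell of ``masked``.

    Summary statistics use the metabolite's *observed* values only.  Labels are
    copied when the matrix carries them.  Passing ``metabolite_codes`` reuses an
    existing encoder (prediction time); unseen metabolites get UNSEEN_CODE.
    """
    if list(tiers.metabolite_ids) != list(masked.metabolite_ids):
        raise ValueError("tier assignment does not match matrix metabolites")
    m, n = masked.shape
    fully_missing = np.nonzero(masked.mask.all(axis=1))[0]
    if fully_missing.size:
        raise ValueError(
            f"metabolite '{masked.metabolite_ids[int(fully_missing[0])]}' is fully "
            "missing; its summary statistics are undefined"
        )
    if metabolite_codes is None:
        metabolite_codes = {mid: c for c, mid in enumerate(sorted(masked.metabolite_ids))}
    if not masked.mask.any():
        logger.warning("matrix has no missing cells; feature table is empty")
        frame = pd.DataFrame(
            columns=["metabolite_id", "sample_id", *FEATURE_COLUMNS, "label"]
        )
        return FeatureTable(frame=frame, metabolite_codes=dict(metabolite_codes))

    row_runs = np.vstack([_run_lengths(masked.mask[i]) for i in range(m)])
    col_runs = np.vstack([_run_lengths(masked.mask[:, j]) for j in range(n)]).T

    records = []
    for i in range(m):
        obs = masked.values[i, ~masked.mask[i]]
        met_stats = (
            float(obs.max()),
            float(obs.min()),
            float(np.median(obs)),
            float(obs.mean()),
            float(masked.mask[i].mean()),
        )
        code = metabolite_codes.get(masked.metabolite_ids[i], UNSEEN_CODE)
        tier_code = TIER_CODES[tiers.tiers[i]]
        for j in np.nonzero(masked.mask[i])[0]:
            label = masked.labels.get((i, int(j))) if masked.labels is not None else None
            records.append(
                (
                    masked.metabolite_ids[i],
                    masked.sample_ids[int(j)],
                    int(row_runs[i, j]),
                    int(col_runs[i, j]),
                    *met_stats,
                    code,
                    tier_code,
                    label,
                )
            )
    frame = pd.DataFrame(
        records, columns=["metabolite_id", "sample_id", *FEATURE_COLUMNS, "label"]
    )
    return FeatureTable(frame=frame, metabolite_codes=dict(metabolite_codes))


def build_training_set(
    complete: AbundanceMatrix,
    params: ThresholdParams,
    rate: float,
    n_copies: int = 5,
    seed: int = 0,
) -> FeatureTable:
    """Labeled training table from ``n_copies`` independent MM draws.

    Each draw re-simulates missingness on the complete subset with the searched
    params (percent-threshold tiers) and extracts features for every missing
    cell; tables are concatenated.  Metabolites a draw censors completely have
    undefined summary statistics and are left out of that draw's rows (at
    prediction time such metabolites bypass the classifier and are called MNAR
    outright).  Deterministic under ``seed``.
    """
    tiers = tier_by_percent(complete, params)
    codes = {mid: c for c, mid in enumerate(sorted(complete.metabolite_ids))}
    frames = []
    for copy_idx in range(n_copies):
        spec = MissingnessSpec(
            rate=rate, params=params, seed=replicate_seed(seed, copy_idx)
        )
        masked = simulate_mm(complete, tiers, spec)
        full = masked.mask.all(axis=1)
        if full.any():
            keep = np.nonzero(~full)[0]
            remap = {int(old): new for new, old in enumerate(keep)}
            masked = MaskedMatrix(
                metabolite_ids=[masked.metabolite_ids[i] for i in keep],
                sample_ids=list(masked.sample_ids),
                values=masked.values[keep],
                mask=masked.mask[keep],
                labels={
                    (remap[i], j): mech
                    for (i, j), mech in masked.labels.items()
                    if i in remap
                },
            )
            draw_tiers = TierAssignment(
                metabolite_ids=list(masked.metabolite_ids),
                tiers=tiers.tiers[keep],
                rule=tiers.rule,
            )
        else:
            draw_tiers = tiers
        frames.append(extract_features(masked, draw_tiers, metabolite_codes=codes).frame)
    frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return FeatureTable(frame=frame, metabolite_codes=codes)
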