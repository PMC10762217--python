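"""Left-panning of missing data and extraction of the maximal complete subset.

Panning shifts each metabolite's observed values to the leftmost columns so the
missing cells collect on the right; the first ``w`` columns, where ``w`` is the
smallest per-metabolite observed count, then form the largest complete
left-aligned block (the pipeline's ``X^Complete``).  The 80% rule drops
metabolites missing in more than 20% of samples, which widens that block when
the retained sample count would otherwise be too small.
"""

from __future__ import annotations

import numpy as np

from .core_io import AbundanceMatrix, MaskedMatrix, MatrixError


def pan_left(masked: MaskedMatrix) -> MaskedMatrix:
    """Shift observed values left within each row, preserving their order.

    Column identity stops being meaningful, so mechanism labels (tied to cell
    coordinates) are dropped.
    """
    m, n = masked.shape
    values = np.full((m, n), np.nan)
    mask = np.ones((m, n), dtype=bool)
    for i in range(m):
        obs = masked.values[i, ~masked.mask[i]]
        values[i, : obs.size] = obs
        mask[i, : obs.size] = False
    return MaskedMatrix(
        metabolite_ids=list(masked.metabolite_ids),
        sample_ids=list(masked.sample_ids),
        values=values,
        mask=mask,
    )


def max_complete_subset(panned: MaskedMatrix) -> AbundanceMatrix:
    """First ``w`` columns of a left-panned matrix, w = min per-row observed count."""
    obs_counts = (~panned.mask).sum(axis=1)
    # left-panned means each row's observed cells are a prefix
    for i, c in enumerate(obs_counts):
        if panned.mask[i, :c].any():
            raise MatrixError("input is not left-panned; call pan_left first")
    w = int(obs_counts.min())
    if w == 0:
        worst = panned.metabolite_ids[int(np.argmin(obs_counts))]
        raise MatrixError(
            f"metabolite '{worst}' has no observed values; "
            "apply the 80% rule (eighty_percent_filter) before subset extraction"
        )
    return AbundanceMatrix(
        metabolite_ids=list(panned.metabolite_ids),
        sample_ids=list(panned.sample_ids[:w]),
        values=np.nan_to_num(panned.values[:, :w], copy=True),
    )


def eighty_percent_filter(masked: MaskedMatrix) -> MaskedMatrix:
    """Drop metabolites whose missing count strictly exceeds 20% of samples."""
    n = len(masked.sample_ids)
    keep = masked.mask.sum(axis=1) <= 0.2 * n
    if not keep.any():
        raise MatrixError("80% rule removed every metabolite")
    idx = np.nonzero(keep)[0]
    labels = None
    if masked.labels is not None:
        remap = {int(old): new for new, old in enumerate(idx)}
        labels = {
            (remap[i], j): mech
            for (i, j), mech in masked.labels.items()
            if i in remap
        }
    return MaskedMatrix(
        metabolite_ids=[masked.metabolite_ids[i] for i in idx],
        sample_ids=list(masked.sample_ids),
        values=masked.values[idx],
        mask=masked.mask[idx],
        labels=labels,
    )
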