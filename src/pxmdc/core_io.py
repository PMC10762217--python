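"""Domain types for abundance matrices with missing values, plus CSV/TSV readers.

The central objects are :class:`AbundanceMatrix` (a complete metabolites x samples
table of nonnegative abundances) and :class:`MaskedMatrix` (the same table with a
boolean missing mask and, for simulated data, a per-missing-cell mechanism label,
``"MNAR"`` or ``"MCAR"``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

MNAR = "MNAR"
MCAR = "MCAR"
MECHANISMS = (MCAR, MNAR)

DEFAULT_NA_TOKENS = frozenset({"", "NA", "NaN"})


class MatrixError(ValueError):
    """Raised for malformed matrices (duplicate ids, bad shapes, bad values)."""


class ParseError(MatrixError):
    """Raised when a cell cannot be parsed as a nonnegative abundance."""


def _check_ids(ids: list[str], kind: str) -> None:
    if len(ids) == 0:
        raise MatrixError(f"matrix must have at least one {kind}")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MatrixError(f"duplicate {kind} identifiers: {dupes}")


@dataclass(frozen=True)
class AbundanceMatrix:
    """Complete metabolites x samples abundance table. All values >= 0, no gaps."""

    metabolite_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_ids(self.metabolite_ids, "metabolite")
        _check_ids(self.sample_ids, "sample")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.metabolite_ids), len(self.sample_ids)):
            raise MatrixError(
                f"values shape {values.shape} does not match "
                f"{len(self.metabolite_ids)} metabolites x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise MatrixError("complete matrix may not contain NaN/inf")
        if np.any(values < 0):
            raise MatrixError("abundances must be nonnegative")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.metabolite_ids, columns=self.sample_ids
        )

    def as_masked(self) -> "MaskedMatrix":
        """View this complete matrix as a MaskedMatrix with an all-false mask."""
        return MaskedMatrix(
            metabolite_ids=list(self.metabolite_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            mask=np.zeros(self.values.shape, dtype=bool),
        )


@dataclass(frozen=True)
class MaskedMatrix:
    """Abundance table with a missing mask and optional per-cell mechanism labels.

    ``values[i, j]`` is NaN wherever ``mask[i, j]`` is True and a nonnegative real
    elsewhere.  ``labels``, when present, maps each masked coordinate ``(i, j)`` to
    its mechanism ("MNAR" or "MCAR") and covers exactly the masked set.
    """

    metabolite_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    labels: Mapping[tuple[int, int], str] | None = field(default=None)

    def __post_init__(self) -> None:
        _check_ids(self.metabolite_ids, "metabolite")
        _check_ids(self.sample_ids, "sample")
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        shape = (len(self.metabolite_ids), len(self.sample_ids))
        if values.shape != shape or mask.shape != shape:
            raise MatrixError("values/mask shape does not match identifier lists")
        observed = values[~mask]
        if not np.all(np.isfinite(observed)) or np.any(observed < 0):
            raise MatrixError("observed cells must be finite and nonnegative")
        values = values.copy()
        values[mask] = np.nan
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        if self.labels is not None:
            masked_set = {tuple(c) for c in np.argwhere(mask)}
            label_set = set(self.labels)
            if label_set != masked_set:
                raise MatrixError(
                    "labels must cover exactly the masked cells "
                    f"({len(label_set)} labels vs {len(masked_set)} masked)"
                )
            bad = {v for v in self.labels.values() if v not in MECHANISMS}
            if bad:
                raise MatrixError(f"unknown mechanisms: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def missing_rate(self) -> float:
        return float(self.mask.mean())

    def to_complete(self) -> AbundanceMatrix:
        if self.mask.any():
            raise MatrixError("matrix has missing cells; cannot view as complete")
        return AbundanceMatrix(
            metabolite_ids=list(self.metabolite_ids),
            sample_ids=list(self.sample_ids),
            values=np.nan_to_num(self.values, copy=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.metabolite_ids, columns=self.sample_ids
        )

    def labels_frame(self) -> pd.DataFrame:
        """Long-format (metabolite_id, sample_id, mechanism) table of the labels."""
        if self.labels is None:
            raise MatrixError("matrix carries no mechanism labels")
        rows = [
            (self.metabolite_ids[i], self.sample_ids[j], mech)
            for (i, j), mech in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["metabolite_id", "sample_id", "mechanism"])


@dataclass(frozen=True)
class ThresholdParams:
    """Concentration-tier thresholds and MNAR share.

    ``x``, ``y``, ``z`` are the percentages of metabolites assigned to the HIGH,
    MEDIUM and LOW concentration tiers (x + y + z = 100); ``alpha`` is the fraction
    of all missing cells that are MNAR (left-censored low-tier values).
    """

    x: float
    y: float
    z: float
    alpha: float

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 0:
            raise ValueError("tier percentages must be nonnegative")
        if abs(self.x + self.y + self.z - 100.0) > 1e-9:
            raise ValueError(
                f"tier percentages must sum to 100, got {self.x + self.y + self.z}"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.z, self.alpha)


@dataclass(frozen=True)
class MissingnessSpec:
    """How much missingness to inject: overall rate, thresholds, RNG seed."""

    rate: float
    params: ThresholdParams
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError(f"missing rate must lie in [0, 1), got {self.rate}")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_matrix(
    path: str | Path, na_tokens: frozenset[str] | set[str] = DEFAULT_NA_TOKENS
) -> MaskedMatrix:
    """Read a CSV/TSV abundance matrix (metabolite rows, sample columns).

    Cells matching an NA token are masked; all other cells must parse as
    nonnegative reals. Delimiter is sniffed from the header line.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        sample_ids = [c.strip() for c in header[1:]]
        metabolite_ids: list[str] = []
        rows: list[list[float]] = []
        mask_rows: list[list[bool]] = []
        for record in reader:
            if not record or (len(record) == 1 and not record[0].strip()):
                continue
            met = record[0].strip()
            metabolite_ids.append(met)
            if len(record) - 1 != len(sample_ids):
                raise ParseError(
                    f"{path}: row '{met}' has {len(record) - 1} cells, "
                    f"expected {len(sample_ids)}"
                )
            vals, miss = [], []
            for sample, cell in zip(sample_ids, record[1:]):
                token = cell.strip()
                if token in na_tokens:
                    vals.append(np.nan)
                    miss.append(True)
                    continue
                try:
                    v = float(token)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell '{token}' at "
                        f"row '{met}', column '{sample}'"
                    ) from None
                if not np.isfinite(v) or v < 0:
                    raise ParseError(
                        f"{path}: negative or non-finite abundance {token!r} at "
                        f"row '{met}', column '{sample}'"
                    )
                vals.append(v)
                miss.append(False)
            rows.append(vals)
            mask_rows.append(miss)
    return MaskedMatrix(
        metabolite_ids=metabolite_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float).reshape(len(metabolite_ids), len(sample_ids)),
        mask=np.array(mask_rows, dtype=bool).reshape(len(metabolite_ids), len(sample_ids)),
    )


def write_matrix(matrix: MaskedMatrix, path: str | Path, na_token: str = "NA") -> None:
    """Write a matrix as CSV (TSV if the path ends in .tsv); masked cells -> na_token.

    Round-trips through :func:`read_matrix`: mask and values are reproduced exactly
    (values are serialized with repr precision).
    """
    path = Path(path)
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["metabolite_id", *matrix.sample_ids])
        for i, met in enumerate(matrix.metabolite_ids):
            row = [
                na_token if matrix.mask[i, j] else repr(float(matrix.values[i, j]))
                for j in range(len(matrix.sample_ids))
            ]
            writer.writerow([met, *row])
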