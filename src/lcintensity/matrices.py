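"""Area transition matrices and series of them.

A :class:`TransitionMatrix` holds the square cross-tabulation ``C[i, j]`` —
the area (km²) that moved from category *i* (rows, start date) to category
*j* (columns, end date) within one stratum during one time interval. A
:class:`MatrixSeries` collects one matrix per (stratum, interval) over a
contiguous interval schedule; it is the sole input the intensity statistics
need, which makes pre-computed matrix tables a first-class entry point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .scheme import CategoryScheme

#: Stratum label used for whole-domain (aggregated) matrices.
ALL_STRATA = "ALL"


@dataclass
class TransitionMatrix:
    """Square area cross-tabulation for one stratum and one interval.

    Parameters
    ----------
    values
        ``(J, J)`` array of areas in km²; ``values[i, j]`` is area moving
        from category ``labels[i]`` to ``labels[j]``. Diagonal = persistence.
    labels
        Category short labels in scheme order.
    from_year, to_year
        Interval bounds; duration is ``to_year - from_year`` years.
    stratum
        Stratum label, or :data:`ALL_STRATA` for a whole-domain matrix.
    """

    values: np.ndarray
    labels: list[str]
    from_year: int
    to_year: int
    stratum: str = ALL_STRATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {self.values.shape}")
        if self.values.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for a {self.values.shape[0]}x"
                f"{self.values.shape[1]} matrix"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative area at ({self.labels[bad[0]]}, {self.labels[bad[1]]})"
            )
        if self.to_year <= self.from_year:
            raise ValueError(f"interval {self.from_year}-{self.to_year} has non-positive duration")

    # -- derived quantities ----------------------------------------------------

    @property
    def duration(self) -> int:
        return self.to_year - self.from_year

    @property
    def interval(self) -> tuple[int, int]:
        return (self.from_year, self.to_year)

    @property
    def interval_label(self) -> str:
        return f"{self.from_year}-{self.to_year}"

    @property
    def start_sizes(self) -> np.ndarray:
        """Category areas at the start of the interval (row sums)."""
        return self.values.sum(axis=1)

    @property
    def end_sizes(self) -> np.ndarray:
        """Category areas at the end of the interval (column sums)."""
        return self.values.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.values.sum())

    @property
    def _offdiag(self) -> np.ndarray:
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        return off

    @property
    def gross_change(self) -> float:
        """Total off-diagonal area — everything that changed category."""
        return float(self._offdiag.sum())

    def gains(self) -> np.ndarray:
        """Per-category gross gain area (column sum excluding the diagonal)."""
        return self._offdiag.sum(axis=0)

    def losses(self) -> np.ndarray:
        """Per-category gross loss area (row sum excluding the diagonal)."""
        return self._offdiag.sum(axis=1)

    def entry(self, frm: str, to: str) -> float:
        return float(self.values[self.labels.index(frm), self.labels.index(to)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def relabel(self, stratum: str) -> "TransitionMatrix":
        return replace(self, values=self.values.copy(), stratum=stratum)

    def __add__(self, other: "TransitionMatrix") -> "TransitionMatrix":
        if self.labels != other.labels or self.interval != other.interval:
            raise ValueError("can only add matrices with identical labels and interval")
        return TransitionMatrix(
            self.values + other.values, list(self.labels), self.from_year, self.to_year, ALL_STRATA
        )


def sum_strata(matrices: list[TransitionMatrix]) -> TransitionMatrix:
    """Element-wise sum of per-stratum matrices for one interval.

    All inputs must share labels and interval bounds and carry distinct
    stratum labels; the result is labelled :data:`ALL_STRATA`. Order of the
    inputs does not matter.
    """
    if not matrices:
        raise ValueError("no matrices to sum")
    first = matrices[0]
    strata = [m.stratum for m in matrices]
    if len(set(strata)) != len(strata):
        raise ValueError(f"duplicate stratum labels in sum: {strata}")
    for m in matrices[1:]:
        if m.labels != first.labels:
            raise ValueError("scheme (label) mismatch across strata")
        if m.interval != first.interval:
            raise ValueError(
                f"interval mismatch: {m.interval_label} vs {first.interval_label}"
            )
    # canonical (label-sorted) summation order: result is bit-identical
    # under any permutation of the inputs
    ordered = sorted(matrices, key=lambda m: m.stratum)
    total = np.sum([m.values for m in ordered], axis=0)
    return TransitionMatrix(total, list(first.labels), first.from_year, first.to_year, ALL_STRATA)


# ---------------------------------------------------------------------------
# Matrix table I/O: wide CSV (first column "from", header = "to" labels) with
# a JSON sidecar {from_year, to_year, stratum}; long format (from,to,area_km2)
# accepted on read.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_matrix_table(matrix: TransitionMatrix, path: str | Path) -> None:
    """Write a matrix as wide CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "from"
    df.to_csv(path, float_format="%.10g")
    meta = {
        "from_year": matrix.from_year,
        "to_year": matrix.to_year,
        "stratum": matrix.stratum,
        "labels": matrix.labels,
        "units": "km2",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_matrix_table(
    path: str | Path,
    scheme: CategoryScheme | None = None,
    *,
    from_year: int | None = None,
    to_year: int | None = None,
    stratum: str | None = None,
) -> TransitionMatrix:
    """Read a wide or long matrix table.

    Metadata comes from the JSON sidecar when present; explicit keyword
    arguments override it. When a ``scheme`` is given, labels are checked
    against it and the matrix is re-ordered (and zero-padded) to full
    scheme order, so tables that omit absent categories still line up.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    from_year = from_year if from_year is not None else meta.get("from_year")
    to_year = to_year if to_year is not None else meta.get("to_year")
    stratum = stratum if stratum is not None else meta.get("stratum", ALL_STRATA)
    if from_year is None or to_year is None:
        raise ValueError(f"{path}: from_year/to_year not in sidecar nor arguments")

    df = pd.read_csv(path, dtype={0: str})
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    long_cols = {"from", "to"}
    if long_cols.issubset({c.lower() for c in cols}) and len(cols) <= 4:
        df.columns = [c.lower() for c in cols]
        area_col = next(c for c in df.columns if c not in long_cols)
        wide = df.pivot_table(
            index="from", columns="to", values=area_col, aggfunc="sum", fill_value=0.0
        )
        labels = sorted(set(wide.index) | set(wide.columns))
        wide = wide.reindex(index=labels, columns=labels, fill_value=0.0)
    else:
        wide = df.set_index(cols[0]).astype(float)
        wide.index = wide.index.astype(str).str.strip()
        if list(wide.index) != list(wide.columns):
            raise ValueError(
                f"{path}: non-square table (rows {list(wide.index)} vs "
                f"columns {list(wide.columns)})"
            )
        labels = list(wide.index)

    if (wide.values < 0).any():
        i, j = np.argwhere(wide.values < 0)[0]
        raise ValueError(f"{path}: negative area at ({labels[i]}, {labels[j]})")

    if scheme is not None:
        unknown = [lab for lab in labels if lab not in scheme.abbrevs]
        if unknown:
            raise ValueError(f"{path}: unknown category label {unknown[0]!r}")
        wide = wide.reindex(index=scheme.abbrevs, columns=scheme.abbrevs, fill_value=0.0)
        labels = list(scheme.abbrevs)

    return TransitionMatrix(wide.values, labels, int(from_year), int(to_year), stratum)


# ---------------------------------------------------------------------------
# Series
# ---------------------------------------------------------------------------


@dataclass
class MatrixSeries:
    """Per-stratum transition matrices over a contiguous interval schedule.

    ``matrices[stratum][t]`` is the matrix of interval ``intervals[t]``.
    Construction checks hard invariants (shared labels, matching interval
    schedule per stratum); soft ones (contiguity, constant area) are the
    domain of :func:`validate_series` so that slightly dirty real data can
    still be loaded and inspected.
    """

    scheme: CategoryScheme
    intervals: list[tuple[int, int]]
    matrices: dict[str, list[TransitionMatrix]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.scheme.abbrevs
        for stratum, mats in self.matrices.items():
            if len(mats) != len(self.intervals):
                raise ValueError(
                    f"stratum {stratum!r}: {len(mats)} matrices for "
                    f"{len(self.intervals)} intervals"
                )
            for m, iv in zip(mats, self.intervals):
                if m.interval != iv:
                    raise ValueError(
                        f"stratum {stratum!r}: matrix interval {m.interval_label} "
                        f"!= schedule {iv[0]}-{iv[1]}"
                    )
                if m.labels != labels:
                    raise ValueError(f"stratum {stratum!r}: label mismatch with scheme")

    @property
    def strata(self) -> list[str]:
        return list(self.matrices.keys())

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def years(self) -> list[int]:
        return [self.intervals[0][0]] + [iv[1] for iv in self.intervals]

    def stratum_series(self, stratum: str) -> list[TransitionMatrix]:
        if stratum == ALL_STRATA and ALL_STRATA not in self.matrices:
            return self.aggregate()
        return self.matrices[stratum]

    def aggregate(self) -> list[TransitionMatrix]:
        """Whole-domain matrix per interval (sum over strata)."""
        return [
            sum_strata([self.matrices[s][t] for s in self.strata])
            for t in range(self.n_intervals)
        ]

    def interval_index(self, interval: tuple[int, int]) -> int:
        return self.intervals.index(tuple(interval))

    @classmethod
    def from_matrices(
        cls, scheme: CategoryScheme, mats: list[TransitionMatrix]
    ) -> "MatrixSeries":
        """Group a flat list of matrices by stratum, ordering intervals by year."""
        intervals = sorted({m.interval for m in mats})
        by_stratum: dict[str, dict[tuple[int, int], TransitionMatrix]] = {}
        for m in mats:
            by_stratum.setdefault(m.stratum, {})[m.interval] = m
        grouped = {}
        for stratum, d in by_stratum.items():
            missing = [iv for iv in intervals if iv not in d]
            if missing:
                raise ValueError(f"stratum {stratum!r} missing intervals {missing}")
            grouped[stratum] = [d[iv] for iv in intervals]
        return cls(scheme, intervals, grouped)


@dataclass
class ValidationIssue:
    kind: str  # "gap" | "overlap" | "scheme" | "area_drift" | "negative"
    message: str
    severity: str = "warning"  # or "error"


def validate_series(series: MatrixSeries, area_rtol: float = 1e-6) -> list[ValidationIssue]:
    """Report soft-invariant violations of a series; empty list iff clean.

    Checks interval contiguity (gaps/overlaps), per-stratum area drift
    (relative deviation of total area across intervals beyond ``area_rtol``)
    and negative entries. Area drift is a warning, not an error: masking in
    real products rarely leaves totals exactly constant.
    """
    issues: list[ValidationIssue] = []
    for (f0, t0), (f1, t1) in zip(series.intervals, series.intervals[1:]):
        if t0 < f1:
            issues.append(ValidationIssue("gap", f"gap between {t0} and {f1}", "error"))
        elif t0 > f1:
            issues.append(
                ValidationIssue("overlap", f"intervals {f0}-{t0} and {f1}-{t1} overlap", "error")
            )
    for stratum in series.strata:
        totals = np.array([m.total_area for m in series.matrices[stratum]])
        if np.any([np.any(m.values < 0) for m in series.matrices[stratum]]):
            issues.append(ValidationIssue("negative", f"negative entries in {stratum}", "error"))
        if totals.max() > 0:
            drift = float((totals.max() - totals.min()) / totals.max())
            if drift > area_rtol:
                issues.append(
                    ValidationIssue(
                        "area_drift",
                        f"stratum {stratum!r}: total area varies by "
                        f"{drift * 100:.3g}% across intervals",
                    )
                )
    return issues
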