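"""Tabular I/O for survival curves, dose-response matrices, and fit reports.

Survival curves come from digitized progression-free-survival plots, so the
reader tolerates small non-monotonicities (digitizer noise) and both 0-1 and
0-100 survival scales.  Dose matrices are plate-reader viability tables
normalized to untreated controls, so values slightly above 1 are allowed.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SurvivalTable",
    "TrialSet",
    "DoseMatrix",
    "monotonize",
    "read_survival_table",
    "read_dose_matrix",
    "write_survival_table",
    "write_dose_matrix",
    "write_fit_report",
    "read_fit_report",
]

#: Largest allowed upward excursion of a raw digitized survival point above
#: the running minimum before the curve is rejected instead of monotonized.
MONOTONE_TOL = 0.02

#: Survival/viability columns whose maximum exceeds this are taken to be on
#: a 0-100 percent scale and divided by 100.
PERCENT_SCALE_CUTOFF = 1.5


class FormatError(ValueError):
    """The file does not have the expected tabular layout."""


class ValidationError(ValueError):
    """The file parses but its values violate a domain invariant."""


@dataclass(frozen=True)
class SurvivalTable:
    """One trial arm's survival curve: S(t) on a strictly increasing time grid.

    Parameters
    ----------
    times
        Time points in months, strictly increasing, non-negative.
    survival
        Surviving fraction at each time, in [0, 1], non-increasing.
    n_patients
        Cohort size behind the curve; required for bootstrap resampling and
        goodness-of-fit, optional otherwise.
    label
        Free-text arm identifier.
    """

    times: np.ndarray
    survival: np.ndarray
    n_patients: int | None = None
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        survival = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", survival)
        if times.ndim != 1 or survival.shape != times.shape:
            raise ValidationError("times and survival must be 1-D and equal length")
        if times.size < 1:
            raise ValidationError("empty survival table")
        if np.any(times < 0):
            raise ValidationError("negative times")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any((survival < 0) | (survival > 1)):
            raise ValidationError("survival values outside [0, 1]")
        if np.any(np.diff(survival) > 0):
            raise ValidationError(
                "survival must be non-increasing (monotonize raw input first)"
            )
        if self.n_patients is not None and self.n_patients <= 0:
            raise ValidationError("n_patients must be a positive integer")

    @property
    def max_time(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TrialSet:
    """The three arms of one combination trial: drug A, drug B, and A+B."""

    arm_A: SurvivalTable
    arm_B: SurvivalTable
    arm_AB: SurvivalTable
    combination_id: str = ""

    def __post_init__(self):
        labels = [self.arm_A.label, self.arm_B.label, self.arm_AB.label]
        if any(labels) and len(set(labels)) != 3:
            raise ValidationError("arm labels must be distinct when given")

    @property
    def arms(self) -> tuple[SurvivalTable, SurvivalTable, SurvivalTable]:
        return (self.arm_A, self.arm_B, self.arm_AB)


@dataclass(frozen=True)
class DoseMatrix:
    """A two-drug viability screen: dose grids, combination matrix, monotherapies.

    ``viability[i, j]`` is the observed combination viability at
    ``doses_A[i]`` of drug A and ``doses_B[j]`` of drug B.  ``mono_A`` /
    ``mono_B`` are the single-drug viabilities on the respective dose grids.
    When a screen lacks true monotherapy rows, the reader approximates them
    by the matrix slice at the other drug's lowest dose and sets
    ``mono_approximated``.
    """

    doses_A: np.ndarray
    doses_B: np.ndarray
    viability: np.ndarray
    mono_A: np.ndarray
    mono_B: np.ndarray
    treatment_time_h: float | None = None
    combination_id: str = ""
    mono_approximated: bool = False

    def __post_init__(self):
        for name in ("doses_A", "doses_B", "viability", "mono_A", "mono_B"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name, doses in (("doses_A", self.doses_A), ("doses_B", self.doses_B)):
            if doses.ndim != 1 or doses.size < 2:
                raise ValidationError(f"{name} must be a vector of >=2 doses")
            if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
                raise ValidationError(f"{name} must be non-negative, strictly increasing")
        if self.viability.shape != (self.doses_A.size, self.doses_B.size):
            raise ValidationError("viability matrix shape does not match dose grids")
        if np.any((self.viability < 0) | (self.viability > 1.5)):
            raise ValidationError("viability values outside [0, 1.5]")
        if self.mono_A.shape != self.doses_A.shape:
            raise ValidationError("mono_A length does not match doses_A")
        if self.mono_B.shape != self.doses_B.shape:
            raise ValidationError("mono_B length does not match doses_B")

    @property
    def shape(self) -> tuple[int, int]:
        return self.viability.shape


def monotonize(values: np.ndarray, tol: float = MONOTONE_TOL) -> np.ndarray:
    """Force a digitized survival sequence to be non-increasing.

    Applies a running minimum from the left.  Any raw point exceeding the
    running minimum by more than ``tol`` is treated as real data corruption
    rather than digitizer jitter and raises :class:`ValidationError`.
    Idempotent, and never increases any value.
    """
    values = np.asarray(values, dtype=float)
    runmin = np.minimum.accumulate(values)
    if np.any(values > runmin + tol):
        worst = float(np.max(values - runmin))
        raise ValidationError(
            f"survival increases by {worst:.3g} > {tol} above the running minimum"
        )
    return runmin


def read_survival_table(
    path: str | Path,
    n_patients: int | None = None,
    label: str = "",
) -> SurvivalTable:
    """Read one arm's survival curve from a two-column CSV.

    Expected columns are ``time_months,survival``; a headerless or
    differently named two-column file is accepted positionally.  Survival on
    a 0-100 percent scale is auto-detected (max > 1.5) and rescaled.  Rows
    are sorted by time, duplicate times collapsed to their minimum survival,
    and the curve monotonized (running minimum, 0.02 jitter allowance).
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip().lower() if isinstance(c, str) else c for c in df.columns]
    if "time_months" in cols and "survival" in cols:
        time = df.iloc[:, cols.index("time_months")]
        surv = df.iloc[:, cols.index("survival")]
    elif df.shape[1] == 2:
        # positional fallback; a headerless file parses its first row as a
        # header, so recover it if numeric
        time, surv = df.iloc[:, 0], df.iloc[:, 1]
        try:
            first = [float(df.columns[0]), float(df.columns[1])]
            time = pd.concat([pd.Series([first[0]]), time], ignore_index=True)
            surv = pd.concat([pd.Series([first[1]]), surv], ignore_index=True)
        except (TypeError, ValueError):
            pass
    else:
        raise FormatError(
            f"{path}: expected columns 'time_months,survival', got {list(df.columns)}"
        )
    time = pd.to_numeric(time, errors="coerce")
    surv = pd.to_numeric(surv, errors="coerce")
    if time.isna().any() or surv.isna().any():
        raise FormatError(f"{path}: non-numeric or missing values")
    times = time.to_numpy(dtype=float)
    survival = surv.to_numpy(dtype=float)

    if np.any(times < 0):
        raise ValidationError(f"{path}: negative times")
    scale = 100.0 if np.nanmax(survival) > PERCENT_SCALE_CUTOFF else 1.0
    if np.any(survival < -MONOTONE_TOL * scale) or np.any(survival > 1.02 * scale):
        raise ValidationError(f"{path}: survival outside [-0.02, 1.02] x scale")
    survival = survival / scale

    order = np.argsort(times, kind="stable")
    times, survival = times[order], survival[order]
    # collapse duplicate times to their minimum survival
    uniq, inverse = np.unique(times, return_inverse=True)
    collapsed = np.full(uniq.size, np.inf)
    np.minimum.at(collapsed, inverse, survival)
    survival = np.clip(monotonize(collapsed), 0.0, 1.0)
    return SurvivalTable(uniq, survival, n_patients=n_patients, label=label)


def read_dose_matrix(
    path: str | Path,
    treatment_time_h: float | None = None,
    combination_id: str = "",
) -> DoseMatrix:
    """Read a combination viability matrix from CSV.

    Layout: header row ``dose_A\\dose_B,<b1>,<b2>,...`` followed by one row
    per drug-A dose.  If both dose grids start at 0, the zero-dose row and
    column are taken as explicit monotherapy measurements; otherwise the
    monotherapies are approximated by the matrix slice at the other drug's
    lowest tested dose and ``mono_approximated`` is set.
    """
    try:
        df = pd.read_csv(path, comment="#", index_col=0)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise FormatError(f"{path}: dose matrix must be at least 2x2")
    try:
        doses_B = np.array([float(c) for c in df.columns])
        doses_A = np.array([float(r) for r in df.index])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric dose labels") from exc
    viability = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(viability).any():
        i, j = np.argwhere(np.isnan(viability))[0]
        raise FormatError(
            f"{path}: blank or non-numeric cell at dose_A={doses_A[i]:g}, "
            f"dose_B={doses_B[j]:g}"
        )
    if np.any(np.diff(doses_A) <= 0) or np.any(np.diff(doses_B) <= 0):
        raise FormatError(f"{path}: dose grids must be strictly increasing")

    explicit_mono = doses_A[0] == 0.0 and doses_B[0] == 0.0
    mono_A = viability[:, 0]
    mono_B = viability[0, :]
    return DoseMatrix(
        doses_A=doses_A,
        doses_B=doses_B,
        viability=viability,
        mono_A=mono_A,
        mono_B=mono_B,
        treatment_time_h=treatment_time_h,
        combination_id=combination_id,
        mono_approximated=not explicit_mono,
    )


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    """Write a survival curve as ``time_months,survival`` CSV."""
    df = pd.DataFrame({"time_months": table.times, "survival": table.survival})
    df.to_csv(path, index=False)


def write_dose_matrix(matrix: DoseMatrix, path: str | Path) -> None:
    """Write a dose matrix in the header-row/index-column CSV layout.

    When the matrix carries true (non-approximated) monotherapy vectors and
    its dose grids do not start at zero, the monotherapies are embedded as
    an explicit dose-0 row and column (with viability 1 at the 0,0 corner)
    so that :func:`read_dose_matrix` recovers them exactly.
    """
    doses_A, doses_B, viab = matrix.doses_A, matrix.doses_B, matrix.viability
    if not matrix.mono_approximated and doses_A[0] > 0 and doses_B[0] > 0:
        doses_A = np.concatenate([[0.0], doses_A])
        doses_B = np.concatenate([[0.0], doses_B])
        top = np.concatenate([[1.0], matrix.mono_B])
        left = matrix.mono_A[:, None]
        viab = np.vstack([top, np.hstack([left, viab])])
    df = pd.DataFrame(viab, index=doses_A, columns=doses_B)
    df.index.name = "dose_A\\dose_B"
    df.to_csv(path)


def _jsonable(obj):
    """Recursively convert a fit result to JSON-serializable values."""
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        if np.isnan(obj):
            warnings.warn("NaN statistic serialized as null", stacklevel=3)
            return None
        return obj
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in items]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj):
        out = {"_type": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = _jsonable(getattr(obj, f.name))
        return out
    return _jsonable(vars(obj))


def write_fit_report(fit, path: str | Path) -> None:
    """Serialize a tCDA or dCDA fit result to JSON.

    Undefined statistics (NaN) become ``null`` with a warning; matrices are
    stored row-major as nested arrays alongside their dose/time grids so the
    report round-trips losslessly through :func:`read_fit_report`.
    """
    payload = _jsonable(fit)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_fit_report(path: str | Path) -> dict:
    """Read back a JSON fit report as a plain nested dict."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
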