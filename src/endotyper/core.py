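"""Domain types, derived-variable formulas and normalization for haemodynamic data.

A cohort is represented as a tidy :class:`pandas.DataFrame` with one row per
20-s data point and canonical short column names::

    patient_id, time_s, map, svi, hr, svv, dpdt, quality_ok, ci, svri

``ci`` (cardiac index, L min⁻¹ m⁻²) and ``svri`` (systemic vascular
resistance index, dyn s cm⁻⁵ m²) are always derived from the measured
variables, never read from disk.  The on-disk CSV schema uses explicit
unit-suffixed names (``map_mmhg``, ``svi_ml_m2``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateDataError, DomainError

#: Variables used for clustering, in canonical order.
CLUSTER_VARS: tuple[str, ...] = ("svi", "hr", "svri", "svv")

#: Variables reported in endotype summary tables (original units).
SUMMARY_VARS: tuple[str, ...] = ("svi", "hr", "svri", "svv", "ci", "dpdt")

#: CSV column name -> canonical short name.
CSV_COLUMNS: dict[str, str] = {
    "patient_id": "patient_id",
    "time_s": "time_s",
    "map_mmhg": "map",
    "svi_ml_m2": "svi",
    "hr_bpm": "hr",
    "svv_pct": "svv",
    "dpdt_mmhg_s": "dpdt",
    "quality_ok": "quality_ok",
}

_REQUIRED_CSV = ("patient_id", "time_s", "map_mmhg", "svi_ml_m2", "hr_bpm", "svv_pct")


@dataclass(frozen=True)
class DerivationConfig:
    """Parameters of the derived-variable formulas.

    Central venous pressure (CVP) is not measured by arterial-line
    monitoring, so SVRI is computed with an assumed constant CVP.
    """

    cvp_mmhg: float = 5.0

    def __post_init__(self) -> None:
        if self.cvp_mmhg < 0:
            raise DomainError(f"cvp_mmhg must be >= 0, got {self.cvp_mmhg}")


def compute_ci(svi, hr):
    """Cardiac index CI = SVI x HR / 1000 (L min⁻¹ m⁻²).

    Parameters are stroke volume index (ml m⁻²) and heart rate
    (beats min⁻¹); scalars or arrays.
    """
    svi = np.asarray(svi, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(svi <= 0) or np.any(hr <= 0):
        raise DomainError("compute_ci requires svi > 0 and hr > 0")
    out = svi * hr / 1000.0
    return out if out.ndim else float(out)


def compute_svri(map_mmhg, ci, cfg: DerivationConfig = DerivationConfig()):
    """Systemic vascular resistance index SVRI = 80 (MAP − CVP) / CI.

    Units: mmHg, L min⁻¹ m⁻² in; dyn s cm⁻⁵ m² out.
    """
    map_mmhg = np.asarray(map_mmhg, dtype=float)
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise DomainError("compute_svri requires ci > 0")
    if np.any(map_mmhg <= cfg.cvp_mmhg):
        raise DomainError(
            f"compute_svri requires map > cvp ({cfg.cvp_mmhg} mmHg)"
        )
    out = 80.0 * (map_mmhg - cfg.cvp_mmhg) / ci
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-variable mean/sd used to z-score the clustering variables.

    The sample standard deviation uses the n−1 denominator.  Fitted on a
    development dataset these parameters are part of the persisted model and
    are reused verbatim when the model is applied to new data.
    """

    mean: np.ndarray
    sd: np.ndarray
    variables: tuple[str, ...] = CLUSTER_VARS

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise DataError("mean and sd must be 1-D arrays of equal length")
        if len(self.variables) != self.mean.size:
            raise DataError("variables and parameter vectors disagree in length")
        if np.any(self.sd <= 0) or not np.all(np.isfinite(self.sd)):
            raise DegenerateDataError("all standard deviations must be > 0 and finite")

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(mean=np.array(d["mean"]), sd=np.array(d["sd"]), variables=tuple(d["variables"]))


def _as_matrix(points, variables: tuple[str, ...]) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        X = points.loc[:, list(variables)].to_numpy(dtype=float)
    else:
        X = np.asarray(points, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != len(variables):
        raise DataError(f"expected {len(variables)} columns, got {X.shape[1]}")
    return X


def fit_normalizer(points, variables: tuple[str, ...] = CLUSTER_VARS) -> NormalizationParams:
    """Fit per-variable z-scoring so each clustering variable gets equal weight.

    ``points`` is an (n, 4) array or a DataFrame holding ``variables``.
    Raises :class:`DegenerateDataError` on a zero-variance variable rather
    than silently dividing by zero.
    """
    X = _as_matrix(points, variables)
    if X.shape[0] < 2:
        raise DegenerateDataError("need at least 2 points to fit a normalizer")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in normalizer input")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise DegenerateDataError(f"zero-variance variable(s): {bad}")
    return NormalizationParams(mean=mean, sd=sd, variables=variables)


def apply_normalizer(points, params: NormalizationParams) -> np.ndarray:
    """z = (x − mean) / sd, per variable."""
    X = _as_matrix(points, params.variables)
    return (X - params.mean) / params.sd


def invert_normalizer(z, params: NormalizationParams) -> np.ndarray:
    """Inverse of :func:`apply_normalizer`: x = z·sd + mean."""
    Z = np.asarray(z, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    return Z * params.sd + params.mean


def derive_variables(frame: pd.DataFrame, cfg: DerivationConfig = DerivationConfig()) -> pd.DataFrame:
    """Return a copy of ``frame`` with ``ci`` and ``svri`` (re)computed.

    Rows violating the formula domains (non-positive SVI/HR/CI, MAP at or
    below the assumed CVP) raise :class:`DomainError`.
    """
    out = frame.copy()
    out["ci"] = compute_ci(out["svi"].to_numpy(), out["hr"].to_numpy())
    out["svri"] = compute_svri(out["map"].to_numpy(), out["ci"].to_numpy(), cfg)
    return out


def validate_series_frame(frame: pd.DataFrame) -> None:
    """Check the per-patient grid invariants: strictly increasing times on a
    positive multiple of the 20-s grid."""
    for pid, g in frame.groupby("patient_id", sort=False):
        t = g["time_s"].to_numpy(dtype=float)
        if t.size == 0:
            continue
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError(f"patient {pid}: timestamps not strictly increasing")
        if np.any(np.abs(np.round(dt / 20.0) * 20.0 - dt) > 1e-9) or np.any(dt < 20.0 - 1e-9):
            raise DataError(f"patient {pid}: grid spacing must be a positive multiple of 20 s")


def load_cohort(path, cfg: DerivationConfig = DerivationConfig(), drop_poor_quality: bool = True) -> pd.DataFrame:
    """Read a cohort CSV, validate the grid, and compute derived variables.

    ``dpdt_mmhg_s`` and ``quality_ok`` are optional (``quality_ok`` defaults
    to 1).  Points flagged as poor quality are dropped before any analysis
    when ``drop_poor_quality`` is set.  Derived columns are always computed,
    never read.
    """
    raw = pd.read_csv(path)
    missing = [c for c in _REQUIRED_CSV if c not in raw.columns]
    if missing:
        raise DataError(f"cohort CSV missing required columns: {missing}")
    frame = pd.DataFrame(
        {short: raw[csv] for csv, short in CSV_COLUMNS.items() if csv in raw.columns}
    )
    if "dpdt" not in frame.columns:
        frame["dpdt"] = np.nan
    if "quality_ok" not in frame.columns:
        frame["quality_ok"] = 1
    frame["quality_ok"] = frame["quality_ok"].fillna(1).astype(int)
    validate_series_frame(frame)
    if drop_poor_quality:
        frame = frame.loc[frame["quality_ok"] == 1].reset_index(drop=True)
    return derive_variables(frame, cfg)


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort frame in the on-disk CSV schema (measured columns only)."""
    inv = {short: csv for csv, short in CSV_COLUMNS.items()}
    cols = [c for c in ("patient_id", "time_s", "map", "svi", "hr", "svv", "dpdt", "quality_ok") if c in frame.columns]
    out = frame.loc[:, cols].rename(columns=inv)
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class HaemoPoint:
    """One 20-s averaged haemodynamic data point.

    All physiological fields are strictly positive when present; SVV is a
    percentage in [0, 50].  ``ci`` and ``svri`` are derived quantities and,
    if supplied, must satisfy their defining identities.
    """

    time_s: float
    map: float
    svi: float
    hr: float
    svv: float
    dpdt: float | None = None
    ci: float | None = None
    svri: float | None = None
    quality_ok: bool = True
    cvp_mmhg: float = 5.0

    def __post_init__(self) -> None:
        for name in ("map", "svi", "hr"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if not (0 <= self.svv <= 50):
            raise DomainError("svv must lie in [0, 50] %")
        if self.dpdt is not None and self.dpdt <= 0:
            raise DomainError("dpdt must be strictly positive when present")
        if self.ci is not None:
            if self.ci <= 0 or abs(self.ci - self.svi * self.hr / 1000.0) >= 1e-9:
                raise DomainError("ci inconsistent with svi*hr/1000")
        if self.svri is not None:
            if self.ci is None:
                raise DomainError("svri requires ci")
            expected = 80.0 * (self.map - self.cvp_mmhg) / self.ci
            if self.svri <= 0 or abs(self.svri - expected) >= 1e-6:
                raise DomainError("svri inconsistent with 80*(map-cvp)/ci")


@dataclass
class HaemoSeries:
    """One patient's time-ordered series of 20-s points, held as a frame."""

    patient_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        t = f["time_s"].to_numpy(dtype=float)
        if t.size:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise DataError("timestamps not strictly increasing")
            if np.any(np.abs(np.round(dt / 20.0) * 20.0 - dt) > 1e-9) or np.any(dt < 20.0 - 1e-9):
                raise DataError("grid spacing must be a positive multiple of 20 s")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, patient_id=None) -> "HaemoSeries":
        if patient_id is None:
            ids = frame["patient_id"].unique()
            if len(ids) != 1:
                raise DataError("frame holds multiple patients; pass patient_id")
            patient_id = ids[0]
        sub = frame.loc[frame["patient_id"] == patient_id].reset_index(drop=True)
        return cls(patient_id=str(patient_id), frame=sub)
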