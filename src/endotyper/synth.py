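"""Synthetic haemodynamic cohorts with planted hypotension endotypes.

The generator emulates the statistical structure the endotyping analysis
assumes: per-patient MAP trajectories alternating between normotensive
baseline, a descent band (65–72 mmHg) immediately preceding hypotension,
and hypotensive plateaus (<65 mmHg, ≥3 consecutive 20-s points); and four
latent endotypes — vasodilation, hypovolaemia, myocardial depression and
bradycardia — whose marginal distributions of (SVI, HR, SVRI, SVV) follow
the published per-endotype means and standard deviations.  Each episode
(with its preceding run) is assigned one endotype drawn from the mixing
weights, and ground-truth per-point labels are returned alongside.

Two modes exist.  ``direct`` draws all four clustering variables straight
from the endotype's Gaussian, so empirical moments converge exactly to the
specification — the mode used for parameter-recovery experiments.
``consistent`` derives SVRI from MAP and CI through the physiological
identity SVRI = 80·(MAP−CVP)/CI, yielding an internally coherent record at
the cost of exact SVRI moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .core import DerivationConfig, compute_ci, compute_svri
from .episodes import HypotensionEpisode
from .errors import ConfigError

#: Canonical endotype order (ties and probability columns follow it).
ENDOTYPE_NAMES: tuple[str, ...] = (
    "vasodilation",
    "hypovolaemia",
    "myocardial_depression",
    "bradycardia",
)


@dataclass(frozen=True, eq=False)
class EndotypeSpec:
    """Distribution of one planted endotype.

    ``mean``/``sd`` are 4-vectors over (svi, hr, svri, svv) in original
    units; ``correlation`` is a 4×4 correlation matrix (identity by default
    — only marginal moments are published).  ``dpdt_mean``/``dpdt_sd``
    parameterize the carried (never clustered) dP/dt variable.
    """

    name: str
    weight: float
    mean: np.ndarray
    sd: np.ndarray
    correlation: np.ndarray | None = None
    dpdt_mean: float = 600.0
    dpdt_sd: float = 250.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        corr = np.eye(4) if self.correlation is None else np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", corr)
        if self.mean.shape != (4,) or self.sd.shape != (4,):
            raise ConfigError("mean and sd must be 4-vectors (svi, hr, svri, svv)")
        if np.any(self.sd <= 0):
            raise ConfigError("all sds must be > 0")
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("correlation must be symmetric 4x4")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigError("correlation matrix must be positive-definite") from exc
        if not (0 <= self.weight <= 1):
            raise ConfigError("weight must lie in [0, 1]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, EndotypeSpec):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __hash__(self) -> int:
        return hash((self.name, self.weight))

    @property
    def cov(self) -> np.ndarray:
        d = np.diag(self.sd)
        return d @ self.correlation @ d

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "weight": self.weight,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "correlation": self.correlation.tolist(),
            "dpdt_mean": self.dpdt_mean,
            "dpdt_sd": self.dpdt_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EndotypeSpec":
        return cls(
            name=d["name"],
            weight=float(d["weight"]),
            mean=np.array(d["mean"], dtype=float),
            sd=np.array(d["sd"], dtype=float),
            correlation=np.array(d["correlation"], dtype=float) if d.get("correlation") is not None else None,
            dpdt_mean=float(d.get("dpdt_mean", 600.0)),
            dpdt_sd=float(d.get("dpdt_sd", 250.0)),
        )


# Published per-endotype haemodynamic signatures, mean (sd) over
# (SVI ml m⁻², HR beats min⁻¹, SVRI dyn s cm⁻⁵ m², SVV %), plus dP/dt.
DEVELOPMENT_SPECS: tuple[EndotypeSpec, ...] = (
    EndotypeSpec("vasodilation", 0.349, (47, 82, 1253, 7), (13, 15, 296, 3), dpdt_mean=682, dpdt_sd=258),
    EndotypeSpec("hypovolaemia", 0.321, (34, 87, 1610, 16), (8, 16, 342, 6), dpdt_mean=629, dpdt_sd=275),
    EndotypeSpec("myocardial_depression", 0.224, (35, 64, 2268, 16), (9, 7, 957, 6), dpdt_mean=534, dpdt_sd=227),
    EndotypeSpec("bradycardia", 0.106, (42, 52, 2255, 9), (9, 5, 579, 3), dpdt_mean=590, dpdt_sd=203),
)

FIRST_VALIDATION_SPECS: tuple[EndotypeSpec, ...] = (
    EndotypeSpec("vasodilation", 0.292, (47, 92, 1130, 8), (12, 14, 351, 3), dpdt_mean=731, dpdt_sd=263),
    EndotypeSpec("hypovolaemia", 0.307, (35, 86, 1591, 16), (10, 15, 442, 7), dpdt_mean=627, dpdt_sd=270),
    EndotypeSpec("myocardial_depression", 0.211, (34, 65, 2289, 16), (10, 8, 908, 7), dpdt_mean=591, dpdt_sd=236),
    EndotypeSpec("bradycardia", 0.190, (53, 57, 1705, 8), (16, 10, 628, 3), dpdt_mean=666, dpdt_sd=258),
)

SECOND_VALIDATION_SPECS: tuple[EndotypeSpec, ...] = (
    EndotypeSpec("vasodilation", 0.396, (40, 94, 1312, 8), (14, 18, 360, 3), dpdt_mean=768, dpdt_sd=347),
    EndotypeSpec("hypovolaemia", 0.478, (31, 93, 1648, 17), (8, 14, 394, 6), dpdt_mean=582, dpdt_sd=277),
    EndotypeSpec("myocardial_depression", 0.105, (32, 68, 2518, 18), (12, 11, 1402, 8), dpdt_mean=658, dpdt_sd=339),
    EndotypeSpec("bradycardia", 0.021, (41, 53, 2223, 9), (9, 6, 589, 4), dpdt_mean=985, dpdt_sd=546),
)

# Normotensive filler between episodes (not part of the analysis point set).
_BASELINE_MEAN = np.array([45.0, 75.0, 1900.0, 8.0])
_BASELINE_SD = np.array([10.0, 12.0, 400.0, 3.0])
_BASELINE_DPDT = (800.0, 250.0)


@dataclass(frozen=True)
class CohortConfig:
    """Shape of a synthetic cohort.

    MAP bands (mmHg) and per-segment lengths (20-s points, inclusive
    integer ranges) define the episode structure; ``endotype_specs`` the
    planted mixture.  A fixed seed makes the output byte-identical.
    """

    n_patients: int = 250
    points_per_patient: int = 300
    mode: str = "direct"
    endotype_specs: tuple[EndotypeSpec, ...] = DEVELOPMENT_SPECS
    baseline_map: tuple[float, float] = (73.0, 90.0)
    preceding_map: tuple[float, float] = (65.0, 71.0)
    episode_map: tuple[float, float] = (55.0, 64.0)
    baseline_len: tuple[int, int] = (2, 5)
    preceding_len: tuple[int, int] = (1, 3)
    episode_len: tuple[int, int] = (3, 8)
    grid_s: float = 20.0
    derivation: DerivationConfig = field(default_factory=DerivationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.points_per_patient < 1:
            raise ConfigError("cohort must have at least one patient and point")
        if self.mode not in ("direct", "consistent"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        w = sum(s.weight for s in self.endotype_specs)
        if abs(w - 1.0) > 1e-9:
            raise ConfigError(f"endotype weights must sum to 1, got {w}")
        if self.episode_map[1] >= 65.0 or self.episode_map[0] >= self.episode_map[1]:
            raise ConfigError("episode MAP band must lie strictly below 65 mmHg")
        if not (65.0 <= self.preceding_map[0] < self.preceding_map[1] < 72.0):
            raise ConfigError("preceding MAP band must lie within [65, 72) mmHg")
        if self.baseline_map[0] < 72.0:
            raise ConfigError("baseline MAP band must lie at or above 72 mmHg")
        if self.episode_len[0] < 3:
            raise ConfigError("episodes need >= 3 points to last 1 min on the 20-s grid")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "points_per_patient": self.points_per_patient,
            "mode": self.mode,
            "endotype_specs": [s.to_dict() for s in self.endotype_specs],
            "baseline_map": list(self.baseline_map),
            "preceding_map": list(self.preceding_map),
            "episode_map": list(self.episode_map),
            "baseline_len": list(self.baseline_len),
            "preceding_len": list(self.preceding_len),
            "episode_len": list(self.episode_len),
            "grid_s": self.grid_s,
            "cvp_mmhg": self.derivation.cvp_mmhg,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        specs = d.pop("endotype_specs", None)
        cvp = d.pop("cvp_mmhg", 5.0)
        kwargs = {
            k: d[k]
            for k in (
                "n_patients", "points_per_patient", "mode", "grid_s", "seed",
            )
            if k in d
        }
        for k in ("baseline_map", "preceding_map", "episode_map", "baseline_len", "preceding_len", "episode_len"):
            if k in d:
                kwargs[k] = tuple(d[k])
        if specs is not None:
            kwargs["endotype_specs"] = tuple(EndotypeSpec.from_dict(s) for s in specs)
        return cls(derivation=DerivationConfig(cvp_mmhg=float(cvp)), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def sample_endotype_points(spec: EndotypeSpec, n: int, seed=None) -> np.ndarray:
    """Draw n points of (svi, hr, svri, svv) from the endotype's Gaussian.

    No truncation is applied, so empirical moments are unbiased estimates
    of the spec's.  ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_normal(spec.mean, spec.cov, size=n, method="cholesky")


def _positive_normal(rng: np.random.Generator, mean, sd, n: int) -> np.ndarray:
    """Normal draws with non-positive values redrawn (for carried variables)."""
    x = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.abs(x) + 1e-6 * (x <= 0)


def _sample_vitals(rng, mean, sd, n, physiological: bool) -> np.ndarray:
    """Diagonal-normal draws of (svi, hr, svri, svv); when ``physiological``,
    rows outside the physiological domain are redrawn."""
    x = rng.normal(mean, sd, size=(n, 4))
    if physiological:
        for _ in range(100):
            bad = (x[:, 0] <= 0) | (x[:, 1] <= 0) | (x[:, 2] <= 0) | (x[:, 3] < 0) | (x[:, 3] > 50)
            if not bad.any():
                break
            x[bad] = rng.normal(mean, sd, size=(int(bad.sum()), 4))
    return x


@dataclass
class SyntheticCohort:
    """A generated cohort: the haemodynamic frame, per-point ground truth,
    and the constructed episode intervals (per patient, in series indices)."""

    frame: pd.DataFrame
    truth: pd.DataFrame
    episodes: dict[str, list[HypotensionEpisode]]
    config: CohortConfig

    def write(self, cohort_path, truth_path=None) -> None:
        from .core import write_cohort

        write_cohort(self.frame, cohort_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort of per-patient series with planted endotypes.

    Each patient's series is a sequence of blocks — baseline (MAP ≥73),
    preceding descent (65 ≤ MAP <72), hypotensive plateau (MAP <65, ≥3
    points) — truncated only at baseline so every constructed episode is
    detectable.  One endotype per episode is drawn from the mixing weights
    and governs the haemodynamics of the episode and its preceding run.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.endotype_specs
    weights = np.array([s.weight for s in specs])
    direct = config.mode == "direct"
    cvp = config.derivation.cvp_mmhg

    rec: dict[str, list] = {k: [] for k in ("patient_id", "time_s", "map", "svi", "hr", "svri", "svv", "dpdt")}
    tru: dict[str, list] = {k: [] for k in ("patient_id", "time_s", "true_endotype", "in_episode", "is_preceding")}
    episodes: dict[str, list[HypotensionEpisode]] = {}

    def emit(pid, i0, n, map_vals, vit, dpdt, endotype, in_ep, is_pre):
        t = (np.arange(i0, i0 + n) * config.grid_s).astype(float)
        rec["patient_id"].append(np.full(n, pid, dtype=object))
        rec["time_s"].append(t)
        rec["map"].append(map_vals)
        rec["svi"].append(vit[:, 0])
        rec["hr"].append(vit[:, 1])
        rec["svri"].append(vit[:, 2])
        rec["svv"].append(np.clip(vit[:, 3], 0.0, 50.0) if not direct else vit[:, 3])
        rec["dpdt"].append(dpdt)
        tru["patient_id"].append(np.full(n, pid, dtype=object))
        tru["time_s"].append(t)
        tru["true_endotype"].append(np.full(n, endotype, dtype=object))
        tru["in_episode"].append(np.full(n, int(in_ep)))
        tru["is_preceding"].append(np.full(n, int(is_pre)))

    width = len(str(config.n_patients))
    for p in range(config.n_patients):
        pid = f"P{p + 1:0{width}d}"
        eps: list[HypotensionEpisode] = []
        i = 0
        remaining = config.points_per_patient
        min_block = config.baseline_len[0] + config.preceding_len[0] + config.episode_len[0]
        while remaining > 0:
            b = int(rng.integers(config.baseline_len[0], config.baseline_len[1] + 1))
            pr = int(rng.integers(config.preceding_len[0], config.preceding_len[1] + 1))
            e = int(rng.integers(config.episode_len[0], config.episode_len[1] + 1))
            if b + pr + e > remaining:
                if remaining < min_block:
                    b, pr, e = remaining, 0, 0
                else:
                    # shrink to the minimal episode block; pad with baseline
                    pr, e = config.preceding_len[0], config.episode_len[0]
                    b = remaining - pr - e
            # baseline
            if b:
                m = rng.uniform(config.baseline_map[0], config.baseline_map[1], b)
                v = _sample_vitals(rng, _BASELINE_MEAN, _BASELINE_SD, b, physiological=True)
                if not direct:
                    v[:, 2] = compute_svri(m, compute_ci(v[:, 0], v[:, 1]), config.derivation)
                d = _positive_normal(rng, *_BASELINE_DPDT, b)
                emit(pid, i, b, m, v, d, "", False, False)
                i += b
            if pr + e == 0:
                break
            # episode endotype
            k = int(rng.choice(len(specs), p=weights))
            spec = specs[k]
            n_ep = pr + e
            if spec.correlation is not None and not np.allclose(spec.correlation, np.eye(4)):
                v = rng.multivariate_normal(spec.mean, spec.cov, size=n_ep, method="cholesky")
            else:
                v = _sample_vitals(rng, spec.mean, spec.sd, n_ep, physiological=not direct)
            d = _positive_normal(rng, spec.dpdt_mean, spec.dpdt_sd, n_ep)
            m_pre = rng.uniform(config.preceding_map[0], config.preceding_map[1], pr)
            m_ep = rng.uniform(config.episode_map[0], config.episode_map[1], e)
            m = np.concatenate([m_pre, m_ep])
            if not direct:
                v[:, 2] = compute_svri(m, compute_ci(v[:, 0], v[:, 1]), DerivationConfig(cvp))
            if pr:
                emit(pid, i, pr, m_pre, v[:pr], d[:pr], spec.name, False, True)
            emit(pid, i + pr, e, m_ep, v[pr:], d[pr:], spec.name, True, False)
            eps.append(HypotensionEpisode(pid, start=i + pr, end=i + pr + e, preceding_start=i))
            i += pr + e
            remaining = config.points_per_patient - i
        episodes[pid] = eps

    frame = pd.DataFrame({k: np.concatenate(v) for k, v in rec.items()})
    frame["quality_ok"] = 1
    # raw arithmetic: direct mode deliberately keeps rare non-positive Gaussian
    # tail draws so that empirical moments stay unbiased
    frame["ci"] = frame["svi"].to_numpy() * frame["hr"].to_numpy() / 1000.0
    if not direct:
        frame["svri"] = compute_svri(frame["map"].to_numpy(), frame["ci"].to_numpy(), config.derivation)
    truth = pd.DataFrame({k: np.concatenate(v) for k, v in tru.items()})
    return SyntheticCohort(frame=frame, truth=truth, episodes=episodes, config=config)


def specs_with_weights(specs: tuple[EndotypeSpec, ...], weights) -> tuple[EndotypeSpec, ...]:
    """Convenience: same distributions, different mixing weights."""
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(specs):
        raise ConfigError("one weight per spec required")
    return tuple(replace(s, weight=float(w)) for s, w in zip(specs, weights))
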