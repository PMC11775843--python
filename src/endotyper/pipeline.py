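"""End-to-end orchestration: detect → normalize → embed → cluster → label.

`run_pipeline` executes the whole endotyping analysis on a cohort frame or
CSV and returns a human-readable :class:`RunReport` plus the frozen
:class:`EndotypeModel`.  A single global seed fans out to per-stage seeds
through stable stage-name hashing, so runs are byte-reproducible while the
stages stay statistically independent.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .autoencoder import AutoencoderConfig, train_autoencoder, encode
from .clustering import GMMConfig, KSelectionResult, hard_labels, select_k
from .core import (
    CSV_COLUMNS,
    DerivationConfig,
    apply_normalizer,
    derive_variables,
    fit_normalizer,
    load_cohort,
)
from .endotyping import (
    ClusterSummary,
    EndotypeModel,
    config_hash,
    label_endotypes,
    summaries_frame,
    summarize_clusters,
)
from .episodes import EpisodeConfig, extract_cohort_points
from .errors import DataError, LabelingError

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2³¹) from the global seed by name hashing."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a full endotyping run."""

    episode: EpisodeConfig = field(default_factory=EpisodeConfig)
    derivation: DerivationConfig = field(default_factory=DerivationConfig)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    gmm: GMMConfig = field(default_factory=GMMConfig)
    k_range: tuple[int, int] = (2, 8)
    include_preceding: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "episode": {
                "hypo_threshold_mmhg": self.episode.hypo_threshold_mmhg,
                "preceding_threshold_mmhg": self.episode.preceding_threshold_mmhg,
                "min_duration_s": self.episode.min_duration_s,
                "grid_s": self.episode.grid_s,
            },
            "cvp_mmhg": self.derivation.cvp_mmhg,
            "autoencoder": self.autoencoder.to_dict(),
            "gmm": {
                "n_restarts": self.gmm.n_restarts,
                "max_iter": self.gmm.max_iter,
                "tol": self.gmm.tol,
                "reg_covar": self.gmm.reg_covar,
            },
            "k_range": list(self.k_range),
            "include_preceding": self.include_preceding,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            episode=EpisodeConfig(**d.get("episode", {})),
            derivation=DerivationConfig(cvp_mmhg=float(d.get("cvp_mmhg", 5.0))),
            autoencoder=AutoencoderConfig.from_dict(d.get("autoencoder", {})),
            gmm=GMMConfig(**d.get("gmm", {})),
            k_range=tuple(d.get("k_range", (2, 8))),
            include_preceding=bool(d.get("include_preceding", True)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Descriptives and tables of one endotyping run."""

    n_patients: int
    n_episodes: int
    n_hypotensive_points: int
    n_preceding_points: int
    k_selection: KSelectionResult
    summaries: list[ClusterSummary]
    label_map: dict[int, str]
    shares: dict[str, float]
    latent: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        return summaries_frame(self.summaries, self.label_map)


def fit_points(points: pd.DataFrame, config: PipelineConfig) -> tuple[RunReport, EndotypeModel]:
    """Fit the endotyping model on an extracted analysis point set.

    ``points`` carries original-unit variables (and optionally the
    ``class`` tag from episode extraction).  Stages: fit normalizer → train
    autoencoder → select k by validity indices → final GMM → physiological
    labelling → original-unit summaries.
    """
    if len(points) == 0:
        raise DataError("no analysis points to fit on")
    log.info("fitting on %d analysis points", len(points))

    normalizer = fit_normalizer(points)
    Z = apply_normalizer(points, normalizer)

    ae_cfg = replace(config.autoencoder, seed=stage_seed(config.seed, "autoencoder"))
    log.info("training autoencoder (%s)", ae_cfg)
    encoder = train_autoencoder(Z, ae_cfg)
    latent = encode(encoder, Z)

    gmm_seed = stage_seed(config.seed, "gmm")
    lo, hi = config.k_range
    log.info("selecting k in [%d, %d] (seed %d)", lo, hi, gmm_seed)
    ksel = select_k(latent, range(lo, hi + 1), seed=gmm_seed, cfg=config.gmm)
    fit = ksel.fits[ksel.selected_k]
    log.info("selected k=%d (agreement=%s)", ksel.selected_k, ksel.agreement)

    labels = hard_labels(fit.params, latent)
    summaries = summarize_clusters(points, labels)
    try:
        label_map = label_endotypes(summaries)
    except LabelingError:
        log.warning("k=%d != 4: clusters keep numeric ids", ksel.selected_k)
        label_map = {s.cluster_id: str(s.cluster_id) for s in summaries}

    model = EndotypeModel(
        normalizer=normalizer,
        encoder=encoder,
        mixture=fit.params,
        label_map=label_map,
        provenance={
            "seed": config.seed,
            "config_hash": config_hash(config.to_dict()),
            "n_points": int(len(points)),
            "selected_k": ksel.selected_k,
        },
    )
    shares = {label_map[s.cluster_id]: s.share for s in summaries}
    cls = points["class"] if "class" in points.columns else pd.Series("hypotensive", index=points.index)
    report = RunReport(
        n_patients=int(points["patient_id"].nunique()) if "patient_id" in points.columns else 0,
        n_episodes=int(points["episode_id"].nunique()) if "episode_id" in points.columns else 0,
        n_hypotensive_points=int((cls == "hypotensive").sum()),
        n_preceding_points=int((cls == "preceding").sum()),
        k_selection=ksel,
        summaries=summaries,
        label_map=label_map,
        shares=shares,
        latent=latent,
        labels=labels,
    )
    return report, model


def run_pipeline(cohort, config: PipelineConfig = PipelineConfig()) -> tuple[RunReport, EndotypeModel]:
    """Full analysis on a cohort (frame or CSV path): episode detection,
    analysis-point extraction, and :func:`fit_points`."""
    if isinstance(cohort, (str, bytes)) or hasattr(cohort, "__fspath__"):
        frame = load_cohort(cohort, config.derivation)
    else:
        frame = cohort.loc[cohort.get("quality_ok", 1) == 1] if "quality_ok" in cohort.columns else cohort
        frame = frame.reset_index(drop=True)
    points = extract_cohort_points(frame, config.episode, config.include_preceding)
    log.info(
        "extracted %d analysis points (%d hypotensive, %d preceding) from %d patients",
        len(points),
        int((points["class"] == "hypotensive").sum()) if len(points) else 0,
        int((points["class"] == "preceding").sum()) if len(points) else 0,
        frame["patient_id"].nunique(),
    )
    return fit_points(points, config)


def write_points_csv(points: pd.DataFrame, path) -> None:
    """Persist an extracted analysis point set in the on-disk schema."""
    inv = {short: csv for csv, short in CSV_COLUMNS.items()}
    out = points.rename(columns=inv)
    cols = [c for c in (
        "patient_id", "time_s", "class", "episode_id",
        "map_mmhg", "svi_ml_m2", "hr_bpm", "svv_pct", "dpdt_mmhg_s", "quality_ok",
    ) if c in out.columns]
    out.loc[:, cols].to_csv(path, index=False)


def read_points_csv(path, cfg: DerivationConfig = DerivationConfig()) -> pd.DataFrame:
    """Read a point set written by :func:`write_points_csv`; derived
    variables are recomputed, never read."""
    raw = pd.read_csv(path)
    frame = raw.rename(columns=CSV_COLUMNS)
    return derive_variables(frame, cfg)


def render_report(report: RunReport, out_dir, plot: bool = False) -> list[str]:
    """Write the report tables (and optionally the latent-space figure).

    Files: ``endotype_summary.csv`` (one row per cluster, original-unit
    statistics), ``k_selection.csv`` (per-k validity indices) and
    ``endotype_shares.csv``; with ``plot=True`` also ``latent_space.png``
    (scatter of latent points with posterior-probability rings).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []

    p = os.path.join(out_dir, "endotype_summary.csv")
    report.summary_frame().to_csv(p, index=False)
    written.append(p)

    p = os.path.join(out_dir, "k_selection.csv")
    report.k_selection.to_frame().to_csv(p, index=False)
    written.append(p)

    p = os.path.join(out_dir, "endotype_shares.csv")
    pd.DataFrame(
        {"endotype": list(report.shares), "share": list(report.shares.values())}
    ).to_csv(p, index=False)
    written.append(p)

    if plot and report.latent is not None:
        try:
            written.append(_plot_latent(report, out_dir))
        except ImportError:  # matplotlib is an optional extra
            log.warning("matplotlib unavailable; skipping latent-space plot")
    return written


def _plot_latent(report: RunReport, out_dir: str) -> str:
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = report.k_selection.fits[report.k_selection.selected_k]
    fig, ax = plt.subplots(figsize=(7, 6))
    order = [report.label_map[c] for c in sorted(report.label_map)]
    sub = np.random.default_rng(0).choice(
        len(report.latent), size=min(20000, len(report.latent)), replace=False
    )
    for cid in sorted(report.label_map):
        mask = report.labels[sub] == cid
        ax.scatter(
            report.latent[sub][mask, 0], report.latent[sub][mask, 1],
            s=3, alpha=0.3, label=report.label_map[cid],
        )
    theta = np.linspace(0, 2 * np.pi, 100)
    for j in range(fit.params.k):
        chol = np.linalg.cholesky(fit.params.covariances[j])
        for r in (1.0, 2.0):  # iso-probability rings at 1 and 2 Mahalanobis radii
            ring = fit.params.means[j][:, None] + r * chol @ np.vstack([np.cos(theta), np.sin(theta)])
            ax.plot(ring[0], ring[1], color="k", lw=0.7, alpha=0.6)
    ax.set_xlabel("latent 1")
    ax.set_ylabel("latent 2")
    ax.legend(markerscale=4, fontsize=8)
    ax.set_title("Endotypes in the autoencoder latent space")
    path = os.path.join(out_dir, "latent_space.png")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
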