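"""From fitted clusters to named endotypes.

Clusters are summarized in original units (Table-style mean/sd/median/IQR
per haemodynamic variable), mapped deterministically onto the four
physiological endotype names, and the frozen model assigns per-point
posterior endotype probabilities — including to new datasets it was never
fitted on (normalizer, encoder weights and mixture parameters are reused
verbatim; nothing is re-fitted).

The labelling rule reconstructs the physiological reading of the endotype
signatures: the slowest-heart-rate cluster is bradycardia; of the rest the
lowest-afterload (SVRI) cluster is vasodilation; the remaining pair is
split by heart rate into myocardial depression (lower) and hypovolaemia.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autoencoder import EncoderModel, encode
from .clustering import MixtureParams, posterior_probs
from .core import CLUSTER_VARS, SUMMARY_VARS, NormalizationParams, apply_normalizer
from .errors import DataError, LabelingError
from .synth import ENDOTYPE_NAMES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterSummary:
    """Original-unit descriptive statistics of one cluster."""

    cluster_id: int
    count: int
    share: float
    stats: dict[str, dict[str, float]]  # variable -> {mean, sd, median, q25, q75}

    def mean(self, var: str) -> float:
        return self.stats[var]["mean"]


def summarize_clusters(points: pd.DataFrame, labels) -> list[ClusterSummary]:
    """Per-cluster summaries of the haemodynamic variables in original units.

    ``points`` must carry the summary variables (``svi, hr, svri, svv, ci,
    dpdt`` — missing ones are skipped); ``labels`` is the per-row hard
    assignment.  Empty clusters are excluded with a warning.
    """
    labels = np.asarray(labels)
    if len(points) != labels.size:
        raise DataError("labels must cover all points")
    total = labels.size
    out: list[ClusterSummary] = []
    for cid in np.unique(labels):
        mask = labels == cid
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"cluster {cid} is empty; excluded", stacklevel=2)
            continue
        grp = points.loc[mask]
        stats = {}
        for var in SUMMARY_VARS:
            if var not in grp.columns:
                continue
            x = grp[var].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size == 0:
                continue
            stats[var] = {
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "median": float(np.median(x)),
                "q25": float(np.percentile(x, 25)),
                "q75": float(np.percentile(x, 75)),
            }
        out.append(ClusterSummary(cluster_id=int(cid), count=n, share=n / total, stats=stats))
    return out


def summaries_frame(summaries: list[ClusterSummary], label_map: dict[int, str] | None = None) -> pd.DataFrame:
    """Table-style frame: one row per cluster, columns n, share and
    per-variable statistics."""
    rows = []
    for s in summaries:
        row: dict = {"cluster_id": s.cluster_id, "n": s.count, "share": s.share}
        if label_map:
            row["endotype"] = label_map.get(s.cluster_id, str(s.cluster_id))
        for var, st in s.stats.items():
            for k, v in st.items():
                row[f"{var}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def label_endotypes(summaries: list[ClusterSummary]) -> dict[int, str]:
    """Deterministically map exactly four clusters onto the endotype names.

    Refuses (raises :class:`LabelingError`) for k ≠ 4 — clusters then keep
    their numeric ids.  Emits a warning when the resulting signature is
    physiologically surprising (vasodilation should be a low-SVV state,
    hypovolaemia a high-SVV state).
    """
    if len(summaries) != 4:
        raise LabelingError(f"labelling requires exactly 4 clusters, got {len(summaries)}")
    by_id = {s.cluster_id: s for s in summaries}
    remaining = sorted(by_id, key=lambda cid: by_id[cid].mean("hr"))
    brady = remaining[0]
    rest = remaining[1:]
    vaso = min(rest, key=lambda cid: by_id[cid].mean("svri"))
    pair = sorted((cid for cid in rest if cid != vaso), key=lambda cid: by_id[cid].mean("hr"))
    myo, hypo = pair
    label_map = {
        vaso: "vasodilation",
        hypo: "hypovolaemia",
        myo: "myocardial_depression",
        brady: "bradycardia",
    }
    if by_id[vaso].mean("svv") >= by_id[hypo].mean("svv"):
        warnings.warn(
            "endotype signature check: vasodilation SVV is not below hypovolaemia SVV",
            stacklevel=2,
        )
    return label_map


@dataclass
class EndotypeModel:
    """Frozen endotyping pipeline state.

    Applying the model normalizes with the stored parameters, encodes with
    the stored weights, evaluates the stored mixture and renames components
    through the label map — no re-fitting ever happens.
    """

    normalizer: NormalizationParams
    encoder: EncoderModel
    mixture: MixtureParams
    label_map: dict[int, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mixture.k == 4:
            if set(self.label_map.values()) != set(ENDOTYPE_NAMES) or len(self.label_map) != 4:
                raise DataError("label map must be a bijection onto the four endotype names")

    @property
    def endotype_order(self) -> list[str]:
        """Component names in canonical endotype order (numeric ids appended)."""
        named = [n for n in ENDOTYPE_NAMES if n in self.label_map.values()]
        other = sorted(str(v) for v in self.label_map.values() if v not in ENDOTYPE_NAMES)
        return named + other

    def to_dict(self) -> dict:
        return {
            "normalizer": self.normalizer.to_dict(),
            "encoder": self.encoder.to_dict(),
            "mixture": self.mixture.to_dict(),
            "label_map": {str(k): v for k, v in self.label_map.items()},
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "EndotypeModel":
        return cls(
            normalizer=NormalizationParams.from_dict(d["normalizer"]),
            encoder=EncoderModel.from_dict(d["encoder"]),
            mixture=MixtureParams.from_dict(d["mixture"]),
            label_map={int(k): v for k, v in d["label_map"].items()},
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def load(cls, path) -> "EndotypeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class EndotypeAssignment:
    """Per-point posterior endotype probabilities plus the hard label."""

    frame: pd.DataFrame
    endotype_order: list[str]

    @property
    def probabilities(self) -> np.ndarray:
        return self.frame[[f"p_{n}" for n in self.endotype_order]].to_numpy()

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]


def assign(model: EndotypeModel, points: pd.DataFrame) -> EndotypeAssignment:
    """Assign endotype probabilities to points given in original units.

    ``points`` must carry the four clustering variables; ``patient_id``,
    ``time_s``, ``class`` and ``episode_id`` columns are carried through
    when present.  Ties in the hard label break by the canonical endotype
    order.
    """
    missing = [v for v in CLUSTER_VARS if v not in points.columns]
    if missing:
        raise DataError(f"points missing clustering variables: {missing}")
    Z = apply_normalizer(points, model.normalizer)
    latent = encode(model.encoder, Z)
    resp = posterior_probs(model.mixture, latent)

    order = model.endotype_order
    name_to_col = {}
    for cid, name in model.label_map.items():
        name_to_col[str(name)] = cid
    P = np.column_stack([resp[:, name_to_col[n]] for n in order])

    out = pd.DataFrame(index=points.index.copy())
    for col in ("patient_id", "time_s", "class", "episode_id"):
        if col in points.columns:
            out[col] = points[col]
    for i, n in enumerate(order):
        out[f"p_{n}"] = P[:, i]
    out["label"] = [order[i] for i in np.argmax(P, axis=1)]
    return EndotypeAssignment(frame=out.reset_index(drop=True), endotype_order=order)


def rollup_episodes(assignment: EndotypeAssignment) -> pd.DataFrame:
    """Episode-level convenience roll-up: mean posterior over each episode's
    points, with the episode label as the argmax of the mean."""
    f = assignment.frame
    if "episode_id" not in f.columns:
        raise DataError("assignment lacks episode ids")
    pcols = [f"p_{n}" for n in assignment.endotype_order]
    grp = f.groupby(["patient_id", "episode_id"], sort=False)[pcols].mean().reset_index()
    grp["label"] = [
        assignment.endotype_order[i] for i in np.argmax(grp[pcols].to_numpy(), axis=1)
    ]
    return grp
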