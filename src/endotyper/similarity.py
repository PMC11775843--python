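"""Endotype similarity by closed-form Gaussian Kullback-Leibler divergence.

Each endotype's point cloud is approximated by a single Gaussian fitted in
a *shared comparison space* — the z-normalized 4-variable space under the
development model's normalizer — because differently trained autoencoders
have incommensurable latent spaces.  Similarity between the endotypes of
two models/datasets is the 4×4 matrix of divergences

    KL(P‖Q) = ½ [tr(Σ_Q⁻¹ Σ_P) + (μ_Q−μ_P)ᵀ Σ_Q⁻¹ (μ_Q−μ_P) − d + ln(det Σ_Q / det Σ_P)]

(rows ‖ columns), together with the minimum-total-divergence bijection
between the two endotype sets.  KL is ≥ 0, zero iff identical, and
asymmetric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .core import apply_normalizer
from .endotyping import EndotypeModel, assign
from .errors import DegenerateDataError, InsufficientDataError
from .synth import ENDOTYPE_NAMES

log = logging.getLogger(__name__)

_RIDGE = 1e-9


@dataclass(frozen=True)
class EndotypeGaussian:
    """Gaussian approximation of one endotype's points in the comparison
    space."""

    name: str
    mean: np.ndarray
    cov: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise DegenerateDataError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise DegenerateDataError("covariance must be symmetric")
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDataError("covariance must be positive-definite") from exc


def fit_endotype_gaussian(points, labels, endotype: str, source: str = "") -> EndotypeGaussian:
    """Sample mean and covariance (n−1 denominator, ridge 1e−9) of one
    endotype's points in the comparison space; needs ≥ 10 points."""
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    sub = X[labels == endotype]
    if sub.shape[0] < 10:
        raise InsufficientDataError(
            f"endotype {endotype!r} has {sub.shape[0]} points; >= 10 required"
        )
    mean = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, ddof=1)
    if np.min(np.linalg.eigvalsh(cov)) < 1e-12:
        raise DegenerateDataError(f"singular covariance for endotype {endotype!r}")
    cov = cov + _RIDGE * np.eye(cov.shape[0])
    return EndotypeGaussian(name=endotype, mean=mean, cov=cov, source=source)


def kl_gaussian(P: EndotypeGaussian, Q: EndotypeGaussian) -> float:
    """Closed-form KL(P‖Q) between two multivariate Gaussians, in nats."""
    if P.mean.size != Q.mean.size:
        raise DegenerateDataError("dimension mismatch")
    d = P.mean.size
    cq = np.linalg.cholesky(Q.cov)
    cp = np.linalg.cholesky(P.cov)
    # tr(Σ_Q⁻¹ Σ_P) = ||cq⁻¹ cp||_F² with cq, cp the Cholesky factors
    A = np.linalg.solve(cq, cp)
    tr = float(np.sum(A**2))
    diff = Q.mean - P.mean
    m = np.linalg.solve(cq, diff)
    maha = float(m @ m)
    logdet = 2.0 * (np.sum(np.log(np.diag(cq))) - np.sum(np.log(np.diag(cp))))
    return 0.5 * (tr + maha - d + logdet)


@dataclass
class SimilarityMatrix:
    """Pairwise divergences between two endotype sets.

    ``matrix`` rows are the first model's endotypes, columns the second's
    (entry = KL(row ‖ column)); ``matching`` is the bijection rows→columns
    minimizing total matched divergence; ``name_match`` flags whether that
    bijection equals the name-based pairing."""

    matrix: pd.DataFrame
    matching: dict[str, str]
    name_match: bool
    row_source: str = ""
    col_source: str = ""

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def similarity_matrix(
    endotypes_a: dict[str, EndotypeGaussian] | list[EndotypeGaussian],
    endotypes_b: dict[str, EndotypeGaussian] | list[EndotypeGaussian],
    row_source: str = "A",
    col_source: str = "B",
) -> SimilarityMatrix:
    """Table of KL(A_i ‖ B_j) with the minimum-cost endotype matching.

    The matching is found by exhaustive search over the bijections (the
    endotype count is small).  A warning is emitted if it disagrees with
    matching by name.
    """
    ga = {g.name: g for g in (endotypes_a.values() if isinstance(endotypes_a, dict) else endotypes_a)}
    gb = {g.name: g for g in (endotypes_b.values() if isinstance(endotypes_b, dict) else endotypes_b)}
    rows = [n for n in ENDOTYPE_NAMES if n in ga] + sorted(set(ga) - set(ENDOTYPE_NAMES))
    cols = [n for n in ENDOTYPE_NAMES if n in gb] + sorted(set(gb) - set(ENDOTYPE_NAMES))
    M = pd.DataFrame(
        [[kl_gaussian(ga[r], gb[c]) for c in cols] for r in rows],
        index=rows,
        columns=cols,
    )
    best_perm = None
    best_cost = np.inf
    vals = M.to_numpy()
    for perm in permutations(range(len(cols)), len(rows)):
        cost = sum(vals[i, j] for i, j in enumerate(perm))
        if cost < best_cost:
            best_cost = cost
            best_perm = perm
    matching = {rows[i]: cols[j] for i, j in enumerate(best_perm)}
    name_match = all(r == c for r, c in matching.items())
    if not name_match:
        warnings.warn("minimum-divergence matching disagrees with name-based pairing", stacklevel=2)
    return SimilarityMatrix(
        matrix=M, matching=matching, name_match=name_match,
        row_source=row_source, col_source=col_source,
    )


def endotype_gaussians(
    model: EndotypeModel,
    points: pd.DataFrame,
    reference: EndotypeModel | None = None,
    source: str = "",
) -> dict[str, EndotypeGaussian]:
    """Fit per-endotype Gaussians for a dataset in the comparison space.

    Hard labels come from ``model``'s own assignment of ``points``; the
    comparison space is the normalized 4-variable space of ``reference``
    (defaults to ``model`` itself — pass the development model to compare
    endotypes across differently trained models in one common space).
    """
    ref = reference if reference is not None else model
    labels = assign(model, points).labels.to_numpy()
    Z = apply_normalizer(points, ref.normalizer)
    out = {}
    for name in sorted(set(labels)):
        out[name] = fit_endotype_gaussian(Z, labels, name, source=source)
    return out


def compare_endotypes(
    model_a: EndotypeModel,
    points_a: pd.DataFrame,
    model_b: EndotypeModel,
    points_b: pd.DataFrame,
    source_a: str = "A",
    source_b: str = "B",
) -> SimilarityMatrix:
    """Similarity of the endotypes of two fitted models/datasets.

    Rows are model A's endotypes (e.g. a validation dataset), columns model
    B's (the development/reference dataset, whose normalizer defines the
    shared comparison space): entry (i, j) = KL(A_i ‖ B_j)."""
    ga = endotype_gaussians(model_a, points_a, reference=model_b, source=source_a)
    gb = endotype_gaussians(model_b, points_b, reference=model_b, source=source_b)
    return similarity_matrix(ga, gb, row_source=source_a, col_source=source_b)
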