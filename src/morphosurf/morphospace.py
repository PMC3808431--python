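"""Correlation-matrix PCA of Jacobian summaries and ontogenetic trajectories.

Each surface model contributes one six-element row (its Jacobian summary in
the documented flattening order); the rows are standardized to zero mean and
unit variance and the correlation matrix is eigendecomposed.  The resulting
eigenvalues sum to the number of retained (non-constant) variables, percent
variances follow from the eigenvalues, and the loading structure is reported
as variable-PC correlations (eigenvector element times the square root of
the eigenvalue).  Axes therefore have no built-in meaning: the morphospace
is empirical, interpreted a posteriori from those correlations.

Because standardization removes column scale but not row differences,
models that differ only in size (radii scaled uniformly) must be ratio-
normalized before ordination to coincide; the measurement-reduction module
provides that normalization.  Models whose Jacobian summaries coincide
outright (degenerate pairs) are flagged during table assembly so a Hessian
post-processing pass can discriminate them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .diffgeo import (
    DEGENERACY_TOL,
    JACOBIAN_ELEMENT_ORDER,
    JacobianSummary,
    jacobian,
)
from .surfaces import MorphosurfError, SurfaceModel

__all__ = [
    "NoVariationError",
    "LabelError",
    "JacobianTable",
    "MorphospaceResult",
    "Trajectory",
    "assemble_table",
    "ordinate",
    "variance_explained",
    "trajectory",
]

logger = logging.getLogger(__name__)


class NoVariationError(MorphosurfError):
    """Ordination input with no varying column (or all-zero eigenvalues)."""


class LabelError(MorphosurfError):
    """A trajectory stage label missing from the ordination."""


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JacobianTable:
    """Labeled n x 6 matrix of flattened Jacobian summaries.

    Column order is fixed to :data:`~morphosurf.diffgeo.JACOBIAN_ELEMENT_ORDER`;
    ``degenerate_pairs`` lists label pairs whose summaries are identical to
    within the degeneracy threshold.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    eval_point: tuple[float, float] = (0.0, 0.0)
    degenerate_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.labels), 6):
            raise ValueError("matrix must be n x 6 with one row per label")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("Jacobian table contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def row(self, label: str) -> np.ndarray:
        try:
            return self.matrix[self.labels.index(label)]
        except ValueError as exc:
            raise LabelError(f"label {label!r} not in table") from exc


def assemble_table(
    models: Sequence[SurfaceModel] | Mapping[str, SurfaceModel],
    eval_point: tuple[float, float] = (0.0, 0.0),
) -> JacobianTable:
    """One Jacobian-summary row per model, flagging degenerate pairs.

    ``models`` is a label->model mapping or a sequence of labeled models
    (labels must be unique); at least two models are required for a
    meaningful ordination.  Singular Jacobians propagate with the model
    label attached.
    """
    if isinstance(models, Mapping):
        items = list(models.items())
    else:
        items = [(m.label or f"model_{i}", m) for i, m in enumerate(models)]
    if len(items) < 2:
        raise MorphosurfError(f"need at least 2 models to assemble a table, got {len(items)}")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise LabelError("model labels must be unique")

    u0, v0 = eval_point
    rows = [jacobian(m, u0, v0).flat for _, m in items]
    matrix = np.array(rows, dtype=float)

    degenerate: list[tuple[str, str]] = []
    for i in range(len(items)):
        for jdx in range(i + 1, len(items)):
            if np.max(np.abs(matrix[i] - matrix[jdx])) < DEGENERACY_TOL:
                degenerate.append((labels[i], labels[jdx]))
    if degenerate:
        logger.warning(
            "Jacobian-degenerate model pairs (consider Hessian post-processing): %s",
            degenerate,
        )
    return JacobianTable(
        labels=tuple(labels),
        matrix=matrix,
        eval_point=eval_point,
        degenerate_pairs=tuple(degenerate),
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphospaceResult:
    """Correlation-matrix PCA of a Jacobian table.

    ``eigenvalues`` are descending and sum to the number of retained
    variables; ``scores`` are the standardized data projected on the
    eigenvectors; ``correlations`` holds variable-PC correlations
    (retained-variable rows by PC columns).  ``column_means`` and
    ``column_stds`` are the standardization parameters of the retained
    columns, and ``dropped`` names any constant columns removed before
    decomposition.  PC signs are fixed so that each PC's largest-magnitude
    variable correlation is positive.
    """

    labels: tuple[str, ...]
    variables: tuple[str, ...]
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    scores: np.ndarray
    correlations: np.ndarray
    column_means: np.ndarray
    column_stds: np.ndarray
    dropped: tuple[str, ...] = ()

    def scores_for(self, label: str) -> np.ndarray:
        try:
            return self.scores[self.labels.index(label)]
        except ValueError as exc:
            raise LabelError(f"label {label!r} not in ordination") from exc


def variance_explained(eigenvalues: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-PC and cumulative percentages, ``100 * lam_i / sum(lam)``.

    Also applicable directly to already-computed percentages (they renormalize
    to themselves since percentages sum to 100).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.any(lam < -1e-12):
        raise NoVariationError("eigenvalues must be non-negative and non-empty")
    total = lam.sum()
    if total <= 0:
        raise NoVariationError("all eigenvalues are zero; no variation to explain")
    percent = 100.0 * lam / total
    return percent, np.cumsum(percent)


def ordinate(table: JacobianTable) -> MorphospaceResult:
    """Eigendecompose the correlation matrix of the (standardized) table.

    Constant columns are dropped (with a log warning) before
    standardization; the eigenvalue sum then equals the retained column
    count.  Scores use the sample (ddof=1) standardization so their
    per-PC variances equal the eigenvalues exactly.
    """
    X = table.matrix
    if X.shape[0] < 2:
        raise MorphosurfError("ordination needs at least 2 rows")
    stds = X.std(axis=0, ddof=1)
    keep = stds > 1e-12
    dropped = tuple(np.array(JACOBIAN_ELEMENT_ORDER)[~keep])
    if dropped:
        logger.warning("dropping constant Jacobian columns before PCA: %s", dropped)
    if not np.any(keep):
        raise NoVariationError("all Jacobian columns are constant; nothing to ordinate")
    variables = tuple(np.array(JACOBIAN_ELEMENT_ORDER)[keep])
    Xk = X[:, keep]
    means = Xk.mean(axis=0)
    sds = Xk.std(axis=0, ddof=1)
    Z = (Xk - means) / sds

    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    correlations = eigvecs * np.sqrt(eigvals)[np.newaxis, :]
    # sign convention: largest-|correlation| variable positive on each PC
    for pc in range(correlations.shape[1]):
        col = correlations[:, pc]
        if np.any(col != 0):
            idx = int(np.argmax(np.abs(col)))
            if col[idx] < 0:
                correlations[:, pc] = -col
                eigvecs[:, pc] = -eigvecs[:, pc]

    scores = Z @ eigvecs
    percent, cumulative = variance_explained(eigvals)
    return MorphospaceResult(
        labels=table.labels,
        variables=variables,
        eigenvalues=eigvals,
        percent_variance=percent,
        cumulative_percent=cumulative,
        scores=scores,
        correlations=correlations,
        column_means=means,
        column_stds=sds,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """An ordered path through morphospace (one point per growth stage).

    ``collinearity`` is the fraction of the path points' variance lying on
    their first principal direction: 1 for a perfect line (isometric
    accretionary growth), lower for allometric bending.
    """

    stage_labels: tuple[str, ...]
    points: np.ndarray
    steps: np.ndarray
    collinearity: float

    @property
    def first_direction_projections(self) -> np.ndarray:
        """Projection of each stage onto the path's first principal direction."""
        centered = self.points - self.points.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        return centered @ vt[0]


def trajectory(stage_labels: Sequence[str], space: MorphospaceResult) -> Trajectory:
    """Extract an ordered score path for the given stages.

    Every stage label must be present in the ordination; repeated identical
    stages produce zero-length steps (size-only growth plots at one point).
    """
    if len(stage_labels) < 2:
        raise MorphosurfError("a trajectory needs at least 2 stages")
    points = np.array([space.scores_for(lab) for lab in stage_labels])
    steps = np.diff(points, axis=0)

    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    total = float(np.sum(sv**2))
    collinearity = 1.0 if total <= 1e-24 else float(sv[0] ** 2 / total)
    return Trajectory(
        stage_labels=tuple(stage_labels),
        points=points,
        steps=steps,
        collinearity=collinearity,
    )
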