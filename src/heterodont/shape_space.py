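"""Shape-space PCA of Procrustes-aligned tooth crowns and the heterodonty index.

All teeth from all specimens enter one joint PCA of the flattened aligned
coordinates.  PC1 of such data is a crown aspect-ratio axis (tall/slender
vs short/stout) and PC2 a curvature axis (curvature spread over the whole
crown vs concentrated at the apex); deterministic sign conventions pin
stout crowns to positive PC1 and apex-concentrated curvature to positive
PC2, removing eigen-solver sign arbitrariness.

Heterodonty of a specimen is the sample variance (n−1 denominator) of the
PC1 scores of its teeth: a homodont row scores 0, a regionalized
(incisor/canine/postcanine) row scores high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .landmark_io import LandmarkConfiguration, SpecimenMetadata
from .superimposition import AlignedSample


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SpecimenHeterodonty:
    specimen_id: str
    n_teeth: int
    pc1_variance: float
    scores_by_position: dict[int, float]


def _bbox_aspect(points: np.ndarray) -> float:
    """Height/width bounding-box ratio (tall > 1, stout < 1)."""
    w = points[:, 0].max() - points[:, 0].min()
    h = points[:, 1].max() - points[:, 1].min()
    return float(h / w) if w > 0 else np.inf


def _apex_turning_fraction(points: np.ndarray) -> float:
    """Fraction of total absolute turning concentrated in the apical third.

    The apical third is the contiguous third of interior vertices centred on
    the highest point; a crown whose curvature is concentrated at the apex
    turns mostly there.
    """
    d = np.diff(points, axis=0)
    ang = np.arctan2(d[:, 1], d[:, 0])
    turn = np.abs(np.angle(np.exp(1j * np.diff(ang))))
    total = turn.sum()
    if total == 0:
        return 0.0
    apex = int(np.argmax(points[:, 1]))
    k = max(1, points.shape[0] // 6)
    lo = max(0, apex - 1 - k)
    hi = min(turn.shape[0], apex - 1 + k + 1)
    return float(turn[lo:hi].sum() / total)


class ShapeSpacePCA(BaseEstimator, TransformerMixin):
    """PCA of flattened aligned landmark coordinates with fixed sign conventions.

    Attributes (after ``fit``)
    --------------------------
    mean_ : (2p,) ndarray — sample mean of the aligned coordinates.
    components_ : (k, 2p) ndarray — orthonormal eigenvectors, descending.
    explained_variance_ : (k,) ndarray — eigenvalues (n−1 denominator).
    explained_variance_ratio_ : (k,) ndarray — proportions, summing to 1.
    scores_ : (n, k) ndarray — PC scores of the fitted sample (zero mean).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: AlignedSample | np.ndarray, y=None) -> "ShapeSpacePCA":
        coords = X.coordinates() if isinstance(X, AlignedSample) else np.asarray(X, float)
        n = coords.shape[0]
        if n < 3:
            raise InsufficientDataError(f"PCA needs >= 3 configurations, got {n}")
        self._p = coords.shape[1] // 2
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(coords)
        self.mean_ = pca.mean_
        self.components_ = pca.components_.copy()
        self.explained_variance_ = pca.explained_variance_.copy()
        total = coords.var(axis=0, ddof=1).sum()
        self.total_variance_ = float(total)
        self.explained_variance_ratio_ = self.explained_variance_ / total
        self.scores_ = scores
        self.sign_convention_: dict[str, str] = {}
        self._fix_signs()
        self.n_features_in_ = coords.shape[1]
        return self

    def _fix_signs(self) -> None:
        """Pin PC1 to stout-positive and PC2 to apex-curvature-positive."""
        if self.components_.shape[0] >= 1:
            s = np.sqrt(self.explained_variance_[0])
            plus = self.shape_at(0, s).points
            minus = self.shape_at(0, -s).points
            if _bbox_aspect(plus) > _bbox_aspect(minus):  # positive must be stouter
                self.components_[0] *= -1
                self.scores_[:, 0] *= -1
            self.sign_convention_["PC1"] = "short/stout crowns score positive"
        if self.components_.shape[0] >= 2:
            s = np.sqrt(self.explained_variance_[1])
            plus = self.shape_at(1, s).points
            minus = self.shape_at(1, -s).points
            if _apex_turning_fraction(plus) < _apex_turning_fraction(minus):
                self.components_[1] *= -1
                self.scores_[:, 1] *= -1
            self.sign_convention_["PC2"] = "apex-concentrated curvature scores positive"

    def transform(self, X: AlignedSample | np.ndarray) -> np.ndarray:
        coords = X.coordinates() if isinstance(X, AlignedSample) else np.asarray(X, float)
        return (coords - self.mean_) @ self.components_.T

    def shape_at(self, pc: int, score: float) -> LandmarkConfiguration:
        """Model shape at a given score along one PC (consensus + score·eigvec)."""
        if not 0 <= pc < self.components_.shape[0]:
            raise ValueError(f"PC index {pc} out of range (have {self.components_.shape[0]})")
        flat = self.mean_ + score * self.components_[pc]
        return LandmarkConfiguration(points=flat.reshape(-1, 2), specimen_id="model")


@dataclass
class ShapeSpace:
    """Fitted shape space bundled with per-tooth provenance."""

    pca: ShapeSpacePCA
    aligned: AlignedSample

    @property
    def scores(self) -> np.ndarray:
        return self.pca.scores_

    def scores_table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.aligned.configurations):
            row = {
                "specimen_id": c.specimen_id,
                "tooth_position": c.tooth_position,
                "centroid_size": self.aligned.centroid_sizes[i],
            }
            for k in range(min(self.scores.shape[1], 10)):
                row[f"PC{k + 1}"] = self.scores[i, k]
            rows.append(row)
        return pd.DataFrame(rows)


def fit_pca(aligned: AlignedSample, n_components: int | None = None) -> ShapeSpace:
    """Fit the joint shape-space PCA on an aligned sample."""
    return ShapeSpace(pca=ShapeSpacePCA(n_components=n_components).fit(aligned), aligned=aligned)


def heterodonty_index(space: ShapeSpace, specimen_id: str) -> SpecimenHeterodonty:
    """Sample variance (n−1) of a specimen's PC1 scores along its toothrow."""
    idx = [
        i
        for i, c in enumerate(space.aligned.configurations)
        if c.specimen_id == specimen_id
    ]
    if len(idx) < 2:
        raise InsufficientDataError(
            f"specimen {specimen_id!r} has {len(idx)} scored teeth; need >= 2"
        )
    pc1 = space.scores[idx, 0]
    positions = [space.aligned.configurations[i].tooth_position for i in idx]
    return SpecimenHeterodonty(
        specimen_id=specimen_id,
        n_teeth=len(idx),
        pc1_variance=float(np.var(pc1, ddof=1)),
        scores_by_position=dict(zip(positions, pc1.tolist())),
    )


def heterodonty_table(space: ShapeSpace) -> pd.DataFrame:
    """Heterodonty index for every specimen with >= 2 teeth."""
    ids = sorted({c.specimen_id for c in space.aligned.configurations})
    rows = []
    for sid in ids:
        n = sum(c.specimen_id == sid for c in space.aligned.configurations)
        if n < 2:
            continue
        h = heterodonty_index(space, sid)
        rows.append({"specimen_id": sid, "n_teeth": h.n_teeth, "pc1_variance": h.pc1_variance})
    return pd.DataFrame(rows, columns=["specimen_id", "n_teeth", "pc1_variance"])


def size_shape_association(
    space: ShapeSpace, metadata: list[SpecimenMetadata] | None = None, clade: str | None = None
) -> dict:
    """Correlations between PC1 score and log10 centroid size within a clade.

    Returns product-moment (r) and rank (rho) correlations with n; constant
    sizes yield ``{"undefined": True}`` rather than NaNs.
    """
    idx = np.arange(len(space.aligned.configurations))
    if clade is not None:
        if metadata is None:
            raise ValueError("clade filtering requires metadata")
        by_id = {m.specimen_id: m.clade for m in metadata}
        idx = np.array(
            [
                i
                for i, c in enumerate(space.aligned.configurations)
                if by_id.get(c.specimen_id) == clade
            ],
            dtype=int,
        )
    if idx.size < 3:
        raise InsufficientDataError(f"group has {idx.size} teeth; need >= 3")
    pc1 = space.scores[idx, 0]
    logsize = np.log10(space.aligned.centroid_sizes[idx])
    if np.ptp(logsize) == 0 or np.ptp(pc1) == 0:
        return {"n": int(idx.size), "undefined": True}
    r, _ = pearsonr(pc1, logsize)
    rho, _ = spearmanr(pc1, logsize)
    return {"n": int(idx.size), "r": float(r), "rho": float(rho), "undefined": False}


def morphospace_summary(
    space: ShapeSpace, metadata: list[SpecimenMetadata]
) -> pd.DataFrame:
    """Per-clade PC1/PC2 ranges, convex-hull area and tooth counts."""
    by_id = {m.specimen_id: m.clade for m in metadata}
    clades: dict[str, list[int]] = {}
    for i, c in enumerate(space.aligned.configurations):
        clade = by_id.get(c.specimen_id)
        if clade is not None:
            clades.setdefault(clade, []).append(i)
    rows = []
    for clade, idx in sorted(clades.items()):
        pts = space.scores[np.asarray(idx)][:, :2]
        area: float | None = None
        if pts.shape[0] >= 3:
            try:
                area = float(ConvexHull(pts).volume)  # 2-D "volume" is the area
            except QhullError:
                area = 0.0  # collinear scores
        rows.append(
            {
                "clade": clade,
                "n_teeth": len(idx),
                "pc1_range": float(np.ptp(pts[:, 0])),
                "pc2_range": float(np.ptp(pts[:, 1])) if pts.shape[1] > 1 else 0.0,
                "hull_area": area,
            }
        )
    return pd.DataFrame(rows, columns=["clade", "n_teeth", "pc1_range", "pc2_range", "hull_area"])
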