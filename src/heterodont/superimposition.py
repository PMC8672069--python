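"""Generalized Procrustes analysis of landmark configurations.

Partial Procrustes superimposition: every configuration is centred, scaled
to unit centroid size, and rotated (rotation only — reflections are never
fitted; handedness is standardized at input) to the running consensus,
which is re-estimated until it stops moving.  Optionally the interior
semi-landmarks are slid along chord-estimated tangent directions to
minimize Procrustes distance to the consensus.

The consensus is finally rotated to a canonical orientation (major
principal axis horizontal, apex up, mesial landmark on the left), removing
the one global rotation GPA leaves arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .landmark_io import DegenerateGeometryError, LandmarkConfiguration


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, iteration_log: list[float]):
        super().__init__(msg)
        self.iteration_log = iteration_log


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared deviations of points from their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    dev = pts - pts.mean(axis=0)
    cs = float(np.sqrt((dev**2).sum()))
    if cs <= 0:
        raise DegenerateGeometryError("all landmarks coincide; centroid size is zero")
    return cs


def _center_scale(pts: np.ndarray) -> np.ndarray:
    dev = pts - pts.mean(axis=0)
    cs = np.sqrt((dev**2).sum())
    if cs <= 0:
        raise DegenerateGeometryError("degenerate configuration (zero centroid size)")
    return dev / cs


def _optimal_rotation(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||target @ R - reference||."""
    u, _, vt = np.linalg.svd(target.T @ reference)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def align_pair(
    target: LandmarkConfiguration, reference: LandmarkConfiguration
) -> tuple[LandmarkConfiguration, float]:
    """Superimpose ``target`` on ``reference``; return it and the Procrustes distance.

    Both are centred and scaled to unit centroid size; the target is rotated
    (no reflection) to minimize the summed squared distance, whose square
    root — the partial Procrustes distance — is returned.
    """
    if target.n_points != reference.n_points:
        raise ValueError(
            f"point-count mismatch: {target.n_points} vs {reference.n_points}"
        )
    t = _center_scale(target.points)
    r = _center_scale(reference.points)
    rot = _optimal_rotation(t, r)
    aligned = t @ rot
    dist = float(np.sqrt(((aligned - r) ** 2).sum()))
    return replace(target, points=aligned), dist


def _slide_pass(pts: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """One Gauss–Seidel sliding pass along chord tangents (min Procrustes distance).

    Semi-landmark i slides along the unit chord direction between its
    neighbours to the foot of the perpendicular from the consensus point.
    Endpoints (the fixed landmarks) never move.
    """
    out = pts.copy()
    for i in range(1, pts.shape[0] - 1):
        tangent = out[i + 1] - out[i - 1]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent /= norm
        out[i] = out[i] + ((consensus[i] - out[i]) @ tangent) * tangent
    return out


@dataclass
class AlignedSample:
    """Result of a GPA run."""

    configurations: list[LandmarkConfiguration]
    consensus: np.ndarray  # (p, 2), unit centroid size, canonical orientation
    centroid_sizes: np.ndarray  # original units
    distances: np.ndarray  # partial Procrustes distance to consensus
    iteration_log: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.configurations)

    def coordinates(self) -> np.ndarray:
        """(n, 2p) matrix of flattened aligned coordinates."""
        return np.stack([c.flattened() for c in self.configurations])


class GeneralizedProcrustesAnalysis(BaseEstimator, TransformerMixin):
    """Iterative Procrustes superimposition to a common consensus.

    Parameters
    ----------
    slide : bool, default False
        Slide semi-landmarks along chord-estimated tangents (one pass per
        outer iteration) to minimize Procrustes distance to the consensus.
    tol : float, default 1e-8
        Convergence tolerance on the RMS change of the consensus.
    max_iter : int, default 100

    Attributes
    ----------
    consensus_ : (p, 2) ndarray
        Mean shape at unit centroid size, canonically oriented.
    iteration_log_ : list of float
        RMS consensus change per iteration (strictly decreasing after the
        first entry on well-posed samples).
    """

    def __init__(self, slide: bool = False, tol: float = 1e-8, max_iter: int = 100):
        self.slide = slide
        self.tol = tol
        self.max_iter = max_iter

    # -- canonical orientation ------------------------------------------------
    @staticmethod
    def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
        """Rotation putting the crown-base chord on x with the apex up.

        Orienting on the chord between the two fixed (crown-base) landmarks
        keeps x mesiodistal and y apicobasal for every sample composition,
        so crown aspect ratios read directly off the aligned coordinates;
        the mesial landmark ends up on the left for left-lateral data.
        """
        chord = consensus[-1] - consensus[0]
        theta = np.arctan2(chord[1], chord[0])
        c, s = np.cos(-theta), np.sin(-theta)
        rot = np.array([[c, s], [-s, c]])  # row-vector rotation by -theta
        rotated = consensus @ rot
        chord_y = 0.5 * (rotated[0, 1] + rotated[-1, 1])
        if rotated[1:-1, 1].mean() < chord_y:  # apex below the base: flip
            rot = rot @ np.array([[-1.0, 0.0], [0.0, -1.0]])
        return rot

    def fit(self, X: list[LandmarkConfiguration], y=None) -> "GeneralizedProcrustesAnalysis":
        self.fit_transform(X)
        return self

    def fit_transform(self, X: list[LandmarkConfiguration], y=None) -> AlignedSample:
        configs = list(X)
        if len(configs) < 2:
            raise ValueError("GPA needs at least 2 configurations")
        p = configs[0].n_points
        if any(c.n_points != p for c in configs):
            raise ValueError("all configurations must have the same point count")

        sizes = np.array([centroid_size(c) for c in configs])
        shapes = np.stack([_center_scale(c.points) for c in configs])

        log: list[float] = []

        def iterate_alignment(consensus: np.ndarray) -> np.ndarray:
            """Align-to-mean / re-mean until the consensus stops moving.

            Iterates past ``tol`` while still contracting so the fixpoint is
            resolved essentially to machine precision (alignment results are
            then independent of input order well below tol).
            """
            prev = np.inf
            for _ in range(self.max_iter):
                for i in range(shapes.shape[0]):
                    shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
                new_consensus = _center_scale(shapes.mean(axis=0))
                change = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
                log.append(change)
                consensus = new_consensus
                if change < 1e-15 or (change < self.tol and change >= 0.9 * prev):
                    return consensus
                prev = change
            if change < self.tol:
                return consensus
            raise ConvergenceError(
                f"GPA did not converge in {self.max_iter} iterations", log
            )

        consensus = iterate_alignment(_center_scale(shapes[0].copy()))
        if self.slide:
            # bounded sliding phase: a few Gauss-Seidel passes, each followed
            # by realignment, then a final plain re-convergence — every step
            # lowers the Procrustes sum of squares from the plain optimum
            for _ in range(5):
                for i in range(shapes.shape[0]):
                    shapes[i] = _center_scale(_slide_pass(shapes[i], consensus))
                    shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
                consensus = _center_scale(shapes.mean(axis=0))
            consensus = iterate_alignment(consensus)

        rot = self._canonical_rotation(consensus)
        consensus = consensus @ rot
        shapes = shapes @ rot

        dists = np.sqrt(((shapes - consensus) ** 2).sum(axis=(1, 2)))
        aligned = [
            replace(c, points=shapes[i]) for i, c in enumerate(configs)
        ]
        self.consensus_ = consensus
        self.iteration_log_ = log
        self.n_features_in_ = 2 * p
        return AlignedSample(
            configurations=aligned,
            consensus=consensus,
            centroid_sizes=sizes,
            distances=dists,
            iteration_log=log,
        )

    def transform(self, X: list[LandmarkConfiguration]) -> AlignedSample:
        """Align new configurations to the fitted consensus (no re-estimation)."""
        if not hasattr(self, "consensus_"):
            raise RuntimeError("GeneralizedProcrustesAnalysis is not fitted")
        sizes = np.array([centroid_size(c) for c in X])
        shapes = []
        for c in X:
            s = _center_scale(c.points)
            s = s @ _optimal_rotation(s, self.consensus_)
            shapes.append(s)
        arr = np.stack(shapes)
        dists = np.sqrt(((arr - self.consensus_) ** 2).sum(axis=(1, 2)))
        aligned = [replace(c, points=arr[i]) for i, c in enumerate(X)]
        return AlignedSample(
            configurations=aligned,
            consensus=self.consensus_,
            centroid_sizes=sizes,
            distances=dists,
            iteration_log=list(self.iteration_log_),
        )


def gpa(
    configs: list[LandmarkConfiguration],
    slide: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedSample:
    """Functional wrapper over :class:`GeneralizedProcrustesAnalysis`."""
    return GeneralizedProcrustesAnalysis(slide=slide, tol=tol, max_iter=max_iter).fit_transform(
        configs
    )
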