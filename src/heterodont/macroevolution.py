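"""Body-mass scaling and stage-binned macroevolutionary time series.

Body mass is estimated from femur length through a power law
``mass = a · FL^b`` fitted by ordinary least squares on log10–log10 axes to
a reference table of taxa with known femur lengths and masses.  Estimated
masses and per-specimen heterodonty indices are then binned by ICS geologic
stage and diet to give mean carnivore/herbivore body mass and mean PC1
variance per stage — the quantities behind diet-partitioned body-size and
heterodonty trajectories through the late Carboniferous and Permian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .landmark_io import STAGE_ORDER, SpecimenMetadata


class DataError(ValueError):
    pass


class PowerLawRegressor(BaseEstimator, RegressorMixin):
    """Power-law fit mass = a · x^b via least squares on log10 scales.

    Attributes
    ----------
    coef_a_ : float — multiplicative coefficient (kg · mm^-b).
    coef_b_ : float — scaling exponent.
    r2_ : float — coefficient of determination on the log10 scale.
    residual_sd_ : float — residual standard deviation of log10(mass).
    n_ : int — number of reference points used.
    """

    def fit(self, X, y) -> "PowerLawRegressor":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if x.size < 3:
            raise DataError(f"power-law fit needs >= 3 points, got {x.size}")
        if (x <= 0).any() or (y <= 0).any():
            raise DataError("femur lengths and masses must all be positive")
        lx, ly = np.log10(x), np.log10(y)
        design = np.column_stack([lx, np.ones_like(lx)])
        (slope, intercept), *_ = np.linalg.lstsq(design, ly, rcond=None)
        self.coef_b_ = float(slope)
        self.coef_a_ = float(10**intercept)
        resid = ly - (slope * lx + intercept)
        ss_res = float((resid**2).sum())
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.residual_sd_ = float(np.sqrt(ss_res / max(x.size - 2, 1)))
        self.n_ = int(x.size)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        if (x <= 0).any():
            raise DataError("femur length must be positive")
        return self.coef_a_ * x**self.coef_b_


def fit_power_law(reference: pd.DataFrame | Iterable[tuple[float, float]]) -> PowerLawRegressor:
    """Fit the femur-length→mass power law from a reference table.

    Accepts a DataFrame with ``femur_length_mm``/``body_mass_kg`` columns or
    an iterable of (femur_length, mass) pairs.
    """
    if isinstance(reference, pd.DataFrame):
        x = reference["femur_length_mm"].to_numpy(float)
        y = reference["body_mass_kg"].to_numpy(float)
    else:
        pairs = np.asarray(list(reference), dtype=float)
        x, y = pairs[:, 0], pairs[:, 1]
    return PowerLawRegressor().fit(x, y)


def estimate_mass(model: PowerLawRegressor, femur_length_mm: float | None) -> float | None:
    """a · FL^b; ``None`` femur lengths yield ``None`` (taxon excluded later)."""
    if femur_length_mm is None or (
        isinstance(femur_length_mm, float) and np.isnan(femur_length_mm)
    ):
        return None
    return float(model.predict([femur_length_mm])[0])


@dataclass
class StageSeries:
    """Stage-binned means, oldest stage first; empty cells are NaN (absent)."""

    table: pd.DataFrame  # one row per stage in declared order

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stage_series(
    metadata: Sequence[SpecimenMetadata],
    masses: dict[str, float | None],
    heterodonty: dict[str, float],
    stage_order: Sequence[str] = STAGE_ORDER,
    exclude_clades_from_heterodonty: Sequence[str] = (),
) -> StageSeries:
    """Per-stage mean mass by diet and mean heterodonty across taxa.

    ``masses`` and ``heterodonty`` map specimen_id → value; specimens with
    missing entries simply do not contribute to that mean (cells with no
    contributors are NaN, never 0).  Clades in the exclusion list (e.g.
    groups lacking a pre-/postcanine dentition) are dropped from the
    heterodonty means only.
    """
    known = set(stage_order)
    bad = sorted({m.stage for m in metadata} - known)
    if bad:
        raise DataError(f"unknown stage labels: {bad}")
    rows = []
    for stage in stage_order:
        recs = [m for m in metadata if m.stage == stage]
        carn = [
            masses[m.specimen_id]
            for m in recs
            if m.diet == "carnivore" and masses.get(m.specimen_id) is not None
        ]
        herb = [
            masses[m.specimen_id]
            for m in recs
            if m.diet == "herbivore" and masses.get(m.specimen_id) is not None
        ]
        het = [
            heterodonty[m.specimen_id]
            for m in recs
            if m.specimen_id in heterodonty
            and m.clade not in exclude_clades_from_heterodonty
        ]
        rows.append(
            {
                "stage": stage,
                "mean_mass_carnivore_kg": np.mean(carn) if carn else np.nan,
                "mean_mass_herbivore_kg": np.mean(herb) if herb else np.nan,
                "mean_pc1_variance": np.mean(het) if het else np.nan,
                "n_carnivores": len(carn),
                "n_herbivores": len(herb),
                "n_heterodonty_taxa": len(het),
            }
        )
    return StageSeries(table=pd.DataFrame(rows))
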