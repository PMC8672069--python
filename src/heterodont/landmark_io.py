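"""TPS landmark/curve file I/O, outline resampling, and specimen metadata.

Tooth crowns are digitized as open 2-D curves running from the mesial
crown-base over the apex to the distal crown-base.  Each curve is reduced to
a fixed 30-point configuration: two fixed landmarks (the crown-base
endpoints) plus 28 semi-landmarks placed at equal arc-length fractions along
the digitized outline.  Both the number of semi-landmarks and the TPS
dialect (LM=, CURVES=, POINTS=, IMAGE=, ID=, SCALE= records) are those of
the tpsDig2/tpsRelW software family.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ICS stages of the studied interval, oldest first (Kasimovian → Changxingian).
STAGE_ORDER: tuple[str, ...] = (
    "Kasimovian",
    "Gzhelian",
    "Asselian",
    "Sakmarian",
    "Artinskian",
    "Kungurian",
    "Roadian",
    "Wordian",
    "Capitanian",
    "Wuchiapingian",
    "Changxingian",
)

#: Sampled higher-level groups used as clade labels.
CLADE_LABELS: tuple[str, ...] = (
    "Caseasauria",
    "Varanopidae",
    "Ophiacodontidae",
    "Edaphosauridae",
    "Sphenacodontia",
    "Biarmosuchia",
    "Dinocephalia",
    "Anomodontia",
    "Gorgonopsia",
    "Therocephalia",
    "Cynodontia",
    "synthetic",
)

DIET_LABELS = ("carnivore", "herbivore", "other")

METADATA_COLUMNS = (
    "specimen_id",
    "taxon",
    "clade",
    "diet",
    "stage",
    "femur_length_mm",
    "skull_length_mm",
)


class TPSFormatError(ValueError):
    """Malformed TPS record (carries the offending line number)."""


class DegenerateGeometryError(ValueError):
    """Outline has no usable geometry (zero length / coincident points)."""


class MetadataError(ValueError):
    """Invalid specimen metadata table."""


@dataclass(frozen=True)
class Outline:
    """Ordered open 2-D curve of one tooth crown.

    Vertices run mesial base → apex → distal base, in calibrated units when
    a TPS SCALE record was present.
    """

    vertices: np.ndarray  # (n, 2) float
    specimen_id: str = ""
    tooth_position: int = 1
    scale: float | None = None
    reflected: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs an (n>=3, 2) vertex array")
        if np.allclose(v[0], v[-1]):
            raise ValueError("outline must be an open curve (first != last vertex)")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class LandmarkConfiguration:
    """Fixed + semi-landmark representation of one tooth crown.

    Point 1 and point ``n`` (1-based, as in the file formats) are the mesial
    and distal crown-base landmarks; interior points are semi-landmarks
    equally spaced in arc length along the source outline.
    """

    points: np.ndarray  # (2 + n_semi, 2)
    specimen_id: str = ""
    tooth_position: int = 1
    reflected: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 4:
            raise ValueError("configuration needs an (n>=4, 2) point array")
        object.__setattr__(self, "points", p)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def n_semi(self) -> int:
        return self.n_points - 2

    def flattened(self) -> np.ndarray:
        return self.points.reshape(-1)


@dataclass(frozen=True)
class SpecimenMetadata:
    specimen_id: str
    taxon: str
    clade: str
    diet: str
    stage: str
    femur_length_mm: float | None = None
    skull_length_mm: float | None = None
    damaged: bool = False


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^\s*(LM|CURVES|POINTS|IMAGE|ID|SCALE)\s*=\s*(.*?)\s*$", re.I)


def _split_id(raw: str) -> tuple[str, int]:
    """ID records encode specimen and tooth position as ``<specimen>__t<k>``."""
    m = re.match(r"^(.*)__t(\d+)$", raw)
    if m:
        return m.group(1), int(m.group(2))
    return raw, 1


def read_tps(path: str | Path, orient_crown_up: bool = True) -> list[Outline]:
    """Read a TPS landmark/curve file into a list of outlines.

    The SCALE factor, when present, multiplies coordinates into calibrated
    units.  If ``orient_crown_up`` the y axis is normalized so the crown
    apex lies above the chord between the curve endpoints (image coordinate
    systems often run y-down).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    outlines: list[Outline] = []
    i = 0
    n = len(lines)

    def parse_points(count: int, start: int) -> tuple[np.ndarray, int]:
        pts = []
        j = start
        while len(pts) < count and j < n:
            line = lines[j].strip()
            j += 1
            if not line:
                continue
            if _TPS_KEY.match(line):
                raise TPSFormatError(
                    f"{path.name}:{j}: expected {count} coordinate pairs, got {len(pts)}"
                )
            parts = line.split()
            if len(parts) < 2:
                raise TPSFormatError(f"{path.name}:{j}: malformed coordinate line {line!r}")
            pts.append((float(parts[0]), float(parts[1])))
        if len(pts) < count:
            raise TPSFormatError(
                f"{path.name}:{j}: expected {count} coordinate pairs, got {len(pts)}"
            )
        return np.asarray(pts, dtype=float), j

    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _TPS_KEY.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TPSFormatError(f"{path.name}:{i + 1}: expected LM= record, got {line!r}")
        n_lm = int(m.group(2))
        i += 1
        fixed, i = parse_points(n_lm, i) if n_lm else (np.empty((0, 2)), i)
        curves: list[np.ndarray] = []
        image = ""
        spec_id = ""
        scale: float | None = None
        while i < n:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            m = _TPS_KEY.match(line)
            if m is None:
                raise TPSFormatError(f"{path.name}:{i + 1}: unexpected line {line!r}")
            key, val = m.group(1).upper(), m.group(2)
            if key == "LM":
                break
            i += 1
            if key == "CURVES":
                n_curves = int(val)
                for _ in range(n_curves):
                    while i < n and not lines[i].strip():
                        i += 1
                    pm = _TPS_KEY.match(lines[i].strip()) if i < n else None
                    if pm is None or pm.group(1).upper() != "POINTS":
                        raise TPSFormatError(f"{path.name}:{i + 1}: expected POINTS= record")
                    n_pts = int(pm.group(2))
                    i += 1
                    pts, i = parse_points(n_pts, i)
                    curves.append(pts)
            elif key == "IMAGE":
                image = val
            elif key == "ID":
                spec_id = val
            elif key == "SCALE":
                scale = float(val)
        if not curves and fixed.shape[0] >= 3:
            curves = [fixed]
        base_id, tooth_pos = _split_id(spec_id or image)
        for k, pts in enumerate(curves):
            v = pts * scale if scale is not None else pts.copy()
            if orient_crown_up:
                chord_y = 0.5 * (v[0, 1] + v[-1, 1])
                if v[1:-1, 1].mean() < chord_y:
                    v[:, 1] = 2 * chord_y - v[:, 1]
            outlines.append(
                Outline(
                    vertices=v,
                    specimen_id=base_id,
                    tooth_position=tooth_pos + k,
                    scale=scale,
                )
            )
    if not outlines:
        logger.warning("TPS file %s contained no outlines", path)
    return outlines


def write_tps(outlines: Iterable[Outline], path: str | Path, scale: float = 1.0) -> None:
    """Write outlines in the TPS curve dialect (LF endings, explicit SCALE).

    Coordinates are divided by ``scale`` on output so a reader applying the
    SCALE record recovers the calibrated values.
    """
    path = Path(path)
    chunks: list[str] = []
    for o in outlines:
        v = o.vertices / scale
        chunks.append("LM=0")
        chunks.append("CURVES=1")
        chunks.append(f"POINTS={o.n_vertices}")
        chunks.extend(f"{x:.10f} {y:.10f}" for x, y in v)
        chunks.append(f"IMAGE={o.specimen_id}.png")
        chunks.append(f"ID={o.specimen_id}__t{o.tooth_position}")
        chunks.append(f"SCALE={scale:.10f}")
    path.write_text("\n".join(chunks) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_to_configuration(outline: Outline, n_semi: int = 28) -> LandmarkConfiguration:
    """Resample an outline to 2 fixed + ``n_semi`` semi-landmarks.

    The endpoints are kept exactly; interior points are placed by linear
    interpolation along the polyline at arc-length fractions ``k/(n_semi+1)``.
    """
    if n_semi < 1:
        raise ValueError("n_semi must be >= 1")
    v = outline.vertices
    if v.shape[0] < n_semi + 2:
        # densify by repeated midpoint insertion; positions are arc-length
        # defined so this does not move the resampled landmarks
        while v.shape[0] < n_semi + 2:
            mids = 0.5 * (v[:-1] + v[1:])
            out = np.empty((v.shape[0] + mids.shape[0], 2))
            out[0::2] = v
            out[1::2] = mids
            v = out
        outline = replace(outline, vertices=v)
    s = outline.arc_lengths()
    total = s[-1]
    if total <= 0:
        raise DegenerateGeometryError(
            f"outline {outline.specimen_id} t{outline.tooth_position} has zero arc length"
        )
    fracs = np.arange(1, n_semi + 1) / (n_semi + 1)
    targets = fracs * total
    xs = np.interp(targets, s, v[:, 0])
    ys = np.interp(targets, s, v[:, 1])
    pts = np.vstack([v[0], np.column_stack([xs, ys]), v[-1]])
    return LandmarkConfiguration(
        points=pts,
        specimen_id=outline.specimen_id,
        tooth_position=outline.tooth_position,
        reflected=outline.reflected,
    )


def reflect_outline(outline: Outline) -> Outline:
    """Mirror a right-jaw outline about the vertical axis (to left-lateral)."""
    v = outline.vertices.copy()
    v[:, 0] = -v[:, 0]
    return replace(outline, vertices=v, reflected=not outline.reflected)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def read_metadata(
    path: str | Path,
    stage_order: Sequence[str] = STAGE_ORDER,
    clade_labels: Sequence[str] = CLADE_LABELS,
) -> list[SpecimenMetadata]:
    """Read and validate the specimen metadata CSV.

    Unknown diets map to ``other`` with a warning; unknown stage or clade
    labels raise.  Missing femur/skull lengths are kept as ``None`` (such
    records are excluded later from mass estimation, not dropped here).
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata CSV missing columns: {missing}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise MetadataError(f"duplicate specimen_id values: {sorted(set(dupes))}")
    bad_stage = sorted(set(df["stage"]) - set(stage_order))
    if bad_stage:
        raise MetadataError(f"unknown stage labels: {bad_stage}")
    bad_clade = sorted(set(df["clade"]) - set(clade_labels))
    if bad_clade:
        raise MetadataError(f"unknown clade labels: {bad_clade}")
    records: list[SpecimenMetadata] = []
    for row in df.itertuples(index=False):
        diet = str(row.diet)
        if diet not in DIET_LABELS:
            logger.warning("diet %r for %s mapped to 'other'", diet, row.specimen_id)
            diet = "other"
        fl = None if pd.isna(row.femur_length_mm) else float(row.femur_length_mm)
        sl = None if pd.isna(row.skull_length_mm) else float(row.skull_length_mm)
        damaged = bool(getattr(row, "damaged", False))
        records.append(
            SpecimenMetadata(
                specimen_id=str(row.specimen_id),
                taxon=str(row.taxon),
                clade=str(row.clade),
                diet=diet,
                stage=str(row.stage),
                femur_length_mm=fl,
                skull_length_mm=sl,
                damaged=damaged,
            )
        )
    return records


def write_metadata(records: Iterable[SpecimenMetadata], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "taxon": r.taxon,
            "clade": r.clade,
            "diet": r.diet,
            "stage": r.stage,
            "femur_length_mm": r.femur_length_mm,
            "skull_length_mm": r.skull_length_mm,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, index=False)
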