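"""Synthetic study inputs with known ground truth.

The real study digitized tooth crowns from photographs and took femur/mass
reference data from the literature; nothing downloadable backs those steps,
so this module generates them:

* parametric single-apex crown outlines (height, base width, recurvature,
  apex sharpness) on a blended triangle/superellipse profile;
* toothrow profiles — ``homodont`` (all positions identical) and
  ``caniniform`` (first three teeth consecutively increasing, a short
  diastema, an enlarged fourth caniniform at least twice the postcanine
  height, then low-crowned postcanines — the pattern of basal
  sphenacodontian dentaries);
* whole assemblages of specimens with clade/diet/stage labels, femur
  lengths and power-law true body masses;
* discrete character matrices evolved root-to-tip on a known tree, for
  parsimony recovery tests;
* a synthetic femur-length→body-mass reference table standing in for
  published extant-tetrapod scaling data.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landmark_io import (
    Outline,
    SpecimenMetadata,
    write_metadata,
    write_tps,
)

#: Default power law linking femur length (mm) to body mass (kg):
#: mass = MASS_COEF * FL**MASS_EXP.  Cube-law exponent with a coefficient
#: placing a 100 mm femur at 10 kg — a realistic mid-sized Permian synapsid.
MASS_COEF = 1e-5
MASS_EXP = 3.0
#: Log-normal multiplicative noise (sd on the log10 scale) for true masses.
MASS_LOG10_SD = 0.1


@dataclass(frozen=True)
class ToothParams:
    """Generative parameters of one crown outline.

    recurvature is the apex offset as a (signed) fraction of half the base
    width — positive values lean the apex distally, as in recurved canines.
    apex_sharpness > 0 blends the flank profile from pointed (<= 1,
    triangular) to blunt (large, superelliptical shoulders).
    """

    height: float
    base_width: float
    recurvature: float = 0.0
    apex_sharpness: float = 1.5

    def __post_init__(self) -> None:
        if self.height <= 0 or self.base_width <= 0:
            raise ValueError("height and base_width must be > 0")
        if abs(self.recurvature) > 1:
            raise ValueError("|recurvature| must be <= 1")
        if self.apex_sharpness <= 0:
            raise ValueError("apex_sharpness must be > 0")

    @property
    def aspect_ratio(self) -> float:
        return self.height / self.base_width


@dataclass(frozen=True)
class ToothrowProfile:
    """Tooth parameters along one jaw.

    ``teeth`` maps 1-based tooth position to parameters; positions listed in
    ``diastema_positions`` carry no tooth and keep their ordinal index.
    ``gap_after_positions`` records short physical diastemata that do not
    consume a tooth position (e.g. the narrow gap between the third tooth
    and the caniniform in basal sphenacodontians).
    """

    n_positions: int
    teeth: Mapping[int, ToothParams]
    diastema_positions: frozenset[int] = frozenset()
    gap_after_positions: frozenset[int] = frozenset()
    profile_name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise ValueError("a toothrow needs >= 2 positions")
        if set(self.teeth) & set(self.diastema_positions):
            raise ValueError("diastema positions must carry no tooth parameters")
        if any(not 1 <= p <= self.n_positions for p in self.teeth):
            raise ValueError("tooth positions must lie in 1..n_positions")

    def heights(self) -> dict[int, float]:
        return {p: t.height for p, t in sorted(self.teeth.items())}


@dataclass(frozen=True)
class SpecimenRecord:
    metadata: SpecimenMetadata
    profile: ToothrowProfile
    outlines: tuple[Outline, ...]
    true_mass_kg: float


@dataclass(frozen=True)
class SimulatedAssemblage:
    specimens: tuple[SpecimenRecord, ...]
    seed: int

    def all_outlines(self) -> list[Outline]:
        return [o for s in self.specimens for o in s.outlines]

    def metadata(self) -> list[SpecimenMetadata]:
        return [s.metadata for s in self.specimens]


# ---------------------------------------------------------------------------
# Crown outlines
# ---------------------------------------------------------------------------


def make_tooth_outline(
    params: ToothParams,
    n_points: int = 101,
    seed: int | None = None,
    specimen_id: str = "",
    tooth_position: int = 1,
) -> Outline:
    """Generate a single-apex crown outline from base to base.

    The curve runs from the mesial base (−w/2, 0) through the apex at
    (r·w/2, h) to the distal base (+w/2, 0).  Each flank is the profile
    y/h = 1 − u**s where u ∈ [0, 1] is the normalized horizontal distance
    from the apex and s the apex sharpness: s = 1 gives a triangle, larger
    s a blunter, superellipse-like crown.  x is monotone on each flank so
    the polyline can never self-intersect.

    With a seed, a smooth low-frequency perturbation (amplitude <= 2% of
    crown height, vanishing at base and apex) emulates digitization noise.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    h, w, r, s = params.height, params.base_width, params.recurvature, params.apex_sharpness
    apex_x = r * w / 2.0
    n_mesial = (n_points + 1) // 2  # includes apex
    n_distal = n_points - n_mesial + 1  # includes apex

    def flank(base_x: float, m: int) -> np.ndarray:
        u = np.linspace(1.0, 0.0, m)  # 1 at base, 0 at apex
        x = apex_x + (base_x - apex_x) * u
        y = h * (1.0 - u**s)
        return np.column_stack([x, y])

    mesial = flank(-w / 2.0, n_mesial)
    distal = flank(+w / 2.0, n_distal)[::-1]  # apex → distal base
    pts = np.vstack([mesial, distal[1:]])

    if seed is not None:
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, 1.0, pts.shape[0])
        wave = np.zeros_like(t)
        for k in (1, 2, 3):
            wave += rng.normal() * np.sin(np.pi * k * t + rng.uniform(0, 2 * np.pi))
        wave *= np.sin(np.pi * t) ** 2  # pin both endpoints
        amp = 0.02 * h / max(np.abs(wave).max(), 1e-12)
        # perturb along local normals of the clean curve
        d = np.gradient(pts, axis=0)
        norms = np.column_stack([-d[:, 1], d[:, 0]])
        norms /= np.linalg.norm(norms, axis=1, keepdims=True)
        pts = pts + (amp * wave)[:, None] * norms
        pts[0] = (-w / 2.0, 0.0)
        pts[-1] = (+w / 2.0, 0.0)

    return Outline(
        vertices=pts,
        specimen_id=specimen_id,
        tooth_position=tooth_position,
    )


# ---------------------------------------------------------------------------
# Toothrow profiles
# ---------------------------------------------------------------------------

_HOMODONT_PARAMS = ToothParams(height=1.5, base_width=1.0, recurvature=0.1, apex_sharpness=1.5)


def make_toothrow(profile_name: str, n_positions: int, seed: int = 0) -> ToothrowProfile:
    """Build a named toothrow profile.

    ``homodont``: every position carries identical parameters.
    ``caniniform``: positions 1–3 strictly increasing in height, a short
    diastema after position 3, an enlarged position-4 caniniform at least
    twice the median postcanine height, then low-aspect postcanines with a
    gentle posterior decline.
    """
    if profile_name == "homodont":
        teeth = {p: _HOMODONT_PARAMS for p in range(1, n_positions + 1)}
        return ToothrowProfile(
            n_positions=n_positions, teeth=teeth, profile_name="homodont"
        )
    if profile_name != "caniniform":
        raise ValueError(f"unknown profile {profile_name!r}; use homodont or caniniform")
    if n_positions < 6:
        raise ValueError("caniniform profile needs >= 6 positions")
    rng = np.random.default_rng(seed)
    post_h = 1.0  # postcanine reference height
    teeth: dict[int, ToothParams] = {}
    # incisor region: consecutively increasing, slender, recurved
    inc_heights = np.array([1.25, 1.6, 2.0]) * post_h
    inc_heights *= 1.0 + rng.uniform(-0.03, 0.03)  # common factor keeps the order strict
    for p, ht in zip((1, 2, 3), inc_heights):
        teeth[p] = ToothParams(
            height=float(ht), base_width=float(ht / 2.6), recurvature=0.25, apex_sharpness=1.2
        )
    # caniniform on its buttress: 2.2–2.5x the postcanines
    can_h = post_h * float(rng.uniform(2.2, 2.5))
    teeth[4] = ToothParams(
        height=can_h, base_width=can_h / 2.8, recurvature=0.3, apex_sharpness=1.1
    )
    # postcanines: low aspect ratio, wide hyperbolic bases, mild posterior decline
    for p in range(5, n_positions + 1):
        decline = 1.0 - 0.3 * (p - 5) / max(n_positions - 5, 1)
        ht = post_h * decline * float(1.0 + rng.uniform(-0.05, 0.05))
        teeth[p] = ToothParams(
            height=ht, base_width=ht / 1.1, recurvature=0.15, apex_sharpness=1.8
        )
    return ToothrowProfile(
        n_positions=n_positions,
        teeth=teeth,
        gap_after_positions=frozenset({3}),
        profile_name="caniniform",
    )


# ---------------------------------------------------------------------------
# Assemblages
# ---------------------------------------------------------------------------


def simulate_assemblage(
    n_specimens: int,
    mix: float = 0.5,
    stage_labels: Sequence[str] = ("Kasimovian", "Asselian", "Artinskian", "Kungurian", "Capitanian"),
    seed: int = 0,
    n_positions: int = 12,
    outline_points: int = 61,
) -> SimulatedAssemblage:
    """Simulate a specimen assemblage with known morphology and body size.

    A fraction ``mix`` of specimens get caniniform (carnivore) toothrows,
    the rest homodont (herbivore) rows.  Femur lengths are drawn log-
    uniformly over 50–500 mm with a stage-dependent diet trend (herbivores
    start smaller and grow faster through the stage sequence, so mean
    herbivore mass overtakes carnivore mass mid-sequence); true masses
    follow mass = MASS_COEF · FL^MASS_EXP with log-normal noise
    (sd MASS_LOG10_SD on log10 mass).
    """
    if not 0 <= mix <= 1:
        raise ValueError("mix must lie in [0, 1]")
    if not stage_labels:
        raise ValueError("stage_labels must be non-empty")
    rng = np.random.default_rng(seed)
    n_can = int(round(mix * n_specimens))
    specimens: list[SpecimenRecord] = []
    for i in range(n_specimens):
        caniniform = i < n_can
        profile_name = "caniniform" if caniniform else "homodont"
        diet = "carnivore" if caniniform else "herbivore"
        stage_idx = int(rng.integers(len(stage_labels)))
        stage_frac = stage_idx / max(len(stage_labels) - 1, 1)
        profile = make_toothrow(profile_name, n_positions, seed=int(rng.integers(2**31)))
        # femur length: log10 mm; carnivores start larger, herbivores overtake
        if diet == "carnivore":
            mu = 2.15 + 0.10 * stage_frac
        else:
            mu = 1.95 + 0.55 * stage_frac
        fl = float(10 ** rng.normal(mu, 0.08))
        mass = MASS_COEF * fl**MASS_EXP * float(10 ** rng.normal(0.0, MASS_LOG10_SD))
        sid = f"SYN{i + 1:04d}"
        meta = SpecimenMetadata(
            specimen_id=sid,
            taxon=f"Synthodon_{profile_name}_{i + 1}",
            clade="synthetic",
            diet=diet,
            stage=stage_labels[stage_idx],
            femur_length_mm=fl,
            skull_length_mm=fl * 1.4,
        )
        outlines = []
        for pos, tp in sorted(profile.teeth.items()):
            outlines.append(
                make_tooth_outline(
                    tp,
                    n_points=outline_points,
                    seed=int(rng.integers(2**31)),
                    specimen_id=sid,
                    tooth_position=pos,
                )
            )
        specimens.append(
            SpecimenRecord(
                metadata=meta,
                profile=profile,
                outlines=tuple(outlines),
                true_mass_kg=mass,
            )
        )
    return SimulatedAssemblage(specimens=tuple(specimens), seed=seed)


def write_assemblage(assemblage: SimulatedAssemblage, out_dir: str | Path) -> dict[str, Path]:
    """Write TPS outlines + metadata CSV + true-mass table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tps_path = out / "outlines.tps"
    meta_path = out / "metadata.csv"
    truth_path = out / "true_masses.csv"
    write_tps(assemblage.all_outlines(), tps_path, scale=1.0)
    write_metadata(assemblage.metadata(), meta_path)
    pd.DataFrame(
        {
            "specimen_id": [s.metadata.specimen_id for s in assemblage.specimens],
            "true_mass_kg": [s.true_mass_kg for s in assemblage.specimens],
            "profile": [s.profile.profile_name for s in assemblage.specimens],
        }
    ).to_csv(truth_path, index=False)
    return {"tps": tps_path, "metadata": meta_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# Body-mass reference data
# ---------------------------------------------------------------------------


def make_reference_masses(
    n: int = 200,
    a: float = MASS_COEF,
    b: float = MASS_EXP,
    log10_sd: float = MASS_LOG10_SD,
    femur_range_mm: tuple[float, float] = (30.0, 600.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic femur-length→body-mass reference table.

    Stands in for published extant non-mammalian tetrapod scaling data
    (which is not redistributed here): femur lengths log-uniform over the
    stated range, masses from the power law with multiplicative log-normal
    noise.  Columns: taxon, femur_length_mm, body_mass_kg.
    """
    if n < 3:
        raise ValueError("need n >= 3 reference points")
    rng = np.random.default_rng(seed)
    fl = 10 ** rng.uniform(np.log10(femur_range_mm[0]), np.log10(femur_range_mm[1]), n)
    mass = a * fl**b * 10 ** rng.normal(0.0, log10_sd, n)
    return pd.DataFrame(
        {
            "taxon": [f"reftaxon_{i + 1}" for i in range(n)],
            "femur_length_mm": fl,
            "body_mass_kg": mass,
        }
    )


# ---------------------------------------------------------------------------
# Character matrices on trees
# ---------------------------------------------------------------------------


def simulate_matrix(
    tree,
    n_chars: int,
    change_prob: float = 0.05,
    n_states: int = 2,
    seed: int = 0,
):
    """Evolve unordered characters root-to-tip on a tree.

    Along every edge each character switches, with probability
    ``change_prob``, to a uniformly chosen different state.  Returns the
    matrix together with the Fitch length of the generating tree (the
    minimum attainable on that topology), for search-recovery tests.

    Parameters
    ----------
    tree : parsimony.SimpleTree
        Generating topology (>= 4 tips).
    """
    from .parsimony import CharacterMatrix, SimpleTree, fitch_length

    if not isinstance(tree, SimpleTree):
        raise TypeError("tree must be a parsimony.SimpleTree")
    if len(tree.taxa) < 4:
        raise ValueError("generating tree needs >= 4 tips")
    if not 0 <= change_prob < 0.5:
        raise ValueError("change_prob must lie in [0, 0.5)")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    rng = np.random.default_rng(seed)

    # evolve on the rooted form of the tree (root state uniform)
    rooted = tree.rooted_edges()  # list of (parent, child); nodes ints, tips < n_taxa
    n_nodes = max(max(p, c) for p, c in rooted) + 1
    states = np.zeros((n_nodes, n_chars), dtype=np.int64)
    root = rooted[0][0]
    states[root] = rng.integers(n_states, size=n_chars)
    for parent, child in rooted:
        flip = rng.random(n_chars) < change_prob
        offset = rng.integers(1, n_states, size=n_chars)
        states[child] = np.where(
            flip, (states[parent] + offset) % n_states, states[parent]
        )
    symbols = "0123456789"[:n_states]
    rows = {
        taxon: "".join(symbols[s] for s in states[i])
        for i, taxon in enumerate(tree.taxa)
    }
    matrix = CharacterMatrix.from_strings(rows, symbols=symbols)
    true_length, _ = fitch_length(tree, matrix)
    return matrix, true_length
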