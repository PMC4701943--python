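"""Synthetic spine meshes and feature tables with analytic ground truth.

Fixture meshes are capped prisms (faceted cylinders): a single prism for a
stubby spine, two coaxial welded prisms (neck under head) for a mushroom
spine, and a narrow two-prism shape with a sub-threshold head for a
thin/filopodium spine.  Ground-truth volume, area and diameters use *exact
faceted-solid* formulas — regular-polygon area and perimeter — so oracle
comparisons are tolerance-free at any tessellation resolution; the familiar
smooth-cylinder formulas are only the n_seg → ∞ limit.

For a regular n-gon inscribed in a circle of diameter d:

    area      A(d, n) = (n/2)·(d/2)²·sin(2π/n)
    perimeter P(d, n) = n·d·sin(π/n)
    equivalent diameter = 2·sqrt(A/π)

Feature tables emulate a reconstructed pyramidal neuron: spines drawn as
mushroom / stubby / thin with dimensions sampled uniformly from observed
ranges (mushroom neck diameter 0.175–1 µm and length 0.38–4.37 µm, head
diameter and length 0.43–1.04 µm; stubby diameter 0.44–1.15 µm and length
0.32–1.66 µm), positioned along synthetic dendritic paths in three regions
(basal / apical-main / apical-collateral, proportions matching the measured
dendritic lengths 4263 / 540 / 3890 µm), with optional planted per-region
feature multipliers for recovery tests.  The membrane-potential-peak
feature is computed by the real compartmental model (vectorised batch run);
thin spines carry it as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import FeatureTable, SpineRecord, TriangleMesh
from .mesh_morphometry import DEFAULT_HEAD_THRESHOLD_UM, SpineMorphometry
from .spine_biophysics import (
    CableParams,
    SimulationConfig,
    SpineGeometryModel,
    SynapseParams,
    batch_membrane_potential_peaks,
)

__all__ = [
    "SpineFixture",
    "DatasetSpec",
    "polygon_area",
    "polygon_perimeter",
    "equivalent_diameter",
    "make_cylinder_mesh",
    "make_stubby_mesh",
    "make_mushroom_spine_mesh",
    "make_thin_spine_mesh",
    "generate_feature_dataset",
    "generate_structured_neuron",
    "sample_geometries",
    "MUSHROOM_RANGES",
    "STUBBY_RANGES",
    "REGION_PROPORTIONS",
]

#: Printed dimension ranges (µm) for the two modelled spine classes.
MUSHROOM_RANGES = {
    "neck_diameter": (0.175, 1.0),
    "neck_length": (0.38, 4.37),
    "head_diameter": (0.43, 1.04),
    "head_length": (0.43, 1.04),
}
STUBBY_RANGES = {"diameter": (0.44, 1.15), "length": (0.32, 1.66)}
#: Thin/filopodia: long narrow protrusion, tip below the head threshold.
THIN_RANGES = {
    "neck_diameter": (0.1, 0.3),
    "neck_length": (1.0, 4.0),
    "head_diameter": (0.2, 0.42),
    "head_length": (0.2, 0.42),
}

#: Region mix derived from reconstructed dendritic lengths 4263/540/3890 µm.
REGION_PROPORTIONS = {
    "basal": 4263 / 8693,
    "apical_main": 540 / 8693,
    "apical_collateral": 3890 / 8693,
}

CLASS_PROPORTIONS = {"mushroom": 0.55, "stubby": 0.25, "thin": 0.20}


# ---------------------------------------------------------------------------
# Faceted-solid closed forms
# ---------------------------------------------------------------------------

def polygon_area(d: float, n_seg: int) -> float:
    """Area of the regular n-gon inscribed in a circle of diameter ``d``."""
    return 0.5 * n_seg * (0.5 * d) ** 2 * math.sin(2.0 * math.pi / n_seg)


def polygon_perimeter(d: float, n_seg: int) -> float:
    return n_seg * d * math.sin(math.pi / n_seg)


def equivalent_diameter(d: float, n_seg: int) -> float:
    """Diameter of the circle with the same area as the inscribed n-gon."""
    return 2.0 * math.sqrt(polygon_area(d, n_seg) / math.pi)


@dataclass
class SpineFixture:
    """A generated mesh plus its exact morphometric truth."""

    mesh: TriangleMesh
    attachment: np.ndarray
    truth: SpineMorphometry
    geometry: SpineGeometryModel


# ---------------------------------------------------------------------------
# Mesh builders
# ---------------------------------------------------------------------------

def _ring(radius: float, z: float, n_seg: int) -> np.ndarray:
    theta = 2.0 * math.pi * np.arange(n_seg) / n_seg
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n_seg, z)]
    )


def _band(lower: np.ndarray, upper: np.ndarray, offset_l: int, offset_u: int):
    """Outward-facing triangle band between two same-size vertex rings."""
    n = len(lower)
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append((offset_l + i, offset_l + j, offset_u + j))
        faces.append((offset_l + i, offset_u + j, offset_u + i))
    return faces


def make_cylinder_mesh(
    d: float, L: float, n_seg: int = 64, name: str = "cylinder"
) -> SpineFixture:
    """Closed capped prism with exact faceted ground truth (stubby class).

    The attachment is the base-disk center at the origin; the solid extends
    along +z.
    """
    if d <= 0 or L <= 0:
        raise ValueError("dimensions must be positive")
    if n_seg < 8:
        raise ValueError("n_seg must be >= 8")

    r = 0.5 * d
    base_ring = _ring(r, 0.0, n_seg)
    top_ring = _ring(r, L, n_seg)
    vertices = np.vstack(
        [[[0.0, 0.0, 0.0]], base_ring, top_ring, [[0.0, 0.0, L]]]
    )
    bc, b0, t0, tc = 0, 1, 1 + n_seg, 1 + 2 * n_seg

    faces = []
    for i in range(n_seg):
        j = (i + 1) % n_seg
        faces.append((bc, b0 + j, b0 + i))       # base cap, outward −z
        faces.append((tc, t0 + i, t0 + j))       # top cap, outward +z
    faces += _band(base_ring, top_ring, b0, t0)  # lateral wall

    mesh = TriangleMesh(vertices, np.array(faces, dtype=np.int64), name=name)

    A = polygon_area(d, n_seg)
    P = polygon_perimeter(d, n_seg)
    truth = SpineMorphometry(
        volume=A * L,
        area=2.0 * A + P * L,
        length=L,
        max_diameter=equivalent_diameter(d, n_seg),
        neck_mean_diameter=None,
        spine_class="stubby",
    )
    geometry = SpineGeometryModel(kind="stubby", head_diameter=d, head_length=L)
    return SpineFixture(
        mesh=mesh, attachment=np.zeros(3), truth=truth, geometry=geometry
    )


def make_stubby_mesh(d: float, L: float, n_seg: int = 64) -> SpineFixture:
    """A stubby spine: single capped cylinder (alias of the prism builder)."""
    return make_cylinder_mesh(d, L, n_seg=n_seg, name="stubby")


def _two_prism_fixture(
    head_d: float,
    head_l: float,
    neck_d: float,
    neck_l: float,
    n_seg: int,
    spine_class: str,
    name: str,
) -> SpineFixture:
    if min(head_d, head_l, neck_d, neck_l) <= 0:
        raise ValueError("dimensions must be positive")
    if head_d <= neck_d:
        raise ValueError(
            f"head diameter ({head_d}) must exceed neck diameter ({neck_d})"
        )
    if n_seg < 8:
        raise ValueError("n_seg must be >= 8")

    rn, rh = 0.5 * neck_d, 0.5 * head_d
    z1, z2 = neck_l, neck_l + head_l
    neck_base = _ring(rn, 0.0, n_seg)
    neck_top = _ring(rn, z1, n_seg)
    head_base = _ring(rh, z1, n_seg)
    head_top = _ring(rh, z2, n_seg)
    vertices = np.vstack(
        [[[0.0, 0.0, 0.0]], neck_base, neck_top, head_base, head_top, [[0.0, 0.0, z2]]]
    )
    bc = 0
    nb, nt, hb, ht = 1, 1 + n_seg, 1 + 2 * n_seg, 1 + 3 * n_seg
    tc = 1 + 4 * n_seg

    faces = []
    for i in range(n_seg):
        j = (i + 1) % n_seg
        faces.append((bc, nb + j, nb + i))       # base cap, −z
        faces.append((tc, ht + i, ht + j))       # top cap, +z
        # annulus under the head overhang, facing −z
        faces.append((nt + i, nt + j, hb + j))
        faces.append((nt + i, hb + j, hb + i))
    faces += _band(neck_base, neck_top, nb, nt)
    faces += _band(head_base, head_top, hb, ht)

    mesh = TriangleMesh(vertices, np.array(faces, dtype=np.int64), name=name)

    An, Ah = polygon_area(neck_d, n_seg), polygon_area(head_d, n_seg)
    Pn, Ph = polygon_perimeter(neck_d, n_seg), polygon_perimeter(head_d, n_seg)
    # the truth label follows the classifier's head rule applied to the
    # faceted solid: a nominal head at the 0.43 µm boundary can facet below it
    if spine_class == "mushroom" and (
        equivalent_diameter(head_d, n_seg) < DEFAULT_HEAD_THRESHOLD_UM
    ):
        spine_class = "thin"
    truth = SpineMorphometry(
        volume=An * neck_l + Ah * head_l,
        area=An + Pn * neck_l + (Ah - An) + Ph * head_l + Ah,
        length=neck_l + head_l,
        max_diameter=equivalent_diameter(head_d, n_seg),
        neck_mean_diameter=equivalent_diameter(neck_d, n_seg),
        spine_class=spine_class,
    )
    geometry = SpineGeometryModel(
        kind="mushroom",
        head_diameter=head_d,
        head_length=head_l,
        neck_diameter=neck_d,
        neck_length=neck_l,
    )
    return SpineFixture(
        mesh=mesh, attachment=np.zeros(3), truth=truth, geometry=geometry
    )


def make_mushroom_spine_mesh(
    head_d: float, head_l: float, neck_d: float, neck_l: float, n_seg: int = 64
) -> SpineFixture:
    """Mushroom spine: head prism welded coaxially on top of a neck prism.

    Watertight by construction; attachment at the neck base center.
    """
    return _two_prism_fixture(
        head_d, head_l, neck_d, neck_l, n_seg, "mushroom", "mushroom"
    )


def make_thin_spine_mesh(
    head_d: float = 0.3,
    head_l: float = 0.3,
    neck_d: float = 0.12,
    neck_l: float = 2.0,
    n_seg: int = 64,
) -> SpineFixture:
    """Thin/filopodium spine: long narrow shaft, tip below the head threshold."""
    if head_d >= DEFAULT_HEAD_THRESHOLD_UM:
        raise ValueError(
            f"thin fixture tip diameter must stay below "
            f"{DEFAULT_HEAD_THRESHOLD_UM} µm, got {head_d}"
        )
    return _two_prism_fixture(head_d, head_l, neck_d, neck_l, n_seg, "thin", "thin")


def sample_geometries(n: int, seed: int) -> list[SpineGeometryModel]:
    """Draw ``n`` lumped-cylinder geometries uniformly from the observed
    mushroom/stubby ranges (alternating kinds), deterministic per seed."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if i % 2 == 0:
            hd = _uniform(rng, MUSHROOM_RANGES["head_diameter"])
            hl = _uniform(rng, MUSHROOM_RANGES["head_length"])
            lo, hi = MUSHROOM_RANGES["neck_diameter"]
            nd = _uniform(rng, (lo, min(hi, 0.95 * hd)))
            nl = _uniform(rng, MUSHROOM_RANGES["neck_length"])
            out.append(
                SpineGeometryModel(
                    kind="mushroom",
                    head_diameter=hd,
                    head_length=hl,
                    neck_diameter=nd,
                    neck_length=nl,
                )
            )
        else:
            out.append(
                SpineGeometryModel(
                    kind="stubby",
                    head_diameter=_uniform(rng, STUBBY_RANGES["diameter"]),
                    head_length=_uniform(rng, STUBBY_RANGES["length"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Feature-table generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """Conditions for a synthetic per-spine feature table.

    ``planted_effects`` maps region → {feature → multiplier}, applied after
    the base draw (for recovery experiments).  ``include_potential`` toggles
    the batch biophysics run that fills the PotentialPeak column.
    """

    n_spines: int = 1000
    seed: int = 0
    region_proportions: dict[str, float] = field(
        default_factory=lambda: dict(REGION_PROPORTIONS)
    )
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(CLASS_PROPORTIONS)
    )
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    include_potential: bool = True

    def __post_init__(self):
        for name, props in (
            ("region", self.region_proportions),
            ("class", self.class_proportions),
        ):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, not 1")


# straight dendritic paths (origin µm, unit direction) per region
_REGION_PATHS = {
    "basal": (np.array([0.0, 0.0, 0.0]), np.array([0.6, -0.8, 0.0]), 150.0),
    "apical_main": (np.array([0.0, 0.0, 5.0]), np.array([0.0, 0.0, 1.0]), 300.0),
    "apical_collateral": (
        np.array([0.0, 0.0, 80.0]),
        np.array([0.8, 0.0, 0.6]),
        120.0,
    ),
}


def _uniform(rng, lo_hi):
    return float(rng.uniform(lo_hi[0], lo_hi[1]))


def _smooth_two_cylinder_features(head_d, head_l, neck_d, neck_l):
    vol = math.pi / 4.0 * (neck_d**2 * neck_l + head_d**2 * head_l)
    area = (
        math.pi * (neck_d * neck_l + head_d * head_l)
        + math.pi / 4.0 * neck_d**2
        + math.pi / 4.0 * (head_d**2 - neck_d**2)
        + math.pi / 4.0 * head_d**2
    )
    return vol, area


def generate_feature_dataset(spec: DatasetSpec) -> FeatureTable:
    """Draw a full synthetic feature table, deterministic per seed.

    Spine classes and dimensions are sampled from the stated proportions and
    ranges; Volume/Area/Length/MaxDiameter/NeckMeanDiameter follow from the
    smooth cylinder formulas; PotentialPeak is computed by the compartmental
    model (missing for thin spines); positions sit on straight per-region
    dendritic paths; planted multipliers apply last.
    """
    rng = np.random.default_rng(spec.seed)
    regions = list(spec.region_proportions)
    region_p = np.array([spec.region_proportions[r] for r in regions])
    classes = list(spec.class_proportions)
    class_p = np.array([spec.class_proportions[c] for c in classes])

    records: list[SpineRecord] = []
    geoms: list[SpineGeometryModel | None] = []
    class_labels: dict[str, str] = {}
    width = len(str(max(spec.n_spines - 1, 1)))

    for i in range(spec.n_spines):
        region = regions[rng.choice(len(regions), p=region_p)]
        cls = classes[rng.choice(len(classes), p=class_p)]

        if cls == "mushroom":
            head_d = _uniform(rng, MUSHROOM_RANGES["head_diameter"])
            head_l = _uniform(rng, MUSHROOM_RANGES["head_length"])
            lo, hi = MUSHROOM_RANGES["neck_diameter"]
            neck_d = _uniform(rng, (lo, min(hi, 0.95 * head_d)))
            neck_l = _uniform(rng, MUSHROOM_RANGES["neck_length"])
            vol, area = _smooth_two_cylinder_features(head_d, head_l, neck_d, neck_l)
            feats = {
                "Volume": vol,
                "Area": area,
                "Length": neck_l + head_l,
                "MaxDiameter": head_d,
                "NeckMeanDiameter": neck_d,
            }
            geom = SpineGeometryModel(
                kind="mushroom",
                head_diameter=head_d,
                head_length=head_l,
                neck_diameter=neck_d,
                neck_length=neck_l,
            )
        elif cls == "stubby":
            d = _uniform(rng, STUBBY_RANGES["diameter"])
            L = _uniform(rng, STUBBY_RANGES["length"])
            feats = {
                "Volume": math.pi / 4.0 * d**2 * L,
                "Area": math.pi * d * L + math.pi / 2.0 * d**2,
                "Length": L,
                "MaxDiameter": d,
            }
            geom = SpineGeometryModel(kind="stubby", head_diameter=d, head_length=L)
        else:  # thin: not modelled electrically
            head_d = _uniform(rng, THIN_RANGES["head_diameter"])
            head_l = _uniform(rng, THIN_RANGES["head_length"])
            lo, hi = THIN_RANGES["neck_diameter"]
            neck_d = _uniform(rng, (lo, min(hi, 0.95 * head_d)))
            neck_l = _uniform(rng, THIN_RANGES["neck_length"])
            vol, area = _smooth_two_cylinder_features(head_d, head_l, neck_d, neck_l)
            feats = {
                "Volume": vol,
                "Area": area,
                "Length": neck_l + head_l,
                "MaxDiameter": head_d,
                "NeckMeanDiameter": neck_d,
            }
            geom = None

        for feat, mult in spec.planted_effects.get(region, {}).items():
            if feat in feats:
                feats[feat] *= mult

        base, direction, extent = _REGION_PATHS[region]
        t = rng.uniform(0.0, extent)
        jitter = rng.normal(0.0, 1.0, size=3)
        pos = base + t * direction + jitter
        sid = f"spine_{i:0{width}d}"
        records.append(
            SpineRecord(sid, tuple(np.round(pos, 6)), region, feats)
        )
        geoms.append(geom)
        class_labels[sid] = cls

    feature_names = ["Volume", "Area", "Length", "MaxDiameter", "NeckMeanDiameter"]
    if spec.include_potential:
        feature_names.append("PotentialPeak")
        peaks = batch_membrane_potential_peaks(
            geoms, CableParams(), SynapseParams(), SimulationConfig()
        )
        for rec, pk in zip(records, peaks):
            if pk is not None:
                rec.features["PotentialPeak"] = pk

    return FeatureTable(records, feature_names, spine_classes=class_labels)


def generate_structured_neuron(
    n: int = 1000, seed: int = 0, include_potential: bool = False
) -> tuple[FeatureTable, dict[str, str]]:
    """Preset with a planted regional effect: apical-main spines carry 2x
    volume and area, emulating a neuron whose largest spines sit on the main
    apical dendrite.  Returns the table and the ground-truth region labels.
    """
    if n < 100:
        raise ValueError("structured preset needs n >= 100")
    spec = DatasetSpec(
        n_spines=n,
        seed=seed,
        planted_effects={"apical_main": {"Volume": 2.0, "Area": 2.0}},
        include_potential=include_potential,
    )
    table = generate_feature_dataset(spec)
    labels = {r.id: r.region for r in table.records}
    return table, labels
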