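"""Compartmentalized ON / OFF cone bipolar cell geometries.

A cell is a tree of electrically lumped compartments (cylinders plus one
spherical soma) laid out along +z: dendrites at the bottom (facing the
stimulating electrode), then the soma, the axon, and the synaptic terminal
branches at the top.  The x/z skeleton is deterministic; the y ("depth")
coordinate of dendritic and terminal compartments is drawn from a confined
(truncated at two sigma) normal distribution, so a fixed seed reproduces the
geometry bitwise.

The two packaged fixtures emulate a type-9 ON cell (94 compartments) and a
type-3 OFF cell (78 compartments).  Their region extents and branch counts
are frozen package conventions chosen to reproduce the qualitative
polarization pattern of perpendicular bipolar cells in a subretinal field;
they are synthetic stand-ins, not traced reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .units import (
    CM_UF_PER_CM2,
    OHM_CM_TO_OHM_UM,
    RHO_AXIAL_OHM_CM,
    UM2_TO_CM2,
)

REGIONS = ("dendrite", "soma", "axon", "terminal")

# SWC type codes: 1 = soma, 2 = axon, 3 = dendrite, custom 5 = terminal
_SWC_TYPE = {"soma": 1, "axon": 2, "dendrite": 3, "terminal": 5}
_SWC_REGION = {v: k for k, v in _SWC_TYPE.items()}


class MorphologyError(ValueError):
    """Raised for inconsistent specs or malformed morphology files."""


@dataclass(frozen=True)
class RegionLayout:
    """Branch pattern of one region.

    ``n_branches`` chains of ``n_per_branch`` cylinders each, spanning
    ``z_extent`` um axially and fanning out to ``+-spread`` um laterally.
    """

    region: str
    z_extent: float
    n_branches: int
    n_per_branch: int
    diameter: float
    spread: float = 0.0

    @property
    def n_compartments(self) -> int:
        return self.n_branches * self.n_per_branch


@dataclass(frozen=True)
class MorphologySpec:
    cell_type: str                       # "ON_type9" | "OFF_type3"
    target_compartments: int
    soma_diameter: float                 # um
    region_layout: tuple[RegionLayout, ...]
    depth_sigma_fraction: float = 0.25
    seed: int = 1234

    def __post_init__(self):
        if self.target_compartments <= 0:
            raise MorphologyError("target_compartments must be positive")
        if self.soma_diameter <= 0:
            raise MorphologyError("soma_diameter must be positive")
        for lay in self.region_layout:
            if lay.region not in REGIONS:
                raise MorphologyError(f"unknown region {lay.region!r}")


@dataclass
class Compartment:
    id: int
    region: str
    shape: str                           # "cylinder" | "sphere"
    center: np.ndarray                   # (x, y, z) um
    length: float                        # um (== diameter for spheres)
    diameter: float                      # um
    surface_area: float                  # um^2
    volume: float                        # um^3
    half_axial_resistance: float         # kOhm
    membrane_capacitance: float          # uF
    parent: int | None
    neighbors: list[int] = field(default_factory=list)

    @property
    def s_over_v(self) -> float:
        """Surface-to-volume ratio in 1/um (drives Ca++ accumulation)."""
        return self.surface_area / self.volume


def compartment_electrics(
    shape: str, length: float, diameter: float, rho_a: float = RHO_AXIAL_OHM_CM
) -> tuple[float, float, float, float]:
    """Return (half_axial_resistance kOhm, capacitance uF, area um^2, volume um^3).

    Cylinders: R/2 = rho_a * (L/2) / cross-section, lateral surface only.
    The spherical soma uses the axial path of an equivalent cylinder of
    length = diameter (R/2 = rho_a * r / (pi r^2)); the membrane area is the
    full sphere.
    """
    if diameter <= 0:
        raise MorphologyError("diameter must be positive")
    r = diameter / 2.0
    rho_um = rho_a * OHM_CM_TO_OHM_UM  # Ohm um
    if shape == "cylinder":
        if length <= 0:
            raise MorphologyError("cylinder length must be positive")
        area = math.pi * diameter * length
        volume = math.pi * r * r * length
        r_half_ohm = rho_um * (length / 2.0) / (math.pi * r * r)
    elif shape == "sphere":
        area = 4.0 * math.pi * r * r
        volume = (4.0 / 3.0) * math.pi * r**3
        r_half_ohm = rho_um * r / (math.pi * r * r)
    else:
        raise MorphologyError(f"unknown shape {shape!r}")
    capacitance = CM_UF_PER_CM2 * area * UM2_TO_CM2
    return r_half_ohm / 1e3, capacitance, area, volume


def _make_compartment(cid, region, shape, center, length, diameter, parent):
    r_half, cap, area, vol = compartment_electrics(shape, length, diameter)
    return Compartment(
        id=cid, region=region, shape=shape,
        center=np.asarray(center, dtype=float),
        length=float(length), diameter=float(diameter),
        surface_area=area, volume=vol,
        half_axial_resistance=r_half, membrane_capacitance=cap,
        parent=parent,
    )


@dataclass
class CellMorphology:
    spec: MorphologySpec | None
    compartments: list[Compartment]

    def __post_init__(self):
        self._wire_neighbors()
        self.validate()

    # -- structure ---------------------------------------------------------
    def _wire_neighbors(self):
        for c in self.compartments:
            c.neighbors = []
        by_id = {c.id: c for c in self.compartments}
        for c in self.compartments:
            if c.parent is not None:
                by_id[c.parent].neighbors.append(c.id)
                c.neighbors.append(c.parent)

    def validate(self):
        somas = [c for c in self.compartments if c.region == "soma"]
        if len(somas) != 1:
            raise MorphologyError(f"expected exactly one soma, got {len(somas)}")
        g = self.graph()
        if g.number_of_nodes() > 0 and not nx.is_tree(g):
            raise MorphologyError("compartment graph is not a tree")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(c.id for c in self.compartments)
        g.add_edges_from(
            (c.id, c.parent) for c in self.compartments if c.parent is not None
        )
        return g

    # -- views -------------------------------------------------------------
    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def soma(self) -> Compartment:
        return next(c for c in self.compartments if c.region == "soma")

    def ids_in(self, region: str) -> list[int]:
        return [c.id for c in self.compartments if c.region == region]

    @property
    def synaptic_ids(self) -> list[int]:
        return self.ids_in("terminal")

    @property
    def dendritic_ids(self) -> list[int]:
        return self.ids_in("dendrite")

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.compartments])

    @property
    def total_area(self) -> float:
        return float(sum(c.surface_area for c in self.compartments))

    def z_extent(self) -> float:
        z = self.centers[:, 2]
        return float(z.max() - z.min())

    def copy(self) -> "CellMorphology":
        comps = [
            replace(c, center=c.center.copy(), neighbors=list(c.neighbors))
            for c in self.compartments
        ]
        return CellMorphology(self.spec, comps)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _confined_normal(rng: np.random.Generator, sigma: float) -> float:
    """Normal variate truncated (by rejection) at +-2 sigma."""
    if sigma <= 0:
        return 0.0
    while True:
        v = rng.normal(0.0, sigma)
        if abs(v) <= 2.0 * sigma:
            return v


def _branch_x_targets(n_branches: int, spread: float) -> list[float]:
    if n_branches == 1:
        return [0.0]
    return list(np.linspace(-spread, spread, n_branches))


def build_cell(spec: MorphologySpec) -> CellMorphology:
    """Build the compartment tree described by ``spec``.

    Deterministic for a fixed ``spec.seed``; raises ``MorphologyError`` if the
    layout cannot produce exactly ``spec.target_compartments`` compartments.
    """
    layout = {lay.region: lay for lay in spec.region_layout}
    for required in ("dendrite", "axon", "terminal"):
        if required not in layout:
            raise MorphologyError(f"region_layout lacks {required!r}")
    n_total = 1 + sum(
        lay.n_compartments for lay in spec.region_layout if lay.region != "soma"
    )
    if n_total != spec.target_compartments:
        raise MorphologyError(
            f"layout yields {n_total} compartments, spec asks for "
            f"{spec.target_compartments}"
        )

    rng = np.random.default_rng(spec.seed)
    comps: list[Compartment] = []
    cid = 0

    dend = layout["dendrite"]
    axon = layout["axon"]
    term = layout["terminal"]
    soma_r = spec.soma_diameter / 2.0
    soma_z = dend.z_extent + soma_r

    # dendrites: chains running from the soma down toward the electrode plane
    dendrite_root_ids = []
    for xb in _branch_x_targets(dend.n_branches, dend.spread):
        parent = None  # patched to soma id afterwards
        dz = dend.z_extent / dend.n_per_branch
        dx = xb / dend.n_per_branch
        sigma = spec.depth_sigma_fraction * max(abs(xb), dend.z_extent) / dend.n_per_branch
        prev_y = 0.0
        for k in range(dend.n_per_branch):
            y = prev_y + _confined_normal(rng, sigma)
            step = math.sqrt(dx * dx + dz * dz + (y - prev_y) ** 2)
            center = (
                dx * (k + 0.5),
                y,
                soma_z - soma_r - dz * (k + 0.5),
            )
            c = _make_compartment(cid, "dendrite", "cylinder", center,
                                  step, dend.diameter, parent)
            comps.append(c)
            if k == 0:
                dendrite_root_ids.append(cid)
            parent = cid
            prev_y = y
            cid += 1

    soma_id = cid
    comps.append(_make_compartment(soma_id, "soma", "sphere",
                                   (0.0, 0.0, soma_z),
                                   spec.soma_diameter, spec.soma_diameter, None))
    cid += 1
    for rid in dendrite_root_ids:
        comps[rid].parent = soma_id

    # axon: straight chain from the soma top along +z
    dz = axon.z_extent / axon.n_per_branch
    parent = soma_id
    for k in range(axon.n_per_branch):
        center = (0.0, 0.0, soma_z + soma_r + dz * (k + 0.5))
        comps.append(_make_compartment(cid, "axon", "cylinder", center,
                                       dz, axon.diameter, parent))
        parent = cid
        cid += 1
    axon_tip = parent

    # terminal branches from the axon tip
    z0 = soma_z + soma_r + axon.z_extent
    for xb in _branch_x_targets(term.n_branches, term.spread):
        parent = axon_tip
        dz = term.z_extent / term.n_per_branch
        dx = xb / term.n_per_branch
        sigma = spec.depth_sigma_fraction * max(abs(xb), term.z_extent) / term.n_per_branch
        prev_y = 0.0
        for k in range(term.n_per_branch):
            y = prev_y + _confined_normal(rng, sigma)
            step = math.sqrt(dx * dx + dz * dz + (y - prev_y) ** 2)
            center = (dx * (k + 0.5), y, z0 + dz * (k + 0.5))
            comps.append(_make_compartment(cid, "terminal", "cylinder", center,
                                           step, term.diameter, parent))
            parent = cid
            prev_y = y
            cid += 1

    cell = CellMorphology(spec, comps)
    assert cell.n_compartments == spec.target_compartments
    return cell


def scale_axon(cell: CellMorphology, factor: float) -> CellMorphology:
    """Rescale the z-coordinates of axonal and terminal compartments about the
    soma ("clinching" for factor < 1, elongation for factor > 1).

    Only compartment centers move; lengths, diameters and hence membrane
    areas, capacitances and the compartment count are unchanged.
    """
    if factor <= 0:
        raise MorphologyError("scale factor must be positive")
    out = cell.copy()
    z_soma = out.soma.center[2]
    for c in out.compartments:
        if c.region in ("axon", "terminal"):
            c.center[2] = z_soma + factor * (c.center[2] - z_soma)
    return out


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def on_type9_spec(seed: int = 1234) -> MorphologySpec:
    """Packaged ON (type 9) cell: 94 compartments, ~96 um tall, 11 um soma."""
    return MorphologySpec(
        cell_type="ON_type9",
        target_compartments=94,
        soma_diameter=11.0,
        region_layout=(
            RegionLayout("dendrite", z_extent=10.0, n_branches=4,
                         n_per_branch=6, diameter=1.2, spread=12.0),
            RegionLayout("axon", z_extent=60.0, n_branches=1,
                         n_per_branch=29, diameter=1.0),
            RegionLayout("terminal", z_extent=15.0, n_branches=4,
                         n_per_branch=10, diameter=1.0, spread=8.0),
        ),
        seed=seed,
    )


def off_type3_spec(seed: int = 4321) -> MorphologySpec:
    """Packaged OFF (type 3) cell: 78 compartments, ~51 um tall, 9 um soma."""
    return MorphologySpec(
        cell_type="OFF_type3",
        target_compartments=78,
        soma_diameter=9.0,
        region_layout=(
            RegionLayout("dendrite", z_extent=10.0, n_branches=5,
                         n_per_branch=5, diameter=1.2, spread=14.0),
            RegionLayout("axon", z_extent=22.0, n_branches=1,
                         n_per_branch=12, diameter=1.0),
            RegionLayout("terminal", z_extent=10.0, n_branches=4,
                         n_per_branch=10, diameter=1.2, spread=8.0),
        ),
        seed=seed,
    )


def build_on_cell(seed: int = 1234) -> CellMorphology:
    return build_cell(on_type9_spec(seed))


def build_off_cell(seed: int = 4321) -> CellMorphology:
    return build_cell(off_type3_spec(seed))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def write_swc(cell: CellMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# SWC export; types: 1 soma, 2 axon, 3 dendrite, 5 terminal\n")
        for c in cell.compartments:
            parent = -1 if c.parent is None else c.parent + 1
            x, y, z = c.center
            fh.write(
                f"{c.id + 1} {_SWC_TYPE[c.region]} {x:.6f} {y:.6f} {z:.6f} "
                f"{c.diameter / 2.0:.6f} {parent}\n"
            )


def read_swc(path) -> CellMorphology:
    """Read a 7-column SWC file into a compartment tree.

    Cylinder lengths are taken as the distance between a node and its parent
    node (the usual SWC segment convention); a type-1 root becomes the
    spherical soma.  Orphan references and cyclic parent links raise
    ``MorphologyError``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"malformed SWC line: {line!r}")
            rows.append(
                (int(parts[0]), int(parts[1]),
                 float(parts[2]), float(parts[3]), float(parts[4]),
                 float(parts[5]), int(parts[6]))
            )
    if not rows:
        raise MorphologyError("empty SWC file")
    index = {sid for sid, *_ in rows}
    comps = []
    id_map = {sid: i for i, (sid, *_rest) in enumerate(rows)}
    centers = {sid: np.array([x, y, z]) for sid, _t, x, y, z, _r, _p in rows}
    for sid, typ, x, y, z, radius, parent in rows:
        if parent != -1 and parent not in index:
            raise MorphologyError(f"orphan node {sid}: parent {parent} missing")
        region = _SWC_REGION.get(typ)
        if region is None:
            raise MorphologyError(f"unsupported SWC type {typ}")
        if parent == -1:
            if region != "soma":
                raise MorphologyError("root node must be the soma (type 1)")
            comps.append(_make_compartment(id_map[sid], "soma", "sphere",
                                           (x, y, z), 2 * radius, 2 * radius,
                                           None))
        else:
            length = float(np.linalg.norm(centers[sid] - centers[parent]))
            if length <= 0:
                raise MorphologyError(f"zero-length segment at node {sid}")
            comps.append(_make_compartment(id_map[sid], region, "cylinder",
                                           (x, y, z), length, 2 * radius,
                                           id_map[parent]))
    # cycle / connectivity check before CellMorphology's own validation
    g = nx.Graph()
    g.add_nodes_from(id_map.values())
    g.add_edges_from((c.id, c.parent) for c in comps if c.parent is not None)
    if g.number_of_edges() >= g.number_of_nodes():
        raise MorphologyError("SWC parent links contain a cycle")
    if not nx.is_connected(g):
        raise MorphologyError("SWC graph is disconnected")
    comps.sort(key=lambda c: c.id)
    return CellMorphology(None, comps)


# ---------------------------------------------------------------------------
# YAML spec files
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: MorphologySpec, path) -> None:
    import yaml

    doc = {
        "cell_type": spec.cell_type,
        "target_compartments": spec.target_compartments,
        "soma_diameter": spec.soma_diameter,
        "depth_sigma_fraction": spec.depth_sigma_fraction,
        "seed": spec.seed,
        "region_layout": [
            {"region": lay.region, "z_extent": lay.z_extent,
             "n_branches": lay.n_branches, "n_per_branch": lay.n_per_branch,
             "diameter": lay.diameter, "spread": lay.spread}
            for lay in spec.region_layout
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> MorphologySpec:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        layout = tuple(RegionLayout(**entry) for entry in doc["region_layout"])
        return MorphologySpec(
            cell_type=doc["cell_type"],
            target_compartments=doc["target_compartments"],
            soma_diameter=doc["soma_diameter"],
            region_layout=layout,
            depth_sigma_fraction=doc.get("depth_sigma_fraction", 0.25),
            seed=doc["seed"],
        )
    except (KeyError, TypeError) as exc:
        raise MorphologyError(f"invalid morphology spec file: {exc}") from exc
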