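"""Extracellular potential in the chip / retina / tamponade sandwich.

The quasi-static potential obeys div(sigma grad V) = 0.  It is discretized
on a structured grid with a 7-point finite-volume stencil; face conductances
use the conductivity of the z-slab each edge crosses (harmonic averaging is
implicit because slab boundaries coincide with grid planes, which the solver
enforces).  Boundary conditions:

* Dirichlet ``drive`` on the electrode nodes: a disk footprint on the
  chip/retina interface plane, extruded ``height`` um into the retina;
* Dirichlet 0 on the lateral (x/y) boundaries of the retinal layer (the
  distant return electrode);
* homogeneous Neumann (insulating) everywhere else — the natural boundary
  condition of the finite-volume stencil.

The linear system is symmetric positive definite and is solved with
Jacobi-preconditioned conjugate gradients.  Because the problem is linear in
the drive, experiments solve once for a unit drive and scale by the stimulus
waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "Layer",
    "VolumeModel",
    "ElectrodeSpec",
    "FieldSolution",
    "solve_potential",
    "sample_potential",
    "shift_cell",
    "FieldConvergenceError",
]


class FieldConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Layer:
    name: str
    thickness: float          # um
    resistivity: float        # Ohm cm

    def __post_init__(self):
        if self.thickness <= 0 or self.resistivity <= 0:
            raise ValueError("layer thickness and resistivity must be positive")


@dataclass(frozen=True)
class VolumeModel:
    """Layered volume, stacked along z with ``layers[0]`` at the bottom.

    ``grounded_layer`` names the layer whose outer lateral boundaries are the
    return electrode (potential 0).  ``insulating_threshold``: layers with
    resistivity above it can optionally be dropped from the computational
    domain and treated as perfect insulators (Neumann boundaries); by default
    all layers are kept as resistive media, as specified.
    """

    layers: tuple[Layer, ...] = (
        Layer("chip", 100.0, 1e6),
        Layer("retina", 300.0, 57.0),
        Layer("tamponade", 300.0, 1e6),
    )
    lateral_extent: float = 2000.0      # um, square cross-section
    grounded_layer: str = "retina"
    interface_layer: str = "retina"     # electrode sits at its lower face
    treat_high_rho_as_insulator: bool = False
    insulating_threshold: float = 1e5   # Ohm cm

    def active_layers(self) -> tuple[Layer, ...]:
        if not self.treat_high_rho_as_insulator:
            return self.layers
        kept = tuple(l for l in self.layers
                     if l.resistivity < self.insulating_threshold)
        if not kept:
            raise ValueError("no conductive layers left")
        return kept

    def z_of_interface(self) -> float:
        """z of the lower face of ``interface_layer`` with z=0 at the bottom
        of the *active* stack."""
        z = 0.0
        for l in self.active_layers():
            if l.name == self.interface_layer:
                return z
            z += l.thickness
        raise ValueError(f"layer {self.interface_layer!r} not in active stack")


def homogeneous_volume(resistivity: float = 57.0, thickness: float = 300.0,
                       lateral_extent: float = 2000.0) -> VolumeModel:
    """Single-layer volume, used for analytic-oracle verification."""
    return VolumeModel(
        layers=(Layer("medium", thickness, resistivity),),
        lateral_extent=lateral_extent,
        grounded_layer="medium",
        interface_layer="medium",
    )


@dataclass(frozen=True)
class ElectrodeSpec:
    diameter: float = 50.0     # um
    height: float = 10.0       # um, extrusion into the retina
    center: tuple[float, float] = (0.0, 0.0)
    shape: str = "disk"


@dataclass
class FieldSolution:
    """Potential on the grid, sampleable anywhere inside the volume."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray              # world z: 0 at the electrode interface plane
    potential: np.ndarray      # (nx, ny, nz), volts
    drive: float
    grid_spacing: float
    residual: float = 0.0
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)

    def sample(self, points) -> np.ndarray:
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                (self.x, self.y, self.z), self.potential,
                method="linear", bounds_error=True)
        return self._interp(np.atleast_2d(np.asarray(points, dtype=float)))

    def on_axis(self, zs) -> np.ndarray:
        pts = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
        return self.sample(pts)


def _disk_mask(x, y, electrode: ElectrodeSpec) -> np.ndarray:
    cx, cy = electrode.center
    xx, yy = np.meshgrid(x - cx, y - cy, indexing="ij")
    return xx**2 + yy**2 <= (electrode.diameter / 2.0) ** 2


def solve_potential(volume: VolumeModel, electrode: ElectrodeSpec,
                    drive: float, grid_spacing: float = 5.0,
                    tol: float = 1e-8, maxiter: int = 20000,
                    boundary_values=None) -> FieldSolution:
    """Solve div(sigma grad V) = 0 for a constant electrode ``drive`` (V).

    ``grid_spacing`` must divide every active layer thickness and the half
    lateral extent.  ``boundary_values``: optional callable ``f(x,y,z) -> V``
    imposing Dirichlet data on *all* outer boundaries instead of the standard
    grounded-retina condition (used for verification against closed forms).
    Raises ``FieldConvergenceError`` if CG does not reach ``tol``.
    """
    h = float(grid_spacing)
    half = volume.lateral_extent / 2.0
    layers = volume.active_layers()
    for l in layers:
        if abs(round(l.thickness / h) * h - l.thickness) > 1e-9:
            raise ValueError(f"grid spacing {h} does not divide layer "
                             f"{l.name} thickness {l.thickness}")
    if abs(round(half / h) * h - half) > 1e-9:
        raise ValueError("grid spacing must divide half the lateral extent")

    x = np.arange(-half, half + h / 2, h)
    y = x.copy()
    z_bottom = -volume.z_of_interface()   # world z of bottom of active stack
    total_th = sum(l.thickness for l in layers)
    z = z_bottom + np.arange(0.0, total_th + h / 2, h)
    nx_, ny_, nz_ = len(x), len(y), len(z)

    # conductivity per z-cell (S/um is irrelevant up to a constant; use 1/rho)
    cell_sigma = np.empty(nz_ - 1)
    zc = z_bottom
    for l in layers:
        n_cells = int(round(l.thickness / h))
        i0 = int(round((zc - z_bottom) / h))
        cell_sigma[i0:i0 + n_cells] = 1.0 / l.resistivity
        zc += l.thickness
    # node-level sigma for lateral edges: mean of adjoining slabs
    node_sigma = np.empty(nz_)
    node_sigma[0] = cell_sigma[0]
    node_sigma[-1] = cell_sigma[-1]
    node_sigma[1:-1] = 0.5 * (cell_sigma[:-1] + cell_sigma[1:])

    if drive == 0.0 and boundary_values is None:
        # homogeneous problem: identically zero without solving
        v = np.zeros((nx_, ny_, nz_))
        return FieldSolution(x, y, z, v, drive, h, residual=0.0)

    shape = (nx_, ny_, nz_)
    n = nx_ * ny_ * nz_

    def idx(i, j, k):
        return (i * ny_ + j) * nz_ + k

    # Dirichlet masks
    dir_mask = np.zeros(shape, dtype=bool)
    dir_val = np.zeros(shape)

    # electrode: disk footprint on the interface plane, extruded `height` up
    k_if = int(round((0.0 - z_bottom) / h))
    n_up = int(round(electrode.height / h))
    disk = _disk_mask(x, y, electrode)
    for k in range(k_if, min(k_if + n_up + 1, nz_)):
        dir_mask[:, :, k] |= disk
        dir_val[:, :, k][disk] = drive

    if boundary_values is not None:
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        vals = boundary_values(xx, yy, zz)
        for sl in (np.s_[0, :, :], np.s_[-1, :, :], np.s_[:, 0, :],
                   np.s_[:, -1, :], np.s_[:, :, 0], np.s_[:, :, -1]):
            m = ~dir_mask[sl]
            dir_mask[sl] |= m
            dir_val[sl][m] = vals[sl][m]
    else:
        # grounded lateral boundaries of the grounded layer
        zg0 = 0.0
        for l in layers:
            if l.name == volume.grounded_layer:
                break
            zg0 += l.thickness
        k0 = int(round(zg0 / h))
        k1 = k0 + int(round(
            next(l for l in layers
                 if l.name == volume.grounded_layer).thickness / h))
        for sl in (np.s_[0, :, k0:k1 + 1], np.s_[-1, :, k0:k1 + 1],
                   np.s_[:, 0, k0:k1 + 1], np.s_[:, -1, k0:k1 + 1]):
            dir_mask[sl] = True
            dir_val[sl] = 0.0

    # assemble the 7-point stencil over free nodes
    free = ~dir_mask
    free_flat = free.ravel()
    n_free = int(free_flat.sum())
    perm = -np.ones(n, dtype=np.int64)
    perm[free_flat] = np.arange(n_free)

    rows, cols, data = [], [], []
    rhs = np.zeros(n_free)
    diag = np.zeros(n_free)

    def add_edges(axis, sigma_per_edge):
        nonlocal rows, cols, data, rhs, diag
        # edges between node (…, m, …) and (…, m+1, …) along `axis`
        idx_all = np.arange(n).reshape(shape)
        if axis == 0:
            a_nodes = idx_all[:-1, :, :].ravel()
            b_nodes = idx_all[1:, :, :].ravel()
            w = np.broadcast_to(sigma_per_edge, (nx_ - 1, ny_, nz_)).ravel()
        elif axis == 1:
            a_nodes = idx_all[:, :-1, :].ravel()
            b_nodes = idx_all[:, 1:, :].ravel()
            w = np.broadcast_to(sigma_per_edge, (nx_, ny_ - 1, nz_)).ravel()
        else:
            a_nodes = idx_all[:, :, :-1].ravel()
            b_nodes = idx_all[:, :, 1:].ravel()
            w = np.broadcast_to(sigma_per_edge, (nx_, ny_, nz_ - 1)).ravel()

        fa = free_flat[a_nodes]
        fb = free_flat[b_nodes]
        va = dir_val.ravel()[a_nodes]
        vb = dir_val.ravel()[b_nodes]
        pa = perm[a_nodes]
        pb = perm[b_nodes]

        both = fa & fb
        rows.append(pa[both]); cols.append(pb[both]); data.append(-w[both])
        rows.append(pb[both]); cols.append(pa[both]); data.append(-w[both])
        np.add.at(diag, pa[fa], w[fa])
        np.add.at(diag, pb[fb], w[fb])
        a_only = fa & ~fb
        np.add.at(rhs, pa[a_only], w[a_only] * vb[a_only])
        b_only = fb & ~fa
        np.add.at(rhs, pb[b_only], w[b_only] * va[b_only])

    sig_lat = node_sigma[np.newaxis, np.newaxis, :]     # x and y edges
    sig_z = cell_sigma[np.newaxis, np.newaxis, :]       # z edges
    add_edges(0, sig_lat)
    add_edges(1, sig_lat)
    add_edges(2, sig_z)

    a_mat = sp.csr_matrix(
        (np.concatenate(data),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_free, n_free))
    a_mat = a_mat + sp.diags(diag)

    precond = sp.diags(1.0 / diag)
    sol, info = spla.cg(a_mat, rhs, rtol=tol, atol=0.0, maxiter=maxiter,
                        M=precond)
    if info != 0:
        raise FieldConvergenceError(
            f"CG did not converge within {maxiter} iterations (info={info})")
    resid = np.linalg.norm(a_mat @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)

    v = dir_val.copy().ravel()
    v[free_flat] = sol
    return FieldSolution(x, y, z, v.reshape(shape), drive, h,
                         residual=float(resid))


def sample_potential(solution: FieldSolution, points) -> np.ndarray:
    """Trilinear interpolation of the potential at ``points`` (um)."""
    return solution.sample(points)


def shift_cell(solution: FieldSolution, placed_centers: np.ndarray,
               dx: float = 0.0, dz: float = 0.0, dy: float = 0.0) -> np.ndarray:
    """Potential per compartment for a cell translated by (dx, dy, dz).

    The field stays fixed; moving the cell is equivalent to sampling at the
    translated compartment centers.
    """
    pts = np.asarray(placed_centers, dtype=float) + np.array([dx, dy, dz])
    return solution.sample(pts)


def disk_half_space_potential(z, radius: float, drive: float) -> np.ndarray:
    """Closed-form on-axis potential of an equipotential disk of ``radius``
    held at ``drive`` on the boundary of a homogeneous half-space:
    V(z) = (2 V0 / pi) arctan(a / z)."""
    z = np.asarray(z, dtype=float)
    return 2.0 * drive / np.pi * np.arctan2(radius, z)


def disk_half_space_potential_3d(x, y, z, radius: float,
                                 drive: float) -> np.ndarray:
    """Off-axis closed form for the same disk (oblate-spheroidal solution):
    V = (2 V0/pi) arcsin(2a / (sqrt((r-a)^2+z^2) + sqrt((r+a)^2+z^2)))."""
    r = np.sqrt(np.asarray(x, float) ** 2 + np.asarray(y, float) ** 2)
    z = np.abs(np.asarray(z, float))
    a = radius
    s1 = np.sqrt((r - a) ** 2 + z**2)
    s2 = np.sqrt((r + a) ** 2 + z**2)
    arg = np.clip(2.0 * a / (s1 + s2), -1.0, 1.0)
    return 2.0 * drive / np.pi * np.arcsin(arg)
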