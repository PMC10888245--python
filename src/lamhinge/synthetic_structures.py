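"""Synthetic atomistic calibration standards.

These builders produce ideal-geometry PDB-style structures used as
calibration inputs and test fixtures: a canonical poly-Ala α-helix, an ideal
trimeric coiled-coil (Crick-style parameterization with the canonical axial
translation of ~1.49 Å per residue), and a laminin-E8-like assembly — a
trimeric coiled-coil whose C-terminal ~9 nm are overlain by a cluster of
three ~3.5 nm pseudo-sphere "LG" domains, mimicking how the LG1-3 cluster
covers the coiled-coil terminus in crystal structures of laminin fragments.

Everything here is synthetic: geometry comes from canonical helix/coiled-coil
parameters and published LG-domain dimensions, not from any deposited
structure.  All coordinates are in Å, with the support plane at z = 0 and the
long axis along x (the "laid flat on mica" orientation used for rendering
and obscuration profiles).
"""

from __future__ import annotations

import math

import numpy as np

from lamhinge.core_io import AtomisticStructure, ResidueRange

__all__ = [
    "ideal_helix",
    "ideal_coiled_coil",
    "synthetic_e8_like",
    "E8_CC_RANGES",
    "E8_LG_CHAIN",
]

#: Canonical α-helix geometry (Å, degrees per residue).
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST = 100.0

#: Canonical coiled-coil axial translation per residue (Å) and supercoil
#: geometry for a trimer.
CC_RISE = 1.49
CC_SUPERCOIL_RADIUS = 6.8
CC_SUPERCOIL_PITCH = 140.0  # left-handed

#: LG pseudo-domain outer radius (Å): each LG domain is ~3.5 nm across.
LG_DOMAIN_RADIUS = 17.5

E8_CC_RANGES = [
    ResidueRange("A", 1, 72),
    ResidueRange("B", 1, 72),
    ResidueRange("C", 1, 72),
]
E8_LG_CHAIN = "L"


def _structure_from_atoms(chain_ids, res_numbers, res_names, atom_names,
                          elements, coords, radii=None) -> AtomisticStructure:
    from lamhinge.core_io import vdw_radius

    coords = np.asarray(coords, dtype=float)
    if radii is None:
        radii = np.array([vdw_radius(e) for e in elements])
    return AtomisticStructure(
        np.asarray(chain_ids), np.asarray(res_numbers, dtype=int),
        np.asarray(res_names), np.asarray(atom_names), np.asarray(elements),
        coords, np.asarray(radii, dtype=float),
    )


def ideal_helix(n_res: int = 60, chain_id: str = "A",
                lying_down: bool = True) -> AtomisticStructure:
    """Poly-Ala Cα trace of a canonical α-helix.

    With ``lying_down`` the helix axis runs along x at a height that rests
    the molecule on z = 0; otherwise the axis is z.
    """
    t = np.arange(n_res)
    phase = np.radians(HELIX_TWIST) * t
    axis = HELIX_RISE * t
    u = HELIX_RADIUS * np.cos(phase)
    v = HELIX_RADIUS * np.sin(phase)
    if lying_down:
        coords = np.column_stack([axis, u, v])
        coords[:, 2] -= coords[:, 2].min() - 1.7  # rest vdW spheres on z=0
    else:
        coords = np.column_stack([u, v, axis])
    n = n_res
    return _structure_from_atoms(
        [chain_id] * n, t + 1, ["ALA"] * n, ["CA"] * n, ["C"] * n, coords
    )


def ideal_coiled_coil(
    n_res: int = 72,
    n_chains: int = 3,
    rise: float = CC_RISE,
    supercoil_radius: float = CC_SUPERCOIL_RADIUS,
    supercoil_pitch: float = CC_SUPERCOIL_PITCH,
    chain_ids: tuple[str, ...] = ("A", "B", "C"),
    axis: str = "x",
    minor_radius: float = HELIX_RADIUS,
) -> AtomisticStructure:
    """Ideal n-stranded coiled-coil Cα trace (Crick-style parameterization).

    Each chain's helix centre line winds left-handed around the supercoil
    axis with the given pitch; Cα atoms spiral around the centre line with
    canonical α-helix minor radius and twist.  The axial translation per
    residue is ``rise`` by construction, so the structure serves as a
    rise-per-residue calibration standard of known ground truth.
    """
    t = np.arange(n_res, dtype=float)
    z = rise * t
    big_omega = -2.0 * math.pi * rise / supercoil_pitch  # rad per residue
    minor_omega = np.radians(HELIX_TWIST) - big_omega  # relative to frame

    chains, resnum, coords = [], [], []
    for k in range(n_chains):
        phi = 2.0 * math.pi * k / n_chains
        big_phase = big_omega * t + phi
        cx = supercoil_radius * np.cos(big_phase)
        cy = supercoil_radius * np.sin(big_phase)
        # local frame: radial and tangential-normal directions
        radial = np.column_stack([np.cos(big_phase), np.sin(big_phase)])
        tangent_n = np.column_stack([-np.sin(big_phase), np.cos(big_phase)])
        minor_phase = minor_omega * t
        off = (minor_radius * np.cos(minor_phase)[:, None] * radial
               + minor_radius * np.sin(minor_phase)[:, None] * tangent_n)
        xyz = np.column_stack([cx + off[:, 0], cy + off[:, 1], z])
        coords.append(xyz)
        chains.extend([chain_ids[k]] * n_res)
        resnum.extend((t + 1).astype(int))
    coords = np.vstack(coords)
    if axis == "x":
        # z -> x, keep right-handed: (x,y,z) -> (z, y, -x)
        coords = np.column_stack([coords[:, 2], coords[:, 1], -coords[:, 0]])
        coords[:, 2] -= coords[:, 2].min() - 1.7
    n = len(coords)
    return _structure_from_atoms(
        chains, resnum, ["ALA"] * n, ["CA"] * n, ["C"] * n, coords
    )


def _sphere_shell(center: np.ndarray, radius: float, n_points: int = 80) -> np.ndarray:
    """Fibonacci-sphere point shell (Å)."""
    i = np.arange(n_points, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    zf = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(1.0 - zf**2)
    theta = golden * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), zf]) * radius
    return pts + np.asarray(center)


def synthetic_e8_like(
    n_res: int = 72,
    lg_span: float = 90.0,
    lg_offset_y: float = 26.0,
    atom_vdw: float = 1.7,
) -> AtomisticStructure:
    """Synthetic laminin-E8-like assembly: trimeric coiled-coil plus an LG
    pseudo-domain cluster overlying the C-terminal ~``lg_span`` Å of the rod.

    The coiled-coil (chains A/B/C, residues 1..n_res, C-terminus at the
    +x end) lies along x on the z = 0 support.  Three pseudo-sphere LG
    domains (chain ``L``, ~3.5 nm across, built from shells of pseudo-atoms)
    rest on the support beside the rod, their footprint spanning the axial
    interval from the coiled-coil C-terminus back ``lg_span`` Å toward the
    N-terminus — the "C-terminus extends to the basal side of the LG
    cluster" geometry that makes the terminus invisible in a topograph.
    """
    cc = ideal_coiled_coil(n_res=n_res, axis="x")
    x_cterm = cc.coords[cc.res_numbers == n_res][:, 0].mean()

    shell_r = LG_DOMAIN_RADIUS - atom_vdw
    centers_x = [x_cterm - lg_span + LG_DOMAIN_RADIUS,
                 x_cterm - lg_span / 2.0,
                 x_cterm - LG_DOMAIN_RADIUS]
    lg_pts = np.vstack([
        _sphere_shell([cx, lg_offset_y, LG_DOMAIN_RADIUS], shell_r)
        for cx in centers_x
    ])
    n_lg = len(lg_pts)
    lg = _structure_from_atoms(
        [E8_LG_CHAIN] * n_lg,
        np.repeat([1, 2, 3], n_lg // 3),
        ["LGD"] * n_lg, ["PS"] * n_lg, ["C"] * n_lg, lg_pts,
        radii=np.full(n_lg, atom_vdw),
    )
    return _structure_from_atoms(
        np.concatenate([cc.chain_ids, lg.chain_ids]),
        np.concatenate([cc.res_numbers, lg.res_numbers]),
        np.concatenate([cc.res_names, lg.res_names]),
        np.concatenate([cc.atom_names, lg.atom_names]),
        np.concatenate([cc.elements, lg.elements]),
        np.vstack([cc.coords, lg.coords]),
        radii=np.concatenate([cc.vdw_radii, lg.vdw_radii]),
    )
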