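"""From an image-space hinge position to a sequence position.

The kink-to-LG distance measured in a topograph underestimates the hinge's
true distance from the coiled-coil C-terminus for two reasons: the terminus
physically extends to the basal side of the LG globule cluster (so a stretch
of rod is overlain by the cluster), and tip-sample convolution widens the
apparent LG footprint further.  :func:`obscured_length` quantifies both
effects from a 1-D axial height profile of the LG cluster;
:func:`rise_per_residue` calibrates nm-per-residue from a coiled-coil
structure; the remaining arithmetic converts the corrected distance into a
residue offset and per-chain residue identities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from lamhinge.core_io import (
    ANGSTROM_PER_NM,
    AtomisticStructure,
    ResidueRange,
    TipModel,
)
from lamhinge.afm_simulate import tip_apex_profile, tip_reach

logger = logging.getLogger("lamhinge")

__all__ = [
    "ObscurationModel",
    "ObscurationResult",
    "RiseCalibration",
    "HingeLocation",
    "obscured_length",
    "lg_profile_from_structure",
    "rise_per_residue",
    "corrected_hinge_distance",
    "residue_offset",
    "map_to_chain",
]


@dataclass
class ObscurationModel:
    """Inputs for the LG-obscuration estimate.

    ``lg_s``/``lg_heights`` give the 1-D height profile of the LG cluster
    along the coiled-coil axis (nm), sampled at ≤ 0.1 nm.  The axial origin
    ``s = 0`` is the **true coiled-coil C-terminus**, with ``s`` increasing
    toward the hinge (along the rod); the cluster typically spans negative
    and small positive ``s``.  ``rod_height`` is the apparent height of the
    bare coiled-coil (nm).
    """

    tip: TipModel = field(default_factory=lambda: TipModel(2.0, 5.0))
    lg_s: np.ndarray = field(default_factory=lambda: np.array([]))
    lg_heights: np.ndarray = field(default_factory=lambda: np.array([]))
    rod_height: float = 2.2

    def __post_init__(self) -> None:
        self.lg_s = np.asarray(self.lg_s, dtype=float)
        self.lg_heights = np.asarray(self.lg_heights, dtype=float)
        if self.lg_s.shape != self.lg_heights.shape or self.lg_s.ndim != 1:
            raise ValueError("lg_s and lg_heights must be matching 1-D arrays")
        if len(self.lg_s) >= 2:
            ds = np.diff(self.lg_s)
            if np.any(ds <= 0):
                raise ValueError("lg_s must be strictly increasing")
            if ds.max() > 0.1 + 1e-12:
                raise ValueError("profile must be sampled at <= 0.1 nm")
        if not (self.rod_height > 0):
            raise ValueError("rod_height must be positive")

    @classmethod
    def from_cap(
        cls,
        footprint_radius: float = 4.5,
        cap_height: float = 4.0,
        cterm_offset: float | None = None,
        tip: TipModel | None = None,
        rod_height: float = 2.2,
        ds: float = 0.02,
    ) -> "ObscurationModel":
        """Parametric spherical-cap LG profile.

        The cap has base radius ``footprint_radius`` and apex height
        ``cap_height`` (nm).  ``cterm_offset`` places the cap centre at that
        axial distance beyond the terminus; the default puts the terminus at
        the distal footprint edge (the rod spans the whole footprint
        underneath, the geometry seen in laminin fragment structures).
        """
        a, h = footprint_radius, cap_height
        if cterm_offset is None:
            cterm_offset = a
        rc = (a * a + h * h) / (2.0 * h)  # sphere radius of the cap
        s = np.arange(cterm_offset - a, cterm_offset + a + ds, ds)
        d = s - cterm_offset
        prof = np.sqrt(np.clip(rc * rc - d * d, 0.0, None)) - (rc - h)
        prof = np.clip(prof, 0.0, None)
        return cls(
            tip=tip if tip is not None else TipModel(2.0, 5.0),
            lg_s=s, lg_heights=prof, rod_height=rod_height,
        )

    @classmethod
    def from_structure(
        cls,
        structure: AtomisticStructure,
        cc_ranges: list[ResidueRange],
        lg_chains: list[str],
        tip: TipModel | None = None,
        rod_height: float = 2.2,
        ds: float = 0.02,
    ) -> "ObscurationModel":
        s, h = lg_profile_from_structure(structure, cc_ranges, lg_chains, ds=ds)
        return cls(
            tip=tip if tip is not None else TipModel(2.0, 5.0),
            lg_s=s, lg_heights=h, rod_height=rod_height,
        )


@dataclass(frozen=True)
class ObscurationResult:
    """Length of coiled-coil invisible as a distinct feature (nm).

    ``obscured`` = axial distance from the true C-terminus to the point where
    the tip-dilated LG image falls below the rod height — the sum of the rod
    length physically overlain by the cluster (``overhang``) and the
    convolution ``broadening`` of the apparent LG edge beyond its physical
    edge.
    """

    obscured: float
    overhang: float
    broadening: float


def obscured_length(model: ObscurationModel) -> ObscurationResult:
    """Tip-obscuration correction for the LG-covered coiled-coil terminus.

    The LG profile is gray-scale dilated with the tip apex profile (1-D);
    the apparent LG edge is the last axial position where the dilated image
    is at least ``rod_height``.  If the true LG profile never exceeds the
    rod height, nothing is obscured (returned 0 with a warning).
    """
    s, h = model.lg_s, model.lg_heights
    if len(s) < 2:
        raise ValueError("LG profile needs at least 2 samples")
    above = h >= model.rod_height
    if not above.any():
        logger.warning("LG profile never exceeds rod height: nothing obscured")
        return ObscurationResult(0.0, 0.0, 0.0)
    s_phys = float(s[above].max())

    ds = float(np.min(np.diff(s)))
    reach = tip_reach(model.tip, float(h.max()))
    pad = int(math.ceil(reach / ds)) + 2
    s_ext = np.concatenate([
        s[0] + ds * np.arange(-pad, 0), s, s[-1] + ds * np.arange(1, pad + 1)
    ])
    # 1-D gray-scale dilation: out(x) = max_u [h(u) - f(|x - u|)]
    dist = np.abs(s_ext[:, None] - s[None, :])
    dilated = np.max(h[None, :] - tip_apex_profile(model.tip, dist), axis=1)
    app = dilated >= model.rod_height
    s_app = float(s_ext[app].max()) if app.any() else s_phys

    obscured = max(s_app, 0.0)
    overhang = max(s_phys, 0.0)
    return ObscurationResult(obscured, overhang, obscured - overhang)


def lg_profile_from_structure(
    structure: AtomisticStructure,
    cc_ranges: list[ResidueRange],
    lg_chains: list[str],
    ds: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial max-height profile of the LG cluster (nm), origin at the
    coiled-coil C-terminus.

    The structure is assumed laid flat in support orientation (z up, resting
    on z = 0 after normalisation).  The coiled-coil axis is the first
    principal component of the Cα atoms in ``cc_ranges``, oriented from the
    C-terminus toward the N-terminus, so ``s`` increases along the rod.  The
    profile is the upper envelope of the LG atoms' vdW spheres projected
    onto that axis.
    """
    ca = structure.ca_mask()
    cc_mask = np.zeros(len(structure), dtype=bool)
    for rr in cc_ranges:
        cc_mask |= structure.range_mask(rr)
    cc_ca = structure.select(cc_mask & ca)
    if len(cc_ca) < 3:
        raise ValueError("coiled-coil ranges resolve to fewer than 3 CA atoms")

    coords = structure.coords.copy()
    coords[:, 2] -= (coords[:, 2] - structure.vdw_radii).min()

    cc_xyz = cc_ca.coords - cc_ca.coords.mean(axis=0)
    _, _, vt = np.linalg.svd(cc_xyz, full_matrices=False)
    axis = vt[0]
    # C-terminal CA of each coiled-coil chain defines the axial origin
    cterm_pts = []
    for rr in cc_ranges:
        m = structure.range_mask(rr) & ca
        if m.any():
            sub = structure.select(m)
            cterm_pts.append(sub.coords[np.argmax(sub.res_numbers)])
    cterm = np.mean(cterm_pts, axis=0)
    proj_all = coords @ axis
    s0 = cterm @ axis
    sign = 1.0 if (cc_ca.coords @ axis).mean() >= s0 else -1.0

    lg_mask = np.isin(structure.chain_ids.astype(str), lg_chains)
    if not lg_mask.any():
        raise ValueError(f"no atoms on LG chains {lg_chains}")
    s_atom = sign * (proj_all[lg_mask] - s0) / ANGSTROM_PER_NM
    z_top = coords[lg_mask, 2] / ANGSTROM_PER_NM
    r = structure.vdw_radii[lg_mask] / ANGSTROM_PER_NM

    s_grid = np.arange(
        (s_atom - r).min(), (s_atom + r).max() + ds, min(ds, 0.1)
    )
    d = np.abs(s_grid[:, None] - s_atom[None, :])
    caps = z_top[None, :] + np.sqrt(np.clip(r[None, :] ** 2 - d**2, 0.0, None))
    caps[d > r[None, :]] = 0.0
    return s_grid, caps.max(axis=1)


@dataclass(frozen=True)
class RiseCalibration:
    """nm of axial translation per amino acid of one chain, with provenance."""

    rise: float
    source: str
    ranges: tuple[ResidueRange, ...]
    axial_extent_nm: float
    residues_spanned: float

    def __post_init__(self) -> None:
        if not (0.05 <= self.rise <= 0.4):
            raise ValueError(
                f"rise {self.rise:.3f} nm/AA outside sanity bounds for "
                "helical assemblies (0.05-0.4)"
            )


def rise_per_residue(
    structure: AtomisticStructure,
    ranges: list[ResidueRange],
    source: str = "",
) -> RiseCalibration:
    """Axial rise per residue of a coiled-coil from its Cα coordinates.

    The bundle axis is the first principal component of all selected Cα
    atoms; the axial extent is the peak-to-peak projection onto it; the
    residue count is the mean range length over chains; rise =
    extent / (residues − 1), in nm/AA.  Rigid motions of the structure leave
    the result unchanged.
    """
    ca = structure.ca_mask()
    sel_pts = []
    for rr in ranges:
        m = structure.range_mask(rr) & ca
        sub = structure.select(m) if m.any() else None
        present = set() if sub is None else set(sub.res_numbers.tolist())
        missing = [i for i in range(rr.first, rr.last + 1) if i not in present]
        if missing:
            raise ValueError(
                f"range {rr}: missing residues (no CA) "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
        if len(sub) < 10:
            raise ValueError(f"range {rr} resolves to {len(sub)} CA atoms (<10)")
        sel_pts.append(sub.coords)
    pts = np.vstack(sel_pts)
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    proj = centred @ axis
    extent_nm = (proj.max() - proj.min()) / ANGSTROM_PER_NM
    spanned = float(np.mean([len(rr) for rr in ranges]))
    rise = extent_nm / (spanned - 1.0)
    return RiseCalibration(
        rise=rise, source=source, ranges=tuple(ranges),
        axial_extent_nm=extent_nm, residues_spanned=spanned,
    )


def corrected_hinge_distance(measured_kink_to_lg: float, obscured: float) -> float:
    """True hinge distance from the coiled-coil C-terminus (nm): the measured
    kink-to-LG-edge distance plus the obscured length."""
    if measured_kink_to_lg < 0 or obscured < 0:
        raise ValueError("distances must be non-negative")
    return measured_kink_to_lg + obscured


def residue_offset(corrected: float, cal: RiseCalibration) -> int:
    """Residue count from the C-terminus: ``round(corrected / rise)``."""
    if not (cal.rise > 0):
        raise ValueError("rise must be positive")
    return int(round(corrected / cal.rise))


@dataclass(frozen=True)
class HingeLocation:
    """Hinge position expressed in sequence coordinates."""

    corrected_nm: float
    offset_aa: int
    residues: dict[str, int]  # chain -> hinge residue number
    windows: dict[str, tuple[int, int]]  # chain -> inclusive hinge region
    cterm_inferred: bool = False


def map_to_chain(
    offset: int,
    cterm: dict[str, int],
    corrected_nm: float = float("nan"),
    half_window: int = 3,
    chain_lengths: dict[str, int] | None = None,
    cterm_inferred: bool = False,
) -> HingeLocation:
    """Per-chain hinge residues: ``cterm − offset`` with a ±``half_window``
    region, in the numbering of the supplied C-terminal residue numbers."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    residues, windows = {}, {}
    for chain, ct in cterm.items():
        res = ct - offset
        limit = chain_lengths.get(chain) if chain_lengths else None
        if res < 1 or (limit is not None and offset > limit):
            raise ValueError(
                f"offset {offset} exceeds chain {chain} length (cterm {ct})"
            )
        residues[chain] = res
        windows[chain] = (res - half_window, res + half_window)
    return HingeLocation(
        corrected_nm=corrected_nm, offset_aa=offset,
        residues=residues, windows=windows, cterm_inferred=cterm_inferred,
    )
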