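"""Pseudo-AFM rendering of atomistic structures and tip-convolution geometry.

Contact-mode AFM image formation with a rigid tip is a gray-scale dilation:
the apparent surface is the locus of the tip apex as the rigid tip touches
the rigid sample,

    out(x, y) = max over (u, v) of [ true(u, v) − f(dist((x,y),(u,v))) ],

where ``f(d)`` is the tip apex profile — the height of the tip surface above
its apex at lateral distance ``d``.  The tip is a sphere of radius ``Rs``
capped tangentially onto a cone of half-angle ``α`` (measured from the tip
axis): sphere for ``d ≤ Rs·cos α``, tangent cone continuation beyond, with
continuous value and slope at the blend.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from lamhinge.core_io import (
    ANGSTROM_PER_NM,
    AtomisticStructure,
    TipModel,
    Topograph,
)

__all__ = [
    "tip_apex_profile",
    "tip_reach",
    "dilate_with_tip",
    "surface_from_structure",
    "simulate_afm",
]


def tip_apex_profile(tip: TipModel, d: np.ndarray | float) -> np.ndarray:
    """Height of the tip surface above its apex at lateral distance ``d`` (nm).

    ``f(0) = 0``; sphere of radius ``Rs`` for ``d ≤ Rs·cos α``; beyond the
    tangency circle the profile continues as the cone flank with slope
    ``cot α``, so value and slope are continuous.
    """
    d = np.abs(np.asarray(d, dtype=float))
    rs = tip.sphere_radius
    alpha = math.radians(tip.cone_half_angle)
    d_star = rs * math.cos(alpha)
    sphere = rs - np.sqrt(np.clip(rs**2 - np.minimum(d, d_star) ** 2, 0.0, None))
    cone = rs * (1.0 - math.sin(alpha)) + (d - d_star) / math.tan(alpha)
    return np.where(d <= d_star, sphere, cone)


def tip_reach(tip: TipModel, depth: float) -> float:
    """Lateral distance at which the apex profile reaches ``depth`` (nm).

    The inverse of :func:`tip_apex_profile`; used to truncate dilation
    support exactly at the image height range.
    """
    if depth <= 0:
        return 0.0
    rs = tip.sphere_radius
    alpha = math.radians(tip.cone_half_angle)
    if depth <= rs * (1.0 - math.sin(alpha)):
        return math.sqrt(depth * (2.0 * rs - depth))
    d_star = rs * math.cos(alpha)
    return d_star + (depth - rs * (1.0 - math.sin(alpha))) * math.tan(alpha)


def dilate_with_tip(topo: Topograph, tip: TipModel) -> Topograph:
    """Gray-scale dilation of a height map with the tip apex profile.

    Implements ``out(x,y) = max_(u,v) [topo(u,v) − f(dist)]`` with the
    support window truncated exactly where ``f`` exceeds the image height
    range (contributions there can never win against the centre pixel).
    Pixels outside the image do not contribute.
    """
    px = topo.pixel_size
    if px > tip.sphere_radius:
        import logging

        logging.getLogger("lamhinge").warning(
            "pixel size %.3g nm exceeds tip sphere radius %.3g nm; "
            "dilation is under-resolved", px, tip.sphere_radius,
        )
    h = topo.heights
    height_range = float(h.max() - h.min())
    if height_range == 0.0:
        return Topograph(h.copy(), px, time=topo.time, frame_index=topo.frame_index)
    # truncating at the height-range reach is exact: a pixel further away is
    # penalised by more than the total relief and can never win
    k = int(math.ceil(tip_reach(tip, height_range) / px))
    k = min(k, max(h.shape) - 1)
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    dist = np.hypot(xx, yy) * px
    struct = -tip_apex_profile(tip, dist)
    footprint = dist <= tip_reach(tip, height_range) + px
    # grey_dilation computes max(input + structure) over the footprint;
    # cval far below min(h) keeps out-of-image pixels from contributing.
    out = ndimage.grey_dilation(
        h,
        structure=np.where(footprint, struct, -np.inf),
        mode="constant",
        cval=h.min() - 10.0 * height_range - 1.0,
    )
    return Topograph(out, px, time=topo.time, frame_index=topo.frame_index)


def surface_from_structure(
    structure: AtomisticStructure,
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    pixel_size: float = 0.1,
    padding: float = 2.0,
) -> Topograph:
    """Hard-sphere top surface of a structure laid on the support plane.

    The molecule is rotated by intrinsic z-y-x Euler angles (degrees),
    translated so the lowest point of any atom sphere sits at height 0, and
    rasterised: each pixel's height is the top of the highest atom sphere
    covering it, ``z_i + sqrt(r_i² − d_i²)`` over atoms with lateral distance
    ``d_i ≤ r_i``; background 0.  Output in nm.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    from scipy.spatial.transform import Rotation

    coords = structure.coords / ANGSTROM_PER_NM  # nm
    radii = structure.vdw_radii / ANGSTROM_PER_NM
    if any(abs(a) > 0 for a in rotation):
        rot = Rotation.from_euler("zyx", rotation, degrees=True)
        coords = rot.apply(coords)
    coords = coords - [coords[:, 0].min(), coords[:, 1].min(), 0.0]
    coords[:, 2] -= (coords[:, 2] - radii).min()

    width = coords[:, 0].max() + 2 * padding
    height = coords[:, 1].max() + 2 * padding
    nx = max(8, int(math.ceil(width / pixel_size)) + 1)
    ny = max(8, int(math.ceil(height / pixel_size)) + 1)
    img = np.zeros((ny, nx))
    # stamp each atom's spherical cap into its local pixel window
    for (x, y, z), r in zip(coords, radii):
        cx, cy = x + padding, y + padding
        j0 = max(0, int((cx - r) / pixel_size))
        j1 = min(nx - 1, int(math.ceil((cx + r) / pixel_size)))
        i0 = max(0, int((cy - r) / pixel_size))
        i1 = min(ny - 1, int(math.ceil((cy + r) / pixel_size)))
        if j1 < j0 or i1 < i0:
            continue
        jj = np.arange(j0, j1 + 1) * pixel_size - cx
        ii = np.arange(i0, i1 + 1) * pixel_size - cy
        d2 = ii[:, None] ** 2 + jj[None, :] ** 2
        cap = z + np.sqrt(np.clip(r**2 - d2, 0.0, None))
        cap[d2 > r**2] = 0.0
        window = img[i0:i1 + 1, j0:j1 + 1]
        np.maximum(window, cap, out=window)
    return Topograph(img, pixel_size)


def _downsample_max(topo: Topograph, factor: int) -> Topograph:
    """Resample to a coarser grid by block maximum (AFM pixels report the
    highest contact within the pixel)."""
    if factor <= 1:
        return topo
    h = topo.heights
    ny = (h.shape[0] // factor) * factor
    nx = (h.shape[1] // factor) * factor
    h = h[:ny, :nx]
    blocks = h.reshape(ny // factor, factor, nx // factor, factor)
    out = blocks.max(axis=(1, 3))
    if out.shape[0] < 8 or out.shape[1] < 8:
        pad_y = max(0, 8 - out.shape[0])
        pad_x = max(0, 8 - out.shape[1])
        out = np.pad(out, ((0, pad_y), (0, pad_x)))
    return Topograph(out, topo.pixel_size * factor, time=topo.time,
                     frame_index=topo.frame_index)


def simulate_afm(
    structure: AtomisticStructure,
    tip: TipModel | None = None,
    scan_step: float = 1.0,
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    padding: float = 3.0,
) -> Topograph:
    """Pseudo-AFM image of a rigid van der Waals structure.

    Renders the hard-sphere surface at fine internal resolution
    (``min(scan_step, 0.5 nm)`` divided into an integer number of steps per
    scan pixel), dilates it with the tip, then resamples to the scan grid.
    Defaults: scan step 1 nm, tip sphere radius 1 nm, cone half-angle 5°.
    """
    if tip is None:
        tip = TipModel(sphere_radius=1.0, cone_half_angle=5.0)
    factor = max(1, int(round(scan_step / min(scan_step, 0.5))))
    fine_px = scan_step / factor
    surface = surface_from_structure(
        structure, rotation=rotation, pixel_size=fine_px, padding=padding
    )
    dilated = dilate_with_tip(surface, tip)
    return _downsample_max(dilated, factor)
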