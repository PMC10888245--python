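"""Synthetic HS-AFM movies of hinged rod molecules with known ground truth.

The generator emulates the statistical structure of flexible trimeric
laminin molecules imaged by high-speed AFM: an elongated rod of ~2 nm
height made of two quasi-straight worm-like-chain arms joined at a hinge
whose angle fluctuates as a mean-reverting (Ornstein–Uhlenbeck) process, a
bulky terminal globule emulating the LG domain cluster at the C-terminal
end, tip-broadened lateral widths from gray-scale dilation with a
parametric tip, and i.i.d. Gaussian pixel noise per frame.  A stiff
S-shaped variant (two gentle circular bends, no hinge) emulates the stable
laminin-111 long arm and serves as the negative control for kink-detection
specificity.

Angle convention: 180° = straight, 0° = fully back-folded; the angle is a
fold magnitude (its sign is unobservable in a topograph), so the process is
clamped to [0°, 180°] rather than reflected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from lamhinge.core_io import MovieStack, TipModel, Topograph
from lamhinge.afm_simulate import dilate_with_tip

logger = logging.getLogger("lamhinge")

__all__ = [
    "HingedRodParams",
    "GroundTruth",
    "ou_angle_series",
    "sample_backbone",
    "s_shape_backbone",
    "render_frame",
    "generate_movie",
]


@dataclass(frozen=True)
class HingedRodParams:
    """Geometry and dynamics of the synthetic hinged rod.

    Defaults reproduce the printed morphometry scales of the flexible
    laminin-332 long arm as *visible* quantities: the C-terminal arm runs
    33 nm from the coiled-coil terminus to the hinge, of which ~9 nm lie
    under the LG globule cluster, leaving the observed ~24 nm kink-to-LG
    distance and (with the 43 nm N-terminal arm) an observed contour of
    ~67 nm from the apparent LG edge to the short-arm junction.  Rod height
    2.0 nm, mean hinge angle 63° with 25° spread, OU relaxation 2 s at
    3 frames/s; noise of 0.15 nm keeps molecules clearly segmentable.
    """

    arm1_length: float = 33.0  # nm, terminus -> hinge (C-terminal arm)
    arm2_length: float = 43.0  # nm, N-terminal arm
    persistence_length: float = 300.0  # nm, arm stiffness (discrete WLC)
    rod_height: float = 2.0  # nm
    rod_width: float = 2.2  # nm, physical base width of the rod
    lg_radius: float = 4.5  # nm, terminal globule footprint radius
    lg_height: float = 4.0  # nm, terminal globule apex height
    mean_angle: float = 63.0  # degrees
    angle_sd: float = 25.0  # degrees
    angle_relax_time: float = 2.0  # s
    noise_sd: float = 0.15  # nm
    pixel_size: float = 1.0  # nm
    frame_interval: float = 1.0 / 3.0  # s

    def __post_init__(self) -> None:
        for name in ("arm1_length", "arm2_length", "persistence_length",
                     "rod_height", "rod_width", "lg_radius", "lg_height",
                     "pixel_size", "frame_interval"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.mean_angle <= 180.0):
            raise ValueError("mean_angle must lie in [0, 180] degrees")
        if self.angle_sd < 0 or self.noise_sd < 0:
            raise ValueError("angle_sd and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-frame ground truth saved alongside a synthetic movie."""

    backbones: list[np.ndarray] = field(default_factory=list)  # (n,2) nm
    hinge_arc_from_lg: list[float] = field(default_factory=list)  # nm
    hinge_angle: list[float] = field(default_factory=list)  # degrees
    contour_length: list[float] = field(default_factory=list)  # nm
    end_to_end: list[float] = field(default_factory=list)  # nm
    lg_centroid: list[np.ndarray] = field(default_factory=list)  # (2,) nm

    def validate(self) -> None:
        for pos, cl, ang in zip(self.hinge_arc_from_lg, self.contour_length,
                                self.hinge_angle):
            if not math.isnan(pos):
                assert 0.0 < pos < cl, "hinge position outside contour"
                assert 0.0 <= ang <= 180.0, "angle outside [0, 180]"
        for cl, e2e in zip(self.contour_length, self.end_to_end):
            assert cl >= e2e - 1e-9, "contour length below end-to-end"

    def __len__(self) -> int:
        return len(self.backbones)


def ou_angle_series(
    mean_angle: float,
    angle_sd: float,
    relax_time: float,
    frame_interval: float,
    n_frames: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Exact stationary OU discretization of the hinge-angle series.

    AR(1) with lag-1 autocorrelation ``exp(−Δt/τ)``, stationary mean
    ``mean_angle`` and stationary sd ``angle_sd``; values clamped to
    [0°, 180°] with clamping events logged.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (relax_time > 0):
        raise ValueError("relax_time must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    phi = math.exp(-frame_interval / relax_time)
    innov_sd = angle_sd * math.sqrt(1.0 - phi * phi)
    x = np.empty(n_frames)
    x[0] = rng.normal(mean_angle, angle_sd)
    eps = rng.normal(0.0, 1.0, size=n_frames - 1)
    for t in range(1, n_frames):
        x[t] = mean_angle + phi * (x[t - 1] - mean_angle) + innov_sd * eps[t - 1]
    n_clamped = int(np.sum((x < 0.0) | (x > 180.0)))
    if n_clamped:
        logger.info("clamped %d of %d hinge angles to [0, 180]", n_clamped,
                    n_frames)
    return np.clip(x, 0.0, 180.0)


def _wlc_arm(length: float, step: float, persistence_length: float,
             noise: np.ndarray) -> np.ndarray:
    """Discrete worm-like-chain arm from standard-normal tangent noise.

    Tangent angle increments are ``noise·sqrt(step/persistence_length)``;
    the returned polyline starts at the origin with its end-to-end direction
    rotated onto +x, so a caller can point the arm exactly.
    """
    n_seg = max(1, int(round(length / step)))
    ds = length / n_seg
    sd = math.sqrt(ds / persistence_length)
    theta = np.concatenate([[0.0], np.cumsum(noise[:n_seg - 1] * sd)]) if n_seg > 1 else np.array([0.0])
    steps = ds * np.column_stack([np.cos(theta), np.sin(theta)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    e2e = pts[-1] - pts[0]
    ang = math.atan2(e2e[1], e2e[0])
    c, s = math.cos(-ang), math.sin(-ang)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T


def _rotate(points: np.ndarray, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return points @ np.array([[c, -s], [s, c]]).T


def _self_overlap(points: np.ndarray) -> bool:
    """True when any two non-adjacent polyline segments properly cross.

    Proximity alone is not an overlap: a back-folded molecule (hinge angle
    near 0°) legitimately lays its arms side by side without crossing.
    """
    p = points[:-1]
    q = points[1:]
    n = len(p)
    d = q - p

    def cross(o, a, b):
        return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - \
               (a[..., 1] - o[..., 1]) * (b[..., 0] - o[..., 0])

    i, j = np.triu_indices(n, k=2)  # skip adjacent segments
    p1, q1 = p[i], q[i]
    p2, q2 = p[j], q[j]
    d1 = cross(p1, q1, p2)
    d2 = cross(p1, q1, q2)
    d3 = cross(p2, q2, p1)
    d4 = cross(p2, q2, q1)
    crossing = (d1 * d2 < 0) & (d3 * d4 < 0)
    return bool(np.any(crossing))


def sample_backbone(
    params: HingedRodParams,
    hinge_angle: float,
    rng: np.random.Generator,
    arm_noise: tuple[np.ndarray, np.ndarray] | None = None,
    orientation: float = 0.0,
    max_attempts: int = 100,
) -> tuple[np.ndarray, int]:
    """Backbone polyline of one hinged rod (nm), LG end first.

    Two discrete worm-like-chain arms are joined at the origin so the angle
    between their end-to-end directions equals ``hinge_angle`` (the split is
    symmetric about +y, then the whole molecule is rotated by
    ``orientation`` degrees).  Self-overlapping conformations are resampled
    (up to ``max_attempts``).  Returns ``(points, hinge_index)`` with points
    ordered from the LG end (arm 1) through the hinge to the short-arm end.
    """
    step = params.pixel_size / 2.0
    n1 = max(1, int(round(params.arm1_length / step)))
    n2 = max(1, int(round(params.arm2_length / step)))
    for attempt in range(max_attempts):
        if arm_noise is not None and attempt == 0:
            z1, z2 = arm_noise
        else:
            z1 = rng.normal(size=n1)
            z2 = rng.normal(size=n2)
        arm1 = _wlc_arm(params.arm1_length, step, params.persistence_length, z1)
        arm2 = _wlc_arm(params.arm2_length, step, params.persistence_length, z2)
        # outward directions at ±hinge_angle/2 about +y
        a1 = _rotate(arm1, 90.0 + hinge_angle / 2.0)
        a2 = _rotate(arm2, 90.0 - hinge_angle / 2.0)
        pts = np.vstack([a1[::-1], a2[1:]])
        pts = _rotate(pts, orientation)
        hinge_idx = len(a1) - 1
        if not _self_overlap(pts):
            return pts, hinge_idx
    raise RuntimeError(
        "persistent self-overlap while sampling the backbone; "
        "increase mean_angle or persistence_length"
    )


def s_shape_backbone(
    radius1: float = 9.2,
    radius2: float = 9.7,
    arc_deg: float = 120.0,
    tail: float = 13.2,
    jitter_sd: float = 3.0,
    rng: np.random.Generator | None = None,
    orientation: float = 0.0,
    step: float = 0.5,
) -> np.ndarray:
    """Stiff S-shaped backbone: two tangent circular arcs of opposite sense
    with short straight tails, emulating the stable laminin-111 long arm.

    Defaults give bend radii of 9.2 and 9.7 nm and a contour length of
    ~66 nm.  ``jitter_sd`` adds small per-frame rotations of each half about
    the inflection point (degrees) — shape jitter without a hinge.
    """
    rng = rng or np.random.default_rng()

    def arc(r: float, span_deg: float, sense: float) -> np.ndarray:
        span_rad = math.radians(span_deg)
        n = max(2, int(round(r * span_rad / step)))
        t = np.linspace(0.0, span_rad, n)
        # starts at origin with tangent +x, curving to the side `sense`
        return np.column_stack([r * np.sin(t), sense * r * (1.0 - np.cos(t))])

    n_tail = max(2, int(round(tail / step)))
    tail_pts = np.column_stack([np.linspace(0.0, tail, n_tail),
                                np.zeros(n_tail)])

    def chain(segments: list[np.ndarray]) -> np.ndarray:
        pts = segments[0]
        for seg in segments[1:]:
            tangent = pts[-1] - pts[-2]
            ang = math.degrees(math.atan2(tangent[1], tangent[0]))
            pts = np.vstack([pts, (_rotate(seg, ang) + pts[-1])[1:]])
        return pts

    j1, j2 = rng.normal(0.0, jitter_sd, size=2)
    pts = chain([
        tail_pts,
        arc(radius1, arc_deg + j1, +1.0),
        arc(radius2, arc_deg + j2, -1.0),
        tail_pts,
    ])
    return _rotate(pts - pts.mean(axis=0), orientation)


def render_frame(
    backbone: np.ndarray,
    params: HingedRodParams,
    tip: TipModel,
    rng: np.random.Generator,
    frame_shape: tuple[int, int],
    offset: np.ndarray | None = None,
    with_lg: bool = True,
) -> tuple[Topograph, np.ndarray | None]:
    """Render one topograph from a backbone polyline.

    The true surface is the union of a rod of semi-elliptical cross-section
    (apex ``rod_height``, base ``rod_width``) along the backbone and a
    spherical-cap globule at the LG end, whose centre sits on the backbone
    ``lg_radius`` nm (arc length) from the LG endpoint so the cap overlies
    the rod terminus.  The image is the gray-scale dilation of that surface
    with the tip apex profile plus i.i.d. Gaussian noise.  Returns the
    topograph and the LG cap centre (nm) or None.
    """
    px = params.pixel_size
    ny, nx = frame_shape
    if backbone is None or len(backbone) == 0:
        img = np.zeros((ny, nx))
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
        return Topograph(img, px), None

    pts = backbone + (offset if offset is not None else 0.0)
    margin = 3.0 * tip.sphere_radius
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    if lo[0] < 0 or lo[1] < 0 or hi[0] > nx * px or hi[1] > ny * px:
        raise ValueError(
            f"backbone bounding box {pts.min(axis=0)}..{pts.max(axis=0)} nm "
            f"does not fit a {nx * px:.0f}x{ny * px:.0f} nm frame with "
            f"{margin:.1f} nm margin"
        )

    # densify the polyline so the distance transform is smooth
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    fine_s = np.arange(0.0, arc[-1], px / 4.0)
    fine = np.column_stack([
        np.interp(fine_s, arc, pts[:, 0]), np.interp(fine_s, arc, pts[:, 1])
    ])

    yy, xx = np.mgrid[0:ny, 0:nx]
    grid = np.column_stack([xx.ravel() * px, yy.ravel() * px])
    tree = cKDTree(fine)
    half_w = params.rod_width / 2.0
    d, _ = tree.query(grid, distance_upper_bound=half_w + px)
    d = d.reshape(ny, nx)
    surface = np.zeros((ny, nx))
    inside = d <= half_w
    surface[inside] = params.rod_height * np.sqrt(
        1.0 - (d[inside] / half_w) ** 2
    )

    lg_center = None
    if with_lg:
        s_c = min(params.lg_radius, arc[-1])
        lg_center = np.array([
            np.interp(s_c, arc, pts[:, 0]), np.interp(s_c, arc, pts[:, 1])
        ])
        a, h = params.lg_radius, params.lg_height
        rc = (a * a + h * h) / (2.0 * h)
        dlg = np.hypot(xx * px - lg_center[0], yy * px - lg_center[1])
        cap = np.sqrt(np.clip(rc * rc - dlg**2, 0.0, None)) - (rc - h)
        np.maximum(surface, np.clip(cap, 0.0, None), out=surface)

    topo = dilate_with_tip(Topograph(surface, px), tip)
    img = topo.heights
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return Topograph(img, px), lg_center


def _default_frame_shape(params: HingedRodParams, n_molecules: int = 1) -> tuple[int, int]:
    span = (params.arm1_length + params.arm2_length) + 2 * params.lg_radius + 24.0
    n = int(math.ceil(span / params.pixel_size))
    return (n, n)


def generate_movie(
    params: HingedRodParams,
    n_frames: int,
    seed: int,
    mode: str = "hinged",
    tip: TipModel | None = None,
    frame_shape: tuple[int, int] | None = None,
    positions: list[tuple[float, float]] | None = None,
    arm_correlation: float = 0.8,
) -> tuple[MovieStack, GroundTruth]:
    """Generate a synthetic movie plus its ground truth, reproducibly.

    ``mode`` is ``"hinged"`` (flexible laminin-332-like molecule, hinge
    angle following the OU series) or ``"s_shape"`` (stiff laminin-111-like
    S-curve, no hinge).  Arm tangent noise is redrawn each frame as an AR(1)
    across frames with correlation ``arm_correlation``, giving temporal
    shape coherence.  ``positions`` places one molecule per entry (frame
    centre by default).  Ground truth lists the first molecule's values when
    several are present.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if mode not in ("hinged", "s_shape"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    tip = tip or TipModel(sphere_radius=2.0, cone_half_angle=5.0)
    shape = frame_shape or _default_frame_shape(params)
    ny, nx = shape
    center = np.array([nx * params.pixel_size / 2.0,
                       ny * params.pixel_size / 2.0])
    if positions is None:
        positions = [tuple(center)]

    angles = ou_angle_series(
        params.mean_angle, params.angle_sd, params.angle_relax_time,
        params.frame_interval, n_frames, rng,
    )

    step = params.pixel_size / 2.0
    n1 = max(1, int(round(params.arm1_length / step)))
    n2 = max(1, int(round(params.arm2_length / step)))
    n_mol = len(positions)
    orientations = rng.uniform(0.0, 360.0, size=n_mol)
    noise_state = [
        (rng.normal(size=n1), rng.normal(size=n2)) for _ in range(n_mol)
    ]
    rho = float(arm_correlation)

    frames: list[Topograph] = []
    truth = GroundTruth()
    for t in range(n_frames):
        surfaces = None
        gt_backbone = None
        gt_hinge_arc = math.nan
        gt_lg = None
        frame_img = np.zeros(shape)
        for m, pos in enumerate(positions):
            if t > 0:
                z1, z2 = noise_state[m]
                z1 = rho * z1 + math.sqrt(1 - rho * rho) * rng.normal(size=n1)
                z2 = rho * z2 + math.sqrt(1 - rho * rho) * rng.normal(size=n2)
                noise_state[m] = (z1, z2)
            if mode == "hinged":
                pts, hinge_idx = sample_backbone(
                    params, angles[t], rng, arm_noise=noise_state[m],
                    orientation=orientations[m],
                )
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                hinge_arc = float(np.sum(seg[:hinge_idx]))
            else:
                pts = s_shape_backbone(rng=rng, orientation=orientations[m])
                hinge_arc = math.nan
            pts = pts - pts.mean(axis=0) + np.asarray(pos)

            quiet = HingedRodParams(
                **{**params.__dict__, "noise_sd": 0.0}
            )
            topo, lg_center = render_frame(
                pts, quiet, tip, rng, shape, with_lg=True,
            )
            np.maximum(frame_img, topo.heights, out=frame_img)
            if m == 0:
                gt_backbone = pts
                gt_hinge_arc = hinge_arc
                gt_lg = lg_center
        if params.noise_sd > 0:
            frame_img = frame_img + rng.normal(0.0, params.noise_sd,
                                               size=frame_img.shape)
        frames.append(
            Topograph(frame_img, params.pixel_size,
                      time=t * params.frame_interval, frame_index=t)
        )
        seg = np.linalg.norm(np.diff(gt_backbone, axis=0), axis=1)
        truth.backbones.append(gt_backbone)
        truth.hinge_arc_from_lg.append(gt_hinge_arc)
        truth.hinge_angle.append(float(angles[t]) if mode == "hinged" else math.nan)
        truth.contour_length.append(float(np.sum(seg)))
        truth.end_to_end.append(float(np.linalg.norm(gt_backbone[-1] - gt_backbone[0])))
        truth.lg_centroid.append(gt_lg)
    truth.validate()
    return MovieStack(frames, frame_interval=params.frame_interval), truth
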