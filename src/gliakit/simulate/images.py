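"""Synthetic fluorescence stacks with analytic ground truth.

Three fixtures mirror the histology quantifications: a branching
microglia-like tree (ground truth = analytic Sholl crossing counts), a
myelin-like fiber field (ground truth = per-frame mask area fraction),
and a nuclei field with marker channels (ground truth = per-nucleus
positivity).  Geometry is specified in micrometres and rasterized at the
configured pixel size; nuclei are disks and fibers constant-width
segments so the planted truth is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..imaging import ImageStack, ShollProfile

__all__ = [
    "SimImageConfig",
    "TreeSpec",
    "random_tree",
    "simulate_microglia_stack",
    "simulate_fiber_stack",
    "simulate_nuclei_field",
]


@dataclass
class SimImageConfig:
    """Physical geometry and noise model of a simulated confocal stack.

    Defaults reproduce a typical confocal acquisition for this assay:
    a 212 x 212 x 30 um field, 30 z-frames, moderate Gaussian read noise
    on a low uniform background.
    """

    field_size_um: tuple[float, float, float] = (212.0, 212.0, 30.0)
    pixel_size_um: float = 0.4
    n_frames: int = 30
    noise_sd: float = 5.0
    background_level: float = 10.0
    signal_level: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be >= 0")

    @property
    def shape_yx(self) -> tuple[int, int]:
        ny = round(self.field_size_um[1] / self.pixel_size_um)
        nx = round(self.field_size_um[0] / self.pixel_size_um)
        return ny, nx

    @property
    def z_step_um(self) -> float:
        return self.field_size_um[2] / self.n_frames


def _noisy_stack(
    config: SimImageConfig, signal_2d: np.ndarray, rng: np.random.Generator,
    frame_gains: np.ndarray | None = None,
) -> ImageStack:
    """Embed a 2-D signal into every frame, add background and noise."""
    ny, nx = signal_2d.shape
    gains = np.ones(config.n_frames) if frame_gains is None else frame_gains
    frames = (
        signal_2d[None, :, :] * gains[:, None, None]
        + config.background_level
        + rng.normal(0.0, config.noise_sd, size=(config.n_frames, ny, nx))
    )
    return ImageStack(
        data=np.clip(frames, 0, None),
        pixel_size_um=(config.pixel_size_um, config.pixel_size_um),
        z_step_um=config.z_step_um,
    )


# ---------------------------------------------------------------------------
# microglia tree


@dataclass
class TreeSpec:
    """Soma plus poly-line branches, all coordinates in um.

    ``branches`` is a list of (polyline, width) pairs; a polyline is an
    (n, 2) array of (y, x) vertices.  Branches are expected to start at
    the soma boundary and not leave the field.
    """

    soma_center_um: tuple[float, float]
    soma_radius_um: float
    branches: list[tuple[np.ndarray, float]] = field(default_factory=list)


def random_tree(
    config: SimImageConfig,
    n_branches: int = 8,
    rng: np.random.Generator | None = None,
    soma_radius_um: float = 3.5,
    branch_length_um: tuple[float, float] = (30.0, 70.0),
    branch_width_um: float = 1.5,
    n_segments: int = 3,
    r_step: float = 5.0,
) -> TreeSpec:
    """Random radial tree whose rasterized Sholl counts are provably the
    centerline crossing counts.

    The construction keeps every circle crossing transversal and every
    run on a sampling circle attributable to exactly one branch:
    branches leave the soma at jittered but well-separated base angles,
    their radius grows strictly monotonically (each vertex is placed at
    a larger radius), angular drift per branch is bounded by a fraction
    of the angular gap so neighboring branches never merge, and tip
    radii are nudged away from multiples of ``r_step`` so a rounded
    branch cap never grazes a sampling circle the centerline does not
    cross.
    """
    rng = rng or np.random.default_rng(0)
    fy, fx = config.field_size_um[1], config.field_size_um[0]
    center = (fy / 2, fx / 2)
    half_gap = math.pi / n_branches
    base_angles = np.linspace(0, 2 * math.pi, n_branches, endpoint=False)
    base_angles = base_angles + rng.uniform(-0.15 * half_gap, 0.15 * half_gap, n_branches)
    drift_budget = 0.2 * half_gap
    max_r = min(fy, fx) / 2 - 4 * branch_width_um
    branches = []
    for ang in base_angles:
        length = rng.uniform(*branch_length_um)
        length = min(length, max_r - soma_radius_um - 2 * branch_width_um)
        tip_r = soma_radius_um + length
        # keep the rounded tip clear of every sampling circle
        nearest = round(tip_r / r_step) * r_step
        if abs(tip_r - nearest) < branch_width_um:
            tip_r = nearest + math.copysign(branch_width_um + 0.3, tip_r - nearest or 1)
        radii = np.linspace(soma_radius_um, tip_r, n_segments + 1)
        # joints near a sampling circle would let the circle graze the
        # capsule corner and split a run; nudge them off the circles
        for j in range(1, n_segments):
            near = round(radii[j] / r_step) * r_step
            if abs(radii[j] - near) < branch_width_um:
                radii[j] = near + math.copysign(
                    branch_width_um + 0.3, radii[j] - near or 1
                )
        thetas = [ang]
        for _ in range(n_segments):
            kink = rng.uniform(-drift_budget / n_segments, drift_budget / n_segments)
            thetas.append(thetas[-1] + kink)
        pts = [
            (center[0] + r * math.sin(t), center[1] + r * math.cos(t))
            for r, t in zip(radii, thetas)
        ]
        branches.append((np.array(pts), branch_width_um))
    return TreeSpec(
        soma_center_um=center, soma_radius_um=soma_radius_um, branches=branches
    )


def _circle_segment_crossings(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float
) -> list[float]:
    """Parameters t in [0, 1) where segment a->b crosses the circle."""
    d = b - a
    f = a - c
    qa = float(d @ d)
    if qa == 0:
        return []
    qb = 2.0 * float(f @ d)
    qc = float(f @ f) - r * r
    disc = qb * qb - 4 * qa * qc
    if disc <= 0:  # miss or tangency: no transversal crossing
        return []
    sq = math.sqrt(disc)
    out = []
    for t in ((-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)):
        if 0.0 <= t < 1.0:
            out.append(t)
    return out


def analytic_sholl(
    tree: TreeSpec, radii_um: np.ndarray
) -> np.ndarray:
    """Crossing count of each sampling circle with the branch centerlines.

    Counted by solving the segment/circle quadratic per polyline segment;
    a half-open segment parameterization avoids double counting at
    shared vertices.
    """
    c = np.asarray(tree.soma_center_um, dtype=float)
    counts = np.zeros(len(radii_um), dtype=int)
    for i, r in enumerate(radii_um):
        n = 0
        for polyline, _width in tree.branches:
            pts = np.asarray(polyline, dtype=float)
            for j in range(len(pts) - 1):
                n += len(_circle_segment_crossings(pts[j], pts[j + 1], c, r))
        counts[i] = n
    return counts


def _paint_capsule(
    img: np.ndarray, a: np.ndarray, b: np.ndarray, half_width_px: float, value: float
) -> None:
    """Set pixels within half_width of segment a->b (pixel coords) to value."""
    lo = np.floor(np.minimum(a, b) - half_width_px - 1).astype(int)
    hi = np.ceil(np.maximum(a, b) + half_width_px + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(img.shape) - 1)
    if (hi < lo).any():
        return
    yy, xx = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    p = np.stack([yy, xx], axis=-1).astype(float)
    d = b - a
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros(p.shape[:2])
    else:
        t = np.clip(((p - a) @ d) / denom, 0.0, 1.0)
    closest = a + t[..., None] * d
    dist = np.hypot(*(p - closest).transpose(2, 0, 1))
    region = img[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    region[dist <= half_width_px] = value


def rasterize_tree(tree: TreeSpec, config: SimImageConfig) -> np.ndarray:
    """Binary 2-D render of soma disk plus branches at the config pixel size."""
    ny, nx = config.shape_yx
    img = np.zeros((ny, nx))
    px = config.pixel_size_um
    c = np.asarray(tree.soma_center_um) / px
    yy, xx = np.mgrid[0:ny, 0:nx]
    img[np.hypot(yy - c[0], xx - c[1]) <= tree.soma_radius_um / px] = 1.0
    for polyline, width in tree.branches:
        if width < 2 * px:
            raise ValueError(
                f"branch width {width} um below 2 px at pixel size {px} um"
            )
        pts = np.asarray(polyline) / px
        for j in range(len(pts) - 1):
            _paint_capsule(img, pts[j], pts[j + 1], width / 2 / px, 1.0)
    return img


def simulate_microglia_stack(
    config: SimImageConfig, tree: TreeSpec, r_start: float = 5.0, r_step: float = 5.0
) -> tuple[ImageStack, ShollProfile, tuple[float, float]]:
    """Rasterize a branching tree into a noisy stack.

    Returns the stack, the analytic Sholl profile of the branch
    centerlines (radii from ``r_start`` in steps of ``r_step`` out to the
    largest circle inside the field), and the soma center in um.
    """
    fy, fx = config.field_size_um[1], config.field_size_um[0]
    cy, cx = tree.soma_center_um
    r_max = min(cy, cx, fy - cy, fx - cx) - config.pixel_size_um
    radii = np.arange(r_start, r_max, r_step)
    for polyline, _ in tree.branches:
        pts = np.asarray(polyline)
        if (pts < 0).any() or (pts[:, 0] > fy).any() or (pts[:, 1] > fx).any():
            raise ValueError("branch leaves the field")
    signal = rasterize_tree(tree, config) * config.signal_level
    rng = np.random.default_rng(config.seed)
    stack = _noisy_stack(config, signal, rng)
    profile = ShollProfile(
        radii_um=radii,
        intersections=analytic_sholl(tree, radii).astype(float),
        soma_center_um=(cy, cx),
    )
    return stack, profile, (cy, cx)


# ---------------------------------------------------------------------------
# fiber field


def simulate_fiber_stack(
    config: SimImageConfig,
    target_fraction: float,
    fiber_width_um: float = 1.2,
    max_fiber_len_um: float = 60.0,
    tol: float = 0.005,
) -> tuple[ImageStack, np.ndarray]:
    """Random-orientation fiber frames at a target area fraction.

    Each frame accumulates constant-width segments until the mask covers
    at least ``target_fraction`` of the frame; fiber length shrinks as
    the gap closes so the recorded truth lands within ``tol`` (0.5
    percentage points by default) of the target.  Frame brightness varies
    so brightest-frame selection is exercised.  Returns the stack and the
    per-frame truth fractions (exact pixel counts of the noiseless mask).
    """
    if not 0 <= target_fraction < 1:
        raise ValueError("target_fraction must lie in [0, 1)")
    ny, nx = config.shape_yx
    px = config.pixel_size_um
    if fiber_width_um < 2 * px:
        raise ValueError("fiber width below 2 px; raise width or resolution")
    rng = np.random.default_rng(config.seed)
    frames = np.zeros((config.n_frames, ny, nx))
    truths = np.zeros(config.n_frames)
    half_w = fiber_width_um / 2 / px
    # area added by one fiber must stay below tol so we can stop in-band
    cap_len_px = tol * ny * nx / (2 * half_w) * 0.8
    for z in range(config.n_frames):
        mask = np.zeros((ny, nx))
        if target_fraction > 0:
            for _ in range(100_000):
                frac = mask.mean()
                if frac >= target_fraction - tol / 2:
                    break
                length = min(max_fiber_len_um / px, cap_len_px)
                a = rng.uniform([0, 0], [ny - 1, nx - 1])
                theta = rng.uniform(0, 2 * math.pi)
                b = a + length * np.array([math.sin(theta), math.cos(theta)])
                b = np.clip(b, 0, [ny - 1, nx - 1])
                _paint_capsule(mask, a, b, half_w, 1.0)
            else:
                raise ValueError(
                    f"target fraction {target_fraction} unreachable with "
                    f"fiber width {fiber_width_um} um"
                )
        truths[z] = mask.mean()
        gain = rng.uniform(0.7, 1.3)
        frames[z] = (
            mask * config.signal_level * gain
            + config.background_level
            + rng.normal(0, config.noise_sd, size=(ny, nx))
        )
    stack = ImageStack(
        data=np.clip(frames, 0, None),
        pixel_size_um=(px, px),
        z_step_um=config.z_step_um,
    )
    return stack, truths


# ---------------------------------------------------------------------------
# nuclei field


def simulate_nuclei_field(
    config: SimImageConfig,
    n_nuclei: int,
    marker_positive_fraction: dict[str, float],
    coexpression: dict[str, str] | None = None,
    nucleus_radius_um: float = 4.0,
    max_retries: int = 20_000,
) -> tuple[dict[str, ImageStack], pd.DataFrame]:
    """Non-overlapping nuclear disks with marker channels.

    The DAPI channel holds ``n_nuclei`` disks; each marker channel is
    bright over ``round(fraction * n_nuclei)`` designated nuclei.
    ``coexpression`` maps a child marker to a parent marker whose
    positive nuclei must contain the child's (e.g. CC3 within APC).
    Returns per-channel stacks (key "DAPI" plus one per marker) and the
    per-nucleus truth table (center, radius, one boolean per marker).
    """
    coexpression = coexpression or {}
    for name, frac in marker_positive_fraction.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"fraction for {name!r} outside [0, 1]")
    for child, parent in coexpression.items():
        if marker_positive_fraction[child] > marker_positive_fraction[parent]:
            raise ValueError(f"{child} fraction exceeds its parent {parent}")

    ny, nx = config.shape_yx
    px = config.pixel_size_um
    r_px = nucleus_radius_um / px
    rng = np.random.default_rng(config.seed)

    centers: list[tuple[float, float]] = []
    tries = 0
    margin = r_px + 2
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not place {n_nuclei} non-overlapping nuclei "
                f"after {max_retries} tries"
            )
        cand = (rng.uniform(margin, ny - 1 - margin), rng.uniform(margin, nx - 1 - margin))
        if all(
            math.hypot(cand[0] - c[0], cand[1] - c[1]) > 2 * r_px + 3 for c in centers
        ):
            centers.append(cand)

    markers = list(marker_positive_fraction)
    positivity: dict[str, np.ndarray] = {}
    # parents first so children can nest inside them
    for name in sorted(markers, key=lambda m: m in coexpression):
        n_pos = round(marker_positive_fraction[name] * n_nuclei)
        if name in coexpression:
            pool = np.flatnonzero(positivity[coexpression[name]])
            if n_pos > len(pool):
                raise ValueError(f"{name} positives exceed parent pool")
            chosen = rng.choice(pool, size=n_pos, replace=False)
        else:
            chosen = rng.choice(n_nuclei, size=n_pos, replace=False)
        mask = np.zeros(n_nuclei, dtype=bool)
        mask[chosen] = True
        positivity[name] = mask

    yy, xx = np.mgrid[0:ny, 0:nx]

    def render(which: np.ndarray) -> np.ndarray:
        img = np.zeros((ny, nx))
        for i in np.flatnonzero(which):
            cy, cx = centers[i]
            img[np.hypot(yy - cy, xx - cx) <= r_px] = 1.0
        return img

    rng_noise = np.random.default_rng(config.seed + 1)
    stacks = {
        "DAPI": _noisy_stack(
            config, render(np.ones(n_nuclei, bool)) * config.signal_level, rng_noise
        )
    }
    for name in markers:
        stacks[name] = _noisy_stack(
            config, render(positivity[name]) * config.signal_level, rng_noise
        )

    truth = pd.DataFrame(
        {
            "y_um": [c[0] * px for c in centers],
            "x_um": [c[1] * px for c in centers],
            "radius_um": nucleus_radius_um,
            **{name: positivity[name] for name in markers},
        }
    )
    return stacks, truth
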