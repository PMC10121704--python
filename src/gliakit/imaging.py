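"""Histology quantifications on confocal stacks.

Implements the four measurements used on the cortical sections: Yen
automatic thresholding with integrated density limited to the threshold
(astrocyte ALDH1L1 intensity), Sholl intersection profiles on
thresholded maximum projections (microglial arborization), the
20-brightest-frame fiber volume fraction (MBP myelin density), and
DAPI/marker co-localization counts (APC+/DAPI+ and CC3+/APC+ ratios).

Coordinates are physical micrometres at the interface and pixel indices
internally (origin at the image corner, y down); conversions go through
``pixel_size_um``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImageStack",
    "ShollProfile",
    "QuantResult",
    "yen_threshold",
    "integrated_density_limited",
    "max_projection",
    "sholl_profile",
    "brightest_substack",
    "fiber_volume_fraction",
    "count_positive_cells",
    "ColocResult",
]


@dataclass
class ImageStack:
    """3-D intensity array (z, y, x) with physical pixel geometry."""

    data: np.ndarray
    pixel_size_um: tuple[float, float]  # (dy, dx)
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError("stack must be 2-D or 3-D")
        if self.data.min() < 0:
            raise ValueError("negative intensities")
        if min(self.pixel_size_um) <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class ShollProfile:
    """Intersection counts per sampling radius around a soma center.

    ``intersections`` is float so that radii whose circle leaves the
    image can be reported as NaN (missing), never as zero.
    """

    radii_um: np.ndarray
    intersections: np.ndarray
    soma_center_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=float)
        if np.any(np.diff(self.radii_um) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.nanmin(self.intersections, initial=0) < 0:
            raise ValueError("intersection counts must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"radius_um": self.radii_um, "intersections": self.intersections}
        )


@dataclass
class QuantResult:
    """A scalar image quantification with its per-unit breakdown."""

    kind: str  # integrated_density | volume_fraction | count_ratio
    value: float
    per_unit: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold: float | np.ndarray | None = None
    threshold_method: str = ""
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# thresholding


def _yen_criterion_terms(hist: np.ndarray):
    p = hist.astype(float)
    total = p.sum()
    if total == 0:
        raise ValueError("empty histogram")
    p = p / total
    p1 = np.cumsum(p)
    p1_sq = np.cumsum(p * p)
    p2_sq = p1_sq[-1] - p1_sq
    return p1, p1_sq, p2_sq


def yen_criterion(hist: np.ndarray, cut: int) -> float:
    """Yen's maximum-correlation criterion for splitting a histogram
    after bin ``cut`` (foreground = bins > cut)."""
    p1, p1_sq, p2_sq = _yen_criterion_terms(hist)
    a, b, c = p1_sq[cut], p2_sq[cut], p1[cut]
    if a <= 0 or b <= 0 or c <= 0 or c >= 1:
        return -np.inf
    return math.log((c * (1 - c)) ** 2 / (a * b))


def yen_threshold(
    image: np.ndarray | None = None,
    hist: np.ndarray | None = None,
    bin_centers: np.ndarray | None = None,
    nbins: int = 256,
) -> float:
    """Automatic threshold maximizing Yen's maximum-correlation criterion.

    Either an intensity array or a precomputed histogram (with optional
    bin centers) may be given.  The image path builds a 256-bin histogram
    over the intensity range.  Foreground is ``value > threshold``.
    """
    if hist is None:
        if image is None:
            raise ValueError("pass an image or a histogram")
        data = np.asarray(image, dtype=float).ravel()
        lo, hi = data.min(), data.max()
        if lo == hi:
            raise ValueError("constant image has no threshold")
        hist, edges = np.histogram(data, bins=nbins, range=(lo, hi))
        bin_centers = (edges[:-1] + edges[1:]) / 2
    else:
        hist = np.asarray(hist, dtype=float)
        if bin_centers is None:
            bin_centers = np.arange(len(hist), dtype=float)
        if (hist > 0).sum() < 2:
            raise ValueError("histogram needs >= 2 occupied bins")

    p1, p1_sq, p2_sq = _yen_criterion_terms(hist)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.log((p1 * (1 - p1)) ** 2 / (p1_sq * p2_sq))
    valid = (p1 > 0) & (p1 < 1) & (p1_sq > 0) & (p2_sq > 0)
    crit[~valid] = -np.inf
    crit[-1] = -np.inf  # no cut after the last bin
    cut = int(np.argmax(crit))
    return float(bin_centers[cut])


# ---------------------------------------------------------------------------
# integrated density


def integrated_density_limited(stack: ImageStack) -> QuantResult:
    """Integrated density limited to the Yen threshold, per frame.

    Each frame gets its own Yen threshold; the frame's integrated
    density is the sum of the strictly suprathreshold pixel intensities,
    and the reported value is the mean over frames (the per-animal
    aggregation being a mean over images).
    """
    per_frame = np.zeros(stack.n_frames)
    thresholds = np.zeros(stack.n_frames)
    flags: list[str] = []
    for z in range(stack.n_frames):
        frame = stack.data[z]
        if frame.min() == frame.max():
            thresholds[z] = frame.min()
            per_frame[z] = 0.0
            flags.append(f"frame {z}: constant, nothing above threshold")
            continue
        thr = yen_threshold(frame)
        thresholds[z] = thr
        above = frame > thr
        if not above.any():
            flags.append(f"frame {z}: nothing above threshold")
        per_frame[z] = float(frame[above].sum())
    return QuantResult(
        kind="integrated_density",
        value=float(per_frame.mean()),
        per_unit=per_frame,
        threshold=thresholds,
        threshold_method="yen",
        flags=flags,
    )


def max_projection(stack: ImageStack) -> np.ndarray:
    """Per-pixel maximum over z."""
    return stack.data.max(axis=0)


# ---------------------------------------------------------------------------
# Sholl


def sholl_profile(
    mask: np.ndarray,
    soma_center_um: tuple[float, float],
    pixel_size_um: tuple[float, float],
    r_start: float = 5.0,
    r_step: float = 5.0,
    r_max: float | None = None,
) -> ShollProfile:
    """Sholl intersection profile of a binary 2-D mask.

    Each sampling circle (radii ``r_start``, ``r_start + r_step``, ... up
    to ``r_max`` or the image edge) is sampled at arc steps of at most
    0.5 px; an intersection is one maximal contiguous run of foreground
    pixels along the circularly-closed sample sequence, so a process of
    any width crossing the circle counts once.  Circles extending past
    the image bounds are reported NaN (missing), not zero.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    mask = mask > 0
    if r_start <= 0:
        raise ValueError("r_start must be positive")
    dy, dx = pixel_size_um
    if abs(dy - dx) > 1e-9:
        raise ValueError("anisotropic pixels not supported in Sholl sampling")
    px = dy
    ny, nx = mask.shape
    cy, cx = soma_center_um[0] / px, soma_center_um[1] / px
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("soma center outside the image")

    edge_r_px = min(cy, cx, ny - 1 - cy, nx - 1 - cx)
    if r_max is None:
        r_max = edge_r_px * px
    radii = np.arange(r_start, r_max + 1e-9, r_step)
    counts = np.full(len(radii), np.nan)
    for i, r_um in enumerate(radii):
        r_px = r_um / px
        if r_px > edge_r_px:
            continue  # missing, stays NaN
        n_samples = max(8, int(math.ceil(2 * math.pi * r_px / 0.5)))
        ang = np.linspace(0, 2 * math.pi, n_samples, endpoint=False)
        ys = np.rint(cy + r_px * np.sin(ang)).astype(int)
        xs = np.rint(cx + r_px * np.cos(ang)).astype(int)
        vals = mask[ys, xs]
        # close single-sample gaps (< 1 px of arc): a binary mask cannot
        # represent a background corridor narrower than a pixel, so such
        # gaps are rounding flicker at a process boundary, not crossings
        vals = vals | (np.roll(vals, 1) & np.roll(vals, -1))
        if vals.all():
            counts[i] = 1.0  # a full foreground ring is a single run
        elif not vals.any():
            counts[i] = 0.0
        else:
            rising = (vals & ~np.roll(vals, 1)).sum()  # circularly closed
            counts[i] = float(rising)
    return ShollProfile(
        radii_um=radii, intersections=counts, soma_center_um=tuple(soma_center_um)
    )


def soma_center_from_mask(
    mask: np.ndarray, pixel_size_um: tuple[float, float]
) -> tuple[float, float]:
    """Centroid (um) of the largest foreground component; fallback center."""
    labeled, n = ndimage.label(np.asarray(mask) > 0)
    if n == 0:
        raise ValueError("empty mask has no soma")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    cy, cx = ndimage.center_of_mass(labeled == biggest)
    return cy * pixel_size_um[0], cx * pixel_size_um[1]


# ---------------------------------------------------------------------------
# fiber volume fraction


def brightest_substack(stack: ImageStack, n: int = 20) -> ImageStack:
    """Substack of the ``n`` brightest frames (by mean intensity).

    Original z order is preserved; exact ties resolve to the lower z
    index.  With fewer than ``n`` frames the whole stack is returned with
    a warning.
    """
    means = stack.data.mean(axis=(1, 2))
    if stack.n_frames <= n:
        if stack.n_frames < n:
            warnings.warn(
                f"stack has {stack.n_frames} < {n} frames; using all of them"
            )
        return stack
    # stable sort on -mean keeps lower z first among ties
    order = np.argsort(-means, kind="stable")[:n]
    keep = np.sort(order)
    return ImageStack(
        data=stack.data[keep],
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um,
    )


def _frame_threshold(frame: np.ndarray, method: str) -> float:
    if method == "otsu":
        from skimage.filters import threshold_otsu

        return float(threshold_otsu(frame, nbins=256))
    if method == "yen":
        return yen_threshold(frame)
    raise ValueError(f"unknown threshold method {method!r}")


def fiber_volume_fraction(
    stack: ImageStack, n_frames: int = 20, method: str = "otsu"
) -> QuantResult:
    """Volume fraction of fibers from the brightest substack.

    The ``n_frames`` brightest frames are auto-thresholded individually
    (Otsu by default, Yen selectable); the per-frame covered fraction of
    the binary mask is averaged into the volume fraction.  Constant
    frames contribute 1.0 if uniformly bright, 0.0 if blank (flagged).
    """
    sub = brightest_substack(stack, n_frames)
    fractions = np.zeros(sub.n_frames)
    thresholds = np.full(sub.n_frames, np.nan)
    flags: list[str] = []
    for z in range(sub.n_frames):
        frame = sub.data[z]
        if frame.min() == frame.max():
            fractions[z] = 1.0 if frame.min() > 0 else 0.0
            flags.append(f"frame {z}: constant intensity")
            continue
        thr = _frame_threshold(frame, method)
        thresholds[z] = thr
        fractions[z] = float((frame > thr).mean())
    return QuantResult(
        kind="volume_fraction",
        value=float(fractions.mean()),
        per_unit=fractions,
        threshold=thresholds,
        threshold_method=method,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# co-localization counts


@dataclass
class ColocResult:
    """Nucleus counts and marker positivity ratios for one field."""

    n_nuclei: int
    positive: dict[str, int]
    pct_of_total: dict[str, float]
    ratios: dict[tuple[str, str], float]
    labels: np.ndarray
    per_nucleus: pd.DataFrame
    threshold_method: str


def count_positive_cells(
    dapi: ImageStack,
    markers: dict[str, ImageStack],
    ratio_pairs: list[tuple[str, str]] | None = None,
    method: str = "otsu",
    smooth_sigma_um: float = 1.0,
    nucleus_diameter_um: float = 10.0,
    min_area_frac: float = 0.1,
    max_area_frac: float = 4.0,
) -> ColocResult:
    """Count DAPI nuclei and their marker positivity.

    Nuclei are segmented from the smoothed, auto-thresholded maximum
    projection of the DAPI channel; connected components are kept inside
    area bounds scaled from a ``nucleus_diameter_um`` disk.  A nucleus is
    positive for a marker iff its mean intensity in the marker's maximum
    projection exceeds that channel's auto-threshold.  ``ratio_pairs``
    (numerator, denominator) report co-positive counts over
    denominator-positive counts, e.g. ``("CC3", "APC")`` for the
    CC3+APC+ / APC+ apoptosis ratio.
    """
    for name, st in markers.items():
        if st.data.shape[1:] != dapi.data.shape[1:]:
            raise ValueError(f"marker {name!r} not co-registered with DAPI")
    px = dapi.pixel_size_um[0]
    proj = max_projection(dapi)
    sigma_px = smooth_sigma_um / px
    smoothed = ndimage.gaussian_filter(proj.astype(float), sigma_px)
    if smoothed.min() == smoothed.max():
        raise ValueError("DAPI projection is constant; no nuclei")
    thr = _frame_threshold(smoothed, method)
    labeled, n_comp = ndimage.label(smoothed > thr)
    nominal_area_px = math.pi * (nucleus_diameter_um / 2 / px) ** 2
    lo, hi = min_area_frac * nominal_area_px, max_area_frac * nominal_area_px
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n_comp + 1))
    keep_ids = [i + 1 for i, a in enumerate(areas) if lo <= a <= hi]
    if not keep_ids:
        raise ValueError("no nuclei within the area bounds")

    relabeled = np.zeros_like(labeled)
    for new, old in enumerate(keep_ids, start=1):
        relabeled[labeled == old] = new
    n_nuclei = len(keep_ids)

    per_nucleus = pd.DataFrame(index=pd.RangeIndex(1, n_nuclei + 1, name="nucleus"))
    positive: dict[str, np.ndarray] = {}
    for name, st in markers.items():
        mproj = max_projection(st).astype(float)
        if mproj.min() == mproj.max():
            mthr = float(mproj.min())  # no signal: nothing exceeds it
        else:
            mthr = _frame_threshold(mproj, method)
        means = ndimage.mean(mproj, relabeled, index=range(1, n_nuclei + 1))
        positive[name] = np.asarray(means) > mthr
        per_nucleus[name] = positive[name]
        per_nucleus[f"{name}_mean"] = np.asarray(means)

    counts = {name: int(mask.sum()) for name, mask in positive.items()}
    pct = {name: 100.0 * counts[name] / n_nuclei for name in counts}
    ratios: dict[tuple[str, str], float] = {}
    for num, den in ratio_pairs or []:
        co = int((positive[num] & positive[den]).sum())
        ratios[(num, den)] = co / counts[den] if counts[den] else float("nan")
    return ColocResult(
        n_nuclei=n_nuclei,
        positive=counts,
        pct_of_total=pct,
        ratios=ratios,
        labels=relabeled,
        per_nucleus=per_nucleus,
        threshold_method=method,
    )
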