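"""ACR TI-RADS feature extraction, scoring and rater comparison.

ACR TI-RADS grades a thyroid nodule on five axes — composition,
echogenicity, margin, shape and echogenic foci — sums the points and maps
the total to a risk level TR1..TR5 with a size-conditioned management
recommendation (no FNA / follow-up / FNA).

The image-derived pipeline works entirely from gray statistics of the
gland: the gland histogram is smoothed, its "line average" (mean smoothed
count) selects the modal gray levels, and the mean/std (mu_g, sigma_g) of
gland pixels at those levels define echogenicity bands in sigma units
(cystic / hypo / iso / hyper / calcification).  Nodule pixels are binned
into the bands; composition and echogenicity scores follow from the band
fractions, shape from the taller-than-wide test, margin from a moment-based
ellipse fit plus a boundary-normal gray-std statistic, and foci from
clustering of calcification-band pixels.  The band cut-points are not part
of the published description and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage import measure
from skimage.draw import ellipse as draw_ellipse

from .losses import mask_boundary

LEVEL_NAMES = {
    1: "benign",
    2: "not suspicious",
    3: "mildly suspicious",
    4: "moderately suspicious",
    5: "highly suspicious",
}

NO_FNA, FOLLOW_UP, FNA = "no FNA", "follow-up", "FNA"


@dataclass
class GlandStats:
    """Gland gray-level statistics from the smoothed histogram."""

    smoothed_hist: np.ndarray   # 256 smoothed counts
    line_average: float         # mean of the smoothed counts
    mu: float                   # mean of above-average gland pixels
    sigma: float                # std of above-average gland pixels


@dataclass
class PixelBands:
    """Echogenicity band boundaries in multiples of sigma around mu.

    Bands: cystic < mu + cystic_hi*sigma <= hypo < mu + hypo_hi*sigma <=
    iso <= mu + iso_hi*sigma < hyper <= mu + calc_lo*sigma < calcification.
    """

    cystic_hi: float = -2.5
    hypo_hi: float = -1.0
    iso_hi: float = 1.0
    calc_lo: float = 3.0

    def __post_init__(self) -> None:
        if not (self.cystic_hi < self.hypo_hi < self.iso_hi < self.calc_lo):
            raise ValueError("band boundaries must be strictly increasing")


@dataclass
class TiradsConfig:
    bands: PixelBands = field(default_factory=PixelBands)
    smoothing_window: int = 5
    cystic_composition_threshold: float = 0.9   # >= -> cystic (0 points)
    solid_composition_threshold: float = 0.1    # <= -> solid (2 points)
    margin_iou_threshold: float = 0.85          # ellipse IoU below -> irregular
    very_hypo_reference: float | None = None    # muscle gray level; None disables 3 pts
    macro_focus_mm: float = 2.0                 # spot equivalent diameter for macro
    peripheral_rim_px: float = 3.0              # boundary distance for rim pixels
    peripheral_fraction: float = 0.6            # rim fraction of foci pixels for 2 pts
    peripheral_coverage: float = 0.5            # boundary fraction the rim must span


@dataclass
class NoduleFeatures:
    band_fractions: dict[str, float]
    margin_stat: float          # mean across-boundary gray std
    ellipse_iou: float
    aspect_ratio: float         # depth extent / width extent
    foci_fraction: float
    foci_pattern: str
    size_mm: float              # largest in-plane diameter


@dataclass
class TiradsScore:
    composition: int
    echogenicity: int
    margin: int
    shape: int
    foci: int
    total: int
    level: int
    category: str
    recommendation: str
    features: NoduleFeatures | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# gland statistics and pixel bands
# ---------------------------------------------------------------------------

def gland_histogram_stats(
    image: np.ndarray, gland_mask: np.ndarray, smoothing_window: int = 5
) -> GlandStats:
    """Smoothed-histogram gland statistics.

    The 256-bin gland histogram is smoothed with a centered moving average;
    the line average is the mean smoothed count.  mu/sigma are computed over
    gland pixels whose gray level's smoothed count exceeds the line average
    (the modal part of the distribution), which de-weights tail pixels such
    as vessels or rim artefacts.  If no bin clears the line average the
    statistics fall back to all gland pixels.
    """
    mask = np.asarray(gland_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty gland mask")
    vals = np.asarray(image).astype(np.uint8)[mask]
    hist = np.bincount(vals, minlength=256).astype(float)
    w = max(1, int(smoothing_window))
    kernel = np.ones(w) / w
    smoothed = np.convolve(hist, kernel, mode="same")
    line_avg = float(smoothed.mean())
    modal_levels = smoothed > line_avg
    selected = vals[modal_levels[vals]]
    if selected.size == 0:
        selected = vals
    return GlandStats(
        smoothed_hist=smoothed,
        line_average=line_avg,
        mu=float(selected.mean()),
        sigma=float(selected.std()),
    )


def band_edges(stats: GlandStats, bands: PixelBands) -> dict[str, tuple[float, float]]:
    """Absolute gray-level interval of each echogenicity band."""
    mu, s = stats.mu, stats.sigma
    return {
        "cystic": (-np.inf, mu + bands.cystic_hi * s),
        "hypo": (mu + bands.cystic_hi * s, mu + bands.hypo_hi * s),
        "iso": (mu + bands.hypo_hi * s, mu + bands.iso_hi * s),
        "hyper": (mu + bands.iso_hi * s, mu + bands.calc_lo * s),
        "calcification": (mu + bands.calc_lo * s, np.inf),
    }


def classify_nodule_pixels(
    image: np.ndarray,
    nodule_mask: np.ndarray,
    stats: GlandStats,
    bands: PixelBands | None = None,
) -> dict[str, float]:
    """Fraction of nodule pixels in each echogenicity band (sums to 1).

    With sigma = 0 the bands degenerate to point thresholds at mu; pixels
    then fall into cystic (below mu), iso (at mu) or calcification (above).
    """
    bands = bands or PixelBands()
    mask = np.asarray(nodule_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nodule mask")
    vals = np.asarray(image, dtype=np.float64)[mask]
    edges = band_edges(stats, bands)
    fractions = {}
    n = vals.size
    for name, (lo, hi) in edges.items():
        if name == "cystic":
            count = (vals < hi).sum()
        elif name == "calcification":
            count = (vals > lo).sum()
        elif name == "iso":
            count = ((vals >= lo) & (vals <= hi)).sum()
        elif name == "hypo":
            count = ((vals >= lo) & (vals < hi)).sum()
        else:  # hyper
            count = ((vals > lo) & (vals <= hi)).sum()
        fractions[name] = count / n
    # guard against double counting at degenerate boundaries
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        fractions = {k: v / total for k, v in fractions.items()}
    return fractions


# ---------------------------------------------------------------------------
# component scores
# ---------------------------------------------------------------------------

def composition_score(
    band_fractions: dict[str, float], config: TiradsConfig | None = None
) -> int:
    """Cystic-dominant 0, mixed 1, solid 2, by the cystic pixel fraction."""
    cfg = config or TiradsConfig()
    c = band_fractions["cystic"]
    if c >= cfg.cystic_composition_threshold:
        return 0
    if c <= cfg.solid_composition_threshold:
        return 2
    return 1


def echogenicity_score(
    band_fractions: dict[str, float],
    nodule_mean: float | None = None,
    config: TiradsConfig | None = None,
) -> int:
    """ACR echogenicity points from the dominant band.

    Anechoic (cystic-dominant) 0, hyper- or isoechoic 1, hypoechoic 2.
    Very hypoechoic (3, darker than the strap muscle) requires a configured
    muscle reference level and is disabled by default.
    """
    cfg = config or TiradsConfig()
    f = band_fractions
    if f["cystic"] >= max(f["hypo"], f["iso"], f["hyper"] + f["calcification"]):
        return 0
    if (
        cfg.very_hypo_reference is not None
        and nodule_mean is not None
        and nodule_mean < cfg.very_hypo_reference
    ):
        return 3
    solid = {
        "hypo": f["hypo"],
        "iso": f["iso"],
        "hyper": f["hyper"] + f["calcification"],
    }
    dominant = max(solid, key=solid.get)
    return 2 if dominant == "hypo" else 1


def ellipse_fit_iou(nodule_mask: np.ndarray) -> float:
    """IoU between the mask and its moment-fitted ellipse.

    The ellipse takes the mask's centroid, orientation and second-moment
    axis lengths, rasterized on the same grid.
    """
    mask = np.asarray(nodule_mask, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("mask too small for an ellipse fit")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    r0, c0 = props.centroid
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    if b <= 0:
        raise ValueError("degenerate (collinear) mask")
    # regionprops measures the major-axis angle from the row axis; the
    # rasterizer's rotation is measured from the column axis, a quarter turn
    # apart (both pi-periodic for an ellipse)
    rot = props.orientation - np.pi / 2
    rr, cc = draw_ellipse(r0, c0, b, a, shape=mask.shape, rotation=rot)
    efit = np.zeros_like(mask)
    efit[rr, cc] = True
    inter = (mask & efit).sum()
    union = (mask | efit).sum()
    return float(inter / union)


def margin_statistic(
    image: np.ndarray, nodule_mask: np.ndarray, n_side: int = 5
) -> float:
    """Mean gray-level std along boundary normals (5 in + mid + 5 out).

    For every boundary pixel the local outward normal is estimated from the
    smoothed distance field of the mask; 2*n_side+1 samples are read along
    it with nearest-neighbour interpolation (clipped at the image border)
    and their std is averaged over the boundary.
    """
    img = np.asarray(image, dtype=np.float64)
    mask = np.asarray(nodule_mask, dtype=bool)
    boundary = mask_boundary(mask)
    by, bx = np.nonzero(boundary)
    if by.size < 8:
        raise ValueError("boundary too short for a margin statistic")
    # signed distance (positive outside) gives a smooth outward normal field
    signed = distance_transform_edt(~mask) - distance_transform_edt(mask)
    gy, gx = np.gradient(signed.astype(np.float64))
    stds = []
    offsets = np.arange(-n_side, n_side + 1)
    h, w = img.shape
    for y, x in zip(by, bx):
        ny_, nx_ = gy[y, x], gx[y, x]
        norm = np.hypot(ny_, nx_)
        if norm == 0:
            continue
        ny_, nx_ = ny_ / norm, nx_ / norm
        ys = np.clip(np.rint(y + offsets * ny_).astype(int), 0, h - 1)
        xs = np.clip(np.rint(x + offsets * nx_).astype(int), 0, w - 1)
        stds.append(img[ys, xs].std())
    return float(np.mean(stds))


def margin_score(
    image: np.ndarray,
    nodule_mask: np.ndarray,
    config: TiradsConfig | None = None,
) -> tuple[int, dict]:
    """0 (smooth / well defined) or 2 (irregular) plus the raw statistics.

    Shape regularity gates the point: an ellipse IoU below the threshold
    marks the margin irregular.  The boundary-normal gray-std statistic is
    reported alongside for inspection but does not gate by default — how
    the two factors combine into the single ACR point is a design choice.
    """
    cfg = config or TiradsConfig()
    iou = ellipse_fit_iou(nodule_mask)
    stat = margin_statistic(image, nodule_mask)
    points = 2 if iou < cfg.margin_iou_threshold else 0
    return points, {"ellipse_iou": iou, "margin_stat": stat}


def shape_score(nodule_mask: np.ndarray, spacing_mm: float = 1.0) -> tuple[int, float]:
    """Taller-than-wide test: 3 points iff depth extent > width extent.

    Extents are bounding-box spans in mm; exact equality scores 0.
    """
    mask = np.asarray(nodule_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nodule mask")
    ys, xs = np.nonzero(mask)
    depth = (ys.max() - ys.min() + 1) * spacing_mm
    width = (xs.max() - xs.min() + 1) * spacing_mm
    aspect = depth / width
    return (3 if aspect > 1.0 else 0), float(aspect)


def foci_score(
    image: np.ndarray,
    nodule_mask: np.ndarray,
    stats: GlandStats,
    config: TiradsConfig | None = None,
    spacing_mm: float = 1.0,
) -> tuple[int, dict]:
    """Echogenic-foci points from clustered calcification-band pixels.

    none 0; peripheral rim 2 (most foci pixels hug the boundary); any spot
    of macrocalcification size 1; otherwise small punctate spots 3.
    """
    cfg = config or TiradsConfig()
    mask = np.asarray(nodule_mask, dtype=bool)
    img = np.asarray(image, dtype=np.float64)
    threshold = stats.mu + cfg.bands.calc_lo * stats.sigma
    foci = mask & (img > threshold)
    info: dict = {"foci_fraction": float(foci.sum() / max(mask.sum(), 1))}
    if not foci.any():
        info["pattern"] = "none"
        return 0, info
    dist_in = distance_transform_edt(mask)  # distance to outside, px
    rim_frac = float((dist_in[foci] <= cfg.peripheral_rim_px).mean())
    info["rim_fraction"] = rim_frac
    # a true peripheral rim also wraps around the nodule: most boundary
    # pixels must have a focus nearby, which scattered punctate spots near
    # the margin do not achieve
    boundary = mask_boundary(mask)
    dist_to_focus = distance_transform_edt(~foci)
    coverage = float((dist_to_focus[boundary] <= cfg.peripheral_rim_px).mean())
    info["boundary_coverage"] = coverage
    labels = measure.label(foci, connectivity=2)
    sizes_px = np.bincount(labels.ravel())[1:]
    macro_area_px = np.pi * (cfg.macro_focus_mm / 2 / spacing_mm) ** 2
    if rim_frac >= cfg.peripheral_fraction and coverage >= cfg.peripheral_coverage:
        info["pattern"] = "peripheral"
        return 2, info
    if sizes_px.max() >= macro_area_px:
        info["pattern"] = "macro"
        return 1, info
    info["pattern"] = "punctate"
    return 3, info


def total_and_level(points) -> tuple[int, int, str]:
    """Sum the five component points and map to the TR level.

    Mapping: 0 -> TR1, 2 -> TR2, 3 -> TR3, 4-6 -> TR4, >= 7 -> TR5.  A total
    of 1 is unreachable from valid ACR components but maps to TR1 by
    convention if it arises from custom configurations.
    """
    pts = list(points)
    if len(pts) != 5:
        raise ValueError("expected five component scores")
    ranges = [(0, 2), (0, 3), (0, 3), (0, 3), (0, 3)]
    for p, (lo, hi) in zip(pts, ranges):
        if not lo <= p <= hi:
            raise ValueError(f"component score {p} outside its ACR range [{lo},{hi}]")
    total = int(sum(pts))
    if total <= 1:
        level = 1
    elif total == 2:
        level = 2
    elif total == 3:
        level = 3
    elif total <= 6:
        level = 4
    else:
        level = 5
    return total, level, LEVEL_NAMES[level]


def recommendation(level: int, size_mm: float) -> str:
    """ACR size-conditioned management advice for a TR level."""
    if size_mm <= 0:
        raise ValueError("size must be positive")
    if level in (1, 2):
        return NO_FNA
    if level == 3:
        return FNA if size_mm >= 25 else FOLLOW_UP if size_mm >= 15 else NO_FNA
    if level == 4:
        return FNA if size_mm >= 15 else FOLLOW_UP if size_mm >= 10 else NO_FNA
    if level == 5:
        return FNA if size_mm >= 10 else FOLLOW_UP if size_mm >= 5 else NO_FNA
    raise ValueError(f"unknown TR level {level}")


def score_nodule(
    image: np.ndarray,
    gland_mask: np.ndarray,
    nodule_mask: np.ndarray,
    spacing_mm: float = 1.0,
    config: TiradsConfig | None = None,
) -> TiradsScore:
    """Full image-derived TI-RADS score for one nodule.

    Gland statistics are computed on the gland parenchyma excluding the
    nodule under evaluation: a large anechoic nodule would otherwise
    contribute its own mode to the reference histogram and shift the
    echogenicity bands.
    """
    cfg = config or TiradsConfig()
    parenchyma = np.asarray(gland_mask, bool) & ~np.asarray(nodule_mask, bool)
    if not parenchyma.any():
        parenchyma = np.asarray(gland_mask, bool)
    stats = gland_histogram_stats(image, parenchyma, cfg.smoothing_window)
    fractions = classify_nodule_pixels(image, nodule_mask, stats, cfg.bands)
    nodule_mean = float(np.asarray(image, dtype=np.float64)[np.asarray(nodule_mask, bool)].mean())
    comp = composition_score(fractions, cfg)
    echo = echogenicity_score(fractions, nodule_mean, cfg)
    margin, margin_info = margin_score(image, nodule_mask, cfg)
    shape, aspect = shape_score(nodule_mask, spacing_mm)
    foci, foci_info = foci_score(image, nodule_mask, stats, cfg, spacing_mm)
    total, level, category = total_and_level([comp, echo, margin, shape, foci])
    ys, xs = np.nonzero(np.asarray(nodule_mask, bool))
    size = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1) * spacing_mm
    features = NoduleFeatures(
        band_fractions=fractions,
        margin_stat=margin_info["margin_stat"],
        ellipse_iou=margin_info["ellipse_iou"],
        aspect_ratio=aspect,
        foci_fraction=foci_info["foci_fraction"],
        foci_pattern=foci_info["pattern"],
        size_mm=float(size),
    )
    return TiradsScore(
        composition=comp,
        echogenicity=echo,
        margin=margin,
        shape=shape,
        foci=foci,
        total=total,
        level=level,
        category=category,
        recommendation=recommendation(level, features.size_mm),
        features=features,
    )


# ---------------------------------------------------------------------------
# rater comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    differences: list[int]              # per-nodule |total_A - total_B|
    histogram: dict[int, int]           # difference -> count
    agreement_count: int                # differences equal to 0

    def as_dict(self) -> dict:
        return {
            "differences": self.differences,
            "histogram": {str(k): v for k, v in self.histogram.items()},
            "agreement_count": self.agreement_count,
        }


def compare_reports(totals_a, totals_b) -> ComparisonReport:
    """Per-nodule absolute total differences between two matched raters."""
    a = list(totals_a)
    b = list(totals_b)
    if len(a) != len(b):
        raise ValueError("rater score lists must be matched and equal length")
    diffs = [abs(int(x) - int(y)) for x, y in zip(a, b)]
    hist: dict[int, int] = {}
    for d in diffs:
        hist[d] = hist.get(d, 0) + 1
    return ComparisonReport(
        differences=diffs,
        histogram=dict(sorted(hist.items())),
        agreement_count=hist.get(0, 0),
    )


COMPONENT_COLUMNS = ["composition", "echogenicity", "margin", "shape", "foci"]


def load_bundled_ratings() -> pd.DataFrame:
    """Bundled example table: 24 nodules scored by a robotic scanner and a
    clinician (long format, one row per nodule and rater), with per-nodule
    sizes and printed management recommendations."""
    with resources.files("thyroscan.data").joinpath("nodule_ratings.csv").open() as fh:
        df = pd.read_csv(fh)
    df["total"] = df[COMPONENT_COLUMNS].sum(axis=1)
    return df


def compare_rating_table(df: pd.DataFrame) -> ComparisonReport:
    """ComparisonReport between the two raters of a long-format table."""
    wide = df.pivot(index="nodule", columns="rater", values="total").sort_index()
    raters = list(wide.columns)
    if len(raters) != 2:
        raise ValueError("expected exactly two raters")
    return compare_reports(wide[raters[0]], wide[raters[1]])
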