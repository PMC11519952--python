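"""Synthetic neck phantom and virtual ultrasound probe.

The phantom is a voxel grid of acoustic tissue properties covering one
thyroid lobe and its neighbourhood (strap muscle background, trachea
cartilage, carotid artery).  Axes are ``(z, y, x)``:

- ``z`` — superior–inferior (the in-plane-scan sweep direction), voxels;
- ``y`` — depth below the transducer face (image rows);
- ``x`` — lateral across the neck (image columns).

A :class:`VirtualProbe` selects one transverse slice (fixed ``z``) and a
lateral footprint window; :func:`render_frame` turns the tissue properties
under the footprint into an 8-bit B-mode-like image:

    intensity = coupling(force) * coupling(tilt) * attenuated echogenicity
                * multiplicative speckle,

quantized round-half-up to 8 bits.  The force coupling saturates above the
2 N knee seen on real probes; tilt coupling is maximal at normal incidence
and strictly decreasing in the tilt magnitude.  There is no RF/beamforming
simulation: downstream algorithms consume B-mode images, so the model stops
at the image level.

Nodules are ellipsoids embedded in the gland whose rendered appearance
encodes the ACR TI-RADS axes: a cystic (anechoic) core with a prescribed
in-slice area fraction, an echogenicity offset relative to the gland mean,
an irregular boundary (random radial harmonics), and optional echogenic
foci (punctate spots, one macrocalcification, or a peripheral rim).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

# tissue class codes in TissueMap.labels
BACKGROUND = 0
MUSCLE = 1
CARTILAGE = 2
CAROTID = 3
GLAND = 4

# default tissue acoustics: (echogenicity mean, relative speckle std, attenuation 1/mm)
TISSUE_ACOUSTICS = {
    BACKGROUND: (70.0, 0.25, 0.010),
    MUSCLE: (90.0, 0.25, 0.010),
    CARTILAGE: (35.0, 0.30, 0.045),
    CAROTID: (18.0, 0.35, 0.005),
    GLAND: (120.0, 0.22, 0.012),
}
CYSTIC_ECHO = 8.0  # anechoic fluid
FOCI_ECHO = 245.0  # calcification
NODULE_REL_STD = 0.15  # solid nodule tissue speckles less than parenchyma


@dataclass
class AnatomyConfig:
    """Geometry of the phantom volume and the embedded lobe (all mm).

    The lobe defaults follow CT-derived adult morphometry: height 47.6 mm,
    unilateral width 14.8 mm, thickness 15.2 mm.
    """

    length_mm: float = 64.0          # superior-inferior extent of the grid
    depth_mm: float = 40.0           # axial extent
    width_mm: float = 56.0           # lateral extent
    spacing_mm: float = 0.5          # isotropic voxel size
    lobe_height_mm: float = 47.6
    lobe_width_mm: float = 14.8
    lobe_thickness_mm: float = 15.2
    gland_depth_mm: float = 14.0     # depth of the lobe centre
    gland_lateral_mm: float | None = None  # lateral centre; None = grid centre + 6 mm

    def grid_shape(self) -> tuple[int, int, int]:
        s = self.spacing_mm
        return (
            max(1, round(self.length_mm / s)),
            max(1, round(self.depth_mm / s)),
            max(1, round(self.width_mm / s)),
        )


@dataclass
class NoduleSpecification:
    """Geometric and echographic description of one synthetic nodule."""

    center_mm: tuple[float, float, float]  # (z, y, x)
    width_mm: float                        # lateral diameter
    depth_mm: float                        # axial diameter (aspect = depth/width)
    irregularity: float = 0.0              # boundary amplitude, fraction of radius
    cystic_fraction: float = 0.0           # in-slice anechoic area fraction
    echo_offset: float = -40.0             # gray levels relative to gland mean
    foci_density: float = 0.0              # punctate spots per mm^2 per slice
    foci_pattern: str = "none"             # none | punctate | macro | peripheral
    allow_outside_gland: bool = False

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("nodule width and depth must be positive")
        if not 0.0 <= self.cystic_fraction <= 1.0:
            raise ValueError("cystic_fraction must lie in [0, 1]")
        if self.foci_density < 0:
            raise ValueError("foci_density must be >= 0")
        if self.foci_pattern not in ("none", "punctate", "macro", "peripheral"):
            raise ValueError(f"unknown foci pattern {self.foci_pattern!r}")

    @property
    def aspect_ratio(self) -> float:
        return self.depth_mm / self.width_mm


@dataclass
class TissueMap:
    """Voxelized acoustic properties and anatomical labels."""

    echo_mean: np.ndarray     # float32 (nz, ny, nx), gray levels
    echo_std: np.ndarray      # float32, speckle std in gray levels
    attenuation: np.ndarray   # float32, 1/mm
    labels: np.ndarray        # uint8 tissue class
    nodule_ids: np.ndarray    # uint16, 0 = none, nodule k has id k+1
    spacing_mm: float
    lobe_extent_mm: float
    nodule_specs: tuple[NoduleSpecification, ...] = ()

    def __post_init__(self) -> None:
        if self.echo_mean.ndim != 3 or min(self.echo_mean.shape) == 0:
            raise ValueError("tissue grid must be 3-D and non-empty")
        if self.echo_mean.min() < 0 or self.echo_mean.max() > 255:
            raise ValueError("echogenicity means must lie in [0, 255]")
        if self.attenuation.min() < 0:
            raise ValueError("attenuation must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.echo_mean.shape

    def gland_mask(self) -> np.ndarray:
        return self.labels == GLAND


@dataclass
class VirtualProbe:
    """Pose and acquisition settings of the simulated linear probe."""

    lateral_mm: float = 0.0       # x of the footprint centre
    elevation_mm: float = 0.0     # z of the imaging plane (sweep direction)
    depth_offset_mm: float = 0.0  # y of the transducer face
    tilt_in_deg: float = 0.0      # rotation about the probe long axis
    tilt_out_deg: float = 0.0     # rotation about the image normal
    footprint_mm: float = 40.0    # linear-array width (4.0 cm probe)
    imaging_depth_mm: float = 40.0
    force_n: float = 3.0
    tilt_limit_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.footprint_mm <= 0 or self.imaging_depth_mm <= 0:
            raise ValueError("footprint and imaging depth must be positive")
        if max(abs(self.tilt_in_deg), abs(self.tilt_out_deg)) > self.tilt_limit_deg:
            raise ValueError("tilt outside configured limits")


@dataclass
class USFrame:
    """One rendered 8-bit frame with its ground-truth masks and pose."""

    image: np.ndarray                     # uint8 (rows=depth, cols=lateral)
    spacing_mm: float
    gland_mask: np.ndarray                # bool, same shape
    nodule_masks: dict[int, np.ndarray]   # nodule id -> bool mask
    pose: VirtualProbe
    seed: int
    contact: bool = True

    def __post_init__(self) -> None:
        if self.image.dtype != np.uint8:
            raise ValueError("frame image must be uint8")
        if self.gland_mask.shape != self.image.shape:
            raise ValueError("masks must share the image shape")


@dataclass
class Panorama:
    """Laterally stitched composite of overlapping frames."""

    image: np.ndarray           # uint8
    goal_position_px: int       # lateral offset of the goal frame
    window_width_px: int
    provenance: np.ndarray      # int, per-column dominant source-frame index
    offsets_px: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.goal_position_px + self.window_width_px > self.image.shape[1]:
            raise ValueError("goal window exceeds panorama width")
        if self.provenance.shape[0] != self.image.shape[1]:
            raise ValueError("provenance must cover every column")


class NoContactError(RuntimeError):
    """Probe footprint does not intersect the tissue grid."""


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _ellipsoid_radius(zz, yy, xx, center, semi):
    """Normalized ellipsoidal radius field (1.0 on the surface)."""
    cz, cy, cx = center
    az, ay, ax = semi
    return np.sqrt(((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)


def generate_phantom(
    config: AnatomyConfig,
    nodules: list[NoduleSpecification] | tuple[NoduleSpecification, ...] = (),
    seed: int = 0,
) -> TissueMap:
    """Build a :class:`TissueMap` with the requested nodules.

    Deterministic for a fixed seed.  A nodule whose ellipsoid is not fully
    contained in the gland is rejected unless its spec sets
    ``allow_outside_gland``.
    """
    nz, ny, nx = config.grid_shape()
    s = config.spacing_mm
    rng = np.random.default_rng(seed)

    zz, yy, xx = np.meshgrid(
        (np.arange(nz) + 0.5) * s,
        (np.arange(ny) + 0.5) * s,
        (np.arange(nx) + 0.5) * s,
        indexing="ij",
    )
    labels = np.full((nz, ny, nx), MUSCLE, dtype=np.uint8)

    # trachea cartilage: medial dark tube along z at the left edge
    trachea_x = 6.0
    r_tr = np.sqrt((yy - 16.0) ** 2 + (xx - trachea_x) ** 2)
    labels[r_tr < 7.0] = CARTILAGE

    # carotid: lateral anechoic vessel along z
    carotid_x = config.width_mm - 10.0
    r_ca = np.sqrt((yy - 18.0) ** 2 + (xx - carotid_x) ** 2)
    labels[r_ca < 3.0] = CAROTID

    gx = (
        config.gland_lateral_mm
        if config.gland_lateral_mm is not None
        else config.width_mm / 2 + 6.0
    )
    gland_center = (config.length_mm / 2, config.gland_depth_mm, gx)
    gland_semi = (
        config.lobe_height_mm / 2,
        config.lobe_thickness_mm / 2,
        config.lobe_width_mm / 2,
    )
    r_gl = _ellipsoid_radius(zz, yy, xx, gland_center, gland_semi)
    labels[r_gl < 1.0] = GLAND
    gland = labels == GLAND

    echo = np.empty((nz, ny, nx), dtype=np.float32)
    std = np.empty_like(echo)
    atten = np.empty_like(echo)
    for code, (mu, rel, att) in TISSUE_ACOUSTICS.items():
        sel = labels == code
        echo[sel] = mu
        std[sel] = mu * rel
        atten[sel] = att

    gland_mu = TISSUE_ACOUSTICS[GLAND][0]
    gland_rel = TISSUE_ACOUSTICS[GLAND][1]
    nodule_ids = np.zeros((nz, ny, nx), dtype=np.uint16)

    for k, spec in enumerate(nodules):
        nid = k + 1
        az = spec.width_mm / 2  # superior-inferior extent follows the width
        ay = spec.depth_mm / 2
        ax = spec.width_mm / 2
        r = _ellipsoid_radius(zz, yy, xx, spec.center_mm, (az, ay, ax))
        # irregular boundary: radial modulation by random in-plane harmonics
        if spec.irregularity > 0:
            phi = np.arctan2(yy - spec.center_mm[1], xx - spec.center_mm[2])
            n_harm = int(rng.integers(4, 7))
            phase = rng.uniform(0, 2 * np.pi, n_harm)
            mod = np.zeros_like(phi)
            for h, ph in enumerate(phase):
                mod += np.cos((h + 3) * phi + ph)
            mod *= spec.irregularity / np.max(np.abs(mod))
            r = r / (1.0 + mod)
        inside = r < 1.0
        if not spec.allow_outside_gland and np.any(inside & ~gland):
            raise ValueError(
                f"nodule {nid} extends outside the gland; set "
                "allow_outside_gland=True to embed it anyway"
            )
        nodule_ids[inside] = nid

        # in-plane normalized radius controls the anechoic core and the rim
        rho = np.where(inside, r, np.inf)
        solid_echo = float(np.clip(gland_mu + spec.echo_offset, 0, 255))
        echo[inside] = solid_echo
        std[inside] = solid_echo * NODULE_REL_STD
        if spec.cystic_fraction > 0:
            core = inside & (rho < np.sqrt(spec.cystic_fraction))
            echo[core] = CYSTIC_ECHO
            std[core] = CYSTIC_ECHO * 0.4
        if spec.foci_pattern == "peripheral":
            rim = inside & (rho > 0.80)
            echo[rim] = FOCI_ECHO
            std[rim] = FOCI_ECHO * 0.05
        elif spec.foci_pattern == "macro":
            blob = _ellipsoid_radius(
                zz, yy, xx, spec.center_mm, (1.6, 1.6, 1.6)
            ) < 1.0
            blob &= inside
            echo[blob] = FOCI_ECHO
            std[blob] = FOCI_ECHO * 0.05
        elif spec.foci_pattern == "punctate":
            density = spec.foci_density if spec.foci_density > 0 else 0.08
            z_idx, y_idx, x_idx = np.nonzero(inside)
            slices = np.unique(z_idx)
            area_mm2 = inside.sum(axis=(1, 2)) * s * s
            for zi in slices:
                n_spots = rng.poisson(density * area_mm2[zi])
                if n_spots == 0:
                    continue
                in_slice = np.nonzero(z_idx == zi)[0]
                pick = rng.choice(in_slice, size=min(n_spots, in_slice.size), replace=False)
                for p in pick:
                    yc, xc = y_idx[p], x_idx[p]
                    echo[zi, yc : yc + 2, xc : xc + 2] = FOCI_ECHO
                    std[zi, yc : yc + 2, xc : xc + 2] = FOCI_ECHO * 0.05

    np.clip(echo, 0, 255, out=echo)
    return TissueMap(
        echo_mean=echo,
        echo_std=std,
        attenuation=atten,
        labels=labels,
        nodule_ids=nodule_ids,
        spacing_mm=s,
        lobe_extent_mm=config.lobe_height_mm,
        nodule_specs=tuple(nodules),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def force_coupling(force_n: float, knee_n: float = 2.0) -> float:
    """Acoustic coupling gain vs contact force: linear up to the knee, then flat."""
    return float(min(max(force_n, 0.0) / knee_n, 1.0))


def tilt_coupling(tilt_in_deg: float, tilt_out_deg: float, width_deg: float = 8.0) -> float:
    """Coupling gain vs probe tilt: Gaussian in the total tilt magnitude."""
    t2 = tilt_in_deg**2 + tilt_out_deg**2
    return float(np.exp(-t2 / (2.0 * width_deg**2)))


def render_frame(tissue: TissueMap, probe: VirtualProbe, seed: int = 0) -> USFrame:
    """Render one transverse B-mode-like frame under the probe footprint.

    Lateral columns outside the tissue grid are padded with background; a
    footprint entirely off the grid raises :class:`NoContactError` unless the
    probe force is zero, in which case an all-dark "no contact" frame is
    returned.
    """
    s = tissue.spacing_mm
    nz, ny, nx = tissue.shape
    zi = int(round(probe.elevation_mm / s - 0.5))
    half = probe.footprint_mm / 2
    x0 = int(round((probe.lateral_mm - half) / s))
    n_cols = max(1, int(round(probe.footprint_mm / s)))
    n_rows = max(1, min(ny, int(round(probe.imaging_depth_mm / s))))

    if zi < 0 or zi >= nz or x0 + n_cols <= 0 or x0 >= nx:
        img = np.zeros((n_rows, n_cols), dtype=np.uint8)
        empty = np.zeros((n_rows, n_cols), dtype=bool)
        return USFrame(img, s, empty, {}, replace(probe), seed, contact=False)

    def window(vol: np.ndarray, fill) -> np.ndarray:
        out = np.full((n_rows, n_cols), fill, dtype=vol.dtype)
        c0, c1 = max(0, x0), min(nx, x0 + n_cols)
        out[:, c0 - x0 : c1 - x0] = vol[zi, :n_rows, c0:c1]
        return out

    echo = window(tissue.echo_mean, TISSUE_ACOUSTICS[BACKGROUND][0])
    std = window(tissue.echo_std, TISSUE_ACOUSTICS[BACKGROUND][0] * 0.25)
    atten = window(tissue.attenuation, TISSUE_ACOUSTICS[BACKGROUND][2])
    labels = window(tissue.labels, np.uint8(BACKGROUND))
    nids = window(tissue.nodule_ids, np.uint16(0))

    # two-way depth attenuation of the echo amplitude
    depth_path = np.cumsum(atten, axis=0) * s
    transmission = np.exp(-2.0 * depth_path)

    # a tilted probe lifts one footprint edge: the lifted side loses contact
    # and its signal drops out with depth, not just in overall gain
    tilt_mag = abs(probe.tilt_in_deg) + abs(probe.tilt_out_deg)
    if tilt_mag > 0:
        deficit = min(tilt_mag / 15.0, 1.0)
        ramp = np.linspace(0.0, 1.0, n_cols)
        if probe.tilt_in_deg < 0:
            ramp = ramp[::-1]
        extra = 0.25 * deficit * ramp[None, :]  # 1/mm in the lifted columns
        depth_mm = ((np.arange(n_rows) + 0.5) * s)[:, None]
        transmission = transmission * np.exp(-2.0 * extra * depth_mm)

    gain = force_coupling(probe.force_n) * tilt_coupling(
        probe.tilt_in_deg, probe.tilt_out_deg
    )

    rng = np.random.default_rng(seed)
    rel = np.clip(std / np.maximum(echo, 1e-6), 1e-3, 1.0)
    shape = 1.0 / rel**2  # unit-mean gamma speckle with the requested std
    speckle = rng.gamma(shape, 1.0 / shape)

    intensity = echo * transmission * gain * speckle
    img = np.floor(np.clip(intensity, 0, 255) + 0.5).astype(np.uint8)  # round half up

    gland_mask = labels == GLAND
    nodule_masks = {
        int(i): nids == i for i in np.unique(nids) if i != 0
    }
    return USFrame(img, s, gland_mask, nodule_masks, replace(probe), seed)


def apply_shadow_mask(frame: USFrame, severity: float, seed: int = 0) -> USFrame:
    """Attenuate random vertical bands, mimicking partial probe contact.

    ``severity`` 0 returns a bitwise-identical copy; 1 shadows roughly a
    third of the width.  Seeded and deterministic.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    img = frame.image.copy()
    if severity > 0:
        rng = np.random.default_rng(seed)
        w = img.shape[1]
        n_bands = 1 + rng.integers(0, 3)
        total = severity * w / 3
        for _ in range(int(n_bands)):
            bw = max(2, int(total / n_bands))
            start = int(rng.integers(0, max(1, w - bw)))
            fade = rng.uniform(0.05, 0.25)
            img[:, start : start + bw] = np.floor(
                img[:, start : start + bw] * fade + 0.5
            ).astype(np.uint8)
    return USFrame(
        img,
        frame.spacing_mm,
        frame.gland_mask.copy(),
        {k: v.copy() for k, v in frame.nodule_masks.items()},
        replace(frame.pose),
        seed,
        contact=frame.contact,
    )


# ---------------------------------------------------------------------------
# panorama stitching
# ---------------------------------------------------------------------------

def _lateral_shift(a: np.ndarray, b: np.ndarray, min_overlap: int = 8) -> tuple[int, float]:
    """Estimated lateral shift of ``b`` relative to ``a`` by 1-D NCC.

    Correlates the column-mean profiles over all shifts that leave at least
    ``min_overlap`` columns of overlap.  Ties on the correlation peak are
    broken toward the smallest \\|shift\\|.
    """
    pa = a.mean(axis=0).astype(np.float64)
    pb = b.mean(axis=0).astype(np.float64)
    best = (0, -np.inf)
    for shift in range(-(pb.size - min_overlap), pa.size - min_overlap + 1):
        lo_a, hi_a = max(0, shift), min(pa.size, shift + pb.size)
        seg_a = pa[lo_a:hi_a]
        seg_b = pb[lo_a - shift : hi_a - shift]
        if seg_a.size < min_overlap:
            continue
        da = seg_a - seg_a.mean()
        db = seg_b - seg_b.mean()
        denom = np.sqrt((da**2).sum() * (db**2).sum())
        corr = 1.0 if denom == 0 else float((da * db).sum() / denom)
        if corr > best[1] + 1e-12 or (
            abs(corr - best[1]) <= 1e-12 and abs(shift) < abs(best[0])
        ):
            best = (shift, corr)
    return best


def build_panorama(
    frames: list[USFrame] | list[np.ndarray],
    goal_index: int,
    corr_threshold: float = 0.2,
) -> Panorama:
    """Stitch laterally overlapping frames into a panorama.

    Pairwise shifts come from 1-D normalized cross-correlation of the
    column-mean profiles; overlaps are blended with linear feathering.  The
    goal window is recorded at the lateral offset of ``frames[goal_index]``.
    """
    imgs = [f.image if isinstance(f, USFrame) else np.asarray(f) for f in frames]
    if len(imgs) < 2:
        raise ValueError("panorama needs at least two frames")
    if not 0 <= goal_index < len(imgs):
        raise ValueError("goal index out of range")

    offsets = [0]
    for a, b in zip(imgs[:-1], imgs[1:]):
        shift, corr = _lateral_shift(a, b)
        if corr < corr_threshold:
            raise ValueError(
                f"no lateral overlap detected (peak correlation {corr:.3f} "
                f"< threshold {corr_threshold})"
            )
        offsets.append(offsets[-1] + shift)
    base = -min(offsets)
    offsets = [o + base for o in offsets]

    height = imgs[0].shape[0]
    width = max(o + im.shape[1] for o, im in zip(offsets, imgs))
    acc = np.zeros((height, width), dtype=np.float64)
    wacc = np.zeros(width, dtype=np.float64)
    prov_w = np.zeros((len(imgs), width), dtype=np.float64)
    for i, (o, im) in enumerate(zip(offsets, imgs)):
        w = im.shape[1]
        feather = np.minimum(np.arange(1, w + 1), np.arange(w, 0, -1)).astype(float)
        acc[:, o : o + w] += im * feather
        wacc[o : o + w] += feather
        prov_w[i, o : o + w] = feather
    pano = np.floor(acc / np.maximum(wacc, 1e-12) + 0.5).astype(np.uint8)
    provenance = prov_w.argmax(axis=0)

    return Panorama(
        image=pano,
        goal_position_px=int(offsets[goal_index]),
        window_width_px=int(imgs[goal_index].shape[1]),
        provenance=provenance,
        offsets_px=tuple(int(o) for o in offsets),
    )


# ---------------------------------------------------------------------------
# helpers for downstream modules
# ---------------------------------------------------------------------------

def downsample(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Area-style resize to ``shape`` preserving the 0–255 range (float64)."""
    return resize(image.astype(np.float64), shape, order=1, anti_aliasing=True,
                  preserve_range=True)


def single_nodule_phantom(
    spec: NoduleSpecification | None = None, seed: int = 0, **anatomy_kwargs
) -> TissueMap:
    """Convenience: a default-anatomy phantom with zero or one nodule."""
    config = AnatomyConfig(**anatomy_kwargs)
    if spec is None:
        return generate_phantom(config, (), seed)
    return generate_phantom(config, (spec,), seed)


def default_nodule(center: tuple[float, float, float] | None = None, **kwargs) -> NoduleSpecification:
    """A solid, mildly hypoechoic, wider-than-tall nodule at the lobe centre."""
    config = AnatomyConfig()
    if center is None:
        gx = config.width_mm / 2 + 6.0
        center = (config.length_mm / 2, config.gland_depth_mm, gx)
    defaults = dict(center_mm=center, width_mm=8.0, depth_mm=6.0)
    defaults.update(kwargs)
    return NoduleSpecification(**defaults)
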