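"""Image-quality metrics for B-mode frames.

Four metrics characterize a frame during scanning: Shannon entropy of the
gray histogram (texture richness, the orientation-optimization objective),
a random-walk confidence map (per-pixel acoustic-coupling reliability),
the centering error of the gland in the lateral direction, and the probe
orientation error against a reference surface normal.  LRIS (left-right
intensity symmetry) summarizes the lateral gray-level balance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve


class GlandNotVisibleError(ValueError):
    """The gland mask is empty: the metric is undefined, not zero."""


@dataclass
class ConfidenceParams:
    """Random-walk confidence-map parameters.

    ``alpha`` is the depth-attenuation exponent applied to the
    contrast-normalized intensities before edge weights are formed,
    ``beta`` the sensitivity of the weights to intensity differences, and
    ``gamma`` a constant penalty on horizontal (across-beam) edges.
    Intensities are normalized by the image mean so the map responds to
    structure (shadows, dropout) rather than to overall gain.  The
    underlying random-walk formulation publishes no values for this probe,
    so the defaults here are the package's own.
    """

    alpha: float = 2.0
    beta: float = 9.0
    gamma: float = 0.06


@dataclass
class QualityReport:
    """Per-frame quality summary."""

    entropy_bits: float
    mean_confidence: float
    centering_error: float | None
    orientation_error_deg: float
    lris: float

    def as_dict(self) -> dict:
        return asdict(self)


def image_entropy(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin gray histogram.

    Exactly 256 integer-level bins, base-2 logarithm, with 0*log(0) := 0.
    Bounded by 8 bits for 8-bit data.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(img.astype(np.uint8).ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def confidence_map(image: np.ndarray, params: ConfidenceParams | None = None) -> np.ndarray:
    """Random-walk confidence of each pixel's acoustic path to the transducer.

    Solves the graph-Laplacian Dirichlet problem on the 4-connected pixel
    lattice with the top row (transducer face) fixed to 1 and the bottom row
    to 0.  Edge weights decay exponentially with the difference of
    depth-attenuated normalized intensities; horizontal edges carry an extra
    constant penalty so confidence is transported predominantly along the
    beam direction.  Returns values clipped to [0, 1].
    """
    params = params or ConfidenceParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 1:
        raise ValueError("confidence map needs a 2-D image with >= 3 rows")
    h, w = img.shape

    depth = np.linspace(0.0, 1.0, h)[:, None]
    g = (img / max(img.mean(), 1e-9)) * np.exp(-params.alpha * depth)

    idx = np.arange(h * w).reshape(h, w)
    wv = np.exp(-params.beta * np.abs(g[:-1, :] - g[1:, :])) + 1e-9
    wh = np.exp(-params.beta * (np.abs(g[:, :-1] - g[:, 1:]) + params.gamma)) + 1e-9

    a_idx = np.concatenate([idx[:-1, :].ravel(), idx[:, :-1].ravel()])
    b_idx = np.concatenate([idx[1:, :].ravel(), idx[:, 1:].ravel()])
    weights = np.concatenate([wv.ravel(), wh.ravel()])
    rows = np.concatenate([a_idx, b_idx])
    cols = np.concatenate([b_idx, a_idx])
    vals = np.concatenate([-weights, -weights])

    n = h * w
    lap = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    diag = -np.asarray(lap.sum(axis=1)).ravel()
    lap = lap + coo_matrix((diag, (np.arange(n), np.arange(n))), shape=(n, n))

    boundary = np.zeros(n, dtype=bool)
    top, bottom = idx[0, :], idx[-1, :]
    boundary[top] = True
    boundary[bottom] = True
    x_b = np.zeros(n)
    x_b[top] = 1.0

    free = ~boundary
    lap_csr = lap.tocsr()
    a = lap_csr[free][:, free]
    b = -lap_csr[free][:, boundary] @ x_b[boundary]
    x = np.zeros(n)
    x[boundary] = x_b[boundary]
    x[free] = spsolve(a.tocsc(), b)
    return np.clip(x.reshape(h, w), 0.0, 1.0)


def centering_error(gland_mask: np.ndarray, frame_width: int | None = None) -> float:
    """Signed lateral offset of the gland centroid, as a fraction of half-width.

    Negative means the gland sits left of the image centre.  Raises
    :class:`GlandNotVisibleError` on an empty mask — "not visible" is a
    distinct state, not a zero error.
    """
    mask = np.asarray(gland_mask, dtype=bool)
    width = frame_width if frame_width is not None else mask.shape[1]
    if not mask.any():
        raise GlandNotVisibleError("gland not visible: empty mask")
    centroid_col = np.nonzero(mask)[1].mean()
    center_col = (width - 1) / 2.0
    return float((centroid_col - center_col) / (width / 2.0))


def lris(image: np.ndarray) -> float:
    """Left-right intensity symmetry: mean(left half) / mean(right half).

    The middle column of an odd-width image belongs to neither half.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[1] < 2:
        raise ValueError("lris needs a 2-D image with width >= 2")
    half = img.shape[1] // 2
    left = img[:, :half].mean()
    right = img[:, img.shape[1] - half :].mean()
    if right == 0:
        raise ZeroDivisionError("right-half mean intensity is zero; LRIS undefined")
    return float(left / right)


def orientation_error(probe_axis: np.ndarray, reference_normal: np.ndarray) -> float:
    """Angle (degrees, in [0, 180]) between the probe axis and a reference normal.

    The reference direction is an explicit parameter: callers may pass a
    pre-operative estimate or the local surface normal.
    """
    a = np.asarray(probe_axis, dtype=np.float64)
    b = np.asarray(reference_normal, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    cosang = np.clip(np.dot(a / na, b / nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def tilt_to_axis(tilt_in_deg: float, tilt_out_deg: float) -> np.ndarray:
    """Unit probe-axis vector for small in-/out-of-plane tilts about +y."""
    ti, to = np.radians(tilt_in_deg), np.radians(tilt_out_deg)
    v = np.array([np.sin(to), np.cos(ti) * np.cos(to), np.sin(ti) * np.cos(to)])
    return v / np.linalg.norm(v)


def report(
    image: np.ndarray,
    gland_mask: np.ndarray | None = None,
    probe_axis: np.ndarray | None = None,
    reference_normal: np.ndarray | None = None,
    confidence_params: ConfidenceParams | None = None,
    confidence_shape: tuple[int, int] | None = (32, 32),
) -> QualityReport:
    """Compute the full :class:`QualityReport` for one frame.

    The confidence map is solved on a downsampled copy (default 32x32) —
    the mean confidence is insensitive to this and it keeps per-tick logging
    cheap.  Pass ``confidence_shape=None`` to solve at full resolution.
    """
    from .phantom import downsample

    cimg = image if confidence_shape is None else downsample(image, confidence_shape)
    conf = confidence_map(cimg, confidence_params)
    try:
        cen = centering_error(gland_mask) if gland_mask is not None else None
    except GlandNotVisibleError:
        cen = None
    if probe_axis is not None and reference_normal is not None:
        oerr = orientation_error(probe_axis, reference_normal)
    else:
        oerr = 0.0
    return QualityReport(
        entropy_bits=image_entropy(image),
        mean_confidence=float(conf.mean()),
        centering_error=cen,
        orientation_error_deg=oerr,
        lris=lris(image),
    )
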