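"""Hand-crafted descriptors of a segmented rosette frame.

The battery concatenates, in a fixed layout of 1056 values:

* ``color[12]`` — mean/max/min of R, G, B over foreground pixels (9) and the
  mean of H, S, V over the same pixels (3; H, S, V on the [0, 1] scale);
* ``shape[8]`` — area (px), perimeter (px), roundness = area/perimeter,
  compactness = area/convex-hull area, eccentricity = hull major/minor axis
  ratio (>= 1), the major and minor axis lengths of the ellipse with the same
  second moments as the region, and extent = area/bounding-box area;
* ``fourier[1024]`` — the outer contour of the largest connected component
  resampled to 512 equally spaced points as complex x+iy, Fourier transformed,
  DC term zeroed for translation invariance; 512 real parts then 512
  imaginary parts;
* ``glcm[12]`` — Energy, Contrast, Homogeneity of the foreground-restricted
  gray-level co-occurrence matrix at distance 1 in the four directions 0,
  45, 90, 135 degrees (direction-major order).

Note the roundness and eccentricity definitions are the ratio forms above,
not the dimensionless isoperimetric quotient / conic eccentricity;
``shape_stats`` offers the conventional roundness behind a flag.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv, rgb2gray
from skimage.measure import find_contours, label, regionprops

__all__ = [
    "COLOR_LEN", "SHAPE_LEN", "FOURIER_LEN", "GLCM_LEN", "FEATURE_LEN",
    "GLCM_DIRECTIONS",
    "color_stats", "shape_stats", "fourier_descriptors", "glcm_features",
    "extract_features", "feature_names",
]

COLOR_LEN = 12
SHAPE_LEN = 8
FOURIER_LEN = 1024
GLCM_LEN = 12
FEATURE_LEN = COLOR_LEN + SHAPE_LEN + FOURIER_LEN + GLCM_LEN

N_CONTOUR_POINTS = FOURIER_LEN // 2

#: (row, col) offsets for the four GLCM directions 0, 45, 90, 135 degrees
GLCM_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _check_mask(mask: np.ndarray, minimum: int = 1) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if m.sum() < minimum:
        raise ValueError(f"mask needs >= {minimum} foreground pixels")
    return m


def color_stats(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean/max/min RGB and mean HSV over foreground pixels (12 values)."""
    m = _check_mask(mask)
    rgb = np.asarray(rgb)
    px = rgb[m].astype(np.float64)
    hsv = rgb2hsv(px.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
    return np.concatenate([
        px.mean(axis=0), px.max(axis=0), px.min(axis=0), hsv.mean(axis=0)])


def shape_stats(mask: np.ndarray, conventional_roundness: bool = False) -> np.ndarray:
    """Region morphometrics of the (possibly disconnected) foreground (8 values).

    Area counts all foreground pixels.  Convex hull, second-moment ellipse and
    bounding box are taken over the union of components.  Raises on degenerate
    (fewer than 3 px, or collinear) regions where the hull has no area.
    """
    m = _check_mask(mask, minimum=3)
    props = regionprops(m.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    hull_area = float(props.area_convex)
    if hull_area <= 0 or props.axis_minor_length <= 0:
        raise ValueError("degenerate (collinear) region")
    if perimeter <= 0:
        raise ValueError("region has no measurable boundary")
    roundness = (4.0 * np.pi * area / perimeter**2) if conventional_roundness \
        else (area / perimeter)
    hull_props = regionprops(props.image_convex.astype(np.uint8))[0]
    eccentricity = hull_props.axis_major_length / hull_props.axis_minor_length
    extent = float(props.extent)
    return np.array([
        area, perimeter, roundness, area / hull_area, eccentricity,
        float(props.axis_major_length), float(props.axis_minor_length), extent,
    ])


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Closed outer contour (n, 2) of the largest connected component."""
    lab = label(mask)
    if lab.max() == 0:
        raise ValueError("empty mask has no contour")
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    comp = np.pad(lab == largest, 1)  # pad so boundary components close
    contours = find_contours(comp.astype(float), 0.5)
    contour = max(contours, key=len)
    return contour - 1.0  # undo padding offset


def _resample_closed(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced by arc length."""
    pts = contour
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("contour has zero length")
    t = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(t, s, pts[:, 0])
    cols = np.interp(t, s, pts[:, 1])
    return np.stack([rows, cols], axis=1)


def fourier_descriptors(mask: np.ndarray) -> np.ndarray:
    """Translation-invariant Fourier contour descriptor (1024 values).

    The outer contour is resampled to 512 points, read as complex x+iy
    (x = column, y = row), Fourier transformed, and the zero-frequency term is
    set to zero so that a pure translation of the shape leaves the descriptor
    unchanged.  Output is 512 real components followed by 512 imaginary ones.
    """
    m = _check_mask(mask)
    pts = _resample_closed(_outer_contour(m), N_CONTOUR_POINTS)
    z = pts[:, 1] + 1j * pts[:, 0]
    spec = np.fft.fft(z)
    spec[0] = 0.0
    return np.concatenate([spec.real, spec.imag])


def glcm_features(gray: np.ndarray, mask: np.ndarray, levels: int = 32) -> np.ndarray:
    """Energy, Contrast, Homogeneity of masked GLCMs in 4 directions (12 values).

    Foreground gray values are quantised to ``levels`` bins over their own
    range (so the descriptor is invariant to affine gray rescaling); one
    co-occurrence matrix per direction at offset distance 1 counts only pixel
    pairs that are BOTH foreground; matrices are symmetrised and normalised to
    sum 1.  Order: [Energy, Contrast, Homogeneity] for 0, 45, 90, 135 degrees.
    """
    m = _check_mask(mask, minimum=2)
    g = np.asarray(gray, dtype=np.float64)
    if g.shape != m.shape:
        raise ValueError("gray image and mask must share shape")
    fg = g[m]
    lo, hi = fg.min(), fg.max()
    if hi > lo:
        q = np.clip(((g - lo) / (hi - lo) * levels).astype(np.int64), 0, levels - 1)
    else:
        q = np.zeros_like(g, dtype=np.int64)

    i_idx, j_idx = np.indices(m.shape)
    out = []
    lev = np.arange(levels)
    diff_sq = (lev[:, None] - lev[None, :]) ** 2
    homog_w = 1.0 / (1.0 + np.abs(lev[:, None] - lev[None, :]))
    any_pairs = False
    for dr, dc in GLCM_DIRECTIONS:
        src_r = i_idx[max(0, -dr): m.shape[0] - max(0, dr),
                      max(0, -dc): m.shape[1] - max(0, dc)]
        src_c = j_idx[max(0, -dr): m.shape[0] - max(0, dr),
                      max(0, -dc): m.shape[1] - max(0, dc)]
        dst_r, dst_c = src_r + dr, src_c + dc
        valid = m[src_r, src_c] & m[dst_r, dst_c]
        a = q[src_r, src_c][valid]
        b = q[dst_r, dst_c][valid]
        counts = np.bincount(a * levels + b, minlength=levels * levels)
        glcm = counts.reshape(levels, levels).astype(np.float64)
        glcm = glcm + glcm.T
        total = glcm.sum()
        if total == 0:
            out.extend([0.0, 0.0, 0.0])
            continue
        any_pairs = True
        p = glcm / total
        out.extend([
            float((p ** 2).sum()),
            float((diff_sq * p).sum()),
            float((homog_w * p).sum()),
        ])
    if not any_pairs:
        raise ValueError("mask has no valid co-occurrence pairs in any direction")
    return np.array(out)


def extract_features(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Full 1056-element handcrafted descriptor of one segmented frame."""
    rgb = np.asarray(rgb)
    gray = rgb2gray(rgb) * 255.0
    return np.concatenate([
        color_stats(rgb, mask),
        shape_stats(mask),
        fourier_descriptors(mask),
        glcm_features(gray, mask),
    ])


def feature_names() -> list[str]:
    """Column names matching the :func:`extract_features` layout."""
    names = [f"{s}_{c}" for s in ("mean", "max", "min") for c in "RGB"]
    names += ["mean_H", "mean_S", "mean_V"]
    names += ["area", "perimeter", "roundness", "compactness", "eccentricity",
              "ellipse_major", "ellipse_minor", "extent"]
    names += [f"fourier_re_{k}" for k in range(N_CONTOUR_POINTS)]
    names += [f"fourier_im_{k}" for k in range(N_CONTOUR_POINTS)]
    names += [f"glcm_{p}_{d}" for d in (0, 45, 90, 135)
              for p in ("energy", "contrast", "homogeneity")]
    assert len(names) == FEATURE_LEN
    return names
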