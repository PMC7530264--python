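"""Traditional texture descriptors: GLCM/Haralick, LBP, Hu moments.

These are the classical "hand-crafted" counterparts to deep feature
extraction. All three operate on the 8-bit heat-map image as a whole:

* the gray-level co-occurrence matrix (GLCM) with the 14 Haralick
  statistics, including the angular second moment ``sum_ij p(i,j)^2``
  and entropy ``-sum_ij p(i,j) log p(i,j)`` (entropies in bits);
* multiscale local binary patterns (LBP): per-pixel codes
  ``sum_p f(g_p - g_c) 2^p`` with the sign convention ``f(x) = 1`` for
  ``x >= 0``, histogrammed per neighborhood (default P=8 at radii
  1, 2, 3 with 16 bins each -> 48 features);
* Hu's seven moment invariants from normalized central moments
  ``eta_pq = mu_pq / mu_00^alpha``. The scale-normalizing exponent is
  ``alpha = (p+q)/2 + 1`` (the value that actually yields scale
  invariance); the truncated variant ``alpha = (p+q)/2`` sometimes seen
  in print is available via ``exponent="printed"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, FeatureVector, HeatmapImage

#: Default GLCM offsets: distance 1 at 0, 45, 90 and 135 degrees
#: (rows increase downward, so "up" is a negative row offset).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

HARALICK_NAMES: tuple[str, ...] = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_correlation_1",
    "info_measure_correlation_2",
    "maximal_correlation_coefficient",
)


def _as_pixel_array(image) -> np.ndarray:
    if isinstance(image, HeatmapImage):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ConfigurationError("image must be a non-empty 2-D array")
    if arr.min() < 0 or arr.max() > 255:
        raise ConfigurationError("image values must lie in [0, 255]")
    return arr


@dataclass
class CooccurrenceMatrix:
    """Normalized joint distribution of gray-level pairs at given offsets."""

    p: np.ndarray
    offsets: tuple[tuple[int, int], ...]
    levels: int
    symmetric: bool

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.levels, self.levels):
            raise ConfigurationError(
                f"co-occurrence matrix must be {self.levels}x{self.levels}"
            )
        if (self.p < 0).any():
            raise ConfigurationError("co-occurrence entries must be nonnegative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("normalized co-occurrence matrix must sum to 1")
        if self.symmetric and not np.allclose(self.p, self.p.T, atol=1e-12):
            raise ConfigurationError("symmetric flag set but matrix is not symmetric")


def compute_glcm(
    image,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = 256,
    symmetric: bool = True,
    normalize: bool = True,
) -> CooccurrenceMatrix:
    """Count gray-level pairs at each offset, summed over offsets.

    Image values are binned uniformly from [0, 255] to ``levels`` gray
    levels. ``symmetric`` adds the transposed counts (each pair counted
    in both directions); ``normalize`` scales counts to sum to 1.
    """
    arr = _as_pixel_array(image)
    if not 2 <= levels <= 256:
        raise ConfigurationError("levels must be in [2, 256]")
    binned = (arr.astype(np.int64) * levels) // 256
    np.minimum(binned, levels - 1, out=binned)
    h, w = binned.shape
    counts = np.zeros((levels, levels), dtype=float)
    for dr, dc in offsets:
        if abs(dr) >= h or abs(dc) >= w:
            raise ConfigurationError(
                f"offset ({dr}, {dc}) exceeds image extent {h}x{w}"
            )
        # source window and its displaced partner
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = binned[r0:r1, c0:c1].ravel()
        dst = binned[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        pair_counts = np.bincount(src * levels + dst, minlength=levels * levels)
        counts += pair_counts.reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ConfigurationError("no valid pixel pairs for the given offsets")
    if normalize:
        counts = counts / total
    return CooccurrenceMatrix(p=counts, offsets=tuple(offsets), levels=levels,
                              symmetric=symmetric)


def _xlog2(v: np.ndarray) -> np.ndarray:
    """v * log2(v) with the 0 * log 0 = 0 convention."""
    out = np.zeros_like(v, dtype=float)
    nz = v > 0
    out[nz] = v[nz] * np.log2(v[nz])
    return out


def asm(p: CooccurrenceMatrix) -> float:
    """Angular second moment: sum of squared entries (textural uniformity)."""
    return float(np.sum(p.p**2))


def glcm_entropy(p: CooccurrenceMatrix) -> float:
    """Co-occurrence entropy in bits."""
    return float(-np.sum(_xlog2(p.p)))


def haralick_features(p: CooccurrenceMatrix) -> FeatureVector:
    """The 14 Haralick statistics of a normalized co-occurrence matrix.

    Order and naming follow :data:`HARALICK_NAMES`. Entropy terms use
    base-2 logarithms. Degenerate denominators (zero variance marginals,
    zero marginal entropies, undefined second eigenvalue) yield 0. The
    sum-variance statistic is taken about the sum average (the customary
    reading of its definition).
    """
    P = p.p
    n = p.levels
    idx = np.arange(n, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sd_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))

    i_grid, j_grid = np.meshgrid(idx, idx, indexing="ij")
    diff = i_grid - j_grid

    # distributions of i+j (0..2n-2) and |i-j| (0..n-1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (i_grid + j_grid).astype(int), P)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(diff).astype(int), P)
    k_sum = np.arange(2 * n - 1, dtype=float)
    k_diff = idx

    f1 = float(np.sum(P**2))
    f2 = float((k_diff**2) @ p_diff)
    if sd_x > 0 and sd_y > 0:
        f3 = float((np.sum(i_grid * j_grid * P) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        f3 = 0.0
    f4 = float(np.sum(((i_grid - mu_x) ** 2) * P))
    f5 = float(np.sum(P / (1.0 + diff**2)))
    f6 = float(k_sum @ p_sum)
    f7 = float(((k_sum - f6) ** 2) @ p_sum)
    f8 = float(-np.sum(_xlog2(p_sum)))
    f9 = float(-np.sum(_xlog2(P)))
    mu_diff = float(k_diff @ p_diff)
    f10 = float(((k_diff - mu_diff) ** 2) @ p_diff)
    f11 = float(-np.sum(_xlog2(p_diff)))

    # information measures of correlation
    hx = float(-np.sum(_xlog2(px)))
    hy = float(-np.sum(_xlog2(py)))
    outer = np.outer(px, py)
    log_outer = np.zeros_like(outer)
    nz = outer > 0
    log_outer[nz] = np.log2(outer[nz])
    hxy1 = float(-np.sum(P * log_outer))
    hxy2 = float(-np.sum(_xlog2(outer)))
    denom = max(hx, hy)
    f12 = float((f9 - hxy1) / denom) if denom > 0 else 0.0
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - f9)))))

    f14 = _max_correlation_coefficient(P, px, py)

    values = np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13, f14])
    return FeatureVector(extractor_id="glcm", names=list(HARALICK_NAMES), values=values)


def _max_correlation_coefficient(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px(i)py(k)).

    Rows/columns with zero marginals carry no mass and are dropped; if
    fewer than two levels remain the coefficient is undefined and 0 is
    returned.
    """
    keep_x = px > 0
    keep_y = py > 0
    if keep_x.sum() < 2 or keep_y.sum() < 2:
        return 0.0
    Psub = P[np.ix_(keep_x, keep_y)]
    pxs = px[keep_x]
    pys = py[keep_y]
    Q = (Psub / pxs[:, None]) @ (Psub / pys[None, :]).T
    eig = np.linalg.eigvals(Q)
    eig = np.sort(eig.real)[::-1]
    if eig.size < 2:
        return 0.0
    return float(np.sqrt(max(0.0, eig[1])))


# ---------------------------------------------------------------------------
# Local binary patterns


@dataclass
class LBPConfig:
    """Multiscale LBP configuration.

    Each ``(P, R)`` pair contributes a normalized
    ``bins_per_neighborhood``-bin histogram of codes over ``[0, 2^P)``;
    the default -- P=8 at radii 1, 2, 3 with 16 bins each -- yields a
    48-feature vector.
    """

    neighborhoods: tuple[tuple[int, int], ...] = ((8, 1), (8, 2), (8, 3))
    bins_per_neighborhood: int = 16
    normalize: bool = True

    def __post_init__(self) -> None:
        for P, R in self.neighborhoods:
            if P < 4:
                raise ConfigurationError(f"neighbor count P={P} must be >= 4")
            if R < 1:
                raise ConfigurationError(f"radius R={R} must be >= 1")
        if self.bins_per_neighborhood < 1:
            raise ConfigurationError("bins_per_neighborhood must be >= 1")

    @property
    def feature_length(self) -> int:
        return len(self.neighborhoods) * self.bins_per_neighborhood


def _neighbor_offsets(P: int, R: float) -> list[tuple[float, float]]:
    """(row, col) offsets of the P neighbors on the radius-R circle.

    Neighbor p sits at angle 2*pi*p/P measured counterclockwise from the
    +column axis; rows grow downward, hence the negated sine. Offsets
    whose coordinates are within 1e-9 of an integer are snapped to it so
    that axis-aligned neighbors are sampled exactly.
    """
    offsets = []
    for p in range(P):
        theta = 2.0 * np.pi * p / P
        dr = -R * np.sin(theta)
        dc = R * np.cos(theta)
        if abs(dr - round(dr)) < 1e-9:
            dr = float(round(dr))
        if abs(dc - round(dc)) < 1e-9:
            dc = float(round(dc))
        offsets.append((dr, dc))
    return offsets


def _bilinear_shift(arr: np.ndarray, dr: float, dc: float,
                    r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
    """Sample ``arr`` at (r+dr, c+dc) for all centers in the given window.

    The displacement is constant across centers, so bilinear
    interpolation reduces to a fixed-weight combination of four
    integer-shifted slices.
    """
    fr, fc = int(np.floor(dr)), int(np.floor(dc))
    ar, ac = dr - fr, dc - fc
    out = np.zeros((r1 - r0, c1 - c0))
    for br, wr in ((0, 1.0 - ar), (1, ar)):
        if wr == 0.0:
            continue
        for bc, wc in ((0, 1.0 - ac), (1, ac)):
            if wc == 0.0:
                continue
            rs = r0 + fr + br
            cs = c0 + fc + bc
            out += (wr * wc) * arr[rs:rs + (r1 - r0), cs:cs + (c1 - c0)]
    return out


def lbp_code_map(image, P: int = 8, R: int = 1) -> np.ndarray:
    """LBP codes for every pixel at least ``ceil(R)`` from the border.

    Code = ``sum_p f(g_p - g_c) 2^p`` with ``f(x) = 1`` for ``x >= 0``
    (an exact tie with the center sets the bit), neighbors bilinearly
    interpolated on the radius-R circle.
    """
    arr = _as_pixel_array(image).astype(float)
    h, w = arr.shape
    margin = int(np.ceil(R))
    if h < 2 * margin + 1 or w < 2 * margin + 1:
        raise ConfigurationError(
            f"image {h}x{w} too small for radius {R} (needs >= {2 * margin + 1} per side)"
        )
    r0, r1 = margin, h - margin
    c0, c1 = margin, w - margin
    center = arr[r0:r1, c0:c1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(_neighbor_offsets(P, R)):
        neighbor = _bilinear_shift(arr, dr, dc, r0, r1, c0, c1)
        codes += ((neighbor - center) >= -1e-9).astype(np.int64) << p
    return codes


def lbp_code(image, center: tuple[int, int], P: int = 8, R: int = 1) -> int:
    """LBP code of a single pixel; errors when closer than R to the border."""
    arr = _as_pixel_array(image)
    h, w = arr.shape
    r, c = center
    margin = int(np.ceil(R))
    if not (margin <= r < h - margin and margin <= c < w - margin):
        raise ConfigurationError(
            f"center {center} closer than radius {R} to the border of a {h}x{w} image"
        )
    codes = lbp_code_map(arr, P=P, R=R)
    return int(codes[r - margin, c - margin])


def lbp_features(image, config: LBPConfig | None = None) -> FeatureVector:
    """Concatenated per-neighborhood LBP code histograms.

    For each ``(P, R)`` the code histogram over all valid pixels is
    binned into ``bins_per_neighborhood`` equal-width bins over
    ``[0, 2^P)`` and normalized to sum to 1.
    """
    config = config or LBPConfig()
    parts = []
    for P, R in config.neighborhoods:
        codes = lbp_code_map(image, P=P, R=R)
        edges = np.linspace(0, 2**P, config.bins_per_neighborhood + 1)
        hist, _ = np.histogram(codes, bins=edges)
        hist = hist.astype(float)
        if config.normalize and hist.sum() > 0:
            hist /= hist.sum()
        names = [
            f"lbp_P{P}_R{R}_bin{b:02d}" for b in range(config.bins_per_neighborhood)
        ]
        parts.append(FeatureVector(extractor_id="lbp", names=names, values=hist))
    return FeatureVector.concatenate(parts, extractor_id="lbp")


# ---------------------------------------------------------------------------
# Hu moment invariants


def hu_moments(image, exponent: str = "standard") -> FeatureVector:
    """Hu's seven moment invariants of the image intensity distribution.

    Central moments are taken about the intensity centroid (translation
    invariance); normalization ``eta_pq = mu_pq / mu_00^alpha`` uses
    ``alpha = (p+q)/2 + 1`` (``exponent="standard"``, scale invariant)
    or the truncated ``alpha = (p+q)/2`` (``exponent="printed"``, kept
    for comparison; not scale invariant).
    """
    if exponent not in ("standard", "printed"):
        raise ConfigurationError(f"unknown exponent convention {exponent!r}")
    arr = _as_pixel_array(image).astype(float)
    total = arr.sum()
    if total == 0:
        raise ConfigurationError("all-zero image has no moments")
    h, w = arr.shape
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    y_bar = float((ys * arr).sum() / total)
    x_bar = float((xs * arr).sum() / total)
    dy = ys - y_bar
    dx = xs - x_bar

    def mu(p: int, q: int) -> float:
        return float(((dx**p) * (dy**q) * arr).sum())

    def eta(p: int, q: int) -> float:
        alpha = (p + q) / 2.0 + (1.0 if exponent == "standard" else 0.0)
        return mu(p, q) / total**alpha

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03 = eta(3, 0), eta(0, 3)
    n21, n12 = eta(2, 1), eta(1, 2)

    phi1 = n20 + n02
    phi2 = (n20 - n02) ** 2 + 4 * n11**2
    phi3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    phi4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    phi5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    phi6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    phi7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)

    values = np.array([phi1, phi2, phi3, phi4, phi5, phi6, phi7])
    names = [f"hu_phi{i}" for i in range(1, 8)]
    return FeatureVector(extractor_id="hu", names=names, values=values)


# ---------------------------------------------------------------------------
# Combined extractor


def glcm_features(
    image,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int = 256,
    symmetric: bool = True,
) -> FeatureVector:
    """The 14 Haralick features of the default (or given) GLCM."""
    return haralick_features(compute_glcm(image, offsets=offsets, levels=levels,
                                          symmetric=symmetric))


def extract_traditional(
    image,
    which: str = "all",
    lbp_config: LBPConfig | None = None,
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    glcm_levels: int = 256,
    hu_exponent: str = "standard",
) -> FeatureVector:
    """Dispatch to one traditional extractor or concatenate all three.

    ``which="all"`` concatenates glcm(14) + lbp(48) + hu(7) -> 69
    features under the default configurations.
    """
    extractors = {
        "glcm": lambda: glcm_features(image, offsets=glcm_offsets, levels=glcm_levels),
        "lbp": lambda: lbp_features(image, config=lbp_config),
        "hu": lambda: hu_moments(image, exponent=hu_exponent),
    }
    if which == "all":
        parts = [extractors[k]() for k in ("glcm", "lbp", "hu")]
        return FeatureVector.concatenate(parts, extractor_id="all")
    if which not in extractors:
        raise ConfigurationError(
            f"unknown extractor {which!r}; choose from glcm, lbp, hu, all"
        )
    return extractors[which]()
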