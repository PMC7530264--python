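"""Independent brute-force oracles, written directly from the textbook
definitions with plain Python loops. They deliberately share no code with
the package implementations they check."""

from __future__ import annotations

import math

import numpy as np


def brute_glcm(image: np.ndarray, offsets, levels: int, symmetric: bool) -> np.ndarray:
    """Pair counting by explicit loops; normalized to sum 1."""
    binned = [[min((int(v) * levels) // 256, levels - 1) for v in row] for row in image]
    h, w = len(binned), len(binned[0])
    counts = [[0.0] * levels for _ in range(levels)]
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[binned[r][c]][binned[r2][c2]] += 1.0
    if symmetric:
        counts = [
            [counts[i][j] + counts[j][i] for j in range(levels)] for i in range(levels)
        ]
    total = sum(sum(row) for row in counts)
    return np.array([[v / total for v in row] for row in counts])


def brute_haralick(p: np.ndarray) -> list[float]:
    """The 14 Haralick statistics from their definitions, entropies in bits."""
    n = p.shape[0]
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def h(values) -> float:
        return -sum(v * math.log2(v) for v in values if v > 0)

    f1 = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    f2 = sum(k**2 * p_diff[k] for k in range(n))
    if sd_x > 0 and sd_y > 0:
        f3 = (
            sum(i * j * p[i][j] for i in range(n) for j in range(n)) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        f3 = 0.0
    f4 = sum((i - mu_x) ** 2 * p[i][j] for i in range(n) for j in range(n))
    f5 = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    f6 = sum(k * p_sum[k] for k in range(2 * n - 1))
    f7 = sum((k - f6) ** 2 * p_sum[k] for k in range(2 * n - 1))
    f8 = h(p_sum)
    f9 = h(p[i][j] for i in range(n) for j in range(n))
    mu_d = sum(k * p_diff[k] for k in range(n))
    f10 = sum((k - mu_d) ** 2 * p_diff[k] for k in range(n))
    f11 = h(p_diff)
    hx, hy = h(px), h(py)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = h(px[i] * py[j] for i in range(n) for j in range(n))
    f12 = (f9 - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f13 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - f9))))

    keep_x = [i for i in range(n) if px[i] > 0]
    keep_y = [j for j in range(n) if py[j] > 0]
    if len(keep_x) < 2 or len(keep_y) < 2:
        f14 = 0.0
    else:
        q = np.array(
            [
                [
                    sum(
                        p[i][k] * p[j][k] / (px[i] * py[k])
                        for k in keep_y
                    )
                    for j in keep_x
                ]
                for i in keep_x
            ]
        )
        eig = sorted(np.linalg.eigvals(q).real, reverse=True)
        f14 = math.sqrt(max(0.0, eig[1])) if len(eig) >= 2 else 0.0
    return [f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13, f14]


def brute_lbp_code(image: np.ndarray, r: int, c: int, P: int, R: float) -> int:
    """LBP code by per-neighbor bilinear interpolation, f(x)=1 for x>=0.

    The >= comparison carries a 1e-9 slack absorbing floating-point noise
    in the interpolation of exact ties (both implementations adopt it)."""
    code = 0
    gc = float(image[r, c])
    for p in range(P):
        theta = 2.0 * math.pi * p / P
        rr = r - R * math.sin(theta)
        cc = c + R * math.cos(theta)
        if abs(rr - round(rr)) < 1e-9:
            rr = round(rr)
        if abs(cc - round(cc)) < 1e-9:
            cc = round(cc)
        r0, c0 = int(math.floor(rr)), int(math.floor(cc))
        fr, fc = rr - r0, cc - c0
        gp = 0.0
        for dr2, wr in ((0, 1 - fr), (1, fr)):
            for dc2, wc in ((0, 1 - fc), (1, fc)):
                if wr * wc > 0:  # zero-weight corners may fall off the image
                    gp += wr * wc * image[r0 + dr2, c0 + dc2]
        if gp - gc >= -1e-9:
            code += 2**p
    return code


def brute_central_moment(image: np.ndarray, p: int, q: int) -> float:
    """mu_pq about the intensity centroid (x = column, y = row)."""
    total = float(image.sum())
    xbar = sum(
        c * float(image[r, c]) for r in range(image.shape[0]) for c in range(image.shape[1])
    ) / total
    ybar = sum(
        r * float(image[r, c]) for r in range(image.shape[0]) for c in range(image.shape[1])
    ) / total
    return sum(
        (c - xbar) ** p * (r - ybar) ** q * float(image[r, c])
        for r in range(image.shape[0])
        for c in range(image.shape[1])
    )
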