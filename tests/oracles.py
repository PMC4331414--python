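"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately written without reference to the package
implementation: plain loops, dense 1-D numeric evaluation and direct
textbook formulas, so the tests compare two independent routes.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# blurred-sphere radial profile (3-D Gaussian convolution of a ball)

def blurred_sphere_profile(r, radius, sigma, n_quad: int = 4000) -> np.ndarray:
    """Radial profile of a unit ball of ``radius`` convolved with an
    isotropic Gaussian of ``sigma``, by dense 1-D numeric quadrature of
    the radial convolution kernel."""
    s = np.linspace(0.0, radius, n_quad)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.empty_like(r)
    norm = math.sqrt(2.0 * math.pi) * sigma
    for i, ri in enumerate(r):
        if ri < 1e-9:
            k = 2.0 * s**2 / (norm * sigma**2) * np.exp(-(s**2) / (2 * sigma**2))
        else:
            k = s / (ri * norm) * (np.exp(-((ri - s) ** 2) / (2 * sigma**2))
                                   - np.exp(-((ri + s) ** 2) / (2 * sigma**2)))
        out[i] = np.trapezoid(k, s)
    return out


def max_gradient_radius(radius, sigma, r_step: float = 0.01) -> float:
    """Radius of the maximum |radial derivative| of the blurred ball."""
    rr = np.arange(0.0, 2.0 * radius, r_step)
    prof = blurred_sphere_profile(rr, radius, sigma)
    deriv = np.gradient(prof, rr)
    return float(rr[np.argmin(deriv)])


# ---------------------------------------------------------------------------
# exhaustive voxel-scan oracles

def threshold_mask_oracle(data, center, radius, spacing, threshold) -> np.ndarray:
    """Per-voxel scan: centre inside the sphere and value >= threshold."""
    out = np.zeros(data.shape, dtype=bool)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                p = (i * spacing[0], j * spacing[1], k * spacing[2])
                d2 = sum((p[a] - center[a]) ** 2 for a in range(3))
                if d2 <= radius**2 and data[i, j, k] >= threshold:
                    out[i, j, k] = True
    return out


def length_oracle_cm(mask, dz) -> float:
    """Exhaustive scan over occupied slice indices; N slices -> N*dz."""
    occupied = [k for k in range(mask.shape[2]) if mask[:, :, k].any()]
    if not occupied:
        raise ValueError("empty")
    return (max(occupied) - min(occupied) + 1) * dz / 10.0


def volume_oracle_cm3(mask, spacing) -> float:
    count = 0
    for v in mask.ravel():
        if v:
            count += 1
    return count * spacing[0] * spacing[1] * spacing[2] / 1000.0


def overlap_oracle(pet_mask, ct_mask) -> float:
    inter = 0
    ct = 0
    for a, b in zip(pet_mask.ravel(), ct_mask.ravel()):
        if b:
            ct += 1
            if a:
                inter += 1
    return inter / ct


def ellipsoid_dilation_oracle(mask, spacing, margins) -> np.ndarray:
    """Exhaustive scaled-distance check of the Minkowski ellipsoid sum."""
    src = np.argwhere(mask)
    out = np.zeros(mask.shape, dtype=bool)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * spacing
        for s in src:
            q = s * spacing
            d = sum(((p[a] - q[a]) / margins[a]) ** 2 if margins[a] > 0
                    else (math.inf if p[a] != q[a] else 0.0) for a in range(3))
            if d <= 1.0 + 1e-9:
                out[idx] = True
                break
    return out


# ---------------------------------------------------------------------------
# sort-based dose statistics

def vx_oracle(doses, x) -> float:
    return sum(1 for d in doses if d >= x) / len(doses) * 100.0


def dq_oracle(doses, q) -> float:
    """Minimum dose to the hottest q %: sort descending, take the
    ceil(q/100 * n)-th value."""
    srt = sorted(doses, reverse=True)
    k = max(1, math.ceil(q / 100.0 * len(srt)))
    return srt[k - 1]


# ---------------------------------------------------------------------------
# direct-formula statistics

def pearson_oracle(x, y) -> tuple[float, float]:
    """Textbook covariance / (sx*sy) and exact two-sided p via the
    t-transform with n-2 degrees of freedom."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    r = cov / math.sqrt(vx * vy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, p


def paired_t_oracle(x, y) -> tuple[float, float]:
    """t = mean(d)/(sd(d)/sqrt(n)) with two-tailed p on n-1 df."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in d) / (n - 1))
    t = m / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, p


def nearest_component_oracle(mask, center, spacing) -> np.ndarray:
    """Brute-force re-statement of the connectivity rule: flood-fill the
    26-connected components, keep the one whose nearest voxel centre is
    closest to ``center`` (ties broken toward the larger component)."""
    visited = np.zeros(mask.shape, dtype=bool)
    best_key, best_comp = None, None
    for start in np.ndindex(mask.shape):
        if not mask[start] or visited[start]:
            continue
        comp = []
        stack = [start]
        visited[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        nb = (cur[0] + di, cur[1] + dj, cur[2] + dk)
                        if (0 <= nb[0] < mask.shape[0] and 0 <= nb[1] < mask.shape[1]
                                and 0 <= nb[2] < mask.shape[2]
                                and mask[nb] and not visited[nb]):
                            visited[nb] = True
                            stack.append(nb)
        dmin = min(math.sqrt(sum((idx[a] * spacing[a] - center[a]) ** 2
                                 for a in range(3))) for idx in comp)
        key = (round(dmin, 6), -len(comp))
        if best_key is None or key < best_key:
            best_key, best_comp = key, comp
    out = np.zeros(mask.shape, dtype=bool)
    if best_comp:
        for idx in best_comp:
            out[idx] = True
    return out


def threshold_segmentation_oracle(data, center, radius, spacing, threshold) -> np.ndarray:
    """Full independent re-computation of the sphere-threshold operation."""
    raw = threshold_mask_oracle(data, center, radius, spacing, threshold)
    if not raw.any():
        return raw
    return nearest_component_oracle(raw, center, spacing)
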