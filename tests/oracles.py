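"""Independent brute-force metric implementations (explicit loops).

These deliberately avoid numpy vectorization and the package's own metric
code paths: every statistic is accumulated element by element so the package
implementations can be checked against them to tight tolerances.
"""

from __future__ import annotations

import math


def _masked_values(img, mask):
    vals = []
    shape = mask.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if mask[i, j, k]:
                    vals.append(float(img[i, j, k]))
    return vals


def mean_loop(vals):
    s = 0.0
    for v in vals:
        s += v
    return s / len(vals)


def rmse_loop(x, y, mask):
    xv, yv = _masked_values(x, mask), _masked_values(y, mask)
    s = 0.0
    for a, b in zip(xv, yv):
        s += (a - b) ** 2
    return math.sqrt(s / len(xv))


def psnr_loop(x, y, mask):
    xv = _masked_values(x, mask)
    peak = max(xv)
    r = rmse_loop(x, y, mask)
    if r == 0.0:
        return float("inf")
    return 20.0 * math.log10(peak / r)


def ssim_loop(x, y, mask, c1=0.01, c2=0.03):
    xv, yv = _masked_values(x, mask), _masked_values(y, mask)
    mx, my = mean_loop(xv), mean_loop(yv)
    vx = mean_loop([(a - mx) ** 2 for a in xv])
    vy = mean_loop([(b - my) ** 2 for b in yv])
    cxy = mean_loop([(a - mx) * (b - my) for a, b in zip(xv, yv)])
    return ((2 * mx * my + c1) * (2 * cxy + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2)
    )


def rc_loop(measured, ground_truth, roi):
    return mean_loop(_masked_values(measured, roi)) / mean_loop(
        _masked_values(ground_truth, roi)
    )


def cov_loop(img, roi):
    vals = _masked_values(img, roi)
    mu = mean_loop(vals)
    var = mean_loop([(v - mu) ** 2 for v in vals])
    return 100.0 * math.sqrt(var) / mu


def sphere_count_loop(radius, center=(0.0, 0.0, 0.0)):
    """Integer lattice points within the closed ball of ``radius``."""
    r = int(math.ceil(radius)) + 1
    count = 0
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                dx = i - center[0]
                dy = j - center[1]
                dz = k - center[2]
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    count += 1
    return count


def erode_ball_loop(mask, radius):
    """Brute-force binary erosion by a Euclidean ball (voxel-center rule)."""
    import numpy as np

    out = np.zeros_like(mask)
    r = int(math.floor(radius))
    offsets = [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if i * i + j * j + k * k <= radius * radius
    ]
    shape = mask.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not mask[i, j, k]:
                    continue
                keep = True
                for di, dj, dk in offsets:
                    a, b, c = i + di, j + dj, k + dk
                    if not (
                        0 <= a < shape[0]
                        and 0 <= b < shape[1]
                        and 0 <= c < shape[2]
                    ) or not mask[a, b, c]:
                        keep = False
                        break
                out[i, j, k] = keep
    return out


def count_parameters_loop(stages, in_channels=1, batch_norm=True):
    """Closed-form parameter count, summed stage by stage."""
    total = 0
    cin = in_channels
    for modules, channels, _dilation in stages:
        for _ in range(modules):
            total += 27 * cin * channels + channels
            if batch_norm:
                total += 2 * channels
            cin = channels
    total += 27 * cin + 1
    return total
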