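"""Independent oracle implementations used only by the tests.

These deliberately share no code with the package: brute-force enumeration
for the rank tests, a literal transcription of the pixel-domain VIF
recipe with explicit loops, and direct co-occurrence counting. They are
slow and only run on tiny inputs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mwu_enumeration(a, b, alternative: str) -> float:
    """Exact Mann-Whitney p by enumerating every assignment of pooled values."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n = len(a)

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yj in y:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        sel = set(comb)
        xs = [pooled[i] for i in sel]
        ys = [pooled[i] for i in range(len(pooled)) if i not in sel]
        us.append(u_stat(xs, ys))
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_enumeration(a, b, alternative: str) -> float:
    """Exact signed-rank p by enumerating all 2^n sign patterns."""
    d = [float(x) - float(y) for x, y in zip(a, b)]
    d = [x for x in d if x != 0]
    if not d:
        return 1.0
    absd = sorted((abs(x), i) for i, x in enumerate(d))
    ranks = [0.0] * len(d)
    i = 0
    while i < len(absd):
        j = i
        while j < len(absd) and absd[j][0] == absd[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = avg
        i = j
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    total = len(ws)
    p_ge = sum(w >= w_obs for w in ws) / total
    p_le = sum(w <= w_obs for w in ws) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def vif_pixel_reference(test, ref, n_scales=4, sigma_nsq=2.0, data_range=2000.0) -> float:
    """Literal multi-scale pixel-domain VIF with per-pixel loops."""
    x = np.asarray(test, dtype=float) * (255.0 / data_range)
    y = np.asarray(ref, dtype=float) * (255.0 / data_range)
    eps = 1e-10
    num = den = 0.0
    for scale in range(1, n_scales + 1):
        width = 2 ** (n_scales - scale + 1) + 1
        sd = width / 5.0
        r = (width - 1) // 2
        g1 = np.exp(-0.5 * (np.arange(-r, r + 1) / sd) ** 2)
        g1 /= g1.sum()
        win = np.outer(g1, g1)
        if scale > 1:
            x = _filt2_valid(x, win)[::2, ::2]
            y = _filt2_valid(y, win)[::2, ::2]
        if min(x.shape) < width + 2:
            break
        mx = _filt2_valid(x, win)
        my = _filt2_valid(y, win)
        vx = _filt2_valid(x * x, win) - mx * mx
        vy = _filt2_valid(y * y, win) - my * my
        cxy = _filt2_valid(x * y, win) - mx * my
        vx = np.maximum(vx, 0.0)
        vy = np.maximum(vy, 0.0)
        for i in range(mx.shape[0]):
            for j in range(mx.shape[1]):
                vr, vd, c = vy[i, j], vx[i, j], cxy[i, j]
                g = c / (vr + eps)
                sv = vd - g * c
                if vr < eps:
                    g, sv, vr = 0.0, vd, 0.0
                if vd < eps:
                    g, sv = 0.0, 0.0
                if g < 0.0:
                    sv, g = vd, 0.0
                sv = max(sv, eps)
                num += math.log10(1.0 + g * g * vr / (sv + sigma_nsq))
                den += math.log10(1.0 + vr / sigma_nsq)
    return num / den


def _filt2_valid(img: np.ndarray, win: np.ndarray) -> np.ndarray:
    h, w = win.shape
    H, W = img.shape
    out = np.zeros((H - h + 1, W - w + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = float(np.sum(img[i : i + h, j : j + w] * win))
    return out


def glcm_brute_force(levels2d, n_levels, offset) -> np.ndarray:
    """Symmetric co-occurrence counts on a full 2-D grid by explicit looping."""
    dy, dx = offset
    counts = np.zeros((n_levels, n_levels))
    h, w = levels2d.shape
    for i in range(h):
        for j in range(w):
            ii, jj = i + dy, j + dx
            if 0 <= ii < h and 0 <= jj < w:
                a, b = levels2d[i, j] - 1, levels2d[ii, jj] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def aa_disk(n: int, fov: float, radius: float, value: float, supersample: int = 8) -> np.ndarray:
    """Anti-aliased rasterization of a centered disk (area-weighted edge pixels)."""
    h = fov / n
    ss = supersample
    c = (n * ss - 1) / 2.0
    x = (np.arange(n * ss) - c) * (h / ss)
    xx, yy = np.meshgrid(x, x)
    fine = (xx**2 + yy**2 <= radius**2).astype(float)
    return value * fine.reshape(n, ss, n, ss).mean(axis=(1, 3))
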