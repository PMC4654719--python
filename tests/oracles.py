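"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain double loops over pixels directly
from the textbook definitions, deliberately avoiding the vectorized
marginal-based code paths of the package.
"""

import math

import numpy as np


def glcm_brute(levels, mask, offset, G):
    """Symmetric co-occurrence matrix by exhaustive pair enumeration."""
    dx, dy = offset
    nr, nc = levels.shape
    counts = np.zeros((G, G))
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < nr and 0 <= c2 < nc and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    t = counts.sum()
    return counts / t if t > 0 else counts


def haralick_brute(p):
    """The 11 co-occurrence statistics by direct double summation."""
    G = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(G) for j in range(G))
    var_x = sum(((i + 1) - mu_x) ** 2 * p[i, j]
                for i in range(G) for j in range(G))

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    psum = {}
    pdif = {}
    for i in range(G):
        for j in range(G):
            psum[(i + 1) + (j + 1)] = psum.get((i + 1) + (j + 1), 0.0) + p[i, j]
            pdif[abs(i - j)] = pdif.get(abs(i - j), 0.0) + p[i, j]
    sum_avg = sum(k * v for k, v in psum.items())
    dif_mean = sum(k * v for k, v in pdif.items())
    sd_x = math.sqrt(var_x)
    if sd_x > 0:
        correlat = (sum((i + 1) * (j + 1) * p[i, j]
                        for i in range(G) for j in range(G)) - mu_x**2) / var_x
    else:
        correlat = 0.0
    return {
        "AngScMom": sum(p[i, j] ** 2 for i in range(G) for j in range(G)),
        "Contrast": sum((i - j) ** 2 * p[i, j]
                        for i in range(G) for j in range(G)),
        "Correlat": correlat,
        "SumOfSqs": var_x,
        "InvDfMom": sum(p[i, j] / (1 + (i - j) ** 2)
                        for i in range(G) for j in range(G)),
        "SumAverg": sum_avg,
        "SumVarnc": sum((k - sum_avg) ** 2 * v for k, v in psum.items()),
        "SumEntrp": ent(psum.values()),
        "Entropy": ent(p.ravel()),
        "DifVarnc": sum((k - dif_mean) ** 2 * v for k, v in pdif.items()),
        "DifEntrp": ent(pdif.values()),
    }


def rlm_brute(levels, mask, step):
    """Run-length statistics by explicit line scans."""
    nr, nc = levels.shape
    dr, dc = step
    runs = []
    starts = [(r, c) for r in range(nr) for c in range(nc)
              if not (0 <= r - dr < nr and 0 <= c - dc < nc)]
    for r0, c0 in starts:
        r, c = r0, c0
        cur, length = None, 0
        while 0 <= r < nr and 0 <= c < nc:
            if mask[r, c] and levels[r, c] == cur:
                length += 1
            else:
                if length:
                    runs.append((cur, length))
                cur, length = (levels[r, c], 1) if mask[r, c] else (None, 0)
            r, c = r + dr, c + dc
        if length:
            runs.append((cur, length))
    n = len(runs)
    npx = int(mask.sum())
    lev_tot = {}
    len_tot = {}
    for g, l in runs:
        lev_tot[g] = lev_tot.get(g, 0) + 1
        len_tot[l] = len_tot.get(l, 0) + 1
    return {
        "ShrtREmp": sum(1 / l**2 for _, l in runs) / n,
        "LngREmph": sum(l**2 for _, l in runs) / n,
        "GLevNonUni": sum(v**2 for v in lev_tot.values()) / n,
        "RLNonUni": sum(v**2 for v in len_tot.values()) / n,
        "Fraction": n / npx,
    }


def gradient_brute(raster, mask):
    """Central-difference gradient stats by per-pixel loops."""
    nr, nc = raster.shape
    mags = []
    for r in range(1, nr - 1):
        for c in range(1, nc - 1):
            if (mask[r, c] and mask[r - 1, c] and mask[r + 1, c]
                    and mask[r, c - 1] and mask[r, c + 1]):
                gy = (raster[r + 1, c] - raster[r - 1, c]) / 2
                gx = (raster[r, c + 1] - raster[r, c - 1]) / 2
                mags.append(math.hypot(gx, gy))
    return np.array(mags)


def geometry_brute(mask):
    """Mask moments by pixel-sum loops."""
    pts = [(r, c) for r in range(mask.shape[0])
           for c in range(mask.shape[1]) if mask[r, c]]
    n = len(pts)
    cy = sum(r for r, _ in pts) / n
    cx = sum(c for _, c in pts) / n
    r0 = min(r for r, _ in pts)
    c0 = min(c for _, c in pts)
    m2 = sum((r - cy) ** 2 + (c - cx) ** 2 for r, c in pts) / n
    mxy = sum((r - cy) * (c - cx) for r, c in pts) / n
    return {"GeoY": cy, "GeoX": cx, "GeoYo": cy - r0, "GeoXo": cx - c0,
            "GeoXYo": (cy - r0) * (cx - c0), "GeoS2": m2, "GeoM2xy": mxy}


def auc_mann_whitney(scores, labels):
    """AUC as the Mann-Whitney U statistic with half-weight ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def greedy_poe_acc_brute(X, labels, k):
    """Exhaustive greedy POE+ACC selection on a small feature set."""
    n, p = X.shape

    def poe(v):
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        m0, m1 = z[labels == 0].mean(), z[labels == 1].mean()
        pred = (np.abs(z - m1) < np.abs(z - m0)).astype(int)
        return float(np.mean(pred != labels))

    def corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return abs(float(np.corrcoef(a, b)[0, 1]))

    selected = []
    for _ in range(k):
        best, best_s = None, None
        for j in range(p):
            if j in selected:
                continue
            s = poe(X[:, j])
            if selected:
                s += np.mean([corr(X[:, j], X[:, i]) for i in selected])
            if best_s is None or s < best_s - 1e-15:
                best, best_s = j, s
        selected.append(best)
    return selected
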