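"""Independent brute-force references for the test suite.

Literal per-pixel loop implementations of the NLM family, loop-based
metrics, disc rasterization, flood fill, and a direct fuzzy-c-means loop.
Deliberately slow and free of any array-manipulation code shared with the
package's fast paths; intended for images of at most ~32x32.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# NLM family, quadruple loop
# ---------------------------------------------------------------------------

def _oracle_patch(img, r, c, radp, dialect):
    """Patch values via explicit mirrored indexing (no np.pad)."""
    H, W = img.shape
    step = 1 if dialect == "contiguous" else 2
    side = 2 * radp + 1
    out = np.empty((side, side))
    for iu, du in enumerate(range(-radp, radp + 1)):
        for iv, dv in enumerate(range(-radp, radp + 1)):
            rr = _mirror(r + du * step, H)
            cc = _mirror(c + dv * step, W)
            out[iu, iv] = img[rr, cc]
    return out


def _mirror(idx, n):
    # symmetric (edge-repeating) reflection, matching np.pad mode='symmetric'
    while idx < 0 or idx >= n:
        if idx < 0:
            idx = -idx - 1
        else:
            idx = 2 * n - idx - 1
    return idx


def _oracle_kernel(radp, a, dialect):
    step = 1 if dialect == "contiguous" else 2
    side = 2 * radp + 1
    k = np.empty((side, side))
    for iu, du in enumerate(range(-radp, radp + 1)):
        for iv, dv in enumerate(range(-radp, radp + 1)):
            if math.isinf(a):
                k[iu, iv] = 1.0
            else:
                d2 = (du * step) ** 2 + (dv * step) ** 2
                k[iu, iv] = math.exp(-d2 / (2.0 * a * a))
    return k / k.sum()


def naive_nlm_family(img, params, sigma=0.0, variant="nlm", no_sqrt=False):
    """Reference output: per-pixel double loop over centers and window."""
    y = np.asarray(img, dtype=float)
    H, W = y.shape
    radp, rads = params.radp, params.rads
    h2 = params.h * params.h
    dialect = params.patch_dialect
    out = np.empty_like(y)
    for r in range(H):
        for c in range(W):
            pc = _oracle_patch(y, r, c, radp, dialect)
            kern = _oracle_kernel(radp, params.a, dialect)
            weights = []
            values = []
            best = -1.0
            best_y = y[r, c]
            for dy in range(-rads, rads + 1):
                for dx in range(-rads, rads + 1):
                    if dy == 0 and dx == 0:
                        continue
                    jr, jc = r + dy, c + dx
                    if not (0 <= jr < H and 0 <= jc < W):
                        continue
                    pj = _oracle_patch(y, jr, jc, radp, dialect)
                    d2 = float(np.sum(kern * (pc - pj) ** 2))
                    phi = math.exp(-d2 / h2)
                    if variant == "rnlm_star":
                        diff = abs(y[r, c] - y[jr, jc])
                        phi *= 1.0 / (1.0 + (diff / params.degc) ** params.omega)
                    weights.append(phi)
                    values.append(y[jr, jc])
                    if phi > best:
                        best = phi
                        best_y = y[jr, jc]
            if variant == "rnlm_star":
                diff = abs(y[r, c] - best_y)
                if diff > 0:
                    theta = 1.0 + (2 * radp + 1) ** 2 / (
                        1.0 + (params.degc / diff) ** params.omega
                    )
                else:
                    theta = 1.0
                w_self = best * theta
            else:
                w_self = best
            weights.append(w_self)
            values.append(y[r, c])
            total = sum(weights)
            if total == 0:
                out[r, c] = y[r, c]
                continue
            if variant == "nlm":
                out[r, c] = sum(w * v for w, v in zip(weights, values)) / total
            else:
                est = sum(w * v * v for w, v in zip(weights, values)) / total
                corrected = max(est - 2.0 * sigma * sigma, 0.0)
                out[r, c] = corrected if no_sqrt else math.sqrt(corrected)
    return out


# ---------------------------------------------------------------------------
# metrics, scalar loops
# ---------------------------------------------------------------------------

def loop_mse(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    total = 0.0
    for a, b in zip(x.ravel(), y.ravel()):
        total += (a - b) ** 2
    return total / x.size


def loop_snr_db(filtered, native):
    s, sh = np.asarray(filtered, float).ravel(), np.asarray(native, float).ravel()
    num = sum(a * a for a in s)
    den = sum((a - b) ** 2 for a, b in zip(s, sh))
    if den == 0:
        return float("inf")
    return 10.0 * math.log10(num / den)


def loop_q_index(x, y):
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    n = x.size
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx, sy = math.sqrt(vx), math.sqrt(vy)
    return (sxy / (sx * sy)) * (2 * mx * my / (mx * mx + my * my)) * (
        2 * sx * sy / (vx + vy)
    )


def loop_pearson(x, y):
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    n = x.size
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


# ---------------------------------------------------------------------------
# local filters, loop references
# ---------------------------------------------------------------------------

def loop_average_filter(img, size):
    y = np.asarray(img, float)
    H, W = y.shape
    r = size // 2
    out = np.empty_like(y)
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for du in range(-r, r + 1):
                for dv in range(-r, r + 1):
                    acc += y[_mirror(i + du, H), _mirror(j + dv, W)]
            out[i, j] = acc / (size * size)
    return out


def loop_median_filter(img, size):
    y = np.asarray(img, float)
    H, W = y.shape
    r = size // 2
    out = np.empty_like(y)
    for i in range(H):
        for j in range(W):
            vals = sorted(
                y[_mirror(i + du, H), _mirror(j + dv, W)]
                for du in range(-r, r + 1)
                for dv in range(-r, r + 1)
            )
            out[i, j] = vals[len(vals) // 2]
    return out


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def rasterize_disc(size, center, radius):
    """Independent disc rasterization by explicit pixel test."""
    mask = np.zeros(size, dtype=bool)
    cy, cx = center
    for i in range(size[0]):
        for j in range(size[1]):
            if (i - cy) ** 2 + (j - cx) ** 2 <= radius * radius:
                mask[i, j] = True
    return mask


def count_components_above(img, threshold):
    """4-connected flood-fill component count of img > threshold."""
    above = np.asarray(img) > threshold
    seen = np.zeros_like(above, dtype=bool)
    H, W = above.shape
    count = 0
    for i in range(H):
        for j in range(W):
            if above[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for na, nb in ((a - 1, b), (a + 1, b), (a, b - 1), (a, b + 1)):
                        if 0 <= na < H and 0 <= nb < W and above[na, nb] and not seen[na, nb]:
                            seen[na, nb] = True
                            stack.append((na, nb))
    return count


# ---------------------------------------------------------------------------
# fuzzy c-means, direct loop on a value/count table
# ---------------------------------------------------------------------------

def loop_fcm_centroids(values, counts, centroids0, m=2.0, tol=1e-6, max_iter=300):
    cents = [float(c) for c in centroids0]
    C = len(cents)
    for _ in range(max_iter):
        num = [0.0] * C
        den = [0.0] * C
        for v, cnt in zip(values, counts):
            d = [abs(v - c) for c in cents]
            if any(x == 0 for x in d):
                u = [0.0] * C
                u[d.index(0.0)] = 1.0
            else:
                inv = [x ** (-2.0 / (m - 1.0)) for x in d]
                s = sum(inv)
                u = [x / s for x in inv]
            for c in range(C):
                w = (u[c] ** m) * cnt
                num[c] += w * v
                den[c] += w
        new = [num[c] / den[c] if den[c] > 0 else cents[c] for c in range(C)]
        shift = max(abs(a - b) for a, b in zip(new, cents))
        cents = new
        if shift < tol:
            break
    return sorted(cents)
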