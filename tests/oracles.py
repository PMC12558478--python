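"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — O(n^2) loops, bisection on tail
probabilities, hand-rolled geodesics — and shares no code with the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# geodesy: Vincenty inverse on the WGS84 ellipsoid


def vincenty_distance(lon1, lat1, lon2, lat2, tol=1e-12, max_iter=200) -> float:
    """Geodesic distance in meters between two lon/lat points (WGS84)."""
    a = 6378137.0
    f = 1.0 / 298.257223563
    b = (1 - f) * a
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1, U2 = math.atan((1 - f) * math.tan(phi1)), math.atan((1 - f) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sigma_m = (
            cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha else 0.0
        )
        C = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * f * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    u2 = cos2_alpha * (a**2 - b**2) / b**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m
        + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m**2)
            - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sigma_m**2)
        )
    )
    return b * A * (sigma - delta_sigma)


# ---------------------------------------------------------------------------
# brute-force overlays


def brute_overlay_a(facilities, polygons, cut, radius):
    """All-pairs individual overlay, polygon dialect: damaged flag per facility."""
    out = {}
    for f in facilities:
        pt = f.location
        hit = any(
            p.damage_fraction > cut and p.geometry.intersects(pt) for p in polygons
        )
        rescue = any(
            p.damage_fraction > cut
            and math.hypot(p.geometry.centroid.x - f.x, p.geometry.centroid.y - f.y) < radius
            for p in polygons
        )
        out[f.facility_id] = hit or rescue
    return out


def brute_overlay_b(facilities, centroids, radius):
    """All-pairs nearest-centroid-within-radius, ties to lowest building id."""
    out = {}
    for f in facilities:
        best = None
        for c in centroids:
            d = math.hypot(c.location.x - f.x, c.location.y - f.y)
            if d < radius and (
                best is None
                or d < best[0]
                or (d == best[0] and c.building_id < best[1])
            ):
                best = (d, c.building_id, c.damage_class)
        out[f.facility_id] = bool(best[2]) if best else False
    return out


# ---------------------------------------------------------------------------
# brute-force grid assignment


def brute_hex_assign(xs, ys, centers):
    """Nearest-center assignment by full distance matrix, ties to lowest id."""
    out = []
    centers = np.asarray(centers)
    for x, y in zip(xs, ys):
        d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
        dmin = d.min()
        out.append(int(np.flatnonzero(d <= dmin + 1e-9).min()))
    return np.array(out)


# ---------------------------------------------------------------------------
# brute-force deduplication (transitive closure by BFS)


def brute_dedup(facilities, radius):
    """Kept facility ids after collapsing duplicate groups, first kept."""
    import re

    def norm(s):
        return re.sub(r"\s+", " ", re.sub(r"[^\w\s]", " ", s.lower())).strip()

    n = len(facilities)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            fi, fj = facilities[i], facilities[j]
            if (
                norm(fi.name) == norm(fj.name)
                and math.hypot(fi.x - fj.x, fi.y - fj.y) < radius
            ):
                adj[i].append(j)
                adj[j].append(i)
    seen = set()
    kept = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k])
        kept.append(facilities[min(comp)].facility_id)
    return sorted(kept)


# ---------------------------------------------------------------------------
# exact binomial interval by tail-probability bisection


def cp_bisect(k, n, alpha):
    """Clopper–Pearson bounds by bisecting the binomial tail equations."""

    def bisect(fn, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(100):
            mid = (lo + hi) / 2
            too_small = fn(mid) < target if increasing else fn(mid) > target
            if too_small:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    # P(X >= k | p) rises with p; the lower bound solves it = alpha/2.
    low = 0.0 if k == 0 else bisect(
        lambda p: stats.binom.sf(k - 1, n, p), alpha / 2, increasing=True
    )
    # P(X <= k | p) falls with p; the upper bound solves it = alpha/2.
    high = 1.0 if k == n else bisect(
        lambda p: stats.binom.cdf(k, n, p), alpha / 2, increasing=False
    )
    return low, high


# ---------------------------------------------------------------------------
# quartile by explicit order-statistic interpolation


def quartile_interpolated(values, q):
    """q-th quantile (q in [0,1]) by linear interpolation on sorted values."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


# ---------------------------------------------------------------------------
# kappa by direct 2x2 table arithmetic


def kappa_from_table(n11, n10, n01, n00):
    """(po - pe) / (1 - pe) from joint counts (x=1&y=1, x=1&y=0, ...)."""
    n = n11 + n10 + n01 + n00
    po = (n11 + n00) / n
    px = (n11 + n10) / n
    py = (n11 + n01) / n
    pe = px * py + (1 - px) * (1 - py)
    return (po - pe) / (1 - pe)
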