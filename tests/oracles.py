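"""Independent brute-force / quadrature oracles used by the test suite.

Each oracle deliberately avoids the code path (and where possible the
library) that the implementation under test uses.
"""

from __future__ import annotations

import math

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.special import gammaln
from scipy.stats import norm


def two_pass_cv_pct(values) -> float:
    """Percent CV via an explicit two-pass mean / sample-SD computation."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    sd = math.sqrt(ss / (n - 1))
    return sd / mean * 100.0


def pairwise_auroc(pos, neg) -> float:
    """AUROC as the exhaustive Mann-Whitney pair count."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pixel_centers_in_polygon(vertices_rc, image_shape) -> np.ndarray:
    """Boolean mask from matplotlib's even-odd point-in-polygon test.

    ``radius`` nudges the path outward so points on the boundary count as
    inside; adequate for generic (non-axis-aligned) random polygons.
    """
    h, w = image_shape
    pts = [(c, r) for r, c in vertices_rc]
    # matplotlib treats the final vertex of a closed path as the CLOSEPOLY
    # placeholder, so the ring must be closed explicitly
    path = MplPath(pts + [pts[0]], closed=True)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    inside = path.contains_points(pts, radius=1e-9)
    inside |= path.contains_points(pts, radius=-1e-9)
    return inside.reshape(h, w)


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """Survival function of the studentized range by nested quadrature.

    CDF(q) = int_0^inf chi_df(s) * P(range of k std normals < q*s) ds with
    P(range < u) = k * int phi(z) [Phi(z) - Phi(z-u)]^(k-1) dz, and chi_df
    the density of sqrt(chi2_df / df).  Both integrals are evaluated on
    fixed Gauss-Legendre grids; written independently of
    scipy.stats.studentized_range.
    """
    if q <= 0:
        return 1.0

    log_c = (
        (df / 2.0) * math.log(df)
        - gammaln(df / 2.0)
        - (df / 2.0 - 1.0) * math.log(2.0)
    )

    # outer grid over the scale factor s ~ sqrt(chi2_df / df)
    half_width = 12.0 / math.sqrt(2.0 * df)
    s_lo, s_hi = max(0.0, 1.0 - half_width), 1.0 + half_width
    xs, ws = np.polynomial.legendre.leggauss(320)
    s = 0.5 * (s_hi - s_lo) * xs + 0.5 * (s_hi + s_lo)
    ws = 0.5 * (s_hi - s_lo) * ws
    with np.errstate(divide="ignore"):
        log_f = log_c + (df - 1.0) * np.log(s) - df * s * s / 2.0
    dens = np.where(s > 0, np.exp(log_f), 0.0)

    # inner grid over z, shared by all outer nodes
    u = q * s  # (ns,)
    z_lo, z_hi = -9.0, 9.0 + float(u.max())
    xz, wz = np.polynomial.legendre.leggauss(400)
    z = 0.5 * (z_hi - z_lo) * xz + 0.5 * (z_hi + z_lo)
    wz = 0.5 * (z_hi - z_lo) * wz
    phi_z = norm.pdf(z)
    cdf_z = norm.cdf(z)
    inner = (phi_z * wz)[None, :] * (
        np.clip(cdf_z[None, :] - norm.cdf(z[None, :] - u[:, None]), 0.0, 1.0)
        ** (k - 1)
    )
    range_cdf = k * inner.sum(axis=1)  # (ns,)

    cdf = float(np.sum(ws * dens * range_cdf))
    return float(min(max(1.0 - cdf, 0.0), 1.0))
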