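"""Independent brute-force oracles used by the test suite."""

import numpy as np


def grid_search_oracle(img, patch_size=9, x_range=None, y_range=None,
                       s_range=None):
    """Exhaustive Gaussian fit: grid over (x0, y0, sigma), linear solve
    for (A, offset) at each node.  Independent of the least-squares path
    under test."""
    y, x = np.mgrid[0:patch_size, 0:patch_size].astype(float)
    best = (np.inf, None)
    xs = x_range if x_range is not None else np.arange(2.0, 6.01, 0.02)
    ys = y_range if y_range is not None else xs
    ss = s_range if s_range is not None else np.arange(0.8, 2.21, 0.01)
    flat = img.ravel()
    ones = np.ones(flat.size)
    for s in ss:
        for x0 in xs:
            gx = np.exp(-((x[0] - x0) ** 2) / (2 * s * s))
            for y0 in ys:
                gy = np.exp(-((y[:, 0] - y0) ** 2) / (2 * s * s))
                g = (gy[:, None] * gx[None, :]) / (2 * np.pi * s * s)
                design = np.column_stack([g.ravel(), ones])
                coef, res, *_ = np.linalg.lstsq(design, flat, rcond=None)
                sse = float(res[0]) if res.size else float(
                    np.sum((design @ coef - flat) ** 2)
                )
                if sse < best[0]:
                    best = (sse, (x0, y0, s, coef[0]))
    return best[1]


def enumeration_pmf(ps):
    """Poisson-binomial pmf by brute force over all 2^n outcomes."""
    ps = np.asarray(ps, dtype=np.float64)
    n = ps.size
    idx = np.arange(2**n, dtype=np.uint64)
    pmf = np.zeros(n + 1)
    prob = np.ones(2**n)
    k = np.zeros(2**n, dtype=np.int64)
    for i, p in enumerate(ps):
        hit = (idx >> np.uint64(i)) & np.uint64(1) == 1
        prob *= np.where(hit, p, 1.0 - p)
        k += hit
    np.add.at(pmf, k, prob)
    return pmf
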