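"""Independent reference implementations used only by the tests.

Each oracle is a deliberately naive second implementation (loops, direct
formulas, quadrature) of an operation the package implements with a faster
or more structured algorithm.  They share no code with the package.
"""

import numpy as np


def law_of_cosines_m(lat1, lon1, lat2, lon2, radius=6_371_008.8):
    """Spherical law-of-cosines great-circle distance."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    c = (np.sin(p1) * np.sin(p2)
         + np.cos(p1) * np.cos(p2) * np.cos(l2 - l1))
    return radius * np.arccos(np.clip(c, -1.0, 1.0))


def piecewise_linear(grid, t, values):
    """Loop-based piecewise-linear interpolation (no extrapolation)."""
    out = np.empty(len(grid), dtype=float)
    for i, g in enumerate(grid):
        j = np.searchsorted(t, g)
        if j == 0:
            out[i] = values[0]
        elif j == len(t):
            out[i] = values[-1]
        elif t[j] == g:
            out[i] = values[j]
        else:
            w = (g - t[j - 1]) / (t[j] - t[j - 1])
            out[i] = (1 - w) * values[j - 1] + w * values[j]
    return out


def rolling_rank_quantile(depth, size, quantile):
    """Per-window order statistic with edge replication, centred window."""
    half = size // 2
    padded = np.r_[np.full(half, depth[0]), depth, np.full(half, depth[-1])]
    rank = int(quantile * size)
    out = np.empty(len(depth))
    for i in range(len(depth)):
        window = np.sort(padded[i:i + size])
        out[i] = window[rank]
    return out


def association_events_naive(t, d, radius, min_duration, max_gap, dt):
    """Reconstruct association runs by walking every timestamp.

    Returns a list of (t_start, t_end, duration, mean_distance) following
    the bridged-run semantics: only in-radius samples count toward the
    duration; interruptions (out-of-radius or missing time) of at least
    ``max_gap`` split runs.
    """
    events = []
    run = []  # list of (time, distance) in-radius samples of current run
    last_in = None
    for i in range(len(t)):
        if d[i] <= radius:
            if last_in is not None and (t[i] - last_in - dt) >= max_gap:
                events.append(run)
                run = []
            run.append((t[i], d[i]))
            last_in = t[i]
    if run:
        events.append(run)
    out = []
    for run in events:
        duration = len(run) * dt
        if duration >= min_duration:
            times = [x[0] for x in run]
            dists = [x[1] for x in run]
            out.append((times[0], times[-1], float(duration),
                        float(np.mean(dists))))
    return out


def agq_logistic_loglik(y, X, groups, beta, sigma, n_points=21):
    """Adaptive Gauss-Hermite marginal log-likelihood for a logit model
    with a single random intercept."""
    from numpy.polynomial.hermite import hermgauss

    nodes, weights = hermgauss(n_points)
    total = 0.0
    for g in np.unique(groups):
        idx = groups == g
        xb = X[idx] @ beta
        yy = y[idx]
        u = 0.0
        for _ in range(100):
            e = xb + u
            mu = 1 / (1 + np.exp(-e))
            grad = np.sum(yy - mu) - u / sigma**2
            hess = np.sum(mu * (1 - mu)) + 1 / sigma**2
            step = grad / hess
            u += step
            if abs(step) < 1e-12:
                break
        sd_hat = 1 / np.sqrt(hess)
        z = u + np.sqrt(2) * sd_hat * nodes
        log_f = np.array([
            float(np.sum(yy * (xb + zk) - np.logaddexp(0, xb + zk))
                  - 0.5 * zk**2 / sigma**2
                  - 0.5 * np.log(2 * np.pi * sigma**2))
            for zk in z
        ])
        total += np.log(np.sqrt(2) * sd_hat
                        * np.sum(weights * np.exp(log_f + nodes**2)))
    return total


def dyad_days_bruteforce(trips, day_seconds=86400):
    """Enumerate (pair, day) keys by scanning every trip pair and day."""
    birds = sorted(trips["bird_id"].unique())
    keys = set()
    for i, a in enumerate(birds):
        for b in birds[i + 1:]:
            for _, ta in trips[trips["bird_id"] == a].iterrows():
                for _, tb in trips[trips["bird_id"] == b].iterrows():
                    lo = max(ta["t_start"], tb["t_start"])
                    hi = min(ta["t_end"], tb["t_end"])
                    if lo > hi:
                        continue
                    for day in range(int(lo // day_seconds),
                                     int(hi // day_seconds) + 1):
                        d0 = day * day_seconds
                        d1 = d0 + day_seconds
                        if max(lo, d0) <= min(hi, d1 - 1):
                            keys.add((a, b, day))
    return keys
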