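"""Independent brute-force oracles the tests check the implementation against.

Everything here is written from first principles (explicit normal
equations, exhaustive enumeration, dense grid search) and deliberately
shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def fluctuation_bruteforce(series, n: int) -> float:
    """Per-window least squares via explicit normal equations, residual RMS."""
    y = np.asarray(series, dtype=float)
    N = len(y)
    assert N % n == 0
    sq = 0.0
    for w in range(N // n):
        seg = y[w * n : (w + 1) * n]
        t = np.arange(n, dtype=float)
        # normal equations for a + b t
        St, Stt = t.sum(), (t * t).sum()
        Sy, Sty = seg.sum(), (t * seg).sum()
        det = n * Stt - St * St
        b = (n * Sty - St * Sy) / det
        a = (Stt * Sy - St * Sty) / det
        sq += float(((seg - a - b * t) ** 2).sum())
    return float(np.sqrt(sq / N))


def limb_r2_bruteforce(x, y) -> float:
    """R^2 = 1 - SS_res / SS_tot from explicit sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    b = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
    a = y.mean() - b * x.mean()
    ss_res = ((y - a - b * x) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)


def best_split_bruteforce(log_x, log_y, splits) -> tuple[int, float]:
    """Exhaustive re-evaluation of the two-limb fit; returns (k, r2)."""
    best_k, best_r2 = None, -np.inf
    n = len(log_x)
    for k in splits:
        r1 = limb_r2_bruteforce(log_x[:k], log_y[:k])
        r2_ = limb_r2_bruteforce(log_x[k:], log_y[k:])
        comb = (k * r1 + (n - k) * r2_) / n
        if comb > best_r2 + 1e-15:
            best_k, best_r2 = k, comb
    return best_k, best_r2


def cox_loglik_single(beta: float, x, time, event) -> float:
    """Breslow partial log-likelihood for one covariate, written naively."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    ll = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        dead = event & (time == t)
        ll += float(x[dead].sum() * beta)
        ll -= int(dead.sum()) * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


def cox_beta_gridsearch(x, time, event, lo=-5.0, hi=5.0) -> float:
    """Golden-section maximization of the explicit partial likelihood."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc = cox_loglik_single(c, x, time, event)
    fd = cox_loglik_single(d, x, time, event)
    for _ in range(200):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = cox_loglik_single(c, x, time, event)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = cox_loglik_single(d, x, time, event)
    return 0.5 * (a + b)


def mage_bruteforce(values, sd: float) -> float:
    """MAGE by explicit scan over alternating extrema."""
    x = list(map(float, values))
    # collapse plateaus
    xs = [x[0]]
    for v in x[1:]:
        if v != xs[-1]:
            xs.append(v)
    if len(xs) < 2:
        return float("nan")
    ext = [xs[0]]
    for i in range(1, len(xs) - 1):
        if (xs[i] - xs[i - 1]) * (xs[i + 1] - xs[i]) < 0:
            ext.append(xs[i])
    ext.append(xs[-1])
    amps = [ext[i + 1] - ext[i] for i in range(len(ext) - 1)]
    qual = [a for a in amps if abs(a) > sd]
    if not qual:
        return float("nan")
    direction = 1.0 if qual[0] > 0 else -1.0
    same = [abs(a) for a in qual if (a > 0) == (direction > 0)]
    return float(np.mean(same))
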