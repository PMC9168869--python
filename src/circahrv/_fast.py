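"""Compiled inner loops.

Two hot paths dominate whole-cohort runs: AR(1) beat generation and the
center-excluded rolling median / quartile-deviation scan used by the
artifact screen.  Both are written as numba kernels with pure-numpy
fallbacks (exact same output) so the package still works, slowly, without
a JIT.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _rolling_center_excluded_nb(x, w):
    n = x.shape[0]
    med = np.empty(n)
    qd = np.empty(n)
    if n < w:
        for i in range(n):
            med[i] = np.nan
            qd[i] = np.nan
        return med, qd
    half = w // 2
    m = w - 1  # neighborhood size with the center beat excluded
    k_med_lo = m // 2 - 1 if m % 2 == 0 else m // 2
    q1pos = 0.25 * (m - 1)
    q3pos = 0.75 * (m - 1)
    i1 = int(q1pos)
    f1 = q1pos - i1
    i3 = int(q3pos)
    f3 = q3pos - i3
    buf = np.sort(x[:w].copy())
    lo = 0
    for i in range(n):
        nlo = i - half
        if nlo < 0:
            nlo = 0
        if nlo > n - w:
            nlo = n - w
        while lo < nlo:
            old = x[lo]
            new = x[lo + w]
            a = 0
            b = w
            while a < b:
                c = (a + b) >> 1
                if buf[c] < old:
                    a = c + 1
                else:
                    b = c
            if new >= old:
                j = a
                while j + 1 < w and buf[j + 1] < new:
                    buf[j] = buf[j + 1]
                    j += 1
                buf[j] = new
            else:
                j = a
                while j - 1 >= 0 and buf[j - 1] > new:
                    buf[j] = buf[j - 1]
                    j -= 1
                buf[j] = new
            lo += 1
        v = x[i]
        a = 0
        b = w
        while a < b:
            c = (a + b) >> 1
            if buf[c] < v:
                a = c + 1
            else:
                b = c
        p = a  # rank of the center beat inside the sorted window
        k = k_med_lo
        s0 = buf[k] if k < p else buf[k + 1]
        if m % 2 == 0:
            k = k_med_lo + 1
            s1 = buf[k] if k < p else buf[k + 1]
            med[i] = 0.5 * (s0 + s1)
        else:
            med[i] = s0
        a0 = buf[i1] if i1 < p else buf[i1 + 1]
        a1 = buf[i1 + 1] if i1 + 1 < p else buf[i1 + 2]
        q1 = a0 * (1.0 - f1) + a1 * f1
        b0 = buf[i3] if i3 < p else buf[i3 + 1]
        b1 = buf[i3 + 1] if i3 + 1 < p else buf[i3 + 2]
        q3 = b0 * (1.0 - f3) + b1 * f3
        qd[i] = 0.5 * (q3 - q1)
    return med, qd


def _rolling_center_excluded_np(x, w):
    """Reference implementation: brute force per index (slow, exact)."""
    n = x.shape[0]
    med = np.full(n, np.nan)
    qd = np.full(n, np.nan)
    if n < w:
        return med, qd
    half = w // 2
    for i in range(n):
        lo = min(max(i - half, 0), n - w)
        nb = np.delete(x[lo : lo + w], i - lo)
        med[i] = np.median(nb)
        qd[i] = 0.5 * (np.percentile(nb, 75) - np.percentile(nb, 25))
    return med, qd


def rolling_center_excluded(x: np.ndarray, window_beats: int):
    """Rolling median and quartile deviation of the ``window_beats``-wide
    neighborhood of each sample, excluding the sample itself.

    Windows are clamped at the series boundaries (each index still sees a
    full ``window_beats``-sized window).  Returns ``(median, qd)`` arrays;
    all-NaN when the series is shorter than the window.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if HAVE_NUMBA:
        return _rolling_center_excluded_nb(x, window_beats)
    return _rolling_center_excluded_np(x, window_beats)


@njit(cache=True)
def _ar1_blocks_nb(mean_b, sigma_b, rho_b, block_s, eps, z0, t_end):
    """Generate AR(1) inter-beat intervals block by block.

    The standardized state z (zero mean, unit variance) is carried across
    block boundaries so the lag-1 autocorrelation holds through parameter
    changes; within a block the process is stationary with the block's
    (mean, sigma, rho).
    """
    n_max = eps.shape[0]
    ibi = np.empty(n_max)
    t = np.empty(n_max)
    z = z0
    k = 0
    now = 0.0
    nb = mean_b.shape[0]
    for b in range(nb):
        block_end = (b + 1) * block_s
        if block_end > t_end:
            block_end = t_end
        mu = mean_b[b]
        sg = sigma_b[b]
        rh = rho_b[b]
        innov = np.sqrt(1.0 - rh * rh)
        while now < block_end:
            if k >= n_max:
                return ibi[:k], t[:k], z, False
            z = rh * z + innov * eps[k]
            v = mu + sg * z
            if v < 250.0:
                v = 250.0
            ibi[k] = v
            now += v / 1000.0
            t[k] = now
            k += 1
        if now >= t_end:
            break
    return ibi[:k], t[:k], z, True


def _ar1_blocks_np(mean_b, sigma_b, rho_b, block_s, eps, z0, t_end):
    n_max = eps.shape[0]
    ibi = np.empty(n_max)
    t = np.empty(n_max)
    z = z0
    k = 0
    now = 0.0
    for b in range(mean_b.shape[0]):
        block_end = min((b + 1) * block_s, t_end)
        mu, sg, rh = mean_b[b], sigma_b[b], rho_b[b]
        innov = np.sqrt(1.0 - rh * rh)
        while now < block_end:
            if k >= n_max:
                return ibi[:k], t[:k], z, False
            z = rh * z + innov * eps[k]
            v = max(mu + sg * z, 250.0)
            ibi[k] = v
            now += v / 1000.0
            t[k] = now
            k += 1
        if now >= t_end:
            break
    return ibi[:k], t[:k], z, True


def ar1_blocks(mean_b, sigma_b, rho_b, block_s, eps, z0, t_end):
    mean_b = np.ascontiguousarray(mean_b, dtype=np.float64)
    sigma_b = np.ascontiguousarray(sigma_b, dtype=np.float64)
    rho_b = np.ascontiguousarray(rho_b, dtype=np.float64)
    eps = np.ascontiguousarray(eps, dtype=np.float64)
    if HAVE_NUMBA:
        return _ar1_blocks_nb(mean_b, sigma_b, rho_b, float(block_s), eps, float(z0), float(t_end))
    return _ar1_blocks_np(mean_b, sigma_b, rho_b, float(block_s), eps, float(z0), float(t_end))


@njit(cache=True, fastmath=True)
def _flag_outliers_nb(x, w, coef_sd, floor):
    """Fused artifact screen: center-excluded rolling median / quartile
    deviation with the threshold comparison applied in-loop."""
    n = x.shape[0]
    flags = np.zeros(n, np.uint8)
    if n < w:
        return flags
    half = w // 2
    m = w - 1  # even for odd w
    kml = m // 2 - 1
    q1pos = 0.25 * (m - 1)
    i1 = int(q1pos)
    f1 = q1pos - i1
    q3pos = 0.75 * (m - 1)
    i3 = int(q3pos)
    f3 = q3pos - i3
    buf = np.sort(x[:w].copy())
    lo = 0
    for i in range(n):
        nlo = i - half
        if nlo < 0:
            nlo = 0
        elif nlo > n - w:
            nlo = n - w
        while lo < nlo:
            old = x[lo]
            new = x[lo + w]
            a = 0
            b = w
            while a < b:
                c = (a + b) >> 1
                if buf[c] < old:
                    a = c + 1
                else:
                    b = c
            if new >= old:
                j = a
                while j + 1 < w and buf[j + 1] < new:
                    buf[j] = buf[j + 1]
                    j += 1
                buf[j] = new
            else:
                j = a
                while j - 1 >= 0 and buf[j - 1] > new:
                    buf[j] = buf[j - 1]
                    j -= 1
                buf[j] = new
            lo += 1
        v = x[i]
        a = 0
        b = w
        while a < b:
            c = (a + b) >> 1
            if buf[c] < v:
                a = c + 1
            else:
                b = c
        p = a
        k = kml
        s0 = buf[k] if k < p else buf[k + 1]
        k = kml + 1
        s1 = buf[k] if k < p else buf[k + 1]
        dev = v - 0.5 * (s0 + s1)
        if dev < 0.0:
            dev = -dev
        if dev <= floor:
            continue
        a0 = buf[i1] if i1 < p else buf[i1 + 1]
        a1 = buf[i1 + 1] if i1 + 1 < p else buf[i1 + 2]
        q1 = a0 * (1.0 - f1) + a1 * f1
        b0 = buf[i3] if i3 < p else buf[i3 + 1]
        b1 = buf[i3 + 1] if i3 + 1 < p else buf[i3 + 2]
        q3 = b0 * (1.0 - f3) + b1 * f3
        thr = coef_sd * 0.5 * (q3 - q1)
        if thr < floor:
            thr = floor
        if dev > thr:
            flags[i] = 1
    return flags


def flag_outliers(x: np.ndarray, window_beats: int, coef_sd: float, floor: float) -> np.ndarray:
    """Artifact flags: |x_i - local median| > max(coef_sd * local robust
    SD-scaled quartile deviation, floor), neighborhood excluding i.
    Equivalent to thresholding :func:`rolling_center_excluded` output."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if HAVE_NUMBA:
        return _flag_outliers_nb(x, window_beats, float(coef_sd), float(floor))
    med, qd = _rolling_center_excluded_np(x, window_beats)
    flags = np.zeros(x.shape[0], np.uint8)
    if x.shape[0] >= window_beats:
        flags[np.abs(x - med) > np.maximum(coef_sd * qd, floor)] = 1
    return flags
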