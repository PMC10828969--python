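"""Bivariate standard-normal orthant probabilities.

The liability-threshold likelihoods in this package reduce every pair outcome
to upper-orthant probabilities P(X > t1, Y > t2) of a standard bivariate
normal.  These are computed with Genz's Gauss-Legendre scheme on the arcsine
identity (the classic tvpack ``BVND`` algorithm), which is accurate to
~1e-15 absolute error over the whole correlation range, including the
near-singular region |rho| > 0.925 where a separate expansion is used.

All routines broadcast over numpy arrays; correlation may vary elementwise.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = ["orthant_upper", "bvn_cdf"]

# 20-point Gauss-Legendre abscissae/weights on (0, 1), as used by tvpack
_XGL = np.array(
    [
        0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
        0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
        0.5108670019508271, 0.3737060887154195, 0.2277858511416451,
        0.0765265211334973,
    ]
)
_WGL = np.array(
    [
        0.0176140071391521, 0.0406014298003869, 0.0626720483341091,
        0.0832767415767048, 0.1019301198172404, 0.1181945319615184,
        0.1316886384491766, 0.1420961093183820, 0.1491729864726037,
        0.1527533871307258,
    ]
)

_TWOPI = 2.0 * np.pi


def _bvnu_moderate(h, k, r):
    """Upper orthant for |r| <= 0.925 (vectorised arcsine-identity quadrature)."""
    hk = h * k
    hs = 0.5 * (h * h + k * k)
    asr = np.arcsin(r)
    acc = np.zeros(np.broadcast(h, k, r).shape)
    for x, w in zip(_XGL, _WGL):
        for s in (-1.0, 1.0):
            sn = np.sin(0.5 * asr * (s * x + 1.0))
            acc += w * np.exp((sn * hk - hs) / (1.0 - sn * sn))
    return acc * asr / (2.0 * _TWOPI) + norm.sf(h) * norm.sf(k)


def _bvnu_extreme(h, k, r):
    """Upper orthant for 0.925 < |r| < 1 (vectorised tvpack tail expansion)."""
    neg = r < 0
    k = np.where(neg, -k, k)
    hk = h * k
    a2 = (1.0 - r) * (1.0 + r)  # 1 - r^2
    a = np.sqrt(a2)
    bs = (h - k) ** 2
    c = (4.0 - hk) / 8.0
    d = (12.0 - hk) / 16.0
    asr = -0.5 * (bs / a2 + hk)
    bvn = np.where(
        asr > -100.0,
        a * np.exp(asr) * (1.0 - c * (bs - a2) * (1.0 - d * bs / 5.0) / 3.0
                           + c * d * a2 * a2 / 5.0),
        0.0,
    )
    b = np.sqrt(bs)
    tail = np.exp(-0.5 * hk) * np.sqrt(_TWOPI) * norm.cdf(-b / a) * b \
        * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0)
    bvn = bvn - np.where(-hk < 100.0, tail, 0.0)
    ah = 0.5 * a
    for x, w in zip(_XGL, _WGL):
        for s in (-1.0, 1.0):
            xs = (ah * (s * x + 1.0)) ** 2
            rs = np.sqrt(1.0 - xs)
            asr = -0.5 * (bs / xs + hk)
            sp = 1.0 + c * xs * (1.0 + d * xs)
            ep = np.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
            bvn = bvn + np.where(asr > -100.0,
                                 ah * w * np.exp(asr) * (ep - sp), 0.0)
    bvn = -bvn / _TWOPI
    pos_part = bvn + norm.sf(np.maximum(h, k))
    neg_part = -bvn + np.where(k > h, norm.cdf(k) - norm.cdf(h), 0.0)
    return np.where(neg, neg_part, pos_part)


def orthant_upper(t1, t2, rho):
    """P(X > t1, Y > t2) for a standard bivariate normal with correlation rho.

    Parameters
    ----------
    t1, t2 : array_like
        Liability cutoffs (finite).
    rho : array_like
        Correlation(s) in [-1, 1].

    Returns
    -------
    ndarray or float
        Upper-orthant probability, absolute error below 1e-12.

    Raises
    ------
    ValueError
        If any ``|rho| > 1`` or any cutoff is not finite.
    """
    h = np.asarray(t1, dtype=float)
    k = np.asarray(t2, dtype=float)
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlation must lie in [-1, 1]")
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(k))):
        raise ValueError("cutoffs must be finite")
    h, k, r = np.broadcast_arrays(h, k, r)
    shape = h.shape
    h, k, r = np.atleast_1d(h).ravel(), np.atleast_1d(k).ravel(), np.atleast_1d(r).ravel()
    out = np.empty(h.shape)

    mod = np.abs(r) <= 0.925
    ext = (~mod) & (np.abs(r) < 1.0)
    sing = np.abs(r) == 1.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore",
                     under="ignore"):
        if mod.any():
            out[mod] = _bvnu_moderate(h[mod], k[mod], r[mod])
        if ext.any():
            out[ext] = _bvnu_extreme(h[ext], k[ext], r[ext])
    if sing.any():
        hi, ki, ri = h[sing], k[sing], r[sing]
        comono = norm.sf(np.maximum(hi, ki))
        counter = np.maximum(0.0, 1.0 - norm.cdf(hi) - norm.cdf(ki))
        out[sing] = np.where(ri > 0, comono, counter)
    out = np.clip(out, 0.0, 1.0).reshape(shape)
    return out.item() if out.ndim == 0 else out


def bvn_cdf(t1, t2, rho):
    """P(X <= t1, Y <= t2); complement identity on :func:`orthant_upper`."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    return orthant_upper(-t1, -t2, rho)
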