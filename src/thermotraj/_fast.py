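"""Numba-compiled evaluation of the Laplace marginal negative log-likelihood.

Numerically identical to the numpy reference in :mod:`thermotraj.de_models`
(asserted by the test suite); only the evaluation strategy differs. Falls
back transparently when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by the fit paths
    from numba import njit

    AVAILABLE = True
except ImportError:  # pragma: no cover
    AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco


_ETA_CLIP = 30.0


@njit(cache=True)
def _loglik_scalar(y: float, mu: float, r: float, is_nb: bool) -> float:
    if is_nb:
        ll = (
            math.lgamma(y + r)
            - math.lgamma(r)
            - math.lgamma(y + 1.0)
            - r * math.log1p(mu / r)
        )
        if y > 0.0:
            ll += y * math.log(mu / (r + mu))
        return ll
    ll = -mu - math.lgamma(y + 1.0)
    if y > 0.0:
        ll += y * math.log(mu)
    return ll


@njit(cache=True)
def negll(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    p: int,
    is_nb: bool,
    is_random: bool,
) -> float:
    n = y.shape[0]
    eta0 = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += X[i, j] * theta[j]
        if s > _ETA_CLIP:
            s = _ETA_CLIP
        elif s < -_ETA_CLIP:
            s = -_ETA_CLIP
        eta0[i] = s

    idx = p
    r = 1.0
    if is_nb:
        r = math.exp(-theta[idx])
        idx += 1

    if not is_random:
        ll = 0.0
        for i in range(n):
            ll += _loglik_scalar(y[i], math.exp(eta0[i]), r, is_nb)
        if math.isnan(ll) or math.isinf(ll):
            return 1e12
        return -ll

    sigma = math.exp(theta[idx])
    sigma2 = sigma * sigma
    b = np.zeros(n_groups)
    score = np.empty(n_groups)
    hess = np.empty(n_groups)
    for _ in range(100):
        for k in range(n_groups):
            score[k] = -b[k] / sigma2
            hess[k] = -1.0 / sigma2
        for i in range(n):
            k = group_idx[i]
            eta = eta0[i] + b[k]
            if eta > _ETA_CLIP:
                eta = _ETA_CLIP
            elif eta < -_ETA_CLIP:
                eta = -_ETA_CLIP
            mu = math.exp(eta)
            if is_nb:
                score[k] += r * (y[i] - mu) / (r + mu)
                hess[k] += -r * mu * (r + y[i]) / ((r + mu) * (r + mu))
            else:
                score[k] += y[i] - mu
                hess[k] += -mu
        max_step = 0.0
        for k in range(n_groups):
            step = score[k] / hess[k]
            if step > 3.0:
                step = 3.0
            elif step < -3.0:
                step = -3.0
            b[k] -= step
            a = abs(step)
            if a > max_step:
                max_step = a
        if max_step < 1e-11:
            break

    ll = 0.0
    W = np.zeros(n_groups)
    for i in range(n):
        k = group_idx[i]
        eta = eta0[i] + b[k]
        if eta > _ETA_CLIP:
            eta = _ETA_CLIP
        elif eta < -_ETA_CLIP:
            eta = -_ETA_CLIP
        mu = math.exp(eta)
        ll += _loglik_scalar(y[i], mu, r, is_nb)
        if is_nb:
            W[k] += r * mu * (r + y[i]) / ((r + mu) * (r + mu))
        else:
            W[k] += mu
    for k in range(n_groups):
        ll -= b[k] * b[k] / (2.0 * sigma2)
        w = W[k]
        if w < 0.0:
            w = 0.0
        ll -= 0.5 * math.log1p(sigma2 * w)
    if math.isnan(ll) or math.isinf(ll):
        return 1e12
    return -ll
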