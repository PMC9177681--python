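"""Compiled inner loops for the sequential belief filters.

These functions are the single source of truth for the batch update
recursions; :mod:`predcontrol.perceptual` wraps them into trajectory
containers and the pure-Python steppers in :mod:`predcontrol.synthetic`
are cross-checked against them in the test suite.
"""

import math

import numpy as np
from numba import njit

# second-level mean clamp keeping the sigmoid finite in float64
MU2_CLAMP = 36.0


@njit(cache=True)
def rw_filter(y, alpha, v0):
    """Fixed-learning-rate delta rule.

    Returns (pred, post): pred[t] is the prediction V(t-1) held before
    outcome y[t]; post[t] the updated value after it.
    """
    n = y.shape[0]
    pred = np.empty(n)
    post = np.empty(n)
    v = v0
    for t in range(n):
        pred[t] = v
        v = v + alpha * (y[t] - v)
        post[t] = v
    return pred, post


@njit(cache=True)
def kf_filter(y, pi, omega, k0, mu0):
    """Kalman filter with gain recursion K <- (K + pi*omega)/(K + pi*omega + 1).

    Returns (pred, gain): pred[t] is the belief before outcome y[t],
    gain[t] the gain used to move from pred[t] to pred[t+1].
    """
    n = y.shape[0]
    pred = np.empty(n)
    gain = np.empty(n)
    mu = mu0
    k = k0
    po = pi * omega
    for t in range(n):
        pred[t] = mu
        k = (k + po) / (k + po + 1.0)
        gain[t] = k
        mu = mu + k * (y[t] - mu)
    return pred, gain


@njit(cache=True)
def hgf2_filter(y, omega, mu2_0, sigma2_0):
    """Two-level binary hierarchical Gaussian filter.

    Level 1 is the Bernoulli intrusion outcome, level 2 a Gaussian
    random walk on its log-odds tendency with step variance exp(omega).
    Per trial, with s() the logistic sigmoid:

        mu1hat = s(mu2)                     prediction
        delta1 = y - mu1hat                 first-level PE
        pi2hat = 1 / (sigma2 + exp(omega))  predicted 2nd-level precision
        pi2    = pi2hat + mu1hat (1-mu1hat) posterior 2nd-level precision
        mu2   += delta1 / pi2               uncertainty-weighted update

    Returns (mu1hat, mu2, sigma2, pi1hat, psi, delta1) with psi = 1/pi2
    the update weight and pi1hat = 1/(mu1hat (1-mu1hat)) the first-level
    prediction precision.
    """
    n = y.shape[0]
    mu1hat = np.empty(n)
    mu2_tr = np.empty(n)
    sigma2_tr = np.empty(n)
    pi1hat = np.empty(n)
    psi = np.empty(n)
    delta1 = np.empty(n)
    mu2 = mu2_0
    sigma2 = sigma2_0
    w = math.exp(omega)
    for t in range(n):
        m1 = 1.0 / (1.0 + math.exp(-mu2))
        mu1hat[t] = m1
        var1 = m1 * (1.0 - m1)
        pi1hat[t] = 1.0 / var1
        d = y[t] - m1
        delta1[t] = d
        pi2hat = 1.0 / (sigma2 + w)
        pi2 = pi2hat + var1
        sigma2 = 1.0 / pi2
        psi[t] = sigma2
        mu2 = mu2 + sigma2 * d
        if mu2 > MU2_CLAMP:
            mu2 = MU2_CLAMP
        elif mu2 < -MU2_CLAMP:
            mu2 = -MU2_CLAMP
        mu2_tr[t] = mu2
        sigma2_tr[t] = sigma2
    return mu1hat, mu2_tr, sigma2_tr, pi1hat, psi, delta1
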