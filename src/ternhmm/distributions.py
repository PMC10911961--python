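"""State-dependent distributions and covariate-linked transition matrices.

Step lengths are gamma-distributed under a mean / standard-deviation
parametrisation (shape k = (mu/sigma)^2, scale theta = sigma^2/mu); turning
angles are von Mises.  Transition probabilities follow a multinomial logit
in an optional per-time covariate, with the diagonal as reference category,
which for two states reduces to a logistic regression on each off-diagonal.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["gamma_logpdf_meansd", "vonmises_logpdf", "transition_matrix"]


def gamma_logpdf_meansd(r, mu, sigma):
    """Gamma log-density of step ``r`` with mean ``mu`` and sd ``sigma`` (km).

    Broadcasts over arrays.  Raises ``ValueError`` on non-positive arguments.
    """
    r = np.asarray(r, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(r <= 0) or np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("gamma_logpdf_meansd requires r, mu, sigma > 0")
    shape = (mu / sigma) ** 2
    scale = sigma**2 / mu
    out = ((shape - 1.0) * np.log(r) - r / scale
           - shape * np.log(scale) - special.gammaln(shape))
    return out if out.ndim else float(out)


def vonmises_logpdf(psi, rho, kappa):
    """Von Mises log-density of angle ``psi`` with mean ``rho``, concentration ``kappa``.

    ``log f = kappa * cos(psi - rho) - log(2 pi I0(kappa))``, evaluated with the
    exponentially scaled Bessel function so large concentrations do not overflow.
    ``kappa = 0`` gives the circular uniform density.
    """
    psi = np.asarray(psi, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("vonmises_logpdf requires kappa >= 0")
    log_i0 = np.log(special.i0e(kappa)) + kappa
    out = kappa * np.cos(psi - rho) - np.log(2.0 * np.pi) - log_i0
    return out if out.ndim else float(out)


def transition_matrix(beta0, beta1=None, c=0.0):
    """Row-stochastic transition matrix Gamma(c) from logit coefficients.

    Parameters
    ----------
    beta0, beta1 : (N, N) arrays
        Intercepts and covariate slopes of the linear predictors
        ``eta_ij = beta0_ij + beta1_ij * c`` for the off-diagonal transitions;
        diagonal entries are the reference category (eta_ii = 0) and are
        ignored.  ``beta1=None`` disables the covariate.
    c : float or (T,) array
        Covariate value(s); with an array, returns a (T, N, N) stack.

    For two states the off-diagonals are ``logistic(eta_ij)`` and the
    diagonals complete each row to one.
    """
    beta0 = np.asarray(beta0, dtype=float)
    n = beta0.shape[0]
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    eta = np.broadcast_to(beta0, (len(c_arr), n, n)).copy()
    if beta1 is not None:
        eta = eta + c_arr[:, None, None] * np.asarray(beta1, dtype=float)
    idx = np.arange(n)
    eta[:, idx, idx] = 0.0
    eta -= eta.max(axis=2, keepdims=True)  # row-wise stabilisation
    expeta = np.exp(eta)
    gamma = expeta / expeta.sum(axis=2, keepdims=True)
    return gamma if np.ndim(c) else gamma[0]
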