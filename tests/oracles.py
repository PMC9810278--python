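"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the closed-form linear algebra used by
the package: posteriors are computed by dense-grid quadrature over the
latents, evidences by direct density evaluation, and stationary covariances
by solving the continuous-time Lyapunov equation on the augmented
(potential, noise) linear system.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, stats


def grid_posterior_moments(A, C, sigma_x2, x, z, half_width=8.0, n_grid=121):
    """Posterior mean/cov over y by Riemann quadrature on a dense cube.

    Evaluates ``N(x; z A y, sigma_x2 I) N(y; 0, C)`` pointwise on a regular
    grid and normalises. Only feasible for <= 3 latents.
    """
    K = A.shape[1]
    axis = np.linspace(-half_width, half_width, n_grid)
    mesh = np.meshgrid(*([axis] * K), indexing="ij")
    Y = np.stack([m.ravel() for m in mesh], axis=1)  # (n_grid**K, K)

    Cinv = np.linalg.inv(C)
    log_prior = -0.5 * np.einsum("ij,jk,ik->i", Y, Cinv, Y)
    logp = np.empty(len(Y))
    chunk = 200_000
    for s in range(0, len(Y), chunk):
        resid = x[None, :] - z * (Y[s : s + chunk] @ A.T)
        logp[s : s + chunk] = -0.5 * np.sum(resid**2, axis=1) / sigma_x2
    logp += log_prior
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mean = w @ Y
    D = Y - mean
    cov = (w[:, None] * D).T @ D
    return mean, cov


def contrast_weights_direct(A, C, sigma_x2, gamma_shape, gamma_scale, x, z_grid):
    """Contrast-grid weights by direct evaluation of the marginal evidence."""
    logw = []
    for z in z_grid:
        S = z**2 * (A @ C @ A.T) + sigma_x2 * np.eye(len(x))
        logw.append(
            stats.multivariate_normal.logpdf(x, mean=np.zeros(len(x)), cov=S)
            + stats.gamma.logpdf(z, a=gamma_shape, scale=gamma_scale)
        )
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def ou_network_stationary_cov(W, k, tau, L_noise, tau_noise):
    """Stationary covariance of u for the *linear* (m=1, no rectification)
    network driven by OU noise, via the augmented Lyapunov equation.

    State (u, eta): du = diag(1/tau)(-u + k W u + eta) dt;
    deta = -eta/tau_noise dt + sqrt(2/tau_noise) L dB.
    """
    n = W.shape[0]
    Tinv = np.diag(1.0 / tau)
    F = np.zeros((2 * n, 2 * n))
    F[:n, :n] = Tinv @ (-np.eye(n) + k * W)
    F[:n, n:] = Tinv
    F[n:, n:] = -np.eye(n) / tau_noise
    Q = np.zeros((2 * n, 2 * n))
    Q[n:, n:] = (2.0 / tau_noise) * (L_noise @ L_noise.T)
    P = linalg.solve_continuous_lyapunov(F, -Q)
    return P[:n, :n]


def ring_kernel_bruteforce(orientations, kernel):
    """Evaluate a stationary orientation kernel entrywise at wrapped distances."""
    n = len(orientations)
    C = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = abs(orientations[i] - orientations[j]) % 180.0
            d = min(d, 180.0 - d)
            C[i, j] = kernel(d)
    return C


def rectified_power_mean(k, m, mu, sd, n_quad=201):
    """E[k max(u,0)^m] for u ~ N(mu, sd^2) by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    u = mu + sd * nodes
    vals = k * np.maximum(u, 0.0) ** m
    return float((weights @ vals) / np.sqrt(2.0 * np.pi))
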