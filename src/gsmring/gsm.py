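"""Gaussian scale mixture (GSM) generative model and exact Bayesian observer.

The GSM describes a small image patch ``x`` as a linear combination of
oriented Gabor features (columns of ``A``) with Gaussian coefficients
``y ~ N(0, C)``, scaled by a global contrast ``z`` drawn from a gamma prior,
plus isotropic pixel noise::

    x | y, z ~ N(z * A @ y, sigma_x2 * I)

Inference targets the posterior over the feature intensities ``y`` given a
patch. Conditioned on ``z`` the posterior is Gaussian and available in closed
form; marginalising over ``z`` is done by quadrature on a contrast grid.

The *hypoprior* perturbation broadens the prior over ``y`` by scaling its
covariance, ``C -> alpha * C`` with ``alpha > 1``, which makes the observer
over-weight sensory evidence (posterior means and SDs both increase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

__all__ = [
    "GaborParams",
    "GammaPrior",
    "RingKernel",
    "GSMModel",
    "PosteriorSummary",
    "build_gabor_bank",
    "build_prior_cov",
    "sample_patch",
    "posterior_given_z",
    "contrast_posterior",
    "posterior_moments",
    "apply_hypoprior",
    "toy1d_curves",
    "default_z_grid",
    "wrapped_orientation_distance",
]


def wrapped_orientation_distance(a, b):
    """Distance between orientations in degrees on the 180-degree ring."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def uniform_orientations(n: int) -> np.ndarray:
    """``n`` preferred orientations uniformly spaced on [-90, 90) degrees."""
    return -90.0 + 180.0 * np.arange(n) / n


@dataclass(frozen=True)
class GaborParams:
    """Parameters of the Gabor template shared by all bank columns.

    ``sigma`` (envelope SD) and ``wavelength`` are in pixels; if ``None`` they
    default to ``patch_side / 5`` and ``patch_side / 2``. ``phase`` is the
    carrier phase in radians (0 = even/cosine Gabor).
    """

    sigma: float | None = None
    wavelength: float | None = None
    phase: float = 0.0


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior over the global contrast variable ``z``."""

    shape: float = 2.0
    scale: float = 1.0

    def logpdf(self, z):
        return stats.gamma.logpdf(z, a=self.shape, scale=self.scale)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)

    def second_moment(self) -> float:
        # E[z^2] = shape*(shape+1)*scale^2 for a gamma distribution
        return self.shape * (self.shape + 1.0) * self.scale**2


@dataclass(frozen=True)
class RingKernel:
    """Stationary periodic kernel on the orientation ring (period 180 deg).

    The kernel is the periodic squared-exponential (von Mises form)
    ``variance * exp(kappa * (cos(2 pi d / 180) - 1))`` with ``kappa`` chosen
    so that for small wrapped distances ``d`` it matches a Gaussian profile
    ``exp(-d^2 / (2 width_deg^2))``. Unlike a raw wrapped Gaussian, this
    kernel is positive definite on the ring for any width.
    """

    variance: float = 1.0
    width_deg: float = 25.0
    jitter: float = 1e-9

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        kappa = (90.0 / (np.pi * self.width_deg)) ** 2
        phi = 2.0 * np.pi * d / 180.0
        return self.variance * np.exp(kappa * (np.cos(phi) - 1.0))


def default_z_grid(n: int = 80, lo: float = 1e-3, hi: float = 12.0) -> np.ndarray:
    """Log-spaced contrast grid covering the bulk of the gamma prior."""
    return np.geomspace(lo, hi, n)


def build_gabor_bank(
    n_latents: int, patch_side: int, gabor_params: GaborParams | None = None
) -> np.ndarray:
    """Build a feature matrix whose columns are oriented Gabor filters.

    Column ``k`` is the template rotated to orientation
    ``-90 + 180 * k / n_latents`` degrees (0 deg = vertical stripes). Columns
    are zero-mean-corrected and normalised to unit L2 norm so that all
    orientations carry equal energy.

    Returns a ``(patch_side**2, n_latents)`` array.
    """
    if n_latents < 2:
        raise ValueError("n_latents must be >= 2")
    if patch_side < 4:
        raise ValueError("patch_side must be >= 4")
    gp = gabor_params or GaborParams()
    sigma = gp.sigma if gp.sigma is not None else patch_side / 5.0
    wavelength = gp.wavelength if gp.wavelength is not None else patch_side / 2.0
    if sigma <= 0 or wavelength <= 0:
        raise ValueError("Gabor envelope sigma and wavelength must be > 0")

    c = (patch_side - 1) / 2.0
    xs = np.arange(patch_side) - c
    X, Y = np.meshgrid(xs, xs)  # X: column coordinate, Y: row coordinate
    env = np.exp(-(X**2 + Y**2) / (2.0 * sigma**2))
    thetas = np.deg2rad(uniform_orientations(n_latents))
    A = np.empty((patch_side**2, n_latents))
    for k, th in enumerate(thetas):
        u = X * np.cos(th) + Y * np.sin(th)
        g = env * np.cos(2.0 * np.pi * u / wavelength + gp.phase)
        g = g - g.mean()
        nrm = np.linalg.norm(g)
        if nrm == 0:
            raise ValueError("degenerate Gabor parameters produced a zero filter")
        A[:, k] = (g / nrm).ravel()
    return A


def build_prior_cov(orientations: np.ndarray, kernel_params: RingKernel | None = None) -> np.ndarray:
    """Rotationally symmetric prior covariance over feature intensities.

    ``C[i, j]`` is a stationary periodic kernel of the wrapped orientation
    distance (period 180 deg), so for uniformly spaced orientations C is
    circulant. A small diagonal jitter guards against numerical rank loss.
    """
    kp = kernel_params or RingKernel()
    th = np.asarray(orientations, dtype=float)
    D = wrapped_orientation_distance(th[:, None], th[None, :])
    C = kp(D) + kp.jitter * np.eye(len(th))
    emin = float(np.linalg.eigvalsh(C)[0])
    if emin <= 0:
        raise ValueError(
            f"prior covariance kernel is not positive definite (smallest eigenvalue {emin:.3e})"
        )
    return C


@dataclass(frozen=True)
class GSMModel:
    """The ideal observer's world model (feature bank, priors, pixel noise)."""

    A: np.ndarray
    C: np.ndarray
    sigma_x2: float
    contrast_prior: GammaPrior = field(default_factory=GammaPrior)
    orientations: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "C", C)
        if self.orientations is None:
            object.__setattr__(self, "orientations", uniform_orientations(A.shape[1]))
        if C.shape != (A.shape[1], A.shape[1]):
            raise ValueError("C must be n_latents x n_latents")
        if len(self.orientations) != A.shape[1]:
            raise ValueError("one orientation per latent required")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if np.linalg.eigvalsh(C)[0] <= 0:
            raise ValueError("C must be positive definite")
        if self.sigma_x2 <= 0:
            raise ValueError("sigma_x2 must be > 0")

    @property
    def n_latents(self) -> int:
        return self.A.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.A.shape[0]

    @classmethod
    def default(
        cls,
        n_latents: int = 32,
        patch_side: int = 16,
        sigma_x2: float = 1.0,
        gabor_params: GaborParams | None = None,
        kernel_params: RingKernel | None = None,
        contrast_prior: GammaPrior | None = None,
    ) -> "GSMModel":
        ori = uniform_orientations(n_latents)
        A = build_gabor_bank(n_latents, patch_side, gabor_params)
        C = build_prior_cov(ori, kernel_params)
        return cls(
            A=A,
            C=C,
            sigma_x2=sigma_x2,
            contrast_prior=contrast_prior or GammaPrior(),
            orientations=ori,
        )


@dataclass
class PosteriorSummary:
    """Mean/covariance of the posterior over feature intensities for one patch."""

    mean: np.ndarray
    cov: np.ndarray
    stimulus_id: str | None = None
    contrast_grid_used: np.ndarray | None = None

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def sample_patch(model: GSMModel, z="from-prior", seed: int = 0):
    """Draw one patch ``x = z*A@y + noise`` from the forward model.

    Returns ``(x, record)`` where ``record`` holds the latents ``y`` and ``z``
    actually used (needed by tests and by training-sample generation).
    """
    rng = np.random.default_rng(seed)
    if isinstance(z, str):
        if z != "from-prior":
            raise ValueError("z must be a nonnegative scalar or 'from-prior'")
        zval = float(model.contrast_prior.sample(rng))
    else:
        zval = float(z)
        if zval < 0:
            raise ValueError("contrast z must be nonnegative")
    y = rng.multivariate_normal(np.zeros(model.n_latents), model.C, method="cholesky")
    eps = rng.normal(0.0, np.sqrt(model.sigma_x2), size=model.n_pixels)
    x = zval * model.A @ y + eps
    return x, {"y": y, "z": zval}


def posterior_given_z(model: GSMModel, x: np.ndarray, z: float) -> PosteriorSummary:
    """Closed-form Gaussian posterior over ``y`` for a known contrast ``z``.

    ``cov = (C^-1 + z^2 A^T A / sigma_x2)^-1`` and
    ``mean = cov @ (z A^T x / sigma_x2)``, evaluated in the numerically
    stable Woodbury form ``cov = C - z^2 C A^T S^-1 A C`` with
    ``S = sigma_x2 I + z^2 A C A^T`` (the prior covariance of a smooth ring
    kernel is severely ill-conditioned, so ``C^-1`` is never formed).
    At ``z == 0`` the stimulus is uninformative and the posterior *is* the
    prior, returned exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_pixels,):
        raise ValueError("x length must match the model's pixel count")
    z = float(z)
    if z < 0:
        raise ValueError("contrast z must be nonnegative")
    if z == 0.0:
        return PosteriorSummary(
            mean=np.zeros(model.n_latents),
            cov=model.C.copy(),
            contrast_grid_used=np.array([0.0]),
        )
    mean, cov = _conditional_posterior(model, x, z)
    return PosteriorSummary(mean=mean, cov=cov, contrast_grid_used=np.array([z]))


def _conditional_posterior(model: GSMModel, x: np.ndarray, z: float):
    """Woodbury-form Gaussian posterior (mean, cov) over y for known z > 0."""
    CA = model.C @ model.A.T  # (K, P)
    S = model.sigma_x2 * np.eye(model.n_pixels) + z**2 * (model.A @ CA)
    cf = cho_factor(S)
    cov = model.C - z**2 * CA @ cho_solve(cf, CA.T)
    cov = 0.5 * (cov + cov.T)
    mean = z * CA @ cho_solve(cf, x)
    return mean, cov


def _marginal_eig(model: GSMModel):
    """Eigendecomposition of A C A^T, reused for evidence evaluation."""
    M = model.A @ model.C @ model.A.T
    lam, U = np.linalg.eigh(M)
    return np.clip(lam, 0.0, None), U


def contrast_posterior(model: GSMModel, x: np.ndarray, z_grid: np.ndarray) -> np.ndarray:
    """Posterior weights over the contrast grid, ``p(z | x)`` up to gridding.

    ``w(z) ∝ N(x; 0, z^2 A C A^T + sigma_x2 I) * gamma_pdf(z)``, evaluated in
    log space and normalised to sum to one.
    """
    x = np.asarray(x, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    if np.any(z_grid < 0) or np.any(np.diff(z_grid) <= 0):
        raise ValueError("z_grid must be increasing and nonnegative")
    lam, U = _marginal_eig(model)
    v2 = (U.T @ x) ** 2
    logw = np.empty(len(z_grid))
    for i, z in enumerate(z_grid):
        d = z**2 * lam + model.sigma_x2
        logw[i] = -0.5 * (np.sum(np.log(d)) + np.sum(v2 / d))
    logw += model.contrast_prior.logpdf(z_grid)
    norm = logsumexp(logw)
    if not np.isfinite(norm):
        raise FloatingPointError(
            "contrast posterior underflowed everywhere; extend or refine z_grid"
        )
    w = np.exp(logw - norm)
    return w / w.sum()


def posterior_moments(
    model: GSMModel,
    x: np.ndarray,
    z_grid: np.ndarray | None = None,
    stimulus_id: str | None = None,
) -> PosteriorSummary:
    """Posterior over ``y`` with contrast marginalised on a grid.

    Mixture-of-Gaussians moments by the law of total variance:
    ``mean = sum_z w(z) mu(z)`` and
    ``cov = sum_z w(z) (Sigma(z) + mu mu^T) - mean mean^T``.
    """
    if z_grid is None:
        z_grid = default_z_grid()
    z_grid = np.atleast_1d(np.asarray(z_grid, dtype=float))
    x = np.asarray(x, dtype=float)
    if len(z_grid) == 1:
        ps = posterior_given_z(model, x, z_grid[0])
        ps.stimulus_id = stimulus_id
        ps.contrast_grid_used = z_grid.copy()
        return ps
    w = contrast_posterior(model, x, z_grid)
    K = model.n_latents
    mean = np.zeros(K)
    second = np.zeros((K, K))
    for wi, z in zip(w, z_grid):
        if wi < 1e-15:
            continue
        if z == 0.0:
            mu = np.zeros(K)
            cov = model.C
        else:
            mu, cov = _conditional_posterior(model, x, z)
        mean += wi * mu
        second += wi * (cov + np.outer(mu, mu))
    cov = second - np.outer(mean, mean)
    cov = 0.5 * (cov + cov.T)
    return PosteriorSummary(
        mean=mean, cov=cov, stimulus_id=stimulus_id, contrast_grid_used=z_grid.copy()
    )


def apply_hypoprior(model: GSMModel, alpha: float) -> GSMModel:
    """Broaden the prior: ``C -> alpha * C`` (alpha > 1 gives a hypoprior)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if alpha < 1:
        warnings.warn(
            "alpha < 1 narrows the prior (hyperprior direction); hypopriors use alpha > 1",
            stacklevel=2,
        )
    return replace(model, C=alpha * model.C)


def toy1d_curves(
    C: float,
    A: float,
    sigma_x2: float,
    alpha: float,
    x_obs: float,
    z_values: np.ndarray,
) -> pd.DataFrame:
    """Conjugate 1D posterior mean/SD versus contrast, true prior vs hypoprior.

    Contrast is treated as known and scales the likelihood precision
    ``z^2 A^2 / sigma_x2``; each row gives the Gaussian posterior under prior
    variance ``C`` (true) and ``alpha * C`` (hypoprior).
    """
    if min(C, A, sigma_x2, alpha) <= 0:
        raise ValueError("C, A, sigma_x2, alpha must all be > 0")
    z = np.asarray(z_values, dtype=float)
    if np.any(z < 0):
        raise ValueError("z_values must be nonnegative")
    out = {"z": z}
    for tag, Cp in (("true", C), ("hypo", alpha * C)):
        prec = 1.0 / Cp + z**2 * A**2 / sigma_x2
        out[f"mean_{tag}"] = (z * A * x_obs / sigma_x2) / prec
        out[f"sd_{tag}"] = 1.0 / np.sqrt(prec)
    return pd.DataFrame(out)
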