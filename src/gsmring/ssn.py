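"""Stochastic stabilized supralinear network (SSN) on an orientation ring.

``N`` excitatory/inhibitory cell pairs are arranged on a ring by preferred
orientation. Membrane potentials follow the Langevin dynamics::

    tau_i du_i = (-u_i + h_i + sum_j W_ij r_j + eta_i) dt
    r_i = k * max(u_i, 0)**m

with eta an Ornstein-Uhlenbeck process noise with a ring-structured spatial
covariance, and W a rotationally symmetric kernel matrix obeying Dale's
principle (excitatory columns nonnegative, inhibitory columns nonpositive).
Feedforward drive is a rectified linear filtering of the image patch through
the same Gabor bank the GSM observer uses, plus a constant baseline.

Index layout: neurons 0..N-1 are E cells, N..2N-1 are I cells; pair ``i``
shares the preferred orientation ``orientations[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .gsm import GaborParams, build_gabor_bank, uniform_orientations, wrapped_orientation_distance

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "RingParams",
    "RingNetwork",
    "Trajectory",
    "build_ring",
    "feedforward_input",
    "simulate",
    "fixed_point",
    "default_nt_params",
]


@dataclass(frozen=True)
class RingParams:
    """Low-dimensional parametrization of the ring network.

    Block amplitudes ``w_xy`` are the *aggregate* synaptic weight from
    population ``y`` onto each cell of population ``x`` (the kernel rows are
    normalised to sum to one, so dynamics are insensitive to ``n_pairs``).
    All four amplitudes are stored positive; inhibitory sign is applied when
    the weight matrix is built. Widths are in degrees of preferred-orientation
    difference; time constants in ms.
    """

    n_pairs: int = 32
    # recurrent kernel: amplitude and width per block (onto <- from)
    w_ee: float = 2.09
    w_ie: float = 2.59
    w_ei: float = 1.19
    w_ii: float = 1.12
    sig_ee: float = 32.0
    sig_ie: float = 32.0
    sig_ei: float = 40.0
    sig_ii: float = 40.0
    # single-neuron properties
    tau_e: float = 20.0
    tau_i: float = 10.0
    k: float = 0.3
    m: float = 2.0
    # process noise: OU with ring-kernel spatial correlations
    noise_sd: float = 0.68
    noise_width_deg: float = 30.0
    noise_corr_frac: float = 0.75
    tau_noise: float = 20.0
    white_noise: bool = False
    # feedforward stage (I cells receive ff_i_frac times the E-cell drive)
    ff_gain: float = 0.155
    ff_i_frac: float = 0.16
    baseline: float = 0.5  # constant background drive to E cells
    baseline_i: float = 0.04  # constant background drive to I cells
    patch_side: int = 16
    gabor: GaborParams = field(default_factory=GaborParams)

    #: names of the positive kernel parameters the calibration stage may free
    FREE_NAMES = (
        "w_ee",
        "w_ie",
        "w_ei",
        "w_ii",
        "sig_ee",
        "sig_ie",
        "sig_ei",
        "sig_ii",
        "noise_sd",
        "noise_width_deg",
        "ff_gain",
        "baseline",
        "tau_e",
        "tau_i",
    )

    def to_vector(self, names) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_vector(self, names, values) -> "RingParams":
        return replace(self, **{n: float(v) for n, v in zip(names, values)})


def default_nt_params(n_pairs: int = 32) -> RingParams:
    """The package's calibrated neurotypical (NT) reference network."""
    return RingParams(n_pairs=n_pairs)


def _ring_kernel(orients: np.ndarray, width_deg: float, normalize: bool = True) -> np.ndarray:
    D = wrapped_orientation_distance(orients[:, None], orients[None, :])
    K = np.exp(-(D**2) / (2.0 * width_deg**2))
    if normalize:
        K = K / K.sum(axis=1, keepdims=True)
    return K


@dataclass
class RingNetwork:
    """A built ring network: weights, noise model, feedforward filters."""

    W: np.ndarray  # (2N, 2N)
    W_ff: np.ndarray  # (2N, n_pixels), gain included
    tau: np.ndarray  # (2N,) ms
    k: float
    m: float
    baseline: np.ndarray  # (2N,) constant background drive
    noise_cov: np.ndarray  # (2N, 2N) stationary spatial covariance of eta
    noise_chol: np.ndarray  # (2N, 2N) factor L with L L^T = noise_cov
    tau_noise: float
    white_noise: bool
    orientations: np.ndarray  # (N,) preferred orientation per pair
    params: RingParams | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.orientations)

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]

    @property
    def E(self) -> slice:
        return slice(0, self.n_pairs)

    @property
    def I(self) -> slice:  # noqa: E743
        return slice(self.n_pairs, 2 * self.n_pairs)

    def check_dale(self) -> None:
        N = self.n_pairs
        if np.any(self.W[:, :N] < 0):
            raise ValueError("Dale violation: excitatory columns must be >= 0")
        if np.any(self.W[:, N:] > 0):
            raise ValueError("Dale violation: inhibitory columns must be <= 0")

    def rates(self, u: np.ndarray, rectify: bool = True) -> np.ndarray:
        v = np.maximum(u, 0.0) if rectify else u
        return self.k * v**self.m


def build_ring(n_pairs: int | None = None, params: RingParams | None = None) -> RingNetwork:
    """Construct the network from its kernel parametrization.

    Every weight block is a row-normalised Gaussian ring kernel scaled by its
    block amplitude, with inhibitory columns negated; the process-noise
    spatial covariance is built from its own ring kernel plus an independent
    (diagonal) component.
    """
    params = params or RingParams()
    if n_pairs is not None:
        params = replace(params, n_pairs=n_pairs)
    N = params.n_pairs
    if N < 4:
        raise ValueError("n_pairs must be >= 4")
    for name in ("w_ee", "w_ie", "w_ei", "w_ii"):
        if getattr(params, name) < 0:
            raise ValueError(
                f"block amplitude {name} must be nonnegative; inhibitory sign is applied internally"
            )
    if params.tau_e <= 0 or params.tau_i <= 0 or params.k <= 0 or params.m < 1:
        raise ValueError("require tau > 0, k > 0, m >= 1")

    ori = uniform_orientations(N)
    W = np.zeros((2 * N, 2 * N))
    W[:N, :N] = params.w_ee * _ring_kernel(ori, params.sig_ee)
    W[N:, :N] = params.w_ie * _ring_kernel(ori, params.sig_ie)
    W[:N, N:] = -params.w_ei * _ring_kernel(ori, params.sig_ei)
    W[N:, N:] = -params.w_ii * _ring_kernel(ori, params.sig_ii)

    tau = np.concatenate([np.full(N, params.tau_e), np.full(N, params.tau_i)])

    # spatial correlation of the OU noise: ring kernel shared by E and I
    Kn = _ring_kernel(ori, params.noise_width_deg, normalize=False)
    full = np.tile(Kn, (2, 2))
    rho = params.noise_corr_frac
    Cn = params.noise_sd**2 * (rho * full / full[0, 0] + (1.0 - rho) * np.eye(2 * N))
    if params.noise_sd > 0:
        lam, V = np.linalg.eigh(Cn)
        lam = np.clip(lam, 0.0, None)
        L = V @ np.diag(np.sqrt(lam))
    else:
        L = np.zeros_like(Cn)

    G = build_gabor_bank(N, params.patch_side, params.gabor)
    W_ff = params.ff_gain * np.vstack([G.T, params.ff_i_frac * G.T])

    net = RingNetwork(
        W=W,
        W_ff=W_ff,
        tau=tau,
        k=params.k,
        m=params.m,
        baseline=np.concatenate([np.full(N, params.baseline), np.full(N, params.baseline_i)]),
        noise_cov=Cn,
        noise_chol=L,
        tau_noise=params.tau_noise,
        white_noise=params.white_noise,
        orientations=ori,
        params=params,
    )
    net.check_dale()
    return net


def feedforward_input(net: RingNetwork, patch: np.ndarray) -> np.ndarray:
    """Stimulus drive ``h = baseline + relu(W_ff @ patch)``, constant in time."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (net.W_ff.shape[1],):
        raise ValueError(
            f"patch length {patch.shape} does not match feedforward filters ({net.W_ff.shape[1]} pixels)"
        )
    return net.baseline + np.maximum(net.W_ff @ patch, 0.0)


@dataclass
class Trajectory:
    """One simulation run: membrane potentials on a regular time grid."""

    t: np.ndarray  # ms, (n_rec,)
    u: np.ndarray  # (n_rec, 2N)
    dt: float  # integration step, ms
    seed: int
    k: float
    m: float
    rectify: bool
    n_pairs: int
    stimulus_id: str | None = None
    onset_time: float | None = None
    delays: np.ndarray | None = None

    @property
    def r(self) -> np.ndarray:
        v = np.maximum(self.u, 0.0) if self.rectify else self.u
        return self.k * v**self.m

    @property
    def record_dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else self.dt


@njit(cache=True)
def _integrate(
    seed,
    u0,
    eta0,
    W,
    k,
    m,
    tau,
    h_pre,
    h_post,
    switch_step,
    L,
    a_eta,
    b_eta,
    white_scale,
    dt,
    n_steps,
    rec_stride,
    rectify,
    white,
):  # pragma: no cover - compiled
    np.random.seed(seed)
    n = u0.shape[0]
    n_rec = n_steps // rec_stride
    U = np.empty((n_rec, n))
    u = u0.copy()
    eta = eta0.copy()
    has_noise = np.any(L != 0.0)
    irec = 0
    bad_step = -1
    for step in range(n_steps):
        if rectify:
            v = np.maximum(u, 0.0)
        else:
            v = u
        r = k * v**m
        rec = np.dot(W, r)
        du = np.empty(n)
        for i in range(n):
            h_i = h_pre[i] if step < switch_step[i] else h_post[i]
            du[i] = (dt / tau[i]) * (-u[i] + h_i + rec[i] + eta[i])
        if has_noise:
            xi = np.random.standard_normal(n)
            Lxi = np.dot(L, xi)
            if white:
                for i in range(n):
                    du[i] += (white_scale / tau[i]) * Lxi[i]
            else:
                for i in range(n):
                    eta[i] = a_eta * eta[i] + b_eta * Lxi[i]
        u = u + du
        if (step & 255) == 0:
            ok = True
            for i in range(n):
                if not np.isfinite(u[i]) or np.abs(u[i]) > 1e7:
                    ok = False
                    break
            if not ok:
                bad_step = step
                break
        if (step + 1) % rec_stride == 0:
            U[irec] = u
            irec += 1
    return U, irec, bad_step


def simulate(
    net: RingNetwork,
    h: np.ndarray,
    duration: float,
    dt: float = 0.25,
    seed: int = 0,
    record_every: float = 1.0,
    u0: np.ndarray | None = None,
    h_pre: np.ndarray | None = None,
    switch_times: np.ndarray | None = None,
    rectify: bool = True,
    stimulus_id: str | None = None,
) -> Trajectory:
    """Euler-Maruyama integration of the network SDE.

    ``h`` is the (post-onset) input; if ``h_pre``/``switch_times`` are given,
    neuron ``i`` receives ``h_pre[i]`` until ``switch_times[i]`` ms and ``h[i]``
    afterwards (used by the transient-onset protocol). OU noise uses the
    exact one-step update; the white-noise variant adds ``L xi sqrt(dt)``
    directly to the potential equation.

    Bit-reproducible given (parameters, seed, dt).
    """
    n = net.n_neurons
    if dt > np.min(net.tau) / 10.0:
        raise ValueError("dt must be <= min(tau)/10 for a faithful integration")
    h = np.asarray(h, dtype=float)
    if h.shape != (n,):
        raise ValueError("h must have one entry per neuron")
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    if n_steps < rec_stride:
        raise ValueError("duration too short for the requested record_every")

    h_pre_arr = h.copy() if h_pre is None else np.asarray(h_pre, dtype=float)
    if switch_times is None:
        switch_step = np.zeros(n, dtype=np.int64)
    else:
        switch_step = np.asarray(
            np.ceil(np.asarray(switch_times, dtype=float) / dt), dtype=np.int64
        )
    u0 = np.zeros(n) if u0 is None else np.asarray(u0, dtype=float).copy()

    # initial OU state drawn from its stationary law (fixed, seed-derived)
    rng = np.random.default_rng((int(seed) % (2**32)) ^ 0x5EED)
    if net.white_noise or not np.any(net.noise_chol):
        eta0 = np.zeros(n)
    else:
        eta0 = net.noise_chol @ rng.standard_normal(n)

    a_eta = float(np.exp(-dt / net.tau_noise))
    b_eta = float(np.sqrt(max(0.0, 1.0 - a_eta**2)))
    white_scale = float(np.sqrt(dt))

    U, n_rec, bad_step = _integrate(
        int(seed) % (2**32),
        u0,
        eta0,
        net.W,
        float(net.k),
        float(net.m),
        net.tau,
        h_pre_arr,
        h,
        switch_step,
        net.noise_chol,
        a_eta,
        b_eta,
        white_scale,
        float(dt),
        n_steps,
        rec_stride,
        rectify,
        bool(net.white_noise),
    )
    if bad_step >= 0:
        raise FloatingPointError(
            f"network diverged at t = {bad_step * dt:.1f} ms (non-finite or huge potential)"
        )
    t = dt * rec_stride * np.arange(1, n_rec + 1)
    return Trajectory(
        t=t,
        u=U[:n_rec],
        dt=dt,
        seed=int(seed),
        k=net.k,
        m=net.m,
        rectify=rectify,
        n_pairs=net.n_pairs,
        stimulus_id=stimulus_id,
        onset_time=None if switch_times is None else float(np.min(switch_step) * dt),
        delays=None,
    )


def fixed_point(
    net: RingNetwork,
    h: np.ndarray,
    u0: np.ndarray | None = None,
    rectify: bool = True,
    tol: float = 1e-12,
) -> np.ndarray:
    """Deterministic equilibrium of the drift, ``u* = h + W r(u*)``.

    Newton-type root solve with an analytic Jacobian; falls back to a
    noise-free relaxation for the initial guess if the first attempt fails.
    The returned state satisfies ``||-u* + h + W r(u*)||_inf < 1e-10``.
    """
    h = np.asarray(h, dtype=float)
    n = net.n_neurons

    def F(u):
        return -u + h + net.W @ net.rates(u, rectify)

    def J(u):
        if rectify:
            v = np.maximum(u, 0.0)
            gain = np.where(u > 0, net.k * net.m * v ** (net.m - 1.0), 0.0)
        elif net.m == 1.0:
            gain = np.full(n, net.k)
        else:
            gain = net.k * net.m * np.sign(u) * np.abs(u) ** (net.m - 1.0)
        return -np.eye(n) + net.W * gain[None, :]

    guesses = []
    if u0 is not None:
        guesses.append(np.asarray(u0, dtype=float))
    guesses.append(h.copy())
    sol = None
    for guess in guesses:
        res = optimize.root(F, guess, jac=J, method="hybr", tol=tol)
        if res.success and np.max(np.abs(F(res.x))) < 1e-10:
            sol = res.x
            break
    if sol is None:
        # relax the noise-free ODE to get into the basin, then polish
        u = guesses[-1].copy()
        dt = float(np.min(net.tau)) / 20.0
        for _ in range(int(2000.0 / dt)):
            u = u + dt / net.tau * F(u)
            if not np.all(np.isfinite(u)):
                break
        if np.all(np.isfinite(u)):
            res = optimize.root(F, u, jac=J, method="hybr", tol=tol)
            if res.success and np.max(np.abs(F(res.x))) < 1e-10:
                sol = res.x
    if sol is None:
        resid = float(np.max(np.abs(F(res.x)))) if res is not None else np.inf
        raise RuntimeError(f"fixed point search did not converge (residual {resid:.3e})")
    return sol
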