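"""Desk-scale moment-matching calibration of the ring network.

The reference network was originally obtained by large-scale training; here
the network's low-dimensional kernel parametrization is fitted instead, by
derivative-free minimisation of a moment-matching loss: squared error
between the network's stationary E-cell potential moments and per-stimulus
targets (e.g., GSM posterior means/variances mapped latent-i <-> E-cell-i).

Common random numbers (one fixed simulation seed per stimulus, shared by all
parameter evaluations) make the loss quasi-deterministic, which lets a
Nelder-Mead search over log-parameters behave like a smooth local optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .gsm import GSMModel, posterior_moments
from .ssn import RingNetwork, RingParams, build_ring, feedforward_input, simulate
from .stimuli import StimulusBank

__all__ = [
    "CalibrationTarget",
    "SimProtocol",
    "estimate_moments",
    "targets_from_gsm",
    "targets_from_network",
    "moment_loss",
    "calibrate",
]

UNSTABLE_PENALTY = 1e8


@dataclass
class CalibrationTarget:
    """Per-stimulus target moments for the E-cell membrane potentials."""

    ids: list[str]
    mean_u: np.ndarray  # (n_stimuli, n_pairs)
    var_u: np.ndarray  # (n_stimuli, n_pairs)

    def __post_init__(self):
        if self.mean_u.shape != self.var_u.shape or len(self.ids) != self.mean_u.shape[0]:
            raise ValueError("inconsistent target dimensions")


@dataclass(frozen=True)
class SimProtocol:
    """Simulation settings used to estimate stationary moments during fitting.

    Deliberately cheaper than the final analysis protocol: moderate duration,
    coarse thinning. ``seed`` is the common-random-number base seed.
    """

    duration: float = 20000.0
    dt: float = 0.5
    burn_in: float = 500.0
    thin: float = 20.0
    seed: int = 1000


def estimate_moments(net: RingNetwork, h: np.ndarray, protocol: SimProtocol, seed_offset: int = 0):
    """Stationary mean and variance of E-cell u under one stimulus drive."""
    traj = simulate(
        net,
        h,
        duration=protocol.duration,
        dt=protocol.dt,
        seed=protocol.seed + seed_offset,
        record_every=protocol.thin,
    )
    N = net.n_pairs
    keep = traj.t > protocol.burn_in
    u = traj.u[keep, :N]
    return u.mean(axis=0), u.var(axis=0, ddof=1)


def targets_from_network(net: RingNetwork, bank: StimulusBank, protocol: SimProtocol) -> CalibrationTarget:
    """Targets measured from a known network (used for recovery experiments)."""
    means, vars_ = [], []
    for i in range(len(bank)):
        h = feedforward_input(net, bank.patches[i])
        m, v = estimate_moments(net, h, protocol, seed_offset=i)
        means.append(m)
        vars_.append(v)
    return CalibrationTarget(ids=list(bank.ids), mean_u=np.array(means), var_u=np.array(vars_))


def targets_from_gsm(model: GSMModel, bank: StimulusBank, z_grid=None) -> CalibrationTarget:
    """GSM posterior moments as network targets (latent i <-> E cell i)."""
    means, vars_ = [], []
    for i in range(len(bank)):
        ps = posterior_moments(model, bank.patches[i], z_grid, stimulus_id=bank.ids[i])
        means.append(ps.mean)
        vars_.append(np.diag(ps.cov))
    return CalibrationTarget(ids=list(bank.ids), mean_u=np.array(means), var_u=np.array(vars_))


def moment_loss(
    param_vector: np.ndarray,
    free_names,
    base_params: RingParams,
    targets: CalibrationTarget,
    patches: np.ndarray,
    protocol: SimProtocol,
    lam: float = 1.0,
    log: list | None = None,
) -> float:
    """Moment-matching loss; unstable candidates get a large finite penalty."""
    try:
        params = base_params.with_vector(free_names, param_vector)
        net = build_ring(params=params)
    except (ValueError, np.linalg.LinAlgError):
        if log is not None:
            log.append("invalid parameter vector")
        return UNSTABLE_PENALTY
    total = 0.0
    for i in range(len(targets.ids)):
        h = feedforward_input(net, patches[i])
        try:
            m, v = estimate_moments(net, h, protocol, seed_offset=i)
        except FloatingPointError:
            if log is not None:
                log.append(f"unstable at stimulus {targets.ids[i]}")
            return UNSTABLE_PENALTY
        total += float(np.sum((m - targets.mean_u[i]) ** 2))
        if lam > 0:
            total += lam * float(np.sum((v - targets.var_u[i]) ** 2))
    return total


def calibrate(
    init_params: RingParams,
    free_names,
    targets: CalibrationTarget,
    patches: np.ndarray,
    protocol: SimProtocol | None = None,
    budget: int = 200,
    lam: float = 1.0,
    seed: int = 0,
    xatol: float = 1e-3,
    restarts: int = 1,
) -> tuple[RingNetwork, dict]:
    """Nelder-Mead search over log-parameters with a monotone acceptance rule.

    The best-so-far parameter vector is tracked explicitly, so the returned
    loss is never worse than the initial one; ``budget`` caps the number of
    loss evaluations (0 returns the initial network unchanged). The budget is
    split across ``restarts + 1`` rounds, each re-initialising the simplex at
    the best point found so far — near-degenerate parameter combinations
    (e.g. E-to-I versus I-to-I amplitude trade-offs seen only through E-cell
    moments) stall a single simplex, and a fresh one escapes the ridge.
    """
    protocol = protocol or SimProtocol()
    free_names = list(free_names)
    x0 = np.log(init_params.to_vector(free_names))
    trace: list[float] = []
    issues: list[str] = []
    best = {"x": x0.copy(), "loss": np.inf}

    def objective(logx):
        loss = moment_loss(
            np.exp(logx), free_names, init_params, targets, patches, protocol, lam, issues
        )
        trace.append(loss)
        if loss < best["loss"]:
            best["loss"] = loss
            best["x"] = logx.copy()
        return loss

    init_loss = objective(x0)
    if not np.isfinite(init_loss) or init_loss >= UNSTABLE_PENALTY:
        raise RuntimeError(f"initial network is unstable under the protocol: {issues}")
    if budget > 0:
        rounds = max(1, restarts + 1)
        per_round = max(1, budget // rounds)
        for _ in range(rounds):
            optimize.minimize(
                objective,
                best["x"].copy(),
                method="Nelder-Mead",
                options={"maxfev": per_round, "xatol": xatol, "fatol": 0.0, "adaptive": True},
            )
    final = init_params.with_vector(free_names, np.exp(best["x"]))
    net = build_ring(params=final)
    report = {
        "free_names": free_names,
        "initial_loss": float(init_loss),
        "final_loss": float(best["loss"]),
        "loss_trace": [float(v) for v in trace],
        "n_evaluations": len(trace),
        "budget": budget,
        "protocol_seed": protocol.seed,
        "seed": seed,
        "lam": lam,
        "initial_params": init_params.to_vector(free_names).tolist(),
        "final_params": np.exp(best["x"]).tolist(),
        "issues": issues,
    }
    return net, report
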