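"""Inhibitory deficit with homeostatic excitatory compensation.

The ASD-network is produced from the NT-network by two column scalings of
the recurrent weight matrix:

* ``scale_inhibition``: inhibitory columns are multiplied by ``1 - delta_I``
  (the inhibitory deficit, the single free parameter of the perturbation);
* ``scale_excitation``: excitatory columns are multiplied by ``1 - delta_E``,
  where ``delta_E`` is chosen by grid-search minimisation of the homeostatic
  cost ``C_h(delta_E) = |mu_s(NT) - mu_s(ASD)|``, the absolute change in mean
  spontaneous activity (zero-contrast E-cell firing rate).

Common random numbers (a fixed protocol seed) de-noise the grid search.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ssn import RingNetwork, simulate

__all__ = [
    "DeficitSpec",
    "SpontaneousProtocol",
    "scale_inhibition",
    "scale_excitation",
    "spontaneous_mean",
    "homeostatic_adapt",
    "make_asd_network",
]


@dataclass(frozen=True)
class SpontaneousProtocol:
    """Fixed protocol for estimating the spontaneous mean rate mu_s.

    The stimulus is the zero-contrast patch, i.e. a pure-baseline drive.
    ``cells`` selects which population mu_s averages over ('E' or 'all'); the
    default reads "activity" as E-cell firing rate.
    """

    duration: float = 10000.0
    dt: float = 0.5
    burn_in: float = 500.0
    seed: int = 4242
    cells: str = "E"


def _scaled_copy(net: RingNetwork, cols: slice, factor: float) -> RingNetwork:
    out = copy.deepcopy(net)
    out.W[:, cols] = out.W[:, cols] * factor
    out.check_dale()
    return out


def scale_inhibition(net: RingNetwork, delta_I: float) -> RingNetwork:
    """Scale inhibitory columns of W by ``1 - delta_I`` (0 <= delta_I < 1)."""
    if not 0.0 <= delta_I < 1.0:
        raise ValueError("delta_I must be in [0, 1)")
    return _scaled_copy(net, net.I, 1.0 - delta_I)


def scale_excitation(net: RingNetwork, delta_E: float) -> RingNetwork:
    """Scale excitatory columns of W by ``1 - delta_E`` (0 <= delta_E < 1)."""
    if not 0.0 <= delta_E < 1.0:
        raise ValueError("delta_E must be in [0, 1)")
    return _scaled_copy(net, net.E, 1.0 - delta_E)


def spontaneous_mean(net: RingNetwork, protocol: SpontaneousProtocol | None = None) -> float:
    """Mean stationary firing rate under pure baseline drive (zero contrast)."""
    protocol = protocol or SpontaneousProtocol()
    h = net.baseline.copy()
    traj = simulate(
        net,
        h,
        duration=protocol.duration,
        dt=protocol.dt,
        seed=protocol.seed,
        record_every=1.0,
    )
    keep = traj.t > protocol.burn_in
    r = traj.r[keep]
    if protocol.cells == "E":
        r = r[:, : net.n_pairs]
    elif protocol.cells != "all":
        raise ValueError("protocol.cells must be 'E' or 'all'")
    return float(r.mean())


@dataclass
class DeficitSpec:
    """Specification of the inhibitory deficit and its homeostatic closure."""

    delta_I: float = 0.1
    delta_E: float | str = "auto"
    grid_step: float = 0.002
    refine_step: float = 0.0005
    protocol: SpontaneousProtocol = field(default_factory=SpontaneousProtocol)


def homeostatic_adapt(
    net_NT: RingNetwork,
    delta_I: float,
    grid: np.ndarray | None = None,
    protocol: SpontaneousProtocol | None = None,
    grid_step: float = 0.002,
    refine_step: float = 0.0005,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the excitatory scaling that preserves spontaneous activity.

    Evaluates ``C_h(delta_E) = |mu_s(NT) - mu_s(ASD(delta_I, delta_E))|`` with
    a common protocol seed across candidates; unless an explicit ``grid`` is
    given, a coarse 0..delta_I sweep is refined once around its argmin.
    Returns the minimising ``delta_E`` and the full cost table.
    """
    protocol = protocol or SpontaneousProtocol()
    mu_nt = spontaneous_mean(net_NT, protocol)
    net_I = scale_inhibition(net_NT, delta_I)

    def cost(dE: float) -> float:
        try:
            mu = spontaneous_mean(scale_excitation(net_I, dE), protocol)
        except FloatingPointError:
            return np.inf
        return abs(mu_nt - mu)

    rows: dict[float, float] = {}

    def sweep(values):
        for dE in values:
            dE = float(round(dE, 10))
            if dE not in rows:
                rows[dE] = cost(dE)

    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("grid must be nonempty")
        if np.any(np.diff(grid) < 0):
            raise ValueError("grid must be sorted")
        sweep(grid)
    else:
        coarse = np.arange(0.0, delta_I + grid_step / 2, grid_step)
        if len(coarse) == 0:
            coarse = np.array([0.0])
        sweep(coarse)
        d0 = min(rows, key=rows.get)
        sweep(np.arange(max(0.0, d0 - grid_step), d0 + grid_step + refine_step / 2, refine_step))

    table = pd.DataFrame(sorted(rows.items()), columns=["delta_E", "cost"])
    if not np.any(np.isfinite(table["cost"])):
        raise RuntimeError("all candidate delta_E values were unstable")
    best = float(table.loc[table["cost"].idxmin(), "delta_E"])
    assert rows[best] <= min(rows.values()) + 1e-15
    return best, table


def make_asd_network(net_NT: RingNetwork, spec: DeficitSpec) -> tuple[RingNetwork, dict]:
    """Apply the inhibitory deficit and its homeostatic excitatory scaling.

    Composition order: inhibition scaling first, then excitation scaling.
    Provenance records the deltas, the cost table, and the residual change in
    spontaneous rate at the optimum.
    """
    provenance: dict = {
        "delta_I": spec.delta_I,
        "protocol_seed": spec.protocol.seed,
        "protocol_cells": spec.protocol.cells,
    }
    if spec.delta_E == "auto":
        delta_E, table = homeostatic_adapt(
            net_NT,
            spec.delta_I,
            protocol=spec.protocol,
            grid_step=spec.grid_step,
            refine_step=spec.refine_step,
        )
        provenance["cost_table"] = table.to_dict(orient="list")
        provenance["spontaneous_residual"] = float(
            table.loc[table["delta_E"] == delta_E, "cost"].iloc[0]
        )
    else:
        delta_E = float(spec.delta_E)
    provenance["delta_E"] = delta_E
    asd = scale_excitation(scale_inhibition(net_NT, spec.delta_I), delta_E)
    return asd, provenance
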