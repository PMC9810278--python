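"""HDF5 / CSV / YAML persistence for networks, banks, trajectories, posteriors."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd

from .gsm import GaborParams, PosteriorSummary
from .ssn import RingNetwork, RingParams, Trajectory

__all__ = [
    "save_network",
    "load_network",
    "save_trajectory",
    "load_trajectory",
    "save_bank",
    "load_bank",
    "posterior_to_csv",
]


def _params_to_json(params: RingParams | None) -> str:
    if params is None:
        return ""
    d = dataclasses.asdict(params)
    return json.dumps(d)


def _params_from_json(s: str) -> RingParams | None:
    if not s:
        return None
    d = json.loads(s)
    gab = d.pop("gabor", None)
    if gab is not None:
        d["gabor"] = GaborParams(**gab)
    return RingParams(**d)


def save_network(net: RingNetwork, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("W", "W_ff", "tau", "baseline", "noise_cov", "noise_chol", "orientations"):
            f.create_dataset(name, data=getattr(net, name))
        f.attrs.update(
            k=net.k,
            m=net.m,
            tau_noise=net.tau_noise,
            white_noise=net.white_noise,
            params_json=_params_to_json(net.params),
        )


def load_network(path) -> RingNetwork:
    with h5py.File(path, "r") as f:
        arrays = {
            name: f[name][...]
            for name in ("W", "W_ff", "tau", "baseline", "noise_cov", "noise_chol", "orientations")
        }
        net = RingNetwork(
            **arrays,
            k=float(f.attrs["k"]),
            m=float(f.attrs["m"]),
            tau_noise=float(f.attrs["tau_noise"]),
            white_noise=bool(f.attrs["white_noise"]),
            params=_params_from_json(str(f.attrs["params_json"])),
        )
    net.check_dale()
    return net


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=traj.t)
        f.create_dataset("u", data=traj.u)
        f.attrs.update(
            dt=traj.dt,
            seed=traj.seed,
            k=traj.k,
            m=traj.m,
            rectify=traj.rectify,
            n_pairs=traj.n_pairs,
            stimulus_id=traj.stimulus_id or "",
        )


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            t=f["t"][...],
            u=f["u"][...],
            dt=float(f.attrs["dt"]),
            seed=int(f.attrs["seed"]),
            k=float(f.attrs["k"]),
            m=float(f.attrs["m"]),
            rectify=bool(f.attrs["rectify"]),
            n_pairs=int(f.attrs["n_pairs"]),
            stimulus_id=str(f.attrs["stimulus_id"]) or None,
        )


def save_bank(bank, path) -> None:
    from .stimuli import StimulusBank  # noqa: F401 (local import avoids cycle)

    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=bank.patches)
        f.create_dataset("contrast_levels", data=bank.contrast_levels)
        f.create_dataset("orientations", data=bank.orientations)
        f.create_dataset("ids", data=np.array(bank.ids, dtype="S"))
        f.attrs["provenance_json"] = json.dumps(bank.provenance)


def load_bank(path):
    from .stimuli import StimulusBank

    with h5py.File(path, "r") as f:
        return StimulusBank(
            patches=f["patches"][...],
            contrast_levels=f["contrast_levels"][...],
            orientations=f["orientations"][...],
            ids=[s.decode() for s in f["ids"][...]],
            provenance=json.loads(f.attrs["provenance_json"]),
        )


def posterior_to_csv(summaries: list[PosteriorSummary], orientations, path) -> None:
    """Flat CSV of posterior mean/SD per latent per stimulus."""
    rows = []
    for ps in summaries:
        sd = ps.sd
        for i, ori in enumerate(orientations):
            rows.append(
                {
                    "stimulus_id": ps.stimulus_id,
                    "orientation_deg": float(ori),
                    "mean": float(ps.mean[i]),
                    "sd": float(sd[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
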