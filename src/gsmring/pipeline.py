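"""End-to-end orchestration of the two perturbation paths.

Path 1 (*hypoprior*): broaden the GSM prior (``C -> alpha C``) and compare
posterior mean/SD versus contrast against the well-calibrated observer, both
for the 1D conjugate toy model and the full multivariate GSM bank.

Path 2 (*circuit*): weaken inhibitory synapses in the NT ring network with
homeostatic excitatory compensation (the ASD-network), then compare
stationary response moments, gamma-band LFP statistics, transient overshoot
peaks, and recurrent E/I input decomposition across the contrast bank.

``run_all`` assembles the consistency table: the sign of the ASD-minus-NT
effect on response mean and SD should match the sign of the
hypoprior-minus-true effect at every contrast.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, gsm, perturb, ssn, stimuli

__all__ = [
    "ExperimentConfig",
    "child_seed",
    "run_hypoprior_path",
    "run_circuit_path",
    "run_all",
    "validate_report",
    "REPORT_REQUIRED_KEYS",
]


def child_seed(master_seed: int, label: str) -> int:
    """Derive a stage seed from the master seed and a stable string label."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


@dataclass
class ExperimentConfig:
    """Serializable configuration of the full two-path experiment."""

    # GSM observer
    n_latents: int = 32
    patch_side: int = 16
    sigma_x2: float = 1.0
    alpha_hypoprior: float = 1.5
    # evaluation bank
    bank_orientations: tuple = (-45.0, 0.0, 45.0)
    contrast_levels: tuple = stimuli.DEFAULT_CONTRASTS
    # 1D toy model
    toy_C: float = 4.0
    toy_A: float = 10.0
    toy_sigma_x2: float = 100.0
    toy_x_obs: float = 10.0
    # deficit ("auto" resolves delta_E by homeostatic grid search)
    delta_I: float = 0.1
    delta_E: float | str = "auto"
    homeo_grid_step: float = 0.002
    homeo_refine_step: float = 0.0005
    spont_duration: float = 10000.0
    # analysis protocol (per network x contrast)
    sim_duration: float = 60000.0
    sim_dt: float = 0.25
    burn_in: float = 500.0
    thin: float = 200.0
    n_transient_trials: int = 100
    transient_contrasts: tuple = (1.0, 2.0, 4.0)
    # seeds / outputs
    master_seed: int = 0
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("bank_orientations", "contrast_levels", "transient_contrasts"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _gsm_model(cfg: ExperimentConfig) -> gsm.GSMModel:
    return gsm.GSMModel.default(
        n_latents=cfg.n_latents, patch_side=cfg.patch_side, sigma_x2=cfg.sigma_x2
    )


def run_hypoprior_path(cfg: ExperimentConfig) -> dict:
    """Posterior mean/SD versus contrast under the true prior and the hypoprior."""
    model = _gsm_model(cfg)
    hypo = gsm.apply_hypoprior(model, cfg.alpha_hypoprior)
    zs = np.asarray([z for z in cfg.contrast_levels])

    toy = gsm.toy1d_curves(
        cfg.toy_C, cfg.toy_A, cfg.toy_sigma_x2, cfg.alpha_hypoprior, cfg.toy_x_obs, zs
    )

    bank = stimuli.make_bank(
        model,
        orientations=cfg.bank_orientations,
        contrast_levels=cfg.contrast_levels,
        noiseless=True,
        seed=child_seed(cfg.master_seed, "bank"),
    )
    z_grid = gsm.default_z_grid()
    rows = []
    for i in range(len(bank)):
        x, z = bank.patches[i], bank.contrast_levels[i]
        for variant, mdl in (("true", model), ("hypo", hypo)):
            cond = gsm.posterior_given_z(mdl, x, z)
            marg = gsm.posterior_moments(mdl, x, z_grid, stimulus_id=bank.ids[i])
            rows.append(
                {
                    "stimulus_id": bank.ids[i],
                    "contrast": float(z),
                    "variant": variant,
                    "mean_cond": float(cond.mean.mean()),
                    "sd_cond": float(cond.sd.mean()),
                    "mean_marg": float(marg.mean.mean()),
                    "sd_marg": float(marg.sd.mean()),
                }
            )
    bank_df = pd.DataFrame(rows)

    # per-contrast averages across bank orientations
    curves = (
        bank_df.groupby(["contrast", "variant"])[["mean_cond", "sd_cond", "mean_marg", "sd_marg"]]
        .mean()
        .reset_index()
    )
    checks = []
    piv = curves.pivot(index="contrast", columns="variant")
    for z in piv.index:
        if z == 0:
            continue
        checks.append(
            {
                "contrast": float(z),
                "mean_hypo_gt_true": bool(
                    piv.loc[z, ("mean_cond", "hypo")] > piv.loc[z, ("mean_cond", "true")]
                ),
                "sd_hypo_gt_true": bool(
                    piv.loc[z, ("sd_cond", "hypo")] > piv.loc[z, ("sd_cond", "true")]
                ),
            }
        )
    return {"toy": toy, "bank": bank_df, "curves": curves, "checks": checks}


def _network_tables(cfg: ExperimentConfig, net, tag: str, model) -> dict:
    """Stationary, spectral, transient and input statistics across the bank."""
    bank = stimuli.make_bank(
        model,
        orientations=(0.0,),
        contrast_levels=cfg.contrast_levels,
        noiseless=True,
        seed=child_seed(cfg.master_seed, "bank"),
    )
    fs = 1000.0  # recorded at 1 ms
    mom_rows, spec_rows, inputs = [], [], {}
    for i in range(len(bank)):
        z = float(bank.contrast_levels[i])
        h = ssn.feedforward_input(net, bank.patches[i])
        traj = ssn.simulate(
            net,
            h,
            duration=cfg.sim_duration,
            dt=cfg.sim_dt,
            seed=child_seed(cfg.master_seed, f"sim:{bank.ids[i]}"),  # common RNs across networks
            record_every=1.0,
            stimulus_id=bank.ids[i],
        )
        mom = analysis.stationary_moments(traj, burn_in=cfg.burn_in, thin=cfg.thin)
        N = net.n_pairs
        mom_rows.append(
            {
                "network": tag,
                "contrast": z,
                "mean_uE": float(mom["mean_u"][:N].mean()),
                "sd_uE": float(mom["sd_u"][:N].mean()),
                "mean_rE": float(mom["mean_r"][:N].mean()),
                "n_samples": int(mom["n_samples"]),
            }
        )
        series = analysis.lfp(traj)[traj.t > cfg.burn_in]
        spec = analysis.power_spectrum(series, fs)
        spec_rows.append(
            {
                "network": tag,
                "contrast": z,
                "f_peak": np.nan if spec.f_peak is None else float(spec.f_peak),
                "gamma_power": float(spec.gamma_power),
            }
        )
        if z == max(cfg.contrast_levels):
            dec = analysis.input_decomposition(net, traj)
            inputs = {
                "network": tag,
                "contrast": z,
                "mean_excitatory_input": float(dec["excitatory"].mean()),
                "mean_inhibitory_input_magnitude": float(dec["inhibitory_magnitude"].mean()),
            }
    trans_rows = []
    for z in cfg.transient_contrasts:
        idx = int(np.argmin(np.abs(bank.contrast_levels - z)))
        ts = analysis.transient_response(
            net,
            bank.patches[idx],
            n_trials=cfg.n_transient_trials,
            seed=child_seed(cfg.master_seed, f"trans:{z}"),
        )
        trans_rows.append(
            {"network": tag, "contrast": float(z), "peak_rate": ts.peak_rate, "peak_time": ts.peak_time}
        )
    return {
        "moments": pd.DataFrame(mom_rows),
        "spectra": pd.DataFrame(spec_rows),
        "transients": pd.DataFrame(trans_rows),
        "inputs": inputs,
    }


def run_circuit_path(cfg: ExperimentConfig, nt_params: ssn.RingParams | None = None) -> dict:
    """NT versus ASD network statistics across the contrast bank."""
    params = nt_params or ssn.default_nt_params()
    # latent i <-> E cell i: the observer must share the network's geometry
    model = gsm.GSMModel.default(
        n_latents=params.n_pairs, patch_side=params.patch_side, sigma_x2=cfg.sigma_x2
    )
    net_nt = ssn.build_ring(params=params)
    spec = perturb.DeficitSpec(
        delta_I=cfg.delta_I,
        delta_E=cfg.delta_E,
        grid_step=cfg.homeo_grid_step,
        refine_step=cfg.homeo_refine_step,
        protocol=perturb.SpontaneousProtocol(
            duration=cfg.spont_duration,
            seed=child_seed(cfg.master_seed, "spont"),
            cells="all",
        ),
    )
    net_asd, provenance = perturb.make_asd_network(net_nt, spec)

    nt = _network_tables(cfg, net_nt, "NT", model)
    asd = _network_tables(cfg, net_asd, "ASD", model)
    moments = pd.concat([nt["moments"], asd["moments"]], ignore_index=True)
    spectra = pd.concat([nt["spectra"], asd["spectra"]], ignore_index=True)
    transients = pd.concat([nt["transients"], asd["transients"]], ignore_index=True)
    inputs = pd.DataFrame([nt["inputs"], asd["inputs"]])

    checks = []
    for z in sorted(set(moments["contrast"])):
        m = moments.set_index(["network", "contrast"])
        s = spectra.set_index(["network", "contrast"])
        checks.append(
            {
                "contrast": float(z),
                "sd_asd_gt_nt": bool(m.loc[("ASD", z), "sd_uE"] > m.loc[("NT", z), "sd_uE"]),
                "mean_asd_gt_nt": bool(m.loc[("ASD", z), "mean_uE"] > m.loc[("NT", z), "mean_uE"]),
                "gamma_asd_gt_nt": bool(
                    s.loc[("ASD", z), "gamma_power"] > s.loc[("NT", z), "gamma_power"]
                ),
            }
        )
    zmax = max(cfg.transient_contrasts)
    tr = transients.set_index(["network", "contrast"])
    peak_check = bool(tr.loc[("ASD", zmax), "peak_rate"] > tr.loc[("NT", zmax), "peak_rate"])
    paradox = bool(
        inputs.set_index("network").loc["ASD", "mean_inhibitory_input_magnitude"]
        > inputs.set_index("network").loc["NT", "mean_inhibitory_input_magnitude"]
    )
    return {
        "moments": moments,
        "spectra": spectra,
        "transients": transients,
        "inputs": inputs,
        "provenance": provenance,
        "checks": checks,
        "peak_rate_asd_gt_nt_at_top_contrast": peak_check,
        "paradoxical_inhibition": paradox,
    }


REPORT_REQUIRED_KEYS = (
    "config",
    "hypoprior_path",
    "circuit_path",
    "consistency",
    "seeds",
)


def validate_report(report: dict) -> None:
    """Minimal schema check for the comparison report."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing required keys: {missing}")
    for row in report["consistency"]:
        for key in ("contrast", "mean_signs_agree", "sd_signs_agree"):
            if key not in row:
                raise ValueError(f"consistency row missing {key}")


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_all(cfg: ExperimentConfig, nt_params: ssn.RingParams | None = None) -> dict:
    """Run both perturbation paths and assemble the consistency report."""
    hp = run_hypoprior_path(cfg)
    cp = run_circuit_path(cfg, nt_params=nt_params)

    hp_by_z = {c["contrast"]: c for c in hp["checks"]}
    consistency = []
    for c in cp["checks"]:
        z = c["contrast"]
        if z == 0 or z not in hp_by_z:
            continue
        consistency.append(
            {
                "contrast": z,
                "mean_signs_agree": bool(hp_by_z[z]["mean_hypo_gt_true"] == c["mean_asd_gt_nt"]),
                "sd_signs_agree": bool(hp_by_z[z]["sd_hypo_gt_true"] == c["sd_asd_gt_nt"]),
            }
        )
    report = {
        "config": dataclasses.asdict(cfg),
        "seeds": {"master": cfg.master_seed},
        "hypoprior_path": _jsonable(hp),
        "circuit_path": _jsonable(cp),
        "consistency": consistency,
    }
    validate_report(report)
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        for name in ("moments", "spectra", "transients"):
            cp[name].to_csv(out / f"{name}.csv", index=False)
        hp["curves"].to_csv(out / "hypoprior_curves.csv", index=False)
        hp["toy"].to_csv(out / "toy_curves.csv", index=False)
    return report
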