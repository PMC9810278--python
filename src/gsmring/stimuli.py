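"""Synthetic stimulus generation from the GSM forward model.

Two kinds of input are produced:

* a deterministic *evaluation bank* of oriented patches crossed with a set of
  contrast levels (including zero contrast, which stands in for spontaneous
  activity), built from a positive bump of feature coefficients; and
* random *training samples* drawn from the full GSM forward model with
  contrast from the gamma prior.

Both are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gsm import GSMModel, wrapped_orientation_distance

__all__ = ["StimulusBank", "make_bank", "make_training_sample", "DEFAULT_CONTRASTS"]

#: Default evaluation contrast levels; 0 represents spontaneous activity.
DEFAULT_CONTRASTS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class StimulusBank:
    """A set of image patches with per-stimulus contrast/orientation labels."""

    patches: np.ndarray  # (n_stimuli, n_pixels)
    contrast_levels: np.ndarray  # (n_stimuli,)
    orientations: np.ndarray  # (n_stimuli,) nominal orientation (NaN for samples)
    ids: list[str]
    provenance: dict = field(default_factory=dict)
    records: list[dict] | None = None  # latent (y, z) actually used, if any

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("stimulus ids must be unique")
        if not np.all(np.isfinite(self.patches)):
            raise ValueError("patches contain non-finite entries")

    def __len__(self) -> int:
        return self.patches.shape[0]

    def patch(self, stim_id: str) -> np.ndarray:
        return self.patches[self.ids.index(stim_id)]


def orientation_bump(
    latent_orientations: np.ndarray,
    center_deg: float,
    width_deg: float = 20.0,
    height: float = 2.0,
) -> np.ndarray:
    """Positive wrapped-Gaussian profile of feature coefficients.

    Used as the canonical ``y*`` for bank stimuli: all intensities are
    nonnegative so that ordering claims about posterior means are well-posed.
    """
    d = wrapped_orientation_distance(latent_orientations, center_deg)
    return height * np.exp(-(d**2) / (2.0 * width_deg**2))


def make_bank(
    model: GSMModel,
    orientations=(-45.0, 0.0, 45.0),
    contrast_levels=DEFAULT_CONTRASTS,
    noiseless: bool = True,
    seed: int = 0,
    bump_width_deg: float = 20.0,
    bump_height: float = 2.0,
) -> StimulusBank:
    """Deterministic oriented-patch bank across contrast levels.

    Each patch is ``z * A @ y*`` with ``y*`` a positive orientation bump;
    pixel noise is added only when ``noiseless=False``. Zero-contrast
    noiseless patches are exactly zero.
    """
    contrast_levels = np.asarray(contrast_levels, dtype=float)
    if np.any(contrast_levels < 0):
        raise ValueError("contrast levels must be nonnegative")
    rng = np.random.default_rng(seed)
    oris = []
    for o in orientations:
        o = float(o)
        if not (-90.0 <= o < 90.0):
            warnings.warn(f"orientation {o} outside [-90, 90); wrapping", stacklevel=2)
            o = ((o + 90.0) % 180.0) - 90.0
        oris.append(o)

    patches, zs, os_, ids, records = [], [], [], [], []
    for o in oris:
        ystar = orientation_bump(model.orientations, o, bump_width_deg, bump_height)
        signal = model.A @ ystar
        for z in contrast_levels:
            x = z * signal
            if not noiseless:
                x = x + rng.normal(0.0, np.sqrt(model.sigma_x2), size=model.n_pixels)
            patches.append(x)
            zs.append(z)
            os_.append(o)
            ids.append(f"ori{o:+07.2f}_z{z:g}")
            records.append({"y": ystar.copy(), "z": float(z)})
    return StimulusBank(
        patches=np.array(patches),
        contrast_levels=np.array(zs),
        orientations=np.array(os_),
        ids=ids,
        provenance={
            "kind": "bank",
            "seed": seed,
            "noiseless": noiseless,
            "bump_width_deg": bump_width_deg,
            "bump_height": bump_height,
            "orientations": list(oris),
            "contrast_levels": contrast_levels.tolist(),
        },
        records=records,
    )


def make_training_sample(model: GSMModel, n: int, seed: int = 0) -> StimulusBank:
    """Draw ``n`` patches from the full GSM forward model.

    Contrast comes from the gamma prior and the latent record (y, z) is kept
    for every patch.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.C)
    zs = model.contrast_prior.sample(rng, size=n)
    Y = rng.standard_normal((n, model.n_latents)) @ L.T
    E = rng.normal(0.0, np.sqrt(model.sigma_x2), size=(n, model.n_pixels))
    X = zs[:, None] * (Y @ model.A.T) + E
    records = [{"y": Y[i], "z": float(zs[i])} for i in range(n)]
    return StimulusBank(
        patches=X,
        contrast_levels=zs.copy(),
        orientations=np.full(n, np.nan),
        ids=[f"sample{i:06d}" for i in range(n)],
        provenance={"kind": "training_sample", "seed": seed, "n": n},
        records=records,
    )
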