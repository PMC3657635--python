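"""Synthetic ROI voxel signals: lagged, drifting, noisy mixtures of the
behavioral variables.

The generator stands in for the scanner.  Each region of interest (ROI)
gets an encoding specification saying which information sources its voxels
are tuned to; a voxel's trace is a weighted sum of (standardized) variable
time courses shifted by the hemodynamic lag, plus slow polynomial drift and
i.i.d. Gaussian noise::

    data[v, t] = sum_k tuning[v, k] * x_k(t - lag) + d1*t + d2*t^2 + eps

Hemodynamics are modeled as a pure 2-TR shift — the same assumption the
decoding stage makes — with an optional gamma-HRF convolution mode to
stress-test robustness to that assumption.

The default ROI roster mirrors the qualitative decodability structure of
navigation experiments: visual regions (V1, Ve, Pa) carry scene and
picture-visibility (and some motion) information, motor regions (M1, PM)
carry motion and reward timing, the hippocampus (Hi) carries only weak
quadrant signal, and a white-matter control (WM) carries nothing at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mazedecode.features import VariableSet, variable_roster

DEFAULT_LAG_TRS = 2

#: ROI name -> (n_voxels, tuned sources, snr multiplier)
ROI_TABLE: dict[str, tuple[int, tuple[str, ...], float]] = {
    "V1": (100, ("scene_rms", "scene_temp", "visibility", "motion"), 1.0),
    "Ve": (80, ("scene_rms", "scene_temp", "visibility"), 1.0),
    "Pa": (60, ("scene_rms", "visibility", "motion"), 0.8),
    "M1": (24, ("motion", "reward"), 1.0),
    "PM": (36, ("motion", "reward"), 0.9),
    "Hi": (40, ("quadrant",), 0.3),
    "WM": (80, (), 0.0),
}


@dataclass
class EncodingSpec:
    """How one ROI's voxels encode the behavioral variables.

    ``tuning`` is an (n_voxels, 73) weight matrix over the canonical
    variable roster; the white-matter control has an identically zero
    tuning.  ``noise_sd`` is the SD of the additive Gaussian noise,
    ``drift_amp`` bounds the per-voxel linear/quadratic drift coefficients
    (drawn uniformly per run on a time axis normalized to [-1, 1]).
    """

    roi: str
    n_voxels: int
    tuning: np.ndarray
    noise_sd: float = 1.0
    drift_amp: float = 2.0
    lag_trs: int = DEFAULT_LAG_TRS
    seed: int = 0

    def __post_init__(self) -> None:
        self.tuning = np.asarray(self.tuning, dtype=float)
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tuning.shape[0] != self.n_voxels:
            raise ValueError("tuning rows must match n_voxels")


@dataclass
class VoxelRun:
    """Voxel x TR signal matrix for one ROI and one run.

    ``trial_bounds`` are half-open (start, end) TR intervals tiling the run.
    """

    roi: str
    data: np.ndarray
    run_id: str
    trial_bounds: list[tuple[int, int]]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.isnan(self.data).any():
            raise ValueError("voxel data contains missing values")
        if self.trial_bounds:
            spans = sorted(self.trial_bounds)
            if spans[0][0] != 0 or spans[-1][1] != self.data.shape[1] or any(
                a[1] != b[0] for a, b in zip(spans[:-1], spans[1:])
            ):
                raise ValueError("trial boundaries must tile the run")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("trial_bounds", data=np.asarray(self.trial_bounds, dtype=int))
            f.attrs["roi"] = self.roi
            f.attrs["run_id"] = self.run_id
            f.attrs["normalized"] = self.normalized

    @classmethod
    def load(cls, path: str | Path) -> "VoxelRun":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                roi=str(f.attrs["roi"]),
                data=f["data"][()],
                run_id=str(f.attrs["run_id"]),
                trial_bounds=[tuple(b) for b in f["trial_bounds"][()]],
                normalized=bool(f.attrs["normalized"]),
            )


def voxelrun_from_nifti(
    image_path: str | Path,
    mask_path: str | Path,
    roi: str,
    run_id: str,
    trial_bounds: list[tuple[int, int]],
) -> VoxelRun:
    """Ingest a real 4D NIfTI run restricted to an ROI mask.

    Produces the same voxel x TR container as the synthetic generator, so
    downstream normalization/decoding is agnostic to the data's origin.
    The mask is any 3D image whose nonzero voxels define the ROI.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    data4d = np.asarray(img.dataobj, dtype=float)
    if data4d.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data4d.shape}")
    mask = np.asarray(nib.load(str(mask_path)).dataobj) != 0
    if mask.shape != data4d.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} != image grid {data4d.shape[:3]}")
    data = data4d[mask, :]  # voxels x TRs
    return VoxelRun(roi, data, run_id, trial_bounds)


def default_roi_profiles(
    snr: float,
    seed: int = 0,
    rois: Sequence[str] | None = None,
    lag_trs: int = DEFAULT_LAG_TRS,
) -> dict[str, EncodingSpec]:
    """Build the default encoding specification for every ROI.

    Tuned voxels each load on a small random subset (1-3) of the variables
    belonging to their ROI's sources; a round-robin first assignment
    guarantees that at usable snr every variable of a tuned source is
    covered by at least one voxel.  ``snr`` scales all tuning weights
    relative to unit noise SD; snr = 0 yields pure-noise profiles.
    """
    if snr < 0:
        raise ValueError("snr must be non-negative")
    roster = variable_roster()
    src_cols: dict[str, list[int]] = {}
    for k, (src, _) in enumerate(roster):
        src_cols.setdefault(src, []).append(k)

    out: dict[str, EncodingSpec] = {}
    for i, roi in enumerate(rois or ROI_TABLE):
        n_vox, sources, mult = ROI_TABLE[roi]
        rng = np.random.default_rng([seed, i])
        tuning = np.zeros((n_vox, len(roster)))
        cols = [c for s in sources for c in src_cols[s]]
        if cols and snr > 0:
            n_tuned = max(len(cols), int(round(0.7 * n_vox)))
            n_tuned = min(n_tuned, n_vox)
            for v in range(n_tuned):
                picks = {cols[v % len(cols)]}
                extra = int(rng.integers(0, 3))
                picks.update(rng.choice(cols, size=extra, replace=True).tolist())
                for c in picks:
                    w = snr * mult * (0.5 + rng.random()) * rng.choice([-1.0, 1.0])
                    tuning[v, c] = w / np.sqrt(len(picks))
        out[roi] = EncodingSpec(roi=roi, n_voxels=n_vox, tuning=tuning,
                                lag_trs=lag_trs, seed=int(seed) + i)
    return out


def _variables_matrix(variables: Sequence[VariableSet]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Concatenate trials into a (73, total_TRs) matrix plus trial bounds."""
    roster = variable_roster()
    blocks, bounds, t0 = [], [], 0
    for vs in variables:
        mat = np.stack([vs.get(src, vid).values for src, vid in roster])
        blocks.append(mat)
        bounds.append((t0, t0 + vs.n_trs))
        t0 += vs.n_trs
    return np.concatenate(blocks, axis=1), bounds


def _gamma_hrf(n_trs: int = 8, tr_s: float = 3.0) -> np.ndarray:
    from scipy.stats import gamma

    t = np.arange(n_trs) * tr_s
    h = gamma.pdf(t, a=6, scale=1.0) - 0.35 * gamma.pdf(t, a=16, scale=1.0)
    return h / h.sum()


def synthesize_run(
    spec: EncodingSpec,
    variables: Sequence[VariableSet],
    seed: int,
    run_id: str = "run",
    hrf: bool = False,
) -> VoxelRun:
    """Generate one ROI run from trial variable sets.

    Variables are standardized per run (zero-variance ones become zero), then
    shifted by ``spec.lag_trs`` — time points before the run start take the
    run-mean value, i.e. zero after standardization — or convolved with a
    canonical double-gamma HRF when ``hrf`` is set.  Noise and drift are
    drawn from ``seed`` and independent of the deterministic component, so
    two seeds share identical signal but differ in noise.
    """
    X, bounds = _variables_matrix(variables)
    n_trs = X.shape[1]
    if spec.lag_trs >= n_trs:
        raise ValueError(f"lag of {spec.lag_trs} TRs >= run length {n_trs}")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    if hrf:
        h = _gamma_hrf()
        Xlag = np.stack([np.convolve(z, h)[:n_trs] for z in Z])
    else:
        Xlag = np.zeros_like(Z)
        Xlag[:, spec.lag_trs:] = Z[:, : n_trs - spec.lag_trs]

    signal = spec.tuning @ Xlag

    rng = np.random.default_rng(seed)
    t = np.linspace(-1.0, 1.0, n_trs)
    d1 = rng.uniform(-spec.drift_amp, spec.drift_amp, size=(spec.n_voxels, 1))
    d2 = rng.uniform(-spec.drift_amp, spec.drift_amp, size=(spec.n_voxels, 1))
    drift = d1 * t + d2 * t**2
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_voxels, n_trs))
    return VoxelRun(spec.roi, signal + drift + noise, run_id, bounds)
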