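"""Run normalization and hemodynamic alignment of ROI signals.

Two steps prepare a raw voxel x TR run for decoding:

1. *normalization* — subtract the scalar mean over all voxels and TRs of the
   run (removes between-run offset differences), then remove per-voxel
   least-squares fits of linear and quadratic drift;
2. *alignment* — pair the behavioral variable at TR t with the fMRI signal
   at TR t + lag (default 2 TRs = 6 s), accounting for the delay of the
   hemodynamic response.  The lag is applied within each trial, never
   across trial boundaries, and trailing TRs without a signal partner are
   dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from mazedecode.features import VariableSeries, VariableSet
from mazedecode.synth_fmri import VoxelRun

DEFAULT_LAG_TRS = 2


@dataclass
class PreparedRun:
    """A normalized run, ready for alignment."""

    run: VoxelRun
    lag_trs: int = DEFAULT_LAG_TRS


def normalize_run(run: VoxelRun, detrend_degree: int = 2) -> PreparedRun:
    """Grand-mean center the run, then detrend each voxel.

    The scalar mean over all voxels and TRs is subtracted first; then, per
    voxel, the least-squares fit of a degree-``detrend_degree`` polynomial
    in time (default quadratic, i.e. basis [1, t, t^2]) is removed.  The
    result has grand mean ~0 and per-voxel residuals orthogonal to the
    drift basis.  Shape is never changed.
    """
    if run.normalized:
        raise ValueError("run is already normalized")
    n_trs = run.n_trs
    if n_trs < detrend_degree + 1:
        raise ValueError(f"run of {n_trs} TRs too short for degree-{detrend_degree} detrend")
    data = run.data - run.data.mean()
    t = np.linspace(-1.0, 1.0, n_trs)
    basis = np.vander(t, detrend_degree + 1, increasing=True)  # [1, t, t^2, ...]
    coef, *_ = np.linalg.lstsq(basis, data.T, rcond=None)
    resid = data - (basis @ coef).T
    out = VoxelRun(run.roi, resid, run.run_id, list(run.trial_bounds), normalized=True)
    return PreparedRun(out)


@dataclass
class AlignedTrial:
    """One trial's decoder-ready pairing of signal and variables.

    ``X`` holds the signal time points (rows) by voxels (columns); the
    variable set is truncated to the same paired TR axis: row i of ``X`` is
    the signal ``lag_trs`` after the variables' TR i.
    """

    X: np.ndarray
    vars: VariableSet
    trial_index: int

    @property
    def n_trs(self) -> int:
        return self.X.shape[0]


def align_to_variables(
    prepared: PreparedRun,
    variable_sets: list[VariableSet],
    lag_trs: int | None = None,
) -> list[AlignedTrial]:
    """Pair each trial's variables with its lag-shifted signal.

    The variable at TR t pairs with the signal at TR t + lag within the
    trial; the last ``lag_trs`` variable TRs of each trial have no partner
    and are dropped.
    """
    lag = prepared.lag_trs if lag_trs is None else lag_trs
    if lag < 0:
        raise ValueError("lag_trs must be >= 0")
    run = prepared.run
    if len(variable_sets) != len(run.trial_bounds):
        raise ValueError(
            f"{len(variable_sets)} variable sets vs {len(run.trial_bounds)} trials in run"
        )
    out: list[AlignedTrial] = []
    for idx, (vs, (t0, t1)) in enumerate(zip(variable_sets, run.trial_bounds)):
        n = t1 - t0
        if vs.n_trs != n:
            raise ValueError(f"trial {idx}: {vs.n_trs} variable TRs vs {n} signal TRs")
        if lag >= n:
            raise ValueError(f"lag {lag} >= trial length {n}")
        keep = n - lag
        X = run.data[:, t0 + lag : t1].T
        truncated = VariableSet(
            [
                VariableSeries(s.source, s.variable_id, s.values[:keep], valid=s.valid[:keep])
                for s in vs
            ]
        )
        out.append(AlignedTrial(X=X, vars=truncated, trial_index=idx))
    return out
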