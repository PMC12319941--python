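"""Event-related GLM: design matrices, high-pass filtering, OLS betas.

Boxcar regressors (one per condition, 2.5 s events) are built on a
10x-oversampled time grid, convolved with the canonical double-gamma
hemodynamic response function, and decimated to volume acquisition
times, so onset jitter need not be TR-locked. Drift is modeled with a
discrete-cosine basis (default 120 s cutoff period) that can either be
appended to the design or projected out of data and design identically.
Estimation is ordinary least squares per voxel (simulated noise is
white, so OLS is the matched estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import N_CONDITIONS

__all__ = [
    "RunBetaArray",
    "hrf_double_gamma",
    "build_design_matrix",
    "dct_drift_basis",
    "highpass",
    "fit_run_glm",
    "average_halves",
]


@dataclass
class RunBetaArray:
    """Per-run GLM condition amplitudes: a voxels x conditions array."""

    values: np.ndarray
    condition_ids: tuple
    run_id: int = 0
    roi: str = ""
    hemisphere: str = ""
    source: str = "experimental"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("beta values must be voxels x conditions")
        if self.values.shape[1] != len(self.condition_ids):
            raise ValueError("one column per condition required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def hrf_double_gamma(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
    normalize: bool = True,
):
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities (shape = delay/dispersion, scale =
    dispersion): a positive response peaking near 5 s and an undershoot
    scaled by ``1/ratio`` centered near 16 s. Causal: zero for t < 0.
    Normalized to unit peak amplitude by default.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    def raw(tt):
        peak = gamma.pdf(tt, peak_delay / peak_disp, scale=peak_disp)
        under = gamma.pdf(tt, undershoot_delay / undershoot_disp, scale=undershoot_disp)
        return peak - under / ratio

    h = np.where(t >= 0, raw(np.clip(t, 0, None)), 0.0)
    if normalize:
        ref = raw(np.arange(0, 32, 0.01))
        h = h / ref.max()
    return float(h[0]) if scalar else h


def dct_drift_basis(n_volumes: int, tr: float, cutoff: float = 120.0) -> np.ndarray:
    """Discrete-cosine drift basis: columns with period longer than ``cutoff``.

    Basis function k (k >= 1) is cos(pi*k*(2i+1)/(2N)) over volumes i,
    with period 2*N*tr/k; the highest retained order is
    floor(2*N*tr/cutoff). The constant term is not included.
    """
    if cutoff <= 2 * tr:
        raise ValueError(
            f"cutoff period ({cutoff} s) must exceed twice the TR ({2 * tr} s)"
        )
    order = int(np.floor(2 * n_volumes * tr / cutoff))
    i = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * i + 1) / (2 * n_volumes)) for k in range(1, order + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def highpass(data, tr: float, cutoff: float = 120.0, axis: int = 0) -> np.ndarray:
    """Remove slow drift by projecting out the constant + DCT basis.

    Components with period longer than ``cutoff`` seconds (including the
    mean) are removed along ``axis``. Idempotent; applied identically to
    data and design matrices so that GLM estimates are invariant to
    drift actually present in the data.
    """
    x = np.asarray(data, dtype=float)
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    basis = np.column_stack([np.ones(n), dct_drift_basis(n, tr, cutoff)])
    q, _ = np.linalg.qr(basis)
    flat = x.reshape(n, -1)
    resid = flat - q @ (q.T @ flat)
    return np.moveaxis(resid.reshape(x.shape), 0, axis)


def build_design_matrix(
    schedule: pd.DataFrame,
    n_volumes: int,
    tr: float,
    conditions=None,
    oversample: int = 10,
    drift_cutoff: float | None = 120.0,
    include_constant: bool = True,
    room_resolved: bool = False,
    hrf_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Event-related design matrix for one run.

    One task column per condition (``cond_<id>``), each the sum of that
    condition's 2.5 s event boxcars convolved with the double-gamma HRF
    and sampled at volume times ``i * tr``. ``conditions`` defaults to
    the conditions present in the schedule (the full canonical set of 10
    for an empty schedule, giving an all-zero task block). With
    ``room_resolved=True`` each condition x room cell present in the run
    gets its own column (``cond_<id>_room_<r>``). DCT drift columns
    (``drift_<k>``) and a constant are appended unless disabled.

    Raises
    ------
    ValueError
        If any event extends beyond the end of the scan.
    """
    if schedule is None:
        schedule = pd.DataFrame(columns=["run", "onset", "duration", "trial_type"])
    run_len = n_volumes * tr
    if len(schedule):
        late = schedule[schedule["onset"] + schedule["duration"] > run_len]
        if len(late):
            row = late.iloc[0]
            raise ValueError(
                f"event at onset {row['onset']:.1f} s (run {int(row.get('run', 0))}) "
                f"extends beyond the {run_len:.1f} s scan"
            )
        runs = schedule["run"].unique() if "run" in schedule else [0]
        if len(runs) > 1:
            raise ValueError("build_design_matrix expects a single run's events")

    if room_resolved:
        keys = sorted(
            {
                (int(r.trial_type), int(r.room_type))
                for r in schedule.itertuples()
            }
        )
        col_names = [f"cond_{c}_room_{m}" for c, m in keys]
        event_key = lambda row: (int(row.trial_type), int(row.room_type))
    else:
        if conditions is None:
            present = sorted(int(c) for c in schedule.get("trial_type", []))
            conditions = sorted(set(present)) or range(1, N_CONDITIONS + 1)
        keys = [int(c) for c in conditions]
        col_names = [f"cond_{c}" for c in keys]
        event_key = lambda row: int(row.trial_type)

    dt = tr / oversample
    n_fine = n_volumes * oversample
    hrf = hrf_double_gamma(np.arange(0, 32 + dt, dt), **(hrf_kwargs or {}))
    key_pos = {k: i for i, k in enumerate(keys)}
    task = np.zeros((n_volumes, len(keys)))
    box = np.zeros((n_fine, len(keys)))
    for row in schedule.itertuples():
        j = key_pos.get(event_key(row))
        if j is None:
            raise ValueError(f"event condition {event_key(row)} not in design columns")
        a = int(np.round(row.onset / dt))
        b = int(np.round((row.onset + row.duration) / dt))
        box[a : min(b, n_fine), j] += 1.0
    if len(schedule):
        for j in range(len(keys)):
            conv = np.convolve(box[:, j], hrf)[:n_fine]
            task[:, j] = conv[::oversample]  # samples at volume times i*tr
    X = pd.DataFrame(task, columns=col_names)
    if drift_cutoff is not None:
        drift = dct_drift_basis(n_volumes, tr, drift_cutoff)
        for k in range(drift.shape[1]):
            X[f"drift_{k + 1}"] = drift[:, k]
    if include_constant:
        X["constant"] = 1.0
    X.attrs["tr"] = tr
    X.attrs["task_columns"] = col_names
    return X


def fit_run_glm(
    timeseries: np.ndarray,
    design: pd.DataFrame,
    run_id: int = 0,
    roi: str = "",
    hemisphere: str = "",
    source: str = "experimental",
) -> RunBetaArray:
    """Per-voxel OLS condition amplitudes for one run.

    ``timeseries`` is voxels x volumes; ``design`` is a frame from
    :func:`build_design_matrix` (volumes x regressors). Only the task
    columns are returned as betas; drift and constant are nuisance.

    Raises
    ------
    ValueError
        On a volume-count mismatch or a rank-deficient design (the error
        names the collinear columns).
    """
    y = np.asarray(timeseries, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    X = design.to_numpy(dtype=float)
    if y.shape[1] != X.shape[0]:
        raise ValueError(
            f"timeseries has {y.shape[1]} volumes but design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the deficiency for the error message
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, keep + [j]])
            if r == len(keep):
                bad.append(design.columns[j])
            else:
                keep.append(j)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    task_cols = design.attrs.get(
        "task_columns", [c for c in design.columns if c.startswith("cond_")]
    )
    idx = [design.columns.get_loc(c) for c in task_cols]
    cond_ids = tuple(_parse_task_column(c) for c in task_cols)
    return RunBetaArray(
        values=beta[idx].T,
        condition_ids=cond_ids,
        run_id=run_id,
        roi=roi,
        hemisphere=hemisphere,
        source=source,
    )


def _parse_task_column(name: str):
    parts = name.split("_")
    if "room" in name:
        return (int(parts[1]), int(parts[3]))
    return int(parts[1])


def average_halves(betas, run_subset=None) -> np.ndarray:
    """Element-wise mean of run beta arrays over a subset of runs.

    ``betas`` is a sequence of :class:`RunBetaArray` (or plain arrays);
    ``run_subset`` selects by ``run_id`` (or position for plain arrays).
    All arrays must share the same voxel and condition dimensions.
    """
    if len(betas) == 0:
        raise ValueError("no beta arrays supplied")
    if isinstance(betas[0], RunBetaArray):
        pool = {b.run_id: b.values for b in betas}
        if run_subset is None:
            run_subset = sorted(pool)
        missing = [r for r in run_subset if r not in pool]
        if missing:
            raise ValueError(f"runs {missing} not present")
        arrs = [pool[r] for r in run_subset]
    else:
        arrs = [np.asarray(b, dtype=float) for b in betas]
        if run_subset is not None:
            arrs = [arrs[r] for r in run_subset]
    if not arrs:
        raise ValueError("empty run subset")
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValueError(f"mismatched voxel/condition shapes across runs: {shapes}")
    return np.mean(arrs, axis=0)
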