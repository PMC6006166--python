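"""First-level fMRI model: HRF, event regressors, design matrix, GLM, PE contrast.

Seven task regressors describe the learning task: three cue-onset regressors
(one per pair type), neutral outcomes (pooled over reward and neutral
trials), reward-pair wins, bivalent wins and bivalent losses.  All events
last 2 s, are convolved with a canonical double-gamma HRF, and each carries a
temporal-derivative column.  The prediction-error contrast compares the two
£1-win regressors (bivalent win minus reward win): identical outcome value
under different expectations, so the contrast isolates the prediction-error
component and is balanced for outcome value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "EVENT_LABELS",
    "EVENT_DURATION_S",
    "double_gamma_hrf",
    "behaviour_events",
    "DesignMatrix",
    "build_design_matrix",
    "GlmFit",
    "fit_glm",
    "pe_contrast",
]

#: The seven task regressors.
EVENT_LABELS = (
    "bivalent_cue",
    "neutral_cue",
    "reward_cue",
    "neutral_outcome",
    "reward_win",
    "bivalent_win",
    "bivalent_loss",
)

EVENT_DURATION_S = 2.0


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised to 1.

    Difference of two gamma densities with the usual defaults (response
    peaking near 5 s, undershoot near 15 s, undershoot 1/6 of the peak).
    """
    for name, v in (
        ("peak_delay", peak_delay),
        ("undershoot_delay", undershoot_delay),
        ("peak_disp", peak_disp),
        ("undershoot_disp", undershoot_disp),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, a=peak_delay / peak_disp, scale=peak_disp) - ratio * gamma_dist.pdf(
        t, a=undershoot_delay / undershoot_disp, scale=undershoot_disp
    )
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def behaviour_events(
    behaviour,
    trial_duration_s: float = 10.0,
    cue_offset_s: float = 0.0,
    outcome_offset_s: float = 4.0,
    event_duration_s: float = EVENT_DURATION_S,
) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, modulation).

    Cue onsets are labelled by pair type; outcome onsets by outcome class
    (reward-pair wins, bivalent wins/losses, everything else pooled as
    neutral outcomes).  ``modulation`` carries the trial's prediction error
    for win events and 1.0 otherwise; it is ignored by the default
    (unmodulated) design and used by the model-based regressor path.
    """
    rows = []
    cue_label = {"reward": "reward_cue", "bivalent": "bivalent_cue", "neutral": "neutral_cue"}
    for i, trial in enumerate(behaviour.schedule.trials):
        t0 = (trial.index - 1) * trial_duration_s
        rows.append(
            {
                "onset": t0 + cue_offset_s,
                "duration": event_duration_s,
                "trial_type": cue_label[trial.pair_type],
                "modulation": 1.0,
            }
        )
        value = behaviour.outcome_values[i]
        if trial.pair_type == "bivalent":
            label = "bivalent_win" if value > 0 else "bivalent_loss"
        elif trial.pair_type == "reward" and value > 0:
            label = "reward_win"
        else:
            label = "neutral_outcome"
        mod = behaviour.deltas[i] if label in ("reward_win", "bivalent_win") else 1.0
        rows.append(
            {
                "onset": t0 + outcome_offset_s,
                "duration": event_duration_s,
                "trial_type": label,
                "modulation": float(mod),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DesignMatrix:
    """Convolved first-level design.

    ``frame`` holds one convolved column and one temporal-derivative column
    per task regressor, followed by any nuisance columns and an intercept.
    """

    frame: pd.DataFrame
    tr: float
    task_labels: tuple[str, ...]
    dropped: tuple[str, ...] = ()
    convolution: str = "double-gamma HRF, 2 s boxcar, finite-difference derivative"

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def build_design_matrix(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    nuisance: pd.DataFrame | np.ndarray | None = None,
    modulated: bool = False,
    dt: float = 0.1,
    hrf_kwargs: dict | None = None,
    allowed_labels: tuple[str, ...] = EVENT_LABELS,
    add_intercept: bool = True,
) -> DesignMatrix:
    """Sample each regressor's boxcar on a fine grid, convolve, downsample.

    Events must fall inside the scan; unknown trial_type labels are rejected.
    Regressors with no events would produce all-zero columns and are dropped
    with a warning.  When ``modulated`` is true the boxcar amplitude is the
    event's ``modulation`` value (parametric modulation); otherwise unit
    amplitude.  Nuisance columns are appended unconvolved.
    """
    scan_end = n_volumes * tr
    unknown = set(events["trial_type"]) - set(allowed_labels)
    if unknown:
        raise ValueError(f"unknown event labels: {sorted(unknown)}")
    if ((events["onset"] < 0) | (events["onset"] + events["duration"] > scan_end)).any():
        raise ValueError("events fall outside the scan (0 to n_volumes*tr)")

    n_fine = int(np.ceil(scan_end / dt)) + 1
    t_fine = np.arange(n_fine) * dt
    hrf = double_gamma_hrf(np.arange(0, 32 + dt, dt), **(hrf_kwargs or {}))
    dhrf = np.gradient(hrf, dt)
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)

    cols: dict[str, np.ndarray] = {}
    dropped = []
    present_labels = []
    for label in allowed_labels:
        ev = events[events["trial_type"] == label]
        if len(ev) == 0:
            dropped.append(label)
            continue
        box = np.zeros(n_fine)
        for onset, dur, mod in zip(ev["onset"], ev["duration"], ev["modulation"]):
            i0 = int(np.round(onset / dt))
            i1 = int(np.round((onset + dur) / dt))
            box[i0:i1] = mod if modulated else 1.0
        conv = np.convolve(box, hrf)[:n_fine] * dt
        dconv = np.convolve(box, dhrf)[:n_fine] * dt
        cols[label] = conv[vol_idx]
        cols[label + "_deriv"] = dconv[vol_idx]
        present_labels.append(label)
    if dropped:
        warnings.warn(f"regressors with zero events dropped: {dropped}", stacklevel=2)

    frame = pd.DataFrame(cols)
    if nuisance is not None:
        if isinstance(nuisance, np.ndarray):
            nuisance = pd.DataFrame(
                nuisance, columns=[f"nuisance_{i}" for i in range(nuisance.shape[1])]
            )
        if len(nuisance) != n_volumes:
            raise ValueError("nuisance length != n_volumes")
        frame = pd.concat([frame, nuisance.reset_index(drop=True)], axis=1)
    if add_intercept:
        frame["intercept"] = 1.0
    return DesignMatrix(
        frame=frame, tr=tr, task_labels=tuple(present_labels), dropped=tuple(dropped)
    )


@dataclass
class GlmFit:
    """Ordinary least-squares fit of a design to one or many voxel time series."""

    betas: np.ndarray  # (n_columns, n_voxels)
    columns: list[str]
    residual_variance: np.ndarray  # (n_voxels,)
    dof: int

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.columns.index(name)]


def fit_glm(ts: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Voxelwise OLS. ``ts`` is (n_volumes,) or (n_volumes, n_voxels)."""
    X = design.values
    y = np.asarray(ts, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"time series length {y.shape[0]} != n_volumes {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient (columns: {bad or 'collinear set'})")
    pinv = np.linalg.pinv(X)
    betas = pinv @ y
    resid = y - X @ betas
    dof = X.shape[0] - X.shape[1]
    resvar = (resid**2).sum(axis=0) / dof
    return GlmFit(betas=betas, columns=design.columns, residual_variance=resvar, dof=dof)


def pe_contrast(fit: GlmFit) -> np.ndarray:
    """Prediction-error COPE: beta(bivalent_win) - beta(reward_win).

    Derivative, cue, loss and nuisance columns all carry zero weight.
    """
    for name in ("bivalent_win", "reward_win"):
        if name not in fit.columns:
            raise ValueError(f"required regressor {name!r} missing from the fit")
    return fit.beta("bivalent_win") - fit.beta("reward_win")
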