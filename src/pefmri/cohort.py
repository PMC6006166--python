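"""Synthetic study generator: subjects, behaviour, ROI masks and BOLD data.

The generator emulates a three-group cross-sectional design (healthy
controls, at-risk mental state, first-episode psychosis; 39/30/14 subjects
by default).  Each subject is a Q-learning agent playing the probabilistic
monetary task; their BOLD signal inside the regions of interest couples to
trial-wise prediction errors with a subject-specific gain drawn from a
group-specific distribution.  The coupling distributions are expressed
directly in COPE units and are calibrated so that the expected extracted
cluster means reproduce the target group structure of the emulated design:
graded midbrain signalling (controls > at-risk > FEP) and preserved
cortical (DLPFC) signalling in the at-risk group with FEP deactivation.

Regions of interest are parameterised geometric volumes on a 2 mm MNI-like
grid: an ellipsoidal dopaminergic-midbrain mask (substantia nigra + VTA
stand-in), a box-pair striatal mask, and a 10 mm sphere in right DLPFC
centred at (50, 30, 28) mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .task import generate_schedule
from .rl import QParams, SubjectBehaviour, simulate_agent
from .design import behaviour_events, build_design_matrix, fit_glm, pe_contrast

__all__ = [
    "RoiMaskSet",
    "make_roi_masks",
    "default_roi_masks",
    "GRID_PRESETS",
    "CohortConfig",
    "default_config",
    "Subject",
    "Cohort",
    "generate_cohort",
    "generate_rts",
    "simulate_bold",
    "subject_copes",
    "cohort_copes",
    "PE_CONTRAST_REF",
]

GROUPS = ("controls", "at_risk", "fep")

#: Population-mean value of beta(bivalent_win) - beta(reward_win) for a unit
#: PE coupling gain under the default agents, estimated once by noise-free
#: simulation (see docs/methods.md).  The forward model normalises the gain
#: by each subject's own noise-free contrast projection so that the
#: coupling, expressed in COPE units, is recovered exactly at zero noise;
#: this constant is only the fallback for degenerate event sequences.
PE_CONTRAST_REF = 0.585

# grid presets: (shape, voxel size mm, origin mm of voxel (0,0,0))
GRID_PRESETS = {
    "full": ((48, 56, 44), 2.0, (-30.0, -40.0, -30.0)),
    "reduced": ((38, 35, 31), 2.0, (-12.0, -26.0, -20.0)),
}

DLPFC_CENTER_MM = (50.0, 30.0, 28.0)
DLPFC_RADIUS_MM = 10.0
MIDBRAIN_CENTER_MM = (0.0, -14.0, -10.0)
MIDBRAIN_SEMI_AXES_MM = (8.0, 8.0, 6.0)
STRIATUM_BOX_CENTERS_MM = ((-26.0, 8.0, 2.0), (26.0, 8.0, 2.0))
STRIATUM_BOX_HALF_MM = (8.0, 10.0, 8.0)


@dataclass
class RoiMaskSet:
    """Named boolean ROI volumes on a shared grid with an mm affine."""

    masks: dict[str, np.ndarray]
    affine: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        names = list(self.masks)
        for n in names:
            if not self.masks[n].any():
                raise ValueError(f"ROI mask {n!r} is empty")
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if (self.masks[a] & self.masks[b]).any():
                    raise ValueError(f"ROI masks {a!r} and {b!r} overlap")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.masks.values())).shape

    def n_voxels(self, name: str) -> int:
        return int(self.masks[name].sum())


def _mm_grids(grid_shape, voxel_size_mm, origin_mm):
    axes = [origin_mm[i] + voxel_size_mm * np.arange(grid_shape[i]) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _affine(voxel_size_mm, origin_mm) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def make_roi_masks(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    centers: dict[str, tuple[float, float, float]],
    radii: dict[str, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RoiMaskSet:
    """Spherical ROI masks by Euclidean distance on the mm grid."""
    xs, ys, zs = _mm_grids(grid_shape, voxel_size_mm, origin_mm)
    masks = {}
    for name, c in centers.items():
        r = radii[name]
        if r <= 0:
            raise ValueError(f"radius for {name!r} must be positive")
        for i, ci in enumerate(c):
            lo = origin_mm[i]
            hi = origin_mm[i] + voxel_size_mm * (grid_shape[i] - 1)
            if not lo <= ci <= hi:
                raise ValueError(f"center of {name!r} lies outside the grid")
        m = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= r**2
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty at radius {r} mm")
        masks[name] = m
    return RoiMaskSet(masks=masks, affine=_affine(voxel_size_mm, origin_mm), voxel_size_mm=voxel_size_mm)


def default_roi_masks(preset: str = "full") -> RoiMaskSet:
    """Midbrain ellipsoid, striatum box-pair and right-DLPFC sphere.

    The ``reduced`` preset uses a smaller field of view containing only the
    midbrain and DLPFC masks, for desk-scale permutation studies.
    """
    if preset not in GRID_PRESETS:
        raise ValueError(f"unknown grid preset {preset!r}")
    shape, vox, origin = GRID_PRESETS[preset]
    xs, ys, zs = _mm_grids(shape, vox, origin)

    cx, cy, cz = MIDBRAIN_CENTER_MM
    ax, ay, az = MIDBRAIN_SEMI_AXES_MM
    midbrain = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0

    dx, dy, dz = DLPFC_CENTER_MM
    dlpfc = (xs - dx) ** 2 + (ys - dy) ** 2 + (zs - dz) ** 2 <= DLPFC_RADIUS_MM**2

    masks = {"midbrain": midbrain, "dlpfc": dlpfc}
    if preset == "full":
        striatum = np.zeros(shape, dtype=bool)
        for c in STRIATUM_BOX_CENTERS_MM:
            striatum |= (
                (np.abs(xs - c[0]) <= STRIATUM_BOX_HALF_MM[0])
                & (np.abs(ys - c[1]) <= STRIATUM_BOX_HALF_MM[1])
                & (np.abs(zs - c[2]) <= STRIATUM_BOX_HALF_MM[2])
            )
        masks["striatum"] = striatum
    return RoiMaskSet(masks=masks, affine=_affine(vox, origin), voxel_size_mm=vox)


@dataclass
class NoiseModel:
    """AR(1) voxel noise plus low-frequency drift and motion artefact."""

    ar1_phi: float = 0.3
    sd: float = 100.0
    drift_amplitude: float = 10.0
    drift_period_s: float = 128.0
    motion_amplitude: float = 5.0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError(f"AR(1) coefficient must be in (-1, 1), got {self.ar1_phi}")
        if self.sd <= 0:
            raise ValueError("noise sd must be positive")


@dataclass
class RtModel:
    """Log-normal response times with pair-type-specific means (ms)."""

    means_ms: dict[str, float] = field(
        default_factory=lambda: {"reward": 1122.83, "bivalent": 1358.99, "neutral": 1329.30}
    )
    subject_sd_log: float = 0.20
    trial_sd_log: float = 0.30


@dataclass
class GroupQParams:
    """Distribution of Q-learning parameters within one group."""

    alpha_mean: float = 0.30
    alpha_sd: float = 0.10
    beta_mean: float = 2.8
    beta_sd: float = 1.0


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"controls": 39, "at_risk": 30, "fep": 14}
    )
    n_per_pair: int = 30
    q_params: dict[str, GroupQParams] = field(
        default_factory=lambda: {
            "controls": GroupQParams(),
            "at_risk": GroupQParams(),
            "fep": GroupQParams(beta_mean=2.2),
        }
    )
    # per-ROI, per-group coupling (mean, sd) in COPE units; midbrain values
    # encode the graded pattern (controls > at-risk > FEP), DLPFC the
    # preserved-at-risk pattern, striatum a common activation with no
    # group difference.
    coupling: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "midbrain": {
                "controls": (24.44, 50.12),
                "at_risk": (0.66, 54.86),
                "fep": (-55.03, 50.70),
            },
            "dlpfc": {
                "controls": (32.90, 62.82),
                "at_risk": (36.29, 53.03),
                "fep": (-45.13, 48.40),
            },
            "striatum": {
                "controls": (10.0, 50.0),
                "at_risk": (10.0, 50.0),
                "fep": (10.0, 50.0),
            },
        }
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    rt: RtModel = field(default_factory=RtModel)
    # symptom scores (CAARMS-total-like): Gaussian truncated at 0
    symptoms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "controls": (2.0, 2.0),
            "at_risk": (15.10, 6.75),
            "fep": (23.86, 6.48),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be positive")
        for roi, per_group in self.coupling.items():
            for g, (_, sd) in per_group.items():
                if sd <= 0:
                    raise ValueError(f"coupling sd for {roi}/{g} must be positive")


def default_config(**overrides) -> CohortConfig:
    return CohortConfig(**overrides)


@dataclass
class Subject:
    sid: str
    group: str
    params: QParams
    behaviour: SubjectBehaviour
    symptom: float
    coupling: dict[str, float]
    bold_seed: int


@dataclass
class Cohort:
    subjects: list[Subject]
    config: CohortConfig

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject": s.sid,
                "group": s.group,
                "alpha": s.params.alpha,
                "beta": s.params.beta,
                "symptom": s.symptom,
            }
            row.update({f"coupling_{k}": v for k, v in s.coupling.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def generate_rts(behaviour: SubjectBehaviour, rt_model: RtModel, rng: np.random.Generator) -> np.ndarray:
    """Draw per-trial log-normal RTs with pair-type-specific means.

    A subject-level log-offset and trial-level log-noise multiply the
    configured pair-type mean; both are variance-corrected so the expected
    RT equals the configured mean.  RTs are strictly positive.
    """
    m = rt_model
    u = rng.normal(0.0, m.subject_sd_log) if m.subject_sd_log > 0 else 0.0
    pts = behaviour.schedule.pair_types
    rts = np.empty(len(pts))
    correction = -0.5 * (m.subject_sd_log**2 + m.trial_sd_log**2)
    for i, pt in enumerate(pts):
        z = rng.normal(0.0, m.trial_sd_log) if m.trial_sd_log > 0 else 0.0
        rts[i] = m.means_ms[pt] * np.exp(u + z + correction)
    behaviour.rts = rts
    return rts


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic study (behaviour and per-subject couplings).

    BOLD data are not materialised here; each subject carries a derived seed
    so that :func:`simulate_bold` / :func:`cohort_copes` are reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    subjects: list[Subject] = []
    i = 0
    for group in config.group_sizes:
        qp = config.q_params[group]
        for _ in range(config.group_sizes[group]):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            sched_seed = int(rng.integers(0, 2**31 - 1))
            schedule = generate_schedule(config.n_per_pair, sched_seed)
            alpha = float(np.clip(rng.normal(qp.alpha_mean, qp.alpha_sd), 0.02, 0.98))
            beta = float(np.clip(rng.normal(qp.beta_mean, qp.beta_sd), 0.1, 20.0))
            params = QParams(alpha=alpha, beta=beta)
            behaviour = simulate_agent(params, schedule, rng)
            generate_rts(behaviour, config.rt, rng)
            coupling = {
                roi: float(rng.normal(*config.coupling[roi][group]))
                for roi in config.coupling
            }
            symptom = _truncated_normal(*config.symptoms[group], rng)
            bold_seed = int(rng.integers(0, 2**31 - 1))
            subjects.append(
                Subject(
                    sid=f"sub-{i:03d}",
                    group=group,
                    params=params,
                    behaviour=behaviour,
                    symptom=symptom,
                    coupling=coupling,
                    bold_seed=bold_seed,
                )
            )
            i += 1
    return Cohort(subjects=subjects, config=config)


def scan_volumes(n_trials: int, trial_duration_s: float = 10.0, tr: float = 2.0) -> int:
    """Number of volumes covering all trials plus a 20 s washout."""
    return int(np.ceil((n_trials * trial_duration_s + 20.0) / tr))


def _make_motion(n_volumes: int, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Six smooth random-walk motion columns, unit-free, unconvolved."""
    rw = np.cumsum(rng.normal(0.0, 1.0, (n_volumes, 6)), axis=0)
    rw -= rw.mean(axis=0)
    sd = rw.std(axis=0)
    sd[sd == 0] = 1.0
    return amplitude * rw / sd


def _ar1_noise(n_vox: int, n_volumes: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), (n_vox, n_volumes))
    return lfilter([1.0], [1.0, -phi], innov, axis=1)


def _subject_signals(
    behaviour: SubjectBehaviour,
    n_volumes: int,
    tr: float,
    trial_duration_s: float,
    motion: np.ndarray,
):
    """Design matrix for fitting, the true PE signal, its noise-free contrast
    projection (per-subject gain normaliser) and the background task signal."""
    events = behaviour_events(behaviour, trial_duration_s=trial_duration_s)
    nuis = pd.DataFrame(motion, columns=[f"motion_{i}" for i in range(motion.shape[1])])
    nuis["trend"] = np.linspace(-1, 1, n_volumes)
    X = build_design_matrix(events, n_volumes, tr, nuisance=nuis)
    Xmod = build_design_matrix(events, n_volumes, tr, modulated=True, add_intercept=False)
    pe_signal = np.zeros(n_volumes)
    for col in ("bivalent_win", "reward_win"):
        if col in Xmod.frame.columns:
            pe_signal += Xmod.frame[col].to_numpy()
    background = np.zeros(n_volumes)
    for col in X.task_labels:
        background += X.frame[col].to_numpy()
    if {"bivalent_win", "reward_win"} <= set(X.task_labels):
        factor = float(pe_contrast(fit_glm(pe_signal, X))[0])
    else:
        factor = 0.0
    if abs(factor) < 0.05:  # degenerate event sequence; fall back
        factor = PE_CONTRAST_REF
    return X, pe_signal, factor, background


def _voxel_timeseries(
    gain: float,
    pe_signal: np.ndarray,
    n_vox: int,
    noise: NoiseModel,
    motion: np.ndarray,
    rng: np.random.Generator,
    tr: float,
) -> np.ndarray:
    """(n_vox, n_volumes) series: PE signal + drift + motion artefact + AR(1)."""
    n_volumes = len(pe_signal)
    t = np.arange(n_volumes) * tr
    phase = rng.uniform(0, 2 * np.pi, n_vox)
    drift = noise.drift_amplitude * np.cos(
        2 * np.pi * t[None, :] / noise.drift_period_s + phase[:, None]
    )
    motion_w = rng.normal(0.0, 0.2, (n_vox, motion.shape[1]))
    artefact = motion_w @ motion.T
    eps = _ar1_noise(n_vox, n_volumes, noise.ar1_phi, noise.sd, rng)
    return gain * pe_signal[None, :] + drift + artefact + eps


def simulate_bold(
    behaviour: SubjectBehaviour,
    masks: RoiMaskSet,
    coupling: dict[str, float],
    noise: NoiseModel,
    rng: np.random.Generator,
    tr: float = 2.0,
    trial_duration_s: float = 10.0,
    n_volumes: int | None = None,
    background_amplitude: float = 20.0,
) -> np.ndarray:
    """Forward model: a full 4D volume for one subject.

    Voxels inside a signal ROI carry the prediction-error-scaled win signal
    with that subject's coupling gain for the ROI; voxels outside the ROIs
    carry generic cue/outcome task signal at a fixed amplitude.  All voxels
    receive low-frequency drift, a weak motion artefact and AR(1) noise.
    """
    for roi, c in coupling.items():
        if not np.isfinite(c):
            raise ValueError(f"coupling for {roi!r} must be finite")
        if roi not in masks.masks:
            raise ValueError(f"coupling given for unknown ROI {roi!r}")
    if n_volumes is None:
        n_volumes = scan_volumes(len(behaviour.schedule), trial_duration_s, tr)
    motion = _make_motion(n_volumes, rng, 1.0)
    _, pe_signal, factor, background = _subject_signals(
        behaviour, n_volumes, tr, trial_duration_s, motion
    )

    shape = masks.shape
    vol = np.empty(shape + (n_volumes,), dtype=np.float32)
    in_roi = np.zeros(shape, dtype=bool)
    for roi, m in masks.masks.items():
        gain = coupling.get(roi, 0.0) / factor
        n_vox = int(m.sum())
        vol[m] = _voxel_timeseries(gain, pe_signal, n_vox, noise, motion, rng, tr)
        in_roi |= m
    outside = ~in_roi
    n_out = int(outside.sum())
    ts = _voxel_timeseries(0.0, pe_signal, n_out, noise, motion, rng, tr)
    ts += background_amplitude * background[None, :]
    vol[outside] = ts
    return vol


def subject_copes(
    subject: Subject,
    masks: RoiMaskSet,
    noise: NoiseModel,
    tr: float = 2.0,
    trial_duration_s: float = 10.0,
    rois: list[str] | None = None,
    rng: np.random.Generator | None = None,
    zero_noise: bool = False,
) -> dict[str, np.ndarray]:
    """Fast first-level path: simulate ROI voxels only, fit the GLM, return COPEs.

    The fitted design is the standard 7-regressor event model (unmodulated,
    with temporal derivatives, motion and trend nuisance and intercept); the
    COPE is beta(bivalent_win) - beta(reward_win) per voxel.
    """
    if rng is None:
        rng = np.random.default_rng(subject.bold_seed)
    rois = rois if rois is not None else [r for r in masks.masks if r in subject.coupling]
    n_volumes = scan_volumes(len(subject.behaviour.schedule), trial_duration_s, tr)
    motion = _make_motion(n_volumes, rng, 1.0)
    X, pe_signal, factor, _ = _subject_signals(
        subject.behaviour, n_volumes, tr, trial_duration_s, motion
    )
    out = {}
    for roi in rois:
        n_vox = masks.n_voxels(roi)
        gain = subject.coupling[roi] / factor
        if zero_noise:
            y = gain * np.tile(pe_signal, (n_vox, 1))
        else:
            y = _voxel_timeseries(gain, pe_signal, n_vox, noise, motion, rng, tr)
        fit = fit_glm(y.T, X)
        out[roi] = pe_contrast(fit)
    return out


def cohort_copes(
    cohort: Cohort,
    masks: RoiMaskSet,
    tr: float = 2.0,
    trial_duration_s: float = 10.0,
    rois: list[str] | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-ROI COPE matrices (n_subjects, n_roi_voxels) for a whole cohort."""
    rois = rois if rois is not None else [
        r for r in masks.masks if r in cohort.subjects[0].coupling
    ]
    copes = {roi: np.empty((len(cohort.subjects), masks.n_voxels(roi))) for roi in rois}
    for i, s in enumerate(cohort.subjects):
        sc = subject_copes(s, masks, cohort.config.noise, tr, trial_duration_s, rois)
        for roi in rois:
            copes[roi][i] = sc[roi]
    return copes, cohort.groups()


def embed_roi(values: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Place per-voxel ROI values back into a full 3D volume."""
    vol = np.full(mask.shape, fill, dtype=float)
    vol[mask] = values
    return vol
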