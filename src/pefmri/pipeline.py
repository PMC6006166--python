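"""End-to-end orchestration: generate -> behave -> first-level -> group-level.

A single YAML config drives the run; every stage seed is derived
deterministically from the master seed, so re-running a config reproduces
behavioural tables byte-for-byte and permutation p-values exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behaviour import cohort_summary, mixed_anova, pairwise_level_tests
from .cohort import (
    CohortConfig,
    GRID_PRESETS,
    cohort_copes,
    default_config,
    default_roi_masks,
    generate_cohort,
)
from .design import behaviour_events
from .inference import extract_cluster_means, permutation_fwe, symptom_correlation

__all__ = [
    "RunConfig",
    "RunReport",
    "validate_config",
    "run_pipeline",
    "PipelineError",
    "STAGES",
]

log = logging.getLogger("pefmri")

STAGES = ("simulate", "behave", "firstlevel", "grouplevel", "report")

#: Planned directional hypotheses for the pairwise group comparisons.
PLANNED_COMPARISONS = [("controls", "at_risk"), ("at_risk", "fep"), ("controls", "fep")]

_KNOWN_KEYS = {
    "group_sizes",
    "n_per_pair",
    "seed",
    "out_dir",
    "tr",
    "trial_duration_s",
    "grid",
    "rois",
    "n_perm",
    "variance_smooth_fwhm_mm",
    "tfce_e",
    "tfce_h",
    "alpha",
    "write_bold",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an exit code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = {"config": 1, "simulate": 2, "behave": 3, "firstlevel": 4,
                     "grouplevel": 5, "report": 6}.get(stage, 9)


@dataclass
class RunConfig:
    """Validated run configuration with all defaults filled."""

    out_dir: Path
    seed: int = 42
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"controls": 39, "at_risk": 30, "fep": 14}
    )
    n_per_pair: int = 30
    tr: float = 2.0
    trial_duration_s: float = 10.0
    grid: str = "reduced"
    rois: list[str] = field(default_factory=lambda: ["midbrain", "dlpfc"])
    n_perm: int = 5000
    variance_smooth_fwhm_mm: float = 3.0
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    alpha: float = 0.05
    write_bold: bool = False

    def cohort_config(self) -> CohortConfig:
        return default_config(
            group_sizes=dict(self.group_sizes), n_per_pair=self.n_per_pair, seed=self.seed
        )

    def derived_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML config; all problems are reported together."""
    path = Path(path)
    if not path.exists():
        raise PipelineError("config", f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        errors.append("out_dir is required")
    alpha = raw.get("alpha", 0.05)
    if not 0 < alpha < 1:
        errors.append(f"alpha must be in (0, 1), got {alpha}")
    n_per_pair = raw.get("n_per_pair", 30)
    if n_per_pair <= 0 or n_per_pair % 2:
        errors.append(f"n_per_pair must be positive and even, got {n_per_pair}")
    grid = raw.get("grid", "reduced")
    if grid not in GRID_PRESETS:
        errors.append(f"grid must be one of {sorted(GRID_PRESETS)}, got {grid!r}")
    rois = raw.get("rois", ["midbrain", "dlpfc"])
    if len(set(rois)) != len(rois):
        errors.append(f"duplicate ROI names: {rois}")
    if grid == "reduced" and "striatum" in rois:
        errors.append("striatum ROI requires grid: full")
    n_perm = raw.get("n_perm", 5000)
    if n_perm < 100:
        errors.append(f"n_perm must be >= 100, got {n_perm}")
    gs = raw.get("group_sizes", {"controls": 39, "at_risk": 30, "fep": 14})
    for g, n in gs.items():
        if n < 2:
            errors.append(f"group_sizes[{g}] must be >= 2, got {n}")
    if errors:
        raise PipelineError("config", "; ".join(errors))
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        seed=int(raw.get("seed", 42)),
        group_sizes=gs,
        n_per_pair=int(n_per_pair),
        tr=float(raw.get("tr", 2.0)),
        trial_duration_s=float(raw.get("trial_duration_s", 10.0)),
        grid=grid,
        rois=list(rois),
        n_perm=int(n_perm),
        variance_smooth_fwhm_mm=float(raw.get("variance_smooth_fwhm_mm", 3.0)),
        tfce_e=float(raw.get("tfce_e", 0.5)),
        tfce_h=float(raw.get("tfce_h", 2.0)),
        alpha=float(alpha),
        write_bold=bool(raw.get("write_bold", False)),
    )


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)
    behaviour_tables: dict[str, str] = field(default_factory=dict)
    inference: list[dict] = field(default_factory=list)
    ordering_verdicts: dict[str, dict] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings_s: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_nifti(vol: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages in order; raises :class:`PipelineError` on failure."""
    report = RunReport(seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track = report.files

    def _record(path: Path) -> None:
        track[str(path.relative_to(out))] = _sha256(path)

    # ---- simulate -------------------------------------------------------
    t0 = time.time()
    try:
        masks = default_roi_masks(config.grid)
        cc = config.cohort_config()
        cohort = generate_cohort(cc)
        sim_dir = out / "dataset"
        sim_dir.mkdir(exist_ok=True)
        for s in cohort.subjects:
            s.behaviour.to_tsv(sim_dir / f"{s.sid}_behaviour.tsv")
            _record(sim_dir / f"{s.sid}_behaviour.tsv")
            ev = behaviour_events(s.behaviour, trial_duration_s=config.trial_duration_s)
            ev.to_csv(sim_dir / f"{s.sid}_events.tsv", sep="\t", index=False)
            _record(sim_dir / f"{s.sid}_events.tsv")
        cohort.manifest().to_csv(sim_dir / "manifest.csv", index=False)
        _record(sim_dir / "manifest.csv")
        for name, m in masks.masks.items():
            _write_nifti(m.astype(np.float32), masks.affine, sim_dir / f"mask_{name}.nii.gz")
            _record(sim_dir / f"mask_{name}.nii.gz")
        cfg_out = {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()}
        (sim_dir / "config.yaml").write_text(yaml.safe_dump(cfg_out))
        _record(sim_dir / "config.yaml")
        if config.write_bold:
            from .cohort import simulate_bold

            for s in cohort.subjects:
                rng = np.random.default_rng(s.bold_seed)
                vol = simulate_bold(
                    s.behaviour, masks, s.coupling, cc.noise, rng,
                    tr=config.tr, trial_duration_s=config.trial_duration_s,
                )
                _write_nifti(vol, masks.affine, sim_dir / f"{s.sid}_bold.nii.gz")
                _record(sim_dir / f"{s.sid}_bold.nii.gz")
        report.stages["simulate"] = "ok"
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e
    report.timings_s["simulate"] = time.time() - t0
    log.info("simulate: ok (%.1fs)", report.timings_s["simulate"])

    # ---- behave ---------------------------------------------------------
    t0 = time.time()
    try:
        beh_dir = out / "behaviour"
        beh_dir.mkdir(exist_ok=True)
        groups = cohort.groups()
        summary = cohort_summary([s.behaviour for s in cohort.subjects], groups)
        summary.to_csv(beh_dir / "summary.csv", index=False)
        _record(beh_dir / "summary.csv")
        for dv in ("correct_rate", "mean_rt"):
            tables = mixed_anova(
                summary, dv=dv, within="pair_type", subject="subject", between="group",
                n_perm=1000, seed=config.derived_seed(f"anova-{dv}"),
            )
            df = pd.DataFrame([asdict(t) for t in tables])
            df.to_csv(beh_dir / f"anova_{dv}.csv", index=False)
            _record(beh_dir / f"anova_{dv}.csv")
            post = pairwise_level_tests(summary, dv=dv, within="pair_type", subject="subject")
            post.to_csv(beh_dir / f"posthoc_{dv}.csv", index=False)
            _record(beh_dir / f"posthoc_{dv}.csv")
            report.behaviour_tables[dv] = f"behaviour/anova_{dv}.csv"
        report.stages["behave"] = "ok"
    except Exception as e:  # noqa: BLE001
        raise PipelineError("behave", str(e)) from e
    report.timings_s["behave"] = time.time() - t0
    log.info("behave: ok (%.1fs)", report.timings_s["behave"])

    # ---- firstlevel -----------------------------------------------------
    t0 = time.time()
    try:
        fl_dir = out / "firstlevel"
        fl_dir.mkdir(exist_ok=True)
        copes, groups = cohort_copes(
            cohort, masks, tr=config.tr, trial_duration_s=config.trial_duration_s,
            rois=config.rois,
        )
        for i, s in enumerate(cohort.subjects):
            vol = np.zeros(masks.shape, dtype=np.float32)
            for roi in config.rois:
                vol[masks.masks[roi]] = copes[roi][i]
            _write_nifti(vol, masks.affine, fl_dir / f"{s.sid}_cope.nii.gz")
            _record(fl_dir / f"{s.sid}_cope.nii.gz")
        report.stages["firstlevel"] = "ok"
    except Exception as e:  # noqa: BLE001
        raise PipelineError("firstlevel", str(e)) from e
    report.timings_s["firstlevel"] = time.time() - t0
    log.info("firstlevel: ok (%.1fs)", report.timings_s["firstlevel"])

    # ---- grouplevel -----------------------------------------------------
    t0 = time.time()
    try:
        gl_dir = out / "grouplevel"
        gl_dir.mkdir(exist_ok=True)
        symptoms = np.array([s.symptom for s in cohort.subjects])
        for roi in config.rois:
            mask = masks.masks[roi]
            vols = np.zeros((len(cohort.subjects),) + masks.shape)
            vols[:, mask] = copes[roi]
            res = permutation_fwe(
                vols, groups, mask,
                n_perm=config.n_perm, seed=config.derived_seed(f"perm-{roi}"),
                variance_smooth_fwhm_mm=config.variance_smooth_fwhm_mm,
                voxel_size_mm=masks.voxel_size_mm,
                E=config.tfce_e, H=config.tfce_h, alpha=config.alpha,
            )
            for nm, vol in (
                ("stat", res.stat_map), ("tfce", res.tfce_map), ("1minusp", 1.0 - res.p_corrected),
            ):
                _write_nifti(vol, masks.affine, gl_dir / f"{roi}_{nm}.nii.gz")
                _record(gl_dir / f"{roi}_{nm}.nii.gz")
            present = sorted(set(groups))
            comparisons = [c for c in PLANNED_COMPARISONS if c[0] in present and c[1] in present]
            cs = extract_cluster_means(
                vols, res.significant, groups, comparisons=comparisons,
                seed=config.derived_seed(f"pairwise-{roi}"),
            )
            rows = []
            for g in present:
                rows.append({"roi": roi, "group": g,
                             "mean": cs.group_means[g], "sd": cs.group_sds[g]})
            pd.DataFrame(rows).to_csv(gl_dir / f"{roi}_cluster_means.csv", index=False)
            _record(gl_dir / f"{roi}_cluster_means.csv")
            verdict = {
                "n_significant": res.n_significant,
                "min_p": res.min_p,
                "empty": cs.empty,
                "pairwise_p": {f"{a}>{b}": p for (a, b), p in cs.pairwise_p.items()},
                "ordering_holds": (
                    not cs.empty
                    and all(
                        cs.group_means.get(a, np.nan) > cs.group_means.get(b, np.nan)
                        for a, b in comparisons
                    )
                ),
            }
            # symptom correlations within the clinical groups
            if not cs.empty:
                for g in ("at_risk", "fep"):
                    if g in present:
                        sel = groups == g
                        rho, p = symptom_correlation(cs.subject_means[sel], symptoms[sel])
                        verdict[f"symptom_rho_{g}"] = rho
                        verdict[f"symptom_p_{g}"] = p
            report.ordering_verdicts[roi] = verdict
            report.inference.append(
                {"roi": roi, "n_significant": res.n_significant, "min_p": res.min_p,
                 "n_perm": res.n_perm, "exhaustive": res.exhaustive}
            )
        manifest = {"seed": config.seed, "n_perm": config.n_perm,
                    "rois": config.rois, "alpha": config.alpha}
        (gl_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        _record(gl_dir / "run_manifest.json")
        report.stages["grouplevel"] = "ok"
    except Exception as e:  # noqa: BLE001
        raise PipelineError("grouplevel", str(e)) from e
    report.timings_s["grouplevel"] = time.time() - t0
    log.info("grouplevel: ok (%.1fs)", report.timings_s["grouplevel"])

    # ---- report ---------------------------------------------------------
    try:
        report.stages["report"] = "ok"
        report.to_json(out / "report.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("report", str(e)) from e
    return report
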