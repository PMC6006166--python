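"""Behavioural analyses: correct-choice rates, win-stay/lose-shift, RTs, mixed ANOVA.

"Correct" means choosing the designated high-probability stimulus of a pair
(for bivalent pairs the designation is arbitrary but fixed, so the rate
measures stimulus preference rather than accuracy).  Win-stay/lose-shift
probabilities condition on consecutive presentations of the same pair:
a "win" is a £1 win for reward and bivalent pairs and feedback kind A
(colour match) for neutral pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import PAIR_TYPES
from .rl import SubjectBehaviour

__all__ = [
    "correct_rate",
    "wsls",
    "learning_curve",
    "summarise",
    "cohort_summary",
    "mixed_anova",
    "AnovaTable",
]


def correct_rate(behaviour: SubjectBehaviour) -> dict[str, float]:
    """Proportion of trials on which the designated correct stimulus was chosen."""
    pts = behaviour.schedule.pair_types
    choices = np.asarray(behaviour.choices)
    return {pt: float(np.mean(choices[pts == pt] == 0)) for pt in PAIR_TYPES}


def _is_win(pair_type: str, value: float, kind: str) -> bool:
    if pair_type == "neutral":
        return kind == "neutral_A"
    return value > 0


def wsls(behaviour: SubjectBehaviour) -> dict[str, dict[str, float]]:
    """Win-stay and lose-shift probabilities per pair type and overall.

    Transitions are consecutive presentations of the same pair (intervening
    trials of other pairs do not break the chain).  Rates with a zero
    denominator are returned as NaN, never as 0.  The returned dict maps
    pair type (and ``"overall"``) to ``{win_stay, lose_shift, n_win, n_lose}``.
    """
    pts = behaviour.schedule.pair_types
    choices = np.asarray(behaviour.choices)
    out: dict[str, dict[str, float]] = {}
    tot_stay = tot_win = tot_shift = tot_lose = 0
    for pt in PAIR_TYPES:
        idx = np.flatnonzero(pts == pt)
        stay = win = shift = lose = 0
        for a, b in zip(idx[:-1], idx[1:]):
            won = _is_win(pt, behaviour.outcome_values[a], behaviour.feedback_kinds[a])
            same = choices[a] == choices[b]
            if won:
                win += 1
                stay += same
            else:
                lose += 1
                shift += not same
        out[pt] = {
            "win_stay": stay / win if win else np.nan,
            "lose_shift": shift / lose if lose else np.nan,
            "n_win": win,
            "n_lose": lose,
        }
        tot_stay += stay
        tot_win += win
        tot_shift += shift
        tot_lose += lose
    out["overall"] = {
        "win_stay": tot_stay / tot_win if tot_win else np.nan,
        "lose_shift": tot_shift / tot_lose if tot_lose else np.nan,
        "n_win": tot_win,
        "n_lose": tot_lose,
    }
    return out


def learning_curve(behaviour: SubjectBehaviour, n_bins: int = 6) -> dict[str, np.ndarray]:
    """Correct-choice rate per trial bin, within pair type."""
    pts = behaviour.schedule.pair_types
    choices = np.asarray(behaviour.choices)
    curves = {}
    for pt in PAIR_TYPES:
        correct = (choices[pts == pt] == 0).astype(float)
        bins = np.array_split(correct, n_bins)
        curves[pt] = np.array([b.mean() if len(b) else np.nan for b in bins])
    return curves


def summarise(behaviour: SubjectBehaviour, n_bins: int = 6) -> dict:
    """Per-subject behavioural summary (rates, WSLS, mean RTs, learning curve)."""
    cr = correct_rate(behaviour)
    ws = wsls(behaviour)
    pts = behaviour.schedule.pair_types
    rts = np.asarray(behaviour.rts, dtype=float)
    mean_rt = {
        pt: (float(np.nanmean(rts[pts == pt])) if np.any(np.isfinite(rts[pts == pt])) else np.nan)
        for pt in PAIR_TYPES
    }
    return {
        "correct_rate": cr,
        "win_stay": {k: v["win_stay"] for k, v in ws.items()},
        "lose_shift": {k: v["lose_shift"] for k, v in ws.items()},
        "mean_rt": mean_rt,
        "learning_curve": learning_curve(behaviour, n_bins),
    }


def cohort_summary(behaviours, groups) -> pd.DataFrame:
    """Long-format per-subject, per-pair-type summary table for a cohort."""
    rows = []
    for i, (b, g) in enumerate(zip(behaviours, groups)):
        s = summarise(b)
        for pt in PAIR_TYPES:
            rows.append(
                {
                    "subject": i,
                    "group": g,
                    "pair_type": pt,
                    "correct_rate": s["correct_rate"][pt],
                    "win_stay": s["win_stay"][pt],
                    "lose_shift": s["lose_shift"][pt],
                    "mean_rt": s["mean_rt"][pt],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaTable:
    """One effect of the mixed ANOVA."""

    effect: str
    F: float
    df1: int
    df2: int
    p_parametric: float
    p_permutation: float


def _mixed_anova_F(wide: np.ndarray, group_codes: np.ndarray) -> tuple[float, float, float]:
    """F statistics (group, within-level, interaction) for a balanced-within
    mixed design.

    ``wide`` is (n_subjects, n_levels); ``group_codes`` integer group per
    subject.  Between-group sizes may be unequal (weighted-means solution).
    """
    n, t = wide.shape
    gm = wide.mean()
    subj_means = wide.mean(axis=1)
    level_means = wide.mean(axis=0)
    k = group_codes.max() + 1
    ss_group = 0.0
    ss_cells = 0.0
    for g in range(k):
        sel = group_codes == g
        ng = sel.sum()
        if ng == 0:
            raise ValueError("empty group")
        gmean = wide[sel].mean()
        ss_group += t * ng * (gmean - gm) ** 2
        cell_means = wide[sel].mean(axis=0)
        ss_cells += ng * np.sum((cell_means - gm) ** 2)
    ss_between_subj = t * np.sum((subj_means - gm) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_level = n * np.sum((level_means - gm) ** 2)
    ss_inter = ss_cells - ss_group - ss_level
    ss_total = np.sum((wide - gm) ** 2)
    ss_err = ss_total - ss_cells - ss_subj_within

    df_group, df_subj = k - 1, n - k
    df_level, df_inter, df_err = t - 1, (k - 1) * (t - 1), (n - k) * (t - 1)
    ms_subj = ss_subj_within / df_subj
    ms_err = ss_err / df_err
    f_group = (ss_group / df_group) / ms_subj if ms_subj > 0 else 0.0
    f_level = (ss_level / df_level) / ms_err if ms_err > 0 else 0.0
    f_inter = (ss_inter / df_inter) / ms_err if ms_err > 0 else 0.0
    return max(f_group, 0.0), max(f_level, 0.0), max(f_inter, 0.0)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[AnovaTable]:
    """Mixed-model ANOVA (between-group x within-subject) with permutation p.

    Requires a complete balanced within-subject design (every subject has
    every level exactly once).  Permutation p-values: the between-group
    effect permutes subject group labels; the within and interaction effects
    permute level labels independently within each subject.  Parametric
    p-values from the F distribution are reported as a cross-check.
    """
    from scipy.stats import f as f_dist

    piv = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="count")
    if piv.isna().any().any() or not (piv == 1).all().all():
        raise ValueError("unbalanced within-subject data: every subject needs every level once")

    wide_df = data.pivot(index=subject, columns=within, values=dv)
    grp = data.groupby(subject)[between].first().loc[wide_df.index]
    group_names = sorted(grp.unique())
    codes = grp.map({g: i for i, g in enumerate(group_names)}).to_numpy()
    wide = wide_df.to_numpy(dtype=float)
    n, t = wide.shape
    k = len(group_names)
    if k < 2:
        raise ValueError("need at least two groups")

    f_obs = _mixed_anova_F(wide, codes)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(3)
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        fg, _, _ = _mixed_anova_F(wide, perm_codes)
        # within-subject exchangeability: shuffle levels within each subject
        shuf = wide.copy()
        idx = np.argsort(rng.random(wide.shape), axis=1)
        shuf = np.take_along_axis(shuf, idx, axis=1)
        _, fl, fi = _mixed_anova_F(shuf, codes)
        exceed += [fg >= f_obs[0], fl >= f_obs[1], fi >= f_obs[2]]
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    dfs = [
        (k - 1, n - k),
        (t - 1, (n - k) * (t - 1)),
        ((k - 1) * (t - 1), (n - k) * (t - 1)),
    ]
    names = ["group", within, f"group*{within}"]
    return [
        AnovaTable(
            effect=nm,
            F=float(f),
            df1=d1,
            df2=d2,
            p_parametric=float(f_dist.sf(f, d1, d2)),
            p_permutation=float(pp),
        )
        for nm, f, (d1, d2), pp in zip(names, f_obs, dfs, p_perm)
    ]


def pairwise_level_tests(
    data: pd.DataFrame, dv: str, within: str, subject: str
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests between within-subject levels."""
    from itertools import combinations

    from scipy.stats import ttest_rel

    wide = data.pivot(index=subject, columns=within, values=dv)
    pairs = list(combinations(wide.columns, 2))
    rows = []
    for a, b in pairs:
        t, p = ttest_rel(wide[a], wide[b])
        rows.append({"a": a, "b": b, "t": float(t), "p_bonf": min(1.0, float(p) * len(pairs))})
    return pd.DataFrame(rows)


def plot_learning_curves(behaviours, path, n_bins: int = 6) -> None:
    """Cohort-mean learning curves per pair type (optional figure output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for pt in PAIR_TYPES:
        curves = np.array([learning_curve(b, n_bins)[pt] for b in behaviours])
        ax.plot(np.arange(1, n_bins + 1), curves.mean(axis=0), marker="o", label=pt)
    ax.set_xlabel("trial bin")
    ax.set_ylabel("P(correct)")
    ax.axhline(0.5, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
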