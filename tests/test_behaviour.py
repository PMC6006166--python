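import numpy as np
import pandas as pd
import pytest

from pefmri.task import PAIR_TYPES, generate_schedule
from pefmri.rl import QParams, SubjectBehaviour, simulate_agent
from pefmri.behaviour import (
    correct_rate,
    learning_curve,
    mixed_anova,
    summarise,
    wsls,
)


def _manual_behaviour(schedule, choices, values, kinds):
    n = len(schedule)
    return SubjectBehaviour(
        schedule=schedule,
        choices=np.asarray(choices),
        outcome_values=np.asarray(values, dtype=float),
        feedback_kinds=list(kinds),
        rts=np.full(n, np.nan),
        deltas=np.zeros(n),
    )


def test_correct_rate_always_high_prob_agent(small_schedule):
    n = len(small_schedule)
    beh = _manual_behaviour(small_schedule, np.zeros(n, int), np.zeros(n), ["neutral_A"] * n)
    assert correct_rate(beh) == {pt: 1.0 for pt in PAIR_TYPES}


def test_correct_rate_random_agent():
    sched = generate_schedule(400, seed=1)
    beh = simulate_agent(QParams(0.0, 0.0), sched, np.random.default_rng(2))
    for rate in correct_rate(beh).values():
        assert rate == pytest.approx(0.5, abs=0.08)


def test_wsls_hand_count():
    """choices A,A,A,B with outcomes win,win,no-win: win_stay=2/2, lose_shift=1/1."""
    sched = generate_schedule(4, seed=3)
    n = len(sched)
    choices = np.zeros(n, int)
    values = np.zeros(n)
    kinds = ["neutral_B"] * n
    reward_idx = np.flatnonzero(sched.pair_types == "reward")
    choices[reward_idx] = [0, 0, 0, 1]
    for j, i in enumerate(reward_idx):
        if j < 2:
            values[i], kinds[i] = 1.0, "win"
        else:
            values[i], kinds[i] = 0.0, "neutral_A"
    beh = _manual_behaviour(sched, choices, values, kinds)
    res = wsls(beh)["reward"]
    assert res["win_stay"] == 1.0
    assert res["n_win"] == 2
    assert res["lose_shift"] == 1.0
    assert res["n_lose"] == 1


def test_wsls_denominators_partition_transitions(typical_behaviour):
    res = wsls(typical_behaviour)
    n_per_pair = typical_behaviour.schedule.n_per_pair
    for pt in PAIR_TYPES:
        assert res[pt]["n_win"] + res[pt]["n_lose"] == n_per_pair - 1
    assert res["overall"]["n_win"] + res["overall"]["n_lose"] == 3 * (n_per_pair - 1)


def test_wsls_random_agent_near_half():
    rng = np.random.default_rng(7)
    ws, ls = [], []
    for i in range(100):
        sched = generate_schedule(30, seed=500 + i)
        beh = simulate_agent(QParams(0.0, 0.0), sched, rng)
        r = wsls(beh)["overall"]
        ws.append(r["win_stay"])
        ls.append(r["lose_shift"])
    assert np.nanmean(ws) == pytest.approx(0.5, abs=0.03)
    assert np.nanmean(ls) == pytest.approx(0.5, abs=0.03)


def test_wsls_zero_denominator_is_nan(small_schedule):
    n = len(small_schedule)
    # all losses on bivalent trials -> no win transitions there
    values = np.where(small_schedule.pair_types == "bivalent", -1.0, 0.0)
    kinds = ["loss" if v < 0 else "neutral_B" for v in values]
    beh = _manual_behaviour(small_schedule, np.zeros(n, int), values, kinds)
    assert np.isnan(wsls(beh)["bivalent"]["win_stay"])


def test_learning_curve_rises_for_learners():
    rng = np.random.default_rng(8)
    curves = []
    for i in range(150):
        sched = generate_schedule(30, seed=900 + i)
        beh = simulate_agent(QParams(0.3, 3.0), sched, rng)
        curves.append(learning_curve(beh)["reward"])
    mean_curve = np.mean(curves, axis=0)
    assert mean_curve[-1] > mean_curve[0] + 0.1


def _toy_mixed_data():
    # 2 groups x 3 subjects x 3 levels, integer values
    rows = []
    values = {
        ("g1", 0): [3, 5, 4], ("g1", 1): [2, 6, 4], ("g1", 2): [4, 7, 6],
        ("g2", 3): [6, 8, 9], ("g2", 4): [5, 9, 8], ("g2", 5): [7, 10, 9],
    }
    for (g, s), vals in values.items():
        for lvl, v in zip("abc", vals):
            rows.append({"subject": s, "group": g, "level": lvl, "y": float(v)})
    return pd.DataFrame(rows)


def _brute_force_F(df):
    """Independent sums-of-squares decomposition with explicit loops."""
    y = df.set_index(["subject", "level"])["y"]
    subjects = sorted(df["subject"].unique())
    levels = sorted(df["level"].unique())
    groups = {s: df[df.subject == s]["group"].iloc[0] for s in subjects}
    gnames = sorted(set(groups.values()))
    gm = df["y"].mean()
    t, n, k = len(levels), len(subjects), len(gnames)
    ss_total = sum((y[(s, l)] - gm) ** 2 for s in subjects for l in levels)
    subj_mean = {s: np.mean([y[(s, l)] for l in levels]) for s in subjects}
    grp_mean = {
        g: np.mean([y[(s, l)] for s in subjects if groups[s] == g for l in levels])
        for g in gnames
    }
    lvl_mean = {l: np.mean([y[(s, l)] for s in subjects]) for l in levels}
    cell_mean = {
        (g, l): np.mean([y[(s, l)] for s in subjects if groups[s] == g])
        for g in gnames
        for l in levels
    }
    ng = {g: sum(1 for s in subjects if groups[s] == g) for g in gnames}
    ss_group = sum(t * ng[g] * (grp_mean[g] - gm) ** 2 for g in gnames)
    ss_subj = sum(t * (subj_mean[s] - gm) ** 2 for s in subjects) - ss_group
    ss_level = sum(n * (lvl_mean[l] - gm) ** 2 for l in levels)
    ss_cells = sum(ng[g] * (cell_mean[(g, l)] - gm) ** 2 for g in gnames for l in levels)
    ss_inter = ss_cells - ss_group - ss_level
    ss_err = ss_total - ss_cells - ss_subj
    f_group = (ss_group / (k - 1)) / (ss_subj / (n - k))
    f_level = (ss_level / (t - 1)) / (ss_err / ((n - k) * (t - 1)))
    f_inter = (ss_inter / ((k - 1) * (t - 1))) / (ss_err / ((n - k) * (t - 1)))
    return f_group, f_level, f_inter


def test_mixed_anova_matches_brute_force_oracle():
    df = _toy_mixed_data()
    tables = mixed_anova(df, dv="y", within="level", subject="subject", between="group",
                         n_perm=200, seed=0)
    expected = _brute_force_F(df)
    for table, f_exp in zip(tables, expected):
        assert table.F == pytest.approx(f_exp, rel=1e-10)
        assert table.F >= 0


def test_mixed_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    df = _toy_mixed_data()
    tables = mixed_anova(df, dv="y", within="level", subject="subject", between="group",
                         n_perm=200, seed=0)
    ref = pg.mixed_anova(data=df, dv="y", within="level", subject="subject", between="group")
    by_name = {t.effect: t for t in tables}
    assert by_name["group"].F == pytest.approx(
        float(ref.loc[ref.Source == "group", "F"].iloc[0]), rel=1e-6
    )
    assert by_name["level"].F == pytest.approx(
        float(ref.loc[ref.Source == "level", "F"].iloc[0]), rel=1e-6
    )
    assert by_name["group*level"].F == pytest.approx(
        float(ref.loc[ref.Source == "Interaction", "F"].iloc[0]), rel=1e-6
    )


def test_mixed_anova_zero_variance_gives_zero_F():
    df = _toy_mixed_data()
    df["y"] = 1.0
    tables = mixed_anova(df, dv="y", within="level", subject="subject", between="group",
                         n_perm=150, seed=0)
    for t in tables:
        assert t.F == 0.0


def test_mixed_anova_rejects_unbalanced():
    df = _toy_mixed_data().iloc[:-1]
    with pytest.raises(ValueError):
        mixed_anova(df, dv="y", within="level", subject="subject", between="group")


def test_mixed_anova_permutation_null_calibration():
    """Group labels exchangeable by construction -> permutation p uniform."""
    rng = np.random.default_rng(10)
    ps = []
    for _ in range(200):
        rows = []
        for s in range(12):
            g = "g1" if s < 6 else "g2"
            for l in "abc":
                rows.append({"subject": s, "group": g, "level": l, "y": rng.normal()})
        df = pd.DataFrame(rows)
        tables = mixed_anova(df, dv="y", within="level", subject="subject",
                             between="group", n_perm=99, seed=int(rng.integers(2**31)))
        ps.append(tables[0].p_permutation)
    ps = np.array(ps)
    assert abs(ps.mean() - 0.5) < 0.07
    assert 0.01 <= (ps <= 0.05).mean() <= 0.10


def test_parametric_and_permutation_p_agree_on_gaussian_data():
    rng = np.random.default_rng(11)
    rows = []
    for s in range(20):
        g = "g1" if s < 10 else "g2"
        shift = 0.8 if g == "g2" else 0.0
        for j, l in enumerate("abc"):
            rows.append({"subject": s, "group": g, "level": l,
                         "y": rng.normal() + shift + 0.3 * j})
    df = pd.DataFrame(rows)
    tables = mixed_anova(df, dv="y", within="level", subject="subject", between="group",
                         n_perm=2000, seed=0)
    for t in tables:
        assert t.p_permutation == pytest.approx(t.p_parametric, abs=0.06)


def test_summarise_reports_all_fields(typical_behaviour):
    s = summarise(typical_behaviour)
    assert set(s) == {"correct_rate", "win_stay", "lose_shift", "mean_rt", "learning_curve"}
    for pt in PAIR_TYPES:
        assert 0.0 <= s["correct_rate"][pt] <= 1.0
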