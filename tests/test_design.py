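import numpy as np
import pandas as pd
import pytest

from pefmri.design import (
    EVENT_LABELS,
    behaviour_events,
    build_design_matrix,
    double_gamma_hrf,
    fit_glm,
    pe_contrast,
)


def test_hrf_shape():
    t = np.arange(0, 32, 0.1)
    h = double_gamma_hrf(t)
    assert h[0] == 0.0
    assert h.max() == pytest.approx(1.0)
    assert 4.5 <= t[np.argmax(h)] <= 5.5
    late = (t > 8) & (t < 20)
    assert h[late].min() < 0  # undershoot


def test_hrf_rejects_nonpositive_parameters():
    t = np.arange(0, 32, 0.1)
    with pytest.raises(ValueError):
        double_gamma_hrf(t, peak_delay=0.0)
    with pytest.raises(ValueError):
        double_gamma_hrf(t, undershoot_disp=-1.0)


def test_hrf_matches_nilearn_spm_shape():
    hm = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
    t = np.arange(0, 32, 0.1)
    ours = double_gamma_hrf(t)
    ref = hm.spm_hrf(1.0, oversampling=10, time_length=32.0)
    n = min(len(ours), len(ref))
    r = np.corrcoef(ours[:n], ref[:n])[0, 1]
    assert r > 0.999


def test_events_table_has_seven_classes_and_2s_durations(typical_behaviour):
    ev = behaviour_events(typical_behaviour)
    assert set(ev["trial_type"]) <= set(EVENT_LABELS)
    assert len(EVENT_LABELS) == 7
    assert (ev["duration"] == 2.0).all()
    assert len(ev) == 2 * len(typical_behaviour.schedule)  # one cue + one outcome per trial


def test_design_has_14_task_columns(typical_behaviour):
    ev = behaviour_events(typical_behaviour)
    X = build_design_matrix(ev, n_volumes=460, tr=2.0)
    task_cols = [c for c in X.columns if c in EVENT_LABELS or c.endswith("_deriv")]
    assert len(X.task_labels) == 7
    assert len(task_cols) == 14


def test_zero_event_regressor_dropped_with_warning():
    ev = pd.DataFrame(
        {"onset": [0.0, 10.0], "duration": [2.0, 2.0],
         "trial_type": ["reward_cue", "reward_win"], "modulation": [1.0, 1.0]}
    )
    with pytest.warns(UserWarning, match="zero events"):
        X = build_design_matrix(ev, n_volumes=20, tr=2.0)
    assert "bivalent_win" in X.dropped
    assert "reward_cue" in X.columns


def test_design_rejects_bad_events():
    ev = pd.DataFrame({"onset": [100.0], "duration": [2.0],
                       "trial_type": ["reward_win"], "modulation": [1.0]})
    with pytest.raises(ValueError, match="outside the scan"):
        build_design_matrix(ev, n_volumes=10, tr=2.0)
    ev = pd.DataFrame({"onset": [0.0], "duration": [2.0],
                       "trial_type": ["mystery"], "modulation": [1.0]})
    with pytest.raises(ValueError, match="unknown event labels"):
        build_design_matrix(ev, n_volumes=10, tr=2.0)


def test_single_event_column_equals_manual_convolution():
    ev = pd.DataFrame({"onset": [0.0], "duration": [2.0],
                       "trial_type": ["reward_win"], "modulation": [1.0]})
    tr, dt, n_vol = 2.0, 0.1, 20
    with pytest.warns(UserWarning):
        X = build_design_matrix(ev, n_volumes=n_vol, tr=tr, dt=dt)
    # oracle: boxcar convolved with the HRF on the fine grid, sampled at TRs
    n_fine = int(np.ceil(n_vol * tr / dt)) + 1
    box = np.zeros(n_fine)
    box[: int(2.0 / dt)] = 1.0
    hrf = double_gamma_hrf(np.arange(0, 32 + dt, dt))
    expected = np.convolve(box, hrf)[:n_fine] * dt
    got = X.frame["reward_win"].to_numpy()
    assert np.allclose(got, expected[np.round(np.arange(n_vol) * tr / dt).astype(int)])


def _tiny_design():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [1.0, 0, 1, 0, 1, 0]})
    from pefmri.design import DesignMatrix

    return DesignMatrix(frame=X, tr=1.0, task_labels=())


def test_glm_exact_recovery_and_orthogonal_residuals():
    design = _tiny_design()
    b_true = np.array([[2.0], [-1.0]])
    y = design.values @ b_true
    fit = fit_glm(y, design)
    assert np.allclose(fit.betas, b_true, atol=1e-12)
    # residual orthogonality on noisy data
    rng = np.random.default_rng(0)
    y = design.values @ b_true + rng.normal(0, 1, (6, 1))
    fit = fit_glm(y, design)
    resid = y - design.values @ fit.betas
    assert np.allclose(design.values.T @ resid, 0, atol=1e-9)


def test_glm_matches_normal_equations_oracle():
    design = _tiny_design()
    rng = np.random.default_rng(1)
    y = rng.normal(size=(6, 3))
    fit = fit_glm(y, design)
    X = design.values
    expected = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.betas, expected)
    resid = y - X @ expected
    assert np.allclose(fit.residual_variance, (resid**2).sum(axis=0) / (6 - 2))
    assert fit.dof == 4


def test_glm_rank_deficiency_names_columns():
    from pefmri.design import DesignMatrix

    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    design = DesignMatrix(frame=X, tr=1.0, task_labels=())
    with pytest.raises(ValueError, match="rank deficient"):
        fit_glm(np.ones(4), design)


def test_glm_rejects_length_mismatch():
    design = _tiny_design()
    with pytest.raises(ValueError, match="length"):
        fit_glm(np.ones(5), design)


def test_pe_contrast_arithmetic_and_missing_regressor():
    from pefmri.design import GlmFit

    fit = GlmFit(betas=np.array([[2.0], [0.5]]), columns=["bivalent_win", "reward_win"],
                 residual_variance=np.array([1.0]), dof=10)
    assert pe_contrast(fit)[0] == pytest.approx(1.5)
    fit2 = GlmFit(betas=np.array([[1.0], [1.0]]), columns=["bivalent_win", "reward_win"],
                  residual_variance=np.array([1.0]), dof=10)
    assert pe_contrast(fit2)[0] == 0.0
    fit3 = GlmFit(betas=np.array([[1.0]]), columns=["bivalent_win"],
                  residual_variance=np.array([1.0]), dof=10)
    with pytest.raises(ValueError, match="reward_win"):
        pe_contrast(fit3)


def test_contrast_is_value_balanced(typical_behaviour):
    """A value-coding (non-PE) response contributes equally to both win
    regressors, so the contrast is exactly zero without noise."""
    ev = behaviour_events(typical_behaviour)
    n_vol = 460
    X = build_design_matrix(ev, n_volumes=n_vol, tr=2.0)
    value_signal = (
        X.frame["bivalent_win"].to_numpy() + X.frame["reward_win"].to_numpy()
    )  # equal unit amplitude for every £1 win
    fit = fit_glm(value_signal, X)
    assert pe_contrast(fit)[0] == pytest.approx(0.0, abs=1e-10)


def test_null_copes_centered_on_zero(typical_behaviour):
    ev = behaviour_events(typical_behaviour)
    n_vol = 460
    X = build_design_matrix(ev, n_volumes=n_vol, tr=2.0)
    rng = np.random.default_rng(2)
    y = rng.normal(0, 1, (n_vol, 500))  # 500 independent null repetitions
    copes = pe_contrast(fit_glm(y, X))
    se = copes.std(ddof=1) / np.sqrt(len(copes))
    assert abs(copes.mean()) < 4 * se


def test_pe_modulated_and_contrast_paths_agree_in_sign():
    """The model-based parametric-modulator estimate and the balanced
    contrast agree in sign for every PE-coupled synthetic subject."""
    from pefmri.task import generate_schedule
    from pefmri.rl import QParams, simulate_agent

    rng = np.random.default_rng(3)
    for i in range(6):
        sched = generate_schedule(30, seed=40 + i)
        beh = simulate_agent(QParams(0.3, 3.0), sched, rng)
        ev = behaviour_events(beh)
        n_vol = 460
        Xmod = build_design_matrix(ev, n_volumes=n_vol, tr=2.0, modulated=True,
                                   add_intercept=False)
        pe_signal = Xmod.frame["bivalent_win"].to_numpy() + Xmod.frame["reward_win"].to_numpy()
        y = 80.0 * pe_signal + rng.normal(0, 20, n_vol)

        X = build_design_matrix(ev, n_volumes=n_vol, tr=2.0)
        cope = pe_contrast(fit_glm(y, X))[0]

        # alternative path: unmodulated events plus a demeaned PE modulator
        ev2 = ev.copy()
        win = ev2["trial_type"].isin(["bivalent_win", "reward_win"])
        ev2.loc[win, "modulation"] -= ev2.loc[win, "modulation"].mean()
        Xpe = build_design_matrix(ev2, n_volumes=n_vol, tr=2.0, modulated=True,
                                  add_intercept=False)
        pe_mod = Xpe.frame["bivalent_win"].to_numpy() + Xpe.frame["reward_win"].to_numpy()
        X2 = build_design_matrix(ev, n_volumes=n_vol, tr=2.0,
                                 nuisance=pd.DataFrame({"pe_mod": pe_mod}))
        beta_pe = fit_glm(y, X2).beta("pe_mod")[0]
        assert np.sign(beta_pe) == np.sign(cope) == 1.0
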