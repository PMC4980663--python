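"""Statistical machinery: ANOVA oracles, stepwise selection, ROC concordance."""

import numpy as np
import pandas as pd
import pytest

from octcornea.stats import (
    anova_groups,
    discriminant_score,
    fit_discriminant,
    roc_analysis,
    stepwise_lda,
)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def test_anova_matches_hand_computed_sums_of_squares():
    """3 groups x 3 values, F from explicit between/within sums of squares."""
    data = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [5.0, 6.0, 10.0]}
    values = np.concatenate(list(data.values()))
    labels = np.repeat(list(data), 3)
    grand = values.mean()
    ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
    ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in data.values())
    F_oracle = (ss_between / 2) / (ss_within / 6)
    res = anova_groups(values, labels)
    assert res["F"].iloc[0] == pytest.approx(F_oracle, rel=1e-12)
    a_row = res[res["group"] == "a"].iloc[0]
    assert a_row["mean"] == pytest.approx(2.0)
    assert a_row["sd"] == pytest.approx(1.0)


def test_two_group_f_equals_squared_t():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)])
    labels = np.array(["a"] * 12 + ["b"] * 15)
    from scipy.stats import ttest_ind

    t, _ = ttest_ind(x[:12], x[12:], equal_var=True)
    F = anova_groups(x, labels)["F"].iloc[0]
    assert F == pytest.approx(t**2, rel=1e-10)


def test_anova_type_I_error_rate_near_nominal():
    """Identically distributed groups: rejection rate at alpha=0.05 is ~5%."""
    rng = np.random.default_rng(17)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        x = rng.normal(0, 1, 150)
        labels = np.repeat(["a", "b", "c"], 50)
        p = anova_groups(x, labels)["p"].iloc[0]
        rejections += p < 0.05
    rate = rejections / n_rep
    assert 0.02 < rate < 0.09  # ~3 SE band around 0.05


def test_anova_small_group_rejected():
    with pytest.raises(ValueError):
        anova_groups(np.arange(4.0), ["a", "a", "a", "b"])


# ---------------------------------------------------------------------------
# stepwise LDA
# ---------------------------------------------------------------------------


def _sim_features(seed, n_per=30, informative_shift=3.0):
    rng = np.random.default_rng(seed)
    labels = np.array(["normal"] * n_per + ["kc"] * n_per)
    df = pd.DataFrame(
        {
            "signal": np.concatenate(
                [rng.normal(0, 1, n_per), rng.normal(informative_shift, 1, n_per)]
            ),
            "noise1": rng.normal(0, 1, 2 * n_per),
            "noise2": rng.normal(0, 1, 2 * n_per),
        }
    )
    return df, labels


def test_stepwise_selects_separating_feature_and_rejects_noise():
    df, labels = _sim_features(seed=20)
    model = stepwise_lda(df, labels, f_enter=3.84)
    assert model.features[0] == "signal"
    assert "noise1" not in model.features and "noise2" not in model.features
    assert all(f > 3.84 for f in model.entry_f)
    # Wilks' lambda strictly decreases along the entry sequence
    assert all(b < a for a, b in zip(model.wilks_trajectory, model.wilks_trajectory[1:]))


def test_stepwise_all_noise_gives_empty_flagged_model():
    df, labels = _sim_features(seed=22, informative_shift=0.0)
    model = stepwise_lda(df, labels, f_enter=3.84)
    assert model.empty
    assert model.features == []
    with pytest.raises(ValueError, match="empty"):
        discriminant_score(model, df)


def test_fisher_closed_form_two_groups():
    """The two-group discriminant direction is proportional to
    pooled-covariance-inverse times the mean difference."""
    rng = np.random.default_rng(9)
    n = 40
    a = rng.multivariate_normal([0, 0], [[2.0, 0.6], [0.6, 1.0]], n)
    b = rng.multivariate_normal([1.5, 0.5], [[2.0, 0.6], [0.6, 1.0]], n)
    df = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2"])
    labels = np.array(["normal"] * n + ["kc"] * n)
    model = fit_discriminant(df, labels, ["f1", "f2"])
    Sa = np.cov(a.T) * (n - 1)
    Sb = np.cov(b.T) * (n - 1)
    S_pooled = (Sa + Sb) / (2 * n - 2)
    w_oracle = np.linalg.solve(S_pooled, b.mean(axis=0) - a.mean(axis=0))
    got = np.asarray(model.coefficients)
    ratio = got / w_oracle
    assert ratio[0] == pytest.approx(ratio[1], rel=1e-8)


def test_discriminant_score_linear_form_and_orientation():
    df, labels = _sim_features(seed=30)
    model = stepwise_lda(df, labels, f_enter=3.84)
    scores = discriminant_score(model, df)
    oracle = df[model.features].to_numpy() @ np.asarray(model.coefficients) + model.intercept
    np.testing.assert_allclose(scores, oracle, atol=1e-12)
    assert scores[labels == "kc"].mean() > scores[labels == "normal"].mean()


def test_stepwise_invariant_to_column_order():
    df, labels = _sim_features(seed=31)
    m1 = stepwise_lda(df, labels)
    m2 = stepwise_lda(df[["noise2", "signal", "noise1"]], labels)
    assert m1.features == m2.features
    np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-10)


def test_missing_feature_value_rejected():
    df, labels = _sim_features(seed=32)
    model = stepwise_lda(df, labels)
    with pytest.raises(ValueError, match="[Mm]issing"):
        discriminant_score(model, df.drop(columns=model.features[0]))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def _auc_pair_counting(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def test_perfect_separation():
    scores = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 6.0])
    y = np.array([False, False, False, True, True, True])
    r = roc_analysis(scores, y)
    assert r.auc == pytest.approx(1.0)
    assert r.sensitivity_at_cutoff == 1.0 and r.specificity_at_cutoff == 1.0
    # the cutoff actually separates the sample
    assert np.all(scores[y] >= r.cutoff) and np.all(scores[~y] < r.cutoff)


def test_null_auc_near_half():
    rng = np.random.default_rng(8)
    scores = rng.normal(size=2000)
    y = rng.random(2000) < 0.5
    r = roc_analysis(scores, y)
    assert abs(r.auc - 0.5) < 0.05


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_pair_counting_with_ties(seed):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 6, 30).astype(float)  # many ties
    y = rng.random(30) < 0.4
    if y.all() or not y.any():
        y[0] = not y[0]
    r = roc_analysis(scores, y)
    assert r.auc == pytest.approx(_auc_pair_counting(scores, y), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(10)
    scores = rng.normal(size=60)
    y = rng.random(60) < 0.5
    y[0], y[1] = True, False
    r1 = roc_analysis(scores, y)
    r2 = roc_analysis(np.exp(2.0 * scores), y)
    assert r1.auc == pytest.approx(r2.auc, abs=1e-12)


def test_lower_direction_and_youden_cutoff():
    """Disease lowers ectasia ratios; direction='lower' handles the flip and
    the cutoff maximises sensitivity + specificity - 1."""
    scores = np.array([95.0, 97.0, 100.0, 102.0, 80.0, 85.0, 96.0])
    y = np.array([False, False, False, False, True, True, True])
    r = roc_analysis(scores, y, positive_direction="lower")
    # oracle: exhaustive scan of thresholds
    best = None
    for c in np.unique(scores):
        sen = np.mean(scores[y] <= c)
        spe = np.mean(scores[~y] > c)
        j = sen + spe - 1
        if best is None or j > best[0] or (j == best[0] and sen > best[1]):
            best = (j, sen, spe)
    assert r.sensitivity_at_cutoff + r.specificity_at_cutoff - 1 == pytest.approx(best[0])
    assert r.sensitivity_at_cutoff == pytest.approx(best[1])


def test_single_class_rejected():
    with pytest.raises(ValueError, match="class"):
        roc_analysis(np.arange(5.0), np.ones(5, dtype=bool))


def test_roc_curve_monotone():
    rng = np.random.default_rng(11)
    scores = rng.normal(size=80)
    y = np.concatenate([np.zeros(40, bool), np.ones(40, bool)])
    scores[40:] += 1.0
    r = roc_analysis(scores, y)
    assert np.all(np.diff(r.sensitivity) >= 0)
    assert np.all(np.diff(1 - r.specificity) >= 0)
    assert 0.0 <= r.auc <= 1.0
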