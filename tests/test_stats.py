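import numpy as np
import pytest
from scipy import stats as sps

import fishrhythm as fr

# ------------------------------------------------------------------ oracles


def oneway_anova_oracle(groups):
    """Hand-computed sums of squares for a one-way fixed-effects ANOVA."""
    all_vals = np.concatenate(groups)
    gm = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, len(all_vals) - len(groups)
    F = (ss_between / df1) / (ss_within / df2)
    return F, df1, df2, sps.f.sf(F, df1, df2)


def mixed_anova_oracle(day, night, labels):
    """Split-plot sums of squares: species between, time (2 levels) within."""
    day, night, labels = map(np.asarray, (day, night, labels))
    species = list(dict.fromkeys(labels))
    k, n = len(species), len(day)
    y = np.stack([day, night], axis=1)  # subjects x time
    gm = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    sp_means = {g: y[labels == g].mean() for g in species}
    ss_between_subj = 2 * ((subj_means - gm) ** 2).sum()
    ss_species = 2 * sum((labels == g).sum() * (sp_means[g] - gm) ** 2 for g in species)
    ss_subj_error = ss_between_subj - ss_species
    ss_time = n * ((time_means - gm) ** 2).sum()
    ss_int = 0.0
    for g in species:
        n_g = (labels == g).sum()
        cell = y[labels == g].mean(axis=0)
        ss_int += n_g * ((cell - sp_means[g] - time_means + gm) ** 2).sum()
    ss_total = ((y - gm) ** 2).sum()
    ss_within_error = ss_total - ss_species - ss_subj_error - ss_time - ss_int

    def f_p(ss, df1, ss_err, df2):
        F = (ss / df1) / (ss_err / df2)
        return F, sps.f.sf(F, df1, df2)

    out = {}
    out["species"] = (*f_p(ss_species, k - 1, ss_subj_error, n - k), (k - 1, n - k))
    out["time"] = (*f_p(ss_time, 1, ss_within_error, n - k), (1, n - k))
    out["species x time"] = (*f_p(ss_int, k - 1, ss_within_error, n - k), (k - 1, n - k))
    return out


def paired_t_oracle(day, night):
    d = np.asarray(day, dtype=float) - np.asarray(night, dtype=float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, n - 1, 2 * sps.t.sf(abs(t), n - 1)


# ------------------------------------------------------------------ one-way


def test_identical_groups_give_f_zero_p_one():
    res = fr.species_anova([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           ["a", "a", "a", "b", "b", "b"])
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_worked_textbook_triple():
    # groups (1,2,3), (2,3,4), (6,7,8): SSB=42 (df 2), SSW=6 (df 6), F=21
    vals = [1, 2, 3, 2, 3, 4, 6, 7, 8]
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    res = fr.species_anova(vals, labels)
    assert res.statistic == pytest.approx(21.0, abs=1e-12)
    assert res.df == (2, 6)
    assert res.p == pytest.approx(sps.f.sf(21.0, 2, 6), abs=1e-12)


def test_oneway_matches_oracle_on_random_data(rng):
    for _ in range(100):
        k = rng.integers(2, 5)
        groups = [rng.normal(rng.normal(), 1.0, rng.integers(3, 9)) for _ in range(k)]
        labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
        res = fr.species_anova(np.concatenate(groups), labels)
        F, df1, df2, p = oneway_anova_oracle(groups)
        assert res.statistic == pytest.approx(F, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-8)
        assert res.df == (df1, df2)


def test_oneway_null_pvalues_are_uniform(rng):
    """Under the null the ANOVA p-value is U(0,1): KS check over 500 runs."""
    ps = []
    for _ in range(500):
        vals = rng.normal(0, 1, 15)
        labels = np.repeat([0, 1, 2], 5)
        ps.append(fr.species_anova(vals, labels).p)
    assert sps.kstest(ps, "uniform").pvalue > 1e-3


def test_oneway_design_errors():
    with pytest.raises(ValueError):
        fr.species_anova([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(ValueError):
        fr.species_anova([1, 2, 3], ["a", "a", "b"])  # singleton group


# ------------------------------------------------------------------ mixed RM


def test_symmetric_day_night_gives_zero_time_effect(rng):
    day = rng.normal(10, 2, 12)
    night = day.copy()  # night = day per subject
    labels = np.repeat(["a", "b"], 6)
    results = fr.day_night_rm_anova(day, night, labels)
    time_res = next(r for r in results if r.term == "time")
    assert time_res.statistic == pytest.approx(0.0, abs=1e-9)


def test_mixed_anova_matches_split_plot_oracle(rng):
    for _ in range(100):
        k = int(rng.integers(2, 4))
        n_per = int(rng.integers(3, 7))
        labels = np.repeat([f"s{i}" for i in range(k)], n_per)
        day = rng.normal(10, 2, k * n_per) + rng.normal(0, 1)
        night = rng.normal(8, 2, k * n_per)
        results = {r.term: r for r in fr.day_night_rm_anova(day, night, labels)}
        oracle = mixed_anova_oracle(day, night, labels)
        for term, (F, p, df) in oracle.items():
            assert results[term].statistic == pytest.approx(F, abs=1e-8), term
            assert results[term].p == pytest.approx(p, abs=1e-8), term
            assert results[term].df == df, term


def test_posthoc_contrasts_are_sidak_adjusted(rng):
    day = rng.normal(10, 2, 12)
    night = rng.normal(8, 2, 12)
    labels = np.repeat(["a", "b"], 6)
    results = fr.day_night_rm_anova(day, night, labels)
    posthoc = [r for r in results if r.test_name == "paired t (post hoc)"]
    assert len(posthoc) == 2
    for r in posthoc:
        assert r.adjusted_p == pytest.approx(fr.sidak_adjust(r.p, 2))


def test_incomplete_pairs_are_dropped(caplog):
    day = np.array([1.0, 2.0, np.nan, 4.0, 2.0, 3.0])
    night = np.array([1.5, 1.0, 2.0, 3.0, 2.5, 1.0])
    labels = np.repeat(["a", "b"], 3)
    with caplog.at_level("WARNING", logger="fishrhythm.stats"):
        results = fr.day_night_rm_anova(day, night, labels)
    assert "dropping 1" in caplog.text
    assert results  # still fits on the 5 complete subjects


def test_sidak_closed_form():
    # m = 6 contrasts at raw p = 0.01
    assert fr.sidak_adjust(0.01, 6) == pytest.approx(1 - 0.99**6)
    assert fr.sidak_adjust(0.01, 6) == pytest.approx(0.0585, abs=5e-4)


# ------------------------------------------------------------------ paired t


def test_paired_identical_values():
    res = fr.paired_day_night_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_paired_constant_nonzero_difference_is_an_error():
    with pytest.raises(ValueError, match="zero variance"):
        fr.paired_day_night_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


def test_paired_t_matches_hand_formula():
    day = [10.0, 12.0, 9.0, 11.0, 13.0, 10.0]
    night = [8.0, 9.0, 9.0, 10.0, 9.0, 7.0]
    res = fr.paired_day_night_test(day, night)
    t, df, p = paired_t_oracle(day, night)
    assert res.statistic == pytest.approx(t, abs=1e-12)
    assert res.df == (df,)
    assert res.p == pytest.approx(p, abs=1e-12)


# ------------------------------------------------------------------ regression


def test_stage_correlation_proportional_means():
    juv = [1.0, 2.0, 3.0, 4.0]
    res = fr.stage_correlation(juv, [2.0, 4.0, 6.0, 8.0])
    assert res.statistic == pytest.approx(1.0)
    assert res.extra["slope"] == pytest.approx(2.0)
    anti = fr.stage_correlation(juv, [8.0, 6.0, 4.0, 2.0])
    assert anti.statistic == pytest.approx(1.0)
    assert anti.extra["slope"] < 0


def test_stage_correlation_matches_closed_form(rng):
    for _ in range(100):
        n = int(rng.integers(4, 10))
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        res = fr.stage_correlation(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        syy = ((y - y.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2 = sxy**2 / (sxx * syy)
        t = np.sqrt(r2) * np.sqrt(n - 2) / np.sqrt(1 - r2)
        p = 2 * sps.t.sf(abs(t), n - 2)
        assert res.statistic == pytest.approx(r2, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-8)


def test_stage_correlation_design_errors():
    with pytest.raises(ValueError):
        fr.stage_correlation([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fr.stage_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
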