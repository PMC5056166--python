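import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pran.erp import MONTAGE_EXP1_3
from pran.lexicon import CompetitionRecord, WIFKey
from pran.stats import (
    median_split,
    pran_regression,
    rm_anova,
    standardize_amplitudes,
    subset_anova,
)

from .oracles import anova_oracle


def records_from_counts(counts):
    logs = np.log(counts)
    z = (logs - logs.mean()) / np.std(logs, ddof=1)
    return [
        CompetitionRecord(WIFKey((f"c{k:03d}", "a"), 1), int(c), float(l), float(zz))
        for k, (c, l, zz) in enumerate(zip(counts, logs, z))
    ]


def cell_data(rng, n_subjects, levels, effect=0.0):
    """Long-format random within-subject data over crossed factor levels."""
    rows = []
    names = [f"f{j}" for j in range(len(levels))]
    for s in range(n_subjects):
        for combo in itertools.product(*[range(l) for l in levels]):
            amp = rng.normal(0, 1) + effect * combo[0]
            rows.append([f"s{s}", *[f"L{c}" for c in combo], amp])
    return pd.DataFrame(rows, columns=["subject", *names, "amplitude"]), names


# ---------------------------------------------------------------- median split

def test_median_split_halves_and_group_stats():
    split = median_split(records_from_counts([1, 2, 3, 4]))
    assert (split.low_mean, split.high_mean) == (1.5, 3.5)
    assert len(split.low_wifs) == len(split.high_wifs) == 2


def test_median_split_boundary_ties_deterministic():
    records = records_from_counts([5, 5, 5, 9])
    split = median_split(records)
    assert len(split.low_wifs) == len(split.high_wifs) == 2
    # tie at the boundary broken by WIF key: lexicographically smallest stay low
    assert split.low_wifs == [r.wif for r in records[:2]]
    assert median_split(records).assignment == split.assignment  # stable


def test_median_split_matches_sort_and_halve_oracle():
    rng = np.random.default_rng(12)
    counts = rng.integers(1, 500, size=52)
    records = records_from_counts(counts)
    split = median_split(records)
    expected_low = sorted(counts)[:26]
    assert sorted(r.count for r in records if r.group == "low") == expected_low
    assert max(r.count for r in records if r.group == "low") <= min(
        r.count for r in records if r.group == "high"
    )
    with pytest.raises(ValueError):
        median_split(records[:1])


# ----------------------------------------------------------------------- ANOVA

def test_rm_anova_constant_data_gives_zero_f():
    df, names = cell_data(np.random.default_rng(0), 6, (2, 3))
    df["amplitude"] = 1.25
    table = rm_anova(df, within=names)
    assert (table["F"] == 0.0).all()
    assert (table["p"] == 1.0).all()
    assert (table["partial_eta_sq"] == 0.0).all()


@pytest.mark.parametrize("n_subjects, expected", [(18, (1, 17, 2, 34)), (20, (1, 19, 2, 38))])
def test_rm_anova_df_patterns(n_subjects, expected):
    """df shapes for the study's subject counts: (1,17)/(2,34) at n=18 and
    (1,19)/(2,38) at n=20."""
    d1, d17, d2, d34 = expected
    df, names = cell_data(np.random.default_rng(1), n_subjects, (2, 3, 2))
    table = rm_anova(df, within=names).set_index("effect")
    assert tuple(table.loc["f0", ["df_num", "df_den"]]) == (d1, d17)
    assert tuple(table.loc["f1", ["df_num", "df_den"]]) == (d2, d34)
    assert tuple(table.loc["f0 × f1", ["df_num", "df_den"]]) == (d2, d34)
    assert tuple(table.loc["f0 × f1 × f2", ["df_num", "df_den"]]) == (d2, d34)


@pytest.mark.parametrize("seed", range(6))
def test_rm_anova_matches_anovarm_oracle(seed):
    rng = np.random.default_rng(seed)
    levels = [(2, 3), (2, 2, 3), (3, 4)][seed % 3]
    n_subj = int(rng.integers(6, 21))
    df, names = cell_data(rng, n_subj, levels, effect=0.4)
    table = rm_anova(df, within=names)
    oracle = anova_oracle(df, within=names)
    assert len(table) == len(oracle)
    for _, row in table.iterrows():
        f, dn, dd, p = oracle[frozenset(row["effect"].split(" × "))]
        assert row["F"] == pytest.approx(f, abs=1e-8)
        assert (row["df_num"], row["df_den"]) == (dn, dd)
        assert row["p"] == pytest.approx(p, abs=1e-8)
        # partial eta^2 from (F, dfs) identity
        eta = dn * f / (dn * f + dd)
        assert row["partial_eta_sq"] == pytest.approx(eta, abs=1e-10)


def test_rm_anova_rejects_bad_designs():
    df, names = cell_data(np.random.default_rng(2), 5, (2, 2))
    with pytest.raises(ValueError, match="missing cells"):
        rm_anova(df.iloc[:-1], within=names)
    dup = pd.concat([df, df.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        rm_anova(dup, within=names)
    single = df[df["subject"] == "s0"]
    with pytest.raises(ValueError, match="2 subjects"):
        rm_anova(single, within=names)


def test_gg_epsilon_bounds():
    df, names = cell_data(np.random.default_rng(3), 12, (2, 3))
    table = rm_anova(df, within=names).set_index("effect")
    for effect, row in table.iterrows():
        k = row["df_num"]
        assert 1.0 / k - 1e-9 <= row["gg_epsilon"] <= 1.0 + 1e-9
    # a 2-level factor is sphere by construction: epsilon exactly 1
    assert table.loc["f0", "gg_epsilon"] == pytest.approx(1.0)


# ---------------------------------------------------------------- subset ANOVA

def _roi_cells(rng, n_subjects=10):
    rows = []
    for s in range(n_subjects):
        for comp in ("few", "many"):
            for roi in MONTAGE_EXP1_3:
                rows.append([f"s{s}", comp, roi.name, rng.normal(0, 1)])
    return pd.DataFrame(rows, columns=["subject", "competitors", "roi", "amplitude"])


def test_subset_anova_full_montage_equals_omnibus():
    rng = np.random.default_rng(4)
    cells = _roi_cells(rng)
    sub = subset_anova(cells, MONTAGE_EXP1_3, [r.name for r in MONTAGE_EXP1_3])
    by_name = {r.name: r for r in MONTAGE_EXP1_3}
    full = cells.copy()
    full["antpost"] = full["roi"].map(lambda n: by_name[n].antpost)
    full["laterality"] = full["roi"].map(lambda n: by_name[n].laterality)
    direct = rm_anova(full, within=["competitors", "antpost", "laterality"])
    pd.testing.assert_frame_equal(
        sub.sort_values("effect").reset_index(drop=True),
        direct.sort_values("effect").reset_index(drop=True),
    )


def test_subset_anova_collapsing_topography():
    rng = np.random.default_rng(5)
    cells = _roi_cells(rng, n_subjects=18)
    # left channels only, Antpost retained: laterality has one level and drops
    left = subset_anova(cells, MONTAGE_EXP1_3,
                        ["left anterior", "left central", "left posterior"])
    assert set(left["effect"]) == {"competitors", "antpost", "competitors × antpost"}
    assert tuple(left.set_index("effect").loc["competitors × antpost",
                                              ["df_num", "df_den"]]) == (2, 34)
    # fully collapsed simple effect: Competitors only, df (1, 17)
    simple = subset_anova(cells, MONTAGE_EXP1_3, ["left central"], collapse=True)
    assert list(simple["effect"]) == ["competitors"]
    assert tuple(simple.loc[0, ["df_num", "df_den"]]) == (1, 17)
    # and it matches the oracle on the averaged data
    oracle = anova_oracle(
        cells[cells["roi"] == "left central"], within=["competitors"]
    )
    f, dn, dd, p = oracle[frozenset({"competitors"})]
    assert simple.loc[0, "F"] == pytest.approx(f, abs=1e-8)
    with pytest.raises(ValueError, match="non-empty"):
        subset_anova(cells, MONTAGE_EXP1_3, [])
    with pytest.raises(ValueError, match="unknown ROI"):
        subset_anova(cells, MONTAGE_EXP1_3, ["nowhere"])


# -------------------------------------------------------------- standardization

def test_standardize_with_study_parameters():
    # study mean -2.44 uV, SD 0.91 uV
    z = standardize_amplitudes([-2.44, -1.53], study_mean=-2.44, study_sd=0.91)
    assert z[0] == pytest.approx(0.0, abs=1e-12)
    assert z[1] == pytest.approx(1.0, abs=1e-12)


def test_standardize_self_referenced():
    rng = np.random.default_rng(6)
    z = standardize_amplitudes(rng.normal(-2, 1, 40))
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="SD"):
        standardize_amplitudes([1.0, 1.0, 1.0])


# ------------------------------------------------------------------- regression

def test_regression_recovers_noiseless_slope():
    rng = np.random.default_rng(7)
    z_comp = standardize_amplitudes(rng.normal(0, 1, 52))
    fit = pran_regression(0.387 * z_comp, z_comp)
    assert fit.coefficients["lexical_competition"] == pytest.approx(0.387, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert (fit.df_model, fit.df_resid) == (1, 50)


def test_simple_slope_equals_pearson_r():
    rng = np.random.default_rng(8)
    x = rng.normal(0, 3, 52)
    y = 0.4 * x + rng.normal(0, 2, 52)
    zx, zy = standardize_amplitudes(x), standardize_amplitudes(y)
    fit = pran_regression(zy, zx)
    r = float(np.corrcoef(x, y)[0, 1])
    assert fit.coefficients["lexical_competition"] == pytest.approx(r, abs=1e-12)
    assert fit.r_squared == pytest.approx(r * r, abs=1e-12)


def test_slope_invariant_to_affine_rescaling():
    rng = np.random.default_rng(9)
    amp = rng.normal(-2, 1, 60)
    comp = rng.normal(0, 1, 60)
    base = pran_regression(standardize_amplitudes(amp), standardize_amplitudes(comp))
    scaled = pran_regression(
        standardize_amplitudes(3.0 * amp - 7.0),
        standardize_amplitudes(-0.5 * comp + 2.0) * -1,  # sign-preserving overall
    )
    assert scaled.coefficients["lexical_competition"] == pytest.approx(
        base.coefficients["lexical_competition"], abs=1e-12
    )


def test_two_predictor_df_bookkeeping():
    rng = np.random.default_rng(10)
    # 52 WIFs x 2 ROIs long format -> F(2, 101); 72 x 3 -> F(2, 213)
    for n_wif, n_roi, df_resid in [(52, 2, 101), (72, 3, 213)]:
        z = np.repeat(standardize_amplitudes(rng.normal(0, 1, n_wif)), n_roi)
        zf = np.repeat(standardize_amplitudes(rng.normal(0, 1, n_wif)), n_roi)
        y = 0.3 * z + rng.normal(0, 1, n_wif * n_roi)
        fit = pran_regression(y, z, zf)
        assert (fit.df_model, fit.df_resid) == (2, df_resid)
        assert fit.n_obs == n_wif * n_roi
        assert set(fit.predictors) == {"lexical_competition", "lexical_frequency"}


def test_one_tailed_direction():
    rng = np.random.default_rng(11)
    z = standardize_amplitudes(rng.normal(0, 1, 52))
    pos = pran_regression(0.5 * z + rng.normal(0, 0.5, 52), z)
    neg = pran_regression(-0.5 * z + rng.normal(0, 0.5, 52), z)
    assert pos.p_competition_one_tailed < 0.05
    assert neg.p_competition_one_tailed > 0.95
    two = 2 * min(pos.p_competition_one_tailed, 1 - pos.p_competition_one_tailed)
    assert two == pytest.approx(pos.p_two_tailed["lexical_competition"], abs=1e-12)


def test_regression_type_one_error_rate():
    """Under the null the one-tailed competition test rejects at ~5%."""
    rng = np.random.default_rng(13)
    z = standardize_amplitudes(rng.normal(0, 1, 52))
    rejections = 0
    n_rep = 2000
    for _ in range(n_rep):
        fit = pran_regression(rng.normal(0, 1, 52), z)
        rejections += fit.p_competition_one_tailed < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.015)


def test_regression_input_validation():
    z = np.array([1.0, -1.0])
    with pytest.raises(ValueError, match="too few"):
        pran_regression(z, z)
    zz = standardize_amplitudes(np.arange(10.0))
    with pytest.raises(ValueError, match="constant predictor"):
        pran_regression(zz, np.ones(10))
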