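"""Inferential machinery: median split, within-subjects factorial ANOVA with
partial eta squared, amplitude standardization, and standardized regressions
of windowed ERP amplitude on lexical competition.

The ANOVA is the classical univariate repeated-measures decomposition: every
within-subject effect is tested against its own effect-by-subject
interaction, with uncorrected degrees of freedom.  Greenhouse-Geisser
epsilon is computed and reported per effect but never applied.  The
regression of z-scored amplitude on z-scored log-competition is ordinary
least squares with an intercept; the competition coefficient is evaluated
one-tailed in the positive direction (amplitude becomes less negative as
competition rises), any other predictor two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .erp import ROISpec
from .lexicon import CompetitionRecord, WIFKey

__all__ = [
    "SplitAssignment",
    "RegressionFit",
    "median_split",
    "rm_anova",
    "subset_anova",
    "standardize_amplitudes",
    "pran_regression",
]


@dataclass
class SplitAssignment:
    """Low/high competition groups from a median split on raw counts."""

    assignment: dict[WIFKey, str]
    low_wifs: list[WIFKey]
    high_wifs: list[WIFKey]
    low_mean: float
    low_sd: float
    high_mean: float
    high_sd: float


def median_split(records: Sequence[CompetitionRecord]) -> SplitAssignment:
    """Rank WIFs by raw competitor count and halve the list at the median.

    Boundary ties are broken deterministically by WIF key; with an odd
    number of records the median element joins the high group.  Group means
    and SDs (sample SD) are reported on the raw count scale.  Mutates each
    record's ``group`` field.
    """
    if len(records) < 2:
        raise ValueError("median split needs at least 2 records")
    ranked = sorted(records, key=lambda r: (r.count, r.wif))
    half = len(ranked) // 2
    low, high = ranked[:half], ranked[half:]
    for r in low:
        r.group = "low"
    for r in high:
        r.group = "high"

    def _stats(rs: Sequence[CompetitionRecord]) -> tuple[float, float]:
        counts = np.array([r.count for r in rs], dtype=float)
        sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
        return float(counts.mean()), sd

    lm, ls = _stats(low)
    hm, hs = _stats(high)
    return SplitAssignment(
        {r.wif: r.group for r in ranked},
        [r.wif for r in low],
        [r.wif for r in high],
        lm, ls, hm, hs,
    )


def _effect_arrays(y: np.ndarray) -> dict[frozenset[int], np.ndarray]:
    """Inclusion-exclusion decomposition of a full-factorial array into
    effect arrays (broadcastable, singleton on axes outside the effect)."""
    ndim = y.ndim
    axes = tuple(range(ndim))
    effects: dict[frozenset[int], np.ndarray] = {}
    order: list[frozenset[int]] = [frozenset()]
    for size in range(1, ndim + 1):
        order.extend(frozenset(c) for c in combinations(axes, size))
    for T in order:
        marg = y.mean(axis=tuple(a for a in axes if a not in T), keepdims=True)
        e = marg.copy()
        for U, eu in effects.items():
            if U < T or U == frozenset():
                e = e - eu
        effects[T] = e
    return effects


def _ss(effects: Mapping[frozenset[int], np.ndarray], T: frozenset[int],
        shape: tuple[int, ...]) -> float:
    mult = 1
    for a, n in enumerate(shape):
        if a not in T:
            mult *= n
    return float(mult * np.sum(effects[T] ** 2))


def _gg_epsilon(y: np.ndarray, factor_axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by ``factor_axes``
    (subject on axis 0), via orthonormal contrasts on the per-subject cell
    means averaged over the remaining factors."""
    n_s = y.shape[0]
    other = tuple(a for a in range(1, y.ndim) if a not in factor_axes)
    cells = y.mean(axis=other) if other else y
    # flatten factor axes -> (n_s, p)
    cells = cells.reshape(n_s, -1)
    contrasts = []
    for ax in factor_axes:
        k = y.shape[ax]
        # orthonormal basis of the (k-1)-dim contrast space
        q, _ = np.linalg.qr(np.vstack([np.ones(k), np.eye(k)[:-1]]).T)
        contrasts.append(q[:, 1:])
    C = contrasts[0]
    for c in contrasts[1:]:
        C = np.kron(C, c)
    scores = cells @ C
    if n_s < 2:
        return float("nan")
    S = np.cov(scores, rowvar=False)
    S = np.atleast_2d(S)
    df = S.shape[0]
    tr = np.trace(S)
    denom = df * np.sum(S * S)
    if denom <= 0:
        return float("nan")
    return float(tr * tr / denom)


def rm_anova(
    data: pd.DataFrame,
    dv: str = "amplitude",
    subject: str = "subject",
    within: Sequence[str] = ("competitors",),
) -> pd.DataFrame:
    """Fully-crossed within-subjects factorial ANOVA on cell means.

    ``data`` is long-format with one row (one mean amplitude) per subject
    per cell of the crossed ``within`` factors.  Missing cells or duplicate
    rows are an error.  Returns a table with one row per within effect:
    effect, df_num, df_den, F, p, partial_eta_sq, gg_epsilon.
    """
    within = list(within)
    if not within:
        raise ValueError("at least one within factor is required")
    subjects = list(pd.unique(data[subject]))
    if len(subjects) < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    levels = {f: sorted(pd.unique(data[f]), key=str) for f in within}
    shape = (len(subjects),) + tuple(len(levels[f]) for f in within)
    idx = [pd.Categorical(data[subject], categories=subjects).codes]
    for f in within:
        idx.append(pd.Categorical(data[f], categories=levels[f]).codes)
    y = np.full(shape, np.nan)
    coords = tuple(np.asarray(ix) for ix in idx)
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, coords, 1)
    if (counts > 1).any():
        raise ValueError("duplicate rows for at least one subject x cell")
    if (counts == 0).any():
        raise ValueError("missing cells in the within-subject design")
    vals = pd.to_numeric(data[dv]).to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing (NaN) cell means")
    y[coords] = vals
    effects = _effect_arrays(y)
    rows = []
    factor_axes = {f: a + 1 for a, f in enumerate(within)}
    for size in range(1, len(within) + 1):
        for combo in combinations(within, size):
            T = frozenset(factor_axes[f] for f in combo)
            ss_eff = _ss(effects, T, shape)
            ss_err = _ss(effects, T | {0}, shape)
            df_num = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_den = (len(subjects) - 1) * df_num
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            if ms_eff <= 1e-300:
                f_val = 0.0
            elif ms_err <= 1e-300:
                f_val = float("inf")
            else:
                f_val = ms_eff / ms_err
            p = float(scipy.stats.f.sf(f_val, df_num, df_den))
            denom = ss_eff + ss_err
            eta = float(ss_eff / denom) if denom > 0 else 0.0
            eps = _gg_epsilon(y, tuple(sorted(T)))
            rows.append((" × ".join(combo), df_num, df_den, f_val, p, eta, eps))
    return pd.DataFrame(
        rows,
        columns=["effect", "df_num", "df_den", "F", "p", "partial_eta_sq", "gg_epsilon"],
    )


def subset_anova(
    data: pd.DataFrame,
    montage: Sequence[ROISpec],
    roi_names: Sequence[str],
    dv: str = "amplitude",
    subject: str = "subject",
    other_within: Sequence[str] = ("competitors",),
    roi_col: str = "roi",
    collapse: bool = False,
) -> pd.DataFrame:
    """Follow-up ANOVA on a subset of ROIs.

    Rows of ``data`` carry subject, the non-topographic factors, an ROI
    column and the amplitude.  The subset's topographic factors (Antpost,
    Laterality) are rebuilt from the montage; factors left with a single
    level are dropped, and with ``collapse=True`` all ROIs in the subset are
    averaged into one value per remaining cell (a simple-effects test).
    """
    if not roi_names:
        raise ValueError("ROI subset must be non-empty")
    by_name = {r.name: r for r in montage}
    unknown = [n for n in roi_names if n not in by_name]
    if unknown:
        raise ValueError(f"unknown ROI name(s): {', '.join(unknown)}")
    sub = data[data[roi_col].isin(roi_names)].copy()
    if sub.empty:
        raise ValueError("no rows match the ROI subset")
    sub["antpost"] = sub[roi_col].map(lambda n: by_name[n].antpost)
    sub["laterality"] = sub[roi_col].map(lambda n: by_name[n].laterality)
    topo = []
    if not collapse:
        for f in ("antpost", "laterality"):
            if sub[f].nunique() > 1:
                topo.append(f)
    factors = list(other_within) + topo
    cells = sub.groupby([subject] + factors, as_index=False)[dv].mean()
    return rm_anova(cells, dv=dv, subject=subject, within=factors)


def standardize_amplitudes(
    values: Sequence[float] | np.ndarray,
    study_mean: float | None = None,
    study_sd: float | None = None,
) -> np.ndarray:
    """z = (amplitude - study_mean) / study_sd.

    When mean/SD are not supplied they are computed from the values
    themselves (sample SD).  A zero SD is an error.
    """
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean()) if study_mean is None else float(study_mean)
    sd = float(np.std(arr, ddof=1)) if study_sd is None else float(study_sd)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("study SD must be positive and finite")
    return (arr - mean) / sd


@dataclass
class RegressionFit:
    """Standardized OLS fit of amplitude on lexical competition."""

    coefficients: dict[str, float]
    t_values: dict[str, float]
    p_two_tailed: dict[str, float]
    p_competition_one_tailed: float
    f_value: float
    df_model: int
    df_resid: int
    r_squared: float
    n_obs: int
    intercept: float = 0.0
    predictors: list[str] = field(default_factory=list)


def pran_regression(
    z_amplitude: Sequence[float] | np.ndarray,
    z_competition: Sequence[float] | np.ndarray,
    z_frequency: Sequence[float] | np.ndarray | None = None,
) -> RegressionFit:
    """OLS of z-scored amplitude on z-scored log-competition, optionally with
    z-scored log lexical frequency as a covariate.

    The competition coefficient gets a one-tailed p in the positive
    direction (the directional hypothesis: larger negativity with fewer
    competitors); the frequency coefficient is two-tailed.
    """
    y = np.asarray(z_amplitude, dtype=float)
    X = pd.DataFrame({"lexical_competition": np.asarray(z_competition, dtype=float)})
    if z_frequency is not None:
        X["lexical_frequency"] = np.asarray(z_frequency, dtype=float)
    n, k = len(y), X.shape[1]
    if len(X) != n:
        raise ValueError("predictor/response length mismatch")
    if n <= k + 1:
        raise ValueError("too few observations for the number of predictors")
    for name in X.columns:
        if float(np.std(X[name].to_numpy())) == 0.0:
            raise ValueError(f"constant predictor: {name}")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    t_comp = float(model.tvalues["lexical_competition"])
    df_resid = int(model.df_resid)
    p_one = float(scipy.stats.t.sf(t_comp, df_resid))
    return RegressionFit(
        coefficients={c: float(model.params[c]) for c in X.columns},
        t_values={c: float(model.tvalues[c]) for c in X.columns},
        p_two_tailed={c: float(model.pvalues[c]) for c in X.columns},
        p_competition_one_tailed=p_one,
        f_value=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=df_resid,
        r_squared=float(model.rsquared),
        n_obs=n,
        intercept=float(model.params["const"]),
        predictors=list(X.columns),
    )
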