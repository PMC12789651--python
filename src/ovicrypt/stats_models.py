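"""Mean-difference inference: mixed models and MANOVA on the feature table.

Every scene contributes 30 correlated rows (shared substrate, illumination
and processing), so all mean comparisons use a linear mixed model with a
per-photograph (nest) random intercept, fitted by REML.  Fixed-effect
t-tests use Satterthwaite's approximation for the degrees of freedom,
computed from the REML variance-component covariance by the delta method:

    df = 2 * [c' C(theta) c]^2 / (g' A g)

where C(theta) = (X' V^-1 X)^-1, g is the gradient of c'Cc with respect to
the variance components theta = (sigma^2_nest, sigma^2_resid), and A is the
inverse observed information of the restricted log-likelihood.  When the
nest variance collapses to zero the model degenerates to OLS; the result is
flagged singular and the residual df is used.

The four texture principal components are additionally tested jointly by
MANOVA using Pillai's trace, trace(H (H+E)^-1), both as test statistic and
as an R^2-like effect size, with the standard approximate-F transformation.
MANOVA runs either on raw samples or on nest means (one row per nest and
cell), the latter matching between-nest questions such as habitat
comparisons.  No multiple-testing correction is applied; the joint MANOVA is
the protection for the texture family.

``run_table_suite`` reproduces the three-way analysis layout: (i) the
object-type x location interaction on all data, (ii) beach vs. salt marsh
separately for eggs and for backgrounds, and (iii) egg vs. background
separately per habitat, with the egg-background effect reported as the
difference in standardised means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA as _SmMANOVA
from statsmodels.tools.sm_exceptions import ConvergenceWarning

SINGULAR_TOL = 1e-6

COLOUR_METRICS = [
    ("avian_lum", "Avian luminance"),
    ("avian_rg", "Avian RG"),
    ("avian_yb", "Avian YB"),
    ("carn_lum", "Carnivore luminance"),
    ("carn_yb", "Carnivore YB"),
]


class StratumError(ValueError):
    """A required data stratum (habitat/object type) is missing."""


@dataclass
class LmmResult:
    term: str
    estimate: float
    se: float
    tstat: float
    df: float
    pvalue: float
    var_photo: float
    var_resid: float
    singular: bool = False


@dataclass
class ManovaResult:
    pillai: float
    f_stat: float
    df1: float
    df2: float
    pvalue: float
    n_responses: int
    n_groups: int


# ---------------------------------------------------------------------------
# REML machinery for the Satterthwaite df
# ---------------------------------------------------------------------------

def _group_blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    _, starts = np.unique(gs, return_index=True)
    bounds = list(starts) + [len(gs)]
    return [(Xs[a:b], ys[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def _reml_pieces(blocks, sg2: float, se2: float):
    """Return (logdetV, XtVinvX, XtVinvy, ytVinvy) for a random-intercept model."""
    p = blocks[0][0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for Xi, yi in blocks:
        ni = len(yi)
        d = se2 + ni * sg2
        logdet += (ni - 1) * np.log(se2) + np.log(d)
        si = Xi.sum(axis=0)
        ti = yi.sum()
        w = sg2 / (se2 * d)
        XtVX += Xi.T @ Xi / se2 - w * np.outer(si, si)
        XtVy += Xi.T @ yi / se2 - w * si * ti
        yty += yi @ yi / se2 - w * ti * ti
    return logdet, XtVX, XtVy, yty


def _reml_loglik(blocks, sg2: float, se2: float) -> float:
    logdet, XtVX, XtVy, yty = _reml_pieces(blocks, max(sg2, 0.0), se2)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    beta = np.linalg.solve(XtVX, XtVy)
    quad = yty - beta @ XtVy
    return -0.5 * (logdet + logdet_xvx + quad)


def _coef_variance(blocks, sg2: float, se2: float) -> np.ndarray:
    _, XtVX, _, _ = _reml_pieces(blocks, max(sg2, 0.0), se2)
    return np.linalg.inv(XtVX)


def satterthwaite_df(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                     sg2: float, se2: float, contrast: np.ndarray) -> float:
    """Satterthwaite df for c'beta in a random-intercept LMM at the REML fit."""
    blocks = _group_blocks(X, y, groups)
    n, p = X.shape
    resid_df = n - p

    def var_c(theta):
        C = _coef_variance(blocks, theta[0], theta[1])
        return float(contrast @ C @ contrast)

    theta = np.array([sg2, se2], dtype=float)
    # gradient of c'Cc (central differences, relative steps)
    grad = np.zeros(2)
    for i in range(2):
        h = max(theta[i], 1e-8) * 1e-4
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 0.0)
        grad[i] = (var_c(tp) - var_c(tm)) / (tp[i] - tm[i])
    # observed information of the REML loglik (negative Hessian)
    def ll(t):
        return _reml_loglik(blocks, t[0], t[1])

    H = np.zeros((2, 2))
    steps = [max(theta[i], 1e-8) * 1e-3 for i in range(2)]
    for i in range(2):
        for j in range(i, 2):
            ti = steps[i]
            tj = steps[j]
            tpp = theta + np.array([ti if k == i else 0 for k in range(2)]) \
                + np.array([tj if k == j else 0 for k in range(2)])
            tpm = theta + np.array([ti if k == i else 0 for k in range(2)]) \
                - np.array([tj if k == j else 0 for k in range(2)])
            tmp = theta - np.array([ti if k == i else 0 for k in range(2)]) \
                + np.array([tj if k == j else 0 for k in range(2)])
            tmm = theta - np.array([ti if k == i else 0 for k in range(2)]) \
                - np.array([tj if k == j else 0 for k in range(2)])
            for t in (tpp, tpm, tmp, tmm):
                t[0] = max(t[0], 0.0)
            H[i, j] = H[j, i] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * ti * tj)
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return float(resid_df)
    denom = float(grad @ A @ grad)
    if denom <= 0:
        return float(resid_df)
    df = 2.0 * var_c(theta) ** 2 / denom
    return float(np.clip(df, 1.0, resid_df))


# ---------------------------------------------------------------------------
# LMM fitting
# ---------------------------------------------------------------------------

def fit_lmm(table: pd.DataFrame, response: str, fixed_terms: str,
            group: str = "nest_id", standardize: bool = False,
            df_terms: list[str] | None = None) -> dict[str, LmmResult]:
    """REML linear mixed model with a per-photograph random intercept.

    ``fixed_terms`` is a formula right-hand side (e.g. ``"object_type"`` or
    ``"object_type * habitat"``).  Returns one result per fixed-effect
    coefficient (intercept included), each with a Satterthwaite df.  With
    ``standardize=True`` the response is z-scored over the supplied stratum
    first, so a two-level effect reads as a difference in standardised
    means.  ``df_terms`` restricts the (comparatively costly) Satterthwaite
    computation to the named coefficients; the others fall back to the
    residual df.
    """
    data = table.copy()
    if data[group].nunique() < 2:
        raise StratumError("need at least two groups for a mixed model")
    if standardize:
        vals = data[response].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            sd = 1.0
        data[response] = (vals - vals.mean()) / sd
    formula = f"{response} ~ {fixed_terms}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # statsmodels reports boundary (zero-variance) fits as UserWarning;
        # the singular flag below carries that information instead
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data[group])
        fit = model.fit(reml=True)
    sg2 = float(np.asarray(fit.cov_re)[0, 0])
    se2 = float(fit.scale)
    singular = se2 <= 0 or sg2 < SINGULAR_TOL * se2
    X = model.exog
    y = model.endog
    groups_arr = np.asarray(data[group])
    n, p = X.shape
    results: dict[str, LmmResult] = {}
    for j, name in enumerate(model.exog_names):
        est = float(fit.fe_params.iloc[j])
        se = float(fit.bse_fe.iloc[j])
        if singular or (df_terms is not None and name not in df_terms):
            df = float(n - p)
        else:
            c = np.zeros(p)
            c[j] = 1.0
            df = satterthwaite_df(X, y, groups_arr, sg2, se2, c)
            # recompute the SE from the same V(theta) used for the df
            se = float(np.sqrt(_coef_variance(_group_blocks(X, y, groups_arr),
                                              sg2, se2)[j, j]))
        t = est / se if se > 0 else 0.0
        pval = 2.0 * scipy.stats.t.sf(abs(t), df)
        results[name] = LmmResult(term=name, estimate=est, se=se, tstat=t, df=df,
                                  pvalue=float(pval), var_photo=sg2, var_resid=se2,
                                  singular=singular)
    return results


def _last_term(results: dict[str, LmmResult]) -> LmmResult:
    return list(results.values())[-1]


# ---------------------------------------------------------------------------
# MANOVA / Pillai
# ---------------------------------------------------------------------------

def manova_pillai(table: pd.DataFrame, responses: list[str], predictor: str,
                  nest_means: bool = False, group: str = "nest_id") -> ManovaResult:
    """One-way MANOVA with Pillai's trace from between/within SSCP matrices.

    With ``nest_means=True`` the analysis runs on per-nest cell means (one
    row per nest and predictor level), which is the between-nest version
    used for habitat comparisons.
    """
    cols = list(dict.fromkeys(
        [*responses, predictor] + ([group] if group in table.columns else [])))
    data = table[cols].copy()
    if nest_means:
        data = (data.groupby([group, predictor], observed=True)[responses]
                .mean().reset_index())
    levels = data[predictor].unique()
    g = len(levels)
    if g < 2:
        raise StratumError(f"predictor '{predictor}' has fewer than two levels")
    Y = data[responses].to_numpy(dtype=float)
    N, k = Y.shape
    if N <= k + g:
        raise ValueError("too few observations for MANOVA")
    grand = Y.mean(axis=0)
    H = np.zeros((k, k))
    E = np.zeros((k, k))
    for lv in levels:
        Yg = Y[(data[predictor] == lv).to_numpy()]
        diff = Yg.mean(axis=0) - grand
        H += len(Yg) * np.outer(diff, diff)
        resid = Yg - Yg.mean(axis=0)
        E += resid.T @ resid
    HE = H + E
    try:
        pillai = float(np.trace(H @ np.linalg.inv(HE)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular H+E SSCP matrix") from exc
    s = min(k, g - 1)
    m = (abs(k - (g - 1)) - 1) / 2.0
    nn = (N - g - k - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    f_stat = (df2 / df1) * (pillai / s) / (1 - pillai / s)
    pval = float(scipy.stats.f.sf(f_stat, df1, df2))
    return ManovaResult(pillai=pillai, f_stat=float(f_stat), df1=float(df1),
                        df2=float(df2), pvalue=pval, n_responses=k, n_groups=g)


def manova_interaction(table: pd.DataFrame, responses: list[str],
                       factor_a: str = "object_type",
                       factor_b: str = "habitat") -> ManovaResult:
    """Pillai test of the A x B interaction for joint responses (raw samples)."""
    lhs = " + ".join(responses)
    mv = _SmMANOVA.from_formula(f"{lhs} ~ {factor_a} * {factor_b}", data=table)
    res = mv.mv_test()
    key = f"{factor_a}:{factor_b}"
    frame = res.results[key]["stat"]
    row = frame.loc["Pillai's trace"]
    return ManovaResult(pillai=float(row["Value"]), f_stat=float(row["F Value"]),
                        df1=float(row["Num DF"]), df2=float(row["Den DF"]),
                        pvalue=float(row["Pr > F"]), n_responses=len(responses),
                        n_groups=4)


# ---------------------------------------------------------------------------
# the three-way analysis suite
# ---------------------------------------------------------------------------

def _pc_columns(table: pd.DataFrame, n_pcs: int) -> list[str]:
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks texture PC columns: {missing}")
    return cols


def run_table_suite(feature_table: pd.DataFrame, n_texture_pcs: int = 4) -> pd.DataFrame:
    """All three analysis splits over the 10-metric grid.

    Splits: ``interaction`` (object type x location, all data),
    ``eggs_by_habitat`` / ``backgrounds_by_habitat`` (between habitats,
    within object type; MANOVA on nest means) and ``egg_vs_background:<hab>``
    (within habitat; standardised LMM effects).  Rows per split: 5 colour
    metrics, the joint texture MANOVA, and each texture PC.
    """
    table = feature_table.copy()
    for col, need in (("habitat", {"beach", "saltmarsh"}),
                      ("object_type", {"egg", "background"})):
        present = set(table[col].unique())
        if not need <= present:
            raise StratumError(f"feature table lacks {col} stratum: {need - present}")
    pcs = _pc_columns(table, n_texture_pcs)
    metrics = COLOUR_METRICS + [(c, c) for c in pcs]
    rows = []

    def add(split, label, effect, stat, df, p, kind):
        rows.append({"split": split, "metric": label, "effect": effect,
                     "statistic": stat, "df": df, "p": p, "kind": kind})

    # (i) type x location interaction on everything
    for col, label in metrics:
        res = _last_term(fit_lmm(table, col, "object_type * habitat"))
        add("interaction", label, res.estimate, abs(res.tstat), res.df, res.pvalue, "t")
    mv = manova_interaction(table, pcs)
    add("interaction", f"PC1-{len(pcs)} jointly", mv.pillai, mv.f_stat,
        f"{mv.df1:g}, {mv.df2:g}", mv.pvalue, "F")

    # (ii) habitat effect, separately for eggs and backgrounds
    for obj, split in (("egg", "eggs_by_habitat"), ("background", "backgrounds_by_habitat")):
        sub = table[table["object_type"] == obj]
        for col, label in metrics:
            res = _last_term(fit_lmm(sub, col, "habitat"))
            add(split, label, res.estimate, abs(res.tstat), res.df, res.pvalue, "t")
        mv = manova_pillai(sub, pcs, "habitat", nest_means=True)
        add(split, f"PC1-{len(pcs)} jointly", mv.pillai, mv.f_stat,
            f"{mv.df1:g}, {mv.df2:g}", mv.pvalue, "F")

    # (iii) egg vs background within habitat, standardised effects
    for hab in ("beach", "saltmarsh"):
        sub = table[table["habitat"] == hab]
        split = f"egg_vs_background:{hab}"
        for col, label in metrics:
            res = _last_term(fit_lmm(sub, col, "object_type", standardize=True))
            add(split, label, res.estimate, abs(res.tstat), res.df, res.pvalue, "t")
        mv = manova_pillai(sub, pcs, "object_type", nest_means=False)
        add(split, f"PC1-{len(pcs)} jointly", mv.pillai, mv.f_stat,
            f"{mv.df1:g}, {mv.df2:g}", mv.pvalue, "F")

    return pd.DataFrame(rows)
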