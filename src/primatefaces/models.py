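"""Species-level attractiveness models.

Per-species mean Likert scores are modelled against morphological
factors, sexual size dimorphism, human-likeness and color covariates:

* ``lg_ratio`` — the Lovich-Gibbons sexual size dimorphism index,
  (mass of the larger sex / mass of the smaller sex) − 1, negative by
  convention when males are larger;
* ordinary least-squares linear models with sequential (Type I) ANOVA
  and backward AIC reduction guarded by a likelihood-ratio test against
  the full model;
* Tukey(-Kramer) post-hoc comparison of group mean attractiveness;
* redundancy analysis (RDA): PCA of the fitted values from the
  multivariate regression of a response matrix on constraints, with
  vegan-style sequential permutation tests (residuals of the reduced
  model) and forward model building;
* a LOWESS smoother for the attractiveness vs. human-likeness
  ("uncanny valley") curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.anova import anova_lm

__all__ = [
    "lg_ratio",
    "LinearModelFit",
    "fit_lm",
    "reduce_aic",
    "tukey_hsd",
    "RDAResult",
    "rda_fit",
    "rda_permutation_terms",
    "rda_model_build",
    "lowess_curve",
]


def lg_ratio(male_weight: float, female_weight: float) -> float:
    """Lovich-Gibbons sexual size dimorphism index.

    Magnitude is (larger/smaller) − 1; the sign is negative when males
    are the (strictly) larger sex, positive when females are larger, and
    the index is 0 for equal weights.
    """
    if male_weight <= 0 or female_weight <= 0:
        raise ValueError("body weights must be positive")
    if male_weight == female_weight:
        return 0.0
    big, small = max(male_weight, female_weight), min(male_weight, female_weight)
    mag = big / small - 1.0
    return -mag if male_weight > female_weight else mag


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------

@dataclass
class LinearModelFit:
    """An OLS fit with its sequential ANOVA and term bookkeeping."""

    formula: str
    response: str
    terms: list[str]              # ordered RHS terms
    coefficients: pd.DataFrame    # estimate, se, t, p per coefficient
    anova: pd.DataFrame           # Type-I rows: df, F, p per term
    r_squared: float
    aic: float
    log_likelihood: float
    n: int
    df_model: int
    data: pd.DataFrame = field(repr=False)
    result: object = field(repr=False, default=None)
    reduction_trace: list[dict] = field(default_factory=list)


def _assemble_formula(response: str, terms: list[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_lm(table: pd.DataFrame, response: str, terms: list[str]) -> LinearModelFit:
    """Least-squares fit of ``response ~ terms`` with sequential ANOVA.

    ``terms`` is an ordered list of patsy terms (e.g. ``["group",
    "factor2", "lg"]``); categorical columns are expanded by treatment
    contrasts, using the column's categorical ordering for the reference
    level.  The Type-I ANOVA respects the given term order.
    """
    table = pd.DataFrame(table)
    formula = _assemble_formula(response, terms)
    model = smf.ols(formula, data=table)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        # identify an aliased column for the error message
        _, r = np.linalg.qr(model.exog)
        bad = [model.exog_names[j] for j in range(r.shape[1])
               if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased term(s): {bad}")
    res = model.fit()
    if res.df_resid <= 0:
        raise ValueError("more coefficients than observations")
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    if terms:
        an = anova_lm(res, typ=1)
        an = an.rename(
            columns={"df": "df", "F": "F", "PR(>F)": "p", "sum_sq": "ss"}
        )
    else:
        an = pd.DataFrame(columns=["df", "ss", "F", "p"])
    return LinearModelFit(
        formula=formula,
        response=response,
        terms=list(terms),
        coefficients=coef,
        anova=an,
        r_squared=float(res.rsquared) if res.df_model > 0 else 0.0,
        aic=float(res.aic),
        log_likelihood=float(res.llf),
        n=int(res.nobs),
        df_model=int(res.df_model),
        data=table,
        result=res,
    )


def reduce_aic(fit: LinearModelFit, alpha: float = 0.05) -> LinearModelFit:
    """Backward AIC elimination guarded by a likelihood-ratio test.

    Repeatedly drops the single term whose removal lowers AIC the most;
    stops when no removal lowers AIC, or when the candidate reduced
    model differs significantly (likelihood-ratio test at ``alpha``)
    from the original full model.  The elimination trace is recorded on
    the returned fit.
    """
    full = fit
    current = fit
    trace: list[dict] = []
    while current.terms:
        candidates = []
        for term in current.terms:
            reduced_terms = [t for t in current.terms if t != term]
            cand = fit_lm(current.data, current.response, reduced_terms)
            candidates.append((cand.aic, term, cand))
        best_aic, best_term, best_fit = min(candidates, key=lambda c: c[0])
        if best_aic >= current.aic:
            break
        lr = 2.0 * (full.log_likelihood - best_fit.log_likelihood)
        df = full.df_model - best_fit.df_model
        p_lr = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else 1.0
        if p_lr < alpha:
            trace.append(
                {"dropped": best_term, "aic": best_aic, "lr_p_vs_full": p_lr,
                 "accepted": False}
            )
            break
        trace.append(
            {"dropped": best_term, "aic": best_aic, "lr_p_vs_full": p_lr,
             "accepted": True}
        )
        current = best_fit
    current.reduction_trace = trace
    return current


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Pairwise Tukey(-Kramer) comparisons of group means.

    Returns one row per unordered pair with the mean difference, the
    studentized-range 95% confidence interval and the adjusted p-value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    samples = [values[labels == g] for g in uniq]
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(uniq, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 items")
    res = stats.tukey_hsd(*samples)
    ci = res.confidence_interval(0.95)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            rows.append(
                {
                    "group_a": uniq[i],
                    "group_b": uniq[j],
                    "difference": float(res.statistic[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p_adjusted": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------

@dataclass
class RDAResult:
    """Constrained ordination of a response matrix on explanatory terms."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    proportion_constrained: float
    site_scores: pd.DataFrame      # items x constrained axes (fitted-value scores)
    biplot_scores: pd.DataFrame    # constraints x constrained axes
    total_variance: float
    term_names: list[str]


def _term_matrix(X) -> tuple[np.ndarray, list[str], list[np.ndarray]]:
    """Normalize constraints to (matrix, term names, per-term column blocks)."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        cols = [np.asarray(X[c], dtype=float).reshape(len(X), -1) for c in X.columns]
    elif isinstance(X, dict):
        names = list(X)
        cols = [np.asarray(v, dtype=float).reshape(len(v), -1) for v in X.values()]
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{i + 1}" for i in range(arr.shape[1])]
        cols = [arr[:, [i]] for i in range(arr.shape[1])]
    return np.hstack(cols), names, cols


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _fit_ss(Yc: np.ndarray, Z: np.ndarray | None) -> tuple[np.ndarray, float]:
    """Fitted values and their sum of squares for centered Y on centered Z."""
    if Z is None or Z.size == 0:
        return np.zeros_like(Yc), 0.0
    Zc = _center(Z)
    q, r = np.linalg.qr(Zc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    fitted = q @ (q.T @ Yc)
    return fitted, float((fitted**2).sum())


def rda_fit(Y, X, scale_response: bool = False) -> RDAResult:
    """Redundancy analysis of responses ``Y`` on constraints ``X``.

    Y is centered column-wise (optionally standardized); the constrained
    axes are the PCA of the fitted values from the multivariate
    regression of Y on X, the unconstrained axes the PCA of the
    residuals.  Eigenvalues use the divisor n − 1, so the constrained
    plus unconstrained eigenvalues sum to the total variance of the
    centered response.  Biplot scores are the correlations of each
    (numeric) constraint column with the constrained site scores.
    """
    Ydf = pd.DataFrame(Y)
    Yv = Ydf.values.astype(float)
    n = Yv.shape[0]
    M, names, cols = _term_matrix(X)
    if M.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    rank_x = np.linalg.matrix_rank(_center(M))
    if n <= rank_x:
        raise ValueError("need more items than independent constraints")
    Yc = _center(Yv)
    if scale_response:
        sd = Yv.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Yc = Yc / sd
    total = float((Yc**2).sum()) / (n - 1)

    fitted, _ = _fit_ss(Yc, M)
    resid = Yc - fitted

    uf, sf, vtf = np.linalg.svd(fitted, full_matrices=False)
    ev_c = (sf**2) / (n - 1)
    n_axes = int((ev_c > 1e-12 * max(ev_c.max(), 1.0)).sum()) if ev_c.size else 0
    n_axes = min(n_axes, rank_x)
    ev_c = ev_c[:n_axes]

    ur, sr, _ = np.linalg.svd(resid, full_matrices=False)
    ev_u = (sr**2) / (n - 1)
    ev_u = ev_u[ev_u > 1e-12 * max(ev_u.max(), 1.0)] if ev_u.size else ev_u

    axes_names = [f"rda{j + 1}" for j in range(n_axes)]
    site = pd.DataFrame(
        (uf[:, :n_axes] * sf[:n_axes]), index=Ydf.index, columns=axes_names
    )
    biplot_rows = {}
    for name, block in zip(names, cols):
        if block.shape[1] == 1 and site.shape[1] > 0:
            x = block[:, 0]
            if np.std(x) > 0:
                biplot_rows[name] = [
                    float(np.corrcoef(x, site[c])[0, 1]) if site[c].std() > 0 else 0.0
                    for c in site.columns
                ]
    biplot = pd.DataFrame.from_dict(biplot_rows, orient="index", columns=axes_names)
    return RDAResult(
        constrained_eigenvalues=ev_c,
        unconstrained_eigenvalues=ev_u,
        proportion_constrained=float(ev_c.sum() / total) if total > 0 else 0.0,
        site_scores=site,
        biplot_scores=biplot,
        total_variance=total,
        term_names=names,
    )


def _sequential_f(Yc: np.ndarray, blocks: list[np.ndarray], i: int) -> float:
    """Pseudo-F of term i given terms 0..i-1, full-model residual denominator."""
    n = Yc.shape[0]
    Z = np.hstack(blocks[:i]) if i > 0 else None
    W = np.hstack(blocks[: i + 1])
    _, ss_z = _fit_ss(Yc, Z)
    _, ss_w = _fit_ss(Yc, W)
    full = np.hstack(blocks)
    _, ss_full = _fit_ss(Yc, full)
    df_i = np.linalg.matrix_rank(_center(W)) - (
        np.linalg.matrix_rank(_center(Z)) if Z is not None else 0
    )
    df_resid = n - 1 - np.linalg.matrix_rank(_center(full))
    ss_resid = float((Yc**2).sum()) - ss_full
    if df_i <= 0 or df_resid <= 0 or ss_resid <= 0:
        return np.inf
    return (ss_w - ss_z) / df_i / (ss_resid / df_resid)


def rda_permutation_terms(
    Y, X, n_perm: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Sequential (Type I) permutation tests of ordered RDA terms.

    Each term is tested conditional on all earlier terms by permuting
    the residuals of the reduced model (the model with the earlier terms
    only): ``Y* = fitted(reduced) + permuted residuals(reduced)``.
    p = (exceedances + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Ydf = pd.DataFrame(Y)
    Yc = _center(Ydf.values.astype(float))
    _, names, blocks = _term_matrix(X)
    rng = np.random.default_rng(seed)
    rows = []
    for i, name in enumerate(names):
        f_obs = _sequential_f(Yc, blocks, i)
        Z = np.hstack(blocks[:i]) if i > 0 else None
        fit_z, _ = _fit_ss(Yc, Z)
        resid_z = Yc - fit_z
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(Yc.shape[0])
            Y_star = fit_z + resid_z[perm]
            if _sequential_f(Y_star, blocks, i) >= f_obs:
                exceed += 1
        rows.append(
            {"term": name, "f_value": f_obs,
             "p_value": (exceed + 1) / (n_perm + 1), "n_perm": n_perm}
        )
    return pd.DataFrame(rows).set_index("term")


def rda_model_build(
    Y,
    candidates,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], RDAResult, pd.DataFrame]:
    """Forward selection of RDA constraints by permutation p-value.

    At each step every remaining candidate is tested conditional on the
    already selected terms (permuting residuals of the selected model);
    the candidate with the smallest p (ties broken by added constrained
    variance) joins the model if its p-value clears the per-step
    entry threshold ``max(alpha / n_remaining, 1 / (n_perm + 1))`` — a
    Bonferroni correction over the candidates examined at that step, so
    screening many inert candidates does not inflate the selection;
    the floor keeps the smallest achievable permutation p admissible.
    An AIC-like criterion
    (n log(RSS/n) + 2k over the pooled residual sum of squares) is
    computed alongside and reported for every step; the permutation p
    is the primary stopping rule.

    Returns (selected term names, RDA of the selected model, step log).
    """
    Ydf = pd.DataFrame(Y)
    Yc = _center(Ydf.values.astype(float))
    n = Yc.shape[0]
    _, names, blocks = _term_matrix(candidates)
    remaining = list(range(len(names)))
    selected: list[int] = []
    rng = np.random.default_rng(seed)
    log_rows = []

    def _aic_like(block_idx: list[int]) -> float:
        Z = np.hstack([blocks[i] for i in block_idx]) if block_idx else None
        _, ss_fit = _fit_ss(Yc, Z)
        rss = float((Yc**2).sum()) - ss_fit
        k = (np.linalg.matrix_rank(_center(Z)) if Z is not None else 0)
        return n * np.log(max(rss, 1e-300) / n) + 2.0 * k

    current_aic = _aic_like([])
    while remaining:
        trial_rows = []
        for idx in remaining:
            order = selected + [idx]
            trial_blocks = [blocks[i] for i in order]
            i_test = len(selected)
            f_obs = _sequential_f(Yc, trial_blocks, i_test)
            Z = np.hstack(trial_blocks[:i_test]) if i_test > 0 else None
            fit_z, _ = _fit_ss(Yc, Z)
            resid_z = Yc - fit_z
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Y_star = fit_z + resid_z[perm]
                if _sequential_f(Y_star, trial_blocks, i_test) >= f_obs:
                    exceed += 1
            p = (exceed + 1) / (n_perm + 1)
            _, ss_w = _fit_ss(Yc, np.hstack(trial_blocks))
            _, ss_z2 = _fit_ss(Yc, Z)
            trial_rows.append((p, -(ss_w - ss_z2), idx, f_obs))
        trial_rows.sort()
        p_best, neg_gain, idx_best, f_best = trial_rows[0]
        threshold = max(alpha / len(remaining), 1.0 / (n_perm + 1))
        new_aic = _aic_like(selected + [idx_best])
        log_rows.append(
            {
                "candidate": names[idx_best],
                "p_value": p_best,
                "entry_threshold": threshold,
                "f_value": f_best,
                "added_variance": -neg_gain / (n - 1),
                "aic_like": new_aic,
                "aic_improves": bool(new_aic < current_aic),
                "accepted": bool(p_best <= threshold),
            }
        )
        if p_best > threshold:
            break
        selected.append(idx_best)
        remaining.remove(idx_best)
        current_aic = new_aic

    sel_names = [names[i] for i in selected]
    if selected:
        sel_X = {names[i]: blocks[i] for i in selected}
        result = rda_fit(Ydf, sel_X)
    else:
        result = RDAResult(
            constrained_eigenvalues=np.array([]),
            unconstrained_eigenvalues=np.array([]),
            proportion_constrained=0.0,
            site_scores=pd.DataFrame(index=Ydf.index),
            biplot_scores=pd.DataFrame(),
            total_variance=float((Yc**2).sum()) / (n - 1),
            term_names=[],
        )
    return sel_names, result, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# LOWESS
# ---------------------------------------------------------------------------

def lowess_curve(x, y, span: float = 2.0 / 3.0, iters: int = 3) -> np.ndarray:
    """Robust locally weighted regression; fitted values at the input x.

    ``span`` is the fraction of points in each local neighborhood
    (tricube weights); ``iters`` robustness iterations downweight
    outliers.  A span too small to hold a local neighborhood is widened
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >= 5 paired points")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    min_span = min(1.0, 4.0 / len(x))
    if span < min_span:
        import warnings

        warnings.warn(f"span widened from {span} to {min_span}", RuntimeWarning)
        span = min_span
    fitted = _sm_lowess(y, x, frac=span, it=iters, return_sorted=False)
    return np.asarray(fitted, dtype=float)
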