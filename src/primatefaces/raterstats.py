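"""Agreement and demographic statistics for Likert rating matrices.

The central object is a complete raters x stimuli matrix of integer
scores in 1..7 (1 = most "beautiful"/"human-like") with per-rater gender
and age metadata.  The module quantifies:

* rater agreement through the two-way, consistency intraclass
  correlation (single and average measures) and the Spearman-Brown
  relation linking them;
* per-stimulus gender differences through Mann-Whitney U tests with a
  Bonferroni-corrected significance level;
* multivariate demographic effects through Wilks' lambda MANOVA (with a
  PCA response-reduction fallback when the response dimension exceeds
  what the sample size supports);
* variance partitioning across a nested taxonomic hierarchy
  (group > genus > species > individual) by method-of-moments ANOVA;
* Spearman rank-correlation screens.

Stimuli play the role of the objects being rated and raters the role of
judges, so ``k`` in the Spearman-Brown relation is the number of raters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingMatrix",
    "ICCResult",
    "icc_consistency",
    "spearman_brown",
    "invert_scale",
    "gender_screen",
    "manova_wilks",
    "nested_variance_components",
    "spearman_screen",
]

LIKERT_MIN, LIKERT_MAX = 1, 7


@dataclass
class RatingMatrix:
    """Complete raters x stimuli Likert score matrix with rater metadata."""

    scores: pd.DataFrame      # raters x stimuli, integers in 1..7
    rater_meta: pd.DataFrame  # index = raters; columns gender, age

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape[0] < 2 or s.shape[1] < 2:
            raise ValueError("need >= 2 raters and >= 2 stimuli")
        if s.isna().any().any():
            raise ValueError("rating matrix must be complete (no missing cells)")
        vals = s.values
        if not np.array_equal(vals, np.rint(vals)) or vals.min() < LIKERT_MIN \
                or vals.max() > LIKERT_MAX:
            raise ValueError("scores must be integers in [1, 7]")
        if not self.rater_meta.index.equals(s.index):
            raise ValueError("rater_meta index must match the score rows")
        bad = set(self.rater_meta["gender"]) - {"male", "female"}
        if bad:
            raise ValueError(f"unknown gender label(s): {sorted(bad)}")
        self.scores = s.astype(int)

    @property
    def n_raters(self) -> int:
        return self.scores.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.scores.shape[1]

    @property
    def stimulus_ids(self) -> list[str]:
        return [str(c) for c in self.scores.columns]

    def species_means(self) -> pd.Series:
        """Mean score per stimulus, pooled over raters."""
        return self.scores.mean(axis=0)

    def subset_gender(self, gender: str) -> "RatingMatrix":
        keep = self.rater_meta["gender"] == gender
        if keep.sum() < 2:
            raise ValueError(f"fewer than 2 raters of gender {gender!r}")
        return RatingMatrix(self.scores.loc[keep], self.rater_meta.loc[keep])

    def to_csv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.insert(0, "age", self.rater_meta["age"])
        out.insert(0, "gender", self.rater_meta["gender"])
        out.index.name = "rater_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingMatrix":
        df = pd.read_csv(path, index_col=0)
        meta = df[["gender", "age"]]
        scores = df.drop(columns=["gender", "age"])
        return cls(scores, meta)


@dataclass
class ICCResult:
    """Two-way consistency ICC from the stimuli x raters ANOVA."""

    icc_single: float
    icc_average: float
    ms_rows: float
    ms_error: float
    n_stimuli: int
    n_raters: int
    f_value: float
    p_value: float


def icc_consistency(m: RatingMatrix) -> ICCResult:
    """Two-way, consistency ICC with stimuli as objects and raters as judges.

    From the two-way ANOVA without interaction (rows = stimuli, columns
    = raters): ``single = (MSR - MSE) / (MSR + (k-1) MSE)`` and
    ``average = (MSR - MSE) / MSR`` with k raters.  Rater main effects
    are absorbed by the column term, so consistent but offset raters
    still agree perfectly.
    """
    X = m.scores.values.T.astype(float)  # stimuli x raters
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err
    if ms_err == 0 and ms_rows == 0:
        raise ZeroDivisionError("undefined ICC: no row variance and no error variance")
    if ms_err == 0:
        single = average = 1.0
        f = np.inf
        p = 0.0
    else:
        single = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        average = (ms_rows - ms_err) / ms_rows
        f = ms_rows / ms_err
        p = float(stats.f.sf(f, df_rows, df_err))
    return ICCResult(
        icc_single=float(single),
        icc_average=float(average),
        ms_rows=float(ms_rows),
        ms_error=float(ms_err),
        n_stimuli=n,
        n_raters=k,
        f_value=float(f),
        p_value=p,
    )


def spearman_brown(icc_single: float, k: int) -> float:
    """Average-measure reliability of k raters from the single-measure ICC."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    denom = 1.0 + (k - 1) * icc_single
    if denom <= 0:
        raise ValueError("nonpositive denominator in the Spearman-Brown relation")
    return k * icc_single / denom


def invert_scale(m: RatingMatrix) -> RatingMatrix:
    """Map every score x to 8 - x so higher means more attractive; involution."""
    return RatingMatrix(8 - m.scores, m.rater_meta)


def gender_screen(m: RatingMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-stimulus Mann-Whitney U comparing male vs. female raw scores.

    Two-sided tests; exact null enumeration when both gender groups have
    at most 8 raters, otherwise the normal approximation with tie and
    continuity corrections.  Significance uses the Bonferroni-corrected
    level ``alpha / n_stimuli``.
    """
    genders = m.rater_meta["gender"]
    male = m.scores.loc[genders == "male"]
    female = m.scores.loc[genders == "female"]
    if len(male) < 2 or len(female) < 2:
        raise ValueError("both genders need >= 2 raters")
    method = "exact" if max(len(male), len(female)) <= 8 else "asymptotic"
    threshold = alpha / m.n_stimuli
    rows = []
    for stim in m.scores.columns:
        res = stats.mannwhitneyu(
            male[stim], female[stim], alternative="two-sided", method=method
        )
        rows.append(
            {
                "stimulus": stim,
                "u_statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "significant": bool(res.pvalue < threshold),
            }
        )
    out = pd.DataFrame(rows).set_index("stimulus")
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tests"] = m.n_stimuli
    return out


def manova_wilks(
    responses: pd.DataFrame,
    design: pd.DataFrame,
    formula_rhs: str,
    reduce_variance: float = 0.95,
) -> pd.DataFrame:
    """Wilks' lambda MANOVA of a response matrix on a design formula.

    ``responses`` is items x q, ``design`` holds the predictor columns
    referenced by ``formula_rhs`` (e.g. ``"age * gender"``).  When q is
    too large for the error degrees of freedom, responses are first
    reduced by PCA retaining ``reduce_variance`` of their variance (and
    at most n - p - 2 components); the reduction is recorded in the
    result's ``attrs``.
    """
    Y = pd.DataFrame(responses).astype(float)
    n, q = Y.shape
    design = design.loc[Y.index]
    n_design = len(
        pd.get_dummies(design, drop_first=True).columns
    ) + 1  # rough count incl. intercept
    reduced = False
    if n <= q + n_design + 1:
        from .morphometry import pca as _pca

        scores, _, frac = _pca(Y.values, standardize=False)
        n_keep = int(np.searchsorted(np.cumsum(frac), reduce_variance) + 1)
        n_keep = min(n_keep, n - n_design - 2)
        if n_keep < 1:
            raise ValueError("too few items for any MANOVA response")
        warnings.warn(
            f"responses reduced by PCA from {q} to {n_keep} components "
            f"({reduce_variance:.0%} variance target)",
            RuntimeWarning,
        )
        Y = pd.DataFrame(
            scores[:, :n_keep], index=Y.index,
            columns=[f"pc{i + 1}" for i in range(n_keep)],
        )
        reduced = True

    import patsy

    dm = patsy.dmatrix(formula_rhs, design, return_type="dataframe")
    X = dm.values.astype(float)
    n_obs, rank_x = X.shape[0], np.linalg.matrix_rank(X)
    Yv = Y.values
    XtX_inv = np.linalg.pinv(X.T @ X)
    B = XtX_inv @ X.T @ Yv
    resid = Yv - X @ B
    E = resid.T @ resid
    v = n_obs - rank_x  # error df
    p = Yv.shape[1]
    if v <= p:
        raise ValueError("singular error matrix: too many responses for n; "
                         "reduce the response dimension")
    rows = []
    for term, sl in dm.design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(*sl.indices(X.shape[1]))
        q = len(idx)
        LB = B[idx]
        Lcov = XtX_inv[np.ix_(idx, idx)]
        H = LB.T @ np.linalg.solve(Lcov, LB)
        # Wilks' lambda and Rao's F approximation
        sign, logdet_e = np.linalg.slogdet(E)
        _, logdet_eh = np.linalg.slogdet(E + H)
        wilks = float(np.exp(logdet_e - logdet_eh))
        pq2 = p**2 + q**2 - 5
        t = np.sqrt((p**2 * q**2 - 4) / pq2) if pq2 > 0 else 1.0
        w = v + q - (p + q + 1) / 2.0
        df1 = p * q
        df2 = w * t - (p * q - 2) / 2.0
        lam_t = wilks ** (1.0 / t)
        f_val = (1.0 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
        rows.append(
            {
                "term": term,
                "wilks_lambda": wilks,
                "f_value": float(f_val),
                "df1": float(df1),
                "df2": float(df2),
                "p_value": float(stats.f.sf(f_val, df1, df2)),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["pca_reduced"] = reduced
    out.attrs["n_responses"] = Y.shape[1]
    return out


def nested_variance_components(scores: pd.DataFrame) -> dict:
    """Method-of-moments variance components for a balanced nested design.

    ``scores`` must be a long table with columns ``group``, ``genus``,
    ``species``, ``value``; rows are individual-level observations.  The
    hierarchy group > genus > species > individual must be strictly
    nested and balanced (equal numbers of genera per group, species per
    genus, individuals per species).  Negative moment estimates are
    truncated at zero and flagged.
    """
    df = pd.DataFrame(scores)
    required = {"group", "genus", "species", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    # nesting checks
    for child, parent in (("genus", "group"), ("species", "genus")):
        parents = df.groupby(child)[parent].nunique()
        if (parents > 1).any():
            bad = parents[parents > 1].index.tolist()
            raise ValueError(f"nesting violation: {child} {bad} appear in >1 {parent}")
    a = df["group"].nunique()
    genera_per_group = df.groupby("group")["genus"].nunique()
    species_per_genus = df.groupby("genus")["species"].nunique()
    obs_per_species = df.groupby("species")["value"].size()
    if genera_per_group.nunique() != 1 or species_per_genus.nunique() != 1 \
            or obs_per_species.nunique() != 1:
        raise ValueError("design must be balanced at every level")
    b = int(genera_per_group.iloc[0])
    c = int(species_per_genus.iloc[0])
    n = int(obs_per_species.iloc[0])

    grand = df["value"].mean()
    gmeans = df.groupby("group")["value"].mean()
    genmeans = df.groupby(["group", "genus"])["value"].mean()
    spmeans = df.groupby(["group", "genus", "species"])["value"].mean()

    ss_group = b * c * n * ((gmeans - grand) ** 2).sum()
    ss_genus = c * n * ((genmeans - genmeans.groupby("group").transform("mean")) ** 2).sum()
    ss_species = n * ((spmeans - spmeans.groupby(["group", "genus"]).transform("mean")) ** 2).sum()
    resid = df["value"] - df.set_index(["group", "genus", "species"]).index.map(spmeans)
    ss_resid = (resid ** 2).sum()

    ms_group = ss_group / (a - 1)
    ms_genus = ss_genus / (a * (b - 1)) if b > 1 else np.nan
    ms_species = ss_species / (a * b * (c - 1)) if c > 1 else np.nan
    ms_resid = ss_resid / (a * b * c * (n - 1)) if n > 1 else np.nan

    est = {
        "residual": ms_resid,
        "species": (ms_species - ms_resid) / n,
        "genus": (ms_genus - ms_species) / (c * n),
        "group": (ms_group - ms_genus) / (b * c * n),
    }
    truncated = [k for k, v in est.items() if np.isfinite(v) and v < 0]
    return {
        "variances": {k: float(max(v, 0.0)) for k, v in est.items()},
        "truncated": truncated,
        "design": {"groups": a, "genera_per_group": b,
                   "species_per_genus": c, "obs_per_species": n},
    }


def spearman_screen(x, Y, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman rank correlation of ``x`` against every column of ``Y``.

    Constant inputs yield a NaN rho with a ``constant`` flag instead of
    an exception.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    Y = pd.DataFrame(Y)
    rows = []
    for col in Y.columns:
        y = Y[col].values.astype(float)
        if len(y) != len(x):
            raise ValueError(f"length mismatch for variable {col!r}")
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"variable": col, "rho": np.nan, "p_value": np.nan,
                         "significant": False, "constant": True})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"variable": col, "rho": float(rho), "p_value": float(p),
                     "significant": bool(p < alpha), "constant": False})
    return pd.DataFrame(rows).set_index("variable")
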