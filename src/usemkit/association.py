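"""Associating individualized network features with behavioral outcomes.

Features are built per subject from the finalized multi-level models:
group-level paths contribute their per-subject coefficient (estimated for
everyone), while individual-level paths passing a prevalence filter
contribute a 0/1 presence indicator (their coefficient would be missing
for subjects without the path). Feature selection uses the adaptive lasso:
a ridge regression (penalty chosen by 10-fold cross-validation) supplies
per-feature penalty factors w_j = 1/|b_ridge,j|^gamma, and an L1 path with
those factors (again 10-fold CV) selects the final set, whose fit is then
summarized by an unpenalized refit. Post hoc per-feature regressions and
subgroup ANOVAs with Benjamini-Hochberg correction round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_search import CohortSearchResult
from .usem_core import PathSpec

__all__ = [
    "FeatureMatrix",
    "AssocResult",
    "build_features",
    "composite_z",
    "adaptive_lasso",
    "posthoc_ols",
    "subgroup_anova",
]


class AssociationError(ValueError):
    pass


@dataclass
class FeatureMeta:
    path: PathSpec
    level: str
    encoding: str  # "beta" or "presence"

    @property
    def name(self) -> str:
        tag = "b" if self.encoding == "beta" else "p"
        return (f"{self.path.from_node}->{self.path.to_node}"
                f".l{self.path.lag}.{tag}")


@dataclass
class FeatureMatrix:
    """Subjects x network-features design with per-feature metadata."""

    X: pd.DataFrame                      # n x f
    meta: list[FeatureMeta] = field(default_factory=list)

    def __post_init__(self):
        if self.X.shape[1] == 0:
            raise AssociationError("empty feature set")
        if len(self.meta) != self.X.shape[1]:
            raise AssociationError("metadata/columns mismatch")
        if not np.isfinite(self.X.to_numpy(float)).all():
            raise AssociationError("non-finite feature values")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.X.index)

    def column(self, path: PathSpec, encoding: str) -> np.ndarray:
        for m, col in zip(self.meta, self.X.columns):
            if m.path == path and m.encoding == encoding:
                return self.X[col].to_numpy(float)
        raise AssociationError(f"no {encoding} feature for {path!r}")

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(name=m.name, from_node=m.path.from_node,
                 to_node=m.path.to_node, lag=m.path.lag, level=m.level,
                 encoding=m.encoding)
            for m in self.meta])


@dataclass
class AssocResult:
    """Adaptive-lasso selection and fit summary for one outcome."""

    outcome: str
    selected: list[str]
    coefficients: pd.Series        # penalized coefficients (selected only)
    ridge_weights: pd.Series       # per-feature penalty factors
    penalty: float                 # chosen lasso lambda
    r2: float
    adjusted_r2: float
    r2_penalized: float
    posthoc: pd.DataFrame | None = None


def build_features(result: CohortSearchResult,
                   min_fraction: float = 0.20) -> FeatureMatrix:
    """Build the design matrix from a finalized cohort search.

    Group paths -> continuous beta columns; subgroup and individual paths
    retained for at least ceil(min_fraction * n) subjects -> binary
    presence columns. Constant presence columns (a path in everyone's
    model) are dropped with a warning.
    """
    from .heterogeneity import prevalence

    models = result.individual_models
    if not models:
        raise AssociationError("result contains no individual models")
    ids = sorted(models)
    n = len(ids)
    cols: dict[str, np.ndarray] = {}
    meta: list[FeatureMeta] = []

    for pth in sorted(result.group_paths, key=PathSpec.sort_key):
        fm = FeatureMeta(pth, "group", "beta")
        cols[fm.name] = np.array([models[s].estimates.get(pth, 0.0)
                                  for s in ids])
        meta.append(fm)

    sub_paths = sorted({p for ps in result.subgroup_paths.values()
                        for p in ps}, key=PathSpec.sort_key)
    prev = prevalence(models, min_fraction,
                      exclude_levels=("null_base", "group", "subgroup"))
    ind_paths = [PathSpec(r.from_node, r.to_node, int(r.lag), "individual")
                 for r in prev.itertuples()]
    for pth, lvl in ([(p, "subgroup") for p in sub_paths]
                     + [(p, "individual") for p in ind_paths]):
        fm = FeatureMeta(pth.relevel(lvl), lvl, "presence")
        col = np.array([1.0 if pth in models[s].free_paths else 0.0
                        for s in ids])
        if col.min() == col.max():
            warnings.warn(f"dropping constant presence feature {pth!r}")
            continue
        cols[fm.name] = col
        meta.append(fm)

    if not cols:
        raise AssociationError("no usable network features")
    X = pd.DataFrame(cols, index=ids)
    return FeatureMatrix(X, meta)


def composite_z(scale_scores: dict[str, pd.Series]) -> pd.Series:
    """Average of z-scored scale sums, per subject.

    Each scale is standardized over the subjects providing it; a subject's
    composite is the mean of their available z-scores, so a missing scale
    falls back to the other(s) alone. Subjects missing every scale get NaN.
    """
    if not scale_scores:
        raise AssociationError("no scales supplied")
    zs = []
    for name, s in scale_scores.items():
        s = pd.Series(s, dtype=float)
        avail = s.dropna()
        if avail.std(ddof=0) == 0:
            raise AssociationError(f"scale '{name}' has zero variance")
        zs.append((s - avail.mean()) / avail.std(ddof=0))
    frame = pd.concat(zs, axis=1)
    out = frame.mean(axis=1, skipna=True)
    if out.isna().any():
        warnings.warn(f"{int(out.isna().sum())} subjects missing all scales")
    return out


def adaptive_lasso(X: FeatureMatrix | pd.DataFrame, y, folds: int = 10,
                   gamma: float = 1.0, seed: int = 0,
                   link: str = "identity",
                   lambda_rule: str | float = 0.25) -> AssocResult:
    """Two-stage adaptive lasso with seeded cross-validation.

    Stage 1 fits a ridge regression with the penalty chosen by
    ``folds``-fold CV and converts its coefficients into per-feature
    penalty factors 1/|b|^gamma (near-zero ridge coefficients get a large
    finite factor). Stage 2 runs the L1 path with those factors, choosing
    the penalty by CV. ``lambda_rule`` picks the point on the CV curve:
    ``"min"`` (minimum CV error, liberal), ``"1se"`` (largest penalty
    within one standard error, conservative), or a float f for the largest
    penalty within f standard errors of the minimum. The default 0.25
    balances false selections under the null against power for moderate
    effects. R-squared values come from an unpenalized refit on the
    selected set; for the logistic link they are McFadden pseudo-R2,
    labeled as such by the link field.
    """
    from sklearn.linear_model import (LassoCV, LogisticRegressionCV,
                                      RidgeCV)
    from sklearn.model_selection import KFold

    if isinstance(X, FeatureMatrix):
        Xdf = X.X
        outcome = getattr(y, "name", None) or "outcome"
    else:
        Xdf = X
        outcome = getattr(y, "name", None) or "outcome"
    yv = np.asarray(y, dtype=float)
    Xv = Xdf.to_numpy(float)
    n, f = Xv.shape
    if n <= folds:
        raise AssociationError("need more observations than folds")
    if folds > n // 3:
        # every fold needs a few observations for a usable CV error
        folds = max(2, n // 3)
        warnings.warn(f"too few observations for the requested folds; "
                      f"using {folds}-fold CV")
    if link == "identity" and np.std(yv) == 0:
        raise AssociationError("outcome has zero variance")

    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(Xdf.columns[sd == 0])
        raise AssociationError(f"constant feature columns: {bad}")
    Xs = (Xv - mu) / sd

    rng = np.random.default_rng((seed, 86028121))
    cv = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2 ** 31)))
    alphas = np.logspace(-4, 4, 81)

    if link == "identity":
        ridge = RidgeCV(alphas=alphas, cv=cv,
                        scoring="neg_mean_squared_error").fit(Xs, yv)
        b_ridge = ridge.coef_
    elif link == "logistic":
        ridge = LogisticRegressionCV(Cs=25, cv=cv, penalty="l2",
                                     max_iter=5000).fit(Xs, yv)
        b_ridge = ridge.coef_.ravel()
    else:
        raise AssociationError(f"unknown link '{link}'")

    tiny = 1e-8
    w = 1.0 / np.maximum(np.abs(b_ridge), tiny) ** gamma
    Xw = Xs / w  # lasso on rescaled columns == per-feature penalty factors

    cv2 = KFold(n_splits=folds, shuffle=True,
                random_state=int(rng.integers(2 ** 31)))
    se_factor = {"min": 0.0, "1se": 1.0}.get(lambda_rule, lambda_rule)
    if not isinstance(se_factor, (int, float)):
        raise AssociationError(f"unknown lambda_rule '{lambda_rule}'")
    if link == "identity":
        lasso = LassoCV(cv=cv2, alphas=100, max_iter=50000).fit(Xw, yv)
        lam = float(lasso.alpha_)
        if se_factor > 0:
            from sklearn.linear_model import Lasso
            mse = lasso.mse_path_.mean(axis=1)
            se = lasso.mse_path_.std(axis=1) / np.sqrt(folds)
            i_min = int(np.argmin(mse))
            ok = np.nonzero(mse <= mse[i_min] + se_factor * se[i_min])[0]
            lam = float(lasso.alphas_[ok[0]])
            lasso = Lasso(alpha=lam, max_iter=50000).fit(Xw, yv)
        coef = lasso.coef_ / w
    else:
        lcv = LogisticRegressionCV(Cs=25, cv=cv2, penalty="l1",
                                   solver="liblinear",
                                   max_iter=5000).fit(Xw, yv)
        lam = float(1.0 / lcv.C_[0])
        coef = lcv.coef_.ravel() / w

    sel_mask = np.abs(coef) > 1e-10
    selected = list(Xdf.columns[sel_mask])
    coefficients = pd.Series(coef[sel_mask], index=selected,
                             name="penalized_beta")
    ridge_weights = pd.Series(w, index=Xdf.columns, name="penalty_factor")

    # penalized-prediction fit
    if link == "identity":
        yhat_pen = Xw @ (coef * w) + (lasso.intercept_
                                      if hasattr(lasso, "intercept_") else 0)
        ss_tot = np.sum((yv - yv.mean()) ** 2)
        r2_pen = float(1.0 - np.sum((yv - yhat_pen) ** 2) / ss_tot)
    else:
        r2_pen = float(np.nan)

    if not selected:
        return AssocResult(outcome=outcome, selected=[],
                           coefficients=coefficients,
                           ridge_weights=ridge_weights, penalty=lam,
                           r2=0.0, adjusted_r2=0.0, r2_penalized=r2_pen)

    # unpenalized refit on the selected set
    import statsmodels.api as sm
    Xsel = sm.add_constant(Xdf[selected].to_numpy(float))
    if link == "identity":
        refit = sm.OLS(yv, Xsel).fit()
        r2, ar2 = float(refit.rsquared), float(refit.rsquared_adj)
    else:
        refit = sm.Logit(yv, Xsel).fit(disp=0)
        r2 = float(refit.prsquared)  # McFadden pseudo-R2
        k = len(selected)
        ar2 = float(1 - (refit.llf - k) / refit.llnull) if refit.llnull else r2
    return AssocResult(outcome=outcome, selected=selected,
                       coefficients=coefficients,
                       ridge_weights=ridge_weights, penalty=lam,
                       r2=r2, adjusted_r2=ar2, r2_penalized=r2_pen)


def posthoc_ols(X: pd.DataFrame, y) -> pd.DataFrame:
    """Simple linear regression of the outcome on each selected feature
    (estimate, SE, t, p), plus a joint OLS row reporting model R2.

    The joint fit drops collinear columns via pivoting, with a warning.
    """
    import statsmodels.api as sm

    if X.shape[1] == 0:
        raise AssociationError("no selected features for post hoc tests")
    yv = np.asarray(y, dtype=float)
    rows = []
    for col in X.columns:
        xi = sm.add_constant(X[col].to_numpy(float))
        fit = sm.OLS(yv, xi).fit()
        rows.append(dict(feature=col, estimate=float(fit.params[1]),
                         se=float(fit.bse[1]), t=float(fit.tvalues[1]),
                         p=float(fit.pvalues[1]),
                         r2=float(fit.rsquared)))
    Xj = X.to_numpy(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(Xj)), Xj]))
    if rank < Xj.shape[1] + 1:
        warnings.warn("collinear features in joint fit; "
                      "statsmodels pivoting applies")
    joint = sm.OLS(yv, sm.add_constant(Xj)).fit()
    rows.append(dict(feature="<joint>", estimate=np.nan, se=np.nan,
                     t=np.nan, p=np.nan, r2=float(joint.rsquared)))
    out = pd.DataFrame(rows)
    out.attrs["joint_r2"] = float(joint.rsquared)
    out.attrs["joint_adjusted_r2"] = float(joint.rsquared_adj)
    return out


def subgroup_anova(outcomes: pd.DataFrame, membership: pd.Series,
                   alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of each outcome across subgroups with BH correction.

    Pairwise Welch t-tests are run only for outcomes whose BH-adjusted q
    falls below ``alpha``; their results are attached in the ``pairwise``
    attr. Subgroups with fewer than 2 members cause the outcome family to
    skip that group with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    labels = membership.loc[outcomes.index]
    groups = sorted(labels.unique())
    usable = []
    for g in groups:
        if (labels == g).sum() < 2:
            warnings.warn(f"subgroup {g} has <2 members; skipped")
        else:
            usable.append(g)
    if len(usable) < 2:
        raise AssociationError("need at least 2 subgroups with >=2 members")
    rows = []
    for col in outcomes.columns:
        samples = [outcomes.loc[labels == g, col].dropna().to_numpy()
                   for g in usable]
        if any(len(s) < 2 for s in samples):
            warnings.warn(f"outcome '{col}' skipped (a subgroup has <2 "
                          "non-missing values)")
            continue
        F, p = stats.f_oneway(*samples)
        rows.append(dict(outcome=col, F=float(F), p=float(p)))
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    _, qvals, _, _ = multipletests(res.p, method="fdr_bh")
    res["q"] = qvals
    pairwise = []
    for r in res.itertuples():
        if r.q < alpha:
            for i, g1 in enumerate(usable):
                for g2 in usable[i + 1:]:
                    a = outcomes.loc[labels == g1, r.outcome].dropna()
                    b = outcomes.loc[labels == g2, r.outcome].dropna()
                    t, p = stats.ttest_ind(a, b, equal_var=False)
                    pairwise.append(dict(outcome=r.outcome, group_a=g1,
                                         group_b=g2, t=float(t),
                                         p=float(p)))
    res.attrs["pairwise"] = pd.DataFrame(
        pairwise, columns=["outcome", "group_a", "group_b", "t", "p"])
    return res
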