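"""Discrimination pipeline: from a feature table to compared logistic models.

The procedure mirrors common practice for clinical discrimination studies:

1. dichotomize the LLFDI function score at the sample median (very high
   functional status, VHFS, is score >= median; high functional status, HFS,
   otherwise);
2. log-transform jerk-score features and z-normalize every instrumented
   feature;
3. report a restricted-cubic-spline linearity check per feature (3 knots at
   the 0.1/0.5/0.9 quantiles; likelihood-ratio p for the nonlinear term) —
   informational only, it never gates the pipeline;
4. iteratively prune multicollinearity: remove the feature with the largest
   variance inflation factor until all VIFs are below 10;
5. univariable screening: keep features whose univariable logistic Wald p is
   <= 0.15;
6. step-wise backward multivariable logistic regression, dropping the
   highest-Wald-p feature until all are <= 0.05;
7. compare models by AUC with DeLong confidence intervals and the DeLong
   paired test;
8. internally validate by Harrell's bootstrap optimism correction, re-running
   the whole selection (screen + stepwise) inside every resample.

Logistic fits use Newton/IRLS (statsmodels) with a deviance tolerance of
1e-8 and at most 100 iterations; quasi-separation is flagged when any
coefficient magnitude exceeds 15 on the z-scored scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError
from .types import LogisticFit, RocComparison, VifReport

HFS, VHFS = "HFS", "VHFS"
SCREEN_ALPHA = 0.15
STEPWISE_ALPHA = 0.05
VIF_THRESHOLD = 10.0
RCS_KNOT_QUANTILES = (0.1, 0.5, 0.9)
_SEPARATION_GUARD = 15.0
_Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# outcome and preprocessing

def dichotomize_llfdi(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add a ``group`` column: VHFS iff ``llfdi >= median`` (HFS otherwise).

    With ties at the median the VHFS side absorbs them, so the median value
    itself is the VHFS minimum.
    """
    if "llfdi" not in cohort.columns:
        raise ConfigurationError("cohort table lacks an 'llfdi' column")
    scores = cohort["llfdi"].astype(float)
    if scores.nunique() < 2:
        raise ConfigurationError("all LLFDI scores identical; no median split")
    med = float(scores.median())
    out = cohort.copy()
    out["group"] = np.where(scores >= med, VHFS, HFS)
    return out


def group_to_binary(group: pd.Series) -> np.ndarray:
    """VHFS -> 1, HFS -> 0."""
    return (np.asarray(group) == VHFS).astype(float)


@dataclass
class Preprocessor:
    """Log-transform of jerk columns followed by per-column z-scoring."""

    njs_columns: list[str]
    means: pd.Series = field(default=None)
    sds: pd.Series = field(default=None)

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy().astype(float)
        for col in self.njs_columns:
            if col not in out.columns:
                continue
            bad = out[col] <= 0
            if bad.any():
                idx = out.index[bad][0]
                raise ConfigurationError(
                    f"non-positive jerk score in column {col!r}, row {idx!r}")
            out[col] = np.log(out[col])
        self.means = out.mean()
        self.sds = out.std(ddof=1)
        zero = self.sds[self.sds == 0]
        if len(zero):
            raise ConfigurationError(
                f"constant feature column(s): {list(zero.index)}")
        return (out - self.means) / self.sds


def preprocess_features(table: pd.DataFrame, njs_columns: list[str]
                        ) -> pd.DataFrame:
    """Log jerk scores, then center/scale every column to z-scores."""
    return Preprocessor(njs_columns=njs_columns).fit_transform(table)


# ---------------------------------------------------------------------------
# logistic fitting

def fit_logistic(X: pd.DataFrame, y: np.ndarray) -> LogisticFit:
    """Newton/IRLS logistic fit with an intercept; Wald inference."""
    names = list(X.columns)
    design = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float)
                                                  for c in names])
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=100,
                                          tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
            coefs = np.asarray(res.params, float)
            ses = np.asarray(res.bse, float)
            pvals = np.asarray(res.pvalues, float)
            probs = np.asarray(res.predict(design), float)
            llf = float(res.llf)
        except Exception as exc:  # perfect separation, singular Hessian, ...
            converged = False
            flags.append(f"fit-failed: {type(exc).__name__}")
            k = design.shape[1]
            coefs = np.full(k, np.nan)
            ses = np.full(k, np.nan)
            pvals = np.full(k, np.nan)
            probs = np.full(len(y), np.mean(y))
            llf = float("nan")
    if converged and np.nanmax(np.abs(coefs)) > _SEPARATION_GUARD:
        flags.append("quasi-separation")
    if not converged and not flags:
        flags.append("non-convergence")
    return LogisticFit(features=names, coefficients=coefs,
                       standard_errors=ses, pvalues=pvals,
                       probabilities=np.clip(probs, 1e-12, 1 - 1e-12),
                       converged=converged, llf=llf, flags=flags)


def fit_intercept_only(y: np.ndarray) -> LogisticFit:
    p = float(np.mean(y))
    b0 = float(np.log(p / (1 - p))) if 0 < p < 1 else 0.0
    return LogisticFit(features=[], coefficients=np.array([b0]),
                       standard_errors=np.array([np.nan]),
                       pvalues=np.array([np.nan]),
                       probabilities=np.full(len(y), p),
                       converged=True,
                       llf=float(len(y) * (p * np.log(max(p, 1e-12))
                                           + (1 - p) * np.log(max(1 - p, 1e-12)))),
                       flags=["intercept-only"])


# ---------------------------------------------------------------------------
# restricted cubic spline linearity check

def rcs_nonlinear_basis(x: np.ndarray, knots: tuple[float, float, float]
                        ) -> np.ndarray:
    """The single nonlinear restricted-cubic-spline basis column for 3 knots.

    Harrell's truncated-power construction, normalized by ``(t3 - t1)^2`` so
    the column is on roughly the scale of ``x``.
    """
    t1, t2, t3 = knots

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    return (cube(x - t1)
            - cube(x - t2) * (t3 - t1) / (t3 - t2)
            + cube(x - t3) * (t2 - t1) / (t3 - t2)) / (t3 - t1) ** 2


def check_linearity_rcs(x: np.ndarray, y: np.ndarray) -> float:
    """Likelihood-ratio p-value for the spline (nonlinearity) term.

    Knots at the empirical 0.1/0.5/0.9 quantiles.  Returns NaN when either
    fit fails or the knots are degenerate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if x.size < 20:
        raise DegenerateInputError("linearity check needs >= 20 observations")
    knots = tuple(np.quantile(x, RCS_KNOT_QUANTILES))
    if not (knots[0] < knots[1] < knots[2]):
        return float("nan")
    lin = fit_logistic(pd.DataFrame({"x": x}), y)
    spline = rcs_nonlinear_basis(x, knots)
    full = fit_logistic(pd.DataFrame({"x": x, "x_spline": spline}), y)
    if not (lin.converged and full.converged):
        return float("nan")
    lr = 2.0 * (full.llf - lin.llf)
    return float(sps.chi2.sf(max(lr, 0.0), df=1))


# ---------------------------------------------------------------------------
# collinearity pruning

def _vif_vector(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j) from regressing column j on the others."""
    n, k = X.shape
    vifs = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst <= 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def iterative_vif_prune(table: pd.DataFrame,
                        threshold: float = VIF_THRESHOLD) -> VifReport:
    """Remove the highest-VIF feature until all VIFs are below the threshold.

    Ties break toward the earliest column in the table's order; perfectly
    collinear columns have infinite VIF and go first.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return VifReport(removed=[], surviving=cols)
    removed: list[tuple[str, float]] = []
    while len(cols) >= 2:
        X = table[cols].to_numpy(float)
        if X.shape[0] <= len(cols):
            raise ConfigurationError(
                "need more observations than features for VIF pruning")
        vifs = _vif_vector(X)
        worst = int(np.argmax(vifs))   # argmax takes the first maximum
        if vifs[worst] < threshold:
            break
        removed.append((cols[worst], float(vifs[worst])))
        cols.pop(worst)
    return VifReport(removed=removed, surviving=cols)


# ---------------------------------------------------------------------------
# screening and stepwise selection

def univariable_screen(table: pd.DataFrame, y: np.ndarray,
                       alpha: float = SCREEN_ALPHA) -> list[str]:
    """Features whose univariable logistic Wald p is <= alpha."""
    keep = []
    for col in table.columns:
        fit = fit_logistic(table[[col]], y)
        if not fit.converged:
            warnings.warn(f"screen: {col} did not converge; excluded",
                          stacklevel=2)
            continue
        if fit.pvalues[1] <= alpha:
            keep.append(col)
    return keep


def stepwise_backward(table: pd.DataFrame, y: np.ndarray,
                      alpha: float = STEPWISE_ALPHA
                      ) -> tuple[LogisticFit, list[tuple[str, float]]]:
    """Backward elimination on Wald p-values.

    Iteratively drops the highest-p feature while that p exceeds alpha,
    refitting after each drop.  Returns the final fit and the removal trail.
    Warns when the events-per-variable ratio is below the 10:1 heuristic.
    An empty survivor set yields a flagged intercept-only model.
    """
    cols = list(table.columns)
    trail: list[tuple[str, float]] = []
    if cols and len(y) / len(cols) < 10:
        warnings.warn("fewer than 10 subjects per candidate variable",
                      stacklevel=2)
    while cols:
        fit = fit_logistic(table[cols], y)
        pv = fit.pvalues[1:]
        if not fit.converged or np.all(np.isnan(pv)):
            # singular/separated fit: drop the largest-|coefficient| feature
            coefs = np.abs(fit.coefficients[1:])
            j = (int(np.nanargmax(coefs))
                 if not np.all(np.isnan(coefs)) else len(cols) - 1)
            trail.append((cols[j], float("nan")))
            cols.pop(j)
            continue
        j = int(np.nanargmax(pv))
        if pv[j] > alpha:
            trail.append((cols[j], float(pv[j])))
            cols.pop(j)
        else:
            return fit, trail
    return fit_intercept_only(y), trail


# ---------------------------------------------------------------------------
# AUC and the DeLong machinery

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray
                       ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """AUC and structural components V10 (cases), V01 (controls)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DegenerateInputError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (np.sum(all_r[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, float(auc), v10, v01


def compute_auc(scores: np.ndarray, y: np.ndarray
                ) -> tuple[float, tuple[float, float], float]:
    """Mann-Whitney AUC (ties count 1/2) with a DeLong-variance 95% CI.

    Returns ``(auc, (lo, hi), variance)``.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y, float)
    _, auc, v10, v01 = _delong_components(scores, y)
    m, n = int(np.sum(y == 1)), int(np.sum(y == 0))
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = _Z95 * np.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half)), float(var)


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                y: np.ndarray) -> RocComparison:
    """DeLong's paired test for two correlated AUCs on the same subjects."""
    y = np.asarray(y, float)
    _, auc_a, v10a, v01a = _delong_components(np.asarray(scores_a, float), y)
    _, auc_b, v10b, v01b = _delong_components(np.asarray(scores_b, float), y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    auc_a_ci = compute_auc(scores_a, y)[1]
    auc_b_ci = compute_auc(scores_b, y)[1]
    flags: list[str] = []
    delta = auc_a - auc_b
    if var_diff <= 1e-16:
        if abs(delta) < 1e-12:
            z, p = 0.0, 1.0
        else:
            z, p = None, None
            flags.append("degenerate-variance")
    else:
        z = float(delta / np.sqrt(var_diff))
        p = float(2.0 * sps.norm.sf(abs(z)))
    return RocComparison(auc_a=float(auc_a), auc_b=float(auc_b),
                         ci_a=auc_a_ci, ci_b=auc_b_ci,
                         delong_z=z, delong_p=p, flags=flags)


# ---------------------------------------------------------------------------
# model-building pipelines and internal validation

@dataclass
class SelectionResult:
    """Everything the screened/stepwise modelling path produced."""

    vif: VifReport
    linearity_p: dict[str, float]
    screened: list[str]
    trail: list[tuple[str, float]]
    fit: LogisticFit


def select_and_fit(table: pd.DataFrame, y: np.ndarray,
                   screen_alpha: float = SCREEN_ALPHA,
                   stepwise_alpha: float = STEPWISE_ALPHA,
                   vif_threshold: float = VIF_THRESHOLD,
                   check_linearity: bool = True) -> SelectionResult:
    """VIF pruning, screening and stepwise backward selection in sequence."""
    vif = iterative_vif_prune(table, vif_threshold)
    pruned = table[vif.surviving]
    linearity = {}
    if check_linearity:
        for col in pruned.columns:
            try:
                linearity[col] = check_linearity_rcs(pruned[col].to_numpy(), y)
            except DegenerateInputError:
                linearity[col] = float("nan")
    screened = univariable_screen(pruned, y, screen_alpha)
    if not screened:
        return SelectionResult(vif, linearity, [], [], fit_intercept_only(y))
    fit, trail = stepwise_backward(pruned[screened], y, stepwise_alpha)
    return SelectionResult(vif, linearity, screened, trail, fit)


def _screen_and_step(table: pd.DataFrame, y: np.ndarray,
                     screen_alpha: float, stepwise_alpha: float) -> LogisticFit:
    screened = univariable_screen(table, y, screen_alpha)
    if not screened:
        return fit_intercept_only(y)
    fit, _ = stepwise_backward(table[screened], y, stepwise_alpha)
    return fit


def _linear_predictor(fit: LogisticFit, table: pd.DataFrame) -> np.ndarray:
    if fit.is_intercept_only:
        return np.zeros(len(table))
    X = np.column_stack([np.ones(len(table))]
                        + [table[c].to_numpy(float) for c in fit.features])
    return X @ fit.coefficients


def bootstrap_optimism(table: pd.DataFrame, y: np.ndarray, B: int,
                       rng: np.random.Generator,
                       screen_alpha: float = SCREEN_ALPHA,
                       stepwise_alpha: float = STEPWISE_ALPHA
                       ) -> dict[str, float]:
    """Harrell's optimism-corrected AUC with backward step-down re-selection.

    Every bootstrap resample reruns screening and stepwise selection from
    scratch; optimism is the mean of (bootstrap-apparent minus
    test-on-original) AUC.  Resamples missing a class are redrawn (counted in
    ``redraws``).
    """
    y = np.asarray(y, float)
    apparent_fit = _screen_and_step(table, y, screen_alpha, stepwise_alpha)
    if apparent_fit.is_intercept_only:
        # a constant model discriminates at exactly 0.5 and has no fitted
        # structure to over-fit: the optimism correction is vacuous
        return {"apparent_auc": 0.5, "optimism": 0.0, "corrected_auc": 0.5,
                "n_boot": 0.0, "redraws": 0.0}
    apparent = compute_auc(_linear_predictor(apparent_fit, table), y)[0]
    n = len(y)
    optimisms = []
    redraws = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            redraws += 1
        tb = table.iloc[idx].reset_index(drop=True)
        fit_b = _screen_and_step(tb, yb, screen_alpha, stepwise_alpha)
        auc_boot = compute_auc(_linear_predictor(fit_b, tb), yb)[0]
        auc_orig = compute_auc(_linear_predictor(fit_b, table), y)[0]
        optimisms.append(auc_boot - auc_orig)
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return {"apparent_auc": float(apparent), "optimism": optimism,
            "corrected_auc": float(apparent - optimism),
            "n_boot": float(len(optimisms)), "redraws": float(redraws)}


# ---------------------------------------------------------------------------
# sensitivity analysis: standard vs instrumented vs combined

@dataclass
class SensitivityResult:
    """Three fitted models for one test plus their pairwise DeLong comparisons."""

    standard_fit: LogisticFit
    instrumented: SelectionResult
    combined_fit: LogisticFit
    auc_standard: tuple[float, tuple[float, float]]
    auc_instrumented: tuple[float, tuple[float, float]]
    auc_combined: tuple[float, tuple[float, float]]
    comparisons: dict[str, RocComparison]


def run_sensitivity(instrumented_table: pd.DataFrame,
                    standard_measure: pd.Series,
                    instrumented_standard: pd.Series,
                    y: np.ndarray,
                    screen_alpha: float = SCREEN_ALPHA,
                    stepwise_alpha: float = STEPWISE_ALPHA,
                    vif_threshold: float = VIF_THRESHOLD,
                    check_linearity: bool = True) -> SensitivityResult:
    """Standard-clinical, instrumented and combined models for one test.

    ``instrumented_table`` holds the preprocessed candidate features with the
    sensor-derived repetition count / total duration already excluded;
    ``standard_measure`` is the assessor-recorded outcome (z-scored here);
    ``instrumented_standard`` is the sensor-derived repetition count or total
    duration added to the final instrumented model to form the combined model.
    """
    y = np.asarray(y, float)

    def z(s: pd.Series) -> pd.Series:
        return (s - s.mean()) / s.std(ddof=1)

    std_df = pd.DataFrame({"standard": z(standard_measure.astype(float))})
    standard_fit = fit_logistic(std_df, y)

    instrumented = select_and_fit(instrumented_table, y, screen_alpha,
                                  stepwise_alpha, vif_threshold,
                                  check_linearity)

    combined_cols = instrumented_table[instrumented.fit.features].copy() \
        if instrumented.fit.features else pd.DataFrame(index=instrumented_table.index)
    combined_cols["instrumented_standard"] = z(instrumented_standard.astype(float))
    combined_fit = fit_logistic(combined_cols, y)

    s_std = _linear_predictor(standard_fit, std_df)
    s_ins = _linear_predictor(instrumented.fit, instrumented_table)
    s_com = _linear_predictor(combined_fit, combined_cols)

    auc_std = compute_auc(s_std, y)[:2]
    auc_ins = compute_auc(s_ins, y)[:2]
    auc_com = compute_auc(s_com, y)[:2]
    comparisons = {
        "standard_vs_instrumented": delong_test(s_std, s_ins, y),
        "instrumented_vs_combined": delong_test(s_ins, s_com, y),
        "standard_vs_combined": delong_test(s_std, s_com, y),
    }
    return SensitivityResult(standard_fit=standard_fit,
                             instrumented=instrumented,
                             combined_fit=combined_fit,
                             auc_standard=auc_std,
                             auc_instrumented=auc_ins,
                             auc_combined=auc_com,
                             comparisons=comparisons)
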