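"""Feature-table statistics: correlation maps, random-forest variable
importance, group tests, ROC cut-offs and survival models.

The chain mirrors how dual-modality heterogeneity features are taken to a
prognostic conclusion: Spearman correlation matrices between slide and PET
features, a bagged-CART random forest with out-of-bag (OOB) error and
mean-decrease-accuracy importance for the binary event-within-horizon
label, Mann-Whitney comparisons of the important variables between outcome
groups, ROC analyses with Youden-index cut-offs, Kaplan-Meier / log-rank
univariable survival at those cut-offs, and a multivariable Cox model.

Random-forest trees and bagging come from scikit-learn; Kaplan-Meier,
log-rank and the Cox partial-likelihood fit (Efron ties) come from
lifelines. The OOB permutation importance, the Hanley-McNeil ROC
machinery, the Youden tie rules and the global score test are implemented
here on top of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test, proportional_hazard_test

__all__ = [
    "CorrelationMatrix",
    "ImportanceReport",
    "RocResult",
    "KmLogrankResult",
    "CoxResult",
    "PipelineConfig",
    "spearman_matrix",
    "rf_importance",
    "mann_whitney",
    "roc_youden",
    "km_logrank",
    "cox_fit",
    "cohort_summary",
    "run_paper_pipeline",
    "encode_covariates",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = (
    "id",
    "age",
    "clinical_stage",
    "grade",
    "histology",
    "molecular_subtype",
    "followup_time",
    "event",
    "efs8_event",
)

_ORDINAL = {"I": 1, "II": 2, "III": 3}


@dataclass(frozen=True)
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean, raw p < alpha

    def as_dict(self) -> dict:
        return {
            "rho": self.rho.to_dict(),
            "p": self.p.to_dict(),
            "significant": self.significant.to_dict(),
        }


@dataclass(frozen=True)
class ImportanceReport:
    oob_error: float
    mean_decrease_accuracy: pd.Series  # indexed by variable
    n_trees: int
    seed: int

    def top(self, k: int) -> list[str]:
        return list(self.mean_decrease_accuracy.sort_values(ascending=False).index[:k])


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    p_value: float  # normal test of AUC = 0.5
    cutoff: float
    direction: str  # ">": score > cutoff predicts the event
    youden_j: float


@dataclass(frozen=True)
class KmLogrankResult:
    curves: dict  # group -> survival step function as a DataFrame
    logrank_chi2: float
    logrank_p: float
    group_sizes: dict


@dataclass(frozen=True)
class CoxResult:
    summary: pd.DataFrame  # per covariate: coef, se, wald_chi2, p, hr, hr ci
    global_tests: pd.DataFrame  # likelihood_ratio / score / wald with df, p
    ph_check: pd.DataFrame  # per covariate proportional-hazards test p


def spearman_matrix(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> CorrelationMatrix:
    """Spearman correlation matrix between two variable blocks.

    Mid-rank Spearman rho per (row variable, column variable) with
    pairwise deletion of missing values; two-sided p via the t
    approximation. Cells with fewer than ``min_pairs`` complete pairs are
    reported missing.
    """
    rho = pd.DataFrame(index=table_a.columns, columns=table_b.columns, dtype=float)
    pmat = rho.copy()
    for ca in table_a.columns:
        for cb in table_b.columns:
            x = pd.to_numeric(table_a[ca], errors="coerce")
            y = pd.to_numeric(table_b[cb], errors="coerce")
            ok = x.notna() & y.notna()
            if int(ok.sum()) < min_pairs:
                continue
            res = sps.spearmanr(x[ok], y[ok])
            rho.loc[ca, cb] = res.statistic
            pmat.loc[ca, cb] = res.pvalue
    return CorrelationMatrix(rho, pmat, pmat < alpha)


def _oob_predictions(
    forest: BaggingClassifier, x: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient OOB majority-vote prediction (nan where never OOB)."""
    votes = np.zeros((n, 2))
    for tree, in_bag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size == 0:
            continue
        pred = tree.predict(x[oob])
        votes[oob, 0] += pred == 0
        votes[oob, 1] += pred == 1
    has = votes.sum(axis=1) > 0
    pred = np.where(votes[:, 1] > votes[:, 0], 1, 0)
    return pred, has


def rf_importance(
    x: pd.DataFrame, y: np.ndarray | pd.Series, n_trees: int = 100, seed: int = 0
) -> ImportanceReport:
    """Bagged-CART classification with OOB error and permutation importance.

    One hundred (by default) unpruned CART trees on bootstrap resamples.
    ``oob_error`` is the misclassification rate of the out-of-bag majority
    vote. ``mean_decrease_accuracy`` per variable is the mean over trees of
    the drop in that tree's OOB accuracy after permuting the variable among
    the tree's OOB rows (Breiman's importance). Fully seeded.
    """
    y = np.asarray(y).astype(int)
    if x.shape[0] < 10:
        raise ValueError("random-forest importance requires at least 10 patients")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; importance is undefined")
    xm = x.to_numpy(dtype=float)
    n = xm.shape[0]
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
    ).fit(xm, y)

    pred, has = _oob_predictions(forest, xm, n)
    oob_error = float(np.mean(pred[has] != y[has])) if has.any() else float("nan")

    rng = np.random.default_rng(seed)
    decreases = np.zeros((n_trees, xm.shape[1]))
    for t, (tree, in_bag) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size == 0:
            decreases[t] = np.nan
            continue
        base_acc = np.mean(tree.predict(xm[oob]) == y[oob])
        for v in range(xm.shape[1]):
            xp = xm[oob].copy()
            xp[:, v] = xp[rng.permutation(oob.size), v]
            decreases[t, v] = base_acc - np.mean(tree.predict(xp) == y[oob])
    mda = pd.Series(np.nanmean(decreases, axis=0), index=x.columns)
    return ImportanceReport(oob_error, mda, n_trees, seed)


def mann_whitney(group0: np.ndarray, group1: np.ndarray) -> dict[str, float]:
    """Mann-Whitney U with mid-rank ties and a two-sided p.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie-corrected variance (no continuity correction).
    Two single-value tied groups give U = 0.5 and p = 1.
    """
    g0 = np.asarray(group0, dtype=float)
    g1 = np.asarray(group1, dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g0, g1])
    if np.unique(pooled).size == 1:
        return {"U": g0.size * g1.size / 2.0, "p": 1.0}
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(g0.size, g1.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(
        g0, g1, alternative="two-sided", method=method, use_continuity=False
    )
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_youden(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Empirical ROC with trapezoidal AUC and a Youden-index cut-off.

    AUC equals the mid-rank U statistic divided by n0*n1; its standard
    error follows Hanley-McNeil and the 95% CI is the normal interval
    truncated to [0, 1]. The direction is chosen so AUC >= 0.5. The cut-off
    is the observed score maximizing J = sensitivity + specificity - 1
    under the rule "event-positive iff score >= cutoff" (direction ">") or
    "<= cutoff" (direction "<"); ties in J break toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    direction = ">"
    if auc < 0.5:
        direction, auc, s_eff = "<", 1.0 - auc, -s
    else:
        s_eff = s

    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    lo, hi = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)
    z = (auc - 0.5) / se if se > 0 else np.inf
    p = float(2 * sps.norm.sf(abs(z)))

    best_j, best_cut, best_spec = -np.inf, float("nan"), -np.inf
    for cut in np.unique(s_eff):
        pred = s_eff >= cut
        sens = float(pred[y == 1].mean())
        spec = float((~pred[y == 0]).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and spec > best_spec):
            best_j, best_cut, best_spec = j, float(cut), spec
    cutoff = best_cut if direction == ">" else -best_cut
    return RocResult(auc, se, (lo, hi), p, cutoff, direction, best_j)


def km_logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> KmLogrankResult:
    """Per-group Kaplan-Meier curves and the two-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if event.sum() < 1:
        raise ValueError("log-rank requires at least one event")
    curves, sizes = {}, {}
    for g in labels:
        sel = group == g
        if not sel.any():
            raise ValueError(f"group {g!r} has no subjects")
        km = KaplanMeierFitter().fit(time[sel], event[sel], label=str(g))
        curves[str(g)] = km.survival_function_
        sizes[str(g)] = int(sel.sum())
    if labels.size != 2:
        raise ValueError("log-rank comparison needs exactly two groups")
    res = logrank_test(
        time[group == labels[0]],
        time[group == labels[1]],
        event[group == labels[0]],
        event[group == labels[1]],
    )
    return KmLogrankResult(curves, float(res.test_statistic), float(res.p_value), sizes)


def _efron_score_info(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score vector and information matrix of the Efron partial likelihood."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    n, k = x.shape
    eta = x @ beta
    w = np.exp(eta)
    score = np.zeros(k)
    info = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        d_idx = np.where((time == t) & (event == 1))[0]
        r_idx = np.where(time >= t)[0]
        d = d_idx.size
        sw_r = w[r_idx].sum()
        sx_r = (w[r_idx, None] * x[r_idx]).sum(axis=0)
        sxx_r = (w[r_idx, None, None] * x[r_idx, :, None] * x[r_idx, None, :]).sum(axis=0)
        sw_d = w[d_idx].sum()
        sx_d = (w[d_idx, None] * x[d_idx]).sum(axis=0)
        sxx_d = (w[d_idx, None, None] * x[d_idx, :, None] * x[d_idx, None, :]).sum(axis=0)
        score += x[d_idx].sum(axis=0)
        for l in range(d):
            c = l / d
            sw = sw_r - c * sw_d
            sx = sx_r - c * sx_d
            sxx = sxx_r - c * sxx_d
            score -= sx / sw
            info += sxx / sw - np.outer(sx, sx) / sw**2
    return score, info


def _efron_loglik(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> float:
    """Efron-tie partial log-likelihood."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    eta = x @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d_idx = np.where((time == t) & (event == 1))[0]
        r_idx = np.where(time >= t)[0]
        d = d_idx.size
        sw_r, sw_d = w[r_idx].sum(), w[d_idx].sum()
        ll += eta[d_idx].sum()
        for l in range(d):
            ll -= np.log(sw_r - (l / d) * sw_d)
    return float(ll)


def cox_fit(
    covariates: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> CoxResult:
    """Multivariable Cox proportional-hazards fit with Efron ties.

    Reports per-covariate coefficients, Wald chi-squares, hazard ratios
    with 95% CIs; global likelihood-ratio, score and Wald tests (df = number
    of covariates); and a proportional-hazards check from scaled Schoenfeld
    residuals against (rank) time. Non-convergence raises an explicit error.
    """
    cov = covariates.astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    k = cov.shape[1]
    if int(event.sum()) < k + 1:
        raise ValueError("fewer events than covariates + 1")
    if (cov.nunique() <= 1).any():
        bad = list(cov.columns[cov.nunique() <= 1])
        raise ValueError(f"constant covariates: {bad}")
    df = cov.copy()
    df["_time"], df["_event"] = time, event
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            fitter.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"precision": 1e-9},
            )
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    coefs = fitter.params_.to_numpy()
    ses = fitter.standard_errors_.to_numpy()
    xmat = cov.to_numpy()
    sd = xmat.std(axis=0)
    # a standardized log-HR beyond 15 per unit sd means separation in practice
    if (
        (np.abs(coefs * sd) > 15).any()
        or not np.isfinite(ses).all()
        or (ses * sd > 1e3).any()
    ):
        raise RuntimeError(
            "Cox model did not converge to an interior maximum (monotone "
            "partial likelihood / separation); estimates are unreliable"
        )

    # polish to the exact partial-likelihood maximum: lifelines' adaptive
    # step size can stop ~1e-4 short of the root on very small datasets;
    # work on centered unit-variance covariates and damp steps
    xs = (xmat - xmat.mean(axis=0)) / sd
    beta = coefs * sd
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _efron_loglik(xs, time, event, beta)
            for _ in range(50):
                score, info = _efron_score_info(xs, time, event, beta)
                step = np.linalg.solve(info, score)
                for _ in range(30):  # halve until the likelihood does not drop
                    ll_new = _efron_loglik(xs, time, event, beta + step)
                    if ll_new >= ll - 1e-12:
                        break
                    step = step / 2.0
                beta = beta + step
                ll = ll_new
                if np.linalg.norm(step) < 1e-12:
                    break
            if not np.isfinite(beta).all() or np.abs(beta).max() > 15:
                # likelihood still climbing at an extreme standardized log-HR
                raise RuntimeError(
                    "Cox model did not converge to an interior maximum "
                    "(monotone partial likelihood / separation)"
                )
            _, info = _efron_score_info(xs, time, event, beta)
            variance = np.linalg.inv(info) / np.outer(sd, sd)
            beta = beta / sd
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    se = np.sqrt(np.diag(variance))
    wald = (beta / se) ** 2
    z975 = sps.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "wald_chi2": wald,
            "p": sps.chi2.sf(wald, 1),
            "hr": np.exp(beta),
            "hr_ci_lo": np.exp(beta - z975 * se),
            "hr_ci_hi": np.exp(beta + z975 * se),
        },
        index=cov.columns,
    )

    lr_chi2 = 2.0 * (
        _efron_loglik(xmat, time, event, beta)
        - _efron_loglik(xmat, time, event, np.zeros(k))
    )
    score0, info0 = _efron_score_info(xmat, time, event, np.zeros(k))
    score_chi2 = float(score0 @ np.linalg.solve(info0, score0))
    wald_chi2 = float(beta @ np.linalg.solve(variance, beta))
    global_tests = pd.DataFrame(
        {
            "chi2": [lr_chi2, score_chi2, wald_chi2],
            "df": [k, k, k],
        },
        index=["likelihood_ratio", "score", "wald"],
    )
    global_tests["p"] = sps.chi2.sf(global_tests["chi2"], global_tests["df"])

    ph = proportional_hazard_test(fitter, df, time_transform="rank")
    ph_check = ph.summary[["test_statistic", "p"]].copy()
    return CoxResult(summary, global_tests, ph_check)


def cohort_summary(table: pd.DataFrame, horizon: float = 8.0) -> dict:
    """Category counts with percentages and the crude event-free proportion.

    Percentages are 100*n/N rounded to one decimal. The crude event-free
    proportion at the horizon is 100*(1 - events/N); the Kaplan-Meier
    estimate at the horizon is reported alongside when follow-up data allow.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    n = len(table)
    out: dict = {"n": n, "categories": {}}
    for col in ("clinical_stage", "grade", "histology", "molecular_subtype"):
        if col in table.columns:
            counts = table[col].value_counts()
            out["categories"][col] = {
                str(k): {"n": int(v), "pct": round(100.0 * v / n, 1)}
                for k, v in counts.items()
            }
    if "efs8_event" in table.columns:
        events = int(table["efs8_event"].sum())
    elif "event" in table.columns:
        events = int(table["event"].sum())
    else:
        events = 0
    out["events"] = events
    out["event_free_pct_crude"] = round(100.0 * (1 - events / n), 1)
    if {"followup_time", "event"}.issubset(table.columns) and table["event"].sum() > 0:
        km = KaplanMeierFitter().fit(table["followup_time"], table["event"])
        out["event_free_pct_km"] = round(
            100.0 * float(km.predict(min(horizon, table["followup_time"].max()))), 1
        )
    return out


def encode_covariates(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Integer-ordinal encoding of stage/grade and categorical codes.

    Stage and grade map I/II/III -> 1/2/3 (they are genuinely ordinal);
    other object columns are encoded as stable category codes.
    """
    out = pd.DataFrame(index=table.index)
    for col in columns:
        s = table[col]
        if s.dtype == object:
            if set(s.dropna().unique()) <= set(_ORDINAL):
                out[col] = s.map(_ORDINAL).astype(float)
            else:
                out[col] = s.astype("category").cat.codes.astype(float)
        else:
            out[col] = pd.to_numeric(s, errors="coerce")
    return out


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_trees: int = 100
    horizon: float = 8.0
    alpha: float = 0.05
    max_selected: int = 7  # cap on variables carried past the forest
    ihc_prefixes: tuple[str, ...] = ("skewness", "kurtosis", "entropy_er",
                                     "energy", "contrast_er", "homogeneity",
                                     "dissimilarity", "correlation_er")
    stage_binary_split: str = "III"  # stage I-II versus III in the Cox model


def _feature_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in CLINICAL_COLUMNS]


def run_paper_pipeline(cohort: pd.DataFrame, config: PipelineConfig = PipelineConfig()) -> dict:
    """Full statistical chain from a cohort table to a prognostic report.

    Stages, in order: Spearman correlation map between the slide-derived
    and PET-derived feature blocks; random-forest variable importance for
    the event-within-horizon label (clinical + all features); Mann-Whitney
    comparison of the selected variables between outcome groups; ROC with
    Youden cut-off for the significantly different ones; Kaplan-Meier /
    log-rank at each cut-off; multivariable Cox with age, stage (I-II vs
    III) and the KM-significant features. Each stage's output lands in one
    structured, JSON-serializable report.
    """
    report: dict = {"config": {"seed": config.seed, "n_trees": config.n_trees,
                               "horizon": config.horizon, "alpha": config.alpha}}
    feats = _feature_columns(cohort)
    ihc_cols = [c for c in feats if c.endswith("_er") or c.endswith("_pr")
                or c in ("skewness_er", "kurtosis_er")]
    pet_cols = [c for c in feats if c not in ihc_cols]
    if ihc_cols and pet_cols:
        corr = spearman_matrix(cohort[ihc_cols], cohort[pet_cols], alpha=config.alpha)
        report["spearman"] = corr.as_dict()

    label = cohort["efs8_event"].to_numpy(int)
    rf_cols = ["age", "clinical_stage", "grade", "histology", "molecular_subtype"]
    rf_cols = [c for c in rf_cols if c in cohort.columns] + feats
    x = encode_covariates(cohort, rf_cols)
    imp = rf_importance(x, label, n_trees=config.n_trees, seed=config.seed)
    report["random_forest"] = {
        "oob_error": imp.oob_error,
        "mean_decrease_accuracy": imp.mean_decrease_accuracy.to_dict(),
    }
    selected = [
        v for v in imp.top(config.max_selected)
        if imp.mean_decrease_accuracy[v] > 0 and v in feats
    ]
    report["selected_variables"] = selected

    mw, significant = {}, []
    for v in selected:
        vals = cohort[v].to_numpy(float)
        res = mann_whitney(vals[label == 0], vals[label == 1])
        mw[v] = res
        if res["p"] < config.alpha:
            significant.append(v)
    report["mann_whitney"] = mw

    roc_table, km_results = {}, {}
    cox_candidates = []
    for v in significant:
        roc = roc_youden(cohort[v].to_numpy(float), label)
        roc_table[v] = {
            "auc": roc.auc, "se": roc.auc_se, "ci95_lo": roc.ci95[0],
            "ci95_hi": roc.ci95[1], "p": roc.p_value,
            "cutoff": roc.cutoff, "direction": roc.direction,
            "youden_j": roc.youden_j,
        }
        split = (
            cohort[v].to_numpy(float) >= roc.cutoff
            if roc.direction == ">"
            else cohort[v].to_numpy(float) <= roc.cutoff
        )
        if split.all() or (~split).all():
            continue
        km = km_logrank(
            cohort["followup_time"].to_numpy(float),
            cohort["event"].to_numpy(int),
            split.astype(int),
        )
        km_results[v] = {
            "logrank_chi2": km.logrank_chi2,
            "logrank_p": km.logrank_p,
            "group_sizes": km.group_sizes,
        }
        if km.logrank_p < config.alpha:
            cox_candidates.append(v)
    report["roc"] = roc_table
    report["km_logrank"] = km_results

    cox_cov = pd.DataFrame(index=cohort.index)
    cox_cov["age"] = cohort["age"].astype(float)
    cox_cov["stage_iii"] = (
        cohort["clinical_stage"] == config.stage_binary_split
    ).astype(float)
    for v in cox_candidates:
        cox_cov[v] = cohort[v].astype(float)
    try:
        cox = cox_fit(
            cox_cov,
            cohort["followup_time"].to_numpy(float),
            cohort["event"].to_numpy(int),
        )
        report["cox"] = {
            "summary": cox.summary.to_dict(),
            "global_tests": cox.global_tests.to_dict(),
            "ph_check": cox.ph_check.to_dict(),
        }
    except (ValueError, RuntimeError) as exc:
        report["cox"] = {"error": f"cox stage failed: {exc}"}
    return report
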