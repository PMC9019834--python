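"""Group-level inference: mixed-effects models, paired and ordinal tests,
FDR, and follow-up contrasts.

The central model is a random-intercept linear mixed model fit by REML,
with marginal (drop-one) F tests for each single-df fixed term.  The
denominator-df convention is the grouping-level rule: within-subject
terms use ``n_obs - n_subjects - p_within`` and subject-level terms use
``n_subjects - p_between - 1`` (with 200 observations, 50 subjects and
three within-subject terms this yields F(1, 147); with four subject-level
covariates, F(1, 45)).

Factors are sum-coded (+/-0.5) and continuous covariates mean-centered,
so each single-df Wald test is an average-effect test; interaction tests
are invariant to this choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Term",
    "ModelResult",
    "CONNECTIVITY_TERMS",
    "BEHAVIOR_TERMS",
    "encode_design",
    "fit_lmm",
    "paired_t",
    "wilcoxon_signed_rank",
    "spearman",
    "fdr_bh",
    "vif",
    "partial_corr",
    "run_connectivity_models",
    "run_behavior_models",
    "run_brain_behavior_models",
    "quartile_contrast",
    "subsample_reanalysis",
]


@dataclass(frozen=True)
class Term:
    name: str
    within: bool  # varies within subject?


#: fixed effects for the connectivity models: social, mentalizing, age,
#: social x age, plus gender / mean FD / IQ as covariates of no interest
CONNECTIVITY_TERMS = (
    Term("social", True),
    Term("mentalizing", True),
    Term("age", False),
    Term("social:age", True),
    Term("gender", False),
    Term("mean_fd", False),
    Term("iq", False),
)

#: in-scanner behaviour models omit mean FD
BEHAVIOR_TERMS = (
    Term("social", True),
    Term("mentalizing", True),
    Term("age", False),
    Term("social:age", True),
    Term("gender", False),
    Term("iq", False),
)


@dataclass
class ModelResult:
    model: str
    outcome: str
    terms: pd.DataFrame  # term, estimate, se, F, df1, df2, p
    n_obs: int
    n_subjects: int
    converged: bool = True
    engine: str = "mixedlm"
    vif: pd.DataFrame | None = None
    posthoc: dict = field(default_factory=dict)

    def p(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    def estimate(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])

    def F(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "F"])


# -- design encoding ----------------------------------------------------

def encode_design(df: pd.DataFrame, center: pd.DataFrame | None = None) -> pd.DataFrame:
    """Numeric-code a long table for model fitting.

    social: Peer +0.5 / Character -0.5; mentalizing: Mental +0.5 /
    Non-Mental -0.5; gender: M +0.5 / F -0.5; age, iq, mean_fd, rt and
    report scores are mean-centered (means taken from ``center`` if
    given, so post-hoc subsets reuse the full-sample centering).
    """
    out = df.copy()
    ref = center if center is not None else df
    if "social" in out and out["social"].dtype == object:
        out["social"] = out["social"].map({"Peer": 0.5, "Character": -0.5})
    if "mentalizing" in out and out["mentalizing"].dtype == object:
        out["mentalizing"] = out["mentalizing"].map(
            {"Mental": 0.5, "Non-Mental": -0.5}
        )
    if "gender" in out and out["gender"].dtype == object:
        out["gender"] = out["gender"].map({"M": 0.5, "F": -0.5})
    for col in ("age", "iq", "mean_fd", "rt", "behavior", "accuracy"):
        if col in out and col in ref:
            out[col] = out[col] - float(pd.to_numeric(ref[col]).mean())
    return out


def _term_matrix(df: pd.DataFrame, terms: tuple[Term, ...]) -> np.ndarray:
    cols = []
    for t in terms:
        if ":" in t.name:
            a, b = t.name.split(":")
            cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        else:
            cols.append(df[t.name].to_numpy(float))
    return np.column_stack(cols)


# -- the mixed model ----------------------------------------------------

def _df_denominator(terms, n_obs: int, n_subj: int) -> dict[str, int]:
    p_within = sum(t.within for t in terms)
    p_between = sum(not t.within for t in terms)
    df_w = n_obs - n_subj - p_within
    df_b = n_subj - p_between - 1
    return {t.name: (df_w if t.within else df_b) for t in terms}


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    terms: tuple[Term, ...] = CONNECTIVITY_TERMS,
    group: str = "subject_id",
    engine: str = "mixedlm",
    model_name: str | None = None,
) -> ModelResult:
    """Random-intercept linear mixed model with per-term marginal F tests.

    ``engine="mixedlm"`` fits by REML via statsmodels; ``engine="split"``
    uses the exact closed form for balanced designs (within-subject terms
    estimated on subject-demeaned data, subject-level terms on subject
    means), which coincides with REML when every subject contributes a
    complete, identical within-subject design.
    """
    data = data.dropna(subset=[outcome]).reset_index(drop=True)
    y = data[outcome].to_numpy(float)
    X = _term_matrix(data, terms)
    groups = data[group].to_numpy()
    n_obs = len(y)
    n_subj = len(np.unique(groups))
    if n_obs < n_subj * 2:
        raise ValueError("need >= 2 observations per subject for within terms")
    dfs = _df_denominator(terms, n_obs, n_subj)
    if min(dfs.values()) < 1:
        raise ValueError(
            f"too few subjects/observations for the requested terms "
            f"(denominator df {min(dfs.values())})"
        )
    name = model_name or outcome

    if engine == "split":
        est, se = _fit_split(y, X, groups, terms)
        converged = True
    elif engine == "mixedlm":
        est, se, converged = _fit_mixedlm(y, X, groups)
        if est is None:  # singular fit: fall back to OLS with a warning
            warnings.warn(
                f"mixed model for {name!r} did not converge; falling back to OLS",
                stacklevel=2,
            )
            Xc = np.column_stack([np.ones(n_obs), X])
            beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            resid = y - Xc @ beta
            sigma2 = resid @ resid / (n_obs - Xc.shape[1])
            cov = sigma2 * np.linalg.pinv(Xc.T @ Xc)
            est, se = beta[1:], np.sqrt(np.diag(cov))[1:]
            converged = False
    else:
        raise ValueError(f"unknown engine {engine!r}")

    rows = []
    for j, t in enumerate(terms):
        tval = est[j] / se[j]
        F = tval**2
        df2 = dfs[t.name]
        p = float(sps.f.sf(F, 1, df2))
        rows.append(
            {
                "term": t.name,
                "estimate": float(est[j]),
                "se": float(se[j]),
                "F": float(F),
                "df1": 1,
                "df2": int(df2),
                "p": p,
            }
        )
    vif_table = (
        vif(pd.DataFrame(X, columns=[t.name for t in terms]))
        if X.shape[1] >= 2
        else None
    )
    return ModelResult(
        model=name,
        outcome=outcome,
        terms=pd.DataFrame(rows),
        n_obs=n_obs,
        n_subjects=n_subj,
        converged=converged,
        engine=engine,
        vif=vif_table,
    )


def _fit_split(y, X, groups, terms):
    """Exact balanced-design decomposition (within / between projection)."""
    uniq, inv = np.unique(groups, return_inverse=True)
    n_subj = len(uniq)
    counts = np.bincount(inv).astype(float)
    y_mean = np.bincount(inv, weights=y) / counts
    X_mean = np.column_stack(
        [np.bincount(inv, weights=X[:, j]) / counts for j in range(X.shape[1])]
    )
    yw = y - y_mean[inv]
    Xw = X - X_mean[inv]

    within_idx = [j for j, t in enumerate(terms) if t.within]
    between_idx = [j for j, t in enumerate(terms) if not t.within]
    est = np.empty(X.shape[1])
    se = np.empty(X.shape[1])

    if within_idx:
        Xw_ = Xw[:, within_idx]
        beta, *_ = np.linalg.lstsq(Xw_, yw, rcond=None)
        resid = yw - Xw_ @ beta
        df_w = len(y) - n_subj - len(within_idx)
        sigma2 = resid @ resid / df_w
        cov = sigma2 * np.linalg.pinv(Xw_.T @ Xw_)
        est[within_idx] = beta
        se[within_idx] = np.sqrt(np.diag(cov))
    if between_idx:
        Xb = np.column_stack([np.ones(n_subj), X_mean[:, between_idx]])
        beta, *_ = np.linalg.lstsq(Xb, y_mean, rcond=None)
        resid = y_mean - Xb @ beta
        df_b = n_subj - len(between_idx) - 1
        sigma2 = resid @ resid / df_b
        cov = sigma2 * np.linalg.pinv(Xb.T @ Xb)
        est[between_idx] = beta[1:]
        se[between_idx] = np.sqrt(np.diag(cov))[1:]
    return est, se


def _fit_mixedlm(y, X, groups):
    """statsmodels REML random-intercept fit; (None, None, False) if singular."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    Xc = np.column_stack([np.ones(len(y)), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            model = sm.MixedLM(y, Xc, groups=groups)
            res = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError):
            return None, None, False
    if not np.isfinite(res.params).all() or not np.isfinite(res.bse).all():
        return None, None, False
    est = np.asarray(res.fe_params)[1:]
    se = np.asarray(res.bse_fe)[1:]
    if not np.isfinite(se).all() or (se == 0).any():
        return None, None, False
    return est, se, bool(res.converged)


# -- elementary tests ---------------------------------------------------

def paired_t(x, y, tail: str = "two-sided") -> tuple[float, int, float]:
    """Paired t-test; returns (t, df, p).

    ``tail`` is "two-sided", "greater" (x > y) or "less".
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired samples must have equal length >= 3")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(x, y, alternative=tail)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def wilcoxon_signed_rank(x, y, tail: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns (W, p).

    Zero differences are dropped; tied absolute differences get average
    ranks.  For n <= 25 retained pairs the p-value is exact (distribution
    of the positive-rank sum over all 2^n sign assignments, computed by
    dynamic programming over the doubled rank sums, valid under ties);
    larger n uses the normal approximation with tie-corrected variance
    and a 0.5 continuity correction.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= 25:
        # doubled ranks are integers even with average ties
        r2 = np.rint(2 * ranks).astype(int)
        total = r2.sum()
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: counts.size - r].copy()
        counts /= 2.0**n
        w2 = int(round(2 * w_pos))
        cdf = counts[: w2 + 1].sum()
        sf = counts[w2:].sum()
        if tail == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif tail == "greater":  # x tends larger -> large W+
            p = sf
        elif tail == "less":
            p = cdf
        else:
            raise ValueError(f"unknown tail {tail!r}")
        return w_pos, float(p)

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if tail == "two-sided":
        z = (abs(w_pos - mean) - 0.5) / np.sqrt(var)
        p = 2 * sps.norm.sf(z)
    elif tail == "greater":
        z = (w_pos - mean - 0.5) / np.sqrt(var)
        p = sps.norm.sf(z)
    elif tail == "less":
        z = (w_pos - mean + 0.5) / np.sqrt(var)
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return w_pos, float(min(1.0, p))


def spearman(x, y, tail: str = "two-sided") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input")
    res = sps.spearmanr(x, y, alternative=tail)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def vif(X: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors, 1 / (1 - R^2_j), per predictor."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    vals = X.to_numpy(float)
    out = []
    for j, name in enumerate(X.columns):
        yj = vals[:, j]
        others = np.column_stack(
            [np.ones(len(yj)), np.delete(vals, j, axis=1)]
        )
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"predictor": name, "vif": float(v), "flag": bool(v > 2)})
    return pd.DataFrame(out)


def partial_corr(x, y, covar) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.column_stack([np.ones(len(x)), np.asarray(covar, float)])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = len(x) - Z.shape[1] - 1
    t = r * np.sqrt(df / (1 - r**2))
    return r, float(2 * sps.t.sf(abs(t), df))


def _ols_age_posthoc(sub: pd.DataFrame, outcome: str, predictor: str,
                     covariates: list[str]) -> dict:
    """Per-condition OLS follow-up: outcome ~ predictor + covariates."""
    cols = [predictor] + covariates
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in cols])
    y = sub[outcome].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df2 = len(y) - X.shape[1]
    sigma2 = resid @ resid / df2
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / np.sqrt(cov[1, 1])
    return {
        "estimate": float(beta[1]),
        "F": float(t**2),
        "df1": 1,
        "df2": int(df2),
        "p": float(sps.f.sf(t**2, 1, df2)),
    }


# -- model batteries ----------------------------------------------------

NETWORK_OUTCOMES = ("within_mentalizing", "within_reward", "between")


def run_connectivity_models(
    long_table: pd.DataFrame,
    node_table: pd.DataFrame | None = None,
    engine: str = "mixedlm",
    alpha: float = 0.05,
    outcomes: tuple[str, ...] | None = None,
) -> dict:
    """The full connectivity battery.

    Three network-level models (within mentalizing, within reward,
    between networks), optional node-strength models with BH-FDR across
    the node x strength family, and per-condition age post-hocs.

    ``long_table``: one row per subject x condition with the outcome
    columns plus social, mentalizing, age, gender, mean_fd, iq.
    ``node_table``: long format with columns roi, strength_type
    ("within"/"between"), value, plus the same covariates.
    """
    if outcomes is None:
        outcomes = tuple(
            c for c in long_table.columns
            if c.startswith("within_") or c == "between"
        ) or NETWORK_OUTCOMES
    enc = encode_design(long_table)
    results: dict = {"network": {}, "node": None, "posthoc_age": {}}
    for outcome in outcomes:
        if outcome not in enc:
            continue
        try:
            res = fit_lmm(enc, outcome, CONNECTIVITY_TERMS, engine=engine)
        except Exception as exc:  # propagate per-model failures without aborting
            results["network"][outcome] = exc
            continue
        results["network"][outcome] = res
        # post-hoc: per social level, connectivity ~ age + gender + fd + iq
        posthoc = {}
        for social, sval in (("Peer", 0.5), ("Character", -0.5)):
            sub = enc[enc["social"] == sval]
            collapsed = (
                sub.groupby("subject_id")
                .agg({outcome: "mean", "age": "first", "gender": "first",
                      "mean_fd": "first", "iq": "first"})
                .reset_index()
            )
            posthoc[social] = _ols_age_posthoc(
                collapsed, outcome, "age", ["gender", "mean_fd", "iq"]
            )
        res.posthoc = posthoc
        results["posthoc_age"][outcome] = posthoc

    if node_table is not None and len(node_table):
        enc_n = encode_design(node_table)
        rows = []
        for (roi, stype), sub in enc_n.groupby(["roi", "strength_type"]):
            try:
                res = fit_lmm(
                    sub.reset_index(drop=True), "value", CONNECTIVITY_TERMS,
                    engine=engine, model_name=f"{roi}[{stype}]",
                )
            except Exception:
                continue
            for t in ("social", "social:age"):
                rows.append(
                    {"roi": roi, "strength_type": stype, "term": t,
                     "F": res.F(t), "p": res.p(t)}
                )
        node_df = pd.DataFrame(rows)
        if len(node_df):
            node_df["p_fdr"] = np.nan
            for t, idx in node_df.groupby("term").groups.items():
                node_df.loc[idx, "p_fdr"] = fdr_bh(node_df.loc[idx, "p"].to_numpy())
        results["node"] = node_df
    return results


def run_behavior_models(
    behavior_table: pd.DataFrame, engine: str = "mixedlm"
) -> dict:
    """RT and accuracy mixed models plus the stated post-hocs.

    ``behavior_table``: one row per subject x condition with rt (mean),
    accuracy (proportion), social, mentalizing, age, gender, iq.
    """
    enc = encode_design(behavior_table)
    out: dict = {}
    for outcome in ("rt", "accuracy"):
        vals = behavior_table[outcome]
        if vals.nunique() <= 1:
            out[outcome] = None  # degenerate outcome (e.g. accuracy == 1)
            continue
        out[outcome] = fit_lmm(enc, outcome, BEHAVIOR_TERMS, engine=engine)

    # post-hoc paired t on Peer vs Character subject means
    wide = (
        behavior_table.groupby(["subject_id", "social"])["rt"].mean().unstack()
    )
    out["rt_paired_t"] = paired_t(wide["Peer"], wide["Character"])
    # post-hoc accuracy-age regression per social level
    acc_posthoc = {}
    for social, sval in (("Peer", 0.5), ("Character", -0.5)):
        sub = enc[enc["social"] == sval]
        collapsed = (
            sub.groupby("subject_id")
            .agg({"accuracy": "mean", "age": "first", "gender": "first",
                  "iq": "first"})
            .reset_index()
        )
        acc_posthoc[social] = _ols_age_posthoc(
            collapsed, "accuracy", "age", ["gender", "iq"]
        )
    out["accuracy_age_posthoc"] = acc_posthoc
    return out


BRAIN_BEHAVIOR_TERMS = (
    Term("social", True),
    Term("behavior", True),
    Term("social:behavior", True),
    Term("age", False),
    Term("gender", False),
    Term("mean_fd", False),
    Term("iq", False),
)


def run_brain_behavior_models(
    bb_table: pd.DataFrame,
    behavior_cols: tuple[str, ...] = ("rt",),
    engine: str = "mixedlm",
) -> dict:
    """Connectivity ~ social x behaviour models on Peer/Character collapsed data.

    ``bb_table``: one row per subject x social level with the three
    collapsed network outcomes, the behaviour measures, and covariates.
    """
    out: dict = {}
    for measure in behavior_cols:
        if bb_table[measure].nunique() <= 1:
            raise ValueError(f"degenerate behaviour predictor {measure!r}")
        tab = bb_table.copy()
        tab["behavior"] = pd.to_numeric(tab[measure])
        enc = encode_design(tab)
        for outcome in NETWORK_OUTCOMES:
            if outcome not in enc:
                continue
            res = fit_lmm(
                enc, outcome, BRAIN_BEHAVIOR_TERMS, engine=engine,
                model_name=f"{outcome}~{measure}",
            )
            posthoc = {}
            for social, sval in (("Peer", 0.5), ("Character", -0.5)):
                sub = enc[enc["social"] == sval].reset_index(drop=True)
                posthoc[social] = _ols_age_posthoc(
                    sub, outcome, "behavior", ["age", "gender", "mean_fd", "iq"]
                )
                r, p = partial_corr(
                    sub["behavior"], sub[outcome], sub[["age"]].to_numpy()
                )
                posthoc[social]["partial_r_age"] = r
                posthoc[social]["partial_r_age_p"] = p
            res.posthoc = posthoc
            out[(outcome, measure)] = res
    return out


def quartile_contrast(
    subject_table: pd.DataFrame,
    outcomes: tuple[str, ...] = NETWORK_OUTCOMES,
    variable: str = "age",
) -> pd.DataFrame:
    """Peer vs Character paired t within the lower and upper quartile groups.

    ``subject_table``: one row per subject with ``<outcome>_peer`` and
    ``<outcome>_character`` columns (condition-collapsed connectivity)
    plus the stratifying variable.  Quartile membership is strict
    (v < Q1, v > Q3), with linear-interpolation quantiles.
    """
    v = subject_table[variable].to_numpy(float)
    if np.unique(v).size == 1:
        raise ValueError(f"{variable} is constant; quartiles undefined")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    rows = []
    for group, mask in (("lower", v < q1), ("upper", v > q3)):
        sub = subject_table[mask]
        if len(sub) < 3:
            raise ValueError(f"{group}-quartile group has fewer than 3 subjects")
        for outcome in outcomes:
            t, df, p = paired_t(
                sub[f"{outcome}_peer"], sub[f"{outcome}_character"], "two-sided"
            )
            rows.append(
                {"group": group, "n": len(sub), "outcome": outcome,
                 "boundary": q1 if group == "lower" else q3,
                 "t": t, "df": df, "p": p,
                 "mean_diff": float(
                     (sub[f"{outcome}_peer"] - sub[f"{outcome}_character"]).mean()
                 )}
            )
    return pd.DataFrame(rows)


def select_low_motion_age_subsample(
    subject_table: pd.DataFrame,
    target_n: int = 30,
    max_abs_corr: float = 0.05,
) -> list:
    """Greedily drop subjects until |corr(age, mean FD)| < threshold.

    At each step the subject whose removal most reduces the absolute
    age-motion correlation is dropped; stops at the threshold or at
    ``target_n`` subjects, whichever comes first.
    """
    if target_n > len(subject_table):
        raise ValueError("target subsample larger than the cohort")
    if target_n < 10:
        raise ValueError("subsample must keep at least 10 subjects")
    tab = subject_table.reset_index(drop=True)
    keep = list(tab.index)

    def corr(idx):
        a = tab.loc[idx, "age"].to_numpy(float)
        f = tab.loc[idx, "mean_fd"].to_numpy(float)
        if np.unique(a).size == 1 or np.unique(f).size == 1:
            return 0.0
        return float(np.corrcoef(a, f)[0, 1])

    while abs(corr(keep)) > max_abs_corr and len(keep) > target_n:
        best, best_c = None, np.inf
        for i in keep:
            trial = [j for j in keep if j != i]
            c = abs(corr(trial))
            if c < best_c:
                best, best_c = i, c
        keep.remove(best)
    return list(tab.loc[keep, "subject_id"])


def subsample_reanalysis(
    long_table: pd.DataFrame,
    subject_table: pd.DataFrame,
    node_table: pd.DataFrame | None = None,
    selector=None,
    target_n: int = 30,
    max_abs_corr: float = 0.05,
    engine: str = "mixedlm",
) -> dict:
    """Re-run the connectivity battery on a low age-motion-correlation subset."""
    if selector is None:
        ids = select_low_motion_age_subsample(subject_table, target_n, max_abs_corr)
    else:
        ids = list(selector(subject_table))
    if len(ids) < 10:
        raise ValueError("selector kept fewer than 10 subjects")
    sub_long = long_table[long_table["subject_id"].isin(ids)].reset_index(drop=True)
    sub_node = (
        node_table[node_table["subject_id"].isin(ids)].reset_index(drop=True)
        if node_table is not None
        else None
    )
    out = run_connectivity_models(sub_long, sub_node, engine=engine)
    out["subject_ids"] = ids
    sel = subject_table[subject_table["subject_id"].isin(ids)]
    out["age_fd_corr"] = float(
        np.corrcoef(sel["age"].astype(float), sel["mean_fd"].astype(float))[0, 1]
    )
    return out
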