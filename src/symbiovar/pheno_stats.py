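"""Phenotype statistics for symbiont-variant comparisons.

Hazard ratios come from a Cox proportional-hazards fit (Efron tie handling)
with line and experiment fixed effects and vial-level clustering handled by a
cluster-robust sandwich variance. All-pairs comparisons of the log hazard
ratios use a single-step maximum-statistic adjustment and are summarized as a
compact letter display. The module also provides the rank tests, z-scaling,
Euclidean complete-linkage clustering, Bonferroni-corrected Pearson
correlations, growth-model comparison (linear vs log-linear, with doubling
time) and the log-scale mixed-effects group contrast used for titre data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import integrate, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

ALPHA_DEFAULT = 0.05


# --------------------------------------------------------------------------
# Cox hazard ratios
# --------------------------------------------------------------------------


@dataclass
class HazardEstimates:
    """ln hazard ratios vs a baseline line, with their joint covariance."""

    baseline: str
    lines: list[str]  # baseline first
    lnhr: np.ndarray  # baseline entry is 0
    se: np.ndarray  # baseline entry is 0
    covariance: np.ndarray  # (k, k); baseline row/col are 0
    inestimable: list[str] = field(default_factory=list)
    policy: str = "cluster-robust"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line": self.lines, "lnhr": self.lnhr, "se": self.se})


def fit_hazard_ratios(
    records: pd.DataFrame,
    baseline: str,
    cluster_policy: str = "cluster-robust",
) -> HazardEstimates:
    """Cox partial-likelihood fit of per-line log hazard ratios.

    ``records`` columns: line, vial, experiment, day, event. Fixed effects are
    the line (treatment-coded against ``baseline``) and the experiment
    replicate; replicate vials are handled with a cluster-robust sandwich
    variance (``cluster_policy='cluster-robust'``) or ignored
    (``'none'``, model-based variance). Ties are handled by Efron's method.
    Lines without a single event are flagged inestimable and dropped.
    """
    if cluster_policy not in ("cluster-robust", "none"):
        raise ValueError(f"unknown cluster policy {cluster_policy!r}")
    required = {"line", "vial", "experiment", "day", "event"}
    if missing := required - set(records.columns):
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if baseline not in set(records["line"]):
        raise ValueError(f"baseline line {baseline!r} absent")

    events_per_line = records.groupby("line")["event"].sum()
    inestimable = sorted(events_per_line[events_per_line == 0].index)
    if baseline in inestimable:
        raise ValueError("baseline line has no events")
    work = records[~records["line"].isin(inestimable)].copy()

    lines = [baseline] + sorted(set(work["line"]) - {baseline})
    design = pd.DataFrame(index=work.index)
    for ln in lines[1:]:
        design[f"line[{ln}]"] = (work["line"] == ln).astype(float)
    experiments = sorted(work["experiment"].unique())
    for ex in experiments[1:]:
        design[f"experiment[{ex}]"] = (work["experiment"] == ex).astype(float)
    design["day"] = work["day"].astype(float)
    design["event"] = work["event"].astype(int)

    fitter = CoxPHFitter()
    kwargs = {}
    if cluster_policy == "cluster-robust":
        design["vial"] = work["vial"].to_numpy()
        kwargs = {"cluster_col": "vial", "robust": True}
    fitter.fit(design, duration_col="day", event_col="event", **kwargs)

    line_params = [f"line[{ln}]" for ln in lines[1:]]
    beta = fitter.params_[line_params].to_numpy()
    cov_fit = fitter.variance_matrix_.loc[line_params, line_params].to_numpy()

    k = len(lines)
    lnhr = np.zeros(k)
    se = np.zeros(k)
    cov = np.zeros((k, k))
    lnhr[1:] = beta
    se[1:] = np.sqrt(np.diag(cov_fit))
    cov[1:, 1:] = cov_fit
    return HazardEstimates(
        baseline=baseline,
        lines=lines,
        lnhr=lnhr,
        se=se,
        covariance=cov,
        inestimable=inestimable,
        policy=cluster_policy,
    )


# --------------------------------------------------------------------------
# all-pairs comparisons and compact letter display
# --------------------------------------------------------------------------


def _pairwise_stats(
    est: np.ndarray, cov: np.ndarray
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    k = len(est)
    pairs = list(itertools.combinations(range(k), 2))
    contrast = np.zeros((len(pairs), k))
    for m, (i, j) in enumerate(pairs):
        contrast[m, i] = 1.0
        contrast[m, j] = -1.0
    diffs = contrast @ est
    vmat = contrast @ cov @ contrast.T
    var = np.diag(vmat)
    if np.any(var <= 0):
        raise ValueError("singular covariance: a pairwise contrast has no variance")
    z = diffs / np.sqrt(var)
    corr = vmat / np.sqrt(np.outer(var, var))
    return pairs, z, corr


def _maxabs_adjust_equicorrelation(abs_z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step adjusted p under a one-factor equicorrelation approximation."""
    m = len(abs_z)
    if m == 1:
        return 2 * stats.norm.sf(abs_z)
    off = corr[~np.eye(m, dtype=bool)]
    rho = float(np.clip(off.mean(), 0.0, 0.999))
    sr, s1 = np.sqrt(rho), np.sqrt(1.0 - rho)

    def p_all_below(t: float) -> float:
        def integrand(x: float) -> float:
            inner = stats.norm.cdf((t - sr * x) / s1) - stats.norm.cdf((-t - sr * x) / s1)
            return stats.norm.pdf(x) * inner**m

        val, _err = integrate.quad(integrand, -8.5, 8.5, limit=200)
        return val

    return np.array([min(1.0, max(0.0, 1.0 - p_all_below(t))) for t in abs_z])


def _maxabs_adjust_mc(
    abs_z: np.ndarray, corr: np.ndarray, n_draws: int = 200_000, seed: int = 20131212
) -> np.ndarray:
    """Seeded Monte-Carlo single-step adjustment using the exact correlation."""
    rng = np.random.default_rng(seed)
    vals, vecs = np.linalg.eigh(corr)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    draws = rng.standard_normal((n_draws, corr.shape[0])) @ root.T
    maxabs = np.abs(draws).max(axis=1)
    return np.array([(maxabs >= t).mean() for t in abs_z])


def pairwise_comparisons(
    estimates: HazardEstimates,
    alpha: float = ALPHA_DEFAULT,
    method: str = "equicorrelation",
) -> pd.DataFrame:
    """All-pairs z tests on lnHR differences, single-step adjusted."""
    pairs, z, corr = _pairwise_stats(estimates.lnhr, estimates.covariance)
    abs_z = np.abs(z)
    if method == "equicorrelation":
        p_adj = _maxabs_adjust_equicorrelation(abs_z, corr)
    elif method == "mc":
        p_adj = _maxabs_adjust_mc(abs_z, corr)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    lines = estimates.lines
    return pd.DataFrame(
        {
            "line_1": [lines[i] for i, _ in pairs],
            "line_2": [lines[j] for _, j in pairs],
            "difference": [estimates.lnhr[i] - estimates.lnhr[j] for i, j in pairs],
            "z": z,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )


def cld_from_significance(
    groups: list[str], significant: dict[tuple[str, str], bool], order: list[str] | None = None
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two groups share a letter iff their comparison is non-significant (the
    significance map is symmetrized). ``order`` fixes letter assignment order
    (default: the given group order).
    """
    sig = set()
    for (a, b), s in significant.items():
        if s:
            sig.add(frozenset((a, b)))
    columns: list[set[str]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb columns contained in others
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(i != j and c < other for j, other in enumerate(columns))
        ]
        # deduplicate
        uniq: list[set[str]] = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    ordering = order or list(groups)
    columns.sort(key=lambda c: min(ordering.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in sorted(col, key=ordering.index):
            letters[g] += letter
    if any(not v for v in letters.values()):
        raise RuntimeError("letter assignment left a group without a letter")
    return letters


def tukey_cld(
    estimates: HazardEstimates,
    alpha: float = ALPHA_DEFAULT,
    method: str = "equicorrelation",
) -> dict[str, str]:
    """Letters per line from the single-step all-pairs comparisons.

    Letters are assigned in order of increasing lnHR, as in published compact
    letter displays.
    """
    comps = pairwise_comparisons(estimates, alpha=alpha, method=method)
    significant = {
        (r.line_1, r.line_2): bool(r.significant) for r in comps.itertuples(index=False)
    }
    order = [ln for _, ln in sorted(zip(estimates.lnhr, estimates.lines))]
    return cld_from_significance(estimates.lines, significant, order=order)


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------


def rank_tests(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus plus Holm-adjusted all-pairs Wilcoxon rank-sum.

    For exactly two groups the Mann-Whitney p is returned as ``two_group_p``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    out: dict = {}
    out["kruskal_p"] = float(stats.kruskal(*arrays).pvalue)
    pairs = list(itertools.combinations(range(len(names)), 2))
    raw = [
        float(stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided").pvalue)
        for i, j in pairs
    ]
    adj = multipletests(raw, method="holm")[1]
    out["pairwise"] = pd.DataFrame(
        {
            "group_1": [names[i] for i, _ in pairs],
            "group_2": [names[j] for _, j in pairs],
            "p_raw": raw,
            "p_holm": adj,
        }
    )
    if len(names) == 2:
        out["two_group_p"] = raw[0]
    return out


# --------------------------------------------------------------------------
# scaling, clustering, correlation
# --------------------------------------------------------------------------


def zscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample SD 1."""
    sd = matrix.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    return (matrix - matrix.mean()) / sd


def cluster_variants(
    scaled: pd.DataFrame, k: int | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """Complete-linkage hierarchical clustering on Euclidean distances.

    Returns the scipy linkage matrix and, when ``k`` is given, cluster labels
    per row. Ties in the distance matrix are broken deterministically by the
    condensed-distance order, i.e. by row order.
    """
    if len(scaled) < 2:
        raise ValueError("need at least two rows to cluster")
    dist = pdist(scaled.to_numpy(dtype=float), metric="euclidean")
    linkage = hierarchy.linkage(dist, method="complete")
    labels = None
    if k is not None:
        labels = pd.Series(
            hierarchy.fcluster(linkage, t=k, criterion="maxclust"), index=scaled.index
        )
    return linkage, labels


def correlate(
    x: np.ndarray, y: np.ndarray, family_size: int = 1
) -> dict[str, float]:
    """Pearson correlation with a Bonferroni-adjusted p over a test family."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_raw": float(p), "p_bonferroni": min(1.0, family_size * float(p))}


# --------------------------------------------------------------------------
# growth models
# --------------------------------------------------------------------------


@dataclass
class GrowthFit:
    preferred: str  # 'linear' or 'exponential'
    aic_linear: float
    aic_exponential: float  # on the raw-titre scale (Jacobian-corrected)
    linear: object  # statsmodels results
    loglinear: object
    slopes_log: dict[str, float]  # per-group total log-scale slope
    slopes_linear: dict[str, float]
    doubling_times: dict[str, float]  # days; inf when the log slope is <= 0


def fit_growth(series: pd.DataFrame, reference_group: str | None = None) -> GrowthFit:
    """Compare linear and log-linear titre growth with group x age interactions.

    Fits titre ~ age * group and log(titre) ~ age * group by OLS, with slope
    and intercept contrasts against ``reference_group`` (default: first group
    alphabetically). Model preference is by AIC on the common raw-titre scale:
    the log model's likelihood is corrected by the Jacobian of the log
    transform (AIC_log + 2*sum(log y)). Doubling time is ln 2 over the
    natural-log-scale slope, reported per group (inf when the slope is not
    positive).
    """
    required = {"strain", "day", "titre"}
    if missing := required - set(series.columns):
        raise ValueError(f"series missing columns: {sorted(missing)}")
    if (series["titre"] <= 0).any():
        raise ValueError("non-positive titre: log-linear model undefined")
    counts = series.groupby("strain")["day"].nunique()
    if (counts < 3).any():
        raise ValueError("every strain needs >= 3 distinct ages")
    groups = sorted(series["strain"].unique())
    ref = reference_group or groups[0]
    df = series.rename(columns={"strain": "group", "day": "age"}).copy()
    df["log_titre"] = np.log(df["titre"])

    if len(groups) > 1:
        formula_lin = f"titre ~ age * C(group, Treatment('{ref}'))"
        formula_log = f"log_titre ~ age * C(group, Treatment('{ref}'))"
    else:
        formula_lin = "titre ~ age"
        formula_log = "log_titre ~ age"
    lin = smf.ols(formula_lin, data=df).fit()
    log = smf.ols(formula_log, data=df).fit()

    aic_lin = float(lin.aic)
    aic_log_raw = float(log.aic + 2.0 * df["log_titre"].sum())
    preferred = "linear" if aic_lin <= aic_log_raw else "exponential"

    def _slopes(res) -> dict[str, float]:
        base = res.params.get("age", 0.0)
        out = {}
        for g in groups:
            inter = 0.0
            key = f"age:C(group, Treatment('{ref}'))[T.{g}]"
            if key in res.params:
                inter = res.params[key]
            out[g] = float(base + inter)
        return out

    slopes_log = _slopes(log)
    doubling = {
        g: (float(np.log(2) / b) if b > 0 else float("inf")) for g, b in slopes_log.items()
    }
    return GrowthFit(
        preferred=preferred,
        aic_linear=aic_lin,
        aic_exponential=aic_log_raw,
        linear=lin,
        loglinear=log,
        slopes_log=slopes_log,
        slopes_linear=_slopes(lin),
        doubling_times=doubling,
    )


# --------------------------------------------------------------------------
# log-scale mixed-effects group contrast
# --------------------------------------------------------------------------


def fit_log_group_effect(
    values: pd.DataFrame,
    group_col: str = "group",
    line_col: str = "line",
    value_col: str = "value",
) -> dict:
    """Two-level model on log values: fixed group effect, random line intercept.

    Fit by REML (statsmodels MixedLM). With a single replicate per line the
    random effect is unidentifiable and the fit falls back to ordinary
    regression with a warning. Returns the contrast of the second group level
    vs the first, its SE and p, and which estimator was used.
    """
    df = values.copy()
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    if (df[value_col] <= 0).any():
        raise ValueError("non-positive values: log undefined")
    df["_log"] = np.log(df[value_col])
    df["_g"] = (df[group_col] == levels[1]).astype(float)
    reps_per_line = df.groupby(line_col).size()
    if (reps_per_line <= 1).all():
        warnings.warn(
            "single replicate per line: falling back to ordinary regression",
            stacklevel=2,
        )
        res = smf.ols("_log ~ _g", data=df).fit()
        return {
            "contrast": float(res.params["_g"]),
            "se": float(res.bse["_g"]),
            "p": float(res.pvalues["_g"]),
            "groups": levels,
            "estimator": "ols",
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("_log ~ _g", groups=df[line_col], data=df)
        res = model.fit(reml=True)
    return {
        "contrast": float(res.params["_g"]),
        "se": float(res.bse["_g"]),
        "p": float(res.pvalues["_g"]),
        "groups": levels,
        "estimator": "mixedlm-reml",
    }
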