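"""Group-comparison statistics for regional morphometry and network metrics.

The comparison layer mirrors a standard GLM workflow: per-region ANCOVA
with group as the between-subject factor and age, sex and scanner as
covariates; Tukey-Kramer-adjusted post hoc pairwise comparisons of the
adjusted group means; Benjamini-Hochberg FDR across regions (or across
network metrics); a linear-regression correspondence of regional values
between field strengths; one-way ANOVA over per-density network-metric
values; and chi-square / ANOVA demographics tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .morphometry import RegionalMorphometryTable

DEFAULT_ALPHA = 0.05


@dataclass
class CorrespondenceResult:
    """Regional correspondence of one measure between two acquisitions."""

    measure: str
    group: str | None
    r: float
    p: float
    n_points: int
    slope: float
    intercept: float


def fdr_correct(p_values, q_level: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(adjusted, reject)`` in the original order; a test is
    rejected iff its adjusted value is <= `q_level`.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return adjusted, reject


def tukey_kramer(levels, means, cov, df_resid, alpha: float = DEFAULT_ALPHA):
    """Tukey-Kramer adjusted pairwise comparisons of (adjusted) means.

    Parameters
    ----------
    levels, means
        Group labels and their estimated (covariate-adjusted) means.
    cov
        k x k covariance matrix of the mean estimates (for a one-way
        layout, ``diag(MSE / n_i)`` — the unequal-n Kramer form).
    df_resid
        Error degrees of freedom of the underlying model.

    Adjusted p values come from the studentized-range distribution with
    ``q = |diff| / sqrt(var(diff) / 2)`` on k means; for k = 2 this
    reproduces the unadjusted two-sided t test.
    """
    means = np.asarray(means, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
            if var <= 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / np.sqrt(var / 2.0)
                p = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append({
                "pair": (levels[i], levels[j]),
                "difference": float(diff),
                "p_adj": min(1.0, p),
                "significant": p <= alpha,
            })
    return rows


def _design_matrices(long: pd.DataFrame, factor: str, covariates):
    """Full and reduced (factor dropped) design matrices with named columns."""
    cols = {"Intercept": np.ones(len(long))}
    flevels = sorted(long[factor].unique())
    fcols = []
    for lev in flevels[1:]:
        name = f"{factor}[{lev}]"
        cols[name] = (long[factor] == lev).to_numpy(dtype=float)
        fcols.append(name)
    for cov in covariates:
        vals = long[cov]
        if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
            clevels = sorted(vals.unique())
            for lev in clevels[1:]:
                cols[f"{cov}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
        else:
            cols[cov] = vals.to_numpy(dtype=float)
    names = list(cols)
    x_full = np.column_stack([cols[c] for c in names])
    red_names = [c for c in names if c not in fcols]
    x_red = np.column_stack([cols[c] for c in red_names])
    return x_full, names, fcols, x_red, flevels


def _check_full_rank(x: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns from the small diagonal entries of R
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        aliased = [names[i] for i in range(len(names)) if diag[i] <= tol]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"aliased terms: {aliased}")


def regional_ancova(
    tables,
    subjects: pd.DataFrame,
    covariates=("age", "sex", "scanner"),
    q_level: float = 0.05,
    alpha: float = DEFAULT_ALPHA,
    posthoc: bool = True,
) -> pd.DataFrame:
    """Per-region ANCOVA of one morphometric measure.

    Fits, for every region, an OLS model ``value ~ group + age + sex +
    scanner`` over the pooled subject-sessions of `tables` (each table
    contributes its group/field cell; scanner = field strength). The
    group factor is tested with the extra-sum-of-squares F test of the
    full against the group-free model (equivalent to the Type-III test
    here, as the model has no interactions), Tukey-Kramer post hocs
    compare covariate-adjusted group means, and region p values are
    BH-FDR corrected.

    Returns a DataFrame with one row per region: F, df1, df2, p, q,
    reject, posthoc (list of pair dicts).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables given")
    measure = tables[0].measure
    regions = tables[0].regions
    rows = []
    for t in tables:
        if t.measure != measure:
            raise ValueError("all tables must share one measure")
        if t.regions != regions:
            raise ValueError("all tables must share the same region set")
        frame = t.values.copy()
        frame["group"] = t.group
        frame["scanner"] = t.field
        frame["subject_id"] = t.values.index
        rows.append(frame)
    long = pd.concat(rows, ignore_index=True)

    groups = sorted(long["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    counts = long["group"].value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"each group needs >= 3 subjects; too small: {dict(small)}")

    meta_cols = [c for c in ("age", "sex") if c in covariates]
    if meta_cols:
        meta = subjects.set_index("subject_id")[meta_cols]
        if meta.isna().any().any():
            raise ValueError("covariates contain missing values")
        missing = [s for s in long["subject_id"] if s not in meta.index]
        if missing:
            raise ValueError(f"subjects missing from metadata: {sorted(set(missing))}")
        long = long.join(meta, on="subject_id")
    used_covs = [c for c in covariates if c == "scanner" or c in meta_cols]
    if "scanner" in used_covs and long["scanner"].nunique() < 2:
        used_covs.remove("scanner")

    x_full, names, fcols, x_red, flevels = _design_matrices(long, "group", used_covs)
    _check_full_rank(x_full, names)

    y = long[regions].to_numpy(dtype=float)
    n, p_full = x_full.shape
    df1 = len(fcols)
    df2 = n - p_full
    if df2 <= 0:
        raise ValueError("no error degrees of freedom")

    beta, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    rss_full = ((y - x_full @ beta) ** 2).sum(axis=0)
    beta_r, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    rss_red = ((y - x_red @ beta_r) ** 2).sum(axis=0)
    mse = rss_full / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss_red - rss_full) / df1) / mse
    f_stat = np.where(mse == 0, 0.0, f_stat)
    p_vals = stats.f.sf(f_stat, df1, df2)
    p_vals = np.where(mse == 0, 1.0, p_vals)
    q_vals, reject = fdr_correct(p_vals, q_level=q_level)

    # covariate-adjusted group means differ only through the group
    # effects (treatment coding: reference level has effect 0)
    xtx_inv = np.linalg.pinv(x_full.T @ x_full)
    gidx = [names.index(c) for c in fcols]
    k = len(flevels)
    effect_cov_unit = np.zeros((k, k))
    sub = xtx_inv[np.ix_(gidx, gidx)]
    effect_cov_unit[1:, 1:] = sub

    out = []
    for r_idx, region in enumerate(regions):
        effects = np.zeros(k)
        effects[1:] = beta[gidx, r_idx]
        pairs = (tukey_kramer(flevels, effects, effect_cov_unit * mse[r_idx],
                              df2, alpha=alpha) if posthoc else [])
        out.append({
            "region": region, "measure": measure,
            "F": float(f_stat[r_idx]), "df1": df1, "df2": df2,
            "p": float(p_vals[r_idx]), "q": float(q_vals[r_idx]),
            "reject": bool(reject[r_idx]), "posthoc": pairs,
        })
    return pd.DataFrame(out)


def network_metric_anova(
    metrics: pd.DataFrame,
    value_columns=("Q", "gamma", "lambda", "sigma"),
    cell_column: str = "cell",
    measure_column: str | None = "measure",
    q_level: float = 0.05,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One-way ANOVA of network metrics across group cells.

    Each metric's per-density values serve as the replicate observations
    of its group cell (e.g. ``HC_3T``). All cell pairs get Tukey-Kramer
    post hocs; FDR is applied across the metric x measure family.
    """
    if measure_column and measure_column in metrics.columns:
        blocks = [(m, g) for m, g in metrics.groupby(measure_column)]
    else:
        blocks = [(None, metrics)]
    rows = []
    for measure, block in blocks:
        cells = sorted(block[cell_column].unique())
        if len(cells) < 2:
            raise ValueError("need >= 2 group cells")
        for metric in value_columns:
            samples = [block.loc[block[cell_column] == c, metric].to_numpy(dtype=float)
                       for c in cells]
            ns = np.array([len(s) for s in samples])
            if (ns < 2).any():
                bad = [c for c, n_i in zip(cells, ns) if n_i < 2]
                raise ValueError(f"cells with a single observation: {bad}")
            means = np.array([s.mean() for s in samples])
            n_tot = int(ns.sum())
            grand = np.concatenate(samples).mean()
            ss_between = float((ns * (means - grand) ** 2).sum())
            ss_within = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
            df1, df2 = len(cells) - 1, n_tot - len(cells)
            mse = ss_within / df2
            f = (ss_between / df1) / mse if mse > 0 else 0.0
            p = float(stats.f.sf(f, df1, df2)) if mse > 0 else 1.0
            posthoc = tukey_kramer(cells, means, np.diag(mse / ns), df2, alpha=alpha)
            rows.append({
                "measure": measure, "metric": metric,
                "F": float(f), "df1": df1, "df2": df2, "p": p,
                "posthoc": posthoc,
            })
    result = pd.DataFrame(rows)
    q_vals, reject = fdr_correct(result["p"].to_numpy(), q_level=q_level)
    result["q"] = q_vals
    result["reject"] = reject
    return result


def regional_correspondence(
    table_a: RegionalMorphometryTable,
    table_b: RegionalMorphometryTable,
    pooling: str = "region_by_subject",
) -> CorrespondenceResult:
    """Linear regression of regional values between two acquisitions.

    ``pooling="region_by_subject"`` pairs one point per subject x region
    (subjects must match between tables); ``"region_means"`` pairs the
    per-region group means (one point per region), which tolerates
    different subject samples. Returns Pearson r with its two-sided
    t-distribution p value (n - 2 df), plus OLS slope and intercept of
    ``table_b ~ table_a``.
    """
    if table_a.measure != table_b.measure:
        raise ValueError("tables measure different quantities")
    if table_a.regions != table_b.regions:
        raise ValueError("tables have different region sets")
    if pooling == "region_by_subject":
        ids_a, ids_b = set(table_a.values.index), set(table_b.values.index)
        if ids_a != ids_b:
            raise ValueError(
                f"subject sets differ: only in first {sorted(ids_a - ids_b)}, "
                f"only in second {sorted(ids_b - ids_a)}")
        order = table_a.values.index
        x = table_a.values.loc[order].to_numpy(dtype=float).ravel()
        y = table_b.values.loc[order].to_numpy(dtype=float).ravel()
    elif pooling == "region_means":
        x = table_a.values.mean(axis=0).to_numpy(dtype=float)
        y = table_b.values.mean(axis=0).to_numpy(dtype=float)
    else:
        raise ValueError("pooling must be 'region_by_subject' or 'region_means'")
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    fit = stats.linregress(x, y)
    group = table_a.group if table_a.group == table_b.group else None
    return CorrespondenceResult(
        measure=table_a.measure, group=group,
        r=float(fit.rvalue), p=float(fit.pvalue), n_points=int(x.size),
        slope=float(fit.slope), intercept=float(fit.intercept))


def demographics_tests(subjects: pd.DataFrame, group_column: str = "group") -> pd.DataFrame:
    """Demographics comparison table across groups.

    Sex (categorical): chi-square test of independence without
    continuity correction, expected counts attached. Continuous
    variables (age, lesion volume, brain parenchymal volume): two-sample
    t test for exactly two groups, one-way ANOVA otherwise.
    """
    groups = sorted(subjects[group_column].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    if "sex" in subjects.columns:
        table = pd.crosstab(subjects[group_column], subjects["sex"])
        observed = table.to_numpy(dtype=float)
        warning = None
        try:
            chi2, p, df, expected = stats.chi2_contingency(observed, correction=False)
        except ValueError:
            expected = (observed.sum(1, keepdims=True) @ observed.sum(0, keepdims=True)
                        ) / observed.sum()
            chi2, p, df = np.nan, np.nan, (observed.shape[0] - 1) * (observed.shape[1] - 1)
            warning = "zero expected count: chi-square statistic undefined"
        if warning is None and (expected < 5).any():
            warning = "expected counts < 5: chi-square approximation may be poor"
        rows.append({"variable": "sex", "test": "chi-square",
                     "statistic": float(chi2), "df": float(df), "p": float(p),
                     "expected": expected, "warning": warning})
    for var in ("age", "wml_volume", "bpv"):
        if var not in subjects.columns:
            continue
        data = subjects[[group_column, var]].dropna()
        samples = [data.loc[data[group_column] == g, var].to_numpy(dtype=float)
                   for g in groups]
        samples = [s for s in samples if s.size > 0]
        if len(samples) < 2:
            continue
        zero_spread = all(np.ptp(s) == 0 for s in samples)
        equal_means = len({float(s.mean()) for s in samples}) == 1
        if zero_spread and equal_means:
            # degenerate but well-defined null: no variation anywhere
            stat, p = 0.0, 1.0
            test = "t" if len(samples) == 2 else "anova"
        elif len(samples) == 2:
            stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
            test = "t"
        else:
            stat, p = stats.f_oneway(*samples)
            test = "anova"
        df = (float(sum(s.size for s in samples) - 2) if test == "t"
              else float(len(samples) - 1))
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "df": df, "p": float(p), "expected": None, "warning": None})
    return pd.DataFrame(rows)
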