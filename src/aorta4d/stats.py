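"""Group-comparison and agreement statistics with exact small-sample contracts.

Rank tests (Mann-Whitney, Kruskal-Wallis), the Pearson correlation, the 2x2
chi-square and Cohen's kappa are implemented directly so their small-sample
behaviour is fully specified: the Mann-Whitney p-value is exact (enumeration
over all group assignments) whenever the combined sample size is at most 12,
and switches to the tie-corrected normal approximation above that.  All
tests are two-sided.  No multiple-testing correction is applied by default
(a Holm adjustment is available as an option in ``build_report``).
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata
from scipy.stats import t as t_dist

EXACT_N_MAX = 12

KAPPA_BANDS = (
    (0.81, 1.01, "almost perfect"),
    (0.61, 0.81, "substantial"),
    (0.41, 0.61, "moderate"),
    (0.21, 0.41, "fair"),
    (0.00, 0.21, "slight"),
    (-1.00, 0.00, "poor"),
)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = #(a > b) pairs + 0.5 per tie."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    Exact by enumeration of all C(n_a+n_b, n_a) group assignments for
    combined n <= 12; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    n_a, n_b = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n_a * n_b / 2.0

    if n_a + n_b <= EXACT_N_MAX:
        pooled = np.concatenate([a, b])
        n = n_a + n_b
        dev = abs(u_obs - mu)
        count = 0
        for idx in combinations(range(n), n_a):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return u_obs, count / comb(n, n_a)

    n = n_a + n_b
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (u_obs - mu) / np.sqrt(var)
    return u_obs, float(2.0 * norm_dist.sf(abs(z)))


def kruskal_wallis(samples) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(samples)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start:start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if correction > 0:
        h /= correction
    df = len(samples) - 1
    return float(h), float(chi2_dist.sf(h, df))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation; two-sided p from t with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has undefined correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * t_dist.sf(abs(t), n - 2))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal")
    n = t.sum()
    chi2 = n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / (
        rows[0] * rows[1] * cols[0] * cols[1])
    return float(chi2), float(chi2_dist.sf(chi2, 1))


def cohen_kappa(ratings_a, ratings_b) -> tuple[float, str]:
    """Cohen's kappa between two raters, with its agreement band.

    Returns (kappa, band); kappa is NaN (band 'undefined') when both raters
    are constant and identical (chance agreement is 1).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size or a.size == 0:
        raise ValueError("ratings must be paired and nonempty")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    conf = np.zeros((cats.size, cats.size))
    for i, ca in enumerate(cats):
        for j, cb in enumerate(cats):
            conf[i, j] = np.sum((a == ca) & (b == cb))
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        return float("nan"), "undefined"
    kappa = (p_o - p_e) / (1.0 - p_e)
    band = next(name for lo, hi, name in KAPPA_BANDS if lo <= kappa < hi)
    return float(kappa), band


def kappa_from_table(table) -> tuple[float, str]:
    """Cohen's kappa directly from a raters' confusion matrix."""
    conf = np.asarray(table, dtype=float)
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        return float("nan"), "undefined"
    kappa = (p_o - p_e) / (1.0 - p_e)
    band = next(name for lo, hi, name in KAPPA_BANDS if lo <= kappa < hi)
    return float(kappa), band


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# report assembly


REQUIRED_COLUMNS = ("subject_id", "group")


def build_report(table: pd.DataFrame, holm: bool = False) -> dict:
    """Assemble the cohort comparison report from a per-subject table.

    Expects columns ``subject_id`` and ``group`` plus any of: regional WSS
    columns (``wss_*``), Z-score columns (``z_*``), a percent size-change
    column (``pct_change_isthmus_pdao``), pattern-grade columns (``grade_*``)
    and covariates (``sex``, ``age``, ``bsa``).  Emits per-variable group
    means +/- sd with two-group Mann-Whitney p (and three-group
    Kruskal-Wallis p when a ``subgroup`` column is present), the sex
    chi-square, and the WSS-vs-size correlation pair for the proximal
    descending aorta.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids")
    groups = sorted(table["group"].unique())

    numeric = [c for c in table.columns
               if c.startswith(("wss_", "z_", "pct_", "grade_")) or c in ("age", "bsa")]
    rows = []
    for col in numeric:
        row = {"variable": col}
        for g in groups:
            vals = table.loc[table["group"] == g, col].dropna()
            row[f"mean_{g}"] = vals.mean()
            row[f"sd_{g}"] = vals.std(ddof=1)
        if len(groups) == 2:
            va = table.loc[table["group"] == groups[0], col].dropna()
            vb = table.loc[table["group"] == groups[1], col].dropna()
            if len(va) and len(vb):
                u, p = mann_whitney(va, vb)
                row["test"] = ("mann_whitney_exact"
                               if len(va) + len(vb) <= EXACT_N_MAX
                               else "mann_whitney_normal")
                row["p"] = p
        rows.append(row)
    comparison = pd.DataFrame(rows)
    if holm and len(groups) == 2 and "p" in comparison:
        comparison["p_holm"] = holm_adjust(comparison["p"].fillna(1.0).to_numpy())
    report = {"comparison": comparison}

    if "subgroup" in table.columns:
        sub_rows = []
        subgroups = sorted(table["subgroup"].unique())
        for col in numeric:
            samples = [table.loc[table["subgroup"] == sg, col].dropna()
                       for sg in subgroups]
            if all(len(s) for s in samples):
                h, p = kruskal_wallis(samples)
                sub_rows.append({"variable": col, "H": h, "p": p})
        report["subgroup_kruskal_wallis"] = pd.DataFrame(sub_rows)

    if "sex" in table.columns and len(groups) == 2:
        counts = pd.crosstab(table["group"], table["sex"]).to_numpy()
        if counts.shape == (2, 2):
            chi2, p = chi_square_2x2(counts)
            report["sex_chi_square"] = {"chi2": chi2, "p": p}

    corr_rows = []
    wss_col = "wss_inner_pDAo"
    if wss_col in table.columns:
        for target in ("z_pDAo", "pct_change_isthmus_pdao"):
            if target in table.columns:
                sub = table[[wss_col, target]].dropna()
                if len(sub) >= 3:
                    r, p = pearson_r(sub[wss_col], sub[target])
                    corr_rows.append({"x": wss_col, "y": target,
                                      "n": len(sub), "R": r, "p": p})
    if corr_rows:
        report["wss_size_correlations"] = pd.DataFrame(corr_rows)
    return report
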