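"""Clinical/diet association statistics.

Covers conversion of food-frequency categories to daily consumption, the
Healthy Food Diversity (HFD) index, macronutrient energy shares, age-adjusted
median (quantile tau=0.5) regression of clinical markers on ordination axes,
Fisher's exact enrichment of diet x microbiota combinations in a phenotype,
and rank-based group tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FfqTable",
    "QuantRegRow",
    "EnrichmentResult",
    "DEFAULT_FREQUENCY_DIALECT",
    "convert_ffq_frequencies",
    "median_regression",
    "fisher_exact",
    "combination_enrichment",
    "group_tests",
    "hfd_index",
    "macronutrient_summary",
]

# kcal per gram of macronutrient (Atwater factors)
KCAL_PER_G = {"protein": 4.0, "fat": 9.0, "carbohydrate": 4.0}

ANNOTATION_COLUMNS = ("group", "health_value", "protein_g", "fat_g", "carb_g", "fibre_g", "kcal")


@dataclass
class FfqTable:
    """Samples x foods daily-consumption matrix plus per-food annotations.

    ``annotations`` is indexed by food and carries the food group, a health
    value in [0, 1] and per-serving macronutrient content (grams of protein,
    fat, carbohydrate and fibre, and kcal).
    """

    consumption: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.consumption.to_numpy(dtype=float) < 0).any():
            raise ValueError("consumption must be non-negative")
        missing = set(self.consumption.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(f"foods without annotation: {sorted(missing)[:5]}")
        hv = self.annotations["health_value"]
        if ((hv < 0) | (hv > 1)).any():
            raise ValueError("health values must lie in [0, 1]")


# Declared FFQ dialect: category string -> consumption per day.  Weekly ranges
# use the range midpoint divided by 7; the floor category maps to 0 and the
# open-ended top category to 4 per day.
DEFAULT_FREQUENCY_DIALECT = {
    "never or less than once a week": 0.0,
    "1-3 times per week": 2.0 / 7.0,
    "4-6 times per week": 5.0 / 7.0,
    "1 time per day": 1.0,
    "2 times per day": 2.0,
    "3 times per day": 3.0,
    "4 or more times per day": 4.0,
}


def _normalize_category(cat: str) -> str:
    s = str(cat).strip().lower()
    s = s.replace("–", "-").replace("—", "-")  # en/em dash
    s = re.sub(r"\s+", " ", s)
    return s


def convert_ffq_frequencies(
    raw: pd.DataFrame,
    dialect: dict | None = None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame | FfqTable:
    """Convert categorical consumption frequencies to daily values.

    `raw` holds category strings per (sample, food).  Every category must be
    present in the dialect table (default: the seven-level weekly FFQ, with
    "never or less than once a week" -> 0 and "4 or more times per day" -> 4;
    weekly ranges use the midpoint then divide by 7, e.g. "1-3 times per week"
    -> 2/7 per day).  Returns the numeric frame, or an :class:`FfqTable` when
    `annotations` are supplied.
    """
    table = {_normalize_category(k): v for k, v in (dialect or DEFAULT_FREQUENCY_DIALECT).items()}
    seen = {_normalize_category(c) for c in pd.unique(raw.to_numpy().ravel())}
    unknown = sorted(seen - set(table))
    if unknown:
        raise ValueError(f"unknown frequency categories: {unknown}")
    daily = raw.apply(lambda col: col.map(lambda c: table[_normalize_category(c)]))
    daily = daily.astype(float)
    if annotations is not None:
        return FfqTable(daily, annotations)
    return daily


@dataclass
class QuantRegRow:
    """One marker-axis median-regression result.

    ``rc_range`` is the axis coefficient scaled to the full span of the axis,
    ``rc_sd`` the coefficient scaled to one axis standard deviation.
    """

    parameter: str
    beta: float
    rc_range: float
    rc_sd: float
    p_value: float
    n: int
    method: str


def _median_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact LAD fit via linear programming.

    minimise sum(r+ + r-)/2 subject to X b + r+ - r- = y, r+- >= 0.
    """
    n, p = X.shape
    c = np.concatenate([np.zeros(p), 0.5 * np.ones(2 * n)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"median-regression LP failed: {res.message}")
    return res.x[:p]


def median_regression(
    marker,
    axis,
    age,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    method: str = "bootstrap",
    parameter: str = "marker",
) -> QuantRegRow:
    """Median regression of a clinical marker on an ordination axis, age-adjusted.

    Solves ``min sum rho_0.5(y - b0 - b1 axis - b2 age)`` exactly by linear
    programming.  Inference on ``b1``:

    ``bootstrap`` (default)
        multiplier (wild) score bootstrap: the quantile score of the
        age-restricted fit is sign-randomized `n_boot` times; finite-sample
        calibrated because residual signs are exchangeable under the null.
    ``pairs``
        xy-pair percentile bootstrap of the slope (mildly conservative at
        moderate n: resampling duplicates inflate the LAD slope spread).
    ``rankscore``
        quantile rank-score test with a normal reference.

    Non-finite marker values are dropped (count warned); at least 10
    complete cases are required.
    """
    y = np.asarray(pd.Series(marker), dtype=float)
    x = np.asarray(pd.Series(axis), dtype=float)
    a = np.asarray(pd.Series(age), dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(a)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} incomplete case(s)", UserWarning, stacklevel=2)
    y, x, a = y[ok], x[ok], a[ok]
    n = y.size
    if n < 10:
        raise ValueError(f"only {n} complete cases (need >= 10)")
    if np.ptp(x) == 0:
        raise ValueError("axis is constant")
    X = np.column_stack([np.ones(n), x, a])
    beta = _median_fit(X, y)
    b1 = float(beta[1])
    span = float(np.ptp(x))
    sd = float(np.std(x, ddof=1))
    rng = np.random.default_rng(seed)
    if method in ("bootstrap", "rankscore"):
        # restricted fit (intercept + age): score for b1 = 0 at tau = 0.5
        Z = np.column_stack([np.ones(n), a])
        beta0 = _median_fit(Z, y)
        resid = y - Z @ beta0
        psi = 0.5 - (resid < 0)
        xz, *_ = np.linalg.lstsq(Z, x, rcond=None)
        xt = x - Z @ xz
        s = psi @ xt
        if method == "bootstrap":
            signs = rng.choice([-1.0, 1.0], size=(n_boot, n))
            s_star = signs @ (np.abs(psi) * xt)
            p = float((np.abs(s_star) >= abs(s) - 1e-15).mean())
            p = min(1.0, max(p, 1.0 / n_boot))
        else:
            v = 0.25 * (xt @ xt)
            z = s / math.sqrt(v) if v > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            p = max(p, np.finfo(float).tiny)
    elif method == "pairs":
        b1s = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                b1s[b] = _median_fit(X[idx], y[idx])[1]
            except RuntimeError:
                b1s[b] = np.nan
        b1s = b1s[np.isfinite(b1s)]
        # two-sided tail fraction of the bootstrap slope around zero,
        # floored at 1/B so the p-value is never exactly 0
        lo = int((b1s <= 0).sum())
        hi = int((b1s >= 0).sum())
        p = min(1.0, max(2.0 * min(lo, hi) / b1s.size, 1.0 / b1s.size))
    else:
        raise ValueError(f"unknown inference method {method!r}")
    return QuantRegRow(
        parameter=parameter, beta=b1,
        rc_range=b1 * span, rc_sd=b1 * sd,
        p_value=float(p), n=n, method=method,
    )


@dataclass
class EnrichmentResult:
    table: np.ndarray          # 2x2 integer contingency counts
    odds_ratio: float          # Haldane-corrected when a zero cell occurs
    p_one_sided: float
    p_two_sided: float

    def __post_init__(self) -> None:
        t = np.asarray(self.table)
        if (t < 0).any():
            raise ValueError("negative contingency counts")


def fisher_exact(table) -> EnrichmentResult:
    """Fisher's exact test for a 2x2 table.

    One-sided p is the hypergeometric tail in the observed direction of
    association; two-sided p sums P(k) over all margin-fixed tables with
    ``P(k) <= P(observed) * (1 + 1e-7)`` (minimum-likelihood rule).  The odds
    ratio applies the Haldane 0.5 correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if not np.allclose(t, np.round(t)):
        raise ValueError("contingency cells must be integers")
    t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("negative contingency counts")
    a, b, c, d = t.ravel()
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty contingency table")
    row1, col1 = a + b, a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    # hypergeometric pmf over the margin-fixed support, via log-binomials
    lg = special.gammaln
    logpmf = (
        lg(col1 + 1) - lg(ks + 1) - lg(col1 - ks + 1)
        + lg(n - col1 + 1) - lg(row1 - ks + 1) - lg(n - col1 - row1 + ks + 1)
        - (lg(n + 1) - lg(row1 + 1) - lg(n - row1 + 1))
    )
    pmf = np.exp(logpmf)
    i_obs = a - kmin
    expected_a = row1 * col1 / n
    if a >= expected_a:
        p_one = float(pmf[i_obs:].sum())
    else:
        p_one = float(pmf[: i_obs + 1].sum())
    p_two = float(pmf[pmf <= pmf[i_obs] * (1 + 1e-7)].sum())
    p_one = min(1.0, p_one)
    p_two = min(1.0, p_two)
    if min(a, b, c, d) == 0:
        ah, bh, ch, dh = (v + 0.5 for v in (a, b, c, d))
    else:
        ah, bh, ch, dh = a, b, c, d
    odds = (ah * dh) / (bh * ch)
    return EnrichmentResult(table=t, odds_ratio=float(odds), p_one_sided=p_one, p_two_sided=p_two)


def combination_enrichment(
    states: pd.Series,
    diet_groups: pd.Series,
    phenotype: pd.Series,
    state_set,
    diet_set,
    subject_map: pd.Series | None = None,
) -> EnrichmentResult:
    """Enrichment of a (steady state x diet group) combination in a phenotype.

    The unit of analysis is the subject: a subject is "in combination" when
    any of its samples carries a state in `state_set` *and* a diet group in
    `diet_set` simultaneously.  `phenotype` is binary (truthy = case), given
    per sample (any-sample rule) or per subject.  Without a `subject_map`,
    samples are treated as subjects.
    """
    states = pd.Series(states)
    diet_groups = pd.Series(diet_groups).loc[states.index]
    in_combo_sample = states.isin(set(state_set)) & diet_groups.isin(set(diet_set))
    if subject_map is None:
        subjects = pd.Series(states.index, index=states.index)
    else:
        subjects = pd.Series(subject_map).loc[states.index]
    combo = in_combo_sample.groupby(subjects).any()
    pheno = pd.Series(phenotype)
    if set(pheno.index) >= set(states.index):
        case = pheno.loc[states.index].astype(bool).groupby(subjects).any()
    else:
        case = pheno.reindex(combo.index).astype(bool)
    a = int((combo & case).sum())
    b = int((~combo & case).sum())
    c = int((combo & ~case).sum())
    d = int((~combo & ~case).sum())
    return fisher_exact([[a, b], [c, d]])


def group_tests(
    features,
    groups: pd.Series,
    pairing: pd.Series | None = None,
    prevalence_min: float = 0.20,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-feature rank tests of relative abundance between groups.

    Features present in fewer than ``prevalence_min`` of samples are dropped.
    Two groups use Mann-Whitney U, or the Wilcoxon signed-rank test when a
    `pairing` map (sample -> subject) pairs them one-to-one; three or more
    groups use Kruskal-Wallis.  Benjamini-Hochberg adjustment across features.
    Zero-variance features are flagged with NaN p-values.
    """
    values = features.values if hasattr(features, "values") and not isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    values = pd.DataFrame(values).astype(float)
    groups = pd.Series(groups).loc[values.index]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    keep = values.columns[(values > 0).mean(axis=0) >= prevalence_min]
    values = values[keep]
    paired = pairing is not None
    if paired:
        if len(levels) != 2:
            raise ValueError("paired test requires exactly two groups")
        pairing = pd.Series(pairing).loc[values.index]
        ga = values.index[groups == levels[0]]
        gb = values.index[groups == levels[1]]
        map_a = pd.Series(ga.to_numpy(), index=pairing.loc[ga].to_numpy())
        map_b = pd.Series(gb.to_numpy(), index=pairing.loc[gb].to_numpy())
        common = map_a.index.intersection(map_b.index)
        if len(common) != len(ga) or len(common) != len(gb):
            raise ValueError("pairing map does not pair the two groups one-to-one")
        ga = map_a.loc[common].to_numpy()
        gb = map_b.loc[common].to_numpy()
    rows = []
    for feat in values.columns:
        v = values[feat]
        stats_row = {"feature": feat}
        for lev in levels:
            sub = v[groups == lev]
            stats_row[f"mean_{lev}"] = float(sub.mean())
            stats_row[f"sem_{lev}"] = float(sub.sem()) if len(sub) > 1 else np.nan
        if v.nunique() <= 1:
            stats_row.update(test="constant", p=np.nan)
            rows.append(stats_row)
            continue
        if len(levels) == 2:
            if paired:
                x, y = v.loc[ga].to_numpy(), v.loc[gb].to_numpy()
                diff = x - y
                if np.all(diff == 0):
                    stats_row.update(test="wilcoxon-paired", p=np.nan)
                else:
                    p = stats.wilcoxon(x, y, zero_method="wilcox").pvalue
                    stats_row.update(test="wilcoxon-paired", p=float(p))
            else:
                x = v[groups == levels[0]].to_numpy()
                y = v[groups == levels[1]].to_numpy()
                p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
                stats_row.update(test="mann-whitney", p=float(p))
        else:
            samples = [v[groups == lev].to_numpy() for lev in levels]
            p = stats.kruskal(*samples).pvalue
            stats_row.update(test="kruskal-wallis", p=float(p))
        rows.append(stats_row)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(out.loc[ok, "p"], method=fdr_method)[1]
    return out


def hfd_index(ffq: FfqTable) -> pd.Series:
    """Healthy Food Diversity index per sample.

    With consumption shares ``s_i`` and per-food health values ``hv_i``,
    ``HFD = (sum hv_i s_i) * (1 - sum s_i^2)``; the second factor is the Berry
    diversity index, zero for a single-food diet and maximal (1 - 1/n) for a
    perfectly even one.
    """
    cons = ffq.consumption.astype(float)
    totals = cons.sum(axis=1)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total consumption for sample(s): {list(zero)}")
    shares = cons.div(totals, axis=0)
    hv = ffq.annotations["health_value"].reindex(cons.columns)
    health = shares @ hv
    berry = 1.0 - (shares ** 2).sum(axis=1)
    out = health * berry
    out.name = "hfd"
    return out


def macronutrient_summary(ffq: FfqTable) -> pd.DataFrame:
    """Per-sample macronutrient energy shares and fibre density.

    Protein/fat/carbohydrate shares are percentages of total kcal using the
    4/9/4 kcal per gram factors against each food's declared kcal; fibre is
    reported as grams per 1000 kcal.  Any energy not attributable to the three
    macronutrients appears in ``other_pct``.
    """
    ann = ffq.annotations.reindex(ffq.consumption.columns)
    cons = ffq.consumption.astype(float)
    kcal = cons @ ann["kcal"]
    zero = kcal.index[kcal <= 0]
    if len(zero):
        raise ValueError(f"zero kcal for sample(s): {list(zero)}")
    protein_g = cons @ ann["protein_g"]
    fat_g = cons @ ann["fat_g"]
    carb_g = cons @ ann["carb_g"]
    fibre_g = cons @ ann["fibre_g"]
    out = pd.DataFrame(index=cons.index)
    out["protein_pct"] = 100.0 * KCAL_PER_G["protein"] * protein_g / kcal
    out["fat_pct"] = 100.0 * KCAL_PER_G["fat"] * fat_g / kcal
    out["carbohydrate_pct"] = 100.0 * KCAL_PER_G["carbohydrate"] * carb_g / kcal
    out["other_pct"] = 100.0 - out[["protein_pct", "fat_pct", "carbohydrate_pct"]].sum(axis=1)
    out["fibre_g_per_1000kcal"] = 1000.0 * fibre_g / kcal
    out["kcal"] = kcal
    return out
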