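"""Downstream analytics on per-nucleus size tables.

Covers the full statistical workflow applied to nuclear-size measurements:

* Sturges-rule class width, volume classing, and putative-ploidy labels
  (class I → 2C, II → 4C, ... doubling per class);
* the two-sample median test used for treatment comparisons;
* lognormal/gamma fitting with Anderson–Darling and AIC model choice;
* the bootstrap moment-statistics procedure (resample → lognormal refit →
  regenerate → mean/sd/CV/skewness/kurtosis per iteration);
* linear-model comparison of skewness/kurtosis across groups with Tukey
  post-hoc, preceded by a Shapiro–Wilk normality gate and square-root
  transform when needed;
* Kruskal–Wallis with Dunn's post-hoc (Bonferroni-corrected), plus tidy
  per-group case-study summaries with compact letter displays.

Measurement tables are long-format DataFrames with one row per nucleus and at
least one of ``area_um2`` / ``volume_um3``; grouping labels (method,
treatment, genotype, cell_category) are ordinary columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PloidyClass", "MomentSummary", "sturges_width", "bin_classes",
           "class_to_ploidy", "median_test", "fit_size_distribution",
           "bootstrap_moments", "compare_moments", "kruskal_dunn",
           "summarize_case_study", "validate_measurements"]

DEFAULT_CLASS_WIDTH = 25.0  # μm³
DEFAULT_CLASS_ANCHOR = 20.0  # μm³

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI"]


@dataclass(frozen=True)
class PloidyClass:
    """One volume class [lower, upper) with its putative C-value label."""

    index: int  # 1-based
    lower: float  # μm³
    upper: float  # μm³

    @property
    def roman(self) -> str:
        return _ROMAN[self.index - 1] if self.index <= len(_ROMAN) else str(self.index)

    @property
    def putative_ploidy(self) -> str:
        return class_to_ploidy(self.index)


@dataclass(frozen=True)
class MomentSummary:
    """First moment statistics of one (re)generated sample."""

    mean: float
    sd: float
    cv: float
    skewness: float
    kurtosis: float  # excess
    n: int
    iteration: int = 0
    seed: int | None = None


def sturges_width(range_R: float, n_items: int) -> float:
    """Optimal class width R / (1 + 3.322·log₁₀ N) by the Sturges rule."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if range_R < 0:
        raise ValueError("range must be non-negative")
    return range_R / (1.0 + 3.322 * math.log10(n_items))


def class_to_ploidy(class_index: int) -> str:
    """Putative C-value for a volume class: class k → 2^k C (I→2C, II→4C, ...)."""
    if class_index < 1:
        raise ValueError("class index starts at 1")
    return f"{2 ** class_index}C"


def bin_classes(volumes, width: float = DEFAULT_CLASS_WIDTH,
                anchor: float = DEFAULT_CLASS_ANCHOR
                ) -> tuple[list[PloidyClass], pd.DataFrame]:
    """Cluster volumes into contiguous classes of fixed width from an anchor.

    Classes are [anchor + k·width, anchor + (k+1)·width), half-open above;
    values below the anchor fold into class I, and a maximum landing exactly
    on the top boundary closes the last class (so a 20–220 μm³ population at
    width 25 yields exactly eight classes). Returns the class list and a
    per-class table of counts, mean ± sd.
    """
    if width <= 0:
        raise ValueError("class width must be positive")
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        return [], pd.DataFrame(columns=["class_index", "class", "lower_um3",
                                         "upper_um3", "putative_ploidy", "n",
                                         "mean_um3", "sd_um3"])
    span = v.max() - anchor
    n_classes = max(1, int(math.ceil(span / width - 1e-9)))
    idx = np.floor((v - anchor) / width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_classes - 1)  # fold below-anchor into I, top onto last
    classes = [PloidyClass(index=k + 1, lower=anchor + k * width,
                           upper=anchor + (k + 1) * width)
               for k in range(n_classes)]
    rows = []
    for k, c in enumerate(classes):
        sel = v[idx == k]
        rows.append({"class_index": c.index, "class": c.roman,
                     "lower_um3": c.lower, "upper_um3": c.upper,
                     "putative_ploidy": c.putative_ploidy, "n": int(sel.size),
                     "mean_um3": float(sel.mean()) if sel.size else np.nan,
                     "sd_um3": float(sel.std(ddof=1)) if sel.size > 1 else np.nan})
    return classes, pd.DataFrame(rows)


def assign_classes(volumes, width: float = DEFAULT_CLASS_WIDTH,
                   anchor: float = DEFAULT_CLASS_ANCHOR) -> np.ndarray:
    """1-based class index per volume, same folding rules as bin_classes."""
    v = np.asarray(list(volumes), dtype=float)
    span = v.max() - anchor if v.size else 0.0
    n_classes = max(1, int(math.ceil(span / width - 1e-9)))
    idx = np.floor((v - anchor) / width + 1e-9).astype(int)
    return np.clip(idx, 0, n_classes - 1) + 1


def median_test(a, b) -> dict:
    """Two-sample independent median test.

    Pools both samples, splits at the grand median (values equal to the
    median count as "not above"), and tests the 2×2 group × above/not-above
    table: exactly (hypergeometric / Fisher) when the pooled size is ≤ 200,
    by chi-square with continuity correction otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    gm = float(np.median(pooled))
    table = np.array([[int((a > gm).sum()), int((b > gm).sum())],
                      [int((a <= gm).sum()), int((b <= gm).sum())]])
    if table[0].sum() == 0 or table[1].sum() == 0:
        warnings.warn("degenerate median split (all values identical?); p = 1",
                      stacklevel=2)
        return {"statistic": 0.0, "p_value": 1.0, "table": table,
                "grand_median": gm, "method": "degenerate"}
    if pooled.size <= 200:
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return {"statistic": float(odds), "p_value": float(p), "table": table,
                "grand_median": gm, "method": "exact"}
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return {"statistic": float(chi2), "p_value": float(p), "table": table,
            "grand_median": gm, "method": "chi-square"}


def _anderson_darling(x: np.ndarray, cdf) -> float:
    x = np.sort(x)
    n = x.size
    F = np.clip(cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log(1 - F[::-1]))))


def fit_size_distribution(values) -> dict:
    """ML-fit lognormal and gamma families; select by AIC.

    Returns per-family parameters, Anderson–Darling statistic and AIC, plus
    the selected (lower-AIC) family name. Requires n ≥ 10 positive values.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 values to fit size distributions")
    if (x <= 0).any():
        raise ValueError("sizes must be positive")
    out = {}
    s, _, scale = sps.lognorm.fit(x, floc=0)
    ll = float(np.sum(sps.lognorm.logpdf(x, s, 0, scale)))
    out["lognormal"] = {"sigma": float(s), "mu": float(np.log(scale)),
                        "aic": 4 - 2 * ll,
                        "ad": _anderson_darling(x, lambda q: sps.lognorm.cdf(q, s, 0, scale))}
    k, _, theta = sps.gamma.fit(x, floc=0)
    ll = float(np.sum(sps.gamma.logpdf(x, k, 0, theta)))
    out["gamma"] = {"shape": float(k), "scale": float(theta),
                    "aic": 4 - 2 * ll,
                    "ad": _anderson_darling(x, lambda q: sps.gamma.cdf(q, k, 0, theta))}
    out["family"] = min(("lognormal", "gamma"), key=lambda f: out[f]["aic"])
    return out


def _moments(x: np.ndarray, iteration: int, seed: int | None) -> MomentSummary:
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return MomentSummary(mean=mean, sd=sd,
                         cv=sd / mean if mean != 0 else float("nan"),
                         skewness=float(sps.skew(x, bias=False)),
                         kurtosis=float(sps.kurtosis(x, bias=False)),  # excess
                         n=int(x.size), iteration=iteration, seed=seed)


def bootstrap_moments(values, iterations: int = 1000, resample_n: int = 500,
                      regen_n: int = 500, seed: int = 0
                      ) -> tuple[list[MomentSummary], pd.DataFrame]:
    """Bootstrap → lognormal refit → regeneration → moment statistics.

    Per iteration: resample ``resample_n`` values with replacement, ML-fit a
    lognormal to the resample, draw ``regen_n`` fresh points from the fit, and
    compute that sample's mean, sd, CV, skewness and excess kurtosis.
    Iterations whose fit degenerates (zero log-variance) are skipped and
    counted; more than 5% skips raises. Returns all iteration summaries and
    an aggregate table (mean ± sd per moment).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if (x <= 0).any():
        raise ValueError("values must be positive")
    rng = np.random.default_rng(seed)
    summaries: list[MomentSummary] = []
    skipped = 0
    for it in range(iterations):
        res = rng.choice(x, size=resample_n, replace=True)
        logs = np.log(res)
        mu, sigma = float(logs.mean()), float(logs.std(ddof=0))  # ML estimates
        if sigma <= 1e-9 * (1.0 + abs(mu)):  # constant resample up to roundoff
            skipped += 1
            continue
        regen = rng.lognormal(mean=mu, sigma=sigma, size=regen_n)
        summaries.append(_moments(regen, iteration=it, seed=seed))
    if skipped > 0.05 * iterations:
        raise RuntimeError(f"{skipped}/{iterations} bootstrap iterations had "
                           "degenerate lognormal fits (constant resamples)")
    agg = pd.DataFrame({
        "moment": ["mean", "sd", "cv", "skewness", "kurtosis"],
        "mean": [np.mean([getattr(s, m) for s in summaries])
                 for m in ("mean", "sd", "cv", "skewness", "kurtosis")],
        "sd": [np.std([getattr(s, m) for s in summaries], ddof=1)
               for m in ("mean", "sd", "cv", "skewness", "kurtosis")],
    })
    agg.attrs["skipped"] = skipped
    return summaries, agg


def compare_moments(summaries_by_group: dict, moment: str = "skewness") -> dict:
    """Linear-model comparison of a moment statistic across groups.

    Each group supplies per-iteration moment values (floats or
    MomentSummary objects). Every group is Shapiro–Wilk tested; if any group
    departs from normality at α = 0.05 and the response is non-negative, it
    is square-root transformed. A Gaussian linear model with the group factor
    is then fit and all pairs are compared with Tukey's HSD.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if moment not in ("skewness", "kurtosis", "mean", "sd", "cv"):
        raise ValueError(f"unknown moment {moment!r}")
    data = {}
    for g, vals in summaries_by_group.items():
        arr = np.asarray([getattr(v, moment) if isinstance(v, MomentSummary) else v
                          for v in vals], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 summaries")
        data[g] = arr
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    non_normal = any(sps.shapiro(v[:5000]).pvalue < 0.05 for v in data.values()
                     if v.size >= 3)
    transformed = False
    if non_normal and all((v >= 0).all() for v in data.values()):
        data = {g: np.sqrt(v) for g, v in data.items()}
        transformed = True
    y = np.concatenate(list(data.values()))
    groups = np.concatenate([[g] * len(v) for g, v in data.items()])
    X = pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    tukey = pairwise_tukeyhsd(y, groups, alpha=0.05)
    pair_rows = []
    res = tukey.summary().data[1:]
    for row in res:
        pair_rows.append({"group1": str(row[0]), "group2": str(row[1]),
                          "diff": float(row[2]), "p_adj": float(row[3]),
                          "reject": bool(row[6])})
    return {"group_means": {g: float(v.mean()) for g, v in data.items()},
            "sqrt_transformed": transformed,
            "model_p": float(model.f_pvalue),
            "pairwise": pd.DataFrame(pair_rows)}


def _h_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    """Kruskal–Wallis H with tie correction (explicit, for the exact mode)."""
    n = values.size
    ranks = sps.rankdata(values)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_dunn(groups: dict, exact: bool = False) -> dict:
    """Kruskal–Wallis omnibus test plus Dunn's pairwise post-hoc.

    Dunn z statistics compare tie-corrected mean ranks; pairwise p-values are
    Bonferroni-multiplied by the number of pairs and capped at 1. With
    ``exact=True`` (total n ≤ 12) the omnibus p is computed by exhaustive
    enumeration of all assignments of the pooled values to groups of the
    observed sizes instead of the chi-square approximation.
    """
    names = list(groups.keys())
    arrays = [np.asarray(list(groups[g]), dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    labels = np.concatenate([[i] * a.size for i, a in enumerate(arrays)])
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # maximally tied: no rank information at all
    else:
        h, p = sps.kruskal(*arrays)
    if exact:
        n = pooled.size
        if n > 12:
            raise ValueError("exact enumeration is limited to pooled n <= 12")
        h_obs = _h_statistic(pooled, labels)
        count = total = 0
        sizes = [a.size for a in arrays]
        idx = list(range(n))

        def recurse(remaining: tuple, gi: int, assign: dict):
            nonlocal count, total
            if gi == len(sizes) - 1:
                lab = np.empty(n, dtype=int)
                for g2, members in assign.items():
                    lab[list(members)] = g2
                lab[list(remaining)] = gi
                total += 1
                if _h_statistic(pooled, lab) >= h_obs - 1e-12:
                    count += 1
                return
            for comb in itertools.combinations(remaining, sizes[gi]):
                rest = tuple(sorted(set(remaining) - set(comb)))
                assign[gi] = comb
                recurse(rest, gi + 1, assign)
            assign.pop(gi, None)

        recurse(tuple(idx), 0, {})
        p = count / total
        h = h_obs
    # Dunn post-hoc on tie-corrected rank means
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts ** 3 - counts).sum())
    pairs = list(itertools.combinations(range(len(names)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        ri = ranks[labels == i].mean()
        rj = ranks[labels == j].mean()
        ni, nj = arrays[i].size, arrays[j].size
        var = (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))) * (1.0 / ni + 1.0 / nj)
        if var <= 0:
            z, pij = 0.0, 1.0
        else:
            z = (ri - rj) / math.sqrt(var)
            pij = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        rows.append({"group1": names[i], "group2": names[j], "z": float(z),
                     "p_adj": float(pij), "reject": pij < 0.05})
    return {"H": float(h), "p_value": float(p),
            "pairwise": pd.DataFrame(rows)}


def _compact_letters(names: list[str], means: dict, pairwise: pd.DataFrame) -> dict:
    """Compact letter display: groups sharing a letter are not distinguishable.

    Groups are ordered by mean; maximal runs of mutually non-significant
    groups get one letter each (means of nuclear sizes order naturally, so
    the non-significance relation is effectively an interval graph).
    """
    order = sorted(names, key=lambda g: means[g])
    sig = {}
    for _, r in pairwise.iterrows():
        sig[frozenset((r["group1"], r["group2"]))] = bool(r["reject"])
    runs = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and all(
                not sig.get(frozenset((order[a], order[j + 1])), False)
                for a in range(i, j + 1)):
            j += 1
        runs.append((i, j))
        i = i + 1 if j + 1 < len(order) else j + 1
    # drop runs nested in another run
    runs = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1]
                                       for o in runs)]
    letters = {g: "" for g in names}
    for li, (a, b) in enumerate(sorted(set(runs))):
        ch = chr(ord("a") + li)
        for g in order[a:b + 1]:
            letters[g] += ch
    return letters


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table invariants; returns the table."""
    has_area = "area_um2" in table.columns
    has_vol = "volume_um3" in table.columns
    if not (has_area or has_vol):
        raise ValueError("measurement table needs area_um2 and/or volume_um3")
    a = table["area_um2"] if has_area else pd.Series(np.nan, index=table.index)
    v = table["volume_um3"] if has_vol else pd.Series(np.nan, index=table.index)
    if (a.isna() & v.isna()).any():
        raise ValueError("every row needs at least one of area_um2/volume_um3")
    for col, s in (("area_um2", a), ("volume_um3", v)):
        if (s.dropna() <= 0).any():
            raise ValueError(f"{col} values must be positive")
    return table


def summarize_case_study(table: pd.DataFrame, grouping,
                         value: str | None = None) -> dict:
    """Per-group descriptive statistics plus the nonparametric group test.

    ``grouping`` is a column name or list of names present in the table;
    ``value`` defaults to volume_um3 when present, else area_um2. With two or
    more groups a Kruskal–Wallis + Dunn comparison is run and each group gets
    a compact-letter label (groups sharing a letter are not significantly
    different at α = 0.05).
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    for g in grouping:
        if g not in table.columns:
            raise ValueError(f"unknown grouping field {g!r}")
    if value is None:
        value = "volume_um3" if "volume_um3" in table.columns else "area_um2"
    if value not in table.columns:
        raise ValueError(f"value column {value!r} not in table")
    sub = table.dropna(subset=[value])
    grouped = sub.groupby(grouping, sort=True)[value]
    summary = grouped.agg(n="count", mean="mean", sd="std", median="median",
                          q1=lambda s: s.quantile(0.25),
                          q3=lambda s: s.quantile(0.75)).reset_index()
    groups = {(" / ".join(map(str, k)) if isinstance(k, tuple) else str(k)): v.values
              for k, v in grouped}
    result: dict = {"summary": summary, "value": value}
    if len(groups) >= 2 and all(len(v) > 0 for v in groups.values()):
        kd = kruskal_dunn(groups)
        means = {g: float(np.mean(v)) for g, v in groups.items()}
        letters = _compact_letters(list(groups.keys()), means, kd["pairwise"])
        keys = [" / ".join(map(str, row)) if len(grouping) > 1 else str(row[0])
                for row in summary[grouping].itertuples(index=False)]
        summary["letters"] = [letters[k] for k in keys]
        result["kruskal_dunn"] = kd
    return result
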