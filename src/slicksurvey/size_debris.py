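"""Size-structure and debris analyses.

* 1-mm size-frequency histograms of larval total length per habitat,
* per-5-mm-bin occurrence proportions (bootstrapped slick share of mean
  density) feeding a beta regression of occurrence probability on length,
* OLS of log fish density on log debris mass per size class and habitat,
* confound screens: one-way ANOVAs of log response ratios on survey design
  factors, and an ANCOVA of log density on debris, time-of-day and habitat.

Size-class edges follow half-open intervals [0,5), [5,10), [10,15),
[15,20), [20, inf) mm so every length falls in exactly one class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import expit, logit
from statsmodels.othermod.betareg import BetaModel

from .data_model import Survey
from .resampling import _boot_means

SIZE_CLASS_EDGES = [0, 5, 10, 15, 20, np.inf]
SIZE_CLASS_LABELS = ["<5", "5-10", "10-15", "15-20", ">20"]


def _fish_length_rows(survey: Survey) -> pd.DataFrame:
    """Count rows carrying a total length, joined with habitat and volume."""
    counts = survey.counts
    if "total_length_mm" not in counts.columns:
        raise ValueError("counts table has no total_length_mm column")
    rows = counts.dropna(subset=["total_length_mm"]).copy()
    rows["total_length_mm"] = rows["total_length_mm"].astype(float)
    rows["habitat"] = rows["tow_id"].map(survey.habitat)
    rows["volume"] = rows["tow_id"].map(survey.volumes)
    return rows


def expand_lengths(survey: Survey) -> pd.DataFrame:
    """One row per measured fish (count rows repeated by their count)."""
    rows = _fish_length_rows(survey)
    return rows.loc[rows.index.repeat(rows["count"].astype(int))].reset_index(drop=True)


def size_histogram(survey: Survey, bin_mm: int = 1) -> pd.DataFrame:
    """Length-frequency counts per habitat in ``bin_mm`` bins.

    Returns a bins x habitat DataFrame of integer counts; column sums equal
    the number of measured fish per habitat.
    """
    fish = expand_lengths(survey)
    bins = np.arange(0, fish["total_length_mm"].max() + 2 * bin_mm, bin_mm)
    fish["bin_low"] = pd.cut(
        fish["total_length_mm"], bins=bins, right=False,
        labels=bins[:-1].astype(int),
    )
    hist = (
        fish.groupby(["bin_low", "habitat"], observed=True)["count"]
        .count()
        .unstack(fill_value=0)
    )
    return hist


def per_tow_bin_densities(survey: Survey, bin_mm: int = 5) -> dict[str, pd.DataFrame]:
    """Per-tow fish densities for every length bin.

    Returns {bin label: DataFrame(tow_id, habitat, density)} where density
    is the summed count of fish in that bin divided by the tow volume; tows
    with no fish in the bin get 0.
    """
    rows = _fish_length_rows(survey)
    top = float(rows["total_length_mm"].max()) if len(rows) else bin_mm
    edges = np.arange(0, top + 2 * bin_mm, bin_mm)
    rows["bin_low"] = pd.cut(
        rows["total_length_mm"], bins=edges, right=False,
        labels=edges[:-1].astype(int),
    ).astype(int)
    base = survey.tows[["tow_id", "habitat"]].copy()
    base["volume"] = base["tow_id"].map(survey.volumes)
    out = {}
    for lo, sub in rows.groupby("bin_low"):
        per_tow = sub.groupby("tow_id")["count"].sum()
        df = base.copy()
        df["density"] = df["tow_id"].map(per_tow).fillna(0.0) / df["volume"]
        out[int(lo)] = df[["tow_id", "habitat", "density"]]
    return out


def squeeze_proportions(p: np.ndarray, n: int) -> np.ndarray:
    """Pull observed proportions off the {0, 1} boundary.

    The standard transform for beta-regression responses:
    (p * (n - 1) + 0.5) / n, with n the number of observations (bins).
    """
    p = np.asarray(p, dtype=float)
    return (p * (n - 1) + 0.5) / n


def occurrence_proportions(
    survey: Survey,
    bin_mm: int = 5,
    nboot: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Slick-occurrence proportion per length bin, from bootstrapped means.

    For each ``bin_mm`` size class, the per-habitat mean density is
    bootstrapped and the proportion p = d̄_slick / (d̄_slick + d̄_ambient)
    formed from the bootstrap grand means. Bins empty in both habitats are
    dropped with a warning; the ``p_squeezed`` column applies
    :func:`squeeze_proportions` so the response is strictly inside (0, 1)
    for the beta regression.

    Columns: bin_low_mm, bin_high_mm, bin_mid_mm, mean_density_slick,
    mean_density_ambient, p, p_squeezed, n_fish.
    """
    rng = np.random.default_rng(seed)
    per_bin = per_tow_bin_densities(survey, bin_mm=bin_mm)
    fish = _fish_length_rows(survey)
    rows = []
    for lo, df in sorted(per_bin.items()):
        s = df.loc[df["habitat"] == "slick", "density"].to_numpy(dtype=float)
        a = df.loc[df["habitat"] == "ambient", "density"].to_numpy(dtype=float)
        mean_s = float(_boot_means(s, nboot, rng).mean()) if s.size else 0.0
        mean_a = float(_boot_means(a, nboot, rng).mean()) if a.size else 0.0
        if mean_s + mean_a == 0:
            warnings.warn(f"bin [{lo},{lo + bin_mm}) empty in both habitats; dropped")
            continue
        in_bin = (fish["total_length_mm"] >= lo) & (fish["total_length_mm"] < lo + bin_mm)
        rows.append({
            "bin_low_mm": lo, "bin_high_mm": lo + bin_mm,
            "bin_mid_mm": lo + bin_mm / 2.0,
            "mean_density_slick": mean_s, "mean_density_ambient": mean_a,
            "p": mean_s / (mean_s + mean_a),
            "n_fish": int(fish.loc[in_bin, "count"].sum()),
        })
    table = pd.DataFrame(rows)
    table["p_squeezed"] = squeeze_proportions(table["p"].to_numpy(), len(table))
    return table


@dataclass
class BetaRegResult:
    """Beta regression of occurrence proportion on length (logit mean link,
    constant precision)."""

    intercept: float
    slope: float                 # logit-scale change per mm
    z_statistic: float           # slope / SE(slope)
    slope_se: float
    p_value: float
    pseudo_r2: float             # squared corr of link-scale fit vs logit(p)
    precision: float             # phi
    converged: bool
    fitted_curve: Callable[[np.ndarray], np.ndarray]

    def predict(self, lengths_mm) -> np.ndarray:
        return self.fitted_curve(np.asarray(lengths_mm, dtype=float))


def beta_regression(
    size_table: pd.DataFrame,
    response: str = "p_squeezed",
    covariate: str = "bin_mid_mm",
) -> BetaRegResult:
    """Maximum-likelihood beta regression of proportion on size.

    The mean follows a logit-linear model in the bin midpoint; the precision
    parameter is a single constant. The z statistic is slope / SE with the
    SE from the inverse observed information at the optimum, and pseudo-R^2
    is the squared correlation between the link-scale fitted values and the
    logit of the observations (the convention of standard beta-regression
    software). Requires >= 4 usable bins strictly inside (0, 1).
    """
    table = size_table.dropna(subset=[response, covariate])
    p = table[response].to_numpy(dtype=float)
    x = table[covariate].to_numpy(dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("responses must be strictly inside (0, 1); squeeze first")
    if len(p) < 4:
        raise ValueError(f"need >= 4 bins, got {len(p)}")
    exog = sm.add_constant(x)
    model = BetaModel(endog=p, exog=exog)
    # robust start values: OLS on the logit scale + moment estimate of phi
    # (the library default start heuristic fails near the boundary)
    eta = logit(p)
    ols = sm.OLS(eta, exog).fit()
    mu0 = expit(ols.fittedvalues)
    resid_var = max(float(np.var(p - mu0)), 1e-6)
    phi0 = float(np.clip(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0, 1e3))
    start = np.concatenate([ols.params, [np.log(phi0)]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(start_params=start, disp=False)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {fit.mle_retvals}")
    intercept, slope = fit.params[0], fit.params[1]
    se = fit.bse[1]
    eta_hat = intercept + slope * x
    r = np.corrcoef(eta_hat, logit(p))[0, 1]
    return BetaRegResult(
        intercept=float(intercept), slope=float(slope),
        z_statistic=float(slope / se), slope_se=float(se),
        p_value=float(fit.pvalues[1]),
        pseudo_r2=float(r**2),
        precision=float(np.exp(fit.params[-1])
                        if model.link_precision.__class__.__name__ == "Log"
                        else fit.params[-1]),
        converged=True,
        fitted_curve=lambda L: expit(intercept + slope * np.asarray(L, dtype=float)),
    )


def debris_density_regression(
    survey: Survey, min_points: int = 3
) -> pd.DataFrame:
    """OLS of log10 fish density on log10 debris mass per size class/habitat.

    Fish density is the per-tow density of fish in the size class
    ({<5, 5-10, 10-15, 15-20, >20} mm); tows with zero density in the class
    (or zero debris) are excluded before logs. Strata with fewer than
    ``min_points`` tows are skipped with a warning. Columns: size_class,
    habitat, n, slope, r2, F, p.
    """
    from .data_model import debris_densities

    debris = debris_densities(survey).data.loc["debris_all"]
    rows = _fish_length_rows(survey)
    base = survey.tows[["tow_id", "habitat"]].copy()
    base["volume"] = base["tow_id"].map(survey.volumes)
    results = []
    for lo, hi, label in zip(SIZE_CLASS_EDGES[:-1], SIZE_CLASS_EDGES[1:], SIZE_CLASS_LABELS):
        sub = rows[(rows["total_length_mm"] >= lo) & (rows["total_length_mm"] < hi)]
        per_tow = sub.groupby("tow_id")["count"].sum()
        df = base.copy()
        df["density"] = df["tow_id"].map(per_tow).fillna(0.0) / df["volume"]
        df["debris"] = df["tow_id"].map(debris)
        for hab in ("slick", "ambient"):
            stratum = df[(df["habitat"] == hab) & (df["density"] > 0) & (df["debris"] > 0)]
            if len(stratum) < min_points:
                warnings.warn(
                    f"size class {label} / {hab}: only {len(stratum)} points, skipped"
                )
                continue
            fit = sm.OLS(
                np.log10(stratum["density"].to_numpy()),
                sm.add_constant(np.log10(stratum["debris"].to_numpy())),
            ).fit()
            results.append({
                "size_class": label, "habitat": hab, "n": int(len(stratum)),
                "slope": float(fit.params[1]), "r2": float(fit.rsquared),
                "F": float(fit.fvalue), "p": float(fit.f_pvalue),
            })
    return pd.DataFrame(results)


def paired_log_response_ratios(
    survey: Survey, group_rows: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-pair log response ratio of total fish density, with design factors.

    For every pair_id with one slick and one ambient tow, computes
    log((density_slick + eps) / (density_ambient + eps)) of summed fish
    counts over volume, carrying year/day/gear/sampling-order columns for
    the confound screens. eps is half the smallest positive density so
    zero-density members stay usable.
    """
    counts = survey.counts if group_rows is None else group_rows
    per_tow = counts.groupby("tow_id")["count"].sum()
    dens = (per_tow / survey.volumes).reindex(survey.tow_ids).fillna(0.0)
    tows = survey.tows.set_index("tow_id")
    pairs = []
    eps_pool = dens[dens > 0]
    eps = float(eps_pool.min()) / 2.0 if len(eps_pool) else 1.0
    valid = tows.dropna(subset=["pair_id"]) if "pair_id" in tows else tows.iloc[0:0]
    for pair_id, sub in valid.groupby("pair_id"):
        if set(sub["habitat"]) != {"slick", "ambient"}:
            continue
        s_id = sub.index[sub["habitat"] == "slick"][0]
        a_id = sub.index[sub["habitat"] == "ambient"][0]
        row = {"pair_id": pair_id,
               "log_ratio": float(np.log((dens[s_id] + eps) / (dens[a_id] + eps)))}
        for factor in ("year", "day", "gear", "sampling_order", "date"):
            if factor in sub.columns:
                row[factor] = sub.loc[s_id, factor]
        pairs.append(row)
    return pd.DataFrame(pairs)


def confound_screen(
    pair_table: pd.DataFrame,
    factors: tuple[str, ...] = ("year", "day", "gear", "sampling_order"),
) -> pd.DataFrame:
    """One-way ANOVA of log response ratios on each survey design factor.

    Single-level factors are skipped. Returns one row per factor with
    (factor, df_num, df_den, F, p).
    """
    out = []
    for factor in factors:
        if factor not in pair_table.columns:
            continue
        sub = pair_table.dropna(subset=[factor, "log_ratio"]).copy()
        sub["_f"] = sub[factor].astype(str)
        if sub["_f"].nunique() < 2:
            warnings.warn(f"factor {factor!r} has a single level; skipped")
            continue
        fit = smf.ols("log_ratio ~ C(_f)", data=sub).fit()
        anova = sm.stats.anova_lm(fit, typ=1)
        out.append({
            "factor": factor,
            "df_num": float(anova.loc["C(_f)", "df"]),
            "df_den": float(anova.loc["Residual", "df"]),
            "F": float(anova.loc["C(_f)", "F"]),
            "p": float(anova.loc["C(_f)", "PR(>F)"]),
        })
    return pd.DataFrame(out)


def ancova(
    survey: Survey,
    subset: str = "all",
) -> pd.DataFrame:
    """ANCOVA of log fish density on log debris mass, time-of-day and habitat.

    ``subset`` selects the fish rows: 'all', 'small' (TL < 10 mm) or
    'large' (TL > 10 mm). Tows with zero density in the subset are excluded
    before the log, following the regression convention. Returns the type-II
    ANOVA table (term, sum_sq, df, F, p).
    """
    rows = _fish_length_rows(survey)
    if subset == "small":
        rows = rows[rows["total_length_mm"] < 10]
    elif subset == "large":
        rows = rows[rows["total_length_mm"] > 10]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    from .data_model import debris_densities

    debris = debris_densities(survey).data.loc["debris_all"]
    per_tow = rows.groupby("tow_id")["count"].sum()
    df = survey.tows[["tow_id", "habitat"]].copy()
    df["volume"] = df["tow_id"].map(survey.volumes)
    df["density"] = df["tow_id"].map(per_tow).fillna(0.0) / df["volume"]
    df["debris"] = df["tow_id"].map(debris)
    if "minutes_from_solar_noon" not in survey.tows.columns:
        raise ValueError("tows table has no minutes_from_solar_noon column")
    df["minutes"] = df["tow_id"].map(
        survey.tows.set_index("tow_id")["minutes_from_solar_noon"]
    ).astype(float)
    df = df[(df["density"] > 0) & (df["debris"] > 0)].copy()
    df["log_density"] = np.log10(df["density"])
    df["log_debris"] = np.log10(df["debris"])
    fit = smf.ols("log_density ~ log_debris + minutes + C(habitat)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2).reset_index(names="term")
    table = table.rename(columns={"PR(>F)": "p"})
    return table
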