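"""Balanced two-way ANOVA, variance components, heritability and BLUP.

The trial design is a balanced factorial: G genotypes × p phosphorus
regimes × r replicates. Sums of squares are the classical balanced-design
decomposition computed from cell and marginal means; variance components
come from equating observed to expected mean squares

    E[MS_e]   = σ²e
    E[MS_GxP] = σ²e + r σ²GP
    E[MS_G]   = σ²e + r σ²GP + p r σ²G

and broad-sense heritability on a genotype-mean basis is

    H² = σ²G / (σ²G + σ²GP/p + σ²e/(p r)).

All F statistics are tested against the error mean square; this matches
reporting a single p-value per factor in a fixed-effects view and is a
documented choice, not the only defensible one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trait_io import PanelError, validate_panel

__all__ = [
    "AnovaResult",
    "VarianceComponents",
    "anova_two_way",
    "variance_components",
    "cv_percent",
    "blup_means",
    "regime_t_test",
    "anova_table",
]


@dataclass
class AnovaResult:
    """Balanced two-way ANOVA decomposition for one trait."""

    trait: str
    grand_mean: float
    n_genotypes: int
    n_regimes: int
    n_replicates: int
    ss: dict[str, float]        # keys: G, P, GxP, error, total
    df: dict[str, int]
    ms: dict[str, float]
    f: dict[str, float]         # keys: G, P, GxP; NaN when undefined
    p: dict[str, float]

    @property
    def cv_percent(self) -> float:
        return cv_percent(self)


@dataclass
class VarianceComponents:
    """Moment estimates of σ²G, σ²GP, σ²e and broad-sense H²."""

    trait: str
    var_g: float
    var_gp: float
    var_e: float
    heritability: float
    truncated: tuple[str, ...] = ()   # components clipped at zero


def _trait_array(panel: pd.DataFrame, trait: str) -> np.ndarray:
    """Reshape one trait's observations to (G, p, r), sorted keys."""
    sub = panel.loc[panel["trait"] == trait]
    if sub.empty:
        raise PanelError(f"trait {trait!r} absent from panel")
    wide = sub.pivot_table(
        index="genotype", columns=["regime", "replicate"], values="value",
        sort=True,
    )
    if wide.isna().any().any():
        raise PanelError(
            f"trait {trait!r} is unbalanced; run validate_panel for details"
        )
    n_g = wide.shape[0]
    regimes = wide.columns.get_level_values(0).unique()
    reps = wide.columns.get_level_values(1).unique()
    return wide.to_numpy().reshape(n_g, len(regimes), len(reps))


def anova_two_way(panel: pd.DataFrame, trait: str) -> AnovaResult:
    """Classical balanced two-way ANOVA with replication for one trait.

    Requires ≥2 genotypes, ≥2 regimes and ≥2 replicates with every cell
    filled. When the total sum of squares is zero the F ratios are
    reported as NaN (not applicable) rather than raising.
    """
    y = _trait_array(panel, trait)
    g, p, r = y.shape
    if g < 2 or p < 2 or r < 2:
        raise PanelError(
            f"two-way ANOVA needs ≥2 genotypes, ≥2 regimes, ≥2 replicates; "
            f"got {g}×{p}×{r}"
        )
    grand = y.mean()
    cell = y.mean(axis=2)              # genotype × regime means
    gm = y.mean(axis=(1, 2))           # genotype margins
    pm = y.mean(axis=(0, 2))           # regime margins

    ss_g = p * r * np.sum((gm - grand) ** 2)
    ss_p = g * r * np.sum((pm - grand) ** 2)
    ss_gp = r * np.sum((cell - gm[:, None] - pm[None, :] + grand) ** 2)
    ss_e = np.sum((y - cell[:, :, None]) ** 2)
    ss_tot = np.sum((y - grand) ** 2)

    df = {"G": g - 1, "P": p - 1, "GxP": (g - 1) * (p - 1),
          "error": g * p * (r - 1)}
    df["total"] = sum(df.values())
    ss = {"G": ss_g, "P": ss_p, "GxP": ss_gp, "error": ss_e, "total": ss_tot}
    ms = {k: ss[k] / df[k] for k in ("G", "P", "GxP", "error")}

    f, pv = {}, {}
    for k in ("G", "P", "GxP"):
        if ms["error"] > 0:
            f[k] = ms[k] / ms["error"]
            pv[k] = float(stats.f.sf(f[k], df[k], df["error"]))
        else:
            f[k] = float("nan")
            pv[k] = float("nan")

    return AnovaResult(
        trait=trait, grand_mean=float(grand),
        n_genotypes=g, n_regimes=p, n_replicates=r,
        ss={k: float(v) for k, v in ss.items()}, df=df,
        ms={k: float(v) for k, v in ms.items()}, f=f, p=pv,
    )


def variance_components(
    anova: AnovaResult, r: int | None = None, p: int | None = None
) -> VarianceComponents:
    """Expected-mean-squares variance components and heritability.

    Negative moment estimates are truncated at zero and recorded in
    ``truncated``; H² then uses the truncated values so it stays in [0, 1].
    """
    r = anova.n_replicates if r is None else r
    p = anova.n_regimes if p is None else p
    if r <= 0 or p <= 1:
        raise ValueError("need r ≥ 1 replicates and p ≥ 2 regimes")
    var_e = anova.ms["error"]
    var_gp = (anova.ms["GxP"] - anova.ms["error"]) / r
    var_g = (anova.ms["G"] - anova.ms["GxP"]) / (p * r)
    truncated = tuple(
        name for name, v in (("var_gp", var_gp), ("var_g", var_g)) if v < 0
    )
    var_gp = max(var_gp, 0.0)
    var_g = max(var_g, 0.0)
    denom = var_g + var_gp / p + var_e / (p * r)
    h2 = var_g / denom if denom > 0 else 0.0
    return VarianceComponents(
        trait=anova.trait, var_g=float(var_g), var_gp=float(var_gp),
        var_e=float(var_e), heritability=float(h2), truncated=truncated,
    )


def cv_percent(anova: AnovaResult) -> float:
    """Residual coefficient of variation, 100·√MS_error / |grand mean|."""
    if anova.grand_mean == 0:
        raise ValueError("CV undefined for zero grand mean")
    return 100.0 * float(np.sqrt(anova.ms["error"])) / abs(anova.grand_mean)


def blup_means(panel: pd.DataFrame, trait: str, regime: str) -> pd.Series:
    """Shrunken genotype means for one trait within one regime.

    Fits the one-way random-genotype model y_ik = μ + g_i + e_ik by the
    method of moments and returns BLUP_i = μ̂ + k·(ȳ_i − μ̂) with shrinkage
    k = σ̂²G / (σ̂²G + σ̂²e/r), clipped to [0, 1]. With no apparent genotype
    variance every prediction collapses to the grand mean.
    """
    sub = panel.loc[(panel["trait"] == trait) & (panel["regime"] == regime)]
    if sub.empty:
        raise PanelError(f"no data for trait {trait!r} in regime {regime!r}")
    counts = sub.groupby("genotype")["value"].size()
    if counts.nunique() != 1 or counts.iloc[0] < 2:
        raise PanelError(
            "BLUP needs a balanced layout with ≥2 replicates per genotype"
        )
    r = int(counts.iloc[0])
    means = sub.groupby("genotype", sort=True)["value"].mean()
    mu = sub["value"].mean()
    g = len(means)

    ss_between = r * np.sum((means - mu) ** 2)
    ss_within = np.sum((sub["value"] - means.reindex(sub["genotype"]).values) ** 2)
    ms_between = ss_between / (g - 1)
    ms_within = ss_within / (g * (r - 1))
    var_g = max((ms_between - ms_within) / r, 0.0)
    var_e = ms_within
    k = var_g / (var_g + var_e / r) if (var_g + var_e / r) > 0 else 0.0
    return mu + k * (means - mu)


def regime_t_test(
    summary: pd.DataFrame, trait: str, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided independent t-test of genotype summaries between regimes.

    Welch's unequal-variance form by default; set ``equal_var=True`` for the
    pooled-variance variant. Returns (t, p)."""
    sub = summary.loc[summary["trait"] == trait]
    regimes = sorted(sub["regime"].unique())
    if len(regimes) != 2:
        raise ValueError(f"need exactly 2 regimes for trait {trait!r}, got {regimes}")
    a = sub.loc[sub["regime"] == regimes[0], "value"].to_numpy()
    b = sub.loc[sub["regime"] == regimes[1], "value"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each regime needs at least 2 genotype values")
    if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(a) == 0 == np.ptp(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def anova_table(panel: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait ANOVA report: mean squares, p-values, CV% and H².

    One row per trait, shaped like the variance-component summary tables
    of multi-environment trial reports.
    """
    report = validate_panel(panel)
    if not report.balanced:
        raise PanelError(
            f"ANOVA requires a balanced panel ({report}); "
            "see trait_io.validate_panel"
        )
    traits = traits or sorted(panel["trait"].unique())
    rows = []
    for t in traits:
        a = anova_two_way(panel, t)
        vc = variance_components(a)
        rows.append({
            "trait": t,
            "df_G": a.df["G"], "df_P": a.df["P"], "df_GxP": a.df["GxP"],
            "df_error": a.df["error"],
            "MS_G": a.ms["G"], "MS_P": a.ms["P"], "MS_GxP": a.ms["GxP"],
            "MS_error": a.ms["error"],
            "p_G": a.p["G"], "p_P": a.p["P"], "p_GxP": a.p["GxP"],
            "CV_percent": cv_percent(a),
            "var_G": vc.var_g, "var_GP": vc.var_gp, "var_e": vc.var_e,
            "H2": vc.heritability,
        })
    return pd.DataFrame(rows)
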