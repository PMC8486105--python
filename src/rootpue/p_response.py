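"""Phosphorus response coefficients, fuzzy membership, and the CPRI.

A genotype's response to phosphorus limitation is summarised per trait by
the P response coefficient

    PRC_ij = X_ij(LP) / X_ij(NLP),

the ratio of its trait-j summary value under limiting (LP) vs non-limiting
(NLP) phosphorus. Within each trait the coefficients are rescaled across
genotypes to fuzzy membership values

    U_ij = (PRC_ij − min_j) / (max_j − min_j) ∈ [0, 1]

(the fuzzy-subordination step), and the comprehensive P response index
aggregates them with PRC-magnitude weights

    CPRI_i = Σ_j U_ij · |PRC_ij| / Σ_j |PRC_ij|.

CPRI is 1 exactly when a genotype attains the trait-wise maximum PRC for
every included trait, 0 when it attains the minimum everywhere, and is
the basis of a five-class responsiveness grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "prc",
    "prc_trait_summary",
    "membership",
    "cpri",
    "classify_response",
    "rank_and_summarize",
    "CLASS_BOUNDS",
]

#: Responsiveness class upper bounds on CPRI: class 1 is (0.70, 1], class 5
#: is [0, 0.10]. Intervals are half-open at the lower edge so each CPRI
#: falls in exactly one class; a boundary value takes the lower class
#: number's *lower* neighbour (0.70 → class 2).
CLASS_BOUNDS: tuple[float, ...] = (0.10, 0.30, 0.50, 0.70)


@dataclass
class ResponseMatrix:
    """Per-genotype × trait P response coefficients and memberships.

    ``prc`` and ``membership`` are genotype × trait DataFrames; excluded
    entries (undefined ratios) are NaN with the reason recorded in
    ``excluded``. ``degenerate_traits`` lists traits whose PRC range
    collapsed (max = min) and which therefore carry no membership signal.
    """

    prc: pd.DataFrame
    membership: pd.DataFrame | None = None
    excluded: list[tuple[str, str, str]] = field(default_factory=list)
    degenerate_traits: list[str] = field(default_factory=list)

    @property
    def trait_min(self) -> pd.Series:
        return self.prc.min(axis=0)

    @property
    def trait_max(self) -> pd.Series:
        return self.prc.max(axis=0)


def _summary_wide(summary: pd.DataFrame, regime: str) -> pd.DataFrame:
    sub = summary.loc[summary["regime"] == regime]
    return sub.pivot_table(index="genotype", columns="trait", values="value",
                           sort=True)


def prc(summary: pd.DataFrame, reference: str = "NLP",
        limiting: str = "LP") -> ResponseMatrix:
    """Per-genotype P response coefficients from a trait summary.

    ``summary`` is the long frame from
    :func:`rootpue.trait_io.summarize_panel` (raw means or BLUPs — the
    choice is the caller's and is carried through to reports). Entries
    whose reference-regime value is ≤ 0 are excluded (NaN) rather than
    emitted as infinities.
    """
    ref = _summary_wide(summary, reference)
    lim = _summary_wide(summary, limiting)
    missing = ref.index.symmetric_difference(lim.index)
    if len(missing):
        raise ValueError(
            f"genotype(s) missing one regime: {list(missing[:5])}"
        )
    lim = lim.reindex(index=ref.index, columns=ref.columns)
    if lim.isna().any().any() or ref.isna().any().any():
        bad = sorted(set(ref.columns[ref.isna().any()]) |
                     set(lim.columns[lim.isna().any()]))
        raise ValueError(f"incomplete summaries for traits {bad}")

    ratios = lim / ref
    excluded = []
    bad = ref <= 0
    for g, t in zip(*np.where(bad.to_numpy())):
        excluded.append((ref.index[g], ref.columns[t], "non-positive reference"))
    ratios = ratios.mask(bad)
    return ResponseMatrix(prc=ratios, excluded=excluded)


def prc_trait_summary(summary: pd.DataFrame, reference: str = "NLP",
                      limiting: str = "LP") -> pd.DataFrame:
    """Per-trait mean P response.

    Reports both conventions: ``prc_ratio_of_means`` (mean LP value over
    mean NLP value — the headline figure) and ``prc_mean_of_ratios`` (the
    average of per-genotype coefficients). They differ whenever genotype
    means and ratios are correlated, so both are surfaced.
    """
    ref = _summary_wide(summary, reference)
    lim = _summary_wide(summary, limiting)
    rm = prc(summary, reference, limiting)
    return pd.DataFrame({
        "trait": ref.columns,
        f"mean_{reference}": ref.mean(axis=0).values,
        f"mean_{limiting}": lim.mean(axis=0).values,
        "prc_ratio_of_means": (lim.mean(axis=0) / ref.mean(axis=0)).values,
        "prc_mean_of_ratios": rm.prc.mean(axis=0).values,
    }).reset_index(drop=True)


def membership(response: ResponseMatrix) -> ResponseMatrix:
    """Min–max rescale PRC within each trait to membership values U ∈ [0, 1].

    Traits with fewer than 2 included genotypes or a collapsed range
    (max = min) are flagged degenerate and their memberships set to NaN;
    they are dropped from the CPRI with renormalised weights.
    """
    p = response.prc
    lo, hi = p.min(axis=0), p.max(axis=0)
    span = hi - lo
    degenerate = [
        str(t) for t in p.columns
        if p[t].notna().sum() < 2 or span[t] == 0
    ]
    u = (p - lo) / span.replace(0, np.nan)
    u[degenerate] = np.nan
    return ResponseMatrix(
        prc=p, membership=u, excluded=list(response.excluded),
        degenerate_traits=degenerate,
    )


def cpri(response: ResponseMatrix) -> pd.DataFrame:
    """Comprehensive P response index per genotype.

    Weights each membership value by the genotype's own |PRC| share over
    its included, non-degenerate traits; weights sum to 1 per genotype so
    CPRI lies in [0, 1]. Returns a frame (genotype, cpri, response_class,
    rank) sorted by rank; ties rank by genotype label.
    """
    if response.membership is None:
        response = membership(response)
    u = response.membership.drop(columns=response.degenerate_traits)
    p = response.prc.drop(columns=response.degenerate_traits)
    if u.shape[1] == 0:
        raise ValueError("no non-degenerate traits; CPRI undefined")
    w = p.abs()
    included = u.notna() & w.notna()
    if (~included).all(axis=1).any():
        bad = u.index[(~included).all(axis=1)]
        raise ValueError(f"genotype(s) with no usable traits: {list(bad[:5])}")
    w = w.where(included)
    w = w.div(w.sum(axis=1), axis=0)
    # round-off in the weight renormalisation can push an extremal score
    # a few ulp outside [0, 1]; clip so the contract holds exactly
    scores = (u * w).sum(axis=1).clip(0.0, 1.0)

    out = pd.DataFrame({
        "genotype": scores.index,
        "cpri": scores.values,
    })
    out["response_class"] = classify_response(out["cpri"].values)
    out = out.sort_values(["cpri", "genotype"], ascending=[False, True],
                          ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def classify_response(values) -> np.ndarray:
    """Five responsiveness classes from CPRI.

    Class 1 (highly responsive): CPRI > 0.70; class 2: (0.50, 0.70];
    class 3: (0.30, 0.50]; class 4: (0.10, 0.30]; class 5: ≤ 0.10.
    Boundaries belong to the weaker-response class.
    """
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("CPRI values must lie in [0, 1]")
    # searchsorted over ascending bounds counts how many cut points are
    # strictly below v; class number descends as CPRI rises.
    n_below = np.searchsorted(CLASS_BOUNDS, v, side="left")
    return (5 - n_below).astype(int)


def rank_and_summarize(
    cpri_result: pd.DataFrame,
    summary: pd.DataFrame,
    k: int = 5,
    reference: str = "NLP",
    limiting: str = "LP",
) -> dict[str, pd.DataFrame]:
    """Top-k / bottom-k genotype tables with per-trait group percent change.

    Percent change for a group is defined here as
    100 × (group-mean LP − group-mean NLP) / group-mean NLP per trait; the
    definition is included in the returned header metadata because other
    summaries (e.g. mean of per-genotype changes) give different numbers.
    """
    if k > len(cpri_result):
        raise ValueError(f"k={k} exceeds {len(cpri_result)} genotypes")
    ranked = cpri_result.sort_values(["cpri", "genotype"],
                                     ascending=[False, True])
    groups = {"top": ranked.head(k), "bottom": ranked.tail(k)}
    wide = summary.pivot_table(index="genotype", columns=["trait", "regime"],
                               values="value", sort=True)
    out = {}
    for name, grp in groups.items():
        table = wide.loc[grp["genotype"]]
        ref_means = table.xs(reference, level="regime", axis=1).mean(axis=0)
        lim_means = table.xs(limiting, level="regime", axis=1).mean(axis=0)
        pct = 100.0 * (lim_means - ref_means) / ref_means
        flat = table.copy()
        flat.columns = [f"{t}_{r}" for t, r in flat.columns]
        flat.insert(0, "cpri", grp.set_index("genotype")["cpri"])
        change = pd.DataFrame({
            "trait": pct.index, "pct_change_group_means": pct.values,
        })
        out[f"{name}_{k}"] = flat.reset_index()
        out[f"{name}_{k}_pct_change"] = change
    out["definition"] = pd.DataFrame({
        "key": ["pct_change"],
        "value": ["100*(group_mean_LP - group_mean_NLP)/group_mean_NLP"],
    })
    return out
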