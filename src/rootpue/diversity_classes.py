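"""Performance classes and Shannon–Weaver phenotypic diversity.

For each trait × regime, genotype summary values are split into three
performance classes around the genotype mean x̄ and standard deviation SD:
low (< x̄ − SD), medium ([x̄ − SD, x̄ + SD]) and high (> x̄ + SD). The SD is
the sample (n−1) standard deviation; values exactly on a threshold are
labelled medium. Diversity of the resulting class distribution is the
Shannon–Weaver index over the three class proportions,

    H′ = −Σ_c p_c ln p_c      (natural log, unnormalised, 0·ln 0 ≡ 0),

so H′ ranges from 0 (all genotypes in one class) to ln 3 ≈ 1.0986
(uniform occupancy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassCounts",
    "performance_classes",
    "class_counts",
    "shannon_h",
    "diversity_table",
]

CLASS_LABELS = ("low", "medium", "high")


@dataclass
class ClassCounts:
    """Class occupancy for one trait × regime."""

    trait: str
    regime: str
    counts: tuple[int, int, int]          # (low, medium, high)
    total: int
    thresholds: tuple[float, float]       # (x̄ − SD, x̄ + SD)
    shannon: float

    @property
    def proportions(self) -> tuple[float, float, float]:
        return tuple(c / self.total for c in self.counts)

    @property
    def percentages(self) -> tuple[float, float, float]:
        """Display percentages, rounded to 2 dp."""
        return tuple(round(100.0 * c / self.total, 2) for c in self.counts)


def performance_classes(values: pd.Series | np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Label each genotype low/medium/high around x̄ ± SD.

    Returns (labels, (lower, upper)). With fewer than 2 values the SD is
    undefined, so this raises; with zero SD everything is medium.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("performance classes need at least 2 genotype values")
    mean = v.mean()
    sd = v.std(ddof=1)
    lo, hi = mean - sd, mean + sd
    labels = np.where(v < lo, "low", np.where(v > hi, "high", "medium"))
    return labels, (float(lo), float(hi))


def class_counts(labels: np.ndarray, trait: str = "", regime: str = "",
                 thresholds: tuple[float, float] = (np.nan, np.nan)) -> ClassCounts:
    """Tally low/medium/high labels into a :class:`ClassCounts`."""
    labels = np.asarray(labels)
    counts = tuple(int(np.sum(labels == c)) for c in CLASS_LABELS)
    total = int(labels.size)
    if total == 0:
        raise ValueError("no labels to count")
    return ClassCounts(
        trait=trait, regime=regime, counts=counts, total=total,
        thresholds=thresholds, shannon=shannon_h(counts),
    )


def shannon_h(counts) -> float:
    """Shannon–Weaver index (nats) over class counts.

    Zero-count classes contribute nothing (0·ln 0 ≡ 0); no normalisation
    by ln(number of classes) is applied.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("at least one class count must be positive")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_table(summary: pd.DataFrame,
                    traits: list[str] | None = None) -> pd.DataFrame:
    """Per trait × regime class counts, percentages and H′.

    ``summary`` is a long genotype-summary frame (one value per genotype ×
    regime × trait). One output row per trait × regime, in the style of a
    performance-class diversity table.
    """
    traits = traits or sorted(summary["trait"].unique())
    rows = []
    for trait in traits:
        for regime in sorted(summary.loc[summary["trait"] == trait, "regime"].unique()):
            vals = summary.loc[
                (summary["trait"] == trait) & (summary["regime"] == regime),
                "value",
            ]
            labels, thr = performance_classes(vals)
            cc = class_counts(labels, trait=trait, regime=regime, thresholds=thr)
            n_low, n_med, n_high = cc.counts
            p_low, p_med, p_high = cc.percentages
            rows.append({
                "trait": trait, "regime": regime, "N": cc.total,
                "n_low": n_low, "pct_low": p_low,
                "n_medium": n_med, "pct_medium": p_med,
                "n_high": n_high, "pct_high": p_high,
                "threshold_low": thr[0], "threshold_high": thr[1],
                "shannon_h": cc.shannon,
            })
    return pd.DataFrame(rows)
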