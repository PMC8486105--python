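"""Trait correlation structure, PCA, and diameter-subclass distributions.

Correlations are pairwise Pearson coefficients across genotype summaries
within a regime, with p-values from the t transform on N−2 degrees of
freedom and (matching common practice in trial reports) no multiplicity
adjustment by default; Benjamini–Hochberg adjustment is available by flag.

PCA is run on the correlation matrix (traits standardised to unit
variance) because the trait panel mixes units spanning five orders of
magnitude; observation rows are genotype × regime combinations so regime
shifts show up in the scores.

Subclass distributions express each diameter class's share of a parent
trait as 100 × mean(subclass) / Σ mean(subclasses). The denominator is the
sum of subclass means, not the separately measured parent total; the two
differ by measurement error and the parent-total variant is available by
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from . import traits as trait_registry
from .traits import DIAMETER_INTERVALS, subclass_names

__all__ = [
    "CorrelationMatrix",
    "PcaResult",
    "pearson_matrix",
    "pca_traits",
    "subclass_percent",
    "subclass_table",
]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson structure over genotype summaries."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    regime: str
    adjusted: bool = False


@dataclass
class PcaResult:
    """Correlation-matrix PCA of the trait panel."""

    loadings: pd.DataFrame            # trait × component
    scores: pd.DataFrame              # observation × component
    explained_variance_ratio: np.ndarray
    dropped_traits: list[str]


def pearson_matrix(summary: pd.DataFrame, regime: str,
                   adjust: bool = False) -> CorrelationMatrix:
    """Trait × trait Pearson correlations within one regime.

    Zero-variance traits yield NaN correlations (reported, not raised).
    ``adjust=True`` applies Benjamini–Hochberg to the off-diagonal
    p-values.
    """
    wide = summary.loc[summary["regime"] == regime].pivot_table(
        index="genotype", columns="trait", values="value", sort=True
    )
    n = len(wide)
    if n < 3:
        raise ValueError(f"need ≥3 genotypes for correlations, got {n}")
    x = wide.to_numpy()
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = 0.5 * (r + r.T)        # enforce exact symmetry against round-off
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))

    # two-sided p from t = r sqrt((n-2)/(1-r^2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(p, np.where(sd == 0, np.nan, 0.0))

    cols = wide.columns
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    if adjust:
        iu = np.triu_indices(len(cols), k=1)
        flat = pdf.to_numpy()[iu]
        ok = ~np.isnan(flat)
        adj = flat.copy()
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        out = pdf.to_numpy()
        out[iu] = adj
        out[(iu[1], iu[0])] = adj
        pdf = pd.DataFrame(out, index=cols, columns=cols)
    return CorrelationMatrix(r=rdf, p=pdf, n=n, regime=regime, adjusted=adjust)


def pca_traits(summary: pd.DataFrame,
               regimes: tuple[str, ...] | None = None) -> PcaResult:
    """PCA of standardised traits over pooled genotype × regime rows.

    Constant traits are dropped with a note (they carry no correlation
    signal). Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is made positive.
    """
    sub = summary if regimes is None else summary.loc[summary["regime"].isin(regimes)]
    wide = sub.pivot_table(index=["genotype", "regime"], columns="trait",
                           values="value", sort=True)
    if wide.shape[0] < 3 or wide.shape[1] < 2:
        raise ValueError("PCA needs ≥3 observation rows and ≥2 traits")
    sd = wide.std(axis=0, ddof=1)
    dropped = [str(t) for t in wide.columns[sd == 0]]
    wide = wide.drop(columns=dropped)
    x = (wide - wide.mean(axis=0)) / wide.std(axis=0, ddof=1)

    n_comp = min(x.shape[0] - 1, x.shape[1])
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(x.to_numpy())
    loadings = model.components_.T          # trait × component

    # sign convention: dominant loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(n_comp)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=wide.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=wide.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
        dropped_traits=dropped,
    )


def subclass_percent(summary: pd.DataFrame, parent: str, regime: str,
                     denominator: str = "subclass_sum") -> pd.DataFrame:
    """Percent of a parent trait in each of the 5 diameter classes.

    Computes 100 × mean(subclass_c) / D where D is the sum of the five
    subclass means (``denominator="subclass_sum"``, the default, which
    makes the shares sum to exactly 100) or the mean of the separately
    measured parent trait (``"parent_total"``).
    """
    names = subclass_names(parent)
    sub = summary.loc[(summary["regime"] == regime) &
                      (summary["trait"].isin(names + [parent]))]
    means = sub.groupby("trait")["value"].mean()
    missing = [n for n in names if n not in means.index]
    if missing:
        raise ValueError(f"missing subclass summaries for {parent}: {missing}")
    cls_means = means.reindex(names)
    if denominator == "subclass_sum":
        denom = cls_means.sum()
    elif denominator == "parent_total":
        if parent not in means.index:
            raise ValueError(f"parent trait {parent!r} absent from summary")
        denom = means[parent]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError(f"all {parent} subclasses are zero in {regime}")
    return pd.DataFrame({
        "parent": parent,
        "regime": regime,
        "diameter_mm": DIAMETER_INTERVALS,
        "subclass": names,
        "mean": cls_means.values,
        "percent": 100.0 * cls_means.values / denom,
        "denominator": denominator,
    })


def subclass_table(summary: pd.DataFrame,
                   denominator: str = "subclass_sum") -> pd.DataFrame:
    """Diameter-class distribution for every subclassed parent × regime."""
    frames = []
    for parent in trait_registry.SUBCLASS_PARENTS:
        for regime in sorted(summary["regime"].unique()):
            frames.append(subclass_percent(summary, parent, regime, denominator))
    return pd.concat(frames, ignore_index=True)
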