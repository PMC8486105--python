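"""Synthetic balanced phosphorus-screening trials with known ground truth.

Emulates a hydroponic root-phenotyping screen: G genotypes grown under a
non-limiting (NLP) and a limiting (LP) phosphorus regime with r replicates,
traits generated from the linear model

    y_ijk = μ_t + δ_t·1[regime = LP] + g_i + (gp)_ij + e_ijk

with independent normal effects g ~ N(0, σ²G), (gp) ~ N(0, σ²GP),
e ~ N(0, σ²e). Diameter subclasses are then allocated compositionally:
each parent observation is split over the five diameter intervals by a
Dirichlet draw centred on a regime-specific probability vector, so
subclasses sum to the parent value by construction.

The default configuration mimics a large bread-wheat screen: 182
genotypes × 2 regimes × 3 replicates, trait means raised under LP for
TRL/TSA/TRV/TRT/TRF and lowered for PRL/RAD, residual CVs of ≈6–24% and
broad-sense heritabilities of ≈0.47–0.83, with fine roots (0–0.5 mm)
dominating length/tip subclasses and the dominance strengthening under LP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .traits import (
    ALL_TRAITS,
    N_SUBCLASSES,
    REGIMES,
    SUBCLASS_PARENTS,
    subclass_names,
)
from .trait_io import PANEL_COLUMNS

__all__ = [
    "TraitSpec",
    "TrialConfig",
    "TruthLedger",
    "generate_trial",
    "generate_subclasses",
    "default_config",
    "ConfigError",
]

#: Truncation floor for physically non-negative traits (trait units).
POSITIVE_FLOOR = 1e-6


class ConfigError(ValueError):
    """Invalid trial configuration."""


@dataclass
class TraitSpec:
    """Generating parameters for one trait.

    ``shift`` is the LP offset: additive on the trait scale by default, or
    a multiplicative factor on the mean when ``shift_type`` is
    ``"multiplicative"`` (useful to dial in a target mean response ratio
    directly).
    """

    mean: float
    shift: float = 0.0
    var_g: float = 0.0
    var_gp: float = 0.0
    var_e: float = 0.0
    shift_type: str = "additive"

    def __post_init__(self) -> None:
        for name in ("var_g", "var_gp", "var_e"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be ≥ 0, got {getattr(self, name)}")
        if self.shift_type not in ("additive", "multiplicative"):
            raise ConfigError(f"unknown shift_type {self.shift_type!r}")

    def regime_mean(self, limiting: bool) -> float:
        if not limiting:
            return self.mean
        if self.shift_type == "additive":
            return self.mean + self.shift
        return self.mean * self.shift


@dataclass
class TrialConfig:
    """Design and generating model of a synthetic screening trial."""

    n_genotypes: int = 182
    n_replicates: int = 3
    regimes: tuple[str, str] = REGIMES
    trait_specs: dict[str, TraitSpec] = field(default_factory=dict)
    #: per parent trait, per regime: probability vector over the 5
    #: diameter intervals.
    subclass_profile: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)
    #: Dirichlet concentration controlling replicate-to-replicate
    #: subclass noise; larger is tighter around the profile.
    concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigError("need at least 2 genotypes")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 replicates")
        if len(self.regimes) != 2 or len(set(self.regimes)) != 2:
            raise ConfigError("regimes must be an ordered pair of distinct labels")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")
        for trait, spec in self.trait_specs.items():
            if trait not in ALL_TRAITS:
                raise ConfigError(f"unknown trait {trait!r} in trait_specs")
            if not isinstance(spec, TraitSpec):
                self.trait_specs[trait] = TraitSpec(**spec)
        for parent, per_regime in self.subclass_profile.items():
            if parent not in SUBCLASS_PARENTS:
                raise ConfigError(f"{parent!r} is not a subclassed parent trait")
            for regime, probs in per_regime.items():
                if regime not in self.regimes:
                    raise ConfigError(f"profile regime {regime!r} not in {self.regimes}")
                probs = tuple(float(x) for x in probs)
                per_regime[regime] = probs
                if len(probs) != N_SUBCLASSES:
                    raise ConfigError(
                        f"{parent}/{regime} profile needs {N_SUBCLASSES} entries"
                    )
                if min(probs) < 0:
                    raise ConfigError(f"{parent}/{regime} profile has negative mass")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{parent}/{regime} profile sums to {sum(probs)}, not 1"
                    )

    @property
    def genotype_labels(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"BW{str(i + 1).zfill(width)}" for i in range(self.n_genotypes)]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["regimes"] = list(self.regimes)
        data["subclass_profile"] = {
            p: {r: list(v) for r, v in per.items()}
            for p, per in self.subclass_profile.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["regimes"] = tuple(data.get("regimes", REGIMES))
        data["trait_specs"] = {
            t: TraitSpec(**s) for t, s in data.get("trait_specs", {}).items()
        }
        return cls(**data)


@dataclass
class TruthLedger:
    """Ground truth implied by a :class:`TrialConfig`.

    ``true_h2`` uses the genotype-mean-basis formula
    σ²G / (σ²G + σ²GP/p + σ²e/(p r)); ``true_mean_prc`` is the ratio of
    the two regime means implied by the shift.
    """

    true_h2: dict[str, float]
    true_mean_prc: dict[str, float]
    genotype_effects: pd.DataFrame            # genotype × trait
    truncation_counts: dict[str, int] = field(default_factory=dict)


def true_h2(spec: TraitSpec, n_replicates: int, n_regimes: int = 2) -> float:
    denom = spec.var_g + spec.var_gp / n_regimes + spec.var_e / (n_regimes * n_replicates)
    return spec.var_g / denom if denom > 0 else 0.0


def generate_trial(config: TrialConfig, seed: int | None = None) -> tuple[pd.DataFrame, TruthLedger]:
    """Draw a balanced trait panel plus its ground-truth ledger.

    The panel has one row per genotype × regime × replicate × trait for
    every trait in ``config.trait_specs``; identical (config, seed) pairs
    give identical panels.
    """
    if not config.trait_specs:
        raise ConfigError("trait_specs is empty; nothing to generate")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genos = config.genotype_labels
    g, r = config.n_genotypes, config.n_replicates
    traits = list(config.trait_specs)

    frames = []
    effects = {}
    truncations = {}
    for trait in traits:
        spec = config.trait_specs[trait]
        g_eff = rng.normal(0.0, np.sqrt(spec.var_g), size=g)
        gp_eff = rng.normal(0.0, np.sqrt(spec.var_gp), size=(g, 2))
        resid = rng.normal(0.0, np.sqrt(spec.var_e), size=(g, 2, r))
        base = np.array([spec.regime_mean(limiting=(j == 1)) for j in range(2)])
        y = base[None, :, None] + g_eff[:, None, None] + gp_eff[:, :, None] + resid

        below = y < POSITIVE_FLOOR
        truncations[trait] = int(below.sum())
        y = np.where(below, POSITIVE_FLOOR, y)

        frames.append(pd.DataFrame({
            "genotype": np.repeat(genos, 2 * r),
            "regime": np.tile(np.repeat(list(config.regimes), r), g),
            "replicate": np.tile(np.arange(1, r + 1), 2 * g),
            "trait": trait,
            "value": y.ravel(),
        }))
        effects[trait] = g_eff

    panel = pd.concat(frames, ignore_index=True)[list(PANEL_COLUMNS)]
    ledger = TruthLedger(
        true_h2={t: true_h2(config.trait_specs[t], r) for t in traits},
        true_mean_prc={
            t: config.trait_specs[t].regime_mean(True) / config.trait_specs[t].regime_mean(False)
            for t in traits
            if config.trait_specs[t].regime_mean(False) != 0
        },
        genotype_effects=pd.DataFrame(effects, index=genos),
        truncation_counts=truncations,
    )
    return panel, ledger


def generate_subclasses(panel: pd.DataFrame, config: TrialConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Augment a panel with compositional diameter-subclass observations.

    Each parent observation is split over the 5 diameter intervals by a
    Dirichlet draw with concentration ``config.concentration`` centred on
    the regime's profile; intervals with zero profile mass get exactly
    zero. Subclass values sum to the parent value to within floating
    round-off. Seeded independently of :func:`generate_trial` so the two
    stages compose deterministically.
    """
    if not config.subclass_profile:
        return panel.copy()
    rng = np.random.default_rng([config.seed if seed is None else seed, 1])
    frames = [panel]
    for parent, per_regime in config.subclass_profile.items():
        sub = panel.loc[panel["trait"] == parent]
        if sub.empty:
            raise ValueError(f"parent trait {parent!r} absent from panel")
        names = subclass_names(parent)
        for regime, probs in per_regime.items():
            rows = sub.loc[sub["regime"] == regime]
            probs = np.asarray(probs, dtype=float)
            pos = probs > 0
            comp = np.zeros((len(rows), N_SUBCLASSES))
            if pos.sum() == 1:
                comp[:, pos] = 1.0
            else:
                comp[:, pos] = rng.dirichlet(
                    config.concentration * probs[pos], size=len(rows)
                )
            values = rows["value"].to_numpy()[:, None] * comp
            for c, name in enumerate(names):
                out = rows.copy()
                out["trait"] = name
                out["value"] = values[:, c]
                frames.append(out)
    augmented = pd.concat(frames, ignore_index=True)
    order = {t: i for i, t in enumerate(ALL_TRAITS)}
    augmented["_o"] = augmented["trait"].map(order)
    augmented = augmented.sort_values(
        ["genotype", "regime", "replicate", "_o"], kind="stable",
        ignore_index=True,
    ).drop(columns="_o")
    return augmented


# ---------------------------------------------------------------------------
# Default study-scale configuration
# ---------------------------------------------------------------------------

# Per main trait: (NLP mean, LP mean, MS_G, MS_GxP, residual CV %).
# These calibration constants reproduce realistic wheat hydroponic-screen
# magnitudes: LP raises TRL/TSA/TRV/TRT/TRF and lowers PRL/RAD, residual
# CVs span ~6-24% and implied heritabilities ~0.47-0.83.
_STUDY_CALIBRATION: dict[str, tuple[float, float, float, float, float]] = {
    "PRL": (42.46, 38.90, 205.79, 72.44, 10.12),
    "TRL": (722.78, 1065.35, 624689.91, 112217.76, 16.33),
    "TSA": (72.93, 97.63, 5510.73, 903.00, 15.42),
    "RAD": (0.32, 0.30, 0.0064, 0.0015, 5.93),
    "TRV": (0.59, 0.72, 0.3383, 0.058, 16.34),
    "TRT": (2739.39, 3140.19, 8912636.24, 4716964.59, 23.68),
    "TRF": (2634.84, 4271.83, 12642180.35, 2471231.18, 21.20),
}

# Per parent trait, per regime: diameter-class shares (will be normalised).
_STUDY_SUBCLASS_SHARES: dict[str, dict[str, tuple[float, ...]]] = {
    "TRL": {"NLP": (82.36, 16.10, 1.12, 0.32, 0.10),
            "LP": (87.66, 11.10, 0.89, 0.27, 0.08)},
    "TSA": {"NLP": (55.27, 37.21, 4.78, 1.96, 0.78),
            "LP": (64.68, 28.57, 4.24, 1.84, 0.67)},
    "TRV": {"NLP": (28.22, 49.88, 11.64, 6.73, 3.51),
            "LP": (35.04, 42.95, 11.48, 7.11, 3.30)},
    "TRT": {"NLP": (98.35, 1.39, 0.06, 0.02, 0.01),
            "LP": (99.00, 0.35, 0.04, 0.02, 0.01)},
}


def _spec_from_calibration(nlp_mean: float, lp_mean: float, ms_g: float,
                           ms_gxp: float, cv_pct: float,
                           n_replicates: int = 3) -> TraitSpec:
    """Back out variance components from mean squares and residual CV.

    σ²e is implied by the CV and the across-regime grand mean; the
    interaction and genotype components follow from the expected mean
    squares of the balanced 2-regime design with r replicates.
    """
    grand = 0.5 * (nlp_mean + lp_mean)
    var_e = (cv_pct / 100.0 * grand) ** 2
    var_gp = max((ms_gxp - var_e) / n_replicates, 0.0)
    var_g = max((ms_g - ms_gxp) / (2 * n_replicates), 0.0)
    return TraitSpec(mean=nlp_mean, shift=lp_mean - nlp_mean,
                     var_g=var_g, var_gp=var_gp, var_e=var_e)


def default_config(n_genotypes: int = 182, n_replicates: int = 3,
                   seed: int = 0, concentration: float = 200.0) -> TrialConfig:
    """Study-scale default: 182 genotypes × 2 regimes × 3 replicates."""
    specs = {
        t: _spec_from_calibration(*cal, n_replicates=n_replicates)
        for t, cal in _STUDY_CALIBRATION.items()
    }
    profile = {
        parent: {
            regime: tuple(np.asarray(shares) / np.sum(shares))
            for regime, shares in per.items()
        }
        for parent, per in _STUDY_SUBCLASS_SHARES.items()
    }
    return TrialConfig(
        n_genotypes=n_genotypes, n_replicates=n_replicates,
        trait_specs=specs, subclass_profile=profile,
        concentration=concentration, seed=seed,
    )
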