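"""Reading, validating and summarising replicated trait tables.

The canonical in-memory container is a tidy :class:`pandas.DataFrame`
("trait panel") with one row per observation and columns

    genotype, regime, replicate, trait, value

Wide tables (one column per trait) and the WinRhizo export dialect are
melted to this long form on read. Long form is canonical because the
(genotype, regime, replicate, trait) key is explicit and unambiguous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import traits
from .traits import ALL_TRAITS, COUNT_TRAITS, REGIMES, STRICTLY_POSITIVE

PANEL_COLUMNS = ("genotype", "regime", "replicate", "trait", "value")
KEY_COLUMNS = PANEL_COLUMNS[:4]

DIALECTS = ("long", "wide-by-trait", "winrhizo-export")

#: Header synonyms found in WinRhizo tabular exports, mapped to trait codes.
#: Diameter-class columns are exported as e.g. "Length(cm) 0-0.5" and are
#: matched by prefix + interval below.
WINRHIZO_ALIASES: dict[str, str] = {
    "Length(cm)": "TRL",
    "SurfArea(cm2)": "TSA",
    "AvgDiam(mm)": "RAD",
    "RootVolume(cm3)": "TRV",
    "Tips": "TRT",
    "Forks": "TRF",
    "PrimaryRootLength(cm)": "PRL",
}

_WINRHIZO_CLASS_PREFIXES = {
    "Length(cm)": "RL",
    "SurfArea(cm2)": "SA",
    "RootVolume(cm3)": "RV",
    "Tips": "RT",
}

_WINRHIZO_INTERVALS = {
    "0-0.5": 1, "0.5-1": 2, "1-1.5": 3, "1.5-2": 4, ">2": 5,
}


class PanelError(ValueError):
    """A trait table violates the panel contract."""


def _map_winrhizo_header(name: str) -> str | None:
    name = name.strip()
    if name in WINRHIZO_ALIASES:
        return WINRHIZO_ALIASES[name]
    for prefix, code in _WINRHIZO_CLASS_PREFIXES.items():
        if name.startswith(prefix + " "):
            interval = name[len(prefix) + 1:].strip()
            if interval in _WINRHIZO_INTERVALS:
                return f"{code}{_WINRHIZO_INTERVALS[interval]}"
    return None


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if line.count("\t") >= line.count(",") else ","
    return ","


def read_trait_table(
    path: str | Path,
    dialect: str = "long",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a trait table into a validated long-format panel.

    Parameters
    ----------
    path
        CSV/TSV file with a mandatory header row. Lines starting with
        ``#`` are treated as metadata comments and skipped.
    dialect
        ``"long"`` (genotype, regime, replicate, trait, value),
        ``"wide-by-trait"`` (genotype, regime, replicate, one column per
        trait code), or ``"winrhizo-export"`` (wide with WinRhizo header
        synonyms, mapped via :data:`WINRHIZO_ALIASES`).
    delimiter
        Override the comma/tab auto-detection.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"genotype": str})

    if dialect == "long":
        missing = set(PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise PanelError(f"long table missing columns: {sorted(missing)}")
        panel = df.loc[:, list(PANEL_COLUMNS)].copy()
        unknown = set(panel["trait"]) - set(ALL_TRAITS)
        if unknown:
            raise PanelError(f"unknown trait names: {sorted(unknown)}")
    else:
        id_cols = ["genotype", "regime", "replicate"]
        missing = set(id_cols) - set(df.columns)
        if missing:
            raise PanelError(f"wide table missing id columns: {sorted(missing)}")
        trait_cols = [c for c in df.columns if c not in id_cols]
        if dialect == "winrhizo-export":
            mapping, unmapped = {}, []
            for c in trait_cols:
                code = _map_winrhizo_header(c)
                (mapping.__setitem__(c, code) if code else unmapped.append(c))
            if unmapped:
                raise PanelError(
                    f"unmapped WinRhizo columns: {unmapped}; known aliases: "
                    f"{sorted(WINRHIZO_ALIASES)}"
                )
            df = df.rename(columns=mapping)
            trait_cols = list(mapping.values())
        unknown = set(trait_cols) - set(ALL_TRAITS)
        if unknown:
            raise PanelError(f"unknown trait columns: {sorted(unknown)}")
        panel = df.melt(
            id_vars=id_cols, value_vars=trait_cols,
            var_name="trait", value_name="value",
        )

    bad = pd.to_numeric(panel["value"], errors="coerce")
    nonnum = panel.index[bad.isna() & panel["value"].notna()]
    if len(nonnum):
        raise PanelError(
            f"non-numeric value at data row(s) {list(nonnum[:5])}"
        )
    panel["value"] = bad
    panel["replicate"] = panel["replicate"].astype(int)
    panel["genotype"] = panel["genotype"].astype(str)
    check_panel(panel)
    return panel.reset_index(drop=True)


def write_trait_table(
    panel: pd.DataFrame,
    path: str | Path,
    dialect: str = "long",
    delimiter: str = ",",
    metadata: dict | None = None,
) -> None:
    """Write a panel as CSV/TSV, optionally with ``#`` metadata headers."""
    if dialect == "long":
        out = panel.loc[:, list(PANEL_COLUMNS)]
    elif dialect in ("wide-by-trait", "winrhizo-export"):
        out = panel.pivot_table(
            index=["genotype", "regime", "replicate"],
            columns="trait", values="value", sort=False,
        ).reset_index()
        out.columns.name = None
        if dialect == "winrhizo-export":
            inverse = {v: k for k, v in WINRHIZO_ALIASES.items()}
            for prefix, code in _WINRHIZO_CLASS_PREFIXES.items():
                for iv, i in _WINRHIZO_INTERVALS.items():
                    inverse[f"{code}{i}"] = f"{prefix} {iv}"
            out = out.rename(columns=inverse)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    buf = io.StringIO()
    for key, val in (metadata or {}).items():
        buf.write(f"# {key}: {val}\n")
    out.to_csv(buf, sep=delimiter, index=False)
    Path(path).write_text(buf.getvalue())


def check_panel(panel: pd.DataFrame) -> None:
    """Raise :class:`PanelError` on hard contract violations.

    Checked: duplicate keys, non-finite values, unregistered regimes,
    RAD ≤ 0, negative counts. Balance is *reported* (see
    :func:`validate_panel`), not enforced here.
    """
    dup = panel.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        key = panel.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
        raise PanelError(f"duplicate observation key {key}")
    if not np.isfinite(panel["value"]).all():
        raise PanelError("panel contains non-finite values")
    bad_regime = set(panel["regime"]) - set(REGIMES)
    if bad_regime:
        raise PanelError(
            f"unregistered regime labels {sorted(bad_regime)}; expected {REGIMES}"
        )
    rad = panel.loc[panel["trait"].isin(STRICTLY_POSITIVE), "value"]
    if (rad <= 0).any():
        raise PanelError("RAD values must be strictly positive")
    counts = panel.loc[panel["trait"].isin(COUNT_TRAITS), "value"]
    if (counts < 0).any():
        raise PanelError("count traits must be non-negative")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`; purely descriptive."""

    balanced: bool
    n_genotypes: int
    n_regimes: int
    n_replicates: int
    n_traits: int
    missing_cells: list[tuple] = field(default_factory=list)
    range_violations: list[tuple] = field(default_factory=list)
    duplicate_keys: list[tuple] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.balanced and not self.range_violations and not self.duplicate_keys

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"balanced: {str(self.balanced).lower()}, "
            f"missing: {len(self.missing_cells)}, "
            f"range violations: {len(self.range_violations)}, "
            f"duplicates: {len(self.duplicate_keys)}"
        )


def validate_panel(panel: pd.DataFrame) -> ValidationReport:
    """Report balance, missing cells and out-of-range values; never mutates."""
    dup_mask = panel.duplicated(subset=list(KEY_COLUMNS))
    duplicates = [tuple(r) for r in panel.loc[dup_mask, list(KEY_COLUMNS)].itertuples(index=False)]

    genos = sorted(panel["genotype"].unique())
    regimes = sorted(panel["regime"].unique())
    reps = sorted(panel["replicate"].unique())
    trts = sorted(panel["trait"].unique())
    expected = pd.MultiIndex.from_product(
        [genos, regimes, reps, trts], names=KEY_COLUMNS
    )
    present = pd.MultiIndex.from_frame(panel[list(KEY_COLUMNS)])
    missing = [tuple(k) for k in expected.difference(present)]

    violations = []
    rad_bad = panel["trait"].isin(STRICTLY_POSITIVE) & (panel["value"] <= 0)
    cnt_bad = panel["trait"].isin(COUNT_TRAITS) & (panel["value"] < 0)
    fin_bad = ~np.isfinite(panel["value"])
    for mask, why in ((rad_bad, "non-positive"), (cnt_bad, "negative count"),
                      (fin_bad, "non-finite")):
        for row in panel.loc[mask, list(PANEL_COLUMNS)].itertuples(index=False):
            violations.append((why, *row))

    return ValidationReport(
        balanced=not missing and not duplicates,
        n_genotypes=len(genos),
        n_regimes=len(regimes),
        n_replicates=len(reps),
        n_traits=len(trts),
        missing_cells=missing,
        range_violations=violations,
        duplicate_keys=duplicates,
    )


def summarize_panel(panel: pd.DataFrame, method: str = "raw_mean") -> pd.DataFrame:
    """Collapse replicates to one value per (genotype, regime, trait).

    ``method="raw_mean"`` takes the arithmetic replicate mean.
    ``method="blup"`` shrinks genotype means toward the regime grand mean
    with the shrinkage factor from a one-way random-genotype fit (see
    :func:`rootpue.variance_blup.blup_means`). The returned frame carries a
    ``method`` column so downstream reports can state which was used.
    """
    if method == "raw_mean":
        out = (
            panel.groupby(["genotype", "regime", "trait"], as_index=False, sort=True)
            ["value"].mean()
        )
    elif method == "blup":
        from .variance_blup import blup_means

        rep_counts = panel.groupby(["genotype", "regime", "trait"])["value"].size()
        if (rep_counts < 2).any():
            raise PanelError("BLUP summaries need at least 2 replicates per cell")
        parts = []
        for (regime, trait), sub in panel.groupby(["regime", "trait"], sort=True):
            shrunk = blup_means(sub, trait, regime)
            parts.append(
                pd.DataFrame({
                    "genotype": shrunk.index,
                    "regime": regime,
                    "trait": trait,
                    "value": shrunk.values,
                })
            )
        out = pd.concat(parts, ignore_index=True)
        out = out.sort_values(["genotype", "regime", "trait"], ignore_index=True)
    else:
        raise ValueError(f"unknown summary method {method!r}")
    out["method"] = method
    return out
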