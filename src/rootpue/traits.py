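"""Registry of root-system-architecture traits.

Seven main traits are measured per plant (WinRhizo scan plus a manual
primary-root measurement), and four of them (TRL, TSA, TRV, TRT) are
partitioned by the image software into five root-diameter subclasses.
Everything downstream — validation, simulation, reporting — keys off the
tables defined here.
"""

from __future__ import annotations

#: Main trait codes, in canonical report order.
MAIN_TRAITS: tuple[str, ...] = ("PRL", "TRL", "TSA", "RAD", "TRV", "TRT", "TRF")

#: Parent traits that WinRhizo partitions into diameter subclasses,
#: mapped to their subclass prefix.
SUBCLASS_PARENTS: dict[str, str] = {
    "TRL": "RL",
    "TSA": "SA",
    "TRV": "RV",
    "TRT": "RT",
}

#: Ordered root-diameter intervals (mm) defining subclasses 1..5.
DIAMETER_INTERVALS: tuple[str, ...] = (
    "0.0-0.5",
    "0.5-1.0",
    "1.0-1.5",
    "1.5-2.0",
    ">2.0",
)

N_SUBCLASSES = len(DIAMETER_INTERVALS)


def subclass_names(parent: str) -> list[str]:
    """Subclass trait codes for a parent trait, e.g. TRL -> [RL1..RL5]."""
    try:
        prefix = SUBCLASS_PARENTS[parent]
    except KeyError:
        raise KeyError(
            f"{parent!r} has no diameter subclasses; "
            f"parents are {sorted(SUBCLASS_PARENTS)}"
        ) from None
    return [f"{prefix}{i}" for i in range(1, N_SUBCLASSES + 1)]


SUBCLASS_TRAITS: tuple[str, ...] = tuple(
    name for parent in SUBCLASS_PARENTS for name in subclass_names(parent)
)

ALL_TRAITS: tuple[str, ...] = MAIN_TRAITS + SUBCLASS_TRAITS

#: Measurement units per trait (subclasses inherit the parent unit).
UNITS: dict[str, str] = {
    "PRL": "cm",
    "TRL": "cm",
    "TSA": "cm2",
    "RAD": "mm",
    "TRV": "cm3",
    "TRT": "count",
    "TRF": "count",
}
for _parent, _prefix in SUBCLASS_PARENTS.items():
    for _name in subclass_names(_parent):
        UNITS[_name] = UNITS[_parent]

#: Traits that must be strictly positive (a zero average diameter is a
#: measurement failure, not a phenotype).
STRICTLY_POSITIVE: frozenset[str] = frozenset({"RAD"})

#: Count-valued traits; must be non-negative.
COUNT_TRAITS: frozenset[str] = frozenset(
    t for t, u in UNITS.items() if u == "count"
)

#: The two phosphorus regimes. The first entry is the reference
#: (non-limiting) regime; PRC ratios are limiting / non-limiting.
REGIMES: tuple[str, str] = ("NLP", "LP")
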