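"""IUCN Red List categories, extinction-probability transformations, and downlisting.

A :class:`RiskTransform` maps each Red List category to a probability of
extinction over a stated time horizon. Several published transformations are
built in; the 50-year IUCN transformation is the package default because it
balances urgency between threat categories (the 500-year and pessimistic
scenarios leave Critically Endangered species nearly doomed either way, so
downlisting them appears almost worthless under those lenses).

The GE ("Global Endangerment") column is the ordinal weighting used by the
EDGE protocol. It is *not* a probability and is refused by every expectation
computation; it exists here only so EDGE scores can be formed for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "CATEGORIES",
    "THREAT_ORDER",
    "RiskTransform",
    "builtin_transform",
    "downlist",
    "load_custom_transform",
]

#: All recognised Red List categories.
CATEGORIES = ("LC", "NT", "DD", "NE", "VU", "EN", "CR", "EW")

#: Categories ordered from most to least threatened; downlisting moves one
#: step to the right. DD/NE sit outside this scale (no defined downlisted
#: state), as does LC (nothing below it).
THREAT_ORDER = ("EW", "CR", "EN", "VU", "NT", "LC")

# Monotonicity is checked over the probability scale LC<=NT<=VU<=EN<=CR<=EW;
# DD/NE mirror NT by convention (they are expected to be reassessed as NT).
_PROB_SCALE = ("LC", "NT", "VU", "EN", "CR", "EW")


@dataclass(frozen=True)
class RiskTransform:
    """A named category -> extinction-probability (or ordinal weight) mapping."""

    name: str
    mapping: Mapping[str, float]
    time_window_years: int | None = None
    probabilistic: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.mapping]
        if missing:
            raise ValueError(f"transform {self.name!r} missing categories: {missing}")
        if self.probabilistic:
            vals = self.mapping
            for c in CATEGORIES:
                if not 0.0 <= vals[c] <= 1.0:
                    raise ValueError(
                        f"transform {self.name!r}: p({c})={vals[c]} outside [0, 1]"
                    )
            for lo, hi in zip(_PROB_SCALE, _PROB_SCALE[1:]):
                if vals[lo] > vals[hi]:
                    raise ValueError(
                        f"transform {self.name!r}: p({lo}) > p({hi}) breaks the "
                        "threat-order monotonicity"
                    )

    def __getitem__(self, category: str) -> float:
        try:
            return self.mapping[category]
        except KeyError:
            raise KeyError(f"unknown IUCN category {category!r}") from None

    def require_probabilistic(self) -> None:
        """Raise if this transform is an ordinal weighting (GE), not a probability."""
        if not self.probabilistic:
            raise ValueError(
                f"transform {self.name!r} is an ordinal weighting, not a probability "
                "of extinction; expected-PD computations require a probabilistic "
                "transform (e.g. IUCN50)"
            )


def _with_ddne(base: dict[str, float]) -> dict[str, float]:
    # DD and NE take the NT value: both are most likely to be reassessed as NT.
    out = dict(base)
    out["DD"] = base["NT"]
    out["NE"] = base["NT"]
    return out


_BUILTINS: dict[str, RiskTransform] = {
    "GE": RiskTransform(
        "GE",
        _with_ddne({"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4, "EW": 6}),
        time_window_years=None,
        probabilistic=False,
    ),
    "IUCN50": RiskTransform(
        "IUCN50",
        _with_ddne(
            {"LC": 0.00005, "NT": 0.004, "VU": 0.05, "EN": 0.42, "CR": 0.97, "EW": 1.0}
        ),
        time_window_years=50,
    ),
    "IUCN500": RiskTransform(
        "IUCN500",
        _with_ddne(
            {"LC": 0.0005, "NT": 0.02, "VU": 0.39, "EN": 0.996, "CR": 1.0, "EW": 1.0}
        ),
        time_window_years=500,
    ),
    "pessimistic": RiskTransform(
        "pessimistic",
        _with_ddne({"LC": 0.2, "NT": 0.4, "VU": 0.8, "EN": 0.9, "CR": 0.99, "EW": 1.0}),
        time_window_years=100,
    ),
}


def builtin_transform(name: str) -> RiskTransform:
    """Return a built-in transform: ``GE``, ``IUCN50``, ``IUCN500`` or ``pessimistic``."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown transform {name!r}; choose from {sorted(_BUILTINS)}"
        ) from None


def downlist(category: str) -> str:
    """Move a species one step down the threat scale (e.g. CR -> EN).

    Raises
    ------
    ValueError
        For LC (nothing below it) and for DD/NE, which have no defined
        downlisted state.
    """
    if category in ("LC", "DD", "NE"):
        raise ValueError(f"category {category!r} cannot be downlisted")
    try:
        i = THREAT_ORDER.index(category)
    except ValueError:
        raise ValueError(f"unknown IUCN category {category!r}") from None
    return THREAT_ORDER[i + 1]


def is_downlistable(category: str) -> bool:
    return category in THREAT_ORDER[:-1]


def load_custom_transform(path: str | Path, name: str = "custom") -> RiskTransform:
    """Read a ``category=probability`` key-value file into a transform.

    Lines starting with ``#`` are ignored. ``time_window_years=<int>`` may be
    given as an extra key. DD/NE default to the NT value when omitted.
    """
    mapping: dict[str, float] = {}
    window: int | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'category=value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key == "time_window_years":
            window = int(val)
        else:
            mapping[key] = float(val)
    for c in ("DD", "NE"):
        if c not in mapping and "NT" in mapping:
            mapping[c] = mapping["NT"]
    return RiskTransform(name, mapping, time_window_years=window)
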