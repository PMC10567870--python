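"""Marker panel, body-fluid taxonomy and tiered threshold rules.

The panel comprises six pyrosequencing CpG assays, each targeting one (or,
for N27SE, two) of seven forensically relevant body fluids:

========  ==========  ============================================
marker    CpG probe   target secretion(s)
========  ==========  ============================================
NB21      cg16518142  nasal blood / nasal secretion (hypomethylated)
B7        cg13763232  peripheral blood (hypermethylated)
MB4       cg04255276  menstrual blood
SA4       cg21597595  saliva
V2        cg26079753  vaginal secretion
N27SE     cg20864568  nasal secretion (band) and sperm (hypermethylated)
========  ==========  ============================================

Calls are made against tiered thresholds.  A tier may be unconditional or
conditioned on the state of the conventional rapid pre-tests for blood
(hemoglobin), saliva (amylase) and sperm: a confirmed *negative* pre-test
excludes secretions and therefore permits a more permissive cutoff (e.g. the
nasal band of N27SE widens from >40 to >30 to >22 as blood and saliva are
ruled out).  All comparators are strict; a value exactly equal to a cutoff
does not fire the rule, and a pre-test that was not performed never
satisfies a "negative" condition.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "BodyFluid",
    "PreTest",
    "PreTestPanel",
    "MarkerDef",
    "Tier",
    "ThresholdRule",
    "NASAL_PAIR_LABEL",
    "VAGINAL_TRACT_LABEL",
    "MARKER_ORDER",
    "default_markers",
    "default_rules",
    "load_panel",
    "resolve_thresholds",
    "panel_to_config",
    "panel_table",
]


class BodyFluid(str, Enum):
    """The seven secretions the workflow can identify."""

    NASAL_SECRETION = "nasal_secretion"
    NASAL_BLOOD = "nasal_blood"
    PERIPHERAL_BLOOD = "peripheral_blood"
    MENSTRUAL_BLOOD = "menstrual_blood"
    SALIVA = "saliva"
    VAGINAL_SECRETION = "vaginal_secretion"
    SPERM_SECRETION = "sperm_secretion"

    @property
    def blood_containing(self) -> bool:
        return self in _BLOOD_CONTAINING

    @property
    def pretest_triggers(self) -> frozenset[str]:
        """Which rapid tests this fluid turns positive."""
        triggers = set()
        if self.blood_containing:
            triggers.add("blood")
        if self is BodyFluid.SALIVA:
            triggers.add("saliva")
        if self is BodyFluid.SPERM_SECRETION:
            triggers.add("sperm")
        return frozenset(triggers)


_BLOOD_CONTAINING = {
    BodyFluid.NASAL_BLOOD,
    BodyFluid.PERIPHERAL_BLOOD,
    BodyFluid.MENSTRUAL_BLOOD,
}

#: NB21 flags the nasal pair without separating its members.
NASAL_PAIR_LABEL = "nasal_secretion_or_nasal_blood"
#: V2 above 25% proves vaginal-tract origin (vaginal secretion or menstrual
#: blood) without resolving which.
VAGINAL_TRACT_LABEL = "vaginal_tract_secretion"


class PreTest(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_DONE = "not_done"


@dataclass(frozen=True)
class PreTestPanel:
    """Results of the three conventional rapid tests for a stain."""

    blood: PreTest = PreTest.NOT_DONE
    saliva: PreTest = PreTest.NOT_DONE
    sperm: PreTest = PreTest.NOT_DONE

    def state(self, name: str) -> PreTest:
        return getattr(self, name)

    @classmethod
    def from_strings(cls, blood: str, saliva: str, sperm: str) -> "PreTestPanel":
        return cls(PreTest(blood), PreTest(saliva), PreTest(sperm))


@dataclass(frozen=True)
class MarkerDef:
    short_name: str
    cpg_id: str
    target_fluids: frozenset[BodyFluid]
    call_direction: str  # below_cutoff | above_cutoff | band

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.short_name


@dataclass(frozen=True)
class Tier:
    """One threshold line of a marker's decision chart.

    ``condition`` maps pre-test names to the state they must be in for the
    tier to apply; an empty condition is unconditional.  ``comparator`` is
    one of ``gt`` / ``lt`` / ``between`` with strict bounds in percent
    methylation.  ``outcome`` is a semantic label consumed by the classifier.
    """

    comparator: str
    bounds: tuple[float, ...]
    outcome: str
    condition: Mapping[str, PreTest] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.comparator not in ("gt", "lt", "between"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        n_expected = 2 if self.comparator == "between" else 1
        if len(self.bounds) != n_expected:
            raise ValueError(
                f"{self.comparator} tier needs {n_expected} bound(s), got {self.bounds}"
            )
        for b in self.bounds:
            if not 0 <= b <= 100:
                raise ValueError(f"bound {b} outside [0, 100]")
        if self.comparator == "between" and not self.bounds[0] < self.bounds[1]:
            raise ValueError(f"band bounds must satisfy lower < upper, got {self.bounds}")

    @property
    def specificity(self) -> int:
        return len(self.condition)

    def applies(self, pretests: PreTestPanel) -> bool:
        return all(pretests.state(name) is state for name, state in self.condition.items())

    def fires(self, value: float) -> bool:
        if self.comparator == "gt":
            return value > self.bounds[0]
        if self.comparator == "lt":
            return value < self.bounds[0]
        return self.bounds[0] < value < self.bounds[1]

    def describe(self) -> str:
        if self.comparator == "gt":
            rule = f"> {self.bounds[0]:g}%"
        elif self.comparator == "lt":
            rule = f"< {self.bounds[0]:g}%"
        else:
            rule = f"{self.bounds[0]:g}% < value < {self.bounds[1]:g}%"
        if self.condition:
            conds = ", ".join(f"{k} {v.value}" for k, v in sorted(self.condition.items()))
            rule += f" [given {conds}]"
        return rule


@dataclass(frozen=True)
class ThresholdRule:
    marker: MarkerDef
    tiers: tuple[Tier, ...]


_NEG = PreTest.NEGATIVE
_POS = PreTest.POSITIVE

MARKER_ORDER = ("NB21", "B7", "MB4", "SA4", "V2", "N27SE")

_CPG_IDS = {
    "NB21": "cg16518142",
    "B7": "cg13763232",
    "MB4": "cg04255276",
    "SA4": "cg21597595",
    "V2": "cg26079753",
    "N27SE": "cg20864568",
}

_TARGETS = {
    "NB21": frozenset({BodyFluid.NASAL_SECRETION, BodyFluid.NASAL_BLOOD}),
    "B7": frozenset({BodyFluid.PERIPHERAL_BLOOD}),
    "MB4": frozenset({BodyFluid.MENSTRUAL_BLOOD}),
    "SA4": frozenset({BodyFluid.SALIVA}),
    "V2": frozenset({BodyFluid.VAGINAL_SECRETION}),
    "N27SE": frozenset({BodyFluid.NASAL_SECRETION, BodyFluid.SPERM_SECRETION}),
}

_DIRECTIONS = {
    "NB21": "below_cutoff",
    "B7": "above_cutoff",
    "MB4": "above_cutoff",
    "SA4": "above_cutoff",
    "V2": "above_cutoff",
    "N27SE": "band",
}

# Published default tiers, in declared order (tier resolution sorts
# most-specific-first, stable within equal specificity).
_DEFAULT_TIERS: dict[str, tuple[Tier, ...]] = {
    "NB21": (Tier("lt", (67,), "nasal_pair_full"),),
    "B7": (Tier("gt", (80,), "peripheral_blood_pure"),),
    "MB4": (
        Tier("gt", (21,), "menstrual_blood_full"),
        Tier("gt", (18,), "menstrual_blood_full", {"sperm": _NEG}),
        Tier("between", (18, 21), "menstrual_sperm_mixture", {"sperm": _POS}),
    ),
    "SA4": (
        Tier("gt", (35,), "saliva_full"),
        Tier("gt", (18,), "saliva_partial"),
    ),
    "V2": (
        Tier("gt", (50,), "vaginal_full"),
        Tier("gt", (40,), "vaginal_full", {"saliva": _NEG}),
        Tier("gt", (25,), "vaginal_tract_partial"),
    ),
    "N27SE": (
        Tier("gt", (75,), "sperm_full"),
        Tier("between", (40, 70), "nasal_band", {"sperm": _NEG}),
        Tier("between", (30, 70), "nasal_band", {"sperm": _NEG, "blood": _NEG}),
        Tier(
            "between",
            (22, 70),
            "nasal_band",
            {"sperm": _NEG, "blood": _NEG, "saliva": _NEG},
        ),
    ),
}


def default_markers() -> tuple[MarkerDef, ...]:
    return tuple(
        MarkerDef(name, _CPG_IDS[name], _TARGETS[name], _DIRECTIONS[name])
        for name in MARKER_ORDER
    )


def default_rules() -> tuple[ThresholdRule, ...]:
    markers = {m.short_name: m for m in default_markers()}
    return tuple(
        ThresholdRule(markers[name], _DEFAULT_TIERS[name]) for name in MARKER_ORDER
    )


def _tier_from_mapping(raw: Mapping) -> Tier:
    condition = {
        name: PreTest(state) for name, state in (raw.get("when") or {}).items()
    }
    for name in condition:
        if name not in ("blood", "saliva", "sperm"):
            raise ValueError(f"unknown pre-test {name!r} in tier condition")
    return Tier(
        comparator=raw["comparator"],
        bounds=tuple(float(b) for b in raw["bounds"]),
        outcome=raw["outcome"],
        condition=condition,
    )


def load_panel(
    config_source: str | Mapping | None = None,
) -> tuple[tuple[MarkerDef, ...], tuple[ThresholdRule, ...]]:
    """Load the marker panel and threshold rules.

    With no ``config_source`` the published defaults are returned, so the
    tool runs with zero files.  A config (YAML text, a path-free mapping, or
    a file-like object) overrides the tier list of the markers it names;
    unnamed markers keep their defaults.

    Raises
    ------
    ValueError
        on an unknown marker name, a bound outside [0, 100], or a band whose
        lower bound is not below its upper bound.
    """
    markers = default_markers()
    by_name = {m.short_name: m for m in markers}
    tiers = dict(_DEFAULT_TIERS)

    if config_source is not None:
        if isinstance(config_source, Mapping):
            doc = config_source
        elif isinstance(config_source, _io.IOBase):
            doc = yaml.safe_load(config_source)
        else:
            doc = yaml.safe_load(str(config_source))
        if doc:
            for name, tier_list in doc.items():
                if name not in by_name:
                    raise ValueError(f"unknown marker name {name!r}")
                tiers[name] = tuple(_tier_from_mapping(t) for t in tier_list)

    rules = tuple(ThresholdRule(by_name[n], tiers[n]) for n in MARKER_ORDER)
    return markers, rules


def resolve_thresholds(
    marker: MarkerDef | str,
    pretests: PreTestPanel,
    rules: Sequence[ThresholdRule] | None = None,
) -> list[Tier]:
    """Return the tiers applicable under the given pre-test states.

    Pure function of its inputs.  Tiers are ordered most-specific-first
    (number of satisfied pre-test conditions, descending; declared order
    within ties), which is also the order the classifier evaluates them in.
    A ``not_done`` pre-test never satisfies a ``negative`` condition.
    """
    rules = default_rules() if rules is None else rules
    name = marker.short_name if isinstance(marker, MarkerDef) else marker
    for rule in rules:
        if rule.marker.short_name == name:
            applicable = [t for t in rule.tiers if t.applies(pretests)]
            return sorted(applicable, key=lambda t: -t.specificity)
    raise KeyError(f"marker {name!r} not in panel")


def panel_to_config(rules: Sequence[ThresholdRule]) -> dict:
    """Serialize threshold rules to the config dialect ``load_panel`` reads."""
    doc: dict = {}
    for rule in rules:
        doc[rule.marker.short_name] = [
            {
                "comparator": t.comparator,
                "bounds": [float(b) for b in t.bounds],
                "outcome": t.outcome,
                **({"when": {k: v.value for k, v in t.condition.items()}} if t.condition else {}),
            }
            for t in rule.tiers
        ]
    return doc


def panel_table(rules: Sequence[ThresholdRule] | None = None) -> pd.DataFrame:
    """Flat, report-friendly table of the panel (one row per tier)."""
    rules = default_rules() if rules is None else rules
    rows = []
    for rule in rules:
        m = rule.marker
        for tier in rule.tiers:
            rows.append(
                {
                    "marker": m.short_name,
                    "cpg_id": m.cpg_id,
                    "targets": ";".join(sorted(f.value for f in m.target_fluids)),
                    "rule": tier.describe(),
                    "outcome": tier.outcome,
                }
            )
    return pd.DataFrame(rows)
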