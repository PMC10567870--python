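"""The body-fluid decision workflow.

Classification combines three evidence sources, in a fixed order:

1. **Pre-test exclusions.**  A confirmed negative blood, saliva or sperm
   rapid test excludes the secretions that would have triggered it (a
   negative blood test excludes peripheral, menstrual and nasal blood).
   A test that was not done excludes nothing.
2. **Marker tiers.**  Each measured marker is evaluated against its
   applicable threshold tiers, most specific first; the first tier that
   fires is that marker's conclusion.  Tier outcomes map onto full calls
   (e.g. B7 > 80% → pure peripheral blood), partial-component calls (SA4 in
   18–35% → saliva present as a mixture component) and explicit mixture
   calls (MB4 in 18–21% with a positive sperm test → menstrual blood plus
   sperm).
3. **Pre-test-supported components.**  A positive sperm or saliva test adds
   its fluid as a component when the methylation evidence does not
   contradict it (a positive sperm test with N27SE at 51% still implies a
   sperm sub-component — pure sperm sits above 75%, but sperm-containing
   mixtures run down to about 33%).  A positive blood test cannot by itself
   say *which* blood-containing secretion is present, so unexplained blood
   positivity is surfaced as a warning rather than a call.

Exclusions always win: a tier naming an excluded fluid is suppressed with a
logged conflict warning.  Ambiguities the assays cannot resolve are
reported as such — NB21 below 67% identifies "nasal secretion or nasal
blood" until the blood pre-test disambiguates, V2 above 25% proves only
"vaginal-tract secretion" when menstrual blood has not been excluded, and
a blood-positive stain with V2 above 25% and B7 at or below 80% may be
menstrual blood or a peripheral-blood/vaginal mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .panel import (
    MARKER_ORDER,
    NASAL_PAIR_LABEL,
    VAGINAL_TRACT_LABEL,
    BodyFluid,
    MarkerDef,
    PreTest,
    PreTestPanel,
    ThresholdRule,
    default_markers,
    default_rules,
    resolve_thresholds,
)

__all__ = [
    "ClassificationResult",
    "EvidenceRow",
    "exclude_by_pretests",
    "select_markers",
    "classify",
]

#: Lowest methylation observed for sperm-containing mixtures at N27SE; a
#: positive sperm pre-test with N27SE below this is treated as contradicted.
SPERM_MIXTURE_FLOOR = 33.0

#: SA4 partial-component bound; a positive saliva pre-test with SA4 at or
#: below this lacks methylation support.
SALIVA_PARTIAL_BOUND = 18.0


@dataclass(frozen=True)
class EvidenceRow:
    marker: str
    value: float
    tier: str  # human-readable tier description, or "no tier fired"
    fired: bool
    conclusion: str


@dataclass
class ClassificationResult:
    sample_id: str
    called_fluids: set[str] = field(default_factory=set)
    partial_components: set[str] = field(default_factory=set)
    excluded_fluids: dict[str, str] = field(default_factory=dict)  # fluid -> reason
    mixture: bool = False
    evidence: list[EvidenceRow] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    ambiguity_flags: list[str] = field(default_factory=list)

    @property
    def undetermined(self) -> bool:
        return not self.called_fluids and not self.partial_components

    @property
    def components(self) -> set[str]:
        """All detected components, full and partial."""
        return self.called_fluids | self.partial_components

    def narrative(self) -> str:
        """Case-report style prose summary."""
        lines = [f"Sample {self.sample_id}:"]
        if self.excluded_fluids:
            lines.append(
                "  Pre-tests excluded: "
                + ", ".join(sorted(self.excluded_fluids))
                + "."
            )
        for row in self.evidence:
            verdict = f"-> {row.conclusion}" if row.fired else "-> no call"
            lines.append(f"  {row.marker} = {row.value:g}% ({row.tier}) {verdict}")
        if self.undetermined:
            lines.append("  Cellular origin could not be determined.")
        else:
            parts = sorted(self.called_fluids) + [
                f"{p} (partial component)" for p in sorted(self.partial_components)
            ]
            kind = "mixture of " if self.mixture else ""
            lines.append(f"  Conclusion: {kind}{', '.join(parts)}.")
        for flag in self.ambiguity_flags:
            lines.append(f"  Ambiguity: {flag}")
        for warn in self.warnings:
            lines.append(f"  Warning: {warn}")
        return "\n".join(lines)


def exclude_by_pretests(pretests: PreTestPanel) -> set[BodyFluid]:
    """Fluids ruled out by confirmed-negative rapid tests."""
    excluded: set[BodyFluid] = set()
    if pretests.blood is PreTest.NEGATIVE:
        excluded |= {
            BodyFluid.PERIPHERAL_BLOOD,
            BodyFluid.MENSTRUAL_BLOOD,
            BodyFluid.NASAL_BLOOD,
        }
    if pretests.saliva is PreTest.NEGATIVE:
        excluded.add(BodyFluid.SALIVA)
    if pretests.sperm is PreTest.NEGATIVE:
        excluded.add(BodyFluid.SPERM_SECRETION)
    return excluded


def select_markers(
    pretests: PreTestPanel,
    markers: Sequence[MarkerDef] | None = None,
) -> set[MarkerDef]:
    """Markers worth assaying given the rapid-test results.

    The three canonical pre-test constellations follow the casework logic:
    all tests negative leaves only the no-pre-test fluids in play (V2 and
    N27SE for vaginal and nasal secretion); blood and sperm both positive
    asks *which* blood-containing secretion accompanies the sperm (NB21,
    B7, MB4, N27SE); saliva positive with blood and sperm negative probes
    saliva and the remaining no-pre-test fluids (SA4, V2, N27SE).  Any
    other constellation falls back to every marker with at least one
    non-excluded target fluid.
    """
    markers = tuple(default_markers()) if markers is None else tuple(markers)
    by_name = {m.short_name: m for m in markers}

    def named(*names: str) -> set[MarkerDef]:
        return {by_name[n] for n in names if n in by_name}

    b, sa, sp = pretests.blood, pretests.saliva, pretests.sperm
    if b is PreTest.NEGATIVE and sa is PreTest.NEGATIVE and sp is PreTest.NEGATIVE:
        return named("V2", "N27SE")
    if b is PreTest.POSITIVE and sp is PreTest.POSITIVE:
        return named("NB21", "B7", "MB4", "N27SE")
    if sa is PreTest.POSITIVE and b is PreTest.NEGATIVE and sp is PreTest.NEGATIVE:
        return named("SA4", "V2", "N27SE")

    excluded = exclude_by_pretests(pretests)
    return {m for m in markers if m.target_fluids - excluded}


def _nasal_call(pretests: PreTestPanel) -> str:
    """Resolve a nasal-pair detection using the blood pre-test."""
    if pretests.blood is PreTest.POSITIVE:
        return BodyFluid.NASAL_BLOOD.value
    if pretests.blood is PreTest.NEGATIVE:
        return BodyFluid.NASAL_SECRETION.value
    return NASAL_PAIR_LABEL


def classify(
    profile: Mapping[str, float],
    pretests: PreTestPanel,
    rules: Sequence[ThresholdRule] | None = None,
    sample_id: str = "",
) -> ClassificationResult:
    """Run the decision workflow on one collapsed methylation profile.

    ``profile`` maps marker short names to methylation percentages (QC-failed
    markers simply absent).  Deterministic: a pure function of (profile,
    pretests, rules).
    """
    rules = default_rules() if rules is None else rules
    rule_names = {r.marker.short_name for r in rules}
    for marker, value in profile.items():
        if marker not in rule_names:
            raise KeyError(f"marker {marker!r} absent from rules")
        if not 0 <= value <= 100:
            raise ValueError(f"{marker}: methylation {value} outside [0, 100]")

    result = ClassificationResult(sample_id=sample_id)
    excluded = exclude_by_pretests(pretests)
    for fluid in excluded:
        result.excluded_fluids[fluid.value] = "negative pre-test"

    fired_outcomes: list[str] = []
    for marker in MARKER_ORDER:
        if marker not in profile:
            continue
        value = profile[marker]
        tiers = resolve_thresholds(marker, pretests, rules)
        fired = next((t for t in tiers if t.fires(value)), None)
        if fired is None:
            result.evidence.append(
                EvidenceRow(marker, value, "no tier fired", False, "no call")
            )
            continue
        fired_outcomes.append(fired.outcome)
        result.evidence.append(
            EvidenceRow(marker, value, fired.describe(), True, fired.outcome)
        )

    calls: set[str] = set()
    partials: set[str] = set()
    mixture_band = False
    for outcome in fired_outcomes:
        if outcome == "nasal_pair_full" or outcome == "nasal_band":
            calls.add(_nasal_call(pretests))
        elif outcome == "peripheral_blood_pure":
            calls.add(BodyFluid.PERIPHERAL_BLOOD.value)
        elif outcome == "menstrual_blood_full":
            calls.add(BodyFluid.MENSTRUAL_BLOOD.value)
        elif outcome == "menstrual_sperm_mixture":
            calls.add(BodyFluid.MENSTRUAL_BLOOD.value)
            calls.add(BodyFluid.SPERM_SECRETION.value)
            mixture_band = True
        elif outcome == "saliva_full":
            calls.add(BodyFluid.SALIVA.value)
        elif outcome == "saliva_partial":
            partials.add(BodyFluid.SALIVA.value)
        elif outcome == "vaginal_full":
            calls.add(BodyFluid.VAGINAL_SECRETION.value)
        elif outcome == "vaginal_tract_partial":
            if pretests.blood is PreTest.NEGATIVE:
                partials.add(BodyFluid.VAGINAL_SECRETION.value)
            else:
                partials.add(VAGINAL_TRACT_LABEL)
        elif outcome == "sperm_full":
            calls.add(BodyFluid.SPERM_SECRETION.value)
        else:  # pragma: no cover - config with custom outcomes
            result.warnings.append(f"unmapped tier outcome {outcome!r}")

    # full calls supersede the same fluid as a partial component
    partials -= calls

    # pre-test-supported components
    n27 = profile.get("N27SE")
    if pretests.sperm is PreTest.POSITIVE and BodyFluid.SPERM_SECRETION.value not in calls:
        if n27 is not None and n27 < SPERM_MIXTURE_FLOOR:
            result.warnings.append(
                "positive sperm pre-test contradicted by N27SE "
                f"{n27:g}% (< {SPERM_MIXTURE_FLOOR:g}%)"
            )
        else:
            partials.add(BodyFluid.SPERM_SECRETION.value)
    sa4 = profile.get("SA4")
    if pretests.saliva is PreTest.POSITIVE and BodyFluid.SALIVA.value not in calls:
        if sa4 is None:
            partials.add(BodyFluid.SALIVA.value)
        elif sa4 <= SALIVA_PARTIAL_BOUND:
            result.warnings.append(
                f"positive saliva pre-test contradicted by SA4 {sa4:g}% "
                f"(<= {SALIVA_PARTIAL_BOUND:g}%)"
            )

    # exclusion wins over marker evidence
    excluded_names = {f.value for f in excluded}
    for pool in (calls, partials):
        for fluid in sorted(pool & excluded_names):
            pool.discard(fluid)
            result.warnings.append(
                f"tier evidence for {fluid} suppressed by negative pre-test"
            )

    # unexplained blood positivity
    blood_names = {f.value for f in BodyFluid if f.blood_containing}
    if pretests.blood is PreTest.POSITIVE and not (
        (calls | partials) & (blood_names | {NASAL_PAIR_LABEL, VAGINAL_TRACT_LABEL})
    ):
        result.warnings.append(
            "positive blood pre-test but no blood-containing fluid identified"
        )

    # menstrual blood vs peripheral-blood/vaginal mixture cannot be separated
    v2 = profile.get("V2")
    b7 = profile.get("B7")
    if (
        pretests.blood is PreTest.POSITIVE
        and v2 is not None
        and v2 > 25
        and (b7 is None or b7 <= 80)
    ):
        result.ambiguity_flags.append(
            "menstrual blood or peripheral-blood/vaginal-secretion mixture"
        )

    # coverage warning for QC-degraded profiles
    missing = [m for m in MARKER_ORDER if m in rule_names and m not in profile]
    if missing and profile:
        result.warnings.append("markers not evaluated: " + ", ".join(missing))

    result.called_fluids = calls
    result.partial_components = partials
    result.mixture = mixture_band or len(calls | partials) > 1
    return result
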