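"""Synthetic stain generator.

Emulates the reference study's per-secretion methylation distributions so the
calibration, classification and validation stages can be exercised without
real casework material.  Each (fluid, marker) cell is modelled as a normal
distribution with the study cohort's mean and SD, clipped to [0, 100] (the
parent normal is recentred so the clipped draw keeps the published mean);
documented outliers (the low peripheral-blood B7 tail, the two low sperm
N27SE values, the single 8% nasal N27SE value) are injected as an explicit
outlier component so the generator reproduces the published ranges, not just
the moments.  Nasal secretion and nasal blood share one distribution — the
reference cohort pooled them.

Mixtures are modelled as DNA-mass-weighted arithmetic means of independent
single-source draws, which is the standard behaviour of methylation
percentages in pooled DNA.  Duplicate pyrosequencing measurements are
derived from one latent per-marker value plus bounded symmetric noise
(±2.5 points by default) so duplicate deviation stays within the 5-point
acceptance bound; QC failures (excess deviation, failed bisulfite conversion
controls) can be injected at configurable rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .panel import MARKER_ORDER, BodyFluid, PreTest, PreTestPanel
from .records import SampleRecord

__all__ = [
    "MarkerDistribution",
    "OutlierSpec",
    "MixtureSpec",
    "default_distributions",
    "draw_single_source",
    "mix_profile",
    "derive_pretests",
    "generate_cohort",
    "DEFAULT_DUPLICATE_NOISE",
]

#: Half-width (percentage points) of the duplicate measurement noise; chosen
#: so |rep1 - rep2| <= 5 points, the study's duplicate acceptance bound.
DEFAULT_DUPLICATE_NOISE = 2.5


@dataclass(frozen=True)
class OutlierSpec:
    """Occasional off-distribution values, as noted in the reference cohorts.

    ``kind`` is ``points`` (uniform choice among fixed values) or ``uniform``
    (uniform draw between two bounds).
    """

    rate: float
    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError(f"outlier rate {self.rate} outside [0, 1]")
        if self.kind not in ("points", "uniform"):
            raise ValueError(f"unknown outlier kind {self.kind!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "points":
            return float(rng.choice(self.params))
        lo, hi = self.params
        return float(rng.uniform(lo, hi))


@dataclass(frozen=True)
class MarkerDistribution:
    fluid: BodyFluid
    marker: str
    mean: float
    sd: float
    n_reference: int
    outlier_spec: OutlierSpec | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mean <= 100:
            raise ValueError(f"mean {self.mean} outside [0, 100]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_reference < 1:
            raise ValueError("n_reference must be >= 1")


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of a stain as (fluid, DNA-mass weight) components."""

    components: tuple[tuple[BodyFluid, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, expected 1")
        for fluid, w in self.components:
            if not 0 < w <= 1:
                raise ValueError(f"weight {w} for {fluid} outside (0, 1]")

    @classmethod
    def single(cls, fluid: BodyFluid) -> "MixtureSpec":
        return cls(((fluid, 1.0),))

    @classmethod
    def of(cls, **weights: float) -> "MixtureSpec":
        return cls(tuple((BodyFluid(name), w) for name, w in weights.items()))

    @property
    def is_single_source(self) -> bool:
        return len(self.components) == 1

    def label(self) -> str:
        return "+".join(f"{f.value}:{w:g}" for f, w in self.components)


# Reference cohort per-(fluid group, marker) statistics: (n, mean %, SD %).
# Nasal secretion and nasal blood were pooled in the reference cohort.
_GROUPS = ("nasal", "blood", "menstrual_blood", "saliva", "vaginal_secretion",
           "sperm_secretion")

_REFERENCE_STATS: dict[str, dict[str, tuple[int, float, float]]] = {
    "NB21": {
        "nasal": (46, 75.13, 17.55),
        "blood": (44, 89.93, 5.74),
        "menstrual_blood": (18, 82.94, 7.44),
        "saliva": (46, 91.96, 5.78),
        "vaginal_secretion": (30, 82.23, 7.5),
        "sperm_secretion": (19, 98.21, 1.91),
    },
    "B7": {
        "nasal": (46, 37.65, 26.84),
        "blood": (42, 87.43, 7.11),
        "menstrual_blood": (27, 41.37, 22.75),
        "saliva": (44, 30.57, 16.42),
        "vaginal_secretion": (22, 30.91, 13.87),
        "sperm_secretion": (18, 9.06, 7.77),
    },
    "MB4": {
        "nasal": (44, 7.52, 4.49),
        "blood": (47, 9.47, 3.53),
        "menstrual_blood": (23, 20.39, 11.84),
        "saliva": (45, 7.76, 3.68),
        "vaginal_secretion": (24, 5.79, 3.11),
        "sperm_secretion": (18, 5.00, 2.69),
    },
    "SA4": {
        "nasal": (45, 7.49, 3.41),
        "blood": (45, 5.82, 4.27),
        "menstrual_blood": (18, 5.22, 2.46),
        "saliva": (46, 38.98, 10.91),
        "vaginal_secretion": (18, 6.89, 3.62),
        "sperm_secretion": (17, 2.00, 1.28),
    },
    "V2": {
        "nasal": (45, 8.51, 3.19),
        "blood": (45, 12.60, 4.13),
        "menstrual_blood": (18, 22.33, 9.30),
        "saliva": (41, 11.32, 4.53),
        "vaginal_secretion": (22, 53.55, 13.35),
        "sperm_secretion": (19, 8.89, 3.42),
    },
    "N27SE": {
        "nasal": (52, 31.40, 8.76),
        "blood": (46, 24.89, 3.97),
        "menstrual_blood": (20, 23.65, 8.82),
        "saliva": (42, 20.36, 5.80),
        "vaginal_secretion": (21, 14.62, 3.85),
        "sperm_secretion": (18, 90.39, 5.31),
    },
}

# Documented off-distribution values in the reference cohorts.
_DEFAULT_OUTLIERS: dict[tuple[str, str], OutlierSpec] = {
    ("B7", "blood"): OutlierSpec(7 / 42, "uniform", (60.0, 87.43)),
    ("N27SE", "sperm_secretion"): OutlierSpec(2 / 18, "points", (81.0, 73.0)),
    ("N27SE", "nasal"): OutlierSpec(1 / 52, "points", (8.0,)),
}

# Post-menopausal vaginal secretion shifts V2 sharply downward.
_POSTMENOPAUSE_V2 = (22.0, 7.0)


def _group_of(fluid: BodyFluid) -> str:
    if fluid in (BodyFluid.NASAL_SECRETION, BodyFluid.NASAL_BLOOD):
        return "nasal"
    if fluid is BodyFluid.PERIPHERAL_BLOOD:
        return "blood"
    return fluid.value


def default_distributions(
    include_outliers: bool = True,
    postmenopausal_vaginal: bool = False,
) -> dict[tuple[BodyFluid, str], MarkerDistribution]:
    """The default generator parameter set, one cell per (fluid, marker).

    ``postmenopausal_vaginal`` swaps the V2 vaginal cell for the
    post-menopause subpopulation (mean 22%, SD 7%); default off.
    """
    table: dict[tuple[BodyFluid, str], MarkerDistribution] = {}
    for fluid in BodyFluid:
        group = _group_of(fluid)
        for marker in MARKER_ORDER:
            n, mean, sd = _REFERENCE_STATS[marker][group]
            if (
                postmenopausal_vaginal
                and fluid is BodyFluid.VAGINAL_SECRETION
                and marker == "V2"
            ):
                mean, sd = _POSTMENOPAUSE_V2
            outlier = _DEFAULT_OUTLIERS.get((marker, group)) if include_outliers else None
            table[(fluid, marker)] = MarkerDistribution(
                fluid, marker, mean, sd, n, outlier
            )
    return table


Distributions = Mapping[tuple[BodyFluid, str], MarkerDistribution]


@lru_cache(maxsize=None)
def _clip_adjusted_mu(mean: float, sd: float) -> float:
    """Location of the underlying normal so the [0, 100]-clipped draw has
    expectation exactly ``mean``.

    Plain clipping pulls the mean of near-boundary cells inward (NB21 in
    sperm sits at 98.21 with SD 1.91, where the bias exceeds the Monte
    Carlo error at large n); recentring the parent normal keeps the emitted
    cohort mean on the published value.  The shift is negligible for
    interior cells.
    """
    if sd == 0:
        return mean

    def emitted_mean(mu: float) -> float:
        a = (0.0 - mu) / sd
        b = (100.0 - mu) / sd
        return (
            100.0 * norm.sf(b)
            + mu * (norm.cdf(b) - norm.cdf(a))
            - sd * (norm.pdf(b) - norm.pdf(a))
        )

    lo, hi = mean - 10 * sd - 1, mean + 10 * sd + 1
    return float(brentq(lambda mu: emitted_mean(mu) - mean, lo, hi, xtol=1e-10))


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def draw_single_source(
    fluid: BodyFluid,
    marker: str,
    rng_seed=None,
    distributions: Distributions | None = None,
    size: int | None = None,
):
    """Draw methylation value(s) for a single-source stain at one marker.

    Values come from a normal distribution with the cell's mean and SD,
    clipped to [0, 100]; with probability ``outlier_spec.rate`` a value is
    replaced by a draw from the outlier component.  ``size=None`` returns a
    scalar, otherwise an ndarray.
    """
    dists = default_distributions() if distributions is None else distributions
    key = (fluid, marker)
    if key not in dists:
        raise KeyError(f"no distribution for ({fluid.value}, {marker})")
    dist = dists[key]
    rng = _as_rng(rng_seed)

    n = 1 if size is None else size
    mu = _clip_adjusted_mu(dist.mean, dist.sd)
    values = np.clip(rng.normal(mu, dist.sd, size=n), 0.0, 100.0)
    if dist.outlier_spec is not None and dist.outlier_spec.rate > 0:
        mask = rng.random(n) < dist.outlier_spec.rate
        for i in np.nonzero(mask)[0]:
            values[i] = np.clip(dist.outlier_spec.draw(rng), 0.0, 100.0)
    return float(values[0]) if size is None else values


def mix_profile(
    spec: MixtureSpec,
    marker: str,
    rng_seed=None,
    distributions: Distributions | None = None,
) -> float:
    """Methylation of a (possibly mixed) stain at one marker.

    Weight-weighted arithmetic mean of independent single-source draws,
    clipped to [0, 100].
    """
    rng = _as_rng(rng_seed)
    value = sum(
        w * draw_single_source(fluid, marker, rng, distributions)
        for fluid, w in spec.components
    )
    return float(np.clip(value, 0.0, 100.0))


def derive_pretests(spec: MixtureSpec, detection_floor: float = 0.0) -> PreTestPanel:
    """Rapid-test results implied by a stain's composition.

    A test is positive iff some component triggering it carries more than
    ``detection_floor`` of the DNA mass; otherwise negative.  This idealises
    the rapid tests as perfectly sensitive above the floor.
    """
    if not 0 <= detection_floor < 1:
        raise ValueError("detection_floor must be in [0, 1)")

    def state(trigger: str) -> PreTest:
        hit = any(
            w > detection_floor and trigger in fluid.pretest_triggers
            for fluid, w in spec.components
        )
        return PreTest.POSITIVE if hit else PreTest.NEGATIVE

    return PreTestPanel(blood=state("blood"), saliva=state("saliva"),
                        sperm=state("sperm"))


def generate_cohort(
    design: Sequence[tuple[MixtureSpec, int]],
    rng_seed: int = 0,
    distributions: Distributions | None = None,
    markers: Sequence[str] = MARKER_ORDER,
    noise_amplitude: float = DEFAULT_DUPLICATE_NOISE,
    deviation_bound: float = 5.0,
    deviation_fail_rate: float = 0.0,
    conversion_fail_rate: float = 0.0,
    detection_floor: float = 0.0,
    concentration_range: tuple[float, float] = (2.5, 50.0),
    id_prefix: str = "S",
) -> list[SampleRecord]:
    """Generate a reproducible cohort of synthetic stains.

    For each sample a latent per-marker methylation value is drawn via
    :func:`mix_profile`; the two replicates are the latent value plus
    independent uniform noise on ±``noise_amplitude`` points.  With
    probability ``deviation_fail_rate`` a sample-marker pair instead gets a
    replicate pushed beyond ``deviation_bound`` (QC-failure injection), and
    with probability ``conversion_fail_rate`` a sample's bisulfite
    conversion control is marked failed.  Per-sample RNG streams are spawned
    from the master seed by counter, so identical (design, seed) give
    byte-identical cohorts regardless of chunking.
    """
    if not design:
        raise ValueError("empty design")
    for _, count in design:
        if count < 1:
            raise ValueError("counts must be >= 1")

    dists = default_distributions() if distributions is None else distributions
    total = sum(count for _, count in design)
    streams = np.random.SeedSequence(rng_seed).spawn(total)

    records: list[SampleRecord] = []
    idx = 0
    for spec, count in design:
        pretests = derive_pretests(spec, detection_floor)
        for _ in range(count):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            replicates: dict[str, tuple[float, ...]] = {}
            for marker in markers:
                latent = mix_profile(spec, marker, rng, dists)
                noise = rng.uniform(-noise_amplitude, noise_amplitude, size=2)
                r1, r2 = np.clip(latent + noise, 0.0, 100.0)
                if deviation_fail_rate > 0 and rng.random() < deviation_fail_rate:
                    # push rep2 just past the acceptance bound
                    shift = deviation_bound + rng.uniform(0.5, 3.0)
                    r2 = float(np.clip(r1 + shift if r1 < 50 else r1 - shift, 0.0, 100.0))
                replicates[marker] = (float(r1), float(r2))
            conversion_ok = not (
                conversion_fail_rate > 0 and rng.random() < conversion_fail_rate
            )
            records.append(
                SampleRecord(
                    sample_id=f"{id_prefix}{idx:05d}",
                    pretests=pretests,
                    replicates=replicates,
                    conversion_control_pass=conversion_ok,
                    concentration_ng_ul=float(rng.uniform(*concentration_range)),
                    true_composition=spec.label(),
                )
            )
    return records
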