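"""Synthetic stand-ins for the restricted fatality and claims registries.

The real sources — coronial case records and the national workers'
compensation data set — are access-restricted, so this module generates
case-level records whose aggregate structure matches the published
marginal tables: work-status, agent, age-band and sex margins for
fatalities; severity mix, agency-of-injury shares, weeks-lost and cost
distributions for claims (serious-claim medians calibrated to the
published 6.3 weeks and $11,750).

Everything is driven by explicit :class:`MarginalSpec` objects (category ->
probability) with packaged defaults derived from the published counts, and
by a single integer seed: the same seed and spec always produce the same
records, byte for byte once written.

What the generator deliberately does NOT emulate: correlations between
axes beyond those stated (e.g. agent and age are sampled independently),
within-band age structure (uniform), secular trends across years, and any
jurisdictional structure.  Green tests downstream therefore establish
correctness of the *pipeline arithmetic*, not epidemiological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from . import published
from .records import (
    AGENT_VOCABULARY,
    BODILY_LOCATIONS,
    ClaimRecord,
    FatalityCase,
    MECHANISM_CATEGORIES,
    NATURE_CATEGORIES,
    SERIOUS_WEEKS_THRESHOLD,
    WORK_STATUSES,
)
from .tabulate import DEFAULT_AGE_BANDS, AgeBand


class SpecError(ValueError):
    """A marginal specification is inconsistent with the category vocabulary."""


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal distribution for one categorical axis."""

    axis: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        if not self.probs:
            raise SpecError(f"axis {self.axis!r}: empty probability map")
        if any(p < 0 for p in self.probs.values()):
            raise SpecError(f"axis {self.axis!r}: negative probability")
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"axis {self.axis!r}: probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(cls, axis: str, counts: dict[str, float]) -> "MarginalSpec":
        total = sum(counts.values())
        return cls(axis, {k: v / total for k, v in counts.items()})

    def categories(self) -> list[str]:
        return list(self.probs)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cats = np.array(self.categories(), dtype=object)
        p = np.array([self.probs[c] for c in cats], dtype=float)
        return rng.choice(cats, size=n, p=p)


# --------------------------------------------------------------------------
# Default fatality specs (published margins)
# --------------------------------------------------------------------------

def default_fatality_specs() -> dict[str, MarginalSpec]:
    agent_counts = {
        f"{group}/{agent}": total
        for group, agents in published.FATALITY_AGENT_TABLE.items()
        for agent, (_, _, total) in agents.items()
    }
    return {
        "work_status": MarginalSpec.from_counts(
            "work_status",
            {
                "work": published.N_WORK_RELATED,
                "non_work": published.N_NON_WORK,
                "unknown": published.N_UNKNOWN_WORK_STATUS,
            },
        ),
        "agent": MarginalSpec.from_counts("agent", agent_counts),
        "age_band": MarginalSpec.from_counts(
            "age_band", {band: n for band, (n, _, _) in published.AGE_BAND_COSTS.items()}
        ),
        # published: 94% of work-related cases were male; non-work mix is a
        # documented default (the source is silent)
        "sex_work": MarginalSpec("sex_work", {"male": 0.94, "female": 0.06}),
        "sex_non_work": MarginalSpec("sex_non_work", {"male": 0.80, "female": 0.20}),
        # placeholder occupation mix over standard classification prefixes
        "occupation": MarginalSpec(
            "occupation",
            {"1211": 0.30, "1212": 0.20, "121": 0.10, "8414": 0.25, "7": 0.10, "3": 0.05},
        ),
    }


def _validate_fatality_specs(
    specs: dict[str, MarginalSpec], age_bands: tuple[AgeBand, ...]
) -> None:
    required = {"work_status", "agent", "age_band", "sex_work", "sex_non_work"}
    missing = required - set(specs)
    if missing:
        raise SpecError(f"fatality specs missing axes: {sorted(missing)}")
    for cat in specs["work_status"].categories():
        if cat not in WORK_STATUSES:
            raise SpecError(f"unknown work status category {cat!r}")
    for cat in specs["agent"].categories():
        group, _, agent = cat.partition("/")
        if group not in AGENT_VOCABULARY or agent not in AGENT_VOCABULARY[group]:
            raise SpecError(f"unknown agent category {cat!r}")
    band_labels = {b.label for b in age_bands}
    for cat in specs["age_band"].categories():
        if cat not in band_labels:
            raise SpecError(f"unknown age band {cat!r}")
    for axis in ("sex_work", "sex_non_work"):
        for cat in specs[axis].categories():
            if cat not in ("male", "female"):
                raise SpecError(f"unknown sex category {cat!r}")


def generate_fatality_cases(
    n: int,
    seed: int,
    specs: dict[str, MarginalSpec] | None = None,
    age_bands: tuple[AgeBand, ...] = DEFAULT_AGE_BANDS,
    year_range: tuple[int, int] = published.FATALITY_YEAR_RANGE,
    max_age: int = 95,
    min_occupation_age: int = 15,
) -> list[FatalityCase]:
    """Draw ``n`` synthetic fatality cases from the configured margins.

    Axes are sampled independently (sex conditionally on work status);
    within-band ages are uniform over the band's integer ages, with the
    open top band truncated at ``max_age``.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    specs = dict(default_fatality_specs() if specs is None else specs)
    _validate_fatality_specs(specs, age_bands)
    bands = {b.label: b for b in age_bands}
    rng = np.random.default_rng(seed)

    statuses = specs["work_status"].sample(rng, n)
    agents = specs["agent"].sample(rng, n)
    band_labels = specs["age_band"].sample(rng, n)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n)
    cases = []
    for k in range(n):
        band = bands[band_labels[k]]
        upper = band.upper if band.upper is not None else max_age
        age = int(rng.integers(band.lower, upper + 1))
        status = str(statuses[k])
        sex_axis = "sex_non_work" if status == "non_work" else "sex_work"
        sex = str(specs[sex_axis].sample(rng, 1)[0])
        if age >= min_occupation_age and "occupation" in specs:
            occupation = str(specs["occupation"].sample(rng, 1)[0])
        else:
            occupation = None
        group, _, agent = str(agents[k]).partition("/")
        cases.append(
            FatalityCase(
                case_id=f"F{k + 1:06d}",
                year=int(years[k]),
                age=age,
                sex=sex,
                work_related=status,
                agent_group=group,
                agent=agent,
                occupation_code=occupation,
            )
        )
    return cases


# --------------------------------------------------------------------------
# Claims
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClaimGenSpec:
    """Severity, duration and cost model for synthetic claims.

    Serious-claim weeks lost follow a lognormal truncated below the
    five-day severity threshold, with the location calibrated numerically
    so the *truncated* median equals ``serious_median_weeks``.  Cost is
    ``base x weeks^elasticity x lognormal noise`` with ``base`` set so the
    serious-claim median cost is ``serious_median_cost``; the dispersion
    defaults put roughly 95% of total cost on serious claims and annual
    totals near the published scale.
    """

    serious_share: dict[str, float] = field(
        default_factory=lambda: {
            **{fy: 0.540 for fy in published.FIN_YEARS_PERIOD_1},
            **{fy: 0.585 for fy in published.FIN_YEARS_PERIOD_2},
        }
    )
    serious_median_weeks: float = published.SERIOUS_MEDIAN_WEEKS
    serious_weeks_sigma: float = 1.6
    serious_median_cost: float = published.SERIOUS_MEDIAN_COST
    cost_elasticity: float = 1.0
    cost_noise_sigma: float = 0.94
    agency: MarginalSpec = field(
        default_factory=lambda: MarginalSpec.from_counts(
            "agency",
            {g: t1 + t2 for g, (t1, _, _, t2, _, _) in published.CLAIMS_BY_AGENCY.items()},
        )
    )
    nature: MarginalSpec = field(
        default_factory=lambda: MarginalSpec(
            "nature",
            dict(
                zip(
                    NATURE_CATEGORIES,
                    # top three ~75% of claims, per the published narrative
                    (0.38, 0.22, 0.15, 0.08, 0.17),
                )
            ),
        )
    )
    mechanism: MarginalSpec = field(
        default_factory=lambda: MarginalSpec(
            "mechanism",
            dict(zip(MECHANISM_CATEGORIES, (0.30, 0.25, 0.20, 0.08, 0.17))),
        )
    )
    bodily_location: MarginalSpec = field(
        default_factory=lambda: MarginalSpec(
            "bodily_location",
            # upper limbs just under 40%; top four > 90%
            dict(zip(BODILY_LOCATIONS, (0.38, 0.25, 0.17, 0.12, 0.08))),
        )
    )


def _truncated_lognormal_mu(median: float, sigma: float, lower: float) -> float:
    """Location ``mu`` such that a lognormal(mu, sigma) truncated to
    ``[lower, inf)`` has the requested median."""
    log_c = math.log(lower)

    def trunc_median(mu: float) -> float:
        f_c = norm.cdf((log_c - mu) / sigma)
        return math.exp(mu + sigma * norm.ppf((1.0 + f_c) / 2.0))

    target = math.log(median)
    return brentq(lambda mu: trunc_median(mu) - median, target - 5 * sigma, target + sigma)


def _sample_truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lower: float
) -> np.ndarray:
    f_c = norm.cdf((math.log(lower) - mu) / sigma)
    u = rng.uniform(f_c, 1.0, size=n)
    return np.exp(mu + sigma * norm.ppf(u))


def generate_claims(
    per_year: dict[str, int],
    seed: int,
    spec: ClaimGenSpec | None = None,
) -> list[ClaimRecord]:
    """Draw synthetic workers' compensation claims, ``per_year`` per label."""
    if not per_year:
        raise ValueError("per_year must be non-empty")
    for fy, count in per_year.items():
        if count < 0:
            raise ValueError(f"negative claim count {count} for {fy!r}")
    spec = spec or ClaimGenSpec()
    rng = np.random.default_rng(seed)
    mu = _truncated_lognormal_mu(
        spec.serious_median_weeks, spec.serious_weeks_sigma, SERIOUS_WEEKS_THRESHOLD
    )
    cost_base = spec.serious_median_cost / spec.serious_median_weeks**spec.cost_elasticity

    claims: list[ClaimRecord] = []
    k = 0
    for fy in per_year:
        n = per_year[fy]
        if n == 0:
            continue
        p_serious = spec.serious_share.get(fy, 0.55)
        serious = rng.random(n) < p_serious
        weeks = np.where(
            serious,
            _sample_truncated_lognormal(
                rng, n, mu, spec.serious_weeks_sigma, SERIOUS_WEEKS_THRESHOLD
            ),
            rng.uniform(0.0, SERIOUS_WEEKS_THRESHOLD, size=n),
        )
        noise = np.exp(rng.normal(0.0, spec.cost_noise_sigma, size=n))
        costs = cost_base * weeks**spec.cost_elasticity * noise
        agencies = spec.agency.sample(rng, n)
        natures = spec.nature.sample(rng, n)
        mechanisms = spec.mechanism.sample(rng, n)
        locations = spec.bodily_location.sample(rng, n)
        for idx in range(n):
            k += 1
            claims.append(
                ClaimRecord(
                    claim_id=f"C{k:07d}",
                    fin_year=fy,
                    severity="serious" if serious[idx] else "minor",
                    agency_group=str(agencies[idx]),
                    nature=str(natures[idx]),
                    mechanism=str(mechanisms[idx]),
                    bodily_location=str(locations[idx]),
                    weeks_lost=float(weeks[idx]),
                    cost=float(costs[idx]),
                )
            )
    return claims


def default_claims_per_year() -> dict[str, int]:
    """Published annual mean claim counts per financial year."""
    return {
        **{fy: 5045 for fy in published.FIN_YEARS_PERIOD_1},
        **{fy: 4920 for fy in published.FIN_YEARS_PERIOD_2},
    }
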