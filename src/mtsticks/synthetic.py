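"""Synthetic section-count datasets with realistic dispersion structure.

The fixed-m stick model is Poisson-binomial per section and therefore
always underdispersed (variance ≤ mean).  Real cross-animal TEM counts
can be overdispersed — e.g. a sample variance of 81 against a mean of 67 —
which no fixed-m model reproduces.  The generator therefore supports
between-animal variation in the microtubule number m via a gamma-Poisson
(negative-binomial) mixture; for fixed stick length h the marginal
moments follow the law of total variance:

    mean     = E[m] · p̄
    variance = E[m] · (p̄ - E[p²]) + p̄² · Var(m)        (p̄ = E[h]/L)

which reduces to E[m]p̄(1-p̄) + p̄²Var(m) when h is fixed.  Length
heterogeneity alone can only *reduce* the variance below the binomial
value, so it is never offered as the overdispersion knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .stick_model import (
    AxonGeometry,
    MTSet,
    SectionPlan,
    SeedLike,
    simulate_experiment,
)
from .summary_tests import SummaryStats

__all__ = [
    "FixedCount",
    "NearFixedCount",
    "GammaPoissonCount",
    "FixedLength",
    "UniformLength",
    "ScenarioConfig",
    "generate_counts",
    "summarize_counts",
    "wt_like_scenario",
    "mutant_like_scenario",
    "paper_like_pair",
    "DEFAULT_AXON_LENGTH_UM",
]

#: Default axon length used by the shipped example scenarios (µm).  The
#: model is fully parametric; this value only anchors examples and tests.
DEFAULT_AXON_LENGTH_UM = 100.0


# --------------------------------------------------------------------------
# distributions for the per-animal microtubule number m

@dataclass(frozen=True)
class FixedCount:
    """Every animal has exactly ``m`` microtubules."""

    m: int

    def __post_init__(self) -> None:
        if self.m < 0 or self.m != int(self.m):
            raise ValueError(f"m must be a non-negative integer, got {self.m}")

    @property
    def mean(self) -> float:
        return float(self.m)

    @property
    def var(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator) -> int:
        return int(self.m)


@dataclass(frozen=True)
class NearFixedCount:
    """Two-point mixture on {floor(mean), ceil(mean)} hitting a non-integer
    mean with the smallest possible variance (frac·(1-frac))."""

    target_mean: float

    def __post_init__(self) -> None:
        if self.target_mean < 0:
            raise ValueError(f"mean must be >= 0, got {self.target_mean}")

    @property
    def mean(self) -> float:
        return float(self.target_mean)

    @property
    def var(self) -> float:
        frac = self.target_mean - math.floor(self.target_mean)
        return frac * (1.0 - frac)

    def sample(self, rng: np.random.Generator) -> int:
        lo = math.floor(self.target_mean)
        frac = self.target_mean - lo
        return int(lo + (rng.random() < frac))


@dataclass(frozen=True)
class GammaPoissonCount:
    """Gamma-mixed Poisson (negative binomial) microtubule number.

    Parametrised by its mean and variance; requires var >= mean (the
    gamma-Poisson family cannot be underdispersed).  var == mean gives a
    pure Poisson.
    """

    mean: float
    var: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"mean must be > 0, got {self.mean}")
        if self.var < self.mean:
            raise ValueError(
                f"gamma-Poisson requires var >= mean, got var={self.var} "
                f"< mean={self.mean}"
            )

    def sample(self, rng: np.random.Generator) -> int:
        if self.var == self.mean:
            return int(rng.poisson(self.mean))
        theta = self.var / self.mean - 1.0  # gamma scale
        k = self.mean / theta  # gamma shape
        return int(rng.poisson(rng.gamma(k, theta)))


CountDistribution = Union[FixedCount, NearFixedCount, GammaPoissonCount]


# --------------------------------------------------------------------------
# distributions for the per-stick length h

@dataclass(frozen=True)
class FixedLength:
    """Every stick has length ``h`` (µm)."""

    h: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")

    @property
    def support_max(self) -> float:
        return self.h

    def p_mean(self, L: float) -> float:
        return self.h / L

    def p2_mean(self, L: float) -> float:
        return (self.h / L) ** 2

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.h)


@dataclass(frozen=True)
class UniformLength:
    """Stick lengths i.i.d. uniform on [lo, hi] (µm)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.hi:
            raise ValueError(f"need 0 < lo <= hi, got ({self.lo}, {self.hi})")

    @property
    def support_max(self) -> float:
        return self.hi

    def p_mean(self, L: float) -> float:
        return (self.lo + self.hi) / (2 * L)

    def p2_mean(self, L: float) -> float:
        # E[h²] = (lo² + lo·hi + hi²)/3
        return (self.lo**2 + self.lo * self.hi + self.hi**2) / (3 * L**2)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size)


LengthDistribution = Union[FixedLength, UniformLength]


# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One genotype's simulation scenario.

    ``fresh_animal_per_section`` (random plans only) draws a new animal per
    section, the design under which cross-section counts are independent.
    """

    genotype: str
    n_animals: int
    m_dist: CountDistribution
    length_dist: LengthDistribution
    axon: AxonGeometry
    plan: SectionPlan
    seed: int | None = 0
    fresh_animal_per_section: bool = True

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError(f"n_animals must be >= 1, got {self.n_animals}")
        if self.length_dist.support_max > self.axon.length_um:
            raise ValueError(
                f"length distribution support (max "
                f"{self.length_dist.support_max} µm) exceeds axon length "
                f"{self.axon.length_um} µm"
            )

    def population_moments(self) -> tuple[float, float]:
        """Marginal (mean, variance) of one count under the circular
        convention, by the law of total variance."""
        L = self.axon.length_um
        p_bar = self.length_dist.p_mean(L)
        p2_bar = self.length_dist.p2_mean(L)
        em, vm = self.m_dist.mean, self.m_dist.var
        mean = em * p_bar
        variance = em * (p_bar - p2_bar) + p_bar**2 * vm
        return mean, variance


def generate_counts(
    config: ScenarioConfig, seed: SeedLike | None = None
) -> pd.DataFrame:
    """Generate a labeled section-count table for one scenario.

    Deterministic per seed; ``seed`` overrides ``config.seed`` when given.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("no seed: set config.seed or pass seed explicitly")

    m_dist, length_dist = config.m_dist, config.length_dist

    def mtset_rule(rng: np.random.Generator) -> MTSet:
        m = m_dist.sample(rng)
        return MTSet(length_dist.sample(rng, m))

    return simulate_experiment(
        mtset_rule,
        config.axon,
        config.plan,
        n_animals=config.n_animals,
        seed=seed,
        genotype=config.genotype,
        fresh_animal_per_section=config.fresh_animal_per_section,
    )


def summarize_counts(
    counts: pd.DataFrame, by: str = "genotype"
) -> dict[str, SummaryStats]:
    """Per-group (mean, sd, n) with the unbiased (n-1) variance.

    Groups are returned in sorted label order; a group with fewer than two
    records is an error naming the group.
    """
    out: dict[str, SummaryStats] = {}
    for label in sorted(counts[by].unique()):
        vals = counts.loc[counts[by] == label, "count"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(
                f"group {label!r} has {vals.size} record(s); need >= 2 for a "
                "standard deviation"
            )
        out[str(label)] = SummaryStats(
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
            n=int(vals.size),
        )
    return out


# --------------------------------------------------------------------------
# shipped example scenarios: wild-type-like (overdispersed) and mutant-like

def wt_like_scenario(
    n_sections: int = 8,
    target_mean: float = 67.0,
    target_var: float = 81.0,
    p_bar: float = 0.7,
    L: float = DEFAULT_AXON_LENGTH_UM,
    seed: int = 0,
) -> tuple[ScenarioConfig, dict]:
    """Overdispersed wild-type-like scenario (random sections, one animal
    per section).

    Solves E[m]·p̄ = target_mean and E[m]p̄(1-p̄) + p̄²Var(m) = target_var
    for a gamma-Poisson m at the chosen crossing probability p̄.  Returns
    the config and a dict with the solved generator truth.
    """
    if not 0 < p_bar < 1:
        raise ValueError(f"p_bar must be in (0, 1), got {p_bar}")
    em = target_mean / p_bar
    vm = (target_var - target_mean * (1.0 - p_bar)) / p_bar**2
    if vm < em:
        raise ValueError(
            f"targets imply Var(m)={vm:.2f} < E[m]={em:.2f}; the "
            "gamma-Poisson mixture cannot reach them at p_bar="
            f"{p_bar} (pick a larger p_bar or smaller target variance)"
        )
    h = p_bar * L
    config = ScenarioConfig(
        genotype="wt",
        n_animals=n_sections,
        m_dist=GammaPoissonCount(mean=em, var=vm),
        length_dist=FixedLength(h),
        axon=AxonGeometry(L, "circular"),
        plan=SectionPlan.random(1),
        seed=seed,
    )
    truth = {"E_m": em, "Var_m": vm, "h": h, "p_bar": p_bar, "L": L}
    return config, truth


def mutant_like_scenario(
    n_sections: int = 8,
    m: int = 120,
    target_mean: float = 85.0,
    L: float = DEFAULT_AXON_LENGTH_UM,
    seed: int = 0,
) -> tuple[ScenarioConfig, dict]:
    """Fixed-m mutant-like scenario: m sticks with h chosen so the mean
    count is ``target_mean`` (h = L·target_mean/m).  The variance is then
    the binomial value target_mean·(1 - target_mean/m), slightly below the
    mean — underdispersed, as a fixed-m model must be."""
    p = target_mean / m
    if not 0 < p < 1:
        raise ValueError(
            f"target mean {target_mean} requires 0 < mean/m < 1, got p={p}"
        )
    h = p * L
    config = ScenarioConfig(
        genotype="mut",
        n_animals=n_sections,
        m_dist=FixedCount(m),
        length_dist=FixedLength(h),
        axon=AxonGeometry(L, "circular"),
        plan=SectionPlan.random(1),
        seed=seed,
    )
    truth = {
        "m": m,
        "h": h,
        "p": p,
        "L": L,
        "mean": target_mean,
        "variance": target_mean * (1.0 - p),
    }
    return config, truth


def paper_like_pair(
    seed: int = 0, n_sections: int = 8, L: float = DEFAULT_AXON_LENGTH_UM
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One wild-type-like and one mutant-like count table, ``n_sections``
    records each, from independent substreams of one seed.

    Population moments: wt-like (67, 81) — overdispersed via between-animal
    m; mutant-like (85, ~24.8) — fixed m = 120.
    """
    ss = np.random.SeedSequence(seed)
    sub_wt, sub_mut = ss.spawn(2)
    wt_cfg, _ = wt_like_scenario(n_sections=n_sections, L=L)
    mut_cfg, _ = mutant_like_scenario(n_sections=n_sections, L=L)
    return (
        generate_counts(wt_cfg, seed=sub_wt),
        generate_counts(mut_cfg, seed=sub_mut),
    )
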