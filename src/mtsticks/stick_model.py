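"""Generative "sticks-in-a-tube" model of microtubule cross-section counts.

An axon is modelled as a one-dimensional tube of length ``L`` (µm) holding
``m`` axis-parallel microtubules ("sticks"), each of length ``h`` (µm),
placed uniformly at random.  A transverse section at coordinate ``s``
intersects every stick whose coverage interval contains ``s``; the number of
intersections ``X`` is the observable that transmission electron microscopy
(TEM) counts on one section.

Two placement conventions are supported:

``circular``
    Stick starts are uniform on ``[0, L)`` and coverage wraps modulo ``L``.
    Every section then sees each stick with probability exactly ``p = h/L``
    and ``X ~ Binomial(m, h/L)``.  This is the default because it realises
    the idealised crossing probability with no edge effects.

``linear``
    Stick starts are uniform on ``[0, L - h]`` so sticks never protrude.
    Sections within ``[h, L - h]`` see each stick with probability
    ``h/(L - h)``; near the ends the probability tapers (see
    :func:`crossing_probability`).  For ``h << L`` both conventions agree
    to first order.

Coverage intervals are half-open ``[a, a + h)`` so that boundary hits are
unambiguous and simulations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AxonGeometry",
    "MTSet",
    "StickPlacement",
    "SectionPlan",
    "SECTION_COLUMNS",
    "crossing_probability",
    "place_sticks",
    "count_intersections",
    "simulate_experiment",
]

#: Canonical column order of a section-count table.
SECTION_COLUMNS = ["animal_id", "genotype", "section_position_um", "count"]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

#: Default serial-section spacing (µm), as used in serial TEM reconstructions.
SERIAL_INCREMENT_UM = 3.2


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AxonGeometry:
    """Axon of length ``length_um`` with a stick-placement convention."""

    length_um: float
    convention: str = "circular"

    def __post_init__(self) -> None:
        if not self.length_um > 0:
            raise ValueError(f"axon length must be > 0, got {self.length_um}")
        if self.convention not in ("circular", "linear"):
            raise ValueError(
                f"convention must be 'circular' or 'linear', got {self.convention!r}"
            )


@dataclass(frozen=True)
class MTSet:
    """A set of microtubules given by their per-stick lengths (µm)."""

    stick_lengths: np.ndarray

    def __init__(self, stick_lengths: Sequence[float]) -> None:
        arr = np.asarray(stick_lengths, dtype=float)
        object.__setattr__(self, "stick_lengths", arr)
        if arr.size and not np.all(arr > 0):
            raise ValueError("every stick length must be strictly positive")

    @property
    def m(self) -> int:
        """Number of microtubules."""
        return int(self.stick_lengths.size)

    def validate_against(self, axon: AxonGeometry) -> None:
        if self.m and np.any(self.stick_lengths > axon.length_um):
            bad = float(self.stick_lengths.max())
            raise ValueError(
                f"stick length {bad} exceeds axon length {axon.length_um}"
            )

    @classmethod
    def fixed(cls, m: int, h: float) -> "MTSet":
        """``m`` sticks all of length ``h``."""
        if m < 0:
            raise ValueError(f"m must be >= 0, got {m}")
        return cls(np.full(m, float(h)))


@dataclass(frozen=True)
class StickPlacement:
    """Realised stick start coordinates for one axon (one animal)."""

    starts: np.ndarray
    mtset: MTSet
    axon: AxonGeometry
    rng_seed: object = None

    def __post_init__(self) -> None:
        if len(self.starts) != self.mtset.m:
            raise ValueError("number of starts must equal number of sticks")


@dataclass(frozen=True)
class SectionPlan:
    """Where to cut the axon: ``random`` positions or a ``serial`` ladder.

    ``positions`` may be ``None``, in which case concrete coordinates are
    drawn (random mode) or offset-anchored (serial mode) when the plan is
    :meth:`realized <realize>` against an axon with an RNG.
    """

    mode: str
    n_sections: int
    increment: float = SERIAL_INCREMENT_UM
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("random", "serial"):
            raise ValueError(f"mode must be 'random' or 'serial', got {self.mode!r}")
        if self.n_sections < 1:
            raise ValueError(f"n_sections must be >= 1, got {self.n_sections}")
        if self.mode == "serial" and not self.increment > 0:
            raise ValueError(f"serial increment must be > 0, got {self.increment}")

    @classmethod
    def random(cls, n_sections: int) -> "SectionPlan":
        return cls(mode="random", n_sections=n_sections)

    @classmethod
    def serial(
        cls,
        n_sections: int,
        increment: float = SERIAL_INCREMENT_UM,
        start: float | None = None,
    ) -> "SectionPlan":
        """Serial ladder of sections spaced ``increment`` µm apart.

        If ``start`` is given, positions are fixed now; otherwise the first
        section gets a seeded uniform offset in ``[0, increment)`` at
        realization time.
        """
        positions = None
        if start is not None:
            positions = start + increment * np.arange(n_sections)
        return cls(mode="serial", n_sections=n_sections, increment=increment,
                   positions=positions)

    def realize(self, axon: AxonGeometry, rng: np.random.Generator) -> np.ndarray:
        """Concrete section coordinates in ``[0, L)`` for one animal."""
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
        elif self.mode == "random":
            pos = rng.uniform(0.0, axon.length_um, self.n_sections)
        else:
            offset = rng.uniform(0.0, self.increment)
            pos = offset + self.increment * np.arange(self.n_sections)
        if np.any(pos < 0) or np.any(pos >= axon.length_um):
            raise ValueError(
                f"section positions must lie in [0, {axon.length_um}); got "
                f"range [{pos.min()}, {pos.max()}]"
            )
        return pos


def crossing_probability(
    h: float, axon: AxonGeometry, position: float | None = None
) -> float:
    """Probability that one stick of length ``h`` crosses a section.

    Circular convention: exactly ``h/L`` for every section position.

    Linear convention (start uniform on ``[0, L-h]``): a section at ``s``
    is crossed when the start lies in ``(s-h, s] ∩ [0, L-h]``, giving

        p(s) = (min(s, L-h) - max(s-h, 0)) / (L-h)

    which equals ``h/(L-h)`` for interior sections ``h <= s <= L-h`` and
    tapers linearly to ``~0`` at the ends; for ``h << L`` this is ``≈ h/L``.
    With ``position=None`` the interior value is returned.
    """
    L = axon.length_um
    if not 0 < h <= L:
        raise ValueError(f"stick length must satisfy 0 < h <= L={L}, got h={h}")
    if position is not None and not 0 <= position < L:
        raise ValueError(f"section position must lie in [0, {L}), got {position}")
    if axon.convention == "circular":
        return h / L
    if h == L:  # degenerate: the stick fills the tube
        return 1.0
    if position is None:
        if h > L - h:
            raise ValueError(
                f"no interior section exists for h={h} > L/2={L / 2}; "
                "pass an explicit position"
            )
        return h / (L - h)
    s = position
    num = min(s, L - h) - max(s - h, 0.0)
    return max(num, 0.0) / (L - h)


def place_sticks(mts: MTSet, axon: AxonGeometry, seed: SeedLike) -> StickPlacement:
    """Place sticks uniformly at random; reproducible for a fixed seed.

    Circular: starts i.i.d. uniform on ``[0, L)``.  Linear: start of stick
    ``i`` uniform on ``[0, L - h_i]``; a full-length stick (``h = L``) is
    degenerate and its start is forced to 0.
    """
    mts.validate_against(axon)
    rng = _as_rng(seed)
    L = axon.length_um
    if axon.convention == "circular":
        starts = rng.uniform(0.0, L, mts.m)
    else:
        span = L - mts.stick_lengths
        # uniform(0, span) per stick; span == 0 forces start 0
        starts = rng.uniform(0.0, 1.0, mts.m) * span
    return StickPlacement(starts=starts, mtset=mts, axon=axon, rng_seed=seed)


def _counts_at(placement: StickPlacement, positions: np.ndarray) -> np.ndarray:
    """Integer intersection counts at each section position."""
    axon = placement.axon
    L = axon.length_um
    positions = np.asarray(positions, dtype=float)
    if np.any(positions < 0) or np.any(positions >= L):
        raise ValueError(f"section positions must lie in [0, {L})")
    if placement.mtset.m == 0:
        return np.zeros(positions.size, dtype=int)
    a = placement.starts[None, :]
    h = placement.mtset.stick_lengths[None, :]
    d = positions[:, None] - a
    if axon.convention == "circular":
        d = np.mod(d, L)
        hit = d < h
    else:
        hit = (d >= 0) & (d < h)
    return hit.sum(axis=1).astype(int)


def count_intersections(
    placement: StickPlacement,
    plan: SectionPlan,
    animal_id: str = "a0",
    genotype: str = "wt",
) -> pd.DataFrame:
    """Count stick crossings at every section of a concretely-positioned plan.

    Returns a section-count table (columns :data:`SECTION_COLUMNS`).  The
    count at section ``s`` is the number of sticks whose half-open coverage
    interval ``[a, a+h)`` — taken modulo ``L`` under the circular
    convention — contains ``s``.
    """
    if plan.positions is None:
        raise ValueError(
            "plan has no concrete positions; call plan.realize(...) first or "
            "use simulate_experiment"
        )
    positions = np.asarray(plan.positions, dtype=float)
    counts = _counts_at(placement, positions)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "genotype": genotype,
            "section_position_um": positions,
            "count": counts,
        },
        columns=SECTION_COLUMNS,
    )


MTSetRule = Union[MTSet, Callable[[np.random.Generator], MTSet]]


def _resolve_mtset(rule: MTSetRule, rng: np.random.Generator) -> MTSet:
    return rule(rng) if callable(rule) else rule


def simulate_experiment(
    mtset_rule: MTSetRule,
    axon: AxonGeometry,
    plan: SectionPlan,
    n_animals: int = 1,
    seed: SeedLike = 0,
    genotype: str = "wt",
    fresh_animal_per_section: bool = True,
) -> pd.DataFrame:
    """Simulate a TEM sectioning experiment and return a count table.

    Serial mode: each of ``n_animals`` animals receives one stick placement
    that is sectioned at every ladder position, so counts within an animal
    share sticks and are dependent.

    Random mode with ``fresh_animal_per_section=True`` (default): every
    section comes from a freshly simulated animal, emulating random
    sections taken from different animals; records are then independent.
    With ``fresh_animal_per_section=False`` each animal is sectioned at
    ``n_sections`` random positions (same-animal sensitivity mode).

    A single top-level seed deterministically derives one substream per
    animal, so increasing ``n_animals`` extends the table without
    reshuffling earlier animals.
    """
    if n_animals < 1:
        raise ValueError(f"n_animals must be >= 1, got {n_animals}")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    fresh = plan.mode == "random" and fresh_animal_per_section
    n_units = n_animals * plan.n_sections if fresh else n_animals
    children = ss.spawn(n_units)
    animal_ids: list[str] = []
    all_positions: list[np.ndarray] = []
    all_counts: list[np.ndarray] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        mts = _resolve_mtset(mtset_rule, rng)
        placement = place_sticks(mts, axon, rng)
        if fresh:
            positions = rng.uniform(0.0, axon.length_um, 1)
        else:
            positions = plan.realize(axon, rng)
        counts = _counts_at(placement, positions)
        animal_ids.extend([f"{genotype}-{i:05d}"] * positions.size)
        all_positions.append(positions)
        all_counts.append(counts)
    return pd.DataFrame(
        {
            "animal_id": animal_ids,
            "genotype": genotype,
            "section_position_um": np.concatenate(all_positions),
            "count": np.concatenate(all_counts),
        },
        columns=SECTION_COLUMNS,
    )
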