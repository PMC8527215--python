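"""Construction of multi-attribute visual choice (MAVC) sets.

The task presents a 3-D cube (the *exemplar*) with an orientation on the X-
and Y-axis, followed after a retention interval by five candidate cubes.  Each
candidate trades off orientation similarity to the exemplar along the two
axes.  Framed in revealed-preference terms, every trial is a linear budget
problem: the participant holds a budget of ``m = 100`` tokens, each token of
similarity along an axis costs ``p_x`` or ``p_y`` tokens, and the five options
are equidistant points on the resulting budget line.  A token buys 0.3 degrees
of rotation toward the exemplar; 0 tokens on an axis means a 30-degree offset,
100 tokens an exact match.

This module owns the geometry and sampling of that construction; scoring of
the resulting choices lives in :mod:`mavc.revealed_preference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EXEMPLAR_ORIENTATIONS",
    "BUDGET",
    "DEG_PER_TOKEN",
    "MAX_OFFSET_DEG",
    "N_OPTIONS",
    "N_TRIALS_PER_BLOCK",
    "RI_MAX_S",
    "Prices",
    "Bundle",
    "ChoiceTrial",
    "Block",
    "draw_prices",
    "make_choice_set",
    "bundle_to_orientation",
    "generate_block",
    "generate_session",
]

#: Permitted exemplar orientations (degrees) on each of the X- and Y-axis.
EXEMPLAR_ORIENTATIONS = (10.0, 75.0, 120.0, 185.0, 250.0, 315.0)

#: Token budget per trial.
BUDGET = 100.0

#: Degrees of rotation toward the exemplar bought by one similarity token.
DEG_PER_TOKEN = 0.3

#: Orientation offset (degrees) of an option with zero similarity tokens.
MAX_OFFSET_DEG = 30.0

#: The two price ranges; each trial assigns them to the axes by a coin flip.
PRICE_RANGE_NARROW = (1.0, 3.0)
PRICE_RANGE_WIDE = (1.0, 10.0)

N_OPTIONS = 5
N_TRIALS_PER_BLOCK = 20

#: Maximum retention interval (seconds).
RI_MAX_S = 30.0


@dataclass(frozen=True)
class Prices:
    """Per-unit token cost of similarity along the X- and Y-axis.

    Exactly one component is drawn from the narrow range [1, 3] and the other
    from the wide range [1, 10]; the assignment of ranges to axes is random
    per trial.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (self.x > 0 and self.y > 0):
            raise ValueError(f"prices must be positive, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Bundle:
    """Similarity tokens purchased on the X- and Y-axis (one choice option)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"token amounts must be non-negative, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def cost(self, prices: Prices) -> float:
        """Total token cost of this bundle at the given prices."""
        return self.x * prices.x + self.y * prices.y


@dataclass
class ChoiceTrial:
    """One budget/price observation with its five-option choice set.

    ``choice_index`` is 1-based (1..5); 0 means "not yet chosen" — chooser
    models from :mod:`mavc.synthetic_data` (or real data) fill it in.
    """

    trial_id: int
    prices: Prices
    budget: float
    exemplar_x: float
    exemplar_y: float
    options: list[Bundle] = field(default_factory=list)
    choice_index: int = 0

    @property
    def chosen_bundle(self) -> Bundle:
        if not 1 <= self.choice_index <= len(self.options):
            raise ValueError(
                f"trial {self.trial_id} has no valid choice_index ({self.choice_index})"
            )
        return self.options[self.choice_index - 1]


@dataclass
class Block:
    """A run of trials sharing a participant and one retention interval."""

    participant_id: int
    block_role: str
    retention_interval: float
    trials: list[ChoiceTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_interval <= RI_MAX_S:
            raise ValueError(
                f"retention interval must lie in [0, {RI_MAX_S}] s, "
                f"got {self.retention_interval}"
            )


def draw_prices(rng: np.random.Generator, integer: bool = False) -> Prices:
    """Draw a price pair: one component uniform on [1, 3], the other on [1, 10].

    The assignment of the narrow/wide range to the X/Y axis is a fair coin
    flip.  With ``integer=True`` prices are drawn uniformly from the integers
    of each range instead of the continuum (sensitivity variant).
    """
    if integer:
        narrow = float(rng.integers(1, 4))
        wide = float(rng.integers(1, 11))
    else:
        narrow = float(rng.uniform(*PRICE_RANGE_NARROW))
        wide = float(rng.uniform(*PRICE_RANGE_WIDE))
    if rng.random() < 0.5:
        return Prices(x=narrow, y=wide)
    return Prices(x=wide, y=narrow)


def make_choice_set(prices: Prices, m: float = BUDGET) -> list[Bundle]:
    """Five equidistant bundles covering the entire budget line.

    Options sit at fractions {0, 1/4, 1/2, 3/4, 1} of the X-intercept
    ``m / p_x``, with the Y-amount determined by the budget identity
    ``x_y = (m - x_x * p_x) / p_y``; the extremes ``(m/p_x, 0)`` and
    ``(0, m/p_y)`` are always included.
    """
    if m <= 0:
        raise ValueError(f"budget must be positive, got {m}")
    fractions = np.linspace(0.0, 1.0, N_OPTIONS)
    x_intercept = m / prices.x
    bundles = []
    for f in fractions:
        x = f * x_intercept
        y = (m - x * prices.x) / prices.y
        # guard against -1e-17 style float dust at the extremes
        bundles.append(Bundle(x=max(x, 0.0), y=max(y, 0.0)))
    return bundles


def bundle_to_orientation(
    b: Bundle, exemplar_deg: float, axis: str = "x", side: int = 1
) -> float:
    """Map a bundle's token amount on one axis to a cube orientation.

    The option orientation is ``exemplar +/- (30 - 0.3 * tokens)`` degrees,
    wrapped to [0, 360).  ``side`` (+1 or -1) selects on which side of the
    exemplar the offset is applied; consistency scoring is side-invariant.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if side not in (1, -1):
        raise ValueError(f"side must be +1 or -1, got {side}")
    tokens = b.x if axis == "x" else b.y
    if tokens > BUDGET + 1e-9:
        raise ValueError(
            f"token amount {tokens} exceeds {BUDGET}; cannot rotate past a match"
        )
    offset = MAX_OFFSET_DEG - DEG_PER_TOKEN * tokens
    return float((exemplar_deg + side * offset) % 360.0)


def generate_block(
    rng: np.random.Generator,
    participant_id: int,
    t: float,
    n_trials: int = N_TRIALS_PER_BLOCK,
    block_role: str = "block",
    integer_prices: bool = False,
) -> Block:
    """Generate a block of trials with fresh prices and exemplar orientations.

    ``choice_index`` is left at 0 (unset) for a chooser model to fill.
    """
    if not 0.0 <= t <= RI_MAX_S:
        raise ValueError(f"retention interval must lie in [0, {RI_MAX_S}] s, got {t}")
    trials = []
    for i in range(n_trials):
        prices = draw_prices(rng, integer=integer_prices)
        ex_x = float(rng.choice(EXEMPLAR_ORIENTATIONS))
        ex_y = float(rng.choice(EXEMPLAR_ORIENTATIONS))
        trials.append(
            ChoiceTrial(
                trial_id=i + 1,
                prices=prices,
                budget=BUDGET,
                exemplar_x=ex_x,
                exemplar_y=ex_y,
                options=make_choice_set(prices, BUDGET),
            )
        )
    return Block(
        participant_id=participant_id,
        block_role=block_role,
        retention_interval=float(t),
        trials=trials,
    )


def generate_session(
    rng: np.random.Generator,
    participant_id: int,
    n_trials: int = N_TRIALS_PER_BLOCK,
    integer_prices: bool = False,
) -> tuple[Block, Block]:
    """Two consecutive blocks, each with an independent RI ~ Uniform(0, 30) s."""
    blocks = []
    for role in ("block1", "block2"):
        t = float(rng.uniform(0.0, RI_MAX_S))
        blocks.append(
            generate_block(
                rng,
                participant_id,
                t,
                n_trials=n_trials,
                block_role=role,
                integer_prices=integer_prices,
            )
        )
    return blocks[0], blocks[1]
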