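"""Synthetic participants and datasets for every stage of the pipeline.

Three generators emulate the study design without any external data:

* **choosers** acting on generated choice sets — uniform random choosers
  (the task-sensitivity benchmark) and utility maximizers with optional
  logit (Gumbel) noise (test harness for the consistency indices);
* **forgetting-curve CCEI datasets** — (retention interval, CCEI) pairs
  drawn from the exponential model with truncated-normal noise;
* **reconstruction-task trials** — orientation reports with a point mass of
  perfect responses (about 42% at the 5 s presentation-time setting) and a
  positively skewed error magnitude that grows with the retention interval
  and shrinks with presentation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import core_task
from .core_task import Block
from .memory_models import CceiDataset, mu_exponential
from .reconstruction import ReconstructionTrial

__all__ = [
    "ChooserSpec",
    "ReconGenSpec",
    "DEFAULT_SEED",
    "simulate_random_participants",
    "simulate_chooser_block",
    "simulate_ccei_dataset",
    "simulate_reconstruction",
]

#: Default seed used by shipped configs; every CLI accepts --seed.
DEFAULT_SEED = 20210308

_RECON_RI_GRID = (1.0, 5.0, 10.0, 30.0)
_RECON_PT_GRID = (1.0, 5.0, 10.0, 30.0)


@dataclass(frozen=True)
class ChooserSpec:
    """How a simulated participant picks among the five options.

    kinds:
        ``random``          uniform over the options (w, noise_sd ignored);
        ``linear-utility``  argmax of ``w * x + (1 - w) * y``;
        ``noisy-utility``   linear utility plus Gumbel noise scaled by
                            ``noise_sd`` (logit choice; noise_sd = 0 reduces
                            to the deterministic maximizer);
        ``ces-utility``     argmax of a CES aggregator
                            ``(w * x^rho + (1 - w) * y^rho)^(1/rho)`` —
                            a curved monotone test utility.
    """

    kind: str = "random"
    w: float = 0.5
    noise_sd: float = 0.0
    rho: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("random", "linear-utility", "noisy-utility", "ces-utility"):
            raise ValueError(f"unknown chooser kind {self.kind!r}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _fill_choices(block: Block, spec: ChooserSpec, rng: np.random.Generator) -> None:
    for trial in block.trials:
        if spec.kind == "random":
            trial.choice_index = int(rng.integers(1, core_task.N_OPTIONS + 1))
            continue
        x = np.array([opt.x for opt in trial.options])
        y = np.array([opt.y for opt in trial.options])
        if spec.kind == "ces-utility":
            util = (spec.w * x**spec.rho + (1 - spec.w) * y**spec.rho) ** (1 / spec.rho)
        else:
            util = spec.w * x + (1 - spec.w) * y
        if spec.kind == "noisy-utility" and spec.noise_sd > 0:
            util = util + spec.noise_sd * rng.gumbel(size=util.size)
        # ties broken toward the lowest option index
        trial.choice_index = int(np.argmax(util)) + 1


def simulate_chooser_block(
    rng: np.random.Generator,
    spec: ChooserSpec,
    t: float,
    participant_id: int = 0,
    n_trials: int = core_task.N_TRIALS_PER_BLOCK,
    block_role: str = "block",
    integer_prices: bool = False,
) -> Block:
    """Generate a fresh block and let the specified chooser fill choice_index."""
    block = core_task.generate_block(
        rng, participant_id, t, n_trials=n_trials, block_role=block_role,
        integer_prices=integer_prices,
    )
    _fill_choices(block, spec, rng)
    return block


def simulate_random_participants(
    rng: np.random.Generator,
    n: int = 1000,
    n_trials: int = core_task.N_TRIALS_PER_BLOCK,
    integer_prices: bool = False,
) -> list[Block]:
    """Virtual participants making uniform random choices (one block each).

    This is the task-sensitivity benchmark: with the study's choice-set
    construction, random behaviour should almost always violate GARP.
    """
    spec = ChooserSpec(kind="random")
    return [
        simulate_chooser_block(
            rng, spec, t=float(rng.uniform(0.0, core_task.RI_MAX_S)),
            participant_id=pid, n_trials=n_trials, integer_prices=integer_prices,
        )
        for pid in range(1, n + 1)
    ]


def simulate_ccei_dataset(
    rng: np.random.Generator,
    a: float = 0.4,
    b: float = 0.9,
    alpha: float = 0.3,
    sigma: float = 0.1,
    n: int = 300,
) -> CceiDataset:
    """(t, CCEI) pairs from the exponential forgetting model.

    ``t ~ Uniform(0, 30)`` and ``CCEI ~ Normal(mu_t, sigma)`` truncated to
    [0, 1] with ``mu_t = a + (1 - a) * b * exp(-alpha * t)``.  The defaults
    are the demonstration parameters of the study design.
    """
    for name, v in (("a", a), ("b", b), ("alpha", alpha), ("sigma", sigma)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if sigma == 0:
        raise ValueError("sigma must be positive")
    t = rng.uniform(0.0, 30.0, size=n)
    mu = mu_exponential(t, a, b, alpha)
    lo, hi = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    ccei = stats.truncnorm.rvs(lo, hi, loc=mu, scale=sigma, random_state=rng)
    return CceiDataset(t=t, ccei=np.clip(ccei, 0.0, 1.0))


@dataclass(frozen=True)
class ReconGenSpec:
    """Calibration of the reconstruction-response generator.

    Responses are a two-component mixture: with probability
    ``p_perfect(t, pt)`` the exemplar orientation is reproduced exactly
    (the observed point mass of perfect reports); otherwise a half-normal
    error magnitude with scale ``error_scale(t, pt)`` degrees and a random
    sign is added and wrapped to [0, 360).  ``p_perfect`` falls with the
    retention interval ``t`` and rises with presentation time ``pt``; the
    error scale does the opposite.  The defaults put the mean perfect-report
    rate at the 5 s presentation-time setting (averaged over the RI grid
    1/5/10/30 s) at 42%.
    """

    perfect_base: float = 0.42
    perfect_pt_slope: float = 0.015  # per second of presentation time
    perfect_ri_slope: float = 0.010  # per second of retention interval
    scale_base: float = 5.0  # degrees
    scale_ri_slope: float = 1.2  # degrees per second of retention
    scale_pt_exponent: float = 0.3

    def p_perfect(self, t: float, pt: float) -> float:
        grid_mean_ri = float(np.mean(_RECON_RI_GRID))
        p = (
            self.perfect_base
            + self.perfect_pt_slope * (pt - 5.0)
            - self.perfect_ri_slope * (t - grid_mean_ri)
        )
        return float(np.clip(p, 0.0, 1.0))

    def error_scale(self, t: float, pt: float) -> float:
        return float(
            (self.scale_base + self.scale_ri_slope * t) * (5.0 / pt) ** self.scale_pt_exponent
        )


def simulate_reconstruction(
    rng: np.random.Generator,
    spec: ReconGenSpec | None = None,
    n_per_cell: int = 10,
    ris: tuple[float, ...] = _RECON_RI_GRID,
    pts: tuple[float, ...] = _RECON_PT_GRID,
    participant_id: int = 1,
) -> list[ReconstructionTrial]:
    """Reconstruction trials for every (presentation time, RI) factorial cell."""
    spec = spec or ReconGenSpec()
    trials = []
    for pt in pts:
        for ri in ris:
            for _ in range(n_per_cell):
                axis = "x" if rng.random() < 0.5 else "y"
                exemplar = float(rng.choice(core_task.EXEMPLAR_ORIENTATIONS))
                if rng.random() < spec.p_perfect(ri, pt):
                    response = exemplar
                else:
                    magnitude = abs(rng.normal(0.0, spec.error_scale(ri, pt)))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    response = (exemplar + sign * magnitude) % 360.0
                trials.append(
                    ReconstructionTrial(
                        participant_id=participant_id,
                        presentation_time=float(pt),
                        retention_interval=float(ri),
                        axis=axis,
                        exemplar_deg=exemplar,
                        response_deg=float(response),
                    )
                )
    return trials
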