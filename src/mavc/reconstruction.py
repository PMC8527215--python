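"""Reconstruction-task scoring: manipulation check and difficulty bootstrap.

The manipulation check asks whether longer retention intervals degrade the
memory representation of the exemplar, operationalized as the absolute
circular error between the exemplar orientation and the reconstructed one.
The task-difficulty analysis compares that error — an upper bound on how
finely participants can discriminate orientations — with the orientation
increment separating adjacent options in the choice task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_task import ChoiceTrial, DEG_PER_TOKEN

__all__ = [
    "ReconstructionTrial",
    "BootstrapResult",
    "circular_error",
    "paper_literal_error",
    "manipulation_summary",
    "increment_step",
    "bootstrap_difficulty",
]


@dataclass(frozen=True)
class ReconstructionTrial:
    """One exemplar/response orientation pair from the reconstruction task."""

    participant_id: int | str
    presentation_time: float
    retention_interval: float
    axis: str
    exemplar_deg: float
    response_deg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "exemplar_deg", float(self.exemplar_deg) % 360.0)
        object.__setattr__(self, "response_deg", float(self.response_deg) % 360.0)


@dataclass(frozen=True)
class BootstrapResult:
    mean_diff: float
    ci95: tuple[float, float]
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= hi:
            raise ValueError(f"CI endpoints out of order: {self.ci95}")


def circular_error(a_deg, b_deg):
    """Absolute circular distance between two orientations, in [0, 180].

    0 and 360 degrees are equivalent, so the error between 90 and 360
    degrees is 90 (not 270).  Accepts scalars or arrays.
    """
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if out.ndim == 0 else out


def paper_literal_error(a_deg, b_deg):
    """Audit variant: ``||a - b| - 180|``.

    This printed formula returns 180 for identical orientations and only
    matches the circular distance when the raw difference exceeds 180; it is
    kept solely so the discrepancy can be inspected.  Use
    :func:`circular_error` for analysis.
    """
    out = np.abs(np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) - 180.0)
    return float(out) if out.ndim == 0 else out


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    from .io import recon_to_frame

    return recon_to_frame(trials)


def manipulation_summary(
    trials, by: tuple[str, ...] = ("retention_interval_s",)
) -> pd.DataFrame:
    """Mean, SEM and n of the absolute circular error per design cell.

    ``by`` may also include ``"presentation_time_s"`` for the two-factor
    table.  Single-trial cells get a NaN SEM and ``sem_defined=False``.  The
    returned frame carries a boolean attr ``monotone_in_ri``: whether cell
    means increase monotonically across the retention-interval levels
    (averaged over any other factors).
    """
    df = _as_frame(trials).copy()
    if df.empty:
        raise ValueError("no reconstruction trials supplied")
    df["abs_error"] = circular_error(df["exemplar_deg"], df["response_deg"])
    grouped = df.groupby(list(by))["abs_error"]
    out = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    out["sem_defined"] = out["n"] > 1
    ri_means = df.groupby("retention_interval_s")["abs_error"].mean().sort_index()
    out.attrs["monotone_in_ri"] = bool(np.all(np.diff(ri_means.values) > 0))
    return out


def increment_step(trial: ChoiceTrial, axis: str) -> float:
    """Orientation increment (degrees) between adjacent options on one axis.

    Options sit at quarter-steps of the axis intercept ``m / p_axis``, and a
    token is worth 0.3 degrees, so the step is ``0.3 * (m / p_axis) / 4``.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    price = trial.prices.x if axis == "x" else trial.prices.y
    return DEG_PER_TOKEN * (trial.budget / price) / 4.0


def bootstrap_difficulty(
    errors, increments, n_boot: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """Percentile bootstrap of mean(reconstruction error) - mean(increment).

    The two samples are resampled independently with replacement.  A
    positive difference with a CI excluding zero indicates that the choice
    options are spaced more finely than participants can discriminate.
    """
    errors = np.asarray(errors, dtype=float)
    increments = np.asarray(increments, dtype=float)
    if errors.size == 0 or increments.size == 0:
        raise ValueError("errors and increments must both be non-empty")
    rng = np.random.default_rng(seed)
    boot = (
        errors[rng.integers(0, errors.size, size=(n_boot, errors.size))].mean(axis=1)
        - increments[
            rng.integers(0, increments.size, size=(n_boot, increments.size))
        ].mean(axis=1)
    )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return BootstrapResult(
        mean_diff=float(errors.mean() - increments.mean()),
        ci95=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
    )
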