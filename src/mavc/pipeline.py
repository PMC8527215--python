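"""End-to-end orchestration: sensitivity study, train/test split, full analysis.

The full analysis mirrors the study's preregistered plan: score every block
with the consistency indices, split each participant's two blocks into a
training and a held-out test set, test the directional hypothesis (H1,
Kendall's-tau Bayes factor), and — only when H1 finds strong support — run
the forgetting-model comparison (H2) and its replication Bayes factor (H3).
Bayes factors are mapped to verdicts with the conventional thresholds:
BF >= 10 strong support, BF <= 0.1 strong support against, otherwise
inconclusive.  Quality controls (floor-effect comparison against random
choosers, test-retest reliability, manipulation check, difficulty
bootstrap) run unconditionally.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import association, io, memory_models, reconstruction, revealed_preference
from . import synthetic_data
from .core_task import Block
from .memory_models import CceiDataset, McmcConfig
from .revealed_preference import ObservationSet

__all__ = [
    "RunConfig",
    "SensitivitySummary",
    "bf_verdict",
    "run_sensitivity",
    "split_train_test",
    "run_full_analysis",
    "validate_report",
]

logger = logging.getLogger("mavc")

BF_STRONG_SUPPORT = 10.0
BF_STRONG_AGAINST = 0.1

CONSISTENCY_INDEX_NAMES = ("ccei", "hmi_fraction", "mpi", "mci")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    seed: int = synthetic_data.DEFAULT_SEED
    n_participants: int = 1000
    n_trials: int = 20
    ccei_variant: str = "varian"  # or "paper-literal"
    integer_prices: bool = False
    mpi_cycle_len: int = 3
    n_boot: int = 10_000
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = McmcConfig(**d["mcmc"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SensitivitySummary:
    """Aggregate outcome of the random-chooser sensitivity simulation."""

    pct_any_violation: float
    median_ccei: float
    pct_ccei_below_090: float
    pct_ccei_below_080: float
    median_inconsistent_choices: float
    pct_ccei_equal_1: float
    n_participants: int
    n_trials: int

    def to_dict(self) -> dict:
        return asdict(self)


def bf_verdict(bf: float) -> str:
    """Map a Bayes factor to the preregistered interpretation label."""
    if bf >= BF_STRONG_SUPPORT:
        return "strong support"
    if bf <= BF_STRONG_AGAINST:
        return "strong support against"
    return "inconclusive"


def _log_stage(stage: str, t0: float, **info) -> None:
    elapsed = time.perf_counter() - t0
    details = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", stage, elapsed, details)


def run_sensitivity(
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SensitivitySummary, pd.DataFrame]:
    """Simulate uniform-random choosers and summarize task sensitivity.

    Returns the aggregate summary plus the per-participant frame
    (participant_id, retention_interval_s, ccei, n_violating_pairs,
    n_inconsistent_choices).
    """
    cfg = config or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t0 = time.perf_counter()
    blocks = synthetic_data.simulate_random_participants(
        rng, n=cfg.n_participants, n_trials=cfg.n_trials,
        integer_prices=cfg.integer_prices,
    )
    rows = []
    for block in blocks:
        obs = ObservationSet.from_block(block)
        viols = revealed_preference.garp_violations(obs, 1.0, variant=cfg.ccei_variant)
        rows.append(
            {
                "participant_id": block.participant_id,
                "retention_interval_s": block.retention_interval,
                "ccei": revealed_preference.ccei(obs, variant=cfg.ccei_variant),
                "n_violating_pairs": len(viols),
                "n_inconsistent_choices": len({k for pair in viols for k in pair}),
            }
        )
    per_participant = pd.DataFrame(rows)
    ccei = per_participant["ccei"].to_numpy()
    summary = SensitivitySummary(
        pct_any_violation=100.0 * float((per_participant["n_violating_pairs"] > 0).mean()),
        median_ccei=float(np.median(ccei)),
        pct_ccei_below_090=100.0 * float((ccei < 0.90).mean()),
        pct_ccei_below_080=100.0 * float((ccei < 0.80).mean()),
        median_inconsistent_choices=float(
            per_participant["n_inconsistent_choices"].median()
        ),
        pct_ccei_equal_1=100.0 * float((ccei >= 1.0 - 1e-9).mean()),
        n_participants=cfg.n_participants,
        n_trials=cfg.n_trials,
    )
    _log_stage("sensitivity", t0, n=cfg.n_participants)
    return summary, per_participant


def split_train_test(
    blocks: list[Block], rng: np.random.Generator
) -> tuple[list[Block], list[Block]]:
    """Per participant, assign one block to train and the other to test.

    The assignment is a fair coin per participant.  Participants without
    exactly two blocks are excluded with a warning.  Block roles are
    relabelled "train"/"test" in the returned lists.
    """
    by_pid: dict = {}
    for b in blocks:
        by_pid.setdefault(b.participant_id, []).append(b)
    train, test = [], []
    for pid in sorted(by_pid, key=str):
        group = by_pid[pid]
        if len(group) != 2:
            warnings.warn(
                f"participant {pid!r} has {len(group)} block(s); excluded from split",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        first_is_train = rng.random() < 0.5
        tr, te = (group[0], group[1]) if first_is_train else (group[1], group[0])
        tr = replace_role(tr, "train")
        te = replace_role(te, "test")
        train.append(tr)
        test.append(te)
    return train, test


def replace_role(block: Block, role: str) -> Block:
    return Block(
        participant_id=block.participant_id,
        block_role=role,
        retention_interval=block.retention_interval,
        trials=block.trials,
    )


def score_blocks(
    blocks: list[Block], config: RunConfig, full_indices: bool = True
) -> pd.DataFrame:
    """Consistency indices per block as a tidy frame."""
    rows = []
    for block in blocks:
        if full_indices:
            rep = revealed_preference.consistency_report(
                block, variant=config.ccei_variant, mpi_cycle_len=config.mpi_cycle_len
            )
            rows.append(
                {
                    "participant_id": block.participant_id,
                    "block_role": block.block_role,
                    "retention_interval_s": block.retention_interval,
                    **asdict(rep),
                }
            )
        else:
            obs = ObservationSet.from_block(block)
            rows.append(
                {
                    "participant_id": block.participant_id,
                    "block_role": block.block_role,
                    "retention_interval_s": block.retention_interval,
                    "ccei": revealed_preference.ccei(obs, variant=config.ccei_variant),
                }
            )
    return pd.DataFrame(rows)


def _ccei_dataset(frame: pd.DataFrame) -> CceiDataset:
    return CceiDataset(
        t=frame["retention_interval_s"].to_numpy(dtype=float),
        ccei=frame["ccei"].to_numpy(dtype=float),
    )


def _input_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).values.tobytes()
    ).hexdigest()[:16]


def run_full_analysis(
    trials: pd.DataFrame | str,
    recon: pd.DataFrame | str,
    config: RunConfig | None = None,
    full_indices: bool = True,
) -> dict:
    """Run the complete preregistered analysis plan on a trials/recon dataset.

    Returns the report as a JSON-serializable dict (see
    ``report_schema.json``).  H2/H3 execute only when the H1 verdict is
    "strong support"; quality controls always run.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    t0 = time.perf_counter()

    trials_df = pd.read_csv(trials) if isinstance(trials, str) else trials
    recon_df = pd.read_csv(recon) if isinstance(recon, str) else recon
    blocks = io.frame_to_blocks(trials_df)
    _log_stage("load", t0, trials_hash=_input_hash(trials_df), n_blocks=len(blocks))

    train_blocks, test_blocks = split_train_test(blocks, rng)
    train_scores = score_blocks(train_blocks, cfg, full_indices=full_indices)
    test_scores = score_blocks(test_blocks, cfg, full_indices=full_indices)
    _log_stage("score", t0, n_train=len(train_scores), n_test=len(test_scores))

    # H1: one-sided Kendall's tau Bayes factor on the training set
    h1_bf = association.bf_kendall_onesided(
        train_scores["retention_interval_s"], train_scores["ccei"],
        alternative="negative",
    )
    h1_verdict = bf_verdict(h1_bf.bf10)
    report: dict = {
        "config": cfg.to_dict(),
        "n_participants": len(train_blocks),
        "h1": {
            "tau": h1_bf.diagnostics["tau"],
            "bf10": h1_bf.bf10,
            "verdict": h1_verdict,
        },
        "h2": None,
        "h3": None,
    }

    # H2/H3 are conditional on strong support for H1 (preregistered gate)
    if h1_verdict == "strong support":
        train_data = _ccei_dataset(train_scores)
        test_data = _ccei_dataset(test_scores)
        seed_h2 = int(rng.integers(2**31 - 1))
        seed_all = int(rng.integers(2**31 - 1))
        bf_train = memory_models.bf_product_space(train_data, cfg.mcmc, seed=seed_h2)
        bf_combined = memory_models.bf_product_space(
            train_data.concat(test_data), cfg.mcmc, seed=seed_all
        )
        bf_rep = memory_models.replication_bf(bf_combined.bf10, bf_train.bf10)
        report["h2"] = {
            "bf10": bf_train.bf10,
            "mc_error": bf_train.mc_error,
            "verdict": bf_verdict(bf_train.bf10),
        }
        report["h3"] = {
            "bf10_combined": bf_combined.bf10,
            "replication_bf": bf_rep,
            "verdict": bf_verdict(bf_rep),
        }
        _log_stage("h2_h3", t0, bf_train=bf_train.bf10, bf_rep=bf_rep)

    # Quality control 1: CCEI vs equal-sized random-chooser sample (rank-sum)
    n = len(train_scores)
    random_blocks = synthetic_data.simulate_random_participants(
        rng, n=n, n_trials=cfg.n_trials, integer_prices=cfg.integer_prices
    )
    random_ccei = [
        revealed_preference.ccei(
            ObservationSet.from_block(b), variant=cfg.ccei_variant
        )
        for b in random_blocks
    ]
    if train_scores["ccei"].nunique() > 1 or len(set(random_ccei)) > 1:
        mwu = stats.mannwhitneyu(
            train_scores["ccei"], random_ccei, alternative="greater"
        )
        floor = {
            "statistic": float(mwu.statistic),
            "p_value": float(mwu.pvalue),
            "non_discernable_from_random": bool(mwu.pvalue >= 0.05),
        }
    else:  # degenerate: all values tied
        floor = {"statistic": float("nan"), "p_value": 1.0, "non_discernable_from_random": True}

    # Quality control 2: test-retest reliability of each index
    reliability = {}
    index_names = CONSISTENCY_INDEX_NAMES if full_indices else ("ccei",)
    for name in index_names:
        try:
            reliability[name] = association.test_retest(train_scores, test_scores, name)
        except ValueError as err:
            reliability[name] = None
            logger.warning("test-retest for %s skipped: %s", name, err)

    # Quality control 3: manipulation check on the reconstruction task
    recon_summary = reconstruction.manipulation_summary(recon_df)
    manip = {
        "per_ri": recon_summary.drop(columns="sem_defined").to_dict(orient="records"),
        "monotone_in_ri": bool(recon_summary.attrs["monotone_in_ri"]),
    }

    # Quality control 4: task-difficulty bootstrap (errors vs increment steps)
    errors = reconstruction.circular_error(
        recon_df["exemplar_deg"], recon_df["response_deg"]
    )
    increments = []
    for block in blocks:
        for trial in block.trials:
            increments.append(reconstruction.increment_step(trial, "x"))
            increments.append(reconstruction.increment_step(trial, "y"))
    boot = reconstruction.bootstrap_difficulty(
        errors, increments, n_boot=cfg.n_boot, seed=int(rng.integers(2**31 - 1))
    )

    report["quality_controls"] = {
        "floor_effect": floor,
        "test_retest": reliability,
        "manipulation_check": manip,
        "difficulty_bootstrap": {
            "mean_diff_deg": boot.mean_diff,
            "ci95": list(boot.ci95),
            "n_boot": boot.n_boot,
        },
    }
    _log_stage("quality_controls", t0)
    validate_report(report)
    return report


def _load_schema() -> dict:
    with resources.files("mavc").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def _check_node(obj, schema, path: str, errors: list[str]) -> None:
    kind = schema.get("type")
    nullable = schema.get("nullable", False)
    if obj is None:
        if not nullable:
            errors.append(f"{path}: unexpected null")
        return
    if kind == "object":
        if not isinstance(obj, dict):
            errors.append(f"{path}: expected object, got {type(obj).__name__}")
            return
        for key, sub in schema.get("properties", {}).items():
            if key not in obj:
                errors.append(f"{path}.{key}: missing")
            else:
                _check_node(obj[key], sub, f"{path}.{key}", errors)
    elif kind == "number":
        if not isinstance(obj, (int, float)) or isinstance(obj, bool):
            errors.append(f"{path}: expected number, got {type(obj).__name__}")
    elif kind == "string":
        if not isinstance(obj, str):
            errors.append(f"{path}: expected string, got {type(obj).__name__}")
    elif kind == "boolean":
        if not isinstance(obj, bool):
            errors.append(f"{path}: expected boolean, got {type(obj).__name__}")
    elif kind == "array":
        if not isinstance(obj, list):
            errors.append(f"{path}: expected array, got {type(obj).__name__}")
    # "any" or unknown kinds are accepted


def validate_report(report: dict) -> None:
    """Validate a report dict against the shipped schema; raise on mismatch."""
    errors: list[str] = []
    _check_node(report, _load_schema(), "report", errors)
    if errors:
        raise ValueError("report schema violations:\n" + "\n".join(errors))
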