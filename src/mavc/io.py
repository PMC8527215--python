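"""CSV schemas and (de)serialization for trials, reconstruction and CCEI data.

Long-format trials CSV, one row per trial::

    participant_id, block_role, retention_interval_s, trial_id,
    price_x, price_y, budget, exemplar_x_deg, exemplar_y_deg,
    opt1_x..opt5_x, opt1_y..opt5_y, choice_index

Reconstruction CSV, one row per reconstruction trial::

    participant_id, presentation_time_s, retention_interval_s, axis,
    exemplar_deg, response_deg

CCEI CSV (input to the forgetting-model comparison)::

    participant_id, retention_interval_s, ccei
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_task import Block, Bundle, ChoiceTrial, Prices

# %.15g keeps >= 12 significant digits and round-trips cleanly for this data
FLOAT_FMT = "%.15g"

TRIAL_COLUMNS = (
    ["participant_id", "block_role", "retention_interval_s", "trial_id"]
    + ["price_x", "price_y", "budget", "exemplar_x_deg", "exemplar_y_deg"]
    + [f"opt{k}_x" for k in range(1, 6)]
    + [f"opt{k}_y" for k in range(1, 6)]
    + ["choice_index"]
)

RECON_COLUMNS = [
    "participant_id",
    "presentation_time_s",
    "retention_interval_s",
    "axis",
    "exemplar_deg",
    "response_deg",
]

CCEI_COLUMNS = ["participant_id", "retention_interval_s", "ccei"]


def blocks_to_frame(blocks: list[Block]) -> pd.DataFrame:
    rows = []
    for block in blocks:
        for trial in block.trials:
            row = {
                "participant_id": block.participant_id,
                "block_role": block.block_role,
                "retention_interval_s": block.retention_interval,
                "trial_id": trial.trial_id,
                "price_x": trial.prices.x,
                "price_y": trial.prices.y,
                "budget": trial.budget,
                "exemplar_x_deg": trial.exemplar_x,
                "exemplar_y_deg": trial.exemplar_y,
                "choice_index": trial.choice_index,
            }
            for k, opt in enumerate(trial.options, start=1):
                row[f"opt{k}_x"] = opt.x
                row[f"opt{k}_y"] = opt.y
            rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_blocks(df: pd.DataFrame) -> list[Block]:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials frame is missing columns: {sorted(missing)}")
    blocks = []
    for (pid, role), group in df.groupby(["participant_id", "block_role"], sort=False):
        ris = group["retention_interval_s"].unique()
        if len(ris) != 1:
            raise ValueError(
                f"block ({pid}, {role}) mixes retention intervals {ris.tolist()}"
            )
        trials = []
        for _, row in group.iterrows():
            options = [
                Bundle(x=float(row[f"opt{k}_x"]), y=float(row[f"opt{k}_y"]))
                for k in range(1, 6)
            ]
            trials.append(
                ChoiceTrial(
                    trial_id=int(row["trial_id"]),
                    prices=Prices(x=float(row["price_x"]), y=float(row["price_y"])),
                    budget=float(row["budget"]),
                    exemplar_x=float(row["exemplar_x_deg"]),
                    exemplar_y=float(row["exemplar_y_deg"]),
                    options=options,
                    choice_index=int(row["choice_index"]),
                )
            )
        blocks.append(
            Block(
                participant_id=pid,
                block_role=str(role),
                retention_interval=float(ris[0]),
                trials=trials,
            )
        )
    return blocks


def write_trials_csv(blocks: list[Block], path) -> None:
    blocks_to_frame(blocks).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trials_csv(path) -> list[Block]:
    return frame_to_blocks(pd.read_csv(path))


def recon_to_frame(trials) -> pd.DataFrame:
    rows = [
        {
            "participant_id": tr.participant_id,
            "presentation_time_s": tr.presentation_time,
            "retention_interval_s": tr.retention_interval,
            "axis": tr.axis,
            "exemplar_deg": tr.exemplar_deg,
            "response_deg": tr.response_deg,
        }
        for tr in trials
    ]
    return pd.DataFrame(rows, columns=RECON_COLUMNS)


def frame_to_recon(df: pd.DataFrame):
    from .reconstruction import ReconstructionTrial

    missing = set(RECON_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reconstruction frame is missing columns: {sorted(missing)}")
    return [
        ReconstructionTrial(
            participant_id=row.participant_id,
            presentation_time=float(row.presentation_time_s),
            retention_interval=float(row.retention_interval_s),
            axis=str(row.axis),
            exemplar_deg=float(row.exemplar_deg),
            response_deg=float(row.response_deg),
        )
        for row in df.itertuples(index=False)
    ]


def write_recon_csv(trials, path) -> None:
    recon_to_frame(trials).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_recon_csv(path):
    return frame_to_recon(pd.read_csv(path))


def ccei_to_frame(dataset, participant_ids=None) -> pd.DataFrame:
    n = len(dataset.t)
    pids = np.arange(1, n + 1) if participant_ids is None else participant_ids
    return pd.DataFrame(
        {
            "participant_id": pids,
            "retention_interval_s": dataset.t,
            "ccei": dataset.ccei,
        },
        columns=CCEI_COLUMNS,
    )


def frame_to_ccei(df: pd.DataFrame):
    from .memory_models import CceiDataset

    missing = set(CCEI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ccei frame is missing columns: {sorted(missing)}")
    return CceiDataset(
        t=df["retention_interval_s"].to_numpy(dtype=float),
        ccei=df["ccei"].to_numpy(dtype=float),
    )


def write_ccei_csv(dataset, path, participant_ids=None) -> None:
    ccei_to_frame(dataset, participant_ids).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_ccei_csv(path):
    return frame_to_ccei(pd.read_csv(path))
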