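"""Table readers/writers and configuration files.

All tables are comma-delimited UTF-8 with a fixed header row.  CDR
stages are serialized as the decimal strings {0, 0.5, 1, 1.5, 2, 2.5,
3} so that repeated round trips cannot drift.  Validation errors name
the offending file row (1-based, counting the header as row 1).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from recalldcb.model import PositionEffects, RecallSequence
from recalldcb._sampler import MCMCConfig
from recalldcb.synth import CohortConfig

__all__ = [
    "RECALL_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "read_recall_table",
    "write_recall_table",
    "to_sequences",
    "read_participant_table",
    "write_participant_table",
    "read_prior_spec",
    "write_prior_spec",
    "read_position_effects",
    "write_position_effects",
    "PipelineConfig",
]

RECALL_COLUMNS = (
    "participant_id", "word_id", "list_id", "pos1", "pos2", "pos3",
    "recall_ifr1", "recall_ifr2", "recall_ifr3", "recall_dfr",
)
PARTICIPANT_COLUMNS = (
    "participant_id", "age", "sex", "education", "phs", "cdr_baseline", "cdr_36m",
)
_RECALL_FIELDS = ("recall_ifr1", "recall_ifr2", "recall_ifr3", "recall_dfr")
_POS_FIELDS = ("pos1", "pos2", "pos3")
_CDR_STAGES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


def _file_row(df_index: int) -> int:
    return int(df_index) + 2  # +1 for the header, +1 for 1-based rows


def read_recall_table(path: str | os.PathLike, list_length: int = 10) -> pd.DataFrame:
    """Read and validate an item-level recall table.

    Raises ``ValueError`` with row-addressed messages for missing
    columns, out-of-range recall indicators or positions, and duplicate
    (participant, word) cells.  An empty-but-headered file yields an
    empty frame.
    """
    df = pd.read_csv(path)
    missing = set(RECALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(RECALL_COLUMNS)]
    if len(df) == 0:
        return df
    for col in _RECALL_FIELDS:
        bad = df.index[~df[col].isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"{path}: {col} must be 0/1; first offending row "
                f"{_file_row(bad[0])} (value {df.loc[bad[0], col]!r})"
            )
    for col in _POS_FIELDS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[
            values.isna() | (values < 1) | (values > list_length)
            | (values != values.round())
        ]
        if len(bad):
            raise ValueError(
                f"{path}: {col} must be an integer in 1..{list_length}; first "
                f"offending row {_file_row(bad[0])} (value {df.loc[bad[0], col]!r})"
            )
    dup = df.duplicated(subset=["participant_id", "word_id"], keep=False)
    if dup.any():
        rows = [str(_file_row(i)) for i in df.index[dup][:5]]
        raise ValueError(
            f"{path}: duplicate (participant_id, word_id) cells at rows "
            f"{', '.join(rows)}"
        )
    for col in _RECALL_FIELDS + _POS_FIELDS:
        df[col] = df[col].astype(int)
    return df


def write_recall_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df = df[list(RECALL_COLUMNS)]
    df.to_csv(path, index=False)


def to_sequences(recall_df: pd.DataFrame, list_length: int | None = None) -> dict:
    """Group an item-level table into RecallSequence lists by participant.

    When ``list_length`` is None it is inferred from the largest
    presentation position in the table (presentations are permutations
    of the full list, so the maximum position equals the list length).
    """
    if list_length is None:
        if len(recall_df) == 0:
            list_length = 10
        else:
            list_length = int(recall_df[list(_POS_FIELDS)].to_numpy().max())
    out: dict = {}
    for row in recall_df.itertuples(index=False):
        seq = RecallSequence(
            word_id=str(row.word_id),
            list_id=str(row.list_id),
            positions=(row.pos1, row.pos2, row.pos3),
            recalls=(row.recall_ifr1, row.recall_ifr2, row.recall_ifr3,
                     row.recall_dfr),
            list_length=list_length,
        )
        out.setdefault(str(row.participant_id), []).append(seq)
    return out


def _format_cdr(value: float) -> str:
    value = float(value)
    if value not in _CDR_STAGES:
        raise ValueError(f"CDR stage must be one of {_CDR_STAGES}, got {value!r}")
    return f"{value:g}"


def read_participant_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "age", "sex", "education", "phs"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("cdr_baseline", "cdr_36m"):
        if col in df.columns and len(df):
            df[col] = df[col].astype(float)
            bad = df.index[~df[col].isin(_CDR_STAGES)]
            if len(bad):
                raise ValueError(
                    f"{path}: {col} must be a CDR stage {_CDR_STAGES}; first "
                    f"offending row {_file_row(bad[0])}"
                )
    return df


def write_participant_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df = df.copy()
    for col in ("cdr_baseline", "cdr_36m"):
        if col in df.columns:
            df[col] = df[col].map(_format_cdr)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Priors, position effects and pipeline configuration
# ---------------------------------------------------------------------------

def write_prior_spec(spec, path: str | os.PathLike) -> None:
    payload = {
        group: {name: [float(a), float(b)] for name, (a, b) in entry.items()}
        for group, entry in spec.groups.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_prior_spec(path: str | os.PathLike):
    from recalldcb.inference import PriorSpec

    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    groups = {
        group: {name: (float(ab[0]), float(ab[1])) for name, ab in entry.items()}
        for group, entry in payload.items()
    }
    return PriorSpec(groups)


def write_position_effects(effects: PositionEffects, path: str | os.PathLike) -> None:
    payload = [
        {"list_id": lid, "position": int(pos), "offset": float(off)}
        for (lid, pos), off in sorted(effects.offsets.items())
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_position_effects(path: str | os.PathLike) -> PositionEffects:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or []
    return PositionEffects(
        {(item["list_id"], int(item["position"])): float(item["offset"])
         for item in payload}
    )


@dataclass
class PipelineConfig:
    """End-to-end run settings, loadable from a YAML file."""

    out_dir: str = "results"
    seed: int = 0
    threshold: float = 0.58
    verbose: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors_path: str | None = None
    effects_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**payload.pop("cohort", {}))
        mcmc = MCMCConfig(**payload.pop("mcmc", {}))
        known = {"out_dir", "seed", "threshold", "verbose", "priors_path",
                 "effects_path"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(cohort=cohort, mcmc=mcmc, **payload)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        payload = asdict(self)
        for block in ("cohort", "mcmc"):
            payload[block] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in payload[block].items()
            }
        return payload
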