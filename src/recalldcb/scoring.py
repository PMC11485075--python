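"""Traditional ADAS-Cog word-recall scoring.

Both scores are *error* counts — words NOT recalled — so higher means
worse memory: the immediate score is the mean number of words not
recalled across the three IFR tasks (0–10 in steps of 1/3 for a 10-word
list), and the delayed score is the integer number of words not
recalled on the single DFR task.  The polarity is never flipped here;
regression signs downstream are interpreted accordingly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from recalldcb.model import N_IFR_TASKS, RecallSequence

__all__ = ["score_immediate", "score_delayed", "score_table"]


def _check(sequences: Sequence[RecallSequence]) -> int:
    if len(sequences) == 0:
        raise ValueError("cannot score an empty word set")
    lengths = {s.list_length for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent list lengths across words: {sorted(lengths)}")
    n = lengths.pop()
    if len(sequences) > n:
        raise ValueError(f"{len(sequences)} words exceed the list length {n}")
    return n


def score_immediate(sequences: Sequence[RecallSequence]) -> float:
    """Mean number of words not recalled across the three IFR tasks."""
    n = _check(sequences)
    recalled = np.array([s.recalls[:N_IFR_TASKS] for s in sequences]).sum(axis=0)
    return float(np.mean(n - recalled))


def score_delayed(sequences: Sequence[RecallSequence]) -> int:
    """Number of words not recalled on the DFR task."""
    n = _check(sequences)
    return int(n - sum(s.recalls[3] for s in sequences))


def score_table(recall_df: pd.DataFrame, list_length: int = 10) -> pd.DataFrame:
    """Traditional scores for every participant in an item-level table.

    Returns a frame with columns ``participant_id``, ``immediate_recall``
    and ``delayed_recall``.
    """
    required = {"participant_id", "recall_ifr1", "recall_ifr2", "recall_ifr3", "recall_dfr"}
    missing = required - set(recall_df.columns)
    if missing:
        raise ValueError(f"recall table is missing columns: {sorted(missing)}")
    grouped = recall_df.groupby("participant_id", sort=True)
    counts = grouped.size()
    too_many = counts[counts > list_length]
    if len(too_many):
        raise ValueError(
            f"participants with more words than the list length {list_length}: "
            f"{list(too_many.index)}"
        )
    sums = grouped[["recall_ifr1", "recall_ifr2", "recall_ifr3", "recall_dfr"]].sum()
    immediate = (list_length - sums[["recall_ifr1", "recall_ifr2", "recall_ifr3"]]).mean(axis=1)
    delayed = (list_length - sums["recall_dfr"]).astype(int)
    return pd.DataFrame(
        {
            "participant_id": sums.index,
            "immediate_recall": immediate.to_numpy(),
            "delayed_recall": delayed.to_numpy(),
        }
    ).reset_index(drop=True)
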