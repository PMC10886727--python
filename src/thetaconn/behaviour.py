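"""Sequence-specific skill (sss) and improvement (ssi) from block reaction times.

For each sequence (reactivated Re / non-reactivated NRe), hand and subject:

    sss_pre        = mean RT of pre-sleep random blocks  - mean RT of last 4 pre-sleep sequence blocks
    sss_post_early = mean RT of post-sleep random blocks - mean RT of first 4 post-sleep sequence blocks
    sss_post_late  = mean RT of post-sleep random blocks - mean RT of last 4 post-sleep sequence blocks
    ssi_early      = sss_post_early - sss_pre
    ssi_late       = sss_post_late  - sss_pre

Subtracting the random blocks removes non-specific sensorimotor speed-up;
higher values indicate more sequence-specific skill / improvement.  All
quantities are in milliseconds.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["sequence_specific_skill", "sequence_specific_improvement", "skill_metrics"]

REQUIRED_COLUMNS = {"session", "sequence", "block_index", "block_type", "rt_ms"}

Which = Literal["pre", "post_early", "post_late"]


def _block_rts(table: pd.DataFrame, summary: str) -> pd.DataFrame:
    """Collapse to one RT per block (median by default) if finer-grained."""
    keys = [c for c in ("subject", "session", "sequence", "hand", "block_index", "block_type")
            if c in table.columns]
    grouped = table.groupby(keys, observed=True)["rt_ms"]
    agg = grouped.median() if summary == "median" else grouped.mean()
    return agg.reset_index()


def sequence_specific_skill(
    table: pd.DataFrame,
    sequence: str,
    which: Which,
    hand: str | None = None,
    summary: str = "median",
) -> float:
    """Random-block mean RT minus the referenced 4 sequence-block mean RT (ms).

    ``which`` selects the session and block position: ``pre`` and
    ``post_late`` use the last 4 sequence blocks of their session,
    ``post_early`` the first 4 after waking.  ``hand`` restricts to one
    hand's trials before block summarisation.
    """
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"behavioural table lacks columns: {sorted(missing)}")
    session = "pre" if which == "pre" else "post"
    sub = table[(table["session"] == session) & (table["sequence"] == sequence)]
    if hand is not None and "hand" in sub.columns:
        sub = sub[sub["hand"] == hand]
    sub = _block_rts(sub, summary)
    random = sub[sub["block_type"] == "random"]
    seq = sub[sub["block_type"] == "sequence"].sort_values("block_index")
    problems = []
    if len(random) < 1:
        problems.append(f"no random blocks in {session}")
    if len(seq) < 4:
        problems.append(f"fewer than 4 sequence blocks in {session}")
    if problems:
        raise ValueError(
            f"missing blocks for {sequence} {which}" + (f" hand={hand}" if hand else "")
            + ": " + "; ".join(problems)
        )
    ref = seq.head(4) if which == "post_early" else seq.tail(4)
    return float(random["rt_ms"].mean() - ref["rt_ms"].mean())


def sequence_specific_improvement(
    sss_pre: float, sss_post_early: float, sss_post_late: float
) -> tuple[float, float]:
    """(ssi_early, ssi_late) = post-sleep skill minus pre-sleep skill."""
    return sss_post_early - sss_pre, sss_post_late - sss_pre


def skill_metrics(
    table: pd.DataFrame,
    per_hand: bool = True,
    summary: str = "median",
) -> pd.DataFrame:
    """All sss/ssi metrics per subject (and hand), for both sequences.

    Returns a tidy frame with columns subject, hand, sequence, sss_pre,
    sss_post_early, sss_post_late, ssi_early, ssi_late (milliseconds).
    ``hand='both'`` rows pool the hands before block summarisation.
    """
    if "subject" not in table.columns:
        table = table.assign(subject=0)
    hands: list[str | None] = (
        [*sorted(table["hand"].unique()), None] if per_hand and "hand" in table.columns else [None]
    )
    rows = []
    for subj, sub in table.groupby("subject"):
        for hand in hands:
            for sequence in sorted(sub["sequence"].unique()):
                pre = sequence_specific_skill(sub, sequence, "pre", hand, summary)
                early = sequence_specific_skill(sub, sequence, "post_early", hand, summary)
                late = sequence_specific_skill(sub, sequence, "post_late", hand, summary)
                ssi_early, ssi_late = sequence_specific_improvement(pre, early, late)
                rows.append(
                    {
                        "subject": subj,
                        "hand": hand if hand is not None else "both",
                        "sequence": sequence,
                        "sss_pre": pre,
                        "sss_post_early": early,
                        "sss_post_late": late,
                        "ssi_early": ssi_early,
                        "ssi_late": ssi_late,
                    }
                )
    return pd.DataFrame(rows)
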