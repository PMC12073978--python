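"""Item banks and percent-correct scoring for the reasoning tasks.

The analogical reasoning task (ART) has 24 test items crossing two analogy
rules (progression, odd-one-out) with two dimensionality conditions (intra-,
cross-dimensional) over three stimulus features (number, colour, size).  The
deductive reasoning task (DRT) has 24 relational items: 12 valid (all
determinate) and 12 invalid (6 determinate, 6 indeterminate).  A perceptual
matching baseline task has 12 items.  Scores are percent correct:
correct / total x 100, overall or within an item subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COLUMNS = [
    "item_id",
    "task",
    "rule",
    "dimensionality",
    "feature",
    "validity",
    "determinacy",
    "difficulty_q",
]

# default latent difficulties (probability-scale thresholds): cross-dimensional
# and indeterminate items are harder, matching the observed accuracy ordering
ART_DIFFICULTY = {("progression", "intra"): 0.30, ("progression", "cross"): 0.50,
                  ("odd_one_out", "intra"): 0.40, ("odd_one_out", "cross"): 0.60}
DRT_DIFFICULTY = {"determinate": 0.40, "indeterminate": 0.65}
BASELINE_DIFFICULTY = 0.05


def art_item_bank() -> pd.DataFrame:
    """24 ART items: 12 progression + 12 odd-one-out, 12 intra + 12 cross,
    features balanced 8/8/8 across number/colour/size."""
    features = ["number", "colour", "size"]
    rows = []
    i = 0
    for rule in ("progression", "odd_one_out"):
        for dim in ("intra", "cross"):
            for _ in range(6):
                rows.append(
                    dict(
                        item_id=f"ART{i + 1:02d}",
                        task="ART",
                        rule=rule,
                        dimensionality=dim,
                        feature=features[i % 3],
                        validity="none",
                        determinacy="none",
                        difficulty_q=ART_DIFFICULTY[(rule, dim)],
                    )
                )
                i += 1
    return pd.DataFrame(rows, columns=_COLUMNS)


def drt_item_bank() -> pd.DataFrame:
    """24 DRT items: 12 valid (determinate) + 12 invalid (6 determinate,
    6 indeterminate)."""
    rows = []
    layout = [("valid", "determinate", 12), ("invalid", "determinate", 6),
              ("invalid", "indeterminate", 6)]
    i = 0
    for validity, determinacy, n in layout:
        for _ in range(n):
            rows.append(
                dict(
                    item_id=f"DRT{i + 1:02d}",
                    task="DRT",
                    rule="none",
                    dimensionality="none",
                    feature="none",
                    validity=validity,
                    determinacy=determinacy,
                    difficulty_q=DRT_DIFFICULTY[determinacy],
                )
            )
            i += 1
    return pd.DataFrame(rows, columns=_COLUMNS)


def baseline_item_bank() -> pd.DataFrame:
    """12 perceptual-matching baseline items (no reasoning rule)."""
    rows = [
        dict(
            item_id=f"BAS{i + 1:02d}",
            task="baseline",
            rule="none",
            dimensionality="none",
            feature="none",
            validity="none",
            determinacy="none",
            difficulty_q=BASELINE_DIFFICULTY,
        )
        for i in range(12)
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def percent_correct(
    log: pd.DataFrame, bank: pd.DataFrame, subset_filter=None
) -> pd.Series:
    """Per-participant percent correct over the items passing ``subset_filter``.

    ``subset_filter`` is a predicate over the item-bank rows (callable taking
    the bank DataFrame and returning a boolean mask), or None for all items.
    Every participant in the log must have answered every filtered item
    exactly once.
    """
    if subset_filter is None:
        items = bank
    else:
        mask = subset_filter(bank)
        items = bank[np.asarray(mask, dtype=bool)]
    if len(items) == 0:
        raise ValueError("item filter selected no items")
    unknown = set(log["item_id"]) - set(bank["item_id"])
    if unknown:
        raise ValueError(f"log contains items absent from the bank: {sorted(unknown)[:5]}")
    sel = log[log["item_id"].isin(set(items["item_id"]))]
    counts = sel.groupby("participant_id")["item_id"].agg(["count", "nunique"])
    if (counts["count"] != len(items)).any() or (counts["nunique"] != len(items)).any():
        raise ValueError("incomplete or duplicated responses for the filtered items")
    pct = sel.groupby("participant_id")["correct"].mean() * 100.0
    pct.name = "percent_correct"
    return pct


def score_summaries(log: pd.DataFrame, bank: pd.DataFrame) -> pd.DataFrame:
    """Overall and per-subtype percent-correct columns for one task's bank."""
    task = bank["task"].iloc[0]
    out = {f"{task}_total": percent_correct(log, bank)}
    subsets = {
        "rule": ("progression", "odd_one_out"),
        "dimensionality": ("intra", "cross"),
        "feature": ("number", "colour", "size"),
        "determinacy": ("determinate", "indeterminate"),
        "validity": ("valid", "invalid"),
    }
    for col, levels in subsets.items():
        for level in levels:
            if (bank[col] == level).any():
                out[f"{task}_{level}"] = percent_correct(
                    log, bank, lambda b, c=col, v=level: b[c] == v
                )
    return pd.DataFrame(out)
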