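"""Cohort end-state tables: counts and integer percentages per group.

Each ear contributes its end-time-point category (clear / MEE only /
biofilm only / MEE and biofilm); ears whose ear canal was completely
blocked at the end time point are excluded.  Percentages are computed on
the post-exclusion ear count and rounded half-up to integers — the
rounding rule that reproduces published two-digit percentages such as
15/16 -> 94 and 2/16 -> 13.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .scan_io import GROUPS

END_STATE_CATEGORIES = ("clear", "mee_only", "biofilm_only", "mee_and_biofilm")


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """``round_half_up(100 * numerator / denominator)`` as an integer."""
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def incidence_from_counts(numerator: int, denominator: int) -> int:
    """Integer incidence percentage, round-half-up (e.g. 15/16 -> 94)."""
    return round_half_up_percent(numerator, denominator)


@dataclass
class GroupRow:
    """One group's end-state counts and percentages."""

    group: str
    n_animals: int
    n_ears: int  # listed ears, including excluded
    excluded: int
    counts: dict  # category -> count
    percents: dict  # category -> integer percent of (n_ears - excluded)


@dataclass
class CohortTable:
    """End-state table over all groups."""

    rows: list

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "group": r.group,
                "n_animals": r.n_animals,
                "n_ears": r.n_ears,
                "excluded": r.excluded,
            }
            for cat in END_STATE_CATEGORIES:
                rec[cat] = r.counts[cat]
                rec[f"{cat}_pct"] = r.percents[cat]
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_text(self) -> str:
        """Render with the dash convention for empty cells."""
        lines = ["group  n_animals  ears  " + "  ".join(END_STATE_CATEGORIES)]
        for r in self.rows:
            cells = []
            for cat in END_STATE_CATEGORIES:
                c = r.counts[cat]
                cells.append("-" if c == 0 else f"{c} ({r.percents[cat]}%)")
            lines.append(
                f"{r.group}  n={r.n_animals}  ears={r.n_ears - r.excluded}  " + "  ".join(cells)
            )
        return "\n".join(lines)


def summarize_cohort(end_states: pd.DataFrame) -> CohortTable:
    """Build the end-state table from per-ear end states.

    ``end_states`` needs columns ``animal``, ``ear``, ``group`` and
    ``end_state`` (a category or ``"excluded"``); every ear appears
    exactly once.  Excluded ears are dropped from both the counts and the
    percentage denominator.
    """
    required = {"animal", "ear", "group", "end_state"}
    missing = required - set(end_states.columns)
    if missing:
        raise ValueError(f"end_states missing columns: {sorted(missing)}")
    bad_groups = set(end_states["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group label(s): {sorted(bad_groups)}; valid: {GROUPS}")
    bad_states = set(end_states["end_state"]) - set(END_STATE_CATEGORIES) - {"excluded"}
    if bad_states:
        raise ValueError(f"unknown end state(s): {sorted(bad_states)}")
    dup = end_states.duplicated(subset=["animal", "ear"])
    if dup.any():
        raise ValueError("every ear must have exactly one end state")

    rows = []
    for group in GROUPS:
        sub = end_states[end_states["group"] == group]
        if len(sub) == 0:
            continue
        excluded = int((sub["end_state"] == "excluded").sum())
        included = sub[sub["end_state"] != "excluded"]
        denom = len(included)
        counts = {
            cat: int((included["end_state"] == cat).sum()) for cat in END_STATE_CATEGORIES
        }
        percents = {
            cat: (round_half_up_percent(c, denom) if denom else 0)
            for cat, c in counts.items()
        }
        rows.append(
            GroupRow(
                group=group,
                n_animals=int(sub["animal"].nunique()),
                n_ears=len(sub),
                excluded=excluded,
                counts=counts,
                percents=percents,
            )
        )
    return CohortTable(rows=rows)
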