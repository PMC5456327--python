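"""Functionality-tag composition summaries per patient group.

Each consensus feature carries one coarse functionality tag (MET, CS,
ENZ, ...). The summary reports, per tag, total/up/down counts, their
percentages of the group, and whether the tag is exclusively up- or
down-regulated.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from fabrymeta.errors import ValidationError

TAG_SUMMARY_COLUMNS = ("group", "tag", "n_total", "n_up", "n_down",
                       "pct_total", "pct_up", "pct_down", "exclusivity")


def _pct(count: int, total: int) -> float:
    """Percentage to one decimal place, half-up rounding."""
    if total == 0:
        return 0.0
    raw = Decimal(count) * 100 / Decimal(total)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_tags(consensus: pd.DataFrame, group: str) -> pd.DataFrame:
    """One summary row per tag present in the group's consensus features.

    Exclusivity is ``all_up`` iff every feature with the tag is
    up-regulated (symmetrically ``all_down``), otherwise ``mixed``.
    Rows are sorted by descending pct_total then tag code. Input order
    never affects any value.
    """
    feats = consensus[consensus["group"] == group]
    if feats.empty:
        raise ValidationError(f"no features to summarize for group {group!r}")
    n_group = len(feats)
    n_up_group = int((feats["direction"] == "up").sum())
    n_down_group = n_group - n_up_group

    rows = []
    for tag, grp in feats.groupby("tag", sort=True):
        n_up = int((grp["direction"] == "up").sum())
        n_down = len(grp) - n_up
        if n_down == 0 and n_up > 0:
            exclusivity = "all_up"
        elif n_up == 0 and n_down > 0:
            exclusivity = "all_down"
        else:
            exclusivity = "mixed"
        rows.append((group, tag, len(grp), n_up, n_down,
                     _pct(len(grp), n_group), _pct(n_up, n_up_group),
                     _pct(n_down, n_down_group), exclusivity))
    out = pd.DataFrame(rows, columns=list(TAG_SUMMARY_COLUMNS))
    return out.sort_values(["pct_total", "tag"],
                           ascending=[False, True]).reset_index(drop=True)
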