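"""Group-round performance metrics and the analysis panel.

Two complementary success measures are computed per group and round:

``mean_coin_harvest``
    the round's coin earnings averaged over the three players.  Flat near
    the yield peak, so it mostly separates groups that found the peak from
    groups that did not.

``optimal_difference``
    the mean over players of the absolute distance (hours) between each
    player's effort and their individual optimum (11 for yellow, 7 each
    for red and blue — the shared resource's 14-hour optimum split
    equally).  Approximately a linearisation of the coin metric near the
    peak, and sensitive to unequal splits of the common pool.

``build_panel`` flattens a cohort into the long-format group-round table
(one row per group per round) that the statistical models consume.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .ecosystem import EffortProfile, RoundOutcome

__all__ = [
    "DEFAULT_OPTIMA",
    "mean_coin_harvest",
    "optimal_difference",
    "build_panel",
    "PANEL_BASE_COLUMNS",
]

#: per-player optimal efforts under the equal-split assumption
DEFAULT_OPTIMA: tuple[float, float, float] = (11.0, 7.0, 7.0)

PANEL_BASE_COLUMNS = [
    "group_id",
    "treatment",
    "round",
    "mean_coin_harvest",
    "optimal_difference",
]


def mean_coin_harvest(outcome: RoundOutcome) -> float:
    """Arithmetic mean of the three players' coins for one round."""
    return (outcome.coins_yellow + outcome.coins_red + outcome.coins_blue) / 3.0


def optimal_difference(
    efforts: EffortProfile, optima: tuple[float, float, float] = DEFAULT_OPTIMA
) -> float:
    """Mean absolute per-player deviation (hours) from individual optima."""
    opt_y, opt_r, opt_b = optima
    return (
        abs(efforts.yellow - opt_y)
        + abs(efforts.red - opt_r)
        + abs(efforts.blue - opt_b)
    ) / 3.0


def per_player_deviations(
    efforts: EffortProfile, optima: tuple[float, float, float] = DEFAULT_OPTIMA
) -> dict[str, float]:
    """Per-player absolute deviations, for exports alongside the group mean."""
    opt_y, opt_r, opt_b = optima
    return {
        "yellow": abs(efforts.yellow - opt_y),
        "red": abs(efforts.red - opt_r),
        "blue": abs(efforts.blue - opt_b),
    }


def build_panel(cohort, optima: tuple[float, float, float] = DEFAULT_OPTIMA) -> pd.DataFrame:
    """Assemble the group-round analysis panel from a cohort.

    One row per group-round with both performance metrics, raw efforts and
    coins, per-sub-category message counts (zero for no-communication
    arms) and their total.  Raises on ragged traces (missing or duplicate
    rounds).
    """
    from .coding import load_default_scheme  # local import: avoid cycle

    topic_names = load_default_scheme().sub_category_names()
    rows: list[dict[str, object]] = []
    for trace in cohort.traces:
        n_rounds = len(trace.rounds)
        seen = [rec.round for rec in trace.rounds]
        if seen != list(range(1, n_rounds + 1)):
            raise ValueError(
                f"group {trace.group_id}: rounds must be 1..{n_rounds}, got {seen}"
            )
        for rec in trace.rounds:
            counts = rec.message_counts or {}
            row: dict[str, object] = {
                "group_id": trace.group_id,
                "treatment": trace.treatment_id,
                "round": rec.round,
                "effort_yellow": rec.efforts.yellow,
                "effort_red": rec.efforts.red,
                "effort_blue": rec.efforts.blue,
                "coins_yellow": rec.outcome.coins_yellow,
                "coins_red": rec.outcome.coins_red,
                "coins_blue": rec.outcome.coins_blue,
                "mean_coin_harvest": mean_coin_harvest(rec.outcome),
                "optimal_difference": optimal_difference(rec.efforts, optima),
            }
            for name in topic_names:
                row[name] = int(counts.get(name, 0))
            row["total_messages"] = int(sum(counts.values()))
            rows.append(row)
    panel = pd.DataFrame(rows)
    if not panel.empty:
        panel = panel.sort_values(["group_id", "round"], kind="stable").reset_index(drop=True)
    return panel


def panel_topic_columns(panel: pd.DataFrame) -> list[str]:
    """Names of the sub-category count columns present in a panel."""
    from .coding import load_default_scheme

    return [c for c in load_default_scheme().sub_category_names() if c in panel.columns]
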