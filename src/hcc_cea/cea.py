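"""Incremental cost-effectiveness comparison and net monetary benefit.

Strategies are compared in order of increasing effectiveness.  For a pair
(comparator, reference) the incremental cost-effectiveness ratio is
``ICER = (C_comp - C_ref) / (E_comp - E_ref)`` in dollars per QALY; the
published tables print negative ICERs rather than dominance labels, so the
ratio is always reported alongside a dominance flag.  Net monetary benefit
linearises the same decision rule: ``NMB = WTP * E - C``; at a fixed
willingness-to-pay the strategy with the higher NMB is preferred, and two
strategies have equal NMB exactly at WTP equal to their pairwise ICER.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .markov import CEAResult

__all__ = [
    "Dominance",
    "IncrementalComparison",
    "NMBValue",
    "incremental_table",
    "nmb",
    "incremental_to_frame",
    "write_incremental_table",
]


class Dominance:
    """Dominance status of the comparator relative to the reference."""

    NONE = "none"
    DOMINANT = "dominant"  # cheaper and more effective
    DOMINATED = "dominated"  # costlier and not more effective


@dataclass(frozen=True)
class IncrementalComparison:
    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None  # None when delta_qaly == 0
    status: str


@dataclass(frozen=True)
class NMBValue:
    strategy: str
    wtp: float
    nmb: float


def _compare(ref: CEAResult, comp: CEAResult) -> IncrementalComparison:
    dc = comp.lifetime_cost - ref.lifetime_cost
    de = comp.qaly_years - ref.qaly_years
    if dc < 0 and de > 0:
        status = Dominance.DOMINANT
    elif dc > 0 and de < 0 or (de == 0 and dc > 0):
        status = Dominance.DOMINATED
    else:
        status = Dominance.NONE
    icer = dc / de if de != 0 else None
    return IncrementalComparison(ref.strategy, comp.strategy, dc, de, icer, status)


def incremental_table(results: list[CEAResult]) -> list[IncrementalComparison]:
    """Pairwise comparisons in order of increasing effectiveness.

    Adjacent strategies are compared, and every strategy after the second
    is additionally compared with the least effective one.  Duplicate
    strategy labels are rejected.
    """
    if len(results) < 2:
        raise ValueError("incremental_table requires at least two strategies")
    labels = [r.strategy for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate strategy labels: {labels}")
    ranked = sorted(results, key=lambda r: r.qaly_years)
    out = [_compare(ranked[i - 1], ranked[i]) for i in range(1, len(ranked))]
    out += [_compare(ranked[0], ranked[i]) for i in range(2, len(ranked))]
    return out


def nmb(result: CEAResult, wtp: float) -> NMBValue:
    """Net monetary benefit ``WTP * QALY - cost`` at a given threshold."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return NMBValue(result.strategy, wtp, wtp * result.qaly_years - result.lifetime_cost)


def incremental_to_frame(table: list[IncrementalComparison]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in table])


def write_incremental_table(
    table: list[IncrementalComparison], path: str | Path
) -> None:
    """Write comparisons as CSV, or JSON if the suffix is .json."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([asdict(c) for c in table], indent=2) + "\n")
    else:
        incremental_to_frame(table).to_csv(path, index=False)
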