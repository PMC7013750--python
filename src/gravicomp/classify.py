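"""Intra- and inter-platform set logic for altered-gravity responses.

This module houses every downstream classification step once differential
expression has been called: double-sensitivity intersections with direction
concordance, the temporal classifier (75 s rocket hypergravity vs 300 s
centrifuge hypergravity), the flight-microgravity vs vector-averaged-gravity
classifier, two/three-set Venn region counts, and the two-step overlap
ledger that cross-tabulates a primary comparison's up/down/non-responsive
groups against secondary comparisons.

Both classifiers partition the TC universe: every transcript receives
exactly one label, and a transcript eliminated by control filtering is
labelled ``eliminated`` regardless of its calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import ComparisonResult
from .io import TranscriptSet

__all__ = [
    "TEMPORAL_LABELS",
    "CROSS_UG_LABELS",
    "classify_temporal",
    "classify_cross_microgravity",
    "classify_counts",
    "double_sensitive",
    "count_direction_concordance",
    "venn_counts",
    "build_overlap_ledger",
    "round_percent",
]

TEMPORAL_LABELS = ("continuous", "adaptation", "late", "non_responsive", "eliminated")
CROSS_UG_LABELS = (
    "same_response",
    "no_or_reverse",
    "vag_only",
    "non_responsive",
    "eliminated",
)

_DIRECTIONS = ("up", "down", "none")


def _check_direction(value: str, name: str) -> None:
    if value not in _DIRECTIONS:
        raise ValueError(f"{name} must be one of {_DIRECTIONS}, got {value!r}")


def classify_temporal(call_75s: str, call_300s: str, eliminated: bool = False) -> str:
    """Temporal hypergravity response class of one transcript cluster.

    ``call_75s`` is the direction after 75 s of launch hypergravity,
    ``call_300s`` after 300 s of centrifuge hypergravity. A transcript
    responding in the same direction at both durations is ``continuous``;
    responding early but not (or oppositely) late is ``adaptation``;
    responding only late is ``late``; otherwise ``non_responsive``. The
    ``eliminated`` flag (control filtering) dominates everything.
    """
    _check_direction(call_75s, "call_75s")
    _check_direction(call_300s, "call_300s")
    if eliminated:
        return "eliminated"
    if call_75s != "none":
        return "continuous" if call_300s == call_75s else "adaptation"
    if call_300s != "none":
        return "late"
    return "non_responsive"


def classify_cross_microgravity(
    call_flight: str, call_vag: str, eliminated: bool = False
) -> str:
    """Flight-microgravity vs vector-averaged-gravity response class.

    Same shape as :func:`classify_temporal` with flight-induced microgravity
    in the leading role: same direction in both -> ``same_response``;
    flight response without matching vag response -> ``no_or_reverse``;
    vag response only -> ``vag_only``; neither -> ``non_responsive``.
    """
    _check_direction(call_flight, "call_flight")
    _check_direction(call_vag, "call_vag")
    if eliminated:
        return "eliminated"
    if call_flight != "none":
        return "same_response" if call_vag == call_flight else "no_or_reverse"
    if call_vag != "none":
        return "vag_only"
    return "non_responsive"


def classify_counts(
    cells: Iterable[tuple[str, str, int]],
    classifier=classify_temporal,
    eliminated: int = 0,
) -> dict[str, int]:
    """Aggregate a classifier over (primary_call, secondary_call, count) cells.

    Useful for reproducing published class totals from cross-tabulated
    counts when per-TC calls are unavailable. ``eliminated`` adds that many
    transcripts to the ``eliminated`` class.
    """
    totals: dict[str, int] = {}
    for call_a, call_b, count in cells:
        label = classifier(call_a, call_b, False)
        totals[label] = totals.get(label, 0) + int(count)
    if eliminated:
        totals["eliminated"] = totals.get("eliminated", 0) + int(eliminated)
    return totals


def count_direction_concordance(
    fc_a: Sequence[float], fc_b: Sequence[float]
) -> tuple[int, int]:
    """Count (same_direction, reverse_direction) pairs of signed FCs."""
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold-change vectors differ in length")
    same = int(((a > 0) == (b > 0)).sum())
    return same, a.size - same


def double_sensitive(
    a: ComparisonResult, b: ComparisonResult
) -> tuple[TranscriptSet, int, int]:
    """Transcripts called in both comparisons, with direction concordance.

    Returns the intersection (directions taken from comparison ``a``) and
    the counts of same-direction and reverse-direction members, judged by
    the sign agreement of the two signed fold changes. Concordance counts
    are symmetric in the arguments.
    """
    if not a.tc_ids.equals(b.tc_ids):
        if set(a.tc_ids) != set(b.tc_ids):
            raise ValueError("comparison results cover different TC universes")
        b = ComparisonResult(b.spec, b.table.reindex(a.tc_ids), b.gene_symbols)
    both = (a.table["call"] != "none") & (b.table["call"] != "none")
    inter = TranscriptSet(
        dict(a.table.loc[both, "call"]),
        source=f"{a.spec.name} & {b.spec.name}",
    )
    same, reverse = count_direction_concordance(
        a.table.loc[both, "fc"], b.table.loc[both, "fc"]
    )
    return inter, same, reverse


def venn_counts(
    sets: Sequence[TranscriptSet],
    annotated: set[str] | None = None,
) -> dict[str, dict[str, int]]:
    """Disjoint Venn region counts for two or three transcript sets.

    Regions are keyed by membership patterns such as ``"110"`` (in the first
    and second set, not the third). Each region reports ``all`` and, when an
    ``annotated`` tc_id set is supplied, ``annotated`` counts.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_counts supports 2 or 3 sets")
    memberships = [s.tc_ids() for s in sets]
    universe = set().union(*memberships)
    regions: dict[str, dict[str, int]] = {}
    n = len(sets)
    for bits in range(1, 2**n):
        pattern = format(bits, f"0{n}b")
        regions[pattern] = {"all": 0}
        if annotated is not None:
            regions[pattern]["annotated"] = 0
    for tc in universe:
        pattern = "".join("1" if tc in m else "0" for m in memberships)
        regions[pattern]["all"] += 1
        if annotated is not None and tc in annotated:
            regions[pattern]["annotated"] += 1
    return regions


def round_percent(count: int, total: int, decimals: int = 1) -> float:
    """Row percentage rounded half-up, as the published tables round."""
    if total == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class OverlapLedger:
    """Two-step cross tabulation of a primary comparison vs secondaries.

    ``rows`` maps primary call category (``up``/``down``/``non_responsive``)
    to a dict with row totals and, per secondary comparison name, counts and
    row percentages in each secondary category. Counts are kept for all TCs
    and for annotated TCs only; raw ratios are preserved alongside the
    rounded percentages.
    """

    primary_name: str
    rows: dict

    def to_dict(self) -> dict:
        return {"primary": self.primary_name, "rows": self.rows}


_CATEGORIES = {"up": "up", "down": "down", "none": "non_responsive"}


def build_overlap_ledger(
    primary: ComparisonResult,
    secondaries: Sequence[ComparisonResult],
    annotated: pd.Series | None = None,
) -> OverlapLedger:
    """Cross-tabulate primary up/down/non-responsive rows over secondaries.

    Every secondary must cover the same TC universe as the primary. Each
    row's secondary counts sum to the row total, and percentages are
    ``100 * count / row_total`` (0 with an ``empty_row`` marker when the row
    total is 0).
    """
    if annotated is None:
        annotated = (
            primary.gene_symbols != ""
            if primary.gene_symbols is not None
            else pd.Series(False, index=primary.tc_ids)
        )
    annotated = annotated.reindex(primary.tc_ids).fillna(False)
    aligned = []
    for sec in secondaries:
        if not sec.tc_ids.equals(primary.tc_ids):
            if set(sec.tc_ids) != set(primary.tc_ids):
                raise ValueError(
                    f"secondary {sec.spec.name!r} covers a different TC universe"
                )
            sec = ComparisonResult(
                sec.spec, sec.table.reindex(primary.tc_ids), sec.gene_symbols
            )
        aligned.append(sec)

    rows: dict = {}
    for call_value, row_label in _CATEGORIES.items():
        mask = (primary.table["call"] == call_value).to_numpy()
        total_all = int(mask.sum())
        total_ann = int((mask & annotated.to_numpy()).sum())
        row = {
            "total": {"all": total_all, "annotated": total_ann},
            "empty_row": total_all == 0,
            "secondaries": {},
        }
        for sec in aligned:
            cells = {}
            for sec_value, sec_label in _CATEGORIES.items():
                sec_mask = (sec.table["call"] == sec_value).to_numpy() & mask
                c_all = int(sec_mask.sum())
                c_ann = int((sec_mask & annotated.to_numpy()).sum())
                cells[sec_label] = {
                    "all": c_all,
                    "annotated": c_ann,
                    "pct_all": round_percent(c_all, total_all),
                    "pct_annotated": round_percent(c_ann, total_ann),
                    "ratio_all": c_all / total_all if total_all else 0.0,
                    "ratio_annotated": c_ann / total_ann if total_ann else 0.0,
                }
            row["secondaries"][sec.spec.name] = cells
        rows[row_label] = row
    return OverlapLedger(primary.spec.name, rows)
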