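"""Control-exclusion filtering of differentially expressed transcript sets.

A primary differential-expression set (e.g. clinostat vs 1 g control) may
contain transcripts that already responded to handling, hardware or the
preceding flight phase. The study's remedy is pure set subtraction: every
transcript differentially expressed in a designated control comparison is
excluded from the primary set, matching on tc_id only — the direction of
regulation in the control comparison is irrelevant.

Three stringency levels exist. On the ground-based platform the only control
comparison is 1 g control vs baseline (``maximal``); the rocket platform has
a ``maximal`` scheme (hardware ground control vs cell culture, plus 1 g
in-flight vs hardware ground control — the union of both is excluded) and a
``minimal`` scheme (in-flight comparison only). ``none`` disables filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .diffexp import ComparisonSpec
from .io import Group, Platform, TranscriptSet

__all__ = ["ControlLevel", "ControlScheme", "build_scheme", "apply_control_exclusion"]


class ControlLevel(str, Enum):
    MAXIMAL = "maximal"
    MINIMAL = "minimal"
    NONE = "none"


@dataclass(frozen=True)
class ControlScheme:
    """Which control comparisons are subtracted, at which stringency."""

    level: ControlLevel
    platform: Platform
    control_comparisons: tuple[ComparisonSpec, ...]

    def __post_init__(self) -> None:
        if self.level == ControlLevel.NONE and self.control_comparisons:
            raise ValueError("level 'none' must carry no control comparisons")


def build_scheme(platform: Platform | str, level: ControlLevel | str) -> ControlScheme:
    """Return the control comparisons of a platform/stringency combination."""
    platform = Platform(platform)
    level = ControlLevel(level)
    if level == ControlLevel.NONE:
        return ControlScheme(level, platform, ())
    if platform == Platform.GBF:
        if level == ControlLevel.MINIMAL:
            raise ValueError(
                "the GBF platform defines only 'maximal' and 'none' control "
                "levels (its single control comparison is 1g control vs BL)"
            )
        specs = (
            ComparisonSpec(
                "1g control vs BL", Group.CONTROL_1G, Group.BL, Platform.GBF
            ),
        )
    else:
        in_flight = ComparisonSpec(
            "1g IF vs H/W 1g GC", Group.IF_1G, Group.HW_1G_GC, Platform.TEXUS
        )
        if level == ControlLevel.MINIMAL:
            specs = (in_flight,)
        else:
            specs = (
                ComparisonSpec(
                    "H/W 1g GC vs CC", Group.HW_1G_GC, Group.CC, Platform.TEXUS
                ),
                in_flight,
            )
    return ControlScheme(level, platform, specs)


def apply_control_exclusion(
    primary: TranscriptSet, controls: Sequence[TranscriptSet] | Iterable[TranscriptSet]
) -> tuple[TranscriptSet, TranscriptSet]:
    """Split a primary set into (controlled, eliminated) by control overlap.

    ``controlled`` keeps every primary member whose tc_id appears in no
    control set; ``eliminated`` collects the rest. Matching is by tc_id
    regardless of direction. The two outputs partition the primary set and
    the operation is idempotent.
    """
    excluded: set[str] = set()
    for control in controls:
        excluded |= control.tc_ids()
    controlled = {
        tc: d for tc, d in primary.members.items() if tc not in excluded
    }
    eliminated = {tc: d for tc, d in primary.members.items() if tc in excluded}
    label = primary.source or "primary"
    return (
        TranscriptSet(controlled, source=f"{label} [controlled]"),
        TranscriptSet(eliminated, source=f"{label} [eliminated]"),
    )
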