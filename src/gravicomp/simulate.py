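"""Synthetic two-platform altered-gravity expression studies with known truth.

The generator emulates the design of the real study: a ground-based-facility
(GBF) arm with baseline (BL), 1 g control, 2D clinostat and 9 g centrifuge
groups, and a suborbital-rocket (TEXUS) arm with cell-culture control (CC),
hardware ground control, 1 g in-flight centrifuge, launch-hypergravity and
flight-microgravity groups. Each transcript cluster is assigned one effect
class that determines which group means are shifted, multiplicatively on the
linear scale, so the planted fold change is exact under zero noise. Noise is
i.i.d. Gaussian on log2 intensities (log-normal on the linear scale).

A handling (baseline) effect class emulates the large expression signal the
study attributed to simply pipetting the cell suspension: those TCs respond
in every pipette-handled group relative to BL/CC *and* in the primary
comparisons, so control-exclusion filtering removes them end to end.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` stream, so identical configurations produce
bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    Group,
    GROUPS_BY_PLATFORM,
    Platform,
    SampleSheet,
    TranscriptSet,
)

__all__ = [
    "EFFECT_CLASSES",
    "PRIMARY_COMPARISON_KEYS",
    "SimulationConfig",
    "TruthLedger",
    "StudyData",
    "generate_study",
    "planted_recovery_report",
]

# Comparison keys used in the truth ledger (group_a_vs_group_b).
PRIMARY_COMPARISON_KEYS = (
    "CLINOSTAT_2D_vs_CONTROL_1G",   # vector-averaged gravity
    "CENTRIFUGE_9G_vs_CONTROL_1G",  # GBF hypergravity
    "TX_UG_vs_IF_1G",               # flight microgravity
    "TX_HYP_G_vs_IF_1G",            # rocket-launch hypergravity
)

# Effect class -> per-group multiplier exponents. A planted signed fold
# change f maps each listed group's linear mean to mean * |f|**e (or
# mean / |f|**e for down-regulation). Handling-sensitive TCs use exponent 1
# for the handled control groups and 2 for the experimental groups, which
# makes them differentially expressed both in the control comparison
# (CONTROL_1G vs BL, HW vs CC) and in every primary comparison.
EFFECT_CLASSES: dict[str, dict[Group, int]] = {
    "handling_sensitive": {
        Group.CONTROL_1G: 1,
        Group.CLINOSTAT_2D: 2,
        Group.CENTRIFUGE_9G: 2,
        Group.HW_1G_GC: 1,
        Group.IF_1G: 1,
        Group.TX_HYP_G: 2,
        Group.TX_UG: 2,
    },
    "vag_only": {Group.CLINOSTAT_2D: 1},
    "flight_ug_only": {Group.TX_UG: 1},
    "hyper_gbf_only": {Group.CENTRIFUGE_9G: 1},
    "hyper_tx_only": {Group.TX_HYP_G: 1},
    "double_sensitive_gbf": {Group.CLINOSTAT_2D: 1, Group.CENTRIFUGE_9G: 1},
    "double_sensitive_tx": {Group.TX_UG: 1, Group.TX_HYP_G: 1},
    "cross_platform_ug": {Group.CLINOSTAT_2D: 1, Group.TX_UG: 1},
    "cross_platform_hyper": {Group.CENTRIFUGE_9G: 1, Group.TX_HYP_G: 1},
    "null": {},
}

# Replicate counts of the real design: 6 per GBF group; the rocket campaign
# processed 7 CC, 7 hardware ground controls, 9 in-flight 1 g, 7 launch
# hypergravity and 9 microgravity samples.
DEFAULT_REPLICATES: dict[Group, int] = {
    Group.BL: 6,
    Group.CONTROL_1G: 6,
    Group.CLINOSTAT_2D: 6,
    Group.CENTRIFUGE_9G: 6,
    Group.CC: 7,
    Group.HW_1G_GC: 7,
    Group.IF_1G: 9,
    Group.TX_HYP_G: 7,
    Group.TX_UG: 9,
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic study.

    ``class_proportions`` maps effect-class labels to fractions of the TC
    universe; the remainder is null. ``fc_range`` bounds the planted |FC|,
    matching the span of fold changes the study reported (about 1.3-4.3).
    ``noise_sd`` is the per-sample log2-scale noise; the study does not
    report within-group variance, so this is a free parameter (default 0.1,
    consistent with its remark about low within-group variance).
    """

    n_tc: int = 2000
    fraction_annotated: float = 0.8
    replicates: dict[Group, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "handling_sensitive": 0.04,
            "vag_only": 0.01,
            "flight_ug_only": 0.01,
            "hyper_gbf_only": 0.04,
            "hyper_tx_only": 0.01,
            "double_sensitive_gbf": 0.01,
            "double_sensitive_tx": 0.005,
            "cross_platform_ug": 0.002,
            "cross_platform_hyper": 0.005,
        }
    )
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.1
    fc_range: tuple[float, float] = (1.3, 4.3)
    fraction_down: float = 0.35  # the study saw more up- than downregulation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tc <= 0:
            raise ValueError("n_tc must be positive")
        if not 0.0 <= self.fraction_annotated <= 1.0:
            raise ValueError("fraction_annotated must be in [0, 1]")
        for group, n in self.replicates.items():
            if n <= 0:
                raise ValueError(f"replicates for {Group(group).value} must be positive")
        unknown = set(self.class_proportions) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if sum(self.class_proportions.values()) > 1.0 + 1e-12:
            raise ValueError("class proportions sum to more than 1")
        lo, hi = self.fc_range
        if not (1.3 <= lo <= hi):
            raise ValueError("fc_range must satisfy 1.3 <= low <= high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["replicates"] = {Group(g).value: n for g, n in self.replicates.items()}
        d["fc_range"] = list(self.fc_range)
        return d


@dataclass
class TruthLedger:
    """Planted truth: per-TC effect class and per-comparison direction.

    ``table`` is indexed by tc_id with columns ``effect_class``, ``true_fc``
    (signed, +1 for null) and one ``dir_<comparison_key>`` column per primary
    comparison holding ``up``/``down``/``none``.
    """

    table: pd.DataFrame

    def classes(self) -> pd.Series:
        return self.table["effect_class"]

    def expected_set(self, comparison_key: str) -> TranscriptSet:
        """TCs truly responsive in a comparison, with planted direction."""
        col = f"dir_{comparison_key}"
        sub = self.table[self.table[col] != "none"]
        return TranscriptSet(dict(sub[col]), source=f"truth:{comparison_key}")

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


@dataclass
class StudyData:
    """One synthetic study: per-platform matrices and sheets plus the truth."""

    matrices: dict[Platform, ExpressionMatrix]
    sheets: dict[Platform, SampleSheet]
    truth: TruthLedger
    config: SimulationConfig


def _allocate_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact largest-remainder allocation of TCs to effect classes."""
    labels = list(config.class_proportions)
    fractions = np.array([config.class_proportions[c] for c in labels])
    exact = fractions * config.n_tc
    counts = np.floor(exact + 1e-9).astype(int)  # tolerate 0.1*1000 = 99.999...
    # distribute leftover non-null TCs by largest fractional part
    target_nonnull = min(int(round(fractions.sum() * config.n_tc)), config.n_tc)
    order = np.argsort(-(exact - counts), kind="stable")
    i = 0
    while counts.sum() < target_nonnull and i < len(order):
        counts[order[i]] += 1
        i += 1
    assignment = np.array(
        [label for label, c in zip(labels, counts) for _ in range(c)]
        + ["null"] * (config.n_tc - counts.sum()),
        dtype=object,
    )
    rng.shuffle(assignment)
    return assignment


def generate_study(config: SimulationConfig) -> StudyData:
    """Generate one two-platform study with a planted truth ledger."""
    rng = np.random.default_rng(config.seed)
    n = config.n_tc
    tc_ids = pd.Index([f"TC{i:06d}.syn" for i in range(n)], name="tc_id")

    annotated = rng.random(n) < config.fraction_annotated
    gene_symbols = pd.Series(
        np.where(annotated, [f"GENE{i}" for i in range(n)], ""), index=tc_ids
    )

    classes = _allocate_classes(config, rng)
    lo, hi = config.fc_range
    magnitudes = rng.uniform(lo, hi, size=n)
    signs = np.where(rng.random(n) < config.fraction_down, -1.0, 1.0)
    true_fc = np.where(classes == "null", 1.0, signs * magnitudes)

    baseline_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    baseline_linear = np.exp2(baseline_log2)

    # per-group multipliers
    group_means: dict[Group, np.ndarray] = {}
    for group in Group:
        exponents = np.array(
            [EFFECT_CLASSES[c].get(group, 0) for c in classes], dtype=float
        )
        factor = np.abs(true_fc) ** exponents
        factor = np.where(true_fc < 0, 1.0 / factor, factor)
        group_means[group] = baseline_linear * factor

    matrices: dict[Platform, ExpressionMatrix] = {}
    sheets: dict[Platform, SampleSheet] = {}
    for platform in Platform:
        sample_ids: list[str] = []
        rows = []
        cols = []
        for group in GROUPS_BY_PLATFORM[platform]:
            n_rep = config.replicates.get(group, DEFAULT_REPLICATES[group])
            for r in range(1, n_rep + 1):
                sid = f"{platform.value}_{group.value}_{r}"
                sample_ids.append(sid)
                rows.append({"sample_id": sid, "platform": platform.value,
                             "group": group.value})
                noise = (
                    np.exp2(rng.normal(0.0, config.noise_sd, n))
                    if config.noise_sd > 0
                    else np.ones(n)
                )
                cols.append(group_means[group] * noise)
        values = pd.DataFrame(
            np.column_stack(cols), index=tc_ids, columns=sample_ids
        )
        matrices[platform] = ExpressionMatrix(values, gene_symbols)
        sheets[platform] = SampleSheet(pd.DataFrame(rows))

    truth_table = pd.DataFrame(
        {"effect_class": classes, "true_fc": true_fc}, index=tc_ids
    )
    for key in PRIMARY_COMPARISON_KEYS:
        group_a = Group(key.split("_vs_")[0])
        affected = np.array(
            [group_a in EFFECT_CLASSES[c] for c in classes], dtype=bool
        )
        direction = np.where(
            ~affected, "none", np.where(true_fc >= 1.0, "up", "down")
        )
        truth_table[f"dir_{key}"] = direction
    return StudyData(matrices, sheets, TruthLedger(truth_table), config)


def planted_recovery_report(
    truth: TruthLedger, called: Mapping[str, TranscriptSet]
) -> dict:
    """Confusion counts of called vs planted TCs, per class and comparison.

    ``called`` maps a primary-comparison key (see
    :data:`PRIMARY_COMPARISON_KEYS`) to the TranscriptSet the pipeline
    called for it. Sensitivity is the fraction of truly responsive TCs of a
    class that were called (any direction); specificity is the fraction of
    truly unresponsive TCs not called.
    """
    universe = set(truth.table.index)
    report: dict = {}
    for key, call_set in called.items():
        col = f"dir_{key}"
        if col not in truth.table.columns:
            raise ValueError(f"unknown comparison key {key!r}")
        extra = call_set.tc_ids() - universe
        if extra:
            raise ValueError(
                f"{key}: called TCs outside the truth universe, e.g. "
                f"{sorted(extra)[0]!r}"
            )
        truth_dir = truth.table[col]
        called_mask = truth.table.index.isin(call_set.tc_ids())
        per_class: dict = {}
        for cls in truth.table["effect_class"].unique():
            cls_mask = (truth.table["effect_class"] == cls).to_numpy()
            responsive = (truth_dir != "none").to_numpy() & cls_mask
            unresponsive = (truth_dir == "none").to_numpy() & cls_mask
            tp = int((responsive & called_mask).sum())
            fn = int((responsive & ~called_mask).sum())
            fp = int((unresponsive & called_mask).sum())
            tn = int((unresponsive & ~called_mask).sum())
            entry = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
            if tp + fn:
                entry["sensitivity"] = tp / (tp + fn)
            if fp + tn:
                entry["specificity"] = tn / (fp + tn)
            per_class[str(cls)] = entry
        report[key] = per_class
    return report
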