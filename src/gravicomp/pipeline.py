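"""End-to-end pipeline: simulate/load -> normalize -> compare -> control ->
classify -> report.

The stage order mirrors the study's analysis: per-platform quantile
normalization, two-group differential-expression calls for the primary and
control comparisons, control-exclusion filtering at a chosen stringency,
then the classification layer (double sensitivity, temporal and
flight-vs-vag classifiers, overlap ledger) and the clinostat physics
report. Each stage logs its input/output cardinalities in the bundle, and a
manifest records versions, seed and thresholds so identical configurations
yield byte-identical report bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    build_overlap_ledger,
    classify_cross_microgravity,
    classify_temporal,
    double_sensitive,
)
from .controls import ControlLevel, apply_control_exclusion, build_scheme
from .diffexp import (
    DEFAULT_ALPHA,
    DEFAULT_FC_THRESHOLD,
    ComparisonResult,
    ComparisonSpec,
    quantile_normalize,
    run_comparison,
)
from .io import (
    ExpressionMatrix,
    Group,
    Platform,
    SampleSheet,
    read_expression_matrix,
    read_sample_sheet,
    write_count_report,
    write_transcript_set,
)
from .physics import physics_report
from .simulate import SimulationConfig, StudyData, generate_study

__all__ = [
    "PRIMARY_SPECS",
    "CONTROL_SPECS",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "render_summary",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


PRIMARY_SPECS: dict[str, ComparisonSpec] = {
    "CLINOSTAT_2D_vs_CONTROL_1G": ComparisonSpec(
        "2D clinostat vs 1g control", Group.CLINOSTAT_2D, Group.CONTROL_1G, Platform.GBF
    ),
    "CENTRIFUGE_9G_vs_CONTROL_1G": ComparisonSpec(
        "9g centrifuge vs 1g control", Group.CENTRIFUGE_9G, Group.CONTROL_1G, Platform.GBF
    ),
    "TX_UG_vs_IF_1G": ComparisonSpec(
        "TX ug vs 1g IF", Group.TX_UG, Group.IF_1G, Platform.TEXUS
    ),
    "TX_HYP_G_vs_IF_1G": ComparisonSpec(
        "TX hyp-g vs 1g IF", Group.TX_HYP_G, Group.IF_1G, Platform.TEXUS
    ),
}

CONTROL_SPECS: dict[str, ComparisonSpec] = {
    "CONTROL_1G_vs_BL": ComparisonSpec(
        "1g control vs BL", Group.CONTROL_1G, Group.BL, Platform.GBF
    ),
    "HW_1G_GC_vs_CC": ComparisonSpec(
        "H/W 1g GC vs CC", Group.HW_1G_GC, Group.CC, Platform.TEXUS
    ),
    "IF_1G_vs_HW_1G_GC": ComparisonSpec(
        "1g IF vs H/W 1g GC", Group.IF_1G, Group.HW_1G_GC, Platform.TEXUS
    ),
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` is set (synthetic study) or both ``matrix_paths``
    and ``sheet_paths`` map platform names to TSV files.
    """

    simulation: SimulationConfig | None = None
    matrix_paths: dict[str, str] = field(default_factory=dict)
    sheet_paths: dict[str, str] = field(default_factory=dict)
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    control_level_gbf: ControlLevel = ControlLevel.MAXIMAL
    control_level_texus: ControlLevel = ControlLevel.MAXIMAL
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        config = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            if "replicates" in sim:
                sim["replicates"] = {Group(g): n for g, n in sim["replicates"].items()}
            if "fc_range" in sim:
                sim["fc_range"] = tuple(sim["fc_range"])
            config.simulation = SimulationConfig(**sim)
        config.control_level_gbf = ControlLevel(config.control_level_gbf)
        config.control_level_texus = ControlLevel(config.control_level_texus)
        return config


def _load_inputs(
    config: PipelineConfig,
) -> tuple[dict[Platform, ExpressionMatrix], dict[Platform, SampleSheet], StudyData | None]:
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**sim.to_dict(), "seed": config.seed})
            sim.replicates = {Group(g): n for g, n in sim.replicates.items()}
            sim.fc_range = tuple(sim.fc_range)
        study = generate_study(sim)
        return study.matrices, study.sheets, study
    matrices = {}
    sheets = {}
    for name, path in config.matrix_paths.items():
        matrices[Platform(name)] = read_expression_matrix(path)
    for name, path in config.sheet_paths.items():
        sheets[Platform(name)] = read_sample_sheet(path)
    if not matrices:
        raise PipelineError("load: no simulation config and no matrix paths")
    return matrices, sheets, None


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages; optionally write the report bundle under ``out_dir``.

    Returns the in-memory bundle: normalized matrices, per-comparison
    results, controlled/eliminated sets, classification counts, overlap
    ledger, physics report, stage log and manifest.
    """
    log: list[dict] = []
    matrices, sheets, study = _load_inputs(config)
    for platform, matrix in matrices.items():
        sheets[platform].validate_against(matrix)
        log.append(
            {"stage": "load", "platform": platform.value,
             "n_tc": matrix.n_tc, "n_samples": len(matrix.sample_ids)}
        )

    # normalization: once per platform across all of its samples
    normalized: dict[Platform, ExpressionMatrix] = {}
    for platform, matrix in matrices.items():
        try:
            normalized[platform] = quantile_normalize(matrix)
        except Exception as exc:
            raise PipelineError(f"normalize: platform {platform.value}: {exc}") from exc
        log.append({"stage": "normalize", "platform": platform.value,
                    "n_tc": matrix.n_tc})

    # differential expression for all primary and control comparisons
    results: dict[str, ComparisonResult] = {}
    for key, spec in {**PRIMARY_SPECS, **CONTROL_SPECS}.items():
        if spec.platform not in normalized:
            continue
        try:
            res = run_comparison(
                normalized[spec.platform], sheets[spec.platform], spec,
                config.fc_threshold, config.alpha,
            )
        except Exception as exc:
            raise PipelineError(f"diffexp: comparison {spec.name!r}: {exc}") from exc
        results[key] = res
        called = res.called_set()
        log.append({"stage": "diffexp", "comparison": key, "n_called": len(called)})

    # control-exclusion filtering
    controlled: dict[str, dict] = {}
    eliminated_union: set[str] = set()
    levels = {
        Platform.GBF: config.control_level_gbf,
        Platform.TEXUS: config.control_level_texus,
    }
    spec_to_key = {spec.key(): key for key, spec in CONTROL_SPECS.items()}
    for key, spec in PRIMARY_SPECS.items():
        if key not in results:
            continue
        scheme = build_scheme(spec.platform, levels[spec.platform])
        control_sets = []
        for cspec in scheme.control_comparisons:
            ckey = spec_to_key[cspec.key()]
            if ckey in results:
                control_sets.append(results[ckey].called_set())
        primary_set = results[key].called_set()
        ctrl, elim = apply_control_exclusion(primary_set, control_sets)
        controlled[key] = {"controlled": ctrl, "eliminated": elim,
                           "level": scheme.level.value}
        eliminated_union |= elim.tc_ids()
        log.append({"stage": "control", "comparison": key,
                    "level": scheme.level.value, "n_primary": len(primary_set),
                    "n_controlled": len(ctrl), "n_eliminated": len(elim)})

    bundle: dict = {
        "results": results,
        "controlled": controlled,
        "log": log,
    }

    # classification layer (needs a shared TC universe across platforms)
    universes = [set(m.tc_ids) for m in matrices.values()]
    shared_universe = universes[0] if len(universes) == 1 else universes[0] & universes[1]
    classifications: dict = {}
    if {"TX_HYP_G_vs_IF_1G", "CENTRIFUGE_9G_vs_CONTROL_1G"} <= results.keys():
        classifications["temporal"] = _classify_pair(
            results["TX_HYP_G_vs_IF_1G"], results["CENTRIFUGE_9G_vs_CONTROL_1G"],
            controlled, ("TX_HYP_G_vs_IF_1G", "CENTRIFUGE_9G_vs_CONTROL_1G"),
            classify_temporal, shared_universe,
        )
    if {"TX_UG_vs_IF_1G", "CLINOSTAT_2D_vs_CONTROL_1G"} <= results.keys():
        classifications["cross_microgravity"] = _classify_pair(
            results["TX_UG_vs_IF_1G"], results["CLINOSTAT_2D_vs_CONTROL_1G"],
            controlled, ("TX_UG_vs_IF_1G", "CLINOSTAT_2D_vs_CONTROL_1G"),
            classify_cross_microgravity, shared_universe,
        )
    bundle["classifications"] = classifications

    # double-sensitive intersections within each platform
    double: dict = {}
    if {"CLINOSTAT_2D_vs_CONTROL_1G", "CENTRIFUGE_9G_vs_CONTROL_1G"} <= results.keys():
        inter, same, rev = double_sensitive(
            results["CLINOSTAT_2D_vs_CONTROL_1G"], results["CENTRIFUGE_9G_vs_CONTROL_1G"]
        )
        double["gbf"] = {"n": len(inter), "same_direction": same,
                         "reverse_direction": rev, "set": inter}
    if {"TX_UG_vs_IF_1G", "TX_HYP_G_vs_IF_1G"} <= results.keys():
        inter, same, rev = double_sensitive(
            results["TX_UG_vs_IF_1G"], results["TX_HYP_G_vs_IF_1G"]
        )
        double["texus"] = {"n": len(inter), "same_direction": same,
                           "reverse_direction": rev, "set": inter}
    bundle["double_sensitive"] = double

    # overlap ledger: clinostat comparison as primary vs the other three
    if len(results) == len(PRIMARY_SPECS) + len(CONTROL_SPECS):
        primary = results["CLINOSTAT_2D_vs_CONTROL_1G"]
        secondaries = [
            results["TX_UG_vs_IF_1G"],
            results["CENTRIFUGE_9G_vs_CONTROL_1G"],
            results["TX_HYP_G_vs_IF_1G"],
        ]
        bundle["overlap_ledger"] = build_overlap_ledger(primary, secondaries)

    bundle["physics"] = physics_report()

    if study is not None:
        bundle["truth"] = study.truth

    bundle["manifest"] = {
        "gravicomp_version": __version__,
        "seed": config.seed,
        "fc_threshold": config.fc_threshold,
        "alpha": config.alpha,
        "control_levels": {p.value: l.value for p, l in levels.items()},
        "simulated": study is not None,
    }

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _classify_pair(res_a, res_b, controlled, keys, classifier, universe) -> dict:
    """Per-TC classification over the shared universe, plus class counts."""
    elim_sets = {
        key: controlled[key]["eliminated"].tc_ids() if key in controlled else set()
        for key in keys
    }
    elim_union = set().union(*elim_sets.values())
    tc_order = sorted(universe)
    calls_a = res_a.table["call"].reindex(tc_order).fillna("none")
    calls_b = res_b.table["call"].reindex(tc_order).fillna("none")
    labels = [
        classifier(a, b, tc in elim_union)
        for tc, a, b in zip(tc_order, calls_a, calls_b)
    ]
    counts: dict[str, int] = {}
    for label in labels:
        counts[label] = counts.get(label, 0) + 1
    return {
        "labels": pd.Series(labels, index=pd.Index(tc_order, name="tc_id")),
        "counts": counts,
        "eliminated_per_stage": {k: len(v) for k, v in elim_sets.items()},
        "universe": len(tc_order),
    }


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, res in bundle["results"].items():
        table = res.table.copy()
        if res.gene_symbols is not None:
            table.insert(0, "gene_symbol", res.gene_symbols)
        table.to_csv(out_dir / f"comparison_{key}.tsv", sep="\t",
                     float_format="%.10g")
    for key, entry in bundle["controlled"].items():
        write_transcript_set(entry["controlled"], out_dir / f"controlled_{key}.tsv")
        write_transcript_set(entry["eliminated"], out_dir / f"eliminated_{key}.tsv")
    class_report = {
        mode: {"counts": entry["counts"],
               "eliminated_per_stage": entry["eliminated_per_stage"],
               "universe": entry["universe"]}
        for mode, entry in bundle["classifications"].items()
    }
    write_count_report(class_report, out_dir / "classifications.json")
    double_report = {
        key: {k: v for k, v in entry.items() if k != "set"}
        for key, entry in bundle["double_sensitive"].items()
    }
    write_count_report(double_report, out_dir / "double_sensitive.json")
    if "overlap_ledger" in bundle:
        write_count_report(bundle["overlap_ledger"].to_dict(),
                           out_dir / "overlap_ledger.json")
    write_count_report(bundle["physics"], out_dir / "physics.json")
    if "truth" in bundle:
        bundle["truth"].to_frame().to_csv(out_dir / "truth.tsv", sep="\t")
    write_count_report(bundle["manifest"], out_dir / "manifest.json")
    with open(out_dir / "stage_log.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["log"], fh, indent=2)
        fh.write("\n")
    with open(out_dir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(render_summary(bundle))


def render_summary(bundle: dict) -> str:
    """Fixed-width text tables of the bundle's counts.

    Counts are shown for all TCs with annotated-only counts in brackets,
    following the dual-count convention of the published tables. Every
    number is taken directly from bundle fields; the only rendering-side
    arithmetic is percentage formatting.
    """
    required = ["results", "controlled", "classifications", "manifest"]
    missing = [k for k in required if k not in bundle]
    if missing:
        raise PipelineError(f"render: bundle incomplete, missing {missing}")
    lines: list[str] = []
    lines.append("Differentially expressed transcript clusters per comparison")
    lines.append(f"{'comparison':<34}{'up':>12}{'down':>12}{'total':>12}")
    for key, res in bundle["results"].items():
        ann = res.gene_symbols != "" if res.gene_symbols is not None else None
        cells = []
        for direction in ("up", "down"):
            mask = res.table["call"] == direction
            n_all = int(mask.sum())
            n_ann = int((mask & ann).sum()) if ann is not None else 0
            cells.append(f"{n_all} ({n_ann})")
        called = res.table["call"] != "none"
        total = f"{int(called.sum())} ({int((called & ann).sum()) if ann is not None else 0})"
        lines.append(f"{res.spec.name:<34}{cells[0]:>12}{cells[1]:>12}{total:>12}")
    lines.append("")
    lines.append("Control-exclusion filtering")
    lines.append(f"{'comparison':<34}{'level':>10}{'kept':>8}{'removed':>9}")
    for key, entry in bundle["controlled"].items():
        lines.append(
            f"{key:<34}{entry['level']:>10}"
            f"{len(entry['controlled']):>8}{len(entry['eliminated']):>9}"
        )
    for mode, entry in bundle["classifications"].items():
        lines.append("")
        lines.append(f"Classification: {mode} (universe {entry['universe']})")
        for label, count in sorted(entry["counts"].items()):
            pct = 100.0 * count / entry["universe"] if entry["universe"] else 0.0
            lines.append(f"  {label:<18}{count:>8}  {pct:5.1f}%")
    return "\n".join(lines) + "\n"
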