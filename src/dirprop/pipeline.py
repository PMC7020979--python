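"""End-to-end study orchestration.

For every fraction that carries manual contours, the pipeline runs rigid
alignment followed by the three deformable algorithms as independent,
order-free branches (plus a rigid-only baseline), propagates the planning
contours onto the fraction grid, scores them against the manual contours
with all four similarity metrics, and finally produces the mixed-model
estimate tables, the modality/fraction subfactor p-value grid, and
per-patient metric traces. Two runs with the same manifest and configuration
produce byte-identical records.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DirpropError
from .image_model import ImageVolume, StructureMask, StudyManifest, read_mask, read_volume
from .lme import subfactor_analysis, summarize_estimates
from .metrics import ALGORITHMS, MetricRecord, evaluate_pair
from .propagation import propagate_mask
from .registration import (
    FFDOptions,
    LevelSpec,
    RegistrationResult,
    RigidOptions,
    register_dir_profile,
    register_nib,
    register_rigid,
)
from .shadowing import ShadowOptions, run_shadowed_nib

log = logging.getLogger("dirprop")

#: two-level pyramid used for study-scale runs: stops at half resolution,
#: which preserves the algorithm orderings at a fraction of the cost
FAST_FFD = FFDOptions(levels=(LevelSpec(4, 32.0, 60), LevelSpec(2, 16.0, 50)))

DEFORMABLE = ("dir_profile", "nib", "shadowed_nib")


@dataclass(frozen=True)
class RunConfig:
    algorithms: tuple[str, ...] = DEFORMABLE
    include_rigid_baseline: bool = True
    ffd: FFDOptions = field(default_factory=lambda: FAST_FFD)
    rigid: RigidOptions = field(default_factory=RigidOptions)
    shadow: ShadowOptions = field(default_factory=ShadowOptions)
    strict: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(DEFORMABLE)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")


@dataclass
class StudyResult:
    records: pd.DataFrame
    estimates: dict[str, pd.DataFrame]  # cohort slice -> estimates table
    subfactors: pd.DataFrame


def _load_masks(row) -> dict[str, StructureMask]:
    return {
        "bladder": read_mask(row.bladder_mask, organ="bladder"),
        "rectum": read_mask(row.rectum_mask, organ="rectum"),
    }


def process_fraction(
    planning: ImageVolume,
    planning_masks: dict[str, StructureMask],
    fraction_image: ImageVolume,
    manual_masks: dict[str, StructureMask],
    config: RunConfig,
    patient_id: str,
    fraction: int,
    modality: str,
) -> list[MetricRecord]:
    """Run all algorithm branches on one fraction and score the propagations."""
    rigid = register_rigid(fraction_image, planning, config.rigid)

    results: dict[str, RegistrationResult] = {}
    if config.include_rigid_baseline:
        results["rigid_only"] = RegistrationResult(rigid, None, 0.0)
    for algorithm in config.algorithms:  # independent branches, any order
        if algorithm == "nib":
            results["nib"] = register_nib(
                fraction_image, planning, config.ffd, rigid=rigid
            )
        elif algorithm == "dir_profile":
            results["dir_profile"] = register_dir_profile(
                fraction_image, planning, config.ffd, rigid=rigid
            )
        elif algorithm == "shadowed_nib":
            results["shadowed_nib"] = run_shadowed_nib(
                planning,
                planning_masks,
                fraction_image,
                manual_masks,
                ffd_options=config.ffd,
                shadow=config.shadow,
                rigid=rigid,
            )

    records = []
    for algorithm, result in results.items():
        for organ, manual in manual_masks.items():
            propagated = propagate_mask(
                planning_masks[organ], result, fraction_image.grid
            )
            records.append(
                evaluate_pair(
                    manual,
                    propagated,
                    patient_id=patient_id,
                    fraction=fraction,
                    modality=modality,
                    algorithm=algorithm,
                )
            )
    return records


def run_study(
    manifest: StudyManifest,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> StudyResult:
    """Process every contoured fraction of a study and write results to disk.

    Writes ``records.csv``, per-cohort estimate tables, and the subfactor
    p-value grid under ``out_dir``. Failures are fatal with ``strict``;
    otherwise the offending fraction is logged and skipped.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_records: list[MetricRecord] = []
    for pid in manifest.patients():
        ref = manifest.reference(pid)
        planning = read_volume(ref.image, modality="PCT")
        planning_masks = _load_masks(ref)
        for row in manifest.fractions(pid):
            if not row.has_masks:
                continue
            t0 = time.perf_counter()
            try:
                fraction_image = read_volume(row.image, modality=row.modality)
                manual = _load_masks(row)
                recs = process_fraction(
                    planning,
                    planning_masks,
                    fraction_image,
                    manual,
                    config,
                    patient_id=pid,
                    fraction=row.fraction,
                    modality=row.modality,
                )
            except DirpropError:
                if config.strict:
                    raise
                log.exception(
                    "patient=%s fraction=%d: stage failed, skipping", pid, row.fraction
                )
                continue
            all_records.extend(recs)
            log.info(
                "patient=%s fraction=%d modality=%s done in %.1fs",
                pid,
                row.fraction,
                row.modality,
                time.perf_counter() - t0,
            )

    records = records_to_frame(all_records)
    records.to_csv(out / "records.csv", index=False, float_format="%.6f")

    estimates: dict[str, pd.DataFrame] = {}
    subfactors = pd.DataFrame()
    if not records.empty:
        slices = {"cohort": records}
        for modality in sorted(records["modality"].unique()):
            slices[modality] = records[records["modality"] == modality]
        for name, sub in slices.items():
            if sub["patient_id"].nunique() >= 2:
                est = summarize_estimates(sub)
                est.to_csv(out / f"estimates_{name}.csv", index=False, float_format="%.6f")
                estimates[name] = est
        if records["patient_id"].nunique() >= 2:
            algos = [a for a in records["algorithm"].unique() if a != "rigid_only"]
            subfactors = subfactor_analysis(records, algorithms=sorted(algos))
            subfactors.to_csv(out / "subfactors.csv", index=False, float_format="%.6f")
    return StudyResult(records=records, estimates=estimates, subfactors=subfactors)


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    cols = [
        "patient_id",
        "fraction",
        "modality",
        "organ",
        "algorithm",
        "hd_mm",
        "mda_mm",
        "dsc",
        "jaccard",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([r.as_dict() for r in records])
    order = {a: i for i, a in enumerate(ALGORITHMS)}
    df = df.sort_values(
        ["patient_id", "fraction", "organ", "algorithm"],
        key=lambda s: s.map(order) if s.name == "algorithm" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return df[cols]


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def report(result: StudyResult, out_dir: str | Path) -> Path:
    """Write a markdown report with estimate tables, bar plots and traces.

    Returns the path of the report file. An empty record set yields a clear
    "no data" report rather than an error.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.md"
    lines = ["# Contour propagation study report", ""]

    if result.records.empty:
        lines += ["No data: the study produced no metric records.", ""]
        path.write_text("\n".join(lines))
        return path

    records = result.records
    lines += [
        f"Patients: {records['patient_id'].nunique()}; "
        f"records: {len(records)}; "
        f"algorithms: {', '.join(sorted(records['algorithm'].unique()))}",
        "",
    ]

    for name, est in result.estimates.items():
        lines += [f"## Estimates ({name})", "", est.to_markdown(index=False), ""]
        fig, axes = plt.subplots(2, 2, figsize=(10, 7))
        for ax, metric in zip(axes.ravel(), ("hd_mm", "mda_mm", "dsc", "jaccard")):
            sub = est[est["metric"] == metric]
            labels = [f"{o[:2]}/{a}" for o, a in zip(sub["organ"], sub["algorithm"])]
            err = np.stack(
                [sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]]
            )
            ax.bar(labels, sub["estimate"], yerr=err, capsize=3)
            ax.set_title(metric)
            ax.tick_params(axis="x", rotation=75, labelsize=7)
        fig.tight_layout()
        fig.savefig(out / f"estimates_{name}.png", dpi=110)
        plt.close(fig)
        lines += [f"![estimates {name}](estimates_{name}.png)", ""]

    if not result.subfactors.empty:
        lines += [
            "## Subfactor p-values (modality, fraction)",
            "",
            result.subfactors.to_markdown(index=False),
            "",
        ]

    # per-fraction traces for the extreme patients (largest/smallest mean MDA)
    mda = records.groupby("patient_id")["mda_mm"].mean()
    for tag, pid in (("largest", mda.idxmax()), ("smallest", mda.idxmin())):
        sub = records[records["patient_id"] == pid]
        fig, axes = plt.subplots(2, 2, figsize=(10, 7))
        for ax, metric in zip(axes.ravel(), ("hd_mm", "mda_mm", "dsc", "jaccard")):
            for (organ, algorithm), grp in sub.groupby(["organ", "algorithm"]):
                ax.plot(grp["fraction"], grp[metric], marker="o", ms=3,
                        label=f"{organ}/{algorithm}")
            ax.set_title(metric)
            ax.set_xlabel("fraction")
        axes[0, 0].legend(fontsize=6)
        fig.tight_layout()
        fname = f"trace_{tag}_{pid}.png"
        fig.savefig(out / fname, dpi=110)
        plt.close(fig)
        lines += [
            f"## Per-fraction trace — {tag} mean MDA (patient {pid})",
            "",
            f"![trace {pid}]({fname})",
            "",
        ]

    path.write_text("\n".join(lines))
    return path
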