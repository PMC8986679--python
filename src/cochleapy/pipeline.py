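"""End-to-end study pipeline: simulate, measure, and analyze agreement.

Orchestrates the synthetic replication of a three-group, three-modality
test-retest imaging study: ground-truth ears are generated and observed
per study design, every observation is reduced to scalar measurements
(A, B, CDL_OC, insertion depths, inter-electrode distances), and each
(group, modality, measurement) block receives the full reliability
analysis — ICC with confidence interval and category, Cronbach's alpha,
paired t-test, and Bland-Altman agreement against the clinical margins.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    BlandAltmanResult,
    CDL_CLINICAL_MARGIN_MM,
    IED_CLINICAL_MARGIN_MM,
    PairedSeries,
    ReliabilityResult,
    bland_altman,
    normality_gate,
    omnibus_modality_test,
    reliability_summary,
)
from .exceptions import CochleapyError, ParameterError, StageError
from .geometry import MeasurementRecord, measure
from .landmarks import LandmarkSet, write_landmarks_csv
from .synthetic import (
    ModalityProfile,
    StudyDesign,
    SubjectDistribution,
    default_profiles,
    simulate_study,
)
from scipy import stats as sps

MEASUREMENT_CSV_COLUMNS = (
    ["subject_id", "group", "modality", "series", "A_mm", "B_mm", "cdl_oc_mm"]
    + [f"ied_{i}" for i in range(1, 12)]
    + [f"depth_{i}" for i in range(1, 13)]
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Reproducible configuration of one pipeline run."""

    design: StudyDesign = field(default_factory=StudyDesign)
    profiles: dict[str, ModalityProfile] = field(default_factory=default_profiles)
    equation_mode: str = "as_printed"
    cdl_margin: float = CDL_CLINICAL_MARGIN_MM
    ied_margin: float = IED_CLINICAL_MARGIN_MM
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cdl_margin <= 0 or self.ied_margin <= 0:
            raise ParameterError("clinical margins must be > 0")
        self.design = replace(self.design, rng_seed=self.rng_seed)

    def to_dict(self) -> dict:
        d = {
            "rng_seed": self.rng_seed,
            "equation_mode": self.equation_mode,
            "clinical_margins": {"cdl_mm": self.cdl_margin, "ied_mm": self.ied_margin},
            "design": {
                "n_subjects": self.design.n_subjects,
                "groups": list(self.design.groups),
                "series_per_modality": self.design.series_per_modality,
                "subjects": asdict(self.design.subjects),
            },
            "profiles": {name: asdict(p) for name, p in self.profiles.items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "PipelineConfig":
        design_d = dict(d.get("design", {}))
        subj = SubjectDistribution(**design_d.pop("subjects", {}))
        n_subjects = design_d.pop("n_subjects", {1: 20, 2: 20, 3: 10})
        if isinstance(n_subjects, dict):
            n_subjects = {int(k): int(v) for k, v in n_subjects.items()}
        design = StudyDesign(
            n_subjects=n_subjects,
            groups=tuple(design_d.pop("groups", (1, 2, 3))),
            series_per_modality=int(design_d.pop("series_per_modality", 2)),
            subjects=subj,
        )
        profiles_d = d.get("profiles")
        profiles = (
            {name: ModalityProfile(**p) for name, p in profiles_d.items()}
            if profiles_d
            else default_profiles()
        )
        margins = d.get("clinical_margins", {})
        rng_seed = int(d.get("rng_seed", 0)) if seed is None else int(seed)
        return cls(
            design=design,
            profiles=profiles,
            equation_mode=d.get("equation_mode", "as_printed"),
            cdl_margin=float(margins.get("cdl_mm", CDL_CLINICAL_MARGIN_MM)),
            ied_margin=float(margins.get("ied_mm", IED_CLINICAL_MARGIN_MM)),
            rng_seed=rng_seed,
        )

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d, seed=seed)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Measurement stage
# ---------------------------------------------------------------------------

def measure_all(
    landmark_sets: list[LandmarkSet], equation_mode: str = "as_printed"
) -> list[MeasurementRecord]:
    """Measure every landmark set; stage errors are re-raised with the
    subject and modality identified."""
    records = []
    for ls in landmark_sets:
        try:
            records.append(measure(ls, equation_mode=equation_mode))
        except CochleapyError as exc:
            raise StageError(
                f"measure ({ls.modality}, series {ls.series})", ls.subject_id, exc
            ) from exc
    return records


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    """Flatten measurement records to the measurement CSV table."""
    rows = []
    for r in records:
        row: dict = {
            "subject_id": r.subject_id,
            "group": r.group,
            "modality": r.modality,
            "series": r.series,
            "A_mm": r.A,
            "B_mm": r.B,
            "cdl_oc_mm": r.cdl_oc,
        }
        for i in range(11):
            row[f"ied_{i + 1}"] = r.ieds[i] if r.ieds is not None else np.nan
        for i in range(12):
            row[f"depth_{i + 1}"] = (
                r.insertion_depths[i] if r.insertion_depths is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=MEASUREMENT_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame, equation_mode: str = "as_printed") -> list[MeasurementRecord]:
    missing = [c for c in MEASUREMENT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        ieds = row[[f"ied_{i}" for i in range(1, 12)]].to_numpy(dtype=float)
        depths = row[[f"depth_{i}" for i in range(1, 13)]].to_numpy(dtype=float)
        has_array = not np.isnan(ieds).all()
        records.append(
            MeasurementRecord(
                subject_id=str(row["subject_id"]),
                group=int(row["group"]),
                modality=str(row["modality"]),
                series=int(row["series"]),
                A=float(row["A_mm"]),
                B=float(row["B_mm"]),
                cdl_oc=float(row["cdl_oc_mm"]),
                equation_mode=equation_mode,
                ieds=ieds if has_array else None,
                insertion_depths=depths if has_array else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Agreement analysis per block
# ---------------------------------------------------------------------------

@dataclass
class BlockReport:
    """Full agreement analysis of one (group, modality, measurement)."""

    group: int
    modality: str
    measurement: str
    n: int
    mean: float
    value_range: tuple[float, float]
    sd: float
    mean_ci_halfwidth: float
    reliability: ReliabilityResult
    bland_altman: BlandAltmanResult
    subject_ids: list = field(default_factory=list, repr=False)


def _block_scalar(records: list[MeasurementRecord], measurement: str) -> dict[str, dict[int, float]]:
    """subject -> {series -> value} for one scalar measurement."""
    out: dict[str, dict[int, float]] = {}
    for r in records:
        val = r.cdl_oc if measurement == "cdl_oc_mm" else r.mean_ied
        if val is None:
            continue
        out.setdefault(r.subject_id, {})[r.series] = float(val)
    return out


def analyze_block(
    records: list[MeasurementRecord],
    group: int,
    modality: str,
    measurement: str,
    clinical_margin: float,
) -> BlockReport | None:
    """Reliability + Bland-Altman analysis for one block; ``None`` when
    the measurement is absent from the block (e.g. IED without arrays)."""
    sub = [r for r in records if r.group == group and r.modality == modality]
    per_subject = _block_scalar(sub, measurement)
    if not per_subject:
        return None
    series_ids = sorted({s for d in per_subject.values() for s in d})
    subjects = sorted(per_subject)
    matrix = np.array(
        [[per_subject[s][ser] for ser in series_ids] for s in subjects]
    )
    ps = PairedSeries(matrix, label=f"G{group}/{modality}/{measurement}")
    values = matrix.ravel()
    n_cells = values.size
    sd = float(values.std(ddof=1))
    t_crit = float(sps.t.ppf(0.975, n_cells - 1))
    return BlockReport(
        group=group,
        modality=modality,
        measurement=measurement,
        n=len(subjects),
        mean=float(values.mean()),
        value_range=(float(values.min()), float(values.max())),
        sd=sd,
        mean_ci_halfwidth=t_crit * sd / np.sqrt(n_cells),
        reliability=reliability_summary(ps),
        bland_altman=bland_altman(ps, clinical_margin, subject_ids=subjects),
        subject_ids=subjects,
    )


# ---------------------------------------------------------------------------
# Cross-modality comparison
# ---------------------------------------------------------------------------

@dataclass
class ModalityComparison:
    group: int
    measurement: str
    omnibus_method: str
    omnibus_p: float
    pairwise: dict[str, dict]  # "MSCT_vs_fpVCT" -> {method, p, significant}


def compare_modalities(
    records: list[MeasurementRecord],
    group: int,
    measurement: str = "cdl_oc_mm",
) -> ModalityComparison:
    """Omnibus and pairwise comparison of modality means within a group.

    Each subject contributes its mean over the test series per modality;
    the omnibus (repeated-measures ANOVA or Friedman, gate-routed) runs
    first, then all pairwise paired comparisons (t-test when the paired
    differences pass the normality gate, Wilcoxon signed-rank otherwise).
    p-values are reported unadjusted.
    """
    sub = [r for r in records if r.group == group]
    modalities = sorted({r.modality for r in sub})
    if len(modalities) < 2:
        raise ParameterError(f"group {group} has fewer than 2 modality blocks")
    per_mod: dict[str, dict[str, float]] = {}
    for m in modalities:
        series_map = _block_scalar([r for r in sub if r.modality == m], measurement)
        per_mod[m] = {s: float(np.mean(list(d.values()))) for s, d in series_map.items()}
    subjects = sorted(set.intersection(*(set(v) for v in per_mod.values())))
    if len(subjects) < 3:
        raise ParameterError(
            f"modality blocks of group {group} share fewer than 3 subjects"
        )
    if any(len(v) != len(subjects) for v in per_mod.values()):
        raise ParameterError(
            f"modality blocks of group {group} are not subject-matched"
        )
    columns = [np.array([per_mod[m][s] for s in subjects]) for m in modalities]
    omni = omnibus_modality_test(columns)
    pairwise: dict[str, dict] = {}
    for i in range(len(modalities)):
        for j in range(i + 1, len(modalities)):
            a, b = columns[i], columns[j]
            d = a - b
            if np.ptp(d) <= 1e-9:  # sub-numerical differences are ties
                method, p = "paired_t", (1.0 if abs(d.mean()) <= 1e-9 else 0.0)
            elif normality_gate(d).parametric:
                method, p = "paired_t", float(sps.ttest_rel(a, b).pvalue)
            else:
                method, p = "wilcoxon", float(sps.wilcoxon(a, b).pvalue)
            pairwise[f"{modalities[i]}_vs_{modalities[j]}"] = {
                "method": method,
                "p": p,
                "significant": bool(p < 0.05),
            }
    return ModalityComparison(
        group=group,
        measurement=measurement,
        omnibus_method=omni.method,
        omnibus_p=omni.p_value,
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Aggregated agreement report of one simulated study run."""

    blocks: list[BlockReport]
    comparisons: list[ModalityComparison]
    metadata: dict

    def block(self, group: int, modality: str, measurement: str = "cdl_oc_mm") -> BlockReport:
        for b in self.blocks:
            if (b.group, b.modality, b.measurement) == (group, modality, measurement):
                return b
        raise KeyError((group, modality, measurement))

    def to_dict(self) -> dict:
        def block_d(b: BlockReport) -> dict:
            return {
                "group": b.group,
                "modality": b.modality,
                "measurement": b.measurement,
                "n": b.n,
                "mean": round(b.mean, 4),
                "range": [round(v, 4) for v in b.value_range],
                "sd": round(b.sd, 4),
                "mean_ci_halfwidth": round(b.mean_ci_halfwidth, 4),
                "icc": round(b.reliability.icc, 4),
                "icc_ci": [
                    round(b.reliability.icc_ci_low, 4),
                    round(b.reliability.icc_ci_high, 4),
                ],
                "icc_category": b.reliability.icc_category,
                "icc_significant": b.reliability.icc_significant,
                "cronbach_alpha": round(b.reliability.alpha, 4),
                "alpha_category": b.reliability.alpha_category,
                "t_test_p": round(b.reliability.t_p_value, 4),
                "series_differ_significantly": b.reliability.significant,
                "bland_altman": {
                    "bias": round(b.bland_altman.bias, 4),
                    "sd_diff": round(b.bland_altman.sd_diff, 4),
                    "loa": [
                        round(b.bland_altman.loa_low, 4),
                        round(b.bland_altman.loa_high, 4),
                    ],
                    "clinical_margin": b.bland_altman.clinical_margin,
                    "n_outliers": b.bland_altman.n_outliers,
                    "outlier_ids": list(b.bland_altman.outlier_ids),
                },
            }

        return {
            "schema_version": 1,
            "metadata": self.metadata,
            "blocks": [block_d(b) for b in self.blocks],
            "modality_comparisons": [
                {
                    "group": c.group,
                    "measurement": c.measurement,
                    "omnibus_method": c.omnibus_method,
                    "omnibus_p": round(c.omnibus_p, 6),
                    "pairwise": {
                        k: {**v, "p": round(v["p"], 6)} for k, v in c.pairwise.items()
                    },
                }
                for c in self.comparisons
            ],
        }

    def blocks_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.to_dict()["blocks"]:
            flat = {k: v for k, v in b.items() if not isinstance(v, (list, dict))}
            flat["range_low"], flat["range_high"] = b["range"]
            flat["icc_ci_low"], flat["icc_ci_high"] = b["icc_ci"]
            ba = b["bland_altman"]
            flat.update(
                ba_bias=ba["bias"],
                ba_sd=ba["sd_diff"],
                ba_loa_low=ba["loa"][0],
                ba_loa_high=ba["loa"][1],
                ba_margin=ba["clinical_margin"],
                ba_n_outliers=ba["n_outliers"],
            )
            rows.append(flat)
        return pd.DataFrame(rows)

    def bland_altman_points(self) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            ba = b.bland_altman
            for sid, m, d in zip(b.subject_ids, ba.means, ba.diffs):
                rows.append(
                    {
                        "group": b.group,
                        "modality": b.modality,
                        "measurement": b.measurement,
                        "subject_id": sid,
                        "mean": m,
                        "diff": d,
                        "outlier_flag": bool(abs(d) > ba.clinical_margin),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        """Write report.json, report.csv and bland_altman_points.csv."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.blocks_frame().to_csv(out / "report.csv", index=False)
        self.bland_altman_points().to_csv(out / "bland_altman_points.csv", index=False)


def analyze_records(
    records: list[MeasurementRecord], config: PipelineConfig
) -> StudyReport:
    """Agreement analysis of an existing measurement table."""
    groups = sorted({r.group for r in records})
    blocks: list[BlockReport] = []
    for g in groups:
        modalities = sorted({r.modality for r in records if r.group == g})
        for m in modalities:
            for measurement, margin in (
                ("cdl_oc_mm", config.cdl_margin),
                ("mean_ied_mm", config.ied_margin),
            ):
                blk = analyze_block(records, g, m, measurement, margin)
                if blk is not None:
                    blocks.append(blk)
    comparisons = []
    for g in groups:
        if len({r.modality for r in records if r.group == g}) >= 2:
            comparisons.append(compare_modalities(records, g, "cdl_oc_mm"))
    metadata = {
        "software_version": __version__,
        "seed": config.rng_seed,
        "equation_mode": config.equation_mode,
        "config_hash": config.config_hash(),
        "clinical_margins_mm": {"cdl": config.cdl_margin, "ied": config.ied_margin},
        "group_sizes": {str(k): v for k, v in config.design.group_sizes().items()},
        "notes": [
            "p-values are reported unadjusted for multiple comparisons",
            "IED margin derives from the CDL margin by proportional "
            "pitch/CDL rescaling (an assumption, recorded here)",
            "normality KS variant: Lilliefors (estimated parameters)",
        ],
    }
    return StudyReport(blocks=blocks, comparisons=comparisons, metadata=metadata)


def run_study(
    config: PipelineConfig,
    out_dir=None,
    keep_landmarks: bool = False,
) -> StudyReport:
    """Simulate, measure and analyze one full study.

    When ``out_dir`` is given, writes ``report.json``, ``report.csv``,
    ``bland_altman_points.csv`` and ``measurements.csv`` (plus
    ``landmarks.csv`` when ``keep_landmarks`` is set).
    """
    landmark_sets = simulate_study(config.design, config.profiles)
    records = measure_all(landmark_sets, equation_mode=config.equation_mode)
    report = analyze_records(records, config)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out)
        records_to_frame(records).to_csv(out / "measurements.csv", index=False)
        if keep_landmarks:
            write_landmarks_csv(landmark_sets, out / "landmarks.csv")
    return report
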