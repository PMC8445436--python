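"""Blind-spot validation protocol: warm-up, scored block, buffer.

A run presents 150 brief stimuli: 25 warm-up trials (detectable only,
excluded from analysis), a scored block of 15 blind-spot + 85 detectable
stimuli in uniformly shuffled order, and 25 buffer trials (detectable only,
excluded).  Scored trials are classified TN/FP/FN/TP per the inverted
convention of :mod:`vistrain.detection_metrics`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .detection_metrics import ConfusionMatrix, MetricsReport, accuracy, cohort_summary, pool
from .geometry import AngularPosition
from .visual_field import (
    FieldStatus,
    VisualFieldMap,
    blind_spot_stimulus_sites,
)

__all__ = [
    "StudyConfig",
    "TrialRecord",
    "PlannedTrial",
    "build_trial_sequence",
    "run_study",
    "run_cohort",
    "CohortResult",
    "write_subject_results",
]


class StudyConfig(BaseModel):
    """Parameters of one validation run."""

    n_warmup: int = Field(default=25, ge=0)
    n_blindspot: int = Field(default=15, ge=0)
    n_detectable: int = Field(default=85, ge=0)
    n_buffer: int = Field(default=25, ge=0)
    stimulus_size_deg: float = Field(default=0.33, gt=0)
    display_ms: float = Field(default=200.0, gt=0)
    response_window_ms: float = Field(default=2000.0, gt=0)
    break_max_ms: float = Field(default=1000.0, ge=0)
    blindspot_site_mode: Literal["centroid", "jitter"] = "centroid"
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_warmup + self.n_blindspot + self.n_detectable + self.n_buffer


class PlannedTrial(NamedTuple):
    block: str  # warmup | scored | buffer
    category: str  # blindspot | detectable
    position: AngularPosition


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation and its outcome."""

    index: int
    block: Literal["warmup", "scored", "buffer"]
    category: Literal["blindspot", "detectable"]
    position: AngularPosition
    clicked: bool
    classification: Literal["TN", "FP", "FN", "TP", "excluded"]
    onset_ms: float = 0.0


def _detectable_pool(field: VisualFieldMap) -> list[AngularPosition]:
    """Intact cells at least one pitch clear of any defect cell, so that a
    stimulus placed there is unambiguously detectable."""
    defect = {ij for ij, st in field.cells.items() if st is FieldStatus.ABSOLUTE_DEFECT}
    pool_pos = []
    for ij, st in field.cells.items():
        if st is not FieldStatus.INTACT:
            continue
        i, j = ij
        if any((i + di, j + dj) in defect for di in (-1, 0, 1) for dj in (-1, 0, 1)):
            continue
        pool_pos.append(field.cell_position(ij))
    pool_pos.sort(key=lambda p: (p.x_deg, p.y_deg))
    return pool_pos


def build_trial_sequence(
    config: StudyConfig, field: VisualFieldMap, rng: Optional[np.random.Generator] = None
) -> list[PlannedTrial]:
    """Plan the full 150-trial run; deterministic for a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool_pos = _detectable_pool(field)
    n_needed = config.n_warmup + config.n_detectable + config.n_buffer
    if len(pool_pos) < max(1, min(1, n_needed)):
        raise ValueError("field has no unambiguous intact cells for detectable stimuli")
    bs_sites = blind_spot_stimulus_sites(
        field, config.n_blindspot, mode=config.blindspot_site_mode, rng=rng
    ) if config.n_blindspot else []

    def draw_detectable(n: int) -> list[AngularPosition]:
        idx = rng.integers(0, len(pool_pos), size=n)
        return [pool_pos[int(i)] for i in idx]

    warmup = [PlannedTrial("warmup", "detectable", p) for p in draw_detectable(config.n_warmup)]
    scored = [PlannedTrial("scored", "blindspot", p) for p in bs_sites] + [
        PlannedTrial("scored", "detectable", p) for p in draw_detectable(config.n_detectable)
    ]
    scored = [scored[int(i)] for i in rng.permutation(len(scored))]
    buffer_ = [PlannedTrial("buffer", "detectable", p) for p in draw_detectable(config.n_buffer)]
    return warmup + scored + buffer_


def _classify(block: str, category: str, clicked: bool) -> str:
    if block != "scored":
        return "excluded"
    if category == "blindspot":
        return "FP" if clicked else "TN"
    return "TP" if clicked else "FN"


def run_study(
    config: StudyConfig, field: VisualFieldMap, responder
) -> tuple[list[TrialRecord], ConfusionMatrix]:
    """Run one subject through the protocol and score the confusion matrix."""
    rng = np.random.default_rng(config.seed)
    sequence = build_trial_sequence(config, field, rng=rng)
    records: list[TrialRecord] = []
    counts = {"TN": 0, "FP": 0, "FN": 0, "TP": 0}
    onset = 0.0
    for i, trial in enumerate(sequence):
        clicked = bool(
            responder(trial.position, category=trial.category, size_deg=config.stimulus_size_deg)
        )
        cls = _classify(trial.block, trial.category, clicked)
        if cls in counts:
            counts[cls] += 1
        records.append(
            TrialRecord(
                index=i,
                block=trial.block,  # type: ignore[arg-type]
                category=trial.category,  # type: ignore[arg-type]
                position=trial.position,
                clicked=clicked,
                classification=cls,  # type: ignore[arg-type]
                onset_ms=onset,
            )
        )
        onset += (
            config.display_ms
            + config.response_window_ms
            + float(rng.uniform(0.0, config.break_max_ms))
        )
    matrix = ConfusionMatrix(tn=counts["TN"], fp=counts["FP"], fn=counts["FN"], tp=counts["TP"])
    return records, matrix


@dataclass
class CohortResult:
    matrices: list[ConfusionMatrix]
    records: list[list[TrialRecord]]
    pooled: Optional[ConfusionMatrix]
    summary: object  # pandas DataFrame of per-metric mean/SD, None when empty

    @property
    def pooled_accuracy(self) -> float:
        if self.pooled is None:
            raise ValueError("empty cohort has no pooled accuracy")
        return accuracy(self.pooled)


def run_cohort(
    configs: Sequence[StudyConfig],
    fields: Sequence[VisualFieldMap],
    responders: Sequence,
) -> CohortResult:
    """Run each (config, field, responder) triple and aggregate."""
    if not (len(configs) == len(fields) == len(responders)):
        raise ValueError("configs, fields and responders must have equal lengths")
    matrices: list[ConfusionMatrix] = []
    all_records: list[list[TrialRecord]] = []
    for cfg, fld, resp in zip(configs, fields, responders):
        recs, m = run_study(cfg, fld, resp)
        matrices.append(m)
        all_records.append(recs)
    if not matrices:
        return CohortResult(matrices=[], records=[], pooled=None, summary=None)
    return CohortResult(
        matrices=matrices,
        records=all_records,
        pooled=pool(matrices),
        summary=cohort_summary(matrices),
    )


def write_subject_results(
    records: Sequence[TrialRecord],
    matrix: ConfusionMatrix,
    csv_path: str | Path,
    summary_path: str | Path,
) -> None:
    """Persist one subject's trial records (CSV) and metric summary (JSON)."""
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "block", "category", "x_deg", "y_deg", "clicked",
                    "classification", "onset_ms"])
        for r in records:
            w.writerow([r.index, r.block, r.category, r.position.x_deg, r.position.y_deg,
                        int(r.clicked), r.classification, f"{r.onset_ms:.1f}"])
    report = MetricsReport.from_matrix(matrix)
    payload = {"tn": matrix.tn, "fp": matrix.fp, "fn": matrix.fn, "tp": matrix.tp}
    payload.update(report.rounded())
    with open(summary_path, "w") as fh:
        json.dump(payload, fh, indent=2)
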