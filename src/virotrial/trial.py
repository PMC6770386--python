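"""Ring-trial orchestration: blinding, collection, batch scoring.

A trial run takes a set of datasets (real or in-silico), relabels them
with a random permutation of 1..N so participants cannot tell what they
received, keeps the label -> dataset answer key in a separate file, and
later scores the returned per-sample virus metrics files cell by cell
(pipeline x sample x database). Missing cells stay missing — they are
flagged, never zero-filled, because an absent submission is not a score
of zero.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .score import (
    AccessionResolver,
    ExpectedVirusPattern,
    SampleScore,
    VirusMetricsRow,
    score_sample,
)

__all__ = [
    "DatasetEntry",
    "TrialPlan",
    "TrialReport",
    "NameCheck",
    "DatabaseComparison",
    "assign_labels",
    "validate_submission_names",
    "score_trial",
    "compare_databases",
    "sample_filename",
]


class DatasetEntry(NamedTuple):
    name: str
    label: int
    settings: str = ""  # canonical token, e.g. "2x150"; "" when fixed
    truth_ref: str = ""  # pointer to the manifest / expected-set for scoring


@dataclass(frozen=True)
class TrialPlan:
    """Blinded sample plan for one increment.

    Labels are a permutation of 1..N; the name -> label mapping is the
    answer key and must never reach participants. Label spaces are
    per-increment, so the same label can recur across increments.
    """

    increment: int
    datasets: tuple[DatasetEntry, ...]
    pipelines: tuple[str, ...] = ()
    label_seed: int = 0

    def __post_init__(self) -> None:
        labels = sorted(d.label for d in self.datasets)
        if labels != list(range(1, len(self.datasets) + 1)):
            raise ValueError("blinded labels must be a permutation of 1..N")
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValueError("dataset names must be unique")

    @property
    def labels(self) -> list[int]:
        return sorted(d.label for d in self.datasets)

    def answer_key(self) -> dict[int, str]:
        return {d.label: d.name for d in self.datasets}

    def participant_manifest(self) -> dict:
        """What participants may see: labels and settings, no names."""
        return {
            "increment": self.increment,
            "samples": [
                {"label": d.label, "settings": d.settings or "as distributed"}
                for d in sorted(self.datasets, key=lambda d: d.label)
            ],
        }

    def write_participant_manifest(self, path: str | Path) -> str:
        text = json.dumps(self.participant_manifest(), indent=2)
        Path(path).write_text(text)
        return hashlib.sha256(text.encode()).hexdigest()

    def write_answer_key(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        """Write the label -> dataset key, kept apart from the bundle.

        If the participant manifest was written first, its checksum is
        embedded so key and bundle can be matched unambiguously later.
        """
        checksum = None
        if manifest_path is not None and Path(manifest_path).exists():
            checksum = hashlib.sha256(Path(manifest_path).read_bytes()).hexdigest()
        data = {
            "increment": self.increment,
            "label_seed": self.label_seed,
            "key": {str(d.label): {"name": d.name, "truth_ref": d.truth_ref} for d in self.datasets},
            "participant_manifest_sha256": checksum,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    def to_json(self, path: str | Path) -> None:
        data = {
            "increment": self.increment,
            "label_seed": self.label_seed,
            "pipelines": list(self.pipelines),
            "datasets": [d._asdict() for d in self.datasets],
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialPlan":
        data = json.loads(Path(path).read_text())
        return cls(
            increment=data["increment"],
            datasets=tuple(DatasetEntry(**d) for d in data["datasets"]),
            pipelines=tuple(data.get("pipelines", ())),
            label_seed=data.get("label_seed", 0),
        )


def assign_labels(
    datasets: Sequence[str | tuple],
    seed: int,
    increment: int = 2,
    pipelines: Sequence[str] = (),
) -> TrialPlan:
    """Relabel datasets with a seeded uniform random permutation of 1..N.

    ``datasets`` is a list of names or (name, settings, truth_ref)
    tuples. The same seed always yields the same permutation.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    rng = np.random.default_rng(seed)
    labels = rng.permutation(len(datasets)) + 1
    entries = []
    for item, label in zip(datasets, labels):
        if isinstance(item, str):
            entries.append(DatasetEntry(name=item, label=int(label)))
        else:
            name, settings, truth = (list(item) + ["", ""])[:3]
            entries.append(
                DatasetEntry(name=name, label=int(label), settings=settings, truth_ref=truth)
            )
    return TrialPlan(
        increment=increment,
        datasets=tuple(entries),
        pipelines=tuple(pipelines),
        label_seed=seed,
    )


# --- submission file names ----------------------------------------------

#: (pipeline letter)(sample number)[_settings].ext; the settings token
#: tolerates "2x100", "2 × 100" and "2X100"
_NAME_RE = re.compile(
    r"^([A-Z])(\d+)(?:_(\d\s*[x×X]\s*\d+))?\.(\w+)$"
)


def sample_filename(pipeline: str, sample: int, settings: str = "", ext: str = "csv") -> str:
    """Canonical submission file name, e.g. ``B4_2x100.csv``."""
    from .simulate import ReadSettings

    token = f"_{ReadSettings.from_token(settings).token}" if settings else ""
    return f"{pipeline}{sample}{token}.{ext}"


class NameCheck(NamedTuple):
    filename: str
    pipeline: str | None
    sample: int | None
    settings: str | None
    problems: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_submission_names(
    files: Sequence[str], plan: TrialPlan
) -> list[NameCheck]:
    """Check submitted file names against the naming convention.

    Parses the pipeline letter, sample number and optional settings
    suffix; malformed names, unknown pipeline letters and labels outside
    the plan are listed as problems, never fatal.
    """
    from .simulate import ReadSettings

    known_labels = set(plan.labels)
    checks: list[NameCheck] = []
    for fname in files:
        m = _NAME_RE.match(Path(fname).name)
        if not m:
            checks.append(
                NameCheck(fname, None, None, None, ("malformed file name",))
            )
            continue
        letter, number, settings_raw, _ext = m.groups()
        problems: list[str] = []
        sample = int(number)
        token = None
        if settings_raw:
            token = ReadSettings.from_token(settings_raw).token
        if plan.pipelines and letter not in plan.pipelines:
            problems.append(f"unknown pipeline letter {letter!r}")
        if sample not in known_labels:
            problems.append(f"sample number {sample} not in the plan")
        checks.append(NameCheck(fname, letter, sample, token, tuple(problems)))
    return checks


# --- batch scoring -------------------------------------------------------


class Cell(NamedTuple):
    pipeline: str
    label: int
    database: str  # "common" or "in-house"


@dataclass(frozen=True)
class TrialReport:
    """All scored cells of a trial plus bookkeeping of the gaps."""

    plan: TrialPlan
    scores: Mapping[Cell, SampleScore]
    missing: tuple[Cell, ...] = ()
    skipped: tuple[str, ...] = ()  # submissions referencing unknown labels

    def table(self) -> pd.DataFrame:
        """Long-format results, one row per scored cell.

        Undefined metrics are NaN in the frame (null in CSV), never 0.
        """
        rows = []
        for cell, s in self.scores.items():
            rows.append(
                {
                    "pipeline": cell.pipeline,
                    "sample": cell.label,
                    "database": cell.database,
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "sensitivity": s.sensitivity,
                    "precision": s.precision,
                    "f1": s.f1,
                    "harmonic_mean_depth": s.harmonic_mean_depth,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "pipeline", "sample", "database", "tp", "fp", "fn",
                "sensitivity", "precision", "f1", "harmonic_mean_depth",
            ],
        ).sort_values(["pipeline", "sample", "database"], ignore_index=True)

    def negative_sample_summary(self, label: int) -> dict[str, dict[str, int]]:
        """FP family counts per (pipeline, database) for one sample."""
        out: dict[str, dict[str, int]] = {}
        for cell, s in self.scores.items():
            if cell.label == label:
                out[f"{cell.pipeline}/{cell.database}"] = dict(s.fp_families)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.table().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        data = {
            "increment": self.plan.increment,
            "cells": [
                {"pipeline": c.pipeline, "sample": c.label, "database": c.database,
                 **s.to_dict()}
                for c, s in self.scores.items()
            ],
            "missing": [c._asdict() for c in self.missing],
            "skipped": list(self.skipped),
        }
        Path(path).write_text(json.dumps(data, indent=2))


def score_trial(
    plan: TrialPlan,
    submissions: Mapping[tuple, Sequence[VirusMetricsRow]],
    expected: Mapping[int, Sequence[ExpectedVirusPattern]],
    resolver: AccessionResolver,
    average_read_length: float | Mapping[int, float] = 150.0,
) -> TrialReport:
    """Score every submitted (pipeline, sample, database) cell.

    ``submissions`` maps (pipeline, label, database) to parsed metrics
    rows; ``expected`` maps each label to its expected-positive pattern
    set (an empty sequence marks a negative sample).
    ``average_read_length`` may vary per label when samples were
    distributed at different settings. Cells present in the plan but not
    submitted are reported as missing; submissions for labels outside
    the plan are skipped and flagged.
    """
    known = set(plan.labels)
    scores: dict[Cell, SampleScore] = {}
    skipped: list[str] = []
    databases: set[str] = set()
    for key, rows in submissions.items():
        cell = Cell(*key)
        if cell.label not in known:
            skipped.append(f"{cell.pipeline}{cell.label}/{cell.database}: unknown label")
            continue
        arl = (
            average_read_length.get(cell.label, 150.0)
            if isinstance(average_read_length, Mapping)
            else average_read_length
        )
        scores[cell] = score_sample(
            rows, list(expected.get(cell.label, ())), resolver, average_read_length=arl
        )
        databases.add(cell.database)
    missing = [
        Cell(p, lab, db)
        for p in plan.pipelines
        for lab in plan.labels
        for db in sorted(databases)
        if Cell(p, lab, db) not in scores
    ]
    return TrialReport(
        plan=plan, scores=scores, missing=tuple(missing), skipped=tuple(skipped)
    )


# --- database comparison -------------------------------------------------


@dataclass(frozen=True)
class DatabaseComparison:
    """Common-vs-in-house performance for one pipeline.

    ``paired`` has one row per sample scored under both databases. The
    rank-sum comparison is a reporting convenience over the two F1
    vectors; with fewer than two paired samples it is not attempted.
    """

    pipeline: str
    paired: pd.DataFrame
    u_statistic: float | None
    p_value: float | None
    insufficient_data: bool = False


def compare_databases(
    report: TrialReport,
    pipeline: str,
    database_a: str = "common",
    database_b: str = "in-house",
) -> DatabaseComparison:
    """Paired per-sample F1 under two databases plus a rank-sum test.

    Uses the two-sided Mann-Whitney U test on the per-sample F1 vectors
    (samples with an undefined F1 under either database are excluded
    from the test but kept in the paired table).
    """
    from scipy.stats import mannwhitneyu

    cells_a = {c.label: s for c, s in report.scores.items()
               if c.pipeline == pipeline and c.database == database_a}
    cells_b = {c.label: s for c, s in report.scores.items()
               if c.pipeline == pipeline and c.database == database_b}
    common_labels = sorted(set(cells_a) & set(cells_b))
    paired = pd.DataFrame(
        {
            "sample": common_labels,
            f"f1_{database_a}": [cells_a[l].f1 for l in common_labels],
            f"f1_{database_b}": [cells_b[l].f1 for l in common_labels],
        }
    )
    x = [cells_a[l].f1 for l in common_labels if cells_a[l].f1 is not None and cells_b[l].f1 is not None]
    y = [cells_b[l].f1 for l in common_labels if cells_a[l].f1 is not None and cells_b[l].f1 is not None]
    if len(x) < 2:
        return DatabaseComparison(pipeline, paired, None, None, insufficient_data=True)
    if len(set(x) | set(y)) == 1:
        # fully tied vectors: U sits at its tie value by convention
        return DatabaseComparison(pipeline, paired, len(x) * len(y) / 2, 1.0)
    res = mannwhitneyu(x, y, alternative="two-sided")
    return DatabaseComparison(pipeline, paired, float(res.statistic), float(res.pvalue))
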