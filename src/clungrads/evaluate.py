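"""End-to-end evaluation: stratify a labelled cohort under one or more rule
systems, compute the confusion-matrix panel and ordinal AUC per system,
compare systems pairwise with the DeLong test, and write CSV/JSON/Markdown
reports. Also reads rater-by-nodule category tables for ICC agreement.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ContractError, DegenerateInputError, SchemaError, ValidationError
from .metrics import (
    AucResult,
    ConfusionMatrix,
    DeLongResult,
    MetricPanel,
    confusion_matrix,
    delong_paired_test,
    icc_absolute_agreement,
    ordinal_auc,
    panel_from_cm,
    pct,
)
from .nodules import Cohort, read_cohort
from .stratify import SystemId, stratify_cohort

__all__ = [
    "SystemEvaluation",
    "EvaluationReport",
    "evaluate_system",
    "run_evaluation",
    "compare_models",
    "rate_agreement",
    "read_ratings",
]


@dataclass(frozen=True)
class SystemEvaluation:
    system: SystemId
    cm: ConfusionMatrix
    panel: MetricPanel
    auc: AucResult | None  # None when pathology is single-class

    def row(self) -> dict:
        """Flat report row; percentages at one decimal, AUC on [0, 1]."""
        r = {"system": str(self.system), **self.cm.as_dict()}
        r.update(
            recall_pct=pct(self.panel.recall),
            precision_pct=pct(self.panel.precision),
            mcc_pct=pct(self.panel.mcc),
            f1_pct=pct(self.panel.f1),
            f_weighted_pct=pct(self.panel.f_weighted),
            accuracy_pct=pct(self.panel.accuracy),
            auc=None if self.auc is None else round(self.auc.auc, 4),
            auc_ci_low=None if self.auc is None else round(self.auc.ci_low, 4),
            auc_ci_high=None if self.auc is None else round(self.auc.ci_high, 4),
        )
        return r


@dataclass
class EvaluationReport:
    label: str
    n_nodules: int
    beta: float
    systems: list[SystemEvaluation]
    pairwise: dict[tuple[str, str], DeLongResult] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.row() for s in self.systems])

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "n_nodules": self.n_nodules,
            "beta": self.beta,
            "systems": [s.row() for s in self.systems],
            "pairwise_delong": [
                {
                    "system_a": a,
                    "system_b": b,
                    "auc_a": r.auc_a,
                    "auc_b": r.auc_b,
                    "difference": r.difference,
                    "z": r.z,
                    "p_two_sided": r.p_two_sided,
                }
                for (a, b), r in self.pairwise.items()
            ],
            "metadata": self.metadata,
        }

    def to_markdown(self) -> str:
        """Side-by-side table, metrics as rows and systems as columns."""
        rows = [
            ("TP", "tp"), ("FP", "fp"), ("FN", "fn"), ("TN", "tn"),
            ("Recall, %", "recall_pct"), ("Precision, %", "precision_pct"),
            ("MCC, %", "mcc_pct"), ("F1 score, %", "f1_pct"),
            ("F-weighted, %", "f_weighted_pct"), ("Accuracy, %", "accuracy_pct"),
            ("AUC", "auc"),
        ]
        cols = [s.row() for s in self.systems]
        header = "| Metric | " + " | ".join(c["system"] for c in cols) + " |"
        sep = "|---" * (len(cols) + 1) + "|"
        lines = [f"# Evaluation report: {self.label}", "", header, sep]
        for title, key in rows:
            cells = " | ".join(
                "-" if c[key] is None else str(c[key]) for c in cols
            )
            lines.append(f"| {title} | {cells} |")
        if self.pairwise:
            lines += ["", "## Pairwise DeLong tests", ""]
            for (a, b), r in self.pairwise.items():
                lines.append(
                    f"- {a} vs {b}: AUC {r.auc_a:.3f} vs {r.auc_b:.3f}, "
                    f"diff {r.difference:+.3f}, z = {r.z:.3f}, "
                    f"p = {r.p_two_sided:.4g}"
                )
        lines += ["", f"_metadata: {json.dumps(self.metadata, sort_keys=True)}_", ""]
        return "\n".join(lines)

    def write(self, output: str | Path, format: str = "json") -> None:
        output = Path(output)
        if format == "csv":
            self.frame().to_csv(output, index=False)
        elif format == "json":
            output.write_text(
                json.dumps(self.to_json_dict(), indent=1), encoding="utf-8"
            )
        elif format == "md":
            output.write_text(self.to_markdown(), encoding="utf-8")
        else:
            raise ValueError(f"unknown report format {format!r}")


def _labels_and_scores(cohort: Cohort, system: SystemId):
    unlabeled = [n.nodule_id for n in cohort.nodules if n.pathology is None]
    if unlabeled:
        raise ValidationError(
            f"nodules without pathology labels: {', '.join(unlabeled[:10])}"
            + ("..." if len(unlabeled) > 10 else "")
        )
    stratified = stratify_cohort(cohort, system)
    labels = np.array([n.invasive for n in cohort.nodules], dtype=bool)
    ranks = np.array([s.category.ordinal_rank for s in stratified], dtype=float)
    positives = np.array([s.positive for s in stratified], dtype=bool)
    return stratified, labels, ranks, positives


def evaluate_system(
    cohort: Cohort, system: SystemId, beta: float = 0.5
) -> SystemEvaluation:
    """Confusion panel and ordinal-rank AUC of one rule system on a cohort."""
    _, labels, ranks, positives = _labels_and_scores(cohort, system)
    cm = confusion_matrix(positives, labels)
    panel = panel_from_cm(cm, beta=beta)
    try:
        auc = ordinal_auc(ranks, labels)
    except DegenerateInputError:
        warnings.warn(
            f"{system}: pathology labels are single-class; AUC omitted",
            stacklevel=2,
        )
        auc = None
    return SystemEvaluation(system=system, cm=cm, panel=panel, auc=auc)


def _cohort_digest(cohort: Cohort) -> str:
    h = hashlib.sha256()
    for n in cohort.nodules:
        h.update(
            f"{n.nodule_id}|{n.mean_diameter_mm!r}|{n.gvr}|"
            f"{n.suspicious_features}|{n.pathology}\n".encode()
        )
    return h.hexdigest()[:16]


def run_evaluation(
    cohort: Cohort | str | Path,
    systems: Sequence[SystemId] | None = None,
    beta: float = 0.5,
    output: str | Path | None = None,
    format: str = "json",
    seed: int | None = None,
) -> EvaluationReport:
    """Evaluate a labelled cohort under the requested systems and optionally
    write the report. Pairwise DeLong comparisons are included whenever two
    or more systems are evaluated and the AUC is defined."""
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    if systems is None:
        systems = list(SystemId)
    systems = [SystemId.parse(s) for s in systems]
    if not systems:
        raise ContractError("no systems requested")
    if len(set(systems)) != len(systems):
        raise ContractError("duplicate systems requested")

    evaluations = [evaluate_system(cohort, s, beta=beta) for s in systems]
    pairwise: dict[tuple[str, str], DeLongResult] = {}
    if all(e.auc is not None for e in evaluations):
        for i in range(len(systems)):
            for j in range(i + 1, len(systems)):
                pairwise[(str(systems[i]), str(systems[j]))] = compare_models(
                    cohort, systems[i], systems[j]
                )

    report = EvaluationReport(
        label=cohort.label,
        n_nodules=len(cohort),
        beta=beta,
        systems=evaluations,
        pairwise=pairwise,
        metadata={
            "tool": "clungrads",
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(
                timespec="seconds"
            ),
            "cohort_digest": _cohort_digest(cohort),
            "seed": seed,
            "beta": beta,
        },
    )
    if output is not None:
        report.write(output, format=format)
    return report


def compare_models(
    cohort: Cohort | str | Path, system_a: SystemId, system_b: SystemId
) -> DeLongResult:
    """Paired DeLong test between two systems' ordinal category ranks."""
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    system_a = SystemId.parse(system_a)
    system_b = SystemId.parse(system_b)
    _, labels, ranks_a, _ = _labels_and_scores(cohort, system_a)
    _, _, ranks_b, _ = _labels_and_scores(cohort, system_b)
    return delong_paired_test(ranks_a, ranks_b, labels)


def read_ratings(source: str | Path) -> pd.DataFrame:
    """Read a long-format ratings CSV (subject_id, rater_id, category) into
    a complete subjects x raters matrix of ordinal ranks."""
    from .nodules import Category

    df = pd.read_csv(source, dtype=str)
    missing = [c for c in ("subject_id", "rater_id", "category") if c not in df.columns]
    if missing:
        raise SchemaError(
            f"ratings table is missing column(s): {', '.join(missing)}",
            missing=missing,
        )
    df = df.assign(rank=[Category.parse(c).ordinal_rank for c in df["category"]])
    wide = df.pivot_table(
        index="subject_id", columns="rater_id", values="rank", aggfunc="first"
    )
    if wide.shape[1] < 2:
        raise ContractError(
            f"need ratings from >=2 raters, found {wide.shape[1]}"
        )
    if wide.isna().any().any():
        holes = [
            f"({subj}, {rater})"
            for subj, row in wide.iterrows()
            for rater, v in row.items()
            if pd.isna(v)
        ]
        raise ContractError(
            "incomplete ratings design; missing pairs: " + ", ".join(holes[:20])
        )
    return wide


def rate_agreement(ratings: str | Path | pd.DataFrame | np.ndarray) -> float:
    """ICC(2,1) of a ratings table (path to long CSV, or a wide matrix)."""
    if isinstance(ratings, (str, Path)):
        ratings = read_ratings(ratings)
    if isinstance(ratings, pd.DataFrame):
        ratings = ratings.to_numpy(dtype=float)
    return icc_absolute_agreement(ratings)


def agreement_band(icc: float) -> str:
    """Conventional qualitative interpretation of an ICC value."""
    if icc >= 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"
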