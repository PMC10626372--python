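"""Cohort workflows: biomarker extraction, group comparison and genotyping.

Two workflows are orchestrated here.  ``run_cohort`` chains compartment
segmentation and biomarker computation over a cohort manifest into a tidy
per-subject table.  ``GenotypingModel`` is the diagnostic model of the
analysis: a biomarker score classifying a binary molecular label, fitted by
DeLong ROC analysis with a stratified train/evaluation split whose training
side fixes the Youden-optimal threshold that is then evaluated frozen on the
held-out side.  ``reproduce_study`` runs the full synthetic study: calibrated
phantom cohort -> rendered images -> compartments -> biomarkers -> statistics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import lesion_record
from .compartments import background_roi, extract_compartments
from .phantom import CohortParams, render_phantom, sample_cohort
from .stats import RocResult, TestResult, mann_whitney_u, roc_delong, youden_optimal
from .volumes import CohortManifest, read_mask, read_volume

__all__ = [
    "SplitPlan",
    "StudyReport",
    "GenotypingModel",
    "GenotypingResults",
    "run_cohort",
    "group_compare",
    "genotyping_experiment",
    "reproduce_study",
    "REFERENCE_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: thresholds reported by the reference clinical study, for comparison
#: plots and annotations only — never used as decision defaults.
REFERENCE_THRESHOLDS = {
    "cu_volumetric_whole_cohort": 5.49,
    "cu_volumetric_training": 5.43,
    "tbr_mean": 2.73,
}

#: biomarker columns evaluated in the synthetic reproduction study
_STUDY_BIOMARKERS = ("cu_volumetric", "cu_suv", "tbr_mean")


@dataclass
class SplitPlan:
    """A stratified train/evaluation split of labelled subjects."""

    train_ids: list
    eval_ids: list
    stratify_on: str
    seed: int
    class_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.eval_ids):
            raise ValueError("train and evaluation sets overlap")


def _attach_absolute_mtv(volume, compartments, background_mean: float, k: float = 1.8) -> None:
    """Fill in the absolute-threshold MTV once the background mean is known.

    Thresholds at k*background within the isocontour search region (not
    within MTV60, which would wrongly clip MTV whenever k*background is below
    0.6*SUVmax)."""
    from .compartments import absolute_mtv

    compartments.mtv_abs = absolute_mtv(
        volume, compartments.search, background_mean, k
    )
    compartments.thresholds_used["mtv_abs"] = (k * background_mean, float("inf"))


def run_cohort(
    manifest: CohortManifest,
    config: Optional[dict] = None,
    max_failure_fraction: float = 0.10,
) -> tuple[pd.DataFrame, list[dict]]:
    """Extract one biomarker record per manifest subject.

    Per-subject failures are quarantined with their reason instead of being
    silently dropped; more than ``max_failure_fraction`` failures aborts.
    Returns (records table, quarantine list).
    """
    config = config or {}
    rows: list[dict] = []
    quarantined: list[dict] = []
    for row in manifest.iter_subjects():
        subject = row["subject_id"]
        try:
            volume = read_volume(manifest.resolve(row["image_path"]))
            lesion = read_mask(manifest.resolve(row["lesion_mask_path"]), "lesion")
            exclusion = None
            if manifest.resolve(row.get("exclusion_mask_path")) is not None:
                exclusion = read_mask(
                    manifest.resolve(row["exclusion_mask_path"]), "exclusion"
                )
            compartments = extract_compartments(
                volume,
                lesion,
                exclusion,
                dilate_voxels=config.get("dilate_voxels", 2),
                robust_peak=config.get("robust_peak", False),
                suvmax_before_exclusion=config.get("suvmax_before_exclusion", False),
            )
            bg = background_roi(volume, lesion, compartments.mtv60)
            _attach_absolute_mtv(
                volume, compartments, bg.mean_suv, config.get("k_background", 1.8)
            )
            ce = t2 = None
            if manifest.resolve(row.get("ce_mask_path")) is not None:
                ce = read_mask(manifest.resolve(row["ce_mask_path"]), "contrast_enhancing")
            if manifest.resolve(row.get("t2_mask_path")) is not None:
                t2 = read_mask(manifest.resolve(row["t2_mask_path"]), "t2")
            labels = {
                m: row[m] for m in ("IDH", "MGMT", "ATRX", "LOH1p19q") if m in row
            }
            record = lesion_record(
                volume, compartments, bg, subject, ce, t2, labels
            )
            logger.info(
                "subject %s: suv_max=%.3f cu_volumetric=%.3f",
                subject, record.suv_max, record.cu_volumetric,
            )
            rows.append(record.to_dict())
        except Exception as exc:
            logger.warning("subject %s quarantined: %s", subject, exc)
            quarantined.append({"subject_id": subject, "reason": str(exc)})
    n_total = len(manifest)
    if len(quarantined) > max_failure_fraction * n_total:
        summary = "; ".join(f"{q['subject_id']}: {q['reason']}" for q in quarantined)
        raise RuntimeError(
            f"{len(quarantined)}/{n_total} subjects failed biomarker extraction: "
            f"{summary}"
        )
    return pd.DataFrame(rows), quarantined


def _median_iqr(values: np.ndarray) -> dict:
    # linear-interpolation (type-7) quantiles throughout
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1), "n": int(len(values))}


def group_compare(
    cohort: pd.DataFrame, biomarker: str, label: str = "IDH"
) -> tuple[TestResult, dict]:
    """Two-tailed Mann-Whitney comparison of a biomarker between the two
    labelled groups, with median/IQR summaries per group."""
    if biomarker not in cohort.columns:
        raise KeyError(f"biomarker column {biomarker!r} not in cohort table")
    sub = cohort[cohort[label].isin(["positive", "negative"])]
    pos = sub.loc[sub[label] == "positive", biomarker].to_numpy(float)
    neg = sub.loc[sub[label] == "negative", biomarker].to_numpy(float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(f"need at least 2 subjects per {label} class")
    test = mann_whitney_u(pos, neg, tails="two")
    summaries = {
        "positive": _median_iqr(pos),
        "negative": _median_iqr(neg),
    }
    return test, summaries


def _stratified_split(
    ids: np.ndarray,
    labels: np.ndarray,
    n_train: int,
    seed: int,
    stratify_on: str,
    max_retries: int = 20,
) -> SplitPlan:
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        train_idx: list[int] = []
        for cls in np.unique(labels):
            cls_idx = np.flatnonzero(labels == cls)
            n_cls = int(round(n_train * len(cls_idx) / len(ids)))
            n_cls = min(max(n_cls, 1), len(cls_idx) - 1)
            train_idx.extend(rng.choice(cls_idx, size=n_cls, replace=False))
        train_mask = np.zeros(len(ids), dtype=bool)
        train_mask[train_idx] = True
        train_lab, eval_lab = labels[train_mask], labels[~train_mask]
        if len(np.unique(train_lab)) == 2 and len(np.unique(eval_lab)) == 2:
            counts = {
                "train": {str(c): int((train_lab == c).sum()) for c in np.unique(labels)},
                "eval": {str(c): int((eval_lab == c).sum()) for c in np.unique(labels)},
            }
            return SplitPlan(
                train_ids=list(ids[train_mask]),
                eval_ids=list(ids[~train_mask]),
                stratify_on=stratify_on,
                seed=seed + attempt,
                class_counts=counts,
            )
    raise RuntimeError("could not produce a non-degenerate stratified split")


@dataclass
class GenotypingResults:
    """Fitted genotyping experiment: whole-cohort ROC, training threshold and
    frozen-threshold evaluation."""

    model: "GenotypingModel"
    split: SplitPlan
    roc_whole: RocResult
    roc_train: RocResult
    roc_eval: RocResult
    threshold: float
    eval_sensitivity: float
    eval_specificity: float
    eval_accuracy: float

    def summary(self) -> str:
        m = self.model
        lines = [
            "Genotyping experiment".center(62),
            "=" * 62,
            f"Biomarker: {m.biomarker:<24} Label: {m.label}",
            f"Subjects:  {len(m.scores):<24} Split: "
            f"{len(self.split.train_ids)}/{len(self.split.eval_ids)} "
            f"(seed {self.split.seed})",
            "-" * 62,
            f"Whole-cohort AUC {self.roc_whole.auc:.2f} +/- {self.roc_whole.se_auc:.2f}"
            f"  95% CI ({self.roc_whole.ci95[0]:.2f}, {self.roc_whole.ci95[1]:.2f})"
            f"  P = {self.roc_whole.p_value:.2g}",
            f"Training AUC     {self.roc_train.auc:.2f} +/- {self.roc_train.se_auc:.2f}"
            f"  threshold ({self.roc_train.direction}) {self.threshold:.2f}",
            f"Evaluation AUC   {self.roc_eval.auc:.2f} +/- {self.roc_eval.se_auc:.2f}",
            f"Frozen-threshold evaluation: sensitivity {self.eval_sensitivity:.0%}, "
            f"specificity {self.eval_specificity:.0%}, accuracy {self.eval_accuracy:.0%}",
            "=" * 62,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "biomarker": self.model.biomarker,
            "label": self.model.label,
            "split": {
                "train_ids": [str(i) for i in self.split.train_ids],
                "eval_ids": [str(i) for i in self.split.eval_ids],
                "seed": self.split.seed,
                "class_counts": self.split.class_counts,
            },
            "roc_whole": asdict(self.roc_whole),
            "roc_train": asdict(self.roc_train),
            "roc_eval": asdict(self.roc_eval),
            "threshold": self.threshold,
            "eval_sensitivity": self.eval_sensitivity,
            "eval_specificity": self.eval_specificity,
            "eval_accuracy": self.eval_accuracy,
        }

    def plot_roc(self, ax=None):
        """Empirical ROC curve of the whole cohort with the fitted cutpoint."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scores, y = self.model.scores, self.model.positive
        s = scores if self.roc_whole.direction == "greater" else -scores
        order = np.argsort(-s, kind="stable")
        tps = np.concatenate([[0], np.cumsum(y[order])]) / max(y.sum(), 1)
        fps = np.concatenate([[0], np.cumsum(~y[order])]) / max((~y).sum(), 1)
        ax.plot(fps, tps, drawstyle="steps-post", label=(
            f"{self.model.biomarker} (AUC {self.roc_whole.auc:.2f})"))
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax


class GenotypingModel:
    """Diagnostic model: a scalar biomarker classifying a binary genotype.

    Mirrors the usual modelling-object idiom: construct from arrays or with
    :meth:`from_dataframe`, then :meth:`fit` performs the ROC analysis and
    the split/threshold experiment, returning a :class:`GenotypingResults`.
    """

    def __init__(self, scores, labels, biomarker: str = "score", label: str = "label"):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        if scores.shape != labels.shape:
            raise ValueError("scores and labels must align")
        self.scores = scores
        self.labels = labels
        self.positive = labels == "positive" if labels.dtype.kind in "OU" else labels.astype(bool)
        self.biomarker = biomarker
        self.label = label
        self.subject_ids = np.arange(len(scores))

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        biomarker: str = "cu_volumetric",
        label: str = "IDH",
    ) -> "GenotypingModel":
        sub = cohort[cohort[label].isin(["positive", "negative"])]
        model = cls(
            sub[biomarker].to_numpy(float),
            sub[label].to_numpy(),
            biomarker=biomarker,
            label=label,
        )
        if "subject_id" in sub.columns:
            model.subject_ids = sub["subject_id"].to_numpy()
        return model

    def fit(
        self,
        seed: int = 0,
        n_train: Optional[int] = None,
        train_class_counts: Optional[dict] = None,
    ) -> GenotypingResults:
        """Fit the genotyping experiment.

        A stratified random split (half/half by default) determines the
        model-building set; the Youden-optimal threshold fitted there is
        evaluated frozen on the held-out set.  ``train_class_counts`` (e.g.
        ``{"negative": 16, "positive": 10}``) overrides stratification with
        exact per-class training sizes.
        """
        y = self.positive
        labels = np.where(y, "positive", "negative")
        if train_class_counts is not None:
            rng = np.random.default_rng(seed)
            train_idx = []
            for cls, n_cls in train_class_counts.items():
                cls_idx = np.flatnonzero(labels == cls)
                if not 1 <= n_cls <= len(cls_idx) - 1:
                    raise ValueError(f"cannot take {n_cls} training subjects of class {cls}")
                train_idx.extend(rng.choice(cls_idx, size=n_cls, replace=False))
            train_mask = np.zeros(len(y), dtype=bool)
            train_mask[train_idx] = True
            split = SplitPlan(
                train_ids=list(self.subject_ids[train_mask]),
                eval_ids=list(self.subject_ids[~train_mask]),
                stratify_on=self.label,
                seed=seed,
                class_counts={"train": dict(train_class_counts)},
            )
        else:
            n_train = n_train or len(y) // 2
            split = _stratified_split(
                self.subject_ids, labels, n_train, seed, self.label
            )
            train_mask = np.isin(self.subject_ids, split.train_ids)

        roc_whole = roc_delong(self.scores, y)
        roc_train = roc_delong(self.scores[train_mask], y[train_mask])
        roc_eval = roc_delong(
            self.scores[~train_mask], y[~train_mask], direction=roc_train.direction
        )
        threshold = roc_train.threshold
        s_eval, y_eval = self.scores[~train_mask], y[~train_mask]
        pred = (
            s_eval >= threshold
            if roc_train.direction == "greater"
            else s_eval <= threshold
        )
        sens = float((pred & y_eval).sum() / y_eval.sum())
        spec = float((~pred & ~y_eval).sum() / (~y_eval).sum())
        acc = float((pred == y_eval).mean())
        return GenotypingResults(
            model=self,
            split=split,
            roc_whole=roc_whole,
            roc_train=roc_train,
            roc_eval=roc_eval,
            threshold=threshold,
            eval_sensitivity=sens,
            eval_specificity=spec,
            eval_accuracy=acc,
        )


def genotyping_experiment(
    cohort: pd.DataFrame,
    biomarker: str = "cu_volumetric",
    label: str = "IDH",
    seed: int = 0,
    train_class_counts: Optional[dict] = None,
) -> GenotypingResults:
    """Functional wrapper over :class:`GenotypingModel`."""
    return GenotypingModel.from_dataframe(cohort, biomarker, label).fit(
        seed=seed, train_class_counts=train_class_counts
    )


@dataclass
class StudyReport:
    """Full synthetic-study output with provenance."""

    group_summaries: dict
    group_tests: dict
    roc: dict
    genotyping: dict
    recovery: dict
    provenance: dict

    _REQUIRED = ("group_summaries", "group_tests", "roc", "genotyping",
                 "recovery", "provenance")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._REQUIRED}

    def validate(self) -> None:
        for key in self._REQUIRED:
            if not isinstance(getattr(self, key), dict):
                raise ValueError(f"report section {key} missing or malformed")
        for name in _STUDY_BIOMARKERS:
            if name not in self.group_summaries:
                raise ValueError(f"missing group summary for {name}")
            if name not in self.roc:
                raise ValueError(f"missing ROC result for {name}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def measure_cohort(
    params: CohortParams, keep_truth: bool = True
) -> pd.DataFrame:
    """Sample, render and measure a calibrated cohort entirely in memory.

    Every biomarker is measured from the rendered image through the full
    compartment pipeline, never copied from the sampled ground truth; the
    ground truth is carried alongside (``true_*`` columns) for bias analysis.
    """
    rows = []
    for subject in sample_cohort(params):
        volume, lesion, truth = render_phantom(subject.spec)
        compartments = extract_compartments(volume, lesion)
        bg = background_roi(volume, lesion, compartments.mtv60)
        _attach_absolute_mtv(volume, compartments, bg.mean_suv)
        record = lesion_record(
            volume,
            compartments,
            bg,
            subject.subject_id,
            labels={
                "IDH": "positive" if subject.genotype == "mutant" else "negative",
                "genotype": subject.genotype,
            },
        )
        row = record.to_dict()
        if keep_truth:
            row.update(
                true_cu_volumetric=truth.volumetric_cu_true,
                true_suv_cu=truth.suv_cu_true,
                true_v_central_cm3=truth.v_central,
                true_v_peripheral_cm3=truth.v_peripheral,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_study(
    config: Optional[dict] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> StudyReport:
    """End-to-end synthetic reproduction of the clinical analysis.

    Simulates the calibrated 21-vs-31 cohort as rendered images, measures all
    biomarkers through the image pipeline, compares groups, fits the
    genotyping model per biomarker and reports the voxelization bias of the
    measured CU ratio against each subject's analytic ground truth.
    """
    config = config or {}
    params = CohortParams(seed=seed, **config.get("cohort", {}))
    cohort = measure_cohort(params)
    group_summaries: dict = {}
    group_tests: dict = {}
    roc: dict = {}
    for name in _STUDY_BIOMARKERS:
        test, summaries = group_compare(cohort, name, "IDH")
        group_summaries[name] = summaries
        group_tests[name] = asdict(test)
        roc[name] = asdict(roc_delong(cohort[name], cohort["IDH"] == "positive"))
    genotyping = genotyping_experiment(
        cohort, "cu_volumetric", "IDH", seed=seed,
        train_class_counts=config.get("train_class_counts"),
    )
    ratio = cohort["cu_volumetric"] / cohort["true_cu_volumetric"]
    recovery = {
        "mean_measured_over_true_cu": float(ratio.mean()),
        "median_measured_over_true_cu": float(ratio.median()),
        "per_group_median_cu": {
            g: float(np.median(cohort.loc[cohort["genotype"] == g, "cu_volumetric"]))
            for g in ("mutant", "wildtype")
        },
        "per_group_median_v_roi60_cm3": {
            g: float(np.median(cohort.loc[cohort["genotype"] == g, "v_roi60_cm3"]))
            for g in ("mutant", "wildtype")
        },
    }
    report = StudyReport(
        group_summaries=group_summaries,
        group_tests=group_tests,
        roc=roc,
        genotyping=genotyping.to_dict(),
        recovery=recovery,
        provenance={
            "seed": seed,
            "software_version": __version__,
            "cohort_params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(params).items()
            },
            "reference_thresholds": REFERENCE_THRESHOLDS,
        },
    )
    report.validate()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        report.to_json(out_dir / "report.json")
        _write_roc_points(cohort, out_dir / "roc_points.csv")
    return report


def _write_roc_points(cohort: pd.DataFrame, path: Path) -> None:
    y = (cohort["IDH"] == "positive").to_numpy()
    s = cohort["cu_volumetric"].to_numpy(float)
    order = np.argsort(-s, kind="stable")
    tps = np.concatenate([[0], np.cumsum(y[order])]) / y.sum()
    fps = np.concatenate([[0], np.cumsum(~y[order])]) / (~y).sum()
    pd.DataFrame({"fpr": fps, "tpr": tps}).to_csv(path, index=False)
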