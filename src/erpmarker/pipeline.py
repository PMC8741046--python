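"""End-to-end study replica: simulate -> process -> features -> train/CV ->
evaluate, fully seeded and reproducible.

The established-patient group never enters training: its subjects are scored
through the final model's linear term only, for the severity (motor UPDRS)
correlation. Evaluation follows the study protocol: Mann-Whitney comparison
of pooled cross-validation scores, ROC with patients as the positive class
(classifier score = 1 - probability of healthy), Hanley-McNeil CI with the
patient count in the first term, the sensitivity-maximizing above-chance
cutoff, a within-control sex comparison and a gender-balanced ROC resampling
check, and Pearson correlations of the marker with motor UPDRS and with the
levodopa-equivalent daily dose.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import (FeatureConfig, SubjectDerived, assemble_feature_table,
                       build_group_templates, derive_subject, score_subject)
from .model import (cross_validate, feature_importance, linear_term,
                    train_final_model)
from .montage import build_montage
from .simulate import CohortDesign, iter_cohort
from .stats import gender_balanced_roc, mann_whitney, pearson_with_ci, roc_auc


@dataclass(frozen=True)
class PipelineConfig:
    """One validated bundle of every stage's parameters."""

    n_hc: int = 30
    n_espd: int = 19
    n_established: int = 20
    #: size of the separate healthy normative pool used to build the group
    #: templates. Scoring cohort subjects against templates built from the
    #: cohort's own controls biases the controls' match rates and similarity
    #: scores (they are inside the templates) and breaks the zero-effect
    #: null; a disjoint pool, as in normative-database practice, avoids that.
    #: `reference="hc"` restores the in-cohort variant.
    n_normative: int = 24
    reference: str = "normative"  # 'normative' | 'hc'
    seed: int = 0
    trial_scale: float = 1.0  # scales task trial counts (proportions kept)
    effect_scale: float = 1.0  # scales every group-effect delta (0 = null)
    noise_sd: float | None = None  # None -> design default
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection_alpha: float = 0.05
    cv_folds: int = 10
    ridge_c: float = 100.0
    gender_check: bool = True

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_espd, self.n_established) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_hc < 4 or self.n_espd < 2:
            raise ValueError("need at least 4 HC and 2 ESPD subjects")
        if self.reference not in ("normative", "hc"):
            raise ValueError("reference must be 'normative' or 'hc'")
        if self.reference == "normative" and self.n_normative < 4:
            raise ValueError("the normative pool needs at least 4 subjects")
        if not 0 < self.trial_scale <= 1:
            raise ValueError("trial_scale must be in (0, 1]")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be non-negative")
        if not 0 <= self.selection_alpha <= 1:
            raise ValueError("selection_alpha must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def design(self) -> CohortDesign:
        design = CohortDesign()
        if self.trial_scale != 1.0:
            design = design.scaled(self.trial_scale)
        if self.noise_sd is not None:
            design = dataclasses.replace(design, noise_sd=self.noise_sd)
        if self.effect_scale != 1.0:
            # the behavioral deficit is part of the disease effect: scaling
            # it too keeps zero-effect cohorts fully exchangeable
            effects = tuple(
                dataclasses.replace(e, delta=e.delta * self.effect_scale)
                for e in design.effects)
            design = dataclasses.replace(
                design, effects=effects,
                behavior_group_gap=design.behavior_group_gap
                * self.effect_scale)
        return design

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        feat = d.pop("features", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if feat is not None:
            d["features"] = FeatureConfig(**feat)
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def derive_cohort(config: PipelineConfig) -> list[SubjectDerived]:
    """Stage 1+2: simulate each subject and reduce epochs to STEPs/ERPv."""
    montage = build_montage()
    design = config.design()
    derived = []
    for record, epoch_sets in iter_cohort(
            config.n_hc, config.n_espd, config.n_established,
            design=design, seed=config.seed, montage=montage):
        derived.append(derive_subject(record, epoch_sets, montage,
                                      config.features))
    return derived


def derive_normative_pool(config: PipelineConfig) -> list[SubjectDerived]:
    """Simulate the disjoint healthy pool that defines the group templates."""
    montage = build_montage()
    design = config.design()
    seed = (config.seed + 1_000_003) % 2 ** 31  # disjoint from the cohort
    derived = []
    for record, epoch_sets in iter_cohort(
            config.n_normative, 0, 0, design=design, seed=seed,
            montage=montage):
        derived.append(derive_subject(record, epoch_sets, montage,
                                      config.features))
    return derived


def _stat_dict(s) -> dict:
    d = {"statistic": s.statistic, "p": s.p, "n": list(s.n)}
    if s.ci95 is not None:
        d["ci95"] = list(s.ci95)
    d.update(s.extra)
    return d


def run_pipeline(config: PipelineConfig,
                 derived: list[SubjectDerived] | None = None) -> dict:
    """Execute every stage and return the run report (JSON-serializable).

    `derived` short-circuits stages 1-2 when the caller already holds the
    per-subject intermediates (e.g. repeated analyses of one cohort).
    """
    montage = build_montage()
    if derived is None:
        derived = derive_cohort(config)

    if config.reference == "normative":
        reference_pool = derive_normative_pool(config)
    else:
        reference_pool = derived
    templates = build_group_templates(reference_pool, "HC", config.features)
    if not templates:
        raise RuntimeError("feature stage produced no group templates")

    scores_by_subject = {d.record.id: score_subject(d, templates, montage,
                                                    config.features)
                         for d in derived}
    train_ids = [d.record.id for d in derived
                 if d.record.group in ("HC", "ESPD")]
    labels = {d.record.id: int(d.record.group == "HC") for d in derived}
    table, y = assemble_feature_table(
        {sid: scores_by_subject[sid] for sid in train_ids},
        labels, templates)

    cv = cross_validate(table, y, k=config.cv_folds, seed=config.seed,
                        alpha=config.selection_alpha, ridge_c=config.ridge_c)
    final = train_final_model(table, y, config.selection_alpha, config.ridge_c)
    importance = feature_importance(final)

    # --- evaluation on pooled out-of-fold scores -------------------------
    hc_scores = cv.scores[y == 1]
    pd_scores = cv.scores[y == 0]
    mw = mann_whitney(pd_scores.to_numpy(), hc_scores.to_numpy())
    # patients are the positive class for sensitivity/specificity
    roc = roc_auc(1.0 - cv.scores.to_numpy(), (y == 0).to_numpy().astype(int))

    report: dict = {
        "config": config.to_dict(),
        "manifest": {
            "n_features": int(table.shape[1]),
            "n_group_steps": len(templates),
            "n_selected_features": len(final.selected_features),
            "group_steps": [
                {"id": g.id, "label": g.label, "band": g.band,
                 "task": g.task, "condition": g.condition, "lock": g.lock,
                 "template_time": round(g.template_time, 2),
                 "member_fraction": round(g.member_fraction, 3)}
                for g in templates],
        },
        "cv_scores": {sid: float(cv.scores[sid]) for sid in cv.scores.index},
        "group_separation": _stat_dict(mw),
        "roc": {
            "auc": roc.auc,
            "ci95": list(roc.ci95) if roc.ci95 else None,
            "sensitivity": roc.operating_point.sensitivity,
            "specificity": roc.operating_point.specificity,
            "threshold": roc.operating_point.threshold,
        },
        "importance": {k: float(v) for k, v in
                       importance.sort_values(ascending=False).items()},
        # per-feature group means (healthy, patient) on the training cohort
        "group_contrasts": {
            col: [round(float(table[col][y == 1].mean(skipna=True)), 4),
                  round(float(table[col][y == 0].mean(skipna=True)), 4)]
            for col in table.columns},
    }

    if config.gender_check:
        sex = np.array([next(d.record.sex for d in derived
                             if d.record.id == sid)
                        for sid in cv.scores.index])
        hc_mask = (y == 1).to_numpy()
        hc_m = cv.scores.to_numpy()[hc_mask & (sex == "M")]
        hc_f = cv.scores.to_numpy()[hc_mask & (sex == "F")]
        if len(hc_m) and len(hc_f):
            report["hc_sex_comparison"] = _stat_dict(mann_whitney(hc_f, hc_m))
        n_f = int((hc_mask & (sex == "F")).sum())
        n_iter, n_fem = 5, 3
        if n_iter * n_fem <= n_f:
            gb = gender_balanced_roc(1.0 - cv.scores.to_numpy(),
                                     (y == 0).to_numpy().astype(int), sex,
                                     n_females=n_fem, n_iter=n_iter,
                                     seed=config.seed)
            report["gender_balanced_roc"] = {
                "mean_auc": gb["mean_auc"], "auc_range": list(gb["auc_range"]),
                "mean_sensitivity": float(np.mean(
                    [p.sensitivity for p in gb["operating_points"]])),
                "mean_specificity": float(np.mean(
                    [p.specificity for p in gb["operating_points"]])),
            }

    # --- established-patient exploration (never part of training) -------
    established = [d for d in derived if d.record.group == "establishedPD"]
    if len(established) >= 4:
        est_table, _ = assemble_feature_table(
            {d.record.id: scores_by_subject[d.record.id] for d in established},
            {d.record.id: 0 for d in established}, templates)
        lt = np.atleast_1d(linear_term(final, est_table))
        mupdrs = np.array([d.record.mupdrs for d in established], dtype=float)
        report["mupdrs_correlation"] = _stat_dict(pearson_with_ci(lt, mupdrs))

    espd = [d for d in derived if d.record.group == "ESPD"]
    if len(espd) >= 4 and all(d.record.ledd is not None for d in espd):
        ledd = np.array([d.record.ledd for d in espd], dtype=float)
        sc = np.array([cv.scores[d.record.id] for d in espd])
        report["ledd_correlation"] = _stat_dict(pearson_with_ci(sc, ledd))

    blob = json.dumps(report, sort_keys=True).encode()
    report["provenance"] = {
        "seed": config.seed,
        "report_sha256": hashlib.sha256(blob).hexdigest(),
    }
    return report


def save_report(report: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path
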