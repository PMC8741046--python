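"""Per-subject feature engineering and assembly of the subjects x features table.

Features per matched group template: amplitude, latency, left-right and
posterior-anterior location, and topographic similarity (5 attributes);
plus, per (task, condition, lock) epoch set, the nine scalp-region ERP
variability scores. Unmatched templates yield missing values (NaN), never
zeros. Feature names follow
``{task}_{condition}_{lock}_{band}_{component}_{attribute}`` and
``{task}_{condition}_{lock}_erpv_{region}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .montage import REGION_NAMES, Montage, build_montage, scalp_regions
from .processing import BANDS, average_erp, rereference_to_mastoids
from .simulate import CONDITIONS, SubjectRecord
from .steps import (GroupStep, Step, cluster_group_steps, erp_variability,
                    extract_steps, match_subject_steps, topographic_similarity)

STEP_BANDS = ("delta", "theta", "alpha", "beta")
STEP_ATTRIBUTES = ("amplitude", "latency", "lr", "pa", "topo_similarity")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the feature-engineering stage."""

    min_prominence: float = 0.5  # microvolts
    min_fraction: float = 0.7  # group-template commonality rule
    cluster_cutoff: float = 1.5  # normalized (time, lr, pa) distance
    max_time_gap: float = 80.0  # ms, matching gate
    max_space_gap: float = 0.6  # montage units, matching gate
    bands: tuple[str, ...] = STEP_BANDS


@dataclass
class SubjectDerived:
    """Cached per-subject intermediates: parcels + variability (epochs freed)."""

    record: SubjectRecord
    steps: list[Step] = field(default_factory=list)
    erpv: dict[str, float] = field(default_factory=dict)
    behavior: dict[str, dict[str, float]] = field(default_factory=dict)


def derive_subject(
    record: SubjectRecord,
    epoch_sets: list[EpochSet],
    montage: Montage | None = None,
    config: FeatureConfig | None = None,
) -> SubjectDerived:
    """Reduce one subject's epochs to STEPs, ERPv scores and behavior summaries."""
    from .simulate import summarize_behavior

    montage = montage or build_montage()
    config = config or FeatureConfig()
    regions = scalp_regions(montage)
    derived = SubjectDerived(record=record)
    for epochs in epoch_sets:
        reref = rereference_to_mastoids(epochs, montage)
        prefix = f"{epochs.task}_{epochs.condition}_{epochs.lock}"
        for band_name in config.bands:
            erp = average_erp(reref, BANDS[band_name])
            derived.steps.extend(
                extract_steps(erp, montage, config.min_prominence))
        for region, value in erp_variability(reref, regions, montage).items():
            derived.erpv[f"{prefix}_erpv_{region}"] = value
        derived.behavior[prefix] = summarize_behavior(epochs)
    return derived


def build_group_templates(
    derived: list[SubjectDerived],
    reference_group: str = "HC",
    config: FeatureConfig | None = None,
) -> list[GroupStep]:
    """Cluster the reference (normative) group's STEPs into labeled templates."""
    from .steps import assign_component_labels

    config = config or FeatureConfig()
    ref = {d.record.id: d.steps for d in derived
           if d.record.group == reference_group}
    group_steps = cluster_group_steps(ref, config.min_fraction,
                                      config.cluster_cutoff)
    return assign_component_labels(group_steps)


def feature_name(gs: GroupStep, attribute: str) -> str:
    return (f"{gs.task}_{gs.condition}_{gs.lock}_{gs.band}_"
            f"{gs.label}_{attribute}")


def feature_columns(group_steps: list[GroupStep]) -> list[str]:
    """Deterministic column inventory for a given template set."""
    cols = [feature_name(gs, attr)
            for gs in group_steps for attr in STEP_ATTRIBUTES]
    for task, cond, lock in CONDITIONS:
        cols.extend(f"{task}_{cond}_{lock}_erpv_{r}" for r in REGION_NAMES)
    return cols


def score_subject(
    derived: SubjectDerived,
    group_steps: list[GroupStep],
    montage: Montage,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Match one subject against the templates and compute all feature values."""
    config = config or FeatureConfig()
    matches = match_subject_steps(derived.steps, group_steps,
                                  config.max_time_gap, config.max_space_gap)
    values: dict[str, float] = {}
    for gs in group_steps:
        step = matches[gs.id]
        if step is None:
            for attr in STEP_ATTRIBUTES:
                values[feature_name(gs, attr)] = np.nan
            continue
        sim = topographic_similarity(step, gs, montage)
        values[feature_name(gs, "amplitude")] = step.amplitude
        values[feature_name(gs, "latency")] = step.peak_time
        values[feature_name(gs, "lr")] = step.lr
        values[feature_name(gs, "pa")] = step.pa
        values[feature_name(gs, "topo_similarity")] = (
            np.nan if sim is None else sim)
    values.update(derived.erpv)
    return values


def assemble_feature_table(
    scores_by_subject: dict[str, dict[str, float]],
    labels: dict[str, int],
    group_steps: list[GroupStep] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the subjects x features table and the label vector.

    Labels follow the "probability of being healthy" convention: healthy = 1,
    patient = 0. Column order is deterministic given the template set; missing
    scores stay NaN. Duplicate feature names raise.
    """
    if group_steps is not None:
        cols = feature_columns(group_steps)
    else:
        cols = sorted({k for s in scores_by_subject.values() for k in s})
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate feature names: {dupes}")
    rows = sorted(scores_by_subject)
    table = pd.DataFrame(
        [[scores_by_subject[sid].get(c, np.nan) for c in cols] for sid in rows],
        index=rows, columns=cols, dtype=float)
    y = pd.Series([labels[sid] for sid in rows], index=rows, name="label",
                  dtype=int)
    return table, y
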