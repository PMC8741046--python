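"""File interfaces: HDF5 epoch/ERP containers, CSV metadata and scores,
JSON templates and models, YAML run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import ERP, EpochSet
from .model import LogisticModel
from .simulate import SubjectRecord
from .steps import GroupStep


def save_epochs(path: str | Path, epoch_sets: list[EpochSet]) -> None:
    """Write epoch sets to one HDF5 file, one group per (subject, task,
    condition, lock), with trial annotations and attributes."""
    with h5py.File(path, "w") as f:
        for es in epoch_sets:
            name = f"{es.subject_id}/{es.task}_{es.condition}_{es.lock}"
            g = f.create_group(name)
            g.create_dataset("data", data=es.data, compression="gzip",
                             compression_opts=1)
            g.create_dataset("correct", data=es.correct.astype(np.uint8))
            g.create_dataset("rt", data=es.rt)
            g.attrs.update({"subject_id": es.subject_id, "task": es.task,
                            "condition": es.condition, "lock": es.lock,
                            "sample_rate": es.sample_rate})


def load_epochs(path: str | Path) -> list[EpochSet]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in f:
            for key in f[sid]:
                g = f[sid][key]
                out.append(EpochSet(
                    subject_id=g.attrs["subject_id"], task=g.attrs["task"],
                    condition=g.attrs["condition"], lock=g.attrs["lock"],
                    data=g["data"][()],
                    correct=g["correct"][()].astype(bool),
                    rt=g["rt"][()],
                    sample_rate=float(g.attrs["sample_rate"]),
                ))
    return out


def save_erps(path: str | Path, erps: list[ERP]) -> None:
    with h5py.File(path, "w") as f:
        for erp in erps:
            name = (f"{erp.subject_id}/{erp.task}_{erp.condition}_"
                    f"{erp.lock}_{erp.band}")
            g = f.create_group(name)
            g.create_dataset("data", data=erp.data, compression="gzip",
                             compression_opts=1)
            g.attrs.update({"subject_id": erp.subject_id, "task": erp.task,
                            "condition": erp.condition, "lock": erp.lock,
                            "band": erp.band, "n_trials": erp.n_trials,
                            "sample_rate": erp.sample_rate})


def load_erps(path: str | Path) -> list[ERP]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in f:
            for key in f[sid]:
                g = f[sid][key]
                out.append(ERP(
                    subject_id=g.attrs["subject_id"], task=g.attrs["task"],
                    condition=g.attrs["condition"], lock=g.attrs["lock"],
                    band=g.attrs["band"], data=g["data"][()],
                    n_trials=int(g.attrs["n_trials"]),
                    sample_rate=float(g.attrs["sample_rate"]),
                ))
    return out


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "group": r.group, "sex": r.sex, "age": r.age,
        "mUPDRS": r.mupdrs, "LEDD": r.ledd,
    } for r in records]).set_index("id")


def save_metadata(path: str | Path, records: list[SubjectRecord]) -> None:
    records_to_frame(records).to_csv(path)


def load_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")


def save_group_steps(path: str | Path, group_steps: list[GroupStep]) -> None:
    payload = [{
        "id": g.id, "canonical_label": g.canonical_label, "band": g.band,
        "task": g.task, "condition": g.condition, "lock": g.lock,
        "polarity": g.polarity, "template_time": g.template_time,
        "template_lr": g.template_lr, "template_pa": g.template_pa,
        "member_fraction": g.member_fraction,
        "template_amplitude": g.template_amplitude,
        "template_patch": np.round(g.template_patch, 6).tolist(),
    } for g in group_steps]
    Path(path).write_text(json.dumps(payload))


def load_group_steps(path: str | Path) -> list[GroupStep]:
    payload = json.loads(Path(path).read_text())
    return [GroupStep(
        id=d["id"], canonical_label=d["canonical_label"], band=d["band"],
        task=d["task"], condition=d["condition"], lock=d["lock"],
        polarity=d["polarity"], template_time=d["template_time"],
        template_lr=d["template_lr"], template_pa=d["template_pa"],
        template_patch=np.asarray(d["template_patch"], dtype=float),
        member_fraction=d["member_fraction"],
        template_amplitude=d.get("template_amplitude", 0.0),
    ) for d in payload]


def save_model(path: str | Path, model: LogisticModel) -> None:
    payload = {
        "intercept": model.intercept,
        "selected_features": model.selected_features,
        "coef": model.coef.tolist(),
        "imputation_values": model.imputation_values.tolist(),
        "standardize_mean": model.standardize_mean.tolist(),
        "standardize_sd": model.standardize_sd.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> LogisticModel:
    d = json.loads(Path(path).read_text())
    return LogisticModel(
        intercept=d["intercept"], coef=np.asarray(d["coef"]),
        selected_features=d["selected_features"],
        imputation_values=np.asarray(d["imputation_values"]),
        standardize_mean=np.asarray(d["standardize_mean"]),
        standardize_sd=np.asarray(d["standardize_sd"]),
    )


def save_features_tidy(path: str | Path, table: pd.DataFrame) -> None:
    """Long-format feature export: one (subject, feature_name, value) row."""
    tidy = (table.rename_axis("subject").reset_index()
            .melt(id_vars="subject", var_name="feature_name",
                  value_name="value"))
    tidy.to_csv(path, index=False)


def save_scores(path: str | Path, scores: pd.Series, folds: pd.Series) -> None:
    pd.DataFrame({"score": scores, "fold": folds}).rename_axis("subject") \
        .to_csv(path)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg
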