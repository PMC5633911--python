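"""CSV and JSON interchange formats.

Waveform CSV (long format), one row per sample:
``subject_id, group, task, joint, component, recording_id,
repetition_index, sample_index, value_deg, missing``.

Clinical CSV, one row per subject:
``subject_id, mmt_elbow_ext, mmt_elbow_sup, mmt_wrist_ext,
mas_elbow_flex, mas_elbow_pron, mas_wrist_flex, classification_level``
("1+" is accepted verbatim in the MAS columns).

Curve CSV (preprocessed), one row per node:
``subject_id, task, joint, component, node, value_deg, n_cycles_used``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clinical import ClinicalProfile
from .datatypes import RawCycle, SubjectTaskCurve
from .synthetic import SyntheticDataset

WAVEFORM_COLUMNS = [
    "subject_id", "group", "task", "joint", "component", "recording_id",
    "repetition_index", "sample_index", "value_deg", "missing",
]
CLINICAL_COLUMNS = [
    "subject_id", "mmt_elbow_ext", "mmt_elbow_sup", "mmt_wrist_ext",
    "mas_elbow_flex", "mas_elbow_pron", "mas_wrist_flex", "classification_level",
]


def write_waveforms(cycles: list[RawCycle], groups: dict[str, str], path) -> None:
    """Write raw cycles as the long-format waveform CSV."""
    frames = []
    for cyc in cycles:
        C, T = cyc.samples.shape
        joints = np.repeat([j for j, _ in cyc.channels], T)
        comps = np.repeat([c for _, c in cyc.channels], T)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": cyc.subject_id,
                    "group": groups[cyc.subject_id],
                    "task": cyc.task,
                    "joint": joints,
                    "component": comps,
                    "recording_id": cyc.recording_id,
                    "repetition_index": cyc.repetition_index,
                    "sample_index": np.tile(np.arange(T), C),
                    "value_deg": cyc.samples.reshape(-1),
                    "missing": cyc.missing.reshape(-1).astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_waveforms(path) -> tuple[list[RawCycle], dict[str, str]]:
    """Read the long-format waveform CSV back into cycles and group labels."""
    df = pd.read_csv(path)
    missing_cols = set(WAVEFORM_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"waveform CSV is missing columns {sorted(missing_cols)}")
    groups = dict(df.drop_duplicates("subject_id")[["subject_id", "group"]].itertuples(index=False))
    cycles: list[RawCycle] = []
    keys = ["subject_id", "task", "recording_id", "repetition_index"]
    for (sid, task, rec, rep), grp in df.groupby(keys, sort=True):
        piv = grp.pivot(index=["joint", "component"], columns="sample_index", values="value_deg")
        miss = grp.pivot(index=["joint", "component"], columns="sample_index", values="missing")
        miss = miss.reindex(piv.index)
        channels = tuple(piv.index.to_list())
        samples = piv.to_numpy(float)
        missing = miss.to_numpy(float) > 0.5
        samples = samples.copy()
        cycles.append(
            RawCycle(
                subject_id=str(sid), task=str(task), recording_id=str(rec),
                repetition_index=int(rep), channels=channels,
                samples=samples, missing=missing,
            )
        )
    return cycles, {str(k): str(v) for k, v in groups.items()}


def write_clinical(profiles: list[ClinicalProfile], path) -> None:
    rows = []
    for p in profiles:
        def fmt_mmt(v: float) -> object:
            return int(v) if float(v).is_integer() else v

        rows.append(
            {
                "subject_id": p.subject_id,
                "mmt_elbow_ext": fmt_mmt(p.mmt_items[0]),
                "mmt_elbow_sup": fmt_mmt(p.mmt_items[1]),
                "mmt_wrist_ext": fmt_mmt(p.mmt_items[2]),
                "mas_elbow_flex": p.mas_items[0],
                "mas_elbow_pron": p.mas_items[1],
                "mas_wrist_flex": p.mas_items[2],
                "classification_level": p.classification_level or "",
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def read_clinical(path) -> list[ClinicalProfile]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing_cols = set(CLINICAL_COLUMNS) - {"classification_level"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"clinical CSV is missing columns {sorted(missing_cols)}")
    profiles = []
    for row in df.itertuples(index=False):
        profiles.append(
            ClinicalProfile(
                subject_id=str(row.subject_id),
                mmt_items=(float(row.mmt_elbow_ext), float(row.mmt_elbow_sup),
                           float(row.mmt_wrist_ext)),
                mas_items=(str(row.mas_elbow_flex), str(row.mas_elbow_pron),
                           str(row.mas_wrist_flex)),
                classification_level=(getattr(row, "classification_level", "") or None),
            )
        )
    return profiles


def write_curves(curves: list[SubjectTaskCurve], path) -> None:
    frames = []
    for cur in curves:
        C, Q = cur.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": cur.subject_id,
                    "task": cur.task,
                    "joint": np.repeat([j for j, _ in cur.channels], Q),
                    "component": np.repeat([c for _, c in cur.channels], Q),
                    "node": np.tile(np.arange(Q), C),
                    "value_deg": cur.values.reshape(-1),
                    "n_cycles_used": cur.n_cycles_used,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_dataset(dataset: SyntheticDataset, waveform_path, clinical_path, truth_path=None) -> None:
    """Write a synthetic dataset as waveform CSV + clinical CSV (+ truth JSON)."""
    write_waveforms(dataset.cycles, dataset.groups, waveform_path)
    write_clinical(dataset.clinical, clinical_path)
    if truth_path is not None:
        import json

        from .synthetic import truth_to_dict

        with open(truth_path, "w") as fh:
            json.dump(truth_to_dict(dataset.truth), fh)
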