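"""Full-study orchestration: group comparison and impairment regression.

For every task x joint cell the vector-then-post-hoc logic is applied:
joints with two or more angle components run the vector-field test
(Hotelling T2 for the group comparison, canonical-correlation X2 for the
impairment regression); only when the vector test yields at least one
significant cluster are the per-component scalar tests run, at the
Bonferroni-adjusted level alpha / p.  The single-component wrist skips the
vector level and runs its scalar test directly.  Group comparisons use
parametric RFT inference by default; impairment regressions (within the
impaired group only) use permutation inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anatomy import JOINTS, TASKS
from .clinical import ClinicalProfile
from .datatypes import SubjectTaskCurve
from .spm import (
    CanonicalCorrelationSnPM,
    HotellingT2SPM,
    RegressionTSPM,
    TwoSampleTSPM,
    bonferroni_alpha,
)

DEFAULT_N_PERM = 10_000


@dataclass
class AnalysisConfig:
    """Inference settings for a study run."""

    alpha: float = 0.05
    two_tailed: bool = True
    n_perm: int = DEFAULT_N_PERM
    Q: int = 101
    seed: int = 0
    tasks: tuple[str, ...] | None = None  # None = all tasks present in the data
    joints: tuple[str, ...] | None = None
    group_method: str = "rft"
    impairment_method: str = "permutation"
    max_enum: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.Q < 3:
            raise ValueError("Q must be >= 3")


@dataclass
class CellResult:
    """Vector-level and conditional post-hoc results of one task x joint cell."""

    task: str
    joint: str
    analysis: str  # "group" | "weakness" | "spasticity"
    vector: dict | None  # None for single-component joints
    posthoc: dict[str, dict] = dfield(default_factory=dict)
    n_components: int = 1

    @property
    def gate_open(self) -> bool:
        """True when post-hoc tests were (or would be) licensed."""
        if self.vector is None:
            return False
        return bool(self.vector["significant"])


def _stack_joint(
    curves: Sequence[SubjectTaskCurve], task: str, joint: str, subjects: Sequence[str]
) -> np.ndarray:
    """Stack curves for one joint into an (n, Q, p) array in subject order."""
    comps = JOINTS[joint]
    lookup = {(c.subject_id, c.task): c for c in curves}
    rows = []
    for sid in subjects:
        curve = lookup.get((sid, task))
        if curve is None:
            raise KeyError(f"no curve for subject {sid!r}, task {task!r}")
        rows.append(np.stack([curve.component(joint, comp) for comp in comps], axis=-1))
    return np.stack(rows)  # (n, Q, p)


def analyze_group_difference(
    curves: Sequence[SubjectTaskCurve],
    groups: dict[str, str],
    task: str,
    joint: str,
    config: AnalysisConfig,
) -> CellResult:
    """Vector-field group comparison for one task x joint, with gated post-hocs."""
    comps = JOINTS[joint]
    p = len(comps)
    have = {(c.subject_id, c.task) for c in curves}
    cases = sorted(s for s, g in groups.items() if g == "case" and (s, task) in have)
    controls = sorted(s for s, g in groups.items() if g == "control" and (s, task) in have)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError(f"need >= 2 subjects per group with curves for task {task!r}")
    YA = _stack_joint(curves, task, joint, cases)
    YB = _stack_joint(curves, task, joint, controls)

    result = CellResult(task=task, joint=joint, analysis="group", vector=None, n_components=p)
    if p == 1:
        model = TwoSampleTSPM(
            alpha=config.alpha, two_tailed=config.two_tailed, method=config.group_method,
            n_perm=config.n_perm, max_enum=config.max_enum, random_state=config.seed,
        ).fit(YA[:, :, 0], YB[:, :, 0])
        result.posthoc[comps[0]] = model.summary()
        return result

    vector = HotellingT2SPM(
        alpha=config.alpha, method=config.group_method, n_perm=config.n_perm,
        max_enum=config.max_enum, random_state=config.seed,
    ).fit(YA, YB)
    result.vector = vector.summary()
    if vector.significant_:
        adj = bonferroni_alpha(config.alpha, p)
        for k, comp in enumerate(comps):
            model = TwoSampleTSPM(
                alpha=adj, two_tailed=config.two_tailed, method=config.group_method,
                n_perm=config.n_perm, max_enum=config.max_enum, random_state=config.seed,
            ).fit(YA[:, :, k], YB[:, :, k])
            result.posthoc[comp] = model.summary()
    return result


def analyze_impairment_effect(
    curves: Sequence[SubjectTaskCurve],
    clinical: Sequence[ClinicalProfile],
    groups: dict[str, str],
    covariate: str,
    task: str,
    joint: str,
    config: AnalysisConfig,
) -> CellResult:
    """Canonical-correlation regression of a joint's curves on a composite score.

    Runs within the impaired group only; permutation (SnPM) inference.
    """
    if covariate not in ("weakness", "spasticity"):
        raise ValueError(f"unknown covariate {covariate!r}")
    comps = JOINTS[joint]
    p = len(comps)
    have = {(c.subject_id, c.task) for c in curves}
    profiles = {prof.subject_id: prof for prof in clinical}
    cases = sorted(
        s for s, g in groups.items() if g == "case" and (s, task) in have and s in profiles
    )
    if len(cases) <= p + 2:
        raise ValueError(f"need n > p + 2 impaired subjects for task {task!r}")
    Y = _stack_joint(curves, task, joint, cases)
    x = np.array([profiles[s].score(covariate) for s in cases])
    if np.ptp(x) == 0:
        raise ValueError(f"{covariate} score is constant in the sample")

    result = CellResult(task=task, joint=joint, analysis=covariate, vector=None, n_components=p)
    if p == 1:
        model = RegressionTSPM(
            alpha=config.alpha, two_tailed=config.two_tailed,
            method=config.impairment_method, n_perm=config.n_perm,
            max_enum=config.max_enum, random_state=config.seed,
        ).fit(Y[:, :, 0], x)
        result.posthoc[comps[0]] = model.summary()
        return result

    vector = CanonicalCorrelationSnPM(
        alpha=config.alpha, n_perm=config.n_perm, max_enum=config.max_enum,
        random_state=config.seed,
    ).fit(Y, x)
    result.vector = vector.summary()
    if vector.significant_:
        adj = bonferroni_alpha(config.alpha, p)
        for k, comp in enumerate(comps):
            model = RegressionTSPM(
                alpha=adj, two_tailed=config.two_tailed,
                method=config.impairment_method, n_perm=config.n_perm,
                max_enum=config.max_enum, random_state=config.seed,
            ).fit(Y[:, :, k], x)
            result.posthoc[comp] = model.summary()
    return result


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _format_p(p: float) -> str:
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def _cluster_strings(clusters: list[dict]) -> tuple[str, str, str]:
    ps = "; ".join(_format_p(c["p_value"]) for c in clusters)
    extents = " ".join(f"{round(c['extent_pct'])}%" for c in clusters)
    ranges = "".join(
        f"({round(c['start_pct'])}-{round(c['end_pct'])})" for c in clusters
    )
    return ps, extents, ranges


def compile_results_table(results: Iterable[CellResult]) -> pd.DataFrame:
    """One row per task x joint x level x component with cluster summaries.

    Percentages are rounded to integers and p-values binned as "<0.01" in
    the formatted columns; exact values live in the JSON results.
    """
    rows = []
    for res in results:
        if res.vector is not None:
            clusters = res.vector["clusters"]
            ps, extents, ranges = _cluster_strings(clusters)
            rows.append(
                dict(task=res.task, joint=res.joint, analysis=res.analysis,
                     level="vector", component="", n_clusters=len(clusters),
                     p_values=ps, extents=extents, ranges=ranges)
            )
        for comp, summary in res.posthoc.items():
            clusters = summary["clusters"]
            ps, extents, ranges = _cluster_strings(clusters)
            rows.append(
                dict(task=res.task, joint=res.joint, analysis=res.analysis,
                     level="component", component=comp, n_clusters=len(clusters),
                     p_values=ps, extents=extents, ranges=ranges)
            )
    return pd.DataFrame(
        rows,
        columns=["task", "joint", "analysis", "level", "component",
                 "n_clusters", "p_values", "extents", "ranges"],
    )


def results_to_json(results: Iterable[CellResult]) -> list[dict]:
    out = []
    for res in results:
        out.append(
            {
                "task": res.task,
                "joint": res.joint,
                "analysis": res.analysis,
                "n_components": res.n_components,
                "vector": res.vector,
                "posthoc": res.posthoc,
            }
        )
    return out


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyResults:
    config: AnalysisConfig
    curves: list[SubjectTaskCurve]
    qc: pd.DataFrame
    group_results: list[CellResult]
    impairment_results: list[CellResult]
    manifest: dict

    @property
    def all_results(self) -> list[CellResult]:
        return self.group_results + self.impairment_results

    def table(self) -> pd.DataFrame:
        return compile_results_table(self.all_results)


def run_full_study(
    waveform_csv,
    clinical_csv,
    config: AnalysisConfig | None = None,
) -> StudyResults:
    """Preprocess a long-format waveform table and run all analyses.

    ``waveform_csv`` / ``clinical_csv`` are paths (or file-like objects) to
    the CSV formats defined in :mod:`cyclespm.io`.  Returns the results
    bundle; writing files is the CLI's job.
    """
    from . import io as cio
    from .preprocessing import CyclePreprocessor

    config = config or AnalysisConfig()
    cycles, groups = cio.read_waveforms(waveform_csv)
    clinical = cio.read_clinical(clinical_csv)

    # cross-reference validation before any statistics run
    problems = []
    profile_ids = {p.subject_id for p in clinical}
    for sid in sorted({c.subject_id for c in cycles}):
        if sid not in groups or groups[sid] not in ("case", "control"):
            problems.append(f"subject {sid}: missing or unknown group label")
        if groups.get(sid) == "case" and sid not in profile_ids:
            problems.append(f"subject {sid}: impaired subject missing a clinical row")
    known_joints = set(JOINTS)
    for c in cycles:
        bad = [j for j, _ in c.channels if j not in known_joints]
        if bad:
            problems.append(f"cycle {c.recording_id}: unknown joints {sorted(set(bad))}")
            break
    if problems:
        raise ValueError("input validation failed:\n" + "\n".join(problems))

    prep = CyclePreprocessor(Q=config.Q)
    curves = prep.transform(cycles)

    tasks = config.tasks or tuple(sorted({c.task for c in curves}, key=lambda t: (TASKS.index(t) if t in TASKS else 99, t)))
    joints = config.joints or tuple(j for j in JOINTS if any(jj == j for c in curves for jj, _ in c.channels))

    group_results = [
        analyze_group_difference(curves, groups, task, joint, config)
        for task in tasks
        for joint in joints
    ]
    impairment_results = [
        analyze_impairment_effect(curves, clinical, groups, cov, task, joint, config)
        for cov in ("weakness", "spasticity")
        for task in tasks
        for joint in joints
    ]

    from . import __version__

    manifest = {
        "software": "cyclespm",
        "version": __version__,
        "config": {
            "alpha": config.alpha, "two_tailed": config.two_tailed,
            "n_perm": config.n_perm, "Q": config.Q, "seed": config.seed,
            "tasks": list(tasks), "joints": list(joints),
            "group_method": config.group_method,
            "impairment_method": config.impairment_method,
        },
        "n_subjects": len({c.subject_id for c in curves}),
        "n_curves": len(curves),
    }
    return StudyResults(
        config=config, curves=curves, qc=prep.qc_,
        group_results=group_results, impairment_results=impairment_results,
        manifest=manifest,
    )


def save_results(results: StudyResults, path) -> None:
    """Write the results bundle (manifest + per-cell records) as JSON."""
    payload = {
        "manifest": results.manifest,
        "group": results_to_json(results.group_results),
        "impairment": results_to_json(results.impairment_results),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
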