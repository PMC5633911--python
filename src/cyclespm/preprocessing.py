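"""From raw repeated cycles to one time-normalized curve per subject and task.

The screening and reduction protocol, applied in fixed order:

1.  screen: exclude a cycle when the fraction of time samples with any
    channel occluded exceeds 20% of movement duration;
2.  fill: cubic-spline interpolation of remaining gaps;
3.  smooth (optional, default off): quintic smoothing spline with a
    predicted-mean-squared-error target;
4.  trim: drop the first and last of the four repetitions per recording,
    leaving four cycles per task across the two recordings;
5.  normalize: linear interpolation onto Q nodes spanning 0-100% of the
    cycle;
6.  select: leave-one-out RMSE against the mean of the remaining cycles,
    keeping the three cycles with lowest RMSE;
7.  average: node-wise mean of the retained cycles.

Every stage logs its decisions into a QC table.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, UnivariateSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import NormalizedCycle, RawCycle, SubjectTaskCurve

DEFAULT_MAX_MISSING = 0.20
DEFAULT_Q = 101


class ProtocolViolationError(ValueError):
    """A recording does not match the expected repetition structure."""


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def screen_occlusion(cycle: RawCycle, max_missing: float = DEFAULT_MAX_MISSING) -> tuple[bool, float]:
    """Keep/exclude decision for marker occlusion.

    Returns ``(keep, missing_fraction)``; a cycle is excluded iff its
    fraction of time samples with any channel missing strictly exceeds
    ``max_missing`` (the rule says "exceeding", so the boundary is kept).
    """
    if not 0.0 < max_missing < 1.0:
        raise ValueError("max_missing must lie in (0, 1)")
    if cycle.n_samples == 0:
        raise ValueError("empty cycle")
    frac = cycle.missing_fraction
    return frac <= max_missing, frac


def fill_gaps(cycle: RawCycle) -> RawCycle:
    """Replace missing runs by cubic-spline interpolation per channel.

    Boundary gaps are filled by extrapolating the nearest spline segment.
    Observed samples pass through unchanged.
    """
    if not np.any(cycle.missing):
        return cycle
    t = np.arange(cycle.n_samples, dtype=float)
    filled = cycle.samples.copy()
    for c in range(len(cycle.channels)):
        miss = cycle.missing[c]
        if not miss.any():
            continue
        obs = ~miss
        if obs.sum() < 4:
            raise ValueError(
                f"channel {cycle.channels[c]} has fewer than 4 observed samples; cannot interpolate"
            )
        spline = CubicSpline(t[obs], cycle.samples[c, obs], extrapolate=True)
        filled[c, miss] = spline(t[miss])
    return RawCycle(
        subject_id=cycle.subject_id,
        task=cycle.task,
        recording_id=cycle.recording_id,
        repetition_index=cycle.repetition_index,
        channels=cycle.channels,
        samples=filled,
        missing=np.zeros_like(cycle.missing),
    )


def smooth_curve(series: np.ndarray, predicted_mse: float) -> np.ndarray:
    """Quintic smoothing spline targeting a predicted mean squared residual.

    The smoothing parameter is chosen so the mean squared residual matches
    ``predicted_mse`` (the spline solver returns the smoothest quintic fit
    whose summed squared residual does not exceed T * predicted_mse, which
    is the interpolating spline when ``predicted_mse`` is 0 and the
    least-squares smooth fit when the target is unattainable).
    """
    if predicted_mse < 0:
        raise ValueError("predicted_mse must be >= 0")
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    T = y.size
    if T < 7:  # quintic spline needs more support than this; pass through
        return y.copy()
    t = np.arange(T, dtype=float)
    spline = UnivariateSpline(t, y, k=5, s=T * predicted_mse)
    return np.asarray(spline(t), dtype=float)


def trim_repetitions(recording: Sequence[RawCycle], strict: bool = True) -> list[RawCycle]:
    """Drop the first and last of the four repetitions of one recording.

    With the two-recordings-of-four protocol this retains repetitions 2 and
    3 of each recording, i.e. four movement cycles per task.  When
    ``strict`` and the recording does not hold exactly 4 repetitions, a
    :class:`ProtocolViolationError` is raised; otherwise the first and last
    present repetitions are dropped with a warning (all are kept when fewer
    than three are present).
    """
    cycles = sorted(recording, key=lambda c: c.repetition_index)
    if len(cycles) != 4:
        if strict:
            raise ProtocolViolationError(
                f"recording {cycles[0].recording_id if cycles else '?'} has "
                f"{len(cycles)} repetitions; expected 4"
            )
        warnings.warn(
            f"recording with {len(cycles)} repetitions; trimming first/last of those present",
            stacklevel=2,
        )
        return cycles[1:-1] if len(cycles) >= 3 else list(cycles)
    return cycles[1:3]


def time_normalize(cycle: RawCycle, Q: int = DEFAULT_Q) -> NormalizedCycle:
    """Linearly interpolate each channel onto Q equally spaced cycle nodes."""
    if Q < 3:
        raise ValueError("Q must be >= 3")
    if np.any(cycle.missing):
        raise ValueError("cycle must be gap-filled before time normalization")
    T = cycle.n_samples
    src = np.linspace(0.0, 1.0, T)
    dst = np.linspace(0.0, 1.0, Q)
    values = np.vstack([np.interp(dst, src, row) for row in cycle.samples])
    return NormalizedCycle(
        subject_id=cycle.subject_id,
        task=cycle.task,
        cycle_id=f"{cycle.recording_id}#rep{cycle.repetition_index}",
        channels=cycle.channels,
        values=values,
    )


def loo_rmse(cycles: Sequence[NormalizedCycle]) -> np.ndarray:
    """Leave-one-out RMSE of each cycle against the mean of the others.

    The RMSE pools all channels and nodes into one scalar per cycle.
    """
    if len(cycles) < 2:
        raise ValueError("need at least two cycles")
    stack = np.stack([c.values for c in cycles])  # (n, C, Q)
    n = stack.shape[0]
    total = stack.sum(axis=0)
    out = np.empty(n)
    for i in range(n):
        ref = (total - stack[i]) / (n - 1)
        out[i] = np.sqrt(np.mean((stack[i] - ref) ** 2))
    return out


def select_cycles_rmse(
    cycles: Sequence[NormalizedCycle],
) -> tuple[list[NormalizedCycle], pd.DataFrame]:
    """Keep the three cycles with lowest leave-one-out RMSE out of four.

    Ties for the largest RMSE are broken by keeping the earlier cycle_id
    (the later of the tied cycles is discarded).  Returns the retained
    cycles (input order preserved) and a per-cycle RMSE report.
    """
    if len(cycles) != 4:
        raise ValueError(f"cycle selection expects exactly 4 cycles, got {len(cycles)}")
    shapes = {c.values.shape for c in cycles}
    chans = {c.channels for c in cycles}
    if len(shapes) != 1 or len(chans) != 1:
        raise ValueError("cycles must share channel set and node count")
    order = sorted(range(4), key=lambda i: cycles[i].cycle_id)
    rmse = loo_rmse(cycles)
    worst_val = rmse.max()
    tied = [i for i in order if rmse[i] == worst_val]
    discard = tied[-1]  # keep earlier cycle_ids
    report = pd.DataFrame(
        {
            "cycle_id": [c.cycle_id for c in cycles],
            "rmse": rmse,
            "retained": [i != discard for i in range(4)],
        }
    )
    return [c for i, c in enumerate(cycles) if i != discard], report


def average_cycles(cycles: Sequence[NormalizedCycle]) -> SubjectTaskCurve:
    """Node-wise, channel-wise arithmetic mean of the retained cycles."""
    if not cycles:
        raise ValueError("no cycles to average")
    shapes = {c.values.shape for c in cycles}
    chans = {c.channels for c in cycles}
    if len(shapes) != 1 or len(chans) != 1:
        raise ValueError("cycles must share channel set and node count")
    values = np.mean(np.stack([c.values for c in cycles]), axis=0)
    first = cycles[0]
    return SubjectTaskCurve(
        subject_id=first.subject_id,
        task=first.task,
        channels=first.channels,
        values=values,
        n_cycles_used=len(cycles),
    )


# ---------------------------------------------------------------------------
# the pipeline transformer
# ---------------------------------------------------------------------------

class CyclePreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the full cycle-reduction protocol.

    Parameters
    ----------
    Q : int
        Number of cycle nodes (0-100% in steps of 100/(Q-1)).
    max_missing : float
        Occlusion screening limit as a fraction of movement duration.
    predicted_mse : float or None
        Quintic smoothing-spline target mean squared residual in squared
        degrees; ``None`` (default) disables smoothing of angle series.
    min_cycles : int
        Minimum normalized cycles required to emit a subject-task curve;
        subject-task cells below this are dropped and logged.

    After :meth:`transform`, ``qc_`` holds a log with one row per
    stage decision (exclusions, protocol deviations, selections).
    """

    def __init__(
        self,
        Q: int = DEFAULT_Q,
        max_missing: float = DEFAULT_MAX_MISSING,
        predicted_mse: float | None = None,
        min_cycles: int = 3,
    ) -> None:
        self.Q = Q
        self.max_missing = max_missing
        self.predicted_mse = predicted_mse
        self.min_cycles = min_cycles

    def fit(self, X: Iterable[RawCycle] | None = None, y=None) -> "CyclePreprocessor":
        """Stateless; present for sklearn pipeline compatibility."""
        return self

    def transform(self, X: Iterable[RawCycle]) -> list[SubjectTaskCurve]:
        qc: list[dict] = []
        by_cell: dict[tuple[str, str], dict[str, list[RawCycle]]] = {}
        for cyc in X:
            by_cell.setdefault((cyc.subject_id, cyc.task), {}).setdefault(
                cyc.recording_id, []
            ).append(cyc)

        curves: list[SubjectTaskCurve] = []
        for (subject, task), recordings in sorted(by_cell.items()):
            kept: list[NormalizedCycle] = []
            for rec_id in sorted(recordings):
                reps = sorted(recordings[rec_id], key=lambda c: c.repetition_index)
                passed: list[RawCycle] = []
                for cyc in reps:
                    keep, frac = screen_occlusion(cyc, self.max_missing)
                    if not keep:
                        qc.append(
                            dict(subject_id=subject, task=task, recording_id=rec_id,
                                 repetition_index=cyc.repetition_index, stage="screen",
                                 action="exclude", detail=f"missing fraction {frac:.3f}")
                        )
                        continue
                    passed.append(fill_gaps(cyc))
                if len(reps) != 4:
                    qc.append(
                        dict(subject_id=subject, task=task, recording_id=rec_id,
                             repetition_index=None, stage="trim", action="protocol_deviation",
                             detail=f"{len(reps)} repetitions present")
                    )
                # trim by repetition index: the protocol drops the first and
                # last recorded repetitions; screening exclusions only shrink
                # what remains
                drop_ids = (
                    {reps[0].repetition_index, reps[-1].repetition_index}
                    if len(reps) >= 3
                    else set()
                )
                for cyc in passed:
                    if cyc.repetition_index in drop_ids:
                        continue
                    if self.predicted_mse is not None:
                        smoothed = np.vstack(
                            [smooth_curve(row, self.predicted_mse) for row in cyc.samples]
                        )
                        cyc = RawCycle(cyc.subject_id, cyc.task, cyc.recording_id,
                                       cyc.repetition_index, cyc.channels, smoothed)
                    kept.append(time_normalize(cyc, self.Q))

            kept.sort(key=lambda c: c.cycle_id)
            if len(kept) == 4:
                kept, report = select_cycles_rmse(kept)
                for _, row in report[~report.retained].iterrows():
                    qc.append(
                        dict(subject_id=subject, task=task, recording_id=None,
                             repetition_index=None, stage="select", action="discard",
                             detail=f"{row.cycle_id} rmse {row.rmse:.3f}")
                    )
            elif len(kept) > 4:  # non-standard protocols: drop worst until 3 remain
                while len(kept) > 3:
                    rmse = loo_rmse(kept)
                    kept.pop(int(np.argmax(rmse)))
            if len(kept) < self.min_cycles:
                qc.append(
                    dict(subject_id=subject, task=task, recording_id=None,
                         repetition_index=None, stage="average", action="drop_cell",
                         detail=f"only {len(kept)} usable cycles")
                )
                continue
            curves.append(average_cycles(kept))

        self.qc_ = pd.DataFrame(
            qc,
            columns=["subject_id", "task", "recording_id", "repetition_index",
                     "stage", "action", "detail"],
        )
        return curves


def preprocess_cycles(
    cycles: Iterable[RawCycle],
    Q: int = DEFAULT_Q,
    max_missing: float = DEFAULT_MAX_MISSING,
    predicted_mse: float | None = None,
) -> tuple[list[SubjectTaskCurve], pd.DataFrame]:
    """Functional wrapper over :class:`CyclePreprocessor`."""
    prep = CyclePreprocessor(Q=Q, max_missing=max_missing, predicted_mse=predicted_mse)
    curves = prep.transform(cycles)
    return curves, prep.qc_
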