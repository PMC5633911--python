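"""In-memory containers for movement cycles and field-statistic results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

Channel = tuple[str, str]  # (joint, component)


@dataclass
class RawCycle:
    """One repetition of one task: variable-duration multi-channel angle series.

    ``samples`` is a (C, T) array of angles in degrees; ``missing`` is a
    (C, T) boolean mask marking occluded samples.
    """

    subject_id: str
    task: str
    recording_id: str
    repetition_index: int
    channels: tuple[Channel, ...]
    samples: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) array")
        if self.missing is None:
            self.missing = np.zeros(self.samples.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.samples.shape:
            raise ValueError("missing mask shape must match samples shape")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("channel list does not match samples rows")
        if self.samples.shape[1] < 3:
            raise ValueError("a cycle needs at least 3 time samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def missing_fraction(self) -> float:
        """Fraction of time samples with any channel missing."""
        return float(np.any(self.missing, axis=0).mean())


@dataclass
class NormalizedCycle:
    """A gap-free cycle time-normalized onto Q nodes spanning 0-100%."""

    subject_id: str
    task: str
    cycle_id: str
    channels: tuple[Channel, ...]
    values: np.ndarray  # (C, Q)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.channels):
            raise ValueError("values must be a (channels, Q) array matching channels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized cycle contains non-finite values")

    @property
    def Q(self) -> int:
        return self.values.shape[1]


@dataclass
class SubjectTaskCurve:
    """One subject's cycle-selected, averaged curve for one task."""

    subject_id: str
    task: str
    channels: tuple[Channel, ...]
    values: np.ndarray  # (C, Q)
    n_cycles_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def Q(self) -> int:
        return self.values.shape[1]

    def component(self, joint: str, component: str) -> np.ndarray:
        from .anatomy import channel_index

        return self.values[channel_index(self.channels, joint, component)]


@dataclass
class SmoothnessEstimate:
    """Residual-field smoothness: FWHM in nodes and resel count (Q-1)/FWHM."""

    fwhm: float
    resels: float

    def to_dict(self) -> dict[str, float]:
        return {"fwhm": float(self.fwhm), "resels": float(self.resels)}


@dataclass
class CriticalThreshold:
    """Field-wide critical value at a family-wise level alpha."""

    u: float
    alpha: float
    method: str  # "rft" | "permutation"
    two_tailed: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "u": float(self.u),
            "alpha": float(self.alpha),
            "method": self.method,
            "two_tailed": bool(self.two_tailed),
        }


@dataclass
class Cluster:
    """A supra-threshold segment of the movement cycle."""

    start_pct: float
    end_pct: float
    p_value: float
    sign: int = 1  # +1 / -1 for t fields; +1 for T2 and X2

    @property
    def extent_pct(self) -> float:
        return self.end_pct - self.start_pct

    def to_dict(self) -> dict[str, Any]:
        return {
            "start_pct": float(self.start_pct),
            "end_pct": float(self.end_pct),
            "extent_pct": float(self.extent_pct),
            "p_value": float(self.p_value),
            "sign": int(self.sign),
        }


@dataclass
class StatField:
    """A node-wise test-statistic curve over the movement cycle.

    ``kind`` is one of ``"t"``, ``"T2"``, ``"X2"``.  ``df`` is the scalar
    degrees of freedom for t fields or the (p, m) pair for T2 fields.
    """

    values: np.ndarray  # (Q,)
    kind: str
    df: float | tuple[int, float]
    n_components: int = 1
    sample_sizes: tuple[int, ...] = ()
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a statistic field is one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic field contains non-finite values")
        if self.kind in ("T2", "X2") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} field must be non-negative")

    @property
    def Q(self) -> int:
        return self.values.shape[0]

    def to_dict(self) -> dict[str, Any]:
        df = self.df if np.isscalar(self.df) else list(self.df)
        return {
            "kind": self.kind,
            "df": df,
            "n_components": self.n_components,
            "sample_sizes": list(self.sample_sizes),
            "values": self.values.tolist(),
            "flags": {k: v for k, v in self.extras.items() if k.endswith("flag")},
        }


@dataclass
class PermutationResult:
    """Null max-statistic and max-cluster-extent distributions."""

    n_perm: int
    exact: bool
    max_stat_distribution: np.ndarray
    cluster_extent_distribution: np.ndarray
    threshold: CriticalThreshold

    def __post_init__(self) -> None:
        self.max_stat_distribution = np.sort(np.asarray(self.max_stat_distribution, float))
        self.cluster_extent_distribution = np.sort(
            np.asarray(self.cluster_extent_distribution, float)
        )

    @property
    def n_total(self) -> int:
        """Size of the null distribution, observed labeling included."""
        return self.max_stat_distribution.size
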