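"""Synthetic joint-angle datasets with the structure the field statistics assume.

The generator emulates a two-group upper-limb study: per subject and task a
smooth 12-channel mean curve over the 0-100% cycle, Gaussian-autocorrelated
between-subject variation (smoothness given as a kernel FWHM in nodes),
localized group mean differences, linear dependence of chosen curve windows
on clinical composite scores, within-subject repetition noise, variable raw
cycle durations, and occasional contiguous missing-sample gaps.  Each
subject contributes 2 recordings x 4 repetitions per task.  Ground truth
(mean curves, effect masks, the configuration) is recorded for recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import correlate1d

from .anatomy import CHANNELS, JOINTS, TASKS
from .clinical import ClinicalProfile
from .datatypes import Channel, RawCycle

# number of recordings per task and repetitions per recording in the protocol
N_RECORDINGS = 2
N_REPETITIONS = 4

#: default MMT item marginals over grades 0..5 (impaired-group distribution)
MMT_ITEM_PROBS = (0.02, 0.05, 0.13, 0.25, 0.30, 0.25)
#: default MAS item marginals over grades 0, 1, 1+, 2, 3, 4
MAS_GRADES = ("0", "1", "1+", "2", "3", "4")
MAS_ITEM_PROBS = (0.30, 0.25, 0.20, 0.15, 0.07, 0.03)


@dataclass(frozen=True)
class EffectWindow:
    """A group mean-curve difference injected on one channel sub-window."""

    joint: str
    component: str
    start_node: int
    end_node: int
    amplitude_deg: float


@dataclass(frozen=True)
class CovariateEffect:
    """Linear dependence of a channel sub-window on a composite score."""

    covariate: str  # "weakness" | "spasticity"
    joint: str
    component: str
    start_node: int
    end_node: int
    slope_deg_per_unit: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for :func:`generate_dataset`.

    Defaults reproduce the full-scale design: 60 subjects per group, a
    101-node cycle, field smoothness FWHM = 20 nodes, between-subject SD
    8 degrees and within-subject repetition SD 2.5 degrees (plausible
    magnitudes for upper-limb joint-angle waveforms; the study reports
    none), raw cycle durations uniform on 80-150 samples.
    """

    n_per_group: int = 60
    Q: int = 101
    fwhm: float = 20.0
    curve_sd: float = 8.0
    rep_sd: float = 2.5
    effect_windows: tuple[EffectWindow, ...] = ()
    covariate_effects: tuple[CovariateEffect, ...] = ()
    raw_duration_range: tuple[int, int] = (80, 150)
    gap_fraction: float = 0.05
    gap_length_range: tuple[float, float] = (0.02, 0.10)
    tasks: tuple[str, ...] = TASKS
    joints: tuple[str, ...] = tuple(JOINTS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Q < 3:
            raise ValueError("Q must be >= 3")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if min(self.curve_sd, self.rep_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        lo, hi = self.raw_duration_range
        if not (3 <= lo <= hi):
            raise ValueError("raw_duration_range must satisfy 3 <= lo <= hi")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must lie in [0, 1]")
        for w in tuple(self.effect_windows) + tuple(self.covariate_effects):
            if not 0 <= w.start_node <= w.end_node < self.Q:
                raise ValueError(f"window {w} outside 0..Q-1")

    @property
    def channels(self) -> tuple[Channel, ...]:
        return tuple((j, c) for j in self.joints for c in JOINTS[j])


@dataclass
class SyntheticDataset:
    """Generated cycles, clinical table and ground truth."""

    cycles: list[RawCycle]
    clinical: list[ClinicalProfile]
    groups: dict[str, str]  # subject_id -> "case" | "control"
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# smooth Gaussian random fields
# ---------------------------------------------------------------------------

def _gaussian_kernel(sigma: float) -> np.ndarray:
    radius = max(int(math.ceil(4.0 * sigma)), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-x * x / (2.0 * sigma * sigma))
    return k / k.sum()


def sample_smooth_fields(
    n: int,
    Q: int,
    fwhm: float,
    sd: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n zero-mean Gaussian fields of length Q with the given smoothness.

    White Gaussian noise on a grid extended by 4 kernel SDs on each side is
    convolved with a Gaussian kernel of full-width-at-half-maximum ``fwhm``
    (in nodes), cropped to Q nodes, and rescaled so the node-wise marginal
    SD equals ``sd`` exactly in expectation.  The resulting autocorrelation
    is Gaussian with parameter sigma*sqrt(2), the null model under which
    the RFT thresholds are exact.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if Q < 3:
        raise ValueError("Q must be >= 3")
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = fwhm / _SQRT_8LN2
    if sigma > 50.0 * Q:
        # smoothness far beyond the window: fields are constant to numerical
        # precision, so draw the single shared level directly
        return sd * rng.standard_normal((n, 1)) * np.ones((1, Q))
    kernel = _gaussian_kernel(sigma)
    pad = kernel.size // 2
    white = rng.standard_normal((n, Q + 2 * pad))
    smooth = correlate1d(white, kernel, axis=1, mode="constant")[:, pad : pad + Q]
    scale = math.sqrt(float(np.sum(kernel * kernel)))
    return sd * smooth / scale


_SQRT_8LN2 = math.sqrt(8.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# clinical profiles
# ---------------------------------------------------------------------------

def generate_clinical_profiles(
    n: int,
    seed: int | np.random.Generator = 0,
    mmt_probs: Sequence[float] = MMT_ITEM_PROBS,
    mas_probs: Sequence[float] = MAS_ITEM_PROBS,
    prefix: str = "case",
) -> list[ClinicalProfile]:
    """Draw n impaired-group clinical profiles from the item marginals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mmt_probs = np.asarray(mmt_probs, float)
    mas_probs = np.asarray(mas_probs, float)
    mmt = rng.choice(6, size=(n, 3), p=mmt_probs / mmt_probs.sum())
    mas = rng.choice(6, size=(n, 3), p=mas_probs / mas_probs.sum())
    return [
        ClinicalProfile(
            subject_id=f"{prefix}{i + 1:03d}",
            mmt_items=tuple(float(v) for v in mmt[i]),
            mas_items=tuple(MAS_GRADES[g] for g in mas[i]),
            classification_level=None,
        )
        for i in range(n)
    ]


def _control_profile(subject_id: str) -> ClinicalProfile:
    # typically developing children: full strength, no spasticity
    return ClinicalProfile(subject_id, (5.0, 5.0, 5.0), ("0", "0", "0"), None)


# ---------------------------------------------------------------------------
# mean-curve templates
# ---------------------------------------------------------------------------

def default_mean_curve(channel: Channel, Q: int) -> np.ndarray:
    """Smooth per-channel template: offset + logistic ramp + mid-cycle bump.

    The shapes are arbitrary smooth stand-ins for real task kinematics; the
    exact parameters vary deterministically with the channel index so the
    twelve channels differ, and can be overridden via ``mean_curves``.
    """
    i = CHANNELS.index(channel) if channel in CHANNELS else hash(channel) % 12
    t = np.linspace(0.0, 1.0, Q)
    offset = 5.0 * ((i % 5) - 2)
    ramp_amp = 20.0 + 4.0 * math.cos(1.3 * i)
    ramp_ctr = 0.35 + 0.04 * (i % 4)
    bump_amp = 10.0 * math.sin(0.9 * i + 0.5)
    bump_ctr = 0.55 + 0.03 * (i % 3)
    ramp = ramp_amp / (1.0 + np.exp(-(t - ramp_ctr) / 0.08))
    bump = bump_amp * np.exp(-((t - bump_ctr) ** 2) / (2.0 * 0.15**2))
    return offset + ramp + bump


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _resample(values: np.ndarray, T: int) -> np.ndarray:
    """Evaluate a (C, Q) normalized curve at T equally spaced phase points."""
    Q = values.shape[1]
    src = np.linspace(0.0, 1.0, Q)
    dst = np.linspace(0.0, 1.0, T)
    return np.vstack([np.interp(dst, src, row) for row in values])


def generate_dataset(
    config: GeneratorConfig,
    mean_curves: dict[Channel, np.ndarray] | Callable[[Channel, int], np.ndarray] | None = None,
) -> SyntheticDataset:
    """Generate raw cycles, clinical profiles and ground truth per ``config``.

    Per subject and task the true curve is the group mean curve plus a
    smooth subject field; the impaired ("case") group additionally receives
    the configured effect-window amplitudes, and covariate effects add
    slope * (score - mean case score) over their windows.  Every cycle is
    the true curve resampled to a random raw duration plus smooth
    repetition noise, with an optional single contiguous missing gap.
    """
    cfg = config
    channels = cfg.channels
    chan_idx = {ch: k for k, ch in enumerate(channels)}
    for w in tuple(cfg.effect_windows) + tuple(cfg.covariate_effects):
        if (w.joint, w.component) not in chan_idx:
            raise ValueError(f"effect window references unknown channel ({w.joint}, {w.component})")

    ss = np.random.SeedSequence(cfg.seed)
    s_clin, s_fields, s_cycles = ss.spawn(3)
    rng_clin = np.random.default_rng(s_clin)
    rng_cycles = np.random.default_rng(s_cycles)

    n = cfg.n_per_group
    cases = generate_clinical_profiles(n, rng_clin, prefix="case")
    controls = [_control_profile(f"ctrl{i + 1:03d}") for i in range(n)]
    clinical = cases + controls
    groups = {p.subject_id: "case" for p in cases}
    groups.update({p.subject_id: "control" for p in controls})
    subjects = [p.subject_id for p in clinical]

    if callable(mean_curves):
        base = {ch: np.asarray(mean_curves(ch, cfg.Q), float) for ch in channels}
    elif mean_curves is not None:
        base = {ch: np.asarray(mean_curves[ch], float) for ch in channels}
    else:
        base = {ch: default_mean_curve(ch, cfg.Q) for ch in channels}

    # group mean curves and truth masks
    case_means = {ch: base[ch].copy() for ch in channels}
    effect_masks: dict[Channel, np.ndarray] = {}
    for w in cfg.effect_windows:
        ch = (w.joint, w.component)
        sl = slice(w.start_node, w.end_node + 1)
        case_means[ch][sl] += w.amplitude_deg
        mask = effect_masks.setdefault(ch, np.zeros(cfg.Q, dtype=bool))
        mask[sl] = True
    covariate_masks: dict[tuple[str, str, str], np.ndarray] = {}
    for w in cfg.covariate_effects:
        mask = covariate_masks.setdefault(
            (w.covariate, w.joint, w.component), np.zeros(cfg.Q, dtype=bool)
        )
        mask[w.start_node : w.end_node + 1] = True

    scores = {
        cov: np.array([p.score(cov) for p in cases]) for cov in ("weakness", "spasticity")
    }
    score_means = {cov: float(v.mean()) for cov, v in scores.items()}

    C = len(channels)
    fields_rng = np.random.default_rng(s_fields)
    cycles: list[RawCycle] = []
    dur_lo, dur_hi = cfg.raw_duration_range

    for task in cfg.tasks:
        subj_fields = sample_smooth_fields(
            2 * n * C, cfg.Q, cfg.fwhm, cfg.curve_sd, fields_rng
        ).reshape(2 * n, C, cfg.Q)
        true_curves = np.empty((2 * n, C, cfg.Q))
        for si, sid in enumerate(subjects):
            is_case = groups[sid] == "case"
            for ch, k in chan_idx.items():
                mean = case_means[ch] if is_case else base[ch]
                true_curves[si, k] = mean + subj_fields[si, k]
            if is_case:
                for w in cfg.covariate_effects:
                    k = chan_idx[(w.joint, w.component)]
                    delta = cases[si].score(w.covariate) - score_means[w.covariate]
                    true_curves[si, k, w.start_node : w.end_node + 1] += (
                        w.slope_deg_per_unit * delta
                    )

        n_cyc = 2 * n * N_RECORDINGS * N_REPETITIONS
        rep_noise = (
            sample_smooth_fields(n_cyc * C, cfg.Q, cfg.fwhm, cfg.rep_sd, fields_rng)
            .reshape(2 * n, N_RECORDINGS * N_REPETITIONS, C, cfg.Q)
            if cfg.rep_sd > 0
            else np.zeros((2 * n, N_RECORDINGS * N_REPETITIONS, C, cfg.Q))
        )
        durations = rng_cycles.integers(dur_lo, dur_hi + 1, size=(2 * n, N_RECORDINGS, N_REPETITIONS))
        gap_draws = rng_cycles.random(size=(2 * n, N_RECORDINGS, N_REPETITIONS, 3))

        for si, sid in enumerate(subjects):
            for rec in range(N_RECORDINGS):
                for rep in range(N_REPETITIONS):
                    T = int(durations[si, rec, rep])
                    curve = true_curves[si] + rep_noise[si, rec * N_REPETITIONS + rep]
                    samples = _resample(curve, T)
                    missing = np.zeros((C, T), dtype=bool)
                    u_gap, u_len, u_pos = gap_draws[si, rec, rep]
                    if cfg.gap_fraction > 0 and u_gap < cfg.gap_fraction:
                        g_lo, g_hi = cfg.gap_length_range
                        glen = max(1, int(round((g_lo + u_len * (g_hi - g_lo)) * T)))
                        gstart = int(u_pos * max(T - glen, 1))
                        missing[:, gstart : gstart + glen] = True
                    samples = samples.copy()
                    samples[missing] = np.nan
                    cycles.append(
                        RawCycle(
                            subject_id=sid,
                            task=task,
                            recording_id=f"{sid}-{task}-r{rec + 1}",
                            repetition_index=rep + 1,
                            channels=channels,
                            samples=samples,
                            missing=missing,
                        )
                    )

    truth = {
        "config": cfg,
        "case_means": case_means,
        "control_means": base,
        "effect_masks": effect_masks,
        "covariate_masks": covariate_masks,
    }
    return SyntheticDataset(cycles=cycles, clinical=clinical, groups=groups, truth=truth)


def truth_to_dict(truth: dict) -> dict:
    """JSON-serializable view of a dataset's ground truth."""
    cfg: GeneratorConfig = truth["config"]
    return {
        "config": {
            "n_per_group": cfg.n_per_group,
            "Q": cfg.Q,
            "fwhm": cfg.fwhm,
            "curve_sd": cfg.curve_sd,
            "rep_sd": cfg.rep_sd,
            "effect_windows": [vars(w) for w in cfg.effect_windows],
            "covariate_effects": [vars(w) for w in cfg.covariate_effects],
            "raw_duration_range": list(cfg.raw_duration_range),
            "gap_fraction": cfg.gap_fraction,
            "gap_length_range": list(cfg.gap_length_range),
            "tasks": list(cfg.tasks),
            "joints": list(cfg.joints),
            "seed": cfg.seed,
        },
        "case_means": {f"{j}:{c}": v.tolist() for (j, c), v in truth["case_means"].items()},
        "control_means": {f"{j}:{c}": v.tolist() for (j, c), v in truth["control_means"].items()},
        "effect_masks": {f"{j}:{c}": v.astype(int).tolist() for (j, c), v in truth["effect_masks"].items()},
        "covariate_masks": {
            f"{cov}:{j}:{c}": v.astype(int).tolist()
            for (cov, j, c), v in truth["covariate_masks"].items()
        },
    }


def scaled_config(config: GeneratorConfig, **overrides) -> GeneratorConfig:
    """Return a copy of ``config`` with fields replaced (convenience)."""
    return replace(config, **overrides)
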