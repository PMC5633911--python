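"""Statistic fields over the movement cycle and their field-wide inference.

Four node-wise statistics are supported:

* two-sample pooled-variance t (group comparison of one angle component);
* Hotelling's T2 (group comparison of a joint's component vector);
* simple-linear-regression t of a component on a clinical covariate;
* canonical correlation of a component vector with a scalar covariate,
  expressed through the Wilks/Bartlett chi-square transform
  X2 = -(n - 1 - (p+2)/2) * ln(1 - r^2).

Inference on a field is either parametric (random field theory, see
:mod:`cyclespm.rft`) or nonparametric (permutation of group labels or of
the covariate vector, with the max-statistic null distribution).  The
estimator classes follow the sklearn protocol: construct with the
inference parameters, call ``fit`` with the curve matrices, read the
fitted attributes (``statistic_``, ``fwhm_``, ``threshold_``,
``clusters_``, ``significant_``).
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator

from . import rft
from .datatypes import (
    Cluster,
    CriticalThreshold,
    PermutationResult,
    SmoothnessEstimate,
    StatField,
)

DEFAULT_VAR_FLOOR = 1e-12
DEFAULT_STAT_CAP = 1e6
DEFAULT_N_PERM = 10_000
DEFAULT_MAX_ENUM = 100_000


# ---------------------------------------------------------------------------
# field builders
# ---------------------------------------------------------------------------

def two_sample_t_field(
    groupA: np.ndarray,
    groupB: np.ndarray,
    var_floor: float = DEFAULT_VAR_FLOOR,
) -> StatField:
    """Node-wise pooled-variance two-sample t field (A minus B), df = n1+n2-2."""
    A = np.atleast_2d(np.asarray(groupA, float))
    B = np.atleast_2d(np.asarray(groupB, float))
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 curves")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the node count")
    df = n1 + n2 - 2
    d = A.mean(axis=0) - B.mean(axis=0)
    ss = ((A - A.mean(axis=0)) ** 2).sum(axis=0) + ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    pooled = ss / df
    floored = pooled < var_floor
    pooled = np.maximum(pooled, var_floor)
    t = d / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    extras = {"residuals": np.vstack([A - A.mean(axis=0), B - B.mean(axis=0)])}
    if floored.any():
        extras["variance_floor_flag"] = np.flatnonzero(floored).tolist()
    return StatField(t, kind="t", df=float(df), n_components=1,
                     sample_sizes=(n1, n2), extras=extras)


def hotelling_t2_field(
    groupA: np.ndarray,
    groupB: np.ndarray,
    ridge: float = DEFAULT_VAR_FLOOR,
) -> StatField:
    """Node-wise two-sample Hotelling T2 field for (n, Q, p) curve stacks.

    T2(q) = n1 n2/(n1+n2) d(q)' S(q)^{-1} d(q) with S the pooled sample
    covariance of the p components; near-singular S is handled by flooring
    its eigenvalues at ``ridge`` (flagged).
    """
    A = np.asarray(groupA, float)
    B = np.asarray(groupB, float)
    if A.ndim == 2:
        A = A[:, :, None]
    if B.ndim == 2:
        B = B[:, :, None]
    n1, n2 = A.shape[0], B.shape[0]
    p = A.shape[2]
    if B.shape[2] != p or A.shape[1] != B.shape[1]:
        raise ValueError("groups must share node count and component count")
    m = n1 + n2 - 2
    if n1 + n2 <= p + 1:
        raise ValueError("need n1 + n2 > p + 1 for a nonsingular pooled covariance")
    Ra = A - A.mean(axis=0)
    Rb = B - B.mean(axis=0)
    d = A.mean(axis=0) - B.mean(axis=0)  # (Q, p)
    S = (np.einsum("nqp,nqr->qpr", Ra, Ra) + np.einsum("nqp,nqr->qpr", Rb, Rb)) / m
    # eigenvalue floor against singular covariance
    w, V = np.linalg.eigh(S)
    ridged = bool((w < ridge).any())
    w = np.maximum(w, ridge)
    Sinv = np.einsum("qpr,qr,qsr->qps", V, 1.0 / w, V)
    t2 = (n1 * n2 / (n1 + n2)) * np.einsum("qp,qps,qs->q", d, Sinv, d)
    t2 = np.maximum(t2, 0.0)
    residuals = np.vstack([Ra, Rb])  # (n, Q, p)
    extras = {"residuals": residuals.transpose(0, 2, 1).reshape(-1, A.shape[1])}
    if ridged:
        extras["ridge_flag"] = True
    return StatField(t2, kind="T2", df=(p, float(m)), n_components=p,
                     sample_sizes=(n1, n2), extras=extras)


def regression_t_field(
    responses: np.ndarray,
    covariate: np.ndarray,
    stat_cap: float = DEFAULT_STAT_CAP,
) -> StatField:
    """Node-wise t field of the simple-linear-regression slope, df = n-2."""
    Y = np.atleast_2d(np.asarray(responses, float))
    x = np.asarray(covariate, float)
    n = Y.shape[0]
    if n < 3 or x.shape[0] != n:
        raise ValueError("need n >= 3 responses matching the covariate length")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise ValueError("covariate is constant")
    Yc = Y - Y.mean(axis=0)
    slope = (xc @ Yc) / sxx
    resid = Yc - np.outer(xc, slope)
    df = n - 2
    mse = (resid**2).sum(axis=0) / df
    se = np.sqrt(mse / sxx)
    capped = se <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(capped, np.sign(slope) * stat_cap, slope / np.where(se > 0, se, 1.0))
    t = np.clip(t, -stat_cap, stat_cap)
    extras = {"residuals": resid, "slope": slope}
    if capped.any():
        extras["cap_flag"] = np.flatnonzero(capped).tolist()
    return StatField(t, kind="t", df=float(df), n_components=1,
                     sample_sizes=(n,), extras=extras)


def cca_x2_field(
    responses: np.ndarray,
    covariate: np.ndarray,
    stat_cap: float = DEFAULT_STAT_CAP,
    ridge: float = DEFAULT_VAR_FLOOR,
) -> StatField:
    """Canonical-correlation X2 field between (n, Q, p) responses and a scalar.

    With a single covariate the first canonical correlation r(q) is the
    multiple correlation of the covariate on the p response components;
    X2(q) = -(n - 1 - (p+2)/2) ln(1 - r(q)^2) is Bartlett's chi-square
    approximation of Wilks' lambda.  Perfect correlation is capped at
    ``stat_cap`` and flagged.
    """
    Y = np.asarray(responses, float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    x = np.asarray(covariate, float)
    n, Q, p = Y.shape
    if x.shape[0] != n:
        raise ValueError("covariate length must match the number of curves")
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise ValueError("covariate is constant")
    Yc = Y - Y.mean(axis=0)
    syy = np.einsum("nqp,nqr->qpr", Yc, Yc)
    sxy = np.einsum("n,nqp->qp", xc, Yc)
    w, V = np.linalg.eigh(syy)
    w = np.maximum(w, ridge)
    syy_inv = np.einsum("qpr,qr,qsr->qps", V, 1.0 / w, V)
    r2 = np.einsum("qp,qps,qs->q", sxy, syy_inv, sxy) / sxx
    r2 = np.clip(r2, 0.0, 1.0)
    coef = n - 1.0 - (p + 2.0) / 2.0
    capped = r2 >= 1.0 - 1e-12
    with np.errstate(divide="ignore"):
        x2 = -coef * np.log1p(-np.where(capped, 0.0, r2))
    x2 = np.where(capped, stat_cap, x2)
    x2 = np.minimum(np.maximum(x2, 0.0), stat_cap)
    extras = {"r": np.sqrt(r2), "wilks_lambda": 1.0 - r2}
    if capped.any():
        extras["cap_flag"] = np.flatnonzero(capped).tolist()
    return StatField(x2, kind="X2", df=float(p), n_components=p,
                     sample_sizes=(n,), extras=extras)


# ---------------------------------------------------------------------------
# smoothness
# ---------------------------------------------------------------------------

def estimate_fwhm(residuals: np.ndarray) -> SmoothnessEstimate:
    """Residual-based FWHM estimate of a set of 1D fields.

    Each residual field is normalized to unit node-wise variance; the mean
    squared forward-difference gradient v then gives
    FWHM = sqrt(4 ln 2 / v) and resels = (Q - 1) / FWHM.
    """
    R = np.atleast_2d(np.asarray(residuals, float))
    if R.shape[0] < 2:
        raise ValueError("need at least 2 residual fields")
    Q = R.shape[1]
    sd = np.sqrt((R**2).mean(axis=0))
    if not np.any(sd > 0):
        raise ValueError("all-zero residuals: smoothness is undefined")
    sd = np.where(sd > 0, sd, np.nan)
    D = R / sd
    grad = np.diff(D, axis=1)
    v = float(np.nanmean(grad**2))
    if v <= 0.0:
        return SmoothnessEstimate(fwhm=np.inf, resels=0.0)
    fwhm = math.sqrt(4.0 * math.log(2.0) / v)
    return SmoothnessEstimate(fwhm=fwhm, resels=(Q - 1) / fwhm)


def bonferroni_alpha(alpha: float, n_components: int) -> float:
    """Bonferroni-adjusted level for the post-hoc family of p components."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    return alpha / n_components


# ---------------------------------------------------------------------------
# cluster geometry
# ---------------------------------------------------------------------------

def _crossing(q0: int, z0: float, z1: float, u: float) -> float:
    """Linear-interpolated node coordinate where the field crosses u."""
    return q0 + (u - z0) / (z1 - z0)


def suprathreshold_segments(z: np.ndarray, u: float) -> list[tuple[float, float]]:
    """Maximal runs with z > u, endpoints refined by linear interpolation.

    Coordinates are returned in node units (0 .. Q-1).
    """
    z = np.asarray(z, float)
    above = z > u
    if not above.any():
        return []
    segs: list[tuple[float, float]] = []
    Q = z.size
    q = 0
    while q < Q:
        if not above[q]:
            q += 1
            continue
        start = q
        while q + 1 < Q and above[q + 1]:
            q += 1
        end = q
        a = float(start) if start == 0 else _crossing(start - 1, z[start - 1], z[start], u)
        b = float(end) if end == Q - 1 else _crossing(end, z[end], z[end + 1], u)
        segs.append((a, b))
        q += 1
    return segs


def cluster_inference(
    field: StatField,
    threshold: CriticalThreshold,
    smoothness: SmoothnessEstimate,
) -> list[Cluster]:
    """RFT cluster-level inference: locate supra-threshold runs and p-value them.

    For two-tailed t fields both tails are scanned at +/- u.  Extents are
    converted to percent of the movement cycle.
    """
    z = field.values
    Q = field.Q
    u = threshold.u
    tails = 2 if threshold.two_tailed else 1
    scan = [(z, 1)] + ([(-z, -1)] if threshold.two_tailed else [])
    pct = 100.0 / (Q - 1)
    clusters: list[Cluster] = []
    for signed, sign in scan:
        for a, b in suprathreshold_segments(signed, u):
            p = rft.cluster_p_value(
                extent_nodes=b - a,
                u=u,
                kind=field.kind,
                df=field.df,
                resels=smoothness.resels,
                Q=Q,
                tails=tails,
            )
            clusters.append(Cluster(start_pct=a * pct, end_pct=b * pct, p_value=p, sign=sign))
    clusters.sort(key=lambda c: c.start_pct)
    return clusters


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Per-row maximal run length (in nodes) of True entries of (B, Q) mask."""
    B, Q = above.shape
    idx = np.arange(Q)
    last_false = np.where(~above, idx, -1)
    last_false = np.maximum.accumulate(last_false, axis=1)
    runs = np.where(above, idx - last_false, 0)
    return runs.max(axis=1).astype(float)


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def group_permutations(
    n1: int,
    n2: int,
    n_perm: int = DEFAULT_N_PERM,
    max_enum: int = DEFAULT_MAX_ENUM,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, bool]:
    """Row-index permutations realizing two-group relabelings.

    Returns ``(perms, exact)`` where ``perms`` is a (B, n1+n2) integer
    array whose first row is the identity (the observed labeling).  All
    C(n1+n2, n1) distinct relabelings are enumerated when their number is
    at most ``max_enum``; otherwise ``n_perm`` random permutations are
    drawn and the identity prepended.
    """
    n = n1 + n2
    n_distinct = math.comb(n, n1)
    if n_distinct <= max_enum:
        rows = []
        allidx = set(range(n))
        for combo in combinations(range(n), n1):
            rest = sorted(allidx - set(combo))
            rows.append(list(combo) + rest)
        perms = np.asarray(rows, dtype=np.intp)
        # move the identity to the front
        ident = np.arange(n)
        pos = int(np.flatnonzero((perms == ident).all(axis=1))[0])
        perms[[0, pos]] = perms[[pos, 0]]
        return perms, True
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=np.intp)
    perms[0] = np.arange(n)
    for b in range(1, n_perm + 1):
        perms[b] = rng.permutation(n)
    return perms, False


def order_permutations(
    n: int,
    n_perm: int = DEFAULT_N_PERM,
    max_enum: int = DEFAULT_MAX_ENUM,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, bool]:
    """Permutations of the covariate order (identity first)."""
    if n <= 13 and math.factorial(n) <= max_enum:
        from itertools import permutations as iperm

        perms = np.asarray(list(iperm(range(n))), dtype=np.intp)
        return perms, True
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=np.intp)
    perms[0] = np.arange(n)
    for b in range(1, n_perm + 1):
        perms[b] = rng.permutation(n)
    return perms, False


def permutation_inference(
    statistic_builder: Callable[[np.ndarray], np.ndarray],
    perms: np.ndarray,
    alpha: float = 0.05,
    two_tailed: bool = False,
) -> tuple[PermutationResult, np.ndarray, float]:
    """Max-statistic permutation inference over precomputed permutations.

    ``statistic_builder`` maps the (B, n) permutation index array to a
    (B, Q) array of statistic fields (row 0 is the observed field).  The
    critical threshold is the ceil((1 - alpha) * B)-th order statistic of
    the per-permutation max statistic (absolute value for two-tailed
    fields), so every permutation p-value is at least 1/B.

    Returns ``(result, observed_field, p_max)`` where ``p_max`` is the
    permutation p-value of the observed field maximum.
    """
    B = perms.shape[0]
    if B < 1:
        raise ValueError("need at least one permutation")
    if B < 1.0 / alpha:
        raise ValueError(
            f"only {B} distinct permutations available; inference at alpha={alpha} "
            "is impossible"
        )
    fields = statistic_builder(perms)
    observed = fields[0]
    mag = np.abs(fields) if two_tailed else fields
    max_stats = mag.max(axis=1)
    sorted_max = np.sort(max_stats)
    k = int(math.ceil((1.0 - alpha) * B))
    u = float(sorted_max[k - 1])
    # permutation distribution of maximal supra-threshold cluster extent
    extents = _max_run_lengths(mag > u)
    p_max = float(np.mean(max_stats >= max_stats[0]))
    threshold = CriticalThreshold(u=u, alpha=alpha, method="permutation", two_tailed=two_tailed)
    result = PermutationResult(
        n_perm=B - 1,
        exact=False,  # caller may overwrite
        max_stat_distribution=sorted_max,
        cluster_extent_distribution=extents,
        threshold=threshold,
    )
    return result, observed, p_max


def permutation_clusters(
    observed: np.ndarray,
    result: PermutationResult,
    Q: int,
) -> list[Cluster]:
    """Clusters of the observed field with permutation extent p-values.

    Observed endpoints are interpolated for reporting; extents compared to
    the permutation distribution are measured in whole-node run lengths on
    both sides, keeping observed and null extents commensurable.
    """
    u = result.threshold.u
    two = result.threshold.two_tailed
    pct = 100.0 / (Q - 1)
    ext_null = result.cluster_extent_distribution
    B = ext_null.size
    clusters: list[Cluster] = []
    scan = [(observed, 1)] + ([(-observed, -1)] if two else [])
    for signed, sign in scan:
        for a, b in suprathreshold_segments(signed, u):
            # count of whole nodes above u, commensurable with _max_run_lengths
            node_extent = int(math.floor(b)) - int(math.ceil(a)) + 1
            p = float(np.mean(ext_null >= node_extent)) if B else 1.0
            p = max(p, 1.0 / max(B, 1))
            clusters.append(
                Cluster(start_pct=a * pct, end_pct=b * pct, p_value=min(p, 1.0), sign=sign)
            )
    clusters.sort(key=lambda c: c.start_pct)
    return clusters


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class _BaseSPM(BaseEstimator):
    """Shared fitted-attribute plumbing for the SPM estimators."""

    def _finish_rft(self, field: StatField, two_tailed: bool) -> None:
        resid = field.extras.pop("residuals")
        smooth = estimate_fwhm(resid)
        threshold = rft.rft_critical_threshold(
            field.kind, field.df, smooth.resels, self.alpha, two_tailed=two_tailed
        )
        clusters = cluster_inference(field, threshold, smooth)
        self._store(field, smooth, threshold, clusters, None)

    def _finish_permutation(
        self,
        field: StatField,
        builder: Callable[[np.ndarray], np.ndarray],
        perms: np.ndarray,
        exact: bool,
        two_tailed: bool,
    ) -> None:
        result, observed, p_max = permutation_inference(
            builder, perms, alpha=self.alpha, two_tailed=two_tailed
        )
        result.exact = exact
        clusters = permutation_clusters(observed, result, field.Q)
        resid = field.extras.pop("residuals", None)
        smooth = estimate_fwhm(resid) if resid is not None else None
        self.p_max_ = p_max
        self._store(field, smooth, result.threshold, clusters, result)

    def _store(self, field, smooth, threshold, clusters, permutation) -> None:
        self.field_ = field
        self.statistic_ = field.values
        self.df_ = field.df
        self.smoothness_ = smooth
        self.fwhm_ = smooth.fwhm if smooth is not None else None
        self.resels_ = smooth.resels if smooth is not None else None
        self.threshold_ = threshold
        self.clusters_ = clusters
        self.permutation_ = permutation
        self.significant_ = len(clusters) > 0

    def summary(self) -> dict:
        """JSON-serializable record of the fitted inference."""
        out = {
            "field": self.field_.to_dict(),
            "threshold": self.threshold_.to_dict(),
            "clusters": [c.to_dict() for c in self.clusters_],
            "significant": bool(self.significant_),
        }
        if self.smoothness_ is not None:
            out["smoothness"] = self.smoothness_.to_dict()
        if self.permutation_ is not None:
            out["permutation"] = {
                "n_perm": int(self.permutation_.n_perm),
                "exact": bool(self.permutation_.exact),
                "p_max": float(getattr(self, "p_max_", np.nan)),
            }
        return out


class TwoSampleTSPM(_BaseSPM):
    """SPM{t}: two-sample t field with RFT or permutation inference.

    The statistic at each node is the pooled-variance unpaired t of group A
    minus group B; residual fields (deviations from the group means) feed
    the smoothness estimate that sets the RFT critical threshold.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        two_tailed: bool = True,
        method: str = "rft",
        n_perm: int = DEFAULT_N_PERM,
        max_enum: int = DEFAULT_MAX_ENUM,
        random_state: int | None = 0,
        var_floor: float = DEFAULT_VAR_FLOOR,
    ) -> None:
        self.alpha = alpha
        self.two_tailed = two_tailed
        self.method = method
        self.n_perm = n_perm
        self.max_enum = max_enum
        self.random_state = random_state
        self.var_floor = var_floor

    def fit(self, groupA: np.ndarray, groupB: np.ndarray) -> "TwoSampleTSPM":
        A = np.atleast_2d(np.asarray(groupA, float))
        B = np.atleast_2d(np.asarray(groupB, float))
        field = two_sample_t_field(A, B, var_floor=self.var_floor)
        if self.method == "rft":
            self._finish_rft(field, self.two_tailed)
        elif self.method == "permutation":
            n1 = A.shape[0]
            stacked = np.vstack([A, B])
            perms, exact = group_permutations(
                n1, B.shape[0], self.n_perm, self.max_enum, self.random_state or 0
            )

            def builder(P: np.ndarray) -> np.ndarray:
                out = np.empty((P.shape[0], A.shape[1]))
                for b, row in enumerate(P):
                    out[b] = two_sample_t_field(
                        stacked[row[:n1]], stacked[row[n1:]], var_floor=self.var_floor
                    ).values
                return out

            self._finish_permutation(field, builder, perms, exact, self.two_tailed)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self


class HotellingT2SPM(_BaseSPM):
    """SPM{T2}: two-sample Hotelling T2 vector field with RFT inference."""

    def __init__(
        self,
        alpha: float = 0.05,
        method: str = "rft",
        n_perm: int = DEFAULT_N_PERM,
        max_enum: int = DEFAULT_MAX_ENUM,
        random_state: int | None = 0,
        ridge: float = DEFAULT_VAR_FLOOR,
    ) -> None:
        self.alpha = alpha
        self.method = method
        self.n_perm = n_perm
        self.max_enum = max_enum
        self.random_state = random_state
        self.ridge = ridge

    def fit(self, groupA: np.ndarray, groupB: np.ndarray) -> "HotellingT2SPM":
        A = np.asarray(groupA, float)
        B = np.asarray(groupB, float)
        field = hotelling_t2_field(A, B, ridge=self.ridge)
        if self.method == "rft":
            self._finish_rft(field, two_tailed=False)
        elif self.method == "permutation":
            n1 = A.shape[0]
            stacked = np.concatenate([A, B], axis=0)
            perms, exact = group_permutations(
                n1, B.shape[0], self.n_perm, self.max_enum, self.random_state or 0
            )

            def builder(P: np.ndarray) -> np.ndarray:
                out = np.empty((P.shape[0], field.Q))
                for b, row in enumerate(P):
                    out[b] = hotelling_t2_field(
                        stacked[row[:n1]], stacked[row[n1:]], ridge=self.ridge
                    ).values
                return out

            self._finish_permutation(field, builder, perms, exact, two_tailed=False)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self


class RegressionTSPM(_BaseSPM):
    """SnPM{t}: scalar-field linear regression on a covariate (permutation).

    Used as the post-hoc of the canonical-correlation vector test; RFT
    inference is also available for completeness.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        two_tailed: bool = True,
        method: str = "permutation",
        n_perm: int = DEFAULT_N_PERM,
        max_enum: int = DEFAULT_MAX_ENUM,
        random_state: int | None = 0,
        stat_cap: float = DEFAULT_STAT_CAP,
    ) -> None:
        self.alpha = alpha
        self.two_tailed = two_tailed
        self.method = method
        self.n_perm = n_perm
        self.max_enum = max_enum
        self.random_state = random_state
        self.stat_cap = stat_cap

    def fit(self, responses: np.ndarray, covariate: np.ndarray) -> "RegressionTSPM":
        Y = np.atleast_2d(np.asarray(responses, float))
        x = np.asarray(covariate, float)
        field = regression_t_field(Y, x, stat_cap=self.stat_cap)
        if self.method == "rft":
            self._finish_rft(field, self.two_tailed)
            return self
        if self.method != "permutation":
            raise ValueError(f"unknown method {self.method!r}")
        perms, exact = order_permutations(
            x.shape[0], self.n_perm, self.max_enum, self.random_state or 0
        )
        xc = x - x.mean()
        sxx = float(xc @ xc)
        Yc = Y - Y.mean(axis=0)
        df = Y.shape[0] - 2
        ssy = (Yc**2).sum(axis=0)

        def builder(P: np.ndarray) -> np.ndarray:
            # vectorized: slope_b = (x_perm_b . Yc)/sxx ; t from the exact
            # per-node residual sum of squares
            X = xc[P]  # (B, n)
            sxy = X @ Yc  # (B, Q)
            slope = sxy / sxx
            sse = ssy[None, :] - sxx * slope**2
            sse = np.maximum(sse, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = slope * np.sqrt(sxx) / np.sqrt(sse / df)
            t = np.nan_to_num(t, nan=0.0, posinf=self.stat_cap, neginf=-self.stat_cap)
            return np.clip(t, -self.stat_cap, self.stat_cap)

        self._finish_permutation(field, builder, perms, exact, self.two_tailed)
        return self


class CanonicalCorrelationSnPM(_BaseSPM):
    """SnPM{X2}: canonical correlation of a component vector with a covariate.

    Inference is nonparametric only: the covariate vector is permuted and
    the max-X2 null distribution sets the critical threshold and cluster
    extent p-values.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_perm: int = DEFAULT_N_PERM,
        max_enum: int = DEFAULT_MAX_ENUM,
        random_state: int | None = 0,
        stat_cap: float = DEFAULT_STAT_CAP,
    ) -> None:
        self.alpha = alpha
        self.n_perm = n_perm
        self.max_enum = max_enum
        self.random_state = random_state
        self.stat_cap = stat_cap

    def fit(self, responses: np.ndarray, covariate: np.ndarray) -> "CanonicalCorrelationSnPM":
        Y = np.asarray(responses, float)
        if Y.ndim == 2:
            Y = Y[:, :, None]
        x = np.asarray(covariate, float)
        field = cca_x2_field(Y, x, stat_cap=self.stat_cap)
        n, Q, p = Y.shape
        perms, exact = order_permutations(n, self.n_perm, self.max_enum, self.random_state or 0)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        Yc = Y - Y.mean(axis=0)
        syy = np.einsum("nqp,nqr->qpr", Yc, Yc)
        w, V = np.linalg.eigh(syy)
        w = np.maximum(w, DEFAULT_VAR_FLOOR)
        syy_inv = np.einsum("qpr,qr,qsr->qps", V, 1.0 / w, V)
        coef = n - 1.0 - (p + 2.0) / 2.0

        def builder(P: np.ndarray) -> np.ndarray:
            X = xc[P]  # (B, n)
            sxy = np.einsum("bn,nqp->bqp", X, Yc)
            r2 = np.einsum("bqp,qps,bqs->bq", sxy, syy_inv, sxy) / sxx
            r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
            return np.minimum(-coef * np.log1p(-r2), self.stat_cap)

        self._finish_permutation(field, builder, perms, exact, two_tailed=False)
        return self
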