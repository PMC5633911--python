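"""Random-field-theory thresholds and cluster inference for 1D statistic fields.

A smooth statistic field z(q) sampled on Q nodes with smoothness FWHM (in
nodes) occupies R = (Q-1)/FWHM resels.  The family-wise exceedance
probability of its maximum is approximated by the expected Euler
characteristic of the excursion set,

    P(max z > u)  ~  rho_0(u) + kappa * rho_1(u),      kappa = sqrt(4 ln 2) R,

where rho_0 is the pointwise survival function and rho_1 the unit-roughness
1D EC density of the field type (Worsley's unified formulas).  The
Hotelling T2 field is handled through its union-intersection representation
T2(q) = max_{a in S^(p-1)} t_a(q)^2: the expected EC over the product space
[0, L] x S^(p-1) of the t field with m degrees of freedom yields the exact
T2 densities as Lipschitz-Killing-weighted sums of higher-order t densities,

    rho_1^{T2}(u) = sum_j  L_j(S^(p-1)) * rho_{j+1}^{t,m}(sqrt(u)),

with L_j the intrinsic volumes of the unit (p-1)-sphere.  The pointwise
term uses the exact T2 -> F distributional identity.

Cluster-level p-values use the classic 1D extent approximation: with
expected cluster count E[m] = kappa * rho_1(u) and expected excursion size
E[N] = Q * rho_0(u) nodes, the extent of a single cluster is modelled as
P(n >= k) = exp(-beta k^2), beta = (Gamma(3/2) E[m]/E[N])^2, and the
cluster p-value is 1 - exp(-E[m] * P(n >= k)).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special, stats

from .datatypes import CriticalThreshold

_SQRT_4LN2 = math.sqrt(4.0 * math.log(2.0))
_TWO_PI = 2.0 * math.pi

KINDS = ("gauss", "t", "chi2", "T2")


# ---------------------------------------------------------------------------
# pointwise survival functions
# ---------------------------------------------------------------------------

def _t2_to_f(u: float, p: int, m: float) -> float:
    """Map a Hotelling T2 value to the equivalent F value."""
    return u * (m - p + 1.0) / (p * m)


def sf_pointwise(u, kind: str, df) -> float:
    """Node-wise (single-test) survival function of the statistic."""
    u = np.asarray(u, dtype=float)
    if kind == "gauss":
        return stats.norm.sf(u)
    if kind == "t":
        return stats.t.sf(u, df)
    if kind == "chi2":
        return stats.chi2.sf(u, df)
    if kind == "T2":
        p, m = int(df[0]), float(df[1])
        if m - p + 1.0 <= 0:
            raise ValueError("T2 needs error df m >= p")
        return stats.f.sf(_t2_to_f(u, p, m), p, m - p + 1.0)
    raise ValueError(f"unknown field kind {kind!r}")


def isf_pointwise(alpha: float, kind: str, df) -> float:
    """Node-wise upper-alpha quantile of the statistic."""
    if kind == "gauss":
        return float(stats.norm.isf(alpha))
    if kind == "t":
        return float(stats.t.isf(alpha, df))
    if kind == "chi2":
        return float(stats.chi2.isf(alpha, df))
    if kind == "T2":
        p, m = int(df[0]), float(df[1])
        f = stats.f.isf(alpha, p, m - p + 1.0)
        return float(f * p * m / (m - p + 1.0))
    raise ValueError(f"unknown field kind {kind!r}")


# ---------------------------------------------------------------------------
# unit-roughness 1D EC densities
# ---------------------------------------------------------------------------

def _rho_t(j: int, x, m: float):
    """j-dimensional unit-roughness EC density of a t field with m df."""
    x = np.asarray(x, dtype=float)
    core = (1.0 + x * x / m) ** (-(m - 1.0) / 2.0)
    if j == 1:
        return core / _TWO_PI
    if j == 2:
        c = math.exp(special.gammaln((m + 1.0) / 2.0) - special.gammaln(m / 2.0))
        c /= math.sqrt(m / 2.0)
        return c * x * core / _TWO_PI ** 1.5
    if j == 3:
        return core * ((m - 1.0) / m * x * x - 1.0) / _TWO_PI ** 2
    raise NotImplementedError(f"t EC density of order {j} not implemented")


def _sphere_lk(n: int, j: int) -> float:
    """Intrinsic volume L_j of the unit n-sphere (0 when n-j is odd)."""
    if j > n or (n - j) % 2 == 1:
        return 0.0

    def s(k: int) -> float:  # surface area of the unit (k-1)-sphere
        return 2.0 * math.pi ** (k / 2.0) / math.gamma(k / 2.0)

    return 2.0 * math.comb(n, j) * s(n + 1) / s(n - j + 1)


def ec_density_1d(u, kind: str, df):
    """Unit-roughness 1D EC density rho_1(u) for the supported field types."""
    u = np.asarray(u, dtype=float)
    if kind == "gauss":
        return np.exp(-u * u / 2.0) / _TWO_PI
    if kind == "t":
        return _rho_t(1, u, float(df))
    if kind == "chi2":
        k = float(df)
        return (
            u ** ((k - 1.0) / 2.0)
            * np.exp(-u / 2.0)
            / (math.sqrt(_TWO_PI) * 2.0 ** ((k - 2.0) / 2.0) * math.gamma(k / 2.0))
        )
    if kind == "T2":
        p, m = int(df[0]), float(df[1])
        if p > 3:
            raise NotImplementedError("T2 EC density implemented for p <= 3 components")
        x = np.sqrt(np.maximum(u, 0.0))
        total = np.zeros_like(x)
        for j in range(p):
            lk = _sphere_lk(p - 1, j)
            if lk:
                total = total + lk * _rho_t(j + 1, x, m)
        return total
    raise ValueError(f"unknown field kind {kind!r}")


# ---------------------------------------------------------------------------
# field-wide inference
# ---------------------------------------------------------------------------

def sf_max(u, kind: str, df, resels: float):
    """EC approximation to P(max of the field > u) (one-tailed)."""
    if resels < 0:
        raise ValueError("resels must be >= 0")
    kappa = _SQRT_4LN2 * resels
    return sf_pointwise(u, kind, df) + kappa * ec_density_1d(u, kind, df)


def expected_clusters(u: float, kind: str, df, resels: float, tails: int = 1) -> float:
    """Expected number of supra-threshold clusters at height u."""
    return tails * _SQRT_4LN2 * resels * float(ec_density_1d(u, kind, df))


def rft_critical_threshold(
    kind: str,
    df,
    resels: float,
    alpha: float = 0.05,
    two_tailed: bool = False,
) -> CriticalThreshold:
    """Critical height u with P(max > u) = alpha under the smooth null.

    For two-tailed t-field inference alpha is split across the tails, so u
    solves 2 * P(max > u) = alpha for the one-tailed exceedance.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if two_tailed and kind not in ("gauss", "t"):
        raise ValueError(f"{kind} fields are one-tailed by construction")
    target = alpha / 2.0 if two_tailed else alpha

    def objective(u: float) -> float:
        return float(sf_max(u, kind, df, resels)) - target

    lo = isf_pointwise(min(target, 0.5), kind, df)
    lo = max(lo, 1e-12) if kind in ("chi2", "T2") else lo
    if objective(lo) < 0.0:  # already below target (can happen only if resels ~ 0)
        lo = lo - 1.0 if kind in ("gauss", "t") else lo / 2.0
    hi = lo + 1.0 if lo > 0 else 1.0
    for _ in range(200):
        if objective(hi) < 0.0:
            break
        hi = hi * 2.0 + 1.0
    else:
        raise ValueError(f"no finite RFT threshold for kind={kind}, df={df}, alpha={alpha}")
    u = optimize.brentq(objective, lo, hi, xtol=1e-12, rtol=1e-14)
    return CriticalThreshold(u=float(u), alpha=alpha, method="rft", two_tailed=two_tailed)


def cluster_p_value(
    extent_nodes: float,
    u: float,
    kind: str,
    df,
    resels: float,
    Q: int,
    tails: int = 1,
) -> float:
    """RFT cluster-extent p-value for a cluster of ``extent_nodes`` at height u."""
    if extent_nodes < 0:
        raise ValueError("cluster extent must be >= 0")
    e_m = expected_clusters(u, kind, df, resels, tails=tails)
    e_n = tails * Q * float(sf_pointwise(u, kind, df))
    if e_m <= 0.0 or e_n <= 0.0:
        return 1.0
    beta = (math.gamma(1.5) * e_m / e_n) ** 2
    p_size = math.exp(-beta * extent_nodes * extent_nodes)
    p = 1.0 - math.exp(-e_m * p_size)
    return float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))
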