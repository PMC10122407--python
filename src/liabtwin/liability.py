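"""Normal-liability primitives.

Binary diagnoses are modelled as a latent standard-normal liability exceeding
a prevalence-determined threshold.  Everything downstream (tetrachoric
correlations, ACE variance components, bivariate decompositions) reduces to
multivariate-normal rectangle probabilities over such thresholds, so this
module provides:

* prevalence <-> threshold conversion,
* bivariate-normal upper-quadrant probabilities (Genz's hybrid
  Gauss-Legendre / tail-transformed quadrature, absolute error < 1e-14),
* 3-4 dimensional rectangle probabilities by Genz's separation-of-variables
  transform integrated with a scrambled Sobol rule at a fixed seed, so
  results are bit-for-bit reproducible,
* maximum-likelihood tetrachoric correlation from a 2x2 table, and
* the reverse map from (prevalences, r, N) to an expected 2x2 table.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.linalg import cholesky as _cholesky
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

__all__ = [
    "Threshold",
    "RectangleQuery",
    "Table2x2",
    "TetrachoricEstimate",
    "threshold_from_prevalence",
    "bvn_upper",
    "mvn_rectangle",
    "tetrachoric_fit",
    "implied_table",
]

# |r| within this distance of 1 is treated as a boundary solution; keeps
# log-likelihoods finite while remaining far below any attainable precision.
BOUNDARY_TOL = 1e-6

# Fixed Sobol seed for the 3-4 dimensional lattice kernel. Changing it changes
# results in the 7th decimal at the default point count; it is part of the
# deterministic contract, not a tunable.
_QMC_SEED = 20230421
_QMC_POINTS = 1 << 13


@dataclasses.dataclass(frozen=True)
class Threshold:
    """Liability cut-point ``t`` (standard-normal units) with prevalence ``K``.

    ``K`` is the upper-tail area beyond ``t``; ``t`` is finite iff 0 < K < 1.
    """

    t: float
    K: float


@dataclasses.dataclass(frozen=True)
class RectangleQuery:
    """Upper-orthant query: P(X_i > lower_i) under correlation matrix ``corr``."""

    lower: np.ndarray
    corr: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "corr", corr)
        d = lower.shape[0]
        if corr.shape != (d, d):
            raise ValueError(f"corr shape {corr.shape} does not match {d} bounds")
        if not 2 <= d <= 4:
            raise ValueError(f"only 2-4 dimensions supported, got {d}")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("corr diagonal must be 1")


@dataclasses.dataclass(frozen=True)
class Table2x2:
    """Cross-classified counts; index 1 = affected (liability above threshold).

    ``n11`` both affected, ``n10`` row-trait only, ``n01`` column-trait only,
    ``n00`` neither.  Counts may be fractional (expected tables).
    """

    n11: float
    n10: float
    n01: float
    n00: float

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def row_margin(self) -> float:
        """Proportion affected on the row trait."""
        return (self.n11 + self.n10) / self.total

    @property
    def col_margin(self) -> float:
        return (self.n11 + self.n01) / self.total

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=float)


@dataclasses.dataclass(frozen=True)
class TetrachoricEstimate:
    r: float
    t_row: Threshold
    t_col: Threshold
    se: float
    at_boundary: bool
    loglik: float
    defined: bool = True


def threshold_from_prevalence(K: float) -> Threshold:
    """Liability threshold whose upper-tail standard-normal area equals ``K``."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {K!r}")
    return Threshold(t=float(-ndtri(K)), K=float(K))


# ---------------------------------------------------------------------------
# Bivariate normal upper quadrant (Genz, TVPACK BVND)
# ---------------------------------------------------------------------------

_GL6_W = np.array([0.1713244923791705, 0.3607615730481384, 0.4679139345726904])
_GL6_X = np.array([0.9324695142031522, 0.6612093864662647, 0.2386191860831970])
_GL12_W = np.array([0.04717533638651177, 0.1069393259953183, 0.1600783285433464,
                    0.2031674267230659, 0.2334925365383547, 0.2491470458134029])
_GL12_X = np.array([0.9815606342467191, 0.9041172563704750, 0.7699026741943050,
                    0.5873179542866171, 0.3678314989981802, 0.1252334085114692])
_GL20_W = np.array([0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
                    0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                    0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
                    0.1527533871307259])
_GL20_X = np.array([0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                    0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                    0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
                    0.07652652113349733])


def bvn_upper(h: float, k: float, r: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation ``r``.

    Genz's hybrid algorithm: Drezner-Wesolowsky quadrature on asin(r) for
    |r| < 0.925, a tail-variable transformation otherwise; max absolute error
    below 5e-16.  Handles infinite bounds and |r| = 1 exactly.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r!r}")
    if h == math.inf or k == math.inf:
        return 0.0
    if h == -math.inf:
        return 1.0 if k == -math.inf else float(ndtr(-k))
    if k == -math.inf:
        return float(ndtr(-h))
    if r == 0.0:
        return float(ndtr(-h) * ndtr(-k))

    tp = 2.0 * math.pi
    hk = h * k
    bvn = 0.0
    if abs(r) < 0.3:
        w, x = _GL6_W, _GL6_X
    elif abs(r) < 0.75:
        w, x = _GL12_W, _GL12_X
    else:
        w, x = _GL20_W, _GL20_X
    w = np.concatenate([w, w])
    x = np.concatenate([1.0 - x, 1.0 + x])

    if abs(r) < 0.925:
        hs = (h * h + k * k) / 2.0
        asr = math.asin(r) / 2.0
        sn = np.sin(asr * x)
        bvn = float(np.exp((sn * hk - hs) / (1.0 - sn**2)) @ w)
        bvn = bvn * asr / tp + float(ndtr(-h) * ndtr(-k))
    else:
        kk = k
        if r < 0.0:
            kk = -k
            hk = -hk
        if abs(r) < 1.0:
            as_ = (1.0 - r) * (1.0 + r)
            a = math.sqrt(as_)
            bs = (h - kk) ** 2
            c = (4.0 - hk) / 8.0
            d = (12.0 - hk) / 16.0
            asr = -(bs / as_ + hk) / 2.0
            if asr > -100.0:
                bvn = a * math.exp(asr) * (1.0 - c * (bs - as_) * (1.0 - d * bs / 5.0) / 3.0
                                           + c * d * as_**2 / 5.0)
            if -hk < 100.0:
                b = math.sqrt(bs)
                bvn -= (math.exp(-hk / 2.0) * math.sqrt(tp) * float(ndtr(-b / a)) * b
                        * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0))
            a /= 2.0
            xs = (a * x) ** 2
            rs = np.sqrt(1.0 - xs)
            asr_v = -(bs / xs + hk) / 2.0
            mask = asr_v > -100.0
            if np.any(mask):
                xm, rm = xs[mask], rs[mask]
                ep = np.exp(-hk * (1.0 - rm) / (2.0 * (1.0 + rm))) / rm
                sp_v = 1.0 + c * xm * (1.0 + d * xm)
                bvn += a * float(w[mask] @ (np.exp(asr_v[mask]) * (ep - sp_v)))
            bvn = -bvn / tp
        if r > 0.0:
            bvn += float(ndtr(-max(h, kk)))
        else:
            bvn = -bvn + max(0.0, float(ndtr(-h) - ndtr(k)))
    return max(0.0, min(1.0, bvn))


# ---------------------------------------------------------------------------
# 3-4 dimensional rectangles (Genz transform + scrambled Sobol)
# ---------------------------------------------------------------------------


def _psd_cholesky(corr: np.ndarray) -> np.ndarray:
    try:
        return _cholesky(corr, lower=True)
    except np.linalg.LinAlgError:
        pass
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigvals.min():.3e})"
        )
    clipped = (eigvecs * np.clip(eigvals, 1e-12, None)) @ eigvecs.T
    return _cholesky(clipped, lower=True)


def sobol_points(d: int, n_points: int = _QMC_POINTS, seed: int = _QMC_SEED) -> np.ndarray:
    """Scrambled Sobol points used by the 3-4-D kernel; cacheable across calls."""
    sob = qmc.Sobol(d=d, scramble=True, rng=np.random.default_rng(seed))
    return sob.random(n_points)


def _orthant_qmc(lower: np.ndarray, corr: np.ndarray, n_points: int, seed: int,
                 u: np.ndarray | None = None) -> float:
    """P(X > lower) by Genz's sequentially-conditioned transform on Sobol points."""
    d = lower.shape[0]
    # Condition on the most truncating variables first (lowers QMC variance).
    order = np.argsort(-lower)
    a = lower[order]
    C = _psd_cholesky(corr[np.ix_(order, order)])

    if u is None:
        u = sobol_points(max(d - 1, 1), n_points, seed)
    n_points = u.shape[0]

    # work with Y = -X so the orthant becomes a lower one: P(Y < -a)
    b = -a
    f = np.full(n_points, float(ndtr(b[0] / C[0, 0])))
    y = np.empty((n_points, d - 1))
    e_prev = f.copy()
    for i in range(1, d):
        # sample y_{i-1} within its conditional slice
        q = np.clip(u[:, i - 1] * e_prev, 1e-15, 1.0 - 1e-15)
        y[:, i - 1] = ndtri(q)
        mu = y[:, :i] @ C[i, :i]
        e_prev = ndtr((b[i] - mu) / C[i, i])
        f *= e_prev
    return float(np.mean(f))


def mvn_rectangle(q: RectangleQuery, n_points: int = _QMC_POINTS,
                  seed: int = _QMC_SEED) -> float:
    """Upper-orthant probability P(X_i > lower_i) for dimensions 2-4.

    2-D uses the closed quadrature (error < 1e-14); 3-4-D the deterministic
    Sobol kernel (error ~1e-7 at the default point count).  Coordinates with
    an infinite lower bound are marginalized out first.
    """
    lower = np.asarray(q.lower, dtype=float)
    corr = np.asarray(q.corr, dtype=float)
    finite = lower > -math.inf
    if not finite.all():
        lower = lower[finite]
        corr = corr[np.ix_(finite, finite)]
    d = lower.shape[0]
    if d == 0:
        return 1.0
    if d == 1:
        return float(ndtr(-lower[0]))
    if d == 2:
        return bvn_upper(lower[0], lower[1], float(corr[0, 1]))
    # validate PSD up front so the error names the eigenvalue
    _psd_cholesky(corr)
    return _orthant_qmc(lower, corr, n_points, seed)


# ---------------------------------------------------------------------------
# Tetrachoric correlation
# ---------------------------------------------------------------------------


def _cell_probs(t1: float, t2: float, r: float) -> np.ndarray:
    p11 = bvn_upper(t1, t2, r)
    p1_ = float(ndtr(-t1))
    p_1 = float(ndtr(-t2))
    p10 = max(p1_ - p11, 0.0)
    p01 = max(p_1 - p11, 0.0)
    p00 = max(1.0 - p11 - p10 - p01, 0.0)
    return np.array([p11, p10, p01, p00])


def _table_nll(params: np.ndarray, counts: np.ndarray) -> float:
    z, t1, t2 = params
    r = math.tanh(z)
    p = np.clip(_cell_probs(t1, t2, r), 1e-12, 1.0)
    return -float(counts @ np.log(p))


def tetrachoric_fit(table: Table2x2, n_effective: float | None = None) -> TetrachoricEstimate:
    """ML tetrachoric correlation with jointly estimated thresholds.

    Maximizes the multinomial likelihood of the four cell probabilities
    implied by a bivariate normal with free correlation and thresholds.
    ``n_effective`` rescales the standard error when the table was built by
    double entry (each pair contributes twice).
    """
    counts = np.array([table.n11, table.n10, table.n01, table.n00], dtype=float)
    if (counts < 0).any():
        raise ValueError("cell counts must be nonnegative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("table total must be positive")

    pr = table.row_margin
    pc = table.col_margin
    if pr <= 0 or pr >= 1 or pc <= 0 or pc >= 1:
        # a trait never / always present: correlation undefined
        nan_thr = Threshold(t=math.nan, K=pr)
        return TetrachoricEstimate(r=math.nan, t_row=nan_thr,
                                   t_col=Threshold(t=math.nan, K=pc),
                                   se=math.nan, at_boundary=False,
                                   loglik=math.nan, defined=False)

    t1_0 = threshold_from_prevalence(pr).t
    t2_0 = threshold_from_prevalence(pc).t
    # moment start: coarse profile over r at fixed margins
    grid = np.linspace(-0.95, 0.95, 39)
    nlls = [_table_nll(np.array([math.atanh(r), t1_0, t2_0]), counts) for r in grid]
    r0 = grid[int(np.argmin(nlls))]

    res = minimize(_table_nll, x0=np.array([math.atanh(r0), t1_0, t2_0]),
                   args=(counts,), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    z, t1, t2 = res.x
    r = math.tanh(z)
    at_boundary = abs(r) >= 1.0 - BOUNDARY_TOL
    if at_boundary:
        r = math.copysign(1.0, r)

    loglik = -res.fun
    n_eff = n if n_effective is None else n_effective
    se = _tetrachoric_se(res.x, counts, n, n_eff, at_boundary)
    return TetrachoricEstimate(
        r=float(r),
        t_row=Threshold(t=float(t1), K=float(ndtr(-t1))),
        t_col=Threshold(t=float(t2), K=float(ndtr(-t2))),
        se=se, at_boundary=at_boundary, loglik=float(loglik))


def _tetrachoric_se(x: np.ndarray, counts: np.ndarray, n: float, n_eff: float,
                    at_boundary: bool) -> float:
    if at_boundary:
        return math.nan
    h = 1e-4
    dim = 3
    H = np.zeros((dim, dim))
    f0 = _table_nll(x, counts)
    for i in range(dim):
        for j in range(i, dim):
            xi, xj = np.zeros(dim), np.zeros(dim)
            xi[i] = h
            xj[j] = h
            fpp = _table_nll(x + xi + xj, counts)
            fpm = _table_nll(x + xi - xj, counts)
            fmp = _table_nll(x - xi + xj, counts)
            fmm = _table_nll(x - xi - xj, counts)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        var_z = cov[0, 0] * (n / n_eff)
        if var_z <= 0:
            return math.nan
        r = math.tanh(x[0])
        return math.sqrt(var_z) * (1.0 - r * r)
    except np.linalg.LinAlgError:
        return math.nan


def implied_table(K_row: float, K_col: float, r: float, N: float) -> Table2x2:
    """Expected (fractional) 2x2 counts under a bivariate normal liability."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r!r}")
    if N <= 0:
        raise ValueError("N must be positive")
    t1 = threshold_from_prevalence(K_row).t
    t2 = threshold_from_prevalence(K_col).t
    p = _cell_probs(t1, t2, r)
    p = p / p.sum()  # cells sum to N exactly
    c = N * p
    return Table2x2(n11=c[0], n10=c[1], n01=c[2], n00=c[3])
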