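"""Sample-based rarefaction and Chao2 accumulation curves.

The observed-richness curve is the analytic hypergeometric expectation
over subsets of pellets (equivalent to exhaustively averaging all
C(m, n) subsets); the Chao2 curve is estimated by seeded resampling of
pellet subsets, since Chao2 of a subsample has no simple closed form.
Curves are averaged across individuals with standard errors of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from dietrep.data import IncidenceMatrix, incidence_counts

__all__ = [
    "AccumulationCurve",
    "expected_richness",
    "chao2",
    "chao2_curve",
    "mean_curve",
    "pellets_for_fraction",
]


@dataclass
class AccumulationCurve:
    """Across-individual mean accumulation curve at n = 1..m pellets."""

    n: np.ndarray
    mean_obs: np.ndarray
    se_obs: np.ndarray
    mean_chao2: np.ndarray
    se_chao2: np.ndarray

    @property
    def m(self) -> int:
        return int(self.n[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "mean_obs": self.mean_obs,
                "se_obs": self.se_obs,
                "mean_chao2": self.mean_chao2,
                "se_chao2": self.se_chao2,
            }
        )


def _log_comb(x: np.ndarray, n: int) -> np.ndarray:
    # log C(x, n), -inf where x < n
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = gammaln(x + 1) - gammaln(n + 1) - gammaln(x - n + 1)
    return np.where(x >= n, out, -np.inf)


def expected_richness(matrix: IncidenceMatrix, n: int) -> float:
    """Expected species count in n pellets drawn without replacement.

    E[S(n)] = sum_t [1 - C(m - m_t, n) / C(m, n)], with C(x, n) = 0 for
    x < n; exact, no resampling.  At n = m this is S_obs.
    """
    m = matrix.m
    if not (1 <= n <= m):
        raise ValueError(f"n must be in [1, {m}], got {n}")
    m_t = incidence_counts(matrix).m_t
    m_t = m_t[m_t > 0]
    log_miss = _log_comb(m - m_t, n) - _log_comb(np.array([m]), n)
    return float(np.sum(1.0 - np.exp(log_miss)))


def chao2(s_obs: int, q1: int, q2: int, m: int) -> float:
    """Bias-corrected incidence-based Chao2 richness estimate.

    S + ((m-1)/m) * Q1^2 / (2 Q2) when Q2 > 0, with the
    Q1(Q1-1) / 2 fallback at Q2 = 0; always >= S_obs.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    corr = (m - 1) / m
    if q2 > 0:
        return s_obs + corr * q1 * q1 / (2 * q2)
    return s_obs + corr * q1 * (q1 - 1) / 2


def chao2_of(matrix: IncidenceMatrix | np.ndarray, m: int | None = None) -> float:
    """Chao2 of a full incidence matrix (convenience wrapper)."""
    c = incidence_counts(matrix)
    if m is None:
        mat = matrix.matrix if isinstance(matrix, IncidenceMatrix) else matrix
        m = mat.shape[0]
    return chao2(c.s_obs, c.q1, c.q2, m)


def chao2_curve(
    matrix: IncidenceMatrix,
    n: int,
    reps: int = 200,
    seed: int | None = None,
) -> float:
    """Mean Chao2 over ``reps`` subsamples of n pellets (without
    replacement).  At n = m the full-matrix Chao2 is returned exactly."""
    m = matrix.m
    if not (1 <= n <= m):
        raise ValueError(f"n must be in [1, {m}], got {n}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n == m:
        return chao2_of(matrix)
    rng = np.random.default_rng(seed)
    mat = matrix.matrix
    vals = np.empty(reps)
    for b in range(reps):
        rows = rng.choice(m, size=n, replace=False)
        m_t = mat[rows].sum(axis=0)
        vals[b] = chao2(
            int((m_t > 0).sum()), int((m_t == 1).sum()), int((m_t == 2).sum()), n
        )
    return float(vals.mean())


def mean_curve(
    matrices: list[IncidenceMatrix],
    reps: int = 200,
    seed: int | None = None,
) -> AccumulationCurve:
    """Across-individual mean accumulation curve.

    n runs from 1 to the smallest m across individuals.  SE is the
    sample SD across individuals divided by sqrt(I); with one individual
    the SE is reported as 0 (convention).
    """
    if not matrices:
        raise ValueError("need at least one individual")
    m_min = min(mx.m for mx in matrices)
    rng = np.random.default_rng(seed)
    ns = np.arange(1, m_min + 1)
    obs = np.empty((len(matrices), m_min))
    cha = np.empty((len(matrices), m_min))
    for i, mx in enumerate(matrices):
        sub_seed = rng.integers(2**63)
        for idx, n in enumerate(ns):
            obs[i, idx] = expected_richness(mx, int(n))
            cha[i, idx] = chao2_curve(mx, int(n), reps=reps, seed=int(sub_seed) + idx)
    I = len(matrices)
    if I > 1:
        se_obs = obs.std(axis=0, ddof=1) / np.sqrt(I)
        se_cha = cha.std(axis=0, ddof=1) / np.sqrt(I)
    else:
        se_obs = np.zeros(m_min)
        se_cha = np.zeros(m_min)
    return AccumulationCurve(ns, obs.mean(axis=0), se_obs, cha.mean(axis=0), se_cha)


def pellets_for_fraction(curve: AccumulationCurve, fraction: float) -> int:
    """Smallest n whose mean observed richness reaches ``fraction`` of
    the full-m mean observed richness."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    target = fraction * curve.mean_obs[-1]
    idx = np.nonzero(curve.mean_obs >= target - 1e-12)[0]
    return int(curve.n[idx[0]])
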