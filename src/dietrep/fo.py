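"""Frequency-of-occurrence descriptors and the pellet-subsampling
Monte-Carlo error procedure.

FO descriptors (per taxon):

- ``fo_tot``: fraction of individuals in which the taxon was detected
  across all m pellets;
- ``fo_pel``: mean, over the individuals detecting it, of the fraction
  of their pellets containing it (missing when fo_tot = 0);
- ``fo_pool``: fraction of individuals whose pooled sample detects it;
- ``fo_pellet_overall``: fraction of all pellets containing it.

The error procedure draws n pellets per individual WITH replacement
(the study's convention; without-replacement available), scores each
individual positive if any drawn pellet contains the taxon, and repeats
R times to build the empirical distribution of FO estimates at each n.
One set of pellet draws per repetition is shared across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dietrep.data import (
    CollapseMode,
    DetectionCube,
    IncidenceMatrix,
    PoolBlock,
    collapse_pcrs,
    collapse_pool,
)

__all__ = [
    "ErrorDistribution",
    "fo_table",
    "resample_fo",
    "error_curve",
    "pool_error",
    "paired_t",
    "exact_mean_fo",
]


@dataclass
class ErrorDistribution:
    """Summary of resampled FO estimates per (taxon, n).

    ``table`` is tidy with columns (taxon, n, mean_fo, mean_error,
    sd_error); errors are relative to the full-m FO when
    ``error_kind == "relative"``, simple differences otherwise.
    """

    table: pd.DataFrame
    error_kind: str
    reps: int

    def mean_error_by_n(self) -> pd.Series:
        """Across-taxon mean error at each n."""
        return self.table.groupby("n")["mean_error"].mean()


def _matrices(data, collapse: CollapseMode | None) -> list[IncidenceMatrix]:
    if isinstance(data, DetectionCube):
        return collapse_pcrs(data, collapse or CollapseMode("union"))
    return list(data)


def fo_table(
    cube: DetectionCube | Sequence[IncidenceMatrix],
    pools: PoolBlock | np.ndarray | None = None,
    collapse: CollapseMode | None = None,
) -> pd.DataFrame:
    """Compute all four FO descriptors after PCR collapse.

    ``cube`` may be a DetectionCube (collapsed here with ``collapse``)
    or pre-collapsed incidence matrices; ``pools`` likewise a PoolBlock
    or a pre-collapsed boolean (I, T) array, or None (fo_pool = NaN).
    """
    mats = _matrices(cube, collapse)
    taxa = mats[0].taxa or [str(t) for t in range(mats[0].matrix.shape[1])]
    T = len(taxa)
    I = len(mats)
    m_it = np.array([mx.matrix.sum(axis=0) for mx in mats], dtype=float)  # (I, T)
    ms = np.array([mx.m for mx in mats], dtype=float)
    detected_in = m_it > 0
    fo_tot = detected_in.mean(axis=0)
    frac = m_it / ms[:, None]
    n_det = detected_in.sum(axis=0)
    with np.errstate(invalid="ignore"):
        fo_pel = np.where(
            n_det > 0,
            (frac * detected_in).sum(axis=0) / np.maximum(n_det, 1),
            np.nan,
        )
    fo_pellet_overall = m_it.sum(axis=0) / ms.sum()

    if pools is None:
        fo_pool = np.full(T, np.nan)
    else:
        pool_mat = (
            collapse_pool(pools, collapse or CollapseMode("union"))
            if isinstance(pools, PoolBlock)
            else np.asarray(pools, dtype=bool)
        )
        fo_pool = pool_mat.mean(axis=0)

    return pd.DataFrame(
        {
            "taxon": taxa,
            "fo_tot": fo_tot,
            "fo_pel": fo_pel,
            "fo_pool": fo_pool,
            "fo_pellet_overall": fo_pellet_overall,
        }
    ).set_index("taxon")


def _draw_indices(
    rng: np.random.Generator, m: int, n: int, reps: int, replace: bool
) -> np.ndarray:
    if replace:
        return rng.integers(m, size=(reps, n))
    if n > m:
        raise ValueError(f"cannot draw {n} pellets from {m} without replacement")
    return rng.random((reps, m)).argsort(axis=1)[:, :n]


def resample_fo(
    matrices: Sequence[IncidenceMatrix],
    taxon: int | str,
    n: int,
    reps: int = 10_000,
    seed: int | None = None,
    replace: bool = True,
) -> np.ndarray:
    """Empirical distribution of FO estimates from n pellets per
    individual; returns ``reps`` estimates in [0, 1].

    Matrices must already be PCR-collapsed to one layer.  Each
    repetition draws n pellets per individual (with replacement by
    default) and marks the individual positive if any drawn pellet
    contains the taxon.
    """
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    mats = list(matrices)
    if isinstance(taxon, str):
        taxon = mats[0].taxa.index(taxon)
    rng = np.random.default_rng(seed)
    positives = np.zeros(reps, dtype=np.int64)
    for mx in mats:
        col = mx.matrix[:, taxon]
        idx = _draw_indices(rng, mx.m, n, reps, replace)
        positives += col[idx].any(axis=1)
    return positives / len(mats)


def _resample_all(
    mats: list[IncidenceMatrix],
    n: int,
    reps: int,
    rng: np.random.Generator,
    replace: bool,
) -> np.ndarray:
    """(reps, T) FO estimates; one pellet draw per rep shared by all taxa."""
    T = mats[0].matrix.shape[1]
    positives = np.zeros((reps, T), dtype=np.int64)
    for mx in mats:
        idx = _draw_indices(rng, mx.m, n, reps, replace)
        positives += mx.matrix[idx].any(axis=1)
    return positives / len(mats)


def exact_mean_fo(mats: Sequence[IncidenceMatrix], n: int) -> np.ndarray:
    """Closed-form E[FO-hat(n)] under with-replacement draws:
    (1/I) sum_i [1 - (1 - m_it/m_i)^n].  Used as an independent check of
    :func:`resample_fo`."""
    probs = [1.0 - (1.0 - mx.matrix.mean(axis=0)) ** n for mx in mats]
    return np.mean(probs, axis=0)


def error_curve(
    cube: DetectionCube | Sequence[IncidenceMatrix],
    taxa: Sequence[int | str] | None = None,
    n_range: Sequence[int] | None = None,
    reps: int = 10_000,
    seed: int | None = None,
    error_kind: str = "relative",
    collapse: CollapseMode | None = None,
    replace: bool = True,
) -> ErrorDistribution:
    """FO estimation error per taxon and pellet sample size n.

    The error at n is FO_m - mean(FO-hat_n), divided by FO_m for the
    relative kind; per-repetition errors feed sd_error.  Taxa default to
    all taxa with nonzero full-m FO (others have no defined relative
    error and are excluded).
    """
    if error_kind not in ("relative", "absolute"):
        raise ValueError("error_kind must be 'relative' or 'absolute'")
    mats = _matrices(cube, collapse)
    names = mats[0].taxa or [str(t) for t in range(mats[0].matrix.shape[1])]
    m_it = np.array([mx.matrix.sum(axis=0) for mx in mats])
    fo_m = (m_it > 0).mean(axis=0)
    if taxa is None:
        t_idx = np.nonzero(fo_m > 0)[0]
    else:
        t_idx = np.array(
            [names.index(t) if isinstance(t, str) else int(t) for t in taxa]
        )
        if (fo_m[t_idx] == 0).any() and error_kind == "relative":
            raise ValueError("relative error undefined for taxa with zero FO")
    if n_range is None:
        n_range = range(1, min(mx.m for mx in mats))

    rng = np.random.default_rng(seed)
    rows = []
    for n in n_range:
        est = _resample_all(mats, int(n), reps, rng, replace)[:, t_idx]
        err = fo_m[t_idx][None, :] - est
        if error_kind == "relative":
            err = err / fo_m[t_idx][None, :]
        rows.append(
            pd.DataFrame(
                {
                    "taxon": [names[t] for t in t_idx],
                    "n": int(n),
                    "mean_fo": est.mean(axis=0),
                    "mean_error": err.mean(axis=0),
                    "sd_error": err.std(axis=0, ddof=1) if reps > 1 else 0.0,
                }
            )
        )
    return ErrorDistribution(
        table=pd.concat(rows, ignore_index=True), error_kind=error_kind, reps=reps
    )


def pool_error(fo: pd.DataFrame, error_kind: str = "relative") -> pd.Series:
    """Per-taxon error of the pool FO against the full-pellet FO,
    (fo_tot - fo_pool) / fo_tot (or the simple difference), over taxa
    with fo_tot > 0."""
    if error_kind not in ("relative", "absolute"):
        raise ValueError("error_kind must be 'relative' or 'absolute'")
    sub = fo[fo["fo_tot"] > 0]
    err = sub["fo_tot"] - sub["fo_pool"]
    if error_kind == "relative":
        err = err / sub["fo_tot"]
    return err.rename("pool_error")


class PairedT(NamedTuple):
    t: float
    df: int
    p: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedT:
    """Classical paired t-test on x - y (two-sided), df = len - 1.

    Identical vectors return (t=0, p=1) by convention; nonzero
    constant differences (zero variance, nonzero mean) are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d vectors, length >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return PairedT(0.0, len(x) - 1, 1.0)
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(x, y)
    return PairedT(float(res.statistic), len(x) - 1, float(res.pvalue))
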