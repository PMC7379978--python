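"""Nested three-level PERMANOVA (individual / pellet within individual /
PCR within pellet) on presence/absence profiles, with residual-
randomization (RRPP) significance.

Distance is squared Euclidean on the raw 0/1 rows, so sums of squares
are computed directly in data space (equivalently from the Gower-
centered squared-distance matrix).  Terms are strictly nested, so the
decomposition is obtained from group means:

    SS_ind = sum_units ||ybar_i  - ybar||^2
    SS_pel = sum_units ||ybar_ij - ybar_i||^2
    SS_pcr = sum_units ||y_ijk   - ybar_ij||^2

Each sampling unit is a single PCR, so the residual of the saturated
model is zero; under the default ``next_nested`` F scheme each term is
tested against the next nested mean square, and the deepest term (which
has no denominator) uses its own mean square as permutation statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dietrep.data import DetectionCube

__all__ = [
    "PermanovaTable",
    "cube_to_units",
    "nested_ss",
    "pseudo_f",
    "rrpp_test",
    "two_group_permanova",
]

TERMS = ["individual", "individual:pellet", "individual:pellet:pcr"]


@dataclass
class PermanovaTable:
    """ANOVA-style table with rows for each nested term, residual, total."""

    table: pd.DataFrame  # index: TERMS + residual + total
    f_scheme: str = "next_nested"
    n_perm: int | None = None

    def __getitem__(self, key):
        return self.table.loc[key]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


class _NestedDesign:
    """Precomputed sort order and group bookkeeping for fast repeated
    SS decompositions (units stay fixed; only Y rows change)."""

    def __init__(self, individual, pellet):
        individual = np.asarray(individual)
        pellet = np.asarray(pellet)
        if individual.shape != pellet.shape:
            raise ValueError("label vectors must have equal length")
        self.N = len(individual)
        ind_codes, _ = pd.factorize(individual, sort=True)
        # pellet groups are (individual, pellet) pairs: nesting enforced
        pel_keys = pd.MultiIndex.from_arrays([individual, pellet])
        pel_codes, _ = pd.factorize(pel_keys, sort=True)
        self.order = np.lexsort((pel_codes, ind_codes))
        pel_sorted = pel_codes[self.order]
        ind_sorted = ind_codes[self.order]
        # starts of each pellet block in sorted unit order
        self.pel_starts = np.nonzero(
            np.r_[True, pel_sorted[1:] != pel_sorted[:-1]]
        )[0]
        self.pel_counts = np.diff(np.r_[self.pel_starts, self.N])
        ind_of_pel = ind_sorted[self.pel_starts]
        self.ind_starts = np.nonzero(
            np.r_[True, ind_of_pel[1:] != ind_of_pel[:-1]]
        )[0]
        pel_block = np.r_[self.pel_starts, self.N]
        self.ind_counts = (
            pel_block[np.r_[self.ind_starts[1:], len(self.pel_starts)]]
            - pel_block[self.ind_starts]
        )
        self.nP = len(self.pel_starts)
        self.nI = len(self.ind_starts)
        self.df_ind = self.nI - 1
        self.df_pel = self.nP - self.nI
        self.df_pcr = self.N - self.nP
        # unit -> group code lookups (original order) for fitted values
        self.ind_codes = ind_codes
        self.pel_codes = pel_codes

    def decompose(self, Y: np.ndarray) -> tuple[float, float, float, float]:
        """(SS_ind, SS_pel, SS_pcr, SS_total) for unit x taxon Y."""
        Ys = Y[self.order]
        t0 = float(np.einsum("ij,ij->", Ys, Ys))
        pel_sums = np.add.reduceat(Ys, self.pel_starts, axis=0)
        ind_sums = np.add.reduceat(pel_sums, self.ind_starts, axis=0)
        grand = ind_sums.sum(axis=0)
        sg = float(((pel_sums**2).sum(axis=1) / self.pel_counts).sum())
        si = float(((ind_sums**2).sum(axis=1) / self.ind_counts).sum())
        sm = float(grand @ grand) / self.N
        return si - sm, sg - si, t0 - sg, t0 - sm

    def group_means(self, Y: np.ndarray, level: str) -> np.ndarray:
        """Per-unit fitted values at a grouping level ('grand',
        'individual' or 'pellet'), in original unit order."""
        if level == "grand":
            return np.broadcast_to(Y.mean(axis=0), Y.shape)
        Ys = Y[self.order]
        if level == "individual":
            sums = np.add.reduceat(
                np.add.reduceat(Ys, self.pel_starts, axis=0), self.ind_starts, axis=0
            )
            means = sums / self.ind_counts[:, None]
            # map back: unit -> individual in sorted coding
            codes = np.empty(self.N, dtype=int)
            sorted_ind = np.repeat(
                np.arange(self.nI),
                self.ind_counts,
            )
            codes[self.order] = sorted_ind
            return means[codes]
        if level == "pellet":
            sums = np.add.reduceat(Ys, self.pel_starts, axis=0)
            means = sums / self.pel_counts[:, None]
            codes = np.empty(self.N, dtype=int)
            codes[self.order] = np.repeat(np.arange(self.nP), self.pel_counts)
            return means[codes]
        raise ValueError(f"unknown level {level!r}")


def cube_to_units(cube: DetectionCube):
    """Flatten a cube's existing (pellet, PCR) cells into a unit x taxon
    matrix plus (individual, pellet, pcr) labels."""
    ii, jj, kk = np.nonzero(cube.present)
    Y = cube.detected[ii, jj, kk].astype(float)
    ind = np.array([cube.individuals[i] for i in ii])
    pel = np.array([cube.pellets[i][j] for i, j in zip(ii, jj)])
    pcr = np.array([cube.pcrs[k] for k in kk])
    return Y, ind, pel, pcr


def nested_ss(Y: np.ndarray, labels) -> PermanovaTable:
    """Sums of squares, df, MS and R-squared for the nested terms.

    ``labels`` is a (individual, pellet[, pcr]) tuple of per-unit label
    vectors; the PCR level is the unit itself, so a pcr vector is
    accepted but not needed.  A level with no replication gets df 0 and
    missing MS.
    """
    Y = np.asarray(Y, dtype=float)
    individual, pellet = labels[0], labels[1]
    d = _NestedDesign(individual, pellet)
    if d.N != len(Y):
        raise ValueError("Y and labels length mismatch")
    ss = d.decompose(Y)
    dfs = [d.df_ind, d.df_pel, d.df_pcr]
    ss_tot = ss[3]
    rows = []
    for term, df, s in zip(TERMS, dfs, ss[:3]):
        ms = s / df if df > 0 else np.nan
        r2 = s / ss_tot if ss_tot > 0 else np.nan
        rows.append((term, df, s, ms, r2))
    rows.append(("residual", 0, 0.0, np.nan, np.nan))
    rows.append(("total", d.N - 1, ss_tot, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "MS", "R2"]
    ).set_index("term")
    table["F"] = np.nan
    table["p"] = np.nan
    out = PermanovaTable(table)
    out._design = d  # cached for rrpp_test
    out._Y = Y
    return out


def pseudo_f(table: PermanovaTable, f_scheme: str = "next_nested") -> PermanovaTable:
    """Attach pseudo-F ratios to a nested SS table.

    ``next_nested``: each term's MS over the MS of the next nested term;
    the deepest term has no denominator (F missing) unless the residual
    has df.  ``residual``: every term over the residual MS (all missing,
    with a warning, when residual df is 0).
    """
    if f_scheme not in ("next_nested", "residual"):
        raise ValueError(f"unknown f_scheme {f_scheme!r}")
    t = table.table
    ms = t["MS"]
    f = pd.Series(np.nan, index=t.index)
    res_df = t.loc["residual", "df"]
    if f_scheme == "residual":
        if res_df == 0:
            warnings.warn("residual df is 0: no F under the residual scheme")
        else:
            denom = t.loc["residual", "MS"]
            for term in TERMS:
                f[term] = _ratio(ms[term], denom)
    else:
        chain = TERMS + (["residual"] if res_df > 0 else [])
        for a, b in zip(chain[:-1], chain[1:]):
            f[a] = _ratio(ms[a], ms[b])
    t["F"] = f
    table.f_scheme = f_scheme
    return table


def _ratio(num: float, den: float) -> float:
    if np.isnan(num) or np.isnan(den):
        return np.nan
    if den == 0:
        warnings.warn("zero denominator MS: F reported as inf")
        return np.inf
    return num / den


_REDUCED_LEVEL = {
    "individual": "grand",
    "individual:pellet": "individual",
    "individual:pellet:pcr": "pellet",
}


def _term_stat(ss: tuple, dfs: tuple, term: str, f_scheme: str) -> float:
    """Permutation statistic for a term given a decomposition.

    F where a denominator exists under the scheme; for the deepest term
    in the saturated model the statistic falls back to the term's own MS.
    """
    ms = [s / df if df > 0 else np.nan for s, df in zip(ss[:3], dfs)]
    i = TERMS.index(term)
    if f_scheme == "residual":
        return np.nan  # residual df 0: nothing testable
    if i < 2 and dfs[i] > 0 and dfs[i + 1] > 0:
        return np.inf if ms[i + 1] == 0 else ms[i] / ms[i + 1]
    return ms[i]


def rrpp_test(
    Y: np.ndarray,
    labels,
    B: int = 999,
    seed: int | None = None,
    f_scheme: str = "next_nested",
) -> PermanovaTable:
    """Nested PERMANOVA with randomized-residual permutation p-values.

    For each term in sequence, residuals of the reduced model (all
    preceding terms) are permuted across units B times, the decomposition
    recomputed, and p = (1 + #{stat* >= stat_obs}) / (1 + B); ties count
    as exceedances.  Seeded and reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    table = pseudo_f(nested_ss(Y, labels), f_scheme)
    d: _NestedDesign = table._design
    Y = table._Y
    dfs = (d.df_ind, d.df_pel, d.df_pcr)
    obs_ss = d.decompose(Y)
    rng = np.random.default_rng(seed)
    for term in TERMS:
        if table.table.loc[term, "df"] == 0:
            continue
        stat_obs = _term_stat(obs_ss, dfs, term, f_scheme)
        if np.isnan(stat_obs):
            continue
        fit = d.group_means(Y, _REDUCED_LEVEL[term])
        resid = Y - fit
        count = 0
        for _ in range(B):
            perm = rng.permutation(d.N)
            ss_b = d.decompose(fit + resid[perm])
            if _term_stat(ss_b, dfs, term, f_scheme) >= stat_obs:
                count += 1
        table.table.loc[term, "p"] = (1 + count) / (1 + B)
    table.n_perm = B
    return table


def two_group_permanova(
    Y: np.ndarray,
    group,
    B: int = 999,
    seed: int | None = None,
):
    """One-factor PERMANOVA (squared Euclidean distance) with raw-unit
    permutation; returns (F, R2, p).

    Intended for the pooled-vs-separate-sample composition comparison.
    """
    Y = np.asarray(Y, dtype=float)
    group = np.asarray(group)
    codes, levels = pd.factorize(group, sort=True)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("each group must have at least 2 units")
    N = len(Y)

    def stat(y):
        grand = y.mean(axis=0)
        ss_tot = float(((y - grand) ** 2).sum())
        ss_b = 0.0
        for g in range(2):
            mean_g = y[codes == g].mean(axis=0)
            ss_b += counts[g] * float(((mean_g - grand) ** 2).sum())
        ss_w = ss_tot - ss_b
        if ss_w <= 0:
            if ss_b == 0:
                warnings.warn("all rows identical: F undefined")
                return np.nan, np.nan
            return np.inf, 1.0
        f = (ss_b / (2 - 1)) / (ss_w / (N - 2))
        r2 = ss_b / ss_tot if ss_tot > 0 else np.nan
        return f, r2

    f_obs, r2 = stat(Y)
    if np.isnan(f_obs):
        return f_obs, r2, np.nan
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        f_b, _ = stat(Y[rng.permutation(N)])
        if f_b >= f_obs:
            count += 1
    return float(f_obs), float(r2), (1 + count) / (1 + B)
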