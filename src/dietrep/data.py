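"""Detection data model, long-table I/O, the per-PCR relative-abundance
filter, and PCR-collapse conventions.

The central object is :class:`DetectionCube`, a boolean incidence tensor
indexed (individual, pellet, PCR, taxon), with an explicit presence mask
so ragged designs (unequal pellets or PCRs per individual) are
representable.  Pooled samples live in a :class:`PoolBlock` with the same
axes minus the pellet axis.  All downstream estimators consume
:class:`IncidenceMatrix` objects produced by :func:`collapse_pcrs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReadCountRecord",
    "DetectionCube",
    "PoolBlock",
    "IncidenceMatrix",
    "IncidenceCounts",
    "CollapseMode",
    "read_long_table",
    "write_long_table",
    "apply_relative_abundance_filter",
    "collapse_pcrs",
    "collapse_pool",
    "incidence_counts",
]

#: canonical long-table column names; remappable via the ``schema`` argument
DEFAULT_SCHEMA = {
    "individual": "individual",
    "unit": "unit",
    "unit_kind": "unit_kind",
    "pcr": "pcr",
    "taxon": "taxon",
    "detected": "detected",
    "reads": "reads",
}

UNIT_KINDS = ("pellet", "pool")


@dataclass(frozen=True)
class ReadCountRecord:
    """One (individual, unit, PCR, taxon) read count.

    Read counts feed only the relative-abundance filter; detection is
    boolean everywhere downstream.
    """

    individual_id: str
    unit_id: str
    unit_kind: str
    pcr_id: str
    taxon_id: str
    reads: int

    def __post_init__(self) -> None:
        if self.unit_kind not in UNIT_KINDS:
            raise ValueError(f"unknown unit_kind {self.unit_kind!r}")
        if self.reads < 0:
            raise ValueError(
                f"negative reads ({self.reads}) for "
                f"({self.individual_id}, {self.unit_id}, {self.pcr_id}, {self.taxon_id})"
            )


@dataclass
class DetectionCube:
    """Boolean incidence tensor individual x pellet x PCR x taxon.

    ``detected`` has shape (I, Jmax, K, T); ``present`` has shape
    (I, Jmax, K) and is False for (pellet, PCR) cells that do not exist
    in the design (ragged designs, missing PCRs).  ``pellets[i]`` lists
    the unit ids of individual i's pellets, so ``len(pellets[i])`` may be
    less than Jmax.
    """

    individuals: list[str]
    pellets: list[list[str]]
    pcrs: list[str]
    taxa: list[str]
    detected: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        I, J, K, T = self.detected.shape
        if len(self.individuals) != I or len(self.pcrs) != K or len(self.taxa) != T:
            raise ValueError("axis labels inconsistent with tensor shape")
        if len(set(self.taxa)) != T:
            raise ValueError("duplicate taxa")
        if self.present.shape != (I, J, K):
            raise ValueError("presence mask shape mismatch")
        # missing combinations are explicit False
        self.detected = self.detected & self.present[..., None]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.detected.shape

    def n_units(self) -> int:
        """Number of existing (pellet, PCR) sampling units."""
        return int(self.present.sum())


@dataclass
class PoolBlock:
    """Pool detections: one pooled sample per individual, K PCRs each."""

    individuals: list[str]
    pool_ids: list[str]
    pcrs: list[str]
    taxa: list[str]
    detected: np.ndarray  # (I, K, T)
    present: np.ndarray  # (I, K)

    def __post_init__(self) -> None:
        if len(self.pool_ids) != len(self.individuals):
            raise ValueError("one pool per individual required")
        self.detected = self.detected & self.present[..., None]


@dataclass
class IncidenceMatrix:
    """Pellet x taxon incidence for one individual, after PCR collapse."""

    individual_id: str
    matrix: np.ndarray  # bool, (m, T)
    taxa: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        """Number of sampling units (pellets)."""
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CollapseMode:
    """How to reduce the K PCR replicates of each unit to one layer.

    ``union`` ORs detections over replicates; ``single_random`` keeps one
    uniformly chosen replicate per unit (seeded).
    """

    mode: str = "union"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("union", "single_random"):
            raise ValueError(f"unknown collapse mode {self.mode!r}")


class IncidenceCounts(NamedTuple):
    m_t: np.ndarray  # incidences per taxon
    s_obs: int
    q1: int  # uniques
    q2: int  # duplicates


# ---------------------------------------------------------------------------
# I/O


def _resolve_schema(schema: dict | None) -> dict:
    out = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise ValueError(f"unknown schema keys: {sorted(unknown)}")
        out.update(schema)
    return out


def read_long_table(
    path: str | Path,
    schema: dict | None = None,
    min_relative_abundance: float | None = None,
) -> tuple[DetectionCube, PoolBlock | None]:
    """Read a long-format delimited table into a cube and pool block.

    The file must have a header and the columns individual, unit,
    unit_kind, pcr, taxon plus either a 0/1 ``detected`` column or a
    ``reads`` column (names remappable via ``schema``).  When reads are
    supplied, detection requires reads > 0; pass
    ``min_relative_abundance`` to apply the per-PCR relative-abundance
    filter first.

    Returns ``(cube, pools)``; ``pools`` is None when the file contains
    no pool rows.  Axis orderings are stable (sorted).
    """
    cols = _resolve_schema(schema)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    required = ["individual", "unit", "unit_kind", "pcr", "taxon"]
    missing = [cols[c] for c in required if cols[c] not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.rename(columns={v: k for k, v in cols.items() if v in df.columns})

    bad_kind = set(df["unit_kind"].unique()) - set(UNIT_KINDS)
    if bad_kind:
        raise ValueError(f"unknown unit_kind values: {sorted(bad_kind)}")

    key = ["individual", "unit", "pcr", "taxon"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate key row: {tuple(first)}")

    if "reads" in df.columns:
        reads = pd.to_numeric(df["reads"])
        if (reads < 0).any():
            raise ValueError("negative reads in input")
        df = df.assign(reads=reads)
        if min_relative_abundance is not None:
            df = _filter_frame(df, min_relative_abundance)
        df = df.assign(detected=(df["reads"] > 0).astype(int))
    elif "detected" in df.columns:
        df = df.assign(detected=pd.to_numeric(df["detected"]).astype(int))
    else:
        raise ValueError("need a 'detected' or 'reads' column")

    taxa = sorted(df["taxon"].unique())
    t_index = {t: i for i, t in enumerate(taxa)}
    pcrs = sorted(df["pcr"].unique())
    k_index = {p: i for i, p in enumerate(pcrs)}
    K = len(pcrs)

    pel = df[df["unit_kind"] == "pellet"]
    individuals = sorted(df["individual"].unique())
    i_index = {b: i for i, b in enumerate(individuals)}
    pellets = [
        sorted(pel.loc[pel["individual"] == b, "unit"].unique()) for b in individuals
    ]
    Jmax = max((len(p) for p in pellets), default=0)
    j_index = [{u: j for j, u in enumerate(units)} for units in pellets]

    I, T = len(individuals), len(taxa)
    detected = np.zeros((I, Jmax, K, T), dtype=bool)
    present = np.zeros((I, Jmax, K), dtype=bool)
    ii = pel["individual"].map(i_index).to_numpy()
    jj = np.fromiter(
        (j_index[i][u] for i, u in zip(ii, pel["unit"])), dtype=int, count=len(pel)
    )
    kk = pel["pcr"].map(k_index).to_numpy()
    tt = pel["taxon"].map(t_index).to_numpy()
    present[ii, jj, kk] = True
    detected[ii, jj, kk, tt] = pel["detected"].to_numpy() > 0
    cube = DetectionCube(individuals, pellets, pcrs, taxa, detected, present)

    poo = df[df["unit_kind"] == "pool"]
    if len(poo) == 0:
        return cube, None
    pool_ids = []
    for b in sorted(poo["individual"].unique()):
        units = poo.loc[poo["individual"] == b, "unit"].unique()
        if len(units) > 1:
            raise ValueError(f"individual {b!r} has {len(units)} pools; expected one")
    pool_inds = sorted(poo["individual"].unique())
    pi_index = {b: i for i, b in enumerate(pool_inds)}
    pool_ids = [poo.loc[poo["individual"] == b, "unit"].iloc[0] for b in pool_inds]
    pdet = np.zeros((len(pool_inds), K, T), dtype=bool)
    ppres = np.zeros((len(pool_inds), K), dtype=bool)
    ii = poo["individual"].map(pi_index).to_numpy()
    kk = poo["pcr"].map(k_index).to_numpy()
    tt = poo["taxon"].map(t_index).to_numpy()
    ppres[ii, kk] = True
    pdet[ii, kk, tt] = poo["detected"].to_numpy() > 0
    pools = PoolBlock(pool_inds, pool_ids, pcrs, taxa, pdet, ppres)
    return cube, pools


def write_long_table(
    cube: DetectionCube,
    pools: PoolBlock | None,
    path: str | Path,
) -> None:
    """Write a cube (and optional pools) as a dense long-format table.

    Every existing (unit, PCR) cell is written for every taxon with a 0/1
    detected flag, so ``read_long_table`` round-trips the presence mask.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frames = []
    I, Jmax, K, T = cube.shape
    ii, jj, kk = np.nonzero(cube.present)
    if len(ii):
        frames.append(
            pd.DataFrame(
                {
                    "individual": np.repeat([cube.individuals[i] for i in ii], T),
                    "unit": np.repeat(
                        [cube.pellets[i][j] for i, j in zip(ii, jj)], T
                    ),
                    "unit_kind": "pellet",
                    "pcr": np.repeat([cube.pcrs[k] for k in kk], T),
                    "taxon": np.tile(cube.taxa, len(ii)),
                    "detected": cube.detected[ii, jj, kk].astype(int).ravel(),
                }
            )
        )
    if pools is not None:
        ii, kk = np.nonzero(pools.present)
        if len(ii):
            frames.append(
                pd.DataFrame(
                    {
                        "individual": np.repeat(
                            [pools.individuals[i] for i in ii], T
                        ),
                        "unit": np.repeat([pools.pool_ids[i] for i in ii], T),
                        "unit_kind": "pool",
                        "pcr": np.repeat([pools.pcrs[k] for k in kk], T),
                        "taxon": np.tile(pools.taxa, len(ii)),
                        "detected": pools.detected[ii, kk].astype(int).ravel(),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Relative-abundance filter


def _filter_frame(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    # zero out (rather than drop) sub-threshold records so the taxon and
    # unit axes survive as explicit non-detections
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    totals = df.groupby(["individual", "unit", "pcr"])["reads"].transform("sum")
    keep = (totals > 0) & (df["reads"] / totals.where(totals > 0) >= threshold)
    return df.assign(reads=df["reads"].where(keep.fillna(False), 0))


def apply_relative_abundance_filter(
    records: Iterable[ReadCountRecord],
    threshold: float = 0.01,
) -> list[ReadCountRecord]:
    """Drop records below ``threshold`` of their PCR's total reads.

    Totals are computed per (individual, unit, PCR); a record is kept iff
    reads / total >= threshold.  PCRs with zero total reads are dropped
    entirely.  Idempotent: surviving records still satisfy the threshold
    against their new (unchanged) totals.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    records = list(records)
    totals: dict[tuple, int] = {}
    for r in records:
        if r.reads < 0:
            raise ValueError("negative reads")
        k = (r.individual_id, r.unit_id, r.pcr_id)
        totals[k] = totals.get(k, 0) + r.reads
    kept = []
    for r in records:
        tot = totals[(r.individual_id, r.unit_id, r.pcr_id)]
        if tot > 0 and r.reads / tot >= threshold and r.reads > 0:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# PCR collapse


def collapse_pcrs(cube: DetectionCube, mode: CollapseMode) -> list[IncidenceMatrix]:
    """Collapse the PCR axis to one detection layer per pellet.

    ``union``: a pellet contains a taxon if any of its PCRs detected it.
    ``single_random``: one PCR is chosen uniformly among the pellet's
    existing PCRs (seeded); detection is copied from that replicate.
    Pellets with no existing PCR are dropped from the matrix.
    """
    if cube.n_units() == 0:
        raise ValueError("empty cube")
    rng = np.random.default_rng(mode.seed)
    out = []
    for i, ind in enumerate(cube.individuals):
        rows = []
        for j in range(len(cube.pellets[i])):
            ks = np.nonzero(cube.present[i, j])[0]
            if len(ks) == 0:
                continue
            if mode.mode == "union":
                rows.append(cube.detected[i, j, ks].any(axis=0))
            else:
                k = ks[rng.integers(len(ks))]
                rows.append(cube.detected[i, j, k])
        mat = (
            np.array(rows, dtype=bool)
            if rows
            else np.zeros((0, len(cube.taxa)), dtype=bool)
        )
        out.append(IncidenceMatrix(ind, mat, list(cube.taxa)))
    return out


def collapse_pool(pools: PoolBlock, mode: CollapseMode) -> np.ndarray:
    """Collapse pool PCRs with the same machinery; returns bool (I, T)."""
    rng = np.random.default_rng(mode.seed)
    I, K, T = pools.detected.shape
    out = np.zeros((I, T), dtype=bool)
    for i in range(I):
        ks = np.nonzero(pools.present[i])[0]
        if len(ks) == 0:
            continue
        if mode.mode == "union":
            out[i] = pools.detected[i, ks].any(axis=0)
        else:
            out[i] = pools.detected[i, ks[rng.integers(len(ks))]]
    return out


def incidence_counts(matrix: IncidenceMatrix | np.ndarray) -> IncidenceCounts:
    """Per-taxon incidence counts m_t plus S_obs and the Q1/Q2 tallies.

    m_t is the number of pellets containing taxon t; Q1 and Q2 count taxa
    occurring in exactly one / exactly two pellets (the unique and
    duplicate counts the Chao2 estimator consumes).
    """
    mat = matrix.matrix if isinstance(matrix, IncidenceMatrix) else np.asarray(matrix)
    m_t = mat.sum(axis=0).astype(int)
    return IncidenceCounts(
        m_t=m_t,
        s_obs=int((m_t > 0).sum()),
        q1=int((m_t == 1).sum()),
        q2=int((m_t == 2).sum()),
    )
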