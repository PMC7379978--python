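"""Hierarchical synthetic detection datasets with ground truth.

The generator emulates the study design the estimators assume: I
individuals x J pellets x K PCRs, plus one J-pellet pool x K PCRs per
individual.  Heterogeneity is layered: taxon-specific consumption
probabilities q_t (strong among-individual differences), Beta-distributed
within-individual pellet frequencies r_it (moderate among-pellet
differences), a high per-PCR detection probability (near-identical
technical replicates), and pools whose detection probability is a
logistic function of r_it (pools preferentially recover taxa that are
frequent within an individual).

Draw order (one seeded generator per dataset, bit-reproducible):

1. q_t             Beta(q_shape) x T            (skipped if q supplied)
2. consumed_it     Bernoulli(q_t), I x T
3. r_it            Beta(r_shape), I x T, zeroed where not consumed
4. presence_ijt    Bernoulli(r_it), I x J x T
5. pcr detections  Bernoulli(d_pcr*presence + fp_pcr*(1-presence)), I x J x K x T
6. pool detections Bernoulli(sigmoid(pool_alpha + pool_beta*r_it) * consumed), I x K x T
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from dietrep.data import DetectionCube, PoolBlock

__all__ = ["SynthParams", "SynthTruth", "generate_dataset", "truth_fo"]


@dataclass
class SynthParams:
    """Parameters of the hierarchical detection generator."""

    I: int = 20  # individuals
    J: int = 15  # pellets per individual
    K: int = 3  # PCRs per unit
    T: int = 150  # taxa
    q: np.ndarray | None = None  # per-taxon consumption probabilities
    q_shape: tuple[float, float] = (0.4, 2.5)  # Beta prior for q when not given
    r_shape: tuple[float, float] = (1.2, 3.0)  # Beta of within-individual frequency
    d_pcr: float = 0.97  # P(detect in a PCR | present in pellet)
    fp_pcr: float = 0.0  # P(detect | absent)
    pool_alpha: float = -3.0  # pool-detection logistic intercept
    pool_beta: float = 6.0  # pool-detection logistic slope on r_it
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.I, self.J, self.K, self.T) < 1:
            raise ValueError("I, J, K, T must all be >= 1")
        for name in ("d_pcr", "fp_pcr"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not np.isfinite(self.pool_beta):
            raise ValueError("pool_beta must be finite")
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=float)
            if self.q.shape != (self.T,) or ((self.q < 0) | (self.q > 1)).any():
                raise ValueError("q must be T probabilities in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["q"] is not None:
            d["q"] = list(map(float, d["q"]))
        d["q_shape"] = list(d["q_shape"])
        d["r_shape"] = list(d["r_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthParams":
        d = dict(d)
        if d.get("q") is not None:
            d["q"] = np.asarray(d["q"], dtype=float)
        for key in ("q_shape", "r_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset (for recovery tests)."""

    q: np.ndarray  # (T,) population consumption probabilities
    consumed: np.ndarray  # bool (I, T)
    r: np.ndarray  # (I, T), zero where not consumed
    taxa: list[str] = field(default_factory=list)

    @property
    def fo_tot(self) -> np.ndarray:
        """Realized population FO: fraction of individuals consuming."""
        return self.consumed.mean(axis=0)

    @property
    def fo_pel(self) -> np.ndarray:
        """Mean within-individual frequency over consumers (NaN if none)."""
        n = self.consumed.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(n > 0, self.r.sum(axis=0) / np.maximum(n, 1), np.nan)
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(
    params: SynthParams,
) -> tuple[DetectionCube, PoolBlock, SynthTruth]:
    """Generate a (cube, pools, truth) triple, reproducible from the seed."""
    p = params
    rng = np.random.default_rng(p.seed)

    q = p.q if p.q is not None else rng.beta(*p.q_shape, size=p.T)
    consumed = rng.random((p.I, p.T)) < q
    r = rng.beta(*p.r_shape, size=(p.I, p.T))
    r = np.where(consumed, r, 0.0)

    presence = rng.random((p.I, p.J, p.T)) < r[:, None, :]
    p_det = p.d_pcr * presence + p.fp_pcr * (~presence)
    detected = rng.random((p.I, p.J, p.K, p.T)) < p_det[:, :, None, :]

    p_pool = _sigmoid(p.pool_alpha + p.pool_beta * r) * consumed
    pool_det = rng.random((p.I, p.K, p.T)) < p_pool[:, None, :]

    width = max(2, len(str(p.I - 1)), len(str(p.J - 1)), len(str(p.T - 1)))
    individuals = [f"b{i:0{width}d}" for i in range(p.I)]
    pellets = [[f"p{j:0{width}d}" for j in range(p.J)] for _ in range(p.I)]
    pcrs = [f"r{k}" for k in range(p.K)]
    taxa = [f"t{t:0{width}d}" for t in range(p.T)]

    cube = DetectionCube(
        individuals,
        pellets,
        pcrs,
        taxa,
        detected,
        np.ones((p.I, p.J, p.K), dtype=bool),
    )
    pools = PoolBlock(
        individuals,
        [f"pool{i:0{width}d}" for i in range(p.I)],
        pcrs,
        taxa,
        pool_det,
        np.ones((p.I, p.K), dtype=bool),
    )
    truth = SynthTruth(q=np.asarray(q, dtype=float), consumed=consumed, r=r, taxa=taxa)
    return cube, pools, truth


def truth_fo(truth: SynthTruth):
    """Ground-truth FO table: FOtot = mean consumption, FOpel = mean r
    over consumers (missing where no individual consumed the taxon)."""
    import pandas as pd

    taxa = truth.taxa or [str(t) for t in range(truth.consumed.shape[1])]
    return pd.DataFrame(
        {"taxon": taxa, "fo_tot": truth.fo_tot, "fo_pel": truth.fo_pel}
    ).set_index("taxon")


def save_truth(truth: SynthTruth, path: str | Path) -> None:
    """Serialize truth as JSON (q, consumed, r, taxa)."""
    payload = {
        "q": truth.q.tolist(),
        "consumed": truth.consumed.astype(int).tolist(),
        "r": truth.r.tolist(),
        "taxa": truth.taxa,
    }
    Path(path).write_text(json.dumps(payload))


def load_truth(path: str | Path) -> SynthTruth:
    d = json.loads(Path(path).read_text())
    return SynthTruth(
        q=np.asarray(d["q"], dtype=float),
        consumed=np.asarray(d["consumed"], dtype=bool),
        r=np.asarray(d["r"], dtype=float),
        taxa=list(d["taxa"]),
    )
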