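"""Discrete-time Monte Carlo engine for the threshold dynamics.

Each iteration (one model month) proceeds in two phases using the adopter
states frozen at the start of the iteration:

1. every susceptible non-immune node adopts *spontaneously* with probability
   ``p_r = p_n / (1 - r)`` (so the innovator flux per network node is
   ``p_n``);
2. one synchronous threshold sweep: a susceptible non-immune node with ``m``
   adopting neighbours at the start of the iteration adopts iff
   ``m / k >= phi``.

Adoption is absorbing, so the dynamics is monotone and freezes at
``rho(inf) = 1 - r``. All nodes adopting in the same iteration share a
timestamp and are mutually invisible to the threshold rule, which matches
the strictly-earlier convention used on the analysis side.

An optional ``update='exhaustive'`` mode re-applies the threshold sweep until
no further node crosses within the iteration, collapsing each cascade into a
single timestamp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import Population

__all__ = ["SimResult", "simulate", "class_rates", "gather_neighbors"]


def gather_neighbors(indptr: np.ndarray, indices: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Concatenated neighbour lists of ``nodes`` (vectorised CSR gather)."""
    nodes = np.asarray(nodes, dtype=np.int64)
    if nodes.size == 0:
        return np.empty(0, dtype=np.int64)
    starts = indptr[nodes]
    counts = indptr[nodes + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    # multi-range gather: start of each block plus the offset within it
    first_pos = np.concatenate([[0], np.cumsum(counts)[:-1]])
    block_start = np.repeat(starts, counts)
    block_off = np.arange(total) - np.repeat(first_pos, counts)
    return indices[block_start + block_off]


@dataclass
class SimResult:
    """Time series produced by one Monte Carlo run.

    ``table`` holds one row per iteration ``t = 1..T`` with columns
    ``rho`` (cumulative adopter fraction), ``rho0`` (cumulative innovator
    fraction, spontaneous channel), and windowed per-node adoption rates
    ``R_i``, ``R_v``, ``R_s``, ``R`` from the observational classification
    (number of strictly earlier adopting neighbours at adoption).
    """

    table: pd.DataFrame
    spontaneous: np.ndarray = field(repr=False)  # ground-truth innovator mask, len n
    t_adopt: np.ndarray = field(repr=False)  # adoption iteration per node, 0 = never

    @property
    def rho(self) -> np.ndarray:
        return self.table["rho"].to_numpy()

    @property
    def rho0(self) -> np.ndarray:
        return self.table["rho0"].to_numpy()


def simulate(
    pop: Population,
    p_n: float,
    t_max: int,
    rng: np.random.Generator,
    update: str = "single",
    seed_nodes: np.ndarray | None = None,
    rate_window: int = 1,
) -> tuple[SimResult, pd.DataFrame]:
    """Run the threshold dynamics for ``t_max`` iterations.

    Parameters
    ----------
    pop
        Substrate with immune flags and thresholds.
    p_n
        Spontaneous adoption rate per *network* node per iteration; the
        per-susceptible-node probability is ``p_n / (1 - r)``.
    t_max
        Number of iterations (months).
    update
        ``'single'`` (default): one threshold sweep per iteration;
        ``'exhaustive'``: sweep to exhaustion within each iteration.
    seed_nodes
        Optional nodes forced to adopt at ``t = 1`` (innovator seeds).

    Returns
    -------
    (SimResult, event log) — the event log is a DataFrame with columns
    ``node`` and ``t`` (integer adoption time in ``[1, t_max]``), one row
    per adopter, immune nodes never appearing.
    """
    if not 0.0 <= p_n <= 1.0:
        raise ValueError("p_n must lie in [0, 1]")
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if update not in ("single", "exhaustive"):
        raise ValueError("update must be 'single' or 'exhaustive'")

    n = pop.n
    r = pop.r
    if r >= 1.0:
        if p_n > 0:
            warnings.warn("all nodes immune: dynamics is empty", RuntimeWarning)
        empty = pd.DataFrame({"node": np.empty(0, dtype=np.int64), "t": np.empty(0, dtype=np.int64)})
        table = pd.DataFrame(
            {
                "t": np.arange(1, t_max + 1),
                "rho": 0.0,
                "rho0": 0.0,
                "R_i": 0.0,
                "R_v": 0.0,
                "R_s": 0.0,
                "R": 0.0,
            }
        )
        return SimResult(table=table, spontaneous=np.zeros(n, dtype=bool), t_adopt=np.zeros(n, dtype=np.int64)), empty

    p_r = min(p_n / (1.0 - r), 1.0)

    adopted = np.zeros(n, dtype=bool)
    t_adopt = np.zeros(n, dtype=np.int64)
    spont = np.zeros(n, dtype=bool)
    m = np.zeros(n, dtype=np.int64)  # adopting-neighbour counts

    # integer trigger count: smallest m with m/k >= phi; k = 0 nodes have no
    # social channel (isolated nodes adopt only spontaneously)
    k = pop.degree
    need = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    sus_mask = ~pop.immune
    with np.errstate(invalid="ignore"):
        kk = k[sus_mask].astype(float) * pop.threshold[sus_mask]
    need_sus = np.ceil(kk - 1e-9).astype(np.int64)
    need_sus[k[sus_mask] == 0] = np.iinfo(np.int64).max
    need[sus_mask] = np.maximum(need_sus, 1)

    rho = np.empty(t_max)
    rho0 = np.empty(t_max)

    def _register(new_nodes: np.ndarray, t: int) -> None:
        adopted[new_nodes] = True
        t_adopt[new_nodes] = t
        nbrs = gather_neighbors(pop.indptr, pop.indices, new_nodes)
        if nbrs.size:
            np.add.at(m, nbrs, 1)

    for t in range(1, t_max + 1):
        candidates = ~adopted & sus_mask
        # phase 1: spontaneous adoptions
        draw = rng.random(n) < p_r
        new_spont = candidates & draw
        # phase 2: threshold sweep on start-of-iteration counts
        new_thresh = candidates & (m >= need)
        new = new_spont | new_thresh
        spont |= new_spont & ~new_thresh
        if t == 1 and seed_nodes is not None:
            seeds = np.asarray(seed_nodes, dtype=np.int64)
            seeds = seeds[sus_mask[seeds] & ~new[seeds]]
            new[seeds] = True
            spont[seeds] = True
        new_idx = np.flatnonzero(new)
        _register(new_idx, t)
        if update == "exhaustive":
            while True:
                more = ~adopted & sus_mask & (m >= need)
                more_idx = np.flatnonzero(more)
                if more_idx.size == 0:
                    break
                _register(more_idx, t)
        rho[t - 1] = adopted.sum() / n
        rho0[t - 1] = spont.sum() / n

    adopters = np.flatnonzero(adopted)
    log = pd.DataFrame({"node": adopters, "t": t_adopt[adopters]})
    log = log.sort_values(["t", "node"], ignore_index=True)

    rates = class_rates(pop, log, window=rate_window, t_max=t_max)
    table = pd.DataFrame({"t": np.arange(1, t_max + 1), "rho": rho, "rho0": rho0})
    table = table.merge(rates, on="t", how="left").fillna(0.0)
    return SimResult(table=table, spontaneous=spont, t_adopt=t_adopt), log


def class_rates(
    pop: Population,
    log: pd.DataFrame,
    window: int = 1,
    t_max: int | None = None,
) -> pd.DataFrame:
    """Windowed per-node adoption rates by observational class.

    Each adopter is assigned ``Phi_k`` = number of neighbours with strictly
    earlier adoption time and classed innovator / vulnerable / stable for
    ``Phi_k = 0 / = 1 / > 1``. Rates are counts per window divided by
    ``N * window`` (adoptions per node per iteration), reported at the
    window's last iteration; ``R = R_i + R_v + R_s``.
    """
    from .cascade_analysis import classify

    if t_max is None:
        t_max = int(log["t"].max()) if len(log) else 1
    cls = classify(pop, log)
    t_grid = np.arange(1, t_max + 1)
    out = pd.DataFrame({"t": t_grid, "R_i": 0.0, "R_v": 0.0, "R_s": 0.0})
    if len(cls):
        win = ((cls["t"] - 1) // window).astype(int)
        for name, col in (("innovator", "R_i"), ("vulnerable", "R_v"), ("stable", "R_s")):
            counts = win[cls["cls"] == name].value_counts()
            for w, cnt in counts.items():
                t_end = min((w + 1) * window, t_max)
                out.loc[out["t"] == t_end, col] = cnt / (pop.n * window)
    out["R"] = out[["R_i", "R_v", "R_s"]].sum(axis=1)
    return out
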