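"""File formats, YAML configuration, and the ground-truth fixture generator.

Exchange formats (all plain text):

* **edge list** — whitespace-separated unordered pairs, one edge per line;
  ``#`` comments and CRLF line endings tolerated; duplicate edges collapsed;
  self-loops rejected;
* **event log** — CSV with header ``node,t``; one record per adopter,
  integer times >= 1, duplicate nodes rejected;
* **node attributes** — CSV ``node,degree,immune,threshold,type``.

The fixture generator wraps the population builder and the Monte Carlo
engine to produce event logs with *known ground truth* (r, p_n, threshold
law, per-node adoption channel), optionally corrupted by same-time "group
adoption" collisions: a configured fraction of socially triggered adopters
is reassigned the timestamp of a random earlier-adopting neighbour, which
mimics instantaneous group adoptions not driven by social influence and
breaks the strictly-earlier classification in a controlled way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distributions import DegreeModel, ThresholdModel
from .dynamics_mc import SimResult, simulate
from .population import Population, build_population

__all__ = [
    "FixtureBundle",
    "generate_fixture",
    "read_edge_list",
    "write_edge_list",
    "read_event_log",
    "write_event_log",
    "write_node_attributes",
    "read_node_attributes",
    "load_config",
    "default_config",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# flat-file formats
# ---------------------------------------------------------------------------


def read_edge_list(path) -> Population:
    """Read a two-column whitespace edge list into a substrate.

    Node labels may be arbitrary integers; they are used directly as node
    ids, with ``n = max(label) + 1``. Malformed lines raise with their line
    number; duplicate edges are collapsed; self-loops are rejected.
    """
    edges = []
    with open(path, "r", newline="") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two columns, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer node id") from exc
            if u == v:
                raise ValueError(f"{path}:{ln}: self-loop {u}-{v} rejected")
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{ln}: negative node id")
            edges.append((u, v))
    if edges:
        arr = np.asarray(edges, dtype=np.int64)
        n = int(arr.max()) + 1
    else:
        arr = np.empty((0, 2), dtype=np.int64)
        n = 1
    return Population.from_edges(n, arr)


def write_edge_list(pop_or_edges, path) -> None:
    edges = pop_or_edges.edges if hasattr(pop_or_edges, "edges") else np.asarray(pop_or_edges)
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u} {v}\n")


def read_event_log(path) -> pd.DataFrame:
    """Read a ``node,t`` CSV event log (comments and CRLF tolerated)."""
    rows = []
    with open(path, "r", newline="") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().replace(" ", "") == "node,t":
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'node,t', got {line!r}")
            try:
                node, t = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer field") from exc
            if t < 0:
                raise ValueError(f"{path}:{ln}: negative adoption time")
            rows.append((node, t))
    df = pd.DataFrame(rows, columns=["node", "t"]).astype(np.int64)
    if df["node"].duplicated().any():
        dup = int(df.loc[df["node"].duplicated(), "node"].iloc[0])
        raise ValueError(f"duplicate adoption record for node {dup}")
    return df


def write_event_log(log: pd.DataFrame, path) -> None:
    log[["node", "t"]].to_csv(path, index=False)


def write_node_attributes(pop: Population, path) -> None:
    pd.DataFrame(
        {
            "node": np.arange(pop.n),
            "degree": pop.degree,
            "immune": pop.immune.astype(int),
            "threshold": pop.threshold,
            "type": pop.ctype,
        }
    ).to_csv(path, index=False)


def read_node_attributes(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """Study-condition defaults: the empirical Skype-like parameterisation.

    Degree law (mu_D, sigma_D, k_min) and threshold law (mu_T, sigma_T) from
    the empirical lognormal fits; p_n = 0.00019 adoptions per node per month;
    T = 89 months of observation.
    """
    return {
        "population": {
            "n": 10_000,
            "r": 0.73,
            "mu_d": 1.09,
            "sigma_d": 1.39,
            "k_min": 1,
            "mu_t": -2.0,
            "sigma_t": 1.0,
        },
        "dynamics": {"p_n": 0.00019, "t_max": 89, "update": "single"},
        "fixture": {"collision_rate": 0.0},
        "analysis": {"window": 1, "months_per_year": 12},
        "estimation": {"burn_in": 24, "r_grid": [0.5, 0.6, 0.7, 0.8, 0.9], "runs": 10},
    }


def load_config(path) -> dict:
    """Load a YAML config, filling unspecified fields from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    bad = [k for k in user if k not in cfg]
    if bad:
        raise ValueError(f"unknown config section(s): {bad}")
    for section, values in user.items():
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        unknown = [k for k in values if k not in cfg[section]]
        if unknown:
            raise ValueError(f"unknown field(s) in [{section}]: {unknown}")
        cfg[section].update(values)
    return cfg


def _models_from_config(cfg: dict) -> tuple[DegreeModel, ThresholdModel]:
    p = cfg["population"]
    deg = DegreeModel(p["mu_d"], p["sigma_d"], k_min=p["k_min"])
    thr = ThresholdModel(p["mu_t"], p["sigma_t"])
    return deg, thr


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """Synthetic substrate + event log with generating ground truth."""

    population: Population
    events: pd.DataFrame
    sim: SimResult = field(repr=False)
    truth: dict = field(default_factory=dict)
    n_collided: int = 0

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_edge_list(self.population, outdir / "substrate.tsv")
        write_event_log(self.events, outdir / "events.csv")
        write_node_attributes(self.population, outdir / "nodes.csv")
        self.sim.table.to_csv(outdir / "series.csv", index=False)
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth, fh)


def _inject_collisions(
    pop: Population, events: pd.DataFrame, rate: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, int]:
    """Reassign a fraction of adopters the timestamp of an earlier neighbour."""
    if rate <= 0 or len(events) == 0:
        return events, 0
    t_adopt = np.zeros(pop.n, dtype=np.int64)
    t_adopt[events["node"].to_numpy()] = events["t"].to_numpy()
    nodes = events["node"].to_numpy()
    chosen = nodes[rng.random(len(nodes)) < rate]
    collided = 0
    new_t = t_adopt.copy()
    for v in chosen:
        nb = pop.indices[pop.indptr[v] : pop.indptr[v + 1]]
        earlier = nb[(t_adopt[nb] > 0) & (t_adopt[nb] < t_adopt[v])]
        if earlier.size == 0:
            continue
        donor = earlier[rng.integers(earlier.size)]
        new_t[v] = t_adopt[donor]
        collided += 1
    out = events.copy()
    out["t"] = new_t[nodes]
    return out.sort_values(["t", "node"], ignore_index=True), collided


def generate_fixture(config: dict | None = None, seed: int = 0, **overrides) -> FixtureBundle:
    """Generate a reproducible ground-truth bundle from a config.

    ``overrides`` are section dicts merged over the config (e.g.
    ``population={'n': 500}``). All randomness flows from the single seed
    recorded in the bundle's truth block.
    """
    cfg = {k: dict(v) for k, v in (config or default_config()).items()}
    for section, values in overrides.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        cfg[section].update(values)

    p, d, f = cfg["population"], cfg["dynamics"], cfg["fixture"]
    if not 0 <= f["collision_rate"] <= 1:
        raise ValueError("fixture.collision_rate must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    deg, thr = _models_from_config(cfg)
    pop = build_population(deg, thr, p["n"], p["r"], rng)
    sim, events = simulate(pop, d["p_n"], d["t_max"], rng, update=d.get("update", "single"))
    events, n_coll = _inject_collisions(pop, events, f["collision_rate"], rng)

    # ground-truth labels: observational classes on the *uncollided* log,
    # plus the simulator's own spontaneous-channel mask
    from .cascade_analysis import classify

    clean = pd.DataFrame({"node": np.flatnonzero(sim.t_adopt > 0)})
    clean["t"] = sim.t_adopt[clean["node"].to_numpy()]
    cls0 = classify(pop, clean)
    adopters = cls0["node"].to_numpy()
    channel = cls0["cls"].to_numpy()
    truth = {
        "seed": int(seed),
        "r": float(p["r"]),
        "p_n": float(d["p_n"]),
        "mu_d": float(p["mu_d"]),
        "sigma_d": float(p["sigma_d"]),
        "mu_t": float(p["mu_t"]),
        "sigma_t": float(p["sigma_t"]),
        "collision_rate": float(f["collision_rate"]),
        "n_collided": int(n_coll),
        "classes": {int(v): str(c) for v, c in zip(adopters, channel)},
        "spontaneous_nodes": [int(v) for v in np.flatnonzero(sim.spontaneous)],
    }
    return FixtureBundle(population=pop, events=events, sim=sim, truth=truth, n_collided=n_coll)
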