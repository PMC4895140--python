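"""Parametric degree and threshold laws.

The social substrate is characterised by two heterogeneous quantities:

* the degree ``k`` of a node, modelled by a lognormal law discretised to the
  integers ``k >= k_min``;
* the fractional adoption threshold ``phi`` of a node, modelled by a
  lognormal law truncated to the unit interval ``(0, 1]`` (a threshold is the
  minimum *fraction* of neighbours that must adopt before the node does).

This module provides closed-form moments, seeded sampling, method-of-moments
fits, and the scaling collapse of per-degree integer-threshold histograms
onto a single master curve, ``P(Phi_k, k) = k P(Phi_k / k)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "DegreeModel",
    "ThresholdModel",
    "IntegerThresholdTable",
    "degree_mean",
    "threshold_moments",
    "fit_lognormal_moments",
    "sample_degrees",
    "sample_thresholds",
    "collapse_integer_thresholds",
]

#: Named conventions for mapping the continuous lognormal onto integers.
DEGREE_CONVENTIONS = ("density", "interval", "continuous")


def _lognormal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    lx = np.log(x[pos])
    out[pos] = np.exp(-((lx - mu) ** 2) / (2 * sigma**2)) / (
        x[pos] * sigma * math.sqrt(2 * math.pi)
    )
    return out


def _lognormal_cdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = ndtr((np.log(x[pos]) - mu) / sigma)
    return out


@dataclass(frozen=True)
class DegreeModel:
    """Lognormal degree law on the integers ``k_min <= k <= k_max``.

    Parameters
    ----------
    mu, sigma
        Location and width of the lognormal on the log scale.
    k_min
        Smallest admissible degree (>= 1).
    k_max
        Structural cutoff; ``None`` means unbounded (a numerical truncation
        far in the tail is applied when tabulating the law).
    """

    mu: float
    sigma: float
    k_min: int = 1
    k_max: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.k_max is not None and self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    # -- tabulated law -----------------------------------------------------

    def _support_cap(self) -> int:
        """Upper end used when tabulating an unbounded law.

        Eight log-scale standard deviations beyond ``mu`` carry < 1e-15 of
        probability mass; going further would only waste memory.
        """
        if self.k_max is not None:
            return self.k_max
        cap = int(math.ceil(math.exp(self.mu + 8.0 * self.sigma)))
        if cap <= self.k_min:
            cap = self.k_min + 1
        if cap > 5_000_000:
            warnings.warn(
                "degree law tail is extremely heavy; truncating support "
                f"at k = {5_000_000}",
                RuntimeWarning,
                stacklevel=2,
            )
            cap = 5_000_000
        return cap

    def pmf(self, convention: str = "density") -> tuple[np.ndarray, np.ndarray]:
        """Integer support and probability masses under a named convention.

        ``density``  -- mass at k proportional to the continuous pdf at k;
        ``interval`` -- mass at k equal to the continuous mass of
        ``[k - 1/2, k + 1/2)``; both renormalised over the support.
        """
        if convention not in ("density", "interval"):
            raise ValueError(f"unknown discretisation convention {convention!r}")
        k = np.arange(self.k_min, self._support_cap() + 1, dtype=np.int64)
        if convention == "density":
            p = _lognormal_pdf(k, self.mu, self.sigma)
        else:
            p = _lognormal_cdf(k + 0.5, self.mu, self.sigma) - _lognormal_cdf(
                np.maximum(k - 0.5, 0.0), self.mu, self.sigma
            )
        tot = p.sum()
        if tot <= 0:
            raise ValueError("degree law has no mass on the requested support")
        return k, p / tot

    def mean(self, convention: str = "density") -> float:
        """Average degree z under the chosen discretisation convention."""
        return degree_mean(self, convention)

    def sample(self, n: int, rng: np.random.Generator, convention: str = "density") -> np.ndarray:
        return sample_degrees(self, n, rng, convention)


def degree_mean(model: DegreeModel, convention: str = "density") -> float:
    """Mean degree z of the (discretised) lognormal degree law.

    ``convention='continuous'`` returns the untruncated closed form
    ``exp(mu + sigma^2 / 2)`` and ignores ``k_min``/``k_max``.
    """
    if convention == "continuous":
        return math.exp(model.mu + model.sigma**2 / 2.0)
    k, p = model.pmf(convention)
    return float((k * p).sum())


def sample_degrees(
    model: DegreeModel,
    n: int,
    rng: np.random.Generator,
    convention: str = "density",
) -> np.ndarray:
    """Draw ``n`` i.i.d. integer degrees; reproducible under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k, p = model.pmf(convention)
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    return k[np.minimum(idx, len(k) - 1)]


@dataclass(frozen=True)
class ThresholdModel:
    """Lognormal threshold law truncated to ``(0, 1]``.

    A raw lognormal puts mass above 1, which is meaningless for a fractional
    threshold; the law is therefore *truncated* (renormalised), not censored.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def _mass_below_one(self) -> float:
        # P(lognormal <= 1) = Phi(-mu / sigma)
        return float(ndtr(-self.mu / self.sigma))

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = _lognormal_cdf(np.clip(x, 0.0, 1.0), self.mu, self.sigma)
        return out / self._mass_below_one

    def ppf(self, q: np.ndarray | float) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        return np.exp(self.mu + self.sigma * ndtri(q * self._mass_below_one))

    def moments(self) -> tuple[float, float]:
        return threshold_moments(self)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_thresholds(self, n, rng)


def threshold_moments(model: ThresholdModel) -> tuple[float, float]:
    """Mean w and standard deviation of the truncated threshold law.

    Uses the closed form for moments of a lognormal conditioned on ``X <= 1``:
    ``E[X^n | X <= 1] = e^{n mu + n^2 s^2/2} Phi((-mu - n s^2)/s) / Phi(-mu/s)``.
    """
    mu, s = model.mu, model.sigma
    z = ndtr(-mu / s)
    m1 = math.exp(mu + s**2 / 2.0) * ndtr((-mu - s**2) / s) / z
    m2 = math.exp(2 * mu + 2 * s**2) * ndtr((-mu - 2 * s**2) / s) / z
    var = max(m2 - m1**2, 0.0)
    return float(m1), float(math.sqrt(var))


def fit_lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments inversion for an (untruncated) lognormal.

    Solves ``sigma^2 = ln(1 + (sd/mean)^2)`` and
    ``mu = ln(mean) - sigma^2 / 2``; the exact inverse of the closed-form
    moment map of the untruncated law.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_thresholds(model: ThresholdModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` thresholds in ``(0, 1]`` by inverse-CDF sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    # avoid the degenerate u=0 corner (would map to phi=0, outside support)
    u = np.clip(u, 1e-15, 1.0)
    phi = model.ppf(u)
    return np.minimum(phi, 1.0)


# ---------------------------------------------------------------------------
# integer thresholds and the scaling collapse
# ---------------------------------------------------------------------------


@dataclass
class IntegerThresholdTable:
    """Histogram of integer thresholds ``Phi_k`` per degree group.

    ``Phi_k`` is the number of neighbours that had already adopted when the
    ego adopted; within a degree group k it takes values 0..k. Stored as a
    tidy table with columns ``k``, ``phi_int``, ``count``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"k", "phi_int", "count"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        t = self.table
        if (t["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (t["phi_int"] > t["k"]).any():
            raise ValueError("integer threshold Phi_k cannot exceed the degree k")

    @classmethod
    def from_observations(cls, degrees: np.ndarray, phi_ints: np.ndarray) -> "IntegerThresholdTable":
        df = (
            pd.DataFrame({"k": np.asarray(degrees), "phi_int": np.asarray(phi_ints)})
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["k", "phi_int"], ignore_index=True)
        )
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "IntegerThresholdTable":
        return cls(pd.read_csv(path))


def collapse_integer_thresholds(
    table: IntegerThresholdTable,
    degree_groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rescale per-degree integer-threshold histograms onto the master curve.

    For each degree group the normalised frequencies ``P(Phi_k, k)`` are
    mapped to points ``x = Phi_k / k``, ``y = k * P(Phi_k, k)``; if the
    fractional thresholds are degree-independent with density ``P(phi)``,
    all groups fall on the same curve ``y = P(x)``.

    Parameters
    ----------
    table
        Per-degree counts.
    degree_groups
        Optional ascending bin edges for logarithmic degree grouping of
        sparse data; each group is pooled and labelled by its mean degree.

    Returns
    -------
    DataFrame with columns ``k`` (group label), ``x``, ``y`` — groups are
    kept separate so collapse quality can be assessed.
    """
    df = table.table
    if degree_groups is not None:
        edges = np.asarray(degree_groups, dtype=float)
        gid = np.searchsorted(edges, df["k"].to_numpy(), side="right")
        df = df.assign(_g=gid)
        key = "_g"
    else:
        df = df.assign(_g=df["k"])
        key = "_g"

    out = []
    for _, grp in df.groupby(key, sort=True):
        total = grp["count"].sum()
        if total == 0:
            warnings.warn("empty degree group skipped in scaling collapse", RuntimeWarning)
            continue
        k_eff = float(np.average(grp["k"], weights=np.maximum(grp["count"], 1)))
        p = grp["count"].to_numpy(dtype=float) / total
        out.append(
            pd.DataFrame(
                {
                    "k": k_eff,
                    "x": grp["phi_int"].to_numpy(dtype=float) / grp["k"].to_numpy(dtype=float),
                    "y": k_eff * p,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["k", "x", "y"])
    return pd.concat(out, ignore_index=True)
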