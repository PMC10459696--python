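"""Probability distributions for the Monte Carlo engine.

Each uncertain aquifer/receptor parameter is described by a
:class:`DistributionSpec` (constant, uniform, normal or lognormal) and
sampled into a :class:`SampleVector` with its own independent,
reproducible random stream.  Lognormal parameters are the mean and
standard deviation of ``ln X`` (natural-log scale), so ``exp(log_mean)``
is the median of the sampled variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "DistributionSpec",
    "SampleVector",
    "stream_seed",
    "sample",
    "empirical_percentile",
    "fraction_below",
]

_KINDS = ("constant", "uniform", "normal", "lognormal")

# Parameter names expected per kind, used both for validation and for
# round-tripping specs through YAML configs.
_PARAM_NAMES = {
    "constant": ("value",),
    "uniform": ("min", "max"),
    "normal": ("mean", "sd"),
    "lognormal": ("log_mean", "log_sd"),
}


class ConfigurationError(ValueError):
    """A distribution or scenario field violates its constraints."""


@dataclass(frozen=True)
class DistributionSpec:
    """Declaration of one sampled input variable.

    Parameters
    ----------
    kind:
        One of ``constant``, ``uniform``, ``normal``, ``lognormal``.
    params:
        Mapping of parameter names to values; the required names depend
        on ``kind`` (see ``_PARAM_NAMES``).
    units:
        Free-text unit label carried through to reports.
    """

    kind: str
    params: dict = field(default_factory=dict)
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown distribution kind {self.kind!r}; expected one of {_KINDS}"
            )
        expected = _PARAM_NAMES[self.kind]
        missing = [p for p in expected if p not in self.params]
        if missing:
            raise ConfigurationError(
                f"{self.kind} distribution missing parameter(s) {missing}"
            )
        p = self.params
        if self.kind == "uniform" and not p["min"] < p["max"]:
            raise ConfigurationError(
                f"uniform distribution requires min < max, got min={p['min']}, max={p['max']}"
            )
        if self.kind == "normal" and not p["sd"] > 0:
            raise ConfigurationError(f"normal distribution requires sd > 0, got sd={p['sd']}")
        if self.kind == "lognormal" and not p["log_sd"] > 0:
            raise ConfigurationError(
                f"lognormal distribution requires log_sd > 0, got log_sd={p['log_sd']}"
            )

    # -- analytic moments, used by tests and sanity reports ------------
    def mean(self) -> float:
        p = self.params
        if self.kind == "constant":
            return float(p["value"])
        if self.kind == "uniform":
            return 0.5 * (p["min"] + p["max"])
        if self.kind == "normal":
            return float(p["mean"])
        return float(np.exp(p["log_mean"] + 0.5 * p["log_sd"] ** 2))

    def median(self) -> float:
        p = self.params
        if self.kind == "lognormal":
            return float(np.exp(p["log_mean"]))
        return self.mean() if self.kind != "uniform" else 0.5 * (p["min"] + p["max"])

    def sd(self) -> float:
        p = self.params
        if self.kind == "constant":
            return 0.0
        if self.kind == "uniform":
            return (p["max"] - p["min"]) / np.sqrt(12.0)
        if self.kind == "normal":
            return float(p["sd"])
        s2 = p["log_sd"] ** 2
        return float(np.sqrt((np.exp(s2) - 1.0)) * np.exp(p["log_mean"] + 0.5 * s2))

    def to_dict(self) -> dict:
        d = {"kind": self.kind, **{k: float(v) for k, v in self.params.items()}}
        if self.units:
            d["units"] = self.units
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        d = dict(d)
        kind = d.pop("kind", None)
        if kind is None:
            raise ConfigurationError(f"distribution mapping missing 'kind': {d}")
        units = d.pop("units", "")
        return cls(kind=kind, params=d, units=units)


@dataclass(frozen=True)
class SampleVector:
    """Named vector of N Monte Carlo draws from one input stream."""

    name: str
    values: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.values)


def stream_seed(master_seed: int, index: int) -> int:
    """Derive the per-variable stream seed from the scenario master seed.

    Distinct (master_seed, index) pairs map to well-separated streams via
    :class:`numpy.random.SeedSequence`; the result is kept below 2**31 so
    it can round-trip through any signed-integer config field.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFF)


def sample(spec: DistributionSpec, n: int, seed: int, name: str = "") -> SampleVector:
    """Draw ``n`` values from ``spec`` using an independent stream ``seed``.

    Constant specs return ``n`` copies of the value.  Re-invocation with
    the same arguments reproduces the vector bit-for-bit.  Normal draws
    used for porosity-like variables are clipped by the caller if a
    physical support applies; this function returns raw draws.
    """
    if not isinstance(spec, DistributionSpec):
        raise TypeError("spec must be a DistributionSpec")
    n = int(n)
    if n < 1:
        raise ValueError(f"draw count must be >= 1, got {n}")
    rng = np.random.default_rng(int(seed))
    p = spec.params
    if spec.kind == "constant":
        values = np.full(n, float(p["value"]))
    elif spec.kind == "uniform":
        values = rng.uniform(p["min"], p["max"], n)
    elif spec.kind == "normal":
        values = rng.normal(p["mean"], p["sd"], n)
    else:  # lognormal: strictly positive by construction
        values = np.exp(rng.normal(p["log_mean"], p["log_sd"], n))
    values.flags.writeable = False
    return SampleVector(name=name, values=values, seed=int(seed))


def empirical_percentile(values: Sequence[float], p: float) -> float:
    """p-th empirical percentile with linear interpolation between order
    statistics; ``p=0`` is the minimum, ``p=100`` the maximum."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empirical_percentile: empty input")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    return float(np.percentile(v, p, method="linear"))


def fraction_below(values: Sequence[float], threshold: float) -> float:
    """Fraction of draws strictly below ``threshold`` (compliance fraction)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("fraction_below: empty input")
    return float(np.mean(v < threshold))
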