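"""Mamdani fuzzy inference for nanoparticle toxicity and ecosystem risk.

Two chained rule systems, mirroring how expert toxicity knowledge is
usually encoded for engineered nanoparticles:

1. a *toxicity* system maps particle properties (size in nm, shape,
   coating) to a toxicity score on [0, 100];
2. a *risk* system combines the receptor concentration (ng/L) with the
   toxicity score into a risk score on [0, 100], banded into the
   categories very_low / low / medium / high.

Inference is classic Mamdani: piecewise-linear (trapezoidal/triangular)
membership functions, min-conjunction of rule antecedents, max
aggregation of clipped consequents, centroid defuzzification on a dense
output grid.  Categorical inputs (shape, coating) enter rules as crisp
terms with membership 0/1.

The shipped default model (``data/fuzzy_agnp_citrate.yaml``) encodes
citrate-coated spherical silver nanoparticles.  Its concentration
breakpoints are calibrated so that the risk-vs-concentration curve is
very-low/low below the 22 ng/L surface-water limit, sits on a flat
medium plateau from 22 to 300 ng/L, rises between 300 and 490 ng/L, and
saturates at the high-risk level from 490 ng/L on (the rule base caps
risk there regardless of further concentration increases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .distributions import ConfigurationError

__all__ = [
    "NanoparticleSpec",
    "FuzzySet",
    "FuzzyVariable",
    "CategoricalVariable",
    "Rule",
    "MamdaniSystem",
    "FuzzyRiskModel",
    "RiskResult",
    "toxicity",
    "risk",
    "risk_distribution",
    "risk_curve",
    "default_model_path",
]

#: points per output-grid unit used for centroid defuzzification
_GRID_STEP = 0.05
#: draws per chunk in batch inference (bounds the membership matrix size)
_BATCH = 2048


@dataclass(frozen=True)
class NanoparticleSpec:
    """Released particle: size (nm) plus shape and coating terms."""

    size_nm: float
    shape: str
    coating: str

    def __post_init__(self) -> None:
        if not self.size_nm > 0:
            raise ValueError(f"particle size must be > 0 nm, got {self.size_nm}")


@dataclass(frozen=True)
class FuzzySet:
    """Trapezoidal membership function with abscissae a <= b <= c <= d.

    ``b == c`` gives a triangle; ``a == b`` (or ``c == d``) gives a
    shoulder flush with the domain edge.
    """

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.a <= self.b <= self.c <= self.d:
            raise ConfigurationError(
                f"fuzzy set {self.name!r}: breakpoints must satisfy a<=b<=c<=d, "
                f"got {(self.a, self.b, self.c, self.d)}"
            )

    def membership(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xs, ys = self._knots()
        out = np.interp(x, xs, ys)
        return float(out) if out.ndim == 0 else out

    def _knots(self):
        xs, ys = [], []
        if self.a == self.b:  # left shoulder
            xs += [self.a]
            ys += [1.0]
        else:
            xs += [self.a, self.b]
            ys += [0.0, 1.0]
        if self.c == self.d:  # right shoulder
            xs += [self.d]
            ys += [1.0]
        else:
            xs += [self.c, self.d]
            ys += [1.0, 0.0]
        # np.interp extends flat beyond the ends; pad explicit zeros when
        # the set does not touch the domain edge so support stays finite.
        return np.array(xs), np.array(ys)

    def centroid(self, clip: float = 1.0) -> float:
        """Exact centroid of the membership function clipped at ``clip``."""
        xs = np.linspace(self.a - 1e-9, self.d + 1e-9, 20001)
        mu = np.minimum(self.membership(xs), clip)
        area = np.trapezoid(mu, xs)
        if area == 0:
            raise ValueError(f"fuzzy set {self.name!r}: zero area at clip={clip}")
        return float(np.trapezoid(mu * xs, xs) / area)


@dataclass(frozen=True)
class FuzzyVariable:
    """Numeric linguistic variable over a closed domain."""

    name: str
    domain: tuple[float, float]
    sets: dict[str, FuzzySet]
    clamp_max: float | None = None  # inputs above are treated as this value

    def membership(self, set_name: str, x):
        return self.sets[set_name].membership(self._clamp(x))

    def _clamp(self, x):
        lo, hi = self.domain
        hi = self.clamp_max if self.clamp_max is not None else hi
        return np.clip(np.asarray(x, dtype=float), lo, hi)

    def validate_coverage(self, n_points: int = 2001) -> None:
        """Every domain point must belong to at least one set (no gaps)."""
        lo = self.domain[0]
        hi = self.clamp_max if self.clamp_max is not None else self.domain[1]
        xs = np.linspace(lo, hi, n_points)
        total = np.zeros_like(xs)
        for s in self.sets.values():
            total = np.maximum(total, s.membership(xs))
        if np.any(total <= 0):
            gap = xs[np.argmin(total)]
            raise ConfigurationError(
                f"variable {self.name!r}: membership coverage gap near x={gap:g}"
            )


@dataclass(frozen=True)
class CategoricalVariable:
    """Crisp categorical input; rule terms must name one category."""

    name: str
    categories: tuple[str, ...]

    def membership(self, set_name: str, value: str) -> float:
        if value not in self.categories:
            raise ConfigurationError(
                f"unknown {self.name} {value!r}; known values: {list(self.categories)}"
            )
        if set_name not in self.categories:
            raise ConfigurationError(
                f"rule refers to unknown {self.name} term {set_name!r}; "
                f"known values: {list(self.categories)}"
            )
        return 1.0 if value == set_name else 0.0


@dataclass(frozen=True)
class Rule:
    """IF conjunction of (variable, set) THEN output set."""

    antecedents: dict[str, str]
    consequent: str


class MamdaniSystem:
    """Min/max Mamdani system with centroid defuzzification."""

    def __init__(
        self,
        inputs: Sequence[FuzzyVariable | CategoricalVariable],
        output: FuzzyVariable,
        rules: Sequence[Rule],
    ) -> None:
        self.inputs = {v.name: v for v in inputs}
        self.output = output
        self.rules = list(rules)
        for rule in self.rules:
            for var, term in rule.antecedents.items():
                if var not in self.inputs:
                    raise ConfigurationError(f"rule references unknown variable {var!r}")
                v = self.inputs[var]
                if isinstance(v, FuzzyVariable) and term not in v.sets:
                    raise ConfigurationError(
                        f"rule references unknown set {term!r} of variable {var!r}"
                    )
            if rule.consequent not in output.sets:
                raise ConfigurationError(
                    f"rule consequent {rule.consequent!r} not a set of output "
                    f"{output.name!r}"
                )
        for v in inputs:
            if isinstance(v, FuzzyVariable):
                v.validate_coverage()
        lo, hi = output.domain
        self._grid = np.linspace(lo, hi, int(round((hi - lo) / _GRID_STEP)) + 1)
        self._set_mf = {
            name: s.membership(self._grid) for name, s in output.sets.items()
        }

    def rule_strengths(self, values: Mapping[str, object]) -> np.ndarray:
        """Firing strength of every rule for one crisp input assignment."""
        strengths = np.empty(len(self.rules))
        for i, rule in enumerate(self.rules):
            s = 1.0
            for var, term in rule.antecedents.items():
                s = min(s, float(self.inputs[var].membership(term, values[var])))
            strengths[i] = s
        return strengths

    def infer(self, values: Mapping[str, object]) -> float:
        """Crisp output for one input assignment (centroid defuzzification)."""
        strengths = self.rule_strengths(values)
        agg = np.zeros_like(self._grid)
        for rule, s in zip(self.rules, strengths):
            if s > 0:
                agg = np.maximum(agg, np.minimum(self._set_mf[rule.consequent], s))
        area = agg.sum()
        if area == 0:
            raise ConfigurationError(
                f"no rule fires for inputs {dict(values)!r}; rule base is not total"
            )
        return float((agg * self._grid).sum() / area)

    def infer_over(self, var_name: str, xs, fixed: Mapping[str, object]) -> np.ndarray:
        """Vectorized inference varying one numeric input, others fixed.

        Used to push a whole Monte Carlo concentration ensemble through
        the risk system at once.
        """
        xs = np.asarray(xs, dtype=float)
        var = self.inputs[var_name]
        # memberships of the varying input per set, per draw
        var_mem = {name: np.asarray(var.membership(name, xs)) for name in var.sets}
        # fixed part of each rule's strength
        fixed_strength = np.empty(len(self.rules))
        for i, rule in enumerate(self.rules):
            s = 1.0
            for v, term in rule.antecedents.items():
                if v != var_name:
                    s = min(s, float(self.inputs[v].membership(term, fixed[v])))
            fixed_strength[i] = s
        out = np.empty(xs.shape)
        flat = xs.ravel()
        res = out.ravel()
        for start in range(0, flat.size, _BATCH):
            sl = slice(start, start + _BATCH)
            agg = np.zeros((self._grid.size, flat[sl].size))
            for i, rule in enumerate(self.rules):
                term = rule.antecedents.get(var_name)
                s = (
                    np.full(flat[sl].size, fixed_strength[i])
                    if term is None
                    else np.minimum(var_mem[term].ravel()[sl], fixed_strength[i])
                )
                if np.any(s > 0):
                    np.maximum(
                        agg,
                        np.minimum(self._set_mf[rule.consequent][:, None], s[None, :]),
                        out=agg,
                    )
            area = agg.sum(axis=0)
            if np.any(area == 0):
                bad = flat[sl][area == 0][0]
                raise ConfigurationError(
                    f"no rule fires at {var_name}={bad!r}; rule base is not total"
                )
            res[sl] = (agg * self._grid[:, None]).sum(axis=0) / area
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RiskResult:
    toxicity_score: float
    risk_score: float
    category: str


@dataclass(frozen=True)
class FuzzyRiskModel:
    """Chained toxicity and risk systems plus the category bands."""

    toxicity_system: MamdaniSystem
    risk_system: MamdaniSystem
    category_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "very_low": (0.0, 25.0),
            "low": (25.0, 50.0),
            "medium": (50.0, 75.0),
            "high": (75.0, 100.0),
        }
    )

    @property
    def categories(self) -> list[str]:
        return sorted(self.category_bands, key=lambda c: self.category_bands[c][0])

    def categorize(self, score) -> np.ndarray | str:
        """Map risk score(s) to the unique category band containing them.

        Bands are half-open [lo, hi); the topmost band includes its
        upper edge so the full score range is covered.
        """
        score = np.asarray(score, dtype=float)
        cats = self.categories
        edges = [self.category_bands[c][0] for c in cats[1:]]
        idx = np.searchsorted(edges, score, side="right")
        if np.ndim(idx) == 0:
            return cats[int(idx)]
        return np.asarray(cats, dtype=object)[idx]

    # -- serialization -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "FuzzyRiskModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "FuzzyRiskModel":
        bands = {
            name: (float(lo), float(hi))
            for name, (lo, hi) in doc["category_bands"].items()
        }
        return cls(
            toxicity_system=_system_from_dict(doc["toxicity_model"]),
            risk_system=_system_from_dict(doc["risk_model"]),
            category_bands=bands,
        )

    @classmethod
    def default(cls) -> "FuzzyRiskModel":
        return cls.from_yaml(default_model_path())


def default_model_path():
    """Path of the shipped citrate-sphere AgNP model definition."""
    from importlib.resources import files

    return files("nanospill.data") / "fuzzy_agnp_citrate.yaml"


def _variable_from_dict(name: str, d: dict) -> FuzzyVariable | CategoricalVariable:
    if "categories" in d:
        return CategoricalVariable(name=name, categories=tuple(d["categories"]))
    sets = {
        sname: FuzzySet(sname, *[float(v) for v in abcd])
        for sname, abcd in d["sets"].items()
    }
    clamp = d.get("clamp_max")
    return FuzzyVariable(
        name=name,
        domain=(float(d["domain"][0]), float(d["domain"][1])),
        sets=sets,
        clamp_max=None if clamp is None else float(clamp),
    )


def _system_from_dict(d: dict) -> MamdaniSystem:
    inputs = [_variable_from_dict(n, spec) for n, spec in d["inputs"].items()]
    out_spec = d["output"]
    output = _variable_from_dict(out_spec["name"], out_spec)
    out_name = out_spec["name"]
    rules = []
    for r in d["rules"]:
        r = dict(r)
        consequent = r.pop(out_name)
        rules.append(Rule(antecedents=r, consequent=consequent))
    return MamdaniSystem(inputs=inputs, output=output, rules=rules)


# -- public operations -------------------------------------------------

def toxicity(np_spec: NanoparticleSpec, model: FuzzyRiskModel) -> float:
    """Defuzzified toxicity score of a particle specification."""
    sysm = model.toxicity_system
    values: dict[str, object] = {}
    for name, var in sysm.inputs.items():
        if isinstance(var, CategoricalVariable):
            value = getattr(np_spec, name)
            if value not in var.categories:
                raise ConfigurationError(
                    f"unknown {name} {value!r}; known values: {list(var.categories)}"
                )
            values[name] = value
        else:
            values[name] = np_spec.size_nm
    return sysm.infer(values)


def risk(C0: float, tox: float, model: FuzzyRiskModel) -> RiskResult:
    """Risk score and category for one concentration (ng/L)."""
    if C0 < 0:
        raise ValueError(f"concentration must be >= 0 ng/L, got {C0}")
    conc_var = _concentration_name(model)
    score = model.risk_system.infer({conc_var: C0, "toxicity": tox})
    return RiskResult(
        toxicity_score=float(tox),
        risk_score=score,
        category=str(model.categorize(score)),
    )


def risk_scores(C0_values, np_spec: NanoparticleSpec, model: FuzzyRiskModel) -> np.ndarray:
    """Vectorized risk scores for an ensemble of concentrations."""
    C0_values = np.asarray(C0_values, dtype=float)
    if np.any(C0_values < 0):
        raise ValueError("concentrations must be >= 0 ng/L")
    tox = toxicity(np_spec, model)
    conc_var = _concentration_name(model)
    return model.risk_system.infer_over(conc_var, C0_values, {"toxicity": tox})


def risk_distribution(
    C0_values, np_spec: NanoparticleSpec, model: FuzzyRiskModel
) -> dict[str, float]:
    """Fraction of draws per risk category (fractions sum to 1)."""
    C0_values = np.asarray(C0_values, dtype=float)
    if C0_values.size == 0:
        raise ValueError("risk_distribution: empty concentration vector")
    cats = model.categorize(risk_scores(C0_values, np_spec, model))
    return {
        c: float(np.mean(cats == c)) for c in model.categories
    }


def risk_curve(model: FuzzyRiskModel, np_spec: NanoparticleSpec, grid):
    """Risk score evaluated on a monotone concentration grid.

    Returns ``(grid, scores)``; feeds the sensitivity-ratio analysis.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    return grid, risk_scores(grid, np_spec, model)


def _concentration_name(model: FuzzyRiskModel) -> str:
    for name, var in model.risk_system.inputs.items():
        if name != "toxicity" and isinstance(var, FuzzyVariable):
            return name
    raise ConfigurationError("risk system has no concentration input variable")
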