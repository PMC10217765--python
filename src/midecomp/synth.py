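"""Seeded generators of contingency tables and case-level records.

Three mechanisms are supported, mirroring the sampling models under
which the package's inference is derived:

``probability-tensor``
    Cell counts drawn Multinomial(N, f) from an explicit joint
    probability tensor.
``loglin-lambda``
    The probability tensor is built from log-linear terms,
    ``f proportional to exp(sum of lambda terms)``, then sampled
    multinomially.  Under a fixed total N this is equivalent to the
    Poisson log-linear sampling model.
``logistic``
    Predictors are drawn from a stated joint distribution and a binary
    target is drawn Bernoulli(logit^-1(linear predictor)), with
    reference-coded main-effect and interaction coefficients.

A scenario is fully determined by its seed; there is no global RNG
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .tables import ContingencyTable, FactorSpec

__all__ = ["ScenarioSpec", "sample_table", "sample_logistic_records", "load_scenario"]


@dataclass
class ScenarioSpec:
    factors: list[FactorSpec]
    mechanism: str  # probability-tensor | loglin-lambda | logistic
    parameters: dict
    N: int
    seed: int

    def __post_init__(self) -> None:
        if self.mechanism not in ("probability-tensor", "loglin-lambda", "logistic"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.N <= 0:
            raise ValueError("N must be positive")

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")


def _tensor_from_lambdas(spec: ScenarioSpec) -> np.ndarray:
    """Normalize exp(sum of lambda terms) into a probability tensor."""
    names = [f.name for f in spec.factors]
    shape = tuple(f.n_levels for f in spec.factors)
    log_f = np.zeros(shape)
    for key, values in spec.parameters["lambdas"].items():
        term = (key,) if isinstance(key, str) else tuple(key)
        arr = np.asarray(values, dtype=float)
        expected = tuple(spec.factor(f).n_levels for f in term)
        if arr.shape != expected:
            raise ValueError(f"lambda term {term} has shape {arr.shape}, expected {expected}")
        bshape = [1] * len(names)
        for f, s in zip(term, arr.shape):
            bshape[names.index(f)] = s
        log_f = log_f + arr.reshape(bshape)
    f = np.exp(log_f - log_f.max())
    return f / f.sum()


def _probability_tensor(spec: ScenarioSpec) -> np.ndarray:
    if spec.mechanism == "probability-tensor":
        f = np.asarray(spec.parameters["probs"], dtype=float)
        if (f < 0).any():
            raise ValueError("negative cell probabilities")
        total = f.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("non-normalizable probability tensor")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cell probabilities must sum to 1")
        expected = tuple(fa.n_levels for fa in spec.factors)
        if f.shape != expected:
            raise ValueError(f"tensor shape {f.shape} does not match factors {expected}")
        return f
    if spec.mechanism == "loglin-lambda":
        return _tensor_from_lambdas(spec)
    raise ValueError("logistic scenarios sample records, not tables")


def sample_table(spec: ScenarioSpec) -> ContingencyTable:
    """Draw one Multinomial(N, f) count tensor under the scenario's seed."""
    f = _probability_tensor(spec)
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.N, f.ravel()).reshape(f.shape)
    return ContingencyTable(list(spec.factors), counts)


def sample_logistic_records(spec: ScenarioSpec) -> pd.DataFrame:
    """Draw case-level records: predictors from their joint distribution,
    target Bernoulli on the inverse-logit of the linear predictor.

    Coefficients are reference-coded: ``intercept`` is a scalar; a main
    term keyed by a factor name maps to per-level effects (reference
    level first, conventionally 0); an interaction keyed by a tuple of
    factor names maps to an effect grid over those factors' levels.
    The target's second level is the modelled event.
    """
    if spec.mechanism != "logistic":
        raise ValueError("sample_logistic_records requires the logistic mechanism")
    params = spec.parameters
    target = params["target"]
    tspec = spec.factor(target)
    if tspec.n_levels != 2:
        raise ValueError("logistic target must be binary")
    predictors = [f for f in spec.factors if f.name != target]
    rng = np.random.default_rng(spec.seed)
    # predictor draw: independent per-factor margins unless a joint tensor is given
    if "predictor_probs" in params:
        probs: Mapping = params["predictor_probs"]
        idx = {}
        for f in predictors:
            p = np.asarray(probs.get(f.name, np.full(f.n_levels, 1.0 / f.n_levels)), float)
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(f"invalid marginal distribution for {f.name!r}")
            idx[f.name] = rng.choice(f.n_levels, size=spec.N, p=p)
    else:
        joint = np.asarray(params["predictor_joint"], dtype=float)
        flat = rng.choice(joint.size, size=spec.N, p=joint.ravel() / joint.sum())
        unr = np.unravel_index(flat, joint.shape)
        idx = {f.name: unr[i] for i, f in enumerate(predictors)}
    coeffs = params["coefficients"]
    known = {"intercept"} | {f.name for f in predictors}
    eta = np.full(spec.N, float(coeffs.get("intercept", 0.0)))
    for key, values in coeffs.items():
        if key == "intercept":
            continue
        term = (key,) if isinstance(key, str) else tuple(key)
        for f in term:
            if f not in known:
                raise KeyError(f"coefficient key {key!r} names unknown predictor {f!r}")
        arr = np.asarray(values, dtype=float)
        expected = tuple(spec.factor(f).n_levels for f in term)
        if arr.shape != expected:
            raise ValueError(f"coefficient {key!r} has shape {arr.shape}, expected {expected}")
        eta = eta + arr[tuple(idx[f] for f in term)]
    p_event = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(spec.N) < p_event).astype(int)
    data = {f.name: np.asarray(f.levels, dtype=object)[idx[f.name]] for f in predictors}
    data[target] = np.asarray(tspec.levels, dtype=object)[y]
    return pd.DataFrame(data)


def load_scenario(path) -> ScenarioSpec:
    """Read a scenario from a YAML config file.

    Layout::

        factors:
          - {name: X1, levels: [a, b]}
        mechanism: logistic
        N: 2000
        seed: 7
        parameters:
          target: T
          coefficients:
            intercept: -1.0
            X1: [0.0, 1.5]
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    factors = [
        FactorSpec(d["name"], tuple(str(v) for v in d["levels"]), d.get("role", "unspecified"))
        for d in cfg["factors"]
    ]
    params = cfg.get("parameters", {})
    # YAML maps cannot key on tuples; accept "A|B" strings for interaction terms
    if "coefficients" in params:
        params["coefficients"] = {
            (tuple(k.split("|")) if isinstance(k, str) and "|" in k else k): v
            for k, v in params["coefficients"].items()
        }
    if "lambdas" in params:
        params["lambdas"] = {
            (tuple(k.split("|")) if "|" in k else k): v for k, v in params["lambdas"].items()
        }
    return ScenarioSpec(
        factors=factors,
        mechanism=cfg["mechanism"],
        parameters=params,
        N=int(cfg["N"]),
        seed=int(cfg["seed"]),
    )
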