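"""Logistic models on contingency tables, fitted on the grouped
(covariate-class) binomial likelihood.

The model is specified by categorical terms: a *main* term for an
L-level factor contributes L-1 reference-coded parameters; a *crossing*
entered as a compound factor (the ``A*B`` dialect) contributes
``L_A * L_B - 1`` parameters; a *pure interaction* added on top of
existing mains (the ``A:B`` dialect) contributes ``(L_A-1)(L_B-1)``.

Deviance is the grouped-binomial G² against the saturated model on the
table of distinct covariate classes; its degrees of freedom are the
nominal class count minus the parameter count (a flag switches to
populated classes only).  Fitting is iteratively reweighted least
squares via statsmodels GLM.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .infodecomp import _pvalue
from .tables import ContingencyTable, crosstab

__all__ = [
    "LogisticTerm",
    "LogisticSpec",
    "LogisticFit",
    "parse_logistic_spec",
    "fit_logistic",
    "goodness_of_fit",
]


@dataclass(frozen=True)
class LogisticTerm:
    kind: str  # main | compound | interaction
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("main", "compound", "interaction"):
            raise ValueError(f"invalid term kind {self.kind!r}")
        if self.kind == "main" and len(self.factors) != 1:
            raise ValueError("main term must name exactly one factor")
        if self.kind in ("compound", "interaction") and len(self.factors) < 2:
            raise ValueError(f"{self.kind} term needs at least two factors")

    def label(self) -> str:
        sep = {"main": "", "compound": "*", "interaction": ":"}[self.kind]
        return sep.join(self.factors) if self.kind != "main" else self.factors[0]


@dataclass(frozen=True)
class LogisticSpec:
    """Target plus model terms; the intercept is always present."""

    target: str
    terms: tuple[LogisticTerm, ...]

    def __post_init__(self) -> None:
        labels = [t.label() for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate terms in spec")
        for t in self.terms:
            if self.target in t.factors:
                raise ValueError("target cannot appear among model terms")

    @property
    def predictor_factors(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            for f in t.factors:
                if f not in seen:
                    seen.append(f)
        return seen


def parse_logistic_spec(spec: str) -> LogisticSpec:
    """Parse the formula dialect ``T ~ A1 + A3*A14 + A5:A9``.

    ``*`` (or the crossing sign) enters the factors as one compound
    variable; ``:`` enters a pure interaction.
    """
    if "~" not in spec:
        raise ValueError("spec must have the form 'target ~ term + term + ...'")
    left, right = spec.split("~", 1)
    target = left.strip()
    if not target:
        raise ValueError("missing target")
    terms: list[LogisticTerm] = []
    for raw in right.split("+"):
        token = raw.strip().replace("×", "*")
        if not token:
            continue
        if "*" in token and ":" in token:
            raise ValueError(f"mixed '*' and ':' in term {token!r}")
        if "*" in token:
            terms.append(LogisticTerm("compound", tuple(t.strip() for t in token.split("*"))))
        elif ":" in token:
            terms.append(LogisticTerm("interaction", tuple(t.strip() for t in token.split(":"))))
        else:
            if not re.fullmatch(r"[\w.]+", token):
                raise ValueError(f"cannot parse term {token!r}")
            terms.append(LogisticTerm("main", (token,)))
    if not terms:
        raise ValueError("no model terms")
    return LogisticSpec(target=target, terms=tuple(terms))


@dataclass
class LogisticFit:
    spec: LogisticSpec
    coefficients: dict[str, float]
    deviance: float
    df: int
    p: float
    loglik: float
    aic: float
    converged: bool
    n_parameters: int
    n_classes_populated: int
    n_classes_nominal: int
    fitted_class_probs: pd.Series


def _design_columns(
    spec: LogisticSpec, table: ContingencyTable, level_idx: np.ndarray, pred_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Reference-coded design matrix for the covariate classes.

    ``level_idx`` has one row per class and one column per predictor
    factor (level indices); reference level is index 0 of each factor.
    """
    cols: list[np.ndarray] = [np.ones(level_idx.shape[0])]
    names: list[str] = ["Intercept"]
    pos = {n: i for i, n in enumerate(pred_names)}
    for term in spec.terms:
        specs = [table.factor(f) for f in term.factors]
        idx = [level_idx[:, pos[f]] for f in term.factors]
        if term.kind == "main":
            (f,) = specs
            for j in range(1, f.n_levels):
                cols.append((idx[0] == j).astype(float))
                names.append(f"{f.name}[{f.levels[j]}]")
        elif term.kind == "compound":
            sizes = [f.n_levels for f in specs]
            for combo in itertools.product(*(range(s) for s in sizes)):
                if all(c == 0 for c in combo):
                    continue  # reference combination
                col = np.ones(level_idx.shape[0])
                for i, c in zip(idx, combo):
                    col *= (i == c).astype(float)
                cols.append(col)
                lab = "|".join(f.levels[c] for f, c in zip(specs, combo))
                names.append(f"{term.label()}[{lab}]")
        else:  # pure interaction: products of non-reference dummies
            ranges = [range(1, f.n_levels) for f in specs]
            for combo in itertools.product(*ranges):
                col = np.ones(level_idx.shape[0])
                for i, c in zip(idx, combo):
                    col *= (i == c).astype(float)
                cols.append(col)
                lab = ":".join(f.levels[c] for f, c in zip(specs, combo))
                names.append(f"{term.label()}[{lab}]")
    return np.column_stack(cols), names


def fit_logistic(
    data,
    spec: LogisticSpec | str,
    tol: float = 1e-8,
    max_iter: int = 100,
    populated_classes: bool = False,
) -> LogisticFit:
    """Fit the logistic model on the grouped contingency table.

    ``data`` may be case-level records (DataFrame) or a
    :class:`ContingencyTable` containing the target and all term factors.
    The target must be binary.  The reference (failure) outcome and the
    reference level of each covariate are the first declared levels for
    table input, and the lexicographically first levels for records.
    """
    if isinstance(spec, str):
        spec = parse_logistic_spec(spec)
    pred_names = spec.predictor_factors
    involved = pred_names + [spec.target]
    if isinstance(data, pd.DataFrame):
        # sort levels so the fit is invariant to record order; the reference
        # level of each factor (and of the target) is the lexicographic first
        from .tables import FactorSpec

        specs = [
            FactorSpec(c, tuple(sorted(data[c].astype(str).unique()))) for c in involved
        ]
        table = crosstab(data, involved, factor_specs=specs)
    else:
        table = data.marginalize([n for n in data.factor_names if n in involved])
    tspec = table.factor(spec.target)
    if tspec.n_levels != 2:
        raise ValueError(f"target {spec.target!r} must be binary, has {tspec.n_levels} levels")
    counts, (C, _) = table.group_view([tuple(pred_names), (spec.target,)])
    shape = tuple(table.factor(f).n_levels for f in pred_names)
    level_idx = np.column_stack(np.unravel_index(np.arange(C), shape))
    X_all, coef_names = _design_columns(spec, table, level_idx, pred_names)
    trials = counts.sum(axis=1)
    events = counts[:, 1]  # second target level is the modelled event
    keep = trials > 0
    X = X_all[keep]
    endog = np.column_stack([events[keep], trials[keep] - events[keep]]).astype(float)
    n_params = X.shape[1]
    if keep.sum() < n_params:
        raise ValueError(
            f"only {int(keep.sum())} populated covariate classes for {n_params} parameters"
        )
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-separation chatter handled below
        res = model.fit(maxiter=max_iter, tol=tol)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn("logistic fit did not converge", RuntimeWarning)
    probs = np.asarray(res.fittedvalues)
    sep = (probs < 1e-8) | (probs > 1 - 1e-8)
    if sep.any() and np.abs(res.params).max() > 10:
        first = int(np.flatnonzero(sep)[0])
        labels = [
            table.factor(f).levels[level_idx[keep][first, i]]
            for i, f in enumerate(pred_names)
        ]
        warnings.warn(
            f"possible complete separation at covariate class {tuple(labels)}",
            RuntimeWarning,
        )
    n_pop = int(keep.sum())
    n_nom = int(math.prod(shape))
    df = (n_pop if populated_classes else n_nom) - n_params
    deviance = float(res.deviance)
    fit = LogisticFit(
        spec=spec,
        coefficients=dict(zip(coef_names, (float(b) for b in res.params))),
        deviance=deviance,
        df=df,
        p=_pvalue(max(deviance, 0.0), df),
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2.0 * n_params),
        converged=converged,
        n_parameters=n_params,
        n_classes_populated=n_pop,
        n_classes_nominal=n_nom,
        fitted_class_probs=pd.Series(probs),
    )
    return fit


def goodness_of_fit(fit: LogisticFit, alpha: float = 0.05) -> tuple[float, int, float, str]:
    """LR goodness-of-fit of the grouped model: (deviance, df, p, verdict).

    Verdict is ``valid`` when p >= alpha (the model's lack of fit is not
    significant), else ``under-fit``.
    """
    verdict = "valid" if fit.p >= alpha else "under-fit"
    return fit.deviance, fit.df, fit.p, verdict
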