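"""Hierarchical log-linear models: IPF fitting, deviance, and the
Pythagorean split of conditional mutual information.

A hierarchical model is specified by its maximal generators (e.g.
``{XZ, YZ}`` for conditional independence of X and Y given Z).  Iterative
proportional fitting (IPF) cyclically matches each generator margin of
the fitted means to the observed margin; the limit is the maximum
likelihood fit, and the G² deviance ``2 * sum n log(n / mu)`` is the
likelihood-ratio statistic against the saturated model.

The split

    CMI(X, Y | Z) = Int(X, Y, Z) + Par(X, Y | Z)

is orthogonal: ``Int`` is the deviance of the homogeneous-association
(no-three-factor-interaction) model {XZ, YZ, XY} — heterogeneity of the
X–Y association across strata of Z — and ``Par``, obtained by
subtraction, is the homogeneous association component.  Testing the two
components separately at sizes alpha1 and alpha2 gives a two-step test
of conditional independence with overall size
``alpha = alpha1 + alpha2 - alpha1*alpha2``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .infodecomp import CLAMP_TOL, InfoTerm, _pvalue, conditional_mi
from .tables import ContingencyTable, FactorSpec

__all__ = [
    "LoglinModel",
    "LoglinFit",
    "PythagoreanSplit",
    "AlphaSplit",
    "TwoStepDecision",
    "parse_model",
    "ipf_fit",
    "model_deviance",
    "pythagorean_split",
    "two_step_test",
    "make_alpha_split",
    "graph_extract",
]


@dataclass(frozen=True)
class LoglinModel:
    """A hierarchical log-linear model given by its maximal generators."""

    generators: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        gens = tuple(frozenset(g) for g in self.generators)
        if not gens:
            raise ValueError("model needs at least one generator")
        for a, b in itertools.permutations(gens, 2):
            if a < b:
                raise ValueError(
                    f"generator {set(a)} is a subset of {set(b)}; list maximal terms only"
                )
        if len(set(gens)) != len(gens):
            raise ValueError("duplicate generators")
        object.__setattr__(self, "generators", gens)

    @property
    def factors(self) -> frozenset:
        return frozenset().union(*self.generators)

    def closure(self) -> set[frozenset]:
        """All non-empty subsets of the generators (the hierarchical terms)."""
        terms: set[frozenset] = set()
        for g in self.generators:
            for r in range(1, len(g) + 1):
                terms.update(frozenset(c) for c in itertools.combinations(g, r))
        return terms

    def n_parameters(self, table: ContingencyTable) -> int:
        """Independent parameters beyond the intercept, nominal level counts."""
        total = 0
        for term in self.closure():
            total += math.prod(table.factor(f).n_levels - 1 for f in term)
        return total

    def __str__(self) -> str:
        return "{" + ", ".join("*".join(sorted(g)) for g in self.generators) + "}"


def parse_model(spec: str, factor_names) -> LoglinModel:
    """Parse the generator mini-language, e.g. ``{CA, CS, ADG}`` or
    ``{A1*A3, A1*A12}``.

    Within a generator, factor names may be separated by ``*`` (or the
    crossing sign) or concatenated when the segmentation into known
    factor names is unambiguous.
    """
    names = list(factor_names)
    body = spec.strip()
    if body.startswith("{") and body.endswith("}"):
        body = body[1:-1]
    gens = []
    for token in body.split(","):
        token = token.strip().replace("×", "*")
        if not token:
            continue
        if "*" in token:
            parts = [t.strip() for t in token.split("*")]
            for p in parts:
                if p not in names:
                    raise ValueError(f"unknown factor {p!r} in model spec")
        else:
            parts = _segment(token, names)
        gens.append(frozenset(parts))
    return LoglinModel(tuple(gens))


def _segment(token: str, names) -> list[str]:
    """All ways to split ``token`` into a sequence of known factor names;
    must be unique."""
    results: list[list[str]] = []

    def rec(rest: str, acc: list[str]) -> None:
        if not rest:
            results.append(list(acc))
            return
        for n in names:
            if rest.startswith(n):
                acc.append(n)
                rec(rest[len(n):], acc)
                acc.pop()

    rec(token, [])
    if not results:
        raise ValueError(f"cannot parse generator {token!r} from factors {names}")
    uniq = {tuple(r) for r in results}
    if len({frozenset(r) for r in uniq}) > 1:
        raise ValueError(f"ambiguous generator {token!r}; use '*' separators")
    return results[0]


@dataclass
class LoglinFit:
    model: LoglinModel
    fitted_means: np.ndarray
    deviance: float
    df: int
    p: float
    converged: bool
    iterations: int
    max_margin_error: float

    def __post_init__(self) -> None:
        if self.deviance < -CLAMP_TOL:
            raise ValueError(f"negative deviance {self.deviance}")
        self.deviance = max(self.deviance, 0.0)


def _margin(arr: np.ndarray, axes_keep: tuple[int, ...]) -> np.ndarray:
    drop = tuple(i for i in range(arr.ndim) if i not in axes_keep)
    return arr.sum(axis=drop) if drop else arr


def _broadcast_shape(ndim: int, axes_keep: tuple[int, ...], margin: np.ndarray):
    shape = [1] * ndim
    for ax, size in zip(axes_keep, margin.shape):
        shape[ax] = size
    return margin.reshape(shape)


def ipf_fit(
    table: ContingencyTable,
    model: LoglinModel,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LoglinFit:
    """Fit a hierarchical log-linear model by iterative proportional fitting.

    Cyclically rescales the fitted means so each generator margin matches
    the observed margin, until the maximum relative margin discrepancy
    falls below ``tol``.  Cycle order is generator declaration order.
    Starts from a uniform positive tensor; observed zero margins drive
    the corresponding fitted cells to zero.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    unknown = model.factors - set(table.factor_names)
    if unknown:
        raise KeyError(f"model uses factors not in table: {sorted(unknown)}")
    n = table.counts.astype(float)
    N = n.sum()
    if N == 0:
        raise ValueError("empty table")
    gen_axes = [tuple(sorted(table.axis(f) for f in g)) for g in model.generators]
    obs_margins = [_margin(n, axes) for axes in gen_axes]
    mu = np.full(n.shape, N / n.size)
    it = 0
    err = np.inf
    for it in range(1, max_iter + 1):
        for axes, obs in zip(gen_axes, obs_margins):
            cur = _margin(mu, axes)
            ratio = np.divide(obs, cur, out=np.zeros_like(obs), where=cur > 0)
            mu = mu * _broadcast_shape(mu.ndim, axes, ratio)
        err = max(
            float(np.max(np.abs(_margin(mu, axes) - obs) / np.maximum(obs, 1.0)))
            for axes, obs in zip(gen_axes, obs_margins)
        )
        if err < tol:
            break
    converged = err < tol
    if not converged:
        warnings.warn(
            f"IPF did not converge in {max_iter} iterations "
            f"(margin discrepancy {err:.3g} > tol {tol:.3g})",
            RuntimeWarning,
        )
    mask = n > 0
    deviance = float(2.0 * (n[mask] * (np.log(n[mask]) - np.log(mu[mask]))).sum())
    cells = n.size
    df = cells - 1 - model.n_parameters(table)
    return LoglinFit(
        model=model,
        fitted_means=mu,
        deviance=deviance,
        df=df,
        p=_pvalue(max(deviance, 0.0), df),
        converged=converged,
        iterations=it,
        max_margin_error=err,
    )


def model_deviance(
    table: ContingencyTable, model: LoglinModel, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[float, int, float]:
    """LR deviance, residual df, and chi-square p of a hierarchical model."""
    fit = ipf_fit(table, model, tol=tol, max_iter=max_iter)
    return fit.deviance, fit.df, fit.p


# -- Pythagorean split -------------------------------------------------------


@dataclass(frozen=True)
class PythagoreanSplit:
    """CMI with its orthogonal interaction and partial-association parts."""

    cmi: InfoTerm
    interaction: InfoTerm
    partial: InfoTerm

    @property
    def additivity_error(self) -> float:
        return abs(self.interaction.stat + self.partial.stat - self.cmi.stat)


def _compound_three_way(table: ContingencyTable, lhs, rhs, given) -> ContingencyTable:
    """Collapse to the factors involved and compound each composite group."""
    sub = table.marginalize(list(lhs) + list(rhs) + list(given))
    for group, name in ((lhs, "__X__"), (rhs, "__Y__"), (given, "__Z__")):
        if len(group) > 1:
            sub = sub.compound(list(group), name)
    names = []
    for group, name in ((lhs, "__X__"), (rhs, "__Y__"), (given, "__Z__")):
        names.append(name if len(group) > 1 else group[0])
    return sub.reorder(names)


def pythagorean_split(
    table: ContingencyTable, lhs, rhs, given, tol: float = 1e-8, max_iter: int = 1000
) -> PythagoreanSplit:
    """Split CMI(lhs, rhs | given) into interaction + partial association.

    The interaction statistic is the IPF deviance of the
    no-three-factor-interaction model {lhs·given, rhs·given, lhs·rhs} on
    the (compounded) three-way table, with (I-1)(J-1)(K-1) df; the
    partial association is obtained by subtraction with (I-1)(J-1) df.
    """
    lhs = (lhs,) if isinstance(lhs, str) else tuple(lhs)
    rhs = (rhs,) if isinstance(rhs, str) else tuple(rhs)
    given = (given,) if isinstance(given, str) else tuple(given)
    if not given:
        raise ValueError("given group must be non-empty")
    cmi = conditional_mi(table, lhs, rhs, given)
    three = _compound_three_way(table, lhs, rhs, given)
    x, y, z = three.factor_names
    model = LoglinModel((frozenset({x, z}), frozenset({y, z}), frozenset({x, y})))
    fit = ipf_fit(three, model, tol=tol, max_iter=max_iter)
    if not fit.converged:
        raise RuntimeError(
            f"IPF failed to converge for the homogeneous-association model "
            f"(margin error {fit.max_margin_error:.3g} after {fit.iterations} iterations)"
        )
    I, J, K = (three.factor(f).n_levels for f in (x, y, z))
    int_df = (I - 1) * (J - 1) * (K - 1)
    par_df = (I - 1) * (J - 1)
    int_stat = fit.deviance
    par_stat = cmi.stat - int_stat
    if par_stat < -1e-6:
        raise RuntimeError(
            f"partial association came out negative ({par_stat:.3g}); "
            "this signals an IPF failure"
        )
    if par_stat < 0:
        warnings.warn("clamping a small negative partial association to 0", RuntimeWarning)
        par_stat = 0.0
    interaction = InfoTerm("INT", lhs, rhs, given, int_stat, int_df)
    partial = InfoTerm("PAR", lhs, rhs, given, par_stat, par_df)
    return PythagoreanSplit(cmi=cmi, interaction=interaction, partial=partial)


# -- two-step test -----------------------------------------------------------


@dataclass(frozen=True)
class AlphaSplit:
    """Sizes of the two orthogonal sub-tests; the overall size satisfies
    alpha = alpha1 + alpha2 - alpha1*alpha2 exactly."""

    alpha: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        ident = self.alpha1 + self.alpha2 - self.alpha1 * self.alpha2
        if abs(ident - self.alpha) > 1e-12:
            raise ValueError(
                f"alpha1 + alpha2 - alpha1*alpha2 = {ident} does not equal alpha = {self.alpha}"
            )


def make_alpha_split(alpha: float, mode: str = "equal", alpha1: float | None = None) -> AlphaSplit:
    """Construct an :class:`AlphaSplit`.

    ``equal`` mode solves alpha1 = alpha2 = 1 - sqrt(1 - alpha);
    ``specified`` mode takes alpha1 and solves alpha2 = (alpha - alpha1) / (1 - alpha1).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if mode == "equal":
        a1 = a2 = 1.0 - math.sqrt(1.0 - alpha)
    elif mode == "specified":
        if alpha1 is None:
            raise ValueError("specified mode requires alpha1")
        if not (0 <= alpha1 < alpha):
            raise ValueError("alpha1 must satisfy 0 <= alpha1 < alpha")
        a1 = alpha1
        a2 = (alpha - alpha1) / (1.0 - alpha1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # recompute alpha from the identity to absorb float round-off
    return AlphaSplit(alpha=a1 + a2 - a1 * a2, alpha1=a1, alpha2=a2)


@dataclass(frozen=True)
class TwoStepDecision:
    """Outcome of the two-step LR test of conditional independence."""

    interaction_significant: bool
    partial_significant: bool
    rejected: bool
    p_interaction: float
    p_partial: float
    alphas: AlphaSplit


def two_step_test(split: PythagoreanSplit, alphas: AlphaSplit) -> TwoStepDecision:
    """Test Int at size alpha1 and Par at size alpha2; conditional
    independence is rejected when either is significant."""
    int_sig = split.interaction.p <= alphas.alpha1 and alphas.alpha1 > 0
    par_sig = split.partial.p <= alphas.alpha2 and alphas.alpha2 > 0
    return TwoStepDecision(
        interaction_significant=int_sig,
        partial_significant=par_sig,
        rejected=int_sig or par_sig,
        p_interaction=split.interaction.p,
        p_partial=split.partial.p,
        alphas=alphas,
    )


# -- graphical model ---------------------------------------------------------


def graph_extract(model: LoglinModel) -> tuple[set[frozenset], list[frozenset]]:
    """Edges (all 2-subsets of every generator) and cliques (generators of
    size >= 3, listed for highlighted rendering)."""
    edges: set[frozenset] = set()
    for g in model.generators:
        edges.update(frozenset(e) for e in itertools.combinations(sorted(g), 2))
    cliques = [g for g in model.generators if len(g) >= 3]
    return edges, cliques


def graph_to_dot(model: LoglinModel) -> str:
    """Plain-text DOT rendering; clique edges are drawn bold."""
    edges, cliques = graph_extract(model)
    clique_edges: set[frozenset] = set()
    for c in cliques:
        clique_edges.update(frozenset(e) for e in itertools.combinations(sorted(c), 2))
    lines = ["graph loglin {"]
    for name in sorted(model.factors):
        lines.append(f'  "{name}";')
    for e in sorted(edges, key=lambda e: tuple(sorted(e))):
        a, b = sorted(e)
        style = " [style=bold]" if e in clique_edges else ""
        lines.append(f'  "{a}" -- "{b}"{style};')
    lines.append("}")
    return "\n".join(lines)
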