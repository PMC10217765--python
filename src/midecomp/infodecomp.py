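"""Plug-in mutual-information estimators on the likelihood-ratio (G²) scale.

All statistics are reported as ``2N * I_hat`` in natural logarithms, i.e.
the G² likelihood-ratio statistic of the corresponding (conditional)
independence hypothesis, which is asymptotically chi-square.  Degrees of
freedom use nominal level counts: for MI between groups with I and J
level combinations, df = (I-1)(J-1); for CMI given a conditioning group
with K combinations, df = (I-1)(J-1)K.  A ``df_observed`` flag
substitutes observed-support counts for sparse tables.

The chain identity I(X,T) = I(X1,T) + I(X2,T|X1) + ... is exact for
plug-in estimates; :func:`chain_decompose` returns the components
together with the joint total so additivity can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .tables import ContingencyTable

__all__ = [
    "InfoTerm",
    "Decomposition",
    "entropy",
    "mutual_information",
    "conditional_mi",
    "chain_decompose",
]

#: statistics within this distance below zero are round-off and clamped
CLAMP_TOL = 1e-8


def _clamp(stat: float, what: str = "statistic") -> float:
    if stat < -CLAMP_TOL:
        raise ValueError(f"{what} is negative beyond round-off: {stat}")
    return max(stat, 0.0)


def _as_group(g) -> tuple[str, ...]:
    if isinstance(g, str):
        return (g,)
    return tuple(g)


@dataclass(frozen=True)
class InfoTerm:
    """One MI / CMI / interaction / partial-association estimate.

    ``stat`` is on the 2N-scaled G² scale; ``p`` is the chi-square
    upper-tail probability at ``df`` degrees of freedom.
    """

    kind: str  # one of {"MI", "CMI", "INT", "PAR"}
    lhs: tuple[str, ...]
    rhs: tuple[str, ...]
    given: tuple[str, ...]
    stat: float
    df: int
    p: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("MI", "CMI", "INT", "PAR"):
            raise ValueError(f"invalid kind {self.kind!r}")
        object.__setattr__(self, "stat", _clamp(self.stat, f"{self.kind} statistic"))
        if self.df < 0:
            raise ValueError("negative degrees of freedom")
        if self.p is None:
            object.__setattr__(self, "p", _pvalue(self.stat, self.df))

    @property
    def mir(self) -> float:
        """MI ratio: the statistic per degree of freedom (selection score)."""
        return self.stat / self.df if self.df > 0 else float("inf")

    def label(self) -> str:
        lhs = ",".join(self.lhs)
        rhs = ",".join(self.rhs)
        if self.given:
            return f"{self.kind}({lhs}; {rhs} | {','.join(self.given)})"
        return f"{self.kind}({lhs}; {rhs})"


def _pvalue(stat: float, df: int) -> float:
    if df == 0:
        # a zero-df statistic carries no test; report p = 1 by convention
        return 1.0
    return float(chi2.sf(stat, df))


@dataclass(frozen=True)
class Decomposition:
    """An orthogonal decomposition: component stats sum to the total."""

    total: InfoTerm
    components: tuple[InfoTerm, ...]

    @property
    def additivity_error(self) -> float:
        return abs(sum(c.stat for c in self.components) - self.total.stat)

    @property
    def df_consistent(self) -> bool:
        return sum(c.df for c in self.components) == self.total.df


# -- estimators -------------------------------------------------------------


def entropy(table: ContingencyTable) -> float:
    """Plug-in Shannon entropy of the joint distribution, in nats."""
    if table.N == 0:
        raise ValueError("empty table")
    p = table.probabilities.ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _g2_independence(counts2d: np.ndarray) -> float:
    """G² of independence on a two-axis count array; 0·log 0 = 0."""
    n = counts2d.astype(float)
    total = n.sum()
    if total == 0:
        return 0.0
    row = n.sum(axis=1, keepdims=True)
    col = n.sum(axis=0, keepdims=True)
    mask = n > 0
    # expected cannot be zero where observed is positive
    contrib = n[mask] * (np.log(n[mask] * total) - np.log((row @ col / total)[mask] * total))
    return float(2.0 * contrib.sum())


def _support_size(counts: np.ndarray, axis_keep: int) -> int:
    """Number of levels with positive marginal count along one axis of a 2-D array."""
    sums = counts.sum(axis=1 - axis_keep)
    return int((sums > 0).sum())


def mutual_information(
    table: ContingencyTable,
    lhs,
    rhs,
    df_observed: bool = False,
) -> InfoTerm:
    """2N-scaled MI (G² of independence) between two disjoint factor groups."""
    lhs, rhs = _as_group(lhs), _as_group(rhs)
    if not lhs or not rhs:
        raise ValueError("factor groups must be non-empty")
    counts, (I, J) = table.group_view([lhs, rhs])
    stat = _g2_independence(counts)
    if df_observed:
        I = _support_size(counts, 0)
        J = _support_size(counts, 1)
    df = (I - 1) * (J - 1)
    return InfoTerm("MI", lhs, rhs, (), stat, df)


def conditional_mi(
    table: ContingencyTable,
    lhs,
    rhs,
    given,
    df_observed: bool = False,
) -> InfoTerm:
    """2N-scaled CMI: sum over conditioning cells of within-stratum G².

    Empty strata contribute 0 to the statistic; df uses the nominal
    number K of conditioning-level combinations, (I-1)(J-1)K.
    """
    lhs, rhs, given = _as_group(lhs), _as_group(rhs), _as_group(given)
    if not given:
        raise ValueError("conditioning group must be non-empty (use mutual_information)")
    counts, (I, J, K) = table.group_view([lhs, rhs, given])
    stat = sum(_g2_independence(counts[:, :, k]) for k in range(K))
    if df_observed:
        flat = counts.reshape(I, J, K)
        nonempty = [k for k in range(K) if flat[:, :, k].sum() > 0]
        df = sum(
            (_support_size(flat[:, :, k], 0) - 1) * (_support_size(flat[:, :, k], 1) - 1)
            for k in nonempty
        )
    else:
        df = (I - 1) * (J - 1) * K
    return InfoTerm("CMI", lhs, rhs, given, stat, df)


def info_term(table: ContingencyTable, lhs, rhs, given=(), **kw) -> InfoTerm:
    """MI if ``given`` is empty, else CMI."""
    given = _as_group(given)
    if given:
        return conditional_mi(table, lhs, rhs, given, **kw)
    return mutual_information(table, lhs, rhs, **kw)


def chain_decompose(
    table: ContingencyTable,
    target,
    order: Sequence[str],
    df_observed: bool = False,
) -> Decomposition:
    """Chain-rule decomposition of the joint MI between a predictor set and
    the target:

        I({X1..Xm}; T) = I(X1;T) + I(X2;T|X1) + ... + I(Xm;T|X1..Xm-1)

    The components depend on the predictor order, the total does not.
    """
    target = _as_group(target)
    order = list(order)
    if len(set(order)) != len(order):
        raise ValueError("duplicate predictors in order")
    if set(target) & set(order):
        raise ValueError("target cannot appear among predictors")
    if not order:
        raise ValueError("empty predictor order")
    components: list[InfoTerm] = []
    for t, x in enumerate(order):
        components.append(
            info_term(table, (x,), target, tuple(order[:t]), df_observed=df_observed)
        )
    total = mutual_information(table, tuple(order), target, df_observed=df_observed)
    return Decomposition(total, tuple(components))
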