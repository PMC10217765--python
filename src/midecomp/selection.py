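"""Stepwise variable selection and model construction by MI decomposition.

The procedure has four steps:

1. *Forward selection.*  Start from the candidate with the best MI score
   against the target; at each later stage add the unselected candidate
   with the most significant CMI given the current set (``min_p``
   criterion) or the largest joint MI-per-df ratio (``mir`` criterion).
   Stop when no remaining candidate is significant at the overall size
   alpha.
2. *Backward deletion.*  Repeatedly drop the selected predictor whose
   leave-one-out CMI given the rest has the largest insignificant
   p-value, until every retained predictor is indispensable.
3. *Rearrangement.*  Order the final predictors in the chain identity so
   the interaction components that can be discarded are pushed to the
   outermost positions.  For five or fewer predictors all orders are
   examined and the one with the fewest significant interaction terms
   wins (ties: lexicographically larger interaction p-values from the
   outermost position inward, then predictor names); for larger sets a
   greedy outermost-in search maximizes each interaction p in turn.
4. *Model construction.*  Keep every significant partial-association
   term as a main effect and every significant interaction term as an
   interaction; a retained high-order interaction may be replaced by a
   set of significant lower-order interactions when their combined
   statistic exceeds it at no larger combined df.

Selection operates on case-level records or on a pre-tabulated
:class:`~midecomp.tables.ContingencyTable`; with records, only the
factors each statistic involves are tabulated, so wide candidate sets
never materialize a full joint tensor.  All decisions are recorded in a
replayable :class:`SelectionTrace`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .infodecomp import Decomposition, InfoTerm, chain_decompose, info_term, mutual_information
from .loglin import AlphaSplit, PythagoreanSplit, make_alpha_split, pythagorean_split
from .tables import ContingencyTable, crosstab

__all__ = [
    "SelectionConfig",
    "SelectionTrace",
    "ModelTerms",
    "forward_select",
    "backward_delete",
    "rearrange_identity",
    "build_model",
    "select_and_build",
]


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    alpha_split: AlphaSplit | None = None
    criterion: str = "min_p"  # or "mir"
    max_predictors: int | None = None
    interaction_replacement: bool = True
    exhaustive_rearrange_limit: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.criterion not in ("min_p", "mir"):
            raise ValueError("criterion must be 'min_p' or 'mir'")
        if self.alpha_split is None:
            object.__setattr__(self, "alpha_split", make_alpha_split(self.alpha))


class _Source:
    """Uniform access to sub-tables from either records or a full table.

    Tabulates (and caches) only the factors a statistic involves, which
    keeps wide candidate sets tractable.
    """

    def __init__(self, data) -> None:
        if isinstance(data, pd.DataFrame):
            self.records: pd.DataFrame | None = data
            self.table: ContingencyTable | None = None
        elif isinstance(data, ContingencyTable):
            self.records = None
            self.table = data
        else:
            raise TypeError("data must be a DataFrame of records or a ContingencyTable")
        self._cache: dict[tuple[str, ...], ContingencyTable] = {}

    def sub(self, names: Sequence[str]) -> ContingencyTable:
        key = tuple(sorted(set(names)))
        if key not in self._cache:
            if self.table is not None:
                self._cache[key] = self.table.marginalize(
                    [n for n in self.table.factor_names if n in key]
                )
            else:
                self._cache[key] = crosstab(self.records, list(key))
        return self._cache[key]

    def term(self, lhs, rhs, given) -> InfoTerm:
        t = self.sub(tuple(lhs) + tuple(rhs) + tuple(given))
        return info_term(t, lhs, rhs, given)

    def split(self, lhs, rhs, given) -> PythagoreanSplit:
        t = self.sub(tuple(lhs) + tuple(rhs) + tuple(given))
        return pythagorean_split(t, lhs, rhs, given)


@dataclass
class StepRecord:
    kind: str  # forward | backward | rearrange
    scores: dict[str, dict]  # candidate -> {stat, df, mir, p}
    chosen: str | None
    reason: str


@dataclass
class SelectionTrace:
    """Replayable audit record: identical inputs reproduce it exactly."""

    steps: list[StepRecord] = field(default_factory=list)

    def record(self, kind: str, scores: dict, chosen: str | None, reason: str) -> None:
        self.steps.append(StepRecord(kind, scores, chosen, reason))

    def to_tsv(self) -> str:
        lines = ["step\tkind\tcandidate\tstat\tdf\tmir\tp\tchosen\treason"]
        for i, s in enumerate(self.steps, 1):
            for cand, sc in sorted(s.scores.items()):
                mark = "*" if cand == s.chosen else ""
                lines.append(
                    f"{i}\t{s.kind}\t{cand}\t{sc['stat']:.3f}\t{sc['df']}\t"
                    f"{sc['mir']:.4f}\t{sc['p']:.3g}\t{mark}\t{s.reason}"
                )
            if not s.scores:
                lines.append(f"{i}\t{s.kind}\t-\t-\t-\t-\t-\t\t{s.reason}")
        return "\n".join(lines)


def _score(term: InfoTerm) -> dict:
    return {"stat": term.stat, "df": term.df, "mir": term.mir, "p": term.p}


def _as_target(target) -> tuple[str, ...]:
    return (target,) if isinstance(target, str) else tuple(target)


def forward_select(
    data,
    target,
    candidates: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
) -> tuple[list[str], SelectionTrace]:
    """Step 1: forward selection of significant predictors.

    Ties are broken by (smaller p, larger MIR, lexicographic name); under
    the ``mir`` criterion the primary key is the joint-MI ratio
    I(selected + candidate; T) / df, with the CMI p-value as the
    significance gate in both modes.
    """
    target = _as_target(target)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate predictors")
    if set(target) & set(candidates):
        raise ValueError("target cannot be a candidate")
    src = _Source(data)
    trace = SelectionTrace()
    selected: list[str] = []
    remaining = list(candidates)
    while remaining:
        if config.max_predictors is not None and len(selected) >= config.max_predictors:
            trace.record("forward", {}, None, "max_predictors reached")
            break
        terms = {name: src.term((name,), target, tuple(selected)) for name in remaining}
        significant = {n: t for n, t in terms.items() if t.p <= config.alpha}
        scores = {n: _score(t) for n, t in terms.items()}
        if not significant:
            reason = (
                "no candidate significant at step 1"
                if not selected
                else "no remaining candidate significant"
            )
            trace.record("forward", scores, None, reason)
            break
        if config.criterion == "mir":
            joint = {
                n: mutual_information(
                    src.sub(tuple(selected) + (n,) + target), tuple(selected) + (n,), target
                ).mir
                for n in significant
            }
            chosen = min(significant, key=lambda n: (-joint[n], significant[n].p, n))
        else:
            chosen = min(
                significant, key=lambda n: (significant[n].p, -significant[n].mir, n)
            )
        trace.record("forward", scores, chosen, f"selected at alpha={config.alpha}")
        selected.append(chosen)
        remaining.remove(chosen)
    return selected, trace


def backward_delete(
    data,
    target,
    selected: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
) -> tuple[list[str], SelectionTrace]:
    """Step 2: drop predictors whose leave-one-out CMI is insignificant.

    At each pass the predictor with the largest insignificant p-value of
    CMI(X', T | rest) is deleted; stops when every leave-one-out CMI is
    significant (or nothing is left).
    """
    target = _as_target(target)
    src = _Source(data)
    retained = list(selected)
    trace = SelectionTrace()
    while retained:
        terms = {
            name: src.term((name,), target, tuple(x for x in retained if x != name))
            for name in retained
        }
        scores = {n: _score(t) for n, t in terms.items()}
        dispensable = {n: t for n, t in terms.items() if t.p > config.alpha}
        if not dispensable:
            trace.record("backward", scores, None, "all retained predictors indispensable")
            break
        drop = max(dispensable, key=lambda n: (dispensable[n].p, -dispensable[n].mir, n))
        trace.record("backward", scores, drop, f"deleted (p={dispensable[drop].p:.3g} > alpha)")
        retained.remove(drop)
    return retained, trace


@dataclass
class RearrangedDecomposition:
    """The chain identity in the chosen order, with a Pythagorean split
    for every CMI term (the machine analogue of a partitioned-CMI table)."""

    order: list[str]  # innermost (X1) first
    decomposition: Decomposition
    splits: list[PythagoreanSplit | None]  # aligned with components; None for the MI term


def _order_profile(src: _Source, target, order_inner_first, alpha1, cache) -> tuple[int, tuple]:
    """(number of significant interactions, interaction p-values outermost-in)."""
    n_sig = 0
    ps = []
    for t in range(len(order_inner_first) - 1, 0, -1):
        pred = order_inner_first[t]
        given = frozenset(order_inner_first[:t])
        key = (pred, given)
        if key not in cache:
            cache[key] = src.split((pred,), target, tuple(sorted(given)))
        p = cache[key].interaction.p
        ps.append(p)
        n_sig += p <= alpha1
    return n_sig, tuple(ps)


def rearrange_identity(
    data,
    target,
    predictors: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
    trace: SelectionTrace | None = None,
) -> RearrangedDecomposition:
    """Step 3: order the chain identity to minimize significant interactions.

    For ``m <= exhaustive_rearrange_limit`` every permutation is profiled;
    otherwise a greedy outermost-in pass places, at each position, the
    predictor whose top-order interaction has the largest p.
    """
    target = _as_target(target)
    predictors = list(predictors)
    if not predictors:
        raise ValueError("no predictors to rearrange")
    src = _Source(data)
    if trace is None:
        trace = SelectionTrace()
    alpha1 = config.alpha_split.alpha1
    cache: dict = {}
    m = len(predictors)
    if m <= config.exhaustive_rearrange_limit:
        best = None
        best_key = None
        for perm in itertools.permutations(sorted(predictors)):
            n_sig, ps = _order_profile(src, target, list(perm), alpha1, cache)
            # fewest significant interactions; then larger p outermost-in
            key = (n_sig, tuple(-p for p in ps), perm)
            if best_key is None or key < best_key:
                best_key = key
                best = list(perm)
        order = best
        trace.record(
            "rearrange",
            {},
            None,
            f"exhaustive order search over {m}! permutations: "
            f"{' -> '.join(order)} ({best_key[0]} significant interaction(s))",
        )
    else:
        order_outer_first: list[str] = []
        pool = list(predictors)
        while len(pool) > 1:
            cand = {}
            for name in pool:
                given = frozenset(x for x in pool if x != name)
                key = (name, given)
                if key not in cache:
                    cache[key] = src.split((name,), target, tuple(sorted(given)))
                cand[name] = cache[key]
            scores = {n: _score(s.interaction) for n, s in cand.items()}
            chosen = max(
                cand, key=lambda n: (cand[n].interaction.p, -cand[n].interaction.stat, n)
            )
            trace.record("rearrange", scores, chosen, "placed outermost (largest interaction p)")
            order_outer_first.append(chosen)
            pool.remove(chosen)
        order = [pool[0]] + list(reversed(order_outer_first))
    table = src.sub(tuple(order) + target)
    decomp = chain_decompose(table, target, order)
    splits: list[PythagoreanSplit | None] = [None]
    for t in range(1, len(order)):
        key = (order[t], frozenset(order[:t]))
        if key not in cache:
            cache[key] = src.split((order[t],), target, tuple(sorted(order[:t])))
        splits.append(cache[key])
    return RearrangedDecomposition(order=order, decomposition=decomp, splits=splits)


@dataclass
class ModelTerms:
    """Retained effects of the final model: main effects are significant
    partial-association terms, interactions are significant interaction
    terms (predictor-side factor groups)."""

    target: str
    mains: list[tuple[str, ...]]
    interactions: list[tuple[str, ...]]


def build_model(
    rearranged: RearrangedDecomposition,
    data,
    target,
    config: SelectionConfig = SelectionConfig(),
) -> ModelTerms:
    """Step 4: assemble the model from the rearranged identity.

    Each CMI term is tested by the two-step rule (Int at alpha1, Par at
    alpha2).  A significant high-order interaction Int(X_t, T, {X_1..X_t-1})
    with two or more conditioning factors is replaced by the set of
    three-way interactions {Int(X_t, T, X_j)} when each member is
    significant, their statistics sum to more than the high-order term,
    and their combined df is no larger.
    """
    target_name = target if isinstance(target, str) else target[0]
    src = _Source(data)
    alphas = config.alpha_split
    mains: list[tuple[str, ...]] = []
    interactions: list[tuple[str, ...]] = []
    order = rearranged.order
    first = rearranged.decomposition.components[0]
    if first.p <= config.alpha:
        mains.append((order[0],))
    for t in range(1, len(order)):
        split = rearranged.splits[t]
        assert split is not None
        pred = order[t]
        given = tuple(order[:t])
        if split.partial.p <= alphas.alpha2:
            mains.append((pred,))
        if split.interaction.p <= alphas.alpha1:
            replaced = False
            if config.interaction_replacement and len(given) >= 2:
                lower = []
                for g in given:
                    sub = src.split((pred,), (target_name,), (g,))
                    if sub.interaction.p <= alphas.alpha1:
                        lower.append((g, sub.interaction))
                if lower:
                    stat_sum = sum(term.stat for _, term in lower)
                    df_sum = sum(term.df for _, term in lower)
                    if stat_sum > split.interaction.stat and df_sum <= split.interaction.df:
                        for g, _ in lower:
                            interactions.append(tuple(sorted((pred, g))))
                        replaced = True
            if not replaced:
                interactions.append(tuple(sorted((pred,) + given)))
    if not mains:
        import warnings

        warnings.warn("no significant effects retained; model is empty", RuntimeWarning)
    return ModelTerms(target=target_name, mains=mains, interactions=interactions)


def select_and_build(
    data,
    target: str,
    candidates: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
) -> tuple[ModelTerms, SelectionTrace]:
    """Run Steps 1-4 end to end and return the model with a merged trace."""
    selected, trace_f = forward_select(data, target, candidates, config)
    trace = SelectionTrace(steps=list(trace_f.steps))
    if not selected:
        return ModelTerms(target=target, mains=[], interactions=[]), trace
    retained, trace_b = backward_delete(data, target, selected, config)
    trace.steps.extend(trace_b.steps)
    if not retained:
        return ModelTerms(target=target, mains=[], interactions=[]), trace
    rearranged = rearrange_identity(data, target, retained, config, trace)
    model = build_model(rearranged, data, target, config)
    return model, trace
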