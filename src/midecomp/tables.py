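"""Multi-way contingency tables with named, levelled axes.

A :class:`ContingencyTable` is a dense non-negative integer count tensor
with one axis per categorical factor.  It is the common currency of the
whole package: tables are built from case-level records
(:func:`crosstab`), reduced by :meth:`~ContingencyTable.marginalize`,
and composite factors (e.g. the conditioning pair ``{Y, Z}`` of a
conditional-independence statement) are formed by
:meth:`~ContingencyTable.compound`.

Level order is first-appearance order unless a :class:`FactorSpec`
pre-declares levels; this keeps degrees of freedom and dummy coding
reproducible across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "ContingencyTable",
    "crosstab",
    "discretize",
    "read_cases_csv",
    "read_uci_german",
    "read_table",
    "write_table",
    "UCI_GERMAN_COLUMNS",
]


@dataclass(frozen=True)
class FactorSpec:
    """A categorical factor: a name, an ordered set of levels, and a role."""

    name: str
    levels: tuple[str, ...]
    role: str = "unspecified"  # one of {"target", "predictor", "unspecified"}

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r} has duplicate levels")
        if self.role not in ("target", "predictor", "unspecified"):
            raise ValueError(f"invalid role {self.role!r}")
        object.__setattr__(self, "levels", tuple(str(lv) for lv in self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class ContingencyTable:
    """Dense count tensor over an ordered list of factors.

    Invariants: ``counts`` is non-negative and integral, its rank equals
    the number of factors, and each axis length equals the factor's
    level count.
    """

    factors: list[FactorSpec]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names in table")
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        expected = tuple(f.n_levels for f in self.factors)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match factor levels {expected}"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def N(self) -> int:
        """Total count."""
        return int(self.counts.sum())

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def probabilities(self) -> np.ndarray:
        """Plug-in cell probabilities counts / N."""
        if self.N == 0:
            raise ValueError("empty table has no probabilities")
        return self.counts / self.N

    def axis(self, name: str) -> int:
        try:
            return self.factor_names.index(name)
        except ValueError:
            raise KeyError(f"unknown factor {name!r}") from None

    def factor(self, name: str) -> FactorSpec:
        return self.factors[self.axis(name)]

    def levels_product(self, names: Iterable[str]) -> int:
        """Nominal number of level combinations of a factor group."""
        out = 1
        for n in names:
            out *= self.factor(n).n_levels
        return out

    # -- core operations -------------------------------------------------

    def marginalize(self, keep: Sequence[str]) -> "ContingencyTable":
        """Sum the count tensor over every factor not in ``keep``.

        The kept factors appear in their original table order; N is
        preserved.
        """
        keep = list(keep)
        if not keep:
            raise ValueError("keep list must be non-empty")
        for name in keep:
            self.axis(name)  # raises on unknown factor
        if len(set(keep)) != len(keep):
            raise ValueError("duplicate factor names in keep list")
        keep_axes = sorted(self.axis(n) for n in keep)
        drop_axes = tuple(i for i in range(len(self.factors)) if i not in keep_axes)
        counts = self.counts.sum(axis=drop_axes) if drop_axes else self.counts.copy()
        return ContingencyTable([self.factors[i] for i in keep_axes], counts)

    def reorder(self, order: Sequence[str]) -> "ContingencyTable":
        """Permute axes to the given factor-name order (all factors)."""
        if sorted(order) != sorted(self.factor_names):
            raise ValueError("order must be a permutation of the table's factors")
        axes = [self.axis(n) for n in order]
        return ContingencyTable(
            [self.factors[i] for i in axes], np.transpose(self.counts, axes)
        )

    def compound(self, merge: Sequence[str], new_name: str) -> "ContingencyTable":
        """Replace ``merge`` factors by one factor over their Cartesian product.

        Levels of the compound factor enumerate the *full* Cartesian
        product of the original level sets — including combinations with
        zero count — so downstream degrees of freedom use nominal level
        counts.  Counts are preserved cell-by-cell.
        """
        merge = list(merge)
        if len(merge) < 2:
            raise ValueError("compound requires at least 2 factors")
        for name in merge:
            self.axis(name)
        remaining = [n for n in self.factor_names if n not in merge]
        if new_name in remaining:
            raise ValueError(f"new factor name {new_name!r} collides with an existing factor")
        # move merged axes to the back, in the order given by `merge`
        ordered = self.reorder(remaining + merge)
        k = len(remaining)
        shape = ordered.counts.shape
        new_counts = ordered.counts.reshape(shape[:k] + (-1,))
        merged_specs = [self.factor(n) for n in merge]
        levels = tuple(
            "|".join(combo)
            for combo in itertools.product(*(f.levels for f in merged_specs))
        )
        new_factor = FactorSpec(new_name, levels)
        return ContingencyTable(
            [self.factor(n) for n in remaining] + [new_factor], new_counts
        )

    def group_view(
        self, groups: Sequence[Sequence[str]]
    ) -> tuple[np.ndarray, tuple[int, ...]]:
        """Collapse the table onto ``groups`` and return a count array with
        one axis per group (axes in group order), plus nominal group sizes.

        Used by the information estimators: a factor *group* behaves as a
        single compound variable.
        """
        flat = [n for g in groups for n in g]
        if len(set(flat)) != len(flat):
            raise ValueError("factor groups overlap")
        sub = self.marginalize(flat).reorder(flat)
        sizes = tuple(self.levels_product(g) for g in groups)
        return sub.counts.reshape(sizes), sizes

    # -- conversion ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per cell (including zeros)."""
        idx = pd.MultiIndex.from_product(
            [f.levels for f in self.factors], names=self.factor_names
        )
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()


# -- construction ---------------------------------------------------------


def crosstab(
    records: pd.DataFrame,
    factor_names: Sequence[str],
    factor_specs: Sequence[FactorSpec] | None = None,
) -> ContingencyTable:
    """Tally case-level records into a contingency table.

    Parameters
    ----------
    records
        One row per subject, one column per factor; values are level labels.
    factor_names
        Columns to cross-tabulate, in the desired axis order.
    factor_specs
        Optional pre-declared factors (fixes level order and level set).
        Without them, level order is first-appearance order in the data.

    Missing values are an error, not a level: silently absorbing NAs
    would corrupt degrees of freedom downstream.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    factor_names = list(factor_names)
    spec_by_name = {s.name: s for s in (factor_specs or [])}
    specs: list[FactorSpec] = []
    codes = np.empty((len(records), len(factor_names)), dtype=np.int64)
    for j, name in enumerate(factor_names):
        if name not in records.columns:
            raise KeyError(f"unknown column {name!r}")
        col = records[name]
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {name!r} at row {row}")
        col = col.astype(str)
        if name in spec_by_name:
            spec = spec_by_name[name]
            unknown = set(col.unique()) - set(spec.levels)
            if unknown:
                raise ValueError(
                    f"column {name!r} contains undeclared levels {sorted(unknown)}"
                )
        else:
            spec = FactorSpec(name, tuple(pd.unique(col)))
        specs.append(spec)
        lookup = {lv: i for i, lv in enumerate(spec.levels)}
        codes[:, j] = col.map(lookup).to_numpy()
    shape = tuple(s.n_levels for s in specs)
    flat = np.ravel_multi_index(codes.T, shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return ContingencyTable(specs, counts)


def discretize(
    values: Sequence[float] | pd.Series,
    cutpoints: Sequence[float],
    labels: Sequence[str],
) -> pd.Series:
    """Bin a numeric column into right-closed intervals.

    Value ``v`` maps to bin ``b`` with ``cutpoints[b-1] < v <= cutpoints[b]``
    (implicit -inf / +inf at the ends).  ``len(labels)`` must equal
    ``len(cutpoints) + 1`` and cutpoints must be strictly increasing.
    """
    cutpoints = list(cutpoints)
    labels = list(labels)
    if len(labels) != len(cutpoints) + 1:
        raise ValueError("need exactly one more label than cutpoints")
    if any(b <= a for a, b in zip(cutpoints, cutpoints[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    arr = pd.to_numeric(pd.Series(values), errors="raise").to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("non-numeric or missing value in numeric column")
    idx = np.searchsorted(np.asarray(cutpoints, dtype=float), arr, side="left")
    out = pd.Series(np.asarray(labels, dtype=object)[idx])
    if isinstance(values, pd.Series):
        out.index = values.index
        out.name = values.name
    return out


# -- I/O -------------------------------------------------------------------

UCI_GERMAN_COLUMNS: tuple[str, ...] = tuple(f"A{i}" for i in range(1, 21)) + ("A21",)

#: Statlog attributes that are natively categorical (A-coded); the other
#: three (A2 duration, A5 amount, A13 age) are numeric and must be
#: discretized before tabulation.
GERMAN_CATEGORICAL: tuple[str, ...] = tuple(
    c for c in UCI_GERMAN_COLUMNS[:-1] if c not in ("A2", "A5", "A13")
)


def read_cases_csv(path, delimiter: str = ",") -> pd.DataFrame:
    """Read case-level records: header row of factor names, one row per subject."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty record set")
    return df


def read_uci_german(paths) -> pd.DataFrame:
    """Read the UCI Statlog German credit file(s).

    Whitespace-separated, 21 columns; attribute codes kept verbatim
    (e.g. ``A11``..``A14`` for attribute 1); column 21 is the binary
    creditability target with codes ``1`` (good) and ``2`` (bad).
    ``paths`` may be a single path or a sequence of file parts that are
    concatenated in order.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "read_text") and not isinstance(paths, (list, tuple)):
        paths = [paths]
    frames = [
        pd.read_csv(p, sep=r"\s+", header=None, names=UCI_GERMAN_COLUMNS, dtype=str)
        for p in paths
    ]
    df = pd.concat(frames, ignore_index=True)
    if df.shape[1] != 21:
        raise ValueError("UCI german.data must have 21 columns")
    return df


def write_table(table: ContingencyTable, path) -> None:
    """Serialize a table to the self-describing text format.

    Header lines name factors and levels; then one ``level-tuple count``
    line per non-zero cell.  Level labels containing whitespace are not
    supported by the format.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for f in table.factors:
            fh.write(f"factor {f.name} {' '.join(f.levels)}\n")
        fh.write("data\n")
        nz = np.argwhere(table.counts > 0)
        for cell in nz:
            labels = [table.factors[i].levels[j] for i, j in enumerate(cell)]
            fh.write(f"{' '.join(labels)} {table.counts[tuple(cell)]}\n")


def read_table(path) -> ContingencyTable:
    """Read a table written by :func:`write_table`."""
    factors: list[FactorSpec] = []
    cells: list[tuple[list[str], int]] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if not in_data:
                if line == "data":
                    in_data = True
                    continue
                parts = line.split()
                if parts[0] != "factor" or len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 'factor <name> <levels...>'")
                factors.append(FactorSpec(parts[1], tuple(parts[2:])))
            else:
                parts = line.split()
                if len(parts) != len(factors) + 1:
                    raise ValueError(f"{path}:{lineno}: wrong number of fields")
                cells.append((parts[:-1], int(parts[-1])))
    if not factors:
        raise ValueError(f"{path}: no factor declarations")
    counts = np.zeros(tuple(f.n_levels for f in factors), dtype=np.int64)
    index = [{lv: i for i, lv in enumerate(f.levels)} for f in factors]
    for labels, n in cells:
        try:
            pos = tuple(index[i][lv] for i, lv in enumerate(labels))
        except KeyError as e:
            raise ValueError(f"{path}: unknown level {e.args[0]!r}") from None
        counts[pos] += n
    return ContingencyTable(factors, counts)
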