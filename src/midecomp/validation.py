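"""End-to-end validation studies: identity checks, independent oracles,
test-size calibration, selection recovery, and the banking-credit
benchmark.

These routines drive the package on randomly generated tables and on
the bundled UCI Statlog German credit data; they are shared by the test
suite and by the reproduction script.  All randomness flows from an
explicit integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .infodecomp import chain_decompose, conditional_mi, mutual_information
from .loglin import LoglinModel, ipf_fit, pythagorean_split
from .logistic import fit_logistic
from .selection import SelectionConfig, backward_delete, forward_select
from .synth import FactorSpec, ScenarioSpec, sample_logistic_records, sample_table
from .tables import ContingencyTable, crosstab, read_uci_german

__all__ = [
    "random_table",
    "identity_suite",
    "split_oracle_suite",
    "calibration_study",
    "selection_recovery_study",
    "german_benchmark",
    "poisson_glm_homogeneous_deviance",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent per-replicate seeds below 2**31."""
    return np.random.default_rng(seed).integers(2**31, size=n)


def random_table(
    rng: np.random.Generator,
    n_factors: int | None = None,
    max_levels: int = 4,
    n_range: tuple[int, int] = (100, 5000),
) -> ContingencyTable:
    """A multinomial table with Dirichlet(1) cell probabilities and random
    shape (2-4 factors, 2-4 levels each by default)."""
    if n_factors is None:
        n_factors = int(rng.integers(2, 5))
    shape = tuple(int(rng.integers(2, max_levels + 1)) for _ in range(n_factors))
    probs = rng.dirichlet(np.ones(int(np.prod(shape)))).reshape(shape)
    N = int(rng.integers(n_range[0], n_range[1] + 1))
    counts = rng.multinomial(N, probs.ravel()).reshape(shape)
    factors = [
        FactorSpec(f"F{i+1}", tuple(f"l{j}" for j in range(s))) for i, s in enumerate(shape)
    ]
    return ContingencyTable(factors, counts)


@dataclass
class IdentityReport:
    n_tables: int
    max_chain_error: float
    max_split_error: float
    df_always_consistent: bool


def identity_suite(seed: int, n_tables: int = 500) -> IdentityReport:
    """Chain additivity, df accounting, and Int + Par = CMI on random tables."""
    rng = np.random.default_rng(seed)
    max_chain = 0.0
    max_split = 0.0
    df_ok = True
    for _ in range(n_tables):
        table = random_table(rng)
        names = table.factor_names
        target = names[-1]
        order = list(names[:-1])
        rng.shuffle(order)
        dec = chain_decompose(table, target, order)
        max_chain = max(max_chain, dec.additivity_error)
        df_ok = df_ok and dec.df_consistent
        if len(names) >= 3:
            split = pythagorean_split(table, (names[0],), (target,), tuple(names[1:-1]))
            max_split = max(max_split, split.additivity_error)
    return IdentityReport(n_tables, max_chain, max_split, df_ok)


def poisson_glm_homogeneous_deviance(counts: np.ndarray) -> float:
    """Independent oracle: deviance of the no-three-factor-interaction
    model on a three-way table, fitted as a Poisson log-linear GLM with
    an explicit main-effects + all-two-way dummy design."""
    I, J, K = counts.shape
    rows = list(itertools.product(range(I), range(J), range(K)))
    cols: list[np.ndarray] = [np.ones(len(rows))]
    idx = np.array(rows)

    def dummies(axis: int, n: int) -> list[np.ndarray]:
        return [(idx[:, axis] == lev).astype(float) for lev in range(1, n)]

    dx, dy, dz = dummies(0, I), dummies(1, J), dummies(2, K)
    cols += dx + dy + dz
    for a, b in ((dx, dy), (dx, dz), (dy, dz)):
        cols += [u * v for u in a for v in b]
    X = np.column_stack(cols)
    import warnings

    with warnings.catch_warnings():
        # tiny tables can fit some cells exactly; the deviance is still valid
        warnings.simplefilter("ignore")
        res = sm.GLM(counts.ravel().astype(float), X, family=sm.families.Poisson()).fit()
    return float(res.deviance)


@dataclass
class OracleReport:
    n_tables: int
    max_interaction_discrepancy: float
    max_cmi_vs_ipf_discrepancy: float


def split_oracle_suite(seed: int, n_tables: int = 200) -> OracleReport:
    """On small all-positive 2x2x2 tables, compare the split's interaction
    statistic with the Poisson-GLM oracle and the CMI with the IPF
    deviance of the conditional-independence model {XZ, YZ}."""
    rng = np.random.default_rng(seed)
    factors = [FactorSpec(n, ("0", "1")) for n in ("X", "Y", "Z")]
    max_int = 0.0
    max_cmi = 0.0
    ci_model = LoglinModel((frozenset({"X", "Z"}), frozenset({"Y", "Z"})))
    for _ in range(n_tables):
        counts = rng.integers(1, 6, size=(2, 2, 2))
        table = ContingencyTable(factors, counts)
        split = pythagorean_split(table, ("X",), ("Y",), ("Z",), tol=1e-12, max_iter=5000)
        oracle = poisson_glm_homogeneous_deviance(counts)
        max_int = max(max_int, abs(split.interaction.stat - oracle))
        ci_fit = ipf_fit(table, ci_model, tol=1e-12, max_iter=5000)
        max_cmi = max(max_cmi, abs(split.cmi.stat - ci_fit.deviance))
    return OracleReport(n_tables, max_int, max_cmi)


@dataclass
class CalibrationReport:
    n_replicates: int
    N: int
    alpha: float
    mi_rejection_rate: float
    int_rejection_rate: float
    par_rejection_rate: float


def calibration_study(
    seed: int, n_replicates: int = 2000, N: int = 2000, alpha: float = 0.05
) -> CalibrationReport:
    """Empirical size of the MI, interaction, and partial-association tests.

    MI is tested on 2x2 tables sampled under exact independence; Int and
    Par on 2x2x2 tables sampled under exact conditional independence
    (both X and Y depend on Z, but not on each other within strata).
    Margins keep every expected cell count well above 5 at the default N.
    """
    seeds = _child_seeds(seed, 2 * n_replicates)
    # independence null for the MI test
    px = np.array([0.4, 0.6])
    py = np.array([0.3, 0.7])
    f2 = np.outer(px, py)
    factors2 = [FactorSpec("X", ("0", "1")), FactorSpec("Y", ("0", "1"))]
    mi_rej = 0
    for i in range(n_replicates):
        rng = np.random.default_rng(int(seeds[i]))
        counts = rng.multinomial(N, f2.ravel()).reshape(2, 2)
        term = mutual_information(ContingencyTable(factors2, counts), "X", "Y")
        mi_rej += term.p <= alpha
    # conditional-independence null for the Int and Par tests
    pz = np.array([0.5, 0.5])
    px_z = np.array([[0.3, 0.7], [0.6, 0.4]])  # stratum -> P(X)
    py_z = np.array([[0.4, 0.6], [0.7, 0.3]])
    f3 = np.einsum("k,ki,kj->ijk", pz, px_z, py_z)
    factors3 = [FactorSpec(n, ("0", "1")) for n in ("X", "Y", "Z")]
    int_rej = 0
    par_rej = 0
    for i in range(n_replicates):
        rng = np.random.default_rng(int(seeds[n_replicates + i]))
        counts = rng.multinomial(N, f3.ravel()).reshape(2, 2, 2)
        split = pythagorean_split(
            ContingencyTable(factors3, counts), ("X",), ("Y",), ("Z",)
        )
        int_rej += split.interaction.p <= alpha
        par_rej += split.partial.p <= alpha
    return CalibrationReport(
        n_replicates=n_replicates,
        N=N,
        alpha=alpha,
        mi_rejection_rate=mi_rej / n_replicates,
        int_rejection_rate=int_rej / n_replicates,
        par_rejection_rate=par_rej / n_replicates,
    )


#: Default recovery scenario: three active binary predictors at |beta| = 1.5
#: plus one inert one.  With forward entry gated at alpha = 0.05, each inert
#: candidate enters by chance with probability close to alpha, so exact
#: recovery cannot exceed roughly (1 - alpha)^k for k inert candidates; one
#: inert candidate keeps the exact-recovery ceiling near 95%.
RECOVERY_ACTIVE = ("X1", "X2", "X3")
RECOVERY_INERT = ("X4",)


def _recovery_scenario(seed: int, N: int, beta: float) -> ScenarioSpec:
    names = list(RECOVERY_ACTIVE + RECOVERY_INERT)
    factors = [FactorSpec(n, ("0", "1")) for n in names] + [FactorSpec("T", ("0", "1"))]
    signs = {"X1": 1.0, "X2": -1.0, "X3": 1.0}
    coeffs: dict = {"intercept": -0.5}
    for n in RECOVERY_ACTIVE:
        coeffs[n] = [0.0, signs[n] * beta]
    return ScenarioSpec(
        factors=factors,
        mechanism="logistic",
        parameters={
            "target": "T",
            "coefficients": coeffs,
            "predictor_probs": {n: [0.5, 0.5] for n in names},
        },
        N=N,
        seed=seed,
    )


@dataclass
class RecoveryReport:
    n_replicates: int
    N: int
    beta: float
    exact_recovery_rate: float
    active_found_rate: float


def selection_recovery_study(
    seed: int, n_replicates: int = 200, N: int = 2000, beta: float = 1.5
) -> RecoveryReport:
    """Forward + backward selection on logistic-mechanism data with a known
    active set; reports how often the retained set equals it exactly."""
    seeds = _child_seeds(seed, n_replicates)
    config = SelectionConfig(alpha=0.05)
    names = list(RECOVERY_ACTIVE + RECOVERY_INERT)
    exact = 0
    found = 0
    for i in range(n_replicates):
        spec = _recovery_scenario(int(seeds[i]), N, beta)
        records = sample_logistic_records(spec)
        table = crosstab(records, names + ["T"])
        selected, _ = forward_select(table, "T", names, config)
        retained, _ = backward_delete(table, "T", selected, config)
        exact += sorted(retained) == sorted(RECOVERY_ACTIVE)
        found += set(RECOVERY_ACTIVE) <= set(retained)
    return RecoveryReport(
        n_replicates=n_replicates,
        N=N,
        beta=beta,
        exact_recovery_rate=exact / n_replicates,
        active_found_rate=found / n_replicates,
    )


def german_benchmark(paths) -> dict[str, float]:
    """Recompute the banking-credit benchmark quantities from the raw data.

    Returns the MI chain decomposition of the target against {A1, A3,
    A12} (CMI / interaction / partial statistics and dfs) and the
    grouped deviances of the two selected logistic models.
    """
    records = read_uci_german(paths)
    table = crosstab(records, ["A1", "A3", "A12", "A14", "A21"])
    out: dict[str, float] = {"n_records": float(len(records))}
    mi = mutual_information(table, "A1", "A21")
    out["mi_a1_target"] = mi.stat
    out["mi_a1_target_df"] = float(mi.df)
    s3 = pythagorean_split(table, ("A3",), ("A21",), ("A1",))
    out["cmi_a3_target_given_a1"] = s3.cmi.stat
    out["cmi_a3_df"] = float(s3.cmi.df)
    out["int_a3"] = s3.interaction.stat
    out["int_a3_df"] = float(s3.interaction.df)
    out["par_a3"] = s3.partial.stat
    out["par_a3_df"] = float(s3.partial.df)
    s12 = pythagorean_split(table, ("A12",), ("A21",), ("A1", "A3"))
    out["cmi_a12_target_given_a1_a3"] = s12.cmi.stat
    out["cmi_a12_df"] = float(s12.cmi.df)
    out["int_a12"] = s12.interaction.stat
    out["int_a12_df"] = float(s12.interaction.df)
    out["par_a12"] = s12.partial.stat
    out["par_a12_df"] = float(s12.partial.df)
    fit1 = fit_logistic(records, "A21 ~ A1 + A3 + A12")
    out["model1_deviance"] = fit1.deviance
    out["model1_df"] = float(fit1.df)
    out["model1_loglik"] = fit1.loglik
    out["model1_aic"] = fit1.aic
    fit2 = fit_logistic(records, "A21 ~ A1 + A3*A14")
    out["model2_deviance"] = fit2.deviance
    out["model2_df"] = float(fit2.df)
    out["model2_loglik"] = fit2.loglik
    out["model2_aic"] = fit2.aic
    return out
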