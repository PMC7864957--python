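"""Permutation inference for general linear models on per-embryo proportions.

Two designs are supported, matching the genetic-interaction study they were
built for:

* the two-group model ``Y_j = b0 + b1*I_j + e_j``, where ``I_j`` indicates
  one of two genotypes and ``H0: b1 = 0`` is tested by shuffling the
  genotype labels across embryos;
* the no-intercept interaction (synergy) model
  ``Y_j = b1*I_n,j + b2*I_M,j + b3*I_n,j*I_M,j + e_j``, where ``I_n`` and
  ``I_M`` indicate heterozygosity for each of two mutations and
  ``H0: b3 = 0`` (no super-additive effect in the double heterozygote) is
  tested with the Smith orthogonalization procedure: the interaction column
  is residualised against the two main-effect columns, its rows are
  permuted, and the coefficient on the permuted column in the re-fitted
  model forms the reference distribution.

Permutation p-values use the Monte-Carlo estimator ``p = (n + 1) / (N + 1)``
with ``n`` the number of permuted coefficients at least as large as the
observed one — a one-sided, upper-tail test, valid by construction.  Exact
enumeration counterparts (feasible for small samples) serve as independent
oracles for the Monte-Carlo engines.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Default permutation count for production runs.
DEFAULT_PERMUTATIONS = 1_000_000

#: Permutations are processed in blocks of this many rows to bound memory.
_BLOCK = 100_000


class RankDeficiencyError(np.linalg.LinAlgError):
    """The design (or nuisance block) does not have full column rank."""


@dataclass(frozen=True)
class ModelFit:
    """Ordinary least-squares fit of a linear model."""

    coefficients: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    column_names: tuple[str, ...]

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.column_names.index(name)])


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation (or exact enumeration) test.

    For Monte-Carlo methods ``p_value = (exceed_count + 1) /
    (n_permutations + 1)``; for exact enumeration it is the exact exceedance
    fraction ``exceed_count / n_permutations`` over all distinct assignments
    (the observed assignment is one of them, so ``p_value >= 1/n``).
    """

    observed_stat: float
    exceed_count: int
    n_permutations: int
    p_value: float
    seed: int | None
    method: str


def _as_matrix(X, names: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    else:
        names = tuple(names)
        if len(names) != X.shape[1]:
            raise ValueError("column_names length does not match design width")
    return X, names


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    # QR diagonal pinpoints which columns are (nearly) linearly dependent.
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    bad = [names[i] for i, d in enumerate(diag) if d <= scale * 1e-10]
    if scale == 0.0 or bad:
        raise RankDeficiencyError(
            f"design is rank deficient; collinear columns: {bad or list(names)}"
        )


def ols_fit(X, y, column_names: Sequence[str] | None = None) -> ModelFit:
    """Least-squares fit of ``y`` on the columns of ``X``.

    Raises :class:`RankDeficiencyError` (naming the collinear columns) if the
    design is rank deficient, and :class:`ValueError` on shape mismatch.
    """
    X, names = _as_matrix(X, column_names)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise ValueError(
            f"response length {y.shape} does not match design rows {X.shape[0]}"
        )
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer rows than columns")
    _check_rank(X, names)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return ModelFit(coef, y - fitted, fitted, names)


def _validate_indicator(g, name: str = "indicator") -> np.ndarray:
    g = np.asarray(g)
    if not np.isin(g, (0, 1)).all():
        raise ValueError(f"{name} entries must be 0 or 1")
    return g.astype(float)


def _tie_tolerance(observed: float) -> float:
    # Coefficients reached via different linear-algebra paths (full OLS,
    # FWL shortcut, enumeration) agree only to rounding; without a guard,
    # exact ties would be counted inconsistently between engines.
    return 1e-12 * max(1.0, abs(observed))


def _count_exceed(stats: np.ndarray, observed: float, tie: str) -> int:
    tol = _tie_tolerance(observed)
    if tie == "ge":
        return int(np.count_nonzero(stats >= observed - tol))
    if tie == "gt":
        return int(np.count_nonzero(stats > observed + tol))
    raise ValueError(f"tie must be 'ge' or 'gt', got {tie!r}")


def two_group_test(
    y,
    group,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    tie: str = "ge",
) -> PermutationResult:
    """Label-permutation test of ``H0: b1 = 0`` in ``Y = b0 + b1*I + e``.

    The observed statistic is the OLS slope (the difference of group means).
    Each permutation uniformly re-assigns the group labels, preserving group
    sizes; ``p = (n + 1)/(N + 1)`` counts permuted slopes at least as large
    as the observed one (``tie='gt'`` counts strictly larger ones instead).
    """
    y = np.asarray(y, dtype=float)
    g = _validate_indicator(group, "group")
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and group must be equal-length 1-D arrays")
    n1 = int(g.sum())
    n0 = g.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    # b1 = mean(y | I=1) - mean(y | I=0): contrast weights make each
    # permuted refit a single dot product.
    w = g / n1 - (1.0 - g) / n0
    observed = float(w @ y)

    rng = np.random.default_rng(seed)
    exceed = 0
    remaining = n_permutations
    while remaining > 0:
        block = min(remaining, _BLOCK)
        perm_y = rng.permuted(np.broadcast_to(y, (block, y.size)), axis=1)
        exceed += _count_exceed(perm_y @ w, observed, tie)
        remaining -= block
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(observed, exceed, n_permutations, p, seed, "two_group")


def smith_orthogonalize(nuisance, z, column_names: Sequence[str] | None = None):
    """Residualise ``z`` against the span of the nuisance columns.

    Returns ``z* = z - P z`` where ``P`` projects onto the nuisance span;
    ``z*`` is orthogonal to every nuisance column.  Raises
    :class:`RankDeficiencyError` if the nuisance block is rank deficient.
    """
    N, names = _as_matrix(nuisance, column_names)
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.shape[0] != N.shape[0]:
        raise ValueError("z must be 1-D with one entry per nuisance row")
    _check_rank(N, names)
    coef, *_ = np.linalg.lstsq(N, z, rcond=None)
    return z - N @ coef


def _interaction_design(i_n: np.ndarray, i_m: np.ndarray) -> np.ndarray:
    return np.column_stack([i_n, i_m, i_n * i_m])


def _check_interaction_groups(i_n: np.ndarray, i_m: np.ndarray) -> None:
    for a, b, label in ((1, 0, "(1,0)"), (0, 1, "(0,1)"), (1, 1, "(1,1)")):
        if not np.any((i_n == a) & (i_m == b)):
            raise ValueError(f"genotype group {label} is empty")


def interaction_test(
    y,
    i_n,
    i_m,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    tie: str = "ge",
    include_baseline: bool = False,
) -> PermutationResult:
    """Smith-orthogonalization permutation test of the synergy coefficient.

    The observed statistic is ``b3`` from the no-intercept model
    ``Y = b1*I_n + b2*I_M + b3*I_n*I_M + e``.  The interaction column is
    orthogonalised against ``(I_n, I_M)``; each permutation shuffles the
    rows of the orthogonalised column ``z*``, re-fits ``y`` on
    ``(I_n, I_M, shuffled z*)`` and records the coefficient on the shuffled
    column.  ``p = (n + 1)/(N + 1)`` as in :func:`two_group_test`.

    With ``include_baseline=True`` the model gains an intercept
    (``Y = b0 + b1*I_n + b2*I_M + b3*I_n*I_M + e``) and wild-type
    ``(I_n, I_M) = (0, 0)`` embryos participate in the fit.  This four-group
    variant departs from the published three-genotype contrast (whose
    no-intercept form is forced: with only three groups the interaction
    column is collinear with an intercept plus the two main effects) and is
    only identifiable when baseline embryos are present.
    """
    y = np.asarray(y, dtype=float)
    i_n = _validate_indicator(i_n, "i_n")
    i_m = _validate_indicator(i_m, "i_m")
    if not (y.shape == i_n.shape == i_m.shape) or y.ndim != 1:
        raise ValueError("y, i_n, i_m must be equal-length 1-D arrays")
    _check_interaction_groups(i_n, i_m)
    if include_baseline and not np.any((i_n == 0) & (i_m == 0)):
        raise ValueError("include_baseline=True needs (0,0) embryos")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    X = _interaction_design(i_n, i_m)
    names: tuple[str, ...] = ("i_n", "i_m", "i_n:i_m")
    if include_baseline:
        X = np.column_stack([np.ones(y.size), X])
        names = ("intercept",) + names
    observed = ols_fit(X, y, names).coefficient("i_n:i_m")

    nuisance = X[:, :-1]
    z_star = smith_orthogonalize(nuisance, X[:, -1], names[:-1])
    if not np.any(np.abs(z_star) > 1e-12):
        raise ValueError(
            "interaction column lies in the span of the main effects; "
            "the Smith statistic is degenerate"
        )

    # Coefficient on the shuffled column in the joint re-fit, via
    # Frisch-Waugh: re-residualise the shuffled z* against the nuisance,
    # then b = <z~, y> / <z~, z~>.
    G = np.linalg.solve(nuisance.T @ nuisance, nuisance.T)  # (2, n)
    rng = np.random.default_rng(seed)
    exceed = 0
    remaining = n_permutations
    while remaining > 0:
        block = min(remaining, _BLOCK)
        Zp = rng.permuted(np.broadcast_to(z_star, (block, z_star.size)), axis=1)
        exceed += _count_exceed(_smith_stats(Zp, G, nuisance, y), observed, tie)
        remaining -= block
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(
        observed, exceed, n_permutations, p, seed, "interaction_smith"
    )


def _smith_stats(
    Zp: np.ndarray, G: np.ndarray, nuisance: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Coefficient on each permuted z* in the joint re-fit with the nuisance.

    A shuffled column that falls exactly in the nuisance span has an
    undefined coefficient; such permutations are scored as ties with any
    observed value (+inf), keeping the p-value conservative.
    """
    Zt = Zp - (Zp @ G.T) @ nuisance.T
    denom = np.einsum("ij,ij->i", Zt, Zt)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = (Zt @ y) / denom
    return np.where(denom > 0.0, stats, np.inf)


def exact_two_group_test(
    y, group, max_assignments: int = 1_000_000, tie: str = "ge"
) -> PermutationResult:
    """Exact enumeration oracle for :func:`two_group_test`.

    Enumerates every distinct assignment of the group labels with group
    sizes preserved; the p-value is the exact fraction of assignments whose
    slope is at least the observed one (the observed assignment included).
    """
    y = np.asarray(y, dtype=float)
    g = _validate_indicator(group, "group")
    n1 = int(g.sum())
    n0 = g.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty")
    total = math.comb(g.size, n1)
    if total > max_assignments:
        raise ValueError(
            f"{total} assignments exceed the enumeration budget "
            f"({max_assignments}); use the Monte-Carlo two_group_test"
        )
    observed = float(y[g == 1].mean() - y[g == 0].mean())
    sum_all = y.sum()
    stats = np.empty(total)
    for k, idx in enumerate(itertools.combinations(range(g.size), n1)):
        s1 = y[list(idx)].sum()
        stats[k] = s1 / n1 - (sum_all - s1) / n0
    exceed = _count_exceed(stats, observed, tie)
    return PermutationResult(
        observed, exceed, total, exceed / total, None, "exact_enumeration"
    )


def exact_interaction_test(
    y, i_n, i_m, max_embryos: int = 8, tie: str = "ge"
) -> PermutationResult:
    """Exact enumeration oracle for :func:`interaction_test`.

    Enumerates all row orderings of the orthogonalised interaction column
    and returns the exact exceedance fraction of the re-fitted coefficient.
    Factorial cost limits this to small samples.
    """
    y = np.asarray(y, dtype=float)
    i_n = _validate_indicator(i_n, "i_n")
    i_m = _validate_indicator(i_m, "i_m")
    _check_interaction_groups(i_n, i_m)
    n = y.size
    if n > max_embryos:
        raise ValueError(
            f"{n} embryos exceed the enumeration limit ({max_embryos}); "
            "use the Monte-Carlo interaction_test"
        )
    X = _interaction_design(i_n, i_m)
    observed = ols_fit(X, y, ("i_n", "i_m", "i_n:i_m")).coefficient("i_n:i_m")
    nuisance = X[:, :2]
    z_star = smith_orthogonalize(nuisance, X[:, 2])
    if not np.any(np.abs(z_star) > 1e-12):
        raise ValueError(
            "interaction column lies in the span of the main effects; "
            "the Smith statistic is degenerate"
        )
    perms = np.array(list(itertools.permutations(range(n))))
    Zp = z_star[perms]
    G = np.linalg.solve(nuisance.T @ nuisance, nuisance.T)
    exceed = _count_exceed(_smith_stats(Zp, G, nuisance, y), observed, tie)
    return PermutationResult(
        observed, exceed, len(perms), exceed / len(perms), None, "exact_enumeration"
    )
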