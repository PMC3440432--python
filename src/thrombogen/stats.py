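"""Pedigree-aware group comparison of thrombogram parameters.

Recursive kinship from a pedigree, maximum-likelihood fit of the polygenic
mixed model ``y ~ N(Xb, 2*Phi*sigma2_g + I*sigma2_e)``, and likelihood-ratio
tests for a group effect adjusted for age and sex.  The fit profiles out the
fixed effects and total variance, leaving a one-dimensional optimization over
the heritability, via a single eigendecomposition of the relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, ttest_ind

from .synthetic import SyntheticPedigree

__all__ = [
    "KinshipMatrix",
    "PolygenicFit",
    "LRTResult",
    "kinship_matrix",
    "fit_polygenic",
    "lrt_group_effect",
    "naive_group_test",
    "gene_drop_kinship",
]


@dataclass(frozen=True)
class KinshipMatrix:
    ids: tuple[str, ...]
    phi: np.ndarray  # kinship coefficients, symmetric

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match ids")

    @property
    def relationship(self) -> np.ndarray:
        """Additive relationship matrix 2*Phi."""
        return 2.0 * self.phi

    def subset(self, ids) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return KinshipMatrix(tuple(ids), self.phi[np.ix_(idx, idx)])


def _pedigree_records(pedigree) -> list[tuple[str, str | None, str | None]]:
    if isinstance(pedigree, SyntheticPedigree):
        return [(m.id, m.father, m.mother) for m in pedigree.members]
    if isinstance(pedigree, pd.DataFrame):
        recs = []
        for row in pedigree.itertuples(index=False):
            def clean(v):
                s = "" if v is None else str(v)
                return None if s in ("", "nan", "None") else s
            recs.append((str(row.id), clean(row.father), clean(row.mother)))
        return recs
    raise TypeError("pedigree must be a SyntheticPedigree or a DataFrame with id/father/mother")


def _toposort(records):
    by_id = {r[0]: r for r in records}
    for rid, father, mother in records:
        for p in (father, mother):
            if p is not None and p not in by_id:
                raise ValueError(f"member {rid!r}: unknown parent id {p!r}")
    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(rid: str, stack: list[str]) -> None:
        if state.get(rid) == 1:
            return
        if state.get(rid) == 0:
            raise ValueError(f"pedigree cycle detected at {rid!r}")
        state[rid] = 0
        _, father, mother = by_id[rid]
        for p in (father, mother):
            if p is not None:
                visit(p, stack + [rid])
        state[rid] = 1
        order.append(rid)

    for rid, _, _ in records:
        visit(rid, [])
    return [by_id[rid] for rid in order]


def kinship_matrix(pedigree) -> KinshipMatrix:
    """Recursive kinship coefficients.

    Founders: Phi_ii = 0.5, unrelated.  Non-founder j with parents f, m:
    Phi_jj = 0.5*(1 + Phi_fm) and Phi_ij = 0.5*(Phi_if + Phi_im) for any i
    earlier in the (topologically sorted) order.
    """
    records = _toposort(_pedigree_records(pedigree))
    input_ids = [r[0] for r in _pedigree_records(pedigree)]
    ids = [r[0] for r in records]
    pos = {rid: i for i, rid in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    for j, (rid, father, mother) in enumerate(records):
        if father is None and mother is None:
            phi[j, j] = 0.5
        else:
            fi, mi = pos[father], pos[mother]
            phi[j, j] = 0.5 * (1.0 + phi[fi, mi])
            for i in range(j):
                phi[i, j] = phi[j, i] = 0.5 * (phi[i, fi] + phi[i, mi])
    return KinshipMatrix(tuple(ids), phi).subset(input_ids)


def gene_drop_kinship(pedigree, n_drops: int = 100_000, seed: int = 0) -> KinshipMatrix:
    """Monte-Carlo kinship: drop alleles through the pedigree and measure the
    probability that one allele sampled from each of two individuals is IBD."""
    records = _toposort(_pedigree_records(pedigree))
    input_ids = [r[0] for r in _pedigree_records(pedigree)]
    ids = [r[0] for r in records]
    pos = {rid: i for i, rid in enumerate(ids)}
    n = len(ids)
    rng = np.random.default_rng(seed)
    # allele labels per drop: (n_drops, n, 2)
    alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
    label = 0
    for j, (rid, father, mother) in enumerate(records):
        if father is None and mother is None:
            alleles[:, j, 0] = 2 * label
            alleles[:, j, 1] = 2 * label + 1
            label += 1
        else:
            for slot, parent in ((0, father), (1, mother)):
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, j, slot] = alleles[np.arange(n_drops), pos[parent], pick]
    # kinship estimate: average over the 4 allele pairings
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            eq = (
                (alleles[:, i, 0] == alleles[:, j, 0]).mean()
                + (alleles[:, i, 0] == alleles[:, j, 1]).mean()
                + (alleles[:, i, 1] == alleles[:, j, 0]).mean()
                + (alleles[:, i, 1] == alleles[:, j, 1]).mean()
            ) / 4.0
            phi[i, j] = phi[j, i] = eq
    return KinshipMatrix(tuple(ids), phi).subset(input_ids)


@dataclass(frozen=True)
class PolygenicFit:
    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool
    aliased: bool  # relationship matrix ~ c*I: only sigma2_g + sigma2_e identifiable


class _EigenLikelihood:
    """Profile ML log-likelihood over h2 after rotating into the eigenbasis
    of the relationship matrix A = 2*Phi."""

    def __init__(self, A: np.ndarray):
        self.d, self.U = np.linalg.eigh(A)
        self.d = np.clip(self.d, 0.0, None)
        self.aliased = (self.d.max() - self.d.min()) < 1e-9 * max(1.0, self.d.max())

    def profile(self, h2: float, ys: np.ndarray, Xs: np.ndarray):
        n = ys.shape[0]
        w = h2 * self.d + (1.0 - h2)
        if w.min() <= 0:
            return -np.inf, None, np.nan
        wi = 1.0 / w
        Xw = Xs * wi[:, None]
        XtWX = Xs.T @ Xw
        # pinv tolerates rank-deficient designs (e.g. a constant covariate)
        beta = np.linalg.pinv(XtWX) @ (Xw.T @ ys)
        r = ys - Xs @ beta
        s2 = float(r @ (wi * r)) / n
        if s2 <= 0:
            return -np.inf, beta, 0.0
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + np.log(w).sum() + n)
        return ll, beta, s2


def fit_polygenic(
    y: np.ndarray,
    X: np.ndarray,
    kinship: KinshipMatrix | np.ndarray,
    *,
    beta_names: tuple[str, ...] | None = None,
) -> PolygenicFit:
    """ML fit of ``y ~ N(Xb, 2*Phi*sigma2_g + I*sigma2_e)``.

    Deterministic: a coarse grid over h2 followed by bounded refinement of the
    best bracket.  When the relationship matrix is (numerically) a multiple of
    the identity the variance split is unidentifiable; the fit is returned at
    the OLS boundary with ``aliased=True``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have matching rows")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"only {n} observations for {p} fixed effects: model unidentifiable")
    phi = kinship.phi if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
    if phi.shape != (n, n):
        raise ValueError("kinship does not align with the data")
    lik = _EigenLikelihood(2.0 * phi)
    ys = lik.U.T @ y
    Xs = lik.U.T @ X

    if lik.aliased:
        ll, beta, s2 = lik.profile(0.0, ys, Xs)
        return PolygenicFit(
            beta, beta_names or tuple(f"b{i}" for i in range(p)),
            0.0, s2, 0.0, ll, True, True,
        )

    grid = np.linspace(0.0, 1.0 - 1e-9, 26)
    lls = np.array([lik.profile(h, ys, Xs)[0] for h in grid])
    i_best = int(np.nanargmax(lls))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda h: -lik.profile(h, ys, Xs)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    h2 = float(res.x)
    ll, beta, s2 = lik.profile(h2, ys, Xs)
    if lls[i_best] > ll:  # grid endpoint beat the refinement
        h2, ll = float(grid[i_best]), float(lls[i_best])
        _, beta, s2 = lik.profile(h2, ys, Xs)
    return PolygenicFit(
        beta, beta_names or tuple(f"b{i}" for i in range(p)),
        h2 * s2, (1.0 - h2) * s2, h2, float(ll), bool(res.success), False,
    )


@dataclass(frozen=True)
class LRTResult:
    lr: float
    df: int
    p_value: float
    group_effect: float
    full: PolygenicFit
    null: PolygenicFit


def _design(age, sex, group=None):
    age = np.asarray(age, dtype=float)
    sex_num = np.asarray([1.0 if s in ("M", 1, True, "male") else 0.0 for s in sex])
    cols = [np.ones(len(age)), age, sex_num]
    names = ["intercept", "age", "sex_male"]
    if group is not None:
        g = np.asarray(group)
        if g.dtype.kind in "OUS":
            levels = sorted(pd.unique(g))
            if len(levels) > 2:
                raise ValueError("group must be binary")
            g = (g == levels[-1]).astype(float)
        cols.append(np.asarray(g, dtype=float))
        names.append("group")
    return np.column_stack(cols), tuple(names)


def lrt_group_effect(y, age, sex, group, kinship: KinshipMatrix | np.ndarray) -> LRTResult:
    """Likelihood-ratio test of the group label, adjusted for age, sex and the
    polygenic component.  LR = 2*(ll_full - ll_null), chi-square with 1 df."""
    X_full, names_full = _design(age, sex, group)
    if np.ptp(X_full[:, -1]) == 0:
        # constant group: full == null by construction
        X_null, names_null = _design(age, sex)
        null = fit_polygenic(y, X_null, kinship, beta_names=names_null)
        full = PolygenicFit(
            np.append(null.beta, 0.0), names_full, null.sigma2_g, null.sigma2_e,
            null.h2, null.loglik, null.converged, null.aliased,
        )
        return LRTResult(0.0, 1, 1.0, 0.0, full, null)
    X_null, names_null = _design(age, sex)
    full = fit_polygenic(y, X_full, kinship, beta_names=names_full)
    null = fit_polygenic(y, X_null, kinship, beta_names=names_null)
    lr = max(2.0 * (full.loglik - null.loglik), 0.0)
    return LRTResult(
        lr, 1, float(chi2.sf(lr, 1)), float(full.beta[-1]), full, null
    )


def naive_group_test(y, group) -> tuple[float, float]:
    """Welch two-sample comparison ignoring relatedness (sensitivity check).

    Returns (difference of means, p-value)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(group)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    a, b = y[g == levels[0]], y[g == levels[1]]
    stat = ttest_ind(b, a, equal_var=False)
    return float(b.mean() - a.mean()), float(stat.pvalue)
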