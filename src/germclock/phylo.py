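"""Phylogenetic generalized least squares with Pagel's lambda.

Cross-species trait regressions violate the independence assumption of OLS
because closely related species inherit correlated trait values.  Under a
Brownian-motion model of trait evolution on a rooted tree, the residual
covariance of tips i and j is proportional to the shared root-to-MRCA path
length.  Pagel's lambda scales the off-diagonal covariances toward zero,
interpolating between a pure Brownian model (lambda = 1) and phylogenetic
independence (lambda = 0); it is estimated here by profile maximum likelihood.

Trees are dendropy objects; regressions are simple (one predictor plus
intercept), matching the comparative analyses this package performs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "TraitTable",
    "RegressionFit",
    "loglog_ols",
    "brownian_vcv",
    "lambda_transform",
    "GLSModel",
    "gls_fit",
    "PGLSModel",
    "pgls_fit",
]


@dataclass(frozen=True)
class RegressionFit:
    """Slope/intercept fit with uncertainty; ``lam`` present for PGLS fits."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    loglik: float
    lam: float | None = None

    def summary(self) -> str:
        lines = [
            f"slope     = {self.slope:.6g}  (SE {self.slope_se:.3g})",
            f"intercept = {self.intercept:.6g}  (SE {self.intercept_se:.3g})",
            f"R^2 = {self.r_squared:.4f}   logL = {self.loglik:.3f}",
        ]
        if self.lam is not None:
            lines.append(f"Pagel's lambda = {self.lam:.4f}")
        return "\n".join(lines)


class TraitTable:
    """Per-species (predictor, response) records for comparative regression."""

    def __init__(self, species: Sequence[str], x: Sequence[float], y: Sequence[float]):
        self.species = [s.strip() for s in species]
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("trait values must be finite")
        if not (len(self.species) == len(self.x) == len(self.y)):
            raise ValueError("species/x/y lengths differ")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str, y: str, species: str = "species"):
        return cls(df[species].astype(str).tolist(), df[x].to_numpy(), df[y].to_numpy())

    def __len__(self) -> int:
        return len(self.species)

    def log_transformed(self) -> "TraitTable":
        bad = [s for s, xv, yv in zip(self.species, self.x, self.y) if xv <= 0 or yv <= 0]
        if bad:
            raise ValueError(f"non-positive trait values for species: {', '.join(bad)}")
        return TraitTable(self.species, np.log(self.x), np.log(self.y))


def _design(table: TraitTable) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([np.ones(len(table)), table.x])
    return X, table.y.copy()


def _gaussian_loglik(resid: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Profile ML: sigma^2 hat = r' V^-1 r / n.  Returns (loglik, sigma2_hat)."""
    n = len(resid)
    L = np.linalg.cholesky(V)
    w = np.linalg.solve(L, resid)
    quad = float(w @ w)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2 = quad / n
    ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + logdet + n)
    return ll, sigma2


def loglog_ols(table: TraitTable) -> RegressionFit:
    """OLS of log(response) on log(predictor).

    Species with non-positive values raise an error naming the offenders.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 records")
    logged = table.log_transformed()
    return gls_fit(logged, np.eye(len(logged)))


def brownian_vcv(tree: dendropy.Tree, tips: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix of tip trait values.

    Entry (i, j) is the path length from the root to the MRCA of tips i and j;
    the diagonal is the root-to-tip distance.
    """
    tips = [t.strip() for t in tips]
    label_to_idx = {lab: i for i, lab in enumerate(tips)}
    if len(label_to_idx) != len(tips):
        raise ValueError("duplicate tip labels requested")
    tree_labels = {leaf.taxon.label.strip() for leaf in tree.leaf_node_iter()}
    missing = set(tips) - tree_labels
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")

    n = len(tips)
    V = np.zeros((n, n))
    # postorder: each node knows its depth from the root and the set of
    # requested tip indices below it; pairs first joined at a node share
    # exactly that node's depth.
    depths: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        if edge < 0:
            raise ValueError("negative branch length")
        depths[id(node)] = (depths[id(parent)] if parent is not None else 0.0) + (
            edge if parent is not None else 0.0
        )
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label.strip()
            idx = label_to_idx.get(lab)
            mine = [idx] if idx is not None else []
            if idx is not None:
                V[idx, idx] = depths[id(node)]
        else:
            children = [below[id(c)] for c in node.child_nodes()]
            d = depths[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            mine = [i for ch in children for i in ch]
        below[id(node)] = mine
    return V


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by Pagel's lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    out = lam * np.asarray(V, dtype=float)
    np.fill_diagonal(out, np.diag(V))
    return out


class GLSModel:
    """Generalized least squares of response on predictor with covariance V."""

    def __init__(self, table: TraitTable, V: np.ndarray) -> None:
        self.table = table
        self.V = np.asarray(V, dtype=float)
        if self.V.shape != (len(table), len(table)):
            raise ValueError("V shape does not match table")

    def fit(self) -> RegressionFit:
        X, y = _design(self.table)
        if np.ptp(self.table.x) == 0:
            raise ValueError("singular design (duplicate predictor values?)")
        try:
            L = np.linalg.cholesky(self.V)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance matrix is singular") from exc
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = y - X @ beta
        ll, sigma2 = _gaussian_loglik(resid, self.V)
        cov_beta = sigma2 * len(y) / max(len(y) - 2, 1) * np.linalg.inv(XtX)
        rw = yw - Xw @ beta
        tss = float((yw - yw.mean()) @ (yw - yw.mean()))
        r2 = 1.0 - float(rw @ rw) / tss if tss > 0 else float("nan")
        return RegressionFit(
            slope=float(beta[1]),
            intercept=float(beta[0]),
            slope_se=float(np.sqrt(cov_beta[1, 1])),
            intercept_se=float(np.sqrt(cov_beta[0, 0])),
            r_squared=r2,
            loglik=ll,
        )


def gls_fit(table: TraitTable, V: np.ndarray) -> RegressionFit:
    return GLSModel(table, V).fit()


class PGLSModel:
    """PGLS with Pagel's lambda estimated by profile maximum likelihood.

    The likelihood is profiled over the regression coefficients and residual
    variance at each lambda; lambda is located on a 21-point grid on [0, 1]
    and refined by bounded 1-D optimization around the best grid cell
    (profile likelihoods on small trees can be flat or multimodal, so the
    grid pass guards the local refinement).
    """

    N_GRID = 21
    XTOL = 1e-6

    def __init__(self, table: TraitTable, tree: dendropy.Tree) -> None:
        if len(table) < 4:
            raise ValueError("need >= 4 species for PGLS")
        tree_labels = {leaf.taxon.label.strip() for leaf in tree.leaf_node_iter()}
        tab_labels = set(table.species)
        if tab_labels - tree_labels:
            raise ValueError(f"species missing from tree: {sorted(tab_labels - tree_labels)}")
        self.table = table
        self.tree = tree
        self.V = brownian_vcv(tree, table.species)

    def _loglik(self, lam: float) -> float:
        Vl = lambda_transform(self.V, lam)
        X, y = _design(self.table)
        try:
            L = np.linalg.cholesky(Vl)
        except np.linalg.LinAlgError:
            return -np.inf
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = y - X @ beta
        ll, _ = _gaussian_loglik(resid, Vl)
        return ll

    def profile(self, grid: Sequence[float] | None = None) -> pd.DataFrame:
        """Profile log-likelihood over a lambda grid (diagnostic)."""
        grid = np.linspace(0, 1, self.N_GRID) if grid is None else np.asarray(grid)
        return pd.DataFrame({"lam": grid, "loglik": [self._loglik(l) for l in grid]})

    def fit(self) -> RegressionFit:
        grid = np.linspace(0.0, 1.0, self.N_GRID)
        lls = np.array([self._loglik(l) for l in grid])
        k = int(np.argmax(lls))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        lam = grid[k]
        if hi > lo:
            res = minimize_scalar(
                lambda l: -self._loglik(l),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": self.XTOL},
            )
            if -res.fun >= lls[k]:
                lam = float(res.x)
        fit = GLSModel(self.table, lambda_transform(self.V, lam)).fit()
        return RegressionFit(
            slope=fit.slope,
            intercept=fit.intercept,
            slope_se=fit.slope_se,
            intercept_se=fit.intercept_se,
            r_squared=fit.r_squared,
            loglik=self._loglik(lam),
            lam=lam,
        )


def pgls_fit(table: TraitTable, tree: dendropy.Tree) -> RegressionFit:
    return PGLSModel(table, tree).fit()
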