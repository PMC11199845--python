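"""Chronogram I/O, Pagel's lambda, PGLS and clade-level behaviour summaries.

Under Brownian-motion (BM) trait evolution on a rooted tree with branch
lengths in time units, the expected trait covariance between species i and
j is the shared path length from the root to their most recent common
ancestor; the variance of species i is its root-to-tip length.  Pagel's
lambda rescales the off-diagonal (shared) covariances by a factor in
[0, 1]: lambda = 1 recovers pure BM, lambda = 0 removes all phylogenetic
covariance (a star phylogeny).  The lambda that maximises the restricted
trait likelihood measures phylogenetic signal; PGLS fits a regression whose
residuals carry that covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import stats as wfstats

__all__ = [
    "Phylogeny",
    "LambdaEstimate",
    "PglsFit",
    "read_newick",
    "bm_covariance",
    "estimate_lambda",
    "pgls_fit",
    "clade_summaries",
]


class NewickError(ValueError):
    """Raised for malformed or unusable Newick input."""


@dataclass
class Phylogeny:
    """A rooted, branch-length-annotated tree with optional clade labels."""

    tree: dendropy.Tree
    clade_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise NewickError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise NewickError(
                    f"missing branch length above {edge.head_node}")
            if edge.length < 0:
                raise NewickError(f"negative branch length {edge.length}")
        self.tip_labels = labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()

    def subset(self, labels: list[str]) -> "Phylogeny":
        """Prune to the given tips (order-insensitive)."""
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(labels)
        cm = ({k: v for k, v in self.clade_map.items() if k in labels}
              if self.clade_map else None)
        return Phylogeny(tree=sub, clade_map=cm)

    def vcv(self) -> pd.DataFrame:
        """BM covariance: C[i, j] = root depth of MRCA(i, j) (diag = tip depth)."""
        labels = self.tip_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        # node depth = distance from root; postorder leaf-set accumulation
        depth: dict[int, float] = {id(self.tree.seed_node): 0.0}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        leafsets: dict[int, list[int]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                leafsets[id(node)] = [i]
                C[i, i] = depth[id(node)]
            else:
                kids = [leafsets[id(ch)] for ch in node.child_nodes()]
                d = depth[id(node)]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = d
                merged: list[int] = []
                for kk in kids:
                    merged.extend(kk)
                leafsets[id(node)] = merged
        return pd.DataFrame(C, index=labels, columns=labels)


def read_newick(path, clade_map: dict[str, str] | None = None) -> Phylogeny:
    """Parse a Newick chronogram (branch lengths required)."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"{path}: {exc}") from exc
    return Phylogeny(tree=tree, clade_map=clade_map)


def read_newick_string(s: str, clade_map: dict[str, str] | None = None) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=s, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise NewickError(str(exc)) from exc
    return Phylogeny(tree=tree, clade_map=clade_map)


def bm_covariance(phy: Phylogeny, lam: float) -> pd.DataFrame:
    """Lambda-scaled BM covariance: off-diagonals x lambda, diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C = phy.vcv().to_numpy().copy()
    d = np.diag(C).copy()
    C *= lam
    np.fill_diagonal(C, d)
    return pd.DataFrame(C, index=phy.tip_labels, columns=phy.tip_labels)


def _gls_profile_loglik(y: np.ndarray, C: np.ndarray, lam: float
                        ) -> tuple[float, float, float]:
    """Profile ML log-likelihood at lambda, with closed-form mu and sigma2."""
    n = len(y)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    L = np.linalg.cholesky(V)
    one = np.ones(n)
    zy = np.linalg.solve(L, y)
    z1 = np.linalg.solve(L, one)
    mu = float(z1 @ zy / (z1 @ z1))
    r = zy - mu * z1
    s2 = float(r @ r) / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * math.log(2.0 * math.pi * s2) + logdet + n)
    return ll, mu, s2


@dataclass(frozen=True)
class LambdaEstimate:
    lambda_hat: float
    sigma2_hat: float
    mu_hat: float
    log_likelihood: float
    lrt_p_vs_zero: float


def estimate_lambda(phy: Phylogeny, trait: pd.Series,
                    boundary_mixture: bool = False,
                    coarse_grid: int = 21, xatol: float = 1e-9
                    ) -> LambdaEstimate:
    """Maximum-likelihood Pagel's lambda for one trait, bounded to [0, 1].

    The 1-D profile likelihood (mean and rate profiled out by GLS in closed
    form) is maximised by a coarse multistart grid followed by bounded
    refinement.  The likelihood-ratio test against lambda = 0 uses the plain
    chi-square(1) reference (conservative at the boundary); pass
    ``boundary_mixture=True`` for the 50:50 point-mass/chi-square mixture.
    On a star phylogeny the likelihood is flat in lambda and 0 is returned
    by convention.  Zero-variance traits leave lambda undefined.
    """
    y = trait.reindex(phy.tip_labels)
    if y.isna().any():
        missing = y[y.isna()].index.tolist()
        raise ValueError(f"trait missing for tips {missing}")
    y = y.to_numpy(dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 species")
    if np.var(y) == 0.0:
        raise ValueError("trait has zero variance; lambda undefined")
    C = phy.vcv().to_numpy()
    off = C - np.diag(np.diag(C))
    ll0, mu0, s20 = _gls_profile_loglik(y, C, 0.0)
    if np.abs(off).max() == 0.0:  # star tree: likelihood flat in lambda
        return LambdaEstimate(0.0, s20, mu0, ll0, 1.0)

    def nll(lam: float) -> float:
        return -_gls_profile_loglik(y, C, lam)[0]

    grid = np.linspace(0.0, 1.0, coarse_grid)
    vals = np.array([nll(g) for g in grid])
    best = int(np.argmin(vals))
    lo = grid[max(0, best - 1)]
    hi = grid[min(coarse_grid - 1, best + 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": xatol})
    lam_hat = float(res.x)
    # snap to a boundary when the optimiser stops just inside it
    for edge in (0.0, 1.0):
        if abs(lam_hat - edge) < 10 * xatol or nll(edge) <= res.fun:
            if nll(edge) <= res.fun + 1e-12:
                lam_hat = edge
    ll, mu, s2 = _gls_profile_loglik(y, C, lam_hat)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    if boundary_mixture:
        p = 0.5 * p if lrt > 0 else 1.0
    return LambdaEstimate(lam_hat, s2, mu, ll, p)


@dataclass(frozen=True)
class PglsFit:
    coefficients: pd.DataFrame  # estimate, se, t, p per term
    lambda_used: float
    log_likelihood: float
    sigma2: float
    n: int


def _gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, float, float]:
    n, p = X.shape
    L = np.linalg.cholesky(V)
    zy = np.linalg.solve(L, y)
    zX = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(zX, zy, rcond=None)
    r = zy - zX @ beta
    rss = float(r @ r)
    s2_ml = rss / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * math.log(2.0 * math.pi * s2_ml) + logdet + n)
    XtX = zX.T @ zX
    if np.linalg.matrix_rank(XtX) < p:
        raise ValueError("design matrix is rank deficient")
    cov = np.linalg.inv(XtX) * (rss / max(n - p, 1))
    se = np.sqrt(np.diag(cov))
    return beta, se, s2_ml, ll


def pgls_fit(phy: Phylogeny, y: pd.Series, X: pd.DataFrame,
             lam: float | str = "ml", add_intercept: bool = True) -> PglsFit:
    """Phylogenetic GLS regression with lambda-structured residuals.

    ``lam`` is a fixed value in [0, 1] or ``"ml"`` to profile it jointly
    with the regression.  With lambda = 0 the fit reduces to (weighted) OLS
    with independent residuals whose variances are the root-to-tip depths.
    """
    yv = y.reindex(phy.tip_labels)
    Xv = X.reindex(phy.tip_labels)
    if yv.isna().any() or Xv.isna().any().any():
        raise ValueError("response/predictors missing for some tips")
    names = list(X.columns)
    Xm = Xv.to_numpy(dtype=float)
    if add_intercept:
        Xm = np.column_stack([np.ones(len(Xm)), Xm])
        names = ["intercept"] + names
    yv = yv.to_numpy(dtype=float)
    C = phy.vcv().to_numpy()

    def fit_at(l: float):
        V = C * l
        np.fill_diagonal(V, np.diag(C))
        return _gls_fit(yv, Xm, V)

    if lam == "ml":
        grid = np.linspace(0.0, 1.0, 21)
        nlls = [-fit_at(g)[3] for g in grid]
        b = int(np.argmin(nlls))
        res = optimize.minimize_scalar(
            lambda l: -fit_at(l)[3],
            bounds=(grid[max(0, b - 1)], grid[min(20, b + 1)]),
            method="bounded", options={"xatol": 1e-8})
        lam_val = float(res.x)
        for edge in (0.0, 1.0):
            if -fit_at(edge)[3] <= res.fun + 1e-12:
                lam_val = edge
    else:
        lam_val = float(lam)
        if not 0.0 <= lam_val <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
    beta, se, s2, ll = fit_at(lam_val)
    n, p = Xm.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(n - p, 1))
    coef = pd.DataFrame({"estimate": beta, "se": se, "t": tvals, "p": pvals},
                        index=names)
    return PglsFit(coefficients=coef, lambda_used=lam_val,
                   log_likelihood=ll, sigma2=s2, n=n)


def clade_summaries(trials: pd.DataFrame,
                    metrics: list[str] | None = None,
                    clade_col: str = "clade",
                    min_trials: int = 2) -> dict:
    """Per-clade mean +/- SD of each WF indicator, with group comparisons.

    Clades with fewer than ``min_trials`` rows are excluded (warned).
    Comparisons (Kruskal-Wallis, then Dunnett T3 pairwise) are skipped when
    fewer than two clades remain.
    """
    if clade_col not in trials.columns:
        raise ValueError(f"missing {clade_col!r} column")
    if metrics is None:
        metrics = [c for c in trials.columns
                   if c.startswith(("wf_", "s_")) and
                   pd.api.types.is_numeric_dtype(trials[c])]
    counts = trials[clade_col].value_counts()
    small = counts[counts < min_trials].index.tolist()
    if small:
        warnings.warn(f"excluding clades with <{min_trials} trials: {small}",
                      stacklevel=2)
    kept = trials[~trials[clade_col].isin(small)]
    summary = kept.groupby(clade_col)[metrics].agg(["mean", "std", "count"])
    out: dict = {"summary": summary, "comparisons": {}}
    clades = sorted(kept[clade_col].unique())
    if len(clades) < 2:
        return out
    for m in metrics:
        groups = [kept.loc[kept[clade_col] == c, m].to_numpy() for c in clades]
        kw = wfstats.kruskal_wallis(groups)
        t3 = wfstats.dunnett_t3(groups, labels=clades)
        out["comparisons"][m] = {"kruskal_wallis": kw, "dunnett_t3": t3}
    return out
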