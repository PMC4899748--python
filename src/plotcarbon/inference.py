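"""Statistical layer: Pearson correlation tables, bidirectional stepwise
regression, LMG hierarchical partitioning of R^2, and recursive path
(observed-variable SEM) models with stepwise pruning.

Path models are estimated equation-by-equation by OLS on z-scored data,
which is maximum-likelihood-equivalent for recursive models with
independent errors. Fit is judged by the likelihood-ratio discrepancy
between the observed correlation matrix S and the model-implied Sigma:

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,   chi2 = (N - 1) F

with df = p(p+1)/2 - t free parameters t (path coefficients + residual
variances + exogenous variances/covariances) and AIC = chi2 + 2t.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# Pearson correlation tables
# --------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_table(
    qframe: pd.DataFrame,
    rows: list[str],
    cols: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson r with two-sided t-test p-values.

    Returns a tidy table (var1, var2, r, p, stars, n) for every (row, col)
    pair; with ``cols=None`` all pairs among ``rows`` are used.
    """
    if cols is None:
        pairs = list(itertools.combinations(rows, 2)) + [(v, v) for v in rows]
    else:
        pairs = [(a, b) for a in rows for b in cols]
    used = sorted({v for p in pairs for v in p})
    data = qframe[used].dropna()
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 complete quadrats for correlations")
    for v in used:
        if data[v].std(ddof=1) == 0:
            raise ValueError(f"zero-variance variable: {v!r}")
    out = []
    for a, b in pairs:
        if a == b:
            r, p = 1.0, 0.0
        else:
            r, p = stats.pearsonr(data[a], data[b])
        out.append(
            {"var1": a, "var2": b, "r": r, "p": p, "stars": significance_stars(p), "n": n}
        )
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Stepwise OLS
# --------------------------------------------------------------------------

@dataclass
class RegressionResult:
    response: str
    regressors: list[str]
    coefficients: pd.Series       # includes "intercept"
    adj_r2: float
    r2: float
    aic: float
    n: int

    @property
    def formula(self) -> str:
        terms = [f"{self.coefficients[v]:+.4g}*{v}" for v in self.regressors]
        const = f"{self.coefficients['intercept']:+.4g}"
        rhs = " ".join(terms + [const]) if terms else const
        return f"{self.response} ~ {rhs}".replace("+", "+ ").replace("-", "- ")


def _ols_fit(y: np.ndarray, X: np.ndarray):
    """OLS with intercept; returns (beta, rss, r2, adj_r2, aic).

    AIC follows the Gaussian profile-likelihood convention
    n*ln(RSS/n) + 2k (k = regressors + intercept), matching stepwise-AIC
    model-selection practice.
    """
    n = len(y)
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k = Z.shape[1]
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else float("nan")
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
    return beta, rss, r2, adj, aic


def stepwise_ols(
    response: str,
    candidates: list[str],
    qframe: pd.DataFrame,
    criterion: str = "aic",
) -> RegressionResult:
    """Bidirectional stepwise search minimizing AIC from intercept-only.

    At each step every single addition and removal is scored; the move with
    the lowest AIC is taken if it improves on the current model, with ties
    broken toward the smaller model. Deterministic given the data.
    """
    if criterion != "aic":
        raise ValueError("only AIC-based stepwise selection is supported")
    data = qframe[[response] + list(candidates)].dropna()
    n = len(data)
    if n <= len(candidates) + 2:
        raise ValueError("too few rows for the candidate set")
    y = data[response].to_numpy(float)

    # drop aliased (rank-deficient) candidates up front
    X_all = data[list(candidates)].to_numpy(float)
    keep = []
    for j, name in enumerate(candidates):
        trial = X_all[:, keep + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), trial])) == len(keep) + 2:
            keep.append(j)
        else:
            warnings.warn(f"dropping aliased regressor {name!r}", stacklevel=2)
    candidates = [candidates[j] for j in keep]

    def score(subset):
        X = data[list(subset)].to_numpy(float)
        return _ols_fit(y, X)

    current: list[str] = []
    _, _, _, _, cur_aic = score(current)
    while True:
        moves = []
        for c in candidates:
            if c not in current:
                moves.append((current + [c], "add", c))
        for c in current:
            moves.append(([v for v in current if v != c], "drop", c))
        best = None
        for subset, kind, name in moves:
            aic = score(subset)[4]
            # strict improvement; ties favour the smaller model
            if aic < cur_aic - 1e-9 and (
                best is None
                or aic < best[1] - 1e-9
                or (abs(aic - best[1]) <= 1e-9 and len(subset) < len(best[0]))
            ):
                best = (subset, aic)
        if best is None:
            break
        current, cur_aic = best

    beta, _, r2, adj, aic = score(current)
    coefs = pd.Series(beta, index=["intercept"] + current)
    return RegressionResult(
        response=response,
        regressors=current,
        coefficients=coefs,
        adj_r2=adj,
        r2=r2,
        aic=aic,
        n=n,
    )


# --------------------------------------------------------------------------
# LMG hierarchical partitioning
# --------------------------------------------------------------------------

@dataclass
class ImportanceDecomposition:
    shares: pd.Series              # per-regressor share of R^2
    full_r2: float
    components: pd.Series | None   # subtotals per variable group


def _r2_of(y, X_full, cols):
    if not cols:
        return 0.0
    X = X_full[:, cols]
    Z = np.column_stack([np.ones(len(y)), X])
    beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss


def lmg_partition(
    response: str,
    regressors: list[str],
    qframe: pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> ImportanceDecomposition:
    """LMG decomposition of R^2: each regressor's share is its sequential
    R^2 increment averaged over all orderings of the regressors.

    Computed by subset enumeration with combinatorial weights
    |S|!(k-|S|-1)!/k!, equivalent to averaging over all k! orderings.
    ``groups`` optionally maps regressor -> component name for subtotals.
    """
    k = len(regressors)
    if k > 12:
        raise ValueError(
            "more than 12 regressors: exact enumeration is infeasible; "
            "reduce the set or sample orderings"
        )
    data = qframe[[response] + list(regressors)].dropna()
    y = data[response].to_numpy(float)
    X = data[list(regressors)].to_numpy(float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < k + 1:
        raise ValueError("design matrix is rank-deficient")

    r2_cache: dict[frozenset, float] = {}

    def r2(subset: frozenset) -> float:
        if subset not in r2_cache:
            r2_cache[subset] = _r2_of(y, X, sorted(subset))
        return r2_cache[subset]

    fact = [math.factorial(i) for i in range(k + 1)]
    shares = np.zeros(k)
    idx_all = list(range(k))
    for i in idx_all:
        others = [j for j in idx_all if j != i]
        for r in range(k):
            w = fact[r] * fact[k - r - 1] / fact[k]
            for combo in itertools.combinations(others, r):
                s = frozenset(combo)
                shares[i] += w * (r2(s | {i}) - r2(s))

    full = r2(frozenset(idx_all))
    shares_s = pd.Series(shares, index=list(regressors), name="lmg_share")
    comp = None
    if groups:
        comp = shares_s.groupby(pd.Series(groups)).sum()
        comp.name = "component_share"
    return ImportanceDecomposition(shares=shares_s, full_r2=full, components=comp)


# --------------------------------------------------------------------------
# Recursive path models
# --------------------------------------------------------------------------

@dataclass
class PathModel:
    """Directed recursive path specification among observed variables.

    ``edges`` are (source, target) pairs; variables with no incoming edge
    are exogenous and carry free variances/covariances among themselves.
    """

    variables: list[str]
    edges: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        self.edges = [tuple(e) for e in self.edges]
        for a, b in self.edges:
            if a not in self.variables or b not in self.variables:
                raise ValueError(f"edge ({a}, {b}) references unknown variable")
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic (recursive)")

    @property
    def endogenous(self) -> list[str]:
        targets = {b for _, b in self.edges}
        return [v for v in self.variables if v in targets]

    @property
    def exogenous(self) -> list[str]:
        targets = {b for _, b in self.edges}
        return [v for v in self.variables if v not in targets]

    def parents(self, v: str) -> list[str]:
        return [a for a, b in self.edges if b == v]

    def n_free_parameters(self) -> int:
        ne = len(self.exogenous)
        return len(self.edges) + len(self.endogenous) + ne * (ne + 1) // 2

    def without(self, edge: tuple) -> "PathModel":
        return PathModel(self.variables, [e for e in self.edges if e != tuple(edge)])

    @classmethod
    def saturated(cls, variables: list[str]) -> "PathModel":
        """Full DAG in the given variable order (chi2 = 0, df = 0)."""
        edges = [
            (variables[i], variables[j])
            for i in range(len(variables))
            for j in range(i + 1, len(variables))
        ]
        return cls(list(variables), edges)

    def to_dot(self, fit: "PathFit | None" = None) -> str:
        lines = ["digraph paths {", "  rankdir=LR;"]
        for v in self.variables:
            lines.append(f'  "{v}";')
        for a, b in self.edges:
            label = ""
            if fit is not None:
                coef = fit.coefficients[(a, b)]
                label = f' [label="{coef:.2f}"]'
            lines.append(f'  "{a}" -> "{b}"{label};')
        ex = self.exogenous
        for i in range(len(ex)):
            for j in range(i + 1, len(ex)):
                lines.append(f'  "{ex[i]}" -> "{ex[j]}" [dir=both, style=dashed];')
        lines.append("}")
        return "\n".join(lines)


def path_fit_stats(chi2: float, n_observed: int, df: int) -> tuple[int, float, float]:
    """Fit-statistic conventions used by the path-model fitter.

    Free parameters t are counted against the p(p+1)/2 covariance moments,
    so t = p(p+1)/2 - df; the information criterion is chi2 + 2t and the
    model P-value is the upper-tail chi-square probability on df.
    """
    if chi2 < 0 or df < 0:
        raise ValueError("chi2 and df must be nonnegative")
    t = n_observed * (n_observed + 1) // 2 - df
    pvalue = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    aic = chi2 + 2 * t
    return t, pvalue, aic


@dataclass
class PathFit:
    model: PathModel
    coefficients: dict              # (src, dst) -> standardized coefficient
    pvalues: dict                   # (src, dst) -> two-sided p
    r2: dict                        # endogenous variable -> R^2
    chi2: float
    df: int
    pvalue: float
    aic: float
    n: int
    n_free: int
    observed_cov: pd.DataFrame
    implied_cov: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "variables": self.model.variables,
            "edges": [
                {
                    "from": a,
                    "to": b,
                    "coefficient": self.coefficients[(a, b)],
                    "p": self.pvalues[(a, b)],
                    "stars": significance_stars(self.pvalues[(a, b)]),
                }
                for a, b in self.model.edges
            ],
            "r2": self.r2,
            "chi2": self.chi2,
            "df": self.df,
            "P": self.pvalue,
            "AIC": self.aic,
            "N": self.n,
            "n_free_parameters": self.n_free,
        }


def fit_path_model(model: PathModel, qframe: pd.DataFrame) -> PathFit:
    """Fit a recursive path model on z-scored data.

    Each endogenous variable is regressed on its parents (standardized
    coefficients with OLS t-test p-values); the implied covariance is built
    from the structural equations and compared to the observed correlation
    matrix via the ML discrepancy.
    """
    vars_ = model.variables
    data = qframe[vars_].dropna()
    n = len(data)
    p = len(vars_)
    if n <= p:
        raise ValueError("need more observations than variables")
    S = pd.DataFrame(np.corrcoef(data.to_numpy(float).T), index=vars_, columns=vars_)
    if np.linalg.matrix_rank(S.to_numpy()) < p:
        raise ValueError("observed covariance matrix is singular")

    idx = {v: k for k, v in enumerate(vars_)}
    B = np.zeros((p, p))          # B[i, j]: coefficient of j -> i
    coefficients: dict = {}
    pvalues: dict = {}
    r2: dict = {}
    Sm = S.to_numpy()

    for v in model.endogenous:
        pa = model.parents(v)
        ii = [idx[a] for a in pa]
        j = idx[v]
        Sxx = Sm[np.ix_(ii, ii)]
        Sxy = Sm[ii, j]
        beta = np.linalg.solve(Sxx, Sxy)
        rv = float(1.0 - beta @ Sxy)          # residual variance on z scale
        r2[v] = float(beta @ Sxy)
        dfree = n - len(pa) - 1
        # standard errors of standardized OLS coefficients
        sigma2 = rv * (n - 1) / dfree
        se = np.sqrt(np.diag(np.linalg.inv(Sxx)) * sigma2 / (n - 1))
        for a, bcoef, s in zip(pa, beta, se):
            B[j, idx[a]] = bcoef
            coefficients[(a, v)] = float(bcoef)
            tstat = bcoef / s
            pvalues[(a, v)] = float(2 * stats.t.sf(abs(tstat), dfree))

    # implied covariance: (I-B)^-1 Psi (I-B)^-T with exogenous block = S
    Psi = np.zeros((p, p))
    ex = [idx[v] for v in model.exogenous]
    Psi[np.ix_(ex, ex)] = Sm[np.ix_(ex, ex)]
    for v in model.endogenous:
        j = idx[v]
        pa_i = [idx[a] for a in model.parents(v)]
        Psi[j, j] = float(Sm[j, j] - B[j, pa_i] @ Sm[pa_i, j])
    inv = np.linalg.inv(np.eye(p) - B)
    Sigma = inv @ Psi @ inv.T

    sign_S, logdet_S = np.linalg.slogdet(Sm)
    sign_I, logdet_I = np.linalg.slogdet(Sigma)
    if sign_S <= 0 or sign_I <= 0:
        raise ValueError("covariance matrix not positive-definite")
    F = logdet_I - logdet_S + float(np.trace(Sm @ np.linalg.inv(Sigma))) - p
    chi2 = max((n - 1) * F, 0.0)

    t_free = model.n_free_parameters()
    df = p * (p + 1) // 2 - t_free
    if df < 0:
        raise ValueError("model has more free parameters than moments")
    _, pvalue, aic = path_fit_stats(chi2, p, df)

    return PathFit(
        model=model,
        coefficients=coefficients,
        pvalues=pvalues,
        r2=r2,
        chi2=float(chi2),
        df=df,
        pvalue=pvalue,
        aic=float(aic),
        n=n,
        n_free=t_free,
        observed_cov=S,
        implied_cov=pd.DataFrame(Sigma, index=vars_, columns=vars_),
    )


def prune_path_model(
    model: PathModel,
    qframe: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[PathModel, PathFit, list[dict]]:
    """Stepwise pruning: repeatedly drop the least significant path.

    While any path has p >= alpha, the path with the largest p is removed
    and the model refit. Returns (final model, final fit, removal trace).
    """
    trace: list[dict] = []
    fit = fit_path_model(model, qframe)
    while fit.model.edges:
        worst = max(fit.model.edges, key=lambda e: fit.pvalues[e])
        if fit.pvalues[worst] < alpha:
            break
        trace.append(
            {"removed": worst, "p": fit.pvalues[worst], "chi2_before": fit.chi2}
        )
        model = fit.model.without(worst)
        fit = fit_path_model(model, qframe)
    if not fit.model.edges:
        warnings.warn("all paths removed during pruning", stacklevel=2)
    return fit.model, fit, trace
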