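"""Phylogenetic generalized least squares of prey mass on predator mass.

Regression of log10 maximum prey body mass on log10 predator body mass in
which the residuals of related species are allowed to covary according to a
trait-evolution model on a time-calibrated phylogeny.  Four residual
covariance structures are supported:

``BM``
    Brownian motion: covariance of two tips equals the time their lineages
    spent together (shared path time from the root to their MRCA).
``LAMBDA``
    Pagel's lambda: shared-history (off-diagonal) covariances multiplied by
    lambda in [0, 1]; lambda = 1 recovers BM, lambda = 0 phylogenetic
    independence (OLS).
``OU``
    Ornstein-Uhlenbeck mean reversion: correlation between two tips decays
    as exp(-alpha * d) with d their patristic (tip-to-tip) distance, with a
    unit diagonal.
``ACDC``
    Accelerating/decelerating evolution: the rate changes exponentially in
    time with parameter g, giving accumulated covariance
    (exp(g * t) - 1) / g over a shared time t, rescaled so the largest
    diagonal entry equals the tree depth; g is held fixed (default 0.5).

Fitting is by maximum likelihood with the structure parameter (lambda or
alpha) profiled by bounded scalar optimisation; models are ranked by AIC.
Outliers are screened beforehand with the generalized extreme studentized
deviate (Rosner) test.  Prediction intervals for a new, phylogenetically
independent observation (e.g. an extinct taxon outside the tree) follow the
classical GLS mean/new-response formulas.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "NewickError",
    "Phylogeny",
    "read_newick",
    "CovarianceModel",
    "model_covariance",
    "GLSFit",
    "gls_fit",
    "aic_rank",
    "OutlierReport",
    "rosner_outliers",
    "IntervalEstimate",
    "predict_interval",
    "MODEL_KINDS",
]

MODEL_KINDS = ("BM", "OU", "LAMBDA", "ACDC")

#: default fixed rate-change parameter for the ACDC structure
ACDC_DEFAULT_G = 0.5


class NewickError(ValueError):
    """Malformed Newick input (syntax, duplicate tips, missing lengths)."""


# ---------------------------------------------------------------------------
# Phylogeny: thin wrapper over dendropy with the queries PGLS needs
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree with branch lengths, queryable for shared path times.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree; every non-root edge must carry a nonnegative length and
        tip labels must be unique.  Validation happens here so that every
        downstream matrix computation can assume a clean tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("unlabeled tip in tree")
            labels.append(leaf.taxon.label)
        if len(labels) < 2:
            raise NewickError("tree must have at least 2 tips")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge length optional
            if edge.length is None:
                node = edge.head_node
                name = node.taxon.label if node.taxon else "<internal>"
                raise NewickError(f"missing branch length on edge above {name!r}")
            if edge.length < 0:
                raise NewickError("negative branch length")
        self.tip_labels: tuple[str, ...] = tuple(labels)

    def __len__(self) -> int:
        return len(self.tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> np.ndarray:
        """Root-to-tip path length per tip, in ``tip_labels`` order."""
        return np.diag(self.shared_time_matrix())

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return float(self.depths().max())

    def shared_time_matrix(self) -> np.ndarray:
        """Matrix C with C[i, j] = root-to-MRCA time of tips i and j.

        This is the Brownian-motion covariance (up to the rate) of tip values
        and the raw material for every other structure.
        """
        n = self.n_tips
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        C = np.zeros((n, n))
        # postorder sweep: at each internal node, pairs of tips drawn from
        # different child subtrees have their MRCA exactly there
        node_depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            node_depth[id(node)] = node_depth[id(node.parent_node)] + (
                node.edge.length or 0.0
            )
        tips_below: dict[int, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                tips_below[id(node)] = [i]
                C[i, i] = node_depth[id(node)]
                continue
            children = [tips_below.pop(id(ch)) for ch in node.child_nodes()]
            d = node_depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            tips_below[id(node)] = [i for ch in children for i in ch]
        return C

    def patristic_distance(self, a: str, b: str) -> float:
        C = self.shared_time_matrix()
        i = self.tip_labels.index(a)
        j = self.tip_labels.index(b)
        return float(C[i, i] + C[j, j] - 2 * C[i, j])

    def prune(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to ``keep``, preserving pairwise path lengths.

        Internal nodes left with a single child are collapsed and their
        branch lengths summed, so retained tip-to-tip distances and
        root-to-MRCA times are unchanged.
        """
        keep = list(dict.fromkeys(keep))
        unknown = sorted(set(keep) - set(self.tip_labels))
        if unknown:
            raise KeyError(f"species not in tree: {unknown}")
        if len(keep) < 2:
            raise ValueError("pruning must retain at least 2 tips")
        if set(keep) == set(self.tip_labels):
            return Phylogeny(self._tree.clone(depth=1))
        sub = self._tree.extract_tree_with_taxa_labels(keep)
        return read_newick(sub.as_string(schema="newick"))

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        ).strip()


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a `Phylogeny`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Covariance structures
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CovarianceModel:
    """A trait-evolution covariance structure and its parameter.

    ``theta`` is ignored for BM, is alpha > 0 for OU, lambda in [0, 1] for
    LAMBDA and the fixed rate-change g for ACDC.
    """

    kind: str
    theta: float | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


def model_covariance(C: np.ndarray, model: CovarianceModel) -> np.ndarray:
    """Build the residual covariance/correlation matrix V from shared times C."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be a square matrix")
    kind, theta = model.kind, model.theta
    if kind == "BM":
        return C.copy()
    if kind == "LAMBDA":
        lam = 1.0 if theta is None else float(theta)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        V = lam * C
        np.fill_diagonal(V, np.diag(C))
        return V
    if kind == "OU":
        if theta is None or theta <= 0:
            raise ValueError(f"OU requires alpha > 0, got {theta}")
        d = np.diag(C)
        D = d[:, None] + d[None, :] - 2.0 * C  # patristic distances
        return np.exp(-float(theta) * D)
    if kind == "ACDC":
        g = ACDC_DEFAULT_G if theta is None else float(theta)
        if abs(g) < 1e-12:
            V = C.copy()
        else:
            V = np.expm1(g * C) / g
        # rescale so the deepest tip keeps variance == tree depth
        depth = float(np.diag(C).max())
        if depth > 0 and V.max() > 0:
            V *= depth / float(np.diag(V).max())
        return V
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GLSFit:
    """One fitted PGLS model.

    ``aic = 2k - 2 loglik`` where k counts intercept, slope, sigma2 and the
    structure parameter when it was profiled (OU, LAMBDA).
    """

    model_kind: str
    intercept: float
    slope: float
    sigma2: float
    theta_hat: float | None
    loglik: float
    aic: float
    n: int
    p: int
    mode: str | None = None
    # internals needed for interval estimation
    xtvix_inv: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.intercept, self.slope])

    @property
    def k(self) -> int:
        return self.p + 1 + (1 if self.model_kind in ("OU", "LAMBDA") else 0)


def _gls_profile_loglik(x, y, V):
    """GLS coefficients and profiled-ML log-likelihood for a fixed V.

    Returns (beta, sigma2_ml, loglik, (X'V^-1X)^-1); raises
    ``np.linalg.LinAlgError`` when V is not positive definite.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    L = np.linalg.cholesky(V)
    # whiten by the Cholesky factor: L^-1 X, L^-1 y
    Xt = solve_triangular(L, X, lower=True)
    yt = solve_triangular(L, y, lower=True)
    A = Xt.T @ Xt  # X' V^-1 X
    beta = np.linalg.solve(A, Xt.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n  # ML scale
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetV + n)
    return beta, sigma2, loglik, np.linalg.inv(A)


def gls_fit(
    x: Sequence[float],
    y: Sequence[float],
    C: np.ndarray,
    model_kind: str,
    theta: float | None = None,
    mode: str | None = None,
) -> GLSFit:
    """Fit y = b0 + b1 x with residual covariance sigma2 * V(model) by ML.

    Parameters
    ----------
    x, y : array-like
        Predictor and response, aligned with the rows of ``C``.
    C : ndarray
        Shared-time matrix from `Phylogeny.shared_time_matrix`.
    model_kind : str
        One of ``BM``, ``OU``, ``LAMBDA``, ``ACDC``.
    theta : float, optional
        Fix the structure parameter instead of profiling it (used for the
        reduction checks lambda=1 -> BM, lambda=0 -> OLS, and always for
        ACDC's fixed g).
    mode : str, optional
        Label of the data stratum (e.g. ``solitary``/``pack``), carried
        through to `aic_rank` compatibility checks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    n = len(y)
    if len(x) != n or C.shape != (n, n):
        raise ValueError("x, y and C must agree in size")
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")

    depth = float(np.diag(C).max())

    def fit_at(th):
        V = model_covariance(C, CovarianceModel(model_kind, th))
        return _gls_profile_loglik(x, y, V)

    if model_kind == "BM":
        theta_hat = None
        beta, sigma2, loglik, A_inv = fit_at(None)
    elif model_kind == "ACDC":
        theta_hat = ACDC_DEFAULT_G if theta is None else float(theta)
        beta, sigma2, loglik, A_inv = fit_at(theta_hat)
    elif theta is not None:
        theta_hat = float(theta)
        beta, sigma2, loglik, A_inv = fit_at(theta_hat)
    else:
        if model_kind == "LAMBDA":
            lo, hi = 1e-6, 1.0
        else:  # OU
            lo, hi = 1e-6, 50.0 / depth

        def nll(th):
            try:
                return -fit_at(th)[2]
            except np.linalg.LinAlgError:
                return np.inf

        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8 * (hi - lo)},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError(f"{model_kind} likelihood profiling failed")
        theta_hat = float(res.x)
        beta, sigma2, loglik, A_inv = fit_at(theta_hat)

    p = 2
    # theta counts toward k for the profiled structures (OU, LAMBDA) but not
    # for BM or fixed-g ACDC
    k = p + 1 + (1 if model_kind in ("OU", "LAMBDA") else 0)
    aic = 2.0 * k - 2.0 * loglik
    return GLSFit(
        model_kind=model_kind,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        sigma2=float(sigma2),
        theta_hat=theta_hat,
        loglik=float(loglik),
        aic=float(aic),
        n=n,
        p=p,
        mode=mode,
        xtvix_inv=A_inv,
    )


def aic_rank(fits: Sequence[GLSFit]) -> list[tuple[GLSFit, float]]:
    """Rank fits by ascending AIC; ties keep input order.

    Returns ``[(fit, delta_aic), ...]``; refuses fits made on different data
    (different n or stratum label).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    if len({(f.n, f.mode) for f in fits}) > 1:
        raise ValueError("fits were made on different data; refusing to rank")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, i))
    best = fits[order[0]].aic
    return [(fits[i], fits[i].aic - best) for i in order]


# ---------------------------------------------------------------------------
# Rosner (generalized ESD) outlier screening
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class OutlierReport:
    tested_values: np.ndarray
    k_max: int
    alpha: float
    flagged: list[int]
    statistics: list[tuple[float, float]]  # (R_i, critical value) per step


def rosner_outliers(values: Sequence[float], k_max: int = 3, alpha: float = 0.05) -> OutlierReport:
    """Generalized extreme studentized deviate test for up to ``k_max`` outliers.

    At step i the most extreme remaining value's studentized deviate
    R_i = max|x - mean| / sd is computed and that value removed; R_i is then
    compared with its t-based critical value

        lambda_i = (n - i) t_{p, n-i-1} / sqrt((n-i-1+t^2)(n-i+1)),
        p = 1 - alpha / (2 (n - i + 1)),

    and the declared outliers are the first i_max removals, where i_max is
    the largest i with R_i > lambda_i.  Approximate normality of the inliers
    is assumed.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"generalized ESD needs n >= 10, got {n}")
    if not 1 <= k_max <= n - 2:
        raise ValueError("k_max must be in [1, n-2]")
    if np.std(x, ddof=1) == 0:
        raise ValueError("degenerate data: zero sample standard deviation")

    remaining = list(range(n))
    removed: list[int] = []
    stats_out: list[tuple[float, float]] = []
    i_max = 0
    for i in range(1, k_max + 1):
        sub = x[remaining]
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(dev.argmax())
        R = float(dev[j] / s)
        m = n - i + 1  # sample size at this step
        p = 1.0 - alpha / (2.0 * m)
        t = stats.t.ppf(p, m - 2)
        crit = (m - 1) * t / np.sqrt((m - 2 + t * t) * m)
        stats_out.append((R, float(crit)))
        removed.append(remaining.pop(j))
        if R > crit:
            i_max = i
    return OutlierReport(
        tested_values=x, k_max=k_max, alpha=alpha,
        flagged=sorted(removed[:i_max]), statistics=stats_out,
    )


# ---------------------------------------------------------------------------
# Confidence / prediction intervals
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class IntervalEstimate:
    x0: float
    fit_value: float
    ci_low: float
    ci_high: float
    pi_low: float
    pi_high: float
    level: float


def predict_interval(fit: GLSFit, x0: float, level: float = 0.95) -> IntervalEstimate:
    """Confidence band on the mean response and prediction band for a new,
    phylogenetically independent observation at predictor value ``x0``.

    The new point is treated as carrying the model's full residual variance
    sigma2 and no covariance with the fitted tips (appropriate for a taxon
    outside the tree); half-widths use the t distribution on n - p degrees
    of freedom.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if fit.xtvix_inv is None:
        raise ValueError("fit carries no design information")
    v0 = np.array([1.0, float(x0)])
    h = float(v0 @ fit.xtvix_inv @ v0)
    fit_value = float(fit.coef @ v0)
    tq = stats.t.ppf(0.5 + level / 2.0, fit.n - fit.p)
    ci_hw = tq * np.sqrt(fit.sigma2 * h)
    pi_hw = tq * np.sqrt(fit.sigma2 * (1.0 + h))
    return IntervalEstimate(
        x0=float(x0), fit_value=fit_value,
        ci_low=fit_value - ci_hw, ci_high=fit_value + ci_hw,
        pi_low=fit_value - pi_hw, pi_high=fit_value + pi_hw,
        level=level,
    )
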