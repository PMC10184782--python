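"""Phylogenetically informed association tests.

Comparative data are not independent: trait covariance between species is
proportional to shared root-to-ancestor branch length under Brownian
motion (BM). This module converts a rooted tree into that covariance
matrix and provides:

* ``fit_pgls`` — phylogenetic generalized least squares with Pagel's
  lambda estimated by maximum likelihood (off-diagonal shrinkage of the
  BM covariance, interpolating star-tree independence at lambda=0 and
  full BM at lambda=1);
* ``fit_phylo_logistic`` — Firth-penalized logistic point estimates with
  inference by parametric bootstrap under a BM threshold (liability)
  null;
* ``fit_ordinal`` — proportional-odds cumulative-logit regression for
  ordered IUCN categories (phylogeny handled via taxonomic-order factors
  in the design matrix, not the error covariance);
* ``pc_regression`` — principal components of the standardized feature
  correlation matrix regressed on a binary outcome;
* ``regression_model_error`` — repeated stratified 80/20 split error
  estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedShuffleSplit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    RankDeficiencyError,
)

logger = logging.getLogger(__name__)

IUCN_ORDER = ("LC", "NT", "VU", "EN", "CR")
THREATENED = frozenset({"NT", "VU", "EN", "CR"})


# ---------------------------------------------------------------------------
# tree -> covariance


@dataclass(frozen=True)
class PhyloCovariance:
    """BM trait covariance induced by a rooted tree.

    ``matrix[i, j]`` is the summed branch length from the root to the most
    recent common ancestor of tips i and j; the diagonal holds tip depths.
    ``scale`` is the maximum tip depth (tree height).
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    scale: float

    def normalized(self) -> np.ndarray:
        """Covariance scaled to unit height (handy for simulation)."""
        return self.matrix / self.scale

    def reordered(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        m = self.matrix[np.ix_(idx, idx)]
        return PhyloCovariance(labels=tuple(labels), matrix=m, scale=self.scale)


def tree_to_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Compute the BM covariance matrix of a rooted tree with branch lengths.

    Raises ``InvalidParameterError`` for unrooted trees (root with more than
    two children and no seed node designation is still usable; a truly
    unrooted dendropy tree must be rooted first, e.g. by midpoint rooting).
    """
    if tree.seed_node is None or not tree.is_rooted and len(tree.seed_node.child_nodes()) > 2:
        raise InvalidParameterError(
            "tree must be rooted; apply midpoint rooting or set an explicit root"
        )
    tips = tree.leaf_nodes()
    labels = tuple(t.taxon.label for t in tips)
    if len(set(labels)) != len(labels):
        raise InvalidParameterError("tip labels must be unique")
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    c = np.zeros((n, n))

    # depth of each node from the root
    depth: dict[int, float] = {id(tree.seed_node): tree.seed_node.edge.length or 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        el = node.edge.length
        if el is None or el < 0:
            raise InvalidParameterError("all branch lengths must be present and >= 0")
        depth[id(node)] = depth[id(node.parent_node)] + el

    # postorder: at each internal node of depth d, every cross-child tip pair
    # has MRCA exactly there
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            c[i, i] = depth[id(node)]
            continue
        children = node.child_nodes()
        sets = [tipsets.pop(id(ch)) for ch in children]
        d = depth[id(node)]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        c[i, j] = c[j, i] = d
        merged: list[int] = []
        for s in sets:
            merged.extend(s)
        tipsets[id(node)] = merged
    return PhyloCovariance(labels=labels, matrix=c, scale=float(np.max(np.diag(c))))


def _lambda_cov(c: np.ndarray, lam: float) -> np.ndarray:
    """Pagel-lambda transform: V(lambda) = lambda*C + (1-lambda)*diag(C)."""
    v = lam * c
    np.fill_diagonal(v, np.diag(c))
    return v


# ---------------------------------------------------------------------------
# PGLS


@dataclass(frozen=True)
class PglsFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    lambda_: float
    sigma2: float
    loglik: float
    n: int
    df_resid: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.tvalues, "p": self.pvalues},
            index=list(self.names),
        )


def _as_design(x, add_intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        mat = x.to_numpy(dtype=float)
    else:
        mat = np.atleast_2d(np.asarray(x, dtype=float))
        if mat.shape[0] == 1 and mat.shape[1] > 1:
            mat = mat.T
        names = [f"x{i}" for i in range(mat.shape[1])]
    if add_intercept and not (mat.shape[1] and np.allclose(mat[:, 0], 1.0)):
        mat = np.column_stack([np.ones(mat.shape[0]), mat])
        names = ["intercept"] + names
    return mat, names


def _gls_profile(x: np.ndarray, y: np.ndarray, c: np.ndarray, lam: float):
    """GLS at fixed lambda; returns (beta, resid_ss, xtvx_inv, logdet, n)."""
    v = _lambda_cov(c, lam)
    try:
        cf = linalg.cho_factor(v, lower=True)
    except linalg.LinAlgError:
        cf = linalg.cho_factor(v + np.eye(len(v)) * 1e-10 * np.trace(v) / len(v), lower=True)
    xs = linalg.cho_solve(cf, x)  # V^-1 X
    xtvx = x.T @ xs
    xtvy = xs.T @ y
    try:
        beta = linalg.solve(xtvx, xtvy, assume_a="pos")
    except linalg.LinAlgError:
        raise RankDeficiencyError(_aliased_message(x))
    r = y - x @ beta
    rss = float(r @ linalg.cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return beta, rss, xtvx, logdet


def _aliased_message(x: np.ndarray) -> str:
    _, r, piv = linalg.qr(x, pivoting=True, mode="economic")
    d = np.abs(np.diag(r))
    tol = d.max() * max(x.shape) * np.finfo(float).eps
    aliased = sorted(int(piv[k]) for k in range(len(d)) if d[k] <= tol)
    return f"design matrix rank deficient; aliased column indices: {aliased}"


def fit_pgls(
    x,
    y,
    cov: PhyloCovariance | np.ndarray,
    lambda_mode: str | float = "ML",
    add_intercept: bool = True,
) -> PglsFit:
    """Phylogenetic GLS with Pagel's lambda.

    For fixed lambda, beta = (X'V^-1 X)^-1 X'V^-1 y with
    V = sigma^2 * (lambda*C + (1-lambda)*diag(C)); sigma^2 by ML; lambda
    maximizes the profile log-likelihood on [0, 1] (``lambda_mode="ML"``)
    or is held at a supplied float. Coefficient t-tests use df = n - p and
    the bias-corrected sigma^2 estimate.
    """
    c = cov.matrix if isinstance(cov, PhyloCovariance) else np.asarray(cov, dtype=float)
    xmat, names = _as_design(x, add_intercept)
    yv = np.asarray(y, dtype=float)
    n, p = xmat.shape
    if n < p + 2:
        raise InsufficientDataError(f"need n >= p + 2 (n={n}, p={p})")
    if np.linalg.matrix_rank(xmat) < p:
        raise RankDeficiencyError(_aliased_message(xmat))

    def negll(lam: float) -> float:
        _, rss, _, logdet = _gls_profile(xmat, yv, c, lam)
        sigma2 = rss / n
        return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

    if lambda_mode == "ML":
        res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(res.x)
        # the optimum may sit on a boundary the bounded optimizer approaches
        # only asymptotically; evaluate the endpoints explicitly
        cands = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, lam)]
        _, lam = min(cands, key=lambda t: t[0])
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise InvalidParameterError(f"lambda must lie in [0, 1], got {lam}")

    beta, rss, xtvx, logdet = _gls_profile(xmat, yv, c, lam)
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    df = n - p
    sigma2_u = rss / df
    covb = sigma2_u * linalg.inv(xtvx)
    se = np.sqrt(np.diag(covb))
    tv = beta / se
    pv = 2.0 * stats.t.sf(np.abs(tv), df)
    return PglsFit(
        names=tuple(names), coef=beta, se=se, tvalues=tv, pvalues=pv,
        lambda_=lam, sigma2=sigma2_ml, loglik=float(loglik), n=n, df_resid=df,
    )


def pgls_loglik_at(x, y, cov, lam: float, add_intercept: bool = True) -> float:
    """Profile log-likelihood of the PGLS model at a fixed lambda."""
    c = cov.matrix if isinstance(cov, PhyloCovariance) else np.asarray(cov, dtype=float)
    xmat, _ = _as_design(x, add_intercept)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    _, rss, _, logdet = _gls_profile(xmat, yv, c, lam)
    sigma2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


# ---------------------------------------------------------------------------
# Firth logistic + phylogenetic parametric bootstrap


def _firth_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys prior).

    Returns (beta, se). Finite for separated data.
    """
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = x @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        xw = x * w[:, None]
        fisher = x.T @ xw
        try:
            finv = linalg.inv(fisher)
        except linalg.LinAlgError:
            fisher = fisher + np.eye(p) * 1e-10
            finv = linalg.inv(fisher)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", xw, finv, x)
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = finv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = x @ beta
    mu = special.expit(eta)
    w = mu * (1.0 - mu)
    finv = linalg.inv(x.T @ (x * w[:, None]))
    se = np.sqrt(np.diag(finv))
    return beta, se


@dataclass(frozen=True)
class PhyloGlmFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray      # Wald, from the Firth fit
    p_boot: np.ndarray | None  # parametric bootstrap under the BM-liability null
    n_boot: int
    n: int

    def summary(self) -> pd.DataFrame:
        d = {"coef": self.coef, "se": self.se, "z": self.zvalues, "p_wald": self.pvalues}
        if self.p_boot is not None:
            d["p_boot"] = self.p_boot
        return pd.DataFrame(d, index=list(self.names))


def fit_phylo_logistic(
    x,
    y,
    cov: PhyloCovariance | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    add_intercept: bool = True,
) -> PhyloGlmFit:
    """Phylogenetic logistic regression of a binary trait.

    Point estimates are Firth-penalized logistic coefficients (finite even
    under separation). Inference is by parametric bootstrap under the null
    of no association given the phylogeny: liabilities are simulated as BM
    on the tree, thresholded so each replicate matches the observed
    prevalence, the model is refit, and the bootstrap two-sided tail
    probability of the Wald statistic is reported per coefficient.
    """
    c = cov.matrix if isinstance(cov, PhyloCovariance) else np.asarray(cov, dtype=float)
    xmat, names = _as_design(x, add_intercept)
    yv = np.asarray(y, dtype=float)
    n, p = xmat.shape
    if len(np.unique(yv)) < 2:
        raise InvalidParameterError("response is constant; logistic model undefined")
    if n < p + 5:
        raise InsufficientDataError(f"need n >= p + 5 (n={n}, p={p})")

    beta, se = _firth_logistic(xmat, yv)
    z = beta / se
    pwald = 2.0 * stats.norm.sf(np.abs(z))

    p_boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        cn = c / np.max(np.diag(c))
        chol = linalg.cholesky(cn + np.eye(n) * 1e-10, lower=True)
        n_pos = int(yv.sum())
        exceed = np.zeros(p)
        for _ in range(n_boot):
            liab = chol @ rng.standard_normal(n)
            yb = np.zeros(n)
            yb[np.argsort(liab)[-n_pos:]] = 1.0  # match observed prevalence
            bb, sb = _firth_logistic(xmat, yb, max_iter=40)
            exceed += np.abs(bb / sb) >= np.abs(z)
        p_boot = (1.0 + exceed) / (n_boot + 1.0)
    return PhyloGlmFit(
        names=tuple(names), coef=beta, se=se, zvalues=z, pvalues=pwald,
        p_boot=p_boot, n_boot=n_boot, n=n,
    )


# ---------------------------------------------------------------------------
# proportional-odds ordinal regression


@dataclass(frozen=True)
class OrdinalFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    cutpoints: np.ndarray          # K-1, strictly increasing
    categories: tuple[str, ...]    # observed categories, in order
    probs: pd.DataFrame            # per-observation probabilities, all 5 columns
    loglik: float


def fit_ordinal(x, y, categories: tuple[str, ...] = IUCN_ORDER) -> OrdinalFit:
    """Proportional-odds cumulative-logit fit of ordered IUCN categories.

    ``y`` holds category labels from ``categories`` (ordered LC < NT < VU <
    EN < CR). Unobserved categories are dropped from the likelihood
    (their predicted probability is reported as 0); fewer than 2 observed
    categories is an error. Taxonomic-order adjustment is achieved by
    passing order dummy columns in ``x``.
    """
    xmat, names = _as_design(x, add_intercept=False)
    ylab = pd.Series(list(y), dtype=object)
    bad = sorted(set(ylab) - set(categories))
    if bad:
        raise InvalidParameterError(f"unknown categories: {bad}")
    observed = tuple(c for c in categories if (ylab == c).any())
    if len(observed) < 2:
        raise InsufficientDataError("need at least 2 observed categories")
    codes = pd.Categorical(ylab, categories=list(observed), ordered=True)
    model = OrderedModel(codes.codes.astype(float), xmat, distr="logit")
    res = model.fit(method="bfgs", maxiter=1000, gtol=1e-10, disp=False)
    k = len(observed)
    coef = res.params[: xmat.shape[1]]
    se = res.bse[: xmat.shape[1]]
    pv = res.pvalues[: xmat.shape[1]]
    cut = model.transform_threshold_params(res.params)[1:-1]  # drop +-inf
    probs_obs = np.asarray(res.predict(xmat))
    probs = pd.DataFrame(0.0, index=range(len(ylab)), columns=list(categories))
    for j, cat in enumerate(observed):
        probs[cat] = probs_obs[:, j]
    return OrdinalFit(
        names=tuple(names), coef=np.asarray(coef), se=np.asarray(se),
        pvalues=np.asarray(pv), cutpoints=np.asarray(cut), categories=observed,
        probs=probs, loglik=float(res.llf),
    )


def order_dummies(orders: pd.Series | list[str]) -> pd.DataFrame:
    """Taxonomic-order factor as dummy columns (first level as baseline)."""
    s = pd.Series(list(orders), dtype=object)
    d = pd.get_dummies(s, prefix="order", drop_first=True, dtype=float)
    d.index = range(len(s))
    return d


# ---------------------------------------------------------------------------
# principal-component regression


@dataclass(frozen=True)
class PcRegressionFit:
    loadings: np.ndarray            # p x k, orthonormal columns
    explained_variance: np.ndarray  # k, non-increasing
    scores: np.ndarray              # n x k
    feature_names: tuple[str, ...]
    glm: PhyloGlmFit                # logistic fit of y on retained PC scores
    n_components: int


def pc_regression(
    features: pd.DataFrame,
    y,
    cov: PhyloCovariance | np.ndarray | None = None,
    n_components: int | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> PcRegressionFit:
    """PCA of standardized genomic features, scores regressed on threat status.

    Missing cells are imputed with the column median before z-scoring;
    the eigendecomposition is of the feature correlation matrix. Scores of
    the retained components enter a (phylogenetic, if ``cov`` given)
    logistic regression on the binary outcome.
    """
    z = features.astype(float).copy()
    med = z.median(axis=0)
    z = z.fillna(med)
    mu = z.mean(axis=0)
    sd = z.std(axis=0, ddof=0)
    if (sd == 0).any():
        dropped = list(z.columns[sd == 0])
        logger.warning("dropping zero-variance feature columns: %s", dropped)
        z = z.drop(columns=dropped)
        mu, sd = mu[z.columns], sd[z.columns]
    zs = (z - mu) / sd
    n, p = zs.shape
    kmax = min(n - 1, p)
    if p >= n:
        logger.warning("more features (%d) than species-1 (%d); retaining %d PCs", p, n - 1, kmax)
    zm = zs.to_numpy()
    u, s, vt = np.linalg.svd(zm, full_matrices=False)
    loadings = vt[:kmax].T
    expl = (s[:kmax] ** 2) / n
    scores = zm @ loadings
    k = min(n_components or kmax, kmax)
    yv = np.asarray(y, dtype=float)
    c = cov if cov is not None else np.eye(n)
    glm = fit_phylo_logistic(
        pd.DataFrame(scores[:, :k], columns=[f"PC{i+1}" for i in range(k)]),
        yv, c, n_boot=n_boot, seed=seed,
    )
    return PcRegressionFit(
        loadings=loadings, explained_variance=expl, scores=scores,
        feature_names=tuple(zs.columns), glm=glm, n_components=k,
    )


# ---------------------------------------------------------------------------
# repeated-split model error


@dataclass(frozen=True)
class ModelErrorReport:
    per_run: pd.DataFrame  # columns: misclassification, log_loss
    mean_misclassification: float
    sd_misclassification: float
    mean_log_loss: float
    sd_log_loss: float


def regression_model_error(
    model_factory,
    x: pd.DataFrame,
    y,
    n_runs: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
) -> ModelErrorReport:
    """Held-out error over repeated stratified splits.

    ``model_factory()`` must return an unfitted estimator with ``fit`` and
    ``predict_proba`` (sklearn interface). Each run fits on a stratified
    ``train_frac`` subset and scores misclassification and log loss on the
    remainder; degenerate splits (a held-out class absent from training)
    are resampled with a logged note.
    """
    yv = np.asarray(pd.factorize(pd.Series(list(y)), sort=True)[0])
    xm = x.to_numpy(dtype=float)
    classes = np.unique(yv)
    if len(classes) < 2:
        raise InvalidParameterError("need at least 2 response categories")
    rng = np.random.default_rng(seed)
    rows = []
    done = 0
    attempts = 0
    while done < n_runs:
        attempts += 1
        if attempts > 20 * n_runs:
            raise InsufficientDataError("could not obtain non-degenerate splits")
        ss = StratifiedShuffleSplit(
            n_splits=1, train_size=train_frac, random_state=int(rng.integers(2**31 - 1))
        )
        (tr, te), = ss.split(xm, yv)
        if len(np.unique(yv[tr])) < len(classes):
            logger.info("degenerate split resampled (missing class in training)")
            continue
        model = model_factory()
        model.fit(xm[tr], yv[tr])
        proba = model.predict_proba(xm[te])
        pred = model.classes_[np.argmax(proba, axis=1)]
        mis = float(np.mean(pred != yv[te]))
        ll = float(log_loss(yv[te], proba, labels=model.classes_))
        rows.append({"misclassification": mis, "log_loss": ll})
        done += 1
    df = pd.DataFrame(rows)
    return ModelErrorReport(
        per_run=df,
        mean_misclassification=float(df.misclassification.mean()),
        sd_misclassification=float(df.misclassification.std(ddof=1)),
        mean_log_loss=float(df.log_loss.mean()),
        sd_log_loss=float(df.log_loss.std(ddof=1)),
    )


def default_logistic_factory():
    """Plain logistic model usable with :func:`regression_model_error`."""
    return LogisticRegression(max_iter=2000)
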