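"""Phylogenetic generalized least squares (PGLS) under Brownian motion.

Closely related species are not independent data points: under a Brownian
model of trait evolution the covariance between two tips equals the branch
length they share on their root-to-tip paths.  PGLS fits a linear model by
generalized least squares with that covariance, optionally shrunk towards
independence by Pagel's lambda (off-diagonal entries scaled by
lambda in [0, 1], estimable by maximum likelihood).

Trees are handled through dendropy; the covariance construction and the
GLS fit are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize, stats


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Every non-root edge must carry a finite branch length and tip labels
    must be unique.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise ValueError("tree contains unlabelled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length
        if bl is None or not math.isfinite(bl) or bl < 0:
            raise ValueError("every branch needs a finite non-negative length")
    return tree


def load_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_species(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    """Restrict a tree to the given tips.

    Unary internal nodes created by pruning are collapsed with their branch
    lengths summed, so path lengths among retained tips are preserved.
    """
    present = set(tip_labels(tree))
    kept = [k for k in keep if k in present]
    if not kept:
        raise ValueError("no requested species present in the tree")
    if len(kept) < 2:
        raise ValueError("degenerate tree: fewer than 2 tips would remain")
    pruned = tree.extract_tree_with_taxa_labels(kept)
    # collapse any remaining unary root produced by extraction
    pruned.suppress_unifurcations()
    return pruned


def bm_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance: shared root-to-tip branch length.

    C_ii is the depth of tip i; C_ij is the depth of the most recent common
    ancestor of i and j.  Returns (tip labels, covariance matrix) with rows
    in the returned label order.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    n = len(leaves)
    idx = {id(leaf): i for i, leaf in enumerate(leaves)}
    C = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        C[i, i] = leaf.root_distance
    # tips in different child subtrees of a node share that node's depth
    for node in tree.preorder_internal_node_iter():
        depth = node.root_distance or 0.0
        child_tip_sets = [
            [idx[id(lf)] for lf in child.leaf_iter()]
            for child in node.child_nodes()
        ]
        for a in range(len(child_tip_sets)):
            for b in range(a + 1, len(child_tip_sets)):
                for i in child_tip_sets[a]:
                    for j in child_tip_sets[b]:
                        C[i, j] = C[j, i] = depth
    return labels, C


@dataclass
class PGLSFit:
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sigma2: float
    lam: float
    log_likelihood: float
    n: int
    predictor_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.predictor_names, self.coefficients.tolist())),
            "std_errors": dict(zip(self.predictor_names, self.std_errors.tolist())),
            "t_values": dict(zip(self.predictor_names, self.t_values.tolist())),
            "p_values": dict(zip(self.predictor_names, self.p_values.tolist())),
            "sigma2": self.sigma2,
            "lambda": self.lam,
            "log_likelihood": self.log_likelihood,
            "n": self.n,
        }


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _cholesky(C: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * np.trace(C) / C.shape[0]
        return linalg.cholesky(C + jitter * np.eye(C.shape[0]), lower=True)


def _gls(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Whitened least squares; returns beta, rss, logdet(C), XtCiX_inv."""
    L = _cholesky(C)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet, np.linalg.inv(XtX)


def _loglik(y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    n = len(y)
    _, rss, logdet, _ = _gls(y, X, C)
    sigma2 = max(rss / n, 1e-300)  # guard exact fits
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def fit_pgls(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    lam: float | str = 1.0,
    predictor_names: Sequence[str] | None = None,
    add_intercept: bool = True,
) -> PGLSFit:
    """Fit y = X beta + e with cov(e) = sigma^2 C(lambda).

    ``lam`` may be a fixed value in [0, 1] or ``"ml"`` for a bounded
    maximum-likelihood search (tolerance 1e-6).  ``lam = 1`` is the pure
    Brownian model; ``lam = 0`` keeps only the diagonal of C (phylogenetic
    signal removed).  Inference uses the t distribution with n - p degrees
    of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    if C.shape != (n, n):
        raise ValueError("covariance does not match the number of tips")
    names = list(predictor_names) if predictor_names else [
        f"x{i}" for i in range(X.shape[1])
    ]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient predictor matrix")
    if n <= p:
        raise ValueError("need more tips than parameters")

    if lam == "ml":
        res = optimize.minimize_scalar(
            lambda l: -_loglik(y, X, _lambda_cov(C, l)),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam_hat = float(res.x)
        # the bounded optimum can hide a better boundary value
        for cand in (0.0, 1.0):
            if _loglik(y, X, _lambda_cov(C, cand)) > _loglik(
                y, X, _lambda_cov(C, lam_hat)
            ):
                lam_hat = cand
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    Cl = _lambda_cov(C, lam_hat)
    beta, rss, logdet, XtX_inv = _gls(y, X, Cl)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    pv = 2 * stats.t.sf(np.abs(t), df=n - p)
    return PGLSFit(
        coefficients=beta,
        std_errors=se,
        t_values=t,
        p_values=pv,
        sigma2=float(sigma2),
        lam=lam_hat,
        log_likelihood=_loglik(y, X, Cl),
        n=n,
        predictor_names=names,
    )
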