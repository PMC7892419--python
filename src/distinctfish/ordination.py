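"""Redundancy analysis (RDA) from first principles.

RDA is a constrained ordination: a multivariate linear regression of a
response matrix Y on predictors X followed by a principal component
analysis of the fitted values.  The share of Y's total variance captured
by the fitted values ("proportion constrained") is the headline
variance-explained figure of the three designs used here:

* spatial   — rows are grid cells; Y = log mean abundance of the common
  (Q1) and distinct (Q4) pools; X = time-averaged environment and effort.
* temporal  — rows are years; Y = log whole-system annual abundance of the
  two pools; X = spatially averaged annual environment/effort plus the
  basin-scale NAO and AMO indices.
* spatiotemporal — rows are cells; Y = the per-cell Spearman trend of each
  pool; X = time-averaged environment and effort.

Predictors measured on incommensurate scales (degC, m, hours, ...) are
standardized to unit variance; this leaves the constrained proportion
unchanged but stabilizes the biplot scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SPATIAL_PREDICTORS = ["sst_c", "sss_psu", "depth_m", "bstress", "pci", "effort_hours"]
TEMPORAL_PREDICTORS = ["sst_c", "sss_psu", "bstress", "pci", "effort_hours", "nao", "amo"]

#: relative singular-value cutoff for the rank-revealing fit
RANK_TOL = 1e-10
#: eigenvalues below this fraction of total variance are reported as zero
EIGEN_ZERO_TOL = 1e-12


@dataclass
class RDADesign:
    """Aligned response (Y) and predictor (X) matrices for one RDA."""

    row_ids: list
    Y: np.ndarray
    X: np.ndarray
    response_names: list[str]
    predictor_names: list[str]
    dropped_rows: list = field(default_factory=list)
    dropped_predictors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("Y and X disagree on row count")
        if len(self.row_ids) != self.Y.shape[0]:
            raise ValueError("row_ids length does not match Y")
        if not (np.all(np.isfinite(self.Y)) and np.all(np.isfinite(self.X))):
            raise ValueError("design contains missing or non-finite entries")


@dataclass
class RDAResult:
    eigenvalues: np.ndarray          # constrained, non-increasing
    residual_eigenvalues: np.ndarray
    proportion_constrained: float
    total_variance: float
    coefficients: pd.DataFrame       # predictors x responses (standardized X)
    site_scores: pd.DataFrame        # rows x axes
    response_scores: pd.DataFrame    # responses x axes
    biplot_scores: pd.DataFrame      # predictors x axes
    scaling: int
    rank: int

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "residual_eigenvalues": self.residual_eigenvalues.tolist(),
            "proportion_constrained": self.proportion_constrained,
            "total_variance": self.total_variance,
            "rank": self.rank,
            "scaling": self.scaling,
            "coefficients": self.coefficients.to_dict(),
            "site_scores": self.site_scores.to_dict(),
            "response_scores": self.response_scores.to_dict(),
            "biplot_scores": self.biplot_scores.to_dict(),
        }


def _drop_constant_predictors(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    for c in dropped:
        warnings.warn(f"predictor {c!r} is constant across rows; dropped")
    return X.drop(columns=dropped), dropped


def _pivot_responses(df: pd.DataFrame, index: str, value: str) -> pd.DataFrame:
    wide = df.pivot(index=index, columns="group", values=value)
    return wide.sort_index()


def build_spatial_design(series: pd.DataFrame, env: pd.DataFrame) -> RDADesign:
    """Cells x (log mean pool abundance | time-averaged predictors)."""
    mean_ab = (
        series.groupby(["group", "cell_id"], as_index=False)
        .agg(mean_total=("total_abundance", "mean"))
    )
    Y = _pivot_responses(mean_ab, "cell_id", "mean_total")
    Y = np.log1p(Y)
    Xmeans = env.groupby("cell_id")[SPATIAL_PREDICTORS].mean()
    return _assemble("cell", Y, Xmeans)


def build_temporal_design(series: pd.DataFrame, env: pd.DataFrame) -> RDADesign:
    """Years x (log annual pool abundance | annual mean predictors)."""
    annual = (
        series.groupby(["group", "year"], as_index=False)
        .agg(total=("total_abundance", "sum"))
    )
    Y = _pivot_responses(annual, "year", "total")
    Y = np.log1p(Y)
    Xmeans = env.groupby("year")[TEMPORAL_PREDICTORS].mean()
    return _assemble("year", Y, Xmeans)


def build_spatiotemporal_design(trends: pd.DataFrame, env: pd.DataFrame) -> RDADesign:
    """Cells x (per-cell pool trend rho | time-averaged predictors)."""
    usable = trends.dropna(subset=["rho"])
    Y = usable.pivot(index="cell_id", columns="group", values="rho").dropna()
    if len(Y) < 3:
        raise ValueError("fewer than 3 cells with defined trends for all groups")
    for col in Y.columns:
        if Y[col].nunique() <= 1:
            raise ValueError(f"degenerate response: trend of {col} constant")
    Xmeans = env.groupby("cell_id")[SPATIAL_PREDICTORS].mean()
    return _assemble("cell", Y, Xmeans)


def _assemble(row_kind: str, Y: pd.DataFrame, X: pd.DataFrame) -> RDADesign:
    common = Y.index.intersection(X.index)
    dropped = sorted(set(Y.index).symmetric_difference(X.index))
    if dropped:
        log.info("%d %s rows dropped (missing response or predictors)",
                 len(dropped), row_kind)
    Y = Y.loc[common]
    X = X.loc[common]
    keep = ~(Y.isna().any(axis=1) | X.isna().any(axis=1))
    dropped += sorted(common[~keep])
    Y, X = Y.loc[keep], X.loc[keep]
    X, dropped_pred = _drop_constant_predictors(X)
    return RDADesign(
        row_ids=list(Y.index),
        Y=Y.to_numpy(dtype=float),
        X=X.to_numpy(dtype=float),
        response_names=[str(c) for c in Y.columns],
        predictor_names=[str(c) for c in X.columns],
        dropped_rows=dropped,
        dropped_predictors=dropped_pred,
    )


def _standardize_X(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column; drop it before fitting")
    return (X - X.mean(axis=0)) / sd


def fit_rda(design: RDADesign, scaling: int = 2) -> RDAResult:
    """Fit the redundancy analysis.

    Y is centered; X is centered and scaled to unit variance.  The
    multivariate least-squares fit uses a rank-revealing SVD (pseudo-inverse
    on rank deficiency).  Constrained axes are the eigenvectors of
    cov(Y_hat) and residual axes those of cov(Y - Y_hat); eigenvalue sums
    conserve the total variance of centered Y.
    """
    if scaling not in (1, 2):
        raise ValueError("scaling must be 1 or 2")
    Y, X = design.Y, design.X
    n, q = Y.shape
    if np.all(Y.std(axis=0) == 0):
        raise ValueError("constant response matrix")
    Yc = Y - Y.mean(axis=0)
    Xs = _standardize_X(X)

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    rank = int(np.sum(s > RANK_TOL * s[0]))
    if rank < 1:
        raise ValueError("predictor matrix has rank 0")
    # centering absorbs one df, so rank == n - 1 already saturates the fit
    if n <= rank + 1:
        raise ValueError(
            f"n = {n} rows with predictor rank {rank}: the constrained "
            "proportion would be trivially 1; refuse to fit"
        )
    Ur = U[:, :rank]
    UtY = Ur.T @ Yc
    Yhat = Ur @ UtY
    B = (Vt[:rank].T / s[:rank]) @ UtY  # coefficients on standardized X

    total_var = float(np.sum(Yc * Yc) / (n - 1))
    lam_c, Vc = _sorted_eig(Yhat.T @ Yhat / (n - 1))
    lam_r, _ = _sorted_eig((Yc - Yhat).T @ (Yc - Yhat) / (n - 1))
    lam_c[lam_c < EIGEN_ZERO_TOL * total_var] = 0.0
    lam_r[lam_r < EIGEN_ZERO_TOL * total_var] = 0.0
    n_axes = min(rank, q)
    lam_c = lam_c[:n_axes]
    Vc = Vc[:, :n_axes]

    prop = float(lam_c.sum() / total_var) if total_var > 0 else 0.0

    site = Yhat @ Vc  # principal coordinates of the fitted values
    if scaling == 2:
        resp = Vc * np.sqrt(np.maximum(lam_c, 0.0))
    else:
        resp = Vc.copy()
    biplot = np.zeros((Xs.shape[1], n_axes))
    for a in range(n_axes):
        if site[:, a].std() > 0:
            for j in range(Xs.shape[1]):
                biplot[j, a] = np.corrcoef(Xs[:, j], site[:, a])[0, 1]

    axes = [f"RDA{a + 1}" for a in range(n_axes)]
    return RDAResult(
        eigenvalues=lam_c,
        residual_eigenvalues=lam_r,
        proportion_constrained=prop,
        total_variance=total_var,
        coefficients=pd.DataFrame(
            B, index=design.predictor_names, columns=design.response_names
        ),
        site_scores=pd.DataFrame(site, index=design.row_ids, columns=axes),
        response_scores=pd.DataFrame(
            resp, index=design.response_names, columns=axes
        ),
        biplot_scores=pd.DataFrame(
            biplot, index=design.predictor_names, columns=axes
        ),
        scaling=scaling,
        rank=rank,
    )


def _sorted_eig(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eigh(m)
    order = np.argsort(lam)[::-1]
    lam = np.maximum(lam[order], 0.0)
    return lam, vec[:, order]


def permutation_test_rda(
    design: RDADesign, n_perm: int = 999, seed: int = 0
) -> dict:
    """Permutation p-value for the constrained proportion.

    Rows of Y are permuted jointly; p = (1 + #{perm >= observed}) /
    (n_perm + 1).  The proportion only needs the squared projection of the
    (permuted) centered Y onto X's column space, so permutations are cheap.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y, X = design.Y, design.X
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Xs = _standardize_X(X)
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    rank = int(np.sum(s > RANK_TOL * s[0]))
    Ur = U[:, :rank]
    total = float(np.sum(Yc * Yc))
    if total == 0:
        raise ValueError("constant response matrix")

    def prop_of(Ym: np.ndarray) -> float:
        return float(np.sum((Ur.T @ Ym) ** 2) / total)

    observed = prop_of(Yc)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        Ym = Yc[rng.permutation(n)]
        if prop_of(Ym) >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return {"proportion_constrained": observed, "p_value": p, "n_perm": n_perm}
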