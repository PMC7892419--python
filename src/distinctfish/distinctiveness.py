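"""Functional distinctiveness: the Di index, quartile pools and trait tests.

Di of species i is its mean Gower dissimilarity to every other species in
the regional pool: Di = sum_{j != i} d_ij / (N - 1).  Because Gower
dissimilarities are bounded in [0, 1], Di is too.  Species are ranked by Di
and split into quartile groups; Q1 (lowest Di) holds the functionally
common species and Q4 (highest Di) the functionally distinct ones.

Trait-distinctiveness associations use Spearman rank correlations for
continuous traits and pairwise two-sided Wilcoxon rank-sum tests (with a
Holm correction across modality pairs) for categorical traits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import holm_adjust, spearman_test
from .traits import DissimilarityMatrix

GROUPS = ("Q1", "Q2", "Q3", "Q4")


def compute_distinctiveness(
    d: DissimilarityMatrix, rescale: str = "none"
) -> pd.DataFrame:
    """Compute Di and deterministic ranks from a dissimilarity matrix.

    Parameters
    ----------
    d : DissimilarityMatrix
    rescale : {"none", "max"}
        ``"max"`` divides every d_ij by the observed maximum before
        averaging, so the most dissimilar pair is exactly 1 apart.  The
        default relies on Gower's native [0, 1] bound and applies no
        rescaling.

    Returns
    -------
    DataFrame with columns ``species``, ``Di``, ``rank`` (1..N ascending
    Di, ties broken lexicographically by species id).
    """
    n = len(d.species_ids)
    if n < 2:
        raise ValueError("need >= 2 species")
    m = d.values
    if rescale == "max":
        mx = m.max()
        if mx > 0:
            m = m / mx
    elif rescale != "none":
        raise ValueError(f"unknown rescale mode {rescale!r}")
    di = m.sum(axis=1) / (n - 1)
    out = pd.DataFrame({"species": list(d.species_ids), "Di": di})
    order = np.lexsort((out["species"].to_numpy(), out["Di"].to_numpy()))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    out["rank"] = ranks
    return out


def assign_quartile_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``group`` column of a distinctiveness table.

    Q4 holds the ceil(N/4) species of highest Di and Q1 the ceil(N/4) of
    lowest Di (so a 130-species pool yields 33 distinct and 33 common
    species); the remainder is split at its median rank into Q2 (lower
    half, rounded up) and Q3.
    """
    n = len(table)
    if n < 4:
        raise ValueError("need >= 4 species for quartile groups")
    if table["rank"].sort_values().tolist() != list(range(1, n + 1)):
        raise ValueError("ranks must be a permutation of 1..N")
    k = math.ceil(n / 4)
    mid = n - 2 * k
    q2 = math.ceil(mid / 2)
    out = table.copy()
    r = out["rank"].to_numpy()
    group = np.empty(n, dtype=object)
    group[r <= k] = "Q1"
    group[(r > k) & (r <= k + q2)] = "Q2"
    group[(r > k + q2) & (r <= n - k)] = "Q3"
    group[r > n - k] = "Q4"
    out["group"] = group
    return out


def membership(table: pd.DataFrame) -> dict[str, str]:
    """species -> quartile group mapping from a grouped table."""
    if "group" not in table.columns:
        raise ValueError("table has no group column; call assign_quartile_groups")
    return dict(zip(table["species"], table["group"]))


@dataclass
class AssociationResult:
    """Outcome of one trait-distinctiveness association test."""

    trait: str
    kind: str  # "spearman" | "pairwise_wilcoxon"
    statistics: list[float]
    p_values: list[float]
    p_adjusted: list[float]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    n: int = 0
    method: str = ""
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "kind": self.kind,
            "statistics": self.statistics,
            "p_values": self.p_values,
            "p_adjusted": self.p_adjusted,
            "pairs": [list(p) for p in self.pairs],
            "n": self.n,
            "method": self.method,
            "warnings": self.warnings,
        }


def continuous_trait_association(
    table: pd.DataFrame, values: Mapping[str, float] | pd.Series, trait: str = ""
) -> AssociationResult:
    """Spearman correlation between a continuous trait and Di.

    Species with a missing trait value are dropped pairwise; at least five
    complete pairs are required.
    """
    v = pd.Series(values).reindex(table["species"]).to_numpy(dtype=float)
    di = table["Di"].to_numpy(dtype=float)
    ok = np.isfinite(v) & np.isfinite(di)
    if ok.sum() < 5:
        raise ValueError(f"trait {trait!r}: fewer than 5 complete pairs")
    rho, p, method = spearman_test(v[ok], di[ok])
    return AssociationResult(
        trait=trait,
        kind="spearman",
        statistics=[rho],
        p_values=[p],
        p_adjusted=[p],
        n=int(ok.sum()),
        method=method,
    )


def categorical_trait_association(
    table: pd.DataFrame,
    values: Mapping[str, str] | pd.Series,
    trait: str = "",
) -> AssociationResult:
    """All pairwise Wilcoxon rank-sum tests of Di between trait modalities.

    Modalities represented by fewer than two species are excluded (a
    warning is recorded); p-values are Holm-adjusted across modality pairs.
    The null distribution is exact when both groups have <= 10 members and
    the pooled Di values carry no ties, and a normal approximation
    otherwise.
    """
    v = pd.Series(values).reindex(table["species"])
    di = pd.Series(table["Di"].to_numpy(), index=table["species"])
    warn: list[str] = []
    groups: dict[str, np.ndarray] = {}
    for mod, sub in di.groupby(v):
        vals = sub.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            warn.append(f"modality {mod!r} excluded (<2 species)")
            continue
        groups[str(mod)] = vals
    if len(groups) < 2:
        raise ValueError(
            f"trait {trait!r}: fewer than 2 usable modalities"
        )
    mods = sorted(groups)
    pairs, statistics, pvals, methods = [], [], [], []
    for i in range(len(mods)):
        for j in range(i + 1, len(mods)):
            a, b = groups[mods[i]], groups[mods[j]]
            pooled = np.concatenate([a, b])
            exact = (
                len(a) <= 10
                and len(b) <= 10
                and len(np.unique(pooled)) == len(pooled)
            )
            method = "exact" if exact else "asymptotic"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.mannwhitneyu(
                    a, b, alternative="two-sided", method=method
                )
            pairs.append((mods[i], mods[j]))
            statistics.append(float(res.statistic))
            pvals.append(float(res.pvalue))
            methods.append(method)
    return AssociationResult(
        trait=trait,
        kind="pairwise_wilcoxon",
        statistics=statistics,
        p_values=pvals,
        p_adjusted=holm_adjust(pvals),
        pairs=pairs,
        n=int(sum(len(g) for g in groups.values())),
        method=",".join(sorted(set(methods))),
        warnings=warn,
    )


def write_distinctiveness_tsv(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("species", "Di", "rank", "group") if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)
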