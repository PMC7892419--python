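"""Extinction risk and fishing-vulnerability tests.

Species carry an IUCN Red List category (CR, EN, VU, NT, LC, DD, NE; the
first three are "threatened") and a published 0-100 intrinsic vulnerability
to fishing.  This module compares the composition of Red List categories
between distinctiveness pools (chi-square homogeneity), correlates
distinctiveness with vulnerability (Spearman) and reports threatened
fractions per pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import spearman_test

IUCN_CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD", "NE")
THREATENED = frozenset({"CR", "EN", "VU"})


def load_status_table(path: str | Path) -> pd.DataFrame:
    """Read the species status CSV (``species,iucn,vulnerability``)."""
    df = pd.read_csv(path)
    for col in ("species", "iucn", "vulnerability"):
        if col not in df.columns:
            raise ValueError(f"status table: missing column {col!r}")
    bad = set(df["iucn"].dropna()) - set(IUCN_CATEGORIES)
    if bad:
        raise ValueError(f"status table: unknown IUCN categories {sorted(bad)}")
    v = df["vulnerability"].to_numpy(dtype=float)
    ok = np.isfinite(v)
    if np.any((v[ok] < 0) | (v[ok] > 100)):
        raise ValueError("status table: vulnerability must lie in [0, 100]")
    if df["species"].duplicated().any():
        raise ValueError("status table: duplicate species ids")
    return df[["species", "iucn", "vulnerability"]].copy()


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: int | None = None
    effect: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "effect": self.effect,
            "warnings": self.warnings,
        }


def chi_square_homogeneity(
    groups: Mapping[str, str], statuses: pd.DataFrame
) -> TestResult:
    """Pearson chi-square on the group x IUCN-category table.

    No continuity correction; categories absent from every group are
    dropped (reducing df); a warning is attached when any expected count
    falls below 5.
    """
    status_of = dict(zip(statuses["species"], statuses["iucn"]))
    rows = [
        {"group": g, "iucn": status_of[sp]}
        for sp, g in groups.items()
        if sp in status_of and pd.notna(status_of[sp])
    ]
    if not rows:
        raise ValueError("no classified species in any group")
    tab = pd.crosstab(
        pd.Series([r["group"] for r in rows], name="group"),
        pd.Series([r["iucn"] for r in rows], name="iucn"),
    )
    empty_groups = set(groups.values()) - set(tab.index)
    if empty_groups:
        raise ValueError(f"groups with zero classified species: {sorted(empty_groups)}")
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2 or tab.shape[0] < 2:
        raise ValueError("contingency table needs >= 2 groups and >= 2 categories")
    chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    warn = []
    if (expected < 5).any():
        warn.append("some expected counts < 5; chi-square approximation is rough")
    props = (tab.T / tab.sum(axis=1)).T
    return TestResult(
        test="chi_square_homogeneity",
        statistic=float(chi2),
        p_value=float(p),
        df=int(dof),
        effect={"proportions": {g: props.loc[g].to_dict() for g in props.index},
                "counts": {g: tab.loc[g].to_dict() for g in tab.index}},
        warnings=warn,
    )


def vulnerability_correlation(
    di_table: pd.DataFrame, statuses: pd.DataFrame
) -> TestResult:
    """Spearman correlation of Di with the fishing-vulnerability score."""
    merged = di_table.merge(statuses, on="species", how="inner")
    v = merged["vulnerability"].to_numpy(dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 5:
        raise ValueError("fewer than 5 species with vulnerability scores")
    rho, p, method = spearman_test(merged.loc[ok, "Di"].to_numpy(), v[ok])
    return TestResult(
        test="spearman_vulnerability",
        statistic=rho,
        p_value=p,
        effect={"n": int(ok.sum()), "n_missing": int((~ok).sum()),
                "method": method},
    )


def threatened_proportion(
    members: Iterable[str], statuses: pd.DataFrame
) -> float:
    """Fraction of pool members whose IUCN category is CR, EN or VU.

    The denominator is the full pool, data-deficient and not-evaluated
    species included.
    """
    members = list(members)
    if not members:
        raise ValueError("empty group")
    status_of = dict(zip(statuses["species"], statuses["iucn"]))
    hits = sum(1 for sp in members if status_of.get(sp) in THREATENED)
    return hits / len(members)
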