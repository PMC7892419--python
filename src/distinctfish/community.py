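"""Survey aggregation by distinctiveness group and temporal trend detection.

The survey is a long table of standardized abundances (individuals per
km^2) per species, grid cell and year; a record that is absent means the
species was not caught (abundance 0).  Group-level richness and total
abundance are computed per cell-year, averaged over time for maps, summed
over space for whole-system annual series, and turned into per-cell and
per-species temporal trends via Spearman rank correlations of abundance
against calendar year.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SURVEY_COLUMNS = ["species", "cell_id", "lat", "lon", "year", "abundance_per_km2"]
ENV_COLUMNS = [
    "cell_id",
    "year",
    "sst_c",
    "sss_psu",
    "depth_m",
    "bstress",
    "pci",
    "effort_hours",
    "nao",
    "amo",
]

#: minimum number of years a series needs before a trend is computed
MIN_TREND_YEARS = 3


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def load_survey_table(path: str | Path) -> pd.DataFrame:
    """Load and validate the long-format survey CSV."""
    df = pd.read_csv(path)
    _check_columns(df, SURVEY_COLUMNS, "survey table")
    df = df[SURVEY_COLUMNS].copy()
    ab = df["abundance_per_km2"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ab)) or np.any(ab < 0):
        raise ValueError("survey table: abundances must be finite and >= 0")
    key = ["species", "cell_id", "year"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"survey table: duplicate record for key {first}")
    df["year"] = df["year"].astype(int)
    return df


def load_env_table(path: str | Path) -> pd.DataFrame:
    """Load and validate the per-cell-year environment/effort CSV."""
    df = pd.read_csv(path)
    _check_columns(df, ENV_COLUMNS, "environment table")
    df = df[ENV_COLUMNS].copy()
    if np.any(df["effort_hours"].to_numpy(dtype=float) < 0):
        raise ValueError("environment table: effort_hours must be >= 0")
    dup = df.duplicated(subset=["cell_id", "year"])
    if dup.any():
        first = df.loc[dup, ["cell_id", "year"]].iloc[0].tolist()
        raise ValueError(f"environment table: duplicate record for key {first}")
    df["year"] = df["year"].astype(int)
    return df


def group_site_year_metrics(
    cube: pd.DataFrame,
    member_of: Mapping[str, str],
    groups: Sequence[str] = ("Q1", "Q4"),
) -> pd.DataFrame:
    """Per (group, cell, year) species richness and total abundance.

    Richness counts member species with strictly positive abundance; total
    abundance sums member abundances.  Every (cell, year) combination that
    was surveyed appears for every requested group, with zeros when no
    member was caught.  Species in the cube but absent from ``member_of``
    are ignored (their count is logged).
    """
    species_in_cube = set(cube["species"].unique())
    unassigned = species_in_cube - set(member_of)
    if unassigned:
        log.info("%d survey species have no group assignment", len(unassigned))
    if not (species_in_cube & set(member_of)):
        raise ValueError("no survey species has a group assignment")

    surveyed = cube[["cell_id", "year"]].drop_duplicates()
    frames = []
    for g in groups:
        members = {s for s, grp in member_of.items() if grp == g}
        sub = cube[cube["species"].isin(members)]
        agg = (
            sub.groupby(["cell_id", "year"], as_index=False)
            .agg(
                richness=("abundance_per_km2", lambda a: int((a > 0).sum())),
                total_abundance=("abundance_per_km2", "sum"),
            )
        )
        full = surveyed.merge(agg, on=["cell_id", "year"], how="left")
        full["richness"] = full["richness"].fillna(0).astype(int)
        full["total_abundance"] = full["total_abundance"].fillna(0.0)
        full.insert(0, "group", g)
        frames.append(full)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "cell_id", "year"], ignore_index=True)


def spatial_mean_map(series: pd.DataFrame) -> pd.DataFrame:
    """Time-averaged richness and total abundance per (group, cell).

    Averages run over the years actually surveyed in each cell, so unequal
    year coverage across cells is handled naturally.
    """
    if series.empty:
        raise ValueError("empty group series")
    out = (
        series.groupby(["group", "cell_id"], as_index=False)
        .agg(
            mean_richness=("richness", "mean"),
            mean_total_abundance=("total_abundance", "mean"),
            n_years=("year", "nunique"),
        )
    )
    return out


def northsea_annual_totals(series: pd.DataFrame) -> pd.DataFrame:
    """Whole-system annual abundance per group (summed over cells)."""
    out = (
        series.groupby(["group", "year"], as_index=False)
        .agg(total_abundance=("total_abundance", "sum"))
    )
    return out.sort_values(["group", "year"], ignore_index=True)


def log_abundance(a: np.ndarray | pd.Series) -> np.ndarray:
    """Natural log of (abundance + 1): keeps zero catches finite."""
    return np.log1p(np.asarray(a, dtype=float))


def _spearman_vs_year(values: np.ndarray, years: np.ndarray):
    if len(np.unique(values)) == 1:
        return np.nan, "constant"
    rho = stats.spearmanr(values, years).statistic
    return float(rho), ""


def per_cell_trend(
    series: pd.DataFrame, min_years: int = MIN_TREND_YEARS
) -> pd.DataFrame:
    """Spearman trend of log abundance against year within each cell.

    Cells with fewer than ``min_years`` surveyed years are skipped (and
    logged); constant series keep their row with a missing rho and reason
    ``"constant"``.  Because Spearman is a rank statistic the log transform
    does not change rho; it is applied for consistency with the ordination
    responses.
    """
    rows = []
    skipped = 0
    for (g, cell), sub in series.groupby(["group", "cell_id"]):
        sub = sub.sort_values("year")
        if sub["year"].nunique() < min_years:
            skipped += 1
            continue
        rho, reason = _spearman_vs_year(
            log_abundance(sub["total_abundance"]), sub["year"].to_numpy()
        )
        rows.append(
            {
                "group": g,
                "cell_id": cell,
                "rho": rho,
                "n_years": int(sub["year"].nunique()),
                "reason": reason,
            }
        )
    if skipped:
        log.info("%d (group, cell) series skipped: fewer than %d years",
                 skipped, min_years)
    return pd.DataFrame(rows, columns=["group", "cell_id", "rho", "n_years", "reason"])


def per_species_trend(
    cube: pd.DataFrame,
    species: Iterable[str],
    min_years: int = MIN_TREND_YEARS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Trend of each species' annual summed abundance, plus a rebound tally.

    Returns a table (species, rho, n_years) and a summary counting species
    with rho > 0 (increased) and rho < 0 (declined); species whose trend is
    undefined (absent, too few years, or constant) are excluded from both
    counts.
    """
    species = list(species)
    all_years = np.sort(cube["year"].unique())
    annual = (
        cube[cube["species"].isin(species)]
        .groupby(["species", "year"], as_index=False)
        .agg(total=("abundance_per_km2", "sum"))
    )
    rows = []
    for sp in species:
        sub = annual[annual["species"] == sp]
        n_obs = int((sub["total"] > 0).sum())
        if n_obs < min_years or len(all_years) < min_years:
            # too sparse a presence record to call a trend
            rows.append({"species": sp, "rho": np.nan, "n_years": n_obs})
            continue
        totals = (
            sub.set_index("year")["total"].reindex(all_years, fill_value=0.0)
        )
        rho, _ = _spearman_vs_year(log_abundance(totals), all_years)
        rows.append({"species": sp, "rho": rho, "n_years": n_obs})
    table = pd.DataFrame(rows)
    defined = table["rho"].dropna()
    summary = {
        "increased": int((defined > 0).sum()),
        "declined": int((defined < 0).sum()),
        "undefined": int(table["rho"].isna().sum() + (defined == 0).sum()),
    }
    return table, summary
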