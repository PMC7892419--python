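"""Mixed-type trait tables and the Gower dissimilarity matrix.

A regional species pool is described by a handful of continuous traits
(trophic level, age and size at maturity, fecundity, offspring size) and
categorical traits (water-column position, diet, parental care).  Gower's
coefficient is the standard dissimilarity for such mixed data: continuous
traits contribute range-standardized absolute differences, categorical
traits contribute simple mismatch indicators, and the per-trait terms are
averaged with weights over the traits observed in *both* species of a pair
(pairwise deletion of missing values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: strings that denote a missing cell in trait CSV files
_NA_STRINGS = {"", "NA"}


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of a single trait column.

    Parameters
    ----------
    name : str
        Column name in the trait CSV.
    kind : {"continuous", "categorical"}
    modalities : tuple of str
        Allowed labels; required (>= 2) for categorical traits.
    weight : float
        Non-negative Gower weight, default 1 (unweighted analysis).
    """

    name: str
    kind: str
    modalities: tuple[str, ...] = ()
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"trait {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.modalities) < 2:
            raise ValueError(
                f"categorical trait {self.name!r} needs >= 2 modalities"
            )
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"trait {self.name!r}: weight must be >= 0")


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of :class:`TraitSpec` records."""

    traits: tuple[TraitSpec, ...]

    def __post_init__(self) -> None:
        if len(self.traits) == 0:
            raise ValueError("schema declares no traits")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in schema")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    def __getitem__(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    @classmethod
    def from_json(cls, path: str | Path) -> "TraitSchema":
        doc = json.loads(Path(path).read_text())
        specs = tuple(
            TraitSpec(
                name=rec["name"],
                kind=rec["kind"],
                modalities=tuple(rec.get("modalities", ())),
                weight=float(rec.get("weight", 1.0)),
            )
            for rec in doc["traits"]
        )
        return cls(specs)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "traits": [
                {
                    "name": t.name,
                    "kind": t.kind,
                    "modalities": list(t.modalities),
                    "weight": t.weight,
                }
                for t in self.traits
            ]
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


@dataclass
class TraitTable:
    """Validated species x trait values.

    ``data`` is a DataFrame indexed by species id, one column per trait.
    Continuous columns are float (NaN = missing); categorical columns are
    object (None = missing).
    """

    species_ids: list[str]
    data: pd.DataFrame
    schema: TraitSchema = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.schema is not None:
            _validate_trait_table(self.species_ids, self.data, self.schema)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


def _validate_trait_table(
    species_ids: Sequence[str], data: pd.DataFrame, schema: TraitSchema
) -> None:
    if len(set(species_ids)) != len(species_ids):
        dupes = pd.Index(species_ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise ValueError(f"duplicate species ids: {dupes}")
    missing_cols = [n for n in schema.names if n not in data.columns]
    if missing_cols:
        raise ValueError(f"trait columns absent from table: {missing_cols}")
    for spec in schema.traits:
        col = data[spec.name]
        if spec.kind == CATEGORICAL:
            allowed = set(spec.modalities)
            for sp, v in col.items():
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                if v not in allowed:
                    raise ValueError(
                        f"species {sp!r}: value {v!r} is not a declared "
                        f"modality of trait {spec.name!r}"
                    )
    obs = pd.DataFrame(
        {
            t.name: data[t.name].notna()
            if schema[t.name].kind == CONTINUOUS
            else data[t.name].map(lambda v: v is not None and v == v)
            for t in schema.traits
        }
    )
    all_missing = obs.index[~obs.any(axis=1)]
    if len(all_missing):
        raise ValueError(
            f"species with every trait missing: {sorted(all_missing)}"
        )


def load_trait_table(path: str | Path, schema: TraitSchema) -> TraitTable:
    """Read a trait CSV (``species,<trait names...>``) and validate it.

    Empty cells or the literal ``NA`` denote missing values.  Raises
    ``ValueError`` on duplicate species ids, undeclared categorical
    modalities, non-numeric values in continuous columns, or species with
    every trait missing.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.columns[0] != "species":
        raise ValueError("first CSV column must be 'species'")
    species = raw["species"].tolist()
    cols: dict[str, object] = {}
    for spec in schema.traits:
        if spec.name not in raw.columns:
            raise ValueError(f"trait column {spec.name!r} absent from CSV")
        vals = raw[spec.name].str.strip()
        if spec.kind == CONTINUOUS:
            parsed = []
            for sp, v in zip(species, vals):
                if v in _NA_STRINGS:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(v))
                except ValueError:
                    raise ValueError(
                        f"species {sp!r}: non-numeric value {v!r} in "
                        f"continuous trait {spec.name!r}"
                    ) from None
            cols[spec.name] = np.asarray(parsed, dtype=float)
        else:
            cols[spec.name] = [None if v in _NA_STRINGS else v for v in vals]
    data = pd.DataFrame(cols, index=pd.Index(species, name="species"))
    return TraitTable(species_ids=species, data=data, schema=schema)


@dataclass
class DissimilarityMatrix:
    """Symmetric species x species Gower dissimilarities in [0, 1]."""

    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.nanmin(d) < -1e-12 or np.nanmax(d) > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")
        self.values = d

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values, index=self.species_ids, columns=self.species_ids
        )
        df.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def _observed_mask(col: pd.Series, kind: str) -> np.ndarray:
    if kind == CONTINUOUS:
        return np.isfinite(col.to_numpy(dtype=float))
    return np.array(
        [v is not None and v == v for v in col.to_numpy(dtype=object)]
    )


def gower_matrix(
    traits: TraitTable, schema: TraitSchema | None = None
) -> DissimilarityMatrix:
    """Gower dissimilarity over the species pool.

    d_ij = sum_t w_t * delta_t(i, j) / sum_t w_t, the sums running over
    traits observed in both species.  Continuous traits use
    |x_it - x_jt| / range_t with the range taken over the pool's observed
    values; categorical traits use a 0/1 mismatch.  A continuous trait whose
    pool range is zero carries no information and is excluded from both the
    numerator and the weight sum.
    """
    schema = schema if schema is not None else traits.schema
    if schema is None:
        raise ValueError("no trait schema supplied")
    n = traits.n_species
    if n < 2:
        raise ValueError("need >= 2 species to compute dissimilarities")

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for spec in schema.traits:
        if spec.weight == 0:
            continue
        col = traits.data[spec.name]
        obs = _observed_mask(col, spec.kind)
        if obs.sum() == 0:
            continue
        both = obs[:, None] & obs[None, :]
        if spec.kind == CONTINUOUS:
            x = col.to_numpy(dtype=float)
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                # constant trait: zero information for every pair
                continue
            with np.errstate(invalid="ignore"):
                delta = np.abs(x[:, None] - x[None, :]) / rng
            delta = np.where(both, delta, 0.0)
        else:
            vals = col.to_numpy(dtype=object)
            delta = np.where(both, (vals[:, None] != vals[None, :]), 0.0)
        num += spec.weight * delta
        den += spec.weight * both

    uncovered = (den == 0) & ~np.eye(n, dtype=bool)
    if uncovered.any():
        i, j = np.argwhere(uncovered)[0]
        raise ValueError(
            f"species pair ({traits.species_ids[i]!r}, "
            f"{traits.species_ids[j]!r}) shares no observed informative trait"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(list(traits.species_ids), d)
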