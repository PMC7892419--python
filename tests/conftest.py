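import numpy as np
import pandas as pd
import pytest

from distinctfish.traits import (
    CATEGORICAL,
    CONTINUOUS,
    TraitSchema,
    TraitSpec,
    TraitTable,
)


@pytest.fixture
def mixed_schema() -> TraitSchema:
    return TraitSchema(
        (
            TraitSpec("TL", CONTINUOUS),
            TraitSpec("position", CATEGORICAL, ("demersal", "pelagic")),
        )
    )


@pytest.fixture
def three_species_table(mixed_schema) -> TraitTable:
    """One continuous trait (range 2) and one categorical trait."""
    data = pd.DataFrame(
        {
            "TL": [3.0, 4.0, 5.0],
            "position": ["demersal", "pelagic", "demersal"],
        },
        index=pd.Index(["a", "b", "c"], name="species"),
    )
    return TraitTable(["a", "b", "c"], data, mixed_schema)


def random_mixed_table(rng, n_species=None, n_traits=None, p_missing=0.1):
    """Random mixed trait table + schema for oracle comparisons."""
    n_species = n_species or rng.integers(3, 21)
    n_traits = n_traits or rng.integers(2, 7)
    specs, cols = [], {}
    ids = [f"s{i:02d}" for i in range(n_species)]
    for t in range(n_traits):
        name = f"t{t}"
        if rng.random() < 0.5:
            specs.append(TraitSpec(name, CONTINUOUS))
            x = rng.normal(size=n_species) * rng.uniform(0.5, 20)
            x[rng.random(n_species) < p_missing] = np.nan
            cols[name] = x
        else:
            mods = tuple(f"m{k}" for k in range(rng.integers(2, 5)))
            specs.append(TraitSpec(name, CATEGORICAL, mods))
            v = rng.choice(mods, size=n_species).astype(object)
            v[rng.random(n_species) < p_missing] = None
            cols[name] = v
    data = pd.DataFrame(cols, index=pd.Index(ids, name="species"))
    # guarantee every species keeps one observed trait and every pair overlaps
    anchor = "t0"
    if isinstance(cols[anchor], np.ndarray) and cols[anchor].dtype != object:
        x = data[anchor].to_numpy(dtype=float)
        x[~np.isfinite(x)] = 0.0
        data[anchor] = x
    else:
        data[anchor] = [v if v is not None else "m0" for v in data[anchor]]
    schema = TraitSchema(tuple(specs))
    return TraitTable(ids, data, schema), schema


def brute_force_gower(table: TraitTable, schema: TraitSchema) -> np.ndarray:
    """Independent oracle: explicit loop over species pairs and traits."""
    n = table.n_species
    ranges = {}
    for spec in schema.traits:
        if spec.kind == CONTINUOUS:
            x = table.data[spec.name].to_numpy(dtype=float)
            obs = x[np.isfinite(x)]
            ranges[spec.name] = obs.max() - obs.min() if len(obs) else 0.0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0.0
            for spec in schema.traits:
                vi = table.data[spec.name].iloc[i]
                vj = table.data[spec.name].iloc[j]
                if spec.kind == CONTINUOUS:
                    if not (np.isfinite(vi) and np.isfinite(vj)):
                        continue
                    if ranges[spec.name] == 0:
                        continue
                    delta = abs(vi - vj) / ranges[spec.name]
                else:
                    if vi is None or vj is None:
                        continue
                    delta = float(vi != vj)
                num += spec.weight * delta
                den += spec.weight
            d[i, j] = num / den
    return d
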