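"""Seeded synthetic scenarios for the whole analysis chain.

The generator emulates the statistical structure of a North Sea-style
bottom-trawl monitoring programme and its companion databases:

* a 130-species pool drawn from two life-history archetypes -- a
  K-selected "distinct" archetype (late maturity, few large offspring,
  high trophic level, parental care, mostly pelagic/benthopelagic) and an
  r-selected "common" archetype (early maturity, many small offspring,
  demersal, benthivorous, little care);
* a 154-cell grid of 1 deg lon x 0.5 deg lat rectangles surveyed for 33
  years, with north-south gradients (the north deeper, colder, more
  saline, less productive, less trawled) and secular change (warming SST,
  declining trawling effort);
* abundances whose expected log values respond to the environment and to
  effort with archetype-specific coefficients, plus archetype-specific
  year trends (a planted "rebound") and multiplicative log-normal noise;
* a Yule phylogeny over a subset of the pool and a status table whose
  vulnerability scores and threatened categories are tilted towards the
  distinct archetype.

All randomness flows from a single integer seed through fixed substreams,
so adding one generator never perturbs another's draws and equal seeds
give byte-identical exports.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .traits import CATEGORICAL, CONTINUOUS, TraitSchema, TraitSpec, TraitTable

# substream offsets (arbitrary, fixed)
_S_TRAITS, _S_ENV, _S_SURVEY, _S_PHYLO, _S_STATUS = 11, 23, 37, 53, 71

ARCHETYPES = ("common", "distinct")

#: log-scale means and sds of the continuous traits per archetype
DEFAULT_TRAIT_MEANS = {
    "trophic_level": {"common": 3.2, "distinct": 4.3},
    "age_maturity_y": {"common": 2.2, "distinct": 9.0},
    "size_maturity_cm": {"common": 21.0, "distinct": 90.0},
    "fecundity": {"common": 2.0e5, "distinct": 70.0},
    "offspring_size_mm": {"common": 1.3, "distinct": 32.0},
}
DEFAULT_TRAIT_SIGMA = {  # sd of log values
    "trophic_level": 0.08,
    "age_maturity_y": 0.30,
    "size_maturity_cm": 0.30,
    "fecundity": 1.00,
    "offspring_size_mm": 0.45,
}
DEFAULT_CAT_PROBS = {
    "position": {
        "modalities": ("demersal", "benthopelagic", "pelagic", "reef"),
        "common": (0.70, 0.15, 0.10, 0.05),
        "distinct": (0.05, 0.35, 0.45, 0.15),
    },
    "diet": {
        "modalities": ("benthivorous", "piscivorous", "planktivorous", "generalist"),
        "common": (0.60, 0.10, 0.15, 0.15),
        "distinct": (0.05, 0.70, 0.10, 0.15),
    },
    "parental_care": {
        "modalities": ("none", "low", "high"),
        "common": (0.65, 0.30, 0.05),
        "distinct": (0.10, 0.20, 0.70),
    },
}

#: archetype response coefficients on standardized env/effort features
DEFAULT_COEFS = {
    "common": {
        "depth_m": -0.80,
        "sst_c": 0.50,
        "sss_psu": -0.20,
        "pci": 0.30,
        "bstress": 0.20,
        "effort_hours": 0.40,
    },
    "distinct": {
        "depth_m": 0.80,
        "sst_c": -0.50,
        "sss_psu": 0.20,
        "pci": -0.20,
        "bstress": -0.20,
        "effort_hours": -0.60,
    },
}


@dataclass
class SynthConfig:
    """Knobs of one synthetic scenario (defaults emulate the study system)."""

    seed: int = 0
    n_common: int = 97
    n_distinct: int = 33
    n_lat: int = 14            # 14 x 11 = 154 grid cells
    n_lon: int = 11
    n_years: int = 33
    first_year: int = 1983
    lat_min: float = 51.0      # degrees North; rows step 0.5 deg
    lon_min: float = -2.0      # degrees East; columns step 1 deg
    # environment: value = intercept + lat_slope * (lat - lat_min) [+ trend]
    depth_intercept: float = 25.0
    depth_lat_slope: float = 14.0      # north deeper
    depth_noise: float = 6.0
    sst_intercept: float = 10.5
    sst_lat_slope: float = -0.35       # north colder
    sst_warming_per_year: float = 0.06
    sst_noise: float = 0.35
    sss_intercept: float = 33.3
    sss_lat_slope: float = 0.18        # north more saline
    sss_noise: float = 0.12
    pci_intercept: float = 2.3
    pci_lat_slope: float = -0.13       # south more productive
    pci_noise: float = 0.15
    bstress_intercept: float = 0.95
    bstress_lat_slope: float = -0.055  # south more bottom stress
    bstress_noise: float = 0.05
    effort_log_base: float = 8.0       # log trawling hours in the far south
    effort_lat_decay: float = 0.28     # per degree latitude
    effort_decline_per_year: float = 0.045
    effort_noise: float = 0.20
    amo_trend_per_year: float = 0.015
    # abundance model
    base_log_abundance: dict = field(
        default_factory=lambda: {"common": 5.2, "distinct": 4.2}
    )
    base_log_sd: float = 0.8
    coefs: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_COEFS.items()
    })
    trend_mean: dict = field(
        default_factory=lambda: {"common": 0.050, "distinct": 0.035}
    )
    trend_sd: dict = field(
        default_factory=lambda: {"common": 0.030, "distinct": 0.045}
    )
    abund_noise_sd: float = 0.5
    detection_threshold: float = 0.5
    # traits
    trait_means: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TRAIT_MEANS.items()
    })
    trait_sigma: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SIGMA))
    cat_probs: dict = field(default_factory=lambda: {
        k: {kk: tuple(vv) if isinstance(vv, (tuple, list)) else vv
            for kk, vv in v.items()}
        for k, v in DEFAULT_CAT_PROBS.items()
    })
    # phylogeny and status
    n_phylo_tips: int = 93
    vuln_intercept: float = 33.0
    vuln_effect: float = 6.0       # shift for the distinct archetype
    vuln_noise: float = 15.0
    threat_midpoint: float = 66.0  # vulnerability at 50% of max threat prob
    threat_scale: float = 8.0
    threat_max_prob: float = 0.45
    threat_archetype_boost: float = 0.18  # extra threat prob, distinct pool

    def __post_init__(self) -> None:
        if self.n_common < 2 or self.n_distinct < 2:
            raise ValueError("each archetype needs >= 2 species")
        for attr in ("n_lat", "n_lon", "n_years"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be positive")

    @property
    def n_species(self) -> int:
        return self.n_common + self.n_distinct

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @classmethod
    def small(cls, seed: int = 0) -> "SynthConfig":
        """Fast preset for tests: 20 species, 12 cells, 10 years."""
        return cls(
            seed=seed, n_common=15, n_distinct=5, n_lat=4, n_lon=3,
            n_years=10, n_phylo_tips=15,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), stream])
    )


def default_trait_schema() -> TraitSchema:
    specs = [
        TraitSpec(name, CONTINUOUS) for name in DEFAULT_TRAIT_MEANS
    ] + [
        TraitSpec(name, CATEGORICAL, modalities=tuple(rec["modalities"]))
        for name, rec in DEFAULT_CAT_PROBS.items()
    ]
    return TraitSchema(tuple(specs))


def simulate_traits(config: SynthConfig) -> tuple[TraitTable, TraitSchema, dict]:
    """Draw the species pool's trait table and its archetype ground truth."""
    rng = _rng(config, _S_TRAITS)
    n = config.n_species
    ids = [f"sp{i + 1:03d}" for i in range(n)]
    arch = np.array(
        ["common"] * config.n_common + ["distinct"] * config.n_distinct
    )
    rng.shuffle(arch)
    is_distinct = arch == "distinct"

    cols: dict[str, object] = {}
    for trait, means in config.trait_means.items():
        mu = np.where(
            is_distinct, np.log(means["distinct"]), np.log(means["common"])
        )
        cols[trait] = np.exp(rng.normal(mu, config.trait_sigma[trait]))
    for trait, rec in config.cat_probs.items():
        mods = list(rec["modalities"])
        vals = np.empty(n, dtype=object)
        for g in ARCHETYPES:
            sel = arch == g
            vals[sel] = rng.choice(mods, size=int(sel.sum()), p=list(rec[g]))
        cols[trait] = vals

    schema = default_trait_schema()
    data = pd.DataFrame(cols, index=pd.Index(ids, name="species"))
    table = TraitTable(species_ids=ids, data=data, schema=schema)
    truth = {
        "archetype": dict(zip(ids, arch.tolist())),
        "distinct_species": [i for i, d in zip(ids, is_distinct) if d],
    }
    return table, schema, truth


def _grid(config: SynthConfig) -> pd.DataFrame:
    lats = config.lat_min + 0.5 * np.arange(config.n_lat)
    lons = config.lon_min + 1.0 * np.arange(config.n_lon)
    lat_g, lon_g = np.meshgrid(lats, lons, indexing="ij")
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i + 1:03d}" for i in range(config.n_cells)],
            "lat": lat_g.ravel(),
            "lon": lon_g.ravel(),
        }
    )
    return cells


def simulate_env_and_survey(
    config: SynthConfig, truth: dict
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the environment/effort table and the survey cube.

    ``truth`` must carry the archetype map from :func:`simulate_traits`.
    Returns (env table, survey table, extended ground truth).
    """
    rng_env = _rng(config, _S_ENV)
    rng_sur = _rng(config, _S_SURVEY)
    cells = _grid(config)
    years = config.first_year + np.arange(config.n_years)
    nc, ny = config.n_cells, config.n_years
    dlat = (cells["lat"].to_numpy() - config.lat_min)[:, None]  # (nc, 1)
    t = np.arange(ny)[None, :]                                   # (1, ny)

    depth = (
        config.depth_intercept
        + config.depth_lat_slope * dlat[:, 0]
        + rng_env.normal(0, config.depth_noise, nc)
    ).clip(min=5.0)
    sst = (
        config.sst_intercept
        + config.sst_lat_slope * dlat
        + config.sst_warming_per_year * t
        + rng_env.normal(0, config.sst_noise, (nc, ny))
    )
    sss = (
        config.sss_intercept
        + config.sss_lat_slope * dlat
        + rng_env.normal(0, config.sss_noise, (nc, ny))
    )
    pci = (
        config.pci_intercept
        + config.pci_lat_slope * dlat
        + rng_env.normal(0, config.pci_noise, (nc, ny))
    ).clip(min=0.05)
    bstress = (
        config.bstress_intercept
        + config.bstress_lat_slope * dlat
        + rng_env.normal(0, config.bstress_noise, (nc, ny))
    ).clip(min=0.02)
    effort = np.exp(
        config.effort_log_base
        - config.effort_lat_decay * dlat
        - config.effort_decline_per_year * t
        + rng_env.normal(0, config.effort_noise, (nc, ny))
    )
    nao = rng_env.normal(0, 1.0, ny)
    amo = -0.2 + config.amo_trend_per_year * np.arange(ny) + rng_env.normal(
        0, 0.08, ny
    )

    env = pd.DataFrame(
        {
            "cell_id": np.repeat(cells["cell_id"].to_numpy(), ny),
            "year": np.tile(years, nc),
            "sst_c": sst.ravel(),
            "sss_psu": sss.ravel(),
            "depth_m": np.repeat(depth, ny),
            "bstress": bstress.ravel(),
            "pci": pci.ravel(),
            "effort_hours": effort.ravel(),
            "nao": np.tile(nao, nc),
            "amo": np.tile(amo, nc),
        }
    )

    arch_map = truth["archetype"]
    ids = list(arch_map)
    arch = np.array([arch_map[s] for s in ids])
    ns = len(ids)

    features = {
        "depth_m": np.broadcast_to(depth[:, None], (nc, ny)),
        "sst_c": sst,
        "sss_psu": sss,
        "pci": pci,
        "bstress": bstress,
        "effort_hours": np.log(effort),  # effort acts on the log scale
    }
    zfeat = {
        k: (v - v.mean()) / v.std() for k, v in features.items()
    }

    base = np.array(
        [config.base_log_abundance[a] for a in arch]
    ) + rng_sur.normal(0, config.base_log_sd, ns)
    trend = np.array(
        [
            rng_sur.normal(config.trend_mean[a], config.trend_sd[a])
            for a in arch
        ]
    )
    coef = {
        f: np.array([config.coefs[a][f] for a in arch]) for f in features
    }

    log_mu = base[:, None, None] + trend[:, None, None] * t[None, :, :]
    for f, z in zfeat.items():
        log_mu = log_mu + coef[f][:, None, None] * z[None, :, :]
    log_mu = log_mu + rng_sur.normal(0, config.abund_noise_sd, (ns, nc, ny))

    abundance = np.exp(log_mu) - config.detection_threshold
    abundance[abundance < 0] = 0.0

    sp_idx, cell_idx, yr_idx = np.nonzero(abundance > 0)
    survey = pd.DataFrame(
        {
            "species": np.array(ids)[sp_idx],
            "cell_id": cells["cell_id"].to_numpy()[cell_idx],
            "lat": cells["lat"].to_numpy()[cell_idx],
            "lon": cells["lon"].to_numpy()[cell_idx],
            "year": years[yr_idx],
            "abundance_per_km2": abundance[sp_idx, cell_idx, yr_idx],
        }
    )

    truth = dict(truth)
    truth.update(
        {
            "coefs": {g: dict(v) for g, v in config.coefs.items()},
            "species_trend": dict(zip(ids, trend.tolist())),
            "env_lat_slopes": {
                "depth_m": config.depth_lat_slope,
                "sst_c": config.sst_lat_slope,
                "sss_psu": config.sss_lat_slope,
                "pci": config.pci_lat_slope,
                "bstress": config.bstress_lat_slope,
                "effort_hours": -config.effort_lat_decay,
            },
        }
    )
    return env, survey, truth


def simulate_phylogeny(config: SynthConfig) -> tuple[dendropy.Tree, list[str]]:
    """Yule pure-birth tree (unit depth) over a subset of the pool."""
    n_tips = min(config.n_phylo_tips, config.n_species)
    if n_tips < 3:
        raise ValueError("need >= 3 tips for a usable phylogeny")
    rng = _rng(config, _S_PHYLO)
    ids = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    chosen = sorted(rng.choice(ids, size=n_tips, replace=False).tolist())

    from dendropy.simulate import treesim

    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    taxa = dendropy.TaxonNamespace(chosen)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=py_rng,
    )
    # drop the stem below the root: shared ancestry starts at the root
    tree.seed_node.edge.length = 0.0
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return tree, chosen


def simulate_status(config: SynthConfig, truth: dict) -> pd.DataFrame:
    """Status table: vulnerability tilted towards the distinct archetype.

    vulnerability = intercept + effect * 1{distinct} + noise, clipped to
    [0, 100]; the probability of a threatened category (CR/EN/VU) rises
    logistically with vulnerability and carries an additional tilt for the
    distinct archetype (long-lived species accumulate listed statuses
    beyond their intrinsic vulnerability score).  Setting ``vuln_effect``
    and ``threat_archetype_boost`` to 0 yields a null scenario with no
    distinctiveness signal.
    """
    rng = _rng(config, _S_STATUS)
    arch_map = truth["archetype"]
    ids = list(arch_map)
    is_distinct = np.array([arch_map[s] == "distinct" for s in ids])
    vuln = np.clip(
        config.vuln_intercept
        + config.vuln_effect * is_distinct
        + rng.normal(0, config.vuln_noise, len(ids)),
        0.0,
        100.0,
    )
    p_threat = config.threat_max_prob / (
        1.0 + np.exp(-(vuln - config.threat_midpoint) / config.threat_scale)
    )
    p_threat = np.clip(
        p_threat + config.threat_archetype_boost * is_distinct, 0.0, 1.0
    )
    threatened = rng.random(len(ids)) < p_threat
    threat_cats = rng.choice(["VU", "EN", "CR"], size=len(ids), p=[0.5, 0.3, 0.2])
    safe_cats = rng.choice(
        ["LC", "NT", "DD", "NE"], size=len(ids), p=[0.72, 0.10, 0.14, 0.04]
    )
    iucn = np.where(threatened, threat_cats, safe_cats)
    return pd.DataFrame(
        {"species": ids, "iucn": iucn, "vulnerability": vuln}
    )


@dataclass
class ScenarioBundle:
    config: SynthConfig
    traits: TraitTable
    schema: TraitSchema
    survey: pd.DataFrame
    env: pd.DataFrame
    status: pd.DataFrame
    tree: dendropy.Tree
    phylo_species: list[str]
    ground_truth: dict


def simulate_scenario(config: SynthConfig) -> ScenarioBundle:
    """Generate every component of one internally consistent scenario."""
    traits, schema, truth = simulate_traits(config)
    env, survey, truth = simulate_env_and_survey(config, truth)
    tree, phylo_species = simulate_phylogeny(config)
    status = simulate_status(config, truth)
    return ScenarioBundle(
        config=config,
        traits=traits,
        schema=schema,
        survey=survey,
        env=env,
        status=status,
        tree=tree,
        phylo_species=phylo_species,
        ground_truth=truth,
    )


def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Export a scenario as CSV/JSON/Newick files plus its ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": outdir / "traits.csv",
        "schema": outdir / "trait_schema.json",
        "survey": outdir / "survey.csv",
        "env": outdir / "environment.csv",
        "status": outdir / "status.csv",
        "tree": outdir / "phylogeny.nwk",
        "ground_truth": outdir / "ground_truth.json",
    }
    tdf = bundle.traits.data.copy()
    tdf.insert(0, "species", bundle.traits.species_ids)
    tdf.to_csv(paths["traits"], index=False)
    bundle.schema.to_json(paths["schema"])
    bundle.survey.to_csv(paths["survey"], index=False)
    bundle.env.to_csv(paths["env"], index=False)
    bundle.status.to_csv(paths["status"], index=False)
    paths["tree"].write_text(
        bundle.tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["ground_truth"].write_text(
        json.dumps(bundle.ground_truth, indent=2, sort_keys=True) + "\n"
    )
    return paths
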