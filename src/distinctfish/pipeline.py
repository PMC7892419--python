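"""End-to-end orchestration: from input files to the full result bundle.

The chain mirrors the analysis design: Gower dissimilarity over the trait
table -> distinctiveness and quartile pools -> trait association tests ->
group aggregation and per-cell/per-species trends -> three redundancy
analyses -> status and vulnerability tests -> phylogenetic regressions.
Every artifact is a pure function of the inputs and the run configuration;
a manifest records input checksums, the seed and all option values so any
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import community, distinctiveness, ordination, phylo, vulnerability
from .traits import TraitSchema, gower_matrix, load_trait_table

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    traits_path: str
    schema_path: str
    survey_path: str
    env_path: str
    status_path: str
    tree_path: str
    outdir: str
    seed: int = 0
    rescale_dij: str = "none"      # "none" | "max"
    rda_scaling: int = 2
    permutations: int = 999
    lambda_mode: str | float = 1.0  # value in [0,1] or "ml"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the whole chain and write the result bundle.

    Returns a mapping of artifact names to written paths.  Raises
    :class:`StageError` naming the failing stage on any error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    schema = _stage("load_schema")(TraitSchema.from_json)(config.schema_path)
    traits = _stage("load_traits")(load_trait_table)(config.traits_path, schema)
    survey = _stage("load_survey")(community.load_survey_table)(config.survey_path)
    env = _stage("load_env")(community.load_env_table)(config.env_path)
    status = _stage("load_status")(vulnerability.load_status_table)(
        config.status_path
    )
    tree = _stage("load_tree")(phylo.load_newick)(config.tree_path)

    # distinctiveness and quartile pools
    @_stage("distinctiveness")
    def _distinct():
        dm = gower_matrix(traits, schema)
        table = distinctiveness.compute_distinctiveness(
            dm, rescale=config.rescale_dij
        )
        return dm, distinctiveness.assign_quartile_groups(table)

    dm, di_table = _distinct()
    paths["distinctiveness"] = outdir / "distinctiveness.tsv"
    distinctiveness.write_distinctiveness_tsv(di_table, paths["distinctiveness"])

    # trait association tests
    @_stage("trait_associations")
    def _assoc():
        out = []
        for spec in schema.traits:
            col = traits.data[spec.name]
            try:
                if spec.kind == "continuous":
                    res = distinctiveness.continuous_trait_association(
                        di_table, col, trait=spec.name
                    )
                else:
                    res = distinctiveness.categorical_trait_association(
                        di_table, col, trait=spec.name
                    )
                out.append(res.to_dict())
            except ValueError as exc:
                out.append({"trait": spec.name, "error": str(exc)})
        return out

    assoc = _assoc()
    paths["trait_associations"] = outdir / "trait_associations.json"
    _write_json(paths["trait_associations"], assoc)

    # community aggregation and trends
    member = distinctiveness.membership(di_table)
    shared = set(survey["species"]) & set(member)
    if not shared:
        raise StageError(
            "aggregation", ValueError("no survey species in the trait pool")
        )

    @_stage("aggregation")
    def _series():
        q14 = {s: g for s, g in member.items() if g in ("Q1", "Q4")}
        if not set(survey["species"]) & set(q14):
            raise ValueError("survey contains no Q1/Q4 species")
        return community.group_site_year_metrics(survey, q14)

    series = _series()
    paths["group_series"] = outdir / "group_series.tsv"
    series.to_csv(paths["group_series"], sep="\t", index=False)

    trends = _stage("trends")(community.per_cell_trend)(series)
    paths["trends"] = outdir / "trends.tsv"
    trends.to_csv(paths["trends"], sep="\t", index=False)

    # three redundancy analyses
    @_stage("rda")
    def _rda():
        designs = {
            "spatial": ordination.build_spatial_design(series, env),
            "temporal": ordination.build_temporal_design(series, env),
            "spatiotemporal": ordination.build_spatiotemporal_design(trends, env),
        }
        out = {}
        for name, design in designs.items():
            result = ordination.fit_rda(design, scaling=config.rda_scaling)
            perm = ordination.permutation_test_rda(
                design, n_perm=config.permutations, seed=config.seed
            )
            payload = result.to_dict()
            payload["permutation_test"] = perm
            payload["row_count"] = len(design.row_ids)
            payload["dropped_predictors"] = design.dropped_predictors
            out[name] = payload
        return out

    rda_payloads = _rda()
    for name, payload in rda_payloads.items():
        paths[f"rda_{name}"] = outdir / f"rda_{name}.json"
        _write_json(paths[f"rda_{name}"], payload)

    # status / vulnerability tests
    @_stage("status_tests")
    def _status_tests():
        q14 = {s: g for s, g in member.items() if g in ("Q1", "Q4")}
        chi = vulnerability.chi_square_homogeneity(q14, status)
        corr = vulnerability.vulnerability_correlation(di_table, status)
        props = {
            g: vulnerability.threatened_proportion(
                [s for s, gg in member.items() if gg == g], status
            )
            for g in ("Q1", "Q4")
        }
        return {
            "chi_square": chi.to_dict(),
            "vulnerability_spearman": corr.to_dict(),
            "threatened_proportion": props,
        }

    status_payload = _status_tests()
    paths["status_tests"] = outdir / "status_tests.json"
    _write_json(paths["status_tests"], status_payload)

    # phylogenetic regressions on the species present in the tree
    @_stage("pgls")
    def _pgls():
        tips = set(phylo.tip_labels(tree))
        di = di_table.set_index("species")["Di"]
        merged = status.set_index("species").join(di, how="inner")
        usable = sorted(
            set(merged.index[np.isfinite(merged["vulnerability"])]) & tips
        )
        if len(merged.index.intersection(tips)) < 4:
            raise ValueError("fewer than 4 species shared with the phylogeny")
        pruned = phylo.prune_to_species(tree, sorted(set(merged.index) & tips))
        labels, C = phylo.bm_covariance(pruned)
        out = {"n_tree_species": len(labels)}

        # vulnerability ~ Di
        lab_v = [l for l in labels if l in usable]
        if len(lab_v) >= 4:
            keep = [labels.index(l) for l in lab_v]
            Cv = C[np.ix_(keep, keep)]
            fit = phylo.fit_pgls(
                merged.loc[lab_v, "vulnerability"].to_numpy(),
                merged.loc[lab_v, "Di"].to_numpy()[:, None],
                Cv,
                lam=config.lambda_mode,
                predictor_names=["Di"],
            )
            out["vulnerability_on_Di"] = fit.to_dict()

        # threatened (0/1 linear probability) ~ Di
        threat = merged.loc[labels, "iucn"].isin(
            sorted(vulnerability.THREATENED)
        ).astype(float)
        if threat.nunique() > 1:
            fit2 = phylo.fit_pgls(
                threat.to_numpy(),
                merged.loc[labels, "Di"].to_numpy()[:, None],
                C,
                lam=config.lambda_mode,
                predictor_names=["Di"],
            )
            out["threatened_on_Di"] = fit2.to_dict()
        else:
            out["threatened_on_Di"] = {
                "skipped": "threatened status constant among tree species"
            }
        return out

    pgls_payload = _pgls()
    paths["pgls"] = outdir / "pgls.json"
    _write_json(paths["pgls"], pgls_payload)

    # manifest: checksums + options; deliberately free of timestamps
    manifest = {
        "inputs": {
            name: _sha256(getattr(config, f"{name}_path"))
            for name in ("traits", "schema", "survey", "env", "status", "tree")
        },
        "seed": config.seed,
        "options": {
            "rescale_dij": config.rescale_dij,
            "rda_scaling": config.rda_scaling,
            "permutations": config.permutations,
            "lambda_mode": config.lambda_mode,
        },
        "artifacts": {k: str(v.name) for k, v in sorted(paths.items())},
    }
    paths["manifest"] = outdir / "manifest.json"
    _write_json(paths["manifest"], manifest)
    return paths
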