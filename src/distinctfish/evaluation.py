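"""Scenario-level evaluation: does the analysis recover planted structure?

These helpers run the full chain (traits -> Gower -> Di -> quartile pools
-> aggregation -> spatial RDA) on one synthetic scenario and score the
outcome against the generator's ground truth.  They are used both in the
test suite and for reporting headline recovery figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import group_site_year_metrics
from .distinctiveness import assign_quartile_groups, compute_distinctiveness, membership
from .ordination import RDAResult, build_spatial_design, fit_rda
from .simulate import ScenarioBundle, SynthConfig, simulate_scenario, simulate_traits
from .traits import gower_matrix

#: predictors whose planted response signs the spatial RDA should recover
SIGN_CHECK_PREDICTORS = ("depth_m", "sst_c", "effort_hours")


def distinctiveness_table(bundle: ScenarioBundle) -> pd.DataFrame:
    dm = gower_matrix(bundle.traits, bundle.schema)
    return assign_quartile_groups(compute_distinctiveness(dm))


def q4_recovery(config: SynthConfig) -> float:
    """Fraction of planted distinct-archetype species landing in Q4.

    Only the trait stage is simulated; the survey is not needed.
    """
    table, schema, truth = simulate_traits(config)
    di = assign_quartile_groups(compute_distinctiveness(gower_matrix(table, schema)))
    q4 = set(di.loc[di["group"] == "Q4", "species"])
    planted = set(truth["distinct_species"])
    return len(q4 & planted) / len(planted)


def spatial_rda(bundle: ScenarioBundle) -> RDAResult:
    """Run the full chain to the spatial RDA on one scenario."""
    di = distinctiveness_table(bundle)
    member = {s: g for s, g in membership(di).items() if g in ("Q1", "Q4")}
    series = group_site_year_metrics(bundle.survey, member)
    design = build_spatial_design(series, bundle.env)
    return fit_rda(design)


def biplot_signs_match(
    result: RDAResult,
    truth: dict,
    predictors=SIGN_CHECK_PREDICTORS,
) -> bool:
    """Do first-axis biplot scores carry the planted coefficient signs?

    The sign of an ordination axis is arbitrary, so the first axis is
    oriented to give the distinct pool (Q4) a positive response score; the
    biplot score of each predictor is then compared against the sign of the
    distinct archetype's planted coefficient.
    """
    axis = "RDA1"
    orient = np.sign(result.response_scores.loc["Q4", axis])
    if orient == 0:
        return False
    coefs = truth["coefs"]["distinct"]
    for pred in predictors:
        if pred not in result.biplot_scores.index:
            return False
        score = orient * result.biplot_scores.loc[pred, axis]
        if np.sign(score) != np.sign(coefs[pred]):
            return False
    return True


def scenario_report(config: SynthConfig) -> dict:
    """Headline recovery metrics for one scenario (single seed)."""
    bundle = simulate_scenario(config)
    di = distinctiveness_table(bundle)
    member = {s: g for s, g in membership(di).items() if g in ("Q1", "Q4")}
    series = group_site_year_metrics(bundle.survey, member)
    q4 = set(di.loc[di["group"] == "Q4", "species"])
    planted = set(bundle.ground_truth["distinct_species"])
    result = spatial_rda(bundle)
    return {
        "bundle": bundle,
        "di_table": di,
        "series": series,
        "q4_recovery": len(q4 & planted) / len(planted),
        "spatial_rda": result,
        "signs_match": biplot_signs_match(result, bundle.ground_truth),
    }
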