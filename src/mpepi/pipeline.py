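"""End-to-end two-step pipeline: network screening, univariate follow-up,
selection-bias sensitivity analysis, and case-case replication.

Step 1 learns a bootstrap-averaged network over the discretized data and
ranks exposures by edge confidence with the 4-level outcome node.  Step 2
carries forward the exposures above the estimated threshold — or, when
none passes, the single top-ranked exposure — into subtype-specific
conditional logistic models with heterogeneity tests, IPW-weighted refits,
and a case-case multinomial replication.  A machine-readable manifest
records seeds, configuration hash, and row counts per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import child_seed
from .bayesnet import AveragedNetwork, bootstrap_average, outcome_edge_ranking
from .casecase import CaseOnlyDesign, ConsistencyReport, RorResult, consistency_with_case_control, ror_result
from .ipw import (
    DEFAULT_AVAILABILITY_COVARIATES,
    AvailabilityModel,
    balance_check,
    compare_complete_case_vs_ipw,
    compute_weights,
)
from .matched import DEFAULT_BIOMARKER_ADJUST, MatchedDesign, SubtypeFitResult, subtype_specific_fit
from .preprocess import OUTCOME_COL, build_discrete_dataset
from .simulate import UNAVAILABLE, Cohort, SimulationConfig, simulate_cohort


def bonferroni_threshold(n_exposures: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_exposures."""
    if n_exposures < 1:
        raise ValueError("n_exposures must be at least 1")
    return alpha / n_exposures


@dataclass
class PipelineResult:
    cohort: Cohort
    network: AveragedNetwork
    ranking: list[tuple[str, float]]
    selected: list[str]
    subtype_results: dict[str, SubtypeFitResult]
    ipw_results: dict[str, SubtypeFitResult]
    balance: object
    comparison: object
    case_case: dict[str, RorResult]
    consistency: dict[str, ConsistencyReport]
    manifest: dict


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full_pipeline(
    config: SimulationConfig,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_bootstrap: int = 1000,
    availability_covariates=DEFAULT_AVAILABILITY_COVARIATES,
    biomarker_adjust=DEFAULT_BIOMARKER_ADJUST,
    adjust_biomarkers: bool = True,
) -> PipelineResult:
    """Simulate (or accept) a cohort and run both analysis steps.

    Identical ``config`` and ``seed`` give bit-identical numeric outputs.
    """
    manifest: dict = {
        "config_hash": _config_hash(config),
        "master_seed": int(seed),
        "stage_seeds": {},
        "row_counts": {},
        "versions": _versions(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    sim_seed = child_seed(seed, "pipeline/simulate")
    manifest["stage_seeds"]["simulate"] = sim_seed
    cohort = simulate_cohort(config, seed=sim_seed)
    df = cohort.data
    manifest["row_counts"]["cohort"] = {
        "subjects": int(len(df)),
        "cases": int(df["is_case"].sum()),
        "controls": int((~df["is_case"]).sum()),
        "cases_unavailable": int((df["subtype"] == UNAVAILABLE).sum()),
    }

    discrete = build_discrete_dataset(cohort)
    manifest["row_counts"]["discrete"] = {
        "rows": int(len(discrete.data)),
        "dropped_cases_missing": discrete.n_dropped_cases,
        "dropped_controls_missing": discrete.n_dropped_controls,
        "dropped_unavailable_sets": discrete.n_unavailable_sets,
    }

    bn_seed = child_seed(seed, "pipeline/bootstrap")
    manifest["stage_seeds"]["bootstrap"] = bn_seed
    network = bootstrap_average(
        discrete.data.drop(columns=["subject_id"]),
        n_bootstrap=n_bootstrap,
        seed=bn_seed,
    )
    ranking = outcome_edge_ranking(network, OUTCOME_COL)
    exposures = set(cohort.config.exposure_names())
    exposure_ranking = [(v, c) for v, c in ranking if v in exposures]
    selected = [v for v, c in exposure_ranking if c > network.threshold]
    if not selected and exposure_ranking:
        # nothing passes the threshold: carry the top-ranked exposure forward
        selected = [exposure_ranking[0][0]]
    manifest["selected_exposures"] = selected
    manifest["edge_threshold"] = network.threshold

    bio_names = set(cohort.biomarker_names())
    subtype_results: dict[str, SubtypeFitResult] = {}
    ipw_results: dict[str, SubtypeFitResult] = {}
    case_case: dict[str, RorResult] = {}
    consistency: dict[str, ConsistencyReport] = {}

    cases = df[df["is_case"]]
    have_unavailable = (cases["subtype"] == UNAVAILABLE).any()
    avail_model = None
    weights = None
    balance = None
    if have_unavailable:
        avail_model = AvailabilityModel(covariates=availability_covariates).fit(cases)
        weights = compute_weights(avail_model, df)
        balance = balance_check(avail_model, cases)

    analysis_df = df.copy()
    for name in selected:
        is_bio = name in bio_names
        covariates = tuple(biomarker_adjust) if (is_bio and adjust_biomarkers) else ()
        col = name
        if is_bio:
            from .preprocess import LogSDScaler

            scaler = LogSDScaler().fit(df.loc[~df["is_case"], name])
            analysis_df[f"{name}__per_sd"] = scaler.transform(df[name])
            col = f"{name}__per_sd"
        design = MatchedDesign(data=analysis_df, exposure=col, covariates=covariates)
        subtype_results[name] = subtype_specific_fit(design)
        if weights is not None:
            ipw_results[name] = subtype_specific_fit(
                design, sample_weight=weights.weights, heterogeneity=False
            )
        cc_design = CaseOnlyDesign(
            data=analysis_df[analysis_df["is_case"] & (analysis_df["subtype"] != UNAVAILABLE)],
            exposure=col,
        )
        case_case[name] = ror_result(cc_design)
        consistency[name] = consistency_with_case_control(
            subtype_results[name], case_case[name]
        )

    comparison = None
    if ipw_results:
        cc_tab = pd.concat([r.to_frame() for r in subtype_results.values()])
        ipw_tab = pd.concat([r.to_frame() for r in ipw_results.values()])
        common = set(map(tuple, cc_tab[["exposure", "subtype"]].to_numpy())) & set(
            map(tuple, ipw_tab[["exposure", "subtype"]].to_numpy())
        )
        mask_cc = cc_tab[["exposure", "subtype"]].apply(tuple, axis=1).isin(common)
        mask_ipw = ipw_tab[["exposure", "subtype"]].apply(tuple, axis=1).isin(common)
        comparison = compare_complete_case_vs_ipw(cc_tab[mask_cc], ipw_tab[mask_ipw])

    result = PipelineResult(
        cohort=cohort,
        network=network,
        ranking=exposure_ranking,
        selected=selected,
        subtype_results=subtype_results,
        ipw_results=ipw_results,
        balance=balance,
        comparison=comparison,
        case_case=case_case,
        consistency=consistency,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, discrete, Path(outdir))
    return result


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    import mpepi

    return {
        "mpepi": mpepi.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }


def _write_outputs(result: PipelineResult, discrete, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.cohort.write(outdir / "cohort.tsv", outdir / "config.yaml")
    discrete.write(outdir / "discrete.tsv", outdir / "rules.yaml")
    result.network.to_edge_list().to_csv(outdir / "edges.tsv", sep="\t", index=False)
    (outdir / "network.dot").write_text(result.network.to_dot())
    pd.DataFrame(result.ranking, columns=["variable", "confidence"]).to_csv(
        outdir / "outcome_ranking.tsv", sep="\t", index=False
    )
    if result.subtype_results:
        pd.concat([r.to_frame() for r in result.subtype_results.values()]).to_csv(
            outdir / "subtype_or.tsv", sep="\t", index=False
        )
    if result.ipw_results:
        pd.concat([r.to_frame() for r in result.ipw_results.values()]).to_csv(
            outdir / "subtype_or_ipw.tsv", sep="\t", index=False
        )
    if result.balance is not None:
        result.balance.to_frame().to_csv(outdir / "balance.tsv", sep="\t")
    if result.comparison is not None:
        result.comparison.table.to_csv(outdir / "cc_vs_ipw.tsv", sep="\t", index=False)
    if result.case_case:
        pd.concat(
            [r.to_frame().assign(exposure=name) for name, r in result.case_case.items()]
        ).to_csv(outdir / "case_case.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
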