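"""End-to-end orchestration: cohort -> income -> imputation -> adjusted
means -> indices -> concordance, with per-stage accounting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .. import _schema as S
from ..adjusted_means import StateGroupMeans, compute_state_group_means
from ..cohort import ExclusionTally, StateEligibility, apply_exclusions, assess_state_eligibility
from ..concordance import ConcordanceReport, compare_rankings
from ..imputation import UnimputableStateError, impute_chained
from ..income import add_income_classification
from ..indices import build_index_table
from ..synthetic_data import generate_population, inject_missingness
from .config import PipelineConfig
from .io import load_poverty_guidelines, load_table2_fixture, read_microdata, write_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "compare_fixture"]

MIN_STATES_FOR_CONCORDANCE = 3


@dataclass
class PipelineResult:
    index_table: pd.DataFrame
    report: ConcordanceReport | None
    exclusion_tally: ExclusionTally
    eligibility: list[StateEligibility]
    state_means: list[StateGroupMeans] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    non_computable_states: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)
    return name


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; identical config and seed reproduce outputs
    byte for byte.  Every dropped state or respondent shows up in the
    result's accounting."""
    config.validate()
    counts: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    stage = "load"
    try:
        if config.input_path is not None:
            data = read_microdata(config.input_path)
        else:
            data = generate_population(config.generator)
            if config.missingness is not None:
                data = inject_missingness(data, config.missingness)
        counts["input_records"] = len(data)
        guidelines = load_poverty_guidelines(config.guideline_path)

        stage = _stage("cohort")
        retained, tally = apply_exclusions(data)
        counts["excluded"] = tally.excluded
        counts["retained"] = tally.retained
        eligibility = assess_state_eligibility(retained, config.missing_threshold)
        eligible_states = [e.state for e in eligibility if e.eligible]
        counts["eligible_states"] = len(eligible_states)
        counts["ineligible_states"] = len(eligibility) - len(eligible_states)

        non_computable: dict[str, str] = {}
        rows = []
        state_means: list[StateGroupMeans] = []
        for state in eligible_states:
            sub = retained[retained[S.STATE] == state]
            stage = _stage(f"imputation[{state}]")
            try:
                imp_spec = replace(
                    config.imputation, seed=config.imputation.seed + eligible_states.index(state)
                )
                stack = impute_chained(sub, imp_spec)
            except UnimputableStateError as exc:
                logger.warning("state %s non-computable: %s", state, exc)
                non_computable[state] = str(exc)
                continue
            stage = _stage(f"income[{state}]")
            classified = [
                add_income_classification(ds, guidelines, config.weighted_percentile)
                for ds in stack.datasets
            ]
            stage = _stage(f"adjusted_means[{state}]")
            per_scheme = {}
            for scheme in S.SCHEMES:
                per_scheme[scheme] = compute_state_group_means(
                    classified,
                    scheme,
                    adjusted=config.adjusted_means,
                    at_covariate_means=config.at_covariate_means,
                )
                state_means.append(per_scheme[scheme])
            rows.append(
                {
                    S.STATE: state,
                    "mean_overall": per_scheme[S.SCHEME_RHWDI].overall,
                    **{
                        f"{scheme}_{g}": per_scheme[scheme].group_means[g]
                        for scheme in S.SCHEMES
                        for g in S.GROUPS
                    },
                }
            )

        stage = _stage("indices")
        if not rows:
            index_table = pd.DataFrame(
                columns=[S.STATE, "rhwdi", "rhwdi_negative", "rhwdi_rank", "hwdi", "hwdi_rank", "computable"]
            )
        else:
            index_table = build_index_table(pd.DataFrame(rows))
        for _, row in index_table.iterrows():
            if not row["computable"] and row[S.STATE] not in non_computable:
                non_computable[row[S.STATE]] = "missing group mean (empty income group)"
        counts["computable_states"] = int(index_table["computable"].sum()) if len(index_table) else 0

        stage = _stage("concordance")
        report = None
        comp = index_table[index_table["computable"]]
        if len(comp) >= MIN_STATES_FOR_CONCORDANCE:
            report = compare_rankings(
                comp.set_index(S.STATE)["rhwdi_rank"].astype(int),
                comp.set_index(S.STATE)["hwdi_rank"].astype(int),
                m_comparisons=config.m_comparisons,
                top_k=config.top_k,
            )
        else:
            logger.warning(
                "concordance skipped: only %d computable states (need >= %d)",
                len(comp),
                MIN_STATES_FOR_CONCORDANCE,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        index_table=index_table,
        report=report,
        exclusion_tally=tally,
        eligibility=eligibility,
        state_means=state_means,
        stage_counts=counts,
        non_computable_states=non_computable,
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    from pathlib import Path

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    write_table(result.index_table, out / "index_table.csv", **meta)
    if result.report is not None:
        (out / "concordance.txt").write_text(result.report.to_text() + "\n")
    elig = pd.DataFrame(
        [{"state": e.state, "eligible": e.eligible, "reasons": ";".join(e.reasons)} for e in result.eligibility]
    )
    write_table(elig, out / "state_eligibility.csv", **meta)
    logger.info("outputs written to %s", out)


def compare_fixture(fixture: pd.DataFrame | None = None, top_k: int = 5, m_comparisons: int = 1) -> ConcordanceReport:
    """Full concordance report computed from a printed two-ranking table
    (defaults to the packaged 49-state fixture)."""
    if fixture is None:
        fixture = load_table2_fixture()
    return compare_rankings(
        fixture.set_index("state")["rhwdi_rank"].astype(int),
        fixture.set_index("state")["hwdi_rank"].astype(int),
        m_comparisons=m_comparisons,
        top_k=top_k,
    )
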