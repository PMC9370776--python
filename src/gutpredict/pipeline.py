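"""End-to-end orchestration: prep -> screening -> elastic net -> MC search ->
final scoring -> prediction -> ordination, with a run manifest.

The global seed fans out deterministically: ``SeedSequence(seed)`` is spawned
once per stage in a fixed order (synthetic, elastic, one per MC weighting x
response, prediction, ordination) and each child's first generated state word
becomes that stage's integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .elastic_select import ENSettings, filter_candidates, run_selection_pair
from .io_prep import drop_blacklisted, load_abundance, load_outcomes, reduce_to_top
from .mc_search import (
    GENUS_SCHEDULE,
    SPECIES_SCHEDULE,
    WEIGHTING_1,
    WEIGHTING_2,
    MCSettings,
    average_ranks,
    reduce_and_iterate,
)
from .ordination import clr_transform, groupwise_tests, pca_scores, permanova, zscore
from .prediction import best_k_term_models, classify_predictions, cv_r2
from .scoring import ScoreWeights, build_candidate_table
from .screening import screen
from .synthetic import CohortSpec, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """One run: either file inputs or a synthetic cohort spec, plus stage settings."""

    output_dir: str = "gutpredict_out"
    seed: int = 0
    # exactly one of the two input routes
    abundance_path: str | None = None
    outcomes_path: str | None = None
    synthetic: dict | None = None
    level: str = "genus"
    # stage settings
    n_keep: int | None = None
    blacklist: str = "default"  # "default" | "none"
    screening_method: str = "pearson"
    en_alpha: float = 1.0
    en_folds: int = 5
    en_repeats: int = 1000
    en_threshold: float = 1.0
    mc_models: int = 20_000
    mc_max_terms: int = 4
    mc_weightings: tuple = (WEIGHTING_1, WEIGHTING_2)
    mc_schedule: tuple | None = None
    mc_responses: tuple = ("rwl",)
    score_weights: tuple = (1.0, 1.0, 3.0, 1.0)
    rank_ceiling: float = 7.0
    min_score: float = 2.0
    k_max: int = 5
    cv_folds: tuple = (3, 5, 8, 15)
    cv_repeats: int = 200
    classify_threshold: float = 10.0
    n_permutations: int = 999

    def __post_init__(self) -> None:
        has_files = self.abundance_path is not None and self.outcomes_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("provide exactly one of (abundance+outcomes paths, synthetic spec)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mc_weightings"] = [list(w) for w in self.mc_weightings]
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["synthetic", "elastic", "mc_0", "mc_1", "mc_2", "mc_3", "prediction", "ordination"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0]) for name, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write CSV outputs plus a manifest, return results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    results: dict = {"output_dir": str(out)}

    def _stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- input ------------------------------------------------------------
    if config.synthetic is not None:
        spec_dict = dict(config.synthetic)
        spec_dict.setdefault("seed", seeds["synthetic"])
        spec = CohortSpec.from_dict(spec_dict)
        cohort = _stage("synthetic")(lambda: generate_cohort(spec))
        write_cohort(cohort, out / "cohort")
        table, outcomes = cohort.abundance, cohort.outcomes
        results["planted_taxa"] = cohort.planted_taxa
    else:
        table = _stage("load")(
            lambda: load_abundance(config.abundance_path, level=config.level)
        )
        outcomes = _stage("load")(lambda: load_outcomes(config.outcomes_path))

    rwl, dbmi, strata = outcomes.rwl, outcomes.delta_bmi, outcomes.groups

    # --- preparation ------------------------------------------------------
    def _prep():
        t = drop_blacklisted(table) if config.blacklist == "default" else table
        n_keep = config.n_keep
        if n_keep is None:
            n_keep = min(102 if t.level == "genus" else 106, t.n_taxa)
        return reduce_to_top(t, min(n_keep, t.n_taxa))

    pm = _stage("prep")(_prep)
    pm.to_dataframe().rename_axis("sample_id").to_csv(out / "predictor_matrix.csv")
    results["predictor_matrix"] = pm
    results["coverage"] = pm.coverage

    # --- screening --------------------------------------------------------
    corr = _stage("screening")(
        lambda: screen(pm, rwl, dbmi, method=config.screening_method)
    )
    corr.to_csv(out / "screening.csv", index=False)
    results["screening"] = corr

    # --- elastic net ------------------------------------------------------
    en_settings = ENSettings(
        alpha=config.en_alpha,
        n_folds=config.en_folds,
        n_repeats=config.en_repeats,
        seed=seeds["elastic"],
    )
    occ = _stage("elastic_select")(lambda: run_selection_pair(pm, rwl, dbmi, en_settings))
    occ.to_csv(out / "elastic_occurrence.csv")
    en_cand = filter_candidates(occ, threshold=config.en_threshold)
    en_cand.to_csv(out / "elastic_candidates.csv")
    results["elastic_occurrence"] = occ
    results["elastic_candidates"] = en_cand

    # --- MC search --------------------------------------------------------
    schedule = config.mc_schedule
    if schedule is None:
        base = GENUS_SCHEDULE if table.level == "genus" else SPECIES_SCHEDULE
        schedule = tuple(
            sorted({min(s, pm.n_taxa) for s in base}, reverse=True)
        )
    responses = {"rwl": rwl, "dbmi": dbmi}
    full_tables, final_tables = [], []
    mc_runs = {}
    i = 0
    for resp_name in config.mc_responses:
        for w in config.mc_weightings:
            settings = MCSettings(
                n_models=config.mc_models,
                max_terms=config.mc_max_terms,
                weights=tuple(w),
                reduction_schedule=tuple(schedule),
                seed=seeds[f"mc_{i}"],
            )
            i += 1
            run = _stage("mc_search")(
                lambda s=settings, yv=responses[resp_name]: reduce_and_iterate(
                    list(pm.taxon_ids), pm, yv, s
                )
            )
            key = f"{resp_name}_w{len(mc_runs) + 1}"
            mc_runs[key] = run
            full_tables.append(run.full_table)
            final_tables.append(run.final_table)
            for stage_i, t in enumerate(run.stage_tables):
                t.to_csv(out / f"mc_{key}_stage{stage_i}_{run.stage_sizes[stage_i]}terms.csv", index=False)
    ranks = average_ranks(full_tables, final_tables)
    ranks.to_csv(out / "mc_rank_summary.csv")
    results["mc_runs"] = mc_runs
    results["mc_ranks"] = ranks

    # --- final scoring ----------------------------------------------------
    weights = ScoreWeights(
        *config.score_weights, rank_ceiling=config.rank_ceiling, min_score=config.min_score
    )
    final_union = sorted({t for run in mc_runs.values() for t in run.final_terms})
    rank_input = ranks.copy()
    rank_input["avg_rank_final"] = rank_input["avg_rank_final"].where(
        rank_input.index.isin(final_union)
    )
    full_scores, report = _stage("final_scoring")(
        lambda: build_candidate_table(rank_input, list(en_cand.index), corr, weights)
    )
    full_scores.to_csv(out / "final_scores_full.csv", index=False)
    report.to_csv(out / "final_scores.csv", index=False)
    results["final_scores"] = full_scores
    results["candidates"] = report

    # --- prediction -------------------------------------------------------
    candidate_terms = list(report["taxon_id"])
    k_max = min(config.k_max, len(candidate_terms))
    model_rows, class_frames = [], []
    models = {}
    if k_max >= 1:
        sub = pm.to_dataframe()[candidate_terms]
        for resp_name, yv in (("rwl", rwl), ("dbmi", dbmi)):
            reports = _stage("prediction")(
                lambda yy=yv, rn=resp_name: best_k_term_models(
                    sub, yy, k_range=range(1, k_max + 1), response=rn
                )
            )
            for k, rep in reports.items():
                for nf in config.cv_folds:
                    if nf <= pm.n_samples:
                        rep.cv_r2[nf] = cv_r2(
                            sub,
                            yv,
                            terms=list(rep.terms),
                            n_folds=nf,
                            n_repeats=config.cv_repeats,
                            seed=seeds["prediction"],
                            strata=strata,
                        )
                model_rows.append(rep.to_row())
                if resp_name == "rwl":
                    ct = classify_predictions(
                        rep.fitted, rwl, threshold=config.classify_threshold,
                        patient_ids=outcomes.patient_ids,
                    )
                    cf = ct.frame.copy()
                    cf.insert(0, "n_terms", k)
                    class_frames.append(cf)
            models[resp_name] = reports
        pd.DataFrame(model_rows).to_csv(out / "model_reports.csv", index=False)
        if class_frames:
            pd.concat(class_frames).to_csv(out / "classification.csv", index=False)
    results["models"] = models

    # --- ordination -------------------------------------------------------
    if len(candidate_terms) >= 2:
        sel = pm.to_dataframe()[candidate_terms]
        clr = clr_transform(sel)
        dist = np.linalg.norm(clr.values[:, None, :] - clr.values[None, :, :], axis=2)
        perm = _stage("ordination")(
            lambda: permanova(dist, strata, config.n_permutations, seed=seeds["ordination"])
        )
        pca = pca_scores(clr.values)
        tests = groupwise_tests(clr, strata)
        pd.DataFrame(
            pca["scores"],
            index=pm.sample_ids,
            columns=[f"PC{i + 1}" for i in range(pca["scores"].shape[1])],
        ).rename_axis("sample_id").to_csv(out / "pca_scores.csv")
        tests.to_csv(out / "group_tests.csv", index=False)
        pd.DataFrame(
            zscore(sel.to_numpy()), index=pm.sample_ids, columns=candidate_terms
        ).rename_axis("sample_id").to_csv(out / "zscores.csv")
        results["permanova"] = perm
        results["group_tests"] = tests
        with (out / "permanova.json").open("w") as fh:
            json.dump(dataclasses.asdict(perm), fh, indent=2)

    # --- manifest ---------------------------------------------------------
    config_dict = config.to_dict()
    manifest = {
        "version": __version__,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": seeds,
        "coverage": pm.coverage,
        "candidates": candidate_terms,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
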