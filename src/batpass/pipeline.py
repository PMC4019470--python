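"""End-to-end orchestration: generate -> segment -> filter -> classify ->
count -> model -> report, as one reproducible, seeded run.

Every stage consumes the previous stage's output through the library API;
all randomness derives from a single root seed via ``numpy``
SeedSequence spawning, so stages are independently re-runnable and a
serialized :class:`RunConfig` fully determines every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, glmm, synth, zc
from .design import ModelSpec
from .studydata import default_species_mix, highway_study_betas

__all__ = ["RunConfig", "RunReport", "make_fixtures", "run_end_to_end"]

log = logging.getLogger("batpass")


def _default_true_model() -> synth.TrueModel:
    return synth.TrueModel(
        beta=tuple(highway_study_betas()["all"]),
        sigma_night=0.3,
        sigma_transect=0.3,
        phi=3.0,
    )


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    survey: synth.SurveyConfig = field(default_factory=synth.SurveyConfig)
    true_model: synth.TrueModel = field(default_factory=_default_true_model)
    n_species: int = 15
    ref_calls_per_species: int = 120
    quality_rate: float = 0.97
    n_trees: int = 100
    features_per_split: int = 3
    train_frac: float = 0.8
    threshold: float = 0.45
    n_replicates: int = 10
    filter_thresholds: zc.QualityThresholds = field(
        default_factory=zc.QualityThresholds
    )
    temp_center_c: float = 24.0
    fit_species: bool = True
    min_species_passes: int = 500
    excluded_species: tuple[str, ...] = ()
    lrt_terms: tuple[str, ...] = ("dist_road", "temp_max", "light")
    seed: int = 0
    log_level: str = "INFO"

    def to_flat_dict(self) -> dict:
        d = {}
        for name, obj in (("survey", self.survey),
                          ("true_model", self.true_model),
                          ("filter", self.filter_thresholds)):
            for f in dataclasses.fields(obj):
                d[f"{name}.{f.name}"] = getattr(obj, f.name)
        for f in dataclasses.fields(self):
            if f.name in ("survey", "true_model", "filter_thresholds"):
                continue
            d[f.name] = getattr(self, f.name)
        return d

    def to_yaml(self, path=None) -> str:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        text = yaml.safe_dump(
            {k: plain(v) for k, v in self.to_flat_dict().items()},
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        text = (
            Path(path_or_text).read_text()
            if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text)
            else str(path_or_text)
        )
        flat = yaml.safe_load(text) or {}
        groups: dict[str, dict] = {"survey": {}, "true_model": {}, "filter": {}}
        top: dict = {}
        for k, v in flat.items():
            if isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            if "." in k:
                g, name = k.split(".", 1)
                groups[g][name] = v
            else:
                top[k] = v
        kw = dict(top)
        if groups["survey"]:
            kw["survey"] = synth.SurveyConfig(**groups["survey"])
        if groups["true_model"]:
            kw["true_model"] = synth.TrueModel(**groups["true_model"])
        if groups["filter"]:
            kw["filter_thresholds"] = zc.QualityThresholds(**groups["filter"])
        for key in ("excluded_species", "lrt_terms"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated outputs of one end-to-end run."""

    config_hash: str
    seed: int
    counts_by_distance: dict
    classifier_accuracy: float | None
    classifier_accuracy_mean: float | None
    classifier_accuracy_sd: float | None
    retained_fraction: float | None
    segmentation_matches: bool
    coefficients: dict          # response -> {term: estimate}
    random_effect_sds: dict     # response -> [sigma_night, sigma_transect]
    dispersion: dict            # response -> phi
    lrt: list                   # rows: response, term, statistic, df, p, stars
    predictions: list           # rows: response, dist, predicted passes/night
    recovery: dict              # truth-vs-estimate deltas for total activity
    excluded: dict
    stage_errors: dict

    def to_json(self, path=None) -> str:
        def plain(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            return v

        text = json.dumps(plain(dataclasses.asdict(self)), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_end_to_end(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full pipeline; see module docstring for the stages.

    Writes intermediate CSVs (nightly-count summary, per-pass probability
    table, coefficient/LRT/prediction tables) under ``out_dir`` when given.
    Stage failures are recorded in the report rather than raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    s_profiles, s_library, s_survey, s_split, s_forest = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )
    errors: dict[str, str] = {}
    chash = config.config_hash()
    log.info("run %s seed=%d", chash, config.seed)

    # --- stage 1: generation ----------------------------------------------
    profiles = synth.make_species_profiles(config.n_species, seed=s_profiles)
    library = synth.simulate_reference_library(
        profiles, config.ref_calls_per_species, seed=s_library,
        quality_rate=config.quality_rate,
    )
    mix = default_species_mix([p.species_code for p in profiles])
    survey = synth.simulate_survey(
        config.survey, config.true_model, profiles, mix, seed=s_survey
    )
    log.info("simulated %d detector-nights, %d passes",
             len(survey.records), int(survey.records["count"].sum()))
    if out is not None:
        synth.write_survey_csv(survey, out / "nightly_counts.csv")

    # --- stage 2: segmentation, filtering, counting ------------------------
    night_ids = survey.records["detector_night_id"].tolist()
    all_passes: list[zc.Pass] = []
    for stream in survey.streams:
        passes = zc.segment_passes(stream)
        for p in passes:
            zc.quality_filter(p, config.filter_thresholds)
        all_passes.extend(passes)
    counted = zc.nightly_counts(all_passes, night_ids=night_ids)
    seg_ok = bool(
        (counted.set_index("detector_night_id")["n_passes"]
         .reindex(night_ids).to_numpy()
         == survey.records["count"].to_numpy()).all()
    )
    if not seg_ok:
        errors["segmentation"] = "pass counts differ from generator truth"
    kept_passes = zc.drop_empty_passes(all_passes)
    log.info("segmented %d passes (%d with quality calls); round-trip=%s",
             len(all_passes), len(kept_passes), seg_ok)

    # --- stage 3: classification ------------------------------------------
    accuracy = acc_mean = acc_sd = retained_frac = None
    assignments: list[classify.PassAssignment] = []
    try:
        train_idx, _ = classify.stratified_split(
            library, train_frac=config.train_frac, seed=s_split
        )
        model = classify.train_classifier(
            library, train_indices=train_idx,
            n_trees=config.n_trees,
            features_per_split=config.features_per_split,
            seed=s_forest,
        )
        report = classify.evaluate(model, library)
        accuracy = report.accuracy
        if config.n_replicates > 1:
            rep = classify.replicate_accuracy(
                library, n_replicates=config.n_replicates, seed=s_forest,
                n_trees=config.n_trees,
                features_per_split=config.features_per_split,
            )
            acc_mean, acc_sd = rep.accuracy_mean, rep.accuracy_sd
        assignments = [classify.classify_pass(model, p) for p in kept_passes]
        for p, a in zip(kept_passes, assignments):
            p.species = a.winner
        _, retained_frac = classify.apply_threshold(
            assignments, config.threshold
        )
        log.info("classifier accuracy %.3f; retained %.2f at threshold %.2f",
                 accuracy, retained_frac, config.threshold)
        if out is not None:
            probs = pd.DataFrame(
                [a.summed_probs for a in assignments]
            )
            probs.insert(0, "pass_id", [a.pass_id for a in assignments])
            probs.insert(1, "detector_night_id",
                         [a.detector_night_id for a in assignments])
            probs.insert(2, "n_calls", [a.n_calls for a in assignments])
            probs.to_csv(out / "pass_probabilities.csv", index=False)
    except Exception as e:  # pragma: no cover - defensive
        errors["classification"] = repr(e)

    # --- stage 4: modeling -------------------------------------------------
    spec = ModelSpec(temp_center_c=config.temp_center_c)
    covars = survey.records.drop(columns=["count", "species"])
    responses: dict[str, pd.DataFrame] = {}
    # total activity is counted before any classification threshold
    responses["all"] = survey.records.copy()
    if config.fit_species and assignments:
        kept, _ = classify.apply_threshold(assignments, config.threshold)
        kept_ids = {id(a) for a in kept}
        by_night_species: dict[tuple[str, str], int] = {}
        for a in assignments:
            if id(a) in kept_ids:
                key = (a.detector_night_id, a.winner)
                by_night_species[key] = by_night_species.get(key, 0) + 1
        for code in sorted({a.winner for a in assignments}):
            df = covars.copy()
            df["count"] = [
                by_night_species.get((nid, code), 0) for nid in night_ids
            ]
            df["species"] = code
            responses[code] = df

    coefficients: dict = {}
    re_sds: dict = {}
    dispersion: dict = {}
    lrt_rows: list = []
    predictions: list = []
    recovery: dict = {}
    excluded: dict = {}
    try:
        fits, coef_table, lrt_table, excluded = glmm.fit_all_models(
            responses, spec,
            min_passes=config.min_species_passes,
            excluded_species=config.excluded_species,
            terms=config.lrt_terms,
        )
        for name, fit in fits.items():
            coefficients[name] = fit.coef().to_dict()
            re_sds[name] = [fit.sigma_night, fit.sigma_transect]
            dispersion[name] = fit.phi
            for dist in (0, 100, 300):
                predictions.append(
                    {"response": name, "dist_road": dist,
                     "passes_per_night": glmm.predict_activity(fit, dist)}
                )
        lrt_rows = lrt_table.to_dict("records")
        truth = np.asarray(config.true_model.beta)
        if "all" in fits:
            delta = fits["all"].beta - truth
            recovery = {
                "max_abs_beta_error": float(np.max(np.abs(delta))),
                "intercept_error": float(delta[0]),
                "dist_road_0_error": float(delta[2]),
            }
        if out is not None:
            coef_table.to_csv(out / "coefficients.csv")
            lrt_table.to_csv(out / "lrt.csv", index=False)
            pd.DataFrame(predictions).to_csv(
                out / "predictions.csv", index=False
            )
    except Exception as e:
        errors["modeling"] = repr(e)

    counts_by_distance = (
        survey.records.groupby("dist_road")["count"].sum().to_dict()
    )
    report = RunReport(
        config_hash=chash,
        seed=config.seed,
        counts_by_distance={str(k): int(v) for k, v in counts_by_distance.items()},
        classifier_accuracy=accuracy,
        classifier_accuracy_mean=acc_mean,
        classifier_accuracy_sd=acc_sd,
        retained_fraction=retained_frac,
        segmentation_matches=seg_ok,
        coefficients=coefficients,
        random_effect_sds=re_sds,
        dispersion=dispersion,
        lrt=lrt_rows,
        predictions=predictions,
        recovery=recovery,
        excluded=excluded,
        stage_errors=errors,
    )
    if out is not None:
        report.to_json(out / "report.json")
        config.to_yaml(out / "config.yaml")
    return report


def small_config(seed: int = 0) -> RunConfig:
    """A scaled-down configuration for tests and quick demonstrations."""
    survey = synth.SurveyConfig(
        site_transects=(("DOED", 2), ("HAYW", 1), ("SAPA", 2)),
        total_nights=45,
        n_calendar_nights=12,
        n_light_points=2,
        seed=seed,
    )
    return RunConfig(
        survey=survey,
        n_species=5,
        ref_calls_per_species=40,
        n_replicates=3,
        fit_species=False,
        lrt_terms=(),
        seed=seed,
    )


def make_fixtures(seed: int = 0, out_dir="fixtures") -> dict:
    """Emit small text fixtures: a call stream with known pass structure,
    a labeled reference library, and a small survey CSV.

    Regenerating with the same seed produces identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    profiles = synth.make_species_profiles(4, seed=seed)
    # stream with 3 passes of 2/1/3 calls at gaps > 5 s
    calls = []
    t = 1.0
    layout = [2, 1, 3]
    for n_calls in layout:
        for _ in range(n_calls):
            times, freqs = synth.generate_call(profiles[0], rng, start_s=t)
            calls.append(zc.Call(times, freqs, species=profiles[0].species_code))
            t = float(times[-1]) + 0.2
        t += 8.0
    stream = zc.ZCCallStream("fixture-night", calls)
    zc.write_zc(stream, out / "stream.txt")

    library = synth.simulate_reference_library(
        profiles, 15, seed=seed, quality_rate=1.0
    )
    rows = []
    for e in library.entries:
        rows.append({"species": e.species,
                     **dict(zip(zc.FEATURE_NAMES, e.features.as_array()))})
    pd.DataFrame(rows).to_csv(out / "library_features.csv", index=False)

    survey = synth.simulate_survey(
        synth.SurveyConfig(
            site_transects=(("DOED", 1), ("HAYW", 1), ("SAPA", 1)),
            total_nights=27,
            n_calendar_nights=10,
            n_light_points=1,
            seed=seed,
        ),
        _default_true_model(),
        profiles,
        default_species_mix([p.species_code for p in profiles]),
        seed=seed,
        emit_streams=False,
    )
    synth.write_survey_csv(survey, out / "survey.csv")
    return {
        "stream": out / "stream.txt",
        "library": out / "library_features.csv",
        "survey": out / "survey.csv",
        "pass_layout": layout,
    }
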