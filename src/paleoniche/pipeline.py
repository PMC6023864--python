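"""End-to-end orchestration: synthetic study construction, the geographic
(SDM transferability) track and the environmental (niche overlap) track.

A run is driven by a :class:`RunConfig` (constructible from YAML/JSON).
Every source of randomness is derived from one master seed through
:func:`stage_seed` (CRC-32 of the stage name folded into the master seed),
so a full run is reproducible and any single stage can be replayed.

The geographic track mirrors the two transferability tables of a
hindcasting study: models calibrated in the reference scenario are
projected (clamped) to every other scenario and validated there with that
scenario's independent presences; models calibrated in each paleo scenario
are transferred back and validated with the reference presences. The
environmental track produces one overlap row per scenario pair: Schoener's
D, equivalency and similarity tests (both directions), the
expansion/stability/unfilling decomposition and centroid shifts.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import envspace as es
from . import sdm as gm
from . import synthetic as syn
from .geodata import ClimateStack, OccurrenceSet, write_report
from .preprocess import select_predictors, thin_to_grid

logger = logging.getLogger(__name__)

DEFAULT_MODEL_ROWS = (
    ("glm_poly", "pseudoabsence"),
    ("random_forest", "pseudoabsence"),
    ("maxent_like", "background"),
    ("glm_poly", "background"),
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed folded with CRC-32(stage)."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of a full synthetic run (all values have defaults)."""

    master_seed: int = 0
    grid_rows: int = 80
    grid_cols: int = 80
    variable_names: tuple[str, ...] = syn.DEFAULT_VARIABLES
    # interpolated bioclimatic rasters are dominated by smooth continental
    # gradients; an autocorrelation length ~15% of the domain reproduces that
    autocorr_length: float = 12.0
    # scenario name -> {"offset": [...], "factor": [...]} climate shifts
    scenarios: dict[str, dict] = dc_field(default_factory=dict)
    # spatial mean/SD of each synthetic variable (temperature-like variables
    # get an SD of 4, a degC-like spread over a peninsula-sized domain, so
    # degC-valued scenario offsets are meaningful; precipitation-like
    # variables are kept on a unit relative scale)
    variable_means: tuple[float, ...] | None = None
    variable_sds: tuple[float, ...] | None = None
    # niche truth in variable units
    niche_optimum: tuple[float, ...] | None = None
    niche_tolerance: tuple[float, ...] | None = None
    max_prevalence: float = 0.9
    # per-scenario optimum displacement (empty = conserved niche)
    niche_shift: dict[str, tuple[float, ...]] = dc_field(default_factory=dict)
    n_presence: int = 404
    n_fossil: dict[str, int] = dc_field(default_factory=dict)
    background_fraction: float = 0.2
    thin_cell_size: float = 1.0
    glm_degree: int = 2
    rf_trees: int = 500
    reg_multiplier: float = 3.0
    bootstrap_iterations: int = 20
    test_fraction: float = 0.4
    model_rows: tuple[tuple[str, str], ...] = DEFAULT_MODEL_ROWS
    env_replicates: int = 100
    env_resolution: int = 100
    env_corrected: bool = True
    similarity_null: str = "random-points"
    env_background_cells: int = 2000
    output_dir: str | None = None

    def __post_init__(self) -> None:
        k = len(self.variable_names)
        temp = {f"bio{i}" for i in range(1, 12)}
        is_temp = [name in temp for name in self.variable_names]
        if self.variable_means is None:
            # precipitation-like variables get a positive mean so that
            # multiplicative drying (e.g. x0.84) actually shifts them
            self.variable_means = tuple(0.0 if t else 5.0 for t in is_temp)
        if self.variable_sds is None:
            self.variable_sds = tuple(4.0 if t else 1.0 for t in is_temp)
        if self.niche_optimum is None:
            self.niche_optimum = tuple(self.variable_means)
        if self.niche_tolerance is None:
            # a habitat specialist: niche breadth = half the spatial spread
            # of each climate variable
            self.niche_tolerance = tuple(0.5 * s for s in self.variable_sds)
        if not self.scenarios:
            # Default three-scenario study: a mild mid-Holocene-like warming,
            # a glacial cooling with wetter winters, and a warm/dry
            # last-interglacial analogue (+3.8 on temperature variables,
            # -16% on precipitation variables).
            def _shift(temp_offset: float, precip_factor: float) -> dict:
                return {"offset": [temp_offset if t else 0.0 for t in is_temp],
                        "factor": [1.0 if t else precip_factor for t in is_temp]}

            self.scenarios = {
                "mis1": _shift(1.0, 1.05),
                "mis2": _shift(-5.0, 1.2),
                "mis5e": _shift(3.8, 0.84),
            }
        if not self.n_fossil:
            self.n_fossil = {name: n for name, n in
                             zip(self.scenarios, (28, 16, 13))}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(data)
        for key in ("variable_names", "variable_means", "variable_sds",
                    "niche_optimum", "niche_tolerance"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        if "model_rows" in payload:
            payload["model_rows"] = tuple(tuple(r) for r in payload["model_rows"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class Study:
    """Materialized study: one stack and one occurrence set per scenario."""

    stacks: dict[str, ClimateStack]
    occurrences: dict[str, OccurrenceSet]     # thinned presences / fossils
    truth: dict[str, syn.NicheTruth]
    reference: str = "current"

    @property
    def paleo_names(self) -> list[str]:
        return [n for n in self.stacks if n != self.reference]


def build_synthetic_study(config: RunConfig) -> Study:
    """Generate climates, truths and thinned occurrence sets for all scenarios."""
    base_cfg = syn.ScenarioConfig(
        grid_rows=config.grid_rows, grid_cols=config.grid_cols,
        variable_names=tuple(config.variable_names),
        autocorr_length=config.autocorr_length,
        variable_means=np.array(config.variable_means),
        variable_sds=np.array(config.variable_sds),
        seed=stage_seed(config.master_seed, "climate"),
        scenario_id="current",
    )
    current = syn.generate_climate_stack(base_cfg)
    stacks = {"current": current}
    truth0 = syn.NicheTruth(np.array(config.niche_optimum),
                            np.array(config.niche_tolerance),
                            config.max_prevalence)
    truths = {"current": truth0}
    for name, shift in config.scenarios.items():
        spec = syn.ShiftSpec(np.asarray(shift["offset"], float),
                             np.asarray(shift["factor"], float))
        stacks[name] = syn.shift_scenario(current, spec, scenario_id=name)
        truths[name] = (truth0.shifted(config.niche_shift[name])
                        if name in config.niche_shift else truth0)

    occurrences: dict[str, OccurrenceSet] = {}
    suit0 = syn.true_suitability(current, truth0)
    occurrences["current"] = thin_to_grid(
        syn.sample_occurrences(suit0, config.n_presence,
                               stage_seed(config.master_seed, "occ:current"),
                               role="presence", period="current"),
        config.thin_cell_size)
    for name in config.scenarios:
        suit = syn.true_suitability(stacks[name], truths[name])
        occurrences[name] = thin_to_grid(
            syn.sample_occurrences(suit, config.n_fossil[name],
                                   stage_seed(config.master_seed, f"occ:{name}"),
                                   role="fossil", period=name),
            config.thin_cell_size)
    return Study(stacks, occurrences, truths)


def _fit_for_row(algorithm: str, config: RunConfig, seed: int):
    if algorithm == "glm_poly":
        return lambda t: gm.fit_glm(t, degree=config.glm_degree)
    if algorithm == "random_forest":
        return lambda t: gm.fit_rf(t, n_trees=config.rf_trees, seed=seed)
    if algorithm == "maxent_like":
        return lambda t: gm.fit_maxent_like(t, reg_multiplier=config.reg_multiplier)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _contrast_sample(stack: ClimateStack, presences: OccurrenceSet,
                     contrast_kind: str, config: RunConfig, seed: int) -> OccurrenceSet:
    if contrast_kind == "background":
        return gm.sample_background(stack, config.background_fraction, seed,
                                    period=stack.scenario_id)
    return gm.sample_pseudoabsences(stack, presences, seed=seed,
                                    period=stack.scenario_id)


def _calibrate_rows(study: Study, calibration: str, config: RunConfig,
                    targets: list[str], seed_tag: str) -> list[dict]:
    """Fit each (algorithm, contrast) row in one scenario; project to targets."""
    stack = study.stacks[calibration]
    presences = study.occurrences[calibration]
    rows = []
    for algorithm, contrast_kind in config.model_rows:
        tag = f"{seed_tag}:{calibration}:{algorithm}:{contrast_kind}"
        contrast = _contrast_sample(stack, presences, contrast_kind, config,
                                    stage_seed(config.master_seed, tag + ":contrast"))
        table = gm.build_training_table(stack, presences, contrast)
        fitter = _fit_for_row(algorithm, config,
                              stage_seed(config.master_seed, tag + ":fit"))
        model = fitter(table)
        report = gm.bootstrap_validate(
            fitter, table, iterations=config.bootstrap_iterations,
            test_fraction=config.test_fraction,
            seed=stage_seed(config.master_seed, tag + ":boot"))
        row = {
            "calibration": calibration,
            "algorithm": algorithm,
            "contrast": contrast_kind,
            "fit_metric_name": model.fit_metric[0],
            "fit_metric": round(model.fit_metric[1], 6),
            "auc_internal_mean": round(report.auc_internal_mean, 6),
            "auc_internal_sd": round(report.auc_internal_sd, 6),
            "auc_external": {},
            "importance": ({k: round(v, 6) for k, v in model.importance.items()}
                           if model.importance else None),
        }
        for target in targets:
            tstack = study.stacks[target]
            suit = gm.project(model, tstack, clamp=True)
            eval_contrast = gm.sample_background(
                tstack, config.background_fraction,
                stage_seed(config.master_seed, tag + f":extbg:{target}"),
                period=target)
            auc_ext = gm.external_validate(suit, study.occurrences[target],
                                           eval_contrast)
            row["auc_external"][target] = round(auc_ext, 6)
        rows.append(row)
    return rows


def run_geographic(study: Study, config: RunConfig) -> dict:
    """The SDM-transferability track.

    Returns a report with a ``forward`` table (calibrated in the reference
    scenario, transferred to each paleo scenario, validated with its
    independent presences), a ``cross_projection`` table (calibrated in each
    paleo scenario, transferred back, validated with the reference
    presences) and per-target MESS summaries for the reference models.
    """
    ref = study.reference
    forward = _calibrate_rows(study, ref, config, study.paleo_names, "geo")
    cross = []
    for name in study.paleo_names:
        cross.extend(_calibrate_rows(study, name, config, [ref], "geo"))

    # MESS of each paleo scenario against the reference training environment
    stack = study.stacks[ref]
    presences = study.occurrences[ref]
    contrast = _contrast_sample(stack, presences, "background", config,
                                stage_seed(config.master_seed, "geo:mess:bg"))
    reference_table = gm.build_training_table(stack, presences, contrast)
    mess_summary = {}
    for name in study.paleo_names:
        result = gm.mess(study.stacks[name], reference_table)
        ok = ~result.nodata_mask
        novel = float((result.mess[ok] < 0).mean())
        counts = {v: int((result.mod[ok] == j).sum())
                  for j, v in enumerate(result.variable_names)}
        mess_summary[name] = {"fraction_novel": round(novel, 6),
                              "mod_cell_counts": counts}
    return {"forward": forward, "cross_projection": cross, "mess": mess_summary}


def run_environmental(study: Study, config: RunConfig) -> list[es.OverlapReport]:
    """The niche-overlap track: one report per (reference, paleo) pair."""
    pca = es.fit_global_pca(list(study.stacks.values()))
    ref = study.reference

    def _env(name: str, occ: OccurrenceSet) -> np.ndarray:
        x, y = occ.xy
        return study.stacks[name].env_at_points(x, y, pca.variable_names)

    def _bg_env(name: str, seed: int) -> np.ndarray:
        env = study.stacks[name].env_table(pca.variable_names)
        if len(env) > config.env_background_cells:
            rng = np.random.default_rng(seed)
            env = env[rng.choice(len(env), config.env_background_cells, replace=False)]
        return env

    ref_occ_env = _env(ref, study.occurrences[ref])
    ref_bg_env = _bg_env(ref, stage_seed(config.master_seed, "env:bg:ref"))
    reports = []
    for name in study.paleo_names:
        occ_env = _env(name, study.occurrences[name])
        bg_env = _bg_env(name, stage_seed(config.master_seed, f"env:bg:{name}"))
        extent = es.shared_extent([pca.transform(ref_bg_env), pca.transform(bg_env)])
        grid_ref = es.grid_from_scores(pca.transform(ref_occ_env),
                                       pca.transform(ref_bg_env), extent,
                                       config.env_resolution,
                                       entity_id=ref, scenario_id=ref)
        grid_pal = es.grid_from_scores(pca.transform(occ_env),
                                       pca.transform(bg_env), extent,
                                       config.env_resolution,
                                       entity_id=name, scenario_id=name)
        d = es.schoener_d(grid_ref, grid_pal, corrected=config.env_corrected)
        _, eq_p, _ = es.equivalency_test(
            ref_occ_env, occ_env, ref_bg_env, bg_env, pca,
            replicates=config.env_replicates,
            seed=stage_seed(config.master_seed, f"env:eq:{name}"),
            resolution=config.env_resolution, corrected=config.env_corrected)
        _, sim_ab, _ = es.similarity_test(
            grid_ref, occ_env, bg_env, pca, replicates=config.env_replicates,
            seed=stage_seed(config.master_seed, f"env:simAB:{name}"),
            null_model=config.similarity_null, corrected=config.env_corrected)
        _, sim_ba, _ = es.similarity_test(
            grid_pal, ref_occ_env, ref_bg_env, pca,
            replicates=config.env_replicates,
            seed=stage_seed(config.master_seed, f"env:simBA:{name}"),
            null_model=config.similarity_null, corrected=config.env_corrected)
        expansion, stability, unfilling = es.niche_dynamics(grid_ref, grid_pal)
        occ_shift, env_shift = es.centroid_shift(grid_ref, grid_pal)
        reports.append(es.OverlapReport(
            entity_a=ref, entity_b=name, D=round(d, 6),
            equivalency_p=eq_p, similarity_p_AtoB=sim_ab, similarity_p_BtoA=sim_ba,
            expansion=expansion, stability=1.0 - expansion, unfilling=unfilling,
            n_replicates=config.env_replicates,
            occ_centroid_shift=(round(float(occ_shift[0]), 6),
                                round(float(occ_shift[1]), 6)),
            env_centroid_shift=(round(float(env_shift[0]), 6),
                                round(float(env_shift[1]), 6)),
        ))
    return reports


def run_all(config: RunConfig) -> dict:
    """Build the synthetic study and run both tracks; optionally write reports."""
    study = build_synthetic_study(config)
    geographic = run_geographic(study, config)
    environmental = [r.as_dict() for r in run_environmental(study, config)]
    report = {"config_seed": config.master_seed,
              "geographic": geographic,
              "environmental": environmental}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(geographic, out / "geographic_report.json")
        write_report({"rows": environmental}, out / "environmental_report.json")
        write_report(report, out / "full_report.json")
    return report
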