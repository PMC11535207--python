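"""End-to-end orchestration: simulate → natal → steps → fit → metrics → CV.

A run is driven by a :class:`RunConfig` (constructible from YAML) and a
master seed.  Per-stage random streams are derived by hashing
(master seed, stage name, individual id), so adding an individual does
not perturb the draws of the others, and a rerun with the same config
and seed is bit-identical.  Every stage writes CSV/JSON outputs and the
run ends with a manifest recording configuration, seeds and per-stage
record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .clogit import FitResult, fit_clogit, fit_phase_interaction, fit_yearly, kfold_cv
from .landscape import write_landscape
from .metrics import ALL_METRICS, PAIR_METRICS, POINT_METRICS, propagate_uncertainty
from .natal import assign_natal_habitats, compute_score_grid
from .steps import (
    build_design,
    build_steps,
    fit_step_length_distribution,
    resample_track,
    speed_filter,
    standardize,
)
from .synthetic import (
    DEFAULT_STEP_RATE,
    LandscapeConfig,
    SimIndividual,
    TrackSegment,
    generate_landscape,
    place_nests,
    simulate_track,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str, individual: str = "") -> int:
    """Deterministic per-stage (and per-individual) seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{individual}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Defaults mirror the analysis conditions: 2 km buffers, 10
    available steps per stratum, hourly resampling with a 15-min
    window, a 35 m/s speed filter, 2 retained PCs, 1000 uncertainty
    replicates and 5 CV folds.
    """

    # paths (None => synthetic mode)
    tracks_path: str | None = None
    nests_path: str | None = None
    elevation_path: str | None = None
    land_cover_path: str | None = None
    out_dir: str = "nhpikit_run"
    # analysis parameters
    buffer_radius: float = 2000.0
    n_avail: int = 10
    resample_interval: float = 3600.0
    resample_tolerance: float = 900.0
    vmax: float = 35.0
    k_retained: int = 2
    n_clusters: int | str = "auto"
    n_sim: int = 1000
    cv_folds: int = 5
    # synthetic-mode parameters
    nest_spacing: float = 1000.0
    n_individuals: int = 20
    n_steps_prospecting: int = 300
    n_steps_settlement: int = 200
    n_prospecting_years: int = 2
    beta_dissim_mean: float = -0.5
    beta_dissim_sd: float = 0.5
    beta_dist_mean: float = -0.2
    beta_dist_sd: float = 0.1
    step_rate: float = DEFAULT_STEP_RATE
    n_candidates: int = 50
    landscape: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in (
            "buffer_radius",
            "n_avail",
            "resample_interval",
            "resample_tolerance",
            "vmax",
            "k_retained",
            "n_sim",
            "cv_folds",
        ):
            if not (float(getattr(self, name)) > 0):
                raise ValueError(f"config parameter {name} must be positive")
        for name in ("tracks_path", "nests_path", "elevation_path", "land_cover_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def simulate_individuals(config: RunConfig) -> list[SimIndividual]:
    """Ground-truth cohort for synthetic mode (raw-scale coefficients)."""
    rng = np.random.default_rng(stage_seed(config.seed, "betas"))
    individuals = []
    for i in range(config.n_individuals):
        b_dis = rng.normal(config.beta_dissim_mean, config.beta_dissim_sd)
        b_dst = rng.normal(config.beta_dist_mean, config.beta_dist_sd)
        b_dis_s = rng.normal(config.beta_dissim_mean, config.beta_dissim_sd)
        segments = [
            TrackSegment("prospecting", y + 1, config.n_steps_prospecting, b_dis, b_dst)
            for y in range(config.n_prospecting_years)
        ]
        if config.n_steps_settlement:
            segments.append(
                TrackSegment(
                    "settlement",
                    config.n_prospecting_years + 1,
                    config.n_steps_settlement,
                    b_dis_s,
                    b_dst,
                )
            )
        individuals.append(
            SimIndividual(
                id=f"id{i:03d}",
                nest=(np.nan, np.nan),
                true_beta_dissim=b_dis,
                true_beta_dist=b_dst,
                segments=segments,
            )
        )
    return individuals


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    t0 = time.time()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(config).items()}, "stages": {}}
    seed = config.seed

    # --- landscape + nests -------------------------------------------------
    if config.elevation_path and config.land_cover_path:
        landscape = nio.read_raster(config.elevation_path, config.land_cover_path)
    else:
        landscape = generate_landscape(
            LandscapeConfig(**config.landscape), seed=stage_seed(seed, "landscape")
        )
        write_landscape(landscape, out)
    if config.nests_path:
        nest_df = nio.read_nests(config.nests_path)
    else:
        nest_df = place_nests(
            landscape,
            config.n_individuals,
            spacing_min=config.nest_spacing,
            seed=stage_seed(seed, "nests"),
            edge_buffer=config.buffer_radius,
        )
        nest_df.to_csv(out / "nests.csv", index=False)
    nests = {
        str(r.individual): (float(r.nest_x), float(r.nest_y))
        for r in nest_df.itertuples()
    }

    # --- natal stage -------------------------------------------------------
    assignments, pca = assign_natal_habitats(
        landscape, nests, radius=config.buffer_radius,
        k=config.n_clusters, k_retained=config.k_retained,
    )
    pca.to_json(out / "pca_model.json")
    natal_df = pd.DataFrame(
        [
            {
                "individual": a.individual,
                **dict(zip(pca.variable_names, a.habitat.as_array())),
                "pc1": a.scores[0],
                "pc2": a.scores[1],
                "cluster": a.cluster,
            }
            for a in assignments
        ]
    )
    natal_df.to_csv(out / "natal_assignments.csv", index=False)
    by_id = {a.individual: a for a in assignments}
    score_grid = compute_score_grid(landscape, pca, radius=config.buffer_radius)
    manifest["stages"]["natal"] = {
        "n_individuals": len(assignments),
        "n_clusters": int(natal_df["cluster"].nunique()),
        "pc_variance_fraction": pca.explained_variance_fraction[:2].tolist(),
    }

    # --- tracks ------------------------------------------------------------
    if config.tracks_path:
        tracks = nio.read_tracks(config.tracks_path)
        truth = None
    else:
        individuals = simulate_individuals(config)
        tracks = []
        truth_rows = []
        for ind in individuals:
            ind.nest = nests[ind.id]
            tracks.append(
                simulate_track(
                    landscape,
                    score_grid,
                    ind,
                    by_id[ind.id].scores,
                    step_rate=config.step_rate,
                    n_candidates=config.n_candidates,
                    seed=stage_seed(seed, "track", ind.id),
                )
            )
            for segment in ind.segments:
                truth_rows.append(
                    {
                        "individual": ind.id,
                        "phase": segment.phase,
                        "year": segment.year,
                        "beta_dissim_raw": segment.beta_dissim,
                        "beta_dist_raw": segment.beta_dist,
                    }
                )
        truth = pd.DataFrame(truth_rows)
        truth.to_csv(out / "true_coefficients.csv", index=False)
        nio.write_tracks(tracks, out / "tracks.csv")
    manifest["stages"]["tracks"] = {"n_tracks": len(tracks), "n_fixes": sum(len(t) for t in tracks)}

    # --- steps + design ----------------------------------------------------
    all_steps = []
    n_removed = 0
    for tr in tracks:
        res = resample_track(tr, config.resample_interval, config.resample_tolerance)
        filt = speed_filter(res, config.vmax)
        n_removed += len(res) - len(filt)
        all_steps.append(build_steps(filt))
    steps_df = pd.concat(all_steps, ignore_index=True)
    rate = fit_step_length_distribution(steps_df["length"].to_numpy())
    designs = []
    for tr, stp in zip(tracks, all_steps):
        designs.append(
            build_design(
                stp,
                score_grid,
                by_id[tr.individual],
                rate,
                n_avail=config.n_avail,
                seed=stage_seed(seed, "avail", tr.individual),
            )
        )
    design = pd.concat(designs, ignore_index=True)
    design.to_csv(out / "design.csv", index=False)
    manifest["stages"]["steps"] = {
        "n_used_steps": int(len(steps_df)),
        "fixes_removed_by_speed_filter": int(n_removed),
        "pooled_exponential_rate_per_m": rate,
        "n_strata": int(design["stratum"].nunique()),
        "n_design_rows": int(len(design)),
    }

    # --- per individual-year fits ------------------------------------------
    covz = ["dissimilarity_z", "distance_z"]
    fits: list[FitResult] = []
    records = []
    for (ind, year, phase), sub in design.groupby(["individual", "year", "phase"]):
        try:
            std, scaling = standardize(sub)
        except ValueError:
            continue
        fit = fit_clogit(std, covz, individual=ind, label=f"{phase}:{year}")
        fits.append(fit)
        records.append(
            {
                "individual": ind,
                "year": int(year),
                "phase": phase,
                "cluster": by_id[ind].cluster,
                "x": fit.nhpi,
                "se": fit.stderr("dissimilarity_z"),
                "converged": fit.converged,
                "beta_dissim_raw": scaling.back_transform(
                    "dissimilarity", fit.coef("dissimilarity_z")
                ),
                "beta_dist_raw": scaling.back_transform("distance", fit.coef("distance_z")),
                "sd_dissimilarity": scaling.sds["dissimilarity"],
                "sd_distance": scaling.sds["distance"],
            }
        )
    nio.write_coefficients(fits, out / "coefficients.csv")
    records_df = pd.DataFrame(records)
    records_df.to_csv(out / "nhpi_records.csv", index=False)
    manifest["stages"]["fits"] = {
        "n_models": len(fits),
        "n_converged": int(sum(f.converged for f in fits)),
    }

    # --- phase / year interaction fits -------------------------------------
    phase_rows = []
    year_rows = []
    for ind, sub in design.groupby("individual"):
        phases = set(sub["phase"])
        if {"prospecting", "settlement"} <= phases:
            last_p = sub.loc[sub["phase"] == "prospecting", "year"].max()
            first_s = sub.loc[sub["phase"] == "settlement", "year"].min()
            window = sub[
                ((sub["phase"] == "prospecting") & (sub["year"] == last_p))
                | ((sub["phase"] == "settlement") & (sub["year"] == first_s))
            ]
            std, _ = standardize(window)
            per_phase = fit_phase_interaction(std, covz, individual=ind)
            for phase, fit in per_phase.items():
                phase_rows.append(
                    {
                        "individual": ind,
                        "phase": phase,
                        "cluster": by_id[ind].cluster,
                        "x": fit.nhpi,
                        "se": fit.stderr("dissimilarity_z"),
                        "converged": fit.converged,
                    }
                )
        pros = sub[sub["phase"] == "prospecting"]
        if pros["year"].nunique() >= 2:
            std, _ = standardize(pros)
            per_year = fit_yearly(std, covz, individual=ind)
            for year, fit in per_year.items():
                year_rows.append(
                    {
                        "individual": ind,
                        "year": int(year),
                        "cluster": by_id[ind].cluster,
                        "x": fit.nhpi,
                        "se": fit.stderr("dissimilarity_z"),
                        "converged": fit.converged,
                    }
                )
    phase_df = pd.DataFrame(phase_rows)
    yearly_df = pd.DataFrame(year_rows)
    phase_df.to_csv(out / "phase_coefficients.csv", index=False)
    yearly_df.to_csv(out / "yearly_coefficients.csv", index=False)
    manifest["stages"]["interactions"] = {
        "n_phase_pairs": int(phase_df["individual"].nunique()) if len(phase_df) else 0,
        "n_yearly_individuals": int(yearly_df["individual"].nunique()) if len(yearly_df) else 0,
    }

    # --- metrics with uncertainty ------------------------------------------
    dists = propagate_uncertainty(
        records_df.assign(phase=records_df["phase"]),
        metrics=POINT_METRICS,
        n_sim=config.n_sim,
        seed=stage_seed(seed, "metrics"),
        by=["cluster", "phase"],
    )
    dists += propagate_uncertainty(
        records_df, metrics=POINT_METRICS, n_sim=config.n_sim,
        seed=stage_seed(seed, "metrics-pooled"),
    )
    if len(phase_df):
        dists += propagate_uncertainty(
            phase_df, metrics=PAIR_METRICS, n_sim=config.n_sim,
            seed=stage_seed(seed, "metrics-phase"),
        )
    if len(yearly_df):
        dists += propagate_uncertainty(
            yearly_df, metrics=("interannual_consistency",), n_sim=config.n_sim,
            seed=stage_seed(seed, "metrics-yearly"),
        )
    metrics_df = pd.DataFrame([d.summary() for d in dists])
    metrics_df.to_csv(out / "metrics.csv", index=False)
    manifest["stages"]["metrics"] = {"n_metric_groups": len(dists)}

    # --- cross-validation ---------------------------------------------------
    cv_rows = []
    for (ind, year, phase), sub in design.groupby(["individual", "year", "phase"]):
        if sub["stratum"].nunique() < config.cv_folds:
            continue
        std, _ = standardize(sub)
        mean_rho, sd_rho, _ = kfold_cv(
            std, covz, k=config.cv_folds,
            seed=np.random.default_rng(stage_seed(seed, "cv", f"{ind}:{year}:{phase}")),
        )
        cv_rows.append(
            {"individual": ind, "year": int(year), "phase": phase,
             "mean_rho": mean_rho, "sd_rho": sd_rho}
        )
    cv_df = pd.DataFrame(cv_rows)
    cv_df.to_csv(out / "cv_report.csv", index=False)
    manifest["stages"]["cv"] = {
        "n_models": len(cv_df),
        "mean_rho": float(cv_df["mean_rho"].mean()) if len(cv_df) else float("nan"),
    }

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    manifest["seed"] = seed
    from . import __version__

    manifest["version"] = __version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
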