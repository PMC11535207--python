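"""Self-contained validation studies on synthetic data.

These are the package's ground-truth experiments: simulate trajectories
under known selection coefficients, run the full analysis chain
(landscape → natal PCA → step design → conditional logit) and measure
how well the truth is recovered.  Simulation coefficients are specified
on the raw covariate scale; the standardised-scale truth for each
individual is beta_raw x SD(covariate) over that individual's design
(the analysis standardises per model dataset).

The default raw effect sizes (−0.65 / 0 / +0.25 for dissimilarity,
−0.25 km⁻¹ for distance) are calibrated once against the default
landscape so the standardised-scale magnitudes are about ±1 and −0.5 —
i.e. effects of the order reported for strong habitat selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clogit import fit_clogit, kfold_cv
from .natal import assign_natal_habitats, compute_score_grid
from .pipeline import stage_seed
from .steps import build_design, build_steps, standardize
from .synthetic import (
    DEFAULT_STEP_RATE,
    LandscapeConfig,
    SimIndividual,
    generate_landscape,
    place_nests,
    simulate_track,
)

#: Raw-scale dissimilarity coefficients cycled across individuals.
RECOVERY_BETAS_DISSIM = (-0.65, 0.0, 0.25)
RECOVERY_BETA_DIST = -0.25

COVARIATES_Z = ["dissimilarity_z", "distance_z"]


@dataclass
class StudyContext:
    """One landscape + nest cohort + fitted natal stage."""

    landscape: object
    nests: dict
    by_id: dict
    pca: object
    score_grid: object


def build_context(seed: int, n_individuals: int, n_rows: int = 120, n_cols: int = 120) -> StudyContext:
    land = generate_landscape(
        LandscapeConfig(n_rows=n_rows, n_cols=n_cols), seed=stage_seed(seed, "landscape")
    )
    nest_df = place_nests(land, n_individuals, spacing_min=1000.0, seed=stage_seed(seed, "nests"))
    nests = {r.individual: (r.nest_x, r.nest_y) for r in nest_df.itertuples()}
    assignments, pca = assign_natal_habitats(land, nests)
    grid = compute_score_grid(land, pca)
    return StudyContext(land, nests, {a.individual: a for a in assignments}, pca, grid)


def _fit_one(ctx: StudyContext, iid: str, beta_dissim: float, beta_dist: float,
             n_steps: int, seed: int, n_avail: int = 10):
    ind = SimIndividual(
        id=iid, nest=ctx.nests[iid],
        true_beta_dissim=beta_dissim, true_beta_dist=beta_dist, n_steps=n_steps,
    )
    track = simulate_track(
        ctx.landscape, ctx.score_grid, ind, ctx.by_id[iid].scores,
        step_rate=DEFAULT_STEP_RATE, seed=stage_seed(seed, "track", iid),
    )
    design = build_design(
        build_steps(track), ctx.score_grid, ctx.by_id[iid], DEFAULT_STEP_RATE,
        n_avail=n_avail, seed=stage_seed(seed, "avail", iid),
    )
    std, scaling = standardize(design)
    fit = fit_clogit(std, COVARIATES_Z, individual=iid)
    return std, scaling, fit


def parameter_recovery_study(
    seed: int = 0,
    n_individuals: int = 50,
    n_steps: int = 1000,
    betas_dissim: tuple = RECOVERY_BETAS_DISSIM,
    beta_dist: float = RECOVERY_BETA_DIST,
) -> pd.DataFrame:
    """Simulate, refit, and report per-individual recovery diagnostics.

    Returns one row per individual with standardised-scale truth and
    estimate, Wald 95% CI coverage indicators and raw-scale back
    transforms.
    """
    ctx = build_context(seed, n_individuals)
    rows = []
    for i, iid in enumerate(ctx.nests):
        b_dis = betas_dissim[i % len(betas_dissim)]
        std, scaling, fit = _fit_one(ctx, iid, b_dis, beta_dist, n_steps, seed)
        sd_dis = scaling.sds["dissimilarity"]
        sd_dst = scaling.sds["distance"]
        tz_dis = b_dis * sd_dis
        tz_dst = beta_dist * sd_dst
        bz_dis, se_dis = fit.coef("dissimilarity_z"), fit.stderr("dissimilarity_z")
        bz_dst, se_dst = fit.coef("distance_z"), fit.stderr("distance_z")
        rows.append(
            {
                "individual": iid,
                "beta_dissim_raw_true": b_dis,
                "beta_dissim_z_true": tz_dis,
                "beta_dissim_z_hat": bz_dis,
                "se_dissim_z": se_dis,
                "covered_dissim": abs(bz_dis - tz_dis) <= 1.96 * se_dis,
                "beta_dist_z_true": tz_dst,
                "beta_dist_z_hat": bz_dst,
                "se_dist_z": se_dst,
                "covered_dist": abs(bz_dst - tz_dst) <= 1.96 * se_dst,
                "beta_dissim_raw_hat": bz_dis / sd_dis,
                "beta_dist_raw_hat": bz_dst / sd_dst,
                "converged": fit.converged,
                "n_strata": fit.n_strata,
            }
        )
    return pd.DataFrame(rows)


def recovery_summary(recovery: pd.DataFrame) -> dict:
    """Bias and coverage aggregates of a recovery-study table."""
    dev = recovery["beta_dissim_z_hat"] - recovery["beta_dissim_z_true"]
    coverage = np.concatenate(
        [recovery["covered_dissim"].to_numpy(), recovery["covered_dist"].to_numpy()]
    )
    return {
        "bias_dissim_z": float(dev.mean()),
        "bias_dissim_raw": float(
            (recovery["beta_dissim_raw_hat"] - recovery["beta_dissim_raw_true"]).mean()
        ),
        "coverage_95": float(coverage.mean()),
        "n_individuals": int(len(recovery)),
    }


def cv_study(
    seed: int = 0,
    beta_dissim: float = 0.0,
    beta_dist: float = 0.0,
    n_replicates: int = 50,
    n_steps: int = 200,
    n_individuals: int = 8,
    k: int = 5,
) -> pd.DataFrame:
    """k-fold CV Spearman (and permutation-null beta) over replicates.

    Each replicate simulates one fresh track under the given raw-scale
    coefficients, builds its design, runs k-fold CV, and refits the
    model after shuffling the used labels within every stratum.
    """
    ctx = build_context(seed, n_individuals)
    ids = list(ctx.nests)
    rows = []
    for rep in range(n_replicates):
        iid = ids[rep % len(ids)]
        std, _, _ = _fit_one(ctx, iid, beta_dissim, beta_dist, n_steps, seed + 1000 + rep)
        rng = np.random.default_rng(stage_seed(seed, "cvrep", str(rep)))
        rho, _, _ = kfold_cv(std, COVARIATES_Z, k=k, seed=rng)
        perm = std.copy()
        new_used = np.zeros(len(perm), dtype=bool)
        for _, idx in perm.groupby("stratum").indices.items():
            new_used[rng.choice(idx)] = True
        perm["is_used"] = new_used
        pfit = fit_clogit(perm, COVARIATES_Z)
        rows.append(
            {"replicate": rep, "cv_rho": rho, "perm_beta_dissim_z": pfit.coef("dissimilarity_z")}
        )
    return pd.DataFrame(rows)
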