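"""Synthetic landscapes, nests and trajectories with known selection.

The generator provides ground truth for every downstream stage:

* a landscape whose elevation rises along one axis (linear gradient +
  smoothed Gaussian noise) and whose land cover is drawn from
  elevation-dependent class probabilities, then modal-smoothed into
  patches — urban/arable frequent at low elevation, grassland/mosaic at
  high elevation, so that several distinguishable natal habitat types
  exist;
* nests stratified across the elevation gradient with a minimum
  spacing, kept one buffer radius clear of the raster edge;
* hourly trajectories generated by a step-selection process: at each
  step, ``n_candidates`` proposals (length ~ Exponential, turn ~
  Uniform(−π, π)) are scored by exp(β_dissim·dissimilarity +
  β_dist·distance) and one is chosen by softmax sampling.  The
  covariates are computed by the same score-grid machinery the analysis
  uses, so the fitted conditional logit is correctly specified by
  construction.

Simulation coefficients are defined on the RAW covariate scale
(dissimilarity in PC-space units, distance in km); the analysis
standardises per model dataset, so the standardised-scale truth for an
individual is beta_raw × SD(covariate) over that individual's design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter

from .landscape import LAND_COVER_CLASSES, LandscapeRaster
from .natal import DEFAULT_BUFFER_RADIUS, PCAModel, ScoreGrid
from .steps import Track, compute_distance

DEFAULT_STEP_RATE = 1.0 / 2000.0  # 1/m: mean hourly step of 2 km


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class PlacementError(RuntimeError):
    """Nest placement could not satisfy the spacing constraint."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved} of {requested} nests under the spacing constraint"
        )


class SimulationError(RuntimeError):
    """Trajectory simulation failed (e.g. proposals repeatedly out of bounds)."""


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    ``gradient`` is the total elevation rise (m) from the bottom to the
    top edge; ``noise_sd``/``noise_scale`` control the smoothed
    Gaussian perturbation; ``mixing`` in [0, 1] flattens the
    elevation-dependence of the class probabilities (1 = spatially
    homogeneous mixture); ``smooth_passes`` modal-smoothing rounds
    creating land-cover patches.
    """

    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 100.0
    base_elevation: float = 500.0
    gradient: float = 600.0  # m rise over the grid, emulating 532-1084 m nests
    noise_sd: float = 40.0
    noise_scale: float = 3.0  # cells
    mixing: float = 0.0
    smooth_passes: int = 2


# Elevation niche of each class: (centre on the 0-1 gradient, width, weight).
_CLASS_NICHES = {
    "arable": (0.15, 0.25, 1.2),
    "grassland": (0.65, 0.30, 1.0),
    "forest": (0.45, 0.35, 1.0),
    "urban": (0.08, 0.15, 0.8),
    "water": (0.05, 0.12, 0.4),
    "mosaic": (0.90, 0.20, 1.2),
}


def generate_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> LandscapeRaster:
    """Deterministic synthetic landscape for a given seed and config."""
    config = config or LandscapeConfig()
    if config.n_rows < 50 or config.n_cols < 50:
        raise ConfigurationError("grid must be at least 50x50 cells")
    rng = np.random.default_rng(seed)
    rows = np.arange(config.n_rows)
    frac = rows / max(config.n_rows - 1, 1)  # 0 at bottom, 1 at top
    elevation = config.base_elevation + config.gradient * frac[:, None]
    elevation = elevation + gaussian_filter(
        rng.normal(0, config.noise_sd, (config.n_rows, config.n_cols)),
        config.noise_scale,
        mode="nearest",
    )
    elevation = np.broadcast_to(elevation, (config.n_rows, config.n_cols)).copy()

    # elevation-dependent class probabilities, flattened by `mixing`
    e_norm = np.clip(
        (elevation - config.base_elevation) / config.gradient if config.gradient else
        np.full_like(elevation, 0.5),
        0,
        1,
    )
    weights = np.empty((len(LAND_COVER_CLASSES),) + elevation.shape)
    for i, cls in enumerate(LAND_COVER_CLASSES):
        centre, width, amp = _CLASS_NICHES[cls]
        weights[i] = amp * np.exp(-0.5 * ((e_norm - centre) / width) ** 2)
    weights = (1 - config.mixing) * weights + config.mixing * weights.mean(
        axis=(1, 2), keepdims=True
    )
    probs = weights / weights.sum(axis=0, keepdims=True)
    u = rng.random(elevation.shape)
    cum = np.cumsum(probs, axis=0)
    land_cover = (u[None] > cum).sum(axis=0)

    for _ in range(config.smooth_passes):
        land_cover = _modal_smooth(land_cover)
    return LandscapeRaster(
        x0=0.0,
        y0=0.0,
        cell_size=config.cell_size,
        elevation=elevation,
        land_cover=land_cover,
    )


def _modal_smooth(land_cover: np.ndarray) -> np.ndarray:
    """3x3 majority filter (ties broken by class order) to form patches."""
    votes = np.stack(
        [
            uniform_filter((land_cover == c).astype(float), size=3, mode="nearest")
            for c in range(len(LAND_COVER_CLASSES))
        ]
    )
    return votes.argmax(axis=0)


def place_nests(
    landscape: LandscapeRaster,
    n_individuals: int,
    spacing_min: float = 2000.0,
    seed: int = 0,
    edge_buffer: float = DEFAULT_BUFFER_RADIUS,
    max_attempts: int = 200,
) -> pd.DataFrame:
    """Nests stratified across the elevation gradient, min spacing apart.

    Candidate cells at least ``edge_buffer`` from the raster edge are
    binned into ``n_individuals`` elevation strata; one nest is drawn
    per stratum subject to the pairwise spacing constraint.  Raises
    :class:`PlacementError` (reporting the achieved count) when the
    raster cannot host the requested configuration.
    """
    if n_individuals < 1:
        raise ConfigurationError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    cs = landscape.cell_size
    margin_cells = int(np.ceil(edge_buffer / cs))
    rows, cols = np.mgrid[0 : landscape.n_rows, 0 : landscape.n_cols]
    interior = (
        (rows >= margin_cells)
        & (rows < landscape.n_rows - margin_cells)
        & (cols >= margin_cells)
        & (cols < landscape.n_cols - margin_cells)
    )
    if not interior.any():
        raise PlacementError(n_individuals, 0)
    cand_r, cand_c = rows[interior], cols[interior]
    elev = landscape.elevation[cand_r, cand_c]
    order = np.argsort(elev, kind="stable")
    strata = np.array_split(order, n_individuals)

    for _ in range(max_attempts):
        placed: list[tuple[float, float, float]] = []
        ok = True
        for stratum in strata:
            found = False
            for _ in range(100):
                pick = stratum[rng.integers(len(stratum))]
                x, y = landscape.cell_center(cand_r[pick], cand_c[pick])
                if all(np.hypot(x - px, y - py) >= spacing_min for px, py, _ in placed):
                    placed.append((float(x), float(y), float(elev[pick])))
                    found = True
                    break
            if not found:
                ok = False
                break
        if ok:
            return pd.DataFrame(
                {
                    "individual": [f"id{i:03d}" for i in range(n_individuals)],
                    "nest_x": [p[0] for p in placed],
                    "nest_y": [p[1] for p in placed],
                    "elevation": [p[2] for p in placed],
                    "tagging_year": 1,
                }
            )
    raise PlacementError(n_individuals, len(placed))


# ---------------------------------------------------------------------------
# Trajectory simulation


@dataclass
class TrackSegment:
    """One contiguous simulated period with its own labels and betas."""

    phase: str
    year: int
    n_steps: int
    beta_dissim: float | None = None  # None = inherit the individual's
    beta_dist: float | None = None


@dataclass
class SimIndividual:
    """Ground truth for one simulated bird.

    Coefficients are on the RAW covariate scale (see module docstring).
    """

    id: str
    nest: tuple[float, float]
    true_beta_dissim: float
    true_beta_dist: float
    n_steps: int = 0
    segments: list[TrackSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            if self.n_steps < 3:
                raise ConfigurationError("n_steps must be >= 3")
            self.segments = [TrackSegment("prospecting", 1, self.n_steps)]
        else:
            self.n_steps = sum(s.n_steps for s in self.segments)
            if self.n_steps < 3:
                raise ConfigurationError("total n_steps must be >= 3")
        if not (np.isfinite(self.true_beta_dissim) and np.isfinite(self.true_beta_dist)):
            raise ConfigurationError("coefficients must be finite")


def simulate_track(
    landscape: LandscapeRaster,
    score_grid: ScoreGrid,
    individual: SimIndividual,
    natal_scores: np.ndarray,
    step_rate: float = DEFAULT_STEP_RATE,
    n_candidates: int = 50,
    seed: int = 0,
    start_time: np.datetime64 = np.datetime64("2016-03-01T00:00:00"),
    max_rejection_rounds: int = 200,
) -> Track:
    """Hourly trajectory under the step-selection process.

    Each step draws ``n_candidates`` proposals (length ~
    Exponential(step_rate), turn ~ Uniform(−π, π) about the previous
    bearing), rejects/redraws out-of-raster proposals, scores the rest
    with exp(β_dissim·dissimilarity + β_dist·distance) and samples one.
    Deterministic for a fixed seed.
    """
    if n_candidates < 2:
        raise ConfigurationError("n_candidates must be >= 2")
    if not bool(landscape.contains(*individual.nest)):
        raise ConfigurationError(f"nest {individual.nest} outside the raster")
    rng = np.random.default_rng(seed)
    natal_scores = np.asarray(natal_scores, dtype=float)[:2]

    xs = [individual.nest[0]]
    ys = [individual.nest[1]]
    phases: list[str] = []
    years: list[int] = []
    bearing = rng.uniform(-np.pi, np.pi)
    for segment in individual.segments:
        b_dis = segment.beta_dissim if segment.beta_dissim is not None else individual.true_beta_dissim
        b_dst = segment.beta_dist if segment.beta_dist is not None else individual.true_beta_dist
        for _ in range(segment.n_steps):
            cx = np.empty(n_candidates)
            cy = np.empty(n_candidates)
            cb = np.empty(n_candidates)
            filled = 0
            for _round in range(max_rejection_rounds):
                need = n_candidates - filled
                L = rng.exponential(1.0 / step_rate, need)
                turn = rng.uniform(-np.pi, np.pi, need)
                br = bearing + turn
                px = xs[-1] + L * np.cos(br)
                py = ys[-1] + L * np.sin(br)
                ok = landscape.contains(px, py)
                k = int(ok.sum())
                cx[filled : filled + k] = px[ok]
                cy[filled : filled + k] = py[ok]
                cb[filled : filled + k] = br[ok]
                filled += k
                if filled >= n_candidates:
                    break
            else:
                raise SimulationError(
                    f"{individual.id}: proposals repeatedly out of bounds at step "
                    f"{len(xs) - 1}"
                )
            sc = score_grid.scores_at(cx, cy)
            dis = np.hypot(sc[:, 0] - natal_scores[0], sc[:, 1] - natal_scores[1])
            dst = compute_distance(individual.nest, cx, cy)
            logw = b_dis * dis + b_dst * dst
            w = np.exp(logw - logw.max())
            choice = rng.choice(n_candidates, p=w / w.sum())
            if np.hypot(cx[choice] - xs[-1], cy[choice] - ys[-1]) > 0:
                bearing = cb[choice]
            xs.append(float(cx[choice]))
            ys.append(float(cy[choice]))
            phases.append(segment.phase)
            years.append(segment.year)
    n = len(xs)
    times = start_time + np.arange(n).astype("timedelta64[h]")
    # the first fix inherits the first segment's labels
    return Track(
        individual=individual.id,
        times=times.astype("datetime64[s]"),
        x=np.array(xs),
        y=np.array(ys),
        phase=np.array([phases[0]] + phases, dtype=object),
        year=np.array([years[0]] + years, dtype=int),
    )


def simulate_coefficients(
    n_ids: int,
    mean: float,
    sd: float,
    se_scale: float,
    phases: list[str] | None = None,
    seed: int = 0,
    cluster: str = "all",
) -> pd.DataFrame:
    """Bare coefficient table: one record per id × phase.

    Coefficients ~ Normal(mean, sd) with constant standard error
    ``se_scale``; a direct fixture for the variation metrics.
    """
    if sd < 0 or se_scale < 0:
        raise ConfigurationError("sd and se_scale must be >= 0")
    phases = phases or ["prospecting"]
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ids):
        for phase in phases:
            rows.append(
                {
                    "individual": f"id{i:03d}",
                    "year": 1,
                    "phase": phase,
                    "cluster": cluster,
                    "x": rng.normal(mean, sd) if sd > 0 else mean,
                    "se": se_scale,
                }
            )
    return pd.DataFrame(rows)
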