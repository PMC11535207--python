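"""Track regularisation and the used/available step-selection design.

Raw GPS tracks are resampled to an hourly series (greedy burst
regularisation), cleaned with a speed filter, and decomposed into
steps.  Each used step with a defined previous bearing becomes a
stratum: the observed step plus ``n_avail`` random alternatives whose
lengths are drawn from an exponential fitted to the population's
observed step lengths and whose turning angles are uniform on
(−π, π].  Two covariates are attached to every step end-location:

* ``dissimilarity`` — Euclidean distance in the natal PCA space (PC1,
  PC2) between the end-location's buffered habitat composition and the
  individual's natal habitat;
* ``distance`` — planar distance to the natal nest, in km.

Both are standardised (z-scored over all rows of a model's dataset)
before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import LandscapeRaster
from .natal import NatalAssignment, PCAModel, ScoreGrid, extract_buffer_composition

logger = logging.getLogger(__name__)

DEFAULT_INTERVAL = 3600.0  # s
DEFAULT_TOLERANCE = 900.0  # s; resampling window half-width
DEFAULT_VMAX = 35.0  # m/s, ground-speed plausibility limit
DEFAULT_N_AVAIL = 10


class TrackError(ValueError):
    """Track unusable for step-selection analysis."""


@dataclass
class Track:
    """One individual's ordered fixes with phase/year labels and bursts."""

    individual: str
    times: np.ndarray  # datetime64[s], strictly increasing
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray  # str per fix ("prospecting" | "settlement")
    year: np.ndarray  # int per fix
    burst: np.ndarray | None = None  # int per fix; None = single burst

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.year = np.asarray(self.year, dtype=int)
        if self.burst is None:
            self.burst = np.zeros(len(self.times), dtype=int)
        else:
            self.burst = np.asarray(self.burst, dtype=int)
        n = len(self.times)
        for name in ("x", "y", "phase", "year", "burst"):
            if len(getattr(self, name)) != n:
                raise TrackError(f"{name} length mismatch")
        if n > 1 and not np.all(np.diff(self.times).astype(float) > 0):
            raise TrackError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TrackError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.times)

    def take(self, idx: np.ndarray) -> "Track":
        return Track(
            self.individual,
            self.times[idx],
            self.x[idx],
            self.y[idx],
            self.phase[idx],
            self.year[idx],
            self.burst[idx] if self.burst is not None else None,
        )


def resample_track(
    track: Track,
    interval: float = DEFAULT_INTERVAL,
    tolerance: float = DEFAULT_TOLERANCE,
) -> Track:
    """Greedy regularisation onto a fixed interval with burst splitting.

    From each kept fix, the next kept fix is the one closest to
    (kept time + interval) within ±tolerance.  When no fix falls in
    that window, the burst ends and a new burst starts at the next
    fix beyond it.  Tracks with fewer than 3 fixes after resampling are
    rejected (excessive gaps).
    """
    t = track.times.astype("datetime64[s]").astype(float)
    n = len(t)
    keep: list[int] = []
    burst_ids: list[int] = []
    burst = 0
    i = 0
    keep.append(0)
    burst_ids.append(0)
    while i < n - 1:
        target = t[i] + interval
        lo = np.searchsorted(t, target - tolerance, side="left")
        hi = np.searchsorted(t, target + tolerance, side="right")
        lo = max(lo, i + 1)
        if lo < hi:
            j = lo + int(np.argmin(np.abs(t[lo:hi] - target)))
        else:
            nxt = np.searchsorted(t, target + tolerance, side="right")
            nxt = max(nxt, i + 1)
            if nxt >= n:
                break
            j = nxt
            burst += 1
        keep.append(j)
        burst_ids.append(burst)
        i = j
    if len(keep) < 3:
        raise TrackError(
            f"track {track.individual}: only {len(keep)} fixes after resampling "
            "(excessive gaps between locations)"
        )
    out = track.take(np.array(keep))
    out.burst = np.array(burst_ids, dtype=int)
    return out


def speed_filter(track: Track, vmax: float = DEFAULT_VMAX) -> Track:
    """Iteratively drop the arriving fix of any segment faster than vmax."""
    if len(track) < 2:
        raise TrackError("need at least 2 fixes")
    idx = np.arange(len(track))
    removed = 0
    while True:
        t = track.times[idx].astype(float)
        dx = np.diff(track.x[idx])
        dy = np.diff(track.y[idx])
        dt = np.diff(t)
        same_burst = np.diff(track.burst[idx]) == 0
        speed = np.hypot(dx, dy) / dt
        bad = np.flatnonzero((speed > vmax) & same_burst)
        if bad.size == 0:
            break
        idx = np.delete(idx, bad[0] + 1)  # drop the arriving fix
        removed += 1
    if removed:
        logger.info("speed filter removed %d fixes from %s", removed, track.individual)
    return track.take(idx)


def build_steps(track: Track) -> pd.DataFrame:
    """One step per consecutive in-burst fix pair, with turn angles.

    The turn angle is the wrapped difference between successive
    absolute bearings.  Zero-length steps carry the last non-zero
    bearing forward; the first step of a burst (no reference bearing)
    has NaN turn angle and cannot anchor a stratum.
    """
    rows = []
    for b in np.unique(track.burst):
        sel = np.flatnonzero(track.burst == b)
        if sel.size < 2:
            continue
        x, y, t = track.x[sel], track.y[sel], track.times[sel]
        dx, dy = np.diff(x), np.diff(y)
        length = np.hypot(dx, dy)
        bearing = np.arctan2(dy, dx)
        # carry bearing forward across zero-length steps
        eff_bearing = bearing.copy()
        last = np.nan
        for i in range(len(length)):
            if length[i] > 0:
                last = bearing[i]
            eff_bearing[i] = last if length[i] == 0 else bearing[i]
        turn = np.full(len(length), np.nan)
        for i in range(1, len(length)):
            prev = eff_bearing[i - 1]
            if np.isnan(prev) or length[i] == 0:
                continue
            turn[i] = _wrap_angle(bearing[i] - prev)
        for i in range(len(length)):
            rows.append(
                {
                    "individual": track.individual,
                    "burst": int(b),
                    "t_start": t[i],
                    "t_end": t[i + 1],
                    "x_start": x[i],
                    "y_start": y[i],
                    "x_end": x[i + 1],
                    "y_end": y[i + 1],
                    "length": length[i],
                    "bearing": bearing[i],
                    "prev_bearing": eff_bearing[i - 1] if i else np.nan,
                    "turn": turn[i],
                    "phase": track.phase[sel[i + 1]],
                    "year": int(track.year[sel[i + 1]]),
                }
            )
    return pd.DataFrame(rows)


def _wrap_angle(a):
    """Wrap to (−π, π]."""
    w = np.mod(-np.asarray(a) + np.pi, 2 * np.pi)
    return -(w - np.pi)


def fit_step_length_distribution(lengths: np.ndarray) -> float:
    """Exponential rate (1/m) fitted by maximum likelihood: 1/mean.

    Pooled over the whole population's observed steps; zero-length
    steps enter the mean.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0 or np.all(lengths == 0):
        raise ValueError("need at least one positive step length")
    return float(1.0 / lengths.mean())


# ---------------------------------------------------------------------------
# Availability sampling and the design table


def generate_available_steps(
    step: pd.Series,
    rate: float,
    n_avail: int = DEFAULT_N_AVAIL,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One stratum: the used step plus n_avail random alternatives.

    Alternative lengths are Exponential(rate); turning angles are
    Uniform(−π, π) applied to the previous absolute bearing, from the
    used step's start point.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isnan(step["prev_bearing"]):
        raise TrackError("used step has no previous bearing; cannot anchor a stratum")
    lengths = rng.exponential(1.0 / rate, n_avail)
    turns = rng.uniform(-np.pi, np.pi, n_avail)
    bearings = step["prev_bearing"] + turns
    rows = [
        {
            "is_used": True,
            "x_end": step["x_end"],
            "y_end": step["y_end"],
            "length": step["length"],
            "turn": step["turn"],
        }
    ]
    for L, tu, br in zip(lengths, turns, bearings):
        rows.append(
            {
                "is_used": False,
                "x_end": step["x_start"] + L * np.cos(br),
                "y_end": step["y_start"] + L * np.sin(br),
                "length": L,
                "turn": tu,
            }
        )
    return pd.DataFrame(rows)


def compute_dissimilarity(pca: PCAModel, natal_scores: np.ndarray, end_scores: np.ndarray) -> np.ndarray:
    """Euclidean distance in (PC1, PC2) between end and natal locations."""
    natal = np.asarray(natal_scores, dtype=float)[:2]
    end = np.atleast_2d(np.asarray(end_scores, dtype=float))[:, :2]
    return np.squeeze(np.hypot(end[:, 0] - natal[0], end[:, 1] - natal[1]))


def dissimilarity_at(
    pca: PCAModel,
    natal: NatalAssignment,
    landscape: LandscapeRaster,
    point: tuple[float, float],
    radius: float = 2000.0,
) -> float:
    """Dissimilarity of one location via exact point-buffer extraction."""
    hv = extract_buffer_composition(landscape, point, radius)
    return float(compute_dissimilarity(pca, natal.scores, pca.project(hv)))


def compute_distance(nest: tuple[float, float], x_end, y_end) -> np.ndarray:
    """Planar distance (km) from step end-locations to the natal nest."""
    return np.hypot(np.asarray(x_end) - nest[0], np.asarray(y_end) - nest[1]) / 1000.0


def build_design(
    steps: pd.DataFrame,
    score_grid: ScoreGrid,
    natal: NatalAssignment,
    rate: float,
    n_avail: int = DEFAULT_N_AVAIL,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 20,
    redraw: bool = True,
) -> pd.DataFrame:
    """Used/available design with covariates for one individual's steps.

    Only used steps with a defined previous bearing anchor strata.
    Available endpoints falling outside the raster are redrawn up to
    ``max_redraws`` times (synthetic mode); with ``redraw=False`` (or
    when redrawing fails) the offending available row is dropped with a
    log entry.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    land = score_grid.landscape
    anchors = steps[steps["prev_bearing"].notna() & steps["turn"].notna()].reset_index(drop=True)
    n = len(anchors)
    if n == 0:
        return pd.DataFrame(
            columns=["stratum", "is_used", "x_end", "y_end", "dissimilarity", "distance", "phase", "year"]
        )
    # vectorised availability sampling with bounded redraws
    L = rng.exponential(1.0 / rate, (n, n_avail))
    T = rng.uniform(-np.pi, np.pi, (n, n_avail))
    br = anchors["prev_bearing"].to_numpy()[:, None] + T
    ax = anchors["x_start"].to_numpy()[:, None] + L * np.cos(br)
    ay = anchors["y_start"].to_numpy()[:, None] + L * np.sin(br)
    if redraw:
        for _ in range(max_redraws):
            bad = ~land.contains(ax, ay)
            if not bad.any():
                break
            k = int(bad.sum())
            L2 = rng.exponential(1.0 / rate, k)
            T2 = rng.uniform(-np.pi, np.pi, k)
            br2 = np.broadcast_to(anchors["prev_bearing"].to_numpy()[:, None], bad.shape)[bad] + T2
            ax[bad] = np.broadcast_to(anchors["x_start"].to_numpy()[:, None], bad.shape)[bad] + L2 * np.cos(br2)
            ay[bad] = np.broadcast_to(anchors["y_start"].to_numpy()[:, None], bad.shape)[bad] + L2 * np.sin(br2)
    ok_avail = land.contains(ax, ay)
    n_dropped = int((~ok_avail).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d available rows with end-location outside the raster",
            natal.individual,
            n_dropped,
        )
    used_ok = land.contains(anchors["x_end"].to_numpy(), anchors["y_end"].to_numpy())
    rows = []
    nest = natal.nest
    for i in range(n):
        if not used_ok[i]:
            logger.info("%s: dropped stratum %d (used end outside raster)", natal.individual, i)
            continue
        xs = [anchors.at[i, "x_end"]] + list(ax[i][ok_avail[i]])
        ys = [anchors.at[i, "y_end"]] + list(ay[i][ok_avail[i]])
        if len(xs) < 2:
            continue
        scores = score_grid.scores_at(np.array(xs), np.array(ys))
        dis = compute_dissimilarity(None, natal.scores, scores)
        dist = compute_distance(nest, np.array(xs), np.array(ys))
        for j in range(len(xs)):
            rows.append(
                {
                    "individual": natal.individual,
                    "stratum": f"{natal.individual}:{i}",
                    "is_used": j == 0,
                    "x_end": xs[j],
                    "y_end": ys[j],
                    "dissimilarity": float(np.atleast_1d(dis)[j]),
                    "distance": float(dist[j]),
                    "phase": anchors.at[i, "phase"],
                    "year": int(anchors.at[i, "year"]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardisation


@dataclass
class ScalingRecord:
    """Mean/SD used to z-score each covariate, for back-transformation."""

    means: dict[str, float]
    sds: dict[str, float]
    pearson_correlation: float | None = None

    def back_transform(self, covariate: str, beta_z: float) -> float:
        """Raw-scale coefficient: beta_z / sd."""
        return beta_z / self.sds[covariate]


def standardize(
    design: pd.DataFrame, covariates: list[str] = ("dissimilarity", "distance")
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Z-score covariates over ALL rows (used + available) of the dataset.

    Standardisation is per model dataset: each individual-year (or
    interaction) model standardises over its own rows.  The scaling
    record allows raw-scale back-transformation; the Pearson
    correlation between the first two covariates is reported as a
    collinearity check (the analysis expects < 0.6).
    """
    covariates = list(covariates)
    df = design.copy()
    means, sds = {}, {}
    for cov in covariates:
        v = df[cov].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            raise ValueError(f"covariate {cov} has zero variance; cannot standardise")
        means[cov] = float(v.mean())
        sds[cov] = float(v.std(ddof=1))
        df[f"{cov}_z"] = (v - means[cov]) / sds[cov]
    corr = None
    if len(covariates) >= 2:
        corr = float(np.corrcoef(df[covariates[0]], df[covariates[1]])[0, 1])
        if abs(corr) >= 0.6:
            warnings.warn(
                f"covariates {covariates[0]}/{covariates[1]} strongly correlated "
                f"(Pearson r = {corr:.2f})",
                stacklevel=2,
            )
    return df, ScalingRecord(means=means, sds=sds, pearson_correlation=corr)
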