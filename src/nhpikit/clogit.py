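"""Matched-set conditional logistic regression for step-selection data.

Each observed ("used") step is matched with its randomly generated
available steps to form a stratum.  The conditional likelihood of the
used step within its stratum,

    L(beta) = prod_strata  exp(beta' x_used) / sum_j exp(beta' x_j),

is concave in beta; it is maximised by Newton iterations with
step-halving.  Standard errors come from the inverse observed
information.  A covariate that is constant within every stratum cancels
from the likelihood and is flagged non-identifiable (its coefficient is
pinned at zero).

The natal-habitat preference index (NHPI) is the *negative* of the
habitat-dissimilarity coefficient: positive NHPI means preference for
habitat resembling the natal area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

GRADIENT_TOL = 1e-8
MAX_ITER = 100
SEPARATION_BOUND = 50.0  # |beta| beyond this on the z-scale => separation


class DesignError(ValueError):
    """Malformed used/available design (empty or inconsistent strata)."""


@dataclass
class FitResult:
    """Fitted conditional-logit coefficients for one model dataset."""

    individual: str
    label: str  # year, phase, or "pooled"
    covariates: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_strata: int
    converged: bool
    flags: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.beta[self.covariates.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.se[self.covariates.index(name)])

    @property
    def nhpi(self) -> float:
        """Negative of the dissimilarity coefficient."""
        for name in self.covariates:
            if name.startswith("dissimilarity"):
                return -self.coef(name)
        raise KeyError("no dissimilarity covariate in this fit")


def _prepare(design: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort rows by stratum and return (X, used, stratum_start_indices)."""
    if design.empty:
        raise DesignError("empty design")
    df = design.sort_values("stratum", kind="stable")
    strata, starts = np.unique(df["stratum"].to_numpy(), return_index=True)
    used = df["is_used"].to_numpy(dtype=bool)
    counts = np.add.reduceat(used.astype(int), starts)
    if not np.all(counts == 1):
        bad = strata[counts != 1]
        raise DesignError(f"strata without exactly one used row: {bad[:5]}")
    sizes = np.diff(np.append(starts, len(df)))
    if np.any(sizes < 2):
        raise DesignError("strata with no available rows")
    X = df[covariates].to_numpy(dtype=float)
    return X, used, starts


def _loglik_grad_hess(beta, X, used, starts):
    eta = X @ beta
    # per-stratum log-sum-exp, stable
    seg = np.repeat(np.arange(len(starts)), np.diff(np.append(starts, len(X))))
    m = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - m[seg])
    denom = np.add.reduceat(w, starts)
    ll = float(eta[used].sum() - (np.log(denom) + m).sum())
    p = w / denom[seg]
    mean_x = np.empty((len(starts), X.shape[1]))
    for j in range(X.shape[1]):
        mean_x[:, j] = np.add.reduceat(p * X[:, j], starts)
    grad = X[used].sum(axis=0) - mean_x.sum(axis=0)
    centered = X - mean_x[seg]
    hess = -(centered * p[:, None]).T @ centered
    return ll, grad, hess


def fit_clogit(
    design: pd.DataFrame,
    covariates: list[str],
    individual: str = "",
    label: str = "pooled",
) -> FitResult:
    """Fit the conditional logit by Newton iterations with step-halving.

    Parameters
    ----------
    design
        One row per used/available step with columns ``stratum``,
        ``is_used`` and the covariates (already standardised).
    covariates
        Column names entering the linear predictor.

    Convergence is declared when the gradient max-norm drops below
    1e-8; after 100 iterations, or if any |beta| exceeds 50 (complete
    separation on the standardised scale), the result is flagged and
    ``converged`` is False.
    """
    X, used, starts = _prepare(design, covariates)
    p = X.shape[1]
    seg = np.repeat(np.arange(len(starts)), np.diff(np.append(starts, len(X))))
    # identifiability: zero within-stratum variance across all strata
    informative = np.zeros(p, dtype=bool)
    for j in range(p):
        first = X[starts, j]
        informative[j] = bool(np.any(X[:, j] != first[seg]))
    flags: list[str] = []
    if not informative.all():
        names = [c for c, k in zip(covariates, informative) if not k]
        flags.append(f"non-identifiable: {','.join(names)}")

    beta = np.zeros(p)
    free = np.flatnonzero(informative)
    converged = False
    ll, grad, hess = _loglik_grad_hess(beta, X, used, starts)
    for _ in range(MAX_ITER):
        if free.size == 0:
            converged = True
            break
        if np.max(np.abs(grad[free])) < GRADIENT_TOL:
            converged = True
            break
        H = hess[np.ix_(free, free)]
        try:
            step = np.linalg.solve(H, -grad[free])
        except np.linalg.LinAlgError:
            flags.append("singular-hessian")
            break
        # step-halving on the concave log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta.copy()
            cand[free] += scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(cand, X, used, starts)
            if ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
                break
            scale *= 0.5
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            flags.append("separation")
            break
    else:
        flags.append("max-iterations")
    # perfect prediction: the conditional log-likelihood is bounded by 0 and
    # attains it only when every used step wins its stratum with certainty
    if free.size and ll > -1e-6 * len(starts) and "separation" not in flags:
        flags.append("separation")

    se = np.zeros(p)
    if free.size:
        try:
            cov = np.linalg.inv(-hess[np.ix_(free, free)])
            se[free] = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            flags.append("singular-information")
            converged = False
    return FitResult(
        individual=individual,
        label=label,
        covariates=tuple(covariates),
        beta=beta,
        se=se,
        loglik=ll,
        n_strata=len(starts),
        converged=converged and "separation" not in flags,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Interaction variants


def _fit_interaction(
    design: pd.DataFrame,
    factor: str,
    covariates: list[str],
    individual: str,
    min_strata: int = 10,
) -> dict[str, FitResult]:
    """One clogit with factor-specific coefficients (interactions only).

    Builds covariate × level columns (no main effects; each stratum
    belongs to one level, so main effects would cancel anyway) and
    returns one :class:`FitResult` view per factor level.
    """
    levels = sorted(design[factor].unique())
    if len(levels) < 2:
        raise DesignError(f"need >= 2 levels of {factor}, got {levels}")
    df = design.copy()
    cols = []
    for cov in covariates:
        for lev in levels:
            col = f"{cov}:{lev}"
            df[col] = df[cov] * (df[factor] == lev)
            cols.append(col)
    fit = fit_clogit(df, cols, individual=individual, label=f"by-{factor}")
    out: dict[str, FitResult] = {}
    for lev in levels:
        n_strata = design.loc[design[factor] == lev, "stratum"].nunique()
        flags = list(fit.flags)
        if n_strata < min_strata:
            flags.append(f"low-information:{lev}")
        idx = [cols.index(f"{cov}:{lev}") for cov in covariates]
        out[str(lev)] = FitResult(
            individual=individual,
            label=str(lev),
            covariates=tuple(covariates),
            beta=fit.beta[idx],
            se=fit.se[idx],
            loglik=fit.loglik,
            n_strata=n_strata,
            converged=fit.converged,
            flags=tuple(flags),
        )
    return out


def fit_phase_interaction(
    design: pd.DataFrame, covariates: list[str], individual: str = ""
) -> dict[str, FitResult]:
    """Separate coefficients per dispersal phase (prospecting/settlement).

    The design should cover the last prospecting year and the first
    settlement year of one individual; only interaction terms are
    fitted, yielding the (x_p, x_s) coefficient pair used by the
    consistency and reversal metrics.
    """
    return _fit_interaction(design, "phase", covariates, individual)


def fit_yearly(
    design: pd.DataFrame, covariates: list[str], individual: str = ""
) -> dict[str, FitResult]:
    """Separate coefficients per prospecting year (interannual metric)."""
    return _fit_interaction(design, "year", covariates, individual)


# ---------------------------------------------------------------------------
# k-fold cross-validation


def kfold_cv(
    design: pd.DataFrame,
    covariates: list[str],
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, np.ndarray]:
    """Used-step rank-frequency Spearman cross-validation.

    Strata are partitioned into ``k`` folds.  For each fold the model
    is refitted on the remaining strata and each held-out stratum's
    members are ranked by fitted score (rank 1 = highest).  Good models
    concentrate the used step at low ranks, so the Spearman correlation
    between rank index and used-step rank frequency is negated: +1 is
    perfect, 0 is uninformative.

    Returns (mean rho, SD of rho, per-fold rho array).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = design["stratum"].unique()
    if k < 2 or k > len(strata):
        raise DesignError(f"k={k} infeasible for {len(strata)} strata")
    perm = rng.permutation(len(strata))
    folds = np.array_split(perm, k)
    stratum_sizes = design.groupby("stratum").size()
    n_members = int(stratum_sizes.max())
    rhos = []
    for fold in folds:
        held = set(strata[fold])
        mask = design["stratum"].isin(held)
        fit = fit_clogit(design[~mask], covariates)
        test = design[mask].copy()
        test["score"] = test[covariates].to_numpy() @ fit.beta
        freq = np.zeros(n_members)
        for _, grp in test.groupby("stratum"):
            order = np.argsort(-grp["score"].to_numpy(), kind="stable")
            rank_of_used = int(np.flatnonzero(grp["is_used"].to_numpy()[order])[0])
            freq[rank_of_used] += 1
        rho = spearmanr(np.arange(1, n_members + 1), freq).statistic
        rhos.append(0.0 if np.isnan(rho) else -float(rho))
    rhos = np.array(rhos)
    return float(rhos.mean()), float(rhos.std(ddof=1)), rhos
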