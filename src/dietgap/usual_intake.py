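"""Usual-intake estimation from repeated day-level food records.

Short food records observe a person's diet with large day-to-day
(within-person) variation; the quantity of interest is *usual intake*, the
long-term mean daily consumption.  Following the measurement-error approach
of the NCI method, two model families are implemented:

* **amount model** — for food groups consumed nearly every day: a Box-Cox
  transformed linear mixed model, ``g_lam(y_ij) = x_ij' beta + u_i + e_ij``
  with a person random intercept ``u_i ~ N(0, sigma_u^2)`` and residual
  ``e_ij ~ N(0, sigma_e^2)``.  The transformation exponent ``lam`` is
  profiled over [0, 1]; for each candidate the mixed model is fitted by
  maximum likelihood (statsmodels MixedLM) and the Box-Cox Jacobian added.
* **correlated two-part ('corr') model** — for episodically consumed
  groups: a mixed-effects logistic model for the probability of consuming
  on a day, plus the amount model for consumed-day amounts, with
  bivariate-normal person effects ``(u1, u2)`` correlated by ``rho``.  The
  joint likelihood integrates the person effects with covariance-scaled
  two-dimensional Gauss-Hermite quadrature.

The population distribution of usual intake is then built by Monte Carlo:
pseudo-persons draw covariates from the observed persons and random
effects from the fitted distribution; each pseudo-person's usual intake is
the 5/7 weekday + 2/7 weekend weighted expectation of daily intake,
back-transforming the Box-Cox scale with a Gauss-Hermite correction for
within-person variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

__all__ = [
    "IdentifiabilityError",
    "ConvergenceError",
    "AmountModelParams",
    "TwoPartModelParams",
    "UsualIntakeDistribution",
    "boxcox",
    "boxcox_inv",
    "fit_amount_model",
    "fit_two_part_model",
    "usual_intake_distribution",
    "summarize_and_attain",
    "build_design",
]

WEEKDAY_WEIGHT = 5.0 / 7.0
WEEKEND_WEIGHT = 2.0 / 7.0


class IdentifiabilityError(ValueError):
    """The data cannot identify the model (e.g. no within-person replicates)."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge to a maximum-likelihood solution."""


def boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox transform; natural log at lam = 0."""
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_inv(z: np.ndarray, lam: float) -> np.ndarray:
    """Inverse Box-Cox transform, clipped to 0 outside the domain."""
    z = np.asarray(z, dtype=float)
    if lam == 0.0:
        return np.exp(z)
    base = lam * z + 1.0
    return np.where(base > 0.0, np.power(np.clip(base, 0.0, None), 1.0 / lam), 0.0)


def _gh(n: int) -> tuple[np.ndarray, np.ndarray]:
    t, w = np.polynomial.hermite.hermgauss(n)
    return t, w


# ---------------------------------------------------------------------------
# amount model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmountModelParams:
    """ML estimates of the Box-Cox linear mixed amount model."""

    lam: float
    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma_u2: float
    sigma_e2: float
    loglik: float
    shift: float = 0.0  # added to all amounts before transforming (zero handling)
    n_persons: int = 0
    n_obs: int = 0

    @property
    def sigma_u(self) -> float:
        return float(np.sqrt(self.sigma_u2))

    @property
    def sigma_e(self) -> float:
        return float(np.sqrt(self.sigma_e2))


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("design matrix and column names disagree")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (aliased or constant column); "
            f"columns: {list(names)}"
        )


def _profile_grid(coarse_step: float = 0.1, fine_step: float = 0.01):
    return np.round(np.arange(0.0, 1.0 + 1e-9, coarse_step), 10)


def _fit_lmm_at_lambda(z, X, person):
    """Exact ML fit of the random-intercept linear mixed model.

    For a model with a single person random intercept the likelihood can
    be profiled analytically: given the variance ratio r = sigma_u^2 /
    sigma_e^2, the GLS estimate of beta and the ML estimate of sigma_e^2
    are closed-form (V_i^{-1} = I - r/(1 + n_i r) J within person), so the
    fit reduces to a one-dimensional search over log r.  This is exact and
    orders of magnitude faster than a generic mixed-model optimizer, which
    matters because it sits inside the Box-Cox profile loop.

    Returns (beta, sigma_u2, sigma_e2, loglik).
    """
    from scipy.optimize import minimize_scalar

    n_total, k = X.shape
    pidx, n_persons = _person_index(person)
    counts = np.bincount(pidx, minlength=n_persons).astype(float)

    # per-person aggregates
    Xg = np.zeros((n_persons, k))
    for j in range(k):
        Xg[:, j] = np.bincount(pidx, weights=X[:, j], minlength=n_persons)
    zg = np.bincount(pidx, weights=z, minlength=n_persons)
    XtX = X.T @ X
    Xtz = X.T @ z
    ztz = float(z @ z)

    def profile_ll(log_r: float):
        r = np.exp(log_r)
        w = r / (1.0 + counts * r)
        A = XtX - (Xg * w[:, None]).T @ Xg
        b = Xtz - Xg.T @ (w * zg)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return -np.inf, None
        # quadratic form e' V^{-1} e without materializing residual groups
        quad = (
            ztz - 2.0 * beta @ Xtz + beta @ XtX @ beta
            - float(w @ (zg - Xg @ beta) ** 2)
        )
        if quad <= 0:
            return -np.inf, None
        se2 = quad / n_total
        ll = (
            -0.5 * n_total * (np.log(2.0 * np.pi * se2) + 1.0)
            - 0.5 * float(np.sum(np.log1p(counts * r)))
        )
        return ll, (beta, r * se2, se2)

    # search over log variance ratio, including the r -> 0 boundary
    opt = minimize_scalar(
        lambda t: -profile_ll(t)[0],
        bounds=(-15.0, 10.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    ll_opt, est_opt = profile_ll(float(opt.x))
    ll_zero, est_zero = profile_ll(-30.0)  # effectively sigma_u2 = 0
    if est_opt is None or (est_zero is not None and ll_zero >= ll_opt):
        ll_opt, est_opt = ll_zero, est_zero
        if est_opt is not None:
            est_opt = (est_opt[0], 0.0, est_opt[2])
    if est_opt is None:
        raise np.linalg.LinAlgError("singular GLS system in mixed-model fit")
    beta, su2, se2 = est_opt
    return beta, su2, se2, ll_opt


def fit_amount_model(
    y: np.ndarray,
    person: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    lam_grid: Sequence[float] | None = None,
    pool_within: bool = False,
) -> AmountModelParams:
    """Fit the Box-Cox linear mixed amount model by profile ML.

    ``y`` are day-level amounts (zeros allowed: all amounts are shifted by
    half the smallest positive value when zeros are present), ``person``
    the person label per row, ``X`` the fixed-effects design (including an
    intercept column).  ``lam`` is profiled over [0, 1]: a coarse 0.1-step
    pass followed by a 0.01-step refinement around the coarse optimum.

    ``pool_within``: accept data without within-person replicates by
    attributing all residual variance to the within-person component
    (sigma_u^2 fixed at 0) — a fallback for sparsely consumed groups.
    """
    y = np.asarray(y, dtype=float)
    person = np.asarray(person)
    X = np.asarray(X, dtype=float)
    if len(y) != len(person) or len(y) != X.shape[0]:
        raise ValueError("y, person and X must have equal length")
    if np.any(y < 0):
        raise ValueError("amounts must be non-negative")
    _check_design(X, names)

    _, counts = np.unique(person, return_counts=True)
    if counts.max() < 2 and not pool_within:
        raise IdentifiabilityError(
            "every person has a single record day: within-person variance "
            "is not identifiable"
        )

    shift = 0.0
    if np.any(y == 0):
        positive = y[y > 0]
        if positive.size == 0:
            raise ValueError("amount model needs positive amounts")
        shift = 0.5 * positive.min()
    ys = y + shift
    log_jac = float(np.sum(np.log(ys)))

    def profile(lam: float):
        z = boxcox(ys, lam)
        try:
            beta, su2, se2, llf = _fit_lmm_at_lambda(z, X, person)
        except (np.linalg.LinAlgError, ValueError):
            return None, -np.inf
        ll = llf + (lam - 1.0) * log_jac
        if not np.isfinite(ll):
            return None, -np.inf
        return (beta, su2, se2), ll

    if lam_grid is None:
        coarse = _profile_grid()
        results = {float(l): profile(float(l)) for l in coarse}
        best_l = max(results, key=lambda l: results[l][1])
        fine = np.round(
            np.arange(max(0.0, best_l - 0.1), min(1.0, best_l + 0.1) + 1e-9, 0.01), 10
        )
        for l in fine:
            l = float(l)
            if l not in results:
                results[l] = profile(l)
    else:
        results = {float(l): profile(float(l)) for l in lam_grid}

    best_l = max(results, key=lambda l: results[l][1])
    res, ll = results[best_l]
    if res is None:
        raise ConvergenceError("mixed-model fit failed at every candidate lambda")
    beta, su2, se2 = res
    if pool_within and counts.max() < 2:
        su2, se2 = 0.0, su2 + se2

    return AmountModelParams(
        lam=best_l,
        beta=beta,
        beta_names=tuple(names),
        sigma_u2=su2,
        sigma_e2=se2,
        loglik=ll,
        shift=shift,
        n_persons=len(counts),
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# correlated two-part model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoPartModelParams:
    """ML estimates of the correlated two-part (episodic) model.

    ``beta_p`` / ``sigma_u1`` parameterize the logistic consumption-
    probability part; ``amount`` holds the Box-Cox amount part; ``rho`` is
    the correlation of the two person effects.  ``prob_degenerate`` marks
    the every-day-consumed limit (p = 1, no probability part fitted).
    """

    amount: AmountModelParams
    beta_p: np.ndarray | None = None
    beta_p_names: tuple[str, ...] = ()
    sigma_u1_2: float = 0.0
    rho: float = 0.0
    loglik: float = np.nan
    prob_degenerate: bool = False
    #: amount part fitted without a person random intercept (no person had
    #: two positive days; all amount variance treated as within-person)
    amount_pooled: bool = False

    @property
    def sigma_u1(self) -> float:
        return float(np.sqrt(self.sigma_u1_2))


def _person_index(person: np.ndarray) -> tuple[np.ndarray, int]:
    _, idx = np.unique(person, return_inverse=True)
    return idx, int(idx.max()) + 1


def _two_part_negloglik(
    theta: np.ndarray,
    kp: int,
    ka: int,
    c: np.ndarray,
    z: np.ndarray,
    Xp: np.ndarray,
    Xa: np.ndarray,
    pidx: np.ndarray,
    n_persons: int,
    pos: np.ndarray,
    gh_t: np.ndarray,
    gh_w: np.ndarray,
) -> float:
    beta_p = theta[:kp]
    beta_a = theta[kp : kp + ka]
    s1 = np.exp(theta[kp + ka])
    s2 = np.exp(theta[kp + ka + 1])
    se = np.exp(theta[kp + ka + 2])
    rho = np.tanh(theta[kp + ka + 3])

    eta_p = Xp @ beta_p
    eta_a = Xa @ beta_a

    # covariance-scaled 2-D Gauss-Hermite grid for (u1, u2)
    a, b = np.meshgrid(gh_t, gh_t, indexing="ij")
    wgrid = np.outer(gh_w, gh_w).ravel() / np.pi
    u1 = np.sqrt(2.0) * s1 * a.ravel()
    u2 = np.sqrt(2.0) * s2 * (rho * a.ravel() + np.sqrt(max(1.0 - rho**2, 1e-12)) * b.ravel())
    n_nodes = u1.size

    # Bernoulli part: sum_j c log p + (1-c) log(1-p), per person and node
    x_pn = eta_p[None, :] + u1[:, None]  # (nodes, obs)
    lp_obs = np.where(c[None, :] == 1, log_expit(x_pn), log_expit(-x_pn))
    # amount part on consumed days
    resid = z[None, pos] - eta_a[None, pos] - u2[:, None]
    la_obs = -0.5 * np.log(2.0 * np.pi * se**2) - resid**2 / (2.0 * se**2)

    # per-person sums via bincount, batched over nodes
    lp = np.vstack(
        [np.bincount(pidx, weights=lp_obs[k], minlength=n_persons) for k in range(n_nodes)]
    )
    pidx_pos = pidx[pos]
    la = np.vstack(
        [np.bincount(pidx_pos, weights=la_obs[k], minlength=n_persons) for k in range(n_nodes)]
    )
    ll_person = logsumexp(lp + la + np.log(wgrid)[:, None], axis=0)
    return -float(np.sum(ll_person))


def fit_two_part_model(
    y: np.ndarray,
    person: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    gh_points: int = 13,
) -> TwoPartModelParams:
    """Fit the correlated two-part model by joint maximum likelihood.

    The same covariates enter both parts.  The Box-Cox exponent is profiled
    on the positive-amount submodel and held fixed during the joint fit.
    With no zero days the probability part degenerates to p = 1 and the
    amount model alone is returned.
    """
    y = np.asarray(y, dtype=float)
    person = np.asarray(person)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0):
        raise ValueError("amounts must be non-negative")
    _check_design(X, names)

    pos = y > 0
    if not np.any(pos):
        raise ValueError("no positive consumption days: cannot fit the amount part")
    if np.all(pos):
        amount = fit_amount_model(y, person, X, names)
        return TwoPartModelParams(amount=amount, prob_degenerate=True, loglik=amount.loglik)

    # without positive-day replicates the amount part's between/within split
    # (and hence rho) is unidentifiable: fall back to a pooled amount part
    _, pc = np.unique(person[pos], return_counts=True)
    pooled = bool(pc.max() < 2)

    amount0 = fit_amount_model(y[pos], person[pos], X[pos], names, pool_within=pooled)
    lam = amount0.lam
    z = np.zeros_like(y)
    z[pos] = boxcox(y[pos] + amount0.shift, lam)

    c = pos.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            logit0 = sm.Logit(c, X).fit(disp=0)
            beta_p0 = np.asarray(logit0.params, dtype=float)
        except Exception:
            beta_p0 = np.zeros(X.shape[1])

    pidx, n_persons = _person_index(person)
    gh_t, gh_w = _gh(gh_points)
    kp = ka = X.shape[1]

    args = (kp, ka, c, z, X, X, pidx, n_persons, pos, gh_t, gh_w)
    if pooled:
        # sigma_u2 pinned near 0 and rho at 0; optimize the rest
        def embed(red: np.ndarray) -> np.ndarray:
            return np.concatenate(
                [red[: kp + ka], red[kp + ka : kp + ka + 1], [np.log(1e-4)],
                 red[kp + ka + 1 : kp + ka + 2], [0.0]]
            )

        red0 = np.concatenate(
            [beta_p0, amount0.beta, [0.0], [0.5 * np.log(max(amount0.sigma_e2, 1e-6))]]
        )
        opt = minimize(
            lambda red: _two_part_negloglik(embed(red), *args),
            red0,
            method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-9},
        )
        th = embed(opt.x)
    else:
        theta0 = np.concatenate(
            [
                beta_p0,
                amount0.beta,
                [0.0],
                [0.5 * np.log(max(amount0.sigma_u2, 1e-6))],
                [0.5 * np.log(max(amount0.sigma_e2, 1e-6))],
                [0.0],
            ]
        )
        opt = minimize(
            _two_part_negloglik,
            theta0,
            args=args,
            method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-9},
        )
        th = opt.x
    if not np.all(np.isfinite(th)):
        raise ConvergenceError("two-part optimizer returned non-finite parameters")
    amount = AmountModelParams(
        lam=lam,
        beta=th[kp : kp + ka].copy(),
        beta_names=tuple(names),
        sigma_u2=0.0 if pooled else float(np.exp(2.0 * th[kp + ka + 1])),
        sigma_e2=float(np.exp(2.0 * th[kp + ka + 2])),
        loglik=np.nan,
        shift=amount0.shift,
        n_persons=n_persons,
        n_obs=int(pos.sum()),
    )
    return TwoPartModelParams(
        amount=amount,
        beta_p=th[:kp].copy(),
        beta_p_names=tuple(names),
        sigma_u1_2=float(np.exp(2.0 * th[kp + ka])),
        rho=0.0 if pooled else float(np.tanh(th[kp + ka + 3])),
        loglik=-float(opt.fun),
        amount_pooled=pooled,
    )


# ---------------------------------------------------------------------------
# Monte Carlo usual-intake distribution
# ---------------------------------------------------------------------------


@dataclass
class UsualIntakeDistribution:
    """Monte Carlo population distribution of usual intake (g/day)."""

    values: np.ndarray
    food_group: str = ""
    age_group: str = ""
    n_mc: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty usual-intake distribution")
        if np.any(self.values < 0):
            raise ValueError("usual intakes must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


def _conditional_mean_amount(
    eta: np.ndarray, lam: float, sigma_e: float, shift: float, gh_points: int = 9
) -> np.ndarray:
    """E[max(g_lam^{-1}(eta + e) - shift, 0)] over e ~ N(0, sigma_e^2)."""
    t, w = _gh(gh_points)
    zz = eta[:, None] + np.sqrt(2.0) * sigma_e * t[None, :]
    vals = np.clip(boxcox_inv(zz, lam) - shift, 0.0, None)
    return vals @ (w / np.sqrt(np.pi))


def usual_intake_distribution(
    params: AmountModelParams | TwoPartModelParams,
    covariates: pd.DataFrame,
    n_mc: int,
    seed: int,
    food_group: str = "",
    age_group: str = "",
    weekend_col: str = "weekend",
    gh_points: int = 9,
) -> UsualIntakeDistribution:
    """Monte Carlo distribution of usual intake for a fitted model.

    ``covariates`` has one row per observed person with the model's design
    columns; pseudo-persons resample rows with replacement.  The weekend
    column, when present in the design, is forced to 0 and 1 to form the
    weekday/weekend design rows, combined with 5/7 and 2/7 weights.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)

    two_part = isinstance(params, TwoPartModelParams)
    amount = params.amount if two_part else params
    names = list(amount.beta_names)
    missing = [n for n in names if n != weekend_col and n not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks model columns: {missing}")

    rows = rng.integers(0, len(covariates), size=n_mc)
    base = pd.DataFrame(
        {n: (covariates[n].to_numpy()[rows] if n in covariates.columns else 0.0) for n in names}
    )

    def design(weekend: float) -> np.ndarray:
        d = base.copy()
        if weekend_col in names:
            d[weekend_col] = weekend
        return d.to_numpy(dtype=float)

    X_wd, X_we = design(0.0), design(1.0)

    if two_part and not params.prob_degenerate:
        L = np.array(
            [
                [params.sigma_u1, 0.0],
                [
                    params.rho * amount.sigma_u,
                    amount.sigma_u * np.sqrt(max(1.0 - params.rho**2, 0.0)),
                ],
            ]
        )
        uu = rng.standard_normal((n_mc, 2)) @ L.T
        u1, u2 = uu[:, 0], uu[:, 1]
        p_wd = expit(X_wd @ params.beta_p + u1)
        p_we = expit(X_we @ params.beta_p + u1)
    else:
        u2 = amount.sigma_u * rng.standard_normal(n_mc)
        p_wd = p_we = 1.0

    e_wd = _conditional_mean_amount(
        X_wd @ amount.beta + u2, amount.lam, amount.sigma_e, amount.shift, gh_points
    )
    e_we = _conditional_mean_amount(
        X_we @ amount.beta + u2, amount.lam, amount.sigma_e, amount.shift, gh_points
    )
    usual = WEEKDAY_WEIGHT * p_wd * e_wd + WEEKEND_WEIGHT * p_we * e_we
    return UsualIntakeDistribution(
        values=np.clip(usual, 0.0, None),
        food_group=food_group,
        age_group=age_group,
        n_mc=n_mc,
        seed=seed,
    )


def implied_population_moments(
    params: AmountModelParams,
    x_row: np.ndarray | None = None,
    gh_points: int = 21,
) -> dict:
    """Population moments of daily intake implied by a fitted amount model.

    Returns, for a fixed covariate row (default: intercept only), the mean
    daily intake, the between-person SD (of the person-level expected
    intake) and the within-person SD (day-to-day, averaged over persons),
    all on the original measurement scale via Gauss-Hermite integration
    over both random effect and residual.  Because these are functionals
    of the data distribution they are invariant to the Box-Cox
    parameterization: when the fitted exponent is 1 they coincide with
    (beta0, sigma_u, sigma_e).
    """
    if x_row is None:
        x_row = np.zeros(len(params.beta))
        x_row[list(params.beta_names).index("intercept")] = 1.0
    m0 = float(x_row @ params.beta)
    t, w = _gh(gh_points)
    wn = w / np.sqrt(np.pi)
    u = np.sqrt(2.0) * params.sigma_u * t
    e = np.sqrt(2.0) * params.sigma_e * t
    vals = np.clip(boxcox_inv(m0 + u[:, None] + e[None, :], params.lam) - params.shift, 0.0, None)
    cond_mean = vals @ wn  # E[y | u], per u node
    cond_m2 = (vals**2) @ wn
    mean = float(wn @ cond_mean)
    var_between = float(wn @ cond_mean**2) - mean**2
    var_within = float(wn @ (cond_m2 - cond_mean**2))
    return {
        "mean": mean,
        "sd_between": float(np.sqrt(max(var_between, 0.0))),
        "sd_within": float(np.sqrt(max(var_within, 0.0))),
    }


def summarize_and_attain(
    dist: UsualIntakeDistribution,
    target=None,
    range_lo: float | None = None,
    range_hi: float | None = None,
) -> dict:
    """Distribution summaries plus target attainment percentages.

    Returns mean and 25th/50th/75th percentiles; when a scaled target is
    given, the percentage of pseudo-persons meeting it; when a range is
    given, below/within/above percentages (summing to exactly 100).
    """
    v = dist.values
    out = {
        "mean": float(np.mean(v)),
        "p25": float(np.percentile(v, 25)),
        "p50": float(np.percentile(v, 50)),
        "p75": float(np.percentile(v, 75)),
    }
    if target is not None:
        if target.direction == "minimum":
            met = v >= target.target_g
        else:
            met = v <= target.target_g
        out["pct_meeting"] = 100.0 * float(np.mean(met))
        if range_lo is None and target.has_range:
            range_lo, range_hi = target.range_lo_g, target.range_hi_g
    if range_lo is not None and range_hi is not None:
        pct_below = 100.0 * float(np.mean(v < range_lo))
        pct_above = 100.0 * float(np.mean(v > range_hi))
        out["pct_below"] = pct_below
        out["pct_above"] = pct_above
        out["pct_within"] = 100.0 - pct_below - pct_above
    return out


def build_design(
    df: pd.DataFrame,
    age_col: str = "age_years",
    sex_col: str = "sex",
    weekend_col: str = "weekend",
) -> tuple[np.ndarray, list[str]]:
    """Intercept + completed-age-year dummies + boy dummy + weekend dummy.

    Age enters as dummies for each completed year beyond the youngest
    present (so a two-year age group yields one dummy).  Sex may be coded
    'girl'/'boy' or 0/1.  Columns that would be constant are dropped.
    """
    n = len(df)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    years = np.floor(df[age_col].to_numpy(dtype=float)).astype(int)
    for yr in sorted(set(years))[1:]:
        cols[f"age{yr}"] = (years == yr).astype(float)
    sex = df[sex_col]
    boy = (
        (sex == "boy").to_numpy(dtype=float)
        if sex.dtype == object
        else sex.to_numpy(dtype=float)
    )
    if len(set(boy.tolist())) > 1:
        cols["boy"] = boy
    we = df[weekend_col].to_numpy(dtype=float)
    if len(set(we.tolist())) > 1:
        cols[weekend_col] = we
    X = np.column_stack(list(cols.values()))
    return X, list(cols)
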