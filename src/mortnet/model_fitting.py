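"""Stochastic maximum-likelihood training of the flux-temperature model.

The objective maximised at each optimisation step is the batch Poisson
log-likelihood of the monthly death counts

    LL_batch = (1 / (n * nbatch)) * sum_{i,m} [ n_im log lambda_im - lambda_im ]

over ``nbatch`` training months drawn with replacement (one GDP-weighted
patient zero per drawn month), plus two log-priors — a soft flat prior
keeping every region's daily outflow fraction inside [0, 0.2], and a
quadratic penalty on the episodic decay length d0_e — and, after an
initial phase, a regulariser pulling the model's between-region
correlations (on the batch) towards the observed ones.

Updates use the Adam rule (beta1 = 0.9, beta2 = 0.99) with the decaying
learning rate lr(step) = 1e-3 (1 + step/1e4)^(-0.75).  Positivity and
range constraints are enforced by optimising logs (sigmoid for mu).
Gradients are obtained by central finite differences in the unconstrained
parameter space: all 2p+1 perturbed parameter vectors share one batch and
one set of patient-zero draws (common random numbers) and are integrated
through the SIR network in a single vectorised sweep, so a full gradient
costs one batched forward pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import (DistanceMatrix, FluxMatrix, MonthlyPanel, RegionTable,
                      ValidationError)
from .flux_model import fit_gravity
from .sir_network import BETA_CAP_FACTOR, FullModelParams, _euler_sweep


@dataclass
class FitConfig:
    """Hyper-parameters of the stochastic fit (defaults = study protocol)."""

    n_steps: int = 10**6
    nbatch_phase1: int = 10
    nbatch_phase2: int = 100
    phase_switch_step: int = 10**4
    upsilon_corr: float = 8.76e2
    flux_fraction_lo: float = 0.0
    flux_fraction_hi: float = 0.2
    flux_prior_stiffness: float = 1e6
    d0e_prior_coeff: float = 9.74e-7  # per km^2
    lr0: float = 1e-3
    lr_decay_scale: float = 1e4
    lr_exponent: float = 0.75
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    adam_eps: float = 1e-8
    fd_step: float = 1e-4  # central-difference step in unconstrained space
    test_eval_interval: int = 2000
    test_i0_draws: int = 5  # Monte-Carlo draws for the i0 expectation
    log_interval: int = 100
    corr_on_rates: bool = False  # compare correlations of per-mean rates
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_steps", "nbatch_phase1", "nbatch_phase2",
                     "phase_switch_step", "test_eval_interval", "log_interval",
                     "test_i0_draws"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.upsilon_corr < 0:
            raise ValidationError("upsilon_corr must be >= 0")


@dataclass(frozen=True)
class TrainTestSplit:
    """Training months and the 12 held-out test months."""

    train_months: list[tuple[int, int]]
    test_months: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# Objective building blocks
# ---------------------------------------------------------------------------

def poisson_loglik(counts: np.ndarray, lambdas: np.ndarray) -> float:
    """Mean Poisson log-likelihood (1/N) sum n log lambda - lambda.

    The log(n!) terms, constant in the parameters, are omitted.
    """
    n = np.asarray(counts, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if n.shape != lam.shape:
        raise ValidationError("counts/lambda shape mismatch")
    if np.any((lam <= 0) & (n > 0)):
        raise ValidationError("lambda <= 0 where counts are positive")
    term = np.where(n > 0, n * np.log(np.where(lam > 0, lam, 1.0)), 0.0) - lam
    return float(term.mean())


def outflow_fractions(flux_values: np.ndarray, pops: np.ndarray) -> np.ndarray:
    """Fraction of each region's residents leaving per day, sum_k f_kj / pop_j."""
    return np.asarray(flux_values).sum(axis=-2) / pops


def flux_fraction_prior(
    flux, regions: RegionTable,
    lo: float = 0.0, hi: float = 0.2, stiffness: float = 1e6,
) -> float:
    """Soft flat log-prior on the daily outflow fraction of every region.

    Zero while each fraction lies in [lo, hi]; quadratic in the excess
    outside, with a stiffness large enough to practically confine the fit.
    """
    if stiffness <= 0:
        raise ValidationError("stiffness must be > 0")
    values = flux.values if isinstance(flux, FluxMatrix) else np.asarray(flux)
    frac = outflow_fractions(values, regions.populations)
    excess = np.maximum(frac - hi, 0.0) + np.maximum(lo - frac, 0.0)
    return float(-stiffness * np.sum(excess**2))


def d0e_log_prior(d0_e: float, coeff: float = 9.74e-7) -> float:
    """Quadratic log-prior -coeff * d0_e^2 penalising long episodic decays."""
    if d0_e < 0:
        raise ValidationError("d0_e must be >= 0")
    return float(-coeff * d0_e**2)


def learning_rate(step: int, cfg: FitConfig) -> float:
    """Decaying Adam learning rate lr0 * (1 + step/scale)^(-exponent)."""
    if step < 0:
        raise ValidationError("step must be >= 0")
    return cfg.lr0 * (1.0 + step / cfg.lr_decay_scale) ** (-cfg.lr_exponent)


def correlation_regularizer(
    model_series: np.ndarray, data_corr: np.ndarray, upsilon: float
) -> float:
    """Penalty -(upsilon / n_pairs) sum_{i>j} (corr_model - corr_data)^2.

    ``model_series`` is a region x month matrix of model expectations;
    ``n_pairs`` = n(n-1)/2 (190 for 20 regions).  Pairs involving a
    zero-variance series are skipped with a warning.
    """
    x = np.asarray(model_series, dtype=float)
    n, m = x.shape
    if n < 2:
        raise ValidationError("need at least 2 regions")
    if m < 3:
        raise ValidationError("need at least 3 months to define correlations")
    data = np.asarray(getattr(data_corr, "values", data_corr), dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance series; their pairs are "
            "skipped in the correlation regulariser", RuntimeWarning,
            stacklevel=2,
        )
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(degenerate, 1.0, sd)[:, None]
    corr = z @ z.T / m
    iu, ju = np.triu_indices(n, k=1)
    keep = ~(degenerate[iu] | degenerate[ju])
    n_pairs = n * (n - 1) // 2
    gaps = (corr[iu, ju] - data[iu, ju])[keep]
    return float(-upsilon / n_pairs * np.sum(gaps**2))


# ---------------------------------------------------------------------------
# Train/test protocol
# ---------------------------------------------------------------------------

_HALF_YEAR_PAIRS = [(m, m + 6) for m in range(1, 7)]  # (Jan,Jul) ... (Jun,Dec)


def make_split(
    months: list[tuple[int, int]], seed: int, generic: bool = False
) -> TrainTestSplit:
    """Hold out 12 of 108 months, one exemplar of each calendar month.

    The months must span 9 complete calendar years.  Nine distinct years
    can host the 12 test months, so three seeded-random years contribute
    two test months each, spaced six calendar months apart (e.g.
    April-October); the remaining six years contribute one month each.
    Pass ``generic=True`` to instead draw a plain uniform 12-month holdout
    from an arbitrary month list.
    """
    months = list(months)
    rng = np.random.default_rng(seed)
    if generic:
        if len(months) < 13:
            raise ValidationError("too few months for a 12-month holdout")
        test_idx = sorted(rng.choice(len(months), size=12, replace=False))
        test = [months[i] for i in test_idx]
        train = [mo for i, mo in enumerate(months) if i not in set(test_idx)]
        return TrainTestSplit(train_months=train, test_months=test)

    years = sorted({y for y, _ in months})
    by_year = {y: sorted(m for yy, m in months if yy == y) for y in years}
    if len(months) != 108 or len(years) != 9 or any(
        by_year[y] != list(range(1, 13)) for y in years
    ):
        raise ValidationError(
            "expected 108 months forming 9 complete calendar years; "
            "pass generic=True for a plain uniform holdout"
        )

    double_years = rng.choice(9, size=3, replace=False)
    pair_ids = rng.choice(6, size=3, replace=False)
    test: list[tuple[int, int]] = []
    for y_idx, p_idx in zip(double_years, pair_ids):
        lo, hi = _HALF_YEAR_PAIRS[p_idx]
        test += [(years[y_idx], lo), (years[y_idx], hi)]
    single_years = [y for i, y in enumerate(years) if i not in set(double_years)]
    leftover = sorted(
        m for p in set(range(6)) - set(pair_ids.tolist())
        for m in _HALF_YEAR_PAIRS[p]
    )
    order = rng.permutation(6)
    for y, m_idx in zip(single_years, order):
        test.append((y, leftover[m_idx]))
    test = sorted(test)
    test_set = set(test)
    train = [mo for mo in months if mo not in test_set]
    return TrainTestSplit(train_months=train, test_months=test)


# ---------------------------------------------------------------------------
# Parameter transforms
# ---------------------------------------------------------------------------

def _logit(x: float) -> float:
    x = min(max(x, 1e-9), 1.0 - 1e-9)
    return float(np.log(x / (1.0 - x)))


def params_to_theta(params: FullModelParams) -> np.ndarray:
    """Pack model parameters into the unconstrained optimisation vector."""
    return np.concatenate([
        [np.log(params.a_h), params.b_h],
        np.log(np.maximum(params.rho0, 1e-12)),
        [np.log(max(params.kappa_e, 1e-300)), np.log(params.d0_e),
         _logit(params.mu), np.log(params.a_beta), params.b_beta,
         np.log(max(params.gamma, 1e-12))],
    ])


def theta_to_params(theta: np.ndarray, n_regions: int) -> FullModelParams:
    """Inverse of :func:`params_to_theta`."""
    t = np.asarray(theta, dtype=float)
    n = n_regions
    return FullModelParams(
        a_h=float(np.exp(t[0])), b_h=float(t[1]),
        rho0=np.exp(t[2:2 + n]),
        kappa_e=float(np.exp(t[2 + n])), d0_e=float(np.exp(t[3 + n])),
        mu=float(1.0 / (1.0 + np.exp(-t[4 + n]))),
        a_beta=float(np.exp(t[5 + n])), b_beta=float(t[6 + n]),
        gamma=float(np.exp(t[7 + n])),
    )


def _decode_batch(thetas: np.ndarray, n: int) -> dict[str, np.ndarray]:
    """Vectorised theta -> natural-parameter arrays over a batch axis."""
    t = np.atleast_2d(thetas)
    return {
        "a_h": np.exp(t[:, 0]), "b_h": t[:, 1],
        "rho0": np.exp(t[:, 2:2 + n]),
        "kappa_e": np.exp(t[:, 2 + n]), "d0_e": np.exp(t[:, 3 + n]),
        "mu": 1.0 / (1.0 + np.exp(-t[:, 4 + n])),
        "a_beta": np.exp(t[:, 5 + n]), "b_beta": t[:, 6 + n],
        "gamma": np.exp(t[:, 7 + n]),
    }


# ---------------------------------------------------------------------------
# Vectorised forward model and objective
# ---------------------------------------------------------------------------

class _FitContext:
    """Precomputed constants shared by every objective evaluation."""

    def __init__(self, deaths: MonthlyPanel, temps: MonthlyPanel,
                 commuters: FluxMatrix, regions: RegionTable,
                 dist: DistanceMatrix, cfg: FitConfig):
        self.pops = regions.populations.astype(float)
        self.gdps = regions.gdps.astype(float)
        self.mass = self.pops[None, :] * self.gdps[:, None]  # pop_j * GDP_i
        self.dist = dist.values
        self.commuter = commuters.values.astype(float)
        self.temps = temps.values  # (n, M)
        self.deaths = deaths.values.astype(float)  # (n, M)
        self.n = regions.n
        self.cfg = cfg
        self.p0 = self.gdps / self.gdps.sum()
        self.offdiag = ~np.eye(self.n, dtype=bool)

    def total_flux_batch(self, kappa_e: np.ndarray, d0_e: np.ndarray):
        """(B,) scales/decays -> (B, n, n) total flux and raw outflow (B, n)."""
        episodic = kappa_e[:, None, None] * self.mass[None] \
            * np.exp(-self.dist[None] / d0_e[:, None, None])
        episodic *= self.offdiag[None]
        f = self.commuter[None] + episodic
        raw_frac = f.sum(axis=-2) / self.pops
        return f, raw_frac


def _batched_mixing(f: np.ndarray, pops: np.ndarray, max_frac: float = 0.95):
    """Mixing matrices for a (B, n, n) flux stack.

    Slices whose outflow fraction would reach 1 (unphysical: more
    travellers than residents) are rescaled to ``max_frac``; the flat-prior
    penalty, computed on the raw fractions, steers the optimiser back long
    before this guard matters.
    """
    frac = f.sum(axis=-2) / pops
    worst = frac.max(axis=-1)  # (B,)
    scale = np.minimum(1.0, max_frac / np.maximum(worst, 1e-300))
    f = f * scale[:, None, None]
    phi = f / pops
    diag = np.arange(f.shape[-1])
    phi[:, diag, diag] = 1.0 - f.sum(axis=-2) / pops
    rowsum = phi.sum(axis=-1, keepdims=True)
    phi_hat = np.swapaxes(phi / rowsum, -1, -2)
    return phi, phi_hat


def _lambda_batch(thetas: np.ndarray, ctx: _FitContext,
                  month_idx: np.ndarray, i0s: np.ndarray):
    """Model expectations for every (parameter slice, batch month) pair.

    Returns lam (B, nb, n) plus the raw outflow fractions (B, n) and the
    decoded parameter dict (for the priors).
    """
    n = ctx.n
    par = _decode_batch(thetas, n)
    B = par["a_h"].shape[0]
    nb = len(month_idx)
    f, raw_frac = ctx.total_flux_batch(par["kappa_e"], par["d0_e"])
    phi, phi_hat = _batched_mixing(f, ctx.pops)

    T = ctx.temps[:, month_idx].T  # (nb, n)
    beta = np.minimum(
        np.exp(-par["a_beta"][:, None, None] * T[None]
               + par["b_beta"][:, None, None]),
        BETA_CAP_FACTOR,
    )  # (B, nb, n); dt = 1 day
    S = np.broadcast_to(ctx.pops, (B, nb, n)).copy()
    I = np.zeros((B, nb, n))
    rows = np.arange(nb)
    S[:, rows, i0s] -= 1.0
    I[:, rows, i0s] = 1.0
    R = np.zeros((B, nb, n))
    clamp: list = []
    S, I, R = _euler_sweep(S, I, R, phi[:, None], phi_hat[:, None], beta,
                           par["gamma"][:, None, None], ctx.pops, 1.0, 30,
                           clamp_counter=clamp)
    warm = ctx.pops[None, None, :] * np.exp(
        par["a_h"][:, None, None] * T[None] + par["b_h"][:, None, None]
    )
    lam = warm + par["rho0"][:, None, :] + par["mu"][:, None, None] * R
    return lam, raw_frac, par


def _batched_corr_penalty(lam: np.ndarray, data_corr: np.ndarray,
                          upsilon: float) -> np.ndarray:
    """(B, nb, n) model expectations -> (B,) correlation penalties."""
    x = np.swapaxes(lam, 1, 2)  # (B, n, nb)
    m = x.shape[-1]
    sd = x.std(axis=-1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - x.mean(axis=-1, keepdims=True)) / sd[..., None]
    corr = z @ np.swapaxes(z, -1, -2) / m  # (B, n, n)
    n = x.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    gaps = corr[:, iu, ju] - data_corr[iu, ju][None]
    n_pairs = n * (n - 1) // 2
    return -upsilon / n_pairs * np.sum(gaps**2, axis=-1)


def _data_corr(counts: np.ndarray, on_rates: bool) -> np.ndarray:
    x = counts / counts.mean(axis=1, keepdims=True) if on_rates else counts
    sd = x.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return z @ z.T / x.shape[1]


def _objective_batch(thetas: np.ndarray, ctx: _FitContext,
                     month_idx: np.ndarray, i0s: np.ndarray,
                     with_corr: bool,
                     data_corr: np.ndarray | None = None) -> np.ndarray:
    """Objective (to maximise) for each parameter slice; shape (B,).

    ``data_corr`` is the fixed observed-correlation target for the
    regulariser (the training loop passes the training-set correlation
    matrix); if None it is computed from the batch months themselves.
    """
    cfg = ctx.cfg
    lam, raw_frac, par = _lambda_batch(thetas, ctx, month_idx, i0s)
    counts = ctx.deaths[:, month_idx].T[None]  # (1, nb, n)
    ll = np.mean(
        np.where(counts > 0, counts * np.log(np.maximum(lam, 1e-300)), 0.0)
        - lam,
        axis=(1, 2),
    )
    excess = np.maximum(raw_frac - cfg.flux_fraction_hi, 0.0) \
        + np.maximum(cfg.flux_fraction_lo - raw_frac, 0.0)
    prior_flux = -cfg.flux_prior_stiffness * np.sum(excess**2, axis=-1)
    prior_d0e = -cfg.d0e_prior_coeff * par["d0_e"] ** 2
    obj = ll + prior_flux + prior_d0e
    if with_corr and cfg.upsilon_corr > 0:
        if data_corr is None:
            data_corr = _data_corr(ctx.deaths[:, month_idx], cfg.corr_on_rates)
        obj = obj + _batched_corr_penalty(lam, data_corr, cfg.upsilon_corr)
    return obj


def batch_objective(params: FullModelParams, deaths: MonthlyPanel,
                    temps: MonthlyPanel, commuters: FluxMatrix,
                    regions: RegionTable, dist: DistanceMatrix,
                    month_idx: np.ndarray, i0s: np.ndarray, cfg: FitConfig,
                    with_corr: bool = False) -> float:
    """The training objective at given parameters for a fixed batch."""
    ctx = _FitContext(deaths, temps, commuters, regions, dist, cfg)
    theta = params_to_theta(params)
    return float(_objective_batch(theta[None], ctx, np.asarray(month_idx),
                                  np.asarray(i0s), with_corr)[0])


def evaluate_test_ll(theta: np.ndarray, ctx: _FitContext,
                     test_idx: np.ndarray, rng: np.random.Generator) -> float:
    """Held-out log-likelihood, patient-zero expectation by sampling."""
    draws = ctx.cfg.test_i0_draws
    month_idx = np.repeat(test_idx, draws)
    i0s = rng.choice(ctx.n, size=len(month_idx), p=ctx.p0)
    lam = _lambda_batch(theta[None], ctx, month_idx, i0s)[0][0]  # (nm, n)
    counts = ctx.deaths[:, month_idx].T
    return poisson_loglik(counts, lam)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _initial_params(deaths: MonthlyPanel, temps: MonthlyPanel,
                    commuters: FluxMatrix, regions: RegionTable,
                    dist: DistanceMatrix) -> FullModelParams:
    """Deterministic data-driven starting point.

    Warm arm from a log-linear regression on the hottest tercile of
    region-months; baselines from region means; episodic decay length from
    twice the commuter gravity fit's d0, with a scale giving a ~1% mean
    outflow fraction; the remaining scalars at mild defaults.
    """
    T = temps.values
    D = deaths.values
    flat_T = T.ravel()
    rate = np.log(np.maximum(D, 0.5) / regions.populations[:, None]).ravel()
    hot = flat_T >= np.quantile(flat_T, 2.0 / 3.0)
    slope, intercept = np.polyfit(flat_T[hot], rate[hot], 1)
    a_h = float(np.clip(slope, 0.01, 1.0))
    b_h = float(intercept - 1.0)  # keep the warm arm below the data at start
    rho0 = 0.75 * D.mean(axis=1)

    try:
        grav = fit_gravity(commuters, dist, regions)
        d0_e = 2.0 * grav.d0
    except ValidationError:
        d0_e = 2.0 * float(np.median(dist.values[dist.values > 0]))
    unit_outflow = (
        (regions.populations[None, :] * regions.gdps[:, None]
         * np.exp(-dist.values / d0_e)) * (~np.eye(regions.n, dtype=bool))
    ).sum(axis=0) / regions.populations
    kappa_e = 0.01 / float(np.mean(unit_outflow))

    mean_T = float(np.mean(T))
    a_beta = 0.05
    b_beta = float(np.log(0.4) + a_beta * min(mean_T, 10.0))
    return FullModelParams(
        a_h=a_h, b_h=b_h, rho0=np.maximum(rho0, 0.5),
        kappa_e=kappa_e, d0_e=d0_e, mu=0.1,
        a_beta=a_beta, b_beta=b_beta, gamma=0.3,
    )


# ---------------------------------------------------------------------------
# Main fitting loop
# ---------------------------------------------------------------------------

def fit_full_model(
    deaths: MonthlyPanel,
    temps: MonthlyPanel,
    commuters: FluxMatrix,
    regions: RegionTable,
    dist: DistanceMatrix,
    split: TrainTestSplit,
    cfg: FitConfig,
    init: FullModelParams | None = None,
) -> tuple[FullModelParams, pd.DataFrame]:
    """Stochastic Adam maximisation of the penalised Poisson likelihood.

    Returns the fitted parameters and a training log with columns
    ``step, lr, nbatch, train_obj, test_ll`` (test LL evaluated every
    ``cfg.test_eval_interval`` steps, NaN elsewhere).  Fully deterministic
    for a given ``cfg.seed``.
    """
    if deaths.region_ids != temps.region_ids:
        raise ValidationError("deaths and temperature panels disagree on regions")
    if deaths.months != temps.months:
        raise ValidationError("deaths and temperature panels disagree on months")
    month_pos = {mo: i for i, mo in enumerate(deaths.months)}
    try:
        train_idx = np.array([month_pos[mo] for mo in split.train_months])
        test_idx = np.array([month_pos[mo] for mo in split.test_months])
    except KeyError as e:  # pragma: no cover - defensive
        raise ValidationError(f"split names unknown month {e}") from None

    ctx = _FitContext(deaths, temps, commuters, regions, dist, cfg)
    n = ctx.n
    p = 8 + n
    if init is None:
        init = _initial_params(deaths, temps, commuters, regions, dist)
    theta = params_to_theta(init)
    # fixed regulariser target: the observed between-region correlations
    # over the training months
    train_corr = _data_corr(ctx.deaths[:, train_idx], cfg.corr_on_rates)

    rng = np.random.default_rng(cfg.seed)
    test_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    h = cfg.fd_step
    eye = np.eye(p)
    m_t = np.zeros(p)
    v_t = np.zeros(p)
    log_rows = []

    for step in range(cfg.n_steps):
        with_corr = step >= cfg.phase_switch_step
        nb = cfg.nbatch_phase2 if with_corr else cfg.nbatch_phase1
        month_idx = train_idx[rng.integers(0, len(train_idx), size=nb)]
        i0s = rng.choice(n, size=nb, p=ctx.p0)

        thetas = np.vstack([theta[None], theta + h * eye, theta - h * eye])
        obj = _objective_batch(thetas, ctx, month_idx, i0s, with_corr,
                               data_corr=train_corr)
        if not np.all(np.isfinite(obj)):
            raise FloatingPointError(
                f"non-finite objective at step {step}; params: "
                f"{theta_to_params(theta, n)}"
            )
        grad = (obj[1:p + 1] - obj[p + 1:]) / (2.0 * h)

        lr = learning_rate(step, cfg)
        m_t = cfg.adam_beta1 * m_t + (1 - cfg.adam_beta1) * grad
        v_t = cfg.adam_beta2 * v_t + (1 - cfg.adam_beta2) * grad**2
        m_hat = m_t / (1 - cfg.adam_beta1 ** (step + 1))
        v_hat = v_t / (1 - cfg.adam_beta2 ** (step + 1))
        theta = theta + lr * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)

        if step % cfg.log_interval == 0 or step == cfg.n_steps - 1:
            test_ll = np.nan
            if step % cfg.test_eval_interval == 0 or step == cfg.n_steps - 1:
                test_ll = evaluate_test_ll(theta, ctx, test_idx, test_rng)
            log_rows.append((step, lr, nb, float(obj[0]), test_ll))

    log = pd.DataFrame(log_rows,
                       columns=["step", "lr", "nbatch", "train_obj", "test_ll"])
    return theta_to_params(theta, n), log


# ---------------------------------------------------------------------------
# Model series for correlation comparison
# ---------------------------------------------------------------------------

def model_lambda_series(
    params: FullModelParams,
    temps: MonthlyPanel,
    commuters: FluxMatrix,
    regions: RegionTable,
    dist: DistanceMatrix,
    i0_seq: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Model expected-death series (n_regions, n_months) over a whole panel.

    Patient zeros come from ``i0_seq`` if given, otherwise one GDP-weighted
    draw per month using ``seed``; if both are None the expectation over
    the patient-zero distribution is returned instead.
    """
    cfg = FitConfig(seed=0)
    ctx = _FitContext(
        MonthlyPanel(temps.region_ids, temps.months,
                     np.zeros_like(temps.values), "deaths"),
        temps, commuters, regions, dist, cfg,
    )
    theta = params_to_theta(params)
    M = temps.n_months
    month_idx = np.arange(M)
    if i0_seq is None and seed is not None:
        i0_seq = np.random.default_rng(seed).choice(ctx.n, size=M, p=ctx.p0)
    if i0_seq is not None:
        lam = _lambda_batch(theta[None], ctx, month_idx,
                            np.asarray(i0_seq))[0][0]
        return lam.T  # (n, M)
    # exact expectation over i0
    out = np.zeros((ctx.n, M))
    for i0 in range(ctx.n):
        lam = _lambda_batch(theta[None], ctx, month_idx,
                            np.full(M, i0))[0][0]
        out += ctx.p0[i0] * lam.T
    return out
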