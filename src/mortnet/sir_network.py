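"""Monthly-restarting metapopulation SIR on the traveller-flux network.

Each month an epidemic starts afresh from a single patient zero placed in
region ``i0`` with probability proportional to regional GDP.  During the
day residents mix across regions according to the column-stochastic matrix
``phi`` built from the total flux ``f_ij``; new infections arise in the
pooled daytime populations and are redistributed home at night by the
reverse-flux matrix ``phi_hat``.  The dynamics are integrated with the
explicit Euler method (dt = 1 day) for a 30-day month; a fraction ``mu``
of the individuals recovered by day 30 dies, contributing the infective
component of monthly mortality on top of a warm-season temperature term
and a region-specific baseline.

The Euler core is written over arbitrary leading batch axes so that many
(month, patient-zero, parameter-perturbation) combinations integrate in a
single vectorised sweep; the stochastic fitting loop relies on this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import FluxMatrix, RegionTable, ValidationError

# strict inequality beta < 1/dt needs a concrete ceiling
BETA_CAP_FACTOR = 1.0 - 1e-9


@dataclass(frozen=True)
class MixingMatrices:
    """Daytime mixing matrix ``phi`` and night redistribution ``phi_hat``.

    Both are column-stochastic: column j of ``phi`` distributes region j's
    residents over their daytime locations; column j of ``phi_hat``
    distributes infections arising in pool j back to residence regions.
    """

    phi: np.ndarray
    phi_hat: np.ndarray


@dataclass
class SIRState:
    """Per-region susceptible/infected/recovered counts (real-valued)."""

    S: np.ndarray
    I: np.ndarray
    R: np.ndarray

    def total(self) -> float:
        return float(np.sum(self.S + self.I + self.R))


@dataclass
class EpidemicConfig:
    """Integration settings for one monthly epidemic."""

    beta: np.ndarray  # per-region transmission rate, 1/day
    gamma: float  # recovery rate, 1/day
    dt: float = 1.0
    t_end: float = 30.0
    i0: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.beta < 0) or np.any(self.beta * self.dt >= 1.0):
            raise ValidationError("beta must satisfy 0 <= beta < 1/dt")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        n_steps = self.t_end / self.dt
        if not np.isclose(n_steps, round(n_steps)) or n_steps <= 0:
            raise ValidationError("t_end must be a positive multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class FullModelParams:
    """The 8 + n free parameters of the flux-temperature mortality model.

    Monthly expected deaths in region i given patient zero in ``i0``:

        lambda_i = pop_i * exp(a_h * T_i + b_h) + rho0_i + mu * R_i(30)

    with the epidemic driven by ``beta_i = exp(-a_beta * T_i + b_beta)``
    (capped just below 1/dt), recovery rate ``gamma``, and the episodic
    flux scale/decay (``kappa_e``, ``d0_e``) completing the network.
    """

    a_h: float  # warm-arm slope, 1/degC
    b_h: float  # warm-arm log-rate offset
    rho0: np.ndarray  # baseline deaths/month per region
    kappa_e: float  # episodic flux scale
    d0_e: float  # episodic decay length, km
    mu: float  # deaths per recovered individual
    a_beta: float  # transmission-temperature slope, 1/degC
    b_beta: float  # transmission log-rate offset
    gamma: float  # recovery rate, 1/day

    def __post_init__(self) -> None:
        self.rho0 = np.asarray(self.rho0, dtype=float)
        if not self.a_h > 0:
            raise ValidationError("a_h must be > 0")
        if not self.a_beta > 0:
            raise ValidationError("a_beta must be > 0")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValidationError("mu must be in [0, 1]")
        if self.kappa_e < 0 or not self.d0_e > 0:
            raise ValidationError("kappa_e >= 0 and d0_e > 0 required")
        if np.any(self.rho0 < 0):
            raise ValidationError("rho0 must be non-negative")

    @property
    def n_regions(self) -> int:
        return len(self.rho0)

    @property
    def n_params(self) -> int:
        return 8 + self.n_regions


# ---------------------------------------------------------------------------
# Mixing matrices
# ---------------------------------------------------------------------------

def mixing_matrices(flux: FluxMatrix, regions: RegionTable) -> MixingMatrices:
    """Build ``phi`` and ``phi_hat`` from a total-flux matrix.

    phi[i, j] = f_ij / pop_j off-diagonal, 1 - (outflow fraction of j) on
    the diagonal; every column sums to 1 by construction.  phi_hat is the
    reverse-flux redistribution, phi_hat[i, j] = phi[j, i] / sum_k phi[j, k],
    also column-stochastic, which makes the night-time redistribution of
    new infections conserve individuals.
    """
    phi, phi_hat = _mixing_arrays(flux.values, regions.populations)
    return MixingMatrices(phi=phi, phi_hat=phi_hat)


def _mixing_arrays(flux_values: np.ndarray, pops: np.ndarray):
    """Batched mixing-matrix construction; flux_values may have batch axes."""
    f = np.asarray(flux_values, dtype=float)
    outflow = f.sum(axis=-2) / pops  # (..., n): fraction of j's residents away
    if np.any(outflow >= 1.0):
        idx = int(np.argmax(np.max(outflow.reshape(-1, f.shape[-1]), axis=0)))
        raise ValidationError(
            f"region index {idx}: daily outflow exceeds its population"
        )
    phi = f / pops  # broadcasts pops over columns
    diag = np.arange(f.shape[-1])
    phi[..., diag, diag] = 1.0 - outflow
    rowsum = phi.sum(axis=-1, keepdims=True)  # (..., n, 1)
    phi_hat = np.swapaxes(phi / rowsum, -1, -2)
    return phi, phi_hat


# ---------------------------------------------------------------------------
# Transmission rate
# ---------------------------------------------------------------------------

def beta_of_temperature(T, a_beta: float, b_beta: float, dt: float = 1.0):
    """Temperature-dependent transmission ``min(exp(-a_beta T + b_beta), cap)``.

    Colder months are more contagious; the cap just below 1/dt keeps the
    Euler update physical (at beta = 1/dt a whole pool would be infected
    in a single step).
    """
    if not a_beta > 0:
        raise ValidationError("a_beta must be > 0")
    return np.minimum(np.exp(-a_beta * np.asarray(T, dtype=float) + b_beta),
                      BETA_CAP_FACTOR / dt)


# ---------------------------------------------------------------------------
# Euler integration
# ---------------------------------------------------------------------------

def _euler_sweep(S, I, R, phi, phi_hat, beta, gamma, pops, dt, n_steps,
                 clamp_counter: list | None = None):
    """Run ``n_steps`` Euler steps over arbitrary leading batch axes.

    Shapes: S, I, R, beta -> (..., n); phi, phi_hat -> broadcastable
    (..., n, n); gamma scalar or (..., 1); pops (n,).  Returns final
    (S, I, R).

    With beta near the 1/dt cap the explicit Euler update can overshoot:
    a step may ask for more new infections (or recoveries) than the
    compartment holds.  Flows are capped at the available mass — the
    states are clamped at zero without creating or destroying individuals,
    so conservation survives the guard — and each capped step is counted
    (or warned about when no counter is supplied).
    """
    gamma = np.asarray(gamma, dtype=float)
    for _ in range(n_steps):
        S_pool = (phi @ S[..., None])[..., 0]
        I_pool = (phi @ I[..., None])[..., 0]
        dI_pool = beta * S_pool * I_pool / pops
        new_I = (phi_hat @ dI_pool[..., None])[..., 0]
        recov = gamma * I
        over = np.sum(new_I * dt > S) + np.sum(recov * dt > I)
        if over:
            if clamp_counter is not None:
                clamp_counter.append(int(over))
            else:
                warnings.warn(
                    "Euler step overshot a compartment; flow capped",
                    RuntimeWarning, stacklevel=2)
            new_I = np.minimum(new_I, S / dt)
            recov = np.minimum(recov, I / dt)
        S = S - dt * new_I
        I = I + dt * (new_I - recov)
        R = R + dt * recov
        if not (np.all(np.isfinite(S)) and np.all(np.isfinite(I))):
            raise FloatingPointError("non-finite SIR state during Euler sweep")
    return S, I, R


def sir_step(state: SIRState, mix: MixingMatrices, cfg: EpidemicConfig,
             regions: RegionTable) -> SIRState:
    """One Euler step of size dt; conserves total S+I+R."""
    S, I, R = _euler_sweep(
        state.S.astype(float), state.I.astype(float), state.R.astype(float),
        mix.phi, mix.phi_hat, cfg.beta, cfg.gamma, regions.populations,
        cfg.dt, 1,
    )
    return SIRState(S=S, I=I, R=R)


def run_monthly_epidemic(
    month_temps: np.ndarray,
    i0: int,
    flux: FluxMatrix,
    params: FullModelParams,
    regions: RegionTable,
    mix: MixingMatrices | None = None,
) -> np.ndarray:
    """Evolve one 30-day epidemic from patient zero in ``i0``; returns R(30).

    Initial state: everyone susceptible except one infected individual in
    region ``i0``.  ``mix`` may be passed to reuse precomputed matrices.
    """
    n = regions.n
    if not 0 <= i0 < n:
        raise ValidationError(f"patient-zero index {i0} out of range")
    if mix is None:
        mix = mixing_matrices(flux, regions)
    beta = beta_of_temperature(month_temps, params.a_beta, params.b_beta)
    S = regions.populations.astype(float).copy()
    I = np.zeros(n)
    R = np.zeros(n)
    S[i0] -= 1.0
    I[i0] = 1.0
    S, I, R = _euler_sweep(S, I, R, mix.phi, mix.phi_hat, beta, params.gamma,
                           regions.populations, 1.0, 30)
    return R


def patient_zero_distribution(regions: RegionTable) -> np.ndarray:
    """p(i0 = i) proportional to GDP_i (GDP as a proxy of external inflow)."""
    return regions.gdps / regions.gdps.sum()


def expected_deaths(
    month_temps: np.ndarray,
    i0: int,
    flux: FluxMatrix,
    params: FullModelParams,
    regions: RegionTable,
    mix: MixingMatrices | None = None,
) -> np.ndarray:
    """Expected monthly deaths per region given patient zero in ``i0``.

    lambda_i = pop_i exp(a_h T_i + b_h) + rho0_i + mu R_i(30).
    """
    R30 = run_monthly_epidemic(month_temps, i0, flux, params, regions, mix=mix)
    warm = regions.populations * np.exp(params.a_h * np.asarray(month_temps)
                                        + params.b_h)
    lam = warm + params.rho0 + params.mu * R30
    if np.any(lam <= 0):
        bad = [regions.region_ids[i] for i in np.nonzero(lam <= 0)[0]]
        raise ValidationError(
            f"expected deaths not positive for region(s) {bad}; "
            "all three mortality components vanish"
        )
    return lam


def expected_deaths_over_i0(
    month_temps: np.ndarray,
    flux: FluxMatrix,
    params: FullModelParams,
    regions: RegionTable,
    mix: MixingMatrices | None = None,
) -> np.ndarray:
    """Expectation of lambda over the patient-zero distribution p(i0) ~ GDP."""
    if mix is None:
        mix = mixing_matrices(flux, regions)
    p = patient_zero_distribution(regions)
    lam = np.zeros(regions.n)
    for i0 in range(regions.n):
        lam += p[i0] * expected_deaths(month_temps, i0, flux, params, regions,
                                       mix=mix)
    return lam
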