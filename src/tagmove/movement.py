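"""Movement configurations: Dirichlet-by-normalisation matrices with optional
year/age random effects.

Annual movement among regions is parameterised by strictly positive movement
weights ``gamma[k, k']`` normalised row-wise, which with iid gamma(1, 1)
(i.e. Exponential(1)) priors induces a flat Dirichlet prior on each row of the
movement matrix. Seven configurations share this construction:

======  =======================================================
kind    structure of the movement weights
======  =======================================================
C       one shared matrix
YF      independent weights per year (fixed year effects)
YR      log-weights per year ~ N(log psi, tau) (year random effects)
AF      independent weights per age (fixed age effects)
AR      log-weights per age ~ N(log phi, omega) (age random effects)
AY      nested random effects: age level delta around phi (sd nu_a),
        year level gamma around delta (sd nu_y)
AYc     AY plus a release-year partial-dispersal correction `ratio`
======  =======================================================

All random-effect spread parameters (tau, omega, nu_a, nu_y) are standard
deviations on the log scale with Uniform(0, 1) priors; ``ratio`` in (0, 1)
scales off-region movement in the release year (1 = full dispersal).
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass

import numpy as np

from .tag_data import StudyFrame

__all__ = [
    "MOVEMENT_KINDS",
    "MovementConfig",
    "MovementParams",
    "MovementMatrix",
    "normalize_movement",
    "initial_year_correction",
    "build_movement",
    "log_prior_movement",
    "sample_prior_movement",
]

MOVEMENT_KINDS = ("C", "YF", "YR", "AF", "AR", "AY", "AYc")


@dataclass(frozen=True)
class MovementConfig:
    """Which movement structure to fit."""

    kind: str = "C"

    def __post_init__(self) -> None:
        if self.kind not in MOVEMENT_KINDS:
            raise ValueError(f"unknown movement kind {self.kind!r}; "
                             f"choose one of {MOVEMENT_KINDS}")

    @property
    def with_initial_correction(self) -> bool:
        return self.kind == "AYc"

    @property
    def by_year(self) -> bool:
        return self.kind in ("YF", "YR", "AY", "AYc")

    @property
    def by_age(self) -> bool:
        return self.kind in ("AF", "AR", "AY", "AYc")


@dataclass
class MovementParams:
    """Natural-scale movement parameters for one configuration.

    ``gamma`` carries the bottom-level weights: shape ``(K, K)`` for C,
    ``(Y, K, K)`` for YF/YR, ``(A, K, K)`` for AF/AR and ``(A, Y, K, K)`` for
    AY/AYc. Hierarchy means (``psi``/``phi``/``delta``), spreads and the
    release-year ``ratio`` exist only for the configurations that use them.
    """

    gamma: np.ndarray
    psi: np.ndarray | None = None
    phi: np.ndarray | None = None
    delta: np.ndarray | None = None
    tau: float | None = None
    omega: float | None = None
    nu_a: float | None = None
    nu_y: float | None = None
    ratio: float | None = None


def _gamma_shape(config: MovementConfig, frame: StudyFrame) -> tuple[int, ...]:
    A, Y, K = frame.n_ages, frame.n_years, frame.n_regions
    return {
        "C": (K, K),
        "YF": (Y, K, K),
        "YR": (Y, K, K),
        "AF": (A, K, K),
        "AR": (A, K, K),
        "AY": (A, Y, K, K),
        "AYc": (A, Y, K, K),
    }[config.kind]


def normalize_movement(gamma_row: np.ndarray) -> np.ndarray:
    """Normalise one row of strictly positive weights into probabilities."""
    g = np.asarray(gamma_row, dtype=float)
    if (g <= 0).any() or not np.isfinite(g).all():
        raise ValueError("movement weights must be strictly positive and finite")
    return g / g.sum(axis=-1, keepdims=True)


def initial_year_correction(pi_row: np.ndarray, ratio: float, source: int = 0
                            ) -> np.ndarray:
    """Shrink off-region movement in the (partial) release year.

    The probability of staying in the release region ``source`` gains
    ``(1 - ratio)`` times the off-region mass; every off-region probability
    is scaled by ``ratio``. ``ratio = 1`` is full dispersal, ``ratio = 0``
    no dispersal.
    """
    row = np.asarray(pi_row, dtype=float)
    out = ratio * row
    off = row.sum() - row[source]
    out[source] = row[source] + (1.0 - ratio) * off
    return out


@dataclass
class MovementMatrix:
    """Row-stochastic movement probabilities on the full (age, year) grid.

    ``pi[a, y, k, k']`` broadcasts simple configurations over unused indices.
    ``pi_init`` is the release-year-corrected matrix (AYc only, else None).
    """

    pi: np.ndarray
    pi_init: np.ndarray | None = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        rs = self.pi.sum(axis=-1)
        if not np.allclose(rs, 1.0, atol=1e-12):
            raise ValueError("movement matrix rows must sum to 1")
        if self.pi_init is not None:
            rs0 = self.pi_init.sum(axis=-1)
            if not np.allclose(rs0, 1.0, atol=1e-12):
                raise ValueError("corrected movement rows must sum to 1")


def _require(config: MovementConfig, params: MovementParams, *names: str) -> None:
    for name in names:
        if getattr(params, name) is None:
            raise ValueError(f"movement config {config.kind} requires "
                             f"parameter block {name!r}")


def build_movement(params: MovementParams, config: MovementConfig,
                   frame: StudyFrame, validate: bool = True) -> MovementMatrix:
    """Assemble the full ``pi[a, y, k, k']`` array for a configuration."""
    A, Y, K = frame.n_ages, frame.n_years, frame.n_regions
    gamma = np.asarray(params.gamma, dtype=float)
    want = _gamma_shape(config, frame)
    if gamma.shape != want:
        raise ValueError(
            f"gamma shape {gamma.shape} != {want} for config {config.kind}"
        )
    base = normalize_movement(gamma)
    if config.kind == "C":
        pi = np.broadcast_to(base, (A, Y, K, K))
    elif config.kind in ("YF", "YR"):
        pi = np.broadcast_to(base[None, :, :, :], (A, Y, K, K))
    elif config.kind in ("AF", "AR"):
        pi = np.broadcast_to(base[:, None, :, :], (A, Y, K, K))
    else:  # AY / AYc
        pi = base
    pi = np.ascontiguousarray(pi)

    pi_init = None
    if config.with_initial_correction:
        _require(config, params, "ratio")
        ratio = float(params.ratio)
        # ratio = 1 (identity correction) kept valid for limiting checks
        if not 0.0 < ratio <= 1.0:
            raise ValueError("ratio must lie in (0, 1]")
        pi_init = ratio * pi
        diag = pi[:, :, np.arange(K), np.arange(K)].copy()  # stay probabilities
        off = 1.0 - diag
        k_idx = np.arange(K)
        pi_init[:, :, k_idx, k_idx] = diag + (1.0 - ratio) * off
    return MovementMatrix(pi=pi, pi_init=pi_init, validate=validate)


def _lognormal_logpdf(x: np.ndarray, mu_log: np.ndarray, sd: float) -> np.ndarray:
    lx = np.log(x)
    return (
        -lx - np.log(sd) - 0.5 * np.log(2.0 * np.pi)
        - 0.5 * ((lx - mu_log) / sd) ** 2
    )


def log_prior_movement(params: MovementParams, config: MovementConfig) -> float:
    """Joint log prior density of all movement parameters (natural scale).

    Exponential(1) on every free top-level weight, log-normal layers for the
    random-effect configurations, Uniform(0, 1) on spreads and ``ratio``.
    Returns ``-inf`` outside the support.
    """
    gamma = np.asarray(params.gamma, dtype=float)
    if (gamma <= 0).any():
        return -np.inf
    kind = config.kind
    total = 0.0
    if kind in ("C", "YF", "AF"):
        total += float(-gamma.sum())
    elif kind == "YR":
        _require(config, params, "psi", "tau")
        psi = np.asarray(params.psi, dtype=float)
        tau = float(params.tau)
        if (psi <= 0).any() or not 0.0 < tau < 1.0:
            return -np.inf
        total += float(-psi.sum())
        total += float(_lognormal_logpdf(gamma, np.log(psi)[None], tau).sum())
    elif kind == "AR":
        _require(config, params, "phi", "omega")
        phi = np.asarray(params.phi, dtype=float)
        omega = float(params.omega)
        if (phi <= 0).any() or not 0.0 < omega < 1.0:
            return -np.inf
        total += float(-phi.sum())
        total += float(_lognormal_logpdf(gamma, np.log(phi)[None], omega).sum())
    else:  # AY / AYc
        _require(config, params, "phi", "delta", "nu_a", "nu_y")
        phi = np.asarray(params.phi, dtype=float)
        delta = np.asarray(params.delta, dtype=float)
        nu_a, nu_y = float(params.nu_a), float(params.nu_y)
        if (phi <= 0).any() or (delta <= 0).any():
            return -np.inf
        if not (0.0 < nu_a < 1.0 and 0.0 < nu_y < 1.0):
            return -np.inf
        total += float(-phi.sum())
        total += float(_lognormal_logpdf(delta, np.log(phi)[None], nu_a).sum())
        total += float(
            _lognormal_logpdf(gamma, np.log(delta)[:, None], nu_y).sum()
        )
        if kind == "AYc":
            _require(config, params, "ratio")
            if not 0.0 < float(params.ratio) < 1.0:
                return -np.inf
    return total


def sample_prior_movement(config: MovementConfig, frame: StudyFrame,
                          rng: np.random.Generator) -> MovementParams:
    """Draw a full movement-parameter set from its prior (for inits/truths)."""
    A, Y, K = frame.n_ages, frame.n_years, frame.n_regions
    kind = config.kind
    if kind in ("C", "YF", "AF"):
        return MovementParams(gamma=rng.exponential(1.0, _gamma_shape(config, frame)))
    if kind == "YR":
        psi = rng.exponential(1.0, (K, K))
        tau = rng.uniform(0.0, 1.0)
        gamma = np.exp(rng.normal(np.log(psi)[None], tau, (Y, K, K)))
        return MovementParams(gamma=gamma, psi=psi, tau=tau)
    if kind == "AR":
        phi = rng.exponential(1.0, (K, K))
        omega = rng.uniform(0.0, 1.0)
        gamma = np.exp(rng.normal(np.log(phi)[None], omega, (A, K, K)))
        return MovementParams(gamma=gamma, phi=phi, omega=omega)
    # AY / AYc
    phi = rng.exponential(1.0, (K, K))
    nu_a = rng.uniform(0.0, 1.0)
    nu_y = rng.uniform(0.0, 1.0)
    delta = np.exp(rng.normal(np.log(phi)[None], nu_a, (A, K, K)))
    gamma = np.exp(rng.normal(np.log(delta)[:, None], nu_y, (A, Y, K, K)))
    ratio = rng.uniform(0.0, 1.0) if kind == "AYc" else None
    return MovementParams(gamma=gamma, phi=phi, delta=delta,
                          nu_a=nu_a, nu_y=nu_y, ratio=ratio)
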