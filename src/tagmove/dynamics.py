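"""Selectivity, survival, exploitation and recovery-probability propagation.

The fate of a tagged cohort is driven by three annual processes: movement
among regions (a row-stochastic matrix ``pi``), continuous-time competing
mortality from fishing (``F`` scaled by age-specific gear selectivity ``s_a``)
and natural causes (``M``), and scanning/reporting of harvested fish
(``lam``). Within a year the order of events is movement first, then
harvest/death; ages advance at year boundaries, with the terminal age class
an absorbing plus-group.

The central object is the recovery-probability tensor
``P[a, ty, tk, fy, fk]``: the probability that a fish tagged at age ``a`` in
year ``ty`` and region ``tk`` is harvested *and reported* in year ``fy`` and
region ``fk``. It is built by iterative vector-matrix propagation of a
row-vector of presence probabilities, never by materialising the symbolic
matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tag_data import StudyFrame

__all__ = [
    "SelectivityParams",
    "DynamicsParams",
    "selectivity",
    "survival",
    "exploitation",
    "recovery_probability_tensor",
]


def selectivity(eta1: float, eta2: float, eta3: float, eta4: float,
                ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Double-logistic (dome-shaped) gillnet selectivity over age classes.

    The raw curve is the product of an increasing logistic with inflection
    ``eta1`` and slope ``eta2`` and a decreasing logistic with inflection
    ``eta3`` and slope ``eta4``::

        s_raw(a) = [1 / (1 + exp(-eta2 (a - eta1)))] *
                   [1 - 1 / (1 + exp(-eta4 (a - eta3)))]

    and is standardised by its maximum so at least one age class is fully
    selected.

    Returns
    -------
    (s_raw, s) : raw and standardised selectivity arrays over ``ages``.
    """
    a = np.asarray(ages, dtype=float)
    with np.errstate(over="ignore"):  # saturating logistic tails are fine
        rise = 1.0 / (1.0 + np.exp(-eta2 * (a - eta1)))
        fall = 1.0 - 1.0 / (1.0 + np.exp(-eta4 * (a - eta3)))
    s_raw = rise * fall
    peak = s_raw.max()
    if not peak > 0.0:
        raise ValueError(
            f"degenerate selectivity: s_raw identically zero for "
            f"eta=({eta1}, {eta2}, {eta3}, {eta4})"
        )
    return s_raw, s_raw / peak


@dataclass
class SelectivityParams:
    """Double-logistic selectivity parameters and the derived curves."""

    eta1: float
    eta2: float
    eta3: float
    eta4: float
    ages: np.ndarray
    s_raw: np.ndarray = field(init=False)
    s: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages)
        self.s_raw, self.s = selectivity(
            self.eta1, self.eta2, self.eta3, self.eta4, self.ages
        )


def survival(s_a, F, M):
    """Annual survival under competing fishing and natural mortality.

    ``S = exp(-s_a F - M)`` with instantaneous rates acting over one year.
    Broadcasts over any compatible shapes.
    """
    s_a = np.asarray(s_a, dtype=float)
    F = np.asarray(F, dtype=float)
    M = np.asarray(M, dtype=float)
    if (F < 0).any() or (M < 0).any():
        raise ValueError("mortality rates must be non-negative")
    return np.exp(-s_a * F - M)


def exploitation(s_a, F, M, S=None):
    """Annual exploitation rate from the competing-risks decomposition.

    ``u = s_a F / (s_a F + M) * (1 - S)``: of the fish that die within the
    year, the fraction attributable to fishing. With no mortality at all the
    rate is zero.
    """
    s_a = np.asarray(s_a, dtype=float)
    F = np.asarray(F, dtype=float)
    M = np.asarray(M, dtype=float)
    if S is None:
        S = survival(s_a, F, M)
    Z = s_a * F + M
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(Z > 0.0, s_a * F / np.where(Z > 0.0, Z, 1.0) * (1.0 - S), 0.0)
    return u


@dataclass
class DynamicsParams:
    """Mortality and selectivity bundle with derived survival/exploitation.

    Parameters
    ----------
    M : instantaneous natural mortality per year (all ages).
    F : fishing mortality ``F[k, fy]`` per region and year.
    sel : selectivity parameters over the frame's age classes.

    Derived attributes are ``S[a, y, k]`` and ``u[a, y, k]``.
    """

    frame: StudyFrame
    M: float
    F: np.ndarray
    sel: SelectivityParams
    S: np.ndarray = field(init=False)
    u: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        f = self.frame
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (f.n_regions, f.n_years):
            raise ValueError(
                f"F shape {self.F.shape} != {(f.n_regions, f.n_years)}"
            )
        if self.M <= 0:
            raise ValueError("natural mortality M must be positive")
        if (self.F < 0).any():
            raise ValueError("fishing mortality must be non-negative")
        s = self.sel.s  # (A,)
        # broadcast to (A, Y, K): F is (K, Y) -> transpose to (Y, K)
        sF = s[:, None, None] * self.F.T[None, :, :]
        self.S = np.exp(-sF - self.M)
        Z = sF + self.M
        self.u = sF / Z * (1.0 - self.S)


def recovery_probability_tensor(
    pi: np.ndarray,
    u: np.ndarray,
    S: np.ndarray,
    lam: np.ndarray,
    frame: StudyFrame,
    pi_init: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate tagged-cohort fates into recovery-cell probabilities.

    Parameters
    ----------
    pi : movement probabilities ``pi[a, y, k, k']``, each row summing to 1.
    u, S : exploitation and survival ``[a, y, k]``.
    lam : reporting rates ``lam[y, k]``.
    pi_init : optional replacement movement matrix applied only at the
        release-year step (partial-dispersal correction).

    Returns
    -------
    ``P[a, ty, tk, fy, fk]`` with ``P = 0`` for ``fy < ty``. For the release
    year the fish moves once and is exposed; for later years the presence
    row-vector is carried forward through move-then-survive steps with the
    age index advancing each year (capped at the plus-group).
    """
    f = frame
    A, Y, K = f.n_ages, f.n_years, f.n_regions
    pi = np.asarray(pi, dtype=float)
    u = np.asarray(u, dtype=float)
    S = np.asarray(S, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if pi.shape != (A, Y, K, K):
        raise ValueError(f"pi shape {pi.shape} != {(A, Y, K, K)}")
    for name, arr, shape in (("u", u, (A, Y, K)), ("S", S, (A, Y, K)),
                             ("lam", lam, (Y, K))):
        if arr.shape != shape:
            raise ValueError(f"{name} shape {arr.shape} != {shape}")
    if pi_init is not None:
        pi_init = np.asarray(pi_init, dtype=float)
        if pi_init.shape != (A, Y, K, K):
            raise ValueError(f"pi_init shape {pi_init.shape} != {(A, Y, K, K)}")

    P = np.zeros((A, Y, K, Y, K))
    ages0 = np.arange(A)
    eye = np.broadcast_to(np.eye(K), (A, K, K))
    # V[ty, a, tk, k]: probability a fish tagged at age a in year ty and
    # region tk is alive in region k just before the year-y movement step.
    # All cohorts released so far are propagated together, one calendar year
    # per loop step.
    V = np.zeros((Y, A, K, K))
    for y in range(Y):
        V[y] = eye  # cohort released at the start of year y
        t = np.arange(y + 1)
        acur = np.minimum(ages0[None, :] + (y - t)[:, None], A - 1)  # (y+1, A)
        pim = pi[acur, y]  # (y+1, A, K, K)
        if pi_init is not None:
            pim[y] = pi_init[ages0, y]  # release-year movement is corrected
        moved = np.einsum("task,takj->tasj", V[: y + 1], pim)
        w = u[acur, y] * lam[y]  # (y+1, A, K)
        P[:, : y + 1, :, y, :] = (moved * w[:, :, None, :]).transpose(1, 0, 2, 3)
        V[: y + 1] = moved * S[acur, y][:, :, None, :]
    return P
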