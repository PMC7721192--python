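"""Stratum fate probabilities and the multinomial tagging likelihood.

Each release stratum (tag year, tag region, length class) is a multinomial
experiment: every released fish either shows up in exactly one recovery cell
(recovery year, recovery region) or remains at large through the final study
year. Cell probabilities mix the age-specific recovery tensor over the
length class's age composition; the at-large probability is the complement
of all recovery cells up to the study horizon.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field

import numpy as np

from .tag_data import StudyFrame, TagDataset

__all__ = [
    "StratumFateProbabilities",
    "LikelihoodResult",
    "stratum_fate_probabilities",
    "negative_log_likelihood",
]


@dataclass
class StratumFateProbabilities:
    """Recovery-cell and at-large probabilities per release stratum.

    ``pr_recap[ty, tk, l, fy, fk]`` and ``pr_atlarge[ty, tk, l]``, with
    ``pr_atlarge = 1 - sum(pr_recap)`` per stratum by construction.
    """

    pr_recap: np.ndarray
    pr_atlarge: np.ndarray
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        tol = 1e-9
        if (self.pr_recap < -tol).any() or (self.pr_recap > 1 + tol).any():
            raise ValueError("recovery probabilities outside [0, 1]")
        resid = 1.0 - self.pr_recap.sum(axis=(3, 4))
        if not np.allclose(resid, self.pr_atlarge, atol=1e-9):
            raise ValueError("at-large probability inconsistent with recovery cells")


def stratum_fate_probabilities(P: np.ndarray, kappa: np.ndarray,
                               frame: StudyFrame,
                               validate: bool = True) -> StratumFateProbabilities:
    """Mix the age-specific recovery tensor over the age-length key.

    ``pr_recap[ty, tk, l, fy, fk] = sum_a kappa[l, a] P[a, ty, tk, fy, fk]``;
    the at-large probability is the complement summed over every recovery
    cell through the final study year.
    """
    A, Y, K, L = frame.n_ages, frame.n_years, frame.n_regions, frame.n_lengths
    P = np.asarray(P, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if P.shape != (A, Y, K, Y, K):
        raise ValueError(f"P shape {P.shape} != {(A, Y, K, Y, K)}")
    if kappa.shape != (L, A):
        raise ValueError(f"kappa shape {kappa.shape} != {(L, A)}")
    pr_recap = np.einsum("la,atkfj->tklfj", kappa, P)
    pr_atlarge = 1.0 - pr_recap.sum(axis=(3, 4))
    return StratumFateProbabilities(
        pr_recap=pr_recap, pr_atlarge=pr_atlarge, validate=validate
    )


@dataclass
class LikelihoodResult:
    """Total negative log likelihood and its per-observation decomposition.

    ``pointwise`` holds one log-likelihood contribution per observation unit
    (stratum multinomials by default; per-fish categorical terms optionally),
    with ``nll = -sum(pointwise)``.
    """

    nll: float
    pointwise: np.ndarray
    strata: list[tuple[int, int, int]] = field(default_factory=list)


def _xlogy(d: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d*log(p) with the 0*log(0) = 0 convention; -inf where d>0 and p<=0."""
    from scipy.special import xlogy

    with np.errstate(divide="ignore", invalid="ignore"):
        out = xlogy(d, p)
    return np.where((d > 0) & (p <= 0), -np.inf, out)


def negative_log_likelihood(dataset: TagDataset,
                            fate: StratumFateProbabilities,
                            pointwise: str = "stratum") -> LikelihoodResult:
    """Multinomial negative log likelihood of the tagging data.

    The multinomial coefficient is omitted (constant in the parameters). A
    zero-probability cell holding a positive count yields an infinite NLL
    (returned, not raised). ``pointwise="stratum"`` gives one term per
    release stratum with any releases; ``pointwise="fish"`` expands each
    stratum into per-fish categorical terms.
    """
    if pointwise not in ("stratum", "fish"):
        raise ValueError("pointwise must be 'stratum' or 'fish'")
    d_rec = dataset.recoveries
    d_al = dataset.at_large
    rec_terms = _xlogy(d_rec, fate.pr_recap).sum(axis=(3, 4))
    al_terms = _xlogy(d_al, fate.pr_atlarge)
    per_stratum = rec_terms + al_terms  # (Y, K, L) log-lik, 0 for empty strata

    strata = [tuple(idx) for idx in np.argwhere(dataset.releases > 0)]
    if pointwise == "stratum":
        pw = np.array([per_stratum[idx] for idx in strata])
    else:
        terms = []
        for idx in strata:
            p_rec = fate.pr_recap[idx]
            d = d_rec[idx]
            for cell in np.argwhere(d > 0):
                c = tuple(cell)
                terms.extend([_safe_log(p_rec[c])] * int(d[c]))
            if d_al[idx] > 0:
                terms.extend([_safe_log(fate.pr_atlarge[idx])] * int(d_al[idx]))
        pw = np.array(terms)
    nll = float(-per_stratum.sum())
    return LikelihoodResult(nll=nll, pointwise=pw, strata=strata)


def _safe_log(p: float) -> float:
    return float(np.log(p)) if p > 0 else -np.inf
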