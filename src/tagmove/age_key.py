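"""Age composition by length class, with sampling uncertainty.

Ages of tagged fish are never read directly; they are inferred from total
length through an age-length key. Per length class ``l`` the age composition
``kappa[l, :]`` is a simplex-valued state variable; the aged subsample
``n[l, :]`` (of size ``N[l]``) is multinomial given ``kappa``, so small aged
samples propagate their uncertainty into every downstream quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .tag_data import AgeLengthSample

__all__ = [
    "AgeComposition",
    "log_lik_age_sample",
    "kappa_conjugate_posterior",
]


@dataclass
class AgeComposition:
    """Proportion of each age class within each length class.

    ``kappa[l, a]`` with rows on the probability simplex.
    """

    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.ndim != 2:
            raise ValueError("kappa must be (n_lengths, n_ages)")
        if (self.kappa < 0).any():
            raise ValueError("kappa must be non-negative")
        if not np.allclose(self.kappa.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each kappa row must sum to 1")


def log_lik_age_sample(kappa: np.ndarray, sample: AgeLengthSample) -> float:
    """Multinomial log likelihood of the aged subsample given ``kappa``.

    Includes the multinomial coefficient (constant in ``kappa``; harmless).
    A zero ``kappa`` cell with a positive count gives ``-inf``. Empty length
    classes (``N[l] = 0``) contribute zero.
    """
    kappa = np.asarray(kappa, dtype=float)
    n = sample.n
    if kappa.shape != n.shape:
        raise ValueError(f"kappa shape {kappa.shape} != counts shape {n.shape}")
    if ((kappa == 0) & (n > 0)).any():
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(np.where(kappa > 0, kappa, 1.0)), 0.0)
    coef = getattr(sample, "_mult_coef", None)
    if coef is None:  # constant in kappa; cache on the sample
        coef = float(gammaln(sample.N + 1).sum() - gammaln(n + 1).sum())
        sample._mult_coef = coef
    return float(coef + terms.sum())


def kappa_conjugate_posterior(sample: AgeLengthSample,
                              prior_concentration: float = 1.0) -> np.ndarray:
    """Dirichlet posterior concentrations for each length class.

    With a Dirichlet(``prior_concentration``) prior per row and a multinomial
    sample, the posterior is Dirichlet(prior + counts) row-wise. Used both as
    a closed-form oracle for the MCMC treatment of ``kappa`` and as a fast
    plug-in (posterior-mean) mode.
    """
    if prior_concentration <= 0:
        raise ValueError("prior concentration must be positive")
    return prior_concentration + sample.n.astype(float)
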