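"""Reversible substitution models with discrete-gamma rate variation.

A model is an exchangeability matrix (``"poisson"`` for all-equal) plus
equilibrium frequencies; the rate matrix is normalised to one expected
substitution per site so branch lengths are in substitutions/site.
Among-site rate variation uses the usual k equal-probability gamma
categories with the bin mean as the category rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Category rates (mean 1) for k equal-probability gamma bins.

    Bin boundaries are gamma quantiles; each category rate is the
    conditional mean of the Gamma(alpha, 1/alpha) density within its bin.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    # E[X; X in bin] = F_{alpha+1}(b) increments (mean-1 gamma identity)
    upper = gamma_dist.cdf(bounds, alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(upper)
    return rates / rates.mean() * 1.0


@dataclass
class SubstitutionModel:
    """Time-reversible model over a k-letter alphabet."""

    k: int
    exchangeabilities: np.ndarray | str = "poisson"
    frequencies: np.ndarray | None = None
    alpha: float | None = None
    n_cat: int = 4
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.frequencies is None:
            self.frequencies = np.full(self.k, 1.0 / self.k)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (self.k,) or np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be k positive values")
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        if isinstance(self.exchangeabilities, str):
            if self.exchangeabilities != "poisson":
                raise ValueError(f"unknown exchangeability tag {self.exchangeabilities!r}")
        else:
            R = np.asarray(self.exchangeabilities, dtype=float)
            if R.shape != (self.k, self.k) or not np.allclose(R, R.T):
                raise ValueError("exchangeability matrix must be symmetric k x k")
            self.exchangeabilities = R

    # -- rate matrix -------------------------------------------------------
    def exchange_matrix(self) -> np.ndarray:
        if isinstance(self.exchangeabilities, str):
            R = np.ones((self.k, self.k))
        else:
            R = np.array(self.exchangeabilities, dtype=float)
        np.fill_diagonal(R, 0.0)
        return R

    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to zero, scaled to mean rate 1."""
        pi = self.frequencies
        Q = self.exchange_matrix() * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def _eigendecomposition(self):
        if self._eig is None:
            pi = self.frequencies
            Q = self.rate_matrix()
            sq = np.sqrt(pi)
            B = (sq[:, None] * Q) / sq[None, :]
            w, U = np.linalg.eigh((B + B.T) / 2.0)
            left = U.T * sq[None, :]          # U^T diag(sqrt pi)
            right = (1.0 / sq)[:, None] * U   # diag(1/sqrt pi) U
            self._eig = (w, right, left)
        return self._eig

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for one branch length (rows: parent state)."""
        w, right, left = self._eigendecomposition()
        P = (right * np.exp(w * t * rate)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_cat)

    def with_frequencies(self, frequencies) -> "SubstitutionModel":
        """Same exchangeabilities rebuilt around new equilibrium frequencies."""
        return SubstitutionModel(self.k, self.exchangeabilities, np.asarray(frequencies),
                                 self.alpha, self.n_cat)

    def with_alpha(self, alpha: float | None, n_cat: int | None = None) -> "SubstitutionModel":
        model = SubstitutionModel(self.k, self.exchangeabilities, self.frequencies,
                                  alpha, n_cat or self.n_cat)
        model._eig = self._eig
        return model


def poisson_model(k: int, alpha: float | None = None, n_cat: int = 4) -> SubstitutionModel:
    return SubstitutionModel(k, "poisson", None, alpha, n_cat)


def model_from_name(name: str, k: int) -> SubstitutionModel:
    """Parse CLI-style model strings like ``poisson``, ``poisson+g4``."""
    parts = name.lower().split("+")
    if parts[0] not in ("poisson", "gtr4" if k == 4 else "poisson"):
        if parts[0] != "poisson":
            raise ValueError(f"unknown model {parts[0]!r}")
    n_cat = 4
    alpha = None
    for part in parts[1:]:
        if part.startswith("g"):
            n_cat = int(part[1:]) if len(part) > 1 else 4
            alpha = alpha if alpha is not None else 1.0
        else:
            raise ValueError(f"unknown model component {part!r}")
    return SubstitutionModel(k, "poisson", None, alpha, n_cat)
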