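"""Per-site rate estimation and stepwise fast-site removal.

The gamma shape is fitted by maximum likelihood on a fixed guide tree;
posterior-mean site rates follow from the discrete-gamma category
likelihoods.  Sites ranked by rate are split into ten deciles (1 =
fastest) and removed stepwise, yielding nested alignments; the combined
treatment removes sites on the amino-acid alignment first and recodes the
survivors afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .likelihood import PruningEngine
from .models import SubstitutionModel, discrete_gamma_rates
from .recode import RecodingScheme, recode
from .trees import Tree

ALPHA_BOUNDS = (0.02, 100.0)


class SiteRateError(ValueError):
    pass


@dataclass
class SiteRateProfile:
    alpha: float
    k: int
    category_rates: np.ndarray
    site_rates: np.ndarray
    decile: np.ndarray | None = None  # 1 = fastest

    def __post_init__(self):
        if not np.isclose(self.category_rates.mean(), 1.0, atol=1e-9):
            raise SiteRateError("category rates must average to 1")
        if np.any(self.site_rates <= 0):
            raise SiteRateError("site rates must be positive")

    def rate_order(self) -> np.ndarray:
        """Columns sorted fastest-first; ties broken by column index."""
        idx = np.arange(len(self.site_rates))
        return np.array(sorted(idx, key=lambda i: (-self.site_rates[i], i)))


@dataclass
class RemovalSeries:
    fractions: tuple[float, ...]
    masks: dict[float, np.ndarray]  # fraction -> sorted retained columns


def _has_variable_site(aln: Alignment) -> bool:
    for j in range(aln.n_cols):
        col = aln.data[:, j]
        states = {s for s in col if s in set(aln.symbols)}
        if len(states) > 1:
            return True
    return False


def estimate_alpha(aln: Alignment, tree: Tree, model: SubstitutionModel,
                   k: int = 4) -> float:
    """ML gamma shape on [0.02, 100] by bracketed 1-D optimisation."""
    if not _has_variable_site(aln):
        raise SiteRateError("alpha undefined: alignment has no variable sites")

    def neg(alpha: float) -> float:
        m = model.with_alpha(alpha, k)
        total, _ = PruningEngine(aln, tree, m).loglik()
        return -total

    res = minimize_scalar(neg, bounds=ALPHA_BOUNDS, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def posterior_site_rates(aln: Alignment, tree: Tree, model: SubstitutionModel,
                         alpha: float, k: int = 4) -> SiteRateProfile:
    """Posterior-mean site rate under equal-prior discrete-gamma categories:
    r_i = sum_c r_c L_i(c) / sum_c L_i(c)."""
    m = model.with_alpha(alpha, k)
    rates = discrete_gamma_rates(alpha, k)
    percat = PruningEngine(aln, tree, m).per_category_site_loglik()  # (k, L)
    log_norm = logsumexp(percat, axis=0)
    weights = np.exp(percat - log_norm[None, :])
    site_rates = weights.T @ rates
    return SiteRateProfile(alpha=alpha, k=k, category_rates=rates,
                           site_rates=site_rates)


def categorize_deciles(profile: SiteRateProfile) -> SiteRateProfile:
    """Split rate-ranked columns into 10 near-equal blocks (sizes differ by
    at most one); category 1 holds the fastest sites."""
    L = len(profile.site_rates)
    if L < 10:
        raise SiteRateError("need at least 10 columns for decile categories")
    order = profile.rate_order()
    decile = np.empty(L, dtype=int)
    blocks = np.array_split(order, 10)
    for c, block in enumerate(blocks, start=1):
        decile[block] = c
    profile.decile = decile
    return profile


def fsr_series(aln: Alignment, profile: SiteRateProfile,
               fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1), 2))) -> RemovalSeries:
    """Nested removal masks: removed(f) = floor(f*L) highest-rate columns."""
    L = aln.n_cols
    if len(profile.site_rates) != L:
        raise SiteRateError("profile was not computed on this alignment")
    order = profile.rate_order()
    masks = {}
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise SiteRateError(f"removal fraction {f} outside (0, 1)")
        n_remove = int(np.floor(f * L))
        retained = np.sort(order[n_remove:])
        masks[float(f)] = retained
    return RemovalSeries(tuple(float(f) for f in fractions), masks)


def treat(aln_aa: Alignment, tree: Tree, model: SubstitutionModel, f: float,
          scheme: RecodingScheme | None = None, alpha: float | None = None,
          k: int = 4, profile: SiteRateProfile | None = None) -> Alignment:
    """Fast-site removal then (optionally) recoding, in that order.

    Rates are always estimated on the amino-acid alignment, never on the
    recoded one.  ``f = 0`` with no scheme is the identity.
    """
    if aln_aa.alphabet != "AA20":
        raise SiteRateError("treatments start from an AA20 alignment")
    out = aln_aa
    if f:
        if profile is None:
            if alpha is None:
                alpha = estimate_alpha(aln_aa, tree, model, k)
            profile = posterior_site_rates(aln_aa, tree, model, alpha, k)
        series = fsr_series(aln_aa, profile, fractions=(f,))
        out = out.take_columns(series.masks[float(f)])
    if scheme is not None:
        out = recode(out, scheme)
    return out


def profile_to_tsv(profile: SiteRateProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\trate\tdecile\n")
        dec = profile.decile if profile.decile is not None else [""] * len(profile.site_rates)
        for i, (r, d) in enumerate(zip(profile.site_rates, dec)):
            fh.write(f"{i}\t{r:.6g}\t{d}\n")
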