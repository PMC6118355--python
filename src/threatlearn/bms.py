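"""Random-effects Bayesian model selection (RFX-BMS) over participants.

Treats the model identity as a random effect: each participant is assumed to
be generated by one model drawn from population frequencies ``r`` with a
Dirichlet prior. Given per-participant log model evidences (here approximated
by -BIC/2), a variational scheme (Stephan et al. 2009) alternates between
participant-wise model responsibilities and the Dirichlet posterior.

Reported quantities:

- ``expected_freq``: posterior mean model frequencies.
- ``xp`` (exceedance probability): probability that a model's frequency
  exceeds all others, from the Dirichlet posterior (closed Beta form for two
  models, Monte Carlo otherwise).
- ``bor`` (Bayes omnibus risk): posterior probability that all frequencies
  are equal, from the free-energy comparison of the RFX model against the
  equal-frequency null (Rigoux et al. 2014).
- ``pxp``: protected exceedance probability,
  ``pxp = (1 - bor) * xp + bor / K``.

Family-level inference aggregates member log evidences per participant by
log-sum-exp with a uniform within-family model prior (so family size does not
bias the comparison) and runs the same RFX scheme over families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

from .models import FAMILIES

__all__ = [
    "BMSConfig",
    "BMSResult",
    "rfx_bms",
    "family_bms",
    "winner",
    "evidence_from_bic",
    "default_partition",
]


class BMSError(ValueError):
    pass


@dataclass(frozen=True)
class BMSConfig:
    """Numerical contract of the variational RFX scheme."""

    tol: float = 1e-8
    max_iter: int = 10_000
    n_mc: int = 1_000_000  # Dirichlet draws for the exceedance probability
    seed: int = 20180831   # fixed for reproducibility; only affects MC noise in xp


@dataclass
class BMSResult:
    """Posterior summary of one RFX-BMS run."""

    labels: list[str]
    alpha: np.ndarray            # posterior Dirichlet concentrations
    expected_freq: np.ndarray    # posterior mean frequencies
    xp: np.ndarray               # exceedance probabilities
    bor: float                   # Bayes omnibus risk
    pxp: np.ndarray              # protected exceedance probabilities
    converged: bool = True
    n_iter: int = 0
    responsibilities: np.ndarray | None = field(default=None, repr=False)


def evidence_from_bic(bic_matrix: np.ndarray) -> np.ndarray:
    """Approximate log model evidence from BIC: log p(y|m) = -BIC / 2."""
    return -0.5 * np.asarray(bic_matrix, dtype=float)


def _exceedance(alpha: np.ndarray, n_mc: int, seed: int) -> np.ndarray:
    k = len(alpha)
    if k == 2:
        # P(r1 > r2) = P(r1 > 1/2) under r1 ~ Beta(a1, a2)
        p = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p, 1.0 - p])
    rng = np.random.default_rng(seed)
    counts = np.zeros(k)
    remaining = int(n_mc)
    # draw in blocks to bound memory
    block = 200_000
    while remaining > 0:
        m = min(block, remaining)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / n_mc


def _free_energy(
    L: np.ndarray, g: np.ndarray, alpha: np.ndarray, alpha0: np.ndarray
) -> float:
    """Variational free energy of the RFX model at the converged posterior."""
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    # entropy of q(r) relative terms + expected log joint (Dirichlet part)
    s_qf = gammaln(alpha).sum() - gammaln(alpha.sum()) - ((alpha - 1.0) * e_log_r).sum()
    s_qm = -np.sum(g * np.log(np.clip(g, 1e-300, None)))
    elj = (
        gammaln(alpha0.sum())
        - gammaln(alpha0).sum()
        + ((alpha0 - 1.0) * e_log_r).sum()
        + np.sum(g * (e_log_r[None, :] + L))
    )
    return float(elj + s_qf + s_qm)


def _null_free_energy(L: np.ndarray) -> float:
    """Log evidence of the null hypothesis of equal model frequencies."""
    n, k = L.shape
    return float(logsumexp(L, axis=1).sum() - n * np.log(k))


def rfx_bms(
    log_evidence: np.ndarray,
    labels: list[str] | None = None,
    config: BMSConfig | None = None,
    alpha0: np.ndarray | None = None,
) -> BMSResult:
    """Random-effects BMS over a participants x models log-evidence matrix.

    Uses a uniform Dirichlet prior (concentration 1 per model) unless
    ``alpha0`` is given. Adding a constant to one participant's row leaves
    the result unchanged (only within-participant evidence differences
    matter).
    """
    config = config or BMSConfig()
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2:
        raise BMSError("log_evidence must be a 2D participants x models array")
    n, k = L.shape
    if k < 2:
        raise BMSError("need at least 2 models")
    if n < 2:
        raise BMSError("random-effects analysis needs at least 2 participants")
    if not np.all(np.isfinite(L)):
        raise BMSError("log evidences must be finite")
    if labels is None:
        labels = [f"m{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise BMSError("labels length does not match number of models")
    alpha0 = np.ones(k) if alpha0 is None else np.asarray(alpha0, dtype=float)

    alpha = alpha0.copy()
    g = np.full((n, k), 1.0 / k)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        log_u = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < config.tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged:
        warnings.warn(
            f"RFX-BMS did not converge in {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    expected_freq = alpha / alpha.sum()
    xp = _exceedance(alpha, config.n_mc, config.seed)
    f1 = _free_energy(L, g, alpha, alpha0)
    f0 = _null_free_energy(L)
    # BOR = p(H0 | y) under equal prior odds on H0 (equal frequencies) vs H1
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * xp + bor / k
    return BMSResult(
        labels=list(labels),
        alpha=alpha,
        expected_freq=expected_freq,
        xp=xp,
        bor=bor,
        pxp=pxp,
        converged=converged,
        n_iter=it,
        responsibilities=g,
    )


def default_partition(models: list[str] | tuple[str, ...]) -> dict[str, str]:
    """Default model -> family map restricted to ``models``."""
    return {m: FAMILIES[m] for m in models}


def family_bms(
    log_evidence: np.ndarray,
    models: list[str],
    partition: dict[str, str] | None = None,
    config: BMSConfig | None = None,
) -> BMSResult:
    """RFX-BMS over model families.

    Per participant, the family log evidence is
    ``logsumexp(member evidences) - ln(family size)`` (uniform within-family
    prior, so prior mass is equalized across families); the RFX scheme then
    runs over families with a unit Dirichlet prior. A partition into
    singleton families reduces exactly to model-level RFX-BMS.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] != len(models):
        raise BMSError("log_evidence columns must match models")
    partition = partition or default_partition(models)
    missing = [m for m in models if m not in partition]
    if missing:
        raise BMSError(f"partition does not cover models: {missing}")
    families = sorted(set(partition[m] for m in models))
    fam_L = np.empty((L.shape[0], len(families)))
    for j, fam in enumerate(families):
        member_cols = [i for i, m in enumerate(models) if partition[m] == fam]
        fam_L[:, j] = logsumexp(L[:, member_cols], axis=1) - np.log(len(member_cols))
    return rfx_bms(fam_L, labels=families, config=config)


def winner(result: BMSResult) -> tuple[str, bool]:
    """Label with the highest protected exceedance probability.

    Ties are broken by the first label in declared order; the second element
    flags a tie (within 1e-12).
    """
    pxp = result.pxp
    best = int(np.argmax(pxp))
    tie = bool(np.sum(np.abs(pxp - pxp[best]) < 1e-12) > 1)
    return result.labels[best], tie
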