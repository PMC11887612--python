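"""Bayesian estimation of potential-outcome rates.

Each of the eight (race, BMI-class, GWG-class) cells contributes a
Binomial(n, PO) likelihood for its case count, with a Uniform(0, 1) prior
on the rate. The model factorizes, so the exact posterior per cell is
Beta(1 + r, 1 + n - r) and the default engine draws from it directly.
Marginal potential outcomes — one or both mediator indices treated as
missing — are fit on the pooled (collapsed) counts, which is what supplying
the aggregated data row to the binomial likelihood does.

A Markov-chain mode (random-walk Metropolis on the logit scale, multiple
chains with disparate starts, burn-in, potential-scale-reduction
diagnostic) replicates the iterative-sampler protocol and serves as an
independent cross-check of the closed form.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit, logit

from .record_prep import CellCounts

logger = logging.getLogger(__name__)

DEFAULT_DRAWS = 10_000
DEFAULT_BURN_IN = 5_000
RHAT_THRESHOLD = 1.05


@dataclass
class PosteriorDraws:
    """Monte-Carlo draws of a rate or a derived contrast."""

    values: np.ndarray
    seed: int | None = None
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("PosteriorDraws needs at least one draw")

    @property
    def S(self) -> int:
        return int(self.values.size)

    def to_csv(self, path) -> None:
        """Export the raw draws (one per line) for audit."""
        np.savetxt(path, self.values, header=self.label, comments="# ")


@dataclass(frozen=True)
class MarginSpec:
    """Which PO to estimate: x fixed; a ``None`` mediator index is collapsed."""

    x: int
    m1: int | None = None
    m2: int | None = None

    def __post_init__(self):
        if self.x not in (1, 2):
            raise ValueError("x must be 1 or 2")
        for v in (self.m1, self.m2):
            if v is not None and v not in (1, 2):
                raise ValueError("mediator indices must be 1, 2 or None")

    def label(self) -> str:
        a = "NA" if self.m1 is None else str(self.m1)
        b = "NA" if self.m2 is None else str(self.m2)
        return f"PO[{self.x},{a},{b}]"


def posterior_cell(
    r: int, n: int, S: int = DEFAULT_DRAWS, seed=None, label: str = ""
) -> PosteriorDraws:
    """Exact conjugate posterior draws for one data row.

    Binomial(n, p) likelihood with Uniform(0, 1) prior gives the
    Beta(1 + r, 1 + n - r) posterior; with no data this is the Uniform
    prior itself.
    """
    r, n = int(r), int(n)
    if r < 0 or n < 0 or r > n:
        raise ValueError(f"need 0 <= r <= n, got r={r}, n={n}")
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.beta(1 + r, 1 + n - r, size=S)
    return PosteriorDraws(values, seed=seed, label=label or f"Beta({1 + r},{1 + n - r})")


def posterior_margin(
    cells: CellCounts, spec: MarginSpec, S: int = DEFAULT_DRAWS, seed=None
) -> PosteriorDraws:
    """Posterior for a PO with ``None`` mediator indices collapsed (pooled)."""
    r, n = cells.collapse(spec.x, spec.m1, spec.m2)
    if n == 0:
        logger.warning(
            "%s: empty collapse (n=0); posterior degrades to the Uniform prior",
            spec.label(),
        )
    return posterior_cell(r, n, S=S, seed=seed, label=spec.label())


def sample_posterior_rate(
    r: int,
    n: int,
    S: int = DEFAULT_DRAWS,
    seed=None,
    engine: str = "conjugate",
    burn_in: int = DEFAULT_BURN_IN,
    chains: int = 2,
    label: str = "",
) -> PosteriorDraws:
    """Posterior rate draws via the chosen engine (conjugate | gibbs)."""
    if engine == "conjugate":
        return posterior_cell(r, n, S=S, seed=seed, label=label)
    if engine == "gibbs":
        kept = -(-S // chains)  # ceil
        draws, _, _ = _metropolis_rates(
            np.array([r]), np.array([n]), burn_in, kept, chains, np.random.default_rng(seed)
        )
        values = draws[:, :, 0].reshape(-1)[:S]
        return PosteriorDraws(values, seed=seed, label=label)
    raise ValueError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# Markov-chain mode


def _log_posterior(theta, r, n):
    # p ~ Uniform prior, theta = logit(p); Jacobian p(1-p) folds into exponents
    return (r + 1) * log_expit(theta) + (n - r + 1) * log_expit(-theta)


def _metropolis_rates(r, n, burn_in, kept, chains, rng):
    """Adaptive random-walk Metropolis on logit(p), vectorized over cells.

    Returns (draws, acceptance, step): draws has shape (chains, kept, k).
    Proposal scale adapts toward ~44% acceptance during burn-in only.
    """
    k = len(r)
    r = r[None, :].astype(float)
    n = n[None, :].astype(float)
    # disparate starting values across chains
    starts = np.where(np.arange(chains)[:, None] % 2 == 0, 0.05, 0.95)
    theta = np.broadcast_to(logit(starts), (chains, k)).copy()
    lp = _log_posterior(theta, r, n)
    step = np.full((chains, k), 1.0)
    draws = np.empty((chains, kept, k))
    accepted = np.zeros((chains, k))
    for t in range(burn_in + kept):
        prop = theta + step * rng.standard_normal((chains, k))
        lp_prop = _log_posterior(prop, r, n)
        accept = np.log(rng.random((chains, k))) < lp_prop - lp
        theta = np.where(accept, prop, theta)
        lp = np.where(accept, lp_prop, lp)
        if t < burn_in:
            step *= np.exp((accept - 0.44) / (t + 1) ** 0.6)
        else:
            draws[:, t - burn_in, :] = expit(theta)
            accepted += accept
    return draws, accepted / max(kept, 1), step


def potential_scale_reduction(chain_draws: np.ndarray) -> float:
    """Split Gelman-Rubin R-hat for an array of shape (chains, iterations)."""
    chains, iters = chain_draws.shape
    if iters < 4:
        return float("nan")
    half = iters // 2
    seqs = np.concatenate(
        [chain_draws[:, :half], chain_draws[:, half : 2 * half]], axis=0
    )
    m, length = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = length * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (length - 1) / length * w + b / length
    return float(np.sqrt(var_plus / w))


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] == 0:
        return float(n)
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
        t += 2
    return float(n / max(tau, 1.0))


@dataclass
class GibbsResult:
    """Markov-chain posteriors per cell, with convergence diagnostics."""

    draws: dict
    rhat: dict
    acceptance: dict
    converged: bool = True
    warnings: list = field(default_factory=list)


def gibbs_mode(
    cells: CellCounts,
    burn_in: int = DEFAULT_BURN_IN,
    kept: int = DEFAULT_DRAWS,
    chains: int = 2,
    seed=None,
) -> GibbsResult:
    """Iterative-sampler estimation of all eight cell rates.

    Runs ``chains`` random-walk Metropolis chains per cell with disparate
    starting values, discards ``burn_in`` iterations, keeps ``kept`` per
    chain (pooled into each cell's PosteriorDraws), and reports the
    potential scale reduction; a diagnostic above 1.05 flags
    non-convergence with a warning.
    """
    if burn_in < 0 or kept < 1 or chains < 1:
        raise ValueError("need burn_in >= 0, kept >= 1, chains >= 1")
    keys = [(x, m1, m2) for x in (1, 2) for m1 in (1, 2) for m2 in (1, 2)]
    r = np.array([cells.cell(*key)[0] for key in keys])
    n = np.array([cells.cell(*key)[1] for key in keys])
    rng = np.random.default_rng(seed)
    draws, acc, _ = _metropolis_rates(r, n, burn_in, kept, chains, rng)

    result = GibbsResult(draws={}, rhat={}, acceptance={})
    for j, key in enumerate(keys):
        chain_draws = draws[:, :, j]
        rhat = potential_scale_reduction(chain_draws)
        result.draws[key] = PosteriorDraws(
            chain_draws.reshape(-1), seed=seed, label=f"PO[{key[0]},{key[1]},{key[2]}]"
        )
        result.rhat[key] = rhat
        result.acceptance[key] = float(acc[:, j].mean())
        if np.isfinite(rhat) and rhat > RHAT_THRESHOLD:
            msg = f"cell {key}: potential scale reduction {rhat:.3f} exceeds {RHAT_THRESHOLD}"
            logger.warning(msg)
            result.warnings.append(msg)
            result.converged = False
    return result
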