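"""Two-component normal mixture dichotomization of the CSF 42/40 ratio.

The CSF AβX-42/X-40 ratio in a mixed memory-clinic sample is clearly
bimodal: an amyloid-negative mode near 0.08 and an amyloid-positive mode
near 0.03.  Fitting a two-component univariate normal mixture by
expectation-maximization and cutting at the intersection of the two
weighted component densities yields an unbiased, purely neurochemical
classification threshold (values at or below the threshold are called
amyloid-positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MixtureFit",
    "DegenerateMixtureError",
    "fit_two_component_mixture",
    "intersection_threshold",
    "classify",
]

POSITIVE = "positive"
NEGATIVE = "negative"
UNCLASSIFIED = "unclassified"


class DegenerateMixtureError(RuntimeError):
    """A component collapsed (vanishing sd or weight) during EM."""


@dataclass(frozen=True)
class MixtureFit:
    """Fitted two-component normal mixture, components ordered mean1 < mean2."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    threshold: float
    log_likelihood: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.weights), 1.0, rel_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if min(self.weights) <= 0 or min(self.sds) <= 0:
            raise ValueError("weights and sds must be positive")
        if not self.means[0] < self.means[1]:
            raise ValueError("components must be ordered means[0] < means[1]")


def _em(
    x: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    tol: float,
    max_iter: int,
    min_sigma: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_dens = np.log(w)[:, None] + stats.norm.logpdf(x[None, :], mu[:, None], sigma[:, None])
        log_norm = np.logaddexp(log_dens[0], log_dens[1])
        ll = float(log_norm.sum())
        # EM guarantees a nondecreasing likelihood; tolerate only fp noise
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"log-likelihood decreased during EM: {prev_ll} -> {ll}"
            )
        resp = np.exp(log_dens - log_norm)
        nk = resp.sum(axis=1)
        if nk.min() < 1e-10:
            raise DegenerateMixtureError(
                f"component weight collapsed to {nk.min():g} at iteration {it}"
            )
        w = nk / x.size
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.sqrt(var)
        if sigma.min() < min_sigma:
            raise DegenerateMixtureError(
                f"component sd collapsed to {sigma.min():g} at iteration {it}"
            )
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return w, mu, sigma, prev_ll, it, converged


def fit_two_component_mixture(
    values,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Fit a 2-component univariate normal mixture by EM.

    The deterministic initialization splits the sample at its median and
    moments each half; ``n_restarts`` additional seeded random
    initializations are tried and the best-likelihood solution kept, so the
    whole fit is deterministic under ``seed``.  Components are returned
    ordered by mean and the intersection threshold is attached.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 finite values to fit a mixture, got {x.size}")
    scale = float(x.std())
    if scale <= 1e-12 * max(1.0, abs(float(x.mean()))):
        raise DegenerateMixtureError("all values (numerically) identical; mixture is degenerate")
    min_sigma = 1e-8 * scale

    inits = []
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if lo.size >= 2 and hi.size >= 2:
        inits.append(
            (
                np.array([lo.size, hi.size], dtype=float) / x.size,
                np.array([lo.mean(), hi.mean()]),
                np.maximum(np.array([lo.std(), hi.std()]), min_sigma * 10),
            )
        )
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        centers = rng.choice(x, size=2, replace=False)
        inits.append(
            (
                np.array([0.5, 0.5]),
                np.sort(centers),
                np.full(2, max(scale / 2, min_sigma * 10)),
            )
        )

    best = None
    last_error: Exception | None = None
    for w0, mu0, s0 in inits:
        try:
            fit = _em(x, w0.copy(), mu0.copy(), s0.copy(), tol, max_iter, min_sigma)
        except DegenerateMixtureError as err:
            last_error = err
            continue
        if best is None or fit[3] > best[3]:
            best = fit
    if best is None:
        raise DegenerateMixtureError(f"all EM initializations degenerated: {last_error}")

    w, mu, sigma, ll, n_iter, converged = best
    order = np.argsort(mu)
    w, mu, sigma = w[order], mu[order], sigma[order]
    tau = intersection_threshold(
        (float(w[0]), float(w[1])),
        (float(mu[0]), float(mu[1])),
        (float(sigma[0]), float(sigma[1])),
    )
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sigma[0]), float(sigma[1])),
        threshold=tau,
        log_likelihood=ll,
        n_iterations=n_iter,
        converged=converged,
    )


def intersection_threshold(
    weights: tuple[float, float],
    means: tuple[float, float],
    sds: tuple[float, float],
) -> float:
    """Point between the component means where the weighted densities cross.

    Solves ``w1 N(x; m1, s1^2) = w2 N(x; m2, s2^2)`` in closed form (the
    log-density difference is quadratic in x) and returns the root inside
    the open interval (m1, m2).  Raises if no crossing lies between the
    means (pathologically overlapping components).
    """
    (w1, w2), (m1, m2), (s1, s2) = weights, means, sds
    if not (m1 < m2):
        raise ValueError("means must satisfy means[0] < means[1]")
    # log(w1) - log(s1) - (x-m1)^2/(2 s1^2) = log(w2) - log(s2) - (x-m2)^2/(2 s2^2)
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + math.log(w1 / w2)
        + math.log(s2 / s1)
    )
    if abs(a) < 1e-300 or math.isclose(s1, s2, rel_tol=1e-12):
        # equal variances: single linear crossing
        if b == 0:
            raise ValueError("densities never cross between the means")
        roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("densities never cross (negative discriminant)")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        raise ValueError(
            f"no density intersection inside ({m1:g}, {m2:g}); roots: {roots}"
        )
    return float(inside[0])


def classify(values, threshold: float) -> np.ndarray:
    """Dichotomize: value <= threshold -> positive, > threshold -> negative.

    The boundary is inclusive on the positive side (a ratio exactly at the
    threshold is amyloid-positive).  Missing values are 'unclassified'.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold!r}")
    x = np.asarray(values, dtype=float)
    out = np.where(x <= threshold, POSITIVE, NEGATIVE)
    out = np.where(np.isfinite(x), out, UNCLASSIFIED)
    return out
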