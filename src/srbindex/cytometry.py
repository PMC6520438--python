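"""Cell-type census from nuclear morphometry.

Nuclear particles are classified into three groups:

* **mononucleated myocytes** — small nuclei (area below a data-driven cutoff);
* **binucleated myocytes** — large, elongated particles (two fused or touching
  nuclei; circularity ratio far above 1); each counts as ONE cell;
* **fibroblasts** — large but round nuclei (circularity ratio near 1).

The area cutoff comes from a two-component Gaussian mixture on log(area);
the large-particle split comes from a two-component Gaussian mixture on
log(circularity ratio), fitted by EM.  Both mixtures are one-dimensional and
are fitted with the same :class:`GaussianMixture1D` routine, which exposes
its per-iteration log-likelihood trajectory (monotone by the EM property).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import InsufficientDataError
from .segmentation import Particle

__all__ = [
    "GaussianMixture1D",
    "AreaCutoff",
    "CircularityMixture",
    "CellCensus",
    "fit_gaussian_mixture_1d",
    "determine_area_cutoff",
    "fit_circularity_mixture",
    "classify_particles",
    "census_cells",
    "MONONUCLEATE",
    "BINUCLEATE",
    "FIBROBLAST",
]

MONONUCLEATE = "mononucleate_myocyte"
BINUCLEATE = "binucleate_myocyte"
FIBROBLAST = "fibroblast"

_MIN_SD = 1e-6


@dataclass
class GaussianMixture1D:
    """Two-component 1-D Gaussian mixture with components ordered by mean."""

    weights: np.ndarray  # (2,), sum to 1
    means: np.ndarray  # (2,), means[0] <= means[1]
    sds: np.ndarray  # (2,), > 0
    converged: bool
    loglik: float
    loglik_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False

    def component_pdf(self, x: np.ndarray) -> np.ndarray:
        """(n, 2) array of weighted component densities."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self.weights * norm.pdf(x[:, None], self.means, self.sds)

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """(n, 2) posterior membership probabilities."""
        wp = self.component_pdf(x)
        total = wp.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return wp / total


def fit_gaussian_mixture_1d(
    x: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
) -> GaussianMixture1D:
    """EM fit of a two-component Gaussian mixture to 1-D data.

    Initialisation is a k-means-style split at the median, which is
    deterministic; ``seed`` only perturbs the split when the median halves
    are degenerate.  Component 1 is always the lower-mean component.
    Degenerate data (near-zero spread) returns ``converged=False`` with the
    ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 observations, got {n}")
    if np.ptp(x) < _MIN_SD:
        sd = max(float(np.std(x)), _MIN_SD)
        m = float(np.mean(x))
        return GaussianMixture1D(
            weights=np.array([0.5, 0.5]),
            means=np.array([m, m]),
            sds=np.array([sd, sd]),
            converged=False,
            loglik=float("nan"),
            degenerate=True,
        )
    split = float(np.median(x))
    lower = x[x <= split]
    upper = x[x > split]
    if upper.size == 0 or lower.size == 0:
        rng = np.random.default_rng(seed)
        split = float(rng.uniform(x.min(), x.max()))
        lower = x[x <= split]
        upper = x[x > split]
    means = np.array([lower.mean(), upper.mean() if upper.size else lower.mean() + 1.0])
    sds = np.array(
        [
            max(lower.std(), _MIN_SD),
            max(upper.std() if upper.size else lower.std(), _MIN_SD),
        ]
    )
    weights = np.array([lower.size / n, max(upper.size, 1) / n])
    weights /= weights.sum()

    trajectory = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        wp = weights * norm.pdf(x[:, None], means, sds)
        total = wp.sum(axis=1)
        total[total <= 0] = np.finfo(float).tiny
        ll = float(np.log(total).sum())
        trajectory.append(ll)
        resp = wp / total[:, None]
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, np.finfo(float).tiny)
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, _MIN_SD**2))
        weights = nk / n
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    order = np.argsort(means)
    return GaussianMixture1D(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        converged=converged,
        loglik=trajectory[-1],
        loglik_trajectory=np.asarray(trajectory),
    )


@dataclass(frozen=True)
class AreaCutoff:
    """Area boundary (um^2) between mononucleate-myocyte and larger nuclei."""

    cutoff: float
    method_detail: str
    component_params: tuple[tuple[float, float, float], ...]  # (mean, sd, weight) on log-area
    degenerate: bool = False


@dataclass(frozen=True)
class CircularityMixture:
    """Two-component log-normal mixture on circularity ratio.

    Component 1 (lower log-mean) is the round, fibroblast-like population;
    component 2 (higher log-mean) is the elongated binucleate population.
    """

    weights: tuple[float, float]
    log_means: tuple[float, float]
    log_sds: tuple[float, float]
    converged: bool
    loglik: float
    degenerate: bool = False

    def posterior_binucleate(self, circularity: np.ndarray) -> np.ndarray:
        """Posterior probability of the elongated (binucleate) component."""
        x = np.log(np.atleast_1d(np.asarray(circularity, dtype=float)))
        w = np.asarray(self.weights)
        wp = w * norm.pdf(x[:, None], np.asarray(self.log_means), np.asarray(self.log_sds))
        total = wp.sum(axis=1)
        total[total == 0] = 1.0
        return wp[:, 1] / total


@dataclass(frozen=True)
class CellCensus:
    """Counts of the three cell classes; each binucleate particle is one cell."""

    n_mono: int
    n_binucleate: int
    n_fibroblast: int
    include_fibroblasts: bool = True

    @property
    def n_cells(self) -> int:
        n = self.n_mono + self.n_binucleate
        if self.include_fibroblasts:
            n += self.n_fibroblast
        return n

    @property
    def n_particles(self) -> int:
        return self.n_mono + self.n_binucleate + self.n_fibroblast

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(mono, binucleate, fibroblast) proportions over all classified cells."""
        total = self.n_particles
        if total == 0:
            return (0.0, 0.0, 0.0)
        return (
            self.n_mono / total,
            self.n_binucleate / total,
            self.n_fibroblast / total,
        )


def _equal_posterior_point(mix: GaussianMixture1D) -> float | None:
    """Solve w1 N(x; m1, s1) = w2 N(x; m2, s2) for x between the means.

    Taking logs gives a quadratic in x; the root inside (m1, m2) is the
    classification boundary.  Falls back to a dense scan if no closed-form
    root lands between the means.
    """
    (w1, w2), (m1, m2), (s1, s2) = mix.weights, mix.means, mix.sds
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + math.log((w1 * s2) / (w2 * s1))
    )
    if abs(a) < 1e-14:  # equal variances: linear boundary
        if abs(b) < 1e-14:
            return None
        root = -c / b
        return root if m1 < root < m2 else None
    disc = b**2 - 4 * a * c
    if disc >= 0:
        for root in ((-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)):
            if m1 < root < m2:
                return float(root)
    grid = np.linspace(m1, m2, 2001)[1:-1]
    post = mix.posterior(grid)
    crossing = np.nonzero(np.diff(np.signbit(post[:, 0] - 0.5)))[0]
    if crossing.size:
        return float(grid[crossing[0]])
    return None


def determine_area_cutoff(
    particles: list[Particle] | np.ndarray,
    fallback_cutoff: float = 90.0,
    separation_sds: float = 0.5,
    seed: int | None = None,
) -> AreaCutoff:
    """Area cutoff separating mononucleate-myocyte nuclei from larger particles.

    Fits a two-component Gaussian mixture to log(area) and places the cutoff
    at the equal-posterior point between the component means.  If the
    components are indistinguishable (|difference of means| below
    ``separation_sds`` pooled standard deviations) the fit is flagged
    degenerate and ``fallback_cutoff`` (um^2; default twice the typical
    mononucleate median area of 45 um^2) is used instead.
    """
    areas = _areas(particles)
    if areas.size < 50:
        raise InsufficientDataError(
            f"need >= 50 particles to determine the area cutoff, got {areas.size}"
        )
    log_area = np.log(areas)
    mix = fit_gaussian_mixture_1d(log_area, seed=seed)
    params = tuple(
        (float(m), float(s), float(w))
        for m, s, w in zip(mix.means, mix.sds, mix.weights)
    )
    pooled_sd = math.sqrt(
        mix.weights[0] * mix.sds[0] ** 2 + mix.weights[1] * mix.sds[1] ** 2
    )
    separated = abs(mix.means[1] - mix.means[0]) >= separation_sds * pooled_sd
    # a unimodal population can still fit as two nested components with
    # nearby means; require the fitted density to actually dip between them
    if separated and not mix.degenerate:
        grid = np.linspace(mix.means[0], mix.means[1], 513)
        pdf = mix.component_pdf(grid).sum(axis=1)
        separated = bool(pdf[1:-1].min() < min(pdf[0], pdf[-1]) * (1 - 1e-9))
    if mix.degenerate or not separated:
        return AreaCutoff(
            cutoff=float(fallback_cutoff),
            method_detail="degenerate mixture; fixed fallback cutoff",
            component_params=params,
            degenerate=True,
        )
    boundary = _equal_posterior_point(mix)
    if boundary is None:
        return AreaCutoff(
            cutoff=float(fallback_cutoff),
            method_detail="no posterior crossing between means; fixed fallback cutoff",
            component_params=params,
            degenerate=True,
        )
    return AreaCutoff(
        cutoff=float(np.exp(boundary)),
        method_detail="equal-posterior point of 2-component Gaussian mixture on log(area)",
        component_params=params,
    )


def fit_circularity_mixture(
    large_particles: list[Particle] | np.ndarray,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> CircularityMixture:
    """Two-component Gaussian mixture on log(circularity ratio) by EM.

    Applied to particles *above* the area cutoff, where round fibroblast
    nuclei (component 1) and elongated binucleate-myocyte particles
    (component 2) separate cleanly on shape.
    """
    circ = _circularities(large_particles)
    if circ.size < 30:
        raise InsufficientDataError(
            f"need >= 30 large particles for the circularity mixture, got {circ.size}"
        )
    mix = fit_gaussian_mixture_1d(np.log(circ), max_iter=max_iter, tol=tol, seed=seed)
    return CircularityMixture(
        weights=(float(mix.weights[0]), float(mix.weights[1])),
        log_means=(float(mix.means[0]), float(mix.means[1])),
        log_sds=(float(mix.sds[0]), float(mix.sds[1])),
        converged=mix.converged,
        loglik=float(mix.loglik),
        degenerate=mix.degenerate,
    )


def classify_particles(
    particles: list[Particle] | np.ndarray,
    cutoff: AreaCutoff,
    mixture: CircularityMixture,
) -> list[str]:
    """Assign each particle one of the three cell-type labels.

    Particles at or below the area cutoff are mononucleated myocytes; larger
    particles are split fibroblast vs binucleate by maximum posterior under
    the circularity mixture, ties broken toward fibroblast.
    """
    areas = _areas(particles)
    circ = _circularities(particles)
    labels = np.where(areas <= cutoff.cutoff, MONONUCLEATE, FIBROBLAST).astype(object)
    large = areas > cutoff.cutoff
    if large.any():
        p_bi = mixture.posterior_binucleate(circ[large])
        labels[large] = np.where(p_bi > 0.5, BINUCLEATE, FIBROBLAST)
    return list(labels)


def census_cells(labels: list[str], include_fibroblasts: bool = True) -> CellCensus:
    """Count particles per class; binucleate particles count as single cells."""
    arr = np.asarray(labels, dtype=object)
    return CellCensus(
        n_mono=int(np.sum(arr == MONONUCLEATE)),
        n_binucleate=int(np.sum(arr == BINUCLEATE)),
        n_fibroblast=int(np.sum(arr == FIBROBLAST)),
        include_fibroblasts=include_fibroblasts,
    )


def _areas(particles) -> np.ndarray:
    if len(particles) and isinstance(particles[0], Particle):
        return np.array([p.area for p in particles], dtype=float)
    return np.asarray(particles, dtype=float)[:, 0] if np.ndim(particles) == 2 else np.asarray(particles, dtype=float)


def _circularities(particles) -> np.ndarray:
    if len(particles) and isinstance(particles[0], Particle):
        return np.array([p.circularity_ratio for p in particles], dtype=float)
    arr = np.asarray(particles, dtype=float)
    return arr[:, 1] if arr.ndim == 2 else arr
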