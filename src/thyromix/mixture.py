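"""Finite-mixture maximum-likelihood estimation of the non-pathologic component.

Routine laboratory data are a mixture of a dominant healthy population and
pathologic contamination.  The indirect approach implemented here:

1. estimates a smoothed kernel density of the mixed data,
2. assumes the main part of the distribution represents the healthy
   population and models it parametrically — gamma for right-skewed analytes
   (TSH), normal for approximately symmetric ones (FT4),
3. fits the healthy component plus low/high pathologic contamination
   components by EM maximum likelihood, starting from an assumed
   healthy:pathologic ratio,
4. scores each candidate model by the Kolmogorov-Smirnov distance between the
   fitted mixture CDF and the empirical CDF over the main part of the data,
   and selects the most parsimonious candidate within sampling noise of the
   best score.

The reference interval is then read off the healthy component alone
(:mod:`thyromix.intervals`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import special, stats

from .errors import (
    DegenerateComponentError,
    DegenerateDataError,
    DomainError,
    FitError,
    InsufficientDataError,
    InvalidParameterError,
)

log = logging.getLogger(__name__)

FAMILIES = ("gamma", "normal")
ROLES = ("healthy", "patho_low", "patho_high")

SHAPE_CAP = 1e6  # gamma shape guard for numerically constant data
MIN_WEIGHT = 1e-4  # components below this weight are pruned mid-EM


@dataclass(frozen=True)
class ComponentSpec:
    """Family and role of one mixture component."""

    family: str
    role: str

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidParameterError(f"unknown family {self.family!r}")
        if self.role not in ROLES:
            raise InvalidParameterError(f"unknown role {self.role!r}")


@dataclass
class Component:
    """One fitted component: spec, parameters and mixing weight.

    Gamma parameters are (shape k, rate r); normal parameters (mean, sd).
    """

    spec: ComponentSpec
    params: Tuple[float, float]
    weight: float

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        a, b = self.params
        if self.spec.family == "gamma":
            with np.errstate(divide="ignore"):
                return stats.gamma.logpdf(x, a, scale=1.0 / b)
        return stats.norm.logpdf(x, loc=a, scale=b)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        a, b = self.params
        if self.spec.family == "gamma":
            return stats.gamma.cdf(x, a, scale=1.0 / b)
        return stats.norm.cdf(x, loc=a, scale=b)

    def ppf(self, p) -> np.ndarray:
        a, b = self.params
        if self.spec.family == "gamma":
            return stats.gamma.ppf(p, a, scale=1.0 / b)
        return stats.norm.ppf(p, loc=a, scale=b)


@dataclass
class DensityEstimate:
    """Gaussian-kernel density on an even grid spanning the data ± 3 bandwidths."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class MixtureFit:
    """A fitted (or initial) mixture with its diagnostics."""

    components: List[Component]
    log_likelihood: float = -np.inf
    n_iterations: int = 0
    converged: bool = False
    ks_main_part: Optional[float] = None
    data_summary: Optional[Tuple[int, float, float]] = None
    ll_trace: List[float] = field(default_factory=list)

    @property
    def healthy(self) -> Component:
        for c in self.components:
            if c.spec.role == "healthy":
                return c
        raise FitError("no healthy component in fit")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def mixture_cdf(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(x, dtype=float))
        for c in self.components:
            out += c.weight * c.cdf(x)
        return out

    def mixture_logpdf(self, x: np.ndarray) -> np.ndarray:
        logd = np.stack([np.log(c.weight) + c.logpdf(x) for c in self.components])
        return special.logsumexp(logd, axis=0)

    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "family": c.spec.family,
                    "role": c.spec.role,
                    "params": [float(p) for p in c.params],
                    "weight": float(c.weight),
                }
                for c in self.components
            ],
            "log_likelihood": float(self.log_likelihood),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "ks_main_part": None if self.ks_main_part is None else float(self.ks_main_part),
            "data_summary": None
            if self.data_summary is None
            else [int(self.data_summary[0]), float(self.data_summary[1]), float(self.data_summary[2])],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MixtureFit":
        comps = [
            Component(ComponentSpec(c["family"], c["role"]), tuple(c["params"]), c["weight"])
            for c in doc["components"]
        ]
        ds = doc.get("data_summary")
        return cls(
            components=comps,
            log_likelihood=doc.get("log_likelihood", -np.inf),
            n_iterations=doc.get("n_iterations", 0),
            converged=doc.get("converged", False),
            ks_main_part=doc.get("ks_main_part"),
            data_summary=None if ds is None else (ds[0], ds[1], ds[2]),
        )


def _check_values(values, positive=False, min_n=1) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise DomainError("values must be finite")
    if positive and np.any(x <= 0):
        raise DomainError("gamma modelling requires strictly positive values")
    if x.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} values, got {x.size}")
    return x


def estimate_density(values, bandwidth_rule: str = "silverman", grid_size: int = 512) -> DensityEstimate:
    """Gaussian-kernel density of the mixed data (Silverman bandwidth by
    default), evaluated on an even grid spanning [min − 3h, max + 3h]."""
    x = _check_values(values, min_n=30)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateDataError("constant sample: kernel bandwidth degenerates to 0")
    kde = stats.gaussian_kde(x, bw_method=bandwidth_rule)
    h = float(kde.factor) * sd
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    return DensityEstimate(grid=grid, density=kde(grid), bandwidth=h)


def _gamma_from_mode_sd(mode: float, sd: float) -> Tuple[float, float]:
    """Gamma (shape, rate) with the given mode (> 0) and standard deviation.

    Solves sd^2 k^2 - (2 sd^2 + mode^2) k + sd^2 = 0 for the root above 1
    (the gamma has an interior mode only for k > 1)."""
    if mode <= 0:
        raise DomainError("gamma mode must be positive")
    b = 2 * sd**2 + mode**2
    k = (b + np.sqrt(b**2 - 4 * sd**4)) / (2 * sd**2)
    return float(k), float((k - 1) / mode)


def _gamma_from_mean_sd(mean: float, sd: float) -> Tuple[float, float]:
    if mean <= 0:
        raise DomainError("gamma mean must be positive")
    k = max((mean / sd) ** 2, 0.05)
    return float(k), float(k / mean)


def initialize_fit(
    density: DensityEstimate,
    values,
    specs: Sequence[ComponentSpec],
    healthy_fraction_init: float = 0.90,
) -> MixtureFit:
    """Initial mixture: healthy component at the dominant density mode with a
    robust (interquartile-range-based) spread, pathologic components seeded at
    the far tails, weights from the assumed healthy fraction."""
    specs = list(specs)
    if sum(s.role == "healthy" for s in specs) != 1:
        raise InvalidParameterError("exactly one component must have role 'healthy'")
    if not 0 < healthy_fraction_init < 1:
        raise InvalidParameterError("healthy_fraction_init must lie in (0, 1)")
    needs_positive = any(s.family == "gamma" for s in specs)
    x = _check_values(values, positive=needs_positive, min_n=30)

    mode = density.mode()
    q25, q75 = np.percentile(x, [25, 75])
    spread = max((q75 - q25) / 1.349, 1e-9 * max(abs(mode), 1.0))
    lo_seed, hi_seed = np.percentile(x, [1, 99])

    n_patho = max(len(specs) - 1, 1)
    components = []
    for spec in specs:
        if spec.role == "healthy":
            w = healthy_fraction_init if len(specs) > 1 else 1.0
            if spec.family == "normal":
                params = (mode, spread)
            else:
                try:
                    params = _gamma_from_mode_sd(mode, spread)
                except (DomainError, FloatingPointError):
                    params = _gamma_from_mean_sd(float(np.mean(x)), spread)
        else:
            w = (1.0 - healthy_fraction_init) / n_patho
            center = lo_seed if spec.role == "patho_low" else hi_seed
            if spec.family == "normal":
                params = (float(center), spread)
            else:
                # seeded wide (coefficient of variation 1) so EM can move it
                params = _gamma_from_mean_sd(float(max(center, 1e-6)), float(max(center, 1e-6)))
        components.append(Component(spec=spec, params=params, weight=w))
    total = sum(c.weight for c in components)
    for c in components:
        c.weight /= total
    return MixtureFit(components=components, data_summary=(x.size, float(x.min()), float(x.max())))


def weighted_normal_mle(values, weights) -> Tuple[float, float]:
    """Weighted maximum-likelihood normal parameters (mean, sd); the variance
    uses the ML denominator sum(w)."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise InvalidParameterError("values and weights must have equal shape")
    sw = w.sum()
    if not sw > 0:
        raise InvalidParameterError("weights must have positive sum")
    mean = float((w * x).sum() / sw)
    sd = float(np.sqrt((w * (x - mean) ** 2).sum() / sw))
    if sd == 0:
        raise DegenerateComponentError("weighted sample has zero spread")
    return mean, sd


def weighted_gamma_mle(values, weights, tol: float = 1e-10, max_newton: int = 100) -> Tuple[float, float]:
    """Weighted maximum-likelihood gamma parameters (shape k, rate r).

    Solves the profile score  ln k − ψ(k) = ln(Ā) − L̄  (Ā the weighted
    arithmetic mean, L̄ the weighted mean log) by Newton iteration from the
    standard closed-form start, with a bisection fallback if Newton leaves the
    bracket; the rate follows as k/Ā.  Numerically constant data drive
    ln(Ā) − L̄ → 0 and the shape is capped at 1e6 with a warning.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(x <= 0):
        raise DomainError("gamma MLE requires strictly positive values")
    sw = w.sum()
    if not sw > 0:
        raise InvalidParameterError("weights must have positive sum")
    A = float((w * x).sum() / sw)
    L = float((w * np.log(x)).sum() / sw)
    c = np.log(A) - L  # >= 0 by Jensen; == 0 only for constant data
    if c <= 1.0 / (2 * SHAPE_CAP):
        warnings.warn("near-constant data: gamma shape capped", RuntimeWarning)
        return SHAPE_CAP, SHAPE_CAP / A

    def score(k):
        return np.log(k) - special.digamma(k) - c

    k = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    for _ in range(max_newton):
        g = score(k)
        if abs(g) < tol:
            break
        dg = 1.0 / k - special.polygamma(1, k)
        step = g / dg
        k_new = k - step
        if not (0 < k_new < SHAPE_CAP):
            # score is monotone decreasing in k: bisect a bracketing interval
            lo, hi = (k, SHAPE_CAP) if g > 0 else (1e-8, k)
            from scipy.optimize import brentq

            k = brentq(score, lo, hi, xtol=1e-12)
            break
        k = k_new
    if k >= SHAPE_CAP:
        warnings.warn("gamma shape at overflow guard", RuntimeWarning)
        k = SHAPE_CAP
    return float(k), float(k / A)


def _m_step(component: Component, x: np.ndarray, resp: np.ndarray) -> Component:
    if component.spec.family == "gamma":
        params = weighted_gamma_mle(x, resp)
    else:
        params = weighted_normal_mle(x, resp)
    return replace(component, params=params)


def fit_mixture_em(
    values,
    init: MixtureFit,
    specs: Optional[Sequence[ComponentSpec]] = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MixtureFit:
    """EM maximum likelihood from an initial mixture.

    E-step responsibilities are computed in log space with log-sum-exp
    renormalisation; M-steps use the weighted gamma/normal MLEs.  Iteration
    stops when the relative log-likelihood improvement drops below ``tol`` or
    after ``max_iter`` iterations.  Components that collapse (weight below
    1e-4 or degenerate spread) are pruned and fitting continues with the
    remainder.  The log-likelihood trace is recorded and is non-decreasing up
    to floating-point error.
    """
    if specs is not None and list(specs) != [c.spec for c in init.components]:
        raise InvalidParameterError("specs do not match the initial mixture")
    needs_positive = any(c.spec.family == "gamma" for c in init.components)
    x = _check_values(values, positive=needs_positive, min_n=2)

    comps = [replace(c) for c in init.components]
    trace: List[float] = []
    ll_old = -np.inf
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        logd = np.stack([np.log(c.weight) + c.logpdf(x) for c in comps])
        log_mix = special.logsumexp(logd, axis=0)
        ll = float(log_mix.sum())
        trace.append(ll)
        resp = np.exp(logd - log_mix)
        new_w = resp.mean(axis=1)

        if len(comps) > 1 and new_w.min() < MIN_WEIGHT:
            j = int(np.argmin(new_w))
            log.info("pruning collapsed %s/%s component (weight %.2e)",
                     comps[j].spec.family, comps[j].spec.role, new_w[j])
            comps.pop(j)
            w = np.array([c.weight for c in comps])
            for c, wi in zip(comps, w / w.sum()):
                c.weight = float(wi)
            # the trace documents contiguous EM on one component set
            trace = []
            ll_old = -np.inf
            continue

        try:
            comps = [
                replace(_m_step(c, x, resp[j]), weight=float(new_w[j]))
                for j, c in enumerate(comps)
            ]
        except DegenerateComponentError:
            if len(comps) == 1:
                raise
            spreads = [c.params[1] if c.spec.family == "normal" else 1.0 / c.params[0] for c in comps]
            j = int(np.argmin(spreads))
            log.info("pruning degenerate component %d", j)
            comps.pop(j)
            w = np.array([c.weight for c in comps])
            for c, wi in zip(comps, w / w.sum()):
                c.weight = float(wi)
            trace = []
            ll_old = -np.inf
            continue

        if np.isfinite(ll_old) and (ll - ll_old) < tol * abs(ll):
            converged = True
            break
        ll_old = ll

    if not any(c.spec.role == "healthy" for c in comps):
        # the nominal healthy component was pruned: the dominant survivor is
        # the de-facto main part
        j = int(np.argmax([c.weight for c in comps]))
        warnings.warn("healthy component pruned; re-identifying dominant component", RuntimeWarning)
        comps[j] = replace(comps[j], spec=ComponentSpec(comps[j].spec.family, "healthy"))
    else:
        healthy = max((c for c in comps if c.spec.role == "healthy"), key=lambda c: c.weight)
        biggest = max(comps, key=lambda c: c.weight)
        if biggest is not healthy:
            warnings.warn(
                "healthy component no longer dominant; re-identifying as the "
                "largest-weight component",
                RuntimeWarning,
            )
            def _mean(c):
                return c.params[0] / c.params[1] if c.spec.family == "gamma" else c.params[0]

            comps = [
                replace(
                    c,
                    spec=ComponentSpec(
                        c.spec.family,
                        "healthy" if c is biggest else ("patho_low" if _mean(c) < _mean(biggest) else "patho_high"),
                    ),
                )
                for c in comps
            ]

    fit = MixtureFit(
        components=comps,
        log_likelihood=trace[-1] if trace else -np.inf,
        n_iterations=it,
        converged=converged,
        data_summary=(x.size, float(x.min()), float(x.max())),
        ll_trace=trace,
    )
    if converged:
        fit.ks_main_part = ks_main_part(fit, x)
    return fit


def ks_main_part(fit: MixtureFit, values, region: Tuple[float, float] = (0.05, 0.95)) -> float:
    """Kolmogorov-Smirnov distance between the fitted mixture CDF and the
    empirical CDF, restricted to the main part of the data.

    The main part is the interval between the healthy component's 5th and
    95th percentiles (configurable via ``region``): the central region the
    healthy-population assumption is about.
    """
    if not fit.converged:
        raise FitError("ks_main_part requires a converged fit")
    x = np.sort(np.asarray(values, dtype=float))
    lo, hi = fit.healthy.ppf(list(region))
    mask = (x >= lo) & (x <= hi)
    if not mask.any():
        raise FitError("no observations inside the main-part region")
    n = x.size
    F = fit.mixture_cdf(x)
    i = np.arange(1, n + 1)
    d_plus = np.abs(i / n - F)[mask].max()
    d_minus = np.abs((i - 1) / n - F)[mask].max()
    return float(max(d_plus, d_minus))


def default_spec_sets(
    families: Sequence[str] = FAMILIES, patho_counts: Sequence[int] = (0, 2)
) -> List[List[ComponentSpec]]:
    """Candidate component sets: per family, a healthy-only model and a model
    with low/high pathologic contamination components of the same family."""
    sets = []
    for fam in families:
        for npatho in patho_counts:
            specs = [ComponentSpec(fam, "healthy")]
            if npatho >= 1:
                specs.append(ComponentSpec(fam, "patho_low"))
            if npatho >= 2:
                specs.append(ComponentSpec(fam, "patho_high"))
            sets.append(specs)
    return sets


def select_model(
    values,
    candidate_spec_sets: Sequence[Sequence[ComponentSpec]],
    healthy_fraction_init: float = 0.90,
    tol: float = 1e-8,
    max_iter: int = 2000,
    ks_tie_tol: Optional[float] = None,
) -> MixtureFit:
    """Fit every candidate component set and select by KS main-part distance.

    Candidates whose KS distance lies within ``ks_tie_tol`` of the minimum are
    treated as statistically indistinguishable; among them the fit with the
    fewest components wins, then the higher log-likelihood.  The default tie
    tolerance is 1/sqrt(n): the KS distance of a correctly specified fitted
    model concentrates at this scale, and flexible extra components can absorb
    that much pure sampling noise, so a contamination component is retained
    only when it improves the main-part fit beyond what noise explains.
    """
    candidate_spec_sets = [list(s) for s in candidate_spec_sets]
    if not candidate_spec_sets:
        raise InvalidParameterError("need at least one candidate spec set")
    x = np.asarray(values, dtype=float)
    if ks_tie_tol is None:
        ks_tie_tol = 1.0 / np.sqrt(max(x.size, 1))

    fits: List[MixtureFit] = []
    failures: List[str] = []
    for specs in candidate_spec_sets:
        try:
            density = estimate_density(x)
            init = initialize_fit(density, x, specs, healthy_fraction_init)
            fit = fit_mixture_em(x, init, tol=tol, max_iter=max_iter)
            if fit.ks_main_part is None:
                fit.ks_main_part = ks_main_part(fit, x)
            fits.append(fit)
        except Exception as exc:  # noqa: BLE001 - aggregate candidate failures
            failures.append(f"{[s.family + '/' + s.role for s in specs]}: {exc}")
    if not fits:
        raise FitError("all candidate fits failed: " + "; ".join(failures))

    best_ks = min(f.ks_main_part for f in fits)
    contenders = [f for f in fits if f.ks_main_part <= best_ks + ks_tie_tol]
    contenders.sort(key=lambda f: (len(f.components), -f.log_likelihood, f.ks_main_part))
    return contenders[0]


def histogram_loglik(fit: MixtureFit, values, bins: str = "fd") -> float:
    """Multinomial log-likelihood of the histogram counts under the fitted
    mixture (Freedman-Diaconis bins by default) — a binned-likelihood
    cross-check of the raw-value fit."""
    x = np.asarray(values, dtype=float)
    edges = np.histogram_bin_edges(x, bins=bins)
    counts, _ = np.histogram(x, bins=edges)
    cdf = fit.mixture_cdf(edges)
    probs = np.diff(cdf)
    # fold tail mass into the outer bins so probabilities sum to 1
    probs[0] += cdf[0]
    probs[-1] += 1.0 - cdf[-1]
    keep = counts > 0
    return float((counts[keep] * np.log(np.maximum(probs[keep], 1e-300))).sum())
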