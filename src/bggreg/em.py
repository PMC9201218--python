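"""Expectation-maximization for the bounded generalized Gaussian mixture.

The M-step corrections for the truncated support (R and G) are
self-normalized Monte-Carlo averages over in-support samples.  Both have
known expectation zero under the unbounded density, so they are computed
with that full-sample mean subtracted as a control variate: when the
support covers all samples the corrections are exactly zero, and under
genuine truncation the estimator remains consistent with lower variance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .model import (
    BGGComponent,
    BGGMixture,
    DegenerateComponentError,
    MonteCarloBank,
    SupportRegion,
    _channel_draw,
    log_likelihood,
    mixture_log_densities,
    shape_constants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EMConfig",
    "ResponsibilityMatrix",
    "e_step",
    "mean_correction",
    "scale_correction",
    "update_means",
    "update_scales",
    "shape_objective",
    "update_shapes",
    "update_weights",
    "kmeans_init",
    "run_em",
    "make_banks",
    "bank_seed",
]


@dataclass
class EMConfig:
    """Knobs for the density-estimation phase.

    ``em_iterations`` is the number of EM cycles per outer round (T1);
    ``newton_damping`` the scale factor added to the second derivative in
    the shape step, doubled on non-improving steps.
    """

    em_iterations: int = 5
    newton_damping: float = 1.0
    shape_bounds: tuple = (0.2, 10.0)
    mc_count: int = 10_000
    tolerance: float = 1e-4
    seed: int = 0
    epsilon: float = 1e-6
    fd_step: float = 1e-3

    def __post_init__(self):
        lo, hi = self.shape_bounds
        if not (0 < lo < hi):
            raise ValueError("shape_bounds must be an interval inside (0, inf)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.em_iterations < 0:
            raise ValueError("em_iterations must be nonnegative")

    @classmethod
    def from_file(cls, path) -> "EMConfig":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {}
        aliases = {"t1": "em_iterations", "damping": "newton_damping"}
        for key, value in payload.items():
            name = aliases.get(key, key)
            if name == "shape_bounds":
                value = tuple(value)
            kwargs[name] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class ResponsibilityMatrix:
    """X-by-M posterior cluster memberships; rows sum to one."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("responsibilities must be a 2-D matrix")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("responsibilities must lie in [0, 1]")
        sums = values.sum(axis=1)
        if not np.allclose(sums, 1.0, rtol=0, atol=1e-9):
            raise ValueError("responsibility rows must sum to 1")
        values = values / sums[:, None]
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


def _vectors(field) -> np.ndarray:
    vectors = getattr(field, "vectors", field)
    return np.atleast_2d(np.asarray(vectors, dtype=float))


def bank_seed(base: int, index: int) -> int:
    """Stable per-component sample-bank seed derived from one base seed."""
    return int(np.random.SeedSequence([int(base), int(index)]).generate_state(1)[0])


def make_banks(mixture: BGGMixture, mc_count: int, base_seed: int):
    """One Monte-Carlo bank per component, seeds fixed per component index.

    The seed depends on the component index only, so regenerating after a
    parameter change reuses the same underlying uniforms (common random
    numbers) and keeps the EM objective smooth across iterations.
    """
    return [
        MonteCarloBank.draw(comp, mc_count, bank_seed(base_seed, m))
        for m, comp in enumerate(mixture.components)
    ]


def e_step(field, mixture: BGGMixture, banks) -> ResponsibilityMatrix:
    """Posterior membership of every pixel in every component (log-sum-exp)."""
    vectors = _vectors(field)
    logs = mixture_log_densities(vectors, mixture, banks)
    finite = np.isfinite(logs)
    dead = ~finite.any(axis=1)
    if dead.any():
        logger.warning("%d pixels had zero density under every component", int(dead.sum()))
    top = logs.max(axis=1, where=finite, initial=-np.inf)
    with np.errstate(invalid="ignore"):
        expd = np.exp(logs - top[:, None])
    expd[~finite] = 0.0
    expd[dead] = 1.0
    resp = expd / expd.sum(axis=1, keepdims=True)
    return ResponsibilityMatrix(resp)


def _in_support_terms(component: BGGComponent, bank: MonteCarloBank, channel: int):
    s = bank.samples[channel]
    lo = component.support.lower[channel]
    hi = component.support.upper[channel]
    inside = (s >= lo) & (s <= hi)
    if not inside.any():
        raise DegenerateComponentError(
            f"channel {channel}: no Monte-Carlo samples inside support"
        )
    return s, inside


def mean_correction(component: BGGComponent, bank: MonteCarloBank) -> np.ndarray:
    """Per-channel truncation correction R for the mean update.

    Self-normalized average of signum(u - S)*|S - u|**(shape-1) over
    in-support samples, with the (analytically zero) full-sample average
    subtracted as a control variate.
    """
    out = np.empty(component.n_channels)
    for c in range(component.n_channels):
        s, inside = _in_support_terms(component, bank, c)
        u, lam = component.mean[c], component.shape[c]
        r = np.where(u - s >= 0, 1.0, -1.0) * np.abs(s - u) ** (lam - 1.0)
        out[c] = r[inside].mean() - r.mean()
    return out


def scale_correction(component: BGGComponent, bank: MonteCarloBank) -> np.ndarray:
    """Per-channel truncation correction G for the scale update.

    Self-normalized average of (-1 + shape*beta*|S-u|**shape / scale**shape)
    over in-support samples, control-variated by the full-sample average.
    """
    out = np.empty(component.n_channels)
    _, beta = shape_constants(component.shape, component.scale)
    for c in range(component.n_channels):
        s, inside = _in_support_terms(component, bank, c)
        u, lam, sig = component.mean[c], component.shape[c], component.scale[c]
        h = -1.0 + lam * beta[c] * np.abs(s - u) ** lam / sig**lam
        out[c] = h[inside].mean() - h.mean()
    return out


def _update_mean_single(vectors, eta, component, bank, epsilon) -> np.ndarray:
    dev = np.abs(vectors - component.mean)
    lam = component.shape
    dev = np.where(lam < 2.0, np.maximum(dev, epsilon), dev)
    w = eta[:, None] * dev ** (lam - 2.0)
    r = mean_correction(component, bank)
    num = (w * vectors).sum(axis=0) + r * eta.sum()
    den = w.sum(axis=0)
    new = np.where(den > 0, num / np.where(den > 0, den, 1.0), component.mean)
    if np.any(den <= 0):
        logger.debug("zero denominator in mean update; keeping previous mean")
    return np.clip(new, component.support.lower, component.support.upper)


def _update_scale_single(vectors, eta, component, bank, epsilon) -> np.ndarray:
    lam = component.shape
    _, beta = shape_constants(lam, component.scale)
    g = scale_correction(component, bank)
    dev = np.abs(vectors - component.mean)
    num = lam * beta * (eta[:, None] * dev**lam).sum(axis=0)
    den = eta.sum() * (1.0 + g)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = num / den
    # zero bracket (all mass at the mean) legitimately floors at epsilon;
    # a negative one (heavy truncation, G < -1) keeps the previous scale
    ok = np.isfinite(bracket) & (bracket >= 0)
    if not ok.all():
        logger.debug("negative bracket in scale update; keeping previous scale")
    new = np.where(ok, np.maximum(bracket, 1e-300) ** (1.0 / lam), component.scale)
    return np.maximum(new, epsilon)


def update_means(field, responsibilities: ResponsibilityMatrix, mixture: BGGMixture, banks, epsilon: float = 1e-6) -> np.ndarray:
    """(M, C) matrix of updated means, clamped into the support box."""
    vectors = _vectors(field)
    eta = responsibilities.values
    return np.stack(
        [
            _update_mean_single(vectors, eta[:, m], comp, bank, epsilon)
            for m, (comp, bank) in enumerate(zip(mixture.components, banks))
        ]
    )


def update_scales(field, responsibilities: ResponsibilityMatrix, mixture: BGGMixture, banks, epsilon: float = 1e-6) -> np.ndarray:
    """(M, C) matrix of updated scales, floored at epsilon."""
    vectors = _vectors(field)
    eta = responsibilities.values
    return np.stack(
        [
            _update_scale_single(vectors, eta[:, m], comp, bank, epsilon)
            for m, (comp, bank) in enumerate(zip(mixture.components, banks))
        ]
    )


def _channel_objective(values_c, eta, mean_c, scale_c, lo, hi, lam, count, seed) -> float:
    """Shape-dependent expected complete log-likelihood for one channel.

    The trial bank is regenerated from the channel's fixed seed so the
    objective is a smooth function of the trial shape.
    """
    alpha, beta = shape_constants(lam, scale_c)
    s = _channel_draw(mean_c, scale_c, lam, count, seed)
    frac = ((s >= lo) & (s <= hi)).mean()
    if frac == 0.0:
        return -np.inf
    dev = np.abs(values_c - mean_c)
    log_t = np.log(alpha) - beta * dev**lam / scale_c**lam
    return float((eta * log_t).sum() - eta.sum() * np.log(frac))


def _channel_seeds(bank: MonteCarloBank, n_channels: int):
    return np.random.SeedSequence(bank.seed).spawn(n_channels)


def shape_objective(field, responsibilities, component: BGGComponent, bank: MonteCarloBank, shape) -> float:
    """Shape-dependent part of the expected complete log-likelihood.

    ``responsibilities`` is the posterior column for this component.
    Evaluated at a trial shape vector with a bank regenerated from the
    bank's seed (common random numbers across trial shapes).
    """
    vectors = _vectors(field)
    eta = np.asarray(responsibilities, dtype=float).ravel()
    shape = np.atleast_1d(np.asarray(shape, dtype=float))
    if shape.size == 1 and component.n_channels > 1:
        shape = np.full(component.n_channels, shape[0])
    seeds = _channel_seeds(bank, component.n_channels)
    total = 0.0
    for c in range(component.n_channels):
        total += _channel_objective(
            vectors[:, c],
            eta,
            component.mean[c],
            component.scale[c],
            component.support.lower[c],
            component.support.upper[c],
            shape[c],
            bank.count,
            seeds[c],
        )
    return total


def _update_shape_single(vectors, eta, component, bank, config: EMConfig) -> np.ndarray:
    """One damped Newton step per channel, kept only if it improves."""
    lo_b, hi_b = config.shape_bounds
    h = config.fd_step
    seeds = _channel_seeds(bank, component.n_channels)
    new = component.shape.copy()
    for c in range(component.n_channels):
        args = (
            vectors[:, c],
            eta,
            component.mean[c],
            component.scale[c],
            component.support.lower[c],
            component.support.upper[c],
        )

        def f(lam):
            return _channel_objective(*args, lam, bank.count, seeds[c])

        lam0 = float(np.clip(component.shape[c], lo_b, hi_b))
        f0 = f(lam0)
        fp = f(lam0 + h)
        fm = f(max(lam0 - h, lo_b / 2))
        if not np.isfinite([f0, fp, fm]).all():
            continue
        q1 = (fp - fm) / (2 * h)
        q2 = (fp - 2 * f0 + fm) / h**2
        denom = q2 + config.newton_damping
        if denom == 0.0:
            denom = q2 + 2.0 * config.newton_damping
        if denom == 0.0:
            continue
        step = -q1 / denom
        # backtrack along the damped-Newton direction; the raw step can
        # badly overshoot when the objective is far from quadratic
        for _ in range(6):
            cand = float(np.clip(lam0 + step, lo_b, hi_b))
            if cand != lam0 and f(cand) > f0:
                new[c] = cand
                break
            step *= 0.5
        # all attempts rejected: keep the previous shape
    return new


def update_shapes(field, responsibilities: ResponsibilityMatrix, mixture: BGGMixture, banks, config: EMConfig) -> np.ndarray:
    """(M, C) matrix of updated shapes, clipped to the configured bounds."""
    vectors = _vectors(field)
    eta = responsibilities.values
    return np.stack(
        [
            _update_shape_single(vectors, eta[:, m], comp, bank, config)
            for m, (comp, bank) in enumerate(zip(mixture.components, banks))
        ]
    )


def update_weights(responsibilities: ResponsibilityMatrix) -> np.ndarray:
    """Mixture weights as column means of the responsibilities."""
    tau = responsibilities.values.mean(axis=0)
    return tau / tau.sum()


def kmeans_init(field, n_components: int, seed: int, support: SupportRegion | None = None, scale_floor: float = 1.0) -> BGGMixture:
    """k-means initialization: centers as means, within-cluster per-channel
    standard deviations as scales (floored), proportions as weights, all
    shapes started at 2."""
    vectors = _vectors(field)
    x, n_ch = vectors.shape
    if x < n_components:
        raise ValueError("need at least as many pixels as components")
    if support is None:
        support = SupportRegion.default(n_ch)
    km = KMeans(n_clusters=n_components, random_state=seed, n_init=4).fit(vectors)
    labels = km.labels_
    rng = np.random.default_rng(seed)
    comps, weights = [], []
    for m in range(n_components):
        members = vectors[labels == m]
        if members.shape[0] == 0:
            members = vectors[rng.integers(0, x, 1)]
        mean = np.clip(members.mean(axis=0), support.lower, support.upper)
        scale = np.maximum(members.std(axis=0), scale_floor)
        comps.append(BGGComponent(mean=mean, scale=scale, shape=np.full(n_ch, 2.0), support=support))
        weights.append(max(members.shape[0], 1) / x)
    weights = np.asarray(weights)
    return BGGMixture(comps, weights / weights.sum())


def run_em(field, mixture: BGGMixture, config: EMConfig):
    """T1 EM cycles: e-step, then mean / scale / shape / weight updates.

    Banks are regenerated (same per-component seeds) after every parameter
    change.  Components whose support loses all Monte-Carlo mass are frozen
    with their weight pushed toward zero.  Returns the final mixture and
    the per-iteration log-likelihood trace (including the starting value).
    """
    vectors = _vectors(field)
    mc, seed = config.mc_count, config.seed
    banks = make_banks(mixture, mc, seed)
    trace = [log_likelihood(vectors, mixture, banks)]
    frozen: set[int] = set()
    for _ in range(config.em_iterations):
        resp = e_step(vectors, mixture, banks)
        comps = []
        for m, comp in enumerate(mixture.components):
            if m in frozen:
                comps.append(comp)
                continue
            eta = resp.values[:, m]
            try:
                bank = banks[m]
                mean = _update_mean_single(vectors, eta, comp, bank, config.epsilon)
                comp = replace(comp, mean=mean)
                bank = MonteCarloBank.draw(comp, mc, bank.seed)
                scale = _update_scale_single(vectors, eta, comp, bank, config.epsilon)
                comp = replace(comp, scale=scale)
                bank = MonteCarloBank.draw(comp, mc, bank.seed)
                shape = _update_shape_single(vectors, eta, comp, bank, config)
                comp = replace(comp, shape=shape)
            except DegenerateComponentError as exc:
                logger.warning("component %d degenerate (%s); freezing", m, exc)
                frozen.add(m)
                comp = mixture.components[m]
            comps.append(comp)
        tau = update_weights(resp)
        if frozen:
            tau = tau.copy()
            tau[list(frozen)] = 1e-12
            tau = tau / tau.sum()
        mixture = BGGMixture(comps, tau)
        banks = make_banks(mixture, mc, seed)
        trace.append(log_likelihood(vectors, mixture, banks))
        rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
        if rel < config.tolerance:
            break
    return mixture, trace
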