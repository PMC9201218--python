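"""Coarse-to-fine registration: alternating density estimation and motion.

At each resolution level the mixture is (re)fitted with a few EM cycles
(T1), then the rigid transform is refined with a run of linearized motion
steps (T2), alternating until the increment norm falls below tolerance.
The transform found at one level seeds the next, with translations
rescaled to the new pixel grid.

Because the joint-intensity likelihood is multi-modal in the rotation
angle (a mixture refitted at a rotated state is locally optimal there),
the coarsest level is restarted from a small set of candidate angles and
the start whose alternation ends with the best per-pixel profile
log-likelihood wins.  Coarse levels are tiny, so this costs little.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.transform import rescale as _skimage_rescale

from .em import EMConfig, e_step, kmeans_init, make_banks, run_em
from .model import BGGMixture, log_likelihood
from .motion import (
    ImagePair,
    MotionIncrement,
    NoOverlapError,
    RigidTransform2D,
    apply_increment,
    build_joint_field,
    intensity_jacobian,
    solve_increment,
)

logger = logging.getLogger(__name__)

__all__ = ["RegistrationConfig", "RegistrationResult", "rescale_transform", "register"]


@dataclass
class RegistrationConfig:
    components: int = 6
    resolutions: tuple = (0.1, 0.2, 1.0)
    em_config: EMConfig = dc_field(default_factory=EMConfig)
    motion_iterations: int = 10
    outer_iterations: int = 20
    increment_tolerance: float = 1e-3
    seed: int = 0
    weight_mode: str = "derived"
    coarse_angle_starts: tuple = (-10.0, -5.0, 0.0, 5.0, 10.0)
    coarse_translation_starts: tuple = (-2.0, -1.0, 0.0, 1.0, 2.0)
    coarse_refine_top: int = 3

    def __post_init__(self):
        res = tuple(float(r) for r in self.resolutions)
        if len(res) < 1 or res[-1] != 1.0:
            raise ValueError("resolutions must end at full scale (1)")
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ValueError("resolutions must be strictly increasing")
        if any(r <= 0 for r in res):
            raise ValueError("resolutions must be positive")
        if self.components < 1:
            raise ValueError("components must be >= 1")
        if self.motion_iterations < 1:
            raise ValueError("motion_iterations (T2) must be >= 1")
        self.resolutions = res
        # a single seed drives every random draw in the run
        self.em_config.seed = self.seed


@dataclass
class RegistrationResult:
    transform: RigidTransform2D
    likelihood_trace: list
    level_transforms: list
    converged: bool
    iterations_used: list
    mixture: BGGMixture | None = None
    pad: float | None = None


def rescale_transform(transform: RigidTransform2D, from_scale: float, to_scale: float) -> RigidTransform2D:
    """Carry a transform between pyramid levels: translations scale, angle doesn't."""
    if from_scale <= 0 or to_scale <= 0:
        raise ValueError("scales must be positive")
    f = to_scale / from_scale
    return RigidTransform2D(transform.tx * f, transform.ty * f, transform.angle)


def _rescale_image(image: np.ndarray, scale: float) -> np.ndarray:
    if scale == 1.0:
        return image.copy()
    out = _skimage_rescale(image, scale, anti_aliasing=True, preserve_range=True, order=1)
    return np.clip(out, 0.0, 255.0)


def _mean_log_likelihood(pair, transform, mixture, banks) -> float:
    fld = build_joint_field(pair, transform)
    return log_likelihood(fld, mixture, banks) / fld.count


def _damped_apply(pair, transform, increment, mixture, banks, q_current):
    """Apply the increment, halving it (up to 5 times) while the average
    log-likelihood under the current mixture would decrease."""
    inc = increment
    for _ in range(6):
        candidate = apply_increment(transform, inc)
        try:
            q_new = _mean_log_likelihood(pair, candidate, mixture, banks)
        except NoOverlapError:
            inc = inc.scaled(0.5)
            continue
        if q_new >= q_current - 1e-12:
            return candidate, inc, q_new
        inc = inc.scaled(0.5)
    return transform, MotionIncrement(0.0, 0.0, 0.0), q_current


def _register_level(pair_s, transform, mixture, config, level, scale):
    """Alternate T1 EM cycles with T2 motion steps at one pyramid level."""
    em_cfg = config.em_config
    trace: list[float] = []
    converged = False
    outer = 0
    for outer in range(1, config.outer_iterations + 1):
        round_start = transform
        try:
            fld = build_joint_field(pair_s, transform)
        except NoOverlapError as exc:
            raise NoOverlapError(f"empty overlap at resolution level {level} (scale {scale})") from exc
        if mixture is None:
            mixture = kmeans_init(fld, config.components, config.seed)
        mixture, em_trace = run_em(fld, mixture, em_cfg)
        trace.extend(em_trace)

        banks = make_banks(mixture, em_cfg.mc_count, em_cfg.seed)
        last_norm = np.inf
        for _ in range(config.motion_iterations):
            try:
                fld = build_joint_field(pair_s, transform)
            except NoOverlapError as exc:
                raise NoOverlapError(
                    f"empty overlap at resolution level {level} (scale {scale})"
                ) from exc
            resp = e_step(fld, mixture, banks)
            jac = intensity_jacobian(pair_s, transform)
            inc = solve_increment(fld, jac, resp, mixture, config.weight_mode)
            q_cur = log_likelihood(fld, mixture, banks) / fld.count
            transform, applied, _ = _damped_apply(pair_s, transform, inc, mixture, banks, q_cur)
            last_norm = applied.norm()
            if last_norm < config.increment_tolerance:
                break
        logger.info(
            "level %d outer %d: transform=(%.3f, %.3f, %.3f deg), |inc|=%.2e",
            level, outer, transform.tx, transform.ty, transform.angle, last_norm,
        )
        round_change = max(
            abs(transform.tx - round_start.tx),
            abs(transform.ty - round_start.ty),
            abs(transform.angle - round_start.angle),
        )
        if last_norm < config.increment_tolerance or round_change < config.increment_tolerance:
            converged = True
            break
    banks = make_banks(mixture, em_cfg.mc_count, em_cfg.seed)
    q_final = _mean_log_likelihood(pair_s, transform, mixture, banks)
    return transform, mixture, trace, outer, converged, q_final


def _quick_score(pair_s, transform, config) -> float:
    """Cheap per-pixel profile likelihood proxy: k-means fit, no EM."""
    try:
        fld = build_joint_field(pair_s, transform)
    except NoOverlapError:
        return -np.inf
    if fld.count < config.components:
        return -np.inf
    mixture = kmeans_init(fld, config.components, config.seed)
    banks = make_banks(mixture, min(config.em_config.mc_count, 2000), config.seed)
    return log_likelihood(fld, mixture, banks) / fld.count


def _coarse_starts(pair_s, incoming: RigidTransform2D, config) -> list:
    """Rank a small angle x translation grid of starting transforms.

    The unshifted incoming transform is always kept so an already
    registered pair is never forced through a perturbed start only.
    """
    candidates = []
    for da in config.coarse_angle_starts:
        for dx in config.coarse_translation_starts:
            for dy in config.coarse_translation_starts:
                t = RigidTransform2D(incoming.tx + dx, incoming.ty + dy, incoming.angle + da)
                candidates.append((_quick_score(pair_s, t, config), t))
    candidates.sort(key=lambda c: c[0], reverse=True)
    top = [t for score, t in candidates[: config.coarse_refine_top] if np.isfinite(score)]
    if incoming not in top:
        top.append(incoming)
    return top or [incoming]


def register(pair: ImagePair, config: RegistrationConfig) -> RegistrationResult:
    """Run the full multi-resolution registration of ``pair``.

    Returns the estimated transform taking the floating image onto the
    reference, per-level likelihood traces and diagnostics.  Deterministic
    for a fixed configuration seed.
    """
    multi_start = len(config.coarse_angle_starts) > 1 or len(config.coarse_translation_starts) > 1
    # each track: [transform, mixture, traces, level_transforms, iterations, converged]
    tracks = [[RigidTransform2D.identity(), None, [], [], [], False]]
    prev_scale = None

    for level, scale in enumerate(config.resolutions):
        pair_s = ImagePair(_rescale_image(pair.reference, scale), _rescale_image(pair.floating, scale))
        if prev_scale is not None:
            for tr in tracks:
                tr[0] = rescale_transform(tr[0], prev_scale, scale)
        prev_scale = scale

        if level == 0 and multi_start:
            starts = _coarse_starts(pair_s, tracks[0][0], config)
        else:
            starts = None

        outcomes = []
        for tr in tracks:
            begin = starts if starts is not None else [tr[0]]
            for start in begin:
                try:
                    transform, mixture, trace, outer, conv, q = _register_level(
                        pair_s, start, tr[1], config, level, scale
                    )
                except NoOverlapError:
                    if len(tracks) == 1 and starts is None:
                        raise
                    continue
                outcomes.append(
                    (
                        q,
                        [
                            transform,
                            mixture,
                            tr[2] + [trace],
                            tr[3] + [transform],
                            tr[4] + [outer],
                            conv,
                        ],
                    )
                )
        if not outcomes:
            raise NoOverlapError(f"empty overlap at resolution level {level} (scale {scale})")
        outcomes.sort(key=lambda o: o[0], reverse=True)
        if level == 0 and len(config.resolutions) > 1 and len(outcomes) > 1:
            # ambiguous basins at the tiny coarse scale: defer the final
            # choice until the candidates have been refined one level up
            tracks = [o[1] for o in outcomes[: max(1, config.coarse_refine_top)]]
        else:
            tracks = [outcomes[0][1]]

    transform, mixture, traces, level_transforms, iterations_used, converged = tracks[0]
    return RegistrationResult(
        transform=transform,
        likelihood_trace=traces,
        level_transforms=level_transforms,
        converged=converged,
        iterations_used=iterations_used,
        mixture=mixture,
    )
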