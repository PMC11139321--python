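"""DDPM math core: schedules, continuous noise levels, forward corruption,
the L1 noise-prediction objective, and the fast conditioned reverse sampler.

The forward process corrupts a clean tile x0 with scheduled Gaussian noise,
x_t = sqrt(abar_t) * x0 + sqrt(1 - abar_t) * eps, where abar_t is the
cumulative product of alpha_t = 1 - beta_t over a linear variance schedule.
Training conditions the denoiser on a *continuous* noise level: at a random
step t the level is drawn uniformly from [l_t, l_{t-1}] where
l_t = prod_{i<=t} (1 - beta_i) and l_0 = 1 (so l_t equals abar_t for t >= 1).
Because the denoiser sees the level rather than the step index, inference can
run a much shorter schedule (T = 50, beta_T = 0.95 by default) than training
(T = 1000, beta_T = 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "build_schedule",
    "sample_noise_level",
    "forward_diffuse",
    "training_loss",
    "reverse_sample",
    "TRAIN_SCHEDULE",
    "INFERENCE_SCHEDULE",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Linear variance schedule with cumulative noise levels.

    ``beta``, ``alpha`` and ``alpha_bar`` are length-T arrays indexed by
    ``t - 1``; ``l`` has length T + 1 with ``l[0] = 1`` and ``l[t]`` equal to
    ``alpha_bar[t - 1]``.
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    l: np.ndarray


def build_schedule(T: int, beta1: float, betaT: float) -> NoiseSchedule:
    """Build a linear schedule from ``beta1`` at t=1 to ``betaT`` at t=T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 < beta1 <= betaT < 1:
        raise ValueError("need 0 < beta1 <= betaT < 1")
    if T == 1:
        beta = np.array([beta1], dtype=np.float64)
    else:
        beta = beta1 + (betaT - beta1) * np.arange(T, dtype=np.float64) / (T - 1)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    l = np.concatenate(([1.0], alpha_bar))
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar, l=l)


#: training defaults
TRAIN_SCHEDULE = dict(T=1000, beta1=1e-4, betaT=0.02)
#: fast inference defaults
INFERENCE_SCHEDULE = dict(T=50, beta1=1e-4, betaT=0.95)


def sample_noise_level(
    schedule: NoiseSchedule, t, rng: np.random.Generator
) -> np.ndarray:
    """Draw a continuous noise level uniformly between l_t and l_{t-1}.

    ``t`` may be a scalar or an array of step indices in [1, T]; one level is
    drawn per index.
    """
    t = np.asarray(t)
    if np.any((t < 1) | (t > schedule.T)):
        raise ValueError("step index out of range [1, T]")
    hi = schedule.l[t - 1]  # l_{t-1} > l_t
    lo = schedule.l[t]
    return rng.uniform(lo, hi)


def forward_diffuse(x0: np.ndarray, level, eps: np.ndarray) -> np.ndarray:
    """x_t = sqrt(abar) * x0 + sqrt(1 - abar) * eps at noise level abar."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError("x0 and eps shapes differ")
    level = np.asarray(level, dtype=np.float64)
    if level.ndim == 1 and x0.ndim > 1:
        level = level.reshape((-1,) + (1,) * (x0.ndim - 1))
    return np.sqrt(level) * x0 + np.sqrt(1.0 - level) * eps


def training_loss(eps: np.ndarray, eps_hat: np.ndarray) -> float:
    """Mean absolute difference between true and predicted noise."""
    eps = np.asarray(eps)
    eps_hat = np.asarray(eps_hat)
    if eps.shape != eps_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(eps - eps_hat)))


def reverse_sample(
    denoiser,
    condition: np.ndarray,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    sigma: str = "posterior",
    zero_noise: bool = False,
    x_init: np.ndarray | None = None,
    clip_denoised: bool = False,
) -> np.ndarray:
    """Ancestral sampling conditioned on a Hi-C tile (or batch of tiles).

    Starts from x_T ~ N(0, I) and iterates t = T .. 1 with

        x_{t-1} = (x_t - (1-alpha_t)/sqrt(1-abar_t) * eps_hat) / sqrt(alpha_t)
                  + sigma_t * z,   z = 0 at t = 1,

    where ``eps_hat = denoiser(x_t, condition, abar_t)`` uses the *inference*
    schedule's cumulative level as the continuous conditioning input.
    ``sigma`` picks the stochastic term's scale: "posterior" (default) uses
    the forward-posterior variance
    sigma_t^2 = (1 - abar_{t-1}) / (1 - abar_t) * beta_t, which stays small
    even on aggressive fast schedules; "beta" uses sigma_t = sqrt(beta_t)
    (equivalent at T=1000-style schedules but over-noising at beta_T near
    1); "zero" disables the term entirely.  sigma_1 = 0 always.  ``clip_denoised`` clamps the
    implied clean tile to the data range [-1, 1] at every step (the usual
    stabilizer in this model family's implementation lineage; off by
    default, which leaves the raw update rule exact).  ``zero_noise`` /
    ``x_init`` exist for closed-form verification.  Fully deterministic
    given ``rng``.
    """
    condition = np.asarray(condition, dtype=np.float64)
    x = rng.standard_normal(condition.shape) if x_init is None \
        else np.array(x_init, dtype=np.float64)
    if x.shape != condition.shape:
        raise ValueError("x_T and condition shapes differ")
    for t in range(schedule.T, 0, -1):
        a_t = schedule.alpha[t - 1]
        abar_t = schedule.alpha_bar[t - 1]
        eps_hat = np.asarray(denoiser(x, condition, abar_t), dtype=np.float64)
        if eps_hat.shape != x.shape:
            raise ValueError(
                f"denoiser output shape {eps_hat.shape} != {x.shape}"
            )
        if clip_denoised:
            sq, sq1 = np.sqrt(abar_t), np.sqrt(1.0 - abar_t)
            x0_hat = np.clip((x - sq1 * eps_hat) / sq, -1.0, 1.0)
            eps_hat = (x - sq * x0_hat) / sq1
        x = (x - (1.0 - a_t) / np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(a_t)
        if t > 1 and sigma != "zero":
            z = np.zeros_like(x) if zero_noise else rng.standard_normal(x.shape)
            if sigma == "posterior":
                abar_prev = schedule.l[t - 1]
                var = (1.0 - abar_prev) / (1.0 - abar_t) * schedule.beta[t - 1]
            else:
                var = schedule.beta[t - 1]
            x = x + np.sqrt(var) * z
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite sample at step t={t}")
    return x
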