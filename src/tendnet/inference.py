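"""Precision-weighted Bayesian integration of prediction and sensory input.

At every time step the internal model emits a Gaussian prediction
(mu_prior, sigma2_prior) for the next input, and the raw sensory signal x is
modelled as Gaussian with fixed variance sigma2_sensor.  The percept is the
Gaussian posterior of the two, with each variance scaled by a reliance
parameter:

    sigma2_post = (H_sensor * sigma2_sensor) * (H_prior * sigma2_prior)
                  / ((H_sensor * sigma2_sensor) + (H_prior * sigma2_prior))

    mu_post = sigma2_post * ( mu_prior / (H_prior * sigma2_prior)
                            + x        / (H_sensor * sigma2_sensor) )

H_prior < 1 sharpens the prior (stronger reliance on the internal model);
H_sensor > 1 blurs the input (weaker reliance on the senses).  The posterior
mean depends only on the ratio of the two scaled variances, so the settings
(H_prior=h, H_sensor=1) and (H_prior=1, H_sensor=1/h) produce identical means
while their posterior variances differ by the factor h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HParams:
    """Multiplicative reliance factors on the prior and sensory variances."""

    h_prior: float = 1.0
    h_sensor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.h_prior > 0 and self.h_sensor > 0):
            raise ValueError(f"H parameters must be positive, got {self}")


@dataclass(frozen=True)
class SensoryModel:
    """Variance of the raw input signal, in normalized trajectory units.

    The default 1e-3 is small enough that unmodified (H = 1) generation tracks
    the input closely, yet large enough that a strongly sharpened prior
    (H_prior ~ 0.05) visibly drags the percept toward the model's prediction.
    """

    sigma2_sensor: float = 1e-3

    def __post_init__(self) -> None:
        if not self.sigma2_sensor > 0:
            raise ValueError("sigma2_sensor must be positive")


@dataclass(frozen=True)
class Percept:
    """Posterior mean and variance of one integrated perceptual sample."""

    mu_post: float
    sigma2_post: float


def posterior(
    mu_prior: float,
    sigma2_prior: float,
    x: float,
    sm: SensoryModel = SensoryModel(),
    h: HParams = HParams(),
) -> Percept:
    """Fuse a Gaussian prediction with a sensory sample.

    Accepts scalars or numpy arrays (broadcast elementwise); returns a
    :class:`Percept` whose fields are floats for scalar input and arrays
    otherwise.
    """
    sigma2_prior = np.asarray(sigma2_prior, dtype=float)
    if np.any(sigma2_prior <= 0):
        raise ValueError("sigma2_prior must be positive")
    vp = h.h_prior * sigma2_prior
    vs = h.h_sensor * sm.sigma2_sensor
    if np.any(vp <= 0) or vs <= 0:
        raise ValueError("scaled variances must be positive")
    s2 = vs * vp / (vs + vp)
    mu = s2 * (np.asarray(mu_prior, dtype=float) / vp + np.asarray(x, dtype=float) / vs)
    if np.ndim(mu) == 0:
        return Percept(float(mu), float(s2))
    return Percept(mu, s2)


def posterior_mean(mu_prior, sigma2_prior, x, sm: SensoryModel, h: HParams):
    """Posterior mean only, in the ratio form (numerically symmetric in h).

    mu_post = (mu_prior * vs + x * vp) / (vs + vp) with vp = H_prior *
    sigma2_prior and vs = H_sensor * sigma2_sensor.  Written this way the mean
    is bitwise-invariant under the rescaling (h, 1) -> (1, 1/h) up to one
    floating-point rounding, which the H_sensor-sweep equivalence relies on.
    """
    vp = h.h_prior * np.asarray(sigma2_prior, dtype=float)
    vs = h.h_sensor * sm.sigma2_sensor
    return (np.asarray(mu_prior, dtype=float) * vs + np.asarray(x, dtype=float) * vp) / (vs + vp)


def equivalent_h_sensor(h_prior: float) -> float:
    """H_sensor value that reproduces the precision ratio of (H_prior, 1).

    Scaling the prior variance by h changes the prior:sensory precision ratio
    by 1/h; the same ratio is obtained with the prior untouched and the
    sensory variance scaled by 1/h.  Hence the mapping is the reciprocal:
    0.5 -> 2, 0.4 -> 2.5, 0.1 -> 10.
    """
    h_prior = float(h_prior)
    if h_prior <= 0:
        raise ValueError(f"h_prior must be positive, got {h_prior}")
    return 1.0 / h_prior
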