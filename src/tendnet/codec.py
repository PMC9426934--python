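"""Encoding of scalar stimulus lengths as one-dimensional multi-step trajectories.

The recurrent internal model consumes time series, not scalars, so every
presented or reproduced length is unrolled into a straight-line path from 0 cm
to the length itself: 20 equally spaced interior points between the start and
the end point, giving T = 22 time steps.  Before entering the network all
trajectories are mapped affinely onto [-1, 1]; with the fixed source range
[0, 14] cm every encoded trajectory starts at exactly -1 and the design maximum
of 14 cm ends at +1.

The decoder inverts the map: a reproduced length is the unsigned difference
between the denormalized start and end points of a generated trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Number of time steps per trajectory (start + 20 interior points + end).
N_TIME_STEPS = 22


@dataclass(frozen=True)
class NormalizationSpec:
    """Affine map from lengths in cm onto the network's [-1, 1] input range.

    The map sends ``source_min_cm`` to -1 and ``source_max_cm`` to +1.  A fixed
    range (default 0..14 cm, the design maximum of the length-reproduction
    task) is shared across participants and conditions so train- and test-time
    encodings are directly comparable.
    """

    source_min_cm: float = 0.0
    source_max_cm: float = 14.0

    def __post_init__(self) -> None:
        if not self.source_min_cm < self.source_max_cm:
            raise ValueError(
                f"source_min_cm ({self.source_min_cm}) must be strictly below "
                f"source_max_cm ({self.source_max_cm})"
            )

    def normalize(self, value_cm):
        """Map lengths (cm) onto [-1, 1]."""
        span = self.source_max_cm - self.source_min_cm
        return -1.0 + 2.0 * (np.asarray(value_cm, dtype=float) - self.source_min_cm) / span

    def denormalize(self, value):
        """Inverse of :meth:`normalize`."""
        span = self.source_max_cm - self.source_min_cm
        return self.source_min_cm + (np.asarray(value, dtype=float) + 1.0) * span / 2.0


def length_to_trajectory(
    length_cm: float,
    spec: NormalizationSpec = NormalizationSpec(),
    *,
    clip: bool = False,
) -> np.ndarray:
    """Encode a length as a normalized 22-step linear trajectory.

    The raw path runs linearly from 0 to ``length_cm`` with spacing
    ``length_cm / 21`` and is then normalized with ``spec``.  Lengths above
    ``spec.source_max_cm`` would leave [-1, 1]; they are rejected unless
    ``clip`` is set, in which case they are clipped to the maximum with a
    logged warning (jittered robot stimuli can exceed the design maximum by a
    fraction of a cm).

    Returns
    -------
    numpy.ndarray of shape (22,), values in [-1, 1], first element exactly -1.
    """
    length_cm = float(length_cm)
    if not np.isfinite(length_cm) or length_cm < 0.0:
        raise ValueError(f"length_cm must be finite and >= 0, got {length_cm}")
    if length_cm > spec.source_max_cm:
        if not clip:
            raise ValueError(
                f"length {length_cm} cm exceeds the normalization maximum "
                f"{spec.source_max_cm} cm; pass clip=True to clip"
            )
        logger.warning(
            "clipping stimulus of %.3f cm to normalization maximum %.3f cm",
            length_cm,
            spec.source_max_cm,
        )
        length_cm = spec.source_max_cm
    raw = np.linspace(0.0, length_cm, N_TIME_STEPS)
    return spec.normalize(raw)


def trajectory_to_length(traj: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> float:
    """Decode a normalized trajectory back to a length in cm.

    The length is the unsigned difference between the denormalized end and
    start points, which makes the decoder applicable to generated trajectories
    that are not perfect straight lines.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 1 or traj.size < 2:
        raise ValueError("trajectory must be a 1-d sequence with at least 2 points")
    if not np.all(np.isfinite(traj)):
        raise ValueError("trajectory contains non-finite values")
    start, end = spec.denormalize(traj[0]), spec.denormalize(traj[-1])
    return float(abs(end - start))


def encode_lengths(lengths_cm, spec: NormalizationSpec = NormalizationSpec(), *, clip: bool = False) -> np.ndarray:
    """Vectorized :func:`length_to_trajectory`: (n,) lengths -> (n, 22) array."""
    return np.stack([length_to_trajectory(l, spec, clip=clip) for l in np.asarray(lengths_cm, dtype=float)])
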