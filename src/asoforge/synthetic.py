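"""Synthetic efficacy oracle and dataset generator.

Real pattern-screening data — many chemically modified variants of one
sequence assayed for mRNA knockdown under shared conditions — is
proprietary or scattered across patents. This module generates records
with the same statistical structure from a known, analytically
checkable oracle, so training and rank-recovery experiments run
offline and ground truth is available for held-out patterns.

The oracle is additive-logistic: each modified position contributes a
position weight, adjacent modified pairs pay a crowding penalty, and a
logistic link squashes the sum into [0, 1]. The default position
weights encode standard gapmer pharmacology: sugar modifications near
the termini (the wings) raise affinity and efficacy, while
modifications toward the center (the RNase H-recruiting gap) are
deleterious. Replicate noise is truncated Gaussian, a proxy for
qRT-PCR measurement scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LengthMismatch
from .patterns import ModificationPattern
from .sequences import AsoSequence
from .training import EfficacyRecord

#: Default oracle shape: weight at distance d from the nearest terminus.
_WEIGHT_AT_TERMINUS = 0.5
_WEIGHT_SLOPE = 0.18
_DEFAULT_INTERACTION = 0.1
_DEFAULT_NOISE_SD = 0.05


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class OracleSpec:
    """Ground-truth efficacy model for one sequence length.

    Attributes
    ----------
    position_weights : tuple of float, length *l*
        Contribution of a modified sugar at each position (logit scale).
    interaction : float
        Penalty per adjacent pair of modified positions (crowding).
    noise_sd : float
        Standard deviation of the truncated Gaussian replicate noise.
    seed : int
        Seed for the noise stream.
    """

    position_weights: tuple[float, ...]
    interaction: float = _DEFAULT_INTERACTION
    noise_sd: float = _DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def length(self) -> int:
        return len(self.position_weights)

    @classmethod
    def default_for_length(cls, l: int, seed: int = 0, **kwargs) -> "OracleSpec":
        """Terminus-anchored default weights for an *l*-mer.

        ``w(p) = 0.5 - 0.18 * d(p)`` where ``d(p)`` is the distance of
        position ``p`` from the nearest terminus: wing-proximal
        modifications help, gap-central ones hurt.
        """
        weights = tuple(
            _WEIGHT_AT_TERMINUS - _WEIGHT_SLOPE * min(p, l - 1 - p) for p in range(l)
        )
        return cls(position_weights=weights, seed=seed, **kwargs)


def oracle_efficacy(
    pattern: ModificationPattern,
    spec: OracleSpec,
    with_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Oracle inhibition rate of a pattern, in [0, 1].

    Noiseless value: ``logistic(sum_i w_i x_i - c * sum adjacent x_i
    x_{i+1})`` with ``x`` the modified-position indicator. With
    ``with_noise``, truncated Gaussian noise (resampled until the value
    stays in [0, 1]) is added from ``rng`` or a spec-seeded stream.

    Raises
    ------
    LengthMismatch
        If the pattern length differs from the spec's.
    """
    if pattern.length != spec.length:
        raise LengthMismatch(
            f"pattern length {pattern.length} != oracle length {spec.length}"
        )
    x = np.array(pattern.modified_indicator(), dtype=float)
    w = np.array(spec.position_weights, dtype=float)
    z = float(w @ x) - spec.interaction * float((x[:-1] * x[1:]).sum())
    value = _logistic(z)
    if with_noise and spec.noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        while True:  # truncate by rejection: keep the value a valid rate
            noisy = value + rng.normal(0.0, spec.noise_sd)
            if 0.0 <= noisy <= 1.0:
                return float(noisy)
    return float(value)


def generate_dataset(
    seq: AsoSequence,
    patterns: list[ModificationPattern],
    spec: OracleSpec,
    replicates: int = 1,
) -> list[EfficacyRecord]:
    """Noisy efficacy records for every pattern, one condition per replicate.

    Each replicate batch shares a ``condition_key`` (``"replicate-<k>"``),
    emulating a plate of assays run under common conditions. Output is
    deterministic given ``spec.seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(spec.seed)
    records: list[EfficacyRecord] = []
    for rep in range(replicates):
        key = f"replicate-{rep}"
        for pat in patterns:
            y = oracle_efficacy(pat, spec, with_noise=spec.noise_sd > 0, rng=rng)
            records.append(
                EfficacyRecord(
                    sequence=seq, pattern=pat, condition_key=key, inhibition=y
                )
            )
    return records
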