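"""Minimal parity systems exhibiting causal decoupling and downward causation.

Three Markovian dynamics over ``n`` binary parts with a uniform initial
state, built around the parity feature ``par(x) = 1`` iff the number of ones
in ``x`` is even:

* ``example1`` — the next state is a uniform draw from the strings of the
  same parity with probability ``gamma``, and of opposite parity otherwise.
  Parity predicts itself but no part predicts (or is predicted by) anything:
  causal decoupling in its purest form.
* ``example2`` — the first part copies the current parity
  (``x'_1 = par(x)``) and every other part is an independent fair coin:
  minimal downward causation.
* ``example3`` — both mechanisms at once: ``x'_1 = par(x)`` always, and the
  parity of the whole next state follows the current parity with
  probability ``gamma``.

State indexing convention: bit-string to integer with part 1 as the least
significant bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .info import conditional_mutual_information
from .prob import ArgumentError, ProbabilityTable, SampleMatrix

__all__ = [
    "ParitySystemSpec",
    "TransitionModel",
    "parity",
    "parity_of_states",
    "state_names",
    "transition_matrix",
    "exact_joint",
    "joint_with_feature",
    "parity_feature_kernel",
    "sample_trajectories",
    "supervenience_check",
    "binary_entropy",
]

_VARIANTS = ("example1", "example2", "example3")


@dataclass(frozen=True)
class ParitySystemSpec:
    """Parameters of a parity system: size ``n``, parity-preservation
    probability ``gamma`` (ignored by ``example2``) and the variant name."""

    n: int
    gamma: float = 0.99
    variant: str = "example1"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ArgumentError("parity systems need n >= 2 parts")
        if self.variant not in _VARIANTS:
            raise ArgumentError(f"variant must be one of {_VARIANTS}")
        if self.variant != "example2" and not (0.0 < self.gamma < 1.0):
            raise ArgumentError("gamma must lie strictly between 0 and 1")


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic one-step kernel over integer-coded bit-string states,
    with the uniform initial distribution."""

    kernel: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        rows = self.kernel.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-12:
            raise ArgumentError("kernel rows must sum to 1")


def parity(bits) -> int:
    """1 if the number of ones is even, else 0."""
    bits = np.asarray(bits)
    if bits.size == 0:
        raise ArgumentError("parity of an empty bit-string")
    return int(bits.sum() % 2 == 0)


def parity_of_states(states: np.ndarray, n: int) -> np.ndarray:
    """Vectorised parity of integer-coded states (1 = even number of ones)."""
    states = np.asarray(states)
    ones = np.zeros(states.shape, dtype=np.int64)
    for j in range(n):
        ones += (states >> j) & 1
    return (ones % 2 == 0).astype(np.int64)


def binary_entropy(g: float) -> float:
    """H_b(g) in bits, with the 0 log 0 = 0 convention."""
    if g <= 0.0 or g >= 1.0:
        return 0.0
    return float(-g * np.log2(g) - (1 - g) * np.log2(1 - g))


def transition_matrix(spec: ParitySystemSpec) -> TransitionModel:
    """One-step transition kernel of the requested parity system."""
    n, g = spec.n, spec.gamma
    m = 1 << n
    states = np.arange(m)
    par = parity_of_states(states, n)  # 1 = even
    same = par[:, None] == par[None, :]
    if spec.variant == "example1":
        kernel = np.where(same, g / (m / 2), (1 - g) / (m / 2))
    elif spec.variant == "example2":
        first_bit = states & 1
        ok = first_bit[None, :] == par[:, None]
        kernel = np.where(ok, 1.0 / (m / 2), 0.0)
    else:  # example3
        first_bit = states & 1
        ok = first_bit[None, :] == par[:, None]
        kernel = np.where(
            ok, np.where(same, g / (m / 4), (1 - g) / (m / 4)), 0.0
        )
    initial = np.full(m, 1.0 / m)
    return TransitionModel(kernel=kernel, initial=initial)


def _bit_names(n: int, suffix: str) -> tuple[str, ...]:
    return tuple(f"x{i + 1}{suffix}" for i in range(n))


def state_names(n: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Labels for the system parts at times t and t' (``x1 .. xn`` and
    ``x1' .. xn'``)."""
    return _bit_names(n, ""), _bit_names(n, "'")


def exact_joint(spec: ParitySystemSpec) -> ProbabilityTable:
    """Exact joint table p(X_t, X_{t+1}) = 2^{-n} K(x -> x').

    Variables are named ``x1..xn`` (time t) and ``x1'..xn'`` (time t+1);
    part 1 is the least significant bit of the state index, so a Fortran-order
    reshape of the (state, state') matrix yields per-bit axes directly.
    """
    if spec.n > 12:
        raise MemoryError(
            "exact joint table would need 4^n cells; use sample_trajectories"
        )
    model = transition_matrix(spec)
    joint = model.initial[:, None] * model.kernel
    masses = joint.reshape((2,) * (2 * spec.n), order="F")
    past, future = state_names(spec.n)
    return ProbabilityTable(past + future, masses, check=False)


def parity_feature_kernel(n: int, noise: float = 0.0) -> np.ndarray:
    """p(V=v | state) for the (possibly noisy) parity feature, shape (2^n, 2)."""
    if not (0.0 <= noise < 0.5):
        raise ArgumentError("feature noise must lie in [0, 0.5)")
    par = parity_of_states(np.arange(1 << n), n)
    pv1 = np.where(par == 1, 1.0 - noise, noise)
    return np.stack([1.0 - pv1, pv1], axis=1)


def joint_with_feature(
    spec: ParitySystemSpec,
    feature_kernel: np.ndarray | None = None,
    feature_name: str = "v",
) -> ProbabilityTable:
    """Joint table over (V_t, X_t, V_{t'}, X_{t'}) with the feature applied
    independently at both times.

    ``feature_kernel`` is a (2^n, c) conditional p(V|state); by default the
    deterministic parity feature.  Variable order: ``v, x1..xn, v', x1'..xn'``.
    """
    n = spec.n
    if feature_kernel is None:
        feature_kernel = parity_feature_kernel(n)
    model = transition_matrix(spec)
    joint_states = model.initial[:, None] * model.kernel  # (s, s')
    # p(v, s, v', s') = p(s, s') p(v|s) p(v'|s')
    c = feature_kernel.shape[1]
    j4 = (
        joint_states[None, :, None, :]
        * feature_kernel.T[:, :, None, None]
        * feature_kernel.T[None, None, :, :]
    )  # axes (v, s, v', s')
    past, future = state_names(n)
    bits = j4.reshape((c,) + (2,) * n + (c,) + (2,) * n, order="F")
    # Fortran reshape of axes (v, s, v', s') unpacks s and s' LSB-first while
    # keeping v and v' scalar axes in place.
    names = (feature_name,) + past + (feature_name + "'",) + future
    return ProbabilityTable(names, bits, check=False)


def sample_trajectories(
    spec: ParitySystemSpec, trials: int, steps: int, seed: int
) -> SampleMatrix:
    """Sample ``trials`` independent trajectories of ``steps + 1`` time points.

    Returns a discrete :class:`SampleMatrix` of shape
    ``(trials, steps + 1, n)`` holding the per-part bits.
    """
    if trials < 1 or steps < 1:
        raise ArgumentError("need trials >= 1 and steps >= 1")
    rng = np.random.default_rng(seed)
    model = transition_matrix(spec)
    m = model.kernel.shape[0]
    cum = np.cumsum(model.kernel, axis=1)
    states = np.empty((trials, steps + 1), dtype=np.int64)
    states[:, 0] = rng.integers(0, m, size=trials)
    for t in range(steps):
        u = rng.random(trials)
        states[:, t + 1] = (
            cum[states[:, t]] < u[:, None]
        ).sum(axis=1)
    bits = ((states[:, :, None] >> np.arange(spec.n)) & 1).astype(np.int64)
    return SampleMatrix(bits, kind="discrete", cardinalities=(2,) * spec.n)


def supervenience_check(
    joint: ProbabilityTable,
    feature_label: str,
    system_labels_t,
    system_labels_tprime,
) -> float:
    """Deviation from supervenience, I(V_t ; X_{t'} | X_t) in bits.

    Zero (within exact-table tolerance) iff the feature is supervenient on
    the time-t state, i.e. V_t - X_t - X_{t'} is a Markov chain.
    """
    return conditional_mutual_information(
        joint, feature_label, tuple(system_labels_tprime), tuple(system_labels_t)
    )
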