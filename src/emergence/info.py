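"""Entropy and mutual information, exact and estimated, in bits.

Exact quantities operate on :class:`~emergence.prob.ProbabilityTable`
objects; estimators operate on :class:`~emergence.prob.SampleMatrix` data.
Three estimators are provided:

* plug-in — empirical frequencies;
* Bayesian — Dirichlet-smoothed frequencies (``prior_strength`` pseudo-counts
  added to every cell of the joint alphabet), a simple shrinkage estimator
  that tames the positive plug-in bias of mutual information on sparse
  contingency tables;
* Gaussian — the covariance closed form
  ``I = 0.5 * log2(det S_A * det S_B / det S_AB)`` for continuous data.

All logarithms are base 2 and ``0 log 0 = 0`` by continuity.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy

from .prob import (
    ArgumentError,
    NumericalRankError,
    ProbabilityTable,
    SampleMatrix,
)

__all__ = [
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "plug_in_table",
    "bayesian_mi",
    "gaussian_mi",
    "encode_rows",
    "mi_from_counts",
    "discrete_mi_samples",
    "gaussian_mi_samples",
]

_LN2 = np.log(2.0)


def _entropy_from_masses(masses: np.ndarray) -> float:
    return float(-xlogy(masses, masses).sum() / _LN2)


def entropy(p: ProbabilityTable, subset: Iterable[str] | str | None = None) -> float:
    """Shannon entropy H (bits) of a subset of variables (all by default)."""
    if subset is None:
        subset = p.names
    return _entropy_from_masses(p.marginal(subset).masses)


def _check_disjoint(*groups: tuple[str, ...]) -> None:
    seen: set[str] = set()
    for g in groups:
        for label in g:
            if label in seen:
                raise ArgumentError(f"variable groups overlap on {label!r}")
            seen.add(label)


def _as_group(g: Iterable[str] | str) -> tuple[str, ...]:
    return (g,) if isinstance(g, str) else tuple(g)


def mutual_information(
    p: ProbabilityTable, group_a: Iterable[str] | str, group_b: Iterable[str] | str
) -> float:
    """I(A;B) = H(A) + H(B) - H(A,B) in bits; groups must be disjoint."""
    a, b = _as_group(group_a), _as_group(group_b)
    if not a or not b:
        raise ArgumentError("both groups must be non-empty")
    _check_disjoint(a, b)
    return entropy(p, a) + entropy(p, b) - entropy(p, a + b)


def conditional_mutual_information(
    p: ProbabilityTable,
    group_a: Iterable[str] | str,
    group_b: Iterable[str] | str,
    group_c: Iterable[str] | str,
) -> float:
    """I(A;B|C) = H(A,C) + H(B,C) - H(A,B,C) - H(C) in bits."""
    a, b, c = _as_group(group_a), _as_group(group_b), _as_group(group_c)
    if not a or not b or not c:
        raise ArgumentError("all three groups must be non-empty")
    _check_disjoint(a, b, c)
    return (
        entropy(p, a + c)
        + entropy(p, b + c)
        - entropy(p, a + b + c)
        - entropy(p, c)
    )


# ----------------------------------------------------------------------
# Estimators on samples
# ----------------------------------------------------------------------

def _pooled(samples: SampleMatrix, columns: Sequence[int]) -> np.ndarray:
    vals = samples.values.reshape(-1, samples.n_vars)
    return vals[:, list(columns)]


def plug_in_table(
    samples: SampleMatrix, subset: Sequence[int] | None = None, names: Sequence[str] | None = None
) -> ProbabilityTable:
    """Empirical joint probability table of the given columns (all by default)."""
    if samples.kind != "discrete":
        raise TypeError("plug_in_table requires discrete samples")
    cols = tuple(range(samples.n_vars)) if subset is None else tuple(subset)
    data = _pooled(samples, cols)
    cards = tuple(samples.cardinalities[j] for j in cols)
    counts = np.zeros(cards, dtype=float)
    np.add.at(counts, tuple(data.T), 1.0)
    if names is None:
        names = tuple(f"x{j}" for j in cols)
    return ProbabilityTable(names, counts / data.shape[0], check=False)


def encode_rows(rows: np.ndarray) -> tuple[np.ndarray, int]:
    """Map distinct rows of a 2-D integer array to codes ``0..K-1``.

    The alphabet is the *observed support*: only patterns that actually occur
    get a code.  Returns ``(codes, K)``.
    """
    rows = np.ascontiguousarray(rows)
    _, codes = np.unique(rows, axis=0, return_inverse=True)
    return codes.ravel(), int(codes.max(initial=0)) + 1


def mi_from_counts(counts: np.ndarray, prior: float = 0.0) -> float:
    """Mutual information (bits) of a 2-D contingency table.

    ``prior`` pseudo-counts are added to every cell before normalising
    (Dirichlet smoothing); ``prior=0`` gives the plug-in estimate.
    """
    if prior < 0:
        raise ArgumentError("prior must be non-negative")
    joint = np.asarray(counts, dtype=float) + prior
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    h = _entropy_from_masses
    return h(pa) + h(pb) - h(joint)


def _joint_counts(a_codes: np.ndarray, ka: int, b_codes: np.ndarray, kb: int) -> np.ndarray:
    counts = np.zeros((ka, kb), dtype=float)
    np.add.at(counts, (a_codes, b_codes), 1.0)
    return counts


def discrete_mi_samples(
    a: np.ndarray, b: np.ndarray, prior: float = 0.0
) -> float:
    """MI (bits) between two blocks of discrete sample columns.

    ``a`` and ``b`` are 2-D arrays with one row per observation.  Each block
    is encoded over its observed support, so the Dirichlet prior mass scales
    with the number of patterns actually seen rather than the full product
    alphabet.
    """
    if a.shape[0] != b.shape[0]:
        raise ArgumentError("sample blocks have different lengths")
    ca, ka = encode_rows(a)
    cb, kb = encode_rows(b)
    return mi_from_counts(_joint_counts(ca, ka, cb, kb), prior)


def bayesian_mi(
    samples: SampleMatrix,
    group_a: Sequence[int],
    group_b: Sequence[int],
    prior_strength: float = 1.0,
) -> float:
    """Dirichlet-smoothed MI (bits) between two column groups, pooled over time.

    ``prior_strength`` pseudo-counts per joint cell; must be positive (use
    the plug-in path for an unsmoothed estimate).
    """
    if samples.kind != "discrete":
        raise TypeError("bayesian_mi requires discrete samples")
    if prior_strength <= 0:
        raise ArgumentError("prior_strength must be positive")
    if set(group_a) & set(group_b):
        raise ArgumentError("variable groups overlap")
    return discrete_mi_samples(
        _pooled(samples, group_a), _pooled(samples, group_b), prior=prior_strength
    )


def plug_in_mi(
    samples: SampleMatrix, group_a: Sequence[int], group_b: Sequence[int]
) -> float:
    """Plug-in MI (bits) between two column groups, pooled over time."""
    if samples.kind != "discrete":
        raise TypeError("plug_in_mi requires discrete samples")
    if set(group_a) & set(group_b):
        raise ArgumentError("variable groups overlap")
    return discrete_mi_samples(_pooled(samples, group_a), _pooled(samples, group_b))


def _logdet_cov(x: np.ndarray, label: str) -> float:
    cov = np.atleast_2d(np.cov(x, rowvar=False))
    sign, logdet = np.linalg.slogdet(cov)
    eigvals = np.linalg.eigvalsh(cov)
    scale = max(float(eigvals[-1]), 1.0)
    if sign <= 0 or float(eigvals[0]) < 1e-12 * scale:
        raise NumericalRankError(f"sample covariance of {label} is singular")
    return logdet


def gaussian_mi_samples(a: np.ndarray, b: np.ndarray) -> float:
    """Gaussian MI (bits) between two blocks of continuous sample columns."""
    if a.shape[0] != b.shape[0]:
        raise ArgumentError("sample blocks have different lengths")
    ld_a = _logdet_cov(a, "group A")
    ld_b = _logdet_cov(b, "group B")
    ld_ab = _logdet_cov(np.hstack([a, b]), "joint group")
    return 0.5 * (ld_a + ld_b - ld_ab) / _LN2


def gaussian_mi(
    samples: SampleMatrix, group_a: Sequence[int], group_b: Sequence[int]
) -> float:
    """Gaussian-copula-free covariance MI for continuous sample columns."""
    if samples.kind != "continuous":
        raise TypeError("gaussian_mi requires continuous samples")
    if set(group_a) & set(group_b):
        raise ArgumentError("variable groups overlap")
    return gaussian_mi_samples(_pooled(samples, group_a), _pooled(samples, group_b))
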