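"""Core containers: joint probability tables and sample matrices.

A :class:`ProbabilityTable` is an explicit joint probability mass function
over a tuple of labelled discrete variables; all exact information-theoretic
computations in this package reduce to marginalisations of such tables.
A :class:`SampleMatrix` holds finite data — trials x time x variables — and
carries the conventions (discrete vs continuous, time-lag pairing) that the
estimators need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProbabilityTable",
    "SampleMatrix",
    "LabelError",
    "ArgumentError",
    "NumericalRankError",
]

_MASS_TOL = 1e-12


class LabelError(KeyError):
    """An operation referenced a variable label that the table does not have."""


class ArgumentError(ValueError):
    """Invalid argument combination (overlapping groups, bad order k, ...)."""


class NumericalRankError(ValueError):
    """A sample covariance matrix is numerically singular."""


class ProbabilityTable:
    """Joint probability mass function over labelled discrete variables.

    Parameters
    ----------
    names:
        Ordered variable labels, one per axis of ``masses``.
    masses:
        Array of non-negative reals whose shape gives the per-variable
        cardinalities.  Must sum to 1 within ``1e-12`` unless
        ``normalise=True``.
    """

    __slots__ = ("names", "masses")

    def __init__(
        self,
        names: Sequence[str],
        masses: np.ndarray,
        *,
        normalise: bool = False,
        check: bool = True,
    ) -> None:
        masses = np.asarray(masses, dtype=float)
        names = tuple(str(n) for n in names)
        if masses.ndim != len(names):
            raise ArgumentError(
                f"{len(names)} labels given for a table of rank {masses.ndim}"
            )
        if len(set(names)) != len(names):
            raise ArgumentError(f"duplicate variable labels in {names}")
        if normalise:
            total = masses.sum()
            if total <= 0:
                raise ArgumentError("cannot normalise a table with zero total mass")
            masses = masses / total
        if check:
            if masses.min(initial=0.0) < -_MASS_TOL:
                raise ArgumentError("negative probability mass")
            if abs(masses.sum() - 1.0) > 1e-9:
                raise ArgumentError(
                    f"masses sum to {masses.sum():.12g}, expected 1"
                )
        self.names = names
        self.masses = np.clip(masses, 0.0, None)

    # ------------------------------------------------------------------
    @property
    def cardinalities(self) -> tuple[int, ...]:
        return self.masses.shape

    def axes_of(self, labels: Iterable[str]) -> tuple[int, ...]:
        labels = (labels,) if isinstance(labels, str) else tuple(labels)
        try:
            return tuple(self.names.index(l) for l in labels)
        except ValueError as exc:
            missing = [l for l in labels if l not in self.names]
            raise LabelError(f"unknown variable label(s): {missing}") from exc

    def marginal(self, labels: Iterable[str]) -> "ProbabilityTable":
        """Marginalise onto ``labels`` (result axes follow the given order)."""
        labels = (labels,) if isinstance(labels, str) else tuple(labels)
        if not labels:
            raise ArgumentError("marginal over an empty set of variables")
        keep = self.axes_of(labels)
        drop = tuple(i for i in range(len(self.names)) if i not in keep)
        reduced = self.masses.sum(axis=drop) if drop else self.masses
        kept_in_order = [n for n in self.names if n in labels]
        perm = tuple(kept_in_order.index(l) for l in labels)
        return ProbabilityTable(labels, np.transpose(reduced, perm), check=False)

    def conditioned_shape_ok(self) -> bool:  # pragma: no cover - debug aid
        return abs(self.masses.sum() - 1.0) < 1e-9

    def __repr__(self) -> str:
        dims = "x".join(str(c) for c in self.cardinalities)
        return f"ProbabilityTable({', '.join(self.names)}; {dims})"


def _as_3d(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim == 2:  # single trial: time x variables
        values = values[None, :, :]
    if values.ndim != 3:
        raise ArgumentError("sample values must be (time x vars) or (trials x time x vars)")
    return values


@dataclass
class SampleMatrix:
    """Finite sample of a multivariate process.

    ``values`` has shape ``(trials, time, n_vars)``; a 2-D array is accepted
    and treated as a single trial.  ``kind`` is ``"discrete"`` (integer codes)
    or ``"continuous"``.  ``cardinalities`` (discrete only) states the
    alphabet size per variable; if omitted it is inferred as ``max+1``.
    ``parts`` optionally groups columns into the system's "parts" (e.g. one
    boid = three columns); by default every column is its own part.
    """

    values: np.ndarray
    kind: str = "discrete"
    cardinalities: tuple[int, ...] | None = None
    parts: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        self.values = _as_3d(self.values)
        if self.kind not in ("discrete", "continuous"):
            raise ArgumentError(f"unknown sample kind {self.kind!r}")
        if self.kind == "discrete":
            vals = self.values
            if not np.issubdtype(vals.dtype, np.integer):
                if np.any(vals != np.round(vals)):
                    raise TypeError("discrete samples must hold integer codes")
                self.values = vals = vals.astype(np.int64)
            if vals.size and vals.min() < 0:
                raise ArgumentError("discrete codes must be non-negative")
            if self.cardinalities is None:
                top = vals.max(axis=(0, 1), initial=0)
                self.cardinalities = tuple(int(t) + 1 for t in top)
            else:
                self.cardinalities = tuple(int(c) for c in self.cardinalities)
                top = vals.max(axis=(0, 1), initial=0)
                if any(t >= c for t, c in zip(top, self.cardinalities)):
                    raise ArgumentError("sample codes exceed stated cardinality")
        if self.parts is None:
            self.parts = tuple((j,) for j in range(self.n_vars))
        else:
            self.parts = tuple(tuple(int(j) for j in p) for p in self.parts)
            flat = [j for p in self.parts for j in p]
            if any(j < 0 or j >= self.n_vars for j in flat):
                raise ArgumentError("part column index out of range")

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def n_vars(self) -> int:
        return self.values.shape[2]

    def lagged(self, tau: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (past, future) 2-D arrays of samples paired at lag ``tau``.

        Pairs are formed within trials only: row ``t`` of a trial is paired
        with row ``t + tau`` of the same trial, then all trials are stacked.
        """
        tau = int(tau)
        if tau < 1 or tau >= self.n_time:
            raise ArgumentError(f"lag tau={tau} must satisfy 1 <= tau < time length")
        past = self.values[:, :-tau, :].reshape(-1, self.n_vars)
        future = self.values[:, tau:, :].reshape(-1, self.n_vars)
        return past, future
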