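"""Exact partial and integrated information decomposition (minimum-MI flavour).

The redundancy lattice is indexed by *antichains*: collections of source
subsets none of which contains another.  The partial ordering is the usual
one — ``alpha <= beta`` iff every member of ``beta`` contains some member of
``alpha`` — with the fully-redundant collection of all singletons at the
bottom and the full-set collection at the top.  Atoms are recovered from the
cumulative redundancy function by Moebius inversion over this order.

The redundancy function is pluggable; the default is minimum mutual
information (MMI): the cumulative redundancy of a collection is the smallest
MI that any one of its members carries about the target, and for the
two-time-series decomposition the double redundancy of a collection pair is
the smallest MI across member pairs.  MMI admits closed forms for the
coarse-grained synergy indices, which this module cross-checks against the
lattice sums.  Moebius inversion under MMI can produce negative atoms; they
are reported as-is (clipping would break the conservation identity) and
flagged.

Lattice computations are capped at three sources (PID) and two variables per
time point (the two-series decomposition); larger systems should use the
whole-minus-sum criteria in :mod:`emergence.criteria`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Callable, Sequence

from .info import mutual_information
from .prob import ArgumentError, ProbabilityTable

__all__ = [
    "Antichain",
    "AtomTable",
    "PhiIDAtomTable",
    "antichain_lattice",
    "antichain_below",
    "format_antichain",
    "pid_mmi",
    "syn_k",
    "syn_k_lattice",
    "un_mmi",
    "un_feature_mmi",
    "phiid_mmi",
    "d_k",
    "g_k",
]

Antichain = frozenset  # of frozensets of 1-based source indices

_MAX_PID_SOURCES = 3
_MAX_PHIID_VARS = 2


def format_antichain(alpha: Antichain) -> str:
    """Human-readable form, e.g. ``{1}{2}`` or ``{12}``."""
    members = sorted(alpha, key=lambda m: (len(m), sorted(m)))
    return "".join("{" + "".join(str(i) for i in sorted(m)) + "}" for m in members)


def _nonempty_subsets(n: int) -> list[frozenset]:
    items = range(1, n + 1)
    return [
        frozenset(c)
        for r in range(1, n + 1)
        for c in combinations(items, r)
    ]


def _is_antichain(collection: Sequence[frozenset]) -> bool:
    for a in collection:
        for b in collection:
            if a is not b and a <= b:
                return False
    return True


def antichain_below(alpha: Antichain, beta: Antichain) -> bool:
    """True iff ``alpha <= beta``: every member of beta contains a member of alpha."""
    return all(any(a <= b for a in alpha) for b in beta)


def _sort_key(alpha: Antichain):
    return (
        sorted((len(m), sorted(m)) for m in alpha),
        -len(alpha),
    )


def antichain_lattice(n: int, *, _cap: int = _MAX_PID_SOURCES) -> list[Antichain]:
    """All antichains of non-empty subsets of ``{1..n}`` in a topological
    order of the redundancy lattice (bottom first).

    Growth is super-exponential in ``n``; generation is refused above the
    module cap (3 sources).
    """
    if n < 1:
        raise ArgumentError("need at least one source")
    if n > _cap:
        raise MemoryError(
            f"antichain lattice for n={n} sources refused (cap {_cap}); "
            "use the whole-minus-sum criteria for larger systems"
        )
    subsets = _nonempty_subsets(n)
    out: list[Antichain] = []
    for r in range(1, len(subsets) + 1):
        for combo in combinations(subsets, r):
            if _is_antichain(combo):
                out.append(frozenset(combo))
    # topological order: alpha before beta whenever alpha < beta
    counts = {a: sum(antichain_below(b, a) for b in out) for a in out}
    out.sort(key=lambda a: (counts[a], _sort_key(a)))
    return out


@dataclass
class AtomTable:
    """PID atoms indexed by antichains; their sum equals the total MI."""

    atoms: dict[Antichain, float]
    n_sources: int
    total: float
    redundancy_name: str = "mmi"

    def __getitem__(self, alpha) -> float:
        return self.atoms[_coerce_antichain(alpha)]

    @property
    def has_negative(self) -> bool:
        return any(v < -1e-12 for v in self.atoms.values())

    def check_conservation(self, tol: float = 1e-9) -> bool:
        return abs(sum(self.atoms.values()) - self.total) <= tol


@dataclass
class PhiIDAtomTable:
    """Two-time-series decomposition atoms indexed by antichain pairs."""

    atoms: dict[tuple[Antichain, Antichain], float]
    total: float
    redundancy_name: str = "mmi"

    def __getitem__(self, key) -> float:
        a, b = key
        return self.atoms[(_coerce_antichain(a), _coerce_antichain(b))]

    @property
    def has_negative(self) -> bool:
        return any(v < -1e-12 for v in self.atoms.values())

    def check_conservation(self, tol: float = 1e-9) -> bool:
        return abs(sum(self.atoms.values()) - self.total) <= tol


def _coerce_antichain(alpha) -> Antichain:
    if isinstance(alpha, frozenset) and all(isinstance(m, frozenset) for m in alpha):
        return alpha
    return frozenset(frozenset(m) for m in alpha)


def _mobius(order: list, cumulative: dict) -> dict:
    atoms: dict = {}
    below = {
        a: [b for b in order if b != a and _pair_below(b, a)] for a in order
    }
    for a in order:
        atoms[a] = cumulative[a] - sum(atoms[b] for b in below[a])
    return atoms


def _pair_below(x, y) -> bool:
    if isinstance(x, tuple):
        return antichain_below(x[0], y[0]) and antichain_below(x[1], y[1])
    return antichain_below(x, y)


def _mmi_redundancy(p: ProbabilityTable, source_groups, target_labels) -> Callable:
    cache: dict[frozenset, float] = {}

    def single(subset: frozenset) -> float:
        if subset not in cache:
            labels = tuple(
                chain.from_iterable(source_groups[i - 1] for i in sorted(subset))
            )
            cache[subset] = mutual_information(p, labels, target_labels)
        return cache[subset]

    def redundancy(alpha: Antichain) -> float:
        return min(single(m) for m in alpha)

    redundancy.single = single  # type: ignore[attr-defined]
    return redundancy


def _as_groups(sources) -> list[tuple[str, ...]]:
    return [
        (g,) if isinstance(g, str) else tuple(g) for g in sources
    ]


def pid_mmi(
    p: ProbabilityTable,
    sources: Sequence,
    target,
    redundancy: Callable[[Antichain], float] | None = None,
) -> AtomTable:
    """Partial information decomposition of I(sources ; target).

    ``sources`` is a sequence of labels or label tuples (each entry one
    source); ``target`` is a label or tuple.  The default redundancy is
    minimum mutual information; an alternative cumulative redundancy function
    (antichain -> bits) may be supplied.
    """
    groups = _as_groups(sources)
    n = len(groups)
    if n > _MAX_PID_SOURCES:
        raise MemoryError(f"PID lattice capped at {_MAX_PID_SOURCES} sources")
    target_labels = (target,) if isinstance(target, str) else tuple(target)
    red = redundancy or _mmi_redundancy(p, groups, target_labels)
    order = antichain_lattice(n)
    cumulative = {a: red(a) for a in order}
    atoms = _mobius(order, cumulative)
    all_labels = tuple(chain.from_iterable(groups))
    total = mutual_information(p, all_labels, target_labels)
    return AtomTable(atoms=atoms, n_sources=n, total=total)


def syn_k(
    p: ProbabilityTable, sources: Sequence, target, k: int
) -> float:
    """k-th order synergy under MMI, Syn(k) = I(X;Y) - max_{|a|=k} I(X^a;Y).

    The closed form holds for the MMI redundancy because the antichains with
    a member of size <= k form a down-set of the lattice whose atom total
    telescopes to the largest size-k source MI; :func:`syn_k_lattice`
    recomputes the same quantity by Moebius inversion for cross-checking.
    """
    groups = _as_groups(sources)
    n = len(groups)
    if not (1 <= k < n):
        raise ArgumentError(f"order k={k} must satisfy 1 <= k < n={n}")
    target_labels = (target,) if isinstance(target, str) else tuple(target)
    all_labels = tuple(chain.from_iterable(groups))
    total = mutual_information(p, all_labels, target_labels)
    best = max(
        mutual_information(
            p, tuple(chain.from_iterable(groups[i] for i in combo)), target_labels
        )
        for combo in combinations(range(n), k)
    )
    return total - best


def syn_k_lattice(
    p: ProbabilityTable, sources: Sequence, target, k: int
) -> float:
    """Lattice-summed Syn(k): sum of atoms whose members all exceed size k."""
    groups = _as_groups(sources)
    n = len(groups)
    if not (1 <= k < n):
        raise ArgumentError(f"order k={k} must satisfy 1 <= k < n={n}")
    table = pid_mmi(p, sources, target)
    return sum(
        v for a, v in table.atoms.items() if min(len(m) for m in a) > k
    )


def un_mmi(
    p: ProbabilityTable,
    feature,
    sources: Sequence,
    target,
    k: int,
) -> float:
    """MMI instantiation of the unique information of a feature beyond
    size-k groups of parts: ``I(V;Y) - max_{|a|=k} I(X^a;Y)`` in bits.

    A positive value certifies causal emergence of order k of the feature.
    Because MI is monotone in source sets, taking the maximum over subsets of
    size exactly k is equivalent to size at most k.
    """
    groups = _as_groups(sources)
    n = len(groups)
    if not (1 <= k < n + 1):
        raise ArgumentError(f"order k={k} must satisfy 1 <= k <= n={n}")
    if k > n:
        raise ArgumentError("k cannot exceed the number of parts")
    feature_labels = (feature,) if isinstance(feature, str) else tuple(feature)
    target_labels = (target,) if isinstance(target, str) else tuple(target)
    i_v = mutual_information(p, feature_labels, target_labels)
    best = max(
        mutual_information(
            p, tuple(chain.from_iterable(groups[i] for i in combo)), target_labels
        )
        for combo in combinations(range(n), k)
    )
    return i_v - best


def un_feature_mmi(
    p: ProbabilityTable,
    feature,
    sources: Sequence,
    feature_future,
    k: int,
) -> float:
    """Unique information of a feature about its own future beyond size-k
    part groups: ``I(V_t;V_t') - max_{|a|=k} I(X_t^a;V_t')`` in bits.

    This is the instantiation through which the whole-minus-sum criterion
    Psi lower-bounds unique information under the MMI redundancy: the
    subtracted sum in Psi dominates the subtracted maximum here, so
    ``Psi <= un_feature_mmi <= syn_k`` holds term by term.  The X_t'-target
    form (:func:`un_mmi`) does not enjoy the first inequality, because the
    minimum-MI redundancy equates a part's self-prediction with the
    feature's content regardless of what the information is about.
    """
    groups = _as_groups(sources)
    n = len(groups)
    if not (1 <= k <= n):
        raise ArgumentError(f"order k={k} must satisfy 1 <= k <= n={n}")
    v_t = (feature,) if isinstance(feature, str) else tuple(feature)
    v_tp = (
        (feature_future,)
        if isinstance(feature_future, str)
        else tuple(feature_future)
    )
    i_vv = mutual_information(p, v_t, v_tp)
    best = max(
        mutual_information(
            p, tuple(chain.from_iterable(groups[i] for i in combo)), v_tp
        )
        for combo in combinations(range(n), k)
    )
    return i_vv - best


def phiid_mmi(
    p: ProbabilityTable,
    past: Sequence,
    future: Sequence,
    redundancy: Callable[[Antichain, Antichain], float] | None = None,
) -> PhiIDAtomTable:
    """Integrated information decomposition of I(X_t ; X_{t'}) for two
    variables per time point.

    Atoms live on the product of two antichain lattices; the default double
    redundancy of a collection pair is the minimum MI over member pairs.
    """
    past_groups = _as_groups(past)
    future_groups = _as_groups(future)
    if len(past_groups) != _MAX_PHIID_VARS or len(future_groups) != _MAX_PHIID_VARS:
        raise ArgumentError(
            "the two-series decomposition is implemented for exactly 2 "
            "variables per time point"
        )
    lattice = antichain_lattice(2)
    cache: dict[tuple[frozenset, frozenset], float] = {}

    def pair_mi(a: frozenset, b: frozenset) -> float:
        key = (a, b)
        if key not in cache:
            la = tuple(chain.from_iterable(past_groups[i - 1] for i in sorted(a)))
            lb = tuple(chain.from_iterable(future_groups[i - 1] for i in sorted(b)))
            cache[key] = mutual_information(p, la, lb)
        return cache[key]

    if redundancy is None:
        def redundancy(alpha: Antichain, beta: Antichain) -> float:
            return min(pair_mi(a, b) for a in alpha for b in beta)

    order = [(a, b) for a in lattice for b in lattice]
    counts = {ab: sum(_pair_below(xy, ab) for xy in order) for ab in order}
    order.sort(key=lambda ab: (counts[ab], _sort_key(ab[0]), _sort_key(ab[1])))
    cumulative = {ab: redundancy(*ab) for ab in order}
    atoms = _mobius(order, cumulative)
    all_past = tuple(chain.from_iterable(past_groups))
    all_future = tuple(chain.from_iterable(future_groups))
    total = mutual_information(p, all_past, all_future)
    return PhiIDAtomTable(atoms=atoms, total=total)


_TOP2 = frozenset({frozenset({1, 2})})


def d_k(atoms: PhiIDAtomTable, k: int = 1) -> float:
    """Downward-causation index D(k): synergistic past information with
    effects on groups of at most k future variables.  Implemented for the
    two-variable decomposition with k = 1."""
    if k != 1:
        raise ArgumentError("d_k is implemented for k = 1 (two variables)")
    return sum(
        v
        for (a, b), v in atoms.atoms.items()
        if a == _TOP2 and b != _TOP2
    )


def g_k(atoms: PhiIDAtomTable, k: int = 1) -> float:
    """Causal-decoupling index G(k): synergy-to-synergy information — the
    collective 'statistical ghost' channel.  k = 1, two variables."""
    if k != 1:
        raise ArgumentError("g_k is implemented for k = 1 (two variables)")
    return atoms.atoms[(_TOP2, _TOP2)]
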