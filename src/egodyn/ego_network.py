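"""Egocentric networks of alters: representation, generation, metrics, I/O.

The ego itself is implicit: it is connected to every alter and never appears
in the alter roster.  Only the ties *among* alters are represented, since
those are what drive degree-weighted influence and the inter-group metrics.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Collection, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "CultureLabel",
    "RelationalDomain",
    "Alter",
    "EgoNetwork",
    "NetworkValidationError",
    "UNDEFINED_WEIGHT",
    "generate_network",
    "same_culture_degree",
    "group_size",
    "interclass_tie_weight",
    "read_network",
    "write_network",
    "write_edge_list",
]


class CultureLabel(Enum):
    """One of the two cultures present in every network."""

    CULTURE_A = "A"
    CULTURE_B = "B"

    @property
    def display_alias(self) -> str:
        return _CULTURE_ALIASES[self]

    @property
    def other(self) -> "CultureLabel":
        return (
            CultureLabel.CULTURE_B
            if self is CultureLabel.CULTURE_A
            else CultureLabel.CULTURE_A
        )


_CULTURE_ALIASES = {
    CultureLabel.CULTURE_A: "Latino",
    CultureLabel.CULTURE_B: "European-American",
}


class RelationalDomain(Enum):
    """Relational domain of an alter; used only by composition/structure
    metrics, never by the identification dynamics."""

    FRIEND = "friend"
    COLLEAGUE = "colleague"
    UNSPECIFIED = "unspecified"


class NetworkValidationError(ValueError):
    """A network (or network file) violates a structural invariant."""


@dataclass(frozen=True)
class Alter:
    id: int
    culture: CultureLabel
    domain: RelationalDomain = RelationalDomain.UNSPECIFIED


#: Sentinel for an inter-class tie weight whose denominator |F|*|C| is zero.
#: Distinguishes "a group has no members" from "members but no ties" (0.0).
UNDEFINED_WEIGHT = math.nan


@dataclass(frozen=True)
class EgoNetwork:
    """A fixed roster of alters plus the undirected ties among them.

    Ties are stored as ``(i, j)`` pairs with ``i < j``; symmetry is therefore
    structural.  The network is immutable: composition and structure are held
    constant over a simulation.
    """

    alters: tuple[Alter, ...]
    ties: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alters", tuple(self.alters))
        ids = [a.id for a in self.alters]
        if ids != list(range(len(ids))):
            raise NetworkValidationError(
                f"alter ids must be 0..{len(ids) - 1} in roster order, got {ids}"
            )
        normalized = set()
        for tie in self.ties:
            try:
                i, j = tie
            except (TypeError, ValueError):
                raise NetworkValidationError(f"malformed tie {tie!r}") from None
            if i == j:
                raise NetworkValidationError(f"self-tie [{i}, {j}] is not allowed")
            if not (0 <= i < len(ids)) or not (0 <= j < len(ids)):
                raise NetworkValidationError(
                    f"tie [{i}, {j}] references an unknown alter id"
                )
            normalized.add((min(i, j), max(i, j)))
        if len(normalized) != len(self.ties):
            raise NetworkValidationError("duplicate ties after normalization")
        object.__setattr__(self, "ties", frozenset(normalized))

    @property
    def n_alters(self) -> int:
        return len(self.alters)

    @property
    def max_ties(self) -> int:
        n = self.n_alters
        return n * (n - 1) // 2

    @property
    def n_ties(self) -> int:
        return len(self.ties)

    def alter(self, alter_id: int) -> Alter:
        if not 0 <= alter_id < self.n_alters:
            raise KeyError(f"unknown alter id {alter_id}")
        return self.alters[alter_id]

    def neighbors(self, alter_id: int) -> set[int]:
        self.alter(alter_id)
        return {j if i == alter_id else i for i, j in self.ties if alter_id in (i, j)}

    def sorted_ties(self) -> list[tuple[int, int]]:
        return sorted(self.ties)


def generate_network(
    n_alters: int,
    n_culture_a: int,
    n_ties: int,
    *,
    domains: bool = False,
    shuffle_cultures: bool = False,
    rng: np.random.Generator,
) -> EgoNetwork:
    """Generate a network with exact culture counts and uniformly random ties.

    Exactly ``n_culture_a`` alters carry :attr:`CultureLabel.CULTURE_A` and
    exactly ``n_ties`` ties are drawn uniformly without replacement from all
    unordered alter pairs.  By default the first ``n_culture_a`` roster slots
    are culture A (the dynamics depend only on counts and ties, not on label
    placement); pass ``shuffle_cultures=True`` for randomly placed labels.

    With ``domains=True`` the first half of the roster is FRIEND and the
    second half COLLEAGUE, mirroring a 4+4 elicitation for n=8.

    Deterministic given the state of ``rng``.
    """
    if n_alters < 1:
        raise ValueError(f"n_alters must be positive, got {n_alters}")
    if not 0 <= n_culture_a <= n_alters:
        raise ValueError(
            f"n_culture_a must be in [0, {n_alters}], got {n_culture_a}"
        )
    max_ties = n_alters * (n_alters - 1) // 2
    if not 0 <= n_ties <= max_ties:
        raise ValueError(f"n_ties must be in [0, {max_ties}], got {n_ties}")

    cultures = [CultureLabel.CULTURE_A] * n_culture_a + [
        CultureLabel.CULTURE_B
    ] * (n_alters - n_culture_a)
    if shuffle_cultures:
        cultures = [cultures[i] for i in rng.permutation(n_alters)]

    half = n_alters // 2
    alters = tuple(
        Alter(
            id=i,
            culture=cultures[i],
            domain=(
                (RelationalDomain.FRIEND if i < half else RelationalDomain.COLLEAGUE)
                if domains
                else RelationalDomain.UNSPECIFIED
            ),
        )
        for i in range(n_alters)
    )

    all_pairs = list(combinations(range(n_alters), 2))
    chosen = rng.choice(len(all_pairs), size=n_ties, replace=False)
    ties = frozenset(all_pairs[k] for k in chosen)
    return EgoNetwork(alters=alters, ties=ties)


def same_culture_degree(network: EgoNetwork, alter_id: int) -> int:
    """Number of ties from this alter to alters sharing its culture.

    This is the degree-centrality quantity that scales an alter's influence
    on the ego; it lies in ``[0, n_alters - 1]``.
    """
    culture = network.alter(alter_id).culture
    return sum(
        1
        for j in network.neighbors(alter_id)
        if network.alters[j].culture is culture
    )


def group_size(network: EgoNetwork, culture: CultureLabel) -> int:
    """Count of alters carrying the given culture label."""
    return sum(1 for a in network.alters if a.culture is culture)


def interclass_tie_weight(
    network: EgoNetwork,
    group_f: Collection[int],
    group_c: Collection[int],
) -> float:
    """Inter-group connectedness: cross ties normalized by |F|*|C|.

    Returns ``e(F, C) / (|F| * |C|)`` where ``e(F, C)`` counts ties with one
    endpoint in each group.  The value lies in ``[0, 1]``, saturating exactly
    when the F-C bipartite graph is complete.  If either group is empty the
    result is :data:`UNDEFINED_WEIGHT` (NaN), not an exception.
    """
    f = set(group_f)
    c = set(group_c)
    if f & c:
        raise ValueError(f"groups must be disjoint; overlap: {sorted(f & c)}")
    for alter_id in f | c:
        network.alter(alter_id)  # KeyError on unknown id
    if not f or not c:
        return UNDEFINED_WEIGHT
    e_fc = sum(
        1
        for i, j in network.ties
        if (i in f and j in c) or (i in c and j in f)
    )
    return e_fc / (len(f) * len(c))


# ---------------------------------------------------------------------------
# Serialization.  Dialect:
#   {"alters": [{"id": 0, "culture": "A", "domain": "friend"}, ...],
#    "ties": [[0, 1], [2, 5], ...]}
# Ties stored smaller-id-first and sorted for reproducible output.
# ---------------------------------------------------------------------------

def write_network(path, network: EgoNetwork) -> None:
    payload = {
        "alters": [
            {"id": a.id, "culture": a.culture.value, "domain": a.domain.value}
            for a in network.alters
        ],
        "ties": [list(t) for t in network.sorted_ties()],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_network(path) -> EgoNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkValidationError(f"{path}: not valid JSON ({exc})") from exc
    try:
        raw_alters = payload["alters"]
        raw_ties = payload["ties"]
    except (TypeError, KeyError) as exc:
        raise NetworkValidationError(
            f"{path}: expected object with 'alters' and 'ties' fields"
        ) from exc

    alters = []
    for k, entry in enumerate(raw_alters):
        try:
            culture = CultureLabel(entry["culture"])
        except (KeyError, ValueError, TypeError) as exc:
            raise NetworkValidationError(
                f"{path}: alters[{k}]: bad or missing culture label "
                f"(expected one of {[c.value for c in CultureLabel]})"
            ) from exc
        try:
            domain = RelationalDomain(entry.get("domain", "unspecified"))
        except ValueError as exc:
            raise NetworkValidationError(
                f"{path}: alters[{k}]: bad domain {entry.get('domain')!r}"
            ) from exc
        alters.append(Alter(id=int(entry.get("id", k)), culture=culture, domain=domain))

    ties = []
    for k, pair in enumerate(raw_ties):
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise NetworkValidationError(
                f"{path}: ties[{k}]: expected a pair, got {pair!r}"
            )
        ties.append((int(pair[0]), int(pair[1])))
    seen = set()
    for k, (i, j) in enumerate(ties):
        key = (min(i, j), max(i, j))
        if key in seen:
            raise NetworkValidationError(f"{path}: ties[{k}]: duplicate tie [{i}, {j}]")
        seen.add(key)

    try:
        return EgoNetwork(alters=tuple(alters), ties=frozenset(ties))
    except NetworkValidationError as exc:
        raise NetworkValidationError(f"{path}: {exc}") from exc


def write_edge_list(network: EgoNetwork, edges_path, alters_path) -> None:
    """Two-column ``source,target`` CSV plus an alter-attribute sidecar CSV."""
    with open(edges_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target"])
        for i, j in network.sorted_ties():
            writer.writerow([i, j])
    with open(alters_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "culture", "domain"])
        for a in network.alters:
            writer.writerow([a.id, a.culture.value, a.domain.value])
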