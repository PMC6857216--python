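"""Domain model: actors, ego networks, and study collections.

An ego network is one focal respondent (the *ego*) plus the alters she named,
with a symmetric binary communication relation ("talks about CHWDIC with")
over all actor pairs.  Ties are stored once per unordered pair; reported tie
counts use the directed-symmetric convention (2 x unordered count, so a
complete 11-actor network has 110 possible ties), matching how matrix-based
network packages print them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .scheme import AttributeScheme, SchemeError, default_scheme

Pair = Tuple[str, str]


class ValidationError(ValueError):
    """Base class for structural violations in roster or tie data."""


class DuplicateActorError(ValidationError):
    pass


class UnknownActorError(ValidationError):
    pass


class SelfTieError(ValidationError):
    pass


class IllegalAttributeError(ValidationError):
    pass


@dataclass(frozen=True)
class Actor:
    """One woman in a network: the ego or one of her alters.

    ``attributes`` maps attribute name -> category label, with ``None`` for
    not-applicable values (e.g. marriage type of a single woman, or the
    relationship-to-ego attributes of the ego herself).  ``age`` is the
    optional age in years backing the categorical ``age_group``.
    """

    actor_id: str
    role: str  # "ego" | "alter"
    attributes: Mapping[str, Optional[str]] = field(default_factory=dict)
    age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ("ego", "alter"):
            raise ValidationError(
                f"actor {self.actor_id!r}: role must be 'ego' or 'alter', "
                f"got {self.role!r}"
            )
        object.__setattr__(self, "attributes", dict(self.attributes))

    def get(self, attribute: str) -> Optional[str]:
        return self.attributes.get(attribute)

    def validate_against(self, scheme: AttributeScheme) -> None:
        for name, value in self.attributes.items():
            if name not in scheme.attributes:
                raise IllegalAttributeError(
                    f"actor {self.actor_id!r}: unknown attribute {name!r}"
                )
            if not scheme.is_legal(name, value):
                raise IllegalAttributeError(
                    f"actor {self.actor_id!r}: {value!r} is not a legal level "
                    f"of {name!r} (levels: {scheme.levels(name)})"
                )
        if (
            self.get("marriage_type") is None
            and self.get("marital_status") == "married"
        ):
            raise IllegalAttributeError(
                f"actor {self.actor_id!r}: marriage_type may be NA only for "
                "single actors"
            )


def _canon_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EgoNetwork:
    """One personal network: ego + alters + symmetric binary ties."""

    label: str
    site: str
    ego: Actor
    alters: Tuple[Actor, ...]
    ties: FrozenSet[Pair]

    @property
    def actors(self) -> List[Actor]:
        return [self.ego, *self.alters]

    @property
    def actor_ids(self) -> List[str]:
        return [a.actor_id for a in self.actors]

    @property
    def n_actors(self) -> int:
        return 1 + len(self.alters)

    @property
    def directed_tie_count(self) -> int:
        """Tie count under the directed-symmetric reporting convention."""
        return 2 * len(self.ties)

    @property
    def possible_directed_ties(self) -> int:
        n = self.n_actors
        return n * (n - 1)

    def actor(self, actor_id: str) -> Actor:
        for a in self.actors:
            if a.actor_id == actor_id:
                return a
        raise UnknownActorError(f"{self.label}: no actor {actor_id!r}")

    def neighbours(self, actor_id: str) -> Set[str]:
        if actor_id not in self.actor_ids:
            raise UnknownActorError(f"{self.label}: no actor {actor_id!r}")
        out: Set[str] = set()
        for a, b in self.ties:
            if a == actor_id:
                out.add(b)
            elif b == actor_id:
                out.add(a)
        return out

    def adjacency(self) -> Dict[str, Set[str]]:
        adj: Dict[str, Set[str]] = {i: set() for i in self.actor_ids}
        for a, b in self.ties:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def relabelled(self, mapping: Mapping[str, str]) -> "EgoNetwork":
        """Same network with actor ids renamed (used by symmetry tests)."""
        new_ego = replace(self.ego, actor_id=mapping[self.ego.actor_id])
        new_alters = tuple(
            replace(a, actor_id=mapping[a.actor_id]) for a in self.alters
        )
        new_ties = frozenset(_canon_pair(mapping[a], mapping[b]) for a, b in self.ties)
        return EgoNetwork(self.label, self.site, new_ego, new_alters, new_ties)


def build_network(
    label: str,
    site: str,
    ego: Actor,
    alters: Sequence[Actor],
    tie_pairs: Sequence[Pair],
    scheme: Optional[AttributeScheme] = None,
) -> EgoNetwork:
    """Validate roster records and tie pairs and assemble an :class:`EgoNetwork`.

    Directed or duplicate input pairs are symmetrized/deduplicated; self-ties,
    ties to undeclared actors, duplicate actor ids and illegal attribute
    levels each raise a distinct :class:`ValidationError` subclass naming the
    offending record.
    """
    scheme = scheme if scheme is not None else default_scheme()
    if ego.role != "ego":
        raise ValidationError(f"{label}: ego record {ego.actor_id!r} has role {ego.role!r}")
    for a in alters:
        if a.role != "alter":
            raise ValidationError(
                f"{label}: alter record {a.actor_id!r} has role {a.role!r}"
            )
    ids = [ego.actor_id] + [a.actor_id for a in alters]
    seen: Set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateActorError(f"{label}: duplicate actor id {i!r}")
        seen.add(i)
    for actor in [ego, *alters]:
        actor.validate_against(scheme)
    ties: Set[Pair] = set()
    for a, b in tie_pairs:
        if a == b:
            raise SelfTieError(f"{label}: self-tie on actor {a!r}")
        if a not in seen:
            raise UnknownActorError(f"{label}: tie references undeclared actor {a!r}")
        if b not in seen:
            raise UnknownActorError(f"{label}: tie references undeclared actor {b!r}")
        ties.add(_canon_pair(a, b))
    return EgoNetwork(label=label, site=site, ego=ego, alters=tuple(alters), ties=frozenset(ties))


def recode_attribute(
    network: EgoNetwork,
    attribute: str,
    scheme: Optional[AttributeScheme] = None,
) -> Tuple[Dict[str, List[str]], List[str]]:
    """Partition the network's actors into the attribute's two binary groups.

    Returns ``(groups, na_ids)`` where ``groups`` maps each of the two group
    labels to the actor ids assigned to it and ``na_ids`` lists actors whose
    attribute value is missing.
    """
    scheme = scheme if scheme is not None else default_scheme()
    rec = scheme.recode_map(attribute)  # raises SchemeError on unknown attribute
    g0, g1 = scheme.binary_groups(attribute)
    groups: Dict[str, List[str]] = {g0: [], g1: []}
    na_ids: List[str] = []
    for actor in network.actors:
        value = actor.get(attribute)
        if value is None:
            na_ids.append(actor.actor_id)
        else:
            groups[rec[value]].append(actor.actor_id)
    return groups, na_ids


@dataclass
class StudyCollection:
    """Ordered set of labelled ego networks sharing one attribute scheme."""

    networks: List[EgoNetwork]
    scheme: AttributeScheme = field(default_factory=default_scheme)

    def __post_init__(self) -> None:
        labels = [n.label for n in self.networks]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate network labels in collection")

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def __getitem__(self, label: str) -> EgoNetwork:
        for n in self.networks:
            if n.label == label:
                return n
        raise KeyError(label)

    @property
    def labels(self) -> List[str]:
        return [n.label for n in self.networks]

    @property
    def egos(self) -> List[Actor]:
        return [n.ego for n in self.networks]

    @property
    def alters(self) -> List[Actor]:
        return [a for n in self.networks for a in n.alters]

    @property
    def n_actors(self) -> int:
        return sum(n.n_actors for n in self.networks)
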