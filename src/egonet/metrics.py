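"""Network statistics for ego networks.

Everything here is implemented from its textbook definition on the undirected
binary graph:

* density — realized ties over possible ties (identical whether counted as
  unordered pairs or under the directed-symmetric convention);
* degree centrality — number of distinct actors an actor is tied to;
* betweenness centrality — Brandes' accumulation over single-source shortest
  paths, with each unordered endpoint pair counted once; nBetweenness rescales
  by the maximum (n-1)(n-2)/2 and is reported as a percentage;
* Freeman degree centralization — sum of (C_max - C_v) over actors, divided by
  its star-graph maximum (n-1)(n-2), as a percentage;
* Krackhardt-Stern E-I index — (external - internal ties)/(total) for a group,
  in [-1, +1]: -1 is perfectly homophilic (all ties internal), +1 perfectly
  heterophilic.  Ties touching an actor with a missing attribute value are
  excluded from both E and I so the index keeps its range under missingness.

Homophily at the actor level has no single canonical rule; the one used here
(an actor is *homophilic* when a strict majority of its countable ties are to
same-category actors, i.e. actor-level E-I < 0) is a declared interpretation
with the comparison threshold exposed as a parameter.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .model import EgoNetwork, StudyCollection, UnknownActorError, recode_attribute
from .scheme import AttributeScheme, default_scheme

HOMOPHILIC = "homophilic"
NOT_HOMOPHILIC = "not_homophilic"
NA = "NA"

#: En dash used for undefined cells in printed tables.
NA_MARK = "–"


def round2(x: float) -> float:
    """Render at two decimals, ties away from zero (5 rounds up in magnitude)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# density and degree


def density(network: EgoNetwork) -> float:
    """Realized ties as a proportion of possible ties (0..1)."""
    n = network.n_actors
    if n < 2:
        raise ValueError(f"{network.label}: density needs at least 2 actors")
    return network.directed_tie_count / (n * (n - 1))


def actor_degree(network: EgoNetwork, actor_id: str) -> int:
    """Number of distinct actors tied to this actor."""
    return len(network.neighbours(actor_id))


def degrees(network: EgoNetwork) -> Dict[str, int]:
    adj = network.adjacency()
    return {i: len(adj[i]) for i in network.actor_ids}


def average_degree(network: EgoNetwork) -> float:
    """Mean directed ties per actor: directed_tie_count / n."""
    n = network.n_actors
    if n < 1:
        raise ValueError("empty network")
    return network.directed_tie_count / n


# ---------------------------------------------------------------------------
# betweenness (Brandes 2001) and centralization (Freeman 1979)


def betweenness_raw(network: EgoNetwork) -> Dict[str, float]:
    """Shortest-path betweenness per actor on the undirected graph.

    For actor v: sum over unordered pairs {s,t} (s != t != v) of
    sigma_st(v)/sigma_st, where sigma_st counts geodesics between s and t and
    sigma_st(v) those passing through v.  Disconnected pairs contribute 0.
    """
    adj = network.adjacency()
    nodes = network.actor_ids
    bc: Dict[str, float] = {v: 0.0 for v in nodes}
    for s in nodes:
        # single-source shortest paths by BFS (unweighted)
        stack: List[str] = []
        pred: Dict[str, List[str]] = {v: [] for v in nodes}
        sigma: Dict[str, float] = {v: 0.0 for v in nodes}
        dist: Dict[str, int] = {v: -1 for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # back-propagation of dependencies
        delta: Dict[str, float] = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: b / 2.0 for v, b in bc.items()}


def betweenness_normalized(network: EgoNetwork) -> Dict[str, float]:
    """Betweenness as a percentage of the maximum (n-1)(n-2)/2."""
    n = network.n_actors
    if n < 3:
        raise ValueError(
            f"{network.label}: normalized betweenness needs at least 3 actors"
        )
    denom = (n - 1) * (n - 2) / 2.0
    return {v: 100.0 * b / denom for v, b in betweenness_raw(network).items()}


def degree_centralization(network: EgoNetwork) -> float:
    """Freeman degree centralization, percent (0 regular graph .. 100 star)."""
    n = network.n_actors
    if n < 3:
        raise ValueError(f"{network.label}: centralization needs at least 3 actors")
    degs = list(degrees(network).values())
    c_max = max(degs)
    return 100.0 * sum(c_max - c for c in degs) / ((n - 1) * (n - 2))


# ---------------------------------------------------------------------------
# E-I homophily


@dataclass(frozen=True)
class EIResult:
    """Group-level E-I index for one attribute group within one network."""

    network_label: str
    attribute: str
    group: str
    external: int
    internal: int

    @property
    def ei_index(self) -> Optional[float]:
        total = self.external + self.internal
        if total == 0:
            return None
        return (self.external - self.internal) / total

    @property
    def is_na(self) -> bool:
        return self.ei_index is None

    def render(self) -> str:
        """Three-decimal string, or the en dash for undefined cells."""
        ei = self.ei_index
        return NA_MARK if ei is None else f"{ei:.3f}"


def group_ei_index(
    network: EgoNetwork,
    attribute: str,
    group: str,
    scheme: Optional[AttributeScheme] = None,
) -> EIResult:
    """E-I index of ``group`` under the attribute's binary recoding.

    internal = ties with both endpoints in the group; external = ties with
    exactly one endpoint in the group.  Ties involving an actor with a
    missing attribute value are excluded.  The index is NA (rendered as an
    en dash) when the group is empty or has no countable ties.
    """
    scheme = scheme if scheme is not None else default_scheme()
    groups, na_ids = recode_attribute(network, attribute, scheme)
    if group not in groups:
        raise KeyError(
            f"{group!r} is not a group of {attribute!r} (groups: {list(groups)})"
        )
    members = set(groups[group])
    na = set(na_ids)
    internal = external = 0
    for a, b in network.ties:
        if a in na or b in na:
            continue
        in_a, in_b = a in members, b in members
        if in_a and in_b:
            internal += 1
        elif in_a or in_b:
            external += 1
    if not members:
        internal = external = 0
    return EIResult(network.label, attribute, group, external, internal)


def actor_homophily(
    network: EgoNetwork,
    actor_id: str,
    attribute: str,
    scheme: Optional[AttributeScheme] = None,
    threshold: float = 0.0,
    use_recoded: bool = True,
) -> str:
    """Classify one actor as homophilic / not homophilic / NA on an attribute.

    The actor's ties are split into internal (partner shares its category)
    and external; the actor is homophilic when its personal E-I index
    (E-I)/(E+I) is strictly below ``threshold`` (default 0: a strict majority
    of ties internal).  Ties to partners with a missing value are excluded;
    the result is NA for isolated actors or actors with a missing value.

    With ``use_recoded`` (default), attributes with more than two levels are
    compared on their binary recoded groups, matching the group-level E-I
    analysis; otherwise the original category labels are compared.
    """
    scheme = scheme if scheme is not None else default_scheme()
    actor = network.actor(actor_id)  # raises UnknownActorError

    if use_recoded:
        rec = scheme.recode_map(attribute)
        category = lambda a: None if a.get(attribute) is None else rec[a.get(attribute)]
    else:
        scheme.levels(attribute)
        category = lambda a: a.get(attribute)

    own = category(actor)
    if own is None:
        return NA
    internal = external = 0
    for nb in network.neighbours(actor_id):
        other = category(network.actor(nb))
        if other is None:
            continue
        if other == own:
            internal += 1
        else:
            external += 1
    total = internal + external
    if total == 0:
        return NA
    ei = (external - internal) / total
    return HOMOPHILIC if ei < threshold else NOT_HOMOPHILIC


@dataclass(frozen=True)
class HomophilySummary:
    """Counts of homophilic actors by role, with role-denominator percents."""

    attribute: str
    ego_count: int
    alter_count: int
    n_egos: int
    n_alters: int

    @property
    def total_count(self) -> int:
        return self.ego_count + self.alter_count

    @property
    def n_total(self) -> int:
        return self.n_egos + self.n_alters

    @property
    def ego_pct(self) -> float:
        return round1(100.0 * self.ego_count / self.n_egos) if self.n_egos else 0.0

    @property
    def alter_pct(self) -> float:
        return round1(100.0 * self.alter_count / self.n_alters) if self.n_alters else 0.0

    @property
    def total_pct(self) -> float:
        return round1(100.0 * self.total_count / self.n_total) if self.n_total else 0.0


def homophily_summary(
    collection: StudyCollection,
    attribute: str,
    threshold: float = 0.0,
    use_recoded: bool = True,
) -> HomophilySummary:
    """Study-wide count of homophilic egos and alters on one attribute.

    Percentages use the full role denominators (all egos / all alters),
    counting NA-classified actors as not homophilic, as in a table of
    homophily sources over every enrolled actor.
    """
    ego_count = alter_count = n_egos = n_alters = 0
    for net in collection:
        for actor in net.actors:
            status = actor_homophily(
                net, actor.actor_id, attribute, collection.scheme,
                threshold=threshold, use_recoded=use_recoded,
            )
            if actor.role == "ego":
                n_egos += 1
                ego_count += status == HOMOPHILIC
            else:
                n_alters += 1
                alter_count += status == HOMOPHILIC
    return HomophilySummary(attribute, ego_count, alter_count, n_egos, n_alters)


# ---------------------------------------------------------------------------
# per-network summary row


@dataclass(frozen=True)
class NetworkMetrics:
    """One summary row: ties, density, degrees, betweenness, centralization."""

    label: str
    site: str
    n_actors: int
    directed_tie_count: int
    density: float
    ego_degree: int
    average_degree: float
    ego_nbetweenness: float
    average_nbetweenness: float
    degree_centralization: Optional[float]
    cbdic_user_count: int

    def rounded(self) -> Dict[str, object]:
        """The row as rendered in the report (2-dp, half away from zero)."""
        return {
            "network": self.label,
            "site": self.site,
            "ties": self.directed_tie_count,
            "density": round2(self.density),
            "ego_degree": self.ego_degree,
            "average_degree": round2(self.average_degree),
            "ego_nbetweenness": round2(self.ego_nbetweenness),
            "average_nbetweenness": round2(self.average_nbetweenness),
            "centralization_pct": (
                None
                if self.degree_centralization is None
                else round2(self.degree_centralization)
            ),
            "cbdic_users": self.cbdic_user_count,
        }


def network_summary(network: EgoNetwork) -> NetworkMetrics:
    """All reported per-network statistics in one pass."""
    n = network.n_actors
    ego_id = network.ego.actor_id
    if n >= 3:
        nb = betweenness_normalized(network)
        central: Optional[float] = degree_centralization(network)
        ego_nb = nb[ego_id]
        avg_nb = sum(nb.values()) / n
    else:
        central = None
        ego_nb = avg_nb = 0.0
    return NetworkMetrics(
        label=network.label,
        site=network.site,
        n_actors=n,
        directed_tie_count=network.directed_tie_count,
        density=density(network),
        ego_degree=actor_degree(network, ego_id),
        average_degree=average_degree(network),
        ego_nbetweenness=ego_nb,
        average_nbetweenness=avg_nb,
        degree_centralization=central,
        cbdic_user_count=sum(a.get("cbdic_use") == "yes" for a in network.actors),
    )


def summary_table(collection: StudyCollection) -> List[NetworkMetrics]:
    return [network_summary(net) for net in collection]
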