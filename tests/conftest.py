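"""Shared fixtures: hand-built networks and an exhaustive betweenness oracle."""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pytest

from egonet.model import Actor, EgoNetwork, build_network
from egonet.scheme import default_scheme

BASE_ATTRS = {
    "age_group": ">=30",
    "marital_status": "married",
    "education": "primary_or_secondary",
    "occupation": "informal",
    "ethnicity": "Hausa",
    "marriage_type": "monogamy",
    "fp_use": "yes",
    "cbdic_use": "yes",
    "relationship": "relative_or_close_friend",
    "interaction_place": "social_visit",
    "interaction_freq": "weekly",
}


def make_actor(actor_id: str, role: str = "alter", **overrides) -> Actor:
    attrs = dict(BASE_ATTRS)
    attrs.update(overrides)
    if role == "ego":
        for k in ("relationship", "interaction_place", "interaction_freq"):
            attrs[k] = None
    if attrs.get("marital_status") == "single":
        attrs["marriage_type"] = None
    return Actor(actor_id=actor_id, role=role, attributes=attrs, age=30.0)


def make_network(
    n_alters: int,
    pairs: Iterable[Tuple[str, str]],
    label: str = "NET",
    alter_overrides: Optional[Dict[str, Dict[str, object]]] = None,
    ego_overrides: Optional[Dict[str, object]] = None,
) -> EgoNetwork:
    """Network with actors 'ego', 'a1'..'aN' and the given tie pairs."""
    alter_overrides = alter_overrides or {}
    ego = make_actor("ego", role="ego", **(ego_overrides or {}))
    alters = [
        make_actor(f"a{i}", role="alter", **alter_overrides.get(f"a{i}", {}))
        for i in range(1, n_alters + 1)
    ]
    return build_network(label, "A", ego, alters, list(pairs))


def complete_pairs(ids: Sequence[str]) -> List[Tuple[str, str]]:
    return list(itertools.combinations(ids, 2))


def star_network(n_alters: int = 10) -> EgoNetwork:
    """Ego at the centre, alters only tied to the ego."""
    return make_network(n_alters, [("ego", f"a{i}") for i in range(1, n_alters + 1)])


def complete_network(n_alters: int = 10) -> EgoNetwork:
    ids = ["ego"] + [f"a{i}" for i in range(1, n_alters + 1)]
    return make_network(n_alters, complete_pairs(ids))


def path_network(n_alters: int) -> EgoNetwork:
    """Path graph ego - a1 - a2 - ... - aN."""
    ids = ["ego"] + [f"a{i}" for i in range(1, n_alters + 1)]
    return make_network(n_alters, list(zip(ids, ids[1:])))


# ---------------------------------------------------------------------------
# exhaustive geodesic-enumeration betweenness oracle (test-only, brute force)


def _all_simple_paths(adj: Dict[str, Set[str]], s: str, t: str) -> List[List[str]]:
    paths: List[List[str]] = []

    def walk(node: str, seen: List[str]) -> None:
        if node == t:
            paths.append(list(seen))
            return
        for nxt in sorted(adj[node]):
            if nxt not in seen:
                seen.append(nxt)
                walk(nxt, seen)
                seen.pop()

    walk(s, [s])
    return paths


def brute_force_betweenness(network: EgoNetwork) -> Dict[str, float]:
    """Betweenness by enumerating every simple path of every actor pair.

    For each unordered pair, all simple paths are listed, the geodesics are
    those of minimum length, and each interior vertex of a geodesic collects
    its share 1/#geodesics.  Pairs with no path contribute nothing.
    """
    adj = network.adjacency()
    nodes = network.actor_ids
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(geodesics)
    return bc


def random_network(seed: int, n_actors: int, tie_prob: float) -> EgoNetwork:
    """Small Bernoulli random graph (possibly disconnected) as an EgoNetwork."""
    import numpy as np

    rng = np.random.default_rng(seed)
    ids = ["ego"] + [f"a{i}" for i in range(1, n_actors)]
    pairs = [p for p in itertools.combinations(ids, 2) if rng.random() < tie_prob]
    return make_network(n_actors - 1, pairs, label=f"RND-{seed}")


@pytest.fixture
def scheme():
    return default_scheme()


@pytest.fixture
def small_collection():
    """Tiny deterministic synthetic study shared across reporting tests."""
    from egonet.synth import GeneratorConfig, generate_study

    return generate_study(GeneratorConfig(seed=42, k_egos=4))
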