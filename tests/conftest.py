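import itertools
from collections import deque

import numpy as np
import pytest
from hypothesis import settings

import herbnet as h

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def small_network_config(seed: int) -> h.GeneratorConfig:
    """A compact two-tier planted network for repeated-seed experiments."""
    return h.GeneratorConfig(
        seed=seed,
        n_nodes=120,
        n_hub_tier=10,
        n_mid_tier=20,
        mid_outer_links=40,
        n_disease_genes=70,
        n_constituents=59,
        n_key_constituents=10,
        peri_max_hub_links=6,
    )


@pytest.fixture
def small_cfg():
    return small_network_config(0)


# ---------------------------------------------------------------------------
# independent brute-force oracles, deliberately naive
# ---------------------------------------------------------------------------

def brute_force_centralities(nodes, edges):
    """All-pairs shortest-path centralities by explicit path enumeration.

    Returns {node: (degree, betweenness, closeness)} with raw betweenness
    (pair counted once) and closeness (n_c - 1) / sum(dist) per component.
    """
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)

    def bfs(src):
        dist = {src: 0}
        q = deque([src])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    q.append(y)
        return dist

    dists = {n: bfs(n) for n in nodes}

    def shortest_paths(s, t):
        """Enumerate every shortest s->t path as a node tuple."""
        d = dists[s]
        if t not in d:
            return []
        out = []

        def walk(path):
            x = path[-1]
            if x == t:
                out.append(tuple(path))
                return
            for y in adj[x]:
                if y in d and d[y] == d[x] + 1 and dists[y].get(t, -1) == d[t] - d[y]:
                    walk(path + [y])

        walk([s])
        return out

    between = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = shortest_paths(s, t)
        if not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for p in paths if n in p)
            between[n] += through / len(paths)

    result = {}
    for n in nodes:
        d = dists[n]
        reach = len(d) - 1
        total = sum(d.values())
        clo = reach / total if total > 0 else 0.0
        result[n] = (len(adj[n]), between[n], clo)
    return result


def brute_force_hypergeom(k, K, n, N):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g in marked) >= k:
            hits += 1
    return hits / total


def random_graph(rng: np.random.Generator, max_nodes: int = 12):
    """A random simple graph as (nodes, edges) with random edge density."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"v{i}" for i in range(n)]
    p = float(rng.uniform(0.1, 0.9))
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
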