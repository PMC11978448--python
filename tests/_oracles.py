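"""Independent brute-force oracles for cross-checking the implementation.

Everything here is deliberately naive -- plain recursion over all simple
paths, dense linear algebra, explicit shortest-path enumeration -- and
shares no search code with the package. Only usable on small inputs.
"""

import numpy as np


def _adjacency(problem):
    adj = {n: set() for n in problem.nodes()}
    for a, b in problem.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def iter_k_gem_paths(problem, current, visited, k):
    """Yield every simple path from ``current`` ending at its k-th new gem."""
    adj = _adjacency(problem)
    blocked = set(visited) - {current}
    gems = set(problem.gems) - blocked - {current}

    def rec(path, got):
        node = path[-1]
        for v in adj[node]:
            if v in blocked or v in path:
                continue
            if v in gems:
                if got + 1 == k:
                    yield tuple(path) + (v,)
                else:
                    yield from rec(path + [v], got + 1)
            else:
                yield from rec(path + [v], got)

    if k >= 1:
        yield from rec([current], 0)


def shortest_k_gem_paths(problem, current, visited, k):
    paths = list(iter_k_gem_paths(problem, current, visited, k))
    if not paths:
        return set()
    best = min(len(p) for p in paths)
    return {p for p in paths if len(p) == best}


def oracle_is_solvable(problem):
    """Does any simple path from home cover all gems? Naive full DFS."""
    adj = _adjacency(problem)
    gems = set(problem.gems)

    def rec(path, left):
        if not left:
            return True
        node = path[-1]
        for v in adj[node]:
            if v in path:
                continue
            if rec(path + [v], left - {v}):
                return True
        return False

    return rec([problem.home], gems - {problem.home})


def oracle_solvable_at_depth(problem, depth):
    """Exhaustive recursion over every tie-break branch of the planner."""
    gems = set(problem.gems)

    def rec(current, visited):
        remaining = gems - visited
        if not remaining:
            return True
        k = min(depth, len(remaining))
        for plan in shortest_k_gem_paths(problem, current, visited, k):
            if rec(plan[-1], visited | set(plan)):
                return True
        return False

    return rec(problem.home, {problem.home})


def oracle_min_depth(problem, max_depth=8):
    for depth in range(1, max_depth + 1):
        if oracle_solvable_at_depth(problem, depth):
            return depth
    return None


# ---------------------------------------------------------------------------
# graph-metric oracles (graphs as networkx for convenience of construction
# only; all computation below is explicit)


def power_iteration_eigenvector(graph, iterations=10_000, tol=1e-12):
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in graph.edges():
        a[index[u], index[v]] = a[index[v], index[u]] = 1.0
    # iterate on A + I: same eigenvectors, but strictly dominant Perron value
    # even on bipartite graphs (lattices!) whose +/- lambda pairs would
    # otherwise make plain power iteration oscillate
    a += np.eye(len(nodes))
    x = np.ones(len(nodes)) / np.sqrt(len(nodes))
    for _ in range(iterations):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    return {v: abs(x[index[v]]) for v in nodes}


def _all_shortest_paths(graph, s, t):
    """Every shortest simple path s->t by BFS distance + bounded DFS."""
    import collections

    dist = {s: 0}
    q = collections.deque([s])
    while q:
        u = q.popleft()
        for v in graph[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t not in dist:
        return []
    out = []

    def rec(path):
        node = path[-1]
        if node == t:
            out.append(tuple(path))
            return
        for v in graph[node]:
            if dist.get(v) == dist[node] + 1 and dist[v] <= dist[t]:
                rec(path + [v])

    rec([s])
    return out


def brute_betweenness(graph):
    """Normalized shortest-path betweenness by explicit path enumeration."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(graph, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                score[v] += through / len(paths)
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        score = {v: s * scale for v, s in score.items()}
    return score


def brute_closeness(graph):
    """(n_reachable - 1) / sum of shortest-path lengths, per node."""
    import collections

    out = {}
    for s in graph.nodes():
        dist = {s: 0}
        q = collections.deque([s])
        while q:
            u = q.popleft()
            for v in graph[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        total = sum(dist.values())
        out[s] = (len(dist) - 1) / total if total > 0 else 0.0
    return out
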