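"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from micromine import simulate


@pytest.fixture(scope="session")
def cohort():
    """Two genomes per subgroup template, no reads (annotation-level tests)."""
    return simulate.generate_cohort(seed=7, n_per_template=2, with_reads=False)


@pytest.fixture(scope="session")
def refs(cohort):
    return cohort.refs


@pytest.fixture(scope="session")
def core_refs(cohort):
    return [r for r in cohort.refs if r.id.startswith("VP")]


@pytest.fixture(scope="session")
def read_cohort():
    """One genome per template with error-free 15x 250-nt reads."""
    return simulate.generate_cohort(seed=8, n_per_template=1, coverage=15.0, read_len=250)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def random_additive_tree(n_leaves, rng):
    """A random unrooted binary tree with positive branch lengths.

    Returns (distance matrix, non-trivial splits, edge lengths) where edge
    lengths are keyed by leaf name for pendant edges and by the canonical
    split for internal edges.  Distances are explicit path sums, so the
    matrix is exactly additive on the tree.
    """
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    next_internal = [n_leaves]
    add_edge(0, 1, float(rng.uniform(0.05, 1.0)))
    attachable = [(0, 1)]
    for leaf in range(2, n_leaves):
        a, b = attachable.pop(int(rng.integers(0, len(attachable))))
        v = next_internal[0]
        next_internal[0] += 1
        w = [x for x in edges[a] if x[0] == b][0][1]
        edges[a] = [x for x in edges[a] if x[0] != b]
        edges[b] = [x for x in edges[b] if x[0] != a]
        split = float(rng.uniform(0.2, 0.8)) * w
        add_edge(a, v, split)
        add_edge(v, b, w - split)
        add_edge(v, leaf, float(rng.uniform(0.05, 1.0)))
        attachable.extend([(a, v), (v, b), (v, leaf)])
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    all_leaves = frozenset(f"L{i}" for i in range(n_leaves))
    splits = set()
    lengths = {}
    seen_pairs = set()
    for a in list(edges):
        for b, w in edges[a]:
            if (b, a) in seen_pairs:
                continue
            seen_pairs.add((a, b))
            if a < n_leaves or b < n_leaves:
                leaf = a if a < n_leaves else b
                lengths[f"L{leaf}"] = w
                continue
            seen = {a, b}
            stack = [b]
            side = set()
            while stack:
                u = stack.pop()
                if u < n_leaves:
                    side.add(f"L{u}")
                for v, _ in edges.get(u, []):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if 2 <= len(side) <= n_leaves - 2:
                key = frozenset((frozenset(side), all_leaves - frozenset(side)))
                splits.add(key)
                lengths[key] = w
    return D, splits, lengths
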