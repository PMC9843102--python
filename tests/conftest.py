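import numpy as np
import pytest

from marisk import ScenarioSpec, SymmetricMatrix, TradeNetwork, gen_scenario


@pytest.fixture
def small_bundle():
    """A 10-target / 3-source scenario with a planted rank-1 country."""
    return gen_scenario(ScenarioSpec(n_targets=10, n_sources=3, seed=7, boost=3.0,
                                     missing_hsi_fraction=0.2))


def write_csv(path, header, rows):
    lines = [header] + [",".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def csv_writer(tmp_path):
    def _write(name, header, rows):
        return write_csv(tmp_path / name, header, rows)
    return _write


def random_digraph(seed, max_n=10, force_dangling=False):
    """A random weighted digraph wrapped as a TradeNetwork (for PageRank tests)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_n + 1))
    nodes = tuple(f"N{i:02d}" for i in range(n))
    edges = {}
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < 0.35:
                edges[(u, v)] = float(rng.uniform(0.05, 1.0))
    if force_dangling or rng.random() < 0.5:
        victim = nodes[int(rng.integers(0, n))]
        edges = {(u, v): w for (u, v), w in edges.items() if u != victim}
    return TradeNetwork(nodes=nodes, edges=edges, k=3)


def dense_pagerank_oracle(net, damping=0.85):
    """Dominant-eigenvector PageRank of the explicitly assembled Google matrix.

    Independent of the power iteration under test: assembles the full
    n x n stochastic matrix and solves the eigenproblem directly.
    """
    nodes = net.nodes
    n = len(nodes)
    idx = {c: i for i, c in enumerate(nodes)}
    S = np.zeros((n, n))
    for (u, v), w in net.edges.items():
        S[idx[u], idx[v]] = w
    out = S.sum(axis=1)
    dangling = out == 0
    S[dangling] = 1.0 / n
    S[~dangling] /= out[~dangling, None]
    G = damping * S + (1.0 - damping) / n
    vals, vecs = np.linalg.eig(G.T)
    lead = np.argmin(np.abs(vals - 1.0))
    v = np.real(vecs[:, lead])
    v = v / v.sum()
    return {c: float(v[idx[c]]) for c in nodes}


def random_connectivity(seed, max_n=12):
    """Random sparse symmetric connectivity with deliberate exact ties."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_n + 1))
    nodes = [f"C{i:02d}" for i in range(n)]
    # Discrete weight levels force frequent exact ties at the k-th value.
    levels = np.round(np.linspace(0.1, 0.9, 5), 2)
    conn = SymmetricMatrix()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.7:
                conn.set(nodes[i], nodes[j], float(rng.choice(levels)))
    return conn


def random_times(seed, conn):
    rng = np.random.default_rng(seed + 10_000)
    times = SymmetricMatrix()
    for a, b, _ in conn.pairs():
        times.set(a, b, float(rng.uniform(1.0, 30.0)))
    return times
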