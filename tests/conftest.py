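import numpy as np
import pytest

from wmnet.core import ConnectivityMatrix, ThresholdedNetwork
from wmnet.simulate import CohortSpec, generate_subject


def random_weighted_network(n: int, density: float, seed: int,
                            binary: bool = False) -> ThresholdedNetwork:
    """Random connected weighted network for metric tests."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        mask = rng.random(iu.size) < density
        vals = rng.uniform(0.05, 1.0, size=iu.size)
        w[iu[mask], ju[mask]] = vals[mask]
        w = w + w.T
        if binary:
            w = (w > 0).astype(float)
        deg = (w > 0).sum(axis=1)
        if deg.min() == 0:
            continue
        # connectivity by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in np.nonzero(w[v])[0]:
                if u not in seen:
                    seen.add(int(u))
                    frontier.append(int(u))
        if len(seen) == n:
            k = int(np.count_nonzero(np.triu(w, 1)))
            return ThresholdedNetwork(weights=w, sparsity=k / (n * (n - 1) // 2),
                                      binary=binary)
    raise RuntimeError("could not build a connected random network")


def net_from_edges(n: int, edges, binary: bool = True) -> ThresholdedNetwork:
    w = np.zeros((n, n))
    for entry in edges:
        if binary:
            i, j = entry
            w[i, j] = w[j, i] = 1.0
        else:
            i, j, val = entry
            w[i, j] = w[j, i] = val
    k = int(np.count_nonzero(np.triu(w, 1)))
    return ThresholdedNetwork(weights=w, sparsity=k / (n * (n - 1) // 2),
                              binary=binary)


@pytest.fixture(scope="session")
def default_subject() -> ConnectivityMatrix:
    """One 90-node control subject from the generator defaults."""
    return generate_subject(CohortSpec(), "control", rng_seed=1,
                            subject_id="ctrl_fixture")


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Scaled-down cohort settings used for simulation-heavy tests."""
    return CohortSpec(n_control=8, n_amusic=8, n_nodes=36,
                      coupling_grid=(0.09, 0.27, 0.09), coupling_n_random=6,
                      seed=11)
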