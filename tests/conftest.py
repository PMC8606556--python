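import numpy as np
import pytest
import scipy.sparse as sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n: int, p: float = 0.3) -> sp.csr_matrix:
    """Random symmetric 0/1 adjacency with zero diagonal."""
    upper = rng.random((n, n)) < p
    upper = np.triu(upper, k=1)
    dense = (upper | upper.T).astype(np.float64)
    return sp.csr_matrix(dense)


def random_connected_adjacency(rng, n: int, p: float = 0.4) -> sp.csr_matrix:
    """Random connected graph: a random spanning tree plus extra edges."""
    dense = np.zeros((n, n))
    order = rng.permutation(n)
    for k in range(1, n):
        parent = order[rng.integers(0, k)]
        dense[order[k], parent] = dense[parent, order[k]] = 1.0
    extra = np.triu(rng.random((n, n)) < p, k=1)
    dense = np.maximum(dense, (extra | extra.T).astype(np.float64))
    np.fill_diagonal(dense, 0.0)
    return sp.csr_matrix(dense)


def flood_fill_components(mask: np.ndarray) -> int:
    """Independent 8-connected component count by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    P, Q = mask.shape
    count = 0
    for r0 in range(P):
        for c0 in range(Q):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < P
                                and 0 <= cc < Q
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def brute_force_edges(mask: np.ndarray) -> set[tuple[int, int]]:
    """O(N^2) oracle: all pixel pairs that are 8-adjacent and both foreground."""
    mask = np.asarray(mask, dtype=bool)
    P, Q = mask.shape
    edges = set()
    for i in range(P * Q):
        for j in range(i + 1, P * Q):
            ri, ci = divmod(i, Q)
            rj, cj = divmod(j, Q)
            if (
                max(abs(ri - rj), abs(ci - cj)) == 1
                and mask[ri, ci]
                and mask[rj, cj]
            ):
                edges.add((i, j))
    return edges
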