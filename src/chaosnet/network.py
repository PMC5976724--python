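"""Newman-Watts small-world connectivity and the coupled-network vector field.

The graph is a ring lattice of N nodes, each linked to its K nearest
neighbours on both sides (degree 2K), augmented with shortcuts: every node
adds, with probability p, one extra edge to a uniformly chosen node that is
neither itself nor an existing neighbour.  No lattice edge is removed, so
the ring backbone is always intact; the adjacency is symmetric because the
couplings are electrical (gap junctions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NeuronParameters, params_to_matrix

__all__ = ["NetworkSpec", "newman_watts", "gap_junction_current", "network_rhs",
           "adjacency_to_csr", "save_edge_list", "load_edge_list"]


class InvalidTopologyError(ValueError):
    pass


def newman_watts(N: int, K: int, p: float, seed: int) -> np.ndarray:
    """Symmetric 0/1 Newman-Watts adjacency matrix (dense, zero diagonal).

    Raises ``InvalidTopologyError`` unless N > 2K >= 2 and 0 <= p <= 1.
    Identical seeds give identical matrices.
    """
    if K < 1 or N <= 2 * K:
        raise InvalidTopologyError(f"need N > 2K >= 2, got N={N}, K={K}")
    if not 0.0 <= p <= 1.0:
        raise InvalidTopologyError(f"shortcut probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    C = np.zeros((N, N), dtype=np.int8)
    for k in range(1, K + 1):
        idx = np.arange(N)
        C[idx, (idx + k) % N] = 1
        C[(idx + k) % N, idx] = 1
    for node in range(N):
        if rng.random() < p:
            # redraw on self-loop or duplicate; a node already connected to
            # everyone simply keeps its degree
            if C[node].sum() >= N - 1:
                continue
            while True:
                target = int(rng.integers(N))
                if target != node and not C[node, target]:
                    break
            C[node, target] = 1
            C[target, node] = 1
    return C


def gap_junction_current(V_k: float, V_l: float, g: float) -> float:
    """Diffusive gap-junction current into neuron k from neighbour l
    (uA/cm^2): positive when V_l > V_k, pulling V_k toward V_l."""
    if g < 0:
        raise ValueError("gap conductance must be >= 0")
    return g * (V_l - V_k)


@dataclass
class NetworkSpec:
    """A coupled network: topology, uniform gap conductance, per-node
    parameters, and the seeds that generated them."""

    C: np.ndarray
    g: float
    params: list[NeuronParameters]
    K: int | None = None
    p: float | None = None
    seed_topology: int | None = None
    seed_params: int | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.C)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise InvalidTopologyError("adjacency must be square")
        if not np.array_equal(C, C.T):
            raise InvalidTopologyError("adjacency must be symmetric")
        if np.any(np.diag(C) != 0):
            raise InvalidTopologyError("adjacency must have zero diagonal")
        if len(self.params) != C.shape[0]:
            raise ValueError("need one parameter set per node")
        self.C = C.astype(np.int8)

    @property
    def N(self) -> int:
        return self.C.shape[0]

    @classmethod
    def build(cls, N: int, K: int, p: float, g: float,
              params: NeuronParameters | list[NeuronParameters],
              seed_topology: int = 0, seed_params: int | None = None) -> "NetworkSpec":
        C = newman_watts(N, K, p, seed_topology)
        if isinstance(params, NeuronParameters):
            params = [params] * N
        return cls(C=C, g=g, params=list(params), K=K, p=p,
                   seed_topology=seed_topology, seed_params=seed_params)

    def param_matrix(self) -> np.ndarray:
        return params_to_matrix(self.params)


def adjacency_to_csr(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour lists (indptr, indices) of a symmetric adjacency."""
    C = np.asarray(C)
    indptr = np.zeros(C.shape[0] + 1, dtype=np.int64)
    indices = []
    for k in range(C.shape[0]):
        nbrs = np.flatnonzero(C[k])
        indices.append(nbrs)
        indptr[k + 1] = indptr[k] + nbrs.size
    return indptr, np.concatenate(indices).astype(np.int64) if indices else np.zeros(0, np.int64)


def network_rhs(states: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Reference (NumPy) vector field of the coupled network.

    ``states`` is (5, N) ordered (V, a_r, a_sd, a_sr, a_h); returns the
    (5, N) derivative.  The synaptic term conserves total current:
    sum_k I_syn,k = 0 for symmetric C.
    """
    from .model import NeuronState, derivatives

    S = np.asarray(states, dtype=float)
    if S.shape != (5, spec.N):
        raise ValueError(f"states must have shape (5, {spec.N})")
    V = S[0]
    I_syn = spec.g * (spec.C.astype(float) @ V - spec.C.sum(axis=1) * V)
    out = np.empty_like(S)
    for n in range(spec.N):
        out[:, n] = derivatives(NeuronState.from_array(S[:, n]), spec.params[n],
                                I_syn=float(I_syn[n]))
    return out


def save_edge_list(C: np.ndarray, path) -> None:
    """Write one '<k> <l>' line per undirected edge (k < l, 0-based)."""
    ku, lu = np.nonzero(np.triu(C, k=1))
    with open(path, "w") as fh:
        for k, l in zip(ku, lu):
            fh.write(f"{k} {l}\n")


def load_edge_list(path, N: int) -> np.ndarray:
    C = np.zeros((N, N), dtype=np.int8)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            k, l = map(int, line.split())
            C[k, l] = C[l, k] = 1
    return C
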