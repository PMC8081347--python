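"""Absorbing Markov transition model over a signaling network.

Signal propagation is modeled as a random walk from the receptor source:
at every non-terminal node the walk moves to a uniformly chosen out-neighbor
(edge signs carry no probability weight), and terminal Bcl-2 states absorb.
Each walk carries a *parity*, the product of traversed edge signs, which
encodes whether the delivered signal activates (+1) or deactivates (-1) its
endpoint.  The binomial walk outcome combines parity with the polarity of
the absorbing terminal (+1 activation state, -1 inhibition state):

    outcome = activation  iff  parity * polarity == +1

so a suppressing signal arriving at the inhibition state still reads out as
Bcl-2 activation (the inhibition was itself inhibited).

Exact absorption probabilities are computed on the parity-doubled chain
(states = node x parity) via the fundamental matrix of the absorbing chain,
and serve as the closed-form oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import scipy.linalg

from .network import PathwayNetwork, TERMINAL, NetworkValidationError

__all__ = [
    "TransitionMatrix",
    "WalkSample",
    "build_transition_matrix",
    "sample_walks",
    "absorption_probabilities",
    "visit_profile",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix with absorbing terminal rows."""

    states: list[str]
    P: np.ndarray
    absorbing: frozenset[str]
    #: edge sign matrix aligned with P (0 where no edge)
    sign: np.ndarray = field(repr=False, default=None)
    #: terminal polarity per state index (+1/-1; +1 for non-terminals)
    polarity: np.ndarray = field(repr=False, default=None)
    source: str = ""

    def index(self, state: str) -> int:
        return self.states.index(state)

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(self.P, index=self.states, columns=self.states).to_csv(path)
        return path

    def to_json(self) -> dict:
        return {
            "states": list(self.states),
            "P": self.P.tolist(),
            "absorbing": sorted(self.absorbing),
            "source": self.source,
        }


@dataclass(frozen=True)
class WalkSample:
    path: tuple[str, ...]
    parity: int
    outcome: str


def build_transition_matrix(net: PathwayNetwork) -> TransitionMatrix:
    """Uniform out-edge transition probabilities; terminals absorb.

    Raises if a non-terminal node has no outgoing edges (the walk would be
    stranded with nowhere to go).
    """
    ids = net.node_ids
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    P = np.zeros((n, n))
    S = np.zeros((n, n), dtype=int)
    for e in net.edges:
        S[idx[e.source], idx[e.target]] = e.sign
    terminals = {t.id for t in net.terminals}
    for node in net.nodes:
        i = idx[node.id]
        if node.role == TERMINAL:
            P[i, i] = 1.0
            continue
        out = net.out_edges(node.id)
        if not out:
            raise NetworkValidationError(
                f"non-terminal node {node.id} has out-degree 0; walks cannot proceed")
        p = 1.0 / len(out)
        for e in out:
            P[i, idx[e.target]] = p
    polarity = np.ones(n, dtype=int)
    for t in net.terminals:
        polarity[idx[t.id]] = t.polarity
    src = net.sources[0].id if net.sources else ids[0]
    return TransitionMatrix(states=list(ids), P=P, absorbing=frozenset(terminals),
                            sign=S, polarity=polarity, source=src)


def _outcome(parity: int, polarity: int) -> str:
    return ACTIVATION if parity * polarity > 0 else INHIBITION


def sample_walks(tm: TransitionMatrix, n: int, seed: int | None = None,
                 source: str | None = None, max_len: int = 200) -> list[WalkSample]:
    """Draw ``n`` absorbing walks from the source.

    Walks that fail to absorb within ``max_len`` steps are discarded and
    resampled; if more than half of all attempts truncate, a diagnostic
    error is raised (the chain is effectively non-absorbing from the
    source).  Fixed seed gives a byte-identical walk list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    src = source if source is not None else tm.source
    if src not in tm.states:
        raise ValueError(f"source state {src!r} not in transition matrix")
    rng = np.random.default_rng(seed)
    start = tm.index(src)
    absorbing_idx = {tm.index(a) for a in tm.absorbing}
    cum = np.cumsum(tm.P, axis=1)

    walks: list[WalkSample] = []
    attempts = 0
    truncated = 0
    while len(walks) < n:
        attempts += 1
        if attempts >= 20 and truncated / attempts > 0.5:
            raise RuntimeError(
                f"{truncated}/{attempts} walk attempts exceeded max_len={max_len}; "
                "the network likely has unreachable terminal states")
        i = start
        path = [i]
        parity = 1
        for _ in range(max_len):
            if i in absorbing_idx:
                break
            j = int(np.searchsorted(cum[i], rng.random(), side="right"))
            j = min(j, len(tm.states) - 1)
            parity *= int(tm.sign[i, j]) or 1
            path.append(j)
            i = j
        else:
            if i not in absorbing_idx:
                truncated += 1
                continue
        walks.append(WalkSample(
            path=tuple(tm.states[k] for k in path),
            parity=parity,
            outcome=_outcome(parity, int(tm.polarity[i])),
        ))
    return walks


def _visited_counts(tm: TransitionMatrix, n: int, rng: np.random.Generator,
                    max_len: int = 200) -> np.ndarray:
    """Per-state count of walks (out of ``n``) that visit each state.

    Vectorized batch simulation used by the architecture search, where
    millions of walks are needed and individual paths are not.  Matches the
    distribution of :func:`sample_walks` (same uniform-out-edge chain).
    """
    S = len(tm.states)
    start = tm.index(tm.source)
    cum = np.cumsum(tm.P, axis=1)
    absorbing = np.zeros(S, dtype=bool)
    for a in tm.absorbing:
        absorbing[tm.index(a)] = True

    current = np.full(n, start, dtype=np.intp)
    visited = np.zeros((n, S), dtype=bool)
    visited[:, start] = True
    active = ~absorbing[current]
    for _ in range(max_len):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        r = rng.random(idx.size)
        rows = cum[current[idx]]
        nxt = (r[:, None] > rows).sum(axis=1)
        np.minimum(nxt, S - 1, out=nxt)
        current[idx] = nxt
        visited[idx, nxt] = True
        active[idx] = ~absorbing[nxt]
    return visited.sum(axis=0)


def absorption_probabilities(tm: TransitionMatrix, source: str | None = None) -> dict[str, float]:
    """Exact binomial outcome probabilities from the source.

    Solves ``(I - Q) B = R`` on the parity-doubled chain (transient states
    are (node, parity) pairs) and folds absorption mass with terminal
    polarity into {activation, inhibition}.  Raises on a singular system,
    which indicates the chain cannot absorb.
    """
    src = source if source is not None else tm.source
    S = len(tm.states)
    trans = [i for i in range(S) if tm.states[i] not in tm.absorbing]
    absb = [i for i in range(S) if tm.states[i] in tm.absorbing]
    t_index = {(i, p): k for k, (i, p) in
               enumerate((i, p) for i in trans for p in (1, -1))}
    nt = len(t_index)
    # doubled absorbing states: (terminal, parity at absorption)
    a_index = {(i, p): k for k, (i, p) in
               enumerate((i, p) for i in absb for p in (1, -1))}
    na = len(a_index)

    Q = np.zeros((nt, nt))
    R = np.zeros((nt, na))
    for (i, p), k in t_index.items():
        for j in np.flatnonzero(tm.P[i] > 0):
            pij = tm.P[i, j]
            q = p * (int(tm.sign[i, j]) or 1)
            if tm.states[j] in tm.absorbing:
                R[k, a_index[(j, q)]] += pij
            else:
                Q[k, t_index[(j, q)]] += pij
    try:
        B = scipy.linalg.solve(np.eye(nt) - Q, R)
    except scipy.linalg.LinAlgError as exc:
        raise RuntimeError("singular absorbing-chain system: chain is not absorbing") from exc
    row = B[t_index[(tm.index(src), 1)]]
    if not np.isclose(row.sum(), 1.0, atol=1e-9):
        raise RuntimeError(
            f"absorption mass from {src} sums to {row.sum():.6f}, not 1: "
            "chain is not absorbing from the source")
    p_act = sum(row[a_index[(i, p)]]
                for (i, p) in a_index
                if p * int(tm.polarity[i]) > 0)
    return {ACTIVATION: float(p_act), INHIBITION: float(1.0 - p_act)}


def visit_profile(walks: list[WalkSample], depths: dict[str, int]) -> dict[int, dict[str, float]]:
    """Fraction of walks visiting each node, grouped by depth stratum."""
    if not walks:
        raise ValueError("walk list is empty")
    n = len(walks)
    counts: dict[str, int] = {nid: 0 for nid in depths}
    for w in walks:
        for nid in set(w.path):
            if nid in counts:
                counts[nid] += 1
    profile: dict[int, dict[str, float]] = {}
    for nid, d in depths.items():
        profile.setdefault(d, {})[nid] = counts[nid] / n
    return {d: profile[d] for d in sorted(profile)}


def export_json(tm: TransitionMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(tm.to_json(), indent=2, sort_keys=True))
    return path
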