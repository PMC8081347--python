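"""Derive a minimal MLP hidden-layer architecture from walk statistics.

The mapping from network to neural architecture is deliberately simple: the
depth strata of the signaling network (shortest-path distance from the
receptor) become candidate hidden layers, and a stratum's layer width is the
number of its nodes that random signal walks actually traffic through.  A
node counts towards its layer when its visit fraction over a batch of walks
reaches a threshold ``tau``; rarely visited side branches therefore do not
inflate the architecture, which gives the rule its minimality character.
Repeating the procedure over many independent walk batches and keeping the
modal candidate yields a converged architecture; on the packaged PI3K/AKT
reference network this recovers a 4-hidden-layer perceptron with 5, 1, 4
and 5 units.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .markov import TransitionMatrix, WalkSample, _visited_counts, build_transition_matrix
from .network import PathwayNetwork, depth_partition

__all__ = ["MLPTopology", "walk_layer_candidate", "search_topology", "TopologySearchResult"]


@dataclass(frozen=True)
class MLPTopology:
    """Feed-forward perceptron shape: input -> hidden layers -> 1 binomial output."""

    input_dim: int
    hidden_sizes: tuple[int, ...]
    output_dim: int = 1

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty positive counts")
        if self.output_dim != 1:
            raise ValueError("output is a single binomial unit")
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_sizes, self.output_dim)


def _candidate_from_fractions(fractions: dict[str, float], depths: dict[str, int],
                              tau: float) -> tuple[int, ...]:
    max_d = max(depths.values())
    sizes = []
    for d in range(1, max_d):  # intermediate strata only
        count = sum(1 for nid, dd in depths.items()
                    if dd == d and fractions.get(nid, 0.0) >= tau)
        if count > 0:
            sizes.append(count)
    return tuple(sizes)


def walk_layer_candidate(walks: list[WalkSample], depths: dict[str, int],
                         tau: float = 0.05, input_dim: int = 3) -> MLPTopology:
    """One architecture candidate from a single batch of walks.

    Layer width at each intermediate depth stratum = number of nodes whose
    visit fraction is >= ``tau``; empty strata are dropped.
    """
    if not walks:
        raise ValueError("walks must be non-empty")
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    n = len(walks)
    counts: dict[str, int] = Counter()
    for w in walks:
        counts.update(set(w.path))
    fractions = {nid: counts.get(nid, 0) / n for nid in depths}
    sizes = _candidate_from_fractions(fractions, depths, tau)
    if not sizes:
        raise ValueError(
            f"no stratum retains any node at tau={tau}; lower the visit threshold")
    return MLPTopology(input_dim=input_dim, hidden_sizes=sizes)


@dataclass
class TopologySearchResult:
    topology: MLPTopology
    modal_frequency: float
    #: candidate hidden-size tuple -> fraction of iterations producing it
    candidate_table: dict[tuple[int, ...], float] = field(default_factory=dict)
    iterations: int = 0

    def to_json(self) -> dict:
        return {
            "hidden_sizes": list(self.topology.hidden_sizes),
            "modal_frequency": self.modal_frequency,
            "iterations": self.iterations,
            "candidate_table": {
                ",".join(map(str, k)): v for k, v in sorted(self.candidate_table.items())
            },
        }


def search_topology(net: PathwayNetwork, iterations: int = 100_000,
                    seed: int | None = None, walks_per_iter: int = 500,
                    tau: float = 0.05, input_dim: int = 3) -> TopologySearchResult:
    """Iterative architecture generation; returns the modal candidate.

    Each iteration simulates a fresh batch of ``walks_per_iter`` absorbing
    walks and converts per-stratum visit counts into a hidden-size tuple.
    Ties between equally frequent candidates break towards fewer total
    hidden units, then fewer layers, then lexicographic order.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    tm = build_transition_matrix(net)
    depths = depth_partition(net)
    max_d = max(depths.values())
    strata_members = [np.array([i for i, nid in enumerate(tm.states) if depths[nid] == d],
                               dtype=np.intp)
                      for d in range(1, max_d)]
    threshold = tau * walks_per_iter

    table: Counter[tuple[int, ...]] = Counter()
    for _ in range(iterations):
        visits = _visited_counts(tm, walks_per_iter, rng)
        sizes = tuple(
            int((visits[members] >= threshold).sum())
            for members in strata_members
            if (visits[members] >= threshold).any()
        )
        table[sizes] += 1

    def rank(item):
        sizes, count = item
        return (-count, sum(sizes), len(sizes), sizes)

    modal_sizes, modal_count = min(table.items(), key=rank)
    if not modal_sizes:
        raise ValueError(f"no stratum retains any node at tau={tau}; lower the threshold")
    return TopologySearchResult(
        topology=MLPTopology(input_dim=input_dim, hidden_sizes=modal_sizes),
        modal_frequency=modal_count / iterations,
        candidate_table={k: v / iterations for k, v in table.items()},
        iterations=iterations,
    )
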