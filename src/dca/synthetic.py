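"""Synthetic benchmarks: planted core-attachment complexes with periodic
expression.

The generator emulates the statistical structure the detector assumes,
at desk scale and with no downloads:

* a sparse Erdos-Renyi background interactome;
* planted complexes, each a near-clique core (every core pair joined
  with high probability, then patched to be connected) plus a few
  attachment proteins each wired to at least a configured fraction of
  the core — attachments are deliberately less connected than the core
  so the core/attachment split of predictions can be checked, not just
  membership;
* periodic expression over ``cycles`` identical cycles (3 cycles of 12
  points by default, mirroring the yeast metabolic-cycle design):
  every gene draws i.i.d. Gaussian baseline noise, and planted genes
  additionally receive an activation boost inside their complex's
  active window in every cycle — core genes across the full window,
  attachment genes across a random sub-window — large enough that the
  three-sigma rule calls them active there.

Everything is reproducible from the single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import Complex, ComplexSet, ExpressionProfileSet


@dataclass
class SyntheticConfig:
    """Benchmark parameters.

    Baseline expression is Normal(5, 0.5) in arbitrary log-scale units;
    the activation boost of 6 (12 baseline SDs) makes active windows
    unambiguous, the regime where activity calling is expected to work.
    """

    seed: int = 1
    n_background: int = 200
    background_p: float = 0.01
    n_complexes: int = 5
    core_size_min: int = 3
    core_size_max: int = 8
    intra_core_p: float = 0.9
    attachments_min: int = 1
    attachments_max: int = 4
    attachment_core_fraction: float = 0.5
    n_timepoints: int = 36
    cycles: int = 3
    window: int = 6
    baseline_mean: float = 5.0
    baseline_sd: float = 0.5
    activation_boost: float = 6.0

    def validate(self) -> None:
        for p in (self.background_p, self.intra_core_p, self.attachment_core_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.core_size_min < 2 or self.core_size_max < self.core_size_min:
            raise ValueError("invalid core size range")
        if self.attachments_min < 0 or self.attachments_max < self.attachments_min:
            raise ValueError("invalid attachment count range")
        if self.n_timepoints % self.cycles != 0:
            raise ValueError("n_timepoints must be divisible by cycles")
        cycle_len = self.n_timepoints // self.cycles
        if not 1 <= self.window <= cycle_len:
            raise ValueError("window must fit inside one cycle")
        planted_max = self.n_complexes * (self.core_size_max + self.attachments_max)
        if self.core_size_max > self.n_background or planted_max > self.n_background:
            raise ValueError("planted complexes exceed the number of nodes")


def generate_benchmark(
    config: SyntheticConfig | None = None,
) -> tuple[nx.Graph, ExpressionProfileSet, ComplexSet]:
    """Generate (static network, expression profiles, ground-truth complexes)."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    nodes = [f"G{i:04d}" for i in range(config.n_background)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)

    # sparse background interactome
    n = len(nodes)
    for i in range(n):
        draws = rng.random(n - i - 1)
        for off, hit in enumerate(draws < config.background_p):
            if hit:
                graph.add_edge(nodes[i], nodes[i + 1 + off])

    # plant complexes on disjoint node sets
    pool = list(nodes)
    rng.shuffle(pool)
    truth: list[Complex] = []
    cursor = 0
    for idx in range(config.n_complexes):
        c_size = int(rng.integers(config.core_size_min, config.core_size_max + 1))
        a_size = int(rng.integers(config.attachments_min, config.attachments_max + 1))
        core = pool[cursor:cursor + c_size]
        cursor += c_size
        atts = pool[cursor:cursor + a_size]
        cursor += a_size

        # near-clique core, patched to be connected
        for i in range(c_size):
            for j in range(i + 1, c_size):
                if rng.random() < config.intra_core_p:
                    graph.add_edge(core[i], core[j])
        comps = sorted(
            nx.connected_components(graph.subgraph(core)), key=min
        )
        for a, b in zip(comps, comps[1:]):
            graph.add_edge(
                sorted(a)[int(rng.integers(len(a)))],
                sorted(b)[int(rng.integers(len(b)))],
            )

        # attachments reach at least the configured fraction of the core
        m = max(1, math.ceil(config.attachment_core_fraction * c_size))
        for att in atts:
            targets = rng.choice(c_size, size=m, replace=False)
            for t in targets:
                graph.add_edge(att, core[int(t)])

        truth.append(
            Complex(
                id=f"T{idx + 1}",
                core=frozenset(core),
                attachments=frozenset(atts),
            )
        )

    # periodic expression: baseline noise + boost in the active windows
    t_total = config.n_timepoints
    cycle_len = t_total // config.cycles
    expr = {
        node: rng.normal(config.baseline_mean, config.baseline_sd, t_total)
        for node in nodes
    }
    for cx in truth:
        start = int(rng.integers(0, cycle_len - config.window + 1))
        core_mask = np.zeros(t_total, dtype=bool)
        for c in range(config.cycles):
            base = c * cycle_len + start
            core_mask[base:base + config.window] = True
        for gene in sorted(cx.core):
            expr[gene] = expr[gene] + config.activation_boost * core_mask
        for gene in sorted(cx.attachments):
            sub_len = int(rng.integers(max(2, config.window // 2), config.window + 1))
            sub_start = start + int(rng.integers(0, config.window - sub_len + 1))
            att_mask = np.zeros(t_total, dtype=bool)
            for c in range(config.cycles):
                base = c * cycle_len + sub_start
                att_mask[base:base + sub_len] = True
            expr[gene] = expr[gene] + config.activation_boost * att_mask

    profiles = ExpressionProfileSet(profiles=expr, n_timepoints=t_total)
    truth_set = ComplexSet(complexes=truth, provenance="reference")
    return graph, profiles, truth_set
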