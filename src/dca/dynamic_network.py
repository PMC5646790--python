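"""Dynamic PPI network construction from time-course expression.

A gene is called *active* at a time point when its expression exceeds a
per-gene three-sigma threshold computed from its own profile,

    Thresh(g) = mu(g) + k * sigma(g) * w(g),      w(g) = 1 / (1 + sigma(g)^2)

with k = 3 by default; sigma is the sample standard deviation (ddof=1).
The damping term w(g) shrinks the threshold toward the mean for noisy
profiles, so highly variable genes are not held to an unreachably high
bar.  At each time point the active proteins and their interactions in
the static network form a snapshot sub-network; the ordered snapshots
are the dynamic network.

Each protein also gets an *active time span* (AT): by default the count
of active time points (robust to the disjoint active runs produced by
periodic expression), or in "span" mode the length last - first + 1 of
the activity envelope, which for a single contiguous run equals the
count.  AT is normalized by T to [0, 1] and later enters the node weight
as the stability term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io_formats import ExpressionProfileSet


@dataclass
class ActivityMatrix:
    """Gene -> boolean active/inactive vector of length ``n_timepoints``."""

    active: dict[str, np.ndarray]
    n_timepoints: int

    def genes_active_at(self, t: int) -> set[str]:
        """Genes active at 0-based time index ``t``."""
        return {g for g, row in self.active.items() if row[t]}


@dataclass
class DynamicNetwork:
    """Ordered snapshot subgraphs plus normalized active time spans.

    ``snapshots[t]`` is the subgraph of the static network induced on the
    genes active at time ``t``; ``at_norm`` maps each protein to its
    AT / T value in [0, 1].
    """

    snapshots: list[nx.Graph]
    at_norm: dict[str, float]

    @property
    def n_timepoints(self) -> int:
        return len(self.snapshots)


def activity_threshold(
    profile: Sequence[float] | np.ndarray,
    *,
    k: float = 3.0,
    sigma_weighting: bool = True,
) -> float:
    """Three-sigma activity threshold for one expression profile.

    Requires at least two time points (the sample standard deviation is
    undefined otherwise).  With ``sigma_weighting`` off the threshold is
    the plain mu + k*sigma.
    """
    vec = np.asarray(profile, dtype=float)
    if vec.size < 2:
        raise ValueError("activity threshold needs a profile of length >= 2")
    mu = float(np.mean(vec))
    sigma = float(np.std(vec, ddof=1))
    weight = 1.0 / (1.0 + sigma * sigma) if sigma_weighting else 1.0
    return mu + k * sigma * weight


def call_activity(
    profiles: ExpressionProfileSet,
    *,
    k: float = 3.0,
    sigma_weighting: bool = True,
) -> ActivityMatrix:
    """Call per-gene, per-time-point activity with strict '>' comparison.

    Strictness means a constant profile (sigma = 0, threshold = mu) is
    never active anywhere.
    """
    active: dict[str, np.ndarray] = {}
    for gene, vec in profiles.profiles.items():
        thresh = activity_threshold(vec, k=k, sigma_weighting=sigma_weighting)
        active[gene] = vec > thresh
    return ActivityMatrix(active=active, n_timepoints=profiles.n_timepoints)


def active_time_span(
    active_row: Sequence[bool] | np.ndarray,
    *,
    mode: str = "count",
) -> tuple[int, float]:
    """(raw, normalized) active time span of one activity row.

    ``count`` mode counts the active time points; ``span`` mode measures
    last_active - first_active + 1.  Both agree on a single contiguous
    run (e.g. active at points 6,7,8 with inactivation at 9 -> 3).  An
    all-inactive row yields (0, 0.0).
    """
    row = np.asarray(active_row, dtype=bool)
    t_total = row.size
    if t_total == 0 or not row.any():
        return 0, 0.0
    if mode == "count":
        raw = int(row.sum())
    elif mode == "span":
        idx = np.flatnonzero(row)
        raw = int(idx[-1] - idx[0] + 1)
    else:
        raise ValueError(f"unknown AT mode {mode!r}")
    return raw, raw / t_total


def build_snapshots(
    net: nx.Graph,
    act: ActivityMatrix,
    *,
    at_mode: str = "count",
) -> DynamicNetwork:
    """Induce the per-time-point snapshot subgraphs and compute AT.

    Only genes present in the static network appear in snapshots; AT is
    computed over all T points for every network protein (proteins never
    active get at_norm = 0 and appear in no snapshot).
    """
    net_nodes = set(net.nodes)
    snapshots: list[nx.Graph] = []
    for t in range(act.n_timepoints):
        active_here = act.genes_active_at(t) & net_nodes
        snapshots.append(net.subgraph(active_here).copy())
    at_norm: dict[str, float] = {}
    for node in net_nodes:
        row = act.active.get(node)
        if row is None:
            at_norm[node] = 0.0
        else:
            _, at_norm[node] = active_time_span(row, mode=at_mode)
    return DynamicNetwork(snapshots=snapshots, at_norm=at_norm)


def build_dynamic_network(
    net: nx.Graph,
    profiles: ExpressionProfileSet,
    *,
    k: float = 3.0,
    sigma_weighting: bool = True,
    at_mode: str = "count",
) -> DynamicNetwork:
    """Convenience wrapper: activity calling + snapshot construction."""
    act = call_activity(profiles, k=k, sigma_weighting=sigma_weighting)
    return build_snapshots(net, act, at_mode=at_mode)
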