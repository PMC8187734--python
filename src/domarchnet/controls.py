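"""Null-model control networks matched in size to evolving-network events.

Three generators provide reference behavior for the chronological
statistics:

* **barabasi** — growth with preferential attachment: each new node links
  to ``m_edges`` existing nodes with probability ∝ k_i^alpha (alpha = 1 is
  linear preferential attachment, whose degree tail approaches exponent 3);
* **barabasi_age** — the age-extended variant P_i ∝ k_i^alpha · l_i^beta,
  where l_i is the number of growth events elapsed since node i was added,
  bucketed into ``aging_bins`` age classes (beta > 0 favors older nodes);
* **erdos_renyi** — G(n, m): m distinct edges placed uniformly at random.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netgen import EvolvingNetwork, snapshot

__all__ = ["ControlSpec", "generate", "match_series"]

MODELS = ("barabasi", "barabasi_age", "erdos_renyi")


@dataclass(frozen=True)
class ControlSpec:
    model: str
    n: int
    m_edges: int = 1  # ER: total edges; PA: edges per new node
    alpha_pa: float = 1.0
    beta_age: float = 0.0
    aging_bins: int | None = None  # default: one bin per growth event
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown control model {self.model!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _preferential_attachment(spec: ControlSpec) -> nx.Graph:
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, max(1, spec.m_edges)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n == 1:
        return g
    seed_size = min(m + 1, n)
    # connected seed clique so every node has degree >= 1
    for i in range(seed_size):
        for j in range(i + 1, seed_size):
            g.add_edge(i, j)
    deg = np.array([g.degree(i) for i in range(n)], dtype=float)
    birth = np.zeros(n, dtype=int)
    bins = spec.aging_bins if spec.aging_bins is not None else max(1, n - seed_size)
    for t, new in enumerate(range(seed_size, n), start=1):
        existing = np.arange(new)
        w = deg[existing] ** spec.alpha_pa
        if spec.beta_age != 0.0:
            l = t - birth[existing]  # events since addition (newer -> smaller)
            span = max(1, t)
            bucket = np.ceil(l * bins / span).clip(1, bins)
            w = w * bucket**spec.beta_age
        if not np.isfinite(w).all() or w.sum() <= 0:
            w = np.ones_like(w)
        p = w / w.sum()
        k = min(m, existing.size)
        targets = rng.choice(existing, size=k, replace=False, p=p)
        for tgt in targets:
            g.add_edge(new, int(tgt))
            deg[tgt] += 1
            deg[new] += 1
        birth[new] = t
    return g


def generate(spec: ControlSpec) -> nx.Graph:
    """Seeded deterministic control graph for the given spec."""
    if spec.model == "erdos_renyi":
        max_m = spec.n * (spec.n - 1) // 2
        if spec.m_edges > max_m:
            raise ValueError(
                f"m_edges={spec.m_edges} infeasible for n={spec.n} (max {max_m})"
            )
        return nx.gnm_random_graph(spec.n, spec.m_edges, seed=spec.seed)
    return _preferential_attachment(spec)


def match_series(
    net: EvolvingNetwork,
    model: str,
    *,
    alpha_pa: float = 1.0,
    beta_age: float = 0.0,
    aging_bins: int | None = None,
    seed: int = 0,
    events=None,
) -> list[nx.Graph]:
    """One control graph per event, matched to the snapshot's node count
    (and edge count, for the Erdős–Rényi model)."""
    if events is None:
        events = range(1, len(net.timeline) + 1)
    out = []
    for ev in events:
        g = snapshot(net, ev)
        n = g.number_of_nodes()
        m = g.number_of_edges()
        if model == "erdos_renyi":
            m_edges = min(m, n * (n - 1) // 2)
        else:
            m_edges = max(1, round(m / n)) if n else 1
        spec = ControlSpec(
            model=model, n=max(n, 1), m_edges=m_edges,
            alpha_pa=alpha_pa, beta_age=beta_age, aging_bins=aging_bins,
            seed=seed + ev,
        )
        out.append(generate(spec))
    return out
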