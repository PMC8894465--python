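"""Synthetic cohort generator with planted structure–dynamics–behavior links.

Stands in for a cohort of subjects, each contributing (a) a binarized
structural network at fixed link density whose community architecture
spans a range of segregation and overlap, (b) a nodes × time functional
panel whose latent community structure switches at Poisson times with a
rate coupled to the subject's structural overlap, and (c) behavioral
scores linearly coupled to the structural overlap score at a target
population Pearson correlation. The planted couplings give ground truth
for end-to-end recovery tests of the full analysis pipeline.

Structural networks are planted-partition graphs whose (p_in, p_out)
are solved against the target density, then trimmed/padded to the exact
edge count — at 10% density the within-module probability lives well
below the dense sweep regime, so the module contrast parameter
``p_in`` is drawn from a range feasible at that density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from ._util import child_seeds, ordered_nodes
from .dynamic_flexibility import TimeSeriesPanel
from .graph_core import density
from .link_communities import normalized_overlap_score
from .synthetic_networks import ModularSpec, generate_modular

__all__ = ["CohortSpec", "SyntheticSubject", "generate_cohort", "generate_switch_panel"]


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 100
    N_structural: int = 164
    M_structural: int = 4
    density: float = 0.10
    p_in_range: tuple = (0.15, 0.38)
    N_ts: int = 50
    M_ts: int = 5
    T: int = 4800
    sampling_interval: float = 0.72
    base_switches: float = 2.0
    coupling_flex: float = 8.0  # extra expected switches per scan per overlap percentile
    coupling_behavior: float = 0.26  # target population Pearson r
    noise_sd: float = 0.816  # within-module correlation ~ 0.6
    n_null: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (-1 < self.coupling_behavior < 1):
            raise ValueError("coupling_behavior must lie in (-1, 1)")
        if self.N_structural % self.M_structural != 0:
            raise ValueError("N_structural must be divisible by M_structural")
        max_pairs = self.N_structural * (self.N_structural - 1) / 2
        if not (0 < self.density <= 1) or round(self.density * max_pairs) < 1:
            raise ValueError("infeasible density for this network size")


@dataclass
class SyntheticSubject:
    subject_id: int
    structural: nx.Graph
    panel: TimeSeriesPanel | None
    behavior_scores: np.ndarray  # pattern-completion-, card-sorting-, flanker-like
    planted: dict  # ground truth: p_in, p_out, switch count/times, overlap, percentile


def _structural_network(spec: CohortSpec, p_in: float, seed: int) -> tuple[nx.Graph, float]:
    """Planted-partition graph trimmed/padded to the exact target edge count."""
    n, m_mod = spec.N_structural, spec.M_structural
    pairs_total = n * (n - 1) // 2
    size = n // m_mod
    pairs_within = m_mod * size * (size - 1) // 2
    pairs_between = pairs_total - pairs_within
    m_target = int(round(spec.density * pairs_total))
    p_out = (m_target - p_in * pairs_within) / pairs_between
    p_out = float(np.clip(p_out, 0.0, 1.0))
    g = generate_modular(ModularSpec(N=n, M=m_mod, p_in=p_in, p_out=p_out, seed=seed))
    rng = np.random.default_rng(seed + 1)
    # pad with random absent pairs / trim random edges to hit m_target exactly
    edges = list(g.edges)
    if len(edges) > m_target:
        drop = rng.choice(len(edges), size=len(edges) - m_target, replace=False)
        g.remove_edges_from([edges[i] for i in drop])
    elif len(edges) < m_target:
        iu, ju = np.triu_indices(n, k=1)
        absent = [(int(a), int(b)) for a, b in zip(iu, ju) if not g.has_edge(int(a), int(b))]
        add = rng.choice(len(absent), size=m_target - len(edges), replace=False)
        g.add_edges_from([absent[i] for i in add])
    return g, p_out


def generate_switch_panel(
    N: int,
    T: int,
    sampling_interval: float,
    switch_times: Sequence[int],
    M: int = 5,
    noise_sd: float = 0.816,
    seed: int = 0,
) -> TimeSeriesPanel:
    """Piecewise-stationary block-correlation panel.

    Node signals follow a shared per-module latent Gaussian series plus
    independent Gaussian noise; the module membership is re-drawn at each
    switch time, so windowed correlation matrices show a block structure
    that reorganizes at the switches.
    """
    switch_times = sorted(int(t) for t in switch_times)
    if any(t <= 0 or t >= T for t in switch_times):
        raise ValueError("switch times must lie strictly inside (0, T)")
    if len(set(switch_times)) != len(switch_times):
        raise ValueError("switch times must be strictly increasing")
    rng = np.random.default_rng(seed)
    bounds = [0] + switch_times + [T]
    values = np.empty((N, T))
    for a, b in zip(bounds[:-1], bounds[1:]):
        membership = rng.permuted(np.arange(N) % M)
        latent = rng.standard_normal((M, b - a))
        values[:, a:b] = latent[membership] + noise_sd * rng.standard_normal((N, b - a))
    return TimeSeriesPanel(values=values, sampling_interval=sampling_interval)


def generate_cohort(spec: CohortSpec, make_panels: bool | int = True) -> list[SyntheticSubject]:
    """Generate a reproducible cohort of synthetic subjects.

    Per subject: a structural network at exact target density with a
    drawn module contrast, its null-normalized overlap score, a panel
    whose latent switching rate is base + coupling_flex · overlap
    percentile, and three behavior scores z_k = r·z_overlap +
    √(1−r²)·ε_k with r the target behavior coupling (scores are in
    standardized units; the population correlation with the overlap
    z-score equals r by construction).

    ``make_panels`` may be an integer k to attach panels only to the
    first k subjects (panels dominate generation cost; analyses often
    run flexibility on a subject subset).
    """
    master = child_seeds(spec.seed, 4 * spec.n_subjects).reshape(spec.n_subjects, 4)
    rng = np.random.default_rng(spec.seed + 1)

    graphs, p_ins, p_outs, overlaps = [], [], [], []
    for i in range(spec.n_subjects):
        p_in = rng.uniform(*spec.p_in_range)
        g, p_out = _structural_network(spec, p_in, seed=int(master[i, 0]))
        res = normalized_overlap_score(
            g, n_null=spec.n_null, seed=int(master[i, 1]), require_connected=True
        )
        graphs.append(g)
        p_ins.append(p_in)
        p_outs.append(p_out)
        overlaps.append(res.normalized_overlap)

    overlaps = np.array(overlaps)
    order = overlaps.argsort().argsort()
    percentile = order / max(1, spec.n_subjects - 1)
    z = (overlaps - overlaps.mean()) / overlaps.std() if overlaps.std() > 0 else np.zeros_like(overlaps)

    r = spec.coupling_behavior
    subjects = []
    for i in range(spec.n_subjects):
        sub_rng = np.random.default_rng(int(master[i, 2]))
        n_switches = sub_rng.poisson(spec.base_switches + spec.coupling_flex * percentile[i])
        switch_times = np.sort(sub_rng.choice(np.arange(1, spec.T), size=n_switches, replace=False)) if n_switches else np.array([], dtype=int)
        panel = None
        n_panels = spec.n_subjects if make_panels is True else int(make_panels)
        if i < n_panels:
            panel = generate_switch_panel(
                N=spec.N_ts,
                T=spec.T,
                sampling_interval=spec.sampling_interval,
                switch_times=switch_times,
                M=spec.M_ts,
                noise_sd=spec.noise_sd,
                seed=int(master[i, 3]),
            )
        eps = sub_rng.standard_normal(3)
        behavior = r * z[i] + np.sqrt(1 - r * r) * eps
        subjects.append(
            SyntheticSubject(
                subject_id=i,
                structural=graphs[i],
                panel=panel,
                behavior_scores=behavior,
                planted={
                    "p_in": p_ins[i],
                    "p_out": p_outs[i],
                    "n_switches": int(n_switches),
                    "switch_times": switch_times.tolist(),
                    "normalized_overlap": float(overlaps[i]),
                    "overlap_percentile": float(percentile[i]),
                },
            )
        )
    return subjects
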