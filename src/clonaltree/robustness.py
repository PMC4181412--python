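"""Stability studies for the clustering and the tree reconstruction.

Two simulations probe how strongly the inferred structure depends on the
mutation profile actually observed:

* the *perturbation study* redraws the frequency of a random fraction of
  mutations uniformly within each mutation's own 95% confidence interval
  and re-clusters, recording the distribution of cluster counts;
* the *deletion study* drops a random fraction of mutations outright,
  re-clusters and re-derives the node combination, recording the
  distribution of combinations.

Both are bitwise reproducible for a fixed master seed: the master seed
spawns one independent substream per iteration, so results do not depend
on iteration order.
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calling import SomaticMutation
from .clustering import cluster_profile
from .trees import node_combination


@dataclass
class SimulationReport:
    """Outcome histogram of a stability simulation."""

    iterations: int
    varied_fraction: float
    histogram: dict  # outcome -> count
    seed: int
    reference: object  # the unperturbed outcome

    @property
    def mode(self):
        return max(self.histogram.items(), key=lambda kv: (kv[1], kv[0]))[0]

    def concentration(self) -> float:
        """Share of iterations reproducing the reference outcome."""
        return self.histogram.get(self.reference, 0) / self.iterations


def _clone_with(m: SomaticMutation, r: int) -> SomaticMutation:
    m2 = copy.copy(m)
    m2.r = int(r)
    m2.frequency = r / m.n
    return m2


def perturbation_study(profile: Sequence[SomaticMutation],
                       fraction: float,
                       iterations: int = 1000,
                       seed: int = 0) -> SimulationReport:
    """Re-cluster after jittering frequencies within their 95% CIs.

    Per iteration, ``floor(fraction * N)`` mutations are chosen uniformly
    without replacement and each one's frequency is redrawn uniformly
    within its own confidence interval (realised as a new variant count
    r at fixed coverage n, so the CI machinery stays consistent); the
    full profile is then re-clustered and the cluster count recorded.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    profile = list(profile)
    reference = len(cluster_profile(profile))
    k = int(fraction * len(profile))
    streams = np.random.SeedSequence(seed).spawn(iterations)
    hist: Counter = Counter()
    for ss in streams:
        rng = np.random.default_rng(ss)
        perturbed = list(profile)
        if k > 0:
            idx = rng.choice(len(profile), size=k, replace=False)
            for i in idx:
                m = profile[i]
                f_new = rng.uniform(m.ci_low, m.ci_high)
                r_new = min(m.n, max(0, int(np.floor(f_new * m.n + 0.5))))
                # keep the mutation callable: frequency stays positive
                perturbed[i] = _clone_with(m, max(1, r_new))
        hist[len(cluster_profile(perturbed))] += 1
    return SimulationReport(iterations=iterations, varied_fraction=fraction,
                            histogram=dict(hist), seed=seed,
                            reference=reference)


def deletion_study(profile: Sequence[SomaticMutation],
                   fraction: float,
                   iterations: int = 1000,
                   seed: int = 0) -> SimulationReport:
    """Re-derive the node combination after random mutation removal.

    Per iteration, ``floor(fraction * N)`` mutations are dropped
    uniformly, the remainder re-clustered, and the canonical node
    combination recorded; the histogram runs over combination signatures.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    profile = list(profile)
    reference = node_combination(cluster_profile(profile)).signature()
    k = int(fraction * len(profile))
    streams = np.random.SeedSequence(seed).spawn(iterations)
    hist: Counter = Counter()
    for ss in streams:
        rng = np.random.default_rng(ss)
        if k > 0:
            drop = set(rng.choice(len(profile), size=k, replace=False)
                       .tolist())
            kept = [m for i, m in enumerate(profile) if i not in drop]
        else:
            kept = profile
        hist[node_combination(cluster_profile(kept)).signature()] += 1
    return SimulationReport(iterations=iterations, varied_fraction=fraction,
                            histogram=dict(hist), seed=seed,
                            reference=reference)
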