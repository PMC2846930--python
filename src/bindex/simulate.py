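"""Reproducible random trees for validating the divergence estimator.

Clock (ultrametric) trees come from a pure-birth construction: the root
splits at time 0, the remaining n-2 split times are drawn uniformly on
(0, depth) and sorted, each split extends a uniformly chosen pending lineage,
and all surviving lineages terminate as leaves exactly at ``depth``.  Every
root-to-tip path therefore equals the configured depth by construction, which
is the regime where the B-index equals the depth exactly.

Departure from the clock is modelled by independent lognormal branch-rate
multipliers with unit mean (log-mean -sigma^2/2, log-sd sigma), the standard
relaxed-clock choice; the expected tree length is then unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .treeio import Node, Tree

__all__ = [
    "SimulationConfig",
    "simulate_clock_tree",
    "apply_rate_heterogeneity",
    "simulate_paralog_pair",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    rate_ratio scales every branch of the focal tree of a paralog pair
    relative to its reference; rate_sigma is the log-sd of the per-branch
    lognormal rate multipliers (0 = strict clock).
    """

    n_leaves: int
    depth: float = 1.0
    model: str = "pure-birth"
    rate_sigma: float = 0.0
    rate_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be at least 2")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.model != "pure-birth":
            raise ValueError(f"unknown topology model: {self.model!r}")
        if self.rate_sigma < 0:
            raise ValueError("rate_sigma must be non-negative")
        if self.rate_ratio <= 0:
            raise ValueError("rate_ratio must be positive")


def simulate_clock_tree(config: SimulationConfig, labels: Sequence[str] | None = None) -> Tree:
    """Ultrametric pure-birth tree with every root-to-tip path equal to depth.

    ``labels``, when given, must provide exactly ``n_leaves`` unique names;
    the default is T01, T02, ...  Identical configs yield identical trees.
    """
    n, depth = config.n_leaves, config.depth
    if labels is None:
        width = max(2, len(str(n)))
        labels = [f"T{i + 1:0{width}d}" for i in range(n)]
    if len(labels) != n or len(set(labels)) != n:
        raise ValueError(f"need {n} unique leaf labels")

    rng = np.random.default_rng(config.seed)
    root = Node()
    pending: list[tuple[Node, float]] = [(root, 0.0), (root, 0.0)]
    for t in np.sort(rng.uniform(0.0, depth, size=n - 2)):
        parent, t0 = pending.pop(int(rng.integers(len(pending))))
        node = Node(branch_length=float(t - t0))
        parent.children.append(node)
        pending.append((node, float(t)))
        pending.append((node, float(t)))
    for label, (parent, t0) in zip(labels, pending):
        parent.children.append(Node(label=label, branch_length=depth - t0))
    return Tree(root)


def apply_rate_heterogeneity(tree: Tree, rate_sigma: float, seed: int) -> Tree:
    """Multiply each branch by an independent unit-mean lognormal factor.

    With ``rate_sigma = 0`` an identical copy is returned.  The multiplier
    order follows a fixed preorder traversal, so results are deterministic
    given the seed and the input tree.
    """
    if rate_sigma < 0:
        raise ValueError("rate_sigma must be non-negative")
    out = tree.copy()
    if rate_sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    mu = -0.5 * rate_sigma * rate_sigma
    for node in out.preorder():
        if node.branch_length is not None:
            node.branch_length *= float(rng.lognormal(mean=mu, sigma=rate_sigma))
    return out


def simulate_paralog_pair(config: SimulationConfig) -> tuple[Tree, Tree]:
    """A (focal, reference) tree pair over one synthetic species set.

    The reference is a clock tree; the focal shares its topology and species
    labels with every branch scaled by ``rate_ratio`` and, when
    ``rate_sigma > 0``, perturbed by lognormal rate multipliers.  Leaf labels
    are ``S<k>_FOC`` and ``S<k>_REF`` so both families parse to the same
    species set.
    """
    rng = np.random.default_rng(config.seed)
    topo_seed = int(rng.integers(2**31))
    noise_seed = int(rng.integers(2**31))

    width = max(2, len(str(config.n_leaves)))
    species = [f"S{i + 1:0{width}d}" for i in range(config.n_leaves)]
    reference = simulate_clock_tree(
        replace(config, seed=topo_seed), labels=[f"{sp}_REF" for sp in species]
    )

    focal = reference.copy()
    for node in focal.preorder():
        if node.branch_length is not None:
            node.branch_length *= config.rate_ratio
        if node.is_leaf and node.label is not None:
            node.label = node.label[: -len("_REF")] + "_FOC"
    if config.rate_sigma > 0:
        focal = apply_rate_heterogeneity(focal, config.rate_sigma, noise_seed)
    return focal, reference
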