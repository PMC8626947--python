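"""Fritz-Purvis D: phylogenetic dispersion of a binary trait.

The observed "sum of sister-clade differences" d is computed by setting
each tip to its 0/1 state, estimating internal node values post-order as
the unweighted mean of the two daughters, and summing |child - parent|
over all edges.  d is then standardized against two simulated nulls:

* random null: tip states shuffled across tips (phylogenetically random
  trait; D is calibrated to 1 here), and
* Brownian null: Brownian motion simulated along branches (variance
  proportional to branch length, root at 0) and thresholded so the
  number of 1-tips matches the data (clumped under the tree; D is
  calibrated to 0 here).

D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian);
D < 0 indicates stronger clumping than Brownian expectation, D > 1
stronger overdispersion than random.

Unrooted or multifurcating input trees are deterministically resolved to
a rooted binary form by the Newick reader.  Branch lengths matter only
for the Brownian simulation; daughter averaging ignores them, matching
the statistic's reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode


@dataclass(frozen=True)
class DResult:
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    n_sim: int
    seed: int | None


def _check_binary(tree: TreeNode) -> None:
    for node in tree.non_tips(include_self=True):
        if len(node.children) != 2:
            raise ValueError("tree must be binary-resolved (use the Newick reader)")


def node_values(tree: TreeNode, tip_states: dict[str, float]) -> dict[int, float]:
    """Post-order node values: tips their state, internal nodes the
    unweighted mean of their two children.  Keyed by node identity."""
    values: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            values[id(node)] = float(tip_states[node.name])
        else:
            kids = [values[id(c)] for c in node.children]
            values[id(node)] = sum(kids) / len(kids)
    return values


def d_sum(tree: TreeNode, values: dict[int, float]) -> float:
    """Sum over edges of |value(child) - value(parent)|."""
    total = 0.0
    for node in tree.traverse(include_self=False):
        total += abs(values[id(node)] - values[id(node.parent)])
    return total


def _d_of_states(tree: TreeNode, states: dict[str, float]) -> float:
    return d_sum(tree, node_values(tree, states))


def _brownian_tips(tree: TreeNode, rng: np.random.Generator) -> dict[str, float]:
    vals: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=True):
        if node.parent is None:
            vals[id(node)] = 0.0
        else:
            bl = node.length if node.length is not None else 1.0
            vals[id(node)] = vals[id(node.parent)] + rng.normal(0.0, 1.0) * np.sqrt(
                max(bl, 0.0)
            )
        if node.is_tip():
            out[node.name] = vals[id(node)]
    return out


def fritz_purvis_d(
    tree: TreeNode,
    tip_states: dict[str, int],
    n_sim: int = 1000,
    seed: int | None = None,
) -> DResult:
    """Fritz-Purvis D with permutation and Brownian-threshold nulls.

    ``tip_states`` maps every tip label to 0 or 1; both states must be
    present.  The two nulls draw from independent substreams of the same
    seed.
    """
    _check_binary(tree)
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in tip_states]
    if missing:
        raise ValueError(f"states missing for tips: {missing[:5]}")
    states = np.array([int(tip_states[t]) for t in tips])
    n_ones = int(states.sum())
    if n_ones == 0 or n_ones == len(states):
        raise ValueError("trait is monomorphic; D is undefined")

    d_obs = _d_of_states(tree, dict(zip(tips, states.astype(float))))

    ss = np.random.SeedSequence(seed)
    rng_perm, rng_bm = (np.random.default_rng(s) for s in ss.spawn(2))

    d_rand = np.empty(n_sim)
    for i in range(n_sim):
        perm = rng_perm.permutation(states)
        d_rand[i] = _d_of_states(tree, dict(zip(tips, perm.astype(float))))

    d_brown = np.empty(n_sim)
    for i in range(n_sim):
        bm = _brownian_tips(tree, rng_bm)
        vals = np.array([bm[t] for t in tips])
        thresh = np.sort(vals)[::-1][n_ones - 1]
        sim_states = (vals >= thresh).astype(float)
        d_brown[i] = _d_of_states(tree, dict(zip(tips, sim_states)))

    mean_rand = float(d_rand.mean())
    mean_brown = float(d_brown.mean())
    if mean_rand <= mean_brown:
        raise ValueError(
            "degenerate tree: random null does not exceed Brownian null; "
            "D is undefined"
        )
    D = (d_obs - mean_brown) / (mean_rand - mean_brown)
    return DResult(d_obs, mean_rand, mean_brown, float(D), n_sim, seed)


def simulate_tree(n_tips: int, seed: int | None = None) -> TreeNode:
    """Random binary tree with exponential branch lengths (mean 0.1).

    Built by successively splitting a uniformly chosen tip; useful for
    calibration experiments on the D statistic.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)

    root = TreeNode(name=None)
    leaves = [root]
    while len(leaves) < n_tips:
        pick = leaves.pop(int(rng.integers(len(leaves))))
        kids = [TreeNode(name=None), TreeNode(name=None)]
        for kid in kids:
            kid.length = float(rng.exponential(0.1))
        pick.extend(kids)
        leaves.extend(kids)
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i:04d}"
    root.length = None
    return root
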