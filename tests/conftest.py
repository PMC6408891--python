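"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: expansion
detection is re-derived by exhaustive node enumeration, and the codon
likelihood by brute-force summation over internal-node states with
transition matrices from `scipy.linalg.expm`.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from expanscan.codonsel.genetic_code import N_CODONS, codon_state
from expanscan.codonsel.model import build_rate_matrix
from expanscan.treeops import GeneTree, node_support


# ---------------------------------------------------------------------------
# Random gene trees (independent of the synthetic_data generators)
# ---------------------------------------------------------------------------


def random_newick(
    rng: np.random.Generator,
    n_leaves: int,
    n_species: int = 6,
    focal_frac: float = 0.45,
    with_support: bool = True,
) -> tuple[str, set[str]]:
    """A random binary Newick string; returns (newick, focal species set).

    Species are s0..s{n-1}; a random subset is 'focal'. Leaves draw species
    uniformly, so focal-only clades of every size arise by chance.
    """
    n_focal = max(1, int(round(focal_frac * n_species)))
    focal = {f"s{i}" for i in rng.choice(n_species, size=n_focal, replace=False)}
    parts = [
        f"s{rng.integers(n_species)}_g{k}:{rng.uniform(0.01, 1.0):.4f}"
        for k in range(n_leaves)
    ]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        sup = f"{rng.uniform(0, 1):.3f}" if with_support else ""
        parts.append(f"({a},{b}){sup}:{rng.uniform(0.01, 1.0):.4f}")
    return parts[0] + ";", focal


def brute_force_expansions(
    gtree: GeneTree, focal: set[str], cutoff: int, min_support: float | None = None
) -> list[frozenset[str]]:
    """All-node enumeration + maximality reduction, as plain set algebra."""
    qualifying = []
    for nd in gtree.tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(leaves) < cutoff:
            continue
        if all(gtree.species_of(l) in focal for l in leaves):
            qualifying.append((leaves, node_support(nd)))
    maximal = [
        (ls, sup)
        for ls, sup in qualifying
        if not any(ls < other for other, _ in qualifying)
    ]
    if min_support is not None:
        maximal = [(ls, sup) for ls, sup in maximal if sup is not None and sup >= min_support]
    # deduplicate identical leaf sets (unary chains cannot occur in our trees)
    return sorted({ls for ls, _ in maximal}, key=lambda s: (-len(s), sorted(s)))


# ---------------------------------------------------------------------------
# Brute-force codon likelihood
# ---------------------------------------------------------------------------


def brute_force_codon_loglik(aln, gtree, freqs, kappa, omega, tree_scale=1.0):
    """Sum over all internal-node codon states explicitly.

    Only feasible for <= 4 taxa (two internal nodes on a rooted binary
    tree): complexity O(sites * 61^n_internal).
    """
    Q = build_rate_matrix(freqs, kappa, omega)
    nodes = list(gtree.tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    if len(internal) > 3:
        raise ValueError("brute force limited to 3 internal nodes")
    P = {}
    for nd in nodes:
        if nd.parent_node is not None:
            P[id(nd)] = expm(Q * float(nd.edge.length) * tree_scale)

    import itertools

    n_sites = aln.n_codons
    states = {
        gid: np.array(
            [codon_state(aln.sequences[gid][3 * c : 3 * c + 3]) for c in range(n_sites)]
        )
        for gid in aln.ids
    }
    root = gtree.tree.seed_node
    # per leaf: emission[parent_state, site] (1 for missing observations)
    leaf_em = {}
    for nd in nodes:
        if nd.is_leaf():
            obs = states[nd.taxon.label]
            em = np.ones((N_CODONS, n_sites))
            seen = obs >= 0
            em[:, seen] = P[id(nd)][:, obs[seen]]
            leaf_em[id(nd)] = em

    total = np.zeros(n_sites)
    for assign in itertools.product(range(N_CODONS), repeat=len(internal)):
        state_of = {id(nd): s for nd, s in zip(internal, assign)}
        scalar = freqs[state_of[id(root)]]
        for nd in internal:
            if nd.parent_node is not None:
                scalar *= P[id(nd)][state_of[id(nd.parent_node)], state_of[id(nd)]]
        if scalar == 0.0:
            continue
        per_site = np.full(n_sites, scalar)
        for nd in nodes:
            if nd.is_leaf():
                per_site = per_site * leaf_em[id(nd)][state_of[id(nd.parent_node)]]
        total += per_site
    return float(np.log(total).sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
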