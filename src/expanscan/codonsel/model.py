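"""Goldman-Yang codon substitution model and pruning likelihood.

The model acts on the 61 sense codons of the standard genetic code. The
instantaneous rate from codon i to codon j (differing at exactly one
nucleotide) is

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous]

with pi the stationary codon frequencies (empirical F3x4 by default),
kappa the transition/transversion rate ratio and omega = dN/dS. Multi-step
changes have rate 0; the generator is scaled so the expected substitution
rate at stationarity is 1, making branch lengths expected substitutions
per codon. The chain is reversible, so the likelihood can be rooted
anywhere (pulley principle).

Likelihood evaluation uses Felsenstein pruning over compressed site
patterns, with transition matrices obtained from a symmetric
eigendecomposition of the generator (one decomposition per distinct omega,
then P(t) by eigenvalue scaling for every branch). Gaps and ambiguous
codons are treated as fully missing (uniform conditional likelihood).
"""

from __future__ import annotations

import numpy as np

from ..treeops import GeneTree
from .alignment import CodonAlignment
from .genetic_code import (
    CODONS,
    GAP_CODON,
    IS_NEIGHBOUR,
    IS_SYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    NT_INDEX,
    codon_state,
)

__all__ = [
    "f3x4_frequencies",
    "equal_frequencies",
    "build_rate_matrix",
    "SpectralQ",
    "transition_matrix",
    "CodonLikelihood",
]

_FREQ_FLOOR = 1e-10


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(sequences) -> np.ndarray:
    """Empirical F3x4 codon frequencies.

    Nucleotide frequencies are counted separately at the three codon
    positions over all ungapped codons (one pseudo-count per nucleotide per
    position keeps every frequency positive); the codon frequency is the
    product over positions, with stop codons zeroed and the rest
    renormalized.
    """
    counts = np.ones((3, 4))
    for seq in sequences:
        s = seq.upper()
        for c in range(0, len(s) - len(s) % 3, 3):
            codon = s[c : c + 3]
            if codon == GAP_CODON or any(n not in NT_INDEX for n in codon):
                continue
            for pos, n in enumerate(codon):
                counts[pos, NT_INDEX[n]] += 1
    ntfreq = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [ntfreq[0, NT_INDEX[c[0]]] * ntfreq[1, NT_INDEX[c[1]]] * ntfreq[2, NT_INDEX[c[2]]]
         for c in CODONS]
    )
    freqs = np.maximum(freqs, _FREQ_FLOOR)
    return freqs / freqs.sum()


def build_rate_matrix(
    freqs: np.ndarray, kappa: float, omega: float, scale: bool = True
) -> np.ndarray:
    """61x61 generator Q of the codon model; rows sum to zero.

    With ``scale`` (the default) Q is normalized so that
    sum_i pi_i sum_{j != i} q_ij = 1, i.e. branch lengths are expected
    substitutions per codon at stationarity.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (N_CODONS,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs <= 0).any():
        raise ValueError("codon frequencies must be 61 positive values summing to 1")
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    rate = np.where(IS_TRANSITION, kappa, 1.0) * np.where(IS_SYNONYMOUS, 1.0, omega)
    Q = np.where(IS_NEIGHBOUR, rate * freqs[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -float(freqs @ np.diag(Q))
        if mu > 0:
            Q = Q / mu
    return Q


class SpectralQ:
    """Eigendecomposition of a scaled generator for fast P(t).

    Uses the reversibility of the model: B = D^{1/2} Q D^{-1/2} is
    symmetric (D = diag(pi)), so P(t) = D^{-1/2} V exp(L t) V^T D^{1/2}
    with one `eigh` per (kappa, omega) and only matrix products per branch.
    """

    def __init__(self, freqs: np.ndarray, kappa: float, omega: float):
        self.freqs = np.asarray(freqs, dtype=float)
        self.Q = build_rate_matrix(self.freqs, kappa, omega)
        sq = np.sqrt(self.freqs)
        B = (sq[:, None] * self.Q) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self._lam = lam
        self._left = V / sq[:, None]          # D^{-1/2} V
        self._right = (V * sq[:, None]).T     # V^T D^{1/2}

    def P(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        return P / P.sum(axis=1, keepdims=True)


def transition_matrix(
    freqs: np.ndarray, kappa: float, omega: float, t: float
) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled generator."""
    return SpectralQ(freqs, kappa, omega).P(t)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


class CodonLikelihood:
    """Pruning-likelihood engine binding one alignment to one tree.

    Edges are indexed by the postorder position of their child node
    (root excluded), giving a stable order for per-branch omega labels and
    branch-length vectors. ``base_lengths`` are the input tree's branch
    lengths (missing lengths are an error).
    """

    def __init__(
        self, aln: CodonAlignment, gtree: GeneTree, freqs: np.ndarray | None = None
    ):
        leaves = set(gtree.leaf_labels())
        seqs = set(aln.ids)
        if leaves != seqs:
            raise ValueError(
                f"tree/alignment mismatch; only in tree: {sorted(leaves - seqs)}, "
                f"only in alignment: {sorted(seqs - leaves)}"
            )
        self.aln = aln
        self.gtree = gtree
        self.freqs = f3x4_frequencies(aln.ungapped(i) for i in aln.ids) if freqs is None else np.asarray(freqs, float)

        nodes = list(gtree.tree.postorder_node_iter())
        self._nodes = nodes
        self._node_pos = {id(nd): k for k, nd in enumerate(nodes)}
        self.edge_child = [k for k, nd in enumerate(nodes) if nd.parent_node is not None]
        self._edge_of_node = {k: e for e, k in enumerate(self.edge_child)}
        self.n_edges = len(self.edge_child)
        base = []
        for k in self.edge_child:
            bl = nodes[k].edge.length
            if bl is None:
                raise ValueError("tree has a missing branch length; cannot compute likelihood")
            base.append(float(bl))
        self.base_lengths = np.array(base)

        # compressed site patterns: states[leaf_row, pattern], -1 = missing
        states = np.empty((len(aln.ids), aln.n_codons), dtype=np.int16)
        order = {gid: r for r, gid in enumerate(aln.ids)}
        for gid in aln.ids:
            seq = aln.sequences[gid]
            states[order[gid]] = [
                codon_state(seq[3 * c : 3 * c + 3]) for c in range(aln.n_codons)
            ]
        patterns, counts = np.unique(states, axis=1, return_counts=True)
        self.patterns = patterns
        self.counts = counts.astype(float)
        self.n_sites = aln.n_codons
        self._leaf_row = order

        # one-hot (or all-ones) leaf partials, built once
        npat = patterns.shape[1]
        self._leaf_partials = {}
        for k, nd in enumerate(nodes):
            if not nd.is_leaf():
                continue
            row = patterns[order[nd.taxon.label]]
            part = np.zeros((N_CODONS, npat))
            miss = row < 0
            part[:, miss] = 1.0
            cols = np.nonzero(~miss)[0]
            part[row[cols], cols] = 1.0
            self._leaf_partials[k] = part

    # -- edge helpers --------------------------------------------------------

    def edges_in_clade(self, leaf_labels: set[str], include_stem: bool = False) -> set[int]:
        """Edge indices inside the clade spanned by ``leaf_labels`` (all
        internal and terminal branches below the MRCA; the stem branch above
        it optionally included)."""
        mrca = self.gtree.tree.mrca(taxon_labels=sorted(leaf_labels))
        idx = set()
        for nd in mrca.postorder_iter():
            if nd is mrca:
                continue
            idx.add(self._edge_of_node[self._node_pos[id(nd)]])
        if include_stem and mrca.parent_node is not None:
            idx.add(self._edge_of_node[self._node_pos[id(mrca)]])
        return idx

    # -- likelihood ----------------------------------------------------------

    def site_likelihoods(
        self,
        kappa: float,
        edge_omegas: np.ndarray,
        branch_lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-pattern likelihood with an omega value per edge."""
        lengths = self.base_lengths if branch_lengths is None else np.asarray(branch_lengths, float)
        edge_omegas = np.asarray(edge_omegas, dtype=float)
        if edge_omegas.shape != (self.n_edges,) or lengths.shape != (self.n_edges,):
            raise ValueError("edge_omegas and branch_lengths must have one entry per edge")
        spectra = {w: SpectralQ(self.freqs, kappa, w) for w in np.unique(edge_omegas)}

        npat = self.patterns.shape[1]
        partials: list[np.ndarray | None] = [None] * len(self._nodes)
        for k, nd in enumerate(self._nodes):
            if nd.is_leaf():
                partials[k] = self._leaf_partials[k]
                continue
            part = np.ones((N_CODONS, npat))
            for child in nd.child_nodes():
                ck = self._node_pos[id(child)]
                e = self._edge_of_node[ck]
                P = spectra[edge_omegas[e]].P(lengths[e])
                part *= P @ partials[ck]
                partials[ck] = None  # free as we go
            partials[k] = part
        root = partials[-1]
        return self.freqs @ root

    def log_likelihood(
        self,
        kappa: float,
        omega,
        branch_lengths: np.ndarray | None = None,
        foreground_edges: set[int] | None = None,
        omega_foreground: float | None = None,
    ) -> float:
        """Total log-likelihood.

        ``omega`` is the (background) dN/dS; when ``foreground_edges`` and
        ``omega_foreground`` are given those edges evolve under the
        foreground ratio instead (two-ratio branch model).
        """
        ew = np.full(self.n_edges, float(omega))
        if foreground_edges:
            if omega_foreground is None:
                raise ValueError("omega_foreground required with foreground_edges")
            ew[list(foreground_edges)] = float(omega_foreground)
        site_l = self.site_likelihoods(kappa, ew, branch_lengths)
        if np.any(site_l <= 0):
            return -np.inf
        return float(self.counts @ np.log(site_l))
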