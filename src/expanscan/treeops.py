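"""Gene-tree operations for lineage-restricted expansion analysis.

A *lineage-specific expansion* is a clade in a gene (family) tree whose
leaves all belong to a focal set of species — evidence that the copies arose
by duplication after that lineage split from the rest of the tree. This
module parses gene trees (Newick, with branch lengths in substitutions/site
and local support values on internal nodes), detects and ranks such clades,
extracts each clade together with its nearest well-supported outgroup, and
summarizes patristic divergence between clade members and reference-lineage
sequences.

Trees are held as :class:`dendropy.Tree` objects wrapped in
:class:`GeneTree`, which adds a leaf-label scheme mapping each leaf to a
species id.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "LabelScheme",
    "GeneTree",
    "ExpansionGroup",
    "DivergenceSummary",
    "TreeError",
    "parse_newick",
    "find_lineage_expansions",
    "extract_group_subtree",
    "patristic_divergence_summary",
    "groups_to_records",
]


class TreeError(ValueError):
    """Malformed tree input or an operation applied to an unsuitable tree."""


@dataclass(frozen=True)
class LabelScheme:
    """How leaf labels encode species and gene ids.

    Default: ``SPECIES_geneid`` with the first ``separator`` splitting the
    two parts. A label with no separator is treated as a bare species id
    (useful for per-sequence trees in codon-model work). Alternatively a
    regex with named groups ``species`` and ``gene`` may be supplied.
    """

    separator: str = "_"
    pattern: str | None = None

    def parse(self, label: str) -> tuple[str, str]:
        if self.pattern is not None:
            m = re.match(self.pattern, label)
            if not m:
                raise TreeError(f"leaf label {label!r} does not match {self.pattern!r}")
            return m.group("species"), m.group("gene")
        sp, _, gene = label.partition(self.separator)
        if not sp:
            raise TreeError(f"leaf label {label!r} has an empty species field")
        return sp, gene


@dataclass
class ExpansionGroup:
    """A detected lineage-restricted clade.

    ``node_id`` is the postorder index of the defining node in the source
    tree; ``rank`` is 1-based after sorting by size (descending).
    ``sister_genes`` holds the leaves of the nearest sister clade passing the
    support filter (filled by :func:`extract_group_subtree`, or during
    detection when ``min_support`` is given).
    """

    node_id: int
    member_genes: list[str]
    member_species: set[str]
    size: int
    support: float | None
    rank: int = 0
    sister_genes: list[str] = field(default_factory=list)
    degenerate_root: bool = False

    def __post_init__(self) -> None:
        if self.size != len(self.member_genes):
            raise ValueError("size must equal len(member_genes)")


@dataclass(frozen=True)
class DivergenceSummary:
    """Quartiles of per-member minimum patristic distance (subs/site)."""

    median: float
    q1: float
    q3: float
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.q1 <= self.median <= self.q3):
            raise ValueError("require 0 <= q1 <= median <= q3")


class GeneTree:
    """A gene tree plus the label scheme mapping leaves to species.

    Branch lengths, when present, are non-negative; internal-node support
    values, when present, lie in [0, 1]. Polytomies are preserved.
    """

    def __init__(self, tree: dendropy.Tree, scheme: LabelScheme | None = None):
        self.tree = tree
        self.scheme = scheme or LabelScheme()
        self._validate()
        self._index()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        leaves = self.leaf_labels()
        if len(leaves) < 3:
            raise TreeError(f"tree has {len(leaves)} leaves; need at least 3")
        bad = []
        for lab in leaves:
            try:
                self.scheme.parse(lab)
            except TreeError:
                bad.append(lab)
        if bad:
            raise TreeError(f"leaf labels not matching scheme: {bad}")
        for nd in self.tree.preorder_node_iter():
            bl = nd.edge.length
            if bl is not None and bl < 0:
                raise TreeError(f"negative branch length {bl} above node {_node_desc(nd)}")
            s = node_support(nd)
            if s is not None and not (0.0 <= s <= 1.0):
                raise TreeError(f"support {s} outside [0, 1] at node {_node_desc(nd)}")

    def _index(self) -> None:
        """(Re)assign stable postorder indices; call after any rerooting."""
        self._nodes = list(self.tree.postorder_node_iter())
        for i, nd in enumerate(self._nodes):
            nd.postorder_index = i

    # -- basic accessors -----------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def species_of(self, label: str) -> str:
        return self.scheme.parse(label)[0]

    def species_present(self) -> set[str]:
        return {self.species_of(lab) for lab in self.leaf_labels()}

    def node(self, node_id: int) -> dendropy.Node:
        return self._nodes[node_id]

    def __len__(self) -> int:
        return len(self.leaf_labels())

    # -- rooting -------------------------------------------------------------

    def root_at_midpoint(self) -> None:
        self.tree.reroot_at_midpoint(update_bipartitions=False)
        self._index()

    def root_at_outgroup(self, outgroup_species: set[str]) -> None:
        """Root on the edge above the smallest clade holding all outgroup
        leaves (the MRCA of the outgroup species)."""
        labels = [l for l in self.leaf_labels() if self.species_of(l) in outgroup_species]
        if not labels:
            raise TreeError(f"no leaves from outgroup species {sorted(outgroup_species)}")
        mrca = self.tree.mrca(taxon_labels=labels)
        if mrca is self.tree.seed_node:
            raise TreeError("outgroup spans the root; cannot reroot")
        self.tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
        self._index()

    # -- serialization -------------------------------------------------------

    def to_newick(self) -> str:
        return _newick_string(self.tree.seed_node) + ";"


def node_support(nd: dendropy.Node) -> float | None:
    """Support value of an internal node (parsed from its Newick label)."""
    if nd.is_leaf() or nd.label is None:
        return None
    try:
        return float(nd.label)
    except ValueError:
        return None


def _node_desc(nd: dendropy.Node) -> str:
    if nd.is_leaf():
        return nd.taxon.label
    some = [lf.taxon.label for lf in nd.leaf_iter()]
    return f"<internal mrca of {some[0]}..{some[-1]}>"


def _newick_string(nd: dendropy.Node) -> str:
    if nd.is_leaf():
        s = nd.taxon.label.replace(" ", "_")
    else:
        s = "(" + ",".join(_newick_string(c) for c in nd.child_nodes()) + ")"
        if nd.label is not None:
            s += str(nd.label)
    if nd.edge.length is not None:
        s += f":{nd.edge.length:.10g}"
    return s


def parse_newick(text: str, scheme: LabelScheme | None = None) -> GeneTree:
    """Parse a Newick string into a :class:`GeneTree`.

    Internal node labels are interpreted as support values in [0, 1] (the
    convention of FastTree-style local support). Missing branch lengths stay
    missing (``None``), never silently zero. Polytomies are preserved.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    # clade direction is taken from the seed node; explicit rerooting is
    # available via root_at_midpoint / root_at_outgroup
    tree.is_rooted = True
    return GeneTree(tree, scheme)


def read_newick(path: str, scheme: LabelScheme | None = None) -> GeneTree:
    with open(path) as fh:
        return parse_newick(fh.read(), scheme)


# ---------------------------------------------------------------------------
# Expansion detection
# ---------------------------------------------------------------------------


def find_lineage_expansions(
    gtree: GeneTree,
    focal_species: set[str],
    cutoff: int = 10,
    min_support: float | None = None,
) -> list[ExpansionGroup]:
    """Detect maximal clades whose leaves all belong to ``focal_species``.

    A node qualifies when every descendant leaf is from a focal species and
    it has at least ``cutoff`` leaves. Only *maximal* qualifying nodes are
    returned (no returned node is an ancestor of another), so nested
    focal-only nodes are not double counted. Groups are ranked by size,
    descending, ties broken by postorder index; the support filter, when
    given, is applied after ranking as a retention criterion on the defining
    node.

    If every leaf of the tree is focal the root is returned as a single
    degenerate group and a warning is emitted — with no non-focal leaf the
    tree cannot polarize where the expansion starts.
    """
    if cutoff < 2:
        raise ValueError(f"cutoff must be >= 2, got {cutoff}")
    if not focal_species:
        raise ValueError("focal_species must be non-empty")

    focal_leaf = {}
    for lab in gtree.leaf_labels():
        focal_leaf[lab] = gtree.species_of(lab) in focal_species

    # postorder sweep: leaf count and all-focal flag per node
    for nd in gtree._nodes:
        if nd.is_leaf():
            nd._n_leaves = 1
            nd._all_focal = focal_leaf[nd.taxon.label]
        else:
            kids = nd.child_nodes()
            nd._n_leaves = sum(k._n_leaves for k in kids)
            nd._all_focal = all(k._all_focal for k in kids)

    root = gtree.tree.seed_node
    if root._all_focal:
        warnings.warn(
            "all leaves belong to the focal lineage; returning the root as a "
            "degenerate group",
            stacklevel=2,
        )
        group = _make_group(gtree, root)
        group.degenerate_root = True
        group.rank = 1
        return [group]

    candidates = []
    for nd in gtree._nodes:
        if nd.is_leaf() or not nd._all_focal or nd._n_leaves < cutoff:
            continue
        parent = nd.parent_node
        if parent is not None and parent._all_focal:
            continue  # not maximal: the parent is also focal-only
        candidates.append(nd)

    candidates.sort(key=lambda nd: (-nd._n_leaves, nd.postorder_index))
    groups = []
    for rank, nd in enumerate(candidates, start=1):
        g = _make_group(gtree, nd)
        g.rank = rank
        groups.append(g)

    if min_support is not None:
        groups = [g for g in groups if g.support is not None and g.support >= min_support]
        for rank, g in enumerate(groups, start=1):
            g.rank = rank
        for g in groups:
            g.sister_genes = _sister_leaves(gtree, gtree.node(g.node_id), min_support)
    return groups


def _make_group(gtree: GeneTree, nd: dendropy.Node) -> ExpansionGroup:
    members = [lf.taxon.label for lf in nd.leaf_iter()]
    return ExpansionGroup(
        node_id=nd.postorder_index,
        member_genes=members,
        member_species={gtree.species_of(m) for m in members},
        size=len(members),
        support=node_support(nd),
    )


# ---------------------------------------------------------------------------
# Subtree extraction (group + supported outgroup)
# ---------------------------------------------------------------------------


def _passes_support(nd: dendropy.Node, min_support: float) -> bool:
    if min_support <= 0:
        return True
    s = node_support(nd)
    return s is not None and s >= min_support


def _supported_ancestor(
    gtree: GeneTree, nd: dendropy.Node, min_support: float
) -> tuple[dendropy.Node, bool]:
    """First ancestor of ``nd`` whose support passes the filter; the root is
    accepted unconditionally. Second value is False when the walk fell back
    to an unsupported root."""
    anc = nd.parent_node
    if anc is None:
        return nd, True
    while anc.parent_node is not None and not _passes_support(anc, min_support):
        anc = anc.parent_node
    ok = anc.parent_node is not None or _passes_support(anc, min_support)
    return anc, ok


def _sister_leaves(gtree: GeneTree, nd: dendropy.Node, min_support: float) -> list[str]:
    anc, _ = _supported_ancestor(gtree, nd, min_support)
    group = {lf.taxon.label for lf in nd.leaf_iter()}
    return [lf.taxon.label for lf in anc.leaf_iter() if lf.taxon.label not in group]


def extract_group_subtree(
    gtree: GeneTree, group: ExpansionGroup, min_support: float = 0.70
) -> GeneTree:
    """Extract the smallest subtree containing ``group`` plus its sister
    clade, requiring the subtending node's support to be at least
    ``min_support``; the walk moves rootward past low-support nodes until
    the condition holds (the root is accepted with a warning).

    Branch lengths and support labels are preserved verbatim.
    """
    nd = gtree.node(group.node_id)
    anc, ok = _supported_ancestor(gtree, nd, min_support)
    if not ok:
        warnings.warn(
            "no ancestor with sufficient support below the root; returning the "
            "subtree at the root",
            stacklevel=2,
        )
    group.sister_genes = [
        lf.taxon.label
        for lf in anc.leaf_iter()
        if lf.taxon.label not in set(group.member_genes)
    ]
    return parse_newick(_newick_string(anc) + ";", gtree.scheme)


# ---------------------------------------------------------------------------
# Patristic divergence
# ---------------------------------------------------------------------------


def patristic_distance_matrix(gtree: GeneTree) -> tuple[list[str], np.ndarray]:
    """Leaf labels and the dense matrix of path-sum (patristic) distances."""
    for nd in gtree.tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            raise TreeError(f"missing branch length above node {_node_desc(nd)}")
    pdm = gtree.tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in gtree.tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    n = len(taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            dist[i, j] = dist[j, i] = d
    return labels, dist


def patristic_divergence_summary(
    gtree: GeneTree, group: ExpansionGroup, reference_species: set[str]
) -> DivergenceSummary:
    """Median and quartiles of each group member's patristic distance to its
    *nearest* reference-species leaf — how far, in substitutions per site,
    the expanded copies sit from their closest relatives outside the focal
    lineage."""
    labels, dist = patristic_distance_matrix(gtree)
    idx = {lab: i for i, lab in enumerate(labels)}
    ref_idx = [i for i, lab in enumerate(labels) if gtree.species_of(lab) in reference_species]
    if not ref_idx:
        raise TreeError(f"no leaves from reference species {sorted(reference_species)}")
    missing = [m for m in group.member_genes if m not in idx]
    if missing:
        raise TreeError(f"group members not in tree: {missing}")
    minima = np.array(
        [dist[idx[m], ref_idx].min() for m in group.member_genes], dtype=float
    )
    q1, med, q3 = np.percentile(minima, [25, 50, 75])
    return DivergenceSummary(median=float(med), q1=float(q1), q3=float(q3), n=len(minima))


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------


def groups_to_records(groups: list[ExpansionGroup]) -> list[dict]:
    return [
        {
            "group_id": f"group{g.rank}",
            "node_id": g.node_id,
            "size": g.size,
            "support": g.support,
            "species": ",".join(sorted(g.member_species)),
            "members": ",".join(g.member_genes),
        }
        for g in groups
    ]


def write_groups_tsv(groups: list[ExpansionGroup], path: str) -> None:
    import pandas as pd

    pd.DataFrame(groups_to_records(groups)).to_csv(path, sep="\t", index=False)
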