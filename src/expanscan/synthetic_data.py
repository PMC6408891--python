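"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without downloads: the
generators here emit gene trees with planted lineage-restricted duplication
bursts, tissue-structured expression matrices mixing broad and
tissue-specific genes, codon alignments evolved under known per-branch
dN/dS, and scaffold layouts mixing tandem-clustered and dispersed genes —
each paired with a machine-readable truth table.

Defaults emulate the shape of a cephalopod GPCR-style study: 16 bilaterian
species of which three are the focal cephalopod lineage, four planted
expansions (two spanning all three cephalopods, two restricted to the two
octopuses), 12 expression tissues, and codon alignments of a few hundred
codons per group. A single root seed expands into per-generator
sub-streams, so each generator is independently reproducible:
byte-identical outputs under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codonsel.alignment import CodonAlignment
from .codonsel.genetic_code import N_CODONS
from .codonsel.model import SpectralQ, equal_frequencies
from .treeops import GeneTree, LabelScheme, parse_newick

__all__ = [
    "PlantedClade",
    "TreeSpec",
    "ExpressionSpec",
    "CodonSpec",
    "ScaffoldSpec",
    "SimulationConfig",
    "simulate_gene_tree",
    "simulate_expression",
    "simulate_codon_alignment",
    "simulate_scaffolds",
    "simulate_bundle",
]

SPECIES_16 = (
    "ANOGA", "DROME", "CAEEL", "CAPTE", "HELRO", "SCHMA", "STRPU", "SACKO",
    "BRAFL", "HUMAN", "LOTGI", "MIZYE", "CRAGI", "OCTBM", "OCMIN", "ESCOL",
)
CEPHALOPODS = ("OCTBM", "OCMIN", "ESCOL")
OCTOPUSES = ("OCTBM", "OCMIN")

TISSUES_12 = (
    "sucker", "testes", "st15", "ova", "skin", "psg",
    "viscera", "sub", "supra", "ol", "anc", "retina",
)


@dataclass(frozen=True)
class PlantedClade:
    """A duplication burst to graft into the gene tree: ``size`` leaves
    drawn from ``species`` only, attached by a stem of ``stem_length``
    substitutions/site."""

    species: tuple[str, ...]
    size: int
    stem_length: float = 0.6

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("planted clade size must be >= 2")
        if self.stem_length <= 0:
            raise ValueError("stem length must be positive")


@dataclass(frozen=True)
class TreeSpec:
    species: tuple[str, ...] = SPECIES_16
    focal_species: tuple[str, ...] = CEPHALOPODS
    n_background_genes: int = 160
    planted: tuple[PlantedClade, ...] = (
        PlantedClade(CEPHALOPODS, 14),
        PlantedClade(CEPHALOPODS, 10),
        PlantedClade(OCTOPUSES, 10),
        PlantedClade(OCTOPUSES, 12),
    )
    background_branch_mean: float = 0.35  # subs/site; sets inter-clade divergence
    planted_branch_mean: float = 0.10     # within-burst divergence
    background_support: tuple[float, float] = (0.40, 1.00)
    planted_support: tuple[float, float] = (0.92, 1.00)


@dataclass(frozen=True)
class ExpressionSpec:
    tissues: tuple[str, ...] = TISSUES_12
    specific_fraction: float = 0.5        # background genes that are tissue specific
    group_specific_fraction: float = 0.95 # expanded-group genes that are specific
    dominance_fold: float = 50.0          # dominant-tissue mean over baseline
    dispersion: float = 0.2               # gamma noise coefficient of variation
    baseline: float = 5.0                 # broad-expression mean (TPM-like units)

    def __post_init__(self):
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")
        if self.dominance_fold <= 1:
            raise ValueError("dominance fold must exceed 1")


@dataclass(frozen=True)
class CodonSpec:
    n_codons: int = 300
    kappa: float = 2.0
    omega_background: float = 0.2
    #: one value per planted group (recycled when shorter); the default
    #: mimics three groups under positive selection and one under purifying
    #: selection.
    omega_foreground: tuple[float, ...] = (2.0, 2.0, 2.0, 0.306)
    tree_scale: float = 1.0  # multiplies tree lengths -> subs/codon

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


@dataclass(frozen=True)
class ScaffoldSpec:
    #: enough scaffolds that non-clustered genes land mostly alone, as in a
    #: fragmented draft assembly
    n_scaffolds: int = 120
    #: tandem-array sizes planted per group (recycled over groups);
    #: remaining group genes are scattered on non-array scaffolds.
    array_sizes: tuple[tuple[int, ...], ...] = ((4,), (3,), (4,), (3, 3))
    intervening_rate: float = 1.0  # Poisson mean of filler genes between members
    #: unrelated (non-family) genes providing the genomic background the
    #: intervening-gene counts are measured against
    n_other_genes: int = 600
    gene_length: tuple[int, int] = (1_000, 5_000)
    gap_length: tuple[int, int] = (2_000, 20_000)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    tree: TreeSpec = TreeSpec()
    expression: ExpressionSpec = ExpressionSpec()
    codon: CodonSpec = CodonSpec()
    scaffold: ScaffoldSpec = ScaffoldSpec()


# ---------------------------------------------------------------------------
# Gene tree with planted expansions
# ---------------------------------------------------------------------------


class _TN:
    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label=None, children=None, length=None, support=None):
        self.label = label
        self.children = children or []
        self.length = length
        self.support = support


def _newick(nd: _TN) -> str:
    if not nd.children:
        s = nd.label
    else:
        s = "(" + ",".join(_newick(c) for c in nd.children) + ")"
        if nd.support is not None:
            s += f"{nd.support:.3f}"
    if nd.length is not None:
        s += f":{nd.length:.6f}"
    return s


def _random_binary(leaves: list[_TN], rng, branch_mean: float) -> _TN:
    """Random topology by sequential joins; edge lengths exponential."""
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.exponential(branch_mean)) + 1e-4
        b.length = float(rng.exponential(branch_mean)) + 1e-4
        nodes.append(_TN(children=[a, b]))
    return nodes[0]


def _internal_nodes(nd: _TN, skip_root=True):
    out = []

    def walk(n, is_root):
        if n.children:
            if not (is_root and skip_root):
                out.append(n)
            for c in n.children:
                walk(c, False)

    walk(nd, True)
    return out


def simulate_gene_tree(
    spec: TreeSpec = TreeSpec(), seed: int = 0
) -> tuple[GeneTree, list[dict]]:
    """Gene tree with planted focal-only clades; returns (tree, truth).

    The background is a random-join topology over genes assigned uniformly
    to all species; each planted burst is a random binary clade over its
    own species set, grafted onto a random background edge with a positive
    stem. Support values are drawn high on planted nodes, broad on the
    background. Truth lists, per planted clade, its leaf labels and
    species set.
    """
    for pc in spec.planted:
        if not set(pc.species) <= set(spec.focal_species):
            raise ValueError(f"planted species {pc.species} not within focal set")
        if pc.size > 10 * len(pc.species) * 1000:
            raise ValueError("requested clade larger than feasible")
    if spec.n_background_genes < 3:
        raise ValueError("need at least 3 background genes")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    leaves = []
    for k in range(spec.n_background_genes):
        sp = spec.species[int(rng.integers(len(spec.species)))]
        leaves.append(_TN(label=f"{sp}_g{k:04d}"))
    root = _random_binary(leaves, rng, spec.background_branch_mean)

    truth = []
    for e, pc in enumerate(spec.planted, start=1):
        members = []
        for i in range(pc.size):
            sp = pc.species[i % len(pc.species)]
            members.append(_TN(label=f"{sp}_x{e}{i:03d}"))
        crown = _random_binary(members, rng, spec.planted_branch_mean)
        crown.length = pc.stem_length
        # graft onto a random non-root edge whose subtree holds at least one
        # non-focal leaf: attaching next to an all-focal subtree would fuse
        # the planted clade with it into a larger focal-only node and the
        # truth table would no longer match the maximal detected clade
        focal = set(spec.focal_species)
        host_pool = []

        def collect(n, is_root):
            leaves_all_focal = _all_leaves_focal(n, focal)
            if not is_root and not leaves_all_focal:
                host_pool.append(n)
            for c in n.children:
                collect(c, False)

        collect(root, True)
        host = host_pool[int(rng.integers(len(host_pool)))]
        parent = _find_parent(root, host)
        u = float(rng.uniform(0.25, 0.75))
        joint = _TN(children=[host, crown], length=host.length * (1 - u))
        host.length = host.length * u
        parent.children[parent.children.index(host)] = joint
        for nd in _internal_nodes(crown, skip_root=False):
            nd.support = float(rng.uniform(*spec.planted_support))
        truth.append(
            {
                "clade": e,
                "members": [m.label for m in members],
                "species": sorted(set(pc.species)),
                "size": pc.size,
            }
        )

    for nd in _internal_nodes(root):
        if nd.support is None:
            nd.support = float(rng.uniform(*spec.background_support))
    gtree = parse_newick(_newick(root) + ";", LabelScheme())
    return gtree, truth


def _all_leaves_focal(nd: _TN, focal: set[str]) -> bool:
    if not nd.children:
        return nd.label.split("_", 1)[0] in focal
    return all(_all_leaves_focal(c, focal) for c in nd.children)


def _find_parent(root: _TN, target: _TN) -> _TN:
    for nd in [root] + _internal_nodes(root, skip_root=False):
        if target in nd.children:
            return nd
    raise RuntimeError("node not in tree")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    spec: ExpressionSpec,
    genes: list[str],
    group_assignment: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x tissue matrix plus per-gene truth (class, dominant tissue).

    Tissue-specific genes get one dominant tissue at ``dominance_fold``
    times the baseline mean; broad genes are uniform at baseline. Values
    carry gamma noise with CV = ``dispersion`` (zero dispersion yields the
    means exactly). Genes of one expanded group share the group's dominant
    tissue, emulating concerted expression of tandem duplicates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tissues = list(spec.tissues)
    group_assignment = group_assignment or {}
    group_tissue: dict[str, str] = {}
    for g in sorted({v for v in group_assignment.values()}):
        group_tissue[g] = tissues[int(rng.integers(len(tissues)))]

    records, truth = [], []
    for gene in genes:
        group = group_assignment.get(gene)
        frac = spec.group_specific_fraction if group is not None else spec.specific_fraction
        specific = bool(rng.random() < frac)
        if group is not None:
            dom = group_tissue[group]
        else:
            dom = tissues[int(rng.integers(len(tissues)))]
        means = np.full(len(tissues), spec.baseline)
        if specific:
            means[tissues.index(dom)] = spec.baseline * spec.dominance_fold
        if spec.dispersion > 0:
            shape = 1.0 / spec.dispersion**2
            x = rng.gamma(shape, means / shape)
        else:
            x = means.copy()
        records.append(x)
        truth.append(
            {
                "gene": gene,
                "class": "specific" if specific else "broad",
                "dominant_tissue": dom if specific else None,
                "group": group,
            }
        )
    matrix = pd.DataFrame(records, index=pd.Index(genes, name="gene"), columns=tissues)
    return matrix, pd.DataFrame(truth).set_index("gene")


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------


def simulate_codon_alignment(
    gtree: GeneTree,
    n_codons: int = 300,
    kappa: float = 2.0,
    omega_background: float = 0.2,
    foreground_leaves: set[str] | None = None,
    omega_foreground: float | None = None,
    site_omegas: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    tree_scale: float = 1.0,
    seed: int = 0,
) -> tuple[CodonAlignment, dict]:
    """Evolve a codon alignment along ``gtree`` under the scaled GY94 model.

    The root sequence is drawn from the stationary frequencies and each
    branch applies its exact transition matrix (spectral exp(Qt)), so there
    are no internal stops by construction. Branch lengths are tree lengths
    times ``tree_scale``, in expected substitutions/codon. Branches inside
    the clade spanned by ``foreground_leaves`` (if given) use
    ``omega_foreground``; ``site_omegas`` (one dN/dS per codon site, applied
    tree-wide) supports sites-model simulations instead.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if site_omegas is not None and foreground_leaves is not None:
        raise ValueError("per-site and per-branch omegas are mutually exclusive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    freqs = equal_frequencies() if freqs is None else np.asarray(freqs, float)

    fg_nodes: set[int] = set()
    if foreground_leaves:
        mrca = gtree.tree.mrca(taxon_labels=sorted(foreground_leaves))
        for nd in mrca.postorder_iter():
            if nd is not mrca:
                fg_nodes.add(id(nd))
        if omega_foreground is None:
            raise ValueError("omega_foreground required with foreground_leaves")

    if site_omegas is None:
        site_class = np.zeros(n_codons, dtype=int)
        class_omegas = [omega_background]
        if fg_nodes:
            class_omegas.append(omega_foreground)
    else:
        site_omegas = np.asarray(site_omegas, dtype=float)
        if site_omegas.shape != (n_codons,):
            raise ValueError("site_omegas must have one value per codon")
        uniq = np.unique(site_omegas)
        site_class = np.searchsorted(uniq, site_omegas)
        class_omegas = list(uniq)

    spectra = {w: SpectralQ(freqs, kappa, w) for w in set(class_omegas)}

    root_states = rng.choice(N_CODONS, size=n_codons, p=freqs / freqs.sum())
    states: dict[int, np.ndarray] = {id(gtree.tree.seed_node): root_states}
    seqs: dict[str, str] = {}
    from .codonsel.genetic_code import CODONS

    for nd in gtree.tree.preorder_node_iter():
        if nd.parent_node is None:
            cur = root_states
        else:
            bl = nd.edge.length
            if bl is None:
                raise ValueError("tree has a missing branch length")
            t = float(bl) * tree_scale
            parent_states = states[id(nd.parent_node)]
            cur = np.empty(n_codons, dtype=int)
            if site_omegas is None:
                w = omega_foreground if id(nd) in fg_nodes else omega_background
                site_w = np.zeros(n_codons, dtype=int)
                P = {0: spectra[w].P(t)}
            else:
                site_w = site_class
                P = {c: spectra[class_omegas[c]].P(t) for c in np.unique(site_class)}
            for c in np.unique(site_w):
                sel = site_w == c
                Pc = P[c]
                for s in np.unique(parent_states[sel]):
                    mask = sel & (parent_states == s)
                    cur[mask] = rng.choice(N_CODONS, size=int(mask.sum()), p=Pc[s])
            states[id(nd)] = cur
        if nd.is_leaf():
            seqs[nd.taxon.label] = "".join(CODONS[s] for s in cur)

    aln = CodonAlignment(list(seqs), seqs)
    truth = {
        "kappa": kappa,
        "omega_background": omega_background,
        "omega_foreground": omega_foreground,
        "foreground_leaves": sorted(foreground_leaves) if foreground_leaves else [],
        "site_omegas": site_omegas.tolist() if site_omegas is not None else None,
        "tree_scale": tree_scale,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Scaffold layout
# ---------------------------------------------------------------------------


def simulate_scaffolds(
    genes: list[str],
    group_assignment: dict[str, str],
    spec: ScaffoldSpec = ScaffoldSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Scaffold layout with planted tandem arrays; returns (loci, truth).

    For each group, arrays of the configured sizes are placed on dedicated
    scaffolds with Poisson-distributed intervening filler genes between
    consecutive members; the group's remaining genes, the non-expanded
    family genes, and ``n_other_genes`` unrelated filler genes are
    scattered over the other scaffolds (filler genes carry no group label
    and stand for the rest of the gene complement — the background that
    intervening-gene counts are measured against). Intervals never overlap
    within a scaffold. Truth lists each planted array's member ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    groups = sorted({g for g in group_assignment.values()})
    members = {g: [x for x in genes if group_assignment.get(x) == g] for g in groups}
    family_background = [x for x in genes if x not in group_assignment]
    filler = [f"other{k:05d}" for k in range(spec.n_other_genes)]

    scaffolds = [f"Scaffold{k:05d}" for k in range(1, spec.n_scaffolds + 1)]
    layout: dict[str, list[tuple[str, str | None]]] = {s: [] for s in scaffolds}
    truth: list[dict] = []
    filler_pool = list(filler)

    next_scaffold = 0
    for gi, g in enumerate(groups):
        sizes = spec.array_sizes[gi % len(spec.array_sizes)]
        pool = list(members[g])
        for size in sizes:
            take = min(size, len(pool))
            if take < 2:
                break
            array, pool = pool[:take], pool[take:]
            if next_scaffold >= len(scaffolds):
                raise ValueError("not enough scaffolds for the requested arrays")
            scaf = scaffolds[next_scaffold]
            next_scaffold += 1
            for k, gene in enumerate(array):
                layout[scaf].append((gene, g))
                if k < len(array) - 1:
                    for _ in range(int(rng.poisson(spec.intervening_rate))):
                        if filler_pool:
                            layout[scaf].append((filler_pool.pop(), None))
            truth.append({"group": g, "scaffold": scaf, "members": array})
        members[g] = pool  # leftovers get scattered

    scatter_scaffolds = scaffolds[next_scaffold:] or scaffolds
    scattered = (
        [(x, group_assignment.get(x)) for g in groups for x in members[g]]
        + [(x, "non_expanded") for x in family_background]
        + [(x, None) for x in filler_pool]
    )
    placement: dict[str, list[tuple[str, str | None]]] = {s: [] for s in scatter_scaffolds}
    for gene, grp in scattered:
        placement[scatter_scaffolds[int(rng.integers(len(scatter_scaffolds)))]].append(
            (gene, grp)
        )
    for scaf, entries in placement.items():
        order = rng.permutation(len(entries))
        layout[scaf].extend(entries[k] for k in order)

    rows = []
    for scaf in scaffolds:
        pos = int(rng.integers(1_000, 10_000))
        for gene, grp in layout[scaf]:
            length = int(rng.integers(*spec.gene_length))
            rows.append(
                {
                    "scaffold": scaf,
                    "start": pos,
                    "stop": pos + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "gene": gene,
                    "group": grp,
                }
            )
            pos += length + int(rng.integers(*spec.gap_length))
    loci = pd.DataFrame(rows)
    return loci, truth


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


def simulate_bundle(config: SimulationConfig, outdir) -> dict:
    """Write a complete synthetic input bundle for the pipeline.

    Produces tree.nwk, expression.tsv, loci.tsv, one codon alignment and
    subtree per planted group (group leaves plus a trimmed outgroup of at
    most four sister sequences, keeping the model fits desk-sized), and
    JSON truth tables. Returns the manifest of written paths.
    """
    from pathlib import Path

    from .codonsel.alignment import write_fasta
    from .treeops import ExpansionGroup, extract_group_subtree

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    s_tree, s_expr, s_codon, s_scaf = np.random.SeedSequence(config.seed).spawn(4)
    rng_codon = np.random.default_rng(s_codon)

    gtree, clade_truth = simulate_gene_tree(config.tree, seed=_small(s_tree))
    (out / "tree.nwk").write_text(gtree.to_newick() + "\n")

    genes = gtree.leaf_labels()
    group_assignment = {
        m: f"group{t['clade']}" for t in clade_truth for m in t["members"]
    }
    matrix, expr_truth = simulate_expression(
        config.expression, genes, group_assignment, seed=_small(s_expr)
    )
    matrix.to_csv(out / "expression.tsv", sep="\t")
    expr_truth.to_csv(out / "expression_truth.tsv", sep="\t")

    selection_units = []
    omegas = config.codon.omega_foreground
    for i, t in enumerate(clade_truth):
        name = f"group{t['clade']}"
        mrca = gtree.tree.mrca(taxon_labels=t["members"])
        group = ExpansionGroup(
            node_id=mrca.postorder_index,
            member_genes=t["members"],
            member_species=set(t["species"]),
            size=t["size"],
            support=None,
        )
        sub = extract_group_subtree(gtree, group, min_support=0.70)
        sub = _trim_outgroup(sub, set(t["members"]), max_outgroup=4)
        w_fg = omegas[i % len(omegas)]
        aln, codon_truth = simulate_codon_alignment(
            sub,
            n_codons=config.codon.n_codons,
            kappa=config.codon.kappa,
            omega_background=config.codon.omega_background,
            foreground_leaves=set(t["members"]),
            omega_foreground=w_fg,
            tree_scale=config.codon.tree_scale,
            seed=_small(rng_codon),
        )
        tree_path = out / f"{name}_subtree.nwk"
        aln_path = out / f"{name}_codon.fasta"
        tree_path.write_text(sub.to_newick() + "\n")
        write_fasta(aln.sequences, aln_path)
        selection_units.append(
            {"name": name, "alignment": str(aln_path), "tree": str(tree_path),
             "foreground": t["members"], "truth": codon_truth}
        )

    # scaffold coordinates exist for one sequenced genome only: restrict the
    # layout to genes of the first focal species (the reference assembly)
    ref = config.tree.focal_species[0]
    ref_genes = [g for g in genes if g.startswith(f"{ref}_")]
    loci, cluster_truth = simulate_scaffolds(
        ref_genes,
        {g: grp for g, grp in group_assignment.items() if g in set(ref_genes)},
        config.scaffold,
        seed=_small(s_scaf),
    )
    loci.to_csv(out / "loci.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "tree": str(out / "tree.nwk"),
        "expression": str(out / "expression.tsv"),
        "loci": str(out / "loci.tsv"),
        "selection_units": selection_units,
        "truth": {
            "clades": clade_truth,
            "clusters": cluster_truth,
        },
        "focal_species": sorted(config.tree.focal_species),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _small(seed_source) -> int:
    """A sub-seed below 2^31 from a SeedSequence or Generator."""
    if isinstance(seed_source, np.random.SeedSequence):
        return int(seed_source.generate_state(1)[0] % (2**31))
    return int(seed_source.integers(2**31))


def _trim_outgroup(sub: GeneTree, members: set[str], max_outgroup: int = 4) -> GeneTree:
    """Keep all group leaves but at most ``max_outgroup`` sister leaves."""
    others = [l for l in sub.leaf_labels() if l not in members]
    if len(others) <= max_outgroup:
        return sub
    keep = sorted(members) + sorted(others)[:max_outgroup]
    pruned = sub.tree.extract_tree_with_taxa_labels(keep)
    return parse_newick(pruned.as_string(schema="newick", suppress_rooting=True,
                                         unquoted_underscores=True), sub.scheme)
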