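# Methods

`expanscan` reimplements, as a tested pipeline, a family of analyses used to
characterize lineage-specific expansions of large receptor families
(prototypically the G-protein-coupled receptors of coleoid cephalopods):
finding lineage-restricted clades in gene trees, asking whether the
duplicated copies diverged in tissue expression, testing them for positive
selection under codon substitution models, and asking whether they sit in
tandem on genome scaffolds. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data do and do
not emulate.

## Expansion detection (treeops)

A gene tree over many species is scanned for nodes whose descendant leaves
all belong to a *focal* species set (e.g. the three cephalopods among 16
bilaterians). Such focal-only clades are the signature of duplication
bursts postdating the focal lineage's split. Nodes are ranked by
descendant count and retained when they reach a paralogue cutoff
(default 10) and, optionally, a local support threshold (default 0.70,
matching Shimodaira–Hasegawa-style supports emitted by fast ML programs).

Design choices where the procedure is genuinely open:

* **Maximality.** Nested focal-only nodes are collapsed to the maximal
  ones, so a burst is reported once rather than once per internal node.
  The test suite checks equivalence against brute-force enumeration of all
  nodes followed by maximality reduction.
* **Support as a retention filter.** The support threshold is applied to
  the ranked, maximal nodes (a property of retained groups), not during
  the traversal.
* **Rooting.** ML gene trees are unrooted; clade direction depends on
  rooting. Trees are used as seed-rooted by default, with explicit
  midpoint (`root_at_midpoint`) and outgroup (`root_at_outgroup`)
  rerooting available. Expansion calls can change under rerooting; the
  choice is the caller's.
* **Polytomies** qualify like any multifurcation if all descendants are
  focal.
* **Ties** in the size ranking break by postorder node index
  (deterministic).

For each group, the analysis subtree is the group plus its nearest sister
clade whose subtending node passes the support threshold, walking rootward
past weakly supported nodes (root accepted with a warning). Divergence is
summarized as the median and quartiles, over group members, of the
patristic distance to the nearest leaf from a designated reference species
set, in substitutions per site.

## Tissue specificity (expression)

For a gene with non-negative expression x₁..x_n over n ≥ 2 tissues,

    Tau = Σᵢ (1 − xᵢ / max_j x_j) / (n − 1),

0 for uniform expression, 1 for single-tissue expression, scale invariant.
Genes with Tau **strictly greater** than 0.8 are called tissue specific.
Expression proportions are xᵢ/Σx. All-zero genes have undefined Tau and
proportions; they are excluded from summaries but counted, never silently
dropped. No transform is applied by default (a `log1p` flag exists because
the Tau literature varies); raw normalized values (TPM-like) are used.
Matrices from different species are never compared on raw values — each
matrix is analysed independently.

Group contrasts use the Kruskal–Wallis rank test (tie-corrected H,
χ²_{k−1} p-value; the degenerate all-identical case is defined as H = 0,
p = 1), followed by Dunn's pairwise z tests on mean ranks with
tie-corrected pooled variance, two-sided, with Holm step-down adjustment
over the single family of all pairs. Group mean Tau is reported with a
95% normal-approximation CI (mean ± 1.96·se; a percentile bootstrap is
available via `ci="bootstrap"`), since small groups make the normal CI
only indicative.

## Codon models and selection tests (codonsel)

Protein-guided back-translation maps a gapped protein alignment onto its
coding sequences (residue → codon, gap → `---`; terminal stop stripped;
internal stops and translation mismatches are hard errors), so codon
columns correspond exactly to protein-alignment columns. Cleaning then
(1) removes codon columns whose residue fraction is below 0.25 and
(2) removes sequences whose *well-overlapped* residues (those sharing a
column with ≥ 25% of the other sequences) cover less than 90% of the
columns — the residue/sequence-overlap behaviour of standard alignment
trimmers, acting on whole codons.

The substitution model is Goldman–Yang-style over the 61 sense codons of
the standard code: q_ij = π_j · κ^[transition] · ω^[non-synonymous] for
single-nucleotide neighbours, 0 otherwise, with empirical F3×4 codon
frequencies by default (equal frequencies behind a flag). The generator is
scaled to one expected substitution per codon at stationarity, so branch
lengths are substitutions/codon. The chain is reversible; transition
matrices come from a symmetric eigendecomposition (one `eigh` per distinct
ω, then eigenvalue scaling per branch), and the likelihood is Felsenstein
pruning over compressed site patterns with gaps/ambiguities as missing
data. Pruning is verified against brute-force summation over internal-node
states to < 1e-8.

Model hierarchy and tests:

* **M0**: one ω tree-wide.
* **Branch (two-ratio)**: ω_fg on the branches inside the expanded clade
  (internal and terminal; stem optional), ω_bg elsewhere; LRT vs M0 with
  1 df. Branch fits with ω̂ > 100 (strict) are excluded from
  positive-selection reporting — such estimates usually reflect vanishing
  synonymous counts or alignment noise.
* **Sites (M1a vs M2a)**: M1a has classes (ω₀ < 1, ω₁ = 1) with free
  weights; M2a adds ω₂ > 1; LRT with 2 df. Per-site posteriors are naive
  empirical Bayes at the MLEs; sites are flagged at posterior ≥ 0.95 with
  ω̂₂ > 1. This is an approximation to Bayes empirical Bayes, which
  integrates over parameter uncertainty and is out of scope; NEB is
  anti-conservative when parameter estimates are noisy, so flagged sites
  on small alignments should be read with that caveat.

LRT statistics are clamped at zero; no boundary mixture-χ² correction is
applied (the plain χ²_k convention). Because the M2a parameterization can
only approach the M1a subspace (the ω₂ weight is a softmax component),
an M2a optimum marginally below M1a is replaced by the M1a value — the
supremum over the closure — and flagged "collapsed to M1a boundary".

Optimization is L-BFGS-B on log/logit-transformed parameters (κ init 2.0,
ω init 0.5, convergence 1e-10 on the objective; `multistart N` adds seeded
perturbed restarts). **Branch lengths:** by default the input tree's
lengths are kept up to one free rate-scale factor (`branch_mode="scale"`).
Input trees are ML trees whose relative lengths are already estimated;
the scale absorbs the site→codon unit change and dataset-specific rate
differences, and it keeps replicated calibration studies tractable.
`branch_mode="full"` frees every branch length (used, e.g., to verify that
identical sequences drive their branches to ~0); `"fixed"` uses the tree
as-is. Calibration results in the test suite (type-I error of the branch
LRT within [0.01, 0.10] at α = 0.05; median ω̂ within 25% at 500 codons/8
taxa) are under the default mode.

## Co-localization (genloc)

Gene coordinates are 0-based half-open internally (a flag converts 1-based
inclusive tables). Per group, the summary counts scaffolds occupied and
scaffolds carrying ≥ m members (default 3) — the "x out of y scaffolds"
statistic. Tandem clusters are maximal runs of ≥ 2 group members along a
scaffold with at most `max_intervening` (default 5) non-group genes
between consecutive members, counted against the full gene complement in
the table; when a scaffold lists only group genes, a base-pair gap
fallback (default 100 kb) is used and labelled as such. Strand is ignored
for clustering (tandem arrays tolerate inversions) but reported as a
pattern string. Clustering is reported descriptively; no enrichment test
is attached.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, each with a machine-readable truth table, under one root seed
that expands into independent per-generator streams (byte-identical
outputs per seed).

* **Gene trees**: a random-join background topology over 160 genes
  assigned uniformly to 16 species (3 focal), with exponential branch
  lengths (mean 0.35 subs/site); planted bursts (defaults 14/10/10/12
  leaves; two spanning all three focal species, two the two "octopus"
  species) are random subtrees with short internal branches (mean 0.10)
  grafted with a 0.6 stem onto an edge whose subtree contains at least one
  non-focal leaf — otherwise the planted clade would fuse with adjacent
  focal leaves and no longer equal the maximal detected clade. Planted
  nodes get support in [0.92, 1], background in [0.40, 1].
* **Expression**: specific genes have one dominant tissue at 50× a
  baseline of 5 (TPM-like) over 12 tissues; gamma noise with CV 0.2;
  expanded-group genes are 95% specific and share the group's dominant
  tissue (concerted expression of tandem duplicates), background genes 50%.
* **Codon alignments**: evolved exactly under the scaled model (root from
  stationarity, per-branch matrix exponentials), 300 codons by default,
  κ = 2, ω_bg = 0.2, per-group foreground ω of (2.0, 2.0, 2.0, 0.306) —
  three positively selected groups and one under purifying selection.
  Group alignments are simulated on the group-plus-outgroup subtree with
  the outgroup trimmed to ≤ 4 sequences to keep fits desk-sized.
* **Scaffolds**: tandem arrays on dedicated scaffolds with Poisson(1)
  intervening filler genes; everything else (leftover group genes,
  non-expanded family genes, 600 non-family filler genes) scattered over
  120 scaffolds; loci are restricted to the first focal species, since
  coordinates exist for one sequenced genome.

What the synthetic data do **not** emulate: real receptor sequence
composition or domain structure, alignment error (alignments are true by
construction), rate heterogeneity beyond the planted ω structure,
expression correlation between tissues, assembly artefacts. Passing tests
therefore demonstrate correctness and calibration of the machinery under
its own model assumptions — not robustness to misalignment or model
misspecification in real data.

## Problem sizes

Default scales are chosen so the complete synthetic pipeline runs in well
under five minutes on one CPU: 200-odd leaf trees for detection, 400-gene
expression matrices, 300–500-codon alignments on 5–15 taxa for model fits,
100–200 replicates for calibration studies. The acceptance script uses the
same generators end to end with sub-seeded streams derived from its
`--seed`.

## Known limitations

* Expansion calls depend on rooting; only maximal clades are reported.
* The NEB site test is anti-conservative relative to BEB on small data.
* The default branch-length treatment conditions on the input tree's
  relative lengths; strongly misestimated input lengths bias ω̂ (use
  `branch_mode="full"` where that is a concern).
* The normal-approximation CI on mean Tau is only indicative for groups of
  fewer than ~10 genes.
* Co-localization denominators (scaffold counts) are properties of the
  input table, not of any fixed reference assembly.
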