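# expanscan

Analysis of **lineage-specific gene-family expansions** from gene trees,
expression matrices, codon alignments and genome coordinates — the
workflow used to characterize bursts of receptor duplication (such as the
G-protein-coupled receptor expansions of coleoid cephalopods) and ask what
the duplicated copies did next: diverge in tissue expression, evolve under
positive selection, and/or remain physically clustered as tandem arrays.

It is written for molecular evolution researchers who have a multi-species
gene tree in hand (with branch lengths in substitutions/site and local
support values), plus per-species expression matrices and gene coordinates,
and want a reproducible, tested path from that tree to biology-level
summaries.

## What it computes

1. **Expansion detection** (`expanscan.treeops`). Maximal clades whose
   leaves all belong to a focal species set, ranked by size, retained at a
   paralogue cutoff (default ≥ 10) and a node-support threshold (default
   0.70); each group is extracted together with its nearest well-supported
   sister clade, and divergence to the closest non-focal relatives is
   summarized as patristic-distance quartiles.
2. **Tissue specificity** (`expanscan.expression`). The specificity index
   Tau = Σᵢ(1 − xᵢ/max x)/(n−1) ∈ [0, 1], with genes called tissue
   specific at Tau > 0.8; expression proportions xᵢ/Σx; group contrasts by
   Kruskal–Wallis with Dunn's post hoc test and Holm adjustment.
3. **Positive selection** (`expanscan.codonsel`). Protein-guided
   back-translation to codon alignments, overlap-based cleaning, and
   Goldman–Yang (GY94) codon models — q_ij ∝ π_j·κ^[ts]·ω^[nonsyn] with
   F3×4 frequencies — fitted by maximum likelihood: M0 (one ω), the
   two-ratio branch model (foreground = branches inside the expanded
   clade; χ²₁ LRT), and M1a/M2a sites models (χ²₂ LRT, NEB site
   posteriors). Branch fits with ω̂ > 100 are excluded from
   positive-selection calls.
4. **Co-localization** (`expanscan.genloc`). Scaffold occupancy per group
   ("x out of y scaffolds carry ≥ 3 members") and tandem clusters: maximal
   runs of group members separated by at most 5 intervening non-group
   genes.
5. **Synthetic data** (`expanscan.synthetic_data`). Deterministic,
   seed-driven generators for all the above inputs with planted ground
   truth, so every stage is testable end to end without downloads.

A pipeline module plus a `expanscan` CLI (`simulate`, `detect`, `tau`,
`selection`, `coloc`, `run-all`, `report`) orchestrate the stages and emit
TSV/JSON outputs and a machine-readable report.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Generate a synthetic study (four planted expansions among 16 species,
three of them focal) and run the full pipeline:

```sh
expanscan simulate --seed 42 --outdir demo
# write a config pointing at the bundle (demo/manifest.json lists paths),
# then:
expanscan run-all --config demo/config.yaml
expanscan report --report demo_results/report.json
```

which prints:

```
expanscan 0.1.0 report (seed 1)
  [     ok] detect
  [     ok] subtrees
  [     ok] expression
  [     ok] selection
  [     ok] colocalization
  group1: size=14  mean_tau=0.978 top=supra  lrt_p=1.92e-46 w_fg=2.05 *positive selection*  clusters=1
  group2: size=12  mean_tau=0.921 top=psg  lrt_p=1.61e-41 w_fg=1.78 *positive selection*  clusters=1
  group3: size=10  mean_tau=0.907 top=skin  lrt_p=1.29e-23 w_fg=1.88 *positive selection*  clusters=1
  group4: size=10  mean_tau=0.979 top=skin  lrt_p=0.0844 w_fg=0.342  clusters=2
  non_expanded: size=None  mean_tau=0.638 top=ova  clusters=0
```

Reading this: four lineage-restricted groups were detected (sizes 14, 12,
10, 10 — exactly the planted bursts). All four are strongly tissue
specific (mean Tau ≫ 0.8) with a named top tissue, versus 0.64 for the
non-expanded background. The branch test rejects homogeneous ω for groups
1–3 (foreground ω̂ ≈ 1.8–2.0 > 1: positive selection; the generator
planted ω_fg = 2.0 there) but not for group 4 (ω̂ = 0.342, purifying;
planted 0.306). Each group also forms at least one tandem cluster on a
scaffold, while the non-expanded genes are dispersed.

The same objects are available as a library:

```python
from expanscan import parse_newick, find_lineage_expansions

tree = parse_newick(open("genes.nwk").read())
groups = find_lineage_expansions(tree, {"OCTBM", "OCMIN", "ESCOL"},
                                 cutoff=10, min_support=0.70)
```

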