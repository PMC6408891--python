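"""End-to-end orchestration: detect expansions, profile expression, test
for positive selection, and map co-localization, with a machine-readable
report.

Stages run in a fixed order (detect -> subtrees -> expression -> selection
-> co-localization -> report) and communicate only through their written
outputs. Per-group selection analyses are independent: a failing fit in
one group is recorded in the report and does not abort the others. Given
unchanged inputs, config and seed, every numeric output is reproduced
exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codonsel import (
    CodonAlignment,
    filter_high_omega,
    fit_branch_model,
    fit_m0,
    fit_sites_models,
    lrt,
    read_fasta,
)
from .expression import compare_groups, read_expression_tsv, summarize_by_group, tau_table
from .genloc import clusters_to_frame, detect_tandem_clusters, read_loci, scaffold_summary
from .treeops import (
    extract_group_subtree,
    find_lineage_expansions,
    groups_to_records,
    read_newick,
)

log = logging.getLogger("expanscan.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Defaults follow the analysis conventions for this kind of study:
    expansion cutoff of 10 paralogues, minimum node support 0.70, Tau
    specificity threshold 0.8, selection test level 0.05, and discarding
    branch fits with omega > 100.
    """

    tree: str
    focal_species: list[str]
    expression: str | None = None
    loci: str | None = None
    #: list of {name, alignment, tree} mappings for per-group selection tests
    selection_units: list[dict] = field(default_factory=list)
    outdir: str = "results"
    cutoff: int = 10
    min_support: float = 0.70
    tau_threshold: float = 0.8
    alpha: float = 0.05
    omega_limit: float = 100.0
    tandem_max_intervening: int = 5
    run_sites_test: bool = True
    branch_mode: str = "scale"
    log1p: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (2 <= self.cutoff):
            raise ValueError("cutoff must be >= 2")
        for v, name, lo, hi in [
            (self.min_support, "min_support", 0, 1),
            (self.tau_threshold, "tau_threshold", 0, 1),
            (self.alpha, "alpha", 0, 1),
        ]:
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must be in [{lo}, {hi}]")
        for path in [self.tree, self.expression, self.loci] + [
            u["alignment"] for u in self.selection_units
        ] + [u["tree"] for u in self.selection_units]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input not found: {path}")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the report dictionary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
        "groups": {},
    }

    # ---- stage 1: expansion detection -------------------------------------
    gtree = read_newick(config.tree)
    groups = find_lineage_expansions(
        gtree, set(config.focal_species), cutoff=config.cutoff,
        min_support=config.min_support,
    )
    records = groups_to_records(groups)
    pd.DataFrame(records).to_csv(out / "groups.tsv", sep="\t", index=False)
    with open(out / "groups.json", "w") as fh:
        json.dump(records, fh, indent=2)
    report["stages"]["detect"] = {"status": "ok", "n_groups": len(groups)}
    for rec, g in zip(records, groups):
        report["groups"][rec["group_id"]] = {
            "size": g.size, "support": g.support, "species": sorted(g.member_species),
        }
    log.info("detect: %d expansion group(s)", len(groups))
    if not groups:
        report["stages"]["subtrees"] = {"status": "skipped", "reason": "no groups"}

    # ---- stage 2: subtree extraction ---------------------------------------
    member_to_group = {}
    if groups:
        for rec, g in zip(records, groups):
            sub = extract_group_subtree(gtree, g, min_support=config.min_support)
            (out / f"{rec['group_id']}_subtree.nwk").write_text(sub.to_newick() + "\n")
            for m in g.member_genes:
                member_to_group[m] = rec["group_id"]
        report["stages"]["subtrees"] = {"status": "ok"}

    # ---- stage 3: expression -----------------------------------------------
    if config.expression:
        matrix = read_expression_tsv(config.expression)
        unmatched = sorted(set(member_to_group) - set(matrix.index))
        tt = tau_table(matrix, threshold=config.tau_threshold, log1p=config.log1p)
        tt.to_csv(out / "tau.tsv", sep="\t")
        summary = summarize_by_group(
            matrix, member_to_group, threshold=config.tau_threshold,
            log1p=config.log1p, seed=config.seed,
        )
        summary.to_csv(out / "tau_by_group.tsv", sep="\t")
        stage = {"status": "ok", "n_genes": len(matrix),
                 "genes_in_groups_missing_from_matrix": unmatched}
        if len(summary) >= 2:
            kw, pairwise = compare_groups(matrix, member_to_group, log1p=config.log1p)
            pairwise.to_csv(out / "tau_pairwise.tsv", sep="\t", index=False)
            stage["kruskal_wallis"] = {"H": kw.H, "df": kw.df, "p_value": kw.p_value}
        report["stages"]["expression"] = stage
        for gid, row in summary.iterrows():
            report["groups"].setdefault(gid, {})["tau"] = {
                "mean": row["mean_tau"],
                "ci": [row["tau_ci_low"], row["tau_ci_high"]],
                "frac_specific": row["frac_specific"],
                "top_tissue": row["top_tissue"],
            }
    else:
        report["stages"]["expression"] = {"status": "skipped", "reason": "no matrix"}

    # ---- stage 4: selection tests ------------------------------------------
    omega_by_group: dict[str, float] = {}
    for unit in config.selection_units:
        name = unit["name"]
        entry: dict = {"status": "ok"}
        try:
            seqs = read_fasta(unit["alignment"])
            aln = CodonAlignment(list(seqs), seqs)
            sub = read_newick(unit["tree"])
            # foreground clade: explicit leaf list if given, else the
            # detected group's members, else all focal-species leaves
            leaves = set(sub.leaf_labels())
            if unit.get("foreground"):
                fg = set(unit["foreground"]) & leaves
            elif name in report["groups"] and name in {r["group_id"] for r in records}:
                members = next(
                    g.member_genes for rec, g in zip(records, groups)
                    if rec["group_id"] == name
                )
                fg = set(members) & leaves
            else:
                fg = {
                    l for l in leaves
                    if sub.species_of(l) in set(config.focal_species)
                }
            m0 = fit_m0(aln, sub, branch_mode=config.branch_mode, seed=config.seed)
            br = fit_branch_model(
                aln, sub, foreground=fg, branch_mode=config.branch_mode,
                seed=config.seed,
            )
            test = lrt(m0, br, df=1)
            w_fg = br.params["omega_foreground"]
            entry.update(
                m0={"log_likelihood": m0.log_likelihood, "omega": m0.params["omega"],
                    "kappa": m0.params["kappa"], "converged": m0.converged},
                branch={
                    "log_likelihood": br.log_likelihood,
                    "omega_foreground": w_fg,
                    "omega_background": br.params["omega_background"],
                    "converged": br.converged,
                },
                lrt={"statistic": test.statistic, "df": test.df, "p_value": test.p_value},
            )
            omega_by_group[name] = w_fg
            entry["positive_selection"] = bool(
                test.p_value < config.alpha and 1.0 < w_fg <= config.omega_limit
            )
            if config.run_sites_test:
                sites = fit_sites_models(
                    aln, sub, branch_mode=config.branch_mode, seed=config.seed
                )
                sites.posteriors.to_csv(out / f"{name}_site_posteriors.tsv",
                                        sep="\t", index=False)
                entry["sites"] = {
                    "lrt_p": sites.lrt.p_value,
                    "omega2": sites.m2a.params["class_omegas"][2],
                    "positive_sites": sites.positive_sites,
                }
        except Exception as exc:  # keep other groups running
            log.exception("selection stage failed for %s", name)
            entry = {"status": "failed", "error": str(exc)}
        report["groups"].setdefault(name, {})["selection"] = entry

    kept, excluded = filter_high_omega(omega_by_group, limit=config.omega_limit)
    report["stages"]["selection"] = {
        "status": "ok" if config.selection_units else "skipped",
        "omega_filter_excluded": excluded,
    }

    # ---- stage 5: co-localization ------------------------------------------
    if config.loci:
        loci = read_loci(config.loci)
        if all(l.group is None for l in loci) and member_to_group:
            from .genloc import GeneLocus

            loci = [
                GeneLocus(l.gene, l.scaffold, l.start, l.stop, l.strand,
                          member_to_group.get(l.gene, "non_expanded"))
                for l in loci
            ]
        summary = scaffold_summary(loci, m=3)
        summary.to_frame().to_csv(out / "scaffold_summary.tsv", sep="\t", index=False)
        all_clusters = []
        coloc: dict = {}
        for grp in sorted(summary.per_group):
            clusters = detect_tandem_clusters(
                loci, grp, max_intervening=config.tandem_max_intervening
            )
            all_clusters.extend(clusters)
            coloc[grp] = {
                "scaffolds_occupied": summary.per_group[grp]["scaffolds_occupied"],
                "scaffolds_with_ge_3": summary.per_group[grp]["scaffolds_with_ge_m"],
                "n_tandem_clusters": len(clusters),
            }
            if grp in report["groups"]:
                report["groups"][grp]["colocalization"] = coloc[grp]
        clusters_to_frame(all_clusters).to_csv(out / "tandem_clusters.tsv",
                                               sep="\t", index=False)
        report["stages"]["colocalization"] = {"status": "ok", "per_group": coloc}
    else:
        report["stages"]["colocalization"] = {"status": "skipped", "reason": "no loci"}

    # ---- stage 6: report -----------------------------------------------------
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
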