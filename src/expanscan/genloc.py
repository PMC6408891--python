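"""Genomic co-localization of gene groups: scaffold occupancy and tandem
clusters.

Tandem duplication leaves paralogues sitting next to each other on a
scaffold; later rearrangement disperses them. Given gene coordinates
(BED-like: scaffold, start, stop, strand, gene id, optional group label),
this module summarizes how many scaffolds each group occupies and how many
carry >= m group members, and detects *tandem clusters*: maximal runs of
group members along a scaffold separated by at most ``max_intervening``
non-group genes.

Coordinates are 0-based half-open internally; 1-based inclusive tables are
converted on input. Strand is ignored for clustering (tandem arrays can
contain inversions) but reported for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneLocus",
    "TandemCluster",
    "ScaffoldSummary",
    "read_loci",
    "scaffold_summary",
    "detect_tandem_clusters",
]

LOCI_COLUMNS = ["scaffold", "start", "stop", "strand", "gene"]


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    scaffold: str
    start: int
    stop: int
    strand: str
    group: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValueError(
                f"{self.gene}: require 0 <= start < stop, got [{self.start}, {self.stop})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TandemCluster:
    scaffold: str
    members: list[str]
    start: int
    stop: int
    strands: str  # e.g. "++-" in scaffold order
    n_intervening: int  # non-group genes inside the run

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ScaffoldSummary:
    """Per-group scaffold occupancy; ``clustered`` counts scaffolds with at
    least ``m`` members of the group."""

    m: int
    per_group: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "n_genes": d["n_genes"],
                "scaffolds_occupied": d["scaffolds_occupied"],
                f"scaffolds_with_ge_{self.m}": d["scaffolds_with_ge_m"],
            }
            for g, d in sorted(self.per_group.items())
        ]
        return pd.DataFrame(rows)


def read_loci(source, one_based: bool = False) -> list[GeneLocus]:
    """Read a BED-like TSV (or DataFrame) of gene loci.

    Columns: scaffold, start, stop, strand, gene[, group]. With
    ``one_based`` the table is interpreted as 1-based inclusive and
    converted to the internal 0-based half-open convention (length
    stop - start is preserved as stop - start + 1 of the original).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    missing = [c for c in LOCI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"loci table missing columns: {missing}")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    loci = []
    for i, row in df.iterrows():
        start, stop = int(row["start"]), int(row["stop"])
        if one_based:
            start, stop = start - 1, stop
        if start >= stop:
            raise ValueError(f"row {i} ({row['gene']}): start >= stop")
        loci.append(
            GeneLocus(
                gene=str(row["gene"]),
                scaffold=str(row["scaffold"]),
                start=start,
                stop=stop,
                strand=str(row["strand"]),
                group=str(row["group"]) if "group" in df.columns and pd.notna(row["group"]) else None,
            )
        )
    return loci


def _by_scaffold(loci: list[GeneLocus]) -> dict[str, list[GeneLocus]]:
    out: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        out.setdefault(loc.scaffold, []).append(loc)
    for scaf in out:
        out[scaf].sort(key=lambda l: (l.start, l.stop, l.gene))
    return out


def scaffold_summary(loci: list[GeneLocus], groups: list[str] | None = None, m: int = 3) -> ScaffoldSummary:
    """For each group: scaffolds occupied and scaffolds carrying >= m
    members — the descriptive statistic behind 'x out of y scaffolds
    harboured >= m genes of the group'."""
    present = sorted({l.group for l in loci if l.group is not None})
    if groups is None:
        groups = present
    else:
        unknown = sorted(set(groups) - set(present))
        if unknown:
            raise ValueError(f"unknown group labels: {unknown}")
    summary = ScaffoldSummary(m=m)
    for g in groups:
        counts: dict[str, int] = {}
        n_genes = 0
        for l in loci:
            if l.group == g:
                counts[l.scaffold] = counts.get(l.scaffold, 0) + 1
                n_genes += 1
        summary.per_group[g] = {
            "n_genes": n_genes,
            "scaffolds_occupied": len(counts),
            "scaffolds_with_ge_m": sum(1 for c in counts.values() if c >= m),
            "scaffold_counts": dict(sorted(counts.items())),
        }
    return summary


def detect_tandem_clusters(
    loci: list[GeneLocus],
    group: str,
    max_intervening: int = 5,
    max_gap_bp: int = 100_000,
) -> list[TandemCluster]:
    """Maximal runs of >= 2 group members along each scaffold.

    Consecutive members may be separated by at most ``max_intervening``
    non-group genes. Intervening genes are counted from the full gene
    complement in ``loci``; when a scaffold carries *only* group genes
    (no background annotated), a distance fallback joins consecutive
    members at most ``max_gap_bp`` apart instead, since the intervening
    count is then unknowable.
    """
    clusters: list[TandemCluster] = []
    for scaffold, genes in sorted(_by_scaffold(loci).items()):
        member_pos = [k for k, l in enumerate(genes) if l.group == group]
        if len(member_pos) < 2:
            continue
        has_background = len(member_pos) < len(genes)
        runs: list[list[int]] = [[member_pos[0]]]
        for prev, cur in zip(member_pos, member_pos[1:]):
            if has_background:
                joined = (cur - prev - 1) <= max_intervening
            else:
                joined = (genes[cur].start - genes[prev].stop) <= max_gap_bp
            if joined:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            if len(run) < 2:
                continue
            members = [genes[k] for k in run]
            clusters.append(
                TandemCluster(
                    scaffold=scaffold,
                    members=[l.gene for l in members],
                    start=members[0].start,
                    stop=max(l.stop for l in members),
                    strands="".join(l.strand for l in members),
                    n_intervening=(run[-1] - run[0] + 1) - len(run),
                )
            )
    return clusters


def clusters_to_frame(clusters: list[TandemCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": c.scaffold,
                "size": c.size,
                "start": c.start,
                "stop": c.stop,
                "strands": c.strands,
                "n_intervening": c.n_intervening,
                "members": ",".join(c.members),
            }
            for c in clusters
        ]
    )
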