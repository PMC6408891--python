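"""Tissue-specificity and expression-divergence profiling.

Works on a gene x tissue matrix of non-negative normalized expression
values (e.g. TPM). The central statistic is the tissue-specificity index
Tau:

    Tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

which is 0 for perfectly uniform expression across the n tissues and 1 when
a single tissue carries all expression. Genes with Tau strictly greater
than a threshold (default 0.8) are classified tissue specific. Group-level
contrasts (expanded vs non-expanded gene sets) use the Kruskal-Wallis rank
test followed by Dunn's pairwise post hoc test with Holm step-down p-value
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_tau",
    "classify_specific",
    "expression_proportions",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "tau_table",
    "summarize_by_group",
    "compare_groups",
    "read_expression_tsv",
    "KruskalResult",
]

NON_EXPANDED = "non_expanded"


def _as_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expression vector must be 1-D with at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    return x


def compute_tau(x, log1p: bool = False) -> float:
    """Tissue-specificity index Tau of one gene's per-tissue expression.

    Scale invariant, in [0, 1]. Returns NaN for an all-zero vector (Tau is
    undefined when the gene is not expressed anywhere). ``log1p`` applies
    log(1 + x) first, a common variance-stabilizing choice in the Tau
    literature; the default works on the raw normalized values.
    """
    x = _as_vector(x)
    if log1p:
        x = np.log1p(x)
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def classify_specific(tau: float, threshold: float = 0.8) -> bool | None:
    """Tissue specific iff Tau strictly exceeds the threshold; an undefined
    (NaN) Tau yields None (unclassified)."""
    if tau is None or np.isnan(tau):
        return None
    return bool(tau > threshold)


def expression_proportions(x) -> np.ndarray:
    """Per-tissue fractions x_i / sum(x); NaNs for an all-zero gene."""
    x = _as_vector(x)
    s = x.sum()
    if s == 0:
        return np.full(x.shape, np.nan)
    return x / s


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment over one family of p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p_value: float


def kruskal_wallis(groups: list) -> KruskalResult:
    """Kruskal-Wallis rank test across k samples (tie-corrected H,
    chi-squared p with k-1 df). All observations identical is handled as
    H = 0, p = 1 by convention (no rank separation to test)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return KruskalResult(H=0.0, df=len(groups) - 1, p_value=1.0)
    H, p = stats.kruskal(*arrs)
    return KruskalResult(H=float(H), df=len(groups) - 1, p_value=float(p))


def dunn_posthoc(
    groups: list, labels: list[str] | None = None, adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's post hoc test on all group pairs after Kruskal-Wallis.

    z statistics compare mean ranks with a tie-corrected pooled variance;
    p-values are two-sided and adjusted over the whole pairwise family
    (Holm step-down by default). Groups of size < 2 are skipped with a
    warning. Returns columns group_a, group_b, z, raw_p, adjusted_p.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValueError("labels must match groups")

    pooled = np.concatenate(arrs)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term for the pooled rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0

    mean_ranks, sizes = [], []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size

    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            if sizes[i] < 2 or sizes[j] < 2:
                warnings.warn(
                    f"pair ({labels[i]}, {labels[j]}) skipped: group of size < 2",
                    stacklevel=2,
                )
                continue
            var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:  # every observation tied
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((labels[i], labels[j], z, min(p, 1.0)))

    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "raw_p"])
    if len(df):
        if adjust == "holm":
            df["adjusted_p"] = holm_adjust(df["raw_p"])
        elif adjust in (None, "none"):
            df["adjusted_p"] = df["raw_p"]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    else:
        df["adjusted_p"] = []
    return df


# ---------------------------------------------------------------------------
# Matrix-level workflows
# ---------------------------------------------------------------------------


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a gene x tissue matrix: unique gene/tissue labels, >= 2 tissues,
    no negative values."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 tissue columns")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate tissue labels")
    if (matrix.values < 0).any():
        raise ValueError("negative expression values")
    return matrix


def read_expression_tsv(path: str) -> pd.DataFrame:
    """TSV with gene ids in the first column and one column per tissue."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_matrix(df)


def tau_table(
    matrix: pd.DataFrame, threshold: float = 0.8, log1p: bool = False
) -> pd.DataFrame:
    """Per-gene Tau, specificity call, argmax tissue, and expression
    proportions. All-zero genes get NaN Tau/proportions and a null call;
    they are counted, not dropped, so the QC trail stays visible."""
    validate_matrix(matrix)
    tissues = list(matrix.columns)
    rows = []
    for gene, x in matrix.iterrows():
        xv = x.to_numpy(dtype=float)
        tau = compute_tau(xv, log1p=log1p)
        props = expression_proportions(xv)
        spec = classify_specific(tau, threshold)
        rows.append(
            {
                "gene": gene,
                "tau": tau,
                "is_specific": spec,
                "argmax_tissue": tissues[int(np.argmax(xv))] if xv.max() > 0 else None,
                **{f"prop_{t}": p for t, p in zip(tissues, props)},
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def summarize_by_group(
    matrix: pd.DataFrame,
    group_assignment: dict[str, str],
    threshold: float = 0.8,
    log1p: bool = False,
    ci: str = "normal",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group Tau summary (n, mean, 95% CI, fraction specific) plus
    per-tissue mean expression proportions.

    The CI is a normal approximation (mean +/- 1.96 se) by default;
    ``ci="bootstrap"`` uses a percentile bootstrap instead. Genes in the
    matrix but absent from ``group_assignment`` are reported under the
    non-expanded background group; empty groups are omitted with a warning.
    """
    tt = tau_table(matrix, threshold=threshold, log1p=log1p)
    tissues = list(matrix.columns)
    rng = np.random.default_rng(seed)

    by_group: dict[str, list[str]] = {}
    for gene in matrix.index:
        by_group.setdefault(group_assignment.get(gene, NON_EXPANDED), []).append(gene)

    rows = []
    for group in sorted(by_group):
        genes = by_group[group]
        taus = tt.loc[genes, "tau"].dropna().to_numpy()
        if taus.size == 0:
            warnings.warn(f"group {group!r} has no gene with defined Tau; omitted",
                          stacklevel=2)
            continue
        mean = float(taus.mean())
        if ci == "bootstrap" and taus.size > 1:
            reps = rng.choice(taus, size=(n_boot, taus.size), replace=True).mean(axis=1)
            lo, hi = np.percentile(reps, [2.5, 97.5])
        else:
            se = taus.std(ddof=1) / np.sqrt(taus.size) if taus.size > 1 else 0.0
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        spec = tt.loc[genes, "is_specific"].dropna()
        props = tt.loc[genes, [f"prop_{t}" for t in tissues]].dropna()
        row = {
            "group": group,
            "n_genes": len(genes),
            "n_defined": int(taus.size),
            "mean_tau": mean,
            "tau_ci_low": float(lo),
            "tau_ci_high": float(hi),
            "frac_specific": float(spec.mean()) if len(spec) else float("nan"),
        }
        mean_props = props.mean(axis=0)
        row.update({c: float(v) for c, v in mean_props.items()})
        row["top_tissue"] = (
            mean_props.idxmax().removeprefix("prop_") if len(props) else None
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def compare_groups(
    matrix: pd.DataFrame,
    group_assignment: dict[str, str],
    log1p: bool = False,
) -> tuple[KruskalResult, pd.DataFrame]:
    """Kruskal-Wallis on per-group Tau distributions, with Dunn/Holm
    pairwise follow-up. Returns (overall test, pairwise table)."""
    tt = tau_table(matrix, log1p=log1p)
    by_group: dict[str, list[float]] = {}
    for gene in matrix.index:
        tau = tt.loc[gene, "tau"]
        if np.isnan(tau):
            continue
        by_group.setdefault(group_assignment.get(gene, NON_EXPANDED), []).append(tau)
    labels = sorted(by_group)
    samples = [by_group[g] for g in labels]
    kw = kruskal_wallis(samples)
    pairwise = dunn_posthoc(samples, labels=labels)
    return kw, pairwise
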