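"""Maximum-likelihood fits of codon models and likelihood-ratio tests.

Implements the model hierarchy used for positive-selection scans on
expanded gene groups:

* M0 — one dN/dS ratio (omega) for the whole tree;
* branch (two-ratio) model — a foreground omega on designated branches, a
  background omega elsewhere; compared to M0 with a 1-df LRT;
* M1a ("nearly neutral", site classes omega0 < 1 and omega1 = 1) vs
  M2a (adds a class omega2 > 1); compared with a 2-df LRT, with per-site
  posterior class probabilities by naive empirical Bayes (NEB) at the MLEs.

Optimization is bounded quasi-Newton (L-BFGS-B) on log/logit-transformed
parameters. By default branch lengths are taken from the input tree up to
a single free rate-scale factor (input trees carry ML branch lengths in
substitutions per site; the scale absorbs the site->codon unit change and
dataset-specific rate differences); ``branch_mode="full"`` frees every
branch length instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..treeops import GeneTree
from .alignment import CodonAlignment
from .model import CodonLikelihood

__all__ = [
    "ModelFit",
    "LRTResult",
    "SitesResult",
    "fit_m0",
    "fit_branch_model",
    "fit_sites_models",
    "lrt",
    "filter_high_omega",
]

_LOG_BOUNDS = {
    "kappa": (np.log(0.02), np.log(99.0)),
    "omega": (np.log(1e-4), np.log(999.0)),
    "scale": (np.log(1e-3), np.log(1e3)),
    "length": (np.log(1e-7), np.log(60.0)),
    "omega_excess": (np.log(1e-3), np.log(999.0)),  # omega2 = 1 + excess
}
_LOGIT_BOUND = 12.0
_KAPPA_INIT = 2.0
_OMEGA_INIT = 0.5


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


@dataclass
class ModelFit:
    """Result of one model optimization."""

    model_tag: str
    log_likelihood: float
    params: dict
    converged: bool
    n_free_params: int
    branch_lengths: np.ndarray | None = None
    message: str = ""


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class SitesResult:
    m1a: ModelFit
    m2a: ModelFit
    lrt: LRTResult
    posteriors: pd.DataFrame
    positive_sites: list[int] = field(default_factory=list)


def _minimize(nll, x0, bounds, multistart: int, seed: int):
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, multistart)):
        x = np.array(x0, dtype=float)
        if s > 0:
            x = x + rng.normal(scale=0.4, size=x.shape)
            x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            nll, x, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _branch_setup(engine: CodonLikelihood, branch_mode: str):
    """Returns (n_length_params, lengths_from(theta_tail), init_tail, bounds_tail)."""
    if branch_mode == "scale":
        return (
            1,
            lambda tail: engine.base_lengths * np.exp(tail[0]),
            [np.log(3.0)],  # ~3 codon subs per site subs, a sensible unit prior
            [_LOG_BOUNDS["scale"]],
        )
    if branch_mode == "full":
        init = np.log(np.clip(engine.base_lengths * 3.0, 1e-4, 50.0))
        return (
            engine.n_edges,
            lambda tail: np.exp(tail),
            list(init),
            [_LOG_BOUNDS["length"]] * engine.n_edges,
        )
    if branch_mode == "fixed":
        return 0, lambda tail: engine.base_lengths, [], []
    raise ValueError(f"unknown branch_mode {branch_mode!r}")


def _engine(aln, gtree, freqs) -> CodonLikelihood:
    if isinstance(aln, CodonLikelihood):
        return aln
    return CodonLikelihood(aln, gtree, freqs=freqs)


# ---------------------------------------------------------------------------
# M0
# ---------------------------------------------------------------------------


def fit_m0(
    aln: CodonAlignment,
    gtree: GeneTree | None = None,
    freqs: np.ndarray | None = None,
    branch_mode: str = "scale",
    kappa_init: float = _KAPPA_INIT,
    omega_init: float = _OMEGA_INIT,
    multistart: int = 1,
    seed: int = 0,
) -> ModelFit:
    """One-ratio model: a single omega across the entire tree.

    Maximizes over omega, kappa and the branch-length parameterization
    chosen by ``branch_mode`` (rate scale by default, every length with
    ``"full"``). Codon frequencies are fixed empirically (F3x4) unless
    given. Non-convergence is reported in ``converged``, never raised.
    """
    eng = _engine(aln, gtree, freqs)
    nL, lengths_from, init_tail, bounds_tail = _branch_setup(eng, branch_mode)

    def nll(theta):
        kappa, omega = np.exp(theta[0]), np.exp(theta[1])
        ll = eng.log_likelihood(kappa, omega, branch_lengths=lengths_from(theta[2:]))
        return -ll if np.isfinite(ll) else 1e12

    x0 = [np.log(kappa_init), np.log(omega_init), *init_tail]
    bounds = [_LOG_BOUNDS["kappa"], _LOG_BOUNDS["omega"], *bounds_tail]
    res = _minimize(nll, x0, bounds, multistart, seed)
    kappa, omega = np.exp(res.x[0]), np.exp(res.x[1])
    lengths = lengths_from(res.x[2:])
    if not res.success:
        warnings.warn(f"M0 optimizer did not converge: {res.message}", stacklevel=2)
    return ModelFit(
        model_tag="M0",
        log_likelihood=-res.fun,
        params={"kappa": float(kappa), "omega": float(omega),
                "codon_frequencies": eng.freqs},
        converged=bool(res.success),
        n_free_params=2 + nL,
        branch_lengths=lengths,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Branch (two-ratio) model
# ---------------------------------------------------------------------------


def fit_branch_model(
    aln: CodonAlignment,
    gtree: GeneTree | None = None,
    foreground: set | None = None,
    freqs: np.ndarray | None = None,
    branch_mode: str = "scale",
    include_stem: bool = False,
    kappa_init: float = _KAPPA_INIT,
    omega_init: float = _OMEGA_INIT,
    multistart: int = 1,
    seed: int = 0,
) -> ModelFit:
    """Two-ratio model: omega_fg on foreground branches, omega_bg elsewhere.

    ``foreground`` is either a set of edge indices (the engine's postorder
    edge order) or a set of leaf labels, in which case every branch inside
    the clade they span (internal and terminal; stem optional) is labelled
    foreground. The foreground must be a non-empty proper subset of the
    branches — foregrounding everything collapses the model onto M0.
    """
    eng = _engine(aln, gtree, freqs)
    if not foreground:
        raise ValueError("foreground must be non-empty")
    fg = set(foreground)
    if any(isinstance(x, str) for x in fg):
        fg = eng.edges_in_clade(fg, include_stem=include_stem)
    if not fg or len(fg) >= eng.n_edges:
        raise ValueError(
            f"foreground must be a non-empty proper subset of the {eng.n_edges} branches"
        )
    fg = {int(e) for e in fg}

    nL, lengths_from, init_tail, bounds_tail = _branch_setup(eng, branch_mode)

    def nll(theta):
        kappa = np.exp(theta[0])
        ll = eng.log_likelihood(
            kappa,
            np.exp(theta[1]),
            branch_lengths=lengths_from(theta[3:]),
            foreground_edges=fg,
            omega_foreground=np.exp(theta[2]),
        )
        return -ll if np.isfinite(ll) else 1e12

    x0 = [np.log(kappa_init), np.log(omega_init), np.log(omega_init), *init_tail]
    bounds = [_LOG_BOUNDS["kappa"], _LOG_BOUNDS["omega"], _LOG_BOUNDS["omega"], *bounds_tail]
    res = _minimize(nll, x0, bounds, multistart, seed)
    if not res.success:
        warnings.warn(f"branch-model optimizer did not converge: {res.message}",
                      stacklevel=2)
    return ModelFit(
        model_tag="branch",
        log_likelihood=-res.fun,
        params={
            "kappa": float(np.exp(res.x[0])),
            "omega_background": float(np.exp(res.x[1])),
            "omega_foreground": float(np.exp(res.x[2])),
            "foreground_edges": sorted(fg),
            "codon_frequencies": eng.freqs,
        },
        converged=bool(res.success),
        n_free_params=3 + nL,
        branch_lengths=lengths_from(res.x[3:]),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Sites models (M1a / M2a)
# ---------------------------------------------------------------------------


def _mixture_nll(eng, class_omegas_from, weights_from, lengths_from, idx):
    """Build a negative log-likelihood over site-class mixtures."""

    def nll(theta):
        kappa = np.exp(theta[0])
        omegas = class_omegas_from(theta)
        weights = weights_from(theta)
        lengths = lengths_from(theta[idx:])
        site = np.zeros_like(eng.counts)
        for w, p in zip(omegas, weights):
            site = site + p * eng.site_likelihoods(kappa, np.full(eng.n_edges, w), lengths)
        if np.any(site <= 0):
            return 1e12
        return -float(eng.counts @ np.log(site))

    return nll


def fit_sites_models(
    aln: CodonAlignment,
    gtree: GeneTree | None = None,
    freqs: np.ndarray | None = None,
    branch_mode: str = "scale",
    posterior_threshold: float = 0.95,
    multistart: int = 1,
    seed: int = 0,
) -> SitesResult:
    """Fit M1a and M2a, run the 2-df LRT, and flag positively selected sites.

    Site-class posteriors are naive empirical Bayes at the MLEs; a site is
    flagged when its posterior probability of the omega2 class reaches
    ``posterior_threshold`` and the estimated omega2 exceeds 1. Site indices
    are 0-based codon columns of the alignment.
    """
    eng = _engine(aln, gtree, freqs)
    nL, lengths_from, init_tail, bounds_tail = _branch_setup(eng, branch_mode)

    # --- M1a: classes (omega0 < 1, 1) with weights (p0, 1 - p0)
    m1a_nll = _mixture_nll(
        eng,
        class_omegas_from=lambda th: (_sigmoid(th[2]), 1.0),
        weights_from=lambda th: (_sigmoid(th[1]), 1.0 - _sigmoid(th[1])),
        lengths_from=lengths_from,
        idx=3,
    )
    x0 = [np.log(_KAPPA_INIT), 0.5, -1.0, *init_tail]
    bounds = [
        _LOG_BOUNDS["kappa"],
        (-_LOGIT_BOUND, _LOGIT_BOUND),
        (-_LOGIT_BOUND, _LOGIT_BOUND),
        *bounds_tail,
    ]
    res1 = _minimize(m1a_nll, x0, bounds, multistart, seed)
    p0 = float(_sigmoid(res1.x[1]))
    m1a = ModelFit(
        model_tag="M1a",
        log_likelihood=-res1.fun,
        params={
            "kappa": float(np.exp(res1.x[0])),
            "class_omegas": (float(_sigmoid(res1.x[2])), 1.0),
            "class_weights": (p0, 1.0 - p0),
        },
        converged=bool(res1.success),
        n_free_params=3 + nL,
        branch_lengths=lengths_from(res1.x[3:]),
        message=str(res1.message),
    )

    # --- M2a: classes (omega0 < 1, 1, omega2 > 1), weights by softmax
    def weights2(th):
        e = np.exp([th[1], th[2], 0.0])
        return e / e.sum()

    m2a_nll = _mixture_nll(
        eng,
        class_omegas_from=lambda th: (_sigmoid(th[3]), 1.0, 1.0 + np.exp(th[4])),
        weights_from=weights2,
        lengths_from=lengths_from,
        idx=5,
    )
    bounds = [
        _LOG_BOUNDS["kappa"],
        (-_LOGIT_BOUND, _LOGIT_BOUND),
        (-_LOGIT_BOUND, _LOGIT_BOUND),
        (-_LOGIT_BOUND, _LOGIT_BOUND),
        _LOG_BOUNDS["omega_excess"],
        *bounds_tail,
    ]
    # two starts: (a) the M1a optimum with a near-zero omega2 class, which
    # guarantees l(M2a) >= l(M1a) up to optimizer tolerance; (b) a start
    # with real mass on omega2 to escape the boundary when selection exists
    p0c = np.clip(p0, 1e-6, 1 - 1e-6)
    collapsed = [
        res1.x[0], float(np.log(p0c) + 8.0), float(np.log(1 - p0c) + 8.0),
        res1.x[2], np.log(0.5), *list(res1.x[3:]),
    ]
    seeded = [res1.x[0], 1.0, 0.0, res1.x[2], np.log(1.0), *list(res1.x[3:])]
    cands = [
        _minimize(m2a_nll, collapsed, bounds, 1, seed + 1),
        _minimize(m2a_nll, seeded, bounds, max(1, multistart), seed + 2),
    ]
    res2 = min(cands, key=lambda r: r.fun)
    # M1a lies on the boundary of the M2a space (omega2 weight -> 0), which
    # the softmax parameterization can only approach; take the supremum so
    # the nested ordering l(M2a) >= l(M1a) holds exactly
    boundary_collapse = res2.fun > res1.fun
    if boundary_collapse:
        res2.fun = res1.fun
    w2 = weights2(res2.x)
    omegas2 = (float(_sigmoid(res2.x[3])), 1.0, float(1.0 + np.exp(res2.x[4])))
    m2a = ModelFit(
        model_tag="M2a",
        log_likelihood=-res2.fun,
        params={
            "kappa": float(np.exp(res2.x[0])),
            "class_omegas": omegas2,
            "class_weights": tuple(float(w) for w in w2),
        },
        converged=bool(res2.success),
        n_free_params=5 + nL,
        branch_lengths=lengths_from(res2.x[5:]),
        message="collapsed to M1a boundary" if boundary_collapse else str(res2.message),
    )

    test = lrt(m1a, m2a, df=2)

    # --- NEB site posteriors under the M2a MLEs
    kappa2 = m2a.params["kappa"]
    lengths2 = m2a.branch_lengths
    class_site = np.stack(
        [
            eng.site_likelihoods(kappa2, np.full(eng.n_edges, w), lengths2)
            for w in omegas2
        ]
    )  # (3, n_patterns)
    joint = class_site * np.asarray(w2)[:, None]
    post_pat = joint / joint.sum(axis=0, keepdims=True)
    # expand pattern posteriors back to alignment columns
    pat_of_site = _pattern_index_per_site(eng)
    post = post_pat[:, pat_of_site]  # (3, n_sites)
    df = pd.DataFrame(
        {
            "site": np.arange(eng.n_sites),
            "p_omega0": post[0],
            "p_omega1": post[1],
            "p_omega2": post[2],
        }
    )
    flagged = (
        df.index[df["p_omega2"] >= posterior_threshold].tolist()
        if omegas2[2] > 1.0
        else []
    )
    df["positive_selection"] = df["site"].isin(flagged)
    return SitesResult(m1a=m1a, m2a=m2a, lrt=test, posteriors=df, positive_sites=flagged)


def _pattern_index_per_site(eng: CodonLikelihood) -> np.ndarray:
    states = np.empty((len(eng.aln.ids), eng.aln.n_codons), dtype=np.int16)
    for gid in eng.aln.ids:
        seq = eng.aln.sequences[gid]
        states[eng._leaf_row[gid]] = [
            _state(seq[3 * c : 3 * c + 3]) for c in range(eng.aln.n_codons)
        ]
    # match each site column against the unique pattern columns
    _, inverse = np.unique(states, axis=1, return_inverse=True)
    return inverse


def _state(codon):
    from .genetic_code import codon_state

    return codon_state(codon)


# ---------------------------------------------------------------------------
# LRT and post-filters
# ---------------------------------------------------------------------------


def lrt(null: ModelFit, alt: ModelFit, df: int) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*(l_alt - l_null) against a
    chi-squared with ``df`` degrees of freedom (the difference in free
    parameters). A negative difference beyond optimizer tolerance signals
    an optimization failure; the statistic is clamped at zero either way.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = 2.0 * (alt.log_likelihood - null.log_likelihood)
    if delta < -1e-4:
        warnings.warn(
            f"alternative log-likelihood below null by {delta / 2:.6g}; "
            "optimizer likely failed — statistic clamped to 0",
            stacklevel=2,
        )
    stat = max(0.0, delta)
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def filter_high_omega(omega_estimates: dict, limit: float = 100.0) -> tuple[dict, list]:
    """Drop branches/groups whose estimated omega exceeds ``limit``
    (strictly); such estimates usually reflect near-zero synonymous counts
    or poor alignment rather than selection. Returns (kept, excluded keys).
    """
    kept = {k: w for k, w in omega_estimates.items() if w <= limit}
    excluded = [k for k, w in omega_estimates.items() if w > limit]
    return kept, excluded
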