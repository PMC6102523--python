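"""Codon substitution models (GY94) on a fixed tree topology.

Implements the Goldman-Yang style 61-state codon process with
transition/transversion ratio kappa, selection parameter omega = dN/dS and
stationary codon frequencies pi (F3x4 by default), plus the standard site
models:

* M0  one omega for all sites,
* M3  discrete, K=3 free (proportion, omega) classes,
* M7  omega ~ Beta(p, q) on (0, 1), discretized into 10 equal-probability
  classes represented by their means,
* M8  M7 plus one extra class with omega >= 1,

and branch-site model A (foreground branches may carry omega2 >= 1 at a
subset of sites; the null model pins omega2 = 1). Likelihoods use
Felsenstein pruning with alignment-pattern compression; gapped or ambiguous
codons contribute a flat partial likelihood (missing data). Mixture models
average the per-site likelihood over classes.

Branch lengths are in expected substitutions per codon (the generator is
rescaled to unit flux). They are optimized once under M0 and then held fixed
for the richer site models, which keeps fits tractable at desk scale.

Positively selected sites are located by empirical Bayes: NEB uses the
posterior class weights at the maximum-likelihood estimates; BEB averages
the NEB posterior over a coarse grid prior on the positive-selection
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, special, stats

from ._gencode import (
    CODON_INDEX,
    CODON_TO_AA,
    N_CODONS,
    NUCS,
    SENSE_CODONS,
    is_transition,
)
from .codon_tools import CodonAlignment
from .phylo import PhyloTree

# ---------------------------------------------------------------------------
# Static structure of the codon graph: single-nucleotide neighbours.

_I, _J, _TS, _SYN = [], [], [], []
for _i, _ca in enumerate(SENSE_CODONS):
    for _j, _cb in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [p for p in range(3) if _ca[p] != _cb[p]]
        if len(diffs) != 1:
            continue
        _p = diffs[0]
        _I.append(_i)
        _J.append(_j)
        _TS.append(is_transition(_ca[_p], _cb[_p]))
        _SYN.append(CODON_TO_AA[_ca] == CODON_TO_AA[_cb])
_I = np.array(_I)
_J = np.array(_J)
_TS = np.array(_TS)
_SYN = np.array(_SYN)


def f3x4_frequencies(codon_aln: CodonAlignment, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies: product of observed per-position nucleotide
    frequencies, restricted to sense codons and renormalized."""
    counts = np.zeros((3, 4))
    nuc_idx = {n: k for k, n in enumerate(NUCS)}
    for row in codon_aln.rows:
        for i in range(0, len(row), 3):
            codon = row[i : i + 3].upper()
            if any(c not in nuc_idx for c in codon):
                continue
            for p in range(3):
                counts[p, nuc_idx[codon[p]]] += 1
    counts += 1.0  # pseudocount keeps every sense codon reachable
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nuc_idx[c[0]]] * freqs[1, nuc_idx[c[1]]] * freqs[2, nuc_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def build_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """GY94 generator, scaled to one expected substitution per codon per
    unit time. Reversible with stationary distribution ``pi``."""
    Q = np.zeros((N_CODONS, N_CODONS))
    rate = pi[_J] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    Q[_I, _J] = rate
    Q[np.diag_indices(N_CODONS)] = -Q.sum(axis=1)
    flux = -(pi * np.diag(Q)).sum()
    if flux <= 0:
        raise ValueError("degenerate rate matrix (zero flux)")
    return Q / flux


def synonymous_flux_fraction(pi: np.ndarray, kappa: float, omega: float) -> float:
    """Fraction of substitution flux that is synonymous, at stationarity."""
    rate = pi[_J] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    total = (pi[_I] * rate).sum()
    syn = (pi[_I] * rate * _SYN).sum()
    return float(syn / total)


def raw_flux(pi: np.ndarray, kappa: float, omega: float) -> float:
    """Unnormalized substitution flux of the GY94 generator.

    Site-class mixtures share one time scale: every class generator is
    divided by the *mixture-average* flux, so classes with larger omega
    evolve faster, not just with a different synonymous/nonsynonymous
    composition. ``raw_flux`` supplies the per-class ingredient for that
    common normalization.
    """
    rate = pi[_J] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    return float((pi[_I] * rate).sum())


def class_rate_multipliers(pi, kappa, proportions, omegas) -> np.ndarray:
    """Per-class branch-length multipliers flux_k / mean flux, so one branch
    length (expected substitutions per codon averaged over classes) serves
    the whole mixture."""
    fluxes = np.array([raw_flux(pi, kappa, om) for om in omegas])
    props = np.asarray(proportions, dtype=float)
    mean_flux = float((props * fluxes).sum() / props.sum())
    return fluxes / mean_flux


class GY94:
    """Cached spectral decomposition of the codon process for fast P(t)."""

    def __init__(self, pi: np.ndarray, kappa: float):
        self.pi = np.asarray(pi, dtype=float)
        self.kappa = float(kappa)
        self._cache: dict[float, tuple] = {}
        self._sqrt_pi = np.sqrt(self.pi)

    def _decompose(self, omega: float):
        key = round(float(omega), 12)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Q = build_rate_matrix(self.pi, self.kappa, omega)
        # reversible: symmetrize with pi^{1/2}, eigh, transform back
        S = Q * (self._sqrt_pi[:, None] / self._sqrt_pi[None, :])
        lam, U = np.linalg.eigh((S + S.T) / 2.0)
        left = U / self._sqrt_pi[:, None]   # pi^{-1/2} U
        right = (U * self._sqrt_pi[:, None]).T  # U^T pi^{1/2}
        if len(self._cache) > 512:
            self._cache.clear()
        self._cache[key] = (lam, left, right)
        return lam, left, right

    def transition_matrix(self, omega: float, t: float) -> np.ndarray:
        lam, left, right = self._decompose(omega)
        P = (left * np.exp(lam * t)) @ right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# Tree plumbing


def _as_dendropy(tree) -> dendropy.Tree:
    if isinstance(tree, PhyloTree):
        return tree.tree.clone(depth=1)
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=str(tree), schema="newick")


class CodonLikelihood:
    """Felsenstein pruning for a codon alignment on a fixed topology."""

    def __init__(self, tree, codon_aln: CodonAlignment, pi: np.ndarray | None = None):
        self.tree = _as_dendropy(tree)
        self.aln = codon_aln
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if set(labels) != set(codon_aln.ids):
            raise ValueError("tree leaf set does not match alignment ids")
        self.pi = f3x4_frequencies(codon_aln) if pi is None else np.asarray(pi)

        # leaf codon states; -1 = missing (gap / ambiguous / stop)
        n_sites = codon_aln.n_codon_columns
        states = np.full((len(labels), n_sites), -1, dtype=int)
        row_of = {rid: r for rid, r in zip(codon_aln.ids, codon_aln.rows)}
        for li, lab in enumerate(labels):
            row = row_of[lab]
            for s in range(n_sites):
                states[li, s] = CODON_INDEX.get(row[3 * s : 3 * s + 3].upper(), -1)

        # compress identical site patterns
        _, first_idx, inverse, counts = np.unique(
            states, axis=1, return_index=True, return_inverse=True, return_counts=True
        )
        self.pattern_states = states[:, first_idx]
        self.pattern_weights = counts.astype(float)
        self.site_to_pattern = inverse
        self.n_sites = n_sites
        self.n_patterns = self.pattern_states.shape[1]

        # postorder node bookkeeping
        self.postorder = list(self.tree.postorder_node_iter())
        self.node_index = {id(nd): k for k, nd in enumerate(self.postorder)}
        self.leaf_row = {}
        for li, lf in enumerate(self.tree.leaf_node_iter()):
            self.leaf_row[id(lf)] = li
        self.edges = [nd for nd in self.postorder if nd.parent_node is not None]
        self.n_edges = len(self.edges)
        self._edge_index = {id(nd): e for e, nd in enumerate(self.edges)}

        # pre-built leaf partials: (n_leaves, 61, n_patterns)
        eye = np.eye(N_CODONS)
        self._leaf_partials = np.empty((len(labels), N_CODONS, self.n_patterns))
        for li in range(len(labels)):
            st = self.pattern_states[li]
            part = np.where(st[None, :] >= 0, eye[:, np.clip(st, 0, None)], 1.0)
            self._leaf_partials[li] = part

    def branch_lengths(self) -> np.ndarray:
        return np.array(
            [nd.edge.length if nd.edge.length is not None else 0.1 for nd in self.edges]
        )

    def foreground_mask(self, foreground_leaves) -> np.ndarray:
        """Edges whose subtree leaf set is contained in the foreground set
        (the clade's stem and internal branches)."""
        fg = set(foreground_leaves)
        all_leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if fg >= all_leaves:
            raise ValueError("foreground cannot be the whole tree")
        mask = np.zeros(self.n_edges, dtype=bool)
        for e, nd in enumerate(self.edges):
            below = {lf.taxon.label for lf in nd.leaf_iter()}
            mask[e] = below <= fg
        return mask

    def _pattern_likelihoods(
        self, model: GY94, omega, bls, fg_mask=None, omega_fg=None, bls_fg=None
    ):
        """Per-pattern likelihood under a single omega (optionally with a
        different omega, and its own time scaling, on foreground edges)."""
        P_edge = []
        for e, nd in enumerate(self.edges):
            if fg_mask is not None and fg_mask[e]:
                om, t = omega_fg, (bls_fg if bls_fg is not None else bls)[e]
            else:
                om, t = omega, bls[e]
            P_edge.append(model.transition_matrix(om, max(t, 0.0)))
        partial = {}
        for nd in self.postorder:
            if nd.is_leaf():
                part = self._leaf_partials[self.leaf_row[id(nd)]]
            else:
                part = np.ones((N_CODONS, self.n_patterns))
                for ch in nd.child_nodes():
                    e = self._edge_index[id(ch)]
                    part = part * (P_edge[e] @ partial[id(ch)])
                # rescale to dodge underflow on deep trees
                scale = part.max(axis=0)
                scale[scale == 0] = 1.0
                part = part / scale
                partial.setdefault("_logscale", np.zeros(self.n_patterns))
                partial["_logscale"] += np.log(scale)
            partial[id(nd)] = part
        root = self.postorder[-1]
        lik = self.pi @ partial[id(root)]
        logscale = partial.get("_logscale", np.zeros(self.n_patterns))
        return lik, logscale

    def site_log_likelihood_matrix(self, model, classes, bls):
        """(K, n_patterns) log-likelihood per class; classes are
        (proportion, omega) or (proportion, (omega_bg, omega_fg), fg_mask).

        All classes share one time scale: branch lengths are expected
        substitutions per codon averaged over the mixture, so each class's
        process is sped up or slowed down by its flux relative to the
        mixture-average flux (computed over background omegas)."""
        bls = np.asarray(bls, dtype=float)
        props = np.array([c[0] for c in classes], dtype=float)
        bg_oms = np.array(
            [c[1] if len(c) == 2 else c[1][0] for c in classes], dtype=float
        )
        fluxes = np.array([raw_flux(self.pi, model.kappa, om) for om in bg_oms])
        mean_flux = float((props * fluxes).sum() / max(props.sum(), 1e-300))
        rows = []
        for cls, flux_bg in zip(classes, fluxes):
            if len(cls) == 2:
                _, om = cls
                lik, ls = self._pattern_likelihoods(
                    model, om, bls * (flux_bg / mean_flux)
                )
            else:
                _, (om_bg, om_fg), fg_mask = cls
                m_fg = raw_flux(self.pi, model.kappa, om_fg) / mean_flux
                lik, ls = self._pattern_likelihoods(
                    model, om_bg, bls * (flux_bg / mean_flux),
                    fg_mask=fg_mask, omega_fg=om_fg, bls_fg=bls * m_fg,
                )
            with np.errstate(divide="ignore"):
                rows.append(np.log(lik) + ls)
        return np.vstack(rows)

    def loglik(self, kappa, classes, bls) -> float:
        """Total log-likelihood of a mixture of omega classes."""
        model = GY94(self.pi, kappa)
        logL = self.site_log_likelihood_matrix(model, classes, bls)
        props = np.array([c[0] for c in classes])
        m = logL.max(axis=0)
        mix = m + np.log((props[:, None] * np.exp(logL - m)).sum(axis=0))
        return float((mix * self.pattern_weights).sum())

    def class_posteriors(self, kappa, classes, bls) -> np.ndarray:
        """(K, n_sites) NEB posterior that each site belongs to each class."""
        model = GY94(self.pi, kappa)
        logL = self.site_log_likelihood_matrix(model, classes, bls)
        props = np.array([c[0] for c in classes])
        w = np.log(np.maximum(props, 1e-300))[:, None] + logL
        w = np.exp(w - w.max(axis=0))
        post = w / w.sum(axis=0)
        return post[:, self.site_to_pattern]


# ---------------------------------------------------------------------------
# Model fitting


@dataclass
class SiteModelFit:
    model: str
    lnl: float
    params: dict
    class_proportions: np.ndarray
    class_omegas: np.ndarray
    site_posteriors: np.ndarray  # (K, n_sites) NEB at the MLEs
    branch_lengths: np.ndarray
    converged: bool
    engine: CodonLikelihood = field(repr=False, default=None)


@dataclass
class LrtResult:
    stat: float  # 2 * (lnL_alt - lnL_null)
    df: int
    p_value: float
    flagged: bool  # negative statistic: optimizer trouble


def likelihood_ratio_test(
    lnl_alt: float, lnl_null: float, df: int, halved: bool = False
) -> LrtResult:
    """LRT with chi2 reference; ``halved`` applies the 50:50 mixture of
    chi2_0 and chi2_df used for boundary tests (branch-site)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl_alt - lnl_null)
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    if halved:
        p = 0.5 * p if stat > 0 else 1.0
    return LrtResult(stat=stat, df=df, p_value=p, flagged=stat < 0)


def beta_class_omegas(p: float, q: float, k: int = 10) -> np.ndarray:
    """Means of K equal-probability bins of Beta(p, q)."""
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    inc = special.betainc(p + 1.0, q, edges)
    means = (inc[1:] - inc[:-1]) * (p / (p + q)) * k
    return np.clip(means, 1e-8, 1.0 - 1e-8)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = np.concatenate([z, [0.0]])
    e = np.exp(z - z.max())
    return e / e.sum()


def _classes_for(model: str, x: np.ndarray, n_beta: int = 10):
    """Decode the transformed parameter vector into (kappa, classes, params)."""
    kappa = math.exp(x[0])
    if model == "M0":
        om = math.exp(x[1])
        return kappa, [(1.0, om)], {"kappa": kappa, "omega": om}
    if model == "M3":
        props = _softmax(x[1:3])
        oms = np.exp(x[3:6])
        classes = [(p, o) for p, o in zip(props, oms)]
        return kappa, classes, {
            "kappa": kappa,
            "p": props,
            "omega": oms,
        }
    if model == "M7":
        p, q = math.exp(x[1]), math.exp(x[2])
        oms = beta_class_omegas(p, q, n_beta)
        classes = [(1.0 / n_beta, o) for o in oms]
        return kappa, classes, {"kappa": kappa, "p": p, "q": q}
    if model == "M8":
        p0 = 1.0 / (1.0 + math.exp(-x[1]))
        p, q = math.exp(x[2]), math.exp(x[3])
        om_s = 1.0 + math.exp(x[4])
        oms = beta_class_omegas(p, q, n_beta)
        classes = [(p0 / n_beta, o) for o in oms] + [(1.0 - p0, om_s)]
        return kappa, classes, {
            "kappa": kappa, "p0": p0, "p": p, "q": q, "omega_s": om_s,
        }
    raise ValueError(f"unknown site model {model!r}")


_X0 = {
    "M0": [math.log(2.0), math.log(0.3)],
    "M3": [math.log(2.0), 0.0, 0.0, math.log(0.05), math.log(0.3), math.log(1.2)],
    "M7": [math.log(2.0), math.log(0.8), math.log(2.0)],
    "M8": [math.log(2.0), 3.0, math.log(0.8), math.log(2.0), math.log(0.5)],
}
_BOUNDS_KAPPA = (math.log(0.05), math.log(50.0))
_BOUNDS_OMEGA = (math.log(1e-5), math.log(30.0))
_BOUNDS_BETA = (math.log(0.05), math.log(50.0))


def _bounds_for(model: str):
    if model == "M0":
        return [_BOUNDS_KAPPA, _BOUNDS_OMEGA]
    if model == "M3":
        return [_BOUNDS_KAPPA, (-8, 8), (-8, 8)] + [_BOUNDS_OMEGA] * 3
    if model == "M7":
        return [_BOUNDS_KAPPA, _BOUNDS_BETA, _BOUNDS_BETA]
    if model == "M8":
        return [_BOUNDS_KAPPA, (-12, 12), _BOUNDS_BETA, _BOUNDS_BETA,
                (math.log(1e-4), math.log(30.0))]
    raise ValueError(model)


def fit_site_model(
    model: str,
    tree,
    codon_aln: CodonAlignment,
    *,
    pi: np.ndarray | None = None,
    branch_lengths: np.ndarray | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-7,
    n_beta: int = 10,
) -> SiteModelFit:
    """Maximum-likelihood fit of one site model.

    Branch lengths are optimized jointly under M0; for M3/M7/M8 they must be
    supplied (typically from a prior M0 fit) — if omitted, a quiet M0 fit is
    run first and its branch lengths reused.
    """
    engine = CodonLikelihood(tree, codon_aln, pi=pi)
    if model != "M0" and branch_lengths is None:
        m0 = fit_site_model(
            "M0", tree, codon_aln, pi=engine.pi,
            n_restarts=max(1, n_restarts - 1), seed=seed, tol=tol,
        )
        branch_lengths = m0.branch_lengths

    opt_bls = model == "M0" and branch_lengths is None
    bls0 = engine.branch_lengths() if branch_lengths is None else np.asarray(branch_lengths)
    rng = np.random.default_rng(seed)

    def unpack(x):
        if opt_bls:
            k = len(_X0[model])
            return x[:k], np.exp(x[k:])
        return x, bls0

    def nll(x):
        xm, bls = unpack(x)
        kappa, classes, _ = _classes_for(model, xm, n_beta)
        try:
            return -engine.loglik(kappa, classes, bls)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    base = np.array(_X0[model], dtype=float)
    bounds = _bounds_for(model)
    if opt_bls:
        base = np.concatenate([base, np.log(np.maximum(bls0, 1e-4))])
        bounds = bounds + [(math.log(1e-6), math.log(20.0))] * engine.n_edges

    best = None
    for r in range(max(1, n_restarts)):
        x0 = base if r == 0 else base + rng.normal(0.0, 0.35, size=base.size)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res

    xm, bls = unpack(best.x)
    kappa, classes, params = _classes_for(model, xm, n_beta)
    post = engine.class_posteriors(kappa, classes, bls)
    return SiteModelFit(
        model=model,
        lnl=-float(best.fun),
        params=params,
        class_proportions=np.array([c[0] for c in classes]),
        class_omegas=np.array([c[1] for c in classes]),
        site_posteriors=post,
        branch_lengths=np.asarray(bls, dtype=float),
        converged=bool(best.success),
        engine=engine,
    )


# ---------------------------------------------------------------------------
# Branch-site model A


def _bs_classes(p0, p1, w0, w2, fg_mask):
    p2 = max(1.0 - p0 - p1, 0.0)
    denom = p0 + p1 if p0 + p1 > 0 else 1.0
    return [
        (p0, (w0, w0), fg_mask),
        (p1, (1.0, 1.0), fg_mask),
        (p2 * p0 / denom, (w0, w2), fg_mask),
        (p2 * p1 / denom, (1.0, w2), fg_mask),
    ]


def fit_branch_site(
    tree,
    codon_aln: CodonAlignment,
    foreground_leaves,
    *,
    pi: np.ndarray | None = None,
    branch_lengths: np.ndarray | None = None,
    n_restarts: int = 2,
    seed: int = 0,
    tol: float = 1e-7,
) -> tuple[SiteModelFit, SiteModelFit]:
    """Branch-site model A and its omega2=1 null on a foreground clade.

    Returns ``(alternative_fit, null_fit)``; their LRT has df=1 (boundary
    test — the halved chi2 mixture is available in the LRT helper).
    """
    engine = CodonLikelihood(tree, codon_aln, pi=pi)
    fg_mask = engine.foreground_mask(foreground_leaves)
    if branch_lengths is None:
        m0 = fit_site_model("M0", tree, codon_aln, pi=engine.pi,
                            n_restarts=1, seed=seed, tol=tol)
        branch_lengths = m0.branch_lengths
    bls = np.asarray(branch_lengths)
    rng = np.random.default_rng(seed)

    def decode(x, null):
        kappa = math.exp(x[0])
        props = _softmax(x[1:3])  # p0, p1, p2
        w0 = 1.0 / (1.0 + math.exp(-x[3]))
        w2 = 1.0 if null else 1.0 + math.exp(x[4])
        return kappa, props[0], props[1], w0, w2

    def make_nll(null):
        def nll(x):
            kappa, p0, p1, w0, w2 = decode(x, null)
            classes = _bs_classes(p0, p1, w0, w2, fg_mask)
            try:
                return -engine.loglik(kappa, classes, bls)
            except (np.linalg.LinAlgError, FloatingPointError):
                return 1e12
        return nll

    fits = []
    for null in (False, True):
        n_par = 4 if null else 5
        base = np.array([math.log(2.0), 1.5, 0.0, 0.0, math.log(1.0)][:n_par])
        bounds = [_BOUNDS_KAPPA, (-8, 8), (-8, 8), (-10, 10), (math.log(1e-4), math.log(30.0))][:n_par]
        best = None
        f = make_nll(null)
        for r in range(max(1, n_restarts)):
            x0 = base if r == 0 else base + rng.normal(0.0, 0.3, size=base.size)
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = optimize.minimize(f, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 400, "ftol": tol})
            if best is None or res.fun < best.fun:
                best = res
        kappa, p0, p1, w0, w2 = decode(best.x, null)
        classes = _bs_classes(p0, p1, w0, w2, fg_mask)
        post = engine.class_posteriors(kappa, classes, bls)
        fits.append(
            SiteModelFit(
                model="branch-site A null" if null else "branch-site A",
                lnl=-float(best.fun),
                params={"kappa": kappa, "p0": p0, "p1": p1,
                        "omega0": w0, "omega2": w2},
                class_proportions=np.array([c[0] for c in classes]),
                class_omegas=np.array([c[1][1] for c in classes]),
                site_posteriors=post,
                branch_lengths=bls,
                converged=bool(best.success),
                engine=engine,
            )
        )
    return fits[0], fits[1]


# ---------------------------------------------------------------------------
# Empirical Bayes site detection


@dataclass
class SiteSelectionCall:
    site: int  # 1-based alignment codon column
    ref_site: int | None  # 1-based codon position in the reference sequence
    probability: float
    tier: str  # "p>0.95" or "p>0.99"


def _positive_mask(fit: SiteModelFit) -> np.ndarray:
    return np.asarray(fit.class_omegas) > 1.0


def map_to_reference(codon_aln: CodonAlignment, ref_id: str) -> dict[int, int]:
    """Alignment codon column (1-based) -> codon index in the ungapped
    reference sequence (1-based); gap columns of the reference are absent."""
    row = codon_aln.row(ref_id)
    out = {}
    k = 0
    for col in range(codon_aln.n_codon_columns):
        codon = row[3 * col : 3 * col + 3]
        if "-" not in codon and "." not in codon:
            k += 1
            out[col + 1] = k
    return out


def eb_site_posteriors(
    fit: SiteModelFit,
    method: str = "NEB",
    thresholds: tuple[float, float] = (0.95, 0.99),
    codon_aln: CodonAlignment | None = None,
    ref_id: str | None = None,
    grid_points: int = 8,
) -> tuple[np.ndarray, list[SiteSelectionCall]]:
    """Per-site posterior of the positive-selection class and threshold calls.

    NEB evaluates the class posterior at the MLEs; BEB (M8 only) averages it
    over a uniform coarse-grid prior on (p0, p, q, omega_s). Models without
    an omega>1 class yield an empty call list.
    """
    pos = _positive_mask(fit)
    if not pos.any() and method.upper() != "BEB":
        return np.zeros(fit.site_posteriors.shape[1]), []
    if method.upper() == "NEB":
        prob = fit.site_posteriors[pos].sum(axis=0)
    elif method.upper() in ("BEB", "BEB-GRID"):
        if fit.model != "M8":
            raise ValueError("grid BEB is implemented for M8 fits")
        prob = _beb_m8(fit, grid_points)
    else:
        raise ValueError(f"unknown EB method {method!r}")

    ref_map = (
        map_to_reference(codon_aln, ref_id)
        if codon_aln is not None and ref_id is not None
        else {}
    )
    lo, hi = thresholds
    calls = [
        SiteSelectionCall(
            site=s + 1,
            ref_site=ref_map.get(s + 1),
            probability=float(p),
            tier=f"p>{hi}" if p > hi else f"p>{lo}",
        )
        for s, p in enumerate(prob)
        if p > lo
    ]
    return prob, calls


def _beb_m8(fit: SiteModelFit, grid_points: int) -> np.ndarray:
    """Coarse-grid Bayes empirical Bayes for M8's omega>1 class.

    Site likelihoods are precomputed on an omega grid and interpolated, then
    averaged over a uniform prior on (p0, p, q, omega_s), weighting each grid
    point by its marginal likelihood.
    """
    engine: CodonLikelihood = fit.engine
    model = GY94(engine.pi, fit.params["kappa"])
    bls = fit.branch_lengths

    # log-likelihood per pattern on an omega knot grid
    knots = np.concatenate([
        np.linspace(0.0, 1.0, 21) ** 2,            # dense near 0
        1.0 + np.linspace(0.1, 10.0, 12),
    ])
    knots = np.unique(np.clip(knots, 1e-8, None))
    # hold the mixture's time scale at its MLE value while the grid prior
    # varies, so single-omega knot likelihoods stay one-dimensional in omega
    props = np.asarray(fit.class_proportions, dtype=float)
    oms_mle = np.asarray(fit.class_omegas, dtype=float)
    fluxes_mle = np.array([raw_flux(engine.pi, model.kappa, om) for om in oms_mle])
    mean_flux = float((props * fluxes_mle).sum())
    logL_rows = []
    for om in knots:
        scale = raw_flux(engine.pi, model.kappa, om) / mean_flux
        lik, ls = engine._pattern_likelihoods(model, om, bls * scale)
        with np.errstate(divide="ignore"):
            logL_rows.append(np.log(lik) + ls)
    logL_knots = np.vstack(logL_rows)

    def interp_logL(om):
        om = np.clip(om, knots[0], knots[-1])
        k = np.searchsorted(knots, om) - 1
        k = np.clip(k, 0, len(knots) - 2)
        w = (om - knots[k]) / (knots[k + 1] - knots[k])
        return (1 - w) * logL_knots[k] + w * logL_knots[k + 1]

    g = grid_points
    p0_grid = np.linspace(0.05, 0.95, g)
    pq_grid = np.exp(np.linspace(math.log(0.1), math.log(10.0), g))
    ws_grid = np.linspace(1.2, 11.0, g)

    wts = engine.pattern_weights
    post_acc = np.zeros(engine.n_patterns)
    log_marg = []
    site_pos = []
    for p in pq_grid:
        for q in pq_grid:
            oms = beta_class_omegas(p, q, 10)
            beta_logL = np.vstack([interp_logL(o) for o in oms])
            for ws in ws_grid:
                pos_logL = interp_logL(ws)
                for p0 in p0_grid:
                    cls_logL = np.vstack([beta_logL, pos_logL[None, :]])
                    logpr = np.log(np.concatenate([np.full(10, p0 / 10), [1 - p0]]))
                    w = logpr[:, None] + cls_logL
                    m = w.max(axis=0)
                    mix = m + np.log(np.exp(w - m).sum(axis=0))
                    log_marg.append(float((mix * wts).sum()))
                    site_pos.append(np.exp(w[-1] - mix))
    log_marg = np.array(log_marg)
    gw = np.exp(log_marg - log_marg.max())
    gw /= gw.sum()
    for wgt, sp in zip(gw, site_pos):
        post_acc += wgt * sp
    return post_acc[engine.site_to_pattern]


# ---------------------------------------------------------------------------
# Simulation under the same machinery (reused by the synthetic-data module)


def simulate_codon_alignment(
    tree,
    n_codons: int,
    kappa: float,
    site_classes,
    rng,
    pi: np.ndarray | None = None,
    fg_leaves=None,
    fg_omegas=None,
    root_states: np.ndarray | None = None,
    fixed_columns: dict[int, str] | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codon sequences along ``tree`` under the GY94 process.

    ``site_classes`` is a list of (proportion, omega); each site draws its
    class once (returned as the truth vector). ``fixed_columns`` pins chosen
    codon columns to a constant codon in every sequence (used to hold the
    family's diagnostic motif invariant). With ``fg_leaves``/``fg_omegas``
    the clade spanned by those leaves evolves under per-class foreground
    omegas instead.
    """
    t = _as_dendropy(tree)
    pi = uniform_frequencies() if pi is None else np.asarray(pi)
    model = GY94(pi, kappa)
    props = np.array([c[0] for c in site_classes], dtype=float)
    props = props / props.sum()
    omegas = np.array([c[1] for c in site_classes], dtype=float)
    classes = rng.choice(len(props), size=n_codons, p=props)
    # one shared time scale across the class mixture (see the likelihood)
    mults = class_rate_multipliers(pi, kappa, props, omegas)
    mean_flux = raw_flux(pi, kappa, omegas[0]) / mults[0]
    fg_mults = (
        np.array([raw_flux(pi, kappa, om) for om in fg_omegas]) / mean_flux
        if fg_omegas is not None
        else None
    )

    fg_set = set(fg_leaves) if fg_leaves else None

    def edge_is_fg(nd):
        if fg_set is None:
            return False
        below = {lf.taxon.label for lf in nd.leaf_iter()}
        return below <= fg_set

    root = t.seed_node
    states = {
        id(root): (
            rng.choice(N_CODONS, size=n_codons, p=pi)
            if root_states is None
            else np.asarray(root_states)
        )
    }
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        bl = nd.edge.length if nd.edge.length is not None else 0.1
        parent_states = states[id(nd.parent_node)]
        child = np.empty(n_codons, dtype=int)
        fg = edge_is_fg(nd)
        for k in range(len(props)):
            if fg and fg_omegas is not None:
                om, mult = fg_omegas[k], fg_mults[k]
            else:
                om, mult = omegas[k], mults[k]
            mask = classes == k
            if not mask.any():
                continue
            P = model.transition_matrix(om, bl * mult)
            # vectorized categorical draw per site
            u = rng.random(mask.sum())
            cum = P[parent_states[mask]].cumsum(axis=1)
            child[mask] = (u[:, None] > cum).sum(axis=1)
        states[id(nd)] = child

    ids, rows = [], []
    for lf in t.leaf_node_iter():
        st = states[id(lf)]
        codons = [SENSE_CODONS[s] for s in st]
        if fixed_columns:
            for col, codon in fixed_columns.items():
                codons[col] = codon
        ids.append(lf.taxon.label)
        rows.append("".join(codons))
    return CodonAlignment(ids=ids, rows=rows), classes
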