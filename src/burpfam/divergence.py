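"""Gu-style type-I and type-II functional divergence between subfamily
clusters.

Type I divergence captures site-specific shifts in evolutionary *rate* after
duplication: a site highly conserved in one cluster but variable in the
other. Following Gu (1999), per-site substitution counts within each cluster
(Fitch parsimony minima) are modelled as Poisson draws whose rates are
either shared between the clusters (drawn once from a gamma distribution,
probability 1 - theta) or independent (probability theta). theta_I, the
gamma shape and the cluster depths are estimated by maximum likelihood; Qk
is the posterior that a site is in the independent-rate (divergent) state.

Type II divergence captures conserved-in-both sites whose residues differ
*radically* in biochemical property between the clusters. A moment-style
estimator compares the observed fraction of radical differences among
conserved-in-both, differing sites with the background expectation under no
divergence; the coefficient is deliberately not clamped, so sampling noise
can make it negative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .phylo import PhyloTree, ProteinAlignment

GAPS = frozenset("-.X")

#: default amino-acid property partition (charge / polarity / hydrophobicity;
#: C, G and P form their own "special" class)
DEFAULT_PROPERTY_PARTITION = {
    "positive": set("KRH"),
    "negative": set("DE"),
    "polar": set("STNQY"),
    "hydrophobic": set("AVLIMFW"),
    "special": set("CGP"),
}


def _property_of(aa: str, partition) -> str | None:
    for name, members in partition.items():
        if aa in members:
            return name
    return None


def radical_fraction_baseline(partition=None) -> float:
    """Expected radical fraction among amino-acid replacements under no
    functional divergence: the proportion of single-nucleotide-step codon
    changes (sense to sense, amino acid altered) that cross the property
    partition. Genetic-code informed and composition independent."""
    from ._gencode import CODON_TO_AA, NUCS, SENSE_CODONS

    if partition is None:
        partition = DEFAULT_PROPERTY_PARTITION
    radical = total = 0
    for codon in SENSE_CODONS:
        aa = CODON_TO_AA[codon]
        for pos in range(3):
            for nt in NUCS:
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                if mut not in SENSE_CODONS:
                    continue
                bb = CODON_TO_AA[mut]
                if bb == aa:
                    continue
                total += 1
                if _property_of(aa, partition) != _property_of(bb, partition):
                    radical += 1
    return radical / total


@dataclass
class DivergenceEstimate:
    theta: float
    se: float
    lrt: float | None = None
    p_value: float | None = None
    qk: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Fitch parsimony substitution counts


def fitch_counts(tree, aln: ProteinAlignment) -> list[int | None]:
    """Minimum substitution count per alignment column (Fitch parsimony).

    Gap or X residues are treated as missing (they constrain nothing);
    columns with no informative residue are ``None`` (excluded downstream).
    """
    t = tree.tree if isinstance(tree, PhyloTree) else tree
    if not isinstance(t, dendropy.Tree):
        t = dendropy.Tree.get(data=str(t), schema="newick")
    row_of = dict(zip(aln.ids, aln.rows))
    for lf in t.leaf_node_iter():
        if lf.taxon.label not in row_of:
            raise ValueError(f"leaf {lf.taxon.label!r} missing from alignment")
    counts: list[int | None] = []
    post = list(t.postorder_node_iter())
    for col in range(aln.length):
        changes = 0
        seen_any = False
        sets: dict[int, frozenset | None] = {}
        for nd in post:
            if nd.is_leaf():
                aa = row_of[nd.taxon.label][col].upper()
                sets[id(nd)] = None if aa in GAPS else frozenset(aa)
                if aa not in GAPS:
                    seen_any = True
            else:
                child_sets = [
                    sets[id(ch)] for ch in nd.child_nodes() if sets[id(ch)] is not None
                ]
                if not child_sets:
                    sets[id(nd)] = None
                    continue
                inter = frozenset.intersection(*child_sets)
                if inter:
                    sets[id(nd)] = inter
                else:
                    sets[id(nd)] = frozenset.union(*child_sets)
                    changes += len(child_sets) - len(
                        _max_compatible(child_sets)
                    )
        counts.append(changes if seen_any else None)
    return counts


def _max_compatible(child_sets):
    """Fitch on a multifurcating node: the union step costs (number of
    children) minus (largest subset of children sharing a state)."""
    best = 1
    state_count: Counter = Counter()
    for s in child_sets:
        for st in s:
            state_count[st] += 1
    if state_count:
        best = max(state_count.values())
    return range(best)  # only the length is used


# ---------------------------------------------------------------------------
# Type I: two-state rate mixture on paired counts


def _log_joint_shared(xa, xb, da, db, alpha):
    """log P(xa, xb) when one gamma(alpha, alpha) rate drives both clusters."""
    return (
        special.gammaln(xa + xb + alpha)
        - special.gammaln(xa + 1)
        - special.gammaln(xb + 1)
        - special.gammaln(alpha)
        + xa * np.log(da)
        + xb * np.log(db)
        + alpha * np.log(alpha)
        - (xa + xb + alpha) * np.log(da + db + alpha)
    )


def _log_marginal(x, d, alpha):
    """log P(x) for one cluster: negative binomial from the gamma mixing."""
    return (
        special.gammaln(x + alpha)
        - special.gammaln(x + 1)
        - special.gammaln(alpha)
        + x * np.log(d)
        + alpha * np.log(alpha)
        - (x + alpha) * np.log(d + alpha)
    )


def estimate_theta1(
    counts_a,
    counts_b,
    qk_threshold: float = 0.95,
) -> DivergenceEstimate:
    """ML estimate of the type-I divergence coefficient from paired per-site
    substitution counts of two clusters."""
    pairs = [
        (a, b)
        for a, b in zip(counts_a, counts_b)
        if a is not None and b is not None
    ]
    if not pairs:
        raise ValueError("no sites with counts in both clusters")
    xa = np.array([p[0] for p in pairs], dtype=float)
    xb = np.array([p[1] for p in pairs], dtype=float)
    if xa.max() == 0 and xb.max() == 0:
        raise ValueError("all sites invariant in both clusters: theta undefined")

    def nll(z, theta_fixed=None):
        if theta_fixed is None:
            theta = 1.0 / (1.0 + np.exp(-z[0]))
            la, lb, lal = z[1:]
        else:
            theta = theta_fixed
            la, lb, lal = z
        da, db, alpha = np.exp(la), np.exp(lb), np.exp(lal)
        shared = _log_joint_shared(xa, xb, da, db, alpha)
        indep = _log_marginal(xa, da, alpha) + _log_marginal(xb, db, alpha)
        m = np.maximum(shared, indep)
        ll = m + np.log(
            (1 - theta) * np.exp(shared - m) + theta * np.exp(indep - m)
        )
        return -ll.sum()

    da0 = max(xa.mean(), 0.05)
    db0 = max(xb.mean(), 0.05)
    x0 = np.array([0.0, np.log(da0), np.log(db0), 0.0])
    bounds = [(-9, 9), (-6, 6), (-6, 6), (-4, 4)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    x0_null = res.x[1:]
    res_null = optimize.minimize(
        lambda z: nll(z, theta_fixed=0.0), x0_null,
        method="L-BFGS-B", bounds=bounds[1:],
    )
    theta = 1.0 / (1.0 + np.exp(-res.x[0]))
    da, db, alpha = np.exp(res.x[1:])
    lrt = 2.0 * (res_null.fun - res.fun)
    p_value = float(stats.chi2.sf(max(lrt, 0.0), 1))

    # posterior of the independent-rate (divergent) state per site
    shared = _log_joint_shared(xa, xb, da, db, alpha)
    indep = _log_marginal(xa, da, alpha) + _log_marginal(xb, db, alpha)
    w1 = np.log(max(theta, 1e-300)) + indep
    w0 = np.log(max(1 - theta, 1e-300)) + shared
    m = np.maximum(w0, w1)
    qk = np.exp(w1 - m) / (np.exp(w0 - m) + np.exp(w1 - m))

    se = _theta_se(nll, res.x)
    return DivergenceEstimate(
        theta=float(theta),
        se=se,
        lrt=float(lrt),
        p_value=p_value,
        qk=qk,
        params={"d_a": float(da), "d_b": float(db), "alpha": float(alpha),
                "qk_threshold": qk_threshold},
    )


def _theta_se(nll, x_hat) -> float:
    """Delta-method SE of theta from the numerical Hessian in logit space."""
    eps = 1e-4
    n = len(x_hat)
    H = np.zeros((n, n))
    f0 = nll(x_hat)
    for i in range(n):
        for j in range(i, n):
            xi = x_hat.copy(); xi[i] += eps
            xj = x_hat.copy(); xj[j] += eps
            xij = x_hat.copy(); xij[i] += eps; xij[j] += eps
            H[i, j] = H[j, i] = (nll(xij) - nll(xi) - nll(xj) + f0) / eps**2
    try:
        cov = np.linalg.inv(H)
        var_z = max(cov[0, 0], 0.0)
    except np.linalg.LinAlgError:
        return float("nan")
    theta = 1.0 / (1.0 + np.exp(-x_hat[0]))
    return float(np.sqrt(var_z) * theta * (1 - theta))


# ---------------------------------------------------------------------------
# Type II: radical property shifts at conserved sites


def consensus_and_conservation(rows: list[str], col: int) -> tuple[str | None, float]:
    """(majority residue, its frequency) among non-gap residues of a column."""
    residues = [r[col].upper() for r in rows if r[col].upper() not in GAPS]
    if not residues:
        return None, 0.0
    top, n = Counter(residues).most_common(1)[0]
    return top, n / len(residues)


def estimate_theta2(
    rows_a: list[str],
    rows_b: list[str],
    partition: dict | None = None,
    conservation: float = 0.8,
    qk_threshold: float = 0.95,
) -> DivergenceEstimate:
    """Moment estimate of type-II divergence from cluster consensus patterns.

    Among columns conserved within both clusters (majority residue frequency
    >= ``conservation``) and differing between them, the fraction of radical
    (cross-property-class) differences is compared with the genetic-code
    baseline (radical fraction among single-nucleotide-step replacements);
    theta_II is the standardized excess, with Qk the posterior of the
    radical-shift state under the implied two-component mixture.
    """
    if partition is None:
        partition = DEFAULT_PROPERTY_PARTITION
    L = len(rows_a[0])
    if any(len(r) != L for r in rows_a + rows_b):
        raise ValueError("cluster rows have unequal lengths")

    r_exp = radical_fraction_baseline(partition)

    site_kind: list[str | None] = []  # None | "same" | "conservative" | "radical"
    for col in range(L):
        ca, fa = consensus_and_conservation(rows_a, col)
        cb, fb = consensus_and_conservation(rows_b, col)
        if ca is None or cb is None or fa < conservation or fb < conservation:
            site_kind.append(None)
            continue
        if ca == cb:
            site_kind.append("same")
        elif _property_of(ca, partition) != _property_of(cb, partition):
            site_kind.append("radical")
        else:
            site_kind.append("conservative")

    n_same = sum(1 for k in site_kind if k == "same")
    n_cons = sum(1 for k in site_kind if k == "conservative")
    n_rad = sum(1 for k in site_kind if k == "radical")
    n_diff = n_cons + n_rad
    if n_same + n_diff == 0:
        raise ValueError("no sites conserved in both clusters")
    flags = []
    if n_diff == 0:
        # no divergent conserved sites at all: coefficient is zero by
        # construction, with no per-site signal
        theta = 0.0
        se = 0.0
        flags.append("no conserved-in-both differing sites")
        qk = np.zeros(L)
    else:
        r_obs = n_rad / n_diff
        denom = 1.0 - r_exp
        theta = (r_obs - r_exp) / denom if denom > 0 else 0.0
        se = float(
            np.sqrt(max(r_obs * (1 - r_obs), 1e-12) / n_diff) / max(denom, 1e-12)
        )
        # mixture posterior: divergent component emits radical with prob 1,
        # the null component with prob r_exp
        th = min(max(theta, 0.0), 1.0)
        qk = np.zeros(L)
        for col, kind in enumerate(site_kind):
            if kind == "radical":
                num = th * 1.0
                den = num + (1 - th) * r_exp
                qk[col] = num / den if den > 0 else 0.0
    return DivergenceEstimate(
        theta=float(theta),
        se=se,
        qk=qk,
        params={
            "r_exp": r_exp,
            "n_same": n_same,
            "n_conservative": n_cons,
            "n_radical": n_rad,
            "conservation": conservation,
            "qk_threshold": qk_threshold,
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Cluster-pair orchestration


@dataclass
class ClusterPair:
    label_a: str
    label_b: str
    ids_a: list[str]
    ids_b: list[str]

    def __post_init__(self):
        if set(self.ids_a) & set(self.ids_b):
            raise ValueError("clusters must be disjoint")
        if len(self.ids_a) < 4 or len(self.ids_b) < 4:
            raise ValueError("each cluster needs >= 4 sequences")


def divergence_table(
    aln: ProteinAlignment,
    tree,
    cluster_pairs: list[ClusterPair],
    ref_id: str | None = None,
    qk_threshold: float = 0.95,
):
    """Type-I and type-II estimates for each cluster pair, one row each."""
    import pandas as pd

    t = tree.tree if isinstance(tree, PhyloTree) else tree
    rows = []
    for cp in cluster_pairs:
        sub_a = aln.subset(cp.ids_a)
        sub_b = aln.subset(cp.ids_b)
        tree_a = _extract_subtree(t, cp.ids_a)
        tree_b = _extract_subtree(t, cp.ids_b)
        counts_a = fitch_counts(tree_a, sub_a)
        counts_b = fitch_counts(tree_b, sub_b)
        est1 = estimate_theta1(counts_a, counts_b, qk_threshold)
        est2 = estimate_theta2(sub_a.rows, sub_b.rows, qk_threshold=qk_threshold)
        ref_map = _ref_map(aln, ref_id) if ref_id else {}
        sites1 = [
            ref_map.get(i + 1, i + 1)
            for i in np.nonzero(est1.qk > qk_threshold)[0]
        ]
        sites2 = [
            ref_map.get(i + 1, i + 1)
            for i in np.nonzero(est2.qk > qk_threshold)[0]
        ]
        rows.append(
            dict(
                group_a=cp.label_a,
                group_b=cp.label_b,
                theta1=est1.theta,
                theta1_se=est1.se,
                lrt=est1.lrt,
                n_sites_type1=len(sites1),
                sites_type1=",".join(map(str, sites1)),
                theta2=est2.theta,
                theta2_se=est2.se,
                n_sites_type2=len(sites2),
                sites_type2=",".join(map(str, sites2)),
            )
        )
    return pd.DataFrame(rows)


def _extract_subtree(t: dendropy.Tree, keep_ids) -> dendropy.Tree:
    sub = t.clone(depth=1)
    sub.retain_taxa_with_labels(list(keep_ids))
    return sub


def _ref_map(aln: ProteinAlignment, ref_id: str) -> dict[int, int]:
    row = aln.rows[aln.ids.index(ref_id)]
    out = {}
    k = 0
    for col, aa in enumerate(row, start=1):
        if aa not in "-.":
            k += 1
            out[col] = k
    return out
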