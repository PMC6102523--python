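"""Reproduction checks on the published numeric tables plus property-based
validation runs on synthetic data with known truth.

The printed tables (segmental pairs with mean Ks, tandem pairs with 4DTv,
site-model log-likelihoods) ship as fixture transcriptions so the checks run
offline; everything else is recomputed from scratch by the package's own
machinery at call time.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _stats

from . import duplication, selection
from .codon_tools import CodonAlignment
from .synthetic_data import SimConfig, simulate_family, plant_truth_check


def _data_path(name):
    return resources.files("burpfam.data") / name


def load_segmental_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("published_segmental_pairs.tsv"), sep="\t")


def load_tandem_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("published_tandem_4dtv.tsv"), sep="\t")


def load_site_model_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("published_site_model_lnl.tsv"), sep="\t")


def load_builtin_clock_rates() -> dict[str, float]:
    with open(_data_path("clock_rates.yaml")) as fh:
        return {k: float(v) for k, v in yaml.safe_load(fh).items()}


# ---------------------------------------------------------------------------
# Printed-table reproductions


def segmental_dating() -> pd.DataFrame:
    """Recompute every segmental duplication age from its printed mean Ks and
    the species clock rate; adds ``age_mya`` next to ``age_printed_mya``."""
    tbl = load_segmental_table().copy()
    rates = load_builtin_clock_rates()
    ages = [
        duplication.date_pair(row.ks_mean, rates[row.species])[0]
        for row in tbl.itertuples()
    ]
    tbl["age_mya"] = ages
    return tbl


def pair_bookkeeping(d4dtv_cut: float = 0.1) -> dict:
    """Pair and gene counts from the fixture transcriptions."""
    t2 = load_segmental_table()
    t3 = load_tandem_table()
    seg_pairs = [
        duplication.DuplicationPair(id_a=r.gene_a, id_b=r.gene_b, mode="segmental")
        for r in t2.itertuples()
    ]
    return {
        "n_segmental_pairs": len(t2),
        "n_segmental_genes": len(duplication.unique_genes(seg_pairs)),
        "n_tandem_pairs": len(t3),
        "n_tandem_pairs_recent": int((t3.d4dtv < d4dtv_cut).sum()),
        "n_tandem_genes": len(set(t3.gene_a) | set(t3.gene_b)),
    }


def lrt_m0_m3() -> selection.LrtResult:
    """LRT statistic from the printed M0 and M3 log-likelihoods (df = 4)."""
    t5 = load_site_model_table().set_index("model")
    return selection.likelihood_ratio_test(
        lnl_alt=float(t5.loc["M3", "lnl"]),
        lnl_null=float(t5.loc["M0", "lnl"]),
        df=int(t5.loc["M3", "n_params"] - t5.loc["M0", "n_params"]),
    )


# ---------------------------------------------------------------------------
# Property-based validation on synthetic data


def _balanced_tree(n_taxa: int, bl: float) -> str:
    ids = [f"t{k}" for k in range(n_taxa)]

    def rec(sub):
        if len(sub) == 1:
            return sub[0]
        mid = len(sub) // 2
        return f"({rec(sub[:mid])}:{bl},{rec(sub[mid:])}:{bl})"

    return rec(ids) + ";"


def m0_omega_recovery(
    seed: int, n_taxa: int = 8, n_codons: int = 500,
    omega_true: float = 0.2, kappa: float = 2.0, bl: float = 0.25,
) -> dict:
    """Simulate one dataset under a single-omega model and refit it."""
    rng = np.random.default_rng(seed)
    tree = _balanced_tree(n_taxa, bl)
    aln, _ = selection.simulate_codon_alignment(
        tree, n_codons, kappa, [(1.0, omega_true)], rng
    )
    fit = selection.fit_site_model("M0", tree, aln, n_restarts=2, seed=seed)
    return {
        "omega_hat": float(fit.params["omega"]),
        "kappa_hat": float(fit.params["kappa"]),
        "lnl": fit.lnl,
        "n": n_taxa * n_codons,
    }


def m7m8_null_calibration(
    seed: int, n_reps: int = 50, n_taxa: int = 5, n_codons: int = 100,
    p_beta: float = 0.8, q_beta: float = 2.0, kappa: float = 2.0,
    bl: float = 0.3, alpha: float = 0.05,
) -> dict:
    """Size of the M7-vs-M8 LRT under the null (data simulated under M7)."""
    rng = np.random.default_rng(seed)
    tree = _balanced_tree(n_taxa, bl)
    beta_oms = selection.beta_class_omegas(p_beta, q_beta, 10)
    classes = [(0.1, float(o)) for o in beta_oms]
    crit = float(_stats.chi2.ppf(1 - alpha, 2))
    rejections = 0
    stats_seen = []
    for rep in range(n_reps):
        aln, _ = selection.simulate_codon_alignment(
            tree, n_codons, kappa, classes, rng
        )
        m0 = selection.fit_site_model("M0", tree, aln, n_restarts=1, seed=seed + rep)
        bls = m0.branch_lengths
        m7 = selection.fit_site_model(
            "M7", tree, aln, branch_lengths=bls, n_restarts=1, seed=seed + rep
        )
        m8 = selection.fit_site_model(
            "M8", tree, aln, branch_lengths=bls, n_restarts=1, seed=seed + rep
        )
        stat = 2.0 * (m8.lnl - m7.lnl)
        stats_seen.append(stat)
        if stat > crit:
            rejections += 1
    return {
        "rejection_rate": rejections / n_reps,
        "n": n_reps,
        "stats": stats_seen,
    }


def eb_planted_site_recovery(
    seed: int, n_taxa: int = 8, n_codons: int = 300,
    omega_bg: float = 0.2, omega_pos: float = 5.0, p_pos: float = 0.10,
    kappa: float = 2.0, bl: float = 0.25, threshold: float = 0.95,
) -> dict:
    """Plant strongly selected sites, refit M8 and call sites by NEB."""
    rng = np.random.default_rng(seed)
    tree = _balanced_tree(n_taxa, bl)
    aln, classes = selection.simulate_codon_alignment(
        tree, n_codons, kappa, [(1 - p_pos, omega_bg), (p_pos, omega_pos)], rng
    )
    fit = selection.fit_site_model("M8", tree, aln, n_restarts=2, seed=seed)
    prob, calls = selection.eb_site_posteriors(fit, method="NEB")
    called = {c.site - 1 for c in calls}
    planted = set(np.nonzero(classes == 1)[0])
    tp = len(called & planted)
    return {
        "recall": tp / len(planted) if planted else None,
        "false_call_rate": (len(called) - tp) / len(called) if called else 0.0,
        "n_called": len(called),
        "n_planted": len(planted),
        "n": n_codons,
    }


def theta1_recovery(
    seed: int, n_reps: int = 20, n_sites: int = 300,
    theta_true: float = 0.5, alpha: float = 1.0, depth: float = 2.0,
) -> dict:
    """Parameter recovery for the type-I divergence mixture on counts drawn
    from its own generative model."""
    from .divergence import estimate_theta1

    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        indep = rng.random(n_sites) < theta_true
        lam_a = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
        lam_b = np.where(
            indep, rng.gamma(alpha, 1.0 / alpha, size=n_sites), lam_a
        )
        xa = rng.poisson(depth * lam_a)
        xb = rng.poisson(depth * lam_b)
        est = estimate_theta1(list(xa), list(xb))
        estimates.append(est.theta)
    return {
        "theta_mean": float(np.mean(estimates)),
        "theta_sd": float(np.std(estimates)),
        "n": n_reps,
    }


def end_to_end_synthetic(seed: int) -> dict:
    """Full pipeline on one simulated family: member detection, duplication
    classification and dating, promoter element counts, all against truth."""
    from . import family_scan, promoter

    cfg = SimConfig(seed=seed, promoter_background="at_only")
    fam = simulate_family(cfg)
    catalog = family_scan.build_catalog(fam.proteins, fam.cds)
    family_ids = set(catalog.ids)
    tandem = duplication.tandem_pairs(fam.gene_models, family_ids)
    segmental = duplication.segmental_pairs(fam.anchor_sets, family_ids)
    for p in segmental:
        sp = p.id_a.split("g")[0]
        p.age_mya, _ = duplication.date_pair(p.ks_mean, fam.clock_rates[sp])
    hits = []
    for g in fam.gene_models:
        if g.id in family_ids:
            window, _ = promoter.extract_upstream(fam.genome, g, cfg.window)
            hits.extend(promoter.scan_elements(window, fam.element_defs, g.id))
    report = plant_truth_check(
        {
            "catalog": catalog,
            "tandem": tandem,
            "segmental": segmental,
            "element_hits": hits,
        },
        fam,
    )
    report["n"] = len(fam.truth_members)
    return report
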