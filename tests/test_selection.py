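"""GY94 machinery: rate matrix, pruning likelihood, model fits, EB calls."""

import numpy as np
import pytest

from burpfam._gencode import CODON_INDEX, CODON_TO_AA, SENSE_CODONS, is_transition
from burpfam.codon_tools import CodonAlignment
from burpfam.selection import (
    CodonLikelihood,
    GY94,
    beta_class_omegas,
    build_rate_matrix,
    class_rate_multipliers,
    eb_site_posteriors,
    f3x4_frequencies,
    fit_branch_site,
    fit_site_model,
    likelihood_ratio_test,
    simulate_codon_alignment,
    uniform_frequencies,
)

PI = uniform_frequencies()


class TestRateMatrix:
    def test_rows_sum_to_zero(self, rng):
        pi = rng.dirichlet(np.ones(61))
        Q = build_rate_matrix(pi, 2.5, 0.4)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self, rng):
        pi = rng.dirichlet(np.ones(61))
        Q = build_rate_matrix(pi, 3.0, 0.7)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_unit_expected_flux(self):
        Q = build_rate_matrix(PI, 2.0, 0.3)
        assert -(PI * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_entries_match_hand_computation(self):
        """Spot-check off-diagonal entries against the defining formula."""
        kappa, omega = 2.0, 0.3
        Q = build_rate_matrix(PI, kappa, omega)
        # unscaled rates, then normalize the same way
        raw = np.zeros((61, 61))
        for i, ca in enumerate(SENSE_CODONS):
            for j, cb in enumerate(SENSE_CODONS):
                diffs = [p for p in range(3) if ca[p] != cb[p]]
                if len(diffs) != 1:
                    continue
                p = diffs[0]
                r = PI[j]
                if is_transition(ca[p], cb[p]):
                    r *= kappa
                if CODON_TO_AA[ca] != CODON_TO_AA[cb]:
                    r *= omega
                raw[i, j] = r
        scale = (PI * raw.sum(axis=1)).sum()
        i, j = CODON_INDEX["TTT"], CODON_INDEX["TTC"]  # syn transition
        assert Q[i, j] == pytest.approx(raw[i, j] / scale)
        i, j = CODON_INDEX["TTT"], CODON_INDEX["TTA"]  # syn transversion
        assert Q[i, j] == pytest.approx(raw[i, j] / scale)
        i, j = CODON_INDEX["TTT"], CODON_INDEX["GTT"]  # nonsyn transversion
        assert Q[i, j] == pytest.approx(raw[i, j] / scale)
        assert Q[CODON_INDEX["TTT"], CODON_INDEX["GGG"]] == 0.0  # >1 difference

    def test_transition_matrix_is_stochastic(self):
        model = GY94(PI, 2.0)
        P = model.transition_matrix(0.5, 0.7)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_class_multipliers_average_to_one(self):
        props = np.array([0.6, 0.3, 0.1])
        mults = class_rate_multipliers(PI, 2.0, props, [0.05, 0.5, 3.0])
        assert (props * mults).sum() == pytest.approx(1.0)
        assert mults[2] > mults[1] > mults[0]  # higher omega, faster clock


class TestLikelihood:
    def test_identical_sequences_zero_branches(self):
        aln = CodonAlignment(ids=["A", "B"], rows=["ATGTTT", "ATGTTT"])
        eng = CodonLikelihood("(A:0,B:0);", aln, pi=PI)
        lnl = eng.loglik(2.0, [(1.0, 0.5)], np.zeros(eng.n_edges))
        expected = sum(np.log(PI[CODON_INDEX[c]]) for c in ("ATG", "TTT"))
        assert lnl == pytest.approx(expected, abs=1e-8)

    def test_three_taxon_brute_force_enumeration(self):
        """Pruning equals the explicit sum over 61^2 internal states."""
        tree = "((A:0.2,B:0.3):0.1,C:0.4);"
        aln = CodonAlignment(ids=["A", "B", "C"], rows=["ATGTTT", "ATGTTC", "ACGTTA"])
        eng = CodonLikelihood(tree, aln, pi=PI)
        lnl = eng.loglik(2.0, [(1.0, 0.5)], eng.branch_lengths())
        model = GY94(PI, 2.0)
        P = {t: model.transition_matrix(0.5, t) for t in (0.1, 0.2, 0.3, 0.4)}
        states = [[CODON_INDEX[r[3 * s : 3 * s + 3]] for r in aln.rows] for s in range(2)]
        brute = 0.0
        for a, b, c in states:
            site = 0.0
            for root in range(61):
                inner = P[0.1][root] @ (P[0.2][:, a] * P[0.3][:, b])
                site += PI[root] * inner * P[0.4][root, c]
            brute += np.log(site)
        assert lnl == pytest.approx(brute, abs=1e-8)

    def test_gap_codon_treated_as_missing(self):
        aln = CodonAlignment(ids=["A", "B"], rows=["ATG---", "ATGTTT"])
        eng = CodonLikelihood("(A:0.1,B:0.1);", aln, pi=PI)
        aln1 = CodonAlignment(ids=["A", "B"], rows=["ATG", "ATG"])
        eng1 = CodonLikelihood("(A:0.1,B:0.1);", aln1, pi=PI)
        # site 2 integrates out: its contribution is ln pi-marginal of B's codon
        full = eng.loglik(2.0, [(1.0, 1.0)], eng.branch_lengths())
        first = eng1.loglik(2.0, [(1.0, 1.0)], eng1.branch_lengths())
        assert full < first  # the extra site has probability < 1
        assert full == pytest.approx(first + np.log(PI[CODON_INDEX["TTT"]]), abs=1e-8)

    def test_rerooting_invariance(self, rng):
        aln, _ = simulate_codon_alignment(
            "((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.1);", 40, 2.0, [(1.0, 0.4)], rng
        )
        t1 = "((A:0.2,B:0.3):0.2,C:0.15,D:0.25);"  # rerooted at the CD node
        eng0 = CodonLikelihood("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.1);", aln, pi=PI)
        eng1 = CodonLikelihood(t1, aln, pi=PI)
        l0 = eng0.loglik(2.0, [(1.0, 0.4)], eng0.branch_lengths())
        l1 = eng1.loglik(2.0, [(1.0, 0.4)], eng1.branch_lengths())
        assert l0 == pytest.approx(l1, abs=1e-8)

    def test_zero_proportion_class_changes_nothing(self, rng):
        aln, _ = simulate_codon_alignment(
            "(A:0.2,B:0.3,C:0.1);", 30, 2.0, [(1.0, 0.3)], rng
        )
        eng = CodonLikelihood("(A:0.2,B:0.3,C:0.1);", aln, pi=PI)
        bls = eng.branch_lengths()
        base = eng.loglik(2.0, [(1.0, 0.3)], bls)
        padded = eng.loglik(2.0, [(1.0, 0.3), (0.0, 5.0)], bls)
        assert padded == pytest.approx(base, abs=1e-9)

    def test_f3x4_frequencies_sum_to_one(self, rng):
        aln, _ = simulate_codon_alignment(
            "(A:0.2,B:0.3,C:0.1);", 50, 2.0, [(1.0, 0.3)], rng
        )
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)
        assert pi.min() > 0


@pytest.fixture(scope="module")
def small_data():
    rng = np.random.default_rng(42)
    tree = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"
    aln, _ = simulate_codon_alignment(tree, 150, 2.0, [(1.0, 0.3)], rng)
    return tree, aln


class TestFits:
    def test_m0_recovers_omega_roughly(self, small_data):
        tree, aln = small_data
        fit = fit_site_model("M0", tree, aln, n_restarts=1, seed=0)
        # small data: just a loose sanity band around the true 0.3
        assert 0.1 <= fit.params["omega"] <= 0.7
        assert fit.converged

    def test_m3_likelihood_dominates_m0(self, small_data):
        tree, aln = small_data
        m0 = fit_site_model("M0", tree, aln, n_restarts=1, seed=0)
        m3 = fit_site_model(
            "M3", tree, aln, branch_lengths=m0.branch_lengths, n_restarts=2, seed=0
        )
        assert m3.lnl >= m0.lnl - 1e-6
        assert m3.class_proportions.sum() == pytest.approx(1.0)

    def test_beta_discretization_means(self):
        oms = beta_class_omegas(2.0, 2.0, 10)
        assert len(oms) == 10
        assert np.all(np.diff(oms) > 0)
        assert oms.mean() == pytest.approx(0.5, abs=1e-6)
        assert np.all((oms > 0) & (oms < 1))

    def test_site_posteriors_sum_to_one(self, small_data):
        tree, aln = small_data
        fit = fit_site_model("M3", tree, aln, n_restarts=1, seed=0)
        assert np.abs(fit.site_posteriors.sum(axis=0) - 1).max() < 1e-9


class TestLrt:
    def test_statistic_and_halved_mixture(self):
        r = likelihood_ratio_test(-20403.3, -20918.0, df=4)
        assert r.stat == pytest.approx(1029.4)
        assert r.p_value < 1e-200
        h = likelihood_ratio_test(-100.0, -101.0, df=1, halved=True)
        full = likelihood_ratio_test(-100.0, -101.0, df=1)
        assert h.p_value == pytest.approx(full.p_value / 2)

    def test_negative_statistic_flagged(self):
        r = likelihood_ratio_test(-101.0, -100.0, df=1)
        assert r.flagged and r.stat < 0


class TestBranchSite:
    def test_foreground_whole_tree_is_error(self, rng):
        tree = "(A:0.1,B:0.1,C:0.1);"
        aln, _ = simulate_codon_alignment(tree, 20, 2.0, [(1.0, 0.3)], rng)
        eng = CodonLikelihood(tree, aln)
        with pytest.raises(ValueError):
            eng.foreground_mask(["A", "B", "C"])

    def test_null_data_not_rejected_and_proportions_sum(self):
        rng = np.random.default_rng(7)
        tree = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"
        aln, _ = simulate_codon_alignment(tree, 200, 2.0, [(1.0, 0.2)], rng)
        m0 = fit_site_model("M0", tree, aln, n_restarts=1, seed=0)
        alt, null = fit_branch_site(
            tree, aln, ["A", "B"], branch_lengths=m0.branch_lengths,
            n_restarts=1, seed=0,
        )
        assert alt.class_proportions.sum() == pytest.approx(1.0)
        r = likelihood_ratio_test(alt.lnl, null.lnl, 1, halved=True)
        assert r.p_value > 0.05


class TestEbCalls:
    def test_model_without_positive_class_yields_no_calls(self, rng):
        tree = "(A:0.2,B:0.2,C:0.2);"
        aln, _ = simulate_codon_alignment(tree, 30, 2.0, [(1.0, 0.3)], rng)
        fit = fit_site_model("M7", tree, aln, n_restarts=1, seed=0)
        prob, calls = eb_site_posteriors(fit, method="NEB")
        assert calls == [] and np.all(prob == 0)

    def test_uninformative_site_posterior_equals_prior(self):
        # two identical sequences at distance 0: every class explains the
        # data equally, so the class posterior equals the prior proportions
        aln = CodonAlignment(ids=["A", "B"], rows=["ATGTTT", "ATGTTT"])
        eng = CodonLikelihood("(A:0,B:0);", aln, pi=PI)
        classes = [(0.7, 0.1), (0.3, 2.0)]
        post = eng.class_posteriors(2.0, classes, np.zeros(eng.n_edges))
        assert np.allclose(post[0], 0.7) and np.allclose(post[1], 0.3)

    def test_calls_partition_at_tiers(self, rng):
        tree = "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);"
        aln, cls = simulate_codon_alignment(
            tree, 120, 2.0, [(0.8, 0.1), (0.2, 8.0)], rng
        )
        fit = fit_site_model("M8", tree, aln, n_restarts=1, seed=0)
        prob, calls = eb_site_posteriors(fit, method="NEB")
        for c in calls:
            assert c.probability > 0.95
            assert c.tier == ("p>0.99" if c.probability > 0.99 else "p>0.95")
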