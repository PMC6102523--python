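"""Back-translation, NG86 rates and 4DTv."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burpfam._gencode import SENSE_CODONS, translate_cds
from burpfam.codon_tools import back_translate, d4dtv, ng86_rates
from burpfam.family_scan import CdsRecord
from burpfam.phylo import ProteinAlignment

from _oracles import ng86_oracle


class TestBackTranslate:
    def test_gap_expansion(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["M-A", "MKA"])
        cds = [CdsRecord("a", "a", "ATGGCT"), CdsRecord("b", "b", "ATGAAAGCT")]
        ca = back_translate(aln, cds)
        assert ca.rows[0] == "ATG---GCT"
        assert ca.rows[1] == "ATGAAAGCT"

    def test_trailing_stop_trimmed(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["MA", "MA"])
        cds = [CdsRecord("a", "a", "ATGGCTTAA"), CdsRecord("b", "b", "ATGGCT")]
        ca = back_translate(aln, cds)
        assert ca.rows[0] == "ATGGCT"

    def test_translation_mismatch_names_position(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["MK", "MK"])
        cds = [CdsRecord("a", "a", "ATGGCT"), CdsRecord("b", "b", "ATGAAA")]
        with pytest.raises(ValueError, match="column 2"):
            back_translate(aln, cds)

    def test_round_trip_on_simulated_family(self, family):
        aln = family.alignment
        cds = {c.id: c for c in family.cds if c.id in aln.ids}
        ca = back_translate(aln, cds)
        for rid, prow in zip(aln.ids, aln.rows):
            crow = ca.rows[ca.ids.index(rid)]
            back = "".join(
                "-" if crow[i : i + 3] == "---" else translate_cds(crow[i : i + 3])
                for i in range(0, len(crow), 3)
            )
            assert back == prow


class TestNg86:
    def test_identical_rows(self):
        r = ng86_rates("ATGGCT", "ATGGCT")
        assert r.ks == 0.0 and r.ka == 0.0

    def test_hand_worked_single_synonymous_change(self):
        """One synonymous difference at a twofold site among 4 codons."""
        r = ng86_rates("TTTGGAGGAGGA", "TTCGGAGGAGGA")
        assert r.s_sites == pytest.approx(10 / 3)
        assert r.sd == pytest.approx(1.0)
        assert r.ks == pytest.approx(0.3831, abs=1e-4)
        assert r.ka == pytest.approx(0.0)

    def test_site_counts_partition_codon_positions(self, rng):
        codons = rng.choice(SENSE_CODONS, size=30)
        row = "".join(codons)
        r = ng86_rates(row, row)
        assert r.s_sites + r.n_sites == pytest.approx(3 * 30)

    def test_matches_pathway_enumeration_oracle(self, rng):
        """500 random codon pairs against the Fraction-arithmetic oracle."""
        for _ in range(500):
            n = int(rng.integers(1, 6))
            ca = [str(c) for c in rng.choice(SENSE_CODONS, size=n)]
            cb = [str(c) for c in rng.choice(SENSE_CODONS, size=n)]
            r = ng86_rates("".join(ca), "".join(cb))
            S, N, Sd, Nd = ng86_oracle(ca, cb)
            assert r.s_sites == pytest.approx(float(S), abs=1e-9)
            assert r.n_sites == pytest.approx(float(N), abs=1e-9)
            assert r.sd == pytest.approx(float(Sd), abs=1e-9)
            assert r.nd == pytest.approx(float(Nd), abs=1e-9)

    def test_symmetric_under_argument_swap(self, rng):
        rows = ["".join(rng.choice(SENSE_CODONS, size=40)) for _ in range(2)]
        r1, r2 = ng86_rates(rows[0], rows[1]), ng86_rates(rows[1], rows[0])
        assert r1.ks == pytest.approx(r2.ks)
        assert r1.ka == pytest.approx(r2.ka)
        assert r1.s_sites == pytest.approx(r2.s_sites)

    def test_gapped_columns_pairwise_deleted(self):
        r = ng86_rates("ATG---GCT", "ATGAAAGCT")
        assert r.n_codons == 2

    def test_no_comparable_codons_is_error(self):
        with pytest.raises(ValueError):
            ng86_rates("---", "ATG")

    def test_neutral_simulation_ka_ks_near_one(self):
        """Under neutral evolution the expected Ka/Ks ratio is 1.

        The valid regime for this consistency property is an unconstrained
        equal-rate nucleotide process (NG86's own model): nonsense changes
        occur and are scored as nonsynonymous, so stop-containing columns
        are retained. 10,000 codons keep the sampling noise within the
        +/-0.05 band."""
        rng = np.random.default_rng(5)
        L = 30_000
        a = rng.choice(list("ACGT"), size=L)
        b = a.copy()
        for i in np.nonzero(rng.random(L) < 0.12)[0]:
            b[i] = rng.choice([n for n in "ACGT" if n != a[i]])
        r = ng86_rates("".join(a), "".join(b), keep_stop_columns=True)
        assert r.ka / r.ks == pytest.approx(1.0, abs=0.05)


class TestD4dtv:
    def test_identical_rows_zero(self):
        r = d4dtv("GGAGGC", "GGAGGC")
        assert r.d4dtv == 0.0 and r.fourfold_sites == 2

    def test_single_transversion(self):
        r = d4dtv("GGA", "GGT")
        assert r.fourfold_sites == 1 and r.d4dtv == 1.0

    def test_single_transition(self):
        r = d4dtv("GGA", "GGG")
        assert r.fourfold_sites == 1 and r.d4dtv == 0.0

    def test_non_fourfold_prefix_ineligible(self):
        # TT prefix is twofold (Phe/Leu): never eligible
        r = d4dtv("TTT", "TTA")
        assert r.fourfold_sites == 0 and r.d4dtv is None and r.flags

    def test_differing_prefixes_ineligible(self):
        r = d4dtv("GGA", "GCA")
        assert r.fourfold_sites == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        ra = "".join(rng.choice(SENSE_CODONS, size=20))
        rb = "".join(rng.choice(SENSE_CODONS, size=20))
        r = d4dtv(ra, rb)
        if r.d4dtv is not None:
            assert 0.0 <= r.d4dtv <= 1.0

    def test_corrected_variant_exceeds_raw(self):
        rows = ("GGAGGAGGAGGA", "GGTGGAGGAGGA")
        raw = d4dtv(*rows).d4dtv
        corr = d4dtv(*rows, corrected=True).d4dtv
        assert corr > raw > 0
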