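"""Codon alignments and pairwise divergence statistics: NG86 Ks/Ka and 4DTv.

The codon alignment is produced by threading each CDS through its row of the
protein alignment (one aligned residue -> one codon, one gap -> '---').

Ks/Ka follow Nei & Gojobori (1986): synonymous site counts average the
per-position synonymous fractions of the two sequences, multi-hit codons
average the synonymous/nonsynonymous difference counts over all substitution
pathways that avoid stop codons, and both proportions receive the
Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p).

4DTv is the raw proportion of transversions at third positions of codon
columns whose first two bases are identical in both sequences and define a
fourfold-degenerate codon family; it lies in [0, 1] by construction and is a
saturation-robust proxy for the age of a duplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from ._gencode import (
    CODON_TO_AA,
    FOURFOLD_PREFIXES,
    NUCS,
    STOP_CODONS,
    is_transition,
    is_transversion,
    translate_codon,
)
from .family_scan import CdsRecord
from .phylo import ProteinAlignment

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """Gap-aware codon matrix; gaps come in whole-codon units."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        L = len(self.rows[0])
        if L % 3 != 0:
            raise ValueError("codon rows must have length divisible by 3")
        if any(len(r) != L for r in self.rows):
            raise ValueError("codon rows have unequal lengths")

    @property
    def n_codon_columns(self) -> int:
        return len(self.rows[0]) // 3

    def codons(self, row_index: int) -> list[str]:
        r = self.rows[row_index]
        return [r[i : i + 3] for i in range(0, len(r), 3)]

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]


def back_translate(
    protein_aln: ProteinAlignment, cds: dict[str, CdsRecord] | list[CdsRecord]
) -> CodonAlignment:
    """Thread CDS sequences through the protein alignment (PAL2NAL-style).

    A trailing stop codon on the CDS is trimmed before mapping. Any
    disagreement between the translated CDS and the aligned protein row is an
    error naming the sequence and position.
    """
    if not isinstance(cds, dict):
        cds = {c.id: c for c in cds}
    rows = []
    for rid, prow in zip(protein_aln.ids, protein_aln.rows):
        if rid not in cds:
            raise ValueError(f"no CDS for aligned protein {rid!r}")
        nt = cds[rid].sequence.upper()
        if len(nt) % 3 == 0 and nt[-3:] in STOP_CODONS:
            nt = nt[:-3]
        n_res = sum(1 for a in prow if a not in "-.")
        if len(nt) != 3 * n_res:
            raise ValueError(
                f"{rid}: CDS length {len(nt)} nt does not match "
                f"{n_res} aligned residues"
            )
        out = []
        k = 0
        for pos, aa in enumerate(prow, start=1):
            if aa in "-.":
                out.append(GAP_CODON)
                continue
            codon = nt[3 * k : 3 * k + 3]
            k += 1
            trans = translate_codon(codon)
            if aa != "X" and trans != "X" and trans != aa.upper():
                raise ValueError(
                    f"{rid}: codon {codon} at alignment column {pos} "
                    f"translates to {trans}, protein row has {aa}"
                )
            out.append(codon)
        rows.append("".join(out))
    return CodonAlignment(ids=list(protein_aln.ids), rows=rows)


@dataclass
class PairwiseRates:
    """NG86 and 4DTv statistics for one sequence pair."""

    ks: float | None = None
    ka: float | None = None
    s_sites: float = 0.0
    n_sites: float = 0.0
    sd: float = 0.0
    nd: float = 0.0
    n_codons: int = 0
    fourfold_sites: int = 0
    fourfold_transversions: int = 0
    d4dtv: float | None = None
    saturated: bool = False
    flags: list[str] = field(default_factory=list)


def _comparable_codons(
    row_a: str, row_b: str, keep_stops: bool = False
) -> list[tuple[str, str]]:
    """Pairwise deletion: drop codon columns with gaps, N or in-frame stops.

    ``keep_stops`` retains stop-containing columns (scored as nonsynonymous
    states); used when the data-generating process genuinely permits
    nonsense changes, e.g. neutral-evolution consistency checks.
    """
    out = []
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3].upper(), row_b[i : i + 3].upper()
        if "-" in ca or "-" in cb or "." in ca or "." in cb:
            continue
        if "N" in ca or "N" in cb:
            continue
        if not keep_stops and (ca in STOP_CODONS or cb in STOP_CODONS):
            continue
        out.append((ca, cb))
    return out


def _syn_fraction(codon: str, pos: int, keep_stops: bool = False) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous.

    Changes creating a stop codon count as nonsynonymous (a nonsense change
    alters the product), which keeps S + N = 3 x (number of codons).
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for n in NUCS:
        if n == codon[pos]:
            continue
        mut = codon[:pos] + n + codon[pos + 1 :]
        if keep_stops:
            if CODON_TO_AA[mut] == aa:
                syn += 1
        elif mut not in STOP_CODONS and CODON_TO_AA[mut] == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str, keep_stops: bool = False) -> float:
    return sum(_syn_fraction(codon, p, keep_stops) for p in range(3))


def _pathway_diffs(ca: str, cb: str, keep_stops: bool = False) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over substitution
    pathways between two codons, excluding pathways through stop codons
    (unless ``keep_stops``, where stop states are scored like any other)."""
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        sd = nd = 0.0
        cur = ca
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if not keep_stops and nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        # all pathways pass through a stop: fall back to counting every
        # pathway, scoring stop-involving steps as nonsynonymous
        for order in itertools.permutations(diff_pos):
            sd = nd = 0.0
            cur = ca
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if (
                    nxt not in STOP_CODONS
                    and cur not in STOP_CODONS
                    and CODON_TO_AA[cur] == CODON_TO_AA[nxt]
                ):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> tuple[float | None, bool]:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None, True
    import math

    return -0.75 * math.log(arg), False


def ng86_rates(
    row_a: str, row_b: str, keep_stop_columns: bool = False
) -> PairwiseRates:
    """Nei-Gojobori (1986) Ks and Ka for one pair of codon rows."""
    codons = _comparable_codons(row_a, row_b, keep_stops=keep_stop_columns)
    if not codons:
        raise ValueError("no comparable codon columns between the pair")
    res = PairwiseRates(n_codons=len(codons))
    s_a = sum(_codon_sites(ca, keep_stop_columns) for ca, _ in codons)
    s_b = sum(_codon_sites(cb, keep_stop_columns) for _, cb in codons)
    res.s_sites = 0.5 * (s_a + s_b)
    res.n_sites = 3.0 * len(codons) - res.s_sites
    for ca, cb in codons:
        sd, nd = _pathway_diffs(ca, cb, keep_stop_columns)
        res.sd += sd
        res.nd += nd
    ps = res.sd / res.s_sites if res.s_sites > 0 else 0.0
    pn = res.nd / res.n_sites if res.n_sites > 0 else 0.0
    res.ks, sat_s = _jc_correct(ps)
    res.ka, sat_n = _jc_correct(pn)
    res.saturated = sat_s or sat_n
    if res.saturated:
        res.flags.append("jukes-cantor correction saturated")
    return res


def d4dtv(row_a: str, row_b: str, corrected: bool = False) -> PairwiseRates:
    """Transversion proportion at fourfold-degenerate third positions.

    Eligible columns have identical first two bases in both codons, with that
    prefix defining a fourfold-degenerate family. With ``corrected=True`` an
    HKY-style transversion distance -0.5 ln(1 - 2v) is reported instead of
    the raw proportion (off by default; the raw proportion is the standard
    4DTv statistic and is bounded by [0, 1]).
    """
    codons = _comparable_codons(row_a, row_b)
    if not codons:
        raise ValueError("no comparable codon columns between the pair")
    res = PairwiseRates(n_codons=len(codons))
    for ca, cb in codons:
        if ca[:2] != cb[:2] or ca[:2] not in FOURFOLD_PREFIXES:
            continue
        res.fourfold_sites += 1
        if is_transversion(ca[2], cb[2]):
            res.fourfold_transversions += 1
    if res.fourfold_sites == 0:
        res.d4dtv = None
        res.flags.append("no fourfold-degenerate columns: 4DTv undefined")
        return res
    v = res.fourfold_transversions / res.fourfold_sites
    if corrected:
        import math

        arg = 1.0 - 2.0 * v
        if arg <= 0:
            res.d4dtv = None
            res.saturated = True
            res.flags.append("corrected 4DTv saturated")
        else:
            res.d4dtv = -0.5 * math.log(arg)
    else:
        res.d4dtv = v
    return res


def pairwise_table(codon_aln: CodonAlignment):
    """All-pairs TSV-shaped table of Ks, Ka, site counts and 4DTv."""
    import pandas as pd

    rows = []
    n = len(codon_aln.ids)
    for i in range(n):
        for j in range(i + 1, n):
            ng = ng86_rates(codon_aln.rows[i], codon_aln.rows[j])
            fd = d4dtv(codon_aln.rows[i], codon_aln.rows[j])
            rows.append(
                dict(
                    id_a=codon_aln.ids[i],
                    id_b=codon_aln.ids[j],
                    ks=ng.ks,
                    ka=ng.ka,
                    s_sites=ng.s_sites,
                    n_sites=ng.n_sites,
                    d4dtv=fd.d4dtv,
                    fourfold_sites=fd.fourfold_sites,
                    flags=";".join(ng.flags + fd.flags),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "ks", "ka", "s_sites", "n_sites",
            "d4dtv", "fourfold_sites", "flags",
        ],
    )
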