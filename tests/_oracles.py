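"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written without reusing package internals:
explicit enumeration, Fraction arithmetic, nested loops. Slow but obviously
correct on small inputs.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from Bio.Data import CodonTable

_std = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_std.stop_codons)
_AA = dict(_std.forward_table)


def _aa(codon):
    return "*" if codon in _STOPS else _AA[codon]


# ---------------------------------------------------------------------------
# BURP pattern: sliding window over every start and spacer combination


def burp_scan_oracle(seq: str):
    """Leftmost complete CH-dyad/terminal-W match by explicit enumeration.

    Returns (start, end) 1-based inclusive, or None. For a given start the
    spacer combinations are tried shortest-first (second spacer outermost),
    mirroring leftmost-minimal matching.
    """
    n = len(seq)
    for start in range(n):
        for sp2 in range(23, 28):
            for sp3 in range(23, 27):
                length = 2 + 10 + 2 + sp2 + 2 + sp3 + 2 + 8 + 1
                if start + length > n:
                    continue
                p = start
                ok = seq[p] == "C" and seq[p + 1] == "H"
                p += 2 + 10
                ok = ok and seq[p] == "C" and seq[p + 1] == "H"
                p += 2 + sp2
                ok = ok and seq[p] == "C" and seq[p + 1] == "H"
                p += 2 + sp3
                ok = ok and seq[p] == "C" and seq[p + 1] == "H"
                p += 2 + 8
                ok = ok and seq[p] == "W"
                if ok:
                    return start + 1, start + length
    return None


# ---------------------------------------------------------------------------
# NG86 via Fractions and explicit pathway recursion


def _syn_sites_codon(codon):
    total = Fraction(0)
    for pos in range(3):
        syn = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in _STOPS and _aa(mut) == _aa(codon):
                syn += 1
        total += Fraction(syn, 3)
    return total


def _pathways(ca, cb):
    diff = [p for p in range(3) if ca[p] != cb[p]]
    out = []
    for order in itertools.permutations(diff):
        steps = []
        cur = ca
        blocked = False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            out.append(steps)
    return out


def ng86_oracle(codons_a, codons_b):
    """(S, N, Sd, Nd) as Fractions for two gap-free codon lists."""
    S = Fraction(0)
    Sd = Fraction(0)
    Nd = Fraction(0)
    for ca, cb in zip(codons_a, codons_b):
        S += (_syn_sites_codon(ca) + _syn_sites_codon(cb)) / 2
        paths = _pathways(ca, cb)
        if not paths:
            # every route hits a stop codon: score all routes, stop steps
            # count as nonsynonymous
            for order in itertools.permutations(
                [p for p in range(3) if ca[p] != cb[p]]
            ):
                cur = ca
                sd = nd = 0
                for p in order:
                    nxt = cur[:p] + cb[p] + cur[p + 1 :]
                    if (
                        nxt not in _STOPS
                        and cur not in _STOPS
                        and _aa(cur) == _aa(nxt)
                    ):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                Sd += Fraction(sd)
                Nd += Fraction(nd)
            ndiff = len([p for p in range(3) if ca[p] != cb[p]])
            k = 1
            for i in range(2, ndiff + 1):
                k *= i
            Sd /= k
            Nd /= k
            continue
        sd_tot = Fraction(0)
        nd_tot = Fraction(0)
        for path in paths:
            for cur, nxt in path:
                if _aa(cur) == _aa(nxt):
                    sd_tot += 1
                else:
                    nd_tot += 1
        Sd += Fraction(sd_tot, len(paths))
        Nd += Fraction(nd_tot, len(paths))
    n_codons = len(codons_a)
    N = 3 * n_codons - S
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive internal labeling


def fitch_oracle(tree, leaf_states: dict[str, str]) -> int:
    """Minimum changes for one column by brute force over all internal
    assignments; ``tree`` is a dendropy tree, states are single characters.
    Missing leaves (state None) are ignored in the cost."""
    internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    alphabet = sorted({s for s in leaf_states.values() if s is not None})
    if not alphabet:
        return 0
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = {id(nd): st for nd, st in zip(internals, combo)}
        for lf in tree.leaf_node_iter():
            assign[id(lf)] = leaf_states.get(lf.taxon.label)
        cost = 0
        for nd in tree.postorder_node_iter():
            if nd.parent_node is None:
                continue
            a = assign[id(nd)]
            b = assign[id(nd.parent_node)]
            if a is not None and b is not None and a != b:
                cost += 1
        # leaves with missing state never add cost; internal states above a
        # missing leaf are unconstrained, handled by the enumeration
        if best is None or cost < best:
            best = cost
    return best
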