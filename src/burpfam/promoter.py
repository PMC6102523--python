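"""Promoter (upstream-region) cis-regulatory element profiling.

The promoter window is the 1500 bp immediately upstream of the translation
start (the coding region's ATG), taken strand-aware from the genome.
Elements are user-supplied IUPAC consensus patterns; scanning reports every
occurrence on both strands, overlapping matches included, because copy
numbers per promoter are the quantity summarized per subfamily.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from ._gencode import revcomp
from .duplication import GeneModel

ELEMENT_CATEGORIES = ("hormone", "stress", "circadian", "light", "other")


@dataclass(frozen=True)
class CisElementDef:
    name: str
    pattern: str  # IUPAC nucleotide codes
    category: str = "other"

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(
                f"{self.name}: invalid IUPAC codes {sorted(bad)!r}"
            )
        if self.category not in ELEMENT_CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class PromoterHit:
    gene_id: str
    element: str
    position: int  # 1-based offset of the match's leftmost base in the window
    strand: str


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC consensus into an overlap-reporting regex."""
    body = "".join(
        f"[{ambiguous_dna_values[c]}]" if len(ambiguous_dna_values[c]) > 1 else c
        for c in pattern.upper()
    )
    return re.compile(f"(?=({body}))")


def extract_upstream(
    genome: dict[str, str],
    gene: GeneModel,
    window: int = 1500,
) -> tuple[str, bool]:
    """Upstream window of one gene, strand-aware.

    Plus strand: the ``window`` bases ending at ``start - 1``. Minus strand:
    reverse complement of the bases beginning at ``end + 1``. Returns
    ``(sequence, truncated)`` where truncated marks windows clipped at a
    chromosome edge.
    """
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} missing from genome")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        lo = max(gene.start - 1 - window, 0)
        seq = chrom[lo : gene.start - 1]
        truncated = len(seq) < window
    else:
        seq = chrom[gene.end : gene.end + window]
        truncated = len(seq) < window
        seq = revcomp(seq)
    return seq.upper(), truncated


def scan_elements(
    seq: str,
    defs: list[CisElementDef],
    gene_id: str = "",
    both_strands: bool = True,
) -> list[PromoterHit]:
    """All element occurrences in a window; minus-strand hits are reported at
    the forward-strand position of their leftmost base."""
    seq = seq.upper()
    hits: list[PromoterHit] = []
    L = len(seq)
    for el in defs:
        rx = iupac_regex(el.pattern)
        plen = len(el.pattern)
        for m in rx.finditer(seq):
            hits.append(PromoterHit(gene_id, el.name, m.start() + 1, "+"))
        if both_strands:
            rc = revcomp(seq)
            for m in rx.finditer(rc):
                fwd_pos = L - (m.start() + plen) + 1
                hits.append(PromoterHit(gene_id, el.name, fwd_pos, "-"))
    hits.sort(key=lambda h: (h.element, h.position, h.strand))
    return hits


def summarize_elements(
    hits: list[PromoterHit],
    assignment: dict[str, str],
    element_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subfamily copy totals in the "count/members" notation.

    Rows: subfamilies (plus a Total row over the whole family); columns: one
    per element with the count/members string, plus mean copies per gene.
    """
    if element_names is None:
        element_names = sorted({h.element for h in hits})
    subfams = sorted(set(assignment.values()))
    members: dict[str, list[str]] = {sf: [] for sf in subfams}
    for gid, sf in assignment.items():
        members[sf].append(gid)
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        sf = assignment.get(h.gene_id)
        if sf is None:
            continue
        counts[(sf, h.element)] = counts.get((sf, h.element), 0) + 1

    n_total = len(assignment)
    rows = []
    for sf in subfams:
        n = len(members[sf])
        row = {"subfamily": sf, "members": n}
        for el in element_names:
            row[el] = f"{counts.get((sf, el), 0)}/{n}"
        rows.append(row)
    total_row = {"subfamily": "Total", "members": n_total}
    for el in element_names:
        tot = sum(counts.get((sf, el), 0) for sf in subfams)
        total_row[el] = f"{tot}/{n_total}"
        total_row[f"{el}_mean_copies"] = round(tot / n_total, 3) if n_total else 0.0
    rows.append(total_row)
    return pd.DataFrame(rows)


def element_counts(hits: list[PromoterHit]) -> pd.DataFrame:
    """Tidy per-gene, per-element copy counts."""
    rows: dict[tuple[str, str], int] = {}
    for h in hits:
        rows[(h.gene_id, h.element)] = rows.get((h.gene_id, h.element), 0) + 1
    return pd.DataFrame(
        [
            {"gene_id": g, "element": e, "copies": c}
            for (g, e), c in sorted(rows.items())
        ]
    )


def read_elements_tsv(path) -> list[CisElementDef]:
    """Element table: name <TAB> IUPAC pattern <TAB> category."""
    defs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "name":
            continue
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        defs.append(CisElementDef(name=parts[0], pattern=parts[1], category=parts[2]))
    return defs
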