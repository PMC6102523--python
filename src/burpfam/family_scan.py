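"""Identification and curation of BURP domain-containing family members.

The BURP domain is a conserved plant-specific C-terminal domain defined by
four cysteine-histidine (CH) dyads with constrained spacers and a terminal
tryptophan::

    C H X{10} C H X{23-27} C H X{23-26} C H X{8} W

where X is any amino acid. Candidate proteins are screened for this pattern;
loci with several isoforms are collapsed to the longest translation, and
genes whose CDS is not a complete open reading frame are set aside as
putative pseudogenes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_VALID_NT = frozenset("ACGTN")

# Full BURP pattern. Spacers are non-greedy so the leftmost match uses the
# minimal spacer lengths; anchors are literal C/H/W (an 'X' in the sequence
# does not satisfy an anchor position). Groups capture each CH dyad.
_FULL = re.compile(r"(CH).{10}(CH).{23,27}?(CH).{23,26}?(CH).{8}W")
# Progressively truncated prefixes used to annotate incomplete domains.
_PARTIALS = (
    re.compile(r"(CH).{10}(CH).{23,27}?(CH).{23,26}?(CH)"),  # 4 dyads, no W
    re.compile(r"(CH).{10}(CH).{23,27}?(CH)"),               # 3 dyads
    re.compile(r"(CH).{10}(CH)"),                            # 2 dyads
)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; ``locus_id`` groups alternative isoforms."""

    id: str
    locus_id: str
    species: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_AA
        if bad:
            raise ValueError(
                f"{self.id}: non-amino-acid characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class CdsRecord:
    id: str
    locus_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty CDS")
        bad = set(self.sequence.upper()) - _VALID_NT
        if bad:
            raise ValueError(f"{self.id}: non-nucleotide characters {sorted(bad)!r}")


@dataclass
class DomainHit:
    """Location of a (possibly incomplete) BURP domain, 1-based inclusive."""

    start: int
    end: int
    motif_spans: list[tuple[int, str]]
    complete: bool


def scan_burp_domain(protein: ProteinRecord) -> DomainHit | None:
    """Locate the BURP CH-repeat domain in one protein.

    Returns the leftmost full match (minimal spacers) with ``complete=True``;
    if only a prefix of the dyad series is present (at least two CH dyads),
    an incomplete hit is returned; otherwise ``None``.
    """
    seq = protein.sequence.upper()
    m = _FULL.search(seq)
    if m is not None:
        return _make_hit(seq, m, complete=True, n_dyads=4, has_w=True)
    for n_dyads, pat in zip((4, 3, 2), _PARTIALS):
        m = pat.search(seq)
        if m is not None:
            return _make_hit(seq, m, complete=False, n_dyads=n_dyads, has_w=False)
    return None


def _make_hit(seq: str, m: re.Match, *, complete: bool, n_dyads: int, has_w: bool) -> DomainHit:
    start, end = m.start() + 1, m.end()  # 1-based inclusive
    spans: list[tuple[int, str]] = [
        (m.start(g) + 1, f"CH{g}") for g in range(1, n_dyads + 1)
    ]
    if has_w:
        spans.append((end, "W"))
    # Additional conserved cysteines: annotate up to two C residues inside the
    # domain that are not part of a CH dyad (present in most family members
    # but not required for completeness).
    dyad_positions = {p for p, lab in spans if lab.startswith("CH")}
    dyad_positions |= {p + 1 for p in dyad_positions}
    extra = [
        (i + 1, "C")
        for i in range(start - 1, end)
        if seq[i] == "C" and (i + 1) not in dyad_positions
    ][:2]
    spans.extend(extra)
    spans.sort()
    return DomainHit(start=start, end=end, motif_spans=spans, complete=complete)


def select_longest_isoform(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Keep one record per locus: the longest; ties broken by smaller id."""
    best: dict[str, ProteinRecord] = {}
    for rec in records:
        cur = best.get(rec.locus_id)
        if (
            cur is None
            or len(rec.sequence) > len(cur.sequence)
            or (len(rec.sequence) == len(cur.sequence) and rec.id < cur.id)
        ):
            best[rec.locus_id] = rec
    return [best[k] for k in sorted(best)]


def check_complete_orf(cds: CdsRecord | str) -> bool:
    """True iff the CDS is a complete ORF.

    Length a multiple of 3, starts with ATG, ends with a stop codon, no
    internal stop. Codons containing N are treated as non-stop. Case
    insensitive.
    """
    seq = (cds.sequence if isinstance(cds, CdsRecord) else cds).upper()
    if len(seq) < 6 or len(seq) % 3 != 0:
        return False
    if not seq.startswith("ATG"):
        return False
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in STOP_CODONS:
        return False
    return not any(c in STOP_CODONS for c in codons[:-1])


def orf_has_ambiguity(cds: CdsRecord | str) -> bool:
    seq = (cds.sequence if isinstance(cds, CdsRecord) else cds).upper()
    return "N" in seq


@dataclass
class FamilyCatalog:
    """Curated family member set plus an exclusion log."""

    members: list[ProteinRecord] = field(default_factory=list)
    hits: dict[str, DomainHit] = field(default_factory=dict)
    cds: dict[str, CdsRecord] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.members]

    def to_table(self):
        import pandas as pd

        rows = []
        for rec in self.members:
            hit = self.hits[rec.id]
            rows.append(
                dict(
                    id=rec.id,
                    species=rec.species,
                    locus=rec.locus_id,
                    domain_start=hit.start,
                    domain_end=hit.end,
                    complete=hit.complete,
                )
            )
        return pd.DataFrame(rows, columns=["id", "species", "locus", "domain_start", "domain_end", "complete"])


def build_catalog(
    proteins: list[ProteinRecord],
    cds: list[CdsRecord] | None = None,
    domain_hits: dict[str, DomainHit | None] | None = None,
) -> FamilyCatalog:
    """Join proteins with CDS, apply curation rules, report exclusions.

    Curation order: longest isoform per locus -> complete-ORF screen (when a
    CDS is supplied) -> BURP domain screen (records with no hit or an
    incomplete domain are excluded).
    """
    catalog = FamilyCatalog()
    if not proteins:
        catalog.warnings.append("empty input: no proteins supplied")
        return catalog

    cds_by_id = {c.id: c for c in (cds or [])}
    if cds:
        unpaired = sorted(set(cds_by_id) ^ {p.id for p in proteins})
        if unpaired:
            raise ValueError(f"protein/CDS id mismatch for: {', '.join(unpaired)}")

    kept = select_longest_isoform(proteins)
    kept_ids = {r.id for r in kept}
    for rec in proteins:
        if rec.id not in kept_ids:
            catalog.excluded.append((rec.id, "redundant isoform"))

    for rec in kept:
        rec_cds = cds_by_id.get(rec.id)
        if rec_cds is not None:
            if orf_has_ambiguity(rec_cds):
                catalog.warnings.append(f"{rec.id}: CDS contains N codons (treated as non-stop)")
            if not check_complete_orf(rec_cds):
                catalog.excluded.append((rec.id, "incomplete ORF (putative pseudogene)"))
                continue
        hit = (
            domain_hits.get(rec.id)
            if domain_hits is not None
            else scan_burp_domain(rec)
        )
        if hit is None:
            catalog.excluded.append((rec.id, "no BURP domain"))
        elif not hit.complete:
            catalog.excluded.append((rec.id, "incomplete BURP domain"))
        else:
            catalog.members.append(rec)
            catalog.hits[rec.id] = hit
            if rec_cds is not None:
                catalog.cds[rec.id] = rec_cds
    return catalog


# ---------------------------------------------------------------------------
# FASTA plumbing


def read_protein_fasta(path, species: str = "", locus_map: dict[str, str] | None = None) -> list[ProteinRecord]:
    """Read proteins; locus id defaults to the record id minus a trailing
    ``.N`` isoform suffix, or comes from an explicit id->locus map."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        locus = (locus_map or {}).get(rid) or re.sub(r"\.\d+$", "", rid)
        out.append(ProteinRecord(id=rid, locus_id=locus, species=species, sequence=str(rec.seq).upper()))
    return out


def read_cds_fasta(path, locus_map: dict[str, str] | None = None) -> list[CdsRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        locus = (locus_map or {}).get(rid) or re.sub(r"\.\d+$", "", rid)
        out.append(CdsRecord(id=rid, locus_id=locus, sequence=str(rec.seq).upper()))
    return out


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
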