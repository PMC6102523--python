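"""Tandem/segmental duplicate classification, molecular-clock dating and
exon-structure summaries.

Tandem duplicates are family genes on one chromosome separated by at most
``max_intervening`` annotated genes (inclusive boundary; intervening genes of
the family itself are counted too). Segmental duplicates come from
collinearity anchor blocks: anchors with Ks > 1.0 are discarded as
saturation-prone, blocks retaining fewer than three anchors are dropped, and
surviving family pairs are dated from the block's mean Ks via the molecular
clock T = Ks / (2 lambda), with lambda the species' synonymous substitution
rate per site per year.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import yaml


@dataclass
class GeneModel:
    """One locus: coordinates are 1-based inclusive."""

    id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.id}: overlapping exons")


@dataclass
class AnchorSet:
    """One collinear block: gene pairs with per-anchor Ks."""

    block_id: str
    anchors: list[tuple[str, str, float]]

    def __post_init__(self):
        for a, b, ks in self.anchors:
            if ks < 0:
                raise ValueError(f"block {self.block_id}: negative Ks for {a}/{b}")


@dataclass
class DuplicationPair:
    id_a: str
    id_b: str
    mode: str  # tandem | segmental
    species: str = ""
    intervening_genes: int | None = None
    ks_mean: float | None = None
    ks_sd: float | None = None
    d4dtv: float | None = None
    n_anchors: int | None = None
    age_mya: float | None = None
    age_mya_raw: float | None = None


def exon_count(gene: GeneModel) -> int:
    if not gene.exons:
        raise ValueError(f"{gene.id}: no exon intervals annotated")
    return len(gene.exons)


def tandem_pairs(
    genes: list[GeneModel],
    family_ids,
    max_intervening: int = 10,
) -> list[DuplicationPair]:
    """All same-chromosome family pairs with <= ``max_intervening`` annotated
    genes strictly between them in start-coordinate order."""
    family = set(family_ids)
    out = []
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault((g.species, g.chromosome), []).append(g)
    for (species, _), chrom_genes in sorted(by_chrom.items()):
        chrom_genes.sort(key=lambda g: (g.start, g.id))
        fam_idx = [i for i, g in enumerate(chrom_genes) if g.id in family]
        for ii, i in enumerate(fam_idx):
            for j in fam_idx[ii + 1 :]:
                intervening = j - i - 1
                if intervening <= max_intervening:
                    a, b = sorted((chrom_genes[i].id, chrom_genes[j].id))
                    out.append(
                        DuplicationPair(
                            id_a=a,
                            id_b=b,
                            mode="tandem",
                            species=species,
                            intervening_genes=intervening,
                        )
                    )
    out.sort(key=lambda p: (p.species, p.id_a, p.id_b))
    return out


def segmental_pairs(
    anchor_sets: list[AnchorSet],
    family_ids=None,
    ks_max: float = 1.0,
    min_anchors: int = 3,
) -> list[DuplicationPair]:
    """Family pairs from anchor blocks surviving the Ks and anchor-count
    filters; each pair carries the block's mean +/- SD Ks over surviving
    anchors."""
    family = set(family_ids) if family_ids is not None else None
    out = []
    for block in anchor_sets:
        surviving = [(a, b, ks) for a, b, ks in block.anchors if ks <= ks_max]
        if len(surviving) < min_anchors:
            continue
        ks_vals = np.array([ks for _, _, ks in surviving])
        ks_mean = float(ks_vals.mean())
        ks_sd = float(ks_vals.std(ddof=1)) if len(ks_vals) > 1 else 0.0
        for a, b, _ in surviving:
            if family is not None and not (a in family and b in family):
                continue
            a, b = sorted((a, b))
            out.append(
                DuplicationPair(
                    id_a=a,
                    id_b=b,
                    mode="segmental",
                    ks_mean=ks_mean,
                    ks_sd=ks_sd,
                    n_anchors=len(surviving),
                )
            )
    out.sort(key=lambda p: (p.id_a, p.id_b))
    return out


def date_pair(ks_mean: float, lam: float) -> tuple[float, float]:
    """Molecular-clock age T = Ks/(2 lambda).

    Returns ``(age_mya_rounded, age_mya_raw)``; the rounded value uses
    half-up rounding to one decimal, matching how such tables print ages.
    """
    if lam <= 0:
        raise ValueError("clock rate lambda must be > 0")
    age_years = ks_mean / (2.0 * lam)
    raw = age_years / 1e6
    rounded = float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return rounded, raw


def unique_genes(pairs: list[DuplicationPair]) -> set[str]:
    out: set[str] = set()
    for p in pairs:
        out.add(p.id_a)
        out.add(p.id_b)
    return out


# ---------------------------------------------------------------------------
# File formats


def load_clock_rates(path) -> dict[str, float]:
    """Species -> lambda (synonymous substitutions/site/year) from YAML."""
    with open(path) as fh:
        rates = yaml.safe_load(fh)
    for sp, lam in rates.items():
        if not lam > 0:
            raise ValueError(f"clock rate for {sp} must be > 0")
    return {sp: float(lam) for sp, lam in rates.items()}


def read_anchors_tsv(path) -> list[AnchorSet]:
    """Tab-delimited anchors: block_id, gene_a, gene_b, Ks (header optional)."""
    blocks: dict[str, list[tuple[str, str, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["block_id"]:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                ks = float(parts[3])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: bad Ks value {parts[3]!r}") from err
            blocks.setdefault(parts[0], []).append((parts[1], parts[2], ks))
    return [AnchorSet(block_id=b, anchors=a) for b, a in sorted(blocks.items())]


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_gff3(path, species_from_seqid: bool = False) -> list[GeneModel]:
    """Minimal GFF3 reader for gene/mRNA/exon features (1-based inclusive).

    Exons are attached to their gene through the Parent chain; the optional
    ``species=`` attribute on gene lines (or the seqid prefix before the
    first '_' when ``species_from_seqid``) fills the species field.
    """
    genes: dict[str, GeneModel] = {}
    mrna_parent: dict[str, str] = {}
    pending_exons: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = cols
            attr = dict(_GFF_ATTR.findall(attrs))
            start, end = int(start), int(end)
            if ftype == "gene":
                gid = attr["ID"]
                species = attr.get("species", "")
                if not species and species_from_seqid:
                    species = seqid.split("_")[0]
                genes[gid] = GeneModel(
                    id=gid, species=species, chromosome=seqid,
                    start=start, end=end, strand=strand,
                )
            elif ftype == "mRNA":
                mrna_parent[attr["ID"]] = attr["Parent"]
            elif ftype == "exon":
                pending_exons.append((attr["Parent"], start, end))
    for parent, start, end in pending_exons:
        gid = mrna_parent.get(parent, parent)
        if gid in genes:
            genes[gid].exons.append((start, end))
    for g in genes.values():
        g.exons.sort()
    return sorted(genes.values(), key=lambda g: (g.chromosome, g.start, g.id))


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chromosome, x.start, x.id)):
            attrs = f"ID={g.id}"
            if g.species:
                attrs += f";species={g.species}"
            fh.write(
                f"{g.chromosome}\tburpfam\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.id}.t1"
            fh.write(
                f"{g.chromosome}\tburpfam\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.id}\n"
            )
            for k, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\tburpfam\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{k};Parent={mrna_id}\n"
                )


def pairs_table(pairs: list[DuplicationPair]):
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                id_a=p.id_a, id_b=p.id_b, mode=p.mode, species=p.species,
                intervening_genes=p.intervening_genes, ks_mean=p.ks_mean,
                ks_sd=p.ks_sd, n_anchors=p.n_anchors, d4dtv=p.d4dtv,
                age_mya=p.age_mya,
            )
            for p in pairs
        ],
        columns=[
            "id_a", "id_b", "mode", "species", "intervening_genes",
            "ks_mean", "ks_sd", "n_anchors", "d4dtv", "age_mya",
        ],
    )
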