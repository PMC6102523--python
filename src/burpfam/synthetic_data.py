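"""Synthetic gene families with known ground truth.

Every pipeline stage consumes files this generator can emit: protein and CDS
FASTA with decoys (incomplete domains, redundant isoforms, pseudogenes), a
protein alignment, GFF3 gene models with filler genes so intervening-gene
counting is exercised realistically, a genome FASTA with planted promoter
elements, collinearity anchor blocks with per-anchor Ks, and truth tables
for every planted feature.

Codon sequences evolve along a subfamily-structured gene tree under the same
GY94 machinery the selection module fits, so model-recovery tests are
self-consistent. The diagnostic CH-dyad/terminal-W core of the family is
held invariant in all non-decoy members. Duplication depths are specified in
Ks units; the generator calibrates the corresponding branch length so that
the *expected* NG86 Ks estimate between the pair equals the requested depth
(the estimator's own currency), leaving only sampling noise.

Promoter background is i.i.d. with 40% GC by default; the ``at_only``
background restricts filler to A/T so GC-containing planted elements cannot
arise by chance (used for exact count checks).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._gencode import SENSE_CODONS, revcomp
from .codon_tools import CodonAlignment, _codon_sites
from .duplication import AnchorSet, GeneModel, write_gff3
from .family_scan import CdsRecord, ProteinRecord
from .phylo import ProteinAlignment
from .promoter import CisElementDef, iupac_regex
from .selection import (
    GY94,
    simulate_codon_alignment,
    synonymous_flux_fraction,
    uniform_frequencies,
)

_SD_MATRIX = None


def _sd_matrix() -> np.ndarray:
    """(61, 61) pathway-averaged synonymous difference counts (NG86)."""
    global _SD_MATRIX
    if _SD_MATRIX is None:
        from .codon_tools import _pathway_diffs

        n = len(SENSE_CODONS)
        M = np.zeros((n, n))
        for i, ca in enumerate(SENSE_CODONS):
            for j, cb in enumerate(SENSE_CODONS):
                if i != j:
                    M[i, j] = _pathway_diffs(ca, cb)[0]
        _SD_MATRIX = M
    return _SD_MATRIX


@dataclass
class DuplicationEvent:
    kind: str  # "tandem" | "segmental"
    species: str
    ks_depth: float
    intervening: int = 2  # tandem only: filler genes between the pair


@dataclass
class SimConfig:
    """Study conditions for one synthetic family."""

    seed: int = 0
    species: tuple = ("spA", "spB", "spC")
    clock_rates: dict = field(
        default_factory=lambda: {"spA": 1.5e-8, "spB": 6.1e-9, "spC": 1.4e-8}
    )
    subfamily_sizes: dict = field(
        default_factory=lambda: {
            "PG1β-like": 6, "BNM2-like": 6, "BURPIII": 6, "BURPIV": 6,
        }
    )
    n_codons: int = 200
    kappa: float = 2.0
    omega_classes: tuple = ((0.7, 0.05), (0.3, 0.4))  # (proportion, omega)
    clade_depth: float = 0.45   # stem length separating subfamilies
    within_bl: tuple = (0.03, 0.12)  # uniform range for within-clade branches
    duplications: tuple = (
        DuplicationEvent("tandem", "spA", 0.10),
        DuplicationEvent("tandem", "spB", 0.40, intervening=5),
        DuplicationEvent("segmental", "spB", 0.40),
        DuplicationEvent("segmental", "spC", 0.60),
    )
    anchors_per_block: int = 4
    anchor_ks_rel_sd: float = 0.10  # per-anchor scatter, relative to depth
    window: int = 1500
    planted_elements: tuple = (("ABRE", "TACGTG", 2), ("MBS", "CAACTG", 1))
    promoter_background: str = "gc40"  # or "at_only"
    decoys: dict = field(
        default_factory=lambda: {
            "incomplete_domain": 1, "extra_isoform": 1, "pseudogene": 1,
        }
    )
    filler_between_family: int = 12  # > tandem threshold, blocks false calls


# BURP core: C H x10 C H x25 C H x24 C H x8 W (spacers at mid-range)
_CORE_TEMPLATE = (
    [("C", 0), ("H", 1)]
    + [(None, k) for k in range(2, 12)]
    + [("C", 12), ("H", 13)]
    + [(None, k) for k in range(14, 39)]
    + [("C", 39), ("H", 40)]
    + [(None, k) for k in range(41, 65)]
    + [("C", 65), ("H", 66)]
    + [(None, k) for k in range(67, 75)]
    + [("W", 75)]
)
CORE_LENGTH = 76
_AA_CODON = {"C": "TGC", "H": "CAC", "W": "TGG", "F": "TTC"}


def core_fixed_columns(n_codons: int) -> dict[int, str]:
    """Codon columns pinned to the diagnostic core, placed near the C
    terminus (the domain is C-terminal in this family)."""
    if n_codons < CORE_LENGTH + 10:
        raise ValueError(f"n_codons must be >= {CORE_LENGTH + 10}")
    offset = n_codons - CORE_LENGTH - 5
    cols = {
        offset + k: _AA_CODON[aa]
        for aa, k in _CORE_TEMPLATE
        if aa is not None
    }
    cols[0] = "ATG"  # translation start, keeps the CDS a complete ORF
    return cols


@dataclass
class SimulatedFamily:
    config: SimConfig
    proteins: list
    cds: list
    alignment: ProteinAlignment
    codon_alignment: CodonAlignment
    tree_newick: str
    gene_models: list
    genome: dict
    anchor_sets: list
    element_defs: list
    truth_members: pd.DataFrame
    truth_duplications: pd.DataFrame
    truth_sites: np.ndarray
    truth_elements: pd.DataFrame
    clock_rates: dict
    subfamily_seeds: dict

    @property
    def member_ids(self) -> list[str]:
        df = self.truth_members
        return list(df.loc[~df.is_decoy, "id"])

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "proteins.faa", [(p.id, p.sequence) for p in self.proteins])
        _write_fasta(out / "cds.fna", [(c.id, c.sequence) for c in self.cds])
        _write_fasta(
            out / "alignment.faa", list(zip(self.alignment.ids, self.alignment.rows))
        )
        _write_fasta(out / "genome.fna", sorted(self.genome.items()))
        (out / "family.nwk").write_text(self.tree_newick + "\n")
        write_gff3(self.gene_models, out / "genes.gff3")
        with open(out / "anchors.tsv", "w") as fh:
            fh.write("block_id\tgene_a\tgene_b\tks\n")
            for block in self.anchor_sets:
                for a, b, ks in block.anchors:
                    fh.write(f"{block.block_id}\t{a}\t{b}\t{ks:.4f}\n")
        with open(out / "elements.tsv", "w") as fh:
            fh.write("name\tpattern\tcategory\n")
            for el in self.element_defs:
                fh.write(f"{el.name}\t{el.pattern}\t{el.category}\n")
        with open(out / "clock_rates.yaml", "w") as fh:
            yaml.safe_dump({k: float(v) for k, v in self.clock_rates.items()}, fh)
        self.truth_members.to_csv(out / "truth_members.tsv", sep="\t", index=False)
        self.truth_duplications.to_csv(
            out / "truth_duplications.tsv", sep="\t", index=False
        )
        self.truth_elements.to_csv(out / "truth_elements.tsv", sep="\t", index=False)
        np.savetxt(out / "truth_site_classes.tsv", self.truth_sites, fmt="%d")

    def sha256(self) -> str:
        """Digest of all emitted content (determinism checks)."""
        h = hashlib.sha256()
        for p in self.proteins:
            h.update(p.id.encode()); h.update(p.sequence.encode())
        for c in self.cds:
            h.update(c.sequence.encode())
        for chrom in sorted(self.genome):
            h.update(self.genome[chrom].encode())
        h.update(self.tree_newick.encode())
        for block in self.anchor_sets:
            h.update(repr(block.anchors).encode())
        h.update(self.truth_members.to_csv().encode())
        return h.hexdigest()


def _write_fasta(path, items):
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Tree construction


def _balanced_newick(ids, rng, lo, hi):
    if len(ids) == 1:
        return ids[0]
    mid = len(ids) // 2
    left = _balanced_newick(ids[:mid], rng, lo, hi)
    right = _balanced_newick(ids[mid:], rng, lo, hi)
    return f"({left}:{rng.uniform(lo, hi):.4f},{right}:{rng.uniform(lo, hi):.4f})"


def _family_tree(cfg: SimConfig, members_by_subfam, rng) -> str:
    clades = []
    lo, hi = cfg.within_bl
    for label in sorted(members_by_subfam):
        ids = members_by_subfam[label]
        clades.append(f"{_balanced_newick(ids, rng, lo, hi)}:{cfg.clade_depth:.4f}")
    inner = ",".join(clades)
    return f"({inner});"


# ---------------------------------------------------------------------------
# Ks calibration


def calibrated_branch_length(
    states: np.ndarray,
    ks_depth: float,
    pi: np.ndarray,
    kappa: float,
    omega_classes,
    fixed_cols,
) -> float:
    """Branch length t such that the expected NG86 Ks between a sequence and
    its descendant after t equals ``ks_depth``.

    The expectation integrates the substitution process exactly: expected
    pathway-averaged synonymous differences are computed from the transition
    matrices, divided by the NG86 synonymous site count of the parent, and
    pushed through the Jukes-Cantor correction; brentq then inverts the map.
    """
    from scipy.optimize import brentq

    if ks_depth <= 0:
        return 0.0
    sd_mat = _sd_matrix()
    evolving = np.array([s for s in range(len(states)) if s not in fixed_cols])
    codons_all = [SENSE_CODONS[s] for s in states]
    s_tot = sum(_codon_sites(c) for c in codons_all)
    # fixed columns contribute sites but never differences
    ev_states = states[evolving]
    counts = np.bincount(ev_states, minlength=len(SENSE_CODONS)).astype(float)
    props = np.array([c[0] for c in omega_classes], dtype=float)
    props /= props.sum()
    omegas = [c[1] for c in omega_classes]
    from .selection import class_rate_multipliers

    mults = class_rate_multipliers(pi, kappa, props, omegas)
    models = [
        (p, GY94(pi, kappa), om, m)
        for p, om, m in zip(props, omegas, mults)
    ]

    def expected_ks(t):
        e_sd = 0.0
        for p, model, om, m in models:
            P = model.transition_matrix(om, t * m)
            e_sd += p * float((counts[:, None] * P * sd_mat).sum())
        ps = e_sd / s_tot
        arg = 1.0 - 4.0 * ps / 3.0
        if arg <= 1e-9:
            return 10.0
        return -0.75 * np.log(arg)

    hi = 1.0
    while expected_ks(hi) < ks_depth and hi < 50:
        hi *= 2
    return float(brentq(lambda t: expected_ks(t) - ks_depth, 1e-9, hi, xtol=1e-8))


def _evolve_states(states, t, pi, kappa, class_of_site, omegas, rng, mults=None):
    """One branch of GY94 evolution for an integer codon-state vector.

    ``mults`` are the shared-time-scale class rate multipliers; they default
    to flux-weighting by the observed class composition."""
    from .selection import class_rate_multipliers

    if mults is None:
        props = np.bincount(class_of_site, minlength=len(omegas)).astype(float)
        mults = class_rate_multipliers(pi, kappa, props / props.sum(), omegas)
    model = GY94(pi, kappa)
    child = states.copy()
    for k, om in enumerate(omegas):
        mask = class_of_site == k
        if not mask.any():
            continue
        P = model.transition_matrix(om, t * mults[k])
        u = rng.random(mask.sum())
        cum = P[states[mask]].cumsum(axis=1)
        child[mask] = (u[:, None] > cum).sum(axis=1)
    return child


# ---------------------------------------------------------------------------
# Main generator


def simulate_family(cfg: SimConfig) -> SimulatedFamily:
    rng = np.random.default_rng(cfg.seed)
    pi = uniform_frequencies()
    fixed_cols = core_fixed_columns(cfg.n_codons)

    # --- membership and tree
    members_by_subfam: dict[str, list[str]] = {}
    species_of: dict[str, str] = {}
    idx = 0
    for label, size in cfg.subfamily_sizes.items():
        ids = []
        for k in range(size):
            sp = cfg.species[(idx + k) % len(cfg.species)]
            gid = f"{sp}g{idx + k + 1:03d}"
            ids.append(gid)
            species_of[gid] = sp
        members_by_subfam[label] = ids
        idx += size
    if sum(cfg.subfamily_sizes.values()) != len(species_of):
        raise ValueError("inconsistent subfamily sizes")
    newick = _family_tree(cfg, members_by_subfam, rng)

    # --- sequence evolution
    aln, classes = simulate_codon_alignment(
        newick,
        cfg.n_codons,
        cfg.kappa,
        list(cfg.omega_classes),
        rng,
        pi=pi,
        fixed_columns=fixed_cols,
    )
    truth_sites = classes.copy()
    truth_sites[list(fixed_cols)] = -1  # invariant core
    from ._gencode import CODON_INDEX

    row_of = dict(zip(aln.ids, aln.rows))
    states_of = {
        rid: np.array([CODON_INDEX[row[3 * i : 3 * i + 3]]
                       for i in range(cfg.n_codons)])
        for rid, row in row_of.items()
    }
    subfam_of = {
        gid: label for label, ids in members_by_subfam.items() for gid in ids
    }

    # --- duplication events
    from .selection import class_rate_multipliers

    omegas = np.array([c[1] for c in cfg.omega_classes])
    class_props = np.array([c[0] for c in cfg.omega_classes])
    class_mults = class_rate_multipliers(pi, cfg.kappa, class_props, omegas)
    dup_rows = []
    anchor_sets = []
    used: set[str] = set()
    partner_of: dict[str, str] = {}
    for ev_i, ev in enumerate(cfg.duplications):
        source = next(
            (g for g in species_of if species_of[g] == ev.species and g not in used),
            None,
        )
        if source is None:
            raise ValueError(f"no free gene in species {ev.species} for event {ev_i}")
        used.add(source)
        suffix = "t" if ev.kind == "tandem" else "s"
        partner = f"{source}{suffix}"
        t = calibrated_branch_length(
            states_of[source], ev.ks_depth, pi, cfg.kappa, cfg.omega_classes, fixed_cols
        )
        child = _evolve_states(
            states_of[source], t, pi, cfg.kappa, classes, omegas, rng,
            mults=class_mults,
        )
        for col, codon in fixed_cols.items():
            child[col] = SENSE_CODONS.index(codon)
        states_of[partner] = child
        species_of[partner] = ev.species
        subfam_of[partner] = subfam_of[source]
        partner_of[source] = partner
        lam = cfg.clock_rates[ev.species]
        rec = dict(
            id_a=source, id_b=partner, mode=ev.kind, species=ev.species,
            ks_true=ev.ks_depth, age_true_mya=ev.ks_depth / (2 * lam) / 1e6,
            intervening=ev.intervening if ev.kind == "tandem" else None,
        )
        dup_rows.append(rec)
        if ev.kind == "segmental":
            anchors = [(source, partner, _anchor_ks(ev.ks_depth, cfg, rng))]
            for k in range(cfg.anchors_per_block - 1):
                anchors.append(
                    (
                        f"{ev.species}fA{ev_i}_{k}",
                        f"{ev.species}fB{ev_i}_{k}",
                        _anchor_ks(ev.ks_depth, cfg, rng),
                    )
                )
            anchor_sets.append(AnchorSet(block_id=f"block{ev_i}", anchors=anchors))

    all_ids = list(states_of)
    codon_rows = {
        rid: "".join(SENSE_CODONS[s] for s in states)
        for rid, states in states_of.items()
    }

    # --- records, decoys and truth table
    proteins: list[ProteinRecord] = []
    cds: list[CdsRecord] = []
    member_rows = []
    from ._gencode import translate_cds

    def add_gene(gid, row, is_decoy=False, decoy_kind=""):
        nt = row + "TAA"
        prot = translate_cds(row)
        proteins.append(
            ProteinRecord(id=gid, locus_id=gid, species=species_of.get(gid, ""),
                          sequence=prot)
        )
        cds.append(CdsRecord(id=gid, locus_id=gid, sequence=nt))
        member_rows.append(
            dict(id=gid, species=species_of.get(gid, ""),
                 subfamily=subfam_of.get(gid, ""),
                 is_decoy=is_decoy, decoy_kind=decoy_kind)
        )

    for gid in all_ids:
        add_gene(gid, codon_rows[gid])

    decoy_src = rng.choice(sorted(set(all_ids) - set(partner_of.values())),
                           size=3, replace=False)
    w_col = max(fixed_cols)  # terminal W column
    for k in range(cfg.decoys.get("incomplete_domain", 0)):
        src = decoy_src[0]
        st = states_of[src].copy()
        st[w_col] = SENSE_CODONS.index(_AA_CODON["F"])  # W -> F: broken core
        gid = f"{src}x{k}"
        species_of[gid] = species_of[src]
        subfam_of[gid] = ""
        add_gene(gid, "".join(SENSE_CODONS[s] for s in st),
                 is_decoy=True, decoy_kind="incomplete_domain")
    for k in range(cfg.decoys.get("pseudogene", 0)):
        src = decoy_src[1]
        row = codon_rows[src]
        gid = f"{src}p{k}"
        nt = row[:30] + "TAA" + row[33:] + "TAA"  # internal stop
        species_of[gid] = species_of[src]
        proteins.append(ProteinRecord(id=gid, locus_id=gid,
                                      species=species_of[gid],
                                      sequence=translate_cds(row)))
        cds.append(CdsRecord(id=gid, locus_id=gid, sequence=nt))
        member_rows.append(dict(id=gid, species=species_of[gid], subfamily="",
                                is_decoy=True, decoy_kind="pseudogene"))
    for k in range(cfg.decoys.get("extra_isoform", 0)):
        src = str(decoy_src[2])
        prot = translate_cds(codon_rows[src])
        short = prot[: len(prot) // 2]
        gid = f"{src}.2"
        proteins.append(ProteinRecord(id=gid, locus_id=src,
                                      species=species_of[src], sequence=short))
        cds.append(CdsRecord(id=gid, locus_id=src,
                             sequence=codon_rows[src][: 3 * len(short)]))
        member_rows.append(dict(id=gid, species=species_of[src], subfamily="",
                                is_decoy=True, decoy_kind="extra_isoform"))

    truth_members = pd.DataFrame(member_rows)

    # --- family alignment (true members only; the process is indel-free so
    # the alignment is the sequence matrix itself)
    true_ids = [m for m in truth_members.loc[~truth_members.is_decoy, "id"]]
    alignment = ProteinAlignment(
        ids=true_ids,
        rows=[translate_cds(codon_rows[g]) for g in true_ids],
    )
    codon_alignment = CodonAlignment(
        ids=true_ids, rows=[codon_rows[g] for g in true_ids]
    )

    # --- genome layout, promoters, planted elements
    element_defs = [
        CisElementDef(name=n, pattern=p, category="hormone")
        for n, p, _ in cfg.planted_elements
    ]
    genome: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    element_rows = []
    tandem_partners = {
        r["id_a"]: (r["id_b"], r["intervening"])
        for r in dup_rows if r["mode"] == "tandem"
    }
    segmental_ids = {
        x for r in dup_rows if r["mode"] == "segmental"
        for x in (r["id_a"], r["id_b"])
    }
    tandem_partner_ids = {p for p, _ in tandem_partners.values()}
    for sp in cfg.species:
        sp_genes = [g for g in true_ids
                    if species_of[g] == sp and not g.endswith("s")
                    and g not in tandem_partner_ids]
        chrom1 = _layout_chromosome(
            f"{sp}_chr1", sp, sp_genes, tandem_partners, cfg, codon_rows,
            element_rows, gene_models, rng,
        )
        genome[f"{sp}_chr1"] = chrom1
        seg = [g for g in true_ids if species_of[g] == sp and g.endswith("s")]
        if seg:
            genome[f"{sp}_chr2"] = _layout_chromosome(
                f"{sp}_chr2", sp, seg, {}, cfg, codon_rows,
                element_rows, gene_models, rng,
            )
    truth_elements = pd.DataFrame(
        element_rows, columns=["gene_id", "element", "position"]
    )
    truth_duplications = pd.DataFrame(dup_rows)

    # subfamily seeds: first member of each subfamily
    seeds = {label: [ids[0]] for label, ids in members_by_subfam.items()}

    return SimulatedFamily(
        config=cfg,
        proteins=proteins,
        cds=cds,
        alignment=alignment,
        codon_alignment=codon_alignment,
        tree_newick=newick,
        gene_models=gene_models,
        genome=genome,
        anchor_sets=anchor_sets,
        element_defs=element_defs,
        truth_members=truth_members,
        truth_duplications=truth_duplications,
        truth_sites=truth_sites,
        truth_elements=truth_elements,
        clock_rates=dict(cfg.clock_rates),
        subfamily_seeds=seeds,
    )


def _anchor_ks(depth, cfg: SimConfig, rng) -> float:
    ks = rng.normal(depth, cfg.anchor_ks_rel_sd * depth)
    return float(np.clip(ks, 0.0, 0.999))


def _background(n, cfg: SimConfig, rng) -> str:
    if cfg.promoter_background == "at_only":
        return "".join(rng.choice(list("AT"), size=n))
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3]))


def _promoter_window(gene_id, cfg: SimConfig, rng, element_rows) -> str:
    seq = list(_background(cfg.window, cfg, rng))
    cursor = 10
    for name, pattern, copies in cfg.planted_elements:
        for _ in range(copies):
            concrete = _instantiate(pattern, rng)
            pos = cursor
            if pos + len(concrete) > cfg.window:
                break
            seq[pos : pos + len(concrete)] = list(concrete)
            element_rows.append(
                dict(gene_id=gene_id, element=name, position=pos + 1)
            )
            cursor = pos + len(concrete) + 12 + int(rng.integers(0, 30))
    return "".join(seq)


def _instantiate(pattern, rng) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return "".join(
        rng.choice(list(ambiguous_dna_values[c])) for c in pattern.upper()
    )


def _layout_chromosome(
    chrom, species, gene_order, tandem_partners, cfg: SimConfig,
    codon_rows, element_rows, gene_models, rng,
) -> str:
    """Place genes left to right; tandem partners follow their source with the
    event's filler count between, everything else is separated by enough
    fillers to preclude spurious tandem calls."""
    pieces: list[str] = []
    cursor = 0
    filler_i = 0

    def emit_filler(n):
        nonlocal cursor, filler_i
        for _ in range(n):
            flen = 300
            gap = 50
            seq = _background(flen + gap, cfg, rng)
            start = cursor + gap + 1
            end = start + flen - 1
            gene_models.append(
                GeneModel(
                    id=f"{chrom}_fill{filler_i}", species=species,
                    chromosome=chrom, start=start, end=end, strand="+",
                    exons=[(start, end)],
                )
            )
            pieces.append(seq)
            cursor = end
            filler_i += 1

    def emit_gene(gid):
        nonlocal cursor
        cds_nt = codon_rows[gid] + "TAA"
        intron = _background(200, cfg, rng)
        e1_len = (len(cds_nt) // 2 // 3) * 3
        promoter = _promoter_window(gid, cfg, rng, element_rows)
        start = cursor + cfg.window + 1
        exon1 = (start, start + e1_len - 1)
        exon2 = (exon1[1] + 201, exon1[1] + 200 + (len(cds_nt) - e1_len))
        end = exon2[1]
        body = cds_nt[:e1_len] + intron + cds_nt[e1_len:]
        pieces.append(promoter + body)
        gene_models.append(
            GeneModel(
                id=gid, species=species, chromosome=chrom,
                start=start, end=end, strand="+",
                exons=[exon1, exon2],
            )
        )
        cursor = end

    first = True
    for gid in gene_order:
        if not first:
            emit_filler(cfg.filler_between_family)
        first = False
        emit_gene(gid)
        if gid in tandem_partners:
            partner, intervening = tandem_partners[gid]
            emit_filler(intervening)
            emit_gene(partner)
    pieces.append(_background(100, cfg, rng))
    return "".join(pieces)


# ---------------------------------------------------------------------------
# Truth comparison


def plant_truth_check(results: dict, truth: SimulatedFamily) -> dict:
    """Precision/recall of pipeline outputs against planted truth.

    ``results`` may contain: ``catalog`` (family_scan.FamilyCatalog),
    ``tandem`` and ``segmental`` (lists of DuplicationPair with ages),
    ``assignment`` (id -> subfamily), ``element_hits`` (PromoterHits).
    """
    report: dict = {}
    tm = truth.truth_members
    true_set = set(tm.loc[~tm.is_decoy, "id"])
    if "catalog" in results:
        found = set(results["catalog"].ids)
        tp = len(found & true_set)
        report["member_precision"] = tp / len(found) if found else 0.0
        report["member_recall"] = tp / len(true_set)
        report["decoys_excluded"] = sorted(
            set(tm.loc[tm.is_decoy, "id"]) - found
        )
    td = truth.truth_duplications
    for mode in ("tandem", "segmental"):
        if mode not in results:
            continue
        truth_pairs = {
            frozenset((r.id_a, r.id_b))
            for r in td.itertuples() if r.mode == mode
        }
        called = {frozenset((p.id_a, p.id_b)) for p in results[mode]}
        tp = len(called & truth_pairs)
        report[f"{mode}_recall"] = tp / len(truth_pairs) if truth_pairs else 1.0
        report[f"{mode}_precision"] = tp / len(called) if called else 1.0
    if "segmental" in results:
        errs = []
        ages = {
            frozenset((r.id_a, r.id_b)): r.age_true_mya
            for r in td.itertuples() if r.mode == "segmental"
        }
        for p in results["segmental"]:
            key = frozenset((p.id_a, p.id_b))
            if key in ages and p.age_mya is not None and ages[key] > 0:
                errs.append(abs(p.age_mya - ages[key]) / ages[key])
        report["segmental_age_max_rel_err"] = max(errs) if errs else None
    if "assignment" in results:
        correct = total = 0
        subfam = dict(zip(tm.id, tm.subfamily))
        for gid, label in results["assignment"].items():
            expected = subfam.get(gid, "")
            if not expected:
                continue
            total += 1
            correct += label == expected
        report["subfamily_accuracy"] = correct / total if total else None
    if "element_hits" in results:
        te = truth.truth_elements
        planted = te.groupby("element").size().to_dict()
        observed: dict[str, int] = {}
        for h in results["element_hits"]:
            observed[h.element] = observed.get(h.element, 0) + 1
        report["element_counts_match"] = planted == observed
        report["element_planted"] = planted
        report["element_observed"] = observed
    return report
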