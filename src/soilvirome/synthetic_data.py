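"""Fully labeled synthetic multi-omics soil community with known ground truth.

The generator emulates the kind of mixed microbial/viral community a prairie
soil study works with: host genomes with distinct compositional signatures,
free and integrated (prophage) DNA viral contigs, CRISPR arrays whose spacers
copy sub-sequences of chosen viral contigs, condition-dependent ("wet"/"dry")
transcript read sets, RdRP-bearing RNA viral contigs, and target/decoy
peptide-spectrum-match tables.  Every planted feature is recorded in a truth
object so downstream stages are testable by direct substring/coordinate
checks, without any external dataset.

What it does *not* emulate: realistic sequencing error profiles, quality
strings, insert-size models, or chimeric reads.  Reads are emitted with
truth-based alignments — the package's in-scope computation is the filtering
and quantification of alignments, not read mapping itself.

Host genome composition is drawn from per-host order-2 Markov chains with
distinct transition tables, which makes alignment-free (Markov-likelihood)
host prediction learnable; viral contigs are generated from their true host's
chain, emulating the amelioration of phage composition toward the host.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    ContigRecord,
    GeneInterval,
    write_fasta,
    write_gff,
    write_sam,
    write_table,
)
from .rna_screen import RDRP_MOTIFS

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

#: one representative codon per amino acid, used to plant peptide motifs
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityConfig:
    """Parameters of the stated synthetic world.

    Defaults are chosen once to resemble a desk-scale soil community: ten
    compositionally distinct hosts, fifty DNA viral contigs in the 3–10 kb
    range (all above the 2.5 kb screening cutoff), one CRISPR spacer per
    host, a third of viruses lysogenic, and a two-fold wet-activation of a
    subset of contigs.
    """

    n_hosts: int = 10
    n_viral: int = 50
    n_rna_viral: int = 6
    host_length: tuple[int, int] = (15_000, 25_000)
    viral_length: tuple[int, int] = (3_000, 10_000)
    rna_viral_length: tuple[int, int] = (1_500, 4_000)
    gene_length: tuple[int, int] = (300, 900)
    intergenic_length: tuple[int, int] = (50, 300)
    spacers_per_host: int = 1
    crispr_host_fraction: float = 1.0
    repeat_length: tuple[int, int] = (23, 47)
    spacer_length: tuple[int, int] = (26, 50)
    lysogenic_fraction: float = 0.3
    prophage_fraction: float = 0.5
    amg_fraction: float = 0.2
    wet_active_fraction: float = 0.3
    dry_active_fraction: float = 0.2
    activity_fold: float = 2.0
    base_depth: float = 2.0
    host_depth: float = 0.5
    markov_alpha: float = 1.0

    def validate(self) -> None:
        for name in ("n_hosts", "n_viral", "n_rna_viral", "spacers_per_host"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("host_length", "viral_length", "rna_viral_length",
                     "gene_length", "intergenic_length", "repeat_length",
                     "spacer_length"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must be a positive (lo, hi) range")
        if self.n_viral and self.spacer_length[1] > self.viral_length[0]:
            raise ConfigError(
                "spacer_length max exceeds the shortest possible viral contig"
            )
        for name in ("lysogenic_fraction", "prophage_fraction", "amg_fraction",
                     "wet_active_fraction", "dry_active_fraction",
                     "crispr_host_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.activity_fold <= 0 or self.base_depth < 0 or self.host_depth < 0:
            raise ConfigError("depths must be non-negative, fold positive")


@dataclass(frozen=True)
class HostGenome:
    id: str
    sequence: str
    taxon: str


@dataclass(frozen=True)
class ViralContig:
    id: str
    sequence: str
    host_taxa: tuple[str, ...]
    lysogenic: bool
    true_host_id: str


@dataclass(frozen=True)
class RnaViralContig:
    id: str
    sequence: str
    taxon: str
    rdrp_peptide: str


@dataclass(frozen=True)
class SpacerPlant:
    sequence: str          # as it appears in the array
    target_viral_id: str
    reverse_complemented: bool


@dataclass
class CommunityTruth:
    """Ground truth for one synthetic community."""

    host_genomes: list[HostGenome]
    viral_contigs: list[ViralContig]
    rna_viral_contigs: list[RnaViralContig]
    gene_map: dict[str, list[GeneInterval]]
    amg_genes: dict[str, list[str]]                      # contig -> gene ids
    spacer_map: dict[str, list[SpacerPlant]]             # host -> plants
    prophage_map: dict[str, list[tuple[int, int, str]]]  # host -> intervals
    expression: dict[str, dict[str, float]]              # contig -> cond -> depth
    markov_tables: dict[str, np.ndarray]                 # host -> (16, 4)
    config: CommunityConfig
    seed: int

    @property
    def taxonomy(self) -> dict[str, str]:
        return {h.id: h.taxon for h in self.host_genomes}

    def all_sequences(self) -> dict[str, str]:
        out = {h.id: h.sequence for h in self.host_genomes}
        out.update({v.id: v.sequence for v in self.viral_contigs})
        out.update({r.id: r.sequence for r in self.rna_viral_contigs})
        return out


# ---------------------------------------------------------------------------
# sequence generation primitives
# ---------------------------------------------------------------------------

def _markov_table(rng: np.random.Generator, alpha: float) -> np.ndarray:
    """Order-2 transition table: 16 dinucleotide contexts x 4 next-base probs."""
    return rng.dirichlet(np.full(4, alpha), size=16)


def _markov_sequence(rng: np.random.Generator, table: np.ndarray,
                     length: int) -> str:
    cum = np.cumsum(table, axis=1)
    u = rng.random(length)
    codes = np.empty(length, dtype=np.int64)
    codes[0] = rng.integers(4)
    if length > 1:
        codes[1] = rng.integers(4)
    ctx = codes[0] * 4 + codes[1] if length > 1 else 0
    for i in range(2, length):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        codes[i] = b
        ctx = (ctx % 4) * 4 + b
    return "".join(_BASES[codes])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _tile_genes(rng: np.random.Generator, contig_len: int,
                cfg: CommunityConfig, prefix: str) -> list[GeneInterval]:
    """Alternate intergenic gaps and genes along a contig."""
    genes: list[GeneInterval] = []
    pos = int(rng.integers(*cfg.intergenic_length))
    i = 0
    while True:
        glen = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        if pos + glen > contig_len:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneInterval(pos, pos + glen, strand, f"{prefix}_g{i}"))
        pos += glen + int(rng.integers(*cfg.intergenic_length))
        i += 1
    return genes


def _encode_peptide(peptide: str) -> str:
    return "".join(CODON[aa] for aa in peptide)


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def make_community(config: CommunityConfig | None = None, *,
                   seed: int) -> CommunityTruth:
    """Generate a labeled community; deterministic for a fixed (config, seed).

    Viral contigs are emitted both free and (for a lysogenic subset) as
    planted prophage intervals inside their designated host genome.  CRISPR
    arrays (>= 3 repeat copies, repeats 23–47 nt, spacers 26–50 nt) are
    inserted into designated hosts with spacers copied — forward or
    reverse-complemented with probability 0.5 — from target viral contigs.
    """
    cfg = config or CommunityConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    # hosts: distinct order-2 composition per host
    tables = {f"host_{i:02d}": _markov_table(rng, cfg.markov_alpha)
              for i in range(cfg.n_hosts)}
    host_base: dict[str, str] = {}
    taxa: dict[str, str] = {}
    for i, hid in enumerate(sorted(tables)):
        L = int(rng.integers(cfg.host_length[0], cfg.host_length[1] + 1))
        host_base[hid] = _markov_sequence(rng, tables[hid], L)
        taxa[hid] = f"Phylum_{i:02d}"

    # DNA viral contigs, drawn from their true host's chain
    viral: list[ViralContig] = []
    gene_map: dict[str, list[GeneInterval]] = {}
    amg_genes: dict[str, list[str]] = {}
    host_ids = sorted(tables)
    for j in range(cfg.n_viral):
        vid = f"vc_{j:03d}"
        hid = host_ids[j % cfg.n_hosts] if cfg.n_hosts else ""
        L = int(rng.integers(cfg.viral_length[0], cfg.viral_length[1] + 1))
        seq = (_markov_sequence(rng, tables[hid], L) if hid
               else _random_sequence(rng, L))
        lys = bool(rng.random() < cfg.lysogenic_fraction)
        viral.append(ViralContig(vid, seq, (taxa.get(hid, ""),), lys, hid))
        genes = _tile_genes(rng, L, cfg, vid)
        gene_map[vid] = genes
        # optionally one internal auxiliary metabolic gene (not first/last)
        if len(genes) >= 3 and rng.random() < cfg.amg_fraction:
            k = int(rng.integers(1, len(genes) - 1))
            amg_genes[vid] = [genes[k].gene_id]

    # CRISPR arrays and prophages, spliced into the host genomes
    spacer_map: dict[str, list[SpacerPlant]] = {}
    prophage_map: dict[str, list[tuple[int, int, str]]] = {}
    viral_by_host: dict[str, list[ViralContig]] = {}
    for v in viral:
        viral_by_host.setdefault(v.true_host_id, []).append(v)

    inserts: dict[str, list[tuple[int, str, str]]] = {h: [] for h in host_base}
    for hid in host_ids:
        targets = viral_by_host.get(hid, [])
        if targets and cfg.spacers_per_host and rng.random() < cfg.crispr_host_fraction:
            plants: list[SpacerPlant] = []
            rep_len = int(rng.integers(cfg.repeat_length[0],
                                       cfg.repeat_length[1] + 1))
            repeat = _random_sequence(rng, rep_len)
            n_repeats = max(3, cfg.spacers_per_host + 1)
            slots: list[str] = []
            for s in range(n_repeats - 1):
                if s < cfg.spacers_per_host:
                    tgt = targets[int(rng.integers(len(targets)))]
                    slen = int(rng.integers(cfg.spacer_length[0],
                                            cfg.spacer_length[1] + 1))
                    pos = int(rng.integers(0, len(tgt.sequence) - slen + 1))
                    spacer = tgt.sequence[pos:pos + slen]
                    rc = bool(rng.random() < 0.5)
                    if rc:
                        spacer = revcomp(spacer)
                    plants.append(SpacerPlant(spacer, tgt.id, rc))
                    slots.append(spacer)
                else:  # filler spacer keeping the array >= 3 repeats
                    slots.append(_random_sequence(
                        rng, int(rng.integers(cfg.spacer_length[0],
                                              cfg.spacer_length[1] + 1))))
            array = repeat + "".join(s + repeat for s in slots)
            pos = int(rng.integers(0, len(host_base[hid]) + 1))
            inserts[hid].append((pos, "crispr", array))
            spacer_map[hid] = plants
        for v in targets:
            if v.lysogenic and rng.random() < cfg.prophage_fraction:
                pos = int(rng.integers(0, len(host_base[hid]) + 1))
                inserts[hid].append((pos, "prophage:" + v.id, v.sequence))

    hosts: list[HostGenome] = []
    for hid in host_ids:
        base = host_base[hid]
        parts: list[str] = []
        cursor = 0
        offset = 0
        intervals: list[tuple[int, int, str]] = []
        for pos, kind, payload in sorted(inserts[hid]):
            parts.append(base[cursor:pos])
            start = pos + offset
            if kind.startswith("prophage:"):
                intervals.append((start, start + len(payload),
                                  kind.split(":", 1)[1]))
            parts.append(payload)
            offset += len(payload)
            cursor = pos
        parts.append(base[cursor:])
        hosts.append(HostGenome(hid, "".join(parts), taxa[hid]))
        if intervals:
            prophage_map[hid] = intervals

    # RNA viral contigs with a planted RdRP motif ORF
    rna: list[RnaViralContig] = []
    motif_taxa = sorted(RDRP_MOTIFS)
    for j in range(cfg.n_rna_viral):
        taxon = motif_taxa[j % len(motif_taxa)]
        pep = RDRP_MOTIFS[taxon]
        cassette = "ATG" + _encode_peptide(pep) + "TAA"
        L = int(rng.integers(cfg.rna_viral_length[0],
                             cfg.rna_viral_length[1] + 1))
        L = max(L, len(cassette) + 200)
        seq = _random_sequence(rng, L)
        pos = int(rng.integers(0, L - len(cassette) + 1))
        seq = seq[:pos] + cassette + seq[pos + len(cassette):]
        rna.append(RnaViralContig(f"rna_{j:02d}", seq, taxon, pep))

    # expected per-condition read depth
    expression: dict[str, dict[str, float]] = {}
    for v in viral:
        u = rng.random()
        if u < cfg.wet_active_fraction:
            expression[v.id] = {"wet": cfg.base_depth * cfg.activity_fold,
                                "dry": cfg.base_depth}
        elif u < cfg.wet_active_fraction + cfg.dry_active_fraction:
            expression[v.id] = {"wet": cfg.base_depth,
                                "dry": cfg.base_depth * cfg.activity_fold}
        else:
            expression[v.id] = {"wet": cfg.base_depth, "dry": cfg.base_depth}
    for h in hosts:
        expression[h.id] = {"wet": cfg.host_depth, "dry": cfg.host_depth}
    for r in rna:
        expression[r.id] = {"wet": cfg.base_depth, "dry": cfg.base_depth}

    return CommunityTruth(
        host_genomes=hosts, viral_contigs=viral, rna_viral_contigs=rna,
        gene_map=gene_map, amg_genes=amg_genes, spacer_map=spacer_map,
        prophage_map=prophage_map, expression=expression,
        markov_tables=tables, config=cfg, seed=seed,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated reads with truth labels and their (truth-based) alignments."""

    condition: str
    read_length: int
    alignments: list[AlignmentRecord]
    sequences: dict[str, str]     # read id -> read sequence
    sources: dict[str, str]       # read id -> true source contig

    @property
    def total_reads(self) -> int:
        return len(self.alignments)


def _sample_reads(contigs: Mapping[str, str], depths: Mapping[str, float],
                  error_rate: float, read_length: int,
                  rng: np.random.Generator, condition: str) -> ReadSet:
    alignments: list[AlignmentRecord] = []
    sequences: dict[str, str] = {}
    sources: dict[str, str] = {}
    cigar = (("M", read_length),)
    for cid in sorted(contigs):
        depth = depths.get(cid, 0.0)
        seq = contigs[cid]
        if depth <= 0:
            continue
        if read_length > len(seq):
            raise ConfigError(
                f"read_length {read_length} exceeds contig {cid} length"
            )
        n = int(rng.poisson(depth * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        n_err = rng.binomial(read_length, error_rate, size=n)
        for i in range(n):
            start = int(starts[i])
            read = list(seq[start:start + read_length])
            k = int(n_err[i])
            if k:
                pos = rng.choice(read_length, size=k, replace=False)
                for p in pos:
                    # substitute with a different base so NM is exact
                    choices = [b for b in "ACGT" if b != read[p]]
                    read[p] = choices[int(rng.integers(3))]
            rid = f"{cid}|{condition}|r{i:06d}"
            alignments.append(AlignmentRecord(
                read_id=rid, contig_id=cid, contig_start=start,
                cigar=cigar, read_length=read_length, mismatch_count=k,
            ))
            sequences[rid] = "".join(read)
            sources[rid] = cid
    return ReadSet(condition, read_length, alignments, sequences, sources)


def simulate_reads(truth: CommunityTruth, condition: str,
                   error_rate: float = 0.0, read_length: int = 100, *,
                   seed: int) -> ReadSet:
    """Simulate a transcript read set for one condition.

    Expected per-contig read counts are proportional to
    ``expression[condition]`` (Poisson depth model); each emitted alignment
    carries a correct CIGAR and mismatch count relative to its source.
    """
    if not 0.0 <= error_rate < 0.25:
        raise ConfigError("error_rate must be in [0, 0.25)")
    conditions = {c for e in truth.expression.values() for c in e}
    if condition not in conditions:
        raise KeyError(
            f"condition {condition!r} not in expression table {sorted(conditions)}"
        )
    rng = np.random.default_rng(seed)
    depths = {cid: e.get(condition, 0.0) for cid, e in truth.expression.items()}
    return _sample_reads(truth.all_sequences(), depths, error_rate,
                         read_length, rng, condition)


# ---------------------------------------------------------------------------
# lysogenic marker references and reads
# ---------------------------------------------------------------------------

def make_marker_reference(n_integrase: int = 3, n_excisionase: int = 2,
                          length: int = 900, *, seed: int
                          ) -> tuple[list[ContigRecord], dict[str, str]]:
    """Random marker gene references labeled integrase/excisionase."""
    rng = np.random.default_rng(seed)
    records: list[ContigRecord] = []
    classes: dict[str, str] = {}
    for i in range(n_integrase):
        mid = f"integrase_{i:02d}"
        records.append(ContigRecord(mid, _random_sequence(rng, length)))
        classes[mid] = "integrase"
    for i in range(n_excisionase):
        mid = f"excisionase_{i:02d}"
        records.append(ContigRecord(mid, _random_sequence(rng, length)))
        classes[mid] = "excisionase"
    return records, classes


def simulate_marker_reads(markers: list[ContigRecord],
                          depths: Mapping[str, float], condition: str,
                          error_rate: float = 0.0, read_length: int = 100, *,
                          seed: int) -> ReadSet:
    """Simulate reads recruited by the lysogenic marker reference set."""
    rng = np.random.default_rng(seed)
    contigs = {m.id: m.sequence for m in markers}
    return _sample_reads(contigs, depths, error_rate, read_length, rng,
                         condition)


# ---------------------------------------------------------------------------
# screening evidence (assembly + per-contig channel values)
# ---------------------------------------------------------------------------

def make_assembly_and_evidence(truth: CommunityTruth, n_nonviral: int = 150, *,
                               seed: int, corrupt_one_channel: bool = False
                               ) -> tuple[list[ContigRecord], pd.DataFrame,
                                          dict[str, bool]]:
    """Build a mixed assembly and an ensemble-evidence table consistent with it.

    Viral contigs receive evidence satisfying all four screening criteria
    (majority viral gene origins, VirSorter category 1–3, IMG/VR E <= 1e-5,
    VirFinder p < 0.05 with score > 0.90); non-viral contigs — fragments cut
    from the host genomes — satisfy none.  With ``corrupt_one_channel`` one
    randomly chosen channel per viral contig is flipped to a failing value,
    exercising the >= 3/4 integration tolerance.

    Returns (contigs, evidence table, truth labels by contig id).
    """
    rng = np.random.default_rng(seed)
    cfg = truth.config
    contigs: list[ContigRecord] = []
    labels: dict[str, bool] = {}
    rows: list[dict] = []

    def viral_gene_scores() -> dict[str, float]:
        return {
            "viral_hmm": float(rng.uniform(60, 150)),
            "viral_pfam": float(rng.uniform(40, 120)),
            "ncvog": float(rng.uniform(20, 80)),
            "bacterial": float(rng.uniform(5, 40)),
            "archaeal": float(rng.uniform(5, 40)),
        }

    def cellular_gene_scores() -> dict[str, float]:
        return {
            "viral_hmm": float(rng.uniform(5, 40)),
            "viral_pfam": float(rng.uniform(5, 40)),
            "ncvog": float(rng.uniform(5, 40)),
            "bacterial": float(rng.uniform(60, 150)),
            "archaeal": float(rng.uniform(20, 80)),
        }

    for v in truth.viral_contigs:
        genes = truth.gene_map.get(v.id, [])
        contigs.append(ContigRecord(v.id, v.sequence, list(genes)))
        labels[v.id] = True
        corrupt = int(rng.integers(4)) if corrupt_one_channel else -1
        channel = {
            "virsorter_category": float(rng.integers(1, 4)),
            "imgvr_evalue": float(10.0 ** rng.uniform(-30, -6)),
            "virfinder_score": float(rng.uniform(0.91, 0.999)),
            "virfinder_p": float(rng.uniform(0.0001, 0.049)),
        }
        if corrupt == 1:
            channel["virsorter_category"] = np.nan
        elif corrupt == 2:
            channel["imgvr_evalue"] = 1.0
        elif corrupt == 3:
            channel["virfinder_score"] = 0.5
        amgs = set(truth.amg_genes.get(v.id, []))
        for g in genes:
            scores = (cellular_gene_scores() if corrupt == 0 or g.gene_id in amgs
                      else viral_gene_scores())
            rows.append({
                "contig_id": v.id, "gene_id": g.gene_id, **scores, **channel,
                "metabolic_evalue": (float(10.0 ** rng.uniform(-12, -6))
                                     if g.gene_id in amgs else np.nan),
            })
        if not genes:
            rows.append({"contig_id": v.id, "gene_id": "", **channel,
                         "metabolic_evalue": np.nan})

    host_seqs = [h.sequence for h in truth.host_genomes]
    for j in range(n_nonviral):
        cid = f"nv_{j:03d}"
        src = host_seqs[j % len(host_seqs)] if host_seqs else None
        L = int(rng.integers(cfg.viral_length[0], cfg.viral_length[1] + 1))
        if src is not None and len(src) > L:
            pos = int(rng.integers(0, len(src) - L + 1))
            seq = src[pos:pos + L]
        else:
            seq = _random_sequence(rng, L)
        genes = _tile_genes(rng, L, cfg, cid)
        contigs.append(ContigRecord(cid, seq, genes))
        labels[cid] = False
        channel = {
            "virsorter_category": np.nan,
            "imgvr_evalue": float(10.0 ** rng.uniform(-3, 0)),
            "virfinder_score": float(rng.uniform(0.0, 0.7)),
            "virfinder_p": float(rng.uniform(0.1, 1.0)),
        }
        for g in genes:
            rows.append({"contig_id": cid, "gene_id": g.gene_id,
                         **cellular_gene_scores(), **channel,
                         "metabolic_evalue": np.nan})

    return contigs, pd.DataFrame(rows), labels


# ---------------------------------------------------------------------------
# host-link hit tables
# ---------------------------------------------------------------------------

def make_host_hit_tables(truth: CommunityTruth, *, seed: int
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Similarity-search hit tables consistent with the planted community.

    The host-similarity table carries a strong hit for every prophage-bearing
    (virus, host) pair; the reference-virus table links a random subset of
    viruses to fictitious references annotated with the true host taxon.
    Returns (host hits, reference hits, reference-host metadata).
    """
    rng = np.random.default_rng(seed)
    host_rows, ref_rows = [], []
    ref_hosts: dict[str, str] = {}
    prophage_pairs = {(vid, hid) for hid, ivals in truth.prophage_map.items()
                      for _, _, vid in ivals}
    taxa = truth.taxonomy
    for v in truth.viral_contigs:
        if (v.id, v.true_host_id) in prophage_pairs:
            host_rows.append({
                "viral_id": v.id, "host_id": v.true_host_id,
                "evalue": float(10.0 ** rng.uniform(-50, -10)),
                "bitscore": float(rng.uniform(200, 900)),
            })
        if rng.random() < 0.3:
            ref = f"ref_{v.id}"
            ref_hosts[ref] = taxa.get(v.true_host_id, "")
            ref_rows.append({
                "viral_id": v.id, "ref_id": ref,
                "evalue": float(10.0 ** rng.uniform(-30, -6)),
                "bitscore": float(rng.uniform(100, 500)),
            })
    cols_h = ["viral_id", "host_id", "evalue", "bitscore"]
    cols_r = ["viral_id", "ref_id", "evalue", "bitscore"]
    return (pd.DataFrame(host_rows, columns=cols_h),
            pd.DataFrame(ref_rows, columns=cols_r), ref_hosts)


# ---------------------------------------------------------------------------
# peptide-spectrum matches
# ---------------------------------------------------------------------------

@dataclass
class PsmScoreModel:
    """Two-component score model (MSGF-style spectral probability, lower=better).

    Target scores mix a "true" low-score component with the null; decoy
    scores are drawn from the null component only.  Scores are log10-normal.
    """

    true_log10_mean: float = -12.0
    true_log10_sd: float = 1.0
    null_log10_mean: float = -5.0
    null_log10_sd: float = 1.0
    true_target_fraction: float = 0.8
    true_ppm_sd: float = 1.5
    null_ppm_max: float = 10.0


_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_psms(truth: CommunityTruth | None, n_target: int, n_decoy: int,
                  score_model: PsmScoreModel | None = None, *,
                  seed: int, viral_fraction: float = 0.5) -> pd.DataFrame:
    """Simulate a target/decoy PSM table with ground-truth component labels.

    Columns: spectrum_id, peptide, is_decoy, score, ppm, db_class, is_true.
    """
    if n_target < 0 or n_decoy < 0:
        raise ConfigError("n_target and n_decoy must be >= 0")
    m = score_model or PsmScoreModel()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_target + n_decoy):
        decoy = i >= n_target
        true = (not decoy) and rng.random() < m.true_target_fraction
        if true:
            score = 10.0 ** rng.normal(m.true_log10_mean, m.true_log10_sd)
            ppm = abs(rng.normal(0.0, m.true_ppm_sd))
        else:
            score = 10.0 ** rng.normal(m.null_log10_mean, m.null_log10_sd)
            ppm = rng.uniform(0.0, m.null_ppm_max)
        pep = "".join(_AA[k] for k in rng.integers(0, 20,
                                                   size=rng.integers(8, 21)))
        rows.append({
            "spectrum_id": f"spec_{i:06d}",
            "peptide": pep,
            "is_decoy": decoy,
            "score": float(score),
            "ppm": float(ppm),
            "db_class": "viral" if rng.random() < viral_fraction else "nonviral",
            "is_true": true,
        })
    cols = ["spectrum_id", "peptide", "is_decoy", "score", "ppm", "db_class",
            "is_true"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_community(truth: CommunityTruth, outdir: str | Path) -> None:
    """Write the community as FASTA/GFF3/TSV plus a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([ContigRecord(h.id, h.sequence) for h in truth.host_genomes],
                outdir / "hosts.fasta")
    write_fasta([ContigRecord(v.id, v.sequence) for v in truth.viral_contigs],
                outdir / "viral_contigs.fasta")
    if truth.rna_viral_contigs:
        write_fasta([ContigRecord(r.id, r.sequence)
                     for r in truth.rna_viral_contigs],
                    outdir / "rna_viral_contigs.fasta")
    write_gff(truth.gene_map, outdir / "genes.gff3")
    spacer_rows = [
        {"host_id": hid, "spacer": p.sequence, "target": p.target_viral_id,
         "reverse_complemented": p.reverse_complemented}
        for hid in sorted(truth.spacer_map) for p in truth.spacer_map[hid]
    ]
    write_table(pd.DataFrame(
        spacer_rows, columns=["host_id", "spacer", "target",
                              "reverse_complemented"]),
        outdir / "spacers.tsv")
    expr_rows = [
        {"contig_id": cid, "condition": cond, "depth": d}
        for cid in sorted(truth.expression)
        for cond, d in sorted(truth.expression[cid].items())
    ]
    write_table(pd.DataFrame(
        expr_rows, columns=["contig_id", "condition", "depth"]),
        outdir / "expression.tsv")
    taxa_rows = [{"host_id": h.id, "taxon": h.taxon}
                 for h in truth.host_genomes]
    write_table(pd.DataFrame(taxa_rows, columns=["host_id", "taxon"]),
                outdir / "taxonomy.tsv")
    manifest = {"seed": truth.seed, "config": asdict(truth.config)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_reads_sam(reads: ReadSet, contig_lengths: Mapping[str, int],
                    path: str | Path) -> None:
    """Write a simulated read set as SAM with NM tags."""
    write_sam(reads.alignments, contig_lengths, path, reads.sequences)
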