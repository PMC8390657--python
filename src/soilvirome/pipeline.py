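"""End-to-end orchestration of the soil virome analysis with a CLI.

``run_all`` executes the stages in dependency order on a self-generated
synthetic community — screen, dereplicate/cluster, activity, hosts, RNA,
PSM filtering, statistics — writing each stage's outputs and a summary
report under a run directory.  Every stage is a pure function of (inputs,
config, seed): re-running with the same seed reproduces the run directory
byte for byte.

The ``soilvirome`` console script exposes per-stage subcommands mirroring
``run-all`` so stages are independently scriptable.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import activity as activity_mod
from . import catalog, host_link, proteo_filter, rna_screen, stats
from . import synthetic_data as synth
from . import viral_screen
from .io_formats import ContigRecord, read_fasta, read_gff, read_sam, \
    read_table, write_fasta, write_gff, write_table

log = logging.getLogger("soilvirome")


@dataclass
class RunConfig:
    """Flat configuration of a full run; thresholds at the study's defaults."""

    seed: int = 0
    outdir: str = "soilvirome_run"
    # community scale (kept desk-sized for the bundled demo)
    n_hosts: int = 6
    n_viral: int = 20
    n_rna_viral: int = 6
    n_nonviral: int = 40
    n_replicates: int = 3
    read_length: int = 100
    error_rate: float = 0.01
    marker_fold: float = 20.0
    marker_base_depth: float = 1.0
    n_psm_target: int = 800
    n_psm_decoy: int = 800
    cluster_max_proteins: int = 5
    # thresholds
    min_length: int = 2500
    min_criteria: int = 3
    id_cut: float = 0.95
    frac_cut: float = 0.80
    aai_cutoff: float = 70.0
    fdr_limit: float = 0.05
    alpha: float = 0.05
    markov_order: int = 2

    def validate(self) -> None:
        if not 0.0 < self.id_cut <= 1.0:
            raise ValueError(f"id_cut {self.id_cut} outside (0, 1]")
        if not 0.0 < self.frac_cut <= 1.0:
            raise ValueError(f"frac_cut {self.frac_cut} outside (0, 1]")
        if not 0.0 < self.fdr_limit < 1.0:
            raise ValueError("fdr_limit must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.aai_cutoff <= 100.0:
            raise ValueError("aai_cutoff must be in (0, 100]")
        if self.min_length <= 0 or not 1 <= self.min_criteria <= 4:
            raise ValueError("invalid screening thresholds")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 for statistics")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ValueError("seed must be a non-negative 31-bit integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat key=value config file (# starts a comment)."""
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (t.strip() for t in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                t = types[key]
                kwargs[key] = (value if t == "str"
                               else int(value) if t == "int"
                               else float(value))
        return cls(**kwargs)


def _seed(base: int, offset: int) -> int:
    return (base * 1000 + offset) % (2 ** 31)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written to disk)."""
    cfg = config
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # ---- stage 0: synthetic community -----------------------------------
    community_cfg = synth.CommunityConfig(
        n_hosts=cfg.n_hosts, n_viral=cfg.n_viral, n_rna_viral=cfg.n_rna_viral)
    truth = synth.make_community(community_cfg, seed=_seed(cfg.seed, 0))
    inputs = out / "inputs"
    synth.write_community(truth, inputs)
    contigs, evidence, truth_labels = synth.make_assembly_and_evidence(
        truth, n_nonviral=cfg.n_nonviral, seed=_seed(cfg.seed, 1))
    write_fasta(contigs, inputs / "assembly.fasta")
    write_gff({c.id: c.genes for c in contigs if c.genes},
              inputs / "assembly_genes.gff3")
    write_table(evidence, inputs / "evidence.tsv")
    summary["community"] = {
        "hosts": len(truth.host_genomes),
        "viral_contigs": len(truth.viral_contigs),
        "rna_viral_contigs": len(truth.rna_viral_contigs),
        "assembly_contigs": len(contigs),
    }

    # ---- stage 1: ensemble screen ---------------------------------------
    stage = out / "screen"
    stage.mkdir(exist_ok=True)
    screened = viral_screen.screen_contigs(
        contigs, evidence, cfg.min_length, cfg.min_criteria)
    write_table(screened, stage / "screened.tsv")
    called = screened.loc[screened["viral"], "contig_id"].tolist()
    by_id = {c.id: c for c in contigs}
    called_contigs = [by_id[cid] for cid in called]
    tp = sum(truth_labels.get(cid, False) for cid in called)
    summary["screen"] = {
        "contigs_screened": len(contigs),
        "viral_called": len(called),
        "true_positive_calls": tp,
    }

    # ---- stage 2: dereplication and clustering --------------------------
    stage = out / "cluster"
    stage.mkdir(exist_ok=True)
    derep = catalog.dereplicate(called_contigs)
    write_fasta(derep, stage / "viral_catalog.fasta")
    protein_sets = {
        c.id: catalog.translate_genes(c)[: cfg.cluster_max_proteins]
        for c in derep
    }
    profiles = {c.id: catalog.tetra_zscores(c.sequence, c.id) for c in derep}
    clusters = catalog.cluster_contigs(protein_sets, profiles,
                                       cutoff=cfg.aai_cutoff)
    write_table(clusters, stage / "clusters.tsv")
    n_clusters = clusters["cluster_id"].nunique()
    singletons = int((clusters.groupby("cluster_id").size() == 1).sum())
    summary["cluster"] = {
        "catalog_size": len(derep),
        "clusters": int(n_clusters),
        "singletons": singletons,
    }

    # ---- stage 3: transcriptional activity ------------------------------
    stage = out / "activity"
    stage.mkdir(exist_ok=True)
    markers, marker_classes = synth.make_marker_reference(
        seed=_seed(cfg.seed, 2))
    write_fasta(markers, inputs / "markers.fasta")
    lengths = {cid: len(seq) for cid, seq in truth.all_sequences().items()}
    samples = [f"{cond}_{r + 1}" for cond in ("wet", "dry")
               for r in range(cfg.n_replicates)]
    conditions = {s: s.split("_")[0] for s in samples}
    act_matrix = pd.DataFrame(0.0, index=sorted(called), columns=samples)
    transcribed: dict[str, set[str]] = {"wet": set(), "dry": set()}
    coding_rows, marker_rows = [], []
    retained_by_sample: dict[str, activity_mod.FilterResult] = {}
    total_by_sample: dict[str, int] = {}
    for i, sample in enumerate(samples):
        cond = conditions[sample]
        reads = synth.simulate_reads(
            truth, cond, error_rate=cfg.error_rate,
            read_length=cfg.read_length, seed=_seed(cfg.seed, 10 + i))
        sam_path = inputs / f"reads_{sample}.sam"
        synth.write_reads_sam(reads, lengths, sam_path)
        records = read_sam(sam_path)
        marker_depths = {
            m.id: (cfg.marker_base_depth * cfg.marker_fold
                   if cond == "dry" else cfg.marker_base_depth)
            for m in markers
        }
        marker_reads = synth.simulate_marker_reads(
            markers, marker_depths, cond, error_rate=cfg.error_rate,
            read_length=cfg.read_length, seed=_seed(cfg.seed, 40 + i))
        total = len(records) + marker_reads.total_reads
        total_by_sample[sample] = total
        retained = activity_mod.filter_alignments(
            records, cfg.id_cut, cfg.frac_cut)
        retained_by_sample[sample] = retained
        by_contig: dict[str, list] = {}
        for a in retained:
            by_contig.setdefault(a.contig_id, []).append(a)
        coding = noncoding = 0
        for cid in sorted(called):
            if cid not in lengths:
                continue
            prof = activity_mod.depth_and_activity(
                by_contig.get(cid, []), cid, lengths[cid], total, sample)
            act_matrix.loc[cid, sample] = prof.normalized_activity
            if prof.mapped_read_count > 0:
                transcribed[cond].add(cid)
            c, nc, _ = activity_mod.partition_coding(
                by_contig.get(cid, []), truth.gene_map.get(cid, []),
                lengths[cid])
            coding += c
            noncoding += nc
        coding_rows.append({
            "sample": sample, "coding": coding, "noncoding": noncoding,
            "percent_noncoding": (100.0 * noncoding / (coding + noncoding)
                                  if coding + noncoding else 0.0),
        })
        mc = activity_mod.marker_counts(
            marker_reads.alignments, marker_classes, total,
            cfg.id_cut, cfg.frac_cut)
        marker_rows.append({"sample": sample, **mc})
    write_table(act_matrix.reset_index(names="contig_id"),
                stage / "activity_matrix.tsv")
    write_table(pd.DataFrame(coding_rows), stage / "coding_noncoding.tsv")
    marker_df = pd.DataFrame(marker_rows)
    write_table(marker_df, stage / "marker_counts.tsv")
    dry_int = marker_df.loc[marker_df["sample"].str.startswith("dry"),
                            "integrase"].mean()
    wet_int = marker_df.loc[marker_df["sample"].str.startswith("wet"),
                            "integrase"].mean()
    summary["activity"] = {
        "samples": len(samples),
        "transcribed_wet": len(transcribed["wet"]),
        "transcribed_dry": len(transcribed["dry"]),
        "transcribed_both": len(transcribed["wet"] & transcribed["dry"]),
        "integrase_dry_over_wet": (float(dry_int / wet_int)
                                   if wet_int else None),
    }

    # ---- stage 4: host linkage ------------------------------------------
    stage = out / "hosts"
    stage.mkdir(exist_ok=True)
    host_contigs = [ContigRecord(h.id, h.sequence)
                    for h in truth.host_genomes]
    host_hits, ref_hits, ref_hosts = synth.make_host_hit_tables(
        truth, seed=_seed(cfg.seed, 3))
    write_table(host_hits, inputs / "host_hits.tsv")
    write_table(ref_hits, inputs / "ref_hits.tsv")
    pairings = host_link.link_hosts(
        called_contigs, host_contigs, truth.taxonomy,
        host_hits, ref_hits, ref_hosts, markov_order=cfg.markov_order)
    write_table(pairings, stage / "host_pairings.tsv")
    summary["hosts"] = {
        "consensus_pairings": len(pairings),
        "viral_with_host": int(pairings["viral_id"].nunique())
        if not pairings.empty else 0,
    }

    # ---- stage 5: RNA viruses -------------------------------------------
    stage = out / "rna"
    stage.mkdir(exist_ok=True)
    rna_contigs = [ContigRecord(r.id, r.sequence)
                   for r in truth.rna_viral_contigs]
    decoys = [by_id[cid] for cid in sorted(truth_labels)
              if not truth_labels[cid]][:5]
    rna_assembly = rna_contigs + [ContigRecord(d.id, d.sequence)
                                  for d in decoys]
    rna_lengths = dict(lengths)
    rna_lengths.update({c.id: len(c) for c in rna_assembly})
    pssms = rna_screen.default_profiles(seed=0)
    hits = [h for h in (rna_screen.classify_rna_contig(c, pssms)
                        for c in rna_assembly) if h is not None]
    hits_df = pd.DataFrame(
        [{"contig_id": h.contig_id, "route": h.route, "best": h.best_name,
          "score": h.score, "taxon": h.taxon} for h in hits],
        columns=["contig_id", "route", "best", "score", "taxon"])
    write_table(hits_df, stage / "rna_hits.tsv")
    taxon_cols = {}
    for sample in samples:
        _, per_taxon = rna_screen.rna_abundance(
            hits, retained_by_sample[sample], rna_lengths,
            total_by_sample[sample], cfg.id_cut, cfg.frac_cut)
        taxon_cols[sample] = per_taxon.set_index("taxon")["abundance"]
    rna_matrix = pd.DataFrame(taxon_cols).fillna(0.0).sort_index()
    write_table(rna_matrix.reset_index(names="taxon"),
                stage / "rna_abundance.tsv")
    summary["rna"] = {
        "rna_viral_hits": len(hits),
        "taxa": int(rna_matrix.shape[0]),
    }

    # ---- stage 6: viral peptides ----------------------------------------
    stage = out / "psm"
    stage.mkdir(exist_ok=True)
    psms = synth.simulate_psms(truth, cfg.n_psm_target, cfg.n_psm_decoy,
                               seed=_seed(cfg.seed, 4))
    write_table(psms, inputs / "psms.tsv")
    cuts = proteo_filter.optimize_thresholds(psms, cfg.fdr_limit)
    if cuts is None:
        retained_peps: list[str] = []
        fdr = None
    else:
        score_cut, ppm_cut = cuts
        passing = psms[(psms["score"] <= score_cut)
                       & (psms["ppm"] <= ppm_cut) & ~psms["is_decoy"]]
        viral_peps = passing.loc[passing["db_class"] == "viral",
                                 "peptide"].tolist()
        nonviral_peps = passing.loc[passing["db_class"] == "nonviral",
                                    "peptide"].tolist()
        retained_peps = proteo_filter.exclude_shared(viral_peps,
                                                     nonviral_peps)
        fdr = proteo_filter.fdr_at(psms, score_cut, ppm_cut)
    write_table(pd.DataFrame({"peptide": sorted(retained_peps)}),
                stage / "viral_peptides.tsv")
    summary["psm"] = {
        "thresholds": list(cuts) if cuts else None,
        "fdr": fdr,
        "viral_peptides_retained": len(retained_peps),
    }

    # ---- stage 7: statistics --------------------------------------------
    stage = out / "stats"
    stage.mkdir(exist_ok=True)
    diff = stats.differential(act_matrix, conditions, alpha=cfg.alpha)
    write_table(diff, stage / "differential.tsv")
    n_wet = [len({a.contig_id for a in retained_by_sample[s]
                  if a.contig_id in set(called)})
             for s in samples if conditions[s] == "wet"]
    n_dry = [len({a.contig_id for a in retained_by_sample[s]
                  if a.contig_id in set(called)})
             for s in samples if conditions[s] == "dry"]
    t, p = stats.t_test(n_wet, n_dry)
    viral_activity = act_matrix.sum(axis=0)
    host_reads = [sum(1 for a in retained_by_sample[s]
                      if a.contig_id.startswith("host_")) for s in samples]
    r2 = stats.correlation_r2(viral_activity.to_numpy(), host_reads)
    summary["stats"] = {
        "significant_entities": int(diff["significant"].sum()),
        "significant_entities_adj": int(diff["significant_adj"].sum()),
        "transcribed_count_t": t,
        "transcribed_count_p": p,
        "viral_vs_host_r2": r2,
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report = [
        f"soilvirome run (seed {cfg.seed})",
        f"  contigs screened: {summary['screen']['contigs_screened']}"
        f" -> viral calls: {summary['screen']['viral_called']}",
        f"  catalog: {summary['cluster']['catalog_size']} sequences in "
        f"{summary['cluster']['clusters']} clusters "
        f"({summary['cluster']['singletons']} singletons)",
        f"  transcribed viral contigs: wet "
        f"{summary['activity']['transcribed_wet']}, dry "
        f"{summary['activity']['transcribed_dry']}, shared "
        f"{summary['activity']['transcribed_both']}",
        f"  consensus virus-host pairings: "
        f"{summary['hosts']['consensus_pairings']}",
        f"  RNA viral hits: {summary['rna']['rna_viral_hits']}",
        f"  viral peptides retained: "
        f"{summary['psm']['viral_peptides_retained']}",
        f"  differential entities (BH-adjusted): "
        f"{summary['stats']['significant_entities_adj']}",
    ]
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return summary


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log at DEBUG level.")
def main(verbose: bool) -> None:
    """Soil virome multi-omics analysis toolkit."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s")


@main.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="Flat key=value config file.")
@click.option("--out", default=None, help="Run directory.")
@click.option("--seed", default=None, type=int)
def run_all_cmd(config_path, out, seed) -> None:
    """Run every stage on a synthetic community and write a report."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    if out is not None:
        cfg.outdir = out
    if seed is not None:
        cfg.seed = seed
    summary = run_all(cfg)
    click.echo((Path(cfg.outdir) / "report.txt").read_text(), nl=False)


@main.command()
@click.option("--out", required=True)
@click.option("--seed", default=0, type=int)
@click.option("--n-hosts", default=10, type=int)
@click.option("--n-viral", default=50, type=int)
def simulate(out, seed, n_hosts, n_viral) -> None:
    """Generate a synthetic community and write its ground truth."""
    cfg = synth.CommunityConfig(n_hosts=n_hosts, n_viral=n_viral)
    truth = synth.make_community(cfg, seed=seed)
    synth.write_community(truth, out)
    click.echo(f"community written to {out}")


@main.command()
@click.option("--contigs", required=True, type=click.Path(exists=True))
@click.option("--genes", type=click.Path(exists=True), default=None)
@click.option("--evidence", required=True, type=click.Path(exists=True))
@click.option("--out", required=True)
@click.option("--min-length", default=2500, type=int)
@click.option("--min-criteria", default=3, type=int)
def screen(contigs, genes, evidence, out, min_length, min_criteria) -> None:
    """Classify contigs as viral by the four-criterion ensemble."""
    recs = read_fasta(contigs)
    if genes:
        gene_map = read_gff(genes)
        recs = [ContigRecord(r.id, r.sequence, gene_map.get(r.id))
                for r in recs]
    table = viral_screen.screen_contigs(
        recs, read_table(evidence, required=["contig_id", "gene_id"]),
        min_length, min_criteria)
    write_table(table, out)
    click.echo(f"{int(table['viral'].sum())} / {len(table)} contigs called "
               "viral")


@main.command()
@click.option("--contigs", required=True, type=click.Path(exists=True))
@click.option("--genes", required=True, type=click.Path(exists=True))
@click.option("--out", required=True)
@click.option("--aai-cutoff", default=70.0, type=float)
def cluster(contigs, genes, out, aai_cutoff) -> None:
    """Dereplicate and cluster viral contigs (AAI + tetranucleotide rescue)."""
    gene_map = read_gff(genes)
    recs = [ContigRecord(r.id, r.sequence, gene_map.get(r.id))
            for r in read_fasta(contigs)]
    derep = catalog.dereplicate(recs)
    protein_sets = {c.id: catalog.translate_genes(c) for c in derep}
    profiles = {c.id: catalog.tetra_zscores(c.sequence, c.id) for c in derep}
    table = catalog.cluster_contigs(protein_sets, profiles, cutoff=aai_cutoff)
    write_table(table, out)
    click.echo(f"{table['cluster_id'].nunique()} clusters for "
               f"{len(table)} contigs")


@main.command("activity")
@click.option("--sam", required=True, type=click.Path(exists=True))
@click.option("--contigs", required=True, type=click.Path(exists=True))
@click.option("--genes", type=click.Path(exists=True), default=None)
@click.option("--out", required=True)
@click.option("--id", "id_cut", default=0.95, type=float)
@click.option("--frac", "frac_cut", default=0.80, type=float)
@click.option("--total-reads", default=None, type=int,
              help="Total reads in the sample (defaults to the SAM count).")
def activity_cmd(sam, contigs, genes, out, id_cut, frac_cut,
                 total_reads) -> None:
    """Filter transcript alignments and compute per-contig activity."""
    recs = read_fasta(contigs)
    gene_map = read_gff(genes) if genes else {}
    records = read_sam(sam)
    total = total_reads or len(records)
    retained = activity_mod.filter_alignments(records, id_cut, frac_cut)
    by_contig: dict[str, list] = {}
    for a in retained:
        by_contig.setdefault(a.contig_id, []).append(a)
    rows = []
    for c in recs:
        prof = activity_mod.depth_and_activity(
            by_contig.get(c.id, []), c.id, len(c), total)
        coding, noncoding, _ = activity_mod.partition_coding(
            by_contig.get(c.id, []), gene_map.get(c.id, []), len(c))
        rows.append({"contig_id": c.id, "reads": prof.mapped_read_count,
                     "avg_coverage": prof.average_base_coverage,
                     "normalized_activity": prof.normalized_activity,
                     "coding": coding, "noncoding": noncoding})
    write_table(pd.DataFrame(rows), out)
    click.echo(f"{len(retained)} alignments retained of {len(records)}")


@main.command()
@click.option("--viral", required=True, type=click.Path(exists=True))
@click.option("--hosts", "hosts_path", required=True,
              type=click.Path(exists=True))
@click.option("--taxonomy", required=True, type=click.Path(exists=True))
@click.option("--host-hits", type=click.Path(exists=True), default=None)
@click.option("--ref-hits", type=click.Path(exists=True), default=None)
@click.option("--out", required=True)
@click.option("--markov-order", default=2, type=int)
def hosts(viral, hosts_path, taxonomy, host_hits, ref_hits, out,
          markov_order) -> None:
    """Assign consensus hosts to viral contigs (Methods 1-4)."""
    taxa = dict(read_table(taxonomy, required=["host_id", "taxon"])
                [["host_id", "taxon"]].itertuples(index=False, name=None))
    table = host_link.link_hosts(
        read_fasta(viral), read_fasta(hosts_path), taxa,
        read_table(host_hits) if host_hits else None,
        read_table(ref_hits) if ref_hits else None,
        ref_hosts={}, markov_order=markov_order)
    write_table(table, out)
    click.echo(f"{len(table)} consensus pairings")


@main.command()
@click.option("--contigs", required=True, type=click.Path(exists=True))
@click.option("--ref-hits", type=click.Path(exists=True), default=None)
@click.option("--out", required=True)
@click.option("--min-orf", default=30, type=int)
def rna(contigs, ref_hits, out, min_orf) -> None:
    """Screen contigs for RNA viruses (RdRP profiles + reference route)."""
    profiles = rna_screen.default_profiles(seed=0)
    refs = read_table(ref_hits) if ref_hits else None
    rows = []
    for c in read_fasta(contigs):
        h = rna_screen.classify_rna_contig(c, profiles, refs, min_orf)
        if h is not None:
            rows.append({"contig_id": h.contig_id, "route": h.route,
                         "best": h.best_name, "score": h.score,
                         "taxon": h.taxon})
    write_table(pd.DataFrame(
        rows, columns=["contig_id", "route", "best", "score", "taxon"]), out)
    click.echo(f"{len(rows)} RNA viral contigs")


@main.command("psm-filter")
@click.option("--psms", required=True, type=click.Path(exists=True))
@click.option("--out", required=True)
@click.option("--fdr", default=0.05, type=float)
def psm_filter(psms, out, fdr) -> None:
    """Optimize PSM score/ppm thresholds at a target-decoy FDR limit."""
    table = read_table(psms, required=list(proteo_filter.REQUIRED_COLUMNS))
    cuts = proteo_filter.optimize_thresholds(table, fdr)
    if cuts is None:
        click.echo("no feasible thresholds")
        write_table(table.iloc[0:0], out)
        return
    score_cut, ppm_cut = cuts
    passing = table[(table["score"] <= score_cut) & (table["ppm"] <= ppm_cut)
                    & ~table["is_decoy"]]
    write_table(passing, out)
    click.echo(f"score<={score_cut:g} ppm<={ppm_cut:g}: "
               f"{len(passing)} target PSMs at FDR "
               f"{proteo_filter.fdr_at(table, score_cut, ppm_cut):.4f}")


@main.command()
@click.option("--matrix", required=True, type=click.Path(exists=True))
@click.option("--metadata", required=True, type=click.Path(exists=True),
              help="TSV with sample and condition columns.")
@click.option("--out", required=True)
@click.option("--alpha", default=0.05, type=float)
def compare(matrix, metadata, out, alpha) -> None:
    """Differential comparison (log2FC wet/dry, Welch t, BH adjustment)."""
    mat = read_table(matrix).set_index("contig_id")
    meta = read_table(metadata, required=["sample", "condition"])
    conditions = dict(meta[["sample", "condition"]]
                      .itertuples(index=False, name=None))
    result = stats.differential(mat, conditions, alpha=alpha)
    write_table(result, out)
    click.echo(f"{int(result['significant_adj'].sum())} entities significant "
               "after BH adjustment")


if __name__ == "__main__":  # pragma: no cover
    main()
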