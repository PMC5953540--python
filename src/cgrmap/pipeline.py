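"""Stage orchestration: chain the library modules on files, with manifests.

Each runner writes its outputs plus a ``manifest.json`` recording the
package version, seed, every threshold in effect and a sha256 of every
input file, so a run can be reproduced exactly. One log line per stage
reports records in/out.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, io
from .alignment import SequenceRecord, dereplicate_strains
from .metagenome import (build_pileup, call_variants, cgr_ratio,
                         copies_per_cell, dagostino_skewness, prevalence,
                         abundance_association, aggregate_individuals,
                         recruit_reads, type_allele)
from .pangenome import build_matrix, cluster_orthologs, conservation_table
from .phylo import random_coalescent_tree, read_newick, write_newick
from .simulate import (PangenomeSimConfig, simulate_pangenome,
                       simulate_qpcr_cohort, simulate_reads,
                       simulate_trait_on_tree)
from .trait_mapping import (METABOLIZER, blomberg_k, collapse_features,
                            exact_discriminators, rf_gini_importance)

log = logging.getLogger("cgrmap")


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, stage: str, seed: int | None,
                   thresholds: Mapping[str, object],
                   inputs: Sequence[Path] = ()) -> None:
    manifest = {
        "stage": stage,
        "cgrmap_version": __version__,
        "seed": seed,
        "thresholds": dict(thresholds),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                           sort_keys=True))


def run_simulate(outdir: str | Path, seed: int = 0,
                 config: PangenomeSimConfig | None = None,
                 n_reads: int = 20000, read_len: int = 100,
                 error_rate: float = 0.005,
                 n_individuals: int = 158) -> Path:
    """Generate a full synthetic dataset: strain collection, tree + trait,
    shotgun reads from a two-strain mixture, and a qPCR-like cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or PangenomeSimConfig(seed=seed)
    ds = simulate_pangenome(cfg)
    ds.write(outdir)
    log.info("simulate: %d genomes, %d genes", len(ds.genomes), len(ds.genes))

    tree = random_coalescent_tree(sorted(ds.genomes), seed=seed)
    write_newick(tree, str(outdir / "tree.nwk"))
    trait = simulate_trait_on_tree(tree, "white_noise", 1.0, seed=seed)
    pd.DataFrame(sorted(trait.items()), columns=["strain_id", "trait"]).to_csv(
        outdir / "trait.tsv", sep="\t", index=False)

    alleles = ds.truth.true_allele_per_strain
    ys = sorted(g for g, a in alleles.items() if a == "Y")
    ns = sorted(g for g, a in alleles.items() if a == "N")
    if ys and ns:
        mix = {ys[0]: 0.7, ns[0]: 0.3}
        reads, rtruth = simulate_reads(
            {g: ds.genomes[g] for g in mix}, mix, n_reads=n_reads,
            read_len=read_len, error_rate=error_rate, seed=seed)
        io.write_fastq(reads, outdir / "reads.fastq")
        rtruth.to_json(outdir / "reads_truth.json")
        log.info("simulate: %d reads from mixture %s", len(reads), mix)

    cohort, ctruth = simulate_qpcr_cohort(n_individuals=n_individuals, seed=seed)
    cohort.to_csv(outdir / "qpcr.csv", index=False)
    ctruth.to_json(outdir / "qpcr_truth.json")
    write_manifest(outdir, "simulate", seed, {
        **asdict(cfg), "n_reads": n_reads, "read_len": read_len,
        "error_rate": error_rate, "n_individuals": n_individuals})
    return outdir


def run_pangenome(gff: str, genome_fasta: str, protein_fasta: str | None,
                  outdir: str | Path, min_identity: float = 60.0,
                  min_coverage: float = 80.0, ani_threshold: float = 99.99,
                  dereplicate: bool = False, conservation: bool = True):
    """Ortholog clustering and presence/absence matrix from annotated genomes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        genes = io.read_gene_records(gff, genome_fasta, protein_fasta)
    except Exception as e:
        raise PipelineError(f"[read-inputs] {e}") from e
    log.info("pangenome: %d gene records in", len(genes))
    genomes = sorted({g.genome_id for g in genes})

    if dereplicate:
        assemblies = io.read_fasta(genome_fasta)
        by_genome: dict[str, list[str]] = {}
        for g in genes:
            by_genome.setdefault(g.genome_id, [])
        for contig, seq in assemblies.items():
            owner = next((g.genome_id for g in genes if g.contig == contig), contig)
            by_genome.setdefault(owner, []).append(seq)
        reps, repl_map = dereplicate_strains(by_genome, threshold=ani_threshold)
        pd.DataFrame(sorted(repl_map.items()),
                     columns=["genome_id", "representative"]).to_csv(
            outdir / "dereplication.tsv", sep="\t", index=False)
        genes = [g for g in genes if g.genome_id in reps]
        genomes = sorted(reps)
        log.info("pangenome: %d representative genomes after dereplication",
                 len(genomes))

    try:
        clusters = cluster_orthologs(genes, min_identity, min_coverage)
    except Exception as e:
        raise PipelineError(f"[cluster-orthologs] {e}") from e
    matrix = build_matrix(clusters, genomes)
    log.info("pangenome: %d clusters out (%s)", len(clusters),
             matrix.class_counts())

    members = pd.DataFrame(
        [(c.cluster_id, m.genome_id, m.gene_id)
         for c in clusters for m in c.members],
        columns=["cluster_id", "genome_id", "gene_id"])
    io.write_tsv(members, outdir / "clusters.tsv")
    io.write_tsv(matrix.presence.astype(int), outdir / "matrix.tsv", index=True,
                 header_comments={"min_identity": min_identity,
                                  "min_coverage": min_coverage})
    cons = None
    if conservation:
        cons = conservation_table(clusters, matrix)
        io.write_tsv(cons, outdir / "conservation.tsv")
    write_manifest(outdir, "pangenome", None,
                   {"min_identity": min_identity, "min_coverage": min_coverage,
                    "ani_threshold": ani_threshold, "dereplicate": dereplicate},
                   [p for p in (gff, genome_fasta, protein_fasta) if p])
    return clusters, matrix, cons


def run_map_trait(gff: str, genome_fasta: str, protein_fasta: str | None,
                  phenotype_tsv: str, tree_nwk: str | None,
                  outdir: str | Path, seed: int = 0, n_trees: int = 500,
                  min_identity: float = 60.0, min_coverage: float = 80.0,
                  n_perm: int = 1000) -> pd.DataFrame:
    """Full discriminative-locus discovery: cluster -> matrix -> collapse ->
    random forest + exact discriminators, plus Blomberg's K when a tree is
    given (on percent conversion)."""
    outdir = Path(outdir)
    clusters, matrix, _ = run_pangenome(gff, genome_fasta, protein_fasta,
                                        outdir, min_identity, min_coverage,
                                        conservation=False)
    pheno = io.read_tsv(phenotype_tsv)
    missing = [g for g in matrix.genomes
               if g not in set(pheno["strain_id"])]
    if missing:
        raise PipelineError(f"[phenotype] phenotype file missing genome(s): "
                            f"{missing}")
    labels = dict(zip(pheno["strain_id"], pheno["label"]))
    try:
        collapsed, groups = collapse_features(matrix)
        table = rf_gini_importance(collapsed, labels, n_trees=n_trees,
                                   seed=seed, group_map=groups)
    except Exception as e:
        raise PipelineError(f"[trait-mapping] {e}") from e
    log.info("map-trait: %d collapsed features, %d perfect discriminators",
             len(collapsed.columns), int(table["perfect_discriminator"].sum()))
    io.write_tsv(table, outdir / "importance.tsv",
                 header_comments={"n_trees": n_trees, "seed": seed})

    if tree_nwk:
        tree = read_newick(tree_nwk)
        trait = dict(zip(pheno["strain_id"], pheno["percent_conversion"]))
        trait = {g: trait[g] for g in matrix.genomes}
        k = blomberg_k(tree, trait, n_perm=n_perm, seed=seed)
        (outdir / "k_report.json").write_text(json.dumps(asdict(k), indent=1))
        log.info("map-trait: Blomberg K=%.4f p=%.4f", k.K, k.p_perm)
    write_manifest(outdir, "map-trait", seed,
                   {"min_identity": min_identity, "min_coverage": min_coverage,
                    "n_trees": n_trees, "n_perm": n_perm},
                   [p for p in (gff, genome_fasta, protein_fasta,
                                phenotype_tsv, tree_nwk) if p])
    return table


def run_quantify(reads_fastq: str, references_fasta: str, outdir: str | Path,
                 marker_ids: Sequence[str] = (), focal_id: str | None = None,
                 min_identity: float = 90.0, min_read_coverage: float = 90.0,
                 min_mapq: int = 10) -> pd.DataFrame:
    """Per-sample marker quantification and variant calling from reads.

    Recruits reads to the gene references, reports per-gene depth and (when
    universal-marker ids are given) copies per cell, and calls majority-rule
    variants on the focal reference, written as a minimal VCF.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = io.read_fasta(references_fasta)
    raw = io.read_fastq(reads_fastq)
    reads = [(rid, seq) for rid, seq, _ in raw]
    log.info("quantify: %d reads in, %d references", len(reads), len(refs))
    alns, depths = recruit_reads(reads, refs, min_identity, min_read_coverage)
    log.info("quantify: %d reads recruited", len(alns))

    marker_depths = [depths[m] for m in marker_ids if m in depths]
    rows = []
    for gene, depth in sorted(depths.items()):
        cpc = (copies_per_cell(depth, marker_depths)
               if marker_depths else None)
        rows.append((gene, depth, cpc, depth > 0))
    abundance = pd.DataFrame(rows, columns=["gene_id", "depth",
                                            "copies_per_cell", "detected"])
    io.write_tsv(abundance, outdir / "abundance.tsv",
                 header_comments={"min_identity": min_identity,
                                  "min_read_coverage": min_read_coverage})

    if focal_id:
        if focal_id not in refs:
            raise PipelineError(f"[variants] focal reference {focal_id!r} "
                                f"not in {references_fasta}")
        ref = SequenceRecord(focal_id, refs[focal_id], "nt")
        pile = build_pileup(alns, ref, min_mapq=min_mapq)
        calls = call_variants(pile)
        io.write_vcf(calls, focal_id, outdir / "variants.vcf")
        log.info("quantify: %d variants called on %s",
                 sum(c.called for c in calls), focal_id)
    write_manifest(outdir, "quantify", None,
                   {"min_identity": min_identity,
                    "min_read_coverage": min_read_coverage,
                    "min_mapq": min_mapq},
                   [reads_fastq, references_fasta])
    return abundance


def run_cohort_report(qpcr_csv: str, outdir: str | Path,
                      detection_limit: float = 1e3) -> dict:
    """Cohort-level prevalence, cgr-ratio, skewness and association report
    from a qPCR table (individual_id, sample_id, elnmrk1/cgr2 copies/g)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(qpcr_csv)
    if table.empty:
        raise PipelineError("[cohort] empty cohort table")
    log.info("report: %d samples from %d individuals", len(table),
             table["individual_id"].nunique())
    prev_eln, per_ind_e = prevalence(table, "elnmrk1_copies_per_g",
                                     detection_limit)
    prev_cgr, _ = prevalence(table, "cgr2_copies_per_g", detection_limit)
    per_ind = aggregate_individuals(
        table, ["elnmrk1_copies_per_g", "cgr2_copies_per_g"])
    ratios = cgr_ratio(per_ind, detection_limit=detection_limit)
    skew = dagostino_skewness(ratios.to_numpy())
    both = per_ind[(per_ind["elnmrk1_copies_per_g"] >= detection_limit)
                   & (per_ind["cgr2_copies_per_g"] >= detection_limit)]
    rho, rho_p = abundance_association(
        np.log10(both["elnmrk1_copies_per_g"]),
        np.log10(both["cgr2_copies_per_g"]))
    report = {
        "n_individuals": int(table["individual_id"].nunique()),
        "detection_limit": detection_limit,
        "prevalence_elnmrk1_pct": prev_eln,
        "prevalence_cgr2_pct": prev_cgr,
        "cgr_ratio_n": int(len(ratios)),
        "cgr_ratio_mean": float(ratios.mean()),
        "skew_g1": skew.g1, "skew_z": skew.z, "skew_p": skew.p,
        "spearman_rho": rho, "spearman_p": rho_p,
    }
    (outdir / "cohort_report.json").write_text(json.dumps(report, indent=1))
    io.write_tsv(per_ind, outdir / "per_individual.tsv",
                 header_comments={"detection_limit": detection_limit})
    log.info("report: prevalence %.1f%% / %.1f%%, skew %.3f (p=%.2g, n=%d)",
             prev_eln, prev_cgr, skew.g1, skew.p, skew.n)
    return report
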