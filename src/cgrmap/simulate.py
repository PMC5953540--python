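"""Synthetic data with embedded ground truth for every pipeline stage.

Four generators emulate the study design of a strain-collection +
metagenome survey of a phenotype-linked gene cluster:

* :func:`simulate_pangenome` — a clonal-frame pan-genome: core genes shared
  by all strains, accessory genes present per-genome at a fixed occupancy,
  and a planted multi-gene cluster carried by metabolizer strains only. One
  planted gene (the "focal" gene, emulating a reductase like cgr2) carries a
  bi-allelic codon (Y = TAT / N = AAT) at a configurable protein position.
* :func:`simulate_trait_on_tree` — Brownian-motion or white-noise continuous
  traits on a phylogeny, the alternative/null pair for phylogenetic-signal
  tests.
* :func:`simulate_reads` — shotgun reads from a mixture of strains with
  uniform fragment starts and a substitution-only error model (constant Q30
  qualities; indel rate exposed, default 0).
* :func:`simulate_qpcr_cohort` — per-individual marker-gene abundance pairs:
  a log-normal total-population marker and a Beta-distributed carrier
  sub-population fraction, giving the negative-skew log-ratio structure seen
  in real cohorts, with a detection limit and optional repeat sampling.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .alignment import SequenceRecord, reverse_complement
from .pangenome import GeneRecord
from .phylo import tree_vcv

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))
Q30_CHAR = "?"  # phred+33

Y_CODON = "TAT"   # tyrosine
N_CODON = "AAT"   # asparagine


# ---------------------------------------------------------------------------
# Pan-genome simulation


@dataclass(frozen=True)
class PangenomeSimConfig:
    """Study-design knobs for the synthetic strain collection.

    Defaults emulate a 24-strain collection in which a third of the strains
    are metabolizers carrying an 8-gene planted cluster, at ~1% nucleotide
    divergence between strains.
    """

    n_genomes: int = 24
    n_core: int = 120
    n_accessory: int = 120
    accessory_occupancy: float = 0.4
    planted_cluster_size: int = 8
    fraction_metabolizers: float = 8 / 24
    gene_length_range: tuple[int, int] = (300, 900)   # nt, multiples of 3
    per_site_divergence: float = 0.01
    fraction_allele_n: float = 5 / 8   # N-allele share among metabolizers
    focal_codon: int = 333             # protein position of the bi-allelic codon
    seed: int = 0

    def __post_init__(self):
        for f in ("accessory_occupancy", "fraction_metabolizers",
                  "per_site_divergence", "fraction_allele_n"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        for f in ("n_genomes", "n_core"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.n_accessory < 0:
            raise ValueError("n_accessory must be >= 0")
        if self.planted_cluster_size < 1:
            raise ValueError("planted_cluster_size must be >= 1")
        lo, hi = self.gene_length_range
        if lo < 90 or hi < lo:
            raise ValueError("gene_length_range must satisfy 90 <= lo <= hi")
        if lo % 3 or hi % 3:
            raise ValueError("gene_length_range bounds must be multiples of 3")
        if self.focal_codon < 2:
            raise ValueError("focal_codon must be >= 2")


@dataclass
class SimTruth:
    """Ground truth embedded by the generators."""

    phenotype_labels: dict[str, str] = field(default_factory=dict)
    planted_gene_ids: list[str] = field(default_factory=list)
    true_allele_per_strain: dict[str, str] = field(default_factory=dict)
    true_depths: dict[str, float] = field(default_factory=dict)
    true_mixture_weights: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, 3))
        if codon not in _STOPS:
            out.append(codon)
    return out


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float,
                keep_codons: Sequence[int] = ()) -> str:
    """Per-site substitutions avoiding internal stops; codon indices in
    ``keep_codons`` (plus start and stop codons) are left untouched."""
    if rate <= 0:
        return cds
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    protected = {0, len(codons) - 1} | set(keep_codons)
    for ci in range(len(codons)):
        if ci in protected:
            continue
        codon = list(codons[ci])
        for p in range(3):
            if rng.random() >= rate:
                continue
            alternatives = [b for b in "ACGT" if b != codon[p]]
            rng.shuffle(alternatives)
            for b in alternatives:
                trial = codon.copy()
                trial[p] = b
                if "".join(trial) not in _STOPS:
                    codon = trial
                    break
        codons[ci] = "".join(codon)
    return "".join(codons)


def _mutate_plain(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitutions without codon constraints (intergenic DNA)."""
    if rate <= 0:
        return seq
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


@dataclass
class PangenomeDataset:
    """Genomes, gene annotations and ground truth from one simulation."""

    config: PangenomeSimConfig
    genomes: dict[str, str]                  # genome_id -> contig sequence
    genes: list[GeneRecord]
    truth: SimTruth
    phenotype: pd.DataFrame                  # strain_id, percent_conversion, label
    presence: pd.DataFrame                   # truth genome x family bool matrix

    def proteins(self) -> list[GeneRecord]:
        return self.genes

    def write(self, outdir: str | Path) -> None:
        from . import io as _io
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_fasta({g: s for g, s in self.genomes.items()},
                        outdir / "genomes.fasta")
        _io.write_fasta({g.gene_id: g.protein.residues for g in self.genes},
                        outdir / "proteins.faa")
        _io.write_fasta({g.gene_id: g.cds.residues for g in self.genes},
                        outdir / "cds.fna")
        _io.write_gff3(self.genes, outdir / "genes.gff3")
        self.phenotype.to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
        self.presence.astype(int).to_csv(outdir / "truth_presence.tsv", sep="\t")
        self.truth.to_json(outdir / "truth.json")


def simulate_pangenome(config: PangenomeSimConfig) -> PangenomeDataset:
    """Simulate a strain collection with a planted phenotype-linked cluster.

    Every genome carries all core genes; accessory genes are present with
    probability ``accessory_occupancy``; the planted cluster is present in a
    genome iff that genome is a metabolizer. Gene sequences diverge from a
    shared ancestral sequence by independent per-site substitutions
    (codon-aware: start/stop codons and the focal codon protected, internal
    stops avoided). The focal planted gene carries allele Y (TAT) or N (AAT)
    at ``focal_codon`` per strain.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome_ids = [f"G{i + 1:02d}" for i in range(cfg.n_genomes)]

    n_met = int(round(cfg.fraction_metabolizers * cfg.n_genomes))
    metabolizers = set(rng.choice(genome_ids, size=n_met, replace=False).tolist())

    # ancestral families: name -> ancestral cds
    lo, hi = cfg.gene_length_range
    families: dict[str, str] = {}

    def ancestral(n_codons_total: int) -> str:
        return "ATG" + "".join(_random_codons(rng, n_codons_total - 2)) + "TAA"

    focal_len_codons = max(cfg.focal_codon + 60 + 27, (lo // 3))
    for k in range(cfg.planted_cluster_size):
        name = f"PLT{k + 1:03d}"
        if k == 0:
            cds = ancestral(focal_len_codons + 1)
            # ancestral focal codon = Y
            i = (cfg.focal_codon - 1) * 3
            cds = cds[:i] + Y_CODON + cds[i + 3:]
        else:
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            cds = ancestral(n_codons)
        families[name] = cds
    for k in range(cfg.n_core):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        families[f"COR{k + 1:04d}"] = ancestral(n_codons)
    for k in range(cfg.n_accessory):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        families[f"ACC{k + 1:04d}"] = ancestral(n_codons)

    planted_ids = [f"PLT{k + 1:03d}" for k in range(cfg.planted_cluster_size)]
    core_ids = [f"COR{k + 1:04d}" for k in range(cfg.n_core)]
    accessory_ids = [f"ACC{k + 1:04d}" for k in range(cfg.n_accessory)]

    # intergenic DNA is part of the clonal frame: one ancestral spacer per
    # gene (its upstream spacer) plus a terminal one, diverging like genes
    anc_spacer = {fam: "".join(rng.choice(_BASES, int(rng.integers(20, 81))))
                  for fam in families}
    anc_tail = "".join(rng.choice(_BASES, int(rng.integers(20, 81))))
    # gene orientation is ancestral too (no rearrangements between strains)
    anc_strand = {fam: ("+" if rng.random() < 0.5 else "-")
                  for fam in families}

    # presence, alleles
    presence = pd.DataFrame(False, index=genome_ids,
                            columns=core_ids + accessory_ids + planted_ids)
    presence.loc[:, core_ids] = True
    for acc in accessory_ids:
        presence[acc] = rng.random(cfg.n_genomes) < cfg.accessory_occupancy
    for plt in planted_ids:
        presence[plt] = [g in metabolizers for g in genome_ids]

    alleles = {}
    for g in sorted(metabolizers):
        alleles[g] = "N" if rng.random() < cfg.fraction_allele_n else "Y"

    focal_codon_idx = cfg.focal_codon - 1
    genes: list[GeneRecord] = []
    genomes: dict[str, str] = {}
    for g in genome_ids:
        order = ([f for f in core_ids if presence.at[g, f]]
                 + [f for f in planted_ids if presence.at[g, f]]
                 + [f for f in accessory_ids if presence.at[g, f]])
        parts: list[str] = []
        pos = 0
        for fam in order:
            keep = (focal_codon_idx,) if fam == planted_ids[0] else ()
            cds = _mutate_cds(rng, families[fam], cfg.per_site_divergence, keep)
            if fam == planted_ids[0]:
                i = focal_codon_idx * 3
                codon = Y_CODON if alleles[g] == "Y" else N_CODON
                cds = cds[:i] + codon + cds[i + 3:]
            strand = anc_strand[fam]
            spacer = _mutate_plain(rng, anc_spacer[fam], cfg.per_site_divergence)
            parts.append(spacer)
            pos += len(spacer)
            start = pos + 1
            parts.append(cds if strand == "+" else reverse_complement(cds))
            pos += len(cds)
            end = pos
            prot = str(Seq(cds).translate()).rstrip("*")
            genes.append(GeneRecord(
                genome_id=g, gene_id=f"{g}|{fam}",
                protein=SequenceRecord(f"{g}|{fam}", prot, "aa"),
                cds=SequenceRecord(f"{g}|{fam}", cds, "nt"),
                contig=g, start=start, end=end, strand=strand))
        parts.append(_mutate_plain(rng, anc_tail, cfg.per_site_divergence))
        genomes[g] = "".join(parts)

    pheno_rows = []
    for g in genome_ids:
        if g in metabolizers:
            pc = float(np.clip(rng.normal(90, 5), 0, 100))
            label = "metabolizer"
        else:
            pc = float(np.clip(abs(rng.normal(0.5, 0.5)), 0, 100))
            label = "non-metabolizer"
        pheno_rows.append((g, pc, label))
    phenotype = pd.DataFrame(pheno_rows,
                             columns=["strain_id", "percent_conversion", "label"])

    truth = SimTruth(
        phenotype_labels={g: ("metabolizer" if g in metabolizers
                              else "non-metabolizer") for g in genome_ids},
        planted_gene_ids=planted_ids,
        true_allele_per_strain=alleles,
        extras={"focal_family": planted_ids[0], "focal_codon": cfg.focal_codon,
                "metabolizers": sorted(metabolizers)})
    return PangenomeDataset(config=cfg, genomes=genomes, genes=genes,
                            truth=truth, phenotype=phenotype, presence=presence)


def simulate_presence_absence(config: PangenomeSimConfig
                              ) -> tuple[pd.DataFrame, SimTruth]:
    """Presence/absence truth only (no sequences): the same pan-genome design
    as :func:`simulate_pangenome` — core columns all-true, accessory columns
    Bernoulli(occupancy), planted columns equal to the metabolizer labels —
    for replicated matrix-level experiments where sequence synthesis would
    dominate runtime."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome_ids = [f"G{i + 1:02d}" for i in range(cfg.n_genomes)]
    n_met = int(round(cfg.fraction_metabolizers * cfg.n_genomes))
    metabolizers = set(rng.choice(genome_ids, size=n_met, replace=False).tolist())
    core_ids = [f"COR{k + 1:04d}" for k in range(cfg.n_core)]
    accessory_ids = [f"ACC{k + 1:04d}" for k in range(cfg.n_accessory)]
    planted_ids = [f"PLT{k + 1:03d}" for k in range(cfg.planted_cluster_size)]
    presence = pd.DataFrame(False, index=genome_ids,
                            columns=core_ids + accessory_ids + planted_ids)
    presence.loc[:, core_ids] = True
    for acc in accessory_ids:
        presence[acc] = rng.random(cfg.n_genomes) < cfg.accessory_occupancy
    for plt in planted_ids:
        presence[plt] = [g in metabolizers for g in genome_ids]
    truth = SimTruth(
        phenotype_labels={g: ("metabolizer" if g in metabolizers
                              else "non-metabolizer") for g in genome_ids},
        planted_gene_ids=planted_ids,
        extras={"metabolizers": sorted(metabolizers)})
    return presence, truth


# ---------------------------------------------------------------------------
# Traits on trees


def simulate_trait_on_tree(tree: dendropy.Tree, model: str = "brownian",
                           sigma2: float = 1.0, seed: int = 0) -> dict[str, float]:
    """A continuous trait at the tips of ``tree``.

    ``brownian``: tip values are jointly normal, mean 0, covariance
    sigma2 * V where V[i,j] is the shared root-to-tip branch length.
    ``white_noise``: independent N(0, sigma2) per tip (no phylogenetic
    signal).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    labels, V = tree_vcv(tree)
    rng = np.random.default_rng(seed)
    n = len(labels)
    if model == "brownian":
        if sigma2 == 0:
            values = np.zeros(n)
        else:
            # Cholesky with a tiny jitter guard for ultrametric ties
            L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(n))
            values = L @ rng.standard_normal(n)
    elif model == "white_noise":
        values = np.sqrt(sigma2) * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown trait model {model!r}")
    return dict(zip(labels, values.tolist()))


# ---------------------------------------------------------------------------
# Shotgun reads


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: str
    source_genome: str
    source_start: int      # 1-based on the source genome, forward strand
    strand: str


def simulate_reads(genomes: Mapping[str, str], mixture_weights: Mapping[str, float],
                   n_reads: int, read_len: int = 100, error_rate: float = 0.01,
                   seed: int = 0, indel_rate: float = 0.0
                   ) -> tuple[list[SimRead], SimTruth]:
    """Shotgun reads from a strain mixture with a substitution error model.

    Fragment starts are uniform over each selected genome; each base is
    substituted independently with probability ``error_rate``. Qualities are
    constant Q30. ``indel_rate`` inserts/deletes single bases (default 0;
    the downstream variant caller is substitution-oriented).
    """
    ids = sorted(genomes)
    w = np.array([mixture_weights[g] for g in ids], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if any(len(genomes[g]) < read_len for g in ids):
        raise ValueError("read_len exceeds the shortest genome")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, w)
    reads: list[SimRead] = []
    k = 0
    for g, c in zip(ids, counts):
        seq = genomes[g].upper()
        L = len(seq)
        starts = rng.integers(0, L - read_len + 1, size=c)
        for s in starts:
            frag = list(seq[s:s + read_len])
            errs = np.nonzero(rng.random(read_len) < error_rate)[0]
            for p in errs:
                frag[p] = str(rng.choice([b for b in "ACGT" if b != frag[p]]))
            if indel_rate > 0:
                out = []
                for ch in frag:
                    r = rng.random()
                    if r < indel_rate / 2:
                        continue                      # deletion
                    out.append(ch)
                    if r > 1 - indel_rate / 2:
                        out.append(str(rng.choice(_BASES)))  # insertion
                frag = out
            strand = "+" if rng.random() < 0.5 else "-"
            s_out = "".join(frag)
            if strand == "-":
                s_out = reverse_complement(s_out)
            reads.append(SimRead(read_id=f"read_{k:07d}", sequence=s_out,
                                 quality=Q30_CHAR * len(s_out),
                                 source_genome=g, source_start=int(s) + 1,
                                 strand=strand))
            k += 1
    truth = SimTruth(
        true_mixture_weights={g: float(x) for g, x in zip(ids, w)},
        true_depths={g: float(mixture_weights[g] * n_reads * read_len
                              / len(genomes[g])) for g in ids},
        extras={"read_counts": {g: int(c) for g, c in zip(ids, counts)},
                "n_reads": n_reads, "read_len": read_len,
                "error_rate": error_rate})
    return reads, truth


# ---------------------------------------------------------------------------
# qPCR-like cohort


def simulate_qpcr_cohort(n_individuals: int = 158,
                         mean_log10_elnmrk1: float = 4.8,
                         sd_log10_elnmrk1: float = 2.0,
                         cgr_beta_a: float = 2.0,
                         cgr_beta_b: float = 0.8,
                         detection_limit: float = 1e3,
                         repeat_probability: float = 0.44,
                         sample_noise_sd_log10: float = 0.15,
                         seed: int = 0) -> tuple[pd.DataFrame, SimTruth]:
    """Per-individual marker-gene abundance pairs with a detection limit.

    Each individual's total-population marker (elnmrk1, copies/g) is
    log-normal; the focal gene (cgr2) is elnmrk1 times a Beta(a, b) carrier
    fraction, so the true log10(cgr2/elnmrk1) ratio is <= 0 and negatively
    skewed. Individuals are repeat-sampled with ``repeat_probability`` (one
    extra sample) and per-sample multiplicative log-normal noise is applied.
    Values below ``detection_limit`` are masked to 0 (non-detected).
    """
    if detection_limit <= 0:
        raise ValueError("detection_limit must be positive")
    if not 0 <= repeat_probability <= 1:
        raise ValueError("repeat_probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    true_log_ratios = {}
    true_elnmrk1 = {}
    true_cgr2 = {}
    for i in range(n_individuals):
        ind = f"I{i + 1:04d}"
        eln = 10 ** rng.normal(mean_log10_elnmrk1, sd_log10_elnmrk1)
        frac = rng.beta(cgr_beta_a, cgr_beta_b)
        cgr = eln * frac
        true_elnmrk1[ind] = eln
        true_cgr2[ind] = cgr
        true_log_ratios[ind] = float(np.log10(frac))
        n_samples = 2 if rng.random() < repeat_probability else 1
        for s in range(n_samples):
            noise_e = 10 ** rng.normal(0.0, sample_noise_sd_log10)
            noise_c = 10 ** rng.normal(0.0, sample_noise_sd_log10)
            ev, cv = eln * noise_e, cgr * noise_c
            rows.append((ind, f"{ind}_S{s + 1}",
                         ev if ev >= detection_limit else 0.0,
                         cv if cv >= detection_limit else 0.0))
    table = pd.DataFrame(rows, columns=["individual_id", "sample_id",
                                        "elnmrk1_copies_per_g",
                                        "cgr2_copies_per_g"])
    truth = SimTruth(extras={
        "true_elnmrk1": true_elnmrk1,
        "true_cgr2": true_cgr2,
        "true_log_ratios": true_log_ratios,
        "detection_limit": detection_limit})
    return table, truth
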