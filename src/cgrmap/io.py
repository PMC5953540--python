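"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA / FASTQ (Bio.SeqIO), GFF3 (1-based inclusive coordinates), newick
(dendropy via :mod:`cgrmap.phylo`), TSV/CSV (pandas), minimal VCF, JSON.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .alignment import SequenceRecord, reverse_complement
from .pangenome import GeneRecord


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    recs = [BioSeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable, path: str | Path) -> None:
    """Write simulated reads (objects with read_id/sequence/quality)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


# ---------------------------------------------------------------------------
# GFF3 (gene features only; coordinates 1-based inclusive)


def write_gff3(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};genome={g.genome_id}"
            fh.write("\t".join([
                g.contig, "cgrmap_sim", "CDS", str(g.start), str(g.end),
                ".", g.strand, "0", attrs]) + "\n")


def read_gene_records(gff_path: str | Path, genome_fasta: str | Path,
                      protein_fasta: str | Path | None = None) -> list[GeneRecord]:
    """Build GeneRecords from a GFF3 + genome FASTA (+ optional protein FASTA).

    CDS sequences are extracted from the genome using the GFF coordinates;
    proteins come from ``protein_fasta`` when given, else by translation.
    """
    import gffutils

    genomes = read_fasta(genome_fasta)
    proteins = read_fasta(protein_fasta) if protein_fasta else {}
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True)
    genes: list[GeneRecord] = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        contig = feat.seqid
        gene_id = feat.attributes.get(
            "ID", [f"{contig}:{feat.start}-{feat.end}"])[0]
        genome_id = feat.attributes.get("genome", [contig])[0]
        if contig not in genomes:
            raise ValueError(f"GFF contig {contig!r} not in genome FASTA")
        cds = genomes[contig][feat.start - 1:feat.end]
        if feat.strand == "-":
            cds = reverse_complement(cds)
        prot = proteins.get(gene_id) or str(Seq(cds).translate()).rstrip("*")
        genes.append(GeneRecord(
            genome_id=genome_id, gene_id=gene_id,
            protein=SequenceRecord(gene_id, prot, "aa"),
            cds=SequenceRecord(gene_id, cds, "nt"),
            contig=contig, start=feat.start, end=feat.end,
            strand=feat.strand))
    return genes


# ---------------------------------------------------------------------------
# Minimal VCF (substitution calls only)


def write_vcf(calls: Sequence, reference_name: str, path: str | Path) -> None:
    """Write majority-rule variant calls as a minimal VCF 4.2 file.

    Only called substitutions are emitted; DP and AF go to INFO.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cgrmap\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,'
                 'Description="Alternative allele fraction">\n')
        fh.write(f"##contig=<ID={reference_name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if not c.called:
                continue
            fh.write(f"{reference_name}\t{c.ref_pos}\t.\t{c.ref_base}\t"
                     f"{c.alt_base}\t.\tPASS\tDP={c.depth};AF={c.alt_fraction:.4f}\n")


def write_tsv(df: pd.DataFrame, path: str | Path,
              header_comments: Mapping[str, object] | None = None,
              index: bool = False) -> None:
    """TSV with optional ``# key=value`` header comment lines naming thresholds."""
    with open(path, "w") as fh:
        if header_comments:
            for k, v in header_comments.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
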