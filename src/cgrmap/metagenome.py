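"""Marker-gene quantification and assembly-free variant calling in metagenomes.

Reads are recruited to gene references by best edit-distance placement
(both strands, edlib infix alignment) with identity/coverage filters
(default 90%/90%); unique best hits get MAPQ 60 and multi-mapped reads MAPQ
0, so the standard MAPQ >= 10 pileup filter removes ambiguous placements.
Per-position base counts feed a majority-rule caller: a variant is called
when at least one read covers the position and strictly more than 50% of
reads support one alternative base.

Gene abundance is expressed as copies per cell: gene depth divided by the
median depth of universal single-copy marker genes. Cohort-level statistics
— prevalence at a detection limit with per-individual medians over repeat
samples, the log10 ratio of a focal gene to a taxon marker, D'Agostino's
skewness test of that ratio, and Spearman association between abundances —
mirror how marker-gene surveys summarise carriage of a locus across
individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .alignment import (AA_SCORING, ScoringScheme, SequenceRecord,
                        global_align, global_identity, reverse_complement)

MAPQ_UNIQUE = 60
MAPQ_MULTI = 0


@dataclass
class ReadAlignment:
    """A read placed on a gene reference (1-based target coordinates)."""

    read_id: str
    target_id: str
    target_start: int
    strand: str
    mapq: int
    percent_identity: float
    fraction_read_aligned: float
    cigar: str = ""          # extended cigar (=/X/I/D), query oriented to target
    read_seq: str = ""       # oriented to the target's forward strand

    def __post_init__(self):
        if not 0.0 <= self.fraction_read_aligned <= 1.0:
            raise ValueError("fraction_read_aligned must be in [0, 1]")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass
class PileupColumn:
    ref_pos: int                 # 1-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys("ACGT", 0) | {"other": 0})

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class VariantCall:
    ref_pos: int
    ref_base: str
    alt_base: str | None
    depth: int
    alt_fraction: float
    called: bool
    ambiguous: bool = False


@dataclass
class SkewnessResult:
    g1: float
    z: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Read recruitment


def _cigar_stats(cigar: str):
    ident = cols = qbases = tbases = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            ident += n; qbases += n; tbases += n
        elif ch == "X":
            qbases += n; tbases += n
        elif ch == "I":
            qbases += n
        elif ch == "D":
            tbases += n
    return ident, cols, qbases, tbases


def recruit_reads(reads: Iterable, references: Mapping[str, str],
                  min_identity: float = 90.0, min_read_coverage: float = 90.0
                  ) -> tuple[list[ReadAlignment], dict[str, float]]:
    """Assign each read to its best-matching reference and compute depths.

    ``reads`` yields objects with ``read_id``/``sequence`` (or (id, seq)
    tuples). Each read goes to the placement with the lowest edit distance
    over all references and strands; ties across references or positions
    are broken toward the lowest target id and leftmost position and marked
    MAPQ 0 (multi-mapped). Reads failing the identity or read-coverage
    filter are dropped. Depth of a reference = recruited aligned bases /
    reference length.
    """
    if not references:
        raise ValueError("references must be non-empty")
    ref_ids = sorted(references)
    refs = {r: references[r].upper() for r in ref_ids}
    alignments: list[ReadAlignment] = []
    tbases_per_ref = dict.fromkeys(ref_ids, 0)
    for rd in reads:
        read_id, seq = (rd.read_id, rd.sequence) if hasattr(rd, "read_id") else rd
        seq = seq.upper()
        best = None   # (distance, target_id, start, strand, result, oriented_seq)
        n_best = 0
        for rid in ref_ids:
            for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
                res = edlib.align(oriented, refs[rid], mode="HW", task="path")
                d = res["editDistance"]
                if d < 0:
                    continue
                locs = res["locations"]
                if best is None or d < best[0]:
                    best = (d, rid, locs[0][0], strand, res, oriented)
                    n_best = len({l[0] for l in locs})
                elif d == best[0]:
                    n_best += len({l[0] for l in locs})
        if best is None:
            continue
        d, rid, start0, strand, res, oriented = best
        ident, cols, qbases, tbases = _cigar_stats(res["cigar"])
        identity = 100.0 * ident / cols if cols else 0.0
        coverage = qbases / len(seq)
        if identity < min_identity or 100.0 * coverage < min_read_coverage:
            continue
        aln = ReadAlignment(
            read_id=read_id, target_id=rid, target_start=start0 + 1,
            strand=strand, mapq=MAPQ_UNIQUE if n_best == 1 else MAPQ_MULTI,
            percent_identity=identity, fraction_read_aligned=coverage,
            cigar=res["cigar"], read_seq=oriented)
        alignments.append(aln)
        tbases_per_ref[rid] += tbases
    depths = {r: tbases_per_ref[r] / len(refs[r]) for r in ref_ids}
    return alignments, depths


# ---------------------------------------------------------------------------
# Pileup and majority-rule variant calling


def build_pileup(alignments: Sequence[ReadAlignment], reference: SequenceRecord,
                 min_mapq: int = 10) -> list[PileupColumn]:
    """Per-position base counts from alignments with MAPQ >= ``min_mapq``.

    Only alignments to ``reference.id`` contribute. Columns cover every
    reference position (1-based), including zero-depth ones.
    """
    ref_seq = reference.residues
    cols = [PileupColumn(ref_pos=i + 1, ref_base=ref_seq[i])
            for i in range(len(ref_seq))]
    for aln in alignments:
        if aln.target_id != reference.id or aln.mapq < min_mapq:
            continue
        qpos = 0
        rpos = aln.target_start - 1
        num = ""
        for ch in aln.cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "=X":
                for k in range(n):
                    if rpos + k >= len(ref_seq):
                        raise ValueError(
                            f"alignment {aln.read_id} overruns reference "
                            f"{reference.id}")
                    base = aln.read_seq[qpos + k]
                    key = base if base in "ACGT" else "other"
                    cols[rpos + k].counts[key] += 1
                qpos += n
                rpos += n
            elif ch == "I":
                qpos += n
            elif ch == "D":
                rpos += n
            else:
                raise ValueError(f"unsupported cigar op {ch!r}")
    return cols


def pileup_from_sam(sam_path: str, reference: SequenceRecord,
                    min_mapq: int = 10) -> list[PileupColumn]:
    """Pileup from a SAM file (mapped reads, aligner-assigned MAPQ)."""
    import pysam

    ref_seq = reference.residues
    cols = [PileupColumn(ref_pos=i + 1, ref_base=ref_seq[i])
            for i in range(len(ref_seq))]
    with pysam.AlignmentFile(sam_path, "r") as sam:
        for read in sam.fetch(until_eof=True):
            if (read.is_unmapped or read.mapping_quality < min_mapq
                    or read.reference_name != reference.id):
                continue
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos >= len(ref_seq):
                    raise ValueError(f"alignment {read.query_name} overruns "
                                     f"reference {reference.id}")
                base = seq[qpos].upper()
                key = base if base in "ACGT" else "other"
                cols[rpos].counts[key] += 1
    return cols


def call_variants(pileup: Sequence[PileupColumn]) -> list[VariantCall]:
    """Majority-rule substitution calls.

    A column is called when depth >= 1 and strictly more than half of the
    reads support one alternative base; a tie between two top alternative
    bases yields no call, flagged ambiguous.
    """
    calls = []
    for col in pileup:
        depth = col.depth
        alt_counts = {b: c for b, c in col.counts.items() if b != col.ref_base}
        if depth == 0 or not alt_counts:
            calls.append(VariantCall(col.ref_pos, col.ref_base, None, depth,
                                     0.0, False))
            continue
        top = max(alt_counts.values())
        top_bases = sorted(b for b, c in alt_counts.items() if c == top)
        ambiguous = len(top_bases) > 1 and top > 0
        if ambiguous:
            calls.append(VariantCall(col.ref_pos, col.ref_base, None, depth,
                                     top / depth, False, ambiguous=True))
            continue
        alt = top_bases[0]
        frac = top / depth
        called = top > 0 and frac > 0.5
        calls.append(VariantCall(col.ref_pos, col.ref_base,
                                 alt if called else (alt if top > 0 else None),
                                 depth, frac, called))
    return calls


# ---------------------------------------------------------------------------
# Allele typing from protein sequences


def type_allele(candidate: SequenceRecord, reference: SequenceRecord,
                focal_position: int = 333, window: int = 60,
                min_identity: float = 80.0,
                scoring: ScoringScheme = AA_SCORING) -> str:
    """Type the residue a candidate protein carries at a focal reference position.

    The candidate is globally aligned to the reference window
    [focal_position - window, focal_position + window] (1-based, clipped);
    candidates below ``min_identity`` percent identity (strict) are
    'unalignable'. Returns 'Y', 'N', 'other' (any other residue) or
    'unalignable' (also when a gap is aligned to the focal column).
    """
    if len(candidate) < 20:
        raise ValueError("candidate shorter than 20 aa")
    if len(reference) < focal_position + window:
        raise ValueError("reference shorter than focal_position + window")
    lo = max(1, focal_position - window)
    ref_window = SequenceRecord(reference.id + "_win",
                                reference.residues[lo - 1:focal_position + window],
                                "aa")
    aln = global_align(candidate, ref_window, scoring)
    if global_identity(aln) <= min_identity:
        return "unalignable"
    focal_offset = focal_position - lo + 1   # 1-based within window
    seen = 0
    for ca, cr in zip(aln.aligned_a, aln.aligned_b):
        if cr != "-":
            seen += 1
            if seen == focal_offset:
                if ca == "-":
                    return "unalignable"
                return ca if ca in ("Y", "N") else "other"
    raise AssertionError("focal column not reached")  # pragma: no cover


# ---------------------------------------------------------------------------
# Abundance, prevalence, ratios


def copies_per_cell(gene_depth: float,
                    universal_marker_depths: Sequence[float]) -> float | None:
    """Gene copies per cell: gene depth over the median universal-marker depth.

    Returns None (undefined) when every marker depth is zero.
    """
    if gene_depth < 0:
        raise ValueError("gene depth must be non-negative")
    med = float(np.median(np.asarray(universal_marker_depths, dtype=float)))
    if med <= 0:
        return None
    return gene_depth / med


def reconstruction_eligibility(proportional_abundance: float,
                               coverage: float) -> bool:
    """Whether a metagenome qualifies for targeted sequence reconstruction:
    proportional abundance strictly above 0.001 OR fold coverage strictly
    above 1."""
    return proportional_abundance > 0.001 or coverage > 1.0


def aggregate_individuals(table: pd.DataFrame, value_cols: Sequence[str],
                          individual_col: str = "individual_id") -> pd.DataFrame:
    """Median per individual over repeat samples, one row per individual."""
    if individual_col not in table.columns:
        raise ValueError(f"missing column {individual_col!r}")
    return (table.groupby(individual_col)[list(value_cols)]
            .median().reset_index())


def prevalence(table: pd.DataFrame, value_col: str,
               detection_limit: float | None = None,
               individual_col: str = "individual_id"
               ) -> tuple[float, pd.DataFrame]:
    """Percent of individuals in whom a gene is detected.

    Per individual the median abundance over repeat samples is used.
    With ``detection_limit`` set (qPCR mode) detection means
    median >= detection_limit; otherwise (metagenome mode) median > 0.
    """
    if table.empty:
        raise ValueError("empty cohort")
    per_ind = aggregate_individuals(table, [value_col], individual_col)
    med = per_ind[value_col]
    detected = med >= detection_limit if detection_limit is not None else med > 0
    per_ind = per_ind.assign(detected=detected)
    return 100.0 * float(detected.mean()), per_ind


def cgr_ratio(per_individual: pd.DataFrame, gene_col: str = "cgr2_copies_per_g",
              marker_col: str = "elnmrk1_copies_per_g",
              detection_limit: float | None = None) -> pd.Series:
    """log10(gene/marker) for individuals where both are quantifiable.

    Quantifiable means >= detection_limit when a limit is given (qPCR mode),
    else strictly positive (copies-per-cell mode). Individuals failing the
    filter are excluded (not NaN-filled), so ``len(result)`` is the n of the
    downstream skewness test.
    """
    g = per_individual[gene_col]
    m = per_individual[marker_col]
    if detection_limit is not None:
        keep = (g >= detection_limit) & (m >= detection_limit)
    else:
        keep = (g > 0) & (m > 0)
    ratio = np.log10(g[keep] / m[keep])
    if "individual_id" in per_individual.columns:
        ratio.index = per_individual.loc[keep, "individual_id"]
    return ratio.rename("cgr_ratio")


def dagostino_skewness(values: Sequence[float]) -> SkewnessResult:
    """D'Agostino's test of sample skewness.

    g1 = m3 / m2^(3/2) with biased central moments; the transformed statistic
    z is standard normal under the null of a symmetric (normal) population;
    two-sided p. Requires n >= 8.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("D'Agostino skewness test requires n >= 8")
    m = x.mean()
    m2 = ((x - m) ** 2).sum() / n
    m3 = ((x - m) ** 3).sum() / n
    if m2 == 0:
        raise ValueError("zero variance")
    g1 = m3 / m2 ** 1.5
    Y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3)
             / ((n - 2) * (n + 5) * (n + 7) * (n + 9)))
    W2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(math.log(math.sqrt(W2)))
    alpha = math.sqrt(2.0 / (W2 - 1.0))
    z = delta * math.asinh(Y / alpha)
    p = 2.0 * stats.norm.sf(abs(z))
    return SkewnessResult(g1=float(g1), z=float(z), p=float(p), n=n)


def abundance_association(x: Sequence[float], y: Sequence[float],
                          method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation between two abundance vectors.

    rho is computed on midranks. p-value: t-approximation, or the exact
    permutation null (all n! orderings) when ``method="exact"`` or
    ``method="auto"`` with n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired vectors of length >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    exact = method == "exact" or (method == "auto" and n <= 10)
    if not exact:
        res = stats.spearmanr(x, y)
        return rho, float(res.pvalue)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
    obs = abs(rx_c @ ry_c / denom)
    count = total = 0
    for perm in permutations(range(n)):
        r = abs(rx_c @ ry_c[list(perm)] / denom)
        count += r >= obs - 1e-12
        total += 1
    return rho, count / total
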