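"""Simplified CLIP-vs-input enrichment statistics.

Uniquely aligned CLIP reads (protein-bound RNA fragments) are compared with
a matched total-RNA input library along three axes: read share per RNA
class (RPM ratios), length-normalized coverage per annotation subcategory
(RPKM ratios), and 5-mer sequence composition of randomly sampled reads.
Every read is assigned exactly one annotation category by a fixed priority
hierarchy (mRNA exon first, intergenic last) using any-overlap on the
matching strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_PRIORITY",
    "ReadSet",
    "AnnotationIndex",
    "category_rpm_ratio",
    "category_rpkm_ratio",
    "kmer_enrichment",
]

# read-to-category priority when a read overlaps several feature types
CATEGORY_PRIORITY = (
    "mRNA_exon",
    "mRNA_intron",
    "lincRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "TES_downstream",
    "intergenic",
)

_NCRNA_BIOTYPES = {"lincRNA", "tRNA", "snRNA", "snoRNA", "miRNA"}


@dataclass
class ReadSet:
    """Aligned reads for one library (CLIP or input).

    ``reads`` has columns chrom, start, end, name, strand with 0-based
    half-open coordinates; ``sequences`` optionally maps read name -> read
    sequence for k-mer analysis.
    """

    label: str
    reads: pd.DataFrame = field(repr=False)
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        needed = {"chrom", "start", "end", "strand"}
        missing = needed - set(self.reads.columns)
        if missing:
            raise ValueError(f"read table missing columns: {sorted(missing)}")
        if (self.reads["start"] >= self.reads["end"]).any():
            raise ValueError("reads must have start < end")
        if not self.reads["strand"].isin(["+", "-"]).all():
            raise ValueError("read strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.reads)

    @classmethod
    def from_bed(cls, path, label: str, fasta=None) -> "ReadSet":
        """Load BED6 alignments; optional FASTA of read sequences by name."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        seqs = None
        if fasta is not None:
            from Bio import SeqIO

            seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        return cls(label=label, reads=df, sequences=seqs)


def _merge(intervals) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


class AnnotationIndex:
    """Strand-aware interval index of annotation categories.

    Built from a feature table (chrom, start, end, strand, category) or a
    GTF.  ``category_lengths`` holds per-category merged base counts;
    ``assign`` maps a read to the highest-priority overlapping category.
    """

    def __init__(self, features: pd.DataFrame):
        needed = {"chrom", "start", "end", "strand", "category"}
        missing = needed - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        bad = set(features["category"]) - set(CATEGORY_PRIORITY)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        self.features = features.reset_index(drop=True)
        self._trees: dict[tuple[str, str, str], IntervalTree] = {}
        for (cat, chrom, strand), grp in features.groupby(["category", "chrom", "strand"]):
            tree = IntervalTree()
            for start, end in zip(grp["start"], grp["end"]):
                tree.addi(int(start), int(end))
            self._trees[(cat, chrom, strand)] = tree
        self.category_lengths = {}
        for cat, grp in features.groupby("category"):
            total = 0
            for (_, _), sub in grp.groupby(["chrom", "strand"]):
                total += sum(e - s for s, e in _merge(zip(sub["start"], sub["end"])))
            self.category_lengths[cat] = total

    @classmethod
    def from_gtf(cls, path, tes_width: int = 500) -> "AnnotationIndex":
        """Build categories from a GTF annotation.

        Protein-coding transcripts contribute exons (mRNA_exon), the gaps
        between consecutive exons (mRNA_intron), and a fixed-width window
        immediately downstream of the transcript end site (TES_downstream,
        strand-aware, default 500 bases).  Genes of noncoding biotypes
        (lincRNA, tRNA, snRNA, snoRNA, miRNA) contribute their gene span.
        """
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
        rows = []

        def biotype(feat):
            for key in ("gene_biotype", "transcript_biotype", "gene_type", "biotype"):
                if key in feat.attributes:
                    return feat.attributes[key][0]
            return "protein_coding"

        for tx in db.features_of_type(("transcript", "mRNA")):
            bt = biotype(tx)
            if bt != "protein_coding":
                continue
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
            )
            if not exons:
                exons = [(tx.start - 1, tx.end)]
            for s, e in exons:
                rows.append((tx.seqid, s, e, tx.strand, "mRNA_exon"))
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 > e1:
                    rows.append((tx.seqid, e1, s2, tx.strand, "mRNA_intron"))
            if tx.strand == "-":
                rows.append((tx.seqid, max(0, tx.start - 1 - tes_width), tx.start - 1, "-", "TES_downstream"))
            else:
                rows.append((tx.seqid, tx.end, tx.end + tes_width, "+", "TES_downstream"))
        for gene in db.features_of_type("gene"):
            bt = biotype(gene)
            if bt in _NCRNA_BIOTYPES:
                rows.append((gene.seqid, gene.start - 1, gene.end, gene.strand, bt))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "category"]))

    def assign(self, chrom: str, start: int, end: int, strand: str) -> str:
        """Category of a read: first overlap in priority order, else intergenic."""
        for cat in CATEGORY_PRIORITY[:-1]:
            tree = self._trees.get((cat, chrom, strand))
            if tree is not None and tree.overlap(start, end):
                return cat
        return "intergenic"

    def assign_reads(self, readset: ReadSet) -> pd.Series:
        cats = [
            self.assign(c, int(s), int(e), st)
            for c, s, e, st in zip(
                readset.reads["chrom"],
                readset.reads["start"],
                readset.reads["end"],
                readset.reads["strand"],
            )
        ]
        return pd.Series(cats, index=readset.reads.index, name="category")


def _category_counts(readset: ReadSet, index: AnnotationIndex) -> pd.Series:
    cats = index.assign_reads(readset)
    counts = cats.value_counts().reindex(CATEGORY_PRIORITY, fill_value=0)
    return counts


def category_rpm_ratio(
    clip: ReadSet, input_: ReadSet, index: AnnotationIndex, eps: float = 1.0
) -> pd.DataFrame:
    """Per-category RPM in each library and the log2 CLIP/input ratio.

    RPM = category reads / total reads x 1e6 (so RPMs sum to 1e6 per
    library); the ratio uses an additive pseudocount ``eps`` (default 1
    RPM-equivalent) in numerator and denominator.
    """
    if len(clip) == 0 or len(input_) == 0:
        raise ValueError("read sets must be nonempty")
    counts_c = _category_counts(clip, index)
    counts_i = _category_counts(input_, index)
    rpm_c = counts_c / len(clip) * 1e6
    rpm_i = counts_i / len(input_) * 1e6
    log2_ratio = np.log2((rpm_c + eps) / (rpm_i + eps))
    return pd.DataFrame(
        {
            "category": CATEGORY_PRIORITY,
            "reads_clip": counts_c.to_numpy(),
            "reads_input": counts_i.to_numpy(),
            "rpm_clip": rpm_c.to_numpy(),
            "rpm_input": rpm_i.to_numpy(),
            "log2_ratio": log2_ratio.to_numpy(),
        }
    )


def category_rpkm_ratio(
    clip: ReadSet, input_: ReadSet, index: AnnotationIndex, eps: float = 0.01
) -> pd.DataFrame:
    """Per-category RPKM in each library and the log2 CLIP/input ratio.

    RPKM = reads / (category kb x total reads / 1e6); categories with zero
    annotated length (e.g. intergenic, which has no defined extent) are
    skipped with a warning.
    """
    counts_c = _category_counts(clip, index)
    counts_i = _category_counts(input_, index)
    rows = []
    for cat in CATEGORY_PRIORITY:
        length = index.category_lengths.get(cat, 0)
        if length <= 0:
            if counts_c[cat] or counts_i[cat]:
                logger.warning("category %s has zero annotated length; skipped", cat)
            continue
        kb = length / 1e3
        rpkm_c = counts_c[cat] / (kb * len(clip) / 1e6)
        rpkm_i = counts_i[cat] / (kb * len(input_) / 1e6)
        rows.append((cat, length, rpkm_c, rpkm_i, np.log2((rpkm_c + eps) / (rpkm_i + eps))))
    return pd.DataFrame(
        rows, columns=["category", "length", "rpkm_clip", "rpkm_input", "log2_ratio"]
    )


def _count_kmers(seqs: list[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total_bases = 0
    for seq in seqs:
        total_bases += len(seq)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts, total_bases


def kmer_enrichment(
    clip: ReadSet,
    input_: ReadSet,
    k: int = 5,
    n_sample: int | None = None,
    seed=None,
    eps: float = 1.0,
) -> pd.DataFrame:
    """k-mer frequency (per 1e6 bases) in sampled reads and CLIP/input ratio.

    ``n_sample`` reads are drawn without replacement from each library
    (all reads when fewer are available); overlapping k-mers are counted,
    reads shorter than k contribute none.  The ratio uses pseudocount
    ``eps`` on both frequencies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for rs in (clip, input_):
        if rs.sequences is None:
            raise ValueError(f"read set {rs.label!r} has no sequences")
    rng = np.random.default_rng(seed)

    def sample_seqs(rs: ReadSet) -> list[str]:
        names = sorted(rs.sequences)
        if n_sample is not None and n_sample < len(names):
            idx = rng.choice(len(names), size=n_sample, replace=False)
            names = [names[i] for i in sorted(idx)]
        return [rs.sequences[nm] for nm in names]

    counts_c, bases_c = _count_kmers(sample_seqs(clip), k)
    counts_i, bases_i = _count_kmers(sample_seqs(input_), k)
    if bases_c == 0 or bases_i == 0:
        raise ValueError("no sequence bases to count k-mers over")
    kmers = sorted(set(counts_c) | set(counts_i))
    freq_c = np.array([counts_c.get(km, 0) for km in kmers]) / bases_c * 1e6
    freq_i = np.array([counts_i.get(km, 0) for km in kmers]) / bases_i * 1e6
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "freq_clip": freq_c,
            "freq_input": freq_i,
            "ratio": (freq_c + eps) / (freq_i + eps),
        }
    )
    return df.sort_values("ratio", ascending=False, kind="stable").reset_index(drop=True)
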