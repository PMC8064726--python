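"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; the GFF3 (1-based
inclusive) and BED (0-based half-open) converters do all the shifting, so no
off-by-one logic leaks into the analysis modules.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_ALPHABET = set("ACGTN")
# IUPAC ambiguity codes degrade to N on load; anything else is a format error.
_AMBIGUITY_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHV"})


class FormatError(ValueError):
    """Malformed input file (bad FASTA alphabet, empty file, ...)."""


class CoordinateError(ValueError):
    """Feature coordinates inconsistent with the loaded genome."""


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass
class GenomeSequence:
    """One contig: upper-case DNA over {A,C,G,T,N}."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.contig_id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        """Strand-respecting substring of the 0-based half-open window."""
        if not (0 <= start <= end <= len(self)):
            raise CoordinateError(
                f"window [{start},{end}) outside contig {self.contig_id!r} "
                f"of length {len(self)}"
            )
        sub = self.sequence[start:end]
        return reverse_complement(sub) if strand == "-" else sub


@dataclass
class GeneFeature:
    """One annotated gene in internal (0-based half-open) coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "CDS"  # one of CDS, tRNA, rRNA, other
    product: str = ""
    start_codon: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"gene {self.gene_id!r}: invalid span [{self.start},{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T").translate(_AMBIGUITY_TO_N)
    bad = set(seq) - _VALID_ALPHABET
    if bad:
        raise FormatError(
            f"record {record_id!r}: non-nucleotide characters {sorted(bad)}"
        )
    return seq


def read_genome(path: str | os.PathLike) -> list[GenomeSequence]:
    """Load a FASTA file; lowercase folded to upper, U mapped to T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return [
        GenomeSequence(contig_id=r.id, sequence=_clean_sequence(str(r.seq), r.id))
        for r in records
    ]


def write_genome(genomes: Iterable[GenomeSequence], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.contig_id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


_FEATURE_CLASSES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _start_codon(genome: GenomeSequence, start: int, end: int, strand: str) -> str:
    if end - start < 3:
        return ""
    if strand == "+":
        return genome.subsequence(start, start + 3)
    return genome.subsequence(end - 3, end, "-")


def read_annotation(
    path: str | os.PathLike, genome: Sequence[GenomeSequence]
) -> list[GeneFeature]:
    """Parse GFF3 gene/CDS/tRNA/rRNA features into internal coordinates.

    GFF3 is 1-based inclusive; internal features are 0-based half-open.
    Product text comes from the ``product`` attribute, falling back to
    ``Name``, else empty. The start codon is read from the genome respecting
    strand. Records with strand '.' are rejected and logged; records
    exceeding contig bounds raise :class:`CoordinateError`.
    """
    contigs = {g.contig_id: g for g in genome}
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features: list[GeneFeature] = []
    seen_spans: set[tuple] = set()
    typed = [f for f in db.all_features() if f.featuretype in _FEATURE_CLASSES]
    plain_genes = [f for f in db.all_features() if f.featuretype == "gene"]
    covered = {(f.seqid, f.start, f.end) for f in typed}
    candidates = typed + [
        f for f in plain_genes if (f.seqid, f.start, f.end) not in covered
    ]
    candidates.sort(key=lambda f: (f.seqid, f.start))
    for f in candidates:
        gene_id = (
            f.attributes.get("ID", [None])[0]
            or f.attributes.get("locus_tag", [None])[0]
            or f"{f.seqid}:{f.start}-{f.end}"
        )
        if f.strand not in ("+", "-"):
            logger.warning("annotation: %s has strand %r, record skipped", gene_id, f.strand)
            continue
        contig = contigs.get(f.seqid)
        if contig is None:
            raise CoordinateError(f"gene {gene_id!r}: unknown contig {f.seqid!r}")
        start, end = f.start - 1, f.end  # GFF3 1-based inclusive -> half-open
        if not (0 <= start < end <= len(contig)):
            raise CoordinateError(
                f"gene {gene_id!r}: span [{start},{end}) exceeds contig "
                f"{f.seqid!r} of length {len(contig)}"
            )
        key = (f.seqid, start, end, f.strand)
        if key in seen_spans:
            continue
        seen_spans.add(key)
        product = (
            f.attributes.get("product", [None])[0]
            or f.attributes.get("Name", [None])[0]
            or ""
        )
        features.append(
            GeneFeature(
                gene_id=gene_id,
                contig_id=f.seqid,
                start=start,
                end=end,
                strand=f.strand,
                feature_class=_FEATURE_CLASSES.get(f.featuretype, "other"),
                product=product,
                start_codon=_start_codon(contig, start, end, f.strand),
            )
        )
    return features


def write_annotation(
    features: Iterable[GeneFeature], path: str | os.PathLike, source: str = "promomine"
) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in features:
            ftype = g.feature_class if g.feature_class in _FEATURE_CLASSES else "gene"
            product = g.product.replace(";", ",").replace("=", " ")
            attrs = f"ID={g.gene_id}"
            if product:
                attrs += f";product={product}"
            fh.write(
                f"{g.contig_id}\t{source}\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


@dataclass
class BedInterval:
    contig_id: str
    start: int
    end: int
    name: str
    score: int
    strand: str


def write_candidates_bed(candidates: Sequence, path: str | os.PathLike):
    """Write candidates as BED6 plus a companion FASTA of their sequences.

    The BED score column is the source gene's TPM rounded and capped at 1000
    (the BED format's score ceiling).
    """
    path = Path(path)
    fasta_path = path.with_suffix(".fa")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in candidates:
            score = min(1000, round(c.source_tpm))
            fh.write(
                f"{c.contig_id}\t{c.start}\t{c.end}\t{c.candidate_id}\t"
                f"{score}\t{c.strand}\n"
            )
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        for c in candidates:
            fh.write(f">{c.candidate_id}\n{c.sequence}\n")
    return path, fasta_path


def read_bed(path: str | os.PathLike) -> list[BedInterval]:
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append(
                BedInterval(
                    contig_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3],
                    score=int(parts[4]),
                    strand=parts[5],
                )
            )
    return intervals
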