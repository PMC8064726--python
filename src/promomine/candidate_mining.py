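"""Candidate promoter mining from highly transcribed genes.

The mining rules mirror a transcriptome-driven promoter screen in a small
bacterial genome:

* genes encoding tRNAs (and rRNAs, whose abundances are depletion artifacts)
  are excluded;
* genes without a recognizable Shine-Dalgarno ribosome-binding site (RBS) in
  the 20 nt upstream of their start codon are excluded;
* contiguous co-oriented genes with similar annotated functions and
  intergenic spacers < 50 nt are collapsed into one transcription unit, and
  only the most-upstream (lead) gene of the unit keeps a candidate;
* the window up to 500 bp upstream of the ORF start, strand-aware, is the
  promoter candidate.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .expression import ExpressionRecord
from .io_formats import GeneFeature, GenomeSequence

logger = logging.getLogger(__name__)

SHINE_DALGARNO = "AGGAGG"
DEFAULT_UPSTREAM_LEN = 500
DEFAULT_SPACER_MAX = 50
DEFAULT_SIMILARITY_MIN = 0.5
DEFAULT_RBS_WINDOW = 20
DEFAULT_RBS_MIN_MATCH = 4


@dataclass
class RBSHit:
    """Best ungapped Shine-Dalgarno match upstream of a start codon.

    ``offset`` is the motif start relative to the start codon (negative:
    -8 means the match begins 8 nt before the first codon base).
    """

    offset: int
    matched: str
    score: int


@dataclass
class GeneCluster:
    """A putative transcription unit of >= 2 co-oriented adjacent genes."""

    member_ids: list[str]
    strand: str
    lead_id: str


@dataclass
class PromoterCandidate:
    """A strand-aware upstream window holding a putative promoter."""

    candidate_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    source_gene: str
    source_tpm: float
    rbs_offset: Optional[int] = None


def best_ungapped_match(
    window: str, reference: str = SHINE_DALGARNO, min_match: int = 4
) -> Optional[tuple[int, str, int]]:
    """Longest contiguous substring of ``reference`` found in ``window``.

    Returns (start index in window, matched string, match length) or None if
    the longest match is shorter than ``min_match``. Ties on length go to
    the rightmost occurrence (closest to the start codon when the window
    immediately precedes it).
    """
    for length in range(len(reference), min_match - 1, -1):
        subs = {reference[j : j + length] for j in range(len(reference) - length + 1)}
        hits = [
            i
            for i in range(len(window) - length + 1)
            if window[i : i + length] in subs
        ]
        if hits:
            i = max(hits)
            return i, window[i : i + length], length
    return None


def _upstream_window(
    genome: GenomeSequence, gene: GeneFeature, window_len: int
) -> str:
    """Strand-respecting window of up to ``window_len`` nt before the start codon."""
    if gene.strand == "+":
        ws = max(0, gene.start - window_len)
        return genome.subsequence(ws, gene.start)
    we = min(len(genome), gene.end + window_len)
    return genome.subsequence(gene.end, we, "-")


def detect_rbs(
    genome: GenomeSequence,
    gene: GeneFeature,
    window_len: int = DEFAULT_RBS_WINDOW,
    min_match: int = DEFAULT_RBS_MIN_MATCH,
    reference: str = SHINE_DALGARNO,
) -> Optional[RBSHit]:
    """Scan the 20 nt before the start codon for a Shine-Dalgarno match.

    A hit needs >= ``min_match`` contiguous matches to the reference
    AGGAGG; ties are broken by the offset closest to the start codon.
    Absence of a hit is a regular outcome, not an error.
    """
    window = _upstream_window(genome, gene, window_len)
    if not window:
        return None
    best = best_ungapped_match(window, reference, min_match)
    if best is None:
        return None
    i, matched, score = best
    return RBSHit(offset=i - len(window), matched=matched, score=score)


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def function_similarity(product_a: str, product_b: str) -> float:
    """Token-set Jaccard similarity of two product descriptions.

    Lowercased, punctuation-stripped; an empty product never matches.
    """
    a = set(_TOKEN_RE.findall(product_a.lower()))
    b = set(_TOKEN_RE.findall(product_b.lower()))
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def collapse_clusters(
    features: Sequence[GeneFeature],
    spacer_max: int = DEFAULT_SPACER_MAX,
    similarity_min: float = DEFAULT_SIMILARITY_MIN,
    use_function: bool = True,
) -> tuple[list[GeneCluster], list[str]]:
    """Greedy left-to-right collapsing of adjacent genes into clusters.

    Two adjacent same-contig, same-strand genes join a cluster iff their
    spacer (next.start - prev.end) is strictly below ``spacer_max`` and
    their products' token-set Jaccard similarity reaches ``similarity_min``
    (skip the similarity test with ``use_function=False``). Every gene lands
    in exactly one cluster or in the singleton list.
    """
    order = [(f.contig_id, f.start) for f in features]
    if order != sorted(order):
        raise ValueError("features must be sorted by (contig, start)")

    clusters: list[GeneCluster] = []
    singletons: list[str] = []
    chain: list[GeneFeature] = []

    def flush() -> None:
        if len(chain) >= 2:
            lead = chain[0] if chain[0].strand == "+" else chain[-1]
            clusters.append(
                GeneCluster(
                    member_ids=[g.gene_id for g in chain],
                    strand=chain[0].strand,
                    lead_id=lead.gene_id,
                )
            )
        elif chain:
            singletons.append(chain[0].gene_id)
        chain.clear()

    for g in features:
        if chain:
            prev = chain[-1]
            joins = (
                g.contig_id == prev.contig_id
                and g.strand == prev.strand
                and g.start - prev.end < spacer_max
                and (
                    not use_function
                    or function_similarity(prev.product, g.product) >= similarity_min
                )
            )
            if not joins:
                flush()
        chain.append(g)
    flush()
    return clusters, singletons


def _candidate_id(gene_id: str) -> str:
    m = re.search(r"(\d+)$", gene_id)
    return f"P_{m.group(1)}" if m else f"P_{gene_id}"


def extract_upstream(
    genome: GenomeSequence,
    gene: GeneFeature,
    upstream_len: int = DEFAULT_UPSTREAM_LEN,
    source_tpm: float = 0.0,
) -> Optional[PromoterCandidate]:
    """Extract the strand-aware window upstream of a gene's ORF.

    Plus strand: [max(0, start - upstream_len), start), sequence as-is.
    Minus strand: [end, min(L, end + upstream_len)), reverse-complemented.
    Windows truncated at a contig edge are returned shorter with a logged
    warning; a zero-length window rejects the candidate (returns None).
    """
    if gene.strand == "+":
        start, end = max(0, gene.start - upstream_len), gene.start
    else:
        start, end = gene.end, min(len(genome), gene.end + upstream_len)
    if end - start == 0:
        logger.warning(
            "gene %s: no upstream sequence on its contig, candidate rejected",
            gene.gene_id,
        )
        return None
    if end - start < upstream_len:
        logger.warning(
            "gene %s: upstream window truncated to %d nt at the contig edge",
            gene.gene_id,
            end - start,
        )
    return PromoterCandidate(
        candidate_id=_candidate_id(gene.gene_id),
        contig_id=gene.contig_id,
        start=start,
        end=end,
        strand=gene.strand,
        sequence=genome.subsequence(start, end, gene.strand),
        source_gene=gene.gene_id,
        source_tpm=source_tpm,
    )


def select_candidates(
    genomes: Sequence[GenomeSequence] | GenomeSequence,
    features: Sequence[GeneFeature],
    expression: Sequence[ExpressionRecord] | Mapping[str, float],
    top_n: Optional[int] = 97,
    tpm_threshold: Optional[float] = None,
    upstream_len: int = DEFAULT_UPSTREAM_LEN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    similarity_min: float = DEFAULT_SIMILARITY_MIN,
    use_function: bool = True,
    rbs_window: int = DEFAULT_RBS_WINDOW,
    rbs_min_match: int = DEFAULT_RBS_MIN_MATCH,
) -> list[PromoterCandidate]:
    """Mine ranked promoter candidates from expression-ranked genes.

    Pipeline: rank genes by TPM descending; drop tRNA/rRNA genes; drop genes
    with no detectable RBS; replace cluster members with their cluster lead
    (deduplicated, the first — highest-TPM — occurrence wins); keep the top
    ``top_n`` survivors (or, with ``tpm_threshold``, all survivors strictly
    above it); extract the upstream window for each. Candidates come back in
    descending source-TPM order.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    contigs = {g.contig_id: g for g in genomes}
    if hasattr(expression, "items"):
        tpm = dict(expression.items())
    else:
        tpm = {r.gene_id: r.tpm for r in expression}

    by_id = {f.gene_id: f for f in features}
    sorted_features = sorted(features, key=lambda f: (f.contig_id, f.start))
    coding = [f for f in sorted_features if f.feature_class not in ("tRNA", "rRNA")]
    clusters, _ = collapse_clusters(
        coding, spacer_max, similarity_min, use_function=use_function
    )
    lead_of = {m: c.lead_id for c in clusters for m in c.member_ids}

    ranked = sorted(
        (f for f in features if f.gene_id in tpm),
        key=lambda f: (-tpm[f.gene_id], f.gene_id),
    )
    survivors: list[tuple[GeneFeature, float]] = []
    seen: set[str] = set()
    for gene in ranked:
        if gene.feature_class in ("tRNA", "rRNA"):
            continue
        contig = contigs[gene.contig_id]
        if detect_rbs(contig, gene, rbs_window, rbs_min_match) is None:
            continue
        rep = by_id[lead_of.get(gene.gene_id, gene.gene_id)]
        if rep.gene_id in seen:
            continue
        seen.add(rep.gene_id)
        survivors.append((rep, tpm[gene.gene_id]))

    if tpm_threshold is not None:
        survivors = [(g, t) for g, t in survivors if t > tpm_threshold]
    elif top_n is not None:
        if top_n > len(survivors):
            warnings.warn(
                f"requested top_n={top_n} but only {len(survivors)} genes "
                "survive the exclusion filters; returning all survivors",
                stacklevel=2,
            )
        survivors = survivors[:top_n]

    candidates = []
    for gene, gene_tpm in survivors:
        cand = extract_upstream(
            contigs[gene.contig_id], gene, upstream_len, source_tpm=gene_tpm
        )
        if cand is None:
            continue
        hit = detect_rbs(contigs[gene.contig_id], gene, rbs_window, rbs_min_match)
        cand.rbs_offset = hit.offset if hit else None
        candidates.append(cand)
    return candidates
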