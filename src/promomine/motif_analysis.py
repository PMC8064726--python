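"""Per-position base statistics and sigma-70 element scanning.

Candidate promoter sets are summarized as position frequency matrices
(PFMs) and scanned for the canonical sigma-70 architecture: a -35 element
(consensus TTGACA, with the TTG trinucleotide the conserved core), a
15-21 nt spacer, a -10 element (consensus TATAAT), a purine-biased
transcription start site (TSS) ~7 nt downstream of the -10 box, and a
Shine-Dalgarno AGGAG consensus in the last 20 nt before the start codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .candidate_mining import RBSHit, best_ungapped_match

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MINUS35_REF = "TTGACA"
MINUS10_REF = "TATAAT"
DEFAULT_SPACER_RANGE = (15, 21)
TSS_OFFSET_FROM_MINUS10_END = 7  # canonical sigma-70 geometry
DEFAULT_MIN_PAIR_SCORE = 6  # of the maximum 12 weighted matches
RBS_CONSENSUS = "AGGAG"


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over an aligned, equal-length sequence set.

    ``counts`` is a 4 x length array (rows A, C, G, T). N bases contribute
    0.25 to each row, so columns always sum to ``n_sequences``. The derived
    probability matrix applies the pseudocount:
    (counts + pc) / (n + 4 pc).
    """

    counts: np.ndarray
    n_sequences: int
    pseudocount: float = 0.5

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        denom = self.n_sequences + 4.0 * self.pseudocount
        return (self.counts + self.pseudocount) / denom

    def consensus(self) -> str:
        """Argmax base per column (ties resolved in A<C<G<T order)."""
        return "".join(BASES[j] for j in self.counts.argmax(axis=0))


@dataclass
class MotifHit:
    """One located element within a candidate sequence.

    ``offset`` is 0-based within the candidate; ``spacer_to_partner`` is set
    on both members of a -35/-10 pair; ``confident`` flags pairs whose score
    reaches the configured minimum.
    """

    element: str  # minus35 | minus10 | rbs | tss
    offset: int
    matched: str
    score: float
    spacer_to_partner: Optional[int] = None
    confident: bool = True


def build_pfm(
    sequences: Sequence[str], pseudocount: float = 0.5
) -> PositionFrequencyMatrix:
    """Tally per-column base counts over equal-length sequences."""
    if not sequences:
        raise ValueError("build_pfm: need at least one sequence")
    L = len(sequences[0])
    counts = np.zeros((4, L), dtype=float)
    for idx, seq in enumerate(sequences):
        if len(seq) != L:
            raise ValueError(
                f"build_pfm: sequence {idx} has length {len(seq)}, expected {L}"
            )
        for j, base in enumerate(seq.upper()):
            if base == "N":
                counts[:, j] += 0.25
            else:
                counts[_BASE_INDEX[base], j] += 1.0
    return PositionFrequencyMatrix(
        counts=counts, n_sequences=len(sequences), pseudocount=pseudocount
    )


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b p log2 p."""
    p = pfm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=0)


def scan_sigma_elements(
    candidate,
    minus35_ref: str = MINUS35_REF,
    minus10_ref: str = MINUS10_REF,
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE,
    anchor: Optional[int] = None,
    min_score: int = DEFAULT_MIN_PAIR_SCORE,
) -> list[MotifHit]:
    """Exhaustively score all -35/-10 window pairs and return the best.

    Every placement of a 6-nt -35 window and a 6-nt -10 window with spacer in
    ``spacer_range`` is scored; the top pair is returned as two hits plus a
    ``tss`` hit 7 nt downstream of the -10 element's end (when it fits the
    sequence). Ties prefer the pair whose TSS lies closest to ``anchor``
    (default: the sequence end, i.e. the ORF start), then the leftmost pair.
    """
    seq = getattr(candidate, "sequence", candidate).upper()
    L = len(seq)
    w35, w10 = len(minus35_ref), len(minus10_ref)
    smin, smax = spacer_range
    if L < w35 + smin + w10:
        logger.warning("sequence of length %d too short for a sigma-element scan", L)
        return []
    if anchor is None:
        anchor = L

    best = None  # (score, -|tss-anchor|, -i, i, spacer)
    for i in range(0, L - (w35 + smin + w10) + 1):
        for s in range(smin, smax + 1):
            j = i + w35 + s
            if j + w10 > L:
                continue
            score = 2 * sum(
                a == b for a, b in zip(seq[i : i + 3], minus35_ref[:3])
            ) + sum(a == b for a, b in zip(seq[j : j + w10], minus10_ref))
            tss_pos = j + w10 + TSS_OFFSET_FROM_MINUS10_END - 1  # 7th nt downstream
            key = (score, -abs(tss_pos - anchor), -i)
            if best is None or key > best[0]:
                best = (key, i, s)
    if best is None:
        return []
    _, i, s = best
    score = best[0][0]
    j = i + w35 + s
    confident = score >= min_score
    hits = [
        MotifHit("minus35", i, seq[i : i + w35], score, s, confident),
        MotifHit("minus10", j, seq[j : j + w10], score, s, confident),
    ]
    tss_pos = j + w10 + TSS_OFFSET_FROM_MINUS10_END - 1
    if tss_pos < L:
        hits.append(MotifHit("tss", tss_pos, seq[tss_pos], score, None, confident))
    return hits


@dataclass
class TSSBaseTable:
    frequencies: dict
    purine_fraction: float
    n: int


def tss_base_frequencies(hits: Sequence[MotifHit]) -> TSSBaseTable:
    """Base frequencies at inferred TSS positions plus the purine fraction."""
    bases = [h.matched for h in hits if h.element == "tss" and h.matched in BASES]
    if not bases:
        return TSSBaseTable(frequencies={}, purine_fraction=float("nan"), n=0)
    counts = pd.Series(bases).value_counts()
    freqs = {b: counts.get(b, 0) / len(bases) for b in BASES}
    return TSSBaseTable(
        frequencies=freqs,
        purine_fraction=freqs["A"] + freqs["G"],
        n=len(bases),
    )


def scan_rbs_consensus(
    candidates: Sequence,
    window_len: int = 20,
    motif: str = RBS_CONSENSUS,
    min_match: int = 4,
) -> tuple[list[Optional[RBSHit]], float]:
    """Best AGGAG match in the last 20 nt of each candidate.

    Candidates end at the ORF start by construction of the upstream
    extraction, so offsets are relative to the start codon. Returns the
    per-candidate hits (None where no >= ``min_match`` contiguous match
    exists) and the fraction of candidates with a hit.
    """
    hits: list[Optional[RBSHit]] = []
    for cand in candidates:
        seq = getattr(cand, "sequence", cand).upper()
        window = seq[-window_len:]
        best = best_ungapped_match(window, motif, min_match)
        if best is None:
            hits.append(None)
        else:
            i, matched, score = best
            hits.append(RBSHit(offset=i - len(window), matched=matched, score=score))
    frac = sum(h is not None for h in hits) / len(hits) if hits else 0.0
    return hits, frac


def pfm_to_frame(pfm: PositionFrequencyMatrix, probabilities: bool = False) -> pd.DataFrame:
    """PFM/PPM as a DataFrame with rows A, C, G, T (logo-tool friendly)."""
    mat = pfm.probabilities if probabilities else pfm.counts
    return pd.DataFrame(mat, index=list(BASES), columns=range(pfm.length))
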