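"""Synthetic genomes, expression tables and reporter assays with ground truth.

The generator emulates the structure a transcriptome-driven promoter screen
assumes in a small bacterial genome:

* a circular multi-gene contig organized into transcription units
  (singletons and operons with intra-operon spacers of 5-49 nt, so the
  < 50 nt clustering rule applies by construction);
* planted sigma-70 promoter cassettes (TTGACA + 15-21 nt spacer + TATAAT,
  purine-biased TSS, mutated per-position at a configurable rate) upstream
  of a subset of transcription-unit leads;
* planted Shine-Dalgarno sites (AGGAGG starting 6-10 nt before the start
  codon) on most genes;
* a heavy-tailed expression law in which planted strong units dominate the
  transcript pool, so roughly 5% of genes exceed 1000 TPM;
* logistic-growth fluorescence time courses whose per-cell reporter
  activity peaks in stationary phase (~36 h).

Every generated record carries ground-truth labels, so cluster recovery,
candidate precision/recall, consensus recovery and strength recovery can be
scored without re-deriving labels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io_formats import GeneFeature, GenomeSequence, write_annotation, write_genome

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PURINES = "AG"
MINUS35_CONSENSUS = "TTGACA"
MINUS10_CONSENSUS = "TATAAT"
RBS_CONSENSUS_FULL = "AGGAGG"

_PRODUCT_ADJ = [
    "membrane-bound", "cytoplasmic", "periplasmic", "NAD-dependent",
    "FAD-dependent", "PQQ-dependent", "putative", "zinc-binding",
]
_PRODUCT_NOUN = [
    "dehydrogenase", "oxidoreductase", "transporter", "kinase", "hydrolase",
    "reductase", "permease", "synthase", "isomerase", "ligase",
]
_TRNA_AA = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]


class PackingError(ValueError):
    """The requested genes do not fit on the requested contig."""


@dataclass
class SyntheticGenomeSpec:
    """Study conditions for the synthetic genome.

    Defaults follow the scale the pipeline is meant to exercise: 200 genes
    on a 200 kb circular contig, ~30% of transcription units being small
    operons, ~5% tRNA genes, planted promoters on ~6% of units with a
    strength law heavy-tailed enough that about 5% of genes exceed
    1000 TPM.
    """

    n_genes: int = 200
    contig_length: int = 200_000
    contig_id: str = "chr"
    operon_fraction: float = 0.3
    operon_size_range: tuple[int, int] = (2, 4)
    spacer_within_operon: tuple[int, int] = (5, 49)
    spacer_between_units: tuple[int, int] = (60, 500)
    gene_length_range: tuple[int, int] = (300, 1100)
    trna_fraction: float = 0.05
    trna_length: int = 80
    rbs_fraction: float = 0.9
    planted_promoter_fraction: float = 0.06
    promoter_mutation_rate: float = 0.1
    utr_length_range: tuple[int, int] = (20, 40)
    purine_tss_prob: float = 0.8
    strong_strength: float = 400.0
    background_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "operon_fraction", "trna_fraction", "rbs_fraction",
            "planted_promoter_fraction", "promoter_mutation_rate",
            "purine_tss_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticGenome:
    genome: GenomeSequence
    features: list[GeneFeature]
    truth: pd.DataFrame


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> tuple[str, int]:
    """Mutate each position with probability ``rate``; return (seq, matches kept)."""
    out = []
    kept = 0
    for base in motif:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
        else:
            out.append(base)
            kept += 1
    return "".join(out), kept


def _plant(seq: np.ndarray, gene_start: int, gene_end: int, strand: str,
           cassette: list[Optional[str]]) -> None:
    """Write a transcription-direction upstream cassette into the genome.

    ``cassette`` reads 5'->3' on the gene's strand and ends immediately
    before the ORF start; None positions leave the background untouched.
    """
    W = len(cassette)
    for k, base in enumerate(cassette):
        if base is None:
            continue
        if strand == "+":
            seq[gene_start - W + k] = base
        else:
            seq[gene_end + W - 1 - k] = _COMPLEMENT[base]


def generate_genome(
    spec: SyntheticGenomeSpec, out_dir: str | os.PathLike | None = None
) -> SyntheticGenome:
    """Generate a genome, annotation and ground-truth table from a spec.

    Deterministic under a fixed seed. Raises :class:`PackingError` before
    writing anything if the genes cannot fit the contig. When ``out_dir``
    is given, writes ``genome.fa``, ``annotation.gff3`` and ``truth.tsv``.
    """
    rng = np.random.default_rng(spec.seed)

    # --- unit composition -------------------------------------------------
    units: list[dict] = []  # kind, n, strand, planted
    remaining = spec.n_genes
    while remaining > 0:
        if rng.random() < spec.trna_fraction:
            kind, n = "tRNA", 1
        elif rng.random() < spec.operon_fraction and remaining >= 2:
            lo, hi = spec.operon_size_range
            n = int(min(rng.integers(lo, hi + 1), remaining))
            kind = "CDS"
        else:
            kind, n = "CDS", 1
        planted = kind == "CDS" and rng.random() < spec.planted_promoter_fraction
        units.append(
            {
                "kind": kind,
                "n": n,
                "strand": "+" if rng.random() < 0.5 else "-",
                "planted": planted,
            }
        )
        remaining -= n

    # --- layout (coordinates only; fail before generating sequence) ------
    pos = 0
    min_gap_after_prev = 0
    for unit in units:
        lo, hi = spec.spacer_between_units
        gap = int(rng.integers(lo, hi + 1))
        if unit["planted"] and gap < 90:
            gap = int(rng.integers(90, 121))  # room for the promoter cassette
        gap = max(gap, min_gap_after_prev)
        pos += gap
        coords = []
        for k in range(unit["n"]):
            if unit["kind"] == "tRNA":
                length = spec.trna_length
            else:
                glo, ghi = spec.gene_length_range
                length = int(rng.integers(glo, ghi + 1))
            coords.append((pos, pos + length))
            pos += length
            if k < unit["n"] - 1:
                slo, shi = spec.spacer_within_operon
                pos += int(rng.integers(slo, shi + 1))
        unit["coords"] = coords
        # a planted minus-strand cassette extends downstream of the unit
        min_gap_after_prev = 90 if (unit["planted"] and unit["strand"] == "-") else 0
    if pos + max(min_gap_after_prev, 100) > spec.contig_length:
        raise PackingError(
            f"{spec.n_genes} genes need ~{pos} nt but the contig is only "
            f"{spec.contig_length} nt"
        )

    # --- background sequence ---------------------------------------------
    seq = np.array(list("ACGT"), dtype="<U1")[
        rng.integers(0, 4, size=spec.contig_length)
    ]

    # --- per-unit planting and truth -------------------------------------
    features: list[GeneFeature] = []
    rows: list[dict] = []
    gene_no = 0
    for uidx, unit in enumerate(units):
        strand = unit["strand"]
        unit_id = f"u{uidx:04d}"
        coords = unit["coords"]
        lead_index = 0 if strand == "+" else len(coords) - 1

        if unit["kind"] == "tRNA":
            family = f"tRNA-{rng.choice(_TRNA_AA)}"
        else:
            family = f"{rng.choice(_PRODUCT_ADJ)} {rng.choice(_PRODUCT_NOUN)}"

        # strength law: planted quality maps monotonically to a strong mean;
        # everything else draws from a lognormal background
        quality = None
        if unit["planted"]:
            elem35, kept35 = _mutate(rng, MINUS35_CONSENSUS, spec.promoter_mutation_rate)
            elem10, kept10 = _mutate(rng, MINUS10_CONSENSUS, spec.promoter_mutation_rate)
            quality = kept35 + kept10
            strength = spec.strong_strength * (0.4 + 0.6 * quality / 12.0)
        else:
            strength = float(rng.lognormal(0.0, spec.background_sigma))

        for k, (start, end) in enumerate(coords):
            gene_no += 1
            gene_id = f"g{gene_no:04d}"
            is_lead = k == lead_index
            codon = "ATG" if rng.random() < 0.8 else "GTG"
            if strand == "+":
                seq[start : start + 3] = list(codon)
            else:
                seq[end - 3 : end] = [_COMPLEMENT[b] for b in reversed(codon)]

            planted_rbs = False
            if unit["kind"] != "tRNA":
                if (unit["planted"] and is_lead) or rng.random() < spec.rbs_fraction:
                    # AGGAGG starting 6-10 nt before the start codon
                    o = int(rng.integers(6, 11))
                    cassette: list[Optional[str]] = [None] * 12
                    cassette[12 - o : 18 - o] = list(RBS_CONSENSUS_FULL)
                    _plant(seq, start, end, strand, cassette)
                    planted_rbs = True

            if unit["kind"] == "tRNA":
                product = family
            elif len(coords) > 1:
                product = f"{family} subunit {chr(65 + k)}"
            else:
                product = f"{family}"
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    contig_id=spec.contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_class=unit["kind"],
                    product=product,
                    start_codon=codon,
                )
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "contig_id": spec.contig_id,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "feature_class": unit["kind"],
                    "length": end - start,
                    "unit_id": unit_id,
                    "is_lead": is_lead,
                    "planted_promoter": bool(unit["planted"]),
                    "planted_rbs": planted_rbs,
                    "promoter_quality": quality if unit["planted"] else np.nan,
                    "true_strength": strength,
                    "product": product,
                }
            )

        if unit["planted"]:
            lead_start, lead_end = coords[lead_index]
            u = int(rng.integers(*spec.utr_length_range))
            s = int(rng.integers(15, 22))
            W = u + s + 18
            cassette = [None] * W
            cassette[0:6] = list(elem35)
            cassette[6 + s : 12 + s] = list(elem10)
            if rng.random() < spec.purine_tss_prob:
                tss_base = str(rng.choice(list(_PURINES)))
            else:
                tss_base = str(rng.choice(list("CT")))
            cassette[18 + s - 1] = tss_base  # 7 nt downstream of the -10 end
            _plant(seq, lead_start, lead_end, strand, cassette)

    genome = GenomeSequence(
        contig_id=spec.contig_id, sequence="".join(seq), circular=True
    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "contig_id", "start", "end", "strand", "feature_class",
            "length", "unit_id", "is_lead", "planted_promoter", "planted_rbs",
            "promoter_quality", "true_strength", "product",
        ],
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome([genome], out / "genome.fa")
        write_annotation(features, out / "annotation.gff3")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    return SyntheticGenome(genome=genome, features=features, truth=truth)


def generate_expression(
    truth: pd.DataFrame,
    total_reads: float = 2_000_000,
    dispersion: float = 0.1,
    background_strength: float = 0.05,
    seed: int = 0,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Draw a gene-level count table from the truth table's strength law.

    Counts are negative-binomial with mean proportional to
    true_strength x gene length (overdispersion ``dispersion``; Poisson at
    0; exact expectations with ``noiseless=True``). A small background
    strength keeps zero-strength genes at a low but nonzero mean.
    """
    rng = np.random.default_rng(seed)
    s = truth["true_strength"].to_numpy(dtype=float) + background_strength
    L = truth["length"].to_numpy(dtype=float)
    weight = s * L
    mean = total_reads * weight / weight.sum()
    if noiseless:
        counts = mean
    elif dispersion <= 0:
        counts = rng.poisson(mean).astype(float)
    else:
        n = 1.0 / dispersion
        p = n / (n + mean)
        counts = rng.negative_binomial(n, p).astype(float)
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "count": counts,
            "effective_length": truth["length"].astype(int),
        }
    )


@dataclass
class AssaySimSpec:
    """Conditions of the simulated fluorescence assay.

    Growth is logistic (OD600 capped at ``carrying_capacity``); per-cell
    reporter activity is s * f(t) with
    f(t) = (1 - exp(-t/tau)) * exp(-delta * t): a maturation rise and a slow
    first-order decay whose closed-form peak
    t* = tau * ln((1 + delta*tau)/(delta*tau)) sits at ~35.8 h with the
    defaults, i.e. in stationary phase. Sampling every 4 h over 0-48 h.
    """

    carrying_capacity: float = 6.0
    growth_rate: float = 0.25  # 1/h
    od_init: float = 0.05
    lag_h: float = 4.0
    maturation_tau_h: float = 14.0
    decay_rate_per_h: float = 0.006
    background_per_od: float = 50.0  # autofluorescence RFU per OD unit
    noise_sigma: float = 25.0
    t_end_h: float = 48.0
    interval_h: float = 4.0
    n_replicates: int = 3
    seed: int = 0


def _od_curve(t: np.ndarray, spec: AssaySimSpec) -> np.ndarray:
    K, r, od0 = spec.carrying_capacity, spec.growth_rate, spec.od_init
    return K / (1.0 + (K / od0 - 1.0) * np.exp(-r * (t - spec.lag_h)))


def _activity_shape(t: np.ndarray, spec: AssaySimSpec) -> np.ndarray:
    return (1.0 - np.exp(-t / spec.maturation_tau_h)) * np.exp(
        -spec.decay_rate_per_h * t
    )


def true_peak_time_continuous(spec: AssaySimSpec) -> float:
    """Closed-form continuous-time peak of the per-cell activity shape."""
    dt = spec.decay_rate_per_h * spec.maturation_tau_h
    return spec.maturation_tau_h * np.log((1.0 + dt) / dt)


def generate_assay(
    strengths: Mapping[str, float],
    spec: AssaySimSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fluorescence time courses for a map construct -> strength.

    Returns (assay table, truth sidecar). The assay table has columns
    construct_id, replicate, time_h, rfu, od600; RFU includes an
    autofluorescence background proportional to OD, so control-subtracted
    relative activity recovers s * f(t). The sidecar records each
    construct's noise-free control-subtracted peak activity, its grid peak
    time and the continuous-time closed-form peak.
    """
    if spec is None:
        spec = AssaySimSpec()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_end_h + spec.interval_h / 2, spec.interval_h)
    od = _od_curve(t, spec)
    shape = _activity_shape(t, spec)
    grid_peak_idx = int(np.argmax(shape))

    assay_rows = []
    truth_rows = []
    for cid in strengths:
        s = float(strengths[cid])
        if s < 0:
            raise ValueError(f"construct {cid!r}: negative strength")
        clean_rfu = (s * shape + spec.background_per_od) * od
        for rep in range(spec.n_replicates):
            # noise scales with OD: per-cell activity noise is homoscedastic
            noise = rng.normal(0.0, spec.noise_sigma, size=t.shape) * od \
                if spec.noise_sigma > 0 else 0.0
            rfu = np.maximum(clean_rfu + noise, 0.0)
            for ti, oi, fi in zip(t, od, rfu):
                assay_rows.append(
                    {
                        "construct_id": cid,
                        "replicate": rep,
                        "time_h": ti,
                        "rfu": fi,
                        "od600": oi,
                    }
                )
        truth_rows.append(
            {
                "construct_id": cid,
                "strength": s,
                "true_peak_activity": s * shape[grid_peak_idx],
                "true_peak_time_h": t[grid_peak_idx],
                "true_peak_time_continuous_h": true_peak_time_continuous(spec),
            }
        )
    return pd.DataFrame(assay_rows), pd.DataFrame(truth_rows)
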