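"""End-to-end orchestration: expression -> mining -> motifs -> strength.

A single :class:`PipelineConfig` drives a deterministic run that writes the
candidate tables (BED/FASTA/TSV), the motif and PFM tables, the strength
table when assay data are supplied, and a machine-readable manifest (config
echo, package version, input checksums, output list).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .candidate_mining import select_candidates
from .expression import compute_tpm, read_counts_tsv, write_expression_tsv
from .io_formats import read_annotation, read_genome, write_candidates_bed
from .motif_analysis import (
    build_pfm,
    pfm_to_frame,
    scan_rbs_consensus,
    scan_sigma_elements,
    tss_base_frequencies,
)
from .strength_assay import (
    average_replicates,
    classify_gradient,
    fold_change,
    read_assay_tsv,
    strength_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    genome: str
    gff: str
    counts: str
    out_dir: str
    assay: Optional[str] = None
    control_id: Optional[str] = None
    reference_ids: list[str] = field(default_factory=list)
    top_n: Optional[int] = 97
    tpm_threshold: Optional[float] = None
    upstream_len: int = 500
    spacer_max: int = 50
    similarity_min: float = 0.5
    rbs_window: int = 20
    rbs_min_match: int = 4
    sigma_spacer_min: int = 15
    sigma_spacer_max: int = 21
    gradient_mode: str = "tertile"
    gradient_bounds: tuple[float, float] = (2000.0, 6000.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("genome", "gff", "counts"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.assay is not None and not Path(self.assay).is_file():
            raise FileNotFoundError(f"assay file not found: {self.assay}")
        if self.upstream_len <= 0:
            raise ValueError("upstream_len must be positive")
        if not 0 <= self.similarity_min <= 1:
            raise ValueError("similarity_min must be in [0, 1]")
        if self.gradient_mode not in ("tertile", "fixed"):
            raise ValueError(f"unknown gradient mode {self.gradient_mode!r}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    genome = _stage("read_genome")(read_genome)(config.genome)
    features = _stage("read_annotation")(read_annotation)(config.gff, genome)

    # expression
    counts = _stage("expression")(read_counts_tsv)(config.counts, features)
    records = _stage("expression")(compute_tpm)(counts)
    write_expression_tsv(records, out / "expression.tsv")
    outputs.append("expression.tsv")

    # candidate mining
    candidates = _stage("mining")(select_candidates)(
        genome,
        features,
        records,
        top_n=config.top_n,
        tpm_threshold=config.tpm_threshold,
        upstream_len=config.upstream_len,
        spacer_max=config.spacer_max,
        similarity_min=config.similarity_min,
        rbs_window=config.rbs_window,
        rbs_min_match=config.rbs_min_match,
    )
    bed_path, fa_path = write_candidates_bed(candidates, out / "candidates.bed")
    outputs += [bed_path.name, fa_path.name]
    cand_df = pd.DataFrame(
        {
            "candidate_id": [c.candidate_id for c in candidates],
            "source_gene": [c.source_gene for c in candidates],
            "tpm": [c.source_tpm for c in candidates],
            "contig": [c.contig_id for c in candidates],
            "start": [c.start for c in candidates],
            "end": [c.end for c in candidates],
            "strand": [c.strand for c in candidates],
            "rbs_offset": [c.rbs_offset for c in candidates],
        }
    )
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False, lineterminator="\n")
    outputs.append("candidates.tsv")

    # motif analysis
    spacer_range = (config.sigma_spacer_min, config.sigma_spacer_max)
    motif_rows = []
    all_hits = []
    for cand in candidates:
        hits = scan_sigma_elements(cand, spacer_range=spacer_range)
        all_hits.extend(hits)
        for h in hits:
            motif_rows.append(
                {
                    "candidate_id": cand.candidate_id,
                    "element": h.element,
                    "offset": h.offset,
                    "matched": h.matched,
                    "score": h.score,
                    "spacer": h.spacer_to_partner,
                    "confident": h.confident,
                }
            )
    rbs_hits, rbs_fraction = scan_rbs_consensus(candidates)
    for cand, hit in zip(candidates, rbs_hits):
        if hit is not None:
            motif_rows.append(
                {
                    "candidate_id": cand.candidate_id,
                    "element": "rbs",
                    "offset": hit.offset,
                    "matched": hit.matched,
                    "score": hit.score,
                    "spacer": None,
                    "confident": True,
                }
            )
    pd.DataFrame(motif_rows).to_csv(
        out / "motifs.tsv", sep="\t", index=False, lineterminator="\n"
    )
    outputs.append("motifs.tsv")

    summary: dict = {"n_candidates": len(candidates), "rbs_fraction": rbs_fraction}
    tss = tss_base_frequencies(all_hits)
    if tss.n:
        summary["tss_purine_fraction"] = tss.purine_fraction

    m35 = [h.matched for h in all_hits if h.element == "minus35"]
    m10 = [h.matched for h in all_hits if h.element == "minus10"]
    for name, seqs in (("minus35", m35), ("minus10", m10)):
        if seqs:
            pfm = build_pfm(seqs)
            pfm_to_frame(pfm, probabilities=True).to_csv(
                out / f"pfm_{name}.tsv", sep="\t", lineterminator="\n"
            )
            outputs.append(f"pfm_{name}.tsv")

    # strength assay (optional)
    if config.assay is not None:
        series = _stage("strength")(read_assay_tsv)(config.assay)
        by_construct: dict[str, list] = {}
        for s in series:
            by_construct.setdefault(s.construct_id, []).append(s)
        control = None
        if config.control_id is not None:
            ctrl_reps = by_construct.pop(config.control_id, None)
            if ctrl_reps is None:
                raise PipelineError(
                    f"stage 'strength' failed: control construct "
                    f"{config.control_id!r} absent from assay table"
                )
            control = ctrl_reps[0]
        profiles = [
            average_replicates(reps, control) for reps in by_construct.values()
        ]
        classify_gradient(profiles, config.gradient_mode, config.gradient_bounds)
        refs = [p for p in profiles if p.construct_id in config.reference_ids]
        for p in profiles:
            fold_change(p, refs)
        strength_table(profiles).to_csv(
            out / "strength.tsv", sep="\t", index=False, lineterminator="\n"
        )
        outputs.append("strength.tsv")

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: _sha256(path)
            for name, path in [
                ("genome", config.genome),
                ("gff", config.gff),
                ("counts", config.counts),
            ]
            + ([("assay", config.assay)] if config.assay else [])
        },
        "outputs": outputs,
        "summary": summary,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
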