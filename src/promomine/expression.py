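"""TPM normalization and transcriptional-activity ranking.

TPM (transcripts per million) normalizes a gene's read count by its length
and rescales so the table sums to 1e6:

    tpm_i = 1e6 * (count_i / len_i) / sum_j (count_j / len_j)

The ranking threshold defaults to 1000 TPM with a strict ``>`` comparison:
"highly transcribed" means strictly above the threshold, so boundary genes at
exactly 1000 fall below.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TPM_THRESHOLD = 1000.0


@dataclass
class ExpressionRecord:
    gene_id: str
    count: float
    effective_length: int
    tpm: float = 0.0


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        df = counts.copy()
    else:
        df = pd.DataFrame(
            list(counts), columns=["gene_id", "count", "effective_length"]
        )
    missing = {"gene_id", "count", "effective_length"} - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def compute_tpm(counts) -> list[ExpressionRecord]:
    """Normalize a (gene_id, count, effective_length) table to TPM.

    Input order is preserved. All-zero counts yield all-zero TPMs with a
    warning; non-positive lengths or negative counts raise ``ValueError``.
    """
    df = _as_frame(counts)
    lengths = df["effective_length"].to_numpy(dtype=float)
    cnt = df["count"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        bad = df.loc[lengths <= 0, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r}: non-positive effective length")
    if np.any(cnt < 0):
        bad = df.loc[cnt < 0, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r}: negative count")
    rate = cnt / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn("all counts are zero; TPMs set to 0", stacklevel=2)
        tpm = np.zeros_like(rate)
    else:
        tpm = 1e6 * rate / total
    return [
        ExpressionRecord(
            gene_id=str(g), count=c, effective_length=int(L), tpm=t
        )
        for g, c, L, t in zip(df["gene_id"], cnt, lengths, tpm)
    ]


def records_from_tpm(table) -> list[ExpressionRecord]:
    """Accept a table already in TPM, skipping normalization.

    The 1e6 column-sum invariant is still checked, to 1% relative tolerance,
    but violation only warns: upstream quantifiers round differently.
    """
    df = table.copy() if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    if "tpm" not in df.columns:
        raise ValueError("TPM table must have a 'tpm' column")
    total = float(df["tpm"].sum())
    if total > 0 and abs(total - 1e6) / 1e6 > 0.01:
        warnings.warn(
            f"TPM column sums to {total:.1f}, not 1e6 (rel. dev. "
            f"{abs(total - 1e6) / 1e6:.2%})",
            stacklevel=2,
        )
    counts = df["count"] if "count" in df.columns else pd.Series(0.0, index=df.index)
    lengths = (
        df["effective_length"]
        if "effective_length" in df.columns
        else pd.Series(1, index=df.index)
    )
    return [
        ExpressionRecord(
            gene_id=str(g), count=float(c), effective_length=int(L), tpm=float(t)
        )
        for g, c, L, t in zip(df["gene_id"], counts, lengths, df["tpm"])
    ]


def rank_by_tpm(
    records: Sequence[ExpressionRecord],
    threshold: float = DEFAULT_TPM_THRESHOLD,
) -> tuple[list[ExpressionRecord], list[ExpressionRecord]]:
    """Partition into (above, below) the threshold; strictly-above only.

    ``above`` is sorted by descending TPM, ties broken lexicographically by
    gene id so the ordering is fully deterministic.
    """
    above = [r for r in records if r.tpm > threshold]
    below = [r for r in records if r.tpm <= threshold]
    above.sort(key=lambda r: (-r.tpm, r.gene_id))
    return above, below


def fraction_below(
    records: Sequence[ExpressionRecord],
    threshold: float = DEFAULT_TPM_THRESHOLD,
) -> float:
    """Percentage of genes with TPM at or below the threshold."""
    if not records:
        raise ValueError("fraction_below: empty record list")
    n_below = sum(1 for r in records if r.tpm <= threshold)
    return 100.0 * n_below / len(records)


def read_counts_tsv(
    path: str | os.PathLike, features: Iterable | None = None
) -> pd.DataFrame:
    """Read a TSV with columns gene_id, count[, length].

    Missing lengths are filled from an annotation (end - start per gene).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    df = df.rename(
        columns={
            cols.get("gene_id", "gene_id"): "gene_id",
            cols.get("count", "count"): "count",
            cols.get("length", "length"): "effective_length",
            cols.get("effective_length", ""): "effective_length",
        }
    )
    if "effective_length" not in df.columns:
        if features is None:
            raise ValueError(
                f"{path}: no length column and no annotation to derive it from"
            )
        lengths = {f.gene_id: f.end - f.start for f in features}
        df["effective_length"] = df["gene_id"].map(lengths)
        if df["effective_length"].isna().any():
            bad = df.loc[df["effective_length"].isna(), "gene_id"].iloc[0]
            raise ValueError(f"gene {bad!r} absent from the annotation")
    return df[["gene_id", "count", "effective_length"]]


def write_expression_tsv(
    records: Sequence[ExpressionRecord], path: str | os.PathLike
) -> None:
    ranked = sorted(records, key=lambda r: (-r.tpm, r.gene_id))
    rank = {r.gene_id: i + 1 for i, r in enumerate(ranked)}
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "count": [r.count for r in records],
            "length": [r.effective_length for r in records],
            "tpm": [r.tpm for r in records],
            "rank": [rank[r.gene_id] for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
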