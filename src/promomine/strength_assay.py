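"""Reporter-based promoter strength from fluorescence/growth time courses.

Promoter strength is quantified with a fluorescent reporter: relative
activity at each timepoint is RFU / OD600 (per-cell fluorescence), the
promoter's relative strength is the maximum of that series over the time
course, and promoters are binned into a weak/medium/strong gradient either
by empirical tertiles or by fixed activity bounds.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FIXED_BOUNDS = (2000.0, 6000.0)
STRENGTH_CLASSES = ("weak", "medium", "strong")


@dataclass
class FluorescenceSeries:
    """One construct's fluorescence/growth time course (one replicate)."""

    construct_id: str
    timepoints: np.ndarray  # hours, strictly increasing
    rfu: np.ndarray
    od600: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if not (len(self.timepoints) == len(self.rfu) == len(self.od600)):
            raise ValueError(
                f"construct {self.construct_id!r}: time/rfu/od vectors differ in length"
            )
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError(
                f"construct {self.construct_id!r}: timepoints must strictly increase"
            )


@dataclass
class StrengthProfile:
    """A time course reduced to a relative-activity series and its peak."""

    construct_id: str
    timepoints: np.ndarray
    relative_activity: np.ndarray
    peak_activity: float = 0.0
    peak_time: float = 0.0
    strength_class: Optional[str] = None
    fold_vs_reference: dict = field(default_factory=dict)
    replicate_peaks: Optional[np.ndarray] = None
    replicate_sd: Optional[float] = None


def relative_activity(
    series: FluorescenceSeries,
    control: Optional[FluorescenceSeries] = None,
) -> StrengthProfile:
    """Per-timepoint RFU / OD600, optionally control-subtracted.

    Points with OD600 <= 0 are dropped with a warning. A control series is
    interpolated onto the sample's time grid, its activity subtracted
    pointwise and the result floored at zero.
    """
    keep = series.od600 > 0
    if not np.all(keep):
        logger.warning(
            "construct %s: dropping %d point(s) with non-positive OD600",
            series.construct_id,
            int((~keep).sum()),
        )
    if not np.any(keep):
        raise ValueError(
            f"construct {series.construct_id!r}: no timepoints with positive OD600"
        )
    t = series.timepoints[keep]
    activity = series.rfu[keep] / series.od600[keep]
    if control is not None:
        ckeep = control.od600 > 0
        cact = np.interp(
            t, control.timepoints[ckeep], control.rfu[ckeep] / control.od600[ckeep]
        )
        activity = np.maximum(activity - cact, 0.0)
    profile = StrengthProfile(
        construct_id=series.construct_id,
        timepoints=t,
        relative_activity=activity,
    )
    profile.peak_activity, profile.peak_time = peak_strength(profile)
    return profile


def peak_strength(profile: StrengthProfile) -> tuple[float, float]:
    """Maximum relative activity and the time attaining it (ties: earliest)."""
    if len(profile.relative_activity) == 0:
        raise ValueError("peak_strength: empty activity series")
    idx = int(np.argmax(profile.relative_activity))  # argmax takes the first tie
    return float(profile.relative_activity[idx]), float(profile.timepoints[idx])


def average_replicates(
    replicates: Sequence[FluorescenceSeries],
    control: Optional[FluorescenceSeries] = None,
) -> StrengthProfile:
    """Pointwise-mean profile across replicates, with per-replicate peaks.

    Replicates must share a time grid. The mean series drives peak
    detection; the per-replicate peak standard deviation is reported
    alongside (the usual mean +/- sd presentation of plate-reader assays).
    """
    if not replicates:
        raise ValueError("average_replicates: no replicate series")
    grids = {tuple(r.timepoints) for r in replicates}
    if len(grids) != 1:
        raise ValueError("replicates must share one time grid")
    profiles = [relative_activity(r, control) for r in replicates]
    t = profiles[0].timepoints
    acts = np.vstack([np.interp(t, p.timepoints, p.relative_activity) for p in profiles])
    mean_profile = StrengthProfile(
        construct_id=replicates[0].construct_id,
        timepoints=t,
        relative_activity=acts.mean(axis=0),
    )
    mean_profile.peak_activity, mean_profile.peak_time = peak_strength(mean_profile)
    peaks = np.array([p.peak_activity for p in profiles])
    mean_profile.replicate_peaks = peaks
    mean_profile.replicate_sd = float(peaks.std(ddof=1)) if len(peaks) > 1 else 0.0
    return mean_profile


def classify_gradient(
    profiles: Sequence[StrengthProfile],
    mode: str = "tertile",
    fixed_bounds: tuple[float, float] = DEFAULT_FIXED_BOUNDS,
) -> list[StrengthProfile]:
    """Assign weak/medium/strong classes by peak activity.

    ``tertile`` bins at the empirical 1/3 and 2/3 quantiles of the peak
    activities; ``fixed`` bins at the given bounds (weak < lower <= medium
    < upper <= strong). Fewer than 3 profiles in tertile mode fall back to
    fixed mode with a warning. Classification is monotone in the peak.
    """
    if not profiles:
        raise ValueError("classify_gradient: no profiles")
    if mode not in ("tertile", "fixed"):
        raise ValueError(f"unknown classification mode {mode!r}")
    if mode == "tertile" and len(profiles) < 3:
        warnings.warn(
            "tertile classification needs >= 3 profiles; falling back to fixed bounds",
            stacklevel=2,
        )
        mode = "fixed"
    peaks = np.array([p.peak_activity for p in profiles])
    if mode == "tertile":
        lower, upper = np.quantile(peaks, [1 / 3, 2 / 3])
    else:
        lower, upper = fixed_bounds
    for p in profiles:
        if p.peak_activity < lower:
            p.strength_class = "weak"
        elif p.peak_activity < upper:
            p.strength_class = "medium"
        else:
            p.strength_class = "strong"
    return list(profiles)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def fold_change(
    profile: StrengthProfile, references: Sequence[StrengthProfile]
) -> dict[str, float]:
    """Peak-activity ratio of a profile over each reference promoter.

    Ratios are stored at full precision in ``profile.fold_vs_reference``;
    callers wanting the conventional 2-significant-figure presentation use
    :func:`round_sig`. A zero reference peak yields no entry, with a warning.
    """
    ratios: dict[str, float] = {}
    for ref in references:
        if ref.peak_activity <= 0:
            warnings.warn(
                f"reference {ref.construct_id!r} has non-positive peak; "
                "fold ratio omitted",
                stacklevel=2,
            )
            continue
        ratios[ref.construct_id] = profile.peak_activity / ref.peak_activity
    profile.fold_vs_reference.update(ratios)
    return ratios


def read_assay_tsv(path: str | os.PathLike) -> list[FluorescenceSeries]:
    """Read a TSV with columns construct_id, replicate, time_h, rfu, od600."""
    df = pd.read_csv(path, sep="\t")
    required = {"construct_id", "replicate", "time_h", "rfu", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: assay table missing columns {sorted(missing)}")
    out = []
    for (cid, rep), grp in df.groupby(["construct_id", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            FluorescenceSeries(
                construct_id=str(cid),
                timepoints=grp["time_h"].to_numpy(),
                rfu=grp["rfu"].to_numpy(),
                od600=grp["od600"].to_numpy(),
                replicate=int(rep),
            )
        )
    return out


def strength_table(profiles: Sequence[StrengthProfile]) -> pd.DataFrame:
    """Summary table: one row per construct with peak, class and fold ratios."""
    ref_ids = sorted({rid for p in profiles for rid in p.fold_vs_reference})
    rows = []
    for p in profiles:
        row = {
            "construct_id": p.construct_id,
            "peak_activity": p.peak_activity,
            "peak_time_h": p.peak_time,
            "class": p.strength_class,
            "replicate_sd": p.replicate_sd,
        }
        for rid in ref_ids:
            row[f"fold_vs_{rid}"] = p.fold_vs_reference.get(rid)
        rows.append(row)
    return pd.DataFrame(rows)
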