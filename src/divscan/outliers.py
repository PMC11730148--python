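"""Percentile-tail outlier classification, cross-condition contrast, gene mapping.

Windows in the upper tail of Tajima's D are flagged as candidate balancing
selection, windows in the lower tail as candidate positive selection (sweep);
everything else is interior.  Tail cutoffs are linear-interpolation
percentiles over the valid windows of each condition, and tail membership is
closed (<= lower cutoff / >= upper cutoff).  Outlier windows are linked to
CDS annotations by coordinate overlap after extending each window by a flank
on both sides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BALANCING_TAIL = "balancing-tail"
POSITIVE_TAIL = "positive-tail"
INTERIOR = "interior"


@dataclass(frozen=True)
class TailThresholds:
    """Percentile tail bounds (defaults: lowest and highest 5%)."""

    lower_q: float = 5.0
    upper_q: float = 95.0

    def __post_init__(self) -> None:
        if not 0 < self.lower_q < self.upper_q < 100:
            raise ValueError("need 0 < lower_q < upper_q < 100")


def classify_tails(
    stats: pd.DataFrame,
    thresholds: TailThresholds = TailThresholds(),
    statistic: str = "tajima_d",
) -> pd.DataFrame:
    """Assign each valid window to a tail class by percentile cutoffs.

    Returns ``scaffold, start, <statistic>, tail_class`` plus the cutoffs in
    ``df.attrs``.  Degenerate inputs where the two cutoffs coincide (e.g.
    all-identical values) would put every window in both tails; such windows
    are assigned interior with a warning.
    """
    valid = stats[stats["valid"] & stats[statistic].notna()].copy()
    if len(valid) < 20:
        warnings.warn(
            f"only {len(valid)} valid windows; percentile cutoffs are unstable",
            stacklevel=2,
        )
    values = valid[statistic].to_numpy(dtype=float)
    lower = float(np.percentile(values, thresholds.lower_q, method="linear"))
    upper = float(np.percentile(values, thresholds.upper_q, method="linear"))

    in_lower = values <= lower
    in_upper = values >= upper
    both = in_lower & in_upper
    if both.any():
        warnings.warn(
            f"{both.sum()} windows fall in both tails (degenerate cutoffs); "
            "assigned interior",
            stacklevel=2,
        )
    tail = np.where(in_upper, BALANCING_TAIL, np.where(in_lower, POSITIVE_TAIL, INTERIOR))
    tail[both] = INTERIOR
    valid["tail_class"] = tail

    out = valid[["scaffold", "start", statistic, "tail_class"]].reset_index(drop=True)
    out.attrs["lower_cutoff"] = lower
    out.attrs["upper_cutoff"] = upper
    out.attrs["statistic"] = statistic
    out.attrs["window_size"] = stats.attrs.get("window_size")
    return out


def _tail_keys(calls: pd.DataFrame, tail: str) -> set[tuple]:
    sub = calls[calls["tail_class"] == tail]
    return set(zip(sub["scaffold"], sub["start"]))


def contrast_conditions(
    calls_control: pd.DataFrame, calls_heat: pd.DataFrame
) -> dict[str, dict[str, int]]:
    """Venn-style shared/unique counts per tail across the two conditions."""
    summary: dict[str, dict[str, int]] = {}
    for tail in (BALANCING_TAIL, POSITIVE_TAIL):
        c = _tail_keys(calls_control, tail)
        h = _tail_keys(calls_heat, tail)
        summary[tail] = {
            "n_control": len(c),
            "n_heat": len(h),
            "n_shared": len(c & h),
            "n_unique_control": len(c - h),
            "n_unique_heat": len(h - c),
            "n_union": len(c | h),
        }
    return summary


def annotate_sharing(
    calls_control: pd.DataFrame, calls_heat: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add a shared/unique column to each condition's tail calls."""
    out = []
    for own, other in (
        (calls_control, calls_heat),
        (calls_heat, calls_control),
    ):
        df = own.copy()
        sharing = np.full(len(df), "", dtype=object)
        for tail in (BALANCING_TAIL, POSITIVE_TAIL):
            other_keys = _tail_keys(other, tail)
            mask = (df["tail_class"] == tail).to_numpy()
            keys = list(zip(df["scaffold"], df["start"]))
            sharing[mask] = [
                "shared" if keys[i] in other_keys else "unique"
                for i in np.flatnonzero(mask)
            ]
        df["sharing"] = sharing
        out.append(df)
    return out[0], out[1]


def map_windows_to_genes(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    flank: int = 1000,
    window_size: int | None = None,
    larva_only: bool = False,
    proteome: pd.DataFrame | None = None,
    tails: tuple[str, ...] = (BALANCING_TAIL, POSITIVE_TAIL),
) -> pd.DataFrame:
    """Link outlier windows to CDS by overlap with the flank-extended window.

    A gene is linked to a window when its (0-based half-open) CDS interval
    overlaps ``[start - flank, start + window_size + flank)``.  Strand is
    ignored.  With ``larva_only`` the annotation is first restricted to genes
    whose protein was detected in larvae (requires ``proteome`` or an
    ``in_larva`` column on the annotation).
    """
    if window_size is None:
        window_size = calls.attrs.get("window_size")
        if window_size is None:
            raise ValueError("window_size not given and absent from calls.attrs")

    ann = annotation
    if larva_only:
        if "in_larva" not in ann.columns:
            if proteome is None:
                raise ValueError("larva_only requires proteome flags")
            ann = ann.merge(proteome[["gene_id", "in_larva"]], on="gene_id", how="left")
        ann = ann[ann["in_larva"].fillna(False).astype(bool)]

    windows = calls[calls["tail_class"].isin(tails)]
    known = set(windows["scaffold"].unique())
    orphan = sorted(set(ann["scaffold"]) - known - set(calls["scaffold"].unique()))
    if orphan:
        log.warning("annotations on scaffolds absent from stats skipped: %s", orphan[:5])

    merged = windows.merge(
        ann[["gene_id", "scaffold", "start", "end"]].rename(
            columns={"start": "gene_start", "end": "gene_end"}
        ),
        on="scaffold",
        how="inner",
    )
    lo = merged["start"] - flank
    hi = merged["start"] + window_size + flank
    hit = (merged["gene_start"] < hi) & (merged["gene_end"] > lo)
    out = merged.loc[
        hit, ["scaffold", "start", "tail_class", "gene_id", "gene_start", "gene_end"]
    ]
    return out.sort_values(["scaffold", "start", "gene_id"]).reset_index(drop=True)
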