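"""Windowed nucleotide diversity (pi) and Tajima's D over non-overlapping bins.

Statistics follow the classical definitions.  For a window with S segregating
sites among the group's non-missing calls and per-site mean pairwise
difference summed to ``pi_sum``,

    theta_W = S / a1,          a1 = sum_{i=1}^{n-1} 1/i
    D = (pi_sum - theta_W) / sqrt(e1*S + e2*S*(S-1))

with the usual a2, b1, b2, c1, c2, e1, e2 constants evaluated at the window's
effective chromosome count.  Missing genotypes are excluded site by site:
each site's pairwise-difference term uses only the chromosomes actually
called there, and the effective n for the variance constants is the median
per-site non-missing chromosome count in the window (``n_mode="full"``
instead uses twice the number of individuals everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    """Binning scheme: half-open windows [k*size, (k+1)*size) per scaffold, 0-based."""

    window_size: int = 5000
    n_mode: str = "median"  # "median" | "full"

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.n_mode not in ("median", "full"):
            raise ValueError("n_mode must be 'median' or 'full'")


@dataclass(frozen=True)
class WattersonConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=4096)
def watterson_constants(n: int) -> WattersonConstants:
    """Variance constants of Tajima's D for n sampled chromosomes (n >= 4)."""
    if n < 4:
        raise ValueError("need at least 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return WattersonConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def per_site_pi(alt_count: int, n_nonmissing_chrom: int) -> float:
    """Mean pairwise difference at one site: a*(n-a) / C(n,2)."""
    n = n_nonmissing_chrom
    if n < 2:
        raise ValueError("need at least 2 non-missing chromosomes")
    if not 0 <= alt_count <= n:
        raise ValueError("alt_count must lie in [0, n_nonmissing_chrom]")
    return alt_count * (n - alt_count) / (n * (n - 1) / 2.0)


def tajima_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from window totals; NaN when undefined (S=0 or n<4)."""
    if S == 0 or n < 4:
        return float("nan")
    k = watterson_constants(n)
    denom = np.sqrt(k.e1 * S + k.e2 * S * (S - 1))
    return float((pi_sum - S / k.a1) / denom)


def window_statistics(
    gm: GenotypeMatrix,
    spec: WindowSpec = WindowSpec(),
    group: str | None = None,
) -> pd.DataFrame:
    """Per-window S, pi and Tajima's D for one condition group.

    Returns one row per window from bin 0 to the last bin containing a site
    on each scaffold; windows without sites carry ``valid=False``.  Columns:
    ``scaffold, start, n_snps, pi_sum, pi, tajima_d, n_eff, valid``;
    ``pi`` is the per-bp value (pi_sum / window_size) and ``pi_sum`` the raw
    window total entering D.  Sites with fewer than 2 called chromosomes are
    ignored.  The returned frame records the window size in ``df.attrs``.
    """
    ac = gm.allele_counts(group)
    ws = spec.window_size

    usable = ac[ac["n_chrom"] >= 2].copy()
    poly = (usable["alt_count"] > 0) & (usable["alt_count"] < usable["n_chrom"])
    a = usable["alt_count"].to_numpy(dtype=float)
    n = usable["n_chrom"].to_numpy(dtype=float)
    usable["site_pi"] = a * (n - a) / (n * (n - 1) / 2.0)
    usable["poly"] = poly
    usable["start"] = ((usable["pos"] - 1) // ws) * ws

    grouped = usable.groupby(["scaffold", "start"], sort=True)
    stats = grouped.agg(
        n_snps=("poly", "sum"),
        pi_sum=("site_pi", "sum"),
        n_eff=("n_chrom", "median"),
    ).reset_index()
    if spec.n_mode == "full":
        n_full = 2 * (gm.n_samples if group is None else gm.sample_indices(group).size)
        stats["n_eff"] = n_full
    stats["n_eff"] = stats["n_eff"].round().astype(int)
    stats["n_snps"] = stats["n_snps"].astype(int)

    d = np.full(len(stats), np.nan)
    for n_eff in stats["n_eff"].unique():
        if n_eff < 4:
            continue
        k = watterson_constants(int(n_eff))
        rows = (stats["n_eff"] == n_eff) & (stats["n_snps"] > 0)
        S = stats.loc[rows, "n_snps"].to_numpy(dtype=float)
        pi_sum = stats.loc[rows, "pi_sum"].to_numpy()
        denom = np.sqrt(k.e1 * S + k.e2 * S * (S - 1))
        d[rows.to_numpy()] = (pi_sum - S / k.a1) / denom
    stats["tajima_d"] = d
    stats["pi"] = stats["pi_sum"] / ws
    stats["valid"] = True

    # emit empty windows (no usable sites) up to the last occupied bin
    frames = [stats]
    for scaffold, sub in stats.groupby("scaffold"):
        have = set(sub["start"])
        all_starts = np.arange(0, sub["start"].max() + ws, ws)
        gaps = [s for s in all_starts if s not in have]
        if gaps:
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": scaffold,
                        "start": gaps,
                        "n_snps": 0,
                        "pi_sum": np.nan,
                        "n_eff": 0,
                        "tajima_d": np.nan,
                        "pi": np.nan,
                        "valid": False,
                    }
                )
            )
    out = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["scaffold", "start"])
        .reset_index(drop=True)
    )
    out = out[
        ["scaffold", "start", "n_snps", "pi_sum", "pi", "tajima_d", "n_eff", "valid"]
    ]
    out.attrs["window_size"] = ws
    out.attrs["n_mode"] = spec.n_mode
    return out


def merge_conditions(
    stats_control: pd.DataFrame, stats_heat: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join per-window stats of the two conditions on (scaffold, start).

    Keeps only windows valid in both conditions; columns are suffixed
    ``_control`` / ``_heat``.  Both inputs must have been computed with the
    same window size.
    """
    ws_c = stats_control.attrs.get("window_size")
    ws_h = stats_heat.attrs.get("window_size")
    if ws_c is not None and ws_h is not None and ws_c != ws_h:
        raise ValueError(f"window sizes differ: {ws_c} vs {ws_h}")
    left = stats_control[stats_control["valid"]]
    right = stats_heat[stats_heat["valid"]]
    merged = left.merge(
        right, on=["scaffold", "start"], suffixes=("_control", "_heat"), how="inner"
    )
    merged.attrs["window_size"] = ws_c if ws_c is not None else ws_h
    return merged
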