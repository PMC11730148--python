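"""Diploid genotype matrix shared by the simulator, filters and window statistics.

Calls are coded as the number of alternate alleles carried by each diploid
individual (0, 1, 2) with ``-1`` marking a missing genotype.  Sites are
biallelic SNPs identified by (scaffold, 1-based position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: recognised condition labels, in canonical order
GROUPS = ("control", "heat")


@dataclass
class GenotypeMatrix:
    """Sites x samples matrix of diploid allele-dosage calls.

    Parameters
    ----------
    sites
        DataFrame with columns ``scaffold``, ``pos`` (1-based), ``ref``, ``alt``;
        one row per biallelic SNP.
    calls
        ``int8`` array of shape ``(n_sites, n_samples)``; entries in
        ``{0, 1, 2, -1}``.
    samples
        Ordered sample identifiers matching the columns of ``calls``.
    groups
        Mapping from sample id to condition label (``control`` / ``heat``).
    """

    sites: pd.DataFrame
    calls: np.ndarray
    samples: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D (sites x samples) array")
        if self.calls.shape[0] != len(self.sites):
            raise ValueError(
                f"{len(self.sites)} site rows but calls has {self.calls.shape[0]} rows"
            )
        if self.calls.shape[1] != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but calls has {self.calls.shape[1]} columns"
            )
        missing = [s for s in self.samples if s not in self.groups]
        if self.groups and missing:
            raise KeyError(f"samples without a group label: {missing[:5]}")

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def sample_indices(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        idx = [i for i, s in enumerate(self.samples) if self.groups.get(s) == group]
        if not idx:
            raise KeyError(f"no samples labelled {group!r}")
        return np.asarray(idx, dtype=int)

    def group_calls(self, group: str) -> np.ndarray:
        """Call sub-matrix restricted to one condition group."""
        return self.calls[:, self.sample_indices(group)]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        """New matrix with only ``sample_ids`` (order preserved as given)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            cols = [pos[s] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc}") from exc
        return GenotypeMatrix(
            sites=self.sites.reset_index(drop=True),
            calls=self.calls[:, cols].copy(),
            samples=list(sample_ids),
            groups={s: self.groups[s] for s in sample_ids},
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping the site rows where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
            samples=list(self.samples),
            groups=dict(self.groups),
        )

    def allele_counts(self, group: str | None = None) -> pd.DataFrame:
        """Per-site alt-allele count and non-missing chromosome count.

        Missing genotypes contribute neither alleles nor chromosomes, which is
        the convention downstream statistics rely on.
        """
        calls = self.calls if group is None else self.group_calls(group)
        observed = calls != MISSING
        alt = np.where(observed, calls, 0).sum(axis=1)
        n_chrom = 2 * observed.sum(axis=1)
        return pd.DataFrame(
            {
                "scaffold": self.sites["scaffold"].to_numpy(),
                "pos": self.sites["pos"].to_numpy(),
                "alt_count": alt.astype(int),
                "n_chrom": n_chrom.astype(int),
            }
        )


def read_group_map(path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"group map {path} needs columns sample_id, group")
    df.columns = ["sample_id", "group", *df.columns[2:]]
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group labels in {path}: {bad}")
    return dict(zip(df["sample_id"], df["group"]))
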