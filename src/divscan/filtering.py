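"""Site filtering: missingness (calling rate), minor allele frequency, HWE exact test.

The three filters reproduce the standard PLINK-style pre-filtering of a joint
call set: a site is dropped when its missing-genotype fraction exceeds the
calling-rate threshold, else when its minor allele frequency (over non-missing
calls, both condition groups pooled) falls below the MAF floor, else when the
two-sided Hardy-Weinberg exact p-value (pooled genotype counts) falls below
the HWE cutoff.  The order is fixed so the per-filter exclusion counts are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix, read_group_map

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Site-filter cutoffs (PLINK flag analogues: --hwe, --maf, --geno)."""

    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    max_missing_frac: float = 0.25

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class FilterReport:
    """Per-filter exclusion bookkeeping; input = survivors + sum(removed)."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_hwe: int
    n_surviving: int

    def __post_init__(self) -> None:
        removed = self.n_removed_missing + self.n_removed_maf + self.n_removed_hwe
        if self.n_input != self.n_surviving + removed:
            raise ValueError("filter report does not account for every site")

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def read_vcf(path, group_map) -> GenotypeMatrix:
    """Read a multi-sample VCF of biallelic SNP genotypes.

    ``group_map`` maps sample id to condition label (dict or TSV path).
    Multiallelic or non-SNP records are skipped with a logged count;
    half-missing diploid calls (e.g. ``./1``) are treated as missing.
    """
    from cyvcf2 import VCF

    if not isinstance(group_map, dict):
        group_map = read_group_map(group_map)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in group_map]
    if unknown:
        raise KeyError(f"samples in VCF absent from group map: {unknown[:5]}")

    rows, calls, n_skipped = [], [], 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        site_calls = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # trailing element is the phased flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                site_calls[j] = MISSING
            else:
                site_calls[j] = alleles[0] + alleles[1]
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        calls.append(site_calls)
    if n_skipped:
        log.info("skipped %d multiallelic/non-SNP records", n_skipped)

    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
    call_matrix = (
        np.vstack(calls) if calls else np.empty((0, len(samples)), dtype=np.int8)
    )
    groups = {s: group_map[s] for s in samples}
    return GenotypeMatrix(sites=sites, calls=call_matrix, samples=samples, groups=groups)


@lru_cache(maxsize=100_000)
def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test on diploid genotype counts.

    Conditions on the observed allele counts: with ``n`` diploids and minor
    allele count ``n_minor``, the heterozygote count ``h`` has conditional
    probability

        P(h) = 2**h * n! / (((n_minor - h)/2)! * h! * ((2n - n_minor - h)/2)!)
               * n_minor! * (2n - n_minor)! / (2n)!

    over heterozygote counts of the same parity as ``n_minor``.  The returned
    p-value sums P(h) over all attainable ``h`` whose probability does not
    exceed that of the observed count (the classical two-sided exact test, no
    mid-p correction).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    h_values = np.arange(n_minor % 2, n_minor + 1, 2)
    h_values = h_values[(n_minor - h_values) % 2 == 0]
    h_values = h_values[(2 * n - n_minor - h_values) >= 0]
    logp = (
        h_values * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_minor - h_values) / 2 + 1)
        - gammaln(h_values + 1)
        - gammaln((2 * n - n_minor - h_values) / 2 + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()

    obs = n_het
    p_obs = prob[h_values == obs]
    if p_obs.size == 0:  # pragma: no cover - parity guard, unreachable for valid input
        raise ValueError("observed heterozygote count has wrong parity")
    p = prob[prob <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hom_ref = (calls == 0).sum(axis=1)
    het = (calls == 1).sum(axis=1)
    hom_alt = (calls == 2).sum(axis=1)
    return hom_ref, het, hom_alt


def apply_filters(
    gm: GenotypeMatrix,
    thresholds: FilterThresholds = FilterThresholds(),
    pooled: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the three site filters in fixed order and account for every site.

    Order: calling rate, then MAF, then HWE, each computed over both condition
    groups pooled (``pooled=False`` instead requires every group to pass MAF
    and HWE individually).
    """
    if gm.n_sites == 0:
        raise ValueError("genotype matrix has no sites")

    group_sets: list[np.ndarray]
    if pooled:
        group_sets = [np.arange(gm.n_samples)]
    else:
        group_sets = [gm.sample_indices(g) for g in sorted(set(gm.groups.values()))]

    calls = gm.calls
    missing_frac = (calls == MISSING).mean(axis=1)
    fail_missing = missing_frac > thresholds.max_missing_frac

    observed = calls != MISSING
    fail_maf = np.zeros(gm.n_sites, dtype=bool)
    for cols in group_sets:
        sub = calls[:, cols]
        obs = observed[:, cols]
        n_chrom = 2 * obs.sum(axis=1)
        alt = np.where(obs, sub, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            af = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), 0.0)
        maf = np.minimum(af, 1.0 - af)
        fail_maf |= (maf < thresholds.maf_min) | (n_chrom == 0)
    fail_maf &= ~fail_missing

    fail_hwe = np.zeros(gm.n_sites, dtype=bool)
    candidates = np.flatnonzero(~fail_missing & ~fail_maf)
    for cols in group_sets:
        hom_ref, het, hom_alt = _genotype_counts(calls[:, cols])
        for i in candidates:
            if hwe_exact_test(int(hom_ref[i]), int(het[i]), int(hom_alt[i])) < thresholds.hwe_p_min:
                fail_hwe[i] = True

    keep = ~(fail_missing | fail_maf | fail_hwe)
    report = FilterReport(
        n_input=gm.n_sites,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_surviving=int(keep.sum()),
    )
    return gm.subset_sites(keep), report
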