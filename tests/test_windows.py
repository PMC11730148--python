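"""Windowed pi / Tajima's D against independent direct-formula oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from divscan import (
    WindowSpec,
    merge_conditions,
    per_site_pi,
    tajima_d,
    window_statistics,
)
from divscan.genotypes import MISSING

from conftest import make_matrix


# --- independent oracles: plain loops straight from the definitions ----------


def pi_pair_oracle(alt_count: int, n_chrom: int) -> float:
    """Mean pairwise difference by enumerating every chromosome pair."""
    chroms = [1] * alt_count + [0] * (n_chrom - alt_count)
    diffs = sum(a != b for a, b in combinations(chroms, 2))
    return diffs / math.comb(n_chrom, 2)


def tajima_oracle(alt_counts, n_chrom: int) -> tuple[float, float]:
    """(pi_sum, D) for one window of polymorphic sites, no missing data."""
    S = sum(1 for a in alt_counts if 0 < a < n_chrom)
    pi_sum = sum(pi_pair_oracle(a, n_chrom) for a in alt_counts)
    n = n_chrom
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    d = (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return pi_sum, d


def calls_for_counts(alt_counts, n_ind):
    """Deterministic diploid calls realising given per-site alt totals."""
    rows = []
    for a in alt_counts:
        row = [2] * (a // 2) + [1] * (a % 2)
        row += [0] * (n_ind - len(row))
        rows.append(row)
    return rows


# --- per-site pi --------------------------------------------------------------


def test_per_site_pi_worked_examples():
    assert per_site_pi(2, 4) == pytest.approx(4 / 6)
    assert per_site_pi(0, 10) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_per_site_pi_matches_pair_enumeration(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        n = int(rng.integers(2, 13))
        a = int(rng.integers(0, n + 1))
        assert per_site_pi(a, n) == pytest.approx(pi_pair_oracle(a, n), abs=1e-12)


def test_per_site_pi_allele_label_swap_invariant():
    for n in (4, 9, 12):
        for a in range(n + 1):
            assert per_site_pi(a, n) == pytest.approx(per_site_pi(n - a, n))


def test_per_site_pi_input_validation():
    with pytest.raises(ValueError):
        per_site_pi(1, 1)
    with pytest.raises(ValueError):
        per_site_pi(5, 4)


# --- Tajima's D ---------------------------------------------------------------


def test_all_singleton_window_pi_and_negative_d():
    """n=10 chromosomes, S=5 singletons: pi_sum = 5 * (2*9)/(10*9) = 1.0, D < 0."""
    gm = make_matrix(calls_for_counts([1] * 5, 5), groups=["control"] * 5)
    stats = window_statistics(gm, WindowSpec(), group="control")
    assert len(stats) == 1
    row = stats.iloc[0]
    assert row["pi_sum"] == pytest.approx(1.0, abs=1e-12)
    exp_pi, exp_d = tajima_oracle([1] * 5, 10)
    assert row["tajima_d"] == pytest.approx(exp_d, abs=1e-9)
    assert row["tajima_d"] < 0


def test_intermediate_frequency_window_positive_d():
    for n_ind in (4, 8):
        counts = [n_ind] * 4  # every site at 50% frequency
        gm = make_matrix(calls_for_counts(counts, n_ind), groups=["control"] * n_ind)
        stats = window_statistics(gm, WindowSpec(), group="control")
        assert stats.iloc[0]["tajima_d"] > 0


def test_monomorphic_window_valid_with_undefined_d():
    gm = make_matrix([[0, 0, 0, 0], [2, 2, 2, 2]], groups=["control"] * 4)
    stats = window_statistics(gm, WindowSpec(), group="control")
    row = stats.iloc[0]
    assert bool(row["valid"])
    assert row["n_snps"] == 0
    assert row["pi"] == 0.0
    assert math.isnan(row["tajima_d"])


def test_zero_numerator_gives_zero_d():
    a1 = sum(1.0 / i for i in range(1, 8))
    assert tajima_d(3, 3 / a1, 8) == pytest.approx(0.0, abs=1e-12)


def test_d_undefined_below_four_chromosomes():
    assert math.isnan(tajima_d(5, 1.0, 3))
    assert math.isnan(tajima_d(0, 0.0, 10))


def test_windowed_stats_match_oracle_with_varying_per_site_n():
    """Missing genotypes shrink per-site n; median n drives the constants."""
    rng = np.random.default_rng(1)
    n_ind = 8
    calls = np.array(calls_for_counts([3, 5, 2, 7, 4], n_ind), dtype=np.int8)
    calls[0, 0] = MISSING  # site 0: n = 14
    gm = make_matrix(calls, groups=["control"] * n_ind)
    stats = window_statistics(gm, WindowSpec(), group="control")
    row = stats.iloc[0]
    # median per-site n over (14,16,16,16,16) = 16
    assert row["n_eff"] == 16
    # per-site pi recomputed with each site's own n: masking the hom-alt
    # individual at site 0 leaves 1 alt allele on 14 chromosomes
    exp_pi = pi_pair_oracle(1, 14) + sum(pi_pair_oracle(a, 16) for a in (5, 2, 7, 4))
    assert row["pi_sum"] == pytest.approx(exp_pi, abs=1e-12)


def test_window_binning_and_empty_window_emission():
    """Sites at 1-based 1..5000 belong to bin 0; an interior empty bin is emitted."""
    n_ind = 4
    calls = np.tile([1, 0, 1, 0], (3, 1)).astype(np.int8)
    gm = make_matrix(calls, groups=["control"] * n_ind)
    gm.sites["pos"] = [5000, 5001, 15000]  # bins 0, 1, 2 with bin 1 occupied too
    stats = window_statistics(gm, WindowSpec(window_size=5000), group="control")
    assert list(stats["start"]) == [0, 5000, 10000]
    assert list(stats["valid"]) == [True, True, True]
    gm.sites["pos"] = [4999, 5000, 15000]
    stats = window_statistics(gm, WindowSpec(window_size=5000), group="control")
    assert list(stats["start"]) == [0, 5000, 10000]
    assert not bool(stats.loc[stats["start"] == 5000, "valid"].iloc[0])


def test_full_n_mode_uses_all_individuals():
    calls = np.array(calls_for_counts([3, 4], 8), dtype=np.int8)
    calls[:, 0] = MISSING
    gm = make_matrix(calls, groups=["control"] * 8)
    median = window_statistics(gm, WindowSpec(n_mode="median"), group="control")
    full = window_statistics(gm, WindowSpec(n_mode="full"), group="control")
    assert median.iloc[0]["n_eff"] == 14
    assert full.iloc[0]["n_eff"] == 16


# --- merge --------------------------------------------------------------------


def _stats_frame(scaffolds, starts, ws=5000):
    df = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "start": starts,
            "n_snps": 3,
            "pi_sum": 1.0,
            "pi": 1.0 / ws,
            "tajima_d": 0.5,
            "n_eff": 10,
            "valid": True,
        }
    )
    df.attrs["window_size"] = ws
    return df


def test_merge_disjoint_scaffolds_is_empty():
    a = _stats_frame(["scaffold_1"] * 3, [0, 5000, 10000])
    b = _stats_frame(["scaffold_2"] * 3, [0, 5000, 10000])
    assert len(merge_conditions(a, b)) == 0


def test_merge_identical_inputs_keeps_all_valid_windows():
    a = _stats_frame(["scaffold_1"] * 4, [0, 5000, 10000, 15000])
    a.loc[3, "valid"] = False
    merged = merge_conditions(a, a.copy())
    assert len(merged) == 3


def test_merge_rejects_mismatched_window_size():
    a = _stats_frame(["scaffold_1"], [0], ws=5000)
    b = _stats_frame(["scaffold_1"], [0], ws=2000)
    with pytest.raises(ValueError, match="window sizes differ"):
        merge_conditions(a, b)


def test_merge_covers_every_cooccupied_truth_window(default_dataset):
    ds = default_dataset
    sc = window_statistics(ds.genotypes, WindowSpec(), group="control")
    sh = window_statistics(ds.genotypes, WindowSpec(), group="heat")
    merged = merge_conditions(sc, sh)
    occupied = sc[sc["valid"]].merge(
        sh[sh["valid"]], on=["scaffold", "start"]
    )
    assert len(merged) == len(occupied)
    assert not merged.duplicated(["scaffold", "start"]).any()
    truth_keys = set(zip(ds.truth["scaffold"], ds.truth["start"]))
    assert set(zip(merged["scaffold"], merged["start"])) <= truth_keys
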