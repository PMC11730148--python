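"""Mixed-model contrast, subsampling reproducibility, survival comparison."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from divscan import (
    WindowSpec,
    lmm_contrast,
    merge_conditions,
    subsample_robustness,
    summarize_subsamples,
    survival_compare,
    window_statistics,
)


def paired_frame(yc, yh):
    n = len(yc)
    df = pd.DataFrame(
        {
            "scaffold": "scaffold_1",
            "start": np.arange(n) * 5000,
            "tajima_d_control": yc,
            "tajima_d_heat": yh,
            "pi_control": np.abs(yc),
            "pi_heat": np.abs(yh),
        }
    )
    df.attrs["window_size"] = 5000
    return df


def test_duplicated_table_gives_null_contrast():
    """Heat identical to control: no condition effect, chisq ~ 0 and p ~ 1."""
    rng = np.random.default_rng(0)
    y = rng.normal(size=100)
    res = lmm_contrast(paired_frame(y, y.copy()))
    assert res.chisq == pytest.approx(0.0, abs=1e-8)
    assert res.p_value == pytest.approx(1.0, abs=1e-6)
    assert res.df == 1


def test_exact_engine_matches_mixedlm():
    """Closed-form ML and the numerical MixedLM fit maximise the same likelihood."""
    rng = np.random.default_rng(3)
    b = rng.normal(0, 0.7, 120)
    yc = b + rng.normal(0, 1, 120)
    yh = b + 0.4 + rng.normal(0, 1, 120)
    paired = paired_frame(yc, yh)
    exact = lmm_contrast(paired, "tajima_d", engine="exact")
    numeric = lmm_contrast(paired, "tajima_d", engine="mixedlm")
    assert exact.chisq == pytest.approx(numeric.chisq, abs=1e-5)
    assert exact.loglik_full == pytest.approx(numeric.loglik_full, abs=1e-5)
    assert exact.loglik_reduced == pytest.approx(numeric.loglik_reduced, abs=1e-5)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_lrt_matches_lme4_oracle(tmp_path):
    """Independent cross-check: lme4 ML likelihood-ratio on the same long table."""
    rng = np.random.default_rng(9)
    b = rng.normal(0, 0.5, 60)
    yc = b + rng.normal(0, 1, 60)
    yh = b + 0.5 + rng.normal(0, 1, 60)
    res = lmm_contrast(paired_frame(yc, yh))

    long = pd.DataFrame(
        {
            "window": np.repeat(np.arange(60), 2),
            "condition": np.tile(["control", "heat"], 60),
            "value": np.column_stack([yc, yh]).ravel(),
        }
    )
    csv = tmp_path / "long.csv"
    long.to_csv(csv, index=False)
    script = tmp_path / "lrt.R"
    script.write_text(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        full <- lmer(value ~ condition + (1|window), data=d, REML=FALSE)
        red  <- lmer(value ~ 1 + (1|window), data=d, REML=FALSE)
        cat(sprintf("%.10f %.10f", 2*(logLik(full)-logLik(red)), logLik(full)))
        """
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    chisq_r, llf_r = (float(x) for x in out.stdout.split())
    assert res.chisq == pytest.approx(chisq_r, abs=1e-3)
    assert res.loglik_full == pytest.approx(llf_r, abs=1e-3)


def test_lrt_invariances():
    rng = np.random.default_rng(4)
    yc = rng.normal(size=80)
    yh = rng.normal(0.3, 1, 80)
    base = lmm_contrast(paired_frame(yc, yh))
    shifted = lmm_contrast(paired_frame(yc + 5.0, yh + 5.0))
    assert shifted.chisq == pytest.approx(base.chisq, abs=1e-9)
    order = np.random.default_rng(1).permutation(80)
    permuted = lmm_contrast(paired_frame(yc[order], yh[order]))
    assert permuted.chisq == pytest.approx(base.chisq, abs=1e-9)


def test_too_few_windows_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match=">= 30 paired windows"):
        lmm_contrast(paired_frame(rng.normal(size=10), rng.normal(size=10)))


def test_subsampling_is_deterministic_and_reduces_to_full(small_config):
    from divscan import simulate_dataset

    ds = simulate_dataset(small_config)
    gm = ds.genotypes
    spec = WindowSpec()

    a = subsample_robustness(gm, spec, k=6, reps=2, base_seed=17)
    b = subsample_robustness(gm, spec, k=6, reps=2, base_seed=17)
    for ra, rb in zip(a, b):
        assert ra.selected == rb.selected
        for name in ("tajima_d", "pi"):
            assert ra.contrasts[name].p_value == rb.contrasts[name].p_value

    # k = full control size reproduces the unsubsampled contrast exactly
    full = subsample_robustness(gm, spec, k=small_config.n_control, reps=1, base_seed=0)
    sc = window_statistics(gm, spec, group="control")
    sh = window_statistics(gm, spec, group="heat")
    direct = lmm_contrast(merge_conditions(sc, sh), "tajima_d")
    assert full[0].contrasts["tajima_d"].chisq == pytest.approx(direct.chisq, abs=1e-12)


def test_subsampling_k_too_large_rejected(small_config):
    from divscan import simulate_dataset

    gm = simulate_dataset(small_config).genotypes
    with pytest.raises(ValueError, match="exceeds control group size"):
        subsample_robustness(gm, WindowSpec(), k=99, reps=1)


def survival_table(props_by_condition, days=5):
    rows = []
    for cond, props in props_by_condition.items():
        for t, endpoint in enumerate(props):
            for day in range(1, days + 1):
                alive = round(200 * (1 - (1 - endpoint) * day / days))
                rows.append((f"{cond}_tank{t}", day, alive, 200, cond))
    return pd.DataFrame(rows, columns=["tank", "day", "alive", "total", "condition"])


def test_survival_identical_groups_p_one():
    tbl = survival_table({"control": [0.7, 0.7, 0.7], "heat": [0.7, 0.7, 0.7]})
    res = survival_compare(tbl)
    assert res.p_value == pytest.approx(1.0)


def test_survival_complete_separation_exact_p():
    """3 vs 3 tanks, fully separated endpoints: two-sided exact p = 2/C(6,3) = 0.1."""
    tbl = survival_table({"control": [0.70, 0.71, 0.72], "heat": [0.50, 0.51, 0.52]})
    res = survival_compare(tbl, mode="endpoint")
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.mode == "endpoint"


def test_survival_loess_constant_curve():
    tbl = survival_table({"control": [1.0, 1.0], "heat": [1.0, 1.0]})
    res = survival_compare(tbl)
    assert np.allclose(res.curves["survival_smoothed"], 1.0)


def test_survival_input_validation():
    tbl = survival_table({"control": [0.7, 0.7], "heat": [0.5, 0.5]})
    bad = tbl.copy()
    bad.loc[0, "total"] = 0
    with pytest.raises(ValueError, match="totals must be positive"):
        survival_compare(bad)
    single_tank = tbl[tbl["tank"] != "control_tank1"]
    with pytest.raises(ValueError, match="2 tanks"):
        survival_compare(single_tank)


def test_summarize_subsamples_reports_direction(small_config):
    from divscan import simulate_dataset

    ds = simulate_dataset(small_config)
    spec = WindowSpec()
    heat = window_statistics(ds.genotypes, spec, group="heat")
    shifted = heat.copy()
    shifted["tajima_d"] = shifted["tajima_d"] + 1.0
    shifted.attrs.update(heat.attrs)
    subs = subsample_robustness(
        ds.genotypes, spec, k=6, reps=5, base_seed=3, heat_stats=shifted
    )
    summary = summarize_subsamples(subs)
    assert summary["tajima_d"]["frac_direction_agree"] == 1.0
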