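"""Mixed-model group contrast, subsampling robustness, survival comparison.

The condition contrast on window statistics fits, by maximum likelihood,

    full:     value ~ condition (fixed)  + random intercept per window
    reduced:  value ~ 1                  + random intercept per window

and reports the likelihood-ratio statistic 2*(logLik_full - logLik_reduced)
against chi-square with 1 df.  ML (not REML) is required for a likelihood
ratio on a fixed effect.  The subsampling procedure repeatedly draws a
reduced control cohort to match the heat-group size, recomputes window
statistics and re-runs the contrast, giving a robustness summary across
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix
from .windows import WindowSpec, merge_conditions, window_statistics


@dataclass
class LmmContrastResult:
    """Likelihood-ratio contrast of a window statistic between conditions."""

    statistic: str
    chisq: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float
    aic_full: float
    aic_reduced: float
    n_windows: int
    converged: bool
    diagnostics: list[str] = field(default_factory=list)

    @property
    def effect_direction(self) -> int:
        """Sign of (heat mean - control mean); stored by lmm_contrast."""
        return self._direction

    _direction: int = 0


def _paired_lmm_loglik(
    y_control: np.ndarray, y_heat: np.ndarray, condition_effect: bool
) -> float:
    """Exact ML log-likelihood of the paired random-intercept model.

    With exactly two observations per window the model
    ``y = mu + beta*condition + b_window + e`` factorises through the
    per-window difference ``d = y_heat - y_control ~ N(beta, 2*sigma_e^2)``
    and sum ``s = y_heat + y_control ~ N(2*mu + beta, 4*sigma_b^2 +
    2*sigma_e^2)``, which are independent; the ML estimates are the sample
    moments subject to ``Var(s) >= Var(d)`` (i.e. ``sigma_b^2 >= 0``, the
    boundary case pooling both variances).  ``condition_effect=False`` forces
    ``beta = 0``.  The log-Jacobian of the (d, s) transform is included so the
    value is comparable with any mixed-model fitter on the original scale.
    """
    n = len(y_control)
    d = y_heat - y_control
    s = y_heat + y_control
    q_d = float(np.sum((d - d.mean()) ** 2)) if condition_effect else float(np.sum(d**2))
    q_s = float(np.sum((s - s.mean()) ** 2))
    v_d = q_d / n
    v_s = q_s / n
    if v_s < v_d:  # sigma_b^2 would be negative: boundary ML pools the variances
        v_d = v_s = (q_d + q_s) / (2.0 * n)
    # degenerate inputs (e.g. heat identical to control) get a variance floor so
    # the LRT comparison stays finite; both models then share the same floor
    floor = 1e-12
    v_d = max(v_d, floor)
    v_s = max(v_s, floor)
    ll = -(n / 2.0) * (np.log(2 * np.pi * v_d) + q_d / (n * v_d))
    ll += -(n / 2.0) * (np.log(2 * np.pi * v_s) + q_s / (n * v_s))
    return ll + n * np.log(2.0)


def _fit_mixedlm_loglik(sub: pd.DataFrame, cols: list[str]) -> tuple[float, float, list[str], bool]:
    """Numerical MixedLM route (statsmodels); slower, any design."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    n = len(sub)
    value = np.column_stack([sub[cols[0]].to_numpy(), sub[cols[1]].to_numpy()]).ravel()
    groups = np.repeat(np.arange(n), 2)
    cond = np.tile([0.0, 1.0], n)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        full = sm.MixedLM(value, np.column_stack([np.ones(2 * n), cond]), groups).fit(
            reml=False
        )
        reduced = sm.MixedLM(value, np.ones((2 * n, 1)), groups).fit(reml=False)
    diagnostics = [str(w.message) for w in caught]
    return (
        float(full.llf),
        float(reduced.llf),
        diagnostics,
        bool(full.converged and reduced.converged),
    )


def lmm_contrast(
    paired: pd.DataFrame, statistic: str = "tajima_d", engine: str = "exact"
) -> LmmContrastResult:
    """LRT for a condition effect on paired per-window statistics.

    ``paired`` is the output of :func:`divscan.windows.merge_conditions`
    (columns ``<statistic>_control`` and ``<statistic>_heat``); windows where
    either value is undefined are dropped.  ``engine="exact"`` (default) uses
    the closed-form ML fit available for this balanced paired layout;
    ``engine="mixedlm"`` fits the same two models numerically with
    statsmodels MixedLM — both maximise the identical likelihood, so the
    reported chi-square agrees between engines.
    """
    cols = [f"{statistic}_control", f"{statistic}_heat"]
    for col in cols:
        if col not in paired.columns:
            raise KeyError(f"paired table lacks column {col}")
    sub = paired.dropna(subset=cols)
    if len(sub) < 30:
        raise ValueError(f"need >= 30 paired windows, got {len(sub)}")

    diagnostics: list[str] = []
    converged = True
    if engine == "exact":
        yc = sub[cols[0]].to_numpy(dtype=float)
        yh = sub[cols[1]].to_numpy(dtype=float)
        llf_full = _paired_lmm_loglik(yc, yh, condition_effect=True)
        llf_reduced = _paired_lmm_loglik(yc, yh, condition_effect=False)
    elif engine == "mixedlm":
        llf_full, llf_reduced, diagnostics, converged = _fit_mixedlm_loglik(sub, cols)
        if not converged:
            warnings.warn(
                f"mixed-model fit did not converge for {statistic}: {diagnostics[:2]}",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    chisq = max(0.0, 2.0 * (llf_full - llf_reduced))
    p = float(sps.chi2.sf(chisq, df=1))
    # parameter counts: full = (mu, beta, sigma_b^2, sigma_e^2), reduced drops beta
    result = LmmContrastResult(
        statistic=statistic,
        chisq=float(chisq),
        df=1,
        p_value=max(p, np.nextafter(0, 1)),
        loglik_full=float(llf_full),
        loglik_reduced=float(llf_reduced),
        aic_full=float(2 * 4 - 2 * llf_full),
        aic_reduced=float(2 * 3 - 2 * llf_reduced),
        n_windows=len(sub),
        converged=converged,
        diagnostics=diagnostics,
    )
    result._direction = int(np.sign(sub[cols[1]].mean() - sub[cols[0]].mean()))
    return result


@dataclass
class SubsampleResult:
    """One subsampling iteration: chosen control individuals and contrasts."""

    iteration: int
    seed: int
    selected: list[str]
    contrasts: dict[str, LmmContrastResult]


def subsample_robustness(
    gm: GenotypeMatrix,
    spec: WindowSpec = WindowSpec(),
    k: int = 10,
    reps: int = 100,
    base_seed: int = 0,
    statistics: tuple[str, ...] = ("tajima_d", "pi"),
    heat_stats: pd.DataFrame | None = None,
) -> list[SubsampleResult]:
    """Repeatedly contrast a size-k control subsample against the heat group.

    Iteration ``r`` draws ``k`` control individuals without replacement with
    seed ``base_seed + r``, recomputes windowed statistics on the subsample
    and re-runs :func:`lmm_contrast` against the (fixed) heat-group
    statistics, so every iteration is independently reproducible.
    ``heat_stats`` may supply precomputed (possibly perturbed) heat-side
    statistics; by default they are computed from ``gm``.
    """
    control_ids = [s for s in gm.samples if gm.groups[s] == "control"]
    heat_ids = [s for s in gm.samples if gm.groups[s] == "heat"]
    if k > len(control_ids):
        raise ValueError(f"k={k} exceeds control group size {len(control_ids)}")
    if heat_stats is None:
        heat_stats = window_statistics(gm, spec, group="heat")

    results = []
    for rep in range(reps):
        seed = base_seed + rep
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(control_ids, size=k, replace=False).tolist())
        sub = gm.subset_samples(chosen + heat_ids)
        stats_c = window_statistics(sub, spec, group="control")
        paired = merge_conditions(stats_c, heat_stats)
        contrasts = {s: lmm_contrast(paired, s) for s in statistics}
        results.append(
            SubsampleResult(iteration=rep, seed=seed, selected=chosen, contrasts=contrasts)
        )
    return results


def summarize_subsamples(
    results: list[SubsampleResult], alpha: float = 0.05
) -> dict[str, dict[str, float]]:
    """Fraction of iterations significant at ``alpha`` and direction agreement."""
    summary: dict[str, dict[str, float]] = {}
    stats_names = results[0].contrasts.keys() if results else []
    for name in stats_names:
        ps = np.array([r.contrasts[name].p_value for r in results])
        dirs = np.array([r.contrasts[name].effect_direction for r in results])
        modal = int(np.sign(dirs.sum())) or 1
        summary[name] = {
            "frac_significant": float((ps < alpha).mean()),
            "frac_direction_agree": float((dirs == modal).mean()),
            "median_p": float(np.median(ps)),
        }
    return summary


@dataclass
class SurvivalComparison:
    """Loess-smoothed survival curves and a rank-sum test between conditions."""

    curves: pd.DataFrame  # condition, day, survival_smoothed
    proportions: pd.DataFrame  # tank, day, condition, proportion
    statistic: float
    p_value: float
    mode: str
    loess_span: float


def _ranksum_exact_or_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact by enumeration for small samples."""
    from .enrichment import exact_mwu_p

    n = len(x) + len(y)
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    if n <= 20:
        p = exact_mwu_p(x, y, alternative="two-sided")
        return float(u.statistic), float(p)
    return float(u.statistic), float(u.pvalue)


def survival_compare(
    table: pd.DataFrame,
    loess_span: float = 0.75,
    mode: str = "endpoint",
) -> SurvivalComparison:
    """Compare per-tank survival proportions between conditions.

    ``table`` has columns ``tank, day, alive, total, condition``.  Survival
    proportions are smoothed per condition with lowess (span recorded), and a
    two-sided Wilcoxon rank-sum test compares per-tank values between the
    conditions — the final-day proportion per tank (``mode="endpoint"``) or
    all per-day proportions pooled (``mode="per-day"``).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if mode not in ("endpoint", "per-day"):
        raise ValueError("mode must be 'endpoint' or 'per-day'")
    if (table["total"] <= 0).any():
        raise ValueError("tank totals must be positive")
    conditions = sorted(table["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    for cond in conditions:
        if table.loc[table["condition"] == cond, "tank"].nunique() < 2:
            raise ValueError(f"need >= 2 tanks per condition ({cond})")

    props = table.copy()
    props["proportion"] = props["alive"] / props["total"]

    curves = []
    for cond, sub in props.groupby("condition"):
        fitted = lowess(
            sub["proportion"], sub["day"], frac=loess_span, return_sorted=True
        )
        curve = pd.DataFrame(fitted, columns=["day", "survival_smoothed"])
        curve = curve.groupby("day", as_index=False).mean()
        curve.insert(0, "condition", cond)
        curves.append(curve)

    if mode == "endpoint":
        end = props.loc[props.groupby(["condition", "tank"])["day"].idxmax()]
        groups = [
            end.loc[end["condition"] == c, "proportion"].to_numpy() for c in conditions
        ]
    else:
        groups = [
            props.loc[props["condition"] == c, "proportion"].to_numpy()
            for c in conditions
        ]
    stat, p = _ranksum_exact_or_asymptotic(groups[0], groups[1])

    return SurvivalComparison(
        curves=pd.concat(curves, ignore_index=True),
        proportions=props[["tank", "day", "condition", "proportion"]],
        statistic=stat,
        p_value=p,
        mode=mode,
        loess_span=loess_span,
    )
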