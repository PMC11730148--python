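"""Two-condition genotype simulator with known per-window selection regimes.

The generator emulates the study design this pipeline targets: a control
cohort of 16 diploid coral larvae and a heat-treated cohort of 10, genotyped
at biallelic SNPs on scaffold-structured coordinates, analysed in 5-kb
windows.  Sites are drawn independently from a regime-specific site frequency
spectrum (SFS):

* ``neutral``    — derived-allele count ``i`` with weight 1/i (the standard
  neutral expectation),
* ``sweep``      — weight 1/i**alpha with ``alpha > 1``, skewing the spectrum
  towards rare alleles and depressing Tajima's D,
* ``balancing``  — a mixture of the neutral law with a Gaussian bump centred
  at intermediate frequency (i ~ n/2), inflating Tajima's D.

Independent sites keep the expected window statistics analytically
controllable; pedigree structure, linkage and demography are deliberately out
of scope.  Every window carries one fully-contained CDS with a gene id, GO
terms and protein-detection flags, and a truth table records the generating
regime per window per condition so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .io import write_vcf

log = logging.getLogger(__name__)

REGIMES = ("neutral", "sweep", "balancing")

#: designated GO terms planted in selected windows, per (condition, regime)
PLANTED_TERMS = {
    ("control", "sweep"): "GO:9000001",
    ("control", "balancing"): "GO:9000002",
    ("heat", "sweep"): "GO:9000003",
    ("heat", "balancing"): "GO:9000004",
}

_NAMESPACES = ("BP", "MF", "CC")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic two-condition cohort.

    Defaults mirror the emulated study: 16 control + 10 heat diploids, 5-kb
    windows, 5% of windows sweep-like and 5% balancing per condition with
    half of the selected windows shared between conditions.
    """

    n_control: int = 16
    n_heat: int = 10
    n_scaffolds: int = 20
    windows_per_scaffold: int = 25
    window_size: int = 5000
    snps_per_window: float = 40.0
    sweep_alpha: float = 3.0
    balancing_beta: float = 5.0
    frac_sweep: float = 0.05
    frac_balancing: float = 0.05
    shared_fraction: float = 0.5
    missing_rate: float = 0.05
    seed: int = 0
    # annotation layer
    go_terms_per_namespace: int = 40
    go_min_terms: int = 1
    go_max_terms: int = 3
    planted_term_prob: float = 0.9
    background_term_prob: float = 0.02
    larva_fraction: float = 0.8
    egg_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_rate >= 0.25:
            log.warning(
                "missing_rate %.2f >= 0.25: many sites will fail the default "
                "calling-rate filter",
                self.missing_rate,
            )
        if self.frac_sweep < 0 or self.frac_balancing < 0:
            raise ValueError("regime fractions must be non-negative")
        if self.frac_sweep + self.frac_balancing > 1:
            raise ValueError("frac_sweep + frac_balancing must be <= 1")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        for name in ("n_control", "n_heat"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")

    @property
    def n_windows(self) -> int:
        return self.n_scaffolds * self.windows_per_scaffold


@dataclass
class SimulatedDataset:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    annotation: pd.DataFrame  # gene_id, scaffold, start, end
    go_map: pd.DataFrame  # gene_id, go_id, namespace
    proteome: pd.DataFrame  # gene_id, in_larva, in_egg
    truth: pd.DataFrame  # scaffold, start, regime_control, regime_heat, ...
    paths: dict[str, Path] = field(default_factory=dict)


def regime_weights(regime: str, n_chrom: int, config: SimulationConfig) -> np.ndarray:
    """Probability of derived-allele count i (i = 1..n_chrom-1) under a regime."""
    if n_chrom < 4:
        raise ValueError("n_chrom must be >= 4")
    i = np.arange(1, n_chrom)
    if regime == "neutral":
        w = 1.0 / i
    elif regime == "sweep":
        w = 1.0 / i ** float(config.sweep_alpha)
    elif regime == "balancing":
        neutral = (1.0 / i) / np.sum(1.0 / i)
        bump = np.exp(-0.5 * ((i - n_chrom / 2.0) / max(1.0, n_chrom / 8.0)) ** 2)
        bump /= bump.sum()
        w = neutral + config.balancing_beta * bump
    else:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    return w / w.sum()


def sample_site_frequencies(
    regime: str,
    n_chrom: int,
    n_sites: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw derived-allele counts in [1, n_chrom-1] for independent sites."""
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if n_sites == 0:
        return np.empty(0, dtype=int)
    w = regime_weights(regime, n_chrom, config)
    return rng.choice(np.arange(1, n_chrom), size=n_sites, p=w)


def genotypes_from_frequencies(
    counts: np.ndarray,
    n_individuals: int,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scatter per-site derived alleles onto diploid individuals.

    For each site the derived alleles are placed on chromosomes uniformly at
    random without replacement, consecutive chromosome pairs form diploids,
    and genotypes are then masked missing independently with probability
    ``missing_rate``.  Returns an ``(n_sites, n_individuals)`` int8 array.
    """
    counts = np.asarray(counts, dtype=int)
    n_chrom = 2 * n_individuals
    if counts.size and (counts.min() < 0 or counts.max() > n_chrom - 1):
        raise ValueError("derived-allele counts must lie in [0, 2*n_individuals - 1]")
    n_sites = counts.size
    # rank of iid uniforms gives a uniform random permutation per site
    order = np.argsort(rng.random((n_sites, n_chrom)), axis=1)
    chrom = order < counts[:, None]
    calls = (chrom[:, ::2].astype(np.int8) + chrom[:, 1::2].astype(np.int8))
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    return calls


def _assign_regimes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pick per-window regimes for both conditions.

    ``shared_fraction`` of each condition's selected windows is common to both
    conditions; the remainder is condition-unique.  Window pools for the four
    unique categories are disjoint, so each window has exactly one regime per
    condition (a window selected only in one condition is neutral in the
    other).
    """
    n_w = config.n_windows
    n_sweep = int(round(config.frac_sweep * n_w))
    n_bal = int(round(config.frac_balancing * n_w))
    n_sweep_shared = int(round(config.shared_fraction * n_sweep))
    n_bal_shared = int(round(config.shared_fraction * n_bal))

    need = 2 * (n_sweep - n_sweep_shared) + 2 * (n_bal - n_bal_shared)
    need += n_sweep_shared + n_bal_shared
    if need > n_w:
        raise ValueError("regime fractions leave no room for unique windows")

    pool = rng.permutation(n_w)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    shared_sweep = take(n_sweep_shared)
    shared_bal = take(n_bal_shared)
    ctrl_sweep = np.concatenate([shared_sweep, take(n_sweep - n_sweep_shared)])
    heat_sweep = np.concatenate([shared_sweep, take(n_sweep - n_sweep_shared)])
    ctrl_bal = np.concatenate([shared_bal, take(n_bal - n_bal_shared)])
    heat_bal = np.concatenate([shared_bal, take(n_bal - n_bal_shared)])

    regime_control = np.full(n_w, "neutral", dtype=object)
    regime_heat = np.full(n_w, "neutral", dtype=object)
    regime_control[ctrl_sweep] = "sweep"
    regime_control[ctrl_bal] = "balancing"
    regime_heat[heat_sweep] = "sweep"
    regime_heat[heat_bal] = "balancing"

    scaffold = [
        f"scaffold_{s + 1}"
        for s in range(config.n_scaffolds)
        for _ in range(config.windows_per_scaffold)
    ]
    start = [
        w * config.window_size
        for _ in range(config.n_scaffolds)
        for w in range(config.windows_per_scaffold)
    ]
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "start": start,
            "regime_control": regime_control,
            "regime_heat": regime_heat,
            "sweep_alpha": config.sweep_alpha,
            "balancing_beta": config.balancing_beta,
        }
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the combined-cohort genotype matrix, annotations and truth."""
    rng = np.random.default_rng(config.seed)
    truth = _assign_regimes(config, rng)

    n_chrom_c = 2 * config.n_control
    n_chrom_h = 2 * config.n_heat

    site_rows = []
    counts_c: list[np.ndarray] = []
    counts_h: list[np.ndarray] = []
    for win in truth.itertuples(index=False):
        m = rng.poisson(config.snps_per_window)
        m = min(m, config.window_size)  # positions are distinct within the window
        offsets = np.sort(
            rng.choice(config.window_size, size=m, replace=False)
        )
        cc = sample_site_frequencies(win.regime_control, n_chrom_c, m, config, rng)
        ch = sample_site_frequencies(win.regime_heat, n_chrom_h, m, config, rng)
        counts_c.append(cc)
        counts_h.append(ch)
        for off in offsets:
            site_rows.append((win.scaffold, win.start + int(off) + 1))

    sites = pd.DataFrame(site_rows, columns=["scaffold", "pos"])
    n_sites = len(sites)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[alt_idx]

    cc_all = np.concatenate(counts_c) if counts_c else np.empty(0, dtype=int)
    ch_all = np.concatenate(counts_h) if counts_h else np.empty(0, dtype=int)
    calls_c = genotypes_from_frequencies(cc_all, config.n_control, config.missing_rate, rng)
    calls_h = genotypes_from_frequencies(ch_all, config.n_heat, config.missing_rate, rng)
    calls = np.hstack([calls_c, calls_h])

    samples = [f"control_{i + 1:02d}" for i in range(config.n_control)]
    samples += [f"heat_{i + 1:02d}" for i in range(config.n_heat)]
    groups = {s: ("control" if s.startswith("control") else "heat") for s in samples}
    gm = GenotypeMatrix(sites=sites, calls=calls, samples=samples, groups=groups)

    annotation, go_map, proteome = _annotate(truth, config, rng)
    return SimulatedDataset(
        config=config,
        genotypes=gm,
        annotation=annotation,
        go_map=go_map,
        proteome=proteome,
        truth=truth,
    )


def _annotate(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One CDS per window, GO terms with planted selection-linked terms, proteome flags."""
    vocab = {
        ns: [f"GO:{1000000 * (k + 1) + j:07d}" for j in range(config.go_terms_per_namespace)]
        for k, ns in enumerate(_NAMESPACES)
    }
    flat_vocab = [(term, ns) for ns in _NAMESPACES for term in vocab[ns]]

    ann_rows, go_rows, prot_rows = [], [], []
    margin = config.window_size // 5
    for i, win in enumerate(truth.itertuples(index=False)):
        gene = f"gene_{i + 1:04d}"
        ann_rows.append(
            (gene, win.scaffold, win.start + margin, win.start + config.window_size - margin)
        )
        terms: set[tuple[str, str]] = set()
        for cond, regime in (("control", win.regime_control), ("heat", win.regime_heat)):
            for key, planted in PLANTED_TERMS.items():
                if key[0] != cond:
                    continue
                prob = (
                    config.planted_term_prob
                    if regime == key[1]
                    else config.background_term_prob
                )
                if rng.random() < prob:
                    terms.add((planted, "BP"))
        n_extra = rng.integers(config.go_min_terms, config.go_max_terms + 1)
        for j in rng.choice(len(flat_vocab), size=n_extra, replace=False):
            terms.add(flat_vocab[j])
        for term, ns in sorted(terms):
            go_rows.append((gene, term, ns))
        prot_rows.append(
            (
                gene,
                int(rng.random() < config.larva_fraction),
                int(rng.random() < config.egg_fraction),
            )
        )

    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "scaffold", "start", "end"])
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "go_id", "namespace"])
    proteome = pd.DataFrame(prot_rows, columns=["gene_id", "in_larva", "in_egg"])
    return annotation, go_map, proteome


def simulate_cohorts(
    config: SimulationConfig,
    outdir,
    split_vcf: bool = False,
) -> SimulatedDataset:
    """Run :func:`simulate_dataset` and write all artefacts to ``outdir``.

    Writes either one combined multi-sample VCF plus a sample-to-group map
    (default, matching a jointly-called dataset) or one VCF per condition when
    ``split_vcf`` is true.  Identical config (including seed) produces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    gm = ds.genotypes

    contigs = {
        f"scaffold_{s + 1}": config.windows_per_scaffold * config.window_size
        for s in range(config.n_scaffolds)
    }
    paths: dict[str, Path] = {}
    if split_vcf:
        for grp in ("control", "heat"):
            ids = [s for s in gm.samples if gm.groups[s] == grp]
            sub = gm.subset_samples(ids)
            paths[f"vcf_{grp}"] = outdir / f"{grp}.vcf"
            write_vcf(sub, paths[f"vcf_{grp}"], contigs)
    else:
        paths["vcf"] = outdir / "cohort.vcf"
        write_vcf(gm, paths["vcf"], contigs)

    paths["groups"] = outdir / "groups.tsv"
    pd.DataFrame(
        {"sample_id": gm.samples, "group": [gm.groups[s] for s in gm.samples]}
    ).to_csv(paths["groups"], sep="\t", index=False)

    paths["cds"] = outdir / "cds.bed"
    bed = ds.annotation.copy()
    bed["score"] = 0
    bed["strand"] = "+"
    bed[["scaffold", "start", "end", "gene_id", "score", "strand"]].to_csv(
        paths["cds"], sep="\t", index=False, header=False
    )

    paths["go_map"] = outdir / "go_map.tsv"
    ds.go_map.to_csv(paths["go_map"], sep="\t", index=False)

    paths["proteome"] = outdir / "proteome.tsv"
    ds.proteome.to_csv(paths["proteome"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)

    ds.paths = paths
    return ds


def neutral_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with selection switched off (all windows neutral)."""
    return replace(config, frac_sweep=0.0, frac_balancing=0.0)
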