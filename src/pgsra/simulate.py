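"""Synthetic two-population study generator.

Real cross-ancestry analyses rest on three structural features of genotype
data: allele-frequency divergence between populations, linkage
disequilibrium (LD) that decays with physical distance, and LD patterns
that differ between populations.  The generator here produces all three
from a single divergence knob, with no external data, via a two-stage
block-mosaic scheme:

1.  *Ancestral haplotype pools.*  The genome is a set of LD blocks.  Per
    block, a pool of K ancestral haplotypes is drawn from a thresholded
    first-order Gaussian autoregression along variants, so alleles on the
    same ancestral haplotype are correlated over a characteristic physical
    scale.

2.  *Drifted mosaic sampling.*  Each population draws its own mixing
    weights over the pool members of each block from a symmetric Dirichlet
    whose concentration is calibrated so the induced allele-frequency
    variance matches Balding-Nichols drift at the target F_ST:  with
    ``alpha = (1/F - 1)/K`` the weight vector satisfies
    ``var(p_l | pool) = F * q(1-q)`` at every variant, and two populations
    drifting independently from the shared pool have expected Hudson F_ST
    equal to ``F``.  Individual haplotypes are mosaics of pool members:
    walking along a block, the pool member being copied is re-drawn (from
    the population's weights) with a per-step probability set by a
    population-specific LD length, so LD decays with distance and decays
    differently in the two populations while keeping LD *sign* consistent
    across populations (both copy from the same ancestral haplotypes).

Causal architecture and phenotypes follow the standard additive model:
``M_C`` causal variants, per-population effect variance proportional to
``[2p(1-p)]^S`` (S = -1 makes every causal variant explain the same
variance), cross-population effect correlation ``rho_b``, and phenotypes
``y = g + e`` with ``var(y) = 1`` and heritability ``h^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genodata import GenotypePanel, allele_frequencies

POP1 = "pop1"
POP2 = "pop2"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-population study.

    Defaults are the desk-scale study conditions used throughout the test
    grid: 10,000 variants in 100 LD blocks, Hudson F_ST 0.10 between the
    populations, a discovery sample of 10,000 plus a 2,000-strong
    same-ancestry validation sample and a 2,000-strong target sample,
    200 causal variants, h^2 = 0.5 in both populations, perfectly
    correlated effects and S = -1 (each causal explains equal variance).
    """

    n_variants: int = 10_000
    n_blocks: int = 100
    block_span_kb: float = 200.0
    target_fst: float = 0.10
    n_discovery: int = 10_000
    n_targets: Mapping[str, int] = field(
        default_factory=lambda: {POP1: 2_000, POP2: 2_000}
    )
    m_causal: int = 200
    h2: Mapping[str, float] = field(default_factory=lambda: {POP1: 0.5, POP2: 0.5})
    S: Mapping[str, float] = field(default_factory=lambda: {POP1: -1.0, POP2: -1.0})
    rho_b: float = 1.0
    maf_floor: float = 0.01
    seed: int = 0
    # haplotype-model knobs (see module docstring); defaults give pop2 the
    # shorter LD, mimicking an African-ancestry target of a European-ancestry
    # discovery GWAS
    pool_size: int = 100
    pool_ld_scale_kb: float = 200.0
    ld_scale_kb: Mapping[str, float] = field(
        default_factory=lambda: {POP1: 100.0, POP2: 50.0}
    )
    drift_unit_kb: float = 25.0
    block_gap_kb: float = 5_000.0

    def __post_init__(self) -> None:
        for pop, h in self.h2.items():
            if not 0 < h <= 1:
                raise ValueError(f"h2[{pop!r}] = {h} outside (0, 1]")
        if not -1 <= self.rho_b <= 1:
            raise ValueError("rho_b must lie in [-1, 1]")
        if self.m_causal >= self.n_variants:
            raise ValueError("m_causal must be smaller than n_variants")
        if self.maf_floor < 0:
            raise ValueError("maf_floor must be non-negative")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must lie in [0, 1)")
        if self.n_blocks > self.n_variants:
            raise ValueError("more blocks than variants")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class EffectTable:
    """Per-causal-variant effect sizes in both populations.

    ``beta`` maps population label to per-minor-allele effects in
    trait-standard-deviation units; ``p`` maps population label to the
    counted-allele frequencies the variances were scaled with.
    """

    variant_ids: np.ndarray
    beta: dict[str, np.ndarray]
    p: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"variant_id": self.variant_ids}
        for pop in self.beta:
            cols[f"beta_{pop}"] = self.beta[pop]
            cols[f"p_{pop}"] = self.p[pop]
        return pd.DataFrame(cols)


@dataclass
class PhenotypeVector:
    """Simulated phenotype y = g + e with its genetic component."""

    sample_ids: list[str]
    y: np.ndarray
    g: np.ndarray
    population_label: str


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _block_layout(config: SimulationConfig) -> list[tuple[np.ndarray, float]]:
    """Per block: 1-based positions and the (uniform) inter-variant spacing."""
    base, rem = divmod(config.n_variants, config.n_blocks)
    sizes = [base + 1] * rem + [base] * (config.n_blocks - rem)
    span_bp = config.block_span_kb * 1000.0
    stride = int(round((config.block_span_kb + config.block_gap_kb) * 1000.0))
    layout = []
    for b, size in enumerate(sizes):
        spacing = max(span_bp / max(size - 1, 1), 1.0)
        start = 1 + b * stride
        pos = start + np.round(spacing * np.arange(size)).astype(np.int64)
        layout.append((pos, spacing))
    return layout


def _sample_block_haplotypes(
    rng: np.random.Generator,
    pool: np.ndarray,
    cum_w: np.ndarray,
    unit_of_col: np.ndarray,
    n_hap: int,
    switch_prob: float,
) -> np.ndarray:
    """Mosaic haplotypes copied from a pool with geometric segment lengths.

    ``cum_w`` holds one cumulative weight vector per drift unit and
    ``unit_of_col`` assigns each variant column to its unit; a switch is
    forced at every unit boundary so each segment is drawn from a single
    unit's weights.
    """
    K, V = pool.shape
    switch = rng.random((n_hap, V), dtype=np.float32) < switch_prob
    switch[:, 0] = True
    boundaries = np.flatnonzero(np.diff(unit_of_col)) + 1
    switch[:, boundaries] = True
    cols = np.arange(V)
    seg_start = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
    # pool members are only drawn where a segment starts
    picks = np.zeros((n_hap, V), dtype=np.int32)
    at = np.nonzero(switch)
    u = rng.random(len(at[0]), dtype=np.float32)
    units_at = unit_of_col[at[1]]
    draws = np.empty(len(u), dtype=np.int64)
    for d in range(cum_w.shape[0]):
        sel = units_at == d
        if sel.any():
            draws[sel] = np.searchsorted(cum_w[d], u[sel])
    picks[at] = np.minimum(draws, K - 1)
    idx = np.take_along_axis(picks, seg_start, axis=1)
    return pool[idx, cols[None, :]]


def simulate_two_populations(config: SimulationConfig) -> dict[str, GenotypePanel]:
    """Generate the two population panels of the study.

    Returns ``{"pop1": panel, "pop2": panel}`` where pop1 holds
    ``n_discovery + n_targets["pop1"]`` individuals (discovery plus
    held-out same-ancestry samples) and pop2 holds ``n_targets["pop2"]``.
    Variants below the MAF floor in either population (or monomorphic) are
    removed from both panels, so the two panels always share a variant
    set with a common allele coding.  Identical configs (including seed)
    give byte-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    K = config.pool_size
    F = config.target_fst
    n_by_pop = {
        POP1: config.n_discovery + int(config.n_targets.get(POP1, 0)),
        POP2: int(config.n_targets.get(POP2, 0)),
    }
    if n_by_pop[POP2] <= 0:
        raise ValueError("n_targets must include a positive pop2 sample size")

    layout = _block_layout(config)
    M = sum(len(pos) for pos, _ in layout)
    genos = {pop: np.empty((n, M), dtype=np.int8) for pop, n in n_by_pop.items()}
    positions = np.concatenate([pos for pos, _ in layout])

    if F > 0:
        alpha = (1.0 / F - 1.0) / K
        if alpha <= 0:
            raise ValueError(
                f"target_fst={F} is unattainable with pool_size={K}; "
                "reduce the target or enlarge the pool"
            )

    col0 = 0
    for pos, spacing in layout:
        V = len(pos)
        # stage 1: ancestral pool with AR(1)-thresholded LD
        p_anc = rng.uniform(0.05, 0.95, size=V)
        a = np.exp(-spacing / (config.pool_ld_scale_kb * 1000.0))
        z = np.empty((K, V))
        z[:, 0] = rng.standard_normal(K)
        eps = rng.standard_normal((K, V - 1)) if V > 1 else None
        for v in range(1, V):
            z[:, v] = a * z[:, v - 1] + np.sqrt(1.0 - a * a) * eps[:, v - 1]
        pool = (z < sps.norm.ppf(p_anc)[None, :]).astype(np.int8)

        # stage 2: per-population drifted weights (one independent draw per
        # drift unit, so drift decorrelates along the chromosome), then
        # mosaic haplotypes
        cols_per_unit = max(int(round(config.drift_unit_kb * 1000.0 / spacing)), 1)
        unit_of_col = np.arange(V) // cols_per_unit
        n_units = int(unit_of_col[-1]) + 1
        for pop in (POP1, POP2):
            if F > 0:
                w = rng.dirichlet(np.full(K, alpha), size=n_units)
            else:
                w = np.full((n_units, K), 1.0 / K)
            cum_w = np.cumsum(w, axis=1)
            cum_w[:, -1] = 1.0
            L = config.ld_scale_kb[pop] * 1000.0
            switch_prob = 1.0 - np.exp(-spacing / L)
            n = n_by_pop[pop]
            hap = _sample_block_haplotypes(
                rng, pool, cum_w, unit_of_col, 2 * n, switch_prob
            )
            genos[pop][:, col0 : col0 + V] = hap[:n] + hap[n:]
        col0 += V

    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{i:06d}" for i in range(M)],
            "chromosome": "1",
            "bp": positions,
            "counted_allele": "A",
            "other_allele": "G",
        }
    )
    panels = {}
    for pop, n in n_by_pop.items():
        panels[pop] = GenotypePanel(
            population_label=pop,
            sample_ids=[f"{pop}_{i:06d}" for i in range(n)],
            variants=variants.copy(),
            genotypes=genos[pop],
        )

    # joint MAF floor: a variant must be common in *every* population
    keep = np.ones(M, dtype=bool)
    for pop in panels:
        p = allele_frequencies(panels[pop])["p"].to_numpy()
        maf = np.minimum(p, 1.0 - p)
        keep &= maf >= max(config.maf_floor, 1e-12)
    kept_ids = variants.loc[keep, "variant_id"]
    return {pop: panel.subset_variants(kept_ids) for pop, panel in panels.items()}


def split_pop1(
    panels: Mapping[str, GenotypePanel], config: SimulationConfig
) -> tuple[GenotypePanel, GenotypePanel, GenotypePanel]:
    """Split into (discovery, validation, target) sub-panels.

    Discovery and validation are disjoint slices of the pop1 panel; the
    target is the pop2 panel.
    """
    pop1 = panels[POP1]
    n_val = int(config.n_targets.get(POP1, 0))
    if pop1.n_samples != config.n_discovery + n_val:
        raise ValueError("pop1 panel size does not match the config split")
    discovery = pop1.subset_samples(np.arange(config.n_discovery))
    validation = pop1.subset_samples(np.arange(config.n_discovery, pop1.n_samples))
    return discovery, validation, panels[POP2]


# ---------------------------------------------------------------------------
# causal effects
# ---------------------------------------------------------------------------

def sample_causal_effects(
    freqs1: pd.DataFrame,
    freqs2: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> EffectTable:
    """Draw causal variants and their per-population effect sizes.

    ``M_C`` causal ids are sampled uniformly (without replacement) from
    variants polymorphic and above the MAF floor in both frequency tables.
    Effects are bivariate normal across populations with correlation
    ``rho_b`` and marginal variance proportional to ``[2 p_l (1-p_l)]^S_l``;
    the proportionality constant is set per population so that
    ``sum_j 2 p_jl (1-p_jl) beta_jl^2`` has expectation ``h_l^2``.  With
    ``S_l = -1`` this is the equal-variance-per-causal architecture
    var(beta) = h^2 / (2p(1-p) M_C), and with ``rho_b = 1`` and equal S the
    two populations' effects are exact deterministic rescalings of each
    other.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    f1 = freqs1.set_index("variant_id")["p"]
    f2 = freqs2.set_index("variant_id")["p"]
    shared = f1.index.intersection(f2.index)
    floor = max(config.maf_floor, 1e-12)
    ok = shared[
        (np.minimum(f1[shared], 1 - f1[shared]) >= floor)
        & (np.minimum(f2[shared], 1 - f2[shared]) >= floor)
    ]
    if len(ok) < config.m_causal:
        raise ValueError(
            f"only {len(ok)} variants eligible as causal; need {config.m_causal}"
        )
    chosen = rng.choice(np.asarray(ok, dtype=object), size=config.m_causal, replace=False)
    chosen = np.asarray(sorted(chosen), dtype=object)

    p = {POP1: f1[chosen].to_numpy(float), POP2: f2[chosen].to_numpy(float)}
    het = {pop: 2.0 * p[pop] * (1.0 - p[pop]) for pop in p}
    sd = {}
    for pop in (POP1, POP2):
        S = config.S[pop]
        sigma2 = config.h2[pop] / np.sum(het[pop] ** (S + 1.0))
        sd[pop] = np.sqrt(sigma2) * het[pop] ** (S / 2.0)

    u1 = rng.standard_normal(config.m_causal)
    if config.rho_b == 1.0:
        u2 = u1
    elif config.rho_b == -1.0:
        u2 = -u1
    else:
        u2 = config.rho_b * u1 + np.sqrt(1.0 - config.rho_b**2) * rng.standard_normal(
            config.m_causal
        )
    beta = {POP1: sd[POP1] * u1, POP2: sd[POP2] * u2}
    return EffectTable(variant_ids=chosen.astype(str), beta=beta, p=p)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotype(
    panel: GenotypePanel,
    effects: EffectTable,
    h2: float,
    seed: int | np.random.SeedSequence | None,
) -> PhenotypeVector:
    """Simulate y = g + e for one panel.

    ``g`` is the dot product of causal minor-allele counts with the
    panel's population effects; ``e ~ N(0, 1 - h^2)`` so that the
    phenotypic variance is about 1.  ``h2 = 1`` returns y = g exactly.
    """
    if not 0 < h2 <= 1:
        raise ValueError(f"h2 = {h2} outside (0, 1]")
    pop = panel.population_label
    if pop not in effects.beta:
        raise KeyError(f"effect table has no effects for population {pop!r}")
    missing = [v for v in effects.variant_ids if v not in panel]
    if missing:
        raise KeyError(f"causal variants absent from panel: {missing[:5]}")
    cols = np.array([panel.col(v) for v in effects.variant_ids])
    X = panel.genotypes[:, cols].astype(np.float64)
    X[X < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    g = X @ effects.beta[pop]
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, np.sqrt(1.0 - h2), size=panel.n_samples) if h2 < 1 else 0.0
    return PhenotypeVector(
        sample_ids=list(panel.sample_ids),
        y=g + e,
        g=g,
        population_label=pop,
    )
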