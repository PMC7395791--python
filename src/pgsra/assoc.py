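"""Discovery GWAS and PLINK-style greedy LD clumping.

The GWAS is deliberately plain: per-variant ordinary least squares of the
phenotype on minor-allele count with an intercept, two-sided p-values from
the t distribution with n-2 degrees of freedom, no covariates.  Clumping
follows the classic greedy algorithm: repeatedly promote the most
significant remaining variant to index SNP and discard its correlated
neighbours, using the discovery panel as the LD reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genodata import MISSING, GenotypePanel, _ld_profile
from .simulate import PhenotypeVector

SUMSTATS_COLUMNS = [
    "variant_id",
    "chromosome",
    "bp",
    "counted_allele",
    "other_allele",
    "beta_hat",
    "se",
    "p_value",
    "n",
]

PGS_COLUMNS = [
    "variant_id",
    "chromosome",
    "bp",
    "counted_allele",
    "other_allele",
    "beta_hat",
    "p_value",
]

#: p-values are floored here so they stay inside (0, 1] even when the t
#: statistic is far beyond double-precision tail resolution.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ClumpParams:
    """Greedy-clumping thresholds (PLINK naming: p1/p2/kb/r2)."""

    p1: float = 5e-8
    p2: float = 5e-8
    window_kb: float = 2_000.0
    r2_max: float = 0.01

    def __post_init__(self) -> None:
        if not self.p1 <= self.p2:
            raise ValueError("p1 must not exceed p2")
        if not 0 < self.r2_max < 1:
            raise ValueError("r2_max must lie in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


def run_gwas(
    panel: GenotypePanel,
    pheno: PhenotypeVector,
    exclude_ids: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Simple linear regression of the phenotype on each variant.

    Returns a summary-statistics table (one row per variant) with
    ``beta_hat = cov(x, y)/var(x)``, its standard error and the two-sided
    p-value from the t distribution with n-2 degrees of freedom.
    Variants in ``exclude_ids`` are absent from the output (used to leave
    causal variants out of the analysis so that association signals come
    from LD tagging only); monomorphic variants are skipped with a warning.
    Samples with a missing genotype are dropped per variant.
    """
    if pheno.sample_ids != panel.sample_ids:
        raise ValueError("phenotype is not aligned to the panel samples")
    y = np.asarray(pheno.y, dtype=np.float64)
    g = panel.genotypes
    n_total = panel.n_samples
    has_missing = bool((g == MISSING).any())

    if has_missing:
        X = g.astype(np.float64)
        mask = X < 0
        X[mask] = np.nan
        n = (~mask).sum(axis=0).astype(np.float64)
        sx = np.nansum(X, axis=0)
        sxx = np.nansum(X * X, axis=0)
        ysum = np.where(mask, 0.0, y[:, None]).sum(axis=0)
        syy = np.where(mask, 0.0, (y**2)[:, None]).sum(axis=0)
        sxy = np.nansum(X * y[:, None], axis=0)
        Sxx = sxx - sx * sx / n
        Sxy = sxy - sx * ysum / n
        Syy = syy - ysum * ysum / n
    else:
        n = np.full(panel.n_variants, float(n_total))
        # counts are 0/1/2, so sum(x^2) = #het + 4 * #hom without upcasting
        sx = g.sum(axis=0, dtype=np.int64).astype(np.float64)
        sxx = (
            (g == 1).sum(axis=0, dtype=np.int64)
            + 4 * (g == 2).sum(axis=0, dtype=np.int64)
        ).astype(np.float64)
        # float32 GEMV is ample for GWAS-scale matrices; small panels get
        # exact float64 arithmetic
        if g.size < 5_000_000:
            Xf = g.astype(np.float64)
            yc = y - y.mean()
        else:
            Xf = panel.as_float()
            yc = (y - y.mean()).astype(np.float32)
        Sxy = (Xf.T @ yc).astype(np.float64)
        Sxx = sxx - sx * sx / n_total
        Syy = float(((y - y.mean()) ** 2).sum())

    poly = Sxx > 1e-12
    if not poly.all():
        skipped = panel.variants.loc[~poly, "variant_id"].tolist()
        warnings.warn(f"skipping {len(skipped)} monomorphic variant(s): {skipped[:5]}")

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = Sxy / Sxx
        df = n - 2
        sse = Syy - beta * Sxy
        s2 = np.maximum(sse, 0.0) / df
        se = np.sqrt(s2 / Sxx)
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)

    out = pd.DataFrame(
        {
            "variant_id": panel.variants["variant_id"].to_numpy(),
            "chromosome": panel.variants["chromosome"].to_numpy(),
            "bp": panel.variants["bp"].to_numpy(),
            "counted_allele": panel.variants["counted_allele"].to_numpy(),
            "other_allele": panel.variants["other_allele"].to_numpy(),
            "beta_hat": beta,
            "se": se,
            "p_value": p,
            "n": n.astype(np.int64),
        }
    )
    out = out[poly]
    if exclude_ids:
        out = out[~out["variant_id"].isin(set(exclude_ids))]
    return out.reset_index(drop=True)


def clump(
    sumstats: pd.DataFrame,
    ld_panel: GenotypePanel,
    params: ClumpParams = ClumpParams(),
) -> pd.DataFrame:
    """Greedy LD clumping of a summary-statistics table.

    Repeatedly takes the smallest-p remaining variant with ``p <= p1`` as
    an index SNP and removes every remaining variant with ``p <= p2``,
    within ``window_kb`` on the same chromosome, whose r^2 with the index
    exceeds ``r2_max`` in ``ld_panel``.  Equal p-values are broken by
    (chromosome, bp), so the output does not depend on input row order.
    Returns the index SNPs, in selection order, as a PGS SNP set table.
    """
    missing = [v for v in sumstats["variant_id"] if v not in ld_panel]
    if missing:
        raise KeyError(f"sumstats variants absent from LD panel: {missing[:5]}")
    cand = sumstats[sumstats["p_value"] <= params.p2].copy()
    cand = cand.sort_values(
        ["p_value", "chromosome", "bp"], kind="mergesort"
    ).reset_index(drop=True)
    pvals = cand["p_value"].to_numpy()
    chrom = cand["chromosome"].to_numpy()
    bp = cand["bp"].to_numpy(dtype=np.int64)
    cols = np.array([ld_panel.col(v) for v in cand["variant_id"]], dtype=np.int64)

    active = np.ones(len(cand), dtype=bool)
    chosen: list[int] = []
    window_bp = params.window_kb * 1000.0
    while True:
        remaining = np.flatnonzero(active)
        if len(remaining) == 0:
            break
        idx = remaining[0]  # smallest p among active rows (sorted order)
        if pvals[idx] > params.p1:
            break
        chosen.append(idx)
        active[idx] = False
        near = remaining[
            (chrom[remaining] == chrom[idx])
            & (np.abs(bp[remaining] - bp[idx]) <= window_bp)
            & (remaining != idx)
        ]
        if len(near):
            r = _ld_profile(ld_panel, cols[idx], cols[near])
            kill = near[np.nan_to_num(r) ** 2 > params.r2_max]
            active[kill] = False

    out = cand.iloc[chosen][PGS_COLUMNS].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chromosome": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns and c in
               ("variant_id", "beta_hat", "p_value")]
    if missing:
        raise ValueError(f"summary statistics file lacks columns: {missing}")
    return df


def write_pgs(pgs: pd.DataFrame, path) -> None:
    pgs.to_csv(path, sep="\t", index=False)


def read_pgs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chromosome": str})
    missing = [c for c in ("variant_id", "beta_hat", "counted_allele") if c not in df]
    if missing:
        raise ValueError(f"PGS SNP file lacks columns: {missing}")
    return df
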