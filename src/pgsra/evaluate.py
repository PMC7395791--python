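"""Empirical accuracy of a PGS: scoring, R^2, liability scale, observed RA.

The observed relative accuracy is the ratio of the squared Pearson
correlation between score and phenotype in the target-ancestry sample
over the same quantity in a held-out sample of the discovery ancestry.
For binary traits the observed-scale R^2 is mapped to the liability scale
with the Lee et al. (2012) transformation using the population prevalence
K and the sample case proportion P.  Uncertainty comes from nonparametric
bootstrap over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genodata import GenotypePanel
from .simulate import PhenotypeVector


@dataclass
class RAObservation:
    """Observed relative accuracy with its uncertainty."""

    r2_ref: float
    r2_target: float
    ra: float
    se_ra: float
    scale: str = "observed"


@dataclass
class LoaReport:
    """Loss of accuracy (LOA) and the share of it a prediction explains.

    LOA = (1 - RA) x 100%.  ``prop_explained`` is predicted LOA over
    observed LOA (in percent of the observed loss); it is only defined
    when the observed RA is below 1, i.e. when there is a loss to explain.
    """

    ra_obs: float
    ra_pred: float
    loa_obs: float
    loa_pred: float
    prop_explained: float | None
    se_prop: float | None


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_pgs(panel: GenotypePanel, pgs: pd.DataFrame) -> np.ndarray:
    """Per-sample PGS: sum of allele counts times effect sizes.

    The PGS table needs columns ``variant_id, beta_hat, counted_allele``
    (and ``other_allele`` when codings can differ).  Variants counted on
    the opposite allele in the panel are flipped (x -> 2 - x) before
    weighting; a PGS-SNP absent from the panel is an error — silently
    dropping SNPs would bias the score variance.  Missing genotypes are
    mean-imputed with 2p from the panel frequency.
    """
    missing = [v for v in pgs["variant_id"] if v not in panel]
    if missing:
        raise KeyError(f"PGS-SNPs absent from panel: {missing[:5]}")
    cols = np.array([panel.col(v) for v in pgs["variant_id"]])
    X = panel.genotypes[:, cols].astype(np.float64)
    miss = X < 0
    X[miss] = np.nan

    panel_counted = panel.variants["counted_allele"].to_numpy()[cols]
    panel_other = panel.variants["other_allele"].to_numpy()[cols]
    want = pgs["counted_allele"].to_numpy()
    flip = panel_counted != want
    if flip.any():
        other_ok = panel_other[flip] == want[flip]
        if not other_ok.all():
            bad = pgs["variant_id"].to_numpy()[flip][~other_ok]
            raise ValueError(f"allele mismatch between PGS and panel: {bad[:5]}")
        X[:, flip] = 2.0 - X[:, flip]

    if miss.any():
        col_mean = np.nanmean(X, axis=0)
        ii, jj = np.nonzero(np.isnan(X))
        X[ii, jj] = col_mean[jj]
    return X @ pgs["beta_hat"].to_numpy(float)


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def observed_r2(scores: np.ndarray, pheno: PhenotypeVector | np.ndarray) -> float:
    """Squared Pearson correlation between scores and phenotypes."""
    y = pheno.y if isinstance(pheno, PhenotypeVector) else np.asarray(pheno, float)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and phenotypes differ in length")
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(s) == 0:
        raise ValueError("scores are constant; R^2 undefined")
    r = np.corrcoef(s, y)[0, 1]
    return float(r * r)


def liability_r2(r2_obs: float, K: float, P: float) -> float:
    """Observed-scale R^2 mapped to the liability scale (Lee et al. 2012).

    ``K`` is the population prevalence and ``P`` the sample case
    proportion.  With t = the liability threshold Phi^-1(1-K), z = phi(t)
    and m = z/K, the transformation is r2 * C / (1 + r2 * theta) with
    C = K^2 (1-K)^2 / (z^2 P (1-P)) and
    theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t).  For a population-based
    sample (P = K) theta vanishes and the map is linear:
    r2 * K(1-K)/z^2.
    """
    for name, v in (("K", K), ("P", P)):
        if not 0 < v < 1:
            raise ValueError(f"{name} = {v} outside (0, 1)")
    t = sps.norm.isf(K)
    z = sps.norm.pdf(t)
    m = z / K
    C = K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P))
    d = m * (P - K) / (1 - K)
    theta = d * (d - t)
    return float(r2_obs * C / (1 + r2_obs * theta))


def _boot_r2(scores: np.ndarray, y: np.ndarray, idx: np.ndarray) -> float:
    s = scores[idx]
    yy = y[idx]
    if np.std(s) == 0 or np.std(yy) == 0:
        return np.nan
    r = np.corrcoef(s, yy)[0, 1]
    return r * r


def relative_accuracy(
    r2_target: float,
    r2_ref: float,
    resamples: tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    | None = None,
    n_boot: int = 1_000,
    seed: int | np.random.SeedSequence = 0,
    scale: str = "observed",
) -> RAObservation:
    """Observed RA = R^2_target / R^2_ref with a bootstrap standard error.

    ``resamples``, when given, is ``((scores_t, y_t), (scores_r, y_r))``:
    the per-individual scores and phenotypes of the target and reference
    samples.  Individuals are resampled independently in the two samples
    for ``n_boot`` replicates; without resamples the SE is reported as
    NaN.  The bootstrap replicate ratios are also returned on the
    observation (attribute ``boot_ra``) for downstream error propagation.
    """
    if r2_ref <= 0:
        raise ValueError("reference R^2 must be positive")
    ra = r2_target / r2_ref
    se = np.nan
    boot = None
    if resamples is not None:
        (st, yt), (sr, yr) = resamples
        st, yt = np.asarray(st, float), np.asarray(yt, float)
        sr, yr = np.asarray(sr, float), np.asarray(yr, float)
        rng = np.random.default_rng(seed)
        nt, nr = len(st), len(sr)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            r2t = _boot_r2(st, yt, rng.integers(0, nt, nt))
            r2r = _boot_r2(sr, yr, rng.integers(0, nr, nr))
            reps[b] = r2t / r2r if (r2r and not np.isnan(r2r)) else np.nan
        boot = reps[~np.isnan(reps)]
        se = float(np.std(boot, ddof=1)) if len(boot) > 1 else np.nan
    obs = RAObservation(
        r2_ref=float(r2_ref),
        r2_target=float(r2_target),
        ra=float(ra),
        se_ra=float(se),
        scale=scale,
    )
    obs.boot_ra = boot  # type: ignore[attr-defined]
    return obs


def loa_explained(
    ra_obs: float,
    ra_pred: float,
    se_inputs: np.ndarray | float | None = None,
) -> LoaReport:
    """Loss of accuracy and the proportion of it the prediction explains.

    ``se_inputs`` propagates uncertainty in the observed RA: an array is
    treated as bootstrap replicates of ra_obs (replicates with no loss,
    ra >= 1, are dropped); a float is treated as se(ra_obs) and propagated
    by the delta method.  With ``ra_obs >= 1`` there is no loss and the
    proportion is reported as undefined (None).
    """
    loa_obs = (1.0 - ra_obs) * 100.0
    loa_pred = (1.0 - ra_pred) * 100.0
    if ra_obs >= 1.0:
        return LoaReport(ra_obs, ra_pred, loa_obs, loa_pred, None, None)
    prop = 100.0 * (1.0 - ra_pred) / (1.0 - ra_obs)
    se_prop: float | None = None
    if se_inputs is not None:
        if np.ndim(se_inputs) > 0:
            reps = np.asarray(se_inputs, float)
            reps = reps[~np.isnan(reps) & (reps < 1.0)]
            if len(reps) > 1:
                se_prop = float(np.std(100.0 * (1.0 - ra_pred) / (1.0 - reps), ddof=1))
        else:
            se_prop = float(
                100.0 * (1.0 - ra_pred) / (1.0 - ra_obs) ** 2 * float(se_inputs)
            )
    return LoaReport(ra_obs, ra_pred, loa_obs, loa_pred, float(prop), se_prop)


def jackknife_se(values: np.ndarray) -> float:
    """Leave-one-out jackknife SE of the mean of ``values``."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        return np.nan
    loo = (x.sum() - x) / (n - 1)
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
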