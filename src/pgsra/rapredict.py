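"""Deterministic prediction of the relative accuracy of a transferred PGS.

A polygenic score built from genome-wide-significant (GWS) SNPs of a
discovery GWAS in population 1 loses accuracy when applied in a
genetically diverged population 2.  Writing R_l^2 for the squared
correlation between score and phenotype in population l, the relative
accuracy RA = R_2^2 / R_1^2 decomposes multiplicatively into

    RA  =  rho_b^2 h_2^2 / h_1^2                       (effect-size term)
        x  [ sum_k  m_k sqrt(het_{k,2}/het_{k,1}) / sum_k v_k ]^2
                                                        (LD + MAF term)
        x  sum_k het_{k,1} beta_k^2 / sum_k het_{k,2} beta_k^2
                                                        (var(PGS) term)

where het_{k,l} = p_{k,l}(1 - p_{k,l}) is the heterozygosity of the k-th
PGS-SNP in population l, beta_k its discovery effect estimate, rho_b the
cross-population correlation of causal effects and h_l^2 the heritability
in population l.  The quantities m_k and v_k summarise how well the
PGS-SNP tags the causal variants around it:

* *known* mode (simulations, where causal variants are known):
  m_k = mean over in-window causals j of r_{jk,1} r_{jk,2};
  v_k = mean of r_{jk,1}^2; with r_{jk,l} the signed LD between causal j
  and PGS-SNP k in the population-l reference panel.
* *heuristic* mode (real data): the causals are replaced by candidate
  causal variants — reference variants within 100 kb of the PGS-SNP whose
  discovery-panel r^2 with it exceeds 0.45, a rule motivated by reported
  fine-mapping precision of GWAS hits.
* *naive* mode: the PGS-SNPs are assumed to be the causal variants
  themselves, m_k = v_k = 1, so only allele-frequency differences remain.

The var(PGS) ratio is computed from the closed form sum p(1-p) beta^2 in
both modes, so a prediction needs nothing beyond summary statistics and
two ancestry-matched reference panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GenotypePanel, _ld_profile, window_cols


@dataclass
class CandidateCausalMap:
    """Per PGS-SNP candidate (or known) causal variants with their LD.

    ``entries`` maps each PGS-SNP id to a table with columns
    ``candidate_id, r1, r2, dbp`` (signed LD in the population-1 and
    population-2 reference panels, and the bp offset from the PGS-SNP).
    Fallback entries — the PGS-SNP standing in for itself when no
    candidate qualifies — carry r1 = r2 = 1 and dbp = 0.
    """

    entries: dict[str, pd.DataFrame]
    mode: str

    @property
    def mean_r1_sq(self) -> pd.Series:
        return pd.Series(
            {k: float(np.mean(df["r1"] ** 2)) for k, df in self.entries.items()}
        )

    @property
    def mean_r1r2(self) -> pd.Series:
        return pd.Series(
            {k: float(np.mean(df["r1"] * df["r2"])) for k, df in self.entries.items()}
        )

    def n_candidates(self) -> pd.Series:
        return pd.Series({k: len(df) for k, df in self.entries.items()})


@dataclass
class RAPrediction:
    """Predicted relative accuracy with its multiplicative decomposition."""

    ra: float
    mode: str
    term_effect: float
    term_ldmaf: float
    term_varpgs: float
    inputs_summary: dict

    def __post_init__(self) -> None:
        assert np.isclose(
            self.ra, self.term_effect * self.term_ldmaf * self.term_varpgs
        )


def _pair_ld(
    panel: GenotypePanel, index_id: str, candidate_ids: np.ndarray
) -> np.ndarray:
    cols = np.array([panel.col(v) for v in candidate_ids])
    return _ld_profile(panel, panel.col(index_id), cols)


def find_candidate_causals(
    pgs_snps: pd.DataFrame,
    ref_panel: GenotypePanel,
    ref2_panel: GenotypePanel | None = None,
    window_kb: float = 100.0,
    r2_min: float = 0.45,
) -> CandidateCausalMap:
    """Identify candidate causal variants for each PGS-SNP.

    Candidates are variants of ``ref_panel`` (the discovery-ancestry
    reference, since GWS SNPs arise from discovery LD) within the closed
    ``window_kb`` window of the PGS-SNP whose squared correlation with it
    exceeds ``r2_min``; the PGS-SNP itself is not its own candidate unless
    no variant qualifies, in which case it is the fallback (r = 1).  When
    ``ref2_panel`` is given, the LD of each retained pair is also computed
    there (candidates absent from it are dropped, with the same fallback).
    """
    missing = [v for v in pgs_snps["variant_id"] if v not in ref_panel]
    if missing:
        raise KeyError(f"PGS-SNPs absent from reference panel: {missing[:5]}")
    ids = ref_panel.variants["variant_id"].to_numpy()
    bp = ref_panel.variants["bp"].to_numpy()
    entries: dict[str, pd.DataFrame] = {}
    for k in pgs_snps["variant_id"]:
        cols = window_cols(ref_panel, k, window_kb, include_index=False)
        cand_ids = ids[cols]
        if ref2_panel is not None:
            in2 = np.array([c in ref2_panel for c in cand_ids], dtype=bool)
            cols, cand_ids = cols[in2], cand_ids[in2]
        if len(cols):
            r1 = _ld_profile(ref_panel, ref_panel.col(k), cols)
            keep = np.nan_to_num(r1) ** 2 > r2_min
            cols, cand_ids, r1 = cols[keep], cand_ids[keep], r1[keep]
        else:
            r1 = np.empty(0)
        if len(cols) == 0:
            entries[k] = _fallback_entry(k)
            continue
        r2 = (
            _pair_ld(ref2_panel, k, cand_ids)
            if ref2_panel is not None
            else np.full(len(cand_ids), np.nan)
        )
        entries[k] = pd.DataFrame(
            {
                "candidate_id": cand_ids,
                "r1": r1,
                "r2": r2,
                "dbp": bp[cols] - bp[ref_panel.col(k)],
            }
        )
    return CandidateCausalMap(entries=entries, mode="heuristic")


def _fallback_entry(k: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"candidate_id": [k], "r1": [1.0], "r2": [1.0], "dbp": [0]}
    )


def build_known_causal_map(
    pgs_snps: pd.DataFrame,
    causal_ids: list[str] | np.ndarray,
    ref1: GenotypePanel,
    ref2: GenotypePanel,
    window_kb: float = 100.0,
) -> CandidateCausalMap:
    """Map each PGS-SNP to the true causal variants within its window.

    Simulation-only: requires the causal ids.  No r^2 filter is applied;
    all causals inside the closed window contribute, with signed LD
    computed in both reference panels.  A PGS-SNP with no causal in its
    window falls back to itself (with a warning), which keeps the
    estimator defined at the cost of treating that SNP as causal.
    """
    causal_set = [c for c in causal_ids if c in ref1 and c in ref2]
    bp1 = ref1.variants["bp"].to_numpy()
    ids1 = ref1.variants["variant_id"].to_numpy()
    causal_cols = np.array([ref1.col(c) for c in causal_set], dtype=np.int64)
    entries: dict[str, pd.DataFrame] = {}
    n_fallback = 0
    for k in pgs_snps["variant_id"]:
        if k not in ref1:
            raise KeyError(f"PGS-SNP {k!r} absent from reference panel")
        kc = ref1.col(k)
        near = causal_cols[
            (ref1.variants["chromosome"].to_numpy()[causal_cols]
             == ref1.variants["chromosome"].iloc[kc])
            & (np.abs(bp1[causal_cols] - bp1[kc]) <= window_kb * 1000.0)
        ]
        if len(near) == 0:
            entries[k] = _fallback_entry(k)
            n_fallback += 1
            continue
        cand_ids = ids1[near]
        r1 = _ld_profile(ref1, kc, near)
        r2 = _pair_ld(ref2, k, cand_ids)
        entries[k] = pd.DataFrame(
            {"candidate_id": cand_ids, "r1": r1, "r2": r2, "dbp": bp1[near] - bp1[kc]}
        )
    if n_fallback:
        warnings.warn(
            f"{n_fallback} PGS-SNP(s) had no causal variant within "
            f"{window_kb} kb; used the SNP itself as fallback"
        )
    return CandidateCausalMap(entries=entries, mode="known")


def predict_relative_accuracy(
    pgs_snps: pd.DataFrame,
    cmap: CandidateCausalMap | None,
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    rho_b: float = 1.0,
    h2_1: float = 1.0,
    h2_2: float = 1.0,
    mode: str = "heuristic",
) -> RAPrediction:
    """Evaluate the deterministic RA formula for a PGS SNP set.

    ``stats1``/``stats2`` are allele-frequency tables (columns
    ``variant_id, p``) for the two reference panels, with coding matched
    to the PGS counted alleles.  ``mode`` is one of ``known``,
    ``heuristic`` (both take m_k/v_k from ``cmap``) or ``naive``
    (m_k = v_k = 1; ``cmap`` ignored).  When phenotype data for the target
    population are unavailable the defaults ``rho_b = h2_1 = h2_2 = 1``
    quantify only the fraction of the RA explained by allele-frequency and
    LD differences.
    """
    if mode not in ("known", "heuristic", "naive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "naive":
        if cmap is None:
            raise ValueError(f"mode {mode!r} requires a candidate causal map")
        missing = [k for k in pgs_snps["variant_id"] if k not in cmap.entries]
        if missing:
            raise KeyError(f"candidate map lacks PGS-SNPs: {missing[:5]}")

    f1 = stats1.set_index("variant_id")["p"]
    f2 = stats2.set_index("variant_id")["p"]
    kids = pgs_snps["variant_id"].to_numpy()
    for vid in kids:
        for name, f in (("population-1", f1), ("population-2", f2)):
            if vid not in f.index:
                raise KeyError(f"no {name} frequency for PGS-SNP {vid!r}")
            if not 0 < f[vid] < 1:
                raise ValueError(
                    f"PGS-SNP {vid!r} is monomorphic (p = {f[vid]}) in the "
                    f"{name} panel; the heterozygosity ratio is undefined"
                )
    p1 = f1[kids].to_numpy(float)
    p2 = f2[kids].to_numpy(float)
    het1 = p1 * (1.0 - p1)
    het2 = p2 * (1.0 - p2)

    if mode == "naive":
        m = np.ones(len(kids))
        v = np.ones(len(kids))
        n_cand = pd.Series(1, index=kids)
    else:
        m = cmap.mean_r1r2[kids].to_numpy(float)
        v = cmap.mean_r1_sq[kids].to_numpy(float)
        n_cand = cmap.n_candidates()[kids]
        if np.isnan(m).any():
            raise ValueError(
                "candidate map has no population-2 LD (was the map built "
                "without a second reference panel?)"
            )

    term_effect = rho_b**2 * h2_2 / h2_1
    term_ldmaf = float(
        (np.sum(m * np.sqrt(het2 / het1)) / np.sum(v)) ** 2
    )
    beta2 = pgs_snps["beta_hat"].to_numpy(float) ** 2
    term_varpgs = float(np.sum(het1 * beta2) / np.sum(het2 * beta2))
    ra = term_effect * term_ldmaf * term_varpgs
    return RAPrediction(
        ra=float(ra),
        mode=mode,
        term_effect=float(term_effect),
        term_ldmaf=term_ldmaf,
        term_varpgs=term_varpgs,
        inputs_summary={
            "m_t": int(len(kids)),
            "candidates_per_snp": {str(k): int(c) for k, c in n_cand.items()},
        },
    )
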