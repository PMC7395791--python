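"""Replicate studies comparing observed and predicted relative accuracy.

One replicate runs the full study: simulate a discovery panel, a held-out
same-ancestry validation panel and a diverged target panel; draw causal
effects and phenotypes; run the discovery GWAS with causal variants left
out; clump to a PGS SNP set; score the two held-out panels; and compute
the observed RA alongside the three deterministic predictions (known
causals, heuristic candidates, naive).  Scenarios aggregate replicates
into signed-bias summaries with jackknife standard errors.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc, evaluate, rapredict, simulate
from .genodata import GenotypePanel, allele_frequencies, hudson_fst_from_stats

logger = logging.getLogger(__name__)

MODES = ("known", "heuristic", "naive")

RECORD_COLUMNS = [
    "scenario_id",
    "seed",
    "population_pair",
    "m_t",
    "ra_obs",
    "ra_pred_known",
    "ra_pred_heuristic",
    "ra_pred_naive",
    "realized_fst",
    "r2_ref",
    "r2_target",
]


@dataclass
class ReplicatePanels:
    """The three panels of one genotype realisation, with frequency tables."""

    discovery: GenotypePanel
    validation: GenotypePanel
    target: GenotypePanel
    stats_discovery: pd.DataFrame
    stats_target: pd.DataFrame
    realized_fst: float

    @classmethod
    def from_config(cls, config: simulate.SimulationConfig) -> "ReplicatePanels":
        panels = simulate.simulate_two_populations(config)
        discovery, validation, target = simulate.split_pop1(panels, config)
        stats1 = allele_frequencies(discovery)
        stats2 = allele_frequencies(target)
        fst = hudson_fst_from_stats(stats1, stats2)
        return cls(discovery, validation, target, stats1, stats2, fst)


def run_replicate(
    panels: ReplicatePanels,
    config: simulate.SimulationConfig,
    rep_seed: int,
    clump_params: assoc.ClumpParams = assoc.ClumpParams(),
    scenario_id: str = "scenario",
    window_kb: float = 100.0,
    r2_min: float = 0.45,
) -> dict:
    """One phenotype/GWAS/PGS replicate on a fixed genotype realisation.

    Effect, phenotype and bootstrap randomness derive from ``rep_seed``
    through independent seed-sequence streams, so records are reproducible
    given (panels, config, rep_seed).  A replicate yielding no
    genome-wide-significant SNP is recorded with ``m_t = 0`` and NaN
    accuracies; callers exclude those from summaries.
    """
    ss = np.random.SeedSequence(rep_seed)
    s_eff, s_disc, s_val, s_tgt = ss.spawn(4)

    effects = simulate.sample_causal_effects(
        panels.stats_discovery, panels.stats_target, config, seed=s_eff
    )
    y_disc = simulate.simulate_phenotype(
        panels.discovery, effects, config.h2[simulate.POP1], s_disc
    )
    y_val = simulate.simulate_phenotype(
        panels.validation, effects, config.h2[simulate.POP1], s_val
    )
    y_tgt = simulate.simulate_phenotype(
        panels.target, effects, config.h2[simulate.POP2], s_tgt
    )

    sumstats = assoc.run_gwas(
        panels.discovery, y_disc, exclude_ids=list(effects.variant_ids)
    )
    pgs = assoc.clump(sumstats, panels.discovery, clump_params)
    base = {
        "scenario_id": scenario_id,
        "seed": rep_seed,
        "population_pair": f"{simulate.POP1}-{simulate.POP2}",
        "m_t": len(pgs),
        "realized_fst": panels.realized_fst,
    }
    if len(pgs) == 0:
        return {
            **base,
            "ra_obs": np.nan,
            "ra_pred_known": np.nan,
            "ra_pred_heuristic": np.nan,
            "ra_pred_naive": np.nan,
            "r2_ref": np.nan,
            "r2_target": np.nan,
        }

    scores_val = evaluate.score_pgs(panels.validation, pgs)
    scores_tgt = evaluate.score_pgs(panels.target, pgs)
    r2_val = evaluate.observed_r2(scores_val, y_val)
    r2_tgt = evaluate.observed_r2(scores_tgt, y_tgt)

    known = rapredict.build_known_causal_map(
        pgs, list(effects.variant_ids), panels.discovery, panels.target, window_kb
    )
    heur = rapredict.find_candidate_causals(
        pgs, panels.discovery, panels.target, window_kb, r2_min
    )
    kwargs = dict(
        stats1=panels.stats_discovery,
        stats2=panels.stats_target,
        rho_b=config.rho_b,
        h2_1=config.h2[simulate.POP1],
        h2_2=config.h2[simulate.POP2],
    )
    pred = {
        "known": rapredict.predict_relative_accuracy(pgs, known, mode="known", **kwargs),
        "heuristic": rapredict.predict_relative_accuracy(
            pgs, heur, mode="heuristic", **kwargs
        ),
        "naive": rapredict.predict_relative_accuracy(pgs, None, mode="naive", **kwargs),
    }
    return {
        **base,
        "ra_obs": r2_tgt / r2_val,
        "ra_pred_known": pred["known"].ra,
        "ra_pred_heuristic": pred["heuristic"].ra,
        "ra_pred_naive": pred["naive"].ra,
        "r2_ref": r2_val,
        "r2_target": r2_tgt,
    }


def run_scenario(
    config: simulate.SimulationConfig,
    n_replicates: int,
    scenario_id: str = "scenario",
    base_seed: int | None = None,
    genotype_seed: int | None = None,
    clump_params: assoc.ClumpParams = assoc.ClumpParams(),
    progress: bool = False,
) -> pd.DataFrame:
    """Run a scenario of independent replicates.

    Replicate seeds are ``base_seed + replicate_index`` (base defaults to
    ``config.seed``) for auditability.  By default every replicate draws
    fresh genotype panels; passing ``genotype_seed`` freezes the genotype
    realisation across replicates (re-drawing only effects and
    phenotypes), which mirrors designs built on a fixed genotype cohort
    and is much cheaper.
    """
    base = config.seed if base_seed is None else base_seed
    records = []
    shared = (
        ReplicatePanels.from_config(config.with_seed(genotype_seed))
        if genotype_seed is not None
        else None
    )
    for i in range(n_replicates):
        rep_seed = base + i
        panels = shared if shared is not None else ReplicatePanels.from_config(
            config.with_seed(rep_seed)
        )
        rec = run_replicate(panels, config, rep_seed, clump_params, scenario_id)
        records.append(rec)
        if progress:
            print(
                f"[{scenario_id}] replicate {i + 1}/{n_replicates}: "
                f"M_T={rec['m_t']} RA_obs={rec['ra_obs']:.3f}",
                file=sys.stderr,
            )
    df = pd.DataFrame.from_records(records, columns=RECORD_COLUMNS)
    n_empty = int((df["m_t"] == 0).sum())
    if n_empty:
        logger.warning(
            "%s: %d replicate(s) with no genome-wide-significant SNP "
            "(excluded from summaries)",
            scenario_id,
            n_empty,
        )
    return df


#: (S_discovery, S_target) pairs of the negative-selection study design:
#: equal mild selection, stronger selection in the discovery population,
#: stronger selection in the target population, and the equal-variance
#: architecture (S = -1) of the main grid.
SELECTION_SCENARIOS = (
    (-0.5, -0.5),
    (-0.75, -0.5),
    (-0.5, -0.75),
    (-1.0, -1.0),
)


def selection_scenario_configs(
    base: simulate.SimulationConfig | None = None,
) -> dict[str, simulate.SimulationConfig]:
    """Scenario configs probing the MAF-effect coupling (selection) exponent.

    Returns one config per (S_1, S_2) pair in :data:`SELECTION_SCENARIOS`,
    keyed ``S1_<v>_S2_<v>``, otherwise identical to ``base`` (default: the
    desk-scale grid).
    """
    import dataclasses

    base = base if base is not None else simulate.SimulationConfig()
    return {
        f"S1_{s1}_S2_{s2}": dataclasses.replace(
            base, S={simulate.POP1: s1, simulate.POP2: s2}
        )
        for s1, s2 in SELECTION_SCENARIOS
    }


def summarize_bias(records: pd.DataFrame) -> pd.DataFrame:
    """Signed percent bias of each predictor per scenario.

    For each scenario and prediction mode: ``signed_bias_pct =
    100 (mean_pred - mean_obs) / mean_obs`` over valid replicates
    (``m_t > 0``), with a leave-one-replicate-out jackknife SE.  Raises if
    a scenario retains fewer than two valid replicates.
    """
    rows = []
    for scenario_id, grp in records.groupby("scenario_id", sort=False):
        valid = grp[grp["m_t"] > 0]
        if len(valid) < 2:
            raise ValueError(
                f"scenario {scenario_id!r} has {len(valid)} valid replicate(s); "
                "need at least 2"
            )
        obs = valid["ra_obs"].to_numpy()
        for mode in MODES:
            pred = valid[f"ra_pred_{mode}"].to_numpy()
            bias = 100.0 * (pred.mean() - obs.mean()) / obs.mean()
            n = len(obs)
            loo = np.array(
                [
                    100.0
                    * (np.delete(pred, i).mean() - np.delete(obs, i).mean())
                    / np.delete(obs, i).mean()
                    for i in range(n)
                ]
            )
            se = float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
            rows.append(
                {
                    "scenario_id": scenario_id,
                    "mode": mode,
                    "n_replicates": n,
                    "mean_ra_obs": float(obs.mean()),
                    "mean_ra_pred": float(pred.mean()),
                    "signed_bias_pct": float(bias),
                    "jackknife_se": se,
                }
            )
    return pd.DataFrame(rows)
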