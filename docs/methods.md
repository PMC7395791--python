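# Methods

## The quantity being modelled

A polygenic score (PGS) built from the genome-wide-significant (GWS) SNPs
of a discovery GWAS in one population (population 1) is applied in a
sample of different ancestry (population 2). Writing `R_l^2` for the
squared correlation between score and phenotype in population *l*, the
package models the **relative accuracy** `RA = R2^2 / R1^2` rather than
either accuracy alone: the ratio does not require knowing the number of
causal variants, which cancels between numerator and denominator.

Under an additive model with `M_C` causal variants shared between
populations (effect correlation `rho_b`, heritabilities `h_l^2`), the RA
factorises into three terms:

```
RA  =  rho_b^2 h2^2 / h1^2                                    (effects)
    x  [ Sum_k m_k sqrt(p_k2 q_k2 / p_k1 q_k1) / Sum_k v_k ]^2  (LD+MAF)
    x  Sum_k p_k1 q_k1 b_k^2 / Sum_k p_k2 q_k2 b_k^2           (var PGS)
```

with `q = 1 - p`, `b_k` the discovery effect estimate of the k-th PGS-SNP,
and, for each PGS-SNP k,

- `v_k` = mean over the causal variants j near k of `r_{jk,1}^2`,
- `m_k` = mean of `r_{jk,1} r_{jk,2}`,

where `r_{jk,l}` is the signed genotype correlation between j and k in a
population-*l* reference panel. Three evaluation modes differ only in
which variants stand in for the causals:

- **known** — the true causal variants within 100 kb of each PGS-SNP
  (available in simulations);
- **heuristic** — *candidate* causal variants: reference variants within
  100 kb of the PGS-SNP with discovery-panel `r^2 > 0.45`, a rule drawn
  from reported fine-mapping precision of GWAS hits (lead SNPs lie within
  100 kb of the causal variant ~90% of the time at that LD level). If no
  variant qualifies, the PGS-SNP itself is the single candidate (r = 1);
- **naive** — the PGS-SNPs are taken to be causal (`m_k = v_k = 1`), so
  only MAF differences and the var(PGS) ratio remain. This mode ignores
  the cross-population decay of tagging and systematically overestimates
  RA on diverged populations; its gap to the other modes measures how
  much of the loss is LD rather than allele frequency.

Candidates are identified in the **discovery-ancestry** reference (GWS
SNPs arise from discovery LD); `r_{jk,2}` is then computed in the target
panel for those same pairs. The var(PGS) ratio always uses the closed
form `Sum p(1-p) b^2` (clumped SNPs are nearly independent, so
off-diagonal LD contributions are negligible), which keeps the whole
prediction computable from summary statistics plus two reference panels.
When target-population phenotype data are unavailable, `rho_b` and the
heritabilities default to 1 and the prediction quantifies only the
LD+MAF share of the RA.

Assumptions worth stating: causal variants are shared between populations
(ancestry-specific causals are the `rho_b < 1` limit); PGS-SNPs are
quasi-independent (enforced by clumping at r^2 <= 0.01); effects are
small enough that per-SNP `R^2` contributions add; reference panels are
of homogeneous ancestry matching discovery and target (admixed panels
are out of scope).

## Derived summaries

Loss of accuracy is `LOA = (1 - RA) x 100%`, and the share of the loss
the LD+MAF prediction explains is `100% x (1 - RA_pred) / (1 - RA_obs)`,
defined only when the observed RA is below 1. For binary traits the
observed-scale `R^2` is mapped to the liability scale with the Lee et al.
(2012) transformation from prevalence `K` and sample case fraction `P`
(for a population-based cohort `P = K` and the map is linear,
`R^2 K(1-K)/z^2`). Standard errors of observed RA and of the explained
proportion come from nonparametric bootstrap over individuals (default
1,000 replicates); averages across replicates or scenarios use
leave-one-out jackknife SEs.

## Synthetic two-population study

Real validation data (biobank-scale genotypes) are out of scope, so the
package ships a generator that reproduces the structural features the
theory responds to. Genotypes come from a two-stage block-mosaic scheme:

1. **Ancestral pools.** The genome is `n_blocks` LD blocks (default 100
   blocks of 100 variants spanning 200 kb each, separated by 5-Mb gaps so
   blocks are unlinked). Per block, K = 100 ancestral haplotypes are
   drawn by thresholding a first-order Gaussian autoregression along
   variants (decay scale 200 kb), giving within-haplotype allele
   correlation that decays with physical distance. Ancestral frequencies
   are uniform on (0.05, 0.95).
2. **Drifted mosaic sampling.** Each population receives its own mixing
   weights over pool members, drawn from a symmetric Dirichlet with
   concentration `alpha = (1/F - 1)/K` per 25-kb *drift unit*. This
   calibration makes the frequency variance around the pool frequency
   exactly `F q(1-q)` — Balding–Nichols drift — so two independently
   drifted populations have expected Hudson F_ST equal to the target `F`
   (realized values track the target with ~4% relative SD at the default
   layout). Individual haplotypes are mosaics of pool members: the copied
   haplotype is re-drawn with per-step probability `1 - exp(-d/L_l)`
   (population-specific LD scale `L_l`, defaults 100 kb for the discovery
   population and 50 kb for the target, mimicking the shorter LD of an
   African-ancestry target of a European-ancestry GWAS) and at every
   drift-unit boundary. Sharing the ancestral pool keeps LD *signs*
   consistent between populations — without this, cross-population
   tagging (and hence any PGS transfer) would collapse — while drifted
   weights and different switch rates make LD magnitudes diverge.

Variants below MAF 0.01 in either population are removed from both
panels, mirroring the common-variant filter used in cross-ancestry
analyses. Causal variants are drawn uniformly from the surviving
variants; effects are bivariate normal across populations with
correlation `rho_b` and marginal variance `c_l [2p(1-p)]^{S_l}`, the
constant `c_l` set so the expected explained variance is `h_l^2`. The
default `S = -1` makes each causal variant explain equal variance (the
strong-negative-selection architecture); `S` nearer 0 weakens the
MAF-effect coupling. Phenotypes are `y = g + e`, `e ~ N(0, 1 - h^2)`, so
`var(y) ~ 1`.

What the generator does **not** emulate: coalescent genealogies, mutation
/recombination-rate heterogeneity, admixture, rare variants, ancestry-
specific causal variants, gene-environment interaction, and genuinely
human LD (the effective LD range here is ~10-25 kb rather than the longer
and more heterogeneous blocks of real European genomes). Passing tests
therefore demonstrate internal consistency of theory and pipeline under
the model's own assumptions, not performance on real cohorts.

## Pipeline defaults

GWAS is per-variant OLS with intercept; p-values from the t distribution
with n-2 df (fixed for reproducibility; indistinguishable from the normal
approximation at GWAS n). Causal variants are excluded from the GWAS so
association signal comes from tagging only, as in the theory. Clumping is
the greedy PLINK-style algorithm at `p1 = p2 = 5e-8`, window 2,000 kb,
`r^2 > 0.01`, with the discovery panel as LD reference; equal p-values
are broken by (chromosome, bp) so results are row-order invariant.
Scoring sums counted-allele dosages times effects, flipping coding where
panels disagree; missing genotypes are mean-imputed (2p) to keep score
variance comparable across samples.

The default replicate study ("desk-scale grid") uses M = 10,000 variants,
N_discovery = 10,000, validation and target samples of 2,000, M_C = 200,
h^2 = 0.5 and target F_ST = 0.10, sized so that each causal variant has a
GWAS non-centrality of ~25, yielding tens of GWS SNPs per replicate and
stable RA estimates in minutes on one CPU; 30 replicates per scenario.
Observed RA per replicate is `R^2(target) / R^2(validation)` with both
held-out panels scored on the same PGS. Replicate seeds are
`base_seed + index`; all derived randomness flows through seed sequences
spawned from the replicate seed.

## Numerical choices and edge cases

- LD is the signed Pearson correlation of unphased genotype counts over
  pairwise-complete samples; monomorphic pairs are an error (undefined),
  windows are closed intervals in bp, positions 1-based.
- Hudson F_ST uses the two-population estimator with finite-sample
  correction (allele counts, i.e. 2x individuals) aggregated as a ratio
  of sums; variants monomorphic in both populations contribute nothing,
  variants with irreconcilable allele codings are dropped with a warning.
- The counted allele is the panel minor allele on read; cross-panel work
  aligns codings to the discovery orientation (swap -> flip coding,
  strand-complement attempted, otherwise dropped with a warning).
- GWAS p-values are floored at 1e-300 to stay in (0, 1]; a PGS-SNP that
  is monomorphic in either reference makes the heterozygosity ratio
  undefined and raises rather than returning infinity.
- A replicate with no GWS SNP is recorded with `M_T = 0` and excluded
  from bias summaries (with a logged count); a PGS-SNP with no known
  causal within 100 kb falls back to itself with a warning, which keeps
  the known-mode estimator defined at the cost of a small optimistic bias
  for that SNP.

## Known limitations

The heuristic candidate set weights all candidates equally; fine-mapping
posterior weights would be a natural refinement. The var(PGS) term is
always the closed form, never the empirical score variance; the two agree
to the extent clumping removed LD between PGS-SNPs. The mean-based
normalisation of the LD terms (means over candidates per PGS-SNP, in both
known and heuristic modes) matches the candidate-based estimator
definition; a sum-based variant would weight PGS-SNPs by their candidate
counts and coincides with the mean-based one when counts are equal.
Binary-trait evaluation supports the liability transformation, but the
bundled simulator is quantitative-only.
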