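"""Genotype panels and population-genetic primitives.

The central container is :class:`GenotypePanel`, an individuals-by-variants
matrix of minor-allele counts together with a variant map.  Everything
downstream — allele frequencies, pairwise LD, windowed LD scans, Hudson's
F_ST — operates on this container.

Conventions
-----------
* Genotypes are stored as ``int8`` counts of the *counted* allele
  (0, 1 or 2); missing calls are coded :data:`MISSING` (-1).
* After reading a panel from disk the counted allele is recoded to the
  minor allele *within that panel* (frequency ties at 0.5 keep the file
  orientation).
* Positions are 1-based, as in BIM/VCF, and strictly increasing within a
  chromosome.
* LD is the signed Pearson correlation of unphased genotype counts,
  computed over samples non-missing at both variants.
* Windows are closed intervals in base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

VARIANT_COLUMNS = ["variant_id", "chromosome", "bp", "counted_allele", "other_allele"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PanelFormatError(ValueError):
    """A genotype file does not parse under the named standard."""


@dataclass
class GenotypePanel:
    """Individuals x variants minor-allele-count matrix with a variant map.

    Parameters
    ----------
    population_label
        Free-form label for the population the samples were drawn from.
    sample_ids
        One id per row of ``genotypes``.
    variants
        Table with columns ``variant_id, chromosome, bp, counted_allele,
        other_allele``; one row per column of ``genotypes``, ordered by
        genomic coordinate.
    genotypes
        ``(n_samples, n_variants)`` int8 array of counted-allele counts in
        {0, 1, 2}, with -1 marking missing calls.
    """

    population_label: str
    sample_ids: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray
    _col_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        if g.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"genotype shape {g.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        self.genotypes = g
        if g.size and (g.max() > 2 or g.min() < -1):
            raise ValueError("genotype values must be 0, 1, 2 or -1 (missing)")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicated variant id: {dup!r}")
        same = self.variants["counted_allele"] == self.variants["other_allele"]
        if same.any():
            bad = self.variants.loc[same, "variant_id"].iloc[0]
            raise ValueError(f"counted and other allele identical at {bad!r}")
        for _, grp in self.variants.groupby("chromosome", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome "
                    f"{grp['chromosome'].iloc[0]!r}"
                )
        self._col_index = {v: i for i, v in enumerate(ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def col(self, variant_id: str) -> int:
        """Column index of a variant id (KeyError if absent)."""
        return self._col_index[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._col_index

    def as_float(self) -> np.ndarray:
        """Genotypes as float32 (missing -> NaN), cached on the panel."""
        cached = getattr(self, "_float_cache", None)
        if cached is None:
            cached = self.genotypes.astype(np.float32)
            cached[cached < 0] = np.nan
            object.__setattr__(self, "_float_cache", cached)
        return cached

    def subset_samples(self, rows: Sequence[int]) -> "GenotypePanel":
        rows = np.asarray(rows)
        return GenotypePanel(
            population_label=self.population_label,
            sample_ids=[self.sample_ids[i] for i in rows],
            variants=self.variants.copy(),
            genotypes=self.genotypes[rows, :],
        )

    def subset_variants(self, variant_ids: Iterable[str]) -> "GenotypePanel":
        cols = np.array([self.col(v) for v in variant_ids])
        order = np.sort(cols)
        return GenotypePanel(
            population_label=self.population_label,
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[order].reset_index(drop=True),
            genotypes=self.genotypes[:, order],
        )


@dataclass(frozen=True)
class LdPair:
    """Signed genotype correlation between two variants in one panel."""

    id_a: str
    id_b: str
    r: float
    population_label: str


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(panel: GenotypePanel) -> pd.DataFrame:
    """Counted-allele frequency per variant.

    Returns a table with columns ``variant_id, p, het, n_obs`` where ``p``
    is the mean count over non-missing genotypes divided by 2, ``het`` is
    p(1-p) heterozygosity-scale 2p(1-p), and ``n_obs`` is the number of
    non-missing samples.  Variants with all genotypes missing get
    ``p = NaN`` and should be excluded downstream.
    """
    if panel.n_variants == 0:
        raise ValueError("panel has no variants")
    g = panel.genotypes
    if g.size and g.min() >= 0:  # fast path: no missing calls
        n_obs = np.full(panel.n_variants, panel.n_samples, dtype=np.int64)
        total = g.sum(axis=0, dtype=np.int64)
    else:
        miss = g == MISSING
        n_obs = (~miss).sum(axis=0)
        total = np.where(miss, 0, g).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, total / (2.0 * np.maximum(n_obs, 1)), np.nan)
    if np.any(n_obs == 0):
        bad = panel.variants.loc[n_obs == 0, "variant_id"].tolist()
        warnings.warn(f"{len(bad)} variant(s) with all genotypes missing: {bad[:5]}")
    return pd.DataFrame(
        {
            "variant_id": panel.variants["variant_id"].to_numpy(),
            "p": p,
            "het": 2.0 * p * (1.0 - p),
            "n_obs": n_obs,
        }
    )


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def _ld_profile(panel: GenotypePanel, index_col: int, cols: np.ndarray) -> np.ndarray:
    """Pearson r between one column and several others, pairwise complete."""
    g = panel.genotypes
    x = g[:, index_col]
    Y = g[:, cols]
    if x.min() == MISSING or Y.min() == MISSING:
        xm = x == MISSING
        out = np.empty(len(cols))
        for i in range(len(cols)):
            y = Y[:, i]
            keep = ~(xm | (y == MISSING))
            out[i] = _pearson(x[keep], y[keep])
        return out
    xf = x.astype(np.float64)
    xf -= xf.mean()
    Yf = Y.astype(np.float64)
    Yf -= Yf.mean(axis=0)
    num = Yf.T @ xf
    den = np.sqrt((xf @ xf) * np.einsum("ij,ij->j", Yf, Yf))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return np.clip(r, -1.0, 1.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return np.nan
    xf = x.astype(np.float64) - x.mean()
    yf = y.astype(np.float64) - y.mean()
    den = np.sqrt((xf @ xf) * (yf @ yf))
    if den == 0:
        return np.nan
    return float(np.clip((xf @ yf) / den, -1.0, 1.0))


def ld_r(panel: GenotypePanel, id_a: str, id_b: str) -> LdPair:
    """Signed LD (genotype Pearson correlation) between two variants.

    The sign is consistent with the counted-allele orientation of the
    panel: flipping the coding of exactly one of the two variants negates
    ``r``.  Raises for variants monomorphic over the pairwise-complete
    samples, where the correlation is undefined.
    """
    r = _ld_profile(panel, panel.col(id_a), np.array([panel.col(id_b)]))[0]
    if np.isnan(r):
        raise ValueError(f"LD undefined between {id_a!r} and {id_b!r} (monomorphic)")
    return LdPair(id_a=id_a, id_b=id_b, r=float(r), population_label=panel.population_label)


def ld_window(
    panel: GenotypePanel,
    index_id: str,
    window_kb: float,
    include_index: bool = False,
) -> list[LdPair]:
    """LD of an index variant with every panel variant within a closed window.

    Returns one :class:`LdPair` for each same-chromosome variant with
    ``|bp - bp_index| <= window_kb * 1000`` (the index itself only when
    ``include_index``).  Variants where the correlation is undefined are
    skipped.
    """
    cols = window_cols(panel, index_id, window_kb, include_index)
    if len(cols) == 0:
        return []
    rs = _ld_profile(panel, panel.col(index_id), cols)
    ids = panel.variants["variant_id"].to_numpy()
    return [
        LdPair(index_id, ids[c], float(r), panel.population_label)
        for c, r in zip(cols, rs)
        if not np.isnan(r)
    ]


def window_cols(
    panel: GenotypePanel,
    index_id: str,
    window_kb: float,
    include_index: bool = False,
) -> np.ndarray:
    """Column indices of variants within ``window_kb`` of the index variant."""
    i = panel.col(index_id)
    chrom = panel.variants["chromosome"].to_numpy()
    bp = panel.variants["bp"].to_numpy()
    mask = (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_kb * 1000.0)
    if not include_index:
        mask[i] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def hudson_fst_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Hudson numerator and denominator.

    ``n1``/``n2`` are sampled allele counts (twice the number of diploid
    individuals).  The numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) -
    p2(1-p2)/(n2-1)`` removes finite-sample variance; the denominator is
    ``p1(1-p2) + p2(1-p1)``.  Pass ``np.inf`` for the population (infinite
    sample) quantities.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    num = np.where(np.isinf(n1), (p1 - p2) ** 2 - p2 * (1 - p2) / (n2 - 1), num)
    num = np.where(np.isinf(n2) & np.isinf(n1), (p1 - p2) ** 2, num)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(
    panel1: GenotypePanel,
    panel2: GenotypePanel,
    variant_ids: Sequence[str] | None = None,
) -> float:
    """Hudson's two-population F_ST, aggregated as a ratio of averages.

    Variants are matched by id between the two panels and coding
    differences are reconciled (a variant counted on opposite alleles
    contributes ``1 - p`` for the second panel; variants whose allele
    pairs cannot be reconciled, or with fewer than two observed samples in
    either panel, are excluded with a warning).  Monomorphic-in-both
    variants contribute nothing to either sum.
    """
    t1 = panel1.variants.merge(allele_frequencies(panel1), on="variant_id")
    t2 = panel2.variants.merge(allele_frequencies(panel2), on="variant_id")
    m = t1.merge(t2, on="variant_id", suffixes=("_1", "_2"))
    if variant_ids is not None:
        wanted = pd.Index(variant_ids)
        absent = wanted.difference(m["variant_id"])
        if len(absent):
            raise KeyError(f"variant {absent[0]!r} absent from one of the panels")
        m = m[m["variant_id"].isin(set(wanted))]

    same = (m["counted_allele_2"] == m["counted_allele_1"]) & (
        m["other_allele_2"] == m["other_allele_1"]
    )
    swapped = (m["counted_allele_2"] == m["other_allele_1"]) & (
        m["other_allele_2"] == m["counted_allele_1"]
    )
    enough = (m["n_obs_1"] >= 2) & (m["n_obs_2"] >= 2)
    usable = (same | swapped) & enough
    if (~usable).any():
        dropped = m.loc[~usable, "variant_id"].tolist()
        warnings.warn(
            f"excluded {len(dropped)} variant(s) from F_ST "
            f"(allele mismatch or <2 samples): {dropped[:5]}"
        )
        m = m[usable]
        swapped = swapped[usable]
    if m.empty:
        raise ValueError("no usable variants for F_ST")
    p2v = np.where(swapped, 1.0 - m["p_2"], m["p_2"])
    num, den = hudson_fst_components(
        m["p_1"].to_numpy(),
        2.0 * m["n_obs_1"].to_numpy(),
        p2v,
        2.0 * m["n_obs_2"].to_numpy(),
    )
    den_sum = den.sum()
    if den_sum <= 0:
        raise ValueError("all variants monomorphic in both panels; F_ST undefined")
    return float(num.sum() / den_sum)


def hudson_fst_from_stats(stats1: pd.DataFrame, stats2: pd.DataFrame) -> float:
    """Hudson F_ST from two allele-frequency tables sharing coding.

    Intended for panels generated by the bundled simulator, where both
    populations share variant ids and counted alleles; avoids recomputing
    frequencies when they are already in hand.
    """
    m = stats1.merge(stats2, on="variant_id", suffixes=("_1", "_2"))
    m = m[(m["n_obs_1"] >= 2) & (m["n_obs_2"] >= 2)]
    num, den = hudson_fst_components(
        m["p_1"].to_numpy(),
        2.0 * m["n_obs_1"].to_numpy(),
        m["p_2"].to_numpy(),
        2.0 * m["n_obs_2"].to_numpy(),
    )
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# coding alignment
# ---------------------------------------------------------------------------

def align_to(panel: GenotypePanel, reference_variants: pd.DataFrame) -> GenotypePanel:
    """Align a panel's allele coding to a reference orientation.

    For every variant shared with ``reference_variants`` (matched by id):
    if the counted/other alleles agree the variant is untouched; if they
    are swapped the genotype coding is flipped (x -> 2 - x) and the allele
    columns swapped; if they agree only after strand complementation the
    alleles are complemented first; otherwise the variant is dropped with
    a warning.  Variants absent from the reference are kept as-is.
    """
    ref = reference_variants.set_index("variant_id")
    variants = panel.variants.copy()
    g = panel.genotypes.copy()
    drop: list[int] = []
    for i, row in variants.iterrows():
        vid = row["variant_id"]
        if vid not in ref.index:
            continue
        want = (ref.loc[vid, "counted_allele"], ref.loc[vid, "other_allele"])
        have = (row["counted_allele"], row["other_allele"])
        comp = tuple(_COMPLEMENT.get(a, "?") for a in have)
        if have == want:
            continue
        if comp == want:
            variants.loc[i, ["counted_allele", "other_allele"]] = list(comp)
            continue
        if have == (want[1], want[0]) or comp == (want[1], want[0]):
            miss = g[:, i] == MISSING
            g[:, i] = 2 - g[:, i]
            g[miss, i] = MISSING
            variants.loc[i, ["counted_allele", "other_allele"]] = [want[0], want[1]]
            continue
        drop.append(i)
    if drop:
        warnings.warn(
            f"dropping {len(drop)} variant(s) with irreconcilable alleles: "
            f"{variants.loc[drop, 'variant_id'].tolist()[:5]}"
        )
        keep = np.setdiff1d(np.arange(len(variants)), drop)
        variants = variants.iloc[keep]
        g = g[:, keep]
    return GenotypePanel(panel.population_label, list(panel.sample_ids), variants, g)


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM I/O
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes, variant-major: 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK BED/BIM/FAM (A1 = counted allele)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = pd.DataFrame(
        {
            "chrom": panel.variants["chromosome"],
            "id": panel.variants["variant_id"],
            "cm": 0,
            "bp": panel.variants["bp"],
            "a1": panel.variants["counted_allele"],
            "a2": panel.variants["other_allele"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "phe": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = panel.n_samples
    n_bytes = (n + 3) // 4
    codes = np.empty_like(panel.genotypes, dtype=np.uint8)
    for count, code in _COUNT_TO_CODE.items():
        codes[panel.genotypes == count] = code
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((panel.n_variants, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.astype(np.uint8).tobytes())


def _read_plink(prefix: Path, population_label: str) -> GenotypePanel:
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    bed_path = prefix.with_suffix(".bed")
    for p in (bim_path, fam_path, bed_path):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        bim = pd.read_csv(
            bim_path,
            sep=r"\s+",
            header=None,
            names=["chrom", "id", "cm", "bp", "a1", "a2"],
            dtype={"chrom": str, "id": str, "a1": str, "a2": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelFormatError(f"malformed BIM file {bim_path}: {exc}") from exc
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam.iloc[:, 1].tolist()

    n = len(sample_ids)
    m = len(bim)
    n_bytes = (n + 3) // 4
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PanelFormatError(f"{bed_path} is not a variant-major PLINK BED file")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * n_bytes:
        raise PanelFormatError(
            f"{bed_path}: expected {m * n_bytes} data bytes, found {body.size}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 3
    codes[:, 1::4] = (body >> 2) & 3
    codes[:, 2::4] = (body >> 4) & 3
    codes[:, 3::4] = (body >> 6) & 3
    g = _CODE_TO_COUNT[codes[:, :n]].T  # samples x variants, counts of A1

    variants = pd.DataFrame(
        {
            "variant_id": bim["id"],
            "chromosome": bim["chrom"],
            "bp": bim["bp"].astype(np.int64),
            "counted_allele": bim["a1"],
            "other_allele": bim["a2"],
        }
    )
    return _finalize_read(population_label, sample_ids, variants, g)


def _read_vcf(path: Path, population_label: str) -> GenotypePanel:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files") from exc
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise PanelFormatError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    rows = []
    geno_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise PanelFormatError(
                f"{path}: variant {rec.ID or rec.POS} is not biallelic"
            )
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        geno_rows.append(gt)
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chromosome": str(rec.CHROM),
                "bp": int(rec.POS),
                "counted_allele": rec.ALT[0],
                "other_allele": rec.REF,
            }
        )
    if not rows:
        raise PanelFormatError(f"{path}: no variant records")
    variants = pd.DataFrame(rows)
    g = np.vstack(geno_rows).T  # samples x variants, ALT counts
    return _finalize_read(population_label, sample_ids, variants, g)


def _finalize_read(
    population_label: str,
    sample_ids: list[str],
    variants: pd.DataFrame,
    g: np.ndarray,
) -> GenotypePanel:
    """Sort by coordinate and recode so the counted allele is the panel minor."""
    order = np.lexsort((variants["bp"].to_numpy(), variants["chromosome"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    g = np.ascontiguousarray(g[:, order])

    miss = g == MISSING
    n_obs = (~miss).sum(axis=0)
    total = np.where(miss, 0, g).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = total / (2.0 * np.maximum(n_obs, 1))
    flip = (p > 0.5) & (n_obs > 0)
    if flip.any():
        cols = np.flatnonzero(flip)
        g[:, cols] = 2 - g[:, cols]
        g[miss] = MISSING
        va = variants.loc[flip, "counted_allele"].copy()
        variants.loc[flip, "counted_allele"] = variants.loc[flip, "other_allele"]
        variants.loc[flip, "other_allele"] = va
    return GenotypePanel(population_label, sample_ids, variants, g)


def read_panel(path: str | Path, format: str, population_label: str) -> GenotypePanel:
    """Read a genotype panel from PLINK (``format="plink"``, path = prefix)
    or VCF (``format="vcf"``).

    On read the counted allele is recoded to the minor allele within the
    panel and variants are ordered by genomic coordinate.
    """
    path = Path(path)
    if format == "plink":
        return _read_plink(path, population_label)
    if format == "vcf":
        return _read_vcf(path, population_label)
    raise ValueError(f"unknown format {format!r}; expected 'plink' or 'vcf'")
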