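"""Polygenic risk score construction: harmonization, thresholding, pruning, scoring.

The pipeline mirrors standard clumping+thresholding practice: GWAS summary
statistics are harmonized to the cohort's genotypes with respect to
reference/alternate allele and strand (strand-ambiguous A/T and C/G variants
dropped), subset to p < 0.05, LD-pruned to r^2 <= 0.2 within a 500-kb window
with higher-frequency variants retained first, and the surviving weights are
dotted with per-person effect-allele dosages, mean-imputing missing
genotypes over the scored cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.05
R2_MAX = 0.2
WINDOW_BP = 500_000

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

SUMSTATS_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p"]


@dataclass
class Genotypes:
    """Cohort genotypes: a variant table plus an alt-allele dosage matrix.

    ``dosages`` is variants x participants, entries in [0, 2] or NaN for
    missing.  ``variants`` has columns id, chrom, pos, ref_allele,
    alt_allele and is positionally aligned with the dosage rows.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    participant_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.variants) != self.dosages.shape[0]:
            raise ValueError("variant table and dosage matrix are misaligned")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages out of [0, 2]")

    @property
    def alt_freq(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=1) / 2.0


def read_dosage_matrix(path: str | Path) -> Genotypes:
    """Read a dosage CSV: columns id, chrom, pos, ref_allele, alt_allele, then one per participant."""
    df = pd.read_csv(path)
    meta_cols = ["id", "chrom", "pos", "ref_allele", "alt_allele"]
    participants = [c for c in df.columns if c not in meta_cols]
    return Genotypes(
        variants=df[meta_cols].reset_index(drop=True),
        dosages=df[participants].to_numpy(dtype=float),
        participant_ids=participants,
    )


def write_dosage_matrix(geno: Genotypes, path: str | Path) -> None:
    out = geno.variants.copy()
    for j, pid in enumerate(geno.participant_ids):
        out[pid] = geno.dosages[:, j]
    out.to_csv(path, index=False)


def read_vcf(path: str | Path) -> Genotypes:
    """Read genotypes from a VCF, preferring DS (dosage) over GT fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, dosage_rows = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("skipping multi-allelic variant at %s:%d", v.CHROM, v.POS)
            continue
        rows.append(
            {"id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": str(v.CHROM), "pos": v.POS,
             "ref_allele": v.REF, "alt_allele": v.ALT[0]}
        )
        ds = v.format("DS")
        if ds is not None:
            d = ds.astype(float).ravel()
        else:
            gt = np.asarray(v.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            d = np.where(gt == 3, 2.0, gt)
            d[gt == 2] = np.nan
        dosage_rows.append(d)
    return Genotypes(pd.DataFrame(rows), np.array(dosage_rows, dtype=float), ids)


@dataclass
class PRSModel:
    """Thresholded, pruned variant set with effect weights and filter provenance."""

    variants: pd.DataFrame  # id, chrom, pos, effect_allele, weight, p, geno_index, flip
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _AMBIGUOUS


def _drop_duplicate_positions(df: pd.DataFrame, label: str) -> pd.DataFrame:
    key = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    dup = key.duplicated(keep="first")
    if dup.any():
        logger.warning("%s: dropping %d duplicate chrom:pos entries", label, int(dup.sum()))
    return df[~dup]


def harmonize(sumstats: pd.DataFrame, geno: Genotypes) -> tuple[pd.DataFrame, dict[str, int]]:
    """Match summary-statistic variants to cohort genotypes by chrom:pos.

    Strand-ambiguous variants (A/T, C/G) and positions absent from the
    cohort are removed.  When the summary alleles match ref/alt directly the
    effect allele is mapped onto the genotype orientation (``flip=True``
    when the effect allele is the genotype ref, so effect dosage = 2 - alt
    dosage); when they only match after complementing both alleles the
    variant is strand-flipped then mapped; anything else is removed as
    mismatched.  Duplicated positions keep the first occurrence.

    Returns the matched table plus counts removed at each stage.
    """
    ss = sumstats.copy()
    gv = geno.variants.reset_index(names="geno_index").copy()
    for df in (ss, gv):
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(int)
    ss = _drop_duplicate_positions(ss, "sumstats")
    gv = _drop_duplicate_positions(gv, "genotypes")
    counts = {"input": len(sumstats)}

    ambiguous = ss.apply(lambda r: _is_ambiguous(r["effect_allele"], r["other_allele"]), axis=1)
    counts["ambiguous"] = int(ambiguous.sum())
    ss = ss[~ambiguous]

    merged = ss.merge(gv, on=["chrom", "pos"], how="left", suffixes=("", "_geno"))
    unmatched = merged["geno_index"].isna()
    counts["unmatched_position"] = int(unmatched.sum())
    merged = merged[~unmatched]

    rows = []
    n_mismatch = 0
    for r in merged.itertuples(index=False):
        ea, oa = r.effect_allele.upper(), r.other_allele.upper()
        ref, alt = r.ref_allele.upper(), r.alt_allele.upper()
        flip = None
        for e, o in ((ea, oa), (_COMPLEMENT.get(ea), _COMPLEMENT.get(oa))):
            if e == alt and o == ref:
                flip = False
                break
            if e == ref and o == alt:
                flip = True
                break
        if flip is None:
            n_mismatch += 1
            continue
        rows.append(
            {"id": r.id, "chrom": r.chrom, "pos": r.pos,
             "effect_allele": alt if not flip else ref,
             "weight": r.beta, "p": r.p,
             "geno_index": int(r.geno_index), "flip": flip}
        )
    counts["allele_mismatch"] = n_mismatch
    matched = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "effect_allele", "weight", "p", "geno_index", "flip"]
    )
    counts["matched"] = len(matched)
    return matched, counts


def threshold(matched: pd.DataFrame, p_cut: float = P_THRESHOLD) -> pd.DataFrame:
    """Keep variants with p strictly below ``p_cut``."""
    return matched[matched["p"] < p_cut].reset_index(drop=True)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        logger.warning("zero dosage variance; treating r^2 as 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def prune(
    variants: pd.DataFrame,
    geno: Genotypes,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
    provenance: dict[str, int] | None = None,
) -> PRSModel:
    """Frequency-informed greedy LD pruning.

    Variants are visited in order of descending minor-allele frequency
    (computed from the cohort's dosages; ties broken by chromosome then
    position); each retained variant eliminates later-visited variants on
    the same chromosome within ±``window_bp`` whose dosage r^2 with it
    exceeds ``r2_max``.  The survivors constitute the PRS model.
    """
    prov = dict(provenance or {})
    prov["pre_prune"] = len(variants)
    if variants.empty:
        prov["pruned_ld"] = 0
        return PRSModel(variants.reset_index(drop=True), prov)

    v = variants.reset_index(drop=True).copy()
    eaf = np.nanmean(geno.dosages[v["geno_index"].to_numpy()], axis=1) / 2.0
    v["maf"] = np.minimum(eaf, 1.0 - eaf)
    order = v.sort_values(
        ["maf", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).index.to_list()

    removed: set[int] = set()
    kept: list[int] = []
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in order:
            if j == i or j in removed or j in kept:
                continue
            if v.at[j, "chrom"] != v.at[i, "chrom"]:
                continue
            if abs(int(v.at[j, "pos"]) - int(v.at[i, "pos"])) > window_bp:
                continue
            r2 = _pairwise_r2(
                geno.dosages[int(v.at[i, "geno_index"])],
                geno.dosages[int(v.at[j, "geno_index"])],
            )
            if r2 > r2_max:
                removed.add(j)
    prov["pruned_ld"] = len(removed)
    out = v.loc[sorted(kept)].drop(columns=["maf"]).reset_index(drop=True)
    prov["final"] = len(out)
    return PRSModel(out, prov)


def score(
    model: PRSModel,
    geno: Genotypes,
    standardize: bool = True,
) -> pd.Series:
    """Per-participant PRS: sum of weight x effect-allele dosage.

    Missing dosages are imputed with the variant's mean dosage over the
    scored cohort.  With ``standardize=True`` (the default) scores are
    z-scored across participants, so downstream regression coefficients are
    per-SD-of-PRS.
    """
    n = len(geno.participant_ids)
    if len(model) == 0:
        return pd.Series(np.zeros(n), index=geno.participant_ids, name="prs")
    idx = model.variants["geno_index"].to_numpy()
    if idx.max() >= geno.dosages.shape[0]:
        raise ValueError("model variant absent from genotypes")
    d = geno.dosages[idx].copy()
    flip = model.variants["flip"].to_numpy(dtype=bool)
    d[flip] = 2.0 - d[flip]
    means = np.nanmean(d, axis=1)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.broadcast_to(means[:, None], d.shape)[nan_mask]
    w = model.variants["weight"].to_numpy(dtype=float)
    s = w @ d
    if standardize:
        sd = s.std()
        if sd > 0:
            s = (s - s.mean()) / sd
    return pd.Series(s, index=geno.participant_ids, name="prs")


def build_prs(
    sumstats: pd.DataFrame,
    geno: Genotypes,
    p_cut: float = P_THRESHOLD,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
    standardize: bool = True,
) -> tuple[pd.Series, PRSModel]:
    """Full harmonize -> threshold -> prune -> score pipeline."""
    matched, counts = harmonize(sumstats, geno)
    kept = threshold(matched, p_cut)
    counts["below_p_threshold"] = len(kept)
    model = prune(kept, geno, r2_max=r2_max, window_bp=window_bp, provenance=counts)
    return score(model, geno, standardize=standardize), model
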