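"""Genetic risk scores from external GWAS summary statistics.

A genetic risk score (GRS) for a subject is the sum over selected variants
of effect-allele dosage times the published effect size. Variant selection
follows the standard p-value-thresholding pipeline: drop the extended APOE
region, LD-clump the remaining summary statistics against a genotype
reference panel (keeping only the most significant variant per correlated
block within a physical window), then score at a ladder of p-value
thresholds. Association of the scores with outcomes is corrected for the
effective number of independent tests (simpleM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "APOE_REGION",
    "GrsConfig",
    "default_thresholds",
    "exclude_region",
    "ld_clump",
    "compute_grs",
    "build_grs_table",
    "simpleM_meff",
    "grs_association",
]

# Extended APOE locus, hg19 coordinates in bp (closed interval).
APOE_REGION = ("19", 44_400_000, 46_500_000)

SUMSTAT_COLUMNS = ("id", "chrom", "pos", "effect_allele", "beta", "p")


def default_thresholds(n: int = 15, low: float = 1e-5, high: float = 0.95) -> np.ndarray:
    """Log-spaced ladder of p-value inclusion thresholds (ascending)."""
    return np.geomspace(low, high, n)


from dataclasses import dataclass, field


@dataclass
class GrsConfig:
    """Risk-score construction settings.

    Fifteen log-spaced p-value thresholds spanning 1e-5 to 0.95, LD
    clumping at r^2 0.2 within 1000 kb, and exclusion of the extended APOE
    region on chromosome 19 (hg19 coordinates).
    """

    thresholds: np.ndarray = field(default_factory=default_thresholds)
    clump_r2: float = 0.2
    clump_kb: float = 1000.0
    exclusion_region: tuple = APOE_REGION

    def __post_init__(self):
        t = np.asarray(self.thresholds, float)
        if np.any((t <= 0) | (t > 1)):
            raise ValueError("thresholds must lie in (0, 1]")
        if not 0 < self.clump_r2 <= 1:
            raise ValueError("clump_r2 must lie in (0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")


def build_grs_table(stats: pd.DataFrame, genotypes,
                    config: GrsConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Risk scores at every threshold of the p-value ladder.

    Applies the region exclusion once, then per threshold LD-clumps and
    scores. Returns (scores DataFrame, subjects x thresholds) and a dict
    threshold -> number of variants in that score. Variant counts are
    non-increasing as the threshold decreases.
    """
    cfg = config or GrsConfig()
    kept = exclude_region(stats, cfg.exclusion_region)
    scores = {}
    counts = {}
    for thr in sorted(np.asarray(cfg.thresholds, float), reverse=True):
        idx = ld_clump(kept, genotypes, thr, r2=cfg.clump_r2, kb=cfg.clump_kb)
        counts[thr] = len(idx)
        scores[thr] = compute_grs(genotypes, kept, idx)
    return pd.DataFrame(scores), counts


def _check_sumstats(stats: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMSTAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if stats["id"].duplicated().any():
        raise ValueError("duplicate variant ids in summary statistics")
    p = stats["p"].to_numpy(float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("summary p-values must lie in (0, 1]")
    return stats


def exclude_region(stats: pd.DataFrame, region: tuple = APOE_REGION) -> pd.DataFrame:
    """Remove variants inside a chrom:[start, end] region (bp, closed)."""
    _check_sumstats(stats)
    chrom, start, end = region
    inside = ((stats["chrom"].astype(str) == str(chrom))
              & (stats["pos"] >= start) & (stats["pos"] <= end))
    return stats[~inside].reset_index(drop=True)


def ld_clump(stats: pd.DataFrame, reference, p_threshold: float,
             r2: float = 0.2, kb: float = 1000.0) -> list:
    """Greedy LD clumping against a genotype reference panel.

    Restricts to variants with p <= threshold, then repeatedly takes the
    smallest-p unclaimed variant as an index variant and claims every
    unclaimed variant on the same chromosome within +-kb that has squared
    dosage correlation >= r2 with it. Returns the index variant ids in
    selection order. Variants absent from the reference are skipped.
    """
    _check_sumstats(stats)
    sel = stats[stats["p"] <= p_threshold].copy()
    ref_ids = {vid: i for i, vid in enumerate(reference.variants["id"])}
    sel = sel[sel["id"].isin(ref_ids)]
    sel = sel.sort_values(["p", "id"]).reset_index(drop=True)
    window = kb * 1000.0
    claimed = np.zeros(len(sel), bool)
    chroms = sel["chrom"].astype(str).to_numpy()
    pos = sel["pos"].to_numpy(float)
    index_ids = []
    dosages = reference.dosages
    for i in range(len(sel)):
        if claimed[i]:
            continue
        claimed[i] = True
        vid = sel.loc[i, "id"]
        index_ids.append(vid)
        gi = dosages[:, ref_ids[vid]]
        near = np.where(~claimed & (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window))[0]
        for j in near:
            gj = dosages[:, ref_ids[sel.loc[j, "id"]]]
            ok = ~np.isnan(gi) & ~np.isnan(gj)
            if ok.sum() < 2 or np.std(gi[ok]) == 0 or np.std(gj[ok]) == 0:
                continue
            r = np.corrcoef(gi[ok], gj[ok])[0, 1]
            if r * r >= r2:
                claimed[j] = True
    return index_ids


def compute_grs(genotypes, stats: pd.DataFrame, index_ids) -> pd.Series:
    """Per-subject risk score: sum of effect-allele dosage x effect size.

    The effect allele is reconciled to the dosage coding (dosage counts
    allele1; when the effect allele is allele2 the dosage is flipped to
    2 - dosage). Missing dosages are imputed with the variant's mean
    dosage (2 x allele frequency).
    """
    _check_sumstats(stats)
    stats = stats.set_index("id")
    scores = np.zeros(genotypes.n_subjects)
    bad = []
    vmeta = genotypes.variants.set_index("id")
    for vid in index_ids:
        dos = genotypes.dosage_for(vid)
        a1 = vmeta.loc[vid, "a1"]
        a2 = vmeta.loc[vid, "a2"]
        eff = stats.loc[vid, "effect_allele"]
        if eff == a1:
            x = dos
        elif eff == a2:
            x = 2.0 - dos
        else:
            bad.append(vid)
            continue
        mean_dos = np.nanmean(x)
        x = np.where(np.isnan(x), mean_dos, x)
        scores = scores + x * float(stats.loc[vid, "beta"])
    if bad:
        raise ValueError(f"effect allele matches neither dosage allele for: {bad}")
    return pd.Series(scores, index=genotypes.subject_ids, name="grs")


def simpleM_meff(corr: np.ndarray, var_explained: float = 0.995) -> int:
    """Effective number of independent tests (simpleM).

    Eigendecomposes the correlation matrix of the tested items and returns
    the smallest k whose top-k eigenvalues explain at least
    ``var_explained`` of the total variance.
    """
    C = np.asarray(corr, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    w = np.linalg.eigvalsh(C)[::-1]
    if w[-1] < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    frac = np.cumsum(w) / w.sum()
    return int(np.searchsorted(frac, var_explained - 1e-12) + 1)


def grs_association(scores: pd.DataFrame, outcome: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    binary: bool | None = None) -> pd.DataFrame:
    """Association of risk scores (one column per threshold) with an outcome.

    Quantitative outcomes use a linear model, binary ones logistic
    regression; ``binary=None`` auto-detects a two-level outcome. Returns a
    per-threshold table of coefficient, p-value and the number of variants
    is left to the caller's score metadata. Perfect separation in a
    logistic fit is flagged with p = NaN.
    """
    ids = scores.index
    y = outcome.loc[ids].to_numpy(float)
    C = covariates.loc[ids].to_numpy(float) if covariates is not None else np.empty((len(ids), 0))
    if binary is None:
        binary = len(np.unique(y)) == 2
    rows = []
    for col in scores.columns:
        s = scores[col].to_numpy(float)
        X = sm.add_constant(np.column_stack([s, C]))
        if binary:
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit((y == np.max(y)).astype(float), X).fit(disp=0, maxiter=200)
                coef, p = fit.params[1], fit.pvalues[1]
                if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
                    p = np.nan
            except Exception:
                coef, p = np.nan, np.nan
        else:
            fit = sm.OLS(y, X).fit()
            coef, p = fit.params[1], fit.pvalues[1]
        rows.append((col, float(coef), float(p)))
    return pd.DataFrame(rows, columns=["threshold", "coef", "p"])
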