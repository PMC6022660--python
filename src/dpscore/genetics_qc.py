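"""Variant- and subject-level genotype quality control.

Implements hard-calling from genotype posterior probabilities, per-variant
statistics (MAF, call rate, Hardy-Weinberg exact test), the standard
filtering cascade (MAF, call rate, HWE, then subject missingness), and
GRM-based relatedness pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "harden_calls",
    "hwe_exact_test",
    "hwe_het_distribution",
    "variant_stats",
    "qc_filter",
    "relatedness_prune",
]


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with variant metadata.

    Dosages are counts of allele1 in {0, 1, 2}; missing calls are NaN.
    ``variants`` has columns id, chrom, pos (1-based), a1, a2 and
    optionally maf.
    """

    dosages: np.ndarray
    subject_ids: list
    variants: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.subject_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match ids/variants")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        if (self.variants["pos"].to_numpy() <= 0).any():
            raise ValueError("variant positions must be positive (1-based)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, subject_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, vi)],
            subject_ids=[self.subject_ids[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
        )

    def dosage_for(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[:, int(idx[0])]

    @classmethod
    def from_tsv(cls, genotypes_path, variants_path) -> "GenotypeMatrix":
        g = pd.read_csv(genotypes_path, sep="\t", index_col=0)
        v = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        return cls(dosages=g.to_numpy(float), subject_ids=list(g.index),
                   variants=v)


def harden_calls(posteriors: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Hard genotype calls from class posterior probabilities.

    ``posteriors`` has shape (..., 3), ordered as P(dosage 0), P(1), P(2).
    The call is the argmax class when its posterior reaches the threshold
    (boundary inclusive), otherwise missing (NaN).
    """
    p = np.asarray(posteriors, float)
    if p.shape[-1] != 3:
        raise ValueError("posterior array must have 3 genotype classes in the last axis")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("posterior triples must be non-negative and sum to 1")
    best = np.argmax(p, axis=-1).astype(float)
    pmax = np.max(p, axis=-1)
    best[pmax < threshold] = np.nan
    return best


def hwe_het_distribution(n_total: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact HWE distribution of heterozygote counts given allele counts.

    Returns (het_counts, probabilities) for all heterozygote counts
    compatible with ``n_minor`` minor alleles among ``n_total`` diploid
    genotypes, computed by the standard stable recurrence
    P(h+2)/P(h) = 4 a b / ((h+2)(h+1)) with a, b the implied homozygote
    counts.
    """
    rare = int(n_minor)
    n = int(n_total)
    if rare > n:  # convention: work with the rarer allele
        rare = 2 * n - rare
    hets = np.arange(rare % 2, rare + 1, 2)
    if len(hets) == 0:
        return hets, np.array([])
    logp = np.zeros(len(hets))
    for i in range(len(hets) - 1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # ratio P(h+2)/P(h)
        logp[i + 1] = logp[i] + np.log(4.0 * hom_r * hom_c) - np.log((h + 2.0) * (h + 1.0))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact test of Hardy-Weinberg equilibrium on genotype counts.

    Two-sided exact p-value: the summed probability, over all heterozygote
    counts compatible with the observed allele counts, of tables no more
    probable than the observed one.
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype count")
    n = n0 + n1 + n2
    if n == 0:
        return float("nan")
    n_minor = min(2 * n0 + n1, 2 * n2 + n1)
    hets, probs = hwe_het_distribution(n, n_minor)
    p_obs = probs[np.searchsorted(hets, n1)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def variant_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAF, call rate, genotype counts and HWE exact p-value.

    All-missing variants get call_rate 0 and NaN maf / hwe_p.
    """
    d = matrix.dosages
    n_subj = matrix.n_subjects
    rows = []
    for v in range(matrix.n_variants):
        col = d[:, v]
        obs = col[~np.isnan(col)]
        n_obs = len(obs)
        if n_obs == 0:
            rows.append((np.nan, 0.0, 0, 0, 0, np.nan))
            continue
        n0 = int((obs == 0).sum())
        n1 = int((obs == 1).sum())
        n2 = int((obs == 2).sum())
        af1 = (2 * n2 + n1) / (2.0 * n_obs)  # frequency of the allele dosage counts
        maf = min(af1, 1.0 - af1)
        rows.append((maf, n_obs / n_subj, n0, n1, n2, hwe_exact_test(n0, n1, n2)))
    stats = pd.DataFrame(rows, columns=["maf", "call_rate", "n0", "n1", "n2", "hwe_p"])
    stats.insert(0, "id", matrix.variants["id"].to_numpy())
    return stats


def qc_filter(matrix: GenotypeMatrix, maf_min: float = 0.05, min_call_rate: float = 0.90,
              hwe_p_min: float = 5.7e-7, subject_missing_max: float = 0.10):
    """Standard genotype QC cascade.

    Variants failing the MAF, call-rate or HWE rule are removed first; then
    subjects missing ``subject_missing_max`` or more of the remaining
    genotypes are removed. Returns (filtered matrix, report dict).
    """
    stats = variant_stats(matrix)
    fail_maf = (stats["maf"].isna() | (stats["maf"] < maf_min)).to_numpy()
    fail_rate = (stats["call_rate"] < min_call_rate).to_numpy()
    fail_hwe = (stats["hwe_p"].isna() | (stats["hwe_p"] < hwe_p_min)).to_numpy()
    keep_v = ~(fail_maf | fail_rate | fail_hwe)
    report = {
        "n_variants_in": matrix.n_variants,
        "removed_maf": [str(i) for i in stats.loc[fail_maf, "id"]],
        "removed_call_rate": [str(i) for i in stats.loc[fail_rate & ~fail_maf, "id"]],
        "removed_hwe": [str(i) for i in stats.loc[fail_hwe & ~fail_maf & ~fail_rate, "id"]],
    }
    if keep_v.sum() == 0:
        raise ValueError(f"no variants survive QC; report: {report}")
    out = matrix.subset(variant_idx=np.where(keep_v)[0])
    miss = np.isnan(out.dosages).mean(axis=1)
    keep_s = miss < subject_missing_max
    report["removed_subjects"] = [out.subject_ids[i] for i in np.where(~keep_s)[0]]
    report["n_variants_out"] = int(keep_v.sum())
    report["n_subjects_out"] = int(keep_s.sum())
    if keep_s.sum() == 0:
        raise ValueError(f"no subjects survive QC; report: {report}")
    return out.subset(subject_idx=np.where(keep_s)[0]), report


def compute_grm(matrix: GenotypeMatrix) -> np.ndarray:
    """Genetic relationship matrix from standardized dosages.

    A_jk = mean over variants of (x_j - 2p)(x_k - 2p) / (2p(1-p)); missing
    dosages are mean-imputed (contributing zero after centring).
    Monomorphic variants are skipped.
    """
    d = matrix.dosages
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() == 0:
        raise ValueError("no polymorphic variants for GRM computation")
    x = d[:, poly]
    p = p[poly]
    z = (np.where(np.isnan(x), 2 * p, x) - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (z @ z.T) / poly.sum()


def relatedness_prune(matrix: GenotypeMatrix, cutoff: float = 0.1) -> list:
    """Greedy relatedness pruning on the GRM.

    While any off-diagonal relatedness exceeds the cutoff, drop the member
    of the worst pair with the larger total relatedness (ties broken by id
    order, the later id dropped). Returns the kept subject ids.
    """
    grm = compute_grm(matrix)
    n = grm.shape[0]
    active = np.ones(n, bool)
    off = grm.copy()
    np.fill_diagonal(off, 0.0)
    while True:
        sub = np.where(active)[0]
        block = off[np.ix_(sub, sub)]
        mx = block.max() if block.size else 0.0
        if mx <= cutoff:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(block), block.shape)
        i, j = sub[i_loc], sub[j_loc]
        tot_i = off[i, active].sum()
        tot_j = off[j, active].sum()
        if tot_i > tot_j:
            drop = i
        elif tot_j > tot_i:
            drop = j
        else:
            drop = max(i, j, key=lambda k: str(matrix.subject_ids[k]))
        active[drop] = False
    return [matrix.subject_ids[i] for i in np.where(active)[0]]
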