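"""Quantitative-trait genotype association under an additive model.

Each variant is tested by ordinary least squares of the phenotype on
[intercept, dosage, covariates]; the dosage coefficient, its standard
error and a two-sided t-test p-value are reported. Subjects with a missing
dosage are dropped for that variant (the PLINK ``--linear`` convention).
Genome-wide (p <= 5e-8) and suggestive (p <= 1e-5) flags, a sex-stratified
test combining per-stratum Z statistics by Stouffer's method, and the
genomic inflation factor lambda are provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
    "additive_test",
    "run_gwas",
    "stratified_x_test",
    "stouffer_combine",
    "genomic_lambda",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5


def _design(dosage, phenotype, covariates):
    g = np.asarray(dosage, float)
    y = np.asarray(phenotype, float)
    if covariates is None:
        C = np.empty((len(y), 0))
        names = []
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                 else [f"cov{i}" for i in range(C.shape[1])])
    keep = ~np.isnan(g)
    g, y, C = g[keep], y[keep], C[keep]
    if np.isnan(y).any() or np.isnan(C).any():
        raise ValueError("phenotype/covariates contain missing values")
    X = np.column_stack([np.ones(len(y)), g, C])
    return X, y, ["const", "dosage"] + names, int(keep.sum())


def additive_test(dosage, phenotype, covariates=None) -> dict:
    """Additive-model association of one variant with a quantitative trait.

    Returns a dict with beta, se, stat (t), p, n and the significance
    flags. Raises on a rank-deficient design, naming the offending columns.
    """
    X, y, names, n = _design(dosage, phenotype, covariates)
    if n < X.shape[1] + 1:
        raise ValueError(f"too few complete cases ({n}) for {X.shape[1]} predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"collinear design; offending columns: {bad}")
    res = sm.OLS(y, X).fit()
    beta, se, t, p = res.params[1], res.bse[1], res.tvalues[1], res.pvalues[1]
    return {
        "beta": float(beta), "se": float(se), "stat": float(t), "p": float(p),
        "n": n,
        "genome_wide": bool(p <= GENOME_WIDE_P),
        "suggestive": bool(p <= SUGGESTIVE_P),
    }


def _batch_ols(G, y, C):
    """Per-variant OLS dosage coefficients for complete-dosage variants.

    Frisch-Waugh: residualize y and every dosage column on [1, C]; the
    dosage beta, with degrees of freedom counted on the full design, is
    identical to per-variant OLS.
    """
    n = len(y)
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gg
        df = n - (C.shape[1] + 2)
        rss = (yr @ yr) - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return beta, se, t, p


def run_gwas(matrix, phenotype: pd.Series, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Association scan over all variants of a genotype matrix.

    ``phenotype`` and ``covariates`` are indexed by subject id and aligned
    to the matrix subjects; misaligned ids raise. Variants without missing
    dosages go through a vectorized path that is numerically identical to
    ``additive_test``; variants with missing dosages are tested one at a
    time with those subjects dropped.
    """
    ids = list(matrix.subject_ids)
    try:
        y = phenotype.loc[ids].to_numpy(float)
    except KeyError as e:
        raise ValueError(f"phenotype is missing subjects present in the genotype matrix: {e}")
    if covariates is not None:
        missing = set(ids) - set(covariates.index)
        if missing:
            raise ValueError(f"covariates missing subjects: {sorted(missing)[:5]}")
        C = covariates.loc[ids].to_numpy(float)
    else:
        C = np.empty((len(ids), 0))
    G = matrix.dosages
    complete = ~np.isnan(G).any(axis=0)

    out = pd.DataFrame(index=range(matrix.n_variants),
                       columns=["beta", "se", "stat", "p", "n"], dtype=float)
    if complete.any():
        b, s, t, p = _batch_ols(G[:, complete], y, C)
        out.loc[complete, "beta"] = b
        out.loc[complete, "se"] = s
        out.loc[complete, "stat"] = t
        out.loc[complete, "p"] = p
        out.loc[complete, "n"] = len(y)
    for v in np.where(~complete)[0]:
        r = additive_test(G[:, v], y, covariates.loc[ids] if covariates is not None else None)
        out.loc[v, ["beta", "se", "stat", "p", "n"]] = [r["beta"], r["se"], r["stat"], r["p"], r["n"]]
    res = matrix.variants[["id", "chrom", "pos", "a1"]].copy()
    res = pd.concat([res, out.reset_index(drop=True)], axis=1)
    res["n"] = res["n"].astype(int)
    res["genome_wide"] = res["p"] <= GENOME_WIDE_P
    res["suggestive"] = res["p"] <= SUGGESTIVE_P
    return res


def _z_from(beta: float, p: float) -> float:
    return float(np.sign(beta) * sps.norm.isf(min(max(p, 1e-300), 1.0) / 2.0))


def stouffer_combine(z_values, weights) -> float:
    """Weighted Stouffer combination Z = sum(w z) / sqrt(sum(w^2))."""
    z = np.asarray(z_values, float)
    w = np.asarray(weights, float)
    return float(np.dot(w, z) / np.sqrt(np.dot(w, w)))


def stratified_x_test(dosage, phenotype, covariates, sex) -> dict:
    """Sex-stratified association with Stouffer combination.

    Fits the additive model separately in males and females (male
    X dosages are expected on the {0, 2} coding) and combines the signed
    per-stratum Z statistics as Z = (w_m Z_m + w_f Z_f) / sqrt(w_m^2 +
    w_f^2) with weights w = sqrt(n). A single-sex input falls back to the
    unstratified test with a warning flag.
    """
    sex = np.asarray(sex)
    dosage = np.asarray(dosage, float)
    phenotype = np.asarray(phenotype, float)
    strata = [np.where(sex == s)[0] for s in np.unique(sex)]
    if len(strata) < 2:
        r = additive_test(dosage, phenotype, covariates)
        r["warning"] = "single-sex input; unstratified test returned"
        return r
    zs, ws = [], []
    per_stratum = []
    for idx in strata:
        cov_s = covariates.iloc[idx] if covariates is not None else None
        r = additive_test(dosage[idx], phenotype[idx], cov_s)
        per_stratum.append(r)
        zs.append(_z_from(r["beta"], r["p"]))
        ws.append(np.sqrt(r["n"]))
    z = stouffer_combine(zs, ws)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return {"z": z, "p": p, "per_stratum": per_stratum,
            "genome_wide": p <= GENOME_WIDE_P, "suggestive": p <= SUGGESTIVE_P}


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median association chi-square over its null median."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / sps.chi2.isf(0.5, df=1))
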