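"""Seeded synthetic cohorts with the structure the progression analysis assumes.

The generator draws, per subject, a latent disease time shift gamma (years),
then produces short-term longitudinal observations of two or more
biomarkers that follow shifted monotone sigmoids with a subject-level
random intercept and slope and Gaussian noise:

    Y_ij(t) = g_j(t + gamma_i) + alpha0_ij + alpha1_ij * t + eps_ij(t).

It also simulates Hardy-Weinberg-consistent genotypes with block LD and one
causal variant that shifts gamma additively, simple covariates, diagnosis
labels from gamma quantile bands, and conversion/death/censoring times with
a carrier-dependent conversion hazard — everything needed to exercise the
downstream fitting, association, risk-score and competing-risks stages
without any real data.

Randomness: one global seed feeds a splittable generator; each
sub-simulation (trajectories, covariates, missingness, genotypes, survival)
gets its own independent stream, so e.g. adding variants never perturbs the
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np
import pandas as pd

from .progression import LongitudinalDataset, PopulationCurve
from .genetics_qc import GenotypeMatrix

__all__ = [
    "BiomarkerSpec",
    "HazardSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_population_curves",
    "sigmoid_curve",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_conversion_data",
    "simulate_study",
    "write_study",
]

_STREAMS = {"trajectories": 0, "covariates": 1, "missingness": 2,
            "genotypes": 3, "survival": 4, "labels": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class BiomarkerSpec:
    """Shifted-sigmoid long-term trajectory for one biomarker.

    The population curve is L_low + (L_high - L_low) / (1 + exp(-k (t - t0)))
    for an increasing marker, mirrored for a decreasing one.
    """

    id: str
    L_low: float
    L_high: float
    k: float  # steepness, 1/years
    t0: float  # inflection point, years
    direction: str = "increasing"

    def curve(self):
        if self.k <= 0:
            raise ValueError(f"biomarker {self.id!r}: steepness k must be positive")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"biomarker {self.id!r}: bad direction {self.direction!r}")
        sign = 1.0 if self.direction == "increasing" else -1.0

        def g(t):
            t = np.asarray(t, float)
            return self.L_low + (self.L_high - self.L_low) / (1.0 + np.exp(-sign * self.k * (t - self.t0)))

        return g


@dataclass
class HazardSpec:
    """Exponential competing-risks event model, rates per year."""

    conversion_rate: float = 0.08
    carrier_hazard_ratio: float = 0.6
    death_rate: float = 0.04
    censor_time: float = 10.0


def _default_biomarkers():
    # An amyloid-SUVR-like marker that rises early and a hippocampal-volume-
    # like marker that declines later in the disease course (Z units).
    return [
        BiomarkerSpec(id="amyloid_suvr", L_low=-1.0, L_high=3.5, k=0.30, t0=2.0,
                      direction="increasing"),
        BiomarkerSpec(id="hippocampal_volume", L_low=-3.0, L_high=1.0, k=0.40, t0=5.0,
                      direction="decreasing"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults give 300 subjects, two biomarkers observed at six visits over
    four years with 10% missingness, a 5-year SD of the latent time shift,
    200 variants in 5-variant LD blocks with one causal variant moving the
    shift by 2 years per effect allele, and a carrier-protective conversion
    hazard with death as a competing event.
    """

    n_subjects: int = 300
    biomarker_specs: list = field(default_factory=_default_biomarkers)
    gamma_sd: float = 5.0
    alpha0_sd: float = 0.2
    alpha1_sd: float = 0.05
    noise_sd: float = 0.3
    visit_times: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)
    missing_rate: float = 0.1
    n_variants: int = 200
    maf_range: tuple = (0.05, 0.5)
    causal_beta: float = 2.0
    causal_maf: float = 0.3
    ld_block_size: int = 5
    flip_prob: float = 0.1
    hazards: HazardSpec = field(default_factory=HazardSpec)
    diagnosis_quantiles: tuple = (0.35, 0.85)  # gamma bands HC / MCI / AD
    label_noise: float = 0.1
    confounded_covariates: bool = False
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not self.biomarker_specs:
            raise ValueError("need at least one biomarker spec")
        for p, name in [(self.missing_rate, "missing_rate"), (self.flip_prob, "flip_prob"),
                        (self.label_noise, "label_noise")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gamma_sd < 0 or self.noise_sd < 0:
            raise ValueError("gamma_sd and noise_sd must be non-negative")
        vt = np.asarray(self.visit_times, float)
        if (vt < 0).any() or (np.diff(vt) <= 0).any():
            raise ValueError("visit_times must be non-negative and strictly increasing")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        hz = self.hazards
        if hz.conversion_rate <= 0 or hz.death_rate < 0 or hz.carrier_hazard_ratio < 0:
            raise ValueError("hazard parameters must be positive")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for recovery checks."""

    subjects: pd.DataFrame  # subject_id, gamma, alpha0_<bm>, alpha1_<bm>
    causal_index: int | None = None
    variant_maf: np.ndarray | None = None

    def to_json(self, path):
        obj = {
            "subjects": self.subjects.to_dict(orient="list"),
            "causal_index": None if self.causal_index is None else int(self.causal_index),
            "variant_maf": None if self.variant_maf is None else np.asarray(self.variant_maf).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def simulate_population_curves(config: SimulationConfig) -> list[PopulationCurve]:
    """Monotone spline representations of the configured sigmoid curves."""
    config.validate()
    from .progression import fit_monotone_curve

    curves = []
    for spec in config.biomarker_specs:
        g = spec.curve()
        half_width = 6.0 / spec.k  # covers the transition region
        lo = spec.t0 - half_width - 3 * config.gamma_sd
        hi = spec.t0 + half_width + 3 * config.gamma_sd
        ts = np.linspace(lo, hi, 200)
        curves.append(fit_monotone_curve(np.column_stack([ts, g(ts)]), spec.direction,
                                         n_interior_knots=20, biomarker_id=spec.id))
    return curves


def sigmoid_curve(spec: BiomarkerSpec):
    """Callable exact sigmoid for a biomarker spec (analytic, not a spline)."""
    return spec.curve()


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def simulate_cohort(config: SimulationConfig, gamma_offset=None):
    """Simulate longitudinal biomarkers, covariates and diagnosis labels.

    Returns (LongitudinalDataset, TruthRecord, covariates DataFrame). The
    optional ``gamma_offset`` (one value per subject, years) is added to the
    latent gamma before trajectory generation; ``simulate_study`` uses it to
    wire in the causal-variant effect.
    """
    config.validate()
    if config.missing_rate >= 1.0:
        raise ValueError("missing_rate = 1 would produce an empty dataset")
    n = config.n_subjects
    ids = _subject_ids(n)
    rng_traj = _rng(config.seed, "trajectories")
    rng_cov = _rng(config.seed, "covariates")
    rng_miss = _rng(config.seed, "missingness")
    rng_lab = _rng(config.seed, "labels")

    gamma = rng_traj.normal(0.0, config.gamma_sd, size=n) if config.gamma_sd > 0 else np.zeros(n)
    if gamma_offset is not None:
        gamma = gamma + np.asarray(gamma_offset, float)

    t = np.asarray(config.visit_times, float)
    rows = []
    truth_cols = {"subject_id": ids, "gamma": gamma}
    for spec in config.biomarker_specs:
        g = spec.curve()
        a0 = rng_traj.normal(0.0, config.alpha0_sd, size=n) if config.alpha0_sd > 0 else np.zeros(n)
        a1 = rng_traj.normal(0.0, config.alpha1_sd, size=n) if config.alpha1_sd > 0 else np.zeros(n)
        truth_cols[f"alpha0_{spec.id}"] = a0
        truth_cols[f"alpha1_{spec.id}"] = a1
        for i in range(n):
            y = g(t + gamma[i]) + a0[i] + a1[i] * t
            if config.noise_sd > 0:
                y = y + rng_traj.normal(0.0, config.noise_sd, size=len(t))
            for tv, yv in zip(t, y):
                rows.append((ids[i], spec.id, float(tv), float(yv)))
    df = pd.DataFrame(rows, columns=["subject_id", "biomarker_id", "time_years", "value"])
    if config.missing_rate > 0:
        keep = rng_miss.random(len(df)) >= config.missing_rate
        # never drop a subject entirely: keep each subject's first row
        first = ~df.duplicated("subject_id")
        df = df[keep | first.to_numpy()]
    data = LongitudinalDataset(df.reset_index(drop=True))

    # Covariates: plausible cohort marginals; independent of gamma unless
    # confounding is switched on.
    age = rng_cov.normal(74.0, 7.5, size=n)
    sex = (rng_cov.random(n) < 0.45).astype(int)  # 1 = female
    edu = np.clip(np.round(rng_cov.normal(16.3, 2.7, size=n)), 8, 22)
    pc1 = rng_cov.normal(0.0, 1.0, size=n)
    pc2 = rng_cov.normal(0.0, 1.0, size=n)
    apoe4 = rng_cov.binomial(2, 0.25, size=n)
    if config.confounded_covariates:
        age = age + 0.4 * gamma
        apoe4 = np.clip(apoe4 + (rng_cov.random(n) < 1 / (1 + np.exp(-0.3 * gamma)) * 0.3).astype(int), 0, 2)

    # Diagnosis from gamma quantile bands, with label noise moving a subject
    # to an adjacent band.
    q1, q2 = np.quantile(gamma, config.diagnosis_quantiles)
    labels = np.where(gamma <= q1, "HC", np.where(gamma <= q2, "MCI", "AD"))
    order = ["HC", "MCI", "AD"]
    if config.label_noise > 0:
        flip = rng_lab.random(n) < config.label_noise
        for i in np.where(flip)[0]:
            j = order.index(labels[i])
            j += rng_lab.choice([-1, 1]) if 0 < j < 2 else (1 if j == 0 else -1)
            labels[i] = order[j]

    cov = pd.DataFrame({
        "subject_id": ids, "age": age, "sex": sex, "education": edu,
        "pc1": pc1, "pc2": pc2, "apoe4": apoe4, "diagnosis": labels,
    })
    truth = TruthRecord(subjects=pd.DataFrame(truth_cols))
    return data, truth, cov


def _draw_hwe(rng, maf: float, n: int) -> np.ndarray:
    return (rng.random((n, 2)) < maf).sum(axis=1).astype(float)


def simulate_genotypes(config: SimulationConfig, truth: TruthRecord) -> GenotypeMatrix:
    """HWE-consistent dosages with block LD; updates ``truth`` in place.

    Variants come in blocks of ``ld_block_size``: the block seed variant is
    drawn under Hardy-Weinberg at its MAF and the other block members copy
    it, each subject's copy being independently redrawn (at the same MAF)
    with probability ``flip_prob`` — flip_prob 0 gives within-block r^2 = 1.
    One variant (HWE-drawn at ``causal_maf``) is designated causal; its
    index and the per-variant MAFs are recorded on the truth record.
    """
    config.validate()
    n = len(truth.subjects)
    if n != config.n_subjects:
        raise ValueError("truth record does not match config.n_subjects")
    rng = _rng(config.seed, "genotypes")
    m = config.n_variants
    lo, hi = config.maf_range
    mafs = np.empty(m)
    dos = np.empty((n, m))
    block = max(1, config.ld_block_size)
    causal = int(rng.integers(0, m))
    for start in range(0, m, block):
        stop = min(start + block, m)
        maf = float(rng.uniform(lo, hi))
        seed_dos = _draw_hwe(rng, maf, n)
        for v in range(start, stop):
            mafs[v] = maf
            if v == start:
                dos[:, v] = seed_dos
            else:
                redraw = rng.random(n) < config.flip_prob
                dos[:, v] = np.where(redraw, _draw_hwe(rng, maf, n), seed_dos)
    # causal variant drawn independently of any block at its own MAF
    mafs[causal] = config.causal_maf
    dos[:, causal] = _draw_hwe(rng, config.causal_maf, n)

    ids = [f"rs{100000 + v}" for v in range(m)]
    variants = pd.DataFrame({
        "id": ids,
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1) * 50_000,
        "a1": ["A"] * m,
        "a2": ["G"] * m,
        "maf": mafs,
    })
    truth.causal_index = causal
    truth.variant_maf = mafs
    return GenotypeMatrix(dosages=dos,
                          subject_ids=list(truth.subjects["subject_id"]),
                          variants=variants)


def simulate_conversion_data(config: SimulationConfig, genotypes: GenotypeMatrix,
                             causal_index: int | None = None) -> pd.DataFrame:
    """Conversion/death/censoring table with a carrier-dependent hazard.

    Latent conversion and death times are exponential; minor-allele
    carriers at the causal variant have their conversion rate multiplied by
    the carrier hazard ratio. The observed time is the minimum of the two
    event times and the administrative censoring time. Times are reported
    in months; status is 0 = censored, 1 = converted, 2 = died.
    """
    config.validate()
    hz = config.hazards
    rng = _rng(config.seed, "survival")
    n = len(genotypes.subject_ids)
    if causal_index is None:
        causal_index = 0
    carrier = (np.nan_to_num(genotypes.dosages[:, causal_index]) >= 1).astype(int)
    rate = hz.conversion_rate * np.where(carrier == 1, hz.carrier_hazard_ratio, 1.0)
    t_conv = rng.exponential(1.0 / rate)
    t_death = rng.exponential(1.0 / hz.death_rate, size=n) if hz.death_rate > 0 else np.full(n, np.inf)
    t_cens = hz.censor_time
    time = np.minimum(np.minimum(t_conv, t_death), t_cens)
    status = np.where(time == t_conv, 1, np.where(time == t_death, 2, 0))
    return pd.DataFrame({
        "subject_id": genotypes.subject_ids,
        "time_months": time * 12.0,
        "status": status.astype(int),
        "carrier": carrier,
    })


def simulate_study(config: SimulationConfig):
    """Full synthetic study: genotypes -> gamma -> trajectories -> survival.

    Returns a dict with keys ``data`` (LongitudinalDataset), ``truth``,
    ``covariates``, ``genotypes`` and ``survival``. The causal variant's
    dosage shifts each subject's gamma by causal_beta years per effect
    allele before trajectory generation.
    """
    config.validate()
    shell = TruthRecord(subjects=pd.DataFrame({"subject_id": _subject_ids(config.n_subjects)}))
    geno = simulate_genotypes(config, shell)
    causal_dos = np.nan_to_num(geno.dosages[:, shell.causal_index])
    offset = config.causal_beta * causal_dos
    data, truth, cov = simulate_cohort(config, gamma_offset=offset)
    truth.causal_index = shell.causal_index
    truth.variant_maf = shell.variant_maf
    surv = simulate_conversion_data(config, geno, causal_index=truth.causal_index)
    return {"data": data, "truth": truth, "covariates": cov,
            "genotypes": geno, "survival": surv}


def write_study(study: dict, outdir) -> None:
    """Write a simulated study to plain-text files in ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    study["data"].to_csv(os.path.join(outdir, "biomarkers.csv"))
    study["covariates"].to_csv(os.path.join(outdir, "covariates.csv"), index=False)
    study["survival"].to_csv(os.path.join(outdir, "survival.csv"), index=False)
    study["truth"].to_json(os.path.join(outdir, "truth.json"))
    geno = study["genotypes"]
    pd.DataFrame(geno.dosages, index=geno.subject_ids,
                 columns=geno.variants["id"]).to_csv(
        os.path.join(outdir, "genotypes.tsv"), sep="\t", index_label="subject_id")
    geno.variants.to_csv(os.path.join(outdir, "variants.tsv"), sep="\t", index=False)
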