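"""Synthetic plate-reader curves and variant cohorts with known ground truth.

Two generators back the whole test surface of the pipeline:

* :func:`simulate_growth_curve` / :func:`simulate_plate` produce OD600 time
  courses for ts-strain cultures expressing wild-type, variant, or GFP
  control alleles: a lag phase followed by logistic growth toward a carrying
  capacity at rate ``base_rate * true_mu``, plus i.i.d. Gaussian read noise.
  Logistic rather than pure exponential growth is deliberate — plate cultures
  saturate inside the assayed window, so the rate estimator's log-phase
  windowing is exercised.

* :func:`simulate_variant_cohort` produces a labeled variant table whose
  assay behaviour (sensitivity/specificity of the spotting score at the 0.6
  cutoff), computational-predictor discrimination (binormal model with the
  target AUROC), annotation classes and allele frequencies are all dialled in
  explicitly, so benchmark statistics can be checked against the generating
  parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, InputError
from .growth import PLATE_COLUMNS, GrowthCurve

#: FCS levels assigned to a deleterious draw and their mixture weights.
#: All three non-zero levels are exercised; complete loss is commonest.
DELETERIOUS_FCS_LEVELS = (0.6, 0.8, 1.0)
DELETERIOUS_FCS_WEIGHTS = (0.25, 0.25, 0.5)

#: HGMD class mixture for disease-annotated variants (DM dominates, as in
#: curated disease-mutation sets) and ClinVar-pathogenic rate among DM.
HGMD_CLASS_WEIGHTS = {"DM": 0.80, "DM?": 0.08, "DP": 0.06, "DFP": 0.04, "FP": 0.02}
CLINVAR_PATHOGENIC_GIVEN_DM = 0.7
CLINVAR_ABSENT_GIVEN_NONPATHOGENIC = 0.6

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GrowthSimConfig:
    """Plate-reader acquisition and growth-model settings.

    interval_min      : minutes between reads (15 in the assays modelled here)
    n_reads           : number of reads per well
    od0               : initial absorbance (~1e5 cells in 100 uL)
    carrying_capacity : absorbance ceiling of the culture
    lag_min           : lag-phase duration in minutes
    noise_sd          : SD of additive Gaussian read noise (OD units)
    """

    interval_min: float = 15.0
    n_reads: int = 97
    od0: float = 0.02
    carrying_capacity: float = 2.0
    lag_min: float = 120.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_min <= 0:
            raise ConfigurationError("interval_min must be > 0")
        if self.n_reads < 2:
            raise ConfigurationError("n_reads must be >= 2")
        if not 0 < self.od0 < self.carrying_capacity:
            raise ConfigurationError("od0 must satisfy 0 < od0 < carrying_capacity")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.lag_min < 0:
            raise ConfigurationError("lag_min must be >= 0")


@dataclass
class StrainSpec:
    """Ground truth for one simulated culture.

    true_mu   : relative growth rate vs the wild-type-allele strain
    base_rate : per-hour exponential rate of the wild-type-allele strain
    """

    strain_id: str
    allele_class: str
    true_mu: float
    base_rate: float

    def __post_init__(self) -> None:
        if self.allele_class not in ("wildtype", "variant", "gfp_control"):
            raise ConfigurationError(f"allele_class invalid: {self.allele_class!r}")
        if self.true_mu < 0:
            raise ConfigurationError("true_mu must be >= 0")
        if self.base_rate <= 0:
            raise ConfigurationError("base_rate must be > 0")
        if self.allele_class == "wildtype" and self.true_mu != 1:
            raise ConfigurationError("allele_class 'wildtype' implies true_mu = 1")


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic variant cohort.

    assay_sensitivity : P(FCS >= 0.6 | disease variant)
    assay_specificity : P(FCS = 0 | nondisease variant)
    predictor_auroc   : target AUROC of the simulated computational score
    contamination     : fraction of disease-labeled rows whose behaviour is
                        drawn from the nondisease model (annotation errors)
    maf_distribution  : (low, high) bounds of the log-uniform ExAC MAF draw
    fct_concentration : Beta concentration of FCT around the FCS level
    """

    n_disease: int = 101
    n_nondisease: int = 78
    assay_sensitivity: float = 0.82
    assay_specificity: float = 0.87
    predictor_auroc: float = 0.79
    contamination: float = 0.0
    maf_distribution: tuple[float, float] = (1e-6, 1e-2)
    # Beta concentration 2.2 reproduces the ~81% FCS-FCT correlation seen in
    # real paired spotting/liquid assays
    fct_concentration: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("assay_sensitivity", "assay_specificity", "contamination"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.5 <= self.predictor_auroc <= 1:
            raise ConfigurationError("predictor_auroc must be in [0.5, 1]")
        if self.n_disease < 1 or self.n_nondisease < 1:
            raise ConfigurationError("n_disease and n_nondisease must be >= 1")
        lo, hi = self.maf_distribution
        if not 0 < lo < hi <= 1:
            raise ConfigurationError("maf_distribution must satisfy 0 < low < high <= 1")
        if self.fct_concentration <= 0:
            raise ConfigurationError("fct_concentration must be > 0")


def _logistic_od(t_min: np.ndarray, spec: StrainSpec, config: GrowthSimConfig) -> np.ndarray:
    rate_h = spec.base_rate * spec.true_mu
    t_h = np.clip(t_min - config.lag_min, 0.0, None) / 60.0
    k = config.carrying_capacity
    # K / (1 + ((K - N0)/N0) e^{-rt}) — numerically stable for large rt
    return k / (1.0 + ((k - config.od0) / config.od0) * np.exp(-rate_h * t_h))


def simulate_growth_curve(
    spec: StrainSpec, config: GrowthSimConfig, rng: np.random.Generator | None = None
) -> GrowthCurve:
    """One well: lag, then logistic growth, then additive read noise."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_reads, dtype=float) * config.interval_min
    od = _logistic_od(t, spec, config)
    if config.noise_sd > 0:
        od = od + rng.normal(0.0, config.noise_sd, size=od.shape)
    return GrowthCurve(times=t, od=od, strain_id=spec.strain_id, allele_class=spec.allele_class)


def simulate_plate(
    specs: list[StrainSpec],
    config: GrowthSimConfig,
    wells: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a plate of wells into a tidy table.

    Columns: well, strain_id, allele_class, time_min, od600.  Each well gets
    an independent noise stream spawned from the config seed.
    """
    if not specs:
        raise InputError("simulate_plate: need at least one strain spec")
    if wells is None:
        wells = [f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}" for i in range(len(specs))]
    if len(wells) != len(specs):
        raise InputError("simulate_plate: wells and specs length mismatch")
    if len(set(wells)) != len(wells):
        raise InputError("simulate_plate: duplicate well identifiers")
    child_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(len(specs))]
    frames = []
    for well, spec, rng in zip(wells, specs, child_rngs):
        curve = simulate_growth_curve(spec, config, rng=rng)
        frames.append(
            pd.DataFrame(
                {
                    "well": well,
                    "strain_id": spec.strain_id,
                    "allele_class": spec.allele_class,
                    "time_min": curve.times,
                    "od600": curve.od,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[PLATE_COLUMNS]


def write_plate(plate: pd.DataFrame, path) -> None:
    """Write a tidy plate table as the plate CSV dialect (UTF-8, '.' decimal)."""
    plate[PLATE_COLUMNS].to_csv(path, index=False)


def _draw_fcs(rng: np.random.Generator, n: int, p_deleterious: float) -> np.ndarray:
    deleterious = rng.random(n) < p_deleterious
    levels = rng.choice(DELETERIOUS_FCS_LEVELS, size=n, p=DELETERIOUS_FCS_WEIGHTS)
    return np.where(deleterious, levels, 0.0)


def _draw_fct(rng: np.random.Generator, fcs: np.ndarray, concentration: float) -> np.ndarray:
    """FCT ~ Beta centred on the FCS level with the given concentration."""
    alpha = np.maximum(fcs * concentration, 0.5)
    beta = np.maximum((1.0 - fcs) * concentration, 0.5)
    return rng.beta(alpha, beta)


def binormal_separation(auroc: float) -> float:
    """Mean shift d of the binormal score model achieving the target AUROC.

    With disease scores ~ N(d, 1) and nondisease ~ N(0, 1),
    AUROC = Phi(d / sqrt(2)), hence d = sqrt(2) * Phi^-1(AUROC).
    """
    return float(np.sqrt(2.0) * norm.ppf(auroc))


def _annotations(rng: np.random.Generator, n: int, disease: bool) -> tuple[np.ndarray, np.ndarray]:
    if not disease:
        hgmd = np.full(n, "none", dtype=object)
        clinvar = np.where(
            rng.random(n) < CLINVAR_ABSENT_GIVEN_NONPATHOGENIC, "absent", "other"
        ).astype(object)
        return hgmd, clinvar
    classes = np.array(list(HGMD_CLASS_WEIGHTS), dtype=object)
    weights = np.array(list(HGMD_CLASS_WEIGHTS.values()))
    hgmd = rng.choice(classes, size=n, p=weights / weights.sum())
    clinvar = np.empty(n, dtype=object)
    for i in range(n):
        if hgmd[i] == "DM" and rng.random() < CLINVAR_PATHOGENIC_GIVEN_DM:
            clinvar[i] = "pathogenic"
        else:
            clinvar[i] = "absent" if rng.random() < CLINVAR_ABSENT_GIVEN_NONPATHOGENIC else "other"
    return hgmd, clinvar


def simulate_variant_cohort(config: CohortConfig) -> pd.DataFrame:
    """Labeled variant cohort with assay, predictor, and annotation columns.

    Returns one row per variant: gene, protein_change, label (annotated
    disease association, 1/0), truth (the generative process actually used,
    differing from label only for contaminated rows), hgmd_class,
    clinvar_status, exac_maf, fcs, fct, predictor.
    """
    rng = np.random.default_rng(config.seed)
    n_dis, n_non = config.n_disease, config.n_nondisease
    n = n_dis + n_non
    label = np.concatenate([np.ones(n_dis, dtype=int), np.zeros(n_non, dtype=int)])

    truth = label.copy()
    n_contam = int(round(config.contamination * n_dis))
    if n_contam:
        contam_idx = rng.choice(n_dis, size=n_contam, replace=False)
        truth[contam_idx] = 0

    p_del = np.where(truth == 1, config.assay_sensitivity, 1.0 - config.assay_specificity)
    fcs = _draw_fcs(rng, n, p_del)
    fct = _draw_fct(rng, fcs, config.fct_concentration)
    d = binormal_separation(config.predictor_auroc)
    predictor = rng.normal(0.0, 1.0, size=n) + d * (truth == 1)

    lo, hi = config.maf_distribution
    maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    hgmd_d, clinvar_d = _annotations(rng, n_dis, disease=True)
    hgmd_n, clinvar_n = _annotations(rng, n_non, disease=False)

    genes = np.array([f"GENE{i % 22 + 1:02d}" for i in range(n)], dtype=object)
    ref = rng.choice(list(AMINO_ACIDS), size=n)
    alt = rng.choice(list(AMINO_ACIDS), size=n)
    pos = rng.integers(2, 800, size=n)
    protein_change = np.array(
        [f"{r}{p}{a if a != r else 'A' if r != 'A' else 'G'}" for r, p, a in zip(ref, pos, alt)],
        dtype=object,
    )

    return pd.DataFrame(
        {
            "gene": genes,
            "protein_change": protein_change,
            "label": label,
            "truth": truth,
            "hgmd_class": np.concatenate([hgmd_d, hgmd_n]),
            "clinvar_status": np.concatenate([clinvar_d, clinvar_n]),
            "exac_maf": maf,
            "fcs": fcs,
            "fct": fct,
            "predictor": predictor,
        }
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as TSV."""
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "protein_change", "label", "fcs"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"cohort file {path}: missing columns {sorted(missing)}")
    return df
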