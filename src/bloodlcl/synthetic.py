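"""Ground-truth-labelled synthetic cohorts of blood and LCL DNA samples.

The generator emulates the signal structure that makes the tissue-of-origin
test work, so that every downstream stage (Ct calling, melting-peak
extraction, ratio classification, voting, evaluation, age prediction) can be
exercised end to end without access to per-sample instrument data:

* 10 ng of genomic DNA per reaction, nominally ~3000 diploid genome
  equivalents; GAPDH amplifies from two alleles per genome.
* EBV templates: LCLs carry 2-500 episomal EBV genome copies per diploid
  genome equivalent (log-uniform by default); most blood samples carry none
  (their EBV assay does not amplify and is later imputed at Ct 40) and a
  minority carry trace copies, exercising both code paths.
* Rearranged TCRgamma templates exist only in the T-cell fraction of blood
  (default 5-40% of cells); LCLs (B-cell derived) have none (imputed Ct 45).
* TCRbeta melting profiles: blood yields a specific product peak above
  89.5 degC, usually with a primer-dimer peak below; LCLs yield only
  dimer/non-specific peaks below 89.5 degC.
* Methylation at the three clock CpGs is the analytic inverse of the affine
  age model in blood (plus independent per-CpG noise), so noiseless blood
  profiles round-trip through predict_age exactly. LCL methylation is
  decorrelated from donor age and shifted by a passage effect, reproducing
  the published pattern of high MAD and low Pearson R in cell lines.

All randomness flows from a single cohort seed through per-sample spawned
generators, so identical configurations reproduce identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import clock
from .qpcr import AmplificationCurve, MeltCurve, simulate_amplification, simulate_melt

TISSUE_BLOOD = "blood"
TISSUE_LCL = "LCL"

# ---------------------------------------------------------------------------
# methylation model inversion
#
# The affine clock (one age, three CpGs) is under-determined; the generator
# fixes one loading direction: each CpG's mean methylation is affine in age,
# with slopes normalised so the clock's coefficients recover age exactly and
# baselines chosen so the intercepts cancel. Values stay inside [0, 100] for
# ages 0-110.
_METH_BASE_RAW = {"elovl2_cpg5": None, "klf14_cpg2": 2.0, "trim59_cpg5": 5.0}
_SLOPE_RAW = np.array([0.70, 0.25, 0.40])
_COEFFS = np.array([clock.AGE_COEFFS[s] for s in clock.CPG_SITES])
METH_SLOPE = _SLOPE_RAW / float(_COEFFS @ _SLOPE_RAW)  # coeffs @ slope == 1
_e0 = (-clock.AGE_INTERCEPT
       - _COEFFS[1] * _METH_BASE_RAW["klf14_cpg2"]
       - _COEFFS[2] * _METH_BASE_RAW["trim59_cpg5"]) / _COEFFS[0]
METH_BASE = np.array([_e0, _METH_BASE_RAW["klf14_cpg2"], _METH_BASE_RAW["trim59_cpg5"]])

#: per-CpG direction of the LCL passage disruption (percent methylation per
#: unit passage effect); chosen to be non-collinear with the age loading
PASSAGE_DISRUPTION = np.array([-6.0, 5.0, -4.0])


def mean_methylation_at_age(age) -> np.ndarray:
    """Noise-free blood methylation percentages for a given age (the model
    inverse used by the generator); shape (3,) ordered as clock.CPG_SITES."""
    age = np.asarray(age, dtype=float)
    return METH_BASE + np.multiply.outer(age, METH_SLOPE)


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class Dist:
    """A small named-distribution spec used for every cohort parameter.

    kinds: ``constant(a)``, ``uniform(a, b)``, ``loguniform(a, b)``,
    ``normal(mean=a, sd=b)``, ``lognormal(median=a, sigma=b)``.
    """

    kind: str
    a: float
    b: float = 0.0

    _KINDS = ("constant", "uniform", "loguniform", "normal", "lognormal")

    def validate(self, name: str) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"{name}: unknown distribution kind {self.kind!r}")
        if self.kind in ("uniform", "loguniform") and not self.a <= self.b:
            raise ValueError(f"{name}: requires a <= b, got ({self.a}, {self.b})")
        if self.kind == "loguniform" and self.a <= 0:
            raise ValueError(f"{name}: loguniform requires a > 0")
        if self.kind in ("normal", "lognormal") and self.b < 0:
            raise ValueError(f"{name}: spread parameter must be non-negative")
        if self.kind == "lognormal" and self.a <= 0:
            raise ValueError(f"{name}: lognormal median must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "constant":
            return self.a
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        if self.kind == "loguniform":
            return float(math.exp(rng.uniform(math.log(self.a), math.log(self.b))))
        if self.kind == "normal":
            return float(rng.normal(self.a, self.b))
        return float(self.a * math.exp(rng.normal(0.0, self.b)))  # lognormal

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "constant":
            return (self.a, self.a)
        if self.kind in ("uniform", "loguniform"):
            return (self.a, self.b)
        if self.kind == "normal":
            return (-math.inf, math.inf)
        return (0.0, math.inf)


# ---------------------------------------------------------------------------
# sample truth and cohort configuration


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one synthetic sample."""

    sample_id: str
    tissue: str
    diploid_genomes_per_reaction: float
    ebv_copies_per_genome: float
    t_cell_fraction: float
    chronological_age: float
    passage_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.tissue not in (TISSUE_BLOOD, TISSUE_LCL):
            raise ValueError(f"tissue must be blood or LCL, got {self.tissue!r}")
        if self.diploid_genomes_per_reaction <= 0:
            raise ValueError("diploid_genomes_per_reaction must be positive")
        if self.ebv_copies_per_genome < 0:
            raise ValueError("ebv_copies_per_genome must be non-negative")
        if not (0.0 <= self.t_cell_fraction <= 1.0):
            raise ValueError("t_cell_fraction must lie in [0, 1]")
        if self.chronological_age < 0:
            raise ValueError("chronological_age must be non-negative")
        if self.passage_effect < 0:
            raise ValueError("passage_effect must be non-negative")
        if self.tissue == TISSUE_LCL and self.t_cell_fraction != 0:
            raise ValueError("LCL samples carry no rearranged-TCR T cells")
        if self.tissue == TISSUE_BLOOD and self.t_cell_fraction == 0:
            raise ValueError("blood samples must have a positive t_cell_fraction")


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; same config (incl. seed) -> same cohort."""

    n_blood: int = 500
    n_lcl: int = 500
    seed: int = 0

    # template amounts: 10 ng input ~ 3000 diploid genome equivalents
    genomes: Dist = Dist("lognormal", 3000.0, 0.05)
    lcl_ebv_copies: Dist = Dist("loguniform", 2.0, 500.0)
    blood_ebv_copies: Dist = Dist("loguniform", 1e-3, 1e-2)
    blood_ebv_zero_prob: float = 0.9
    blood_t_cell_fraction: Dist = Dist("uniform", 0.05, 0.40)
    age: Dist = Dist("uniform", 19.0, 79.0)
    passage_effect: Dist = Dist("lognormal", 1.0, 0.3)

    # amplification settings
    efficiency: dict[str, float] = field(
        default_factory=lambda: {"GAPDH": 2.0, "EBV": 2.0, "TCRG": 2.0})
    plateau: float = 10.0
    fluorescence_noise_sd: float = 0.05
    ct_jitter_sd: float = 0.15
    n_cycles: int = 50

    # TCRbeta melting settings
    blood_product_tm: Dist = Dist("uniform", 89.8, 90.8)
    dimer_tm: Dist = Dist("uniform", 82.0, 86.0)
    nonspecific_tm: Dist = Dist("uniform", 86.0, 88.8)
    blood_dimer_prob: float = 0.6
    lcl_nonspecific_prob: float = 0.5
    melt_noise_sd: float = 0.02

    # methylation settings
    methylation_noise_sd: float = 2.6
    lcl_methylation_decorrelation: float = 0.9

    def __post_init__(self) -> None:
        if self.n_blood < 0 or self.n_lcl < 0:
            raise ValueError("n_blood and n_lcl must be non-negative")
        for name in ("genomes", "lcl_ebv_copies", "blood_ebv_copies",
                     "blood_t_cell_fraction", "age", "passage_effect",
                     "blood_product_tm", "dimer_tm", "nonspecific_tm"):
            getattr(self, name).validate(name)
        for name, lo, hi in (("blood_ebv_zero_prob", 0, 1),
                             ("blood_dimer_prob", 0, 1),
                             ("lcl_nonspecific_prob", 0, 1),
                             ("lcl_methylation_decorrelation", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")
        for name in ("plateau",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fluorescence_noise_sd", "ct_jitter_sd", "melt_noise_sd",
                     "methylation_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for assay in ("GAPDH", "EBV", "TCRG"):
            e = self.efficiency.get(assay)
            if e is None or not (1.0 < e <= 2.0):
                raise ValueError(f"efficiency[{assay!r}] must lie in (1, 2]")
        lo, hi = self.blood_t_cell_fraction.support
        if lo <= 0 or hi > 1:
            raise ValueError("blood_t_cell_fraction support must lie in (0, 1]")
        if self.blood_ebv_copies.support[0] < 0:
            raise ValueError("blood_ebv_copies support must be non-negative")
        if self.blood_product_tm.support[0] <= 89.5:
            raise ValueError("blood_product_tm support must lie above 89.5 degC")
        for name in ("dimer_tm", "nonspecific_tm"):
            if getattr(self, name).support[1] >= 89.5:
                raise ValueError(f"{name} support must lie below 89.5 degC")

    def with_overrides(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CohortSample:
    """One generated sample: truth, raw curves per assay, methylation."""

    truth: SampleTruth
    amplification: dict[str, AmplificationCurve]
    melt: MeltCurve
    methylation: clock.MethylationProfile


# ---------------------------------------------------------------------------
# generation


def _draw_truth(cfg: CohortConfig, tissue: str, sample_id: str,
                rng: np.random.Generator) -> SampleTruth:
    genomes = cfg.genomes.sample(rng)
    age = max(0.0, cfg.age.sample(rng))
    if tissue == TISSUE_BLOOD:
        ebv = 0.0 if rng.random() < cfg.blood_ebv_zero_prob \
            else cfg.blood_ebv_copies.sample(rng)
        tcf = cfg.blood_t_cell_fraction.sample(rng)
        passage = 0.0
    else:
        ebv = cfg.lcl_ebv_copies.sample(rng)
        tcf = 0.0
        passage = cfg.passage_effect.sample(rng)
    return SampleTruth(
        sample_id=sample_id, tissue=tissue,
        diploid_genomes_per_reaction=genomes,
        ebv_copies_per_genome=ebv, t_cell_fraction=tcf,
        chronological_age=age, passage_effect=passage,
    )


def _amplify(cfg: CohortConfig, truth: SampleTruth, assay: str, copies: float,
             rng: np.random.Generator) -> AmplificationCurve:
    eff = cfg.efficiency[assay]
    if copies > 0 and cfg.ct_jitter_sd > 0:
        # a Ct jitter of j cycles is equivalent to scaling the template by E**-j
        copies = copies * eff ** (-rng.normal(0.0, cfg.ct_jitter_sd))
    return simulate_amplification(
        copies, efficiency=eff, plateau=cfg.plateau,
        noise_sd=cfg.fluorescence_noise_sd, n_cycles=cfg.n_cycles,
        seed=rng, sample_id=truth.sample_id, assay=assay,
    )


def _melt_products(cfg: CohortConfig, truth: SampleTruth,
                   rng: np.random.Generator) -> list[tuple[float, float]]:
    products: list[tuple[float, float]] = []
    if truth.tissue == TISSUE_BLOOD:
        products.append((cfg.blood_product_tm.sample(rng), 0.7))
        if rng.random() < cfg.blood_dimer_prob:
            products.append((cfg.dimer_tm.sample(rng), 0.25))
    else:
        products.append((cfg.dimer_tm.sample(rng), 0.5))
        if rng.random() < cfg.lcl_nonspecific_prob:
            products.append((cfg.nonspecific_tm.sample(rng), 0.3))
    return products


def _methylation(cfg: CohortConfig, truth: SampleTruth,
                 rng: np.random.Generator) -> clock.MethylationProfile:
    age = truth.chronological_age
    if truth.tissue == TISSUE_BLOOD:
        mean = mean_methylation_at_age(age)
    else:
        # decorrelate from donor age by mixing toward an independent age draw,
        # then shift along the passage-disruption direction
        d = cfg.lcl_methylation_decorrelation
        age_eff = (1.0 - d) * age + d * max(0.0, cfg.age.sample(rng))
        mean = mean_methylation_at_age(age_eff) + truth.passage_effect * PASSAGE_DISRUPTION
    if cfg.methylation_noise_sd > 0:
        mean = mean + rng.normal(0.0, cfg.methylation_noise_sd, size=3)
    vals = np.clip(mean, 0.0, 100.0)
    return clock.MethylationProfile(
        sample_id=truth.sample_id,
        elovl2_cpg5=float(vals[0]), klf14_cpg2=float(vals[1]),
        trim59_cpg5=float(vals[2]),
        chronological_age=age, tissue=truth.tissue,
    )


def generate_sample(cfg: CohortConfig, tissue: str, sample_id: str,
                    rng: np.random.Generator) -> CohortSample:
    """Generate one fully simulated sample of the given tissue."""
    truth = _draw_truth(cfg, tissue, sample_id, rng)
    genomes = truth.diploid_genomes_per_reaction
    copies = {
        "GAPDH": genomes * 2.0,  # two alleles per diploid genome
        "EBV": genomes * truth.ebv_copies_per_genome,
        "TCRG": genomes * truth.t_cell_fraction,
    }
    amps = {assay: _amplify(cfg, truth, assay, copies[assay], rng)
            for assay in ("GAPDH", "EBV", "TCRG")}
    melt = simulate_melt(
        _melt_products(cfg, truth, rng), noise_sd=cfg.melt_noise_sd,
        seed=rng, sample_id=truth.sample_id, assay="TCRB",
    )
    meth = _methylation(cfg, truth, rng)
    return CohortSample(truth=truth, amplification=amps, melt=melt, methylation=meth)


def generate_cohort(cfg: CohortConfig) -> list[CohortSample]:
    """Generate ``n_blood + n_lcl`` labelled samples (blood first).

    Each sample draws from its own generator spawned off the cohort seed, so
    the cohort is reproducible and insensitive to how many samples precede a
    given one only in id, not in randomness ordering.
    """
    n_total = cfg.n_blood + cfg.n_lcl
    if n_total == 0:
        return []
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_total)
    samples: list[CohortSample] = []
    for i in range(cfg.n_blood):
        rng = np.random.default_rng(seeds[i])
        samples.append(generate_sample(cfg, TISSUE_BLOOD, f"B{i + 1:04d}", rng))
    for j in range(cfg.n_lcl):
        rng = np.random.default_rng(seeds[cfg.n_blood + j])
        samples.append(generate_sample(cfg, TISSUE_LCL, f"L{j + 1:04d}", rng))
    return samples
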