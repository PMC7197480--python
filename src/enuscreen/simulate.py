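"""Synthetic ENU suppressor screens: variants, pedigrees, and phenotypes.

Generates complete backcross screens with the statistical structure the
downstream analyses assume, so that scoring, segregation testing,
filtering, and association can all be exercised end to end without colony
data.  The generative model:

* **Pedigree.** A mutagenized N1 founder carries 1–3 dominant suppressor
  loci; each locus passes to each N2 with probability 1/2 and from a
  carrier N2 to each N3 with probability 1/2, loci independent unless a
  pairwise recombination fraction declares them linked.
* **Ordinal health.** Each animal-week has a latent health severity
  (higher = sicker): a disease baseline, plus per-locus latent shifts
  (negative = healthier) and optional pairwise interactions, plus a
  shared per-week Gaussian frailty, plus independent standard-logistic
  noise per parameter; parameter-specific cutpoints threshold it to the
  0/1/2 scores.  The frailty induces cross-trait correlation while each
  parameter remains marginally (approximately) proportional-odds.
* **Weight.** Gaussian, with a per-gram-per-latent-unit genotype shift.
* **Survival.** Weibull accelerated failure time: the scale (and hence
  every quantile, including the median) is multiplied by
  exp(sum of carrier log-accelerations); administrative right-censoring
  at a fixed sacrifice age.
* **Founder variants.** Poisson-many lesions per founder, with
  consequence and substitution classes drawn from the ENU spectrum
  (mostly missense; A>G and T>C transitions dominate) and positions drawn
  from a small synthetic gene catalogue.

Wild-type (non-Mecp2-null) littermates get a large negative latent offset
placing them at score ~0, the wild-type anchor of the scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .scoring import (
    SUBJECTIVE_PARAMETERS,
    HealthAssessment,
    InvalidInputError,
)
from .variants import BASES, SUBSTITUTION_CLASSES, Variant

ARCHITECTURES = ("single", "additive", "epistatic", "independent")

# Synthetic gene catalogue (gene, chrom, start, length in bp).  Names echo
# genes recurrently hit in mouse ENU screens; the coordinates are invented
# and serve only to give simulated lesions plausible positions.  Ttn is
# huge and soaks up alleles in nearly every real screen, which the length
# weighting reproduces.
GENE_CATALOGUE: Tuple[Tuple[str, str, int, int], ...] = (
    ("Ttn", "chr2", 76_700_000, 280_000),
    ("Sqle", "chr15", 59_300_000, 20_000),
    ("Rbbp8", "chr18", 11_700_000, 40_000),
    ("Tet1", "chr10", 62_800_000, 60_000),
    ("Birc6", "chr17", 74_500_000, 120_000),
    ("Celsr3", "chr9", 108_800_000, 26_000),
    ("Kdm4a", "chr4", 118_000_000, 45_000),
    ("Cd22", "chr7", 30_800_000, 15_000),
    ("Aacs", "chr5", 125_500_000, 55_000),
    ("Atp8a1", "chr5", 67_600_000, 180_000),
    ("Tm7sf2", "chr19", 6_000_000, 4_000),
    ("Apoa5", "chr9", 46_200_000, 3_000),
    ("Fan1", "chr7", 64_300_000, 30_000),
    ("Shank1", "chr7", 44_300_000, 50_000),
    ("Hcn2", "chr10", 79_700_000, 25_000),
    ("Arhgef15", "chr11", 68_900_000, 20_000),
    ("Spin1", "chr13", 51_100_000, 45_000),
    ("Dbnl", "chr11", 5_790_000, 12_000),
    ("Gtf3c5", "chr2", 28_500_000, 18_000),
    ("Clint1", "chr11", 45_800_000, 60_000),
    ("Prdm15", "chr16", 97_800_000, 70_000),
    ("Zzz3", "chr3", 152_400_000, 55_000),
    ("Brca1", "chr11", 101_500_000, 60_000),
    ("Brca2", "chr5", 150_500_000, 47_000),
    ("Mre11a", "chr9", 14_800_000, 40_000),
    ("Rad50", "chr11", 53_600_000, 55_000),
    ("Ncor1", "chr11", 62_300_000, 100_000),
    ("Sin3a", "chr9", 57_000_000, 50_000),
    ("Rcor1", "chr12", 111_000_000, 35_000),
    ("Dennd4a", "chr9", 64_800_000, 90_000),
)

DEFAULT_CONSEQUENCE_SPECTRUM: Dict[str, float] = {
    "missense": 0.92,
    "nonsense": 0.04,
    "splice": 0.03,
    "frameshift": 0.01,  # frameshift / stop-loss remainder class
}

# ENU substitution spectrum, as sequenced (12 ordered classes): A>G and
# T>C transitions dominate (22% / 18%), T>A and A>T transversions follow
# (16% / 11%), C>G and G>C are rare (<1%); the remaining mass is spread
# evenly over the other six classes.
DEFAULT_SUBSTITUTION_SPECTRUM: Dict[str, float] = {
    "A>G": 0.22,
    "T>C": 0.18,
    "T>A": 0.16,
    "A>T": 0.11,
    "C>G": 0.005,
    "G>C": 0.005,
    **{cls: 0.32 / 6 for cls in ("A>C", "C>A", "C>T", "G>A", "G>T", "T>G")},
}

DEFAULT_CUTPOINTS: Dict[str, Tuple[float, float]] = {
    "clasping": (0.5, 2.5),
    "tremor": (0.8, 2.8),
    "activity": (0.6, 2.6),
    "body_condition": (1.0, 3.0),
    "muscle_tone": (1.2, 3.2),
}


def _check_spectrum(name: str, spectrum: Mapping[str, float], keys: Sequence[str]) -> None:
    if set(spectrum) != set(keys):
        raise InvalidInputError(f"{name} must have keys {sorted(keys)}")
    total = sum(spectrum.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidInputError(f"{name} must sum to 1, got {total}")


@dataclass(frozen=True)
class SuppressorModel:
    """Ground-truth genetic architecture of one founder line.

    ``latent_effects`` shift the latent severity per carried locus
    (negative = healthier); ``survival_log_acceleration`` multiplies log
    survival time per locus.  ``interaction_latent`` /
    ``interaction_survival`` add pairwise terms when both loci of a pair
    are carried.  ``linkage`` declares per-pair recombination fractions;
    absent pairs segregate independently.
    """

    loci: Tuple[str, ...]
    latent_effects: Mapping[str, float]
    survival_log_acceleration: Mapping[str, float]
    interaction_latent: Mapping[FrozenSet[str], float] = field(default_factory=dict)
    interaction_survival: Mapping[FrozenSet[str], float] = field(default_factory=dict)
    linkage: Mapping[FrozenSet[str], float] = field(default_factory=dict)
    architecture: str = "additive"

    def __post_init__(self) -> None:
        if not self.loci:
            raise InvalidInputError("at least one locus required")
        if len(set(self.loci)) != len(self.loci):
            raise InvalidInputError("duplicate loci")
        if self.architecture not in ARCHITECTURES:
            raise InvalidInputError(f"unknown architecture {self.architecture!r}")
        declared = set(self.loci)
        for mapping in (self.latent_effects, self.survival_log_acceleration):
            if set(mapping) - declared:
                raise InvalidInputError("effect for undeclared locus")
        for pairs in (self.interaction_latent, self.interaction_survival, self.linkage):
            for pair in pairs:
                if len(pair) != 2 or set(pair) - declared:
                    raise InvalidInputError(
                        f"interaction/linkage pair {set(pair)} must name two declared loci"
                    )
        for pair, r in self.linkage.items():
            if not 0 <= r <= 0.5:
                raise InvalidInputError(
                    f"recombination fraction must be in [0, 0.5], got {r}"
                )

    def latent_shift(self, carrier_flags: Mapping[str, bool]) -> float:
        shift = sum(
            self.latent_effects.get(l, 0.0) for l in self.loci if carrier_flags.get(l)
        )
        for pair, eff in self.interaction_latent.items():
            if all(carrier_flags.get(l) for l in pair):
                shift += eff
        return shift

    def log_acceleration(self, carrier_flags: Mapping[str, bool]) -> float:
        acc = sum(
            self.survival_log_acceleration.get(l, 0.0)
            for l in self.loci
            if carrier_flags.get(l)
        )
        for pair, eff in self.interaction_survival.items():
            if all(carrier_flags.get(l) for l in pair):
                acc += eff
        return acc


def single_locus_model(
    locus: str = "SupA",
    latent_effect: float = -2.5,
    log_acceleration: float = math.log(112 / 77),
) -> SuppressorModel:
    """One dominant suppressor: healthier scores, longer life in carriers."""
    return SuppressorModel(
        loci=(locus,),
        latent_effects={locus: latent_effect},
        survival_log_acceleration={locus: log_acceleration},
        architecture="single",
    )


def two_locus_model(
    architecture: str = "additive",
    loci: Tuple[str, str] = ("SupA", "SupB"),
    latent_effect: float = -2.5,
    log_acceleration: float = math.log(112 / 77),
    recombination: Optional[float] = None,
) -> SuppressorModel:
    """Two-suppressor architectures seen in real lines.

    ``additive``: each locus improves on its own and effects add.
    ``independent``: each improves different margins on its own, no bonus
    (here: both act, no interaction — distinguishable from additive only
    through the interaction term being null).
    ``epistatic``: neither locus does anything alone; improvement requires
    both (the both-required pattern behind unresolved lines).
    """
    a, b = loci
    pair = frozenset(loci)
    if architecture in ("additive", "independent"):
        latent = {a: latent_effect, b: latent_effect}
        accel = {a: log_acceleration, b: log_acceleration}
        inter_l: Dict[FrozenSet[str], float] = {}
        inter_s: Dict[FrozenSet[str], float] = {}
    elif architecture == "epistatic":
        latent = {a: 0.0, b: 0.0}
        accel = {a: 0.0, b: 0.0}
        inter_l = {pair: 2 * latent_effect}
        inter_s = {pair: 2 * log_acceleration}
    else:
        raise InvalidInputError(f"unknown two-locus architecture {architecture!r}")
    return SuppressorModel(
        loci=loci,
        latent_effects=latent,
        survival_log_acceleration=accel,
        interaction_latent=inter_l,
        interaction_survival=inter_s,
        linkage={pair: recombination} if recombination is not None else {},
        architecture=architecture,
    )


@dataclass(frozen=True)
class ScreenConfig:
    """Sizes, spectra, and phenotype-model parameters of a simulated screen.

    Defaults reflect the study conditions: ~10 N2 families of ~10 assessed
    Mecp2/Y N3 each where possible, a mean of 50 candidate lesions per
    founder with the ENU consequence/substitution spectra, baseline
    Mecp2/Y median survival of 77 d with sacrifice (censoring) at 98 d,
    and a disease baseline severe enough that unsuppressed animals
    typically score >= 8 of 12 at 8 wk.
    """

    n_lines: int = 1
    n2_families_per_line: int = 10
    n3_per_family: int = 10
    n3_wildtype_per_family: int = 2
    variants_per_founder_mean: float = 50.0
    consequence_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_SPECTRUM)
    )
    substitution_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_SPECTRUM)
    )
    weibull_shape: float = 4.0
    baseline_median_survival_days: float = 77.0
    censor_age_days: int = 98
    baseline_latent: float = 4.0
    wildtype_latent_offset: float = -8.0
    shared_frailty_sd: float = 0.5
    ordinal_cutpoints: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CUTPOINTS)
    )
    weight_mean_g: float = 32.0
    weight_sd_g: float = 3.0
    wildtype_weight_mean_g: float = 25.0
    weight_per_latent_g: float = 1.0
    assessment_ages_days: Tuple[int, ...] = tuple(range(35, 84, 7))

    def __post_init__(self) -> None:
        for name in ("n_lines", "n2_families_per_line", "n3_per_family"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")
        if self.n3_wildtype_per_family < 0:
            raise InvalidInputError("n3_wildtype_per_family must be >= 0")
        if self.variants_per_founder_mean < 0:
            raise InvalidInputError("variants_per_founder_mean must be >= 0")
        _check_spectrum(
            "consequence_spectrum",
            self.consequence_spectrum,
            tuple(DEFAULT_CONSEQUENCE_SPECTRUM),
        )
        _check_spectrum(
            "substitution_spectrum", self.substitution_spectrum, SUBSTITUTION_CLASSES
        )
        for param, (c1, c2) in self.ordinal_cutpoints.items():
            if param not in SUBJECTIVE_PARAMETERS:
                raise InvalidInputError(f"unknown parameter {param!r}")
            if not c1 < c2:
                raise InvalidInputError(
                    f"cutpoints for {param} must be strictly increasing"
                )
        if set(self.ordinal_cutpoints) != set(SUBJECTIVE_PARAMETERS):
            raise InvalidInputError("cutpoints required for all five parameters")
        if self.weibull_shape <= 0 or self.baseline_median_survival_days <= 0:
            raise InvalidInputError("Weibull parameters must be positive")

    @property
    def weibull_scale_days(self) -> float:
        """Baseline scale so the survival median equals the configured value."""
        return self.baseline_median_survival_days / math.log(2) ** (
            1.0 / self.weibull_shape
        )


@dataclass
class SimAnimal:
    animal_id: str
    line: str
    family: str
    generation: str  # N1 / N2 / N3
    mecp2_null: bool
    carrier_flags: Dict[str, bool]
    assessments: List[HealthAssessment] = field(default_factory=list)
    survival_days: Optional[int] = None
    censored: Optional[bool] = None


@dataclass
class SimLine:
    founder: SimAnimal
    families: List[Tuple[SimAnimal, List[SimAnimal]]]
    truth: SuppressorModel

    @property
    def n3_animals(self) -> List[SimAnimal]:
        return [a for _, offspring in self.families for a in offspring]

    @property
    def all_animals(self) -> List[SimAnimal]:
        out = [self.founder]
        for parent, offspring in self.families:
            out.append(parent)
            out.extend(offspring)
        return out


def _linked_groups(model: SuppressorModel) -> List[Tuple[str, ...]]:
    """Loci partitioned into linked pairs and unlinked singletons."""
    paired = set()
    groups: List[Tuple[str, ...]] = []
    for pair in model.linkage:
        a, b = sorted(pair)
        if a in paired or b in paired:
            raise InvalidInputError("a locus may belong to at most one linked pair")
        paired.update(pair)
        groups.append((a, b))
    groups.extend((l,) for l in model.loci if l not in paired)
    return groups


def _transmit(
    parent_flags: Mapping[str, bool],
    model: SuppressorModel,
    rng: np.random.Generator,
) -> Dict[str, bool]:
    """One meiosis: each carried locus passes w.p. 1/2; linked pairs jointly.

    A parent heterozygous in cis for a linked pair transmits both with
    probability (1-r)/2, neither with (1-r)/2, and each alone with r/2.
    """
    child: Dict[str, bool] = {l: False for l in model.loci}
    for group in _linked_groups(model):
        if len(group) == 1:
            (locus,) = group
            if parent_flags.get(locus):
                child[locus] = bool(rng.random() < 0.5)
        else:
            a, b = group
            r = model.linkage[frozenset(group)]
            carries_a, carries_b = parent_flags.get(a, False), parent_flags.get(b, False)
            if carries_a and carries_b:
                u = rng.random()
                if u < (1 - r) / 2:
                    child[a] = child[b] = True
                elif u < 1 - r:
                    pass  # neither
                elif u < 1 - r / 2:
                    child[a] = True
                else:
                    child[b] = True
            else:
                if carries_a:
                    child[a] = bool(rng.random() < 0.5)
                if carries_b:
                    child[b] = bool(rng.random() < 0.5)
    return child


def simulate_pedigree(
    config: ScreenConfig,
    model: SuppressorModel,
    rng_seed: int,
    line_id: str = "line1",
) -> SimLine:
    """Found a line carrying every model locus and backcross N1 -> N2 -> N3.

    Genotypes only; phenotypes are filled by :func:`simulate_phenotypes`.
    Wild-type N3 littermates (``n3_wildtype_per_family``) are generated
    alongside the assessed Mecp2/Y N3s.
    """
    rng = np.random.default_rng(rng_seed)
    founder = SimAnimal(
        animal_id=f"{line_id}_N1",
        line=line_id,
        family="founder",
        generation="N1",
        mecp2_null=True,
        carrier_flags={l: True for l in model.loci},
    )
    families = []
    for fam_idx in range(config.n2_families_per_line):
        fam = f"F{fam_idx + 1}"
        parent = SimAnimal(
            animal_id=f"{line_id}_{fam}_N2",
            line=line_id,
            family=fam,
            generation="N2",
            mecp2_null=False,  # N2 dams/sires are not themselves assessed
            carrier_flags=_transmit(founder.carrier_flags, model, rng),
        )
        offspring = []
        for i in range(config.n3_per_family + config.n3_wildtype_per_family):
            is_null = i < config.n3_per_family
            offspring.append(
                SimAnimal(
                    animal_id=f"{line_id}_{fam}_N3_{i + 1}",
                    line=line_id,
                    family=fam,
                    generation="N3",
                    mecp2_null=is_null,
                    carrier_flags=_transmit(parent.carrier_flags, model, rng),
                )
            )
        families.append((parent, offspring))
    return SimLine(founder=founder, families=families, truth=model)


def _simulate_animal_phenotype(
    animal: SimAnimal,
    model: SuppressorModel,
    config: ScreenConfig,
    rng: np.random.Generator,
) -> None:
    if animal.mecp2_null:
        shift = model.latent_shift(animal.carrier_flags)
        location = config.baseline_latent + shift
        weight_mean = config.weight_mean_g + config.weight_per_latent_g * shift
        scale = config.weibull_scale_days * math.exp(
            model.log_acceleration(animal.carrier_flags)
        )
        t = scale * rng.weibull(config.weibull_shape)
        if t >= config.censor_age_days:
            animal.survival_days, animal.censored = config.censor_age_days, True
        else:
            animal.survival_days, animal.censored = max(1, int(round(t))), False
    else:
        location = config.baseline_latent + config.wildtype_latent_offset
        weight_mean = config.wildtype_weight_mean_g
        animal.survival_days, animal.censored = config.censor_age_days, True

    animal.assessments = []
    for age in config.assessment_ages_days:
        if age > animal.survival_days:
            break
        frailty = rng.normal(0.0, config.shared_frailty_sd)
        scores = {}
        for param in SUBJECTIVE_PARAMETERS:
            c1, c2 = config.ordinal_cutpoints[param]
            latent = location + frailty + rng.logistic(0.0, 1.0)
            scores[param] = 0 if latent < c1 else (1 if latent < c2 else 2)
        weight = max(1.0, rng.normal(weight_mean, config.weight_sd_g))
        animal.assessments.append(
            HealthAssessment(
                animal_id=animal.animal_id,
                age_days=age,
                body_weight_g=float(round(weight, 1)),
                **scores,
            )
        )


def simulate_phenotypes(
    line: SimLine, config: ScreenConfig, rng_seed: int
) -> SimLine:
    """Fill assessments and survival for the founder and every N3.

    Deterministic given the seed; assessments run weekly from P35 until
    death or sacrifice.
    """
    rng = np.random.default_rng(rng_seed)
    _simulate_animal_phenotype(line.founder, line.truth, config, rng)
    for _, offspring in line.families:
        for animal in offspring:
            _simulate_animal_phenotype(animal, line.truth, config, rng)
    return line


def simulate_line(
    config: ScreenConfig,
    model: SuppressorModel,
    rng_seed: int,
    line_id: str = "line1",
) -> SimLine:
    """Pedigree plus phenotypes in one call (independent sub-seeds)."""
    seeds = np.random.SeedSequence(rng_seed).generate_state(2)
    line = simulate_pedigree(config, model, int(seeds[0]), line_id=line_id)
    return simulate_phenotypes(line, config, int(seeds[1]))


def simulate_founder_variants(
    config: ScreenConfig, rng_seed: int, line_id: str = "line1"
) -> List[Variant]:
    """Draw a founder's candidate lesion list from the ENU spectra.

    Poisson-many variants; genes sampled proportional to length from the
    synthetic catalogue; consequence and substitution classes from the
    configured spectra.  Predictions are all "damaging" (the list emulates
    a post-tolerance-filter candidate set).
    """
    rng = np.random.default_rng(rng_seed)
    n = rng.poisson(config.variants_per_founder_mean)
    if n == 0:
        return []
    lengths = np.array([g[3] for g in GENE_CATALOGUE], dtype=float)
    gene_p = lengths / lengths.sum()
    cons_keys = list(config.consequence_spectrum)
    cons_p = np.array([config.consequence_spectrum[k] for k in cons_keys])
    sub_keys = list(config.substitution_spectrum)
    sub_p = np.array([config.substitution_spectrum[k] for k in sub_keys])
    out = []
    used_pos = set()
    for _ in range(n):
        gene, chrom, start, length = GENE_CATALOGUE[rng.choice(len(GENE_CATALOGUE), p=gene_p)]
        pos = int(start + rng.integers(0, length))
        while (chrom, pos) in used_pos:
            pos = int(start + rng.integers(0, length))
        used_pos.add((chrom, pos))
        ref, alt = sub_keys[rng.choice(len(sub_keys), p=sub_p)].split(">")
        out.append(
            Variant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                line=line_id,
                consequence=cons_keys[rng.choice(len(cons_keys), p=cons_p)],
                prediction="damaging",
            )
        )
    return out


def simulate_screen(
    config: ScreenConfig,
    model: SuppressorModel,
    rng_seed: int,
) -> Tuple[List[SimLine], Dict[str, List[Variant]]]:
    """``n_lines`` full lines (pedigree + phenotypes) plus founder variants."""
    seeds = np.random.SeedSequence(rng_seed).spawn(config.n_lines)
    lines, variants = [], {}
    for i, ss in enumerate(seeds):
        line_id = f"line{i + 1}"
        sub = ss.generate_state(2)
        lines.append(
            simulate_line(config, model, int(sub[0]), line_id=line_id)
        )
        variants[line_id] = simulate_founder_variants(
            config, int(sub[1]), line_id=line_id
        )
    return lines, variants
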