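"""Synthetic rearing-study generator with known ground truth.

Emulates the design of the Melissa blue (Lycaeides melissa) rearing
experiment that the analysis pipeline targets: two source populations
(BST, HWR) crossed with two host plants (Medicago sativa "Me", Lupinus
argenteus "Lu"), caterpillars sampled at 15, 20 and 25 days via frass
(non-lethal) or sacrifice (whole-caterpillar), plus leaf epiphyte and
endophyte samples.  Community counts are Dirichlet-multinomial: each
sample's composition is drawn around a treatment- and age-specific mean,
whole-caterpillar samples receive a Wolbachia spike (an intracellular
endosymbiont abundant in insect tissue but nearly absent from frass),
diversity declines with age, host plant affects weight, and population
affects survival.  Default effect sizes are the study's reported posterior
medians, so recovery tests run against realistic truths.

All randomness flows from a single seed; the realized generative
parameters are recorded in ``SimulatedStudy.truth``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .otu_table import (
    OtuTable,
    Plant,
    Population,
    SampleMetadata,
    SampleType,
    TaxonomyLineage,
)

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "simulate_dm_counts"]

WOLBACHIA_LINEAGE = (
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; "
    "f__Rickettsiaceae; g__Wolbachia"
)

# Plausible 16S lineages for community OTUs, cycled across the table; the
# first three carry the orders reported as treatment-responsive so the
# differential-abundance stage has named targets.
_COMMUNITY_LINEAGES = [
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Streptococcaceae; g__Lactococcus",
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Pseudomonadales; f__Pseudomonadaceae; g__Pseudomonas",
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhizobiales; f__Rhizobiaceae; g__Rhizobium",
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Enterobacteriales; f__Enterobacteriaceae; g__Enterobacter",
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Sphingomonadales; f__Sphingomonadaceae; g__Sphingomonas",
    "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Burkholderiales; f__Comamonadaceae; g__Delftia",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__Microbacteriaceae; g__Microbacterium",
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Xanthomonadales; f__Xanthomonadaceae; g__Stenotrophomonas",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Bacillaceae; g__Bacillus",
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhodospirillales; f__Acetobacteraceae; g__Gluconobacter",
]

_CONTAMINANT_LINEAGES = [
    ("Chloro1", "k__Bacteria; p__Cyanobacteria; c__Chloroplast; o__Streptophyta"),
    ("Chloro2", "k__Bacteria; p__Cyanobacteria; c__Chloroplast; o__Chlorophyta"),
    ("Mito1", "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; f__mitochondria"),
    ("Unassigned1", "Unassigned"),
]


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic rearing study.

    Defaults are the study conditions: 181 caterpillars allocated equally
    across population x plant cells, ages 15/20/25 days, Wolbachia relative
    abundance in whole-caterpillar samples with mean 0.37 and s.d. 0.36,
    weight slopes (mg) beta_age = 0.225 and beta_plant(Me) = -0.961,
    survival logit coefficients a_pop(BST) = -0.56 and a_plant(Lu) = -0.15
    with intercept -0.49 (marginal survival ~0.31), and a mean diversity
    decline of 0.151 effective phylotypes per day of larval age.
    """

    n_caterpillars: int = 181
    treatments: tuple[tuple[tuple[str, str], float], ...] = (
        (("BST", "Me"), 0.25),
        (("BST", "Lu"), 0.25),
        (("HWR", "Me"), 0.25),
        (("HWR", "Lu"), 0.25),
    )
    ages: tuple[int, ...] = (15, 20, 25)
    n_otus: int = 40
    # concentration vectors per treatment; None = power-law default with
    # treatment-specific multipliers on three indicator OTUs
    base_composition: dict[tuple[str, str], np.ndarray] | None = None
    total_concentration: float = 50.0
    composition_power: float = 0.9
    treatment_effect_multiplier: float = 2.5
    type_effect: np.ndarray | None = None  # per-OTU multiplier for larva samples
    wolbachia_mean: float = 0.37
    wolbachia_sd: float = 0.36
    frass_wolbachia_mean: float = 0.0007
    age_diversity_slope: float = -0.151  # effective phylotypes per day
    depth_lognormal_params: tuple[float, float] = (math.log(5000.0), 0.6)
    amplification_failure_prob: float = 0.5
    failure_depth_max: int = 1310
    sacrifice_prob: float = 0.2
    n_plant_samples_per_kind: int = 3  # per (epiphyte/endophyte) x plant species
    # weight model (mg): b0, b_plant (Me=1), b_pop (BST=1), b_age (per day), residual sd
    weight_model: tuple[float, float, float, float, float] = (2.0, -0.961, 0.0, 0.225, 1.0)
    # survival to 15 d on the logit scale: a0, a_pop (BST=1), a_plant (Lu=1)
    survival_model: tuple[float, float, float] = (-0.49, -0.56, -0.15)
    calibration_depth: int = 500  # analysis depth at which the diversity slope is defined
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [p for _, p in self.treatments]
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValueError("treatment allocation probabilities must sum to 1")
        if not 0 <= self.wolbachia_mean < 1:
            raise ValueError("wolbachia_mean must be in [0, 1)")
        if self.total_concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.base_composition is not None:
            for k, a in self.base_composition.items():
                if np.any(np.asarray(a) <= 0):
                    raise ValueError(f"non-positive concentration for treatment {k}")

    def treatment_names(self) -> list[tuple[str, str]]:
        return [t for t, _ in self.treatments]


@dataclass
class SimulatedStudy:
    otu_table: OtuTable
    metadata: list[SampleMetadata]
    truth: dict

    def __post_init__(self) -> None:
        table_ids = set(self.otu_table.sample_ids)
        meta_ids = {m.sample_id for m in self.metadata}
        if table_ids != meta_ids:
            raise ValueError("metadata and table sample ids do not match")


def simulate_dm_counts(pi: np.ndarray, depth: int, seed) -> np.ndarray:
    """One multinomial draw of ``depth`` sequences with composition ``pi``."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0):
        raise ValueError("pi entries must be non-negative")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must sum to 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, pi)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    v = sd * sd
    limit = mean * (1.0 - mean)
    if v >= limit:
        raise ValueError(f"sd {sd} too large for a Beta with mean {mean}")
    common = limit / v - 1.0
    return mean * common, (1.0 - mean) * common


def _default_base_probs(config: SimulationConfig) -> np.ndarray:
    """Shared community composition over n_otus-1 free OTUs (index 0 is the
    designated Wolbachia OTU, which carries no community mass)."""
    k = config.n_otus - 1
    raw = (np.arange(1, k + 1)) ** (-config.composition_power)
    p = np.zeros(config.n_otus)
    p[1:] = raw / raw.sum()
    return p


def _treatment_probs(config: SimulationConfig) -> dict[tuple[str, str], np.ndarray]:
    if config.base_composition is not None:
        return {
            t: np.asarray(a, dtype=float) / np.asarray(a, dtype=float).sum()
            for t, a in config.base_composition.items()
        }
    base = _default_base_probs(config)
    m = config.treatment_effect_multiplier
    out = {}
    for pop, plant in config.treatment_names():
        p = base.copy()
        # OTU 1 (Lactobacillales-like) responds to Lu diet, OTU 2
        # (Pseudomonadales-like) to Me diet, OTU 3 (Rhizobiales-like) to BST
        if plant == "Lu":
            p[1] *= m
        if plant == "Me":
            p[2] *= m
        if pop == "BST":
            p[3] *= m
        out[(pop, plant)] = p / p.sum()
    return out


def _predicted_mean_d2(p: np.ndarray, c: float, depth: int,
                       rng: np.random.Generator, n_mc: int = 4000) -> float:
    """Moment-based prediction of the mean observed inverse-Simpson diversity
    for samples with composition ~ Dirichlet(c*p) counted to ``depth``."""
    active = p > 0
    draws = rng.dirichlet(c * p[active], size=n_mc)
    simpson = (draws**2).sum(axis=1)
    plug_in = (1.0 - 1.0 / depth) * simpson + 1.0 / depth
    return float(np.mean(1.0 / plug_in))


# calibration cache: the bisection below is deterministic given the mean
# composition, concentration, depth, slope and age grid, so repeated
# simulations under one design pay for it once
_EXPONENT_CACHE: dict[tuple, dict[int, float]] = {}


def _solve_age_exponents(config: SimulationConfig,
                         mean_probs: np.ndarray) -> dict[int, float]:
    """Solve the per-age power exponent t so that the predicted mean observed
    diversity follows D(age) = D(age0) + slope * (age - age0).

    The power transform p^t (renormalized) changes evenness without changing
    OTU identity; t = 1 at the youngest age.  Solved by bisection against a
    fixed-seed Monte-Carlo moment prediction, so the calibration is
    deterministic and independent of the study seed.
    """
    ages = sorted(config.ages)
    exponents = {ages[0]: 1.0}
    if len(ages) == 1 or config.age_diversity_slope == 0:
        return {a: 1.0 for a in ages}
    c, depth = config.total_concentration, config.calibration_depth
    cache_key = (
        tuple(np.round(mean_probs, 12)), c, depth,
        config.age_diversity_slope, tuple(ages),
    )
    if cache_key in _EXPONENT_CACHE:
        return dict(_EXPONENT_CACHE[cache_key])
    d0 = _predicted_mean_d2(mean_probs, c, depth, np.random.default_rng(987654321))

    def predicted(t: float) -> float:
        # monotone decreasing in t: larger exponent -> more uneven -> lower D
        active = mean_probs > 0
        pt = np.zeros_like(mean_probs)
        pt[active] = mean_probs[active] ** t
        pt /= pt.sum()
        return _predicted_mean_d2(pt, c, depth, np.random.default_rng(987654321))

    for age in ages[1:]:
        target = d0 + config.age_diversity_slope * (age - ages[0])
        if target < 1.5:
            raise ValueError("age_diversity_slope drives diversity below its floor")
        lo, hi = 0.05, 6.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if predicted(mid) > target:
                lo = mid
            else:
                hi = mid
        exponents[age] = 0.5 * (lo + hi)
    _EXPONENT_CACHE[cache_key] = dict(exponents)
    return exponents


def _age_transform(p: np.ndarray, t: float) -> np.ndarray:
    active = p > 0
    out = np.zeros_like(p)
    out[active] = p[active] ** t
    return out / out.sum()


def _taxonomies(n_otus: int) -> tuple[list[str], list[TaxonomyLineage]]:
    otu_ids = ["OTU_wolbachia"]
    lineages = [TaxonomyLineage.parse(WOLBACHIA_LINEAGE)]
    for i in range(1, n_otus):
        base = _COMMUNITY_LINEAGES[(i - 1) % len(_COMMUNITY_LINEAGES)]
        otu_ids.append(f"OTU_{i:03d}")
        lineages.append(TaxonomyLineage.parse(base))
    for name, lin in _CONTAMINANT_LINEAGES:
        otu_ids.append(f"OTU_{name}")
        lineages.append(TaxonomyLineage.parse(lin))
    return otu_ids, lineages


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study: OTU table, metadata, and truth record.

    Each caterpillar is assigned a population x plant treatment; survival to
    15 days is Bernoulli on the logit scale.  Survivors yield a frass sample
    at each sampling age until (with probability ``sacrifice_prob`` per age)
    they are sacrificed, producing a whole-caterpillar sample instead.  Leaf
    epiphyte/endophyte samples are added per plant species and site.  Counts
    are Multinomial(depth, pi) with pi ~ Dirichlet around the treatment/age
    mean; whole-caterpillar samples mix in a Beta-distributed Wolbachia
    fraction; contaminant OTUs (chloroplast, mitochondria, unassigned)
    are included so the taxonomic filters have work to do.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_assign, s_surv, s_weight, s_comp, s_depth, s_counts, s_wolb,
     s_sac) = ss.spawn(8)
    rng_assign = np.random.default_rng(s_assign)
    rng_surv = np.random.default_rng(s_surv)
    rng_weight = np.random.default_rng(s_weight)
    rng_comp = np.random.default_rng(s_comp)
    rng_depth = np.random.default_rng(s_depth)
    rng_counts = np.random.default_rng(s_counts)
    rng_wolb = np.random.default_rng(s_wolb)
    rng_sac = np.random.default_rng(s_sac)

    treat_probs = _treatment_probs(config)
    mean_probs = np.mean([treat_probs[t] for t in config.treatment_names()], axis=0)
    exponents = _solve_age_exponents(config, mean_probs)
    b0, b_plant, b_pop, b_age, resid_sd = config.weight_model
    a0, a_pop, a_plant = config.survival_model
    n_otus_total = config.n_otus + len(_CONTAMINANT_LINEAGES)
    otu_ids, lineages = _taxonomies(config.n_otus)
    # contaminant relative concentrations (of the pre-contaminant mass)
    contam_frass = np.array([0.02, 0.01, 0.01, 0.01])
    contam_plant = np.array([0.10, 0.05, 0.005, 0.01])

    if config.wolbachia_mean > 0 and config.wolbachia_sd > 0:
        wolb_a, wolb_b = _beta_params(config.wolbachia_mean, config.wolbachia_sd)
    else:
        wolb_a = wolb_b = None
    frass_w = (
        config.frass_wolbachia_mean * (config.wolbachia_mean / 0.37)
        if config.wolbachia_mean > 0
        else 0.0
    )

    treat_names = config.treatment_names()
    probs = np.array([p for _, p in config.treatments])
    assignment = rng_assign.choice(len(treat_names), size=config.n_caterpillars, p=probs)

    type_mult = (
        np.ones(config.n_otus) if config.type_effect is None
        else np.asarray(config.type_effect, dtype=float)
    )

    def community_probs(treatment: tuple[str, str], age: int | None,
                        sample_type: SampleType) -> np.ndarray:
        p = treat_probs[treatment].copy()
        if age is not None:
            p = _age_transform(p, exponents[age])
        if sample_type == SampleType.LARVA:
            p = p * type_mult
            p = p / p.sum()
        return p

    def draw_depth() -> int:
        if rng_depth.random() < config.amplification_failure_prob:
            return int(rng_depth.integers(10, config.failure_depth_max + 1))
        meanlog, sdlog = config.depth_lognormal_params
        return max(1, int(round(rng_depth.lognormal(meanlog, sdlog))))

    def realized_counts(p_comm: np.ndarray, sample_type: SampleType,
                        depth: int) -> tuple[np.ndarray, float]:
        # Wolbachia spike by mixing: pi = (1 - w) * pi_community + w * e_wolb
        if sample_type == SampleType.LARVA:
            if wolb_a is not None:
                w = float(rng_wolb.beta(wolb_a, wolb_b))
            else:
                w = config.wolbachia_mean
        elif sample_type == SampleType.FRASS:
            w = frass_w
        else:
            w = 0.0
        active = p_comm > 0
        pi = np.zeros(config.n_otus)
        if active.any():
            conc = config.total_concentration * p_comm[active]
            pi[active] = rng_comp.dirichlet(conc)
        pi = (1.0 - w) * pi
        pi[0] += w
        contam = contam_plant if sample_type.is_plant else contam_frass
        full = np.concatenate([pi, contam])
        full = full / full.sum()
        return rng_counts.multinomial(depth, full), w

    counts_rows: list[np.ndarray] = []
    metadata: list[SampleMetadata] = []
    sample_ids: list[str] = []
    depths: dict[str, int] = {}
    wolb_fracs: dict[str, float] = {}
    n_families = 20

    def add_sample(sid: str, meta: SampleMetadata, p_comm: np.ndarray,
                   stype: SampleType) -> None:
        depth = draw_depth()
        row, w = realized_counts(p_comm, stype, depth)
        counts_rows.append(row)
        metadata.append(meta)
        sample_ids.append(sid)
        depths[sid] = depth
        wolb_fracs[sid] = w

    survived = np.zeros(config.n_caterpillars, dtype=bool)
    weights_truth: dict[str, dict[int, float]] = {}
    caterpillars: list[dict] = []
    for i in range(config.n_caterpillars):
        pop, plant = treat_names[assignment[i]]
        cat_id = f"cat{i + 1:03d}"
        eta = a0 + a_pop * (pop == "BST") + a_plant * (plant == "Lu")
        alive = rng_surv.random() < 1.0 / (1.0 + math.exp(-eta))
        survived[i] = alive
        caterpillars.append(
            {
                "cat_id": cat_id,
                "population": pop,
                "plant": plant,
                "survived_15d": bool(alive),
                "family_id": f"fam{(i % n_families) + 1:02d}",
            }
        )
        if not alive:
            continue
        weights_truth[cat_id] = {}
        sacrificed = False
        for age in sorted(config.ages):
            if sacrificed:
                break
            mu_w = b0 + b_plant * (plant == "Me") + b_pop * (pop == "BST") + b_age * age
            weight = mu_w + (rng_weight.normal(0.0, resid_sd) if resid_sd > 0 else 0.0)
            weight = max(weight, 0.0)
            weights_truth[cat_id][age] = weight
            sacrifice_now = rng_sac.random() < config.sacrifice_prob
            stype = SampleType.LARVA if sacrifice_now else SampleType.FRASS
            sid = f"{cat_id}_{'lar' if sacrifice_now else 'fr'}_{age}d"
            meta = SampleMetadata(
                sample_id=sid,
                sample_type=stype,
                population=Population(pop),
                plant=Plant(plant),
                age_days=age,
                weight_mg=weight,
                survived_15d=True,
                family_id=f"fam{(i % n_families) + 1:02d}",
            )
            add_sample(sid, meta, community_probs((pop, plant), age, stype), stype)
            sacrificed = sacrifice_now

    # leaf samples: epiphyte + endophyte per plant species, sites alternating
    plant_kinds = [SampleType.PLANT_EPIPHYTE, SampleType.PLANT_ENDOPHYTE]
    sites = ["BST", "HWR"]
    for plant in ("Me", "Lu"):
        for kind in plant_kinds:
            for r in range(config.n_plant_samples_per_kind):
                site = sites[r % 2]
                if (site, plant) not in treat_probs:
                    site = next(s for s in sites if (s, plant) in treat_probs)
                sid = f"plant_{plant}_{kind.value.split('_')[1]}_{site}_{r + 1}"
                meta = SampleMetadata(
                    sample_id=sid,
                    sample_type=kind,
                    population=Population(site),
                    plant=Plant(plant),
                )
                add_sample(sid, meta, community_probs((site, plant), None, kind), kind)

    table = OtuTable(
        counts=np.asarray(counts_rows, dtype=np.int64),
        sample_ids=sample_ids,
        otu_ids=otu_ids,
        taxonomy=lineages,
    )
    truth = {
        "seed": config.seed,
        "treatment_compositions": {
            f"{pop}-{plant}": treat_probs[(pop, plant)].tolist()
            for pop, plant in treat_names
        },
        "age_exponents": {str(a): t for a, t in exponents.items()},
        "age_diversity_slope": config.age_diversity_slope,
        "weight_model": {
            "b0": b0, "b_plant_Me": b_plant, "b_pop_BST": b_pop,
            "b_age": b_age, "residual_sd": resid_sd,
        },
        "survival_model": {"a0": a0, "a_pop_BST": a_pop, "a_plant_Lu": a_plant},
        "wolbachia": {"mean": config.wolbachia_mean, "sd": config.wolbachia_sd,
                      "frass_mean": frass_w},
        "n_caterpillars": config.n_caterpillars,
        "n_survived_15d": int(survived.sum()),
        "caterpillars": caterpillars,
        "depths": depths,
        "wolbachia_fractions": wolb_fracs,
        "weights": weights_truth,
        "warnings": [],
    }
    cell_counts = {
        f"{pop}-{plant}": int(np.sum(assignment == k))
        for k, (pop, plant) in enumerate(treat_names)
    }
    truth["cell_counts"] = cell_counts
    for cell, n in cell_counts.items():
        if n == 0:
            truth["warnings"].append(f"treatment cell {cell} received no caterpillars")
    return SimulatedStudy(otu_table=table, metadata=metadata, truth=truth)
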