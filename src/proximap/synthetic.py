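"""Synthetic BioID / screen / cohort generator with recorded ground truth.

Emulates the study design the pipeline was built for: five RAD51-paralog
baits profiled in two conditions (untreated and hydroxyurea) with two
biological replicates each, planted BCDX2/CX3 complex co-membership,
background binders, classical contaminants, HU-responsive preys, planted
essential genes in guide-level CRISPR counts, planted drug sensitizers in
NormZ profiles, and expression-linked hazards in a patient cohort.

Spectral and guide counts are drawn from negative binomial distributions
(overdispersion is the norm for count data of this kind). ``noiseless=True``
sets the detection probability to 1, the decoy fraction to 0 and makes
condition-paired counts deterministic transformations of one base draw, so
set-level recovery of the planted structure is exact.

Background preys receive a random bait-membership signature drawn from the
non-empty bait subsets *excluding* the three reserved signatures (all five
baits, exactly BCDX2, exactly CX3); the planted complex-level sets are
therefore identifiable from the generated tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .ingest import PreyRecord
from .screens import ScreenProfile
from .setalgebra import BAITS, BCDX2, CX3
from .survival import SurvivalCohort

OLAPARIB_SCREENS = ("olaparib_RPE1", "olaparib_HeLa", "olaparib_SUM149PT")
HU_SCREEN = "HU_chronic"

#: Named contaminants injected into generated prey tables.
INJECTED_CONTAMINANTS = (
    "AHNAK", "PRKDC", "TOP1", "HLCS", "FLNB", "PRKAA1", "PRKAA2",
    "KRT1", "KRT10", "RPL7", "RPS3", "PC", "LYZ",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the generator.

    The BioID defaults mirror the emulated study: 5 baits x 2 conditions x
    2 replicates, planted complex-level sets of 945 (all-common), 97
    (BCDX2-exclusive) and 46 (CX3-exclusive) preys. Screen defaults plant 50
    essentials (guide D14 counts at 10% of the D0 expectation) among 2000
    neutral genes with 4 guides per gene and 2 replicates; the cohort default
    is 500 patients with hazard ratio 2 genes.
    """

    seed: int
    baits: tuple[str, ...] = BAITS
    # BioID
    n_all_common: int = 945
    n_bcdx2_exclusive: int = 97
    n_cx3_exclusive: int = 46
    n_bait_specific: int = 100  # per bait
    n_background: int = 300
    count_mean: float = 10.0  # mean average spectral count of a detected prey
    count_dispersion: float = 2.0  # negative binomial size (smaller = noisier)
    detection_prob: float = 0.9
    decoy_fraction: float = 0.05
    contaminant_rate: float = 0.5  # per-table inclusion probability per contaminant
    n_hu_modulated: int = 50
    hu_effect: float = 2.0  # |log2 shift| of HU-modulated prey means
    noiseless: bool = False
    # CRISPR screen
    n_genes: int = 2000  # neutral genes
    n_essential: int = 50
    guides_per_gene: int = 4
    n_screen_replicates: int = 2
    d0_mean: float = 500.0
    essential_effect: float = 0.1  # D14 expectation as a fraction of D0
    # NormZ profile
    n_sensitizers: int = 6
    # survival cohort
    n_patients: int = 500
    n_cohort_genes: int = 200
    n_hazardous: int = 10
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.02  # events per month
    censor_rate: float = 0.005
    max_follow_up: float = 120.0  # months

    def __post_init__(self) -> None:
        for name in ("detection_prob", "decoy_fraction", "contaminant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.essential_effect <= 1.0:
            raise ValueError("essential_effect must be in (0, 1]")
        for name in ("count_mean", "count_dispersion", "d0_mean",
                     "baseline_hazard", "hazard_ratio", "max_follow_up"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside every generated dataset."""

    seed: int
    membership: dict[str, str] = field(default_factory=dict)
    hu_modulated: dict[str, float] = field(default_factory=dict)
    essentials: frozenset[str] = frozenset()
    sensitizers: frozenset[str] = frozenset()
    hazardous: dict[str, float] = field(default_factory=dict)

    def members(self, category: str) -> frozenset[str]:
        return frozenset(
            p for p, c in self.membership.items() if c == category
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "membership": self.membership,
                "hu_modulated": self.hu_modulated,
                "essentials": sorted(self.essentials),
                "sensitizers": sorted(self.sensitizers),
                "hazardous": self.hazardous,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            membership=d["membership"],
            hu_modulated=d["hu_modulated"],
            essentials=frozenset(d["essentials"]),
            sensitizers=frozenset(d["sensitizers"]),
            hazardous=d["hazardous"],
        )


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per generator stage."""
    return np.random.default_rng([config.seed, stream])


def _nb_counts(
    rng: np.random.Generator, mean: float, size_param: float, n: int
) -> np.ndarray:
    """Negative binomial draws with the given mean and size (dispersion) parameter."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _background_signatures(baits: tuple[str, ...]) -> list[frozenset[str]]:
    """Non-empty bait subsets excluding the reserved complex signatures."""
    reserved = {frozenset(baits), BCDX2, CX3}
    sigs = []
    for r in range(1, len(baits) + 1):
        for combo in combinations(baits, r):
            sig = frozenset(combo)
            if sig not in reserved:
                sigs.append(sig)
    return sigs


def generate_bioid(
    config: GeneratorConfig,
) -> tuple[list[PreyRecord], SyntheticTruth]:
    """Prey tables for all bait x condition pairs, plus the planted truth.

    Complex-member preys appear in exactly their defining baits' tables
    (subject to the detection probability; 1 in noiseless mode). HU tables
    shift the HU-modulated preys' mean counts by ``hu_effect`` log2 units
    (alternating sign). Contaminants and low-confidence decoys are injected
    so the confidence/contaminant filter has real work to do.
    """
    rng = _rng(config, 1)
    baits = config.baits
    detection = 1.0 if config.noiseless else config.detection_prob
    decoy_fraction = 0.0 if config.noiseless else config.decoy_fraction

    # --- prey roster with membership signatures -------------------------
    signatures: dict[str, frozenset[str]] = {}
    truth = SyntheticTruth(seed=config.seed)
    counter = 0

    def new_prey(category: str, sig: frozenset[str]) -> str:
        nonlocal counter
        name = f"SP{counter:04d}"
        counter += 1
        signatures[name] = sig
        truth.membership[name] = category
        return name

    for _ in range(config.n_all_common):
        new_prey("all_common", frozenset(baits))
    for _ in range(config.n_bcdx2_exclusive):
        new_prey("bcdx2_exclusive", BCDX2)
    for _ in range(config.n_cx3_exclusive):
        new_prey("cx3_exclusive", CX3)
    for bait in baits:
        for _ in range(config.n_bait_specific):
            new_prey(f"bait_specific:{bait}", frozenset({bait}))
    bg_sigs = _background_signatures(baits)
    for _ in range(config.n_background):
        sig = bg_sigs[rng.integers(len(bg_sigs))]
        new_prey("background", sig)

    preys = list(signatures)
    lengths = {p: int(rng.integers(100, 2001)) for p in preys}

    # --- HU-modulated preys (drawn from the all-common set) -------------
    common = sorted(truth.members("all_common"))
    modulated = rng.choice(common, size=min(config.n_hu_modulated, len(common)),
                           replace=False)
    for i, prey in enumerate(sorted(modulated)):
        sign = 1.0 if i % 2 == 0 else -1.0
        truth.hu_modulated[prey] = sign * config.hu_effect

    # --- base counts per (prey, bait) ------------------------------------
    r = config.count_dispersion
    base: dict[tuple[str, str], int] = {}
    for prey in preys:
        floor = 4 if prey in truth.hu_modulated else 1
        for bait in signatures[prey]:
            draw = int(_nb_counts(rng, max(config.count_mean - floor, 0.5), r, 1)[0])
            base[(prey, bait)] = floor + draw

    def avg_spec(mean_count: float) -> float:
        if config.noiseless:
            return float(round(mean_count))
        reps = _nb_counts(rng, max(mean_count, 0.1), r, 2)
        return float(reps.mean())

    records: list[PreyRecord] = []
    for bait in baits:
        for condition in ("untreated", "HU"):
            for prey in preys:
                if bait not in signatures[prey]:
                    continue
                if detection < 1.0 and rng.random() >= detection:
                    continue
                u = base[(prey, bait)]
                if condition == "HU" and prey in truth.hu_modulated:
                    mean = u * 2.0 ** truth.hu_modulated[prey]
                elif condition == "HU" and config.noiseless:
                    mean = float(u)
                else:
                    mean = float(u)
                spec = float(round(mean)) if config.noiseless else avg_spec(mean)
                if spec <= 0 and condition == "HU" and prey in truth.hu_modulated:
                    spec = 0.0  # fully depleted under HU: drop the row
                if spec <= 0:
                    continue
                records.append(
                    PreyRecord(
                        bait=bait,
                        condition=condition,
                        prey=prey,
                        avg_spec=spec,
                        unique_peptides=1 + int(rng.poisson(3)),
                        iprophet_prob=float(rng.uniform(0.95, 1.0)),
                        protein_length_aa=lengths[prey],
                        n_replicates=2,
                    )
                )

    # --- contaminants (pass confidence, removed by the contaminant list) -
    cont_lengths = {c: int(rng.integers(100, 2001)) for c in INJECTED_CONTAMINANTS}
    for bait in baits:
        for condition in ("untreated", "HU"):
            for cont in INJECTED_CONTAMINANTS:
                if rng.random() < config.contaminant_rate:
                    truth.membership.setdefault(cont, "contaminant")
                    records.append(
                        PreyRecord(
                            bait=bait,
                            condition=condition,
                            prey=cont,
                            avg_spec=float(1 + _nb_counts(rng, 20.0, r, 1)[0]),
                            unique_peptides=1 + int(rng.poisson(5)),
                            iprophet_prob=float(rng.uniform(0.95, 1.0)),
                            protein_length_aa=cont_lengths[cont],
                            n_replicates=2,
                        )
                    )

    # --- low-confidence decoys (removed by the confidence filter) --------
    if decoy_fraction > 0:
        n_decoys = int(round(decoy_fraction * len(preys)))
        for bait in baits:
            for condition in ("untreated", "HU"):
                for j in range(n_decoys):
                    name = f"DECOY{j:04d}"
                    truth.membership.setdefault(name, "decoy")
                    low_prob = rng.random() < 0.7
                    records.append(
                        PreyRecord(
                            bait=bait,
                            condition=condition,
                            prey=name,
                            avg_spec=float(1 + _nb_counts(rng, 3.0, r, 1)[0]),
                            unique_peptides=0 if not low_prob else 1,
                            iprophet_prob=float(rng.uniform(0.2, 0.85))
                            if low_prob
                            else float(rng.uniform(0.95, 1.0)),
                            protein_length_aa=int(rng.integers(100, 2001)),
                            n_replicates=2,
                        )
                    )
    return records, truth


def generate_normz_profile(
    config: GeneratorConfig, truth: SyntheticTruth
) -> ScreenProfile:
    """Chemogenomic NormZ profile over the generated preys.

    Screens: three olaparib screens (planted sensitizers, drawn from the
    BCDX2-exclusive preys, score < -1.5 in at least two of them) and one
    chronic-HU screen in which the HU-modulated preys score |NormZ| > 2.5
    with the sign of their BioID shift; all other cells are standard normal.
    """
    rng = _rng(config, 2)
    genes = sorted(
        p for p, c in truth.membership.items() if c not in ("contaminant", "decoy")
    )
    screens = [*OLAPARIB_SCREENS, HU_SCREEN]
    normz = pd.DataFrame(
        rng.standard_normal((len(genes), len(screens))),
        index=genes,
        columns=screens,
    )
    bcdx2 = sorted(truth.members("bcdx2_exclusive"))
    n_sens = min(config.n_sensitizers, len(bcdx2))
    sens = sorted(rng.choice(bcdx2, size=n_sens, replace=False))
    for gene in sens:
        hit_in = rng.choice(len(OLAPARIB_SCREENS), size=2, replace=False)
        for idx in hit_in:
            normz.loc[gene, OLAPARIB_SCREENS[idx]] = -float(rng.uniform(1.5, 3.0))
    truth.sensitizers = frozenset(sens)
    for gene, effect in truth.hu_modulated.items():
        normz.loc[gene, HU_SCREEN] = math.copysign(
            float(rng.uniform(2.5, 4.0)), effect
        )
    return ScreenProfile(normz=normz)


def generate_screen(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Guide-level D0/D14 count table with planted essential genes.

    D0 counts are negative binomial around ``d0_mean``; D14 counts are
    Poisson around the D0 count scaled by the gene's fitness
    (``essential_effect`` for essentials, 1 for neutral genes).
    """
    rng = _rng(config, 3)
    n_total = config.n_genes + config.n_essential
    genes = [f"G{i:05d}" for i in range(n_total)]
    essentials = frozenset(
        rng.choice(genes, size=config.n_essential, replace=False)
    )
    truth = SyntheticTruth(seed=config.seed, essentials=essentials)

    fitness = np.array(
        [config.essential_effect if g in essentials else 1.0 for g in genes]
    )
    rows = []
    for rep in range(1, config.n_screen_replicates + 1):
        d0 = 1 + _nb_counts(
            rng, config.d0_mean, config.count_dispersion * 5, n_total * config.guides_per_gene
        )
        lam = d0 * np.repeat(fitness, config.guides_per_gene)
        d14 = rng.poisson(lam)
        for i, gene in enumerate(np.repeat(genes, config.guides_per_gene)):
            guide_idx = i % config.guides_per_gene
            rows.append(
                {
                    "guide": f"{gene}_g{guide_idx}",
                    "gene": gene,
                    "replicate": f"rep{rep}",
                    "count_d0": int(d0[i]),
                    "count_d14": int(d14[i]),
                }
            )
    return pd.DataFrame(rows), truth


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[SurvivalCohort, SyntheticTruth]:
    """Patient cohort with expression-linked hazards.

    Expression is log-normal and i.i.d. across genes. Each patient's hazard
    is the baseline multiplied by ``hazard_ratio`` for every planted
    hazardous gene whose expression exceeds its cohort median. Survival times
    are exponential; censoring is independent (exponential, administratively
    capped at ``max_follow_up`` months).
    """
    rng = _rng(config, 4)
    genes = [f"CG{i:04d}" for i in range(config.n_cohort_genes)]
    hazardous = sorted(
        rng.choice(genes, size=min(config.n_hazardous, len(genes)), replace=False)
    )
    expr = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=1.0, size=(config.n_patients, len(genes))),
        columns=genes,
        index=[f"P{i:04d}" for i in range(config.n_patients)],
    )
    hazard = np.full(config.n_patients, config.baseline_hazard)
    for gene in hazardous:
        above = expr[gene].to_numpy() > float(expr[gene].median())
        hazard *= np.where(above, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_censor = np.minimum(
            rng.exponential(1.0 / config.censor_rate, size=config.n_patients),
            config.max_follow_up,
        )
    else:
        t_censor = np.full(config.n_patients, config.max_follow_up)
    time = np.minimum(t_event, t_censor)
    time = np.maximum(time, 1e-6)  # strictly positive follow-up
    event = (t_event <= t_censor).astype(int)
    cohort = SurvivalCohort(time=time, event=event, expression=expr, endpoint="OS")
    truth = SyntheticTruth(
        seed=config.seed,
        hazardous={g: config.hazard_ratio for g in hazardous},
    )
    return cohort, truth


def generate_gene_sets(
    config: GeneratorConfig, truth: SyntheticTruth, n_random_terms: int = 20
) -> GeneSetCollection:
    """GMT-style collection: the planted complex modules plus random terms."""
    rng = _rng(config, 5)
    universe = sorted(
        p for p, c in truth.membership.items() if c not in ("contaminant", "decoy")
    )
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    bcdx2 = truth.members("bcdx2_exclusive")
    cx3 = truth.members("cx3_exclusive")
    if bcdx2:
        sets["MOD:BCDX2"] = ("planted BCDX2-proximal module", bcdx2)
    if cx3:
        sets["MOD:CX3"] = ("planted CX3-proximal module", cx3)
    for i in range(n_random_terms):
        size = int(rng.integers(10, 60))
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        sets[f"RND:{i:03d}"] = (f"random term {i}", genes)
    return GeneSetCollection(sets=sets, source="synthetic")


def generate_known_edges(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    known_fraction: float = 0.1,
) -> list[tuple[str, str]]:
    """Known-interaction catalogue: ``known_fraction`` of bait-prey pairs,
    plus an equal number of random prey-prey pairs (for network augmentation)."""
    rng = _rng(config, 6)
    edges: list[tuple[str, str]] = []
    preys_by_bait: dict[str, list[str]] = {b: [] for b in config.baits}
    for prey, cat in sorted(truth.membership.items()):
        if cat in ("contaminant", "decoy"):
            continue
        # recover the signature from the category
        if cat == "all_common":
            sig: Iterable[str] = config.baits
        elif cat == "bcdx2_exclusive":
            sig = BCDX2
        elif cat == "cx3_exclusive":
            sig = CX3
        elif cat.startswith("bait_specific:"):
            sig = [cat.split(":", 1)[1]]
        else:  # background: attribute to no catalogue edge
            continue
        for bait in sig:
            preys_by_bait[bait].append(prey)
    for bait, preys in preys_by_bait.items():
        n_known = int(round(known_fraction * len(preys)))
        if n_known:
            for prey in rng.choice(preys, size=n_known, replace=False):
                edges.append((bait, str(prey)))
    all_preys = sorted({p for preys in preys_by_bait.values() for p in preys})
    n_pp = int(round(known_fraction * len(all_preys)))
    if len(all_preys) >= 2:
        for _ in range(n_pp):
            a, b = rng.choice(all_preys, size=2, replace=False)
            edges.append((str(a), str(b)))
    return edges


def write_fixture_dir(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture directory: every input the pipeline consumes.

    Returns a name -> path map of the files written. Same config (and seed)
    produces byte-identical files.
    """
    from .enrichment import write_gmt
    from .ingest import write_prey_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_bioid(config)
    profile = generate_normz_profile(config, truth)
    guides, screen_truth = generate_screen(config)
    cohort, cohort_truth = generate_cohort(config)
    truth.essentials = screen_truth.essentials
    truth.hazardous = cohort_truth.hazardous
    collection = generate_gene_sets(config, truth)
    edges = generate_known_edges(config, truth)

    paths = {
        "prey_table": outdir / "prey_table.tsv",
        "normz": outdir / "normz.tsv",
        "guide_counts": outdir / "guide_counts.tsv",
        "cohort": outdir / "cohort.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "known_edges": outdir / "known_edges.tsv",
        "truth": outdir / "truth.json",
    }
    write_prey_table(records, paths["prey_table"])
    profile.write_tsv(paths["normz"])
    guides.to_csv(paths["guide_counts"], sep="\t", index=False)
    cohort.write_tsv(paths["cohort"])
    write_gmt(collection, paths["gene_sets"])
    pd.DataFrame(edges, columns=["symbol_a", "symbol_b"]).to_csv(
        paths["known_edges"], sep="\t", index=False
    )
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
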