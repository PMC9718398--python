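"""End-to-end validation metrics computed by running the pipeline on
generated data.

Four families of checks, mirroring how simulation-backed analysis packages
document their behaviour:

* formula identities -- direct evaluations of the SAF and differential
  log2 fold-change definitions;
* oracle equivalence -- agreement of the set algebra, the hypergeometric
  tail and the threshold classifiers with brute-force enumeration;
* statistical calibration -- null-simulation false-positive rates of the
  overrepresentation test, the median-split log-rank screen and the
  drugZ-style scorer;
* planted-truth recovery -- exact recovery of the planted complex-level
  sets and HU-responsive preys in noiseless mode, recall of planted
  essentials, and power against a planted hazard-ratio-2 gene.

Every function takes a seed and returns ``(value, n)`` where ``n`` is the
problem size the value was measured on.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom

from . import abundance as ab
from . import screens as sc
from . import setalgebra as sa
from . import survival as sv
from .ingest import Interactome, build_interactomes, filter_preys
from .synthetic import (
    HU_SCREEN,
    GeneratorConfig,
    generate_bioid,
    generate_cohort,
    generate_normz_profile,
    generate_screen,
)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------- formulas

def saf_identity() -> tuple[float, int]:
    """saf(10, 100); the definition gives 0.1."""
    return ab.saf(10, 100), 1


def log2fc_identity() -> tuple[float, int]:
    """log2((7+1)/(3+1)); the printed formula gives 1.0."""
    u = Interactome(bait="B", condition="untreated", preys={"P": 3.0})
    h = Interactome(bait="B", condition="HU", preys={"P": 7.0})
    return ab.differential_hu(u, h)[0].log2fc, 1


def log2fc_antisymmetry(seed: int, n_pairs: int = 1000) -> tuple[float, int]:
    """Max |fc(u,h) + fc(h,u)| over random count pairs (0 up to round-off)."""
    rng = np.random.default_rng([seed, 101])
    worst = 0.0
    for _ in range(n_pairs):
        u, h = rng.uniform(0, 1000, size=2)
        a = Interactome(bait="B", condition="untreated", preys={"P": float(u)})
        b = Interactome(bait="B", condition="HU", preys={"P": float(h)})
        fwd = ab.differential_hu(a, b)[0].log2fc
        rev = ab.differential_hu(
            Interactome(bait="B", condition="untreated", preys={"P": float(h)}),
            Interactome(bait="B", condition="HU", preys={"P": float(u)}),
        )[0].log2fc
        worst = max(worst, abs(fwd + rev))
    return worst, n_pairs


# ----------------------------------------------------------------- oracles

def _random_interactomes(rng: np.random.Generator, n_preys: int = 80) -> dict:
    preys = [f"P{i:03d}" for i in range(n_preys)]
    out = {}
    for bait in sa.BAITS:
        chosen = [p for p in preys if rng.random() < 0.4] or [preys[0]]
        out[bait] = Interactome(
            bait=bait, condition="untreated", preys={p: 1.0 for p in chosen}
        )
    return out


def intersect_oracle_agreement(seed: int, trials: int = 100) -> tuple[float, int]:
    """Fraction of random 5-bait fixtures where intersect == per-prey enumeration."""
    rng = np.random.default_rng([seed, 102])
    agree = 0
    for _ in range(trials):
        m = _random_interactomes(rng)
        include = set(rng.choice(sa.BAITS, size=int(rng.integers(1, 6)),
                                 replace=False))
        exclude = {b for b in sa.BAITS if b not in include and rng.random() < 0.5}
        spec = sa.IntersectionSpec(frozenset(include), frozenset(exclude))
        union = {p for i in m.values() for p in i.preys}
        expected = sorted(
            p for p in union
            if all(p in m[b].preys for b in include)
            and not any(p in m[b].preys for b in exclude)
        )
        agree += sa.intersect(m, spec) == expected
    return agree / trials, trials


def upset_oracle_agreement(seed: int, trials: int = 100) -> tuple[float, int]:
    """Fraction of fixtures where every upset cell matches brute-force signatures."""
    rng = np.random.default_rng([seed, 103])
    agree = 0
    for _ in range(trials):
        m = _random_interactomes(rng, n_preys=200)
        cells = sa.upset_decompose(m)
        expected: dict[frozenset, set] = {}
        for prey in {p for i in m.values() for p in i.preys}:
            sig = frozenset(b for b in m if prey in m[b].preys)
            expected.setdefault(sig, set()).add(prey)
        agree += cells == {s: frozenset(p) for s, p in expected.items()}
    return agree / trials, trials


def hypergeom_enumeration_max_dev(max_n: int = 12) -> tuple[float, int]:
    """Max |p - enumeration| over all upper-tail instances with N <= max_n.

    The oracle enumerates every size-n draw from N elements of which the
    first K are marked and counts draws with >= k marked.
    """
    worst = 0.0
    n_instances = 0
    for N in range(1, max_n + 1):
        for n in range(1, N + 1):
            draws = np.array(list(combinations(range(N), n)))
            total = draws.shape[0]
            for K in range(0, N + 1):
                counts = (draws < K).sum(axis=1)
                for k in range(0, min(K, n) + 1):
                    exact = float((counts >= k).sum()) / total
                    p = float(hypergeom.sf(k - 1, N, K, n))
                    worst = max(worst, abs(p - exact))
                    n_instances += 1
    return worst, n_instances


def classifier_oracle_agreement(seed: int, trials: int = 50) -> tuple[float, int]:
    """Fraction of random NormZ matrices where classify_* match brute force."""
    import pandas as pd

    rng = np.random.default_rng([seed, 104])
    agree = 0
    for _ in range(trials):
        n_genes = int(rng.integers(20, 120))
        n_screens = int(rng.integers(2, 6))
        m = rng.normal(size=(n_genes, n_screens))
        m[rng.random(m.shape) < 0.1] = np.nan
        genes = [f"g{i}" for i in range(n_genes)]
        screens = [f"s{j}" for j in range(n_screens)]
        profile = sc.ScreenProfile(pd.DataFrame(m, index=genes, columns=screens))
        threshold = float(rng.uniform(-2.5, -0.5))
        min_screens = int(rng.integers(1, n_screens + 1))
        expected = {
            g for i, g in enumerate(genes)
            if sum(1 for j in range(n_screens)
                   if not np.isnan(m[i, j]) and m[i, j] < threshold) >= min_screens
        }
        got = sc.classify_sensitizers(profile, screens, threshold, min_screens)
        agree += got == expected
    return agree / trials, trials


# ------------------------------------------------------------- calibration

def ora_null_significant_fraction(
    seed: int,
    n_reps: int = 1000,
    n_universe: int = 1200,
    n_terms: int = 50,
    term_size: int = 120,
    query_size: int = 120,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Fraction of terms with p < alpha for queries drawn uniformly from the universe.

    The default design keeps the hypergeometric null close to continuous (its
    attainable alpha at 0.05 is 0.044), so the observed fraction estimates the
    nominal level rather than a discreteness artefact.
    """
    rng = np.random.default_rng([seed, 105])
    term_matrix = np.zeros((n_terms, n_universe), dtype=bool)
    for t in range(n_terms):
        term_matrix[t, rng.choice(n_universe, size=term_size, replace=False)] = True
    query_matrix = np.zeros((n_reps, n_universe), dtype=bool)
    for r in range(n_reps):
        query_matrix[r, rng.choice(n_universe, size=query_size, replace=False)] = True
    overlaps = query_matrix.astype(np.int32) @ term_matrix.T.astype(np.int32)
    pvals = hypergeom.sf(overlaps - 1, n_universe, term_size, query_size)
    return float((pvals < alpha).mean()), n_reps * n_terms


def logrank_null_significant_fraction(
    seed: int, n_genes: int = 200, n_patients: int = 500, alpha: float = 0.05
) -> tuple[float, int]:
    """Median-split screen on expression independent of outcome; expect ~alpha."""
    config = GeneratorConfig(
        seed=seed, n_patients=n_patients, n_cohort_genes=n_genes, n_hazardous=0
    )
    cohort, _ = generate_cohort(config)
    results = sv.screen_genes(cohort, cutoff_mode="median", alpha=alpha)
    return float(np.mean([r.significant for r in results])), n_genes


def screen_null_fraction_below(
    seed: int, threshold: float = -1.5
) -> tuple[float, int]:
    """Fraction of genes below the essentiality threshold in a no-effect screen."""
    config = GeneratorConfig(seed=seed, essential_effect=1.0)
    guides, _ = generate_screen(config)
    normz = sc.rank_essentiality(guides)
    return float((normz < threshold).mean()), len(normz)


# ---------------------------------------------------------------- recovery

def noiseless_set_recovery(seed: int) -> dict[str, tuple[float, int]]:
    """Jaccard of recovered vs planted complex-level sets under noiseless BioID."""
    config = GeneratorConfig(seed=seed, noiseless=True)
    records, truth = generate_bioid(config)
    kept, _ = filter_preys(records)
    interactomes = build_interactomes(kept, "untreated")
    out = {}
    for name, spec, category in (
        ("bcdx2_exclusive", sa.BCDX2_EXCLUSIVE, "bcdx2_exclusive"),
        ("cx3_exclusive", sa.CX3_EXCLUSIVE, "cx3_exclusive"),
        ("all_common", sa.ALL_COMMON, "all_common"),
    ):
        planted = truth.members(category)
        recovered = set(sa.intersect(interactomes, spec))
        out[name] = (_jaccard(planted, recovered), len(planted))
    return out


def hu_hit_recovery(seed: int) -> tuple[float, int]:
    """Jaccard of |log2FC|>1 & |NormZ|>2 hits vs planted HU-modulated preys."""
    config = GeneratorConfig(seed=seed, noiseless=True)
    records, truth = generate_bioid(config)
    kept, _ = filter_preys(records)
    profile = generate_normz_profile(config, truth)
    untreated = build_interactomes(kept, "untreated")
    hu = build_interactomes(kept, "HU")
    diffs = []
    for bait in config.baits:
        diffs.extend(ab.differential_hu(untreated[bait], hu[bait]))
    hits = sc.differential_hu_hits(diffs, profile, HU_SCREEN)
    return _jaccard(hits, set(truth.hu_modulated)), len(truth.hu_modulated)


def essential_recall_bottom_k(seed: int) -> tuple[float, int]:
    """Recall of the planted essentials within the bottom-k NormZ ranks.

    Default design: 50 essentials depleted to 10% of the D0 expectation among
    2000 neutral genes, 4 guides per gene, 2 replicates; k = number planted.
    """
    config = GeneratorConfig(seed=seed)
    guides, truth = generate_screen(config)
    normz = sc.rank_essentiality(guides)
    k = len(truth.essentials)
    bottom = set(normz.nsmallest(k).index)
    return len(bottom & truth.essentials) / k, k


def survival_power(
    seed: int, n_sims: int = 40, n_patients: int = 500, hazard_ratio: float = 2.0
) -> tuple[float, int]:
    """Fraction of simulated cohorts where the planted HR gene is flagged at 0.05."""
    flagged = 0
    for i in range(n_sims):
        config = GeneratorConfig(
            seed=(seed * 1000 + i) % (2**31 - 1),
            n_patients=n_patients,
            n_cohort_genes=4,
            n_hazardous=1,
            hazard_ratio=hazard_ratio,
        )
        cohort, truth = generate_cohort(config)
        (gene,) = truth.hazardous
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sv.screen_genes(cohort, [gene])[0]
        flagged += result.significant
    return flagged / n_sims, n_sims
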