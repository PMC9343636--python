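"""Synthetic longitudinal multi-compartment OTU datasets with ground truth.

Each generator is the sampling dual of one estimator in the package:
beta-binomial local communities for the Sloan neutral-model fit, linear
abundance trends for the successional-mode classifier, multinomial
source mixtures for EM source tracking, correlated log-normal bases for
SparCC, and a full-study composer that emulates the longitudinal rice
design (compartments BS/RS/R/S1-S9/L1-L3/FL/Se, seven sampling ages,
3 biological x 3 technical replicates, two seed generations) with every
planted truth recorded. All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable, DataError, SampleMeta, TaxonomyTable

#: ages (days after transplanting) of the emulated sampling campaign
DEFAULT_AGES = (48, 62, 76, 90, 106, 120, 141)
#: ages at which progeny seeds exist (heading through harvest)
DEFAULT_SEED_AGES = (76, 90, 106, 120, 141)

DEFAULT_COMPARTMENTS = (
    "BS", "RS", "R",
    "S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9",
    "L1", "L2", "L3", "FL", "Se",
)


@dataclass
class GroundTruth:
    """Machine-readable record of everything a generator planted."""

    m: float | None = None
    source_alpha: dict | None = None
    transmitted_otus: set = field(default_factory=set)
    transient_otus: dict = field(default_factory=dict)  # otu -> dropped group name
    trend_otus: dict = field(default_factory=dict)  # otu -> (mode, slope)
    basis_correlations: pd.DataFrame | None = None
    niche_otus: dict = field(default_factory=dict)  # otu -> age-effect size
    metacommunity_p: pd.Series | None = None
    generation_groups: dict = field(default_factory=dict)  # name -> sample ids
    guilds: dict = field(default_factory=dict)  # compartment -> list of co-occurring OTU lists

    def to_json_dict(self) -> dict:
        out = {
            "m": self.m,
            "source_alpha": self.source_alpha,
            "transmitted_otus": sorted(self.transmitted_otus),
            "transient_otus": dict(sorted(self.transient_otus.items())),
            "trend_otus": {k: list(v) for k, v in sorted(self.trend_otus.items())},
            "niche_otus": dict(sorted(self.niche_otus.items())),
            "generation_groups": {k: list(v) for k, v in self.generation_groups.items()},
        }
        return out


@dataclass
class StudyDesign:
    """Shape of the emulated longitudinal study."""

    compartments: tuple = DEFAULT_COMPARTMENTS
    ages_days: tuple = DEFAULT_AGES
    seed_ages: tuple = DEFAULT_SEED_AGES
    depth_mean: int = 10_000
    n_bio_rep: int = 3
    n_tech_rep: int = 3
    two_generations: bool = True
    year: int = 2018
    parent_year: int = 2017
    site: str = "SW"

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise DataError("depth_mean must be > 0")
        if "Se" not in self.compartments:
            raise DataError("the design must include the seed compartment 'Se'")


# ---------------------------------------------------------------------------
# Neutral-model generator
# ---------------------------------------------------------------------------

def simulate_neutral_local_communities(
    n_otus: int,
    n_communities: int,
    N: int,
    m: float,
    p=None,
    seed: int | None = None,
) -> tuple[CountTable, GroundTruth]:
    """Sample local communities under Sloan's neutral model.

    Per community and OTU the local relative abundance is drawn from
    Beta(N*m*p_i, N*m*(1-p_i)) and counts from Binomial(N, .). When
    ``p`` is omitted, metacommunity abundances are log-uniform over
    [1e-4, 1e-1], normalized.
    """
    if not (0.0 < m <= 1.0):
        raise DataError("migration rate m must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if p is None:
        p = np.exp(rng.uniform(np.log(1e-4), np.log(1e-1), size=n_otus))
        p = p / p.sum()
    else:
        p = np.asarray(p, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise DataError("metacommunity abundances must sum to 1")
    a = N * m * p
    b = N * m * (1.0 - p)
    rel = rng.beta(a[:, None], b[:, None], size=(n_otus, n_communities))
    counts = rng.binomial(N, rel)
    # guard the count-table invariant: an (unlikely) empty community gets
    # one read of the most abundant taxon
    empty = counts.sum(axis=0) == 0
    if empty.any():
        counts[int(np.argmax(p)), empty] = 1
    otus = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    samples = [f"LC{j + 1:04d}" for j in range(n_communities)]
    table = CountTable(pd.DataFrame(counts, index=otus, columns=samples))
    truth = GroundTruth(m=m, metacommunity_p=pd.Series(p, index=otus))
    return table, truth


# ---------------------------------------------------------------------------
# Trend injection
# ---------------------------------------------------------------------------

def inject_trends(
    t: CountTable,
    otus,
    mode: str = "Late",
    slope: float = 0.002,
    noise_sd: float = 0.0005,
    ages=None,
    seed: int | None = None,
    base_ra: float = 0.001,
) -> tuple[CountTable, GroundTruth]:
    """Plant linear abundance-age trends into a community table.

    For each injected OTU the expected relative abundance is
    ``base_ra + slope * (age - age_min)`` (Late) or the mirrored
    decreasing ramp (Early), plus Gaussian noise, truncated at 0;
    columns are then renormalized and multinomially resampled at the
    original depths, so the realized slopes are compressed by closure
    but keep their sign.
    """
    if mode not in ("Early", "Late"):
        raise DataError("mode must be 'Early' or 'Late'")
    otus = list(otus)
    missing = set(otus) - set(t.otu_ids)
    if missing:
        raise DataError(f"OTU(s) not in table: {sorted(missing)[:5]}")
    if ages is None:
        raise DataError("ages (one per sample column) are required")
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(t.sample_ids):
        raise DataError("ages must align with the sample columns")
    rng = np.random.default_rng(seed)
    ra = t.relative_abundance().to_numpy()
    idx = [t.otu_ids.index(o) for o in otus]
    span = ages - ages.min()
    truncated = False
    for i in idx:
        if mode == "Late":
            expect = base_ra + slope * span
        else:
            expect = base_ra + slope * (span.max() - span)
        expect = expect + rng.normal(0.0, noise_sd, size=len(ages))
        below = expect < 0
        if below.any():
            truncated = True
        ra[i] = np.clip(expect, 0.0, None)
    ra = ra / ra.sum(axis=0, keepdims=True)
    depths = t.depths().to_numpy()
    counts = np.column_stack([
        rng.multinomial(int(depths[j]), ra[:, j]) for j in range(ra.shape[1])
    ])
    empty = counts.sum(axis=0) == 0
    if empty.any():
        counts[np.argmax(ra[:, empty], axis=0), empty] = 1
    out = CountTable(pd.DataFrame(counts, index=t.otu_ids, columns=t.sample_ids))
    signed = slope if mode == "Late" else -slope
    truth = GroundTruth(trend_otus={o: (mode, signed) for o in otus})
    if truncated:
        truth.trend_otus = {o: (mode, signed) for o in otus}
        truth.niche_otus["_truncated_at_zero"] = 1.0
    return out, truth


# ---------------------------------------------------------------------------
# Source-sink generator
# ---------------------------------------------------------------------------

def simulate_sources_sink(
    source_profiles: pd.DataFrame,
    alpha,
    depth: int = 100_000,
    seed: int | None = None,
    unknown_profile: pd.Series | None = None,
    n_unknown_otus: int = 50,
) -> tuple[pd.Series, pd.DataFrame, GroundTruth]:
    """Draw a sink community as a known mixture of source profiles.

    ``source_profiles`` is a K x n_otus count (or fraction) frame, one
    row per source; ``alpha`` has K+1 entries, the last being the
    Unknown proportion. The default Unknown profile is uniform over
    ``n_unknown_otus`` fresh OTU ids disjoint from every source, which
    makes the mixture exactly identifiable. Returns the sink count
    vector, the source matrix extended to the full OTU axis, and the
    truth.
    """
    alpha = np.asarray(alpha, dtype=float)
    k = source_profiles.shape[0]
    if len(alpha) != k + 1:
        raise DataError("alpha must have one entry per source plus Unknown")
    if abs(alpha.sum() - 1.0) > 1e-9 or (alpha < 0).any():
        raise DataError("alpha must be a probability vector")
    rng = np.random.default_rng(seed)
    gammas = source_profiles.div(source_profiles.sum(axis=1), axis=0)
    if unknown_profile is None:
        u_ids = [f"U{i + 1:04d}" for i in range(n_unknown_otus)]
        unknown_profile = pd.Series(1.0 / n_unknown_otus, index=u_ids)
    unknown_profile = unknown_profile / unknown_profile.sum()
    all_otus = list(source_profiles.columns) + [
        o for o in unknown_profile.index if o not in source_profiles.columns
    ]
    gammas = gammas.reindex(columns=all_otus, fill_value=0.0)
    unk = unknown_profile.reindex(all_otus, fill_value=0.0)
    mix = gammas.T @ alpha[:k] + unk.to_numpy() * alpha[k]
    mix = mix / mix.sum()
    sink = pd.Series(rng.multinomial(depth, mix), index=all_otus, name="sink")
    sources_ext = source_profiles.reindex(columns=all_otus, fill_value=0)
    names = list(source_profiles.index) + ["Unknown"]
    truth = GroundTruth(source_alpha=dict(zip(names, alpha)))
    return sink, sources_ext, truth


# ---------------------------------------------------------------------------
# Correlated counts for SparCC
# ---------------------------------------------------------------------------

def simulate_correlated_counts(
    n_otus: int,
    n_samples: int,
    basis_corr: pd.DataFrame | np.ndarray | None = None,
    lognormal_mu=None,
    lognormal_sigma: float = 1.0,
    depth: int = 10_000,
    seed: int | None = None,
) -> tuple[CountTable, GroundTruth]:
    """Compositional counts from a correlated log-normal basis.

    Latent log absolute abundances are multivariate normal with the
    given correlation matrix (identity when omitted), per-taxon means
    ``lognormal_mu`` (drawn N(0,1) when omitted) and common scale
    ``lognormal_sigma``; samples are closed to fractions and
    multinomially sampled at ``depth``.
    """
    rng = np.random.default_rng(seed)
    if basis_corr is None:
        corr = np.eye(n_otus)
    else:
        corr = np.asarray(basis_corr, dtype=float)
    if corr.shape != (n_otus, n_otus):
        raise DataError("basis_corr must be n_otus x n_otus")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-8:
        raise DataError(
            f"basis_corr is not positive semidefinite (min eigenvalue {eigmin:.3g}); "
            "project to the nearest PSD matrix first"
        )
    if lognormal_mu is None:
        mu = rng.normal(0.0, 1.0, size=n_otus)
    else:
        mu = np.broadcast_to(np.asarray(lognormal_mu, dtype=float), (n_otus,))
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_otus))
    z = chol @ rng.standard_normal((n_otus, n_samples))
    log_abs = mu[:, None] + lognormal_sigma * z
    absab = np.exp(log_abs)
    fractions = absab / absab.sum(axis=0, keepdims=True)
    counts = np.column_stack([
        rng.multinomial(depth, fractions[:, j]) for j in range(n_samples)
    ])
    otus = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    samples = [f"S{j + 1:04d}" for j in range(n_samples)]
    table = CountTable(pd.DataFrame(counts, index=otus, columns=samples))
    truth = GroundTruth(basis_correlations=pd.DataFrame(corr, index=otus, columns=otus))
    return table, truth


# ---------------------------------------------------------------------------
# Full-study composer
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """What to plant in a full synthetic study."""

    n_bacteria: int = 120
    n_fungi: int = 80
    n_transmitted: int = 20
    n_transient: int = 24
    n_unknown_source_otus: int = 30
    #: nominal source mixture of harvest-stage progeny seeds:
    #: (stem S1 at ripening, parent seeds, unknown)
    alpha_stem: float = 0.4
    alpha_parent: float = 0.3
    alpha_unknown: float = 0.3
    stem_source_age: int = 120
    niche_effects: tuple = (0.0, 1.0, 2.0)  # planted CLR-scale age effects

    def __post_init__(self) -> None:
        total = self.alpha_stem + self.alpha_parent + self.alpha_unknown
        if abs(total - 1.0) > 1e-9:
            raise DataError("scenario source mixture must sum to 1")


_PHYLA = {
    "Bacteria": ["Proteobacteria", "Actinobacteria", "Firmicutes", "Chloroflexi"],
    "Fungi": ["Ascomycota", "Basidiomycota"],
}
_CLASSES = {
    "Proteobacteria": ["Alphaproteobacteria", "Gammaproteobacteria"],
    "Actinobacteria": ["Actinobacteria_c"],
    "Firmicutes": ["Bacilli"],
    "Chloroflexi": ["Anaerolineae"],
    "Ascomycota": ["Dothideomycetes", "Sordariomycetes", "Eurotiomycetes"],
    "Basidiomycota": ["Ustilaginomycetes", "Tremellomycetes"],
}


def _make_taxonomy(otus_by_kingdom: dict, rng: np.random.Generator) -> TaxonomyTable:
    rows = {}
    for kingdom, otus in otus_by_kingdom.items():
        for otu in otus:
            phylum = rng.choice(_PHYLA[kingdom])
            clazz = rng.choice(_CLASSES[phylum])
            rows[otu] = {
                "kingdom": kingdom, "phylum": phylum, "class": clazz,
                "order": f"{clazz}_o{rng.integers(1, 4)}",
                "family": f"{clazz}_f{rng.integers(1, 6)}",
                "genus": f"{clazz}_g{rng.integers(1, 9)}",
            }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


def generate_full_study(
    design: StudyDesign | None = None,
    scenario: Scenario | None = None,
    seed: int | None = None,
) -> tuple[CountTable, SampleMeta, TaxonomyTable, GroundTruth]:
    """Compose a complete synthetic seed-to-seed study with known truth.

    The bundle contains three seed generation groups (parent-generation
    harvest seeds, sowing-stage seeds Se0, progeny harvest seeds),
    planted transmitted OTUs present in all three, planted transient
    OTUs each zeroed out of exactly one group, progeny seed communities
    that interpolate from an early-colonizer profile toward the parent
    profile as the seed matures (so transmitted OTUs are late
    successors), harvest-stage progeny seeds drawn as a known source
    mixture (stem + parent seeds + disjoint unknown), and all other
    compartments with their own stable profiles. Deterministic per seed.
    """
    design = design or StudyDesign()
    scenario = scenario or Scenario()
    rng = np.random.default_rng(seed)

    if scenario.n_transmitted + scenario.n_transient > scenario.n_bacteria + scenario.n_fungi:
        raise DataError("scenario plants more seed OTUs than exist")

    n_bac, n_fun = scenario.n_bacteria, scenario.n_fungi
    bac = [f"B{i + 1:04d}" for i in range(n_bac)]
    fun = [f"F{i + 1:04d}" for i in range(n_fun)]
    unknown = [f"U{i + 1:04d}" for i in range(scenario.n_unknown_source_otus)]
    # unknown-source taxa get taxonomy too (they appear in progeny seeds)
    otus = bac + fun + unknown
    tax = _make_taxonomy(
        {"Bacteria": bac + unknown[: len(unknown) // 2],
         "Fungi": fun + unknown[len(unknown) // 2:]}, rng
    )

    # --- seed OTU roles ----------------------------------------------------
    n_tr, n_ts = scenario.n_transmitted, scenario.n_transient
    seed_pool = bac[: n_tr // 2 + n_ts // 2] + fun[: (n_tr - n_tr // 2) + (n_ts - n_ts // 2)]
    transmitted = seed_pool[: n_tr]
    transient = seed_pool[n_tr: n_tr + n_ts]
    # transient OTUs drop out of one of the first two generation groups;
    # the progeny-harvest community is a pure source mixture, so OTUs
    # absent from every source are automatically absent there too
    groups = ("parent_harvest", "sowing")
    dropout = {o: groups[i % 2] for i, o in enumerate(transient)}

    idx = {o: i for i, o in enumerate(otus)}
    n_all = len(otus)

    def seed_profile(group: str) -> np.ndarray:
        """Expected seed community of one generation group."""
        prof = np.zeros(n_all)
        w_tr = rng_profiles["seed_tr"]
        prof[[idx[o] for o in transmitted]] = w_tr
        for o in transient:
            if dropout[o] != group:
                prof[idx[o]] = rng_profiles["seed_ts"][transient.index(o)]
        return prof / prof.sum()

    # fixed weights so the three generations share a compositional core
    rng_profiles = {
        "seed_tr": np.exp(rng.normal(0.0, 0.6, size=n_tr)) * (0.7 / n_tr),
        "seed_ts": np.exp(rng.normal(-0.5, 0.6, size=n_ts)) * (0.3 / n_ts),
    }

    # --- compartment background profiles ----------------------------------
    soil_pool = np.exp(rng.normal(0.0, 1.5, size=n_all))
    soil_pool[[idx[o] for o in transmitted + transient + unknown]] = 0.0
    plant_pool = np.exp(rng.normal(0.0, 1.5, size=n_all))
    plant_pool[[idx[o] for o in unknown]] = 0.0
    # transmitted OTUs are systemically present in aboveground tissue
    plant_pool[[idx[o] for o in transmitted]] *= 4.0
    plant_pool[[idx[o] for o in transient]] = 0.0

    comp_profiles: dict = {}
    for comp in design.compartments:
        if comp == "Se":
            continue
        pool = soil_pool if comp in ("BS", "RS") else plant_pool
        jitter = np.exp(rng.normal(0.0, 0.4, size=n_all))
        prof = pool * jitter
        comp_profiles[comp] = prof / prof.sum()

    parent_profile = seed_profile("parent_harvest")
    sowing_profile = seed_profile("sowing")

    # --- harvest-seed source mixture ---------------------------------------
    # progeny harvest seeds are drawn exactly from the planted mixture of
    # stem endosphere, parent (sowing) seeds, and a disjoint unknown pool
    stem_comp = "S1" if "S1" in comp_profiles else next(iter(comp_profiles))
    unk_profile = np.zeros(n_all)
    unk_profile[[idx[o] for o in unknown]] = np.exp(
        rng.normal(0.0, 0.5, size=len(unknown))
    )
    unk_profile /= unk_profile.sum()
    sink_mix = (
        scenario.alpha_stem * comp_profiles[stem_comp]
        + scenario.alpha_parent * sowing_profile
        + scenario.alpha_unknown * unk_profile
    )
    sink_mix /= sink_mix.sum()

    # early-colonizer progeny seed profile: transmitted OTUs scarce,
    # other plant taxa abundant; seed maturation interpolates toward the
    # harvest mixture, making transmitted OTUs late successors
    early = sink_mix.copy()
    early[[idx[o] for o in transmitted]] *= 0.05
    spill = plant_pool / plant_pool.sum() * 0.5
    early = early + spill
    early = early / early.sum()

    # --- co-occurrence guilds ----------------------------------------------
    # within each non-seed compartment two OTU guilds fluctuate together
    # across samples (a shared log-normal factor), planting genuine
    # positive associations for the network stage; seed communities are
    # left untouched so the planted abundance-age trends stay clean
    guilds: dict = {}
    for comp, prof in comp_profiles.items():
        pool_ids = [int(i) for i in np.argsort(prof)[::-1][:30]]
        half = max(len(pool_ids) // 2, 1)
        guilds[comp] = [pool_ids[:half], pool_ids[half:]] if len(pool_ids) > 1 else [pool_ids]

    # --- assemble samples ---------------------------------------------------
    seed_ages = tuple(design.seed_ages)
    harvest_age = max(seed_ages)
    columns: dict = {}
    meta_rows: list = []

    def add_sample(profile, comp, age, year, bio, tech):
        sid = f"{year}_{comp}_{age}_b{bio}t{tech}"
        noisy = profile * np.exp(rng.normal(0.0, 0.25, size=n_all))
        for guild in guilds.get(comp, ()):
            noisy[guild] = noisy[guild] * np.exp(rng.normal(0.0, 0.8))
        total = noisy.sum()
        if total == 0:
            raise DataError("degenerate all-zero sample profile")
        depth = int(rng.poisson(design.depth_mean))
        counts = rng.multinomial(max(depth, 1), noisy / total)
        if counts.sum() == 0:
            counts[int(np.argmax(noisy))] = 1
        columns[sid] = counts
        meta_rows.append({
            "sample_id": sid, "compartment": comp, "age_days": int(age),
            "year": year, "site": design.site, "bio_rep": bio, "tech_rep": tech,
        })

    # parent-generation harvest seeds (previous year) and sowing seeds (age 0)
    if design.two_generations:
        for bio in range(1, design.n_bio_rep + 1):
            for tech in range(1, design.n_tech_rep + 1):
                add_sample(parent_profile, "Se", harvest_age, design.parent_year, bio, tech)
    for bio in range(1, design.n_bio_rep + 1):
        for tech in range(1, design.n_tech_rep + 1):
            add_sample(sowing_profile, "Se", 0, design.year, bio, tech)

    # progeny seeds: interpolate early -> harvest mixture with age
    for age in seed_ages:
        lam = (age - min(seed_ages)) / (harvest_age - min(seed_ages))
        profile = sink_mix if age == harvest_age else (1 - lam) * early + lam * sink_mix
        profile = profile / profile.sum()
        for bio in range(1, design.n_bio_rep + 1):
            for tech in range(1, design.n_tech_rep + 1):
                add_sample(profile, "Se", age, design.year, bio, tech)

    # other compartments at every age
    for comp, prof in comp_profiles.items():
        for age in design.ages_days:
            for bio in range(1, design.n_bio_rep + 1):
                for tech in range(1, design.n_tech_rep + 1):
                    add_sample(prof, comp, age, design.year, bio, tech)

    table = CountTable(pd.DataFrame(columns, index=otus))
    meta = SampleMeta(pd.DataFrame(meta_rows))

    gen_groups = {
        "parent_harvest": meta.samples(compartment="Se", year=design.parent_year,
                                       age_days=harvest_age),
        "sowing": meta.samples(compartment="Se", year=design.year, age_days=0),
        "progeny_harvest": meta.samples(compartment="Se", year=design.year,
                                        age_days=harvest_age),
    }

    delta = sink_mix - early
    trend = {}
    for o in transmitted:
        trend[o] = ("Late", float(delta[idx[o]] / (harvest_age - min(seed_ages))))
    truth = GroundTruth(
        source_alpha={
            f"{stem_comp}@{scenario.stem_source_age}": scenario.alpha_stem,
            "Se@0": scenario.alpha_parent,
            "Unknown": scenario.alpha_unknown,
        },
        transmitted_otus=set(transmitted),
        transient_otus=dropout,
        trend_otus=trend,
        generation_groups=gen_groups,
        niche_otus={},
        guilds={comp: [[otus[i] for i in g] for g in gs] for comp, gs in guilds.items()},
    )
    return table, meta, tax, truth
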