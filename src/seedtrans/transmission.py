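"""Vertically transmitted OTUs, successional modes, convergence, core sets.

An OTU is called vertically transmitted when it is detected in all three
designated seed generation groups (parent-generation harvest seeds,
sowing-stage seeds, progeny harvest seeds), with detection applied to the
across-biological-replicate mean abundance; all other seed OTUs are
transient. Successional modes classify each seed OTU by the sign and
significance of the OLS slope of relative abundance on host age:
Early (t < 0, p < alpha), Late (t > 0, p < alpha), Mid/no-trend
otherwise. Convergence trajectories quantify how progeny seed
communities approach the parent-seed community over maturation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountTable, DataError, DistMatrix, NormalizedTable, SampleMeta
from .stats import KruskalDunnResult, dissimilarity, kruskal_dunn

logger = logging.getLogger(__name__)


@dataclass
class TransmissionResult:
    """Per-OTU transmitted/transient status across seed generations."""

    status: pd.Series  # otu_id -> 'transmitted' | 'transient'
    presence: pd.DataFrame  # otu_id x generation-group bool flags
    group_names: tuple

    @property
    def transmitted(self) -> list[str]:
        return list(self.status.index[self.status == "transmitted"])

    @property
    def transient(self) -> list[str]:
        return list(self.status.index[self.status == "transient"])

    def summary_by_age(self, t: CountTable, meta: SampleMeta, compartment: str = "Se") -> pd.DataFrame:
        """Counts and cumulative relative abundance of each status per age."""
        ra = t.relative_abundance()
        rows = []
        for age in sorted(set(meta.table.loc[meta.table["compartment"] == compartment, "age_days"])):
            sids = meta.samples(compartment=compartment, age_days=age)
            sub = ra[sids]
            for status in ("transmitted", "transient"):
                otus = [o for o in self.status.index[self.status == status] if o in sub.index]
                present = (sub.loc[otus] > 0).any(axis=1).sum() if otus else 0
                cum_ra = float(sub.loc[otus].sum(axis=0).mean()) if otus else 0.0
                rows.append(
                    {"age_days": age, "status": status, "n_detected": int(present),
                     "cumulative_relative_abundance": cum_ra}
                )
        return pd.DataFrame(rows)


@dataclass
class SuccessionResult:
    """OLS trend per OTU: slope, t, p and Early/MidNoTrend/Late mode."""

    table: pd.DataFrame  # index otu_id; columns slope, t_stat, p_value, mode, degenerate

    def mode_counts(self) -> pd.Series:
        return self.table["mode"].value_counts()


@dataclass
class CoreSet:
    """Per-compartment core OTU sets at a prevalence threshold."""

    sets: dict  # compartment -> set of otu ids
    prevalence: float


@dataclass
class ConvergenceResult:
    distances: pd.DataFrame  # age_days, parent_id, progeny_id, distance
    test: KruskalDunnResult | None


def detect_transmitted(
    t: CountTable,
    meta: SampleMeta,
    generation_groups: dict,
    detection: str = "mean_gt_zero",
    min_count: int = 5,
) -> TransmissionResult:
    """Call transmitted vs transient OTUs across three seed generation groups.

    ``generation_groups`` maps group names to sample-id lists; all samples
    must be seed (Se) samples and the groups must be disjoint. Detection
    operates on the across-replicate mean count of each group:
    ``mean_gt_zero`` requires the mean > 0; ``min_count`` requires the
    mean >= ``min_count``. The seed OTU universe is every OTU detected in
    at least one group; transmitted OTUs are those detected in all groups.
    """
    names = list(generation_groups)
    if len(names) < 2:
        raise DataError("need at least two generation groups")
    if detection not in ("mean_gt_zero", "min_count"):
        raise DataError(f"unknown detection rule {detection!r}")
    all_ids: list[str] = []
    for name in names:
        ids = list(generation_groups[name])
        if not ids:
            raise DataError(f"generation group {name!r} is empty")
        comps = {meta.lookup(s)["compartment"] for s in ids}
        if comps != {"Se"}:
            raise DataError(f"generation group {name!r} contains non-seed samples: {comps - {'Se'}}")
        all_ids.extend(ids)
    if len(all_ids) != len(set(all_ids)):
        raise DataError("generation groups overlap")

    means = pd.DataFrame(
        {name: t.counts[list(generation_groups[name])].mean(axis=1) for name in names}
    )
    if detection == "mean_gt_zero":
        detected = means > 0
    else:
        detected = means >= min_count
    seed_universe = detected.any(axis=1) | (means > 0).any(axis=1)
    detected = detected.loc[seed_universe]
    status = pd.Series(
        np.where(detected.all(axis=1), "transmitted", "transient"),
        index=detected.index,
        name="status",
    )
    return TransmissionResult(status=status, presence=detected, group_names=tuple(names))


def classify_succession(
    t: NormalizedTable,
    meta: SampleMeta,
    compartment: str = "Se",
    alpha: float = 0.05,
    include_parent: bool = False,
) -> SuccessionResult:
    """Classify each OTU's successional mode from its abundance-age trend.

    Ordinary least squares of relative abundance on age_days across all
    replicates of the compartment; parent seeds (age 0) are excluded by
    default so the trend describes progeny maturation. Modes follow the
    sign/significance rule: Early (t < 0, p < alpha), Late (t > 0,
    p < alpha), MidNoTrend otherwise. An OTU absent from every sample is
    MidNoTrend with p = 1 and the ``degenerate`` flag set.
    """
    if t.method != "relative_abundance":
        raise DataError("classify_succession expects a relative-abundance table")
    sids = meta.samples(compartment=compartment)
    if not include_parent:
        sids = [s for s in sids if int(meta.lookup(s)["age_days"]) > 0]
    ages = np.array([int(meta.lookup(s)["age_days"]) for s in sids], dtype=float)
    if len(set(ages)) < 3:
        raise DataError("classify_succession needs >= 3 distinct timepoints")
    sub = t.values[sids]
    rows = []
    for otu in sub.index:
        y = sub.loc[otu].to_numpy(dtype=float)
        if np.all(y == 0) or np.ptp(y) == 0:
            rows.append((otu, 0.0, 0.0, 1.0, "MidNoTrend", True))
            continue
        res = sps.linregress(ages, y)
        slope = float(res.slope)
        if res.stderr > 0:
            p = float(res.pvalue)
            tstat = slope / res.stderr
        else:
            # perfect fit: zero residual variance
            tstat = float(np.sign(slope)) * float("inf") if slope != 0 else 0.0
            p = 0.0 if slope != 0 else 1.0
        if p < alpha and tstat < 0:
            mode = "Early"
        elif p < alpha and tstat > 0:
            mode = "Late"
        else:
            mode = "MidNoTrend"
        rows.append((otu, slope, float(tstat), p, mode, False))
    table = pd.DataFrame(
        rows, columns=["otu_id", "slope", "t_stat", "p_value", "mode", "degenerate"]
    ).set_index("otu_id")
    return SuccessionResult(table)


def convergence_trajectory(
    t: CountTable,
    meta: SampleMeta,
    parent_age: int = 0,
    compartment: str = "Se",
    metric: str = "bray_curtis",
    restrict_to=None,
    run_test: bool = True,
) -> ConvergenceResult:
    """Parent-progeny community dissimilarity per progeny age.

    All pairwise distances between parent seeds (age ``parent_age``,
    conventionally the Se0 sowing-stage seeds) and progeny seeds at each
    later age, on relative abundances, optionally restricted to an OTU
    set (e.g. the transmitted OTUs). Ages with fewer than two progeny
    samples are excluded with a warning. Per-age distributions are
    compared by Kruskal-Wallis with Dunn's test.
    """
    parent_ids = meta.samples(compartment=compartment, age_days=parent_age)
    if not parent_ids:
        raise DataError("parent group is empty")
    ra = t.relative_abundance()
    if restrict_to is not None:
        keep = [o for o in ra.index if o in set(restrict_to)]
        ra = ra.loc[keep]
    ages = sorted(
        a for a in set(meta.table.loc[meta.table["compartment"] == compartment, "age_days"])
        if a != parent_age
    )
    rows = []
    for age in ages:
        prog_ids = meta.samples(compartment=compartment, age_days=age)
        if len(prog_ids) < 2:
            logger.warning("progeny age %s has < 2 samples; excluded", age)
            continue
        block = ra[parent_ids + prog_ids]
        d = dissimilarity(block, metric=metric)
        mat = d.matrix
        for p_id in parent_ids:
            for s_id in prog_ids:
                rows.append((age, p_id, s_id, float(mat.loc[p_id, s_id])))
    dist = pd.DataFrame(rows, columns=["age_days", "parent_id", "progeny_id", "distance"])
    test = None
    if run_test and dist["age_days"].nunique() >= 2:
        grouped = {
            str(age): grp["distance"].to_numpy()
            for age, grp in dist.groupby("age_days", sort=True)
        }
        test = kruskal_dunn(grouped)
    return ConvergenceResult(distances=dist, test=test)


def core_otus(
    t: CountTable,
    meta: SampleMeta,
    prevalence: float = 0.8,
    compartments=None,
) -> CoreSet:
    """Core OTUs per compartment at a prevalence threshold (inclusive >=).

    An OTU belongs to a compartment's core when it is detected
    (count > 0) in at least ``prevalence`` of that compartment's samples.
    """
    if not (0.0 < prevalence <= 1.0):
        raise DataError("prevalence must be in (0, 1]")
    if compartments is None:
        compartments = sorted(set(meta.table["compartment"]))
    sets = {}
    for comp in compartments:
        sids = meta.samples(compartment=comp)
        if not sids:
            logger.warning("compartment %s has no samples; skipped", comp)
            continue
        frac = (t.counts[sids] > 0).mean(axis=1)
        sets[comp] = set(frac.index[frac >= prevalence])
    return CoreSet(sets=sets, prevalence=prevalence)


def overlap_summary(sets_by_name: dict) -> pd.DataFrame:
    """Venn-region counts for a family of OTU sets.

    Returns one row per non-empty membership pattern (a region of the
    Venn diagram): which sets the region belongs to and how many OTUs
    fall exactly in that region. Deterministic, ordered by pattern.
    """
    names = list(sets_by_name)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets_by_name[n]) for n in combo))
            outside = set().union(*(set(sets_by_name[n]) for n in names if n not in combo)) if len(combo) < len(names) else set()
            region = inside - outside
            rows.append({
                "sets": "&".join(combo),
                "n_sets": r,
                "count": len(region),
            })
    return pd.DataFrame(rows)


def transmission_overlap(trans: TransmissionResult, cores: CoreSet, compartments=("L1", "S1", "Se")) -> pd.DataFrame:
    """Venn regions of the transmitted set against selected core sets."""
    sets = {"transmitted": set(trans.transmitted)}
    for comp in compartments:
        if comp in cores.sets:
            sets[f"core_{comp}"] = cores.sets[comp]
    return overlap_summary(sets)
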