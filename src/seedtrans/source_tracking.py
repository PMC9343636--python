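"""Microbial source tracking by expectation-maximization.

Each sink community is modeled as a mixture of multinomials: the sink's
taxon distribution is sum_j alpha_j * gamma_j over K named source
profiles plus one latent "Unknown" source. EM alternates
responsibilities r_ij proportional to alpha_j * gamma_j(i) with closed-form
updates of the mixing proportions alpha (and, by default, a joint update
of the source profiles gamma that pools the observed source counts with
the sink reads assigned to that source — the FEAST-style variant;
``update_gamma=False`` gives the fixed-profile SourceTracker-style
variant). The full-data log-likelihood (source counts + sink counts) is
non-decreasing at every iteration and is asserted as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable, DataError, SampleMeta

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"


@dataclass
class SourceContribution:
    sink_id: str
    alpha: pd.Series  # source name (incl. 'Unknown') -> proportion
    log_likelihood: list
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        total = float(self.alpha.sum())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"alpha does not sum to 1 (got {total})")


def _total_loglik(y, X, alpha, gamma):
    """Joint log-likelihood of source counts and sink counts.

    Constant multinomial coefficients are omitted (they do not affect
    EM monotonicity or convergence).
    """
    eps = 1e-300
    mix = gamma.T @ alpha  # (n_otus,)
    ll = float(y @ np.log(mix + eps))
    if X is not None:
        ll += float(np.sum(X * np.log(gamma[: X.shape[0]] + eps)))
    return ll


def fit_source_mixture(
    sink,
    sources,
    source_names=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int | None = None,
    update_gamma: bool = True,
    unknown_support: str = "uncovered",
    pseudocount: float = 1e-8,
    sink_id: str = "sink",
) -> SourceContribution:
    """EM fit of source mixing proportions for one sink community.

    ``sink`` is a count vector over OTUs; ``sources`` a K x n_otus count
    matrix sharing the OTU axis. Known-source profiles are initialized at
    the empirical source frequencies (with a small pseudocount).

    The Unknown component represents, by default
    (``unknown_support='uncovered'``), the sink mass on taxa absent from
    every named source — which keeps the mixture identifiable (a
    free-profile unknown could explain the whole sink by itself, the
    degenerate maximum-likelihood solution). ``unknown_support='free'``
    lets the Unknown range over all taxa, initialized at the residual
    sink mass.

    Iteration stops when ``max(|delta alpha|) < tol`` or at ``max_iter``;
    the best of ``n_restarts`` jittered initializations (by total
    log-likelihood) is returned. alpha lies on the probability simplex.
    """
    y = np.asarray(sink, dtype=float)
    X = np.atleast_2d(np.asarray(sources, dtype=float))
    K, n_otus = X.shape
    if K < 1:
        raise DataError("need at least one source")
    if y.shape[0] != n_otus:
        raise DataError("sink and sources must share the OTU axis")
    if y.sum() <= 0:
        raise DataError("sink has zero depth")
    if source_names is None:
        source_names = [f"source_{j}" for j in range(K)]
    names = list(source_names) + [UNKNOWN]

    if unknown_support not in ("uncovered", "free"):
        raise DataError(f"unknown unknown_support {unknown_support!r}")
    gamma_known = (X + pseudocount)
    gamma_known /= gamma_known.sum(axis=1, keepdims=True)
    covered = X.sum(axis=0) > 0
    if unknown_support == "uncovered":
        support = ~covered
        uncovered_mass = np.where(support, y, 0.0)
        if uncovered_mass.sum() > 0:
            gamma_unknown0 = uncovered_mass / uncovered_mass.sum()
        elif support.any():
            gamma_unknown0 = support / support.sum()
        else:
            gamma_unknown0 = np.zeros(n_otus)  # sources cover everything
    else:
        support = np.ones(n_otus, dtype=bool)
        resid = np.clip(y / y.sum() - gamma_known.mean(axis=0), 0.0, None)
        if resid.sum() > 0:
            gamma_unknown0 = resid / resid.sum()
        else:
            gamma_unknown0 = np.full(n_otus, 1.0 / n_otus)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        alpha = np.full(K + 1, 1.0 / (K + 1))
        if restart > 0:
            alpha = rng.dirichlet(np.ones(K + 1) * 5.0)
        gamma = np.vstack([gamma_known, gamma_unknown0]).copy()
        ll_trace = []
        converged = False
        for it in range(max_iter):
            mix = gamma.T @ alpha  # (n_otus,)
            mix = np.where(mix <= 0, 1e-300, mix)
            r = (gamma * alpha[:, None]) / mix[None, :]  # (K+1, n_otus)
            assigned = r * y[None, :]  # expected reads per source per OTU
            new_alpha = assigned.sum(axis=1) / y.sum()
            if update_gamma:
                # exact M-step (no pseudocount) keeps the EM monotone;
                # the Unknown profile stays within its support
                pooled = assigned.copy()
                pooled[:K] += X
                pooled[K] *= support
                totals = pooled.sum(axis=1, keepdims=True)
                nonzero = totals[:, 0] > 0
                gamma[nonzero] = pooled[nonzero] / totals[nonzero]
            ll = _total_loglik(y, X if update_gamma else None, new_alpha, gamma)
            if ll_trace and ll < ll_trace[-1] - 1e-6 * max(1.0, abs(ll_trace[-1])):
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll_trace[-1]} -> {ll}"
                )
            delta = float(np.max(np.abs(new_alpha - alpha)))
            alpha = new_alpha
            ll_trace.append(ll)
            if delta < tol:
                converged = True
                break
        result = (ll_trace[-1], alpha, ll_trace, it + 1, converged)
        if best is None or result[0] > best[0]:
            best = result
    _, alpha, ll_trace, n_iter, converged = best
    alpha = alpha / alpha.sum()
    return SourceContribution(
        sink_id=sink_id,
        alpha=pd.Series(alpha, index=names, name="alpha"),
        log_likelihood=ll_trace,
        n_iter=n_iter,
        converged=converged,
    )


@dataclass
class SourceTrackingResult:
    per_sink: pd.DataFrame  # sink_id, source_compartment, source_age, alpha
    by_compartment: pd.DataFrame  # compartment -> alpha_mean, alpha_sd
    by_compartment_age: pd.DataFrame
    contributions: list = field(default_factory=list)


def track_by_timepoint(
    t: CountTable,
    meta: SampleMeta,
    sink_compartment: str = "Se",
    sink_age: int | None = None,
    sink_year: int | None = None,
    exclude_harvest_sources: bool = True,
    sources_include=None,
    sources_exclude=None,
    **fit_kwargs,
) -> SourceTrackingResult:
    """Source-sink attribution of harvest-stage seed communities.

    Sinks are the seed samples at the harvest age (the latest seed age
    unless given); sources are every (compartment, age) community at
    earlier ages, with the harvest-stage non-seed communities excluded
    (at harvest the plant body is senescent and is not treated as a
    source). Replicates of a source group are summed into one profile.
    Each sink (biological replicate; technical replicates summed) is fit
    separately; contributions are aggregated by source compartment and
    by compartment x age, with mean and sd across sinks. By construction
    each compartment total equals the sum of its age-resolved
    contributions. ``sources_include`` / ``sources_exclude`` optionally
    restrict the source groups to named (compartment, age) pairs, e.g.
    to drop developing-seed sources that are near-copies of the sink.
    """
    meta.check_join(t)
    seed_ages = sorted(set(meta.table.loc[meta.table["compartment"] == sink_compartment, "age_days"]))
    if sink_age is None:
        sink_age = max(seed_ages)
    if sink_year is None:
        sink_year = int(meta.table["year"].max())
    sink_rows = meta.table[
        (meta.table["compartment"] == sink_compartment)
        & (meta.table["age_days"] == sink_age)
        & (meta.table["year"] == sink_year)
    ]
    if sink_rows.empty:
        raise DataError("no sink samples at the harvest age")

    # source groups: (compartment, age) with age < sink_age, or seeds at
    # earlier ages; harvest-age non-seed compartments dropped by default,
    # and harvest-age seeds (any year/generation) never act as sources
    src = meta.table[~meta.table["sample_id"].isin(sink_rows["sample_id"])]
    src = src[src["age_days"] <= sink_age]
    if exclude_harvest_sources:
        src = src[~((src["age_days"] == sink_age) & (src["compartment"] != sink_compartment))]
    src = src[~((src["compartment"] == sink_compartment) & (src["age_days"] == sink_age))]
    if sources_include is not None:
        allowed = {(c, int(a)) for c, a in sources_include}
        src = src[[(r.compartment, int(r.age_days)) in allowed for r in src.itertuples()]]
    if sources_exclude is not None:
        banned = {(c, int(a)) for c, a in sources_exclude}
        src = src[[(r.compartment, int(r.age_days)) not in banned for r in src.itertuples()]]
    groups = []
    for (comp, age), sub in src.groupby(["compartment", "age_days"], sort=True):
        profile = t.counts[list(sub["sample_id"])].sum(axis=1).to_numpy(dtype=float)
        if profile.sum() == 0:
            logger.warning("source (%s, %s) has zero depth; dropped", comp, age)
            continue
        groups.append(((comp, int(age)), profile))
    if not groups:
        raise DataError("no usable source groups")
    source_names = [f"{comp}@{age}" for (comp, age), _ in groups]
    X = np.vstack([profile for _, profile in groups])

    contribs = []
    rows = []
    for bio_rep, sub in sink_rows.groupby("bio_rep", sort=True):
        y = t.counts[list(sub["sample_id"])].sum(axis=1).to_numpy(dtype=float)
        fit = fit_source_mixture(
            y, X, source_names=source_names, sink_id=f"{sink_compartment}@{sink_age}_rep{bio_rep}",
            **fit_kwargs,
        )
        contribs.append(fit)
        for name, a in fit.alpha.items():
            if name == UNKNOWN:
                comp, age = UNKNOWN, -1
            else:
                comp, age_s = name.split("@")
                age = int(age_s)
            rows.append({
                "sink_id": fit.sink_id, "bio_rep": bio_rep,
                "source_compartment": comp, "source_age": age, "alpha": float(a),
            })
    per_sink = pd.DataFrame(rows)
    by_ca = (
        per_sink.groupby(["source_compartment", "source_age"])["alpha"]
        .agg(alpha_mean="mean", alpha_sd="std")
        .fillna(0.0)
        .reset_index()
    )
    per_comp = (
        per_sink.groupby(["sink_id", "source_compartment"])["alpha"].sum().reset_index()
    )
    by_c = (
        per_comp.groupby("source_compartment")["alpha"]
        .agg(alpha_mean="mean", alpha_sd="std")
        .fillna(0.0)
        .reset_index()
    )
    return SourceTrackingResult(
        per_sink=per_sink, by_compartment=by_c, by_compartment_age=by_ca,
        contributions=contribs,
    )
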