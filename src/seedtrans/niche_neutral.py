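"""Niche responsiveness (heritability analog) and Sloan's neutral model.

Niche responsiveness treats host age as the "genetic" factor of a
heritability analysis: for each OTU a linear mixed model regresses the
CLR-transformed abundance on age (categorical fixed effect) with a
random intercept per biological replicate, and

    h^2 = Var(fitted fixed effect) / (Var(fitted) + sigma^2_rep + sigma^2_res)

is the fraction of abundance variance attributable to the changing host
environment. OTUs are classed High (h^2 > 0.4), Moderate
(0.2 < h^2 <= 0.4) or Low (h^2 <= 0.2) on the bootstrap mean.

Sloan's neutral model predicts the occurrence frequency of a taxon in a
set of local communities from its mean metacommunity relative abundance
p_i, the community size N (mean read depth) and a single migration rate
m, via the incomplete beta function; taxa whose observed occurrence
falls outside the 95% interval around the prediction are partitioned as
'above' (more frequent than neutral expectation) or 'below'.
Speciation/diversification are excluded from the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.proportion import proportion_confint

from .io import CountTable, DataError, NormalizedTable, SampleMeta

logger = logging.getLogger(__name__)


def filter_low_abundance(t: CountTable, threshold: float = 1e-4) -> CountTable:
    """Drop OTUs whose mean relative abundance is strictly below threshold."""
    if not (0.0 <= threshold < 1.0):
        raise DataError("abundance threshold must be in [0, 1)")
    mean_ra = t.relative_abundance().mean(axis=1)
    keep = mean_ra >= threshold
    if not keep.any():
        raise DataError("abundance filter removed every OTU")
    return CountTable(t.counts.loc[keep].copy())


# ---------------------------------------------------------------------------
# Niche responsiveness (h^2)
# ---------------------------------------------------------------------------

@dataclass
class NicheResponsivenessResult:
    table: pd.DataFrame  # otu_id -> h2_mean, h2_sd, n_boot, class, singular_frac

    def classes(self) -> pd.Series:
        return self.table["class"]


def classify_h2(h2: float) -> str:
    """High (h2 > 0.4), Moderate (0.2 < h2 <= 0.4), Low (h2 <= 0.2)."""
    if h2 > 0.4:
        return "High"
    if h2 > 0.2:
        return "Moderate"
    return "Low"


def _h2_single(
    y: np.ndarray,
    age: np.ndarray,
    rep: np.ndarray,
    age_categorical: bool,
    bias_correction: bool = True,
) -> tuple[float, bool]:
    """One REML random-intercept fit; returns (h2, singular_flag).

    The raw variance of the fitted fixed effects overstates the age
    variance component by about sigma^2 (p-1)/n (the sampling variance
    of the estimated age means); with ``bias_correction`` that term is
    subtracted and the result clipped at zero, the usual unbiased
    variance-component estimate for a fixed factor. Falls back to OLS
    with sigma^2_replicate = 0 when the mixed fit is singular or fails
    to converge.
    """
    if np.ptp(y) == 0:
        return 0.0, False
    X = _design_matrix(y, age, age_categorical)
    h2, _, _, _, _, singular = _fit_components(y, X, rep, bias_correction)
    return h2, singular


def _design_matrix(y: np.ndarray, age: np.ndarray, age_categorical: bool) -> np.ndarray:
    if age_categorical:
        levels = np.unique(age)
        return np.column_stack(
            [np.ones_like(y)] + [(age == a).astype(float) for a in levels[1:]])
    return np.column_stack([np.ones_like(y), age.astype(float)])


def _fit_components(y, X, rep, bias_correction=True):
    """REML fit; returns (h2, var_fixed, var_re, resid_var, fitted, singular)."""
    import statsmodels.api as sm

    singular = False
    var_re = 0.0
    fitted = None
    resid_var = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=rep)
            fit = model.fit(reml=True, method="lbfgs")
        var_re = float(np.asarray(fit.cov_re).ravel()[0])
        resid_var = float(fit.scale)
        fitted = X @ np.asarray(fit.fe_params)
        if not np.isfinite(var_re) or var_re < 0:
            singular = True
    except Exception:
        singular = True
    if singular or fitted is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        dof = max(len(y) - X.shape[1], 1)
        resid_var = float(resid @ resid) / dof
        var_re = 0.0
    var_fixed = float(np.var(fitted, ddof=1)) if len(fitted) > 1 else 0.0
    if bias_correction:
        var_fixed -= (resid_var or 0.0) * (X.shape[1] - 1) / len(y)
        var_fixed = max(var_fixed, 0.0)
    total = var_fixed + var_re + (resid_var or 0.0)
    h2 = var_fixed / total if total > 0 else 0.0
    return min(max(h2, 0.0), 1.0), var_fixed, var_re, resid_var or 0.0, fitted, singular


def estimate_niche_responsiveness(
    t_clr: NormalizedTable,
    meta: SampleMeta,
    compartment: str = "Se",
    n_boot: int = 100,
    seed: int | None = None,
    age_categorical: bool = True,
    include_parent: bool = False,
    otus=None,
    bias_correction: bool = True,
    bootstrap: str = "parametric",
) -> NicheResponsivenessResult:
    """Bootstrap h^2 per OTU from a CLR table and the study design.

    The default bootstrap is parametric (the lme4 ``bootMer``
    convention): ``n_boot`` response vectors are simulated from the
    fitted model (fixed age effects + fresh replicate intercepts +
    residual noise) and refit, giving the mean and sd of h^2 and the
    High/Moderate/Low class of the mean. ``bootstrap='cluster'``
    resamples whole biological replicates with replacement instead;
    with very few plants the duplicated series collapse the residual
    variance, so the parametric scheme is preferred. ``otus``
    optionally restricts the estimation to a subset (the CLR geometry
    is unaffected).
    """
    if t_clr.method != "CLR":
        raise DataError("estimate_niche_responsiveness expects a CLR table")
    sids = meta.samples(compartment=compartment)
    if not include_parent:
        sids = [s for s in sids if int(meta.lookup(s)["age_days"]) > 0]
    age = np.array([int(meta.lookup(s)["age_days"]) for s in sids])
    rep = np.array([int(meta.lookup(s)["bio_rep"]) for s in sids])
    if len(np.unique(age)) < 3:
        raise DataError("need >= 3 ages")
    for a in np.unique(age):
        if len(np.unique(rep[age == a])) < 2:
            raise DataError(f"age {a} has < 2 biological replicates")
    sub = t_clr.values[sids]
    if otus is not None:
        sub = sub.loc[[o for o in otus if o in sub.index]]
    if bootstrap not in ("parametric", "cluster"):
        raise DataError(f"unknown bootstrap scheme {bootstrap!r}")
    rng = np.random.default_rng(seed)
    reps = np.unique(rep)
    rep_index = np.searchsorted(reps, rep)
    rows = []
    for otu in sub.index:
        y = sub.loc[otu].to_numpy(dtype=float)
        h2_boot = np.empty(n_boot)
        n_singular = 0
        if bootstrap == "parametric":
            if np.ptp(y) == 0:
                h2_boot[:] = 0.0
            else:
                X = _design_matrix(y, age, age_categorical)
                _, var_fixed, var_re, resid_var, fitted, point_singular = _fit_components(
                    y, X, rep, bias_correction)
                n_singular += point_singular
                # simulate from the bias-corrected model: shrink the fitted
                # age deviations so their variance equals the corrected
                # age variance component (raw fitted spread carries the
                # sampling noise of the estimated age means)
                raw_var = float(np.var(fitted, ddof=1))
                shrink = np.sqrt(var_fixed / raw_var) if raw_var > 0 else 0.0
                fitted = fitted.mean() + (fitted - fitted.mean()) * shrink
                for b in range(n_boot):
                    b_re = rng.normal(0.0, np.sqrt(max(var_re, 0.0)), size=len(reps))
                    y_star = (fitted + b_re[rep_index]
                              + rng.normal(0.0, np.sqrt(max(resid_var, 0.0)), size=len(y)))
                    h2, singular = _h2_single(y_star, age, rep, age_categorical,
                                              bias_correction)
                    h2_boot[b] = h2
                    n_singular += singular
        else:
            for b in range(n_boot):
                chosen = rng.choice(reps, size=len(reps), replace=True)
                idx = np.concatenate([np.flatnonzero(rep == r) for r in chosen])
                # relabel duplicated plants as distinct grouping units
                boot_rep = np.concatenate(
                    [np.full((rep == r).sum(), k) for k, r in enumerate(chosen)]
                )
                h2, singular = _h2_single(y[idx], age[idx], boot_rep, age_categorical,
                                          bias_correction)
                h2_boot[b] = h2
                n_singular += singular
        h2_mean = float(h2_boot.mean())
        rows.append({
            "otu_id": otu,
            "h2_mean": h2_mean,
            "h2_sd": float(h2_boot.std(ddof=1)) if n_boot > 1 else 0.0,
            "n_boot": n_boot,
            "class": classify_h2(h2_mean),
            "singular_frac": n_singular / n_boot,
        })
    return NicheResponsivenessResult(pd.DataFrame(rows).set_index("otu_id"))


# ---------------------------------------------------------------------------
# Sloan neutral model
# ---------------------------------------------------------------------------

@dataclass
class NeutralFit:
    m: float
    N: float
    d: float
    R2: float
    table: pd.DataFrame  # otu_id -> p, freq_obs, freq_pred, ci_lo, ci_hi, partition
    at_bound: bool
    n_communities: int


def _predict_freq(
    m: float, N: float, p: np.ndarray, d: float, prediction: str = "beta_cdf"
) -> np.ndarray:
    """Predicted detection frequency under the neutral model.

    'beta_cdf' is Sloan's threshold approximation
    P(abundance > d) = 1 - BetaCDF(d; Nmp, Nm(1-p)). 'beta_binomial'
    is the exact detection probability when a community of size N is
    read-sampled: 1 - P(0 reads) = 1 - B(Nmp, Nm(1-p)+N)/B(Nmp, Nm(1-p)).
    The two agree for abundant taxa; for rare taxa the threshold
    approximation undershoots detection, which biases a fitted m upward.
    """
    a = N * m * p
    b = N * m * (1.0 - p)
    if prediction == "beta_cdf":
        return 1.0 - sps.beta.cdf(d, a, b)
    if prediction == "beta_binomial":
        from scipy.special import betaln

        log_p0 = betaln(a, b + N) - betaln(a, b)
        return 1.0 - np.exp(log_p0)
    raise DataError(f"unknown prediction variant {prediction!r}")


def fit_neutral_model(
    t: CountTable,
    local_communities=None,
    ci_alpha: float = 0.05,
    ci_method: str = "wilson",
    depth_mean: str = "arithmetic",
    prediction: str = "beta_cdf",
) -> NeutralFit:
    """Fit Sloan's neutral model to occurrence-abundance data.

    Local communities default to all samples of the table. N is the mean
    read depth (arithmetic by default, 'geometric' exposed), the
    detection limit is d = 1/N, p_i the mean relative abundance across
    communities and freq_obs_i the detection fraction. The migration
    rate m minimizes the sum of squared occurrence residuals over
    (1e-6, 1); R^2 = 1 - SSE/SST. Per-OTU 95% intervals around
    freq_pred use the Wilson score interval with n = number of local
    communities; observed occurrence above/below the interval marks the
    OTU as non-neutral.
    """
    sub = t if local_communities is None else t.subset_samples(local_communities)
    n_comm = len(sub.sample_ids)
    if n_comm < 10:
        raise DataError("neutral-model fit needs >= 10 local communities")
    depths = sub.depths().to_numpy(dtype=float)
    if depth_mean == "arithmetic":
        N = float(depths.mean())
    elif depth_mean == "geometric":
        N = float(np.exp(np.log(depths).mean()))
    else:
        raise DataError(f"unknown depth_mean {depth_mean!r}")
    d = 1.0 / N
    ra = sub.relative_abundance()
    p = ra.mean(axis=1).to_numpy(dtype=float)
    freq_obs = (sub.counts.to_numpy() > 0).mean(axis=1)
    keep = p > 0
    p, freq_obs = p[keep], freq_obs[keep]
    otu_ids = list(np.asarray(sub.otu_ids)[keep])

    def sse(m):
        return float(np.sum((freq_obs - _predict_freq(m, N, p, d, prediction)) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    m = float(res.x)
    at_bound = m >= 1.0 - 1e-5 or m <= 2e-6
    if at_bound:
        logger.warning("neutral-model migration rate at bound: m=%.3g", m)
    freq_pred = _predict_freq(m, N, p, d, prediction)
    sst = float(np.sum((freq_obs - freq_obs.mean()) ** 2))
    r2 = 1.0 - sse(m) / sst if sst > 0 else float("nan")
    if ci_method == "wilson":
        ci_lo, ci_hi = proportion_confint(
            np.round(freq_pred * n_comm), n_comm, alpha=ci_alpha, method="wilson"
        )
    elif ci_method == "normal":
        se = np.sqrt(np.clip(freq_pred * (1 - freq_pred) / n_comm, 0, None))
        z = sps.norm.ppf(1 - ci_alpha / 2)
        ci_lo, ci_hi = np.clip(freq_pred - z * se, 0, 1), np.clip(freq_pred + z * se, 0, 1)
    else:
        raise DataError(f"unknown ci_method {ci_method!r}")
    ci_lo = np.minimum(ci_lo, freq_pred)
    ci_hi = np.maximum(ci_hi, freq_pred)
    partition = np.where(freq_obs > ci_hi, "above",
                         np.where(freq_obs < ci_lo, "below", "neutral"))
    table = pd.DataFrame({
        "p": p, "freq_obs": freq_obs, "freq_pred": freq_pred,
        "ci_lo": ci_lo, "ci_hi": ci_hi, "partition": partition,
    }, index=pd.Index(otu_ids, name="otu_id"))
    return NeutralFit(m=m, N=N, d=d, R2=r2, table=table,
                      at_bound=at_bound, n_communities=n_comm)


def partition_neutral(fit: NeutralFit) -> pd.DataFrame:
    """Per-partition OTU counts and mean abundance from a neutral fit."""
    tab = fit.table
    out = tab.groupby("partition").agg(
        n_otus=("p", "size"), mean_abundance=("p", "mean"),
        mean_freq_obs=("freq_obs", "mean"),
    )
    return out.reset_index()


def niche_consensus(
    fit: NeutralFit, h2: NicheResponsivenessResult
) -> pd.DataFrame:
    """OTUs flagged as niche-assembled by both lines of evidence.

    An OTU is jointly niche-flagged when its niche responsiveness class
    is High and its observed occurrence deviates from the neutral
    prediction (partition 'above' or 'below').
    """
    joined = fit.table.join(h2.table[["h2_mean", "class"]], how="inner")
    joined["niche_by_h2"] = joined["class"] == "High"
    joined["niche_by_neutral"] = joined["partition"] != "neutral"
    joined["niche_consensus"] = joined["niche_by_h2"] & joined["niche_by_neutral"]
    return joined
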