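"""Community dissimilarities, ordination, and the shared statistical tests.

Bray-Curtis and presence/absence Jaccard dissimilarities, principal
coordinates analysis (Gower double-centering via scikit-bio), one-factor
PERMANOVA with an explicit R^2, and Kruskal-Wallis with Dunn's post-hoc
z tests plus a compact letter display. Benjamini-Hochberg adjustment is
the single multiple-testing correction used throughout the package.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import CountTable, DataError, DistMatrix, NormalizedTable, TestResult

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (monotone step-up q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Dissimilarity
# ---------------------------------------------------------------------------

def dissimilarity(t, metric: str = "bray_curtis") -> DistMatrix:
    """Pairwise Bray-Curtis or Jaccard dissimilarity between samples.

    Bray-Curtis works on the (normalized) abundances:
    ``BC(u, v) = sum |u_i - v_i| / sum (u_i + v_i)``. Jaccard works on
    presence/absence: ``1 - |A & B| / |A | B|``. A pair of all-zero
    samples gets distance 0 with a logged warning.
    """
    if isinstance(t, (CountTable,)):
        values = t.counts.to_numpy(dtype=float)
        ids = t.sample_ids
    elif isinstance(t, NormalizedTable):
        values = t.values.to_numpy(dtype=float)
        ids = t.sample_ids
    elif isinstance(t, pd.DataFrame):
        values = t.to_numpy(dtype=float)
        ids = list(t.columns)
    else:
        values = np.asarray(t, dtype=float)
        ids = [f"s{i}" for i in range(values.shape[1])]
    n = values.shape[1]
    if n < 2:
        raise DataError("dissimilarity requires at least 2 samples")
    if metric not in ("bray_curtis", "jaccard"):
        raise DataError(f"unknown distance metric {metric!r}")
    out = np.zeros((n, n))
    warned = False
    if metric == "jaccard":
        present = values > 0
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "bray_curtis":
                u, v = values[:, i], values[:, j]
                denom = float((u + v).sum())
                degenerate = denom == 0
                d = float(np.abs(u - v).sum()) / denom if denom > 0 else 0.0
            else:
                a, b = present[:, i], present[:, j]
                union = int((a | b).sum())
                degenerate = union == 0
                d = 1.0 - int((a & b).sum()) / union if union > 0 else 0.0
            if degenerate and not warned:
                logger.warning(
                    "all-zero sample pair (%s, %s): distance defined as 0", ids[i], ids[j]
                )
                warned = True
            out[i, j] = out[j, i] = d
    return DistMatrix(pd.DataFrame(out, index=ids, columns=ids), metric=metric)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending, negatives included
    proportion_explained: np.ndarray


def pcoa(d: DistMatrix, k: int = 2) -> PCoAResult:
    """Principal coordinates analysis of a dissimilarity matrix.

    Gower double-centering followed by eigendecomposition (delegated to
    scikit-bio); axes are ordered by eigenvalue and negative eigenvalues
    are reported rather than dropped.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.ordination import pcoa as skbio_pcoa

    n = len(d.sample_ids)
    if k > n - 1:
        raise DataError(f"requested {k} axes from {n} samples (max {n - 1})")
    res = skbio_pcoa(SkbioDM(d.matrix.to_numpy(dtype=float), ids=d.sample_ids), method="eigh")
    eig = np.asarray(res.eigvals, dtype=float)
    coords = res.samples.iloc[:, :k]
    coords.index = d.sample_ids
    coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=np.asarray(res.proportion_explained, dtype=float),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray, uniq) -> tuple[float, float]:
    """Total and within-group sums of squared distances / group size."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistMatrix,
    grouping,
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> TestResult:
    """One-factor PERMANOVA (pseudo-F on squared dissimilarities).

    ``R^2 = SS_between / SS_total``;
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` over random label
    permutations (or over all distinct relabelings when
    ``exhaustive=True``, where p is the exact fraction).
    """
    labels = np.asarray(list(grouping))
    ids = d.sample_ids
    if len(labels) != len(ids):
        raise DataError("grouping length must match number of samples")
    uniq = np.unique(labels)
    k = len(uniq)
    n = len(ids)
    if k < 2:
        raise DataError("PERMANOVA needs at least 2 groups")
    if k == n:
        raise DataError("PERMANOVA needs at least one group with > 1 sample")
    d2 = d.matrix.to_numpy(dtype=float) ** 2

    def f_stat(lab):
        ss_t, ss_w = _permanova_ss(d2, lab, uniq)
        ss_b = ss_t - ss_w
        if ss_w <= 0:
            return math.inf, ss_b / ss_t if ss_t > 0 else 0.0
        f = (ss_b / (k - 1)) / (ss_w / (n - k))
        r2 = ss_b / ss_t if ss_t > 0 else 0.0
        return f, r2

    f_obs, r2 = f_stat(labels)
    if exhaustive:
        seen = set()
        count_ge, total = 0, 0
        for perm in itertools.permutations(range(n)):
            lab = tuple(labels[list(perm)])
            if lab in seen:
                continue
            seen.add(lab)
            total += 1
            if f_stat(np.asarray(lab))[0] >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_perm):
            lab = rng.permutation(labels)
            if f_stat(lab)[0] >= f_obs - 1e-12:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_perm)
        n_used = n_perm
    return TestResult(
        statistic=f_obs,
        p_value=p,
        n_perm=n_used,
        groups=tuple(uniq),
        extra={"R2": r2, "n": n, "k_groups": k},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

@dataclass
class KruskalDunnResult:
    kw: TestResult
    pairwise: pd.DataFrame  # group_a, group_b, z, p, q
    letters: dict  # group -> compact letter display string


def _compact_letters(groups, distinct_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are *not* significantly different. ``groups``
    must be ordered (letters are assigned along that order).
    """
    distinct = {frozenset(p) for p in distinct_pairs}
    # letter sets: start with one set holding everything, split on conflicts
    sets: list[set] = [set(groups)]
    for a, b in [tuple(sorted(p)) for p in sorted(map(sorted, distinct))]:
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: min(groups.index(g) for g in s) if s else 0)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(itertools.cycle(alphabet), sets):
        for g in s:
            out[g] += letter
    return out


def kruskal_dunn(values_by_group: dict, alpha: float = 0.05) -> KruskalDunnResult:
    """Kruskal-Wallis H with tie correction plus pairwise Dunn z tests.

    Dunn p-values are two-sided and BH-adjusted across all pairs; the
    compact letter display groups pairs whose adjusted q >= alpha.
    Constant data yields H=0, p=1 and a single shared letter.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise DataError("kruskal_dunn needs at least 2 groups")
    for g in groups:
        if len(values_by_group[g]) < 2:
            raise DataError(f"group {g!r} has < 2 observations")
    pooled = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        kw = TestResult(statistic=0.0, p_value=1.0, df=len(groups) - 1)
        pw = pd.DataFrame(
            [(a, b, 0.0, 1.0, 1.0) for a, b in itertools.combinations(groups, 2)],
            columns=["group_a", "group_b", "z", "p", "q"],
        )
        return KruskalDunnResult(kw, pw, {g: "a" for g in groups})
    h, p_kw = sps.kruskal(*[values_by_group[g] for g in groups])
    kw = TestResult(statistic=float(h), p_value=float(p_kw), df=len(groups) - 1)

    ranks = sps.rankdata(pooled)
    sizes = [len(values_by_group[g]) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {
        g: ranks[bounds[i]:bounds[i + 1]].mean() for i, g in enumerate(groups)
    }
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(groups, 2):
        na, nb = len(values_by_group[a]), len(values_by_group[b])
        se = math.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((a, b, z, min(p, 1.0)))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    pw["q"] = bh_adjust(pw["p"].to_numpy())
    distinct = [
        (r.group_a, r.group_b) for r in pw.itertuples() if r.q < alpha
    ]
    letters = _compact_letters(groups, distinct)
    return KruskalDunnResult(kw, pw, letters)
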