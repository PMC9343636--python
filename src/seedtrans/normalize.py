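"""Count normalizations: cumulative-sum scaling, relative abundance, CLR.

CSS rescales each sample by the cumulative sum of its counts up to a
quantile of that sample's nonzero count distribution, damping the
influence of a few very deeply sampled taxa; with q=1 it reduces to
total-sum scaling. The centered log-ratio (CLR) transform maps each
sample onto the real line relative to its geometric mean, the standard
way to take compositional count data into ordinary linear models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountTable, DataError, NormalizedTable, TaxonomyTable


def css_normalize(
    t: CountTable,
    quantile: float = 0.5,
    scale: float = 1000.0,
    log2_plus1: bool = True,
) -> NormalizedTable:
    """Cumulative-sum scaling with optional log2(x+1) transform.

    Per sample j the scaling factor ``s_j`` is the sum of counts less than
    or equal to the ``quantile``-th quantile of the sample's *nonzero*
    counts; each count becomes ``log2(x / s_j * scale + 1)`` (or the
    unlogged ratio when ``log2_plus1=False``).
    """
    if not (0.0 < quantile <= 1.0):
        raise DataError(f"CSS quantile must be in (0, 1], got {quantile}")
    counts = t.counts.to_numpy(dtype=float)
    out = np.empty_like(counts)
    for j, sample in enumerate(t.sample_ids):
        col = counts[:, j]
        nz = col[col > 0]
        qval = np.quantile(nz, quantile)
        s = col[col <= qval].sum()
        if s == 0:
            raise DataError(f"CSS scaling factor is 0 for sample {sample!r}")
        scaled = col / s * scale
        out[:, j] = np.log2(scaled + 1.0) if log2_plus1 else scaled
    df = pd.DataFrame(out, index=t.otu_ids, columns=t.sample_ids)
    return NormalizedTable(df, method="CSS_log")


def transform(
    t: CountTable,
    method: str = "relative_abundance",
    pseudocount: float = 0.5,
) -> NormalizedTable:
    """Relative-abundance or centered log-ratio transform.

    CLR uses ``log((x + pseudocount) / g_j)`` with ``g_j`` the geometric
    mean of the pseudocounted column, so every CLR column sums to zero.
    """
    counts = t.counts.to_numpy(dtype=float)
    if method == "relative_abundance":
        out = counts / counts.sum(axis=0, keepdims=True)
    elif method == "CLR":
        if pseudocount <= 0:
            raise DataError("CLR pseudocount must be > 0")
        x = counts + pseudocount
        logx = np.log(x)
        out = logx - logx.mean(axis=0, keepdims=True)
    else:
        raise DataError(f"unknown transform method {method!r}")
    df = pd.DataFrame(out, index=t.otu_ids, columns=t.sample_ids)
    return NormalizedTable(df, method=method if method == "CLR" else "relative_abundance")


def aggregate_taxa(
    t: CountTable,
    tax: TaxonomyTable,
    rank: str,
    min_mean_ra: float = 0.005,
) -> NormalizedTable:
    """Sum relative abundances by taxon at a rank, pooling rare groups.

    Groups whose mean relative abundance across samples is strictly below
    ``min_mean_ra`` (default 0.5%) are pooled into an 'other' bin; a group
    sitting exactly at the threshold is retained. Output columns sum to 1.
    """
    tax.check_covers(t)
    labels = tax.labels(rank, t.otu_ids)
    ra = t.relative_abundance()
    grouped = ra.groupby(labels.to_numpy()).sum()
    mean_ra = grouped.mean(axis=1)
    keep = mean_ra >= min_mean_ra
    kept = grouped.loc[keep]
    pooled = grouped.loc[~keep].sum(axis=0)
    if (~keep).any():
        kept = pd.concat([kept, pooled.to_frame("other").T])
    return NormalizedTable(kept, method="relative_abundance")


def mean_technical_replicates(t: CountTable, meta) -> tuple[CountTable, "object"]:
    """Average technical replicates into one column per biological unit.

    Pairwise community distances are computed from the mean abundance
    tables of technical replicates; this collapses each
    (compartment, age, year, site, bio_rep) group to its rounded mean
    count profile. Returns the collapsed table and matching metadata
    (tech_rep set to 0).
    """
    from .io import SampleMeta

    meta.check_join(t)
    key_cols = ["compartment", "age_days", "year", "site", "bio_rep"]
    groups = meta.table.groupby(key_cols, sort=True)
    cols, rows = {}, []
    for key, sub in groups:
        sid = "_".join(str(k) for k in key)
        mean_counts = t.counts[list(sub["sample_id"])].mean(axis=1)
        cols[sid] = np.round(mean_counts).astype(np.int64)
        rec = dict(zip(key_cols, key))
        rec["sample_id"] = sid
        rec["tech_rep"] = 0
        rows.append(rec)
    df = pd.DataFrame(cols, index=t.otu_ids)
    # rounding can zero out an extremely shallow column; guard the invariant
    nonzero = df.sum(axis=0) > 0
    df = df.loc[:, nonzero]
    rows = [r for r in rows if r["sample_id"] in set(df.columns)]
    return CountTable(df), SampleMeta(pd.DataFrame(rows))
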