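"""Stage-resolved expression dynamics: TPM, TMM, clustering and enrichment.

Counts are normalized to TPM within samples and by trimmed-mean-of-M-values
(TMM) factors between samples.  Expressed genes (TPM > 1 in at least one
sample) are clustered on per-stage Z-scaled profiles with K-means, and
stage-enriched genes are called by a Welch t-test on log2-CPM with
Benjamini–Hochberg correction at the thresholds FDR < 0.05 and
|log2 fold change| > 1.  The count-model test is a documented stand-in for
an external DE package: its contract is type-I control and recovery of
planted effects, not coefficient-level equality with any particular tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

LOG2_PSEUDOCOUNT = 0.5


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized counts rescaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene needs an effective length")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn(f"all-zero sample columns: {list(denom.index[zero_cols])}")
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, re-centered to geometric mean 1.

    The reference sample is the one whose upper-quartile of library-scaled
    counts is closest to the mean upper-quartile.  For each sample, M (log2
    ratio vs reference) and A (average log2 abundance) are computed over genes
    positive in both; the 30% M-tails and 5% A-tails are trimmed and the
    factor is 2 to the precision-weighted mean of the surviving M values.
    """
    x = counts.values.astype(float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("library size 0 for some sample")
    n_samples = x.shape[1]
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    scaled = x / lib
    if ref_sample is None:
        f75 = np.quantile(scaled, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    r, nr = x[:, ref_idx], lib[ref_idx]
    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref_idx:
            continue
        o, no = x[:, j], lib[j]
        ok = (o > 0) & (r > 0)
        if ok.sum() < 10:
            warnings.warn(f"fewer than 10 usable genes for sample {counts.columns[j]}; factor 1")
            continue
        m = np.log2((o[ok] / no) / (r[ok] / nr))
        a = 0.5 * np.log2((o[ok] / no) * (r[ok] / nr))
        # double trim: drop rank tails of M and of A (floor-based bounds as in
        # the original TMM implementation)
        rm = stats.rankdata(m, method="average")
        ra = stats.rankdata(a, method="average")
        n = int(ok.sum())
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() < 10:
            warnings.warn(f"fewer than 10 genes survive trimming for sample {counts.columns[j]}; factor 1")
            continue
        # delta-method precision weights (inverse asymptotic variance of M)
        w = 1.0 / ((no - o[ok]) / (no * o[ok]) + (nr - r[ok]) / (nr * r[ok]))
        log_factors[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def filter_expressed(tpm: pd.DataFrame, tpm_min: float = 1.0) -> pd.Index:
    """Genes with TPM above the threshold in at least one sample."""
    if tpm.shape[1] == 0 or tpm.shape[0] == 0:
        return pd.Index([], name=tpm.index.name)
    return tpm.index[(tpm > tpm_min).any(axis=1)]


@dataclass
class StageClusterResult:
    labels: pd.Series            # gene -> cluster label in 1..k (0 = zero-variance sentinel)
    centroids: np.ndarray        # (k, n_stages) in Z-space
    stage_order: list
    k: int


def average_replicates(tpm: pd.DataFrame, stage_of_sample: dict) -> pd.DataFrame:
    stages = pd.Series({s: stage_of_sample[s] for s in tpm.columns})
    uniq = list(dict.fromkeys(stages.values))
    return pd.DataFrame(
        {st: tpm.loc[:, stages.index[stages == st]].mean(axis=1) for st in uniq}
    )


def cluster_stage_profiles(
    tpm: pd.DataFrame, stage_of_sample: dict, k: int = 10, seed: int = 0,
    n_init: int = 25,
) -> StageClusterResult:
    """K-means on per-gene Z-scaled stage means (replicates averaged first).

    Genes with zero variance across stages cannot be Z-scaled and are assigned
    the sentinel cluster 0.
    """
    prof = average_replicates(tpm, stage_of_sample)
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    variable = sd > 0
    if k > int(variable.sum()):
        raise ValueError(f"k={k} exceeds the {int(variable.sum())} genes with variable profiles")
    z = prof.loc[variable].sub(mu[variable], axis=0).div(sd[variable], axis=0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z.values)
    labels = pd.Series(0, index=prof.index, name="cluster", dtype=int)
    labels.loc[variable] = km.labels_ + 1
    return StageClusterResult(labels=labels, centroids=km.cluster_centers_,
                              stage_order=list(prof.columns), k=k)


def log2_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    cpm = counts.div(lib, axis=1) * 1e6
    return np.log2(cpm + LOG2_PSEUDOCOUNT)


def differential_enrichment(
    counts: pd.DataFrame,
    stage_of_sample: dict,
    contrast: tuple[str, str] = ("adult", "larva"),
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Welch t-test on TMM-normalized log2-CPM between two stages.

    Returns a table with ``log2fc`` (first contrast stage minus second),
    ``p_value``, BH-adjusted ``fdr`` and ``enriched_class`` in
    {adult_enriched, larva_enriched, not_significant}.  Genes with identical
    counts in all samples are excluded from testing (p = 1 convention).
    """
    hi, lo = contrast
    cols_hi = [s for s in counts.columns if stage_of_sample[s] == hi]
    cols_lo = [s for s in counts.columns if stage_of_sample[s] == lo]
    for stage, cols in ((hi, cols_hi), (lo, cols_lo)):
        if len(cols) < 2:
            raise ValueError(f"stage {stage!r} has fewer than 2 replicates")
    factors = tmm_factors(counts[cols_hi + cols_lo])
    lcpm = log2_cpm(counts[cols_hi + cols_lo], factors)
    a, b = lcpm[cols_hi].values, lcpm[cols_lo].values
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    # identical raw counts across all samples: test undefined by convention
    raw = counts[cols_hi + cols_lo].values
    degenerate = (np.ptp(raw, axis=1) == 0) | (np.ptp(np.concatenate([a, b], axis=1), axis=1) == 0)
    pvals = np.ones(len(counts))
    testable = ~degenerate
    if testable.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            t = stats.ttest_ind(a[testable], b[testable], axis=1, equal_var=False)
        p = np.asarray(t.pvalue)
        p[~np.isfinite(p)] = 1.0
        pvals[testable] = p
    fdr = np.ones(len(counts))
    if testable.any():
        fdr[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    cls = np.where(
        (fdr < fdr_threshold) & (log2fc > lfc_threshold), f"{hi}_enriched",
        np.where((fdr < fdr_threshold) & (log2fc < -lfc_threshold), f"{lo}_enriched",
                 "not_significant"),
    )
    cls[degenerate] = "not_significant"
    return pd.DataFrame(
        {"gene_id": counts.index, "log2fc": log2fc, "p_value": pvals,
         "fdr": fdr, "enriched_class": cls}
    ).set_index("gene_id")
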