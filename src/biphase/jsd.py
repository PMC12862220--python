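"""Cross-species transcriptome divergence by Jensen–Shannon divergence.

Given a species × stage × ortholog TPM panel, each pairwise comparison
(reference species vs another species) proceeds as:

1. quantile-normalize the stage columns of the comparison so every column
   shares the same empirical distribution (ranks preserved, ties averaged);
2. turn each stage column into a probability profile over orthologs and
   compute the base-2 Jensen–Shannon divergence
   ``JSD(p, q) = H(m) − (H(p) + H(q)) / 2`` with ``m = (p + q) / 2`` for
   every (reference stage, other-species stage) pair — bounded in [0, 1];
3. bootstrap orthologs (default 1,000 replicates) for mean and sd;
4. adjust mean JSD by the comparison's ortholog count, min-max normalize the
   adjusted values globally across all comparisons, and within each
   comparison (relative values);
5. call, per reference stage, the other species' stage of minimal divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import child_rng


def quantile_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns (ties share averaged values).

    Every column's sorted vector becomes the mean of the column-wise sorted
    vectors; within-column rank order is preserved.
    """
    x = matrix.values.astype(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to quantile-normalize")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"constant column {matrix.columns[j]!r} mapped to reference values")
        ranks = stats.rankdata(col, method="average")       # 1-based, ties averaged
        # average rank r maps to interpolated reference value
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _entropy2(p: np.ndarray) -> float:
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def jsd(p, q) -> float:
    """Base-2 Jensen–Shannon divergence between two expression profiles.

    Profiles are normalized to probability vectors; the result lies in
    [0, 1], is symmetric, and is 0 iff the normalized profiles coincide.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("profiles must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp == 0 or sq == 0:
        raise ValueError("zero-sum profile")
    p, q = p / sp, q / sq
    m = 0.5 * (p + q)
    return _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))


def jsd_matrix(ref_profiles: pd.DataFrame, other_profiles: pd.DataFrame) -> pd.DataFrame:
    """JSD for every (reference stage, other stage) column pair."""
    out = np.empty((ref_profiles.shape[1], other_profiles.shape[1]))
    for i, rs in enumerate(ref_profiles.columns):
        for j, os_ in enumerate(other_profiles.columns):
            out[i, j] = jsd(ref_profiles[rs].values, other_profiles[os_].values)
    return pd.DataFrame(out, index=ref_profiles.columns, columns=other_profiles.columns)


def bootstrap_jsd(
    ref_profiles: pd.DataFrame,
    other_profiles: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    max_retries: int = 100,
):
    """Bootstrap orthologs with replacement; mean and sd of JSD per stage pair."""
    n = ref_profiles.shape[0]
    if n < 5:
        raise ValueError("need at least 5 orthologs to bootstrap")
    rng = child_rng(seed, "jsd-bootstrap")
    acc = np.zeros((n_boot, ref_profiles.shape[1], other_profiles.shape[1]))
    rv, ov = ref_profiles.values, other_profiles.values
    for b in range(n_boot):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            r, o = rv[idx], ov[idx]
            if np.all(r.sum(axis=0) > 0) and np.all(o.sum(axis=0) > 0):
                break
        else:
            raise RuntimeError("could not draw a bootstrap replicate with non-zero profiles")
        for i in range(r.shape[1]):
            for j in range(o.shape[1]):
                acc[b, i, j] = jsd(r[:, i], o[:, j])
    mean = pd.DataFrame(acc.mean(axis=0), index=ref_profiles.columns,
                        columns=other_profiles.columns)
    sd = pd.DataFrame(acc.std(axis=0, ddof=1), index=ref_profiles.columns,
                      columns=other_profiles.columns)
    return mean, sd


def normalize_jsd(
    mean_by_comparison: dict[str, pd.DataFrame],
    n_orthologs: dict[str, int],
):
    """Ortholog-count adjustment plus global and per-comparison min-max scaling.

    Returns ``(adjusted, global_norm, relative)`` dicts of matrices keyed like
    the input.  Global normalization uses the min and max over all adjusted
    values across comparisons; relative normalization rescales within each
    comparison.
    """
    if not mean_by_comparison:
        raise ValueError("need at least one comparison")
    adjusted = {k: m / n_orthologs[k] for k, m in mean_by_comparison.items()}
    allvals = np.concatenate([m.values.ravel() for m in adjusted.values()])
    lo, hi = allvals.min(), allvals.max()
    if hi == lo:
        warnings.warn("all adjusted JSD values equal; global normalization set to 0")
        global_norm = {k: m * 0.0 for k, m in adjusted.items()}
    else:
        global_norm = {k: (m - lo) / (hi - lo) for k, m in adjusted.items()}
    relative = {}
    for k, m in adjusted.items():
        mlo, mhi = m.values.min(), m.values.max()
        relative[k] = m * 0.0 if mhi == mlo else (m - mlo) / (mhi - mlo)
    return adjusted, global_norm, relative


def minimal_divergence_stage(matrix: pd.DataFrame, reference_stage: str):
    """Stage of the other species minimizing divergence to one reference stage.

    Ties are broken by the earlier stage order and flagged.
    """
    row = matrix.loc[reference_stage]
    lo = row.min()
    winners = [s for s in matrix.columns if row[s] == lo]
    return winners[0], len(winners) > 1


@dataclass
class JsdResult:
    species_pair: tuple[str, str]
    mean: pd.DataFrame
    sd: pd.DataFrame
    adjusted: pd.DataFrame | None = None
    global_norm: pd.DataFrame | None = None
    relative: pd.DataFrame | None = None
    argmin_stage: dict = field(default_factory=dict)


def panel_profiles(panel: pd.DataFrame, species: str) -> pd.DataFrame:
    """Orthologs × stages TPM matrix for one species, stage order preserved."""
    sub = panel[panel.species == species]
    stages = list(dict.fromkeys(sub.stage))
    mat = sub.pivot(index="ortholog", columns="stage", values="tpm")[stages]
    return mat


def compare_species(
    panel: pd.DataFrame,
    reference_species: str,
    n_boot: int = 1000,
    seed: int = 0,
    reference_stage: str | None = None,
) -> dict[str, JsdResult]:
    """Full divergence analysis of every species against the reference.

    Quantile normalization is applied jointly over the stage columns of each
    pairwise comparison; bootstrap means are ortholog-adjusted and normalized
    globally and per comparison; the minimal-divergence stage is called for
    every reference stage (on the globally normalized matrix — the argmin is
    invariant to the monotone rescaling).
    """
    others = [s for s in dict.fromkeys(panel.species) if s != reference_species]
    results: dict[str, JsdResult] = {}
    means, n_orth = {}, {}
    ref_mat_all = panel_profiles(panel, reference_species)
    for sp in others:
        other_mat = panel_profiles(panel, sp)
        common = ref_mat_all.index.intersection(other_mat.index)
        ref_mat = ref_mat_all.loc[common]
        oth_mat = other_mat.loc[common]
        joint = pd.concat(
            [ref_mat.add_prefix("ref::"), oth_mat.add_prefix("oth::")], axis=1
        )
        qn = quantile_transform(joint)
        ref_qn = qn[[c for c in qn.columns if c.startswith("ref::")]]
        ref_qn.columns = [c.removeprefix("ref::") for c in ref_qn.columns]
        oth_qn = qn[[c for c in qn.columns if c.startswith("oth::")]]
        oth_qn.columns = [c.removeprefix("oth::") for c in oth_qn.columns]
        mean, sd = bootstrap_jsd(ref_qn, oth_qn, n_boot=n_boot, seed=seed)
        results[sp] = JsdResult(species_pair=(reference_species, sp), mean=mean, sd=sd)
        means[sp] = mean
        n_orth[sp] = len(common)
    adjusted, global_norm, relative = normalize_jsd(means, n_orth)
    for sp in others:
        res = results[sp]
        res.adjusted = adjusted[sp]
        res.global_norm = global_norm[sp]
        res.relative = relative[sp]
        ref_stages = [reference_stage] if reference_stage else list(res.mean.index)
        for rs in ref_stages:
            res.argmin_stage[rs] = minimal_divergence_stage(res.global_norm, rs)
    return results
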