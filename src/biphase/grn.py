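"""Stage-specific gene-regulatory-network construction.

Two evidence channels are combined per stage:

* a *signal* network: motif sites are scored by a logistic combination of
  standardized ATAC, H3K27ac and motif scores over a summit-centered ±100 bp
  window; TF→target edges aggregate the mean binding score of the TF's sites
  in the target's regulatory domain (promoter ∪ genic), weighted by
  rank-scaled TF and target expression, and only the top-quantile (default
  top 25%) of edges is retained;
* a *footprint* network: a site is "bound" when its accessibility dip —
  mean flank minus mean center signal — exceeds a threshold placed at the
  valley of a two-component Gaussian mixture over all site scores of the
  stage; every bound site in a target's domain yields an edge.

The binding model is a documented monotone stand-in for external tools whose
internals the source study does not specify; its contract is planted-edge
recovery, not equality with any particular software.  The final GRN is the
union of the two channels (intersection behind a flag), restricted to a
target gene list, summarized by TF outdegree centrality and the TF sets
shared between stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .config import ACTIVE_OR_POISED, CATEGORIES, MARKS
from .linkage import genic_interval, promoter_interval

SUMMIT_HALF_BP = 100


# ---------------------------------------------------------------------------
# peak selection
# ---------------------------------------------------------------------------

def select_regulatory_peaks(
    peaks: pd.DataFrame,
    category_idx_by_chrom: dict[str, np.ndarray],
    bin_bp: int = 200,
    min_overlap: float = 0.5,
    summit_half_bp: int = SUMMIT_HALF_BP,
) -> pd.DataFrame:
    """Keep peaks with ≥50% of their length in poised/active bins; summit-center.

    The retained interval is [summit − 100 bp, summit + 100 bp).
    """
    act_idx = {CATEGORIES.index(c) for c in ACTIVE_OR_POISED}
    rows = []
    for p in peaks.itertuples(index=False):
        if not (p.start <= p.start + p.summit_offset < p.end):
            raise ValueError(f"summit outside peak {p.peak_id}")
        cats = category_idx_by_chrom[p.chrom]
        n_bins = cats.size
        length = p.end - p.start
        covered = 0
        b0 = max(p.start // bin_bp, 0)
        b1 = min(-(-p.end // bin_bp), n_bins)
        for b in range(b0, b1):
            if int(cats[b]) in act_idx:
                lo = max(p.start, b * bin_bp)
                hi = min(p.end, (b + 1) * bin_bp)
                covered += hi - lo
        if covered / length >= min_overlap:
            summit = p.start + p.summit_offset
            rows.append((p.peak_id, p.chrom, summit - summit_half_bp,
                         summit + summit_half_bp, summit))
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "summit"])


# ---------------------------------------------------------------------------
# binding scores
# ---------------------------------------------------------------------------

def binding_score(atac_z, k27ac_z, motif_z, weights=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Logistic combination of standardized signals; monotone in each input."""
    z = (weights[0] * np.asarray(atac_z) + weights[1] * np.asarray(k27ac_z)
         + weights[2] * np.asarray(motif_z))
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite standardized signal")
    return 1.0 / (1.0 + np.exp(-z))


def _window_mean_signal(track_by_chrom, chrom, start, end, bin_bp):
    arr = track_by_chrom[chrom]
    b0 = max(start // bin_bp, 0)
    b1 = min(-(-end // bin_bp), arr.shape[0])
    if b1 <= b0:
        return np.nan
    return float(np.mean(arr[b0:b1]))


def score_sites(
    sites: pd.DataFrame,
    atac_by_chrom: dict[str, np.ndarray],
    k27ac_by_chrom: dict[str, np.ndarray],
    bin_bp: int = 200,
    window_half_bp: int = SUMMIT_HALF_BP,
    weights=(1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Binding score per motif site from z-scored window signals.

    ATAC/H3K27ac window means are log1p-transformed (coverage is multiplicative)
    and standardized, together with the motif scores, across all candidate
    sites of the stage, then combined logistically.
    """
    center = ((sites.start + sites.end) // 2).values
    atac = np.array([
        _window_mean_signal(atac_by_chrom, c, int(m - window_half_bp),
                            int(m + window_half_bp), bin_bp)
        for c, m in zip(sites.chrom, center)
    ])
    k27 = np.array([
        _window_mean_signal(k27ac_by_chrom, c, int(m - window_half_bp),
                            int(m + window_half_bp), bin_bp)
        for c, m in zip(sites.chrom, center)
    ])
    out = sites.copy()
    out["atac_z"] = _zscore(np.log1p(atac))
    out["k27ac_z"] = _zscore(np.log1p(k27))
    out["motif_z"] = _zscore(sites.motif_score.values.astype(float))
    out["binding_score"] = binding_score(out.atac_z, out.k27ac_z, out.motif_z, weights)
    return out


def sites_in_peaks(sites: pd.DataFrame, selected_peaks: pd.DataFrame) -> pd.DataFrame:
    """Subset of motif sites whose center lies inside a selected peak window."""
    if selected_peaks.empty:
        return sites.iloc[0:0]
    by_chrom = {c: p for c, p in selected_peaks.groupby("chrom")}
    keep = []
    for i, s in enumerate(sites.itertuples(index=False)):
        p = by_chrom.get(s.chrom)
        if p is None:
            continue
        mid = (s.start + s.end) // 2
        if ((p.start <= mid) & (mid < p.end)).any():
            keep.append(i)
    return sites.iloc[keep]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - np.mean(x)) / sd


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def footprint_score(
    profile: np.ndarray, center_bins: int, flank_bins: int
) -> float:
    """Mean flank signal minus mean center signal over a site-centered profile.

    ``profile`` covers [flank | center | flank]; a positive score means the
    center is depleted relative to its flanks (a protected footprint).
    """
    profile = np.asarray(profile, float)
    if profile.size != center_bins + 2 * flank_bins:
        raise ValueError("profile length does not match center + 2*flank")
    flank = np.concatenate([profile[:flank_bins], profile[-flank_bins:]])
    center = profile[flank_bins: flank_bins + center_bins]
    return float(flank.mean() - center.mean())


def footprint_scores_for_sites(
    sites: pd.DataFrame,
    hires_by_chrom: dict[str, np.ndarray],
    hires_bin_bp: int = 10,
    center_bp: int = 20,
    flank_bp: int = 40,
) -> pd.Series:
    """Footprint score per site from the high-resolution accessibility track."""
    cb = center_bp // hires_bin_bp
    fb = flank_bp // hires_bin_bp
    out = np.full(len(sites), np.nan)
    for i, s in enumerate(sites.itertuples(index=False)):
        arr = hires_by_chrom[s.chrom]
        mid = (s.start + s.end) // 2 // hires_bin_bp
        lo = mid - cb // 2 - fb
        hi = mid - cb // 2 + cb + fb
        if lo < 0 or hi > arr.size:
            warnings.warn(f"site {i} window truncated by chromosome edge; skipped")
            continue
        out[i] = footprint_score(arr[lo:hi], cb, fb)
    return pd.Series(out, index=sites.index, name="footprint_score")


def bound_threshold(scores: np.ndarray, seed: int = 0) -> float:
    """Valley of a 2-component Gaussian mixture over site footprint scores.

    Falls back to the 90th percentile when the mixture is degenerate (nearly
    coincident components or a vanishing weight).
    """
    x = np.asarray(scores, float)
    x = x[np.isfinite(x)]
    if x.size < 10 or np.ptp(x) == 0:
        return float(np.quantile(x, 0.9)) if x.size else np.inf
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(x[:, None])
    means = gm.means_.ravel()
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    w_lo, w_hi = gm.weights_[order]
    if (m_hi - m_lo) < 1e-6 * max(abs(m_hi), 1.0) or min(w_lo, w_hi) < 0.02:
        return float(np.quantile(x, 0.9))
    grid = np.linspace(m_lo, m_hi, 512)
    dens = np.exp(gm.score_samples(grid[:, None]))
    return float(grid[int(np.argmin(dens))])


def call_bound_sites(
    sites: pd.DataFrame,
    hires_by_chrom: dict[str, np.ndarray],
    hires_bin_bp: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    out = sites.copy()
    out["footprint_score"] = footprint_scores_for_sites(out, hires_by_chrom, hires_bin_bp)
    thr = bound_threshold(out["footprint_score"].values, seed=seed)
    out["bound"] = out["footprint_score"] > thr
    out.loc[out["footprint_score"].isna(), "bound"] = False
    return out


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def gene_domains(genes: pd.DataFrame, promoter=(-2000, 500)) -> pd.DataFrame:
    """Promoter ∪ genic regulatory domain per gene as one genomic interval."""
    rows = []
    for row in genes.itertuples(index=False):
        p0, p1 = promoter_interval(row, promoter)
        g0, g1 = genic_interval(row, promoter)
        rows.append((row.gene_id, row.chrom, min(p0, g0), max(p1, g1)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _sites_to_targets(sites: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Inner join of sites against overlapping gene domains (site may hit several)."""
    rows = []
    by_chrom = {c: d for c, d in domains.groupby("chrom")}
    for i, s in enumerate(sites.itertuples(index=False)):
        d = by_chrom.get(s.chrom)
        if d is None:
            continue
        hit = d[(d.start < s.end) & (s.start < d.end)]
        for g in hit.gene_id:
            rows.append((i, s.tf, g))
    return pd.DataFrame(rows, columns=["site_index", "tf", "target"])


def rank_scale(expr: pd.Series) -> pd.Series:
    """Rank-scaled expression in (0, 1]: rank / n, average ranks for ties."""
    r = stats.rankdata(expr.values, method="average")
    return pd.Series(r / len(r), index=expr.index)


def build_signal_network(
    scored_sites: pd.DataFrame,
    domains: pd.DataFrame,
    stage_tpm: pd.Series,
    stage: str,
) -> pd.DataFrame:
    """Signal-evidence edges: mean binding score × g(TF expr) × g(target expr).

    ``stage_tpm`` is the per-gene TPM for the stage; edges whose TF has no
    expression record are dropped with a warning.  Scores are min-max rescaled
    to [0, 1] within the stage.
    """
    hits = _sites_to_targets(scored_sites, domains)
    if hits.empty:
        return pd.DataFrame(columns=["tf", "target", "probability_score", "evidence", "stage"])
    hits = hits.merge(
        scored_sites.reset_index(drop=True)["binding_score"],
        left_on="site_index", right_index=True,
    )
    g = rank_scale(stage_tpm)
    no_expr = sorted(set(hits.tf) - set(g.index))
    if no_expr:
        warnings.warn(f"TFs without expression records dropped: {no_expr}")
        hits = hits[~hits.tf.isin(no_expr)]
    hits = hits[hits.target.isin(g.index)]
    if hits.empty:
        return pd.DataFrame(columns=["tf", "target", "probability_score", "evidence", "stage"])
    agg = hits.groupby(["tf", "target"])["binding_score"].mean().reset_index()
    raw = agg.binding_score.values * g.reindex(agg.tf).values * g.reindex(agg.target).values
    lo, hi = raw.min(), raw.max()
    scaled = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return pd.DataFrame({
        "tf": agg.tf, "target": agg.target, "probability_score": scaled,
        "evidence": "signal", "stage": stage,
    })


def filter_top_edges(edges: pd.DataFrame, q: float = 0.75) -> pd.DataFrame:
    """Retain edges with score strictly above the q-quantile (linear interpolation)."""
    if edges.empty:
        return edges
    cut = float(np.quantile(edges.probability_score.values, q))
    kept = edges[edges.probability_score > cut]
    if kept.empty:
        warnings.warn("no edges exceed the score quantile (tied scores?)")
    return kept.reset_index(drop=True)


def build_footprint_network(
    bound_sites: pd.DataFrame, domains: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """One edge per (TF, target) with ≥1 bound site in the target's domain."""
    bs = bound_sites[bound_sites.bound].reset_index(drop=True)
    hits = _sites_to_targets(bs, domains)
    if hits.empty:
        return pd.DataFrame(columns=["tf", "target", "probability_score", "evidence", "stage"])
    pairs = hits[["tf", "target"]].drop_duplicates().reset_index(drop=True)
    pairs["probability_score"] = np.nan
    pairs["evidence"] = "footprint"
    pairs["stage"] = stage
    return pairs


def combine_networks(
    signal_edges: pd.DataFrame,
    footprint_edges: pd.DataFrame,
    targets: list[str],
    mode: str = "union",
) -> pd.DataFrame:
    """Union (default) or intersection of the two evidence channels.

    Restricted to the provided target list; the evidence column records which
    channels support each edge.
    """
    if not targets:
        raise ValueError("target gene list is empty")
    tset = set(targets)
    sig = signal_edges[signal_edges.target.isin(tset)]
    fp = footprint_edges[footprint_edges.target.isin(tset)]
    sig_pairs = set(zip(sig.tf, sig.target))
    fp_pairs = set(zip(fp.tf, fp.target))
    if mode == "union":
        pairs = sig_pairs | fp_pairs
    elif mode == "intersection":
        pairs = sig_pairs & fp_pairs
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    score = dict(zip(zip(sig.tf, sig.target), sig.probability_score))
    stage = None
    for df in (sig, fp):
        if len(df):
            stage = df.stage.iloc[0]
    rows = [
        (tf, tg, score.get((tf, tg), np.nan),
         ",".join(sorted(
             (["signal"] if (tf, tg) in sig_pairs else [])
             + (["footprint"] if (tf, tg) in fp_pairs else [])
         )), stage)
        for tf, tg in sorted(pairs)
    ]
    return pd.DataFrame(rows, columns=["tf", "target", "probability_score", "evidence", "stage"])


@dataclass
class NetworkSummary:
    outdegree: dict            # stage -> {tf: distinct target count}
    tf_sets: dict              # stage -> set of TFs with >= 1 edge
    shared_tfs: set
    shared_fraction: float
    centrality_rank: dict      # stage -> {tf: normalized outdegree rank in (0, 1]}


def network_summary(grn_by_stage: dict[str, pd.DataFrame]) -> NetworkSummary:
    outdeg, tf_sets, rank = {}, {}, {}
    for stage, grn in grn_by_stage.items():
        deg = grn.groupby("tf")["target"].nunique().to_dict()
        outdeg[stage] = deg
        tf_sets[stage] = set(deg)
        if deg:
            vals = pd.Series(deg)
            rank[stage] = (stats.rankdata(vals.values, method="average") / len(vals))
            rank[stage] = dict(zip(vals.index, rank[stage]))
        else:
            rank[stage] = {}
    all_tfs = set().union(*tf_sets.values()) if tf_sets else set()
    shared = set.intersection(*tf_sets.values()) if tf_sets else set()
    frac = len(shared) / len(all_tfs) if all_tfs else 0.0
    return NetworkSummary(outdegree=outdeg, tf_sets=tf_sets, shared_tfs=shared,
                          shared_fraction=frac, centrality_rank=rank)
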