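"""Planted-truth synthetic data generator.

Every input the pipeline consumes is generated here, together with a manifest
of the planted truth, so each downstream stage can be scored against known
answers without any external download:

* a gene annotation on a small multi-chromosome genome;
* per-stage chromatin tracks: a Markov chain over hidden chromatin states
  emits, per 200-bp bin and mark, Poisson counts at a signal rate where the
  state presents the mark and at a background rate otherwise;
* negative-binomial expression counts with planted per-stage log2 fold
  changes, and active-mark rate multipliers in the windows of "linked" genes
  so expression and chromatin changes are concordant by construction;
* a TF→target network: each true edge places a motif site inside the
  target's promoter/genic region, within an accessibility peak whose ATAC and
  H3K27ac rates are elevated and whose central 20 bp is depleted in a
  high-resolution insertion track (the footprint); decoy motif sites carry no
  peak, no elevation and no dip;
* paralog pairs planted as no-/one-sided/both-sided regulatory divergence;
* a species × stage × ortholog expression panel in which one stage of each
  non-reference species is the reference-stage profile plus small noise.

All randomness flows from one root seed through named child streams, so the
same configuration is byte-reproducible and adding a generator does not
perturb the draws of the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import MARKS, N_MARKS, SyntheticConfig, child_rng

DEFAULT_TAXON_ORDER = [
    "Cellular organisms", "Eukaryota", "Metazoa", "Bilateria", "Protostomia",
    "Lophotrochozoa", "Mollusca", "Bivalvia", "Ostreida", "Crassostrea",
]

_GENE_MARGIN_BP = 12_000       # keep gene windows clear of chromosome edges
_MOTIF_BP = 20
_MAX_PLACEMENT_RETRIES = 50


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def simulate_genes(config: SyntheticConfig) -> pd.DataFrame:
    """Non-overlapping genes laid out in regular slots with random offsets.

    The first ``n_tfs`` genes double as the TF repertoire (their ids are the
    TF ids of the motif table).
    """
    config.validate()
    rng = child_rng(config.seed, "genes")
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    rows = []
    gid = 0
    lo_len, hi_len = config.gene_length_range
    for ci, chrom in enumerate(config.chrom_names):
        n = per_chrom[ci]
        usable = config.chrom_length_bp - 2 * _GENE_MARGIN_BP
        slot = usable // max(n, 1)
        if slot <= hi_len:
            raise ValueError("chromosomes too short for the requested gene count")
        for k in range(n):
            length = int(rng.integers(lo_len, hi_len + 1))
            start = _GENE_MARGIN_BP + k * slot + int(rng.integers(0, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid + 1:04d}", chrom, start, start + length, strand, gid < config.n_tfs))
            gid += 1
    return pd.DataFrame(rows, columns=io.GENE_COLUMNS)


# ---------------------------------------------------------------------------
# paralog and DEG planting
# ---------------------------------------------------------------------------

def plan_paralogs(config: SyntheticConfig, genes: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Choose paralog pairs and the per-member planted specialization.

    Members of a pair are drawn from non-TF genes without reuse.  A member
    specialized for a stage gets a planted expression fold change toward that
    stage and is flagged for active-mark planting in that stage.
    """
    rng = child_rng(config.seed, "paralogs")
    pool = [g for g, tf in zip(genes.gene_id, genes.is_tf) if not tf]
    n_pairs = sum(config.paralog_patterns.values())
    if 2 * n_pairs > len(pool):
        raise ValueError("requested paralog pairs exceed available non-TF genes")
    chosen = list(rng.choice(pool, size=2 * n_pairs, replace=False))
    lfc_mag = float(np.mean(config.deg_lfc_range))
    rows, member_plan = [], {}
    i = 0
    for pattern in ("no_divergence", "one_sided", "both_sided"):
        for _ in range(config.paralog_patterns.get(pattern, 0)):
            a, b = chosen[i], chosen[i + 1]
            i += 2
            node = DEFAULT_TAXON_ORDER[int(rng.integers(0, len(DEFAULT_TAXON_ORDER)))]
            rows.append((a, b, node, pattern))
            if pattern == "no_divergence":
                member_plan[a] = member_plan[b] = (0.0, None)
            elif pattern == "one_sided":
                member_plan[a] = (-lfc_mag, "larva")
                member_plan[b] = (0.0, None)
            else:  # both_sided
                member_plan[a] = (-lfc_mag, "larva")
                member_plan[b] = (lfc_mag, "adult")
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "duplication_node", "true_pattern"])
    return pairs, member_plan


def plan_degs(config: SyntheticConfig, genes: pd.DataFrame, member_plan: dict):
    """Planted per-gene log2 fold changes (adult/larva) and the linked subset.

    Half of the free planted genes are adult-enriched (positive lfc), half
    larva-enriched; a ``linked_fraction`` of them additionally get concordant
    active-mark planting.  Paralog members keep their pattern-driven plan and
    specialized members are always linked (the pattern is defined by marks).
    """
    rng = child_rng(config.seed, "degs")
    lfc = pd.Series(0.0, index=genes.gene_id, name="planted_lfc")
    mark_stage: dict[str, str] = {}
    for g, (l, st) in member_plan.items():
        lfc[g] = l
        if st is not None:
            mark_stage[g] = st
    free = [g for g, tf in zip(genes.gene_id, genes.is_tf)
            if not tf and g not in member_plan]
    n = min(config.n_deg, len(free))
    picked = list(rng.choice(free, size=n, replace=False))
    lo, hi = config.deg_lfc_range
    for j, g in enumerate(picked):
        mag = float(rng.uniform(lo, hi))
        sign = 1.0 if j % 2 == 0 else -1.0
        lfc[g] = sign * mag
        if rng.random() < config.linked_fraction:
            mark_stage[g] = "adult" if sign > 0 else "larva"
    return lfc, mark_stage


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SyntheticConfig,
    genes: pd.DataFrame | None = None,
    planted_lfc: pd.Series | None = None,
    expressed_genes: set | None = None,
    base_scale: pd.Series | None = None,
):
    """Negative-binomial counts per gene and replicate with planted fold changes.

    Stage means are split symmetrically around a per-gene base mean:
    ``mean_larva = base * 2^(-lfc/2)``, ``mean_adult = base * 2^(+lfc/2)`` so
    the planted log2 ratio adult/larva equals ``lfc`` exactly in expectation.
    ``expressed_genes`` (regulators and their planted targets) draw their base
    mean from a tighter, clearly-expressed distribution — networks are built
    over expressed genes, so planted edges must connect expressed genes.
    ``base_scale`` couples the remaining genes' expression to their chromatin
    landscape (genes in closed domains are lowly expressed, as in real tissue).
    Returns (counts, effective lengths, true DEG table).
    """
    config.validate()
    if genes is None:
        genes = simulate_genes(config)
    rng = child_rng(config.seed, "expression")
    gene_ids = list(genes.gene_id)
    n = len(gene_ids)
    if planted_lfc is None:
        planted_lfc = pd.Series(0.0, index=gene_ids)
    planted_lfc = planted_lfc.reindex(gene_ids).fillna(0.0)
    base = np.exp(rng.normal(config.expr_mean_log, config.expr_mean_sd, size=n))
    if base_scale is not None:
        base = base * base_scale.reindex(gene_ids).fillna(1.0).values
    expressed_mask = np.array(
        [g in expressed_genes for g in gene_ids] if expressed_genes else [False] * n
    )
    base[expressed_mask] = np.exp(rng.normal(np.log(400.0), 0.5, size=int(expressed_mask.sum())))
    # planted genes get a tighter, higher base so the effect is the planted lfc,
    # not an extreme-low-count artefact
    planted = planted_lfc.abs().values > 0
    base[planted] = np.exp(rng.normal(np.log(300.0), 0.5, size=int(planted.sum())))
    disp = config.expr_dispersion
    if disp <= 0:
        raise ValueError("NB dispersion must be positive")
    lengths = pd.Series(
        rng.integers(config.eff_length_range[0], config.eff_length_range[1] + 1, size=n),
        index=gene_ids, name="effective_length_bp", dtype=float,
    )
    samples, stage_of_sample = [], {}
    cols = {}
    for stage, shift in (("larva", -0.5), ("adult", 0.5)):
        mean = base * np.power(2.0, shift * planted_lfc.values)
        for r in range(1, config.n_replicates + 1):
            name = f"{stage}_rep{r}"
            # NB(mean mu, dispersion phi): r = 1/phi, p = r/(r+mu)
            r_param = 1.0 / disp
            p_param = r_param / (r_param + mean)
            cols[name] = rng.negative_binomial(r_param, p_param)
            stage_of_sample[name] = stage
            samples.append(name)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    true_deg = pd.DataFrame({
        "gene_id": gene_ids,
        "planted_lfc": planted_lfc.values,
        "true_class": np.where(
            planted_lfc.values > 1, "adult_enriched",
            np.where(planted_lfc.values < -1, "larva_enriched", "not_enriched"),
        ),
    }).set_index("gene_id")
    return counts, lengths, stage_of_sample, true_deg


# ---------------------------------------------------------------------------
# network plan (true edges, motif sites, peaks)
# ---------------------------------------------------------------------------

def _gene_domain(row, promoter=(-2000, 500)):
    """Promoter ∪ genic span of a gene as one genomic interval (strand-aware)."""
    up, down = -promoter[0], promoter[1]
    if row.strand == "+":
        return row.start - up, row.end
    return row.start, row.end + up


def plan_network(
    config: SyntheticConfig,
    genes: pd.DataFrame,
    closed_bins: dict[str, np.ndarray] | None = None,
    decoy_gene_pool: list[str] | None = None,
    target_exclude: set | None = None,
):
    """True edges, their motif sites and peaks, decoy sites, and target list.

    ``closed_bins`` (per-chrom boolean arrays, True where ATAC is absent in the
    latent landscape) steers decoy motif sites into quiescent loci; without it
    decoys are placed without regard to the chromatin state.  ``target_exclude``
    removes genes (e.g. ones carrying planted expression effects) from the
    true-edge target pool so the network truth is orthogonal to the DE truth.
    """
    rng = child_rng(config.seed, "network")

    def _is_closed(chrom: str, pos: int, flank_bp: int = 100) -> bool:
        if closed_bins is None:
            return True
        arr = closed_bins[chrom]
        b0 = max((pos - flank_bp) // config.bin_size_bp, 0)
        b1 = min(-(-(pos + flank_bp) // config.bin_size_bp), arr.size)
        return bool(arr[b0:b1].all())
    tfs = list(genes.gene_id[genes.is_tf])
    if len(tfs) < 1:
        raise ValueError("need at least one TF")
    non_tf = genes[~genes.is_tf]
    pool_ids = [g for g in non_tf.gene_id if not target_exclude or g not in target_exclude]
    if not pool_ids:
        raise ValueError("no genes left for the network target pool")
    n_bio = min(80, len(pool_ids))
    bio_genes = list(rng.choice(pool_ids, size=n_bio, replace=False))
    targets = tfs + bio_genes
    # distinct TF->target pairs
    all_pairs = [(tf, g) for tf in tfs for g in bio_genes]
    idx = rng.choice(len(all_pairs), size=min(config.n_true_edges, len(all_pairs)), replace=False)
    true_edges = [all_pairs[i] for i in sorted(idx)]
    gene_by_id = genes.set_index("gene_id")
    domains = {
        row.gene_id: (row.chrom, *_gene_domain(row)) for row in genes.itertuples(index=False)
    }
    half = config.peak_halfwidth_bp
    peak_rows, site_rows = [], []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}

    def _unambiguous(chrom: str, pos: int, target: str) -> bool:
        """Site interval overlaps the target's domain and no other gene's."""
        s0, s1 = pos - _MOTIF_BP // 2, pos + _MOTIF_BP // 2
        for g, (c, d0, d1) in domains.items():
            if g != target and c == chrom and s0 < d1 and d0 < s1:
                return False
        return True

    for k, (tf, target) in enumerate(true_edges):
        row = gene_by_id.loc[target]
        lo, hi = _gene_domain(row)
        pos = None
        for _ in range(_MAX_PLACEMENT_RETRIES):
            cand = int(rng.integers(lo + half, hi - half)) if hi - half > lo + half else (lo + hi) // 2
            if _unambiguous(row.chrom, cand, target) and all(
                abs(cand - (a + b) // 2) > 2 * half for a, b in occupied[row.chrom]
            ):
                pos = cand
                break
        if pos is None:
            warnings.warn(f"placement collision for edge {tf}->{target}; using center")
            pos = (lo + hi) // 2
        occupied[row.chrom].append((pos - half, pos + half))
        peak_rows.append((f"peak{k + 1}", row.chrom, pos - half, pos + half, half))
        site_rows.append((tf, row.chrom, pos - _MOTIF_BP // 2, pos + _MOTIF_BP // 2,
                          float(rng.normal(11.0, 1.5)), target, True))
    # decoys: half inside quiescent gene domains (no peak), half intergenic;
    # decoy hosts are quiescent bystander genes, never network participants
    n_dec = config.n_decoy_sites
    pool = list(decoy_gene_pool) if decoy_gene_pool else list(non_tf.gene_id)
    pool = [g for g in pool if g not in set(bio_genes)] or pool
    def _overlapping_domains(chrom: str, pos: int) -> set:
        s0, s1 = pos - _MOTIF_BP // 2, pos + _MOTIF_BP // 2
        return {
            g for g, (c, d0, d1) in domains.items()
            if c == chrom and s0 < d1 and d0 < s1
        }

    for j in range(n_dec):
        tf = tfs[int(rng.integers(0, len(tfs)))]
        placed = False
        for _ in range(_MAX_PLACEMENT_RETRIES):
            if j % 2 == 0:
                host = str(rng.choice(pool))
                row = gene_by_id.loc[host]
                lo, hi = _gene_domain(row)
                chrom = row.chrom
                cand = int(rng.integers(lo, hi))
                allowed = {host}
            else:
                chrom = config.chrom_names[int(rng.integers(0, config.n_chroms))]
                cand = int(rng.integers(_GENE_MARGIN_BP, config.chrom_length_bp - _GENE_MARGIN_BP))
                allowed = set()
            if (
                _is_closed(chrom, cand)
                and _overlapping_domains(chrom, cand) <= allowed
                and all(not (a - _MOTIF_BP < cand < b + _MOTIF_BP) for a, b in occupied[chrom])
            ):
                site_rows.append((tf, chrom, cand - _MOTIF_BP // 2, cand + _MOTIF_BP // 2,
                                  float(rng.normal(9.0, 1.5)), "", False))
                placed = True
                break
        if not placed:
            warnings.warn("decoy placement collision; decoy skipped")
    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end", "summit_offset"])
    sites = pd.DataFrame(
        site_rows,
        columns=["tf", "chrom", "start", "end", "motif_score", "true_target", "is_true"],
    )
    return true_edges, sites, peaks, targets


# ---------------------------------------------------------------------------
# chromatin tracks
# ---------------------------------------------------------------------------

def _window_bins(row, bin_bp, n_bins, window_up):
    if row.strand == "+":
        lo, hi = row.start - window_up, row.end
    else:
        lo, hi = row.start, row.end + window_up
    return max(lo // bin_bp, 0), min(-(-hi // bin_bp), n_bins)


def build_rate_multipliers(
    config: SyntheticConfig,
    genes: pd.DataFrame,
    mark_stage: dict[str, str],
    peaks: pd.DataFrame | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-stage, per-chrom (n_bins x 4) Poisson-rate multipliers.

    Linked genes get H3K4me3/H3K27ac (and ATAC) elevated over their window in
    their enriched stage; peaks get ATAC/H3K27ac elevated in both stages.
    """
    nb = config.n_bins_per_chrom
    mult = {st: {c: np.ones((nb, N_MARKS)) for c in config.chrom_names}
            for st in ("larva", "adult")}
    gene_by_id = genes.set_index("gene_id")
    i_atac, i_k4, i_k27ac = MARKS.index("ATAC"), MARKS.index("H3K4me3"), MARKS.index("H3K27ac")
    for g, st in mark_stage.items():
        row = gene_by_id.loc[g]
        b0, b1 = _window_bins(row, config.bin_size_bp, nb, 5000)
        for mi in (i_atac, i_k4, i_k27ac):
            mult[st][row.chrom][b0:b1, mi] *= config.mark_fold
    if peaks is not None:
        for p in peaks.itertuples(index=False):
            b0 = max(p.start // config.bin_size_bp, 0)
            b1 = min(-(-p.end // config.bin_size_bp), nb)
            for st in ("larva", "adult"):
                mult[st][p.chrom][b0:b1, i_atac] *= config.peak_atac_fold
                mult[st][p.chrom][b0:b1, i_k27ac] *= config.peak_k27ac_fold
    return mult


def sample_state_path(A: np.ndarray, pi: np.ndarray, n: int, rng) -> np.ndarray:
    """Sample one Markov-chain state path by inverse-CDF on uniform draws."""
    A = np.asarray(A, float)
    if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    path = np.empty(n, dtype=int)
    path[0] = rng.choice(len(pi), p=pi)
    u = rng.random(n)
    cdf = np.cumsum(A, axis=1)
    for t in range(1, n):
        path[t] = np.searchsorted(cdf[path[t - 1]], u[t])
    return path


def simulate_binary_hmm(
    emissions: np.ndarray,
    transitions: np.ndarray,
    n_sequences: int,
    seq_length: int,
    seed: int = 0,
):
    """Binary mark sequences from a planted product-Bernoulli HMM.

    Used for parameter-recovery and decoding-accuracy studies; returns
    ``(sequences, paths)`` with one (T, 4) binary array and one state path per
    sequence.
    """
    E = np.asarray(emissions, float)
    A = np.asarray(transitions, float)
    K = E.shape[0]
    rng = child_rng(seed, "binary-hmm")
    pi = np.full(K, 1.0 / K)
    seqs, paths = [], []
    for _ in range(n_sequences):
        path = sample_state_path(A, pi, seq_length, rng)
        obs = (rng.random((seq_length, E.shape[1])) < E[path]).astype(float)
        seqs.append(obs)
        paths.append(path)
    return seqs, paths


def sample_landscape(config: SyntheticConfig):
    """Latent chromatin landscape: one state path and mark-presence per chromosome."""
    rng = child_rng(config.seed, "chromatin")
    nb = config.n_bins_per_chrom
    K = config.n_states
    pi = np.full(K, 1.0 / K)
    landscape = {}
    for chrom in config.chrom_names:
        path = sample_state_path(config.state_transition_probs, pi, nb, rng)
        present = rng.random((nb, N_MARKS)) < config.state_emission_probs[path]
        landscape[chrom] = (path, present)
    return landscape


def simulate_chromatin(
    config: SyntheticConfig,
    multipliers: dict | None = None,
    n_replicates: int | None = None,
    landscape: dict | None = None,
):
    """Sample the latent chromatin landscape and per-mark Poisson bin counts.

    One state path and one per-bin mark-presence pattern are drawn per
    chromosome from the Markov chain and shared by both stages, so that every
    cross-stage signal difference is planted explicitly through the rate
    multipliers (and is therefore knowable truth).  Each stage and replicate
    then draws counts Poisson(signal rate) where the mark is present and
    Poisson(background rate) otherwise, times the stage's multiplier.  Returns
    ``(tracks, true_paths)`` where ``tracks[stage]`` has per-replicate count
    arrays and their merged (summed) track.
    """
    config.validate()
    if landscape is None:
        landscape = sample_landscape(config)
    rng = child_rng(config.seed, "chromatin-counts")
    n_rep = n_replicates if n_replicates is not None else config.n_replicates
    nb = config.n_bins_per_chrom
    lam0, lam1 = config.signal_rates
    base_rate: dict[str, np.ndarray] = {}
    paths: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        path, present = landscape[chrom]
        base_rate[chrom] = np.where(present, lam1, lam0)
        paths[chrom] = path
    tracks: dict[str, dict] = {}
    true_paths: dict[str, dict[str, np.ndarray]] = {}
    for stage in ("larva", "adult"):
        reps = [dict() for _ in range(n_rep)]
        merged: dict[str, np.ndarray] = {}
        for chrom in config.chrom_names:
            rate = base_rate[chrom]
            if multipliers is not None:
                rate = rate * multipliers[stage][chrom]
            total = np.zeros((nb, N_MARKS))
            for r in range(n_rep):
                c = rng.poisson(rate)
                reps[r][chrom] = c
                total += c
            merged[chrom] = total
        tracks[stage] = {"merged": merged, "replicates": reps}
        true_paths[stage] = paths
    return tracks, true_paths


def simulate_hires_atac(config: SyntheticConfig, peaks: pd.DataFrame, sites: pd.DataFrame):
    """10-bp-bin ATAC insertion track with peak enrichment and site footprints."""
    rng = child_rng(config.seed, "hires-atac")
    hb = config.hires_bin_bp
    n = config.chrom_length_bp // hb
    out: dict[str, dict[str, np.ndarray]] = {}
    base = {c: np.full(n, config.hires_background_rate) for c in config.chrom_names}
    for p in peaks.itertuples(index=False):
        base[p.chrom][p.start // hb: -(-p.end // hb)] = config.hires_peak_rate
    for s in sites.itertuples(index=False):
        if s.is_true:
            base[s.chrom][s.start // hb: -(-s.end // hb)] = config.footprint_center_rate
    for stage in ("larva", "adult"):
        out[stage] = {c: rng.poisson(base[c]).astype(float) for c in config.chrom_names}
    return out


# ---------------------------------------------------------------------------
# ortholog panel
# ---------------------------------------------------------------------------

def simulate_ortholog_panel(config: SyntheticConfig):
    """Species × stage × ortholog TPM panel with a planted most-similar stage.

    The reference species gets independent log-normal stage profiles.  Each
    other species' planted stage is the reference species' reference-stage
    profile perturbed by small multiplicative noise; its other stages are the
    same profile perturbed by large noise, so the planted stage is the nearest
    by construction.
    """
    config.validate()
    if len(config.panel_species) < 2 or len(config.panel_stages) < 2:
        raise ValueError("panel needs at least 2 species and 2 stages")
    if config.n_orthologs < 5:
        raise ValueError("panel needs at least 5 orthologs")
    rng = child_rng(config.seed, "panel")
    orth = [f"tf{i + 1:02d}" for i in range(config.n_orthologs)]
    stages = list(config.panel_stages)
    ref_sp = config.panel_reference_species
    ref_stage = config.panel_reference_stage
    if ref_sp not in config.panel_species or ref_stage not in stages:
        raise ValueError("reference species/stage missing from the panel configuration")
    ref_profiles = {
        st: np.exp(rng.normal(np.log(50.0), 1.0, size=config.n_orthologs)) for st in stages
    }
    rows = []
    true_similar: dict[str, str] = {}
    for sp in config.panel_species:
        if sp == ref_sp:
            for st in stages:
                for o, v in zip(orth, ref_profiles[st]):
                    rows.append((sp, st, o, v))
            continue
        planted = stages[int(rng.integers(0, len(stages)))]
        true_similar[sp] = planted
        for st in stages:
            scale = config.panel_noise_small if st == planted else config.panel_noise_large
            prof = ref_profiles[ref_stage] * np.exp(rng.normal(0.0, scale, size=config.n_orthologs))
            for o, v in zip(orth, prof):
                rows.append((sp, st, o, v))
    panel = pd.DataFrame(rows, columns=["species", "stage", "ortholog", "tpm"])
    return panel, true_similar


# ---------------------------------------------------------------------------
# gene ages
# ---------------------------------------------------------------------------

def simulate_gene_ages(config: SyntheticConfig, genes: pd.DataFrame) -> pd.DataFrame:
    rng = child_rng(config.seed, "gene-ages")
    nodes = [DEFAULT_TAXON_ORDER[int(rng.integers(0, len(DEFAULT_TAXON_ORDER)))]
             for _ in range(len(genes))]
    return pd.DataFrame({"gene_id": genes.gene_id, "origin_node": nodes})


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    stage_of_sample: dict
    tracks: dict
    hires_atac: dict
    peaks: pd.DataFrame
    motifs: pd.DataFrame
    paralogs: pd.DataFrame
    gene_ages: pd.DataFrame
    panel: pd.DataFrame
    taxon_order: list = field(default_factory=lambda: list(DEFAULT_TAXON_ORDER))
    manifest: dict = field(default_factory=dict)
    targets: list = field(default_factory=list)


def simulate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every pipeline input plus the ground-truth manifest."""
    config.validate()
    genes = simulate_genes(config)
    pairs, member_plan = plan_paralogs(config, genes)
    planted_lfc, mark_stage = plan_degs(config, genes, member_plan)
    landscape = sample_landscape(config)
    atac_closed = {c: ~pres[:, MARKS.index("ATAC")] for c, (path, pres) in landscape.items()}
    # chromatin-expression coupling: genes in closed domains are lowly expressed
    open_frac = {}
    nb = config.n_bins_per_chrom
    for row in genes.itertuples(index=False):
        lo, hi = _gene_domain(row)
        b0, b1 = max(lo // config.bin_size_bp, 0), min(-(-hi // config.bin_size_bp), nb)
        open_frac[row.gene_id] = 1.0 - float(atac_closed[row.chrom][b0:b1].mean())
    open_frac = pd.Series(open_frac)
    base_scale = open_frac.clip(lower=0.05)
    planted_set = set(planted_lfc.index[planted_lfc != 0])
    closed_pool = [
        g for g, tf in zip(genes.gene_id, genes.is_tf)
        if not tf and g not in planted_set and open_frac[g] <= 0.5
    ]
    true_edges, sites, peaks, targets = plan_network(
        config, genes, closed_bins=atac_closed, decoy_gene_pool=closed_pool or None,
        target_exclude=set(planted_lfc.index[planted_lfc != 0]),
    )
    participants = {tf for tf, _ in true_edges} | {t for _, t in true_edges} | set(
        genes.gene_id[genes.is_tf]
    )
    counts, lengths, stage_of_sample, true_deg = simulate_expression(
        config, genes, planted_lfc, expressed_genes=participants, base_scale=base_scale
    )
    mult = build_rate_multipliers(config, genes, mark_stage, peaks)
    tracks, true_paths = simulate_chromatin(config, multipliers=mult, landscape=landscape)
    hires = simulate_hires_atac(config, peaks, sites)
    panel, true_similar = simulate_ortholog_panel(config)
    ages = simulate_gene_ages(config, genes)
    manifest = {
        "seed": config.seed,
        "n_genes": len(genes),
        "n_tfs": int(genes.is_tf.sum()),
        "stages": ["larva", "adult"],
        "true_state_sequence": {
            st: {c: p.tolist() for c, p in true_paths[st].items()} for st in true_paths
        },
        "true_deg_table": {
            g: {"planted_lfc": float(r.planted_lfc), "true_class": r.true_class}
            for g, r in true_deg.iterrows()
        },
        "true_linked": {g: st for g, st in sorted(mark_stage.items())},
        "true_edges": [list(e) for e in true_edges],
        "true_site_indices": [int(i) for i in np.flatnonzero(sites.is_true.values)],
        "true_paralog_patterns": {
            f"{r.gene_a}|{r.gene_b}": r.true_pattern for r in pairs.itertuples(index=False)
        },
        "true_similar_stage": true_similar,
        "targets": list(targets),
    }
    motifs = sites[["tf", "chrom", "start", "end", "motif_score"]].copy()
    return SyntheticDataset(
        config=config, genes=genes, counts=counts, lengths=lengths,
        stage_of_sample=stage_of_sample, tracks=tracks, hires_atac=hires,
        peaks=peaks, motifs=motifs, paralogs=pairs[["gene_a", "gene_b", "duplication_node"]],
        gene_ages=ages, panel=panel, manifest=manifest, targets=list(targets),
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset in the pipeline's on-disk layout (plain text only)."""
    out = Path(outdir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    (out / "expr").mkdir(exist_ok=True)
    io.write_genes(ds.genes, out / "genes.tsv", out / "genes.gff3")
    ds.counts.rename_axis("gene_id").reset_index().to_csv(out / "expr" / "counts.tsv", sep="\t", index=False)
    ds.lengths.rename_axis("gene_id").reset_index().to_csv(out / "expr" / "lengths.tsv", sep="\t", index=False)
    bin_bp = ds.config.bin_size_bp
    for stage, tr in ds.tracks.items():
        for mi, mark in enumerate(MARKS):
            io.write_bedgraph(
                out / "tracks" / f"{stage}_{mark}.bedgraph",
                {c: v[:, mi] for c, v in tr["merged"].items()}, bin_bp,
            )
            for r, rep in enumerate(tr["replicates"], start=1):
                io.write_bedgraph(
                    out / "tracks" / f"{stage}_{mark}_rep{r}.bedgraph",
                    {c: v[:, mi] for c, v in rep.items()}, bin_bp,
                )
        io.write_bedgraph(
            out / "tracks" / f"{stage}_ATAC_hires.bedgraph",
            ds.hires_atac[stage], ds.config.hires_bin_bp,
        )
        io.write_peaks_bed(out / "peaks" / f"{stage}.bed", ds.peaks)
    io.write_table(ds.motifs, out / "motifs.tsv")
    io.write_table(ds.paralogs, out / "paralogs.tsv")
    io.write_table(ds.gene_ages, out / "gene_ages.tsv")
    io.write_table(ds.panel, out / "ortholog_panel.tsv")
    (out / "taxon_order.txt").write_text("\n".join(ds.taxon_order) + "\n")
    (out / "targets.txt").write_text("\n".join(ds.targets) + "\n")
    io.write_json(ds.manifest, out / "manifest.json")
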