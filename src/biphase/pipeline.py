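"""End-to-end pipeline: simulate → expression → chromstates → link → paralogs → grn → jsd.

Each stage reads its declared inputs from the run directory and writes its
declared outputs there; a stage whose outputs all exist is skipped, so runs
are idempotent and resumable.  ``provenance.json`` records the configuration
hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chromstate, expression, grn, io, jsd, linkage, paralogs, synthetic
from .config import CATEGORIES, MARKS, PipelineConfig

log = logging.getLogger("biphase")

STAGE_OUTPUTS = {
    "simulate": ["data/manifest.json", "data/genes.tsv", "data/expr/counts.tsv"],
    "expression": ["tpm.tsv", "de_results.tsv", "clusters.tsv"],
    "chromstates": ["model.json", "segmentation_larva.bed", "segmentation_adult.bed",
                    "gene_states.tsv", "transitions.tsv"],
    "link": ["annotation.tsv", "feature_changes.tsv", "linkage.tsv", "upset_membership.tsv"],
    "paralogs": ["paralog_classes.tsv", "divergence_summary.tsv"],
    "grn": ["grn_larva.tsv", "grn_adult.tsv", "summary.tsv"],
    "jsd": ["jsd_summary.tsv"],
}
STAGE_ORDER = list(STAGE_OUTPUTS)


def _chrom_lengths(cfg: PipelineConfig) -> dict[str, int]:
    syn = cfg.synthetic
    return {c: syn.chrom_length_bp for c in syn.chrom_names}


def _stage_done(rundir: Path, stage: str) -> bool:
    return all((rundir / p).exists() for p in STAGE_OUTPUTS[stage])


def _read_tracks(cfg: PipelineConfig, rundir: Path):
    """Merged and per-replicate binned tracks for both stages, from bedGraph."""
    lengths = _chrom_lengths(cfg)
    bin_bp = cfg.synthetic.bin_size_bp
    tracks = {}
    for stage in cfg.stages:
        merged = {c: np.zeros((lengths[c] // bin_bp, len(MARKS))) for c in lengths}
        reps = [
            {c: np.zeros((lengths[c] // bin_bp, len(MARKS))) for c in lengths}
            for _ in range(cfg.synthetic.n_replicates)
        ]
        for mi, mark in enumerate(MARKS):
            vals = io.read_bedgraph(
                rundir / "data" / "tracks" / f"{stage}_{mark}.bedgraph", bin_bp, lengths
            )
            for c, v in vals.items():
                merged[c][:, mi] = v
            for r in range(cfg.synthetic.n_replicates):
                vals = io.read_bedgraph(
                    rundir / "data" / "tracks" / f"{stage}_{mark}_rep{r + 1}.bedgraph",
                    bin_bp, lengths,
                )
                for c, v in vals.items():
                    reps[r][c][:, mi] = v
        tracks[stage] = {"merged": merged, "replicates": reps}
    return tracks


def _stage_of_sample(cfg: PipelineConfig, columns) -> dict:
    return {c: c.rsplit("_", 1)[0] for c in columns}


def run_simulate(cfg: PipelineConfig, rundir: Path) -> None:
    syn = cfg.synthetic
    syn.seed = cfg.seed
    ds = synthetic.simulate_all(syn)
    synthetic.write_dataset(ds, rundir / "data")


def run_expression(cfg: PipelineConfig, rundir: Path) -> None:
    counts = io.read_table(rundir / "data" / "expr" / "counts.tsv").set_index("gene_id")
    lengths = io.read_table(rundir / "data" / "expr" / "lengths.tsv").set_index("gene_id")[
        "effective_length_bp"]
    stage_of_sample = _stage_of_sample(cfg, counts.columns)
    tpm = expression.compute_tpm(counts, lengths)
    expressed = expression.filter_expressed(tpm, cfg.tpm_min)
    de = expression.differential_enrichment(
        counts.loc[expressed], stage_of_sample, contrast=("adult", "larva"),
        fdr_threshold=cfg.de_fdr, lfc_threshold=cfg.de_lfc,
    )
    k = min(cfg.k_clusters, max(2, len(expressed) // 10))
    clusters = expression.cluster_stage_profiles(
        tpm.loc[expressed], stage_of_sample, k=k, seed=cfg.seed
    )
    io.write_table(tpm.rename_axis("gene_id").reset_index(), rundir / "tpm.tsv")
    io.write_table(de.reset_index(), rundir / "de_results.tsv")
    io.write_table(
        clusters.labels.rename_axis("gene_id").reset_index(), rundir / "clusters.tsv"
    )


def run_chromstates(cfg: PipelineConfig, rundir: Path) -> None:
    tracks = _read_tracks(cfg, rundir)
    genes = io.read_genes(rundir / "data" / "genes.tsv")
    binarized = {
        stage: chromstate.binarize(tracks[stage]["merged"]) for stage in cfg.stages
    }
    model = chromstate.fit_hmm(binarized, k=cfg.hmm_k, seed=cfg.seed, max_iter=100)
    cat_map = chromstate.collapse_states(model.E)
    io.write_json(model.to_dict(), rundir / "model.json")
    gene_rows = {}
    seg_cats = {}
    for stage in cfg.stages:
        states = chromstate.decode_stage(model, binarized[stage])
        cats = chromstate.categories_per_bin(states, cat_map)
        seg_cats[stage] = cats
        bin_bp = cfg.synthetic.bin_size_bp
        with open(rundir / f"segmentation_{stage}.bed", "w") as fh:
            for chrom in sorted(states):
                s, c = states[chrom], cats[chrom]
                for b in range(s.size):
                    fh.write(f"{chrom}\t{b * bin_bp}\t{(b + 1) * bin_bp}\t"
                             f"{s[b] + 1}\t{CATEGORIES[c[b]]}\n")
        gene_rows[stage] = chromstate.assign_gene_category(
            cats, genes, bin_bp=bin_bp, window_up=cfg.window_up
        )
    gene_states = pd.DataFrame(gene_rows).rename_axis("gene_id")
    io.write_table(gene_states.reset_index(), rundir / "gene_states.tsv")
    trans = chromstate.category_transitions(
        gene_states[cfg.stages[0]], gene_states[cfg.stages[1]]
    )
    fwd = trans["forward"].rename_axis("from_category")
    io.write_table(fwd.reset_index(), rundir / "transitions.tsv")


def run_link(cfg: PipelineConfig, rundir: Path) -> None:
    tracks = _read_tracks(cfg, rundir)
    genes = io.read_genes(rundir / "data" / "genes.tsv")
    peaks = io.read_peaks_bed(rundir / "data" / "peaks" / "larva.bed")
    de = io.read_table(rundir / "de_results.tsv").set_index("gene_id")
    ann = linkage.annotate_regions(
        peaks.rename(columns={"peak_id": "region_id"}), genes,
        promoter=cfg.promoter, distal_max=cfg.distal_max,
        chrom_lengths=_chrom_lengths(cfg),
    )
    replicate_tracks = {st: tracks[st]["replicates"] for st in cfg.stages}
    changes = linkage.window_signal_change(
        replicate_tracks, genes, contrast=("adult", "larva"),
        bin_bp=cfg.synthetic.bin_size_bp, window_up=cfg.window_up,
        fdr_threshold=cfg.de_fdr, lfc_threshold=cfg.peak_lfc,
    )
    linked = linkage.link_enriched_genes(de, changes)
    io.write_table(ann, rundir / "annotation.tsv")
    io.write_table(changes, rundir / "feature_changes.tsv")
    io.write_table(linked, rundir / "linkage.tsv")
    io.write_table(linked[["gene_id", *MARKS]], rundir / "upset_membership.tsv")


def run_paralogs(cfg: PipelineConfig, rundir: Path) -> None:
    pairs = io.read_table(rundir / "data" / "paralogs.tsv")
    ages = io.read_table(rundir / "data" / "gene_ages.tsv")
    taxon_order = Path(rundir / "data" / "taxon_order.txt").read_text().splitlines()
    de = io.read_table(rundir / "de_results.tsv").set_index("gene_id")
    changes = io.read_table(rundir / "linkage.tsv")  # not used; changes table below
    changes = io.read_table(rundir / "feature_changes.tsv")
    spec = paralogs.classify_gene_regulatory_specialization(de, changes)
    classified = paralogs.classify_pairs(pairs, spec, de)
    node_buckets = paralogs.bucket_phylostrata(
        classified.rename(columns={"duplication_node": "origin_node"})[["origin_node"]],
        taxon_order,
    )
    classified["bucket"] = node_buckets["bucket"].values
    summary = paralogs.summarize_divergence(classified)
    io.write_table(classified, rundir / "paralog_classes.tsv")
    io.write_table(summary, rundir / "divergence_summary.tsv")
    ages_bucketed = paralogs.bucket_phylostrata(ages, taxon_order)
    io.write_table(ages_bucketed, rundir / "gene_age_buckets.tsv")


def run_grn(cfg: PipelineConfig, rundir: Path) -> None:
    genes = io.read_genes(rundir / "data" / "genes.tsv")
    motifs = io.read_table(rundir / "data" / "motifs.tsv")
    tpm = io.read_table(rundir / "tpm.tsv").set_index("gene_id")
    targets = Path(rundir / "data" / "targets.txt").read_text().split()
    lengths = _chrom_lengths(cfg)
    bin_bp = cfg.synthetic.bin_size_bp
    domains = grn.gene_domains(genes, promoter=cfg.promoter)
    grns = {}
    for stage in cfg.stages:
        seg = pd.read_csv(
            rundir / f"segmentation_{stage}.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "state", "category"],
        )
        cat_idx = {
            c: np.array([CATEGORIES.index(x) for x in sub.sort_values("start").category])
            for c, sub in seg.groupby("chrom")
        }
        peaks = io.read_peaks_bed(rundir / "data" / "peaks" / f"{stage}.bed")
        selected = grn.select_regulatory_peaks(peaks, cat_idx, bin_bp=bin_bp)
        # signal channel: only motif sites inside selected summit-centered peaks
        merged = {}
        for mark in ("ATAC", "H3K27ac"):
            merged[mark] = io.read_bedgraph(
                rundir / "data" / "tracks" / f"{stage}_{mark}.bedgraph", bin_bp, lengths
            )
        stage_cols = [c for c in tpm.columns if c.startswith(stage)]
        stage_tpm = tpm[stage_cols].mean(axis=1)
        stage_tpm = stage_tpm[stage_tpm > cfg.tpm_min]
        candidate_sites = grn.sites_in_peaks(motifs, selected)
        scored = grn.score_sites(candidate_sites, merged["ATAC"], merged["H3K27ac"], bin_bp=bin_bp)
        signal = grn.build_signal_network(scored, domains, stage_tpm, stage)
        signal = grn.filter_top_edges(signal, q=cfg.edge_quantile)
        # footprint channel
        hires = io.read_bedgraph(
            rundir / "data" / "tracks" / f"{stage}_ATAC_hires.bedgraph",
            cfg.synthetic.hires_bin_bp, lengths,
        )
        bound = grn.call_bound_sites(motifs, hires, cfg.synthetic.hires_bin_bp, seed=cfg.seed)
        footprint = grn.build_footprint_network(bound, domains, stage)
        combined = grn.combine_networks(signal, footprint, targets)
        grns[stage] = combined
        io.write_table(combined, rundir / f"grn_{stage}.tsv")
    summary = grn.network_summary(grns)
    rows = []
    for stage in cfg.stages:
        for tf, d in sorted(summary.outdegree[stage].items()):
            rows.append((stage, tf, d, summary.centrality_rank[stage][tf],
                         tf in summary.shared_tfs))
    io.write_table(
        pd.DataFrame(rows, columns=["stage", "tf", "outdegree", "centrality_rank", "shared"]),
        rundir / "summary.tsv",
    )


def run_jsd(cfg: PipelineConfig, rundir: Path) -> None:
    panel = io.read_table(rundir / "data" / "ortholog_panel.tsv")
    ref_sp = cfg.synthetic.panel_reference_species
    results = jsd.compare_species(panel, ref_sp, n_boot=cfg.n_boot, seed=cfg.seed)
    rows = []
    for sp, res in sorted(results.items()):
        for rs in res.mean.index:
            for os_ in res.mean.columns:
                arg, tie = res.argmin_stage[rs]
                rows.append((
                    ref_sp, sp, rs, os_,
                    res.mean.loc[rs, os_], res.sd.loc[rs, os_],
                    res.adjusted.loc[rs, os_], res.global_norm.loc[rs, os_],
                    res.relative.loc[rs, os_], arg, tie,
                ))
    io.write_table(
        pd.DataFrame(rows, columns=[
            "reference_species", "species", "reference_stage", "stage",
            "mean_jsd", "sd_jsd", "adjusted", "global_norm", "relative",
            "argmin_stage", "argmin_tie",
        ]),
        rundir / "jsd_summary.tsv",
    )


_RUNNERS = {
    "simulate": run_simulate, "expression": run_expression,
    "chromstates": run_chromstates, "link": run_link,
    "paralogs": run_paralogs, "grn": run_grn, "jsd": run_jsd,
}


def config_hash(cfg: PipelineConfig) -> str:
    d = cfg.to_dict()
    d.pop("outdir", None)  # the run's identity is its parameters, not its location
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Run the stages in order, resuming at the first stage with missing outputs.

    Everything downstream of an incomplete stage is recomputed, so deleting an
    intermediate invalidates its dependents but leaves earlier stages alone.
    """
    rundir = Path(cfg.outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    if force:
        first = 0
    else:
        first = next(
            (i for i, s in enumerate(STAGE_ORDER) if not _stage_done(rundir, s)),
            len(STAGE_ORDER),
        )
    for stage in STAGE_ORDER[:first]:
        log.info("stage %s: outputs present, skipping", stage)
    for stage in STAGE_ORDER[first:]:
        log.info("stage %s: running", stage)
        try:
            _RUNNERS[stage](cfg, rundir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    io.write_json(
        {"config_hash": config_hash(cfg), "seed": cfg.seed,
         "version": __version__, "stages_run": STAGE_ORDER},
        rundir / "provenance.json",
    )
    return rundir
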