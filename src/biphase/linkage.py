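"""Gene↔chromatin-feature linkage.

Regions are annotated to genomic features with the precedence
promoter > genic > distal > none, where the promoter spans −2,000..+500 bp of
the TSS (transcription-oriented), genic runs from +500 bp of the TSS to the
TES, distal covers everything within 100 kb of the nearest gene, and regions
farther away carry no annotation.

Differential chromatin signal is called per gene window (−5 kb..TES): bin
counts are summed per replicate, the window × sample matrix is TMM-normalized
and tested with the same Welch/BH machinery as expression, at the
differential-peak thresholds FDR < 0.05 and |log2FC| > 0.  Stage-enriched
genes are then linked to concordant feature changes: an active feature
(ATAC, H3K4me3, H3K27ac) significantly higher in the gene's enriched stage,
or H3K27me3 significantly higher in the opposite stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import MARKS
from .expression import differential_enrichment

ACTIVE_MARKS = ("ATAC", "H3K4me3", "H3K27ac")
REPRESSIVE_MARK = "H3K27me3"


# ---------------------------------------------------------------------------
# strand-aware gene geometry
# ---------------------------------------------------------------------------

def promoter_interval(row, promoter=(-2000, 500)) -> tuple[int, int]:
    up, down = -promoter[0], promoter[1]
    if row.strand == "+":
        return row.start - up, row.start + down
    return row.end - down, row.end + up


def genic_interval(row, promoter=(-2000, 500)) -> tuple[int, int]:
    """From +500 bp of the TSS to the TES; may be empty for very short genes."""
    down = promoter[1]
    if row.strand == "+":
        return min(row.start + down, row.end), row.end
    return row.start, max(row.end - down, row.start)


def gene_window(row, window_up: int = 5000) -> tuple[int, int]:
    if row.strand == "+":
        return row.start - window_up, row.end
    return row.start, row.end + window_up


def _tss(row) -> int:
    return row.start if row.strand == "+" else row.end


# ---------------------------------------------------------------------------
# region annotation
# ---------------------------------------------------------------------------

def annotate_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter=(-2000, 500),
    distal_max: int = 100_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Assign each region to promoter/genic/distal/none with gene and distance.

    Precedence: a region overlapping any promoter window is ``promoter``
    (ties between overlapping promoters go to the gene with the nearer TSS);
    otherwise any genic overlap makes it ``genic``; otherwise it is ``distal``
    if within ``distal_max`` of the nearest gene and ``none`` beyond that.
    """
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    records = []
    for idx, region in enumerate(regions.itertuples(index=False)):
        start, end = int(region.start), int(region.end)
        if chrom_lengths is not None and region.chrom in chrom_lengths:
            clipped = (max(start, 0), min(end, chrom_lengths[region.chrom]))
            if clipped != (start, end):
                warnings.warn(f"region {idx} clipped to chromosome bounds")
                start, end = clipped
        region_id = getattr(region, "region_id", idx)
        g = by_chrom.get(region.chrom)
        if g is None or len(g) == 0:
            records.append((region_id, "none", "", np.inf))
            continue
        feature, gene_id, best_dist = "none", "", np.inf
        # promoter, tie-broken by TSS distance
        prom_hits = []
        for row in g.itertuples(index=False):
            p0, p1 = promoter_interval(row, promoter)
            if start < p1 and p0 < end:
                center = (start + end) / 2.0
                prom_hits.append((abs(_tss(row) - center), row.gene_id))
        if prom_hits:
            prom_hits.sort()
            feature, gene_id, best_dist = "promoter", prom_hits[0][1], 0.0
        else:
            genic_hits = []
            for row in g.itertuples(index=False):
                g0, g1 = genic_interval(row, promoter)
                if start < g1 and g0 < end:
                    center = (start + end) / 2.0
                    genic_hits.append((abs(_tss(row) - center), row.gene_id))
            if genic_hits:
                genic_hits.sort()
                feature, gene_id, best_dist = "genic", genic_hits[0][1], 0.0
            else:
                # distance to the nearest gene boundary
                dists = []
                for row in g.itertuples(index=False):
                    if start < row.end and row.start < end:
                        d = 0
                    elif end <= row.start:
                        d = row.start - end
                    else:
                        d = start - row.end
                    dists.append((d, row.gene_id))
                dists.sort()
                best_dist, gene_id = dists[0]
                feature = "distal" if best_dist <= distal_max else "none"
                if feature == "none":
                    gene_id = ""
        records.append((region_id, feature, gene_id, float(best_dist)))
    return pd.DataFrame(records, columns=["region_id", "feature", "nearest_gene", "distance_bp"])


# ---------------------------------------------------------------------------
# window-level differential signal
# ---------------------------------------------------------------------------

def window_counts(
    replicate_tracks: dict[str, list[dict[str, np.ndarray]]],
    genes: pd.DataFrame,
    mark: str,
    bin_bp: int = 200,
    window_up: int = 5000,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene window count matrix (genes × stage replicates) for one mark.

    ``replicate_tracks[stage]`` is a list of per-replicate
    ``{chrom: (n_bins, 4)}`` count arrays.
    """
    mi = MARKS.index(mark)
    cols, stage_of_sample = {}, {}
    for stage, reps in replicate_tracks.items():
        for r, rep in enumerate(reps, start=1):
            vals = []
            for row in genes.itertuples(index=False):
                arr = rep[row.chrom]
                n_bins = arr.shape[0]
                lo, hi = gene_window(row, window_up)
                b0 = max(lo // bin_bp, 0)
                b1 = min(-(-hi // bin_bp), n_bins)
                vals.append(arr[b0:b1, mi].sum())
            name = f"{stage}_rep{r}"
            cols[name] = np.asarray(vals)
            stage_of_sample[name] = stage
    counts = pd.DataFrame(cols, index=pd.Index(genes.gene_id, name="gene_id"))
    return counts, stage_of_sample


def window_signal_change(
    replicate_tracks: dict[str, list[dict[str, np.ndarray]]],
    genes: pd.DataFrame,
    contrast: tuple[str, str] = ("adult", "larva"),
    bin_bp: int = 200,
    window_up: int = 5000,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Differential window signal per gene and mark at the peak thresholds.

    Returns a long table (gene_id, mark, log2fc, fdr, significant, not_tested);
    ``significant`` means fdr < 0.05 and |log2fc| > 0.
    """
    frames = []
    for mark in MARKS:
        counts, stage_of_sample = window_counts(
            replicate_tracks, genes, mark, bin_bp, window_up
        )
        all_zero = (counts.sum(axis=1) == 0)
        de = differential_enrichment(
            counts, stage_of_sample, contrast=contrast,
            fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold,
        )
        sig = (de.fdr < fdr_threshold) & (de.log2fc.abs() > lfc_threshold) & ~all_zero
        frames.append(pd.DataFrame({
            "gene_id": de.index, "mark": mark, "log2fc": de.log2fc.values,
            "fdr": de.fdr.values, "significant": sig.values,
            "not_tested": all_zero.values,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# linkage of enriched genes to concordant feature changes
# ---------------------------------------------------------------------------

def link_enriched_genes(
    de_results: pd.DataFrame,
    changes: pd.DataFrame,
    contrast: tuple[str, str] = ("adult", "larva"),
) -> pd.DataFrame:
    """Concordance of stage-enriched genes with chromatin-feature changes.

    A gene enriched in stage S is concordant if at least one active feature
    is significantly higher in S, or the repressive mark is significantly
    higher in the opposite stage.  ``log2fc`` in ``changes`` is oriented as
    first contrast stage over second.  Output has one row per enriched gene
    with per-feature membership flags and a linkage status in
    {active, repressive_only, unlinked}.
    """
    hi, lo = contrast
    wide_lfc = changes.pivot(index="gene_id", columns="mark", values="log2fc")
    wide_sig = changes.pivot(index="gene_id", columns="mark", values="significant")
    rows = []
    enriched = de_results[de_results.enriched_class != "not_significant"]
    for gene, rec in enriched.iterrows():
        stage = rec.enriched_class.removesuffix("_enriched")
        sign = 1.0 if stage == hi else -1.0
        membership = {}
        if gene not in wide_lfc.index:
            rows.append({"gene_id": gene, "enriched_class": rec.enriched_class,
                         **{m: False for m in MARKS}, "linkage": "unlinked",
                         "missing_changes": True})
            continue
        for m in ACTIVE_MARKS:
            membership[m] = bool(wide_sig.loc[gene, m]) and sign * wide_lfc.loc[gene, m] > 0
        membership[REPRESSIVE_MARK] = (
            bool(wide_sig.loc[gene, REPRESSIVE_MARK])
            and sign * wide_lfc.loc[gene, REPRESSIVE_MARK] < 0
        )
        if any(membership[m] for m in ACTIVE_MARKS):
            status = "active"
        elif membership[REPRESSIVE_MARK]:
            status = "repressive_only"
        else:
            status = "unlinked"
        rows.append({"gene_id": gene, "enriched_class": rec.enriched_class,
                     **membership, "linkage": status, "missing_changes": False})
    cols = ["gene_id", "enriched_class", *MARKS, "linkage", "missing_changes"]
    return pd.DataFrame(rows, columns=cols)


def linkage_summary(linkage: pd.DataFrame) -> pd.Series:
    """Fractions of enriched genes linked via active marks, repression only, or not."""
    n = len(linkage)
    if n == 0:
        return pd.Series(dtype=float)
    return linkage.linkage.value_counts(normalize=True).reindex(
        ["active", "repressive_only", "unlinked"], fill_value=0.0
    )


def expression_mark_correlation(
    de_results: pd.DataFrame, changes: pd.DataFrame, mark: str
) -> tuple[float, float]:
    """Pearson correlation of expression log2FC with one mark's window log2FC."""
    mc = changes[changes["mark"] == mark].set_index("gene_id")
    common = de_results.index.intersection(mc.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genes with both values")
    x = de_results.loc[common, "log2fc"].values
    y = mc.loc[common, "log2fc"].values
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
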