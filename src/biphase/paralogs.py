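"""Paralog regulatory-divergence classification and phylostratum bucketing.

A gene is regulatory-specialized for a stage when it is both expression-
enriched in that stage and carries significantly stronger active histone
marks (H3K4me3 or H3K27ac, direction-consistent) there.  A paralog pair is
then classified by how many members are specialized:

* ``no_divergence`` — neither member specialized;
* ``one_sided`` — exactly one member specialized;
* ``both_sided`` — both members specialized (typically reciprocally).

Gene and duplication ages arrive as tables; the phylostratum bucket is
``pre_mollusca`` when the origin node ranks at or before the Lophotrochozoa
ancestor in the supplied root-first taxon ordering, ``mollusca_plus``
otherwise.
"""

from __future__ import annotations

import pandas as pd

ACTIVE_HISTONE_MARKS = ("H3K4me3", "H3K27ac")
PATTERNS = ("no_divergence", "one_sided", "both_sided")


def classify_gene_regulatory_specialization(
    de_results: pd.DataFrame,
    changes: pd.DataFrame,
    contrast: tuple[str, str] = ("adult", "larva"),
    require_both_marks: bool = False,
) -> pd.Series:
    """Per-gene specialization in {larva, adult, none}.

    Specialized for a stage iff expression-enriched there AND at least one
    (or, in strict mode, both) of H3K4me3/H3K27ac is significantly higher in
    the same stage.  Genes missing either record are ``none``.
    """
    hi, lo = contrast
    mk = changes[changes["mark"].isin(ACTIVE_HISTONE_MARKS)]
    sig_hi = mk.pivot(index="gene_id", columns="mark", values="significant") & (
        mk.pivot(index="gene_id", columns="mark", values="log2fc") > 0
    )
    sig_lo = mk.pivot(index="gene_id", columns="mark", values="significant") & (
        mk.pivot(index="gene_id", columns="mark", values="log2fc") < 0
    )
    agg = "all" if require_both_marks else "any"
    out = {}
    for gene, rec in de_results.iterrows():
        if gene not in sig_hi.index:
            out[gene] = "none"
            continue
        marks_hi = getattr(sig_hi.loc[gene], agg)()
        marks_lo = getattr(sig_lo.loc[gene], agg)()
        if rec.enriched_class == f"{hi}_enriched" and marks_hi:
            out[gene] = hi
        elif rec.enriched_class == f"{lo}_enriched" and marks_lo:
            out[gene] = lo
        else:
            out[gene] = "none"
    return pd.Series(out, name="reg_specialized")


def classify_pair(spec_a: str, spec_b: str) -> str:
    """Divergence pattern from the two members' specializations (symmetric)."""
    n = int(spec_a != "none") + int(spec_b != "none")
    return PATTERNS[n]


def classify_pairs(
    pairs: pd.DataFrame, specialization: pd.Series, de_results: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Classify every pair; optionally flag functional (expression) divergence."""
    out = pairs.copy()
    spec_a = specialization.reindex(out.gene_a).fillna("none").values
    spec_b = specialization.reindex(out.gene_b).fillna("none").values
    out["reg_specialized_a"] = spec_a
    out["reg_specialized_b"] = spec_b
    out["divergence_pattern"] = [classify_pair(a, b) for a, b in zip(spec_a, spec_b)]
    if de_results is not None:
        cls = de_results["enriched_class"]
        out["functionally_diverged"] = (
            cls.reindex(out.gene_a).fillna("not_significant").values
            != cls.reindex(out.gene_b).fillna("not_significant").values
        )
    return out


def bucket_phylostrata(
    origins: pd.DataFrame,
    taxon_order: list[str],
    boundary: str = "Lophotrochozoa",
) -> pd.DataFrame:
    """Bucket each entry as pre_mollusca / mollusca_plus by origin-node rank."""
    if boundary not in taxon_order:
        raise ValueError(f"boundary node {boundary!r} missing from taxon ordering")
    rank = {node: i for i, node in enumerate(taxon_order)}
    unknown = sorted(set(origins["origin_node"]) - set(rank))
    if unknown:
        raise ValueError(f"unknown origin nodes: {unknown}")
    cut = rank[boundary]
    out = origins.copy()
    out["bucket"] = [
        "pre_mollusca" if rank[n] <= cut else "mollusca_plus" for n in origins["origin_node"]
    ]
    return out


def summarize_divergence(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pattern fractions, overall and per duplication bucket if present."""
    if len(pairs) == 0:
        return pd.DataFrame(columns=["group", "pattern", "count", "fraction"])
    rows = []

    def _add(group, sub):
        counts = sub["divergence_pattern"].value_counts().reindex(PATTERNS, fill_value=0)
        total = counts.sum()
        for pat, c in counts.items():
            rows.append((group, pat, int(c), c / total if total else 0.0))

    _add("all", pairs)
    if "bucket" in pairs.columns:
        for bucket, sub in pairs.groupby("bucket"):
            _add(bucket, sub)
    return pd.DataFrame(rows, columns=["group", "pattern", "count", "fraction"])
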