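"""Plain-text readers and writers for the pipeline's file formats.

All coordinates are 0-based, half-open on disk for BED/bedGraph; GFF3 is
converted to its native 1-based, closed convention on write.  Binned signal
tracks are stored as run-length-merged bedGraph and expanded back onto the
fixed bin grid on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "is_tf"]


def write_genes(genes: pd.DataFrame, tsv_path, gff3_path=None) -> None:
    genes[GENE_COLUMNS].to_csv(tsv_path, sep="\t", index=False)
    if gff3_path is not None:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in genes.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\tbiphase\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene_id}\n"
                )


def read_genes(tsv_path) -> pd.DataFrame:
    genes = pd.read_csv(tsv_path, sep="\t")
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return genes


def write_bedgraph(path, values_by_chrom: dict[str, np.ndarray], bin_bp: int) -> None:
    """Write per-bin values, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom, vals in values_by_chrom.items():
            vals = np.asarray(vals)
            if vals.size == 0:
                continue
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                v_str = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{s * bin_bp}\t{e * bin_bp}\t{v_str}\n")


def read_bedgraph(path, bin_bp: int, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph onto the fixed bin grid; uncovered bins are 0."""
    out = {c: np.zeros(length // bin_bp) for c, length in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom not in out:
            raise ValueError(f"unknown chromosome {row.chrom!r} in {path}")
        if row.start % bin_bp or row.end % bin_bp:
            raise ValueError(f"interval [{row.start},{row.end}) not aligned to {bin_bp}-bp bins")
        out[row.chrom][row.start // bin_bp: row.end // bin_bp] = row.value
    return out


def write_peaks_bed(path, peaks: pd.DataFrame) -> None:
    """BED6+1: name/score/strand placeholders, column 7 = summit offset from start."""
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            name = getattr(row, "peak_id", f"peak{i + 1}")
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t.\t{row.summit_offset}\n"
            )


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id", "score", "strand", "summit_offset"],
    )
    return df[["peak_id", "chrom", "start", "end", "summit_offset"]]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
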