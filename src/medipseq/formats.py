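"""Readers/writers for the text formats the pipeline exchanges.

Internal coordinates are 0-based half-open; GFF3 is 1-based inclusive and
the conversion happens only at this boundary (``start + 1`` on write,
``start - 1`` on read). BED is 0-based half-open like the internal
convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fragments import FRAGMENT_COLUMNS, FragmentSet
from .genome import ANNOTATION_COLUMNS, GenomeSpec
from .track import MethylomeTrack
from .windows import WindowGrid


class FormatError(ValueError):
    """Malformed record, reported with its line number."""


# ---------------------------------------------------------------------------
# fragments: BED6 + sidecar duplicate flags


def write_fragments_bed(frags: FragmentSet, bed_path, flags_path) -> None:
    rec = frags.records
    bed = pd.DataFrame(
        {
            "chrom": rec.chrom,
            "start": rec.start,
            "end": rec.end,
            "name": [f"{frags.sample_id}_{i}" for i in range(len(rec))],
            "score": rec.mapq,
            "strand": rec.strand,
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    pd.DataFrame({"name": bed.name, "is_duplicate": rec.is_duplicate.astype(int)}).to_csv(
        flags_path, sep="\t", index=False
    )


def read_fragments_bed(bed_path, flags_path, sample_id: str) -> FragmentSet:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    _check_intervals(bed, bed_path)
    flags = pd.read_csv(flags_path, sep="\t").set_index("name")["is_duplicate"]
    rec = pd.DataFrame(
        {
            "chrom": bed.chrom,
            "start": bed.start.astype(np.int64),
            "end": bed.end.astype(np.int64),
            "strand": bed.strand,
            "mapq": bed.score.astype(np.int64),
            "is_duplicate": flags.reindex(bed.name).fillna(0).astype(bool).to_numpy(),
        },
        columns=FRAGMENT_COLUMNS,
    )
    return FragmentSet(sample_id, rec)


def _check_intervals(df: pd.DataFrame, path) -> None:
    bad = df.index[(df.start < 0) | (df.end <= df.start)]
    if len(bad):
        raise FormatError(f"{path}: malformed interval at line {bad[0] + 1}")


# ---------------------------------------------------------------------------
# annotations: BED (id|class|family in the name column) and GFF3


def write_annotations_bed(genome: GenomeSpec, path) -> None:
    ann = genome.annotations
    name = ann.feature_id + "|" + ann.feature_class + "|" + ann.family.fillna(".")
    pd.DataFrame(
        {
            "chrom": ann.chrom,
            "start": ann.start,
            "end": ann.end,
            "name": name,
            "score": 0,
            "strand": ann.strand.replace({None: "."}),
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_annotations_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    _check_intervals(bed, path)
    parts = bed.name.str.split("|", expand=True)
    fam = parts[2].mask(parts[2] == ".") if parts.shape[1] > 2 else np.nan
    return pd.DataFrame(
        {
            "chrom": bed.chrom,
            "start": bed.start.astype(np.int64),
            "end": bed.end.astype(np.int64),
            "feature_class": parts[1],
            "feature_id": parts[0],
            "strand": bed.strand,
            "family": fam,
        },
        columns=ANNOTATION_COLUMNS,
    )


def write_annotations_gff3(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for row in genome.annotations.itertuples():
            attrs = f"ID={row.feature_id}"
            if isinstance(row.family, str):
                attrs += f";family={row.family}"
            strand = row.strand if row.strand in ("+", "-") else "."
            fh.write(
                f"{row.chrom}\tmedipseq\t{row.feature_class}\t{row.start + 1}\t{row.end}"
                f"\t.\t{strand}\t.\t{attrs}\n"
            )


def read_annotations_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns at line {ln}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}: bad coordinates at line {ln}") from exc
            if start_i < 0 or end_i <= start_i:
                raise FormatError(f"{path}: malformed interval at line {ln}")
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            rows.append(
                (chrom, start_i, end_i, ftype, attr_map.get("ID", f"line{ln}"),
                 strand, attr_map.get("family", np.nan))
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# CpG table and expression matrix


def write_cpg_table(genome: GenomeSpec, path) -> None:
    rows = [
        pd.DataFrame({"chrom": chrom, "pos": pos})
        for chrom, pos in genome.cpg_positions.items()
    ]
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_cpg_table(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        chrom: np.sort(sub.pos.to_numpy(dtype=np.int64))
        for chrom, sub in df.groupby("chrom", sort=False)
    }


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# methylome tracks: GFF3 (one record per callable window) and bedGraph


def write_track_gff3(track: MethylomeTrack, path) -> None:
    """Per-sample GFF3: one record per callable 100-bp window, score =
    methylation; coordinates 1-based inclusive."""
    grid = track.grid
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in grid.chroms:
            off, n = grid.offset(chrom), grid.n_windows(chrom)
            starts = grid.starts(chrom)
            for i in range(n):
                s = track.score[off + i]
                if np.isnan(s):
                    continue
                fh.write(
                    f"{chrom}\tmedipseq\tmethylation_window\t{starts[i] + 1}"
                    f"\t{starts[i] + grid.size}\t{s:.4f}\t.\t.\t"
                    f"ID={chrom}:{starts[i]};ci_half={track.ci_half[off + i]:.4f};"
                    f"coverage={track.coverage[off + i]}\n"
                )


def read_track_gff3(path, grid: WindowGrid, sample_id: str) -> MethylomeTrack:
    score = np.full(grid.total_windows, np.nan)
    ci = np.full(grid.total_windows, np.nan)
    cov = np.zeros(grid.total_windows, dtype=np.int64)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns at line {ln}")
            chrom, _, _, start, _, sc, _, _, attrs = parts
            idx = grid.offset(chrom) + (int(start) - 1) // grid.size
            score[idx] = float(sc)
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            ci[idx] = float(attr_map.get("ci_half", "nan"))
            cov[idx] = int(attr_map.get("coverage", 0))
    return MethylomeTrack(sample_id, grid, score, ci, cov)


def write_track_bedgraph(track: MethylomeTrack, path) -> None:
    grid = track.grid
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample_id} methylation"\n')
        for chrom in grid.chroms:
            off, n = grid.offset(chrom), grid.n_windows(chrom)
            starts = grid.starts(chrom)
            for i in range(n):
                s = track.score[off + i]
                if np.isnan(s):
                    continue
                fh.write(f"{chrom}\t{starts[i]}\t{starts[i] + grid.size}\t{s:.4f}\n")
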