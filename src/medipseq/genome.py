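"""Toy genome model: chromosome sizes, CpG positions and feature annotations.

The generator lays out a small multi-chromosome genome with the structural
ingredients a MeDIP-seq methylome analysis cares about: genes (one promoter
and one gene body each), CpG islands (CGIs) that are several-fold denser in
CpGs than the chromosomal background, CGI shores, and interspersed/tandem
repeats of four classes (SINE, LINE, LTR, satellite) with named families.
No nucleotide sequence is simulated; CpGs are represented as positions only.

Coordinates are 0-based half-open throughout; 1-based inclusive coordinates
appear only at the GFF3 boundary (see :mod:`medipseq.formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import WindowGrid

FEATURE_CLASSES = (
    "promoter",
    "gene_body",
    "cgi",
    "cgi_shore",
    "SINE",
    "LINE",
    "LTR",
    "satellite",
)
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "satellite")

_REPEAT_FAMILIES = {
    "SINE": (("AluJb", 0.3), ("AluSx", 0.3), ("AluY", 0.2), ("MIR", 0.2)),
    "LINE": (("L1", 0.65), ("L2", 0.35)),
    "LTR": (("ERVL", 0.5), ("ERV1", 0.5)),
    "satellite": (("ALR", 0.6), ("SAR", 0.4)),
}
_REPEAT_LENGTHS = {
    "SINE": (250, 350),
    "LINE": (800, 2000),
    "LTR": (400, 700),
    "satellite": (500, 1500),
}

ANNOTATION_COLUMNS = ["chrom", "start", "end", "feature_class", "feature_id", "strand", "family"]


class SizingError(ValueError):
    """Requested features cannot be placed without disallowed overlap."""


@dataclass
class GenomeSpec:
    """A toy genome: chromosome lengths, CpG positions and annotations.

    Attributes
    ----------
    chrom_lengths : dict
        Chromosome name -> length in bp.
    cpg_positions : dict
        Chromosome name -> sorted, strictly increasing 0-based CpG positions.
    annotations : pandas.DataFrame
        One row per feature with columns ``chrom, start, end, feature_class,
        feature_id, strand, family``; intervals are half-open ``[start, end)``.
    tss : pandas.DataFrame
        One row per gene: ``gene_id, chrom, pos, strand`` (0-based TSS).
    """

    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    annotations: pd.DataFrame
    tss: pd.DataFrame
    grid: WindowGrid = field(init=False, repr=False)

    def __post_init__(self):
        self.grid = WindowGrid(self.chrom_lengths)

    def features(self, feature_class: str | None = None) -> pd.DataFrame:
        ann = self.annotations
        return ann if feature_class is None else ann[ann.feature_class == feature_class]

    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())

    def cpg_count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.cpg_positions[chrom]
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def background_cpg_density(self, chrom: str) -> float:
        """CpGs per bp outside annotated CGIs on this chromosome."""
        cgis = self.features("cgi")
        cgis = cgis[cgis.chrom == chrom]
        in_cgi = sum(self.cpg_count_in(chrom, s, e) for s, e in zip(cgis.start, cgis.end))
        cgi_bp = int((cgis.end - cgis.start).sum())
        rest = self.chrom_lengths[chrom] - cgi_bp
        return (len(self.cpg_positions[chrom]) - in_cgi) / max(rest, 1)

    def validate(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            pos = self.cpg_positions.get(chrom, np.empty(0, dtype=np.int64))
            if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] >= length):
                raise ValueError(f"CpG positions on {chrom} not strictly increasing in-bounds")
        ann = self.annotations
        for _, row in ann.iterrows():
            if not (0 <= row.start < row.end <= self.chrom_lengths[row.chrom]):
                raise ValueError(f"feature {row.feature_id} out of bounds")
            if row.feature_class not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {row.feature_class!r}")
        for cls in ("promoter", "gene_body"):
            per_gene = ann[ann.feature_class == cls].feature_id.str.replace(f"{cls}:", "")
            if per_gene.duplicated().any():
                raise ValueError(f"duplicate {cls} records")
            if set(per_gene) != set(self.tss.gene_id):
                raise ValueError(f"every gene needs exactly one {cls}")
        for _, cgi in ann[ann.feature_class == "cgi"].iterrows():
            dens = self.cpg_count_in(cgi.chrom, cgi.start, cgi.end) / (cgi.end - cgi.start)
            if dens < 4 * self.background_cpg_density(cgi.chrom):
                raise ValueError(f"CGI {cgi.feature_id} below 4x background CpG density")


def _place_nonoverlapping(rng, length, occupied, span, tries=400):
    """Uniform start for an interval of ``span`` bp avoiding ``occupied``
    (sorted list of (start, end)); returns None when no slot is found."""
    for _ in range(tries):
        s = int(rng.integers(0, length - span))
        e = s + span
        if all(e <= os or s >= oe for os, oe in occupied):
            return s
    return None


def _place_within(rng, host_start, host_end, span):
    if host_end - host_start <= span:
        return None
    return int(rng.integers(host_start, host_end - span))


def generate_genome(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 500_000,
    n_genes: int = 50,
    n_repeats_per_class: int = 40,
    *,
    background_cpg_rate: float = 0.01,
    cgi_density_fold: float = 8.0,
    shore_mode: str = "flanks",
) -> GenomeSpec:
    """Generate a deterministic toy genome.

    Parameters
    ----------
    seed
        Seed for the generator; the output is a pure function of the inputs.
    n_chroms, chrom_length
        Number and size (>= 100 kb) of chromosomes.
    n_genes
        Total genes across the genome; each gets a 1-kb promoter upstream of
        its TSS and a 3-8 kb gene body, and one associated CGI (placed at the
        promoter for ~60 % of genes, intragenic for ~25 %, intergenic else).
    n_repeats_per_class
        Total repeats per class across the genome. SINEs are preferentially
        intragenic (nested in gene bodies), LINEs/LTRs/satellites mostly
        intergenic, mirroring their genomic distribution.
    background_cpg_rate
        Background CpGs per bp (clustered placement, ~1 per 100 bp default).
    cgi_density_fold
        Nominal CGI CpG density as a multiple of background (floor 4.5x).
    shore_mode
        ``"flanks"`` (default): shores are the 2-kb flanks on both sides of
        each CGI. ``"tss_upstream"``: one shore per gene covering the 2 kb
        upstream of the TSS.
    """
    if chrom_length < 100_000:
        raise SizingError("chrom_length must be >= 100 kb")
    if n_chroms < 1:
        raise SizingError("need at least one chromosome")
    if n_genes < 0 or n_repeats_per_class < 0:
        raise SizingError("counts must be non-negative")
    if shore_mode not in ("flanks", "tss_upstream"):
        raise ValueError(f"unknown shore_mode {shore_mode!r}")

    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: int(chrom_length) for c in chroms}

    genes_per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    rep_per_chrom = {
        cls: [n_repeats_per_class // n_chroms + (1 if i < n_repeats_per_class % n_chroms else 0) for i in range(n_chroms)]
        for cls in REPEAT_CLASSES
    }

    records: list[tuple] = []
    tss_rows: list[tuple] = []
    cpg_positions: dict[str, np.ndarray] = {}
    gene_counter = 0
    cgi_counter = 0
    rep_counter = {cls: 0 for cls in REPEAT_CLASSES}

    for ci, chrom in enumerate(chroms):
        length = chrom_lengths[chrom]
        margin = 5_000
        ng = genes_per_chrom[ci]
        body_lens = rng.integers(3_000, 8_001, size=ng) if ng else np.empty(0, dtype=int)
        slot_lens = body_lens + 1_000
        min_gap = 800
        needed = int(slot_lens.sum() + (ng + 1) * min_gap + 2 * margin)
        if needed > length:
            raise SizingError(
                f"{ng} genes need {needed} bp but {chrom} has {length}; "
                "reduce n_genes or increase chrom_length"
            )
        slack = length - needed
        shares = rng.dirichlet(np.ones(ng + 1)) * slack if ng else np.array([slack])
        gaps = (shares + min_gap).astype(int)

        occupied: list[tuple[int, int]] = []  # gene spans + CGIs + repeats
        gene_spans: list[tuple[int, int]] = []
        cursor = margin
        genes_here: list[str] = []
        for gi in range(ng):
            cursor += gaps[gi]
            gene_id = f"g{gene_counter:03d}"
            gene_counter += 1
            genes_here.append(gene_id)
            strand = "+" if (gene_counter % 2) else "-"
            blen = int(body_lens[gi])
            if strand == "+":
                prom = (cursor, cursor + 1_000)
                body = (cursor + 1_000, cursor + 1_000 + blen)
                tss = body[0]
            else:
                body = (cursor, cursor + blen)
                prom = (cursor + blen, cursor + blen + 1_000)
                tss = body[1] - 1
            records.append((chrom, prom[0], prom[1], "promoter", f"promoter:{gene_id}", strand, None))
            records.append((chrom, body[0], body[1], "gene_body", f"gene_body:{gene_id}", strand, None))
            tss_rows.append((gene_id, chrom, int(tss), strand))
            span = (min(prom[0], body[0]), max(prom[1], body[1]))
            occupied.append(span)
            gene_spans.append(body)
            cursor = span[1]

        # --- CGIs: one per gene plus two intergenic extras per chromosome
        cgi_intervals: list[tuple[int, int, str]] = []
        for gene_id in genes_here:
            g_tss = next(t for t in tss_rows if t[0] == gene_id)
            body = next(
                (r[1], r[2]) for r in records if r[4] == f"gene_body:{gene_id}"
            )
            clen = int(rng.integers(400, 801))
            u = rng.random()
            if u < 0.60:  # promoter CGI straddling the TSS
                s = int(np.clip(g_tss[2] - clen // 2, 0, length - clen))
            elif u < 0.85:  # intragenic CGI
                s = _place_within(rng, body[0] + 200, body[1] - 200, clen)
                if s is None:
                    s = int(np.clip(g_tss[2] - clen // 2, 0, length - clen))
            else:  # intergenic CGI
                s = _place_nonoverlapping(rng, length, occupied, clen)
                if s is None:
                    raise SizingError("no room for intergenic CGI; genome too crowded")
            cgi_id = f"cgi_{cgi_counter:03d}"
            cgi_counter += 1
            cgi_intervals.append((s, s + clen, cgi_id))
        for _ in range(2):
            clen = int(rng.integers(400, 801))
            s = _place_nonoverlapping(rng, length, occupied + [(a, b) for a, b, _ in cgi_intervals], clen)
            if s is None:
                raise SizingError("no room for extra intergenic CGI")
            cgi_id = f"cgi_{cgi_counter:03d}"
            cgi_counter += 1
            cgi_intervals.append((s, s + clen, cgi_id))
        for s, e, cgi_id in cgi_intervals:
            records.append((chrom, s, e, "cgi", cgi_id, ".", None))

        # --- CGI shores
        if shore_mode == "flanks":
            for s, e, cgi_id in cgi_intervals:
                left = (max(s - 2_000, 0), s)
                right = (e, min(e + 2_000, length))
                if left[1] > left[0]:
                    records.append((chrom, left[0], left[1], "cgi_shore", f"{cgi_id}_shoreL", ".", None))
                if right[1] > right[0]:
                    records.append((chrom, right[0], right[1], "cgi_shore", f"{cgi_id}_shoreR", ".", None))
        else:  # 2 kb upstream of each TSS
            for gene_id, tchrom, tpos, strand in tss_rows:
                if tchrom != chrom:
                    continue
                if strand == "+":
                    s, e = max(tpos - 2_000, 0), tpos
                else:
                    s, e = tpos + 1, min(tpos + 1 + 2_000, length)
                if e > s:
                    records.append((chrom, s, e, "cgi_shore", f"shore_{gene_id}", ".", None))

        blocked = occupied + [(a, b) for a, b, _ in cgi_intervals]

        # --- repeats
        intragenic_frac = {"SINE": 0.7, "LINE": 0.3, "LTR": 0.35, "satellite": 0.0}
        for cls in REPEAT_CLASSES:
            fams, probs = zip(*_REPEAT_FAMILIES[cls])
            lo, hi = _REPEAT_LENGTHS[cls]
            placed_reps: list[tuple[int, int]] = []
            for _ in range(rep_per_chrom[cls][ci]):
                rlen = int(rng.integers(lo, hi + 1))
                s = None
                if gene_spans and rng.random() < intragenic_frac[cls]:
                    for _ in range(50):  # nest inside a gene body, avoid CGIs/repeats
                        host = gene_spans[int(rng.integers(len(gene_spans)))]
                        cand = _place_within(rng, host[0], host[1], rlen)
                        if cand is not None and all(
                            cand + rlen <= a or cand >= b
                            for a, b, *_ in cgi_intervals + [(x, y) for x, y in placed_reps]
                        ):
                            s = cand
                            break
                if s is None:
                    s = _place_nonoverlapping(rng, length, blocked + placed_reps, rlen)
                if s is None:
                    raise SizingError(f"no room for {cls} repeat on {chrom}")
                fam = str(rng.choice(fams, p=np.asarray(probs)))
                rid = f"{cls}_{rep_counter[cls]:03d}"
                rep_counter[cls] += 1
                strand = "+" if rng.random() < 0.5 else "-"
                records.append((chrom, s, s + rlen, cls, rid, strand, fam))
                placed_reps.append((s, s + rlen))

        # --- CpG positions: clustered background + dense CGIs
        n_clusters = rng.poisson(length * background_cpg_rate * 0.8 / 4)
        centers = rng.integers(0, length, size=n_clusters)
        pts = np.repeat(centers, rng.poisson(4, size=n_clusters))
        pts = pts + rng.normal(0, 120, size=len(pts)).astype(int)
        sprinkle = rng.integers(0, length, size=rng.poisson(length * background_cpg_rate * 0.2))
        pos = np.concatenate([pts, sprinkle])
        pos = pos[(pos >= 0) & (pos < length)]
        bg_density = len(pos) / length
        cgi_pts = []
        for s, e, _ in cgi_intervals:
            clen = e - s
            n_cpg = max(
                int(rng.poisson(cgi_density_fold * bg_density * clen)),
                int(np.ceil(4.5 * bg_density * clen)),
            )
            cgi_pts.append(rng.integers(s, e, size=n_cpg))
        if cgi_pts:
            pos = np.concatenate([pos] + cgi_pts)
        cpg_positions[chrom] = np.unique(pos.astype(np.int64))

    annotations = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos", "strand"])
    spec = GenomeSpec(chrom_lengths, cpg_positions, annotations, tss)
    spec.validate()
    return spec
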