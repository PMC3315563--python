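"""Synthetic AML-like MeDIP-seq cohort generator.

This module fabricates everything the downstream analysis consumes, with the
statistical structure a real leukemia methylome study exhibits:

* a ground-truth methylome per sample on the 100-bp window grid — bimodal,
  with gene bodies and repeats highly methylated and CpG islands mostly
  unmethylated;
* a five-group design (four AML-like cytogenetic subtypes of three samples
  each, plus four normal-bone-marrow-like controls) with implanted
  differentially methylated regions (DMRs) in every feature class, including
  AML-wide SINE hypomethylation and subtype-specific repeat hypomethylation;
* immunoprecipitation fragments whose placement probability is proportional
  to the methylated-CpG content they cover, plus a nonspecific background,
  contaminated with a known fraction of PCR duplicates and low-mapping-quality
  alignments so that read filtering is exercised;
* log2 expression values inversely coupled to promoter methylation.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FRAGMENT_COLUMNS, FragmentSet
from .genome import REPEAT_CLASSES, GenomeSpec

AML_GROUPS = ("t(8;21)", "t(15;17)", "NK", "+8")
NBM_GROUP = "NBM"
DEFAULT_GROUP_SIZES = {"t(8;21)": 3, "t(15;17)": 3, "NK": 3, "+8": 3, NBM_GROUP: 4}

# Precedence used to assign each window a single truth class (highest first):
# islands beat the promoters that contain them, repeats beat their host gene
# body, anything unannotated is background.
_CLASS_PRECEDENCE = ("cgi", "promoter", "cgi_shore", "satellite", "SINE", "LINE", "LTR", "gene_body")

# Feature-level baseline methylation: (components, weights) mixtures of Beta
# distributions, tuned so gene bodies/repeats sit high, CGIs low, matching the
# bimodal methylome the analysis assumes.
_BASELINES: dict[str, tuple[tuple[tuple[float, float], ...], tuple[float, ...]]] = {
    "cgi": (((1.5, 12.0), (8.0, 3.0)), (0.85, 0.15)),
    # promoters are bimodal: CGI-type promoters unmethylated, CpG-poor
    # promoters substantially methylated
    "promoter": (((1.5, 10.0), (12.0, 4.0)), (0.6, 0.4)),
    "cgi_shore": (((3.0, 3.0),), (1.0,)),
    "gene_body": (((40.0, 3.2), (2.0, 6.0)), (0.83, 0.17)),
    "SINE": (((45.0, 3.0),), (1.0,)),
    "LINE": (((35.0, 4.0),), (1.0,)),
    "LTR": (((35.0, 4.0),), (1.0,)),
    "satellite": (((30.0, 3.5),), (1.0,)),
    "background": (((25.0, 4.5),), (1.0,)),
}


@dataclass(frozen=True)
class ImplantedDmr:
    """One planned group-specific methylation shift on an annotated feature."""

    feature_id: str
    groups: tuple[str, ...]
    delta: float

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


@dataclass
class CohortDesign:
    """Group sizes and DMR plan for :func:`generate_truth`.

    ``dmr_plan=None`` requests the default plan (shared AML CGI
    hypermethylation, AML-wide SINE hypomethylation, and subtype-specific
    DMRs in every feature class); an explicit empty list gives a null cohort.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    dmr_plan: list[ImplantedDmr] | None = None
    noise_sd: float = 0.05
    window_jitter_sd: float = 0.02
    shared_cgi_hyper: int = 12
    shared_cgi_delta: float = 0.4
    aml_sine_hypo_frac: float = 0.22
    aml_sine_hypo_delta: float = -0.3
    subtype_counts: dict[str, int] = field(
        default_factory=lambda: {
            "promoter": 4,
            "cgi": 3,
            "gene_body": 3,
            "cgi_shore": 3,
            "SINE": 5,
            "LINE": 4,
            "LTR": 3,
            "satellite": 2,
        }
    )
    subtype_deltas: dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.4,
            "cgi": 0.45,
            "gene_body": -0.3,
            "cgi_shore": 0.3,
            "SINE": -0.35,
            "LINE": -0.3,
            "LTR": -0.3,
            "satellite": -0.3,
        }
    )


@dataclass
class TruthMethylome:
    """Ground-truth window methylation for a synthetic cohort."""

    genome: GenomeSpec
    samples: list[str]
    group_labels: dict[str, str]
    group_names: list[str]
    scores: np.ndarray  # (n_samples, total_windows), sample-level truth in [0,1]
    group_means: np.ndarray  # (n_groups, total_windows), pre-noise
    window_class: np.ndarray  # per-window truth class label
    window_feature: np.ndarray  # per-window feature_id ("" = background)
    implanted: pd.DataFrame  # feature_id, feature_class, groups, delta, direction
    noise_sd: float

    @property
    def grid(self):
        return self.genome.grid

    def sample_scores(self, sample: str) -> np.ndarray:
        return self.scores[self.samples.index(sample)]

    def group_mean(self, group: str) -> np.ndarray:
        return self.group_means[self.group_names.index(group)]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_labels[s] == group]

    def class_windows(self, feature_class: str) -> np.ndarray:
        return np.flatnonzero(self.window_class == feature_class)


def _sample_baseline(rng, feature_class: str, n: int = 1) -> np.ndarray:
    comps, weights = _BASELINES[feature_class]
    which = rng.choice(len(comps), size=n, p=np.asarray(weights))
    out = np.empty(n)
    for i, c in enumerate(which):
        a, b = comps[c]
        out[i] = rng.beta(a, b)
    return out


def _assign_window_classes(genome: GenomeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Assign each window one truth class/feature by center containment,
    resolving overlaps with the fixed precedence order."""
    grid = genome.grid
    total = grid.total_windows
    wclass = np.full(total, "background", dtype=object)
    wfeat = np.full(total, "", dtype=object)
    assigned = np.zeros(total, dtype=bool)
    half = grid.size // 2
    for cls in _CLASS_PRECEDENCE:
        for row in genome.features(cls).itertuples():
            # windows whose center start+half lies in [start, end)
            lo = int(np.ceil((row.start - half) / grid.size))
            hi = (row.end - half - 1) // grid.size
            lo = max(lo, 0)
            hi = min(hi, grid.n_windows(row.chrom) - 1)
            if hi < lo:
                continue
            idx = grid.flat_index(row.chrom, np.arange(lo, hi + 1))
            free = idx[~assigned[idx]]
            wclass[free] = cls
            wfeat[free] = row.feature_id
            assigned[free] = True
    return wclass, wfeat


def _feature_windows(genome: GenomeSpec, row) -> np.ndarray:
    lo, hi = genome.grid.overlapping_windows(row.chrom, row.start, row.end)
    return genome.grid.flat_index(row.chrom, np.arange(lo, hi))


def _default_dmr_plan(genome: GenomeSpec, design: CohortDesign, rng,
                      baseline_by_feature: dict[str, float]) -> list[ImplantedDmr]:
    """Shared + subtype-specific implants, choosing features whose baseline
    leaves room for the planned shift without truncation at 0 or 1."""
    plan: list[ImplantedDmr] = []
    used: set[str] = set()

    def eligible(feature_class: str, delta: float) -> list[str]:
        rows = genome.features(feature_class)
        return [
            fid
            for fid in rows.feature_id
            if fid not in used and 0.03 <= baseline_by_feature.get(fid, 0.5) + delta <= 0.97
        ]

    def pick(feature_class: str, n: int, delta: float) -> list[str]:
        ok = eligible(feature_class, delta)
        chosen = list(rng.choice(ok, size=min(n, len(ok)), replace=False))
        used.update(chosen)
        return chosen

    subtypes = [g for g in AML_GROUPS if g in design.group_sizes]

    # shared AML implants, scaled down on small genomes so subtype-specific
    # implants keep a feature pool
    n_cgi = len(genome.features("cgi"))
    n_shared = min(design.shared_cgi_hyper, max(n_cgi - len(subtypes) * design.subtype_counts["cgi"] - 2, 0))
    for fid in pick("cgi", n_shared, design.shared_cgi_delta):
        plan.append(ImplantedDmr(fid, AML_GROUPS, design.shared_cgi_delta))
    sines = genome.features("SINE").feature_id.tolist()
    n_sine = int(round(design.aml_sine_hypo_frac * len(sines)))
    n_sine = min(n_sine, max(len(sines) - len(subtypes) * design.subtype_counts["SINE"], 0))
    for fid in pick("SINE", n_sine, design.aml_sine_hypo_delta):
        plan.append(ImplantedDmr(fid, AML_GROUPS, design.aml_sine_hypo_delta))

    for group in subtypes:
        for cls, n in design.subtype_counts.items():
            delta = design.subtype_deltas[cls]
            if cls == "cgi_shore":  # shores sit mid-scale; shift whichever way fits
                rows = genome.features(cls)
                cands = [f for f in rows.feature_id if f not in used]
                chosen = list(rng.choice(cands, size=min(n, len(cands)), replace=False))
                used.update(chosen)
                for fid in chosen:
                    d = delta if baseline_by_feature.get(fid, 0.5) < 0.5 else -delta
                    plan.append(ImplantedDmr(fid, (group,), d))
                continue
            for fid in pick(cls, n, delta):
                plan.append(ImplantedDmr(fid, (group,), delta))
    if not plan:
        raise ValueError("default DMR plan is empty: genome has too few features")
    return plan


def generate_truth(genome: GenomeSpec, design: CohortDesign | None = None, seed: int = 0) -> TruthMethylome:
    """Draw ground-truth methylomes for a grouped cohort.

    Baseline methylation is drawn per feature (plus small per-window jitter),
    planned DMRs shift the affected groups' means by their delta over every
    window overlapping the target feature, and each sample adds independent
    Gaussian noise (sd ``design.noise_sd``) around its group mean, truncated
    to [0, 1].
    """
    design = design or CohortDesign()
    if len(design.group_sizes) < 1 or any(n < 1 for n in design.group_sizes.values()):
        raise ValueError("every group needs at least one sample")
    rng = np.random.default_rng(seed)
    grid = genome.grid
    total = grid.total_windows

    wclass, wfeat = _assign_window_classes(genome)

    # feature-level baselines; background drawn per 5-window block for local smoothness
    baseline_by_feature: dict[str, float] = {}
    for cls in _CLASS_PRECEDENCE:
        feats = genome.features(cls).feature_id.tolist()
        vals = _sample_baseline(rng, cls, len(feats))
        baseline_by_feature.update(zip(feats, vals))
    baseline = np.empty(total)
    for i in range(total):
        if wfeat[i]:
            baseline[i] = baseline_by_feature[wfeat[i]]
        else:
            baseline[i] = np.nan
    bg = np.isnan(baseline)
    n_blocks = int(np.ceil(total / 5))
    block_vals = _sample_baseline(rng, "background", n_blocks)
    baseline[bg] = np.repeat(block_vals, 5)[:total][bg]
    baseline = np.clip(baseline + rng.normal(0.0, design.window_jitter_sd, size=total), 0.01, 0.99)

    plan = design.dmr_plan
    if plan is None:
        plan = _default_dmr_plan(genome, design, rng, baseline_by_feature)
    ann = genome.annotations.set_index("feature_id", drop=False)
    for implant in plan:
        if implant.feature_id not in ann.index:
            raise ValueError(f"DMR plan references unknown feature {implant.feature_id!r}")
        if abs(implant.delta) < 0.25:
            raise ValueError(f"implanted |delta| must be >= 0.25 (got {implant.delta})")
        unknown = set(implant.groups) - set(design.group_sizes)
        if unknown:
            raise ValueError(f"DMR plan references unknown groups {sorted(unknown)}")

    group_names = list(design.group_sizes)
    group_means = np.tile(baseline, (len(group_names), 1))
    for implant in plan:
        win = _feature_windows(genome, ann.loc[implant.feature_id])
        for g in implant.groups:
            group_means[group_names.index(g), win] += implant.delta
    group_means = np.clip(group_means, 0.0, 1.0)

    samples, group_labels = [], {}
    for g in group_names:
        tag = "".join(ch for ch in g if ch.isalnum()).lower() or "g"
        for k in range(design.group_sizes[g]):
            sid = f"{tag}_{k + 1}"
            samples.append(sid)
            group_labels[sid] = g
    scores = np.empty((len(samples), total), dtype=np.float64)
    for i, sid in enumerate(samples):
        mu = group_means[group_names.index(group_labels[sid])]
        scores[i] = np.clip(mu + rng.normal(0.0, design.noise_sd, size=total), 0.0, 1.0)

    implanted = pd.DataFrame(
        [
            (p.feature_id, ann.loc[p.feature_id, "feature_class"], ",".join(p.groups), p.delta, p.direction)
            for p in plan
        ],
        columns=["feature_id", "feature_class", "groups", "delta", "direction"],
    )
    return TruthMethylome(
        genome, samples, group_labels, group_names, scores, group_means,
        np.asarray(wclass), np.asarray(wfeat), implanted, design.noise_sd,
    )


def simulate_fragments(
    genome: GenomeSpec,
    truth: TruthMethylome,
    sample: str,
    n_fragments: int,
    fragment_length_dist: tuple[float, float] = (450.0, 100.0),
    background_rate: float = 0.05,
    seed: int = 0,
    *,
    duplicate_frac: float = 0.05,
    lowq_frac: float = 0.05,
) -> FragmentSet:
    """Simulate MeDIP fragments for one sample.

    Each non-background fragment is anchored on a CpG drawn with probability
    proportional to its true methylation, then placed uniformly among the
    starts that cover that CpG — i.e. placement probability proportional to
    the methylated-CpG content a fragment covers. A ``background_rate``
    fraction is placed uniformly (nonspecific pull-down). Fragment lengths
    are Normal(mean, sd) truncated to [100, 1000] bp. A known fraction of
    records is turned into flagged PCR duplicates and another fraction is
    given sub-threshold mapping quality.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if not (0.0 <= background_rate < 1.0):
        raise ValueError("background_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    grid = genome.grid
    s_scores = truth.sample_scores(sample)

    chroms = list(genome.chrom_lengths)
    cpg_chrom_idx, cpg_pos, cpg_m = [], [], []
    for ci, chrom in enumerate(chroms):
        pos = genome.cpg_positions[chrom]
        widx = grid.window_of(chrom, pos)
        keep = widx >= 0
        pos, widx = pos[keep], widx[keep]
        cpg_chrom_idx.append(np.full(len(pos), ci))
        cpg_pos.append(pos)
        cpg_m.append(s_scores[grid.flat_index(chrom, widx)])
    cpg_chrom_idx = np.concatenate(cpg_chrom_idx) if cpg_chrom_idx else np.empty(0, int)
    cpg_pos = np.concatenate(cpg_pos) if cpg_pos else np.empty(0, int)
    cpg_m = np.concatenate(cpg_m) if cpg_m else np.empty(0)
    total_m = float(cpg_m.sum())
    if total_m <= 0 and background_rate == 0:
        raise ValueError("no methylated CpGs and zero background: sampling measure is empty")

    mean_len, sd_len = fragment_length_dist
    lengths = np.clip(np.round(rng.normal(mean_len, sd_len, size=n_fragments)), 100, 1000).astype(int)
    p_bg = background_rate if total_m > 0 else 1.0
    is_bg = rng.random(n_fragments) < p_bg

    chrom_lens = np.array([genome.chrom_lengths[c] for c in chroms])
    starts = np.empty(n_fragments, dtype=np.int64)
    chrom_of = np.empty(n_fragments, dtype=np.int64)

    n_bg = int(is_bg.sum())
    if n_bg:
        cidx = rng.choice(len(chroms), size=n_bg, p=chrom_lens / chrom_lens.sum())
        chrom_of[is_bg] = cidx
        starts[is_bg] = (rng.random(n_bg) * (chrom_lens[cidx] - lengths[is_bg])).astype(np.int64)
    n_sig = n_fragments - n_bg
    if n_sig:
        anchor = rng.choice(len(cpg_pos), size=n_sig, p=cpg_m / total_m)
        offs = (rng.random(n_sig) * lengths[~is_bg]).astype(np.int64)
        s = cpg_pos[anchor] - offs
        cidx = cpg_chrom_idx[anchor]
        s = np.clip(s, 0, chrom_lens[cidx] - lengths[~is_bg])
        chrom_of[~is_bg] = cidx
        starts[~is_bg] = s

    order = rng.permutation(n_fragments)
    chrom_of, starts, lengths = chrom_of[order], starts[order], lengths[order]
    strand = np.where(rng.random(n_fragments) < 0.5, "+", "-")
    is_dup = np.zeros(n_fragments, dtype=bool)
    n_dup = int(round(duplicate_frac * n_fragments))
    if n_dup and n_fragments > 1:
        tgt = rng.choice(n_fragments, size=n_dup, replace=False)
        src = rng.choice(np.setdiff1d(np.arange(n_fragments), tgt), size=n_dup, replace=True)
        chrom_of[tgt], starts[tgt], lengths[tgt], strand[tgt] = (
            chrom_of[src], starts[src], lengths[src], strand[src])
        is_dup[tgt] = True
    mapq = rng.integers(20, 41, size=n_fragments)
    n_lowq = int(round(lowq_frac * n_fragments))
    if n_lowq:
        lowq = rng.choice(n_fragments, size=n_lowq, replace=False)
        mapq[lowq] = rng.integers(0, 10, size=n_lowq)

    records = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object)[chrom_of],
            "start": starts,
            "end": starts + lengths,
            "strand": strand,
            "mapq": mapq,
            "is_duplicate": is_dup,
        },
        columns=FRAGMENT_COLUMNS,
    )
    return FragmentSet(sample, records)


def simulate_expression(
    truth: TruthMethylome,
    genome: GenomeSpec,
    coupling_strength: float = -4.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> pd.DataFrame:
    """Gene x sample log2 expression, linearly coupled to promoter methylation.

    ``expression = baseline_g + coupling_strength * promoter_methylation +
    Normal(0, noise_sd)``; the default negative coupling gives the inverse
    methylation-expression relation typical of promoters.
    """
    rng = np.random.default_rng(seed)
    grid = genome.grid
    promoters = genome.features("promoter").set_index("feature_id")
    rows = []
    gene_ids = list(truth.genome.tss.gene_id)
    for gene in gene_ids:
        pid = f"promoter:{gene}"
        if pid not in promoters.index:
            raise ValueError(f"gene {gene!r} lacks a promoter annotation")
        row = promoters.loc[pid]
        lo, hi = grid.overlapping_windows(row.chrom, row.start, row.end)
        win = grid.flat_index(row.chrom, np.arange(lo, hi))
        rows.append(truth.scores[:, win].mean(axis=1))
    meth = np.asarray(rows)  # genes x samples
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(gene_ids))[:, None]
    noise = rng.normal(0.0, noise_sd, size=meth.shape) if noise_sd > 0 else 0.0
    expr = baseline + coupling_strength * meth + noise
    return pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=truth.samples)


def promoter_methylation(truth: TruthMethylome, genome: GenomeSpec) -> pd.DataFrame:
    """True mean promoter methylation per gene and sample (genes x samples)."""
    grid = genome.grid
    promoters = genome.features("promoter")
    out = {}
    for row in promoters.itertuples():
        gene = row.feature_id.split(":", 1)[1]
        lo, hi = grid.overlapping_windows(row.chrom, row.start, row.end)
        win = grid.flat_index(row.chrom, np.arange(lo, hi))
        out[gene] = truth.scores[:, win].mean(axis=1)
    return pd.DataFrame(out).T.set_axis(truth.samples, axis=1)
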