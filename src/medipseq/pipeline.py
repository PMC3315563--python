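"""End-to-end pipeline: simulate -> quantify -> annotate -> dmr -> cluster ->
global -> expression, with file artifacts between stages.

Each stage reads its upstream artifacts from the output directory and fails
with a named-dependency error when they are missing. All randomness flows
from the seeds in :class:`medipseq.config.PipelineConfig`; logs are
machine-parseable ``key=value`` lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats
from .annotate import FeatureMatrix, aggregate_features
from .batman import BatmanModel, InferenceConfig
from .cluster import cluster_report, write_linkage
from .config import PipelineConfig
from .coupling import compute_coupling
from .dmr import DifferentialMethylation
from .expression import binned_methylation_expression, de_set_methylation_test
from .fragments import filter_fragments
from .genome import GenomeSpec, generate_genome
from .globalprofile import compare_bin_profiles, group_profile
from .simulate import (
    AML_GROUPS,
    NBM_GROUP,
    CohortDesign,
    generate_truth,
    simulate_expression,
    simulate_fragments,
)
from .windows import WindowGrid

log = logging.getLogger("medipseq")

STAGES = ("simulate", "quantify", "annotate", "dmr", "cluster", "global", "expression")


class DependencyError(RuntimeError):
    """An upstream artifact required by a stage is missing."""


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{stage}' needs {path.name} produced by stage '{produced_by}'"
        )
    return path


def _log(stage: str, **kv) -> None:
    log.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kv.items()))


def _load_genome(outdir: Path, stage: str) -> GenomeSpec:
    sizes = pd.read_csv(_require(outdir / "chrom_sizes.tsv", stage, "simulate"), sep="\t")
    ann = formats.read_annotations_gff3(_require(outdir / "annotations.gff3", stage, "simulate"))
    cpgs = formats.read_cpg_table(_require(outdir / "cpg_positions.tsv", stage, "simulate"))
    tss = pd.read_csv(_require(outdir / "tss.tsv", stage, "simulate"), sep="\t")
    return GenomeSpec(dict(zip(sizes.chrom, sizes.length)), cpgs, ann, tss)


def _load_groups(outdir: Path, stage: str) -> dict[str, str]:
    df = pd.read_csv(_require(outdir / "groups.tsv", stage, "simulate"), sep="\t")
    return dict(zip(df["sample"], df["group"]))


def run_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    g = cfg.genome
    genome = generate_genome(
        seed=g.seed, n_chroms=g.n_chroms, chrom_length=g.chrom_length,
        n_genes=g.n_genes, n_repeats_per_class=g.n_repeats_per_class,
        shore_mode=g.shore_mode,
    )
    design = CohortDesign(noise_sd=cfg.cohort.noise_sd,
                          dmr_plan=[] if cfg.cohort.null else None)
    truth = generate_truth(genome, design, seed=cfg.cohort.seed)
    pd.DataFrame(
        {"chrom": list(genome.chrom_lengths), "length": list(genome.chrom_lengths.values())}
    ).to_csv(outdir / "chrom_sizes.tsv", sep="\t", index=False)
    formats.write_annotations_gff3(genome, outdir / "annotations.gff3")
    formats.write_annotations_bed(genome, outdir / "annotations.bed")
    formats.write_cpg_table(genome, outdir / "cpg_positions.tsv")
    genome.tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample": truth.samples, "group": [truth.group_labels[s] for s in truth.samples]}
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    truth.implanted.to_csv(outdir / "implanted_dmrs.tsv", sep="\t", index=False)
    np.savetxt(outdir / "truth_scores.tsv", truth.scores.T, delimiter="\t",
               header="\t".join(truth.samples), comments="")
    f = cfg.fragments
    for i, sample in enumerate(truth.samples):
        frags = simulate_fragments(
            genome, truth, sample, f.n_fragments,
            fragment_length_dist=(f.length_mean, f.length_sd),
            background_rate=f.background_rate, seed=f.seed + 7 * i,
            duplicate_frac=f.duplicate_frac, lowq_frac=f.lowq_frac,
        )
        formats.write_fragments_bed(frags, outdir / f"fragments_{sample}.bed",
                                    outdir / f"fragments_{sample}.flags.tsv")
    expr = simulate_expression(
        truth, genome, coupling_strength=cfg.expression.coupling_strength,
        noise_sd=cfg.expression.noise_sd, seed=cfg.expression.seed,
    )
    formats.write_expression(expr, outdir / "expression.tsv")
    _log("simulate", n_samples=len(truth.samples), n_windows=genome.grid.total_windows,
         n_cpgs=genome.n_cpgs(), n_implanted=len(truth.implanted),
         fragments_per_sample=f.n_fragments)


def run_quantify(cfg: PipelineConfig, outdir: Path) -> None:
    genome = _load_genome(outdir, "quantify")
    groups = _load_groups(outdir, "quantify")
    coupling = compute_coupling(genome, cfg.fragments.length_mean)
    inf = InferenceConfig(
        burn_in=cfg.quant.burn_in, draws=cfg.quant.draws,
        proposal_width=cfg.quant.proposal_width, c_min=cfg.quant.c_min,
        smooth_l1=cfg.quant.smooth_l1, smooth_l2=cfg.quant.smooth_l2,
    )
    for i, sample in enumerate(groups):
        raw = formats.read_fragments_bed(
            _require(outdir / f"fragments_{sample}.bed", "quantify", "simulate"),
            _require(outdir / f"fragments_{sample}.flags.tsv", "quantify", "simulate"),
            sample,
        )
        filt, report = filter_fragments(raw, cfg.fragments.mapq_min)
        res = BatmanModel(filt, coupling, inf).fit(seed=cfg.quant.seed + 13 * i)
        formats.write_track_gff3(res.track, outdir / f"methylome_{sample}.gff3")
        formats.write_track_bedgraph(res.track, outdir / f"methylome_{sample}.bedgraph")
        _log("quantify", sample=sample, n_input=report.n_input,
             n_duplicates=report.n_duplicates_removed, n_lowq=report.n_lowq_removed,
             n_kept=report.n_kept, callable=res.track.n_callable,
             r=f"{res.calibration.r:.3f}", b=f"{res.calibration.b:.3f}")


def _load_tracks(outdir: Path, stage: str, grid: WindowGrid, samples) -> list:
    return [
        formats.read_track_gff3(
            _require(outdir / f"methylome_{s}.gff3", stage, "quantify"), grid, s
        )
        for s in samples
    ]


def run_annotate(cfg: PipelineConfig, outdir: Path) -> None:
    genome = _load_genome(outdir, "annotate")
    groups = _load_groups(outdir, "annotate")
    tracks = _load_tracks(outdir, "annotate", genome.grid, list(groups))
    fm = aggregate_features(tracks, genome, min_windows=cfg.dmr.min_windows)
    fm.to_tsv(outdir / "feature_matrix.tsv")
    _log("annotate", n_features=len(fm.values), n_samples=len(fm.samples),
         n_incomplete=len(fm.incomplete_rows))


def dmr_contrasts(groups: dict[str, str]) -> list[tuple[str, str]]:
    """The six standard contrasts: each AML subtype vs the rest, plus
    all-AML ('rest') vs normal bone marrow."""
    present = set(groups.values())
    contrasts = [(g, "rest") for g in AML_GROUPS if g in present]
    if NBM_GROUP in present:
        contrasts.append(("rest", NBM_GROUP))
    return contrasts


def _contrast_tag(contrast: tuple[str, str]) -> str:
    clean = lambda s: "".join(ch for ch in s if ch.isalnum()) or "rest"
    return f"{clean(contrast[0])}_vs_{clean(contrast[1])}"


def run_dmr(cfg: PipelineConfig, outdir: Path) -> None:
    fm = FeatureMatrix.from_tsv(_require(outdir / "feature_matrix.tsv", "dmr", "annotate"))
    groups = _load_groups(outdir, "dmr")
    model = DifferentialMethylation(fm, groups)
    for contrast in dmr_contrasts(groups):
        res = model.fit(contrast, p_thresh=cfg.dmr.p_thresh, delta_thresh=cfg.dmr.delta_thresh)
        tag = _contrast_tag(contrast)
        res.to_tsv(outdir / f"dmr_{tag}.tsv")
        res.to_bed9(outdir / f"dmr_{tag}.bed", fm.meta)
        _log("dmr", contrast=tag, tested=len(res.table), dmrs=int(res.table.is_dmr.sum()),
             hyper=int((res.table.direction == "hyper").sum()),
             hypo=int((res.table.direction == "hypo").sum()))


def run_cluster(cfg: PipelineConfig, outdir: Path) -> None:
    fm = FeatureMatrix.from_tsv(_require(outdir / "feature_matrix.tsv", "cluster", "annotate"))
    table = pd.read_csv(
        _require(outdir / "dmr_rest_vs_NBM.tsv", "cluster", "dmr"),
        sep="\t", index_col="feature_id",
    )
    rep = cluster_report(
        fm.complete().values, table, p_select=cfg.dmr.p_select,
        k_max=cfg.cluster.k_max, n_folds=cfg.cluster.n_folds, seed=cfg.cluster.seed,
    )
    write_linkage(rep.linkage, outdir / "cluster_linkage.tsv")
    rep.similarity.to_csv(outdir / "cluster_similarity.tsv", sep="\t")
    if rep.strength is not None:
        rep.strength.table.to_csv(outdir / "prediction_strength.tsv", sep="\t", index=False)
    _log("cluster", selected=len(rep.selected), leaf_order=",".join(rep.leaf_order))


def run_global(cfg: PipelineConfig, outdir: Path) -> None:
    genome = _load_genome(outdir, "global")
    groups = _load_groups(outdir, "global")
    tracks = _load_tracks(outdir, "global", genome.grid, list(groups))
    scores = {s: t.score for s, t in zip(groups, tracks)}
    aml = np.vstack([scores[s] for s, g in groups.items() if g != NBM_GROUP])
    nbm = np.vstack([scores[s] for s, g in groups.items() if g == NBM_GROUP])
    prof_aml, prof_nbm = group_profile(aml), group_profile(nbm)
    out = pd.concat(
        [prof_aml.to_frame().assign(group="AML"), prof_nbm.to_frame().assign(group="NBM")]
    )
    out.to_csv(outdir / "global_bins.tsv", sep="\t", index=False)
    fisher = compare_bin_profiles(prof_aml, prof_nbm, seed=cfg.cluster.seed)
    _log("global", aml_mean_pct=f"{prof_aml.mean_pct:.2f}",
         nbm_mean_pct=f"{prof_nbm.mean_pct:.2f}", fisher_p=f"{fisher.p:.4g}",
         fisher_mode=fisher.mode)


def run_expression(cfg: PipelineConfig, outdir: Path) -> None:
    expr = formats.read_expression(_require(outdir / "expression.tsv", "expression", "simulate"))
    fm = FeatureMatrix.from_tsv(_require(outdir / "feature_matrix.tsv", "expression", "annotate"))
    groups = _load_groups(outdir, "expression")
    prom = fm.subset_class("promoter")
    meth = prom.values.copy()
    meth.index = [fid.split(":", 1)[1] for fid in meth.index]
    corr = binned_methylation_expression(meth, expr)
    corr.per_sample.to_csv(outdir / "expression_binned_correlation.tsv", sep="\t", index=False)
    rows = []
    for subtype in [g for g in AML_GROUPS if g in set(groups.values())]:
        in_g = [s for s, g in groups.items() if g == subtype]
        rest = [s for s in groups if s not in in_g]
        diff = (expr[in_g].mean(axis=1) - expr[rest].mean(axis=1)).sort_values()
        n_set = min(30, len(diff) // 3)
        over, under = list(diff.index[-n_set:]), list(diff.index[:n_set])
        m = meth[in_g].mean(axis=1)
        cmp_ = de_set_methylation_test(m, over, under)
        rows.append((subtype, cmp_.median_over, cmp_.median_under, cmp_.u_statistic, cmp_.p))
    pd.DataFrame(
        rows, columns=["subtype", "median_over", "median_under", "U", "p"]
    ).to_csv(outdir / "expression_set_tests.tsv", sep="\t", index=False)
    _log("expression", mean_binned_r=f"{corr.mean_r:.3f}", n_subtype_tests=len(rows))


_RUNNERS = {
    "simulate": run_simulate,
    "quantify": run_quantify,
    "annotate": run_annotate,
    "dmr": run_dmr,
    "cluster": run_cluster,
    "global": run_global,
    "expression": run_expression,
}


def run_pipeline(cfg: PipelineConfig, stages, outdir) -> None:
    """Run the requested stages in canonical order."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if "all" in stages else [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES) - {"all"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg.to_yaml(outdir / "config_used.yaml")
    for stage in requested:
        _RUNNERS[stage](cfg, outdir)
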