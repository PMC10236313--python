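"""End-to-end orchestration: enhancers -> eRNA -> inducible sets -> EPU ->
occupancy and promoter dynamics.

A single :class:`PipelineConfig` names every input file and stage
parameter; :func:`run_pipeline` validates it, runs the stages in order,
writes per-stage TSV/BED outputs plus a JSON summary into the run
directory, and logs resolved parameters and input checksums. Runs are
deterministic given config + inputs; a failing stage leaves a FAILED
marker naming the stage and keeps any outputs already written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import differential, epu, erna, occupancy
from .core import (
    GenomeLayout,
    Interval,
    Peak,
    promoter_region,
    read_chrom_sizes,
    read_gene_table,
    read_intervals,
    write_bed6,
)
from .enhancers import (
    EnhancerCall,
    EnhancerRuleConfig,
    assign_activity_class,
    qualify_enhancers,
    split_location_class,
)
from .erna import ErnaFilterConfig, ErnaLocus
from .signal import (
    LibraryStats,
    Tags,
    bin_counts,
    deduplicate_tags,
    extend_tags,
    read_tagalign,
    rpm_normalize,
)


@dataclass
class PipelineConfig:
    """Paths to all inputs plus every stage parameter."""

    # annotation
    chrom_sizes: Path = Path()
    genes_refseq: Path = Path()
    genes_est: Optional[Path] = None
    # peak files
    p300_peaks: Path = Path()
    h3k4me3_peaks: Path = Path()
    h3k4me1_peaks: Path = Path()
    h3k9ac_peaks: Optional[Path] = None
    h3k9me3_peaks: Optional[Path] = None
    ctcf_peaks: Optional[Path] = None
    factor_sites_unstim: Optional[Path] = None
    factor_sites_stim: Optional[Path] = None
    # tag libraries
    rna_unstim: Optional[Path] = None
    rna_stim: Optional[Path] = None
    h4ac_unstim: Optional[Path] = None
    h4ac_stim: Optional[Path] = None
    h3k9ac_unstim: Optional[Path] = None
    h3k9ac_stim: Optional[Path] = None
    me2_ip_unstim: Optional[Path] = None
    me2_ip_stim: Optional[Path] = None
    me2_input_unstim: Optional[Path] = None
    me2_input_stim: Optional[Path] = None
    # auxiliary
    rrna_blacklist: Optional[Path] = None
    repeat_regions: Optional[Path] = None
    expression_matrix: Optional[Path] = None
    # parameters
    enhancer_rules: EnhancerRuleConfig = field(default_factory=EnhancerRuleConfig)
    erna_filters: ErnaFilterConfig = field(default_factory=ErnaFilterConfig)
    extension_bp: int = 100
    bin_size: int = 100
    dedup_threshold: float = 0.3
    promoter_half_width: int = 1000
    epu_max_range: int = 200_000
    mark_fdr: float = 0.1
    window_pad: int = 500
    lfc_threshold: float = 1.0
    expression_alpha: float = 0.05
    n_top_sites: int = 30
    out_dir: Path = Path("pipeline_out")

    @classmethod
    def from_fixture_dir(cls, fixture: str | Path, out_dir: str | Path) -> "PipelineConfig":
        """Config wired to the file layout the synthetic generator writes."""
        d = Path(fixture)
        return cls(
            chrom_sizes=d / "genome.chrom.sizes",
            genes_refseq=d / "genes_refseq.refflat",
            genes_est=d / "genes_est.refflat",
            p300_peaks=d / "peaks" / "p300.narrowPeak",
            h3k4me3_peaks=d / "peaks" / "h3k4me3.bed",
            h3k4me1_peaks=d / "peaks" / "h3k4me1.bed",
            h3k9ac_peaks=d / "peaks" / "h3k9ac.bed",
            h3k9me3_peaks=d / "peaks" / "h3k9me3.bed",
            ctcf_peaks=d / "peaks" / "ctcf.narrowPeak",
            factor_sites_unstim=d / "peaks" / "factor_unstim.bed",
            factor_sites_stim=d / "peaks" / "factor_stim.bed",
            rna_unstim=d / "tags" / "rna_unstim.tagAlign",
            rna_stim=d / "tags" / "rna_stim.tagAlign",
            h4ac_unstim=d / "tags" / "h4ac_unstim.tagAlign",
            h4ac_stim=d / "tags" / "h4ac_stim.tagAlign",
            h3k9ac_unstim=d / "tags" / "h3k9ac_unstim.tagAlign",
            h3k9ac_stim=d / "tags" / "h3k9ac_stim.tagAlign",
            me2_ip_unstim=d / "tags" / "h3k9me2_ip_unstim.tagAlign",
            me2_ip_stim=d / "tags" / "h3k9me2_ip_stim.tagAlign",
            me2_input_unstim=d / "tags" / "h3k9me2_input_unstim.tagAlign",
            me2_input_stim=d / "tags" / "h3k9me2_input_stim.tagAlign",
            rrna_blacklist=d / "blacklist_rrna.bed",
            repeat_regions=d / "repeats.bed",
            expression_matrix=d / "expression.tsv",
            out_dir=Path(out_dir),
        )

    def required_paths(self) -> list[Path]:
        req = [self.chrom_sizes, self.genes_refseq, self.p300_peaks,
               self.h3k4me3_peaks, self.h3k4me1_peaks]
        opt = [
            self.genes_est, self.h3k9ac_peaks, self.h3k9me3_peaks, self.ctcf_peaks,
            self.factor_sites_unstim, self.factor_sites_stim,
            self.rna_unstim, self.rna_stim, self.h4ac_unstim, self.h4ac_stim,
            self.h3k9ac_unstim, self.h3k9ac_stim,
            self.me2_ip_unstim, self.me2_ip_stim,
            self.me2_input_unstim, self.me2_input_stim,
            self.rrna_blacklist, self.repeat_regions, self.expression_matrix,
        ]
        return req + [p for p in opt if p is not None]

    def validate(self) -> None:
        missing = [str(p) for p in self.required_paths() if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: PipelineConfig
    layout: GenomeLayout
    enhancer_calls: list[EnhancerCall]
    erna_unstim: list[ErnaLocus]
    erna_stim: list[ErnaLocus]
    erna_induction: dict[str, float]
    erna_induction_median: float
    inducible_enhancer_ids: list[str]
    inducible_genes: list[differential.InducibleGeneCall]
    epu_assignments: list[epu.EpuAssignment]
    site_annotations: dict[str, list[occupancy.BindingSiteAnnotation]]
    colocalization: dict[str, dict[str, float]]
    top_colocalization: dict[str, dict[str, float]]
    bound_fractions: dict[str, Optional[float]]
    promoter_signal: dict[str, list[occupancy.PromoterSignalRecord]]
    contrasts: dict[str, occupancy.SetContrast]
    summary: dict

    @property
    def qualified(self) -> list[EnhancerCall]:
        return [c for c in self.enhancer_calls if c.qualified]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def prepare_tags(
    tags: Tags,
    layout: GenomeLayout,
    extension: int,
    dedup_threshold: float = 0.3,
) -> tuple[Tags, LibraryStats]:
    """Library preprocessing in the fixed order dedup -> extend.

    Deduplication runs only when the measured duplication rate exceeds
    ``dedup_threshold``; the library normalizer is the post-dedup tag
    count. Extension happens after deduplication so identical fragments
    collapse on their original coordinates.
    """
    deduped, rate = deduplicate_tags(tags)
    if rate <= dedup_threshold:
        deduped, kept_rate = tags, rate
    else:
        kept_rate = rate
    stats = LibraryStats(max(1, len(deduped)), kept_rate)
    return extend_tags(deduped, extension, layout), stats


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log("parameters: " + json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(cfg).items()}, sort_keys=True))
    for p in cfg.required_paths():
        log(f"input {p} sha256:{_checksum(Path(p))}")

    current_stage = "load"
    try:
        result = _run_stages(cfg, out, log)
    except StageError:
        (out / "FAILED").write_text("see run.log")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        (out / "FAILED").write_text(current_stage)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise StageError(current_stage, exc) from exc

    log_lines += result.summary.get("log", [])
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    if (out / "FAILED").exists():
        (out / "FAILED").unlink()
    return result


def _run_stages(cfg: PipelineConfig, out: Path, log) -> PipelineResult:
    stage = "load"
    try:
        layout = read_chrom_sizes(cfg.chrom_sizes)
        genes = read_gene_table(cfg.genes_refseq, source="refseq_like")
        if cfg.genes_est:
            genes += read_gene_table(cfg.genes_est, source="est_like")
        p300 = read_intervals(cfg.p300_peaks, "narrowpeak", layout, mark="p300")
        me3 = read_intervals(cfg.h3k4me3_peaks, "bed6", layout, mark="h3k4me3")
        me1 = read_intervals(cfg.h3k4me1_peaks, "bed6", layout, mark="h3k4me1")

        stage = "enhancers"
        calls = qualify_enhancers(p300, me3, me1, genes, cfg.enhancer_rules)
        calls = split_location_class(calls, genes, cfg.enhancer_rules)
        if cfg.h3k9ac_peaks and cfg.h3k9me3_peaks:
            h3k9ac = read_intervals(cfg.h3k9ac_peaks, "bed6", layout)
            h3k9me3 = read_intervals(cfg.h3k9me3_peaks, "bed6", layout)
            calls = assign_activity_class(calls, h3k9ac, h3k9me3)
        qualified = [c for c in calls if c.qualified]
        extragenic = [c for c in qualified if c.location_class == "extragenic"]
        log(f"enhancers: {len(p300)} p300 peaks, {len(qualified)} qualified, "
            f"{len(extragenic)} extragenic")
        _write_enhancer_tables(out, calls)

        stage = "erna"
        erna_unstim: list[ErnaLocus] = []
        erna_stim: list[ErnaLocus] = []
        induction: dict[str, float] = {}
        induction_median = float("nan")
        if cfg.rna_unstim and cfg.rna_stim:
            blacklist = [p.interval for p in read_intervals(cfg.rrna_blacklist, "bed3")] \
                if cfg.rrna_blacklist else []
            repeats = [p.interval for p in read_intervals(cfg.repeat_regions, "bed3")] \
                if cfg.repeat_regions else []
            from .core import IntervalIndex

            repeat_idx = IntervalIndex(repeats)
            tags_u = read_tagalign(cfg.rna_unstim)
            tags_s = read_tagalign(cfg.rna_stim)
            stats_u = tags_u.stats()
            stats_s = tags_s.stats()
            erna_unstim = erna.build_erna_loci(extragenic, tags_u, stats_u, layout)
            erna_stim = erna.build_erna_loci(extragenic, tags_s, stats_s, layout)
            flags = {
                l.id: any(repeat_idx.overlaps(w) for w in l.windows())
                for l in erna_unstim
            }
            erna_unstim = erna.apply_erna_filters(
                erna_unstim, cfg.erna_filters, blacklist, flags)
            erna_stim = erna.apply_erna_filters(
                erna_stim, cfg.erna_filters, blacklist, flags)
            passed_ids = {l.id for l in erna_unstim if l.passed}
            induction, induction_median = erna.erna_induction(
                [l for l in erna_unstim if l.id in passed_ids],
                [l for l in erna_stim if l.id in passed_ids],
            )
            log(f"erna: {len(erna_unstim)} loci, {len(passed_ids)} passed, "
                f"median induction {induction_median:.3f}")
            _write_erna_tables(out, erna_unstim)

        stage = "differential"
        inducible_enhancer_ids: list[str] = []
        windows = [
            Interval(
                c.peak.interval.chrom,
                max(0, c.peak.interval.start - cfg.window_pad),
                c.peak.interval.end + cfg.window_pad,
            )
            for c in qualified
        ]
        mark_results = {}
        for mark, (path_u, path_s) in {
            "h4ac": (cfg.h4ac_unstim, cfg.h4ac_stim),
            "h3k9ac": (cfg.h3k9ac_unstim, cfg.h3k9ac_stim),
        }.items():
            if not (path_u and path_s):
                continue
            tu, ts = read_tagalign(path_u), read_tagalign(path_s)
            res = differential.window_differential_test(
                windows, ts, tu, ts.stats(), tu.stats(), fdr=cfg.mark_fdr)
            mark_results[mark] = res
            _write_window_tests(out / f"window_tests_{mark}.tsv", res)
        if mark_results:
            flagged = differential.call_inducible_enhancers(
                qualified,
                mark_results.get("h4ac", ()),
                mark_results.get("h3k9ac", ()),
            )
            inducible_enhancer_ids = sorted(c.id for c in flagged)
            log(f"differential: {len(inducible_enhancer_ids)} inducible enhancers "
                f"at FDR<{cfg.mark_fdr}")

        stage = "expression"
        gene_calls: list[differential.InducibleGeneCall] = []
        if cfg.expression_matrix:
            expr = differential.read_expression_matrix(cfg.expression_matrix)
            labels = ["stim" if c.startswith("stim") else "unstim" for c in expr.columns]
            gene_calls = differential.call_inducible_genes(
                expr, labels, cfg.lfc_threshold, cfg.expression_alpha)
            n_ind = sum(g.inducible for g in gene_calls)
            log(f"expression: {n_ind} inducible genes of {len(gene_calls)}")
            pd.DataFrame([dataclasses.asdict(g) for g in gene_calls]).to_csv(
                out / "inducible_genes.tsv", sep="\t", index=False)

        stage = "epu"
        assignments: list[epu.EpuAssignment] = []
        if cfg.ctcf_peaks:
            ctcf = read_intervals(cfg.ctcf_peaks, "narrowpeak", layout, mark="ctcf")
            blocks = epu.partition_by_ctcf(ctcf, layout)
            inducible_names = {g.gene for g in gene_calls if g.inducible}
            target_genes = [g for g in genes
                            if g.source == "refseq_like"
                            and (not inducible_names or g.name in inducible_names)]
            assignments = epu.assign_enhancers_to_genes(
                extragenic, target_genes, blocks, layout, cfg.epu_max_range)
            n_assigned = sum(a.gene is not None for a in assignments)
            log(f"epu: {n_assigned}/{len(assignments)} extragenic enhancers assigned")
            pd.DataFrame([dataclasses.asdict(a) for a in assignments]).to_csv(
                out / "epu_assignments.tsv", sep="\t", index=False)

        stage = "occupancy"
        promoters = [
            promoter_region(g, layout, cfg.promoter_half_width)
            for g in genes if g.source == "refseq_like"
        ]
        site_annotations: dict[str, list[occupancy.BindingSiteAnnotation]] = {}
        coloc: dict[str, dict[str, float]] = {}
        top_coloc: dict[str, dict[str, float]] = {}
        bound_fractions: dict[str, Optional[float]] = {}
        for cond, path in (("unstim", cfg.factor_sites_unstim),
                           ("stim", cfg.factor_sites_stim)):
            if not path:
                continue
            sites = read_intervals(path, "bed6", layout, mark="factor", condition=cond)
            ann = occupancy.classify_binding_sites(sites, qualified, promoters, cond)
            site_annotations[cond] = ann
            coloc[cond] = occupancy.colocalization_fractions(ann)
            top = occupancy.top_n_sites(sites, min(cfg.n_top_sites, len(sites)))
            top_ann = occupancy.classify_binding_sites(top, qualified, promoters, cond)
            top_coloc[cond] = occupancy.colocalization_fractions(top_ann)
            if cond == "unstim":
                _, bound_fractions = occupancy.stratify_enhancers_by_binding(
                    qualified, sites)
        if coloc:
            _write_colocalization(out / "colocalization.tsv", coloc, top_coloc)

        stage = "promoter_dynamics"
        promoter_signal: dict[str, list[occupancy.PromoterSignalRecord]] = {}
        contrasts: dict[str, occupancy.SetContrast] = {}
        me2_paths = (cfg.me2_ip_unstim, cfg.me2_ip_stim,
                     cfg.me2_input_unstim, cfg.me2_input_stim)
        if all(me2_paths):
            tracks = {}
            for name, path in zip(
                ("ip_unstim", "ip_stim", "input_unstim", "input_stim"), me2_paths):
                tags = read_tagalign(path)
                prepared, stats = prepare_tags(
                    tags, layout, cfg.extension_bp, cfg.dedup_threshold)
                tracks[name] = rpm_normalize(
                    bin_counts(prepared, layout, cfg.bin_size), stats)
            for cond in ("unstim", "stim"):
                promoter_signal[cond] = occupancy.promoter_signal_ratio(
                    tracks[f"ip_{cond}"], tracks[f"input_{cond}"], promoters,
                    condition=cond)
                _write_promoter_signal(
                    out / f"promoter_signal_{cond}.tsv", promoter_signal[cond])
            if gene_calls:
                inducible_names = sorted(
                    g.gene for g in gene_calls if g.inducible)
                others = sorted(
                    g.gene for g in gene_calls if not g.inducible)
                # deterministic comparison set of matching size: evenly
                # spaced draw from the sorted non-inducible genes
                k = min(len(inducible_names), len(others)) or 1
                step = max(1, len(others) // k)
                random_names = others[::step][:k]
                contrasts, me2_ratios = _promoter_contrasts(
                    promoter_signal, inducible_names, random_names,
                    site_annotations)
            else:
                me2_ratios = {}

        summary = _summarize(
            calls, erna_unstim, induction_median, inducible_enhancer_ids,
            gene_calls, assignments, coloc, top_coloc, bound_fractions)
        if promoter_signal:
            summary["me2_post_pre_ratio"] = me2_ratios
            summary["me2_contrasts"] = {
                name: dataclasses.asdict(c) for name, c in contrasts.items()
            }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

        return PipelineResult(
            config=cfg,
            layout=layout,
            enhancer_calls=calls,
            erna_unstim=erna_unstim,
            erna_stim=erna_stim,
            erna_induction=induction,
            erna_induction_median=induction_median,
            inducible_enhancer_ids=inducible_enhancer_ids,
            inducible_genes=gene_calls,
            epu_assignments=assignments,
            site_annotations=site_annotations,
            colocalization=coloc,
            top_colocalization=top_coloc,
            bound_fractions=bound_fractions,
            promoter_signal=promoter_signal,
            contrasts=contrasts,
            summary=summary,
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc


def _promoter_contrasts(
    promoter_signal: dict[str, list[occupancy.PromoterSignalRecord]],
    inducible_names: list[str],
    random_names: list[str],
    site_annotations: dict[str, list[occupancy.BindingSiteAnnotation]],
) -> tuple[dict[str, occupancy.SetContrast], dict[str, float]]:
    """Stimulation contrasts of input-normalized promoter signal.

    Returns paired pre/post contrasts for the inducible and comparison
    gene sets, a bound-vs-unbound contrast among inducible promoters when
    stimulated-condition factor sites are available, and the mean
    post/pre ratio per set.
    """
    by_cond = {
        cond: {r.gene: r for r in recs} for cond, recs in promoter_signal.items()
    }
    contrasts: dict[str, occupancy.SetContrast] = {}
    ratios: dict[str, float] = {}
    for label, names in (("inducible", inducible_names), ("random", random_names)):
        pre = [by_cond["unstim"][n] for n in names if n in by_cond["unstim"]]
        post = [by_cond["stim"][n] for n in names if n in by_cond["stim"]]
        if len(pre) >= 2 and len(post) >= 2:
            contrasts[f"{label}_post_vs_pre"] = occupancy.compare_promoter_sets(
                post, pre, paired=True)
            ratios[label] = float(
                pd.Series(
                    [by_cond["stim"][n].ratio / by_cond["unstim"][n].ratio
                     for n in names
                     if n in by_cond["stim"] and n in by_cond["unstim"]]
                ).mean()
            )
    stim_ann = site_annotations.get("stim")
    if stim_ann and inducible_names:
        from .core import IntervalIndex

        site_idx = IntervalIndex(a.site.interval for a in stim_ann)
        bound, unbound = [], []
        for n in inducible_names:
            rec = by_cond["stim"].get(n)
            if rec is None:
                continue
            (bound if site_idx.overlaps(rec.window.interval) else unbound).append(rec)
        if len(bound) >= 2 and len(unbound) >= 2:
            contrasts["bound_vs_unbound_stim"] = occupancy.compare_promoter_sets(
                bound, unbound, paired=False)
    return contrasts, ratios


def _summarize(calls, erna_loci, induction_median, inducible_enh, gene_calls,
               assignments, coloc, top_coloc, bound_fractions) -> dict:
    qualified = [c for c in calls if c.qualified]
    by_loc = {
        loc: sum(c.location_class == loc for c in qualified)
        for loc in ("intragenic", "extragenic", "excluded_near_tes")
    }
    reasons: dict[str, int] = {}
    for c in calls:
        for r in sorted(c.rejection_reasons):
            reasons[r] = reasons.get(r, 0) + 1
    erna_reasons: dict[str, int] = {}
    for l in erna_loci:
        for r in sorted(l.exclusion_reasons):
            erna_reasons[r] = erna_reasons.get(r, 0) + 1
    return {
        "p300_peaks": len(calls),
        "qualified_enhancers": len(qualified),
        "location_counts": by_loc,
        "rejection_reason_counts": reasons,
        "erna_loci": len(erna_loci),
        "erna_passed": sum(l.passed for l in erna_loci),
        "erna_exclusion_counts": erna_reasons,
        "erna_induction_median": induction_median,
        "inducible_enhancers": len(inducible_enh),
        "inducible_genes": sum(g.inducible for g in gene_calls),
        "genes_tested": len(gene_calls),
        "epu_assigned": sum(a.gene is not None for a in assignments),
        "epu_reason_counts": {
            r: sum(a.reason == r for a in assignments)
            for r in ("assigned_nearest_in_block", "no_tss_in_block", "out_of_range")
        },
        "colocalization_pct": coloc,
        "top_sites_colocalization_pct": top_coloc,
        "bound_fractions": bound_fractions,
    }


def _write_enhancer_tables(out: Path, calls) -> None:
    rows = []
    for c in calls:
        iv = c.peak.interval
        rows.append(dict(
            id=c.id, chrom=iv.chrom, start=iv.start, end=iv.end,
            score=c.peak.score, summit=c.summit, qualified=c.qualified,
            rejection_reasons=",".join(sorted(c.rejection_reasons)),
            location_class=c.location_class,
            activity_class=c.activity_class or "",
        ))
    pd.DataFrame(rows).to_csv(out / "enhancer_calls.tsv", sep="\t", index=False)
    write_bed6(
        out / "qualified_enhancers.bed",
        [(c.peak.interval, c.id, c.peak.score, ".") for c in calls if c.qualified],
    )


def _write_erna_tables(out: Path, loci) -> None:
    rows = []
    for l in loci:
        rows.append(dict(
            id=l.id, summit=l.summit,
            plus_down=l.plus_down_counts, minus_up=l.minus_up_counts,
            plus_far=l.plus_far_counts, minus_far=l.minus_far_counts,
            fpkm_plus=l.fpkm_plus, fpkm_minus=l.fpkm_minus,
            passed=l.passed,
            exclusion_reasons=",".join(sorted(l.exclusion_reasons)),
        ))
    pd.DataFrame(rows).to_csv(out / "erna_loci.tsv", sep="\t", index=False)
    write_bed6(
        out / "erna_passed.bed",
        [
            (l.enhancer.peak.interval, l.id, l.total_fpkm, ".")
            for l in loci if l.passed
        ],
    )


def _write_window_tests(path: Path, results) -> None:
    rows = [dict(
        chrom=r.window.chrom, start=r.window.start, end=r.window.end,
        count_stim=r.count_stim, count_ctrl=r.count_ctrl,
        p_value=r.p_value, q_value=r.q_value, enriched=r.enriched,
    ) for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_colocalization(path: Path, coloc, top_coloc) -> None:
    rows = []
    for scope, table in (("all", coloc), ("top", top_coloc)):
        for cond, fracs in table.items():
            rows.append(dict(scope=scope, condition=cond, **fracs))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_promoter_signal(path: Path, records) -> None:
    rows = [dict(
        gene=r.gene, chrom=r.window.interval.chrom,
        start=r.window.interval.start, end=r.window.interval.end,
        ip_rpm=r.ip_rpm, input_rpm=r.input_rpm, ratio=r.ratio,
        condition=r.condition,
    ) for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
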