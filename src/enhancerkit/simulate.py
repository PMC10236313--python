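"""Seed-deterministic synthetic fixture generator with ground truth.

Builds a miniature genome whose features exercise every pipeline stage:
planted enhancers carrying p300 + H3K4me1 (with class-appropriate
H3K9ac / H3K9me3 and H3K27ac / H3K27me3 peaks), promoters carrying
H3K4me3, bidirectional stranded eRNA tag clusters at enhancer summits,
decoy loci violating each qualification and eRNA-exclusion rule, CTCF
sites creating assignable / blocked / out-of-range enhancer-promoter
cases, condition-dependent acetylation gains at inducible enhancers,
promoter H3K9me2 depletion on stimulation, factor binding sites that
redistribute from enhancers to inducible promoters, and a two-condition
expression matrix with planted log2 fold changes.

Layout is cassette-based: each feature lives in its own fixed-size
cassette placed sequentially (with seeded jitter gaps) along the
chromosomes, which guarantees the spacing margins the enhancer
definition requires and makes every expected outcome computable at
generation time. Counts are Poisson; expression noise is Normal on the
log2 scale. Identical config + seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    GeneModel,
    GenomeLayout,
    Interval,
    Peak,
    write_bed6,
    write_gene_table,
)
from .signal import Tags, write_tagalign

READ_LEN = 36

QUAL_DECOY_CLASSES = (
    "low_score",
    "h3k4me3_overlap",
    "refseq_tss_proximity",
    "est_tss_proximity",
    "no_h3k4me1",
)
ERNA_DECOY_CLASSES = ("unidirectional", "long_transcript", "repeat", "rrna")


class PackingError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (7_000_000, 7_000_000)

    # annotation
    n_genes_refseq: int = 400
    n_genes_est_standalone: int = 3
    n_ctcf_extra: int = 30

    # enhancers (true set, by activity class) and structural variants
    n_active: int = 20
    n_intermediate: int = 15
    n_poised: int = 15
    n_intragenic: int = 4
    n_near_tes: int = 3
    n_qual_decoys_per_class: int = 3
    n_erna_decoys_per_class: int = 10
    n_epu_assigned: int = 6
    n_epu_blocked: int = 3
    n_epu_far: int = 1

    # eRNA rates (expected tags per 2-kb window)
    erna_rate: float = 60.0
    erna_far_rate: float = 0.0
    erna_induction_fold: float = 2.0
    erna_uni_plus_rate: float = 150.0
    erna_uni_minus_rate: float = 5.0
    erna_long_prox_rate: float = 20.0
    erna_long_far_rate: float = 100.0
    erna_repeat_rate: float = 300.0
    rna_depth: int = 80_000

    # differential acetylation (tags per enhancer window)
    mark_base_rate: float = 60.0
    mark_induced_fold: float = 5.0
    n_inducible_enhancers: int = 20  # half driven by H4ac, half by H3K9ac
    mark_depth: int = 12_000

    # promoter H3K9me2 dynamics (tags per promoter window)
    me2_rate_pre: float = 600.0
    me2_rate_post_inducible: float = 300.0
    input_rate: float = 600.0
    me2_depth: int = 270_000

    # factor binding sites
    n_factor_sites: int = 100
    site_composition_pre: tuple[float, float, float] = (0.70, 0.08, 0.22)
    site_redistribution_fraction: float = 0.05
    bound_enhancer_fraction: float = 0.30
    n_random_gene_set: int = 40

    # expression
    induced_gene_fraction: float = 0.10
    induced_effect_log2: float = 2.0
    expression_noise_sd: float = 0.25
    n_replicates: int = 3
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        if not (0 <= self.site_redistribution_fraction <= 1):
            raise ValueError("site_redistribution_fraction must be in [0,1]")
        if not (0 <= self.induced_gene_fraction <= 1):
            raise ValueError("induced_gene_fraction must be in [0,1]")
        if abs(sum(self.site_composition_pre) - 1.0) > 1e-9:
            raise ValueError("site_composition_pre must sum to 1")

    @property
    def n_true_extragenic(self) -> int:
        return self.n_active + self.n_intermediate + self.n_poised


# ---------------------------------------------------------------------------
# Planned features


@dataclass
class PlannedEnhancer:
    id: str
    kind: str  # true_extragenic | intragenic | near_tes | decoy_<x> | erna_decoy_<x>
    chrom: str = ""
    summit: int = 0
    score: float = 0.0
    activity_class: str = "intermediate"
    has_me1: bool = True
    me3_decoy: bool = False
    expected_qualified: bool = True
    expected_rejection: str = ""
    expected_location: str = ""
    erna_class: str = "none"  # true | <decoy class> | none
    expected_erna_excluded: str = ""
    lam_plus_prox: float = 0.0
    lam_minus_prox: float = 0.0
    lam_plus_far: float = 0.0
    lam_minus_far: float = 0.0
    repeat_region: bool = False
    blacklisted: bool = False
    inducible_mark: str = ""  # h4ac | h3k9ac | ""
    epu_case: str = ""  # assigned | no_tss_in_block | out_of_range | ""
    epu_expected_gene: str = ""
    bound: bool = False

    @property
    def p300_interval(self) -> Interval:
        return Interval(self.chrom, self.summit - 250, self.summit + 250)


@dataclass
class PlannedGene:
    name: str
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    source: str = "refseq_like"
    has_me3: bool = True
    induced: bool = False
    me2_set: str = ""  # inducible | random | ""
    plain: bool = False  # lives in an ordinary single-gene cassette

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def to_model(self) -> GeneModel:
        return GeneModel(self.name, Interval(self.chrom, self.start, self.end), self.strand, self.source)  # type: ignore[arg-type]


@dataclass
class PlannedSite:
    interval: Interval
    score: float
    category: str  # enhancer | promoter | other
    enhancer_id: str = ""
    moves_post: bool = False


@dataclass
class AnnotationBundle:
    cfg: SimulationConfig
    layout: GenomeLayout
    genes: list[PlannedGene]
    enhancers: list[PlannedEnhancer]
    ctcf_summits: list[tuple[str, int]]
    other_slots: list[tuple[str, int]]
    sites_pre: list[PlannedSite] = field(default_factory=list)
    sites_post: list[PlannedSite] = field(default_factory=list)

    @property
    def gene_models(self) -> list[GeneModel]:
        return [g.to_model() for g in self.genes]

    @property
    def ctcf_peaks(self) -> list[Peak]:
        return [
            Peak(Interval(c, s - 100, s + 100), score=100.0, summit=s, mark="ctcf")
            for c, s in self.ctcf_summits
        ]

    def truth(self) -> "SyntheticTruth":
        return SyntheticTruth.from_bundle(self)


@dataclass
class SyntheticTruth:
    """Long-form manifest of every planted feature and its expected outcome."""

    manifest: pd.DataFrame

    @classmethod
    def from_bundle(cls, ann: "AnnotationBundle") -> "SyntheticTruth":
        rows = []
        for e in ann.enhancers:
            rows.append(
                dict(
                    feature_id=e.id,
                    kind="enhancer",
                    subkind=e.kind,
                    chrom=e.chrom,
                    start=e.p300_interval.start,
                    end=e.p300_interval.end,
                    summit=e.summit,
                    expected_qualified=e.expected_qualified,
                    expected_rejection=e.expected_rejection,
                    expected_location=e.expected_location,
                    activity_class=e.activity_class if e.expected_qualified else "",
                    erna_class=e.erna_class,
                    expected_erna_excluded=e.expected_erna_excluded,
                    inducible_mark=e.inducible_mark,
                    epu_case=e.epu_case,
                    epu_expected_gene=e.epu_expected_gene,
                    bound=e.bound,
                    induced=False,
                    me2_set="",
                )
            )
        for g in ann.genes:
            rows.append(
                dict(
                    feature_id=g.name,
                    kind="gene",
                    subkind=g.source,
                    chrom=g.chrom,
                    start=g.start,
                    end=g.end,
                    summit=g.tss,
                    expected_qualified=pd.NA,
                    expected_rejection="",
                    expected_location="",
                    activity_class="",
                    erna_class="none",
                    expected_erna_excluded="",
                    inducible_mark="",
                    epu_case="",
                    epu_expected_gene="",
                    bound=False,
                    induced=g.induced,
                    me2_set=g.me2_set,
                )
            )
        for cond, sites in (("unstim", ann.sites_pre), ("stim", ann.sites_post)):
            for i, s in enumerate(sites):
                rows.append(
                    dict(
                        feature_id=f"site_{cond}_{i:04d}",
                        kind=f"factor_site_{cond}",
                        subkind=s.category,
                        chrom=s.interval.chrom,
                        start=s.interval.start,
                        end=s.interval.end,
                        summit=s.interval.midpoint,
                        expected_qualified=pd.NA,
                        expected_rejection="",
                        expected_location="",
                        activity_class="",
                        erna_class="none",
                        expected_erna_excluded="",
                        inducible_mark="",
                        epu_case="",
                        epu_expected_gene=s.enhancer_id,
                        bound=False,
                        induced=False,
                        me2_set="",
                    )
                )
        return cls(pd.DataFrame(rows))

    def enhancer_rows(self) -> pd.DataFrame:
        return self.manifest[self.manifest.kind == "enhancer"]

    def gene_rows(self) -> pd.DataFrame:
        return self.manifest[self.manifest.kind == "gene"]

    def site_composition(self, condition: str) -> dict[str, float]:
        rows = self.manifest[self.manifest.kind == f"factor_site_{condition}"]
        n = len(rows)
        return {
            cat: 100.0 * (rows.subkind == cat).sum() / n
            for cat in ("enhancer", "promoter", "other")
        }


# ---------------------------------------------------------------------------
# Cassette layout


@dataclass
class _Cassette:
    kind: str
    size: int
    payload: dict


def _enhancer_cassette_features(
    enh: PlannedEnhancer, chrom: str, base: int, center_off: int = 15_000
) -> None:
    enh.chrom = chrom
    enh.summit = base + center_off


def _build_cassette_specs(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Cassette]:
    specs: list[_Cassette] = []
    eid = iter(f"enh_{i:04d}" for i in range(10_000))
    gid = iter(f"gene_{i:04d}" for i in range(10_000))

    classes = (
        ["active"] * cfg.n_active
        + ["intermediate"] * cfg.n_intermediate
        + ["poised"] * cfg.n_poised
    )
    true_enhancers = [
        PlannedEnhancer(next(eid), "true_extragenic", activity_class=c, erna_class="true")
        for c in classes
    ]
    rng.shuffle(true_enhancers)  # decouple class from EPU-case designation

    # designated EPU cases consume true extragenic enhancers
    i = 0
    for _ in range(cfg.n_epu_assigned):
        e = true_enhancers[i]
        i += 1
        g = PlannedGene(next(gid), induced=True, me2_set="inducible")
        e.epu_case = "assigned"
        e.epu_expected_gene = g.name
        specs.append(_Cassette("epu_pair", 50_000, dict(enh=e, gene=g)))
    for _ in range(cfg.n_epu_blocked):
        e = true_enhancers[i]
        i += 1
        e.epu_case = "no_tss_in_block"
        specs.append(_Cassette("epu_blocked", 30_000, dict(enh=e)))
    for _ in range(cfg.n_epu_far):
        e = true_enhancers[i]
        i += 1
        g = PlannedGene(next(gid))
        e.epu_case = "out_of_range"
        specs.append(_Cassette("epu_far", 260_000, dict(enh=e, gene=g)))
    for e in true_enhancers[i:]:
        specs.append(_Cassette("enhancer", 30_000, dict(enh=e)))

    for k in range(cfg.n_intragenic):
        e = PlannedEnhancer(next(eid), "intragenic", erna_class="none")
        g = PlannedGene(next(gid))
        specs.append(_Cassette("intragenic", 40_000, dict(enh=e, gene=g)))
    for k in range(cfg.n_near_tes):
        e = PlannedEnhancer(next(eid), "near_tes", erna_class="none")
        g = PlannedGene(next(gid))
        specs.append(_Cassette("near_tes", 40_000, dict(enh=e, gene=g)))

    for cls in QUAL_DECOY_CLASSES:
        for _ in range(cfg.n_qual_decoys_per_class):
            e = PlannedEnhancer(
                next(eid),
                f"decoy_{cls}",
                expected_qualified=False,
                expected_rejection=cls,
                erna_class="none",
            )
            payload: dict = dict(enh=e)
            size = 30_000
            if cls == "refseq_tss_proximity":
                payload["gene"] = PlannedGene(next(gid))
            elif cls == "est_tss_proximity":
                payload["gene"] = PlannedGene(next(gid), source="est_like", has_me3=False)
            specs.append(_Cassette(f"decoy_{cls}", size, payload))

    for cls in ERNA_DECOY_CLASSES:
        for _ in range(cfg.n_erna_decoys_per_class):
            e = PlannedEnhancer(next(eid), f"erna_decoy_{cls}", erna_class=cls)
            specs.append(_Cassette("enhancer", 30_000, dict(enh=e)))

    for _ in range(cfg.n_genes_est_standalone):
        g = PlannedGene(next(gid), source="est_like", has_me3=False)
        specs.append(_Cassette("gene", 20_000, dict(gene=g)))

    n_special_genes = (
        cfg.n_epu_assigned
        + cfg.n_epu_far
        + cfg.n_intragenic
        + cfg.n_near_tes
        + cfg.n_qual_decoys_per_class  # refseq_tss_proximity decoy genes
    )
    n_regular = cfg.n_genes_refseq - n_special_genes
    if n_regular < 0:
        raise PackingError("n_genes_refseq smaller than the structurally required gene count")
    for _ in range(n_regular):
        strand = "+" if rng.random() < 0.5 else "-"
        specs.append(
            _Cassette("gene", 20_000, dict(gene=PlannedGene(next(gid), strand=strand)))
        )

    n_other = max(0, round(cfg.n_factor_sites * cfg.site_composition_pre[2]))
    for _ in range(n_other):
        specs.append(_Cassette("other_slot", 10_000, dict()))

    rng.shuffle(specs)
    return specs


def _place_cassette(
    cas: _Cassette, chrom: str, base: int, ann_lists: dict
) -> None:
    kind = cas.kind
    enh: Optional[PlannedEnhancer] = cas.payload.get("enh")
    gene: Optional[PlannedGene] = cas.payload.get("gene")

    def put_gene(g: PlannedGene, start_off: int, length: int) -> None:
        # strand was fixed when the cassette spec was built; special
        # cassettes rely on the default '+' geometry
        g.chrom, g.start, g.end = chrom, base + start_off, base + start_off + length
        ann_lists["genes"].append(g)

    if kind in ("enhancer", "epu_blocked"):
        _enhancer_cassette_features(enh, chrom, base)
        if kind == "epu_blocked":
            ann_lists["ctcf"] += [(chrom, base), (chrom, base + cas.size)]
    elif kind == "epu_pair":
        _enhancer_cassette_features(enh, chrom, base)
        put_gene(gene, 35_000, 10_000)
        ann_lists["ctcf"] += [(chrom, base), (chrom, base + cas.size)]
    elif kind == "epu_far":
        put_gene(gene, 5_000, 8_000)
        _enhancer_cassette_features(enh, chrom, base, center_off=245_000)
        ann_lists["ctcf"] += [(chrom, base), (chrom, base + cas.size)]
    elif kind == "intragenic":
        put_gene(gene, 5_000, 30_000)
        _enhancer_cassette_features(enh, chrom, base, center_off=20_000)
        enh.expected_location = "intragenic"
    elif kind == "near_tes":
        put_gene(gene, 5_000, 15_000)
        _enhancer_cassette_features(enh, chrom, base, center_off=23_000)
        enh.expected_location = "excluded_near_tes"
    elif kind == "decoy_refseq_tss_proximity":
        put_gene(gene, 20_000, 8_000)
        enh.chrom, enh.summit = chrom, base + 20_850
    elif kind == "decoy_est_tss_proximity":
        put_gene(gene, 16_750, 6_000)
        _enhancer_cassette_features(enh, chrom, base)
    elif kind.startswith("decoy_"):
        _enhancer_cassette_features(enh, chrom, base)
    elif kind == "gene":
        gene.plain = True
        put_gene(gene, 5_000, 8_000)
    elif kind == "other_slot":
        ann_lists["other_slots"].append((chrom, base + 5_000))
    else:  # pragma: no cover
        raise AssertionError(kind)

    if enh is not None:
        ann_lists["enhancers"].append(enh)


def _finalize_enhancer(enh: PlannedEnhancer, cfg: SimulationConfig, rng: np.random.Generator) -> None:
    """Scores, decoy-specific attributes, eRNA rates, expected outcomes."""
    enh.score = float(np.round(rng.uniform(70, 180), 1))
    kind = enh.kind
    if kind == "decoy_low_score":
        enh.score = 59.0
    elif kind == "decoy_h3k4me3_overlap":
        enh.me3_decoy = True
    elif kind == "decoy_no_h3k4me1":
        enh.has_me1 = False
    if kind == "decoy_refseq_tss_proximity":
        # p300 sits 600 bp downstream of its cassette gene's TSS
        pass

    if kind == "true_extragenic" or kind.startswith("erna_decoy"):
        enh.expected_location = "extragenic"

    cls = enh.erna_class
    if cls == "true":
        enh.lam_plus_prox = enh.lam_minus_prox = cfg.erna_rate
        enh.lam_plus_far = enh.lam_minus_far = cfg.erna_far_rate
    elif cls == "unidirectional":
        enh.lam_plus_prox = cfg.erna_uni_plus_rate
        enh.lam_minus_prox = cfg.erna_uni_minus_rate
        enh.expected_erna_excluded = "strand_ratio"
    elif cls == "long_transcript":
        enh.lam_plus_prox = enh.lam_minus_prox = cfg.erna_long_prox_rate
        enh.lam_plus_far = cfg.erna_long_far_rate
        enh.expected_erna_excluded = "flanking_signal"
    elif cls == "repeat":
        enh.lam_plus_prox = enh.lam_minus_prox = cfg.erna_repeat_rate
        enh.repeat_region = True
        enh.expected_erna_excluded = "repeat_signal"
    elif cls == "rrna":
        enh.lam_plus_prox = enh.lam_minus_prox = cfg.erna_rate
        enh.blacklisted = True
        enh.expected_erna_excluded = "rrna_homology"


def simulate_annotation(cfg: SimulationConfig) -> AnnotationBundle:
    """Lay out the genome: genes, enhancers, CTCF sites, factor sites.

    Raises :class:`PackingError` when the requested features do not fit
    on the configured chromosomes.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    specs = _build_cassette_specs(cfg, rng)

    chrom_names = [f"chr{i + 1}" for i in range(len(cfg.chromosome_lengths))]
    layout = GenomeLayout.from_pairs(zip(chrom_names, cfg.chromosome_lengths))
    ann_lists: dict = dict(genes=[], enhancers=[], ctcf=[], other_slots=[])

    cursor = {c: 2_000 for c in chrom_names}
    ci = 0
    for cas in specs:
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            gap = int(rng.integers(0, 2_000))
            base = cursor[chrom] + gap
            if base + cas.size + 2_000 <= layout.length_of(chrom):
                _place_cassette(cas, chrom, base, ann_lists)
                cursor[chrom] = base + cas.size
                placed = True
                ci += 1
                break
            ci += 1
        if not placed:
            raise PackingError(
                f"cassette {cas.kind} ({cas.size} bp) does not fit: "
                f"{len(specs)} features on {sum(cfg.chromosome_lengths)} bp"
            )

    for enh in ann_lists["enhancers"]:
        _finalize_enhancer(enh, cfg, rng)

    genes: list[PlannedGene] = ann_lists["genes"]
    enhancers: list[PlannedEnhancer] = ann_lists["enhancers"]

    # remaining induced genes beyond the EPU-pair genes
    n_induced = round(cfg.induced_gene_fraction * sum(g.source == "refseq_like" for g in genes))
    pool = [g for g in genes if g.source == "refseq_like" and not g.induced and g.me2_set == ""]
    extra = n_induced - sum(g.induced for g in genes)
    if extra > 0:
        for idx in rng.choice(len(pool), size=extra, replace=False):
            pool[int(idx)].induced = True
            pool[int(idx)].me2_set = "inducible"
    pool = [g for g in genes if g.source == "refseq_like" and not g.induced]
    for idx in rng.choice(len(pool), size=min(cfg.n_random_gene_set, len(pool)), replace=False):
        pool[int(idx)].me2_set = "random"

    # designated inducible enhancers: the EPU-assigned set first, then more
    # true extragenic enhancers, alternating the driving acetylation mark
    true_list = [e for e in enhancers if e.kind == "true_extragenic"]
    chosen = [e for e in true_list if e.epu_case == "assigned"]
    chosen += [e for e in true_list if e.epu_case != "assigned"][
        : max(0, cfg.n_inducible_enhancers - len(chosen))
    ]
    for j, e in enumerate(chosen):
        e.inducible_mark = "h4ac" if j % 2 == 0 else "h3k9ac"

    # extra CTCF boundaries at ordinary gene-cassette edges (never inside
    # the designated EPU cassettes)
    regular_gene_starts = [
        (g.chrom, g.start - 5_000)
        for g in genes
        if g.plain and g.source == "refseq_like"
    ]
    k = min(cfg.n_ctcf_extra, len(regular_gene_starts))
    for idx in rng.choice(len(regular_gene_starts), size=k, replace=False):
        ann_lists["ctcf"].append(regular_gene_starts[int(idx)])

    ann = AnnotationBundle(
        cfg=cfg,
        layout=layout,
        genes=genes,
        enhancers=enhancers,
        ctcf_summits=sorted(set(ann_lists["ctcf"])),
        other_slots=ann_lists["other_slots"],
    )
    _plan_factor_sites(cfg, ann, rng)
    return ann


def _plan_factor_sites(cfg: SimulationConfig, ann: AnnotationBundle, rng: np.random.Generator) -> None:
    qualified = [e for e in ann.enhancers if e.expected_qualified]
    n_bound = round(cfg.bound_enhancer_fraction * len(qualified))
    weights = np.array(
        [{"active": 5.0, "intermediate": 1.0, "poised": 0.5}[e.activity_class] for e in qualified]
    )
    bound_idx = rng.choice(len(qualified), size=n_bound, replace=False, p=weights / weights.sum())
    bound = [qualified[int(i)] for i in sorted(bound_idx)]
    for e in bound:
        e.bound = True

    frac_enh, frac_prom, frac_other = cfg.site_composition_pre
    n_enh = round(cfg.n_factor_sites * frac_enh)
    n_prom = round(cfg.n_factor_sites * frac_prom)
    n_other = cfg.n_factor_sites - n_enh - n_prom
    if n_enh < n_bound:
        raise PackingError("enhancer-site budget smaller than the bound-enhancer count")
    if n_other > len(ann.other_slots):
        raise PackingError("not enough empty slots for 'other' factor sites")

    sites: list[PlannedSite] = []
    hosts = list(bound) + [bound[int(i)] for i in rng.integers(0, len(bound), n_enh - n_bound)]
    for e in hosts:
        sites.append(
            PlannedSite(
                Interval(e.chrom, e.summit - 200, e.summit + 200),
                score=float(np.round(rng.uniform(100, 200), 1)),
                category="enhancer",
                enhancer_id=e.id,
            )
        )
    prom_pool = [g for g in ann.genes if g.source == "refseq_like" and not g.induced]
    for idx in rng.choice(len(prom_pool), size=n_prom, replace=False):
        g = prom_pool[int(idx)]
        sites.append(
            PlannedSite(
                Interval(g.chrom, g.tss - 300, g.tss + 300),
                score=float(np.round(rng.uniform(50, 150), 1)),
                category="promoter",
            )
        )
    for chrom, center in ann.other_slots[:n_other]:
        sites.append(
            PlannedSite(
                Interval(chrom, center - 200, center + 200),
                score=float(np.round(rng.uniform(20, 80), 1)),
                category="other",
            )
        )

    # post-stimulation: a fraction of enhancer sites moves to inducible promoters,
    # chosen only among multi-site enhancers so the bound set is unchanged
    n_move = round(cfg.site_redistribution_fraction * cfg.n_factor_sites)
    counts: dict[str, int] = {}
    for s in sites:
        if s.category == "enhancer":
            counts[s.enhancer_id] = counts.get(s.enhancer_id, 0) + 1
    movable = [s for s in sites if s.category == "enhancer" and counts[s.enhancer_id] > 1]
    if n_move > len(movable):
        raise PackingError("not enough multi-site enhancers to redistribute from")
    for idx in rng.choice(len(movable), size=n_move, replace=False):
        movable[int(idx)].moves_post = True

    induced = [g for g in ann.genes if g.induced]
    targets = [induced[int(i)] for i in rng.choice(len(induced), size=n_move, replace=False)]
    post: list[PlannedSite] = []
    ti = 0
    for s in sites:
        if s.moves_post:
            g = targets[ti]
            ti += 1
            post.append(
                PlannedSite(
                    Interval(g.chrom, g.tss - 300, g.tss + 300),
                    score=float(np.round(rng.uniform(50, 150), 1)),
                    category="promoter",
                )
            )
        else:
            post.append(dataclasses.replace(s))
    ann.sites_pre = sites
    ann.sites_post = post


# ---------------------------------------------------------------------------
# Tag and peak synthesis


def _window_tags(
    rng: np.random.Generator, chrom: str, lo: int, hi: int, n: int, strand: int
) -> list[tuple[str, int, int, int]]:
    if n == 0 or hi - lo <= READ_LEN:
        return []
    starts = rng.integers(lo, hi - READ_LEN, size=n)
    return [(chrom, int(s), int(s) + READ_LEN, strand) for s in starts]


def _background_tags(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    exclusion: dict[str, np.ndarray],
    stranded: bool,
) -> list[tuple[str, int, int, int]]:
    """Uniform background tags avoiding exclusion zones (sorted [start,end) pairs)."""
    chroms = layout.names
    lengths = np.array([layout.length_of(c) for c in chroms], dtype=float)
    out: list[tuple[str, int, int, int]] = []
    while len(out) < n:
        draw = max(1024, int((n - len(out)) * 1.5))
        ci = rng.choice(len(chroms), size=draw, p=lengths / lengths.sum())
        pos = (rng.random(draw) * (lengths[ci] - READ_LEN)).astype(np.int64)
        strands = rng.choice([1, -1], size=draw) if stranded else rng.choice([1, -1], size=draw)
        for j in range(draw):
            chrom = chroms[ci[j]]
            zones = exclusion.get(chrom)
            p = int(pos[j])
            if zones is not None and len(zones):
                k = np.searchsorted(zones[:, 0], p, side="right") - 1
                if k >= 0 and p < zones[k, 1]:
                    continue
            out.append((chrom, p, p + READ_LEN, int(strands[j])))
            if len(out) == n:
                break
    return out


def _to_tags(rows: list[tuple[str, int, int, int]]) -> Tags:
    buckets: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, s, e, st in rows:
        buckets.setdefault(chrom, []).append((s, e, st))
    data = {}
    for chrom, r in sorted(buckets.items()):
        arr = np.asarray(sorted(r), dtype=np.int64)
        data[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2].astype(np.int8))
    return Tags(data)


def _zones(points: list[tuple[str, int]], half: int) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for chrom, p in points:
        by.setdefault(chrom, []).append((max(0, p - half), p + half))
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in by.items()}


@dataclass
class ChipRnaBundle:
    peaks: dict[str, list[Peak]]
    tags: dict[str, Tags]
    rrna_blacklist: list[Interval]
    repeat_regions: list[Interval]


def simulate_chip_and_rna(cfg: SimulationConfig, ann: AnnotationBundle) -> ChipRnaBundle:
    """Draw peak files and Poisson tag libraries over the planted features.

    Libraries are padded with uniform background tags (kept clear of the
    quantified windows) to a fixed per-library depth so condition-wise
    normalizers match.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    peaks: dict[str, list[Peak]] = {k: [] for k in (
        "p300", "h3k4me1", "h3k4me3", "h3k9ac", "h3k9me3", "h3k27ac", "h3k27me3",
        "ctcf", "factor_unstim", "factor_stim",
    )}

    for g in ann.genes:
        if g.has_me3:
            peaks["h3k4me3"].append(
                Peak(Interval(g.chrom, max(0, g.tss - 500), g.tss + 500), 80.0, mark="h3k4me3")
            )
    for e in ann.enhancers:
        c, s = e.chrom, e.summit
        peaks["p300"].append(Peak(Interval(c, s - 250, s + 250), e.score, summit=s, mark="p300"))
        if e.has_me1:
            peaks["h3k4me1"].append(Peak(Interval(c, s - 700, s + 700), 70.0, mark="h3k4me1"))
        if e.me3_decoy:
            peaks["h3k4me3"].append(Peak(Interval(c, s - 300, s + 300), 80.0, mark="h3k4me3"))
        if e.expected_qualified:
            if e.activity_class == "active":
                peaks["h3k9ac"].append(Peak(Interval(c, s - 400, s + 400), 60.0, mark="h3k9ac"))
                peaks["h3k27ac"].append(Peak(Interval(c, s - 400, s + 400), 60.0, mark="h3k27ac"))
            elif e.activity_class == "poised":
                peaks["h3k9me3"].append(Peak(Interval(c, s - 400, s + 400), 60.0, mark="h3k9me3"))
                peaks["h3k27me3"].append(Peak(Interval(c, s - 400, s + 400), 60.0, mark="h3k27me3"))
    peaks["ctcf"] = ann.ctcf_peaks
    for cond, planned in (("unstim", ann.sites_pre), ("stim", ann.sites_post)):
        peaks[f"factor_{cond}"] = [
            Peak(s.interval, s.score, mark="factor", condition=cond) for s in planned
        ]

    blacklist = [
        Interval(e.chrom, e.summit - 2_100, e.summit + 2_100)
        for e in ann.enhancers
        if e.blacklisted
    ]
    repeats = [
        Interval(e.chrom, e.summit - 2_100, e.summit + 2_100)
        for e in ann.enhancers
        if e.repeat_region
    ]

    tags: dict[str, Tags] = {}
    layout = ann.layout

    # --- stranded RNA libraries -------------------------------------
    erna_zone = _zones([(e.chrom, e.summit) for e in ann.enhancers], 6_000)
    for cond in ("unstim", "stim"):
        rows: list[tuple[str, int, int, int]] = []
        for e in ann.enhancers:
            fold = cfg.erna_induction_fold if (cond == "stim" and e.erna_class == "true") else 1.0
            c, s = e.chrom, e.summit
            for lam, lo, hi, strand in (
                (e.lam_plus_prox * fold, s, s + 2_000, 1),
                (e.lam_minus_prox * fold, s - 2_000, s, -1),
                (e.lam_plus_far, s + 2_000, s + 4_000, 1),
                (e.lam_minus_far, s - 4_000, s - 2_000, -1),
            ):
                if lam > 0:
                    rows += _window_tags(rng, c, lo, hi, rng.poisson(lam), strand)
        n_bg = cfg.rna_depth - len(rows)
        if n_bg < 0:
            raise PackingError("rna_depth smaller than planted eRNA tag count")
        rows += _background_tags(rng, layout, n_bg, erna_zone, stranded=True)
        tags[f"rna_{cond}"] = _to_tags(rows)

    # --- acetylation libraries for the differential stand-in --------
    enh_zone = _zones([(e.chrom, e.summit) for e in ann.enhancers], 1_500)
    for mark in ("h4ac", "h3k9ac"):
        for cond in ("unstim", "stim"):
            rows = []
            for e in ann.enhancers:
                if not e.expected_qualified:
                    continue
                lam = cfg.mark_base_rate
                if cond == "stim" and e.inducible_mark == mark:
                    lam *= cfg.mark_induced_fold
                rows += _window_tags(
                    rng, e.chrom, e.summit - 500, e.summit + 500, rng.poisson(lam), 1
                )
            n_bg = cfg.mark_depth - len(rows)
            if n_bg < 0:
                raise PackingError("mark_depth smaller than planted acetylation tags")
            rows += _background_tags(rng, layout, n_bg, enh_zone, stranded=False)
            tags[f"{mark}_{cond}"] = _to_tags(rows)

    # --- promoter H3K9me2 IP and input libraries --------------------
    tss_zone = _zones([(g.chrom, g.tss) for g in ann.genes], 1_500)
    for cond in ("unstim", "stim"):
        ip_rows, input_rows = [], []
        for g in ann.genes:
            if g.source != "refseq_like":
                continue
            lam = cfg.me2_rate_pre
            if cond == "stim" and g.me2_set == "inducible":
                lam = cfg.me2_rate_post_inducible
            lo, hi = g.tss - 1_000, g.tss + 1_000
            ip_rows += _window_tags(rng, g.chrom, lo, hi, rng.poisson(lam), 1)
            input_rows += _window_tags(rng, g.chrom, lo, hi, rng.poisson(cfg.input_rate), 1)
        for name, rows in (("ip", ip_rows), ("input", input_rows)):
            n_bg = cfg.me2_depth - len(rows)
            if n_bg < 0:
                raise PackingError("me2_depth smaller than planted promoter tags")
            rows += _background_tags(rng, layout, n_bg, tss_zone, stranded=False)
            tags[f"h3k9me2_{name}_{cond}"] = _to_tags(rows)

    return ChipRnaBundle(peaks=peaks, tags=tags, rrna_blacklist=blacklist, repeat_regions=repeats)


def simulate_expression(cfg: SimulationConfig, ann: AnnotationBundle) -> pd.DataFrame:
    """Log2-scale genes x samples expression matrix with planted induction."""
    rng = np.random.default_rng([cfg.seed, 3])
    genes = [g for g in ann.genes if g.source == "refseq_like"]
    n = len(genes)
    k = cfg.n_replicates
    baseline = rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2, size=n)
    effect = np.array([cfg.induced_effect_log2 if g.induced else 0.0 for g in genes])
    unstim = baseline[:, None] + rng.normal(0, cfg.expression_noise_sd, size=(n, k))
    stim = (baseline + effect)[:, None] + rng.normal(0, cfg.expression_noise_sd, size=(n, k))
    cols = [f"unstim_{i + 1}" for i in range(k)] + [f"stim_{i + 1}" for i in range(k)]
    return pd.DataFrame(
        np.round(np.hstack([unstim, stim]), 6),
        index=pd.Index([g.name for g in genes], name="gene"),
        columns=cols,
    )


# ---------------------------------------------------------------------------
# Fixture assembly and serialization


@dataclass
class Fixture:
    cfg: SimulationConfig
    annotation: AnnotationBundle
    chip_rna: ChipRnaBundle
    expression: pd.DataFrame
    truth: SyntheticTruth


def simulate_all(cfg: SimulationConfig) -> Fixture:
    ann = simulate_annotation(cfg)
    chip = simulate_chip_and_rna(cfg, ann)
    expr = simulate_expression(cfg, ann)
    return Fixture(cfg, ann, chip, expr, ann.truth())


def write_fixture(fix: Fixture, outdir: str | Path) -> Path:
    """Write the complete fixture as the text dialects the pipeline reads."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tags").mkdir(exist_ok=True)

    with open(out / "genome.chrom.sizes", "w") as fh:
        for name, length in fix.annotation.layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
    write_gene_table(
        out / "genes_refseq.refflat",
        [g.to_model() for g in fix.annotation.genes if g.source == "refseq_like"],
    )
    write_gene_table(
        out / "genes_est.refflat",
        [g.to_model() for g in fix.annotation.genes if g.source == "est_like"],
    )

    def write_narrowpeak(path: Path, plist: list[Peak]) -> None:
        with open(path, "w") as fh:
            for i, p in enumerate(plist):
                iv = p.interval
                offset = p.resolved_summit - iv.start
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{p.score:g}\t."
                    f"\t0\t-1\t-1\t{offset}\n"
                )

    for name, plist in fix.chip_rna.peaks.items():
        if name in ("p300", "ctcf"):
            write_narrowpeak(out / "peaks" / f"{name}.narrowPeak", plist)
        else:
            write_bed6(
                out / "peaks" / f"{name}.bed",
                [(p.interval, f"{name}_{i}", p.score, ".") for i, p in enumerate(plist)],
            )
    for name, t in fix.chip_rna.tags.items():
        write_tagalign(out / "tags" / f"{name}.tagAlign", t)
    with open(out / "blacklist_rrna.bed", "w") as fh:
        for iv in fix.chip_rna.rrna_blacklist:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(out / "repeats.bed", "w") as fh:
        for iv in fix.chip_rna.repeat_regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    fix.expression.to_csv(out / "expression.tsv", sep="\t")
    fix.truth.manifest.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(fix.cfg), fh, sort_keys=True)
    return out
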