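"""End-to-end orchestration: simulate → extract → classify → MEI/LINE-1
analyses → rates → STR enrichment → duplication summary.

Each stage reads its predecessor's files from the output directory, so
stages are re-runnable in isolation, and the whole run is deterministic
under a fixed configuration and seed (byte-identical report JSON).

Desk-scale note: the default duplication-summary thresholds here are
scaled to the synthetic megabase-scale genome (the classification
functions themselves default to the full-genome values).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .dup_and_identity import (
    filter_and_classify_dup_pairs,
    read_dup_pairs,
    summarize_dup_pairs,
)
from .io_formats import (
    AnnotationSet,
    RepeatAnnotation,
    read_fasta,
    read_pangenome_vcf,
    read_repeatmasker_out,
)
from .line1_biology import (
    GenomeAligner,
    extract_3prime_transduction,
    filter_transduction_alignments,
    find_intact_orfs,
    is_fully_intact,
    resolve_parentless,
)
from .mei_genetics import DERIVED, allele_sharing, identify_clean_mei_loci
from .rates_and_enrichment import (
    count_snp_divergence,
    estimate_insertion_rate,
    filter_line1_3prime_intact,
    str_enrichment,
)
from .repeat_annotation import (
    LibraryAnnotator,
    find_exact_tandem_repeats,
    merge_intervals,
    merge_repeat_annotations,
    sdust_mask,
)
from .sv_classification import classify_locus, classification_summary
from .sv_extraction import allele_body, extract_sv_loci, longest_allele
from .synthetic_data import (
    HAPLOTYPES,
    REFERENCE_SAMPLE,
    SAMPLES,
    CohortParams,
    build_repeat_library,
    emit_cohort,
    simulate_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds, surfaced as named keys (never inline)."""

    outdir: str = "canisv_run"
    seed: int = 0
    simulate: bool = True
    cohort: CohortParams = None  # defaults derived from seed when None
    samples: List[str] = field(default_factory=lambda: list(SAMPLES))
    outgroup_hap: str = "GWsim.1"
    rate_second_hap: str = "ACDsim.1"  # the GW.1-vs-X comparison closing the panel
    # extraction / classification
    min_size_diff: int = 50
    coverage_threshold: float = 0.70
    partial_threshold: float = 0.05
    str_unit_max: int = 6
    vntr_unit_min: int = 7
    min_identity: float = 0.8
    simple_repeat_max_unit: int = 13
    simple_repeat_min_span: int = 20
    # LINE-1 analyses
    orf_min_l1_len: int = 4000
    transduction_min_len: int = 25
    transduction_min_score: float = 25
    transduction_min_unmasked: int = 25
    transduction_proximal_bp: int = 7000
    transduction_max_hits: int = 5
    transduction_span_excess: int = 100
    source_window: int = 1000
    l1_3prime_tolerance: int = 100
    # rates / enrichment
    mu: float = 4.5e-9
    n_perm: int = 100
    # duplication summary (desk-scale defaults for the synthetic genome)
    dup_base_min_len: int = 500
    dup_base_max_div: float = 0.10
    dup_min_len: int = 2000
    dup_max_div: float = 0.05
    dup_tandem_sep: int = 100_000
    dup_centromeric_window: int = 100_000
    # inputs when simulate=False
    vcf: Optional[str] = None
    reference_fasta: Optional[str] = None
    reference_out: Optional[str] = None
    dup_pairs: Optional[str] = None


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float):
        if math.isnan(obj) or math.isinf(obj):
            return None
        return obj
    if hasattr(obj, "item"):  # numpy scalars
        return _json_safe(obj.item())
    return obj


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class AnnotationEngine:
    """Shared allele annotation/classification with per-body caching.

    Wraps the consensus-library annotator, the exact tandem-repeat scan
    (plus RepeatMasker-style Simple_repeat emission for short-unit runs),
    DUST masking and the category decision, so that every stage classifies
    alleles identically and each distinct allele body is processed once.
    """

    def __init__(self, library, config: PipelineConfig):
        self.config = config
        self.library = library
        self.annotator = LibraryAnnotator(library, min_identity=config.min_identity)
        self._annot_cache: Dict[str, Tuple[AnnotationSet, list, list]] = {}
        self._class_cache: Dict[str, object] = {}

    def annotate_body(self, body: str) -> Tuple[AnnotationSet, list, list]:
        hit = self._annot_cache.get(body)
        if hit is not None:
            return hit
        cfg = self.config
        annots = self.annotator.annotate(body)
        trs = find_exact_tandem_repeats(body, max_unit=None)
        for r in trs:
            if r.unit_length <= cfg.simple_repeat_max_unit and r.span >= cfg.simple_repeat_min_span:
                annots.add(
                    RepeatAnnotation(
                        "query", r.start, r.end, f"({r.canonical_unit})n", "Simple_repeat"
                    )
                )
        merged = merge_repeat_annotations(annots)
        dust = sdust_mask(body)
        result = (merged, dust, trs)
        self._annot_cache[body] = result
        return result

    def classify_body(self, body: str):
        hit = self._class_cache.get(body)
        if hit is None:
            cfg = self.config
            merged, dust, trs = self.annotate_body(body)
            hit = classify_locus(
                body, merged, dust, trs,
                coverage_threshold=cfg.coverage_threshold,
                partial_threshold=cfg.partial_threshold,
                str_unit_max=cfg.str_unit_max,
                vntr_unit_min=cfg.vntr_unit_min,
            )
            self._class_cache[body] = hit
        return hit

    def category_of(self, body: str) -> str:
        return self.classify_body(body).category


def run_full_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run every stage and return (and write) the machine-readable report."""
    t0 = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    report: Dict[str, object] = {"config_seed": config.seed}
    stage_times: Dict[str, float] = {}

    def tick(stage: str, start: float) -> None:
        stage_times[stage] = round(time.time() - start, 3)
        log.info("stage %s done in %.1fs", stage, stage_times[stage])

    # ---- stage: simulate ----------------------------------------------------
    t = time.time()
    library = build_repeat_library(config.seed)
    if config.simulate:
        params = config.cohort or CohortParams(seed=config.seed)
        cohort = simulate_cohort(library, params)
        paths = emit_cohort(cohort, os.path.join(config.outdir, "sim"))
        vcf_path = paths["vcf"]
        ref_fa = paths["reference_fasta"]
        ref_out = paths["reference_out"]
        dup_path = paths["dup_pairs"]
    else:
        if not config.vcf or not os.path.exists(config.vcf):
            raise FileNotFoundError(f"input VCF not found: {config.vcf!r} (simulate=False)")
        vcf_path, ref_fa, ref_out, dup_path = (
            config.vcf, config.reference_fasta, config.reference_out, config.dup_pairs,
        )
    tick("simulate", t)

    # ---- stage: extract -----------------------------------------------------
    t = time.time()
    vset = read_pangenome_vcf(vcf_path, config.samples, reference_sample=REFERENCE_SAMPLE)
    loci, filter_counts = extract_sv_loci(vset, config.samples, config.min_size_diff)
    report["filter_counts"] = filter_counts
    tick("extract", t)

    # ---- stage: classify ----------------------------------------------------
    t = time.time()
    engine = AnnotationEngine(library, config)
    annotator = engine.annotator
    annotate_body = engine.annotate_body
    classify_body = engine.classify_body

    for locus in loci:
        locus.classification = classify_body(allele_body(longest_allele(locus)))
    summary = classification_summary(loci)
    report["category_counts"] = {
        cat: {col: int(v) for col, v in row.items()}
        for cat, row in summary["category_table"].iterrows()
    }
    report["n_loci"] = len(loci)
    report["locus_categories"] = {
        locus.locus_id: locus.classification.category
        for locus in loci
        if locus.locus_id is not None
    }
    with open(os.path.join(config.outdir, "classified.tsv"), "w") as fh:
        fh.write("locus_id\tchrom\tpos\tcategory\tn_alleles\tmax_size_diff\n")
        for locus in loci:
            fh.write(
                f"{locus.locus_id}\t{locus.chrom}\t{locus.pos}\t"
                f"{locus.classification.category}\t{len(locus.alleles)}\t{locus.max_size_diff}\n"
            )
    tick("classify", t)

    # ---- stage: MEI genetics ------------------------------------------------
    t = time.time()

    def classify_allele(body: str) -> str:
        return classify_body(body).category

    sinec_loci, sinec_counts = identify_clean_mei_loci(loci, "SINEC", classify_allele)
    line1_loci, line1_counts = identify_clean_mei_loci(loci, "LINE1", classify_allele)
    report["clean_mei_counts"] = {"SINEC": sinec_counts, "LINE1": line1_counts}
    report["sinec_heterogeneity"] = {
        "multi_allele_loci": sum(1 for l in sinec_loci if l.n_derived_distinct > 1),
        "total": len(sinec_loci),
    }
    autosomes = list(vset.contigs) or sorted({l.chrom for l in sinec_loci})
    sharing = allele_sharing(
        sinec_loci, config.samples, autosomes_only=True, autosomes=autosomes,
        focal_sample=config.outgroup_hap.split(".")[0],
    )
    sharing["profile_counts"] = {"+".join(k): v for k, v in sharing["profile_counts"].items()}
    report["sinec_sharing"] = sharing
    tick("mei", t)

    # ---- stage: LINE-1 biology ----------------------------------------------
    t = time.time()
    reference = read_fasta(ref_fa)
    ref_annots = read_repeatmasker_out(ref_out) if ref_out else AnnotationSet()
    aligner = GenomeAligner(reference)
    primary_chroms = list(reference)

    def longest_derived_body(mei) -> str:
        body = max(mei.derived_alleles, key=len)
        return allele_body(body)

    fully_intact = []
    elongated_orf2 = []
    for mei in line1_loci:
        body = longest_derived_body(mei)
        merged, _d, _t = annotate_body(body)
        calls = find_intact_orfs(body, merged, library, min_len=config.orf_min_l1_len)
        if is_fully_intact(calls):
            fully_intact.append(mei.base.locus_id)
        for c in calls:
            if c.intact and c.matches == "ORF2p" and c.insertion_codons >= 10:
                elongated_orf2.append(
                    {"locus_id": mei.base.locus_id, "insertion_codons": c.insertion_codons}
                )
    report["line1_fully_intact"] = {"count": len(fully_intact), "loci": sorted(fully_intact)}
    report["elongated_orf2"] = sorted(elongated_orf2, key=lambda d: d["locus_id"])

    transduction_calls = []
    filter_totals: Dict[str, int] = {}
    for mei in line1_loci:
        body = longest_derived_body(mei)
        merged, dust, _t = annotate_body(body)
        call = extract_3prime_transduction(
            body, merged, min_len=config.transduction_min_len, locus_id=mei.base.locus_id
        )
        if call is None:
            continue
        seg = call.transduced_seq
        seg_annots = annotator.annotate(seg)
        seg_mask = [(a.start, a.end) for a in seg_annots] + [
            (m.start, m.end) for m in sdust_mask(seg)
        ]
        call.alignments = aligner.align(seg, query_id=call.locus_id)
        call, counts = filter_transduction_alignments(
            call,
            (mei.chrom, mei.pos),
            seg_mask,
            primary_chroms,
            min_score=config.transduction_min_score,
            min_unmasked=config.transduction_min_unmasked,
            proximal_bp=config.transduction_proximal_bp,
            max_hits=config.transduction_max_hits,
            span_excess=config.transduction_span_excess,
        )
        for k, v in counts.items():
            filter_totals[k] = filter_totals.get(k, 0) + v
        transduction_calls.append(call)
    resolved, families = resolve_parentless(
        transduction_calls, line1_loci, ref_annots, window=config.source_window
    )
    report["transductions"] = {
        "n_candidates": len(transduction_calls),
        "n_pass": sum(1 for c in resolved if c.status == "PASS"),
        "filter_counts": filter_totals,
        "calls": [
            {
                "locus_id": c.locus_id,
                "status": c.status,
                "fail_reason": c.fail_reason,
                "source_kind": c.source_kind,
                "source_locus": c.source_locus,
            }
            for c in sorted(resolved, key=lambda c: c.locus_id)
        ],
        "families": {
            src: sorted(members) for src, members in sorted(families.items())
        },
    }
    tick("line1", t)

    # ---- stage: rates -------------------------------------------------------
    t = time.time()
    ref_l1_intervals: Dict[str, List[Tuple[int, int]]] = {}
    for a in ref_annots:
        if a.repeat_class.startswith("LINE/L1"):
            ref_l1_intervals.setdefault(a.seq_id, []).append((a.start, a.end))

    def annots_of(mei):
        merged, _d, _t = annotate_body(longest_derived_body(mei))
        return merged

    line1_3p, l1_filter_report = filter_line1_3prime_intact(
        line1_loci, annots_of, len(library.line1_consensus),
        tolerance=config.l1_3prime_tolerance, ref_l1_intervals=ref_l1_intervals,
    )
    report["line1_3prime_filter"] = l1_filter_report

    mask: Dict[str, List[Tuple[int, int]]] = {}
    if dup_path and os.path.exists(dup_path):
        for p in read_dup_pairs(dup_path):
            mask.setdefault(p.chrom_a, []).append((p.start_a, p.end_a))
            mask.setdefault(p.chrom_b, []).append((p.start_b, p.end_b))
    genome_size = sum(len(s) for s in reference.values())
    masked_bp = sum(
        e - s for ivals in mask.values() for s, e in merge_intervals(ivals)
    )
    rate_genome = genome_size - masked_bp

    out_sample, out_hap = config.outgroup_hap.rsplit(".", 1)
    comparisons = [h for h in HAPLOTYPES if h != config.outgroup_hap]

    def derived_in(mei, hap_id: str) -> bool:
        s, _, h = hap_id.rpartition(".")
        return mei.state_of.get((s, int(h))) == DERIVED

    rates = {}
    for etype, pool in (("SINEC", sinec_loci), ("LINE1", line1_3p)):
        ins, snps = [], []
        for hap in comparisons:
            n = sum(1 for m in pool if derived_in(m, hap) and not derived_in(m, config.outgroup_hap))
            d = count_snp_divergence(vset, hap, config.outgroup_hap, mask=mask, autosomes=autosomes)
            ins.append((f"{hap}_vs_{config.outgroup_hap}", n))
            snps.append((f"{hap}_vs_{config.outgroup_hap}", d))
        n = sum(
            1 for m in pool
            if derived_in(m, config.outgroup_hap) and not derived_in(m, config.rate_second_hap)
        )
        d = count_snp_divergence(
            vset, config.outgroup_hap, config.rate_second_hap, mask=mask, autosomes=autosomes
        )
        label = f"{config.outgroup_hap}_vs_{config.rate_second_hap}"
        ins.append((label, n))
        snps.append((label, d))
        est = estimate_insertion_rate(ins, snps, rate_genome, mu=config.mu, element_type=etype)
        rates[etype] = {
            "mean_rate": est.mean_rate,
            "one_in_n_births": est.mean_rate_reciprocal,
            "genome_size": est.genome_size,
            "mu": est.mu,
            "per_comparison": [
                {
                    "label": c.label, "snp_count": c.snp_count,
                    "divergence_generations": c.divergence_generations,
                    "insertion_count": c.insertion_count, "rate": c.rate,
                }
                for c in est.per_comparison
            ],
        }
    report["insertion_rates"] = rates
    tick("rates", t)

    # ---- stage: STR enrichment ----------------------------------------------
    t = time.time()
    chrom_sizes = {c: len(s) for c, s in reference.items()}
    strs: List[Tuple[str, int, int]] = []
    for chrom, seq in reference.items():
        runs = find_exact_tandem_repeats(seq, max_unit=config.str_unit_max)
        for s, e in merge_intervals([(r.start, r.end) for r in runs]):
            strs.append((chrom, s, e))
    classes: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    for a in ref_annots:
        if a.repeat_name.startswith("SINEC"):
            key = "SINEC"
        elif a.repeat_class.startswith("LINE/L1"):
            key = "LINE/L1"
        elif a.repeat_class.startswith("Satellite"):
            key = "Satellite"
        else:
            continue
        classes.setdefault(key, {}).setdefault(a.seq_id, []).append((a.start, a.end))
    enrich = str_enrichment(strs, classes, chrom_sizes, n_perm=config.n_perm, seed=config.seed)
    report["str_enrichment"] = {
        r.class_name: {
            "observed_overlap_bp": r.observed_overlap,
            "mean_permuted_bp": (
                sum(r.permuted_overlaps) / len(r.permuted_overlaps)
                if r.permuted_overlaps else 0.0
            ),
            "fold": r.fold,
        }
        for r in enrich
    }
    report["n_str_intervals"] = len(strs)
    tick("enrichment", t)

    # ---- stage: duplication summary -----------------------------------------
    t = time.time()
    if dup_path and os.path.exists(dup_path):
        pairs = read_dup_pairs(dup_path)
        classified, dup_counts = filter_and_classify_dup_pairs(
            pairs,
            min_len=config.dup_min_len,
            max_div=config.dup_max_div,
            tandem_sep=config.dup_tandem_sep,
            centromeric_window=config.dup_centromeric_window,
            base_min_len=config.dup_base_min_len,
            base_max_div=config.dup_base_max_div,
        )
        dup_summary = summarize_dup_pairs(classified, chrom_sizes)
        report["dup_pairs"] = {"filter_counts": dup_counts, "summary": dup_summary}
    tick("dup", t)

    report["stage_seconds"] = stage_times
    report["total_seconds"] = round(time.time() - t0, 3)
    # stage output hashes (content only, path-independent)
    report["input_hashes"] = {
        os.path.basename(p): _sha256(p)
        for p in (vcf_path, ref_fa, ref_out, dup_path)
        if p and os.path.exists(p)
    }
    safe = _json_safe(report)
    # timings are run-dependent; the persisted report drops them so that
    # identical config+seed produces byte-identical files
    persisted = {k: v for k, v in safe.items() if k not in ("stage_seconds", "total_seconds")}
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(persisted, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return safe
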