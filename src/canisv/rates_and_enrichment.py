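"""Insertion-rate estimation and STR interval enrichment.

The rate estimator calibrates divergence time from SNP counts: two
lineages separated for T generations accumulate D ≈ 2·μ·T·L pairwise
differences over L analyzable bp, so T = D / (2·μ·L) with μ the per-bp
per-generation mutation rate (canine point estimate 4.5e-9).  The
element insertion rate per generation (per "birth") on one lineage is
then r = N / T for N insertions private to that lineage, averaged over a
panel of comparisons against the outgroup haplotype.

STR enrichment follows the shuffle paradigm: every STR interval is
re-placed uniformly at random on the genome (length preserved, chromosome
chosen proportional to its length) and observed overlap bp with an
annotation class is compared with the permuted mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import MISSING, VariantSet
from .mei_genetics import MEILocus
from .repeat_annotation import merge_intervals


def _hap_key(hap_id: str) -> Tuple[str, int]:
    sample, _, h = hap_id.rpartition(".")
    return sample, int(h)


def count_snp_divergence(
    variants: VariantSet,
    hap_a: str,
    hap_b: str,
    mask: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
    autosomes: Optional[Sequence[str]] = None,
) -> int:
    """Count biallelic SNP sites where two haplotypes carry different alleles.

    Only sites where every allele is 1 bp long count; sites inside
    ``mask`` intervals (e.g. regions annotated as duplicated) or off the
    autosome list are excluded.  Haplotype ids are ``"SAMPLE.H"``.
    """
    ka, kb = _hap_key(hap_a), _hap_key(hap_b)
    masked = {c: merge_intervals(iv) for c, iv in (mask or {}).items()}
    autoset = set(autosomes) if autosomes is not None else None
    count = 0
    for rec in variants:
        if autoset is not None and rec.chrom not in autoset:
            continue
        if any(len(a) != 1 for a in rec.alleles):
            continue
        a = rec.allele_of.get(ka, MISSING)
        b = rec.allele_of.get(kb, MISSING)
        if a is MISSING or b is MISSING:
            raise ValueError(f"haplotype missing at {rec.chrom}:{rec.pos}")
        if a == b:
            continue
        ivals = masked.get(rec.chrom, ())
        if any(s <= rec.pos < e for s, e in ivals):
            continue
        count += 1
    return count


def filter_line1_3prime_intact(
    mei_loci: Sequence[MEILocus],
    annots_of,  # Callable[[MEILocus], AnnotationSet] for the longest derived allele
    consensus_length: int,
    tolerance: int = 100,
    ref_l1_intervals: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> Tuple[List[MEILocus], Dict[str, object]]:
    """Keep LINE-1 loci whose annotation reaches the consensus 3' end.

    A locus passes when the LINE-1 annotation of its longest derived
    allele ends within ``tolerance`` bp of the consensus 3' end; failures
    are dominated by intra-LINE-1 deletion variants, which did not arise
    as new insertions.  The report splits removal by whether the locus
    lies inside a LINE-1 annotated in the reference, with the 2x2 table
    and Fisher's exact test.
    """
    from scipy.stats import fisher_exact

    ref_l1 = {c: merge_intervals(iv) for c, iv in (ref_l1_intervals or {}).items()}

    def inside_ref_l1(locus: MEILocus) -> bool:
        for s, e in ref_l1.get(locus.chrom, ()):
            if s <= locus.pos < e:
                return True
        return False

    kept: List[MEILocus] = []
    table = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for locus in mei_loci:
        annots = annots_of(locus)
        cons_ends = [
            a.cons_end
            for a in annots
            if a.repeat_class.startswith("LINE/L1") and a.cons_end is not None
        ]
        ok = bool(cons_ends) and max(cons_ends) >= consensus_length - tolerance
        table[(inside_ref_l1(locus), not ok)] += 1
        if ok:
            kept.append(locus)
    n = len(list(mei_loci))
    removed = n - len(kept)
    contingency = [
        [table[(True, True)], table[(True, False)]],
        [table[(False, True)], table[(False, False)]],
    ]
    if min(sum(r) for r in contingency) > 0:
        odds, p = fisher_exact(contingency)
    else:
        odds, p = float("nan"), float("nan")
    in_ref_total = table[(True, True)] + table[(True, False)]
    out_ref_total = table[(False, True)] + table[(False, False)]
    report = {
        "input": n,
        "kept": len(kept),
        "removed": removed,
        "removed_fraction": removed / n if n else 0.0,
        "removed_fraction_in_ref_l1": (table[(True, True)] / in_ref_total) if in_ref_total else 0.0,
        "removed_fraction_not_in_ref_l1": (table[(False, True)] / out_ref_total) if out_ref_total else 0.0,
        "contingency": contingency,
        "odds_ratio": odds,
        "fisher_p": p,
    }
    return kept, report


@dataclass
class RateComparison:
    label: str
    snp_count: int  # D
    divergence_generations: float  # T = D / (2 mu L)
    insertion_count: int  # N
    rate: float  # r = N / T


@dataclass
class RateEstimate:
    element_type: str
    per_comparison: List[RateComparison]
    mean_rate: float
    mean_rate_reciprocal: float  # "1 in X births"
    mu: float
    genome_size: int

    def self_consistent(self, rel_tol: float = 1e-9) -> bool:
        for c in self.per_comparison:
            t = c.snp_count / (2 * self.mu * self.genome_size)
            if abs(t - c.divergence_generations) > rel_tol * max(1.0, t):
                return False
            r = c.insertion_count / c.divergence_generations if c.divergence_generations else 0.0
            if abs(r - c.rate) > rel_tol * max(1e-12, abs(r)):
                return False
        mean = sum(c.rate for c in self.per_comparison) / len(self.per_comparison)
        return abs(mean - self.mean_rate) <= rel_tol * max(1e-12, mean)


def estimate_insertion_rate(
    insertions_by_comparison: Sequence[Tuple[str, int]],
    snp_by_comparison: Sequence[Tuple[str, int]],
    genome_size: int,
    mu: float = 4.5e-9,
    element_type: str = "SINEC",
) -> RateEstimate:
    """SNP-calibrated insertion rate per generation, averaged over comparisons."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    snps = dict(snp_by_comparison)
    if set(snps) != {label for label, _ in insertions_by_comparison}:
        raise ValueError("comparison labels differ between insertion and SNP lists")
    per: List[RateComparison] = []
    for label, n_ins in insertions_by_comparison:
        d = snps[label]
        if d == 0:
            if n_ins > 0:
                raise ValueError(f"comparison {label}: zero SNP divergence with insertions present")
            per.append(RateComparison(label, 0, 0.0, 0, 0.0))
            continue
        t = d / (2 * mu * genome_size)
        per.append(RateComparison(label, d, t, n_ins, n_ins / t))
    mean_rate = sum(c.rate for c in per) / len(per) if per else 0.0
    reciprocal = round(1.0 / mean_rate) if mean_rate > 0 else float("inf")
    return RateEstimate(
        element_type=element_type,
        per_comparison=per,
        mean_rate=mean_rate,
        mean_rate_reciprocal=reciprocal,
        mu=mu,
        genome_size=genome_size,
    )


# ---------------------------------------------------------------------------
# STR enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    class_name: str
    observed_overlap: int
    permuted_overlaps: List[int]
    fold: float
    n_perm: int
    seed: int


class _CoverageIndex:
    """Prefix-sum index over merged per-chromosome intervals for overlap bp."""

    def __init__(self, intervals: Mapping[str, Sequence[Tuple[int, int]]]):
        self.index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in intervals.items():
            merged = merge_intervals(ivals)
            if not merged:
                continue
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            prefix = np.concatenate(([0], np.cumsum(ends - starts)))
            self.index[chrom] = (starts, ends, prefix)

    def _covered_before(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        starts, ends, prefix = self.index[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        out = np.zeros(pos.shape, dtype=np.int64)
        valid = i >= 0
        iv = i[valid]
        out[valid] = prefix[iv] + np.clip(pos[valid] - starts[iv], 0, ends[iv] - starts[iv])
        return out

    def overlap_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> int:
        if chrom not in self.index:
            return 0
        return int(np.sum(self._covered_before(chrom, ends) - self._covered_before(chrom, starts)))


def str_enrichment(
    strs: Sequence[Tuple[str, int, int]],
    classes: Mapping[str, Mapping[str, Sequence[Tuple[int, int]]]],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 100,
    seed: int = 0,
) -> List[EnrichmentResult]:
    """Shuffle-based enrichment of STR intervals within annotation classes.

    Each permutation re-places every STR interval uniformly at random on
    the genome: the chromosome is drawn proportional to its length and the
    start uniformly so the interval fits; overlaps among placed intervals
    are permitted.  ``fold`` is observed / mean(permuted).  Deterministic
    under ``seed``.
    """
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    lengths = np.array([e - s for _c, s, e in strs], dtype=np.int64)
    if len(lengths) and lengths.max() > sizes.max():
        raise ValueError("an STR interval exceeds every chromosome length")
    indices = {name: _CoverageIndex(ivals) for name, ivals in classes.items()}

    observed: Dict[str, int] = {name: 0 for name in classes}
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in strs:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivals in by_chrom.items():
        s_arr = np.array([s for s, _ in ivals], dtype=np.int64)
        e_arr = np.array([e for _, e in ivals], dtype=np.int64)
        for name, idx in indices.items():
            observed[name] += idx.overlap_bp(chrom, s_arr, e_arr)

    rng = np.random.default_rng(seed)
    permuted: Dict[str, List[int]] = {name: [] for name in classes}
    probs = sizes / sizes.sum()
    for _p in range(n_perm):
        chrom_idx = rng.choice(len(chroms), size=len(lengths), p=probs)
        u = rng.random(len(lengths))
        totals = {name: 0 for name in classes}
        for ci, chrom in enumerate(chroms):
            sel = chrom_idx == ci
            if not sel.any():
                continue
            room = np.maximum(int(chrom_sizes[chrom]) - lengths[sel], 1)
            starts = (u[sel] * room).astype(np.int64)
            ends = np.minimum(starts + lengths[sel], int(chrom_sizes[chrom]))
            for name, idx in indices.items():
                totals[name] += idx.overlap_bp(chrom, starts, ends)
        for name in classes:
            permuted[name].append(totals[name])

    results = []
    for name in classes:
        mean_perm = float(np.mean(permuted[name])) if permuted[name] else 0.0
        if mean_perm > 0:
            fold = observed[name] / mean_perm
        else:
            fold = float("inf") if observed[name] > 0 else float("nan")
        results.append(
            EnrichmentResult(
                class_name=name,
                observed_overlap=observed[name],
                permuted_overlaps=permuted[name],
                fold=fold,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results
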