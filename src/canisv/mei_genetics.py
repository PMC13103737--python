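"""Dimorphic mobile-element genetics: clean loci, heterogeneity, sharing.

A "clean" SINEC or LINE-1 locus is one where every observed allele is
either the 1 bp empty site or an allele classified to the element type.
The empty (pre-insertion) site is the ancestral state, known a priori for
mobile-element insertions, so presence of the element is identity by
descent and allele sharing across samples is directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

from .sv_extraction import SVLocus, allele_body

ANCESTRAL = "ANCESTRAL"
DERIVED = "DERIVED"


@dataclass
class MEILocus:
    base: SVLocus
    mei_type: str  # "SINEC" or "LINE1"
    state_of: Dict[Tuple[str, int], str]  # (sample, hap) -> ANCESTRAL | DERIVED
    derived_alleles: List[str]  # distinct derived allele sequences (anchor included)
    n_derived_distinct: int

    @property
    def chrom(self) -> str:
        return self.base.chrom

    @property
    def pos(self) -> int:
        return self.base.pos

    def samples_with_derived(self) -> FrozenSet[str]:
        return frozenset(s for (s, _h), st in self.state_of.items() if st == DERIVED)


_MEI_CATEGORY = {"SINEC": "SINEC", "LINE1": "LINE/L1"}


def identify_clean_mei_loci(
    loci: Sequence[SVLocus],
    mei_type: str,
    classify_allele: Callable[[str], str],
) -> Tuple[List[MEILocus], Dict[str, int]]:
    """Select loci where every allele is the empty site or the element type.

    ``classify_allele`` maps an allele body (anchor stripped) to a category
    string; it is called once per distinct non-empty allele.  Returns the
    clean loci and exclusion counts by reason.
    """
    want = _MEI_CATEGORY[mei_type]
    kept: List[MEILocus] = []
    counts = {"input": 0, "clean": 0, "no_empty_or_element": 0, "no_derived": 0}
    for locus in loci:
        counts["input"] += 1
        states: Dict[int, str] = {}
        ok = True
        for i, allele in enumerate(locus.alleles):
            if len(allele) == 1:
                states[i] = ANCESTRAL
            elif classify_allele(allele_body(allele)) == want:
                states[i] = DERIVED
            else:
                ok = False
                break
        if not ok:
            counts["no_empty_or_element"] += 1
            continue
        derived = [locus.alleles[i] for i, st in sorted(states.items()) if st == DERIVED]
        if not derived:
            counts["no_derived"] += 1
            continue
        counts["clean"] += 1
        kept.append(
            MEILocus(
                base=locus,
                mei_type=mei_type,
                state_of={k: states[i] for k, i in locus.hap_allele.items()},
                derived_alleles=derived,
                n_derived_distinct=len(set(derived)),
            )
        )
    return kept, counts


def allele_heterogeneity(locus: MEILocus) -> int:
    """Number of distinct derived allele sequences at the locus."""
    return len(set(locus.derived_alleles))


def allele_sharing(
    loci: Sequence[MEILocus],
    samples: Sequence[str],
    autosomes_only: bool = True,
    autosomes: Optional[Sequence[str]] = None,
    focal_sample: Optional[str] = None,
) -> Dict[str, object]:
    """Sharing/zygosity profiles of the derived state across samples.

    Presence is counted per individual (either haplotype).  Loci with no
    ancestral allele observed count as present in every sample.  Output
    includes singleton counts per sample, counts of every non-empty
    presence pattern, per-sample heterozygous/homozygous derived counts,
    and (optionally) conditional sharing fractions given presence in
    ``focal_sample``.
    """
    samples = list(samples)
    if autosomes_only and autosomes is not None:
        autoset = set(autosomes)
        loci = [l for l in loci if l.chrom in autoset]
    singleton: Dict[str, int] = {s: 0 for s in samples}
    het: Dict[str, int] = {s: 0 for s in samples}
    hom: Dict[str, int] = {s: 0 for s in samples}
    profiles: Dict[Tuple[str, ...], int] = {}
    focal_shared: Dict[str, int] = {s: 0 for s in samples}
    focal_total = 0
    for locus in loci:
        present: List[str] = []
        for s in samples:
            st1 = locus.state_of.get((s, 1))
            st2 = locus.state_of.get((s, 2))
            if st1 not in (ANCESTRAL, DERIVED) or st2 not in (ANCESTRAL, DERIVED):
                raise ValueError(f"sample {s} absent from locus {locus.base.locus_id}")
            n_derived = (st1 == DERIVED) + (st2 == DERIVED)
            if n_derived == 1:
                het[s] += 1
                present.append(s)
            elif n_derived == 2:
                hom[s] += 1
                present.append(s)
        if not present:
            continue
        key = tuple(sorted(present))
        profiles[key] = profiles.get(key, 0) + 1
        if len(present) == 1:
            singleton[present[0]] += 1
        if focal_sample is not None and focal_sample in present:
            focal_total += 1
            for s in present:
                focal_shared[s] += 1
    result: Dict[str, object] = {
        "n_loci": len(list(loci)),
        "singleton_counts": singleton,
        "profile_counts": profiles,
        "heterozygous_derived": het,
        "homozygous_derived": hom,
    }
    if focal_sample is not None:
        result["focal_sample"] = focal_sample
        result["focal_present_loci"] = focal_total
        result["focal_shared_fraction"] = {
            s: (focal_shared[s] / focal_total if focal_total else 0.0) for s in samples
        }
    return result
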