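"""Ten-way composition classification of SV locus alleles.

The longest allele of each locus (anchor base stripped) is classified
from three annotation layers: merged repeat annotations, symmetric-DUST
low-complexity intervals, and exact tandem-repeat runs.  The decision
procedure, applied in order with a 70% coverage criterion:

1. a single repeat type (SINEC; LINE/L1; LTR/ERV; anything else pooled as
   OtherRepeat) covering >= 70% of the allele classifies the locus as that
   type;
2. else DUST together with Simple_repeat/Low_complexity annotations
   covering >= 70% classifies it Low Complexity, re-labeled VNTR when
   tandem runs with unit >= 7 bp cover >= 70%, or STR when runs with unit
   <= 6 bp cover >= 70%;
3. else a DUST + repeat-annotation union covering >= 70% is Mixed;
4. else coverage >= 5% is Partial;
5. else Unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, RepeatAnnotation
from .repeat_annotation import MaskedInterval, TandemRepeatRun, union_coverage
from .sv_extraction import SVLocus

CATEGORIES = [
    "SINEC",
    "LINE/L1",
    "LTR/ERV",
    "OtherRepeat",
    "LowComplexity",
    "STR",
    "VNTR",
    "Mixed",
    "Partial",
    "Unclassified",
]

_TYPE_PRIORITY = {"SINEC": 0, "LINE/L1": 1, "LTR/ERV": 2, "OtherRepeat": 3}
_LOWCOMP_CLASSES = {"Simple_repeat", "Low_complexity"}


@dataclass
class LocusClassification:
    category: str
    rm_fraction: float
    dust_fraction: float
    union_fraction: float
    tr_fraction_str: float
    tr_fraction_vntr: float
    type_fractions: Dict[str, float]


def repeat_type_of(annotation: RepeatAnnotation) -> Optional[str]:
    """Map an element annotation to one of the four repeat-type bins."""
    if annotation.repeat_class in _LOWCOMP_CLASSES:
        return None
    if annotation.repeat_name.startswith("SINEC"):
        return "SINEC"
    if annotation.repeat_class.startswith("LINE/L1"):
        return "LINE/L1"
    if annotation.repeat_class.startswith("LTR"):
        return "LTR/ERV"
    return "OtherRepeat"


def classify_locus(
    allele: str,
    annots: AnnotationSet,
    dust: Sequence[MaskedInterval],
    trs: Sequence[TandemRepeatRun],
    coverage_threshold: float = 0.70,
    partial_threshold: float = 0.05,
    str_unit_max: int = 6,
    vntr_unit_min: int = 7,
) -> LocusClassification:
    """Classify one allele body (anchor base already stripped).

    ``annots`` must be the merged annotation set (see
    :func:`~canisv.repeat_annotation.merge_repeat_annotations`).
    """
    length = len(allele)
    if length == 0:
        raise ValueError("allele length must be > 0")

    by_type: Dict[str, List[Tuple[int, int]]] = {}
    lowcomp: List[Tuple[int, int]] = []
    all_rm: List[Tuple[int, int]] = []
    for a in annots:
        all_rm.append(a.interval())
        t = repeat_type_of(a)
        if t is None:
            lowcomp.append(a.interval())
        else:
            by_type.setdefault(t, []).append(a.interval())

    dust_ivals = [(m.start, m.end) for m in dust]
    type_fracs = {t: union_coverage(iv, length) for t, iv in by_type.items()}
    rm_fraction = union_coverage(all_rm, length) if all_rm else 0.0
    dust_fraction = union_coverage(dust_ivals, length) if dust_ivals else 0.0
    lowcomp_union = union_coverage(dust_ivals + lowcomp, length)
    union_fraction = union_coverage(dust_ivals + all_rm, length)
    str_frac = union_coverage(
        [(r.start, r.end) for r in trs if r.unit_length <= str_unit_max], length
    )
    vntr_frac = union_coverage(
        [(r.start, r.end) for r in trs if r.unit_length >= vntr_unit_min], length
    )

    category = "Unclassified"
    winners = [t for t, f in type_fracs.items() if f >= coverage_threshold]
    if winners:
        # larger covered length wins; ties break by category frequency order
        category = min(winners, key=lambda t: (-type_fracs[t], _TYPE_PRIORITY[t]))
    elif lowcomp_union >= coverage_threshold:
        category = "LowComplexity"
        vntr_hit = vntr_frac >= coverage_threshold
        str_hit = str_frac >= coverage_threshold
        if vntr_hit and str_hit:
            category = "STR" if str_frac >= vntr_frac else "VNTR"
        elif vntr_hit:
            category = "VNTR"
        elif str_hit:
            category = "STR"
    elif union_fraction >= coverage_threshold:
        category = "Mixed"
    elif union_fraction >= partial_threshold:
        category = "Partial"

    return LocusClassification(
        category=category,
        rm_fraction=rm_fraction,
        dust_fraction=dust_fraction,
        union_fraction=union_fraction,
        tr_fraction_str=str_frac,
        tr_fraction_vntr=vntr_frac,
        type_fractions=type_fracs,
    )


def count_distinct_alleles(locus: SVLocus) -> Tuple[int, str]:
    """Number of distinct allele sequences carried, and its class.

    Classes follow the pangenome convention: ``biallelic`` (2),
    ``triallelic`` (3), ``multiallelic`` (>3).
    """
    carried = {locus.alleles[i] for i in locus.hap_allele.values()}
    n = len(carried)
    if n <= 2:
        cls = "biallelic"
    elif n == 3:
        cls = "triallelic"
    else:
        cls = "multiallelic"
    return n, cls


def classification_summary(loci: Sequence[SVLocus]) -> Dict[str, pd.DataFrame]:
    """Per-category counts split by allele-count class, plus a size histogram.

    The size histogram uses bins of equal size on a log scale over the
    max-min allele size difference, mirroring the usual SV size-spectrum
    presentation.
    """
    table = pd.DataFrame(
        0, index=CATEGORIES, columns=["biallelic", "triallelic", "multiallelic"]
    )
    diffs: List[int] = []
    for locus in loci:
        if locus.classification is None:
            raise ValueError(f"locus {locus.locus_id} not classified")
        _, cls = count_distinct_alleles(locus)
        table.loc[locus.classification.category, cls] += 1
        diffs.append(locus.max_size_diff)
    if diffs:
        lo = max(1, min(diffs))
        hi = max(diffs)
        edges = np.logspace(np.log10(lo), np.log10(hi + 1), 25)
        counts, edges = np.histogram(diffs, bins=edges)
        hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
    else:
        hist = pd.DataFrame(columns=["bin_low", "bin_high", "count"])
    return {"category_table": table, "size_histogram": hist}
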