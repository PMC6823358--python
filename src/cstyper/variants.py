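"""Somatic/germline variant containers and the pre-analysis filtering stages.

The pipeline consumes per-caller somatic variant tables, merges them with a
2-of-3 consensus rule, and then removes the artifact classes that dominate
noise in formalin-fixed (FFPE) material: poorly mapped reads, shallow sites,
indels at homopolymer runs, cohort-recurrent artifacts, and variants on
aneuploid chromosomes (where allele frequencies are uninterpretable).
Germline variants are reduced to the rare nonsynonymous set.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

__all__ = [
    "SomaticVariant",
    "GermlineVariant",
    "CopyNumberSegment",
    "VariantKey",
    "consensus_merge",
    "apply_ffpe_filters",
    "filter_germline",
    "call_loh",
    "modal_chromosome_ploidy",
]

log = logging.getLogger(__name__)

VariantKey = tuple  # (chrom, pos, ref, alt)

CONSEQUENCES = {"missense", "truncating", "inframe", "synonymous", "splice"}

# printed thresholds of the filtering scheme
MIN_MAPPING_QUALITY = 30       # variants below are removed
MIN_SOMATIC_DEPTH = 50         # "read depth < 50" removed; depth 50 retained
HOMOPOLYMER_MIN_RUN = 5        # "more than 4 of the same successive nucleotides"
LOH_VAF_THRESHOLD = 0.6        # LOH iff VAF > 0.6, strict
GERMLINE_MIN_DEPTH = 20        # germline kept iff depth > 20
GERMLINE_MIN_VAF = 0.2         # ... and VAF > 0.2
GERMLINE_MAX_MAF = 0.01        # ... and population MAF < 0.01
DEFAULT_RECURRENCE_THRESHOLD = 2


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call, the unit every filter and merge acts on."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    consequence: str = "missense"
    vaf: float = 0.0
    depth: int = 0
    mapping_quality: float = 60.0
    component_id: str = "bulk"
    callers: frozenset = frozenset()
    origin: str = "somatic"
    ref_context: str | None = None  # +/- 6 bp of reference around pos (13 bp)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence != "synonymous"


@dataclass(frozen=True)
class GermlineVariant(SomaticVariant):
    population_maf: float = 0.0
    pathogenicity: str = "VUS"  # input flag: pathogenic/likely_pathogenic/VUS/benign
    origin: str = "germline"

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.population_maf <= 1.0:
            raise ValueError("population_maf must be in [0,1]")
        if self.pathogenicity not in {"pathogenic", "likely_pathogenic", "VUS", "benign"}:
            raise ValueError(f"unknown pathogenicity {self.pathogenicity!r}")

    @property
    def is_pathogenic(self) -> bool:
        return self.pathogenicity in {"pathogenic", "likely_pathogenic"}


@dataclass(frozen=True)
class CopyNumberSegment:
    """Per-sample genomic interval with log2 ratio and integer copy number.

    Coordinates are 1-based and inclusive at both ends (SEG convention here,
    unlike BED).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    integer_cn: int
    baf: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.integer_cn < 0:
            raise ValueError("integer_cn must be non-negative")
        if self.baf is not None and not 0.0 <= self.baf <= 1.0:
            raise ValueError("baf must be in [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# consensus merge of per-caller tables
# ---------------------------------------------------------------------------

def consensus_merge(calls_per_caller: dict, min_callers: int = 2) -> list:
    """Merge per-caller variant tables, keeping calls supported by >= 2 callers.

    Parameters
    ----------
    calls_per_caller
        Mapping ``caller name -> iterable of SomaticVariant``.  A duplicate
        variant key within a single caller's table is a malformed input and
        raises.
    min_callers
        Minimum number of supporting callers (default 2 of 3).

    Returns
    -------
    list of SomaticVariant with the ``callers`` field recording supporters
    and VAF/depth set to the median across supporting callers.
    """
    by_key: dict = defaultdict(dict)  # key -> caller -> variant
    for caller, variants in calls_per_caller.items():
        seen = set()
        for v in variants:
            if v.key in seen:
                raise ValueError(
                    f"duplicate variant key {v.key} in caller {caller!r}"
                )
            seen.add(v.key)
            by_key[v.key][caller] = v
    merged = []
    for key in sorted(by_key):
        supporters = by_key[key]
        if len(supporters) < min_callers:
            continue
        callers = sorted(supporters)
        vafs = [supporters[c].vaf for c in callers]
        depths = [supporters[c].depth for c in callers]
        base = supporters[callers[0]]
        merged.append(
            replace(
                base,
                vaf=float(statistics.median(vafs)),
                depth=int(round(statistics.median(depths))),
                callers=frozenset(callers),
            )
        )
    return merged


# ---------------------------------------------------------------------------
# FFPE artifact filters
# ---------------------------------------------------------------------------

def _indel_at_homopolymer(v: SomaticVariant) -> bool:
    """True when an indel sits at the edge of a >=5-base homopolymer run.

    The variant's reference context (13 bp, variant position at the center)
    is scanned for maximal single-base runs; a run of length >= 5 starting or
    ending within 1 bp of the indel's reference footprint triggers the
    filter.
    """
    if v.variant_class != "indel":
        return False
    if not v.ref_context:
        raise ValueError(
            f"indel {v.chrom}:{v.pos} {v.ref}>{v.alt} lacks reference context"
        )
    ctx = v.ref_context.upper()
    center = len(ctx) // 2
    var_start = center
    var_end = center + len(v.ref) - 1
    i = 0
    while i < len(ctx):
        j = i
        while j + 1 < len(ctx) and ctx[j + 1] == ctx[i]:
            j += 1
        run_len = j - i + 1
        if run_len >= HOMOPOLYMER_MIN_RUN and i <= var_end + 1 and j >= var_start - 1:
            return True
        i = j + 1
    return False


def apply_ffpe_filters(
    variants,
    cohort_recurrence: dict | None = None,
    whitelist: set | None = None,
    chrom_ploidy: dict | None = None,
    recurrence_threshold: int = DEFAULT_RECURRENCE_THRESHOLD,
) -> list:
    """Remove FFPE-type artifact classes from a somatic variant list.

    The five criteria are independent; a variant survives iff it passes all
    of them, so the result does not depend on evaluation order.

    Parameters
    ----------
    cohort_recurrence
        Mapping variant key -> number of cohort samples carrying it.
    whitelist
        Keys exempt from the recurrence filter (known hotspot catalogue).
    chrom_ploidy
        Mapping chromosome -> modal integer copy number; chromosomes whose
        ploidy differs from 2 are treated as aneuploid and their variants
        removed.  Missing chromosomes default to 2.
    """
    variants = list(variants)
    cohort_recurrence = cohort_recurrence or {}
    whitelist = whitelist or set()
    chrom_ploidy = chrom_ploidy or {}
    kept = []
    removed = Counter()
    for v in variants:
        fail = []
        if v.mapping_quality < MIN_MAPPING_QUALITY:
            fail.append("mapping_quality")
        if v.depth < MIN_SOMATIC_DEPTH:
            fail.append("depth")
        if _indel_at_homopolymer(v):
            fail.append("homopolymer")
        if (
            cohort_recurrence.get(v.key, 0) >= recurrence_threshold
            and v.key not in whitelist
        ):
            fail.append("recurrent")
        if chrom_ploidy.get(v.chrom, 2) != 2:
            fail.append("aneuploid_chrom")
        if fail:
            removed.update(fail)
        else:
            kept.append(v)
    log.info(
        "FFPE filter: %d in, %d kept, removals by criterion %s",
        len(variants),
        len(kept),
        dict(removed),
    )
    return kept


def filter_germline(variants) -> list:
    """Keep rare nonsynonymous germline variants.

    Retains variants that are nonsynonymous, with read depth > 20, variant
    read frequency > 0.2 and population minor allele frequency < 0.01.
    """
    return [
        v
        for v in variants
        if v.is_nonsynonymous
        and v.depth > GERMLINE_MIN_DEPTH
        and v.vaf > GERMLINE_MIN_VAF
        and v.population_maf < GERMLINE_MAX_MAF
    ]


def call_loh(variant) -> bool:
    """Loss of the wildtype allele: variant read frequency strictly > 0.6."""
    return variant.vaf > LOH_VAF_THRESHOLD


def modal_chromosome_ploidy(segments) -> dict:
    """Length-weighted modal integer copy number per chromosome.

    Used to decide which chromosomes count as aneuploid for the FFPE filter.
    """
    weights: dict = defaultdict(Counter)
    for s in segments:
        weights[s.chrom][s.integer_cn] += s.length
    return {
        chrom: max(sorted(counts), key=lambda cn: counts[cn])
        for chrom, counts in weights.items()
    }
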