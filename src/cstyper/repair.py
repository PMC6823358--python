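"""DNA-repair-deficiency annotation: MMR / HR / non-HRD mechanism per tumor.

Each sample receives exactly one repair call.  Mismatch-repair (MMR)
deficiency is evidenced by MLH1 promoter hypermethylation or biallelic
inactivation of an MMR gene; homologous-recombination (HR) deficiency by
BRCA1/RAD51C promoter hypermethylation, germline inactivation plus LOH of
an HR gene, or somatic PTEN mutation; non-HRD chromosomal instability by
CCNE1 amplification or RB1/NF1 homozygous deletion.  When several
mechanisms co-occur the fixed precedence MMR > HR > non-HRD (and, within a
pathway, hypermethylation > germline+LOH > somatic) picks the reported one;
the rest are kept as secondary evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .variants import call_loh

__all__ = [
    "MMR_GENES",
    "HR_GENES",
    "PromoterMethylation",
    "RepairCall",
    "select_dmr_probes",
    "call_hypermethylation",
    "copy_number_class",
    "gene_copy_number",
    "annotate_repair",
    "annotate_cohort_repair",
]

log = logging.getLogger(__name__)

MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})
HR_GENES = frozenset({"BRCA1", "BRCA2", "ATM", "RAD50", "BLM", "RAD51C", "PTEN"})
METHYLATION_GENES = ("MLH1", "BRCA1", "RAD51C")

#: probe selection: per-probe (max - min) across samples must exceed this
DMR_MIN_RANGE = 0.4
#: ... and the per-probe median across samples must fall below this
DMR_MAX_MEDIAN = 0.1
#: a sample is hypermethylated when its mean beta over selected probes is >= this
HYPERMETHYLATION_BETA = 0.4

AMPLIFICATION_MIN_CN = 6


@dataclass(frozen=True)
class PromoterMethylation:
    """Per-sample beta values over the selected probes of one repair gene."""

    gene: str
    probe_betas: dict  # probe id -> beta in [0, 1]

    def __post_init__(self) -> None:
        if self.gene not in METHYLATION_GENES:
            raise ValueError(f"methylation tracked only for {METHYLATION_GENES}")
        for probe, b in self.probe_betas.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"beta out of [0,1] for probe {probe}: {b}")

    @property
    def mean_beta(self) -> float:
        if not self.probe_betas:
            raise ValueError(f"no probes selected for {self.gene}")
        return float(np.mean(list(self.probe_betas.values())))


@dataclass
class RepairCall:
    pathway: str                 # MMR | HR | nonHRD | none
    mechanism: str | None = None
    gene: str | None = None
    sample_id: str = ""
    evidence: list = field(default_factory=list)  # (pathway, mechanism, gene) triples

    def __post_init__(self) -> None:
        if self.pathway not in {"MMR", "HR", "nonHRD", "none"}:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if (self.pathway == "none") != (self.mechanism is None):
            raise ValueError("pathway 'none' iff mechanism absent")


def select_dmr_probes(beta_matrix) -> list:
    """Probes informative for promoter hypermethylation across a cohort.

    ``beta_matrix`` is a DataFrame-like (probes x samples) or a mapping
    ``probe -> array of betas``.  A probe is kept when its range across
    samples exceeds 0.4 (it varies) and its median is below 0.1 (the
    baseline is unmethylated).  Returns probe ids sorted; empty with a
    warning when nothing survives.
    """
    if hasattr(beta_matrix, "iterrows"):
        items = [(p, row.to_numpy(dtype=float)) for p, row in beta_matrix.iterrows()]
    else:
        items = [(p, np.asarray(v, dtype=float)) for p, v in beta_matrix.items()]
    selected = []
    for probe, betas in items:
        if betas.size < 2:
            raise ValueError("probe selection requires >= 2 samples")
        if (betas.max() - betas.min()) > DMR_MIN_RANGE and np.median(betas) < DMR_MAX_MEDIAN:
            selected.append(probe)
    if not selected:
        log.warning("no probe passed the DMR filters; gene unassessable")
    return sorted(selected)


def call_hypermethylation(sample_betas) -> bool:
    """Hypermethylated iff the mean beta over selected probes is >= 0.4."""
    betas = np.asarray(list(sample_betas.values()) if hasattr(sample_betas, "values")
                       else sample_betas, dtype=float)
    if betas.size == 0:
        raise ValueError("cannot call hypermethylation on an empty probe set")
    return float(betas.mean()) >= HYPERMETHYLATION_BETA


def copy_number_class(integer_cn: int) -> str:
    """Discrete copy-number category from the integer copy number."""
    if integer_cn < 0:
        raise ValueError("integer_cn must be non-negative")
    if integer_cn >= AMPLIFICATION_MIN_CN:
        return "amplification"
    if integer_cn >= 3:
        return "gain"
    if integer_cn == 2:
        return "neutral"
    if integer_cn == 1:
        return "loss"
    return "homozygous_deletion"


def gene_copy_number(segments, locus) -> int | None:
    """Integer copy number of the segment with maximal overlap of a gene locus."""
    chrom, start, end = locus
    best, best_ov = None, 0
    for s in segments:
        if s.chrom != chrom:
            continue
        ov = min(end, s.end) - max(start, s.start) + 1
        if ov > best_ov:
            best, best_ov = s, ov
    return best.integer_cn if best else None


# ---------------------------------------------------------------------------
# the annotator
# ---------------------------------------------------------------------------

def _gene_variants(variants, gene):
    return [v for v in variants if v.gene == gene]


def _biallelic_somatic(somatic, gene) -> "object | None":
    """First somatic truncating hit with biallelic evidence (LOH or 2nd hit)."""
    hits = [v for v in _gene_variants(somatic, gene) if v.is_nonsynonymous]
    truncating = [v for v in hits if v.consequence in {"truncating", "splice"}]
    for v in truncating:
        if call_loh(v) or len(hits) >= 2:
            return v
    return None


def annotate_repair(
    profile,
    selected_probes: dict | None = None,
    gene_loci: dict | None = None,
    mmr_genes=MMR_GENES,
    hr_genes=HR_GENES,
) -> RepairCall:
    """Assign one mutually exclusive repair-deficiency mechanism to a sample.

    Parameters
    ----------
    profile
        A :class:`~cstyper.profiles.TumorProfile`; its ``promoter_betas``
        carry probe betas for MLH1/BRCA1/RAD51C.
    selected_probes
        Mapping gene -> cohort-selected probe ids (see
        :func:`select_dmr_probes`).  When None, all probes present on the
        profile are used.
    gene_loci
        Mapping gene -> (chrom, start, end) for the copy-number-driven
        mechanisms (CCNE1, RB1, NF1).  Genes without a locus or overlapping
        segment are skipped.
    """
    evidence = []  # ordered (pathway, mechanism, gene)

    def betas_for(gene):
        probes = profile.promoter_betas.get(gene, {})
        if selected_probes is not None:
            probes = {p: b for p, b in probes.items() if p in selected_probes.get(gene, ())}
        return probes

    # --- MMR -------------------------------------------------------------
    mlh1 = betas_for("MLH1")
    if mlh1 and call_hypermethylation(mlh1):
        evidence.append(("MMR", "promoter_hypermethylation", "MLH1"))
    for gene in sorted(mmr_genes):
        germ = [
            v for v in profile.germline_variants
            if v.gene == gene and v.is_pathogenic
        ]
        for v in germ:
            second_somatic = any(
                s.is_nonsynonymous for s in _gene_variants(profile.somatic_variants, gene)
            )
            if call_loh(v) or second_somatic:
                evidence.append(("MMR", "germline_plus_LOH", gene))
                break
        som = _biallelic_somatic(profile.somatic_variants, gene)
        if som is not None:
            evidence.append(("MMR", "somatic_biallelic", gene))

    # --- HR --------------------------------------------------------------
    for gene in ("BRCA1", "RAD51C"):
        b = betas_for(gene)
        if b and call_hypermethylation(b):
            evidence.append(("HR", "promoter_hypermethylation", gene))
    for gene in sorted(hr_genes - {"PTEN"}):
        for v in profile.germline_variants:
            if v.gene == gene and v.is_pathogenic and call_loh(v):
                evidence.append(("HR", "germline_plus_LOH", gene))
                break
    if any(
        v.is_nonsynonymous for v in _gene_variants(profile.somatic_variants, "PTEN")
    ):
        evidence.append(("HR", "somatic_PTEN", "PTEN"))

    # --- non-HRD chromosomal instability ----------------------------------
    gene_loci = gene_loci or {}
    for gene, mechanism in (
        ("CCNE1", "CCNE1_amplification"),
        ("RB1", "RB1_homozygous_deletion"),
        ("NF1", "NF1_homozygous_deletion"),
    ):
        locus = gene_loci.get(gene)
        if locus is None:
            continue
        cn = gene_copy_number(profile.segments, locus)
        if cn is None:
            continue
        cls = copy_number_class(cn)
        if gene == "CCNE1" and cls == "amplification":
            evidence.append(("nonHRD", mechanism, gene))
        elif gene in {"RB1", "NF1"} and cls == "homozygous_deletion":
            evidence.append(("nonHRD", mechanism, gene))

    if not evidence:
        return RepairCall("none", sample_id=profile.sample_id)

    pathway_rank = {"MMR": 0, "HR": 1, "nonHRD": 2}
    mechanism_rank = {
        "promoter_hypermethylation": 0,
        "germline_plus_LOH": 1,
        "somatic_biallelic": 2,
        "somatic_PTEN": 3,
        "CCNE1_amplification": 0,
        "RB1_homozygous_deletion": 1,
        "NF1_homozygous_deletion": 2,
    }
    evidence.sort(key=lambda e: (pathway_rank[e[0]], mechanism_rank[e[1]], e[2]))
    top = evidence[0]
    return RepairCall(
        pathway=top[0], mechanism=top[1], gene=top[2],
        sample_id=profile.sample_id, evidence=evidence,
    )


def annotate_cohort_repair(profiles, gene_loci: dict | None = None) -> list:
    """Cohort-level annotation: select DMR probes across samples, then call.

    Probe selection for each methylation-tracked gene pools the betas of
    every sample, mirroring the cohort-wide differential-methylation rule;
    per-sample hypermethylation is then judged on the selected probes only.
    """
    selected: dict = {}
    for gene in METHYLATION_GENES:
        probes: dict = {}
        for p in profiles:
            for probe, b in p.promoter_betas.get(gene, {}).items():
                probes.setdefault(probe, []).append(b)
        matrix = {probe: np.asarray(v) for probe, v in probes.items() if len(v) >= 2}
        selected[gene] = set(select_dmr_probes(matrix)) if matrix else set()
    return [
        annotate_repair(p, selected_probes=selected, gene_loci=gene_loci)
        for p in profiles
    ]
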