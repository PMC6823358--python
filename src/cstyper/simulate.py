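"""Synthetic cohort generator with recorded ground truth.

Every observable the pipeline consumes is simulated forward from a recorded
truth value, so each analysis stage can be tested as an inverse problem:
subtype labels drive mutation burdens and spectra, planted repair lesions
drive variants/methylation/copy number, planted purity drives the B-allele
frequencies of LOH regions, and planted cancer cell fractions drive VAFs
through the purity/copy-number mixture model with binomial read noise.

The genome model is a synthetic 596-gene panel laid out on 22 chromosomes
(no real reference required): variants live on genes of chr1-12 (kept
diploid), copy-number aberrations on chr13-20 arms, the non-HRD genes
(CCNE1/RB1/NF1) on chr21, and chr22 carries the LOH regions used for
purity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import TumorProfile
from .subtyping import MSI_MARKERS, MsiPanelResult
from .variants import CopyNumberSegment, GermlineVariant, SomaticVariant

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "panel_loci",
    "hotspot_whitelist",
    "generate_cohort",
    "generate_biphasic",
    "generate_multiregion",
    "generate_expression_methylome",
]

SUBTYPES = ("POLE", "MSI", "CNH", "CNL")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CHROM_LENGTH = 150_000_000
ARM_SPLIT = 60_000_000
GENE_LENGTH = 10_000
N_PANEL_GENES = 596

# genes with a role in classification or repair annotation; never used as
# passenger loci
SPECIAL_VARIANT_GENES = (
    "POLE", "PTEN", "ARID1A", "TP53", "PPP2R1A",
    "MLH1", "MSH2", "MSH6", "PMS2",
    "BRCA1", "BRCA2", "ATM", "RAD50", "BLM", "RAD51C",
)
NONHRD_GENES = ("CCNE1", "RB1", "NF1")  # placed on chr21, lesions by copy number

#: a neutral 13-bp reference context (no homopolymer run) given to planted
#: indels so they pass the homopolymer artifact filter
SAFE_CONTEXT = "ACGTGACTGACGT"

POLE_HOTSPOT_CODONS = {"P286R": 286, "V411L": 411, "S297F": 297}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated cohort.

    Burden triples are (min, median, max); counts are drawn from a
    split-lognormal anchored at the printed median and truncated to the
    printed range, with the log-spread capped so the subtype burden
    distributions overlap only in their extreme tails.
    """

    n_samples: int = 109
    subtype_counts: dict = field(default_factory=lambda: {
        "POLE": 11, "MSI": 24, "CNH": 64, "CNL": 10,
    })
    snv_burden: dict = field(default_factory=lambda: {
        "POLE": (190, 479, 1999), "MSI": (8, 55, 207),
        "CNH": (1, 6, 19), "CNL": (1, 5, 19),
    })
    indel_burden: dict = field(default_factory=lambda: {
        "POLE": (1, 3, 56), "MSI": (10, 27, 63),
        "CNH": (0, 1, 6), "CNL": (0, 1, 6),
    })
    cnv_burden: dict = field(default_factory=lambda: {
        "POLE": (0, 1, 28), "MSI": (0, 2, 7),
        "CNH": (1, 17, 48), "CNL": (0, 1, 5),
    })
    # substitution spectrum weights over C>A, C>G, C>T, T>A, T>C, T>G:
    # T>C transitions dominate MSI, T>G transversions dominate POLE
    spectrum: dict = field(default_factory=lambda: {
        "POLE": (0.20, 0.05, 0.30, 0.05, 0.10, 0.30),
        "MSI": (0.05, 0.05, 0.30, 0.05, 0.45, 0.10),
        "CNH": (0.10, 0.10, 0.50, 0.10, 0.15, 0.05),
        "CNL": (0.10, 0.10, 0.50, 0.10, 0.15, 0.05),
    })
    purity_range: tuple = (0.40, 0.95)
    depth: int = 300           # panel-like per-variant coverage
    baf_reads: int = 5000      # aggregated allele reads per LOH region
    read_noise: bool = True
    clonal_fraction: float = 0.75  # fraction of variants planted clonal
    # conditional lesion frequencies within subtypes
    mmr_rate_msi: float = 22 / 24
    hr_rate_cnh: float = 23 / 64
    nonhrd_rate_cnh: float = 17 / 64
    # trunk fraction of shared mutations in biphasic tumors
    trunk_fraction: dict = field(default_factory=lambda: {
        "CNL": 15 / 16, "CNH": 56 / 74, "POLE": 0.30, "MSI": 0.40,
    })

    def __post_init__(self) -> None:
        if set(self.subtype_counts) != set(SUBTYPES):
            raise ValueError(f"subtype_counts must cover {SUBTYPES}")
        if sum(self.subtype_counts.values()) != self.n_samples:
            raise ValueError(
                f"subtype counts {self.subtype_counts} do not sum to "
                f"n_samples={self.n_samples}"
            )
        for rate in (self.mmr_rate_msi, self.hr_rate_cnh, self.nonhrd_rate_cnh):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("lesion rates must be probabilities")
        if self.hr_rate_cnh + self.nonhrd_rate_cnh > 1.0:
            raise ValueError("HR and non-HRD rates within CNH must sum to <= 1")


@dataclass
class SyntheticTruth:
    """Per-sample ground truth behind every generated observable."""

    samples: dict = field(default_factory=dict)  # sample_id -> dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, t in self.samples.items():
            rows.append({
                "sample_id": sid, "subtype": t["subtype"],
                "purity": t["purity"], "ploidy": t["ploidy"],
                "repair_pathway": t["repair"][0],
                "repair_mechanism": t["repair"][1] or "",
                "repair_gene": t["repair"][2] or "",
                "n_snv": t["n_snv"], "n_indel": t["n_indel"], "n_cnv": t["n_cnv"],
                "sarcoma_fraction": t["sarcoma_fraction"],
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

def panel_loci() -> dict:
    """Deterministic gene -> (chrom, start, end) map for the 596-gene panel."""
    loci: dict = {}
    names = list(SPECIAL_VARIANT_GENES)
    n_fillers = N_PANEL_GENES - len(SPECIAL_VARIANT_GENES) - len(NONHRD_GENES)
    names += [f"G{i:04d}" for i in range(1, n_fillers + 1)]
    # chr1..chr20 hold variant/filler genes; chr21 is reserved for the
    # copy-number-driven non-HRD genes; chr22 stays gene-free (LOH regions)
    per_chrom = -(-len(names) // 20)
    for i, gene in enumerate(names):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = 2_000_000 + slot * 4_500_000
        loci[gene] = (chrom, start, start + GENE_LENGTH - 1)
    for j, gene in enumerate(NONHRD_GENES):
        start = 5_000_000 + j * 20_000_000
        loci[gene] = ("chr21", start, start + GENE_LENGTH - 1)
    return loci


def _passenger_pool(loci: dict) -> list:
    """Filler genes on chr1-12 (chromosomes kept diploid by construction)."""
    keep = {f"chr{i}" for i in range(1, 13)}
    return sorted(
        g for g, (c, _, _) in loci.items()
        if g.startswith("G") and c in keep
    )


def hotspot_whitelist(loci: dict | None = None) -> set:
    """Variant keys of the planted POLE hotspots, exempt from the
    cohort-recurrence artifact filter (stands in for a hotspot catalogue)."""
    loci = loci or panel_loci()
    chrom, start, _ = loci["POLE"]
    keys = set()
    for change, codon in POLE_HOTSPOT_CODONS.items():
        pos = start + codon * 3
        keys.add((chrom, pos, "T", "G"))
    return keys


# anchored split-lognormal count model ---------------------------------------

_SIGMA_CLIP = (0.10, 0.55)


def _draw_count(rng, lo: int, med: int, hi: int) -> int:
    z = rng.standard_normal()
    lo_eff = max(lo, 0.5)
    sigma_hi = np.clip(np.log(max(hi, 1) / max(med, 0.5)) / 3.0, *_SIGMA_CLIP)
    sigma_lo = np.clip(np.log(max(med, 0.5) / lo_eff) / 3.0, *_SIGMA_CLIP)
    sigma = sigma_hi if z >= 0 else sigma_lo
    c = max(med, 0.5) * np.exp(z * sigma)
    return int(np.clip(round(c), lo, hi))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _spectrum_alleles(rng, weights) -> tuple:
    cls = SUBSTITUTIONS[rng.choice(len(SUBSTITUTIONS), p=np.asarray(weights) / np.sum(weights))]
    ref, alt = cls.split(">")
    return ref, alt


def _vaf(rng, ccf, purity, depth, noise, tumor_cn=2, normal_cn=2, mult=1):
    expected = ccf * purity * mult / (purity * tumor_cn + (1 - purity) * normal_cn)
    if not noise:
        return expected
    return rng.binomial(depth, expected) / depth


def _plant_snv(rng, sample_id, gene, loci, cfg, purity, used, *,
               protein_change="", consequence=None, ccf=None, vaf=None,
               is_indel=False, spectrum=None):
    chrom, start, end = loci[gene]
    while True:
        pos = int(start + rng.integers(0, GENE_LENGTH))
        if (gene, pos) not in used:
            used.add((gene, pos))
            break
    if is_indel:
        ref, alt = ("AT", "A") if rng.random() < 0.5 else ("A", "AT")
    else:
        ref, alt = _spectrum_alleles(rng, spectrum or cfg.spectrum["CNL"])
    if ccf is None:
        ccf = (
            float(rng.uniform(0.85, 1.0)) if rng.random() < cfg.clonal_fraction
            else float(rng.uniform(0.2, 0.7))
        )
    if vaf is None:
        vaf = _vaf(rng, ccf, purity, cfg.depth, cfg.read_noise)
    if consequence is None:
        consequence = rng.choice(
            ["missense", "synonymous", "truncating"], p=[0.8, 0.1, 0.1]
        )
    v = SomaticVariant(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        gene=gene, protein_change=protein_change, consequence=str(consequence),
        vaf=float(np.clip(vaf, 0.0, 1.0)), depth=cfg.depth,
        mapping_quality=60.0, callers=frozenset({"caller1", "caller2", "caller3"}),
        ref_context=SAFE_CONTEXT if is_indel else None,
    )
    return v, ccf


def _pole_hotspot_variant(rng, sample_id, loci, cfg, purity):
    change, codon = "P286R", POLE_HOTSPOT_CODONS["P286R"]
    chrom, start, _ = loci["POLE"]
    vaf = _vaf(rng, 1.0, purity, cfg.depth, cfg.read_noise)
    return SomaticVariant(
        sample_id=sample_id, chrom=chrom, pos=start + codon * 3, ref="T", alt="G",
        gene="POLE", protein_change=f"p.{change}", consequence="missense",
        vaf=float(np.clip(vaf, 0.0, 1.0)), depth=cfg.depth,
        callers=frozenset({"caller1", "caller2", "caller3"}),
    )


def _cnv_segments(rng, sample_id, subtype, n_cnv):
    """Copy-number segments on chr13-20 arms.

    CNH samples fill a fixed 12-arm signature (consistent gain/loss sign per
    arm, high amplitude), mirroring recurrent arm-level aberrations of
    high-copy-number disease; other subtypes scatter low-amplitude segments.
    """
    arms = [
        (f"chr{c}", 1, ARM_SPLIT) for c in range(13, 21)
    ] + [
        (f"chr{c}", ARM_SPLIT + 1, CHROM_LENGTH) for c in range(13, 21)
    ]
    signature = arms[:12]
    segs = []
    for i in range(n_cnv):
        if subtype == "CNH":
            chrom, a_start, a_end = signature[i % len(signature)]
            sign = 1 if (i % len(signature)) % 2 == 0 else -1
            log2r = sign * float(rng.uniform(0.5, 1.3))
        else:
            chrom, a_start, a_end = arms[rng.integers(0, len(arms))]
            sign = 1 if rng.random() < 0.5 else -1
            log2r = sign * float(rng.uniform(0.3, 0.6))
        length = int(rng.integers(10_000_000, 30_000_000))
        start = int(rng.integers(a_start, max(a_start + 1, a_end - length)))
        cn = max(0, int(round(2 * 2**log2r))) if log2r > 0 else 1
        segs.append(CopyNumberSegment(
            sample_id=sample_id, chrom=chrom, start=start, end=start + length,
            log2_ratio=log2r, integer_cn=cn,
        ))
    return segs


def _loh_segments(rng, sample_id, purity, cfg):
    """Four LOH regions on chr22 whose BAF encodes the planted purity."""
    b = 1.0 / (2.0 - purity)
    segs = []
    for k in range(4):
        baf = b
        if cfg.read_noise:
            baf = rng.binomial(cfg.baf_reads, b) / cfg.baf_reads
        start = 1 + k * 37_000_000
        segs.append(CopyNumberSegment(
            sample_id=sample_id, chrom="chr22", start=start,
            end=start + 36_999_999, log2_ratio=-1.0, integer_cn=1,
            baf=float(np.clip(baf, 0.0, 1.0)),
        ))
    return segs


def _promoter_betas(rng, hypermethylated_gene: str | None) -> dict:
    """Probe betas for MLH1/BRCA1/RAD51C: 5 informative probes per gene plus
    one constitutively intermediate probe that the DMR filters must drop."""
    betas = {}
    for gene in ("MLH1", "BRCA1", "RAD51C"):
        probes = {}
        hyper = gene == hypermethylated_gene
        for k in range(5):
            if hyper:
                probes[f"{gene}_p{k}"] = float(rng.uniform(0.45, 0.85))
            else:
                probes[f"{gene}_p{k}"] = float(rng.uniform(0.0, 0.09))
        probes[f"{gene}_px"] = float(rng.uniform(0.4, 0.6))  # fails median filter
        betas[gene] = probes
    return betas


def _plant_repair_lesion(rng, sample_id, subtype, cfg, loci, purity, used,
                         somatic, germline):
    """Plant at most one repair lesion; returns ((pathway, mechanism, gene),
    hypermethylated_gene)."""
    u = rng.random()
    if subtype == "MSI" and u < cfg.mmr_rate_msi:
        mech = rng.choice(
            ["promoter_hypermethylation", "germline_plus_LOH", "somatic_biallelic"],
            p=[0.6, 0.2, 0.2],
        )
        if mech == "promoter_hypermethylation":
            return ("MMR", "promoter_hypermethylation", "MLH1"), "MLH1"
        gene = str(rng.choice(["MLH1", "MSH2", "MSH6", "PMS2"]))
        if mech == "germline_plus_LOH":
            chrom, start, _ = loci[gene]
            germline.append(GermlineVariant(
                sample_id=sample_id, chrom=chrom,
                pos=int(start + rng.integers(0, GENE_LENGTH)), ref="C", alt="T",
                gene=gene, consequence="truncating", vaf=0.8, depth=120,
                population_maf=0.0, pathogenicity="pathogenic",
            ))
            return ("MMR", "germline_plus_LOH", gene), None
        v, _ = _plant_snv(rng, sample_id, gene, loci, cfg, purity, used,
                          consequence="truncating", vaf=0.7)
        somatic.append(v)
        return ("MMR", "somatic_biallelic", gene), None
    if subtype == "CNH":
        if u < cfg.hr_rate_cnh:
            mech = rng.choice(
                ["promoter_hypermethylation", "germline_plus_LOH", "somatic_PTEN"],
                p=[0.5, 0.3, 0.2],
            )
            if mech == "promoter_hypermethylation":
                gene = str(rng.choice(["BRCA1", "RAD51C"]))
                return ("HR", "promoter_hypermethylation", gene), gene
            if mech == "germline_plus_LOH":
                gene = str(rng.choice(["BRCA1", "BRCA2", "ATM", "RAD50", "BLM"]))
                chrom, start, _ = loci[gene]
                germline.append(GermlineVariant(
                    sample_id=sample_id, chrom=chrom,
                    pos=int(start + rng.integers(0, GENE_LENGTH)), ref="G", alt="A",
                    gene=gene, consequence="truncating", vaf=0.8, depth=150,
                    population_maf=0.0, pathogenicity="pathogenic",
                ))
                return ("HR", "germline_plus_LOH", gene), None
            v, _ = _plant_snv(rng, sample_id, "PTEN", loci, cfg, purity, used,
                              consequence="missense", vaf=0.4)
            somatic.append(v)
            return ("HR", "somatic_PTEN", "PTEN"), None
        if u < cfg.hr_rate_cnh + cfg.nonhrd_rate_cnh:
            # 15:2 CCNE1 amplification vs RB1 homozygous deletion
            if rng.random() < 15 / 17:
                return ("nonHRD", "CCNE1_amplification", "CCNE1"), None
            return ("nonHRD", "RB1_homozygous_deletion", "RB1"), None
    return ("none", None, None), None


def _nonhrd_segment(rng, sample_id, mechanism, loci):
    gene = {"CCNE1_amplification": "CCNE1",
            "RB1_homozygous_deletion": "RB1",
            "NF1_homozygous_deletion": "NF1"}[mechanism]
    chrom, start, end = loci[gene]
    if mechanism == "CCNE1_amplification":
        return CopyNumberSegment(
            sample_id=sample_id, chrom=chrom, start=start - 1_000_000,
            end=end + 1_000_000, log2_ratio=2.0, integer_cn=8,
        )
    return CopyNumberSegment(
        sample_id=sample_id, chrom=chrom, start=start - 1_000_000,
        end=end + 1_000_000, log2_ratio=-3.0, integer_cn=0,
    )


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0):
    """Generate a full cohort of tumor profiles plus its ground truth.

    Returns ``(profiles, truth)``; deterministic given ``seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    loci = panel_loci()
    passengers = _passenger_pool(loci)

    labels = [s for s in SUBTYPES for _ in range(cfg.subtype_counts[s])]
    rng.shuffle(labels)

    profiles, truth = [], SyntheticTruth()
    for i, subtype in enumerate(labels):
        sid = f"CS{i+1:03d}"
        purity = float(rng.uniform(*cfg.purity_range))
        ploidy = float(rng.uniform(2.8, 4.2)) if subtype == "CNH" else float(rng.uniform(1.8, 2.2))
        n_snv = _draw_count(rng, *cfg.snv_burden[subtype])
        n_indel = _draw_count(rng, *cfg.indel_burden[subtype])
        n_cnv = _draw_count(rng, *cfg.cnv_burden[subtype])

        used: set = set()
        somatic: list = []
        germline: list = []
        ccf_truth: dict = {}

        if subtype == "POLE":
            somatic.append(_pole_hotspot_variant(rng, sid, loci, cfg, purity))
            ccf_truth[somatic[-1].key] = 1.0

        # passenger burden (the hotspot counts toward the SNV burden)
        for _ in range(max(0, n_snv - (1 if subtype == "POLE" else 0))):
            gene = passengers[rng.integers(0, len(passengers))]
            v, ccf = _plant_snv(rng, sid, gene, loci, cfg, purity, used,
                                spectrum=cfg.spectrum[subtype])
            somatic.append(v)
            ccf_truth[v.key] = ccf
        for _ in range(n_indel):
            gene = passengers[rng.integers(0, len(passengers))]
            v, ccf = _plant_snv(rng, sid, gene, loci, cfg, purity, used,
                                is_indel=True, consequence="truncating")
            somatic.append(v)
            ccf_truth[v.key] = ccf

        # histotype driver genes (PTEN is reserved for HR lesion planting)
        if subtype in {"POLE", "MSI"} and rng.random() < 0.6:
            v, _ = _plant_snv(rng, sid, "ARID1A", loci, cfg, purity, used,
                              consequence="truncating")
            somatic.append(v)
        if subtype == "CNL" and rng.random() < 0.4:
            v, _ = _plant_snv(rng, sid, "ARID1A", loci, cfg, purity, used,
                              consequence="truncating")
            somatic.append(v)
        if subtype == "CNH" and rng.random() < 0.85:
            v, _ = _plant_snv(rng, sid, "TP53", loci, cfg, purity, used,
                              consequence="missense")
            somatic.append(v)
        if subtype == "CNH" and rng.random() < 0.2:
            v, _ = _plant_snv(rng, sid, "PPP2R1A", loci, cfg, purity, used,
                              consequence="missense")
            somatic.append(v)

        # common benign germline background
        for _ in range(2):
            gene = passengers[rng.integers(0, len(passengers))]
            chrom, start, _ = loci[gene]
            germline.append(GermlineVariant(
                sample_id=sid, chrom=chrom,
                pos=int(start + rng.integers(0, GENE_LENGTH)), ref="A", alt="G",
                gene=gene, consequence="missense", vaf=float(rng.uniform(0.4, 0.6)),
                depth=100, population_maf=0.05, pathogenicity="benign",
            ))

        repair, hyper_gene = _plant_repair_lesion(
            rng, sid, subtype, cfg, loci, purity, used, somatic, germline
        )

        segments = _cnv_segments(rng, sid, subtype, n_cnv)
        if repair[0] == "nonHRD":
            segments.append(_nonhrd_segment(rng, sid, repair[1], loci))
        segments += _loh_segments(rng, sid, purity, cfg)

        if subtype == "MSI":
            n_unstable = 2 + int(rng.binomial(4, 0.5))
        else:
            n_unstable = 1 if rng.random() < 0.1 else 0
        unstable = set(rng.choice(len(MSI_MARKERS), size=n_unstable, replace=False))
        panel = MsiPanelResult({m: (j in unstable) for j, m in enumerate(MSI_MARKERS)})

        sarcoma_fraction = float(rng.uniform(0.1, 0.9))
        age = float(rng.normal(66, 8)) if subtype == "CNH" else float(rng.normal(58, 9))
        if subtype == "CNH":
            hist = str(rng.choice(["serous", "endometrioid", "undifferentiated"],
                                  p=[0.7, 0.2, 0.1]))
        else:
            hist = str(rng.choice(["endometrioid", "serous"], p=[0.9, 0.1]))

        profiles.append(TumorProfile(
            sample_id=sid, somatic_variants=somatic, germline_variants=germline,
            segments=segments, msi_panel=panel, ploidy=ploidy,
            promoter_betas=_promoter_betas(rng, hyper_gene),
            sarcoma_fraction=sarcoma_fraction, age=age,
            carcinoma_histology=hist,
            sarcoma_histology=str(rng.choice(["ESS", "RMS", "CHS", "other"])),
        ))
        truth.samples[sid] = {
            "subtype": subtype, "purity": purity, "ploidy": ploidy,
            "repair": repair, "n_snv": n_snv, "n_indel": n_indel, "n_cnv": n_cnv,
            "sarcoma_fraction": sarcoma_fraction, "ccf": ccf_truth,
        }
    return profiles, truth


# ---------------------------------------------------------------------------
# biphasic and multi-region tumors
# ---------------------------------------------------------------------------

def generate_biphasic(
    config: GeneratorConfig | None = None,
    subtype: str = "CNH",
    seed: int = 0,
    n_mutations: int | None = None,
    n_drivers: int = 3,
):
    """Carcinoma/sarcoma variant sets of one biphasic tumor.

    A shared trunk pool of ``round(f * N)`` mutations (f = the subtype's
    trunk fraction) is given to both components; the rest is split between
    the private branches.  Drivers are planted on the trunk with high
    probability in low-burden subtypes and are allowed on branches in the
    hypermutator subtypes.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    loci = panel_loci()
    passengers = _passenger_pool(loci)
    f = cfg.trunk_fraction[subtype]
    if not 0.0 < f <= 1.0:
        raise ValueError("trunk fraction must be in (0, 1]")
    if n_mutations is None:
        n_mutations = max(
            2, _draw_count(rng, *cfg.snv_burden[subtype])
            + _draw_count(rng, *cfg.indel_burden[subtype])
        )
    purity = float(rng.uniform(*cfg.purity_range))
    n_trunk = int(round(f * n_mutations))
    n_private = n_mutations - n_trunk
    n_ca = n_private // 2
    n_sa = n_private - n_ca
    used: set = set()

    # drivers are part of the mutation totals; place them first, then fill
    # the remaining slots with passengers
    driver_pool = ["TP53", "PTEN", "ARID1A", "PPP2R1A", "PIK3R1", "KRAS"]
    trunk_driver_p = 1.0 if subtype in {"CNL", "CNH"} else 0.6
    slots = {"trunk": n_trunk, "Ca": n_ca, "Sa": n_sa}
    trunk: list = []
    ca_priv: list = []
    sa_priv: list = []
    pools = {"trunk": trunk, "Ca": ca_priv, "Sa": sa_priv}
    drivers = []
    for g in driver_pool[:n_drivers]:
        comp = "trunk" if rng.random() < trunk_driver_p else (
            "Ca" if rng.random() < 0.5 else "Sa")
        if slots[comp] == 0:
            comp = max(slots, key=slots.get)
        if slots[comp] == 0:
            break
        gene = g if g in loci else passengers[rng.integers(0, len(passengers))]
        v, _ = _plant_snv(rng, "BIPH1", gene, loci, cfg, purity, used,
                          ccf=1.0 if comp == "trunk" else None,
                          consequence="missense")
        v = replace(v, component_id=comp)
        drivers.append(v)
        pools[comp].append(v)
        slots[comp] -= 1

    def make(component, ccf):
        gene = passengers[rng.integers(0, len(passengers))]
        v, _ = _plant_snv(rng, "BIPH1", gene, loci, cfg, purity, used, ccf=ccf)
        return replace(v, component_id=component)

    trunk += [make("trunk", 1.0) for _ in range(slots["trunk"])]
    ca_priv += [make("Ca", None) for _ in range(slots["Ca"])]
    sa_priv += [make("Sa", None) for _ in range(slots["Sa"])]

    carcinoma = [replace(v, component_id="Ca") for v in trunk + ca_priv]
    sarcoma = [replace(v, component_id="Sa") for v in trunk + sa_priv]
    truth = {
        "subtype": subtype, "purity": purity,
        "trunk_fraction_requested": f,
        "trunk_fraction_realized": n_trunk / n_mutations,
        "n_trunk": n_trunk, "n_total": n_mutations,
        "drivers": {v.key: v.component_id for v in drivers},
    }
    return carcinoma, sarcoma, truth


def generate_multiregion(
    config: GeneratorConfig | None = None,
    n_regions: int = 4,
    seed: int = 0,
    trunk_mean: float = 30.0,
    branch_mean: float = 8.0,
    homoplasy_rate: float = 0.0,
):
    """Presence matrix of a multi-region tumor with a planted region tree.

    A random bifurcating tree over the regions is drawn; mutation counts
    are Poisson on each edge (internal edges carry at least one mutation so
    the planted topology is identifiable), and each mutation is present in
    exactly the regions below its edge (perfect phylogeny).  With a nonzero
    ``homoplasy_rate`` that fraction of characters gains a second,
    independent origin on another edge.

    Returns ``(matrix, truth)``: a regions x variants DataFrame and a dict
    with the planted splits, per-clade mutation counts and region names.
    """
    if n_regions < 2:
        raise ValueError("need >= 2 regions")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    regions = [f"T{i+1}" for i in range(n_regions)]

    # random bifurcating tree by sequential joining; nodes are leaf sets
    nodes = [frozenset([r]) for r in regions]
    clades = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        clades.append(merged)
    # edges of the rooted tree = every clade (internal) + every leaf,
    # with the root clade acting as the trunk
    edge_clades = [frozenset([r]) for r in regions] + clades
    counts = {}
    for clade in edge_clades:
        is_trunk = len(clade) == n_regions
        is_internal = 1 < len(clade) < n_regions
        mean = trunk_mean if is_trunk else branch_mean
        c = int(rng.poisson(mean))
        if is_trunk or is_internal:
            c = max(1, c)
        counts[clade] = c

    cols, data = [], []
    k = 0
    for clade, c in counts.items():
        for _ in range(c):
            k += 1
            name = f"var{k:04d}"
            present = {r: (r in clade) for r in regions}
            if homoplasy_rate > 0 and rng.random() < homoplasy_rate and len(clade) < n_regions:
                other = edge_clades[rng.integers(0, len(edge_clades))]
                for r in other:
                    present[r] = True
            cols.append(name)
            data.append([int(present[r]) for r in regions])
    matrix = pd.DataFrame(
        np.array(data, dtype=int).T, index=regions, columns=cols
    )
    truth = {
        "regions": regions,
        "splits": frozenset(c for c in clades if 1 < len(c) < n_regions),
        "edge_counts": counts,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# expression + methylome
# ---------------------------------------------------------------------------

def generate_expression_methylome(
    config: GeneratorConfig | None = None,
    n_samples: int = 97,
    seed: int = 0,
    polarity: dict | None = None,
    n_probes: int = 200,
    n_coupled: int = 6,
    expression_noise: float = 0.3,
    beta_noise: float = 0.05,
):
    """Expression and methylation matrices driven by planted EMT mixing.

    Each sample's expression is a mixture of an epithelial and a
    mesenchymal archetype weighted by its planted sarcoma fraction, plus
    Gaussian noise.  A set of ``n_coupled`` CpG probes (named
    ``cg_mir200_*``, emulating the miR-200-family promoter probes) has beta
    values coupled to the mixing fraction; the remaining probes are
    independent noise around probe-specific baselines.

    Returns ``(expression, betas, truth)``: samples x genes log-expression,
    probes x samples betas, and a DataFrame with the planted fractions.
    """
    from .emt import load_marker_polarity

    rng = np.random.default_rng(seed)
    polarity = polarity or load_marker_polarity()
    genes = sorted(polarity)
    mes = np.array([polarity[g] == "mesenchymal" for g in genes])
    epithelial_archetype = np.where(mes, 0.5, 3.0)
    mesenchymal_archetype = np.where(mes, 3.0, 0.5)

    samples = [f"S{i+1:03d}" for i in range(n_samples)]
    frac = rng.uniform(0.0, 1.0, size=n_samples)
    X = (
        np.outer(1 - frac, epithelial_archetype)
        + np.outer(frac, mesenchymal_archetype)
        + rng.normal(0.0, expression_noise, size=(n_samples, len(genes)))
    )
    expression = pd.DataFrame(np.clip(X, 0.0, None), index=samples, columns=genes)

    probe_names = [f"cg_mir200_{i+1}" for i in range(n_coupled)] + [
        f"cg{i+1:05d}" for i in range(n_probes - n_coupled)
    ]
    B = np.empty((n_probes, n_samples))
    for p in range(n_probes):
        if p < n_coupled:
            base = 0.1 + 0.7 * frac
        else:
            base = np.full(n_samples, rng.uniform(0.1, 0.9))
        B[p] = np.clip(base + rng.normal(0.0, beta_noise, size=n_samples), 0.0, 1.0)
    betas = pd.DataFrame(B, index=probe_names, columns=samples)
    truth = pd.DataFrame({"sample_id": samples, "sarcoma_fraction": frac})
    return expression, betas, truth
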