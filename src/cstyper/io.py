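"""Readers/writers for the tabular exchange formats plus pipeline config.

Conventions: all coordinates are 1-based and inclusive at both ends,
including SEG-like segment tables (which therefore differ from BED).  The
mutation table is a TSV with a 12-column documented core
(sample_id, component_id, chrom, pos, ref, alt, gene, protein_change,
consequence, vaf, depth, mapping_quality) and optional extra columns
(origin, callers, population_maf, pathogenicity, ref_context).  VCF input
is a v4.2 subset; the tumor sample column must carry AD and DP, from which
VAF and depth are derived.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .profiles import TumorProfile
from .subtyping import MSI_MARKERS, MsiPanelResult
from .variants import CopyNumberSegment, GermlineVariant, SomaticVariant

__version__ = "0.1.0"

MUTATION_COLUMNS = [
    "sample_id", "component_id", "chrom", "pos", "ref", "alt", "gene",
    "protein_change", "consequence", "vaf", "depth", "mapping_quality",
]
OPTIONAL_COLUMNS = ["origin", "callers", "population_maf", "pathogenicity", "ref_context"]
SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio", "integer_cn", "baf"]


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def write_mutation_tsv(variants, path) -> None:
    rows = []
    for v in variants:
        row = {c: getattr(v, c) for c in MUTATION_COLUMNS}
        row["origin"] = v.origin
        row["callers"] = ",".join(sorted(v.callers))
        row["ref_context"] = v.ref_context or ""
        if isinstance(v, GermlineVariant):
            row["population_maf"] = v.population_maf
            row["pathogenicity"] = v.pathogenicity
        rows.append(row)
    cols = MUTATION_COLUMNS + OPTIONAL_COLUMNS
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    df[cols].to_csv(path, sep="\t", index=False)


def read_mutation_tsv(path) -> list:
    """Parse a mutation TSV into Somatic/Germline variant objects."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # fail fast, naming the file
        raise ValueError(f"malformed mutation table {path}: {exc}") from exc
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            common = dict(
                sample_id=str(row["sample_id"]),
                component_id=str(row.get("component_id", "bulk") or "bulk"),
                chrom=str(row["chrom"]), pos=int(row["pos"]),
                ref=str(row["ref"]), alt=str(row["alt"]),
                gene=str(row["gene"]) if pd.notna(row["gene"]) else "",
                protein_change=(str(row["protein_change"])
                                if pd.notna(row["protein_change"]) else ""),
                consequence=str(row["consequence"]),
                vaf=float(row["vaf"]), depth=int(row["depth"]),
                mapping_quality=float(row["mapping_quality"]),
                callers=frozenset(
                    c for c in str(row.get("callers", "") or "").split(",") if c
                ),
                ref_context=(str(row["ref_context"])
                             if pd.notna(row.get("ref_context")) and row.get("ref_context")
                             else None),
            )
            if str(row.get("origin", "somatic")) == "germline":
                out.append(GermlineVariant(
                    **common,
                    population_maf=float(row.get("population_maf", 0.0) or 0.0),
                    pathogenicity=str(row.get("pathogenicity", "VUS") or "VUS"),
                ))
            else:
                out.append(SomaticVariant(**common))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

def write_vcf(variants, path, sample_id: str | None = None) -> None:
    """Write a minimal VCF 4.2 with AD/DP in the tumor sample column."""
    variants = list(variants)
    sample_id = sample_id or (variants[0].sample_id if variants else "TUMOR")
    lines = [
        "##fileformat=VCFv4.2",
    ] + [
        f"##contig=<ID={c}>" for c in sorted({v.chrom for v in variants})
    ] + [
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
        '##INFO=<ID=PCH,Number=1,Type=String,Description="Protein change">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        alt_reads = int(round(v.vaf * v.depth))
        info = f"GENE={v.gene or '.'};CSQ={v.consequence}"
        if v.protein_change:
            info += f";PCH={v.protein_change}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}"
            f"\tAD:DP\t{v.depth - alt_reads},{alt_reads}:{v.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, sample_id: str | None = None, mapping_quality: float = 60.0) -> list:
    """Read the VCF subset back into SomaticVariant objects (AD/DP required)."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    if not vcf.samples:
        raise ValueError(f"{path}: no sample column")
    sample_id = sample_id or vcf.samples[0]
    out = []
    for rec in vcf:
        ad = rec.format("AD")
        dp = rec.format("DP")
        if ad is None or dp is None:
            raise ValueError(f"{path}: {rec.CHROM}:{rec.POS} lacks AD/DP")
        depth = int(dp[0][0])
        alt_reads = int(ad[0][1])
        out.append(SomaticVariant(
            sample_id=sample_id, chrom=rec.CHROM, pos=rec.POS,
            ref=rec.REF, alt=rec.ALT[0],
            gene=rec.INFO.get("GENE") or "",
            protein_change=rec.INFO.get("PCH") or "",
            consequence=rec.INFO.get("CSQ") or "missense",
            vaf=alt_reads / depth if depth else 0.0,
            depth=depth, mapping_quality=mapping_quality,
        ))
    return out


# ---------------------------------------------------------------------------
# segments, MSI panel, matrices
# ---------------------------------------------------------------------------

def write_seg(segments, path) -> None:
    rows = [{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "log2_ratio": s.log2_ratio, "integer_cn": s.integer_cn,
        "baf": "" if s.baf is None else s.baf,
    } for s in segments]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            baf = row.get("baf")
            out.append(CopyNumberSegment(
                sample_id=str(row["sample_id"]), chrom=str(row["chrom"]),
                start=int(row["start"]), end=int(row["end"]),
                log2_ratio=float(row["log2_ratio"]),
                integer_cn=int(row["integer_cn"]),
                baf=float(baf) if pd.notna(baf) and baf != "" else None,
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_msi_panel(panels: dict, path) -> None:
    """``panels`` maps sample_id -> MsiPanelResult."""
    rows = []
    for sid, panel in panels.items():
        for marker in MSI_MARKERS:
            rows.append({"sample_id": sid, "marker": marker,
                         "unstable": int(panel.flags[marker])})
    pd.DataFrame(rows, columns=["sample_id", "marker", "unstable"]).to_csv(
        path, sep="\t", index=False)


def read_msi_panel(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for sid, grp in df.groupby("sample_id"):
        flags = dict(zip(grp["marker"], grp["unstable"].astype(bool)))
        out[str(sid)] = MsiPanelResult(flags)
    return out


def write_matrix(df: pd.DataFrame, path, index_name: str) -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_beta_matrix(profiles, path, probe_map_path) -> None:
    """Promoter probe betas as probes x samples TSV plus probe -> gene map."""
    probes: dict = {}
    probe_gene = {}
    for p in profiles:
        for gene, d in p.promoter_betas.items():
            for probe, beta in d.items():
                probes.setdefault(probe, {})[p.sample_id] = beta
                probe_gene[probe] = gene
    df = pd.DataFrame(probes).T
    df = df.loc[sorted(probes)] if probes else df
    write_matrix(df, path, "probe")
    pd.DataFrame(
        sorted(probe_gene.items()), columns=["probe", "gene"]
    ).to_csv(probe_map_path, sep="\t", index=False)


def read_beta_matrix(path, probe_map_path) -> dict:
    """Returns ``{sample_id: {gene: {probe: beta}}}``."""
    df = read_matrix(path)
    probe_gene = dict(
        pd.read_csv(probe_map_path, sep="\t").values
    )
    out: dict = {}
    for probe, row in df.iterrows():
        gene = probe_gene[probe]
        for sid, beta in row.items():
            out.setdefault(str(sid), {}).setdefault(gene, {})[probe] = float(beta)
    return out


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id", "purity", "ploidy", "sarcoma_fraction", "age",
    "carcinoma_histology", "sarcoma_histology",
]


def write_cohort(profiles, outdir) -> None:
    """Write a profile bundle: mutations, segments, MSI panel, betas, clinical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = [v for p in profiles for v in p.somatic_variants + p.germline_variants]
    write_mutation_tsv(variants, outdir / "mutations.tsv")
    write_seg([s for p in profiles for s in p.segments], outdir / "segments.seg")
    write_msi_panel({p.sample_id: p.msi_panel for p in profiles if p.msi_panel},
                    outdir / "msi_panel.tsv")
    write_beta_matrix(profiles, outdir / "promoter_betas.tsv",
                      outdir / "probe_gene_map.tsv")
    pd.DataFrame(
        [{c: getattr(p, c) for c in CLINICAL_COLUMNS} for p in profiles],
        columns=CLINICAL_COLUMNS,
    ).to_csv(outdir / "clinical.tsv", sep="\t", index=False)


def read_cohort(indir) -> list:
    indir = Path(indir)
    variants = read_mutation_tsv(indir / "mutations.tsv")
    segments = read_seg(indir / "segments.seg")
    panels = read_msi_panel(indir / "msi_panel.tsv")
    betas = read_beta_matrix(indir / "promoter_betas.tsv", indir / "probe_gene_map.tsv")
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t")
    profiles = []
    for _, row in clinical.iterrows():
        sid = str(row["sample_id"])
        profiles.append(TumorProfile(
            sample_id=sid,
            somatic_variants=[v for v in variants
                              if v.sample_id == sid and v.origin == "somatic"],
            germline_variants=[v for v in variants
                               if v.sample_id == sid and v.origin == "germline"],
            segments=[s for s in segments if s.sample_id == sid],
            msi_panel=panels.get(sid),
            purity=row["purity"] if pd.notna(row["purity"]) else None,
            ploidy=row["ploidy"] if pd.notna(row["ploidy"]) else None,
            promoter_betas=betas.get(sid, {}),
            sarcoma_fraction=(row["sarcoma_fraction"]
                              if pd.notna(row["sarcoma_fraction"]) else None),
            age=row["age"] if pd.notna(row["age"]) else None,
            carcinoma_histology=(str(row["carcinoma_histology"])
                                 if pd.notna(row["carcinoma_histology"]) else None),
            sarcoma_histology=(str(row["sarcoma_histology"])
                               if pd.notna(row["sarcoma_histology"]) else None),
        ))
    return profiles


# ---------------------------------------------------------------------------
# pipeline configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and paths of a pipeline run; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "results"
    n_samples: int = 109
    depth: int = 300
    read_noise: bool = True
    aberration_threshold: float = 0.3
    cnh_count_threshold: float = 8.0
    recurrence_threshold: int = 2
    consensus_reps: int = 1000
    consensus_subsample: float = 0.8
    k_range: tuple = (2, 3, 4)

    def __post_init__(self) -> None:
        if not 0.0 < self.consensus_subsample <= 1.0:
            raise ValueError("consensus_subsample must be in (0,1]")
        if self.aberration_threshold < 0:
            raise ValueError("aberration_threshold must be >= 0")
        if self.depth < 1 or self.n_samples < 1:
            raise ValueError("depth and n_samples must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def sha256(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def write_provenance(outdir, config: PipelineConfig, seed: int, command: str) -> None:
    record = {
        "command": command,
        "seed": seed,
        "config_sha256": config.sha256(),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(outdir, "provenance.json").write_text(json.dumps(record, indent=2) + "\n")
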