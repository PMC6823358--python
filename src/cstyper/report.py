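"""Cohort-level summary tables and association tests."""

from __future__ import annotations

import pandas as pd

from .stats import fisher_exact_two_sided, mann_whitney_u
from .subtyping import driver_mutation_subtype

__all__ = ["cohort_summary", "association_tests", "oncoprint_table"]


def cohort_summary(profiles, subtype_calls, repair_calls=None) -> pd.DataFrame:
    """One row per sample: subtype, burdens, repair call, driver genotype."""
    rows = []
    repair_calls = repair_calls or [None] * len(profiles)
    for p, call, rep in zip(profiles, subtype_calls, repair_calls):
        snvs = [v for v in p.somatic_variants if v.variant_class == "SNV"]
        indels = [v for v in p.somatic_variants if v.variant_class == "indel"]
        driver = driver_mutation_subtype(p.somatic_variants)
        rows.append({
            "sample_id": p.sample_id,
            "subtype": call.label,
            "msi_marker_count": call.msi_marker_count,
            "aberrant_segments": call.aberrant_segment_count,
            "n_snv": len(snvs), "n_indel": len(indels),
            "driver_subtype": driver.label,
            "repair_pathway": rep.pathway if rep else "",
            "repair_mechanism": (rep.mechanism or "") if rep else "",
            "repair_gene": (rep.gene or "") if rep else "",
            "purity": p.purity, "ploidy": p.ploidy,
            "age": p.age, "carcinoma_histology": p.carcinoma_histology,
            "sarcoma_fraction": p.sarcoma_fraction,
        })
    return pd.DataFrame(rows)


def association_tests(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-subtype association tests against histology (Fisher) and age
    (Mann-Whitney), each subtype versus the rest of the cohort."""
    rows = []
    for subtype in sorted(summary["subtype"].unique()):
        in_grp = summary["subtype"] == subtype
        serous = summary["carcinoma_histology"] == "serous"
        if serous.notna().any():
            a = int((in_grp & serous).sum())
            b = int((in_grp & ~serous).sum())
            c = int((~in_grp & serous).sum())
            d = int((~in_grp & ~serous).sum())
            try:
                p_fisher = fisher_exact_two_sided((a, b, c, d))
            except ValueError:
                p_fisher = float("nan")
            rows.append({
                "subtype": subtype, "test": "histology_serous_fisher",
                "statistic": float("nan"), "p_value": p_fisher,
                "table": f"{a}/{b} vs {c}/{d}",
            })
        ages_in = summary.loc[in_grp, "age"].dropna()
        ages_out = summary.loc[~in_grp, "age"].dropna()
        if len(ages_in) and len(ages_out):
            res = mann_whitney_u(ages_in, ages_out)
            rows.append({
                "subtype": subtype, "test": "age_mann_whitney",
                "statistic": res["U"], "p_value": res["p_value"], "table": "",
            })
    return pd.DataFrame(rows)


def oncoprint_table(profiles, repair_calls) -> pd.DataFrame:
    """Long-format alteration table (sample, gene, alteration, origin)."""
    rows = []
    for p, rep in zip(profiles, repair_calls):
        for pathway, mechanism, gene in (rep.evidence or []):
            rows.append({
                "sample_id": p.sample_id, "gene": gene,
                "alteration": mechanism, "pathway": pathway,
                "origin": "germline" if mechanism == "germline_plus_LOH" else "somatic",
            })
        for v in p.somatic_variants:
            if v.gene in {"POLE", "TP53", "PTEN", "ARID1A", "PPP2R1A"} and v.is_nonsynonymous:
                rows.append({
                    "sample_id": p.sample_id, "gene": v.gene,
                    "alteration": v.consequence, "pathway": "",
                    "origin": "somatic",
                })
    return pd.DataFrame(rows, columns=["sample_id", "gene", "alteration", "pathway", "origin"])
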