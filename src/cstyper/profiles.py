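"""Aggregate per-sample record consumed by the classification stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TumorProfile:
    """Everything the pipeline knows about one tumor sample.

    ``promoter_betas`` maps a repair gene (MLH1/BRCA1/RAD51C) to its probe
    beta values, ``{gene: {probe_id: beta}}``.  ``sarcoma_fraction`` is the
    pathologist-estimated mesenchymal content of the bulk sample.
    """

    sample_id: str
    somatic_variants: list = field(default_factory=list)
    germline_variants: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    msi_panel: "object | None" = None
    purity: float | None = None
    ploidy: float | None = None
    promoter_betas: dict = field(default_factory=dict)
    sarcoma_fraction: float | None = None
    age: float | None = None
    carcinoma_histology: str | None = None
    sarcoma_histology: str | None = None
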