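"""EMT scoring from the marker-gene panel and methylome-EMT correlation.

The EMT (epithelial-mesenchymal transition) score of a sample is its
projection on the first principal component of the cohort's
log10(FPKM + 1) expression over an 81-gene marker panel.  PCA is run on
column-centered (not scaled) data; the sign of the component is fixed so
that mesenchymal markers load positively, making high scores mesenchymal.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import spearman_rho, spearman_test

__all__ = [
    "EmtResult",
    "load_marker_polarity",
    "emt_score",
    "score_vs_content",
    "top_variance_probes",
    "probe_emt_correlation",
]

#: fraction of highest-variance probes retained for methylome correlation
TOP_VARIANCE_FRACTION = 0.20


@dataclass
class EmtResult:
    scores: pd.Series              # per-sample PC1 projection, cohort mean 0
    loadings: pd.Series            # per-gene PC1 loading (after orientation)
    orientation_sign: int          # +1 or -1 applied to the raw component
    variance_explained: float


def load_marker_polarity() -> dict:
    """Bundled 81-gene EMT marker panel with epithelial/mesenchymal polarity.

    The shipped panel is a synthetic stand-in list of canonical EMT marker
    genes (see ``data/emt_markers_synthetic.tsv``); it is editable and any
    mapping ``gene -> 'epithelial' | 'mesenchymal'`` may be passed instead.
    """
    ref = importlib.resources.files("cstyper").joinpath("data/emt_markers_synthetic.tsv")
    polarity = {}
    for line in ref.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, pol = line.split("\t")
        polarity[gene] = pol
    return polarity


def emt_score(
    expression: pd.DataFrame,
    polarity: dict | None = None,
    scale: bool = False,
    allow_subset: bool = False,
) -> EmtResult:
    """EMT score = oriented first principal component of marker expression.

    Parameters
    ----------
    expression
        Samples x genes matrix of log-transformed expression
        (log10(FPKM+1) convention).
    polarity
        Mapping gene -> 'epithelial'/'mesenchymal'; defaults to the bundled
        panel.  Genes of the panel missing from the matrix raise unless
        ``allow_subset`` is set.
    scale
        Divide centered columns by their standard deviation before the PCA
        (off by default; log expression is already on a comparable scale).
    """
    polarity = polarity or load_marker_polarity()
    genes = sorted(polarity)
    missing = [g for g in genes if g not in expression.columns]
    if missing:
        if not allow_subset:
            raise ValueError(f"genes missing from expression matrix: {missing}")
        genes = [g for g in genes if g not in missing]
    if expression.shape[0] < 3:
        raise ValueError("EMT scoring requires >= 3 samples")
    X = expression.loc[:, genes].to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        X = X / np.where(sd > 0, sd, 1.0)
    # thin SVD: scores = U * s on the first right singular vector
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[0]
    scores = U[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0

    mes = np.array([polarity[g] == "mesenchymal" for g in genes])
    sign = 1
    if loadings[mes].mean() < loadings[~mes].mean():
        sign = -1
    return EmtResult(
        scores=pd.Series(sign * scores, index=expression.index, name="emt_score"),
        loadings=pd.Series(sign * loadings, index=genes, name="pc1_loading"),
        orientation_sign=sign,
        variance_explained=var_explained,
    )


def score_vs_content(scores, sarcoma_fraction) -> dict:
    """Spearman association of EMT score with sarcoma content.

    Positive rho means higher scores in sarcoma-richer samples (the
    mesenchymal orientation); against carcinoma content the sign flips.
    """
    scores = np.asarray(scores, dtype=float)
    frac = np.asarray(sarcoma_fraction, dtype=float)
    if scores.size < 3:
        raise ValueError("need >= 3 paired samples")
    return spearman_test(scores, frac)


def top_variance_probes(beta_matrix: pd.DataFrame, fraction: float = TOP_VARIANCE_FRACTION):
    """Highest-variance probes of a probes x samples beta matrix.

    Probes are ranked by variance across samples; the top ``fraction`` is
    retained (at least one probe), ties broken by probe id so the selection
    is deterministic and stable under sample permutation.
    """
    if beta_matrix.shape[1] < 2:
        raise ValueError("probe variance needs >= 2 samples")
    var = beta_matrix.var(axis=1, ddof=1)
    n_keep = max(1, int(round(fraction * len(var))))
    order = sorted(var.index, key=lambda p: (-var[p], str(p)))
    return list(order[:n_keep])


def probe_emt_correlation(beta_matrix: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Per-probe Spearman rho between beta values and the EMT score.

    Returns a DataFrame (probe, rho) sorted by rho descending; reported
    descriptively, without multiple-testing adjustment.  Constant probes
    get rho = NaN.
    """
    samples = [s for s in beta_matrix.columns if s in scores.index]
    if len(samples) < 3:
        raise ValueError("need >= 3 matched samples")
    sc = scores.loc[samples].to_numpy(dtype=float)
    rows = []
    for probe, betas in beta_matrix.loc[:, samples].iterrows():
        rho = spearman_rho(betas.to_numpy(dtype=float), sc, on_constant="nan")
        rows.append((probe, rho))
    out = pd.DataFrame(rows, columns=["probe", "rho"])
    return out.sort_values("rho", ascending=False, ignore_index=True)
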