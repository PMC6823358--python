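"""Genomic-aberration subtyping: the POLE / MSI / CNH / CNL decision tree.

Samples are classified in a fixed order: first by a somatic POLE mutation
in the exonuclease (proofreading) domain, then by microsatellite
instability at >= 2 of the 6 panel markers, then by membership of a
high-copy-number-burden consensus cluster (CNH); the remainder is copy
number low (CNL).  A second, independent scheme labels samples by the
mutational status of four histotype driver genes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "MSI_MARKERS",
    "MsiPanelResult",
    "SubtypeCall",
    "DriverMutationSubtype",
    "ConsensusClusterResult",
    "call_pole",
    "call_msi_high",
    "aberrant_segment_count",
    "consensus_cluster",
    "assign_cnh",
    "classify_cohort",
    "classify_subtype",
    "driver_mutation_subtype",
    "default_subtyping_regions",
    "region_log2r_matrix",
]

MSI_MARKERS = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250", "BAT40")
MSI_HIGH_MIN_MARKERS = 2

# POLE proofreading (exonuclease) domain in codon coordinates, and the
# recurrent hotspot substitutions accepted outside strict domain parsing.
POLE_EXONUCLEASE_RANGE = (268, 471)
POLE_HOTSPOTS = frozenset({"P286R", "V411L", "S297F", "A456P", "S459F"})

#: |log2 ratio| at or above which a segment counts as a copy-number aberration
ABERRANT_LOG2R = 0.3
#: scalar fallback / cluster-median threshold for the CNH call
CNH_COUNT_THRESHOLD = 8
#: additive margin over the cohort median for the relative CNH cluster rule
CNH_MEDIAN_MARGIN = 4.0
#: below this many clusterable samples the scalar fallback is used
MIN_CLUSTER_SAMPLES = 10

ENDOMETRIOID_DRIVERS = frozenset({"PTEN", "ARID1A"})
SEROUS_DRIVERS = frozenset({"TP53", "PPP2R1A"})

_PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Za-z\*])(\d+)")


@dataclass(frozen=True)
class MsiPanelResult:
    """Stability flags for the six-marker microsatellite panel."""

    flags: dict

    def __post_init__(self) -> None:
        if set(self.flags) != set(MSI_MARKERS):
            raise ValueError(
                f"MSI panel must cover exactly markers {MSI_MARKERS}, "
                f"got {sorted(self.flags)}"
            )

    @property
    def unstable_count(self) -> int:
        return sum(bool(v) for v in self.flags.values())


@dataclass
class SubtypeCall:
    label: str  # POLE | MSI | CNH | CNL
    sample_id: str = ""
    pole_evidence: "object | None" = None
    msi_marker_count: int = 0
    cn_cluster_id: int | None = None
    aberrant_segment_count: int = 0

    def __post_init__(self) -> None:
        if self.label not in {"POLE", "MSI", "CNH", "CNL"}:
            raise ValueError(f"unknown subtype label {self.label!r}")
        if self.label == "POLE" and self.pole_evidence is None:
            raise ValueError("POLE call requires pole_evidence")
        if self.label == "MSI" and self.msi_marker_count < MSI_HIGH_MIN_MARKERS:
            raise ValueError("MSI call requires >= 2 unstable markers")


@dataclass(frozen=True)
class DriverMutationSubtype:
    label: str  # endometrioid_like | serous_like | unclassified
    genes: frozenset = frozenset()
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if (self.label == "unclassified") != (len(self.genes) == 0):
            raise ValueError("unclassified iff triggering gene set is empty")


def _codon_of(protein_change: str) -> int | None:
    m = _PROTEIN_CHANGE_RE.match(protein_change or "")
    return int(m.group(2)) if m else None


def call_pole(
    somatic_variants,
    exonuclease_range: tuple = POLE_EXONUCLEASE_RANGE,
    hotspot_list=POLE_HOTSPOTS,
):
    """Return the first somatic POLE exonuclease-domain variant, or None.

    A variant qualifies when it is a nonsynonymous POLE mutation whose codon
    falls in the exonuclease domain, or whose protein change matches a known
    hotspot.  Variants with unparseable protein changes are skipped.
    """
    lo, hi = exonuclease_range
    hotspots = {h.removeprefix("p.") for h in hotspot_list}
    for v in somatic_variants:
        if v.gene != "POLE" or not v.is_nonsynonymous:
            continue
        change = (v.protein_change or "").removeprefix("p.")
        if change in hotspots:
            return v
        codon = _codon_of(v.protein_change)
        if codon is None:
            continue
        if lo <= codon <= hi:
            return v
    return None


def call_msi_high(panel: MsiPanelResult) -> bool:
    """MSI-high: instability at 2 or more of the 6 panel markers."""
    return panel.unstable_count >= MSI_HIGH_MIN_MARKERS


def aberrant_segment_count(segments, threshold: float = ABERRANT_LOG2R) -> int:
    """Number of segments whose |log2 ratio| reaches the aberration threshold."""
    return sum(1 for s in segments if abs(s.log2_ratio) >= threshold)


# ---------------------------------------------------------------------------
# consensus clustering of region-level copy number
# ---------------------------------------------------------------------------

@dataclass
class ConsensusClusterResult:
    labels: np.ndarray              # cluster id per sample, for chosen k
    chosen_k: int
    consensus: dict                 # k -> (n, n) consensus matrix
    cdf_areas: dict                 # k -> area under the consensus CDF
    pac: dict                       # k -> proportion of ambiguous clustering


def consensus_cluster(
    matrix,
    k_range=(2, 3, 4),
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    k_selection: str = "pac",
) -> ConsensusClusterResult:
    """Subsampled k-means consensus clustering of a samples x regions matrix.

    For each candidate ``k``, ``reps`` random subsamples of ``subsample`` of
    the samples are clustered with k-means (Euclidean distance); the
    consensus matrix holds, for every sample pair, the fraction of
    co-subsampled runs in which the pair co-clustered.  Final labels for the
    chosen ``k`` come from average-linkage hierarchical clustering of
    ``1 - consensus``.

    ``k_selection`` is either ``"pac"`` (minimise the proportion of
    ambiguous consensus values, the stabler automatic rule) or
    ``"delta_area"`` (maximal relative change in the area under the
    consensus CDF).
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("consensus clustering requires >= 2 samples")
    k_range = [int(k) for k in k_range]
    if any(k >= n for k in k_range):
        raise ValueError(f"every k must be < n_samples={n}")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))

    consensus: dict = {}
    for k in k_range:
        hits = np.zeros((n, n))
        pair_counts = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            sub = X[idx]
            with warnings.catch_warnings():
                # empty clusters are expected for k above the true structure
                warnings.simplefilter("ignore")
                _, lab = kmeans2(sub, k, minit="++", seed=rng, missing="warn")
            pair_counts[np.ix_(idx, idx)] += 1
            for c in range(k):
                members = idx[lab == c]
                hits[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore"):
            cons = np.where(pair_counts > 0, hits / np.maximum(pair_counts, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        consensus[k] = cons

    areas, pac = {}, {}
    for k in k_range:
        tri = consensus[k][np.triu_indices(n, k=1)]
        xs = np.sort(tri)
        # area under the empirical CDF on [0, 1]
        areas[k] = float(1.0 - xs.mean())
        pac[k] = float(np.mean((tri > 0.1) & (tri < 0.9)))

    ks = sorted(k_range)
    if k_selection == "pac":
        chosen = min(ks, key=lambda k: (round(pac[k], 12), k))
    elif k_selection == "delta_area":
        delta = {ks[0]: areas[ks[0]]}
        for prev, k in zip(ks, ks[1:]):
            delta[k] = (areas[k] - areas[prev]) / max(areas[prev], 1e-12)
        chosen = max(ks, key=lambda k: (delta[k], -k))
    else:
        raise ValueError(f"unknown k_selection {k_selection!r}")

    dist = 1.0 - consensus[chosen]
    np.fill_diagonal(dist, 0.0)
    agg = AgglomerativeClustering(
        n_clusters=chosen, metric="precomputed", linkage="average"
    )
    labels = agg.fit_predict(dist)
    return ConsensusClusterResult(
        labels=labels, chosen_k=chosen, consensus=consensus,
        cdf_areas=areas, pac=pac,
    )


def assign_cnh(
    labels,
    counts,
    margin: float = CNH_MEDIAN_MARGIN,
    count_threshold: float = CNH_COUNT_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of samples in copy-number-high clusters.

    A cluster is CNH when its median aberrant-segment count exceeds the
    cohort median by ``margin``, or reaches the absolute ``count_threshold``.
    The absolute rule anchors the decision when one class dominates the
    cohort and the relative margin degenerates.
    """
    labels = np.asarray(labels)
    counts = np.asarray(counts, dtype=float)
    if labels.shape != counts.shape:
        raise ValueError("labels and counts must align")
    if labels.size == 0:
        return np.zeros(0, dtype=bool)
    global_median = float(np.median(counts))
    mask = np.zeros(labels.size, dtype=bool)
    for c in np.unique(labels):
        med = float(np.median(counts[labels == c]))
        if med > global_median + margin or med >= count_threshold:
            mask[labels == c] = True
    return mask


def default_subtyping_regions(
    n_chromosomes: int = 22,
    chrom_length: int = 150_000_000,
    arm_split: int = 60_000_000,
) -> list:
    """Chromosome-arm regions over the synthetic genome model.

    Stand-in for a curated subtyping-region list; fully configurable by
    passing an explicit ``[(chrom, start, end), ...]`` wherever a region
    list is accepted.
    """
    regions = []
    for i in range(1, n_chromosomes + 1):
        chrom = f"chr{i}"
        regions.append((chrom, 1, arm_split))
        regions.append((chrom, arm_split + 1, chrom_length))
    return regions


def region_log2r_matrix(profiles, regions=None) -> np.ndarray:
    """Length-weighted mean segment log2 ratio per (sample, region)."""
    if regions is None:
        regions = default_subtyping_regions()
    out = np.zeros((len(profiles), len(regions)))
    for i, p in enumerate(profiles):
        for j, (chrom, start, end) in enumerate(regions):
            w = 0.0
            acc = 0.0
            for s in p.segments:
                if s.chrom != chrom:
                    continue
                ov = min(end, s.end) - max(start, s.start) + 1
                if ov > 0:
                    acc += ov * s.log2_ratio
                    w += ov
            out[i, j] = acc / w if w > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# the decision tree
# ---------------------------------------------------------------------------

def classify_cohort(
    profiles,
    regions=None,
    seed: int = 0,
    k_range=(2, 3, 4),
    reps: int = 1000,
    subsample: float = 0.8,
    aberration_threshold: float = ABERRANT_LOG2R,
) -> list:
    """Run the four-way decision tree over a cohort.

    POLE and MSI assignment are per-sample; the CNH/CNL split is made
    jointly over the remaining samples by consensus clustering of
    region-level copy number, with a scalar aberrant-count fallback for
    small residual cohorts.  Returns one :class:`SubtypeCall` per profile,
    in input order.
    """
    calls: list = [None] * len(profiles)
    residual = []
    for i, p in enumerate(profiles):
        if p.msi_panel is None:
            raise ValueError(f"sample {p.sample_id}: MSI panel missing, cannot classify")
        counts = aberrant_segment_count(p.segments, aberration_threshold)
        pole_ev = call_pole(p.somatic_variants)
        if pole_ev is not None:
            calls[i] = SubtypeCall(
                "POLE", sample_id=p.sample_id, pole_evidence=pole_ev,
                msi_marker_count=p.msi_panel.unstable_count,
                aberrant_segment_count=counts,
            )
        elif call_msi_high(p.msi_panel):
            calls[i] = SubtypeCall(
                "MSI", sample_id=p.sample_id,
                msi_marker_count=p.msi_panel.unstable_count,
                aberrant_segment_count=counts,
            )
        else:
            residual.append(i)

    if residual:
        counts = np.array(
            [aberrant_segment_count(profiles[i].segments, aberration_threshold)
             for i in residual],
            dtype=float,
        )
        cluster_ids = [None] * len(residual)
        if len(residual) >= MIN_CLUSTER_SAMPLES:
            mat = region_log2r_matrix([profiles[i] for i in residual], regions)
            cc = consensus_cluster(
                mat, k_range=k_range, reps=reps, subsample=subsample, seed=seed
            )
            cnh_mask = assign_cnh(cc.labels, counts)
            cluster_ids = [int(c) for c in cc.labels]
        else:
            cnh_mask = counts >= CNH_COUNT_THRESHOLD
        for j, i in enumerate(residual):
            p = profiles[i]
            calls[i] = SubtypeCall(
                "CNH" if cnh_mask[j] else "CNL",
                sample_id=p.sample_id,
                msi_marker_count=p.msi_panel.unstable_count,
                cn_cluster_id=cluster_ids[j],
                aberrant_segment_count=int(counts[j]),
            )
    return calls


def classify_subtype(profile, cohort_profiles=None, **kwargs) -> SubtypeCall:
    """Classify one sample in the context of a cohort.

    The CNH decision is cohort-relative, so the profile is classified
    jointly with ``cohort_profiles`` (defaulting to the profile alone, in
    which case the scalar aberrant-count fallback decides CNH vs CNL).
    """
    cohort = list(cohort_profiles) if cohort_profiles else []
    ids = [id(p) for p in cohort]
    if id(profile) not in ids:
        cohort.append(profile)
        ids.append(id(profile))
    calls = classify_cohort(cohort, **kwargs)
    return calls[ids.index(id(profile))]


def driver_mutation_subtype(somatic_variants) -> DriverMutationSubtype:
    """Histotype genotype from the four major driver genes.

    PTEN/ARID1A mutation -> endometrioid-like (evaluated first); else
    TP53/PPP2R1A -> serous-like; neither -> unclassified.  Samples mutated
    in both gene pairs are endometrioid-like and flagged ambiguous.
    """
    mutated = {
        v.gene for v in somatic_variants
        if v.is_nonsynonymous and v.gene in (ENDOMETRIOID_DRIVERS | SEROUS_DRIVERS)
    }
    endo = mutated & ENDOMETRIOID_DRIVERS
    serous = mutated & SEROUS_DRIVERS
    if endo:
        return DriverMutationSubtype(
            "endometrioid_like", frozenset(endo), ambiguous=bool(serous)
        )
    if serous:
        return DriverMutationSubtype("serous_like", frozenset(serous))
    return DriverMutationSubtype("unclassified")
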