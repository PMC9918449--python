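"""Seasonal waterlogging-stress typology by k-means clustering.

Each season's daily photosynthesis stress trajectory is condensed to six
numbers: the mean stress index within six growth-phase bins defined on the
Zadoks-like decimal growth-stage scale — early juvenile JV1 [10, 21), late
juvenile JV2 [21, 32), floral initiation to heading FIN [32, 65), flowering
to grain fill FL [65, 71), early grain filling GF1 [71, 80) and late grain
filling GF2 [80, 87). (The continuous 1-11 stage code of the simulator is
mapped to that scale through fixed anchor points.) The resulting
six-vectors across years, sites, genotypes and managements are partitioned
into k = 4 clusters by k-means (within-cluster variance minimisation),
then ordered and labelled by severity and onset timing: SW0/WW0 minimal
waterlogging up to SW3/WW3 severe (spring/winter prefix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "PhaseBins",
    "DEFAULT_BINS",
    "zadoks_stage",
    "phase_stress_vector",
    "StressTypology",
    "fit_typology",
    "label_clusters",
    "pattern_frequencies",
]

# Anchors mapping the continuous 1-11 stage code to the decimal (Zadoks-like)
# growth-stage scale used by the phase bins: emergence 10, end of juvenile
# 21, floral initiation 32, flowering 65, start of grain fill 71, end of
# grain fill 87, maturity 90.
_APSIM_ANCHORS = (1.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 11.0)
_ZADOKS_ANCHORS = (0.0, 10.0, 21.0, 32.0, 65.0, 71.0, 87.0, 90.0, 100.0)


def zadoks_stage(stage: float | np.ndarray) -> np.ndarray:
    """Decimal growth stage from the continuous 1-11 stage code."""
    return np.interp(stage, _APSIM_ANCHORS, _ZADOKS_ANCHORS)


@dataclass(frozen=True)
class PhaseBins:
    """Six contiguous half-open intervals on the decimal stage scale."""

    names: tuple[str, ...] = ("JV1", "JV2", "FIN", "FL", "GF1", "GF2")
    edges: tuple[float, ...] = (10.0, 21.0, 32.0, 65.0, 71.0, 80.0, 87.0)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.names) + 1:
            raise ValueError("need one more edge than bin names")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")


DEFAULT_BINS = PhaseBins()


def phase_stress_vector(
    daily: pd.DataFrame, bins: PhaseBins = DEFAULT_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Condense one season's trajectory to per-phase stress means.

    Parameters
    ----------
    daily:
        Season trajectory with columns ``stage`` (continuous 1-11 code) and
        ``oxdef_photo`` (daily stress index, 1 = no stress).

    Returns
    -------
    (means, waterlogged_days)
        ``means[b]`` is the mean ``oxdef_photo`` over days whose decimal
        stage falls in bin ``b`` (NaN if the crop never entered the bin);
        ``waterlogged_days[b]`` counts days in the bin with index < 1.
    """
    if len(daily) == 0:
        raise ValueError("empty trajectory")
    z = zadoks_stage(daily["stage"].to_numpy(dtype=float))
    stress = daily["oxdef_photo"].to_numpy(dtype=float)
    n_bins = len(bins.names)
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    idx = np.digitize(z, bins.edges) - 1  # bin b covers [edge_b, edge_{b+1})
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            means[b] = float(stress[mask].mean())
            counts[b] = int((stress[mask] < 1.0).sum())
    return means, counts


@dataclass
class StressTypology:
    """Fitted k-means typology over six-element phase-stress vectors."""

    k: int
    centroids: np.ndarray  # (k, 6)
    assignments: np.ndarray  # cluster index per season
    within_cluster_ss: float
    total_ss: float
    bins: PhaseBins = DEFAULT_BINS
    labels: list[str] | None = None  # set by label_clusters
    descriptors: list[str] | None = None
    order: np.ndarray | None = None  # severity rank per original cluster

    @property
    def variance_explained(self) -> float:
        if self.total_ss <= 0.0:
            return 1.0
        return 1.0 - self.within_cluster_ss / self.total_ss

    def labelled_assignments(self) -> np.ndarray:
        """Assignments expressed as severity-ordered label strings."""
        if self.labels is None or self.order is None:
            raise ValueError("call label_clusters first")
        rank = self.order
        return np.array([self.labels[rank[a]] for a in self.assignments])

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "within_cluster_ss": self.within_cluster_ss,
            "total_ss": self.total_ss,
            "variance_explained": self.variance_explained,
            "bin_names": list(self.bins.names),
        }
        if self.labels is not None:
            d["labels"] = self.labels
            d["descriptors"] = self.descriptors
            d["severity_rank"] = self.order.tolist()
        return d


def fit_typology(
    vectors: np.ndarray | pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
) -> StressTypology:
    """Partition phase-stress vectors into k clusters minimising
    within-cluster sums of squares (Lloyd's algorithm, k-means++ seeding,
    best of ``n_restarts``; deterministic under a fixed seed).

    Rows containing NaN (phases the crop never entered) must be excluded by
    the caller; they are rejected here.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be 2-D (n_seasons, n_phases)")
    if np.isnan(X).any():
        raise ValueError("vectors contain NaN; drop incomplete seasons first")
    if len(X) < k:
        raise ValueError(f"need at least k={k} vectors, got {len(X)}")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd"
    ).fit(X)
    wss = float(km.inertia_)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    return StressTypology(
        k=k,
        centroids=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        within_cluster_ss=wss,
        total_ss=tss,
    )


#: Centroid element below which a phase counts as stressed for the
#: onset-timing descriptor.
ONSET_THRESHOLD = 0.95


def _descriptor(centroid: np.ndarray, n_bins: int) -> str:
    stressed = np.where(centroid < ONSET_THRESHOLD)[0]
    if stressed.size == 0:
        return "minimal waterlogging"
    onset = int(stressed[0])
    if onset < 2:  # juvenile bins
        timing = "early-onset"
    elif onset == 2:  # floral initiation to heading
        timing = "mid-season"
    else:  # flowering or grain fill
        timing = "late-onset"
    total = float(np.sum(1.0 - centroid))
    severity = "severe" if total > 0.15 * n_bins else "moderate"
    return f"{timing} {severity} waterlogging"


def label_clusters(
    typology: StressTypology, maturity_class: str = "spring"
) -> StressTypology:
    """Order clusters by ascending total stress and attach labels.

    Total stress of a centroid is the sum over phases of (1 - element);
    ties break earlier-onset first. Labels are SW0..SW{k-1} for spring and
    WW0..WW{k-1} for winter, index 0 being minimal waterlogging, each with
    a verbal severity/timing descriptor.
    """
    if maturity_class not in ("spring", "winter"):
        raise ValueError("maturity_class must be 'spring' or 'winter'")
    prefix = "SW" if maturity_class == "spring" else "WW"
    cent = typology.centroids
    total = np.sum(1.0 - cent, axis=1)
    onset = np.array(
        [
            int(np.where(c < ONSET_THRESHOLD)[0][0])
            if (c < ONSET_THRESHOLD).any()
            else cent.shape[1]
            for c in cent
        ]
    )
    # ascending severity; ties: earlier onset first
    order_idx = np.lexsort((onset, np.round(total, 12)))
    rank = np.empty(typology.k, dtype=int)
    rank[order_idx] = np.arange(typology.k)
    labels = [f"{prefix}{i}" for i in range(typology.k)]
    descriptors = [
        _descriptor(cent[order_idx[i]], cent.shape[1]) for i in range(typology.k)
    ]
    typology.labels = labels
    typology.descriptors = descriptors
    typology.order = rank
    return typology


def pattern_frequencies(
    assignments: pd.DataFrame,
    group_by: list[str] | str,
    label_col: str = "pattern",
) -> pd.DataFrame:
    """Recurrence frequency (% of seasons) of each pattern within groups.

    ``assignments`` has one row per season with a pattern label column and
    grouping metadata columns. Percentages within each group sum to 100;
    raw counts are reported alongside. Empty groups never appear (pandas
    drops them); all observed patterns get a row in every group, zero
    filled.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    patterns = sorted(assignments[label_col].unique())
    out = []
    for keys, grp in assignments.groupby(group_by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(grp)
        for p in patterns:
            c = int((grp[label_col] == p).sum())
            out.append(dict(zip(group_by, keys)) | {
                label_col: p,
                "count": c,
                "percent": 100.0 * c / n,
            })
    return pd.DataFrame(out)
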