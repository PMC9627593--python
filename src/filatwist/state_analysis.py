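"""Pooling, clustering and mechanics of detected twist states.

Segments from many simulations are pooled into a :class:`StateCatalog`;
1D k-means over the state means recovers the mode structure of the twist
landscape (four modes near 0, 5, 10 and 12.5 degrees for the reference
ensemble), silhouette scoring makes the cluster count auditable, and the
equilibrium fluctuation within each state yields a torsional stiffness via
the small-angle relation

    K = kB * T * l / sigma^2

with sigma the state's angular standard deviation in radians and l the
monomer length (~5 nm).  K is reported both in units of kB*T*nm and in
pN*nm^2.  Note that any slow drift of the mean within a state inflates the
fitted sigma and therefore underestimates K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .geometry import BendTrace, TwistTrace
from .segmentation import StateSegment, trimmed_mean_sigma

__all__ = [
    "BOLTZMANN_J_PER_K",
    "StateCatalog",
    "ModulusEstimate",
    "fit_state_gaussian",
    "cluster_state_means",
    "select_n_clusters",
    "mode_histogram",
    "twist_modulus",
    "twist_bend_correlation",
    "moduli_for_catalog",
]

BOLTZMANN_J_PER_K = 1.380649e-23
_J_TO_PN_NM = 1.0e21  # 1 J = 1e21 pN nm


@dataclass
class StateCatalog:
    """Pooled state segments with optional cluster assignment.

    ``entries`` holds (segment, source-label) pairs; after clustering,
    ``labels`` assigns each entry to a cluster and ``centroids`` lists the
    cluster centres sorted ascending (labels are renumbered accordingly, so
    label 0 is the lowest-twist cluster).
    """

    entries: list[tuple[StateSegment, str]]
    labels: np.ndarray | None = None
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.entries),):
                raise ValueError("labels must have one entry per catalog entry")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if np.any(np.diff(self.centroids) < 0):
                raise ValueError("centroids must be sorted ascending")

    @classmethod
    def from_segments(cls, segments_by_source: dict[str, list[StateSegment]]):
        entries = [
            (seg, source)
            for source, segments in segments_by_source.items()
            for seg in segments
        ]
        return cls(entries=entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def means(self) -> np.ndarray:
        return np.array([seg.mean_twist for seg, _ in self.entries])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([seg.sigma for seg, _ in self.entries])

    @property
    def lifetimes_ns(self) -> np.ndarray:
        return np.array([seg.lifetime_ns for seg, _ in self.entries])

    @property
    def sources(self) -> list[str]:
        return [source for _, source in self.entries]


@dataclass(frozen=True)
class ModulusEstimate:
    """Twist modulus of one state, with the inputs that produced it."""

    K_kT_nm: float  # in multiples of kB*T*nm
    K_pN_nm2: float
    sigma_rad: float
    temperature: float  # K
    monomer_length: float  # nm

    def __post_init__(self) -> None:
        if self.K_kT_nm <= 0 or self.K_pN_nm2 <= 0:
            raise ValueError("modulus must be positive")
        if self.sigma_rad <= 0:
            raise ValueError("sigma_rad must be positive")


def fit_state_gaussian(
    trace: TwistTrace,
    segment: StateSegment,
    trim_fraction: float = 0.05,
    min_frames: int = 30,
) -> tuple[float, float]:
    """ML Gaussian fit (mean, sigma) to a boundary-trimmed state segment.

    Equals the sample mean and ML standard deviation of the trimmed values;
    raises if fewer than ``min_frames`` frames survive trimming or if the
    segment is constant (a state must fluctuate; sigma > 0).
    """
    values = trace.twist[segment.start_frame : segment.end_frame]
    cut = int(values.size * trim_fraction)
    if values.size - 2 * cut < min_frames:
        raise ValueError(
            f"segment has {values.size - 2 * cut} trimmed frames; need >= {min_frames}"
        )
    mean, sigma = trimmed_mean_sigma(values, trim_fraction)
    if sigma <= 0.0:
        raise ValueError("constant segment: sigma must be positive")
    return mean, sigma


def _kmeans_1d(values: np.ndarray, n_clusters: int, seed) -> KMeans:
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=50,
        random_state=seed,
    )
    km.fit(values.reshape(-1, 1))
    return km


def cluster_state_means(
    catalog: StateCatalog, n_clusters: int = 4, seed: int = 0
) -> StateCatalog:
    """K-means partition of the pooled state means into twist modes.

    Lloyd's algorithm with k-means++ initialization, 50 restarts, best
    inertia kept; deterministic for a fixed seed.  Returns a new catalog
    with labels renumbered so centroids are ascending.
    """
    means = catalog.means
    if len(catalog) < n_clusters:
        raise ValueError(
            f"{len(catalog)} states cannot form {n_clusters} clusters"
        )
    if np.unique(means).size < n_clusters:
        raise ValueError(
            "degenerate duplicates: fewer distinct state means than clusters"
        )
    km = _kmeans_1d(means, n_clusters, seed)
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids)
    relabel = np.empty_like(order)
    relabel[order] = np.arange(n_clusters)
    return replace(
        catalog, labels=relabel[km.labels_], centroids=centroids[order]
    )


def select_n_clusters(
    catalog: StateCatalog,
    k_range=range(2, 9),
    seed: int = 0,
    min_silhouette: float = 0.7,
) -> int:
    """Cluster count maximizing the mean silhouette over ``k_range``.

    Makes the visually-read mode count algorithmic.  If even the best
    silhouette is below ``min_silhouette`` the means carry no convincing
    cluster structure (e.g. a single Gaussian blob); the smallest k in the
    range is returned with a warning.
    """
    k_range = list(k_range)
    means = catalog.means
    if len(catalog) < max(k_range):
        raise ValueError(
            f"{len(catalog)} states are too few to evaluate k up to {max(k_range)}"
        )
    scores = {}
    for k in k_range:
        km = _kmeans_1d(means, k, seed)
        scores[k] = silhouette_score(means.reshape(-1, 1), km.labels_)
    best_k = max(scores, key=lambda k: scores[k])
    if scores[best_k] < min_silhouette:
        warnings.warn(
            f"weak cluster structure (best silhouette {scores[best_k]:.2f} < "
            f"{min_silhouette}); returning smallest k={min(k_range)}",
            stacklevel=2,
        )
        return min(k_range)
    return best_k


def mode_histogram(
    catalog: StateCatalog, bin_width: float = 0.5, weighted: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of state means; optionally occupancy-weighted.

    Bins of ``bin_width`` degrees aligned to the bin grid.  Unweighted, each
    state contributes one count (mass sums to the number of states);
    weighted, each contributes its lifetime in ns (mass sums to the total
    occupancy time).  Returns (counts, bin_edges).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(catalog) < 1:
        raise ValueError("empty catalog")
    means = catalog.means
    lo = np.floor(means.min() / bin_width) * bin_width
    hi = np.ceil(means.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    weights = catalog.lifetimes_ns if weighted else None
    counts, edges = np.histogram(means, bins=edges, weights=weights)
    return counts, edges


def twist_modulus(
    sigma: float,
    temperature: float = 310.0,
    monomer_length: float = 5.0,
) -> ModulusEstimate:
    """Twist modulus from a state's angular fluctuation (small-angle limit).

    ``sigma`` is the state's standard deviation in *degrees* (converted to
    radians internally); ``monomer_length`` in nm.  Equipartition over one
    monomer length gives K = kB*T*l / sigma_rad^2, so sigma = 1 rad and
    l = 5 nm yield exactly 5 kB*T*nm.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if monomer_length <= 0:
        raise ValueError("monomer_length must be positive")
    sigma_rad = np.radians(sigma)
    k_kt_nm = monomer_length / sigma_rad**2
    kbt_pn_nm = BOLTZMANN_J_PER_K * temperature * _J_TO_PN_NM
    return ModulusEstimate(
        K_kT_nm=float(k_kt_nm),
        K_pN_nm2=float(k_kt_nm * kbt_pn_nm),
        sigma_rad=float(sigma_rad),
        temperature=float(temperature),
        monomer_length=float(monomer_length),
    )


def moduli_for_catalog(
    catalog: StateCatalog, temperature: float = 310.0, monomer_length: float = 5.0
) -> list[ModulusEstimate]:
    """Twist modulus of every state in the catalog."""
    return [
        twist_modulus(seg.sigma, temperature, monomer_length)
        for seg, _ in catalog.entries
    ]


def twist_bend_correlation(
    twist: TwistTrace, bend: BendTrace
) -> tuple[float, int]:
    """Pearson correlation of twist against out-of-plane bend.

    Returns (r, sign(r)).  A weak negative correlation indicates a trade-off
    between twisting and bending away from the membrane plane.
    """
    x = twist.twist
    y = bend.out_of_plane
    if x.size != y.size:
        raise ValueError("twist and bend traces must have equal length")
    if x.size < 30:
        raise ValueError("need at least 30 frames for a meaningful correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(np.sign(r))
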