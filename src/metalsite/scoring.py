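"""Cluster scoring: structure term, sequence term, per-residue aggregation
and z-normalization.

Each aligned substructure (cluster) is scored by two conservation terms:

* ``s_str`` — structural, 1 − RMSD/RMSD_max over the matched Cα atoms after
  a fresh least-squares superposition, clamped at 0; clusters at or above
  RMSD_max (default 3 Å) are discarded.
* ``s_seq`` — sequence, the BLOSUM62 sum over matched residues normalized
  by the template fragment's self-score (its maximum attainable alignment
  score); clusters must exceed a per-metal threshold θ.

Qualifying clusters contribute their combined score (product by default) to
every query residue they align; the per-chain raw vector is z-normalized so
a single per-metal calling threshold is meaningful across chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .fragment_transform import Cluster, Triplet, kabsch

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Clusters with Cα-RMSD at or above this bound (Å) never qualify.
DEFAULT_RMSD_MAX = 3.0

#: Default sequence-conservation threshold θ (s_seq must exceed it).
DEFAULT_THETA = 0.30


def blosum62(a: str, b: str) -> float:
    """BLOSUM62 substitution score for one-letter codes; 'X' (and anything
    outside the matrix) scores 0 against everything."""
    if a == "X" or b == "X":
        return 0.0
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return 0.0


@dataclass
class ScoringParams:
    rmsd_max: float = DEFAULT_RMSD_MAX
    theta_seq: float = DEFAULT_THETA
    theta_per_metal: dict[str, float] = field(default_factory=dict)
    combine_mode: str = "product"  # or "mean"
    aggregate_mode: str = "sum"  # or "max"
    d_c: float = 2.0
    min_cluster_size: int = 3
    prefilter: bool = False

    def __post_init__(self) -> None:
        if self.rmsd_max <= 0:
            raise ValueError("rmsd_max must be positive")
        if self.combine_mode not in ("product", "mean"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if self.aggregate_mode not in ("sum", "max"):
            raise ValueError(f"unknown aggregate_mode {self.aggregate_mode!r}")

    def theta_for(self, metal: str | None) -> float:
        if metal is not None and metal.upper() in self.theta_per_metal:
            return self.theta_per_metal[metal.upper()]
        return self.theta_seq


@dataclass
class ClusterScore:
    cluster: Cluster
    rmsd_ca: float
    seq_raw: float
    seq_max: float
    s_str: float
    s_seq: float
    combined: float
    passed_filters: bool


def cluster_rmsd(
    cluster: Cluster,
    query_triplets: list[Triplet],
    template_triplets: list[Triplet],
) -> float:
    """Cα-RMSD of the aligned substructure after a fresh Kabsch superposition
    of the matched Cα sets (not the triplet transform)."""
    if cluster.size < 3:
        raise ValueError("cluster RMSD needs at least 3 correspondences")
    q = np.array([query_triplets[i].ca for i, _ in cluster.correspondence])
    t = np.array([template_triplets[j].ca for _, j in cluster.correspondence])
    _, rmsd = kabsch(q, t)
    return rmsd


def seq_score(
    cluster: Cluster,
    query_triplets: list[Triplet],
    template_triplets: list[Triplet],
) -> tuple[float, float, float]:
    """(seq_raw, seq_max, s_seq): BLOSUM62 sum over the correspondence and
    its normalization by the template fragment's self-score."""
    if not cluster.correspondence:
        raise ValueError("empty correspondence")
    seq_raw = 0.0
    seq_max = 0.0
    for i, j in cluster.correspondence:
        q = query_triplets[i].one_letter
        t = template_triplets[j].one_letter
        seq_raw += blosum62(q, t)
        seq_max += blosum62(t, t)
    # seq_max can only vanish for all-'X' template fragments
    s_seq = seq_raw / seq_max if seq_max > 0 else 0.0
    return seq_raw, seq_max, s_seq


def structure_score(rmsd_ca: float, rmsd_max: float = DEFAULT_RMSD_MAX) -> float:
    """s_str = 1 − RMSD/RMSD_max, clamped to 0.  Callers must additionally
    treat rmsd_ca >= rmsd_max as a filter failure."""
    if rmsd_ca < 0:
        raise ValueError("rmsd_ca must be non-negative")
    return max(0.0, 1.0 - rmsd_ca / rmsd_max)


def score_cluster(
    cluster: Cluster,
    query_triplets: list[Triplet],
    template_triplets: list[Triplet],
    params: ScoringParams | None = None,
    metal: str | None = None,
) -> ClusterScore:
    """Score one cluster and apply the RMSD and sequence filters."""
    params = params or ScoringParams()
    rmsd_ca = cluster_rmsd(cluster, query_triplets, template_triplets)
    seq_raw, seq_max, s_seq = seq_score(cluster, query_triplets, template_triplets)
    s_str = structure_score(rmsd_ca, params.rmsd_max)
    if params.combine_mode == "product":
        combined = s_str * s_seq
    else:
        combined = 0.5 * (s_str + s_seq)
    theta = params.theta_for(metal)
    passed = (rmsd_ca < params.rmsd_max) and (s_seq > theta)
    return ClusterScore(cluster, rmsd_ca, seq_raw, seq_max, s_str, s_seq, combined, passed)


def residue_raw_scores(
    n_residues: int,
    scored: list[tuple[ClusterScore, list[Triplet]]],
    aggregate_mode: str = "sum",
) -> np.ndarray:
    """Aggregate qualifying cluster scores onto chain residues.

    ``scored`` pairs each ClusterScore with the query triplets it was built
    from (so correspondences resolve to chain residue indices).  Residues in
    no qualifying cluster score 0.
    """
    raw = np.zeros(n_residues)
    for cs, query_triplets in scored:
        if not cs.passed_filters:
            continue
        for i, _ in cs.cluster.correspondence:
            ridx = query_triplets[i].residue_index
            if aggregate_mode == "sum":
                raw[ridx] += cs.combined
            else:
                raw[ridx] = max(raw[ridx], cs.combined)
    return raw


@dataclass
class ResidueScoreVector:
    raw: np.ndarray
    mean: float
    std: float
    z: np.ndarray


def normalize_scores(raw: np.ndarray) -> ResidueScoreVector:
    """z-normalize a raw score vector with the population standard
    deviation; an all-constant vector maps to all-zero z-scores."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("raw score vector must be 1-D with length >= 2")
    mu = float(raw.mean())
    sigma = float(raw.std())  # population (ddof=0)
    if sigma == 0.0:
        warnings.warn("constant raw score vector; z-scores set to 0")
        z = np.zeros_like(raw)
    else:
        z = (raw - mu) / sigma
    return ResidueScoreVector(raw=raw, mean=mu, std=sigma, z=z)
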