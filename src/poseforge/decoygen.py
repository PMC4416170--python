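"""Decoy-set construction: RMSD filter, binning, clustering, representatives.

Candidate poses further than ``max_rmsd`` (default 10 Å) from the native
pose are discarded; the survivors are grouped into contiguous RMSD bins
(default ten 1 Å bins), each bin is clustered into at most
``clusters_per_bin`` clusters by complete-linkage hierarchical clustering on
the pairwise pose-pose heavy-atom RMSD matrix, and from each cluster the
pose with the lowest interaction energy is kept. A fully populated run with
the ``test100`` preset therefore yields 10 × 10 = 100 diverse decoys per
complex; the ``train50`` preset keeps 5 per bin. Under-populated bins
contribute fewer representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .posemetrics import pairwise_rmsd_matrix
from .structio import MoleculeStructure, PoseSet, StructureError

__all__ = [
    "DecoyConfig",
    "DecoyRow",
    "DecoySet",
    "PRESETS",
    "filter_and_bin",
    "cluster_bin",
    "select_representatives",
    "builtin_energy",
    "build_decoy_set",
]


@dataclass(frozen=True)
class DecoyConfig:
    """Decoy pipeline settings; the defaults follow the 100-pose test protocol."""

    max_rmsd: float = 10.0
    bin_width: float = 1.0
    clusters_per_bin: int = 10
    include_native: bool = False
    energy_source: str = "provided"  # or "builtin"

    def __post_init__(self) -> None:
        n_bins = self.max_rmsd / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9 or n_bins < 1:
            raise ValueError("max_rmsd must be an integral number of bin widths")
        if self.clusters_per_bin < 1:
            raise ValueError("clusters_per_bin must be >= 1")
        if self.energy_source not in ("provided", "builtin"):
            raise ValueError(f"unknown energy_source {self.energy_source!r}")

    @property
    def n_bins(self) -> int:
        return int(round(self.max_rmsd / self.bin_width))


#: presets mirroring the 100-pose test protocol and the 50-pose training protocol
PRESETS: dict[str, DecoyConfig] = {
    "test100": DecoyConfig(clusters_per_bin=10),
    "train50": DecoyConfig(clusters_per_bin=5),
}


@dataclass(frozen=True)
class DecoyRow:
    pose_index: int  # index into the candidate list
    rmsd: float
    bin_index: int  # 1-based
    cluster_index: int  # 1-based within the bin
    energy: float


@dataclass
class DecoySet:
    complex_id: str
    representatives: list[DecoyRow]
    config: DecoyConfig

    def pose_indices(self) -> list[int]:
        return [r.pose_index for r in self.representatives]

    def __len__(self) -> int:
        return len(self.representatives)


def filter_and_bin(
    rmsds: Sequence[float],
    config: DecoyConfig = DecoyConfig(),
) -> dict[int, list[int]]:
    """Map 1-based bin index -> candidate indices, RMSD > max_rmsd discarded.

    Bin k holds rmsd in ((k-1)·w, k·w]; an exact 0 (the native itself) lands
    in bin 1 only when ``include_native`` is set, otherwise it is dropped.
    """
    w = config.bin_width
    bins: dict[int, list[int]] = {}
    for i, r in enumerate(rmsds):
        r = float(r)
        if r < 0:
            raise StructureError(f"negative rmsd {r} at candidate {i}")
        if r > config.max_rmsd:
            continue
        if r == 0.0:
            if not config.include_native:
                continue
            k = 1
        else:
            # (k-1)w < r <= kw  <=>  k = ceil(r/w) for r > 0
            k = int(np.ceil(r / w))
        bins.setdefault(k, []).append(i)
    return dict(sorted(bins.items()))


def cluster_bin(poses: Sequence[MoleculeStructure], k: int) -> np.ndarray:
    """Complete-linkage clustering of one bin on pairwise pose RMSD.

    Returns 1-based cluster labels, at most min(k, n) distinct, deterministic
    given input order.
    """
    n = len(poses)
    if n == 0:
        raise ValueError("cannot cluster an empty bin")
    if n == 1:
        return np.array([1])
    dm = pairwise_rmsd_matrix(poses)
    # squareform requires an exactly symmetric, zero-diagonal matrix
    dm = (dm + dm.T) / 2.0
    np.fill_diagonal(dm, 0.0)
    Z = linkage(squareform(dm, checks=False), method="complete")
    labels = fcluster(Z, t=min(k, n), criterion="maxclust")
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels by first appearance so output is order-stable."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def select_representatives(
    member_indices: Sequence[int],
    labels: np.ndarray,
    energies: Sequence[float],
) -> list[tuple[int, int]]:
    """Per cluster, the minimum-energy member; ties -> lowest pose index.

    Returns (candidate_index, cluster_label) pairs ordered by cluster label.
    """
    out: list[tuple[int, int]] = []
    for lab in sorted(set(int(l) for l in labels)):
        members = [idx for idx, l in zip(member_indices, labels) if l == lab]
        best = min(members, key=lambda idx: (float(energies[idx]), idx))
        out.append((best, lab))
    return out


def builtin_energy(
    receptor: MoleculeStructure,
    pose: MoleculeStructure,
    cutoff: float = 8.0,
    r0: float = 3.5,
) -> float:
    """Deterministic Lennard-Jones-like pairwise score (a surrogate only).

    Sum over protein-ligand heavy-atom pairs within ``cutoff`` of
    4·((r0/d)^12 − (r0/d)^6), distances clamped at 1 Å; lower is more
    favorable. This stands in for docking-engine interaction energies so the
    pipeline runs on synthetic data; it has no physical calibration.
    """
    from scipy.spatial.distance import cdist

    d = cdist(receptor.coords, pose.coords)
    mask = d <= cutoff
    if not mask.any():
        return 0.0
    d = np.clip(d[mask], 1.0, None)
    x = r0 / d
    return float(np.sum(4.0 * (x**12 - x**6)))


def build_decoy_set(
    pose_set: PoseSet,
    config: DecoyConfig | str = "test100",
    energies: Sequence[float] | Mapping[int, float] | None = None,
) -> DecoySet:
    """Run the full filter → bin → cluster → select pipeline on one complex."""
    if isinstance(config, str):
        config = PRESETS[config]
    if pose_set.rmsd_to_native is None:
        raise StructureError(f"{pose_set.complex_id!r}: rmsd_to_native missing")

    n = len(pose_set.candidates)
    if energies is None:
        energies = pose_set.energies
    if config.energy_source == "provided":
        if energies is None:
            raise StructureError(
                f"{pose_set.complex_id!r}: energy_source='provided' but no energies given"
            )
        evec = np.asarray(
            [energies[i] for i in range(n)] if isinstance(energies, Mapping) else energies,
            dtype=np.float64,
        )
        if evec.shape != (n,):
            raise StructureError("need one energy per candidate pose")
    else:
        evec = np.array(
            [builtin_energy(pose_set.receptor, c) for c in pose_set.candidates]
        )

    bins = filter_and_bin(pose_set.rmsd_to_native, config)
    rows: list[DecoyRow] = []
    for bin_idx, members in bins.items():
        labels = cluster_bin([pose_set.candidates[i] for i in members], config.clusters_per_bin)
        for cand_idx, lab in select_representatives(members, labels, evec):
            rows.append(
                DecoyRow(
                    pose_index=cand_idx,
                    rmsd=float(pose_set.rmsd_to_native[cand_idx]),
                    bin_index=bin_idx,
                    cluster_index=lab,
                    energy=float(evec[cand_idx]),
                )
            )
    return DecoySet(pose_set.complex_id, rows, config)
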