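"""Pose-to-pose RMSD in the shared receptor frame.

Docking decoys are generated inside a fixed binding site, so the deviation
from the native pose is measured without any superposition: atoms are paired
by index and the root-mean-square Euclidean displacement is returned. No
graph-automorphism symmetry correction is applied; a pluggable
``atom_matching`` hook exists for callers that need one.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .structio import MoleculeStructure, PairingError

__all__ = ["rmsd", "pairwise_rmsd_matrix"]

AtomMatching = Callable[[MoleculeStructure, MoleculeStructure], Sequence[tuple[int, int]]]


def _identity_matching(a: MoleculeStructure, b: MoleculeStructure) -> list[tuple[int, int]]:
    if len(a) != len(b):
        raise PairingError(
            f"cannot pair poses with {len(a)} vs {len(b)} heavy atoms"
        )
    return [(i, i) for i in range(len(a))]


def rmsd(
    pose_a: MoleculeStructure,
    pose_b: MoleculeStructure,
    atom_matching: AtomMatching | None = None,
) -> float:
    """Heavy-atom RMSD (Å) between two poses, atoms paired by index.

    ``atom_matching`` may supply an alternative index pairing (e.g. a
    symmetry-aware matcher); the default pairs atom i with atom i and
    requires equal atom counts.
    """
    pairs = (atom_matching or _identity_matching)(pose_a, pose_b)
    ia, ib = zip(*pairs)
    diff = pose_a.coords[list(ia)] - pose_b.coords[list(ib)]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def pairwise_rmsd_matrix(poses: Sequence[MoleculeStructure]) -> np.ndarray:
    """Symmetric (n, n) matrix of pairwise pose RMSDs (used for decoy clustering)."""
    n = len(poses)
    coords = np.stack([p.coords for p in poses])  # (n, atoms, 3)
    if len({c.shape for c in coords}) > 1:  # pragma: no cover - stack already fails
        raise PairingError("poses have differing atom counts")
    # (n, n) via broadcasting; fine at decoy-pool sizes (hundreds of poses)
    diff = coords[:, None, :, :] - coords[None, :, :, :]
    msd = np.mean(np.sum(diff * diff, axis=-1), axis=-1)
    return np.sqrt(msd)
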