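"""Synthetic complexes, poses with controlled RMSD, and feature tables.

The generator emulates the data regime of a docking-power benchmark without
any structure downloads: a rigid receptor pocket (points in a spherical
shell), a native ligand pose inside it, candidate poses displaced to exact
target RMSDs, geometric R features computed from the actual coordinates,
synthetic stand-ins for the external X/A/G descriptor families in which a
configurable number of columns carry an RMSD-linked signal with tunable
noise, and a binding-affinity label that exists only for native poses
(mirroring why BA-response training tables are one row per complex while
RMSD-response tables scale with poses per complex).

Default scenario: 200 complexes, 20 candidate poses per complex with target
RMSDs uniform on (0, 12] Å, unit feature noise. Everything is deterministic
under the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geomfeat import FAMILY_WIDTHS, build_feature_table
from .structio import AtomRecord, MoleculeStructure, PoseSet, assemble_pose_set

__all__ = ["SynthScenario", "make_complex", "perturb_to_rmsd", "make_benchmark"]

_RECEPTOR_ELEMENTS = ("C", "N", "O", "S")
_RECEPTOR_WEIGHTS = (0.62, 0.16, 0.18, 0.04)
_LIGAND_ELEMENTS = ("C", "N", "O", "F", "P", "S", "CL", "BR", "I")
_LIGAND_WEIGHTS = (0.60, 0.12, 0.14, 0.04, 0.02, 0.03, 0.03, 0.01, 0.01)


@dataclass(frozen=True)
class SynthScenario:
    """Parameters of one synthetic benchmark; JSON-round-trippable."""

    n_complexes: int = 200
    receptor_atoms: int = 60
    ligand_atoms: int = 12  # mean; actual size varies per complex (BA signal)
    poses_per_complex: int = 20
    rmsd_max: float = 12.0  # targets uniform on (0, rmsd_max]
    feature_noise_sd: float = 1.0
    n_signal_features: int = 20  # synthetic X/A/G columns carrying RMSD signal
    ba_intercept: float = 9.0  # BA = intercept - size_coeff * n_ligand_atoms + noise
    ba_size_coeff: float = 0.25
    ba_noise_sd: float = 0.5
    seed: int = 20070101

    def __post_init__(self) -> None:
        if min(self.n_complexes, self.receptor_atoms, self.ligand_atoms, self.poses_per_complex) < 1:
            raise ValueError("all counts must be >= 1")
        if self.feature_noise_sd < 0 or self.ba_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SynthScenario":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def _complex_rng(scenario: SynthScenario, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, int(index)]))


def make_complex(scenario: SynthScenario, index: int) -> PoseSet:
    """One synthetic complex: shell receptor, pocket-centred native, no candidates yet."""
    rng = _complex_rng(scenario, index)

    # receptor: points on a shell of radius 8-14 A around the pocket origin
    n_rec = scenario.receptor_atoms
    dirs = rng.normal(size=(n_rec, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = rng.uniform(8.0, 14.0, size=n_rec)
    rec_xyz = dirs * radii[:, None]
    rec_elems = rng.choice(_RECEPTOR_ELEMENTS, size=n_rec, p=_RECEPTOR_WEIGHTS)

    # ligand size varies so the native-only affinity label has a real signal
    n_lig = max(4, int(rng.integers(scenario.ligand_atoms - 4, scenario.ligand_atoms + 5)))
    lig_xyz = rng.uniform(-3.0, 3.0, size=(n_lig, 3))
    lig_elems = rng.choice(_LIGAND_ELEMENTS, size=n_lig, p=_LIGAND_WEIGHTS)

    cid = f"synth{index:04d}"
    receptor = MoleculeStructure(
        cid + "_rec",
        [AtomRecord(str(e), tuple(map(float, xyz))) for e, xyz in zip(rec_elems, rec_xyz)],
    )
    native = MoleculeStructure(
        cid + "_native",
        [
            AtomRecord(str(e), tuple(map(float, xyz)), is_ligand=True)
            for e, xyz in zip(lig_elems, lig_xyz)
        ],
    )
    return PoseSet(cid, receptor, native, candidates=[])


def perturb_to_rmsd(
    native: MoleculeStructure,
    target: float,
    rng: np.random.Generator | int | None = None,
    pose_id: str | None = None,
) -> MoleculeStructure:
    """Pose at an exact heavy-atom RMSD from ``native``.

    A random rigid translation plus per-atom jitter is rescaled so the
    achieved RMSD equals the target to better than 1e-6 Å; target 0 returns
    an identical copy.
    """
    if target < 0:
        raise ValueError("target RMSD must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    coords = native.coords
    if target == 0:
        return native.with_coords(coords, pose_id or native.molecule_id)
    translation = rng.normal(scale=1.0, size=3)
    jitter = rng.normal(scale=0.5, size=coords.shape)
    disp = translation[None, :] + jitter
    achieved = np.sqrt(np.mean(np.sum(disp * disp, axis=1)))
    disp *= target / achieved
    return native.with_coords(coords + disp, pose_id or f"{native.molecule_id}_p")


def _synthetic_family_columns() -> list[tuple[str, str]]:
    cols = []
    for fam in ("X", "A", "G"):
        for j in range(FAMILY_WIDTHS[fam]):
            cols.append((fam, f"{fam}.s{j + 1:02d}"))
    return cols


def make_benchmark(
    scenario: SynthScenario,
    indices: Sequence[int] | None = None,
) -> tuple[list[PoseSet], pd.DataFrame]:
    """Pose sets plus a feature table with R geometry + synthetic X/A/G columns.

    Signal columns (``n_signal_features`` of the 50 synthetic columns, chosen
    deterministically from the scenario seed) are c_j·RMSD + d_j·RMSD² plus
    Gaussian noise with sd ``feature_noise_sd``; the rest are pure noise.
    BA = intercept − size_coeff·(ligand atoms) + noise, native rows only.
    """
    if indices is None:
        indices = range(scenario.n_complexes)
    master = np.random.default_rng(np.random.SeedSequence([scenario.seed, 987654321]))
    fam_cols = _synthetic_family_columns()
    n_syn = len(fam_cols)
    n_signal = min(scenario.n_signal_features, n_syn)
    signal_idx = np.sort(master.choice(n_syn, size=n_signal, replace=False))
    lin_coef = master.uniform(0.5, 1.5, size=n_signal) * master.choice([-1.0, 1.0], size=n_signal)
    quad_coef = master.uniform(-0.05, 0.05, size=n_signal)

    pose_sets: list[PoseSet] = []
    ba: dict[str, float] = {}
    for index in indices:
        base = make_complex(scenario, index)
        rng = _complex_rng(scenario, index)
        rng = np.random.default_rng(rng.integers(2**31))  # decouple from geometry draws
        targets = rng.uniform(0.0, scenario.rmsd_max, size=scenario.poses_per_complex)
        targets = np.nextafter(targets, scenario.rmsd_max)  # open at 0, closed at max
        candidates = [
            perturb_to_rmsd(base.native, float(t), rng, pose_id=f"pose{j + 1:03d}")
            for j, t in enumerate(targets)
        ]
        ps = assemble_pose_set(base.receptor, base.native, candidates, complex_id=base.complex_id)
        pose_sets.append(ps)
        ba[ps.complex_id] = float(
            scenario.ba_intercept
            - scenario.ba_size_coeff * len(ps.native)
            + rng.normal(scale=scenario.ba_noise_sd)
        )

    table = build_feature_table(pose_sets, selection=("R",), ba=ba)

    # synthetic external-family columns, aligned to table rows
    rmsd_col = table["RMSD"].to_numpy()
    noise_rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 24601]))
    syn = noise_rng.normal(scale=max(scenario.feature_noise_sd, 1e-12), size=(len(table), n_syn))
    if scenario.feature_noise_sd == 0:
        syn[:] = 0.0
    for k, col_idx in enumerate(signal_idx):
        syn[:, col_idx] += lin_coef[k] * rmsd_col + quad_coef[k] * rmsd_col**2
    syn_df = pd.DataFrame(syn, index=table.index, columns=[name for _, name in fam_cols])

    responses = table[["BA", "RMSD"]]
    features = pd.concat([syn_df[[n for f, n in fam_cols if f == "X"]],
                          syn_df[[n for f, n in fam_cols if f == "A"]],
                          table.drop(columns=["BA", "RMSD"]),
                          syn_df[[n for f, n in fam_cols if f == "G"]]], axis=1)
    out = pd.concat([features, responses], axis=1)
    return pose_sets, out
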