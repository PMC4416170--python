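"""Geometrical atom-pair count features and feature-table assembly.

The R feature family counts occurrences of protein-ligand heavy-atom element
pairs within a distance cutoff: 4 protein elements {C, N, O, S} × 9 ligand
elements {C, N, O, F, P, S, Cl, Br, I} = 36 counts at a single 12 Å cutoff,
or 36 counts per distance bin in the extended binned variant (five 4 Å bins
→ 180 features). Elements outside the two sets contribute nothing.

Descriptor families computed by external empirical scoring tools — X (6
X-Score features), A (30 AffiScore/SLIDE features), G (14 GOLD descriptors)
— are ingested as tables keyed by (complex_id, pose_id), never recomputed
here. Note the widths: 6 + 30 + 14 + 180 = 230 columns are available when
the binned R variant replaces plain R, although the combined pool is often
quoted as 220; both widths are exposed and callers pick the pool.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import MoleculeStructure, PoseSet, StructureError

__all__ = [
    "PROTEIN_ELEMENTS",
    "LIGAND_ELEMENTS",
    "FAMILY_WIDTHS",
    "PairCountVector",
    "FeatureFamilySelection",
    "SchemaError",
    "CoverageError",
    "pair_counts",
    "binned_pair_counts",
    "pair_feature_names",
    "load_external_features",
    "enumerate_family_combinations",
    "build_feature_table",
    "feature_columns",
]

PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "CL", "BR", "I")

#: nominal widths of the externally computed families and the geometric family
FAMILY_WIDTHS: dict[str, int] = {"X": 6, "A": 30, "R": 36, "G": 14}

KEY_COLUMNS = ("complex_id", "pose_id")
RESPONSE_COLUMNS = ("BA", "RMSD")


class SchemaError(ValueError):
    """An external feature table violates the expected schema."""


class CoverageError(ValueError):
    """A requested feature family does not cover every (complex, pose) key."""


@dataclass(frozen=True)
class PairCountVector:
    """Ordered atom-pair counts plus the cutoff/bin scheme that produced them."""

    counts: np.ndarray
    names: tuple[str, ...]
    bin_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.counts.shape != (len(self.names),):
            raise ValueError("counts and names must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("pair counts must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.names))


@dataclass(frozen=True)
class FeatureFamilySelection:
    """A non-empty subset of the families {X, A, R, G}; order-insensitive."""

    families: frozenset[str]

    def __init__(self, families: Iterable[str]):
        fams = frozenset(f.upper() for f in families)
        if not fams:
            raise ValueError("family selection must be non-empty")
        unknown = fams - set(FAMILY_WIDTHS)
        if unknown:
            raise ValueError(f"unknown feature families {sorted(unknown)}")
        object.__setattr__(self, "families", fams)

    @property
    def label(self) -> str:
        """Canonical label in X, A, R, G order, e.g. 'XARG'."""
        return "".join(f for f in "XARG" if f in self.families)

    def __contains__(self, family: str) -> bool:
        return family.upper() in self.families

    def __iter__(self):
        return iter(sorted(self.families, key="XARG".index))

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.label


def pair_feature_names(bin_edges: Sequence[float]) -> tuple[str, ...]:
    """Fixed column order: bins outermost, then protein element, then ligand element."""
    names = []
    for b in range(len(bin_edges) - 1):
        lo, hi = bin_edges[b], bin_edges[b + 1]
        suffix = "" if len(bin_edges) == 2 else f".{lo:g}-{hi:g}"
        for p in PROTEIN_ELEMENTS:
            for l in LIGAND_ELEMENTS:
                names.append(f"R.{p}.{l.capitalize()}{suffix}")
    return tuple(names)


def _binned_counts(
    receptor: MoleculeStructure,
    ligand: MoleculeStructure,
    bin_edges: Sequence[float],
) -> PairCountVector:
    edges = tuple(float(e) for e in bin_edges)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if edges[0] != 0.0 or any(hi <= lo for lo, hi in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must start at 0 and be strictly increasing: {edges}")

    n_bins = len(edges) - 1
    counts = np.zeros((n_bins, len(PROTEIN_ELEMENTS), len(LIGAND_ELEMENTS)), dtype=np.int64)

    p_elems = np.array([a.element for a in receptor.atoms])
    l_elems = np.array([a.element for a in ligand.atoms])
    p_idx = {e: i for i, e in enumerate(PROTEIN_ELEMENTS)}
    l_idx = {e: i for i, e in enumerate(LIGAND_ELEMENTS)}
    p_keep = np.array([e in p_idx for e in p_elems])
    l_keep = np.array([e in l_idx for e in l_elems])
    if p_keep.any() and l_keep.any():
        d = cdist(receptor.coords[p_keep], ligand.coords[l_keep])
        pi = np.array([p_idx[e] for e in p_elems[p_keep]])
        li = np.array([l_idx[e] for e in l_elems[l_keep]])
        # half-open-at-left bins (lo, hi]; d == 0 (coincident atoms) never counts
        bin_of = np.searchsorted(edges, d, side="left") - 1
        valid = (d > 0) & (d <= edges[-1])
        bi, pj, lj = bin_of[valid], np.broadcast_to(pi[:, None], d.shape)[valid], np.broadcast_to(li[None, :], d.shape)[valid]
        np.add.at(counts, (bi, pj, lj), 1)
    return PairCountVector(counts.reshape(-1), pair_feature_names(edges), edges)


def pair_counts(
    receptor: MoleculeStructure,
    ligand: MoleculeStructure,
    cutoff: float = 12.0,
) -> PairCountVector:
    """36 protein-ligand element-pair occurrence counts with 0 < d ≤ cutoff Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return _binned_counts(receptor, ligand, (0.0, float(cutoff)))


def binned_pair_counts(
    receptor: MoleculeStructure,
    ligand: MoleculeStructure,
    bin_edges: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0),
) -> PairCountVector:
    """36 counts per distance bin; the default five 4 Å bins give 180 features."""
    return _binned_counts(receptor, ligand, bin_edges)


def enumerate_family_combinations(
    available: Iterable[str] = ("X", "A", "R", "G"),
) -> list[FeatureFamilySelection]:
    """All non-empty family subsets, ordered by size then lexicographically."""
    fams = sorted({f.upper() for f in available})
    if not fams:
        raise ValueError("available families must be non-empty")
    out = []
    for size in range(1, len(fams) + 1):
        for combo in itertools.combinations(fams, size):
            out.append(FeatureFamilySelection(combo))
    return out


def load_external_features(path: str | Path, family: str) -> pd.DataFrame:
    """Load an externally computed descriptor table fragment (family X, A or G).

    The CSV/TSV must carry ``complex_id`` and ``pose_id`` key columns; all
    other columns become features renamed with the family prefix. A column
    count differing from the family's nominal width warns but does not fail.
    """
    family = family.upper()
    if family not in ("X", "A", "G"):
        raise ValueError(f"external families are X, A, G; got {family!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [k for k in KEY_COLUMNS if k not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing key columns {missing}")
    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        keys = df.loc[dup, list(KEY_COLUMNS)].itertuples(index=False, name=None)
        raise SchemaError(f"{path.name}: duplicated keys {sorted(set(keys))}")
    feats = [c for c in df.columns if c not in KEY_COLUMNS]
    if len(feats) != FAMILY_WIDTHS[family]:
        warnings.warn(
            f"{path.name}: family {family} has {len(feats)} feature columns, "
            f"nominal width is {FAMILY_WIDTHS[family]}",
            stacklevel=2,
        )
    if df[feats].isna().any().any():
        bad = df[feats].isna().any(axis=1)
        raise SchemaError(f"{path.name}: missing values in rows {list(df.index[bad])}")
    renamed = {c: c if c.startswith(f"{family}.") else f"{family}.{c}" for c in feats}
    out = df.rename(columns=renamed)
    out = out.set_index(list(KEY_COLUMNS))
    return out


def feature_columns(table: pd.DataFrame, selection: FeatureFamilySelection) -> list[str]:
    """Columns of ``table`` belonging to the selected families, in X,A,R,G order."""
    cols: list[str] = []
    for fam in selection:
        fam_cols = [c for c in table.columns if c.startswith(f"{fam}.")]
        if not fam_cols:
            raise CoverageError(f"family {fam} has no columns in this table")
        cols.extend(fam_cols)
    return cols


def build_feature_table(
    pose_sets: Sequence[PoseSet],
    selection: FeatureFamilySelection | Iterable[str] = ("R",),
    external: Mapping[str, pd.DataFrame] | None = None,
    ba: Mapping[str, float] | None = None,
    *,
    binned: bool = False,
    cutoff: float = 12.0,
    bin_edges: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0),
    native_pose_id: str = "native",
) -> pd.DataFrame:
    """One row per (complex, pose), native rows included with RMSD = 0.

    R-family features are computed from geometry (plain 36-count vector, or
    the binned variant when ``binned``); X/A/G fragments come from
    ``external`` (family → indexed DataFrame from :func:`load_external_features`).
    ``ba`` maps complex_id → experimental affinity, filled on native rows only.
    """
    if not isinstance(selection, FeatureFamilySelection):
        selection = FeatureFamilySelection(selection)
    external = external or {}

    rows: list[dict] = []
    for ps in pose_sets:
        if ps.rmsd_to_native is None:
            raise StructureError(f"pose set {ps.complex_id!r} lacks rmsd_to_native")
        poses = [(native_pose_id, ps.native, 0.0)] + [
            (cand.molecule_id, cand, float(r))
            for cand, r in zip(ps.candidates, ps.rmsd_to_native)
        ]
        for pose_id, pose, rms in poses:
            row: dict = {"complex_id": ps.complex_id, "pose_id": pose_id, "RMSD": rms}
            if "R" in selection:
                vec = (
                    binned_pair_counts(ps.receptor, pose, bin_edges)
                    if binned
                    else pair_counts(ps.receptor, pose, cutoff)
                )
                row.update(zip(vec.names, vec.counts.astype(float)))
            row["BA"] = (
                float(ba[ps.complex_id])
                if ba is not None and pose_id == native_pose_id and ps.complex_id in ba
                else np.nan
            )
            rows.append(row)

    table = pd.DataFrame(rows).set_index(list(KEY_COLUMNS))

    for fam in selection:
        if fam == "R":
            continue
        if fam not in external:
            raise CoverageError(f"family {fam} requested but no external fragment supplied")
        frag = external[fam]
        missing = table.index.difference(frag.index)
        if len(missing):
            raise CoverageError(
                f"family {fam} fragment missing keys {list(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
        table = table.join(frag.loc[table.index])

    # stable column order: families in XARG order, then responses
    feat_cols = feature_columns(table, selection)
    return table[feat_cols + ["BA", "RMSD"]]
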