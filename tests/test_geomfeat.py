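import numpy as np
import pandas as pd
import pytest

from poseforge.geomfeat import (
    FAMILY_WIDTHS,
    LIGAND_ELEMENTS,
    PROTEIN_ELEMENTS,
    CoverageError,
    FeatureFamilySelection,
    SchemaError,
    binned_pair_counts,
    build_feature_table,
    enumerate_family_combinations,
    load_external_features,
    pair_counts,
)
from poseforge.structio import AtomRecord, MoleculeStructure, assemble_pose_set

from conftest import random_structure


def mono(element, coords, name="m"):
    return MoleculeStructure(name, [AtomRecord(element, coords)])


def brute_force_counts(receptor, ligand, bin_edges):
    """Exhaustive double loop over all atom pairs, independent of cdist path."""
    counts = {}
    for b in range(len(bin_edges) - 1):
        for p in PROTEIN_ELEMENTS:
            for l in LIGAND_ELEMENTS:
                counts[(b, p, l)] = 0
    for pa in receptor.atoms:
        for la in ligand.atoms:
            if pa.element not in PROTEIN_ELEMENTS or la.element not in LIGAND_ELEMENTS:
                continue
            d = sum((x - y) ** 2 for x, y in zip(pa.coords, la.coords)) ** 0.5
            if d <= 0 or d > bin_edges[-1]:
                continue
            for b in range(len(bin_edges) - 1):
                if bin_edges[b] < d <= bin_edges[b + 1]:
                    counts[(b, pa.element, la.element)] += 1
    order = [
        (b, p, l)
        for b in range(len(bin_edges) - 1)
        for p in PROTEIN_ELEMENTS
        for l in LIGAND_ELEMENTS
    ]
    return np.array([counts[k] for k in order])


class TestPairCounts:
    def test_single_pair_increments_one_key(self):
        rec = mono("N", (0.0, 0.0, 0.0))
        lig = mono("C", (5.0, 0.0, 0.0))
        vec = pair_counts(rec, lig)
        assert len(vec.counts) == 36
        assert vec.counts.sum() == 1
        assert vec.as_series()["R.N.C"] == 1

    def test_pair_beyond_cutoff_counts_nothing(self):
        rec = mono("N", (0.0, 0.0, 0.0))
        lig = mono("C", (12.5, 0.0, 0.0))
        assert pair_counts(rec, lig, cutoff=12).counts.sum() == 0

    def test_pair_exactly_at_cutoff_is_included(self):
        rec = mono("C", (0.0, 0.0, 0.0))
        lig = mono("O", (12.0, 0.0, 0.0))
        assert pair_counts(rec, lig, cutoff=12).counts.sum() == 1

    def test_unknown_elements_ignored(self):
        rec = mono("ZN", (0.0, 0.0, 0.0))
        lig = mono("C", (3.0, 0.0, 0.0))
        assert pair_counts(rec, lig).counts.sum() == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            rec = random_structure(rng, 50, elements=("C", "N", "O", "S", "ZN"), scale=8)
            lig = random_structure(rng, 10, elements=("C", "N", "O", "CL", "BR"), scale=8)
            vec = pair_counts(rec, lig, cutoff=12)
            assert np.array_equal(vec.counts, brute_force_counts(rec, lig, (0, 12)))

    def test_atom_order_permutation_invariance(self, rng):
        rec = random_structure(rng, 30, scale=6)
        lig = random_structure(rng, 8, elements=("C", "N", "O"), scale=6)
        perm_rec = MoleculeStructure("p", [rec.atoms[i] for i in rng.permutation(len(rec))])
        perm_lig = MoleculeStructure("q", [lig.atoms[i] for i in rng.permutation(len(lig))])
        assert np.array_equal(
            pair_counts(rec, lig).counts, pair_counts(perm_rec, perm_lig).counts
        )


class TestBinnedPairCounts:
    def test_default_scheme_yields_180_features(self, rng):
        rec = random_structure(rng, 10)
        lig = random_structure(rng, 5, elements=("C", "O"))
        assert len(binned_pair_counts(rec, lig).counts) == 180

    def test_pair_lands_in_correct_bin(self):
        rec = mono("C", (0.0, 0.0, 0.0))
        lig = mono("O", (9.0, 0.0, 0.0))
        vec = binned_pair_counts(rec, lig)
        assert vec.as_series()["R.C.O.8-12"] == 1
        assert vec.counts.sum() == 1

    def test_count_conservation_against_flat_cutoff(self, rng):
        for _ in range(10):
            rec = random_structure(rng, 40, scale=9)
            lig = random_structure(rng, 8, elements=("C", "N", "O", "S"), scale=9)
            binned = binned_pair_counts(rec, lig, bin_edges=(0, 4, 8, 12))
            flat = pair_counts(rec, lig, cutoff=12)
            summed = binned.counts.reshape(3, 36).sum(axis=0)
            assert np.array_equal(summed, flat.counts)

    def test_binned_matches_brute_force(self, rng):
        rec = random_structure(rng, 40, scale=12)
        lig = random_structure(rng, 8, elements=("C", "N", "F", "I"), scale=12)
        vec = binned_pair_counts(rec, lig)
        assert np.array_equal(vec.counts, brute_force_counts(rec, lig, (0, 4, 8, 12, 16, 20)))

    def test_non_monotone_edges_rejected(self, rng):
        rec = random_structure(rng, 3)
        lig = random_structure(rng, 3)
        with pytest.raises(ValueError):
            binned_pair_counts(rec, lig, bin_edges=(0, 8, 4))
        with pytest.raises(ValueError):
            binned_pair_counts(rec, lig, bin_edges=(1, 4, 8))


class TestFamilyCombinations:
    def test_four_families_give_fifteen(self):
        combos = enumerate_family_combinations(("X", "A", "R", "G"))
        assert len(combos) == 15
        assert len({c.label for c in combos}) == 15

    def test_two_families_give_three(self):
        labels = [c.label for c in enumerate_family_combinations(("X", "G"))]
        # size-then-lexicographic enumeration order; labels are canonical
        assert labels == ["G", "X", "XG"]
        assert set(labels) == {"X", "G", "XG"}

    def test_single_family(self):
        assert [c.label for c in enumerate_family_combinations(("R",))] == ["R"]

    def test_selection_is_order_insensitive(self):
        assert FeatureFamilySelection("XR").label == FeatureFamilySelection("RX").label == "XR"

    def test_widths_and_pool_arithmetic(self):
        assert FAMILY_WIDTHS == {"X": 6, "A": 30, "R": 36, "G": 14}
        assert sum(FAMILY_WIDTHS.values()) == 86
        # extended pool when the binned variant replaces plain R
        assert 6 + 30 + 14 + 36 * 5 == 230


class TestExternalFeatures:
    def _write(self, tmp_path, df, name="x.csv"):
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    def test_nominal_x_table_loads(self, tmp_path):
        df = pd.DataFrame(
            {
                "complex_id": [f"c{i}" for i in range(10)],
                "pose_id": ["native"] * 10,
                **{f"f{j}": np.arange(10.0) for j in range(6)},
            }
        )
        frag = load_external_features(self._write(tmp_path, df), "X")
        assert frag.shape == (10, 6)
        assert all(c.startswith("X.") for c in frag.columns)

    def test_width_mismatch_warns_but_loads(self, tmp_path):
        df = pd.DataFrame(
            {
                "complex_id": ["c1"],
                "pose_id": ["native"],
                **{f"f{j}": [1.0] for j in range(29)},
            }
        )
        with pytest.warns(UserWarning, match="29"):
            frag = load_external_features(self._write(tmp_path, df), "A")
        assert frag.shape == (1, 29)

    def test_duplicate_key_raises_schema_error(self, tmp_path):
        df = pd.DataFrame(
            {"complex_id": ["c1", "c1"], "pose_id": ["p1", "p1"], "f": [1.0, 2.0]}
        )
        with pytest.raises(SchemaError, match="c1"):
            load_external_features(self._write(tmp_path, df), "G")

    def test_missing_key_columns_raise(self, tmp_path):
        df = pd.DataFrame({"complex": ["c1"], "f": [1.0]})
        with pytest.raises(SchemaError, match="pose_id"):
            load_external_features(self._write(tmp_path, df), "X")


class TestBuildFeatureTable:
    def _pose_sets(self, rng, n_complexes=2, n_decoys=4):
        out = []
        for i in range(n_complexes):
            rec = random_structure(rng, 20, name=f"c{i}")
            nat = random_structure(rng, 6, elements=("C", "N", "O"), name="nat")
            cands = [
                nat.with_coords(nat.coords + rng.normal(size=(6, 3)), f"d{j}")
                for j in range(n_decoys)
            ]
            out.append(assemble_pose_set(rec, nat, cands, complex_id=f"c{i}"))
        return out

    def test_row_and_column_counts(self, rng):
        table = build_feature_table(self._pose_sets(rng), selection=("R",))
        assert table.shape[0] == 2 * 5
        feature_cols = [c for c in table.columns if c.startswith("R.")]
        assert len(feature_cols) == 36

    def test_native_rows_have_zero_rmsd_and_ba(self, rng):
        ba = {"c0": 6.1, "c1": 7.9}
        table = build_feature_table(self._pose_sets(rng), selection=("R",), ba=ba)
        natives = table.xs("native", level="pose_id")
        assert (natives["RMSD"] == 0.0).all()
        assert natives["BA"].tolist() == [6.1, 7.9]
        decoys = table[table.index.get_level_values("pose_id") != "native"]
        assert decoys["BA"].isna().all()

    def test_missing_external_fragment_is_coverage_error(self, rng):
        pose_sets = self._pose_sets(rng)
        with pytest.raises(CoverageError, match="G"):
            build_feature_table(pose_sets, selection=("R", "G"))

    def test_incomplete_fragment_lists_missing_keys(self, rng):
        pose_sets = self._pose_sets(rng)
        rows = [
            {"complex_id": ps.complex_id, "pose_id": pid, **{f"G.g{j}": 0.0 for j in range(14)}}
            for ps in pose_sets
            for pid in ["native"] + [c.molecule_id for c in ps.candidates]
        ]
        frag = pd.DataFrame(rows[:-1]).set_index(["complex_id", "pose_id"])  # drop one pose
        with pytest.raises(CoverageError):
            build_feature_table(pose_sets, selection=("R", "G"), external={"G": frag})
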