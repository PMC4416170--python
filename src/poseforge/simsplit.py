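"""Similarity-constrained train/test splits for the novel-target protocol.

The protocol evaluates scoring functions on proteins dissimilar to anything
they were trained on: a test set of ``n_test`` complexes is drawn at random,
then ``T`` training complexes are sought whose binding-site similarity to
*every* test complex is at most a cutoff S (%). If fewer than T qualify, a
fresh test set is drawn and the search repeats. Similarity comes in as a
precomputed symmetric percentage matrix (the original protocol used BLAST
binding-site similarity; computing it is out of scope here). A deterministic
global-alignment sequence-identity scorer is provided as a testing
surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "SplitSpec",
    "InfeasibleSplitError",
    "constrained_split",
    "repeat_splits",
    "verify_split",
    "sequence_identity",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class InfeasibleSplitError(RuntimeError):
    """No admissible split found within the retry budget."""

    def __init__(self, message: str, best_achievable_T: int):
        super().__init__(message)
        self.best_achievable_T = best_achievable_T


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity in % over complex ids; diagonal = 100."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if list(df.index) != list(df.columns):
            raise ValueError("similarity matrix must have identical row/column ids")
        vals = df.to_numpy(dtype=np.float64)
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValueError("similarities must lie in [0, 100]")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric (within 1e-9)")
        if not np.allclose(np.diag(vals), 100.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must be 100")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def sim(self, a: str, b: str) -> float:
        return float(self.data.loc[a, b])

    def max_to_set(self, candidate: str, group: Sequence[str]) -> float:
        return float(self.data.loc[candidate, list(group)].max())

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)


@dataclass(frozen=True)
class SplitSpec:
    S: float  # similarity cutoff in %
    T: int  # training-set size
    n_test: int = 100
    n_repeats: int = 100
    max_retries: int = 200
    seed: int = 20070101

    def __post_init__(self) -> None:
        if not 0 < self.S <= 100:
            raise ValueError("S must lie in (0, 100]")
        if self.T < 1 or self.n_test < 1:
            raise ValueError("T and n_test must be >= 1")


def constrained_split(
    ids: Sequence[str],
    sim: SimilarityMatrix,
    spec: SplitSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str]]:
    """One (train, test) pair with max train-test similarity <= S.

    Resamples the test set (up to ``max_retries`` times) whenever fewer than
    T training complexes qualify.
    """
    ids = list(ids)
    if len(ids) < spec.n_test + spec.T:
        raise ValueError(
            f"need at least n_test + T = {spec.n_test + spec.T} ids, got {len(ids)}"
        )
    rng = rng or np.random.default_rng(spec.seed)
    S = spec.S
    mat = sim.data.loc[ids, ids].to_numpy(dtype=np.float64)
    best_T = 0
    for _attempt in range(spec.max_retries):
        test_pos = rng.choice(len(ids), size=spec.n_test, replace=False)
        test_mask = np.zeros(len(ids), dtype=bool)
        test_mask[test_pos] = True
        # a training candidate must be <= S similar to EVERY test complex
        max_sim_to_test = mat[:, test_mask].max(axis=1)
        pool = np.flatnonzero(~test_mask & (max_sim_to_test <= S))
        best_T = max(best_T, len(pool))
        if len(pool) >= spec.T:
            # scan the remaining complexes in random order until T are found
            order = rng.permutation(pool)
            train_pos = order[: spec.T]
            return [ids[i] for i in train_pos], [ids[i] for i in test_pos]
    raise InfeasibleSplitError(
        f"no split with T={spec.T} at S={S}% after {spec.max_retries} attempts "
        f"(best achievable T was {best_T})",
        best_achievable_T=best_T,
    )


def repeat_splits(
    ids: Sequence[str],
    sim: SimilarityMatrix,
    spec: SplitSpec,
) -> list[tuple[list[str], list[str]]]:
    """``n_repeats`` independent constrained splits, reproducible under seed."""
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_repeats) % (2**31)
    out = []
    for i, s in enumerate(child_seeds):
        try:
            out.append(constrained_split(ids, sim, spec, rng=np.random.default_rng(int(s))))
        except InfeasibleSplitError as exc:
            raise InfeasibleSplitError(f"repeat {i}: {exc}", exc.best_achievable_T) from exc
    return out


def verify_split(
    train: Sequence[str],
    test: Sequence[str],
    sim: SimilarityMatrix,
    S: float,
) -> bool:
    """True iff the sides are disjoint and every train-test pair is <= S similar."""
    if set(train) & set(test):
        return False
    sub = sim.data.loc[list(train), list(test)].to_numpy(dtype=np.float64)
    return bool(np.all(sub <= S + 1e-9))


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment % identity between two amino-acid sequences.

    Needleman-Wunsch with match +1, mismatch 0, linear gap -1; identity is
    matched positions over total alignment columns × 100. A deterministic
    surrogate for BLAST binding-site similarity, intended for tests.
    """
    from Bio import Align

    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"{name} sequence has non-amino-acid letters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length
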