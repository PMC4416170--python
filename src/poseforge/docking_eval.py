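"""Docking-power evaluation: S_C^N success rates and experiment harnesses.

S_C^N is the percentage of complexes for which at least one of the N
top-ranked poses lies within C Å RMSD of the native pose. S_0^1 — the top
pose *is* the native pose — is the most stringent variant; C = 0 is tested
as RMSD <= ``zero_tolerance`` (default 1e-6 Å) to be robust to float noise.
The hit test is inclusive (RMSD <= C).

The harnesses reproduce the study designs around that statistic: native-pose
exclusion, learning curves over training-set size (more complexes, or more
poses per complex), and curves over the number of randomly drawn features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import sfmodels
from .sfmodels import ScoringModel

__all__ = [
    "EvalConfig",
    "SuccessRateReport",
    "success_rate",
    "evaluate",
    "rank_table",
    "learning_curve",
    "feature_curve",
]


@dataclass(frozen=True)
class EvalConfig:
    cutoffs: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    depths: tuple[int, ...] = (1, 2, 3, 5)
    include_native: bool = True
    zero_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be >= 0")
        if any(n < 1 for n in self.depths):
            raise ValueError("depths must be >= 1")


@dataclass
class SuccessRateReport:
    """Per-(C, N) success rates in %, plus the per-complex hit matrix."""

    rates: pd.DataFrame  # index C, columns N, values in [0, 100]
    hits: pd.DataFrame  # index complex_id, columns (C, N), boolean
    n_complexes: int
    config: EvalConfig

    def rate(self, C: float, N: int) -> float:
        return float(self.rates.loc[C, N])

    def check_monotone(self) -> None:
        """S_C^N must be non-decreasing in both C (rows) and N (columns)."""
        vals = self.rates.to_numpy()
        if np.any(np.diff(vals, axis=0) < -1e-9) or np.any(np.diff(vals, axis=1) < -1e-9):
            raise AssertionError("success rates are not monotone in C/N")


def _is_hit(ranked_rmsds: Sequence[float], C: float, N: int, zero_tol: float) -> bool:
    top = np.asarray(ranked_rmsds[:N], dtype=np.float64)
    thr = zero_tol if C == 0 else C
    return bool(np.any(top <= thr))


def success_rate(
    rankings: Mapping[str, Sequence[float]],
    C: float,
    N: int,
    zero_tolerance: float = 1e-6,
) -> float:
    """Percentage of complexes whose top-N ranked poses contain one within C Å."""
    if not rankings:
        raise ValueError("no complexes to evaluate")
    hits = 0
    for cid, rmsds in rankings.items():
        if len(rmsds) == 0:
            raise ValueError(f"complex {cid!r} has an empty ranking")
        hits += _is_hit(rmsds, C, N, zero_tolerance)
    return 100.0 * hits / len(rankings)


def report_from_rankings(
    rankings: Mapping[str, Sequence[float]],
    config: EvalConfig = EvalConfig(),
) -> SuccessRateReport:
    hit_rows = {}
    for cid, rmsds in rankings.items():
        if len(rmsds) == 0:
            raise ValueError(f"complex {cid!r} has an empty ranking")
        hit_rows[cid] = {
            (C, N): _is_hit(rmsds, C, N, config.zero_tolerance)
            for C in config.cutoffs
            for N in config.depths
        }
    hits = pd.DataFrame.from_dict(hit_rows, orient="index")
    hits.columns = pd.MultiIndex.from_tuples(hits.columns, names=["C", "N"])
    rates = pd.DataFrame(
        {N: [100.0 * hits[(C, N)].mean() for C in config.cutoffs] for N in config.depths},
        index=list(config.cutoffs),
    )
    rates.index.name = "C"
    rates.columns.name = "N"
    report = SuccessRateReport(rates, hits, len(rankings), config)
    report.check_monotone()
    return report


def rank_table(
    model: ScoringModel,
    table: pd.DataFrame,
    config: EvalConfig = EvalConfig(),
) -> dict[str, np.ndarray]:
    """Per-complex true-RMSD lists ordered by the model's ranking."""
    rankings: dict[str, np.ndarray] = {}
    for cid, group in table.groupby(level="complex_id", sort=False):
        if not config.include_native:
            group = group[group["RMSD"] > config.zero_tolerance]
        if len(group) == 0:
            raise ValueError(f"complex {cid!r} has no poses after native exclusion")
        order = sfmodels.rank_poses(model, group)
        rankings[str(cid)] = group["RMSD"].to_numpy(dtype=np.float64)[order]
    return rankings


def evaluate(
    model: ScoringModel,
    table: pd.DataFrame,
    config: EvalConfig = EvalConfig(),
) -> SuccessRateReport:
    """Rank every complex's poses with the model and tabulate S_C^N."""
    return report_from_rankings(rank_table(model, table, config), config)


# ---------------------------------------------------------------------------
# experiment harnesses


def _s11(model: ScoringModel, test_table: pd.DataFrame, config: EvalConfig) -> float:
    return success_rate(rank_table(model, test_table, config), 1.0, 1, config.zero_tolerance)


def learning_curve(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    method: str,
    response: str = "RMSD",
    params: Mapping | None = None,
    fractions: Sequence[float] = tuple(range(10, 101, 10)),
    repeats: int = 50,
    seed: int = sfmodels.DEFAULT_SEED,
    axis: str = "complexes",
    config: EvalConfig = EvalConfig(),
    feature_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean S_1^1 vs training-set size, averaged over random subsamples.

    ``axis='complexes'`` samples the given percentage of training complexes
    (all their poses in RMSD mode, natives only in BA mode). With
    ``axis='poses'`` the ``fractions`` are absolute pose counts drawn per
    complex while every complex is kept (RMSD mode only).
    """
    if axis not in ("complexes", "poses"):
        raise ValueError("axis must be 'complexes' or 'poses'")
    rng_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    complexes = train_table.index.get_level_values("complex_id").unique().to_numpy()
    rows = []
    for x in fractions:
        rates = []
        for r in range(repeats):
            rng = np.random.default_rng(rng_seeds[r] + int(x))
            if axis == "complexes":
                if not 0 < x <= 100:
                    raise ValueError("fractions must lie in (0, 100]")
                n_keep = max(1, int(round(len(complexes) * x / 100.0)))
                keep = (
                    complexes
                    if n_keep >= len(complexes)
                    else rng.choice(complexes, size=n_keep, replace=False)
                )
                sub = train_table.loc[train_table.index.get_level_values("complex_id").isin(keep)]
            else:
                parts = []
                for cid, group in train_table.groupby(level="complex_id", sort=False):
                    n_take = min(int(x), len(group))
                    idx = (
                        np.arange(len(group))
                        if n_take == len(group)
                        else rng.choice(len(group), size=n_take, replace=False)
                    )
                    parts.append(group.iloc[np.sort(idx)])
                sub = pd.concat(parts)
            if len(sub.dropna(subset=[response])) < 10:
                raise ValueError(
                    f"fraction {x} leaves fewer than 10 usable training rows"
                )
            model = sfmodels.fit(
                sub, method, response=response, params=params,
                seed=int(rng_seeds[r]), feature_cols=feature_cols,
            )
            rates.append(_s11(model, test_table, config))
        rows.append({"size": x, "mean_s11": float(np.mean(rates)), "sd_s11": float(np.std(rates))})
    return pd.DataFrame(rows)


def feature_curve(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    method: str,
    pool: Sequence[str],
    response: str = "RMSD",
    params: Mapping | None = None,
    sizes: Sequence[int] = tuple(range(20, 221, 40)),
    repeats: int = 100,
    seed: int = sfmodels.DEFAULT_SEED,
    config: EvalConfig = EvalConfig(),
) -> pd.DataFrame:
    """Mean S_1^1 vs number of features randomly drawn (without replacement)."""
    pool = list(pool)
    if any(s > len(pool) for s in sizes):
        raise ValueError(f"requested subset size exceeds pool width {len(pool)}")
    rng_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    rows = []
    for size in sizes:
        rates = []
        n_rep = 1 if size == len(pool) else repeats
        for r in range(n_rep):
            rng = np.random.default_rng(rng_seeds[r] + size)
            cols = (
                pool
                if size == len(pool)
                else [pool[i] for i in np.sort(rng.choice(len(pool), size=size, replace=False))]
            )
            assert len(set(cols)) == len(cols)
            model = sfmodels.fit(
                train_table, method, response=response, params=params,
                seed=int(rng_seeds[r]), feature_cols=cols,
            )
            rates.append(_s11(model, test_table, config))
        rows.append(
            {"n_features": size, "mean_s11": float(np.mean(rates)), "sd_s11": float(np.std(rates))}
        )
    return pd.DataFrame(rows)
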