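"""Sparsity tuning by repeated balanced subsampling, and stability selection.

Tuning runs a one-component fit on many small class-balanced subsets for each
candidate sparsity value of one omic (the other omics held at a reference
value) and records the selected-feature count and the AVE.  The chosen value
maximises the mean AVE with a one-standard-error preference for fewer
features.

Stability selection counters LASSO-style instability: the final model is
refit many times on random half-samples, per-feature selection frequencies
are recorded, and only features selected in at least ``keep_threshold`` of
the runs are kept.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .blocks import OmicsBlock, check_aligned
from .exceptions import SamplingError, TuningError
from .sgcca import SGCCAParams, sgcca_fit

logger = logging.getLogger(__name__)

#: the default tuning grid: 0.01..0.09 step 0.01, then 0.1..0.9 step 0.1
DEFAULT_GRID = tuple(round(0.01 * i, 2) for i in range(1, 10)) + \
    tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass
class TuningResult:
    """Per (omic, grid value): mean/sd of AVE and selected count; chosen value per omic."""

    table: pd.DataFrame            # omic, sparsity, mean_ave, sd_ave, mean_n_selected, sd_n_selected, n_reps
    chosen: Dict[str, float]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class StabilityResult:
    """Per-feature selection frequencies over resampled refits and the kept set."""

    frequencies: pd.Series         # feature -> frequency in [0, 1]
    block_of: pd.Series            # feature -> omic type
    n_runs: int
    subsample_fraction: float
    keep_threshold: float
    seed: int

    @property
    def kept(self) -> list:
        f = self.frequencies
        return list(f.index[f.to_numpy() >= self.keep_threshold])

    def kept_at(self, threshold: float) -> list:
        f = self.frequencies
        return list(f.index[f.to_numpy() >= threshold])

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "feature": self.frequencies.index,
            "omic_type": self.block_of.reindex(self.frequencies.index).to_numpy(),
            "frequency": self.frequencies.to_numpy(),
            "kept": self.frequencies.to_numpy() >= self.keep_threshold,
        }).to_csv(path, sep="\t", index=False)


def _child_seeds(seed: int, count: int) -> np.ndarray:
    """Independent per-run seeds derived from a master seed via a counter."""
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=count)


def balanced_subset(labels: pd.Series, per_group: int, seed: int) -> list:
    """Exactly per_group samples drawn without replacement from each group.

    Groups are visited in order of first appearance; within each group the
    chosen samples keep their original order, so per_group == group size
    returns the group intact.
    """
    rng = np.random.default_rng(seed)
    chosen = []
    for g in pd.unique(labels):
        ids = list(labels.index[labels == g])
        if len(ids) < per_group:
            raise SamplingError(f"group {g!r} has {len(ids)} samples < per_group={per_group}")
        if len(ids) == per_group:
            pick = ids
        else:
            idx = rng.choice(len(ids), size=per_group, replace=False)
            pick = [ids[i] for i in sorted(idx)]
        chosen.extend(pick)
    return chosen


def tune_sparsity(blocks: Sequence[OmicsBlock], labels: pd.Series,
                  grid: Sequence[float] = DEFAULT_GRID, reps: int = 10,
                  per_group: int = 10, seed: int = 0,
                  reference: float = 0.1) -> TuningResult:
    """Grid-search sparsity per omic on repeated balanced subsets (one component).

    Other omics are held at ``reference`` (clamped up to 1/sqrt(p) when that
    is infeasible for a small block).  Infeasible grid values are skipped
    with a log entry.  The chosen value per omic is the one-standard-error
    pick: among values whose mean AVE is within one SE of the best, the one
    selecting fewest features.
    """
    blocks = list(blocks)
    check_aligned(blocks)
    if not all(0 < g <= 1 for g in grid):
        raise TuningError("grid values must lie in (0, 1]")
    dims = [b.n_features for b in blocks]
    floors = [1.0 / math.sqrt(p) for p in dims]
    ref = [max(reference, f) for f in floors]
    for j, (r, f) in enumerate(zip(ref, floors)):
        if r > reference:
            logger.info("reference sparsity clamped to %.4f for block %d (1/sqrt(p))", r, j)

    # common random subsets: the same balanced draws are reused for every
    # grid value, so AVE differences across the grid are paired comparisons
    # rather than being dominated by the subset draw
    seeds = _child_seeds(seed, reps)
    subsets = [balanced_subset(labels, per_group, int(s)) for s in seeds]
    sub_block_cache = [[b.subset_samples(sub) for b in blocks] for sub in subsets]
    rows = []
    chosen = {}
    for j, block in enumerate(blocks):
        per_value = []
        for g in grid:
            if g < floors[j] - 1e-12:
                logger.info("skipping infeasible sparsity %.3g for omic %s (p=%d)",
                            g, block.omic_type, dims[j])
                continue
            aves, counts = [], []
            for r in range(reps):
                sub_blocks = sub_block_cache[r]
                sp = list(ref)
                sp[j] = g
                model = sgcca_fit(sub_blocks, SGCCAParams(sparsity=sp, ncomp=1))
                aves.append(float(model.ave.iloc[0][block.omic_type]))
                counts.append(len(model.selected(0, j)))
            rows.append({"omic": block.omic_type, "sparsity": g,
                         "mean_ave": float(np.mean(aves)), "sd_ave": float(np.std(aves, ddof=1)) if reps > 1 else 0.0,
                         "mean_n_selected": float(np.mean(counts)),
                         "sd_n_selected": float(np.std(counts, ddof=1)) if reps > 1 else 0.0,
                         "n_reps": reps})
            per_value.append(rows[-1])
        if not per_value:
            raise TuningError(f"no feasible grid value for omic {block.omic_type}")
        best = max(per_value, key=lambda r: r["mean_ave"])
        se = best["sd_ave"] / math.sqrt(best["n_reps"])
        near = [r for r in per_value if r["mean_ave"] >= best["mean_ave"] - se]
        pick = min(near, key=lambda r: (r["mean_n_selected"], r["sparsity"]))
        chosen[block.omic_type] = float(pick["sparsity"])
    return TuningResult(table=pd.DataFrame(rows), chosen=chosen)


def stability_select(blocks: Sequence[OmicsBlock], params: SGCCAParams,
                     n_runs: int = 100, subsample_fraction: float = 0.5,
                     keep_threshold: float = 0.7, seed: int = 0) -> StabilityResult:
    """Refit on n_runs random subsamples; keep features selected often enough.

    A feature counts as selected in a run if any component gives it a
    non-zero loading.
    """
    blocks = list(blocks)
    check_aligned(blocks)
    if not 0 < subsample_fraction < 1:
        raise SamplingError("subsample_fraction must be in (0, 1)")
    if n_runs < 1:
        raise SamplingError("n_runs must be >= 1")
    n = blocks[0].n_samples
    m = int(math.floor(subsample_fraction * n))
    if m < 3:
        raise SamplingError(f"subsample of {m} samples is too small")
    # draws are made over the sorted ids so frequencies do not depend on the
    # row order of the input blocks
    samples = sorted(blocks[0].sample_ids)
    all_features = [f for b in blocks for f in b.feature_ids]
    block_of = pd.Series({f: b.omic_type for b in blocks for f in b.feature_ids})
    counts = pd.Series(0, index=pd.Index(all_features), dtype=int)
    seeds = _child_seeds(seed, n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng(int(seeds[r]))
        idx = sorted(rng.choice(n, size=m, replace=False))
        sub = [samples[i] for i in idx]
        model = sgcca_fit([b.subset_samples(sub) for b in blocks], params)
        selected = set()
        for h in range(model.ncomp):
            for j in range(len(blocks)):
                selected.update(model.selected(h, j))
        counts.loc[list(selected)] += 1
    freq = counts / n_runs
    return StabilityResult(frequencies=freq, block_of=block_of, n_runs=n_runs,
                           subsample_fraction=subsample_fraction,
                           keep_threshold=keep_threshold, seed=seed)
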