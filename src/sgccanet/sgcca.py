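"""Sparse generalized canonical correlation analysis, centroid scheme.

Given J sample-aligned blocks X_1..X_J and a symmetric design matrix C with
zero diagonal, the centroid-scheme objective is

    maximize  sum_{j<k} c_jk * | cov(X_j a_j, X_k a_k) |
    subject to ||a_j||_2 = 1  and  ||a_j||_1 <= s_j * sqrt(p_j)

for per-block loading vectors a_j.  The absolute value permits negatively
correlated blocks.  The l1 bound (LASSO-style) drives exact zeros in the
loadings; s_j in (1/sqrt(p_j), 1] interpolates between a one-feature solution
and the unconstrained unit sphere.  The problem is solved by block-coordinate
ascent: each a_j update maximises v'a over the l2-sphere/l1-ball intersection
with v the gradient of a sign-fixed linearisation, a step that never decreases
the objective.  Further components come from deflating each block by its own
component score and refitting.

Covariances use the 1/(n-1) convention throughout.
"""
from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blocks import OmicsBlock, check_aligned
from .exceptions import ConstraintError, DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters and model containers
# ---------------------------------------------------------------------------

@dataclass
class SGCCAParams:
    """Hyper-parameters of a multi-block sparse fit.

    sparsity : per-block values in (0, 1]; the l1 bound on block j is
        sparsity[j] * sqrt(p_j) and must be >= 1, i.e. sparsity[j] >= 1/sqrt(p_j).
    ncomp : number of components to extract (extraction may stop early when a
        deflated block is numerically zero or the objective is below tol).
    design : symmetric nonnegative J x J connection matrix, zero diagonal.
        None means fully connected (c_jk = 1 for j != k).
    n_starts : deterministic ascent restarts per component.  The |cov| terms
        make the objective multimodal; the first start is the dominant-
        singular-vector initialisation, followed by its relative sign flips
        and fixed-seed random unit starts.  The best final objective wins.
    """

    sparsity: Sequence[float] | float = 1.0
    ncomp: int = 1
    design: Optional[np.ndarray] = None
    scheme: str = "centroid"
    max_iter: int = 1000
    tol: float = 1e-8
    n_starts: int = 16

    def resolve(self, n_blocks: int, dims: Sequence[int]):
        if self.scheme != "centroid":
            raise ValidationError(f"unsupported scheme {self.scheme!r}; only 'centroid'")
        if self.ncomp < 1:
            raise ValidationError("ncomp must be >= 1")
        s = self.sparsity
        if np.isscalar(s):
            s = [float(s)] * n_blocks
        s = [float(v) for v in s]
        if len(s) != n_blocks:
            raise ValidationError("one sparsity value per block required")
        for v, p in zip(s, dims):
            if not 0 < v <= 1:
                raise ValidationError("sparsity values must lie in (0, 1]")
            if v * np.sqrt(p) < 1 - 1e-12:
                raise ConstraintError(
                    f"sparsity {v} infeasible for block of dimension {p}: need >= 1/sqrt(p)"
                )
        if self.design is None:
            C = np.ones((n_blocks, n_blocks)) - np.eye(n_blocks)
        else:
            C = np.asarray(self.design, dtype=float)
            if C.shape != (n_blocks, n_blocks):
                raise ValidationError("design matrix shape mismatch")
            if not np.allclose(C, C.T) or (np.diag(C) != 0).any() or (C < 0).any():
                raise ValidationError("design must be symmetric, nonnegative, zero diagonal")
        return s, C


@dataclass
class SGCCAModel:
    """Fitted model: per component h and block j, sparse loadings and scores.

    loadings[h][j] is a pandas Series over block j's features (unit l2 norm),
    scores[h][j] the sample-level projection of the (deflated) block, and
    ave.loc[h, block] the variance-weighted mean squared correlation between
    the original block's features and the component score.
    """

    loadings: list  # [comp][block] -> pd.Series
    scores: list    # [comp][block] -> pd.Series
    ave: pd.DataFrame
    objective_traces: list
    converged: list
    sparsity: list
    design: np.ndarray
    block_names: list
    sample_ids: list

    @property
    def ncomp(self) -> int:
        return len(self.loadings)

    def selected(self, comp: int, block: int) -> list:
        """Features of one block with exactly non-zero loading in a component."""
        a = self.loadings[comp][block]
        return list(a.index[a.to_numpy() != 0.0])

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        for j, name in enumerate(self.block_names):
            L = pd.DataFrame({f"comp{h + 1}": self.loadings[h][j] for h in range(self.ncomp)})
            L.to_csv(os.path.join(directory, f"loadings_{name}.tsv"), sep="\t",
                     index_label="feature")
            S = pd.DataFrame({f"comp{h + 1}": self.scores[h][j] for h in range(self.ncomp)})
            S.to_csv(os.path.join(directory, f"scores_{name}.tsv"), sep="\t",
                     index_label="sample_id")
        self.ave.to_csv(os.path.join(directory, "ave.tsv"), sep="\t", index_label="component")
        meta = {
            "block_names": list(self.block_names),
            "sparsity": list(self.sparsity),
            "design": np.asarray(self.design).tolist(),
            "converged": [bool(c) for c in self.converged],
            "objective_traces": [[float(v) for v in t] for t in self.objective_traces],
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise sign(v) * max(|v| - lam, 0)."""
    if lam < 0:
        raise ValidationError("lam must be nonnegative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def project_l1_sphere(v: np.ndarray, t: float) -> np.ndarray:
    """Maximise v'a over {||a||_2 = 1, ||a||_1 <= t}.

    The maximiser has the form a = S(v, lam)/||S(v, lam)||_2 with S the
    soft-threshold operator and lam >= 0 the smallest value making the l1
    constraint hold; lam is found by bisection.  t must be >= 1 (the l1 norm
    of any unit-l2 vector is at least 1).
    """
    v = np.asarray(v, dtype=float)
    if t < 1 - 1e-12:
        raise ConstraintError("l1 bound t < 1 is infeasible with a unit l2 norm")
    nrm2 = np.linalg.norm(v)
    if nrm2 == 0:
        raise ValidationError("cannot project the zero vector")
    a = v / nrm2
    if np.abs(a).sum() <= t + 1e-12:
        return a

    def unit(lam):
        s = soft_threshold(v, lam)
        n = np.linalg.norm(s)
        return s / n if n > 0 else None

    lo, hi = 0.0, float(np.abs(v).max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        u = unit(mid)
        if u is None or np.abs(u).sum() > t:
            lo = mid
        else:
            hi = mid
    u = unit(hi)
    if u is None or np.abs(u).sum() > t + 1e-8:
        # only reachable when |v| ties at its max and t is below sqrt(#ties):
        # fall back to the tightest feasible solution, a signed one-hot.
        i = int(np.argmax(np.abs(v)))
        u = np.zeros_like(v)
        u[i] = np.sign(v[i]) or 1.0
    return u


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float((a - a.mean()) @ (b - b.mean()) / (len(a) - 1))


def centroid_objective(scores: Sequence[np.ndarray], design: np.ndarray) -> float:
    """sum_{j<k} c_jk * |cov(y_j, y_k)| over block score vectors."""
    ys = [np.asarray(y, dtype=float) for y in scores]
    n = {len(y) for y in ys}
    if len(n) != 1:
        raise ValidationError("score vectors must have equal length")
    C = np.asarray(design, dtype=float)
    total = 0.0
    for j in range(len(ys)):
        for k in range(j + 1, len(ys)):
            if C[j, k] != 0:
                total += C[j, k] * abs(_cov(ys[j], ys[k]))
    return total


def deflate(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove the score direction from a block: X - y (y'X)/(y'y)."""
    y = np.asarray(y, dtype=float)
    denom = float(y @ y)
    if denom <= 1e-300:
        raise DegenerateDataError("cannot deflate by a zero score")
    return X - np.outer(y, y @ X) / denom


def compute_ave(X: np.ndarray, y: np.ndarray) -> float:
    """Variance-weighted mean over features of cor^2(feature, score).

    Zero-variance features are excluded from the average.  The score must
    have nonzero variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    sy = float(yc @ yc)
    if sy <= 1e-300:
        raise DegenerateDataError("score has zero variance")
    Xc = X - X.mean(axis=0)
    var = (Xc ** 2).sum(axis=0)
    ok = var > 1e-300
    if not ok.any():
        return 0.0
    num = Xc[:, ok].T @ yc
    cor2 = num ** 2 / (var[ok] * sy)
    w = var[ok] / (len(y) - 1)
    return float((w * cor2).sum() / w.sum())


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------

def _init_loading(X: np.ndarray) -> np.ndarray:
    """Dominant right singular vector (deterministic sign: largest entry positive)."""
    if np.linalg.norm(X) <= 1e-300:
        a = np.zeros(X.shape[1])
        a[0] = 1.0
        return a
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    a = vt[0]
    i = int(np.argmax(np.abs(a)))
    if a[i] < 0:
        a = -a
    return a


def _block_coordinate_ascent(Xs, C, bounds, a_init, n, tol, max_iter):
    """One ascent run from a given start; returns (a, y, trace, converged)."""
    a = [ai.copy() for ai in a_init]
    y = [x @ ai for x, ai in zip(Xs, a)]
    prev = centroid_objective(y, C)
    trace = [prev]
    conv = False
    for _ in range(max_iter):
        for j in range(len(Xs)):
            z = np.zeros(n)
            for k in range(len(Xs)):
                if k == j or C[j, k] == 0:
                    continue
                z += C[j, k] * np.sign(_cov(y[j], y[k])) * y[k]
            v = Xs[j].T @ (z - z.mean())
            if np.linalg.norm(v) <= 1e-14:
                continue
            a[j] = project_l1_sphere(v, bounds[j])
            y[j] = Xs[j] @ a[j]
        obj = centroid_objective(y, C)
        trace.append(obj)
        if obj - prev <= tol * max(1.0, abs(obj)):
            conv = True
            break
        prev = obj
    return a, y, trace, conv


def sgcca_fit(blocks: Sequence[OmicsBlock], params: SGCCAParams) -> SGCCAModel:
    """Fit the centroid-scheme sparse multi-block model.

    Blocks are column-centered internally.  Non-convergence within max_iter
    sets a flag on the model rather than raising.
    """
    blocks = list(blocks)
    check_aligned(blocks)
    dims = [b.n_features for b in blocks]
    sparsity, C = params.resolve(len(blocks), dims)
    n = blocks[0].n_samples
    if n < 3:
        raise ValidationError("need at least 3 samples")
    for b in blocks:
        if np.isnan(b.values).any():
            raise ValidationError(f"block {b.omic_type} has missing values; impute first")

    X0 = [b.values - b.values.mean(axis=0) for b in blocks]
    Xs = [x.copy() for x in X0]
    bounds = [s * np.sqrt(p) for s, p in zip(sparsity, dims)]
    names = [b.omic_type for b in blocks]
    sample_ids = blocks[0].sample_ids

    loadings, scores, traces, converged, ave_rows = [], [], [], [], []
    for h in range(params.ncomp):
        if all(np.linalg.norm(x) <= 1e-10 for x in Xs):
            logger.info("stopping at component %d: all deflated blocks are zero", h + 1)
            break
        # initial loadings: dominant right singular vectors, projected onto
        # the constraint set so the whole trace lives in the feasible region
        a0 = []
        for x, t in zip(Xs, bounds):
            ai = _init_loading(x)
            if np.abs(ai).sum() > t + 1e-12:
                ai = project_l1_sphere(ai, t)
            a0.append(ai)
        # multimodal landscape: collect deterministic starts (SVD init, its
        # relative sign flips, then fixed-seed random unit vectors), run the
        # ascent from each, keep the best final objective
        starts = []
        for pattern in itertools.product((1.0, -1.0), repeat=len(Xs) - 1):
            signs = (1.0,) + pattern
            starts.append([s * ai for s, ai in zip(signs, a0)])
        rng = np.random.default_rng(987654321 + h)
        while len(starts) < params.n_starts:
            cand = []
            for x, t in zip(Xs, bounds):
                v = rng.standard_normal(x.shape[1])
                v /= max(np.linalg.norm(v), 1e-12)
                if np.abs(v).sum() > t + 1e-12:
                    v = project_l1_sphere(v, t)
                cand.append(v)
            starts.append(cand)
        best = None
        for a_start in starts[:max(1, params.n_starts)]:
            run = _block_coordinate_ascent(Xs, C, bounds, a_start, n,
                                           params.tol, params.max_iter)
            if best is None or run[2][-1] > best[2][-1]:
                best = run
        a, y, trace, conv = best
        if not conv:
            logger.warning("component %d did not converge in %d iterations", h + 1, params.max_iter)
        loadings.append([pd.Series(ai, index=b.feature_ids, name=f"comp{h + 1}")
                         for ai, b in zip(a, blocks)])
        scores.append([pd.Series(yi, index=sample_ids, name=f"comp{h + 1}") for yi in y])
        traces.append(trace)
        converged.append(conv)
        row = {}
        for j, name in enumerate(names):
            yj = y[j]
            if float((yj - yj.mean()) @ (yj - yj.mean())) <= 1e-300:
                row[name] = 0.0
            else:
                row[name] = compute_ave(X0[j], yj)
        ave_rows.append(row)
        final = trace[-1]
        Xs = [deflate(x, yi) if float(yi @ yi) > 1e-300 else x for x, yi in zip(Xs, y)]
        if final < params.tol:
            logger.info("stopping after component %d: objective %.3g below tol", h + 1, final)
            break

    ave = pd.DataFrame(ave_rows, index=[f"comp{h + 1}" for h in range(len(ave_rows))])
    return SGCCAModel(loadings=loadings, scores=scores, ave=ave,
                      objective_traces=traces, converged=converged,
                      sparsity=sparsity, design=C, block_names=names,
                      sample_ids=sample_ids)


def co_selected_sets(model: SGCCAModel) -> list:
    """Per component, the union across blocks of features with non-zero loading."""
    out = []
    for h in range(model.ncomp):
        s = set()
        for j in range(len(model.block_names)):
            s.update(model.selected(h, j))
        out.append(s)
    return out
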