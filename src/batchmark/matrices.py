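"""Observed counts and the linear map from latent history counts to data.

With batch marks, individual histories are unobservable.  The data are

* ``m_kt`` -- individuals first marked on occasion ``t`` of period ``k``,
* ``n_kjt`` -- individuals marked in period ``k`` and recaptured on occasion
  ``t`` of period ``j``.

Structural zeros (``j < k``, or ``j = k`` with ``t = 1``) are removed from
``n``.  Both blocks are linear in the latent multinomial counts ``x``:
``m = A x``, ``n = B x``, and stacking gives ``y = T x`` with ``T`` a known
0/1 matrix whose columns follow the canonical history order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .design import StudyDesign
from .histories import capture_period_range, enumerate_histories, first_capture


def count_index(design: StudyDesign):
    """Ordered index lists for the ``m`` and ``n`` blocks.

    ``m`` entries are ``(k, t)`` in period-major order; ``n`` entries are
    ``(k, j, t)`` lexicographic with ``k < j`` (any ``t``) or ``k = j`` and
    ``t >= 2``.  All indices 1-based.
    """
    m_index = design.occasions
    n_index = []
    for k in range(1, design.K + 1):
        for j in range(k, design.K + 1):
            for t in range(1, design.Tks[j - 1] + 1):
                if j == k and t == 1:
                    continue
                n_index.append((k, j, t))
    return m_index, n_index


@dataclass
class CountData:
    """Observed batch-mark counts for a given study design.

    ``m`` is ordered as ``count_index``'s m-block, ``n`` as its n-block.
    """

    design: StudyDesign
    m: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m)
        self.n = np.asarray(self.n)
        m_index, n_index = count_index(self.design)
        if self.m.shape != (len(m_index),):
            raise ValueError("m has wrong length for this design")
        if self.n.shape != (len(n_index),):
            raise ValueError("n has wrong length for this design")
        for name, arr in (("m", self.m), ("n", self.n)):
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{name} entries must be nonnegative integers")
        self.m = self.m.astype(np.int64)
        self.n = self.n.astype(np.int64)

    @property
    def y(self) -> np.ndarray:
        """Concatenated observed vector ``(m', n')'``."""
        return np.concatenate([self.m, self.n])

    @property
    def total_marked(self) -> int:
        return int(self.m.sum())

    @property
    def total_recaptures(self) -> int:
        return int(self.n.sum())


@dataclass
class TransformMatrices:
    """Sparse 0/1 matrices linking latent counts to observed counts."""

    A: sp.csr_matrix
    B: sp.csr_matrix
    T_mat: sp.csr_matrix
    column_index: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.column_index is None:
            self.column_index = np.arange(self.T_mat.shape[1], dtype=np.int64)


def build_A(design: StudyDesign, H: np.ndarray = None) -> sp.csr_matrix:
    """First-marking matrix: ``A[(k,t), j] = 1`` iff history ``j`` is first
    captured on occasion ``(k, t)``.  Each column has at most one 1."""
    if H is None:
        H = enumerate_histories(design)
    J = H.shape[0]
    m_index, _ = count_index(design)
    row_of = {kt: i for i, kt in enumerate(m_index)}
    # first set bit position per history
    nz_any = H.any(axis=1)
    first_pos = np.argmax(H, axis=1)
    rows, cols = [], []
    occ = design.occasions
    for j in np.flatnonzero(nz_any):
        rows.append(row_of[occ[first_pos[j]]])
        cols.append(j)
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(len(m_index), J))


def build_B(design: StudyDesign, H: np.ndarray = None) -> sp.csr_matrix:
    """Recapture matrix: row ``(k, j, t)`` has a 1 in column ``omega`` iff the
    history was first captured in period ``k`` (strictly before occasion ``t``
    when ``j = k``) and has a capture on occasion ``(j, t)``."""
    if H is None:
        H = enumerate_histories(design)
    nhist = H.shape[0]
    _, n_index = count_index(design)
    nz_any = H.any(axis=1)
    first_pos = np.argmax(H, axis=1)
    rows, cols = [], []
    occ_pos = {kt: i for i, kt in enumerate(design.occasions)}
    # first-capture period per history
    fp = np.full(nhist, -1, dtype=np.int64)
    for k in range(1, design.K + 1):
        off = design.occasion_offset(k)
        in_k = (first_pos >= off) & (first_pos < off + design.Tks[k - 1]) & nz_any
        fp[in_k] = k
    for r, (k, j, t) in enumerate(n_index):
        pos = occ_pos[(j, t)]
        cand = (fp == k) & (H[:, pos] == 1)
        if j == k:
            cand &= first_pos < pos
        for c in np.flatnonzero(cand):
            rows.append(r)
            cols.append(c)
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(len(n_index), nhist))


def stack_T(A: sp.csr_matrix, B: sp.csr_matrix) -> sp.csr_matrix:
    """Stack ``T = (A', B')'`` so that ``y = T x``."""
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must have the same number of columns")
    return sp.vstack([A, B]).tocsr()


def build_transform(design: StudyDesign, H: np.ndarray = None) -> TransformMatrices:
    if H is None:
        H = enumerate_histories(design)
    A = build_A(design, H)
    B = build_B(design, H)
    return TransformMatrices(A=A, B=B, T_mat=stack_T(A, B))


def aggregate_counts(design: StudyDesign, x: np.ndarray,
                     tm: TransformMatrices = None) -> CountData:
    """Observed counts ``y = T x`` from latent history counts ``x``."""
    if tm is None:
        tm = build_transform(design)
    y = np.asarray(tm.T_mat @ np.asarray(x, dtype=float))
    m_len = tm.A.shape[0]
    return CountData(design=design, m=np.round(y[:m_len]),
                     n=np.round(y[m_len:]))


def forced_zero_reduction(T_mat: sp.spmatrix, y: np.ndarray):
    """Drop history columns that are impossible given the observed data.

    A column ``j`` with a 1 in any row ``l`` where ``y_l = 0`` would force
    ``x_j > 0`` to violate ``T x = y`` under nonnegativity, so it is removed.
    With 0/1 entries and nonnegative counts a single pass suffices.  The
    all-zero history column (all-zero in ``T``) is always retained.

    Returns ``(kept, dropped)`` canonical column index arrays.
    """
    y = np.asarray(y)
    T_csr = sp.csr_matrix(T_mat)
    zero_rows = np.flatnonzero(y == 0)
    if zero_rows.size == 0:
        kept = np.arange(T_csr.shape[1], dtype=np.int64)
        return kept, np.empty(0, dtype=np.int64)
    hits = np.asarray(T_csr[zero_rows].sum(axis=0)).ravel()
    kept = np.flatnonzero(hits == 0).astype(np.int64)
    dropped = np.flatnonzero(hits > 0).astype(np.int64)
    return kept, dropped


def is_feasible(T_mat: sp.spmatrix, y: np.ndarray, tol: float = 1e-7) -> bool:
    """Whether a nonnegative real solution of ``T x = y`` exists (LP check)."""
    T_csr = sp.csr_matrix(T_mat)
    res = linprog(c=np.zeros(T_csr.shape[1]), A_eq=T_csr, b_eq=np.asarray(y, float),
                  bounds=(0, None), method="highs")
    return bool(res.status == 0)


def prefilter_histories(pi_init: np.ndarray, fraction: float = 0.10,
                        always_keep=None, T_mat: sp.spmatrix = None,
                        y: np.ndarray = None) -> np.ndarray:
    """Retain the top-probability fraction of latent histories.

    Keeps the ``ceil(fraction * J)`` histories with the largest initial-value
    probabilities (ties broken by canonical index), plus ``always_keep``.
    When ``T_mat`` and ``y`` are supplied, dropped histories are greedily
    re-added in probability order until ``T x = y`` admits a nonnegative
    solution, so prefiltering never makes the observed data infeasible.
    """
    pi_init = np.asarray(pi_init, dtype=float)
    J = pi_init.size
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = int(np.ceil(fraction * J))
    order = np.lexsort((np.arange(J), -pi_init))  # prob desc, index asc
    keep = set(order[:n_keep].tolist())
    if always_keep is not None:
        keep.update(int(i) for i in np.atleast_1d(always_keep))
    if T_mat is not None and y is not None:
        T_csr = sp.csr_matrix(T_mat)
        remaining = [j for j in order[n_keep:] if j not in keep]
        while True:
            cols = np.array(sorted(keep), dtype=np.int64)
            if is_feasible(T_csr[:, cols], y):
                break
            if not remaining:
                raise RuntimeError("observed data infeasible even with all histories")
            keep.add(int(remaining.pop(0)))
    return np.array(sorted(keep), dtype=np.int64)


def dump_coordinates(mat: sp.spmatrix, path):
    """Write a sparse 0/1 matrix as text triples ``row col value`` (debugging)."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write(f"# shape {coo.shape[0]} {coo.shape[1]} nnz {coo.nnz}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {v:g}\n")
    return path


def enumerate_latent_solutions(T_mat, y, N: int):
    """All nonnegative integer ``x`` with ``T x = y`` and ``sum x = N``.

    Exhaustive depth-first search with partial-sum pruning; intended for tiny
    designs (exact-likelihood oracles), not production use.
    """
    T_dense = np.asarray(sp.csr_matrix(T_mat).todense(), dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    L, J = T_dense.shape
    col_rows = [np.flatnonzero(T_dense[:, j]) for j in range(J)]
    zero_cols = [j for j in range(J) if col_rows[j].size == 0]
    active = [j for j in range(J) if col_rows[j].size > 0]
    if len(zero_cols) > 1:
        raise ValueError("at most one all-zero column supported")
    sols = []
    x = np.zeros(J, dtype=np.int64)

    def dfs(i, resid, used):
        if i == len(active):
            if not resid.any():
                slack = N - used
                if slack == 0 and not zero_cols:
                    sols.append(x.copy())
                elif slack >= 0 and zero_cols:
                    x[zero_cols[0]] = slack
                    sols.append(x.copy())
                    x[zero_cols[0]] = 0
            return
        j = active[i]
        # prune: rows no later column touches must already be satisfied
        later = active[i:]
        touched = np.zeros(L, dtype=bool)
        for jj in later:
            touched[col_rows[jj]] = True
        if np.any((resid > 0) & ~touched):
            return
        cap = min(N - used, int(resid[col_rows[j]].min()))
        for v in range(cap + 1):
            x[j] = v
            dfs(i + 1, resid - v * T_dense[:, j], used + v)
        x[j] = 0

    dfs(0, y.copy(), 0)
    return sols
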