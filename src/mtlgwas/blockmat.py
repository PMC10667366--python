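"""Structured linear algebra for the multi-trait longitudinal mixed model.

The coefficient matrix of the random-effects block, ``Z'R^-1 Z + G^-1``, is a
grid of trait-by-trait partitions in which every structurally nonzero
partition is itself block diagonal: the atomic blocks couple the random
intercept and slope of one individual and nothing else.  :class:`BlockMatrix`
stores exactly that structure (each partition as a stack of atomic blocks),
and :func:`recursive_partition_inverse` inverts it by peeling one partition
row/column per round with the four-block (Schur complement) identity.  The
pattern of structurally nonzero partitions is preserved by the inversion, so
storage for the matrix and its inverse is identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BlockMatrix",
    "KroneckerFactors",
    "SingularBlockError",
    "StructureError",
    "kron_inverse",
    "four_block_inverse",
    "recursive_partition_inverse",
]

logger = logging.getLogger(__name__)

#: reciprocal-condition threshold below which an atomic block is declared singular
RCOND_FLOOR = 1e-12


class SingularBlockError(np.linalg.LinAlgError):
    """An atomic diagonal block is numerically singular."""

    def __init__(self, message, partition=None, block_index=None, rcond=None):
        super().__init__(message)
        self.partition = partition
        self.block_index = block_index
        self.rcond = rcond


class StructureError(ValueError):
    """Input violates the structural contract of an operation."""


@dataclass(frozen=True)
class KroneckerFactors:
    """Factors of ``left (x) I_right_order``.

    ``left`` is a small dense square matrix (a trait covariance such as E or
    C); the right factor is an identity whose order is the number of records
    or individuals.  The Kronecker product itself is never materialised.
    """

    left: np.ndarray
    right_order: int

    def __post_init__(self):
        left = np.asarray(self.left, dtype=float)
        if left.ndim != 2 or left.shape[0] != left.shape[1]:
            raise StructureError("left factor must be a square matrix")
        if self.right_order < 1:
            raise StructureError("right_order must be a positive integer")
        object.__setattr__(self, "left", left)

    @property
    def order(self) -> int:
        return self.left.shape[0] * self.right_order

    def to_dense(self) -> np.ndarray:
        return np.kron(self.left, np.eye(self.right_order))


class BlockMatrix:
    """Symmetric-patterned matrix of block-diagonal partitions.

    Parameters
    ----------
    n_part
        Number of partition rows (e.g. the number of traits).  Square by
        default; off-diagonal quadrants may pass ``n_part_col``.
    n_inner
        Number of atomic blocks along the diagonal of each partition
        (e.g. the number of individuals).
    inner_order
        Order of each atomic block (2 for an intercept/slope pair, 1 for a
        scalar band).
    blocks
        Mapping ``(i, j) -> ndarray of shape (n_inner, inner_order,
        inner_order)``.  Missing keys are structural zeros.  For a symmetric
        matrix it suffices to provide ``i <= j``; mirrors are filled in.
    symmetric
        Declare the matrix symmetric; block ``(j, i)`` is then the atomic
        transpose of block ``(i, j)``.
    """

    def __init__(
        self, n_part, n_inner, inner_order, blocks, symmetric=True, n_part_col=None
    ):
        self.n_part = int(n_part)
        self.n_part_col = self.n_part if n_part_col is None else int(n_part_col)
        self.n_inner = int(n_inner)
        self.inner_order = int(inner_order)
        self.symmetric = bool(symmetric) and self.n_part == self.n_part_col
        shape = (self.n_inner, self.inner_order, self.inner_order)
        self.blocks: dict[tuple[int, int], np.ndarray] = {}
        for (i, j), blk in blocks.items():
            blk = np.asarray(blk, dtype=float)
            if blk.shape != shape:
                raise StructureError(
                    f"block {(i, j)} has shape {blk.shape}, expected {shape}"
                )
            self.blocks[(i, j)] = blk
        if self.symmetric:
            for (i, j) in list(self.blocks):
                if (j, i) not in self.blocks:
                    self.blocks[(j, i)] = np.swapaxes(self.blocks[(i, j)], -1, -2)

    # -- structure ---------------------------------------------------------

    @property
    def partition_sizes(self) -> list[int]:
        return [self.n_inner * self.inner_order] * self.n_part

    @property
    def order(self) -> int:
        return self.n_part * self.n_inner * self.inner_order

    @property
    def order_col(self) -> int:
        return self.n_part_col * self.n_inner * self.inner_order

    @property
    def sparsity(self) -> frozenset:
        """Index set of structurally nonzero partitions."""
        return frozenset(self.blocks)

    def is_symmetric(self, tol=1e-12) -> bool:
        if self.n_part != self.n_part_col:
            return False
        for (i, j), blk in self.blocks.items():
            other = self.blocks.get((j, i))
            if other is None:
                return False
            if not np.allclose(blk, np.swapaxes(other, -1, -2), atol=tol, rtol=0.0):
                return False
        return True

    # -- conversion and application ---------------------------------------

    def to_dense(self) -> np.ndarray:
        d, m = self.inner_order, self.n_inner
        size = m * d
        out = np.zeros((self.order, self.order_col))
        for (i, j), blk in self.blocks.items():
            for a in range(m):
                r = i * size + a * d
                c = j * size + a * d
                out[r : r + d, c : c + d] = blk[a]
        return out

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Multiply by a vector (or a matrix of stacked columns).

        ``x`` has shape ``(order,)`` or ``(order, k)``.
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[:, None]
        d, m = self.inner_order, self.n_inner
        xs = x.reshape(self.n_part_col, m, d, -1)
        out = np.zeros((self.n_part,) + xs.shape[1:])
        for (i, j), blk in self.blocks.items():
            out[i] += blk @ xs[j]
        out = out.reshape(self.order, -1)
        return out[:, 0] if single else out

    def __matmul__(self, other: "BlockMatrix") -> "BlockMatrix":
        if not isinstance(other, BlockMatrix):
            return NotImplemented
        if (other.n_part, other.n_inner, other.inner_order) != (
            self.n_part_col,
            self.n_inner,
            self.inner_order,
        ):
            raise StructureError("incompatible block structure for product")
        out: dict[tuple[int, int], np.ndarray] = {}
        for (i, k), blk in self.blocks.items():
            for j in range(other.n_part_col):
                rhs = other.blocks.get((k, j))
                if rhs is None:
                    continue
                contrib = blk @ rhs
                if (i, j) in out:
                    out[(i, j)] += contrib
                else:
                    out[(i, j)] = contrib
        return BlockMatrix(
            self.n_part,
            self.n_inner,
            self.inner_order,
            out,
            symmetric=False,
            n_part_col=other.n_part_col,
        )

    def copy(self) -> "BlockMatrix":
        return BlockMatrix(
            self.n_part,
            self.n_inner,
            self.inner_order,
            {k: v.copy() for k, v in self.blocks.items()},
            symmetric=self.symmetric,
            n_part_col=self.n_part_col,
        )


# ---------------------------------------------------------------------------
# atomic-block inversion with singularity diagnostics


def _atomic_inverse(stack: np.ndarray, partition=None) -> np.ndarray:
    """Invert a stack of small blocks, raising on near-singular members."""
    if stack.shape[-1] == 1:
        flat = stack[..., 0, 0]
        amax = np.abs(flat).max(initial=0.0)
        bad = np.abs(flat) <= RCOND_FLOOR * max(amax, 1.0)
        if bad.any():
            idx = int(np.argmax(bad))
            raise SingularBlockError(
                f"singular atomic block {idx} in partition {partition}",
                partition=partition,
                block_index=idx,
            )
        return (1.0 / flat)[..., None, None]
    sv = np.linalg.svd(stack, compute_uv=False)
    rcond = sv[..., -1] / np.maximum(sv[..., 0], np.finfo(float).tiny)
    bad = ~(rcond > RCOND_FLOOR)
    if bad.any():
        idx = int(np.argmax(bad))
        raise SingularBlockError(
            f"singular atomic block {idx} in partition {partition} "
            f"(rcond={rcond[idx]:.3e})",
            partition=partition,
            block_index=idx,
            rcond=float(rcond[idx]),
        )
    return np.linalg.inv(stack)


def kron_inverse(factors: KroneckerFactors) -> BlockMatrix:
    """Inverse of ``left (x) I`` via the Kronecker identity.

    The result is ``left^-1 (x) I`` stored as a :class:`BlockMatrix` of
    scalar bands; the full dense product is never formed.  Decoupled groups
    of indices in ``left`` (exact zero cross-blocks) stay structurally absent
    in the result.
    """
    left = factors.left
    k = left.shape[0]
    cond = np.linalg.cond(left)
    if not np.isfinite(cond) or cond > 1.0 / RCOND_FLOOR:
        raise SingularBlockError(
            f"left Kronecker factor is singular or ill-conditioned "
            f"(condition number {cond:.3e})"
        )
    inv = np.zeros_like(left)
    for comp in _coupling_components(left != 0.0):
        sub = np.ix_(comp, comp)
        inv[sub] = np.linalg.inv(left[sub])
    blocks = {}
    for i in range(k):
        for j in range(k):
            if inv[i, j] != 0.0 or (left[i, j] != 0.0 and i == j):
                blocks[(i, j)] = np.full(
                    (factors.right_order, 1, 1), inv[i, j], dtype=float
                )
    return BlockMatrix(
        k, factors.right_order, 1, blocks, symmetric=bool(np.allclose(left, left.T))
    )


def _coupling_components(adj: np.ndarray) -> list[list[int]]:
    """Connected components of a symmetric coupling pattern."""
    k = adj.shape[0]
    seen = np.zeros(k, dtype=bool)
    comps = []
    for s in range(k):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            nbrs = np.nonzero(adj[v] | adj[:, v])[0]
            for w in nbrs:
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        comps.append(sorted(comp))
    return comps


# ---------------------------------------------------------------------------
# four-block inversion core (operates on partition dictionaries)


def _dict_select(blocks, rows, cols):
    out = {}
    rmap = {r: a for a, r in enumerate(rows)}
    cmap = {c: b for b, c in enumerate(cols)}
    for (i, j), blk in blocks.items():
        if i in rmap and j in cmap:
            out[(rmap[i], cmap[j])] = blk
    return out


def _dict_mul(x, y, n_left, n_mid, n_right):
    out = {}
    for (i, k), blk in x.items():
        for j in range(n_right):
            rhs = y.get((k, j))
            if rhs is None:
                continue
            contrib = blk @ rhs
            if (i, j) in out:
                out[(i, j)] += contrib
            else:
                out[(i, j)] = contrib
    return out


def _dict_transpose(x):
    return {(j, i): np.swapaxes(blk, -1, -2) for (i, j), blk in x.items()}


def _four_block_core(a, b, d_inv, n_a, n_d, *, c=None, partition_label=None):
    """Blocks of the inverse of ``[[A, B], [C, D]]`` given ``D^-1``.

    ``a``, ``b``, ``c`` and ``d_inv`` are partition dictionaries; ``c`` of
    ``None`` means the symmetric case ``C = B'`` so only one off-diagonal
    product is formed and mirrored.  Returns the combined dictionary indexed
    over ``n_a + n_d`` partitions.
    """
    symmetric = c is None
    bd = _dict_mul(b, d_inv, n_a, n_d, n_d)  # B D^-1
    if symmetric:
        dc = _dict_transpose(bd)  # D^-1 C = (B D^-1)'
        cb = _dict_transpose(b)
    else:
        cb = c
        dc = _dict_mul(d_inv, c, n_d, n_d, n_a)
    # Schur complement A - B D^-1 C, block diagonal by construction
    schur = {k: v.copy() for k, v in a.items()}
    for (i, j), blk in _dict_mul(bd, cb, n_a, n_d, n_a).items():
        if (i, j) in schur:
            schur[(i, j)] -= blk
        else:
            schur[(i, j)] = -blk
    if set(schur) - {(i, i) for i in range(n_a)}:
        raise StructureError(
            "Schur complement is not partition-diagonal; input lacks the "
            "required band structure"
        )
    s_inv = {
        (i, i): _atomic_inverse(schur[(i, i)], partition=(partition_label, i))
        for i in range(n_a)
        if (i, i) in schur
    }
    top_right = _dict_mul(s_inv, bd, n_a, n_a, n_d)
    for blk in top_right.values():
        blk *= -1.0
    if symmetric:
        bottom_left = _dict_transpose(top_right)
    else:
        bottom_left = _dict_mul(dc, s_inv, n_d, n_a, n_a)
        for blk in bottom_left.values():
            blk *= -1.0
    # D^-1 + (D^-1 C) S^-1 (B D^-1); reuse -S^-1 B D^-1 = top_right
    correction = _dict_mul(dc, top_right, n_d, n_a, n_d)
    bottom = {k: v.copy() for k, v in d_inv.items()}
    for (i, j), blk in correction.items():
        if (i, j) in bottom:
            bottom[(i, j)] -= blk
        else:
            bottom[(i, j)] = -blk
    out = {}
    for (i, j), blk in s_inv.items():
        out[(i, j)] = blk
    for (i, j), blk in top_right.items():
        out[(i, n_a + j)] = blk
    for (i, j), blk in bottom_left.items():
        out[(n_a + i, j)] = blk
    for (i, j), blk in bottom.items():
        out[(n_a + i, n_a + j)] = blk
    return out


def four_block_inverse(a, b, c, d, d_inv) -> BlockMatrix:
    """Invert ``[[A, B], [C, D]]`` given the inverse of ``D``.

    All five arguments are :class:`BlockMatrix` quadrants sharing
    ``n_inner`` and ``inner_order``; ``a``/``d`` are square over their own
    partitions.  When ``C`` equals the transpose of ``B`` the symmetric
    shortcut is used: one off-diagonal product is computed and mirrored.
    """
    for m in (a, b, c, d, d_inv):
        if (m.n_inner, m.inner_order) != (a.n_inner, a.inner_order):
            raise StructureError("quadrants must share atomic block structure")
    n_a, n_d = a.n_part, d.n_part
    symmetric = c.sparsity == frozenset(
        (j, i) for (i, j) in b.sparsity
    ) and all(
        np.allclose(c.blocks[(j, i)], np.swapaxes(blk, -1, -2))
        for (i, j), blk in b.blocks.items()
    )
    combined = _four_block_core(
        dict(a.blocks),
        dict(b.blocks),
        dict(d_inv.blocks),
        n_a,
        n_d,
        c=None if symmetric else dict(c.blocks),
        partition_label="A",
    )
    return BlockMatrix(
        n_a + n_d, a.n_inner, a.inner_order, combined, symmetric=symmetric
    )


def recursive_partition_inverse(m: BlockMatrix) -> BlockMatrix:
    """Invert a banded block matrix by recursive partitioning.

    Starting from the bottom-right partition, each round applies the
    four-block identity with the previous round's result standing in for the
    inverse of the growing lower-right submatrix ``D``; the new inverse
    overwrites it in place, since ``D`` itself is no longer needed.  The
    Schur complement of every round is partition-diagonal with atomic blocks
    of order ``m.inner_order``, so only atomic blocks are ever inverted, and
    the structural sparsity pattern of the input is preserved exactly.

    Cost grows linearly in the number of atomic blocks per partition and
    roughly quadratically in the number of partition rows, against cubic
    growth of dense inversion in the full order.
    """
    if not m.symmetric or not m.is_symmetric(tol=1e-10):
        raise StructureError("recursive partition inverse requires a symmetric matrix")
    k = m.n_part
    if k == 0:
        return m.copy()
    # round 0: invert the bottom-right partition directly
    tail = [k - 1]
    d_inv = {(0, 0): _atomic_inverse(m.blocks[(k - 1, k - 1)], partition=k - 1)}
    for r in range(k - 2, -1, -1):
        t0 = time.perf_counter()
        a = {(0, 0): m.blocks[(r, r)]}
        b = _dict_select(m.blocks, [r], tail)
        d_inv = _four_block_core(
            a, b, d_inv, 1, len(tail), partition_label=r
        )
        tail = [r] + tail
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "recursive inverse round %d: %d stored partitions, %.3f ms",
                k - 1 - r,
                len(d_inv),
                1e3 * (time.perf_counter() - t0),
            )
    blocks = {(tail[i], tail[j]): blk for (i, j), blk in d_inv.items()}
    return BlockMatrix(k, m.n_inner, m.inner_order, blocks, symmetric=True)
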