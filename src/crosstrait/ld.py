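"""Block-diagonal LD structure: storage, LD scores, greedy pruning.

LD is held as an ordered list of disjoint blocks; each block carries the
allelic correlation matrix ``r`` of its member SNPs. Correlations between
SNPs in different blocks are defined to be zero, which is what makes
random pruning and locus definition tractable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["LDStructure", "ld_scores", "greedy_prune", "random_prune"]


@dataclass
class LDStructure:
    """Block-diagonal pairwise allelic correlations among SNPs.

    Parameters
    ----------
    snp_id : array of str
        SNP identifiers in block-contiguous order.
    chrom : array of str
        Chromosome label per SNP.
    pos : array of int
        1-based base-pair position per SNP.
    block_id : array of int
        Block index per SNP (0-based, nondecreasing).
    matrices : list of ndarray
        Per-block correlation matrices ``r`` (symmetric, unit diagonal,
        positive semidefinite).
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    block_id: np.ndarray
    matrices: list = field(repr=False)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.block_id = np.asarray(self.block_id, dtype=np.int64)
        sizes = np.bincount(self.block_id, minlength=len(self.matrices))
        for b, mat in enumerate(self.matrices):
            mat = np.asarray(mat, dtype=np.float64)
            if mat.shape != (sizes[b], sizes[b]):
                raise ValueError(f"block {b}: matrix shape {mat.shape} != size {sizes[b]}")
            if mat.size:
                if not np.allclose(mat, mat.T):
                    raise ValueError(f"block {b}: matrix not symmetric")
                if not np.allclose(np.diag(mat), 1.0):
                    raise ValueError(f"block {b}: diagonal not 1")
                if np.abs(mat).max() > 1 + 1e-12:
                    raise ValueError(f"block {b}: |r| > 1")
            self.matrices[b] = mat
        # per-SNP index within its block, in storage order
        idx = np.zeros(self.n_snps, dtype=np.int64)
        counts = np.zeros(len(self.matrices), dtype=np.int64)
        for j, b in enumerate(self.block_id):
            idx[j] = counts[b]
            counts[b] += 1
        self._idx_in_block = idx
        self._row: dict = {s: j for j, s in enumerate(self.snp_id)}
        self._packed = None

    # ------------------------------------------------------------------ basics
    @property
    def n_snps(self) -> int:
        return self.snp_id.size

    @property
    def n_blocks(self) -> int:
        return len(self.matrices)

    def r2(self, snp_a: str, snp_b: str) -> float:
        """Squared correlation between two SNPs (0 across blocks)."""
        i, j = self._row[snp_a], self._row[snp_b]
        if self.block_id[i] != self.block_id[j]:
            return 0.0
        m = self.matrices[self.block_id[i]]
        return float(m[self._idx_in_block[i], self._idx_in_block[j]] ** 2)

    def r2_with(self, snp: str, others: np.ndarray) -> np.ndarray:
        """Vector of r2 between ``snp`` and each of ``others``."""
        i = self._row[snp]
        b = self.block_id[i]
        out = np.zeros(len(others))
        mat = self.matrices[b]
        for k, s in enumerate(others):
            j = self._row.get(s)
            if j is not None and self.block_id[j] == b:
                out[k] = mat[self._idx_in_block[i], self._idx_in_block[j]] ** 2
        return out

    def subset(self, keep_ids) -> "LDStructure":
        """Restrict to the given SNP ids (order preserved; matrices sliced)."""
        keep_set = set(keep_ids)
        keep = np.array([s in keep_set for s in self.snp_id])
        new_mats = []
        new_block = np.empty(keep.sum(), dtype=np.int64)
        ptr = 0
        for b in range(self.n_blocks):
            mask = keep[self.block_id == b]
            sub = self.matrices[b][np.ix_(mask, mask)]
            new_mats.append(sub)
            new_block[ptr : ptr + mask.sum()] = b
            ptr += mask.sum()
        return LDStructure(
            snp_id=self.snp_id[keep],
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            block_id=new_block,
            matrices=new_mats,
        )

    # ------------------------------------------------------------- numba pack
    def _pack(self):
        """Flatten block matrices for the njit pruning kernel."""
        if self._packed is None:
            sizes = np.array([m.shape[0] for m in self.matrices], dtype=np.int64)
            offs = np.zeros(len(sizes) + 1, dtype=np.int64)
            np.cumsum(sizes**2, out=offs[1:])
            flat = np.empty(int(offs[-1]), dtype=np.float64)
            for b, m in enumerate(self.matrices):
                flat[offs[b] : offs[b + 1]] = (m**2).ravel()
            self._packed = (flat, offs[:-1], sizes)
        return self._packed

    # -------------------------------------------------------------------- io
    def to_triplets(self, path) -> None:
        """Write (snp_i, snp_j, r) triplets, i <= j within each block, as TSV."""
        import pandas as pd

        rows_i, rows_j, rs = [], [], []
        for b, mat in enumerate(self.matrices):
            ids = self.snp_id[self.block_id == b]
            k = len(ids)
            iu, ju = np.triu_indices(k)
            rows_i.extend(ids[iu])
            rows_j.extend(ids[ju])
            rs.extend(mat[iu, ju])
        pd.DataFrame({"SNP_I": rows_i, "SNP_J": rows_j, "R": rs}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_triplets(cls, path, chrom=None, pos=None) -> "LDStructure":
        """Rebuild block structure from a triplet TSV written by to_triplets.

        Blocks are the connected components of the (i, j) pairs, in order of
        first appearance; positions default to 1..n when not supplied.
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"SNP_I": str, "SNP_J": str})
        order: dict = {}
        for s in pd.concat([df["SNP_I"], df["SNP_J"]]):
            if s not in order:
                order[s] = len(order)
        ids = np.array(list(order), dtype=object)
        n = len(ids)
        parent = np.arange(n)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ii = df["SNP_I"].map(order).to_numpy()
        jj = df["SNP_J"].map(order).to_numpy()
        for a, b in zip(ii, jj):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        roots = np.array([find(i) for i in range(n)])
        _, block = np.unique(roots, return_inverse=True)
        # reorder SNPs to be block-contiguous, stable in first-appearance order
        perm = np.lexsort((np.arange(n), block))
        ids = ids[perm]
        block = block[perm]
        new_index = np.empty(n, dtype=np.int64)
        new_index[perm] = np.arange(n)
        local = np.zeros(n, dtype=np.int64)  # index within block, new order
        counts: dict = {}
        for j, b in enumerate(block):
            local[j] = counts.get(b, 0)
            counts[b] = local[j] + 1
        mats = [np.eye(counts[b]) for b in range(block.max() + 1)]
        for a, c, r in zip(ii, jj, df["R"].to_numpy()):
            na, nc = new_index[a], new_index[c]
            bi = block[na]
            mats[bi][local[na], local[nc]] = r
            mats[bi][local[nc], local[na]] = r
        if chrom is None:
            chrom = np.array(["1"] * n, dtype=object)
        if pos is None:
            pos = np.arange(1, n + 1, dtype=np.int64)
        return cls(snp_id=ids, chrom=np.asarray(chrom, dtype=object)[:n],
                   pos=np.asarray(pos)[:n], block_id=block, matrices=mats)


def ld_scores(ld: LDStructure) -> np.ndarray:
    """Per-SNP LD score ``ell_j = sum_k r2_jk`` over the SNP's block (self included)."""
    out = np.empty(ld.n_snps)
    ptr = 0
    for b, mat in enumerate(ld.matrices):
        k = mat.shape[0]
        out[ptr : ptr + k] = (mat**2).sum(axis=1)
        ptr += k
    return out


@njit(cache=True)
def _greedy_prune_kernel(order, block_id, idx_in_block, r2_flat, offs, sizes, thresh):
    n = order.size
    kept = np.zeros(n, dtype=np.bool_)
    n_blocks = sizes.size
    maxk = 0
    for b in range(n_blocks):
        if sizes[b] > maxk:
            maxk = sizes[b]
    members = np.full((n_blocks, maxk), -1, dtype=np.int64)
    counts = np.zeros(n_blocks, dtype=np.int64)
    for t in range(n):
        j = order[t]
        b = block_id[j]
        ij = idx_in_block[j]
        off = offs[b]
        k = sizes[b]
        ok = True
        for s in range(counts[b]):
            if r2_flat[off + ij * k + members[b, s]] >= thresh:
                ok = False
                break
        if ok:
            kept[j] = True
            members[b, counts[b]] = ij
            counts[b] += 1
    return kept


def greedy_prune(ld: LDStructure, order: np.ndarray, r2_thresh: float) -> np.ndarray:
    """Greedy pruning: visit SNPs in ``order``, keep a SNP iff its r2 with every
    previously kept SNP is strictly below ``r2_thresh``. Returns a boolean mask
    over the LD storage order."""
    flat, offs, sizes = ld._pack()
    return _greedy_prune_kernel(
        np.asarray(order, dtype=np.int64),
        ld.block_id,
        ld._idx_in_block,
        flat,
        offs,
        sizes,
        float(r2_thresh),
    )


def random_prune(ld: LDStructure, r2_thresh: float, rng: np.random.Generator) -> np.ndarray:
    """One random-order greedy pruning pass; boolean keep mask."""
    return greedy_prune(ld, rng.permutation(ld.n_snps), r2_thresh)
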