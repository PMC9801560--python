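"""Sequence and profile kernels, and their normalized hybrid combination.

Two views of a candidate TSS window are compared here: the raw base sequence,
via position-anchored string kernels (weighted degree, with optional shifts),
and the physical opening/bubble probability profile, via an RBF kernel.  A
fixed convex combination of the two unit-diagonal-normalized Gram matrices
gives the hybrid (multiple-kernel) view used by the downstream SVM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf

from .pbd import SequenceAlphabetError, VALID_BASES

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


def wd_weights(d: int) -> np.ndarray:
    """k-mer order weights beta_k = 2 (d - k + 1) / (d (d + 1)); they sum to 1."""
    if d < 1:
        raise ValueError("kernel order d must be >= 1")
    k = np.arange(1, d + 1)
    return 2.0 * (d - k + 1) / (d * (d + 1.0))


def encode_sequence(seq: str) -> np.ndarray:
    seq = str(seq).upper()
    if set(seq) - VALID_BASES:
        raise SequenceAlphabetError(f"invalid characters in sequence {seq[:20]!r}...")
    return np.fromiter((_BASE_CODE[b] for b in seq), dtype=np.uint8, count=len(seq))


def _check_pair(s1, s2, d):
    if len(s1) != len(s2):
        raise ValueError(f"sequences must have equal length, got {len(s1)} and {len(s2)}")
    if len(s1) < d:
        raise ValueError(f"sequence length {len(s1)} shorter than kernel order {d}")


def _cumulative_weights(d: int) -> np.ndarray:
    """B[t] = sum of beta_k for k <= t, with B[0] = 0."""
    return np.concatenate([[0.0], np.cumsum(wd_weights(d))])


def wd_kernel(s1: str, s2: str, d: int) -> float:
    """Weighted degree kernel: weighted count of co-occurring k-mers, k = 1..d.

    A matching stretch of length r at some position contributes every k-mer
    match it contains, so the kernel is ``sum_l B(min(r_l, d))`` where ``r_l``
    is the match-run length starting at l and ``B`` the cumulative beta weight.
    """
    _check_pair(s1, s2, d)
    a, b = encode_sequence(s1), encode_sequence(s2)
    match = a == b
    runs = _run_lengths(match[None, :])[0]
    B = _cumulative_weights(d)
    return float(B[np.minimum(runs, d)].sum())


def wd_self_similarity(L: int, d: int) -> float:
    """Closed form k(s, s) = sum_k beta_k (L - k + 1); identical for all s of length L."""
    if L < d:
        raise ValueError("L must be >= d")
    k = np.arange(1, d + 1)
    return float((wd_weights(d) * (L - k + 1)).sum())


def _run_lengths(match: np.ndarray) -> np.ndarray:
    """Per row, length of the True-run starting at each column (0 if False)."""
    P, L = match.shape
    runs = np.zeros((P, L), dtype=np.int32)
    runs[:, L - 1] = match[:, L - 1]
    for l in range(L - 2, -1, -1):
        runs[:, l] = match[:, l] * (runs[:, l + 1] + 1)
    return runs


def wd_gram(sequences: Sequence[str], degrees: Sequence[int] | int,
            other: Sequence[str] | None = None,
            chunk: int = 4096) -> dict[int, np.ndarray] | np.ndarray:
    """Weighted-degree Gram (or cross-Gram) matrices for one or more orders d.

    The pairwise match-run lengths are computed once and shared across all
    requested orders.  With ``other`` given, returns matrices of shape
    ``(len(sequences), len(other))``; otherwise symmetric Grams.
    """
    single = np.isscalar(degrees)
    degs = [int(degrees)] if single else [int(d) for d in degrees]
    A = np.stack([encode_sequence(s) for s in sequences])
    L = A.shape[1]
    for d in degs:
        if L < d:
            raise ValueError(f"sequence length {L} shorter than kernel order {d}")
    B_tabs = {d: _cumulative_weights(d) for d in degs}
    if other is None:
        n = len(sequences)
        ii, jj = np.triu_indices(n, k=1)
        out = {d: np.full((n, n), wd_self_similarity(L, d)) for d in degs}
        for lo in range(0, ii.size, chunk):
            sl = slice(lo, lo + chunk)
            runs = _run_lengths(A[ii[sl]] == A[jj[sl]])
            for d in degs:
                vals = B_tabs[d][np.minimum(runs, d)].sum(axis=1)
                out[d][ii[sl], jj[sl]] = vals
                out[d][jj[sl], ii[sl]] = vals
    else:
        C = np.stack([encode_sequence(s) for s in other])
        if C.shape[1] != L:
            raise ValueError("all sequences must have equal length")
        n, m = len(sequences), len(other)
        ii, jj = np.divmod(np.arange(n * m), m)
        out = {d: np.empty((n, m)) for d in degs}
        for lo in range(0, ii.size, chunk):
            sl = slice(lo, lo + chunk)
            runs = _run_lengths(A[ii[sl]] == C[jj[sl]])
            for d in degs:
                out[d][ii[sl], jj[sl]] = B_tabs[d][np.minimum(runs, d)].sum(axis=1)
    return out[degs[0]] if single else out


def wds_kernel(s1: str, s2: str, d: int, shift_max: int,
               position_weights: Sequence[float] | None = None) -> float:
    """Weighted degree kernel with shifts.

    Matches of k-mers displaced by up to ``shift_max`` positions count with
    weight ``1/(2(s+1))``; position weights default to 1 and the shift range
    is constant over positions.  With ``shift_max = 0`` and unit position
    weights this reduces exactly to :func:`wd_kernel`.
    """
    _check_pair(s1, s2, d)
    if shift_max < 0:
        raise ValueError("shift_max must be >= 0")
    a, b = encode_sequence(s1), encode_sequence(s2)
    L = len(a)
    gam = np.ones(L) if position_weights is None else np.asarray(position_weights, float)
    if gam.size != L:
        raise ValueError("position_weights must have one entry per position")
    beta = wd_weights(d)
    total = 0.0
    for k in range(1, d + 1):
        nk = L - k + 1
        for s in range(0, shift_max + 1):
            if s >= nk:
                break
            w = 1.0 / (2.0 * (s + 1))
            # I(u_{k,l+s}(s1) = u_{k,l}(s2)) + I(u_{k,l}(s1) = u_{k,l+s}(s2))
            m1 = np.ones(nk - s, dtype=bool)
            m2 = np.ones(nk - s, dtype=bool)
            for off in range(k):
                m1 &= a[s + off:s + off + nk - s] == b[off:off + nk - s]
                m2 &= a[off:off + nk - s] == b[s + off:s + off + nk - s]
            contrib = gam[:nk - s] * w * (m1.astype(float) + m2.astype(float))
            total += beta[k - 1] * contrib.sum()
    return float(total)


def rbf_kernel(x1, x2, gamma: float) -> float:
    """Gaussian kernel exp(-gamma ||x1 - x2||^2) between two feature vectors."""
    x1 = np.asarray(x1, float).ravel()
    x2 = np.asarray(x2, float).ravel()
    if x1.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x1 - x2) ** 2)))


def rbf_gram(X: np.ndarray, Y: np.ndarray | None = None, gamma: float | None = None) -> np.ndarray:
    """RBF Gram (rows of X [and Y] are instances); gamma defaults to the
    1 / (n_features * pooled variance) heuristic computed on X."""
    X = np.atleast_2d(np.asarray(X, float))
    if gamma is None:
        gamma = rbf_gamma_heuristic(X)
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    return _sk_rbf(X, Y if Y is None else np.atleast_2d(np.asarray(Y, float)), gamma=gamma)


def rbf_gamma_heuristic(X: np.ndarray) -> float:
    """Default RBF width 1 / (n_features * pooled feature variance)."""
    X = np.atleast_2d(np.asarray(X, float))
    var = float(X.var())
    if var <= 0:
        return 1.0
    return 1.0 / (X.shape[1] * var)


@dataclass(frozen=True)
class KernelConfig:
    kind: str = "WD"  # WD | WDS | RBF | hybrid
    d: int = 12
    gamma: float = 1.0
    shift_max: int = 0
    weights: tuple[float, ...] = (0.5, 0.5)
    normalize: bool = False

    def __post_init__(self):
        if self.kind not in ("WD", "WDS", "RBF", "hybrid"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("hybrid weights must be nonnegative and sum to 1")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "d": self.d, "gamma": self.gamma,
                "shift_max": self.shift_max, "weights": list(self.weights),
                "normalize": self.normalize}

    @classmethod
    def from_dict(cls, data: dict) -> "KernelConfig":
        data = dict(data)
        data["weights"] = tuple(data.get("weights", (0.5, 0.5)))
        return cls(**data)


@dataclass
class KernelGram:
    """Symmetric kernel matrix over an ordered set of instances."""

    instance_ids: tuple[str, ...]
    values: np.ndarray
    config: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self):
        self.instance_ids = tuple(str(i) for i in self.instance_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.instance_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"gram shape {self.values.shape} does not match {n} instance ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("gram matrix is not symmetric within 1e-10")

    def normalized(self) -> "KernelGram":
        return KernelGram(self.instance_ids, normalize_gram(self.values),
                          KernelConfig(**{**self.config.to_dict(), "normalize": True}))

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#config\t" + json.dumps(self.config.to_dict()) + "\n")
            fh.write("\t".join(self.instance_ids) + "\n")
            np.savetxt(fh, self.values, delimiter="\t", fmt="%.17g")

    @classmethod
    def load_tsv(cls, path) -> "KernelGram":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#config\t"):
                raise ValueError("missing #config header line")
            config = KernelConfig.from_dict(json.loads(header.split("\t", 1)[1]))
            ids = tuple(fh.readline().rstrip("\n").split("\t"))
            values = np.loadtxt(fh, delimiter="\t", ndmin=2)
        return cls(ids, values, config)


def normalize_gram(K: np.ndarray, diag_rows=None, diag_cols=None) -> np.ndarray:
    """Unit-diagonal (cosine) normalization k(x,y)/sqrt(k(x,x) k(y,y)).

    For a square Gram the diagonals are taken from K itself; for a cross
    matrix pass the self-similarities of the row and column instances.
    """
    K = np.asarray(K, dtype=float)
    if diag_rows is None:
        diag_rows = np.diag(K)
        diag_cols = diag_rows
    diag_rows = np.asarray(diag_rows, float)
    diag_cols = np.asarray(diag_cols, float) if diag_cols is not None else diag_rows
    if np.any(diag_rows <= 0) or np.any(diag_cols <= 0):
        raise ValueError("self-similarities must be positive for normalization")
    return K / np.sqrt(np.outer(diag_rows, diag_cols))


def hybrid_gram(seq_gram: KernelGram, prof_gram: KernelGram,
                weights: tuple[float, float] = (0.5, 0.5)) -> KernelGram:
    """Convex combination of the unit-diagonal-normalized sequence and profile Grams."""
    if seq_gram.instance_ids != prof_gram.instance_ids:
        raise ValueError("instance orderings of the two grams do not match")
    w = np.asarray(weights, float)
    if w.size != 2 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be two nonnegative values summing to 1")
    values = (w[0] * normalize_gram(seq_gram.values)
              + w[1] * normalize_gram(prof_gram.values))
    config = KernelConfig(kind="hybrid", d=seq_gram.config.d,
                          gamma=prof_gram.config.gamma,
                          weights=(float(w[0]), float(w[1])), normalize=True)
    return KernelGram(seq_gram.instance_ids, values, config)


def min_max_eigenvalues(K: np.ndarray) -> tuple[float, float]:
    vals = np.linalg.eigvalsh(np.asarray(K, float))
    return float(vals[0]), float(vals[-1])


def clip_negative_eigenvalues(K: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """Project a nearly-PSD matrix onto the PSD cone if round-off pushed an
    eigenvalue below ``-rel_tol * lambda_max``; otherwise return K unchanged."""
    K = np.asarray(K, float)
    vals, vecs = np.linalg.eigh(K)
    lam_max = vals[-1]
    if vals[0] >= -rel_tol * max(lam_max, 1e-30):
        return K
    clipped = np.clip(vals, 0.0, None)
    return (vecs * clipped) @ vecs.T
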