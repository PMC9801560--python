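"""Equilibrium opening and bubble statistics of DNA under the Peyrard-Bishop-Dauxois model.

The PBD model describes double-stranded DNA as a one-dimensional chain of
base-pair stretching coordinates ``y_1 ... y_N`` (Angstrom).  Each base pair
feels an on-site potential (a Morse well for the hydrogen bonds plus a
solvent/entropy barrier for ``y > 0``) and couples to its neighbour through an
anharmonic stacking potential whose effective stiffness drops from
``K (1 + rho)`` to ``K`` when either pair opens.  Because the model is
one-dimensional, every configurational average reduces to a chain of
one-dimensional integrals that can be evaluated exactly by an iterative
transfer-integral scheme, in time linear in the chain length and quadratic in
the number of quadrature points.

This module converts a base sequence at a given temperature into

* per-position closed/opening probabilities in the double-stranded (dsDNA)
  ensemble, i.e. the ensemble from which the fully denatured state is removed;
* the bubble probability matrix ``P_bub(k, m)``: the probability of a
  *denaturation bubble* of exact size ``m`` (a run of ``m`` open pairs flanked
  by closed pairs, with virtual closed pairs beyond the chain ends) centred on
  base pair ``k``;
* the participation profile ``P_part(k, m)``: the probability that base pair
  ``k`` lies inside a bubble of size at least ``m``.

All statistical weights are propagated with per-step renormalisation and an
accumulated logarithmic scale, so that 300-base windows (whose raw Boltzmann
weights span hundreds of orders of magnitude) are handled without underflow;
every reported probability is a ratio and is invariant to that scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

#: Boltzmann constant in eV/K, matching the eV / Angstrom parameter units.
KB = 8.617333e-5

VALID_BASES = frozenset("ACGT")

#: Stacking strength K (eV/A^2) for each ordered dimer, read 5'->3' on the
#: given strand; the bond between base pairs i-1 and i is keyed by
#: ``seq[i-1] + seq[i]``.
DIMER_STACKING = {
    "AT": 0.00176,
    "AA": 0.00418,
    "TT": 0.00418,
    "GT": 0.00480,
    "AC": 0.00462,
    "TA": 0.00506,
    "GA": 0.00546,
    "TC": 0.00546,
    "CC": 0.00810,
    "GG": 0.00810,
    "GC": 0.00865,
    "CT": 0.00865,
    "AG": 0.00865,
    "CA": 0.01140,
    "TG": 0.01140,
    "CG": 0.01690,
}


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""

    def __init__(self, message: str, record_ids: Sequence[str] = ()):
        super().__init__(message)
        self.record_ids = list(record_ids)


class NumericalRegimeError(ArithmeticError):
    """The dsDNA ensemble is numerically degenerate (Z_I ~= Z_II)."""


def _clean_sequence(sequence: str) -> str:
    seq = str(sequence).upper()
    if len(seq) == 0:
        raise SequenceAlphabetError("empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceAlphabetError(
            f"sequence contains invalid characters {sorted(bad)}; only A/C/G/T are supported"
        )
    return seq


def _normalize_dimer(dimer: str) -> str:
    key = str(dimer).upper().replace("–", "").replace("-", "")
    if len(key) != 2 or set(key) - VALID_BASES:
        raise ValueError(f"unknown dimer {dimer!r}")
    return key


@dataclass(frozen=True)
class PBDParameters:
    """Physical constants of the PBD model with a barrier-augmented on-site well.

    Defaults are the published parameterisation calibrated on melting curves of
    short heterogeneous duplexes: Morse depth ``D`` and inverse width ``alpha``
    per pair type, barrier amplitude ``b``, inverse width ``c`` and position
    factor ``d``, stacking drop ``rho``, stacking decay ``delta``, sixteen
    ordered-dimer stacking strengths, and the open/closed stretching threshold
    ``y0`` (the average base separation observed in melting experiments).
    """

    D_AT: float = 0.09075  # eV
    D_GC: float = 0.09900  # eV
    alpha_AT: float = 3.0  # 1/A
    alpha_GC: float = 3.4  # 1/A
    b_AT: float = 4.00  # eV/A^3
    b_GC: float = 6.00  # eV/A^3
    c_AT: float = 0.74  # 1/A
    c_GC: float = 0.74  # 1/A
    d_AT: float = 0.20  # dimensionless
    d_GC: float = 0.20  # dimensionless
    rho: float = 25.0
    delta: float = 0.8  # 1/A
    y0: float = 1.5  # A
    kB: float = KB  # eV/K
    K_dimer: Mapping[str, float] = field(default_factory=lambda: dict(DIMER_STACKING))

    def __post_init__(self):
        positive = {
            "D_AT": self.D_AT, "D_GC": self.D_GC,
            "alpha_AT": self.alpha_AT, "alpha_GC": self.alpha_GC,
            "b_AT": self.b_AT, "b_GC": self.b_GC,
            "c_AT": self.c_AT, "c_GC": self.c_GC,
            "rho": self.rho, "delta": self.delta, "y0": self.y0, "kB": self.kB,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.d_AT < 0 or self.d_GC < 0:
            raise ValueError("barrier position factors must be nonnegative")
        cleaned = {_normalize_dimer(k): float(v) for k, v in self.K_dimer.items()}
        if len(cleaned) != 16:
            raise ValueError(f"K_dimer must have exactly 16 ordered dimers, got {len(cleaned)}")
        if any(v <= 0 for v in cleaned.values()):
            raise ValueError("all stacking strengths must be strictly positive")
        object.__setattr__(self, "K_dimer", cleaned)

    def pair_constants(self, pair: str) -> tuple[float, float, float, float, float]:
        """Return ``(D, alpha, b, c, d)`` for pair type ``"AT"`` or ``"GC"``."""
        pair = str(pair).upper().replace("–", "").replace("-", "")
        if pair in ("AT", "TA"):
            return self.D_AT, self.alpha_AT, self.b_AT, self.c_AT, self.d_AT
        if pair in ("GC", "CG"):
            return self.D_GC, self.alpha_GC, self.b_GC, self.c_GC, self.d_GC
        raise ValueError(f"unknown base-pair type {pair!r}; expected 'AT' or 'GC'")

    def stacking_K(self, dimer: str) -> float:
        return self.K_dimer[_normalize_dimer(dimer)]

    def cache_key(self) -> tuple:
        return (
            self.D_AT, self.D_GC, self.alpha_AT, self.alpha_GC,
            self.b_AT, self.b_GC, self.c_AT, self.c_GC, self.d_AT, self.d_GC,
            self.rho, self.delta, self.y0, self.kB,
            tuple(sorted(self.K_dimer.items())),
        )


def onsite_potential(y, pair: str, params: PBDParameters | None = None):
    """On-site potential V(y) in eV: Morse well plus a barrier active for y > 0.

    ``V(y) = D (e^{-alpha y} - 1)^2 + Theta(y) * b y^3 / cosh^2[c (alpha y - d ln 2)]``

    The Heaviside factor uses the convention ``Theta(0) = 1`` (immaterial: the
    ``y^3`` factor kills the barrier at y = 0, and quadrature nodes never sit
    exactly on the threshold).
    """
    params = params or PBDParameters()
    D, alpha, b, c, d = params.pair_constants(pair)
    y = np.asarray(y, dtype=float)
    morse = D * (np.exp(-alpha * y) - 1.0) ** 2
    barrier = np.where(
        y >= 0.0,
        b * y**3 / np.cosh(c * (alpha * y - d * math.log(2.0))) ** 2,
        0.0,
    )
    out = morse + barrier
    return float(out) if out.ndim == 0 else out


def stacking_potential(y_i, y_prev, dimer: str, params: PBDParameters | None = None):
    """Stacking potential W(y_i, y_prev) in eV for the given ordered dimer.

    ``W = 1/2 K (1 + rho e^{-delta (y_i + y_prev)}) (y_i - y_prev)^2``;
    symmetric in its two stretching arguments.
    """
    params = params or PBDParameters()
    K = params.stacking_K(dimer)
    y_i = np.asarray(y_i, dtype=float)
    y_prev = np.asarray(y_prev, dtype=float)
    out = 0.5 * K * (1.0 + params.rho * np.exp(-params.delta * (y_i + y_prev))) * (y_i - y_prev) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QuadratureGrid:
    """Finite quadrature domain and rule for the transfer integrals.

    The configuration integrals are taken over ``[y_min, y_max]``; the Morse
    wall makes the integrand vanish below about -1 A and the potential reaches
    its plateau well before +50 A, so the dsDNA-ensemble probabilities do not
    depend on the cutoffs (the fully-open weight Z_II is subtracted).

    The rule is a composite of two Gauss-Legendre panels joined exactly at the
    open/closed threshold ``xi``, so that integrals restricted to ``y < xi``
    (closed) or ``y > xi`` (open) are quadrature sums over whole panels of a
    smooth integrand and converge spectrally under refinement.
    """

    y_min: float = -2.0
    y_max: float = 50.0
    n_points: int = 600
    scheme: str = "gauss-legendre-split"
    xi: float = 1.5

    def __post_init__(self):
        if not (self.y_min < 0.0 < self.xi < self.y_max):
            raise ValueError("grid must satisfy y_min < 0 < xi < y_max")
        if self.n_points < 64:
            raise ValueError("n_points must be at least 64")
        if self.scheme != "gauss-legendre-split":
            raise ValueError(f"unknown quadrature scheme {self.scheme!r}")

    @property
    def nodes(self) -> np.ndarray:
        return _grid_arrays(self)[0]

    @property
    def weights(self) -> np.ndarray:
        return _grid_arrays(self)[1]

    @property
    def closed_mask(self) -> np.ndarray:
        return _grid_arrays(self)[2]

    @property
    def open_mask(self) -> np.ndarray:
        return _grid_arrays(self)[3]


@lru_cache(maxsize=32)
def _grid_arrays(grid: QuadratureGrid):
    n_closed = grid.n_points // 2
    n_open = grid.n_points - n_closed
    panels = []
    for (lo, hi, n) in ((grid.y_min, grid.xi, n_closed), (grid.xi, grid.y_max, n_open)):
        x, w = leggauss(n)
        half = 0.5 * (hi - lo)
        panels.append((half * x + 0.5 * (hi + lo), half * w))
    nodes = np.concatenate([p[0] for p in panels])
    weights = np.concatenate([p[1] for p in panels])
    closed = nodes < grid.xi
    open_ = ~closed
    nodes.setflags(write=False)
    weights.setflags(write=False)
    closed.setflags(write=False)
    open_.setflags(write=False)
    return nodes, weights, closed, open_


@dataclass
class OpeningProfile:
    """Per-position probability profile of a sequence at one temperature."""

    sequence_id: str
    temperature: float
    values: np.ndarray
    kind: str  # "opening" | "closed" | "participation-m"
    m: int = 1
    trimmed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if np.any(self.values < -1e-12) or np.any(self.values > 1.0 + 1e-12):
            raise ValueError("profile values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        if self.m < 1:
            raise ValueError("bubble size m must be >= 1")


@dataclass
class BubbleMatrix:
    """P_bub(k, m): exact-size bubble probabilities in the dsDNA ensemble.

    ``values[k-1, m-1]`` is the probability of a bubble of exact size ``m``
    centred on base pair ``k`` (for even ``m`` the centre is the base directly
    to the left of the midpoint).
    """

    sequence_id: str
    temperature: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("bubble matrix must be two-dimensional (position x size)")
        if np.any(self.values < -1e-12) or np.any(self.values > 1.0 + 1e-12):
            raise ValueError("bubble probabilities must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def m_max(self) -> int:
        return self.values.shape[1]


# Constraint states accepted by the partition-function routines.
FREE, CLOSED, OPEN = "free", "closed", "open"
_STATES = (FREE, CLOSED, OPEN)


def _constraint_states(n: int, constraint) -> list[str]:
    states = [FREE] * n
    if constraint is None:
        return states
    if isinstance(constraint, Mapping):
        for pos, state in constraint.items():
            pos = int(pos)
            if not 1 <= pos <= n:
                raise ValueError(f"constraint position {pos} outside 1..{n}")
            if state not in _STATES:
                raise ValueError(f"unknown constraint state {state!r}")
            states[pos - 1] = state
        return states
    constraint = list(constraint)
    if len(constraint) != n:
        raise ValueError(f"constraint list must have length {n}, got {len(constraint)}")
    for i, state in enumerate(constraint):
        if state not in _STATES:
            raise ValueError(f"unknown constraint state {state!r}")
        states[i] = state
    return states


class TransferIntegrator:
    """Iterative transfer-integral engine for one (parameters, grid, T) triple.

    Per-pair Boltzmann weight vectors and per-dimer transfer matrices are
    precomputed once, so the engine can be reused across many sequences at the
    same temperature (the production pipeline computes thousands of 300-base
    windows this way).
    """

    def __init__(self, params: PBDParameters | None = None,
                 grid: QuadratureGrid | None = None,
                 temperature: float = 310.0):
        self.params = params or PBDParameters()
        self.grid = grid or QuadratureGrid()
        self.temperature = float(temperature)
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (K)")
        self.beta = 1.0 / (self.params.kB * self.temperature)
        y, w, cmask, omask = _grid_arrays(self.grid)
        self.y = y
        self.closed_mask = cmask.astype(float)
        self.open_mask = omask.astype(float)
        # quadrature weight folded into the on-site Boltzmann factor
        self._v = {
            "AT": w * np.exp(-self.beta * onsite_potential(y, "AT", self.params)),
            "GC": w * np.exp(-self.beta * onsite_potential(y, "GC", self.params)),
        }
        g = (0.5 * (1.0 + self.params.rho * np.exp(-self.params.delta * (y[:, None] + y[None, :])))
             * (y[:, None] - y[None, :]) ** 2)
        self._transfer = {
            K: np.exp(-self.beta * K * g) for K in set(self.params.K_dimer.values())
        }

    # -- chain assembly ----------------------------------------------------

    @staticmethod
    def _pair_type(base: str) -> str:
        return "AT" if base in ("A", "T") else "GC"

    def _chain(self, sequence: str):
        seq = _clean_sequence(sequence)
        if len(seq) < 2:
            raise ValueError("chain must have at least 2 base pairs")
        v = [self._v[self._pair_type(b)] for b in seq]
        mats = [self._transfer[self.params.K_dimer[seq[i - 1] + seq[i]]]
                for i in range(1, len(seq))]
        return seq, v, mats

    # -- partition functions ----------------------------------------------

    def log_partition(self, sequence: str, constraint=None) -> float:
        """Log of the constrained configuration integral over the grid domain.

        ``constraint`` maps positions (1-based) to "free"/"closed"/"open", or
        is a length-N list of such states; ``None`` means all free and yields
        log Z_I restricted to the grid domain.
        """
        seq, v, mats = self._chain(sequence)
        states = _constraint_states(len(seq), constraint)
        masks = {FREE: None, CLOSED: self.closed_mask, OPEN: self.open_mask}
        f = v[0] if masks[states[0]] is None else v[0] * masks[states[0]]
        log_scale = 0.0
        for i in range(1, len(seq)):
            f = v[i] * (mats[i - 1] @ f)
            mask = masks[states[i]]
            if mask is not None:
                f = f * mask
            peak = f.max()
            if peak <= 0.0:
                return -math.inf
            f = f / peak
            log_scale += math.log(peak)
        total = f.sum()
        if total <= 0.0:
            return -math.inf
        return math.log(total) + log_scale

    def _forward(self, v, mats):
        n = len(v)
        f = [None] * n
        lf = np.zeros(n)
        cur = v[0]
        acc = 0.0
        for i in range(n):
            if i > 0:
                cur = v[i] * (mats[i - 1] @ cur)
            peak = cur.max()
            cur = cur / peak
            acc += math.log(peak)
            f[i] = cur
            lf[i] = acc
        return f, lf

    def _backward(self, v, mats):
        """ghat[i] sums out positions i+1..N given y_i (bond i,i+1 included)."""
        n = len(v)
        ghat = [None] * n
        lghat = np.zeros(n)
        cur = np.ones_like(v[0])
        acc = 0.0
        ghat[n - 1] = cur
        for i in range(n - 2, -1, -1):
            cur = mats[i].T @ (v[i + 1] * cur)
            peak = cur.max()
            cur = cur / peak
            acc += math.log(peak)
            ghat[i] = cur
            lghat[i] = acc
        return ghat, lghat

    def _log_denominator(self, sequence: str) -> tuple[float, float, float]:
        """Return (log Z_I, log Z_II, log(Z_I - Z_II)) for the dsDNA ensemble."""
        log_zi = self.log_partition(sequence)
        log_zii = self.log_partition(sequence, [OPEN] * len(_clean_sequence(sequence)))
        if log_zi == -math.inf:
            raise NumericalRegimeError("configuration integral underflowed to zero")
        ratio = math.exp(min(log_zii - log_zi, 0.0))
        if ratio > 1.0 - 1e-12:
            raise NumericalRegimeError(
                "dsDNA ensemble is degenerate: fully-open weight Z_II ~= Z_I "
                f"at T = {self.temperature} K"
            )
        return log_zi, log_zii, log_zi + math.log1p(-ratio)

    # -- per-position probabilities ---------------------------------------

    def closed_probabilities(self, sequence: str) -> np.ndarray:
        """P_dsDNA(j closed) = Z(j closed) / (Z_I - Z_II) for every position j."""
        seq, v, mats = self._chain(sequence)
        _, _, log_denom = self._log_denominator(seq)
        f, lf = self._forward(v, mats)
        ghat, lghat = self._backward(v, mats)
        out = np.empty(len(seq))
        for j in range(len(seq)):
            val = float((self.closed_mask * f[j]) @ ghat[j])
            if val <= 0.0:
                out[j] = 0.0
            else:
                out[j] = math.exp(math.log(val) + lf[j] + lghat[j] - log_denom)
        return np.clip(out, 0.0, 1.0)

    def opening_profile(self, sequence: str, sequence_id: str = "") -> OpeningProfile:
        """Single-base opening probabilities P_part(k, 1) = <theta_k>_mu."""
        seq, v, mats = self._chain(sequence)
        log_zi, log_zii, log_denom = self._log_denominator(seq)
        f, lf = self._forward(v, mats)
        ghat, lghat = self._backward(v, mats)
        out = np.empty(len(seq))
        for j in range(len(seq)):
            val = float((self.open_mask * f[j]) @ ghat[j])
            log_open = (math.log(val) + lf[j] + lghat[j]) if val > 0 else -math.inf
            # <theta_k mu> = Z(k open) - Z_II
            if log_open == -math.inf:
                out[j] = 0.0
            else:
                frac = math.exp(min(log_zii - log_open, 0.0))
                out[j] = 0.0 if frac >= 1.0 else math.exp(
                    log_open + math.log1p(-frac) - log_denom)
        return OpeningProfile(sequence_id, self.temperature, np.clip(out, 0.0, 1.0),
                              kind="opening", m=1)

    # -- bubbles -----------------------------------------------------------

    def _run_log_weights(self, v, mats, f, lf, ghat, lghat, m_max: int) -> np.ndarray:
        """log Z of every open run [a, a+m-1] with closed flanks, as (N, m_max).

        Entry [a, m-1] (0-based start a, size m) is the log statistical weight
        of the event "positions a..a+m-1 open, positions a-1 and a+m closed"
        (flank constraints dropped beyond the chain ends, where virtual closed
        pairs are assumed).  The sweep keeps one column per active run start
        and advances all runs with a single matrix product per chain position.
        """
        n = len(v)
        out = np.full((n, m_max), -math.inf)
        ncols0 = self.y.size
        cols = np.empty((ncols0, 0))   # (grid, n_active) run vectors
        col_log = np.empty(0)          # per-column accumulated log scale
        starts = np.empty(0, dtype=int)
        with np.errstate(divide="ignore"):
            for j in range(n):
                if j > 0 and starts.size:
                    x = mats[j - 1] @ cols
                    # close runs [a, j-1] with a closed pair at j
                    z = (ghat[j] * self.closed_mask * v[j]) @ x
                    sizes = j - starts
                    good = z > 0.0
                    out[starts[good], sizes[good] - 1] = (
                        np.log(z[good]) + col_log[good] + lghat[j])
                    # extend runs into j, retiring those that exceed m_max
                    keep = sizes < m_max
                    cols = (self.open_mask * v[j])[:, None] * x[:, keep]
                    col_log = col_log[keep]
                    starts = starts[keep]
                # start a new run at j (left flank closed at j-1, or chain end)
                if j == 0:
                    new = self.open_mask * v[0]
                    new_log = 0.0
                else:
                    new = self.open_mask * v[j] * (mats[j - 1] @ (self.closed_mask * f[j - 1]))
                    new_log = lf[j - 1]
                cols = np.concatenate([cols, new[:, None]], axis=1)
                col_log = np.concatenate([col_log, [new_log]])
                starts = np.concatenate([starts, [j]])
                # renormalise columns; drop dead (underflowed) ones
                peaks = cols.max(axis=0)
                alive = peaks > 0.0
                cols = cols[:, alive] / peaks[alive][None, :]
                col_log = col_log[alive] + np.log(peaks[alive])
                starts = starts[alive]
            # runs ending at the chain end (right flank is the virtual pair N+1)
            sums = cols.sum(axis=0)
            sizes = n - starts
            good = (sums > 0.0) & (sizes <= m_max)
            out[starts[good], sizes[good] - 1] = np.log(sums[good]) + col_log[good]
        return out

    def bubble_matrix(self, sequence: str, m_max: int | None = None,
                      sequence_id: str = "") -> BubbleMatrix:
        """Exact-size bubble probabilities P_bub(k, m) for m = 1..m_max.

        The all-open state is excluded by the dsDNA conditioning, so the
        full-chain "bubble" of size N has probability zero.
        """
        seq, v, mats = self._chain(sequence)
        n = len(seq)
        if m_max is None:
            m_max = n
        if not 1 <= m_max <= n:
            raise ValueError(f"m_max must be in 1..{n}, got {m_max}")
        _, _, log_denom = self._log_denominator(seq)
        f, lf = self._forward(v, mats)
        ghat, lghat = self._backward(v, mats)
        runs = self._run_log_weights(v, mats, f, lf, ghat, lghat, m_max)
        values = np.zeros((n, m_max))
        for m in range(1, m_max + 1):
            offset = (m - 1) // 2 if m % 2 == 1 else m // 2 - 1
            starts = np.arange(n - m + 1)
            centres = starts + offset
            col = np.exp(runs[starts, m - 1] - log_denom)
            if m == n:
                col[:] = 0.0  # theta^[N] * mu vanishes identically
            values[centres, m - 1] = col
        return BubbleMatrix(sequence_id, self.temperature, values)

    def participation_profile(self, bub: BubbleMatrix, m: int,
                              sequence_id: str | None = None) -> OpeningProfile:
        """P_part(k, m): probability of lying in a bubble of size >= m.

        Sums the exact-size bubble matrix over all sizes ``m' >= m`` and all
        centres whose bubble covers position ``k`` (separate even/odd centre
        ranges); centres outside the chain contribute zero.  Requires the
        bubble matrix to carry all sizes up to the chain length.
        """
        n = bub.n_positions
        if bub.m_max != n:
            raise ValueError("participation sums need a bubble matrix with m_max = N")
        if not 1 <= m <= bub.m_max:
            raise ValueError(f"m must be in 1..{bub.m_max}, got {m}")
        k = np.arange(n)
        total = np.zeros(n)
        for mp in range(m, n + 1):
            col = bub.values[:, mp - 1]
            if not col.any():
                continue
            cs = np.concatenate([[0.0], np.cumsum(col)])
            if mp % 2 == 0:
                lo = k - mp // 2
                hi = k + mp // 2 - 1
            else:
                lo = k - (mp - 1) // 2
                hi = k + (mp - 1) // 2
            total += cs[np.clip(hi + 1, 0, n)] - cs[np.clip(lo, 0, n)]
        return OpeningProfile(sequence_id if sequence_id is not None else bub.sequence_id,
                              self.temperature, np.clip(total, 0.0, 1.0),
                              kind=f"participation-{m}", m=m)


# -- module-level convenience wrappers (one call, one sequence) -------------

def transfer_partition(sequence: str, temperature: float,
                       grid: QuadratureGrid | None = None,
                       params: PBDParameters | None = None,
                       constraint=None) -> float:
    """Log statistical weight of the constrained configuration integral.

    Returned in natural-log form because raw weights of long chains overflow
    double precision; all probabilities are ratios of such weights.
    """
    return TransferIntegrator(params, grid, temperature).log_partition(sequence, constraint)


def closed_probability(sequence: str, temperature: float,
                       grid: QuadratureGrid | None = None,
                       params: PBDParameters | None = None,
                       j: int | None = None):
    """P_dsDNA(j closed); all positions if ``j`` is None, else position j (1-based)."""
    engine = TransferIntegrator(params, grid, temperature)
    probs = engine.closed_probabilities(sequence)
    if j is None:
        return probs
    if not 1 <= j <= probs.size:
        raise ValueError(f"position {j} outside 1..{probs.size}")
    return float(probs[j - 1])


def bubble_matrix(sequence: str, temperature: float,
                  grid: QuadratureGrid | None = None,
                  params: PBDParameters | None = None,
                  m_max: int | None = None,
                  sequence_id: str = "") -> BubbleMatrix:
    return TransferIntegrator(params, grid, temperature).bubble_matrix(
        sequence, m_max, sequence_id)


def participation_profile(bub: BubbleMatrix, m: int,
                          params: PBDParameters | None = None,
                          grid: QuadratureGrid | None = None) -> OpeningProfile:
    engine = TransferIntegrator(params, grid, bub.temperature)
    return engine.participation_profile(bub, m)


#: Number of boundary positions trimmed from each end of a physics window.
TRIM = 50
#: Length of the physics window fed to the model.
PBD_WINDOW = 300


def profile_for_window(sequence300: str, temperature: float,
                       grid: QuadratureGrid | None = None,
                       params: PBDParameters | None = None,
                       m: int = 1,
                       sequence_id: str = "",
                       integrator: TransferIntegrator | None = None) -> OpeningProfile:
    """Trimmed participation profile of a 300-base physics window.

    Computes ``P_part(k, m)`` over the full 300-base chain and discards the
    first and last 50 values (boundary effects of the free chain ends),
    returning the 200 central probabilities.
    """
    seq = _clean_sequence(sequence300)
    if len(seq) != PBD_WINDOW:
        raise ValueError(f"physics window must be exactly {PBD_WINDOW} bases, got {len(seq)}")
    engine = integrator or TransferIntegrator(params, grid, temperature)
    bub = engine.bubble_matrix(seq, m_max=PBD_WINDOW, sequence_id=sequence_id)
    prof = engine.participation_profile(bub, m)
    return OpeningProfile(sequence_id, engine.temperature,
                          prof.values[TRIM:PBD_WINDOW - TRIM],
                          kind=prof.kind, m=m, trimmed=True)
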