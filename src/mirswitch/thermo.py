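"""Single-strand RNA secondary-structure thermodynamics.

Implements a nearest-neighbor energy model (Watson-Crick and G.U wobble
pairs; hairpin, stack, bulge, internal and multiloop terms; optional
helix-end dangle terms) together with

* Zuker-style minimum-free-energy folding with deterministic traceback,
* an exhaustive structure enumerator used as a brute-force oracle at small n,
* a McCaskill partition function with equilibrium base-pair probabilities
  (inside-outside dynamic programming in log space),
* hard per-position constraints (forced unpaired / forced paired), and
* cotranscriptional folding via reach-dependent down-weighting of
  long-range pairs, gamma(d) = alpha * exp(-d/tau) + (1 - alpha).

The parameter table ("mirswitch-nn-1") uses the published Watson-Crick
nearest-neighbor stack free energies at 37 degC with simplified wobble,
loop-initiation and dangle terms; the table identifier is recorded in every
report.  Pseudoknots are never allowed.  Salt (1 M Na+) is the reference
condition of the table and is carried as metadata only.

A single grammar is shared, through the same compiled energy-term
functions, by ``structure_energy``, the MFE recursions and the partition
function, so the exhaustive oracle checks the dynamic programs directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from numba import njit

from .core import RnaSequence, AlphabetError, is_pair

# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

R_KCAL = 1.98717e-3  # kcal/(mol*K)

PARAMETER_TABLE_ID = "mirswitch-nn-1"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# Pair type codes (0 = not pairable).
_PT = np.zeros((4, 4), dtype=np.int64)
_PT[1, 2] = 1  # CG
_PT[2, 1] = 2  # GC
_PT[2, 3] = 3  # GU
_PT[3, 2] = 4  # UG
_PT[0, 3] = 5  # AU
_PT[3, 0] = 6  # UA

_REV_PT = np.array([0, 2, 1, 4, 3, 6, 5], dtype=np.int64)


def _build_stack_table() -> np.ndarray:
    """Stack free energies stack[pt(i,j)][pt(i+1,j-1)] in kcal/mol."""
    stack = np.zeros((7, 7), dtype=np.float64)
    stack[:] = np.inf
    # Watson-Crick nearest-neighbor dimers, 5'XY3'/3'WZ5' -> stack[pt(X,W)][pt(Y,Z)].
    code = _BASE_CODE
    wc_dimers = [
        ("AA", "UU", -0.93),
        ("AU", "UA", -1.10),
        ("UA", "AU", -1.33),
        ("CU", "GA", -2.08),
        ("CA", "GU", -2.11),
        ("GU", "CA", -2.24),
        ("GA", "CU", -2.35),
        ("CG", "GC", -2.36),
        ("GG", "CC", -3.26),
        ("GC", "CG", -3.42),
    ]
    for top, bottom, dg in wc_dimers:
        p1 = _PT[code[top[0]], code[bottom[0]]]
        p2 = _PT[code[top[1]], code[bottom[1]]]
        stack[p1, p2] = dg
        # Reading the duplex in the other direction.
        stack[_REV_PT[p2], _REV_PT[p1]] = dg
    # Approximate wobble-containing stacks by category.
    strong = (1, 2)  # CG, GC
    weak = (5, 6)  # AU, UA
    wobble = (3, 4)  # GU, UG
    for p in range(1, 7):
        for q in range(1, 7):
            if np.isfinite(stack[p, q]):
                continue
            nw = (p in wobble) + (q in wobble)
            if nw == 1:
                other = q if p in wobble else p
                stack[p, q] = -2.1 if other in strong else -1.3
            elif nw == 2:
                if (p, q) == (4, 3):  # 5'UG/3'GU motif is destabilizing
                    stack[p, q] = 0.5
                else:
                    stack[p, q] = -0.5
    stack[0, :] = np.inf
    stack[:, 0] = np.inf
    return stack


_STACK = _build_stack_table()

# Loop initiation free energies (kcal/mol); Jacobson-Stockmayer extrapolation
# beyond the tabulated sizes with 1.75 * R * T * ln(n / n_max).
_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_INIT = {2: 1.0, 3: 1.5, 4: 1.7, 5: 1.8, 6: 2.0, 7: 2.2, 8: 2.3, 9: 2.4, 10: 2.5}

TERMINAL_AU = 0.5  # helix-end penalty for AU/UA/GU/UG closing pairs
INTERNAL_CLOSURE_AU = 0.7  # the same penalty inside internal loops
ASYMMETRY = 0.6
ASYMMETRY_MAX = 3.0
ML_CLOSE = 3.4  # multiloop offset
ML_BRANCH = 0.4  # per branch, including the closing helix
ML_UNPAIRED = 0.0
GNRA_BONUS = -1.5
DUPLEX_INIT = 4.09  # two-strand duplex initiation (displacement model)
MAX_INTERIOR = 30

# Simplified dangle terms, indexed by the dangling base only.
_DANGLE5 = np.array([-0.3, -0.1, -0.3, -0.1], dtype=np.float64)  # base 5' of a helix end
_DANGLE3 = np.array([-0.5, -0.2, -0.5, -0.2], dtype=np.float64)  # base 3' of a helix end

_INF = 1e9


def _loop_array(table: dict[int, float], n: int) -> np.ndarray:
    """Initiation-energy array up to length n with log extrapolation."""
    kmax = max(table)
    lxc = 1.75 * R_KCAL * 310.15
    out = np.full(n + 2, _INF, dtype=np.float64)
    for k in range(n + 2):
        if k in table:
            out[k] = table[k]
        elif k > kmax:
            out[k] = table[kmax] + lxc * math.log(k / kmax)
    return out


@dataclass(frozen=True)
class EnergyModelParams:
    """Configuration of the nearest-neighbor energy model.

    ``temperature`` (degC) enters the Boltzmann factor of the partition
    function; the free-energy table itself is defined at 37 degC.  ``salt``
    is metadata (1 M Na+ is the table's reference condition; no correction
    is applied).  ``dangle_mode`` is "none" or "some"; "some" applies
    dangle terms on exterior-loop and multiloop helix ends.  Pseudoknots
    are always forbidden.
    """

    temperature: float = 37.0
    salt: float = 1.0
    dangle_mode: str = "some"
    parameter_table: str = PARAMETER_TABLE_ID
    min_loop: int = 3
    max_interior: int = MAX_INTERIOR

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        if self.dangle_mode not in ("none", "some"):
            raise ValueError(f"unsupported dangle_mode {self.dangle_mode!r}")

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15

    @property
    def rt(self) -> float:
        return R_KCAL * self.kelvin

    def _key(self) -> tuple:
        return (self.temperature, self.dangle_mode, self.min_loop, self.max_interior)


@dataclass(frozen=True)
class CofoldParams:
    """Reach-dependent scaling for cotranscriptional folding.

    The energy contribution of a pair spanning distance d is scaled by
    gamma(d) = alpha * exp(-d / tau) + (1 - alpha).  alpha = 0 recovers the
    equilibrium fold exactly.
    """

    alpha: float = 0.5
    tau: float = 640.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


# --------------------------------------------------------------------------
# Structures
# --------------------------------------------------------------------------


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"bad dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return frozenset(pairs)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure with its free energy (kcal/mol)."""

    dot_bracket: str
    pairs: frozenset[tuple[int, int]]
    delta_g: float
    parameter_table: str = PARAMETER_TABLE_ID
    dangle_mode: str = "some"

    def __len__(self) -> int:
        return len(self.dot_bracket)

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass(frozen=True)
class BasePairProbabilityMatrix:
    """Equilibrium pairing probabilities p[i][j] (1-based, symmetric)."""

    matrix: np.ndarray  # (n, n), 0-based storage
    p_unpaired: np.ndarray  # (n,)

    def p(self, i: int, j: int) -> float:
        return float(self.matrix[i - 1, j - 1])

    def paired_probability(self, i: int) -> float:
        return 1.0 - float(self.p_unpaired[i - 1])

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class PartitionFunctionResult:
    ensemble_free_energy: float  # -RT ln Z, kcal/mol
    probabilities: BasePairProbabilityMatrix
    log_z: float
    parameter_table: str = PARAMETER_TABLE_ID


# --------------------------------------------------------------------------
# Compiled energy terms (0-based indices; shared by every algorithm)
# --------------------------------------------------------------------------


@njit(cache=False)
def _ptype(a, b, pt):
    return pt[a, b]


@njit(cache=False)
def _end_penalty(p):
    if p >= 3:  # GU, UG, AU, UA
        return TERMINAL_AU
    return 0.0


@njit(cache=False)
def _e_hairpin(seq, i, j, pt, hp_init):
    l = j - i - 1
    e = hp_init[l] + _end_penalty(pt[seq[i], seq[j]])
    if l == 4:
        # GNRA-type tetraloop bonus
        if seq[i + 1] == 2 and seq[j - 1] == 0 and (seq[i + 3] == 0 or seq[i + 3] == 2):
            e += GNRA_BONUS
    return e


@njit(cache=False)
def _e_interior(seq, i, j, k, l, pt, stack, bulge_init, int_init):
    """Energy of the two-loop between closing pair (i,j) and inner pair (k,l)."""
    p1 = pt[seq[i], seq[j]]
    p2 = pt[seq[k], seq[l]]
    u1 = k - i - 1
    u2 = j - l - 1
    if u1 == 0 and u2 == 0:
        return stack[p1, p2]
    if u1 + u2 == 1:
        # bulge of one keeps the flanking stack
        return bulge_init[1] + stack[p1, p2]
    if u1 == 0 or u2 == 0:
        u = u1 + u2
        return bulge_init[u] + _end_penalty(p1) + _end_penalty(p2)
    asym = ASYMMETRY * abs(u1 - u2)
    if asym > ASYMMETRY_MAX:
        asym = ASYMMETRY_MAX
    e = int_init[u1 + u2] + asym
    if p1 >= 3:
        e += INTERNAL_CLOSURE_AU
    if p2 >= 3:
        e += INTERNAL_CLOSURE_AU
    return e


@njit(cache=False)
def _ext_branch_term(seq, i, j, n, pt, d5, d3, dangle_on):
    """Terminal term for a helix (i,j) in the exterior loop."""
    p = pt[seq[i], seq[j]]
    e = _end_penalty(p)
    if dangle_on:
        if i > 0:
            e += d5[seq[i - 1]]
        if j < n - 1:
            e += d3[seq[j + 1]]
    return e


@njit(cache=False)
def _ml_branch_term(seq, i, j, pt, d5, d3, dangle_on):
    """Terminal term for a branch helix (i,j) inside a multiloop."""
    p = pt[seq[i], seq[j]]
    e = _end_penalty(p)
    if dangle_on:
        e += d5[seq[i - 1]] + d3[seq[j + 1]]
    return e


@njit(cache=False)
def _ml_close_term(seq, i, j, pt, d5, d3, dangle_on):
    """Terminal term for the closing helix (i,j) of a multiloop, seen from inside."""
    p = pt[seq[i], seq[j]]
    e = _end_penalty(p)
    if dangle_on:
        e += d3[seq[i + 1]] + d5[seq[j - 1]]
    return e


@njit(cache=False)
def _clean(fp_cum, a, b):
    """True if no forced-paired position lies in [a, b] (0-based, inclusive)."""
    if a > b:
        return True
    return fp_cum[b + 1] - fp_cum[a] == 0


@njit(cache=False)
def _pair_ok(seq, mask, i, j, pt, min_loop):
    if j - i <= min_loop:
        return False
    if mask[i] == 1 or mask[j] == 1:
        return False
    return pt[seq[i], seq[j]] != 0


# --------------------------------------------------------------------------
# MFE fill and traceback
# --------------------------------------------------------------------------


@njit(cache=False)
def _mfe_fill(seq, mask, gam, pt, stack, hp_init, bulge_init, int_init, d5, d3,
              dangle_on, min_loop, max_int):
    n = seq.shape[0]
    V = np.full((n, n), _INF)
    M = np.full((n, n), _INF)
    M1 = np.full((n, n), _INF)
    W = np.full(n + 1, _INF)
    fp_cum = np.zeros(n + 1, dtype=np.int64)
    for t in range(n):
        fp_cum[t + 1] = fp_cum[t] + (1 if mask[t] == 2 else 0)

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not _pair_ok(seq, mask, i, j, pt, min_loop):
                continue
            g = gam[span]
            best = _INF
            # hairpin
            if _clean(fp_cum, i + 1, j - 1):
                e = g * _e_hairpin(seq, i, j, pt, hp_init)
                if e < best:
                    best = e
            # interior loops (incl. stacks and bulges)
            kmax = i + max_int + 2
            if kmax > j - 1:
                kmax = j - 1
            for k in range(i + 1, kmax):
                u1 = k - i - 1
                if not _clean(fp_cum, i + 1, k - 1):
                    break
                lmin = k + min_loop + 1
                llo = j - 1 - (max_int - u1)
                if llo < lmin:
                    llo = lmin
                for l in range(j - 1, llo - 1, -1):
                    if V[k, l] >= _INF:
                        continue
                    if not _clean(fp_cum, l + 1, j - 1):
                        continue
                    e = g * _e_interior(seq, i, j, k, l, pt, stack, bulge_init, int_init) + V[k, l]
                    if e < best:
                        best = e
            # multiloop closure
            if j - i > 2 * (min_loop + 2):
                base = g * (ML_CLOSE + ML_BRANCH + _ml_close_term(seq, i, j, pt, d5, d3, dangle_on))
                for u in range(i + 2, j - 1):
                    if M[i + 1, u - 1] < _INF and M1[u, j - 1] < _INF:
                        e = base + M[i + 1, u - 1] + M1[u, j - 1]
                        if e < best:
                            best = e
            V[i, j] = best

        # M1 and M for this span band; multiloop segments always have a
        # closing pair outside them, so boundary cells are never needed.
        for i in range(1, n - span):
            j = i + span
            if j > n - 2:
                continue
            # M1: one branch starting exactly at i, trailing unpaired
            best = _INF
            if j > i and M1[i, j - 1] < _INF and mask[j] != 2:
                e = M1[i, j - 1] + ML_UNPAIRED
                if e < best:
                    best = e
            if V[i, j] < _INF:
                e = V[i, j] + ML_BRANCH + _ml_branch_term(seq, i, j, pt, d5, d3, dangle_on)
                if e < best:
                    best = e
            M1[i, j] = best
            # M: one or more branches, decomposed by the last branch ending
            # exactly at j (or j unpaired)
            best = _INF
            if j > i and M[i, j - 1] < _INF and mask[j] != 2:
                e = M[i, j - 1] + ML_UNPAIRED
                if e < best:
                    best = e
            for k in range(i, j + 1):
                if V[k, j] >= _INF:
                    continue
                wb = V[k, j] + ML_BRANCH + _ml_branch_term(seq, k, j, pt, d5, d3, dangle_on)
                if k == i:
                    if wb < best:
                        best = wb
                else:
                    if _clean(fp_cum, i, k - 1):
                        e = ML_UNPAIRED * (k - i) + wb
                        if e < best:
                            best = e
                    if M[i, k - 1] < _INF:
                        e = M[i, k - 1] + wb
                        if e < best:
                            best = e
            M[i, j] = best

    # exterior
    W[0] = 0.0
    for j in range(0, n):
        best = _INF
        if mask[j] != 2 and W[j] < _INF:
            best = W[j]
        for i in range(0, j):
            if W[i] < _INF and V[i, j] < _INF:
                e = W[i] + V[i, j] + _ext_branch_term(seq, i, j, n, pt, d5, d3, dangle_on)
                if e < best:
                    best = e
        W[j + 1] = best
    return V, M, M1, W


@njit(cache=False)
def _mfe_traceback(seq, mask, gam, V, M, M1, W, pt, stack, hp_init, bulge_init,
                   int_init, d5, d3, dangle_on, min_loop, max_int):
    n = seq.shape[0]
    EPS = 1e-7
    partner = np.full(n, -1, dtype=np.int64)
    fp_cum = np.zeros(n + 1, dtype=np.int64)
    for t in range(n):
        fp_cum[t + 1] = fp_cum[t] + (1 if mask[t] == 2 else 0)

    # stack of (tag, i, j): tag 0=V, 1=M, 2=M1
    st_tag = np.empty(4 * n + 8, dtype=np.int64)
    st_i = np.empty(4 * n + 8, dtype=np.int64)
    st_j = np.empty(4 * n + 8, dtype=np.int64)
    top = 0

    # exterior: scan from the right, preferring the smallest pairing start i
    j = n - 1
    while j >= 0:
        target = W[j + 1]
        done = False
        for i in range(0, j + 1):
            if V[i, j] >= _INF or W[i] >= _INF:
                continue
            e = W[i] + V[i, j] + _ext_branch_term(seq, i, j, n, pt, d5, d3, dangle_on)
            if e <= target + EPS:
                st_tag[top] = 0
                st_i[top] = i
                st_j[top] = j
                top += 1
                j = i - 1
                done = True
                break
        if not done:
            j -= 1

    while top > 0:
        top -= 1
        tag = st_tag[top]
        i = st_i[top]
        j = st_j[top]
        if tag == 0:
            partner[i] = j
            partner[j] = i
            target = V[i, j]
            g = gam[j - i]
            if _clean(fp_cum, i + 1, j - 1):
                if g * _e_hairpin(seq, i, j, pt, hp_init) <= target + EPS:
                    continue
            found = False
            kmax = i + max_int + 2
            if kmax > j - 1:
                kmax = j - 1
            for k in range(i + 1, kmax):
                if found:
                    break
                u1 = k - i - 1
                if not _clean(fp_cum, i + 1, k - 1):
                    break
                lmin = k + min_loop + 1
                llo = j - 1 - (max_int - u1)
                if llo < lmin:
                    llo = lmin
                for l in range(j - 1, llo - 1, -1):
                    if V[k, l] >= _INF:
                        continue
                    if not _clean(fp_cum, l + 1, j - 1):
                        continue
                    e = g * _e_interior(seq, i, j, k, l, pt, stack, bulge_init, int_init) + V[k, l]
                    if e <= target + EPS:
                        st_tag[top] = 0
                        st_i[top] = k
                        st_j[top] = l
                        top += 1
                        found = True
                        break
            if found:
                continue
            base = g * (ML_CLOSE + ML_BRANCH + _ml_close_term(seq, i, j, pt, d5, d3, dangle_on))
            for u in range(i + 2, j - 1):
                if M[i + 1, u - 1] < _INF and M1[u, j - 1] < _INF:
                    if base + M[i + 1, u - 1] + M1[u, j - 1] <= target + EPS:
                        st_tag[top] = 1
                        st_i[top] = i + 1
                        st_j[top] = u - 1
                        top += 1
                        st_tag[top] = 2
                        st_i[top] = u
                        st_j[top] = j - 1
                        top += 1
                        break
        elif tag == 2:
            # M1: strip trailing unpaired, then the branch is (i, j)
            target = M1[i, j]
            jj = j
            while jj > i:
                if V[i, jj] < _INF and _clean(fp_cum, jj + 1, j):
                    e = V[i, jj] + ML_BRANCH + _ml_branch_term(seq, i, jj, pt, d5, d3, dangle_on)
                    if e + ML_UNPAIRED * (j - jj) <= target + EPS:
                        break
                jj -= 1
            st_tag[top] = 0
            st_i[top] = i
            st_j[top] = jj
            top += 1
        else:
            # M
            target = M[i, j]
            if j > i and M[i, j - 1] < _INF and mask[j] != 2:
                if M[i, j - 1] + ML_UNPAIRED <= target + EPS:
                    st_tag[top] = 1
                    st_i[top] = i
                    st_j[top] = j - 1
                    top += 1
                    continue
            resolved = False
            for k in range(i, j + 1):
                if V[k, j] >= _INF:
                    continue
                wb = V[k, j] + ML_BRANCH + _ml_branch_term(seq, k, j, pt, d5, d3, dangle_on)
                if k == i and wb <= target + EPS:
                    st_tag[top] = 0
                    st_i[top] = k
                    st_j[top] = j
                    top += 1
                    resolved = True
                    break
                if k > i:
                    if _clean(fp_cum, i, k - 1) and ML_UNPAIRED * (k - i) + wb <= target + EPS:
                        st_tag[top] = 0
                        st_i[top] = k
                        st_j[top] = j
                        top += 1
                        resolved = True
                        break
                    if M[i, k - 1] < _INF and M[i, k - 1] + wb <= target + EPS:
                        st_tag[top] = 1
                        st_i[top] = i
                        st_j[top] = k - 1
                        top += 1
                        st_tag[top] = 0
                        st_i[top] = k
                        st_j[top] = j
                        top += 1
                        resolved = True
                        break
            if not resolved:
                # numerical safety: leave segment unpaired
                pass
    return partner


# --------------------------------------------------------------------------
# Partition function (inside + outside, log space)
# --------------------------------------------------------------------------


@njit(cache=False)
def _ladd(a, b):
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


@njit(cache=False)
def _pf_inside(seq, mask, beta, pt, stack, hp_init, bulge_init, int_init, d5, d3,
               dangle_on, min_loop, max_int):
    n = seq.shape[0]
    NEG = -np.inf
    ZB = np.full((n, n), NEG)
    ZM = np.full((n, n), NEG)
    ZM1 = np.full((n, n), NEG)
    Qf = np.full(n + 1, NEG)
    Qr = np.full(n + 2, NEG)
    fp_cum = np.zeros(n + 1, dtype=np.int64)
    for t in range(n):
        fp_cum[t + 1] = fp_cum[t] + (1 if mask[t] == 2 else 0)

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not _pair_ok(seq, mask, i, j, pt, min_loop):
                continue
            acc = NEG
            if _clean(fp_cum, i + 1, j - 1):
                acc = _ladd(acc, -beta * _e_hairpin(seq, i, j, pt, hp_init))
            kmax = i + max_int + 2
            if kmax > j - 1:
                kmax = j - 1
            for k in range(i + 1, kmax):
                u1 = k - i - 1
                if not _clean(fp_cum, i + 1, k - 1):
                    break
                lmin = k + min_loop + 1
                llo = j - 1 - (max_int - u1)
                if llo < lmin:
                    llo = lmin
                for l in range(j - 1, llo - 1, -1):
                    if ZB[k, l] == NEG:
                        continue
                    if not _clean(fp_cum, l + 1, j - 1):
                        continue
                    e = _e_interior(seq, i, j, k, l, pt, stack, bulge_init, int_init)
                    acc = _ladd(acc, -beta * e + ZB[k, l])
            if j - i > 2 * (min_loop + 2):
                base = -beta * (ML_CLOSE + ML_BRANCH + _ml_close_term(seq, i, j, pt, d5, d3, dangle_on))
                mlsum = NEG
                for u in range(i + 2, j - 1):
                    if ZM[i + 1, u - 1] != NEG and ZM1[u, j - 1] != NEG:
                        mlsum = _ladd(mlsum, ZM[i + 1, u - 1] + ZM1[u, j - 1])
                if mlsum != NEG:
                    acc = _ladd(acc, base + mlsum)
            ZB[i, j] = acc

        for i in range(1, n - span):
            j = i + span
            if j > n - 2:
                continue
            # ZM1
            acc = NEG
            if j > i and ZM1[i, j - 1] != NEG and mask[j] != 2:
                acc = _ladd(acc, ZM1[i, j - 1] - beta * ML_UNPAIRED)
            if ZB[i, j] != NEG:
                acc = _ladd(acc, ZB[i, j] - beta * (ML_BRANCH + _ml_branch_term(seq, i, j, pt, d5, d3, dangle_on)))
            ZM1[i, j] = acc
            # ZM: decomposition by the last branch ending exactly at j
            acc = NEG
            if j > i and ZM[i, j - 1] != NEG and mask[j] != 2:
                acc = _ladd(acc, ZM[i, j - 1] - beta * ML_UNPAIRED)
            for k in range(i, j + 1):
                if ZB[k, j] == NEG:
                    continue
                wb = ZB[k, j] - beta * (ML_BRANCH + _ml_branch_term(seq, k, j, pt, d5, d3, dangle_on))
                if k == i:
                    acc = _ladd(acc, wb)
                else:
                    if _clean(fp_cum, i, k - 1):
                        acc = _ladd(acc, -beta * ML_UNPAIRED * (k - i) + wb)
                    if ZM[i, k - 1] != NEG:
                        acc = _ladd(acc, ZM[i, k - 1] + wb)
            ZM[i, j] = acc

    Qf[0] = 0.0
    for j in range(0, n):
        acc = NEG
        if mask[j] != 2 and Qf[j] != NEG:
            acc = Qf[j]
        for i in range(0, j + 1):
            if ZB[i, j] != NEG and Qf[i] != NEG:
                acc = _ladd(acc, Qf[i] + ZB[i, j] - beta * _ext_branch_term(seq, i, j, n, pt, d5, d3, dangle_on))
        Qf[j + 1] = acc

    Qr[n] = 0.0
    for i in range(n - 1, -1, -1):
        acc = NEG
        if mask[i] != 2 and Qr[i + 1] != NEG:
            acc = Qr[i + 1]
        for j in range(i + 1, n):
            if ZB[i, j] != NEG and Qr[j + 1] != NEG:
                acc = _ladd(acc, ZB[i, j] - beta * _ext_branch_term(seq, i, j, n, pt, d5, d3, dangle_on) + Qr[j + 1])
        Qr[i] = acc

    return ZB, ZM, ZM1, Qf, Qr


@njit(cache=False)
def _pf_outside(seq, mask, beta, ZB, ZM, Qf, Qr, pt, stack, hp_init, bulge_init,
                int_init, d5, d3, dangle_on, min_loop, max_int):
    n = seq.shape[0]
    NEG = -np.inf
    logZ = Qf[n]
    fp_cum = np.zeros(n + 1, dtype=np.int64)
    for t in range(n):
        fp_cum[t + 1] = fp_cum[t] + (1 if mask[t] == 2 else 0)

    # candidate pairs sorted by decreasing span
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            if ZB[i, j] != NEG:
                npairs += 1
    pi = np.empty(npairs, dtype=np.int64)
    pj = np.empty(npairs, dtype=np.int64)
    t = 0
    for span in range(n - 1, min_loop, -1):
        for i in range(0, n - span):
            if ZB[i, i + span] != NEG:
                pi[t] = i
                pj[t] = i + span
                t += 1

    logP = np.full((n, n), NEG)
    for t1 in range(npairs):
        i = pi[t1]
        j = pj[t1]
        acc = NEG
        # exterior context
        if Qf[i] != NEG and Qr[j + 1] != NEG:
            acc = _ladd(acc, Qf[i] + Qr[j + 1] - beta * _ext_branch_term(seq, i, j, n, pt, d5, d3, dangle_on))
        # enclosing contexts: pairs with strictly larger span appear earlier
        for t2 in range(t1):
            p = pi[t2]
            q = pj[t2]
            if p >= i or q <= j:
                continue
            if logP[p, q] == NEG:
                continue
            # outside weight of (p, q): O(p,q) = P(p,q) * Z / ZB(p,q)
            out_pq = logP[p, q] - ZB[p, q] + logZ
            u1 = i - p - 1
            u2 = q - j - 1
            # interior-loop context
            if u1 + u2 <= max_int:
                if _clean(fp_cum, p + 1, i - 1) and _clean(fp_cum, j + 1, q - 1):
                    e = _e_interior(seq, p, q, i, j, pt, stack, bulge_init, int_init)
                    acc = _ladd(acc, out_pq - beta * e)
            # multiloop context
            inner = NEG
            left_clean = _clean(fp_cum, p + 1, i - 1)
            right_clean = _clean(fp_cum, j + 1, q - 1)
            zm_left = ZM[p + 1, i - 1] if i - 1 >= p + 1 else NEG
            zm_right = ZM[j + 1, q - 1] if q - 1 >= j + 1 else NEG
            if left_clean and zm_right != NEG:
                inner = _ladd(inner, -beta * ML_UNPAIRED * u1 + zm_right)
            if zm_left != NEG and right_clean:
                inner = _ladd(inner, zm_left - beta * ML_UNPAIRED * u2)
            if zm_left != NEG and zm_right != NEG:
                inner = _ladd(inner, zm_left + zm_right)
            if inner != NEG:
                w = (
                    out_pq
                    - beta * (ML_CLOSE + ML_BRANCH + _ml_close_term(seq, p, q, pt, d5, d3, dangle_on))
                    - beta * (ML_BRANCH + _ml_branch_term(seq, i, j, pt, d5, d3, dangle_on))
                    + inner
                )
                acc = _ladd(acc, w)
        if acc != NEG:
            logP[i, j] = acc + ZB[i, j] - logZ

    P = np.zeros((n, n))
    for t1 in range(npairs):
        i = pi[t1]
        j = pj[t1]
        if logP[i, j] != NEG:
            v = math.exp(logP[i, j])
            P[i, j] = v
            P[j, i] = v
    return P


# --------------------------------------------------------------------------
# Python-side helpers and public API
# --------------------------------------------------------------------------


def encode(seq: RnaSequence | str) -> np.ndarray:
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    try:
        return np.array([_BASE_CODE[b] for b in residues.upper().replace("T", "U")], dtype=np.int64)
    except KeyError as exc:
        raise AlphabetError(f"non-RNA character in sequence: {exc}") from exc


def _tables(params: EnergyModelParams, n: int):
    hp = _loop_array(_HAIRPIN_INIT, max(n, 32))
    bu = _loop_array(_BULGE_INIT, max(n, 32))
    it = _loop_array(_INTERNAL_INIT, max(n, 32))
    return hp, bu, it


def _build_mask(n: int, constraints: Optional[dict[int, str]]) -> np.ndarray:
    mask = np.zeros(n, dtype=np.int64)
    if constraints:
        for pos, kind in constraints.items():
            if not 1 <= pos <= n:
                raise ValueError(f"constraint position {pos} outside sequence")
            if kind in ("unpaired", "forced_unpaired"):
                mask[pos - 1] = 1
            elif kind in ("paired", "forced_paired"):
                mask[pos - 1] = 2
            else:
                raise ValueError(f"unknown constraint {kind!r}")
    return mask


def _gamma_array(n: int, cofold: Optional[CofoldParams]) -> np.ndarray:
    if cofold is None or cofold.alpha == 0.0:
        return np.ones(n + 1, dtype=np.float64)
    d = np.arange(n + 1, dtype=np.float64)
    return cofold.alpha * np.exp(-d / cofold.tau) + (1.0 - cofold.alpha)


def _partner_to_structure(seq, partner, params, delta_g=None) -> SecondaryStructure:
    n = len(partner)
    pairs = frozenset(
        (i + 1, int(partner[i]) + 1) for i in range(n) if partner[i] > i
    )
    db = pairs_to_dotbracket(pairs, n)
    if delta_g is None:
        delta_g = structure_energy(seq, pairs, params)
    return SecondaryStructure(db, pairs, float(delta_g), params.parameter_table, params.dangle_mode)


def _mfe_impl(seq, params, constraints, cofold):
    codes = encode(seq)
    n = codes.shape[0]
    mask = _build_mask(n, constraints)
    gam = _gamma_array(n, cofold)
    hp, bu, it = _tables(params, n)
    dangle_on = params.dangle_mode == "some"
    V, M, M1, W = _mfe_fill(
        codes, mask, gam, _PT, _STACK, hp, bu, it, _DANGLE5, _DANGLE3,
        dangle_on, params.min_loop, params.max_interior,
    )
    if W[n] >= _INF / 2:
        raise ValueError("contradictory constraints: no admissible structure")
    partner = _mfe_traceback(
        codes, mask, gam, V, M, M1, W, _PT, _STACK, hp, bu, it, _DANGLE5, _DANGLE3,
        dangle_on, params.min_loop, params.max_interior,
    )
    return _partner_to_structure(seq, partner, params)


_fold_cache: dict[tuple, SecondaryStructure] = {}
_pf_cache: dict[tuple, PartitionFunctionResult] = {}


def _residues(seq: RnaSequence | str) -> str:
    return seq.residues if isinstance(seq, RnaSequence) else RnaSequence(seq).residues


def fold_mfe(seq: RnaSequence | str, params: EnergyModelParams | None = None) -> SecondaryStructure:
    """Minimum-free-energy structure under the nearest-neighbor model.

    Deterministic: ties are broken by the traceback's fixed candidate order
    (5'-most pairings first), so identical inputs give identical dot-brackets.
    """
    params = params or EnergyModelParams()
    key = (_residues(seq), params._key(), None, None)
    if key not in _fold_cache:
        _fold_cache[key] = _mfe_impl(seq, params, None, None)
    return _fold_cache[key]


def constrained_fold(
    seq: RnaSequence | str,
    params: EnergyModelParams | None = None,
    constraints: Optional[dict[int, str]] = None,
) -> SecondaryStructure:
    """MFE over structures satisfying per-position constraints.

    ``constraints`` maps 1-based positions to "unpaired" or "paired".  With
    no constraints the result equals :func:`fold_mfe`.
    """
    params = params or EnergyModelParams()
    if not constraints:
        return fold_mfe(seq, params)
    ckey = tuple(sorted(constraints.items()))
    key = (_residues(seq), params._key(), ckey, None)
    if key not in _fold_cache:
        _fold_cache[key] = _mfe_impl(seq, params, constraints, None)
    return _fold_cache[key]


def cofold_mfe(
    seq: RnaSequence | str,
    params: EnergyModelParams | None = None,
    cofold: CofoldParams | None = None,
) -> SecondaryStructure:
    """MFE with reach-dependent down-weighting of long-range pairs.

    Each loop term closed by a pair spanning distance d is scaled by
    gamma(d) = alpha * exp(-d / tau) + (1 - alpha) during the search; the
    returned ``delta_g`` is the unscaled free energy of the chosen structure.
    With alpha = 0 the search is identical to :func:`fold_mfe`.
    """
    params = params or EnergyModelParams()
    cofold = cofold or CofoldParams()
    if cofold.alpha == 0.0:
        return fold_mfe(seq, params)
    key = (_residues(seq), params._key(), None, (cofold.alpha, cofold.tau))
    if key not in _fold_cache:
        _fold_cache[key] = _mfe_impl(seq, params, None, cofold)
    return _fold_cache[key]


def partition_function(
    seq: RnaSequence | str,
    params: EnergyModelParams | None = None,
    constraints: Optional[dict[int, str]] = None,
) -> PartitionFunctionResult:
    """Boltzmann ensemble: Z and equilibrium base-pair probabilities.

    Inside-outside dynamic programming in log space (no overflow for
    sequences of several hundred nucleotides).  For an unpairable sequence
    Z = 1 and every pairing probability is 0.
    """
    params = params or EnergyModelParams()
    ckey = tuple(sorted(constraints.items())) if constraints else None
    key = (_residues(seq), params._key(), ckey)
    if key in _pf_cache:
        return _pf_cache[key]
    codes = encode(seq)
    n = codes.shape[0]
    mask = _build_mask(n, constraints)
    hp, bu, it = _tables(params, n)
    dangle_on = params.dangle_mode == "some"
    beta = 1.0 / params.rt
    ZB, ZM, ZM1, Qf, Qr = _pf_inside(
        codes, mask, beta, _PT, _STACK, hp, bu, it, _DANGLE5, _DANGLE3,
        dangle_on, params.min_loop, params.max_interior,
    )
    log_z = float(Qf[n])
    if not np.isfinite(log_z):
        raise ValueError("contradictory constraints: empty ensemble")
    P = _pf_outside(
        codes, mask, beta, ZB, ZM, Qf, Qr, _PT, _STACK, hp, bu, it,
        _DANGLE5, _DANGLE3, dangle_on, params.min_loop, params.max_interior,
    )
    p_unpaired = np.clip(1.0 - P.sum(axis=1), 0.0, 1.0)
    result = PartitionFunctionResult(
        ensemble_free_energy=-params.rt * log_z,
        probabilities=BasePairProbabilityMatrix(P, p_unpaired),
        log_z=log_z,
        parameter_table=params.parameter_table,
    )
    _pf_cache[key] = result
    return result


def ensemble_free_energy(
    seq: RnaSequence | str,
    params: EnergyModelParams | None = None,
    constraints: Optional[dict[int, str]] = None,
) -> float:
    """-RT ln Z, optionally under constraints (cheaper path used by reports)."""
    return partition_function(seq, params, constraints).ensemble_free_energy


# --------------------------------------------------------------------------
# structure_energy: score an arbitrary given structure with the same grammar
# --------------------------------------------------------------------------


def _loop_decomposition(partner: dict[int, int], n: int):
    """Yield (closing_pair_or_None, branches, n_unpaired) for every loop.

    ``closing_pair`` is None for the exterior loop; branches are (i, j)
    pairs directly interior to the loop.  All coordinates 1-based.
    """

    def scan(lo: int, hi: int):
        branches = []
        unpaired = 0
        k = lo
        while k <= hi:
            if k in partner and partner[k] > k:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            elif k in partner:
                raise ValueError(f"structure inconsistent at position {k}")
            else:
                unpaired += 1
                k += 1
        return branches, unpaired

    out = []
    ext_branches, ext_unpaired = scan(1, n)
    out.append((None, ext_branches, ext_unpaired))
    stack = list(ext_branches)
    while stack:
        i, j = stack.pop()
        branches, unpaired = scan(i + 1, j - 1)
        out.append(((i, j), branches, unpaired))
        stack.extend(branches)
    return out


def structure_energy(
    seq: RnaSequence | str,
    structure: SecondaryStructure | Iterable[tuple[int, int]] | str,
    params: EnergyModelParams | None = None,
) -> float:
    """Free energy (kcal/mol) of a given nested structure; open chain = 0.

    Accepts a :class:`SecondaryStructure`, a pair collection, or a
    dot-bracket string.  Raises for pairs the model cannot form (non-canonical
    or violating the minimum loop).
    """
    params = params or EnergyModelParams()
    if isinstance(structure, SecondaryStructure):
        pairs = structure.pairs
    elif isinstance(structure, str):
        pairs = dotbracket_to_pairs(structure)
    else:
        pairs = frozenset((int(i), int(j)) for i, j in structure)
    residues = _residues(seq)
    codes = encode(residues)
    n = len(residues)
    partner: dict[int, int] = {}
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise ValueError(f"pair ({i}, {j}) outside sequence")
        if j - i <= params.min_loop:
            raise ValueError(f"pair ({i}, {j}) violates minimum loop size")
        if not is_pair(residues[i - 1], residues[j - 1]):
            raise ValueError(f"pair ({i}, {j}) is not Watson-Crick or wobble")
        if i in partner or j in partner:
            raise ValueError("position in more than one pair")
        partner[i] = j
        partner[j] = i

    hp, bu, it = _tables(params, n)
    dangle_on = params.dangle_mode == "some"
    total = 0.0
    for closing, branches, unpaired in _loop_decomposition(partner, n):
        if closing is None:
            for (bi, bj) in branches:
                total += _ext_branch_term(codes, bi - 1, bj - 1, n, _PT, _DANGLE5, _DANGLE3, dangle_on)
        else:
            i, j = closing
            if len(branches) == 0:
                total += _e_hairpin(codes, i - 1, j - 1, _PT, hp)
            elif len(branches) == 1:
                k, l = branches[0]
                total += _e_interior(codes, i - 1, j - 1, k - 1, l - 1, _PT, _STACK, bu, it)
            else:
                total += ML_CLOSE + ML_BRANCH * (len(branches) + 1) + ML_UNPAIRED * unpaired
                total += _ml_close_term(codes, i - 1, j - 1, _PT, _DANGLE5, _DANGLE3, dangle_on)
                for (bi, bj) in branches:
                    total += _ml_branch_term(codes, bi - 1, bj - 1, _PT, _DANGLE5, _DANGLE3, dangle_on)
    return float(total)


# --------------------------------------------------------------------------
# Exhaustive enumeration (brute-force oracle, small n only)
# --------------------------------------------------------------------------

ENUMERATION_CAP = 22


def enumerate_structures(
    seq: RnaSequence | str,
    params: EnergyModelParams | None = None,
    constraints: Optional[dict[int, str]] = None,
) -> Iterator[SecondaryStructure]:
    """Every nested structure over canonical pairs, each scored exactly.

    Intended as a test oracle; refuses sequences longer than
    ``ENUMERATION_CAP`` nucleotides.
    """
    params = params or EnergyModelParams()
    residues = _residues(seq)
    n = len(residues)
    if n > ENUMERATION_CAP:
        raise ValueError(f"enumeration capped at {ENUMERATION_CAP} nt (got {n})")
    mask = _build_mask(n, constraints)

    def can_pair(i: int, j: int) -> bool:  # 1-based
        if j - i <= params.min_loop:
            return False
        if mask[i - 1] == 1 or mask[j - 1] == 1:
            return False
        return is_pair(residues[i - 1], residues[j - 1])

    def gen(lo: int, hi: int):
        if lo > hi:
            yield []
            return
        # position lo unpaired
        if mask[lo - 1] != 2:
            for rest in gen(lo + 1, hi):
                yield rest
        # position lo paired with k
        for k in range(lo + params.min_loop + 1, hi + 1):
            if not can_pair(lo, k):
                continue
            for inner in gen(lo + 1, k - 1):
                for outer in gen(k + 1, hi):
                    yield [(lo, k)] + inner + outer

    for pair_list in gen(1, n):
        pairs = frozenset(pair_list)
        dg = structure_energy(residues, pairs, params)
        yield SecondaryStructure(
            pairs_to_dotbracket(pairs, n), pairs, dg, params.parameter_table, params.dangle_mode
        )


# --------------------------------------------------------------------------
# Two-strand duplex energy (used by the strand-displacement model)
# --------------------------------------------------------------------------


def duplex_energy(
    strand_a: RnaSequence | str,
    strand_b: RnaSequence | str,
    params: EnergyModelParams | None = None,
) -> float:
    """Nearest-neighbor hybridization energy of two antiparallel strands.

    Position k of ``strand_a`` faces position (len - k + 1) of ``strand_b``
    (the geometry of a site against its trigger miRNA).  Paired runs are
    scored with stack terms plus helix-end penalties; runs separated by m
    mismatched aligned positions contribute a symmetric internal-loop
    penalty; a single duplex-initiation term is added if any pair forms.
    Unaligned overhangs are left unpaired.  Returns 0 for no pairing.
    """
    params = params or EnergyModelParams()
    a = _residues(strand_a)
    b = _residues(strand_b)
    m = min(len(a), len(b))
    paired = [is_pair(a[k], b[len(b) - 1 - k]) for k in range(m)]
    if not any(paired):
        return 0.0
    codes_a = encode(a)
    codes_b = encode(b)
    hp, bu, it = _tables(params, max(len(a), len(b)))
    total = DUPLEX_INIT
    runs: list[tuple[int, int]] = []
    k = 0
    while k < m:
        if paired[k]:
            start = k
            while k < m and paired[k]:
                k += 1
            runs.append((start, k - 1))
        else:
            k += 1
    for (s, e) in runs:
        for k in range(s, e):
            p1 = _PT[codes_a[k], codes_b[len(b) - 1 - k]]
            p2 = _PT[codes_a[k + 1], codes_b[len(b) - 2 - k]]
            total += _STACK[p1, p2]
        total += _end_penalty(_PT[codes_a[s], codes_b[len(b) - 1 - s]])
        total += _end_penalty(_PT[codes_a[e], codes_b[len(b) - 1 - e]])
    for (prev, nxt) in zip(runs, runs[1:]):
        gap = nxt[0] - prev[1] - 1
        total += float(it[min(2 * gap, len(it) - 1)])
    return float(total)


def clear_caches() -> None:
    """Drop memoized fold/partition-function results (mainly for tests)."""
    _fold_cache.clear()
    _pf_cache.clear()
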