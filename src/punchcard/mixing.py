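"""Codecs for pooling several nick patterns on copies of the SAME register.

Fragments from identical register copies cannot be demultiplexed by
alignment, so information must survive the *adder channel*: the decoder
only observes, per site, how many mixture members were nicked there.  Two
schemes are provided:

* **Detecting-matrix (Lindström-style) coding** — choose N binary row
  vectors of length M whose 2^N subset sums are all distinct; an N-bit
  selector is written by pooling the selected rows' patterns and read back
  by inverting the per-site count vector.  Asymptotically M can be as small
  as 2N/log2(N); this module ships a deterministic backtracking search for
  the smallest M it can verify (node-budgeted), with the always-valid
  identity matrix (M = N) as fallback.  Every constructed matrix is
  verified exhaustively before use.

* **k-of-N group testing** — the message selects which k of N agreed-upon
  patterns are pooled, carrying floor(log2 C(N, k)) ~ k*log2(N) bits;
  encoded by the combinatorial number system.

`estimate_counts` bridges the sequencing decoder to both schemes: at known
equimolar mixing and per-fragment coverage c, each member nicked at a site
contributes two flanking-fragment boundaries, i.e. 2c boundary counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqcore import ANTISENSE, SENSE

VERIFY_BUDGET_N = 20
_SEARCH_NODE_BUDGET = 5_000_000


class BudgetError(RuntimeError):
    pass


class InconsistentSumError(RuntimeError):
    """The observed count vector is not an achievable subset sum."""


@dataclass(frozen=True)
class DetectingMatrix:
    """N binary row vectors of length M with injective subset sums."""

    rows: tuple  # tuple of tuples of 0/1

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def M(self) -> int:
        return len(self.rows[0])


def verify_detecting(rows) -> bool:
    """Exhaustively check that all 2^N subset sums are distinct (N <= 20)."""
    rows = [tuple(r) for r in rows]
    N = len(rows)
    if N > VERIFY_BUDGET_N:
        raise BudgetError(f"N={N} exceeds the 2^{VERIFY_BUDGET_N} enumeration budget")
    sums = {tuple([0] * len(rows[0]))}
    for r in rows:
        new = {tuple(s + x for s, x in zip(t, r)) for t in sums}
        if new & sums:
            return False
        sums |= new
    return len(sums) == 2**N


def _search_rows(N: int, M: int, budget: int) -> tuple | None:
    """Deterministic lexicographic DFS for N detecting rows of length M.

    Sum vectors are packed into single integers, 5 bits per column (column
    counts never exceed N <= 16 < 32, so digit arithmetic never carries);
    the budget counts packed-sum additions, keeping the per-M search cost
    flat regardless of recursion depth.
    """
    def pack(bits) -> int:
        v = 0
        for b in bits:
            v = (v << 5) | b
        return v

    all_rows = [tuple((v >> (M - 1 - j)) & 1 for j in range(M)) for v in range(1, 2**M)]
    packed = [pack(r) for r in all_rows]
    work = 0
    chosen: list = []
    sums_stack = [frozenset({0})]

    def rec(start: int) -> bool:
        nonlocal work
        if len(chosen) == N:
            return True
        sums = sums_stack[-1]
        for idx in range(start, len(all_rows) - (N - len(chosen)) + 1):
            work += len(sums)
            if work > budget:
                return False
            rp = packed[idx]
            new = {s + rp for s in sums}
            if not new.isdisjoint(sums):
                continue
            chosen.append(all_rows[idx])
            sums_stack.append(sums | new)
            if rec(idx + 1):
                return True
            chosen.pop()
            sums_stack.pop()
            if work > budget:
                return False
        return False

    return tuple(chosen) if rec(0) else None


_matrix_cache: dict = {}
_DIRECT_SEARCH_MAX_N = 9  # exhaustive DFS above this is not worth the budget


def _direct_sum(a: DetectingMatrix, b: DetectingMatrix) -> DetectingMatrix:
    """Block-diagonal composition; preserves the detecting property."""
    rows = [r + (0,) * b.M for r in a.rows]
    rows += [(0,) * a.M + r for r in b.rows]
    return DetectingMatrix(tuple(rows))


def build_detecting_matrix(N: int, compact: bool = True) -> DetectingMatrix:
    """Construct a verified detecting matrix for N mixture members.

    With ``compact`` the construction recurses: the best of (i) an
    exhaustive smallest-M row search (budgeted, N <= 9) and (ii) the
    shortest block-diagonal composition of two smaller detecting matrices;
    subset sums of a block-diagonal stack separate by coordinate block, so
    the composition is detecting whenever its parts are.  This achieves
    M < N for every N >= 4.  The identity matrix (M = N) is the always-valid
    fallback.  Deterministic in N; results are verified and cached.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if (N, compact) in _matrix_cache:
        return _matrix_cache[N, compact]
    identity = tuple(tuple(int(i == j) for j in range(N)) for i in range(N))
    out = DetectingMatrix(identity)
    if compact and N <= 16:
        for a in range(1, N // 2 + 1):
            combo = _direct_sum(
                build_detecting_matrix(N - a), build_detecting_matrix(a)
            )
            if combo.M < out.M:
                out = combo
        if N <= _DIRECT_SEARCH_MAX_N:
            m_lo = max(1, math.ceil(N / math.log2(N + 1)))
            for M in range(m_lo, out.M):
                rows = _search_rows(N, M, _SEARCH_NODE_BUDGET)
                if rows is not None:
                    out = DetectingMatrix(rows)
                    break
    if N <= VERIFY_BUDGET_N:
        assert verify_detecting(out.rows)
    _matrix_cache[N, compact] = out
    return out


def mix_encode(selector, D: DetectingMatrix) -> tuple:
    """Per-site nick counts of the pooled selection: s = sum_i x_i * row_i."""
    if len(selector) != D.N or not set(selector) <= {0, 1}:
        raise ValueError("selector must be an N-bit 0/1 vector")
    s = [0] * D.M
    for x, row in zip(selector, D.rows):
        if x:
            s = [a + b for a, b in zip(s, row)]
    return tuple(s)


def mix_decode(counts, D: DetectingMatrix) -> tuple:
    """Invert a count vector to the unique selector (DFS with pruning)."""
    counts = tuple(counts)
    if len(counts) != D.M:
        raise ValueError("count vector length must equal M")

    def rec(i: int, residual):
        if i == D.N:
            return () if not any(residual) else None
        # suffix feasibility: remaining rows must be able to cover the residual
        without = rec_try(i, residual, 0)
        if without is not None:
            return without
        return rec_try(i, residual, 1)

    def rec_try(i, residual, take):
        if take:
            nxt = tuple(r - x for r, x in zip(residual, D.rows[i]))
            if any(v < 0 for v in nxt):
                return None
        else:
            nxt = residual
        sub = rec(i + 1, nxt)
        return None if sub is None else (take,) + sub

    out = rec(0, counts)
    if out is None:
        raise InconsistentSumError(f"count vector {counts} is not an achievable sum")
    return out


# ---------------------------------------------------------------------------
# k-of-N group testing (combinatorial number system)
# ---------------------------------------------------------------------------

def gt_capacity_bits(k: int, N: int) -> int:
    return int(math.comb(N, k)).bit_length() - 1


def gt_encode(message: int, k: int, N: int) -> tuple:
    """Unrank *message* into the message-th k-subset of {0..N-1} (colex order)."""
    if not 0 <= message < math.comb(N, k):
        raise ValueError(f"message {message} out of range for C({N},{k})")
    chosen = []
    m = message
    for i in range(k, 0, -1):
        c = i - 1
        while math.comb(c + 1, i) <= m:
            c += 1
        chosen.append(c)
        m -= math.comb(c, i)
    return tuple(sorted(chosen))


def gt_decode(subset, k: int, N: int) -> int:
    subset = sorted(subset)
    if len(subset) != k or len(set(subset)) != k:
        raise ValueError("subset must contain k distinct indices")
    if subset and not 0 <= subset[-1] < N:
        raise ValueError("subset index out of range")
    return sum(math.comb(c, i + 1) for i, c in enumerate(subset))


# ---------------------------------------------------------------------------
# Bridging decoder evidence to counts
# ---------------------------------------------------------------------------

def estimate_counts(
    table, register, mixture_size: int, coverage_per_member: int
) -> tuple:
    """Per-site nick multiplicities from boundary evidence.

    Each member nicked at a site contributes boundaries from its two
    flanking fragments, each sequenced ``coverage_per_member`` times, so the
    estimate is round(boundaries / (2 * coverage)), clamped to
    [0, mixture_size].  Assumes equimolar mixing.
    """
    if coverage_per_member < 1:
        raise ValueError("coverage_per_member must be >= 1")
    counts = []
    for site in register.sites:
        ev = table.sites[register.id][site.ordinal]
        total = ev[SENSE] + ev[ANTISENSE]
        est = int(round(total / (2.0 * coverage_per_member)))
        counts.append(max(0, min(mixture_size, est)))
    return tuple(counts)


# --- matrix file format (TSV of 0/1 rows) -----------------------------------

def save_matrix(D: DetectingMatrix, path) -> None:
    with open(path, "w") as fh:
        for row in D.rows:
            fh.write("\t".join(map(str, row)) + "\n")


def load_matrix(path) -> DetectingMatrix:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(tuple(int(x) for x in line.split()))
    D = DetectingMatrix(tuple(rows))
    if not verify_detecting(D.rows):
        raise ValueError(f"{path}: matrix is not detecting")
    return D
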