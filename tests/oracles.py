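"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
glocal profile-HMM scores come from explicit enumeration of every legal state
path, and global alignment scores from a freshly written Gotoh recursion plus
(for tiny inputs) exhaustive enumeration of monotone alignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from acdscan.core_io import AMINO_ACIDS


def _lg(x: float) -> float:
    return -math.inf if x == 0 else math.log2(x)


def enumerate_glocal(p, s: str) -> tuple[float, float]:
    """(Viterbi, forward) bit scores by enumerating all glocal paths.

    A path chooses match-or-delete for every profile column (at least one
    match), insert-run lengths between consecutive matched columns, and the
    placement of the consumed subsequence.  Only feasible for tiny instances.
    """
    M = p.M
    aa = {a: i for i, a in enumerate(AMINO_ACIDS)}
    bg = p.background

    def esc(j: int, a: str) -> float:
        return _lg(p.match_emit[j, aa[a]]) - _lg(bg[aa[a]])

    def isc(j: int, a: str) -> float:
        return _lg(p.insert_emit[j + 1, aa[a]]) - _lg(bg[aa[a]])

    scores: list[float] = []
    for states in itertools.product("MD", repeat=M):
        n_match = states.count("M")
        if n_match == 0:
            continue
        for ins in itertools.product(range(len(s) + 1), repeat=max(M - 1, 0)):
            # insert states sit between two *matched* columns (no I<->D moves)
            if any(
                k > 0 and not (states[j] == "M" and states[j + 1] == "M")
                for j, k in enumerate(ins)
            ):
                continue
            consumed = n_match + sum(ins)
            if consumed > len(s):
                continue
            for a0 in range(len(s) - consumed + 1):
                sub = s[a0:a0 + consumed]
                sc = _lg(p.entry_m) if states[0] == "M" else _lg(p.entry_d)
                pos = 0
                for j, st in enumerate(states):
                    if j > 0:
                        k = ins[j - 1]
                        if k > 0:
                            sc += (_lg(p.t_mi[j - 1])
                                   + (k - 1) * _lg(p.t_ii[j - 1])
                                   + _lg(p.t_im[j - 1]))
                            for _ in range(k):
                                sc += isc(j - 1, sub[pos])
                                pos += 1
                        else:
                            pair = states[j - 1] + st
                            t = {"MM": p.t_mm, "MD": p.t_md,
                                 "DM": p.t_dm, "DD": p.t_dd}[pair]
                            sc += _lg(t[j - 1])
                    if st == "M":
                        sc += esc(j, sub[pos])
                        pos += 1
                scores.append(sc)
    arr = np.asarray(scores)
    return float(arr.max()), float(np.logaddexp2.reduce(arr))


def random_tiny_profile(rng: np.random.Generator, max_m: int = 3):
    """A random small ProfileHMM over the uniform background."""
    from acdscan.profile_hmm import ProfileHMM

    M = int(rng.integers(1, max_m + 1))
    n = M - 1
    tm = rng.dirichlet(np.ones(3), size=n) if n else np.zeros((0, 3))
    ti = rng.dirichlet(np.ones(2), size=n) if n else np.zeros((0, 2))
    td = rng.dirichlet(np.ones(2), size=n) if n else np.zeros((0, 2))
    em = rng.dirichlet(np.ones(2))
    return ProfileHMM(
        match_emit=rng.dirichlet(np.ones(20) * 0.5, size=M),
        insert_emit=rng.dirichlet(np.ones(20) * 2.0, size=M + 1),
        t_mm=tm[:, 0], t_mi=tm[:, 1], t_md=tm[:, 2],
        t_im=ti[:, 0], t_ii=ti[:, 1], t_dm=td[:, 0], t_dd=td[:, 1],
        entry_m=float(em[0]), entry_d=float(em[1]),
        background=np.full(20, 0.05),
    )


# ---------------------------------------------------------------------------
# global alignment oracles


def gotoh_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Affine-gap global alignment score; gap of length k costs
    ``gap_open + (k - 1) * gap_extend``."""
    inf = float("inf")
    la, lb = len(a), len(b)
    Mm = [[-inf] * (lb + 1) for _ in range(la + 1)]
    Ix = [[-inf] * (lb + 1) for _ in range(la + 1)]  # gap in b (consumes a)
    Iy = [[-inf] * (lb + 1) for _ in range(la + 1)]  # gap in a (consumes b)
    Mm[0][0] = 0.0
    for i in range(1, la + 1):
        Ix[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Iy[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = sub[a[i - 1], b[j - 1]]
            Mm[i][j] = max(Mm[i-1][j-1], Ix[i-1][j-1], Iy[i-1][j-1]) + s
            Ix[i][j] = max(Mm[i-1][j] - gap_open, Ix[i-1][j] - gap_extend,
                           Iy[i-1][j] - gap_open)
            Iy[i][j] = max(Mm[i][j-1] - gap_open, Iy[i][j-1] - gap_extend,
                           Ix[i][j-1] - gap_open)
    return max(Mm[la][lb], Ix[la][lb], Iy[la][lb])


def enumerate_global(a: str, b: str, sub, gap_open: float,
                     gap_extend: float) -> float:
    """Best global-alignment score by enumerating every monotone alignment."""
    best = [-float("inf")]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "")
    return best[0]
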