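"""Profile hidden Markov model: construction, scoring, calibration, scanning.

The model follows the classic match/insert/delete profile architecture with
the seven transition types M->M, M->I, M->D, I->M, I->I, D->M, D->D (no I<->D
exchange).  Alignment mode is *glocal*: every profile column must be accounted
for (matched or deleted) while the model aligns to one contiguous subsequence
of the target, so partial domains never qualify.  Scores are log2-odds ("bits")
against an i.i.d. background model; flanking residues outside the aligned
envelope are scored as background and therefore contribute nothing.

Statistical significance uses the extreme-value (Gumbel) model: the profile is
calibrated by scoring random background sequences, fitting location mu and
scale lambda, and converting bit scores to E-values with

    E = db_size * (1 - exp(-exp(-lambda * (score - mu))))
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    ALPHABET,
    AMINO_ACIDS,
    GAP,
    Alignment,
    SeedAnnotation,
    SequenceRecord,
)

NEG_INF = -np.inf
_EULER_GAMMA = 0.5772156649015329

#: index of the unknown residue X in encoded sequences
_X_INDEX = 20
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_INDEX["X"] = _X_INDEX


def encode(residues: str) -> np.ndarray:
    """Encode residues as integers 0..19 (canonical order) with X -> 20."""
    try:
        return np.fromiter((_AA_INDEX[a] for a in residues), dtype=np.int64,
                           count=len(residues))
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None


def swissprot_background() -> np.ndarray:
    """Swiss-Prot-like amino-acid background frequencies (canonical order)."""
    from .data import load_background

    return load_background()


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class GumbelFit:
    """Extreme-value calibration of a profile: score ~ Gumbel(mu, 1/lambda)."""

    mu: float
    lam: float
    n_samples: int
    sample_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if self.n_samples < 100:
            raise ValueError(f"need >= 100 calibration samples, got {self.n_samples}")


@dataclass
class AlignmentPath:
    """Viterbi path of one glocal alignment.

    ``column_map[j]`` is the 1-based target position matched by profile column
    ``j+1``, or ``None`` if the column was deleted.  ``insert_counts[j]`` is
    the number of inserted target residues between columns ``j+1`` and ``j+2``.
    """

    column_map: tuple[Optional[int], ...]
    insert_counts: tuple[int, ...]

    @property
    def start(self) -> int:
        return min(p for p in self.column_map if p is not None)

    @property
    def end(self) -> int:
        return max(p for p in self.column_map if p is not None)


@dataclass
class DomainHit:
    """One detected ACD: envelope coordinates, score, E-value and path."""

    accession: str
    acd_start: int
    acd_end: int
    bit_score: float
    e_value: float
    column_map: tuple[Optional[int], ...]
    insert_counts: tuple[int, ...]
    multi_acd: bool = False

    def __post_init__(self) -> None:
        matched = [p for p in self.column_map if p is not None]
        if not matched:
            raise ValueError(f"{self.accession}: hit with no matched column")
        if any(b <= a for a, b in zip(matched, matched[1:])):
            raise ValueError(f"{self.accession}: column map not strictly increasing")
        if not self.acd_start <= self.acd_end:
            raise ValueError(f"{self.accession}: empty envelope")
        span = self.acd_end - self.acd_start + 1
        if span != len(matched) + sum(self.insert_counts):
            raise ValueError(
                f"{self.accession}: envelope length {span} != matches "
                f"{len(matched)} + inserts {sum(self.insert_counts)}"
            )

    @property
    def acd_length(self) -> int:
        return self.acd_end - self.acd_start + 1


@dataclass
class ProfileHMM:
    """A calibrated profile HMM over the 20-letter amino-acid alphabet.

    Transition arrays are indexed by source column ``j`` (0-based, length
    M-1): ``t_mm[j]`` is M_j -> M_{j+1}, ``t_im[j]`` is I_j -> M_{j+1} for the
    insert state between columns j and j+1, and so on.  ``entry_m``/``entry_d``
    are the begin-state probabilities into M_1/D_1; the final match and delete
    states exit with probability 1.
    """

    match_emit: np.ndarray          # (M, 20)
    insert_emit: np.ndarray         # (M + 1, 20); interior rows used
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    entry_m: float
    entry_d: float
    background: np.ndarray          # (20,)
    landmark_of_column: dict[int, str] = field(default_factory=dict)
    calibration: Optional[GumbelFit] = None

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()
        self._prepare_scores()

    # -- structure -----------------------------------------------------
    @property
    def M(self) -> int:
        return self.match_emit.shape[0]

    def validate(self) -> None:
        M = self.M
        if M < 1:
            raise ValueError("profile needs at least one match state")
        if self.match_emit.shape != (M, 20):
            raise ValueError("match_emit must be (M, 20)")
        if not np.allclose(self.match_emit.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.allclose(self.insert_emit.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("insert emission rows must sum to 1")
        if not math.isclose(self.entry_m + self.entry_d, 1.0, abs_tol=1e-9):
            raise ValueError("entry probabilities must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        n = M - 1
        for arrs, label in (
            ((self.t_mm, self.t_mi, self.t_md), "match"),
            ((self.t_im, self.t_ii), "insert"),
            ((self.t_dm, self.t_dd), "delete"),
        ):
            for a in arrs:
                if a.shape != (n,):
                    raise ValueError(f"{label} transition arrays must have length M-1")
            if n and not np.allclose(sum(arrs), 1.0, atol=1e-9):
                raise ValueError(f"{label}-state transition groups must sum to 1")
        if self.landmark_of_column and sorted(self.landmark_of_column) != list(
            range(1, M + 1)
        ):
            raise ValueError("landmark map must cover profile columns 1..M")

    def _prepare_scores(self) -> None:
        """Precompute log2-odds tables used by the scoring recurrences."""
        with np.errstate(divide="ignore"):
            lg = np.log2
            bg = self.background
            esc = lg(self.match_emit) - lg(bg)[None, :]
            self._esc = np.concatenate([esc, np.zeros((self.M, 1))], axis=1)
            if self.M > 1:
                ins = self.insert_emit[1:self.M]  # I_1..I_{M-1} interior states
                isc = lg(ins) - lg(bg)[None, :]
                self._isc = np.concatenate([isc, np.zeros((self.M - 1, 1))], axis=1)
            else:
                self._isc = np.zeros((0, 21))
            self._l_mm = lg(self.t_mm)
            self._l_mi = lg(self.t_mi)
            self._l_md = lg(self.t_md)
            self._l_im = lg(self.t_im)
            self._l_ii = lg(self.t_ii)
            self._l_dm = lg(self.t_dm)
            self._l_dd = lg(self.t_dd)
            # entry_head[j]: begin -> (delete columns 1..j) -> match column j+1
            cdd = np.concatenate([[0.0], np.cumsum(self._l_dd)])
            head = np.full(self.M, NEG_INF)
            head[0] = lg(self.entry_m)
            if self.M > 1:
                head[1:] = lg(self.entry_d) + cdd[:-1] + self._l_dm
            self._entry_head = head
            # del_tail[j]: match column j+1 -> delete columns j+2..M -> exit
            tail = np.zeros(self.M)
            if self.M > 1:
                rev = np.concatenate([[0.0], np.cumsum(self._l_dd[::-1])])[::-1]
                tail[:-1] = self._l_md + rev[1:]
            self._del_tail = tail
            self._cdd = cdd

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.match_emit, axis=1))

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.match_emit, self.t_mm, self.t_mi, self.t_md,
                    self.t_im, self.t_ii, self.t_dm, self.t_dd):
            h.update(np.round(arr, 12).tobytes())
        return h.hexdigest()[:16]

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        """Write the profile as a versioned JSON text file (log2-odds emissions)."""
        with np.errstate(divide="ignore"):
            lg_bg = np.log2(self.background)
            doc = {
                "format": "acdscan-profile",
                "version": 1,
                "M": self.M,
                "background": self.background.tolist(),
                "match_log2odds": (np.log2(np.maximum(self.match_emit, 1e-300))
                                   - lg_bg).tolist(),
                "insert_log2odds": (np.log2(np.maximum(self.insert_emit, 1e-300))
                                    - lg_bg).tolist(),
                "transitions": {
                    name: getattr(self, name).tolist()
                    for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii",
                                 "t_dm", "t_dd")
                },
                "entry_m": self.entry_m,
                "entry_d": self.entry_d,
                "landmarks": {str(k): v for k, v in self.landmark_of_column.items()},
                "calibration": None if self.calibration is None else vars(self.calibration),
            }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "acdscan-profile" or doc.get("version") != 1:
            raise ValueError(f"{path}: not a version-1 acdscan profile file")
        bg = np.asarray(doc["background"], dtype=float)

        def probs(log2odds):
            p = bg[None, :] * np.exp2(np.asarray(log2odds, dtype=float))
            return p / p.sum(axis=1, keepdims=True)

        cal = doc.get("calibration")
        return cls(
            match_emit=probs(doc["match_log2odds"]),
            insert_emit=probs(doc["insert_log2odds"]),
            entry_m=doc["entry_m"],
            entry_d=doc["entry_d"],
            background=bg,
            landmark_of_column={int(k): v for k, v in doc["landmarks"].items()},
            calibration=None if cal is None else GumbelFit(**cal),
            **{k: np.asarray(v, dtype=float) for k, v in doc["transitions"].items()},
        )


# ---------------------------------------------------------------------------
# profile construction


def determine_match_columns(aln: Alignment, gap_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask over alignment columns: match iff gap fraction < threshold."""
    if not 0 < gap_threshold <= 1:
        raise ValueError("gap_threshold must be in (0, 1]")
    n = aln.n_rows
    mask = np.empty(aln.n_columns, dtype=bool)
    for c in range(1, aln.n_columns + 1):
        gaps = aln.column(c).count(GAP)
        mask[c - 1] = gaps / n < gap_threshold
    if not mask.any():
        raise ValueError("no column passes the match-column gap threshold")
    return mask


def henikoff_weights(aln: Alignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff), normalized to mean 1."""
    n = aln.n_rows
    w = np.zeros(n)
    for c in range(1, aln.n_columns + 1):
        col = aln.column(c).upper()
        symbols = [s for s in col if s != GAP]
        if not symbols:
            continue
        r = len(set(symbols))
        for i, s in enumerate(col):
            if s != GAP:
                w[i] += 1.0 / (r * col.count(s))
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


#: Dirichlet-style transition pseudocounts.  The default favors match
#: continuation and quick returns from insert/delete states, so a state that
#: was never observed in the training alignment still prices a gap-extension
#: step at roughly 2 bits instead of the 1 bit a flat +1 prior would give;
#: long unsupported delete/insert excursions at the domain edges would
#: otherwise be nearly free and wash out the envelope boundaries.
TRANSITION_PRIOR = {
    "mm": 2.0, "mi": 0.5, "md": 0.5,
    "im": 1.6, "ii": 0.4,
    "dm": 1.6, "dd": 0.4,
    "bm": 1.8, "bd": 0.2,
}
FLAT_TRANSITION_PRIOR = {k: 1.0 for k in TRANSITION_PRIOR}


def build_profile(
    aln: Alignment,
    ann: SeedAnnotation,
    pseudocount_weight: float = 20.0,
    gap_threshold: float = 0.5,
    background: np.ndarray | None = None,
    weighting: str = "none",
    transition_prior: dict[str, float] | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an annotated alignment.

    Emission probabilities are background-proportional pseudocount mixtures,
    ``(counts + w * bg) / (n + w)`` with total pseudocount weight ``w`` per
    column; transition groups are smoothed with :data:`TRANSITION_PRIOR`
    pseudocounts.  Every match column (gap fraction below ``gap_threshold``)
    must carry a structural landmark label from ``ann``.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    prior = TRANSITION_PRIOR if transition_prior is None else transition_prior
    bg = swissprot_background() if background is None else np.asarray(background, float)
    mask = determine_match_columns(aln, gap_threshold)
    match_cols = [c + 1 for c in range(aln.n_columns) if mask[c]]  # 1-based
    missing = [c for c in match_cols if c not in ann.element_of_column]
    if missing:
        raise ValueError(f"match columns without landmark label: {missing}")
    M = len(match_cols)

    if weighting == "henikoff":
        weights = henikoff_weights(aln)
    elif weighting == "none":
        weights = np.ones(aln.n_rows)
    else:
        raise ValueError(f"unknown weighting scheme {weighting!r}")

    counts = np.zeros((M, 20))
    n_tr = M - 1
    c_mm = np.zeros(n_tr); c_mi = np.zeros(n_tr); c_md = np.zeros(n_tr)
    c_im = np.zeros(n_tr); c_ii = np.zeros(n_tr)
    c_dm = np.zeros(n_tr); c_dd = np.zeros(n_tr)
    c_bm = 0.0
    c_bd = 0.0

    col_is_match = {c: j for j, c in enumerate(match_cols)}
    for (acc, row), w in zip(aln.rows, weights):
        row = row.upper()
        # emissions
        for c, j in col_is_match.items():
            a = row[c - 1]
            if a not in (GAP, "X"):
                counts[j, _AA_INDEX[a]] += w
        # transition path: state at each match column, inserts in between
        states = []  # (j, 'M' or 'D')
        for c, j in sorted(col_is_match.items()):
            states.append((j, "M" if row[c - 1] != GAP else "D"))
        inserts = np.zeros(M, dtype=int)  # residues after match column j
        j_before = -1
        for c in range(1, aln.n_columns + 1):
            if mask[c - 1]:
                j_before = col_is_match[c]
            elif row[c - 1] != GAP and j_before >= 0:
                inserts[j_before] += 1
        if states[0][1] == "M":
            c_bm += w
        else:
            c_bd += w
        for (j, s), (_, s2) in zip(states, states[1:]):
            k = inserts[j]
            if s == "M":
                if k:
                    c_mi[j] += w
                    c_ii[j] += w * (k - 1)
                    c_im[j] += w  # I->D folded into I->M (no I->D transition)
                elif s2 == "M":
                    c_mm[j] += w
                else:
                    c_md[j] += w
            else:
                if k:  # D followed by inserts: fold into D->M path
                    c_dm[j] += w
                    c_ii[j] += w * (k - 1)
                    c_im[j] += w
                elif s2 == "M":
                    c_dm[j] += w
                else:
                    c_dd[j] += w

    match_emit = (counts + pseudocount_weight * bg[None, :]) / (
        counts.sum(axis=1, keepdims=True) + pseudocount_weight
    )
    insert_emit = np.tile(bg, (M + 1, 1))

    def norm(*groups):
        tot = sum(g + prior[k] for k, g in groups)
        return [(g + prior[k]) / tot for k, g in groups]

    t_mm, t_mi, t_md = norm(("mm", c_mm), ("mi", c_mi), ("md", c_md))
    t_im, t_ii = norm(("im", c_im), ("ii", c_ii))
    t_dm, t_dd = norm(("dm", c_dm), ("dd", c_dd))
    entry_m, entry_d = norm(("bm", np.array(c_bm)), ("bd", np.array(c_bd)))

    landmarks = {j + 1: ann.element_of_column[c] for c, j in col_is_match.items()}
    return ProfileHMM(
        match_emit=match_emit, insert_emit=insert_emit,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
        entry_m=float(entry_m), entry_d=float(entry_d),
        background=bg, landmark_of_column=landmarks,
    )


# ---------------------------------------------------------------------------
# scoring


def _viterbi_matrices(p: ProfileHMM, seq: np.ndarray):
    """Run the glocal Viterbi recurrence; returns (VM, VI, VD) of shape (L, M)."""
    M, L = p.M, len(seq)
    esc = p._esc
    VM = np.full((L, M), NEG_INF)
    VI = np.full((L, max(M - 1, 0)), NEG_INF)
    VD = np.full((L, M), NEG_INF)
    prev_m = np.full(M, NEG_INF)
    prev_i = np.full(max(M - 1, 0), NEG_INF)
    prev_d = np.full(M, NEG_INF)
    for i in range(L):
        e = esc[:, seq[i]]
        best = p._entry_head.copy()
        if M > 1:
            np.maximum(best[1:], prev_m[:-1] + p._l_mm, out=best[1:])
            np.maximum(best[1:], prev_i + p._l_im, out=best[1:])
            np.maximum(best[1:], prev_d[:-1] + p._l_dm, out=best[1:])
        vm = e + best
        VM[i] = vm
        if M > 1:
            vi = p._isc[:, seq[i]] + np.maximum(
                prev_m[:-1] + p._l_mi, prev_i + p._l_ii
            )
            VI[i] = vi
            # delete chain within one target position, via prefix maximum
            g = vm[:-1] + p._l_md - p._cdd[1:]
            vd = np.full(M, NEG_INF)
            vd[1:] = p._cdd[1:] + np.maximum.accumulate(g)
            VD[i] = vd
            prev_i = vi
            prev_d = vd
        prev_m = vm
    return VM, VI, VD


def viterbi(p: ProfileHMM, s: str) -> tuple[float, AlignmentPath]:
    """Best glocal alignment of the whole profile to a subsequence of ``s``.

    Returns the bit score (log2 of best-path probability over the background
    probability of the aligned subsequence) and the traceback path.  Ties are
    broken preferring match over delete over insert predecessors.
    """
    score, path = _viterbi(p, s, traceback=True)
    assert path is not None
    return score, path


def viterbi_score(p: ProfileHMM, s: str) -> float:
    return _viterbi(p, s, traceback=False)[0]


def _viterbi(p: ProfileHMM, s: str, traceback: bool):
    if not s:
        raise ValueError("empty sequence")
    seq = encode(s)
    M, L = p.M, len(seq)
    VM, VI, VD = _viterbi_matrices(p, seq)
    totals = VM + p._del_tail[None, :]
    flat = int(np.argmax(totals))
    i, j = divmod(flat, M)
    score = float(totals[i, j])
    if not traceback:
        return score, None
    if score == NEG_INF:
        raise ValueError("no valid glocal alignment (degenerate profile)")

    column_map: list[Optional[int]] = [None] * M
    insert_counts = [0] * max(M - 1, 0)
    atol = 1e-9
    state = "M"
    while True:
        if state == "M":
            column_map[j] = i + 1
            val = VM[i, j] - p._esc[j, seq[i]]
            if j == 0:
                state = "B"
            else:
                cands = (
                    ("M", VM[i - 1, j - 1] + p._l_mm[j - 1] if i > 0 else NEG_INF),
                    ("D", VD[i - 1, j - 1] + p._l_dm[j - 1] if i > 0 else NEG_INF),
                    ("I", VI[i - 1, j - 1] + p._l_im[j - 1] if i > 0 else NEG_INF),
                    ("B", p._entry_head[j]),
                )
                state = _pick(val, cands, atol)
                if state in ("M", "I"):
                    i -= 1
                    j -= 1
                elif state == "D":
                    i -= 1
                    j -= 1
            if state == "B":
                break
        elif state == "D":
            val = VD[i, j]
            cands = (
                ("M", VM[i, j - 1] + p._l_md[j - 1]),
                ("D", VD[i, j - 1] + p._l_dd[j - 1]),
            )
            state = _pick(val, cands, atol)
            j -= 1
        else:  # insert state I_j between columns j+1 and j+2
            insert_counts[j] += 1
            val = VI[i, j] - p._isc[j, seq[i]]
            cands = (
                ("M", VM[i - 1, j] + p._l_mi[j] if i > 0 else NEG_INF),
                ("I", VI[i - 1, j] + p._l_ii[j] if i > 0 else NEG_INF),
            )
            state = _pick(val, cands, atol)
            i -= 1
    path = AlignmentPath(tuple(column_map), tuple(insert_counts))
    return score, path


def _pick(val: float, cands, atol: float) -> str:
    best_state, best_v = None, NEG_INF
    for state, v in cands:
        if v >= val - atol:
            return state
        if v > best_v:
            best_state, best_v = state, v
    return best_state  # numerical fallback


def forward(p: ProfileHMM, s: str) -> float:
    """Glocal forward bit score: log2 sum over all paths (>= Viterbi score)."""
    if not s:
        raise ValueError("empty sequence")
    seq = encode(s)
    M, L = p.M, len(seq)
    lse = np.logaddexp2
    prev_m = np.full(M, NEG_INF)
    prev_i = np.full(max(M - 1, 0), NEG_INF)
    prev_d = np.full(M, NEG_INF)
    total = NEG_INF
    for i in range(L):
        acc = p._entry_head.copy()
        if M > 1:
            acc[1:] = lse(acc[1:], prev_m[:-1] + p._l_mm)
            acc[1:] = lse(acc[1:], prev_i + p._l_im)
            acc[1:] = lse(acc[1:], prev_d[:-1] + p._l_dm)
        vm = p._esc[:, seq[i]] + acc
        if M > 1:
            vi = p._isc[:, seq[i]] + lse(prev_m[:-1] + p._l_mi, prev_i + p._l_ii)
            g = vm[:-1] + p._l_md - p._cdd[1:]
            vd = np.full(M, NEG_INF)
            vd[1:] = p._cdd[1:] + lse.accumulate(g)
            prev_i, prev_d = vi, vd
        prev_m = vm
        total = lse(total, lse.reduce(vm + p._del_tail))
    return float(total)


# ---------------------------------------------------------------------------
# calibration and E-values


def calibrate(
    p: ProfileHMM,
    n: int = 200,
    length: int = 150,
    seed: int = 0,
) -> GumbelFit:
    """Fit the Gumbel null model from Viterbi scores of random sequences.

    Sequences are drawn i.i.d. from the profile's background distribution.
    The fit is method-of-moments (lambda = pi / (sigma * sqrt(6)),
    mu = mean - gamma / lambda) refined by maximum likelihood.
    """
    if n < 100:
        raise ValueError(f"calibration needs n >= 100, got {n}")
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n, length), p=p.background)
    scores = np.empty(n)
    for k in range(n):
        s = "".join(AMINO_ACIDS[i] for i in draws[k])
        scores[k] = viterbi_score(p, s)
    return fit_gumbel(scores, sample_length=length, seed=seed)


def fit_gumbel(scores: np.ndarray, sample_length: int = 0, seed: int = 0) -> GumbelFit:
    """Moment fit + ML refinement of Gumbel(mu, 1/lambda) on a score sample."""
    scores = np.asarray(scores, dtype=float)
    sigma = scores.std(ddof=1)
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("degenerate score variance; cannot calibrate")
    lam0 = math.pi / (sigma * math.sqrt(6.0))
    mu0 = scores.mean() - _EULER_GAMMA / lam0
    loc, scale = stats.gumbel_r.fit(scores, loc=mu0, scale=1.0 / lam0)
    return GumbelFit(
        mu=float(loc), lam=float(1.0 / scale),
        n_samples=len(scores), sample_length=sample_length, seed=seed,
    )


def evalue(score: float, fit: GumbelFit, db_size: int) -> float:
    """Expected number of hits at or above ``score`` in ``db_size`` sequences."""
    x = -fit.lam * (score - fit.mu)
    # E = N * (1 - exp(-exp(x))); -expm1 is accurate for tiny tail probabilities
    return float(db_size * -math.expm1(-math.exp(min(x, 700.0))))


# ---------------------------------------------------------------------------
# databank scanning


def scan(
    p: ProfileHMM,
    db: Sequence[SequenceRecord],
    e_threshold: float,
    db_size: int | None = None,
) -> list[DomainHit]:
    """Scan a databank; one best complete-profile hit per sequence.

    Requires a calibrated profile.  The whole profile must align (glocal), so
    sequences carrying only a partial domain never qualify.  A sequence whose
    flanks harbor a second qualifying envelope is flagged ``multi_acd``.
    """
    if p.calibration is None:
        raise ValueError("profile is not calibrated; run calibrate() first")
    N = len(db) if db_size is None else db_size
    hits: list[DomainHit] = []
    for rec in db:
        score, path = viterbi(p, rec.residues)
        e = evalue(score, p.calibration, N)
        if e > e_threshold:
            continue
        start, end = path.start, path.end
        multi = False
        for flank in (rec.residues[: start - 1], rec.residues[end:]):
            if len(flank) >= p.M // 2:
                if evalue(viterbi_score(p, flank), p.calibration, N) <= e_threshold:
                    multi = True
                    break
        hits.append(
            DomainHit(
                accession=rec.accession, acd_start=start, acd_end=end,
                bit_score=score, e_value=e,
                column_map=path.column_map, insert_counts=path.insert_counts,
                multi_acd=multi,
            )
        )
    return hits


def hits_to_tsv(hits: Sequence[DomainHit], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "accession": h.accession, "acd_start": h.acd_start,
                "acd_end": h.acd_end, "bits": round(h.bit_score, 3),
                "evalue": f"{h.e_value:.3e}", "multi_acd": int(h.multi_acd),
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)
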