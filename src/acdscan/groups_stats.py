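"""Group assignment, pairwise-identity classification, logos and statistics.

Sequences are grouped by taxonomic lineage (animals, plants, fungi, archaea,
other eukaryotes); bacterial sequences are sub-classified as class A (bacA),
class B (bacB) or neither (bacOther) by best percent identity of a global
pairwise alignment against per-class reference sequences.

Sequence logos are gap-aware: a deletion at a profile column counts as an
explicit 21st symbol when computing column information content, but gaps are
not drawn, so letter heights are residue frequency (over all 21 symbols)
times the column information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import AMINO_ACIDS, SequenceRecord
from .profile_hmm import DomainHit, ProfileHMM

GROUP_LABELS = (
    "animals", "plants", "fungi", "archaea", "bacA", "bacB", "bacOther", "other",
)

#: sentinel returned for bacterial lineages pending A/B sub-classification
BACTERIA_PENDING = "bacteria-pending"

N_LOGO_SYMBOLS = 21  # 20 amino acids + gap
MAX_INFO_BITS = math.log2(N_LOGO_SYMBOLS)


def assign_taxonomic_group(rec: SequenceRecord) -> str:
    """Lineage-based group label; bacteria are returned as pending.

    Metazoa -> animals, Viridiplantae -> plants, Fungi -> fungi,
    Archaea -> archaea, Bacteria -> :data:`BACTERIA_PENDING`, any other
    Eukaryota (or an empty/unrecognized lineage) -> other.
    """
    taxa = set(rec.lineage)
    if "Metazoa" in taxa:
        return "animals"
    if "Viridiplantae" in taxa:
        return "plants"
    if "Fungi" in taxa:
        return "fungi"
    if "Archaea" in taxa:
        return "archaea"
    if "Bacteria" in taxa:
        return BACTERIA_PENDING
    return "other"


def _aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def needleman_wunsch(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[float, float]:
    """Affine-gap global alignment score and percent identity.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Identity is
    identical aligned pairs over the alignment length (gap columns included),
    as a percentage.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    aligner = _aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    identity = 100.0 * matches / len(s1)
    return float(aln.score), identity


def classify_bacterial(
    rec: SequenceRecord,
    refs_a: Sequence[str],
    refs_b: Sequence[str],
    min_identity: float = 40.0,
) -> str:
    """bacA / bacB / bacOther by best global-alignment percent identity.

    The record gets the label of the reference class with the higher best
    identity when that identity reaches ``min_identity``; ties and
    sub-threshold similarities give bacOther.
    """
    if not refs_a or not refs_b:
        raise ValueError("both reference sets must be non-empty")
    best_a = max(needleman_wunsch(rec.residues, r)[1] for r in refs_a)
    best_b = max(needleman_wunsch(rec.residues, r)[1] for r in refs_b)
    if best_a == best_b or max(best_a, best_b) < min_identity:
        return "bacOther"
    return "bacA" if best_a > best_b else "bacB"


def assign_group_label(
    rec: SequenceRecord,
    refs_a: Sequence[str] | None = None,
    refs_b: Sequence[str] | None = None,
    min_identity: float = 40.0,
) -> str:
    """Full group label, resolving bacterial sequences via the references.

    Without reference sets, bacterial records fall to bacOther.
    """
    label = assign_taxonomic_group(rec)
    if label != BACTERIA_PENDING:
        return label
    if refs_a is None or refs_b is None:
        return "bacOther"
    return classify_bacterial(rec, refs_a, refs_b, min_identity)


# ---------------------------------------------------------------------------
# gap-aware logos


@dataclass
class LogoMatrix:
    """Per-profile-column symbol counts and information content.

    ``counts`` is (M, 21): the 20 amino acids in canonical order plus the gap
    symbol (deletions).  ``info`` is the column information content in bits,
    ``log2(21) - H`` with H the Shannon entropy over 21-symbol frequencies.
    ``heights`` (M, 20) are the drawn letter heights, frequency * info, for
    the amino acids only.  Columns with zero observations are flagged.
    """

    counts: np.ndarray
    info: np.ndarray
    heights: np.ndarray
    empty_columns: tuple[int, ...] = ()  # 1-based, info undefined

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        symbols = list(AMINO_ACIDS) + ["-"]
        rows = []
        for j in range(self.n_columns):
            for k, sym in enumerate(symbols):
                if self.counts[j, k] == 0:
                    continue
                rows.append(
                    {
                        "column": j + 1,
                        "symbol": sym,
                        "count": self.counts[j, k],
                        "info_bits": self.info[j],
                        "height": self.heights[j, k] if k < 20 else 0.0,
                    }
                )
        return pd.DataFrame(rows)


def column_information(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Information content and letter heights from a (M, 21) count matrix."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    info = np.zeros(counts.shape[0])
    heights = np.zeros((counts.shape[0], 20))
    nonzero = totals[:, 0] > 0
    freq = np.zeros_like(counts)
    freq[nonzero] = counts[nonzero] / totals[nonzero]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    H = -plogp.sum(axis=1)
    info[nonzero] = MAX_INFO_BITS - H[nonzero]
    heights[nonzero] = freq[nonzero, :20] * info[nonzero, None]
    return info, heights


def logo_counts(
    hits: Sequence[DomainHit],
    records: Sequence[SequenceRecord],
    p: ProfileHMM,
) -> LogoMatrix:
    """Count residues matched to each profile column, deletions as gaps.

    Inserted residues match no profile position and are ignored.  Unknown
    residues (X) are also ignored.
    """
    by_acc = {r.accession: r for r in records}
    counts = np.zeros((p.M, N_LOGO_SYMBOLS))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for h in hits:
        rec = by_acc.get(h.accession)
        if rec is None:
            raise ValueError(f"hit references unknown accession {h.accession!r}")
        for j, t in enumerate(h.column_map):
            if t is None:
                counts[j, 20] += 1
            else:
                a = rec.residues[t - 1]
                if a != "X":
                    counts[j, aa_index[a]] += 1
    info, heights = column_information(counts)
    empty = tuple(int(j + 1) for j in np.where(counts.sum(axis=1) == 0)[0])
    return LogoMatrix(counts=counts, info=info, heights=heights, empty_columns=empty)


def plot_logo(logo: LogoMatrix, path: str, title: str = "") -> None:
    """Minimal stacked-letter logo rendering (matplotlib text glyphs)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, logo.n_columns / 6), 3))
    for j in range(logo.n_columns):
        order = np.argsort(logo.heights[j])
        y = 0.0
        for k in order:
            h = logo.heights[j, k]
            if h <= 0:
                continue
            ax.text(j + 1, y + h / 2, AMINO_ACIDS[k], ha="center", va="center",
                    fontsize=6 + 10 * h / MAX_INFO_BITS)
            y += h
    ax.set_xlim(0, logo.n_columns + 1)
    ax.set_ylim(0, MAX_INFO_BITS)
    ax.set_xlabel("profile column")
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# distributions and overlap


@dataclass
class LengthDistribution:
    """Integer histogram of region lengths with summary statistics."""

    table: pd.DataFrame  # columns: length, count
    mean: float
    sd: float
    n: int

    def fraction(self, lo: int, hi: int) -> float:
        """Fraction of values inside the inclusive interval [lo, hi]."""
        if self.n == 0:
            return float("nan")
        sel = self.table["length"].between(lo, hi)
        return float(self.table.loc[sel, "count"].sum() / self.n)

    @property
    def mode(self) -> Optional[int]:
        if self.table.empty:
            return None
        return int(self.table.loc[self.table["count"].idxmax(), "length"])


def length_distribution(values: Sequence[int]) -> LengthDistribution:
    """Histogram (bin width 1) of non-negative integer lengths."""
    values = list(values)
    if any(v < 0 for v in values):
        raise ValueError("lengths must be non-negative")
    if not values:
        return LengthDistribution(
            table=pd.DataFrame(columns=["length", "count"]),
            mean=float("nan"), sd=float("nan"), n=0,
        )
    arr = np.asarray(values)
    lengths, counts = np.unique(arr, return_counts=True)
    table = pd.DataFrame({"length": lengths, "count": counts})
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return LengthDistribution(table=table, mean=float(arr.mean()), sd=sd, n=len(arr))


def annotation_overlap(detected: set[str], labeled: set[str]) -> float:
    """Percentage of externally labeled accessions recovered by detection."""
    if not labeled:
        raise ValueError("the labeled reference set is empty")
    return 100.0 * len(labeled & detected) / len(labeled)
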