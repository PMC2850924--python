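"""Iterative profile enrichment (iHMMER-style loop) and dataset curation.

The loop alternates databank scanning and profile re-estimation while the
E-value acceptance threshold is relaxed one order of magnitude per iteration:

1. build the initial profile from the structural seed alignment;
2. scan the databank at the current threshold;
3. filter out envelopes longer than the maximum ACD length and extract them;
4. re-align the accepted ACDs on the profile columns;
5. re-estimate the profile from that alignment;
6. re-calibrate;
7. raise the threshold tenfold and return to step 2.

A final pass keeps sequences whose best envelope satisfies the final E-value
cut.  Curation then retains complete, well-evidenced, single-ACD proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import GAP, Alignment, SeedAnnotation, SequenceRecord
from .profile_hmm import (
    DomainHit,
    ProfileHMM,
    build_profile,
    calibrate,
    scan,
)

log = logging.getLogger(__name__)


@dataclass
class IterationConfig:
    """Thresholds and limits of the enrichment loop.

    E-value thresholds run from ``10**start_exponent`` to ``10**end_exponent``
    in unit exponent steps; the final selection pass uses
    ``10**final_e_exponent``.  ``max_acd_length`` is the envelope-length filter
    (no ACD longer than 100 residues by default).
    """

    start_exponent: int = -10
    end_exponent: int = -5
    final_e_exponent: int = -5
    max_acd_length: int = 100
    max_iterations: int = 10
    pseudocount_weight: float = 20.0
    gap_threshold: float = 0.5
    calibration_n: int = 200
    calibration_length: int = 150
    keep_inserts: bool = True

    def __post_init__(self) -> None:
        if self.start_exponent > self.end_exponent:
            raise ValueError("start_exponent must be <= end_exponent")
        if self.max_acd_length <= 0:
            raise ValueError("max_acd_length must be positive")

    def thresholds(self) -> list[float]:
        exps = range(self.start_exponent, self.end_exponent + 1)
        return [10.0 ** e for e in list(exps)[: self.max_iterations]]


@dataclass
class IterationTrace:
    """Per-iteration record: threshold, hit counts, profile checksum."""

    rows: list[dict] = field(default_factory=list)

    def add(self, iteration: int, threshold: float, n_hits: int,
            n_new_hits: int, checksum: str) -> None:
        if self.rows and threshold < self.rows[-1]["threshold"]:
            raise ValueError("iteration thresholds must be non-decreasing")
        self.rows.append(
            {
                "iteration": iteration,
                "threshold": threshold,
                "n_hits": n_hits,
                "n_new_hits": n_new_hits,
                "profile_checksum": checksum,
            }
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def filter_hits(hits: Sequence[DomainHit], max_len: int) -> list[DomainHit]:
    """Keep hits whose ACD envelope is at most ``max_len`` residues long."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    kept = [h for h in hits if h.acd_length <= max_len]
    if hits and not kept:
        log.warning("all %d hits exceeded the %d-residue ACD length filter",
                    len(hits), max_len)
    return kept


def hits_to_alignment(
    p: ProfileHMM,
    hits: Sequence[DomainHit],
    db: Sequence[SequenceRecord],
    keep_inserts: bool = True,
) -> tuple[Alignment, SeedAnnotation]:
    """Re-express hit envelopes as a multiple alignment on profile columns.

    Each row has one character per profile column (residue or ``-`` for a
    deletion); inserted residues go into dedicated insert columns between
    match columns, sized by the widest insert across rows (``keep_inserts``
    False discards them).  The returned annotation labels every column with
    its structural element, insert columns inheriting the label of the
    preceding profile column, so the alignment can seed :func:`build_profile`
    directly.
    """
    by_acc = {r.accession: r for r in db}
    M = p.M
    widths = np.zeros(max(M - 1, 0), dtype=int)
    if keep_inserts:
        for h in hits:
            widths = np.maximum(widths, np.asarray(h.insert_counts, dtype=int))
    rows = []
    for h in hits:
        rec = by_acc.get(h.accession)
        if rec is None:
            raise ValueError(f"hit references unknown accession {h.accession!r}")
        chars: list[str] = []
        pos = h.acd_start  # next unconsumed target position
        for j in range(M):
            t = h.column_map[j]
            if t is None:
                chars.append(GAP)
            else:
                chars.append(rec.residues[t - 1])
                pos = t + 1
            if j < M - 1 and widths[j]:
                k = h.insert_counts[j]
                ins = rec.residues[pos - 1: pos - 1 + k]
                pos += k
                chars.append(ins + GAP * (int(widths[j]) - k))
        rows.append((h.accession, "".join(chars).upper()))
    aln = Alignment(rows)
    labels: dict[int, str] = {}
    col = 1
    for j in range(M):
        labels[col] = p.landmark_of_column[j + 1]
        col += 1
        if j < M - 1 and widths[j]:
            for _ in range(int(widths[j])):
                labels[col] = p.landmark_of_column[j + 1]
                col += 1
    return aln, SeedAnnotation(labels)


def iterate(
    seed_aln: Alignment,
    ann: SeedAnnotation,
    db: Sequence[SequenceRecord],
    cfg: IterationConfig | None = None,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[ProfileHMM, list[DomainHit], IterationTrace]:
    """Run the full enrichment loop and final selection pass.

    Deterministic given ``seed``: each calibration uses a sub-seed derived
    from (master seed, iteration index).  Raises if the first iteration finds
    no hit.  Sequences accepted earlier are always re-evaluated against the
    current profile (no grandfathering).
    """
    cfg = cfg or IterationConfig()

    def sub_seed(i: int) -> int:
        return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))

    profile = build_profile(
        seed_aln, ann, pseudocount_weight=cfg.pseudocount_weight,
        gap_threshold=cfg.gap_threshold, background=background,
    )
    profile.calibration = calibrate(
        profile, n=cfg.calibration_n, length=cfg.calibration_length,
        seed=sub_seed(0),
    )
    trace = IterationTrace()
    prev_accs: set[str] = set()
    for it, thr in enumerate(cfg.thresholds(), start=1):
        hits = filter_hits(scan(profile, db, thr), cfg.max_acd_length)
        accs = {h.accession for h in hits}
        if it == 1 and not hits:
            raise RuntimeError(
                f"no hit at the initial threshold {thr:g}; the seed profile "
                "does not match the databank"
            )
        if not accs >= prev_accs:
            log.warning(
                "iteration %d lost %d previously accepted sequence(s) "
                "(profile drift)", it, len(prev_accs - accs),
            )
        trace.add(it, thr, len(hits), len(accs - prev_accs), profile.checksum())
        prev_accs = accs
        if len(hits) >= 2:
            aln2, ann2 = hits_to_alignment(profile, hits, db, cfg.keep_inserts)
            profile = build_profile(
                aln2, ann2, pseudocount_weight=cfg.pseudocount_weight,
                gap_threshold=cfg.gap_threshold, background=background,
            )
        else:
            log.warning("iteration %d: only %d hit(s); profile kept", it, len(hits))
        profile.calibration = calibrate(
            profile, n=cfg.calibration_n, length=cfg.calibration_length,
            seed=sub_seed(it),
        )
    final_hits = filter_hits(
        scan(profile, db, 10.0 ** cfg.final_e_exponent), cfg.max_acd_length
    )
    return profile, final_hits, trace


def curate(hits: Sequence[DomainHit], db: Sequence[SequenceRecord]) -> list[str]:
    """Accessions of complete, well-evidenced, single-ACD proteins.

    Keeps records that are not fragments, have protein-existence level <= 3,
    and carry exactly one qualifying ACD envelope.
    """
    by_acc = {r.accession: r for r in db}
    kept = []
    for h in hits:
        rec = by_acc.get(h.accession)
        if rec is None:
            continue
        if rec.is_fragment or rec.existence_level > 3 or h.multi_acd:
            continue
        kept.append(h.accession)
    return kept
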