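"""Synthetic sHSP-like databanks with planted domains and ground truth.

Positive records concatenate a random-background N-terminal region, an ACD
sampled from a profile HMM (optionally mutated), a C-terminal anchoring
module whose final three residues realize the aliphatic anchor motif, and a
background tail.  Decoys are pure background.  Region lengths follow
truncated normal distributions whose defaults mirror the statistics of real
sHSP monomers: N-terminal 53 +/- 35 residues, CAM 14 +/- 3 (minimum 3, the
motif itself).  Ground truth for every region boundary is emitted alongside,
so detection, delineation and architecture stages can be scored exactly.

The leftmost-motif convention of the architecture stage is kept sharp by
construction: interior CAM residues exclude I/V/L, so the planted motif is
always the leftmost occurrence in the C-terminal region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AMINO_ACIDS, SequenceRecord, write_fasta, write_metadata
from .core_io import Alignment, SeedAnnotation, ZONE_OF_ELEMENT, read_seed_alignment
from .profile_hmm import ProfileHMM, build_profile

_ALIPHATIC = ("I", "V", "L")

#: lineages used when drawing record metadata for each group
GROUP_LINEAGES = {
    "animals": ["Eukaryota", "Metazoa", "Chordata"],
    "plants": ["Eukaryota", "Viridiplantae", "Streptophyta"],
    "fungi": ["Eukaryota", "Fungi", "Ascomycota"],
    "other": ["Eukaryota", "Alveolata"],
    "bacteria": ["Bacteria", "Proteobacteria"],
    "archaea": ["Archaea", "Euryarchaeota"],
}


@dataclass
class SynthesisParams:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_positives: int = 50
    n_decoys: int = 50
    nterm_mean: float = 53.0
    nterm_sd: float = 35.0
    nterm_min: int = 0
    cam_mean: float = 14.0
    cam_sd: float = 3.0
    cam_min: int = 3
    tail_mean: float = 5.0
    tail_sd: float = 5.0
    tail_min: int = 0
    mutation_rate: float = 0.2
    extended_motif: bool = True
    #: distribution of the central X of the anchor motif (rest from background)
    motif_central: dict[str, float] = field(
        default_factory=lambda: {"P": 0.3, "E": 0.3}
    )
    #: distribution of the aliphatic flanks; isoleucine predominates at both
    #: extremities in real monomers
    motif_flank: dict[str, float] = field(
        default_factory=lambda: {"I": 0.7, "V": 0.25, "L": 0.05}
    )
    fragment_fraction: float = 0.0
    existence_levels: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.3, 3: 0.5}
    )
    group_mix: dict[str, float] = field(
        default_factory=lambda: {
            "animals": 0.15, "plants": 0.18, "bacteria": 0.58,
            "archaea": 0.04, "fungi": 0.03, "other": 0.02,
        }
    )
    decoy_length_mean: float = 160.0
    decoy_length_sd: float = 40.0
    decoy_length_min: int = 30
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_positives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        for p in (self.mutation_rate, self.fragment_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def load_seed() -> tuple[Alignment, SeedAnnotation]:
    """The packaged synthetic seed ACD alignment and its landmarks."""
    from .data import seed_alignment_path

    return read_seed_alignment(seed_alignment_path())


def generator_profile(background: np.ndarray | None = None) -> ProfileHMM:
    """Sharp profile used to *sample* family members.

    Built from the seed with pseudocount weight 1: real family members are
    draws from the family distribution itself, not from the deliberately
    smoothed estimate the scanner uses.
    """
    aln, ann = load_seed()
    return build_profile(aln, ann, pseudocount_weight=1.0, background=background)


def _truncated_normal_int(rng: np.random.Generator, mean: float, sd: float,
                          minimum: int) -> int:
    return max(minimum, int(round(rng.normal(mean, sd)))) if sd > 0 else max(
        minimum, int(round(mean))
    )


def _background_string(rng: np.random.Generator, bg: np.ndarray, n: int,
                       exclude: tuple[str, ...] = ()) -> str:
    if n <= 0:
        return ""
    if exclude:
        keep = [i for i, a in enumerate(AMINO_ACIDS) if a not in exclude]
        probs = bg[keep] / bg[keep].sum()
        draws = rng.choice(keep, size=n, p=probs)
    else:
        draws = rng.choice(20, size=n, p=bg)
    return "".join(AMINO_ACIDS[i] for i in draws)


def sample_acd(p: ProfileHMM, seed: int | np.random.Generator) -> tuple[str, dict[str, int]]:
    """Draw one ACD by a stochastic pass through the profile's states.

    Returns the emitted residues and the true per-zone lengths implied by the
    path (match and insert emissions count toward the zone of their profile
    column, insertions toward the preceding column's zone; deletions add 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues: list[str] = []
    zone_len = {"b2b5": 0, "l57": 0, "b7b9": 0}

    def zone(j: int) -> str:
        return ZONE_OF_ELEMENT[p.landmark_of_column[j + 1]]

    def emit(probs: np.ndarray) -> str:
        return AMINO_ACIDS[rng.choice(20, p=probs / probs.sum())]

    state = "M" if rng.random() < p.entry_m else "D"
    j = 0
    while True:
        if state == "M":
            residues.append(emit(p.match_emit[j]))
            zone_len[zone(j)] += 1
        if j == p.M - 1:
            break
        if state == "M":
            r = rng.random()
            if r < p.t_mm[j]:
                state = "M"
            elif r < p.t_mm[j] + p.t_mi[j]:
                # insert run between columns j+1 and j+2
                while True:
                    residues.append(emit(p.insert_emit[j + 1]))
                    zone_len[zone(j)] += 1
                    if rng.random() < p.t_im[j]:
                        break
                state = "M"  # I -> M only (no I -> D)
            else:
                state = "D"
        else:
            state = "M" if rng.random() < p.t_dm[j] else "D"
        j += 1
    return "".join(residues), zone_len


def _mutate(rng: np.random.Generator, residues: str, rate: float,
            bg: np.ndarray) -> str:
    if rate == 0:
        return residues
    out = list(residues)
    for i, a in enumerate(out):
        if rng.random() < rate:
            b = a
            while b == a:
                b = AMINO_ACIDS[rng.choice(20, p=bg)]
            out[i] = b
    return "".join(out)


def _draw_categorical(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist)
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _motif_central_residue(rng: np.random.Generator, params: SynthesisParams,
                           bg: np.ndarray) -> str:
    named = params.motif_central
    total_named = sum(named.values())
    if rng.random() < total_named:
        return str(_draw_categorical(rng, named))
    return _background_string(rng, bg, 1)


def generate_record(
    p: ProfileHMM,
    params: SynthesisParams,
    index: int,
    seed: int | np.random.Generator,
    positive: bool = True,
) -> tuple[SequenceRecord, dict]:
    """One synthetic record plus its ground-truth row."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg = p.background
    group = str(_draw_categorical(rng, params.group_mix))
    lineage = GROUP_LINEAGES[group]
    is_fragment = rng.random() < params.fragment_fraction
    existence = int(_draw_categorical(rng, params.existence_levels))
    prefix = "POS" if positive else "NEG"
    acc = f"{prefix}{index:05d}"

    if not positive:
        L = _truncated_normal_int(rng, params.decoy_length_mean,
                                  params.decoy_length_sd, params.decoy_length_min)
        rec = SequenceRecord(acc, _background_string(rng, bg, L),
                             description="synthetic decoy", lineage=lineage,
                             is_fragment=is_fragment, existence_level=existence)
        truth = {
            "accession": acc, "is_positive": 0, "acd_start": 0, "acd_end": 0,
            "b2b5_len": 0, "l57_len": 0, "b7b9_len": 0, "cam_len": 0,
            "tail_len": 0, "group": group,
        }
        return rec, truth

    nterm = _background_string(
        rng, bg, _truncated_normal_int(rng, params.nterm_mean, params.nterm_sd,
                                       params.nterm_min),
    )
    acd, zones = sample_acd(p, rng)
    acd = _mutate(rng, acd, params.mutation_rate, bg)
    cam_len = _truncated_normal_int(rng, params.cam_mean, params.cam_sd,
                                    params.cam_min)
    # interior excludes I/V/L so the planted motif is the leftmost occurrence
    interior = _background_string(rng, bg, cam_len - 3, exclude=_ALIPHATIC)
    flank_dist = dict(params.motif_flank)
    if not params.extended_motif:
        flank_dist.pop("L", None)
    motif = (
        str(_draw_categorical(rng, flank_dist))
        + _motif_central_residue(rng, params, bg)
        + str(_draw_categorical(rng, flank_dist))
    )
    tail = _background_string(
        rng, bg, _truncated_normal_int(rng, params.tail_mean, params.tail_sd,
                                       params.tail_min)
    )
    residues = nterm + acd + interior + motif + tail
    acd_start = len(nterm) + 1
    acd_end = len(nterm) + len(acd)
    rec = SequenceRecord(acc, residues, description="synthetic sHSP-like",
                         lineage=lineage, is_fragment=is_fragment,
                         existence_level=existence)
    truth = {
        "accession": acc, "is_positive": 1,
        "acd_start": acd_start, "acd_end": acd_end,
        "b2b5_len": zones["b2b5"], "l57_len": zones["l57"],
        "b7b9_len": zones["b7b9"], "cam_len": cam_len, "tail_len": len(tail),
        "group": group,
    }
    return rec, truth


def generate_dataset(
    p: ProfileHMM,
    params: SynthesisParams,
    out_dir: str | Path | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate the full shuffled databank and its ground-truth table.

    Deterministic given ``params.seed``.  With ``out_dir``, writes
    ``databank.fasta``, ``metadata.tsv`` and ``truth.tsv``.
    """
    if params.n_positives + params.n_decoys == 0:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(params.seed)
    records: list[SequenceRecord] = []
    truths: list[dict] = []
    for i in range(params.n_positives):
        rec, truth = generate_record(p, params, i + 1, rng, positive=True)
        records.append(rec)
        truths.append(truth)
    for i in range(params.n_decoys):
        rec, truth = generate_record(p, params, i + 1, rng, positive=False)
        records.append(rec)
        truths.append(truth)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truths = [truths[i] for i in order]
    truth_df = pd.DataFrame(truths)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "databank.fasta")
        write_metadata(records, out / "metadata.tsv")
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    return records, truth_df


def expected_acd_length(p: ProfileHMM) -> float:
    """Expected emitted length of :func:`sample_acd`, from the Markov chain.

    Backward recursion over the feed-forward state graph; the insert state
    contributes a geometric run of mean 1 / (1 - t_ii).
    """
    M = p.M
    e_m = np.zeros(M + 1)  # expected residues emitted from M_j onward (1-based)
    e_d = np.zeros(M + 1)
    for j in range(M, 0, -1):
        if j == M:
            e_m[j] = 1.0
            e_d[j] = 0.0
            continue
        t_mm, t_mi, t_md = p.t_mm[j - 1], p.t_mi[j - 1], p.t_md[j - 1]
        t_ii = p.t_ii[j - 1]
        e_i = (1.0 + (1.0 - t_ii) * e_m[j + 1]) / (1.0 - t_ii)
        e_m[j] = 1.0 + t_mm * e_m[j + 1] + t_mi * e_i + t_md * e_d[j + 1]
        e_d[j] = p.t_dm[j - 1] * e_m[j + 1] + p.t_dd[j - 1] * e_d[j + 1]
    return float(p.entry_m * e_m[1] + p.entry_d * e_d[1])
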