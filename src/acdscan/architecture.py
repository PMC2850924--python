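"""Monomer architecture: region slicing, C-terminal motif, CAM, hydropathy.

Each detected monomer is partitioned into the N-terminal region (everything
before the beta2 strand), the ACD (beta2 through beta9, subdivided into the
beta2-beta5 zone, the L57 loop and the beta7-beta9 zone) and the C-terminal
region.  Within the C-terminal region, the aliphatic anchor motif
I/V-X-I/V (or the extended I/V/L-X-I/V/L) bounds the C-terminal Anchoring
Module (CAM): the fragment from the end of the ACD to the end of the motif.
Whatever follows the CAM is the C-terminal tail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import SequenceRecord, ZONE_OF_ELEMENT, validate_region
from .profile_hmm import DomainHit, ProfileHMM

Region = tuple[int, int]  # 1-based inclusive (start, end)

#: Kyte-Doolittle hydropathy indices; X (unknown) contributes 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

MOTIF_CORE = re.compile(r"[IV].[IV]")
MOTIF_EXTENDED = re.compile(r"[IVL].[IVL]")

ZONES = ("b2b5", "l57", "b7b9")


def _region_len(r: Optional[Region]) -> int:
    return 0 if r is None else r[1] - r[0] + 1


@dataclass
class MonomerArchitecture:
    """The sliced monomer: regions are 1-based inclusive or None if empty."""

    accession: str
    length: int
    nterm: Optional[Region]
    acd: Region
    zone_b2b5: Optional[Region]
    loop_l57: Optional[Region]
    zone_b7b9: Optional[Region]
    cterm: Optional[Region]
    motif_kind: str = "none"              # {"IVxIV", "IVLxIVL", "none"}
    motif_span: Optional[Region] = None   # sequence coordinates
    has_core_motif: bool = False          # I/V-X-I/V found anywhere in C-term
    cam: Optional[Region] = None
    cter_tail: Optional[Region] = None
    empty_zones: tuple[str, ...] = ()     # zones with no matched column
    hydropathy: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def acd_start(self) -> int:
        return self.acd[0]

    @property
    def acd_end(self) -> int:
        return self.acd[1]

    def region_lengths(self) -> dict[str, int]:
        return {
            "nterm": _region_len(self.nterm),
            "acd": _region_len(self.acd),
            "b2b5": _region_len(self.zone_b2b5),
            "l57": _region_len(self.loop_l57),
            "b7b9": _region_len(self.zone_b7b9),
            "cterm": _region_len(self.cterm),
            "cam": _region_len(self.cam),
            "tail": _region_len(self.cter_tail),
        }


def hydropathy_score(residues: str) -> float:
    """Mean Kyte-Doolittle hydropathy index of a fragment (X counts 0)."""
    if not residues:
        raise ValueError("hydropathy of an empty fragment is undefined")
    return sum(KYTE_DOOLITTLE[a] for a in residues) / len(residues)


def find_cterm_motif(cterm_residues: str, extended: bool = True) -> Optional[Region]:
    """Leftmost anchor-motif occurrence, in C-terminal 1-based coordinates.

    The pattern is ``[IV].[IV]`` or, with ``extended``, ``[IVL].[IVL]``.
    Returns None when the region lacks the motif (or is empty).
    """
    pat = MOTIF_EXTENDED if extended else MOTIF_CORE
    m = pat.search(cterm_residues)
    if m is None:
        return None
    return (m.start() + 1, m.end())


def slice_regions(
    rec: SequenceRecord, hit: DomainHit, p: ProfileHMM
) -> MonomerArchitecture:
    """Partition a monomer into N-terminal, ACD zones and C-terminal regions.

    Zone boundaries on the target are the positions matched by the first and
    last profile columns of each zone; inserted residues between two columns
    of the same zone belong to that zone, and insertions at a zone boundary go
    to the preceding zone.  Deleted columns contribute zero length.  A zone
    with no matched column is flagged in ``empty_zones``.
    """
    L = len(rec.residues)
    validate_region(hit.acd_start, hit.acd_end, L, "ACD envelope")
    if not p.landmark_of_column:
        raise ValueError("profile has no landmark map")

    zone_len = {z: 0 for z in ZONES}
    for j in range(p.M):
        z = ZONE_OF_ELEMENT[p.landmark_of_column[j + 1]]
        if hit.column_map[j] is not None:
            zone_len[z] += 1
        if j < p.M - 1:
            zone_len[z] += hit.insert_counts[j]

    regions: dict[str, Optional[Region]] = {}
    pos = hit.acd_start
    empty = []
    for z in ZONES:
        if zone_len[z] == 0:
            regions[z] = None
            empty.append(z)
        else:
            regions[z] = (pos, pos + zone_len[z] - 1)
            pos += zone_len[z]
    assert pos == hit.acd_end + 1, "zone lengths must tile the ACD envelope"

    nterm = (1, hit.acd_start - 1) if hit.acd_start > 1 else None
    cterm = (hit.acd_end + 1, L) if hit.acd_end < L else None

    hydro = {
        z: (hydropathy_score(rec.residues[r[0] - 1: r[1]]) if r else None)
        for z, r in regions.items()
    }

    arch = MonomerArchitecture(
        accession=rec.accession, length=L,
        nterm=nterm, acd=(hit.acd_start, hit.acd_end),
        zone_b2b5=regions["b2b5"], loop_l57=regions["l57"],
        zone_b7b9=regions["b7b9"], cterm=cterm,
        empty_zones=tuple(empty), hydropathy=hydro,
    )
    return arch


def delineate_cam(
    arch: MonomerArchitecture, rec: SequenceRecord, extended: bool = True
) -> MonomerArchitecture:
    """Locate the anchor motif and split the C-terminal region into CAM + tail.

    The CAM runs from the first residue after the ACD through the last residue
    of the leftmost motif occurrence; its length therefore equals the motif's
    end offset within the C-terminal region.  Without a motif the C-terminal
    region is reported whole (``motif_kind`` "none").
    """
    if arch.cterm is None:
        return arch
    c0, c1 = arch.cterm
    cterm_res = rec.residues[c0 - 1: c1]
    arch.has_core_motif = MOTIF_CORE.search(cterm_res) is not None
    span = find_cterm_motif(cterm_res, extended=extended)
    if span is None:
        return arch
    triplet = cterm_res[span[0] - 1: span[1]]
    arch.motif_kind = "IVxIV" if MOTIF_CORE.fullmatch(triplet) else "IVLxIVL"
    arch.motif_span = (c0 + span[0] - 1, c0 + span[1] - 1)
    cam_end = arch.acd_end + span[1]
    arch.cam = (arch.acd_end + 1, cam_end)
    arch.cter_tail = (cam_end + 1, arch.length) if cam_end < arch.length else None
    return arch


def annotate(
    rec: SequenceRecord, hit: DomainHit, p: ProfileHMM, extended: bool = True
) -> MonomerArchitecture:
    """Slice regions then delineate the CAM, in one pass."""
    return delineate_cam(slice_regions(rec, hit, p), rec, extended=extended)


def architecture_table(archs: Sequence[MonomerArchitecture]):
    """Summarize architectures as a DataFrame (the TSV export layout)."""
    import pandas as pd

    rows = []
    for a in archs:
        lens = a.region_lengths()
        rows.append(
            {
                "accession": a.accession,
                "L": a.length,
                "nterm_len": lens["nterm"],
                "acd_start": a.acd_start,
                "acd_end": a.acd_end,
                "acd_len": lens["acd"],
                "b2b5_len": lens["b2b5"],
                "l57_len": lens["l57"],
                "b7b9_len": lens["b7b9"],
                "motif_kind": a.motif_kind,
                "cam_len": lens["cam"],
                "tail_len": lens["tail"],
                "hydropathy_b2b5": a.hydropathy.get("b2b5"),
                "hydropathy_l57": a.hydropathy.get("l57"),
                "hydropathy_b7b9": a.hydropathy.get("b7b9"),
            }
        )
    return pd.DataFrame(rows)


def regions_to_bed(archs: Sequence[MonomerArchitecture]):
    """BED-style export: 0-based half-open intervals, one row per region."""
    import pandas as pd

    rows = []
    for a in archs:
        for name, region in (
            ("nterm", a.nterm), ("acd", a.acd), ("b2b5", a.zone_b2b5),
            ("l57", a.loop_l57), ("b7b9", a.zone_b7b9), ("cam", a.cam),
            ("cter_tail", a.cter_tail),
        ):
            if region is not None:
                rows.append(
                    {"accession": a.accession, "start": region[0] - 1,
                     "end": region[1], "name": name}
                )
    return pd.DataFrame(rows)
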