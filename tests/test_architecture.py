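"""Monomer slicing, anchor-motif search, CAM delineation and hydropathy."""

import numpy as np
import pytest

from acdscan.architecture import (
    MonomerArchitecture,
    annotate,
    delineate_cam,
    find_cterm_motif,
    hydropathy_score,
    slice_regions,
)
from acdscan.core_io import SequenceRecord
from acdscan.profile_hmm import DomainHit

from .conftest import delta_profile


def toy_profile():
    """M=10: beta2-beta5 zone 4 columns, L57 3 columns, beta7-beta9 3 columns."""
    landmarks = {}
    for c in range(1, 5):
        landmarks[c] = "b2"
    for c in range(5, 8):
        landmarks[c] = "L57"
    for c in range(8, 11):
        landmarks[c] = "b9"
    return delta_profile("ACDEFGHIKL", landmarks)


def contiguous_hit(acc: str, start: int, M: int) -> DomainHit:
    cmap = tuple(start + j for j in range(M))
    return DomainHit(acc, start, start + M - 1, 50.0, 1e-9, cmap,
                     (0,) * (M - 1))


class TestSliceRegions:
    def test_region_arithmetic(self):
        p = toy_profile()
        rec = SequenceRecord("r", "M" * 100)
        hit = contiguous_hit("r", 21, 10)  # ACD 21..30
        arch = slice_regions(rec, hit, p)
        assert arch.nterm == (1, 20)
        assert arch.acd == (21, 30)
        assert arch.zone_b2b5 == (21, 24)
        assert arch.loop_l57 == (25, 27)
        assert arch.zone_b7b9 == (28, 30)
        assert arch.cterm == (31, 100)
        lens = arch.region_lengths()
        assert lens["nterm"] + lens["acd"] + lens["cterm"] == 100
        assert lens["b2b5"] + lens["l57"] + lens["b7b9"] == lens["acd"]

    def test_hit_covering_whole_sequence(self):
        p = toy_profile()
        rec = SequenceRecord("r", "M" * 10)
        arch = slice_regions(rec, contiguous_hit("r", 1, 10), p)
        assert arch.nterm is None and arch.cterm is None
        assert arch.region_lengths()["nterm"] == 0
        assert arch.region_lengths()["cterm"] == 0

    def test_boundary_insertions_go_to_preceding_zone(self):
        p = toy_profile()
        # insert of 2 after column 4 (last b2b5 column) -> counted in b2b5
        cmap = (11, 12, 13, 14, 17, 18, 19, 20, 21, 22)
        ins = (0, 0, 0, 2, 0, 0, 0, 0, 0)
        hit = DomainHit("r", 11, 22, 50.0, 1e-9, cmap, ins)
        rec = SequenceRecord("r", "M" * 40)
        arch = slice_regions(rec, hit, p)
        assert arch.region_lengths()["b2b5"] == 6
        assert arch.region_lengths()["l57"] == 3

    def test_deleted_zone_has_zero_length_and_flag(self):
        p = toy_profile()
        cmap = (11, 12, 13, 14, None, None, None, 15, 16, 17)
        hit = DomainHit("r", 11, 17, 50.0, 1e-9, cmap, (0,) * 9)
        rec = SequenceRecord("r", "M" * 30)
        arch = slice_regions(rec, hit, p)
        assert arch.loop_l57 is None
        assert arch.empty_zones == ("l57",)
        lens = arch.region_lengths()
        assert lens["b2b5"] + lens["l57"] + lens["b7b9"] == lens["acd"] == 7

    def test_alpha_crystallin_scale_zone_lengths(self, gen_profile):
        """Zone widths 38/14/31 tile an 83-residue ACD, the human
        alpha-crystallin arrangement."""
        M = gen_profile.M
        assert M == 83
        rec = SequenceRecord("r", "M" * 200)
        hit = contiguous_hit("r", 55, M)
        arch = slice_regions(rec, hit, gen_profile)
        lens = arch.region_lengths()
        assert lens["acd"] == 83
        assert (lens["b2b5"], lens["l57"], lens["b7b9"]) == (38, 14, 31)


class TestMotif:
    def test_leftmost_extended_match(self):
        assert find_cterm_motif("KTIPVSREEK", extended=True) == (3, 5)

    def test_absent_motif(self):
        assert find_cterm_motif("AAAAA", extended=True) is None
        assert find_cterm_motif("", extended=True) is None

    def test_leftmost_wins_among_overlaps(self):
        assert find_cterm_motif("IEIAIPI", extended=True) == (1, 3)

    def test_core_pattern_excludes_leucine(self):
        assert find_cterm_motif("LPLAAA", extended=False) is None
        assert find_cterm_motif("LPLAAA", extended=True) == (1, 3)


class TestDelineateCam:
    def _arch(self, L, acd_end):
        return MonomerArchitecture(
            accession="r", length=L, nterm=(1, 10), acd=(11, acd_end),
            zone_b2b5=None, loop_l57=None, zone_b7b9=None,
            cterm=(acd_end + 1, L),
        )

    def test_cam_and_tail_lengths(self):
        # motif at C-terminal offsets 12..14 of a 60-residue C-terminal region
        L, acd_end = 200, 140
        rec = SequenceRecord("r", "M" * acd_end + "A" * 11 + "IPV" + "A" * 46)
        arch = delineate_cam(self._arch(L, acd_end), rec)
        assert arch.cam == (141, 154)
        assert arch.region_lengths()["cam"] == 14
        assert arch.cter_tail == (155, 200)
        assert arch.region_lengths()["tail"] == 46
        assert arch.motif_kind == "IVxIV"

    def test_motif_at_last_residue_leaves_empty_tail(self):
        L, acd_end = 154, 140
        rec = SequenceRecord("r", "M" * acd_end + "A" * 11 + "LEV")
        arch = delineate_cam(self._arch(L, acd_end), rec)
        assert arch.cam == (141, 154)
        assert arch.cter_tail is None
        assert arch.region_lengths()["tail"] == 0
        assert arch.motif_kind == "IVLxIVL"  # leucine needs the extended pattern

    def test_no_motif_reports_whole_cterm(self):
        L, acd_end = 160, 140
        rec = SequenceRecord("r", "M" * acd_end + "A" * 20)
        arch = delineate_cam(self._arch(L, acd_end), rec)
        assert arch.cam is None and arch.cter_tail is None
        assert arch.motif_kind == "none"
        assert arch.cterm == (141, 160)


class TestHydropathy:
    @pytest.mark.parametrize(
        "fragment,score",
        [("III", 4.5), ("RRRR", -4.5), ("IR", 0.0), ("XX", 0.0)],
    )
    def test_mean_kyte_doolittle(self, fragment, score):
        assert hydropathy_score(fragment) == pytest.approx(score)

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_score("")


class TestPipelineProperties:
    def test_region_conservation_and_zone_additivity(self, pipeline):
        profile, hits, trace, records, truth = pipeline
        by_acc = {r.accession: r for r in records}
        assert hits
        for h in hits:
            arch = annotate(by_acc[h.accession], h, profile)
            lens = arch.region_lengths()
            assert lens["nterm"] + lens["acd"] + lens["cterm"] == arch.length
            assert lens["b2b5"] + lens["l57"] + lens["b7b9"] == lens["acd"]
            if arch.cam is not None:
                assert lens["cam"] + lens["tail"] == lens["cterm"]

    def test_l57_more_hydrophilic_than_strand_zones(self, pipeline):
        """The dimerization loop is charged/polar; strand zones are not."""
        profile, hits, trace, records, truth = pipeline
        by_acc = {r.accession: r for r in records}
        l57, b2b5 = [], []
        for h in hits:
            arch = annotate(by_acc[h.accession], h, profile)
            if arch.hydropathy["l57"] is not None and arch.hydropathy["b2b5"] is not None:
                l57.append(arch.hydropathy["l57"])
                b2b5.append(arch.hydropathy["b2b5"])
        assert np.mean(l57) < np.mean(b2b5)
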