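"""Shared fixtures: packaged seed, profiles, and one full pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from acdscan.core_io import read_seed_alignment
from acdscan.data import seed_alignment_path
from acdscan.ihmmer import IterationConfig, iterate
from acdscan.profile_hmm import ProfileHMM, build_profile
from acdscan.synthetic import SynthesisParams, generate_dataset, generator_profile


@pytest.fixture(scope="session")
def seed_alignment():
    return read_seed_alignment(seed_alignment_path())


# cheap to build, so function-scoped: tests may attach calibrations freely
@pytest.fixture()
def seed_profile(seed_alignment):
    aln, ann = seed_alignment
    return build_profile(aln, ann)


@pytest.fixture()
def gen_profile():
    return generator_profile()


@pytest.fixture(scope="session")
def databank():
    """The 50 positives + 50 decoys study databank (mutation 0.2, seed 42)."""
    records, truth = generate_dataset(generator_profile(), SynthesisParams(seed=42))
    return records, truth


@pytest.fixture(scope="session")
def pipeline(seed_alignment, databank):
    """Full enrichment run at default thresholds on the study databank."""
    aln, ann = seed_alignment
    records, truth = databank
    profile, hits, trace = iterate(aln, ann, records, IterationConfig(), seed=42)
    return profile, hits, trace, records, truth


def delta_profile(consensus: str, landmarks: dict[int, str],
                  background=None) -> ProfileHMM:
    """Deterministic single-path profile: delta emissions, all-match path."""
    M = len(consensus)
    from acdscan.core_io import AMINO_ACIDS

    bg = np.full(20, 0.05) if background is None else np.asarray(background)
    emit = np.zeros((M, 20))
    for j, a in enumerate(consensus):
        emit[j, AMINO_ACIDS.index(a)] = 1.0
    n = max(M - 1, 0)
    return ProfileHMM(
        match_emit=emit, insert_emit=np.tile(bg, (M + 1, 1)),
        t_mm=np.ones(n), t_mi=np.zeros(n), t_md=np.zeros(n),
        t_im=np.ones(n), t_ii=np.zeros(n), t_dm=np.ones(n), t_dd=np.zeros(n),
        entry_m=1.0, entry_d=0.0, background=bg,
        landmark_of_column=landmarks,
    )
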