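"""Packaged data: background frequencies, seed alignment, class references."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ..core_io import AMINO_ACIDS


def _path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def load_background() -> np.ndarray:
    """Swiss-Prot-like amino-acid frequencies in canonical (ACDE...) order."""
    df = pd.read_csv(_path("background_frequencies.tsv"), sep="\t")
    freq = dict(zip(df["residue"], df["frequency"]))
    v = np.array([freq[a] for a in AMINO_ACIDS], dtype=float)
    return v / v.sum()


def seed_alignment_path() -> Path:
    """Stockholm file of the synthetic seed ACD alignment (with landmarks)."""
    return _path("synthetic_seed_acd.sto")


def bac_class_refs_path() -> Path:
    """TSV of synthetic bacterial class A/B reference sequences."""
    return _path("synthetic_bac_class_refs.tsv")


def load_bac_class_refs() -> tuple[list[str], list[str]]:
    """Return (class A, class B) reference residue strings."""
    df = pd.read_csv(bac_class_refs_path(), sep="\t")
    refs_a = df.loc[df["class"] == "A", "residues"].tolist()
    refs_b = df.loc[df["class"] == "B", "residues"].tolist()
    return refs_a, refs_b
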