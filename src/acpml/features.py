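"""Fixed-length sequence featurisations: AAC, DPC, ATC and PCP.

Four encodings map a peptide to a numeric vector with a frozen column
order, so that persisted models stay valid across sessions:

* AAC — amino acid composition, 20 values: count of each residue divided by
  peptide length; columns in alphabetical residue order.
* DPC — dipeptide composition, 400 values: overlapping two-residue-window
  counts divided by the L-1 windows; columns row-major over the 20x20
  alphabet (AA, AC, ..., YY). A length-1 peptide gets an all-zero block.
* ATC — atomic composition, 5 values: frequencies of C, H, N, O, S atoms
  summed over residues, using the free-amino-acid molecular formulas
  (G = C2H5NO2, ...) shipped as a TSV resource.
* PCP — physicochemical properties, 11 values: the fraction of residues in
  each of ten (overlapping, non-exhaustive) residue classes — polar,
  hydrophobic, charged, aliphatic, aromatic, positively charged, negatively
  charged, tiny, small, large — plus the peptide mass in Daltons (sum of
  average residue masses + one water). The mass column is raw, ~10^3 larger
  than the fractions; the SVM pipeline standardises columns, the random
  forest is scale-invariant.

The default hybrid encoding concatenates AAC||DPC||ATC||PCP: 436 columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS, Peptide

WATER_MASS = 18.0153  # Da, added once per peptide chain

ATOMS = ("C", "H", "N", "O", "S")

#: Residue-class memberships for the ten PCP fractions, in reporting order.
PCP_CLASSES: dict[str, frozenset] = {
    "polar": frozenset("DERKQN"),
    "hydrophobic": frozenset("CVLIMFW"),
    "charged": frozenset("DEKHR"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FHWY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "tiny": frozenset("ACDGST"),
    "small": frozenset("EHILKMNPQV"),
    "large": frozenset("FRWY"),
}

BLOCK_SIZES = {"AAC": 20, "DPC": 400, "ATC": 5, "PCP": 11}

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
DIPEPTIDES = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("acpml.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col="residue")


_ATOM_TABLES = {"free_amino_acid_v1": None}  # lazy cache
_MASS_TABLE: Optional[pd.Series] = None


def atom_counts(atom_table_id: str = "free_amino_acid_v1") -> pd.DataFrame:
    """Per-residue atom-count table (rows = residues, columns = C,H,N,O,S)."""
    if atom_table_id not in _ATOM_TABLES:
        raise KeyError(f"unknown atom table: {atom_table_id!r}")
    if _ATOM_TABLES[atom_table_id] is None:
        _ATOM_TABLES[atom_table_id] = _load_table("atom_counts.tsv")
    return _ATOM_TABLES[atom_table_id]


def residue_masses() -> pd.Series:
    """Average residue masses in Daltons."""
    global _MASS_TABLE
    if _MASS_TABLE is None:
        _MASS_TABLE = _load_table("residue_masses.tsv")["mass"]
    return _MASS_TABLE


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks to compute, in which order.

    ``blocks`` is an ordered subset of AAC, DPC, ATC, PCP (no duplicates);
    the default is the full hybrid. ``atom_table_id`` names the per-residue
    atom-count resource used by ATC so it can be swapped.
    """

    blocks: tuple[str, ...] = ("AAC", "DPC", "ATC", "PCP")
    atom_table_id: str = "free_amino_acid_v1"
    pcp_mass_units: str = "Da"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("FeatureConfig.blocks must be non-empty")
        if len(set(self.blocks)) != len(self.blocks):
            raise ValueError("duplicate feature block")
        for b in self.blocks:
            if b not in BLOCK_SIZES:
                raise ValueError(f"unknown feature block: {b!r}")

    @property
    def n_features(self) -> int:
        return sum(BLOCK_SIZES[b] for b in self.blocks)


def aac(seq: str) -> np.ndarray:
    """Amino acid composition: fraction of each residue, alphabetical order."""
    if not seq:
        raise ValueError("cannot featurise an empty sequence")
    idx = np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    return np.bincount(idx, minlength=20) / len(seq)


def dpc(seq: str) -> np.ndarray:
    """Dipeptide composition over the L-1 overlapping windows.

    Row-major 20x20 order (AA, AC, ..., YY); all zeros for length-1 input.
    """
    if not seq:
        raise ValueError("cannot featurise an empty sequence")
    if len(seq) < 2:
        return np.zeros(400)
    idx = np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    pairs = idx[:-1] * 20 + idx[1:]
    return np.bincount(pairs, minlength=400) / (len(seq) - 1)


def atc(seq: str, atom_table_id: str = "free_amino_acid_v1") -> np.ndarray:
    """Atomic composition: C, H, N, O, S atom frequencies over the peptide.

    Frequencies are count ratios over the residues' free-amino-acid
    formulas, so they are invariant under sequence repetition.
    """
    if not seq:
        raise ValueError("cannot featurise an empty sequence")
    table = atom_counts(atom_table_id)
    missing = set(seq) - set(table.index)
    if missing:
        raise KeyError(f"residues missing from atom table: {sorted(missing)}")
    totals = table.loc[list(seq), list(ATOMS)].to_numpy().sum(axis=0)
    return totals / totals.sum()


def pcp(seq: str) -> np.ndarray:
    """Ten residue-class fractions (in [0,1]) plus peptide mass in Daltons."""
    if not seq:
        raise ValueError("cannot featurise an empty sequence")
    n = len(seq)
    fractions = [
        sum(1 for c in seq if c in members) / n
        for members in PCP_CLASSES.values()
    ]
    mass = float(residue_masses().loc[list(seq)].sum()) + WATER_MASS
    return np.array(fractions + [mass])


_BLOCK_FN = {
    "AAC": lambda seq, cfg: aac(seq),
    "DPC": lambda seq, cfg: dpc(seq),
    "ATC": lambda seq, cfg: atc(seq, cfg.atom_table_id),
    "PCP": lambda seq, cfg: pcp(seq),
}

_BLOCK_NAMES = {
    "AAC": tuple(f"AAC:{a}" for a in AMINO_ACIDS),
    "DPC": tuple(f"DPC:{d}" for d in DIPEPTIDES),
    "ATC": tuple(f"ATC:{a}" for a in ATOMS),
    "PCP": tuple(f"PCP:{c}" for c in PCP_CLASSES) + ("PCP:mass",),
}


def feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Column labels of :func:`encode` output, stable for equal configs."""
    names: list[str] = []
    for block in config.blocks:
        names.extend(_BLOCK_NAMES[block])
    return names


def encode(
    peptide: "Peptide | str", config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Concatenate the configured feature blocks for one peptide."""
    seq = peptide.seq if isinstance(peptide, Peptide) else peptide
    return np.concatenate([_BLOCK_FN[b](seq, config) for b in config.blocks])


def encode_dataset(
    peptides: Iterable[Peptide],
    config: FeatureConfig = FeatureConfig(),
    require_labels: bool = False,
) -> tuple[pd.DataFrame, Optional[np.ndarray]]:
    """Encode peptides into a (n, features) DataFrame plus a label vector.

    Row order preserves input order; the index holds peptide ids. The label
    vector is ``None`` when no peptide carries a label; a mix of labelled
    and unlabelled peptides is an error.
    """
    peptides = list(peptides)
    names = feature_names(config)
    if not peptides:
        return pd.DataFrame(columns=names, dtype=float), None
    rows = np.vstack([encode(p, config) for p in peptides])
    matrix = pd.DataFrame(rows, columns=names, index=[p.id for p in peptides])
    labelled = [p.label is not None for p in peptides]
    if any(labelled) and not all(labelled):
        raise ValueError("mixed labelled and unlabelled peptides")
    if require_labels and not all(labelled):
        raise ValueError("labels required but absent")
    labels = (
        np.array([p.label for p in peptides], dtype=int)
        if all(labelled)
        else None
    )
    return matrix, labels
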