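"""Amino-acid physicochemical tables and WT-vs-mutant delta features.

A missense mutation replaces one residue with another; four scalar features
summarise how drastic that replacement is at the biochemical level: the
absolute mass difference (Daltons), the absolute Kyte–Doolittle
hydrophobicity difference, the absolute side-chain charge difference at a
given pH, and a categorical polarity-change flag. All four depend only on
the (wild-type, mutant) residue pair, never on the peptide window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "UnknownResidueError",
    "ResiduePropertyTable",
    "POLARITY_CHANGE_CODES",
    "delta_size",
    "delta_hydrophobicity",
    "residue_charge",
    "delta_charge",
    "polarity_change",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed numeric encoding of the polarity-change category used by the
#: classifier feature column.
POLARITY_CHANGE_CODES = {
    "none": 0,
    "polar_to_nonpolar": 1,
    "nonpolar_to_polar": 2,
}


class UnknownResidueError(KeyError):
    """Raised when a symbol is not one of the 20 canonical residues.

    Non-canonical codes (X, U, B, Z, gaps) are rejected rather than imputed:
    a silently imputed property would corrupt the delta features.
    """

    def __init__(self, symbol: object):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # noqa: D105
        return f"unknown residue symbol {self.symbol!r}; expected one of {CANONICAL_RESIDUES}"


@dataclass(frozen=True)
class ResidueProperties:
    """Constants for one residue."""

    mass: float  # average free-amino-acid mass, Da
    kd: float  # Kyte–Doolittle hydrophobicity index
    pka: float | None  # side-chain pKa; None if not ionizable
    acid_or_base: str  # "acid", "base", or "none"
    polarity: str  # "polar" or "nonpolar"


class ResiduePropertyTable:
    """Lookup table of per-residue physicochemical constants.

    Backed by a plain tab-separated file with columns
    ``residue, mass, kd, pka, acid_or_base, polarity`` (``NA`` marks a
    missing pKa). Users may supply a replacement file with identical
    columns, e.g. to reclassify borderline residues (G, C, Y) or to swap
    the mass scale.
    """

    def __init__(self, entries: dict[str, ResidueProperties]):
        missing = set(CANONICAL_RESIDUES) - set(entries)
        extra = set(entries) - set(CANONICAL_RESIDUES)
        if missing or extra:
            raise ValueError(
                f"property table must cover exactly the 20 canonical residues; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for aa, p in entries.items():
            if not p.mass > 0:
                raise ValueError(f"non-positive mass for residue {aa}")
            if not -4.5 <= p.kd <= 4.5:
                raise ValueError(f"Kyte–Doolittle index out of [-4.5, 4.5] for {aa}")
            if p.polarity not in ("polar", "nonpolar"):
                raise ValueError(f"bad polarity class {p.polarity!r} for {aa}")
            if p.acid_or_base not in ("acid", "base", "none"):
                raise ValueError(f"bad ionization flag {p.acid_or_base!r} for {aa}")
            if (p.acid_or_base != "none") != (p.pka is not None):
                raise ValueError(f"pKa / ionization flag inconsistent for {aa}")
        self._entries = dict(entries)

    def __getitem__(self, residue: str) -> ResidueProperties:
        try:
            return self._entries[residue]
        except KeyError:
            raise UnknownResidueError(residue) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResiduePropertyTable":
        df = pd.read_csv(path, sep="\t", dtype={"residue": str}, na_values=["NA"])
        entries = {}
        for row in df.itertuples(index=False):
            pka = None if pd.isna(row.pka) else float(row.pka)
            entries[row.residue] = ResidueProperties(
                mass=float(row.mass),
                kd=float(row.kd),
                pka=pka,
                acid_or_base=str(row.acid_or_base),
                polarity=str(row.polarity),
            )
        return cls(entries)

    @classmethod
    def default(cls) -> "ResiduePropertyTable":
        """Packaged table: average free amino-acid masses, Kyte–Doolittle
        indices, standard side-chain pKa values."""
        ref = resources.files("neoreact.data") / "residue_properties.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


_DEFAULT: ResiduePropertyTable | None = None


def default_table() -> ResiduePropertyTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ResiduePropertyTable.default()
    return _DEFAULT


def delta_size(wt: str, mut: str, table: ResiduePropertyTable | None = None) -> float:
    """Absolute mass difference |m(mut) - m(wt)| in Daltons."""
    table = table or default_table()
    return abs(table[mut].mass - table[wt].mass)


def delta_hydrophobicity(wt: str, mut: str, table: ResiduePropertyTable | None = None) -> float:
    """Absolute Kyte–Doolittle index difference |KD(mut) - KD(wt)|."""
    table = table or default_table()
    return abs(table[mut].kd - table[wt].kd)


def residue_charge(res: str, ph: float = 7.4, table: ResiduePropertyTable | None = None) -> float:
    """Fractional side-chain charge at the given pH.

    Henderson–Hasselbalch on the side chain only (backbone termini are
    excluded because the comparison is residue-vs-residue): acids carry
    -1/(1+10^(pKa-pH)), bases +1/(1+10^(pH-pKa)), non-ionizable side chains
    0. Histidine (pKa 6.0) thus gets a small positive partial charge at
    physiological pH rather than an arbitrary 0/+1.
    """
    if not 0 < ph < 14:
        raise ValueError(f"pH must be in (0, 14), got {ph}")
    table = table or default_table()
    p = table[res]
    if p.acid_or_base == "none":
        return 0.0
    assert p.pka is not None
    if p.acid_or_base == "acid":
        return -1.0 / (1.0 + math.pow(10.0, p.pka - ph))
    return 1.0 / (1.0 + math.pow(10.0, ph - p.pka))


def delta_charge(
    wt: str, mut: str, ph: float = 7.4, table: ResiduePropertyTable | None = None
) -> float:
    """Absolute difference of fractional side-chain charges at ``ph``."""
    table = table or default_table()
    return abs(residue_charge(mut, ph, table) - residue_charge(wt, ph, table))


def polarity_change(wt: str, mut: str, table: ResiduePropertyTable | None = None) -> str:
    """Polarity-change category: none / polar_to_nonpolar / nonpolar_to_polar."""
    table = table or default_table()
    pw, pm = table[wt].polarity, table[mut].polarity
    if pw == pm:
        return "none"
    return "polar_to_nonpolar" if pw == "polar" else "nonpolar_to_polar"


def polarity_change_code(wt: str, mut: str, table: ResiduePropertyTable | None = None) -> int:
    """Numeric encoding of :func:`polarity_change` (see POLARITY_CHANGE_CODES)."""
    return POLARITY_CHANGE_CODES[polarity_change(wt, mut, table)]
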