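"""Candidate neo-epitope enumeration and seven-feature vector assembly.

Given a somatic missense mutation in a protein, every 9- and 10-residue
window of the mutated sequence that contains the mutated position is a
candidate MHC class I epitope (MHC-binding filtering is an upstream
concern: this stage assumes candidates were, or will be, filtered by a
binding predictor). Each candidate gets seven features: the source gene's
log expression, the four WT-vs-mutant residue deltas (size,
hydrophobicity, charge, polarity change), the proteasomal cleavage
probability of the window in its protein context, and its TAP score.

Coordinate conventions: protein positions are 1-based inclusive (mutation
nomenclature); window offsets are 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import residue_props as rp
from . import processing_scores as ps

__all__ = [
    "MutationRecord",
    "CandidateEpitope",
    "FEATURE_COLUMNS",
    "LabeledDataset",
    "enumerate_candidates",
    "expression_filter",
    "build_feature_vector",
    "featurize_dataset",
    "read_proteome",
    "read_mutation_table",
    "window_count",
]

logger = logging.getLogger(__name__)

#: Fixed feature column order of the classifier input.
FEATURE_COLUMNS = [
    "expression",
    "size_diff",
    "hydro_diff",
    "charge_diff",
    "polar_change",
    "cleavage",
    "tap",
]

DEFAULT_LENGTHS = (9, 10)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic missense mutation in protein coordinates."""

    sample: str
    gene_id: str
    protein_id: str
    position: int  # 1-based residue index
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in rp.CANONICAL_RESIDUES:
                raise rp.UnknownResidueError(aa)
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"synonymous record {self.protein_id}:{self.position} "
                f"{self.wt_aa}->{self.mut_aa}: wt and mutant residues are equal"
            )


@dataclass(frozen=True)
class CandidateEpitope:
    """One mutated 9/10-mer with provenance and flanking context."""

    peptide: str
    mut_offset: int  # 0-based index of the mutated residue within the peptide
    mutation: MutationRecord
    n_flank: str = ""
    c_flank: str = ""
    annotation: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.peptide) not in (9, 10):
            raise ValueError(f"peptide length must be 9 or 10, got {len(self.peptide)}")
        if not 0 <= self.mut_offset < len(self.peptide):
            raise ValueError("mut_offset outside peptide")
        if self.peptide[self.mut_offset] != self.mutation.mut_aa:
            raise ValueError("peptide does not carry the mutant residue at mut_offset")

    @property
    def candidate_id(self) -> str:
        m = self.mutation
        return (
            f"{m.protein_id}:{m.position}{m.wt_aa}>{m.mut_aa}"
            f"|len{len(self.peptide)}|off{self.mut_offset}"
        )


@dataclass
class LabeledDataset:
    """Feature table + binary reactivity labels + provenance.

    ``features``: DataFrame with FEATURE_COLUMNS, indexed by candidate id;
    ``labels``: int array (1 = T-cell reactive); ``provenance``: free-form
    dataset tag (e.g. "synthetic").
    """

    features: pd.DataFrame
    labels: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        self.features = self.features[FEATURE_COLUMNS]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError(
                f"dataset must contain both classes (pos={self.n_pos}, neg={self.n_neg})"
            )

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="candidate_id")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "LabeledDataset":
        df = pd.read_csv(path, index_col=0)
        if "label" not in df.columns:
            raise ValueError(f"{path}: labeled feature CSV requires a 'label' column")
        return cls(
            features=df[FEATURE_COLUMNS],
            labels=df["label"].to_numpy(),
            provenance=provenance or str(path),
        )


def window_count(protein_length: int, position: int, k: int) -> int:
    """Closed form: number of k-windows of a length-L protein containing
    1-based position p = max(0, min(k, p, L - p + 1, L - k + 1))."""
    return max(0, min(k, position, protein_length - position + 1, protein_length - k + 1))


def enumerate_candidates(
    protein: str,
    mutation: MutationRecord,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    flank_width: int = 2,
) -> list[CandidateEpitope]:
    """All 9/10-mer windows of the mutated protein containing the mutation.

    The wild-type residue is checked against the protein sequence; flanks
    of ``flank_width`` residues are taken from the mutated protein for
    cleavage context (termini padded downstream).
    """
    L = len(protein)
    p = mutation.position
    if p > L:
        raise ValueError(
            f"mutation position {p} outside protein {mutation.protein_id} of length {L}"
        )
    if protein[p - 1] != mutation.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {mutation.protein_id}:{p}: "
            f"FASTA has {protein[p - 1]!r}, mutation record says {mutation.wt_aa!r}"
        )
    mutated = protein[: p - 1] + mutation.mut_aa + protein[p:]
    out: list[CandidateEpitope] = []
    for k in sorted(lengths):
        # 0-based window starts s with s <= p-1 <= s+k-1, inside the protein
        lo = max(0, p - k)
        hi = min(p - 1, L - k)
        for s in range(lo, hi + 1):
            out.append(
                CandidateEpitope(
                    peptide=mutated[s : s + k],
                    mut_offset=(p - 1) - s,
                    mutation=mutation,
                    n_flank=mutated[max(0, s - flank_width) : s],
                    c_flank=mutated[s + k : s + k + flank_width],
                )
            )
    # deterministic order: window start, then length
    out.sort(key=lambda c: (c.mutation.position - 1 - c.mut_offset, len(c.peptide)))
    return out


def expression_filter(
    candidates: Sequence[CandidateEpitope],
    table: ps.ExpressionTable,
    min_fpkm: float = 1.0,
) -> list[CandidateEpitope]:
    """Retain candidates whose source gene has FPKM >= min_fpkm (inclusive)."""
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be non-negative")
    kept = [c for c in candidates if table.get_fpkm(c.mutation.gene_id) >= min_fpkm]
    logger.info(
        "expression filter (min FPKM %g): kept %d of %d candidates",
        min_fpkm,
        len(kept),
        len(candidates),
    )
    return kept


def build_feature_vector(
    candidate: CandidateEpitope,
    expr: ps.ExpressionTable,
    tap: ps.TapScoringMatrix | None = None,
    cleav: ps.CleavageModel | None = None,
    props: rp.ResiduePropertyTable | None = None,
    ph: float = 7.4,
) -> pd.Series:
    """The seven features for one candidate, in FEATURE_COLUMNS order."""
    m = candidate.mutation
    try:
        values = {
            "expression": ps.log_expression(m.gene_id, expr),
            "size_diff": rp.delta_size(m.wt_aa, m.mut_aa, props),
            "hydro_diff": rp.delta_hydrophobicity(m.wt_aa, m.mut_aa, props),
            "charge_diff": rp.delta_charge(m.wt_aa, m.mut_aa, ph, props),
            "polar_change": rp.polarity_change_code(m.wt_aa, m.mut_aa, props),
            "cleavage": ps.cleavage_score(
                candidate.peptide, candidate.c_flank, candidate.n_flank, cleav
            ),
            "tap": ps.tap_score(candidate.peptide, tap),
        }
    except (rp.UnknownResidueError, ps.MissingGeneError, ValueError) as exc:
        raise type(exc)(f"candidate {candidate.candidate_id}: {exc}") from exc
    return pd.Series(values, index=FEATURE_COLUMNS, name=candidate.candidate_id)


def read_proteome(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; id is the first whitespace token."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


MUTATION_COLUMNS = ["sample", "gene_id", "protein_id", "position", "wt_aa", "mut_aa"]


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene_id": str, "protein_id": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation TSV missing columns {missing}")
    return df[MUTATION_COLUMNS]


def featurize_dataset(
    mutations: pd.DataFrame,
    proteome: dict[str, str],
    expr: ps.ExpressionTable,
    tap: ps.TapScoringMatrix | None = None,
    cleav: ps.CleavageModel | None = None,
    props: rp.ResiduePropertyTable | None = None,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    min_fpkm: float = 1.0,
    ph: float = 7.4,
) -> tuple[pd.DataFrame, list[str]]:
    """End-to-end enumeration -> expression filter -> feature assembly.

    Returns (feature table, record-level error messages). Row order is
    deterministic: input mutation order, then window start, then length.
    Record-level failures (wild-type mismatch, missing gene under the error
    policy, non-canonical residues) are collected per row, not fatal;
    structural errors (bad schema) raise.
    """
    tap = tap or ps.TapScoringMatrix.default()
    cleav = cleav or ps.CleavageModel.default()
    props = props or rp.default_table()
    rows: list[pd.Series] = []
    meta: list[dict] = []
    errors: list[str] = []
    for i, rec in enumerate(mutations.itertuples(index=False)):
        try:
            mut = MutationRecord(
                sample=str(rec.sample),
                gene_id=str(rec.gene_id),
                protein_id=str(rec.protein_id),
                position=int(rec.position),
                wt_aa=str(rec.wt_aa),
                mut_aa=str(rec.mut_aa),
            )
            if mut.protein_id not in proteome:
                raise ValueError(f"protein {mut.protein_id!r} absent from proteome")
            cands = enumerate_candidates(
                proteome[mut.protein_id], mut, lengths, flank_width=cleav.window_half_width
            )
            cands = expression_filter(cands, expr, min_fpkm=min_fpkm)
            for c in cands:
                rows.append(build_feature_vector(c, expr, tap, cleav, props, ph=ph))
                meta.append(
                    {
                        "sample": mut.sample,
                        "gene_id": mut.gene_id,
                        "protein_id": mut.protein_id,
                        "position": mut.position,
                        "wt_aa": mut.wt_aa,
                        "mut_aa": mut.mut_aa,
                        "peptide": c.peptide,
                        "mut_offset": c.mut_offset,
                        "length": len(c.peptide),
                    }
                )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i} ({getattr(rec, 'protein_id', '?')}): {exc}")
    if rows:
        feats = pd.DataFrame(rows)
        table = pd.concat([pd.DataFrame(meta, index=feats.index), feats], axis=1)
    else:
        table = pd.DataFrame(columns=list(meta[0]) if meta else
                             ["sample", "gene_id", "protein_id", "position", "wt_aa",
                              "mut_aa", "peptide", "mut_offset", "length"] + FEATURE_COLUMNS)
    table.index.name = "candidate_id"
    return table, errors


def max_per_mutation(feature_table: pd.DataFrame, score_column: str = "tap") -> pd.DataFrame:
    """Optional report: best-scoring window per mutation (no modeling role)."""
    key = ["protein_id", "position", "wt_aa", "mut_aa"]
    idx = feature_table.groupby(key)[score_column].idxmax()
    return feature_table.loc[idx]
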