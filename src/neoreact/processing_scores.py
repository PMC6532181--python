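"""Antigen-processing scores: expression, TAP transport, proteasomal cleavage.

Before a peptide can be loaded onto MHC class I it must exist in the ER in
sufficient copy number. Three quantities proxy that supply: the expression
level of the source gene (log10 FPKM), an additive position-specific TAP
binding score, and the probability that the proteasome generates the exact
peptide (C-terminal cut made, no internal cut). Their sum is the ER
delivery score used as a composite axis in the screening analysis.

The packaged TAP matrix and cleavage weight tables
(``tap_matrix.synthetic.tsv``, ``cleavage_weights.synthetic.tsv``) are
synthetic stand-ins with the qualitative structure of published consensus
models (hydrophobic/basic C-terminal anchor for TAP, hydrophobic-P1
cleavage preference); every scoring function accepts a user-supplied
replacement table with the same columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .residue_props import CANONICAL_RESIDUES, UnknownResidueError

__all__ = [
    "TapScoringMatrix",
    "CleavageModel",
    "ExpressionTable",
    "MissingGeneError",
    "tap_score",
    "cleavage_score",
    "log_expression",
    "er_delivery_score",
]

#: neutral padding symbol for protein termini in cleavage windows
PAD = "-"


def _packaged(name: str) -> Path:
    ref = resources.files("neoreact.data") / name
    with resources.as_file(ref) as path:
        return Path(path)


class TapScoringMatrix:
    """9 x 20 additive TAP-binding score matrix.

    For 9-mers the score is the plain sum of per-position residue weights.
    Longer precursors are scored by their C-terminal residue (at matrix
    position 9) plus ``alpha`` times the contribution of the first
    ``nterm_span`` residues (at matrix positions 1..nterm_span) — the
    consensus-matrix convention for N-terminally extended precursors.
    """

    N_POSITIONS = 9

    def __init__(self, weights: pd.DataFrame, alpha: float = 0.2, nterm_span: int = 3):
        # weights: index 1..9, columns = residues
        weights = weights.sort_index()
        if list(weights.index) != list(range(1, self.N_POSITIONS + 1)):
            raise ValueError("TAP matrix must cover positions 1..9 exactly")
        if set(weights.columns) != set(CANONICAL_RESIDUES):
            raise ValueError("TAP matrix must cover the 20 canonical residues")
        if not np.isfinite(weights.to_numpy()).all():
            raise ValueError("TAP matrix contains non-finite weights")
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        if not 1 <= nterm_span <= self.N_POSITIONS:
            raise ValueError("nterm_span out of range")
        self.weights = weights
        self.alpha = float(alpha)
        self.nterm_span = int(nterm_span)

    def weight(self, position: int, residue: str) -> float:
        if residue not in self.weights.columns:
            raise UnknownResidueError(residue)
        return float(self.weights.at[position, residue])

    @classmethod
    def from_tsv(cls, path: str | Path, alpha: float = 0.2, nterm_span: int = 3) -> "TapScoringMatrix":
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="position", columns="residue", values="weight")
        return cls(wide, alpha=alpha, nterm_span=nterm_span)

    @classmethod
    def default(cls) -> "TapScoringMatrix":
        return cls.from_tsv(_packaged("tap_matrix.synthetic.tsv"))


@dataclass
class CleavageModel:
    """Per-site sigmoid cleavage model.

    A cut site sits between two residues; its linear score is
    ``bias + sum of position_weights`` over a window of
    ``window_half_width`` residues on each side of the site (offsets
    -w..-1 upstream, 1..w downstream; protein termini padded with a neutral
    symbol contributing 0). The per-site cut probability is the logistic
    sigmoid of that score.
    """

    position_weights: pd.DataFrame  # index: offsets (-w..-1, 1..w), columns: residues
    bias: float = 0.0
    window_half_width: int = field(init=False)

    def __post_init__(self) -> None:
        offsets = sorted(self.position_weights.index)
        w = max(abs(o) for o in offsets)
        expected = [o for o in range(-w, w + 1) if o != 0]
        if offsets != expected or w < 1:
            raise ValueError(
                "cleavage weights must cover symmetric offsets -w..-1, 1..w with w >= 1"
            )
        if not np.isfinite(self.position_weights.to_numpy()).all():
            raise ValueError("cleavage weights contain non-finite values")
        self.window_half_width = w

    def site_score(self, context: str, bond: int) -> float:
        """Linear score of the cut site between ``context[bond]`` and
        ``context[bond + 1]``; pad / out-of-range positions contribute 0."""
        return _site_score(self, context, bond)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CleavageModel":
        df = pd.read_csv(path, sep="\t", dtype={"offset": str})
        bias_rows = df[df["offset"] == "bias"]
        bias = float(bias_rows["weight"].iloc[0]) if len(bias_rows) else 0.0
        body = df[df["offset"] != "bias"].copy()
        body["offset"] = body["offset"].astype(int)
        wide = body.pivot(index="offset", columns="residue", values="weight")
        return cls(position_weights=wide, bias=bias)

    @classmethod
    def default(cls) -> "CleavageModel":
        return cls.from_tsv(_packaged("cleavage_weights.synthetic.tsv"))


def _site_score(model: CleavageModel, context: str, bond: int) -> float:
    """Linear score of the cut site between context[bond] and context[bond+1].

    Offset -1 is context[bond] (P1), +1 is context[bond+1] (P1'); offsets
    reaching past the ends or hitting the pad symbol contribute 0.
    """
    s = model.bias
    w = model.window_half_width
    wt = model.position_weights
    for off in range(-w, 0):
        idx = bond + off + 1  # off=-1 -> bond
        if 0 <= idx < len(context) and context[idx] != PAD:
            res = context[idx]
            if res not in wt.columns:
                raise UnknownResidueError(res)
            s += float(wt.at[off, res])
    for off in range(1, w + 1):
        idx = bond + off  # off=+1 -> bond+1
        if 0 <= idx < len(context) and context[idx] != PAD:
            res = context[idx]
            if res not in wt.columns:
                raise UnknownResidueError(res)
            s += float(wt.at[off, res])
    return s


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def tap_score(peptide: str, matrix: TapScoringMatrix | None = None) -> float:
    """Additive TAP-binding score of a peptide of length >= 9.

    9-mers: sum over matrix positions 1..9. Longer precursors: C-terminal
    residue scored at position 9 plus ``alpha`` x the first ``nterm_span``
    residues scored at positions 1..nterm_span.
    """
    matrix = matrix or TapScoringMatrix.default()
    n = len(peptide)
    if n < matrix.N_POSITIONS:
        raise ValueError(f"TAP scoring requires length >= 9, got {n} ({peptide!r})")
    if n == matrix.N_POSITIONS:
        return sum(matrix.weight(i + 1, peptide[i]) for i in range(n))
    cterm = matrix.weight(matrix.N_POSITIONS, peptide[-1])
    nterm = sum(matrix.weight(i + 1, peptide[i]) for i in range(matrix.nterm_span))
    return cterm + matrix.alpha * nterm


def cleavage_score(
    peptide: str,
    c_flank: str = "",
    n_flank: str = "",
    model: CleavageModel | None = None,
) -> float:
    """Probability that the proteasome generates the peptide's C-terminus
    and leaves the body intact.

    P = sigma(s_Cterm) * prod over internal bonds (1 - sigma(s_internal)),
    where s are the per-site linear scores in the flanked context.
    N-terminal generation is attributed to downstream trimming and not
    modeled. Flanks shorter than the window are padded with a neutral
    symbol at protein termini.
    """
    model = model or CleavageModel.default()
    if not peptide:
        raise ValueError("empty peptide")
    w = model.window_half_width
    nf = (PAD * w + n_flank)[-w:]
    cf = (c_flank + PAD * w)[:w]
    context = nf + peptide + cf
    start = len(nf)  # index of peptide[0] in context
    # C-terminal bond: between last peptide residue and first c_flank residue
    p = _sigmoid(_site_score(model, context, start + len(peptide) - 1))
    for i in range(len(peptide) - 1):  # internal bonds
        p *= 1.0 - _sigmoid(_site_score(model, context, start + i))
    return p


class MissingGeneError(KeyError):
    def __init__(self, gene: str):
        super().__init__(gene)
        self.gene = gene

    def __str__(self) -> str:  # noqa: D105
        return f"gene {self.gene!r} absent from expression table"


class ExpressionTable:
    """Gene -> FPKM mapping with a log10(x + pseudocount) transform.

    ``missing_policy`` controls lookups of absent genes: ``"error"``
    (default) raises MissingGeneError; ``"impute"`` returns the sentinel
    log-expression 0.0 (FPKM 0) and records the gene in
    ``imputed_genes``.
    """

    def __init__(
        self,
        fpkm: dict[str, float] | pd.Series,
        pseudocount: float = 1.0,
        missing_policy: str = "error",
    ):
        series = pd.Series(fpkm, dtype=float)
        if series.index.has_duplicates:
            dups = series.index[series.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression table: {dups}")
        if (series < 0).any():
            bad = series.index[series < 0].tolist()
            raise ValueError(f"negative FPKM for genes: {bad}")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if missing_policy not in ("error", "impute"):
            raise ValueError(f"unknown missing-gene policy {missing_policy!r}")
        self.fpkm = series
        self.pseudocount = float(pseudocount)
        self.missing_policy = missing_policy
        self.imputed_genes: set[str] = set()

    def __contains__(self, gene: str) -> bool:
        return gene in self.fpkm.index

    def get_fpkm(self, gene: str) -> float:
        if gene not in self.fpkm.index:
            if self.missing_policy == "impute":
                self.imputed_genes.add(gene)
                return 0.0
            raise MissingGeneError(gene)
        return float(self.fpkm[gene])

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["gene_id", "fpkm"]:
            raise ValueError(
                f"expression TSV must have header columns gene_id, fpkm; got {list(df.columns)}"
            )
        return cls(pd.Series(df["fpkm"].to_numpy(), index=df["gene_id"]), **kwargs)


def log_expression(gene: str, table: ExpressionTable) -> float:
    """log10(FPKM + pseudocount) for one gene."""
    return math.log10(table.get_fpkm(gene) + table.pseudocount)


def er_delivery_score(log_expr: float, tap: float, cleav: float) -> float:
    """Composite ER-delivery proxy: log expression + TAP score + cleavage."""
    for name, v in (("log_expr", log_expr), ("tap", tap), ("cleav", cleav)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite {name}: {v}")
    return log_expr + tap + cleav
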