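"""Seeded generators of labeled neo-epitope datasets.

Real labeled neo-epitope screens (dozens of confirmed reactive peptides
against hundreds of non-reactive MHC binders per cohort) are not publicly
redistributable, so the package ships generators that emulate their
statistical structure at the same scale — by default 35 positives and 450
negatives:

- **feature level**: feature vectors drawn directly from group-specific
  correlated Gaussians, with positives shifted upward in log-expression,
  TAP score and cleavage score (the antigen-supply axis) and unshifted in
  the mutation-delta features, whose correlation structure differs
  between groups instead.
- **sequence level**: a random proteome, random missense mutations and
  log-normal expression are pushed through the real enumeration /
  featurization pipeline; labels are then drawn from a logistic model on
  the standardized ER-delivery composite, so the ground truth depends on
  the features only through that composite.

Neither mode imitates real HLA-binding motifs or real mutational
signatures; they exist so every downstream stage is testable without any
download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import processing_scores as ps
from .epitope_features import (
    FEATURE_COLUMNS,
    LabeledDataset,
    MutationRecord,
    enumerate_candidates,
    build_feature_vector,
)
from .residue_props import CANONICAL_RESIDUES, default_table

__all__ = ["GeneratorConfig", "generate_feature_level", "generate_sequence_level",
           "SequenceLevelData"]

#: continuous features drawn from the group Gaussians, in order
_CONTINUOUS = ["expression", "size_diff", "hydro_diff", "charge_diff", "cleavage", "tap"]

#: marginal (mean, sd) of each continuous feature on its natural scale;
#: cleavage is parameterized on a logit scale and squashed into [0, 1]
_MARGINALS = {
    "expression": (1.0, 0.6),  # log10 FPKM
    "size_diff": (40.0, 25.0),  # Da, folded to >= 0
    "hydro_diff": (3.0, 2.0),  # KD units, folded
    "charge_diff": (0.5, 0.5),  # fractional charge, folded
    "cleavage": (-2.0, 1.5),  # logit scale
    "tap": (0.0, 2.0),  # energy-like units
}


def _default_corr(group: str) -> np.ndarray:
    """Default group correlation structure: independence among negatives;
    positives couple the two physicochemical deltas and the two processing
    scores (the qualitative between-group difference the screen looks
    for)."""
    n = len(_CONTINUOUS)
    c = np.eye(n)
    if group == "pos":
        i_size, i_hydro = _CONTINUOUS.index("size_diff"), _CONTINUOUS.index("hydro_diff")
        i_cle, i_tap = _CONTINUOUS.index("cleavage"), _CONTINUOUS.index("tap")
        c[i_size, i_hydro] = c[i_hydro, i_size] = 0.5
        c[i_cle, i_tap] = c[i_tap, i_cle] = 0.4
    return c


@dataclass
class GeneratorConfig:
    """Study-scale parameters of the synthetic cohorts.

    ``effect_shift`` is the upward mean shift of the positive group per
    feature, in SD units of that feature's marginal; defaults put the
    separation on the antigen-supply scores only. ``label_beta`` is the
    logistic coefficient per SD of the ER-delivery composite in
    sequence-level mode.
    """

    n_pos: int = 35
    n_neg: int = 450
    effect_shift: dict = field(
        default_factory=lambda: {"expression": 1.0, "tap": 1.0, "cleavage": 0.8}
    )
    corr_pos: np.ndarray | None = None
    corr_neg: np.ndarray | None = None
    polar_change_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)
    label_beta: float = 3.0
    protein_length: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("group sizes must be >= 1")
        if not all(math.isfinite(v) for v in self.effect_shift.values()):
            raise ValueError("effect shifts must be finite")
        unknown = set(self.effect_shift) - set(_CONTINUOUS)
        if unknown:
            raise ValueError(f"effect_shift names unknown features: {sorted(unknown)}")

    def corr(self, group: str) -> np.ndarray:
        c = self.corr_pos if group == "pos" else self.corr_neg
        c = _default_corr(group) if c is None else np.asarray(c, dtype=float)
        if c.shape != (len(_CONTINUOUS),) * 2 or not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric 6x6")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return c


def _draw_group(rng: np.random.Generator, n: int, group: str, cfg: GeneratorConfig) -> pd.DataFrame:
    corr = cfg.corr(group)
    z = rng.multivariate_normal(np.zeros(len(_CONTINUOUS)), corr, size=n, method="cholesky")
    cols = {}
    for j, feat in enumerate(_CONTINUOUS):
        mu, sd = _MARGINALS[feat]
        shift = cfg.effect_shift.get(feat, 0.0) if group == "pos" else 0.0
        x = mu + sd * (z[:, j] + shift)
        if feat == "cleavage":
            x = 1.0 / (1.0 + np.exp(-x))  # squash logit into a probability
        elif feat in ("size_diff", "hydro_diff", "charge_diff"):
            x = np.abs(x)  # delta features are non-negative by construction
        cols[feat] = x
    cols["polar_change"] = rng.choice(3, size=n, p=cfg.polar_change_probs)
    return pd.DataFrame(cols)


def generate_feature_level(config: GeneratorConfig | None = None) -> LabeledDataset:
    """Draw a labeled feature table directly from the group distributions."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    pos = _draw_group(rng, cfg.n_pos, "pos", cfg)
    neg = _draw_group(rng, cfg.n_neg, "neg", cfg)
    feats = pd.concat([pos, neg], ignore_index=True)[FEATURE_COLUMNS]
    feats.index = [f"synth{m:04d}" for m in range(len(feats))]
    labels = np.concatenate([np.ones(cfg.n_pos, int), np.zeros(cfg.n_neg, int)])
    return LabeledDataset(features=feats, labels=labels, provenance="synthetic/feature_level")


@dataclass
class SequenceLevelData:
    """A sequence-level synthetic cohort plus its ground truth."""

    proteome: dict[str, str]
    mutations: pd.DataFrame
    expression: pd.DataFrame  # gene_id, fpkm
    dataset: LabeledDataset
    truth: pd.DataFrame  # candidate_id, peptide, er_delivery, p_reactive, label
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit exactly the formats the pipeline reads, plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "mutations": outdir / "mutations.tsv",
            "expression": outdir / "expression.tsv",
            "features": outdir / "features.csv",
            "truth": outdir / "truth.csv",
        }
        with open(paths["proteome"], "w") as fh:
            for pid, seq in self.proteome.items():
                fh.write(f">{pid}\n{seq}\n")
        self.mutations.to_csv(paths["mutations"], sep="\t", index=False)
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        self.dataset.to_csv(paths["features"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def generate_sequence_level(config: GeneratorConfig | None = None) -> SequenceLevelData:
    """Generate a cohort through the real enumeration/featurization pipeline.

    One protein per variant (uniform residue composition), one candidate
    window sampled per mutation so the cohort has exactly
    ``n_pos + n_neg`` peptides; expression log-normal with log10 FPKM
    truncated at 0 (every gene passes the upstream FPKM >= 1 screen);
    labels Bernoulli(sigmoid(beta * z + c)) with z the standardized
    ER-delivery composite and the intercept c solved so the expected
    positive fraction equals n_pos / (n_pos + n_neg).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_pos + cfg.n_neg
    aa = np.array(list(CANONICAL_RESIDUES))
    tap = ps.TapScoringMatrix.default()
    cleav = ps.CleavageModel.default()
    props = default_table()

    proteome: dict[str, str] = {}
    mut_rows = []
    expr_rows = []
    feats = []
    ids = []
    peptides = []
    # log10 FPKM ~ truncated normal >= 0 (expressed genes only)
    log_fpkm = stats.truncnorm.rvs(
        (0.0 - 1.2) / 0.5, np.inf, loc=1.2, scale=0.5, size=n_total, random_state=rng
    )
    for i in range(n_total):
        pid = f"PROT{i:04d}"
        gid = f"GENE{i:04d}"
        L = cfg.protein_length
        seq = "".join(rng.choice(aa, size=L))
        pos = int(rng.integers(11, L - 9))  # full 9/10-mer windows on both sides
        wt = seq[pos - 1]
        mut = str(rng.choice([a for a in CANONICAL_RESIDUES if a != wt]))
        proteome[pid] = seq
        mut_rows.append(
            {"sample": "synthetic", "gene_id": gid, "protein_id": pid,
             "position": pos, "wt_aa": wt, "mut_aa": mut}
        )
        expr_rows.append({"gene_id": gid, "fpkm": 10.0 ** log_fpkm[i]})
        record = MutationRecord("synthetic", gid, pid, pos, wt, mut)
        cands = enumerate_candidates(seq, record, flank_width=cleav.window_half_width)
        cand = cands[int(rng.integers(len(cands)))]
        table = ps.ExpressionTable({gid: 10.0 ** log_fpkm[i]})
        feats.append(build_feature_vector(cand, table, tap, cleav, props))
        ids.append(cand.candidate_id)
        peptides.append(cand.peptide)

    features = pd.DataFrame(feats)
    features.index = ids
    er = (
        features["expression"] + features["tap"] + features["cleavage"]
    ).to_numpy()
    z = (er - er.mean()) / er.std()
    target = cfg.n_pos / n_total

    def mean_prob(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(cfg.label_beta * z + c)))))

    lo, hi = -50.0, 50.0
    if not mean_prob(lo) - target <= 0 <= mean_prob(hi) - target:
        raise ValueError(
            f"cannot achieve positive fraction {target:.3f}; achievable range "
            f"[{mean_prob(lo):.3f}, {mean_prob(hi):.3f}]"
        )
    c = optimize.brentq(lambda v: mean_prob(v) - target, lo, hi)
    p = 1.0 / (1.0 + np.exp(-(cfg.label_beta * z + c)))
    labels = rng.binomial(1, p)
    if labels.sum() < 2 or labels.sum() == n_total:
        raise ValueError(
            f"degenerate label draw (got {int(labels.sum())} positives of {n_total}); "
            "use a different seed or larger cohort"
        )
    dataset = LabeledDataset(
        features=features, labels=labels, provenance="synthetic/sequence_level"
    )
    truth = pd.DataFrame(
        {"candidate_id": ids, "peptide": peptides, "er_delivery": er,
         "p_reactive": p, "label": labels}
    )
    truth.attrs["intercept"] = c
    return SequenceLevelData(
        proteome=proteome,
        mutations=pd.DataFrame(mut_rows),
        expression=pd.DataFrame(expr_rows),
        dataset=dataset,
        truth=truth,
        config=cfg,
    )
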