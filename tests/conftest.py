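import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from neoreact.processing_scores import CleavageModel, ExpressionTable, TapScoringMatrix
from neoreact.residue_props import CANONICAL_RESIDUES, default_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props():
    return default_table()


@pytest.fixture(scope="session")
def toy_tap():
    """Toy TAP matrix: weight 1 for A at positions 1..8, 2 for K at 9, 5 for
    C at position 1; everything else 0."""
    w = pd.DataFrame(0.0, index=range(1, 10), columns=list(CANONICAL_RESIDUES))
    for i in range(1, 9):
        w.at[i, "A"] = 1.0
    w.at[9, "K"] = 2.0
    w.at[1, "C"] = 5.0
    return TapScoringMatrix(w, alpha=0.2, nterm_span=3)


@pytest.fixture(scope="session")
def zero_tap():
    w = pd.DataFrame(0.0, index=range(1, 10), columns=list(CANONICAL_RESIDUES))
    return TapScoringMatrix(w)


def make_cleavage(bias=0.0, half_width=1, weights=None):
    w = pd.DataFrame(
        0.0,
        index=[o for o in range(-half_width, half_width + 1) if o != 0],
        columns=list(CANONICAL_RESIDUES),
    )
    for (off, aa), v in (weights or {}).items():
        w.at[off, aa] = v
    return CleavageModel(position_weights=w, bias=bias)


@pytest.fixture(scope="session")
def zero_cleavage():
    return make_cleavage(bias=0.0)


@pytest.fixture(scope="session")
def toy_proteome():
    rng = np.random.default_rng(77)
    aa = np.array(list(CANONICAL_RESIDUES))
    return {f"P{i}": "".join(rng.choice(aa, size=40)) for i in range(5)}


@pytest.fixture(scope="session")
def toy_mutations(toy_proteome):
    rows = []
    for i, (pid, seq) in enumerate(sorted(toy_proteome.items())):
        pos = 15 + i
        wt = seq[pos - 1]
        mut = "A" if wt != "A" else "V"
        rows.append(
            {"sample": "s1", "gene_id": f"G{i}", "protein_id": pid,
             "position": pos, "wt_aa": wt, "mut_aa": mut}
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def toy_expression():
    return ExpressionTable({f"G{i}": float(2 + 3 * i) for i in range(5)})
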