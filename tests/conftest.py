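import numpy as np
import pandas as pd
import pytest

import epiland as ep


@pytest.fixture(scope="session")
def small_landscape():
    """A modest planted landscape shared by clustering tests."""
    spec = ep.LandscapeSpec(n_genes=800, n_unexpressed=1200)
    return spec, ep.gen_landscape(spec, seed=11)


@pytest.fixture(scope="session")
def small_delta(small_landscape):
    spec, land = small_landscape
    return ep.make_delta(land.gh, land.sh, land.expressed_genes)


@pytest.fixture()
def tiny_signal_pair():
    genes = ["gA", "gB", "gC"]
    gh = ep.SignalMatrix(
        "mRNA", "GH",
        pd.DataFrame({"r1": [2.0, 4.0, 6.0], "r2": [2.0, 4.0, 6.0]}, index=genes),
    )
    sh = ep.SignalMatrix(
        "mRNA", "SH",
        pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [1.0, 2.0, 3.0]}, index=genes),
    )
    return gh, sh


def sharp_motif(consensus: str, background=None, dominant=0.9) -> ep.MotifModel:
    """A near-degenerate PWM around a consensus string."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    mat = np.full((len(consensus), 4), (1.0 - dominant) / 3.0)
    for i, c in enumerate(consensus):
        mat[i, "ACGT".index(c)] = dominant
    return ep.MotifModel(
        motif_id=f"M_{consensus}", tf_gene="tf", matrix=mat, background=bg,
        pseudocount=1e-4,
    )
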