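import numpy as np
import pandas as pd
import pytest

from ylineage import generate, paper_like_preset
from ylineage.panel import MarkerPanel

PRESET_SEED = 11


@pytest.fixture(scope="session")
def preset():
    """One paper-like synthetic survey (table + ground-truth ledger)."""
    return generate(paper_like_preset(), PRESET_SEED)


@pytest.fixture(scope="session")
def preset_table(preset):
    return preset[0]


@pytest.fixture(scope="session")
def preset_ledger(preset):
    return preset[1]


@pytest.fixture
def tiny_panel():
    """A 2-band, 2-locus panel for hand-checkable fixtures."""
    return MarkerPanel(
        imm_markers={"IMMX": (10, 11)},
        msat_loci=("L1", "L2"),
        repeat_units={"L1": 2, "L2": 2},
    )


def tiny_frame(rows, panel):
    """Rows: (sample, pop, bands-present tuple, L1, L2)."""
    recs = []
    for sid, pop, bands, l1, l2 in rows:
        rec = {"sample_id": sid, "population": pop, "region": "R"}
        for marker, labels in panel.imm_markers.items():
            for b in labels:
                rec[f"{marker}_b{b}"] = int(b in bands)
        rec["L1"], rec["L2"] = l1, l2
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20260928))
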