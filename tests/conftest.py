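import numpy as np
import pandas as pd
import pytest

from sitefunc.seqio import ActivityTable, Alignment, GappedRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def toy_alignment():
    """Five-sequence toy family; TMPL is gap-free and serves as template."""
    rows = [
        ("TMPL", "MKYGAVILDW"),
        ("HOM1", "MKYGA-ILDW"),
        ("HOM2", "MKFGAVLLDW"),
        ("HOM3", "MR-GAVILEW"),
        ("HOM4", "MKYGSVILDW"),
    ]
    return Alignment(GappedRecord(i, s) for i, s in rows)


@pytest.fixture
def toy_activities():
    rates = pd.DataFrame(
        {"S1": [1.0, 2.0, 0.5, np.nan, 4.0], "S2": [0.1, 0.2, np.nan, 0.4, 0.8]},
        index=["TMPL", "HOM1", "HOM2", "HOM3", "HOM4"],
    )
    return ActivityTable(rates=rates, detection_floor=1e-3)


def random_gapped_alignment(rng, n_seqs=None, n_cols=None, gap_frac=0.15,
                            template_gapfree=False):
    """Random alignment over the full alphabet with scattered gaps."""
    from sitefunc.seqio import AMINO_ACIDS

    n_seqs = int(rng.integers(3, 9)) if n_seqs is None else n_seqs
    n_cols = int(rng.integers(8, 40)) if n_cols is None else n_cols
    records = []
    for k in range(n_seqs):
        chars = [AMINO_ACIDS[i] for i in rng.integers(0, 20, n_cols)]
        gappable = rng.random(n_cols) < gap_frac
        if template_gapfree and k == 0:
            gappable[:] = False
        for i in np.flatnonzero(gappable):
            chars[i] = "-"
        if all(c == "-" for c in chars):  # keep rows de-gappable
            chars[0] = "A"
        records.append(GappedRecord(f"seq{k:02d}", "".join(chars)))
    return Alignment(records)
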