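import numpy as np
import pandas as pd
import pytest

from tapseries import io as sio
from tapseries import simulate as sim


@pytest.fixture(scope="session")
def design():
    return sio.default_design()


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic dataset at seed 0: peptides, truths, protein table."""
    cfg = sim.SimConfig(seed=0)
    peptides, truths = sim.simulate_dataset(cfg)
    table = sio.infer_proteins(peptides, list(cfg.design))
    return cfg, peptides, truths, table


def make_protein_table(design, rows: dict[str, dict[str, float]], n_peptides: int = 2):
    """Small protein table from {accession: {sample_id: value}} (others NaN)."""
    sample_ids = sio.sample_columns(design)
    data = []
    for acc, vals in rows.items():
        data.append(
            {"gene_name": "", "n_unique_peptides": n_peptides,
             **{s: vals.get(s, np.nan) for s in sample_ids}}
        )
    out = pd.DataFrame(data, index=pd.Index(list(rows), name="accessions"))
    return out


@pytest.fixture
def tiny_design():
    """3 bait replicates at one time point + 3 controls (for closed-form tests)."""
    recs = [sio.SampleRecord(f"B{r}", "bait", 7.0, r) for r in "ABC"]
    recs += [sio.SampleRecord(f"W{r}", "control", z, "A") for r, z in zip("ABC", (7.0, 11.0, 19.0))]
    return recs
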