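import numpy as np
import pandas as pd
import pytest

from ampliconcna.amplicon_io import AmpliconPanel
from ampliconcna.pipeline import RunConfig, run_control_phase, run_tumor_phase
from ampliconcna.simulate import CnaSpec, SimConfig, simulate_cohort


def make_panel(n, chrom="chr1", gene_size=None, gc=None, length=None, start=1000):
    """Small in-memory panel: n amplicons, optionally grouped into genes."""
    rng = np.random.default_rng(0)
    gc = np.full(n, 0.5) if gc is None else np.asarray(gc, float)
    length = np.full(n, 100, int) if length is None else np.asarray(length, int)
    rows, pos = [], start
    for i in range(n):
        gene = f"G{i // gene_size + 1:03d}" if gene_size else f"G{i + 1:03d}"
        rows.append((chrom, pos, pos + int(length[i]), gene, float(gc[i])))
        pos += int(length[i]) + 100
    return AmpliconPanel(pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "gc"]))


GAIN_GENES = tuple(f"GENE{i:03d}" for i in (1, 2, 11, 12))
LOSS_GENES = tuple(f"GENE{i:03d}" for i in (21, 22, 31, 32))


@pytest.fixture(scope="session")
def tumor_cohort():
    """15 controls + 1 diploid tumor (c=1) with one-copy gains/losses on 8
    of 40 genes (8 amplicons each), noise sd 0.1."""
    cfg = SimConfig(
        n_genes=40,
        amplicons_per_gene=8,
        n_controls=15,
        cna_spec=(
            CnaSpec(GAIN_GENES, "gain", 1, 1.0),
            CnaSpec(LOSS_GENES, "loss", 1, 1.0),
        ),
        sample_noise_sd=0.1,
        seed=11,
    )
    cm, truth, ratios = simulate_cohort(cfg)
    return cm, truth, ratios, cfg


@pytest.fixture(scope="session")
def control_phase(tumor_cohort):
    cm, *_ = tumor_cohort
    return run_control_phase(cm, RunConfig(seed=11), control_names=cm.samples[:-1])


@pytest.fixture(scope="session")
def tumor_result(tumor_cohort, control_phase):
    cm, *_ = tumor_cohort
    return run_tumor_phase(
        cm.column("T01"), cm.panel, control_phase.baseline, RunConfig(seed=11),
        sample="T01",
    )
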