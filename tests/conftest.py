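import numpy as np
import pandas as pd
import pytest

from cnvdrive.io import ProbeCnvTable


def make_probe_table(rows, states, samples, controls=()):
    """Build a discrete ProbeCnvTable from (probe_id, chrom, start, end, genes)
    rows and a probe × sample int state matrix."""
    probes = pd.DataFrame(
        [(r[1], r[2], r[3], tuple(r[4])) for r in rows],
        columns=["chrom", "start", "end", "gene_ids"],
        index=pd.Index([r[0] for r in rows], name="probe_id"),
    )
    states = pd.DataFrame(
        np.asarray(states, dtype=np.int8), index=probes.index, columns=samples
    )
    table = ProbeCnvTable(probes=probes, states=states, control_samples=tuple(controls))
    table.validate()
    return table


@pytest.fixture(scope="session")
def scaled_config():
    """Builder for cohorts under the scaled synthetic study configuration."""
    from cnvdrive.simulate import SimulationConfig, simulate_cohort

    def build(seed, **overrides):
        kwargs = dict(
            seed=seed,
            n_samples=120,
            n_metastatic=40,
            n_genes=2000,
            n_pathways=50,
            driver_loss_freq_metastatic=0.6,
            driver_loss_freq_nonmetastatic=0.3,
        )
        kwargs.update(overrides)
        return simulate_cohort(SimulationConfig(**kwargs))

    return build


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by read-only tests."""
    from cnvdrive.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        seed=7, n_samples=60, n_metastatic=20, n_genes=300, n_pathways=20,
        driver_loss_freq_metastatic=0.7, driver_loss_freq_nonmetastatic=0.2,
    )
    return simulate_cohort(cfg)
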