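import numpy as np
import pandas as pd
import pytest

from heteroscan.panel import AccessionTable, GenotypePanel, HybridTable
from heteroscan.synthetic import PanelConfig, generate_hybrid_table, generate_panel


def make_panel(calls, chrom="chr01", positions=None, accessions=None, vclass="SNP"):
    """Hand-built panel from a (n_accessions, n_sites) code array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_sites = calls.shape
    positions = positions or [100 * (j + 1) for j in range(n_sites)]
    accessions = accessions or [f"acc{i:02d}" for i in range(n_acc)]
    classes = [vclass] * n_sites if isinstance(vclass, str) else list(vclass)
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["G" if c == "SNP" else "GT" for c in classes],
            "vclass": classes,
        }
    )
    return GenotypePanel(accessions=accessions, sites=sites, calls=calls)


def make_hybrids(pairs, system="3-line", status="superior"):
    rows = [
        (f"h{k}", f_id, m_id, system, status) for k, (f_id, m_id) in enumerate(pairs)
    ]
    return HybridTable(
        pd.DataFrame(rows, columns=["hybrid_id", "female_id", "male_id", "system", "status"])
    )


def make_accessions(spec):
    """spec: list of (id, role, subgroup)."""
    return AccessionTable(pd.DataFrame(spec, columns=["id", "role", "subgroup"]))


@pytest.fixture(scope="session")
def default_panel():
    """A mid-sized generated panel shared across read-only tests."""
    config = PanelConfig(seed=11, n_snps=8000, n_indels=800)
    panel, accessions, truth = generate_panel(config)
    return panel, accessions, truth, config


@pytest.fixture(scope="session")
def default_hybrids(default_panel):
    _, accessions, _, _ = default_panel
    return generate_hybrid_table(accessions, 40, 15, seed=12)
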