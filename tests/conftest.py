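import pandas as pd
import pytest
from hypothesis import settings

from airrtoolkit import SimulationSpec, simulate_repertoire

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def clean_tcr_repertoire():
    """300-cell TCR repertoire with no doublets/dropout: exact recovery holds."""
    spec = SimulationSpec(
        n_cells=300,
        seed=11,
        doublet_rate=0.0,
        missing_chain_rate=0.0,
        multi_chain_rate=0.0,
    )
    return simulate_repertoire(spec)


@pytest.fixture(scope="session")
def messy_tcr_repertoire():
    """200-cell TCR repertoire with doublets, dropout and secondary chains."""
    spec = SimulationSpec(
        n_cells=200,
        seed=23,
        doublet_rate=0.05,
        missing_chain_rate=0.15,
        multi_chain_rate=0.1,
    )
    return simulate_repertoire(spec)


@pytest.fixture()
def tiny_contigs():
    """Hand-written normalised contig table for targeted assembly tests."""
    rows = [
        # barcode, locus, v, d, j, c, aa, nt, reads, umis, productive
        ("cellA", "TRA", "TRAV1", "NA", "TRAJ3", "TRAC", "CAVRF", "TGTGCTGTGAGGTTT", 50, 5, True),
        ("cellA", "TRB", "TRBV2", "TRBD1", "TRBJ4", "TRBC1", "CASSF", "TGTGCTAGCAGTTTT", 90, 9, True),
        ("cellB", "TRA", "TRAV5", "NA", "TRAJ1", "TRAC", "CAAAF", "TGTGCTGCAGCATTC", 10, 1, True),
        ("cellB", "TRA", "TRAV6", "NA", "TRAJ2", "TRAC", "CAGGF", "TGTGCTGGAGGATTT", 30, 9, True),
        ("cellC", "TRB", "TRBV9", "TRBD2", "TRBJ1", "TRBC2", "CASSLGF", "TGTGCTAGCAGTCTGGGGTTT", 40, 4, True),
        ("cellD", "TRB", "TRBV9", "TRBD2", "TRBJ1", "TRBC2", "CASSLGF", "TGTGCTAGCAGTCTGGGGTTT", 40, 4, False),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "barcode", "locus", "v_gene", "d_gene", "j_gene", "c_gene",
            "cdr3_aa", "cdr3_nt", "reads", "umis", "productive",
        ],
    ).assign(
        contig_id=lambda d: d["barcode"] + "_" + d.index.astype(str),
        sample_id="s1",
    )
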