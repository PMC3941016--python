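"""Shared fixtures: small simulated families and a genotype-file writer."""

import pandas as pd
import pytest

from famsnp import GenotypeTable, make_panel, simulate_family


def make_table(label, rows, **kw):
    """Build a GenotypeTable from (marker_id, chromosome, position, genotype) rows."""
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position", "genotype"])
    return GenotypeTable(label, df, **kw)


@pytest.fixture(scope="session")
def clean_family():
    """Error-free family: 20k markers, 8 chromosomes of 100 Mb, no deletions."""
    panel = make_panel(20_000, n_chromosomes=8, chrom_length=100_000_000, seed=11)
    return simulate_family(panel, error_x=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_family():
    """Family with undercall errors: 100k markers, x = 0.005."""
    panel = make_panel(100_000, n_chromosomes=8, chrom_length=100_000_000, seed=12)
    return simulate_family(panel, error_x=0.005, seed=12)


@pytest.fixture()
def genotype_file(tmp_path):
    """Write raw genotype text to a temp file and return its path."""

    def _write(text, name="sample.txt"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
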