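import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_fragment_table(rows):
    """Rows of (rna_id, term, prime, barcode, read_count) -> DataFrame."""
    return pd.DataFrame(
        rows,
        columns=["rna_id", "termination_pos", "priming_pos", "barcode", "read_count"],
    )


def write_pdb(path, atoms):
    """Write a minimal PDB file.

    ``atoms``: iterable of (serial, name, resname, chain, resseq, x, y, z, element).
    """
    lines = []
    for serial, name, resname, chain, resseq, x, y, z, element in atoms:
        padded = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {serial:5d} {padded:<4s} {resname:>3s} {chain:1s}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def fragment_table_factory():
    return make_fragment_table
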