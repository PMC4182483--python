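"""Shared fixtures: hand-written PDB snippets and a session-scoped synthetic
benchmark reused by the slower end-to-end tests."""

import pytest

from xcmasa.config import SearchConfig
from xcmasa.fixtures import FixtureSpec, make_benchmark
from xcmasa.statistics import load_abundance_table, load_evd_params
from xcmasa.templates import expand_library


def atom_line(serial, name, res, chain, seq, x, y, z, element,
              altloc=" ", occ=1.00, icode=" ", record="ATOM"):
    name_f = name if len(name) >= 4 else f" {name}"
    return (f"{record:<6s}{serial:5d} {name_f:<4s}{altloc}{res:<3s} {chain}"
            f"{seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}\n")


@pytest.fixture
def ser_pdb():
    """One serine: N, CA, CB, OG."""
    return (
        atom_line(1, "N", "SER", "A", 1, 0.0, 0.0, 0.0, "N")
        + atom_line(2, "CA", "SER", "A", 1, 1.46, 0.0, 0.0, "C")
        + atom_line(3, "CB", "SER", "A", 1, 2.00, 1.40, 0.0, "C")
        + atom_line(4, "OG", "SER", "A", 1, 2.50, 2.70, 0.0, "O")
        + "END\n"
    )


@pytest.fixture(scope="session")
def abundance():
    return load_abundance_table()


@pytest.fixture(scope="session")
def evd():
    return load_evd_params()


@pytest.fixture(scope="session")
def cfg():
    return SearchConfig()


@pytest.fixture(scope="session")
def benchmark_nom():
    """20 exact planted positives + 100 decoys, and the master library."""
    queries, lib = make_benchmark(FixtureSpec(seed=11))
    return queries, lib, expand_library(lib)


@pytest.fixture(scope="session")
def benchmark_mut():
    """Same recipe, but every positive alanine-scanned."""
    queries, lib = make_benchmark(FixtureSpec(mutation="alanine_scan", seed=11))
    return queries, lib, expand_library(lib)
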