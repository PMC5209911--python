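"""Shared fixtures: synthetic genome/annotation and one small simulation."""

from __future__ import annotations

import pytest

from chimkit import Genome, detect, read_gtf
from chimkit.filters import CATEGORIES
from chimkit.simulate import SimConfig, run_simulation
from chimkit.synthetic import SyntheticConfig, build_synthetic


@pytest.fixture(scope="session")
def syn_paths(tmp_path_factory):
    """Synthetic genome FASTA + GTF: 3 chromosomes, 75 multi-exon genes."""
    out = tmp_path_factory.mktemp("syn")
    syn = build_synthetic(SyntheticConfig(), seed=7)
    fasta, gtf = syn.write(out)
    return fasta, gtf


@pytest.fixture(scope="session")
def index(syn_paths):
    return read_gtf(str(syn_paths[1]))


@pytest.fixture(scope="session")
def genome(syn_paths):
    return Genome(str(syn_paths[0]))


@pytest.fixture(scope="session")
def sim_cfg():
    """Two chimeras per class, deep enough coverage for both read types."""
    return SimConfig(
        counts={c: 2 for c in CATEGORIES},
        coverage=30.0,
        bg_fraction=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_paths(syn_paths, sim_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return run_simulation(syn_paths[0], syn_paths[1], sim_cfg, out)


@pytest.fixture(scope="session")
def truth_junctions(sim_paths):
    """Truth (donor, acceptor) site pairs with class labels."""
    rows = {}
    with open(sim_paths["truth"]) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            key = ((f[6], int(f[7]), f[8]), (f[9], int(f[10]), f[11]))
            rows[key] = f[1]
    return rows


@pytest.fixture(scope="session")
def detection(sim_paths, syn_paths, tmp_path_factory):
    out = tmp_path_factory.mktemp("det")
    return detect(
        sim_paths["sam"], syn_paths[0], syn_paths[1], out_dir=out
    )
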