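from __future__ import annotations

import numpy as np
import pytest

from domesticscan.seqio import AlignmentMatrix
from domesticscan.synthpop import SimulationConfig, generate_dataset


def make_matrix(alleles, cds_length=None, gene_id="g", refs=None, alts=None,
                positions=None):
    """Build an AlignmentMatrix from a plain nested list of 0/1/-1 codes."""
    alleles = np.array(alleles, dtype=np.int8)
    if alleles.ndim == 1:
        alleles = alleles.reshape(len(alleles), 0)
    n, s = alleles.shape
    if cds_length is None:
        cds_length = max(3 * s, 3)
    if positions is None:
        positions = list(range(s))
    return AlignmentMatrix(
        gene_id=gene_id,
        sample_ids=[f"s{i}" for i in range(n)],
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=list(refs) if refs else ["A"] * s,
        alt_alleles=list(alts) if alts else ["T"] * s,
        alleles=alleles,
        cds_length=cds_length,
    )


def random_matrix(rng, n_samples=None, n_sites=None, missing_rate=0.0):
    """Random small matrix for oracle-equivalence checks."""
    n = n_samples or int(rng.integers(4, 9))
    s = n_sites or int(rng.integers(1, 20))
    alleles = rng.integers(0, 2, size=(n, s)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, s)) < missing_rate
        alleles[mask] = -1
    return make_matrix(alleles, cds_length=3 * max(s, 1))


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """A small synthetic panel on disk, shared across read-oriented tests."""
    outdir = tmp_path_factory.mktemp("panel")
    config = SimulationConfig(n_candidate_genes=6, n_neutral_genes=8,
                              cds_length=300, rng_seed=11)
    truth = generate_dataset(config, outdir)
    return {"dir": outdir, "config": config, "truth": truth}
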