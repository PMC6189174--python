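"""Shared fixtures: small hand-built matrices and a session-scoped synthetic plate."""

import numpy as np
import pandas as pd
import pytest

import glandscape as gl
from glandscape import noise_replicates as nr
from glandscape import qc_normalize as qn
from glandscape.matrix_io import CountMatrix


def make_matrix(
    counts,
    gene_ids=None,
    cell_ids=None,
    well_type="sample",
    lengths=1000,
    tissue=None,
    group=None,
) -> CountMatrix:
    """Build a CountMatrix from a plain array with minimal annotations.

    Gene ids starting with ``ERCC-`` are flagged as spike-ins.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_genes, n_cells = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(n_cells)]
    if np.isscalar(lengths):
        lengths = [lengths] * n_genes
    if isinstance(well_type, str):
        well_type = [well_type] * n_cells
    gene_table = pd.DataFrame(
        {
            "length_bp": lengths,
            "is_spikein": [g.startswith("ERCC-") for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cell_table = pd.DataFrame(
        {
            "patient": "P1",
            "tissue": tissue if tissue is not None else "T",
            "well_type": well_type,
            "group": group if group is not None else "G",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    values = pd.DataFrame(counts, index=gene_table.index, columns=cell_table.index)
    return CountMatrix(values, gene_table, cell_table)


@pytest.fixture(scope="session")
def plate():
    """Default synthetic plate (3 populations × 100 cells, 12 spike-ins, 6 controls)."""
    return gl.default_plate(7)


@pytest.fixture(scope="session")
def filtered_plate(plate):
    return gl.filter_cells(plate, gl.qc_threshold(plate))


@pytest.fixture(scope="session")
def normalized(filtered_plate):
    """(kept_genes, TPM matrix) after the FPKM and variability gene filters."""
    f = filtered_plate
    lengths = f.gene_table["length_bp"].to_dict()
    norm = qn.tmm_factors(f)
    mask = qn.filter_genes_fpkm(qn.fpkm(f, lengths, norm))
    tp = qn.tpm(f, lengths, mask.index[mask])
    cv = qn.filter_low_variability(tp)
    kept = cv.index[cv].tolist()
    return kept, qn.tpm(f, lengths, kept)


@pytest.fixture(scope="session")
def noise_model(filtered_plate):
    return nr.fit_noise_model(filtered_plate)
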