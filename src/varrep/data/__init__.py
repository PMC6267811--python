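"""Packaged reference tables.

``human_chromosomes.tsv`` carries, per nuclear chromosome (1-22, X, Y), the
protein-coding gene census (19,786 genes total, Ensembl protein-coding), the
summed coding-sequence length in nucleotides, and the per-chromosome counts
of the VariSNP neutral single-nucleotide variant benchmark (446,013 variants,
of which 445,989 carry a chromosome assignment).  These numbers drive the
worked chromosomal-distribution example and the gene-census weights used by
the synthetic proteome generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_chromosome_table() -> pd.DataFrame:
    """Human chromosome gene census, CDS lengths and VariSNP neutral counts.

    Returns a DataFrame indexed by chromosome label with columns
    ``n_genes``, ``cds_length_nt`` and ``varisnp_neutral_observed``.
    """
    with resources.files("varrep.data").joinpath("human_chromosomes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
    return df.set_index("chromosome")


def gene_census_weights() -> dict[str, int]:
    """Per-chromosome protein-coding gene counts (weights for expectations)."""
    return load_chromosome_table()["n_genes"].to_dict()


def cds_length_weights() -> dict[str, int]:
    """Per-chromosome summed coding-sequence lengths in nucleotides."""
    return load_chromosome_table()["cds_length_nt"].to_dict()


def varisnp_neutral_counts() -> dict[str, int]:
    """Observed per-chromosome variant counts of the VariSNP neutral set."""
    return load_chromosome_table()["varisnp_neutral_observed"].to_dict()
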