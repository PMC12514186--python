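"""Bundled external annotation inputs for the collation step.

The collation of candidate genes consumes externally curated inputs: gene
lists from published limb-proportion studies (JH — jerboa hindlimb; MY —
young vs. mature mouse tibia; TP — proximal tibia vs. distal phalanx;
SHR — human GWAS of leg-to-body proportion) and mouse tail-mutant phenotype
annotations mined from MGI. This module ships the curated membership table
for the 20 vertebral-proportion candidate genes that carry a tail phenotype
and/or appear in three or more of those datasets, as consumed inputs for
the collation operation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

EXTERNAL_DATASETS = ("SHR", "JH", "MY", "TP")


def load_candidate_memberships() -> pd.DataFrame:
    """The curated candidate table: per gene, its external-dataset tags and
    tail-phenotype flag.

    Returns a DataFrame indexed by ``gene_id`` with one boolean column per
    dataset in :data:`EXTERNAL_DATASETS` plus ``tail_phenotype``.
    """
    ref = resources.files("axoprop.data") / "tail_proportion_candidates.tsv"
    with resources.as_file(ref) as path:
        raw = pd.read_csv(path, sep="\t", index_col="gene_id",
                          keep_default_na=False)
    out = pd.DataFrame(index=raw.index)
    for ds in EXTERNAL_DATASETS:
        out[ds] = [ds in str(tags).split(",") for tags in raw["datasets"]]
    out["tail_phenotype"] = raw["tail_phenotype"].astype(str) == "True"
    return out


def external_gene_sets() -> dict[str, set[str]]:
    """The four external dataset memberships as named gene sets."""
    table = load_candidate_memberships()
    return {ds: set(table.index[table[ds]]) for ds in EXTERNAL_DATASETS}


def phenotype_gene_set() -> set[str]:
    """Genes with a reported mouse tail-mutant phenotype."""
    table = load_candidate_memberships()
    return set(table.index[table["tail_phenotype"]])
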