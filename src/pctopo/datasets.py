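"""Bundled worked-example data.

``load_gaucher_variants`` returns the published structural feature values
and assay outcomes for seven glucocerebrosidase (Gaucher disease)
variants: predicted ΔΔG of mutation (kcal/mol), ligand contact,
contact count, catalytic-domain membership, inverse-parallel relation
count, and observed responsiveness in cell-based chaperone assays (the
first three variants against N-nonyl-deoxynojirimycin, the last four
against Ambroxol). These rows are the standard smoke-test input for the
decision-tree classifier.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_gaucher_variants() -> pd.DataFrame:
    """Feature table for the seven reference Gaucher-disease variants."""
    with resources.files("pctopo.data").joinpath("gaucher_variants.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("binds_ligand", "catalytic_domain", "observed_responsive"):
        df[col] = df[col].astype(bool)
    return df
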