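"""Small reference tables bundled with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: number of brain regions in the published DTI region screen
N_REFERENCE_REGIONS = 23
#: number of candidate genes in the published imaging-genetics screen
N_REFERENCE_GENES = 61


def load_reference_roi_pvalues() -> pd.DataFrame:
    """Published ROI-vs-disease causal-test p-values at four timepoints.

    Columns: ``timepoint`` (baseline/m06/m12/m24), ``unit_id`` (ROI index),
    ``p_value`` (float as string; censored entries like ``"<0.00005"``).
    Only regions with p < 0.05 appear.  Used by the screening examples and
    by the validation suite to exercise the Bonferroni filter on real output.
    """
    ref = resources.files("neurocausal").joinpath("data/roi_causation_pvalues.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"p_value": str})
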