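"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def sweep_marker_frequencies() -> pd.DataFrame:
    """Reported per-group major-allele frequencies for candidate sweep
    markers in a Mediterranean durum-wheat landrace/cultivar panel — the
    worked example for the dual-allele ≥80% rule.

    Columns: hotspot_id, marker_id, position_cM, allele_group1,
    freq_group1, allele_group2, freq_group2.
    """
    ref = resources.files("eigensweep").joinpath("data/sweep_marker_frequencies.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"marker_id": str,
                                                  "allele_group1": str,
                                                  "allele_group2": str})
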