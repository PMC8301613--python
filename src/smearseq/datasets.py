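"""Bundled reference tables from the published 21-patient archival-smear
cohort: the curated pathogenic-mutation list (DNA panel) and the
fusion/karyotype list (RNA panel).  Both are small plain-text transcriptions
used as worked examples and fixtures."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("smearseq.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_cohort_mutations() -> pd.DataFrame:
    """Curated pathogenic mutations of the 21-patient smear DNA cohort.

    One row per (patient, mutation); gene '-' marks patients in whom no
    pathogenic mutation survived the cascade and curation.
    """
    return _load("cohort_mutations.tsv")


def load_cohort_fusions() -> pd.DataFrame:
    """Fusion calls, karyotypes and mapped-read totals of the 15-sample
    smear RNA cohort.  fusion '-' marks fusion-negative samples."""
    df = _load("cohort_fusions.tsv")
    df["mapped_reads"] = df["mapped_reads"].astype(int)
    return df
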