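"""Bundled example data.

The package ships the published worked example for the survival test: the
44 internal mutations (those present in at least three haplotypes) of the
fruitless C3 exon surveyed across three Anastrepha fruit-fly species,
with their effect class and descendant-haplotype counts f*, plus the tied
ranks as published.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def fruitless_internal_mutations() -> pd.DataFrame:
    """44 internal fruitless C3 exon mutations (9 nonsynonymous, 35 synonymous).

    Columns: ``mutation`` (label), ``effect``, ``f`` (descendant-haplotype
    count) and ``published_rank`` (tied rank as printed in the source
    survey; midranks recomputed from ``f`` reproduce it).
    """
    ref = resources.files("hapsurv.data").joinpath("fruitless_internal_mutations.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
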