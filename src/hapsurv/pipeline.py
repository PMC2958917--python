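"""Composition helpers: alignment -> haplotypes -> network -> mutation table.

Shared by the command-line interface and the calibration harness so both
run exactly the same analysis path.
"""

from __future__ import annotations

import pandas as pd

from .mutmap import annotate_mutations, tabulate_mutations
from .parsnet import ParsimonyNetwork, build_network, parsimony_limit
from .seqio import Alignment, HaplotypeTable, collapse_haplotypes
from .survtest import RankTestResult, filter_internal, mann_whitney_survival


def analyze_mutations(
    aln: Alignment,
    alpha_parsimony: float = 0.95,
    max_steps: int | None = None,
    count: str = "haplotypes",
    fallback: bool = False,
) -> tuple[HaplotypeTable, ParsimonyNetwork, pd.DataFrame]:
    """Collapse, build the parsimony network and annotate every mutation."""
    ht = collapse_haplotypes(aln)
    limit = parsimony_limit(len(ht.site_index), alpha_parsimony, override=max_steps)
    net = build_network(ht, limit)
    muts = annotate_mutations(net, fallback=fallback, count=count)
    return ht, net, tabulate_mutations(muts)


def survival_from_table(
    table: pd.DataFrame,
    min_f: int = 3,
    method: str = "auto",
    continuity: bool = True,
) -> tuple[RankTestResult | None, pd.DataFrame]:
    """Filter the mutation table and run the survival rank test.

    Returns ``(None, kept)`` when either effect group is empty after
    filtering (the test refuses to run on an empty group).
    """
    kept = filter_internal(table, min_f=min_f)
    f_non = kept.loc[kept["effect"] == "nonsynonymous", "f"]
    f_syn = kept.loc[kept["effect"] == "synonymous", "f"]
    if len(f_non) == 0 or len(f_syn) == 0:
        return None, kept
    res = mann_whitney_survival(f_non, f_syn, method=method, continuity=continuity)
    return res, kept
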