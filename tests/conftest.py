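import itertools

import numpy as np
import pytest

import ptcscape as P
from ptcscape.reads import VariantCountTable


@pytest.fixture(scope="session")
def design_2058():
    return P.get_design("2058-2062")


@pytest.fixture(scope="session")
def scheme():
    return P.builtin_barcodes()


def toy_design(k: int = 2, wt: str | None = None) -> P.LibraryDesign:
    """Tiny design for brute-force oracles (k = 1..3)."""
    return P.LibraryDesign(
        region_id=f"toy-{k}",
        positions=tuple(range(101, 101 + k)),
        wt_bases=wt or ("AU" + "GCA")[:k],
        upstream_anchor="GATTACCGTCAGGCAATCGA",
        downstream_anchor="CTTGAGCCAATGGTACGTCA",
    )


def noiseless_count_table(truth: P.TruthModel, depth_per_variant: int) -> VariantCountTable:
    """Expected (rounded, unsampled) counts under the selection model."""
    design = truth.design
    exp = P.SimulatedExperiment.with_depth_per_variant(design, truth, depth_per_variant)
    table = VariantCountTable(design_id=design.region_id)
    for cond in ("positive", "negative", "unselected"):
        freq = P.apply_selection(exp, cond)
        counts = np.round(freq * exp.depth_per_condition).astype(int)
        table.counts[cond] = {v: int(c) for v, c in zip(design.variants(), counts)}
    table.reads_in = sum(table.totals.values())
    return table


def count_table_from_dict(design, counts: dict) -> VariantCountTable:
    table = VariantCountTable(design_id=design.region_id)
    for cond, cv in counts.items():
        table.counts[cond] = dict(cv)
    table.reads_in = sum(table.totals.values())
    return table


def all_variants(k: int) -> list[str]:
    return ["".join(c) for c in itertools.product("ACGU", repeat=k)]
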