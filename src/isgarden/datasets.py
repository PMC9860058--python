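"""Packaged example data.

``load_insertion_catalog`` returns the bundled synthetic 142-clone insertion
catalog: a constructed stand-in for a sequenced reporter-trap screen across
the nine common gardens (the real per-clone records live in figures and
supplements that are not redistributable here).  Its garden-level structure
matches the experiment this package models — 142 clones, 34 in the 88-nt
5'-UTR and 108 in the 1422-nt CDS, with a dominant IS5-family element
carrying 65.7% of the CDS events — so it exercises every downstream
computation at realistic scale.

``demo_tables`` builds the matching environment and abundance tables for
the niche analysis: the environment table from the synthetic garden
generator (reporter GC recoding plus motif scans) and the abundance table
from the catalog's coding-region events.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from isgarden.catalog import InsertionEvent, build_count_matrix
from isgarden.io import read_events_tsv
from isgarden.simulate import GardenSpec, SimulationConfig, generate_gardens

GARDEN_ORDER = [
    "L_pA", "L_pB", "L_Ch",
    "M_pA", "M_pB", "M_Ch",
    "H_pA", "H_pB", "H_Ch",
]


def load_insertion_catalog() -> list[InsertionEvent]:
    """The bundled synthetic 142-clone insertion catalog."""
    ref = resources.files("isgarden") / "data" / "synthetic_catalog.tsv"
    with resources.as_file(ref) as path:
        return read_events_tsv(path)


def demo_tables(
    seed: int = 0, utr_len: int = 88
) -> tuple[list[GardenSpec], pd.DataFrame, pd.DataFrame]:
    """(gardens, environment table, abundance table) for the demo analysis.

    The abundance table counts coding-region clones per IS per garden from
    the bundled catalog; the environment table comes from the garden
    generator at the given seed (variant GC, replicon GC, enzyme activity,
    per-IS copy numbers and available-site counts).
    """
    events = load_insertion_catalog()
    cds_events = [e for e in events if e.position > utr_len]
    gardens, env = generate_gardens(SimulationConfig(seed=seed))
    env = env.loc[GARDEN_ORDER]
    is_ids = sorted({e.is_id for e in cds_events})
    abund = build_count_matrix(cds_events, gardens=GARDEN_ORDER, is_ids=is_ids)
    return gardens, env, abund
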