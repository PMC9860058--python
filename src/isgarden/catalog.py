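"""Bookkeeping and statistics over screened reporter mutants.

A sucrose counterselection screen yields (i) colony counts on selective and
non-selective plates, from which the mutation frequency is estimated, and
(ii) a catalog of sequenced insertion events — which IS landed where, in
which common garden, and in how many independent clones.  This module turns
those raw records into the quantities the niche analysis consumes:
TSS-relative partitions, hotspot calls, IS-by-garden count matrices,
mechanism proportions and Fisher-exact enrichment tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from isgarden.seq_design import TSD

MCLASSES = ("large_insertion", "snp_or_small_indel", "gene_loss")


@dataclass(frozen=True)
class PlatingCount:
    """One dilution-plating replicate.

    ``A`` colonies were counted on the selective plate after plating at
    dilution 10**-a; ``B`` on the non-selective plate at dilution 10**-b.
    """

    A: int
    a: int
    B: int
    b: int
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("colony counts must be non-negative")
        if self.a < 0 or self.b < 0:
            raise ValueError("dilution exponents must be non-negative")


@dataclass(frozen=True)
class InsertionEvent:
    """One sequenced insertion capture.

    ``position`` is 1-based relative to the transcription start site
    (+1 = first transcribed nucleotide), so the 5'-UTR occupies
    [1, utr_len] and the CDS the remainder.  ``n_clones`` counts the
    independent clones carrying this same event.
    """

    garden_id: str
    is_id: str
    position: int
    orientation: str = "unknown"
    tsd: TSD = field(default_factory=lambda: TSD("", 0))
    n_clones: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-", "unknown"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


@dataclass(frozen=True)
class MutationRecord:
    garden_id: str
    mclass: str
    expected_len: int
    observed_len: int | None

    def __post_init__(self) -> None:
        if self.mclass not in MCLASSES:
            raise ValueError(f"bad mutation class {self.mclass!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    is_id: str
    garden_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float
    scope: str


# ---------------------------------------------------------------------------


def mutation_frequency(pc: PlatingCount) -> float:
    """Mutation frequency from one plating replicate: (A/B) * 10**(a-b).

    ``A * 10**a`` estimates mutant CFU per plated volume of undiluted
    culture and ``B * 10**b`` the total CFU, so their ratio is the mutant
    fraction. Requires B > 0.
    """
    if pc.B == 0:
        raise ValueError("frequency undefined: zero colonies on the control plate")
    return (pc.A / pc.B) * 10.0 ** (pc.a - pc.b)


def classify_mutation(
    garden_id: str,
    expected_len: int,
    observed_len: int | None,
    large_threshold: int = 100,
) -> MutationRecord:
    """Triage a screened mutant by its diagnostic amplicon.

    No product at all means the reporter region is gone (``gene_loss``); a
    product more than ``large_threshold`` bp over the expected size is a
    ``large_insertion`` (candidate IS capture); anything else is a SNP or
    small indel.
    """
    if expected_len <= 0:
        raise ValueError("expected amplicon length must be positive")
    if observed_len is None:
        mclass = "gene_loss"
    elif observed_len - expected_len > large_threshold:
        mclass = "large_insertion"
    else:
        mclass = "snp_or_small_indel"
    return MutationRecord(garden_id, mclass, expected_len, observed_len)


def partition_by_region(
    events: list[InsertionEvent], utr_len: int = 88, cds_len: int = 1422
) -> tuple[int, int]:
    """Clone counts in the 5'-UTR vs the coding region.

    Positions are TSS-relative; the UTR spans [1, utr_len] and the CDS
    (utr_len, utr_len + cds_len]. Counts are weighted by ``n_clones``.
    """
    total_len = utr_len + cds_len
    bad = [e for e in events if not 1 <= e.position <= total_len]
    if bad:
        raise ValueError(
            "positions outside [1, %d]: %s"
            % (total_len, [(e.garden_id, e.is_id, e.position) for e in bad])
        )
    n_utr = sum(e.n_clones for e in events if e.position <= utr_len)
    n_cds = sum(e.n_clones for e in events) - n_utr
    return n_utr, n_cds


def hotspots(events: list[InsertionEvent]) -> pd.DataFrame:
    """Insertion positions whose clone tallies are Tukey outliers.

    Clones are tallied per distinct position; positions with tally above
    Q3 + 1.5 IQR (linear-interpolation quartiles) are flagged.  Fewer than
    four distinct positions cannot support fences: an empty frame is
    returned with a warning.
    """
    tally: dict[int, int] = {}
    for e in events:
        tally[e.position] = tally.get(e.position, 0) + e.n_clones
    out_cols = ["position", "n_clones", "fence"]
    if len(tally) < 4:
        warnings.warn("fewer than 4 distinct positions; no hotspot call possible")
        return pd.DataFrame(columns=out_cols)
    counts = np.array(list(tally.values()), dtype=float)
    q1, q3 = np.percentile(counts, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    rows = [
        {"position": pos, "n_clones": n, "fence": fence}
        for pos, n in sorted(tally.items())
        if n > fence
    ]
    return pd.DataFrame(rows, columns=out_cols)


def build_count_matrix(
    events: list[InsertionEvent],
    gardens: list[str] | None = None,
    is_ids: list[str] | None = None,
) -> pd.DataFrame:
    """IS-by-garden clone-count matrix (the "species x sites" table).

    Row/column order follows ``is_ids``/``gardens`` when given, else sorted
    label order; absent combinations are zero.
    """
    tally: dict[tuple[str, str], int] = {}
    for e in events:
        key = (e.is_id, e.garden_id)
        tally[key] = tally.get(key, 0) + e.n_clones
    rows = is_ids or sorted({k[0] for k in tally})
    cols = gardens or sorted({k[1] for k in tally})
    cm = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (i, g), n in tally.items():
        if i in cm.index and g in cm.columns:
            cm.loc[i, g] = n
        else:
            raise ValueError(f"event ({i}, {g}) outside the declared row/column sets")
    cm.index.name = "is_id"
    cm.columns.name = "garden_id"
    return cm


def mechanism_proportions(records: list[MutationRecord]) -> pd.DataFrame:
    """Per-garden fractions of mutation events by mechanism class."""
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        counts.setdefault(r.garden_id, dict.fromkeys(MCLASSES, 0))
        counts[r.garden_id][r.mclass] += 1
    out = pd.DataFrame(counts).T.reindex(columns=list(MCLASSES)).fillna(0)
    totals = out.sum(axis=1)
    props = out.div(totals.where(totals > 0, 1), axis=0)
    props.index.name = "garden_id"
    return props


def _fisher_table(
    cm: pd.DataFrame, is_id: str, garden_id: str, scope: str, replicon_of
) -> tuple[tuple[int, int], tuple[int, int]]:
    if scope == "replicon":
        rep = replicon_of(garden_id)
        cols = [g for g in cm.columns if replicon_of(g) == rep]
    elif scope == "all":
        cols = list(cm.columns)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    sub = cm[cols]
    a = int(sub.loc[is_id, garden_id])
    b = int(sub.loc[is_id].sum() - a)
    c = int(sub[garden_id].sum() - a)
    d = int(sub.values.sum() - a - b - c)
    return ((a, b), (c, d))


def default_replicon_of(garden_id: str) -> str:
    """Replicon label from garden ids of the form '<variant>_<replicon>'."""
    return garden_id.split("_", 1)[1] if "_" in garden_id else garden_id


def enrichment_fisher(
    cm: pd.DataFrame,
    is_id: str,
    garden_id: str,
    scope: str = "replicon",
    replicon_of=default_replicon_of,
) -> EnrichmentResult:
    """Two-sided Fisher exact test for enrichment of one IS in one garden.

    The 2x2 table partitions clone counts into {this IS vs other ISs} x
    {this garden vs the other gardens in scope}, where the scope is either
    the gardens sharing the focal garden's replicon (``'replicon'``) or all
    gardens (``'all'``).  A table with a zero margin carries no information:
    p = 1 with a warning.
    """
    table = _fisher_table(cm, is_id, garden_id, scope, replicon_of)
    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn(f"zero margin for ({is_id}, {garden_id}); p set to 1")
        return EnrichmentResult(is_id, garden_id, table, float("nan"), 1.0, scope)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return EnrichmentResult(is_id, garden_id, table, float(odds), float(p), scope)


def enrichment_scan(
    cm: pd.DataFrame, scope: str = "replicon", replicon_of=default_replicon_of
) -> pd.DataFrame:
    """Fisher enrichment for every (IS, garden) cell, with BH-adjusted q-values."""
    rows = []
    for is_id in cm.index:
        for garden_id in cm.columns:
            r = enrichment_fisher(cm, is_id, garden_id, scope, replicon_of)
            rows.append(
                {
                    "is_id": is_id,
                    "garden_id": garden_id,
                    "count": int(cm.loc[is_id, garden_id]),
                    "odds_ratio": r.odds_ratio,
                    "p": r.p_two_sided,
                }
            )
    out = pd.DataFrame(rows)
    out["q_bh"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out
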