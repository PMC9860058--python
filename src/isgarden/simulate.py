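"""Generative model of IS insertion capture in intracellular common gardens.

Everything the analysis pipeline consumes can be simulated here with the
statistical structure the analysis assumes: nine gardens formed by three
GC-recoded reporter variants placed on three replicons, an IS community
with degenerate target motifs and replicon-biased copy numbers, insertion
events drawn from a log-linear niche-preference model, full mutant alleles
for TSD round-trips, and dilution-plating colony counts.

The insertion-intensity model for IS i in garden g is

    lambda_ig = baseline_i * exp(beta_i . z_g) * sites_ig ** gamma_i

where z_g is the garden's standardized environment vector, beta_i the IS's
preference weights over named variables, sites_ig its available-target-site
count and gamma_i a site-dependence exponent.  beta_i = 0 and equal sites
recover the indifference null the permutation tests assume.  This kernel is
the test harness's modelling assumption, chosen because it nests that null
and yields tunable marginality; it is not an estimate of any real system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from isgarden.catalog import InsertionEvent, PlatingCount
from isgarden.seq_design import (
    CodingSequence,
    NucleotideSequence,
    RecodedVariant,
    TSD,
    TargetMotif,
    gc_fraction,
    recode_to_gc,
    scan_motif,
)

#: Default reporter geometry: 88-nt 5'-UTR followed by a 1422-nt CDS.
UTR_LEN = 88
CDS_LEN = 1422

#: Default garden layout: GC-variant x replicon. Replicon GC% mirrors a
#: multipartite rhizobial genome (symbiosis plasmid pA 59%, chromid pB 62%,
#: chromosome Ch 62.6%); reporter variant GC% are 38.8 (wild-type low-GC
#: levansucrase gene), 54.6 (medium) and 61.6 (high).
VARIANT_GC = {"L": 0.388, "M": 0.546, "H": 0.616}
REPLICON_GC = {"pA": 59.0, "pB": 62.0, "Ch": 62.6}
#: Levansucrase activity model (arbitrary units): a variant-level base — the
#: high-GC recode is closer to host codon usage and is assigned the higher
#: expression — modulated by a replicon factor (weaker expression from the
#: accessory low-GC replicon) and, in the generator, a small seeded
#: measurement jitter, since activity is assayed per strain.
VARIANT_ACTIVITY = {"L": 1.0, "M": 1.6, "H": 2.2}
REPLICON_ACTIVITY_FACTOR = {"pA": 0.85, "pB": 1.0, "Ch": 1.05}
ACTIVITY_JITTER_SD = 0.05  # lognormal sigma on the measured value


@dataclass
class GardenSpec:
    """One common garden: a reporter variant at a position on a replicon."""

    garden_id: str
    replicon_id: str
    replicon_gc: float
    variant_id: str
    variant: RecodedVariant
    reporter: NucleotideSequence  # UTR + CDS, TSS-relative coordinates
    activity: float
    copy_numbers: dict[str, int]


@dataclass
class ISProfile:
    """A simulated IS: target motif, length, and niche-preference parameters."""

    is_id: str
    family: str
    element_length: int
    motif: TargetMotif
    baseline_rate: float = 1.0
    preference: dict[str, float] = field(default_factory=dict)  # variable -> beta
    site_exponent: float = 1.0
    hotspot_concentration: float = math.inf

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.element_length <= 0:
            raise ValueError("element_length must be positive")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_events: int = 150
    sampling: str = "multinomial"  # or "poisson" (per-cell Poisson)
    strand: str = "forward"
    # plating model
    true_mutant_fraction: float = 1e-5
    culture_size: float = 2e9
    dilution_a: int = 0
    dilution_b: int = 5
    plated_volume_factor: float = 1e-1
    n_plating_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not 0.0 <= self.true_mutant_fraction <= 1.0:
            raise ValueError("true_mutant_fraction must lie in [0, 1]")
        if self.sampling not in ("multinomial", "poisson"):
            raise ValueError(f"unknown sampling scheme {self.sampling!r}")


# ---------------------------------------------------------------------------
# Sequence generation


def random_cds(
    n_codons: int = CDS_LEN // 3,
    gc: float = VARIANT_GC["L"],
    seed: int | np.random.Generator = 0,
    id: str = "reporter",
) -> CodingSequence:
    """A random CDS (start codon, no internal stops, terminal stop) near a GC target.

    Nucleotides are drawn with GC-biased composition, stop codons are
    resampled away, and a final synonymous recoding pass pins the GC
    fraction to the target as closely as synonymy permits.
    """
    if n_codons < 3:
        raise ValueError("need at least start, one internal codon, and stop")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(["A", "G", "C", "T"])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(bases, size=3, p=p))
            if codon not in stops:
                codons.append(codon)
                break
    codons.append("TAA")
    draft = CodingSequence(id=id, residues="".join(codons))
    pinned = recode_to_gc(draft, target_gc=gc, direction="nearest")
    return pinned.as_cds(id=id)


def random_sequence(
    length: int, gc: float, seed: int | np.random.Generator = 0, id: str = "seq"
) -> NucleotideSequence:
    """A random DNA sequence of the given length and expected GC fraction."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    residues = "".join(rng.choice(np.array(["A", "G", "C", "T"]), size=length, p=p))
    return NucleotideSequence(id=id, residues=residues)


# ---------------------------------------------------------------------------
# Default IS community


def default_is_profiles() -> list[ISProfile]:
    """A realistic default IS roster for fixtures and simulations.

    Mirrors the qualitative shape of a rhizobial IS community: a dominant
    IS5-family element with a W-N-A target and strong preference for
    low-GC reporters on the low-GC replicon; an IS1595-family element with
    a W-H-W target and similar but weaker preferences; an IS3-family
    element with flexible targeting (site exponent ~0) preferring the
    high-GC reporter on the low-GC replicon; an IS630-family TA-targeting
    element; and two minor players, one with a long specific target site.
    """
    return [
        ISProfile(
            "IS5_1", "IS5", 1252, TargetMotif("IS5_1", "WNA"),
            baseline_rate=3.0,
            preference={"sacB_GC": -1.2, "Replicon_GC": -0.8},
            site_exponent=1.0,
            hotspot_concentration=0.5,
        ),
        ISProfile(
            "IS1595_1", "IS1595", 1057, TargetMotif("IS1595_1", "WHW"),
            baseline_rate=1.0,
            preference={"sacB_GC": -0.8, "Replicon_GC": -0.6},
            site_exponent=1.0,
            hotspot_concentration=0.5,
        ),
        ISProfile(
            "IS3_1", "IS3", 1497, TargetMotif("IS3_1", "NNN"),
            baseline_rate=60.0,
            preference={"sacB_GC": 0.7, "Replicon_GC": -0.7},
            site_exponent=0.0,
        ),
        ISProfile(
            "IS630_1", "IS630", 1156, TargetMotif("IS630_1", "TA"),
            baseline_rate=0.8,
            preference={"sacB_GC": -0.6},
            site_exponent=1.0,
            hotspot_concentration=1.0,
        ),
        ISProfile(
            "IS4_1", "IS4", 838, TargetMotif("IS4_1", "TWA"),
            baseline_rate=0.4,
            preference={},
            site_exponent=1.0,
        ),
        ISProfile(
            "IS1182_1", "IS1182", 1330, TargetMotif("IS1182_1", "AACTACCG"),
            baseline_rate=30.0,
            preference={},
            site_exponent=0.0,
        ),
        ISProfile(
            "IS5_2", "IS5", 1199, TargetMotif("IS5_2", "TNA"),
            baseline_rate=0.2,
            preference={"sacB_GC": -0.4},
            site_exponent=1.0,
        ),
        ISProfile(
            "IS3_2", "IS3", 1443, TargetMotif("IS3_2", "ATAT"),
            baseline_rate=10.0,
            preference={"sacB_GC": 0.4, "Replicon_GC": -0.4},
            site_exponent=0.0,
        ),
        ISProfile(
            "IS256_1", "IS256", 1333, TargetMotif("IS256_1", "ATA"),
            baseline_rate=0.1,
            preference={},
            site_exponent=1.0,
        ),
        ISProfile(
            "IS110_1", "IS110", 1450, TargetMotif("IS110_1", "TCA"),
            baseline_rate=8.0,
            preference={},
            site_exponent=0.0,
        ),
    ]


#: Default per-replicon IS copy numbers: most mobile elements concentrate on
#: the low-GC accessory replicon.
DEFAULT_COPY_NUMBERS: dict[str, dict[str, int]] = {
    "IS5_1": {"pA": 7, "pB": 1, "Ch": 0},
    "IS1595_1": {"pA": 4, "pB": 1, "Ch": 1},
    "IS3_1": {"pA": 0, "pB": 2, "Ch": 3},
    "IS630_1": {"pA": 3, "pB": 2, "Ch": 2},
    "IS4_1": {"pA": 2, "pB": 1, "Ch": 1},
    "IS1182_1": {"pA": 1, "pB": 1, "Ch": 0},
    "IS5_2": {"pA": 2, "pB": 0, "Ch": 0},
    "IS3_2": {"pA": 0, "pB": 1, "Ch": 2},
    "IS256_1": {"pA": 1, "pB": 0, "Ch": 0},
    "IS110_1": {"pA": 0, "pB": 0, "Ch": 1},
}


# ---------------------------------------------------------------------------
# Garden and environment-table generation


def generate_gardens(
    config: SimulationConfig | None = None,
    base_cds: CodingSequence | None = None,
    profiles: list[ISProfile] | None = None,
    copy_numbers: dict[str, dict[str, int]] | None = None,
    activity: dict[str, float] | None = None,
) -> tuple[list[GardenSpec], pd.DataFrame]:
    """Build the nine default gardens and their environment table.

    The three reporter GC variants are produced from ``base_cds`` by
    synonymous recoding; available-target-site columns are computed by
    scanning each variant's CDS with each IS's motif.  The environment
    table rows are gardens, columns are: sacB_GC, Replicon_GC,
    Levansucrase, one N_<is> copy-number column per IS and one
    Sites_<is> available-site column per IS.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    profiles = profiles if profiles is not None else default_is_profiles()
    copy_numbers = copy_numbers or DEFAULT_COPY_NUMBERS
    activity = activity or VARIANT_ACTIVITY
    if base_cds is None:
        base_cds = random_cds(CDS_LEN // 3, gc=VARIANT_GC["L"], seed=rng)
    utr = random_sequence(UTR_LEN, gc=0.361, seed=rng, id="utr")

    variants: dict[str, RecodedVariant] = {}
    for vid, target in VARIANT_GC.items():
        variants[vid] = recode_to_gc(base_cds, target_gc=target, direction="nearest")

    gardens: list[GardenSpec] = []
    rows = []
    for vid in VARIANT_GC:
        for rep in REPLICON_GC:
            gid = f"{vid}_{rep}"
            var = variants[vid]
            reporter = NucleotideSequence(
                id=f"reporter_{gid}",
                residues=utr.residues + var.residues,
                origin_note=f"UTR+CDS for garden {gid}",
            )
            cn = {p.is_id: copy_numbers.get(p.is_id, {}).get(rep, 0) for p in profiles}
            measured_activity = (
                activity[vid]
                * REPLICON_ACTIVITY_FACTOR[rep]
                * math.exp(rng.normal(0.0, ACTIVITY_JITTER_SD))
            )
            gardens.append(
                GardenSpec(
                    garden_id=gid,
                    replicon_id=rep,
                    replicon_gc=REPLICON_GC[rep],
                    variant_id=vid,
                    variant=var,
                    reporter=reporter,
                    activity=measured_activity,
                    copy_numbers=cn,
                )
            )
            row = {
                "garden_id": gid,
                "sacB_GC": var.achieved_gc * 100.0,
                "Replicon_GC": REPLICON_GC[rep],
                "Levansucrase": measured_activity,
            }
            for p in profiles:
                row[f"N_{p.is_id}"] = cn[p.is_id]
            for p in profiles:
                row[f"Sites_{p.is_id}"] = len(
                    scan_motif(var.residues, p.motif, strand=config.strand)
                )
            rows.append(row)
    env = pd.DataFrame(rows).set_index("garden_id")
    return gardens, env


# ---------------------------------------------------------------------------
# Insertion simulation


def _standardize(env: pd.DataFrame) -> pd.DataFrame:
    sd = env.std(axis=0, ddof=0)
    keep = sd[sd > 0].index
    return (env[keep] - env[keep].mean(axis=0)) / sd[keep]


def _site_positions(garden: GardenSpec, profile: ISProfile, strand: str) -> list[int]:
    return scan_motif(garden.reporter, profile.motif, strand=strand)


def simulate_insertions(
    gardens: list[GardenSpec],
    profiles: list[ISProfile],
    config: SimulationConfig,
    env: pd.DataFrame | None = None,
) -> tuple[list[InsertionEvent], dict]:
    """Draw insertion events from the log-linear niche-preference model.

    Returns the event list and a truth record: the intensity matrix, each
    IS's preference parameters, and the per-(IS, garden) expected shares —
    enough for parameter-recovery tests to know which ISs were built
    niche-differentiated and toward which gardens.
    """
    rng = np.random.default_rng(config.seed)
    if env is None:
        _, env = generate_gardens(config, profiles=profiles)
        env = env.loc[[g.garden_id for g in gardens]]
    Z = _standardize(env)

    site_map: dict[tuple[str, str], list[int]] = {}
    kept: list[ISProfile] = []
    for p in profiles:
        any_sites = False
        for g in gardens:
            sites = _site_positions(g, p, config.strand)
            site_map[(p.is_id, g.garden_id)] = sites
            if sites:
                any_sites = True
        if any_sites:
            kept.append(p)
        else:
            import warnings

            warnings.warn(f"IS {p.is_id} has no target site in any garden; skipped")

    lam = np.zeros((len(kept), len(gardens)))
    for i, p in enumerate(kept):
        beta = np.zeros(Z.shape[1])
        for var, b in p.preference.items():
            if var not in Z.columns:
                raise KeyError(f"preference variable {var!r} not in environment table")
            beta[Z.columns.get_loc(var)] = b
        for j, g in enumerate(gardens):
            n_sites = len(site_map[(p.is_id, g.garden_id)])
            if n_sites == 0:
                lam[i, j] = 0.0
                continue
            kernel = math.exp(float(beta @ Z.loc[g.garden_id].values))
            lam[i, j] = p.baseline_rate * kernel * n_sites**p.site_exponent
    if lam.sum() == 0:
        raise ValueError("all insertion intensities are zero")

    if config.sampling == "multinomial":
        cells = rng.multinomial(config.n_events, (lam / lam.sum()).ravel()).reshape(
            lam.shape
        )
    else:
        scale = config.n_events / lam.sum() if lam.sum() else 0.0
        cells = rng.poisson(lam * scale)

    events: list[InsertionEvent] = []
    for i, p in enumerate(kept):
        for j, g in enumerate(gardens):
            n = int(cells[i, j])
            if n == 0:
                continue
            sites = site_map[(p.is_id, g.garden_id)]
            if math.isfinite(p.hotspot_concentration):
                weights = rng.dirichlet(
                    np.full(len(sites), p.hotspot_concentration)
                )
            else:
                weights = np.full(len(sites), 1.0 / len(sites))
            picks = rng.multinomial(n, weights)
            for site_idx, n_clones in enumerate(picks):
                if n_clones == 0:
                    continue
                pos = sites[site_idx]
                tsd_len = p.motif.tsd_length
                tsd_seq = g.reporter.residues[pos - 1 : pos - 1 + tsd_len]
                events.append(
                    InsertionEvent(
                        garden_id=g.garden_id,
                        is_id=p.is_id,
                        position=pos,
                        orientation="+" if rng.random() < 0.5 else "-",
                        tsd=TSD(tsd_seq, len(tsd_seq)),
                        n_clones=int(n_clones),
                    )
                )
    truth = {
        "seed": config.seed,
        "intensity": pd.DataFrame(
            lam, index=[p.is_id for p in kept], columns=[g.garden_id for g in gardens]
        ),
        "expected_share": pd.DataFrame(
            lam / lam.sum(),
            index=[p.is_id for p in kept],
            columns=[g.garden_id for g in gardens],
        ),
        "preferences": {p.is_id: dict(p.preference) for p in kept},
        "differentiated": [p.is_id for p in kept if any(p.preference.values())],
    }
    return events, truth


# ---------------------------------------------------------------------------
# Allele construction (inverse of find_tsd)


def make_insertion_allele(
    ref: NucleotideSequence,
    pos: int,
    is_seq: str,
    tsd_len: int = 0,
    id: str | None = None,
) -> NucleotideSequence:
    """Mutant allele with ``is_seq`` inserted after 1-based ``pos``.

    The ``tsd_len`` nucleotides ending at ``pos`` are duplicated on the far
    side of the element, emulating staggered target cleavage:
    ``ref[1..pos] + is_seq + ref[pos-tsd_len+1..pos] + ref[pos+1..]``.
    """
    n = len(ref)
    if not 1 <= pos <= n:
        raise ValueError(f"pos {pos} outside sequence of length {n}")
    if tsd_len < 0 or tsd_len > pos:
        raise ValueError(f"tsd_len {tsd_len} invalid for pos {pos}")
    if not is_seq:
        raise ValueError("is_seq is empty")
    r = ref.residues
    mutant = r[:pos] + is_seq + r[pos - tsd_len : pos] + r[pos:]
    return NucleotideSequence(
        id=id or f"{ref.id}_ins{pos}",
        residues=mutant,
        origin_note=f"insertion of {len(is_seq)} nt after {pos}, TSD {tsd_len}",
    )


# ---------------------------------------------------------------------------
# Plating simulation


def simulate_plating(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[PlatingCount]:
    """Poisson colony counts for selective and non-selective plating.

    A ~ Poisson(N * f * 10**-a * v) and B ~ Poisson(N * 10**-b * v) for
    culture size N, true mutant fraction f and plated volume factor v.
    """
    rng = rng or np.random.default_rng(config.seed)
    N, f, v = config.culture_size, config.true_mutant_fraction, config.plated_volume_factor
    out = []
    for r in range(config.n_plating_replicates):
        A = rng.poisson(N * f * 10.0**-config.dilution_a * v)
        B = rng.poisson(N * 10.0**-config.dilution_b * v)
        out.append(
            PlatingCount(
                A=int(A), a=config.dilution_a, B=int(B), b=config.dilution_b,
                replicate=f"rep{r + 1}",
            )
        )
    return out
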