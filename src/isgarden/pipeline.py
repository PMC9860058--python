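"""End-to-end pipeline: design -> scan -> catalog -> niche statistics.

``run_pipeline`` ties the stages together and produces a JSON-serializable
report embedding the resolved configuration, so a run is reproducible from
the report alone.  Inputs may be supplied as files (event catalog,
environment table, abundance table) or simulated by the synthetic-data
generator when absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from isgarden import catalog as cat
from isgarden import io as igio
from isgarden import niche, simulate
from isgarden.config import RunConfig

REPORT_SCHEMA_VERSION = 1


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the report bundle as a dict."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "stages": {},
    }

    # --- design + environment -------------------------------------------
    sim_cfg = simulate.SimulationConfig(
        seed=config.seed, n_events=config.n_events, strand=config.strand
    )
    try:
        gardens, env = simulate.generate_gardens(sim_cfg)
        if config.env_path:
            env = igio.read_matrix_tsv(config.env_path, index_col="garden_id")
    except Exception as exc:  # pragma: no cover - stage naming only
        raise RuntimeError(f"stage 'design' failed: {exc}") from exc

    # --- events ----------------------------------------------------------
    try:
        if config.events_path:
            events = igio.read_events_tsv(config.events_path)
            truth = None
        else:
            events, truth = simulate.simulate_insertions(
                gardens, simulate.default_is_profiles(), sim_cfg, env=env
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'events' failed: {exc}") from exc

    # --- catalog ---------------------------------------------------------
    try:
        n_utr, n_cds = cat.partition_by_region(
            events, utr_len=config.utr_len, cds_len=config.cds_len
        )
        hs = cat.hotspots(events)
        cds_events = [e for e in events if e.position > config.utr_len]
        garden_ids = [g.garden_id for g in gardens]
        cm = cat.build_count_matrix(
            cds_events,
            gardens=[g for g in garden_ids if any(e.garden_id == g for e in cds_events)]
            or None,
        )
        enr = cat.enrichment_scan(cm, scope=config.enrichment_scope)
        report["stages"]["catalog"] = {
            "n_clones_total": int(sum(e.n_clones for e in events)),
            "n_utr": int(n_utr),
            "n_cds": int(n_cds),
            "hotspots": _jsonable(hs),
            "count_matrix": _jsonable(cm),
            "enrichment": _jsonable(enr),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'catalog' failed: {exc}") from exc

    # --- niche statistics -------------------------------------------------
    try:
        if config.abundance_path:
            abund = igio.read_matrix_tsv(config.abundance_path, index_col="is_id")
        else:
            abund = cm.reindex(columns=env.index, fill_value=0)
        abund = abund.loc[abund.sum(axis=1) > 0]
        Z = niche.standardize_env(env)
        res = niche.omi(abund, Z)
        perm = niche.omi_permutation_test(
            abund, Z, n_perm=config.n_perm, seed=config.seed
        )
        part = niche.delineate_subsets(Z, k=config.k)
        wit = niche.witomi(abund, Z, part, n_perm=config.n_perm, seed=config.seed)
        subset_sig = niche.subset_significance(
            Z, part, n_perm=config.n_perm, seed=config.seed
        )
        var_sig = niche.variable_significance(
            Z, part, n_perm=config.n_perm, seed=config.seed
        )
        report["stages"]["niche"] = {
            "variance_explained_pct": [float(v) for v in res.variance_explained],
            "eigenvalues": [float(v) for v in res.eigenvalues],
            "omi_params": _jsonable(res.params),
            "omi_permutation": _jsonable(perm),
            "subsets": {g: int(s) for g, s in part.labels.items()},
            "witomi": _jsonable(wit.reset_index()),
            "subset_significance": {
                k: {"observed": r.observed, "p": r.p, "p_normal_approx": r.p_normal_approx}
                for k, r in subset_sig.items()
            },
            "variable_significance": {
                v: {"observed": r.observed, "p": r.p} for v, r in var_sig.items()
            },
        }
        if truth is not None:
            report["stages"]["truth"] = {
                "differentiated": truth["differentiated"],
                "expected_share": _jsonable(truth["expected_share"]),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'niche' failed: {exc}") from exc

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        igio.write_events_tsv(events, out / "events.tsv")
        igio.write_matrix_tsv(env, out / "environment.tsv", comment="gardens x variables")
        igio.write_matrix_tsv(abund, out / "abundance.tsv", comment="IS x gardens")
    return report


def summarize(report: dict) -> str:
    """Human-readable one-screen summary of a report bundle."""
    cat_s = report["stages"]["catalog"]
    nic = report["stages"]["niche"]
    lines = [
        f"clones: {cat_s['n_clones_total']} "
        f"(5'-UTR {cat_s['n_utr']}, CDS {cat_s['n_cds']})",
        "variance explained by OMI axes (%): "
        + ", ".join(f"{v:.1f}" for v in nic["variance_explained_pct"][:3]),
        "subsets: " + ", ".join(f"{g}:{s}" for g, s in nic["subsets"].items()),
    ]
    perm = nic["omi_permutation"]
    idx = perm["index"]
    cols = perm["columns"]
    p_col = cols.index("p")
    omi_col = cols.index("omi")
    for is_id, row in zip(idx, perm["data"]):
        lines.append(f"  {is_id}: OMI={row[omi_col]:.3f} p={row[p_col]:.4g}")
    return "\n".join(lines)
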