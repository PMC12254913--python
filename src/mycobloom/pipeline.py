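"""End-to-end pipeline: simulate/load -> filter -> metrics -> report.

A single YAML config drives every stage; the ``sola2025`` preset pins the
study defaults (1000-read sample filter, 50 fungal reads for diversity, 5%
bloom threshold, 2-900 day periodogram at alpha 0.01, winter = Jan-Mar).
Each stage writes plain TSV/JSON artefacts into the output directory; a
run manifest with content digests is written last, so a completed manifest
certifies a complete, reproducible run.  On a stage failure the partial
outputs of that stage are renamed with a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import cra_table, select_major_taxa
from .blooms import bloom_fraction_by_month, detect_blooms, persistence
from .core_tables import (AsvTable, DataError, SampleFilterPolicy,
                          filter_samples, read_table, subset_fraction)
from .diversity import alpha_diversity, compare_diversity
from .growth import feasibility, required_mu, scenario
from .rhythm import RhythmRules, classify_rhythm
from .simulate import SimulationConfig, simulate_table, write_simulation

logger = logging.getLogger(__name__)

#: the study preset: every stage parameter at its published setting
SOLA2025 = {
    "filter": {"min_total_reads": 1000},
    "cra": {"group": "Fungi", "threshold": 0.9},
    "blooms": {"threshold": 0.05, "levels": [0.5, 0.9],
               "persistence_threshold": 0.10, "max_gap_days": 8},
    "rhythm": {"fraction": "gt3um"},
    "diversity": {"min_fungal_reads": 50, "group_by": ["season", "month",
                                                       "size_fraction"]},
    "growth": {"x": 1e5, "y": 2.5e-6, "t": 72.0, "mode": "printed"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if cfg.get("preset", "sola2025") == "sola2025":
        merged = {k: dict(v) for k, v in SOLA2025.items()}
        for key, val in cfg.items():
            if isinstance(val, dict) and key in merged:
                merged[key].update(val)
            else:
                merged[key] = val
        cfg = merged
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _get_table(cfg: dict, outdir: Path) -> AsvTable:
    if "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("counts", "taxonomy", "metadata"):
            p = Path(inp[key])
            if not p.exists():
                raise DataError(f"input file not found: {p}")
        return read_table(inp["counts"], inp["taxonomy"], inp["metadata"])
    sim_kwargs = dict(cfg.get("simulate", {}))
    sim_kwargs.setdefault("seed", cfg.get("seed", 42))
    for key in ("rhythmic_peak_ra", "chaotic_spike_ra", "ephemeral_ra",
                "ephemeral_duration_days", "fractions", "mixing_beta"):
        if key in sim_kwargs and isinstance(sim_kwargs[key], list):
            sim_kwargs[key] = tuple(sim_kwargs[key])
    table, truth = simulate_table(SimulationConfig(**sim_kwargs))
    write_simulation(table, truth, outdir / "simulated")
    return table


def run_pipeline(config_path, outdir) -> dict:
    """Run every stage defined in the config; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 42))
    manifest: dict = {
        "tool": "mycobloom",
        "version": __version__,
        "seed": seed,
        "config_sha256": _sha256(Path(config_path)),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
    }
    stage = "inputs"
    written: list[Path] = []
    try:
        table = _get_table(cfg, outdir)

        stage = "filter"
        policy = SampleFilterPolicy(
            min_total_reads=int(cfg["filter"]["min_total_reads"]),
            min_fungal_reads_for_diversity=int(cfg["diversity"]["min_fungal_reads"]),
        )
        table = filter_samples(table, policy)
        manifest["stages"]["filter"] = {"n_samples": table.n_samples,
                                        **dataclasses.asdict(policy)}

        stage = "cra"
        ccfg = cfg["cra"]
        records = cra_table(table, members=ccfg["group"], group=ccfg["group"])
        major = select_major_taxa(records, float(ccfg["threshold"]))
        cra_df = pd.DataFrame(
            [{"taxon_id": r.taxon_id, "group": r.group, "cra": r.cra,
              "n_samples": r.n_samples} for r in records]
        ).sort_values("cra", ascending=False)
        p = outdir / "cra.tsv"
        cra_df.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "major_set.json"
        p.write_text(json.dumps({
            "threshold": major.threshold,
            "taxon_ids": major.taxon_ids,
            "cumulative_coverage": major.cumulative_coverage,
        }, indent=1))
        written.append(p)
        manifest["stages"]["cra"] = {"n_records": len(records),
                                     "n_major": len(major.taxon_ids),
                                     "coverage": major.coverage}

        stage = "blooms"
        bcfg = cfg["blooms"]
        events = detect_blooms(table, threshold=float(bcfg["threshold"]),
                               levels=tuple(bcfg["levels"]))
        monthly = bloom_fraction_by_month(events, table)
        per_fraction_runs = {}
        for frac in sorted(set(table.samples["size_fraction"])):
            sub = subset_fraction(table, frac)
            order = sub.samples.sort_values("date")
            # duplicate dates within a fraction cannot enter one series
            uniq = order[~order["date"].duplicated()]
            ra = (sub.fungal_reads() / sub.total_reads()).loc[uniq.index]
            rep = persistence(uniq["date"], ra.to_numpy(),
                              threshold=float(bcfg["persistence_threshold"]),
                              max_gap_days=float(bcfg["max_gap_days"]))
            per_fraction_runs[frac] = {
                "max_run": rep.max_run,
                "runs": [[str(a.date()), str(b.date()), n] for a, b, n in rep.runs],
            }
        p = outdir / "blooms.json"
        p.write_text(json.dumps({
            "threshold": float(bcfg["threshold"]),
            "events": [{
                "sample_id": e.sample_id, "date": str(e.date.date()),
                "size_fraction": e.size_fraction, "ra_fungi": e.ra_fungi,
                "dominance": {str(k): v for k, v in e.dominance.m.items()},
            } for e in events],
            "bloom_fraction_by_month": monthly,
            "persistence": per_fraction_runs,
        }, indent=1))
        written.append(p)
        manifest["stages"]["blooms"] = {"n_events": len(events)}

        stage = "rhythm"
        rcfg = dict(cfg.get("rhythm", {}))
        frac = rcfg.pop("fraction", "gt3um")
        rules = RhythmRules(**{k: v for k, v in rcfg.items()
                               if k in RhythmRules.__dataclass_fields__})
        sub = subset_fraction(table, frac)
        ordered = sub.samples.sort_values("date")
        ordered = ordered[~ordered["date"].duplicated()]
        t0 = ordered["date"].iloc[0]
        times = (ordered["date"] - t0).dt.days.to_numpy(dtype=float)
        totals = sub.total_reads().loc[ordered.index].to_numpy(dtype=float)
        rows = []
        for aid in sub.fungal_ids():
            vals = sub.counts.loc[aid, ordered.index].to_numpy(dtype=float) / totals
            try:
                rc = classify_rhythm(times, vals, rules=rules)
                rows.append({"asv_id": aid, "label": rc.label,
                             "n_windows": rc.n_windows,
                             "peak_period": rc.peak_period,
                             "p_value": rc.p_value})
            except DataError:
                rows.append({"asv_id": aid, "label": "absent", "n_windows": 0,
                             "peak_period": None, "p_value": None})
        p = outdir / "rhythm.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
        manifest["stages"]["rhythm"] = {
            "fraction": frac,
            "n_classified": sum(r["label"] != "absent" for r in rows),
        }

        stage = "diversity"
        dcfg = cfg["diversity"]
        records_df = alpha_diversity(table, min_fungal_reads=int(dcfg["min_fungal_reads"]))
        p = outdir / "diversity.tsv"
        records_df.to_csv(p, sep="\t")
        written.append(p)
        comparisons = {}
        for by in dcfg.get("group_by", []):
            for index in ("shannon", "gini_simpson"):
                try:
                    gc = compare_diversity(records_df, index=index, by=by)
                    comparisons[f"{index}_by_{by}"] = {
                        "H": gc.h_statistic, "p": gc.p_value,
                        "pairwise": [list(row) for row in gc.pairwise],
                    }
                except DataError as exc:
                    comparisons[f"{index}_by_{by}"] = {"error": str(exc)}
        p = outdir / "diversity_tests.json"
        p.write_text(json.dumps(comparisons, indent=1))
        written.append(p)
        manifest["stages"]["diversity"] = {"n_samples": len(records_df)}

        stage = "growth"
        gcfg = cfg["growth"]
        sc = scenario(float(gcfg["x"]), float(gcfg["y"]), float(gcfg["t"]),
                      mode=gcfg.get("mode", "printed"))
        verdict = feasibility(sc.mu)
        p = outdir / "growth.json"
        p.write_text(json.dumps({
            "x": sc.x, "y": sc.y, "t_hours": sc.t, "mode": sc.mode,
            "mu_per_hour": sc.mu,
            "reference_range_per_hour": list(verdict.reference_range),
            "verdict": verdict.verdict,
        }, indent=1))
        written.append(p)
        manifest["stages"]["growth"] = {"mu_per_hour": sc.mu,
                                        "verdict": verdict.verdict}
    except Exception as exc:
        for p in written[-2:]:
            if p.exists() and stage in p.name:
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
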