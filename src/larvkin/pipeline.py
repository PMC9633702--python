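"""End-to-end pipeline driver: simulate -> qc -> kinfind -> dpg ->
ckmr-eval -> report.

Each stage writes its artifacts before the next stage reads them, no
stage mutates its inputs, and re-running with an identical configuration
reproduces identical outputs.  A provenance record (config hash, seed,
package version) accompanies every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ckmr, genoqc, io, kin, sibgraph, simdata, survey

log = logging.getLogger("larvkin")

STAGE_ORDER = ("simulate", "qc", "kinfind", "dpg", "ckmr_eval", "report")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "larvkin-out",
    "log_level": "INFO",
    "simulate": {},  # SimConfig field overrides
    "qc": {
        "maf_min": 0.05,
        "depth_min": 25.0,
        "thin_mode": "random",
        "dup_concordance": 0.95,
        "outlier_z": 3.5,
    },
    "kinfind": {"error_rate": 0.01, "cutoff_mode": "midpoint", "min_shared_loci": 100},
    "dpg": {"max_exact": 12, "resolve_conflicts": False},
    "ckmr_eval": {"n_adults": 100_000, "m_A": 500, "reps": 20_000},
    "report": {},
}


class PipelineConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the defaults, rejecting unknown keys."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    for source in (user, overrides or {}):
        for key, value in source.items():
            if key not in config:
                raise PipelineConfigError(f"unknown config key {key!r}")
            if isinstance(config[key], dict):
                if not isinstance(value, dict):
                    raise PipelineConfigError(f"config block {key!r} must be a mapping")
                if key != "simulate":
                    unknown = set(value) - set(config[key])
                    if unknown:
                        raise PipelineConfigError(
                            f"unknown keys in block {key!r}: {sorted(unknown)}"
                        )
                config[key].update(value)
            else:
                config[key] = value
    sim_fields = {f.name for f in dataclasses.fields(simdata.SimConfig)}
    unknown = set(config["simulate"]) - sim_fields
    if unknown:
        raise PipelineConfigError(f"unknown simulate keys: {sorted(unknown)}")
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _provenance(config: dict, out: Path) -> None:
    rec = {
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "version": __version__,
        "stages": list(STAGE_ORDER),
    }
    (out / "provenance.json").write_text(json.dumps(rec, indent=2))


def run_pipeline(config: dict, stages=STAGE_ORDER) -> dict:
    """Run the requested stages in fixed order; returns artifact paths."""
    out = io.ensure_outdir(config["out_dir"])
    logging.basicConfig(level=config.get("log_level", "INFO"))
    _provenance(config, out)
    artifacts: dict = {}
    seed = int(config["seed"])

    if "simulate" in stages:
        sim_cfg = simdata.SimConfig(**{**config["simulate"], "seed": seed})
        ped, tows, geno, loci, meta = simdata.simulate_dataset(sim_cfg)
        io.write_genotypes(geno, out / "genotypes.csv")
        io.write_loci(loci, out / "loci.csv")
        io.write_sample_meta(meta, out / "samples.csv")
        io.write_truth(ped.larvae, out / "truth.csv")
        log.info("simulate: %d samples x %d loci", geno.n_samples, geno.n_loci)
        artifacts.update(
            genotypes=out / "genotypes.csv",
            loci=out / "loci.csv",
            samples=out / "samples.csv",
            truth=out / "truth.csv",
        )

    if "qc" in stages:
        for name in ("genotypes", "loci"):
            path = artifacts.get(name, out / f"{name}.csv")
            if not Path(path).exists():
                raise FileNotFoundError(f"qc stage input missing: {path}")
        geno = io.read_genotypes(artifacts.get("genotypes", out / "genotypes.csv"))
        loci = io.read_loci(artifacts.get("loci", out / "loci.csv"))
        q = config["qc"]
        policy = genoqc.OutlierPolicy(q["outlier_z"], q["outlier_z"], q["outlier_z"])
        geno_f, loci_f, report = genoqc.run_qc(
            geno,
            loci,
            maf_min=q["maf_min"],
            depth_min=q["depth_min"],
            thin_mode=q["thin_mode"],
            dup_concordance=q["dup_concordance"],
            outlier_policy=policy,
            seed=seed,
        )
        io.write_genotypes(geno_f, out / "genotypes.filtered.csv")
        io.write_loci(loci_f, out / "loci.filtered.csv")
        report.to_frame().to_csv(out / "qc_report.csv", index=False)
        for row in report.stages:
            log.info("qc %-28s removed %5d retained %5d", row["stage"], row["n_removed"], row["n_retained"])
        artifacts.update(
            genotypes_filtered=out / "genotypes.filtered.csv",
            loci_filtered=out / "loci.filtered.csv",
            qc_report=out / "qc_report.csv",
        )

    if "kinfind" in stages:
        geno_f = io.read_genotypes(out / "genotypes.filtered.csv")
        loci_f = io.read_loci(out / "loci.filtered.csv")
        k = config["kinfind"]
        pairs, reference = kin.find_kin_pairs(
            geno_f,
            loci_f,
            error_rate=k["error_rate"],
            cutoff_mode=k["cutoff_mode"],
            min_shared_loci=k["min_shared_loci"],
        )
        io.write_kin_pairs(pairs, out / "kin_pairs.csv")
        ref_rows = [
            {
                "class": name,
                "mean": reference.means[name],
                "variance": reference.variances[name],
            }
            for name in ("UP", "HSP", "FSP", "DUP")
        ]
        ref = pd.DataFrame(ref_rows)
        ref["cutoff_up_hsp"] = reference.cutoff_up_hsp
        ref["cutoff_hsp_fsp"] = reference.cutoff_hsp_fsp
        ref["cutoff_dup"] = reference.cutoff_dup
        ref.to_csv(out / "plod_reference.csv", index=False)
        n_kin = int(pairs["kin_class"].isin(("FSP", "HSP")).sum())
        log.info("kinfind: %d pairs scanned, %d sibling pairs", len(pairs), n_kin)
        artifacts.update(kin_pairs=out / "kin_pairs.csv", plod_reference=out / "plod_reference.csv")

    if "dpg" in stages:
        pairs = io.read_kin_pairs(out / "kin_pairs.csv")
        meta = io.read_sample_meta(out / "samples.csv")
        retained = set(io.read_genotypes(out / "genotypes.filtered.csv").sample_ids)
        meta = meta[meta["sample_id"].isin(retained)]
        graphs, cross_hsp, anomalies = sibgraph.build_sibgraph(pairs, meta)
        tabs, members = [], []
        for cohort in sorted(graphs):
            g = graphs[cohort]
            if config["dpg"]["resolve_conflicts"]:
                g = sibgraph.resolve_conflicts(g, max_exact=config["dpg"]["max_exact"])
            assignment = sibgraph.assign_parents(g, max_exact=config["dpg"]["max_exact"])
            tabs.append(sibgraph.tabulate_dpgs(assignment, cohort))
            for label, larvae in sorted(assignment.groups.items()):
                for larva in larvae:
                    members.append(
                        {"parent_label": f"{cohort}-P{label:05d}", "larva_id": larva, "cohort": cohort}
                    )
        io.write_tabulation(tabs, out / "dpg_tabulation.csv")
        pd.DataFrame(members).to_csv(out / "dpg_members.csv", index=False)
        cross_hsp.to_csv(out / "cross_cohort_hsp.csv", index=False)
        anomalies.to_csv(out / "cross_cohort_anomalies.csv", index=False)
        log.info("dpg: %s", "; ".join(f"{t.cohort}: NDP={t.ndp}" for t in tabs))
        artifacts.update(tabulation=out / "dpg_tabulation.csv", dpg_members=out / "dpg_members.csv")

    if "ckmr_eval" in stages:
        tabs = io.read_tabulation(out / "dpg_tabulation.csv")
        rows = [ckmr.effective_size_report(t).to_row() for t in tabs]
        c = config["ckmr_eval"]
        for row, tab in zip(rows, tabs):
            mc = ckmr.simulate_kin_count_variance(
                tab, N=c["n_adults"], m_A=c["m_A"], reps=c["reps"], model="POP", seed=seed
            )
            row["mc_pop_variance_ratio"] = mc["variance_ratio"]
        df = pd.DataFrame(rows)
        df.to_csv(out / "effective_sizes.csv", index=False)
        log.info("ckmr-eval:\n%s", df.to_string(index=False))
        artifacts["effective_sizes"] = out / "effective_sizes.csv"

    if "report" in stages:
        pairs = io.read_kin_pairs(out / "kin_pairs.csv")
        meta = io.read_sample_meta(out / "samples.csv")
        retained = set(io.read_genotypes(out / "genotypes.filtered.csv").sample_ids)
        meta = meta[meta["sample_id"].isin(retained)]
        survey.tabulate_by_tow(pairs, meta).to_csv(out / "tow_table.csv", index=False)
        survey.sibship_summary(pairs, meta).to_csv(out / "sibship_summary.csv", index=False)
        sib = pairs[pairs["kin_class"].isin(("FSP", "HSP"))]
        survey.pair_distances(sib, meta).to_csv(out / "pair_distances.csv", index=False)
        artifacts.update(
            tow_table=out / "tow_table.csv",
            sibship_summary=out / "sibship_summary.csv",
            pair_distances=out / "pair_distances.csv",
        )

    return artifacts
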