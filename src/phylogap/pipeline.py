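"""End-to-end orchestration: genetics → clustering → assignment → mtDNA →
niche → connectivity, from one config, with deterministic per-stage seeds.

The config is a flat YAML file with per-module sections; every stochastic
stage derives its seed from the global seed plus the stage name, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import assignment as asg
from . import clustering as clu
from . import connectivity as con
from . import mtdna as mt
from . import niche
from . import popgen as pg
from . import simulate as sim

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]

_DEFAULTS: dict[str, dict[str, Any]] = {
    "scenario": {},
    "cluster": {"k_min": 1, "k_max": 4, "runs": 3,
                "burnin": 800, "reps": 1200},
    "popgen": {"n_perm": 1000, "rarefaction_g": None},
    "assignment": {"n_sim": 1000, "alpha": 0.01},
    "mtdna": {"rate_per_lineage": 0.007, "confidence": 0.95},
    "niche": {"beta": 1.0, "lv_threshold": 0.1, "cell_area_km2": 100.0},
    "connectivity": {"diagonal": True},
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: Path = Path("phylogap_out")
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seed = int(raw.pop("seed", 0))
        outdir = Path(raw.pop("outdir", "phylogap_out"))
        return cls(seed=seed, outdir=outdir, sections=raw)

    def section(self, name: str) -> dict[str, Any]:
        out = dict(_DEFAULTS.get(name, {}))
        out.update(self.sections.get(name, {}))
        return out


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run the whole pipeline on a synthetic scenario; write per-stage CSV
    and JSON artifacts plus a summary, and return the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed}

    sc = sim.Scenario(seed=stage_seed(config.seed, "scenario"),
                      **config.section("scenario"))

    # --- genetics ----------------------------------------------------------
    gm, true_q = sim.simulate_microsatellites(sc)
    loc_table = sim.locality_table(sc)
    grouping = loc_table.cluster_of() or None
    fst = pg.fst_pairwise(gm, grouping)
    rst = pg.rst_pairwise(gm, grouping)
    fst.to_frame().to_csv(out / "fst.csv")
    rst.to_frame().to_csv(out / "rst.csv")
    nm = {}
    labels = rst.labels
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            r = rst.get(a, b)
            nm[f"{a}|{b}"] = (pg.nm_from_fixation(r) if r > 0 else None)
    (out / "nm.json").write_text(json.dumps(nm, indent=1))
    summary["n_individuals"] = gm.n_individuals
    summary["fst_mean"] = float(np.nanmean(fst.offdiag()))
    summary["rst_mean"] = float(np.nanmean(rst.offdiag()))

    pcfg = config.section("popgen")
    richness = pg.allelic_richness(gm, pcfg["rarefaction_g"])
    richness.per_locus.to_csv(out / "allelic_richness.csv")
    by_loc = sim.locality_table(sc).cluster_of()
    p_rich = pg.richness_permutation_test(
        richness, by_loc, n_perm=pcfg["n_perm"],
        seed=stage_seed(config.seed, "richness"))
    summary["richness_permutation_p"] = p_rich

    geo = pg.geographic_distance_km(loc_table)
    rst_loc = pg.rst_pairwise(gm)   # per locality, matches geo labels
    rst_loc_aligned = pg.PairwiseMatrix(
        geo.labels,
        rst_loc.to_frame().loc[geo.labels, geo.labels].to_numpy(),
        "rst")
    ibd = {}
    for transform in ("linear", "log_distance", "fst_linearized"):
        r, r2, p = pg.mantel_test(
            geo, rst_loc_aligned, transform=transform, n_perm=pcfg["n_perm"],
            seed=stage_seed(config.seed, f"mantel-{transform}"))
        ibd[transform] = {"r": r, "r2": r2, "p": p}
    (out / "ibd.json").write_text(json.dumps(ibd, indent=1))
    summary["ibd"] = ibd

    # --- clustering --------------------------------------------------------
    ccfg = config.section("cluster")
    runs: dict[int, list[float]] = {}
    fits: dict[int, clu.ClusterFit] = {}
    for k in range(ccfg["k_min"], ccfg["k_max"] + 1):
        runs[k] = []
        for rep in range(ccfg["runs"]):
            fit = clu.fit_admixture(
                gm, k, burnin=ccfg["burnin"], reps=ccfg["reps"],
                seed=stage_seed(config.seed, f"cluster-K{k}-r{rep}"))
            runs[k].append(fit.lnPD)
            if rep == 0:
                fits[k] = fit
    if len(runs) >= 3:
        dk = clu.delta_k(runs)
        dk.frame.to_csv(out / "delta_k.csv")
        summary["best_k"] = dk.best_k()
    best = fits[max(fits, key=lambda k: np.mean(runs[k]))]
    np.savetxt(out / "Q.csv", best.Q, delimiter=",")
    clu.membership_by_locality(best, gm).to_csv(out / "membership.csv")

    # --- assignment --------------------------------------------------------
    acfg = config.section("assignment")
    calls = asg.detect_first_gen_migrants(
        gm, n_sim=acfg["n_sim"], alpha=acfg["alpha"],
        seed=stage_seed(config.seed, "migrants"))
    asg.migrant_table(calls).to_csv(out / "migrants.csv", index=False)
    summary["n_migrants_flagged"] = int(sum(c.flagged for c in calls))

    # --- mtDNA -------------------------------------------------------------
    mcfg = config.section("mtdna")
    aln = sim.simulate_mtdna(sc)
    pmat = mt.p_distance(aln)
    tn = mt.tn93_distance(aln)
    pmat.to_frame().to_csv(out / "p_distance.csv")
    tn.to_frame().to_csv(out / "tn93.csv")
    groups = {sid: sid.rsplit("_s", 1)[0] for sid in aln.ids}
    between = mt.group_mean_distance(pmat, groups)
    between.to_csv(out / "p_between.csv")
    clock = mt.ClockConfig(mcfg["rate_per_lineage"])
    times = between.copy()
    for a in times.index:
        for b in times.columns:
            if np.isfinite(between.loc[a, b]) and a != b:
                times.loc[a, b] = mt.divergence_time(between.loc[a, b], clock)
    times.to_csv(out / "divergence_myr.csv")
    div = mt.diversity_indices(aln)
    summary["diversity"] = {"n": div.n, "h": div.h, "s": div.s,
                            "hd": div.hd, "pi": div.pi}
    hap = mt.collapse_haplotypes(aln)
    limit = mt.parsimony_connection_limit(aln.length, mcfg["confidence"])
    net = mt.build_haplotype_network(hap, limit)
    edges = [f"{u} {v} {d['steps']}" for u, v, d in net.edges(data=True)]
    (out / "network_edges.txt").write_text("\n".join(edges) + "\n")
    summary["parsimony_limit"] = limit
    summary["n_haplotypes"] = hap.n_haplotypes

    # --- niche + connectivity ---------------------------------------------
    ncfg = config.section("niche")
    land = sim.simulate_landscape(sc)
    niche_summary = {}
    suits = {}
    for lineage in ("north", "south"):
        model = niche.fit_maxent(land.presences[lineage], land.current,
                                 beta=ncfg["beta"])
        cur = niche.predict_logistic(model, land.current)
        past = niche.predict_logistic(model, land.lgm)
        suits[lineage] = (cur, past)
        a = niche.auc(cur, land.presences[lineage])
        east = np.zeros_like(land.gap_mask)
        east[:, land.gap_mask.any(axis=0).nonzero()[0].max() + 1:] = True
        west = np.zeros_like(land.gap_mask)
        west[:, : land.gap_mask.any(axis=0).nonzero()[0].min()] = True
        side = east if lineage == "south" else west
        niche_summary[lineage] = {
            "auc": a,
            "area_current_km2": niche.suitable_area(
                cur, ncfg["lv_threshold"], ncfg["cell_area_km2"], side),
            "area_lgm_km2": niche.suitable_area(
                past, ncfg["lv_threshold"], ncfg["cell_area_km2"], side),
        }
    summary["niche"] = niche_summary

    kcfg = config.section("connectivity")
    conn = {}
    for lineage in ("north", "south"):
        cur, past = suits[lineage]
        rep = con.gap_connectivity_report(
            cur, past, land.gap_mask, land.borders["east"],
            land.borders["west"], diagonal=kcfg["diagonal"])
        conn[lineage] = {k: rep[k] for k in
                         ("cost_current", "cost_lgm", "paired_t", "paired_p",
                          "verdict")}
    summary["connectivity"] = conn

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float))
    return summary
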