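"""End-to-end region analysis: configuration, staging, JSON report.

``run_region_analysis`` executes the full pipeline on one region —
per-population diversity and neutrality statistics with simulated
significance, the sliding-window F_ST scan, the ML-HKA test, haplotype
blocks, the median-joining network with clade frequencies, and the
calibrated TMRCA — and returns a JSON-serialisable report carrying a
provenance block (inputs, seeds, parameters, version).  Identical
configuration and seed give a byte-identical report.

Stages are isolated: a stage that fails records its error in the report
and the remaining stages still run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from typing import Any, Mapping

import numpy as np

import balsel
from balsel import coalsim, fst, hka, ldnet, sumstats, tmrca as tmrca_mod
from balsel.haplotypes import HaplotypeAlignment, read_haplotype_fasta, read_phased_vcf

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "null": {"iterations": 1000},
    "fst": {"window": 20, "step": 3, "bins": 50, "pct": 95.0},
    "blocks": {},
    "tmrca": {"t_split": 6.0e6, "g": 25.0, "bootstrap": 200},
    "hka": {"n_reference": 19, "T": 8.0},
}


class ConfigError(ValueError):
    pass


def _merged(config: Mapping[str, Any]) -> dict:
    out = json.loads(json.dumps(DEFAULTS))
    for key, val in config.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def _load_alignment(cfg: dict, seed: int) -> HaplotypeAlignment:
    inp = cfg.get("input")
    if not inp:
        raise ConfigError("config requires an 'input' section")
    if "vcf" in inp:
        v = inp["vcf"]
        return read_phased_vcf(v["path"], v.get("region"), v.get("pop_map"))
    if "fasta" in inp:
        f = inp["fasta"]
        aln = read_haplotype_fasta(
            f["path"], f.get("outgroup"), f.get("pop_map")
        )
        if aln.outgroup is not None:
            from balsel.haplotypes import polarize

            aln, _ = polarize(aln)
        return aln
    if "simulate" in inp:
        s = dict(inp["simulate"])
        preset = s.pop("preset", "constant")
        n = list(np.atleast_1d(s.get("n", [40])))
        labels = None
        if preset == "calibrated_human_3pop":
            model = coalsim.calibrated_human_3pop()
        else:
            # panmictic pool: multiple sample groups are label splits only
            model = coalsim.DemographicModel.constant(s.pop("N", 10000))
            if len(n) > 1:
                labels = [
                    f"pop{i + 1}" for i, k in enumerate(n) for _ in range(int(k))
                ]
                n = [int(sum(n))]
        cfg_sim = coalsim.SimConfig(
            n=n,
            L=int(s.get("length", 5000)),
            theta=float(s.get("theta", 10.0)),
            rho=float(s.get("rho", 0.0)),
            seed=seed,
            iterations=1,
            mode=s.get("mode", "neutral"),
            balanced_age=s.get("balanced_age"),
            balanced_freq=float(s.get("balanced_freq", 0.5)),
            balanced_switch_rate=float(s.get("balanced_switch_rate", 0.0)),
        )
        sim = coalsim.simulate(cfg_sim, model)[0]
        aln = sim.alignment
        if labels is not None:
            aln.pop_labels = labels
        return aln
    raise ConfigError("input must name one of: vcf, fasta, simulate")


def _null_panels(aln, pop, cfg, seed):
    """Constant-size null panels for each SFS statistic, matched to n and theta."""
    sub = aln.for_population(pop)
    S = int(sub.segregating().sum())
    theta = max(S / sumstats.harmonic(sub.n_hap - 1), 0.5)
    sim_cfg = coalsim.SimConfig(
        n=[sub.n_hap],
        L=aln.l_physical,
        theta=theta,
        seed=seed,
        iterations=cfg["null"]["iterations"],
    )
    model = coalsim.DemographicModel.constant(10000)
    panels = {}
    for stat in ("pi", "theta_w", "tajimas_d", "fu_li_dstar", "fu_li_fstar"):
        panels[stat] = coalsim.null_distribution(stat, sim_cfg, model)
    return panels


def _diversity_stage(aln, cfg, seed):
    out = {}
    for i, pop in enumerate(aln.populations):
        res = sumstats.diversity(aln, population=pop)
        panels = _null_panels(aln, pop, cfg, seed + 101 + i)
        entry = asdict(res)
        entry["significance"] = {}
        for stat, attr in (
            ("pi", "pi"),
            ("theta_w", "theta_w"),
            ("tajimas_d", "tajima_d"),
            ("fu_li_dstar", "fu_li_dstar"),
            ("fu_li_fstar", "fu_li_fstar"),
        ):
            val = getattr(res, attr)
            if val is None:
                entry["significance"][stat] = None
                continue
            entry["significance"][stat] = {
                "rank": sumstats.empirical_rank(val, panels[stat]),
                "p_sim": sumstats.sim_pvalue(val, panels[stat], "two-sided"),
            }
        out[pop] = entry
    return out


def _fst_stage(aln, cfg, seed):
    if len(aln.populations) < 2:
        return {"skipped": "single population"}
    fcfg = cfg["fst"]
    windows = fst.window_fst(aln, fcfg["window"], fcfg["step"])
    # reference distribution of window F_ST from matched neutral simulation
    sub_seed = seed + 202
    sim_cfg = coalsim.SimConfig(
        n=[aln.pop_labels.count(p) for p in aln.populations],
        L=aln.l_physical,
        theta=max(float(aln.segregating().sum()), 5.0),
        seed=sub_seed,
        iterations=max(cfg["null"]["iterations"] // 20, 20),
    )
    model = coalsim.calibrated_human_3pop() if len(aln.populations) == 3 else (
        coalsim.DemographicModel.island(len(aln.populations), 10000, 1e-4)
    )
    ref_vals = []
    for rep in coalsim.simulate(sim_cfg, model):
        try:
            for w in fst.window_fst(rep.alignment, fcfg["window"], fcfg["step"]):
                if np.isfinite(w.fst):
                    ref_vals.append(w.fst)
        except ValueError:
            continue
    thr = fst.reference_threshold(np.asarray(ref_vals), fcfg["pct"]) if ref_vals else None
    table = []
    ref_arr = np.asarray(ref_vals)
    for w in windows:
        rec = {
            "window": w.index,
            "start": w.first_pos,
            "end": w.last_pos,
            "pair": "/".join(w.pair),
            "n_snps": w.n_snps,
            "fst": None if not np.isfinite(w.fst) else round(w.fst, 6),
            "truncated": w.truncated,
        }
        if thr is not None and np.isfinite(w.fst):
            rec["percentile"] = round(sumstats.empirical_rank(w.fst, ref_arr), 4)
            rec["outlier"] = bool(w.fst > thr)
        table.append(rec)
    return {
        "threshold_pct": fcfg["pct"],
        "threshold": thr,
        "reference_windows": len(ref_vals),
        "windows": table,
    }


def _hka_stage(aln, cfg, seed):
    hcfg = cfg["hka"]
    out = {}
    if "locus_table" in hcfg:
        import pandas as pd

        df = pd.read_csv(hcfg["locus_table"], sep="\t")
        loci = hka.loci_from_frame(df)
        selected = [l.locus_id for l in loci if l.selected]
        neutral_fit = fit = None
        neutral_fit = hka.fit_hka(loci, [], seed=seed)
        fit = hka.fit_hka(loci, selected, seed=seed)
        stat, p = hka.hka_lrt(neutral_fit, fit)
        return {
            "k": fit.k,
            "T": fit.T,
            "lrt_stat": stat,
            "p": p,
            "n_loci": len(loci),
        }
    # no external locus table: compare the region against simulated
    # neutral reference loci drawn from the Poisson HKA model
    F = cfg["tmrca"].get("fixed_diffs")
    if F is None:
        return {"skipped": "no locus table and no fixed-difference count"}
    T = float(hcfg["T"])
    n_ref = int(hcfg["n_reference"])
    for i, pop in enumerate(aln.populations):
        sub = aln.for_population(pop)
        S = int(sub.segregating().sum())
        ref_theta = 0.5 * S / (sumstats.harmonic(sub.n_hap - 1) * aln.l_physical)
        ref = hka.simulate_hka_counts(
            theta=[max(ref_theta, 1e-5)] * n_ref,
            T=T,
            n=[sub.n_hap] * n_ref,
            L=[aln.l_physical] * n_ref,
            seed=seed + 303 + i,
        )
        region = hka.LocusCounts(
            locus_id="region",
            S=S,
            D=int(F),
            n=sub.n_hap,
            L=aln.l_physical,
            selected=True,
        )
        loci = ref + [region]
        neutral_fit = hka.fit_hka(loci, [], seed=seed)
        fit = hka.fit_hka(loci, ["region"], seed=seed)
        stat, p = hka.hka_lrt(neutral_fit, fit)
        out[pop] = {
            "k": fit.k["region"],
            "T": fit.T,
            "lrt_stat": stat,
            "p": p,
            "n_loci": len(loci),
            "reference": "simulated",
        }
    return out


def _blocks_stage(aln, cfg):
    blocks = ldnet.ci_blocks(aln, **cfg["blocks"])
    return [asdict(b) for b in blocks]


def _network_stage(aln):
    polarized = bool(np.all(aln.polarized)) and aln.n_sites > 0
    net = ldnet.mj_network(aln, attach_mrca=polarized)
    summary = {
        "n_nodes": net.number_of_nodes(),
        "n_observed": sum(1 for _, d in net.nodes(data=True) if d["count"] > 0),
        "n_median": sum(1 for _, d in net.nodes(data=True) if d["median"]),
        "n_edges": net.number_of_edges(),
        "total_mutations": sum(d["weight"] for _, _, d in net.edges(data=True)),
    }
    try:
        split = ldnet.clade_split(net)
        summary["clades"] = {
            "counts": list(split.clade_counts),
            "pop_counts": [split.pop_counts[0], split.pop_counts[1]],
            "cut_weight": split.cut_weight,
            "weak": split.weak,
        }
    except ValueError as exc:
        summary["clades"] = {"error": str(exc)}
    return summary


def _tmrca_stage(aln, cfg, seed):
    tcfg = cfg["tmrca"]
    F = tcfg.get("fixed_diffs")
    if F is None:
        return {"skipped": "no fixed-difference count for calibration"}
    if not bool(np.all(aln.polarized)):
        return {"skipped": "alignment not fully polarized"}
    cal = tmrca_mod.calibrate_mu(
        int(F), aln.l_effective, tcfg["t_split"], tcfg["g"]
    )
    filtered, removed = tmrca_mod.infinite_sites_filter(aln)
    est = tmrca_mod.pairwise_diff_tmrca(filtered, cal)
    sd = None
    if filtered.segregating().sum() > 0 and tcfg["bootstrap"] > 0:
        sd = tmrca_mod.tmrca_sd(
            filtered, cal, replicates=int(tcfg["bootstrap"]), seed=seed + 404
        )
    S = int(filtered.segregating().sum())
    ne = None
    if S > 0:
        theta_locus = S / sumstats.harmonic(filtered.n_hap - 1)
        ne = tmrca_mod.estimate_ne(theta_locus, cal).ne
    return {
        "tmrca_years": est.years,
        "sd_years": sd,
        "method": est.method,
        "sites_removed": removed,
        "sites_used": est.sites_used,
        "mu_year": cal.mu_year,
        "mu_gen": cal.mu_gen,
        "ne": ne,
    }


def run_region_analysis(config: Mapping[str, Any] | str) -> dict:
    """Run the full pipeline and return the region report as a dict."""
    if isinstance(config, str):
        config = load_config(config)
    cfg = _merged(config)
    seed = int(cfg["seed"])
    aln = _load_alignment(cfg, seed)

    report: dict[str, Any] = {
        "provenance": {
            "package": "balsel",
            "version": balsel.__version__,
            "seed": seed,
            "config": cfg,
            "n_hap": aln.n_hap,
            "n_sites": aln.n_sites,
            "populations": aln.populations,
            "region": f"{aln.chrom}:{aln.start}-{aln.end}",
        }
    }

    stages = [
        ("diversity", lambda: _diversity_stage(aln, cfg, seed)),
        ("fst_scan", lambda: _fst_stage(aln, cfg, seed)),
        ("hka", lambda: _hka_stage(aln, cfg, seed)),
        ("ld_blocks", lambda: _blocks_stage(aln, cfg)),
        ("network", lambda: _network_stage(aln)),
        ("tmrca", lambda: _tmrca_stage(aln, cfg, seed)),
    ]
    for name, fn in stages:
        try:
            report[name] = fn()
        except Exception as exc:  # stage isolation
            logger.exception("stage %s failed", name)
            report[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialisation: sorted keys, fixed float formatting."""

    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, float)):
            return float(f"{float(x):.10g}")
        if isinstance(x, np.integer):
            return int(x)
        return x

    return json.dumps(clean(report), indent=2, sort_keys=True) + "\n"
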