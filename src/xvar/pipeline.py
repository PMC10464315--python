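"""End-to-end orchestration of the X-methylation aging analysis.

A single entry point, :func:`run_pipeline`, executes the full study design
on synthetic (or user-supplied) data: simulate a discovery cohort plus a
whole-blood-like and a purified-monocyte-like replication cohort; adjust
batches and RIN-transform per cohort and sex; run the sex-stratified DGLM
scans; empirical-null correct each scan's mean and dispersion statistics;
call Bonferroni discovery hits and apply the FDR + direction dual-cohort
replication rule; call regions, count distinct loci, annotate and test
enrichment of the replicated hits; and associate them with simulated gene
expression.  All stage outputs are written as TSV plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dglm import scan
from .empirical_null import correct, estimate_null
from .expression import associate
from .preprocess import batch_adjust, estimate_latent_factors, rin_transform_frame
from .regions_annot import (
    call_regions,
    count_distinct_loci,
    enrichment_test,
    meth_category,
)
from .replication import bonferroni_select, replicate
from .synth import (
    Landscape,
    SimConfig,
    generate_landscape,
    plant_truth,
    simulate_cohort,
    simulate_expression,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Study-design knobs for a synthetic end-to-end run."""

    n_cpgs: int = 2000
    n_f_discovery: int = 600
    n_m_discovery: int = 450
    n_f_rep: int = 300
    n_m_rep: int = 250
    age_range: tuple[float, float] = (18.0, 85.0)
    discovery_cohorts: tuple[str, ...] = ("B1", "B2", "B3")

    plant_effects: bool = True
    n_var_xi: int = 60
    n_var_xa: int = 6
    n_mean_xa: int = 8
    n_mean_xi: int = 6
    n_composition: int = 50
    beta1: float = 0.0015
    gamma1: float = 0.03

    sim: SimConfig = field(default_factory=SimConfig)

    latent_k: int = 5
    alpha_discovery: float = 0.05
    alpha_replication: float = 0.05

    n_genes: int = 300
    n_links: int = 3
    link_slope: float = 0.5
    expression_fraction: float = 0.8  # discovery samples with RNA-seq

    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        for key in ("age_range", "discovery_cohorts"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _corrected(scan_df: pd.DataFrame, which: str) -> pd.DataFrame:
    """Empirical-null correct one submodel's statistics of one scan."""
    z_col = "z_mean" if which == "mean" else "z_disp"
    ok = scan_df["converged"] & np.isfinite(scan_df[z_col])
    z = scan_df.loc[ok, z_col].to_numpy()
    if z.size >= 30:
        est = estimate_null(z, min_n=30)
    else:  # too few statistics for a mixture fit: robust rescaling only
        from .empirical_null import NullEstimate, _MAD_SCALE

        med = float(np.median(z)) if z.size else 0.0
        mad = float(_MAD_SCALE * np.median(np.abs(z - med))) if z.size else 1.0
        est = NullEstimate(med, mad if mad > 0 else 1.0, 1.0,
                           np.array([med] * 3), np.array([1.0] * 3),
                           np.array([0.0, 1.0, 0.0]), np.nan, 0, "robust")
    zc, pc = correct(z, est)
    out = scan_df.loc[ok, []].copy()
    out["z"] = zc
    out["p"] = pc
    out.attrs["bias"] = est.bias
    out.attrs["inflation"] = est.inflation
    return out


def _split_loss_gain(hits: pd.DataFrame) -> tuple[int, int]:
    loss = int((hits["direction"] == "loss").sum())
    gain = int((hits["direction"] == "gain").sum())
    return loss, gain


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Run the full synthetic study; returns a results dictionary.

    The dictionary holds the landscape/truth, per-scan result frames, the
    hit tables with replication flags, the region/annotation/enrichment
    summaries, the expression associations and a Tables-1/2-style summary
    frame (``summary``).  When ``out_dir`` (or ``config.out_dir``) is set,
    per-stage TSVs and a JSON manifest are written there.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir or cfg.out_dir) if (out_dir or cfg.out_dir) else None
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(12)]

    # ---- simulate ---------------------------------------------------------
    land = generate_landscape(cfg.n_cpgs, seed=seeds[0])
    if cfg.plant_effects:
        land, truth = plant_truth(
            land,
            n_var_xi=cfg.n_var_xi, n_var_xa=cfg.n_var_xa,
            n_mean_xa=cfg.n_mean_xa, n_mean_xi=cfg.n_mean_xi,
            n_composition=cfg.n_composition,
            beta1=cfg.beta1, gamma1=cfg.gamma1, seed=seeds[1],
        )
    else:
        _, truth = plant_truth(
            land, n_var_xi=0, n_var_xa=0, n_mean_xa=0, n_mean_xi=0,
            n_composition=0, seed=seeds[1],
        )

    datasets: dict[str, dict] = {}
    specs = [
        ("discovery", cfg.n_f_discovery, cfg.n_m_discovery, "blood",
         cfg.discovery_cohorts, seeds[2]),
        ("rep_blood", cfg.n_f_rep, cfg.n_m_rep, "blood", ("J1",), seeds[3]),
        ("rep_mono", cfg.n_f_rep, cfg.n_m_rep, "monocyte", ("R1",), seeds[4]),
    ]
    for name, n_f, n_m, kind, cohorts, seed in specs:
        meth, samp = simulate_cohort(
            land, truth, n_f, n_m, age_range=cfg.age_range, config=cfg.sim,
            kind=kind, cohorts=cohorts, sample_prefix=f"{name[:4]}_", seed=seed,
        )
        datasets[name] = {"meth": meth, "samples": samp, "kind": kind}

    # ---- preprocess + scans ----------------------------------------------
    scans: dict[tuple[str, str], pd.DataFrame] = {}
    corrected: dict[tuple[str, str, str], pd.DataFrame] = {}
    diag: dict[str, dict] = {}
    for name, d in datasets.items():
        meth, samp = d["meth"], d["samples"]
        if samp["cohort"].nunique() > 1:
            covs = samp[["age", "sex", "sentrix_position", "sample_plate"]]
            meth = batch_adjust(meth, samp["cohort"], covs)
        rin = rin_transform_frame(meth, samp)
        d["rin"] = rin
        for sex in ("F", "M"):
            sub = samp.index[samp["sex"] == sex]
            known_cols = [
                c for c in (
                    ["age", "cohort", "sentrix_position", "sample_plate"]
                    + (["cd8t", "cd4t", "nk", "bcell", "mono"]
                       if d["kind"] == "blood" else ["purity"])
                )
                if samp.loc[sub, c].nunique() > 1
            ]
            factors = estimate_latent_factors(
                rin.loc[:, sub], samp.loc[sub, known_cols], k=cfg.latent_k
            )
            res = scan(rin, samp, factors=factors, sex=sex)
            scans[(name, sex)] = res
            for which in ("mean", "disp"):
                c = _corrected(res, which)
                corrected[(name, sex, which)] = c
                diag[f"{name}_{sex}_{which}"] = {
                    "bias": c.attrs["bias"], "inflation": c.attrs["inflation"],
                }

    # ---- discovery + replication -----------------------------------------
    classes = {"aDMC": "mean", "aVMC": "disp"}
    hit_tables: dict[tuple[str, str], pd.DataFrame] = {}
    rates: dict[tuple[str, str], dict] = {}
    discovery_hits: dict[tuple[str, str], pd.DataFrame] = {}
    for cls, which in classes.items():
        per_sex = {}
        for sex in ("F", "M"):
            c = corrected[("discovery", sex, which)]
            m = len(c)
            idx = bonferroni_select(c["p"].to_numpy(), cfg.alpha_discovery, m)
            per_sex[sex] = c.iloc[idx]
        m_unique = len(per_sex["F"].index.union(per_sex["M"].index))
        for sex in ("F", "M"):
            disc = per_sex[sex]
            discovery_hits[(cls, sex)] = disc
            rep1 = corrected[("rep_blood", sex, which)]
            rep2 = corrected[("rep_mono", sex, which)]
            tab, rt = replicate(
                disc, rep1, rep2, m_unique=max(m_unique, len(disc)),
                alpha=cfg.alpha_replication,
                rep_names=("blood", "mono"),
            )
            hit_tables[(cls, sex)] = tab
            rates[(cls, sex)] = rt

    # ---- regions, distinct loci, annotation ------------------------------
    pos = land.cpgs["pos"]
    all_positions = pos.to_numpy()
    regions_out: dict[tuple[str, str], list] = {}
    loci: dict[tuple[str, str], int] = {}
    for (cls, sex), tab in hit_tables.items():
        rep_ids = tab.index[tab["doubly_replicated"]]
        sig_pos = np.sort(pos.loc[rep_ids].to_numpy())
        regs = call_regions(sig_pos, all_positions)
        regions_out[(cls, sex)] = regs
        loci[(cls, sex)] = count_distinct_loci(len(rep_ids), regs, sig_pos)

    # annotation of replicated hits vs non-hit background
    all_hits = set()
    for tab in hit_tables.values():
        all_hits |= set(tab.index)
    background = land.cpgs.index.difference(sorted(all_hits))
    disc_meth = datasets["discovery"]["meth"]
    disc_samp = datasets["discovery"]["samples"]
    mean_beta = {
        sex: disc_meth.loc[:, disc_samp.index[disc_samp["sex"] == sex]].mean(axis=1)
        for sex in ("F", "M")
    }

    annot = land.cpgs[["pos", "cgi_class", "xci_status"]].copy()
    enrich: dict[str, dict] = {}
    for (cls, sex), tab in hit_tables.items():
        rep_ids = tab.index[tab["doubly_replicated"]]
        if len(rep_ids) == 0:
            continue
        cats = {}
        meth_cat_hit = [meth_category(b) for b in mean_beta[sex].loc[rep_ids]]
        meth_cat_bg = [meth_category(b) for b in mean_beta[sex].loc[background]]
        for axis, hit_vals, bg_vals in (
            ("meth_level", meth_cat_hit, meth_cat_bg),
            ("cgi", annot.loc[rep_ids, "cgi_class"], annot.loc[background, "cgi_class"]),
            ("xci",
             annot.loc[rep_ids, "xci_status"][annot.loc[rep_ids, "xci_status"] != "unannotated"],
             annot.loc[background, "xci_status"][annot.loc[background, "xci_status"] != "unannotated"]),
        ):
            h = pd.Series(list(hit_vals)).value_counts()
            b = pd.Series(list(bg_vals)).value_counts()
            levels = sorted(set(h.index) | set(b.index))
            if len(levels) < 2 or len(h) == 0:
                continue
            hv = np.array([int(h.get(lv, 0)) for lv in levels])
            bv = np.array([int(b.get(lv, 0)) for lv in levels])
            try:
                stat, p, method = enrichment_test(hv, bv, seed=seeds[5])
            except ValueError:
                continue
            cats[axis] = {
                "levels": levels,
                "hit_counts": hv.tolist(),
                "bg_counts": bv.tolist(),
                "stat": stat, "p": p, "method": method,
            }
        enrich[f"{cls}_{sex}"] = cats

    # ---- expression association ------------------------------------------
    expr_results: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seeds[6])
    n_rna = int(cfg.expression_fraction * len(disc_samp))
    rna_samples = disc_samp.index[
        np.sort(rng.choice(len(disc_samp), n_rna, replace=False))
    ]
    links = []
    var_cpgs = truth.index[
        (truth["effect_type"] == "variance") & ~truth["xa_specific"]
    ]
    for i, cpg in enumerate(var_cpgs[: cfg.n_links]):
        links.append((cpg, f"geneE{i:04d}", cfg.link_slope))
    expr, genes = simulate_expression(
        datasets["discovery"]["meth"].loc[:, rna_samples],
        links, cfg.n_genes, seed=seeds[7],
    )
    flow = genes.attrs["flowcell"]
    for sex in ("F", "M"):
        hit_ids = sorted(
            set().union(*(set(hit_tables[(cls, sex)].index[
                hit_tables[(cls, sex)]["doubly_replicated"]
            ]) for cls in classes))
        )
        if not hit_ids:
            expr_results[sex] = pd.DataFrame()
            continue
        samp_sex = disc_samp.loc[rna_samples]
        samp_sex = samp_sex[samp_sex["sex"] == sex].copy()
        samp_sex["flowcell"] = flow.loc[samp_sex.index]
        factors = estimate_latent_factors(
            datasets["discovery"]["rin"].loc[:, samp_sex.index],
            samp_sex[[c for c in ["age", "cohort", "sentrix_position", "sample_plate",
                                  "cd8t", "cd4t", "nk", "bcell", "mono", "flowcell"]
                      if samp_sex[c].nunique() > 1]],
            k=cfg.latent_k,
        )
        expr_results[sex] = associate(
            datasets["discovery"]["rin"].loc[hit_ids, samp_sex.index],
            expr.loc[:, samp_sex.index],
            samp_sex,
            factors=factors,
            gene_tss=genes["tss_pos"],
            cpg_pos=land.cpgs["pos"],
        )

    # ---- summary ----------------------------------------------------------
    summary_rows = []
    for cls in classes:
        for sex in ("F", "M"):
            tab = hit_tables[(cls, sex)]
            loss, gain = _split_loss_gain(tab)
            rt = rates[(cls, sex)]
            loss_d = int(((tab["direction"] == "loss") & tab["doubly_replicated"]).sum())
            gain_d = int(((tab["direction"] == "gain") & tab["doubly_replicated"]).sum())
            summary_rows.append({
                "class": cls, "sex": sex,
                "n_discovery": len(tab), "loss": loss, "gain": gain,
                "rate_blood": rt["rate_blood"], "rate_mono": rt["rate_mono"],
                "rate_doubly": rt["rate_doubly"],
                "n_doubly": int(rt["n_doubly"]),
                "loss_doubly": loss_d, "gain_doubly": gain_d,
                "n_regions": len(regions_out[(cls, sex)]),
                "n_distinct_loci": loci[(cls, sex)],
            })
    summary = pd.DataFrame(summary_rows)

    # truth-stratified replication of discovery aDMCs (composition vs allele)
    mech = truth["mechanism"]
    comp_rates = {}
    for sex in ("F", "M"):
        tab = hit_tables[("aDMC", sex)]
        comp_ids = tab.index[mech.loc[tab.index] == "composition"]
        if len(comp_ids):
            comp_rates[sex] = {
                "n": len(comp_ids),
                "rate_blood": float(tab.loc[comp_ids, "replicated_blood"].mean()),
                "rate_mono": float(tab.loc[comp_ids, "replicated_mono"].mean()),
                "rate_doubly": float(tab.loc[comp_ids, "doubly_replicated"].mean()),
            }

    results = {
        "config": cfg,
        "landscape": land,
        "truth": truth,
        "datasets": datasets,
        "scans": scans,
        "corrected": corrected,
        "diagnostics": diag,
        "hit_tables": hit_tables,
        "rates": rates,
        "regions": regions_out,
        "distinct_loci": loci,
        "enrichment": enrich,
        "expression": expr_results,
        "summary": summary,
        "composition_admc_rates": comp_rates,
    }

    if out is not None:
        _write_outputs(out, cfg, results)
    return results


def _write_outputs(out: Path, cfg: PipelineConfig, results: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    land: Landscape = results["landscape"]
    land.cpgs.to_csv(out / "landscape.tsv", sep="\t")
    results["truth"].to_csv(out / "truth.tsv", sep="\t")
    with open(out / "cgi.bed", "w") as fh:
        for s, e in land.cgi_intervals:
            fh.write(f"chrX\t{s - 1}\t{e}\tCGI\n")
    for name, d in results["datasets"].items():
        d["meth"].to_csv(out / f"meth_{name}.tsv", sep="\t")
        d["samples"].to_csv(out / f"samples_{name}.tsv", sep="\t")
    for (name, sex), res in results["scans"].items():
        res.to_csv(out / f"scan_{name}_{sex}.tsv", sep="\t")
    for (cls, sex), tab in results["hit_tables"].items():
        tab.to_csv(out / f"hits_{cls}_{sex}.tsv", sep="\t")
    for sex, df in results["expression"].items():
        if len(df):
            df.to_csv(out / f"expression_assoc_{sex}.tsv", sep="\t", index=False)
    results["summary"].to_csv(out / "summary.tsv", sep="\t", index=False)

    cfg_dict = dataclasses.asdict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "package": "xvar",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": __import__("scipy").__version__,
        "diagnostics": results["diagnostics"],
        "composition_admc_rates": results["composition_admc_rates"],
        "distinct_loci": {f"{c}_{s}": v for (c, s), v in results["distinct_loci"].items()},
        "enrichment": results["enrichment"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
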