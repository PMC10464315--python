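"""Seeded synthetic X-methylation cohorts with planted age effects.

The generator works at the allele level.  Every CpG carries a baseline
methylation value for the active X (Xa) and for the inactive X (Xi).  A
male sample measures the Xa allele only; a female sample measures the
average of Xa and Xi.  This single modelling choice reproduces the two
structural facts the analysis leans on:

* the female marginal beta distribution is trimodal (low where both alleles
  are unmethylated = XCI escape, intermediate where a hypomethylated Xa
  averages with a hypermethylated Xi = subject to XCI, high where both
  alleles are methylated) while the male distribution is bimodal;
* an age effect planted on the Xa allele appears at full size in males but
  halved in females, because the unaffected Xi dilutes it — the "dilution
  factor 2" property.

Age effects are planted per allele: a mean effect shifts the allele mean
linearly in age; a variance effect scales the allele noise SD by
exp(gamma1 * (age - midpoint) / 2), so the allele variance grows as
exp(gamma1 * age).  Confounding is modelled as an unmeasured, age-drifting
cell-composition axis (think shifts of granulocyte/lymphocyte subtypes):
the reported cell fractions are only weak proxies of it, so adjusting for
them leaves a residual age-correlated signal at CpGs that load on the axis
— exactly the mechanism that makes composition-driven mean hits replicate
in whole blood but not in purified monocytes, where the axis is absent and
only a per-sample purity covariate remains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .regions_annot import annotate_cgi, merge_intervals

__all__ = [
    "Landscape",
    "SimConfig",
    "generate_landscape",
    "plant_truth",
    "simulate_cohort",
    "simulate_expression",
    "dilution_experiment",
]

CELL_TYPES = ("cd8t", "cd4t", "nk", "bcell", "mono")

#: mean blood fractions (granulocytes = remainder, excluded from models)
_BASE_FRACTIONS = {"cd8t": 0.08, "cd4t": 0.15, "nk": 0.05, "bcell": 0.05, "mono": 0.07}
#: loading of each reported fraction on the latent composition axis
_FRACTION_LOADINGS = {"cd8t": -0.005, "cd4t": -0.008, "nk": 0.002, "bcell": -0.003, "mono": 0.003}


@dataclass
class Landscape:
    """A synthetic CpG landscape: per-CpG table, CGI track and TSS table."""

    cpgs: pd.DataFrame                 # indexed by cpg_id
    cgi_intervals: np.ndarray          # merged 1-based inclusive (start, end)
    tss: pd.DataFrame                  # gene_id, pos, xci_status

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)


@dataclass
class SimConfig:
    """Noise magnitudes and confounding knobs for cohort simulation.

    Defaults are the package's standing study conditions: array-scale
    measurement noise, allele-level biological noise of a few percent
    methylation, and a composition axis whose age drift is strong enough to
    induce detectable mean hits at the default cohort sizes.
    """

    sd_xa: float = 0.025          # biological noise SD of the Xa allele (beta units)
    sd_xi: float = 0.06           # biological noise SD of the Xi allele (noisier compartment)
    sd_meas: float = 0.012        # measurement noise on the observed beta
    age_mid: float = 51.5         # centring age for planted effects
    confounding: bool = True      # age-drifting composition axis on/off
    drift_per_year: float = 0.025 # composition-axis drift per year of age
    u_sd: float = 1.0             # SD of the axis around its age trend
    frac_noise_sd: float = 0.015  # per-fraction noise around base + loading*u
    batch_sd: float = 0.006       # additive offset SD per technical-batch level
    cohort_sd: float = 0.008      # additive offset SD per cohort
    n_sentrix: int = 8            # sentrix-position levels
    n_plates: int = 6             # sample-plate levels
    purity_mean: float = 0.9      # monocyte cohort: mean purity
    purity_sd: float = 0.04


def generate_landscape(
    n_cpgs: int,
    cgi_fraction: float = 0.35,
    xci_mix: tuple[float, float, float] = (0.75, 0.15, 0.10),
    seed: int = 0,
) -> Landscape:
    """Generate a CpG landscape with promoter CGI clusters around gene TSSs.

    ``xci_mix`` gives the (subject, escape, variable) proportions of genes —
    and hence of TSS-annotated CpGs.  Roughly ``cgi_fraction`` of CpGs fall
    inside CGI islands.  Positions are sorted, unique, 1-based.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    mix = np.asarray(xci_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-8:
        raise ValueError("xci_mix must be three non-negative proportions summing to 1")
    rng = np.random.default_rng(seed)

    span = max(n_cpgs * 2000, 20000)
    n_genes = max(1, round(n_cpgs / 12))
    gene_spacing = span / n_genes
    tss_pos = np.sort(
        (np.arange(n_genes) + 0.5) * gene_spacing
        + rng.normal(0, 0.15 * gene_spacing, n_genes)
    ).astype(np.int64)
    tss_pos = np.maximum.accumulate(np.maximum(tss_pos, 1) + np.arange(n_genes))  # unique
    statuses = rng.choice(["subject", "escape", "variable"], size=n_genes, p=mix)

    # promoter clusters: ~6.5 CpGs within [-400, +600] of each TSS
    prom_positions: list[int] = []
    prom_gene: list[int] = []
    for g, t in enumerate(tss_pos):
        k = int(rng.integers(5, 9))
        offs = np.unique(rng.integers(-400, 601, k))
        for o in offs:
            prom_positions.append(int(t + o))
            prom_gene.append(g)
    n_prom = len(prom_positions)
    p_cgi = float(np.clip(cgi_fraction * n_cpgs / max(n_prom, 1), 0.0, 1.0))
    gene_has_cgi = rng.random(n_genes) < p_cgi

    positions = list(dict.fromkeys(prom_positions))  # unique, order-stable
    if len(positions) > n_cpgs:
        keep_idx = np.sort(rng.choice(len(positions), n_cpgs, replace=False))
        positions = [positions[i] for i in keep_idx]
    taken = set(positions)
    while len(positions) < n_cpgs:
        cand = int(rng.integers(1, span + 1))
        if cand not in taken:
            positions.append(cand)
            taken.add(cand)
    pos = np.sort(np.array(positions, dtype=np.int64))

    # CGI track from promoter clusters of CGI genes
    islands = []
    for g, t in enumerate(tss_pos):
        if gene_has_cgi[g]:
            islands.append((max(1, int(t) - 450), int(t) + 650))
    cgi = merge_intervals(np.array(islands, dtype=np.int64).reshape(-1, 2))

    # nearest TSS and XCI annotation
    idx = np.searchsorted(tss_pos, pos)
    left = np.clip(idx - 1, 0, n_genes - 1)
    right = np.clip(idx, 0, n_genes - 1)
    nearest = np.where(np.abs(pos - tss_pos[left]) <= np.abs(tss_pos[right] - pos), left, right)
    tss_distance = pos - tss_pos[nearest]
    near = np.abs(tss_distance) <= 2000
    xci_status = np.where(near, statuses[nearest], "unannotated").astype(object)

    # allele baselines keyed on the XCI annotation (truncated normals keep
    # the mixture components smooth — no boundary spikes)
    def _tn(mean, sd, lo, hi, size=None):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    n = n_cpgs
    baseline_xa = np.empty(n)
    baseline_xi = np.empty(n)
    for i in range(n):
        st = xci_status[i]
        if st == "subject":
            baseline_xa[i] = _tn(0.09, 0.028, 0.02, 0.16)
            baseline_xi[i] = _tn(0.82, 0.05, 0.67, 0.97)
        elif st == "escape":
            baseline_xa[i] = _tn(0.09, 0.028, 0.02, 0.16)
            baseline_xi[i] = _tn(0.11, 0.04, 0.02, 0.20)
        elif st == "variable":
            baseline_xa[i] = _tn(0.09, 0.028, 0.02, 0.16)
            baseline_xi[i] = rng.uniform(0.30, 0.65)
        else:  # gene body / intergenic: methylated on both alleles
            baseline_xa[i] = _tn(0.86, 0.04, 0.74, 0.98)
            baseline_xi[i] = _tn(0.88, 0.035, 0.765, 0.985)

    cpg_ids = [f"cgS{i:06d}" for i in range(n)]
    cpgs = pd.DataFrame(
        {
            "pos": pos,
            "baseline_xa": baseline_xa,
            "baseline_xi": baseline_xi,
            "cgi_class": annotate_cgi(pos, cgi),
            "tss_distance": tss_distance,
            "xci_status": xci_status,
            "sens_latent": 0.0,           # loading on the composition axis
            "impurity_delta": rng.normal(0.0, 0.04, n),  # monocyte-impurity offset
            **{f"sens_{c}": 0.0 for c in CELL_TYPES},
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    tss = pd.DataFrame(
        {
            "gene_id": [f"geneS{g:04d}" for g in range(n_genes)],
            "pos": tss_pos,
            "xci_status": statuses,
        }
    ).set_index("gene_id")
    return Landscape(cpgs=cpgs, cgi_intervals=cgi, tss=tss)


def plant_truth(
    landscape: Landscape,
    n_var_xi: int = 60,
    n_var_xa: int = 6,
    n_mean_xa: int = 8,
    n_mean_xi: int = 6,
    n_composition: int = 50,
    beta1: float = 0.0015,
    gamma1: float = 0.03,
    sens_latent: float = 0.08,
    subject_preference: float = 0.85,
    seed: int = 0,
) -> tuple[Landscape, pd.DataFrame]:
    """Plant age effects and return (updated landscape, truth table).

    Xi-variance effects (the female-specific variability signature) are
    drawn preferentially from subject-to-XCI promoter CpGs, which is where
    Xi hypermethylation lives; composition-driven CpGs get a loading on the
    latent cell-composition axis instead of an allele effect.  Effects are
    mutually exclusive across CpGs.
    """
    rng = np.random.default_rng(seed)
    cpgs = landscape.cpgs.copy()
    ids = cpgs.index.to_numpy()
    pool = set(range(len(ids)))

    # map CpGs to their nearest gene's promoter (|distance to TSS| <= 700)
    tss_pos = landscape.tss["pos"].to_numpy()
    gene_status = landscape.tss["xci_status"].to_numpy()
    cpg_pos = cpgs["pos"].to_numpy()
    gi = np.searchsorted(tss_pos, cpg_pos)
    left = np.clip(gi - 1, 0, len(tss_pos) - 1)
    right = np.clip(gi, 0, len(tss_pos) - 1)
    nearest_gene = np.where(
        np.abs(cpg_pos - tss_pos[left]) <= np.abs(tss_pos[right] - cpg_pos), left, right
    )
    in_promoter = np.abs(cpg_pos - tss_pos[nearest_gene]) <= 700

    def _draw(k: int, prefer: np.ndarray | None = None, p_prefer: float = 0.0) -> list[int]:
        chosen: list[int] = []
        pref = [i for i in (prefer if prefer is not None else []) if i in pool]
        rng.shuffle(pref)
        for _ in range(k):
            if pref and rng.random() < p_prefer:
                i = pref.pop()
            else:
                avail = list(pool - set(pref))
                if not avail:
                    avail = list(pool)
                i = int(rng.choice(avail))
                if i in pref:
                    pref.remove(i)
            pool.discard(i)
            chosen.append(i)
        return chosen

    escape_idx = np.flatnonzero(
        cpgs["xci_status"].isin(["escape", "variable"]).to_numpy()
    )

    # Xi-variance effects are planted gene-wise: whole promoter clusters of
    # subject-to-XCI genes (preferring CGI promoters) destabilise together,
    # which is what makes VMRs — runs of significant CpGs — callable
    is_cgi = (cpgs["cgi_class"] == "CGI").to_numpy()
    subj_genes = [
        g for g in range(len(tss_pos))
        if gene_status[g] == "subject" and np.any((nearest_gene == g) & in_promoter)
    ]
    cgi_genes = [
        g for g in subj_genes
        if np.any((nearest_gene == g) & in_promoter & is_cgi)
    ]
    other_genes = [g for g in subj_genes if g not in set(cgi_genes)]
    rng.shuffle(cgi_genes)
    rng.shuffle(other_genes)
    var_xi: list[int] = []
    while len(var_xi) < n_var_xi and (cgi_genes or other_genes):
        take_cgi = cgi_genes and (rng.random() < subject_preference or not other_genes)
        g = cgi_genes.pop() if take_cgi else other_genes.pop()
        members = np.flatnonzero((nearest_gene == g) & in_promoter)
        for i in members:
            if i in pool and len(var_xi) < n_var_xi:
                var_xi.append(int(i))
                pool.discard(int(i))
    var_xa = _draw(min(n_var_xa, len(pool)))
    mean_xa = _draw(min(n_mean_xa, len(pool)))
    mean_xi = _draw(min(n_mean_xi, len(pool)), escape_idx, 0.7)
    comp = _draw(min(n_composition, len(pool)))

    truth = pd.DataFrame(
        {
            "effect_type": "none",
            "beta1_true": 0.0,
            "gamma1_true": 0.0,
            "xa_specific": False,
            "mechanism": "none",
        },
        index=cpgs.index,
    )
    truth.iloc[var_xi, truth.columns.get_loc("effect_type")] = "variance"
    truth.iloc[var_xi, truth.columns.get_loc("gamma1_true")] = gamma1
    truth.iloc[var_xi, truth.columns.get_loc("mechanism")] = "allele"

    truth.iloc[var_xa, truth.columns.get_loc("effect_type")] = "variance"
    truth.iloc[var_xa, truth.columns.get_loc("gamma1_true")] = gamma1
    truth.iloc[var_xa, truth.columns.get_loc("xa_specific")] = True
    truth.iloc[var_xa, truth.columns.get_loc("mechanism")] = "allele"

    signs = rng.choice([-1.0, 1.0], size=len(mean_xa))
    truth.iloc[mean_xa, truth.columns.get_loc("effect_type")] = "mean"
    truth.iloc[mean_xa, truth.columns.get_loc("beta1_true")] = beta1 * signs
    truth.iloc[mean_xa, truth.columns.get_loc("xa_specific")] = True
    truth.iloc[mean_xa, truth.columns.get_loc("mechanism")] = "allele"

    signs = rng.choice([-1.0, 1.0], size=len(mean_xi))
    truth.iloc[mean_xi, truth.columns.get_loc("effect_type")] = "mean"
    truth.iloc[mean_xi, truth.columns.get_loc("beta1_true")] = beta1 * signs
    truth.iloc[mean_xi, truth.columns.get_loc("mechanism")] = "allele"

    truth.iloc[comp, truth.columns.get_loc("effect_type")] = "mean"
    truth.iloc[comp, truth.columns.get_loc("mechanism")] = "composition"
    loads = rng.normal(sens_latent, 0.015, size=len(comp)) * rng.choice([-1, 1], len(comp))
    cpgs.iloc[comp, cpgs.columns.get_loc("sens_latent")] = loads

    return replace(landscape, cpgs=cpgs), truth


def _cell_fractions(rng, u: np.ndarray, cfg: SimConfig) -> pd.DataFrame:
    """Reported cell fractions: base + loading * composition axis + noise,
    clipped so the implicit granulocyte remainder stays non-negative."""
    n = u.size
    cols = {}
    for c in CELL_TYPES:
        f = _BASE_FRACTIONS[c] + _FRACTION_LOADINGS[c] * u + rng.normal(0, cfg.frac_noise_sd, n)
        cols[c] = np.clip(f, 0.005, 0.5)
    frame = pd.DataFrame(cols)
    total = frame.sum(axis=1)
    over = total > 0.95  # keep granulocytes >= 5%
    if over.any():
        frame.loc[over] = frame.loc[over].mul(0.95 / total[over], axis=0)
    return frame


def simulate_cohort(
    landscape: Landscape,
    truth: pd.DataFrame,
    n_f: int,
    n_m: int,
    age_range: tuple[float, float] = (18.0, 85.0),
    config: SimConfig | None = None,
    kind: str = "blood",
    cohorts: tuple[str, ...] = ("C1",),
    sample_prefix: str = "S",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (methylation CpGs x samples, sample table).

    ``kind`` is "blood" (composition axis active, cell fractions reported)
    or "monocyte" (purified cells: no composition axis, a purity covariate
    and per-CpG impurity offsets instead).
    """
    cfg = config or SimConfig()
    if n_f + n_m == 0:
        raise ValueError("need at least one sample")
    if age_range[0] >= age_range[1]:
        raise ValueError("age_range must be (low, high) with low < high")
    if not landscape.cpgs.index.isin(truth.index).all():
        raise ValueError("truth table must cover every CpG in the landscape")
    if kind not in ("blood", "monocyte"):
        raise ValueError("kind must be 'blood' or 'monocyte'")
    rng = np.random.default_rng(seed)

    n = n_f + n_m
    sex = np.array(["F"] * n_f + ["M"] * n_m)
    age = rng.uniform(age_range[0], age_range[1], n)
    cohort = rng.choice(list(cohorts), n)
    sentrix = rng.integers(0, cfg.n_sentrix, n)
    plate = rng.integers(0, cfg.n_plates, n)
    ids = [f"{sample_prefix}{i:05d}" for i in range(n)]

    tr = truth.loc[landscape.cpgs.index]
    cp = landscape.cpgs
    base_xa = cp["baseline_xa"].to_numpy()[:, None]
    base_xi = cp["baseline_xi"].to_numpy()[:, None]
    b1 = tr["beta1_true"].to_numpy()[:, None]
    g1 = tr["gamma1_true"].to_numpy()[:, None]
    on_xa = tr["xa_specific"].to_numpy()[:, None]
    da = (age - cfg.age_mid)[None, :]

    mean_xa = base_xa + np.where(on_xa, b1, 0.0) * da
    mean_xi = base_xi + np.where(on_xa, 0.0, b1) * da
    sd_xa = cfg.sd_xa * np.exp(np.where(on_xa, g1, 0.0) * da / 2.0)
    sd_xi = cfg.sd_xi * np.exp(np.where(on_xa, 0.0, g1) * da / 2.0)
    xa = mean_xa + rng.standard_normal((len(cp), n)) * sd_xa
    xi = mean_xi + rng.standard_normal((len(cp), n)) * sd_xi

    female = sex == "F"
    beta = np.where(female[None, :], (xa + xi) / 2.0, xa)

    samples = pd.DataFrame(
        {"age": age, "sex": sex, "cohort": cohort,
         "sentrix_position": [f"R{r + 1:02d}" for r in sentrix],
         "sample_plate": [f"P{p + 1:02d}" for p in plate]},
        index=pd.Index(ids, name="sample_id"),
    )

    if kind == "blood":
        drift = cfg.drift_per_year if cfg.confounding else 0.0
        u = drift * (age - cfg.age_mid) + rng.normal(0, cfg.u_sd, n)
        fracs = _cell_fractions(rng, u, cfg)
        fracs.index = samples.index
        samples = pd.concat([samples, fracs], axis=1)
        beta = beta + cp["sens_latent"].to_numpy()[:, None] * u[None, :]
        sens_cells = cp[[f"sens_{c}" for c in CELL_TYPES]].to_numpy()
        centered = fracs.to_numpy() - np.array([_BASE_FRACTIONS[c] for c in CELL_TYPES])
        beta = beta + sens_cells @ centered.T
    else:
        purity = np.clip(rng.normal(cfg.purity_mean, cfg.purity_sd, n), 0.7, 0.995)
        samples["purity"] = purity
        beta = beta + cp["impurity_delta"].to_numpy()[:, None] * (1.0 - purity)[None, :]

    # technical batches and cohort offsets, additive on the beta scale
    for labels, sd in (
        (samples["sentrix_position"], cfg.batch_sd),
        (samples["sample_plate"], cfg.batch_sd),
        (samples["cohort"], cfg.cohort_sd),
    ):
        levels = pd.unique(labels)
        offs = rng.normal(0, sd, (len(cp), len(levels)))
        lut = {lv: k for k, lv in enumerate(levels)}
        beta = beta + offs[:, [lut[v] for v in labels]]

    beta = beta + rng.standard_normal(beta.shape) * cfg.sd_meas
    beta = np.clip(beta, 0.0, 1.0)
    meth = pd.DataFrame(beta, index=cp.index, columns=samples.index)
    return meth, samples


def simulate_expression(
    meth: pd.DataFrame,
    links: list[tuple[str, str, float]],
    n_genes: int,
    samples: pd.DataFrame | None = None,
    low_expression_fraction: float = 0.4,
    noise_sd: float = 1.0,
    n_flowcells: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an RNA-seq count matrix with CpG-linked genes.

    ``links`` is a list of (cpg_id, gene_id, slope): the linked gene's
    log2-CPM depends linearly on the linked CpG's standardised methylation
    with the given slope (in units of the gene's noise SD).  A
    ``low_expression_fraction`` of genes is simulated at median CPM < 1 to
    exercise the expression filter.  Returns (counts genes x samples,
    gene table with TSS positions and flowcell assignment per sample in
    the gene table's attrs).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"geneE{i:04d}" for i in range(n_genes)]
    known = set(gene_ids)
    for cpg, gene, _ in links:
        if gene not in known:
            raise ValueError(f"link references unknown gene {gene!r}")
        if cpg not in meth.index:
            raise ValueError(f"link references unknown CpG {cpg!r}")

    n = meth.shape[1]
    low = rng.random(n_genes) < low_expression_fraction
    gidx0 = {g: i for i, g in enumerate(gene_ids)}
    for _, gene, _ in links:  # linked genes are expressed by construction
        low[gidx0[gene]] = False
    base_log2cpm = np.where(low, rng.uniform(-3.5, -1.2, n_genes), rng.uniform(1.5, 8.0, n_genes))
    lib = rng.lognormal(np.log(1.5e6), 0.25, n)
    flow = rng.integers(0, n_flowcells, n)
    flow_off = rng.normal(0, 0.1, n_flowcells)

    log2cpm = np.tile(base_log2cpm[:, None], (1, n)).astype(float)
    log2cpm += rng.standard_normal((n_genes, n)) * noise_sd
    log2cpm += flow_off[flow][None, :]
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for cpg, gene, slope in links:
        m = meth.loc[cpg].to_numpy(dtype=float)
        ms = (m - m.mean()) / (m.std() + 1e-12)
        log2cpm[gidx[gene]] += slope * noise_sd * ms

    lam = lib[None, :] * np.exp2(np.clip(log2cpm, -10, 14)) / 1e6
    counts = rng.poisson(lam).astype(np.int64)
    expr = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=meth.columns)
    genes = pd.DataFrame(
        {"tss_pos": rng.integers(1, max(2, meth.shape[0] * 300), n_genes), "low": low},
        index=expr.index,
    )
    genes.attrs["flowcell"] = pd.Series(
        [f"FC{f + 1}" for f in flow], index=meth.columns, name="flowcell"
    )
    return expr, genes


def dilution_experiment(
    n_per_sex: int = 5000,
    beta1: float = 0.002,
    n_replicates: int = 50,
    seed: int = 0,
) -> dict[str, float]:
    """Measure the male/female slope ratio for an Xa-specific mean effect.

    For each replicate a single-CpG landscape with a mid-range baseline gets
    an Xa-only age slope; per-sex ordinary least squares on the raw betas
    estimates the apparent slope.  Because females measure the average of an
    affected Xa and an unaffected Xi, the male/female ratio converges to 2.
    Returns the mean ratio, the per-sex mean slopes and the Monte-Carlo SE.
    """
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_replicates)
    slopes_m = np.empty(n_replicates)
    slopes_f = np.empty(n_replicates)
    for r in range(n_replicates):
        land = generate_landscape(1, seed=int(rng.integers(2**31 - 1)))
        cpgs = land.cpgs.copy()
        cpgs.loc[:, "baseline_xa"] = 0.45
        cpgs.loc[:, "baseline_xi"] = 0.70
        land = replace(land, cpgs=cpgs)
        truth = pd.DataFrame(
            {
                "effect_type": ["mean"],
                "beta1_true": [beta1],
                "gamma1_true": [0.0],
                "xa_specific": [True],
                "mechanism": ["allele"],
            },
            index=land.cpgs.index,
        )
        cfg = SimConfig(confounding=False, batch_sd=0.0, cohort_sd=0.0)
        meth, samples = simulate_cohort(
            land, truth, n_per_sex, n_per_sex, config=cfg,
            seed=int(rng.integers(2**31 - 1)),
        )
        y = meth.iloc[0].to_numpy()
        slopes = {}
        for s in ("F", "M"):
            m = (samples["sex"] == s).to_numpy()
            a = samples["age"].to_numpy()[m]
            slopes[s] = float(np.polyfit(a, y[m], 1)[0])
        slopes_f[r], slopes_m[r] = slopes["F"], slopes["M"]
        ratios[r] = slopes["M"] / slopes["F"]
    return {
        "ratio_mean": float(np.mean(ratios)),
        "ratio_se": float(np.std(ratios, ddof=1) / np.sqrt(n_replicates)),
        "slope_m": float(np.mean(slopes_m)),
        "slope_f": float(np.mean(slopes_f)),
    }
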