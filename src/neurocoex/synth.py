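"""Seeded synthetic data with planted structure for every pipeline stage.

The generator emulates four inputs at once, sharing one gene universe:

* a developmental brain expression matrix (8 ordinal stages × 9 regions ×
  replicates) with K planted coexpression modules, each following a
  smooth trajectory peaking at a designated stage and preferring a region
  class (cortex / limbic / cerebellum);
* a per-cell-type mean-expression matrix in which each module is elevated
  in one assigned cell type by a configurable fold;
* a three-group case/control cortex dataset (control / OCD / eating
  disorder) with RIN, pH, age, PMI and sex covariates and a planted,
  cross-disorder-correlated differential-expression signal;
* a toy genome (genes tiled on two chromosomes) with one GWAS summary per
  disorder in which planted risk genes carry a sub-threshold tag SNP.

Expression is a factor model on the log10 scale: gene g in module m has
``z_g = mu_g + lambda_g * F_m + eps`` with the module factor F_m shared by
all its genes, so module recovery by correlation networks is well defined.
RPKM output is ``10**z - 1`` (floored at zero), which the downstream
``log10(x + 1)`` transform inverts exactly.

Ground truth (module membership, risk lists, true effects) is emitted
alongside the data so recovery tests never need to re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnalysisConfig,
    ExpressionDataset,
    GeneAnnotation,
    GeneSetCollection,
    GwasSummary,
    write_expression,
    write_gene_bed,
    write_gmt,
    write_gwas,
)

__all__ = [
    "SynthSpec",
    "SynthTruth",
    "module_assignment",
    "generate_developmental",
    "generate_cell_type",
    "generate_case_control",
    "generate_genome_and_gwas",
    "generate_gene_sets",
    "generate_bundle",
]

PERIODS = [f"P{i}" for i in range(1, 9)]  # P1-P4 prenatal, P5-P8 postnatal
CORTEX = ["PFC", "TC", "PC", "OC"]
LIMBIC = ["AMY", "HIP", "STR", "MD"]
REGIONS = CORTEX + LIMBIC + ["CB"]
CELL_TYPES = ["Ex_neuron", "In_neuron", "astrocyte", "endothelium",
              "microglia", "OPC", "oligodendrocyte"]


@dataclass
class SynthSpec:
    """Parameters of the synthetic study; defaults mirror the study design.

    Group sizes (102 controls, 16 OCD, 15 eating-disorder cases) and risk
    list sizes (92 AN, 51 OCD) reproduce the source cohorts.  Module count,
    loading range and noise levels are chosen so planted modules have
    within-module correlations in the high range typical of strongly
    trajectory-driven developmental expression.
    """

    n_genes: int = 2000
    n_modules: int = 8
    module_size: int = 150
    n_replicates: int = 3
    loading_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.15          # per-gene noise around the module factor
    background_noise_sd: float = 0.3
    trajectory_jitter_sd: float = 0.3  # sample-level (donor-like) factor jitter
    bump_width: float = 2.0         # stages; width of the trajectory peak
    offregion_weight: float = 0.4   # factor amplitude outside the preferred region class
    invariant_fraction: float = 0.15  # low/invariant genes for the filter to remove
    celltype_fold: float = 3.0
    # risk-gene spec
    n_an: int = 92
    n_ocd: int = 51
    planted_fraction: float = 0.3
    # designated disorder modules (0-based module indices)
    an_module: int = 5              # postnatal-peaking, limbic, endothelium
    ocd_module: int = 2             # prenatal-peaking, cortical, excitatory neuron
    # case/control spec
    n_control: int = 102
    n_ocd_cases: int = 16
    n_ed_cases: int = 15
    n_de: int = 300
    de_in_module_fraction: float = 0.2  # fraction of DE genes planted in the AN module
    de_module_shift: float = -0.8       # mean effect of module-planted DE genes
    effect_sd: float = 0.8
    rho: float = 0.7                # cross-disorder effect correlation
    var_prior_df: float = 4.0       # residual variances ~ scaled-inv-chi2(d0, s0^2)
    var_prior_scale: float = 0.04
    # genome spec
    gene_length: int = 10_000
    gene_gap: int = 40_000
    n_chromosomes: int = 2
    n_background_snps: int = 2000
    an_threshold: float = 5e-8
    ocd_threshold: float = 1e-5
    gwas_window: int = 20_000       # LD-window consistent with the gene tiling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules do not fit in n_genes")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must be in [-1, 1]")
        for name in ("n_genes", "n_modules", "module_size", "n_replicates",
                     "n_an", "n_ocd", "n_control", "n_ocd_cases", "n_ed_cases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def module_peak(self, m: int) -> int:
        """1-based peak stage of module m; modules cycle through the 8 stages."""
        return (m % len(PERIODS)) + 1

    def module_region_class(self, m: int) -> str:
        classes = ["cortex", "limbic", "cortex", "cortex",
                   "limbic", "limbic", "cortex", "limbic"]
        return classes[m % len(classes)]

    def module_cell_type(self, m: int) -> str:
        assigned = ["astrocyte", "microglia", "Ex_neuron", "oligodendrocyte",
                    "OPC", "endothelium", "In_neuron", "astrocyte"]
        return assigned[m % len(assigned)]


@dataclass
class SynthTruth:
    """Planted ground truth, serialized next to the data for recovery tests."""

    module_of: dict[str, str] = field(default_factory=dict)
    module_meta: dict[str, dict] = field(default_factory=dict)
    risk_genes: dict[str, list[str]] = field(default_factory=dict)
    de_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    rho: float | None = None

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.module_of.items() if m == label]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def merge(self, other: "SynthTruth") -> "SynthTruth":
        merged = SynthTruth(
            module_of={**self.module_of, **other.module_of},
            module_meta={**self.module_meta, **other.module_meta},
            risk_genes={**self.risk_genes, **other.risk_genes},
            de_effects={**self.de_effects, **other.de_effects},
            rho=other.rho if other.rho is not None else self.rho,
        )
        return merged


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def module_assignment(spec: SynthSpec) -> tuple[dict[str, str], list[str], list[str]]:
    """Deterministic gene → module layout shared by all generators.

    Returns (module_of, background_genes, invariant_genes).  The first
    ``n_modules * module_size`` genes form the modules, the last
    ``invariant_fraction`` of genes are low/invariant filler, and the
    remainder is expressed background noise.
    """
    genes = spec.gene_ids
    n_planted = spec.n_modules * spec.module_size
    n_invariant = int(round(spec.invariant_fraction * spec.n_genes))
    n_invariant = min(n_invariant, spec.n_genes - n_planted)
    module_of = {}
    for m in range(spec.n_modules):
        for g in genes[m * spec.module_size:(m + 1) * spec.module_size]:
            module_of[g] = f"mod{m}"
    invariant = genes[spec.n_genes - n_invariant:]
    background = genes[n_planted:spec.n_genes - n_invariant]
    return module_of, background, invariant


def _trajectory(spec: SynthSpec, m: int, period_rank: np.ndarray,
                region: np.ndarray) -> np.ndarray:
    """Raw (unstandardized) module factor over samples: bump × region weight."""
    peak = spec.module_peak(m)
    bump = np.exp(-((period_rank - peak) ** 2) / (2.0 * spec.bump_width**2))
    cls = spec.module_region_class(m)
    preferred = {"cortex": CORTEX, "limbic": LIMBIC, "CB": ["CB"]}[cls]
    weight = np.where(np.isin(region, preferred), 1.0, spec.offregion_weight)
    return bump * weight


def generate_developmental(spec: SynthSpec) -> tuple[ExpressionDataset, SynthTruth]:
    """Developmental RPKM matrix with planted trajectory-driven modules."""
    rng = _rng(spec, 1)
    module_of, background, invariant = module_assignment(spec)
    genes = spec.gene_ids

    sample_ids, period, region, rep = [], [], [], []
    for p_i, p in enumerate(PERIODS, start=1):
        for r in REGIONS:
            for k in range(1, spec.n_replicates + 1):
                sample_ids.append(f"{p}_{r}_{k}")
                period.append(p)
                region.append(r)
                rep.append(k)
    period_rank = np.array([PERIODS.index(p) + 1 for p in period], dtype=float)
    region_arr = np.array(region)
    n_samples = len(sample_ids)

    # standardized module factors with sample-level jitter (donor variation)
    factors = np.empty((spec.n_modules, n_samples))
    for m in range(spec.n_modules):
        f = _trajectory(spec, m, period_rank, region_arr)
        f = f + rng.normal(0.0, spec.trajectory_jitter_sd, n_samples)
        factors[m] = (f - f.mean()) / f.std()

    z = np.zeros((spec.n_genes, n_samples))  # filler rows overwritten below
    mu = rng.normal(1.5, 0.25, spec.n_genes)
    lo, hi = spec.loading_range
    for m in range(spec.n_modules):
        rows = slice(m * spec.module_size, (m + 1) * spec.module_size)
        lam = rng.uniform(lo, hi, spec.module_size)
        eps = rng.normal(0.0, spec.noise_sd, (spec.module_size, n_samples))
        z[rows] = mu[rows, None] + lam[:, None] * factors[m] + eps

    if background:
        i0 = spec.n_modules * spec.module_size
        i1 = i0 + len(background)
        z[i0:i1] = (mu[i0:i1, None]
                    + rng.normal(0.0, spec.background_noise_sd,
                                 (len(background), n_samples)))

    rpkm = np.maximum(10.0 ** np.clip(z, 0.0, None) - 1.0, 0.0)

    # invariant/low filler: half exactly constant (CV = 0), half mostly-zero
    n_inv = len(invariant)
    if n_inv:
        i0 = spec.n_genes - n_inv
        half = n_inv // 2
        rpkm[i0:i0 + half] = rng.uniform(1.0, 10.0, half)[:, None]
        low = rng.uniform(0.0, 0.5, (n_inv - half, n_samples))
        mask = rng.random((n_inv - half, n_samples)) < 0.7
        low[mask] = 0.0
        rpkm[i0 + half:] = low

    meta = pd.DataFrame({
        "sample": sample_ids,
        "period": period,
        "period_rank": [PERIODS.index(p) + 1 for p in period],
        "epoch": ["prenatal" if PERIODS.index(p) < 4 else "postnatal"
                  for p in period],
        "region": region,
        "region_class": ["cortex" if r in CORTEX else
                         ("limbic" if r in LIMBIC else "CB") for r in region],
        "replicate": rep,
    }).set_index("sample")

    dataset = ExpressionDataset(genes, sample_ids, rpkm, meta)

    truth = SynthTruth(
        module_of={**module_of,
                   **{g: "background" for g in background},
                   **{g: "invariant" for g in invariant}},
        module_meta={
            f"mod{m}": {
                "peak_period": spec.module_peak(m),
                "epoch": "prenatal" if spec.module_peak(m) <= 4 else "postnatal",
                "region_class": spec.module_region_class(m),
                "cell_type": spec.module_cell_type(m),
            }
            for m in range(spec.n_modules)
        },
    )
    return dataset, truth


def generate_cell_type(spec: SynthSpec) -> ExpressionDataset:
    """Mean expression per cell type; each module elevated in its own type.

    One column per cell type (a mean profile, as produced by averaging
    single-cell data), rows ordered exactly as the developmental genes.
    """
    rng = _rng(spec, 2)
    module_of, background, invariant = module_assignment(spec)
    genes = spec.gene_ids
    n_ct = len(CELL_TYPES)

    base = 10.0 ** rng.normal(1.0, 0.3, spec.n_genes)
    values = base[:, None] * rng.uniform(0.8, 1.2, (spec.n_genes, n_ct))
    for m in range(spec.n_modules):
        ct = CELL_TYPES.index(spec.module_cell_type(m))
        rows = slice(m * spec.module_size, (m + 1) * spec.module_size)
        values[rows, ct] *= spec.celltype_fold

    meta = pd.DataFrame({
        "sample": CELL_TYPES,
        "cell_type": CELL_TYPES,
    }).set_index("sample")
    return ExpressionDataset(genes, list(CELL_TYPES), values, meta)


def generate_case_control(spec: SynthSpec) -> tuple[ExpressionDataset, SynthTruth]:
    """Three-group cortex expression with covariates and planted DE signal.

    For planted DE genes the per-disorder effects (ED, OCD) are drawn from
    a bivariate normal with correlation ``rho``; a fraction of DE genes is
    placed inside the AN-designated module with a negative mean shift, so
    that module reads out as downregulated in eating-disorder cortex.
    Per-gene residual variances follow a scaled inverse chi-square prior.
    """
    if min(spec.n_control, spec.n_ocd_cases, spec.n_ed_cases) < 2:
        raise ValueError("each group needs >= 2 samples for variance estimation")
    rng = _rng(spec, 3)
    module_of, background, invariant = module_assignment(spec)
    genes = spec.gene_ids
    n = spec.n_control + spec.n_ocd_cases + spec.n_ed_cases

    group = (["control"] * spec.n_control + ["OCD"] * spec.n_ocd_cases
             + ["ED"] * spec.n_ed_cases)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    covars = pd.DataFrame({
        "sample": sample_ids,
        "group": group,
        "RIN": rng.uniform(5.0, 9.0, n),
        "pH": rng.uniform(6.0, 7.0, n),
        "age": rng.uniform(16.0, 70.0, n),
        "PMI": rng.uniform(5.0, 40.0, n),
        "sex": rng.integers(0, 2, n),
    }).set_index("sample")
    # guard against a degenerate all-one-sex draw
    if covars["sex"].nunique() == 1:
        covars.iloc[0, covars.columns.get_loc("sex")] = 1 - covars["sex"].iloc[0]

    # choose DE genes: a slice of the AN module plus random other genes
    n_de = spec.n_de
    de_genes: list[str] = []
    if n_de:
        n_mod = int(round(spec.de_in_module_fraction * n_de))
        an_genes = [g for g, m in module_of.items() if m == f"mod{spec.an_module}"]
        n_mod = min(n_mod, len(an_genes))
        mod_de = list(rng.choice(an_genes, size=n_mod, replace=False))
        eligible = [g for g in genes
                    if g not in set(mod_de) and g not in set(invariant)]
        other_de = list(rng.choice(eligible, size=n_de - n_mod, replace=False))
        de_genes = mod_de + other_de

    cov = spec.effect_sd**2 * np.array([[1.0, spec.rho], [spec.rho, 1.0]])
    effects = np.zeros((spec.n_genes, 2))  # columns: ED, OCD
    if de_genes:
        draws = rng.multivariate_normal([0.0, 0.0], cov, size=len(de_genes))
        gi = {g: i for i, g in enumerate(genes)}
        for j, g in enumerate(de_genes):
            shift = spec.de_module_shift if j < n_mod else 0.0
            effects[gi[g]] = draws[j] + shift

    d0, s0sq = spec.var_prior_df, spec.var_prior_scale
    sigma_sq = d0 * s0sq / rng.chisquare(d0, spec.n_genes)

    X_ed = (np.array(group) == "ED").astype(float)
    X_ocd = (np.array(group) == "OCD").astype(float)
    C = covars[["RIN", "pH", "age", "PMI", "sex"]].to_numpy(dtype=float)
    Cc = C - C.mean(axis=0)
    coef = rng.normal(0.0, 0.05, (spec.n_genes, 5))

    intercept = rng.normal(7.0, 1.0, spec.n_genes)
    y = (intercept[:, None]
         + np.outer(effects[:, 0], X_ed)
         + np.outer(effects[:, 1], X_ocd)
         + coef @ Cc.T
         + rng.standard_normal((spec.n_genes, n)) * np.sqrt(sigma_sq)[:, None])

    dataset = ExpressionDataset(genes, sample_ids, y, covars)
    truth = SynthTruth(
        de_effects={g: {"ED": float(effects[i, 0]), "OCD": float(effects[i, 1])}
                    for i, g in enumerate(genes) if g in set(de_genes)},
        rho=spec.rho,
    )
    return dataset, truth


def _choose_risk_genes(spec: SynthSpec, rng: np.random.Generator,
                       n_risk: int, module_idx: int) -> list[str]:
    module_of, background, invariant = module_assignment(spec)
    label = f"mod{module_idx}"
    in_module = [g for g, m in module_of.items() if m == label]
    n_in = min(int(round(spec.planted_fraction * n_risk)), len(in_module), n_risk)
    chosen = list(rng.choice(in_module, size=n_in, replace=False))
    eligible = [g for g in spec.gene_ids
                if g not in set(chosen) and g not in set(invariant)
                and module_of.get(g) != label]
    chosen += list(rng.choice(eligible, size=n_risk - n_in, replace=False))
    return sorted(chosen)


def generate_genome_and_gwas(
    spec: SynthSpec,
) -> tuple[GeneAnnotation, dict[str, GwasSummary], SynthTruth]:
    """Toy genome plus one GWAS summary per disorder.

    Genes are tiled ``gene_length`` bp each with ``gene_gap`` bp gaps on
    ``n_chromosomes`` synthetic chromosomes.  Every planted risk gene gets
    one tag SNP inside its interval with p drawn log-uniform below the
    disorder threshold; background SNPs are uniform above it.
    """
    rng = _rng(spec, 4)
    genes = spec.gene_ids
    pitch = spec.gene_length + spec.gene_gap
    per_chrom = int(np.ceil(spec.n_genes / spec.n_chromosomes))
    rows = []
    for i, g in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        start = 10_000 + (i % per_chrom) * pitch
        rows.append((g, chrom, start, start + spec.gene_length))
    annotation = GeneAnnotation(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))
    coords = {g: (c, s, e) for g, c, s, e in rows}
    chrom_len = 10_000 + per_chrom * pitch

    risk = {
        "AN": _choose_risk_genes(spec, rng, spec.n_an, spec.an_module),
        "OCD": _choose_risk_genes(spec, rng, spec.n_ocd, spec.ocd_module),
    }
    thresholds = {"AN": spec.an_threshold, "OCD": spec.ocd_threshold}

    gwas = {}
    for disorder, gene_list in risk.items():
        thr = thresholds[disorder]
        recs = []
        for j, g in enumerate(gene_list):
            chrom, start, end = coords[g]
            pos = int(rng.integers(start + 1, end + 1))  # 1-based inside gene
            logp = rng.uniform(np.log10(thr) - 4.0, np.log10(thr))
            recs.append((f"rs{disorder}_{j}", chrom, pos, 10.0 ** logp))
        for j in range(spec.n_background_snps):
            chrom = f"chr{int(rng.integers(1, spec.n_chromosomes + 1))}"
            pos = int(rng.integers(1, chrom_len + 1))
            recs.append((f"rs{disorder}_bg{j}", chrom, pos,
                         float(rng.uniform(thr, 1.0))))
        gwas[disorder] = GwasSummary(
            pd.DataFrame(recs, columns=["snp", "chrom", "pos", "p"]))

    truth = SynthTruth(risk_genes=risk)
    return annotation, gwas, truth


def generate_gene_sets(spec: SynthSpec, n_random: int = 10,
                       random_size: int = 50) -> GeneSetCollection:
    """GMT-style collection: one set per planted module plus random sets."""
    rng = _rng(spec, 5)
    module_of, background, invariant = module_assignment(spec)
    sets: dict[str, tuple[str, list[str]]] = {}
    for m in range(spec.n_modules):
        members = [g for g, lab in module_of.items() if lab == f"mod{m}"]
        sets[f"pathway_mod{m}"] = (f"genes of planted module {m}", members)
    universe = [g for g in spec.gene_ids if g not in set(invariant)]
    for j in range(n_random):
        members = sorted(rng.choice(universe, size=random_size, replace=False))
        sets[f"pathway_rand{j}"] = ("random gene set", list(members))
    return GeneSetCollection(sets)


def generate_bundle(spec: SynthSpec, outdir: str | Path) -> SynthTruth:
    """Write the complete synthetic input bundle plus truth.json and config.

    Produces every file the pipeline driver consumes: developmental and
    case/control expression (TSV + CSV metadata), cell-type matrix, gene
    BED, per-disorder GWAS TSVs, a GMT collection, a ready-to-run YAML
    config whose LD window matches the synthetic gene tiling, and the
    merged ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dev, truth = generate_developmental(spec)
    write_expression(dev, outdir / "expression.tsv", outdir / "expression_meta.csv")

    ct = generate_cell_type(spec)
    write_expression(ct, outdir / "celltype.tsv", outdir / "celltype_meta.csv")

    cc, cc_truth = generate_case_control(spec)
    write_expression(cc, outdir / "casecontrol.tsv", outdir / "casecontrol_meta.csv")
    truth = truth.merge(cc_truth)

    annotation, gwas, gw_truth = generate_genome_and_gwas(spec)
    write_gene_bed(annotation, outdir / "genes.bed")
    write_gwas(gwas["AN"], outdir / "an_gwas.tsv")
    write_gwas(gwas["OCD"], outdir / "ocd_gwas.tsv")
    truth = truth.merge(gw_truth)

    write_gmt(generate_gene_sets(spec), outdir / "genesets.gmt")
    truth.to_json(outdir / "truth.json")

    config = AnalysisConfig(
        an_gwas_threshold=spec.an_threshold,
        ocd_gwas_threshold=spec.ocd_threshold,
        ld_window=spec.gwas_window,
        seed=spec.seed,
        expression=str(outdir / "expression.tsv"),
        expression_meta=str(outdir / "expression_meta.csv"),
        celltype_expression=str(outdir / "celltype.tsv"),
        celltype_meta=str(outdir / "celltype_meta.csv"),
        casecontrol=str(outdir / "casecontrol.tsv"),
        casecontrol_meta=str(outdir / "casecontrol_meta.csv"),
        gene_bed=str(outdir / "genes.bed"),
        an_gwas=str(outdir / "an_gwas.tsv"),
        ocd_gwas=str(outdir / "ocd_gwas.tsv"),
        gene_sets=str(outdir / "genesets.gmt"),
    )
    config.to_yaml(outdir / "config.yaml")
    return truth
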