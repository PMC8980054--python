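"""Synthetic twin-structured methylation cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: adult blood (or child buccal) cohorts containing monozygotic (MZ)
pairs, dizygotic (DZ) pairs and singletons; a binary phenotype drawn from a
liability-threshold model with a polygenic, a family-shared and a unique
component; methylation beta-values produced on the logit scale from a CpG
intercept, covariate effects, a family-shared component, locally correlated
CpG "blocks" and unique noise, then mapped through the logistic function and
clipped to (0, 1).

Planted effects are specified on the *beta-value* scale (the scale on which
all regressions run) and converted to the logit scale by dividing by the
average logistic density over the realised linear predictor, so that the
expected case−control beta-value difference equals the requested effect to
first order.

All randomness flows from the single ``seed`` in :class:`SimConfig` through
one :class:`numpy.random.Generator`; identical configs give byte-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from twinewas.datatypes import DataError, MethylationDataset

BETA_CLIP = 1e-6

#: Mean blood cell proportions used for the Dirichlet covariate draw
#: (neutrophils, lymphocytes, monocytes, eosinophils, basophils).
BLOOD_CELL_MEANS = {
    "neut": 0.52,
    "lymph": 0.33,
    "mono": 0.08,
    "eos": 0.055,
    "baso": 0.015,
}


class SimulationError(DataError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults describe an adult twin-register blood cohort: ~2682 samples of
    which roughly 40% sit in MZ pairs and 30% in DZ pairs, left-handedness
    prevalence 12%, and 20,000 array CpGs arranged in short correlated
    blocks across 22 autosomes.

    Parameters that matter most downstream:

    prevalence_K
        Population prevalence of the phenotype (left-handedness: 0.08-0.15
        across cohorts; default 0.12).
    block_rho
        Exchangeable correlation of methylation residuals between CpGs of
        the same block. Must satisfy ``block_rho <= 1 - family_meth_var``.
    family_liability_var
        Liability variance shared within a family (MZ co-twins share it
        fully, DZ co-twins half); default 0.25, the ballpark of twin-study
        heritability estimates for handedness.
    pgs_liability_r2
        Liability variance explained by the true polygenic score (0 = the
        null configuration).
    planted_dmps
        List of ``(cpg_index, delta)`` pairs: case-minus-control methylation
        difference ``delta`` on the beta-value scale.
    planted_dmrs
        List of ``(block_index, delta)`` pairs: every CpG of the block gets
        the per-CpG beta-scale effect ``delta``.
    """

    n_samples: int = 2682
    family_structure: dict = field(
        default_factory=lambda: {"mz_pairs": 0.4, "dz_pairs": 0.3, "singletons": 0.3}
    )
    prevalence_K: float = 0.12
    n_cpgs: int = 20000
    n_chromosomes: int = 22
    block_size_range: tuple = (2, 6)
    block_spacing_bp: int = 150
    block_gap_bp: tuple = (20000, 200000)
    block_rho: float = 0.5
    #: Total per-CpG noise SD on the logit scale. 0.2 gives residual
    #: beta-scale SDs of ~0.05 at mid-methylation CpGs and much less at
    #: extreme CpGs, the magnitude implied by per-CpG standard errors in
    #: published blood EWAS of this size.
    sigma_logit: float = 0.2
    family_meth_var: float = 0.15
    family_liability_var: float = 0.25
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.05, "sex": 0.08, "smoking": 0.10, "neut": 0.15}
    )
    planted_dmps: list = field(default_factory=list)
    planted_dmrs: list = field(default_factory=list)
    enrichment_shift: float = 0.0
    n_snps: int = 1000
    n_causal_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    pgs_liability_r2: float = 0.0
    n_trait_loci: int = 20
    n_control_loci: int = 20
    cohort_type: str = "adult"  # "adult" (blood) or "child" (buccal)
    cohort_name: str = "cohort"
    n_plates: int = 8
    n_rows: int = 12
    seed: int = 0
    #: Seed for the array layout (CpG blocks, positions, per-CpG intercepts).
    #: Cohorts of one study share a manifest: give them the same
    #: manifest_seed and different sample seeds. None = use ``seed``.
    manifest_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_K < 1:
            raise SimulationError("prevalence_K must lie in (0, 1)")
        if not 0 <= self.block_rho < 1:
            raise SimulationError("block_rho must lie in [0, 1)")
        if self.block_rho > 1 - self.family_meth_var:
            raise SimulationError(
                "block_rho + family_meth_var must not exceed 1 "
                "(both are shares of the per-CpG logit noise variance)"
            )
        for name in ("n_samples", "n_cpgs", "n_chromosomes", "n_snps"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        total = sum(self.family_structure.values())
        if abs(total - 1.0) > 1e-8:
            raise SimulationError("family_structure proportions must sum to 1")
        if not 0 <= self.pgs_liability_r2 < 1:
            raise SimulationError("pgs_liability_r2 must lie in [0, 1)")
        if self.pgs_liability_r2 + self.family_liability_var >= 1:
            raise SimulationError("liability variance components must sum to < 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi == 0.5)):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        if self.cohort_type not in ("adult", "child"):
            raise SimulationError("cohort_type must be 'adult' or 'child'")


@dataclass
class SyntheticCohort:
    """A generated cohort plus everything needed to score and to check it."""

    dataset: MethylationDataset
    genotypes: pd.DataFrame  # samples × SNPs dosages in {0,1,2}
    locus_sets: dict  # name -> DataFrame(snp, chr, pos, p)
    truth: dict

    def __post_init__(self) -> None:
        zyg = self.dataset.samples["zygosity"]
        fam = self.dataset.samples["family_id"]
        for fid, members in self.dataset.samples.groupby("family_id").groups.items():
            if len(members) == 2 and (zyg.loc[members] == "MZ").all():
                g = self.genotypes.loc[members].to_numpy()
                if not np.array_equal(g[0], g[1]):
                    raise SimulationError(f"MZ co-twins in family {fid} differ in genotype")
            _ = fam  # family ids already validated by grouping


def _family_layout(config: SimConfig, rng: np.random.Generator):
    """Assign samples to MZ pairs, DZ pairs and singletons."""
    n = config.n_samples
    p_mz = config.family_structure.get("mz_pairs", 0.0)
    p_dz = config.family_structure.get("dz_pairs", 0.0)
    n_mz = int(round(n * p_mz / 2))
    n_dz = int(round(n * p_dz / 2))
    n_single = n - 2 * (n_mz + n_dz)
    if n_single < 0:  # rounding overshoot
        n_dz += n_single // 2
        n_single = n - 2 * (n_mz + n_dz)
    family_id, zygosity, twin_slot = [], [], []
    fid = 0
    for _ in range(n_mz):
        fid += 1
        family_id += [fid, fid]
        zygosity += ["MZ", "MZ"]
        twin_slot += [0, 1]
    for _ in range(n_dz):
        fid += 1
        family_id += [fid, fid]
        zygosity += ["DZ", "DZ"]
        twin_slot += [0, 1]
    for _ in range(n_single):
        fid += 1
        family_id.append(fid)
        zygosity.append("NA")
        twin_slot.append(0)
    sample_id = [f"s{i:05d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "family_id": [f"fam{f:04d}" for f in family_id],
            "zygosity": zygosity,
            "_slot": twin_slot,
        }
    ).set_index("sample_id")


def _simulate_genotypes(layout: pd.DataFrame, config: SimConfig, rng: np.random.Generator):
    """Mendelian transmission within families: MZ co-twins share both
    gametes, DZ co-twins draw independent gametes from the same parents."""
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    fam_codes, fam_index = pd.factorize(layout["family_id"])
    n_fam = len(fam_index)
    # Parental allele pairs per family: father (a1,a2), mother (b1,b2).
    par = rng.random((n_fam, 4, config.n_snps)) < mafs  # bool alleles
    n = len(layout)
    G = np.zeros((n, config.n_snps), dtype=np.int8)
    slot = layout["_slot"].to_numpy()
    zyg = layout["zygosity"].to_numpy()
    # Gamete choices: which paternal / maternal allele each meiosis passes.
    pick = rng.integers(0, 2, size=(n, 2, config.n_snps))
    for i in range(n):
        f = fam_codes[i]
        if zyg[i] == "MZ" and slot[i] == 1:
            j = i - 1  # co-twin generated immediately before
            G[i] = G[j]
            continue
        pat = par[f, pick[i, 0], np.arange(config.n_snps)]
        mat = par[f, 2 + pick[i, 1], np.arange(config.n_snps)]
        G[i] = pat.astype(np.int8) + mat.astype(np.int8)
    snp_ids = [f"rs{i:06d}" for i in range(1, config.n_snps + 1)]
    return pd.DataFrame(G, index=layout.index, columns=snp_ids), mafs


def _family_shared_normal(layout: pd.DataFrame, rng: np.random.Generator, size=None):
    """Per-sample standard-normal draws with correlation 1 within MZ pairs
    and 0.5 within DZ pairs. ``size`` optionally adds trailing dimensions."""
    fam_codes, fam_index = pd.factorize(layout["family_id"])
    shape_fam = (len(fam_index),) if size is None else (len(fam_index),) + tuple(size)
    shape_ind = (len(layout),) if size is None else (len(layout),) + tuple(size)
    a_fam = rng.standard_normal(shape_fam)
    a_own = rng.standard_normal(shape_ind)
    zyg = layout["zygosity"].to_numpy()
    out = a_fam[fam_codes]
    dz = zyg == "DZ"
    out[dz] = np.sqrt(0.5) * out[dz] + np.sqrt(0.5) * a_own[dz]
    return out


def _simulate_covariates(layout: pd.DataFrame, config: SimConfig, rng: np.random.Generator):
    n = len(layout)
    fam_codes, fam_index = pd.factorize(layout["family_id"])
    cov = pd.DataFrame(index=layout.index)
    if config.cohort_type == "adult":
        fam_age = rng.uniform(25, 65, size=len(fam_index))
        cov["age"] = fam_age[fam_codes]  # co-twins share age
        cov["sex"] = rng.integers(0, 2, size=n)
        mz = layout["zygosity"].to_numpy() == "MZ"
        slot1 = layout["_slot"].to_numpy() == 1
        sex = cov["sex"].to_numpy()
        sex[mz & slot1] = sex[np.flatnonzero(mz & slot1) - 1]  # MZ pairs same sex
        cov["sex"] = sex
        cov["bmi"] = np.clip(25 + 2.5 * _family_shared_normal(layout, rng)
                             + 2.5 * rng.standard_normal(n), 16, 45)
        cov["smoking"] = (rng.random(n) < 0.25).astype(int)
    else:
        fam_age = rng.uniform(6, 12, size=len(fam_index))
        cov["age"] = fam_age[fam_codes]
        cov["sex"] = rng.integers(0, 2, size=n)
        mz = layout["zygosity"].to_numpy() == "MZ"
        slot1 = layout["_slot"].to_numpy() == 1
        sex = cov["sex"].to_numpy()
        sex[mz & slot1] = sex[np.flatnonzero(mz & slot1) - 1]
        cov["sex"] = sex
        ga_fam = np.clip(39.0 + 1.6 * rng.standard_normal(len(fam_index)), 28, 43)
        cov["gestational_age"] = ga_fam[fam_codes]
        cov["birth_weight"] = np.clip(
            3300 + 180 * (cov["gestational_age"] - 39) + 380 * rng.standard_normal(n),
            800, 5500,
        )
        msm_fam = (rng.random(len(fam_index)) < 0.15).astype(int)
        cov["maternal_smoking"] = msm_fam[fam_codes]
        cov["bmi"] = np.clip(17 + 2.0 * rng.standard_normal(n), 12, 35)
        cov["smoking"] = 0
    # Cell proportions: Dirichlet around typical blood means.
    names = list(BLOOD_CELL_MEANS)
    alpha = np.array([BLOOD_CELL_MEANS[k] for k in names]) * 200
    cells = rng.dirichlet(alpha, size=n)
    for k, name in enumerate(names):
        cov[name] = cells[:, k]
    cov["plate"] = np.array([f"P{v + 1}" for v in rng.integers(0, config.n_plates, size=n)])
    cov["row"] = np.array([f"R{v + 1}" for v in rng.integers(0, config.n_rows, size=n)])
    return cov


def _simulate_manifest(config: SimConfig, rng: np.random.Generator):
    """Lay CpGs out in blocks along chromosomes; returns (manifest, block_id)."""
    lo, hi = config.block_size_range
    sizes = []
    total = 0
    while total < config.n_cpgs:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, config.n_cpgs - total)
        sizes.append(s)
        total += s
    n_blocks = len(sizes)
    block_chrom = rng.integers(1, config.n_chromosomes + 1, size=n_blocks)
    order = np.argsort(block_chrom, kind="stable")
    chroms, positions, block_ids = [], [], []
    pos_cursor = {}
    for b in order:
        c = int(block_chrom[b])
        gap = int(rng.integers(config.block_gap_bp[0], config.block_gap_bp[1]))
        start = pos_cursor.get(c, 0) + gap
        for k in range(sizes[b]):
            chroms.append(str(c))
            positions.append(start + k * config.block_spacing_bp)
            block_ids.append(b)
        pos_cursor[c] = positions[-1]
    cpg_ids = [f"cg{i:07d}" for i in range(1, config.n_cpgs + 1)]
    manifest = pd.DataFrame({"chr": chroms, "pos": positions}, index=pd.Index(cpg_ids, name="cpg"))
    return manifest, np.asarray(block_ids)


def _simulate_locus_sets(manifest: pd.DataFrame, config: SimConfig, rng: np.random.Generator):
    """Trait and control SNP locus lists placed on the simulated genome."""
    chrom_max = manifest.groupby("chr")["pos"].max()
    sets = {}
    for name, n_loci, pscale in (
        ("trait", config.n_trait_loci, 1e-9),
        ("control", config.n_control_loci, 1e-9),
    ):
        chrs = rng.choice(chrom_max.index.to_numpy(), size=n_loci)
        pos = np.array([int(rng.integers(1, chrom_max[c] + 1)) for c in chrs])
        sets[name] = pd.DataFrame(
            {
                "snp": [f"snp_{name}_{i:03d}" for i in range(1, n_loci + 1)],
                "chr": chrs,
                "pos": pos,
                "p": rng.uniform(0.1, 1.0, size=n_loci) * pscale,
            }
        )
    return sets


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Simulate one cohort under ``config``.

    Returns a :class:`SyntheticCohort` whose ``truth`` record holds the
    planted CpG/DMR effects (ids and beta-scale deltas), the causal SNP
    weights of the polygenic component and the true liability-scale
    variance explained, for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    mseed = config.seed if config.manifest_seed is None else config.manifest_seed
    mrng = np.random.default_rng(mseed)
    layout = _family_layout(config, rng)
    genotypes, mafs = _simulate_genotypes(layout, config, rng)
    covariates = _simulate_covariates(layout, config, rng)

    # --- liability-threshold phenotype ---------------------------------
    n = len(layout)
    r2 = config.pgs_liability_r2
    c2 = config.family_liability_var
    causal = rng.choice(config.n_snps, size=min(config.n_causal_snps, config.n_snps), replace=False)
    w = np.zeros(config.n_snps)
    w[causal] = rng.standard_normal(len(causal))
    raw_pgs = genotypes.to_numpy(dtype=float) @ w
    sd = raw_pgs.std(ddof=0)
    pgs_std = (raw_pgs - raw_pgs.mean()) / sd if sd > 0 else np.zeros(n)
    fam_liab = _family_shared_normal(layout, rng)
    eps = rng.standard_normal(n)
    liability = np.sqrt(r2) * pgs_std + np.sqrt(c2) * fam_liab + np.sqrt(1 - r2 - c2) * eps
    threshold = norm.ppf(1 - config.prevalence_K)
    handedness = (liability > threshold).astype(float)

    # --- methylation ----------------------------------------------------
    # Array layout and per-CpG baselines are properties of the assay and
    # the epigenome, not of the cohort: drawn from the manifest seed.
    manifest, block_id = _simulate_manifest(config, mrng)
    m = config.n_cpgs
    mu = np.clip(mrng.normal(0.0, 1.2, size=m), -3.5, 3.5)  # logit-scale intercepts

    lp = np.tile(mu[:, None], (1, n))
    for cov_name, eff in config.covariate_effects.items():
        if cov_name not in covariates.columns:
            raise SimulationError(f"covariate_effects refers to unknown covariate {cov_name!r}")
        x = covariates[cov_name].to_numpy(dtype=float)
        xs = (x - x.mean()) / (x.std(ddof=0) or 1.0)
        lp += eff * xs[None, :]
    # Small technical (plate) effects so residualization is exercised.
    plate_codes, plates = pd.factorize(covariates["plate"])
    plate_eff = rng.normal(0, 0.03, size=(m, len(plates)))
    lp += plate_eff[:, plate_codes]

    sigma = config.sigma_logit
    v_f = config.family_meth_var
    v_b = config.block_rho
    v_u = 1.0 - v_f - v_b
    fam_comp = _family_shared_normal(layout, rng, size=(m,))  # n × m
    lp += sigma * np.sqrt(v_f) * fam_comp.T
    if v_b > 0:
        n_blocks = block_id.max() + 1
        b_comp = rng.standard_normal((n_blocks, n))
        lp += sigma * np.sqrt(v_b) * b_comp[block_id]
    lp += sigma * np.sqrt(v_u) * rng.standard_normal((m, n))

    # --- planted case-control effects (beta scale -> logit scale) -------
    cpg_ids = manifest.index.to_numpy()
    planted = {}
    for j, delta in config.planted_dmps:
        planted[int(j)] = planted.get(int(j), 0.0) + float(delta)
    for b, delta in config.planted_dmrs:
        for j in np.flatnonzero(block_id == int(b)):
            planted[int(j)] = planted.get(int(j), 0.0) + float(delta)
    case = handedness == 1
    for j, delta in planted.items():
        deriv = expit(lp[j]) * (1 - expit(lp[j]))
        scale = deriv.mean()
        if scale < 1e-4:
            raise SimulationError(
                f"planted effect at CpG {cpg_ids[j]} infeasible: methylation saturated"
            )
        dl = delta / scale
        target = expit(lp[j]).mean() + delta
        if not (BETA_CLIP < target < 1 - BETA_CLIP):
            raise SimulationError(
                f"planted effect {delta} at CpG {cpg_ids[j]} targets a mean "
                f"beta of {target:.3f}, outside (0, 1)"
            )
        shifted = expit(lp[j, case] + dl)
        frac_clipped = np.mean((shifted < BETA_CLIP) | (shifted > 1 - BETA_CLIP))
        if frac_clipped > 0.01:
            raise SimulationError(
                f"planted effect {delta} at CpG {cpg_ids[j]} pushes beta out of "
                f"[0,1] for {frac_clipped:.1%} of samples"
            )
        lp[j, case] += dl

    beta = np.clip(expit(lp), BETA_CLIP, 1 - BETA_CLIP)

    samples = layout.drop(columns=["_slot"]).copy()
    samples["handedness"] = handedness
    samples = samples.join(covariates)
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=manifest.index, columns=layout.index),
        manifest=manifest,
        samples=samples,
    )

    locus_sets = _simulate_locus_sets(manifest, config, rng)
    truth = {
        "planted_dmps": [
            {"cpg": str(cpg_ids[j]), "index": int(j), "delta": float(d)}
            for j, d in sorted(planted.items())
        ],
        "planted_dmr_blocks": [
            {
                "block": int(b),
                "delta": float(d),
                "cpgs": [str(c) for c in cpg_ids[block_id == int(b)]],
            }
            for b, d in config.planted_dmrs
        ],
        "pgs_weights": {f"rs{i + 1:06d}": float(w[i]) for i in causal},
        "pgs_liability_r2": float(r2),
        "prevalence_K": float(config.prevalence_K),
        "case_fraction": float(handedness.mean()),
        "block_id": [int(b) for b in block_id],
        "seed": int(config.seed),
        "config": {k: v for k, v in asdict(config).items()
                   if not isinstance(v, (list, dict, tuple))},
    }
    return SyntheticCohort(dataset=dataset, genotypes=genotypes, locus_sets=locus_sets, truth=truth)


def generate_summary_null(n_cpgs: int, indicator, shift: float, seed: int) -> pd.DataFrame:
    """Summary-level simulation for enrichment calibration.

    Z-scores are N(0, 1) where ``indicator == 0`` and N(``shift``, 1) where
    ``indicator == 1``; two-sided normal p-values; beta = z with SE = 1 so
    the summary schema stays internally consistent.
    """
    indicator = np.asarray(indicator)
    if indicator.shape != (n_cpgs,):
        raise DataError(f"indicator length {indicator.shape} != n_cpgs {n_cpgs}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_cpgs) + shift * indicator
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "cpg": [f"cg{i:07d}" for i in range(1, n_cpgs + 1)],
            "chr": "1",
            "pos": np.arange(1, n_cpgs + 1) * 1000,
            "beta": z,
            "se": 1.0,
            "z": z,
            "p": p,
            "n": np.nan,
            "cohort": "summary-sim",
            "model": "null" if shift == 0 else f"shift={shift}",
        }
    )
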