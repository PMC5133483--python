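"""Synthetic family study generator: pedigrees, gene-dropped genotypes,
covariates and expression with known architecture.

The generator emulates the structure the family eQTL analysis assumes:
multigenerational pedigrees, Mendelian transmission of founder alleles,
and per-probe expression built from fixed covariate effects, a polygenic
component with covariance sigma_g^2 * 2*Phi, an optional causal cis-SNP
effect, two latent batch factors shared across probes, and i.i.d. Gaussian
noise.  Every probe's ground truth (causal SNP, effect size, narrow-sense
heritability, batch loadings) is returned in a :class:`TruthTable` so the
whole pipeline is testable without any restricted study data.

Variance bookkeeping: sigma_g^2 + sigma_e^2 = 1 per probe, with
sigma_g^2 = h2_true, so h2 has its narrow-sense meaning relative to the
polygenic-plus-residual variance.  The causal SNP's effect size is scaled so
that the SNP explains a requested fraction of the total residual variance
(polygenic + noise + batch + SNP), making the single-SNP regression R^2
match that fraction in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (CovariateTable, ExpressionMatrix, GenotypeMatrix,
                         Pedigree, ProbeAnnotation)
from .relatedness import KinshipMatrix


@dataclass
class PedigreeStructure:
    """Per-family layout: one founder couple per generation branch.

    ``children_per_generation`` lists, for each non-founder generation, how
    many offspring are produced.  Generation 1 children are offspring of the
    founder couple; in each later generation the first child of the previous
    generation marries a new founder and produces the listed number of
    offspring.  With ``children_per_generation=[4]`` a family is a nuclear
    2-founder + 4-offspring sibship of size 6.
    """

    children_per_generation: list[int] = field(default_factory=lambda: [4])

    def family_size(self) -> int:
        if not self.children_per_generation:
            raise ValueError("structure must have at least one generation of children")
        size = 2  # founder couple
        for g, c in enumerate(self.children_per_generation):
            if g > 0:
                size += 1  # married-in founder
            size += c
        return size


def simulate_pedigree(n_families: int, structure: PedigreeStructure,
                      seed: int | np.random.Generator = 0) -> Pedigree:
    """Generate ``n_families`` disjoint families with the given structure.

    Deterministic for a fixed seed (sexes of offspring are the only random
    draw).  Individual ids are ``F<f>_I<k>``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not structure.children_per_generation:
        raise ValueError("structure must have at least one generation of children")
    rows = []
    for f in range(n_families):
        fam = f"F{f + 1}"
        k = 0

        def new_id():
            nonlocal k
            k += 1
            return f"{fam}_I{k}"

        dad, mom = new_id(), new_id()
        rows.append((fam, dad, None, None, 1))
        rows.append((fam, mom, None, None, 2))
        prev_first_child = None
        for g, n_children in enumerate(structure.children_per_generation):
            if g == 0:
                father, mother = dad, mom
            else:
                spouse = new_id()
                # married-in founder; sex opposite to the lineal parent
                rows.append((fam, spouse, None, None, 2 if g % 2 else 1))
                father, mother = prev_first_child, spouse
            first = None
            for _ in range(n_children):
                cid = new_id()
                sex = int(rng.integers(1, 3))
                rows.append((fam, cid, father, mother, sex))
                if first is None:
                    first = cid
            prev_first_child = first
    return Pedigree(pd.DataFrame(rows, columns=["family", "individual",
                                                "father", "mother", "sex"]))


def drop_genotypes(pedigree: Pedigree, snp_spec: pd.DataFrame,
                   seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Mendelian gene drop of biallelic SNPs through a pedigree.

    ``snp_spec`` needs columns chrom, pos, maf (and optionally id).  Founder
    alleles are i.i.d. Bernoulli(maf); each offspring inherits one uniformly
    chosen allele per parent.  Dosage is the allele sum, so children are
    Mendelian-consistent with their parents by construction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    maf = np.asarray(snp_spec["maf"], dtype=float)
    if ((maf < 0) | (maf > 0.5)).any():
        raise ValueError("maf must lie in [0, 0.5]")
    ped = pedigree.sorted_parents_first()
    t = ped.table
    ids = t["individual"].tolist()
    idx = {iid: k for k, iid in enumerate(ids)}
    n, s = len(ids), len(maf)

    alleles = np.empty((n, 2, s), dtype=np.int8)
    loci = np.arange(s)
    for k, (_, row) in enumerate(t.iterrows()):
        f, m = row["father"], row["mother"]
        if f is None:
            alleles[k] = rng.random((2, s)) < maf
        else:
            alleles[k, 0] = alleles[idx[f], rng.integers(0, 2, s), loci]
            alleles[k, 1] = alleles[idx[m], rng.integers(0, 2, s), loci]
    dosage = alleles.sum(axis=1).astype(float)

    snps = pd.DataFrame({
        "id": snp_spec["id"] if "id" in snp_spec else
              [f"snp_{c}_{p}" for c, p in zip(snp_spec["chrom"], snp_spec["pos"])],
        "chrom": snp_spec["chrom"].astype(str),
        "pos": snp_spec["pos"].astype(int),
        "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(ids, snps.reset_index(drop=True), dosage)


def uniform_snp_spec(n_snps: int, chroms: tuple[str, ...] = ("1", "2"),
                     chrom_len: int = 250_000_000,
                     maf_low: float = 0.05, maf_high: float = 0.5,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Evenly spaced SNP positions on synthetic chromosomes with U(maf_low,
    maf_high) allele frequencies; spacing controls the cis-window SNP count."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    per = int(np.ceil(n_snps / len(chroms)))
    rows = []
    for c in chroms:
        pos = np.linspace(1, chrom_len, per, dtype=int)
        pos = np.unique(pos)
        for p in pos:
            rows.append((c, int(p)))
    rows = rows[:n_snps]
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["maf"] = rng.uniform(maf_low, maf_high, len(df))
    return df


@dataclass
class TruthTable:
    """Per-probe ground truth of the simulated architecture."""

    table: pd.DataFrame  # probe_id, causal_snp_id, beta_s, h2_true, batch_l1, batch_l2

    def __post_init__(self) -> None:
        t = self.table
        has_snp = t["causal_snp_id"].notnull()
        if not ((t["beta_s"] != 0) == has_snp).all():
            raise ValueError("beta_s must be nonzero iff a causal SNP is set")
        if (t["h2_true"] >= 1).any() or (t["h2_true"] < 0).any():
            raise ValueError("h2_true must lie in [0, 1)")

    def causal_probes(self) -> list[str]:
        t = self.table
        return t.loc[t["causal_snp_id"].notnull(), "probe_id"].tolist()


@dataclass
class ExpressionParams:
    """Architecture of the simulated expression panel.

    n_probes: probe count, laid out alternately on the genotype chromosomes.
    causal_fraction: fraction of probes given one causal cis SNP.
    snp_var_frac: fraction of each causal probe's total residual variance
        (polygenic + noise + batch + SNP) explained by the SNP.
    h2_dist: (low, high) of the uniform distribution of true heritability.
    batch_sd: s.d. of per-probe loadings on the 2 latent batch factors.
    beta_age, beta_sex, beta_smoking: fixed covariate effects, small and
        nonzero by default so adjustment is exercised.
    cis_window_bp: half-width used when picking a causal SNP for a probe.
    """

    n_probes: int = 200
    causal_fraction: float = 0.1
    snp_var_frac: float = 0.2
    h2_dist: tuple[float, float] = (0.0, 0.9)
    h2_fixed: float | None = None
    batch_sd: float = 0.3
    beta_age: float = 0.005
    beta_sex: float = 0.1
    beta_smoking: float = 0.1
    cis_window_bp: int = 1_000_000
    tx_len: int = 10_000


def simulate_covariates(pedigree: Pedigree,
                        rng: np.random.Generator) -> CovariateTable:
    """Age ~ U(20, 80); sex taken from the pedigree; smoking ~ Bernoulli(0.5)."""
    ids = pedigree.individual_ids
    t = pd.DataFrame({
        "age": rng.uniform(20, 80, len(ids)),
        "sex": (np.asarray(pedigree.table["sex"]) == 2).astype(int),
        "smoking": rng.integers(0, 2, len(ids)),
    }, index=pd.Index(ids, name="sample_id"))
    return CovariateTable(t)


def simulate_expression_panel(pedigree: Pedigree, kinship: KinshipMatrix,
                              genotypes: GenotypeMatrix,
                              params: ExpressionParams,
                              seed: int | np.random.Generator = 0,
                              ) -> tuple[ExpressionMatrix, ProbeAnnotation,
                                         CovariateTable, TruthTable]:
    """Simulate a probe panel with polygenic, cis-SNP and batch components.

    For each probe::

        Y = b0 + b1*age + b2*sex + b3*smoking + L1*f1 + L2*f2
            + beta_s*SNP + g + eps

    with g ~ MVN(0, h2 * 2*Phi) sampled per family block, eps ~ N(0, 1-h2),
    and f1, f2 latent per-sample batch factors shared across probes so that
    expression PCA can recover them.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = params
    ids = kinship.sample_ids
    if ids != pedigree.sorted_parents_first().individual_ids:
        # only the sample set must agree; order follows the kinship matrix
        if set(ids) != set(pedigree.individual_ids):
            raise ValueError("kinship does not match pedigree samples")
    geno = genotypes.subset_samples(ids)
    n = len(ids)

    h2 = (np.full(p.n_probes, float(p.h2_fixed)) if p.h2_fixed is not None
          else rng.uniform(*p.h2_dist, p.n_probes))
    if (h2 >= 1).any():
        raise ValueError("h2 must be < 1")

    covar = simulate_covariates(pedigree, rng)
    cov = covar.table.loc[ids]

    # probe coordinates: alternate over genotype chromosomes, evenly spaced
    chroms = sorted(geno.snps["chrom"].unique().tolist())
    chrom_max = {c: int(geno.snps.loc[geno.snps["chrom"] == c, "pos"].max())
                 for c in chroms}
    ann_rows = []
    for j in range(p.n_probes):
        c = chroms[j % len(chroms)]
        k = j // len(chroms)
        n_on_c = (p.n_probes + len(chroms) - 1 - (j % len(chroms))) // len(chroms)
        start = int(1 + (k + 0.5) / max(n_on_c, 1) * (chrom_max[c] - p.tx_len))
        ann_rows.append((f"probe_{j + 1}", f"GENE{j + 1}", c,
                         start, start + p.tx_len))
    ann = pd.DataFrame(ann_rows, columns=["probe_id", "gene_symbol", "chrom",
                                          "tx_start", "tx_end"])

    # choose causal probes and one cis SNP each
    n_causal = int(round(p.causal_fraction * p.n_probes))
    causal_idx = rng.choice(p.n_probes, n_causal, replace=False)
    dose = geno.imputed_dosage()
    snp_pos = geno.snps["pos"].to_numpy()
    snp_chrom = geno.snps["chrom"].to_numpy()
    causal_snp = np.full(p.n_probes, None, dtype=object)
    beta_s = np.zeros(p.n_probes)

    # family-block Cholesky of 2*Phi for the polygenic draws
    K = kinship.additive_relationship()
    chol_blocks = [(a, b, np.linalg.cholesky(
        K[a:b, a:b] + 1e-10 * np.eye(b - a))) for a, b in kinship.family_blocks]
    z = rng.standard_normal((n, p.n_probes))
    g = np.empty_like(z)
    for a, b, L in chol_blocks:
        g[a:b] = L @ z[a:b]
    g *= np.sqrt(h2)[None, :]

    eps = rng.standard_normal((n, p.n_probes)) * np.sqrt(1.0 - h2)[None, :]

    factors = rng.standard_normal((n, 2))
    loadings = rng.normal(0.0, p.batch_sd, (p.n_probes, 2))
    batch = factors @ loadings.T  # n x probes
    batch_var = (loadings ** 2).sum(axis=1)

    Y = np.empty((p.n_probes, n))
    base = (p.beta_age * cov["age"].to_numpy()
            + p.beta_sex * cov["sex"].to_numpy()
            + p.beta_smoking * cov["smoking"].to_numpy())
    for j in range(p.n_probes):
        y = base + batch[:, j] + g[:, j] + eps[:, j]
        if j in set(causal_idx):
            a = ann.iloc[j]
            in_cis = np.where(
                (snp_chrom == a["chrom"])
                & (snp_pos >= a["tx_start"] - p.cis_window_bp)
                & (snp_pos <= a["tx_end"] + p.cis_window_bp))[0]
            usable = in_cis[dose[:, in_cis].std(axis=0) > 0]
            if usable.size:
                s_idx = int(rng.choice(usable))
                s = dose[:, s_idx]
                v_rest = 1.0 + batch_var[j]  # polygenic + noise + batch
                f = p.snp_var_frac
                b = np.sqrt(f / (1.0 - f) * v_rest / s.var())
                causal_snp[j] = geno.snps.iloc[s_idx]["id"]
                beta_s[j] = b
                y = y + b * s
        Y[j] = y

    truth = TruthTable(pd.DataFrame({
        "probe_id": ann["probe_id"], "causal_snp_id": causal_snp,
        "beta_s": beta_s, "h2_true": h2,
        "batch_l1": loadings[:, 0], "batch_l2": loadings[:, 1],
    }))
    expr = ExpressionMatrix(ann["probe_id"].tolist(), list(ids), Y)
    return expr, ProbeAnnotation(ann), covar, truth


# ---------------------------------------------------------------------------
# Canonical study scenarios
# ---------------------------------------------------------------------------

@dataclass
class Study:
    """A complete simulated family study, ready for the scan."""

    pedigree: Pedigree
    kinship: "KinshipMatrix"
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    annotation: ProbeAnnotation
    covariates: CovariateTable
    truth: TruthTable


def _make_study(seed: int, n_families: int, children: int, n_snps: int,
                params: ExpressionParams) -> Study:
    from .relatedness import kinship_from_pedigree

    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(n_families, PedigreeStructure([children]), rng)
    kin = kinship_from_pedigree(ped)
    spec = uniform_snp_spec(n_snps, seed=rng)
    geno = drop_genotypes(ped, spec, rng)
    expr, ann, covar, truth = simulate_expression_panel(ped, kin, geno,
                                                        params, rng)
    return Study(ped, kin, geno, expr, ann, covar, truth)


def planted_eqtl_study(seed: int = 0, n_families: int = 50, children: int = 4,
                       n_snps: int = 3750, n_probes: int = 200,
                       causal_fraction: float = 0.1,
                       snp_var_frac: float = 0.2) -> Study:
    """Planted-eQTL recovery scenario: 300 samples in 50 six-member
    families, 200 probes of which 10% carry a causal cis SNP explaining
    20% of the probe's variance.

    SNPs sit every ~133 kb on two 250 Mb chromosomes, giving ~15 SNPs per
    2 Mb cis window; a 200-probe panel spread over such a genome has probes
    megabases apart, so cis windows of distinct probes do not overlap —
    as for a sparse panel on a real genome.  Probe heritabilities are drawn
    U(0.6, 0.9): eGenes are empirically a moderate-to-high-heritability
    class, and concentrating the panel in the top heritability bin keeps
    the shared permutation pool large enough for the bin-level empirical p
    (resolution 1/(3 x bin occupancy)) to resolve below the FDR threshold
    at this panel size.
    """
    params = ExpressionParams(n_probes=n_probes,
                              causal_fraction=causal_fraction,
                              snp_var_frac=snp_var_frac,
                              h2_dist=(0.6, 0.9))
    return _make_study(seed, n_families, children, n_snps, params)


def global_null_study(seed: int = 0, n_families: int = 50, children: int = 4,
                      n_snps: int = 3750, n_probes: int = 500) -> Study:
    """Global-null scenario: no causal SNPs anywhere, heritability drawn
    U(0, 0.9) so the probes span all seven heritability bins."""
    params = ExpressionParams(n_probes=n_probes, causal_fraction=0.0,
                              snp_var_frac=0.0, h2_dist=(0.0, 0.9))
    return _make_study(seed, n_families, children, n_snps, params)


# ---------------------------------------------------------------------------
# Writers for the formats io_formats reads
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages back out as an unphased GT-only VCF 4.2 file."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for k, row in geno.snps.iterrows():
            gts = [code.get(d, "./.") if not np.isnan(d) else "./."
                   for d in geno.dosage[:, k]]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def write_expression(expr: ExpressionMatrix, ann: ProbeAnnotation,
                     expr_path: str | Path, ann_path: str | Path) -> None:
    pd.DataFrame(expr.values, index=pd.Index(expr.probe_ids, name="probe_id"),
                 columns=expr.sample_ids).to_csv(expr_path, sep="\t")
    ann.table.to_csv(ann_path, sep="\t", index=False)


def write_covariates(covar: CovariateTable, path: str | Path) -> None:
    covar.table.to_csv(path, sep="\t")


def write_truth(truth: TruthTable, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
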