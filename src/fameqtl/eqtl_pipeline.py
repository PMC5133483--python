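"""The cis-eQTL scan: windows, association, surrogate permutations, FDR.

Orchestration of the family-based scan:

1.  Expression PCs (Pc1, Pc2) are computed and appended to the covariates.
2.  Per probe, heritability is estimated from the covariates-only mixed
    model and the probe is assigned to one of seven h2 bins with fixed
    edges {0, .1, .2, .3, .4, .5, .6, 1}.
3.  Every SNP within 1 Mb of the transcript start or end is tested by the
    mixed model Wald test; the probe's minimum raw p over its N_g cis SNPs
    is multiplied by the effective-tests factor (N_g + 1)/2 (capped at 1).
4.  A familial-correlation-preserving null is built by surrogate
    permutation: each probe's values are reordered by the sample ranking of
    a random same-bin probe, the cis scan is rerun, and the minimum
    adjusted p is deposited into the bin's null pool (three permutations
    per probe).
5.  Each probe's observed adjusted p is converted to an empirical p
    against its bin pool, (r+1)/(B+1), and Benjamini-Hochberg FDR at
    q = 0.05 flags significant probes (eGenes).  Cis SNPs of significant
    probes whose own adjusted p reaches the same empirical threshold are
    reported as eSNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import (CovariateTable, ExpressionMatrix, GenotypeMatrix,
                         ProbeAnnotation, ScanConfig, check_sample_alignment,
                         get_logger, log_stage)
from .lmm_core import (KinshipEigen, eigen_kinship, fit_rotated_fast,
                       normality_scan, pca_covariates, reml_fit, wald_p)
from .relatedness import KinshipMatrix, block_view

H2_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0)


@dataclass
class CisSet:
    """SNPs in one probe's cis window; n_g is the per-gene test count."""

    probe_id: str
    snp_ids: list[str]
    snp_indices: np.ndarray  # column indices into the genotype matrix

    @property
    def n_g(self) -> int:
        return len(self.snp_ids)


def cis_window_snps(probe: pd.Series, genotypes: GenotypeMatrix,
                    window_bp: int = 1_000_000,
                    anchor: str = "transcript") -> CisSet:
    """SNPs on the probe's chromosome within ``window_bp`` of the transcript.

    ``anchor='transcript'`` takes the window from transcript start AND end
    (tx_start - w <= pos <= tx_end + w, boundaries inclusive);
    ``anchor='tss'`` measures from the transcript start site only.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if anchor == "transcript":
        lo, hi = probe["tx_start"] - window_bp, probe["tx_end"] + window_bp
    elif anchor == "tss":
        lo, hi = probe["tx_start"] - window_bp, probe["tx_start"] + window_bp
    else:
        raise ValueError(f"unknown cis anchor {anchor!r}")
    snps = genotypes.snps
    mask = ((snps["chrom"] == probe["chrom"]).to_numpy()
            & (snps["pos"].to_numpy() >= lo) & (snps["pos"].to_numpy() <= hi))
    idx = np.where(mask)[0]
    return CisSet(probe["probe_id"], snps["id"].iloc[idx].tolist(), idx)


def assign_h2_bins(h2: np.ndarray,
                   edges: tuple[float, ...] = H2_BIN_EDGES) -> np.ndarray:
    """Bin label (1..len(edges)-1) per probe; intervals closed on the left,
    last interval closed on both ends."""
    h2 = np.asarray(h2, float)
    if ((h2 < 0) | (h2 > 1)).any():
        raise ValueError("h2 outside [0, 1]")
    labels = np.digitize(h2, edges[1:-1], right=False) + 1
    return labels


def merge_sparse_bins(bins: np.ndarray, n_bins: int,
                      min_probes: int = 2) -> np.ndarray:
    """Merge adjacent heritability bins until every occupied group holds at
    least ``min_probes`` probes, so each probe has surrogate candidates and
    a non-empty null pool.

    Returns a relabelled copy of ``bins`` (labels renumbered 1..k by
    ascending heritability); empty bins are absorbed silently.  The
    published seven-bin summary keeps the original labels.
    """
    counts = [int((bins == b).sum()) for b in range(1, n_bins + 1)]
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_n = 0
    for b, c in zip(range(1, n_bins + 1), counts):
        cur.append(b)
        cur_n += c
        if cur_n >= min_probes:
            groups.append(cur)
            cur, cur_n = [], 0
    if cur:
        if groups and 0 < cur_n < min_probes:
            groups[-1].extend(cur)  # tail too sparse: absorb backwards
        elif cur_n > 0:
            groups.append(cur)
        elif groups:
            groups[-1].extend(cur)
    label_of = {}
    for g, members in enumerate(groups, start=1):
        for b in members:
            label_of[b] = g
    merged = np.array([label_of[int(b)] for b in bins])
    if len(groups) < sum(1 for c in counts if c):
        get_logger().info("merged %d heritability bins into %d groups "
                          "(sparse bins)", n_bins, len(groups))
    return merged


def surrogate_permute(y_target: np.ndarray, candidate_values: np.ndarray,
                      rng: np.random.Generator,
                      forced_surrogate: int | None = None,
                      ) -> tuple[np.ndarray, int]:
    """Reorder a probe's values by the sample ranking of a same-bin surrogate.

    ``candidate_values`` is (n_candidates, n_samples), excluding the target
    probe itself.  The output holds exactly the multiset of ``y_target``
    values: the sample holding the surrogate's rank-r value receives the
    target's rank-r value.  This preserves the familial correlation pattern
    of the surrogate while keeping the target's marginal distribution.
    Ties in the surrogate are broken by sample index (stable sort).
    """
    if candidate_values.ndim != 2 or candidate_values.shape[0] < 1:
        raise ValueError("need at least one surrogate candidate; "
                         "merge heritability bins if a bin is too sparse")
    k = (int(rng.integers(0, candidate_values.shape[0]))
         if forced_surrogate is None else forced_surrogate)
    s = candidate_values[k]
    order = np.argsort(s, kind="stable")
    out = np.empty_like(np.asarray(y_target, float))
    out[order] = np.sort(y_target)
    return out, k


def effective_test_adjust(p_min: float, n_g: int) -> float:
    """Adjust a probe's minimum p for its N_g cis tests: min(1, p*(N_g+1)/2).

    (N_g + 1)/2 estimates the effective number of tests among LD-correlated
    cis SNPs.  n_g = 0 means no test exists; callers skip the record.
    """
    if n_g < 1:
        raise ValueError("n_g must be >= 1 (no tests exist for n_g = 0)")
    if not (0 < p_min <= 1):
        raise ValueError("p_min must lie in (0, 1]")
    return min(1.0, p_min * (n_g + 1) / 2.0)


def empirical_p(observed_adjusted_p: float, null_pool: np.ndarray) -> float:
    """(r + 1)/(B + 1) with r = #{null <= observed}; always in (0, 1]."""
    pool = np.asarray(null_pool, float)
    if pool.size == 0:
        raise ValueError("empty permutation null pool")
    r = int(np.count_nonzero(pool <= observed_adjusted_p))
    return (r + 1) / (pool.size + 1)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags (ties share fate)."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return np.zeros(0, bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class PermutationNull:
    """Per-bin pools of minimum adjusted p statistics from permutations."""

    bin_edges: tuple[float, ...]
    pools: dict[int, np.ndarray]  # bin label -> sorted statistics

    def pool(self, bin_label: int) -> np.ndarray:
        if bin_label not in self.pools or self.pools[bin_label].size == 0:
            raise ValueError(f"no permutation statistics in bin {bin_label}; "
                             "merge bins or add probes")
        return self.pools[bin_label]

    @property
    def counts(self) -> dict[int, int]:
        return {b: int(v.size) for b, v in self.pools.items()}


@dataclass
class EqtlRecord:
    """One probe-SNP association with all p-value layers."""

    probe_id: str
    gene_symbol: str
    snp_id: str
    chromosome: str
    position: int
    beta_s: float
    raw_p: float
    adjusted_p: float
    empirical_p: float
    fdr_significant: bool


# ---------------------------------------------------------------------------
# Scan internals
# ---------------------------------------------------------------------------

@dataclass
class _ScanWorkspace:
    """Precomputed rotated quantities shared by the observed scan and all
    permutation rescans."""

    eig: KinshipEigen
    Xr: np.ndarray            # rotated covariate design (n x p0)
    Yr: np.ndarray            # rotated expression (probes x n)
    Gr: np.ndarray            # rotated imputed dosages (n x snps)
    dose: np.ndarray
    names: list[str]
    raw_Y_sample: np.ndarray = None  # sample-space expression (probes x n)


def _min_p_scan(ws: _ScanWorkspace, yr: np.ndarray, snp_idx: np.ndarray,
                collect: bool = False) -> tuple[float, int, np.ndarray, np.ndarray]:
    """Wald-test every cis SNP for one (possibly permuted) phenotype.

    Returns (min raw p, argmin position, per-SNP raw p, per-SNP beta);
    the per-SNP arrays are filled only when ``collect`` is True.
    """
    from scipy.stats import chi2

    m = snp_idx.size
    pvals = np.full(m, np.nan) if collect else np.empty(0)
    betas = np.full(m, np.nan) if collect else np.empty(0)
    best_p, best_k = 1.0, 0
    lam = ws.eig.lam
    X = np.empty((ws.Xr.shape[0], ws.Xr.shape[1] + 1))
    X[:, :-1] = ws.Xr
    for k, j in enumerate(snp_idx):
        X[:, -1] = ws.Gr[:, j]
        beta, se, _gamma = fit_rotated_fast(yr, X, lam)
        p = float(chi2.sf((beta / se) ** 2, 1)) if se > 0 else float("nan")
        if collect:
            pvals[k] = p
            betas[k] = beta
        if np.isfinite(p) and p < best_p:
            best_p, best_k = float(p), k
    return best_p, best_k, pvals, betas


def build_null(ws: _ScanWorkspace, cis_sets: list[CisSet],
               bins: np.ndarray, n_perm_per_probe: int,
               rng: np.random.Generator,
               bin_edges: tuple[float, ...] = H2_BIN_EDGES,
               ) -> PermutationNull:
    """Surrogate-permute every probe ``n_perm_per_probe`` times, rerun its
    cis scan, and pool the minimum adjusted p per heritability bin.

    Surrogates are drawn with replacement across repeats, excluding only the
    target probe itself.
    """
    pools: dict[int, list[float]] = {b: [] for b in range(1, len(bin_edges))}
    by_bin: dict[int, np.ndarray] = {
        b: np.where(bins == b)[0] for b in range(1, len(bin_edges))}
    for i, cs in enumerate(cis_sets):
        if cs.n_g == 0:
            continue
        b = int(bins[i])
        candidates = by_bin[b][by_bin[b] != i]
        if candidates.size == 0:
            raise ValueError(f"probe {cs.probe_id}: no surrogate candidates in "
                             f"bin {b}; merge heritability bins")
        for _ in range(n_perm_per_probe):
            y_perm, _k = surrogate_permute(ws.raw_Y_sample[i],
                                           ws.raw_Y_sample[candidates], rng)
            yr = ws.eig.rotate(y_perm)
            p_min, *_ = _min_p_scan(ws, yr, cs.snp_indices)
            pools[b].append(effective_test_adjust(max(p_min, 1e-300), cs.n_g))
    out: dict[int, np.ndarray] = {}
    for b, vals in pools.items():
        if by_bin[b].size and not vals:
            raise ValueError(f"heritability bin {b} produced no permutation "
                             "statistics; merge bins")
        out[b] = np.sort(np.asarray(vals))
    return PermutationNull(tuple(bin_edges), out)


@dataclass
class ScanResult:
    """Everything the cis scan produces."""

    records: list[EqtlRecord]
    null: PermutationNull
    probe_table: pd.DataFrame    # probe-level: h2, bin, n_g, min/adj/emp p, flag
    summary: dict
    normality: pd.DataFrame


def run_cis_eqtl_scan(genotypes: GenotypeMatrix, expr: ExpressionMatrix,
                      annotation: ProbeAnnotation, covariates: CovariateTable,
                      kinship: KinshipMatrix, config: ScanConfig | None = None,
                      rng: np.random.Generator | int = 0) -> ScanResult:
    """Run the full family-based cis-eQTL scan on aligned in-memory inputs."""
    cfg = config or ScanConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    log = get_logger()

    samples = check_sample_alignment(expr, covariates, genotypes)
    kin = block_view(kinship, samples)
    samples = kin.sample_ids  # family-major order
    expr = expr.subset_samples(samples)
    geno = genotypes.subset_samples(samples)

    with log_stage("pca_covariates"):
        pcs = pca_covariates(expr, k=2)
        cov = covariates.table.loc[samples].copy()
        cov["pc1"], cov["pc2"] = pcs[:, 0], pcs[:, 1]
        covariates = CovariateTable(cov)
    X = covariates.design_matrix(samples)

    with log_stage("normality_scan"):
        norm = normality_scan(expr)
        frac = float(norm["bonferroni_significant"].mean())
        log.info("normality_scan: %.1f%% of probes non-normal after Bonferroni",
                 100 * frac)

    with log_stage("rotation"):
        eig = eigen_kinship(kin)
        Xr = eig.rotate(X)
        dose = geno.imputed_dosage()
        Gr = eig.rotate(dose)
        Yr = np.vstack([eig.rotate(y) for y in expr.values])
    ws = _ScanWorkspace(eig=eig, Xr=Xr, Yr=Yr, Gr=Gr, dose=dose,
                        names=["intercept", "age", "sex", "smoking", "pc1", "pc2"],
                        raw_Y_sample=expr.values)

    ann = annotation.table.set_index("probe_id", drop=False).loc[expr.probe_ids]

    with log_stage("h2_and_bins"):
        h2 = np.array([reml_fit(Yr[i], Xr, eig=eig, rotated=True).h2
                       for i in range(len(expr.probe_ids))])
        edges = tuple(cfg.h2_bin_edges)
        bins = assign_h2_bins(h2, edges)
        scan_bins = merge_sparse_bins(bins, len(edges) - 1, min_probes=2)

    with log_stage("cis_sets"):
        cis_sets = [cis_window_snps(ann.iloc[i], geno, cfg.window_bp,
                                    cfg.cis_anchor)
                    for i in range(len(expr.probe_ids))]
        log.info("cis_sets: mean N_g = %.1f",
                 float(np.mean([c.n_g for c in cis_sets])))

    with log_stage("observed_scan"):
        obs_adj = np.full(len(cis_sets), np.nan)
        snp_p: list[np.ndarray] = []
        snp_beta: list[np.ndarray] = []
        for i, cs in enumerate(cis_sets):
            if cs.n_g == 0:
                snp_p.append(np.empty(0))
                snp_beta.append(np.empty(0))
                continue
            p_min, _, pv, bs = _min_p_scan(ws, Yr[i], cs.snp_indices, collect=True)
            snp_p.append(pv)
            snp_beta.append(bs)
            obs_adj[i] = effective_test_adjust(max(p_min, 1e-300), cs.n_g)

    with log_stage("permutation_null"):
        null = build_null(ws, cis_sets, scan_bins, cfg.n_perm, rng, edges)
        log.info("null pools: %s", null.counts)

    with log_stage("empirical_and_fdr"):
        tested = np.array([cs.n_g > 0 for cs in cis_sets])
        emp = np.full(len(cis_sets), np.nan)
        for i in np.where(tested)[0]:
            emp[i] = empirical_p(obs_adj[i], null.pool(int(scan_bins[i])))
        flags = np.zeros(len(cis_sets), bool)
        flags[tested] = bh_fdr(emp[tested], cfg.fdr_q)
        # empirical-p cutoff implied by BH: largest rejected empirical p
        cutoff = float(emp[tested][flags[tested]].max()) if flags.any() else 0.0

    with log_stage("records"):
        records: list[EqtlRecord] = []
        for i, cs in enumerate(cis_sets):
            if cs.n_g == 0:
                continue
            a = ann.iloc[i]
            pool = null.pool(int(scan_bins[i]))
            for k, j in enumerate(cs.snp_indices):
                s = geno.snps.iloc[j]
                p_raw = float(snp_p[i][k])
                if not np.isfinite(p_raw):
                    continue
                adj = effective_test_adjust(max(p_raw, 1e-300), cs.n_g)
                e = empirical_p(adj, pool)
                is_esnp = bool(flags[i]) and e <= cutoff
                records.append(EqtlRecord(
                    probe_id=cs.probe_id, gene_symbol=a["gene_symbol"],
                    snp_id=s["id"], chromosome=s["chrom"], position=int(s["pos"]),
                    beta_s=float(snp_beta[i][k]), raw_p=p_raw, adjusted_p=adj,
                    empirical_p=e, fdr_significant=is_esnp))

    probe_table = pd.DataFrame({
        "probe_id": expr.probe_ids, "gene_symbol": ann["gene_symbol"].tolist(),
        "h2": h2, "h2_bin": bins,
        "n_g": [cs.n_g for cs in cis_sets],
        "adjusted_p": obs_adj, "empirical_p": emp, "fdr_significant": flags,
    })
    summary = summarize_scan(records, probe_table, tuple(cfg.h2_bin_edges))
    log.info("scan: %d eSNPs, %d eGenes, %d eQTL pairs",
             summary["n_esnps"], summary["n_egenes"], summary["n_eqtl_pairs"])
    return ScanResult(records, null, probe_table, summary, norm)


def summarize_scan(records: list[EqtlRecord], probe_table: pd.DataFrame,
                   edges: tuple[float, ...] = H2_BIN_EDGES) -> dict:
    """eSNP/eGene/pair counts plus the per-bin breakdown (eSNPs, genes
    tested, mean SNPs per gene)."""
    sig = [r for r in records if r.fdr_significant]
    esnps = {r.snp_id for r in sig}
    egenes = {r.probe_id for r in sig}
    per_bin = []
    for b in range(1, len(edges)):
        sub = probe_table[probe_table["h2_bin"] == b]
        probes_b = set(sub["probe_id"])
        per_bin.append({
            "h2_bin": f"{edges[b - 1]:g}-{edges[b]:g}",
            "esnps": len({r.snp_id for r in sig if r.probe_id in probes_b}),
            "genes_tested": int((sub["n_g"] > 0).sum()),
            "snps_per_gene_mean": float(sub.loc[sub["n_g"] > 0, "n_g"].mean())
            if (sub["n_g"] > 0).any() else 0.0,
        })
    return {
        "n_esnps": len(esnps),
        "n_egenes": len(egenes),
        "n_eqtl_pairs": len(sig),
        "esnps_multi_gene": sum(
            1 for s in esnps
            if len({r.probe_id for r in sig if r.snp_id == s}) > 1),
        "per_bin": per_bin,
    }
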