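"""Inversion effects on gene expression and trait associations.

Targeted cis-eQTL testing regresses rank-normalized, covariate-adjusted
expression on inversion O2-allele dosage for features with a transcription
start site within a window of the inversion, with Benjamini–Hochberg FDR
across all tested pairs and a genotype-permutation negative-control mode.
A joint analysis ranks the inversion among nearby variants per feature to
flag lead eQTLs.  Trait associations are assessed by clustering GWAS
signals into loci and comparing the locus count inside an inversion ±20 kb
against matched random genomic regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenotypeTable, InversionRecord, InvpopkitError, VariantPanel


# ---------------------------------------------------------------------------
# Rank normalization
# ---------------------------------------------------------------------------

def rank_normalize(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Map values to N(0,1) scores through their ranks (Blom offset).

    score_i = Phi^{-1}((rank_i - offset) / (n + 1 - 2*offset)), ties
    averaged.  Invariant to any monotone transform of the input; raises on
    constant vectors (no rank information).
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 3:
        raise InvpopkitError("need at least 3 non-missing values")
    if np.nanstd(x) == 0:
        raise InvpopkitError("constant vector cannot be rank-normalized")
    out = np.full_like(x, np.nan)
    r = stats.rankdata(x[ok])
    n = ok.sum()
    out[ok] = stats.norm.ppf((r - offset) / (n + 1 - 2 * offset))
    return out


# ---------------------------------------------------------------------------
# Targeted inversion eQTL
# ---------------------------------------------------------------------------

@dataclass
class EQTLResult:
    table: pd.DataFrame          # feature, beta, t, p, q, n, tss_distance
    covariates_used: list[str]
    n_tested: int
    permuted: bool = False


def _expression_pcs(expr: np.ndarray, n_pcs: int) -> np.ndarray:
    centred = expr - expr.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    k = min(n_pcs, u.shape[1])
    return u[:, :k] * s[:k]


def inversion_eqtl(
    gt: GenotypeTable,
    inversion: str,
    expression: pd.DataFrame,
    tss: dict[str, tuple[str, int]] | None = None,
    inv_record: InversionRecord | None = None,
    covariates: pd.DataFrame | None = None,
    n_expression_pcs: int = 10,
    window: int = 1_000_000,
    fdr: float = 0.05,
    min_expressed_fraction: float = 0.2,
    permute_seed: int | None = None,
) -> EQTLResult:
    """Additive-dosage cis-eQTL regression for one inversion.

    ``expression`` is samples x features; only features expressed (non-zero)
    in at least ``min_expressed_fraction`` of samples and, when ``tss`` and
    ``inv_record`` are given, with TSS within ``window`` of the inversion
    are tested.  Expression is adjusted for the supplied covariates plus
    ``n_expression_pcs`` expression principal components, residuals are
    rank-normalized, and q-values are Benjamini–Hochberg across all tested
    pairs.  ``permute_seed`` activates the negative-control mode that
    permutes inversion genotypes relative to expression.
    """
    samples = [s for s in expression.index if s in gt.sample_ids]
    if len(samples) < 20:
        raise InvpopkitError("need at least 20 samples with genotype and expression")
    expr = expression.loc[samples]
    dosage = gt.dosage(inversion, samples)
    if permute_seed is not None:
        rng = np.random.default_rng(permute_seed)
        dosage = rng.permutation(dosage)

    features = []
    for f in expr.columns:
        col = expr[f].to_numpy(dtype=float)
        if np.mean(col != 0) < min_expressed_fraction:
            continue
        if tss is not None and inv_record is not None:
            chrom, pos = tss[f]
            if chrom != inv_record.chromosome:
                continue
            d = _tss_distance(pos, inv_record)
            if abs(d) > window:
                continue
        features.append(f)
    if not features:
        return EQTLResult(pd.DataFrame(
            columns=["feature", "beta", "t", "p", "q", "n", "tss_distance"]),
            [], 0, permute_seed is not None)

    cov_cols: list[str] = []
    cov_mat = np.ones((len(samples), 1))
    if covariates is not None:
        cov = covariates.loc[samples]
        keep = []
        for c in cov.columns:
            candidate = np.column_stack([cov_mat, cov[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(candidate) == candidate.shape[1]:
                cov_mat = candidate
                keep.append(c)
            # rank-deficient covariates dropped
        cov_cols = keep
    if n_expression_pcs > 0:
        pcs = _expression_pcs(expr[features].to_numpy(dtype=float), n_expression_pcs)
        cov_mat = np.column_stack([cov_mat, pcs])
        cov_cols += [f"expr_PC{i+1}" for i in range(pcs.shape[1])]

    # project out covariates once, then per-feature OLS slope tests
    q_proj, _ = np.linalg.qr(cov_mat)
    ok = ~np.isnan(dosage)
    rows = []
    for f in features:
        y = expr[f].to_numpy(dtype=float)
        resid = y - q_proj @ (q_proj.T @ y)
        ystar = rank_normalize(resid)
        x = dosage
        sel = ok & ~np.isnan(ystar)
        n = int(sel.sum())
        xs, ys = x[sel], ystar[sel]
        xs = xs - xs.mean()
        if np.all(xs == 0):
            continue
        beta = float(xs @ ys / (xs @ xs))
        dof = n - 2 - cov_mat.shape[1] + 1
        resid2 = ys - ys.mean() - beta * xs
        se = float(np.sqrt((resid2 @ resid2) / max(dof, 1) / (xs @ xs)))
        t = beta / se if se > 0 else np.inf
        p = 2 * stats.t.sf(abs(t), max(dof, 1))
        d = (np.nan if tss is None or inv_record is None
             else _tss_distance(tss[f][1], inv_record))
        rows.append({"feature": f, "beta": beta, "t": t, "p": p,
                     "n": n, "tss_distance": d})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] <= fdr
        table = table.sort_values("p").reset_index(drop=True)
    return EQTLResult(table, cov_cols, len(table), permute_seed is not None)


def _tss_distance(pos: int, inv: InversionRecord) -> int:
    if pos < inv.bp1_start:
        return pos - inv.bp1_start
    if pos >= inv.bp2_end:
        return pos - inv.bp2_end
    return 0


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH q-values (convenience wrapper used across modules)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Joint lead-eQTL ranking
# ---------------------------------------------------------------------------

def joint_lead_eqtl(inversion_stats: pd.DataFrame,
                    variant_stats: pd.DataFrame) -> pd.DataFrame:
    """Rank the inversion among all local variants per feature.

    Inputs hold columns (feature, id, p, beta).  Per feature, candidates
    are ranked by ascending nominal p with ties broken by descending
    absolute effect then lexicographic id (deterministic); the inversion is
    the lead eQTL when ranked first.  Features absent from either table are
    skipped.
    """
    needed = {"feature", "id", "p", "beta"}
    for df in (inversion_stats, variant_stats):
        if not needed <= set(df.columns):
            raise InvpopkitError(f"stats tables need columns {sorted(needed)}")
    common = set(inversion_stats["feature"]) & set(variant_stats["feature"])
    rows = []
    for feature in sorted(common):
        cands = pd.concat([
            inversion_stats[inversion_stats["feature"] == feature].assign(kind="inversion"),
            variant_stats[variant_stats["feature"] == feature].assign(kind="variant"),
        ])
        cands = cands.assign(abs_beta=cands["beta"].abs()).sort_values(
            ["p", "abs_beta", "id"], ascending=[True, False, True]
        ).reset_index(drop=True)
        inv_rank = int(cands.index[cands["kind"] == "inversion"][0]) + 1
        rows.append({
            "feature": feature,
            "inversion_rank": inv_rank,
            "lead": inv_rank == 1,
            "lead_id": cands.iloc[0]["id"],
            "n_candidates": len(cands),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GWAS locus clustering and enrichment
# ---------------------------------------------------------------------------

def cluster_gwas_loci(signals: pd.DataFrame,
                      ld: "callable | None" = None,
                      locus_span: int = 100_000,
                      r2_threshold: float = 0.8) -> pd.DataFrame:
    """Deduplicate GWAS signals into loci, keeping the strongest per locus.

    ``signals`` holds (chrom, pos, pvalue, phenotype) sorted or not; the
    greedy pass runs in ascending p order.  A signal joins an existing
    locus when it shares the phenotype and is within ``locus_span`` of any
    member, or in high LD (``ld(a, b) >= r2_threshold``) with any member —
    i.e. single-linkage/transitive chaining, which makes the outcome
    deterministic.  Each locus keeps its minimum-p representative.
    """
    df = signals.sort_values(["pvalue", "chrom", "pos"]).reset_index(drop=True)
    loci: list[dict] = []
    for row in df.itertuples(index=False):
        joined = None
        for locus in loci:
            if locus["phenotype"] != row.phenotype:
                continue
            for member in locus["members"]:
                if member[0] == row.chrom and abs(member[1] - row.pos) <= locus_span:
                    joined = locus
                    break
                if ld is not None and ld((row.chrom, row.pos), member) >= r2_threshold:
                    joined = locus
                    break
            if joined:
                break
        if joined is None:
            loci.append({
                "phenotype": row.phenotype,
                "chrom": row.chrom,
                "pos": row.pos,
                "pvalue": row.pvalue,
                "members": [(row.chrom, row.pos)],
            })
        else:
            joined["members"].append((row.chrom, row.pos))
            # representative already has the smallest p (ascending scan)
    return pd.DataFrame(
        [{k: l[k] for k in ("chrom", "pos", "pvalue", "phenotype")}
         | {"n_signals": len(l["members"])} for l in loci]
    )


@dataclass
class EnrichmentResult:
    observed: int
    null_counts: np.ndarray
    fold: float
    p_value: float
    n_null: int
    matching: dict = field(default_factory=dict)


def count_loci_in_region(loci: pd.DataFrame, chrom: str, start: int, end: int) -> int:
    sel = (loci["chrom"] == chrom) & (loci["pos"] >= start) & (loci["pos"] < end)
    return int(sel.sum())


def gwas_enrichment(
    loci: pd.DataFrame,
    inv: InversionRecord,
    variants: VariantPanel,
    flank: int = 20_000,
    n_null: int = 1000,
    seed: int = 1,
    freq_tol: float = 0.01,
    chi2_alpha: float = 0.05,
    gaps: list[tuple[str, int, int]] | None = None,
    max_tries_factor: int = 200,
    genome_span: dict[str, tuple[int, int]] | None = None,
) -> EnrichmentResult:
    """Observed vs matched-random-region GWAS locus counts for one inversion.

    The tested region is the inversion ±``flank``.  Null regions of the
    same length are sampled uniformly (excluding declared gaps and chrY)
    and accepted when (1) their mean variant alt frequency is within
    ``freq_tol`` of the region's, and (2) a chi-square test comparing
    their count of variants with MAF < 0.2 vs >= 0.2 to the region's is
    non-significant (p > ``chi2_alpha``).  One-tailed empirical
    p = (r+1)/(n+1) with r = null regions with count >= observed.
    """
    rng = np.random.default_rng(seed)
    start = inv.bp1_start - flank
    end = inv.bp2_end + flank
    length = end - start
    observed = count_loci_in_region(loci, inv.chromosome, start, end)

    maf = variants.minor_allele_frequency()
    p_alt = variants.alt_frequency()

    def region_stats(chrom, lo, hi):
        sel = (variants.chromosome == chrom) & (variants.positions >= lo) \
            & (variants.positions < hi)
        if sel.sum() == 0:
            return None
        return float(np.nanmean(p_alt[sel])), int((maf[sel] < 0.2).sum()), \
            int((maf[sel] >= 0.2).sum())

    target = region_stats(inv.chromosome, start, end)
    if target is None:
        raise InvpopkitError("inversion region holds no variants to match on")
    t_freq, t_low, t_high = target

    spans = genome_span or {}
    chroms = [c for c in dict.fromkeys(variants.chromosome)
              if c.removeprefix("chr") != "Y"]
    gaps = gaps or []

    def in_gap(chrom, lo, hi):
        return any(g[0] == chrom and lo < g[2] and hi > g[1] for g in gaps)

    null_counts = []
    tries = 0
    max_tries = max_tries_factor * n_null
    while len(null_counts) < n_null and tries < max_tries:
        tries += 1
        chrom = chroms[rng.integers(len(chroms))]
        if chrom in spans:
            glo, ghi = spans[chrom]
        else:
            on = variants.positions[variants.chromosome == chrom]
            glo, ghi = int(on.min()), int(on.max())
        if ghi - glo <= length:
            continue
        lo = int(rng.integers(glo, ghi - length))
        hi = lo + length
        if in_gap(chrom, lo, hi):
            continue
        st = region_stats(chrom, lo, hi)
        if st is None:
            continue
        freq, low, high = st
        if abs(freq - t_freq) > freq_tol:
            continue
        table = np.array([[t_low, t_high], [low, high]])
        if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
            chi_p = stats.chi2_contingency(table)[1]
            if chi_p <= chi2_alpha:
                continue
        null_counts.append(count_loci_in_region(loci, chrom, lo, hi))
    if len(null_counts) < n_null:
        rate = len(null_counts) / max(tries, 1)
        if rate < 0.01:
            raise InvpopkitError(
                f"null-region acceptance rate {rate:.4f} too low; "
                "relax the matching criteria"
            )
    null_counts = np.asarray(null_counts)
    r = int(np.sum(null_counts >= observed))
    null_mean = float(null_counts.mean()) if null_counts.size else float("nan")
    return EnrichmentResult(
        observed=observed,
        null_counts=null_counts,
        fold=observed / null_mean if null_mean > 0 else float("nan"),
        p_value=(r + 1) / (null_counts.size + 1),
        n_null=int(null_counts.size),
        matching={"freq_tol": freq_tol, "target_freq": t_freq,
                  "tries": tries},
    )
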