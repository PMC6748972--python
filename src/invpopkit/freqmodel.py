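"""Ascertainment-aware inversion frequency analysis.

Inversions were discovered in small panels (paired-end mapping in nine
individuals, or a single assembly comparison), so their frequency spectrum
is biased toward common alleles.  This module simulates that two-step
detection process on a SNP pool — (1) keep variants polymorphic within the
discovery panel, (2) sample variants weighted by a detection-probability
function — to build matched null frequency distributions, provides the
Hardy–Weinberg exact QC test, the empirical two-tailed frequency test, and
robust stepwise regression of inversion frequency on genomic variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import InvpopkitError, VariantPanel
from .synthdata import simulate_discovery_panel


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value for diploid counts.

    Sums the conditional probabilities P(het | n, minor-allele count) of all
    heterozygote counts no more probable than the observed one.  Monomorphic
    samples return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise InvpopkitError("genotype counts must be >= 0")
    n = n_hom1 + n_het + n_hom2
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n == 0 or n_minor == 0:
        return 1.0

    # P(het = h) ∝ 2^h * n! / (hom_minor! * h! * hom_major!), h ≡ n_minor (mod 2)
    from scipy.special import gammaln

    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    ok = hom_major >= 0
    hs, hom_minor, hom_major = hs[ok], hom_minor[ok], hom_major[ok]
    logp = (
        hs * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hs + 1)
        - gammaln(hom_major + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hs == n_het]
    if len(p_obs) == 0:
        raise InvpopkitError("heterozygote count inconsistent with allele count parity")
    return float(min(p[p <= p_obs[0] * (1 + 1e-12)].sum(), 1.0))


def hwe_by_population(gt, inversion: str, panel=None) -> dict[str, float]:
    """HWE exact p per population (diploid samples only)."""
    panel = panel or gt.panel
    out = {}
    for pop, sub in panel.table.groupby("population"):
        counts = {"O1/O1": 0, "O1/O2": 0, "O2/O2": 0}
        for s in sub["sample_id"]:
            if s not in gt.sample_ids:
                continue
            al = gt.alleles(s, inversion)
            if len(al) == 2:
                counts["/".join(sorted(al))] += 1
        out[pop] = hwe_exact_test(counts["O1/O1"], counts["O1/O2"], counts["O2/O2"])
    return out


# ---------------------------------------------------------------------------
# Detection simulation
# ---------------------------------------------------------------------------

def carrier_presence_probability(p_alt: np.ndarray, n_chromosomes: int) -> np.ndarray:
    """P(at least one discovery chromosome carries the non-reference allele)."""
    p_alt = np.asarray(p_alt, dtype=float)
    return 1.0 - (1.0 - p_alt) ** n_chromosomes


@dataclass
class AscertainmentModel:
    """Discovery-panel composition and detection-probability function.

    ``detection_fn(p_alt, model)`` returns per-variant detection
    probabilities; the default is carrier presence in the discovery
    chromosomes times a length factor (identically 1 unless configured).
    ``source`` records whether the inversion came from the multi-individual
    PEM panel or a single-assembly comparison (the latter uses one
    individual).
    """

    discovery_samples: list[str] = field(default_factory=list)
    source: str = "PEM_panel"
    length_factor: float = 1.0
    detection_fn: Callable | None = None

    def n_chromosomes(self, ploidy: int = 2) -> int:
        return ploidy * len(self.discovery_samples)

    def detection_probability(self, p_alt: np.ndarray, ploidy: int = 2) -> np.ndarray:
        if self.detection_fn is not None:
            prob = np.asarray(self.detection_fn(p_alt, self), dtype=float)
        else:
            prob = carrier_presence_probability(p_alt, self.n_chromosomes(ploidy))
            prob = prob * self.length_factor
        if np.any((prob < 0) | (prob > 1)):
            raise InvpopkitError("detection probabilities must be in [0, 1]")
        return prob


def simulate_detection(variants: VariantPanel, model: AscertainmentModel,
                       n_sets: int = 10_000, seed: int = 1,
                       ploidy: int = 2) -> dict:
    """Two-step detection simulation producing matched null SNP draws.

    Step 1 restricts the pool to variants polymorphic within the discovery
    individuals; step 2 draws ``n_sets`` variants (with replacement across
    draws) with probability proportional to the detection probability.
    Returns the ascertained pool, the index draws and their frequencies.
    """
    asc = simulate_discovery_panel(variants, model.discovery_samples)
    pool = asc.panel
    if pool.n_variants == 0:
        raise InvpopkitError("no variants polymorphic in the discovery panel")
    # the detection probability is driven by the allele frequency seen in the
    # discovery panel itself (the data the detection step operates on)
    idx = [pool.samples.index(s) for s in model.discovery_samples]
    sub = pool.genotypes[:, idx, :]
    called = sub >= 0
    with np.errstate(invalid="ignore"):
        p_panel = np.where(called, sub, 0).sum(axis=(1, 2)) / called.sum(axis=(1, 2))
    weights = model.detection_probability(p_panel, ploidy)
    p_alt = pool.alt_frequency()
    if weights.sum() <= 0:
        raise InvpopkitError("all detection probabilities are zero")
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool.n_variants, size=n_sets, replace=True,
                       p=weights / weights.sum())
    maf = pool.minor_allele_frequency()
    return {
        "pool": pool,
        "kept": asc.kept,
        "weights": weights,
        "draws": draws,
        "maf_draws": maf[draws],
        "alt_freq_draws": p_alt[draws],
    }


# ---------------------------------------------------------------------------
# Empirical frequency test
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalTestResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    tail: str
    n_null: int
    matching: dict = field(default_factory=dict)


def empirical_frequency_test(observed: float, null_values: Sequence[float],
                             tail: str = "two-sided") -> EmpiricalTestResult:
    """Empirical p as twice the fraction of null samples at least as extreme.

    The two-tailed convention doubles the smaller tail fraction (samples
    with values more extreme *or equal* than the observed), capped at 1.
    An observed value beyond every null sample gives p = 0, to be reported
    with a "< 2/n" annotation by the caller.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size == 0:
        raise InvpopkitError("null sample is empty")
    ge = np.mean(null_values >= observed)
    le = np.mean(null_values <= observed)
    if tail == "greater":
        p = ge
    elif tail == "less":
        p = le
    elif tail == "two-sided":
        p = 2.0 * min(ge, le)
    else:
        raise InvpopkitError(f"unknown tail {tail!r}")
    return EmpiricalTestResult(
        observed=float(observed),
        null_values=null_values,
        p_value=float(min(p, 1.0)),
        tail=tail,
        n_null=null_values.size,
    )


# ---------------------------------------------------------------------------
# Robust stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class RobustFit:
    predictors: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    pseudo_r2: float
    model: object
    skipped_collinear: list[str]


def _design(df: pd.DataFrame, cols: list[str], transform: dict[str, str]) -> np.ndarray:
    X = []
    for c in cols:
        x = df[c].to_numpy(dtype=float)
        if transform.get(c, "identity") == "log":
            if np.any(x <= 0):
                raise InvpopkitError(f"log transform of non-positive predictor {c}")
            x = np.log(x)
        X.append(x)
    return np.column_stack(X) if X else np.empty((len(df), 0))


def _rlm_fit(y: np.ndarray, X: np.ndarray):
    return sm.RLM(y, sm.add_constant(X, has_constant="add"),
                  M=sm.robust.norms.TukeyBiweight()).fit()


def _pseudo_r2(y: np.ndarray, fit) -> float:
    """Robust variance explained: 1 - ratio of residual to total M-scale."""
    from statsmodels.robust.scale import mad

    resid_scale = mad(fit.resid)
    total_scale = mad(y - np.median(y))
    if total_scale == 0:
        return float("nan")
    return float(1.0 - (resid_scale / total_scale) ** 2)


def robust_regression_stepwise(
    response: Sequence[float],
    predictors: pd.DataFrame,
    transform: dict[str, str] | None = None,
    alpha: float = 0.05,
    min_obs_per_predictor: int = 5,
) -> RobustFit:
    """Forward-selection robust (M-estimation, bisquare) regression.

    At each step the candidate with the smallest robust-test p-value is
    added if below ``alpha``; collinear candidates are skipped with a
    warning.  The response is an inversion frequency vector (DAF or MAF);
    candidate predictors may be log-transformed via ``transform``.
    Variance explained is a robust pseudo-R² (one minus the squared ratio
    of the residual to total M-scale).
    """
    transform = transform or {}
    y = np.asarray(list(response), dtype=float)
    df = predictors.reset_index(drop=True)
    if len(y) != len(df):
        raise InvpopkitError("response and predictor lengths differ")

    selected: list[str] = []
    skipped: list[str] = []
    candidates = list(df.columns)
    while candidates:
        if len(y) < min_obs_per_predictor * (len(selected) + 1):
            break
        best = None
        for cand in candidates:
            cols = selected + [cand]
            X = _design(df, cols, transform)
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
                if cand not in skipped:
                    skipped.append(cand)
                continue
            try:
                fit = _rlm_fit(y, X)
            except Exception:
                continue
            p = float(fit.pvalues[-1])
            if best is None or p < best[0]:
                best = (p, cand)
        if best is None or best[0] >= alpha:
            break
        selected.append(best[1])
        candidates = [c for c in candidates if c != best[1] and c not in skipped]

    X = _design(df, selected, transform)
    fit = _rlm_fit(y, X)
    names = ["const"] + selected
    return RobustFit(
        predictors=selected,
        coefficients=dict(zip(names, map(float, fit.params))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
        pseudo_r2=_pseudo_r2(y, fit) if selected else 0.0,
        model=fit,
        skipped_collinear=skipped,
    )
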