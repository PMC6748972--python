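"""Selection scans around inversions.

Three families of evidence:

* **F_ST** — Weir–Cockerham variance components between populations, with
  empirical p-values against frequency-matched SNP null distributions
  (positive selection raising an allele in some populations).
* **LSFS** — the frequency spectrum of variants *linked* to the inverted
  allele, each variant annotated by its carrier-set topology relative to
  the inversion carriers (nested / disjoint / discordant).  Linear
  statistics T = w·ξ with simulation-calibrated weights, tested against an
  empirical null bank conditioned on the focal-allele frequency; per-window
  population p-values combined by Edgington's method.  Suited to
  low-recombination regions where classical SFS tests lose power.
* **NCD1/NCD2** — non-central deviation statistics measuring how tightly
  window minor-allele frequencies cluster around a target frequency
  (0.3/0.4/0.5); low values indicate long-term balancing selection.  NCD2
  adds interspecies fixed differences as sites with MAF 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import HaplotypeSet, InvpopkitError

# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_components_diploid(p, h, n):
    """Variance components (a, b, c) of Weir & Cockerham's theta for one
    locus: ``p`` per-population alt frequencies, ``h`` observed heterozygote
    frequencies, ``n`` diploid sample sizes."""
    p, h, n = map(np.asarray, (p, h, n))
    r = len(p)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _wc_components_haploid(p, n):
    """Haploid analogue: between/within mean squares; returns (a, b) with
    theta = a / (a + b)."""
    p, n = map(np.asarray, (p, n))
    r = len(p)
    n_tot = n.sum()
    pbar = (n * p).sum() / n_tot
    msp = (n * (p - pbar) ** 2).sum() / (r - 1)
    msg = (n * p * (1 - p)).sum() / (n - 1).sum() if np.all(n > 1) else \
        (n * p * (1 - p)).sum() / max((n - 1).sum(), 1)
    nc = (n_tot - (n**2).sum() / n_tot) / (r - 1)
    a = (msp - msg) / nc
    b = msg
    return a, b


def weir_cockerham_fst(dosages_per_pop: list[np.ndarray], ploidy: int = 2) -> dict:
    """Per-locus and multi-locus Weir–Cockerham F_ST.

    ``dosages_per_pop`` holds one (n_loci, n_samples) array per population:
    alt-allele dosage 0/1/2 for diploids (``ploidy=2``) or 0/1 haploid
    calls (``ploidy=1``, used for chrY and male chrX loci); NaN marks
    missing calls.  Monomorphic loci get NaN.  The multi-locus value is the
    weighted average sum(a)/sum(a+b+c).
    """
    if len(dosages_per_pop) < 2:
        raise InvpopkitError("need at least two populations")
    mats = [np.atleast_2d(np.asarray(d, dtype=float)) for d in dosages_per_pop]
    n_loci = mats[0].shape[0]
    per_locus = np.full(n_loci, np.nan)
    num = den = 0.0
    for li in range(n_loci):
        ps, hs, ns = [], [], []
        for mat in mats:
            x = mat[li]
            x = x[~np.isnan(x)]
            if len(x) == 0:
                continue
            ns.append(len(x))
            if ploidy == 2:
                ps.append(x.mean() / 2.0)
                hs.append(np.mean(x == 1))
            else:
                ps.append(x.mean())
        if len(ns) < 2:
            continue
        pbar_all = np.average(ps, weights=ns)
        if pbar_all in (0.0, 1.0):
            continue
        if ploidy == 2:
            a, b, c = _wc_components_diploid(ps, hs, ns)
            denom = a + b + c
        else:
            a, b = _wc_components_haploid(ps, ns)
            denom = a + b
        if denom != 0:
            per_locus[li] = a / denom
        num += a
        den += denom
    return {
        "per_locus": per_locus,
        "global": num / den if den != 0 else float("nan"),
    }


def fst_empirical_pvalue(inv_fst: float, inv_freq: float,
                         null_fst: np.ndarray, null_freq: np.ndarray,
                         bin_halfwidth: float = 0.02,
                         min_matches: int = 1000,
                         max_halfwidth: float = 0.25) -> dict:
    """Percentile of an inversion's F_ST within a frequency-matched SNP null.

    Null variants are matched on (minor-allele) frequency within
    ``bin_halfwidth``; the bin widens (with a record of the final width)
    until ``min_matches`` variants are available.  Classification: *strong*
    in the top 1% of the null, *weak* in the top 5%, else *none*.
    """
    null_fst = np.asarray(null_fst, dtype=float)
    null_freq = np.asarray(null_freq, dtype=float)
    ok = ~np.isnan(null_fst) & ~np.isnan(null_freq)
    null_fst, null_freq = null_fst[ok], null_freq[ok]

    hw = bin_halfwidth
    sel = np.abs(null_freq - inv_freq) <= hw
    while sel.sum() < min_matches and hw < max_halfwidth:
        hw *= 2
        sel = np.abs(null_freq - inv_freq) <= hw
    matched = null_fst[sel]
    if matched.size == 0:
        raise InvpopkitError("no matched null variants")
    percentile = float(np.mean(matched < inv_fst))
    if percentile >= 0.99:
        signal = "strong"
    elif percentile >= 0.95:
        signal = "weak"
    else:
        signal = "none"
    return {
        "percentile": percentile,
        "signal": signal,
        "n_matched": int(matched.size),
        "final_halfwidth": hw,
        "widened": hw > bin_halfwidth,
    }


# ---------------------------------------------------------------------------
# LSFS
# ---------------------------------------------------------------------------

LINKAGE_CLASSES = ("nested", "disjoint", "discordant")


@dataclass
class LSFSSpectrum:
    """Linked-site frequency spectrum of one window.

    ``counts[f, c]`` counts window variants in derived-frequency class ``f``
    and linkage class ``c`` (nested / disjoint / discordant with respect to
    the focal carrier set).  Discordant variants are tallied but excluded
    from the statistic by default (they indicate exchange between
    backgrounds rather than genealogy on either background).
    """

    counts: np.ndarray
    focal_frequency: float
    span: tuple[int, int]
    n_variants: int = 0

    def vector(self, include_discordant: bool = False) -> np.ndarray:
        k = 3 if include_discordant else 2
        return self.counts[:, :k].ravel().astype(float)


def classify_linkage(carriers: frozenset, focal: frozenset) -> str:
    if carriers <= focal or focal <= carriers:
        return "nested"
    if not (carriers & focal):
        return "disjoint"
    return "discordant"


def lsfs_build(haps: HaplotypeSet, windows: list[tuple[int, int]],
               n_freq_classes: int = 10,
               focal_orientation: str = "O2") -> list[LSFSSpectrum]:
    """Build one spectrum per window from orientation-labeled haplotypes.

    The focal carrier set is the set of haplotypes with the focal
    orientation; each derived variant's carrier set is classified nested /
    disjoint / discordant against it, and its derived frequency binned into
    ``n_freq_classes`` equal classes over (0, 1).
    """
    labeled = haps.labeled()
    focal = frozenset(np.flatnonzero(labeled.orientation == focal_orientation))
    n = labeled.n_haplotypes
    if not focal or len(focal) == n:
        raise InvpopkitError("focal orientation absent or fixed among labeled haplotypes")
    out = []
    acc = labeled.accessible.astype(bool)
    for lo, hi in windows:
        in_win = (labeled.positions >= lo) & (labeled.positions < hi) & acc
        counts = np.zeros((n_freq_classes, 3), dtype=int)
        n_var = 0
        for col in np.flatnonzero(in_win):
            alleles = labeled.haplotypes[:, col]
            carriers = frozenset(np.flatnonzero(alleles == 1))
            if not carriers or len(carriers) == n:
                continue
            n_var += 1
            cls = LINKAGE_CLASSES.index(classify_linkage(carriers, focal))
            f = len(carriers) / n
            fbin = min(int(f * n_freq_classes), n_freq_classes - 1)
            counts[fbin, cls] += 1
        out.append(LSFSSpectrum(counts=counts, focal_frequency=len(focal) / n,
                                span=(lo, hi), n_variants=n_var))
    return out


def estimate_lsfs_weights(null_spectra: list[LSFSSpectrum],
                          alt_spectra: list[LSFSSpectrum],
                          sd_floor: float = 1e-3) -> np.ndarray:
    """Nearly-optimal linear weights from simulated spectra.

    w ∝ (E_alt[ξ] − E_null[ξ]) / SD_null[ξ] on normalized spectra, so T is
    largest when a window resembles the simulated alternative.
    """
    def _norm(spectra):
        return np.array([
            s.vector() / max(s.n_variants, 1) for s in spectra
        ])

    null_m = _norm(null_spectra)
    alt_m = _norm(alt_spectra)
    sd = null_m.std(axis=0)
    w = (alt_m.mean(axis=0) - null_m.mean(axis=0)) / np.maximum(sd, sd_floor)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lsfs_statistic(spec: LSFSSpectrum, weights: np.ndarray | None = None) -> float:
    """T = w · ξ normalized by the window variant count (weights ≡ 1 gives
    the fraction of non-discordant variants, ~the variant count sanity
    identity)."""
    xi = spec.vector()
    if weights is None:
        weights = np.ones_like(xi)
    return float(np.dot(weights, xi) / max(spec.n_variants, 1))


def lsfs_linear_test(window_spectra: list[LSFSSpectrum],
                     null_bank: list[LSFSSpectrum],
                     weights: np.ndarray | None = None,
                     freq_tol: float = 0.05) -> dict:
    """Empirical LSFS test of one inversion in one population.

    Each window's statistic is ranked within the null-bank windows whose
    focal frequency matches the window's within ``freq_tol`` (the test is
    conditioned on the inversion frequency); the per-window empirical p is
    (r+1)/(n+1) with r the count of null statistics >= T.  Across windows
    the conservative combination is the Bonferroni-adjusted minimum and the
    approximate combination is Edgington's method; both are reported.
    """
    if len(null_bank) < 100:
        raise InvpopkitError("null bank must hold at least 100 windows")
    bank_t = np.array([lsfs_statistic(s, weights) for s in null_bank])
    bank_f = np.array([s.focal_frequency for s in null_bank])
    p_windows = []
    for spec in window_spectra:
        t = lsfs_statistic(spec, weights)
        sel = np.abs(bank_f - spec.focal_frequency) <= freq_tol
        ref = bank_t[sel] if sel.sum() >= 100 else bank_t
        r = int(np.sum(ref >= t))
        p_windows.append((r + 1) / (len(ref) + 1))
    p_windows = np.asarray(p_windows)
    return {
        "p_windows": p_windows,
        "p_conservative": float(min(p_windows.min() * len(p_windows), 1.0)),
        "p_approximate": edgington_combine(list(p_windows)),
    }


def edgington_combine(pvalues: list[float]) -> float:
    """Edgington's sum-of-uniforms combination (Irwin–Hall tail).

    P = Σ_{k=0..⌊S⌋} (−1)^k C(n,k) (S−k)^n / n!,  S = Σ p_i, capped to [0,1].
    """
    if len(pvalues) == 0:
        raise InvpopkitError("no p-values to combine")
    if any(p < 0 or p > 1 for p in pvalues):
        raise InvpopkitError("p-values must be in [0, 1]")
    if len(pvalues) == 1:
        return float(pvalues[0])
    n = len(pvalues)
    s = float(sum(pvalues))
    if n > 30:
        # Irwin-Hall tail by its normal limit (exact sum overflows floats)
        from scipy.stats import norm
        return float(min(max(norm.cdf((s - n / 2) / math.sqrt(n / 12.0)), 0.0), 1.0))
    total = 0.0
    for k in range(int(math.floor(s)) + 1):
        total += (-1) ** k * math.comb(n, k) * (s - k) ** n
    total /= math.factorial(n)
    return float(min(max(total, 0.0), 1.0))


# ---------------------------------------------------------------------------
# NCD
# ---------------------------------------------------------------------------

@dataclass
class NCDResult:
    statistic: float
    target_frequency: float
    n_informative: int
    n_fixed_diffs: int
    span: tuple[int, int] = (0, 0)


def ncd_statistic(mafs, tf: float, fixed_diffs: int = 0,
                  min_informative: int = 8) -> float:
    """Non-central deviation statistic NCD(tf).

    sqrt(mean squared deviation of minor-allele frequencies from the target
    frequency); with ``fixed_diffs`` > 0 this is NCD2, counting each
    interspecies fixed difference as an informative site of MAF 0.  Windows
    with fewer than ``min_informative`` informative sites are excluded
    (error), not scored zero.
    """
    mafs = np.asarray(list(mafs), dtype=float)
    n_is = len(mafs) + fixed_diffs
    if n_is < min_informative:
        raise InvpopkitError(
            f"window has {n_is} informative sites (< {min_informative}); excluded"
        )
    ss = float(((mafs - tf) ** 2).sum() + fixed_diffs * tf**2)
    return math.sqrt(ss / n_is)


def ncd_windows(positions: np.ndarray, mafs: np.ndarray, span: tuple[int, int],
                tf: float, window: int = 2000, step: int = 1000,
                fixed_diff_positions: np.ndarray | None = None,
                coverage: np.ndarray | None = None,
                min_informative: int = 8,
                min_coverage: float = 0.167) -> list[NCDResult]:
    """NCD over overlapping windows; under-informative or under-covered
    windows are dropped.  ``coverage`` is an optional per-window alignment
    coverage fraction aligned with the produced windows."""
    fixed_diff_positions = np.asarray(
        [] if fixed_diff_positions is None else fixed_diff_positions
    )
    out = []
    starts = list(range(span[0], max(span[1] - window, span[0]) + 1, step))
    for wi, lo in enumerate(starts):
        hi = lo + window
        sel = (positions >= lo) & (positions < hi)
        fd = int(np.sum((fixed_diff_positions >= lo) & (fixed_diff_positions < hi)))
        if coverage is not None and coverage[wi] < min_coverage:
            continue
        try:
            stat = ncd_statistic(mafs[sel], tf, fixed_diffs=fd,
                                 min_informative=min_informative)
        except InvpopkitError:
            continue
        out.append(NCDResult(statistic=stat, target_frequency=tf,
                             n_informative=int(sel.sum()) + fd,
                             n_fixed_diffs=fd, span=(lo, hi)))
    return out


def ncd_empirical_pvalue(inv_windows: list[NCDResult],
                         genome_bank: np.ndarray,
                         min_bank: int = 1000) -> dict:
    """Lower-tail empirical p for one inversion region in one population.

    The inversion is summarised by its minimum-NCD window (the strongest
    balancing-like signal); p = (r+1)/(n+1) with r the number of bank
    values <= the summary.  Low NCD values are balancing-selection-like.
    """
    genome_bank = np.asarray(genome_bank, dtype=float)
    if genome_bank.size < min_bank:
        raise InvpopkitError(f"bank of {genome_bank.size} regions is too small")
    if not inv_windows:
        raise InvpopkitError("no scored windows for this inversion")
    summary = min(w.statistic for w in inv_windows)
    r = int(np.sum(genome_bank <= summary))
    return {
        "summary_ncd": summary,
        "p_value": (r + 1) / (genome_bank.size + 1),
        "n_bank": int(genome_bank.size),
    }


# ---------------------------------------------------------------------------
# Simulation-driven banks and weights
# ---------------------------------------------------------------------------

def neutral_lsfs_windows(n_windows: int, seed: int, window: int = 3000,
                         n_samples: int = 30, mutation_rate: float = 1.5e-7,
                         freq_band: tuple[float, float] = (0.2, 0.8),
                         n_freq_classes: int = 10) -> list[LSFSSpectrum]:
    """Neutral-coalescent LSFS windows around random focal alleles.

    Each window comes from an independent neutral simulation; the focal
    carrier set is that of the variant nearest the window centre whose
    derived frequency falls in ``freq_band`` (windows without one are
    redrawn).  Serves as the empirical null bank conditioned on focal
    frequency.
    """
    from .core_io import HaplotypeSet
    from .synthdata import SimConfig, simulate_haplotypes

    rng = np.random.default_rng(seed)
    out = []
    tries = 0
    while len(out) < n_windows and tries < n_windows * 20:
        tries += 1
        cfg = SimConfig(
            n_samples=n_samples, sequence_length=window, span=(0, window),
            target_frequency=0.5, origin="none", mutation_rate=mutation_rate,
            recombination_rate=0.0, seed=int(rng.integers(1, 2**31 - 1)),
        )
        haps, _, _, _ = simulate_haplotypes(cfg)
        if haps.n_sites < 5:
            continue
        freqs = haps.haplotypes.mean(axis=0)
        ok = (freqs >= freq_band[0]) & (freqs <= freq_band[1])
        if not ok.any():
            continue
        centre_dist = np.abs(haps.positions - window / 2)
        focal_col = np.flatnonzero(ok)[np.argmin(centre_dist[ok])]
        carriers = haps.haplotypes[:, focal_col] == 1
        labeled = HaplotypeSet(
            haplotypes=haps.haplotypes,
            positions=haps.positions,
            orientation=np.where(carriers, "O2", "O1").astype(object),
            sample_id=haps.sample_id,
        )
        out.extend(lsfs_build(labeled, [(0, window)],
                              n_freq_classes=n_freq_classes))
    if len(out) < n_windows:
        raise InvpopkitError("could not build enough neutral windows")
    return out[:n_windows]


def inversion_lsfs_windows(kind: str, n_windows: int, seed: int,
                           window: int = 3000, n_samples: int = 30,
                           mutation_rate: float = 1.5e-7,
                           n_freq_classes: int = 10) -> list[LSFSSpectrum]:
    """LSFS windows from simulated selection-like inversion scenarios.

    ``kind='balancing'`` emulates a long-term balanced polymorphism (old
    origin held at intermediate frequency: two deep clades); ``kind='sweep'``
    emulates a recent rapid rise (young origin at high frequency with a
    star-like derived background).  Used to estimate the linear-test
    weights, never as a null.
    """
    from .synthdata import SimConfig, simulate_haplotypes

    if kind == "balancing":
        freq, age, deme = 0.5, 40_000.0, None
    elif kind == "sweep":
        freq, age, deme = 0.8, 400.0, 50.0
    else:
        raise InvpopkitError("kind must be 'balancing' or 'sweep'")
    rng = np.random.default_rng(seed)
    out = []
    tries = 0
    while len(out) < n_windows and tries < n_windows * 20:
        tries += 1
        cfg = SimConfig(
            n_samples=n_samples, sequence_length=window, span=(0, window),
            target_frequency=freq, origin="unique", age_generations=age,
            mutation_rate=mutation_rate, recombination_rate=0.0,
            derived_deme_size=deme, seed=int(rng.integers(1, 2**31 - 1)),
        )
        haps, _, _, _ = simulate_haplotypes(cfg)
        if haps.n_sites < 5:
            continue
        out.extend(lsfs_build(haps, [(0, window)],
                              n_freq_classes=n_freq_classes))
    if len(out) < n_windows:
        raise InvpopkitError("could not build enough scenario windows")
    return out[:n_windows]


def load_default_weights(kind: str) -> np.ndarray:
    """Load the stored, versioned LSFS weight vector (``balancing`` or
    ``sweep``), estimated once by seeded simulation (see
    analysis/06_selection_scans.py, which regenerates the file)."""
    import json
    from importlib import resources

    with resources.files("invpopkit.data").joinpath("lsfs_weights.json").open() as fh:
        data = json.load(fh)
    if kind not in data["weights"]:
        raise InvpopkitError(f"no stored weights for {kind!r}")
    return np.asarray(data["weights"][kind], dtype=float)


def classify_ncd_signal(pvalues_by_population: dict[str, float],
                        alpha: float = 0.05, strong_alpha: float = 0.01,
                        min_populations: int = 3) -> str:
    """Signal class from per-population p-values: a signature must appear
    in at least ``min_populations`` populations; *strong* needs the
    stricter threshold in all of them."""
    sig = [p for p in pvalues_by_population.values() if p < alpha]
    strong = [p for p in pvalues_by_population.values() if p < strong_alpha]
    if len(strong) >= min_populations:
        return "strong"
    if len(sig) >= min_populations:
        return "weak"
    return "none"
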