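"""Ancestral-orientation inference and divergence-based inversion dating.

The ancestral orientation is read off outgroup species (chimpanzee,
gorilla, orangutan, macaque, archaic hominins); species polymorphic for the
region are uninformative for direction, because a shared polymorphism across
such divergence times is best explained by independent recurrence rather
than a trans-species allele.

A unique inversion of age ``T`` generations accumulates net divergence
between orientations of ``2 * mu * T`` per site (mutations accrue on both
the inverted and the standard lineage since the origin), on top of the
ancestral diversity present when the inversion arose.  The age estimator is
therefore::

    age = (pi_between - max(pi_within_O1, pi_within_O2)) / (2 * rate)

with the larger within-orientation diversity as the ancestral-diversity
correction.  Rates are substitutions per site per *year* by default (tag
``per_year``); per-generation rates are converted through the configurable
generation time (default 29 years).  A non-positive net divergence is
reported as a non-positive/undetermined age, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import HaplotypeSet, InvpopkitError
from .synthdata import DEFAULT_GENERATION_TIME

#: outgroup species in increasing phylogenetic distance from humans
SPECIES_ORDER = ("archaic", "chimpanzee", "gorilla", "orangutan", "macaque")


# ---------------------------------------------------------------------------
# Ancestral orientation
# ---------------------------------------------------------------------------

def infer_ancestral(observations: dict[str, str]) -> str:
    """Consensus ancestral orientation across outgroup species.

    ``observations`` maps species name to ``O1``, ``O2``, ``polymorphic``
    or ``untested``.  Polymorphic species are uninformative for direction.
    The informative species, ordered by phylogenetic distance, are resolved
    by small parsimony on the species ladder; parsimony ties are broken by
    majority over informative species, and a remaining tie is ``unknown``.
    """
    informative = [
        (SPECIES_ORDER.index(sp), obs)
        for sp, obs in observations.items()
        if sp in SPECIES_ORDER and obs in ("O1", "O2")
    ]
    if not informative:
        return "unknown"
    informative.sort()
    states = [obs for _, obs in informative]
    if len(set(states)) == 1:
        return states[0]

    # parsimony on the ladder ((((H, s1), s2), s3), ...): cost of assigning
    # each state to the node joining the human lineage
    cost = {"O1": 0.0, "O2": 0.0}
    # walk from the deepest species inward: each backbone node pays the tip
    # edge of its species plus the cheaper continuation deeper in the ladder
    for obs in reversed(states):
        nxt = {}
        for s in ("O1", "O2"):
            other = "O1" if s == "O2" else "O2"
            nxt[s] = (0 if s == obs else 1) + min(cost[s], cost[other] + 1)
        cost = nxt
    best = min(cost.values())
    winners = [s for s, c in cost.items() if c == best]
    if len(winners) == 1:
        return winners[0]
    n1 = states.count("O1")
    n2 = states.count("O2")
    if n1 > n2:
        return "O1"
    if n2 > n1:
        return "O2"
    return "unknown"


# ---------------------------------------------------------------------------
# Pairwise diversity
# ---------------------------------------------------------------------------

def _pair_diff_stats(h1: np.ndarray, h2: np.ndarray | None = None):
    """Mean pairwise Hamming difference (count of differing sites).

    Within-group when ``h2`` is None, between the two groups otherwise;
    computed from per-site allele counts, which equals the brute-force
    all-pairs average.
    """
    if h2 is None:
        n = h1.shape[0]
        if n < 2:
            return float("nan")
        c = h1.sum(axis=0)
        return float((c * (n - c)).sum() * 2.0 / (n * (n - 1)))
    n1, n2 = h1.shape[0], h2.shape[0]
    if n1 == 0 or n2 == 0:
        return float("nan")
    c1 = h1.sum(axis=0)
    c2 = h2.sum(axis=0)
    return float((c1 * (n2 - c2) + c2 * (n1 - c1)).sum() / (n1 * n2))


def pairwise_diversity(haps: HaplotypeSet,
                       span: tuple[int, int] | list[tuple[int, int]] | None = None,
                       site_length: int | None = None) -> dict:
    """Per-site mean pairwise differences within and between orientations.

    Only accessible sites inside ``span`` (an interval or list of intervals;
    None = all sites) contribute.  ``site_length`` is the number of bases
    the retained sites represent (monomorphic bases included) used for the
    per-site normalisation; by default the spanned length is used.  Returns
    ``pi_between``, ``pi_within_O1``, ``pi_within_O2``, ``pi_within_max``
    and ``n_sites``; a within-value is missing (NaN) when fewer than two
    haplotypes carry that orientation.
    """
    spans = span if isinstance(span, list) else ([span] if span else None)
    mask = haps.accessible.astype(bool).copy()
    if spans:
        in_any = np.zeros(haps.n_sites, dtype=bool)
        for lo, hi in spans:
            in_any |= (haps.positions >= lo) & (haps.positions < hi)
        mask &= in_any
    if site_length is None:
        if spans:
            site_length = int(sum(hi - lo for lo, hi in spans))
        else:
            site_length = int(haps.positions.max() - haps.positions.min() + 1) \
                if haps.n_sites else 0
    if site_length <= 0:
        raise InvpopkitError("site_length must be positive")

    h1 = haps.haplotypes[haps.orientation == "O1"][:, mask]
    h2 = haps.haplotypes[haps.orientation == "O2"][:, mask]
    w1 = _pair_diff_stats(h1) / site_length
    w2 = _pair_diff_stats(h2) / site_length
    between = _pair_diff_stats(h1, h2) / site_length
    return {
        "pi_between": between,
        "pi_within_O1": w1,
        "pi_within_O2": w2,
        "pi_within_max": np.nanmax([w1, w2]),
        "n_sites": int(mask.sum()),
        "site_length": site_length,
    }


# ---------------------------------------------------------------------------
# Age estimation
# ---------------------------------------------------------------------------

@dataclass
class AgeEstimate:
    pi_between: float
    pi_within_max: float
    ages_years: dict[str, float]            # per substitution rate
    ci_years: dict[str, tuple[float, float]]
    n_sites: int
    determined: bool


def _age_from_pi(pi_between: float, pi_within_max: float, rate_per_year: float) -> float:
    return (pi_between - pi_within_max) / (2.0 * rate_per_year)


def _rates_per_year(rates: dict[str, float], rate_unit: str,
                    generation_time: float) -> dict[str, float]:
    if rate_unit == "per_year":
        return dict(rates)
    if rate_unit == "per_generation":
        return {k: v / generation_time for k, v in rates.items()}
    raise InvpopkitError("rate_unit must be 'per_year' or 'per_generation'")


def estimate_age(div: dict, rates: dict[str, float],
                 rate_unit: str = "per_year",
                 generation_time: float = DEFAULT_GENERATION_TIME) -> AgeEstimate:
    """Divergence-based age per substitution rate.

    ``rates`` maps a rate label to a substitution rate per site (unit set
    by ``rate_unit``).  An age is undetermined (``determined=False``, value
    still reported) when net divergence is not positive.
    """
    if any(r <= 0 for r in rates.values()):
        raise InvpopkitError("rates must be > 0")
    per_year = _rates_per_year(rates, rate_unit, generation_time)
    ages = {
        k: _age_from_pi(div["pi_between"], div["pi_within_max"], r)
        for k, r in per_year.items()
    }
    determined = div["pi_between"] > div["pi_within_max"]
    return AgeEstimate(
        pi_between=div["pi_between"],
        pi_within_max=div["pi_within_max"],
        ages_years=ages,
        ci_years={},
        n_sites=div["n_sites"],
        determined=determined,
    )


def bootstrap_ci(haps: HaplotypeSet,
                 rates: dict[str, float],
                 span=None,
                 n_boot: int = 1000,
                 seed: int = 1,
                 rate_unit: str = "per_year",
                 generation_time: float = DEFAULT_GENERATION_TIME,
                 site_length: int | None = None) -> dict:
    """Percentile 95% CI of the age by resampling individuals.

    Individuals (not haplotypes) are resampled with replacement ``n_boot``
    times; resamples in which one orientation ends up with fewer than two
    haplotypes are skipped and counted.  Deterministic for a given seed.
    """
    if n_boot < 100:
        raise InvpopkitError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    per_year = _rates_per_year(rates, rate_unit, generation_time)

    base = pairwise_diversity(haps, span=span, site_length=site_length)
    samples = np.unique(haps.sample_id)
    site_len = base["site_length"]

    # site mask matching pairwise_diversity
    spans = span if isinstance(span, list) else ([span] if span else None)
    mask = haps.accessible.astype(bool).copy()
    if spans:
        in_any = np.zeros(haps.n_sites, dtype=bool)
        for lo, hi in spans:
            in_any |= (haps.positions >= lo) & (haps.positions < hi)
        mask &= in_any
    h1 = haps.haplotypes[haps.orientation == "O1"][:, mask].astype(float)
    h2 = haps.haplotypes[haps.orientation == "O2"][:, mask].astype(float)
    s1 = haps.sample_id[haps.orientation == "O1"]
    s2 = haps.sample_id[haps.orientation == "O2"]

    def weighted_pi(h, m):
        """Mean pairwise difference under haplotype multiplicities ``m``,
        excluding pairs formed by two copies of the same original haplotype
        (their distance is identically zero and would deflate the
        resampled diversity)."""
        M = m.sum()
        denom = M * M - (m * m).sum()
        if denom <= 0:
            return float("nan")
        c = m @ h
        return float((2 * c * (M - c)).sum() / denom) / site_len

    def weighted_between(ha, ma, hb, mb):
        Ma, Mb = ma.sum(), mb.sum()
        if Ma == 0 or Mb == 0:
            return float("nan")
        ca, cb = ma @ ha, mb @ hb
        return float((ca * (Mb - cb) + cb * (Ma - ca)).sum() / (Ma * Mb)) / site_len

    ages = {k: [] for k in per_year}
    n_skipped = 0
    for _ in range(n_boot):
        chosen = rng.choice(samples, size=len(samples), replace=True)
        mult = dict(zip(*np.unique(chosen, return_counts=True)))
        m1 = np.array([mult.get(s, 0) for s in s1], dtype=float)
        m2 = np.array([mult.get(s, 0) for s in s2], dtype=float)
        if (m1 > 0).sum() < 2 or (m2 > 0).sum() < 2:
            n_skipped += 1
            continue
        w1 = weighted_pi(h1, m1)
        w2 = weighted_pi(h2, m2)
        between = weighted_between(h1, m1, h2, m2)
        wmax = np.nanmax([w1, w2])
        for k, r in per_year.items():
            ages[k].append(_age_from_pi(between, wmax, r))

    ci = {}
    for k in per_year:
        arr = np.asarray(ages[k])
        if len(arr) == 0:
            ci[k] = (float("nan"), float("nan"))
        else:
            ci[k] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return {"ci_years": ci, "n_skipped": n_skipped, "n_used": {k: len(v) for k, v in ages.items()}}


def date_inversion(haps: HaplotypeSet, rates: dict[str, float], span=None,
                   n_boot: int = 1000, seed: int = 1,
                   rate_unit: str = "per_year",
                   generation_time: float = DEFAULT_GENERATION_TIME,
                   site_length: int | None = None) -> AgeEstimate:
    """Point age per rate plus bootstrap CI, in one call."""
    div = pairwise_diversity(haps, span=span, site_length=site_length)
    est = estimate_age(div, rates, rate_unit=rate_unit,
                       generation_time=generation_time)
    boot = bootstrap_ci(haps, rates, span=span, n_boot=n_boot, seed=seed,
                        rate_unit=rate_unit, generation_time=generation_time,
                        site_length=site_length)
    est.ci_years = boot["ci_years"]
    return est
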