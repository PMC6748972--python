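"""Linkage between inversions and nearby variants.

Covers pairwise r² (haplotype-based or composite genotype-based), tag-variant
discovery, the fixed / shared / private classification of variants with
respect to the two inversion orientations, windowed shared-fraction profiles
around the breakpoints, and the definition of the non-recombining flanking
region on each side of an inversion.

The fixed-vs-shared contrast is the diagnostic signal for inversion origin:
a unique origin with crossover suppression leaves variants either perfectly
associated with orientation (fixed) or private to one orientation, while
recurrence or genetic exchange produces variants unambiguously polymorphic
on both orientations (shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    GenotypeTable,
    HaplotypeSet,
    InversionRecord,
    InvpopkitError,
    VariantPanel,
)

CLASS_LABELS = ("fixed", "shared", "private_O1", "private_O2", "unassigned")


# ---------------------------------------------------------------------------
# r-squared
# ---------------------------------------------------------------------------

def ld_r2_haplotype(a: np.ndarray, b: np.ndarray) -> float:
    """Haplotype-based r² = D² / (p_A p_a p_B p_b) by direct gamete counting.

    ``a`` and ``b`` are 0/1 allele vectors over the same haplotypes;
    entries < 0 or NaN are removed pairwise.  Returns NaN when either
    vector is monomorphic after missing-data removal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a >= 0) & (b >= 0) & ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = np.mean(a * b)
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_r2_genotype(da: np.ndarray, db: np.ndarray) -> float:
    """Composite LD for unphased data: squared dosage correlation.

    Phase-free and reduces to the haplotype r² under Hardy-Weinberg
    proportions.  NaN dosages removed pairwise; monomorphic input → NaN.
    """
    da = np.asarray(da, dtype=float)
    db = np.asarray(db, dtype=float)
    ok = ~np.isnan(da) & ~np.isnan(db)
    da, db = da[ok], db[ok]
    if len(da) < 2 or da.std() == 0 or db.std() == 0:
        return float("nan")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)


def ld_r2(a, b, method: str = "auto") -> tuple[float, str]:
    """Pairwise r² with the method used recorded.

    ``method``: ``haplotype`` (both inputs are phased 0/1 allele vectors),
    ``genotype`` (dosage vectors) or ``auto`` (haplotype if both inputs are
    binary).
    """
    if method == "auto":
        av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        binary = all(
            np.all(np.isin(v[~np.isnan(v)], (0.0, 1.0))) for v in (av, bv)
        )
        method = "haplotype" if binary else "genotype"
    if method == "haplotype":
        return ld_r2_haplotype(a, b), "haplotype"
    if method == "genotype":
        return ld_r2_genotype(a, b), "genotype"
    raise InvpopkitError(f"unknown LD method {method!r}")


# ---------------------------------------------------------------------------
# Tag variants
# ---------------------------------------------------------------------------

def find_tag_variants(
    gt: GenotypeTable,
    inversion: str,
    variants: VariantPanel,
    inv_record: InversionRecord,
    window: int = 200_000,
    threshold: float = 0.8,
    strata: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Variants with r² >= threshold with the inversion, per stratum.

    The search window extends ``window`` bases from each breakpoint (the
    region between the breakpoints is always included).  Returns one row per
    stratum x variant above threshold, sorted by descending r² within each
    stratum; perfect tags (r² == 1) are flagged, and ``o2_allele`` records
    which variant allele (0=ref, 1=alt) travels with the O2 orientation.
    """
    if window < 0:
        raise InvpopkitError("window must be >= 0")
    lo = inv_record.bp1_start - window
    hi = inv_record.bp2_end + window
    region = variants.in_region(inv_record.chromosome, lo, hi)
    strata = strata or {"all": gt.sample_ids}

    rows = []
    for stratum, samples in strata.items():
        samples = [s for s in samples if s in variants.samples]
        vidx = [variants.samples.index(s) for s in samples]
        inv_dos = gt.dosage(inversion, samples)
        dos = region.alt_dosage()[:, vidx]
        for i in range(region.n_variants):
            r2 = ld_r2_genotype(inv_dos, dos[i])
            if np.isnan(r2) or r2 < threshold:
                continue
            ok = ~np.isnan(inv_dos) & ~np.isnan(dos[i])
            sign = np.corrcoef(inv_dos[ok], dos[i][ok])[0, 1]
            rows.append(
                {
                    "stratum": stratum,
                    "chromosome": region.chromosome[i],
                    "position": int(region.positions[i]),
                    "r2": r2,
                    "perfect": bool(r2 >= 1.0 - 1e-9),
                    "o2_allele": 1 if sign > 0 else 0,
                }
            )
    df = pd.DataFrame(
        rows, columns=["stratum", "chromosome", "position", "r2", "perfect", "o2_allele"]
    )
    if not df.empty:
        df = df.sort_values(["stratum", "r2"], ascending=[True, False]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Fixed / shared / private classification
# ---------------------------------------------------------------------------

def _evidence_from_genotypes(gt: GenotypeTable, inversion: str,
                             variants: VariantPanel):
    """Alleles observable on each orientation using only inversion
    homozygotes / hemizygotes (the only samples whose chromosomes have an
    unambiguous orientation without phase information)."""
    n_var = variants.n_variants
    sets_o1 = [set() for _ in range(n_var)]
    sets_o2 = [set() for _ in range(n_var)]
    counts = np.zeros((n_var, 2, 2), dtype=int)  # (variant, orientation, allele)
    for j, sample in enumerate(variants.samples):
        inv_alleles = set(gt.alleles(sample, inversion))
        if not inv_alleles:
            continue
        g = variants.genotypes[:, j, :]
        if len(inv_alleles) == 1:
            # homozygote / hemizygote: every variant allele sits on this
            # orientation
            oi = 0 if inv_alleles == {"O1"} else 1
            target = sets_o1 if oi == 0 else sets_o2
            for allele_col in range(2):
                col = g[:, allele_col]
                for a in (0, 1):
                    hit = (col >= 0) & (col == a)
                    counts[hit, oi, a] += 1
                    for vi in np.flatnonzero(hit):
                        target[vi].add(a)
        else:
            # heterokaryotype: only variant homozygotes are unambiguous —
            # the same allele must sit on both orientations
            hom = (g[:, 0] >= 0) & (g[:, 0] == g[:, 1])
            for a in (0, 1):
                hit = hom & (g[:, 0] == a)
                counts[hit, 0, a] += 1
                counts[hit, 1, a] += 1
                for vi in np.flatnonzero(hit):
                    sets_o1[vi].add(a)
                    sets_o2[vi].add(a)
    return sets_o1, sets_o2, counts


def _evidence_from_haplotypes(haps: HaplotypeSet):
    n_var = haps.n_sites
    sets_o1 = [set() for _ in range(n_var)]
    sets_o2 = [set() for _ in range(n_var)]
    counts = np.zeros((n_var, 2, 2), dtype=int)
    for oi, orient in enumerate(("O1", "O2")):
        rows = haps.haplotypes[haps.orientation == orient]
        for a in (0, 1):
            c = (rows == a).sum(axis=0)
            counts[:, oi, a] = c
            for vi in np.flatnonzero(c > 0):
                (sets_o1 if oi == 0 else sets_o2)[vi].add(a)
    return sets_o1, sets_o2, counts


def classify_variants(
    gt: GenotypeTable | None,
    inversion: str | None,
    variants: VariantPanel | None = None,
    haps: HaplotypeSet | None = None,
    use_mask: bool = False,
) -> pd.DataFrame:
    """Classify variants as fixed / shared / private_O1 / private_O2.

    Orientation assignment of alleles uses only inversion homozygotes and
    hemizygotes unless phased haplotypes with orientation labels are
    supplied via ``haps``.  A variant is *fixed* when the two orientations
    carry different, internally monomorphic alleles (equivalent to r² = 1
    with the inversion on the evidence chromosomes); *shared* when both
    variant alleles are unambiguously observed on both orientations;
    *private* when polymorphic on exactly one orientation; and
    *unassigned* when the evidence cannot orient the alleles.  With
    ``use_mask`` only accessibility-mask-passing variants are classified
    (others are labeled unassigned with zero evidence).
    """
    if haps is not None:
        sets_o1, sets_o2, counts = _evidence_from_haplotypes(haps)
        positions = haps.positions
        accessible = haps.accessible
        n_var = haps.n_sites
    else:
        if gt is None or inversion is None or variants is None:
            raise InvpopkitError("need (gt, inversion, variants) or haps")
        sets_o1, sets_o2, counts = _evidence_from_genotypes(gt, inversion, variants)
        positions = variants.positions
        accessible = variants.accessible
        n_var = variants.n_variants

    labels = []
    for vi in range(n_var):
        if use_mask and not accessible[vi]:
            labels.append("unassigned")
            continue
        s1, s2 = sets_o1[vi], sets_o2[vi]
        if len(s1) == 2 and len(s2) == 2:
            labels.append("shared")
        elif len(s1) == 1 and len(s2) == 1:
            labels.append("fixed" if s1 != s2 else "unassigned")
        elif len(s1) == 2 and len(s2) <= 1:
            labels.append("private_O1")
        elif len(s2) == 2 and len(s1) <= 1:
            labels.append("private_O2")
        else:
            labels.append("unassigned")
    return pd.DataFrame(
        {
            "position": positions,
            "label": labels,
            "n_O1_ref": counts[:, 0, 0],
            "n_O1_alt": counts[:, 0, 1],
            "n_O2_ref": counts[:, 1, 0],
            "n_O2_alt": counts[:, 1, 1],
        }
    )


# ---------------------------------------------------------------------------
# Window profiles
# ---------------------------------------------------------------------------

def window_shared_profile(
    classes: pd.DataFrame,
    inv: InversionRecord,
    window: int = 10_000,
    step: int = 5_000,
    flank_span: int = 40_000,
) -> pd.DataFrame:
    """Shared/fixed fractions for the inverted region and flanking windows.

    One record covers the whole inverted region; sliding windows of
    ``window`` bases with ``step`` offset cover ``flank_span`` bases on each
    side.  ``distance`` is the signed distance of the window centre to the
    nearest breakpoint (negative inside the inversion).  Fractions are
    relative to the polymorphic variants classified in the window; windows
    without polymorphic variants get NaN fractions.
    """
    if flank_span <= 0:
        raise InvpopkitError("flank_span must be > 0")
    informative = classes[classes["label"] != "unassigned"]

    def _segment(lo, hi, centre_dist, kind):
        sel = informative[(informative["position"] >= lo) & (informative["position"] < hi)]
        n = len(sel)
        shared = (sel["label"] == "shared").sum()
        fixed = (sel["label"] == "fixed").sum()
        return {
            "start": lo,
            "end": hi,
            "kind": kind,
            "distance": centre_dist,
            "n_polymorphic": n,
            "shared_fraction": shared / n if n else float("nan"),
            "fixed_fraction": fixed / n if n else float("nan"),
        }

    span_lo, span_hi = inv.inverted_span()
    centre = (span_lo + span_hi) / 2
    rows = [
        _segment(span_lo, span_hi,
                 -min(centre - span_lo, span_hi - centre), "inverted")
    ]
    for start in range(inv.bp1_start - flank_span, inv.bp1_start - window + 1, step):
        c = start + window / 2
        rows.append(_segment(start, start + window, inv.bp1_start - c, "left_flank"))
    for start in range(inv.bp2_end, inv.bp2_end + flank_span - window + 1, step):
        c = start + window / 2
        rows.append(_segment(start, start + window, c - inv.bp2_end, "right_flank"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Non-recombining flanks
# ---------------------------------------------------------------------------

@dataclass
class FlankInterval:
    side: str
    start: int
    end: int
    stopped_by: int | None      # position of the stopping shared variant
    n_exempted: int             # gene-conversion-like shared variants skipped

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_side(classes: pd.DataFrame, origin: int, outward: int, max_span: int,
               bracket: int, fixed_rule: str, fixed_fraction: float) -> FlankInterval:
    """Scan outward from one breakpoint.

    The flank extends to the first shared variant compatible with a
    crossing-over event, or the full ``max_span`` if none occurs.  An
    isolated shared variant bracketed by fixed/private variants within
    ``bracket`` bases on both sides is treated as gene-conversion evidence
    and skipped.  When the scan stops early the flank is truncated at the
    outermost fixed variant inside the stopping point (rule ``outermost``),
    at the point keeping ``fixed_fraction`` of fixed variants (rule
    ``fraction``) or simply just before the stopping variant (rule
    ``none``).
    """
    side = "left" if outward < 0 else "right"
    lo, hi = (origin - max_span, origin) if outward < 0 else (origin, origin + max_span)
    sel = classes[(classes["position"] >= lo) & (classes["position"] < hi)]
    sel = sel[sel["label"] != "unassigned"]
    sel = sel.sort_values("position", ascending=outward > 0).reset_index(drop=True)

    pos = sel["position"].to_numpy()
    lab = sel["label"].to_numpy()
    anchored = np.flatnonzero(np.isin(lab, ("fixed", "private_O1", "private_O2")))
    anchor_pos = pos[anchored]

    stop = None
    n_exempt = 0
    for i in np.flatnonzero(lab == "shared"):
        p = pos[i]
        near_in = anchor_pos[np.abs(anchor_pos - p) <= bracket]
        has_both = (near_in < p).any() and (near_in > p).any()
        others = pos[(lab == "shared") & (np.abs(pos - p) <= bracket) & (pos != p)]
        if has_both and len(others) == 0:
            n_exempt += 1     # isolated, bracketed: gene-conversion-like
            continue
        stop = int(p)
        break

    if stop is None:
        start, end = lo, hi
    else:
        inside = (pos < stop) if outward > 0 else (pos > stop)
        fixed_inside = pos[inside & (lab == "fixed")]
        if fixed_rule == "none" or len(fixed_inside) == 0:
            edge = stop
        elif fixed_rule == "outermost":
            edge = int(fixed_inside.max() + 1) if outward > 0 else int(fixed_inside.min())
        elif fixed_rule == "fraction":
            k = max(int(np.ceil(fixed_fraction * len(fixed_inside))), 1)
            ordered = np.sort(np.abs(fixed_inside - origin))
            edge_dist = int(ordered[k - 1]) + 1
            edge = origin + outward * edge_dist
        else:
            raise InvpopkitError(f"unknown fixed_rule {fixed_rule!r}")
        if outward > 0:
            start, end = origin, min(edge, stop)
        else:
            start, end = max(edge, stop + 1), origin
    if end < start:
        start = end = origin
    return FlankInterval(side, int(start), int(end), stop, n_exempt)


def nonrecombining_flank(
    classes: pd.DataFrame,
    inv: InversionRecord,
    max_span: int = 20_000,
    bracket: int = 1_000,
    fixed_rule: str = "outermost",
    fixed_fraction: float = 0.9,
) -> dict[str, FlankInterval]:
    """Define the non-recombining flanking interval on each side.

    The flank is the longest sequence outside the breakpoints, up to
    ``max_span``, that contains no shared variant compatible with a
    crossing-over event (isolated gene-conversion-like shared variants are
    exempt) while including the fixed variants; an empty interval is a
    legitimate outcome.
    """
    return {
        "left": _scan_side(classes, inv.bp1_start, -1, max_span, bracket,
                           fixed_rule, fixed_fraction),
        "right": _scan_side(classes, inv.bp2_end, +1, max_span, bracket,
                            fixed_rule, fixed_fraction),
    }


def write_flanks_bed(flanks: dict[str, FlankInterval], inv: InversionRecord, path) -> None:
    with open(path, "w") as fh:
        for side, f in flanks.items():
            fh.write(f"{inv.chromosome}\t{f.start}\t{f.end}\t"
                     f"{inv.inversion_id}_{side}_flank\n")
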