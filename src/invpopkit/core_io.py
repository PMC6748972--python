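"""Data model and readers/writers for the inversion-analysis pipeline.

The central objects are a sample panel (:class:`PopulationPanel`), an
orientation genotype table (:class:`GenotypeTable`, samples x inversions with
cells like ``O1/O2``), a biallelic variant panel read from VCF
(:class:`VariantPanel`) and a phased haplotype matrix with per-haplotype
inversion-orientation labels (:class:`HaplotypeSet`).

Coordinates are 0-based half-open everywhere internally; VCF's 1-based
positions are converted at the boundary.  Orientation ``O1`` is by convention
the orientation of the reference assembly and is never assumed ancestral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("invpopkit")

#: Tokens accepted in a genotype table.
DIPLOID_CALLS = {"O1/O1", "O1/O2", "O2/O2"}
HAPLOID_CALLS = {"O1", "O2"}
MISSING = "NA"

#: Normalisation of heterozygote spelling: O2/O1 == O1/O2.
_CALL_ALIASES = {"O2/O1": "O1/O2"}

POPULATION_GROUPS = ("AFR", "EUR", "SAS", "EAS", "other")


class InvpopkitError(ValueError):
    """Hard error raised on invalid input."""


# ---------------------------------------------------------------------------
# Population panel
# ---------------------------------------------------------------------------

@dataclass
class PopulationPanel:
    """Sample metadata: sex, population, population group and family roles.

    ``table`` holds one row per sample with columns ``sample_id``, ``sex``
    (male/female/unknown), ``population`` (e.g. YRI), ``group`` (AFR, EUR,
    SAS, EAS or other), ``family_role`` (unrelated/father/mother/child) and
    optional ``family_id``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "sex", "population", "group", "family_role"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvpopkitError(f"panel missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table["sample_id"][self.table["sample_id"].duplicated()]
            raise InvpopkitError(f"duplicate sample ids: {sorted(set(dups))}")
        if "family_id" not in self.table.columns:
            self.table = self.table.assign(family_id=pd.NA)
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def sex_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise InvpopkitError(f"sample {sample_id} not in panel")
        return str(row["sex"].iloc[0])

    def population_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise InvpopkitError(f"sample {sample_id} not in panel")
        return str(row["population"].iloc[0])

    def trios(self) -> list[dict]:
        """Complete father-mother-child trios present in the panel.

        Returns one record per child whose family has both a father and a
        mother; children of incomplete families are reported with
        ``complete=False``.
        """
        out = []
        fam = self.table.dropna(subset=["family_id"])
        for family_id, members in fam.groupby("family_id"):
            roles = {r: list(m) for r, m in members.groupby("family_role")["sample_id"]}
            for child in roles.get("child", []):
                rec = {
                    "family_id": family_id,
                    "child": child,
                    "father": roles.get("father", [None])[0],
                    "mother": roles.get("mother", [None])[0],
                }
                rec["complete"] = rec["father"] is not None and rec["mother"] is not None
                out.append(rec)
        return out


def read_panel(path) -> PopulationPanel:
    """Read a tab-delimited population panel file."""
    return PopulationPanel(pd.read_csv(path, sep="\t", dtype=str))


def write_panel(panel: PopulationPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Inversion records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InversionRecord:
    """Breakpoint coordinates and descriptors of one inversion.

    Breakpoints are 0-based half-open intervals ``[bp1_start, bp1_end)`` and
    ``[bp2_start, bp2_end)``.  ``mechanism`` is ``NAHR`` (inverted-repeat
    mediated) or ``NH`` (non-homologous); ``ir_length`` is 0 for NH.
    ``inverted_length`` defaults to the inner span ``bp2_start - bp1_end``;
    the alternative convention counting the breakpoint intervals themselves
    (IR bases included) is selected with ``include_breakpoints=True`` in
    :func:`inverted_span_length`.
    """

    inversion_id: str
    chromosome: str
    bp1_start: int
    bp1_end: int
    bp2_start: int
    bp2_end: int
    mechanism: str = "NH"
    ir_length: int = 0
    genetic_length: float | None = None  # cumulative 4*Ne*r units
    ancestral: str = "unknown"

    def __post_init__(self):
        if not (self.bp1_start <= self.bp1_end <= self.bp2_start <= self.bp2_end):
            raise InvpopkitError(
                f"{self.inversion_id}: breakpoints must be ordered "
                f"bp1_start<=bp1_end<=bp2_start<=bp2_end"
            )
        if self.ir_length < 0:
            raise InvpopkitError("ir_length must be >= 0")
        if self.mechanism not in ("NH", "NAHR"):
            raise InvpopkitError(f"unknown mechanism {self.mechanism!r}")
        if self.ancestral not in ("O1", "O2", "unknown"):
            raise InvpopkitError(f"bad ancestral state {self.ancestral!r}")

    @property
    def inverted_length(self) -> int:
        return self.bp2_start - self.bp1_end

    def inverted_span(self, include_breakpoints: bool = False) -> tuple[int, int]:
        """Inverted interval, with or without the breakpoint intervals."""
        if include_breakpoints:
            return self.bp1_start, self.bp2_end
        return self.bp1_end, self.bp2_start


def inverted_span_length(inv: InversionRecord, include_breakpoints: bool = False) -> int:
    a, b = inv.inverted_span(include_breakpoints)
    return b - a


def read_inversions(path) -> list[InversionRecord]:
    """Read a BED-like tab-delimited inversion table."""
    df = pd.read_csv(path, sep="\t")
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(
            InversionRecord(
                inversion_id=str(d["inversion_id"]),
                chromosome=str(d["chromosome"]),
                bp1_start=int(d["bp1_start"]),
                bp1_end=int(d["bp1_end"]),
                bp2_start=int(d["bp2_start"]),
                bp2_end=int(d["bp2_end"]),
                mechanism=str(d.get("mechanism", "NH")),
                ir_length=int(d.get("ir_length", 0)),
                genetic_length=(None if pd.isna(d.get("genetic_length", np.nan))
                                else float(d["genetic_length"])),
                ancestral=str(d.get("ancestral", "unknown")),
            )
        )
    return recs


def write_inversions(recs: Sequence[InversionRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "inversion_id": r.inversion_id,
                "chromosome": r.chromosome,
                "bp1_start": r.bp1_start,
                "bp1_end": r.bp1_end,
                "bp2_start": r.bp2_start,
                "bp2_end": r.bp2_end,
                "mechanism": r.mechanism,
                "ir_length": r.ir_length,
                "genetic_length": r.genetic_length,
                "ancestral": r.ancestral,
            }
            for r in recs
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------

def _ploidy(chromosome: str, sex: str) -> int:
    """Expected call ploidy for one sample at one inversion."""
    chrom = chromosome.removeprefix("chr")
    if chrom == "Y":
        return 1
    if chrom == "X" and sex == "male":
        return 1
    return 2


@dataclass
class GenotypeTable:
    """Orientation genotypes: one row per sample, one column per inversion.

    Cells hold ``O1/O1``, ``O1/O2``, ``O2/O2`` (diploid), ``O1``/``O2``
    (hemizygous, chrY and male chrX) or ``NA``.  ``chromosomes`` maps
    inversion id -> chromosome and drives ploidy validation together with
    the panel's sex column.
    """

    table: pd.DataFrame  # index: sample_id, columns: inversion ids, dtype str
    panel: PopulationPanel
    chromosomes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        panel_ids = set(self.panel.sample_ids)
        absent = [s for s in self.table.index if s not in panel_ids]
        if absent:
            raise InvpopkitError(f"samples absent from panel: {absent[:5]}")
        self.validate_ploidy()

    def validate_ploidy(self) -> None:
        for inv in self.table.columns:
            chrom = self.chromosomes.get(inv, "autosome")
            for sample, call in self.table[inv].items():
                if call == MISSING:
                    continue
                p = _ploidy(chrom, self.panel.sex_of(sample))
                if p == 1 and call in DIPLOID_CALLS:
                    raise InvpopkitError(
                        f"diploid call {call} for hemizygous sample {sample} "
                        f"at {inv} ({chrom})"
                    )
                if p == 2 and call in HAPLOID_CALLS:
                    raise InvpopkitError(
                        f"haploid call {call} for diploid sample {sample} at {inv}"
                    )

    @property
    def inversion_ids(self) -> list[str]:
        return list(self.table.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def alleles(self, sample: str, inversion: str) -> tuple[str, ...]:
        """Orientation alleles of one call; empty tuple when missing."""
        call = self.table.at[sample, inversion]
        if call == MISSING:
            return ()
        return tuple(call.split("/"))

    def dosage(self, inversion: str, samples: Sequence[str] | None = None) -> np.ndarray:
        """O2-allele dosage per sample (NaN for missing calls)."""
        samples = self.sample_ids if samples is None else list(samples)
        out = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            al = self.alleles(s, inversion)
            if al:
                out[i] = sum(a == "O2" for a in al)
        return out

    def o2_frequency(self, inversion: str, samples: Sequence[str] | None = None) -> float:
        """Frequency of the O2 orientation among non-missing alleles."""
        samples = self.sample_ids if samples is None else list(samples)
        n2 = n = 0
        for s in samples:
            for a in self.alleles(s, inversion):
                n += 1
                n2 += a == "O2"
        return n2 / n if n else float("nan")


def read_genotype_table(path, panel: PopulationPanel,
                        chromosomes: Mapping[str, str] | None = None) -> GenotypeTable:
    """Read a tab-delimited genotype table (header row of inversion ids).

    Unknown tokens are converted to missing with a logged warning count;
    samples absent from the panel and diploid calls on hemizygous
    chromosomes raise hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    n_unknown = 0
    valid = DIPLOID_CALLS | HAPLOID_CALLS | {MISSING}
    for col in df.columns:
        normalised = df[col].map(lambda c: _CALL_ALIASES.get(c, c))
        bad = ~normalised.isin(valid)
        n_unknown += int(bad.sum())
        df[col] = normalised.where(~bad, MISSING)
    if n_unknown:
        logger.warning("genotype table %s: %d unknown tokens set to missing", path, n_unknown)
    return GenotypeTable(df, panel, chromosomes or {})


def write_genotype_table(gt: GenotypeTable, path) -> None:
    gt.table.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Variant panel (VCF)
# ---------------------------------------------------------------------------

@dataclass
class VariantPanel:
    """Biallelic variants with per-sample genotypes.

    ``genotypes`` has shape (n_variants, n_samples, 2) with allele codes
    0/1 and -1 for missing; hemizygous calls are stored as (allele, -9)
    where -9 marks the absent second allele.  ``phased`` is per-variant,
    per-sample.  Positions are 0-based and strictly increasing within a
    chromosome.
    """

    chromosome: np.ndarray      # (n_variants,) str
    positions: np.ndarray       # (n_variants,) int, 0-based
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray       # (n_variants, n_samples, 2) int8
    phased: np.ndarray          # (n_variants, n_samples) bool
    samples: list[str]
    accessible: np.ndarray | None = None      # (n_variants,) bool
    ancestral: np.ndarray | None = None       # (n_variants,) str or None
    is_snp: np.ndarray | None = None
    n_dropped_multiallelic: int = 0

    ABSENT = -9  # second-allele slot of a hemizygous call

    def __post_init__(self):
        if self.accessible is None:
            self.accessible = np.ones(self.n_variants, dtype=bool)
        if self.is_snp is None:
            self.is_snp = np.array(
                [len(r) == 1 and len(a) == 1 for r, a in zip(self.ref, self.alt)]
            )
        for chrom in np.unique(self.chromosome):
            pos = self.positions[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise InvpopkitError(f"positions not strictly increasing on {chrom}")

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "VariantPanel":
        return replace(
            self,
            chromosome=self.chromosome[mask],
            positions=self.positions[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
            phased=self.phased[mask],
            accessible=self.accessible[mask],
            ancestral=None if self.ancestral is None else self.ancestral[mask],
            is_snp=self.is_snp[mask],
        )

    def in_region(self, chromosome: str, start: int, end: int) -> "VariantPanel":
        """Variants with 0-based position in [start, end)."""
        mask = (
            (self.chromosome == chromosome)
            & (self.positions >= start)
            & (self.positions < end)
        )
        return self.subset(mask)

    def alt_dosage(self) -> np.ndarray:
        """Per-variant, per-sample count of alt alleles (NaN if missing)."""
        g = self.genotypes.astype(float)
        g[self.genotypes == self.ABSENT] = 0.0
        g[self.genotypes == -1] = np.nan
        return g.sum(axis=2)

    def alt_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing alleles."""
        called = (self.genotypes >= 0)
        n_alt = np.where(called, self.genotypes, 0).sum(axis=(1, 2))
        n = called.sum(axis=(1, 2))
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, n_alt / np.maximum(n, 1), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1 - p)


def read_variants(path, panel: PopulationPanel | None = None,
                  region: tuple[str, int, int] | None = None) -> VariantPanel:
    """Read biallelic records from a VCF file.

    Multiallelic and symbolic records are dropped (count logged and stored
    on the returned panel); samples present in the VCF but absent from the
    panel are dropped with a warning.  ``region`` is a 0-based half-open
    (chrom, start, end) filter applied after reading.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if panel is not None:
        keep = [s for s in vcf_samples if s in set(panel.sample_ids)]
        dropped = [s for s in vcf_samples if s not in set(panel.sample_ids)]
        if dropped:
            logger.warning("VCF %s: %d samples not in panel dropped", path, len(dropped))
    else:
        keep = vcf_samples
    keep_idx = [vcf_samples.index(s) for s in keep]

    chroms, poss, refs, alts, gts, phs = [], [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.ALT[0].startswith("<") or "*" in rec.ALT:
            n_multi += 1
            continue
        g = np.asarray(rec.genotype.array())  # (n_samples, ploidy+1); last col=phase
        alleles = g[keep_idx, :-1]
        phase = g[keep_idx, -1].astype(bool)
        if alleles.shape[1] == 1:
            alleles = np.column_stack(
                [alleles[:, 0], np.full(len(keep_idx), VariantPanel.ABSENT)]
            )
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)  # to 0-based
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts.append(alleles.astype(np.int8))
        phs.append(phase)
    if not poss:
        raise InvpopkitError(f"no usable biallelic records in {path}")
    vp = VariantPanel(
        chromosome=np.array(chroms),
        positions=np.array(poss, dtype=int),
        ref=np.array(refs),
        alt=np.array(alts),
        genotypes=np.stack(gts),
        phased=np.stack(phs),
        samples=keep,
        n_dropped_multiallelic=n_multi,
    )
    if n_multi:
        logger.warning("VCF %s: dropped %d multiallelic/symbolic records", path, n_multi)
    if region is not None:
        vp = vp.in_region(*region)
    return vp


def write_vcf(vp: VariantPanel, path) -> None:
    """Write a minimal VCF 4.2 file (positions back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(vp.chromosome):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vp.samples) + "\n")
        for i in range(vp.n_variants):
            cells = []
            for j in range(vp.n_samples):
                a, b = vp.genotypes[i, j]
                sep = "|" if vp.phased[i, j] else "/"
                if b == VariantPanel.ABSENT:
                    cells.append("." if a < 0 else str(a))
                else:
                    sa = "." if a < 0 else str(a)
                    sb = "." if b < 0 else str(b)
                    cells.append(f"{sa}{sep}{sb}")
            fh.write(
                f"{vp.chromosome[i]}\t{vp.positions[i] + 1}\t.\t{vp.ref[i]}\t"
                f"{vp.alt[i]}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Haplotype set
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotypes with per-haplotype orientation labels.

    Two haplotypes per diploid sample, one per hemizygote.  ``orientation``
    entries are ``O1``, ``O2`` or ``unknown``; they are set only by perfect
    tag variants or by restriction to inversion homozygotes/hemizygotes
    (see :mod:`invpopkit.recurrence`), or carried over from a simulator.
    """

    haplotypes: np.ndarray          # (n_haps, n_sites) int8, -1 missing
    positions: np.ndarray           # (n_sites,) int
    orientation: np.ndarray         # (n_haps,) str
    sample_id: np.ndarray           # (n_haps,) str
    population: np.ndarray | None = None
    accessible: np.ndarray | None = None    # (n_sites,) bool
    ancestral_is_ref: np.ndarray | None = None

    def __post_init__(self):
        n_haps, n_sites = self.haplotypes.shape
        if len(self.positions) != n_sites or len(self.orientation) != n_haps:
            raise InvpopkitError("inconsistent haplotype set dimensions")
        if self.accessible is None:
            self.accessible = np.ones(n_sites, dtype=bool)
        if self.population is None:
            self.population = np.array(["pop0"] * n_haps)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def in_span(self, start: int, end: int) -> "HaplotypeSet":
        mask = (self.positions >= start) & (self.positions < end)
        return HaplotypeSet(
            haplotypes=self.haplotypes[:, mask],
            positions=self.positions[mask],
            orientation=self.orientation.copy(),
            sample_id=self.sample_id.copy(),
            population=self.population.copy(),
            accessible=self.accessible[mask],
            ancestral_is_ref=None if self.ancestral_is_ref is None
            else self.ancestral_is_ref[mask],
        )

    def labeled(self) -> "HaplotypeSet":
        """Subset to haplotypes with a known orientation."""
        mask = self.orientation != "unknown"
        return HaplotypeSet(
            haplotypes=self.haplotypes[mask],
            positions=self.positions.copy(),
            orientation=self.orientation[mask],
            sample_id=self.sample_id[mask],
            population=self.population[mask],
            accessible=self.accessible.copy(),
            ancestral_is_ref=self.ancestral_is_ref,
        )


# ---------------------------------------------------------------------------
# Mendelian transmission check
# ---------------------------------------------------------------------------

def _legal_child_calls(father: tuple, mother: tuple, chromosome: str,
                       child_sex: str) -> set[tuple]:
    """All child genotypes consistent with Mendelian transmission.

    Enumerates every parental gamete combination, respecting chrX and chrY
    hemizygosity (fathers transmit chrX only to daughters; chrY only to
    sons; mothers never transmit chrY).
    """
    chrom = chromosome.removeprefix("chr")
    if chrom == "Y":
        if child_sex == "female":
            return set()        # untestable: daughters carry no Y
        return {(a,) for a in father} if father else set()
    if chrom == "X":
        mother_gametes = set(mother)
        if child_sex == "male":
            return {(g,) for g in mother_gametes}
        father_gametes = set(father)
        return {
            tuple(sorted((f, m))) for f in father_gametes for m in mother_gametes
        }
    return {
        tuple(sorted((f, m))) for f in set(father) for m in set(mother)
    }


def mendelian_check(gt: GenotypeTable, panel: PopulationPanel | None = None) -> pd.DataFrame:
    """Check genetic transmission in all complete trios.

    Returns one row per trio x inversion with status ``consistent``,
    ``violation`` or ``untestable`` (missing data, or configurations with
    no informative expectation such as chrY in daughters).
    """
    panel = panel or gt.panel
    rows = []
    trios = [t for t in panel.trios() if t["complete"]]
    if not trios:
        raise InvpopkitError("panel contains no complete trio")
    for trio in trios:
        child_sex = panel.sex_of(trio["child"])
        for inv in gt.inversion_ids:
            chrom = gt.chromosomes.get(inv, "autosome")
            f = gt.alleles(trio["father"], inv)
            m = gt.alleles(trio["mother"], inv)
            c = gt.alleles(trio["child"], inv)
            chrom_short = chrom.removeprefix("chr")
            needs_father = chrom_short != "X" or child_sex != "male"
            needs_mother = chrom_short != "Y"
            if not c or (needs_father and not f) or (needs_mother and not m):
                status = "untestable"
            else:
                legal = _legal_child_calls(f, m, chrom, child_sex)
                if not legal:
                    status = "untestable"
                else:
                    status = "consistent" if tuple(sorted(c)) in legal else "violation"
            rows.append(
                {
                    "family_id": trio["family_id"],
                    "child": trio["child"],
                    "inversion_id": inv,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
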