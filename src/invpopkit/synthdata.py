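"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emits phased haplotype panels that carry a polymorphic
inversion, plus the matching variant panel, orientation genotype table and a
ground-truth record, so every downstream stage (linkage, recurrence, dating,
frequency, selection, expression) can be exercised and calibrated at desk
scale.

Model
-----
The two inversion orientations suppress crossing over between each other
inside the inverted span (single crossovers in heterokaryotypes produce
unbalanced gametes), while exchange among same-orientation chromosomes is
unaffected.  This is modeled with the structured coalescent: the O1 and O2
orientation classes are msprime sub-populations with zero migration, joined
at the origin event(s).  A unique origin of age ``T`` generations is a
single population split at ``T``; a recurrent inversion with ``k`` events is
``k`` derived demes splitting independently from the O1 background, giving
``k`` disjoint haplotype backgrounds.  Because demes never exchange lineages
after the split, no variant inside the span can become unambiguously
polymorphic on both orientations except through gene conversion, which is
added explicitly as short copied tracts (default 200 bp) between random
opposite-orientation haplotypes.

Outside the span, crossovers between orientation classes do occur; they are
emulated by explicit exchange events in the flanks whose expected number
follows the ancestral-recombination-graph scaling rho * L * H(n-1) thinned
by the probability 2f(1-f) that an exchange joins opposite classes.  Sites
far from the breakpoint are shuffled by more events, so the shared-variant
fraction rises with flank distance, as observed around unique inversions.

The O1 deme and the ancestral population share the effective size ``Ne``
and the O2 deme has size ``f * Ne``, so the expected net divergence
``pi_between - max(pi_within)`` equals ``2 * mu * T`` — the quantity the
divergence-based dating module estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import dendropy
import msprime
import numpy as np
import pandas as pd

from .core_io import (
    GenotypeTable,
    HaplotypeSet,
    InversionRecord,
    InvpopkitError,
    PopulationPanel,
    VariantPanel,
)

DEFAULT_GENERATION_TIME = 29.0  # years per generation


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    ``target_frequency`` is the fraction of sampled haplotypes carrying the
    O2 orientation; it is realised exactly by the sample composition of the
    structured model.  ``origin`` is ``unique`` (one event of
    ``age_generations``), ``recurrent`` (``k_events`` independent origins)
    or ``none`` (plain neutral panel, no inversion).  Rates are per site and
    per generation.
    """

    n_samples: int = 50                      # diploid individuals
    ploidy: int = 2
    sequence_length: int = 100_000
    mutation_rate: float = 1e-7
    recombination_rate: float = 0.0
    effective_size: float = 10_000.0
    span: tuple[int, int] = (30_000, 70_000)  # inversion span, 0-based half-open
    target_frequency: float = 0.3
    origin: str = "unique"
    age_generations: float = 2_000.0
    k_events: int = 1
    event_ages: tuple[float, ...] | None = None
    gene_conversion_rate: float = 0.0        # expected tracts per bp per haplotype
    gene_conversion_tract: int = 200
    derived_deme_size: float | None = None   # per-event O2 class size; None -> f*Ne/k
    discrete_positions: bool = True          # False -> infinite-sites (no homoplasy)
    generation_time: float = DEFAULT_GENERATION_TIME
    seed: int = 1
    max_retries: int = 30

    def __post_init__(self):
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise InvpopkitError("rates must be >= 0")
        if self.origin not in ("unique", "recurrent", "none"):
            raise InvpopkitError(f"unknown origin model {self.origin!r}")
        if self.origin == "recurrent" and self.k_events < 1:
            raise InvpopkitError("k_events must be >= 1")
        if self.origin != "none" and not 0.0 < self.target_frequency < 1.0:
            raise InvpopkitError("target_frequency must be in (0, 1)")
        if not (0 <= self.span[0] < self.span[1] <= self.sequence_length):
            raise InvpopkitError("span must lie within the sequence")


@dataclass
class TruthRecord:
    """Ground truth of a synthetic dataset, for recovery tests."""

    origin_events: list[dict] = field(default_factory=list)  # {age, carriers}
    age_generations: float | None = None
    tag_sites: list[int] = field(default_factory=list)       # perfect-tag site idx
    eqtl_effects: dict[str, float] = field(default_factory=dict)
    ytree_event_edges: list[str] = field(default_factory=list)
    n_gene_conversion_tracts: int = 0
    n_flank_exchanges: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


def _event_counts(n_o2: int, k: int) -> list[int]:
    base = n_o2 // k
    counts = [base + (1 if i < n_o2 - base * k else 0) for i in range(k)]
    if min(counts) < 1:
        raise InvpopkitError(f"cannot place {k} origin events on {n_o2} O2 haplotypes")
    return counts


def _demography(cfg: SimConfig, event_ages: list[float]) -> msprime.Demography:
    demog = msprime.Demography()
    # the O1 background hosts samples from time 0, so it must stay active
    # despite also being the ancestral side of the split events
    demog.add_population(name="O1", initial_size=cfg.effective_size,
                         initially_active=True)
    f = cfg.target_frequency
    size = (cfg.derived_deme_size if cfg.derived_deme_size is not None
            else f * cfg.effective_size / len(event_ages))
    for i, age in enumerate(event_ages):
        demog.add_population(name=f"O2_{i}", initial_size=max(size, 1.0))
    for i, age in sorted(enumerate(event_ages), key=lambda t: t[1]):
        # each orientation event starts from a single founder chromosome:
        # force full coalescence of the derived deme at the event time, then
        # merge the founder lineage into the background population
        demog.add_simple_bottleneck(time=age, population=f"O2_{i}", proportion=1.0)
        demog.add_population_split(
            time=age * (1 + 1e-9) + 1e-9, derived=[f"O2_{i}"], ancestral="O1"
        )
    demog.sort_events()
    return demog


def simulate_haplotypes(cfg: SimConfig):
    """Simulate one cohort.

    Returns ``(HaplotypeSet, VariantPanel, GenotypeTable, TruthRecord)``.
    Haplotype orientation labels in the returned set are the simulator
    truth; analyses that must *infer* orientation should blank them first.
    """
    rng = np.random.default_rng(cfg.seed)
    n_haps = cfg.n_samples * cfg.ploidy

    if cfg.origin == "none":
        event_ages: list[float] = []
        n_per_event: list[int] = []
        n_o2 = 0
        samples = {"O1": n_haps}
        demog = msprime.Demography()
        demog.add_population(name="O1", initial_size=cfg.effective_size)
    else:
        k = cfg.k_events if cfg.origin == "recurrent" else 1
        if cfg.event_ages is not None:
            if len(cfg.event_ages) != k:
                raise InvpopkitError("event_ages length must equal the event count")
            event_ages = list(cfg.event_ages)
        else:
            event_ages = [cfg.age_generations] * k
        n_o2 = int(round(cfg.target_frequency * n_haps))
        if not 0 < n_o2 < n_haps:
            raise InvpopkitError(
                "target_frequency unattainable at this sample size; "
                "increase n_samples"
            )
        n_per_event = _event_counts(n_o2, k)
        samples = {"O1": n_haps - n_o2}
        samples.update({f"O2_{i}": c for i, c in enumerate(n_per_event)})
        demog = _demography(cfg, event_ages)

    for attempt in range(cfg.max_retries):
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demog,
            sequence_length=cfg.sequence_length,
            recombination_rate=cfg.recombination_rate,
            ploidy=1,  # haplotypes sampled individually; pairing done below
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        if cfg.origin != "recurrent" or cfg.k_events == 1 or \
                _backgrounds_distinct(ts, cfg):
            break
    else:
        raise InvpopkitError(
            "could not realise distinct haplotype backgrounds for the "
            "requested recurrent events; increase n_samples or max_retries"
        )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        model=msprime.BinaryMutationModel(),
        discrete_genome=cfg.discrete_positions,
    )

    # keep polymorphic single-mutation sites: each variant then marks one
    # clade of the genealogy (infinite-sites behaviour, no homoplasy)
    G = ts.genotype_matrix()  # (sites, haps)
    n_mut = np.array([len(s.mutations) for s in ts.sites()])
    if cfg.discrete_positions:
        positions = np.array([int(s.position) for s in ts.sites()], dtype=int)
    else:
        positions = np.array([s.position for s in ts.sites()], dtype=float)
    poly = (G.sum(axis=1) > 0) & (G.sum(axis=1) < G.shape[1]) & (n_mut == 1)
    positions, G = positions[poly], G[poly]
    H = G.T.astype(np.int8)
    # discretisation can duplicate positions; keep the first of each
    uniq = np.concatenate(([True], np.diff(positions) > 0))
    positions, H = positions[uniq], H[:, uniq]

    # haplotype orientation truth, in tree-sequence sample order
    orientation = np.array(["O1"] * n_haps, dtype=object)
    carriers_per_event: list[list[int]] = []
    idx = n_haps - n_o2
    for c in n_per_event:
        carriers = list(range(idx, idx + c))
        carriers_per_event.append(carriers)
        orientation[carriers] = "O2"
        idx += c

    truth = TruthRecord(
        origin_events=[
            {"age_generations": a, "carriers": c}
            for a, c in zip(event_ages, carriers_per_event)
        ],
        age_generations=event_ages[0] if cfg.origin == "unique" else None,
    )

    # between-class crossovers in the flanks (span stays suppressed)
    H = _flank_exchanges(H, positions, cfg, orientation, rng, truth)
    # gene-conversion tracts across orientation classes inside the span
    H = _gene_conversion(H, positions, cfg, orientation, rng, truth)

    # shuffle haplotypes into diploid samples so orientation classes mix
    order = rng.permutation(n_haps)
    H = H[order]
    orientation = orientation[order]
    remap = {old: new for new, old in enumerate(order)}
    for ev in truth.origin_events:
        ev["carriers"] = sorted(remap[c] for c in ev["carriers"])

    sample_ids = np.array(
        [f"s{i // cfg.ploidy:04d}" for i in range(n_haps)], dtype=object
    )
    haps = HaplotypeSet(
        haplotypes=H,
        positions=positions,
        orientation=orientation,
        sample_id=sample_ids,
        population=np.array(["pop0"] * n_haps, dtype=object),
    )

    if cfg.origin != "none":
        o2 = haps.orientation == "O2"
        span_mask = (positions >= cfg.span[0]) & (positions < cfg.span[1])
        for j in np.flatnonzero(span_mask):
            col = H[:, j].astype(bool)
            if np.array_equal(col, o2) or np.array_equal(~col, o2):
                truth.tag_sites.append(int(j))

    panel, gt = cohort_tables(haps, cfg)
    return haps, panel, gt, truth


def _backgrounds_distinct(ts, cfg: SimConfig) -> bool:
    """True when the k origin events sit on genuinely distinct backgrounds.

    The generator's contract is that the minimum-change reconstruction of
    orientation on the true genealogy equals the number of placed events.
    Realisations where, e.g., two derived clades are sisters (one older flip
    plus a re-inversion explains the tips more cheaply) are rejected and
    redrawn.  Checked by small parsimony on the local tree at the inversion
    midpoint.
    """
    tree = ts.at((cfg.span[0] + cfg.span[1]) / 2)
    state = {int(n): (0 if ts.node(n).population == 0 else 1)
             for n in ts.samples()}

    def cost(node):
        children = tree.children(node)
        if not children:
            s = state[int(node)]
            return [0 if s == 0 else np.inf, 0 if s == 1 else np.inf]
        total = [0.0, 0.0]
        for ch in children:
            c = cost(ch)
            total[0] += min(c[0], c[1] + 1)
            total[1] += min(c[1], c[0] + 1)
        return total

    roots = tree.roots
    changes = sum(min(cost(r)) for r in roots)
    if changes != cfg.k_events:
        return False

    # additionally require genuine interleaving: under the joint MRCA of any
    # two derived demes there must be at least two maximal O1-only clades,
    # so a flip+re-inversion explanation is strictly more expensive
    by_pop: dict[int, list[int]] = {}
    for n in ts.samples():
        by_pop.setdefault(ts.node(n).population, []).append(int(n))
    demes = [v for k, v in sorted(by_pop.items()) if k != 0]

    def n_o1_clades(node):
        children = tree.children(node)
        if not children:
            return (1, True) if state[int(node)] == 0 else (0, False)
        counts, flags = zip(*(n_o1_clades(ch) for ch in children))
        if all(flags):
            return 1, True
        return sum(counts), False

    for i in range(len(demes)):
        for j in range(i + 1, len(demes)):
            m = tree.mrca(*(demes[i] + demes[j]))
            if n_o1_clades(m)[0] < 2:
                return False
    return True


def _flank_exchanges(H, positions, cfg, orientation, rng, truth):
    """Explicit crossovers between orientation classes outside the span."""
    if cfg.origin == "none" or cfg.recombination_rate == 0:
        return H
    o1 = np.flatnonzero(orientation == "O1")
    o2 = np.flatnonzero(orientation == "O2")
    n = len(orientation)
    f = len(o2) / n
    harmonic = np.log(max(n - 1, 2)) + 0.5772
    rho = 4 * cfg.effective_size * cfg.recombination_rate
    for flank, away_right in (((0, cfg.span[0]), False),
                              ((cfg.span[1], cfg.sequence_length), True)):
        length = flank[1] - flank[0]
        if length <= 0:
            continue
        lam = rho * length * harmonic * 2 * f * (1 - f)
        for _ in range(rng.poisson(lam)):
            u = rng.uniform(*flank)
            i, j = rng.choice(o1), rng.choice(o2)
            # swap the material distal to u (away from the breakpoint)
            distal = positions >= u if away_right else positions < u
            H[i, distal], H[j, distal] = H[j, distal].copy(), H[i, distal].copy()
            truth.n_flank_exchanges += 1
    return H


def _gene_conversion(H, positions, cfg, orientation, rng, truth):
    if cfg.origin == "none" or cfg.gene_conversion_rate == 0:
        return H
    o1 = np.flatnonzero(orientation == "O1")
    o2 = np.flatnonzero(orientation == "O2")
    span_len = cfg.span[1] - cfg.span[0]
    lam = cfg.gene_conversion_rate * span_len * len(orientation)
    for _ in range(rng.poisson(lam)):
        start = rng.uniform(cfg.span[0], cfg.span[1] - cfg.gene_conversion_tract)
        tract = (positions >= start) & (positions < start + cfg.gene_conversion_tract)
        if rng.random() < 0.5:
            donor, recipient = rng.choice(o1), rng.choice(o2)
        else:
            donor, recipient = rng.choice(o2), rng.choice(o1)
        H[recipient, tract] = H[donor, tract]
        truth.n_gene_conversion_tracts += 1
    return H


def cohort_tables(haps: HaplotypeSet, cfg: SimConfig):
    """Package a haplotype set into a VariantPanel and GenotypeTable."""
    n_haps, n_sites = haps.haplotypes.shape
    n_samples = n_haps // cfg.ploidy
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]

    if cfg.ploidy == 2:
        geno = np.stack(
            [haps.haplotypes[0::2], haps.haplotypes[1::2]], axis=2
        ).transpose(1, 0, 2)
    else:
        geno = np.stack(
            [haps.haplotypes, np.full_like(haps.haplotypes, VariantPanel.ABSENT)],
            axis=2,
        ).transpose(1, 0, 2)

    panel_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": ["male" if cfg.ploidy == 1 else ("female" if i % 2 else "male")
                    for i in range(n_samples)],
            "population": "pop0",
            "group": "other",
            "family_role": "unrelated",
        }
    )
    pop_panel = PopulationPanel(panel_df)

    vp = VariantPanel(
        chromosome=np.array(["chrS"] * n_sites),
        positions=haps.positions.copy(),
        ref=np.array(["A"] * n_sites),
        alt=np.array(["G"] * n_sites),
        genotypes=geno.astype(np.int8),
        phased=np.ones((n_sites, n_samples), dtype=bool),
        samples=sample_ids,
    )

    calls = []
    chrom_label = "chrY" if cfg.ploidy == 1 else "chrS"
    for i in range(n_samples):
        labels = haps.orientation[i * cfg.ploidy:(i + 1) * cfg.ploidy]
        calls.append("/".join(sorted(labels)) if cfg.ploidy == 2 else labels[0])
    gt = GenotypeTable(
        pd.DataFrame({"inv0": calls}, index=pd.Index(sample_ids, name="sample_id")),
        pop_panel,
        chromosomes={"inv0": chrom_label},
    )
    return vp, gt


def inversion_record_for(cfg: SimConfig, inversion_id: str = "inv0") -> InversionRecord:
    """The InversionRecord describing a simulated cohort's inversion."""
    return InversionRecord(
        inversion_id=inversion_id,
        chromosome="chrS" if cfg.ploidy == 2 else "chrY",
        bp1_start=cfg.span[0],
        bp1_end=cfg.span[0],
        bp2_start=cfg.span[1],
        bp2_end=cfg.span[1],
        mechanism="NH" if cfg.origin == "unique" else "NAHR",
        ir_length=0,
    )


# ---------------------------------------------------------------------------
# Discovery-panel ascertainment
# ---------------------------------------------------------------------------

@dataclass
class AscertainedVariants:
    """Variants surviving discovery in a small panel, with per-variant
    probability that the discovery process would detect them."""

    panel: VariantPanel
    detection_prob: np.ndarray
    kept: np.ndarray  # boolean mask over the input panel's variants


def simulate_discovery_panel(variants: VariantPanel,
                             discovery_samples: list[str]) -> AscertainedVariants:
    """Keep variants polymorphic within the discovery individuals.

    Mirrors variant discovery in a small sequencing panel: a variant can
    only be found if its alternative allele segregates among the discovery
    individuals.  The recorded detection probability is the carrier-presence
    probability 1 - (1 - p)^m computed from the full-panel alt frequency
    ``p`` and the number ``m`` of discovery chromosomes.
    """
    if not discovery_samples:
        raise InvpopkitError("empty discovery panel")
    idx = [variants.samples.index(s) for s in discovery_samples]
    sub = variants.genotypes[:, idx, :]
    called = sub >= 0
    n_alt = np.where(called, sub, 0).sum(axis=(1, 2))
    n_called = called.sum(axis=(1, 2))
    polymorphic = (n_alt > 0) & (n_alt < n_called)

    m = int(called[polymorphic].sum(axis=(1, 2)).mean()) if polymorphic.any() else 2 * len(idx)
    p = variants.alt_frequency()
    prob = 1.0 - (1.0 - p) ** m
    return AscertainedVariants(
        panel=variants.subset(polymorphic),
        detection_prob=prob[polymorphic],
        kept=polymorphic,
    )


# ---------------------------------------------------------------------------
# chr-Y genealogy with placed inversion events
# ---------------------------------------------------------------------------

def simulate_ytree(n_tips: int, k_events: int, seed: int,
                   mean_edge_generations: float = 500.0,
                   max_tries: int = 500):
    """Random rooted genealogy with ``k_events`` orientation flips.

    Events are placed on distinct edges with pairwise-disjoint tip sets so
    that the minimum-change (Fitch) reconstruction equals ``k_events``;
    placements are redrawn (bounded) until that holds.  Returns
    ``(dendropy.Tree, tip_states dict, TruthRecord)``; edge lengths are in
    generations.
    """
    from .recurrence import fitch_parsimony_events

    if n_tips < 2:
        raise InvpopkitError("need at least two tips")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = _random_coalescent_tree(taxa, rng, mean_edge_generations)
    edges = [
        e for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    ]
    if k_events > len(edges):
        raise InvpopkitError("k_events too large for this tree")

    for _ in range(max_tries):
        if k_events == 0:
            chosen = []
        else:
            chosen = list(rng.choice(len(edges), size=k_events, replace=False))
        states = {t.label: "O1" for t in taxa}
        for ei in chosen:
            for leaf in edges[ei].head_node.leaf_iter():
                states[leaf.taxon.label] = "O2"
        tip_sets = [
            frozenset(l.taxon.label for l in edges[ei].head_node.leaf_iter())
            for ei in chosen
        ]
        disjoint = all(
            not (a & b) for i, a in enumerate(tip_sets) for b in tip_sets[i + 1:]
        )
        if not disjoint:
            continue
        if fitch_parsimony_events(tree, states, root_state="O1") == k_events:
            truth = TruthRecord(
                ytree_event_edges=[f"edge{ei}" for ei in chosen],
                origin_events=[
                    {"age_generations": None, "carriers": sorted(s)}
                    for s in tip_sets
                ],
            )
            return tree, states, truth
    raise InvpopkitError(
        f"could not place {k_events} independent events on this tree"
    )


def _random_coalescent_tree(taxa, rng, mean_edge: float) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=t)
        node.age = 0.0
        nodes.append(node)
    t_now = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t_now += rng.exponential(mean_edge * 2.0 / (k * (k - 1)) * k)
        i, j = rng.choice(k, size=2, replace=False)
        parent = dendropy.Node()
        parent.age = t_now
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = parent.age - child.age
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Expression with a planted genotype effect
# ---------------------------------------------------------------------------

def simulate_expression(gt: GenotypeTable, effects, noise_sd: float,
                        n_genes: int | None = None, baseline: float = 10.0,
                        seed: int = 1, inversion: str | None = None):
    """Expression matrix = baseline + effect * O2-dosage + Gaussian noise.

    ``effects`` is a scalar or per-gene vector; returns ``(DataFrame
    samples x genes, TruthRecord)``.
    """
    rng = np.random.default_rng(seed)
    inversion = inversion or gt.inversion_ids[0]
    effects = np.atleast_1d(np.asarray(effects, dtype=float))
    if n_genes is None:
        n_genes = len(effects)
    if len(effects) == 1:
        effects = np.repeat(effects, n_genes)
    if len(effects) != n_genes:
        raise InvpopkitError("effects length must match n_genes")
    if not np.all(np.isfinite(effects)):
        raise InvpopkitError("effects must be finite")

    dosage = gt.dosage(inversion)
    expr = baseline + np.outer(dosage, effects)
    expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    genes = [f"gene{i:03d}" for i in range(n_genes)]
    df = pd.DataFrame(expr, index=gt.sample_ids, columns=genes)
    truth = TruthRecord(eqtl_effects={g: float(b) for g, b in zip(genes, effects)})
    return df, truth
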