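import itertools

import numpy as np
import pandas as pd
import pytest

from invpopkit.core_io import InversionRecord, InvpopkitError, VariantPanel
from invpopkit.linkage import (
    classify_variants,
    find_tag_variants,
    ld_r2,
    ld_r2_genotype,
    ld_r2_haplotype,
    nonrecombining_flank,
    window_shared_profile,
)
from invpopkit.synthdata import SimConfig, simulate_haplotypes
from conftest import make_gt


class TestLdR2:
    def test_perfect_cosegregation(self):
        a = np.array([0, 0, 1, 1, 0, 1])
        assert ld_r2_haplotype(a, a) == pytest.approx(1.0)
        assert ld_r2_haplotype(a, 1 - a) == pytest.approx(1.0)

    def test_independent_alleles_at_expected_counts(self):
        # all four gametes at frequency-product counts -> D = 0
        a = np.array([0, 0, 1, 1] * 5)
        b = np.array([0, 1, 0, 1] * 5)
        assert ld_r2_haplotype(a, b) == pytest.approx(0.0)

    def test_hand_computed_gamete_counts(self):
        # AB=4, Ab=1, aB=1, ab=4: D = 0.4 - 0.25 = 0.15, r2 = 0.0225/0.0625
        a = np.array([1] * 5 + [0] * 5)
        b = np.array([1] * 4 + [0] + [1] + [0] * 4)
        assert ld_r2_haplotype(a, b) == pytest.approx(0.36)

    def test_monomorphic_returns_nan(self):
        assert np.isnan(ld_r2_haplotype(np.zeros(6), np.array([0, 1] * 3)))

    def test_genotype_mode_equals_haplotype_under_random_pairing(self, rng):
        h1 = rng.integers(0, 2, 400)
        h2 = np.where(rng.random(400) < 0.9, h1, 1 - h1)
        d1 = h1[0::2] + h1[1::2]
        d2 = h2[0::2] + h2[1::2]
        r_h = ld_r2_haplotype(h1, h2)
        r_g = ld_r2_genotype(d1, d2)
        assert r_g == pytest.approx(r_h, abs=0.08)

    def test_method_recorded(self):
        v, m = ld_r2(np.array([0, 1, 1, 0]), np.array([0, 1, 0, 1]))
        assert m == "haplotype"
        v, m = ld_r2(np.array([0.0, 2.0, 1.0]), np.array([0.0, 2.0, 1.0]))
        assert m == "genotype"


class TestTagVariants:
    def test_unique_origin_has_perfect_tag(self, unique_sim):
        cfg, haps, vp, gt, truth = unique_sim
        inv = InversionRecord("inv0", "chrS", cfg.span[0], cfg.span[0],
                              cfg.span[1], cfg.span[1])
        tags = find_tag_variants(gt, "inv0", vp, inv)
        assert len(truth.tag_sites) > 0
        assert tags["perfect"].any()

    def test_recurrent_origin_lacks_perfect_tag(self, recurrent_sim):
        cfg, haps, vp, gt, truth = recurrent_sim
        inv = InversionRecord("inv0", "chrS", cfg.span[0], cfg.span[0],
                              cfg.span[1], cfg.span[1])
        tags = find_tag_variants(gt, "inv0", vp, inv, threshold=0.0)
        assert truth.tag_sites == []
        assert not tags.empty
        assert tags["r2"].max() < 1.0 - 1e-9

    def test_threshold_above_one_yields_empty(self, unique_sim):
        cfg, _, vp, gt, _ = unique_sim
        inv = InversionRecord("inv0", "chrS", cfg.span[0], cfg.span[0],
                              cfg.span[1], cfg.span[1])
        tags = find_tag_variants(gt, "inv0", vp, inv, threshold=1.01)
        assert tags.empty


def _variant_panel(geno, positions=None):
    """(n_var, n_samples, 2) array -> VariantPanel."""
    geno = np.asarray(geno, dtype=np.int8)
    n_var, n_samples, _ = geno.shape
    return VariantPanel(
        chromosome=np.array(["chr1"] * n_var),
        positions=np.arange(n_var) * 10 if positions is None else np.asarray(positions),
        ref=np.array(["A"] * n_var),
        alt=np.array(["G"] * n_var),
        genotypes=geno,
        phased=np.zeros((n_var, n_samples), dtype=bool),
        samples=[f"u{i}" for i in range(n_samples)],
    )


def _unrelated_panel(n):
    from invpopkit.core_io import PopulationPanel

    return PopulationPanel(pd.DataFrame({
        "sample_id": [f"u{i}" for i in range(n)],
        "sex": "female", "population": "CHB", "group": "EAS",
        "family_role": "unrelated",
    }))


class TestClassifyVariants:
    def test_fixed_shared_private_unassigned_examples(self, trio_panel):
        # samples u0..u3 hold the informative genotypes
        gt = make_gt(trio_panel, {"inv": ["NA"] * 6 + ["O1/O1", "O1/O1", "O2/O2", "O1/O2"]})
        geno = np.array([
            # fixed: O1/O1 ref-hom, O2/O2 alt-hom, het sample het
            [[0, 0], [0, 0], [1, 1], [0, 1]],
            # shared: an O1 homozygote is alt-hom and the O2 homozygote is
            # variant-het, so both alleles sit on both orientations
            [[0, 0], [1, 1], [0, 1], [0, 1]],
            # het only in inversion heterozygote, homozygotes uninformative
            [[0, 0], [0, 0], [0, 0], [0, 1]],
            # polymorphic among O1 homozygotes only
            [[0, 0], [0, 1], [0, 0], [0, 0]],
        ])
        vp = _variant_panel(geno)
        cls = classify_variants(gt, "inv", vp)
        assert cls["label"].tolist() == ["fixed", "shared", "unassigned",
                                         "private_O1"]

    def test_shared_from_haplotype_evidence(self):
        from invpopkit.core_io import HaplotypeSet
        haps = HaplotypeSet(
            haplotypes=np.array([[0], [1], [0], [1]], dtype=np.int8),
            positions=np.array([100]),
            orientation=np.array(["O1", "O1", "O2", "O2"], dtype=object),
            sample_id=np.array(["a", "a", "b", "b"], dtype=object),
        )
        cls = classify_variants(None, None, haps=haps)
        assert cls["label"].iloc[0] == "shared"

    def test_agrees_with_assignment_enumeration_oracle(self, rng):
        """The unambiguous evidence sets must equal the allele placements
        forced in every genotype-consistent allele-to-orientation
        assignment (instances of <= 10 diploid samples)."""
        panel = _unrelated_panel(10)
        for _ in range(100):
            inv_calls = list(rng.choice(["O1/O1", "O1/O2", "O2/O2"], 10))
            geno = rng.choice([0, 1], size=(1, 10, 2))
            gt = make_gt(panel, {"inv": inv_calls})
            vp = _variant_panel(geno)
            cls = classify_variants(gt, "inv", vp)
            forced1, forced2 = self._forced_placements(inv_calls, geno[0])
            got1 = {a for a in (0, 1) if cls[f"n_O1_{'ref' if a == 0 else 'alt'}"][0] > 0}
            got2 = {a for a in (0, 1) if cls[f"n_O2_{'ref' if a == 0 else 'alt'}"][0] > 0}
            assert got1 == forced1
            assert got2 == forced2

    @staticmethod
    def _forced_placements(inv_calls, geno):
        """Enumerate all phase assignments of double heterozygotes; return
        the allele sets present on each orientation in EVERY assignment."""
        choices = []
        fixed_part_o1, fixed_part_o2 = [], []
        for call, g in zip(inv_calls, geno):
            alleles = call.split("/")
            if alleles[0] == alleles[1]:
                target = fixed_part_o1 if alleles[0] == "O1" else fixed_part_o2
                target.extend(g)
            else:
                if g[0] == g[1]:
                    fixed_part_o1.append(g[0])
                    fixed_part_o2.append(g[0])
                else:
                    choices.append(tuple(g))
        placements = []
        for combo in itertools.product([0, 1], repeat=len(choices)):
            o1 = set(fixed_part_o1)
            o2 = set(fixed_part_o2)
            for pick, pair in zip(combo, choices):
                o1.add(pair[pick])
                o2.add(pair[1 - pick])
            placements.append((frozenset(o1), frozenset(o2)))
        forced1 = set.intersection(*(set(p[0]) for p in placements))
        forced2 = set.intersection(*(set(p[1]) for p in placements))
        return forced1, forced2


class TestWindowProfile:
    INV = InversionRecord("inv", "chr1", 10_000, 10_000, 20_000, 20_000)

    def test_fraction_arithmetic(self):
        classes = pd.DataFrame({
            "position": np.arange(11_000, 11_010),
            "label": ["shared"] * 3 + ["fixed"] * 2 + ["private_O1"] * 5,
        })
        prof = window_shared_profile(classes, self.INV, flank_span=10_000)
        inv_row = prof[prof["kind"] == "inverted"].iloc[0]
        assert inv_row["shared_fraction"] == pytest.approx(0.3)
        assert inv_row["fixed_fraction"] == pytest.approx(0.2)

    def test_unique_origin_zero_shared_inside(self, unique_sim):
        cfg, haps, _, _, _ = unique_sim
        cls = classify_variants(None, None, haps=haps)
        inv = InversionRecord("inv0", "chrS", cfg.span[0], cfg.span[0],
                              cfg.span[1], cfg.span[1])
        prof = window_shared_profile(cls, inv, flank_span=20_000)
        assert prof[prof["kind"] == "inverted"]["shared_fraction"].iloc[0] == 0.0

    def test_recurrent_origin_shared_inside(self, recurrent_sim):
        cfg, haps, _, _, _ = recurrent_sim
        cls = classify_variants(None, None, haps=haps)
        inv = InversionRecord("inv0", "chrS", cfg.span[0], cfg.span[0],
                              cfg.span[1], cfg.span[1])
        prof = window_shared_profile(cls, inv, flank_span=20_000)
        assert prof[prof["kind"] == "inverted"]["shared_fraction"].iloc[0] > 0.0

    def test_shared_fraction_rises_with_flank_distance(self):
        """With between-orientation crossovers in the flanks, the average
        shared fraction grows away from the breakpoints (monotone rank
        trend over 50 replicates), while the inversion interior stays at
        zero."""
        from scipy.stats import spearmanr

        dist_all, frac_all = [], []
        for seed in range(50):
            cfg = SimConfig(n_samples=20, sequence_length=60_000,
                            span=(20_000, 40_000), target_frequency=0.4,
                            origin="unique", age_generations=4_000,
                            mutation_rate=4e-7, recombination_rate=2e-8,
                            derived_deme_size=300, seed=7_000 + seed)
            haps, _, _, _ = simulate_haplotypes(cfg)
            cls = classify_variants(None, None, haps=haps)
            inv = InversionRecord("inv0", "chrS", 20_000, 20_000, 40_000, 40_000)
            prof = window_shared_profile(cls, inv, flank_span=20_000)
            flanks = prof[prof["kind"] != "inverted"].dropna(subset=["shared_fraction"])
            dist_all.extend(flanks["distance"])
            frac_all.extend(flanks["shared_fraction"])
        rho, p = spearmanr(dist_all, frac_all)
        assert rho > 0
        assert p < 0.01

    def test_bad_flank_span_rejected(self):
        with pytest.raises(InvpopkitError):
            window_shared_profile(pd.DataFrame({"position": [], "label": []}),
                                  self.INV, flank_span=0)


class TestNonrecombiningFlank:
    INV = InversionRecord("inv", "chr1", 50_000, 50_000, 80_000, 80_000)

    @staticmethod
    def _classes(entries):
        return pd.DataFrame(entries, columns=["position", "label"])

    def test_no_shared_gives_full_span(self):
        cls = self._classes([(81_000, "fixed"), (85_000, "private_O1")])
        fl = nonrecombining_flank(cls, self.INV)
        assert fl["right"].length == 20_000
        assert fl["left"].length == 20_000

    def test_stops_before_first_shared(self):
        cls = self._classes([(82_000, "fixed"), (87_340, "shared"),
                             (89_000, "fixed")])
        fl = nonrecombining_flank(cls, self.INV)
        assert fl["right"].stopped_by == 87_340
        assert fl["right"].end <= 87_340
        # default rule truncates at the outermost fixed variant inside
        assert fl["right"].end == 82_001

    def test_gene_conversion_exemption(self):
        """An isolated shared SNP bracketed by fixed variants within 1 kb on
        both sides is skipped and the scan continues."""
        cls = self._classes([(82_000, "fixed"), (82_400, "shared"),
                             (82_900, "fixed"), (95_000, "shared")])
        fl = nonrecombining_flank(cls, self.INV)
        assert fl["right"].n_exempted == 1
        # the scan continues past the exempted SNP and stops at the next
        # (isolated but unbracketed) shared variant
        assert fl["right"].stopped_by == 95_000
        assert fl["right"].end == 82_901

    def test_adjacent_shared_pair_not_exempt(self):
        cls = self._classes([(82_000, "fixed"), (82_400, "shared"),
                             (82_600, "shared"), (82_900, "fixed")])
        fl = nonrecombining_flank(cls, self.INV)
        assert fl["right"].stopped_by == 82_400

    def test_empty_flank_possible(self):
        # shared variants right at the breakpoints leave nothing
        cls = self._classes([(80_000, "shared"), (49_999, "shared")])
        fl = nonrecombining_flank(cls, self.INV)
        assert fl["right"].length == 0
        assert fl["left"].length == 0
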