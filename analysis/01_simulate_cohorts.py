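"""Generate the synthetic study cohorts every later stage consumes.

Writes, under <out>/cohorts/: a unique-origin inversion cohort, a
recurrent-origin (k=3) cohort and a large neutral SNP pool — each as
VCF + population panel + orientation genotype table + ground-truth JSON.
"""

import argparse
import pathlib

from invpopkit.core_io import write_genotype_table, write_panel, write_vcf
from invpopkit.synthdata import SimConfig, simulate_haplotypes

PRESETS = {
    "unique": SimConfig(n_samples=30, sequence_length=60_000,
                        span=(20_000, 40_000), target_frequency=0.3,
                        origin="unique", age_generations=5_000,
                        mutation_rate=5e-7, derived_deme_size=300),
    "recurrent": SimConfig(n_samples=30, sequence_length=60_000,
                           span=(20_000, 40_000), target_frequency=0.4,
                           origin="recurrent", k_events=3,
                           age_generations=5_000, mutation_rate=5e-7,
                           derived_deme_size=300),
    "neutral_pool": SimConfig(n_samples=500, sequence_length=2_000_000,
                              span=(0, 1), target_frequency=0.5,
                              origin="none", mutation_rate=1.25e-8,
                              recombination_rate=1e-8),
}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()

    outdir = args.out / "cohorts"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, preset in PRESETS.items():
        cfg = SimConfig(**{**preset.__dict__, "seed": args.seed})
        haps, vp, gt, truth = simulate_haplotypes(cfg)
        write_vcf(vp, outdir / f"{name}.vcf")
        write_panel(gt.panel, outdir / f"{name}.panel.tsv")
        write_genotype_table(gt, outdir / f"{name}.genotypes.tsv")
        truth.to_json(outdir / f"{name}.truth.json")
        print(f"{name}: {haps.n_haplotypes} haplotypes, {haps.n_sites} variants, "
              f"{len(truth.origin_events)} origin event(s)")


if __name__ == "__main__":
    main()
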