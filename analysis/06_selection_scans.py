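"""Selection scans on simulated scenarios, and regeneration of the stored
LSFS weight vectors.

Runs the Weir-Cockerham F_ST scan with a frequency-matched empirical null,
the LSFS linear tests (sweep-like and balancing-like weights) on neutral,
sweep and balancing scenarios, and the NCD1 balancing-selection scan.
``--regenerate-weights`` rebuilds src/invpopkit/data/lsfs_weights.json from
seeded simulations.
"""

import argparse
import json
import pathlib

import numpy as np
import pandas as pd

from invpopkit.core_io import InvpopkitError
from invpopkit.selection import (
    NCDResult,
    estimate_lsfs_weights,
    fst_empirical_pvalue,
    inversion_lsfs_windows,
    load_default_weights,
    lsfs_linear_test,
    ncd_empirical_pvalue,
    ncd_statistic,
    neutral_lsfs_windows,
    weir_cockerham_fst,
)
from invpopkit.synthdata import SimConfig, simulate_haplotypes


def regenerate_weights(seed: int) -> None:
    null_train = neutral_lsfs_windows(200, seed=seed)
    weights = {}
    for i, kind in enumerate(("balancing", "sweep")):
        alt = inversion_lsfs_windows(kind, 200, seed=seed + 1 + i)
        weights[kind] = estimate_lsfs_weights(null_train, alt).tolist()
    path = (pathlib.Path(__file__).resolve().parents[1]
            / "src" / "invpopkit" / "data" / "lsfs_weights.json")
    with open(path, "w") as fh:
        json.dump({
            "version": 1, "n_freq_classes": 10,
            "linkage_classes": ["nested", "disjoint"],
            "training": {"n_null": 200, "n_alt": 200,
                         "seeds": {"null": seed, "balancing": seed + 1,
                                   "sweep": seed + 2},
                         "window_bp": 3000, "n_samples": 30,
                         "mutation_rate": 1.5e-7},
            "weights": weights,
        }, fh, indent=1)
    print(f"rewrote {path}")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    ap.add_argument("--regenerate-weights", action="store_true")
    args = ap.parse_args()
    outdir = args.out / "selection"
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    if args.regenerate_weights:
        regenerate_weights(101)

    # --- F_ST with a frequency-matched empirical null
    def fst_of(ps, n=50):
        pops = [rng.binomial(2, p, n).astype(float).reshape(1, -1) for p in ps]
        return weir_cockerham_fst(pops)["global"]

    null_f, null_p = [], []
    for _ in range(3000):
        p = rng.uniform(0.05, 0.95)
        null_f.append(fst_of([p] * 4))
        null_p.append(p)
    shifted = fst_of([0.7, 0.3, 0.3, 0.3])
    res = fst_empirical_pvalue(shifted, 0.4, np.array(null_f), np.array(null_p),
                               bin_halfwidth=0.05, min_matches=200)
    print(f"locally adapted inversion: F_ST {shifted:.3f}, percentile "
          f"{res['percentile']:.3f}, class {res['signal']}")

    # --- LSFS linear tests
    bank = neutral_lsfs_windows(400, seed=args.seed + 10)
    rows = []
    for scenario in ("neutral", "sweep", "balancing"):
        if scenario == "neutral":
            windows = neutral_lsfs_windows(30, seed=args.seed + 20)
        else:
            windows = inversion_lsfs_windows(scenario, 30, seed=args.seed + 21)
        for kind in ("sweep", "balancing"):
            w = load_default_weights(kind)
            r = lsfs_linear_test(windows, bank, weights=w)
            rows.append({"scenario": scenario, "weights": kind,
                         "p_conservative": r["p_conservative"],
                         "p_approximate": r["p_approximate"]})
    lsfs = pd.DataFrame(rows)
    lsfs.to_csv(outdir / "lsfs.tsv", sep="\t", index=False)
    print(lsfs.to_string(index=False))

    # --- NCD1 scan: neutral bank, balancing-like target region
    def ncd_of(cfg_seed, origin, age=100_000):
        cfg = SimConfig(n_samples=25, sequence_length=2_000, span=(0, 2_000),
                        origin=origin, target_frequency=0.5,
                        age_generations=age, mutation_rate=3e-7,
                        seed=cfg_seed)
        haps, _, _, _ = simulate_haplotypes(cfg)
        f = haps.haplotypes.mean(axis=0)
        return ncd_statistic(np.minimum(f, 1 - f), 0.5)

    bank_vals = []
    while len(bank_vals) < 1000:
        try:
            bank_vals.append(ncd_of(int(rng.integers(1, 2**31 - 1)), "none"))
        except InvpopkitError:
            pass
    target = ncd_of(args.seed + 33, "unique")
    ncd_res = ncd_empirical_pvalue([NCDResult(target, 0.5, 8, 0)],
                                   np.asarray(bank_vals))
    print(f"ancient balanced polymorphism: NCD1 {target:.3f}, "
          f"p = {ncd_res['p_value']:.4f}")
    with open(outdir / "ncd.json", "w") as fh:
        json.dump({"ncd1": target, "p": ncd_res["p_value"],
                   "fst_class": res["signal"]}, fh, indent=1)


if __name__ == "__main__":
    main()
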