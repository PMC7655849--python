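"""Simulate the study panels: one hard-sweep replicate and one matched
neutral replicate under the standard two-population conditions.

Writes phased VCFs, population maps, outgroup calls and truth sidecars under
results/data/, and prints where the sweep truly is.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sweepscan.simulate import (simulate_outgroups, simulate_wright_fisher,
                                two_population_study_config, write_dataset)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 1) -> None:
    for label, sweep in (("sweep", True), ("neutral", False)):
        cfg = two_population_study_config(seed, sweep=sweep)
        ds = simulate_wright_fisher(cfg)
        simulate_outgroups(ds, concordance=0.95, seed=cfg.seed + 1)
        paths = write_dataset(ds, OUT / label)
        print(f"{label}: {ds.haplotypes.n_samples} samples x "
              f"{ds.haplotypes.n_markers} markers -> {paths['vcf']}")
        if sweep:
            t = ds.truth
            print(f"  selected site {t.selected_pos_bp:,} bp (s={t.s}), "
                  f"final frequency {t.final_freq['pop0']:.2f}, "
                  f"sweep interval {t.sweep_interval_bp[0]:,}-"
                  f"{t.sweep_interval_bp[1]:,} bp")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
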