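"""Apply the scan-path preprocessing to the simulated panels: MAF 0.05,
then ancestral-allele inference by outgroup majority (the simulator's truth
labels are discarded first, so polarization is genuinely re-inferred).

The PI-HAT relatedness screen and windowed LD pruning are part of the
package and are exercised on purpose-built pedigrees and LD blocks in the
test suite, but they are not applied here: in a simulated deme of N_e = 100
every sample pair shares recent ancestors and exceeds the local-population
threshold (the filter would gut the panel), and pruning by r^2 thins the
haplotype structure the EHH scans measure. Real cohorts, with effective
sizes in the thousands, are the setting those filters target.

Reads results/data/{sweep,neutral}/, writes filtered VCFs and a filter
report per panel.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sweepscan import io_formats, preprocess

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for label in ("sweep", "neutral"):
        src = ROOT / "data" / label
        matrix = io_formats.read_phased_vcf(src / "haplotypes.vcf")
        popmap = io_formats.read_population_map(src / "popmap.tsv")
        popmap.check_covers(matrix.sample_ids)
        matrix.pop_labels = [popmap.population_of(s)
                             for s in matrix.sample_ids]
        outgroups = io_formats.read_outgroup_alleles(src / "outgroups.tsv")

        reports = []
        matrix, rep = preprocess.maf_filter(matrix)
        reports.append(rep)
        # the simulator emits polarized data; redo inference from outgroups
        matrix.markers["ancestral_state"] = "unresolved"
        matrix, rep = preprocess.infer_ancestral(matrix, outgroups)
        reports.append(rep)

        out = ROOT / "filtered" / label
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_phased_vcf(matrix, out / "haplotypes.vcf")
        popmap.table.to_csv(out / "popmap.tsv", sep="\t", index=False)
        with open(out / "filter_report.json", "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=1)
        print(f"{label}: " + "; ".join(
            f"{r.stage}: {r.n_markers_in}->{r.n_markers_out} markers"
            for r in reports))


if __name__ == "__main__":
    main()
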