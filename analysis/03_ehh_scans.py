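"""Score iHS (within the focal group) and Rsb/XP-EHH (focal vs reference)
on the filtered panels and report how many markers clear -log10 p >= 3.

Writes per-marker score tracks under results/scores/ and, when matplotlib
is available, a Manhattan-style PNG per track.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sweepscan import ehh, io_formats, preprocess

ROOT = Path(__file__).resolve().parents[1] / "results"


def manhattan(track, path):
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, ax = plt.subplots(figsize=(9, 2.5))
    ax.scatter(track.table["pos_bp"] / 1e6, track.table["mlog10p"], s=4)
    ax.axhline(3.0, ls="--", c="crimson", lw=0.8)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{track.test} {track.contrast or ''}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    outdir = ROOT / "scores"
    outdir.mkdir(parents=True, exist_ok=True)
    for label in ("sweep", "neutral"):
        src = ROOT / "filtered" / label
        matrix = io_formats.read_phased_vcf(src / "haplotypes.vcf")
        popmap = io_formats.read_population_map(src / "popmap.tsv")
        matrix.pop_labels = [popmap.population_of(s)
                             for s in matrix.sample_ids]
        focal = preprocess.pool_haplotypes(matrix, popmap, "NorthAFT")
        reference = preprocess.pool_haplotypes(matrix, popmap, "EUT")
        ies_focal = ehh.ies_scan(focal)
        ies_ref = ehh.ies_scan(reference)
        tracks = [ehh.ihs_scan(focal),
                  ehh.rsb_scan(ies_ref, ies_focal, contrast="EUT"),
                  ehh.xpehh_scan(ies_ref, ies_focal, contrast="EUT")]
        for track in tracks:
            stem = f"{label}_{track.test.lower()}"
            io_formats.write_scores(track, outdir / f"{stem}.tsv")
            manhattan(track, outdir / f"{stem}.png")
            n_sig = int((track.table["mlog10p"] >= 3.0).sum())
            print(f"{label} {track.test:6s}: {len(track.table):4d} markers, "
                  f"{n_sig:3d} at -log10 p >= 3")


if __name__ == "__main__":
    main()
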