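"""Quality-filter the panel and summarize its diversity.

Applies the staged SNP filters (presence r=0.75, MAF >= 0.05, missingness
<= 20%), tallies transition/transversion classes, per-chromosome SNP density,
and the per-locus (MAF, PIC, gene diversity, observed het) and per-sample
(het %) statistics.  Writes the filtered VCF and stat tables to results/.
"""

from pathlib import Path

from radpop.diversity_stats import locus_stats, sample_stats
from radpop.genotype_io import read_vcf, write_vcf
from radpop.variant_filtering import maf_missing_filter, snp_density, ts_tv_counts

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_vcf(ROOT / "panel" / "panel.vcf")
    filtered, report = maf_missing_filter(gm, maf_min=0.05, miss_max=0.20)
    write_vcf(filtered, ROOT / "panel_filtered.vcf")
    print(
        f"filtering: {report.n_input} -> presence {report.n_after_presence} "
        f"-> MAF {report.n_after_maf} -> missingness {report.n_after_missingness}"
    )

    ts, tv = ts_tv_counts(filtered)
    ratio = ts / tv if tv else float("nan")
    print(f"Ts/Tv on filtered set: {ts}/{tv} = {ratio:.2f}")

    density = snp_density(filtered)
    density.to_csv(ROOT / "snp_density.tsv", sep="\t", index=False)
    mean_kb = density["mean_interdistance_kb"].mean()
    print(f"mean inter-SNP distance across chromosomes: {mean_kb:.2f} kb")

    ls = locus_stats(filtered)
    ss = sample_stats(filtered)
    ls.to_csv(ROOT / "locus_stats.tsv", sep="\t", index=False)
    ss.to_csv(ROOT / "sample_stats.tsv", sep="\t", index=False)
    print(
        f"locus stats: mean PIC {ls['pic'].mean():.3f} (max {ls['pic'].max():.3f}), "
        f"mean gene diversity {ls['gene_diversity'].mean():.3f}"
    )
    print(f"sample het: mean {ss['het_percent'].mean():.2f}%")


if __name__ == "__main__":
    main()
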