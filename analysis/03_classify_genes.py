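"""Classify pan-genome gene categories and compare per-individual counts.

Computes presence frequencies over the called cohort, assigns
core/softcore/shell/cloud categories, writes the category summary, and
compares the number of genes detected per individual between the wild,
native and improved classes with two-sided Mann-Whitney U tests.
"""

from itertools import combinations
from pathlib import Path

from pavkit import io_formats as iof
from pavkit import pangenome as pg

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "sim"


def main() -> None:
    matrix_path = RESULTS / "called_presence.tsv"
    if not matrix_path.exists():
        raise SystemExit("run analysis/02_call_presence.py first")
    matrix = iof.read_presence_matrix(matrix_path)
    popmap = iof.read_population_map(RESULTS / "population_map.tsv")

    freq = pg.presence_frequency(matrix)
    assignment = pg.classify_genes(freq)
    summary = pg.category_summary(assignment)
    freq.join(assignment).to_csv(RESULTS / "gene_categories.tsv", sep="\t")
    summary.to_csv(RESULTS / "category_summary.tsv", sep="\t", index=False)

    print("pan-genome gene categories:")
    for _, row in summary.iterrows():
        print(f"  {row['category']:<12} {row['count']:>6}  ({row['percent']:.2f}%)")

    counts = pg.per_individual_gene_count(matrix)
    counts.to_csv(RESULTS / "per_individual_gene_counts.tsv", sep="\t")
    print("\nper-individual detected-gene counts (mean by class):")
    by_class = {}
    for cls in ("wild", "native", "improved"):
        members = [i for i in popmap.members_of_class(cls) if i in counts.index]
        by_class[cls] = counts[members]
        print(f"  {cls:<9} n={len(members):<3} mean={by_class[cls].mean():.1f}")
    print("\nMann-Whitney U (two-sided):")
    for cls_a, cls_b in combinations(by_class, 2):
        u, p = pg.mann_whitney_u(by_class[cls_a], by_class[cls_b])
        print(f"  {cls_a} vs {cls_b}: U={u:.1f}, P={p:.4g}")


if __name__ == "__main__":
    main()
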