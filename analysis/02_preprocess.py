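#!/usr/bin/env python
"""Filter and normalize the simulated cohorts: CPM > 0.5 in >= 90% of
samples, annotation filter, length-corrected upper-quartile normalization,
log2(x + 1), then the pooled tumor-vs-normal |logFC| > 1 pre-filter.
Writes the normalized matrix, the fold-change table and a stage-by-stage
filter report under results/."""

from pathlib import Path

import pandas as pd

from cosig.io import attach_lengths, load_annotation, load_counts, load_sample_table
from cosig.preprocess import (
    compute_logfc,
    filter_by_annotation,
    filter_by_cpm,
    filter_by_logfc,
    normalize_uqua,
)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    cm = attach_lengths(load_counts(DATA / "counts.tsv"), load_annotation(DATA / "annotation.tsv"))
    meta = load_sample_table(DATA / "metadata.tsv")
    annot = load_annotation(DATA / "annotation.tsv")

    stages = {"input": cm.n_genes}
    cm = filter_by_cpm(cm)
    stages["after_cpm_filter"] = cm.n_genes
    cm = filter_by_annotation(cm, set(annot["gene_id"]))
    stages["after_annotation_filter"] = cm.n_genes
    expr = normalize_uqua(cm)
    fc = compute_logfc(expr, meta)
    candidates = filter_by_logfc(fc)
    stages["after_logfc_filter"] = len(candidates)

    expr.rename_axis("gene_id").to_csv(OUT / "normalized.tsv", sep="\t", float_format="%.10g")
    fc.rename_axis("gene_id").to_csv(OUT / "fold_change.tsv", sep="\t", float_format="%.10g")
    pd.Series(stages, name="genes").rename_axis("stage").to_csv(
        OUT / "filter_report.tsv", sep="\t"
    )

    for stage, n in stages.items():
        print(f"{stage}: {n} genes")
    up = (fc.loc[sorted(candidates), "direction"] == "up").sum()
    print(f"candidates: {len(candidates)} ({up} up, {len(candidates) - up} down)")


if __name__ == "__main__":
    main()
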