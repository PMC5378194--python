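#!/usr/bin/env python
"""Classify TSSs (g/i/a/n) and summarise 5' UTR architecture.

Assigns the non-exclusive gene/internal/antisense/non-coding categories,
computes per-gene 5' UTRs (leaderless below 10 nt), lists multi-TSS genes
and mutually antisense sRNA pairs, and compares the recovered UTR
distribution with the simulator's planted truth. Writes
results/tss_annotation.tsv and results/utr_stats.json.
"""

import json

from _common import get_result, outdir

from tss_atlas.tss_classify import (annotations_table, multi_tss_genes,
                                    pair_mutual_antisense, utr_stats)


def main():
    res = get_result()
    anns = res.annotations
    counts = {c: sum(c in a.categories for a in anns) for c in "gian"}
    print(f"classified {len(anns)} TSSs: "
          + ", ".join(f"{c}TSS={n}" for c, n in counts.items()))
    st = utr_stats(anns)
    print(f"5' UTRs: median {st['median']:.0f} nt, max {st['max']} nt, "
          f"{100 * st['leaderless_fraction']:.1f}% leaderless, "
          f"{100 * st['frac_gt_50']:.1f}% >50 nt, "
          f"{100 * st['frac_gt_150']:.1f}% >150 nt")
    multi = multi_tss_genes(anns)
    truth_multi = {u.covered_gene_ids[0] for u in res.sim.truth
                   if u.unit_id.endswith(".long")}
    print(f"multi-TSS genes: {len(multi)} recovered "
          f"(planted: {len(truth_multi)}, "
          f"exact match: {set(multi) == truth_multi})")
    pairs = pair_mutual_antisense(anns)
    print(f"mutually antisense sRNA pairs in shared IGRs: {len(pairs)}")
    annotations_table(anns).to_csv(outdir() / "tss_annotation.tsv",
                                   sep="\t", index=False)
    with open(outdir() / "utr_stats.json", "w") as fh:
        json.dump(st, fh, indent=2)


if __name__ == "__main__":
    main()
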