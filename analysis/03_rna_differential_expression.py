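#!/usr/bin/env python
"""Differential expression on the discovery cohort and signature scoring.

Runs the three contrasts (paired BL vs OT in CB, paired BL vs OT in N-CB,
CB vs N-CB at OT), intersects the DEG sets, and scores the resulting
signature (mean normalized expression at OT) in CB vs N-CB patients.
Outputs under results/rna/.
"""

import json
from pathlib import Path

import pandas as pd

from mmresp import rna

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort_dir = BASE / "cohort"
    out = BASE / "rna"
    out.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(cohort_dir / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(cohort_dir / "samples.tsv", sep="\t")
    disc = samples[samples["cohort"] == "discovery"]
    counts_disc = counts[disc["sample_id"]]

    filtered, report = rna.filter_genes(
        counts_disc, groups=disc.set_index("sample_id")["group"]
    )
    print(f"gene filter: {report}")
    expr = rna.normalized_log_expression(filtered)

    dea_cb = rna.paired_dea(expr, disc, group="CB")
    dea_ncb = rna.paired_dea(expr, disc, group="N-CB")
    dea_ot = rna.group_dea(expr, disc)
    for name, df in (("dea_cb", dea_cb), ("dea_ncb", dea_ncb), ("dea_ot", dea_ot)):
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    sets = {n: rna.deg_set(d) for n, d in
            (("cb", dea_cb), ("ncb", dea_ncb), ("ot", dea_ot))}
    venn = rna.intersect_deg_sets(sets["cb"], sets["ncb"], sets["ot"])
    print(
        f"DEGs: longitudinal CB {len(sets['cb'])}, longitudinal N-CB "
        f"{len(sets['ncb'])}, OT group {len(sets['ot'])}; signature set "
        f"{len(venn['signature_set'])} genes"
    )
    (out / "deg_intersections.json").write_text(
        json.dumps({"counts": venn["counts"],
                    "signature_set": sorted(venn["signature_set"])}, indent=1)
    )

    if venn["signature_set"]:
        scores, p = rna.signature_score(expr, disc, venn["signature_set"])
        scores.to_csv(out / "signature_scores.tsv", sep="\t", index=False)
        med = scores.groupby("group")["score"].median()
        print(
            f"signature score at OT: median CB {med.get('CB', float('nan')):.2f} vs "
            f"N-CB {med.get('N-CB', float('nan')):.2f}, rank-sum p = {p:.2e}"
        )


if __name__ == "__main__":
    main()
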