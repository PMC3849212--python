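#!/usr/bin/env python
"""Cluster diseases by their mouse age pattern (distance 1 - r, average
linkage) and report the k=2 partition; with the simulated panel the
younger-onset diseases separate from the older-onset ones."""

from pathlib import Path

import pandas as pd

from agemap import clustering, matrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    mouse = matrix.read_matrix(ROOT / "simulated" / "mouse_matrix_planted.tsv")
    dend = clustering.cluster_diseases(mouse, linkage="average")
    (ROOT / "tree.nwk").write_text(clustering.to_newick(dend))
    groups = clustering.cut_tree(dend, 2)
    pd.Series(groups, name="cluster").rename_axis("concept_id").to_csv(
        ROOT / "clusters.tsv", sep="\t"
    )
    print(f"{dend.n_leaves} diseases clustered ({dend.linkage_method} linkage)")
    for k in sorted(set(groups.values())):
        members = sorted(c for c, g in groups.items() if g == k)
        print(f"  cluster {k}: {', '.join(members)}")
    print(f"-> {ROOT / 'tree.nwk'}, {ROOT / 'clusters.tsv'}")


if __name__ == "__main__":
    main()
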