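#!/usr/bin/env python
"""Build the mouse age-disease matrix from the mined store (1-day bins,
0..1028 days), drop inferred ranges, filter to diseases with enough
instances, and normalize rows to frequencies."""

from pathlib import Path

from agemap import matrix, store

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ev = store.read_store(ROOT / "store")
    opts = matrix.MatrixBuildOptions(range_policy="midpoint", min_instances=5)
    counts = matrix.build_matrix(ev, "mouse", opts)
    norm = matrix.normalize(counts)
    matrix.write_matrix(norm, ROOT / "mouse_matrix_mined.tsv")
    totals = counts.data.sum(axis=1).astype(int)
    print(f"mouse matrix: {len(norm.diseases)} diseases x {norm.data.shape[1]} day bins")
    for cid, n in totals.items():
        print(f"  {cid}: {n} instances")
    print(f"-> {ROOT / 'mouse_matrix_mined.tsv'}")


if __name__ == "__main__":
    main()
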