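#!/usr/bin/env python
"""Generate the study inputs: a toy disease ontology, a template MEDLINE
corpus with gold annotations, and a human/mouse matrix pair with planted
disease-specific shifts (99, 90, 265, 264 days, plus one unrelated
disease).  All downstream steps read from results/simulated/."""

import json
from pathlib import Path

from agemap import matrix, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20130101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = synthetic.example_specs()

    (OUT / "ontology.obo").write_text(synthetic.generate_ontology(specs))
    text, gold = synthetic.generate_corpus(specs, n_distractors=30, seed=SEED, n_blocked=6)
    (OUT / "corpus.medline").write_text(text)
    (OUT / "gold.json").write_text(json.dumps([vars(g) for g in gold], indent=2))

    human, mouse, truth = synthetic.generate_matrix_pair(specs, noise_cv=0.0, seed=SEED)
    matrix.write_matrix(human, OUT / "human_matrix.tsv")
    matrix.write_matrix(mouse, OUT / "mouse_matrix_planted.tsv")
    truth.to_csv(OUT / "planted_shifts.tsv", sep="\t", index=False)

    n_pos = sum(g.is_age_related for g in gold)
    print(f"wrote {len(gold)} abstracts ({n_pos} age-related in gold), "
          f"{len(specs)} diseases, planted shifts "
          f"{sorted(truth['planted_shift_days'])} -> {OUT}")


if __name__ == "__main__":
    main()
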