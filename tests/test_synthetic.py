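"""Generators: determinism, gold consistency, planted-shift construction."""

import numpy as np
import pytest

from agemap import mining
from agemap.lexicon import build_lexicon
from agemap.mapper import best_shift
from agemap.synthetic import (
    AgeComponent,
    DiseaseSpec,
    example_specs,
    generate_corpus,
    generate_matrix_pair,
    generate_ontology,
)


def test_ontology_round_trips_through_lexicon(specs):
    lex = build_lexicon(generate_ontology(specs))
    for s in specs:
        assert lex.lookup(s.name) == s.concept_id
        for syn in s.synonyms:
            assert lex.lookup(syn) == s.concept_id
    n_surfaces = len({x.lower() for s in specs for x in [s.name] + s.synonyms})
    assert len(lex) == n_surfaces


def test_duplicate_concept_ids_rejected():
    spec = example_specs()[0]
    with pytest.raises(ValueError, match="duplicate"):
        generate_ontology([spec, spec])


def test_same_seed_same_corpus(specs):
    a, _ = generate_corpus(specs, n_distractors=10, seed=42)
    b, _ = generate_corpus(specs, n_distractors=10, seed=42)
    c, _ = generate_corpus(specs, n_distractors=10, seed=43)
    assert a == b
    assert a != c


def test_instance_counts_match_specs(clean_corpus, specs, synthetic_lexicon):
    corpus, gold = clean_corpus
    instances = mining.mine_corpus(corpus, synthetic_lexicon)
    assert len(instances) == sum(s.n_instances for s in specs)
    by_concept = {}
    for inst in instances:
        for p in inst.phenotypes:
            by_concept[p.concept_id] = by_concept.get(p.concept_id, 0) + 1
    for s in specs:
        assert by_concept[s.concept_id] == s.n_instances


def test_gold_matches_mined_ages_exactly(clean_corpus, synthetic_lexicon):
    corpus, gold = clean_corpus
    from agemap.synthetic import DEFAULT_STRAINS

    gold_by_pmid = {g.pmid: g for g in gold}
    for inst in mining.mine_corpus(corpus, synthetic_lexicon, DEFAULT_STRAINS):
        g = gold_by_pmid[inst.pmid]
        mined = {(a.start_days, a.end_days) for a in inst.ages}
        assert mined == set(g.ages)
        assert {p.concept_id for p in inst.phenotypes} == set(g.concept_ids)
        if g.gender is not None:
            assert inst.gender == g.gender
        if g.strain is not None:
            assert inst.strain == g.strain


def test_age_only_distractor_flagged_but_not_stored(mixed_corpus, synthetic_lexicon):
    corpus, gold = mixed_corpus
    instances = mining.mine_corpus(corpus, synthetic_lexicon)
    flags = mining.flag_age_related(corpus)
    stored = {i.pmid for i in instances}
    age_only = [g for g in gold if g.is_age_related and not g.concept_ids]
    assert age_only  # the mixed corpus contains them
    for g in age_only:
        assert g.pmid in flags
        assert g.pmid not in stored


def test_matrix_pair_same_seed_identical(specs):
    h1, m1, t1 = generate_matrix_pair(specs, noise_cv=0.3, seed=8)
    h2, m2, t2 = generate_matrix_pair(specs, noise_cv=0.3, seed=8)
    assert np.array_equal(h1.data.to_numpy(), h2.data.to_numpy())
    assert np.array_equal(m1.data.to_numpy(), m2.data.to_numpy())
    assert t1.equals(t2)


def test_matrix_pair_rows_are_normalized(specs):
    human, mouse, _ = generate_matrix_pair(specs, noise_cv=0.5, seed=8)
    assert np.allclose(human.data.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(mouse.data.sum(axis=1), 1.0, atol=1e-9)
    assert human.data.shape[1] == 121 and mouse.data.shape[1] == 1029


def test_noiseless_pair_gives_perfect_recovery_for_every_planted_shift():
    shifts = [0, 3, 99, 264, 500]
    specs = [
        DiseaseSpec(f"D:{s}", f"disease{s}", age_model=[AgeComponent(40.0, 10.0)],
                    planted_shift_days=s)
        for s in shifts
    ]
    human, mouse, _ = generate_matrix_pair(specs, noise_cv=0.0, seed=0)
    for s in shifts:
        got, r = best_shift(human.row(f"D:{s}"), mouse.row(f"D:{s}"))
        assert got == s
        assert r == pytest.approx(1.0)


def test_shift_beyond_axis_rejected():
    bad = DiseaseSpec("X:1", "x", planted_shift_days=2000)
    with pytest.raises(ValueError, match="axis"):
        generate_matrix_pair([bad], seed=0)
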