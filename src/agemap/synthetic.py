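"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a toy OBO disease
ontology, a MEDLINE-format abstract corpus built from sentence templates
with planted age phrases and disease mentions (plus distractors), and
paired human/mouse age-disease matrices with disease-specific planted
shifts and multiplicative noise.  All generators are pure functions of
(specs, parameters, seed).

Age models live on the human year index: a disease's pattern is a Gaussian
mixture over human ages 0..120 years, and its mouse pattern is the same
curve placed ``planted_shift_days`` bins later on the day axis (one human
year bin aligns with one mouse day bin).  Corpus ages are sampled in mouse
days at ``year-index + shift``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .matrix import AgeDiseaseMatrix, SPECIES_DEFAULTS


@dataclass
class AgeComponent:
    mean: float  # human-year-index units
    sd: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class DiseaseSpec:
    concept_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    age_model: list[AgeComponent] = field(default_factory=lambda: [AgeComponent(40.0, 10.0)])
    n_instances: int = 10
    planted_shift_days: int = 0
    related: bool = True  # False: mouse pattern independent of human pattern

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.age_model)
        if total <= 0:
            raise ValueError("age_model weights must sum to a positive value")
        for c in self.age_model:
            c.weight /= total
        if self.n_instances < 0:
            raise ValueError("n_instances must be >= 0")


@dataclass
class GoldAnnotation:
    """Ground truth for one generated abstract."""

    pmid: str
    is_age_related: bool
    ages: list[tuple[float, float]] = field(default_factory=list)
    concept_ids: list[str] = field(default_factory=list)
    gender: str | None = None
    strain: str | None = None


def example_specs() -> list[DiseaseSpec]:
    """A small default disease panel echoing the classic worked examples:
    shifts from a few days to several hundred, plus an unrelated disease."""
    return [
        DiseaseSpec("DOID:9351", "diabetes mellitus", ["DM"],
                    [AgeComponent(45.0, 12.0)], n_instances=12, planted_shift_days=99),
        DiseaseSpec("DOID:1240", "leukemia", ["leukaemia"],
                    [AgeComponent(25.0, 8.0)], n_instances=12, planted_shift_days=90),
        DiseaseSpec("DOID:2355", "anemia", ["anaemia"],
                    [AgeComponent(55.0, 15.0)], n_instances=12, planted_shift_days=265),
        DiseaseSpec("DOID:10652", "Alzheimer's disease", ["Alzheimer disease"],
                    [AgeComponent(75.0, 9.0)], n_instances=12, planted_shift_days=264),
        DiseaseSpec("DOID:0000000", "phantom syndrome", [],
                    [AgeComponent(35.0, 10.0)], n_instances=12, planted_shift_days=50,
                    related=False),
    ]


DEFAULT_STRAINS = ["C57BL/6", "BALB/c", "129S1/SvImJ", "DBA/2", "FVB/N"]


# ---------------------------------------------------------------------------
# ontology

def generate_ontology(specs: list[DiseaseSpec]) -> str:
    """Valid OBO 1.2 text with one non-obsolete [Term] per spec."""
    if not specs:
        raise ValueError("specs must be non-empty")
    ids = [s.concept_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate concept ids in specs")
    lines = ["format-version: 1.2", "ontology: synthetic-disease-ontology", ""]
    for s in specs:
        lines += ["[Term]", f"id: {s.concept_id}", f"name: {s.name}"]
        for syn in s.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# corpus

# Sentence frames are data, not code: each key sentence embeds one {age}
# phrase and (except distractors) one {disease} surface form.
KEY_FRAMES = [
    "In this study, {age} {strain} mice developed {disease}.",
    "We examined {gender} {strain} mice {age_aged} for signs of {disease}.",
    "{disease_cap} was induced in {strain} mice {age_at}.",
    "Histology revealed {disease} in {gender} mice {age_at}.",
    "{age_cap} {strain} mice showed early features of {disease}.",
    "Symptoms of {disease} appeared in mice {age_aged}.",
    "By {age_plain}, most {strain} mice had progressed to overt {disease}.",
    "Onset of {disease} occurred {age_at} in {gender} animals.",
    "Mice {age_aged} were screened weekly for {disease}.",
    "{disease_cap} incidence peaked in animals {age_at}.",
]

FILLER_SENTENCES = [
    "Tissue samples were collected and processed for further analysis.",
    "These findings extend previous observations in murine cohorts.",
    "Standard housing and chow were provided throughout the experiment.",
    "Statistical analysis employed nonparametric tests where appropriate.",
    "The experimental protocol was approved by the institutional committee.",
    "Body weight was recorded twice per week during the study.",
]

_UNIT_FACTORS = [("year", 365), ("month", 30), ("week", 7), ("day", 1)]


def _format_age(days: int, rng: np.random.Generator) -> tuple[dict[str, str], float, float]:
    """Render an integer day age as a grammar-covered phrase bundle.

    Returns ({age, age_aged, age_at, age_plain, age_cap}, start_days, end_days).
    """
    units = [(u, f) for u, f in _UNIT_FACTORS if days % f == 0 and days // f > 0]
    if not units:
        units = [("day", 1)]
    unit, factor = units[int(rng.integers(len(units)))]
    n = max(days // factor, 1)
    plural = unit + "s" if n != 1 else unit
    if rng.random() < 0.2:  # explicit range, symmetric around the target bin
        lo, hi = n, n + 2
        phrase = f"{lo} to {hi} {unit}s"
        start, end = lo * factor, hi * factor
        bundle = {
            "age": f"{lo}-{hi}-{unit}-old",
            "age_aged": f"aged {phrase}",
            "age_at": f"at {phrase} of age",
            "age_plain": f"the age of {phrase}",
            "age_cap": f"{lo}-{hi}-{unit}-old".capitalize(),
        }
    else:
        start = end = n * factor
        bundle = {
            "age": f"{n}-{unit}-old",
            "age_aged": f"aged {n} {plural}",
            "age_at": f"at {n} {plural} of age",
            "age_plain": f"the age of {n} {plural}",
            "age_cap": f"{n}-{unit}-old".capitalize(),
        }
    return bundle, float(start), float(end)


def _sample_mouse_age_days(spec: DiseaseSpec, rng: np.random.Generator) -> int:
    weights = [c.weight for c in spec.age_model]
    comp = spec.age_model[int(rng.choice(len(spec.age_model), p=weights))]
    mean = comp.mean + spec.planted_shift_days
    days = int(round(rng.normal(mean, comp.sd)))
    return int(np.clip(days, 1, SPECIES_DEFAULTS["mouse"]["n_bins"] - 1))


def _medline_record(pmid: str, title: str, body: str, year: int) -> str:
    return "\n".join(
        [f"PMID- {pmid}", f"TI  - {title}", f"AB  - {body}", f"DP  - {year} Jan",
         "PT  - Journal Article", ""]
    )


def generate_corpus(
    specs: list[DiseaseSpec],
    n_distractors: int = 0,
    seed: int = 0,
    n_blocked: int = 0,
) -> tuple[str, list[GoldAnnotation]]:
    """Template corpus in MEDLINE flat format plus exact gold annotations.

    Per spec, ``n_instances`` abstracts each carry one age phrase and one
    disease surface form in the same sentence.  Distractors cycle through
    age-only, disease-only and neither; ``n_blocked`` adds abstracts whose
    key sentence names rats (age + disease present, but excluded by the
    organism filter, so their gold carries no concept).
    """
    rng = np.random.default_rng(seed)
    records: list[str] = []
    gold: list[GoldAnnotation] = []
    pmid_counter = 10000001

    def next_pmid() -> str:
        nonlocal pmid_counter
        pmid_counter += 1
        return str(pmid_counter - 1)

    for spec in specs:
        surfaces = [spec.name] + list(spec.synonyms)
        for _ in range(spec.n_instances):
            pmid = next_pmid()
            days = _sample_mouse_age_days(spec, rng)
            bundle, start, end = _format_age(days, rng)
            frame = KEY_FRAMES[int(rng.integers(len(KEY_FRAMES)))]
            disease = surfaces[int(rng.integers(len(surfaces)))]
            strain = DEFAULT_STRAINS[int(rng.integers(len(DEFAULT_STRAINS)))]
            gender = ["male", "female"][int(rng.integers(2))]
            key = frame.format(
                disease=disease,
                disease_cap=disease[0].upper() + disease[1:],
                strain=strain,
                gender=gender,
                **bundle,
            )
            fillers = rng.choice(len(FILLER_SENTENCES), size=2, replace=False)
            body = " ".join([FILLER_SENTENCES[fillers[0]], key, FILLER_SENTENCES[fillers[1]]])
            year = int(rng.integers(2000, 2013))
            records.append(_medline_record(pmid, f"A study of {spec.name} in mice.", body, year))
            gold.append(
                GoldAnnotation(
                    pmid=pmid,
                    is_age_related=True,
                    ages=[(start, end)],
                    concept_ids=[spec.concept_id],
                    gender=gender if "{gender}" in frame else None,
                    strain=strain if "{strain}" in frame else None,
                )
            )

    all_surfaces = [s.name for s in specs]
    for i in range(n_distractors):
        pmid = next_pmid()
        kind = i % 3
        year = int(rng.integers(2000, 2013))
        if kind == 0:  # age, no disease
            days = int(rng.integers(7, 700))
            bundle, start, end = _format_age(days, rng)
            body = " ".join(
                [FILLER_SENTENCES[0], f"Healthy control mice {bundle['age_aged']} were observed.",
                 FILLER_SENTENCES[1]]
            )
            gold.append(GoldAnnotation(pmid, True, [(start, end)], []))
        elif kind == 1:  # disease, no age
            disease = all_surfaces[int(rng.integers(len(all_surfaces)))]
            body = " ".join(
                [FILLER_SENTENCES[2], f"A colony maintained for studies of {disease} was described.",
                 FILLER_SENTENCES[3]]
            )
            gold.append(GoldAnnotation(pmid, False, [], []))
        else:  # neither
            body = " ".join([FILLER_SENTENCES[4], FILLER_SENTENCES[5], FILLER_SENTENCES[0]])
            gold.append(GoldAnnotation(pmid, False, [], []))
        records.append(_medline_record(pmid, "A methodological note.", body, year))

    for i in range(n_blocked):
        pmid = next_pmid()
        spec = specs[i % len(specs)]
        days = _sample_mouse_age_days(spec, rng)
        bundle, start, end = _format_age(days, rng)
        body = " ".join(
            [FILLER_SENTENCES[1],
             f"In contrast, rats {bundle['age_aged']} also developed {spec.name}.",
             FILLER_SENTENCES[2]]
        )
        records.append(_medline_record(pmid, "A comparative note in rats.", body, 2010))
        gold.append(GoldAnnotation(pmid, True, [(start, end)], []))

    return "\n".join(records), gold


# ---------------------------------------------------------------------------
# matrix pairs

def _pattern_on_year_axis(spec: DiseaseSpec, n_bins: int) -> np.ndarray:
    y = np.arange(n_bins, dtype=float)
    pat = np.zeros(n_bins)
    for c in spec.age_model:
        pat += c.weight * np.exp(-0.5 * ((y - c.mean) / c.sd) ** 2) / c.sd
    return pat


def _multiplicative_noise(shape, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    k = 1.0 / cv**2  # gamma with mean 1, coefficient of variation cv
    return rng.gamma(k, 1.0 / k, size=shape)


def generate_matrix_pair(
    specs: list[DiseaseSpec], noise_cv: float = 0.0, seed: int = 0
) -> tuple[AgeDiseaseMatrix, AgeDiseaseMatrix, pd.DataFrame]:
    """Paired normalized human/mouse matrices with planted shifts.

    The human row is the spec's mixture density on the year axis; the
    mouse row is the same curve shifted by ``planted_shift_days`` on the
    day axis (rows of ``related=False`` specs get an independent random
    pattern instead).  Independent per-cell multiplicative noise with the
    given coefficient of variation is applied before row normalization.
    """
    rng = np.random.default_rng(seed)
    n_h = SPECIES_DEFAULTS["human"]["n_bins"]
    n_m = SPECIES_DEFAULTS["mouse"]["n_bins"]
    human_rows, mouse_rows, truth = {}, {}, []
    for spec in specs:
        if spec.planted_shift_days > n_m - 1:
            raise ValueError(f"{spec.concept_id}: planted shift exceeds the mouse axis")
        h = _pattern_on_year_axis(spec, n_h)
        m = np.zeros(n_m)
        if spec.related:
            w = min(n_h, n_m - spec.planted_shift_days)
            m[spec.planted_shift_days : spec.planted_shift_days + w] = h[:w]
        else:
            m = rng.random(n_m)
        h = h * _multiplicative_noise(n_h, noise_cv, rng)
        m = m * _multiplicative_noise(n_m, noise_cv, rng)
        human_rows[spec.concept_id] = h
        mouse_rows[spec.concept_id] = m
        truth.append(
            {"concept_id": spec.concept_id, "planted_shift_days": spec.planted_shift_days,
             "related": spec.related}
        )

    def _norm(rows: dict[str, np.ndarray], species: str, res: float) -> AgeDiseaseMatrix:
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = range(df.shape[1])
        df = df.div(df.sum(axis=1), axis=0)
        return AgeDiseaseMatrix(species, res, df, normalized=True,
                                meta={"synthetic": True, "noise_cv": noise_cv, "seed": seed})

    human = _norm(human_rows, "human", 365.0)
    mouse = _norm(mouse_rows, "mouse", 1.0)
    return human, mouse, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# spec I/O

def load_specs(path) -> list[DiseaseSpec]:
    """Read a YAML/JSON list of disease specs (documented in docs/methods.md)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for d in raw:
        comps = [AgeComponent(**c) for c in d.get("age_model", [{"mean": 40.0, "sd": 10.0}])]
        specs.append(
            DiseaseSpec(
                concept_id=d["concept_id"],
                name=d["name"],
                synonyms=list(d.get("synonyms", [])),
                age_model=comps,
                n_instances=int(d.get("n_instances", 10)),
                planted_shift_days=int(d.get("planted_shift_days", 0)),
                related=bool(d.get("related", True)),
            )
        )
    return specs
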