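"""Mining age-disease evidence from abstracts.

The pipeline has three stages: (1) find age-related abstracts with a
regular-expression grammar over age phrases and normalize every mention to
days, (2) cut a snippet of at most three sentences around each age-bearing
sentence, and (3) map the snippet to disease concepts by case-insensitive,
token-boundary, longest-match dictionary lookup, also picking up mouse
strain and gender.  Snippets that mention a non-mouse organism, or that
yield no phenotype, produce no evidence instance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import Medline

from .lexicon import DiseaseLexicon

logger = logging.getLogger(__name__)

#: days per age unit (1-day resolution throughout)
UNIT_DAYS = {"day": 1.0, "week": 7.0, "month": 30.0, "year": 365.0}

#: organisms whose snippets are discarded (the corpus is mouse literature)
DEFAULT_ORGANISM_BLOCKLIST = (
    "rat", "rats", "human", "humans", "patient", "patients", "zebrafish", "drosophila",
)


@dataclass
class AbstractRecord:
    pmid: str
    title: str
    body: str
    year: int | None = None
    pub_types: list[str] = field(default_factory=list)


@dataclass
class AgeMention:
    """An age expression normalized to days.

    ``inferred`` marks open-ended relational expressions ("under age 30",
    "over 22 weeks"), which are kept as evidence but excluded from the
    quantitative matrices.  For "under N" the range is [0, N]; for "over N"
    both bounds sit at N (the upper bound is unknown).
    """

    surface: str
    start_days: float
    end_days: float
    unit: str
    inferred: bool
    char_span: tuple[int, int]


@dataclass
class PhenotypeMatch:
    concept_id: str
    surface: str
    source: str
    char_span: tuple[int, int]


@dataclass
class EvidenceInstance:
    pmid: str
    snippet: str
    ages: list[AgeMention]
    phenotypes: list[PhenotypeMatch]
    strain: str | None = None
    gender: str | None = None
    year: int | None = None
    pub_type: str | None = None


# ---------------------------------------------------------------------------
# age grammar

_NUM = r"\d+(?:\.\d+)?"
_SEP = r"\s*(?:-|–|—|to)\s*"
_UNIT = r"(?P<unit>day|week|month|year)s?"
_REL_LOW = r"under|below|less\s+than|younger\s+than"
_REL_HIGH = r"over|above|more\s+than|older\s+than"
_REL = rf"(?:{_REL_LOW}|{_REL_HIGH})"

_AGE_PATTERNS = [
    # "under 4 weeks of age", "over the age of 22 months"
    re.compile(
        rf"(?P<rel>{_REL})\s+(?:the\s+age\s+of\s+)?(?P<a>{_NUM})[\s-]*{_UNIT}"
        rf"(?:\s+of\s+age|[\s-]*old)?",
        re.IGNORECASE,
    ),
    # "under age 30", "over age 22 years"
    re.compile(
        rf"(?P<rel>{_REL})\s+age\s+(?P<a>{_NUM})(?:[\s-]*{_UNIT})?",
        re.IGNORECASE,
    ),
    # "6-week-old", "12 to 15 month old"
    re.compile(
        rf"(?P<a>{_NUM})(?:{_SEP}(?P<b>{_NUM}))?[\s-]*{_UNIT}[\s-]*old",
        re.IGNORECASE,
    ),
    # "aged 6 weeks", "aged 12-15 months"
    re.compile(
        rf"aged\s+(?P<a>{_NUM})(?:{_SEP}(?P<b>{_NUM}))?\s*{_UNIT}",
        re.IGNORECASE,
    ),
    # "6 weeks of age", "12-15 months of age"
    re.compile(
        rf"(?P<a>{_NUM})(?:{_SEP}(?P<b>{_NUM}))?\s*{_UNIT}\s+of\s+age",
        re.IGNORECASE,
    ),
    # "the age of 12-15 months"
    re.compile(
        rf"age\s+of\s+(?P<a>{_NUM})(?:{_SEP}(?P<b>{_NUM}))?\s*{_UNIT}",
        re.IGNORECASE,
    ),
    # "at age 30", "at age 6 weeks"
    re.compile(
        rf"at\s+age\s+(?P<a>{_NUM})(?:{_SEP}(?P<b>{_NUM}))?(?:\s*{_UNIT})?",
        re.IGNORECASE,
    ),
]

_REL_LOW_RE = re.compile(rf"^(?:{_REL_LOW})", re.IGNORECASE)


def detect_age_mentions(body: str, default_unit: str = "day") -> list[AgeMention]:
    """Find all age expressions in ``body``, normalized to days.

    Overlapping matches are resolved longest-first; each returned mention
    carries its verbatim surface text and character span.  Expressions
    without an explicit unit ("under age 30") use ``default_unit``.
    """
    raw: list[tuple[int, int, re.Match]] = []
    for pat in _AGE_PATTERNS:
        for m in pat.finditer(body):
            raw.append((m.start(), m.end(), m))
    # longest-match-wins across overlapping candidates
    raw.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    kept: list[tuple[int, int, re.Match]] = []
    for s, e, m in raw:
        if any(s < ke and ks < e for ks, ke, _ in kept):
            continue
        kept.append((s, e, m))
    kept.sort(key=lambda t: t[0])

    mentions = []
    for s, e, m in kept:
        groups = m.groupdict()
        unit = (groups.get("unit") or default_unit).lower()
        factor = UNIT_DAYS[unit]
        a = float(groups["a"]) * factor
        rel = groups.get("rel")
        if rel is not None:
            if _REL_LOW_RE.match(rel):
                start_days, end_days = 0.0, a
            else:
                start_days, end_days = a, a
            inferred = True
        else:
            b = groups.get("b")
            end_days = float(b) * factor if b is not None else a
            start_days = a
            inferred = False
        if start_days > end_days:  # reversed range like "15-12 months": skip
            continue
        mentions.append(
            AgeMention(
                surface=body[s:e],
                start_days=start_days,
                end_days=end_days,
                unit=unit,
                inferred=inferred,
                char_span=(s, e),
            )
        )
    return mentions


# ---------------------------------------------------------------------------
# sentence segmentation & snippets

_ABBREVIATIONS = {"e.g", "i.e", "vs", "fig", "figs", "et al", "al", "ca", "cf", "approx", "resp"}
_BOUNDARY_RE = re.compile(r"[.?!]+(\s+)(?=[A-Z0-9(\"'])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Deterministic sentence spans: split on [.?!] + space + capital/digit,
    skipping a small abbreviation stoplist."""
    spans = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        before = text[: m.start() + 1]
        last = before.rstrip(".?!").split()
        if last and last[-1].lower().strip("().,;") in _ABBREVIATIONS:
            continue
        spans.append((start, m.start() + len(m.group(0)) - len(m.group(1))))
        start = m.end(1) + (m.end() - m.end(1))
    if start < len(text) and text[start:].strip():
        spans.append((start, len(text)))
    return spans


def extract_snippet(record: AbstractRecord, mention: AgeMention) -> str:
    """The sentence containing ``mention`` plus one neighbour on each side."""
    s, e = mention.char_span
    if not (0 <= s < e <= len(record.body)):
        raise ValueError(f"mention span {mention.char_span} outside abstract {record.pmid}")
    spans = split_sentences(record.body)
    idx = next((i for i, (a, b) in enumerate(spans) if a <= s < b), None)
    if idx is None:
        raise ValueError(f"mention span {mention.char_span} not inside a sentence")
    lo = max(0, idx - 1)
    hi = min(len(spans) - 1, idx + 1)
    return record.body[spans[lo][0] : spans[hi][1]].strip()


# ---------------------------------------------------------------------------
# dictionary matching

def _term_regex(term: str) -> re.Pattern:
    # token boundaries that tolerate terms ending in non-word characters
    return re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(term) + r"(?![A-Za-z0-9])", re.IGNORECASE
    )


def match_phenotypes(snippet: str, lexicon: DiseaseLexicon) -> list[PhenotypeMatch]:
    """Longest-match-wins dictionary matching; one match per concept."""
    covered = [False] * len(snippet)
    hits: list[PhenotypeMatch] = []
    for surface in sorted(lexicon.entries, key=len, reverse=True):
        cid = lexicon.entries[surface]
        for m in _term_regex(surface).finditer(snippet):
            if any(covered[m.start() : m.end()]):
                continue  # a longer term already claimed this text
            for i in range(m.start(), m.end()):
                covered[i] = True
            hits.append(
                PhenotypeMatch(
                    concept_id=cid,
                    surface=m.group(0),
                    source=lexicon.sources.get(cid, "disease_ontology"),
                    char_span=(m.start(), m.end()),
                )
            )
    # collapse duplicate concepts, keep earliest occurrence
    hits.sort(key=lambda h: h.char_span)
    seen: set[str] = set()
    out = []
    for h in hits:
        if h.concept_id in seen:
            continue
        seen.add(h.concept_id)
        out.append(h)
    return out


_MALE_RE = re.compile(r"(?<![A-Za-z])males?(?![A-Za-z])", re.IGNORECASE)
_FEMALE_RE = re.compile(r"(?<![A-Za-z])females?(?![A-Za-z])", re.IGNORECASE)


def assign_gender(snippet: str) -> str | None:
    """Gender only when exactly one gender-term class occurs in the snippet."""
    has_female = bool(_FEMALE_RE.search(snippet))
    has_male = bool(_MALE_RE.search(snippet))
    if has_male and not has_female:
        return "male"
    if has_female and not has_male:
        return "female"
    return None


def assign_strain(snippet: str, strain_list: list[str]) -> str | None:
    """First (leftmost, then longest) strain-name occurrence, or None."""
    best: tuple[int, int] | None = None
    best_name = None
    for name in strain_list:
        m = _term_regex(name).search(snippet)
        if m is None:
            continue
        key = (m.start(), -len(name))
        if best is None or key < best:
            best = key
            best_name = name
    return best_name


# ---------------------------------------------------------------------------
# corpus mining

def mine_corpus(
    corpus: list[AbstractRecord],
    lexicon: DiseaseLexicon,
    strain_list: list[str] | None = None,
    organism_blocklist: tuple[str, ...] | list[str] = DEFAULT_ORGANISM_BLOCKLIST,
    stats: dict | None = None,
) -> list[EvidenceInstance]:
    """Run the full pipeline over a corpus.

    One candidate instance is produced per (abstract, age-bearing sentence)
    pair; candidates missing a phenotype or whose snippet names a blocklisted
    organism are dropped.  Stage counts are logged and, if ``stats`` is
    given, recorded there.
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon: nothing to match phenotypes against")
    strain_list = strain_list or []
    blocklist_res = [_term_regex(t) for t in organism_blocklist]

    n_age_related = 0
    n_candidates = 0
    n_blocked = 0
    instances: list[EvidenceInstance] = []
    for rec in corpus:
        mentions = detect_age_mentions(rec.body)
        if not mentions:
            continue
        n_age_related += 1
        spans = split_sentences(rec.body)
        by_sentence: dict[int, list[AgeMention]] = {}
        for men in mentions:
            idx = next(i for i, (a, b) in enumerate(spans) if a <= men.char_span[0] < b)
            by_sentence.setdefault(idx, []).append(men)
        for idx in sorted(by_sentence):
            n_candidates += 1
            snippet = extract_snippet(rec, by_sentence[idx][0])
            if any(r.search(snippet) for r in blocklist_res):
                n_blocked += 1
                continue
            phenos = match_phenotypes(snippet, lexicon)
            if not phenos:
                continue
            instances.append(
                EvidenceInstance(
                    pmid=rec.pmid,
                    snippet=snippet,
                    ages=by_sentence[idx],
                    phenotypes=phenos,
                    strain=assign_strain(snippet, strain_list),
                    gender=assign_gender(snippet),
                    year=rec.year,
                    pub_type=rec.pub_types[0] if rec.pub_types else None,
                )
            )
    counts = {
        "abstracts_in": len(corpus),
        "age_related_abstracts": n_age_related,
        "candidate_snippets": n_candidates,
        "blocked_organism": n_blocked,
        "instances_stored": len(instances),
    }
    logger.info("mine_corpus: %s", counts)
    if stats is not None:
        stats.update(counts)
    return instances


# ---------------------------------------------------------------------------
# evaluation against gold annotations

@dataclass
class EvaluationResult:
    """Confusion counts with sensitivity/specificity/precision.

    A rate whose denominator is zero is reported as None (not applicable).
    """

    true_pos: int
    false_pos: int
    true_neg: int
    false_neg: int

    @property
    def sensitivity(self) -> float | None:
        d = self.true_pos + self.false_neg
        return self.true_pos / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.true_neg + self.false_pos
        return self.true_neg / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.true_pos + self.false_pos
        return self.true_pos / d if d else None


def flag_age_related(corpus: list[AbstractRecord]) -> set[str]:
    """PMIDs of abstracts the age grammar flags as age-related (stage 1)."""
    return {rec.pmid for rec in corpus if detect_age_mentions(rec.body)}


def evaluate_mining(
    instances: list[EvidenceInstance], gold, age_related_pmids: set[str] | None = None
) -> dict[str, EvaluationResult]:
    """Score mined output against gold annotations for two tasks.

    ``gold`` is a list of annotations with attributes ``pmid``,
    ``is_age_related`` and ``concept_ids`` (the synthetic generator's
    ground truth, or a human reader's).  ``age_related_pmids`` are the
    stage-1 flags (see :func:`flag_age_related`); when omitted they are
    derived from the instances, which under-counts abstracts whose age
    mention yielded no phenotype.  Returns results keyed by
    ``age_flagging`` (abstract-level) and ``phenotype_mapping``
    ((abstract, concept)-level over the gold concept universe).
    """
    gold_by_pmid = {g.pmid: g for g in gold}
    extra = sorted({i.pmid for i in instances} - set(gold_by_pmid))
    if extra:
        raise ValueError(f"predicted pmids absent from gold set: {extra}")

    pred_age = age_related_pmids if age_related_pmids is not None else {i.pmid for i in instances}
    tp = sum(1 for g in gold if g.is_age_related and g.pmid in pred_age)
    fn = sum(1 for g in gold if g.is_age_related and g.pmid not in pred_age)
    fp = sum(1 for g in gold if not g.is_age_related and g.pmid in pred_age)
    tn = sum(1 for g in gold if not g.is_age_related and g.pmid not in pred_age)
    age_res = EvaluationResult(tp, fp, tn, fn)

    universe = sorted({c for g in gold for c in g.concept_ids})
    pred_pairs: dict[str, set[str]] = {}
    for inst in instances:
        pred_pairs.setdefault(inst.pmid, set()).update(p.concept_id for p in inst.phenotypes)
    ptp = pfp = ptn = pfn = 0
    for g in gold:
        predicted = pred_pairs.get(g.pmid, set())
        expected = set(g.concept_ids)
        for c in universe:
            if c in expected and c in predicted:
                ptp += 1
            elif c in expected:
                pfn += 1
            elif c in predicted:
                pfp += 1
            else:
                ptn += 1
    # predicted concepts outside the gold universe are false positives too
    for pmid, predicted in pred_pairs.items():
        pfp += len(predicted - set(universe))
    pheno_res = EvaluationResult(ptp, pfp, ptn, pfn)
    return {"age_flagging": age_res, "phenotype_mapping": pheno_res}


# ---------------------------------------------------------------------------
# MEDLINE input

def read_medline(path) -> list[AbstractRecord]:
    """Read abstracts from a MEDLINE flat file (PMID/TI/AB/DP/PT fields)."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID")
            body = rec.get("AB", "")
            if not pmid or not body:
                continue
            year = None
            dp = rec.get("DP", "")
            m = re.match(r"(\d{4})", dp)
            if m:
                year = int(m.group(1))
            records.append(
                AbstractRecord(
                    pmid=pmid,
                    title=rec.get("TI", ""),
                    body=body,
                    year=year,
                    pub_types=list(rec.get("PT", [])),
                )
            )
    return records


def read_lines(path) -> list[str]:
    """One term per line; blank and '#' lines skipped."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
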