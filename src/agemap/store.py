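"""Three-table evidence store.

Mined evidence is persisted as three TSV tables mirroring the knowledgebase
schema: an *evidence* table (snippet and its descriptors), an *evidence-age*
table (one row per age mention) and an *evidence-phenotype* table (one row
per linked concept).  Referential integrity is checked on both write and
read, and the store answers the three query types of the data browser:
by age, by phenotype, and by both, with conjunctive refinements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mining import AgeMention, EvidenceInstance, PhenotypeMatch

EVIDENCE_FILE = "evidence.tsv"
AGE_FILE = "evidence_age.tsv"
PHENOTYPE_FILE = "evidence_phenotype.tsv"

_EVIDENCE_COLS = ["evidence_id", "pmid", "snippet", "strain", "gender", "year", "pub_type"]
_AGE_COLS = ["evidence_id", "start_days", "end_days", "inferred"]
_PHENO_COLS = ["evidence_id", "concept_id", "source"]


@dataclass
class EvidenceStore:
    """In-memory view of the three tables (pandas DataFrames)."""

    evidence: pd.DataFrame
    ages: pd.DataFrame
    phenotypes: pd.DataFrame
    concept_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = set(self.evidence["evidence_id"])
        if len(ids) != len(self.evidence):
            raise ValueError("duplicate evidence_id in evidence table")
        for name, table in (("age", self.ages), ("phenotype", self.phenotypes)):
            orphans = set(table["evidence_id"]) - ids
            if orphans:
                raise ValueError(f"{name} rows reference unknown evidence_ids: {sorted(orphans)}")

    def __len__(self) -> int:
        return len(self.evidence)


def _instances_to_tables(instances: list[EvidenceInstance]) -> EvidenceStore:
    ev_rows, age_rows, ph_rows = [], [], []
    for i, inst in enumerate(instances):
        eid = f"E{i:06d}"
        ev_rows.append(
            {
                "evidence_id": eid,
                "pmid": inst.pmid,
                "snippet": inst.snippet.replace("\t", " ").replace("\n", " "),
                "strain": inst.strain or "",
                "gender": inst.gender or "",
                "year": inst.year if inst.year is not None else "",
                "pub_type": inst.pub_type or "",
            }
        )
        for a in inst.ages:
            age_rows.append(
                {
                    "evidence_id": eid,
                    "start_days": float(a.start_days),
                    "end_days": float(a.end_days),
                    "inferred": int(a.inferred),
                }
            )
        for p in inst.phenotypes:
            ph_rows.append({"evidence_id": eid, "concept_id": p.concept_id, "source": p.source})
    return EvidenceStore(
        evidence=pd.DataFrame(ev_rows, columns=_EVIDENCE_COLS),
        ages=pd.DataFrame(age_rows, columns=_AGE_COLS),
        phenotypes=pd.DataFrame(ph_rows, columns=_PHENO_COLS),
    )


def write_store(instances: list[EvidenceInstance], path) -> EvidenceStore:
    """Write the three TSV tables under directory ``path``; returns the store."""
    store = _instances_to_tables(instances)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    store.evidence.to_csv(path / EVIDENCE_FILE, sep="\t", index=False)
    store.ages.to_csv(path / AGE_FILE, sep="\t", index=False)
    store.phenotypes.to_csv(path / PHENOTYPE_FILE, sep="\t", index=False)
    return store


def read_store(path) -> EvidenceStore:
    """Read a store directory back into DataFrames (integrity-checked)."""
    path = Path(path)
    evidence = pd.read_csv(path / EVIDENCE_FILE, sep="\t", dtype={"pmid": str}, keep_default_na=False)
    ages = pd.read_csv(path / AGE_FILE, sep="\t")
    phenotypes = pd.read_csv(path / PHENOTYPE_FILE, sep="\t", keep_default_na=False)
    if evidence.empty:
        evidence = pd.DataFrame(columns=_EVIDENCE_COLS)
        ages = pd.DataFrame(columns=_AGE_COLS)
        phenotypes = pd.DataFrame(columns=_PHENO_COLS)
    return EvidenceStore(evidence=evidence, ages=ages, phenotypes=phenotypes)


def store_to_instances(store: EvidenceStore) -> list[EvidenceInstance]:
    """Reassemble EvidenceInstance objects from the tables."""
    ages_by_id: dict[str, list[AgeMention]] = {}
    for row in store.ages.itertuples():
        ages_by_id.setdefault(row.evidence_id, []).append(
            AgeMention(
                surface="",
                start_days=float(row.start_days),
                end_days=float(row.end_days),
                unit="day",
                inferred=bool(row.inferred),
                char_span=(0, 0),
            )
        )
    phenos_by_id: dict[str, list[PhenotypeMatch]] = {}
    for row in store.phenotypes.itertuples():
        phenos_by_id.setdefault(row.evidence_id, []).append(
            PhenotypeMatch(concept_id=row.concept_id, surface="", source=row.source, char_span=(0, 0))
        )
    out = []
    for row in store.evidence.itertuples():
        out.append(
            EvidenceInstance(
                pmid=str(row.pmid),
                snippet=row.snippet,
                ages=ages_by_id.get(row.evidence_id, []),
                phenotypes=phenos_by_id.get(row.evidence_id, []),
                strain=row.strain or None,
                gender=row.gender or None,
                year=int(row.year) if str(row.year) not in ("", "nan") else None,
                pub_type=row.pub_type or None,
            )
        )
    return out


def query(
    store: EvidenceStore,
    age_range: tuple[float, float] | None = None,
    phenotype: str | None = None,
    year_range: tuple[int | None, int | None] | None = None,
    pub_type: str | None = None,
    lexicon=None,
) -> pd.DataFrame:
    """Select evidence rows by age interval and/or phenotype, refined.

    Age intervals are closed in days; a point age is a 1-day interval, so a
    query range overlaps an evidence range when ``start <= q_max`` and
    ``end >= q_min``.  ``phenotype`` may be a concept id, or a name/synonym
    when a lexicon is supplied.  Refinements are conjunctive.
    """
    if age_range is None and phenotype is None:
        raise ValueError("give at least one of age_range or phenotype")
    keep = set(store.evidence["evidence_id"])
    if age_range is not None:
        lo, hi = age_range
        a = store.ages
        hit = a[(a["start_days"] <= hi) & (a["end_days"] >= lo)]
        keep &= set(hit["evidence_id"])
    if phenotype is not None:
        cid = phenotype
        known = set(store.phenotypes["concept_id"])
        if cid not in known:
            if lexicon is not None:
                cid = lexicon.resolve(phenotype)
            else:
                import difflib

                near = difflib.get_close_matches(phenotype, sorted(known), n=3)
                raise KeyError(f"unknown phenotype {phenotype!r}; nearest: {near}")
        hit = store.phenotypes[store.phenotypes["concept_id"] == cid]
        keep &= set(hit["evidence_id"])
    result = store.evidence[store.evidence["evidence_id"].isin(keep)].copy()
    if year_range is not None:
        lo, hi = year_range
        years = pd.to_numeric(result["year"], errors="coerce")
        if lo is not None:
            result = result[years >= lo]
            years = years[years >= lo]
        if hi is not None:
            result = result[years <= hi]
    if pub_type is not None:
        result = result[result["pub_type"] == pub_type]
    return result.reset_index(drop=True)
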