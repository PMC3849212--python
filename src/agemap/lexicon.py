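"""Disease lexicon: surface form -> concept id dictionaries.

The lexicon is compiled from an OBO 1.2 ontology (term names and exact
synonyms of every non-obsolete term) plus an optional plain concept/synonym
term list standing in for a restricted meta-vocabulary subset.  All lookup
is case-insensitive; each surface form maps to exactly one concept, with
cross-concept collisions resolved in favour of the first concept seen in
file order (and logged).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)

_SYNONYM_RE = re.compile(r'synonym:\s*"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]*)')


class OboParseError(ValueError):
    """Raised when a [Term] stanza cannot be parsed; names the stanza."""


@dataclass
class DiseaseLexicon:
    """Dictionary of normalized surface forms for disease concepts.

    Attributes
    ----------
    entries:
        Map from lower-cased surface form to concept id.
    concept_names:
        Map from concept id to its preferred name.
    sources:
        Map from concept id to the source label (``disease_ontology`` or
        ``term_list``).
    """

    entries: dict[str, str] = field(default_factory=dict)
    concept_names: dict[str, str] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> str | None:
        return self.entries.get(surface.strip().lower())

    def resolve(self, key: str) -> str:
        """Resolve a concept id or a name/synonym to a concept id.

        Raises ``KeyError`` with nearest-name suggestions when unknown.
        """
        if key in self.concept_names:
            return key
        hit = self.lookup(key)
        if hit is not None:
            return hit
        import difflib

        candidates = list(self.entries) + list(self.concept_names.values())
        near = difflib.get_close_matches(key.lower(), candidates, n=3)
        raise KeyError(f"unknown phenotype {key!r}; nearest names: {near}")

    def add(self, surface: str, concept_id: str, name: str | None, source: str) -> None:
        norm = surface.strip().lower()
        if not norm:
            return
        prior = self.entries.get(norm)
        if prior is not None and prior != concept_id:
            logger.warning(
                "synonym collision: %r maps to %s, ignoring later %s", norm, prior, concept_id
            )
            return
        self.entries[norm] = concept_id
        if concept_id not in self.concept_names:
            self.concept_names[concept_id] = name if name is not None else concept_id
            self.sources[concept_id] = source


def _parse_obo_stanzas(text: str) -> Iterable[dict]:
    """Yield [Term] stanzas as dicts of tag -> list of values."""
    stanza: dict | None = None
    in_term = False
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].rstrip() if not raw.lstrip().startswith("!") else ""
        line = line.strip()
        if line.startswith("["):
            if stanza is not None:
                yield stanza
            in_term = line == "[Term]"
            stanza = {} if in_term else None
            continue
        if not in_term or not line:
            continue
        if ":" not in line:
            ident = stanza.get("id", ["<no id>"])[0] if stanza else "<no id>"
            raise OboParseError(f"malformed line {line!r} in [Term] stanza {ident}")
        tag, value = line.split(":", 1)
        stanza.setdefault(tag.strip(), []).append(value.strip())
    if stanza is not None:
        yield stanza


def build_lexicon(
    obo_document: str,
    extra_terms: Iterable[tuple[str, str]] | None = None,
) -> DiseaseLexicon:
    """Compile a :class:`DiseaseLexicon` from OBO text plus extra terms.

    Parameters
    ----------
    obo_document:
        OBO 1.2 flat-file content.  Every non-obsolete ``[Term]`` contributes
        its name and all synonyms, lower-cased.
    extra_terms:
        Optional iterable of ``(concept_id, surface_form)`` pairs appended
        with source ``term_list``.
    """
    lex = DiseaseLexicon()
    for stanza in _parse_obo_stanzas(obo_document):
        ids = stanza.get("id", [])
        if len(ids) != 1:
            raise OboParseError(f"[Term] stanza without a single id: {stanza}")
        cid = ids[0]
        if stanza.get("is_obsolete", ["false"])[0].lower() == "true":
            continue
        names = stanza.get("name", [])
        if not names:
            raise OboParseError(f"[Term] stanza {cid} has no name")
        lex.add(names[0], cid, names[0], "disease_ontology")
        for syn_line in stanza.get("synonym", []):
            m = _SYNONYM_RE.match("synonym: " + syn_line)
            if m is None:
                raise OboParseError(f"malformed synonym in stanza {cid}: {syn_line!r}")
            lex.add(m.group("text").replace('\\"', '"'), cid, names[0], "disease_ontology")
    if extra_terms is not None:
        for cid, surface in extra_terms:
            lex.add(surface, cid, None, "term_list")
    return lex


def read_term_list(path) -> list[tuple[str, str]]:
    """Read a 2-column TSV of (concept_id, surface_form); '#' lines skipped."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, surface = line.split("\t")[:2]
            pairs.append((cid, surface))
    return pairs
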