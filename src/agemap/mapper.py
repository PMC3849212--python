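"""Disease-specific cross-species age mapping by shifted correlation.

For each disease present in both species' normalized matrices, the human
age pattern (year-indexed) is slid against the mouse pattern (day-indexed),
aligning human year ``y`` with mouse day ``y + s`` for every shift
``s = 0..max_shift``.  The shift with the best Pearson correlation is the
disease's age offset; diseases pass into the age map when the correlation
is strong (r^2 above threshold, default 0.5) and positive.  The map then
converts ages in either direction: human years = mouse days - shift.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import AgeDiseaseMatrix

logger = logging.getLogger(__name__)


@dataclass
class MapperOptions:
    max_shift: int = 1028
    r2_threshold: float = 0.5
    min_overlap: int = 10
    score: str = "r"  # "r": maximize r, require r>0; "r2": strict |r| mode

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.score not in ("r", "r2"):
            raise ValueError("score must be 'r' or 'r2'")


@dataclass
class ShiftMapResult:
    disease: str
    shift_days: int
    r: float
    r2: float
    n_overlap: int
    accepted: bool


@dataclass
class AgeMap:
    """Accepted per-disease shifts, plus run provenance."""

    entries: dict[str, ShiftMapResult] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    n_compared: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.entries)


def pearson_at_shift(
    human_vec: np.ndarray, mouse_vec: np.ndarray, s: int, min_overlap: int = 10
) -> float | None:
    """Pearson r between human bins 0..w-1 and mouse bins s..s+w-1.

    Returns None (undefined) when the aligned window is shorter than
    ``min_overlap`` or either windowed vector has zero variance.
    """
    if s < 0:
        raise ValueError("shift must be non-negative")
    human_vec = np.asarray(human_vec, dtype=float)
    mouse_vec = np.asarray(mouse_vec, dtype=float)
    w = min(len(human_vec), len(mouse_vec) - s)
    if w < max(min_overlap, 2):
        return None
    h = human_vec[:w]
    m = mouse_vec[s : s + w]
    hc = h - h.mean()
    mc = m - m.mean()
    denom = np.sqrt((hc @ hc) * (mc @ mc))
    if denom == 0:
        return None
    return float(np.clip((hc @ mc) / denom, -1.0, 1.0))


def best_shift(
    human_vec: np.ndarray,
    mouse_vec: np.ndarray,
    options: MapperOptions | None = None,
) -> tuple[int, float] | None:
    """Scan all shifts 0..max_shift; return (s*, r*) with ties to smaller s.

    Maximizes r itself by default (an age map needs positive association);
    with ``score="r2"`` it maximizes |r| to mirror a pure r^2 criterion.
    """
    options = options or MapperOptions()
    best: tuple[int, float] | None = None
    best_score = -np.inf
    for s in range(options.max_shift + 1):
        r = pearson_at_shift(human_vec, mouse_vec, s, options.min_overlap)
        if r is None:
            continue
        score = r * r if options.score == "r2" else r
        if score > best_score:
            best_score = score
            best = (s, r)
    return best


def map_diseases(
    human_matrix: AgeDiseaseMatrix,
    mouse_matrix: AgeDiseaseMatrix,
    options: MapperOptions | None = None,
) -> AgeMap:
    """Build the age map over diseases present in both matrices."""
    options = options or MapperOptions()
    if not (human_matrix.normalized and mouse_matrix.normalized):
        raise ValueError("both matrices must be normalized")
    shared = sorted(set(human_matrix.diseases) & set(mouse_matrix.diseases))
    if not shared:
        logger.warning("disease sets are disjoint: empty age map")
    amap = AgeMap(
        provenance={
            "human": {"resolution_days": human_matrix.resolution_days, **human_matrix.meta},
            "mouse": {"resolution_days": mouse_matrix.resolution_days, **mouse_matrix.meta},
            "options": vars(options),
        },
        n_compared=len(shared),
    )
    for cid in shared:
        hv = human_matrix.row(cid)
        mv = mouse_matrix.row(cid)
        res = best_shift(hv, mv, options)
        if res is None:
            continue
        s, r = res
        w = min(len(hv), len(mv) - s)
        accepted = r * r > options.r2_threshold and (options.score == "r2" or r > 0)
        if accepted:
            amap.entries[cid] = ShiftMapResult(cid, s, r, r * r, w, True)
    logger.info("age map: %d diseases compared, %d accepted", amap.n_compared, amap.n_accepted)
    return amap


def mouse_to_human_age(amap: AgeMap, disease: str, mouse_age_days: float) -> float:
    """Human age in years for a mouse age, via the disease's shift."""
    if disease not in amap.entries:
        raise KeyError(f"disease {disease!r} not in age map")
    shift = amap.entries[disease].shift_days
    if mouse_age_days < shift:
        raise ValueError(
            f"mouse age {mouse_age_days} d is below the shift ({shift} d): "
            "would map to a negative human age"
        )
    return mouse_age_days - shift


def human_to_mouse_age(amap: AgeMap, disease: str, human_age_years: float) -> float:
    """Mouse age in days for a human age; exact inverse of mouse_to_human_age."""
    if disease not in amap.entries:
        raise KeyError(f"disease {disease!r} not in age map")
    if human_age_years < 0:
        raise ValueError("human age must be non-negative")
    return human_age_years + amap.entries[disease].shift_days


def write_age_map(amap: AgeMap, path, concept_names: dict[str, str] | None = None) -> None:
    """JSON (entries + provenance) and a flat TSV beside it."""
    path = Path(path)
    names = concept_names or {}
    payload = {
        "n_compared": amap.n_compared,
        "n_accepted": amap.n_accepted,
        "provenance": amap.provenance,
        "diseases": [
            {
                "concept_id": e.disease,
                "name": names.get(e.disease, e.disease),
                "shift_days": e.shift_days,
                "r": e.r,
                "r2": e.r2,
                "n_overlap": e.n_overlap,
            }
            for e in amap.entries.values()
        ],
    }
    path.write_text(json.dumps(payload, indent=2))
    rows = payload["diseases"]
    pd.DataFrame(rows, columns=["concept_id", "name", "shift_days", "r", "r2", "n_overlap"]).to_csv(
        path.with_suffix(".tsv"), sep="\t", index=False
    )


def read_age_map(path) -> AgeMap:
    payload = json.loads(Path(path).read_text())
    amap = AgeMap(provenance=payload.get("provenance", {}), n_compared=payload.get("n_compared", 0))
    for d in payload["diseases"]:
        amap.entries[d["concept_id"]] = ShiftMapResult(
            d["concept_id"], d["shift_days"], d["r"], d["r2"], d["n_overlap"], True
        )
    return amap
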