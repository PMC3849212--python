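"""Quantitative age-disease matrices.

For one species, a matrix counts evidence instances per disease per age
bin: mouse ages at 1-day resolution over 0..1028 days, human ages at 1-year
resolution over 0..120 years.  Evidence with inferred (open-ended) age
ranges is excluded; an explicit range contributes at its midpoint bin by
default.  Rows are normalized to frequencies by the disease's total
instance count so over- or under-studied diseases weigh equally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .store import EvidenceStore

logger = logging.getLogger(__name__)

#: default axis extents: mouse day bins 0..1028, human year bins 0..120
SPECIES_DEFAULTS = {
    "mouse": {"resolution_days": 1.0, "n_bins": 1029, "bin_unit": "day"},
    "human": {"resolution_days": 365.0, "n_bins": 121, "bin_unit": "year"},
}


@dataclass
class MatrixBuildOptions:
    resolution_days: float | None = None  # None -> species default
    range_policy: str = "midpoint"  # or "start"
    min_instances: int = 0

    def __post_init__(self) -> None:
        if self.resolution_days is not None and self.resolution_days <= 0:
            raise ValueError("resolution must be positive")
        if self.range_policy not in ("midpoint", "start"):
            raise ValueError("range_policy must be 'midpoint' or 'start'")


@dataclass
class AgeDiseaseMatrix:
    """Disease x age-bin matrix for one species.

    ``data`` is indexed by concept id with integer bin-start columns
    (0, 1, 2, ... in units of ``resolution_days``).
    """

    species: str
    resolution_days: float
    data: pd.DataFrame
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return list(self.data.index)

    def row(self, concept_id: str) -> np.ndarray:
        return self.data.loc[concept_id].to_numpy(dtype=float)


def build_matrix(
    store: EvidenceStore, species: str, options: MatrixBuildOptions | None = None
) -> AgeDiseaseMatrix:
    """Count (evidence, phenotype) contributions into age bins.

    Inferred age ranges are excluded; each remaining evidence contributes
    +1 per distinct linked phenotype at its point-age bin or, for explicit
    ranges, at the bin chosen by ``range_policy``.  Ages beyond the axis
    maximum are dropped and logged.
    """
    options = options or MatrixBuildOptions()
    defaults = SPECIES_DEFAULTS[species]
    res = options.resolution_days or defaults["resolution_days"]
    n_bins = int(np.ceil(defaults["n_bins"] * defaults["resolution_days"] / res))
    max_days = defaults["n_bins"] * defaults["resolution_days"]

    if len(store) == 0:
        logger.warning("empty store: returning empty %s matrix", species)
        data = pd.DataFrame(np.zeros((0, n_bins)), columns=range(n_bins))
        return AgeDiseaseMatrix(species, res, data, meta={"range_policy": options.range_policy})

    usable = store.ages[store.ages["inferred"] == 0]
    counts: dict[str, np.ndarray] = {}
    n_over = 0
    n_contrib = 0
    phenos_by_id: dict[str, list[str]] = {}
    for row in store.phenotypes.itertuples():
        phenos_by_id.setdefault(row.evidence_id, []).append(row.concept_id)

    for row in usable.itertuples():
        start, end = float(row.start_days), float(row.end_days)
        if options.range_policy == "midpoint":
            days = (start + end) / 2.0
        else:
            days = start
        if days >= max_days:
            n_over += 1
            continue
        b = int(days // res)
        for cid in set(phenos_by_id.get(row.evidence_id, [])):
            if cid not in counts:
                counts[cid] = np.zeros(n_bins)
            counts[cid][b] += 1
            n_contrib += 1
    if n_over:
        logger.info("dropped %d age rows beyond the %s axis maximum", n_over, species)

    data = pd.DataFrame.from_dict(counts, orient="index", columns=range(n_bins)).sort_index()
    mat = AgeDiseaseMatrix(
        species,
        res,
        data,
        meta={
            "range_policy": options.range_policy,
            "contributions": n_contrib,
            "dropped_over_max": n_over,
        },
    )
    if options.min_instances > 0:
        mat = filter_min_instances(mat, options.min_instances)
    return mat


def normalize(matrix: AgeDiseaseMatrix) -> AgeDiseaseMatrix:
    """Divide each disease row by its total count; zero rows are dropped."""
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    sums = matrix.data.sum(axis=1)
    zero = sums[sums == 0].index
    if len(zero):
        logger.warning("dropping %d all-zero disease rows: %s", len(zero), list(zero)[:5])
    kept = matrix.data.loc[sums > 0]
    data = kept.div(sums[sums > 0], axis=0)
    return replace(matrix, data=data, normalized=True)


def filter_min_instances(matrix: AgeDiseaseMatrix, k: int) -> AgeDiseaseMatrix:
    """Keep only diseases with at least ``k`` counted instances."""
    if matrix.normalized:
        raise ValueError("filter on raw counts, before normalization")
    sums = matrix.data.sum(axis=1)
    data = matrix.data.loc[sums >= k]
    if data.empty and len(matrix.data):
        logger.warning("all %d diseases fall below min_instances=%d", len(matrix.data), k)
    return replace(matrix, data=data)


def rebin(matrix: AgeDiseaseMatrix, factor: int) -> AgeDiseaseMatrix:
    """Aggregate ``factor`` consecutive bins (e.g. day -> week with 7)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = matrix.data.to_numpy(dtype=float)
    n = arr.shape[1]
    pad = (-n) % factor
    if pad:
        arr = np.pad(arr, ((0, 0), (0, pad)))
    agg = arr.reshape(arr.shape[0], -1, factor).sum(axis=2)
    data = pd.DataFrame(agg, index=matrix.data.index, columns=range(agg.shape[1]))
    return replace(matrix, data=data, resolution_days=matrix.resolution_days * factor)


def write_matrix(matrix: AgeDiseaseMatrix, path) -> None:
    """TSV (first column disease id, bin-start columns) + JSON sidecar."""
    path = Path(path)
    out = matrix.data.copy()
    out.index.name = "concept_id"
    out.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "species": matrix.species,
                "resolution_days": matrix.resolution_days,
                "n_bins": matrix.data.shape[1],
                "normalized": matrix.normalized,
                **matrix.meta,
            },
            indent=2,
        )
    )


def read_matrix(path) -> AgeDiseaseMatrix:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col="concept_id")
    data.columns = data.columns.astype(int)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return AgeDiseaseMatrix(
        species=meta.get("species", "mouse"),
        resolution_days=float(meta.get("resolution_days", 1.0)),
        data=data,
        normalized=bool(meta.get("normalized", False)),
        meta={k: v for k, v in meta.items() if k not in ("species", "resolution_days", "normalized", "n_bins")},
    )
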