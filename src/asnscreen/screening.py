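"""Per-protein screening statistics and multi-criteria candidate ranking.

Retained 9-mer cores are aggregated into one screening row per protein:

* epitope count — distinct (core sequence, start) pairs pooled across alleles;
* mean CPR — arithmetic mean, over counted epitopes, of each epitope's minimum
  core percentile across alleles (its strongest allele);
* allele coverage — number of distinct panel alleles with a retained core;
* epitope density (ED):

      ED = epitope_count × (2 − mean_cpr) / (length − epitope_size + 1)

  with epitope_size 9 (the counted unit is the 9-mer core). Lower ED predicts
  a less immunogenic protein.

Candidates are then compared to a reference enzyme (E. coli type II
asparaginase in the shipped fixtures) and ranked by Pareto dominance on
(ED, allele coverage, antigenicity probability), all minimized.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .epitopes import CORE_LENGTH, EpitopeCore
from .intake import ProteinRecord, load_family_table

logger = logging.getLogger(__name__)

DEFAULT_EPITOPE_SIZE = 9


class ScreeningTableError(ValueError):
    """A malformed screening or antigenicity table."""


@dataclass(frozen=True)
class ScreeningRow:
    """One protein's screening summary."""

    id: str
    epitope_count: int
    mean_cpr: float
    allele_count: int
    ed: float
    length: int | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.epitope_count < 0 or self.allele_count < 0:
            raise ValueError("counts must be non-negative")
        if self.ed < 0:
            raise ValueError("epitope density must be non-negative")


@dataclass(frozen=True)
class DensityMap:
    """Per-residue count of covering (core, allele) instances."""

    protein_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if (c < 0).any():
            raise ValueError("density counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class AntigenicityScore:
    """Externally predicted probability that a protein is antigenic."""

    id: str
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("antigenicity probability must lie in [0, 1]")


@dataclass(frozen=True)
class CandidateRanking:
    """Ordered candidates with Pareto-front and selection flags."""

    reference_id: str
    ordered_ids: tuple[str, ...]
    pareto_front: frozenset[str]
    selected: frozenset[str]
    criteria: Mapping[str, tuple[float, int, float]]

    def __post_init__(self) -> None:
        if not self.selected <= self.pareto_front:
            raise ValueError("selected candidates must lie on the Pareto front")
        if self.reference_id in self.selected:
            raise ValueError("the reference is never selected")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def epitope_density(
    epitope_count: int,
    mean_cpr: float,
    length: int,
    epitope_size: int = DEFAULT_EPITOPE_SIZE,
) -> float:
    """Epitope density: count × (2 − mean CPR) / (length − epitope_size + 1)."""
    if epitope_count < 0:
        raise ValueError("epitope count must be non-negative")
    if not (0.0 <= mean_cpr < 2.0):
        raise ValueError("mean CPR must lie in [0, 2)")
    if length < epitope_size:
        raise ValueError("protein shorter than the epitope size")
    return epitope_count * (2.0 - mean_cpr) / (length - epitope_size + 1)


def allele_coverage(cores: Sequence[EpitopeCore]) -> int:
    """Number of distinct alleles with at least one retained core."""
    ids = {c.protein_id for c in cores}
    if len(ids) > 1:
        raise ValueError(f"cores span multiple proteins: {sorted(ids)}")
    return len({c.allele for c in cores})


def density_map(cores: Sequence[EpitopeCore], length: int) -> DensityMap:
    """Per-residue epitope hit counts; each (core, allele) instance adds one
    to its nine covered positions, so counts sum to 9 × instance count."""
    ids = {c.protein_id for c in cores}
    if len(ids) > 1:
        raise ValueError(f"cores span multiple proteins: {sorted(ids)}")
    counts = np.zeros(length, dtype=int)
    for c in cores:
        if c.start < 1 or c.start + CORE_LENGTH - 1 > length:
            raise ValueError(
                f"core at {c.start} exceeds protein length {length}"
            )
        counts[c.start - 1 : c.start + CORE_LENGTH - 1] += 1
    return DensityMap(protein_id=ids.pop() if ids else "", counts=counts)


def build_screening_row(
    protein: ProteinRecord,
    cores: Sequence[EpitopeCore],
    epitope_size: int = DEFAULT_EPITOPE_SIZE,
    family: str | None = None,
) -> ScreeningRow:
    """Aggregate one protein's retained cores into its screening row."""
    for c in cores:
        if c.protein_id != protein.id:
            raise ValueError(f"core for {c.protein_id!r} on protein {protein.id!r}")
    # one counted epitope per distinct (core sequence, start), pooled over
    # alleles; its CPR is the minimum across alleles (strongest allele)
    per_epitope: dict[tuple[str, int], float] = {}
    for c in cores:
        key = (c.core, c.start)
        per_epitope[key] = min(per_epitope.get(key, np.inf), c.core_cpr)
    count = len(per_epitope)
    mean_cpr = float(np.mean(list(per_epitope.values()))) if count else 0.0
    return ScreeningRow(
        id=protein.id,
        epitope_count=count,
        mean_cpr=mean_cpr,
        allele_count=allele_coverage(cores) if cores else 0,
        ed=epitope_density(count, mean_cpr, protein.length, epitope_size),
        length=protein.length,
        family=family,
    )


# ---------------------------------------------------------------------------
# screening-table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["id", "epitope_number", "cpr_value", "allele_number", "ed"]


def _strip_version(acc: str) -> str:
    """Accession without a trailing '.N' version suffix."""
    head, dot, tail = acc.rpartition(".")
    return head if dot and tail.isdigit() else acc


def load_screening_table(
    path: str | Path | None = None,
    epitope_size: int = DEFAULT_EPITOPE_SIZE,
) -> list[ScreeningRow]:
    """Load a screening TSV (id, epitope_number, cpr_value, allele_number, ed).

    With no path, the packaged 26-row reference screening table is
    loaded, with lengths joined from the representative family table where the
    accession (version-insensitive) appears there. Tabulated ED values are kept
    verbatim; when a length is available, the ED recomputed from the formula is
    compared and any discrepancy is logged as a warning, never an error.
    """
    if path is None:
        text = resources.files("asnscreen.data").joinpath("table2.tsv").read_text()
        df = pd.read_csv(pd.io.common.StringIO(text), sep="\t")
    else:
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            raise ScreeningTableError(f"{path}: empty screening table") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScreeningTableError(f"screening table missing columns {missing}")

    lengths: dict[str, int] = {}
    families: dict[str, str] = {}
    for fam_row in load_family_table():
        key = _strip_version(fam_row.id)
        lengths[key] = fam_row.length
        families[key] = fam_row.family

    rows: list[ScreeningRow] = []
    for rec in df.itertuples(index=False):
        key = _strip_version(str(rec.id))
        length = lengths.get(key) if "length" not in df.columns else int(rec.length)
        family = families.get(key) if "family" not in df.columns else rec.family
        row = ScreeningRow(
            id=str(rec.id),
            epitope_count=int(rec.epitope_number),
            mean_cpr=float(rec.cpr_value),
            allele_count=int(rec.allele_number),
            ed=float(rec.ed),
            length=length,
            family=family,
        )
        if row.length is not None:
            recomputed = epitope_density(
                row.epitope_count, row.mean_cpr, row.length, epitope_size
            )
            if abs(recomputed - row.ed) > 5e-4:
                logger.warning(
                    "%s: tabulated ED %.4f differs from formula value %.4f",
                    row.id, row.ed, recomputed,
                )
        rows.append(row)
    return rows


def write_screening_tsv(rows: Iterable[ScreeningRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([*_REQUIRED_COLUMNS, "length", "family"])
        for r in rows:
            w.writerow(
                [
                    r.id,
                    r.epitope_count,
                    f"{r.mean_cpr:.4f}",
                    r.allele_count,
                    f"{r.ed:.6f}",
                    "" if r.length is None else r.length,
                    r.family or "",
                ]
            )


def load_antigenicity_table(path: str | Path) -> list[AntigenicityScore]:
    """Read an antigenicity TSV (id, probability) produced by an external
    predictor."""
    df = pd.read_csv(path, sep="\t")
    if not {"id", "probability"}.issubset(df.columns):
        raise ScreeningTableError(f"{path}: need columns id, probability")
    return [
        AntigenicityScore(id=str(r.id), probability=float(r.probability))
        for r in df.itertuples(index=False)
    ]


def write_density_tsv(maps: Iterable[DensityMap], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "position", "count"])
        for dm in maps:
            for pos, cnt in enumerate(dm.counts, start=1):
                w.writerow([dm.protein_id, pos, int(cnt)])


# ---------------------------------------------------------------------------
# reference comparison and candidate selection
# ---------------------------------------------------------------------------

def compare_to_reference(
    rows: Sequence[ScreeningRow], reference_id: str
) -> list[str]:
    """Ids with ED strictly greater than the reference's, sorted by ED
    descending (ties by id for determinism)."""
    by_id = {r.id: r for r in rows}
    if reference_id not in by_id:
        raise KeyError(f"reference {reference_id!r} not in the screening table")
    ref_ed = by_id[reference_id].ed
    above = [r for r in rows if r.id != reference_id and r.ed > ref_ed]
    above.sort(key=lambda r: (-r.ed, r.id))
    return [r.id for r in above]


def _dominates(
    a: tuple[float, int, float], b: tuple[float, int, float]
) -> bool:
    """True when a is no worse than b in every minimized criterion and
    strictly better in at least one."""
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def select_candidates(
    rows: Sequence[ScreeningRow],
    antigenicity: Sequence[AntigenicityScore] | Mapping[str, float],
    reference_id: str,
    family_labels: Mapping[str, str] | None = None,
    family: str | None = None,
) -> CandidateRanking:
    """Pareto selection of candidates on (ED, allele coverage, antigenicity).

    All three criteria are minimized jointly; the front excludes the reference.
    ``family`` optionally restricts the selected set (not the front) to rows
    whose label — from ``family_labels`` or the rows themselves — matches.
    Ordered ids sort by ED, then allele count, then antigenicity, then id.
    """
    anti: Mapping[str, float]
    if isinstance(antigenicity, Mapping):
        anti = antigenicity
    else:
        anti = {a.id: a.probability for a in antigenicity}
    by_id = {r.id: r for r in rows}
    if reference_id not in by_id:
        raise KeyError(f"reference {reference_id!r} not in the screening table")
    missing = sorted(r.id for r in rows if r.id not in anti)
    if missing:
        raise ScreeningTableError(f"rows without an antigenicity score: {missing}")

    criteria = {r.id: (r.ed, r.allele_count, anti[r.id]) for r in rows}
    candidates = [r.id for r in rows if r.id != reference_id]
    front = frozenset(
        cid
        for cid in candidates
        if not any(
            _dominates(criteria[other], criteria[cid])
            for other in candidates
            if other != cid
        )
    )
    if family is not None:
        labels = dict(family_labels or {})
        for r in rows:
            labels.setdefault(r.id, r.family)
        selected = frozenset(cid for cid in front if labels.get(cid) == family)
    else:
        selected = front
    ordered = tuple(sorted(candidates, key=lambda cid: (*criteria[cid], cid)))
    return CandidateRanking(
        reference_id=reference_id,
        ordered_ids=ordered,
        pareto_front=front,
        selected=selected,
        criteria=criteria,
    )


def write_ranking(
    ranking: CandidateRanking, tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "ed", "allele_count", "antigenicity", "pareto", "selected"])
        for cid in ranking.ordered_ids:
            ed, ac, ag = ranking.criteria[cid]
            w.writerow(
                [
                    cid,
                    f"{ed:.6f}",
                    ac,
                    f"{ag:.4f}",
                    int(cid in ranking.pareto_front),
                    int(cid in ranking.selected),
                ]
            )
    if json_path is not None:
        payload = {
            "reference_id": ranking.reference_id,
            "ordered_ids": list(ranking.ordered_ids),
            "pareto_front": sorted(ranking.pareto_front),
            "selected": sorted(ranking.selected),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
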