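"""Sequence intake: FASTA reading, completeness filtering, redundancy clustering,
and motif-based family labeling.

This module implements the front end of the asparaginase screening pipeline:

* :func:`read_fasta` / :func:`filter_records` — load candidate protein sequences
  and exclude partial or out-of-range entries before any scoring.
* :func:`pairwise_identity` / :func:`greedy_cluster` — CD-HIT-style greedy
  incremental clustering at an identity cutoff (default 60%) to remove
  redundancy among homologs.
* :func:`compile_motif` / :func:`scan_motifs` / :func:`assign_family` — scan for
  family-diagnostic conserved motifs (written in a fixed-residue / ``x``
  wildcard notation) and label each sequence with the asparaginase family
  (PF00710.11 or PF06089.11) whose motif set it matches best.

Identity between two sequences is defined as the number of identical aligned
positions in an optimal global alignment (match +1, mismatch 0, gap −0.5, end
gaps free), divided by the length of the shorter sequence — the denominator
convention used by CD-HIT.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, in alphabetical order.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard codes tolerated at intake when explicitly allowed.
#: They never match a fixed motif residue and never count as identical in
#: alignments, but they do match motif wildcards.
AMBIGUOUS_RESIDUES = "BXZU"

_ALLOWED = frozenset(CANONICAL_RESIDUES + AMBIGUOUS_RESIDUES)
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Default length bounds for "complete" asparaginases: the extremes present in
#: the representative family table (316 and 428 residues).
DEFAULT_MIN_LENGTH = 316
DEFAULT_MAX_LENGTH = 428

#: Default redundancy-reduction identity cutoff.
DEFAULT_IDENTITY_CUTOFF = 0.6

PF00710 = "PF00710.11"
PF06089 = "PF06089.11"

_GAP2 = -1  # gap step on the doubled-score scale (2 × −0.5)
_ID_BASE = 512  # packing base: |identity difference| < 512 < one score unit


class FastaFormatError(ValueError):
    """Raised for an empty or malformed FASTA file."""


class MotifParseError(ValueError):
    """Raised when a motif notation string cannot be compiled."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with identifier and 1-based coordinates."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_RESIDUES for c in self.sequence)


@dataclass(frozen=True)
class Cluster:
    """A redundancy cluster: a representative and its members (inclusive)."""

    representative_id: str
    member_ids: tuple[str, ...]
    cutoff: float
    #: identity of each member to the representative, keyed by member id
    identities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be among member_ids")
        if not (0.0 < self.cutoff <= 1.0):
            raise ValueError("cutoff must lie in (0, 1]")


@dataclass(frozen=True)
class MotifPattern:
    """A compiled conserved-sequence motif.

    Tokens are ``("fixed", residue)`` or ``("any", n)`` for ``n`` consecutive
    wildcards; the source notation writes a wildcard as lowercase ``x`` and a
    run of ``n`` wildcards as ``x(n)``.
    """

    name: str
    tokens: tuple[tuple[str, object], ...]
    span: int

    def to_notation(self) -> str:
        """Canonical notation string (wildcard runs collapsed to ``x(n)``)."""
        parts: list[str] = []
        for kind, val in self.tokens:
            if kind == "fixed":
                parts.append(str(val))
            else:
                parts.append("x" if val == 1 else f"x({val})")
        return "".join(parts)

    @property
    def regex(self) -> str:
        """Regex over the validated intake alphabet; wildcards also match
        ambiguity codes, fixed residues match only themselves."""
        wild = f"[{CANONICAL_RESIDUES}{AMBIGUOUS_RESIDUES}]"
        out: list[str] = []
        for kind, val in self.tokens:
            if kind == "fixed":
                out.append(str(val))
            else:
                out.append(f"{wild}{{{val}}}")
        return "".join(out)


@dataclass(frozen=True)
class MotifHit:
    """A single motif occurrence, 1-based inclusive coordinates."""

    protein_id: str
    motif_name: str
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("hit span does not match the matched substring")


@dataclass(frozen=True)
class FamilyRow:
    """One row of the representative-asparaginase family table."""

    id: str
    organism: str
    length: int
    family: str

    def __post_init__(self) -> None:
        if self.family not in (PF00710, PF06089):
            raise ValueError(f"unknown family label {self.family!r}")


# ---------------------------------------------------------------------------
# FASTA intake and filtering
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased. Raises :class:`FastaFormatError` for an empty
    file or one that does not start with a header line, and
    :class:`OSError` for an unreadable path.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        raise FastaFormatError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        first_bad = next(
            i for i, line in enumerate(text.splitlines(), start=1) if line.strip()
        )
        raise FastaFormatError(f"{path}: line {first_bad}: expected '>' header")
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id, description=rec.description, sequence=str(rec.seq).upper()
            )
        )
    if not records:
        raise FastaFormatError(f"{path}: no sequence records found")
    return records


#: machine-readable rejection reasons
TOO_SHORT = "too_short"
TOO_LONG = "too_long"
AMBIGUOUS = "ambiguous_residues"


def filter_records(
    records: Iterable[ProteinRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
    reject_ambiguous: bool = True,
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Partition records into (kept, rejected-with-reason).

    Emulates the exclusion of partial entries by length bounds; records with
    ambiguity codes (X/B/Z/U) are rejected unless ``reject_ambiguous`` is off.
    """
    if min_length > max_length:
        raise ValueError("min_length must not exceed max_length")
    kept: list[ProteinRecord] = []
    rejected: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        if rec.length < min_length:
            rejected.append((rec, TOO_SHORT))
        elif rec.length > max_length:
            rejected.append((rec, TOO_LONG))
        elif reject_ambiguous and rec.has_ambiguous:
            rejected.append((rec, AMBIGUOUS))
        else:
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# Pairwise identity and greedy clustering
# ---------------------------------------------------------------------------

def _alignment_stats(a: str, b: str) -> tuple[float, int]:
    """Optimal global alignment of ``a`` and ``b`` with match +1, mismatch 0,
    gap −0.5 and free end gaps; returns ``(score, identities)``.

    Among co-optimal alignments the one with the most identical columns is
    reported, which makes the identity value deterministic. Implemented as a
    single integer DP: each cell packs ``2·score`` and the identity count as
    ``2·score·512 + identities`` (identity counts stay below 512 for the
    protein lengths handled here), so one ``max`` optimizes both keys
    lexicographically. Ambiguity codes never count as identical.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("sequences must be nonempty")
    if max(n, m) >= _ID_BASE:
        raise ValueError(f"sequences longer than {_ID_BASE - 1} are not supported")
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    canonical = np.frombuffer(CANONICAL_RESIDUES.encode("ascii"), dtype=np.uint8)
    a_ok = np.isin(av, canonical)
    b_ok = np.isin(bv, canonical)
    match = (av[:, None] == bv[None, :]) & a_ok[:, None] & b_ok[None, :]
    # packed contribution of a diagonal (aligned-pair) step
    sub = np.where(match, 2 * _ID_BASE + 1, 0).astype(np.int64)

    C = np.zeros((n + 1, m + 1), dtype=np.int64)
    gap_step = _GAP2 * _ID_BASE
    for d in range(2, n + m + 1):
        i_lo, i_hi = max(1, d - m), min(n, d - 1)
        if i_lo > i_hi:
            continue
        i = np.arange(i_lo, i_hi + 1)
        j = d - i
        best = C[i - 1, j - 1] + sub[i - 1, j - 1]
        np.maximum(best, C[i - 1, j] + gap_step, out=best)
        np.maximum(best, C[i, j - 1] + gap_step, out=best)
        C[i, j] = best
    # free trailing end gaps: best over the last row and last column
    packed = int(max(C[n, 1:].max(initial=0), C[1:, m].max(initial=0), 0))
    identities = packed % _ID_BASE
    score = (packed // _ID_BASE) / 2.0
    return score, identities


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Fraction of identical aligned positions over the shorter sequence length.

    Symmetric; 1.0 for identical sequences. See :func:`_alignment_stats` for
    the alignment scoring.
    """
    _, identities = _alignment_stats(a.sequence, b.sequence)
    return identities / min(a.length, b.length)


def greedy_cluster(
    records: Sequence[ProteinRecord], cutoff: float = DEFAULT_IDENTITY_CUTOFF
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Records are processed longest-first (ties broken by id); each record joins
    the first existing cluster whose representative it matches at ≥ ``cutoff``
    identity, otherwise it founds a new cluster. Representatives of distinct
    clusters therefore sit below the cutoff pairwise, and every member reaches
    its representative at or above it.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    idents: list[dict[str, float]] = []
    for rec in ordered:
        placed = False
        for k, rep in enumerate(reps):
            ident = pairwise_identity(rec, rep)
            if ident >= cutoff:
                members[k].append(rec.id)
                idents[k][rec.id] = ident
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec.id])
            idents.append({rec.id: 1.0})
    return [
        Cluster(
            representative_id=rep.id,
            member_ids=tuple(mem),
            cutoff=cutoff,
            identities=dict(ident),
        )
        for rep, mem, ident in zip(reps, members, idents)
    ]


def write_clusters_tsv(clusters: Iterable[Cluster], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["representative_id", "member_id", "identity"])
        for cl in clusters:
            for mid in cl.member_ids:
                w.writerow([cl.representative_id, mid, f"{cl.identities[mid]:.4f}"])


# ---------------------------------------------------------------------------
# Motif compilation, scanning, family assignment
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"([A-Y])|x(?:\((\d+)\))?")


def compile_motif(name: str, notation: str) -> MotifPattern:
    """Compile a motif written as fixed residues plus ``x``/``x(n)`` wildcards.

    Example: ``"SHSGEx(2)H"`` spans 8 positions with wildcards at 6 and 7.
    Raises :class:`MotifParseError` for stray characters, zero repeats, or an
    empty notation.
    """
    if not notation:
        raise MotifParseError(f"motif {name!r}: empty notation")
    tokens: list[tuple[str, object]] = []
    pos = 0
    while pos < len(notation):
        m = _TOKEN_RE.match(notation, pos)
        if m is None:
            raise MotifParseError(
                f"motif {name!r}: unexpected character {notation[pos]!r} at "
                f"offset {pos}"
            )
        if m.group(1) is not None:
            res = m.group(1)
            if res not in _CANONICAL_SET:
                raise MotifParseError(
                    f"motif {name!r}: {res!r} is not a canonical residue"
                )
            tokens.append(("fixed", res))
        else:
            count = 1 if m.group(2) is None else int(m.group(2))
            if count < 1:
                raise MotifParseError(f"motif {name!r}: zero-length wildcard run")
            # collapse adjacent wildcard runs for a canonical token stream
            if tokens and tokens[-1][0] == "any":
                tokens[-1] = ("any", tokens[-1][1] + count)  # type: ignore[operator]
            else:
                tokens.append(("any", count))
        pos = m.end()
    span = sum(1 if kind == "fixed" else int(val) for kind, val in tokens)
    return MotifPattern(name=name, tokens=tuple(tokens), span=span)


def scan_motifs(
    record: ProteinRecord, patterns: Iterable[MotifPattern]
) -> list[MotifHit]:
    """Report every (overlapping) occurrence of each pattern, 1-based inclusive."""
    hits: list[MotifHit] = []
    seq = record.sequence
    for pat in patterns:
        if pat.span > len(seq):
            continue
        rx = re.compile(f"(?=({pat.regex}))")
        for m in rx.finditer(seq):
            start = m.start() + 1
            hits.append(
                MotifHit(
                    protein_id=record.id,
                    motif_name=pat.name,
                    start=start,
                    end=start + pat.span - 1,
                    matched=m.group(1),
                )
            )
    return hits


UNASSIGNED = "unassigned"
AMBIGUOUS_FAMILY = "ambiguous"


def assign_family(
    record: ProteinRecord,
    pf00710_patterns: Sequence[MotifPattern],
    pf06089_patterns: Sequence[MotifPattern],
) -> str:
    """Label a sequence with the family whose motif set yields more hits.

    Returns ``"unassigned"`` when neither set matches and ``"ambiguous"`` on a
    tie. This is a lightweight proxy for profile-HMM family assignment.
    """
    if not pf00710_patterns or not pf06089_patterns:
        raise ValueError("both family pattern sets must be nonempty")
    n710 = len(scan_motifs(record, pf00710_patterns))
    n089 = len(scan_motifs(record, pf06089_patterns))
    if n710 == 0 and n089 == 0:
        return UNASSIGNED
    if n710 == n089:
        return AMBIGUOUS_FAMILY
    return PF00710 if n710 > n089 else PF06089


def load_motif_definitions(
    path: str | Path | None = None,
) -> dict[str, list[MotifPattern]]:
    """Load a motif definition TSV (name, notation, family) → patterns per family.

    With no path, the packaged motif set is used: the four PF06089.11-family
    conserved motifs plus the active-site motif, and the catalytic-threonine
    context motifs characteristic of PF00710.11 type-II asparaginases.
    """
    if path is None:
        src = resources.files("asnscreen.data").joinpath("motifs.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    by_family: dict[str, list[MotifPattern]] = {}
    rows = csv.DictReader(text.splitlines(), delimiter="\t")
    required = {"name", "notation", "family"}
    if rows.fieldnames is None or not required.issubset(rows.fieldnames):
        raise FastaFormatError("motif file must have columns name, notation, family")
    for row in rows:
        pat = compile_motif(row["name"], row["notation"])
        by_family.setdefault(row["family"], []).append(pat)
    return by_family


def write_motif_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "motif", "start", "end", "matched"])
        for h in hits:
            w.writerow([h.protein_id, h.motif_name, h.start, h.end, h.matched])


def load_family_table(path: str | Path | None = None) -> list[FamilyRow]:
    """Load the representative-asparaginase table (id, organism, length, family).

    With no path, the packaged transcription of the 26 representative
    Streptomyces asparaginases (19 PF00710.11 + 7 PF06089.11) is returned.
    """
    if path is None:
        text = resources.files("asnscreen.data").joinpath("table1.tsv").read_text()
    else:
        text = Path(path).read_text()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    required = {"id", "organism", "length", "family"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise FastaFormatError(
            "family table must have columns id, organism, length, family"
        )
    return [
        FamilyRow(
            id=row["id"],
            organism=row["organism"],
            length=int(row["length"]),
            family=row["family"],
        )
        for row in reader
    ]
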