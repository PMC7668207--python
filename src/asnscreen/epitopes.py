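"""MHC class II epitope prediction for protein screening.

The prediction pipeline mirrors the standard consensus workflow for HLA-DRB1
binding: every protein is tiled into overlapping 15-mer windows; each window
is scored per allele by a pluggable method; raw scores are converted to
percentile ranks against a large background of random 15-mers (lower
percentile = stronger predicted binder); and per-method percentiles are
combined into a consensus percentile rank (CPR) as their median.

The one scoring method implemented in-repo is an additive pocket-profile
matrix (TEPITOPE/Sturniolo style): a 9 positions × 20 residues weight table
per allele, applied to each of the seven 9-mer frames of a 15-mer, the best
frame giving the window's raw score. External predictors (NN-align, SMM-align,
CombLib, NetMHCIIpan, ...) enter only as percentile tables read from TSV
exports; their percentiles join the median alongside the pocket-profile rank.

Windows with CPR below 2 count as high-affinity binders; of those, the best
9-mer core is retained only when the core's own pocket-profile percentile is
below 1, and cores are deduplicated by (protein, allele, core start).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intake import CANONICAL_RESIDUES, ProteinRecord

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 15
CORE_LENGTH = 9
N_FRAMES = WINDOW_LENGTH - CORE_LENGTH + 1

#: name of the in-repo scoring method
POCKET_METHOD = "pocket_profile"

#: the 8-allele HLA-DRB1 panel covering >95% of the world population
DEFAULT_ALLELES = (
    "HLA-DRB1*01:01",
    "HLA-DRB1*03:01",
    "HLA-DRB1*04:01",
    "HLA-DRB1*07:01",
    "HLA-DRB1*08:01",
    "HLA-DRB1*11:01",
    "HLA-DRB1*13:01",
    "HLA-DRB1*15:01",
)

DEFAULT_BINDER_THRESHOLD = 2.0
DEFAULT_CORE_THRESHOLD = 1.0
DEFAULT_BACKGROUND_SIZE = 100_000

_RES_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}


class ConfigurationError(ValueError):
    """An allele/background/matrix wiring problem."""


class PredictionTableError(ValueError):
    """A malformed external prediction export."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a canonical-residue string to integer indices 0..19."""
    try:
        return np.array([_RES_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class PeptideWindow:
    """A 15-mer peptide window, 1-based start within its protein."""

    protein_id: str
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError("peptide windows are 15-mers")
        if self.start < 1:
            raise ValueError("window start is 1-based")


@dataclass(frozen=True)
class PocketProfileMatrix:
    """Additive 9-position × 20-residue binding weight table for one allele."""

    allele: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (CORE_LENGTH, 20):
            raise ValueError("pocket profile must be 9 positions × 20 residues")
        object.__setattr__(self, "weights", w)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# allele={self.allele}\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["pos", *CANONICAL_RESIDUES])
            for p in range(CORE_LENGTH):
                w.writerow([p + 1, *(f"{x:.6g}" for x in self.weights[p])])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PocketProfileMatrix":
        lines = Path(path).read_text().splitlines()
        allele = None
        body: list[str] = []
        for ln in lines:
            if ln.startswith("#"):
                if "allele=" in ln:
                    allele = ln.split("allele=", 1)[1].strip()
            elif ln.strip():
                body.append(ln)
        if allele is None:
            raise ValueError(f"{path}: missing '# allele=...' comment line")
        header = body[0].split("\t")
        if header[0] != "pos" or sorted(header[1:]) != sorted(CANONICAL_RESIDUES):
            raise ValueError(f"{path}: bad residue header")
        col = {r: k for k, r in enumerate(header[1:])}
        rows = body[1:]
        if len(rows) != CORE_LENGTH:
            raise ValueError(f"{path}: expected 9 position rows, got {len(rows)}")
        w = np.zeros((CORE_LENGTH, 20))
        for p, ln in enumerate(rows):
            vals = ln.split("\t")[1:]
            for r in CANONICAL_RESIDUES:
                w[p, _RES_INDEX[r]] = float(vals[col[r]])
        return cls(allele=allele, weights=w)


@dataclass(frozen=True)
class AlleleScore:
    """One window's score under one method for one allele."""

    window: PeptideWindow
    allele: str
    method: str
    raw: float
    percentile: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percentile <= 100.0):
            raise ValueError("percentile must lie in [0, 100]")


@dataclass(frozen=True)
class ConsensusRecord:
    """Consensus percentile rank of one (window, allele) pair."""

    window: PeptideWindow
    allele: str
    cpr: float
    per_method: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class EpitopeCore:
    """A retained 9-mer binding core (pocket-profile percentile < threshold)."""

    protein_id: str
    core: str
    start: int
    allele: str
    core_cpr: float
    source_windows: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LENGTH:
            raise ValueError("epitope cores are 9-mers")


@dataclass(frozen=True)
class BackgroundSet:
    """Sorted raw scores of random background 15-mers for one (method, allele)."""

    method: str
    allele: str
    scores: np.ndarray
    n: int

    def __post_init__(self) -> None:
        s = np.sort(np.asarray(self.scores, dtype=float))
        if s.size < 1:
            raise ValueError("background must be nonempty")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "n", int(s.size))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def window_peptides(
    record: ProteinRecord, k: int = WINDOW_LENGTH
) -> list[PeptideWindow]:
    """Tile a protein into its length−k+1 overlapping k-mer windows."""
    if record.length < k:
        logger.warning(
            "protein %s (length %d) is shorter than the %d-mer window",
            record.id, record.length, k,
        )
        return []
    seq = record.sequence
    return [
        PeptideWindow(protein_id=record.id, start=i + 1, sequence=seq[i : i + k])
        for i in range(record.length - k + 1)
    ]


def score_core(matrix: PocketProfileMatrix, core: str) -> float:
    """Additive pocket-profile score of a 9-mer: sum of per-position weights."""
    if len(core) != CORE_LENGTH:
        raise ValueError("core must be a 9-mer")
    idx = encode_sequence(core)
    return float(matrix.weights[np.arange(CORE_LENGTH), idx].sum())


def _core_scores_along(matrix: PocketProfileMatrix, enc: np.ndarray) -> np.ndarray:
    """Scores of every 9-mer frame of an encoded sequence (length L−8)."""
    frames = np.lib.stride_tricks.sliding_window_view(enc, CORE_LENGTH)
    return matrix.weights[np.arange(CORE_LENGTH)[None, :], frames].sum(axis=1)


def score_window(
    matrix: PocketProfileMatrix, window: PeptideWindow
) -> tuple[float, int]:
    """Best 9-mer frame score of a 15-mer and its offset (0..6, ties → smallest)."""
    enc = encode_sequence(window.sequence)
    scores = _core_scores_along(matrix, enc)
    off = int(np.argmax(scores))  # argmax returns the first maximum
    return float(scores[off]), off


def calibrate_percentile(raw: float, background: BackgroundSet) -> float:
    """Percentile rank: 100 × fraction of background scoring strictly above raw.

    0 for a score above the whole background, 100 for one below it; ties with
    background scores do not penalize the query. Monotone non-increasing in the
    raw score.
    """
    greater = background.n - int(
        np.searchsorted(background.scores, raw, side="right")
    )
    return 100.0 * greater / background.n


def consensus_rank(per_method: Sequence[tuple[str, float]]) -> float:
    """Consensus percentile rank: the median of per-method percentiles."""
    if not per_method:
        raise ValueError("consensus requires at least one method percentile")
    return float(np.median([p for _, p in per_method]))


def build_background(
    matrix: PocketProfileMatrix,
    size: int = DEFAULT_BACKGROUND_SIZE,
    frequencies: np.ndarray | None = None,
    seed: int = 0,
) -> BackgroundSet:
    """Score ``size`` random 15-mers under ``matrix`` for percentile calibration.

    Peptides are drawn residue-wise from ``frequencies`` (uniform over the 20
    canonical residues by default; a Swiss-Prot-like composition is packaged,
    see :func:`swissprot_frequencies`). Each peptide's raw score is its best
    9-mer frame, matching how query windows are scored. Deterministic per seed.
    """
    if size < 1:
        raise ValueError("background size must be positive")
    rng = np.random.default_rng(seed)
    if frequencies is None:
        frequencies = np.full(20, 1 / 20)
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.shape != (20,) or abs(frequencies.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be 20 probabilities summing to 1")
    peptides = rng.choice(20, size=(size, WINDOW_LENGTH), p=frequencies)
    pos = np.arange(CORE_LENGTH)
    best = np.full(size, -np.inf)
    for off in range(N_FRAMES):
        frame = peptides[:, off : off + CORE_LENGTH]
        np.maximum(best, matrix.weights[pos[None, :], frame].sum(axis=1), out=best)
    return BackgroundSet(
        method=POCKET_METHOD, allele=matrix.allele, scores=best, n=size
    )


def swissprot_frequencies() -> np.ndarray:
    """Packaged Swiss-Prot-like amino-acid composition, normalized, in the
    canonical residue order."""
    text = resources.files("asnscreen.data").joinpath(
        "swissprot_frequencies.tsv"
    ).read_text()
    freq = np.zeros(20)
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        freq[_RES_INDEX[row["residue"]]] = float(row["frequency"])
    return freq / freq.sum()


# ---------------------------------------------------------------------------
# consensus prediction and core extraction
# ---------------------------------------------------------------------------

def _external_lookup(
    extra: Iterable[AlleleScore] | None,
) -> dict[tuple[str, int, str], list[tuple[str, float]]]:
    table: dict[tuple[str, int, str], list[tuple[str, float]]] = {}
    if extra:
        for sc in extra:
            key = (sc.window.protein_id, sc.window.start, sc.allele)
            table.setdefault(key, []).append((sc.method, sc.percentile))
    return table


def predict_epitopes(
    record: ProteinRecord,
    matrices: Mapping[str, PocketProfileMatrix],
    backgrounds: Mapping[str, BackgroundSet],
    extra_method_tables: Iterable[AlleleScore] | None = None,
) -> list[ConsensusRecord]:
    """Consensus percentile rank of every (15-mer window, allele) pair.

    Each allele needs a pocket-profile matrix with a matching calibration
    background; external method percentiles, when supplied, join the median.
    """
    if not matrices:
        raise ConfigurationError("at least one allele matrix is required")
    missing = [al for al in matrices if al not in backgrounds]
    if missing:
        raise ConfigurationError(f"alleles without a background: {missing}")
    external = _external_lookup(extra_method_tables)
    windows = window_peptides(record)
    out: list[ConsensusRecord] = []
    if not windows:
        return out
    enc = encode_sequence(record.sequence)
    for allele in matrices:
        matrix = matrices[allele]
        core_scores = _core_scores_along(matrix, enc)
        frame_view = np.lib.stride_tricks.sliding_window_view(core_scores, N_FRAMES)
        raw = frame_view.max(axis=1)
        bg = backgrounds[allele]
        greater = bg.n - np.searchsorted(bg.scores, raw, side="right")
        pocket_pct = 100.0 * greater / bg.n
        for w, win in enumerate(windows):
            per_method = [(POCKET_METHOD, float(pocket_pct[w]))]
            per_method += external.get((record.id, win.start, allele), [])
            out.append(
                ConsensusRecord(
                    window=win,
                    allele=allele,
                    cpr=consensus_rank(per_method),
                    per_method=tuple(per_method),
                )
            )
    return out


def extract_cores(
    consensus: Iterable[ConsensusRecord],
    matrices: Mapping[str, PocketProfileMatrix],
    backgrounds: Mapping[str, BackgroundSet],
    binder_threshold: float = DEFAULT_BINDER_THRESHOLD,
    core_threshold: float = DEFAULT_CORE_THRESHOLD,
) -> list[EpitopeCore]:
    """Retain 9-mer cores of high-affinity windows.

    From every window with CPR < ``binder_threshold``, the best-scoring 9-mer
    frame per allele is scored on its own under the pocket-profile method;
    cores with percentile < ``core_threshold`` are kept, deduplicated by
    (protein, allele, core start) with overlapping source windows pooled.
    """
    if binder_threshold <= 0 or core_threshold <= 0:
        raise ValueError("thresholds must be positive")
    merged: dict[tuple[str, str, int], dict] = {}
    for rec in consensus:
        if rec.cpr >= binder_threshold:
            continue
        allele = rec.allele
        if allele not in matrices or allele not in backgrounds:
            raise ConfigurationError(f"no matrix/background for allele {allele!r}")
        raw, off = score_window(matrices[allele], rec.window)
        pct = calibrate_percentile(raw, backgrounds[allele])
        if pct >= core_threshold:
            continue
        start = rec.window.start + off
        key = (rec.window.protein_id, allele, start)
        entry = merged.setdefault(
            key,
            {
                "core": rec.window.sequence[off : off + CORE_LENGTH],
                "cpr": pct,
                "windows": set(),
            },
        )
        entry["cpr"] = min(entry["cpr"], pct)
        entry["windows"].add(rec.window.start)
    return [
        EpitopeCore(
            protein_id=pid,
            core=entry["core"],
            start=start,
            allele=allele,
            core_cpr=entry["cpr"],
            source_windows=tuple(sorted(entry["windows"])),
        )
        for (pid, allele, start), entry in sorted(merged.items())
    ]


# ---------------------------------------------------------------------------
# external prediction exports and TSV output
# ---------------------------------------------------------------------------

_PREDICTION_COLUMNS = ["protein_id", "start", "peptide", "allele", "method",
                       "percentile"]


def read_prediction_table(path: str | Path) -> list[AlleleScore]:
    """Read an external predictor export: TSV of
    (protein_id, start, peptide, allele, method, percentile).

    Rows are validated (15-mer peptide, percentile in [0, 100]); errors name
    the offending data row. The raw score of imported records is NaN — only
    their percentiles participate in the consensus.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise PredictionTableError(f"{path}: missing columns {missing}")
    out: list[AlleleScore] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        peptide = str(row.peptide)
        if len(peptide) != WINDOW_LENGTH:
            raise PredictionTableError(
                f"{path}: row {i}: peptide length {len(peptide)} != 15"
            )
        try:
            start = int(row.start)
            pct = float(row.percentile)
        except ValueError:
            raise PredictionTableError(f"{path}: row {i}: non-numeric field") from None
        if not (0.0 <= pct <= 100.0):
            raise PredictionTableError(
                f"{path}: row {i}: percentile {pct} outside [0, 100]"
            )
        out.append(
            AlleleScore(
                window=PeptideWindow(
                    protein_id=str(row.protein_id), start=start, sequence=peptide
                ),
                allele=str(row.allele),
                method=str(row.method),
                raw=float("nan"),
                percentile=pct,
            )
        )
    return out


def write_consensus_tsv(records: Iterable[ConsensusRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "start", "allele", "cpr", "n_methods"])
        for rec in records:
            w.writerow(
                [
                    rec.window.protein_id,
                    rec.window.start,
                    rec.allele,
                    f"{rec.cpr:.6g}",
                    len(rec.per_method),
                ]
            )


def write_cores_tsv(cores: Iterable[EpitopeCore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "allele", "start", "core", "core_cpr",
                    "source_windows"])
        for c in cores:
            w.writerow(
                [
                    c.protein_id,
                    c.allele,
                    c.start,
                    c.core,
                    f"{c.core_cpr:.6g}",
                    ",".join(map(str, c.source_windows)),
                ]
            )
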