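"""Synthetic inputs for every pipeline stage.

Generators here emulate the study's inputs at test scale: pocket-profile
matrices with a planted favored core, proteomes of 300–430-residue proteins
with allele-specific binder cores spliced at known positions, homolog families
of controlled pairwise identity for clustering, and screening tables with
known ED extrema. Every generator is a pure function of its arguments plus a
seed — the same seed yields byte-identical output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .epitopes import CORE_LENGTH, PocketProfileMatrix
from .intake import CANONICAL_RESIDUES, ProteinRecord


@dataclass(frozen=True)
class PlantedCore:
    """A binder core to splice into a synthetic protein."""

    protein_index: int
    allele: str
    core: str
    start: int  # 1-based

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LENGTH:
            raise ValueError("planted cores are 9-mers")
        if self.start < 1:
            raise ValueError("start is 1-based")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic proteome with planted epitopes."""

    n_proteins: int
    length_range: tuple[int, int] = (300, 430)
    residue_frequencies: np.ndarray | None = None
    alleles: tuple[str, ...] = ()
    planted: tuple[PlantedCore, ...] = ()
    background_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        lo, hi = self.length_range
        if not (CORE_LENGTH <= lo <= hi):
            raise ValueError("bad length range")
        if self.residue_frequencies is not None:
            f = np.asarray(self.residue_frequencies, dtype=float)
            if f.shape != (20,) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("frequencies must be 20 probabilities summing to 1")
            object.__setattr__(self, "residue_frequencies", f)
        for p in self.planted:
            if not (0 <= p.protein_index < self.n_proteins):
                raise ValueError(f"planted core for missing protein {p.protein_index}")


def _frequencies(freq: np.ndarray | None) -> np.ndarray:
    return np.full(20, 1 / 20) if freq is None else np.asarray(freq, dtype=float)


def _random_sequence(rng: np.random.Generator, length: int,
                     freq: np.ndarray, alphabet: str = CANONICAL_RESIDUES) -> str:
    idx = rng.choice(len(alphabet), size=length, p=freq)
    return "".join(alphabet[i] for i in idx)


def generate_pssm(
    allele: str,
    favored_core: str,
    contrast: float,
    seed: int = 0,
) -> PocketProfileMatrix:
    """A pocket-profile matrix that favors one 9-mer core.

    Weights start as standard-normal noise; the favored core's residues are
    then raised until its score exceeds the mean score of random 9-mers
    (uniform residue model) by at least ``contrast`` standard deviations.
    With a small contrast the favored core is not reliably separable from the
    background — the matrix is then just noise with a mild bias.
    """
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    if len(favored_core) != CORE_LENGTH:
        raise ValueError("favored core must be a 9-mer")
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1.0, size=(CORE_LENGTH, 20))
    idx = [CANONICAL_RESIDUES.index(c) for c in favored_core]
    for _ in range(50):
        mean = w.mean(axis=1).sum()
        sd = float(np.sqrt(w.var(axis=1).sum()))
        favored = float(w[np.arange(CORE_LENGTH), idx].sum())
        deficit = (mean + contrast * sd) - favored
        if deficit <= 0:
            break
        for p, r in enumerate(idx):
            w[p, r] += deficit / CORE_LENGTH + 1e-9
    return PocketProfileMatrix(allele=allele, weights=w)


def generate_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[PlantedCore]]:
    """Random proteome with planted cores spliced in (overwriting residues,
    keeping lengths fixed). Returns the records and the realized truth table.

    Raises ``ValueError`` when two planted cores of one protein overlap.
    """
    rng = np.random.default_rng(spec.seed)
    freq = _frequencies(spec.residue_frequencies)
    lo, hi = spec.length_range
    records: list[ProteinRecord] = []
    by_protein: dict[int, list[PlantedCore]] = {}
    for p in spec.planted:
        by_protein.setdefault(p.protein_index, []).append(p)
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_sequence(rng, length, freq))
        occupied: set[int] = set()
        for planted in sorted(by_protein.get(i, []), key=lambda p: p.start):
            span = range(planted.start - 1, planted.start - 1 + CORE_LENGTH)
            if planted.start + CORE_LENGTH - 1 > length:
                raise ValueError(
                    f"planted core at {planted.start} exceeds protein {i} "
                    f"length {length}"
                )
            if occupied & set(span):
                raise ValueError(f"overlapping planted cores in protein {i}")
            occupied |= set(span)
            seq[planted.start - 1 : planted.start - 1 + CORE_LENGTH] = planted.core
        records.append(
            ProteinRecord(
                id=f"SYN{i:04d}",
                description=f"SYN{i:04d} synthetic protein",
                sequence="".join(seq),
            )
        )
    truth = sorted(spec.planted, key=lambda p: (p.protein_index, p.allele, p.start))
    return records, list(truth)


def generate_homolog_family(
    ancestor_length: int,
    n_members: int,
    substitution_rate: float,
    seed: int = 0,
    alphabet: str = CANONICAL_RESIDUES,
    id_prefix: str = "FAM",
) -> list[ProteinRecord]:
    """Family of equal-length homologs from one random ancestor.

    Each member independently substitutes every site with probability
    ``substitution_rate``; the replacement is drawn uniformly over the whole
    alphabet, so a substitution can be silent. Expected pairwise identity for
    alphabet size A is (1 − r·(A−1)/A)² + complementary coincidence terms —
    e.g. 0.5 for r=1 on a two-letter alphabet.
    """
    if not (0.0 <= substitution_rate <= 1.0):
        raise ValueError("substitution rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    A = len(alphabet)
    ancestor = rng.integers(0, A, size=ancestor_length)
    records = []
    for m in range(n_members):
        mutate = rng.random(ancestor_length) < substitution_rate
        repl = rng.integers(0, A, size=ancestor_length)
        derived = np.where(mutate, repl, ancestor)
        seq = "".join(alphabet[i] for i in derived)
        records.append(
            ProteinRecord(
                id=f"{id_prefix}_{m:03d}",
                description=f"{id_prefix}_{m:03d} synthetic homolog",
                sequence=seq,
            )
        )
    return records


def columnwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Per-site identity of two equal-length sequences (no alignment)."""
    if a.length != b.length:
        raise ValueError("columnwise identity needs equal lengths")
    matches = sum(x == y for x, y in zip(a.sequence, b.sequence))
    return matches / a.length


def generate_screening_table(
    path: str | Path,
    n_rows: int,
    ed_range: tuple[float, float],
    allele_range: tuple[int, int],
    seed: int,
    planted_min_id: str,
    planted_max_id: str,
) -> None:
    """Write a screening TSV whose unique ED minimum / maximum rows carry the
    planted ids; parseable by ``load_screening_table``. With one row the
    planted-minimum id is both extreme."""
    if n_rows < 1:
        raise ValueError("need at least one row")
    lo, hi = ed_range
    if not (0.0 <= lo <= hi):
        raise ValueError("bad ED range")
    a_lo, a_hi = allele_range
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, float, int, float]] = []
    if n_rows == 1:
        ids = [planted_min_id]
        eds = [lo]
    else:
        ids = [planted_min_id, planted_max_id] + [
            f"ROW{k:04d}" for k in range(n_rows - 2)
        ]
        margin = (hi - lo) / 10 if hi > lo else 0.0
        interior = rng.uniform(lo + margin, hi - margin, size=n_rows - 2) if (
            n_rows > 2
        ) else np.empty(0)
        eds = [lo, hi, *interior]
    for rid, ed in zip(ids, eds):
        rows.append(
            (
                rid,
                int(rng.integers(1, 15)),
                float(np.round(rng.uniform(0.3, 0.8), 4)),
                int(rng.integers(a_lo, a_hi + 1)),
                float(ed),
            )
        )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "epitope_number", "cpr_value", "allele_number", "ed"])
        for rid, n_ep, cpr, n_al, ed in rows:
            w.writerow([rid, n_ep, f"{cpr:.4f}", n_al, f"{ed:.6f}"])


def write_fasta(records: Sequence[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Plain FASTA writer used by the simulators and the CLI."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_truth_tsv(truth: Sequence[PlantedCore], records: Sequence[ProteinRecord],
                    path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "allele", "start", "core"])
        for t in truth:
            w.writerow([records[t.protein_index].id, t.allele, t.start, t.core])
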