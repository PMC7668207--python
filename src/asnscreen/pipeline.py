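"""End-to-end orchestration: FASTA + matrices + config in, ranked report out.

``run_screening`` wires the stages — intake → clustering → motif/family
labeling → per-allele consensus prediction → core extraction → screening
statistics → optional Pareto ranking — writes every intermediate artifact as
TSV next to the final report, and records the resolved configuration and seed
for provenance. Identical config + seed reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import epitopes, intake, screening, simulate
from .epitopes import (
    DEFAULT_ALLELES,
    DEFAULT_BACKGROUND_SIZE,
    DEFAULT_BINDER_THRESHOLD,
    DEFAULT_CORE_THRESHOLD,
    BackgroundSet,
    PocketProfileMatrix,
)
from .intake import DEFAULT_IDENTITY_CUTOFF, DEFAULT_MAX_LENGTH, DEFAULT_MIN_LENGTH

logger = logging.getLogger(__name__)

#: pipeline stages in execution order, also used for CLI exit codes
STAGES = ("config", "intake", "cluster", "motifs", "predict", "screen", "rank")


class StageError(RuntimeError):
    """A pipeline failure, carrying the stage where it happened."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one screening run."""

    fasta: str
    outdir: str
    matrix_paths: tuple[str, ...] = ()
    motif_file: str | None = None
    min_length: int = DEFAULT_MIN_LENGTH
    max_length: int = DEFAULT_MAX_LENGTH
    reject_ambiguous: bool = True
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF
    binder_threshold: float = DEFAULT_BINDER_THRESHOLD
    core_threshold: float = DEFAULT_CORE_THRESHOLD
    epitope_size: int = screening.DEFAULT_EPITOPE_SIZE
    background_size: int = DEFAULT_BACKGROUND_SIZE
    background_frequencies: str = "uniform"  # "uniform" | "swissprot"
    prediction_table: str | None = None
    antigenicity: str | None = None
    reference_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binder_threshold <= 0 or self.core_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.identity_cutoff <= 1):
            raise ValueError("identity cutoff must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise StageError("config", f"{path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", f"{path}: unknown keys {sorted(unknown)}")
        if "matrix_paths" in data:
            data["matrix_paths"] = tuple(data["matrix_paths"])
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise StageError("config", str(exc)) from exc


@dataclass
class RunSummary:
    """Counts per stage, output paths, and non-fatal warnings."""

    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _load_matrices(
    config: RunConfig,
) -> dict[str, PocketProfileMatrix]:
    matrices: dict[str, PocketProfileMatrix] = {}
    for p in config.matrix_paths:
        m = PocketProfileMatrix.from_tsv(p)
        if m.allele in matrices:
            raise StageError("config", f"duplicate matrix for allele {m.allele}")
        matrices[m.allele] = m
    if not matrices:
        raise StageError("config", "no pocket-profile matrices configured")
    return matrices


def build_backgrounds(
    matrices: Mapping[str, PocketProfileMatrix],
    size: int,
    frequencies: str | np.ndarray,
    seed: int,
) -> dict[str, BackgroundSet]:
    """One calibration background per allele, seeded independently but
    reproducibly (seed stream spawned in sorted-allele order)."""
    if isinstance(frequencies, str):
        if frequencies == "uniform":
            freq = None
        elif frequencies == "swissprot":
            freq = epitopes.swissprot_frequencies()
        else:
            raise StageError("config", f"unknown frequency model {frequencies!r}")
    else:
        freq = frequencies
    alleles = sorted(matrices)
    children = np.random.SeedSequence(seed).spawn(len(alleles))
    return {
        al: epitopes.build_background(
            matrices[al], size=size, frequencies=freq,
            seed=int(children[k].generate_state(1)[0] % (2**31)),
        )
        for k, al in enumerate(alleles)
    }


def run_screening(config: RunConfig) -> RunSummary:
    """Execute the full screening pipeline; returns a stage-count summary.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure are left in place for inspection.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()

    # --- intake ---------------------------------------------------------
    try:
        records = intake.read_fasta(config.fasta)
    except (OSError, intake.FastaFormatError) as exc:
        raise StageError("intake", str(exc)) from exc
    kept, rejected = intake.filter_records(
        records, config.min_length, config.max_length, config.reject_ambiguous
    )
    summary.counts["input"] = len(records)
    summary.counts["kept"] = len(kept)
    summary.counts["rejected"] = len(rejected)
    logger.info("intake: %d records, %d kept", len(records), len(kept))
    if not kept:
        raise StageError("intake", "no records pass the length/ambiguity filter")

    # --- cluster --------------------------------------------------------
    clusters = intake.greedy_cluster(kept, config.identity_cutoff)
    reps = {c.representative_id for c in clusters}
    representatives = [r for r in kept if r.id in reps]
    summary.counts["clusters"] = len(clusters)
    intake.write_clusters_tsv(clusters, out / "clusters.tsv")
    summary.outputs["clusters"] = str(out / "clusters.tsv")
    logger.info("cluster: %d clusters at %.2f", len(clusters), config.identity_cutoff)

    # --- motifs / family ------------------------------------------------
    try:
        motif_sets = intake.load_motif_definitions(config.motif_file)
    except (OSError, ValueError) as exc:
        raise StageError("motifs", str(exc)) from exc
    pf00710 = motif_sets.get(intake.PF00710, [])
    pf06089 = motif_sets.get(intake.PF06089, [])
    all_patterns = pf00710 + pf06089
    hits = []
    families: dict[str, str] = {}
    for rec in representatives:
        hits.extend(intake.scan_motifs(rec, all_patterns))
        if pf00710 and pf06089:
            families[rec.id] = intake.assign_family(rec, pf00710, pf06089)
        else:
            families[rec.id] = intake.UNASSIGNED
    intake.write_motif_hits_tsv(hits, out / "motif_hits.tsv")
    with open(out / "families.tsv", "w") as fh:
        fh.write("protein_id\tfamily\n")
        for rec in representatives:
            fh.write(f"{rec.id}\t{families[rec.id]}\n")
    summary.counts["motif_hits"] = len(hits)
    summary.outputs["motif_hits"] = str(out / "motif_hits.tsv")
    summary.outputs["families"] = str(out / "families.tsv")

    # --- predict --------------------------------------------------------
    matrices = _load_matrices(config)
    backgrounds = build_backgrounds(
        matrices, config.background_size, config.background_frequencies, config.seed
    )
    extra = None
    if config.prediction_table:
        try:
            extra = epitopes.read_prediction_table(config.prediction_table)
        except epitopes.PredictionTableError as exc:
            raise StageError("predict", str(exc)) from exc
    consensus = []
    cores = []
    try:
        for rec in representatives:
            cons = epitopes.predict_epitopes(rec, matrices, backgrounds, extra)
            consensus.extend(cons)
            cores.extend(
                epitopes.extract_cores(
                    cons, matrices, backgrounds,
                    config.binder_threshold, config.core_threshold,
                )
            )
    except (ValueError, epitopes.ConfigurationError) as exc:
        raise StageError("predict", str(exc)) from exc
    epitopes.write_consensus_tsv(consensus, out / "consensus.tsv")
    epitopes.write_cores_tsv(cores, out / "cores.tsv")
    summary.counts["windows_scored"] = len(consensus)
    summary.counts["cores_retained"] = len(cores)
    summary.outputs["consensus"] = str(out / "consensus.tsv")
    summary.outputs["cores"] = str(out / "cores.tsv")
    logger.info("predict: %d consensus records, %d cores", len(consensus), len(cores))

    # --- screen ---------------------------------------------------------
    by_protein: dict[str, list] = {rec.id: [] for rec in representatives}
    for c in cores:
        by_protein[c.protein_id].append(c)
    rows = []
    maps = []
    try:
        for rec in representatives:
            rows.append(
                screening.build_screening_row(
                    rec, by_protein[rec.id], config.epitope_size,
                    family=families.get(rec.id),
                )
            )
            maps.append(screening.density_map(by_protein[rec.id], rec.length))
    except ValueError as exc:
        raise StageError("screen", str(exc)) from exc
    screening.write_screening_tsv(rows, out / "screening.tsv")
    screening.write_density_tsv(maps, out / "density.tsv")
    summary.counts["screened"] = len(rows)
    summary.outputs["screening"] = str(out / "screening.tsv")
    summary.outputs["density"] = str(out / "density.tsv")

    # --- rank (optional) ------------------------------------------------
    ranking = None
    if config.reference_id:
        try:
            if not config.antigenicity:
                raise screening.ScreeningTableError(
                    "ranking requires an antigenicity table"
                )
            anti = screening.load_antigenicity_table(config.antigenicity)
            ranking = screening.select_candidates(
                rows, anti, config.reference_id, family_labels=families
            )
        except (KeyError, OSError, ValueError) as exc:
            raise StageError("rank", str(exc)) from exc
        screening.write_ranking(
            ranking, out / "ranking.tsv", out / "ranking.json"
        )
        summary.counts["pareto_front"] = len(ranking.pareto_front)
        summary.outputs["ranking"] = str(out / "ranking.tsv")

    # --- provenance and report -----------------------------------------
    resolved = dataclasses.asdict(config)
    resolved["matrix_paths"] = list(resolved["matrix_paths"])
    (out / "resolved_config.json").write_text(
        json.dumps(resolved, indent=2, sort_keys=True) + "\n"
    )
    summary.outputs["config"] = str(out / "resolved_config.json")
    report = render_report(summary, rows, ranking)
    (out / "report.md").write_text(report)
    summary.outputs["report"] = str(out / "report.md")
    return summary


def render_report(
    summary: RunSummary,
    rows: Sequence[screening.ScreeningRow],
    ranking: screening.CandidateRanking | None,
) -> str:
    """Human-readable markdown report; every number equals its TSV counterpart."""
    lines = ["# Screening report", "", "## Stage counts", ""]
    for key, val in summary.counts.items():
        lines.append(f"- {key}: {val}")
    lines += ["", "## Screening table", ""]
    lines.append("| id | epitopes | mean CPR | alleles | ED |")
    lines.append("|---|---|---|---|---|")
    for r in sorted(rows, key=lambda r: r.ed):
        lines.append(
            f"| {r.id} | {r.epitope_count} | {r.mean_cpr:.4f} "
            f"| {r.allele_count} | {r.ed:.6f} |"
        )
    if rows:
        best = min(rows, key=lambda r: (r.ed, r.id))
        lines += ["", f"Lowest epitope density: {best.id} (ED {best.ed:.6f})."]
    if ranking is not None:
        lines += ["", "## Candidate ranking", ""]
        above = [
            cid for cid in ranking.ordered_ids
            if ranking.criteria[cid][0] > ranking.criteria[ranking.reference_id][0]
        ]
        lines.append(
            f"Reference {ranking.reference_id}: ED "
            f"{ranking.criteria[ranking.reference_id][0]:.6f}; "
            f"{len(above)} candidates exceed it."
        )
        if ranking.selected:
            lines.append("")
            lines.append("Selected (Pareto-optimal) candidates:")
            for cid in ranking.ordered_ids:
                if cid in ranking.selected:
                    ed, ac, ag = ranking.criteria[cid]
                    lines.append(
                        f"- {cid}: ED {ed:.6f}, {ac} alleles, "
                        f"antigenicity {ag:.4f}"
                    )
        else:
            lines.append("")
            lines.append("No candidates selected.")
    if summary.warnings:
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in summary.warnings]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# synthetic run inputs
# ---------------------------------------------------------------------------

def simulate_run_inputs(
    outdir: str | Path,
    n_proteins: int = 10,
    alleles: Sequence[str] = DEFAULT_ALLELES[:2],
    cores_per_protein: int = 8,
    contrast: float = 12.0,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    seed: int = 0,
) -> RunConfig:
    """Write a complete synthetic input set and return a ready RunConfig.

    The last protein carries no planted cores (pure background control); every
    other protein gets ``cores_per_protein`` planted binder cores alternating
    across the allele panel at evenly spaced, non-overlapping positions. One
    pocket-profile matrix per allele favors that allele's planted core at the
    given contrast. A truth table records every planted (protein, allele,
    start) for recovery checks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    alleles = tuple(alleles)
    favored = {
        al: simulate._random_sequence(rng, epitopes.CORE_LENGTH, np.full(20, 1 / 20))
        for al in alleles
    }
    length_range = (300, 430)
    planted: list[simulate.PlantedCore] = []
    spacing = (length_range[0] - 40) // max(cores_per_protein, 1)
    for i in range(n_proteins - 1):
        for k in range(cores_per_protein):
            allele = alleles[k % len(alleles)]
            planted.append(
                simulate.PlantedCore(
                    protein_index=i,
                    allele=allele,
                    core=favored[allele],
                    start=20 + k * spacing,
                )
            )
    spec = simulate.SyntheticSpec(
        n_proteins=n_proteins,
        length_range=length_range,
        alleles=alleles,
        planted=tuple(planted),
        background_size=background_size,
        seed=int(rng.integers(0, 2**31)),
    )
    records, truth = simulate.generate_proteome(spec)
    simulate.write_fasta(records, outdir / "proteome.fasta")
    simulate.write_truth_tsv(truth, records, outdir / "truth.tsv")
    matrix_paths = []
    for k, al in enumerate(alleles):
        m = simulate.generate_pssm(
            al, favored[al], contrast, seed=int(rng.integers(0, 2**31))
        )
        p = outdir / f"matrix_{k}.tsv"
        m.to_tsv(p)
        matrix_paths.append(str(p))
    with open(outdir / "antigenicity.tsv", "w") as fh:
        fh.write("id\tprobability\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rng.uniform(0.05, 0.95):.4f}\n")
    config = RunConfig(
        fasta=str(outdir / "proteome.fasta"),
        outdir=str(outdir / "results"),
        matrix_paths=tuple(matrix_paths),
        min_length=1,
        max_length=10_000,
        background_size=background_size,
        antigenicity=str(outdir / "antigenicity.tsv"),
        reference_id=records[0].id,
        seed=seed,
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return config
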