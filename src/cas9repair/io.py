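"""Readers and writers for the screen's tabular formats.

The target library is a TSV (target_id, sequence, protospacer_start,
pam_start) with an optional FASTA sidecar; read counts live in a long/tidy
TSV keyed by (cell_line, replicate, timepoint, target_id, outcome, reads)
with outcomes in the ``DEL:a-b`` / ``INS:pos:SEQ`` / ``IND:a-b:SEQ``
serialization.  Outcomes are canonicalized on load, so equivalent raw
records collapse onto one key; all writers emit deterministically sorted
rows so outputs are diff-able across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .outcomes import Indel, TargetSite, canonicalize

__all__ = [
    "SampleKey",
    "OutcomeProfile",
    "ScreenDataset",
    "read_dataset",
    "write_dataset",
    "read_targets",
    "write_targets",
    "write_table",
]

COUNTS_COLUMNS = ["cell_line", "replicate", "timepoint", "target_id", "outcome", "reads"]
LIBRARY_COLUMNS = ["target_id", "sequence", "protospacer_start", "pam_start"]


class SampleKey(NamedTuple):
    """One sequenced sample: a cell line at one replicate and timepoint."""

    cell_line: str
    replicate: int
    timepoint: str


@dataclass
class OutcomeProfile:
    """Read counts per canonical outcome for one (sample, target).

    Counts are integers for sequenced data; probability-valued (float)
    profiles are also supported so that analyses can be run on exact
    generative distributions.
    """

    target_id: str
    counts: dict[Indel, float] = field(default_factory=dict)

    @property
    def total_mutated(self) -> float:
        return sum(self.counts.values())

    def frequencies(self) -> dict[Indel, float]:
        tot = self.total_mutated
        if tot <= 0:
            return {o: 0.0 for o in self.counts}
        return {o: n / tot for o, n in self.counts.items()}


@dataclass
class ScreenDataset:
    """All profiles of one screen plus the target library."""

    targets: dict[str, TargetSite]
    profiles: dict[tuple[SampleKey, str], OutcomeProfile]
    control_line_name: str = "control"

    def __post_init__(self) -> None:
        for (key, tid), prof in self.profiles.items():
            if tid not in self.targets:
                raise ValueError(f"profile references unknown target {tid!r}")
            if prof.target_id != tid:
                raise ValueError(f"profile target_id mismatch for {tid!r}")

    @property
    def cell_lines(self) -> list[str]:
        return sorted({key.cell_line for key, _ in self.profiles})

    @property
    def knockout_lines(self) -> list[str]:
        return [ln for ln in self.cell_lines if ln != self.control_line_name]

    @property
    def sample_keys(self) -> list[SampleKey]:
        return sorted({key for key, _ in self.profiles})

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.targets)

    def profiles_for_line(self, cell_line: str) -> dict[tuple[SampleKey, str], OutcomeProfile]:
        return {
            (key, tid): p
            for (key, tid), p in self.profiles.items()
            if key.cell_line == cell_line
        }


def read_targets(library_path: str | Path) -> dict[str, TargetSite]:
    lib = pd.read_csv(library_path, sep="\t", dtype={"target_id": str, "sequence": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in lib.columns]
    if missing:
        raise ValueError(f"library file missing columns {missing}")
    targets: dict[str, TargetSite] = {}
    for row in lib.itertuples(index=False):
        if row.target_id in targets:
            raise ValueError(f"duplicate target_id {row.target_id!r} in library")
        targets[row.target_id] = TargetSite(
            target_id=row.target_id,
            sequence=row.sequence,
            protospacer_start=int(row.protospacer_start),
            pam_start=int(row.pam_start),
        )
    return targets


def write_targets(
    targets: Mapping[str, TargetSite],
    library_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    rows = [
        (t.target_id, t.sequence, t.protospacer_start, t.pam_start)
        for _, t in sorted(targets.items())
    ]
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(library_path, sep="\t", index=False)
    if fasta_path is not None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(t.sequence), id=t.target_id, description="")
            for _, t in sorted(targets.items())
        ]
        SeqIO.write(records, str(fasta_path), "fasta")


def read_dataset(
    library_path: str | Path,
    counts_path: str | Path,
    control_line: str = "control",
) -> ScreenDataset:
    """Load a screen: targets, then counts with canonicalization and
    aggregation of duplicate (sample, target, outcome) rows."""
    targets = read_targets(library_path)
    counts = pd.read_csv(
        counts_path,
        sep="\t",
        dtype={"cell_line": str, "timepoint": str, "target_id": str, "outcome": str},
    )
    missing = [c for c in COUNTS_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts file missing columns {missing}")
    profiles: dict[tuple[SampleKey, str], OutcomeProfile] = {}
    for i, row in enumerate(counts.itertuples(index=False), start=2):  # 1-based + header
        tid = row.target_id
        target = targets.get(tid)
        if target is None:
            raise ValueError(f"counts row {i}: unknown target {tid!r}")
        try:
            indel = canonicalize(target, Indel.from_key(row.outcome))
        except ValueError as exc:
            raise ValueError(f"counts row {i}: bad outcome {row.outcome!r}: {exc}") from exc
        reads = int(row.reads)
        if reads < 0:
            raise ValueError(f"counts row {i}: negative read count")
        key = SampleKey(row.cell_line, int(row.replicate), row.timepoint)
        prof = profiles.setdefault((key, tid), OutcomeProfile(tid))
        prof.counts[indel] = prof.counts.get(indel, 0) + reads
    return ScreenDataset(targets=targets, profiles=profiles, control_line_name=control_line)


def dataset_to_frame(dataset: ScreenDataset) -> pd.DataFrame:
    rows = []
    for (key, tid), prof in dataset.profiles.items():
        for indel, n in prof.counts.items():
            n_out = int(n) if float(n).is_integer() else n
            rows.append((key.cell_line, key.replicate, key.timepoint, tid, indel.key(), n_out))
    df = pd.DataFrame(rows, columns=COUNTS_COLUMNS)
    return df.sort_values(COUNTS_COLUMNS[:5], kind="mergesort").reset_index(drop=True)


def write_dataset(
    dataset: ScreenDataset,
    library_path: str | Path,
    counts_path: str | Path,
) -> None:
    """Write library + counts TSVs; round-trips through read_dataset."""
    write_targets(dataset.targets, library_path)
    dataset_to_frame(dataset).to_csv(counts_path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path: str | Path, sort_by: Iterable[str] | None = None) -> None:
    """Write any result table as a TSV with deterministic row order."""
    out = table.copy()
    cols = list(sort_by) if sort_by is not None else [
        c for c in out.columns if out[c].dtype == object
    ]
    if cols:
        out = out.sort_values(cols, kind="mergesort")
    out.to_csv(path, sep="\t", index=False)
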